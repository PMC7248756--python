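"""Structure/trajectory I/O and topology resolution.

Coordinates are in Å throughout, residue numbers follow the author
(PDB) numbering of the input file.  Multi-model PDB is the interchange
trajectory format; every frame of a trajectory shares one atom table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as biotite_pdb

__all__ = [
    "Atom",
    "AtomTable",
    "Frame",
    "Trajectory",
    "ProbeSite",
    "HexamerTopology",
    "RigidTransform",
    "StructureError",
    "read_structure",
    "write_structure",
    "expand_assembly",
    "select_atoms",
    "selection_coverage",
    "load_transforms",
]

#: Average atomic masses (amu) for elements that occur in protein/DNA inputs.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "NA": 22.990, "K": 39.098, "CL": 35.45, "CA": 40.078,
}


class StructureError(ValueError):
    """Raised for unreadable or internally inconsistent structure input."""


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    icode: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "atom_name", self.atom_name.strip())


class AtomTable:
    """Column store of per-atom metadata shared by all frames of a trajectory."""

    def __init__(self, chain_id, residue_number, residue_name, atom_name,
                 element, occupancy=None, altloc=None, icode=None, hetero=None):
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.residue_number = np.asarray(residue_number, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype="U4")
        self.atom_name = np.char.strip(np.asarray(atom_name, dtype="U6"))
        self.element = np.char.upper(np.char.strip(np.asarray(element, dtype="U2")))
        n = len(self.chain_id)
        self.occupancy = (np.ones(n) if occupancy is None
                          else np.asarray(occupancy, dtype=float))
        self.altloc = (np.full(n, "", dtype="U1") if altloc is None
                       else np.asarray(altloc, dtype="U1"))
        self.icode = (np.full(n, "", dtype="U1") if icode is None
                      else np.asarray(icode, dtype="U1"))
        self.hetero = (np.zeros(n, dtype=bool) if hetero is None
                       else np.asarray(hetero, dtype=bool))
        for col in (self.residue_number, self.residue_name, self.atom_name,
                    self.element, self.occupancy, self.altloc, self.icode, self.hetero):
            if len(col) != n:
                raise StructureError("atom table columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.chain_id)

    @property
    def n_atoms(self) -> int:
        return len(self)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.isin(self.element, ("H", "D"))

    @property
    def masses(self) -> np.ndarray:
        """Per-atom average masses in amu (unknown elements fall back to carbon)."""
        return np.array([ATOMIC_MASSES.get(el, 12.011) for el in self.element])

    def residue_keys(self):
        """(chain, residue_number, icode) triples, one per atom."""
        return list(zip(self.chain_id, self.residue_number, self.icode))

    def check_unique_keys(self):
        keys = list(zip(self.chain_id, self.residue_number, self.icode,
                        self.atom_name, self.altloc))
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise StructureError(f"duplicate atom key after altloc resolution: {dup}")


class Frame:
    """One set of coordinates for an :class:`AtomTable`."""

    def __init__(self, table: AtomTable, coords: np.ndarray, time_ns: float = 0.0):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(table), 3):
            raise StructureError(
                f"coordinate shape {coords.shape} does not match table of {len(table)} atoms")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates in frame")
        if time_ns < 0:
            raise StructureError("frame time must be non-negative")
        self.table = table
        self.coords = coords
        self.time_ns = float(time_ns)

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def atoms(self) -> Iterator[Atom]:
        t = self.table
        for i in range(len(t)):
            yield Atom(t.chain_id[i], int(t.residue_number[i]), t.residue_name[i],
                       t.atom_name[i], t.element[i], self.coords[i],
                       float(t.occupancy[i]), t.altloc[i], t.icode[i])

    def copy(self) -> "Frame":
        return Frame(self.table, self.coords.copy(), self.time_ns)


class Trajectory:
    """Ordered frames over a single atom table with uniform atom ordering."""

    def __init__(self, table: AtomTable, coords: np.ndarray,
                 times_ns: np.ndarray | None = None,
                 frame_interval_ns: float = 1.0, source: str = ""):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(table), 3):
            raise StructureError(f"bad trajectory coordinate shape {coords.shape}")
        if coords.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if frame_interval_ns <= 0:
            raise StructureError("frame interval must be positive")
        if times_ns is None:
            times_ns = np.arange(coords.shape[0]) * frame_interval_ns
        times_ns = np.asarray(times_ns, dtype=float)
        if len(times_ns) != coords.shape[0]:
            raise StructureError("times length does not match frame count")
        if len(times_ns) > 1 and np.any(np.diff(times_ns) <= 0):
            raise StructureError("frame times must increase monotonically")
        self.table = table
        self.coords = coords
        self.times_ns = times_ns
        self.frame_interval_ns = float(frame_interval_ns)
        self.source = source

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def frame(self, i: int) -> Frame:
        return Frame(self.table, self.coords[i], self.times_ns[i])

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


@dataclass(frozen=True)
class ProbeSite:
    """Named functional-group probe: a residue and its member atom names."""
    residue: int
    atoms: tuple[str, ...]


def _default_probes() -> dict[str, ProbeSite]:
    return {
        "K75_amine": ProbeSite(75, ("NZ",)),
        "R78_guanidino": ProbeSite(78, ("NH1", "NH2", "NE")),
        "D82_carboxylate": ProbeSite(82, ("OD1", "OD2")),
        "D82_backbone_O": ProbeSite(82, ("O",)),
        "ARG43_CA": ProbeSite(43, ("CA",)),
    }


@dataclass
class HexamerTopology:
    """Chain grouping, cross-trimer pairing and domain limits of the hexamer.

    Defaults follow the canonical chain layout: trimers {A,B,C} / {D,E,F},
    nearest cross-trimer pairs A–F, B–E, C–D, rotation centroids over C-domain
    residues 85–149, and domain split N: 1–71 / C: 72–149.
    """
    trimer1_chains: tuple[str, str, str] = ("A", "B", "C")
    trimer2_chains: tuple[str, str, str] = ("D", "E", "F")
    pairing: tuple[tuple[str, str], ...] = (("A", "F"), ("B", "E"), ("C", "D"))
    com_residue_range: tuple[int, int] = (85, 149)
    n_domain_range: tuple[int, int] = (1, 71)
    c_domain_range: tuple[int, int] = (72, 149)
    probe_atoms: dict[str, ProbeSite] = field(default_factory=_default_probes)

    def __post_init__(self):
        t1, t2 = set(self.trimer1_chains), set(self.trimer2_chains)
        if len(t1) != 3 or len(t2) != 3 or (t1 & t2):
            raise StructureError("trimer chain sets must be disjoint triples")
        paired = [c for pair in self.pairing for c in pair]
        if sorted(paired) != sorted(t1 | t2):
            raise StructureError("pairing must cover each chain exactly once")
        for pair in self.pairing:
            if not ((pair[0] in t1 and pair[1] in t2) or (pair[0] in t2 and pair[1] in t1)):
                raise StructureError(f"pair {pair} does not cross the trimer interface")
        for lo, hi in (self.com_residue_range, self.n_domain_range, self.c_domain_range):
            if lo > hi:
                raise StructureError("residue ranges must be non-empty")
        if self.n_domain_range[1] + 1 != self.c_domain_range[0]:
            raise StructureError("N and C domain ranges must partition the chain")

    @property
    def all_chains(self) -> tuple[str, ...]:
        return tuple(self.trimer1_chains) + tuple(self.trimer2_chains)

    def swapped(self) -> "HexamerTopology":
        """Topology with trimer1/trimer2 roles exchanged (pairs reversed)."""
        return HexamerTopology(
            trimer1_chains=self.trimer2_chains,
            trimer2_chains=self.trimer1_chains,
            pairing=tuple((b, a) for a, b in self.pairing),
            com_residue_range=self.com_residue_range,
            n_domain_range=self.n_domain_range,
            c_domain_range=self.c_domain_range,
            probe_atoms=dict(self.probe_atoms),
        )

    def to_json(self, path) -> None:
        doc = {
            "trimer1_chains": list(self.trimer1_chains),
            "trimer2_chains": list(self.trimer2_chains),
            "pairing": [list(p) for p in self.pairing],
            "com_residue_range": list(self.com_residue_range),
            "n_domain_range": list(self.n_domain_range),
            "c_domain_range": list(self.c_domain_range),
            "probe_atoms": {k: {"residue": v.residue, "atoms": list(v.atoms)}
                            for k, v in self.probe_atoms.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path) -> "HexamerTopology":
        doc = json.loads(Path(path).read_text())
        kwargs = {}
        for key in ("trimer1_chains", "trimer2_chains", "com_residue_range",
                    "n_domain_range", "c_domain_range"):
            if key in doc:
                kwargs[key] = tuple(doc[key])
        if "pairing" in doc:
            kwargs["pairing"] = tuple(tuple(p) for p in doc["pairing"])
        if "probe_atoms" in doc:
            kwargs["probe_atoms"] = {
                k: ProbeSite(v["residue"], tuple(v["atoms"]))
                for k, v in doc["probe_atoms"].items()}
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# reading / writing

_ALTLOC_POLICIES = ("occupancy", "first", "all")


def read_structure(path, altloc_policy: str = "occupancy",
                   frame_interval_ns: float = 1.0) -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    One frame is produced per MODEL record (a single frame if there are
    none).  Altloc groups are resolved by ``altloc_policy``: ``occupancy``
    keeps the highest-occupancy location (ties go to the first listed),
    ``first`` keeps the first listed, ``all`` keeps every location.
    """
    path = Path(path)
    if altloc_policy not in _ALTLOC_POLICIES:
        raise ValueError(f"altloc_policy must be one of {_ALTLOC_POLICIES}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = biotite_pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(
            model=None, altloc=altloc_policy,
            extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various error types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError(f"no atoms found in {path}")
    altloc_col = (stack.get_annotation("altloc_id")
                  if "altloc_id" in stack.get_annotation_categories() else None)
    table = AtomTable(
        chain_id=stack.chain_id,
        residue_number=stack.res_id,
        residue_name=stack.res_name,
        atom_name=stack.atom_name,
        element=stack.element,
        occupancy=stack.get_annotation("occupancy"),
        altloc=(np.char.replace(altloc_col, ".", "") if altloc_col is not None else None),
        icode=np.char.strip(stack.ins_code),
        hetero=stack.hetero,
    )
    if altloc_policy != "all":
        table.altloc = np.full(len(table), "", dtype="U1")
    table.check_unique_keys()
    return Trajectory(table, np.asarray(stack.coord, dtype=float),
                      frame_interval_ns=frame_interval_ns, source=str(path))


def write_structure(traj: Trajectory | Frame, path) -> None:
    """Write a trajectory (or single frame) as a multi-model PDB file."""
    if isinstance(traj, Frame):
        traj = Trajectory(traj.table, traj.coords[None, :, :],
                          times_ns=[traj.time_ns], frame_interval_ns=1.0)
    t = traj.table
    n = len(t)
    atoms = struc.AtomArray(n)
    atoms.chain_id = t.chain_id
    atoms.res_id = t.residue_number
    atoms.res_name = t.residue_name
    atoms.atom_name = t.atom_name
    atoms.element = t.element
    atoms.hetero = t.hetero
    atoms.ins_code = t.icode
    atoms.set_annotation("occupancy", t.occupancy)
    atoms.set_annotation("b_factor", np.zeros(n))
    stack = struc.stack([atoms] * traj.n_frames)
    stack.coord = traj.coords
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# assembly expansion

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t with a chain relabeling map."""
    rotation: np.ndarray           # (3, 3)
    translation: np.ndarray        # (3,)
    chain_map: Mapping[str, str]   # original chain id -> new chain id

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tr = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tr)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise StructureError("transform rotation is not orthogonal")
        if np.linalg.det(rot) < 0:
            raise StructureError("transform is a reflection (determinant -1)")

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=1e-9)
                and np.allclose(self.translation, 0, atol=1e-9))


def load_transforms(path) -> list[RigidTransform]:
    """Load assembly transforms from a JSON list of {rotation, translation, chain_map}."""
    doc = json.loads(Path(path).read_text())
    return [RigidTransform(np.array(d["rotation"]), np.array(d["translation"]),
                           dict(d["chain_map"])) for d in doc]


def expand_assembly(frame: Frame, transforms: Sequence[RigidTransform]) -> Frame:
    """Append rigid-transformed, relabeled copies of ``frame``'s chains.

    The original atoms are kept unchanged; each transform contributes
    transformed copies of the chains named in its ``chain_map`` under the
    mapped chain ids.  Identity transforms with an identity chain map are
    skipped (they would collide with the originals).
    """
    t = frame.table
    present = set(t.chain_id)
    tables = [t]
    coords = [frame.coords]
    for tf in transforms:
        for old in tf.chain_map:
            if old not in present:
                raise StructureError(f"transform references unknown chain {old!r}")
        if tf.is_identity and all(k == v for k, v in tf.chain_map.items()):
            continue
        mask = np.isin(t.chain_id, list(tf.chain_map))
        if not mask.any():
            continue
        new_chains = np.array([tf.chain_map[c] for c in t.chain_id[mask]], dtype="U4")
        collisions = set(new_chains) & set(np.concatenate([tb.chain_id for tb in tables]))
        if collisions:
            raise StructureError(f"chain-id collision in assembly expansion: {sorted(collisions)}")
        tables.append(AtomTable(
            chain_id=new_chains,
            residue_number=t.residue_number[mask],
            residue_name=t.residue_name[mask],
            atom_name=t.atom_name[mask],
            element=t.element[mask],
            occupancy=t.occupancy[mask],
            altloc=t.altloc[mask],
            icode=t.icode[mask],
            hetero=t.hetero[mask],
        ))
        coords.append(frame.coords[mask] @ tf.rotation.T + tf.translation)
    merged = AtomTable(
        chain_id=np.concatenate([tb.chain_id for tb in tables]),
        residue_number=np.concatenate([tb.residue_number for tb in tables]),
        residue_name=np.concatenate([tb.residue_name for tb in tables]),
        atom_name=np.concatenate([tb.atom_name for tb in tables]),
        element=np.concatenate([tb.element for tb in tables]),
        occupancy=np.concatenate([tb.occupancy for tb in tables]),
        altloc=np.concatenate([tb.altloc for tb in tables]),
        icode=np.concatenate([tb.icode for tb in tables]),
        hetero=np.concatenate([tb.hetero for tb in tables]),
    )
    return Frame(merged, np.vstack(coords), frame.time_ns)


# ---------------------------------------------------------------------------
# selection

def select_atoms(frame_or_table, chains: Iterable[str] | None = None,
                 residue_range: tuple[int, int] | None = None,
                 atom_names: Iterable[str] | None = None,
                 heavy_only: bool = False,
                 allow_empty: bool = False) -> np.ndarray:
    """Return atom indices matching the selection, in input order.

    Raises :class:`StructureError` for chains absent from the structure, and
    (unless ``allow_empty``) for selections that match nothing.
    """
    table = frame_or_table.table if isinstance(frame_or_table, (Frame, Trajectory)) \
        else frame_or_table
    mask = np.ones(len(table), dtype=bool)
    if chains is not None:
        chains = [chains] if isinstance(chains, str) else list(chains)
        unknown = set(chains) - set(table.chain_id)
        if unknown:
            raise StructureError(f"unknown chain id(s): {sorted(unknown)}")
        mask &= np.isin(table.chain_id, chains)
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (table.residue_number >= lo) & (table.residue_number <= hi)
    if atom_names is not None:
        atom_names = [atom_names] if isinstance(atom_names, str) else list(atom_names)
        mask &= np.isin(table.atom_name, atom_names)
    if heavy_only:
        mask &= ~table.is_hydrogen
    idx = np.flatnonzero(mask)
    if len(idx) == 0 and not allow_empty:
        raise StructureError(
            f"empty selection (chains={chains}, residues={residue_range}, atoms={atom_names})")
    return idx


def selection_coverage(frame_or_table, chains, residue_range) -> float:
    """Fraction of requested residues actually present (crystal gaps skip silently)."""
    table = frame_or_table.table if isinstance(frame_or_table, (Frame, Trajectory)) \
        else frame_or_table
    chains = [chains] if isinstance(chains, str) else list(chains)
    lo, hi = residue_range
    wanted = (hi - lo + 1) * len(chains)
    found = 0
    for ch in chains:
        present = set(table.residue_number[table.chain_id == ch])
        found += len(present & set(range(lo, hi + 1)))
    frac = found / wanted if wanted else 0.0
    if frac < 1.0:
        warnings.warn(f"selection covers {frac:.1%} of requested residues", stacklevel=2)
    return frac
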