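"""Probe-atom distance series, hydrogen-bond occupancy and contact tables.

Hydrogen bonds are scored by heavy-atom donor–acceptor distance alone:
a contact counts when its distance is strictly below 3 Å in strictly more
than 50% of the frames of the scoring window.  Chemically equivalent
group members (NH1/NH2, OD1/OD2) are reduced by a frame-wise minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import HexamerTopology, StructureError, Trajectory, select_atoms
from .window import TimeWindow, resolve_window

__all__ = [
    "AtomSite",
    "ContactSpec",
    "HBondCandidate",
    "HBondRecord",
    "distance_series",
    "occupancy",
    "score_hbond_table",
    "saltbridge_panel",
    "DEFAULT_CUTOFF_A",
    "DEFAULT_MIN_OCCUPANCY",
]

DEFAULT_CUTOFF_A = 3.0
DEFAULT_MIN_OCCUPANCY = 0.5


@dataclass(frozen=True)
class AtomSite:
    """One functional-group site: a chain, residue and its member atom names."""
    chain: str
    residue: int
    atom_names: tuple[str, ...]

    def __post_init__(self):
        if not self.atom_names:
            raise ValueError("atom site needs at least one atom name")

    def resolve(self, traj: Trajectory) -> np.ndarray:
        try:
            return select_atoms(traj, chains=self.chain,
                                residue_range=(self.residue, self.residue),
                                atom_names=list(self.atom_names))
        except StructureError as exc:
            raise StructureError(f"cannot resolve site {self}: {exc}") from exc


@dataclass(frozen=True)
class ContactSpec:
    name: str
    site_a: AtomSite
    site_b: AtomSite
    reduction: str = "min"          # "min" | "specific-pair"

    def __post_init__(self):
        if self.reduction not in ("min", "specific-pair"):
            raise ValueError("reduction must be 'min' or 'specific-pair'")
        if self.reduction == "specific-pair" and (
                len(self.site_a.atom_names) != 1 or len(self.site_b.atom_names) != 1):
            raise ValueError("specific-pair reduction needs single-atom sites")


def distance_series(traj: Trajectory, spec: ContactSpec) -> np.ndarray:
    """Per-frame reduced distance (Å) between the two sites of ``spec``."""
    ia = spec.site_a.resolve(traj)
    ib = spec.site_b.resolve(traj)
    # (F, |a|, |b|) pairwise distances, reduced per frame
    diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return dist.reshape(traj.n_frames, -1).min(axis=1)


def occupancy(series: np.ndarray, cutoff_A: float = DEFAULT_CUTOFF_A,
              window: TimeWindow | tuple[float, float] | None = None,
              times_ns: np.ndarray | None = None) -> float:
    """Fraction of window frames with distance strictly below ``cutoff_A``."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty distance series")
    if window is not None:
        if times_ns is None:
            raise ValueError("windowed occupancy needs the frame times")
        series = series[resolve_window(np.asarray(times_ns), window)]
    return float(np.mean(series < cutoff_A))


@dataclass(frozen=True)
class HBondCandidate:
    """Per-subunit hydrogen-bond template, instantiated once per chain.

    ``placement`` chooses where the acceptor lives relative to the donor
    chain: ``intra`` (same chain) or ``paired`` (the donor chain's
    cross-trimer partner) — the tabulated pairs are not necessarily within
    one subunit.
    """
    name: str
    donor_residue: int
    donor_atoms: tuple[str, ...]
    acceptor_residue: int
    acceptor_atoms: tuple[str, ...]
    placement: str = "intra"        # "intra" | "paired"

    def __post_init__(self):
        if self.placement not in ("intra", "paired"):
            raise ValueError("placement must be 'intra' or 'paired'")


@dataclass
class HBondRecord:
    """Scoring result for one candidate across the six subunit instances."""
    candidate: HBondCandidate
    occupancies: dict[str, float]           # instance label -> occupancy
    scored_instances: tuple[str, ...]
    count_per_hexamer: int
    window: tuple[float, float]
    cutoff_A: float = DEFAULT_CUTOFF_A
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY

    @property
    def scored(self) -> bool:
        return self.count_per_hexamer > 0

    def __post_init__(self):
        if self.count_per_hexamer > 6:
            raise ValueError("count_per_hexamer cannot exceed 6")


def _partner_map(topology: HexamerTopology) -> dict[str, str]:
    m = {}
    for a, b in topology.pairing:
        m[a] = b
        m[b] = a
    return m


def score_hbond_table(traj: Trajectory, topology: HexamerTopology,
                      candidates: list[HBondCandidate],
                      cutoff_A: float = DEFAULT_CUTOFF_A,
                      min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
                      window: TimeWindow | tuple[float, float] | None = None,
                      include_unscored: bool = False) -> list[HBondRecord]:
    """Instantiate each candidate on all six subunits and score occupancies.

    Instances whose residues are missing from the structure are skipped with
    a warning (crystal gaps).  Candidates with zero scored instances are
    omitted unless ``include_unscored`` is set.
    """
    mask = resolve_window(traj.times_ns, window)
    win = (float(traj.times_ns[mask][0]), float(traj.times_ns[mask][-1]))
    partners = _partner_map(topology)
    records = []
    for cand in candidates:
        occupancies: dict[str, float] = {}
        scored = []
        for donor_chain in topology.all_chains:
            acceptor_chain = (donor_chain if cand.placement == "intra"
                              else partners[donor_chain])
            label = f"{donor_chain}->{acceptor_chain}"
            spec = ContactSpec(
                name=f"{cand.name}[{label}]",
                site_a=AtomSite(donor_chain, cand.donor_residue, cand.donor_atoms),
                site_b=AtomSite(acceptor_chain, cand.acceptor_residue, cand.acceptor_atoms),
            )
            try:
                series = distance_series(traj, spec)
            except StructureError:
                warnings.warn(f"skipping unresolvable instance {spec.name}", stacklevel=2)
                continue
            occ = float(np.mean(series[mask] < cutoff_A))
            occupancies[label] = occ
            if occ > min_occupancy:
                scored.append(label)
        rec = HBondRecord(candidate=cand, occupancies=occupancies,
                          scored_instances=tuple(scored),
                          count_per_hexamer=len(scored), window=win,
                          cutoff_A=cutoff_A, min_occupancy=min_occupancy)
        if rec.scored or include_unscored:
            records.append(rec)
    return records


#: Default α4/α4' salt-bridge probe pairs (donor group vs acceptor group).
_SALTBRIDGE_PROBES = (
    ("R78_guanidino", "D82_carboxylate"),
    ("K75_amine", "D82_carboxylate"),
    ("K75_amine", "D82_backbone_O"),
)


def saltbridge_panel(traj: Trajectory, topology: HexamerTopology,
                     probes=_SALTBRIDGE_PROBES) -> pd.DataFrame:
    """Distance series for the cross-trimer salt-bridge probes.

    For each of the three nearest cross-trimer pairs the probe distances are
    computed in both directions (X donor vs Y acceptor and vice versa).
    Columns are labelled ``"<probe_a>:X-<probe_b>:Y"``; missing probe atoms
    drop the affected column with a warning.
    """
    data: dict[str, np.ndarray] = {}
    for probe_a, probe_b in probes:
        pa = topology.probe_atoms[probe_a]
        pb = topology.probe_atoms[probe_b]
        for x, y in topology.pairing:
            for donor_chain, acceptor_chain in ((x, y), (y, x)):
                label = f"{probe_a}:{donor_chain}-{probe_b}:{acceptor_chain}"
                spec = ContactSpec(
                    name=label,
                    site_a=AtomSite(donor_chain, pa.residue, pa.atoms),
                    site_b=AtomSite(acceptor_chain, pb.residue, pb.atoms),
                )
                try:
                    data[label] = distance_series(traj, spec)
                except StructureError:
                    warnings.warn(f"missing probe atoms for {label}; column skipped",
                                  stacklevel=2)
    return pd.DataFrame(data, index=pd.Index(traj.times_ns, name="time_ns"))
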