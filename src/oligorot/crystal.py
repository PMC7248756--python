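"""Crystal-structure geometry benchmarks.

Computes the reference geometric observables (internal trimer-trimer
rotation angles, paired N-domain marker distances, functional-group
contact distances) from deposited PDB entries placed under a data
directory:

    1F9N.pdb  intact apo hexamer (chains A-F)
    2P5M.pdb  holo C-domain, refined as a trimer; the hexamer is built
              from user-supplied transforms in 2P5M_assembly.json unless
              the file already contains six protein chains
    2P5L.pdb  two DNA-bound N-terminal domains
    3FHZ.pdb / 3BUE.pdb  divergent-family holo/apo hexamers

All files are plain RCSB downloads; nothing is fetched over the network.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .rotation import infer_topology, rotation_angle
from .structio import (Frame, StructureError, expand_assembly, load_transforms,
                       read_structure, select_atoms)

__all__ = ["crystal_targets", "internal_rotation", "min_group_distance",
           "residue_marker_positions"]

#: Cα residue window used for subunit centroids, per structure family.
COM_RANGES = {
    "1F9N": (85, 149),
    "2P5M": (85, 149),
    "3FHZ": (107, 170),
    "3BUE": (107, 170),
}


def _load_frame(data_dir: Path, entry: str) -> Frame:
    traj = read_structure(Path(data_dir) / f"{entry}.pdb")
    return traj.frame(0)


def _protein_chains_with_ca(frame: Frame, residue_range) -> list[str]:
    lo, hi = residue_range
    t = frame.table
    counts = {}
    for ch in sorted(set(t.chain_id)):
        n = int(np.sum((t.chain_id == ch) & (t.atom_name == "CA")
                       & (t.residue_number >= lo) & (t.residue_number <= hi)))
        if n >= 3:
            counts[ch] = n
    return sorted(counts, key=lambda c: (-counts[c], c))


def hexamer_frame(data_dir: Path, entry: str) -> Frame:
    """Load ``entry`` and, for trimer depositions, expand to the hexamer."""
    frame = _load_frame(data_dir, entry)
    com_range = COM_RANGES.get(entry, (85, 149))
    chains = _protein_chains_with_ca(frame, com_range)
    if len(chains) >= 6:
        return frame
    tf_path = Path(data_dir) / f"{entry}_assembly.json"
    if not tf_path.exists():
        raise StructureError(
            f"{entry} holds {len(chains)} subunit chains; assembly transforms "
            f"required at {tf_path}")
    return expand_assembly(frame, load_transforms(tf_path))


def internal_rotation(data_dir: Path, entry: str) -> float:
    """Unsigned internal trimer-trimer rotation angle of a hexamer (deg)."""
    frame = hexamer_frame(data_dir, entry)
    com_range = COM_RANGES.get(entry, (85, 149))
    chains = _protein_chains_with_ca(frame, com_range)
    if len(chains) > 6:
        warnings.warn(f"{entry}: using the 6 largest of {len(chains)} chains")
        chains = sorted(chains[:6])
    topo = infer_topology(frame, com_residue_range=com_range, chains=chains)
    mean, _ = rotation_angle(frame, topo)
    return abs(mean)


def residue_marker_positions(frame: Frame, residue: int,
                             atom: str = "CA") -> dict[str, np.ndarray]:
    """Position of ``residue``'s ``atom`` for every chain that has it."""
    out = {}
    for ch in sorted(set(frame.table.chain_id)):
        idx = select_atoms(frame, chains=ch, residue_range=(residue, residue),
                           atom_names=atom, allow_empty=True)
        if len(idx):
            out[ch] = frame.coords[idx[0]]
    return out


def min_group_distance(frame: Frame, residue_a: int, atoms_a, residue_b: int,
                       atoms_b, exclude_same_chain: bool = False) -> float:
    """Global minimum distance between two residue atom groups over all
    chain combinations."""
    t = frame.table
    best = np.inf
    chains = sorted(set(t.chain_id))
    for ca in chains:
        ia = select_atoms(frame, chains=ca, residue_range=(residue_a, residue_a),
                          atom_names=list(atoms_a), allow_empty=True)
        if not len(ia):
            continue
        for cb in chains:
            if exclude_same_chain and ca == cb:
                continue
            ib = select_atoms(frame, chains=cb,
                              residue_range=(residue_b, residue_b),
                              atom_names=list(atoms_b), allow_empty=True)
            if not len(ib):
                continue
            d = np.linalg.norm(frame.coords[ia][:, None] - frame.coords[ib][None],
                               axis=-1).min()
            best = min(best, float(d))
    if not np.isfinite(best):
        raise StructureError(
            f"no atoms found for residues {residue_a}/{residue_b}")
    return best


def crystal_targets(data_dir) -> dict[str, float]:
    """All crystal geometry benchmarks; raises if an input is missing."""
    data_dir = Path(data_dir)
    values: dict[str, float] = {}

    values["t1"] = internal_rotation(data_dir, "1F9N")
    values["t2"] = abs(internal_rotation(data_dir, "1F9N")
                       - internal_rotation(data_dir, "2P5M"))
    values["t3"] = abs(internal_rotation(data_dir, "3FHZ")
                       - internal_rotation(data_dir, "3BUE"))

    # paired N-domain marker distance in the DNA co-crystal (two domains)
    frame_2p5l = _load_frame(data_dir, "2P5L")
    markers = residue_marker_positions(frame_2p5l, 43)
    if len(markers) < 2:
        raise StructureError("2P5L: need residue-43 CA in two chains")
    pos = list(markers.values())
    pairs = [np.linalg.norm(pos[i] - pos[j])
             for i in range(len(pos)) for j in range(i + 1, len(pos))]
    values["t4"] = float(min(pairs))

    # nearest cross-trimer residue-43 marker pair in the intact apo hexamer
    frame_1f9n = _load_frame(data_dir, "1F9N")
    topo = infer_topology(frame_1f9n, com_residue_range=COM_RANGES["1F9N"])
    m = residue_marker_positions(frame_1f9n, 43)
    cross = [np.linalg.norm(m[a] - m[b])
             for a in topo.trimer1_chains for b in topo.trimer2_chains
             if a in m and b in m]
    values["t5"] = float(min(cross))

    # minimum guanidino-carboxylate distance in the holo C-domain assembly
    frame_2p5m = hexamer_frame(data_dir, "2P5M")
    values["t6"] = min_group_distance(frame_2p5m, 78, ("NH1", "NH2", "NE"),
                                      82, ("OD1", "OD2"))
    return values
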