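"""Superposition, RMSD/RMSF profiles, B-factor conversion and N-domain
pair distances.

Superposition is unweighted least squares (Kabsch, proper rotations
only).  RMSF is computed for heavy atoms about the window-mean structure
after an iterative fit, reported per residue, and convertible to
crystallographic B-factors via B = (8π²/3)·RMSF².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structio import Frame, HexamerTopology, StructureError, Trajectory, select_atoms
from .window import TimeWindow, resolve_window

__all__ = [
    "FluctuationProfile",
    "DomainPairDistanceSeries",
    "kabsch",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "rmsf_to_bfactor",
    "domain_pair_distances",
    "BFACTOR_PREFACTOR",
]

#: B = (8π²/3) · RMSF²
BFACTOR_PREFACTOR = 8.0 * np.pi ** 2 / 3.0

#: VMD presentation scaling reported alongside B-factor maps (metadata only).
BFACTOR_COLOR_SCALE = {"offset": 0.10, "midpoint": 0.28}


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t with R@x+t ≈ reference.

    Requires ≥ 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise StructureError("superposition needs matching selections of >= 3 atoms")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    # degenerate (collinear) point sets leave the rotation underdetermined
    if s[1] < 1e-9 * max(s[0], 1e-12):
        raise StructureError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    return rot, trans


def superpose(mobile: Frame, reference: Frame,
              fit_selection: np.ndarray) -> tuple[Frame, float]:
    """Rigidly fit ``mobile`` onto ``reference`` over ``fit_selection``.

    Returns the transformed frame (all atoms moved) and the fitted RMSD
    over the fit atoms.
    """
    fit_selection = np.asarray(fit_selection, dtype=int)
    rot, trans = kabsch(mobile.coords[fit_selection], reference.coords[fit_selection])
    moved = mobile.coords @ rot.T + trans
    delta = moved[fit_selection] - reference.coords[fit_selection]
    rmsd = float(np.sqrt((delta ** 2).sum(axis=1).mean()))
    return Frame(mobile.table, moved, mobile.time_ns), rmsd


def _fit_coords(coords: np.ndarray, ref: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    """Fit every frame of (F, N, 3) coords onto ``ref`` over ``fit_idx``."""
    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        rot, trans = kabsch(coords[i, fit_idx], ref[fit_idx])
        out[i] = coords[i] @ rot.T + trans
    return out


def rmsd_series(traj: Trajectory, reference: Frame,
                fit_selection: np.ndarray,
                measure_selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after fitting on ``fit_selection``.

    Distinct fit and measure selections reproduce the whole-complex-fit vs
    own-domain-fit contrast.
    """
    fit_idx = np.asarray(fit_selection, dtype=int)
    meas_idx = fit_idx if measure_selection is None else np.asarray(measure_selection, dtype=int)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rot, trans = kabsch(traj.coords[i, fit_idx], reference.coords[fit_idx])
        moved = traj.coords[i, meas_idx] @ rot.T + trans
        delta = moved - reference.coords[meas_idx]
        out[i] = np.sqrt((delta ** 2).sum(axis=1).mean())
    return out


@dataclass
class FluctuationProfile:
    """Per-residue heavy-atom RMSF (Å) with derived B-factors (Å²)."""
    residue_index: np.ndarray
    rmsf_A: np.ndarray
    aggregation: str                         # "mean-over-monomers" | "max-over-monomers"
    window: tuple[float, float]
    per_monomer: dict[str, np.ndarray] | None = None
    color_scale: dict = None

    def __post_init__(self):
        if np.any(self.rmsf_A < 0):
            raise ValueError("RMSF must be non-negative")
        if self.color_scale is None:
            self.color_scale = dict(BFACTOR_COLOR_SCALE)

    @property
    def bfactor_A2(self) -> np.ndarray:
        return rmsf_to_bfactor(self.rmsf_A)


def rmsf_to_bfactor(rmsf_A: np.ndarray) -> np.ndarray:
    """Convert RMSF (Å) to crystallographic B-factors: B = (8π²/3)·RMSF²."""
    return BFACTOR_PREFACTOR * np.square(np.asarray(rmsf_A, dtype=float))


def _iterative_mean_fit(coords: np.ndarray, fit_idx: np.ndarray,
                        passes: int = 2) -> np.ndarray:
    """Fit frames to their arithmetic mean, recompute the mean, repeat."""
    ref = coords.mean(axis=0)
    fitted = coords
    for _ in range(passes):
        fitted = _fit_coords(fitted, ref, fit_idx)
        new_ref = fitted.mean(axis=0)
        if np.abs(new_ref - ref).max() < 1e-6:
            ref = new_ref
            break
        ref = new_ref
    return fitted


def rmsf_profile(traj: Trajectory, topology: HexamerTopology | None = None,
                 window: TimeWindow | tuple[float, float] | None = None,
                 aggregation: str = "mean",
                 chains=None) -> FluctuationProfile:
    """Heavy-atom RMSF per residue, aggregated over the six monomers.

    Each window frame is superposed on the window-mean structure over all
    selected heavy atoms (iterative mean fit), per-atom RMSF is averaged
    within each residue, and residues are aggregated across monomers by
    ``aggregation`` ("mean", the figure convention, or "max", the text's).
    """
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    mask = resolve_window(traj.times_ns, window)
    win = (float(traj.times_ns[mask][0]), float(traj.times_ns[mask][-1]))
    if chains is None:
        chains = list(topology.all_chains) if topology is not None \
            else sorted(set(traj.table.chain_id))
    heavy = select_atoms(traj, chains=chains, heavy_only=True)
    sub = traj.coords[mask][:, heavy]
    fitted = _iterative_mean_fit(sub, np.arange(len(heavy)))
    mean_pos = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))

    table = traj.table
    chain_col = table.chain_id[heavy]
    res_col = table.residue_number[heavy]
    per_monomer: dict[str, np.ndarray] = {}
    residues = np.unique(res_col)
    stacked = np.full((len(chains), len(residues)), np.nan)
    for ci, ch in enumerate(chains):
        vals = np.full(len(residues), np.nan)
        for ri, res in enumerate(residues):
            m = (chain_col == ch) & (res_col == res)
            if m.any():
                vals[ri] = per_atom[m].mean()
        per_monomer[ch] = vals
        stacked[ci] = vals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN residues
        agg = (np.nanmean(stacked, axis=0) if aggregation == "mean"
               else np.nanmax(stacked, axis=0))
    keep = ~np.isnan(agg)
    return FluctuationProfile(
        residue_index=residues[keep],
        rmsf_A=agg[keep],
        aggregation=f"{aggregation}-over-monomers",
        window=win,
        per_monomer={ch: v[keep] for ch, v in per_monomer.items()},
    )


@dataclass
class DomainPairDistanceSeries:
    """Cα–Cα distance time series of one cross-trimer N-domain pair."""
    pair_label: str
    times_ns: np.ndarray
    distance_A: np.ndarray
    competence_threshold_A: float = 26.0
    canonical: bool = False

    def __post_init__(self):
        if np.any(self.distance_A <= 0):
            raise ValueError("pair distances must be positive")

    @property
    def flagged(self) -> np.ndarray:
        """Frames at or below the DNA-binding-competence threshold."""
        return self.distance_A <= self.competence_threshold_A


def domain_pair_distances(traj: Trajectory, topology: HexamerTopology,
                          residue: int = 43, atom: str = "CA",
                          competence_threshold_A: float = 26.0
                          ) -> list[DomainPairDistanceSeries]:
    """Residue-``residue`` Cα–Cα distances for all 9 inter-trimer chain pairs.

    Chains lacking the residue are skipped with a warning.  The three
    canonical nearest pairs of the topology are tagged ``canonical``.
    """
    positions: dict[str, np.ndarray] = {}
    for ch in topology.all_chains:
        try:
            idx = select_atoms(traj, chains=ch, residue_range=(residue, residue),
                               atom_names=atom)
        except StructureError:
            warnings.warn(f"residue {residue} {atom} missing in chain {ch}; "
                          f"pairs involving it are skipped", stacklevel=2)
            continue
        positions[ch] = traj.coords[:, idx[0], :]
    canonical = {frozenset(p) for p in topology.pairing}
    out = []
    for a in topology.trimer1_chains:
        for b in topology.trimer2_chains:
            if a not in positions or b not in positions:
                continue
            dist = np.linalg.norm(positions[a] - positions[b], axis=1)
            out.append(DomainPairDistanceSeries(
                pair_label=f"{a}-{b}",
                times_ns=traj.times_ns.copy(),
                distance_A=dist,
                competence_threshold_A=competence_threshold_A,
                canonical=frozenset((a, b)) in canonical,
            ))
    return out
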