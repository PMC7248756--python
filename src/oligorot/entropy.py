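"""Quasi-harmonic configurational entropy, the Schlitter upper bound,
entropy differences from covariance determinants, and PCA of atomic
fluctuations.

All entropies are reported per mole (R-based) in J mol⁻¹ K⁻¹.  The
covariance of Cartesian fluctuations is accumulated in Å² (amu·Å² when
mass-weighted) and converted to SI inside the entropy formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .structio import StructureError, Trajectory
from .window import TimeWindow, resolve_window

__all__ = [
    "CovarianceModel",
    "EntropyResult",
    "covariance",
    "schlitter_entropy",
    "quasiharmonic_entropy",
    "entropy_difference",
    "pca_modes",
    "project_trajectory",
]

_AMU_A2_TO_SI = constants.atomic_mass * 1e-20     # amu·Å² -> kg·m²
_R = constants.R                                   # J mol⁻¹ K⁻¹


@dataclass
class CovarianceModel:
    """Covariance of Cartesian fluctuations over a selection of N atoms."""
    matrix: np.ndarray                 # (3N, 3N), Å² or amu·Å² if mass-weighted
    masses: np.ndarray                 # (N,) amu
    mass_weighted: bool
    n_frames: int
    temperature_K: float = 300.0
    selection: np.ndarray | None = None
    fitted: bool = False
    fit_reference: np.ndarray | None = field(default=None, repr=False)  # (N, 3)
    window: tuple[float, float] | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 3:
            raise ValueError(f"covariance must be square 3Nx3N, got {m.shape}")
        scale = max(np.abs(m).max(), 1e-30)
        if np.abs(m - m.T).max() > 1e-10 * scale:
            raise ValueError("covariance matrix is not symmetric")
        self.matrix = 0.5 * (m + m.T)
        self.masses = np.asarray(self.masses, dtype=float)
        if 3 * len(self.masses) != m.shape[0]:
            raise ValueError("need one mass per atom (3 coordinates each)")

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Ascending eigenvalue spectrum; trips on significant negatives."""
        lam = np.linalg.eigvalsh(self.matrix)
        tol = 1e-10 * max(np.trace(self.matrix), 1e-30)
        if lam[0] < -tol:
            raise ValueError(f"covariance has negative eigenvalue {lam[0]:.3e}")
        return np.clip(lam, 0.0, None)

    def default_dropped_modes(self) -> int:
        """6 rigid-body null modes when the frames were fitted, else 0."""
        return 6 if self.fitted else 0


@dataclass
class EntropyResult:
    method: str                        # "schlitter" | "quasiharmonic" | "determinant-difference"
    value: float                       # J mol⁻¹ K⁻¹
    dropped_modes: int = 0
    per_mode_contributions: np.ndarray | None = None
    temperature_K: float = 300.0

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("entropy value must be finite")


def covariance(traj: Trajectory, selection: np.ndarray,
               window: TimeWindow | tuple[float, float] | None = None,
               mass_weighted: bool = True, fit: bool = True,
               temperature_K: float = 300.0,
               masses: np.ndarray | None = None) -> CovarianceModel:
    """Covariance of the selected atoms' Cartesian fluctuations.

    Frames inside the window are optionally superposed on the window-mean
    structure (iterative fit) before the second moments are accumulated.
    """
    from .fluct import _iterative_mean_fit  # local import avoids a cycle

    selection = np.asarray(selection, dtype=int)
    mask = resolve_window(traj.times_ns, window)
    win = (float(traj.times_ns[mask][0]), float(traj.times_ns[mask][-1]))
    sub = traj.coords[mask][:, selection]
    n_frames, n_atoms = sub.shape[0], sub.shape[1]
    if n_frames < 3 * n_atoms:
        warnings.warn(
            f"{n_frames} frames for {3 * n_atoms} coordinates: covariance is "
            "rank-deficient", stacklevel=2)
    if fit and n_atoms >= 3:
        sub = _iterative_mean_fit(sub, np.arange(n_atoms))
    mean = sub.mean(axis=0)
    x = (sub - mean).reshape(n_frames, 3 * n_atoms)
    sigma = x.T @ x / n_frames
    if masses is None:
        masses = traj.table.masses[selection]
    masses = np.asarray(masses, dtype=float)
    if mass_weighted:
        w = np.sqrt(np.repeat(masses, 3))
        sigma = sigma * np.outer(w, w)
    return CovarianceModel(matrix=sigma, masses=masses, mass_weighted=mass_weighted,
                           n_frames=n_frames, temperature_K=temperature_K,
                           selection=selection, fitted=bool(fit and n_atoms >= 3),
                           fit_reference=mean, window=win)


def _retained(lam_ascending: np.ndarray, dropped: int) -> np.ndarray:
    if dropped < 0 or dropped >= len(lam_ascending):
        raise ValueError(f"cannot drop {dropped} of {len(lam_ascending)} modes")
    return lam_ascending[dropped:]


def schlitter_entropy(cov: CovarianceModel,
                      dropped_modes: int | None = None) -> EntropyResult:
    """Schlitter upper bound: S = (R/2) Σ ln(1 + k_B·T·e²/ħ² · λᵢ).

    λᵢ are eigenvalues of the mass-weighted covariance; the smallest
    ``dropped_modes`` (default 6 after rigid-body fitting) are excluded.
    """
    if not cov.mass_weighted:
        raise ValueError("Schlitter entropy needs a mass-weighted covariance")
    if dropped_modes is None:
        dropped_modes = cov.default_dropped_modes()
    lam = _retained(cov.eigenvalues(), dropped_modes) * _AMU_A2_TO_SI
    kT = constants.k * cov.temperature_K
    arg = kT * np.e ** 2 / constants.hbar ** 2 * lam
    per_mode = 0.5 * _R * np.log1p(arg)
    return EntropyResult(method="schlitter", value=float(per_mode.sum()),
                         dropped_modes=dropped_modes,
                         per_mode_contributions=per_mode,
                         temperature_K=cov.temperature_K)


def quasiharmonic_entropy(cov: CovarianceModel,
                          dropped_modes: int | None = None,
                          stiff_mode_tol: float = 0.0) -> EntropyResult:
    """Quasi-harmonic entropy of the effective oscillators ωᵢ = √(k_B·T/λᵢ).

    Per retained mode, with αᵢ = ħωᵢ/(k_B·T):
    S = R Σ [ αᵢ/(e^{αᵢ} − 1) − ln(1 − e^{−αᵢ}) ].
    Retained modes must have λᵢ > 0 (a zero eigenvalue means an infinitely
    stiff oscillator whose contribution would be 0, but indicates that the
    rigid-body null space was not dropped).
    """
    if not cov.mass_weighted:
        raise ValueError("quasi-harmonic entropy needs a mass-weighted covariance")
    if dropped_modes is None:
        dropped_modes = cov.default_dropped_modes()
    lam = _retained(cov.eigenvalues(), dropped_modes) * _AMU_A2_TO_SI
    if np.any(lam <= stiff_mode_tol):
        raise ValueError("non-positive eigenvalue among retained modes; "
                         "increase dropped_modes")
    kT = constants.k * cov.temperature_K
    alpha = constants.hbar * np.sqrt(kT / lam) / kT
    per_mode = _R * (alpha / np.expm1(alpha) - np.log(-np.expm1(-alpha)))
    return EntropyResult(method="quasiharmonic", value=float(per_mode.sum()),
                         dropped_modes=dropped_modes,
                         per_mode_contributions=per_mode,
                         temperature_K=cov.temperature_K)


def entropy_difference(cov_a: CovarianceModel, cov_b: CovarianceModel,
                       dropped_modes: int | None = None) -> float:
    """ΔS = (R/2)·ln(det σ_a / det σ_b) over the common retained modes.

    Determinants are pseudo-determinants over the retained eigenvalues,
    evaluated as sums of log-eigenvalues.  Returned per mole, J mol⁻¹ K⁻¹.
    """
    if cov_a.dim != cov_b.dim:
        raise ValueError(f"dimensionality mismatch: {cov_a.dim} vs {cov_b.dim}")
    if dropped_modes is None:
        dropped_modes = max(cov_a.default_dropped_modes(), cov_b.default_dropped_modes())
    la = _retained(cov_a.eigenvalues(), dropped_modes)
    lb = _retained(cov_b.eigenvalues(), dropped_modes)
    if np.any(la <= 0) or np.any(lb <= 0):
        raise ValueError("zero eigenvalue among retained modes; increase dropped_modes")
    return float(0.5 * _R * (np.sum(np.log(la)) - np.sum(np.log(lb))))


def pca_modes(cov: CovarianceModel, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``k`` eigenpairs of the covariance, eigenvalues non-increasing.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvectors as columns.
    """
    if k < 1 or k > cov.dim:
        raise ValueError(f"k must be in [1, {cov.dim}]")
    lam, vec = np.linalg.eigh(cov.matrix)
    order = np.argsort(lam)[::-1][:k]
    return lam[order], vec[:, order]


def project_trajectory(traj: Trajectory, cov: CovarianceModel,
                       modes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project (fitted, centered) coordinates of ``cov``'s selection on modes.

    Returns ``(projections, argmin_frames, argmax_frames)`` where
    projections has shape (n_frames, n_modes) and the index arrays locate
    the extreme frame along each mode.
    """
    from .fluct import _fit_coords

    if cov.selection is None:
        raise ValueError("covariance model carries no atom selection")
    modes = np.asarray(modes, dtype=float)
    if modes.ndim == 1:
        modes = modes[:, None]
    if modes.shape[0] != cov.dim:
        raise ValueError("mode dimensionality does not match the covariance")
    sub = traj.coords[:, cov.selection]
    ref = cov.fit_reference
    if cov.fitted and ref is not None:
        sub = _fit_coords(sub, ref, np.arange(sub.shape[1]))
    mean = ref if ref is not None else sub.mean(axis=0)
    x = (sub - mean).reshape(sub.shape[0], -1)
    if cov.mass_weighted:
        x = x * np.sqrt(np.repeat(cov.masses, 3))
    proj = x @ modes
    return proj, proj.argmin(axis=0), proj.argmax(axis=0)
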