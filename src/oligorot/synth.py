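"""Ground-truthed synthetic inputs for every analysis module.

Generates rigid-body hexamer pseudo-trajectories with an injected,
exactly known trimer-trimer rotation time course, per-subunit wobble,
functional-group probe atoms whose cross-trimer distances close with
rotation, mobile N-domain markers, and Gaussian pseudo-trajectories
with a prescribed covariance for entropy validation.

Geometry: two C3-symmetric trimers of rigid subunits stacked on the z
axis (chains A,B,C above, D,E,F below; F under A, E under B, D under C).
Each subunit is a deterministic pseudo-Cα blob; the lower trimer is
rotated about the axis by θ(t) = θ₀ + (θ_eq − θ₀)(1 − e^{−t/τ}) + ε(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomTable, HexamerTopology, StructureError, Trajectory

__all__ = [
    "RotationCourse",
    "SyntheticSpec",
    "GroundTruth",
    "generate_hexamer_trajectory",
    "generate_contact_trajectory",
    "generate_gaussian_trajectory",
]

_CHAIN_AZIMUTH_DEG = {"A": 90.0, "B": 210.0, "C": 330.0,
                      "F": 90.0, "E": 210.0, "D": 330.0}
_TOP_CHAINS = ("A", "B", "C")
_BOTTOM_CHAINS = ("D", "E", "F")


@dataclass(frozen=True)
class RotationCourse:
    """θ(t) = θ₀ + (θ_eq − θ₀)(1 − e^{−t/τ}) + ε(t), ε optional AR(1) noise."""
    theta0_deg: float = 0.0
    theta_eq_deg: float = 0.0
    tau_ns: float = 100.0
    noise_deg: float = 0.0
    noise_ar1: float = 0.8

    def evaluate(self, times_ns: np.ndarray,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        t = np.asarray(times_ns, dtype=float)
        if self.tau_ns > 0:
            theta = self.theta0_deg + (self.theta_eq_deg - self.theta0_deg) * (
                1.0 - np.exp(-t / self.tau_ns))
        else:
            theta = np.full_like(t, self.theta_eq_deg)
        if self.noise_deg > 0:
            if rng is None:
                raise ValueError("noisy rotation course needs an RNG")
            theta = theta + _ar1(rng, len(t), self.noise_deg, self.noise_ar1)
        return theta


@dataclass(frozen=True)
class SyntheticSpec:
    triangle_radius_A: float = 20.0
    axial_separation_A: float = 25.0
    rotation_course: RotationCourse = field(default_factory=RotationCourse)
    wobble_A: float = 0.0
    wobble_ar1: float = 0.8
    n_frames: int = 100
    frame_interval_ns: float = 1.0
    ndomain_offset_A: float = 12.0
    ndomain_azimuth_offset_deg: float = 25.0
    ndomain_jitter_A: float = 0.0
    probe_radius_A: float = 15.0
    theta_contact_deg: float = 22.0
    contact_distance_A: float = 3.0
    atom_jitter_A: float = 0.0
    asymmetry_A: float = 0.0
    ndomain_residues: tuple[int, int] = (1, 71)
    cdomain_residues: tuple[int, int] = (85, 149)
    seed: int = 0

    def __post_init__(self):
        for name in ("triangle_radius_A", "axial_separation_A", "probe_radius_A",
                     "contact_distance_A", "frame_interval_ns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.probe_radius_A > self.triangle_radius_A:
            raise StructureError("probe radius exceeds triangle radius (steric nonsense)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


@dataclass
class GroundTruth:
    """Exact per-frame values injected by the generator (noise-free geometry)."""
    times_ns: np.ndarray
    rotation_deg: np.ndarray                       # (F,)
    subunit_centroids: dict[str, np.ndarray]       # chain -> (F, 3)
    probe_min_distance: dict[str, np.ndarray]      # "R78:X-D82:Y" -> (F,)
    arg43_pair_distance: dict[str, np.ndarray]     # "X-Y" -> (F,)
    rmsf_per_residue_A: float | None = None        # σ√3 for pure atom jitter

    def __post_init__(self):
        n = len(self.times_ns)
        assert len(self.rotation_deg) == n
        for arr in self.subunit_centroids.values():
            assert arr.shape == (n, 3)


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float,
         shape: tuple = ()) -> np.ndarray:
    """Stationary AR(1) series with marginal std ``sigma``."""
    out = np.empty((n,) + shape)
    out[0] = rng.normal(0.0, sigma, size=shape)
    scale = sigma * np.sqrt(1.0 - rho ** 2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + rng.normal(0.0, scale, size=shape)
    return out


def _rz(angles_rad: np.ndarray) -> np.ndarray:
    """(F, 3, 3) rotation matrices about z."""
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    out = np.zeros(angles_rad.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _blob(n: int, local_radius: float = 4.0, rise: float = 0.12,
          turn: float = 0.35) -> np.ndarray:
    """Deterministic compact helical blob of n points, centroid at origin."""
    i = np.arange(n, dtype=float)
    pts = np.stack([local_radius * np.cos(turn * i),
                    local_radius * np.sin(turn * i),
                    rise * (i - (n - 1) / 2.0)], axis=1)
    return pts - pts.mean(axis=0)


def _probe_layout(spec: SyntheticSpec) -> dict[str, float]:
    """Azimuthal probe offsets (rad) solving the contact condition."""
    c, rp = spec.contact_distance_A, spec.probe_radius_A
    zp = 0.4 * c
    chord = np.sqrt(c ** 2 - (2 * zp) ** 2)
    arg = chord / (2 * rp)
    if arg > 1:
        raise StructureError("contact distance unreachable on the probe circle")
    gap_contact = 2.0 * np.arcsin(arg)
    offset = 0.5 * (np.radians(spec.theta_contact_deg) + gap_contact)
    return {"z_probe": zp, "offset_rad": offset}


def _chain_base_coords(spec: SyntheticSpec, chain: str):
    """Base (unrotated, θ=0) coordinates and atom metadata for one chain.

    Returns (coords, residue_numbers, residue_names, atom_names, elements,
    index arrays of special atoms).
    """
    layout = _probe_layout(spec)
    phi = np.radians(_CHAIN_AZIMUTH_DEG[chain])
    s = 1.0 if chain in _TOP_CHAINS else -1.0
    radius = spec.triangle_radius_A + (spec.asymmetry_A if chain in ("A", "F") else 0.0)
    zc = s * spec.axial_separation_A / 2.0
    center = np.array([radius * np.cos(phi), radius * np.sin(phi), zc])

    rows = []   # (residue_number, residue_name, atom_name, element, xyz)

    # N-domain pseudo-Cα blob; residue 43's CA sits exactly at the placement point
    nd_lo, nd_hi = spec.ndomain_residues
    nd_res = np.arange(nd_lo, nd_hi + 1)
    nd_blob = _blob(len(nd_res), local_radius=5.0)
    anchor = 43 if nd_lo <= 43 <= nd_hi else nd_res[len(nd_res) // 2]
    nd_blob = nd_blob - nd_blob[np.searchsorted(nd_res, anchor)]
    # N-domain markers sit ahead of the subunit azimuth (sign follows the
    # hemisphere) so that paired-domain distances start large and close as
    # the lower trimer rotates
    nd_radius = radius + spec.ndomain_offset_A
    nd_phi = phi + s * np.radians(spec.ndomain_azimuth_offset_deg)
    nd_center = np.array([nd_radius * np.cos(nd_phi), nd_radius * np.sin(nd_phi), zc])
    az = _rz(np.array(phi))
    for res, xyz in zip(nd_res, nd_blob @ az.T + nd_center):
        rows.append((int(res), "ARG" if res == anchor else "GLY", "CA", "C", xyz))

    # α4 functional-group probes on the probe circle near the interface plane
    off, zp = layout["offset_rad"], layout["z_probe"]
    rp = spec.probe_radius_A

    def on_circle(azimuth, z, dr=0.0):
        return np.array([(rp + dr) * np.cos(azimuth), (rp + dr) * np.sin(azimuth), z])

    # both groups sit at azimuth offset +s·off so that each cross-trimer
    # R78→D82 gap is |θ − 2·off|, reaching the contact distance at θ_contact
    tang = 0.3 / rp   # ~0.3 Å tangential spread inside a group
    r78_az = phi + s * off
    d82_az = phi + s * off
    rows.append((75, "LYS", "NZ", "N", on_circle(r78_az, s * (zp + 0.5))))
    rows.append((78, "ARG", "NE", "N", on_circle(r78_az - tang, s * zp)))
    rows.append((78, "ARG", "NH1", "N", on_circle(r78_az, s * zp)))
    rows.append((78, "ARG", "NH2", "N", on_circle(r78_az + tang, s * zp)))
    rows.append((82, "ASP", "O", "O", on_circle(d82_az, s * (zp + 0.5), dr=0.5)))
    rows.append((82, "ASP", "OD1", "O", on_circle(d82_az - tang, s * zp)))
    rows.append((82, "ASP", "OD2", "O", on_circle(d82_az + tang, s * zp)))

    # C-domain pseudo-Cα blob, centroid exactly at the subunit center
    cd_lo, cd_hi = spec.cdomain_residues
    cd_res = np.arange(cd_lo, cd_hi + 1)
    cd_blob = _blob(len(cd_res)) @ az.T + center
    for res, xyz in zip(cd_res, cd_blob):
        rows.append((int(res), "ALA", "CA", "C", xyz))

    coords = np.array([r[4] for r in rows])
    meta = {
        "residue_number": np.array([r[0] for r in rows]),
        "residue_name": np.array([r[1] for r in rows]),
        "atom_name": np.array([r[2] for r in rows]),
        "element": np.array([r[3] for r in rows]),
    }
    return coords, meta, center


def _partner(chain: str) -> str:
    return dict(zip("ABCDEF", "FEDCBA"))[chain]


def default_topology() -> HexamerTopology:
    return HexamerTopology()


def generate_hexamer_trajectory(spec: SyntheticSpec
                                ) -> tuple[Trajectory, GroundTruth]:
    """Build the rigid-body hexamer trajectory and its exact ground truth.

    The lower trimer is rotated about the z axis by θ(t); wobble is applied
    afterwards as temporally correlated per-subunit rigid perturbations, and
    atom jitter as i.i.d. Gaussian displacements.  The ground truth records
    the noise-free geometry (θ(t) including any injected angle noise, probe
    and marker distances from the ideal rigid placement).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames) * spec.frame_interval_ns
    theta_deg = spec.rotation_course.evaluate(times, rng)
    theta_rad = np.radians(theta_deg)
    rot_bottom = _rz(theta_rad)                            # (F, 3, 3)

    chains = ("A", "B", "C", "D", "E", "F")
    base, metas, centers = {}, {}, {}
    for ch in chains:
        base[ch], metas[ch], centers[ch] = _chain_base_coords(spec, ch)

    n_frames = spec.n_frames
    coords_per_chain = {}
    true_centroids = {}
    for ch in chains:
        if ch in _BOTTOM_CHAINS:
            xyz = np.einsum("fij,nj->fni", rot_bottom, base[ch])
            cen = np.einsum("fij,j->fi", rot_bottom, centers[ch])
        else:
            xyz = np.broadcast_to(base[ch], (n_frames,) + base[ch].shape).copy()
            cen = np.broadcast_to(centers[ch], (n_frames, 3)).copy()
        true_centroids[ch] = cen
        if spec.wobble_A > 0:
            sigma_rot = spec.wobble_A / spec.triangle_radius_A
            rotvec = _ar1(rng, n_frames, sigma_rot, spec.wobble_ar1, (3,))
            trans = _ar1(rng, n_frames, spec.wobble_A, spec.wobble_ar1, (3,))
            wob = Rotation.from_rotvec(rotvec).as_matrix()   # (F, 3, 3)
            pivot = xyz.mean(axis=1, keepdims=True)
            xyz = np.einsum("fij,fnj->fni", wob, xyz - pivot) + pivot + trans[:, None, :]
        if spec.ndomain_jitter_A > 0:
            nd_mask = metas[ch]["residue_number"] <= spec.ndomain_residues[1]
            drift = _ar1(rng, n_frames, spec.ndomain_jitter_A, spec.wobble_ar1, (3,))
            xyz[:, nd_mask, :] += drift[:, None, :]
        coords_per_chain[ch] = xyz

    coords = np.concatenate([coords_per_chain[ch] for ch in chains], axis=1)
    if spec.atom_jitter_A > 0:
        coords = coords + rng.normal(0.0, spec.atom_jitter_A, size=coords.shape)

    table = AtomTable(
        chain_id=np.concatenate([[ch] * len(metas[ch]["residue_number"]) for ch in chains]),
        residue_number=np.concatenate([metas[ch]["residue_number"] for ch in chains]),
        residue_name=np.concatenate([metas[ch]["residue_name"] for ch in chains]),
        atom_name=np.concatenate([metas[ch]["atom_name"] for ch in chains]),
        element=np.concatenate([metas[ch]["element"] for ch in chains]),
    )
    traj = Trajectory(table, coords, times_ns=times,
                      frame_interval_ns=spec.frame_interval_ns,
                      source=f"synthetic(seed={spec.seed})")

    truth = GroundTruth(
        times_ns=times,
        rotation_deg=theta_deg.copy(),
        subunit_centroids=true_centroids,
        probe_min_distance=_ideal_probe_distances(spec, metas, base, rot_bottom),
        arg43_pair_distance=_ideal_arg43_distances(spec, metas, base, rot_bottom),
        rmsf_per_residue_A=(spec.atom_jitter_A * np.sqrt(3.0)
                            if spec.wobble_A == 0 and spec.ndomain_jitter_A == 0
                            else None),
    )
    return traj, truth


def _ideal_group(meta, base_xyz, residue: int, atom_names) -> np.ndarray:
    m = (meta["residue_number"] == residue) & np.isin(meta["atom_name"], list(atom_names))
    return base_xyz[m]


def _ideal_probe_distances(spec, metas, base, rot_bottom) -> dict[str, np.ndarray]:
    """Closed-form min group distances R78(X)→D82(partner X), noise-free."""
    out = {}
    for donor in "ABCDEF":
        acceptor = _partner(donor)
        g_r = _ideal_group(metas[donor], base[donor], 78, ("NH1", "NH2", "NE"))
        g_d = _ideal_group(metas[acceptor], base[acceptor], 82, ("OD1", "OD2"))
        rot_r = (np.einsum("fij,nj->fni", rot_bottom, g_r)
                 if donor in _BOTTOM_CHAINS else g_r[None, :, :])
        rot_d = (np.einsum("fij,nj->fni", rot_bottom, g_d)
                 if acceptor in _BOTTOM_CHAINS else g_d[None, :, :])
        diff = rot_r[:, :, None, :] - rot_d[:, None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1)).reshape(rot_bottom.shape[0], -1)
        out[f"R78:{donor}-D82:{acceptor}"] = dist.min(axis=1)
    return out


def _ideal_arg43_distances(spec, metas, base, rot_bottom) -> dict[str, np.ndarray]:
    nd_lo, nd_hi = spec.ndomain_residues
    if not (nd_lo <= 43 <= nd_hi):
        return {}
    out = {}
    pos = {}
    for ch in "ABCDEF":
        p = _ideal_group(metas[ch], base[ch], 43, ("CA",))[0]
        pos[ch] = (np.einsum("fij,j->fi", rot_bottom, p)
                   if ch in _BOTTOM_CHAINS else np.broadcast_to(p, (rot_bottom.shape[0], 3)))
    for a, b in (("A", "F"), ("B", "E"), ("C", "D")):
        out[f"{a}-{b}"] = np.linalg.norm(pos[a] - pos[b], axis=1)
    return out


def generate_contact_trajectory(n_contact_pairs: int, n_frames: int = 20,
                                contact_distance_A: float = 2.8,
                                far_distance_A: float = 9.0,
                                frame_interval_ns: float = 1.0,
                                seed: int = 0) -> tuple[Trajectory, dict]:
    """Static hexamer fixture with exactly ``n_contact_pairs`` of the six
    directed R78(X)→D82(partner) probe pairs held in contact.

    Each directed pair occupies its own region of space, so contact counts
    are exact by construction.  Returns the trajectory and the truth dict
    ``{"in_contact": {label: bool}, "count": int}``.
    """
    if not 0 <= n_contact_pairs <= 6:
        raise ValueError("n_contact_pairs must be in [0, 6]")
    rng = np.random.default_rng(seed)
    chains = ("A", "B", "C", "D", "E", "F")
    order = [f"R78:{d}-D82:{_partner(d)}" for d in chains]
    in_contact = {lab: i < n_contact_pairs for i, lab in enumerate(order)}

    chain_rows: dict[str, list] = {ch: [] for ch in chains}
    for i, donor in enumerate(chains):
        acceptor = _partner(donor)
        origin = np.array([60.0 * i, 0.0, 0.0])
        sep = contact_distance_A if in_contact[order[i]] else far_distance_A
        for name, off in (("NE", (-0.3, 0, 0)), ("NH1", (0, 0, 0)), ("NH2", (0.3, 0, 0))):
            chain_rows[donor].append((78, "ARG", name, "N", origin + off))
        for name, off in (("OD1", (-0.3, sep, 0)), ("OD2", (0.3, sep, 0))):
            chain_rows[acceptor].append((82, "ASP", name, "O", origin + off))

    rows = [r for ch in chains for r in chain_rows[ch]]
    chain_ids = [ch for ch in chains for _ in chain_rows[ch]]
    coords0 = np.array([r[4] for r in rows], dtype=float)
    table = AtomTable(
        chain_id=chain_ids,
        residue_number=[r[0] for r in rows],
        residue_name=[r[1] for r in rows],
        atom_name=[r[2] for r in rows],
        element=[r[3] for r in rows],
    )
    coords = np.broadcast_to(coords0, (n_frames,) + coords0.shape).copy()
    traj = Trajectory(table, coords, frame_interval_ns=frame_interval_ns,
                      source=f"synthetic-contacts(seed={seed})")
    return traj, {"in_contact": in_contact, "count": n_contact_pairs}


def generate_gaussian_trajectory(true_covariance: np.ndarray,
                                 n_frames: int, seed: int = 0,
                                 masses: np.ndarray | None = None,
                                 frame_interval_ns: float = 0.001,
                                 temperature_K: float = 300.0
                                 ) -> tuple[Trajectory, dict]:
    """Pseudo-molecule whose frames are i.i.d. draws from N(mean, Σ).

    ``true_covariance`` is the (3N, 3N) Cartesian covariance in Å²
    (unweighted).  Alongside the trajectory the analytic Schlitter and
    quasi-harmonic entropies of the true (mass-weighted) covariance are
    returned for validation.
    """
    from .entropy import CovarianceModel, quasiharmonic_entropy, schlitter_entropy

    sigma = np.asarray(true_covariance, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1] or sigma.shape[0] % 3:
        raise ValueError(f"covariance must be 3Nx3N, got {sigma.shape}")
    if np.abs(sigma - sigma.T).max() > 1e-10 * max(np.abs(sigma).max(), 1e-30):
        raise ValueError("covariance must be symmetric")
    lam, vec = np.linalg.eigh(sigma)
    if lam[0] < -1e-10 * max(lam[-1], 1e-30):
        raise ValueError("covariance is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)
    n_atoms = sigma.shape[0] // 3
    if masses is None:
        masses = np.full(n_atoms, 12.011)
    masses = np.asarray(masses, dtype=float)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, sigma.shape[0]))
    draw = z @ (vec * np.sqrt(lam)).T                       # samples of N(0, Σ)
    mean = _blob(n_atoms, local_radius=5.0, rise=1.0).reshape(-1)
    coords = (mean + draw).reshape(n_frames, n_atoms, 3)

    table = AtomTable(
        chain_id=["A"] * n_atoms,
        residue_number=np.arange(1, n_atoms + 1),
        residue_name=["GLY"] * n_atoms,
        atom_name=["CA"] * n_atoms,
        element=["C"] * n_atoms,
    )
    traj = Trajectory(table, coords, frame_interval_ns=frame_interval_ns,
                      source=f"gaussian(seed={seed})")

    w = np.sqrt(np.repeat(masses, 3))
    model = CovarianceModel(matrix=sigma * np.outer(w, w), masses=masses,
                            mass_weighted=True, n_frames=n_frames,
                            temperature_K=temperature_K, fitted=False)
    zero = np.allclose(sigma, 0.0)
    analytic = {
        "schlitter_J_per_molK": 0.0 if zero else schlitter_entropy(model, 0).value,
        "quasiharmonic_J_per_molK": (0.0 if zero
                                     else quasiharmonic_entropy(model, 0).value),
        "masses_amu": masses,
    }
    return traj, analytic
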