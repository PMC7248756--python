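import numpy as np
import pytest

from oligorot import (
    AtomTable,
    Frame,
    HexamerTopology,
    RotationCourse,
    SyntheticSpec,
    Trajectory,
    generate_hexamer_trajectory,
)


@pytest.fixture
def topology():
    return HexamerTopology()


def build_frame(atom_rows, time_ns=0.0):
    """atom_rows: (chain, resnum, resname, atomname, element, xyz)."""
    table = AtomTable(
        chain_id=[r[0] for r in atom_rows],
        residue_number=[r[1] for r in atom_rows],
        residue_name=[r[2] for r in atom_rows],
        atom_name=[r[3] for r in atom_rows],
        element=[r[4] for r in atom_rows],
    )
    coords = np.array([r[5] for r in atom_rows], dtype=float)
    return Frame(table, coords, time_ns)


def build_trajectory(atom_rows, coords_per_frame, frame_interval_ns=1.0):
    frame = build_frame(atom_rows)
    coords = np.asarray(coords_per_frame, dtype=float)
    return Trajectory(frame.table, coords, frame_interval_ns=frame_interval_ns)


@pytest.fixture
def eclipsed_traj():
    """Static eclipsed hexamer (zero rotation, no noise), 5 frames."""
    spec = SyntheticSpec(n_frames=5)
    traj, truth = generate_hexamer_trajectory(spec)
    return traj, truth


@pytest.fixture
def rotated_traj_factory():
    def make(theta_eq, n_frames=50, tau_ns=5.0, theta0=0.0, **kwargs):
        spec = SyntheticSpec(
            n_frames=n_frames,
            rotation_course=RotationCourse(theta0_deg=theta0,
                                           theta_eq_deg=theta_eq, tau_ns=tau_ns),
            **kwargs)
        return generate_hexamer_trajectory(spec)
    return make


def small_hexamer_spec(**kwargs):
    """Hexamer spec with trimmed blobs for fast large-frame-count tests."""
    defaults = dict(ndomain_residues=(40, 46), cdomain_residues=(85, 105))
    defaults.update(kwargs)
    return SyntheticSpec(**defaults)


def small_topology():
    return HexamerTopology(com_residue_range=(85, 105),
                           n_domain_range=(1, 71), c_domain_range=(72, 149))
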