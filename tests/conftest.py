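import numpy as np
import pandas as pd
import pytest

from smlm_register import LocalizationTable, RigidTransform2D, SimulationConfig, simulate_channel
from smlm_register.synthetic_data import _poisson_disc


def make_table(frames, xs, ys, intensity=None, n_frames=None, channel_id="t"):
    """Small LocalizationTable from parallel lists."""
    data = {"frame": np.asarray(frames, dtype=np.int64),
            "x": np.asarray(xs, dtype=float),
            "y": np.asarray(ys, dtype=float)}
    if intensity is not None:
        data["intensity"] = np.asarray(intensity, dtype=float)
    return LocalizationTable(data=pd.DataFrame(data), channel_id=channel_id, n_frames=n_frames)


def random_table(rng, n=200, n_frames=50, field=5000.0, with_intensity=True):
    frames = rng.integers(1, n_frames + 1, size=n)
    tab = {"frame": frames, "x": rng.uniform(0, field, n), "y": rng.uniform(0, field, n)}
    if with_intensity:
        tab["intensity"] = rng.uniform(0, 5000, n)
    return LocalizationTable(data=pd.DataFrame(tab), n_frames=n_frames)


def two_channel_bead_sim(seed, n_fid=8, sigma=10.0, n_frames=400, transform=None,
                         n_spurious=0, structures=()):
    """Reference + misaligned moving channel sharing bead positions.

    Returns (ref_table, mov_table, true_common_positions, transform).
    Spurious beads (present in only one channel) are appended per channel.
    """
    rng = np.random.default_rng(seed)
    if transform is None:
        transform = RigidTransform2D(theta=rng.uniform(-0.02, 0.02),
                                     tx=rng.uniform(-1500, 1500),
                                     ty=rng.uniform(-1500, 1500))
    cfg = SimulationConfig(seed=0, n_fiducials=n_fid, n_frames=n_frames,
                           fiducial_jitter=sigma, structures=tuple(structures))
    all_beads = _poisson_disc(rng, n_fid + 2 * n_spurious, cfg.field_size,
                              cfg.min_fiducial_spacing)
    common = all_beads[:n_fid]
    beads_ref = np.vstack([common, all_beads[n_fid:n_fid + n_spurious]])
    beads_mov = np.vstack([common, all_beads[n_fid + n_spurious:]])
    ref, _ = simulate_channel(cfg, "ref", rng=rng, fiducial_positions=beads_ref)
    mov, _ = simulate_channel(cfg, "mov", transform=transform, rng=rng,
                              fiducial_positions=beads_mov)
    return ref, mov, common, transform


@pytest.fixture
def rng():
    return np.random.default_rng(42)
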