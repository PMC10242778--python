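"""Synthetic multi-channel SMLM data with known ground truth.

Emulates the localization-table output of a STORM acquisition at the level
this package consumes: stable fiducial emitters that localize in (almost)
every frame with Gaussian localization jitter, blinking structured signal
(filament polylines and Gaussian clusters) that turns on sparsely per frame,
a known rigid misalignment per channel, and optional exponential bleaching.
Camera noise, PSF shape and fitting artifacts are out of scope — the
generator produces coordinates, not frames.

Default geometry follows a typical EMCCD STORM acquisition: a 256 x 256
pixel region at 130 nm effective pixel size (33 280 nm square field).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .localization_io import LocalizationTable
from .rigid_registration import RigidTransform2D

__all__ = [
    "ClusterSpec",
    "FilamentSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_channel",
    "emulate_bleaching",
]

#: 256 px ROI at 130 nm/px.
DEFAULT_FIELD_SIZE = 256 * 130.0


@dataclass(frozen=True)
class FilamentSpec:
    """A blinking filament: localizations appear sparsely along a polyline.

    ``blink_rate`` is the expected number of localizations per frame over
    the whole filament (Poisson); ``width`` the transverse Gaussian spread.
    """

    vertices: tuple[tuple[float, float], ...]
    blink_rate: float = 2.0
    width: float = 20.0


@dataclass(frozen=True)
class ClusterSpec:
    """A blinking cluster: Gaussian-scattered blinks around a centre.

    ``blink_rate`` is the expected localizations per frame (Poisson);
    ``sigma`` the isotropic spread in nm.
    """

    center: tuple[float, float]
    blink_rate: float = 1.0
    sigma: float = 50.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated acquisition.

    Defaults emulate a bead-calibration acquisition: a 33.3 µm square field,
    2000 frames, beads on in ~95% of frames with 10 nm localization
    precision, beads separated by at least 10 bead diameters so landmark
    correspondence is unambiguous.
    """

    field_size: float = DEFAULT_FIELD_SIZE
    n_frames: int = 2000
    n_fiducials: int = 8
    fiducial_on_prob: float = 0.95
    fiducial_jitter: float = 10.0
    min_fiducial_spacing: float = 1000.0
    structures: tuple[FilamentSpec | ClusterSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fiducial_on_prob <= 1:
            raise ValueError("fiducial_on_prob must be in [0, 1]")
        if self.field_size <= 0 or self.n_frames < 1:
            raise ValueError("field_size and n_frames must be positive")
        if self.fiducial_jitter < 0:
            raise ValueError("fiducial_jitter must be >= 0")


@dataclass
class GroundTruth:
    """True emitter geometry for one simulated channel.

    ``fiducials`` are bead centres in the common (reference) frame;
    ``fiducials_transformed`` the same centres mapped by the channel's
    misalignment — where detection should find them.  ``membership`` labels
    each table row: 'fiducial', 'filament' or 'cluster'.
    """

    fiducials: np.ndarray
    fiducials_transformed: np.ndarray
    transform: RigidTransform2D
    membership: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))


def _poisson_disc(
    rng: np.random.Generator, n: int, field: float, min_spacing: float
) -> np.ndarray:
    """Random points with pairwise spacing >= min_spacing (dart throwing)."""
    pts: list[np.ndarray] = []
    for _ in range(100_000):
        if len(pts) == n:
            break
        p = rng.uniform(0, field, size=2)
        if all(np.hypot(*(p - q)) >= min_spacing for q in pts):
            pts.append(p)
    if len(pts) < n:
        raise RuntimeError(
            f"could not place {n} fiducials with spacing {min_spacing} in field {field}"
        )
    return np.array(pts)


def simulate_channel(
    config: SimulationConfig,
    channel_id: str = "",
    transform: RigidTransform2D | None = None,
    rng: np.random.Generator | None = None,
    fiducial_positions: np.ndarray | None = None,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate one channel's localization table.

    Fiducials blink on with independent per-frame Bernoulli(``on_prob``) and
    localize at their true position plus isotropic Gaussian jitter;
    structures emit Poisson-distributed blinks per frame.  All coordinates
    are then mapped by *transform* (the channel's misalignment; identity
    for the reference channel).

    Parameters
    ----------
    fiducial_positions
        Bead centres shared across channels of one acquisition; freshly
        drawn by Poisson-disc sampling when None.
    rng
        Source of randomness; defaults to ``default_rng(config.seed)``.
        Pass the same generator for successive channels so they differ.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    transform = transform or RigidTransform2D.identity()
    if fiducial_positions is None:
        fiducial_positions = _poisson_disc(
            rng, config.n_fiducials, config.field_size, config.min_fiducial_spacing
        )
    else:
        fiducial_positions = np.asarray(fiducial_positions, dtype=float)

    frames: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    # fiducials: Bernoulli emission, Gaussian jitter
    for fx, fy in fiducial_positions:
        on = rng.random(config.n_frames) < config.fiducial_on_prob
        f_idx = np.flatnonzero(on) + 1
        jitter = rng.normal(0, config.fiducial_jitter, size=(f_idx.size, 2))
        frames.append(f_idx)
        coords.append(np.array([fx, fy]) + jitter)
        labels.append(np.full(f_idx.size, "fiducial", dtype=object))

    for spec in config.structures:
        n_per_frame = rng.poisson(spec.blink_rate, size=config.n_frames)
        total = int(n_per_frame.sum())
        if total == 0:
            continue
        f_idx = np.repeat(np.arange(1, config.n_frames + 1), n_per_frame)
        if isinstance(spec, FilamentSpec):
            pts = _sample_polyline(rng, np.asarray(spec.vertices, dtype=float), total)
            pts += rng.normal(0, spec.width, size=(total, 2))
            kind = "filament"
        else:
            pts = np.asarray(spec.center, dtype=float) + rng.normal(
                0, spec.sigma, size=(total, 2)
            )
            kind = "cluster"
        frames.append(f_idx)
        coords.append(pts)
        labels.append(np.full(total, kind, dtype=object))

    frame_arr = np.concatenate(frames) if frames else np.array([], dtype=int)
    xy = np.concatenate(coords) if coords else np.zeros((0, 2))
    label_arr = np.concatenate(labels) if labels else np.array([], dtype=object)
    order = np.argsort(frame_arr, kind="stable")
    frame_arr, xy, label_arr = frame_arr[order], xy[order], label_arr[order]
    xy = transform.apply(xy) if len(xy) else xy

    data = pd.DataFrame(
        {
            "frame": frame_arr.astype(np.int64),
            "x": xy[:, 0] if len(xy) else np.array([]),
            "y": xy[:, 1] if len(xy) else np.array([]),
            "intensity": rng.uniform(2000, 10000, size=len(frame_arr)),
        }
    )
    table = LocalizationTable(data=data, channel_id=channel_id, n_frames=config.n_frames)
    truth = GroundTruth(
        fiducials=fiducial_positions,
        fiducials_transformed=transform.apply(fiducial_positions)
        if len(fiducial_positions)
        else fiducial_positions,
        transform=transform,
        membership=label_arr,
    )
    return table, truth


def _sample_polyline(
    rng: np.random.Generator, vertices: np.ndarray, n: int
) -> np.ndarray:
    """Uniform samples along a polyline by arc length."""
    seg = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    s = rng.uniform(0, cum[-1], size=n)
    i = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[i]) / np.where(seg_len[i] > 0, seg_len[i], 1)
    return vertices[i] + seg[i] * frac[:, None]


def emulate_bleaching(
    table: LocalizationTable,
    half_life: float,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> LocalizationTable:
    """Thin localizations by exponential photobleaching.

    Each localization in frame ``f`` is retained with probability
    ``2^(-f / half_life)``; late frames lose most of their signal, the way
    bead emission fades over a long acquisition.
    """
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    frames = table.frames
    p_keep = np.exp2(-frames / half_life)
    keep = rng.random(len(frames)) < p_keep
    return table.with_data(table.data[keep])
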