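"""Detect fiducial beads in a localization table by their stable emission.

Fiducial markers (e.g. 100 nm TetraSpeck beads) emit continuously through a
STORM acquisition, while genuine single-molecule signal blinks.  A bead
therefore produces a localization in (almost) every frame inside a small
neighborhood, with low frame-to-frame variation in the neighborhood count.

Detection seeds one candidate per localization in the densest frame, then
scores each candidate over all analyzed frames ``f = 1..n`` with

* the *mean tolerance*  ``MT = (1/n) sum_f |N_f|``, and
* the *variance limit*  ``VL = (1/n) sum_f (|N_f| - MT)^2``,

where ``N_f`` is the set of frame-``f`` localizations strictly closer than
the tolerance radius ``r`` (the bead diameter) to the candidate.  A stable
emitter scores MT near 1 and VL near 0; blinking structure is excluded by
its high count variance (a Poisson-blinking neighborhood with mean rate
``lambda`` has VL ~ ``lambda``, so anything bright enough to pass the MT
threshold fails the VL threshold).  Candidates passing ``MT >= mt_min`` and
``VL <= vl_max`` are merged within ``r`` (one landmark per physical bead)
and their position is refined to the centroid of all in-radius
localizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .localization_io import EmptyTableError, LocalizationTable

__all__ = [
    "DetectionParams",
    "Landmark",
    "LandmarkSet",
    "LandmarkSource",
    "NoLandmarksError",
    "seed_candidates",
    "neighbor_counts_per_frame",
    "score_candidate",
    "detect_fiducials",
]


class NoLandmarksError(RuntimeError):
    """Detection produced no usable landmarks."""


class LandmarkSource(str, Enum):
    FIDUCIAL = "fiducial"
    CLUSTER = "cluster"
    ANNOTATION = "annotation"


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of fiducial detection.

    Parameters
    ----------
    r
        Neighborhood tolerance in nm; default 100, the fiducial bead
        diameter.
    mt_min
        Minimum acceptable mean tolerance (mean per-frame neighbor count).
    vl_max
        Maximum acceptable variance limit (population variance of the count).
    frame_first, frame_last
        Optional 1-based inclusive frame range to restrict detection to;
        useful when beads bleach late in the acquisition.
    """

    r: float = 100.0
    mt_min: float = 0.5
    vl_max: float = 0.25
    frame_first: int | None = None
    frame_last: int | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.mt_min < 0 or self.vl_max < 0:
            raise ValueError("mt_min and vl_max must be >= 0")


@dataclass
class Landmark:
    """A registration landmark: detected bead, cluster centre or annotation."""

    x: float
    y: float
    mt: float | None = None
    vl: float | None = None
    support: int = 0
    source: LandmarkSource = LandmarkSource.FIDUCIAL


@dataclass
class LandmarkSet:
    """Landmarks of one channel together with the parameters that found them."""

    channel_id: str
    landmarks: list[Landmark] = field(default_factory=list)
    params: DetectionParams | None = None

    def __len__(self) -> int:
        return len(self.landmarks)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of landmark coordinates in nm."""
        return np.array([[lm.x, lm.y] for lm in self.landmarks], dtype=float).reshape(-1, 2)


def seed_candidates(table: LocalizationTable) -> list[Landmark]:
    """One candidate per localization in the densest frame.

    The frame holding the most localizations is most likely to contain every
    bead at least once.  Ties are broken toward the lowest frame index for
    determinism.  MT/VL are left unset on the returned candidates.
    """
    if not len(table):
        raise EmptyTableError("cannot seed candidates from an empty table")
    frames = table.frames
    counts = np.bincount(frames)
    densest = int(np.argmax(counts))  # np.argmax returns the first (lowest) maximum
    xy = table.xy[frames == densest]
    return [Landmark(x=float(x), y=float(y)) for x, y in xy]


def neighbor_counts_per_frame(
    table: LocalizationTable, candidate: Landmark, r: float
) -> np.ndarray:
    """Per-frame neighbor counts ``|N_f|`` for one candidate.

    Entry ``f-1`` counts the localizations of frame ``f`` with Euclidean
    distance strictly below ``r`` from the candidate; frames without
    localizations contribute 0.  Length is ``table.n_frames``.
    """
    counts = _neighbor_count_matrix(table, np.array([[candidate.x, candidate.y]]), r)
    return counts[0]


def _neighbor_count_matrix(
    table: LocalizationTable, candidates_xy: np.ndarray, r: float
) -> np.ndarray:
    """(n_candidates, n_frames) matrix of strict-< per-frame neighbor counts."""
    if r <= 0:
        raise ValueError("r must be > 0")
    n_frames = int(table.n_frames)
    out = np.zeros((len(candidates_xy), n_frames), dtype=np.int64)
    if not len(table):
        return out
    xy = table.xy
    frames = table.frames
    tree = cKDTree(xy)
    for i, c in enumerate(candidates_xy):
        idx = tree.query_ball_point(c, r)
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.linalg.norm(xy[idx] - c, axis=1)
        idx = idx[d < r]  # query_ball_point includes the boundary; the criterion is strict
        if idx.size:
            out[i] += np.bincount(frames[idx] - 1, minlength=n_frames)[:n_frames]
    return out


def score_candidate(counts: np.ndarray, n: int) -> tuple[float, float]:
    """Mean tolerance and variance limit from per-frame neighbor counts.

    ``mt`` is the mean count over the ``n`` analyzed frames and ``vl`` the
    population variance (divisor ``n``), with frames absent from *counts*
    counting as zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    mt = total / n
    # zero-padded frames contribute (0 - mt)^2 each
    vl = (np.sum((counts - mt) ** 2) + (n - counts.size) * mt**2) / n
    return float(mt), float(vl)


def detect_fiducials(table: LocalizationTable, params: DetectionParams | None = None) -> LandmarkSet:
    """Full fiducial-detection pipeline: seed, score, threshold, merge, refine.

    Raises
    ------
    NoLandmarksError
        If no candidate passes both thresholds; the message suggests
        loosening ``mt_min``/``vl_max`` or checking the frame range.
    """
    params = params or DetectionParams()
    work = table
    if params.frame_first is not None or params.frame_last is not None:
        from .localization_io import restrict_frames

        first = params.frame_first or 1
        last = params.frame_last or int(table.n_frames)
        work = restrict_frames(table, first, last)
    if not len(work):
        raise EmptyTableError("no localizations in the analyzed frame range")

    candidates = seed_candidates(work)
    cand_xy = np.array([[c.x, c.y] for c in candidates])
    n = int(work.n_frames)
    count_matrix = _neighbor_count_matrix(work, cand_xy, params.r)

    passing: list[Landmark] = []
    for cand, counts in zip(candidates, count_matrix):
        mt, vl = score_candidate(counts, n)
        if mt >= params.mt_min and vl <= params.vl_max:
            passing.append(replace(cand, mt=mt, vl=vl, support=int(counts.sum())))
    if not passing:
        raise NoLandmarksError(
            "no fiducials found: no candidate satisfied "
            f"MT >= {params.mt_min} and VL <= {params.vl_max}; consider relaxing the "
            "thresholds, adjusting r, or restricting the frame range to before bleaching"
        )

    merged = _merge_within_radius(passing, params.r)
    refined = [_refine_centroid(lm, work, params.r) for lm in merged]
    return LandmarkSet(channel_id=table.channel_id, landmarks=refined, params=params)


def _merge_within_radius(landmarks: list[Landmark], r: float) -> list[Landmark]:
    """One landmark per bead: greedily keep the best candidate, suppress within r.

    Candidates are ordered by highest MT, then lowest VL, then lowest x (a
    deterministic total order); a candidate within ``r`` of an already kept
    one is absorbed by it.
    """
    order = sorted(
        range(len(landmarks)),
        key=lambda i: (-landmarks[i].mt, landmarks[i].vl, landmarks[i].x, landmarks[i].y),
    )
    kept: list[Landmark] = []
    kept_xy: list[tuple[float, float]] = []
    for i in order:
        lm = landmarks[i]
        if all((lm.x - kx) ** 2 + (lm.y - ky) ** 2 >= r**2 for kx, ky in kept_xy):
            kept.append(lm)
            kept_xy.append((lm.x, lm.y))
    return kept


def _refine_centroid(landmark: Landmark, table: LocalizationTable, r: float) -> Landmark:
    """Move a landmark to the centroid of its strict-< r neighbors over all frames.

    Averaging over every frame's localizations suppresses the single-frame
    jitter of the seed coordinate, giving a bead-centre estimate with
    standard error ~ sigma/sqrt(support).
    """
    xy = table.xy
    tree = cKDTree(xy)
    idx = np.asarray(tree.query_ball_point([landmark.x, landmark.y], r))
    if idx.size:
        d = np.linalg.norm(xy[idx] - [landmark.x, landmark.y], axis=1)
        idx = idx[d < r]
    if not idx.size:
        return landmark
    cx, cy = xy[idx].mean(axis=0)
    return replace(landmark, x=float(cx), y=float(cy), support=int(idx.size))
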