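"""Fiducial-free landmark detection from dense localization clusters.

When no fiducial beads are present (e.g. fluorescently labeled lipid
nanoparticles imaged in two channels), the densest localization clusters
serve as registration landmarks instead.  No per-frame statistics are used:
for every localization, the number of neighbors within a user radius ``r_c``
is counted across all frames pooled, and the top-``k`` localizations by
neighbor count are retained.

By default a non-maximum suppression step discards candidates within
``r_c`` of an already-selected, higher-ranked one, so the ``k`` landmarks
are spatially distinct clusters rather than ``k`` points from the single
densest cluster; pass ``suppress=False`` for the literal top-``k`` list.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .fiducial_detect import Landmark, LandmarkSet, LandmarkSource, NoLandmarksError
from .localization_io import EmptyTableError, LocalizationTable

__all__ = ["detect_clusters"]

DEFAULT_RC = 750.0
DEFAULT_K = 25


def detect_clusters(
    table: LocalizationTable,
    r_c: float = DEFAULT_RC,
    k: int = DEFAULT_K,
    suppress: bool = True,
) -> LandmarkSet:
    """Return up to *k* cluster-centre landmarks ranked by neighbor count.

    Parameters
    ----------
    table
        Localizations of one channel.
    r_c
        Neighborhood radius in nm (default 750, suited to ~100 nm
        nanoparticles rendered at typical localization densities).
    k
        Number of landmarks to retain (default 25).
    suppress
        Suppress candidates within ``r_c`` of a higher-ranked selection.

    Notes
    -----
    The neighbor count of a localization includes the localization itself
    (distance 0), so ``n`` identical points each have support ``n``.
    Counts use the strict ``d < r_c`` criterion.

    Raises
    ------
    NoLandmarksError
        If fewer than 2 landmarks survive — a rigid fit needs at least two.
    """
    if r_c <= 0:
        raise ValueError("r_c must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not len(table):
        raise EmptyTableError("cannot detect clusters in an empty table")

    xy = table.xy
    tree = cKDTree(xy)
    # boundary-inclusive ball counts, then subtract pairs at exactly r_c
    counts = tree.query_ball_point(xy, r_c, return_length=True).astype(np.int64)
    boundary = tree.query_pairs(r_c, output_type="ndarray")
    if len(boundary):
        d = np.linalg.norm(xy[boundary[:, 0]] - xy[boundary[:, 1]], axis=1)
        for i, j in boundary[d == r_c]:
            counts[i] -= 1
            counts[j] -= 1

    order = np.lexsort((np.arange(len(xy)), -counts))  # by count desc, then row order
    selected: list[int] = []
    for idx in order:
        if len(selected) == k:
            break
        if suppress and any(
            np.hypot(*(xy[idx] - xy[j])) < r_c for j in selected
        ):
            continue
        selected.append(int(idx))

    landmarks = [
        Landmark(
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            support=int(counts[i]),
            source=LandmarkSource.CLUSTER,
        )
        for i in selected
    ]
    if len(landmarks) < min(2, k):
        raise NoLandmarksError(
            f"cluster detection found {len(landmarks)} landmark(s); at least 2 are "
            "needed for a rigid fit — increase k or r_c, or check the input density"
        )
    return LandmarkSet(channel_id=table.channel_id, landmarks=landmarks, params=None)
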