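"""Strip fiducial-marker localizations from corrected tables.

After registration the bright bead signal is often unwanted in the final
reconstruction; every localization strictly closer than one bead diameter to
any detected landmark is removed (the same strict-< convention used by the
detection neighborhoods).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .fiducial_detect import LandmarkSet
from .localization_io import LocalizationTable

__all__ = ["remove_fiducials"]

DEFAULT_DIAMETER = 100.0


def remove_fiducials(
    table: LocalizationTable,
    landmarks: LandmarkSet,
    diameter: float = DEFAULT_DIAMETER,
) -> LocalizationTable:
    """Drop localizations with distance < *diameter* from any landmark.

    The removal radius equals the full bead diameter (default 100 nm) so the
    whole localization footprint of a bead is cleared, not just its core.
    An empty landmark set returns the table unchanged with a warning.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    if not len(landmarks):
        warnings.warn("no landmarks given; nothing removed", stacklevel=2)
        return table.with_data(table.data.copy())
    xy = table.xy
    tree = cKDTree(landmarks.xy)
    dist, _ = tree.query(xy)
    keep = dist >= diameter
    return table.with_data(table.data[np.asarray(keep)])
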