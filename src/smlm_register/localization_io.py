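"""Read, write and filter localization tables in the ThunderSTORM CSV dialect.

A localization table holds one row per single-molecule blink event: the
acquisition frame index (1-based), the fitted x/y position in nanometres and
optionally an intensity (photon-count scale) and a localization uncertainty.
ThunderSTORM exports these as CSV with bracketed unit headers
(``"x [nm]"``); other reconstruction packages use bare names, so column
recognition goes through a configurable alias map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CsvDialect",
    "LocalizationTable",
    "LocalizationFormatError",
    "EmptyTableError",
    "read_localizations",
    "write_localizations",
    "filter_by_intensity",
    "restrict_frames",
]


class LocalizationFormatError(ValueError):
    """A localization file does not conform to the expected CSV layout."""


class EmptyTableError(ValueError):
    """An operation that requires localizations received none."""


#: Canonical column -> accepted header aliases (case-sensitive, checked in order).
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "frame": ("frame", '"frame"', "Frame", "frame_idx"),
    "x": ("x [nm]", "x[nm]", "x", "x_nm", "X"),
    "y": ("y [nm]", "y[nm]", "y", "y_nm", "Y"),
    "intensity": ("intensity [photon]", "intensity[photon]", "intensity", "I"),
    "uncertainty": ("uncertainty [nm]", "uncertainty[nm]", "uncertainty", "uncertainty_xy [nm]"),
}


@dataclass(frozen=True)
class CsvDialect:
    """Column-name configuration for reading/writing localization CSVs.

    Parameters
    ----------
    aliases
        Mapping from canonical column names (``frame``, ``x``, ``y``,
        ``intensity``, ``uncertainty``) to the header spellings accepted on
        input.  The first alias is used when writing a new file.
    """

    aliases: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_ALIASES))

    def resolve(self, header: list[str]) -> dict[str, str]:
        """Map canonical names to the actual header names present in *header*."""
        found: dict[str, str] = {}
        for canonical, options in self.aliases.items():
            for name in options:
                if name in header:
                    found[canonical] = name
                    break
        return found


@dataclass
class LocalizationTable:
    """All localizations of one acquisition channel.

    Attributes
    ----------
    data
        DataFrame with at least columns ``frame`` (int, 1-based), ``x``,
        ``y`` (float, nm); optionally ``intensity`` and ``uncertainty``.
        Row order is meaningful and preserved by all operations.
    channel_id
        Free-form channel label, e.g. ``"642"``.
    n_frames
        Number of frames in the analyzed range (>= max frame index present).
        This is the denominator of the per-frame detection statistics.
    column_names
        Original header spellings (canonical -> as-read), used to write
        output files in the same dialect as the input.
    """

    data: pd.DataFrame
    channel_id: str = ""
    n_frames: int | None = None
    column_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"frame", "x", "y"}
        missing = required - set(self.data.columns)
        if missing:
            raise LocalizationFormatError(f"table missing columns: {sorted(missing)}")
        if len(self.data):
            frames = self.data["frame"].to_numpy()
            if frames.min() < 1:
                raise LocalizationFormatError("frame indices must be >= 1")
            if not np.all(np.isfinite(self.data[["x", "y"]].to_numpy())):
                raise LocalizationFormatError("non-finite coordinates")
            max_frame = int(frames.max())
        else:
            max_frame = 0
        if self.n_frames is None:
            self.n_frames = max_frame
        elif self.n_frames < max_frame:
            raise ValueError(
                f"n_frames={self.n_frames} smaller than max frame index {max_frame}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_intensity(self) -> bool:
        return "intensity" in self.data.columns

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        """(n,) int array of 1-based frame indices."""
        return self.data["frame"].to_numpy(dtype=np.int64)

    def with_data(self, data: pd.DataFrame) -> "LocalizationTable":
        """Copy of this table with replaced rows, same metadata."""
        return LocalizationTable(
            data=data.reset_index(drop=True),
            channel_id=self.channel_id,
            n_frames=self.n_frames,
            column_names=dict(self.column_names),
        )


def read_localizations(
    path,
    dialect: CsvDialect | None = None,
    channel_id: str = "",
) -> LocalizationTable:
    """Read a localization CSV (ThunderSTORM dialect by default).

    Rows whose frame/x/y fields are non-numeric are rejected (dropped with a
    warning); missing mandatory columns raise :class:`LocalizationFormatError`
    naming the accepted aliases.
    """
    dialect = dialect or CsvDialect()
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyTableError(f"{path}: file contains no data") from None
    if raw.empty:
        raise EmptyTableError(f"{path}: no localization rows")

    header = [str(c).strip() for c in raw.columns]
    raw.columns = header
    found = dialect.resolve(header)
    for mandatory in ("frame", "x", "y"):
        if mandatory not in found:
            raise LocalizationFormatError(
                f"{path}: no column for '{mandatory}'; accepted aliases: "
                f"{list(dialect.aliases[mandatory])}"
            )

    canonical_order = [c for c in ("frame", "x", "y", "intensity", "uncertainty") if c in found]
    data = raw[[found[c] for c in canonical_order]].copy()
    data.columns = canonical_order
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric[["frame", "x", "y"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d rows with non-numeric fields", path, int(bad.sum()))
    data = numeric[~bad].reset_index(drop=True)
    if data.empty:
        raise EmptyTableError(f"{path}: no valid localization rows")
    data["frame"] = data["frame"].astype(np.int64)
    return LocalizationTable(
        data=data,
        channel_id=channel_id,
        column_names={c: found[c] for c in canonical_order},
    )


def write_localizations(table: LocalizationTable, path) -> str:
    """Write *table* as CSV re-importable by ThunderSTORM and by this package.

    Uses the header spellings recorded at read time; a table built in memory
    falls back to the ThunderSTORM spellings.  Coordinates are written with
    repr-precision so a read/write round trip preserves them bitwise.
    """
    if not len(table):
        raise EmptyTableError("refusing to write an empty localization table")
    dialect = CsvDialect()
    out = table.data.copy()
    out.columns = [
        table.column_names.get(c, dialect.aliases[c][0]) for c in table.data.columns
    ]
    out.to_csv(path, index=False, float_format="%.17g")
    return str(path)


def filter_by_intensity(table: LocalizationTable, min_intensity: float) -> LocalizationTable:
    """Keep localizations with ``intensity >= min_intensity``.

    The boundary value is kept: background suppression discards only rows
    strictly below the threshold.  A table without an intensity column passes
    through unchanged when the threshold is 0, and is an error otherwise
    (silently keeping everything would defeat the filter).
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be >= 0")
    if not table.has_intensity:
        if min_intensity > 0:
            raise ValueError(
                "table has no intensity column; cannot filter with min_intensity > 0"
            )
        return table.with_data(table.data.copy())
    keep = table.data["intensity"].to_numpy(dtype=float) >= min_intensity
    return table.with_data(table.data[keep])


def restrict_frames(table: LocalizationTable, first: int, last: int) -> LocalizationTable:
    """Keep localizations with ``first <= frame <= last`` (inclusive).

    Frames are re-indexed to ``1 .. last-first+1`` and ``n_frames`` is set to
    the restricted range length, so the per-frame detection statistics
    normalize over included frames only.  An empty result is permitted (a
    warning is logged) — downstream detection will raise if it matters.
    """
    if not (1 <= first <= last):
        raise ValueError(f"invalid frame range [{first}, {last}]")
    frames = table.data["frame"].to_numpy()
    keep = (frames >= first) & (frames <= last)
    data = table.data[keep].copy()
    data["frame"] = data["frame"] - (first - 1)
    if data.empty:
        warnings.warn(
            f"frame restriction [{first}, {last}] left no localizations", stacklevel=2
        )
    result = LocalizationTable(
        data=data.reset_index(drop=True),
        channel_id=table.channel_id,
        n_frames=last - first + 1,
        column_names=dict(table.column_names),
    )
    return result
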