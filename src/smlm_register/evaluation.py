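"""Registration-quality metrics: TRE, NCC, annotation snapping, Wilcoxon test.

Target Registration Error (TRE) is the Euclidean distance between
index-matched landmark annotations in two channels; its per-pair values
before vs. after registration are compared with a two-sided Wilcoxon
signed-rank test.  Normalized Cross-Correlation (NCC) is the product-moment
correlation of pixel intensities of two images rendered from the
localization tables,

    NCC = sum_ij (I1_ij - mean(I1)) (I2_ij - mean(I2)) / (N M sigma1 sigma2)

with population standard deviations, so NCC is in [-1, 1] and invariant to
affine intensity rescaling of either image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .localization_io import EmptyTableError, LocalizationTable

__all__ = [
    "AnnotationSet",
    "RenderedImage",
    "TRESummary",
    "snap_annotations",
    "tre",
    "render",
    "ncc",
    "paired_wilcoxon",
    "read_annotations",
]


@dataclass
class AnnotationSet:
    """Index-matched (x, y) annotations (nm) for one channel."""

    points: np.ndarray  # (n, 2) float, nm
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class RenderedImage:
    """Pixel grid synthesized from localizations (used only for NCC)."""

    pixels: np.ndarray  # (ny, nx), nonnegative
    pixel_size: float  # nm / pixel
    origin: tuple[float, float] = (0.0, 0.0)  # nm position of pixel (0, 0) corner

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2D grid of at least 1x1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class TRESummary:
    """Per-pair distances with mean ± sample SD (divisor n-1)."""

    distances: np.ndarray
    mean: float
    sd: float
    n: int


def read_annotations(path, channel_id: str = "") -> AnnotationSet:
    """Read a 2-column x,y text file (nm), comma- or whitespace-delimited.

    Compatible with ImageJ multi-point exports saved as plain text.
    """
    pts = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",", ndmin=2)
    return AnnotationSet(points=pts[:, :2], channel_id=channel_id)


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                return "," not in line
    return True


def snap_annotations(annotations: AnnotationSet, table: LocalizationTable) -> AnnotationSet:
    """Replace each annotation by the nearest localization coordinate.

    Manual clicks land near, not on, the structures they mark; snapping to
    the closest recorded localization removes that hand jitter.  Ties are
    broken toward the lowest row index.
    """
    if not len(table):
        raise EmptyTableError("cannot snap annotations to an empty table")
    xy = table.xy
    snapped = np.empty_like(annotations.points)
    for i, p in enumerate(annotations.points):
        d2 = np.sum((xy - p) ** 2, axis=1)
        snapped[i] = xy[int(np.argmin(d2))]  # argmin takes the first (lowest-index) minimum
    return AnnotationSet(points=snapped, channel_id=annotations.channel_id)


def tre(points_moving: AnnotationSet, points_reference: AnnotationSet) -> TRESummary:
    """Per-pair Euclidean distances between index-matched annotation sets."""
    a, b = points_moving.points, points_reference.points
    if len(a) != len(b):
        raise ValueError(f"annotation counts differ: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("need at least one annotation pair")
    d = np.linalg.norm(a - b, axis=1)
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return TRESummary(distances=d, mean=float(np.mean(d)), sd=sd, n=len(d))


def render(
    table: LocalizationTable,
    pixel_size: float,
    sigma: float = 20.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> RenderedImage:
    """Render localizations to a pixel grid for NCC evaluation.

    Each localization deposits a unit-integral 2D Gaussian of width *sigma*
    (nm), pixel-integrated via the error function so total intensity equals
    the number of in-bounds localizations up to boundary truncation;
    ``sigma = 0`` gives a plain 2D histogram.

    Parameters
    ----------
    bounds
        ``(xmin, xmax, ymin, ymax)`` in nm; defaults to the data extent
        padded by ``3 sigma``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    xy = table.xy
    if bounds is None:
        if not len(table):
            raise ValueError("cannot infer bounds from an empty table")
        pad = 6 * sigma + pixel_size  # keep >1-1e-9 of each spot's mass in frame
        bounds = (
            float(xy[:, 0].min()) - pad,
            float(xy[:, 0].max()) + pad,
            float(xy[:, 1].min()) - pad,
            float(xy[:, 1].max()) + pad,
        )
    xmin, xmax, ymin, ymax = bounds
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"empty bounds {bounds}")
    nx = max(1, int(np.ceil((xmax - xmin) / pixel_size)))
    ny = max(1, int(np.ceil((ymax - ymin) / pixel_size)))
    # snap the upper bounds so every pixel is exactly pixel_size wide
    xmax = xmin + nx * pixel_size
    ymax = ymin + ny * pixel_size

    if sigma == 0:
        img, _, _ = np.histogram2d(
            xy[:, 1], xy[:, 0], bins=(ny, nx), range=((ymin, ymax), (xmin, xmax))
        )
        return RenderedImage(pixels=img, pixel_size=pixel_size, origin=(xmin, ymin))

    img = np.zeros((ny, nx))
    xedges = xmin + pixel_size * np.arange(nx + 1)
    yedges = ymin + pixel_size * np.arange(ny + 1)
    half = int(np.ceil(5 * sigma / pixel_size)) + 1  # ±5 sigma support per spot
    root2s = np.sqrt(2.0) * sigma
    from scipy.special import erf

    for x, y in xy:
        cx = int((x - xmin) / pixel_size)
        cy = int((y - ymin) / pixel_size)
        x0, x1 = max(0, cx - half), min(nx, cx + half + 1)
        y0, y1 = max(0, cy - half), min(ny, cy + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        fx = 0.5 * (erf((xedges[x0 : x1 + 1] - x) / root2s))
        fy = 0.5 * (erf((yedges[y0 : y1 + 1] - y) / root2s))
        img[y0:y1, x0:x1] += np.outer(np.diff(fy), np.diff(fx))
    return RenderedImage(pixels=img, pixel_size=pixel_size, origin=(xmin, ymin))


def ncc(image1: RenderedImage, image2: RenderedImage) -> float:
    """Normalized cross-correlation of two same-geometry rendered images."""
    if image1.pixels.shape != image2.pixels.shape:
        raise ValueError(
            f"image shapes differ: {image1.pixels.shape} vs {image2.pixels.shape}"
        )
    if image1.pixel_size != image2.pixel_size:
        raise ValueError("pixel sizes differ")
    a = image1.pixels.ravel()
    b = image2.pixels.ravel()
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance image: correlation undefined")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def paired_wilcoxon(before: np.ndarray, after: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired distance samples.

    Used to test whether registration changed the TRE distribution; the
    conventional significance level is 0.05.  Identical samples (all
    differences zero) return p = 1 with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if len(before) < 5:
        raise ValueError("need at least 5 pairs for a meaningful signed-rank test")
    if np.all(before == after):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(before, after, alternative="two-sided")
    return float(res.pvalue)
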