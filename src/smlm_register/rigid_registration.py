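"""Rigid 2D registration of landmark sets via Iterative Closest Point.

The alignment model between sequentially acquired channels is rigid: a
rotation about the coordinate origin followed by a translation,

    T(p) = R(theta) p + t,    det R = +1 (no reflection, no scaling).

``estimate_rigid`` solves the landmark least-squares problem
``min sum ||T(m_i) - r_i||^2`` in closed form (centroid subtraction and the
angle of the 2x2 cross-covariance — the planar Kabsch/Procrustes solution).
``icp`` alternates nearest-neighbor correspondence with that fit: at every
iteration pair distances whose value exceeds ``mean + outlier_sd * SD`` of
the current distances are discarded as outliers (landmarks visible in only
one channel), the rigid fit is recomputed on the inliers, and iteration
stops once the inlier mean distance changes by less than ``convergence_tol``
(1 nm) between consecutive rounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fiducial_detect import LandmarkSet
from .localization_io import LocalizationTable

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform2D",
    "ICPConfig",
    "RegistrationResult",
    "DegenerateConfigurationError",
    "estimate_rigid",
    "icp",
    "apply_transform",
]


class DegenerateConfigurationError(ValueError):
    """The point configuration does not determine a rigid transform."""


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` about the origin, then translation by ``(tx, ty)``."""

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of points; a single (2,) point is also accepted."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equal to applying *other* first, then *self*."""
        t = self.rotation @ other.translation + self.translation
        return RigidTransform2D(theta=self.theta + other.theta, tx=float(t[0]), ty=float(t[1]))

    def inverse(self) -> "RigidTransform2D":
        t = -self.rotation.T @ self.translation
        return RigidTransform2D(theta=-self.theta, tx=float(t[0]), ty=float(t[1]))

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls()


@dataclass(frozen=True)
class ICPConfig:
    """ICP control parameters.

    ``convergence_tol`` is the threshold (nm) on the change of the inlier
    mean nearest-neighbor distance between consecutive iterations;
    ``outlier_sd`` the number of standard deviations above the mean distance
    beyond which a pair is an outlier; ``max_iterations`` guards against
    oscillation (a warning is emitted if reached without convergence).
    """

    convergence_tol: float = 1.0
    max_iterations: int = 100
    outlier_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Outcome of one ICP run: the transform plus diagnostics."""

    transform: RigidTransform2D
    n_iterations: int
    final_mean_distance: float
    matched_pairs: list[tuple[int, int]]
    converged: bool
    mean_distances: list[float] = field(default_factory=list)


def estimate_rigid(moving_pts: np.ndarray, reference_pts: np.ndarray) -> RigidTransform2D:
    """Least-squares rigid transform mapping *moving_pts* onto *reference_pts*.

    Closed form: subtract centroids, take ``theta = atan2`` of the
    cross-covariance components (guaranteeing ``det R = +1``), then recover
    the translation from the centroids.

    Raises
    ------
    DegenerateConfigurationError
        Fewer than 2 pairs, or all moving points coincident (the rotation is
        then unidentifiable).
    """
    m = np.asarray(moving_pts, dtype=float)
    r = np.asarray(reference_pts, dtype=float)
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("point sets must both be (n, 2) arrays of equal length")
    if len(m) < 2:
        raise DegenerateConfigurationError("need at least 2 point pairs for a rigid fit")
    cm, cr = m.mean(axis=0), r.mean(axis=0)
    dm, dr = m - cm, r - cr
    if not np.any(np.abs(dm) > 0):
        raise DegenerateConfigurationError(
            "all moving points coincide; rotation is unidentifiable"
        )
    # cross-covariance H = dm^T dr; optimal angle maximizes trace(R H)
    h = dm.T @ dr
    theta = float(np.arctan2(h[0, 1] - h[1, 0], h[0, 0] + h[1, 1]))
    rot = RigidTransform2D(theta=theta)
    t = cr - rot.rotation @ cm
    return RigidTransform2D(theta=theta, tx=float(t[0]), ty=float(t[1]))


def icp(
    moving: LandmarkSet | np.ndarray,
    reference: LandmarkSet | np.ndarray,
    config: ICPConfig | None = None,
) -> RegistrationResult:
    """Align *moving* landmarks onto *reference* landmarks by ICP.

    Correspondences run moving -> nearest reference neighbor.  The returned
    transform is the exact composition of all iteration updates and maps
    original moving coordinates into reference space.

    Raises
    ------
    DegenerateConfigurationError
        If either set has fewer than 2 landmarks or outlier rejection leaves
        fewer than 2 pairs.
    """
    config = config or ICPConfig()
    mov = moving.xy if isinstance(moving, LandmarkSet) else np.asarray(moving, dtype=float)
    ref = reference.xy if isinstance(reference, LandmarkSet) else np.asarray(reference, dtype=float)
    if len(mov) < 2 or len(ref) < 2:
        raise DegenerateConfigurationError(
            f"ICP needs >= 2 landmarks per channel (got {len(mov)} moving, {len(ref)} reference)"
        )

    tree = cKDTree(ref)
    total = RigidTransform2D.identity()
    current = mov.copy()
    prev_mean: float | None = None
    mean_history: list[float] = []
    converged = False
    inlier_idx = np.arange(len(mov))
    nn_idx = np.zeros(len(mov), dtype=int)
    n_done = 0

    for iteration in range(1, config.max_iterations + 1):
        n_done = iteration
        dists, nn_idx = tree.query(current)
        inliers = _trim_outliers(dists, config.outlier_sd)
        inlier_idx = np.flatnonzero(inliers)
        if inlier_idx.size < 2:
            raise DegenerateConfigurationError(
                f"outlier rejection left {inlier_idx.size} of {len(mov)} pairs at "
                f"iteration {iteration} (mean {float(np.mean(dists)):.1f} nm, "
                f"SD {float(np.std(dists)):.1f} nm)"
            )
        inlier_mean = float(np.mean(dists[inliers]))
        mean_history.append(inlier_mean)
        if prev_mean is not None and abs(inlier_mean - prev_mean) < config.convergence_tol:
            converged = True
            break
        prev_mean = inlier_mean
        step = estimate_rigid(current[inliers], ref[nn_idx[inliers]])
        total = step.compose(total)
        current = step.apply(current)

    if not converged:
        warnings.warn(
            f"ICP did not converge in {config.max_iterations} iterations "
            f"(last mean distance {mean_history[-1]:.3g} nm)",
            stacklevel=2,
        )
    pairs = [(int(i), int(nn_idx[i])) for i in inlier_idx]
    return RegistrationResult(
        transform=total,
        n_iterations=n_done,
        final_mean_distance=mean_history[-1],
        matched_pairs=pairs,
        converged=converged,
        mean_distances=mean_history,
    )


def _trim_outliers(dists: np.ndarray, outlier_sd: float) -> np.ndarray:
    """Boolean inlier mask: pairs with distance > mean + outlier_sd * SD are out.

    The rule is applied recursively — after discarding outliers the mean and
    SD are recomputed on the survivors and the rule re-applied until the set
    is stable.  A single pass is not robust here: landmark nearest-neighbor
    distances are heavy-tailed when some landmarks exist in only one
    channel, and one pass can leave moderately distant spurious pairs inside
    the threshold, where they bias the rigid fit into a contaminated
    equilibrium.  Two guards keep the recursion from eating good pairs:
    a pair is only discarded if its distance is also materially large —
    at least twice the surviving mean and above 1e-6 nm — so a unimodal
    distance distribution (early iterations, or pure numerical noise at
    convergence) is never trimmed; and trimming never discards more than
    half of the pairs (floor of max(3, n/2) survivors), so the fit always
    follows the majority correspondences.
    """
    floor = max(3, len(dists) // 2)
    mask = np.ones(len(dists), dtype=bool)
    while mask.sum() > floor:
        d = dists[mask]
        cut = max(d.mean() + outlier_sd * d.std(), 2.0 * d.mean(), 1e-6)
        new_mask = mask & (dists <= cut)
        if new_mask.sum() == mask.sum() or new_mask.sum() < floor:
            break
        mask = new_mask
    return mask


def apply_transform(table: LocalizationTable, transform: RigidTransform2D) -> LocalizationTable:
    """Map every localization's (x, y); all other columns and order unchanged."""
    data = table.data.copy()
    xy = transform.apply(table.xy)
    data["x"] = xy[:, 0]
    data["y"] = xy[:, 1]
    return table.with_data(data)
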