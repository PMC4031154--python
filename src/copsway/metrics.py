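"""Center-of-pressure (COP) trajectory parameters.

A quiet-standing trial on a force platform yields a planar COP trajectory:
laterolateral (``x``) and anteroposterior (``y``) coordinates in millimetres
sampled at a fixed rate.  Nine scalar parameters summarise one trial:

==========  =======  ====================================================
parameter   units    definition
==========  =======  ====================================================
``L``       mm       path length, sum of consecutive segment lengths
``V``       mm/s     mean velocity, ``L`` divided by trial duration
``V_AP``    mm/s     anteroposterior velocity, per-axis path over duration
``V_LL``    mm/s     laterolateral velocity, per-axis path over duration
``X``       mm       mean laterolateral position
``Y``       mm       mean anteroposterior position
``A``       cm^2     area of the 90 % prediction ellipse
``SA1``     cm       major semiaxis of that ellipse
``SA2``     cm       minor semiaxis of that ellipse
==========  =======  ====================================================

The 90 % ellipse is the covariance-based prediction ellipse: with sample
covariance :math:`\\Sigma` (``n-1`` denominator) and eigenvalues
:math:`\\lambda_1 \\ge \\lambda_2`, the semiaxes are
:math:`\\sqrt{q\\,\\lambda_i}` where :math:`q` is the chi-square quantile
with 2 degrees of freedom at the requested coverage
(:math:`q \\approx 4.60517` at 0.90), so that for Gaussian sway the ellipse
contains the stated fraction of samples.  Semiaxes are principal-axis
aligned (SA1 = major), not platform-axis aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

__all__ = [
    "COPTrajectory",
    "COPMetrics",
    "path_length",
    "mean_velocity",
    "directional_velocities",
    "mean_position",
    "confidence_ellipse",
    "compute_all",
    "compute_metrics_batch",
    "METRIC_NAMES",
]

_log = logging.getLogger(__name__)

#: canonical order of the nine parameters, used by every table in the package
METRIC_NAMES = ("L", "V", "V_AP", "V_LL", "X", "Y", "A", "SA1", "SA2")

_MM2_PER_CM2 = 100.0
_MM_PER_CM = 10.0


@dataclass(frozen=True)
class COPTrajectory:
    """One trial's sampled COP path.

    Parameters
    ----------
    t : array of seconds, strictly increasing, uniformly spaced
    x : array of mm, laterolateral coordinate (positive right)
    y : array of mm, anteroposterior coordinate (positive forward)
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise InvalidArgumentError("t, x, y must be one-dimensional")
        if not (len(t) == len(x) == len(y)):
            raise InvalidArgumentError(
                f"t, x, y lengths differ: {len(t)}, {len(x)}, {len(y)}"
            )
        if len(t) < 2:
            raise InvalidArgumentError("a trajectory needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InvalidArgumentError("t must be strictly increasing")
        # uniform spacing within 1e-9 relative tolerance
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise InvalidArgumentError("t must be uniformly spaced")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (last minus first timestamp)."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class COPMetrics:
    """The nine scalar parameters of one trial (units as in the module docs)."""

    L: float
    V: float
    V_AP: float
    V_LL: float
    X: float
    Y: float
    A: float
    SA1: float
    SA2: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def path_length(traj: COPTrajectory) -> float:
    """Total path length L in mm: sum of segment lengths between samples."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def mean_velocity(traj: COPTrajectory) -> float:
    """Mean velocity V = L / duration, in mm/s."""
    if traj.duration <= 0:
        raise InvalidArgumentError("trial duration must be positive")
    return path_length(traj) / traj.duration


def directional_velocities(traj: COPTrajectory) -> tuple[float, float]:
    """(V_AP, V_LL): per-axis path length over duration, in mm/s."""
    dur = traj.duration
    if dur <= 0:
        raise InvalidArgumentError("trial duration must be positive")
    v_ap = float(np.abs(np.diff(traj.y)).sum()) / dur
    v_ll = float(np.abs(np.diff(traj.x)).sum()) / dur
    return v_ap, v_ll


def mean_position(traj: COPTrajectory) -> tuple[float, float]:
    """(X, Y): arithmetic mean of the coordinates, in mm."""
    return float(np.mean(traj.x)), float(np.mean(traj.y))


def confidence_ellipse(
    traj: COPTrajectory, coverage: float = 0.90
) -> tuple[float, float, float, float]:
    """Prediction ellipse of the COP samples.

    Returns ``(A, SA1, SA2, orientation)``: area in cm^2, major and minor
    semiaxes in cm, and the major-axis angle in radians within
    ``(-pi/2, pi/2]`` measured from the laterolateral axis.

    Collinear samples give a degenerate ellipse (``SA2 = 0``, ``A = 0``);
    this is logged as a warning, not raised.
    """
    if not 0.0 < coverage < 1.0:
        raise InvalidArgumentError("coverage must be in (0, 1)")
    if traj.n_samples < 3:
        raise InvalidArgumentError("ellipse needs at least 3 samples")
    cov = np.cov(traj.x, traj.y, ddof=1)
    lam, vec = np.linalg.eigh(cov)  # ascending eigenvalues
    lam = np.clip(lam, 0.0, None)
    lam1, lam2 = float(lam[1]), float(lam[0])
    if lam1 > 0 and lam2 <= 1e-12 * lam1:
        _log.warning("collinear COP samples: degenerate ellipse (SA2 = 0)")
        lam2 = 0.0
    q = stats.chi2.ppf(coverage, df=2)
    sa1 = math.sqrt(q * lam1) / _MM_PER_CM
    sa2 = math.sqrt(q * lam2) / _MM_PER_CM
    area = math.pi * sa1 * sa2
    major = vec[:, 1]
    orientation = math.atan2(major[1], major[0])
    # map to (-pi/2, pi/2]: an ellipse axis is direction-free
    if orientation > math.pi / 2:
        orientation -= math.pi
    elif orientation <= -math.pi / 2:
        orientation += math.pi
    return area, sa1, sa2, orientation


def compute_all(traj: COPTrajectory, coverage: float = 0.90) -> COPMetrics:
    """All nine parameters of one trial."""
    L = path_length(traj)
    V = mean_velocity(traj)
    v_ap, v_ll = directional_velocities(traj)
    X, Y = mean_position(traj)
    A, sa1, sa2, _ = confidence_ellipse(traj, coverage)
    return COPMetrics(L=L, V=V, V_AP=v_ap, V_LL=v_ll, X=X, Y=Y, A=A, SA1=sa1, SA2=sa2)


def compute_metrics_batch(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, coverage: float = 0.90
) -> dict[str, np.ndarray]:
    """Vectorised metrics for a stack of trials sharing one time base.

    ``x`` and ``y`` have shape ``(n_trials, n_samples)``; ``t`` has shape
    ``(n_samples,)``.  Returns ``{name: array of n_trials}`` for the nine
    parameters.  Equivalent to calling :func:`compute_all` per trial.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape != y.shape or t.shape != (x.shape[1],):
        raise InvalidArgumentError("x, y must be (n_trials, n_samples); t matching")
    if x.shape[1] < 3:
        raise InvalidArgumentError("batch metrics need at least 3 samples per trial")
    dur = float(t[-1] - t[0])
    if dur <= 0:
        raise InvalidArgumentError("trial duration must be positive")
    dx = np.diff(x, axis=1)
    dy = np.diff(y, axis=1)
    L = np.hypot(dx, dy).sum(axis=1)
    V = L / dur
    v_ap = np.abs(dy).sum(axis=1) / dur
    v_ll = np.abs(dx).sum(axis=1) / dur
    X = x.mean(axis=1)
    Y = y.mean(axis=1)
    n = x.shape[1]
    xc = x - X[:, None]
    yc = y - Y[:, None]
    sxx = np.einsum("ij,ij->i", xc, xc) / (n - 1)
    syy = np.einsum("ij,ij->i", yc, yc) / (n - 1)
    sxy = np.einsum("ij,ij->i", xc, yc) / (n - 1)
    half_tr = 0.5 * (sxx + syy)
    root = np.sqrt(np.clip(0.25 * (sxx - syy) ** 2 + sxy**2, 0.0, None))
    lam1 = np.clip(half_tr + root, 0.0, None)
    lam2 = np.clip(half_tr - root, 0.0, None)
    q = stats.chi2.ppf(coverage, df=2)
    sa1 = np.sqrt(q * lam1) / _MM_PER_CM
    sa2 = np.sqrt(q * lam2) / _MM_PER_CM
    area = np.pi * sa1 * sa2
    return {
        "L": L,
        "V": V,
        "V_AP": v_ap,
        "V_LL": v_ll,
        "X": X,
        "Y": Y,
        "A": area,
        "SA1": sa1,
        "SA2": sa2,
    }
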