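"""Circular statistics used as internal controls on inferred positions.

* :func:`periodic_loess` — local polynomial regression of a response on a
  circular predictor, made periodic by fitting on three concatenated copies
  of the data shifted by one period and keeping the middle window; R^2 is
  computed on the middle copy only.
* :func:`circular_corr` — the Fisher–Lee circular correlation coefficient
  with von Mises maximum-likelihood circular means.
* :func:`aligned_circular_rho` — circular correlation maximized over a
  global rotation offset and optional reflection, the right score when one
  angle is only defined up to rotation/reflection of an embedding.
* :func:`angular_silhouette` — silhouette index under the angular
  separation distance d(i,j) = 1 - cos(theta_i - theta_j).
* :func:`proliferation_fraction` — fraction of cells in the open interval
  (0.25*pi, 1.5*pi), interpreted as actively proliferating (S/G2/M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi

DEFAULT_SPAN = 0.3
DEFAULT_DEGREE = 2


@dataclass
class PeriodicFit:
    """A periodic loess fit: grid curve, per-point fit, and middle-copy R^2."""

    theta: np.ndarray  # input angles (wrapped, NaN dropped)
    y: np.ndarray
    fitted: np.ndarray  # fit at the input angles
    grid: np.ndarray  # evaluation grid over [0, 2*pi)
    grid_fitted: np.ndarray
    span: float
    degree: int
    r_squared: float  # NaN when SS_total == 0

    def peak_location(self) -> float:
        """Angle of maximal fitted response on the grid."""
        return float(self.grid[np.argmax(self.grid_fitted)])


@dataclass
class CircCorrResult:
    rho: float
    mu1: float
    mu2: float
    n: int


@dataclass
class AlignedRho:
    """Best circular correlation over rotation offsets (and reflection)."""

    rho: float
    offset: float
    reflected: bool


@dataclass
class SilhouetteResult:
    s: np.ndarray  # per cell
    a: np.ndarray
    b: np.ndarray
    mean_s: float
    labels: np.ndarray


# -- loess -----------------------------------------------------------------


def _loess(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float, degree: int) -> np.ndarray:
    """Local weighted polynomial regression with tricube weights.

    For each evaluation point the ``ceil(span * n)`` nearest data points are
    used, weighted by tricube of distance scaled to the neighborhood radius.
    """
    n = len(x)
    k = min(n, max(degree + 2, int(np.ceil(span * n))))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        if k < n:
            nearest = np.argpartition(d, k - 1)[:k]
        else:
            nearest = np.arange(n)
        dk = d[nearest]
        dmax = dk.max()
        if dmax == 0:
            out[i] = ys[nearest].mean()
            continue
        w = np.clip(1.0 - (dk / dmax) ** 3, 0.0, None) ** 3
        sw = np.sqrt(w)
        design = np.vander(xs[nearest] - x0, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ys[nearest] * sw, rcond=None)
        out[i] = coef[0]
    return out


def periodic_loess(
    theta,
    y,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    n_grid: int = 512,
) -> PeriodicFit:
    """Periodic local regression of ``y`` on a circular predictor.

    Angles are wrapped into [0, 2*pi); pairs with NaN in either variable
    are dropped (count logged as a warning).  The loess is fitted on the
    tripled data ([theta - 2*pi, theta, theta + 2*pi], [y, y, y]) and the
    fit is reported at the original angles and on an ``n_grid``-point grid
    over [0, 2*pi).  R^2 = 1 - SS_res/SS_total uses middle-copy residuals
    only; it is NaN (with a warning) when y is constant and may be negative
    for pathological fits.

    ``span`` is the neighborhood fraction *of the tripled data*: the default
    0.3 gives a smoothing window of about 0.9 periods.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape != y.shape:
        raise ValueError("theta and y must have equal length")
    ok = np.isfinite(theta) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"periodic_loess: dropped {n_dropped} non-finite pairs", stacklevel=2)
    theta, y = np.mod(theta[ok], TWO_PI), y[ok]
    if len(theta) < 10:
        raise ValueError("periodic_loess needs at least 10 finite (theta, y) pairs")
    x3 = np.concatenate([theta - TWO_PI, theta, theta + TWO_PI])
    y3 = np.concatenate([y, y, y])
    grid = np.arange(n_grid) * TWO_PI / n_grid
    eval_points = np.concatenate([theta, grid])
    fit = _loess(x3, y3, eval_points, span=span, degree=degree)
    fitted, grid_fitted = fit[: len(theta)], fit[len(theta):]
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        warnings.warn("periodic_loess: constant response, R^2 undefined", stacklevel=2)
        r2 = np.nan
    else:
        r2 = 1.0 - ss_res / ss_total
    return PeriodicFit(
        theta=theta,
        y=y,
        fitted=fitted,
        grid=grid,
        grid_fitted=grid_fitted,
        span=span,
        degree=degree,
        r_squared=r2,
    )


# -- circular correlation --------------------------------------------------


def circular_mean(theta: np.ndarray) -> float:
    """Von Mises ML location: atan2 of the mean resultant components."""
    return float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))))


def circular_corr(theta1, theta2) -> CircCorrResult:
    """Fisher–Lee circular correlation between two angle vectors.

    rho = sum sin(t1 - mu1) sin(t2 - mu2) /
          sqrt(sum sin^2(t1 - mu1) * sum sin^2(t2 - mu2))

    NaN pairs are dropped (pairwise complete).  A degenerate vector (all
    angles identical, zero denominator) yields rho = NaN with a warning.
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    if theta1.shape != theta2.shape:
        raise ValueError("theta1 and theta2 must have equal length")
    ok = np.isfinite(theta1) & np.isfinite(theta2)
    theta1, theta2 = theta1[ok], theta2[ok]
    if len(theta1) < 3:
        raise ValueError("circular_corr needs at least 3 complete pairs")
    mu1, mu2 = circular_mean(theta1), circular_mean(theta2)
    s1, s2 = np.sin(theta1 - mu1), np.sin(theta2 - mu2)
    denom = np.sqrt(np.sum(s1**2) * np.sum(s2**2))
    if denom == 0:
        warnings.warn("circular_corr: degenerate (constant) angle vector", stacklevel=2)
        rho = np.nan
    else:
        rho = float(np.sum(s1 * s2) / denom)
    return CircCorrResult(rho=rho, mu1=mu1, mu2=mu2, n=len(theta1))


def circular_rank_rho(theta1, theta2) -> float:
    """Fisher–Lee rank circular correlation (circular analogue of Spearman).

    Both angle vectors are replaced by their uniform rank angles
    ``2*pi*rank/n``; with A = sum cos(b)cos(g), B = sum sin(b)sin(g),
    C = sum cos(b)sin(g), D = sum sin(b)cos(g) the statistic is
    ``(4/n^2)(AB - CD)``.  It lies in [-1, 1], equals 1 when one ordering
    is a rotation of the other, -1 for a reflection, and is invariant to
    any rotation of either variable — which makes it well defined even for
    uniform marginals, where the mean-direction-based coefficient is not.
    """
    theta1 = np.asarray(theta1, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)
    ok = np.isfinite(theta1) & np.isfinite(theta2)
    theta1, theta2 = theta1[ok], theta2[ok]
    n = len(theta1)
    if n < 3:
        raise ValueError("circular_rank_rho needs at least 3 complete pairs")
    b = TWO_PI * np.argsort(np.argsort(theta1, kind="stable"), kind="stable") / n
    g = TWO_PI * np.argsort(np.argsort(theta2, kind="stable"), kind="stable") / n
    a_ = np.sum(np.cos(b) * np.cos(g))
    b_ = np.sum(np.sin(b) * np.sin(g))
    c_ = np.sum(np.cos(b) * np.sin(g))
    d_ = np.sum(np.sin(b) * np.cos(g))
    return float(4.0 / n**2 * (a_ * b_ - c_ * d_))


def aligned_circular_rho(
    theta_ref,
    theta_est,
    method: str = "rank",
    n_offsets: int = 512,
    allow_reflection: bool = True,
) -> AlignedRho:
    """Circular concordance tolerant of the embedding's inherent ambiguity.

    Angles read off an embedding are defined only up to a global rotation
    and a reflection (direction of travel), so recovery must be scored
    after aligning for both.

    ``method="rank"`` (default) uses :func:`circular_rank_rho`, which is
    rotation invariant by construction, maximized over reflection.  This is
    the recommended recovery score: the mean-direction-based coefficient is
    unstable when the angle marginals are near uniform (the circular mean
    is then nearly unidentified and tracks any rotation applied to the
    data, so maximizing it over rotation offsets is ineffective).

    ``method="grid"`` performs the literal grid search: parametric
    :func:`circular_corr` over ``n_offsets`` rotation offsets times
    reflection, taking the maximum.  Use only with clearly non-uniform
    angle marginals.

    The reported offset is the circular mean of the aligned angle
    difference.
    """
    theta_ref = np.asarray(theta_ref, dtype=float)
    theta_est = np.asarray(theta_est, dtype=float)
    reflections = (False, True) if allow_reflection else (False,)
    best = AlignedRho(rho=-np.inf, offset=0.0, reflected=False)
    if method == "rank":
        ok = np.isfinite(theta_ref) & np.isfinite(theta_est)
        for reflected in reflections:
            base = np.mod(-theta_est if reflected else theta_est, TWO_PI)
            rho = circular_rank_rho(theta_ref, base)
            if rho > best.rho:
                off = circular_mean(theta_ref[ok] - base[ok])
                best = AlignedRho(rho=rho, offset=float(np.mod(off, TWO_PI)), reflected=reflected)
        return best
    if method == "grid":
        offsets = np.arange(n_offsets) * TWO_PI / n_offsets
        for reflected in reflections:
            base = -theta_est if reflected else theta_est
            for off in offsets:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho = circular_corr(theta_ref, np.mod(base + off, TWO_PI)).rho
                if np.isfinite(rho) and rho > best.rho:
                    best = AlignedRho(rho=rho, offset=float(off), reflected=reflected)
        if not np.isfinite(best.rho):
            raise ValueError("aligned_circular_rho: correlation undefined at every offset")
        return best
    raise ValueError("method must be 'rank' or 'grid'")


# -- silhouette ------------------------------------------------------------


def angular_silhouette(theta, labels) -> SilhouetteResult:
    """Silhouette index under d(i,j) = 1 - cos(theta_i - theta_j).

    a(i) is the mean distance to same-label cells (0 for singletons), b(i)
    the smallest mean distance to another label, and

        s(i) = (b - a) / max(a, b)   if the cell's label has > 1 member,
        s(i) = 0                     for singletons.

    Cells with NaN theta or the label "NA"/None are excluded.  A mean s
    above 0 indicates agreement between labels and angular position; the
    continuous nature of the cycle means boundaries are soft, so values
    well below cluster-separation levels are expected.
    """
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if theta.shape != labels.shape:
        raise ValueError("theta and labels must have equal length")
    def _is_na_label(l) -> bool:
        if l is None or (isinstance(l, float) and np.isnan(l)):
            return True
        return str(l) in ("NA", "nan", "")

    ok = np.isfinite(theta) & ~np.array([_is_na_label(l) for l in labels])
    theta, labels = theta[ok], labels[ok]
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("angular_silhouette needs at least 2 distinct labels")
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # per-label resultant sums: mean distance to a label needs only these
    sums = {
        k: (np.sum(cos_t[labels == k]), np.sum(sin_t[labels == k]), int(np.sum(labels == k)))
        for k in uniq
    }
    n = len(theta)
    a = np.zeros(n)
    b = np.empty(n)
    s = np.zeros(n)
    for i in range(n):
        k = labels[i]
        sc, ss, nk = sums[k]
        if nk > 1:
            # mean over same-label cells excluding self
            a[i] = 1.0 - (cos_t[i] * (sc - cos_t[i]) + sin_t[i] * (ss - sin_t[i])) / (nk - 1)
        b[i] = min(
            1.0 - (cos_t[i] * sc2 + sin_t[i] * ss2) / n2
            for k2, (sc2, ss2, n2) in sums.items()
            if k2 != k
        )
        if sums[k][2] > 1:
            denom = max(a[i], b[i])
            s[i] = (b[i] - a[i]) / denom if denom > 0 else 0.0
    return SilhouetteResult(s=s, a=a, b=b, mean_s=float(s.mean()), labels=labels)


# -- proliferation index ---------------------------------------------------

PROLIF_LO = 0.25 * np.pi
PROLIF_HI = 1.5 * np.pi


@dataclass
class ProliferationResult:
    fraction: float
    flags: np.ndarray  # per input cell; False where theta is NaN
    n_defined: int


def proliferation_fraction(theta) -> ProliferationResult:
    """Fraction of cells with theta strictly inside (0.25*pi, 1.5*pi).

    The interval covers S/G2/M; cells there count as actively
    proliferating.  NaN positions are excluded from the denominator (count
    logged as a warning).
    """
    theta = np.asarray(theta, dtype=float)
    defined = np.isfinite(theta)
    if not defined.any():
        raise ValueError("proliferation_fraction: no defined theta values")
    n_na = int((~defined).sum())
    if n_na:
        warnings.warn(
            f"proliferation_fraction: excluded {n_na} cells with undefined theta",
            stacklevel=2,
        )
    flags = defined & (theta > PROLIF_LO) & (theta < PROLIF_HI)
    return ProliferationResult(
        fraction=float(flags.sum() / defined.sum()),
        flags=flags,
        n_defined=int(defined.sum()),
    )
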