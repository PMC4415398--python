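"""Value-curve fits in (H, K) space and the local loss-aversion ratio.

Each limb of the relative-preference value graph (approach, K > 0;
avoidance, K < 0) is fitted with a monotone curve through the origin.
Loss aversion is the local, slope-ratio definition: s- and s+ are the
mean slope of each fitted limb over the fraction of the H-range closest
to the origin (default 10%), and lambda = |s-/s+|.  A cohort-level
two-standard-deviation rule flags lambda outliers before any group
statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .keypress_analysis import CategoryValuation

FORMS = ("power", "linear", "quadratic")

#: minimum relative H spread (range / max) below which the power
#: exponent is unidentifiable and the limb falls back to the linear form
MIN_POWER_H_SPREAD = 0.05


class UnfittableLimbError(ValueError):
    """The limb's points cannot identify the requested curve form."""


@dataclass
class ValueCurveFit:
    """A fitted limb: |K| = a*H^b (power), a*H (linear) or
    a*H + b*H^2 (quadratic); avoidance limbs carry sign -1."""

    limb: str  # "approach" | "avoidance"
    form: str
    params: tuple[float, float]
    h_range: tuple[float, float]
    rms_residual: float
    n_points: int

    def magnitude(self, h: np.ndarray | float) -> np.ndarray | float:
        """|K| at H = h."""
        a, b = self.params
        h = np.asarray(h, dtype=float)
        if self.form == "power":
            return a * h**b
        if self.form == "linear":
            return a * h
        return a * h + b * h**2

    def predict(self, h):
        """Signed K at H = h."""
        sign = -1.0 if self.limb == "avoidance" else 1.0
        return sign * self.magnitude(h)


@dataclass
class LossAversionResult:
    subject_id: str
    s_minus: float  # <= 0, avoidance-limb local slope
    s_plus: float  # >= 0, approach-limb local slope
    lam: float  # |s_minus / s_plus|
    window_fraction: float = 0.10
    outlier: bool = False


def fit_value_curve(
    points: Sequence[tuple[float, float]],
    form: str = "power",
    limb: str | None = None,
) -> ValueCurveFit:
    """Least-squares fit of one limb's (H, K) points.

    The limb is inferred from the sign of K unless given.  The power
    form is fit by log-log regression (exact on noiseless power data);
    linear is the through-origin slope and is defined down to a single
    point; quadratic solves the two-column normal equations.
    """
    if form not in FORMS:
        raise ValueError(f"form must be one of {FORMS}")
    pts = [(float(h), float(k)) for h, k in points]
    if not pts:
        raise UnfittableLimbError("no points")
    H = np.array([p[0] for p in pts])
    K = np.array([p[1] for p in pts])
    if np.any(H < 0):
        raise UnfittableLimbError("H must be non-negative")
    signs = np.sign(K[K != 0])
    if signs.size and not (np.all(signs > 0) or np.all(signs < 0)):
        raise UnfittableLimbError("limb points must share a sign")
    if limb is None:
        limb = "avoidance" if (signs.size and signs[0] < 0) else "approach"
    absK = np.abs(K)

    n = len(pts)
    min_pts = 1 if form == "linear" else 2
    if n < min_pts:
        raise UnfittableLimbError(f"{form} fit needs >= {min_pts} points")
    if form != "linear" and np.unique(H).size < 2:
        raise UnfittableLimbError("all H identical: limb unfittable")

    if form == "linear":
        denom = float(np.sum(H**2))
        if denom == 0:
            raise UnfittableLimbError("all H zero: limb unfittable")
        a = float(np.sum(H * absK) / denom)
        params = (a, 0.0)
    elif form == "power":
        mask = (H > 0) & (absK > 0)
        if mask.sum() < 2 or np.unique(H[mask]).size < 2:
            raise UnfittableLimbError("power fit needs >= 2 strictly positive points")
        h_spread = (H[mask].max() - H[mask].min()) / H[mask].max()
        if h_spread < MIN_POWER_H_SPREAD:
            raise UnfittableLimbError(
                f"H spread {h_spread:.3g} too small to identify a power exponent"
            )
        x = np.log(H[mask])
        y = np.log(absK[mask])
        b, loga = np.polyfit(x, y, 1)
        params = (float(math.exp(loga)), float(b))
    else:  # quadratic through the origin: a*H + b*H^2
        X = np.column_stack([H, H**2])
        sol, *_ = np.linalg.lstsq(X, absK, rcond=None)
        params = (float(sol[0]), float(sol[1]))

    fit = ValueCurveFit(
        limb=limb,
        form=form,
        params=params,
        h_range=(0.0, float(H.max())) if form == "linear" else (float(H.min()), float(H.max())),
        rms_residual=0.0,
        n_points=n,
    )
    resid = absK - np.asarray(fit.magnitude(H))
    fit.rms_residual = float(np.sqrt(np.mean(resid**2)))
    return fit


def local_slope(fit: ValueCurveFit, fraction: float = 0.10) -> float:
    """Mean slope of the fitted curve over the window of width
    ``fraction * (H-range)`` starting at the endpoint nearest the
    origin (smallest |K|): ``(f(h0 + w) - f(h0)) / w``.  Signed:
    negative for the avoidance limb."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    lo, hi = fit.h_range
    width = hi - lo
    if width <= 0:
        raise ValueError("zero-width h_range")
    # the limbs meet near K = 0, so the origin-side endpoint is the one
    # with the smaller fitted |K|
    h0 = lo if fit.magnitude(lo) <= fit.magnitude(hi) else hi - fraction * width
    w = fraction * width
    slope_mag = (fit.magnitude(h0 + w) - fit.magnitude(h0)) / w
    return float(-slope_mag if fit.limb == "avoidance" else slope_mag)


def loss_aversion(
    fit_minus: ValueCurveFit,
    fit_plus: ValueCurveFit,
    fraction: float = 0.10,
    subject_id: str = "",
) -> LossAversionResult:
    """lambda = |s-/s+| from the two limb fits' local slopes."""
    if fit_minus.limb != "avoidance" or fit_plus.limb != "approach":
        raise ValueError("expected (avoidance, approach) limb fits")
    s_minus = local_slope(fit_minus, fraction)
    s_plus = local_slope(fit_plus, fraction)
    if s_plus == 0:
        warnings.warn(f"subject {subject_id!r}: zero approach slope; lambda infinite")
        lam = math.inf
    else:
        lam = abs(s_minus / s_plus)
    return LossAversionResult(
        subject_id=subject_id,
        s_minus=s_minus,
        s_plus=s_plus,
        lam=lam,
        window_fraction=fraction,
    )


def flag_outliers(values: Sequence[float], k: float = 2.0) -> np.ndarray:
    """Cohort-level outlier rule: flag value i iff
    ``|x_i - mean| > k * sd`` with the sample (n-1) standard deviation
    over all values.  Non-finite values are always flagged; a constant
    cohort (sd = 0) flags nothing finite."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for the outlier rule")
    finite = np.isfinite(x)
    flags = ~finite
    if finite.sum() >= 2:
        m = x[finite].mean()
        sd = x[finite].std(ddof=1)
        if sd > 0:
            flags = flags | (np.abs(np.where(finite, x, m) - m) > k * sd)
    return flags


def subject_loss_aversion(
    valuations: Sequence[CategoryValuation],
    form: str = "power",
    fraction: float = 0.10,
    subject_id: str = "",
) -> LossAversionResult:
    """Limb split + fit + slope ratio for one subject's category points.

    Limb membership follows the paradigm's valence classes where the
    category is a known face condition (angry/fearful/sad -> avoidance,
    happy -> approach); neutral-valence and baseline categories never
    enter the fits, and a known-valence category whose K carries the
    wrong sign (a subject pressing toward a nominally aversive
    category) is dropped with a warning.  Unknown category names fall
    back to the sign-derived limb label.  With the face set there is a
    single approach category, so the approach limb (and any limb the
    requested form cannot identify) falls back to the through-origin
    linear form; the form actually used is recorded on the fit.
    """
    from .task_design import VALENCE_CLASS

    pts_minus: list[tuple[float, float]] = []
    pts_plus: list[tuple[float, float]] = []
    for v in valuations:
        vclass = VALENCE_CLASS.get(v.category)
        if vclass == "negative":
            if v.K < 0:
                pts_minus.append((v.H, v.K))
            else:
                warnings.warn(
                    f"subject {subject_id!r}: {v.category} has non-negative K; dropped"
                )
        elif vclass == "positive":
            if v.K > 0:
                pts_plus.append((v.H, v.K))
            else:
                warnings.warn(
                    f"subject {subject_id!r}: {v.category} has non-positive K; dropped"
                )
        elif vclass is None:
            if v.limb == "avoidance":
                pts_minus.append((v.H, v.K))
            elif v.limb == "approach":
                pts_plus.append((v.H, v.K))
    if not pts_minus or not pts_plus:
        raise UnfittableLimbError(
            f"subject {subject_id!r}: need points on both limbs "
            f"({len(pts_minus)} avoidance, {len(pts_plus)} approach)"
        )
    fit_minus = _fit_with_fallback(pts_minus, form, "avoidance")
    fit_plus = _fit_with_fallback(pts_plus, form, "approach")
    return loss_aversion(fit_minus, fit_plus, fraction, subject_id=subject_id)


def _fit_with_fallback(points, form, limb) -> ValueCurveFit:
    try:
        return fit_value_curve(points, form=form, limb=limb)
    except UnfittableLimbError:
        if form == "linear":
            raise
        return fit_value_curve(points, form="linear", limb=limb)
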