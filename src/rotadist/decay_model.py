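"""Infestation–distance decay model for site-specifically overwintering pests.

The model is the exponential decay curve

    y = a * exp(-MD / b)

where ``MD`` is the minimum crop rotation distance in meters — the
edge-to-edge distance from a current crop site to the nearest previous-year
crop site — ``a`` is the y-intercept (percent seed infestation of a
non-rotated field) and ``b`` the e-folding scale in meters: the distance over
which predicted infestation falls by a factor 1/e.

Risk-buffer distances for planning are derived from fitted parameters:
inner = b (all grain peas), middle = b + SE(b), outer = b + SE(b) of the
fit restricted to insecticide-free sites (the worst case, since treatment
status of previous sites is generally unknown). Green peas, harvested
immature, interrupt the pea moth life cycle and carry a fixed 500 m safety
buffer instead of a fitted one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistanceObservation",
    "DecayFitResult",
    "BufferDerivation",
    "DecayFitError",
    "predict",
    "fit_decay",
    "derive_buffers",
    "significance_stars",
    "GREEN_PEA_BUFFER_M",
    "PEA_MOTH_FIT_ALL",
    "PEA_MOTH_FIT_NO_INSECTICIDE",
    "PEA_MOTH_FIT_INSECTICIDE",
    "PEA_MOTH_SITE_COUNTS",
    "site_count_summary",
]

#: Fixed safety buffer for previous-year green-pea sites (meters).
GREEN_PEA_BUFFER_M = 500


class DecayFitError(RuntimeError):
    """Nonlinear fit failed; the message carries the last iterate."""


@dataclass(frozen=True)
class DistanceObservation:
    """One (minimum distance, percent seed infestation) record."""

    md_m: float
    infestation_pct: float
    insecticide: bool | None = None

    def __post_init__(self):
        if self.md_m < 0:
            raise ValueError(f"md_m must be >= 0, got {self.md_m}")
        if not (0.0 <= self.infestation_pct <= 100.0):
            raise ValueError(
                f"infestation_pct must be in [0, 100], got {self.infestation_pct}"
            )


@dataclass(frozen=True)
class DecayFitResult:
    """Estimates and fit statistics of the exponential decay regression.

    ``rmse`` uses the regression convention sqrt(SSE / (n - p)) with p = 2
    parameters; ``r2_adj`` is 1 - (1 - R^2)(n - 1)/(n - p - 1) with R^2
    against the mean-only model; p-values come from t = estimate/SE on n - 2
    degrees of freedom. ``p_a``/``p_b`` are None for externally supplied
    (published) estimates whose exact p-values are unknown.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    rmse: float
    r2_adj: float
    n: int
    p_a: float | None = None
    p_b: float | None = None

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be positive")
        if self.se_a < 0 or self.se_b < 0 or self.rmse < 0:
            raise ValueError("standard errors and rmse must be non-negative")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.r2_adj > 1:
            raise ValueError("adjusted R^2 cannot exceed 1")

    @property
    def stars_a(self) -> str:
        return significance_stars(self.p_a)

    @property
    def stars_b(self) -> str:
        return significance_stars(self.p_b)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "rmse": self.rmse,
            "r2_adj": self.r2_adj,
            "n": self.n,
            "p_a": self.p_a,
            "p_b": self.p_b,
        }


@dataclass(frozen=True)
class BufferDerivation:
    """Inner/middle/outer risk-buffer distances in whole meters."""

    inner_m: int
    middle_m: int
    outer_m: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.inner_m, self.middle_m, self.outer_m)


def significance_stars(p: float | None) -> str:
    """Legend: ``***`` for p < 0.001, ``**`` for p < 0.01, ``*`` for p < 0.05."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def predict(a: float, b: float, md) -> float | np.ndarray:
    """Predicted percent infestation at minimum distance ``md`` (meters).

    Strictly decreasing in ``md``; equals ``a`` at ``md = 0``.
    """
    if a <= 0:
        raise ValueError(f"y-intercept a must be positive, got {a}")
    if b <= 0:
        raise ValueError(f"decay scale b must be positive, got {b}")
    md_arr = np.asarray(md, dtype=float)
    if np.any(md_arr < 0):
        raise ValueError("md must be >= 0")
    result = a * np.exp(-md_arr / b)
    return float(result) if np.isscalar(md) or md_arr.ndim == 0 else result


#: Optimizer box constraints: percent scale for a, geographic plausibility for b.
_A_BOUNDS = (1e-9, 100.0)
_B_BOUNDS = (1e-6, 1.0e6)
_MAX_NFEV = 10_000


def fit_decay(
    observations: Iterable[DistanceObservation],
    a0: float | None = None,
    b0: float | None = None,
    max_nfev: int = _MAX_NFEV,
) -> DecayFitResult:
    """Least-squares fit of y = a * exp(-md / b) to distance observations.

    Starting values default to a0 = max(y) and b0 = max(md)/2, which are
    robust for decay-shaped data; both are overridable. Parameters are
    box-constrained to a in (0, 100] and b in (0, 1e6] meters.

    Raises
    ------
    ValueError
        Fewer than 3 observations, fewer than 2 distinct distances, or no
        positive infestation (degenerate, unidentifiable — e.g. green peas).
    DecayFitError
        Optimizer did not converge within ``max_nfev`` evaluations; the
        message carries the last iterate.
    """
    obs = list(observations)
    md = np.array([o.md_m for o in obs], dtype=float)
    y = np.array([o.infestation_pct for o in obs], dtype=float)
    n = len(obs)
    if n < 3:
        raise ValueError(f"need >= 3 observations to fit, got {n}")
    if len(np.unique(md)) < 2:
        raise ValueError("need >= 2 distinct distances to identify the decay scale")
    if not np.any(y > 0):
        raise ValueError("degenerate: no positive infestation among observations")

    if a0 is None:
        a0 = float(np.clip(y.max(), _A_BOUNDS[0] * 10, _A_BOUNDS[1]))
    if b0 is None:
        b0 = float(np.clip(md.max() / 2.0, 1.0, _B_BOUNDS[1]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        return a * np.exp(-md / b) - y

    result = optimize.least_squares(
        residuals,
        x0=np.array([a0, b0]),
        bounds=(np.array([_A_BOUNDS[0], _B_BOUNDS[0]]), np.array([_A_BOUNDS[1], _B_BOUNDS[1]])),
        max_nfev=max_nfev,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    a_hat, b_hat = result.x
    if not result.success:
        raise DecayFitError(
            f"decay fit did not converge after {max_nfev} evaluations "
            f"(last iterate a={a_hat:.6g}, b={b_hat:.6g}): {result.message}"
        )

    dof = n - 2
    sse = float(np.sum(result.fun**2))
    rmse = math.sqrt(sse / dof)
    # Gauss-Newton covariance: s^2 * (J^T J)^-1 from the final Jacobian
    jtj = result.jac.T @ result.jac
    try:
        cov = (sse / dof) * np.linalg.inv(jtj)
        se_a, se_b = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_a = se_b = float("nan")

    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)

    def pval(est: float, se: float) -> float | None:
        if not np.isfinite(se):
            return None
        if se == 0:  # perfect fit: the t statistic diverges
            return 0.0 if est != 0 else None
        t = est / se
        return float(2.0 * stats.t.sf(abs(t), dof))

    return DecayFitResult(
        a=float(a_hat),
        b=float(b_hat),
        se_a=float(se_a),
        se_b=float(se_b),
        rmse=rmse,
        r2_adj=float(r2_adj),
        n=n,
        p_a=pval(a_hat, se_a),
        p_b=pval(b_hat, se_b),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def derive_buffers(
    fit_all: DecayFitResult, fit_no_insecticide: DecayFitResult
) -> BufferDerivation:
    """Derive the inner/middle/outer risk-buffer distances in whole meters.

    inner = round(b_all); middle = round(b_all + SE); outer =
    round(b_no_insecticide + SE). Rounding is half-away-from-zero. A violated
    inner <= middle <= outer ordering is data-dependent and only warned about.
    """
    inner = _round_half_away(fit_all.b)
    middle = _round_half_away(fit_all.b + fit_all.se_b)
    outer = _round_half_away(fit_no_insecticide.b + fit_no_insecticide.se_b)
    if not (inner <= middle <= outer):
        warnings.warn(
            f"derived buffers not ordered: inner={inner}, middle={middle}, outer={outer}",
            stacklevel=2,
        )
    return BufferDerivation(inner_m=inner, middle_m=middle, outer_m=outer)


# ---------------------------------------------------------------------------
# Published reference estimates — pea moth on grain peas, German monitoring
# 2016-2019 (three growing regions, 513 sample sites). Exact p-values were
# not published, only significance classes (a: p<0.001 in all groups;
# b: p<0.001 for the pooled fit, p<0.01 in the treatment subgroups).
# ---------------------------------------------------------------------------

PEA_MOTH_FIT_ALL = DecayFitResult(
    a=9.79, b=1260.70, se_a=0.92, se_b=299.45, rmse=9.10, r2_adj=0.05, n=370
)
PEA_MOTH_FIT_NO_INSECTICIDE = DecayFitResult(
    a=12.85, b=1426.23, se_a=1.45, se_b=398.92, rmse=9.98, r2_adj=0.08, n=188
)
PEA_MOTH_FIT_INSECTICIDE = DecayFitResult(
    a=8.13, b=619.05, se_a=1.09, se_b=187.02, rmse=7.41, r2_adj=0.07, n=182
)

#: Monitoring sample sites by (crop, region), year -> (with insecticide,
#: without insecticide). Regions: ST = Saxony-Anhalt, SN = Saxony, HE = Hesse.
PEA_MOTH_SITE_COUNTS: dict[tuple[str, str], dict[int, tuple[int, int]]] = {
    ("grain_pea", "ST"): {2016: (57, 1), 2017: (50, 3), 2018: (32, 9)},
    ("grain_pea", "SN"): {2016: (7, 21), 2017: (4, 15), 2018: (2, 9), 2019: (2, 6)},
    ("grain_pea", "HE"): {2016: (3, 31), 2017: (14, 44), 2018: (11, 34), 2019: (0, 15)},
    ("green_pea", "SN"): {2016: (33, 19), 2017: (13, 24), 2018: (20, 32), 2019: (0, 2)},
}


def site_count_summary() -> dict[str, int]:
    """Aggregate the monitoring sample bookkeeping.

    Returns totals over all sites plus the grain-pea counts split by
    insecticide treatment — the sample sizes behind the three reference fits.
    """
    total = 0
    grain_with = 0
    grain_without = 0
    green = 0
    for (crop, _region), years in PEA_MOTH_SITE_COUNTS.items():
        for with_ins, without_ins in years.values():
            total += with_ins + without_ins
            if crop == "grain_pea":
                grain_with += with_ins
                grain_without += without_ins
            else:
                green += with_ins + without_ins
    return {
        "total_sites": total,
        "grain_pea_with_insecticide": grain_with,
        "grain_pea_without_insecticide": grain_without,
        "grain_pea_total": grain_with + grain_without,
        "green_pea_total": green,
    }


def observations_from_frame(frame) -> list[DistanceObservation]:
    """Build observations from a DataFrame with columns md_m,
    infestation_pct and optionally insecticide."""
    has_ins = "insecticide" in frame.columns
    obs = []
    for row in frame.itertuples(index=False):
        ins = getattr(row, "insecticide", None) if has_ins else None
        if ins is not None and not isinstance(ins, bool):
            ins = None if (isinstance(ins, float) and math.isnan(ins)) else bool(ins)
        obs.append(
            DistanceObservation(
                md_m=float(row.md_m),
                infestation_pct=float(row.infestation_pct),
                insecticide=ins,
            )
        )
    return obs
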