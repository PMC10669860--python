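"""Rank correlation and chance-corrected rater agreement for continuous ratings.

Two statistics drive the reliability analysis of the eruption quotient:

* Spearman's rank correlation rho between quotient and chronological age,
  with a 95% CI from the Fisher z transform using the Bonett-Wright
  standard error sqrt((1 + rho^2/2) / (n - 3)) (a unit-level percentile
  bootstrap is available as an alternative).

* Krippendorff's alpha = 1 - D_o / D_e for units-by-observers matrices of
  continuous ratings with missing entries.  With pairable values grouped by
  unit u (m_u >= 2 values each, n pairable values in total),

      D_o = (1/n) * sum_u [ sum over ordered within-unit pairs d2(c,k) ] / (m_u - 1)
      D_e = (1/(n(n-1))) * sum over ordered pairs of all pooled values d2(c,k)

  with the interval difference d2(c,k) = (c-k)^2 (default, affine
  invariant) or the ratio difference d2(c,k) = ((c-k)/(c+k))^2 (scale
  invariant, for strictly positive ratings).  The CI for alpha is a
  percentile bootstrap over units (cluster bootstrap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "CorrelationResult",
    "ReliabilityResult",
    "rank_with_ties",
    "spearman_rho",
    "spearman_ci",
    "spearman_with_ci",
    "krippendorff_alpha",
    "alpha_bootstrap_ci",
    "alpha_with_ci",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """The statistic is not defined on this input (e.g. zero variance)."""


@dataclass
class RatingsMatrix:
    """Continuous ratings of units (radiograph x tooth) by observers.

    ``values`` is a units-by-observers array with NaN marking missing
    ratings.  Units with fewer than two non-missing values carry no
    agreement information; they are dropped before estimation and counted
    in ``n_dropped_units``.
    """

    units: list
    observers: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.units), len(self.observers)):
            raise ValueError("values shape must be (n_units, n_observers)")
        if len(self.observers) < 2:
            raise ValueError("at least two observers required")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatingsMatrix":
        """Build from a wide DataFrame (index = units, columns = observers)."""
        return cls(units=list(df.index), observers=list(df.columns),
                   values=df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.units, columns=self.observers)

    @property
    def pairable_mask(self) -> np.ndarray:
        """Boolean mask of units contributing at least two ratings."""
        return (~np.isnan(self.values)).sum(axis=1) >= 2

    @property
    def n_dropped_units(self) -> int:
        return int((~self.pairable_mask).sum())

    def pairable(self) -> np.ndarray:
        """Rows of the value grid restricted to pairable units."""
        return self.values[self.pairable_mask]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    level: float
    lcl: float
    ucl: float
    ci_method: str
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "rho": self.rho, "n": self.n, "level": self.level,
            "lcl": self.lcl, "ucl": self.ucl, "ci_method": self.ci_method,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    metric: str
    n_units: int
    n_pairable: int
    lcl: float
    ucl: float
    n_boot: int
    seed: int | None
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha, "metric": self.metric,
            "n_units": self.n_units, "n_pairable": self.n_pairable,
            "lcl": self.lcl, "ucl": self.ucl, "n_boot": self.n_boot,
            "seed": self.seed, "level": self.level,
        }


def rank_with_ties(values) -> np.ndarray:
    """Average (mid) ranks, ties receiving the mean of the ranks they span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    if np.isnan(arr).any():
        raise ValueError("NaN in values to rank")
    return stats.rankdata(arr, method="average")


def spearman_rho(x, y) -> float:
    """Spearman's rho: the Pearson correlation of the mid-ranks of x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx = rank_with_ties(x)
    ry = rank_with_ties(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise UndefinedStatisticError("constant input: rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_ci(rho: float, n: int, level: float = 0.95,
                method: str = "fisher_bonett_wright") -> tuple[float, float, bool]:
    """CI for Spearman's rho.

    Default: Fisher z transform with the Bonett-Wright standard error
    sqrt((1 + rho^2 / 2) / (n - 3)), back-transformed with tanh.  Returns
    (lcl, ucl, degenerate); |rho| = 1 yields the flagged degenerate
    interval (rho, rho).
    """
    if method != "fisher_bonett_wright":
        raise ValueError(f"unknown CI method {method!r}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho outside [-1, 1]")
    if abs(rho) == 1.0:
        return (rho, rho, True)
    if n < 5:
        raise ValueError("need n >= 5 for the Fisher-transform interval")
    z = math.atanh(rho)
    se = math.sqrt((1.0 + rho ** 2 / 2.0) / (n - 3))
    crit = stats.norm.ppf(0.5 + level / 2.0)
    return (math.tanh(z - crit * se), math.tanh(z + crit * se), False)


def spearman_with_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Convenience wrapper: rho plus its default-method confidence interval."""
    rho = spearman_rho(x, y)
    lcl, ucl, degenerate = spearman_ci(rho, len(np.asarray(x)), level=level)
    return CorrelationResult(rho=rho, n=len(np.asarray(x)), level=level,
                             lcl=lcl, ucl=ucl,
                             ci_method="fisher_bonett_wright",
                             degenerate=degenerate)


def _disagreement_terms(values: np.ndarray, metric: str) -> tuple[float, float, int]:
    """(D_o, D_e, n_pairable) for a pairable units-by-observers grid.

    Vectorised via the identity
        sum over ordered pairs (c - k)^2 = 2 * (m * sum c^2 - (sum c)^2)
    for the interval metric; the ratio metric transforms each pair, so the
    within-unit and pooled sums are built from small per-unit pair blocks.
    """
    m_u = (~np.isnan(values)).sum(axis=1)
    n = int(m_u.sum())
    if n < 2 or values.shape[0] < 2:
        raise UndefinedStatisticError("need >= 2 pairable units")
    pooled = values[~np.isnan(values)]

    if metric == "interval":
        d_o_num = 0.0
        for row, m in zip(values, m_u):
            v = row[~np.isnan(row)]
            d_o_num += 2.0 * (m * np.sum(v * v) - np.sum(v) ** 2) / (m - 1)
        d_e = 2.0 * (n * np.sum(pooled * pooled) - np.sum(pooled) ** 2) / (n * (n - 1))
    elif metric == "ratio":
        def pair_sum(v: np.ndarray) -> float:
            c = v[:, None]
            k = v[None, :]
            denom = c + k
            if np.any(denom == 0):
                raise UndefinedStatisticError("ratio metric undefined for c + k = 0")
            d = ((c - k) / denom) ** 2
            return float(d.sum())  # ordered pairs: full off-diagonal sum

        d_o_num = 0.0
        for row, m in zip(values, m_u):
            v = row[~np.isnan(row)]
            d_o_num += pair_sum(v) / (m - 1)
        d_e = pair_sum(pooled) / (n * (n - 1))
    else:
        raise ValueError(f"unknown alpha metric {metric!r}")

    d_o = d_o_num / n
    return float(d_o), float(d_e), n


def krippendorff_alpha(m: RatingsMatrix, metric: str = "interval") -> float:
    """Krippendorff's alpha (1 - D_o/D_e) for continuous ratings.

    Units with fewer than two ratings are dropped first.  Raises
    :class:`UndefinedStatisticError` when all pooled pairable values are
    identical (D_e = 0; agreement is then vacuous, not perfect).
    """
    values = m.pairable()
    d_o, d_e, _ = _disagreement_terms(values, metric)
    if d_e == 0.0:
        raise UndefinedStatisticError(
            "all pairable values identical: expected disagreement is zero"
        )
    return 1.0 - d_o / d_e


def alpha_bootstrap_ci(m: RatingsMatrix, metric: str = "interval",
                       n_boot: int = 2000, level: float = 0.95,
                       seed: int | None = None,
                       max_redraws: int = 100) -> tuple[float, float]:
    """Percentile bootstrap CI for alpha, resampling units with replacement.

    Resampled matrices on which alpha is undefined (all values identical)
    are redrawn up to ``max_redraws`` times each; if fewer than 20 valid
    resamples can be obtained in total the interval is not estimable and a
    :class:`UndefinedStatisticError` is raised.  Deterministic given seed.
    """
    if seed is None:
        raise ValueError("alpha_bootstrap_ci requires an explicit seed")
    values = m.pairable()
    # validates the point estimate is estimable before bootstrapping
    d_o, d_e, _ = _disagreement_terms(values, metric)
    if d_e == 0.0:
        raise UndefinedStatisticError("alpha undefined on the full matrix")

    rng = np.random.default_rng(seed)
    n_units = values.shape[0]
    alphas = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws + 1):
            idx = rng.integers(0, n_units, size=n_units)
            try:
                bo, be, _ = _disagreement_terms(values[idx], metric)
            except UndefinedStatisticError:
                continue
            if be > 0.0:
                alphas[b] = 1.0 - bo / be
                break
        else:
            alphas[b] = np.nan
            n_failed += 1
    valid = alphas[~np.isnan(alphas)]
    if valid.size < 20:
        raise UndefinedStatisticError(
            f"only {valid.size} valid bootstrap resamples (of {n_boot})"
        )
    lo, hi = np.quantile(valid, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


def alpha_with_ci(m: RatingsMatrix, metric: str = "interval",
                  n_boot: int = 2000, level: float = 0.95,
                  seed: int | None = None) -> ReliabilityResult:
    """Alpha point estimate plus cluster-bootstrap CI in one result object.

    ``n_boot = 0`` skips the bootstrap and reports NaN bounds.
    """
    values = m.pairable()
    d_o, d_e, n_pairable = _disagreement_terms(values, metric)
    if d_e == 0.0:
        raise UndefinedStatisticError("alpha undefined: zero expected disagreement")
    alpha = 1.0 - d_o / d_e
    if n_boot > 0:
        lcl, ucl = alpha_bootstrap_ci(m, metric=metric, n_boot=n_boot,
                                      level=level, seed=seed)
    else:
        lcl = ucl = float("nan")
    return ReliabilityResult(alpha=alpha, metric=metric,
                             n_units=int(values.shape[0]),
                             n_pairable=n_pairable,
                             lcl=lcl, ucl=ucl, n_boot=n_boot, seed=seed,
                             level=level)
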