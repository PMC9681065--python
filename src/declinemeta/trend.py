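"""Variance-weighted pooling and loess trends of effect sizes over time.

This module quantifies the *decline effect* — the shrinkage of reported
effect sizes over publication years — in a corpus of lnRR effect sizes.
Two complementary views are produced, mirroring standard meta-analytic
practice:

1. **Yearly pooled means.**  Within each publication year, effects are
   pooled with inverse-variance weights, either fixed-effect
   (w_i = 1/v_i) or random-effects with the DerSimonian-Laird moment
   estimator of the between-study variance tau^2
   (w_i = 1/(v_i + tau^2), tau^2 = max(0, (Q - df) / C)).

2. **A loess trend** of effect-size magnitude (or signed value) against
   year, with bootstrap percentile confidence bands.

Decline strength is summarised by ``decline_ratio`` (pooled effect over
the first two observed years divided by the last two) and
``weighted_slope`` (inverse-variance-weighted linear slope vs year).

The public surface follows the model/results idiom: build a
:class:`DeclineTrend` from an effects table, call :meth:`~DeclineTrend.fit`,
inspect the returned :class:`DeclineTrendResults`.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.75
DEFAULT_BOOT_REPS = 1000
DEFAULT_SEED = 20221122
Z95 = 1.959963984540054  # scipy.stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# pooling primitives
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PooledEstimate:
    mean: float
    se: float
    tau2: float
    k: int
    q: float

    @property
    def ci_low(self) -> float:
        return self.mean - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.mean + Z95 * self.se


def pool_effects(y: np.ndarray, v: np.ndarray, model: str = "random_dl") -> PooledEstimate:
    """Inverse-variance pooling of effects ``y`` with sampling variances ``v``.

    ``model="fixed"`` uses weights 1/v_i.  ``model="random_dl"`` estimates
    tau^2 by the DerSimonian-Laird moment estimator (truncated at zero)
    and pools with weights 1/(v_i + tau^2); with tau^2 = 0 the two
    coincide.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if y.size == 0:
        raise ValueError("cannot pool an empty set of effects")
    if (v <= 0).any() or not np.isfinite(v).all():
        raise ValueError("all sampling variances must be finite and > 0 (floor zeros first)")
    if model not in ("fixed", "random_dl"):
        raise ValueError(f"model must be 'fixed' or 'random_dl', got {model!r}")

    k = y.size
    w = 1.0 / v
    sw = w.sum()
    mean_fixed = float((w * y).sum() / sw)
    q = float((w * (y - mean_fixed) ** 2).sum())

    if model == "fixed" or k == 1:
        tau2 = 0.0
    else:
        c = sw - (w**2).sum() / sw
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0

    if model == "fixed":
        return PooledEstimate(mean_fixed, float(np.sqrt(1.0 / sw)), 0.0, k, q)

    w_star = 1.0 / (v + tau2)
    sw_star = w_star.sum()
    mean = float((w_star * y).sum() / sw_star)
    return PooledEstimate(mean, float(np.sqrt(1.0 / sw_star)), tau2, k, q)


def floor_zero_variances(effects: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace zero sampling variances by the smallest positive one present.

    Records where both arms have zero SD (typically forced 0%-vs-100%
    contrasts) have a delta-method variance of exactly 0, which would give
    them infinite pooling weight.  They are floored to the corpus's
    smallest positive variance; the flooring is logged and counted.
    """
    out = effects.copy()
    zero = out["variance"] <= 0
    n_floored = int(zero.sum())
    if n_floored:
        positive = out.loc[~zero, "variance"]
        if positive.empty:
            raise ValueError("every effect has zero variance; nothing to floor to")
        floor = float(positive.min())
        out.loc[zero, "variance"] = floor
        logger.info("floored %d zero variances to %.3g", n_floored, floor)
    return out, n_floored


def yearly_weighted_means(
    effects: pd.DataFrame,
    model: str = "random_dl",
    response: str = "magnitude",
) -> pd.DataFrame:
    """Per-year variance-weighted pooled effects.

    Returns one row per observed year (years with no effects are omitted)
    with columns ``year, k, pooled_mean, pooled_se, ci_low, ci_high, tau2,
    model``.  ``response`` selects magnitude (default, for decline-effect
    analyses) or the signed lnRR.
    """
    if response not in ("magnitude", "signed"):
        raise ValueError(f"response must be 'magnitude' or 'signed', got {response!r}")
    col = "magnitude" if response == "magnitude" else "lnrr"
    effects, _ = floor_zero_variances(effects)
    rows = []
    for year, grp in effects.groupby("year", sort=True):
        est = pool_effects(grp[col].to_numpy(), grp["variance"].to_numpy(), model)
        rows.append(
            {
                "year": int(year),
                "k": est.k,
                "pooled_mean": est.mean,
                "pooled_se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "tau2": est.tau2,
                "model": model,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DeclineTrend:
    """Effect-size-vs-year trend model for a table of lnRR effects.

    Parameters
    ----------
    effects : frame with columns ``record_id, year, lnrr, variance``
        (``magnitude`` is derived if absent), e.g. from
        :func:`declinemeta.effects.compute_effects`.
    response : ``"magnitude"`` (default) or ``"signed"`` — which response
        the loess, the yearly pooling and the slope are computed on.
    pooling : ``"random_dl"`` (default) or ``"fixed"``.
    span : loess span (fraction of points in each local fit), in (0, 1].

    Examples
    --------
    >>> model = DeclineTrend(effects_table)
    >>> res = model.fit(boot_reps=200, seed=7)
    >>> res.decline_ratio, res.weighted_slope
    """

    MIN_EFFECTS = 10
    MIN_YEARS = 3

    def __init__(
        self,
        effects: pd.DataFrame,
        response: str = "magnitude",
        pooling: str = "random_dl",
        span: float = DEFAULT_SPAN,
    ) -> None:
        if response not in ("magnitude", "signed"):
            raise ValueError(f"response must be 'magnitude' or 'signed', got {response!r}")
        if pooling not in ("fixed", "random_dl"):
            raise ValueError(f"pooling must be 'fixed' or 'random_dl', got {pooling!r}")
        if not (0.0 < span <= 1.0):
            raise ValueError(f"span must lie in (0, 1], got {span}")
        required = {"record_id", "year", "lnrr", "variance"}
        missing = required - set(effects.columns)
        if missing:
            raise ValueError(f"effects table missing columns: {sorted(missing)}")
        n_years = effects["year"].nunique()
        if len(effects) < self.MIN_EFFECTS or n_years < self.MIN_YEARS:
            raise ValueError(
                f"need >= {self.MIN_EFFECTS} effects spanning >= {self.MIN_YEARS} "
                f"distinct years, got {len(effects)} effects over {n_years} years"
            )
        effects = effects.copy()
        if "magnitude" not in effects.columns:
            effects["magnitude"] = effects["lnrr"].abs()
        self.effects, self.n_floored = floor_zero_variances(effects)
        self.response = response
        self.pooling = pooling
        self.span = span
        self._ycol = "magnitude" if response == "magnitude" else "lnrr"

    @classmethod
    def from_corpus(
        cls,
        corpus: pd.DataFrame,
        policy,
        ruleset=None,
        year_source: str = "online",
        **kwargs,
    ) -> "DeclineTrend":
        """Screen a corpus, compute lnRR effects, and build the model."""
        from .effects import compute_effects
        from .screening import get_ruleset, screen

        if ruleset is not None:
            corpus, _ = screen(corpus, get_ruleset(ruleset))
        return cls(compute_effects(corpus, policy, year_source=year_source), **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        boot_reps: int = DEFAULT_BOOT_REPS,
        seed: int = DEFAULT_SEED,
        grid_points: int = 101,
    ) -> "DeclineTrendResults":
        """Fit the loess trend and compute pooled summaries.

        ``boot_reps`` bootstrap resamples of effects (percentile method)
        give the 95% band around the loess curve; ``boot_reps=0`` skips
        the bootstrap (the band columns are NaN).  Identical inputs and
        seed give identical results.
        """
        eff = self.effects
        x = eff["year"].to_numpy(dtype=float)
        y = eff[self._ycol].to_numpy(dtype=float)

        grid = np.linspace(x.min(), x.max(), grid_points)
        fitted = lowess(y, x, frac=self.span, xvals=grid)

        if boot_reps > 0:
            rng = np.random.default_rng(seed)
            boots = np.empty((boot_reps, grid_points))
            n = len(eff)
            for b in range(boot_reps):
                idx = rng.integers(0, n, size=n)
                boots[b] = lowess(y[idx], x[idx], frac=self.span, xvals=grid)
            with np.errstate(all="ignore"):
                lo = np.nanpercentile(boots, 2.5, axis=0)
                hi = np.nanpercentile(boots, 97.5, axis=0)
        else:
            lo = np.full(grid_points, np.nan)
            hi = np.full(grid_points, np.nan)

        curve = pd.DataFrame(
            {"year": grid, "fitted": fitted, "ci_low": lo, "ci_high": hi}
        )

        yearly = yearly_weighted_means(eff, model=self.pooling, response=self.response)

        years = np.sort(eff["year"].unique())
        early_years, late_years = years[:2], years[-2:]
        early = pool_effects(
            eff.loc[eff["year"].isin(early_years), self._ycol].to_numpy(),
            eff.loc[eff["year"].isin(early_years), "variance"].to_numpy(),
            self.pooling,
        )
        late = pool_effects(
            eff.loc[eff["year"].isin(late_years), self._ycol].to_numpy(),
            eff.loc[eff["year"].isin(late_years), "variance"].to_numpy(),
            self.pooling,
        )

        overall = pool_effects(y, eff["variance"].to_numpy(), self.pooling)
        slope, slope_se = _weighted_slope(
            x, y, eff["variance"].to_numpy(), overall.tau2 if self.pooling == "random_dl" else 0.0
        )

        return DeclineTrendResults(
            model=self,
            yearly=yearly,
            curve=curve,
            early_mean=early.mean,
            late_mean=late.mean,
            early_years=tuple(int(v) for v in early_years),
            late_years=tuple(int(v) for v in late_years),
            weighted_slope=slope,
            slope_se=slope_se,
            tau2=overall.tau2,
            boot_reps=boot_reps,
            seed=seed,
        )


def _weighted_slope(
    x: np.ndarray, y: np.ndarray, v: np.ndarray, tau2: float
) -> tuple[float, float]:
    """Closed-form weighted least squares slope of y on x, weights 1/(v+tau2)."""
    w = 1.0 / (v + tau2)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise ValueError("no year spread; slope undefined")
    slope = float((w * (x - xbar) * (y - ybar)).sum() / sxx)
    return slope, float(np.sqrt(1.0 / sxx))


@dataclasses.dataclass
class DeclineTrendResults:
    """Fitted trend: loess curve, yearly pooled means and decline metrics.

    Attributes
    ----------
    yearly : per-year pooled means with CIs (see
        :func:`yearly_weighted_means`).
    curve : loess grid with columns ``year, fitted, ci_low, ci_high``.
    early_mean, late_mean : pooled effect over the first / last two
        observed years; ``decline_ratio = early_mean / late_mean`` (> 1
        indicates decline).
    weighted_slope : inverse-variance-weighted linear slope of the
        response vs year (negative = decline), with ``slope_se``.
    tau2 : DerSimonian-Laird between-study variance over all effects.
    """

    model: DeclineTrend
    yearly: pd.DataFrame
    curve: pd.DataFrame
    early_mean: float
    late_mean: float
    early_years: tuple[int, int]
    late_years: tuple[int, int]
    weighted_slope: float
    slope_se: float
    tau2: float
    boot_reps: int
    seed: int

    @property
    def decline_ratio(self) -> float:
        return self.early_mean / self.late_mean

    def summary(self) -> str:
        m = self.model
        lines = [
            "Decline-effect trend results",
            "=" * 46,
            f"effects:          {len(m.effects)} over years "
            f"{int(m.effects['year'].min())}-{int(m.effects['year'].max())}",
            f"response:         {m.response}",
            f"pooling:          {m.pooling} (tau2 = {self.tau2:.4f})",
            f"loess span:       {m.span} (bootstrap reps: {self.boot_reps})",
            f"zero-var floored: {m.n_floored}",
            "-" * 46,
            f"early mean {self.early_years}:  {self.early_mean:.4f}",
            f"late mean  {self.late_years}:  {self.late_mean:.4f}",
            f"decline ratio:    {self.decline_ratio:.4f}",
            f"weighted slope:   {self.weighted_slope:.4f} (se {self.slope_se:.4f}) per year",
            "-" * 46,
            "yearly pooled means:",
            self.yearly.to_string(
                index=False,
                formatters={
                    c: (lambda val: f"{val:.4f}")
                    for c in ("pooled_mean", "pooled_se", "ci_low", "ci_high", "tau2")
                },
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look plot: effect scatter, loess band, yearly means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        eff = self.model.effects
        ax.scatter(eff["year"], eff[self.model._ycol], s=12, alpha=0.4, label="effects")
        ax.plot(self.curve["year"], self.curve["fitted"], color="C1", label="loess")
        if self.boot_reps > 0:
            ax.fill_between(
                self.curve["year"], self.curve["ci_low"], self.curve["ci_high"],
                color="C1", alpha=0.2,
            )
        ax.errorbar(
            self.yearly["year"], self.yearly["pooled_mean"],
            yerr=Z95 * self.yearly["pooled_se"],
            fmt="s", color="C2", capsize=3, label="yearly pooled",
        )
        ax.set_xlabel("year")
        ax.set_ylabel(f"lnRR {self.model.response}")
        ax.legend()
        return ax


def loess_trend(
    effects: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    boot_reps: int = DEFAULT_BOOT_REPS,
    seed: int = DEFAULT_SEED,
    response: str = "magnitude",
    pooling: str = "random_dl",
) -> DeclineTrendResults:
    """Functional wrapper: build a :class:`DeclineTrend` and fit it."""
    return DeclineTrend(effects, response=response, pooling=pooling, span=span).fit(
        boot_reps=boot_reps, seed=seed
    )


@dataclasses.dataclass
class TrendComparison:
    """Side-by-side comparison of named trend results."""

    metrics: pd.DataFrame
    yearly_means: pd.DataFrame
    steepest_decline: str


def compare_trends(results: Mapping[str, DeclineTrendResults]) -> TrendComparison:
    """Compare named trend results over their common year range.

    Raises if fewer than two results are given or their year ranges are
    disjoint.  The configuration with the largest decline ratio is flagged
    as the steepest decline.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 trend results to compare")
    ranges = {
        name: (res.yearly["year"].min(), res.yearly["year"].max())
        for name, res in results.items()
    }
    common_lo = max(lo for lo, _ in ranges.values())
    common_hi = min(hi for _, hi in ranges.values())
    if common_lo >= common_hi:
        raise ValueError(f"results share fewer than two years: {ranges}")

    metrics = pd.DataFrame(
        [
            {
                "name": name,
                "decline_ratio": res.decline_ratio,
                "weighted_slope": res.weighted_slope,
                "early_mean": res.early_mean,
                "late_mean": res.late_mean,
                "tau2": res.tau2,
            }
            for name, res in results.items()
        ]
    ).set_index("name")
    steepest = metrics["decline_ratio"].idxmax()
    metrics["steepest_decline"] = metrics.index == steepest

    yearly = pd.concat(
        {name: res.yearly.set_index("year")["pooled_mean"] for name, res in results.items()},
        axis=1,
    )
    yearly.columns = list(results)
    return TrendComparison(metrics=metrics, yearly_means=yearly, steepest_decline=steepest)
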