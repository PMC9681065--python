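"""Log response ratios under zero-replacement policies on bounded scales.

The effect size is the log response ratio lnRR = ln(treatment mean /
control mean), with delta-method sampling variance

    v = sd_t^2 / (n_t * m_t^2) + sd_c^2 / (n_c * m_c^2).

lnRR is undefined when either mean is zero, which on percentage (0-100)
and proportion (0-1) scales happens routinely (floor/ceiling effects in
behavioural assays).  A :class:`ReplacementPolicy` substitutes a small
constant ``c`` for exact zeros and, symmetrically, ``bound - c`` for
full-scale values before the ratio is formed.  The choice of ``c`` is
consequential: for a 0% control vs 100% treatment contrast,

    c = 1      ->  ln(99/1)            ~  4.6
    c = 0.1    ->  ln(99.9/0.1)        ~  6.9
    c = 0.0001 ->  ln(99.9999/0.0001)  ~ 13.8

so the smaller the replacement constant, the more the effect size is
inflated — the mechanism this package exists to expose.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .corpus import SCALE_BOUNDS


@dataclasses.dataclass(frozen=True)
class ReplacementPolicy:
    """Per-scale zero/bound replacement constants.

    Parameters
    ----------
    percentage_c : constant substituted for 0 on the 0-100 scale, in (0, 50).
    proportion_c : constant substituted for 0 on the 0-1 scale, in (0, 0.5).
    symmetric_upper : replace the upper bound (100 or 1) by ``bound - c``
        as well.  Defaults to True: a 100% treatment becomes 99, 99.9 or
        99.9999 depending on ``c``.
    """

    percentage_c: float
    proportion_c: float
    symmetric_upper: bool = True
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 < self.percentage_c < 50.0):
            raise ValueError(f"percentage_c must be in (0, 50), got {self.percentage_c}")
        if not (0.0 < self.proportion_c < 0.5):
            raise ValueError(f"proportion_c must be in (0, 0.5), got {self.proportion_c}")

    def constant_for(self, scale_type: str) -> float:
        if scale_type == "percentage":
            return self.percentage_c
        if scale_type == "proportion":
            return self.proportion_c
        raise ValueError(f"no replacement constant for scale {scale_type!r}")


#: Named policy presets.  "four_decimal" mirrors the 4-decimal-place tiny
#: replacement (0.0001 on both scales); "one_decimal" is 0.1 for percentage
#: and 0.001 for proportional data; "whole_number" the smallest whole
#: number, 1 for percentage and 0.01 for proportional data.
POLICY_PRESETS: dict[str, ReplacementPolicy] = {
    "four_decimal": ReplacementPolicy(0.0001, 0.0001, name="four_decimal"),
    "one_decimal": ReplacementPolicy(0.1, 0.001, name="one_decimal"),
    "whole_number": ReplacementPolicy(1.0, 0.01, name="whole_number"),
}


def get_policy(name_or_policy: str | ReplacementPolicy) -> ReplacementPolicy:
    if isinstance(name_or_policy, ReplacementPolicy):
        return name_or_policy
    try:
        return POLICY_PRESETS[name_or_policy]
    except KeyError:
        raise ValueError(
            f"unknown policy {name_or_policy!r}; presets: {sorted(POLICY_PRESETS)}"
        ) from None


@dataclasses.dataclass(frozen=True)
class EffectSize:
    """A signed lnRR with its delta-method sampling variance."""

    record_id: str
    lnrr: float
    variance: float
    year: int

    @property
    def magnitude(self) -> float:
        return abs(self.lnrr)


def _adjust_mean(mean: float, bound: float, c: float, symmetric_upper: bool) -> tuple[float, bool]:
    if mean == 0.0:
        return c, True
    if symmetric_upper and mean == bound:
        return bound - c, True
    return mean, False


def apply_replacement(record: Mapping, policy: ReplacementPolicy | str) -> dict:
    """Return an adjusted copy of one record with bound values replaced.

    Continuous-scale records pass through unchanged unless a mean is
    exactly zero, in which case lnRR is genuinely undefined and the record
    must be screened out rather than patched — that raises.

    The returned dict carries ``replacement_applied`` provenance flags.
    """
    policy = get_policy(policy)
    rec = dict(record)
    scale = rec["scale_type"]
    bound = SCALE_BOUNDS.get(scale)
    if bound is None:
        if rec["control_mean"] == 0.0 or rec["treatment_mean"] == 0.0:
            raise ValueError(
                f"record {rec.get('record_id')!r}: lnRR is undefined for a "
                "continuous-scale mean of 0; replacement applies to bounded "
                "scales only — screen this record out"
            )
        rec["control_adjusted"] = False
        rec["treatment_adjusted"] = False
        return rec
    c = policy.constant_for(scale)
    rec["control_mean"], rec["control_adjusted"] = _adjust_mean(
        rec["control_mean"], bound, c, policy.symmetric_upper
    )
    rec["treatment_mean"], rec["treatment_adjusted"] = _adjust_mean(
        rec["treatment_mean"], bound, c, policy.symmetric_upper
    )
    return rec


def compute_lnrr(record: Mapping, policy: ReplacementPolicy | str) -> EffectSize:
    """Compute the lnRR effect size for one record under a policy.

    The variance uses the replacement-adjusted means; SDs are never
    adjusted.  A record with zero SD in both arms gets variance 0 — the
    pooling stage floors such variances before weighting.
    """
    adj = apply_replacement(record, policy)
    m_c, m_t = adj["control_mean"], adj["treatment_mean"]
    if m_c <= 0 or m_t <= 0:
        raise ValueError(
            f"record {adj.get('record_id')!r}: adjusted mean <= 0 "
            f"(control={m_c}, treatment={m_t}); replacement policy misconfigured"
        )
    lnrr = math.log(m_t / m_c)
    variance = (
        adj["treatment_sd"] ** 2 / (adj["treatment_n"] * m_t**2)
        + adj["control_sd"] ** 2 / (adj["control_n"] * m_c**2)
    )
    year = int(adj.get("year", adj.get("year_online", 0)))
    return EffectSize(
        record_id=str(adj.get("record_id", "")),
        lnrr=lnrr,
        variance=variance,
        year=year,
    )


def compute_effects(
    corpus: pd.DataFrame,
    policy: ReplacementPolicy | str,
    year_source: str = "online",
) -> pd.DataFrame:
    """Vectorised lnRR computation for a whole corpus.

    Returns a frame with columns ``record_id, year, lnrr, variance,
    magnitude, replacement_applied``, one row per input record, in input
    order.
    """
    policy = get_policy(policy)
    year_col = "year_online" if year_source == "online" else "year_print"

    scale = corpus["scale_type"].to_numpy()
    m_c = corpus["control_mean"].to_numpy(dtype=float).copy()
    m_t = corpus["treatment_mean"].to_numpy(dtype=float).copy()

    continuous = scale == "continuous"
    if ((m_c == 0) | (m_t == 0))[continuous].any():
        bad = corpus.loc[continuous & ((m_c == 0) | (m_t == 0)), "record_id"].tolist()
        raise ValueError(
            f"continuous-scale records with a zero mean (lnRR undefined, "
            f"screen them out): {bad[:5]}"
        )

    adjusted = np.zeros(len(corpus), dtype=bool)
    for scale_name, bound in SCALE_BOUNDS.items():
        on_scale = scale == scale_name
        if not on_scale.any():
            continue
        c = policy.constant_for(scale_name)
        for arr in (m_c, m_t):
            at_zero = on_scale & (arr == 0.0)
            arr[at_zero] = c
            adjusted |= at_zero
            if policy.symmetric_upper:
                at_bound = on_scale & (arr == bound)
                arr[at_bound] = bound - c
                adjusted |= at_bound

    if (m_c <= 0).any() or (m_t <= 0).any():
        raise ValueError("adjusted means <= 0 after replacement; policy misconfigured")

    lnrr = np.log(m_t / m_c)
    variance = (
        corpus["treatment_sd"].to_numpy(dtype=float) ** 2
        / (corpus["treatment_n"].to_numpy(dtype=float) * m_t**2)
        + corpus["control_sd"].to_numpy(dtype=float) ** 2
        / (corpus["control_n"].to_numpy(dtype=float) * m_c**2)
    )

    return pd.DataFrame(
        {
            "record_id": corpus["record_id"].to_numpy(),
            "year": corpus[year_col].to_numpy(dtype=int),
            "lnrr": lnrr,
            "variance": variance,
            "magnitude": np.abs(lnrr),
            "replacement_applied": adjusted,
        }
    )


def inflation_curve(
    treatment_values: Iterable[float],
    control_grid: Iterable[float],
) -> pd.DataFrame:
    """Analytic lnRR inflation curve on the percentage scale.

    For each treatment value and each (already-replaced) control value in
    the grid, lnRR = ln(treatment_adj / control), where a treatment of
    exactly 100 gets the bound-symmetric adjustment ``100 - control`` (so a
    control of 0.0001 faces a numerator of 99.9999).  Rows are ordered by
    treatment, then by descending control — the direction in which the
    inflation grows.
    """
    controls = np.asarray(sorted(control_grid, reverse=True), dtype=float)
    if (controls <= 0).any() or (controls >= 100).any():
        raise ValueError("control grid values must lie strictly inside (0, 100)")
    rows = []
    for t in treatment_values:
        t = float(t)
        for ctl in controls:
            t_adj = 100.0 - ctl if t == 100.0 else t
            rows.append((t, ctl, math.log(t_adj / ctl)))
    return pd.DataFrame(rows, columns=["treatment", "control", "lnrr"])
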