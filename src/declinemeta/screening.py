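"""Declarative inclusion/exclusion rules with an audit trail.

Screening decides which contrasts count as genuine ocean-acidification
treatments before effect sizes are pooled.  The rules mirror the
methodological disputes in this literature:

* **sham treatments** (e.g. blank seawater injections) are procedural
  checks expected to show no effect; counting them as OA contrasts
  dilutes pooled effect sizes;
* **fluctuating-CO2 treatments** (daily CO2 cycles) attenuate behavioural
  effects relative to stable elevated CO2;
* **procedural controls** (seawater on both flume sides) likewise measure
  apparatus, not exposure;
* **opposite-direction responses** are often the *strongest* OA effects,
  so excluding them biases the pool downward — hence an inclusion toggle;
* a **minimum CO2 level** (e.g. >=800 uatm) restricts to strong exposures.

Rules are pure predicates on record flags: the output depends only on
(records, rules), and every exclusion is attributed to the first matching
rule in a documented order so the report reconciles exactly.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

#: Attribution order for the audit report (first matching rule wins).
RULE_ORDER = ("sham", "fluctuating_co2", "procedural_control", "co2_threshold", "opposite_direction")


@dataclasses.dataclass(frozen=True)
class ScreeningRuleSet:
    exclude_sham: bool = False
    exclude_fluctuating_co2: bool = False
    exclude_procedural_controls: bool = False
    include_opposite_direction: bool = True
    min_co2_uatm: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.min_co2_uatm is not None and self.min_co2_uatm < 0:
            raise ValueError("min_co2_uatm must be >= 0 or None")


@dataclasses.dataclass
class ScreeningReport:
    """Audit of one screening pass: input == included + sum(exclusions)."""

    n_input: int
    n_included: int
    exclusions: dict[str, int]
    excluded_ids: dict[str, list[str]]
    ruleset: str = "custom"

    def reconciles(self) -> bool:
        return self.n_input == self.n_included + sum(self.exclusions.values())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def screen(
    records: pd.DataFrame,
    rules: ScreeningRuleSet,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Apply a rule set; return (included records, audit report).

    A record is excluded iff it trips an enabled rule; attribution follows
    :data:`RULE_ORDER`.  ``include_opposite_direction=True`` retains
    opposite-direction records (the rule re-admits rather than excludes).
    Empty input yields empty output and a zeroed report.
    """
    n = len(records)
    excluded_ids: dict[str, list[str]] = {rule: [] for rule in RULE_ORDER}
    if n == 0:
        report = ScreeningReport(0, 0, {r: 0 for r in RULE_ORDER}, excluded_ids, rules.name)
        return records.copy(), report

    predicates = {
        "sham": rules.exclude_sham and records["is_sham"],
        "fluctuating_co2": rules.exclude_fluctuating_co2 and records["is_fluctuating_co2"],
        "procedural_control": (
            rules.exclude_procedural_controls and records["is_procedural_control"]
        ),
        "co2_threshold": (
            (records["co2_uatm"] < rules.min_co2_uatm)
            if rules.min_co2_uatm is not None
            else False
        ),
        "opposite_direction": (
            (not rules.include_opposite_direction) and records["direction_opposite"]
        ),
    }

    attributed = pd.Series(False, index=records.index)
    for rule in RULE_ORDER:
        pred = predicates[rule]
        if pred is False:
            continue
        hits = pred & ~attributed
        excluded_ids[rule] = records.loc[hits, "record_id"].tolist()
        attributed |= hits

    included = records.loc[~attributed].copy()
    report = ScreeningReport(
        n_input=n,
        n_included=len(included),
        exclusions={rule: len(ids) for rule, ids in excluded_ids.items()},
        excluded_ids=excluded_ids,
        ruleset=rules.name,
    )
    assert report.reconciles()
    return included, report


def preset_rulesets() -> dict[str, ScreeningRuleSet]:
    """Named rule sets for the screening-comparison experiments.

    ``screened``
        exclude sham and fluctuating-CO2 treatments, retain
        opposite-direction responses, no CO2 floor.
    ``screened_high_co2``
        as above, restricted to treatments at >=800 uatm CO2.
    ``unscreened``
        sham and fluctuating-CO2 treatments included, opposite-direction
        responses excluded, procedural controls removed — the contrasting
        configuration the screened analyses argue against.
    """
    return {
        "screened": ScreeningRuleSet(
            exclude_sham=True,
            exclude_fluctuating_co2=True,
            include_opposite_direction=True,
            name="screened",
        ),
        "screened_high_co2": ScreeningRuleSet(
            exclude_sham=True,
            exclude_fluctuating_co2=True,
            include_opposite_direction=True,
            min_co2_uatm=800.0,
            name="screened_high_co2",
        ),
        "unscreened": ScreeningRuleSet(
            exclude_sham=False,
            exclude_fluctuating_co2=False,
            exclude_procedural_controls=True,
            include_opposite_direction=False,
            name="unscreened",
        ),
    }


def get_ruleset(name_or_rules: str | ScreeningRuleSet) -> ScreeningRuleSet:
    if isinstance(name_or_rules, ScreeningRuleSet):
        return name_or_rules
    presets = preset_rulesets()
    try:
        return presets[name_or_rules]
    except KeyError:
        raise ValueError(
            f"unknown ruleset {name_or_rules!r}; presets: {sorted(presets)}"
        ) from None
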