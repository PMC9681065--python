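"""Synthetic study corpora with the statistical structure of the OA
fish-behaviour literature.

The generator emulates a decade-long corpus of control-vs-treatment
behavioural contrasts in which

* a latent true log response ratio follows a configurable year schedule
  (constant, linear, or a "gentle decline" preset) with between-study
  heterogeneity ``tau_true``;
* exact zeros on bounded scales (floor effects in behavioural assays)
  are more common in the earliest years than in later ones, following a
  ``zero_prevalence`` schedule;
* sham treatments carry essentially no effect, and fluctuating-CO2
  treatments carry an attenuated one.

Zeros are imposed by forcing an otherwise strictly-interior mean to the
scale floor (and, with some probability, the other arm to the ceiling),
so bound values arise only through this explicit mechanism: apart from
it, baselines are resampled until the implied treatment mean lies
strictly inside the scale bounds.  Observed arm means carry no
additional sampling noise — each record's computed lnRR equals its
latent effect exactly — so the pipeline's behaviour can be checked
against a known truth.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .corpus import CORPUS_COLUMNS, SCALE_BOUNDS

_SPECIES = (
    "Amphiprion percula",
    "Acanthochromis polyacanthus",
    "Pomacentrus amboinensis",
    "Gadus morhua",
    "Dicentrarchus labrax",
    "Pagrus auratus",
)
_LIFE_STAGES = ("larva", "juvenile", "adult")
_CUE_TYPES = ("predator", "alarm", "habitat", "conspecific", "none")
_METRICS = ("time_in_cue", "activity", "lateralization", "feeding_strikes", "boldness")


@dataclasses.dataclass(frozen=True)
class Schedule:
    """A year-indexed linear schedule between two endpoint values."""

    start: float
    end: float

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls(value, value)

    def value(self, year: int, year_min: int, year_max: int) -> float:
        if year_max == year_min:
            return self.start
        frac = (year - year_min) / (year_max - year_min)
        return self.start + frac * (self.end - self.start)


#: Preset truth schedules.  "gentle_decline" echoes a corpus whose pooled
#: magnitude starts below 3 and stays well above zero at the end of the
#: decade; it is illustrative, not calibrated to any real corpus.
TRUE_EFFECT_PRESETS: dict[str, Schedule] = {
    "constant_one": Schedule.constant(1.0),
    "gentle_decline": Schedule(2.2, 0.7),
}

#: Preset zero-prevalence schedules ("early_zeros": common early, rare late).
ZERO_PREVALENCE_PRESETS: dict[str, Schedule] = {
    "none": Schedule.constant(0.0),
    "early_zeros": Schedule(0.4, 0.02),
}


@dataclasses.dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generator configuration; config + seed fully determine the corpus.

    Defaults emulate a corpus of roughly ninety studies over 2009-2019
    with a few effect-size contrasts each: 8 studies per year, 2-6
    records per study, per-arm sample sizes of 6-30 fish and coefficients
    of variation of 0.15-0.5.
    """

    years: tuple[int, int] = (2009, 2019)
    studies_per_year: int = 8
    records_per_study: tuple[int, int] = (2, 6)
    true_effect: Schedule | str = "gentle_decline"
    zero_prevalence: Schedule | str = "early_zeros"
    scale_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    #: probabilities over (percentage, proportion, continuous)
    n_range: tuple[int, int] = (6, 30)
    cv_range: tuple[float, float] = (0.15, 0.5)
    flag_rates: dict = dataclasses.field(
        default_factory=lambda: {
            "is_sham": 0.05,
            "is_fluctuating_co2": 0.05,
            "is_procedural_control": 0.02,
            "direction_opposite": 0.05,
        }
    )
    co2_range: tuple[float, float] = (500.0, 1300.0)
    baseline_frac: tuple[float, float] = (0.05, 0.60)
    #: control-mean interval on bounded scales, as a fraction of the bound
    continuous_baseline: tuple[float, float] = (5.0, 50.0)
    tau_true: float = 0.3
    sham_sd: float = 0.05
    fluctuating_attenuation: float = 0.3
    bound_force_prob: float = 0.3
    #: given a forced zero, probability the other arm is forced to the ceiling
    max_resamples: int = 1000
    seed: int = 20221122

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        if self.records_per_study[1] < self.records_per_study[0]:
            raise ValueError("records_per_study range is empty")
        if not math.isclose(sum(self.scale_mix), 1.0, abs_tol=1e-9):
            raise ValueError("scale_mix must sum to 1")
        for key, p in {**self.flag_rates, "bound_force_prob": self.bound_force_prob}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {key}={p} outside [0, 1]")

    def true_effect_at(self, year: int) -> float:
        sched = self.true_effect
        if isinstance(sched, str):
            sched = TRUE_EFFECT_PRESETS[sched]
        return sched.value(year, *self.years)

    def zero_prevalence_at(self, year: int) -> float:
        sched = self.zero_prevalence
        if isinstance(sched, str):
            sched = ZERO_PREVALENCE_PRESETS[sched]
        return sched.value(year, *self.years)


def simulate_corpus(
    config: SyntheticCorpusConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a corpus of study records from a configuration.

    ``seed`` overrides ``config.seed``.  All generated records satisfy the
    corpus invariants; zero means appear only on bounded scales via the
    zero-prevalence mechanism.
    """
    config = config or SyntheticCorpusConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scales = np.array(["percentage", "proportion", "continuous"])
    rows: list[dict] = []

    for year in range(config.years[0], config.years[1] + 1):
        mu = config.true_effect_at(year)
        p_zero = config.zero_prevalence_at(year)
        for s in range(config.studies_per_year):
            study_id = f"S{year}-{s:02d}"
            co2 = float(rng.uniform(*config.co2_range))
            year_print = min(year + int(rng.random() < 0.15), config.years[1])
            species = str(rng.choice(_SPECIES))
            n_records = int(rng.integers(config.records_per_study[0], config.records_per_study[1] + 1))
            for r in range(n_records):
                rows.append(
                    _simulate_record(
                        rng, config, f"{study_id}-r{r}", study_id, year, year_print,
                        species, co2, mu, p_zero, scales,
                    )
                )
    return pd.DataFrame(rows, columns=list(CORPUS_COLUMNS))


def _simulate_record(
    rng, config, record_id, study_id, year, year_print, species, co2, mu, p_zero, scales,
) -> dict:
    scale = str(rng.choice(scales, p=config.scale_mix))
    flags = {name: bool(rng.random() < rate) for name, rate in config.flag_rates.items()}

    def draw_latent() -> float:
        if flags["is_sham"]:
            latent = rng.normal(0.0, config.sham_sd)
        else:
            latent = rng.normal(mu, config.tau_true)
            if flags["is_fluctuating_co2"]:
                latent *= config.fluctuating_attenuation
        if flags["direction_opposite"]:
            latent = -latent
        return latent

    bound = SCALE_BOUNDS.get(scale)
    if bound is None:
        latent = draw_latent()
        control = float(rng.uniform(*config.continuous_baseline))
        treatment = control * math.exp(latent)
    else:
        # keep the latent draw and truncate the baseline interval to what the
        # bound allows: conditioning the baseline (not the effect) leaves the
        # latent lnRR marginal exactly N(mu, tau^2)
        lo, hi = (config.baseline_frac[0] * bound, config.baseline_frac[1] * bound)
        for attempt in range(config.max_resamples):
            latent = draw_latent()
            ctl_hi = min(hi, bound * math.exp(-latent)) if latent > 0 else hi
            if ctl_hi > lo:
                control = float(rng.uniform(lo, ctl_hi))
                treatment = control * math.exp(latent)
                if 0.0 < treatment < bound:
                    break
        else:
            raise RuntimeError(
                f"{record_id}: could not place a latent effect of ~{mu:.2f} inside "
                f"the {scale} bounds after {config.max_resamples} resamples; "
                "lower the baseline interval or the effect schedule"
            )

    n_c = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
    n_t = int(rng.integers(config.n_range[0], config.n_range[1] + 1))

    # floor-effect zeros: only on bounded scales, more often in early years;
    # an arm forced onto a bound has no between-individual spread (sd = 0)
    forced_c = forced_t = False
    if bound is not None and rng.random() < p_zero:
        if treatment < control:
            treatment, forced_t = 0.0, True
            if rng.random() < config.bound_force_prob:
                control, forced_c = bound, True
        else:
            control, forced_c = 0.0, True
            if rng.random() < config.bound_force_prob:
                treatment, forced_t = bound, True

    sd_c = 0.0 if forced_c else float(rng.uniform(*config.cv_range)) * control
    sd_t = 0.0 if forced_t else float(rng.uniform(*config.cv_range)) * treatment

    return {
        "record_id": record_id,
        "study_id": study_id,
        "year_online": year,
        "year_print": year_print,
        "species": species,
        "life_stage": str(rng.choice(_LIFE_STAGES)),
        "cue_type": str(rng.choice(_CUE_TYPES)),
        "behaviour_metric": str(rng.choice(_METRICS)),
        "scale_type": scale,
        "control_mean": control,
        "treatment_mean": treatment,
        "control_sd": sd_c,
        "treatment_sd": sd_t,
        "control_n": n_c,
        "treatment_n": n_t,
        "co2_uatm": co2,
        **flags,
    }


_NO_FLAGS = {
    "is_sham": 0.0,
    "is_fluctuating_co2": 0.0,
    "is_procedural_control": 0.0,
    "direction_opposite": 0.0,
}

FIXTURE_NAMES = ("worked_example", "no_zeros_flat", "early_zeros_constant_effect")


def make_fixture(name: str, seed: int = 20221122) -> tuple[pd.DataFrame, dict]:
    """Build a named regression fixture: (corpus, expected values).

    ``worked_example``
        the single percentage record with control 0% and treatment 100%;
        expected lnRR under the three preset policies (printed precision).
    ``no_zeros_flat``
        a flat-truth corpus containing no bound values at all, so every
        replacement policy must yield identical effect tables.
    ``early_zeros_constant_effect``
        constant true effect with zeros concentrated in early years — the
        corpus on which a small replacement constant manufactures a
        decline effect out of nothing.
    """
    if name == "worked_example":
        corpus = pd.DataFrame(
            [
                {
                    "record_id": "worked-1",
                    "study_id": "worked",
                    "year_online": 2009,
                    "year_print": 2009,
                    "species": "Amphiprion percula",
                    "life_stage": "larva",
                    "cue_type": "predator",
                    "behaviour_metric": "time_in_cue",
                    "scale_type": "percentage",
                    "control_mean": 0.0,
                    "treatment_mean": 100.0,
                    "control_sd": 0.0,
                    "treatment_sd": 0.0,
                    "control_n": 10,
                    "treatment_n": 10,
                    "co2_uatm": 1000.0,
                    "is_sham": False,
                    "is_fluctuating_co2": False,
                    "is_procedural_control": False,
                    "direction_opposite": False,
                }
            ],
            columns=list(CORPUS_COLUMNS),
        )
        expected = {"whole_number": 4.6, "one_decimal": 6.9, "four_decimal": 13.8}
        return corpus, expected
    if name == "no_zeros_flat":
        config = SyntheticCorpusConfig(
            true_effect=Schedule.constant(1.0),
            zero_prevalence=Schedule.constant(0.0),
            flag_rates=dict(_NO_FLAGS),
            seed=seed,
        )
        return simulate_corpus(config), {"policy_invariant": True, "mu": 1.0}
    if name == "early_zeros_constant_effect":
        config = SyntheticCorpusConfig(
            true_effect=Schedule.constant(1.0),
            zero_prevalence="early_zeros",
            flag_rates=dict(_NO_FLAGS),
            seed=seed,
        )
        return simulate_corpus(config), {"mu": 1.0}
    raise ValueError(f"unknown fixture {name!r}; valid names: {FIXTURE_NAMES}")
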