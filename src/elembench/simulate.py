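"""Synthetic qiviut element tables with known ground truth.

The generator emulates the statistical structure of a multi-population hair
biomonitoring survey: trend-dependent element means, log-normal concentration
noise, nested random intercepts (population, and year within population),
additive log-scale covariate shifts for collection method, age class and sex,
and below-LOQ censoring.

For sample *i* of element *e* the concentration is

    c_ie = exp( ln(m[e, trend_i]) - s_tot(e)^2 / 2
                + b_pop(i) + b_year(i) + shift(covariates_i, e) + eps_ie )

with ``b_pop ~ N(0, pop_sd^2)``, ``b_year ~ N(0, year_sd^2)`` drawn once per
population and population-year, and ``eps ~ N(0, log_sd[e]^2)``. The
``- s_tot^2 / 2`` term (``s_tot^2 = pop_sd^2 + year_sd^2 + log_sd[e]^2``)
makes the *arithmetic* mean at baseline covariates equal the configured
group mean, so simulated group means converge to ``trend_means`` as n grows.

Default means come from published group means (with 95% CIs) of an
11-population muskox qiviut survey; the default population roster mirrors
that survey's layout (4 increasing, 3 stable, 4 declining populations,
unequal sizes, 1-6 growth years each).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .panel import ElementPanel, default_panel
from .qc import METADATA_COLUMNS, TREND_LEVELS, flag_col

# element -> trend -> (mean, ci_lower, ci_upper), all µg/g
REFERENCE_TREND_MEANS: dict[str, dict[str, tuple[float, float, float]]] = {
    "Na": {"increasing": (57.97, 41.49, 74.45), "stable": (47.24, 35.27, 59.21), "declining": (50.17, 40.51, 59.84)},
    "Mg": {"increasing": (119.61, 92.60, 146.62), "stable": (114.07, 95.55, 132.59), "declining": (112.79, 98.75, 126.83)},
    "Ca": {"increasing": (356.68, 325.88, 387.47), "stable": (470.78, 449.33, 492.24), "declining": (418.31, 393.28, 443.33)},
    "Cr": {"increasing": (0.53, 0.36, 0.70), "stable": (0.24, 0.03, 0.45), "declining": (0.64, 0.12, 1.16)},
    "Mn": {"increasing": (5.95, 4.36, 7.54), "stable": (2.77, 1.74, 3.80), "declining": (1.65, 1.11, 2.18)},
    "Fe": {"increasing": (312.94, 253.50, 372.39), "stable": (20.43, 17.57, 23.29), "declining": (46.79, 32.11, 61.46)},
    "Co": {"increasing": (0.11, 0.08, 0.13), "stable": (0.02, 0.02, 0.02), "declining": (0.02, 0.01, 0.03)},
    "Cu": {"increasing": (5.90, 5.60, 6.20), "stable": (5.26, 5.16, 5.36), "declining": (4.51, 4.38, 4.63)},
    "Zn": {"increasing": (92.50, 86.24, 98.77), "stable": (104.20, 102.40, 105.99), "declining": (99.18, 97.36, 101.00)},
    "Se": {"increasing": (0.39, 0.36, 0.42), "stable": (0.29, 0.27, 0.30), "declining": (0.19, 0.18, 0.21)},
    "Mo": {"increasing": (0.06, 0.05, 0.07), "stable": (0.05, 0.02, 0.09), "declining": (0.06, 0.05, 0.07)},
}

#: per-trend sample sizes of the reference survey, used to back-solve SDs from CIs
REFERENCE_TREND_N = {"increasing": 91, "stable": 149, "declining": 174}

#: (population id, trend, growth years, n per year, collection method)
REFERENCE_POPULATIONS: tuple[tuple, ...] = (
    ("alaska_east_ns", "stable", (2006, 2007), 10, "capture"),
    ("seward", "stable", (2008, 2018), 8, "capture"),
    ("yukon_ns", "increasing", (2016, 2017, 2018), 7, "capture"),
    ("banks", "declining", (2017,), 9, "shed"),
    ("nw_victoria", "declining", (2016, 2017, 2018), 20, "hunted"),
    ("north_great_slave", "increasing", (2017,), 22, "shed"),
    ("east_victoria", "declining", (2014, 2015, 2016, 2017, 2018), 12, "hunted"),
    ("nunavut_mainland", "stable", (2013, 2014, 2015, 2016, 2017, 2018), 19, "hunted"),
    ("east_hudson_bay", "increasing", (2016,), 30, "capture"),
    ("ungava", "increasing", (2018,), 19, "capture"),
    ("zackenberg", "declining", (2013, 2015, 2017), 15, "capture"),
)

# illustrative magnitudes for the known small covariate effects: ground-
# collected (shed) hair runs higher in Mn and Co, hunted samples lower in Se
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, dict[str, float]]] = {
    "collection": {"shed": {"Mn": 0.35, "Co": 0.35}, "hunted": {"Se": -0.25}},
    "age_class": {"calf": {"Co": -0.15}},
    "sex": {"male": {"Mo": -0.12}},
}

AGE_LEVELS = ("calf", "yearling", "adult")
AGE_PROBS = (0.10, 0.15, 0.75)
SEX_LEVELS = ("male", "female")

LOG_SD_FLOOR = 0.05
LOG_SD_CAP = 1.2


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    trend: str
    years: tuple[int, ...]
    n_per_year: int
    collection: str = "capture"


@dataclass
class SyntheticConfig:
    """Everything the generator needs; defaults define the study-like conditions."""

    panel: ElementPanel
    trend_means: dict[str, dict[str, float]]
    log_sd: dict[str, float]
    pop_sd: float = 0.10
    year_sd: float = 0.06
    covariate_effects: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    populations: tuple[PopulationSpec, ...] = ()
    below_loq_rate: dict[str, float] = field(default_factory=dict)
    missing_meta_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        for el in self.panel.names:
            means = self.trend_means.get(el, {})
            for trend in TREND_LEVELS:
                if trend not in means:
                    raise ValueError(f"trend_means missing ({el}, {trend})")
                if not means[trend] > 0:
                    raise ValueError(f"trend mean for ({el}, {trend}) must be > 0")
            if self.log_sd.get(el, 0.0) < 0:
                raise ValueError(f"log_sd[{el}] must be >= 0")
        if self.pop_sd < 0 or self.year_sd < 0:
            raise ValueError("random-effect SDs must be >= 0")
        for el, r in self.below_loq_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"below_loq_rate[{el}] must be in [0, 1]")


@dataclass
class GroundTruth:
    """Realized random intercepts, reproducible from (config, seed)."""

    pop_effects: dict[str, float]
    year_effects: dict[tuple[str, int], float]
    config: SyntheticConfig
    seed: int


def _backsolve_log_sd(el: str) -> float:
    """Total log-scale SD implied by the printed per-trend 95% CIs.

    CI half-width -> group SD (half-width * sqrt(n) / 1.96) -> CV ->
    log-normal sigma via sqrt(ln(1 + CV^2)); the median over the three
    trends is taken, capped to keep heavy right tails realistic for hair.
    """
    sigmas = []
    for trend, (mean, lo, hi) in REFERENCE_TREND_MEANS[el].items():
        half = (hi - lo) / 2.0
        n = REFERENCE_TREND_N[trend]
        sd = half * np.sqrt(n) / 1.96
        cv = sd / mean
        sigmas.append(np.sqrt(np.log1p(cv ** 2)))
    s = float(np.median(sigmas))
    return float(np.clip(s, LOG_SD_FLOOR, LOG_SD_CAP))


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-like default configuration.

    Trend means are the reference survey group means; residual log-SDs are
    back-solved from the printed CIs net of the random-intercept SDs
    (pop_sd=0.10, year_sd=0.06 on the log scale).
    """
    panel = default_panel()
    trend_means = {el: {t: REFERENCE_TREND_MEANS[el][t][0] for t in TREND_LEVELS}
                   for el in panel.names}
    pop_sd, year_sd = 0.10, 0.06
    log_sd = {}
    for el in panel.names:
        total = _backsolve_log_sd(el)
        resid2 = total ** 2 - pop_sd ** 2 - year_sd ** 2
        log_sd[el] = float(np.sqrt(max(resid2, LOG_SD_FLOOR ** 2)))
    pops = tuple(PopulationSpec(*row) for row in REFERENCE_POPULATIONS)
    return SyntheticConfig(
        panel=panel,
        trend_means=trend_means,
        log_sd=log_sd,
        pop_sd=pop_sd,
        year_sd=year_sd,
        covariate_effects={k: {l: dict(d) for l, d in v.items()}
                           for k, v in DEFAULT_COVARIATE_EFFECTS.items()},
        populations=pops,
        seed=seed,
    )


def _covariate_shift(cfg: SyntheticConfig, el: str, collection, age, sex) -> float:
    shift = 0.0
    levels = {"collection": collection, "age_class": age, "sex": sex}
    for cov, by_level in cfg.covariate_effects.items():
        lvl = levels.get(cov)
        if lvl is not None and lvl in by_level:
            shift += by_level[lvl].get(el, 0.0)
    return shift


def simulate_dataset(config: SyntheticConfig, seed: Optional[int] = None
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a sample table from the generative model.

    Deterministic given ``(config, seed)``; ``seed=None`` uses ``config.seed``.
    Below-LOQ cells are flagged and their value withheld (NaN), exactly as a
    laboratory export would report them.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    elements = list(config.panel.names)

    pop_effects = {p.name: rng.normal(0.0, config.pop_sd) for p in config.populations}
    year_effects = {(p.name, y): rng.normal(0.0, config.year_sd)
                    for p in config.populations for y in p.years}

    rows = []
    sid = 0
    for p in config.populations:
        for y in p.years:
            for _ in range(p.n_per_year):
                sid += 1
                if p.collection == "shed":
                    age, sex = None, None
                else:
                    age = AGE_LEVELS[rng.choice(len(AGE_LEVELS), p=AGE_PROBS)]
                    sex = SEX_LEVELS[int(rng.integers(2))]
                    if config.missing_meta_rate and rng.uniform() < config.missing_meta_rate:
                        if rng.uniform() < 0.5:
                            age = None
                        else:
                            sex = None
                row = {
                    "sample_id": f"S{sid:05d}",
                    "population": p.name,
                    "growth_year": y,
                    "trend": p.trend,
                    "collection": p.collection,
                    "age_class": age,
                    "sex": sex,
                }
                for el in elements:
                    s_resid = config.log_sd.get(el, 0.0)
                    s_tot2 = config.pop_sd ** 2 + config.year_sd ** 2 + s_resid ** 2
                    mu = (np.log(config.trend_means[el][p.trend]) - s_tot2 / 2.0
                          + pop_effects[p.name] + year_effects[(p.name, y)]
                          + _covariate_shift(config, el, p.collection, age, sex))
                    eps = rng.normal(0.0, s_resid) if s_resid > 0 else 0.0
                    row[el] = float(np.exp(mu + eps))
                rows.append(row)

    table = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + elements)
    table["growth_year"] = table["growth_year"].astype("Int64")
    table["trend"] = pd.Categorical(table["trend"], categories=TREND_LEVELS, ordered=True)

    for el in elements:
        vals = table[el].to_numpy()
        if el in config.panel.loq:
            flagged = vals < config.panel.loq[el]
        else:
            rate = config.below_loq_rate.get(el, 0.0)
            flagged = rng.uniform(size=len(table)) < rate if rate > 0 else np.zeros(len(table), bool)
        table[flag_col(el)] = flagged
        table.loc[flagged, el] = np.nan

    truth = GroundTruth(pop_effects=pop_effects, year_effects=year_effects,
                        config=config, seed=seed)
    return table, truth


def inject_covariate_effects(table: pd.DataFrame,
                             effects: Mapping[str, Mapping[str, Mapping[str, float]]]
                             ) -> pd.DataFrame:
    """Multiply concentrations by ``exp(shift)`` for matching records.

    ``effects`` maps covariate -> level -> element -> log-scale shift.
    Raises if a referenced level does not occur in the table.
    """
    table = table.copy()
    for cov, by_level in effects.items():
        if cov not in table.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        present = set(table[cov].dropna().unique())
        for level, by_el in by_level.items():
            if level not in present:
                raise ValueError(f"covariate {cov!r} has no level {level!r} in the table")
            mask = table[cov] == level
            for el, shift in by_el.items():
                if el not in table.columns:
                    raise ValueError(f"unknown element {el!r}")
                table.loc[mask, el] = table.loc[mask, el] * float(np.exp(shift))
    return table


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Sidecar CSV of the realized random intercepts."""
    rows = [{"level": "population", "population": p, "growth_year": "", "effect": b}
            for p, b in truth.pop_effects.items()]
    rows += [{"level": "year", "population": p, "growth_year": y, "effect": b}
             for (p, y), b in truth.year_effects.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
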