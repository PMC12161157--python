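"""Synthetic DHS-like two-module microdata with known ground truth.

The generator emulates the structure of a multi-wave FGM survey series:
stratified two-stage cluster samples (PSUs within strata, respondents
within PSUs, weights = inverse inclusion probability normalized to mean 1
per survey), a women's module (self-report, ages 15-49) and a daughters'
module (proxy report by mothers, ages 0-14), FGM prevalence by birth
cohort, and a true age-at-FGM distribution over ages 0..17.

On top of the truth sits a *reporting layer* that produces the quality
defects the pipeline measures, applied in order heap -> infancy-code ->
missingness:

* heaping: with probability ``heap_prob`` a reported age snaps to the
  nearest multiple of 5 (window +/-2 years, target within 0..17);
* infancy coding: with probability ``infancy_prob`` a reported age <= 5
  becomes the approximate "during infancy" answer;
* missingness: the age is dropped with probability from a logistic model
  (intercept + women's-module effect + optional age/education effects on
  the log-odds of *complete* reporting).

Heaping and infancy coding default to the women's module only — the
self-/proxy-report quality contrast is the design, not something the
generator tests — while the missingness model spans both modules so the
module effect is a recoverable parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .schema import APPROX_COL, COLUMNS, cohort_from_birth_year

MAX_TRUE_AGE = 17
HEAP_TARGETS = (0, 5, 10, 15)
HEAP_WINDOW = 2


@dataclass
class SurveyConfig:
    """Design of one survey wave."""

    survey_id: str
    year: int
    eligible_population: int = 6_000_000
    n_strata: int = 8
    psus_per_stratum: int = 12
    respondents_per_psu: int = 25
    women_share: float = 0.57  # 1.0 => women-only wave, 0.0 => daughters-only

    def validate(self):
        if min(self.n_strata, self.psus_per_stratum, self.respondents_per_psu) < 1:
            raise ValueError(f"{self.survey_id}: sample sizes must be >= 1")
        if not 0.0 <= self.women_share <= 1.0:
            raise ValueError(f"{self.survey_id}: women_share must be in [0, 1]")
        if self.eligible_population <= 0:
            raise ValueError(f"{self.survey_id}: eligible_population must be positive")


@dataclass
class ReportingConfig:
    """Reporting-quality layer applied to true ages at FGM."""

    heap_prob: float = 0.0
    infancy_prob: float = 0.0
    infancy_max_age: int = 5
    complete_intercept: float = 8.0  # log-odds that the age is reported
    women_complete_logor: float = 0.0
    age_complete_logor: float = 0.0  # per year of current age
    education_complete_logor: float = 0.0  # per ordinal education step
    distorted_modules: tuple = ("women",)  # heap/infancy apply here only

    def validate(self):
        for name in ("heap_prob", "infancy_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.infancy_max_age <= MAX_TRUE_AGE:
            raise ValueError("infancy_max_age out of range")
        bad = set(self.distorted_modules) - {"women", "daughters"}
        if bad:
            raise ValueError(f"unknown module(s) {sorted(bad)}")


_EDU_LEVELS = ("none", "primary", "secondary", "higher", "other", "missing")
_EDU_SCORE = {"none": 0, "primary": 1, "secondary": 2, "higher": 3, "other": 0, "missing": 0}


@dataclass
class GeneratorConfig:
    """Complete recipe for one synthetic dataset."""

    surveys: list = field(default_factory=list)
    prevalence_by_cohort: dict = field(default_factory=lambda: {c: 0.3 for c in (
        "1960s", "1970s", "1980s", "1990s", "2000s", "2010s", "post2020", "missing")})
    age_at_fgm_dist: tuple = field(
        default_factory=lambda: tuple(np.full(MAX_TRUE_AGE + 1, 1.0 / (MAX_TRUE_AGE + 1)))
    )
    education_probs: dict = field(default_factory=lambda: {
        "none": 0.62, "primary": 0.20, "secondary": 0.164,
        "higher": 0.014, "other": 0.001, "missing": 0.001})
    dob_imputed_prob: float = 0.64
    cohort_missing_prob: float = 0.005  # share with unusable date of birth
    reporting: ReportingConfig = field(default_factory=ReportingConfig)
    seed: int | None = None

    def validate(self):
        if not self.surveys:
            raise ValueError("at least one survey is required")
        for sv in self.surveys:
            sv.validate()
        dist = np.asarray(self.age_at_fgm_dist, dtype=float)
        if dist.shape != (MAX_TRUE_AGE + 1,) or (dist < 0).any():
            raise ValueError(f"age_at_fgm_dist must be {MAX_TRUE_AGE + 1} non-negative values")
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("age_at_fgm_dist must sum to 1")
        if dist[0] <= 0:
            raise ValueError("age_at_fgm_dist must put mass at age 0")
        for k, v in self.prevalence_by_cohort.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence for {k!r} must be in [0, 1]")
        ep = np.asarray([self.education_probs.get(l, 0.0) for l in _EDU_LEVELS])
        if (ep < 0).any() or abs(ep.sum() - 1.0) > 1e-9:
            raise ValueError("education_probs must be non-negative and sum to 1")
        if not 0.0 <= self.dob_imputed_prob <= 1.0:
            raise ValueError("dob_imputed_prob must be in [0, 1]")
        if not 0.0 <= self.cohort_missing_prob <= 1.0:
            raise ValueError("cohort_missing_prob must be in [0, 1]")
        self.reporting.validate()

    def totals_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "survey_id": [sv.survey_id for sv in self.surveys],
            "eligible_population": [sv.eligible_population for sv in self.surveys],
        })

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """True ages before reporting distortions, aligned row-by-row to the records."""

    frame: pd.DataFrame  # columns: true_age_at_fgm (NaN for FGM-negative)
    config: GeneratorConfig


def nearest_heap_target(ages: np.ndarray) -> np.ndarray:
    """Nearest multiple of 5 within 0..17 (every age 0..17 is within +/-2 of one)."""
    return np.clip(5 * np.round(np.asarray(ages, dtype=float) / 5.0), 0, 15)


def expected_heaping_ratio(age_dist, heap_prob: float, target: int) -> float:
    """Closed-form smooth-transition ratio at ``target`` after heaping.

    Mass at non-target ages inside a heap window is thinned by
    ``heap_prob``; target ages gain the displaced window mass.  This is the
    population value the sample heaping index converges to when heaping is
    the only distortion.
    """
    f = np.asarray(age_dist, dtype=float)
    ages = np.arange(len(f))
    tgt = nearest_heap_target(ages)
    in_window = np.abs(ages - tgt) <= HEAP_WINDOW
    c = f.copy()
    moved = np.where(in_window & (ages != tgt), heap_prob * f, 0.0)
    c -= moved
    for t in HEAP_TARGETS:
        c[t] += moved[(tgt == t)].sum()
    expected = (c[target - 1] + c[target + 1]) / 2.0
    return float(c[target] / expected)


def solve_heap_prob(target_ratio: float, age_dist, target: int = 5) -> float:
    """Heap probability at which the closed-form ratio equals ``target_ratio``."""

    def g(p):
        return expected_heaping_ratio(age_dist, p, target) - target_ratio

    return float(brentq(g, 0.0, 1.0 - 1e-9))


def _truncated_age_draw(rng, dist_cdf, caps):
    """Draw ages from the truth distribution truncated at each record's cap."""
    top = dist_cdf[caps]
    u = rng.uniform(0.0, top)
    return np.searchsorted(dist_cdf, u, side="left").astype(float)


def generate(config: GeneratorConfig, seed: int | None = None):
    """Generate one synthetic dataset.

    Returns ``(records, truth)``: a harmonized records frame that passes
    the schema invariants, and the :class:`SyntheticTruth` with every
    FGM-positive record's true age at FGM before distortion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rep = config.reporting
    dist_cdf = np.cumsum(np.asarray(config.age_at_fgm_dist, dtype=float))
    dist_cdf[-1] = 1.0

    frames, truths = [], []
    for sv in config.surveys:
        n = sv.n_strata * sv.psus_per_stratum * sv.respondents_per_psu
        stratum = np.repeat(np.arange(sv.n_strata), sv.psus_per_stratum * sv.respondents_per_psu)
        psu = np.repeat(np.arange(sv.n_strata * sv.psus_per_stratum), sv.respondents_per_psu)
        # notional PSU pools grow across strata => inclusion probabilities and
        # hence weights differ by stratum (a real design effect)
        psu_pool = 2 * sv.psus_per_stratum + 3 * stratum
        p_psu = sv.psus_per_stratum / psu_pool
        p_resp = 0.5
        w_raw = 1.0 / (p_psu * p_resp)
        weight_norm = w_raw / w_raw.mean()

        women = rng.random(n) < sv.women_share
        # oldest observed birth year is 1960, as in the emulated series
        women_age_hi = min(49, sv.year - 1960)
        cur_age = np.where(
            women,
            rng.integers(15, women_age_hi + 1, size=n),
            rng.integers(0, 15, size=n),
        )
        cohort = cohort_from_birth_year(sv.year - cur_age).to_numpy()
        cohort[rng.random(n) < config.cohort_missing_prob] = "missing"
        education = rng.choice(
            _EDU_LEVELS, size=n, p=[config.education_probs.get(l, 0.0) for l in _EDU_LEVELS]
        )
        dob = np.where(rng.random(n) < config.dob_imputed_prob, "imputed", "complete")
        prev = np.vectorize(lambda c: config.prevalence_by_cohort.get(c, 0.0))(cohort)
        fgm = rng.random(n) < prev

        true_age = np.full(n, np.nan)
        caps = np.minimum(cur_age[fgm], MAX_TRUE_AGE)
        true_age[fgm] = _truncated_age_draw(rng, dist_cdf, caps)

        distorted = np.isin(np.where(women, "women", "daughters"), list(rep.distorted_modules))
        reported = true_age.copy()
        # 1) heaping
        heapable = fgm & distorted
        tgt = nearest_heap_target(np.nan_to_num(reported))
        snap = heapable & (rng.random(n) < rep.heap_prob) & (tgt <= np.maximum(cur_age, 0))
        reported[snap] = tgt[snap]
        # 2) infancy coding
        approx = (
            fgm & distorted
            & (reported <= rep.infancy_max_age)
            & (rng.random(n) < rep.infancy_prob)
        )
        # 3) missingness (applies to both modules)
        eta = (
            rep.complete_intercept
            + rep.women_complete_logor * women
            + rep.age_complete_logor * cur_age
            + rep.education_complete_logor * np.vectorize(_EDU_SCORE.get)(education)
        )
        missing = fgm & (rng.random(n) >= expit(eta))
        reported[missing] = np.nan
        approx[missing] = False
        reported[approx] = np.nan

        frames.append(pd.DataFrame({
            "survey_id": sv.survey_id,
            "module": np.where(women, "women", "daughters"),
            "current_age": cur_age.astype(int),
            "birth_cohort": cohort,
            "fgm_status": np.where(fgm, "yes", "no"),
            "age_at_fgm": reported,
            APPROX_COL: approx,
            "education": education,
            "dob_complete": dob,
            "stratum_id": np.char.add(f"{sv.survey_id}-h", np.char.zfill(stratum.astype(str), 2)),
            "cluster_id": np.char.add(
                np.char.add(f"{sv.survey_id}-h", np.char.zfill(stratum.astype(str), 2)),
                np.char.add("-c", np.char.zfill(psu.astype(str), 4)),
            ),
            "weight_norm": weight_norm,
        }))
        truths.append(pd.DataFrame({"true_age_at_fgm": true_age}))

    records = pd.concat(frames, ignore_index=True)
    truth_frame = pd.concat(truths, ignore_index=True)
    cut = COLUMNS.index("age_at_fgm") + 1
    records = records[COLUMNS[:cut] + [APPROX_COL] + COLUMNS[cut:]]
    return records, SyntheticTruth(frame=truth_frame, config=config)


# --- study-conditions preset -------------------------------------------------

#: true age-at-FGM distribution: early-childhood practice, lower median 3 years
#: (cumulative mass at age 2 is 49.7%, just under half)
_PRESET_AGE_DIST = np.array(
    [19, 16, 13.5, 13, 11, 8.5, 5, 3.5, 2.2, 1.6, 1.2, 0.9, 0.7, 0.5, 0.35, 0.25, 0.18, 0.12]
)
_PRESET_AGE_DIST = tuple(_PRESET_AGE_DIST / _PRESET_AGE_DIST.sum())

#: per-wave layout proportional to the published series (year, rows, women share)
_PRESET_WAVES = [
    ("SV2005", 2005, 14599, 1.000, 5_400_000),
    ("SV2010", 2010, 26187, 0.599, 6_200_000),
    ("SV2012", 2012, 2805, 0.000, 6_500_000),
    ("SV2014", 2014, 16367, 0.519, 6_800_000),
    ("SV2015", 2015, 17051, 0.519, 7_000_000),
    ("SV2016", 2016, 16781, 0.528, 7_200_000),
    ("SV2017", 2017, 31815, 0.528, 7_400_000),
    ("SV2018", 2018, 17793, 0.529, 7_600_000),
    ("SV2019", 2019, 16477, 0.525, 7_800_000),
    ("SV2023", 2023, 30178, 0.549, 8_600_000),
]


def preset_paper_like(scale: float = 1.0) -> GeneratorConfig:
    """Study-conditions preset: a ten-wave series with realistic quality defects.

    Expected headline outputs: women's FGM prevalence ~34%, daughters' ~20%;
    missing-age share ~6% (women) vs 1% (daughters); ~45% of women's young
    ages given as "infancy"; heaping ratio at age 5 of 2.5 in the women's
    module (the heap probability is solved from the closed displacement
    form under the preset age distribution).

    ``scale`` shrinks every wave's PSU occupancy proportionally for quick
    runs; the design (strata, PSUs) is unchanged.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    surveys = []
    for sid, year, n_rows, women_share, pop in _PRESET_WAVES:
        n_strata, psus = 14, 10
        rpp = max(1, round(scale * n_rows / (n_strata * psus)))
        surveys.append(SurveyConfig(
            survey_id=sid, year=year, eligible_population=pop,
            n_strata=n_strata, psus_per_stratum=psus, respondents_per_psu=rpp,
            women_share=women_share,
        ))
    reporting = ReportingConfig(
        heap_prob=solve_heap_prob(2.5, _PRESET_AGE_DIST, target=5),
        infancy_prob=0.45,
        complete_intercept=float(logit(0.99)),
        women_complete_logor=float(np.log(0.16)),
    )
    return GeneratorConfig(
        surveys=surveys,
        prevalence_by_cohort={
            "1960s": 0.36, "1970s": 0.35, "1980s": 0.35, "1990s": 0.33,
            "2000s": 0.26, "2010s": 0.19, "post2020": 0.16, "missing": 0.30,
        },
        age_at_fgm_dist=_PRESET_AGE_DIST,
        reporting=reporting,
    )
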