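"""Synthetic cohorts of phase III cancer RCTs.

The analyses in this package operate on a table of randomized controlled
trials (RCTs), one row per trial, carrying the cooperative group that ran
it, the disease and treatment type studied, the publication year, and the
reported survival hazard ratio (HR, coded so HR > 1 favors the new
treatment) with its p-value. The registry of NCI cooperative-group trials
that motivates this structure is not publicly deposited, so this module
generates cohorts with the statistical features the downstream network
analysis assumes:

* log-HR drawn from a body centered slightly above parity (new treatments
  are on average marginally superior — the equipoise regime) mixed with a
  small-probability heavy (power-law) right tail of breakthrough results;
* p-values stochastically decreasing in effect size, via a normal test
  statistic proportional to ``|log HR| * sqrt(events)`` with jitter;
* categorical group/disease/treatment labels with configurable marginal
  frequencies (ECOG, the largest cooperative group, gets the largest share);
* chronological ordering, which the growth-model network construction
  requires (later trials can only attach to earlier ones).
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "TrialRecord",
    "TrialCohort",
    "HRModel",
    "SignificanceModel",
    "CohortConfig",
    "generate_cohort",
    "success_score",
    "success_scores",
    "SCORE_RULES",
    "DEFAULT_ATTRIBUTE_FREQUENCIES",
]

#: Default marginal label frequencies. ECOG carries the largest group share,
#: reflecting its standing as the largest NCI cooperative group.
DEFAULT_ATTRIBUTE_FREQUENCIES: dict[str, dict[str, float]] = {
    "group": {
        "ECOG": 0.30, "SWOG": 0.18, "RTOG": 0.13, "CALGB": 0.12,
        "GOG": 0.11, "NCCTG": 0.09, "CHOG": 0.07,
    },
    "disease": {
        "breast": 0.16, "GI": 0.15, "lung": 0.14, "GYN": 0.12,
        "leukemia": 0.11, "H&N": 0.09, "prostate": 0.09,
        "melanoma": 0.07, "CNS": 0.07,
    },
    "treatment": {
        "definitive": 0.28, "adjuvant": 0.24, "induction": 0.16,
        "maintenance": 0.12, "supportive": 0.11, "other": 0.09,
    },
}

ATTRIBUTES = ("group", "disease", "treatment")


@dataclass(frozen=True)
class TrialRecord:
    """One randomized controlled trial.

    ``hr`` is the survival hazard ratio, coded so values above 1 favor the
    new treatment; a trial is conventionally called successful when
    ``hr > 1`` at ``p_value <= 0.05``.
    """

    trial_id: str
    year: int
    group: str
    disease: str
    treatment: str
    hr: float
    p_value: float

    def __post_init__(self):
        if not self.hr > 0:
            raise ValueError(f"trial {self.trial_id!r}: hr must be > 0, got {self.hr}")
        if not 0 < self.p_value <= 1:
            raise ValueError(
                f"trial {self.trial_id!r}: p_value must be in (0, 1], got {self.p_value}"
            )


class TrialCohort:
    """An ordered collection of trials, non-decreasing in publication year.

    Chronological order is an invariant of the container: records are
    stably sorted by year on construction, so ties keep their input order.
    """

    def __init__(
        self,
        trials: Sequence[TrialRecord],
        attribute_domains: Mapping[str, Sequence[str]] | None = None,
    ):
        self.trials: tuple[TrialRecord, ...] = tuple(
            sorted(trials, key=lambda t: t.year)
        )
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate trial_id(s) in cohort: {sorted(dupes)}")
        self._by_id = {t.trial_id: t for t in self.trials}
        if attribute_domains is None:
            attribute_domains = {
                attr: sorted({getattr(t, attr) for t in self.trials})
                for attr in ATTRIBUTES
            }
        self.attribute_domains = {k: tuple(v) for k, v in attribute_domains.items()}

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialCohort) and self.trials == other.trials

    @property
    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    @property
    def hr(self) -> np.ndarray:
        return np.array([t.hr for t in self.trials])

    @property
    def p_value(self) -> np.ndarray:
        return np.array([t.p_value for t in self.trials])

    @property
    def years(self) -> np.ndarray:
        return np.array([t.year for t in self.trials])

    def record(self, trial_id: str) -> TrialRecord:
        try:
            return self._by_id[trial_id]
        except KeyError:
            raise KeyError(f"no trial {trial_id!r} in cohort") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "year": [t.year for t in self.trials],
                "group": [t.group for t in self.trials],
                "disease": [t.disease for t in self.trials],
                "treatment": [t.treatment for t in self.trials],
                "hr": [t.hr for t in self.trials],
                "p_value": [t.p_value for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialCohort":
        records = [
            TrialRecord(
                trial_id=str(row.trial_id),
                year=int(row.year),
                group=str(row.group),
                disease=str(row.disease),
                treatment=str(row.treatment),
                hr=float(row.hr),
                p_value=float(row.p_value),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    def __repr__(self) -> str:
        yrs = (self.trials[0].year, self.trials[-1].year) if self.trials else ("-", "-")
        return f"<TrialCohort n={len(self)} years={yrs[0]}-{yrs[1]}>"


@dataclass(frozen=True)
class HRModel:
    """Survival hazard-ratio distribution: log-normal body + Pareto tail.

    With probability ``tail_mass`` the HR is a breakthrough drawn from a
    Pareto tail with survival exponent ``tail_exponent`` above
    ``tail_xmin``; otherwise ``log HR ~ Normal(body_location, body_scale)``,
    with the location slightly above 0 so new treatments are on average
    marginally superior.
    """

    body_location: float = 0.05
    body_scale: float = 0.25
    tail_exponent: float = 2.8
    tail_mass: float = 0.05
    tail_xmin: float = 1.5

    def validate(self):
        if self.body_scale <= 0:
            raise ConfigurationError(f"body_scale must be > 0, got {self.body_scale}")
        if not 0 <= self.tail_mass <= 1:
            raise ConfigurationError(f"tail_mass must be in [0, 1], got {self.tail_mass}")
        if self.tail_exponent <= 1:
            raise ConfigurationError(
                f"tail_exponent must be > 1, got {self.tail_exponent}"
            )
        if self.tail_xmin <= 0:
            raise ConfigurationError(f"tail_xmin must be > 0, got {self.tail_xmin}")


@dataclass(frozen=True)
class SignificanceModel:
    """Monotone-with-noise link from effect size to p-value.

    The test statistic is ``z = |log HR| / se`` with the asymptotic
    standard error of a log hazard ratio, ``se = 2 / sqrt(events)``, the
    event count drawn log-uniformly per trial; multiplicative log-normal
    jitter keeps the link stochastic. ``p = 2 * Phi(-z)``, clipped into
    (0, 1].
    """

    events_min: int = 50
    events_max: int = 800
    jitter_sd: float = 0.3
    p_floor: float = 1e-12

    def validate(self):
        if not 0 < self.events_min <= self.events_max:
            raise ConfigurationError(
                f"need 0 < events_min <= events_max, got "
                f"({self.events_min}, {self.events_max})"
            )
        if self.jitter_sd < 0:
            raise ConfigurationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    Defaults emulate the study scale: 280 phase III trials spanning
    1955-2006.
    """

    n_trials: int = 280
    seed: int = 0
    hr_model: HRModel = field(default_factory=HRModel)
    significance_model: SignificanceModel = field(default_factory=SignificanceModel)
    attribute_frequencies: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ATTRIBUTE_FREQUENCIES
    )
    year_range: tuple[int, int] = (1955, 2006)

    def validate(self):
        if self.n_trials < 0:
            raise ConfigurationError(f"n_trials must be >= 0, got {self.n_trials}")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigurationError(f"invalid year_range {self.year_range}")
        self.hr_model.validate()
        self.significance_model.validate()
        for attr in ATTRIBUTES:
            if attr not in self.attribute_frequencies:
                raise ConfigurationError(f"missing attribute_frequencies[{attr!r}]")
            probs = np.array(list(self.attribute_frequencies[attr].values()), float)
            if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-8):
                raise ConfigurationError(
                    f"attribute_frequencies[{attr!r}] must be a probability vector "
                    f"(sum {probs.sum():.6f})"
                )

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))


def _sample_hr(model: HRModel, n: int, rng: np.random.Generator) -> np.ndarray:
    hr = np.exp(rng.normal(model.body_location, model.body_scale, size=n))
    in_tail = rng.random(n) < model.tail_mass
    n_tail = int(in_tail.sum())
    if n_tail:
        # Pareto with survival function (x/xmin)^-(a-1), inverse-CDF sampled
        u = rng.random(n_tail)
        hr[in_tail] = model.tail_xmin * u ** (-1.0 / (model.tail_exponent - 1.0))
    return hr


def _sample_p_values(
    hr: np.ndarray, model: SignificanceModel, rng: np.random.Generator
) -> np.ndarray:
    n = len(hr)
    log_events = rng.uniform(np.log(model.events_min), np.log(model.events_max), n)
    se = 2.0 / np.sqrt(np.exp(log_events))
    z = np.abs(np.log(hr)) / se * np.exp(rng.normal(0.0, model.jitter_sd, n))
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, model.p_floor, 1.0)


def generate_cohort(config: CohortConfig) -> TrialCohort:
    """Generate a synthetic RCT cohort.

    Fully deterministic under ``config.seed``: two calls with an identical
    config are record-for-record identical. Years are drawn uniformly over
    ``year_range`` and sorted; trial identifiers are assigned in
    chronological order.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    if n == 0:
        return TrialCohort([], attribute_domains={
            attr: tuple(config.attribute_frequencies[attr]) for attr in ATTRIBUTES
        })

    years = np.sort(rng.integers(config.year_range[0], config.year_range[1] + 1, n))
    labels: dict[str, np.ndarray] = {}
    for attr in ATTRIBUTES:
        freq = config.attribute_frequencies[attr]
        labels[attr] = rng.choice(list(freq), size=n, p=list(freq.values()))
    hr = _sample_hr(config.hr_model, n, rng)
    p = _sample_p_values(hr, config.significance_model, rng)

    width = max(4, len(str(n)))
    records = [
        TrialRecord(
            trial_id=f"T{i:0{width}d}",
            year=int(years[i]),
            group=str(labels["group"][i]),
            disease=str(labels["disease"][i]),
            treatment=str(labels["treatment"][i]),
            hr=float(hr[i]),
            p_value=float(p[i]),
        )
        for i in range(n)
    ]
    return TrialCohort(records, attribute_domains={
        attr: tuple(config.attribute_frequencies[attr]) for attr in ATTRIBUTES
    })


# --- attachment fitness -----------------------------------------------------

SCORE_RULES = ("hr_times_one_minus_p", "hr_only", "hr_if_significant")


def success_score(trial: TrialRecord, weighting: str = "hr_times_one_minus_p") -> float:
    """Unnormalized attachment fitness of a trial.

    The growth model ties new trials to existing ones with probability
    proportional to this score, which combines the hazard ratio with the
    statistical significance of the reported result. Rules:

    ``hr_times_one_minus_p``
        ``hr * (1 - p_value)`` (default): success discounted by how
        unconvincing the evidence is.
    ``hr_only``
        the hazard ratio alone.
    ``hr_if_significant``
        ``hr`` if ``p_value <= 0.05``, else 0.
    """
    if weighting == "hr_times_one_minus_p":
        return trial.hr * (1.0 - trial.p_value)
    if weighting == "hr_only":
        return trial.hr
    if weighting == "hr_if_significant":
        return trial.hr if trial.p_value <= 0.05 else 0.0
    raise ValueError(f"unknown score rule {weighting!r}; known: {SCORE_RULES}")


def success_scores(cohort: TrialCohort, weighting: str = "hr_times_one_minus_p") -> np.ndarray:
    """Vector of :func:`success_score` over a cohort, in cohort order."""
    return np.array([success_score(t, weighting) for t in cohort])
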