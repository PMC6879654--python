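"""Day/night cohort construction and characterization.

Patients are classified by clock time of injury into a daytime window
(08:00-17:00, the shortest annual daylight period at the study latitude)
or a nighttime window (22:00-05:00, the shortest night period); everyone
else is "Neither" and excluded from the two-group comparison.  Severity
filtering (ISS > 20), one-to-one propensity matching on age within exact
sex strata, exact 2x2 categorical tests, and Table-1-style cohort
summaries live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Daytime window, minutes since midnight, half-open [start, end).
DAY_WINDOW = (480, 1020)  # 08:00 - 17:00
#: Nighttime window wraps midnight: [22:00, 24:00) + [00:00, 05:00).
NIGHT_WINDOWS = ((1320, 1440), (0, 300))

MINUTES_PER_DAY = 1440

AIS_REGIONS = ("head_neck", "face", "chest", "abdomen", "extremities", "external")
MECHANISMS = ("MVA", "fall", "motorcycle", "other")
SEXES = ("male", "female")


@dataclass
class PatientRecord:
    """One enrolled blunt-trauma subject.

    ``injury_clock_time`` is minutes since midnight in [0, 1440).
    ``ais`` maps the six body regions (``AIS_REGIONS``) to 0-6 scores.
    ``icu_los_days <= hospital_los_days`` is deliberately *not* enforced:
    registry data can violate it and is recorded as-is.
    """

    patient_id: str
    age: float
    sex: str
    iss: int
    ais: dict[str, int]
    injury_clock_time: int
    mechanism: str
    comorbidities: set[str] = field(default_factory=set)
    icu_los_days: float = 0.0
    hospital_los_days: float = 0.0
    vent_days: float = 0.0
    nosocomial_infection: bool = False
    mod_scores: Sequence[float] | None = None
    group: str = field(init=False, default="Neither")

    def __post_init__(self) -> None:
        if not 0 <= self.injury_clock_time < MINUTES_PER_DAY:
            raise ValueError(
                f"injury_clock_time {self.injury_clock_time} outside [0, 1440)"
            )
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.iss < 0:
            raise ValueError("iss must be >= 0")
        for region in AIS_REGIONS:
            score = self.ais.get(region, 0)
            if not 0 <= score <= 6:
                raise ValueError(f"AIS {region} score {score} outside [0, 6]")
        self.group = classify_time_of_injury(self.injury_clock_time)


def classify_time_of_injury(t: float) -> str:
    """Classify a clock time (minutes since midnight) as Day/Night/Neither.

    Windows are half-open [start, end): 17:00 itself is not Day and 05:00
    is not Night, so the three classes partition the 24-h dial.

    Raises
    ------
    ValueError
        If ``t`` is outside [0, 1440).
    """
    if not 0 <= t < MINUTES_PER_DAY:
        raise ValueError(f"clock time {t} outside [0, 1440)")
    if DAY_WINDOW[0] <= t < DAY_WINDOW[1]:
        return "Day"
    for start, end in NIGHT_WINDOWS:
        if start <= t < end:
            return "Night"
    return "Neither"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows index group, columns outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is all zero")


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p-value by hypergeometric enumeration.

    Uses the sum-of-small-probabilities convention: the p-value is the
    total probability, under fixed margins, of every table whose
    probability does not exceed that of the observed table (a relative
    tolerance of 1e-7 guards the comparison against floating-point noise).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # support of the (1,1) cell given the margins
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class MatchResult:
    """Outcome of 1:1 propensity matching between day and night cohorts."""

    pairs: list[tuple[str, str]]
    unmatched: list[str]
    match_distance: list[float]


def propensity_match(
    day: Iterable[PatientRecord],
    night: Iterable[PatientRecord],
    iss_min: int = 20,
    caliper_years: float = 10.0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on age within exact sex strata.

    Only patients with ``iss > iss_min`` are candidates.  Candidate pairs
    are ranked globally by absolute age difference, then absolute ISS
    difference, then patient ids; the best available pair is accepted
    repeatedly until no pair within ``caliper_years`` of age remains.
    Ranking on the pair (rather than iterating one side) makes the result
    symmetric in the two cohorts when ages are distinct.

    A logistic propensity model on (age, sex, ISS-filter) with sex matched
    exactly and ISS reduced to a hard filter degenerates to exactly this
    age-distance matching, which is why no fitted model is involved.
    """
    day = list(day)
    night = list(night)
    day_ids = {p.patient_id for p in day}
    if day_ids & {p.patient_id for p in night}:
        raise ValueError("day and night cohorts must be disjoint")
    if iss_min < 0:
        raise ValueError("iss_min must be >= 0")

    day_elig = [p for p in day if p.iss > iss_min]
    night_elig = [p for p in night if p.iss > iss_min]

    candidates = []
    for p in day_elig:
        for q in night_elig:
            if p.sex != q.sex:
                continue
            age_d = abs(p.age - q.age)
            if age_d > caliper_years:
                continue
            candidates.append((age_d, abs(p.iss - q.iss), p.patient_id, q.patient_id))
    candidates.sort()

    used_day: set[str] = set()
    used_night: set[str] = set()
    pairs: list[tuple[str, str]] = []
    dists: list[float] = []
    for age_d, _iss_d, pid, qid in candidates:
        if pid in used_day or qid in used_night:
            continue
        used_day.add(pid)
        used_night.add(qid)
        pairs.append((pid, qid))
        dists.append(age_d)

    order = np.argsort([p for p, _ in pairs], kind="stable")
    pairs = [pairs[i] for i in order]
    dists = [dists[i] for i in order]
    unmatched = sorted(
        [p.patient_id for p in day_elig if p.patient_id not in used_day]
        + [q.patient_id for q in night_elig if q.patient_id not in used_night]
    )
    return MatchResult(pairs=pairs, unmatched=unmatched, match_distance=dists)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / sqrt(n)).

    SEM is 0.0 for a constant sample and requires n >= 2 (NaN for n == 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty sample")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, float("nan")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return mean, sem


def percent(count: int, total: int) -> float:
    """``100 * count / total`` rounded half-up to one decimal (table style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cohort(records: Sequence[PatientRecord]):
    """Table-1-style cohort summary.

    Continuous variables (age, ISS, AIS regions, outcomes) are reported as
    mean +/- SEM; categorical variables (sex, mechanism, comorbidities,
    nosocomial infection) as n (%).  Returns a tidy DataFrame with columns
    ``variable, level, kind, n, mean, sem, count, percent``.
    """
    import pandas as pd

    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    rows = []

    def cont(name: str, values: Sequence[float]) -> None:
        m, s = mean_sem(values)
        rows.append(
            dict(variable=name, level="", kind="continuous", n=n, mean=m, sem=s,
                 count=np.nan, percent=np.nan)
        )

    def cat(name: str, level: str, count: int) -> None:
        rows.append(
            dict(variable=name, level=level, kind="categorical", n=n,
                 mean=np.nan, sem=np.nan, count=count, percent=percent(count, n))
        )

    cont("age", [p.age for p in records])
    cont("iss", [p.iss for p in records])
    for region in AIS_REGIONS:
        cont(f"ais_{region}", [p.ais.get(region, 0) for p in records])
    cont("vent_days", [p.vent_days for p in records])
    cont("icu_los_days", [p.icu_los_days for p in records])
    cont("hospital_los_days", [p.hospital_los_days for p in records])

    for sex in SEXES:
        cat("sex", sex, sum(p.sex == sex for p in records))
    for mech in MECHANISMS:
        cat("mechanism", mech, sum(p.mechanism == mech for p in records))
    comorbs = sorted({c for p in records for c in p.comorbidities})
    for c in comorbs:
        cat("comorbidity", c, sum(c in p.comorbidities for p in records))
    cat("comorbidity", "none", sum(not p.comorbidities for p in records))
    cat("nosocomial_infection", "yes", sum(p.nosocomial_infection for p in records))

    return pd.DataFrame(rows)
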