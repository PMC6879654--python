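"""Seeded synthetic cohorts with the study's longitudinal design.

The generator emulates the sampling scheme of the clinical study this
package analyzes: two injury-time groups (Day / Night), three draws in the
first 24 h (nominally 0, 8, 16 h post-injury) plus daily samples through
day 7, and a 32-analyte circulating inflammatory mediator panel measured
in pg/mL.

Mediator concentrations follow a log-normal model:

    value = exp(mu_m(t, group) + sigma * (L z)_m),   z ~ N(0, I)

where ``mu`` combines a per-mediator baseline with an exponentially
decaying post-injury elevation (peak at the first draw) and any active
group effects, and ``L`` is the Cholesky factor of a block correlation
matrix.  Values are truncated below at an assay floor of 0.01 pg/mL and
thinned by i.i.d. missingness.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    DAY_WINDOW,
    MECHANISMS,
    NIGHT_WINDOWS,
    AIS_REGIONS,
    PatientRecord,
)

#: The 32 circulating mediators of the assay panel.
MEDIATOR_PANEL = (
    "IL-1b", "IL-1Ra", "IL-2", "sIL-2Ra", "IL-4", "IL-5", "IL-6", "IL-7",
    "IL-8", "IL-10", "IL-13", "IL-15", "IL-17A", "IFN-g", "IP-10", "MIG",
    "MIP-1a", "MIP-1b", "MCP-1", "GM-CSF", "Eotaxin", "TNF-a", "IL-9",
    "IL-21", "IL-22", "IL-23", "IL-17E/25", "IL-33", "sST2", "NO2-/NO3-",
    "cortisol", "TGF-b1",
)

#: Nominal sampling grid, hours post-injury.
DEFAULT_SAMPLE_TIMES = (0.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)

ASSAY_FLOOR = 0.01  # pg/mL


@dataclass(frozen=True)
class GroupEffect:
    """A group-specific mean shift on the natural-log scale.

    Active for samples of ``group`` with ``onset_h <= t < offset_h``;
    ``log_fold_change`` adds to the log-mean (ln units), so 1.0 is an
    ~2.7-fold elevation.
    """

    mediator: str
    group: str
    onset_h: float
    offset_h: float
    log_fold_change: float

    def __post_init__(self) -> None:
        if not self.onset_h < self.offset_h:
            raise ValueError("onset_h must be < offset_h")
        if self.group not in ("Day", "Night"):
            raise ValueError("group must be Day or Night")

    def active(self, group: str, t: float) -> bool:
        return group == self.group and self.onset_h <= t < self.offset_h


@dataclass(frozen=True)
class CorrelationBlock:
    """A set of mediators sharing within-block noise correlation rho.

    ``group`` and the half-open time window restrict where the block
    applies; both default to everywhere (the matched-group comparison
    needs blocks that exist early in one group only).
    """

    mediators: tuple[str, ...]
    rho: float
    group: str | None = None
    start_h: float = -np.inf
    end_h: float = np.inf

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if len(set(self.mediators)) != len(self.mediators):
            raise ValueError("duplicate mediator within a block")

    def active(self, group: str, t: float) -> bool:
        return (self.group is None or group == self.group) and (
            self.start_h <= t < self.end_h
        )


@dataclass
class SyntheticConfig:
    """Full parameterization of a simulated cohort."""

    n_day: int = 15
    n_night: int = 15
    seed: int = 0
    mediator_names: tuple[str, ...] = MEDIATOR_PANEL
    sample_times_h: tuple[float, ...] = DEFAULT_SAMPLE_TIMES
    effects: tuple[GroupEffect, ...] = ()
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    noise_sigma_log: float = 0.8
    missing_rate: float = 0.02
    age_mean: float = 43.0
    age_sd: float = 15.0
    iss_mean: float = 24.0
    iss_sd: float = 4.0
    baseline_log_range: tuple[float, float] = (0.0, 7.0)
    peak_log_amplitude: float = 1.5
    decay_tau_h: float = 48.0

    def __post_init__(self) -> None:
        if min(self.n_day, self.n_night) < 1:
            raise ValueError("n_day and n_night must be >= 1")
        names = list(self.mediator_names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate mediator names in config")
        times = list(self.sample_times_h)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if self.noise_sigma_log <= 0:
            raise ValueError("noise_sigma_log must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for blk in self.correlation_blocks:
            unknown = set(blk.mediators) - set(names)
            if unknown:
                raise ValueError(f"correlation block names unknown: {unknown}")
        # a mediator may sit in at most one block applicable to the same
        # group and overlapping time range
        for i, b1 in enumerate(self.correlation_blocks):
            for b2 in self.correlation_blocks[i + 1:]:
                if set(b1.mediators) & set(b2.mediators):
                    groups_overlap = (
                        b1.group is None or b2.group is None or b1.group == b2.group
                    )
                    times_overlap = b1.start_h < b2.end_h and b2.start_h < b1.end_h
                    if groups_overlap and times_overlap:
                        raise ValueError(
                            "mediator shared by two overlapping correlation blocks"
                        )


def _draw_clock_time(rng: np.random.Generator, group: str) -> int:
    if group == "Day":
        return int(rng.integers(DAY_WINDOW[0], DAY_WINDOW[1]))
    # night window wraps midnight; draw from the union by length
    lengths = [end - start for start, end in NIGHT_WINDOWS]
    which = rng.choice(len(NIGHT_WINDOWS), p=np.array(lengths) / sum(lengths))
    start, end = NIGHT_WINDOWS[which]
    return int(rng.integers(start, end))


def _correlation_factor(
    config: SyntheticConfig, group: str, t: float
) -> np.ndarray:
    """Cholesky factor of the block correlation matrix active at (group, t)."""
    names = list(config.mediator_names)
    m = len(names)
    corr = np.eye(m)
    for blk in config.correlation_blocks:
        if not blk.active(group, t):
            continue
        idx = [names.index(x) for x in blk.mediators]
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = blk.rho
    return np.linalg.cholesky(corr)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate patient records and a long-format mediator sample table.

    Returns ``(patients, samples)`` where ``samples`` has columns
    ``patient_id, mediator, time_h, value_pg_ml``.  Byte-identical for
    identical config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.mediator_names)
    m = len(names)

    lo, hi = config.baseline_log_range
    baseline_log = rng.uniform(lo, hi, size=m)

    patients: list[PatientRecord] = []
    groups = ["Day"] * config.n_day + ["Night"] * config.n_night
    for i, group in enumerate(groups):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 95))
        iss = int(np.clip(round(rng.normal(config.iss_mean, config.iss_sd)), 0, 75))
        ais = {r: int(rng.integers(0, 5)) for r in AIS_REGIONS}
        icu = float(rng.lognormal(1.3, 0.8))
        patients.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                age=age,
                sex="male" if rng.random() < 0.733 else "female",
                iss=iss,
                ais=ais,
                injury_clock_time=_draw_clock_time(rng, group),
                mechanism=str(rng.choice(MECHANISMS, p=[0.6, 0.2, 0.13, 0.07])),
                comorbidities=set(),
                icu_los_days=icu,
                hospital_los_days=icu + float(rng.lognormal(1.5, 0.6)),
                vent_days=float(rng.lognormal(0.5, 1.0)),
                nosocomial_infection=bool(rng.random() < 0.23),
            )
        )

    # cache Cholesky factors: they depend only on (group, time)
    factors: dict[tuple[str, float], np.ndarray] = {}
    rows_pid: list[str] = []
    rows_med: list[str] = []
    rows_t: list[float] = []
    rows_val: list[float] = []
    for patient, group in zip(patients, groups):
        for t in config.sample_times_h:
            key = (group, t)
            if key not in factors:
                factors[key] = _correlation_factor(config, group, t)
            mu = baseline_log + config.peak_log_amplitude * np.exp(
                -t / config.decay_tau_h
            )
            for eff in config.effects:
                if eff.active(group, t):
                    mu[names.index(eff.mediator)] += eff.log_fold_change
            z = rng.standard_normal(m)
            log_vals = mu + config.noise_sigma_log * (factors[key] @ z)
            vals = np.maximum(np.exp(log_vals), ASSAY_FLOOR)
            keep = rng.random(m) >= config.missing_rate
            for j in np.nonzero(keep)[0]:
                rows_pid.append(patient.patient_id)
                rows_med.append(names[j])
                rows_t.append(t)
                rows_val.append(float(vals[j]))

    samples = pd.DataFrame(
        {
            "patient_id": rows_pid,
            "mediator": rows_med,
            "time_h": rows_t,
            "value_pg_ml": rows_val,
        }
    )
    return patients, samples


def generate_var1_panel(
    n_series: int,
    length: int,
    adjacency: np.ndarray,
    coef: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """First-order vector-autoregressive panel for network-recovery tests.

    Each of ``n_series`` independent subjects evolves as
    ``x_{t+1} = coef * A @ x_t + eps``, ``eps ~ N(0, noise_sd^2 I)``, with
    ``x_0 ~ N(0, I)``.  Row i of ``A`` lists the parents of variable i.
    Returns a long table (``patient_id, mediator, time_h, value_pg_ml``)
    with variables named V1..Vd and unit-spaced times 0..length-1; values
    are Gaussian (not concentrations) despite the shared column name.

    Raises
    ------
    ValueError
        If ``|coef| * max row sum of |A| >= 1`` (unstable process).
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if abs(coef) * np.abs(A).sum(axis=1).max() >= 1:
        raise ValueError("unstable VAR(1): |coef| * max row sum must be < 1")
    d = A.shape[0]
    rng = np.random.default_rng(seed)
    names = [f"V{i + 1}" for i in range(d)]

    frames = []
    for s in range(n_series):
        x = rng.standard_normal(d)
        traj = np.empty((length, d))
        traj[0] = x
        for t in range(1, length):
            x = coef * (A @ x) + noise_sd * rng.standard_normal(d)
            traj[t] = x
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(f"S{s + 1:03d}", length * d),
                    "mediator": np.tile(names, length),
                    "time_h": np.repeat(np.arange(length, dtype=float), d),
                    "value_pg_ml": traj.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
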