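"""End-to-end run driver: simulate/load -> match -> stats -> DyNA -> DyBN.

A run is fully described by a :class:`RunConfig` (loadable from YAML or
JSON); outputs land in one directory with a manifest recording the config
hash, package version and seed, so identical configs give identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import propensity_match, summarize_cohort
from .dybn import build_transitions, central_nodes, infer_structure
from .dyna import DEFAULT_THRESHOLD, DEFAULT_WINDOWS, density_trace
from .io import (
    read_measurements,
    read_patients,
    write_graphml,
    write_measurements,
    write_patients,
    write_sif,
)
from .mediator_stats import anova_screen
from .synthetic import CorrelationBlock, GroupEffect, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``patients_csv`` + ``measurements_csv`` or ``synthetic`` must
    be provided.  ``dybn_grid`` defaults to the sampling grid of the
    study design.
    """

    patients_csv: str | None = None
    measurements_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    iss_min: int = 20
    caliper_years: float = 10.0
    dyna_windows: tuple = DEFAULT_WINDOWS
    dyna_threshold: float = DEFAULT_THRESHOLD
    dyna_method: str = "pearson"
    dybn_grid: tuple = (0.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)
    dybn_fan_in: int = 3
    transform: str | None = "log10"
    seed: int = 0
    out_dir: str = "run_output"

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.patients_csv or not self.measurements_csv:
                raise ValueError(
                    "config needs either 'synthetic' or both 'patients_csv' "
                    "and 'measurements_csv'"
                )
            for name in ("patients_csv", "measurements_csv"):
                path = getattr(self, name)
                if not Path(path).exists():
                    raise ValueError(f"{name}: no such file {path}")
        wins = sorted(self.dyna_windows)
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ValueError("dyna windows must not overlap")


def _config_dict(config: RunConfig) -> dict:
    def unpack(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [unpack(v) for v in obj]
        if isinstance(obj, float) and not np.isfinite(obj):
            return str(obj)
        return obj

    return unpack(config)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    syn = raw.pop("synthetic", None)
    if syn is not None:
        effects = tuple(GroupEffect(**e) for e in syn.pop("effects", []))
        blocks = tuple(
            CorrelationBlock(mediators=tuple(b.pop("mediators")), **b)
            for b in syn.pop("correlation_blocks", [])
        )
        for key in ("mediator_names", "sample_times_h"):
            if key in syn:
                syn[key] = tuple(syn[key])
        raw["synthetic"] = SyntheticConfig(
            effects=effects, correlation_blocks=blocks, **syn
        )
    for key in ("dyna_windows", "dybn_grid"):
        if key in raw:
            raw[key] = tuple(tuple(w) if isinstance(w, list) else w for w in raw[key])
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Stage outputs: patients/measurements CSVs, match result, cohort
    summaries, per-mediator statistics, DyNA trace + networks, per-group
    DyBN edge posteriors and central-node rankings, a manifest and a
    short human-readable report.  A single mediator failing its ANOVA is
    logged, not fatal.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: data ---------------------------------------------------
    if config.synthetic is not None:
        patients, samples = generate_cohort(config.synthetic)
        write_patients(patients, out / "patients.csv")
        write_measurements(samples, out / "measurements.csv")
    else:
        patients = read_patients(config.patients_csv)
        samples = read_measurements(config.measurements_csv)

    # --- stage 2: cohorts and matching -----------------------------------
    day = [p for p in patients if p.group == "Day"]
    night = [p for p in patients if p.group == "Night"]
    match = propensity_match(day, night, config.iss_min, config.caliper_years)
    pd.DataFrame(
        {
            "day_patient_id": [a for a, _ in match.pairs],
            "night_patient_id": [b for _, b in match.pairs],
            "age_distance": match.match_distance,
        }
    ).to_csv(out / "match.csv", index=False)

    matched_ids = {pid for pair in match.pairs for pid in pair}
    by_id = {p.patient_id: p for p in patients}
    groups = {pid: by_id[pid].group for pid in matched_ids}
    matched_day = [by_id[a] for a, _ in match.pairs]
    matched_night = [by_id[b] for _, b in match.pairs]
    if matched_day:
        summarize_cohort(matched_day).to_csv(out / "summary_day.csv", index=False)
        summarize_cohort(matched_day).to_json(out / "summary_day.json",
                                              orient="records")
    if matched_night:
        summarize_cohort(matched_night).to_csv(out / "summary_night.csv", index=False)
        summarize_cohort(matched_night).to_json(out / "summary_night.json",
                                                orient="records")

    matched_samples = samples[samples["patient_id"].isin(matched_ids)]
    if matched_samples.empty:
        raise ValueError("stage stats: no measurements for matched patients")

    # --- stage 3: mediator statistics ------------------------------------
    stats = anova_screen(matched_samples, groups, transform=config.transform)
    stats.to_csv(out / "mediator_stats.csv", index=False)

    # --- stage 4: DyNA ----------------------------------------------------
    trace, nets = density_trace(
        matched_samples,
        groups,
        windows=config.dyna_windows,
        threshold=config.dyna_threshold,
        method=config.dyna_method,
        transform=config.transform,
    )
    trace.to_csv(out / "dyna_density.csv", index=False)
    for net in nets:
        stem = f"dyna_{net.group}_{net.window.start_h:g}-{net.window.end_h:g}h"
        write_sif(net, out / f"{stem}.sif")
        write_graphml(net, out / f"{stem}.graphml")

    # --- stage 5: DyBN ----------------------------------------------------
    central = {}
    for label, cohort_samples in (
        ("Day", matched_samples[matched_samples["patient_id"].map(groups) == "Day"]),
        ("Night", matched_samples[matched_samples["patient_id"].map(groups) == "Night"]),
    ):
        work = cohort_samples
        if config.transform == "log10":
            work = work.assign(value_pg_ml=np.log10(work["value_pg_ml"] + 0.01))
        try:
            data = build_transitions(work, config.dybn_grid)
            model = infer_structure(data, fan_in=config.dybn_fan_in)
        except ValueError as exc:
            logger.warning("DyBN skipped for %s: %s", label, exc)
            continue
        model.edge_table().to_csv(out / f"dybn_{label}_edges.csv", index=False)
        ranking = central_nodes(model, k=len(model.variables))
        pd.DataFrame(ranking, columns=["variable", "outgoing_posterior"]).to_csv(
            out / f"dybn_{label}_central.csv", index=False
        )
        logger.info(
            "DyBN %s: %d pairs, feedback nodes %s",
            label, model.n_pairs, model.feedback_nodes(),
        )
        central[label] = ranking[:5]

    # --- manifest and report ----------------------------------------------
    cfg = _config_dict(config)
    # the hash identifies the analysis, not where its files land
    hashed = {k: v for k, v in cfg.items() if k != "out_dir"}
    cfg_json = json.dumps(hashed, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
        "seed": config.seed,
        "n_patients": len(patients),
        "n_matched_pairs": len(match.pairs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = [
        f"traumanet {__version__} run (seed {config.seed})",
        f"patients: {len(patients)} ({len(day)} Day, {len(night)} Night)",
        f"matched pairs: {len(match.pairs)}",
        f"mediators screened: {len(stats)}",
        "density trace:",
        trace.to_string(index=False),
    ]
    for label, ranking in central.items():
        lines.append(
            f"DyBN {label} top central nodes: "
            + ", ".join(f"{v} ({s:.2f})" for v, s in ranking)
        )
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
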