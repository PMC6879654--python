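"""Dynamic Network Analysis (DyNA): windowed correlation networks.

Mediator networks are built per group in adjacent 8-h windows over the
first 24 h post-injury (0-8, 8-16, 16-24 h).  Within a window each
patient contributes one value per mediator (the mean of any repeats);
an edge joins two mediators when the across-patient correlation of their
values reaches a fixed threshold (0.7 by default, on |r| — inverse
co-regulation counts).  Network complexity per window is summarized by
the density statistic

    density = E * N / (N * (N - 1) / 2) = 2 E / (N - 1)

where N counts the mediators with evaluable data in the window, so the
statistic stays comparable across windows with missing assays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7
DEFAULT_WINDOWS = ((0.0, 8.0), (8.0, 16.0), (16.0, 24.0))


@dataclass(frozen=True)
class TimeWindow:
    """Half-open time interval [start_h, end_h), hours post-injury."""

    start_h: float
    end_h: float

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError("window start must precede end")

    def contains(self, t: float) -> bool:
        return self.start_h <= t < self.end_h


@dataclass
class CorrelationNetwork:
    """Thresholded mediator correlation graph for one group and window."""

    group: str
    window: TimeWindow
    nodes: tuple[str, ...]
    #: unordered mediator pair -> signed correlation
    edges: dict[frozenset, float]
    threshold: float
    method: str = "pearson"
    absolute: bool = True

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, r in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, r=r)
        return g

    def to_sif(self) -> str:
        lines = [f"{a}\tpp\t{b}" for a, b in sorted(tuple(sorted(p)) for p in self.edges)]
        return "\n".join(lines) + ("\n" if lines else "")


def window_values(samples: pd.DataFrame, window: TimeWindow) -> pd.DataFrame:
    """Patient x mediator value matrix for one window.

    Samples with ``window.start_h <= time_h < window.end_h`` are selected;
    repeats for the same (patient, mediator) are averaged.  Patients with
    no sample in the window are simply absent.
    """
    mask = (samples["time_h"] >= window.start_h) & (samples["time_h"] < window.end_h)
    sub = samples[mask]
    if sub.empty:
        return pd.DataFrame()
    return sub.pivot_table(
        index="patient_id", columns="mediator", values="value_pg_ml", aggfunc="mean"
    )


def build_network(
    values: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "pearson",
    absolute: bool = True,
    min_patients: int = 3,
    group: str = "",
    window: TimeWindow | None = None,
) -> CorrelationNetwork:
    """Threshold pairwise mediator correlations into a network.

    Correlations are computed across patients on pairwise-complete values
    (at least ``min_patients`` complete pairs per edge).  An edge is
    created when ``|r| >= threshold`` (or ``r >= threshold`` with
    ``absolute=False``); the signed r is stored either way.  Mediators
    that are constant across patients cannot be correlated; those pairs
    are skipped with a log message.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    window = window or TimeWindow(-np.inf, np.inf)

    if values.empty:
        return CorrelationNetwork(group, window, (), {}, threshold, method, absolute)

    evaluable = [
        c
        for c in values.columns
        if values[c].notna().sum() >= min_patients and values[c].nunique() > 1
    ]
    dropped = set(values.columns) - set(evaluable)
    if dropped:
        logger.info(
            "window [%s, %s) group %s: %d mediators not evaluable (constant or "
            "< %d values): %s",
            window.start_h, window.end_h, group, len(dropped), min_patients,
            sorted(dropped),
        )
    vals = values[evaluable]
    corr = vals.corr(method=method, min_periods=min_patients)

    edges: dict[frozenset, float] = {}
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                continue
            passes = abs(r) >= threshold if absolute else r >= threshold
            if passes:
                edges[frozenset((a, b))] = float(r)
    return CorrelationNetwork(
        group, window, tuple(evaluable), edges, threshold, method, absolute
    )


def network_density(net: CorrelationNetwork) -> float:
    """Density = E*N / (N choose 2) = 2E/(N-1); equals N for a complete graph."""
    n = len(net.nodes)
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    max_edges = n * (n - 1) / 2
    return net.n_edges * n / max_edges


def density_trace(
    samples: pd.DataFrame,
    groups: dict[str, str],
    windows=DEFAULT_WINDOWS,
    threshold: float = DEFAULT_THRESHOLD,
    method: str = "pearson",
    absolute: bool = True,
    transform: str | None = "log10",
    floor: float = 0.01,
    min_patients: int = 3,
) -> tuple[pd.DataFrame, list[CorrelationNetwork]]:
    """Per-group density across adjacent windows (the complexity trace).

    ``groups`` maps patient_id -> group label.  Concentrations are
    log10(x + floor)-transformed by default before correlating (a
    monotone map, so Spearman is unaffected; Pearson becomes a
    correlation of log-levels).  Returns a tidy trace table (columns
    ``group, window_start, window_end, n_nodes, n_edges, density``)
    ordered by group then window start, plus the networks themselves.
    """
    samples = samples.assign(group=samples["patient_id"].map(groups)).dropna(
        subset=["group"]
    )
    if transform == "log10":
        samples = samples.assign(
            value_pg_ml=np.log10(samples["value_pg_ml"] + floor)
        )
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    rows = []
    nets: list[CorrelationNetwork] = []
    for grp in sorted(samples["group"].unique()):
        per_group = samples[samples["group"] == grp]
        for start, end in sorted(windows):
            win = TimeWindow(start, end)
            vals = window_values(per_group, win)
            net = build_network(
                vals, threshold, method, absolute, min_patients, group=grp,
                window=win,
            )
            nets.append(net)
            n = len(net.nodes)
            rows.append(
                dict(
                    group=grp,
                    window_start=start,
                    window_end=end,
                    n_nodes=n,
                    n_edges=net.n_edges,
                    density=network_density(net) if n >= 2 else 0.0,
                )
            )
    return pd.DataFrame(rows), nets
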