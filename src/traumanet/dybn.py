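"""Dynamic Bayesian network structure inference over time-sliced panels.

The model is a first-order, homogeneous, linear-Gaussian DBN: every
mediator at time slice t+1 is conditioned on a bounded set of parent
mediators at slice t (self-edges allowed — they are the feedback motifs).
Because all edges run t -> t+1, the structure decomposes over children,
so for each child we *exhaustively* enumerate every parent set up to the
fan-in bound and score it; the per-child optima compose into the exact
global optimum with no search heuristics, and normalizing the scores
gives exact Bayesian model averaging under a uniform structure prior.

Score: Gaussian BIC for the least-squares regression of the standardized
child at t+1 on the standardized parents at t plus an intercept,

    score(S) = -n/2 * log(RSS/n) - (|S| + 2)/2 * log(n).

Transitions pool all consecutive occupied grid steps of every patient
into one Markov kernel regardless of step length (8 h early, 24 h late);
gaps in a patient's sampling break the chain rather than being imputed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12
DEFAULT_FAN_IN = 3


@dataclass
class TransitionDataset:
    """Paired (x_t, x_{t+1}) observations on a common variable set.

    ``x_now`` and ``x_next`` are (n_pairs, V) arrays of standardized
    values; ``mean`` / ``sd`` hold the per-variable standardization
    parameters (computed over both slices of the retained pairs).
    """

    variables: tuple[str, ...]
    x_now: np.ndarray
    x_next: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    pair_index: pd.DataFrame  # columns: patient_id, t_from, t_to

    @property
    def n_pairs(self) -> int:
        return self.x_now.shape[0]


def build_transitions(
    samples: pd.DataFrame,
    grid,
    tolerance_h: float = 2.0,
) -> TransitionDataset:
    """Snap samples to a time grid and collect consecutive-slot pairs.

    Each sample is assigned to the nearest grid level within
    ``tolerance_h`` (others are discarded); repeats in a slot are
    averaged.  For every patient, every pair of *consecutive occupied*
    grid slots contributes one observation — a missed draw breaks the
    chain (the 8h->24h pair is NOT formed when the 16h sample is absent).
    Pairs with any missing variable are dropped (complete case), constant
    variables are dropped with a warning, and the remaining columns are
    z-scored over the retained pairs.

    Raises
    ------
    ValueError
        If fewer than 3 pairs remain (unscorable).
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) < 2:
        raise ValueError("grid needs at least two levels")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    t = samples["time_h"].to_numpy(dtype=float)
    idx = np.argmin(np.abs(t[:, None] - grid[None, :]), axis=1)
    dist = np.abs(t - grid[idx])
    keep = dist <= tolerance_h
    snapped = samples.loc[keep].assign(slot=idx[keep])

    wide = snapped.pivot_table(
        index=["patient_id", "slot"], columns="mediator", values="value_pg_ml",
        aggfunc="mean",
    )
    variables = list(wide.columns)

    now_rows, next_rows, meta = [], [], []
    for pid, per_patient in wide.groupby(level="patient_id"):
        slots = per_patient.index.get_level_values("slot").to_numpy()
        order = np.argsort(slots)
        slots = slots[order]
        mat = per_patient.to_numpy()[order]
        for k in range(len(slots) - 1):
            if slots[k + 1] == slots[k] + 1:  # consecutive occupied slots only
                now_rows.append(mat[k])
                next_rows.append(mat[k + 1])
                meta.append((pid, grid[slots[k]], grid[slots[k + 1]]))

    if not now_rows:
        raise ValueError("no transition pairs on the grid")
    x_now = np.array(now_rows)
    x_next = np.array(next_rows)

    complete = ~np.isnan(x_now).any(axis=1) & ~np.isnan(x_next).any(axis=1)
    x_now, x_next = x_now[complete], x_next[complete]
    meta = [m for m, ok in zip(meta, complete) if ok]
    if x_now.shape[0] < 3:
        raise ValueError(f"only {x_now.shape[0]} complete transition pairs; need >= 3")

    stacked = np.vstack([x_now, x_next])
    sd = stacked.std(axis=0, ddof=0)
    constant = sd < np.sqrt(VARIANCE_FLOOR)
    if constant.any():
        names = [v for v, c in zip(variables, constant) if c]
        warnings.warn(f"dropping constant variables: {names}", stacklevel=2)
        keep_cols = ~constant
        x_now, x_next = x_now[:, keep_cols], x_next[:, keep_cols]
        variables = [v for v, c in zip(variables, constant) if not c]
        stacked = np.vstack([x_now, x_next])
        sd = stacked.std(axis=0, ddof=0)
    mean = stacked.mean(axis=0)

    x_now = (x_now - mean) / sd
    x_next = (x_next - mean) / sd
    return TransitionDataset(
        variables=tuple(variables),
        x_now=x_now,
        x_next=x_next,
        mean=mean,
        sd=sd,
        pair_index=pd.DataFrame(meta, columns=["patient_id", "t_from", "t_to"]),
    )


def _bic_from_rss(rss: float, n: int, n_parents: int) -> float:
    rss = max(rss, VARIANCE_FLOOR)
    return -n / 2 * np.log(rss / n) - (n_parents + 2) / 2 * np.log(n)


def score_parent_set(child: str, parents, data: TransitionDataset) -> float:
    """Gaussian BIC of regressing child_{t+1} on parents_t plus intercept.

    Higher is better.  Collinear parents fall through to the
    pseudo-inverse solution (least-norm coefficients) with a log message;
    an exact fit is guarded by a residual-variance floor of 1e-12.
    """
    parents = tuple(parents)
    var_idx = {v: i for i, v in enumerate(data.variables)}
    y = data.x_next[:, var_idx[child]]
    n = data.n_pairs
    X = np.column_stack(
        [np.ones(n)] + [data.x_now[:, var_idx[p]] for p in parents]
    )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.info("collinear parent set %s for %s; pseudo-inverse fit", parents, child)
    resid = y - X @ beta
    return float(_bic_from_rss(resid @ resid, n, len(parents)))


@dataclass
class ChildResult:
    """Exact model-averaging result for one child variable."""

    best_parents: tuple[str, ...]
    best_score: float
    #: parent -> posterior probability the parent is in the true set
    edge_posterior: dict[str, float]
    #: total posterior mass (normalization check; should be 1)
    posterior_mass: float


@dataclass
class DybnModel:
    """Inferred time-slice network: all edges run slice t -> slice t+1."""

    variables: tuple[str, ...]
    children: dict[str, ChildResult]
    fan_in: int
    n_pairs: int
    posterior_cutoff: float = 0.5

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(
                child=c,
                parent=p,
                posterior=post,
                best_set_member=p in res.best_parents,
            )
            for c, res in self.children.items()
            for p, post in res.edge_posterior.items()
        ]
        return pd.DataFrame(rows).sort_values(
            ["child", "parent"], ignore_index=True
        )

    def consensus_edges(self, cutoff: float | None = None) -> list[tuple[str, str]]:
        """Directed (parent, child) edges with posterior above the cutoff."""
        cutoff = self.posterior_cutoff if cutoff is None else cutoff
        return sorted(
            (p, c)
            for c, res in self.children.items()
            for p, post in res.edge_posterior.items()
            if post > cutoff
        )

    def feedback_nodes(self, cutoff: float | None = None) -> list[str]:
        """Variables with a confident self-edge (feedback motif)."""
        cutoff = self.posterior_cutoff if cutoff is None else cutoff
        return sorted(
            c for c, res in self.children.items()
            if res.edge_posterior.get(c, 0.0) > cutoff
        )


def infer_structure(
    data: TransitionDataset,
    fan_in: int = DEFAULT_FAN_IN,
    posterior_cutoff: float = 0.5,
) -> DybnModel:
    """Exact per-child enumeration of all parent sets up to ``fan_in``.

    For each child, every subset of the slice-t variables (including the
    child itself) with size <= fan_in is scored; the best set is the
    score argmax with ties broken toward the smaller set then
    lexicographically.  Parent-set posteriors are softmax-normalized
    scores (uniform structure prior); an edge's posterior is the mass of
    all sets containing that parent.
    """
    if fan_in < 0:
        raise ValueError("fan_in must be >= 0")
    V = len(data.variables)
    if fan_in > V:
        warnings.warn(f"fan_in {fan_in} capped at number of variables {V}",
                      stacklevel=2)
        fan_in = V
    n_sets = sum(_n_choose_k(V, k) for k in range(fan_in + 1))
    if n_sets > 1_000_000:
        raise ValueError(
            f"{n_sets} parent sets per child exceeds the enumeration budget"
        )

    n = data.n_pairs
    # Precompute Gram blocks of the design [1, X_t] once; every parent-set
    # regression then solves a tiny normal-equation subsystem.
    Z = np.column_stack([np.ones(n), data.x_now])
    G = Z.T @ Z
    H = Z.T @ data.x_next  # (V+1, V)
    yty = (data.x_next**2).sum(axis=0)

    parent_sets = [
        combo
        for k in range(fan_in + 1)
        for combo in itertools.combinations(range(V), k)
    ]
    set_cols = [np.array((0,) + tuple(i + 1 for i in s)) for s in parent_sets]

    children: dict[str, ChildResult] = {}
    for ci, child in enumerate(data.variables):
        scores = np.empty(len(parent_sets))
        for si, cols in enumerate(set_cols):
            Gs = G[np.ix_(cols, cols)]
            hs = H[cols, ci]
            try:
                beta = np.linalg.solve(Gs, hs)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Gs, hs, rcond=None)[0]
            rss = yty[ci] - beta @ hs
            scores[si] = _bic_from_rss(rss, n, len(cols) - 1)

        best = max(
            range(len(parent_sets)),
            key=lambda i: (scores[i], -len(parent_sets[i]),
                           tuple(-o for o in parent_sets[i])),
        )
        w = np.exp(scores - scores.max())
        w /= w.sum()
        edge_post = {v: 0.0 for v in data.variables}
        for s, wi in zip(parent_sets, w):
            for i in s:
                edge_post[data.variables[i]] += float(wi)
        children[child] = ChildResult(
            best_parents=tuple(data.variables[i] for i in parent_sets[best]),
            best_score=float(scores[best]),
            edge_posterior=edge_post,
            posterior_mass=float(w.sum()),
        )

    return DybnModel(
        variables=data.variables,
        children=children,
        fan_in=fan_in,
        n_pairs=n,
        posterior_cutoff=posterior_cutoff,
    )


def central_nodes(model: DybnModel, k: int) -> list[tuple[str, float]]:
    """Top-k variables by summed outgoing edge posterior (influence).

    Descending score; ties broken lexicographically.  ``k`` larger than
    the variable count returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out_mass = {v: 0.0 for v in model.variables}
    for res in model.children.values():
        for parent, post in res.edge_posterior.items():
            out_mass[parent] += post
    ranked = sorted(out_mass.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[: min(k, len(ranked))]


def _n_choose_k(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)
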