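"""Group x time statistics for mediator trajectories.

The central comparison is a fixed-effects two-way ANOVA (group, time,
interaction) on log10-transformed concentrations, computed by
design-matrix least squares with Type II sums of squares so unbalanced
cohorts (missed draws) are handled without reference-level choices.
Nonparametric confirmation (Mann-Whitney U) and Spearman correlation
round out the toolkit.  Repeated measures are treated as independent
observations — the same simplification as the desktop statistics package
the original analysis used — and this is a documented limitation, not an
oversight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import mean_sem

logger = logging.getLogger(__name__)

LOG_FLOOR = 0.01  # added before log10 so assay-floor zeros stay finite


@dataclass
class FactorResult:
    sum_sq: float
    df: int
    F: float
    p: float


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition: group, time, interaction, residual."""

    group: FactorResult
    time: FactorResult
    interaction: FactorResult
    residual_sum_sq: float
    residual_df: int


def _dummy(labels: np.ndarray) -> np.ndarray:
    """Full one-hot coding (overparameterized; RSS is coding-invariant)."""
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def two_way_anova(
    values,
    group,
    time,
    transform: str | None = "log10",
    floor: float = LOG_FLOOR,
    ss_type: int = 2,
    on_empty_cells: str = "error",
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction.

    Parameters
    ----------
    values, group, time
        Response and the two categorical factors, equal length.
    transform
        ``"log10"`` (default) applies ``log10(x + floor)``; ``None`` uses
        the raw response.
    ss_type
        2 (default) uses Type II sums of squares — each main effect is
        adjusted for the other, the interaction for both — which is
        well-defined for unbalanced data.  3 uses Type III via
        sum-to-zero contrasts.
    on_empty_cells
        ``"error"`` (default) rejects designs with empty group x time
        cells; ``"drop_interaction"`` fits main effects only.

    Raises
    ------
    ValueError
        If either factor has fewer than two levels, or empty cells are
        present and not permitted.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    t = np.asarray(time)
    if not (len(y) == len(g) == len(t)):
        raise ValueError("values, group and time must have equal length")
    if transform == "log10":
        y = np.log10(y + floor)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    g_levels = pd.unique(g)
    t_levels = pd.unique(t)
    if len(g_levels) < 2 or len(t_levels) < 2:
        raise ValueError("each factor needs at least two levels")

    cells = {(gi, ti) for gi, ti in zip(g, t)}
    full_grid = len(g_levels) * len(t_levels)
    drop_interaction = False
    if len(cells) < full_grid:
        if on_empty_cells == "drop_interaction":
            drop_interaction = True
        else:
            raise ValueError(
                f"{full_grid - len(cells)} empty group x time cells; pass "
                "on_empty_cells='drop_interaction' to fit main effects only"
            )

    G = _dummy(g)
    T = _dummy(t)
    ones = np.ones((len(y), 1))
    # row-wise product of one-hots = interaction one-hot
    I = (G[:, :, None] * T[:, None, :]).reshape(len(y), -1)

    if ss_type == 2:
        X_full = np.hstack([ones, G, T] + ([] if drop_interaction else [I]))
        rss_full, rank_full = _rss_rank(X_full, y)
        rss_gt, rank_gt = _rss_rank(np.hstack([ones, G, T]), y)
        rss_g, rank_g = _rss_rank(np.hstack([ones, G]), y)
        rss_t, rank_t = _rss_rank(np.hstack([ones, T]), y)

        ss_group = rss_t - rss_gt
        df_group = rank_gt - rank_t
        ss_time = rss_g - rss_gt
        df_time = rank_gt - rank_g
        ss_int = 0.0 if drop_interaction else rss_gt - rss_full
        df_int = 0 if drop_interaction else rank_full - rank_gt
    elif ss_type == 3:
        Gs = _sum_code(g, g_levels)
        Ts = _sum_code(t, t_levels)
        Is = (Gs[:, :, None] * Ts[:, None, :]).reshape(len(y), -1)
        blocks = [ones, Gs, Ts] + ([] if drop_interaction else [Is])
        X_full = np.hstack(blocks)
        rss_full, rank_full = _rss_rank(X_full, y)

        def drop(which: int) -> tuple[float, int]:
            kept = [b for k, b in enumerate(blocks) if k != which]
            rss, rank = _rss_rank(np.hstack(kept), y)
            return rss - rss_full, rank_full - rank

        ss_group, df_group = drop(1)
        ss_time, df_time = drop(2)
        if drop_interaction:
            ss_int, df_int = 0.0, 0
        else:
            ss_int, df_int = drop(3)
    else:
        raise ValueError("ss_type must be 2 or 3")

    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid
    # scale-relative zero: exactly cell-constant data leaves O(eps^2)
    # rounding residue in every sum of squares
    tiny = 1e-20 * max(1.0, float(y @ y))

    def factor(ss: float, df: int) -> FactorResult:
        ss = max(ss, 0.0)
        if df == 0 or ss <= tiny:
            return FactorResult(ss, df, 0.0, 1.0)
        if mse <= tiny:
            return FactorResult(ss, df, np.inf, 0.0)
        F = (ss / df) / mse
        return FactorResult(ss, df, float(F), float(sps.f.sf(F, df, df_resid)))

    return AnovaResult(
        group=factor(ss_group, df_group),
        time=factor(ss_time, df_time),
        interaction=factor(ss_int, df_int),
        residual_sum_sq=rss_full,
        residual_df=df_resid,
    )


def _sum_code(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) contrasts; last level is the negative base."""
    levels = list(levels)
    k = len(levels)
    out = np.zeros((len(labels), k - 1))
    for i, lab in enumerate(labels):
        j = levels.index(lab)
        if j < k - 1:
            out[i, j] = 1.0
        else:
            out[i, :] = -1.0
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with midranks; exact p for small tie-free samples.

    Returns ``(U_x, two-sided p)``.  The exact null enumeration is used
    when ``n_x * n_y <= 400`` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie and continuity
    corrections applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson on midranks, t-approximation p.

    Pairs with any missing value are dropped first.  A constant vector has
    no defined rank correlation and raises ``ValueError`` rather than
    propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def timecourse_table(
    samples: pd.DataFrame,
    mediator: str,
    groups: dict[str, str],
) -> pd.DataFrame:
    """Per-group, per-time mean +/- SEM for one mediator (figure-style).

    ``groups`` maps patient_id -> group label.  Output columns:
    ``group, time_h, n, mean, sem``, ordered by group then time.
    """
    sub = samples[samples["mediator"] == mediator]
    if sub.empty:
        raise ValueError(f"no samples for mediator {mediator!r}")
    sub = sub.assign(group=sub["patient_id"].map(groups)).dropna(subset=["group"])
    rows = []
    for (grp, t), chunk in sub.groupby(["group", "time_h"], sort=True):
        m, s = mean_sem(chunk["value_pg_ml"].to_numpy())
        rows.append(dict(group=grp, time_h=t, n=len(chunk), mean=m, sem=s))
    return pd.DataFrame(rows).sort_values(["group", "time_h"], ignore_index=True)


def anova_screen(
    samples: pd.DataFrame,
    groups: dict[str, str],
    transform: str | None = "log10",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Run the two-way ANOVA plus Mann-Whitney confirmation per mediator.

    Returns one row per mediator: F/p for group, time and interaction, and
    ``mw_p`` — the smallest per-time-point Mann-Whitney p across time
    points with both groups represented (the nonparametric confirmation of
    a group difference).  ``adjust="bh"`` appends Benjamini-Hochberg
    adjusted group p-values; by default p-values are reported per mediator
    without multiplicity adjustment.  Mediators whose ANOVA fails (e.g. a
    single represented level) are logged and skipped.
    """
    sub = samples.assign(group=samples["patient_id"].map(groups)).dropna(
        subset=["group"]
    )
    rows = []
    for med, chunk in sub.groupby("mediator", sort=True):
        try:
            res = two_way_anova(
                chunk["value_pg_ml"].to_numpy(),
                chunk["group"].to_numpy(),
                chunk["time_h"].to_numpy(),
                transform=transform,
            )
        except ValueError as exc:
            logger.warning("ANOVA skipped for %s: %s", med, exc)
            continue
        mw_ps = []
        for t, at_t in chunk.groupby("time_h"):
            by_group = {g: v["value_pg_ml"].to_numpy() for g, v in at_t.groupby("group")}
            if len(by_group) == 2 and all(len(v) > 0 for v in by_group.values()):
                vals = list(by_group.values())
                mw_ps.append(mann_whitney_u(vals[0], vals[1])[1])
        rows.append(
            dict(
                mediator=med,
                F_group=res.group.F, p_group=res.group.p,
                F_time=res.time.F, p_time=res.time.p,
                F_int=res.interaction.F, p_int=res.interaction.p,
                mw_p=min(mw_ps) if mw_ps else np.nan,
            )
        )
    out = pd.DataFrame(rows)
    if adjust == "bh" and not out.empty:
        out["p_group_bh"] = _benjamini_hochberg(out["p_group"].to_numpy())
    elif adjust not in (None, "bh"):
        raise ValueError("adjust must be None or 'bh'")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj
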