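"""DyBN inference: transition building, scoring, exact enumeration, recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

import traumanet as tn
from traumanet.dybn import (
    TransitionDataset,
    build_transitions,
    central_nodes,
    infer_structure,
    score_parent_set,
)


def long_samples(records):
    """records: (patient, mediator, time, value) tuples."""
    return pd.DataFrame(
        records, columns=["patient_id", "mediator", "time_h", "value_pg_ml"]
    )


def naive_score(y, X_parents, n):
    """Oracle BIC via an independent per-regression least squares."""
    X = np.column_stack([np.ones(n)] + list(X_parents))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = max(float(((y - X @ beta) ** 2).sum()), 1e-12)
    k = X.shape[1] - 1
    return -n / 2 * np.log(rss / n) - (k + 2) / 2 * np.log(n)


def brute_force_model(data: TransitionDataset, fan_in: int):
    """Oracle: re-enumerate every parent set with naive regressions."""
    V = len(data.variables)
    out = {}
    for ci, child in enumerate(data.variables):
        y = data.x_next[:, ci]
        sets, scores = [], []
        for k in range(fan_in + 1):
            for combo in itertools.combinations(range(V), k):
                sets.append(combo)
                scores.append(
                    naive_score(y, [data.x_now[:, j] for j in combo], data.n_pairs)
                )
        scores = np.array(scores)
        w = np.exp(scores - scores.max())
        w /= w.sum()
        posts = {v: 0.0 for v in data.variables}
        for s, wi in zip(sets, w):
            for j in s:
                posts[data.variables[j]] += wi
        best = max(range(len(sets)),
                   key=lambda i: (scores[i], -len(sets[i]),
                                  tuple(-o for o in sets[i])))
        out[child] = (tuple(data.variables[j] for j in sets[best]), posts)
    return out


class TestBuildTransitions:
    def grid(self):
        return (0.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0)

    def test_full_sampling_gives_nine_pairs(self):
        recs = [("p1", m, t, 1.0 + i + t / 100)
                for i, m in enumerate(["A", "B", "C"])
                for t in self.grid()]
        # add a second patient with distinct values so nothing is constant
        recs += [("p2", m, t, 2.0 + 2 * i - t / 50)
                 for i, m in enumerate(["A", "B", "C"])
                 for t in self.grid()]
        data = build_transitions(long_samples(recs), self.grid())
        assert data.n_pairs == 18

    def test_gap_breaks_the_chain(self):
        times = [t for t in self.grid() if t != 16.0]
        recs = [(p, m, t, v + t / 100)
                for p, v in [("p1", 1.0), ("p2", 5.0), ("p3", -2.0)]
                for m, dv in [("A", 0.0), ("B", 1.0)]
                for t, v2 in [(t, v + dv) for t in times]
                for v in [v2]]
        data = build_transitions(long_samples(recs), self.grid())
        formed = set(zip(data.pair_index.t_from, data.pair_index.t_to))
        assert (8.0, 16.0) not in formed
        assert (16.0, 24.0) not in formed
        assert (8.0, 24.0) not in formed  # gaps are not bridged
        assert (0.0, 8.0) in formed and (24.0, 48.0) in formed

    def test_constant_variable_dropped_with_warning(self):
        recs = []
        for p, v in [("p1", 1.0), ("p2", 3.0), ("p3", 7.0)]:
            for t in (0.0, 8.0, 16.0):
                recs.append((p, "A", t, v + t))
                recs.append((p, "K", t, 42.0))
        with pytest.warns(UserWarning, match="constant"):
            data = build_transitions(long_samples(recs), (0.0, 8.0, 16.0))
        assert data.variables == ("A",)

    def test_standardization(self):
        recs = [(p, m, t, np.sin(hash((p, m)) % 10 + t))
                for p in ("p1", "p2", "p3", "p4")
                for m in ("A", "B")
                for t in (0.0, 8.0, 16.0)]
        data = build_transitions(long_samples(recs), (0.0, 8.0, 16.0))
        stacked = np.vstack([data.x_now, data.x_next])
        assert np.allclose(stacked.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(stacked.std(axis=0), 1, atol=1e-9)

    def test_snapping_tolerance(self):
        # 17.9 snaps to 16 (within 2 h); 20.5 is discarded
        recs = [("p1", "A", t, float(i))
                for i, t in enumerate([0.0, 8.0, 17.9])]
        recs += [("p1", "B", t, float(3 - i))
                 for i, t in enumerate([0.0, 8.0, 20.5])]
        recs += [("p2", "A", t, float(i) * 2) for i, t in enumerate([0.0, 8.0, 16.0])]
        recs += [("p2", "B", t, 5.0 - i) for i, t in enumerate([0.0, 8.0, 16.0])]
        data = build_transitions(long_samples(recs), (0.0, 8.0, 16.0, 24.0))
        # p1 B at 16h missing -> complete-case drops p1's (8,16) pair
        formed = set(
            zip(data.pair_index.patient_id, data.pair_index.t_from,
                data.pair_index.t_to)
        )
        assert ("p2", 8.0, 16.0) in formed
        assert ("p1", 8.0, 16.0) not in formed

    def test_too_few_pairs_rejected(self):
        recs = [("p1", "A", 0.0, 1.0), ("p1", "A", 8.0, 2.0)]
        with pytest.raises(ValueError):
            build_transitions(long_samples(recs), (0.0, 8.0))


def make_dataset(rng, n=30, V=3):
    x_now = rng.standard_normal((n, V))
    x_next = rng.standard_normal((n, V))
    stacked = np.vstack([x_now, x_next])
    mean, sd = stacked.mean(0), stacked.std(0)
    return TransitionDataset(
        variables=tuple(f"V{i+1}" for i in range(V)),
        x_now=(x_now - mean) / sd,
        x_next=(x_next - mean) / sd,
        mean=mean,
        sd=sd,
        pair_index=pd.DataFrame({"patient_id": ["p"] * n,
                                 "t_from": 0.0, "t_to": 1.0}),
    )


class TestScoreParentSet:
    def test_empty_set_is_intercept_only_bic(self, rng):
        data = make_dataset(rng)
        y = data.x_next[:, 0]
        n = data.n_pairs
        rss = float(((y - y.mean()) ** 2).sum())
        expected = -n / 2 * np.log(rss / n) - 2 / 2 * np.log(n)
        assert score_parent_set("V1", (), data) == pytest.approx(expected)

    def test_irrelevant_parent_outscored_by_empty_set(self):
        rng = np.random.default_rng(42)
        n = 500
        x_now = rng.standard_normal((n, 2))
        x_next = rng.standard_normal((n, 2))
        data = TransitionDataset(
            variables=("V1", "V2"), x_now=x_now, x_next=x_next,
            mean=np.zeros(2), sd=np.ones(2),
            pair_index=pd.DataFrame({"patient_id": ["p"] * n,
                                     "t_from": 0.0, "t_to": 1.0}),
        )
        assert score_parent_set("V1", (), data) > score_parent_set(
            "V1", ("V2",), data
        )

    def test_exact_linear_parent_beats_empty_set(self, rng):
        n = 20
        x_now = rng.standard_normal((n, 2))
        x_next = np.column_stack([2 * x_now[:, 1], rng.standard_normal(n)])
        data = TransitionDataset(
            variables=("V1", "V2"), x_now=x_now, x_next=x_next,
            mean=np.zeros(2), sd=np.ones(2),
            pair_index=pd.DataFrame({"patient_id": ["p"] * n,
                                     "t_from": 0.0, "t_to": 1.0}),
        )
        # noise-free fit hits the variance floor but must still win
        assert score_parent_set("V1", ("V2",), data) > score_parent_set(
            "V1", (), data
        )


class TestInferStructure:
    @pytest.mark.parametrize("V,fan_in", [(3, 2), (4, 2), (5, 2), (5, 1)])
    def test_equals_brute_force_oracle(self, V, fan_in, rng):
        data = make_dataset(rng, n=25, V=V)
        model = infer_structure(data, fan_in=fan_in)
        oracle = brute_force_model(data, fan_in)
        for child in data.variables:
            best, posts = oracle[child]
            res = model.children[child]
            assert res.best_parents == best
            for v in data.variables:
                assert res.edge_posterior[v] == pytest.approx(posts[v], abs=1e-9)

    def test_posteriors_normalized(self, rng):
        data = make_dataset(rng, n=40, V=4)
        model = infer_structure(data, fan_in=2)
        for res in model.children.values():
            assert res.posterior_mass == pytest.approx(1.0, abs=1e-9)
            assert all(0 <= p <= 1 + 1e-12 for p in res.edge_posterior.values())

    def test_identity_var1_recovers_self_edges_as_feedback(self):
        panel = tn.generate_var1_panel(20, 10, np.eye(3), coef=0.9,
                                       noise_sd=0.4, seed=21)
        data = build_transitions(panel, grid=range(10), tolerance_h=0.1)
        model = infer_structure(data, fan_in=2)
        for v in data.variables:
            assert model.children[v].best_parents == (v,)
        assert model.feedback_nodes() == list(data.variables)

    def test_pure_noise_yields_sparse_consensus(self):
        false_rates = []
        for seed in range(20):
            panel = tn.generate_var1_panel(50, 11, np.zeros((5, 5)), 0.0, 1.0,
                                           seed=seed)
            data = build_transitions(panel, grid=range(11), tolerance_h=0.1)
            model = infer_structure(data, fan_in=2)
            false_rates.append(len(model.consensus_edges(0.5)) / 25)
        assert np.mean(false_rates) <= 0.05

    def test_score_invariant_to_affine_rescaling(self):
        panel = tn.generate_var1_panel(10, 8, np.eye(2), 0.5, 1.0, seed=3)
        scaled = panel.assign(
            value_pg_ml=np.where(panel.mediator == "V1",
                                 panel.value_pg_ml * 37 - 4, panel.value_pg_ml)
        )
        d1 = build_transitions(panel, grid=range(8), tolerance_h=0.1)
        d2 = build_transitions(scaled, grid=range(8), tolerance_h=0.1)
        for child in d1.variables:
            for parents in [(), ("V1",), ("V1", "V2")]:
                assert score_parent_set(child, parents, d1) == pytest.approx(
                    score_parent_set(child, parents, d2), rel=1e-9
                )

    def test_fan_in_capped_with_warning(self, rng):
        data = make_dataset(rng, n=20, V=3)
        with pytest.warns(UserWarning, match="capped"):
            model = infer_structure(data, fan_in=10)
        assert model.fan_in == 3


class TestCentralNodes:
    def test_hub_ranked_first(self):
        # V1 drives every variable; others are noise
        A = np.zeros((4, 4))
        A[:, 0] = 0.9
        panel = tn.generate_var1_panel(40, 10, A, coef=0.5, noise_sd=1.0, seed=17)
        data = build_transitions(panel, grid=range(10), tolerance_h=0.1)
        model = infer_structure(data, fan_in=2)
        assert central_nodes(model, 1)[0][0] == "V1"

    def test_k_larger_than_v_returns_all(self, rng):
        data = make_dataset(rng, n=20, V=3)
        model = infer_structure(data, fan_in=1)
        assert len(central_nodes(model, 10)) == 3

    def test_ties_broken_lexicographically(self, rng):
        data = make_dataset(rng, n=20, V=3)
        model = infer_structure(data, fan_in=1)
        ranked = central_nodes(model, 3)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
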