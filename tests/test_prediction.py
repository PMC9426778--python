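import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskeye.errors import AnalysisError
from whiskeye.stats_nonparametric import mann_whitney_u
from whiskeye.synthetic_data import GeneratorConfig, generate_session
from whiskeye.turn_prediction import (
    backward_epoch_predictors,
    bin_points,
    bin_predictors,
    contribution_analysis,
    fit_separator,
    roc_analysis,
    roc_curve,
)


def labels_of(y):
    return ["left" if v else "right" for v in y]


class TestRocCurve:
    def test_perfect_separation(self):
        _, _, auc = roc_curve([0.8, 0.6, -0.5, -0.7], ["left", "left", "right", "right"])
        assert auc == 1.0

    def test_chance_with_independent_labels(self, rng):
        v = rng.normal(0, 1, 4000)
        y = labels_of(rng.random(4000) < 0.5)
        _, _, auc = roc_curve(v, y)
        assert abs(auc - 0.5) < 0.05

    def test_curve_monotone_from_origin_to_corner(self, rng):
        v = rng.normal(0, 1, 50)
        y = labels_of(rng.random(50) < 0.4)
        fpr, tpr, _ = roc_curve(v, y)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_curve([1.0, 2.0], ["left", "left"])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_auc_equals_u_statistic(self, data):
        # brute-force pairwise-comparison oracle, shared with the U test
        n1 = data.draw(st.integers(1, 10))
        n2 = data.draw(st.integers(1, 10))
        x = data.draw(st.lists(st.integers(-5, 5), min_size=n1, max_size=n1))
        y = data.draw(st.lists(st.integers(-5, 5), min_size=n2, max_size=n2))
        values = list(map(float, x + y))
        labels = ["left"] * n1 + ["right"] * n2
        _, _, auc = roc_curve(values, labels)
        u = mann_whitney_u(x, y).statistic
        assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)


class TestBinning:
    def test_ramp_bin_means(self):
        n = 500
        ramp = np.linspace(0, 100, n)
        epochs = [{"asym": ramp, "eye": np.zeros(n), "label": "left"}]
        table = bin_predictors(epochs)
        means = [table.values("asym", b)[0] for b in range(5)]
        assert means == pytest.approx([10, 30, 50, 70, 90], abs=1.0)

    def test_row_count_equals_epoch_count(self):
        epochs = [
            {"asym": np.zeros(40), "eye": np.zeros(40), "label": d}
            for d in ("left", "right", "left")
        ]
        assert len(bin_predictors(epochs).table) == 3

    def test_missing_eye_gives_nan_not_row_drop(self):
        epochs = [
            {"asym": np.zeros(40), "eye": np.full(40, np.nan), "label": "left"},
            {"asym": np.zeros(40), "eye": np.zeros(40), "label": "right"},
        ]
        table = bin_predictors(epochs)
        assert len(table.table) == 2
        assert np.isnan(table.values("eye", 0)[0])
        assert np.isfinite(table.values("asym", 0)).all()

    def test_bin_points_pools_timepoints(self):
        epochs = [{"asym": np.arange(10.0), "eye": np.arange(10.0), "label": "left"}]
        pts = bin_points(epochs)
        assert sum(len(b["points"]) for b in pts) == 10


class TestSeparator:
    def test_separable_clusters_fidelity_one(self, rng):
        a = rng.normal((3, 3), 0.5, (50, 2))
        b = rng.normal((-3, -3), 0.5, (50, 2))
        pts = np.vstack([a, b])
        labels = ["left"] * 50 + ["right"] * 50
        sep = fit_separator(pts, labels, seed=0)
        assert sep.fidelity == 1.0

    def test_duplicated_points_both_labels_fidelity_half(self, rng):
        pts = rng.normal(0, 1, (50, 2))
        doubled = np.vstack([pts, pts])
        labels = ["left"] * 50 + ["right"] * 50
        sep = fit_separator(doubled, labels, seed=0)
        assert sep.fidelity == 0.5

    def test_fidelity_at_least_majority(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(3, 30, 2)
            pts = rng.normal(0, 1, (n1 + n2, 2))
            labels = ["left"] * n1 + ["right"] * n2
            sep = fit_separator(pts, labels, seed=1)
            assert sep.fidelity >= max(n1, n2) / (n1 + n2) - 1e-12

    def test_deterministic(self, rng):
        pts = rng.normal(0, 1, (40, 2))
        labels = labels_of(rng.random(40) < 0.5)
        a = fit_separator(pts, labels, seed=7)
        b = fit_separator(pts, labels, seed=7)
        assert a == b

    def test_predict_matches_fidelity(self, rng):
        pts = np.vstack([rng.normal((2, 2), 1, (20, 2)), rng.normal((-2, -2), 1, (20, 2))])
        labels = np.array(["left"] * 20 + ["right"] * 20, dtype=object)
        sep = fit_separator(pts, labels, seed=0)
        if sep.method != "majority":
            pred = sep.predict(pts)
            acc = np.mean(pred == labels)
            assert max(acc, 1 - acc) == pytest.approx(sep.fidelity)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            fit_separator(np.zeros((4, 2)), ["left"] * 4, seed=0)


def synthetic_bin_points(rng, n=60, signal=("asym",), balance=True):
    """Per-bin 2D point sets with controllable signal carriers."""
    out = []
    for _ in range(5):
        y = np.array([1] * (n // 2) + [0] * (n - n // 2)) if balance else (rng.random(n) < 0.5).astype(int)
        pts = rng.normal(0, 1, (n, 2))
        shift = np.where(y == 1, 2.5, -2.5)
        if "asym" in signal:
            pts[:, 0] += shift
        if "eye" in signal:
            pts[:, 1] += shift
        out.append({"points": pts, "labels": np.array(labels_of(y), dtype=object)})
    return out


class TestContribution:
    def test_duplicated_signal_is_redundant(self, rng):
        # both columns carry identical information: shuffling one leaves the
        # other intact, so no significant fidelity drop
        bins = []
        for _ in range(5):
            y = np.array([1] * 30 + [0] * 30)
            sig = np.where(y == 1, 2.5, -2.5) + rng.normal(0, 0.5, 60)
            pts = np.c_[sig, sig]
            bins.append({"points": pts, "labels": np.array(labels_of(y), dtype=object)})
        res = contribution_analysis(bins, n_shuffles=30, seed=0)
        for p in ("asym", "eye"):
            for b in range(5):
                assert res.partial_vs_full[p][b].p_value > 0.05
                assert abs(res.contribution[p][b]) < 0.05
        # but the full model beats the null
        assert all(t.p_value < 0.05 for t in res.vs_null)

    def test_whisker_only_signal(self, rng):
        bins = synthetic_bin_points(rng, signal=("asym",))
        res = contribution_analysis(bins, n_shuffles=30, seed=0)
        for b in range(5):
            # shuffling the carrier drops fidelity to null level
            assert res.partial_vs_full["asym"][b].p_value < 0.05
            assert np.median(res.partial["asym"][b]) == pytest.approx(
                np.median(res.null[b]), abs=0.1
            )
            # shuffling the informationless column does not
            assert res.partial_vs_full["eye"][b].p_value > 0.05

    def test_null_median_half_for_balanced_labels(self, rng):
        # a linear fit can overfit small shuffled samples, so the null
        # fidelity approaches 0.5 from above as n grows
        bins = synthetic_bin_points(rng, n=400, signal=())
        res = contribution_analysis(bins[:2], n_shuffles=30, seed=0)
        for b in range(2):
            assert np.median(res.null[b]) == pytest.approx(0.5, abs=0.07)


@pytest.fixture(scope="module")
def session_tables():
    tables = []
    for seed in range(6):
        cfg = GeneratorConfig(n_trials=10, seed=100 + seed)
        session, _ = generate_session(cfg)
        epochs = backward_epoch_predictors(session)
        if len({e["label"] for e in epochs}) == 2:
            tables.append(bin_predictors(epochs))
    return tables


class TestRocAnalysis:
    def test_real_beats_null_with_default_effects(self, session_tables):
        res = roc_analysis(session_tables, n_shuffles=100, seed=0)
        assert res.vs_null["asym"][4].p_value < 0.05
        med_real = np.nanmedian(res.auc["asym"][:, 4])
        med_null = np.nanmedian(res.null_auc["asym"][:, 4])
        assert med_real > med_null

    def test_shuffled_median_near_half(self, session_tables):
        res = roc_analysis(session_tables[:2], n_shuffles=1000, seed=1)
        med = np.nanmedian(res.null_distribution["asym"][0, 4, :])
        assert abs(med - 0.5) < 0.05

    def test_label_permutation_invariance_of_null(self, session_tables):
        # relabeling left<->right with value negation leaves the null
        # distribution unchanged (same seed)
        table = session_tables[0]
        flipped = table.table.copy()
        for col in flipped.columns:
            if col[0] in ("asym", "eye"):
                flipped[col] = -flipped[col]
        flipped[("label", "")] = [
            "right" if l == "left" else "left" for l in table.labels
        ]
        from whiskeye.turn_prediction import BinnedPredictorTable

        res_a = roc_analysis([table], n_shuffles=200, seed=5)
        res_b = roc_analysis([BinnedPredictorTable(flipped)], n_shuffles=200, seed=5)
        a = np.sort(res_a.null_distribution["asym"][0, 4, :])
        b = np.sort(res_b.null_distribution["asym"][0, 4, :])
        assert np.allclose(a, b)

    def test_late_ramp_recovery(self):
        # ramp confined to the last 40% of backward: early bins chance,
        # final bin near-perfect
        aucs = []
        for seed in range(8):
            cfg = GeneratorConfig(
                n_trials=10,
                seed=200 + seed,
                asymmetry_ramp=0.4,
                couple_saccades=False,
            )
            session, _ = generate_session(cfg)
            epochs = backward_epoch_predictors(session)
            if len({e["label"] for e in epochs}) < 2:
                continue
            table = bin_predictors(epochs)
            aucs.append(
                [roc_curve(table.values("asym", b), table.labels)[2] for b in range(5)]
            )
        med = np.median(np.asarray(aucs), axis=0)
        assert abs(med[0] - 0.5) < 0.15
        assert abs(med[1] - 0.5) < 0.15
        assert med[4] > 0.9
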