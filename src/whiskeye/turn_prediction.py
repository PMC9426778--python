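"""Prediction of upcoming turn direction from backward-movement behavior.

Two complementary analyses over five normalized-time bins of the backward
epoch:

* per-bin ROC/AUC for each single predictor (whisker asymmetry as
  right-minus-left protraction; eye position leftward-positive), with
  within-session label-shuffled nulls, and
* a two-variable linear-separation fidelity with shuffle-based unique
  contributions of each predictor.

The left turn is the positive class throughout, so raw (direction-unsigned)
predictors are expected to be high on left-turn epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Perceptron

from . import kinematics
from .errors import AnalysisError
from .io_formats import SessionRecord
from .stats_nonparametric import TestResult, bonferroni, kruskal_wallis, mann_whitney_u

__all__ = [
    "BinnedPredictorTable",
    "RocResult",
    "LinearSeparator",
    "FidelityResult",
    "backward_epoch_predictors",
    "bin_predictors",
    "bin_points",
    "roc_curve",
    "roc_analysis",
    "fit_separator",
    "contribution_analysis",
]

N_BINS = 5


# ---------------------------------------------------------------------------
# predictor extraction and binning


def backward_epoch_predictors(session: SessionRecord) -> list[dict]:
    """Per backward epoch: raw predictor traces on the eye clock plus label.

    Whisker asymmetry is right-minus-left normalized protraction (percent
    of trial range), downsampled to the eye clock by block averaging; eye
    position is the two-eye mean head-centered deviation (leftward
    positive, percent of eye width).
    """
    factor = session.clock_factor
    bounds = [(t.start_frame, t.end_frame) for t in session.trials]
    w_left = kinematics.normalize_whisker(session.whisker_traces["left"], bounds)
    w_right = kinematics.normalize_whisker(session.whisker_traces["right"], bounds)
    asym_raw = w_right.values - w_left.values  # positive expected on left turns
    hc_left = kinematics.to_head_centered(session.pupil_traces["left"], "left")
    hc_right = kinematics.to_head_centered(session.pupil_traces["right"], "right")
    eye_raw = (hc_left + hc_right) / 2.0
    epochs = []
    for trial in session.trials:
        ep = trial.epoch("backward")
        if ep is None:
            continue
        _, start, end = ep
        asym = kinematics.downsample_to_eye_clock(asym_raw[start:end], factor)
        eye = eye_raw[start // factor : end // factor]
        epochs.append({"asym": asym, "eye": eye, "label": trial.cued_direction})
    return epochs


@dataclass
class BinnedPredictorTable:
    """One row per backward epoch; per-bin means of each signed raw predictor."""

    table: pd.DataFrame  # columns: MultiIndex (predictor, bin) plus ('label', '')
    n_bins: int = N_BINS

    @property
    def labels(self) -> np.ndarray:
        return self.table[("label", "")].to_numpy()

    def values(self, predictor: str, b: int) -> np.ndarray:
        return self.table[(predictor, b)].to_numpy(dtype=float)


def _bin_slices(n: int, n_bins: int):
    """Partition normalized epoch time [0, 1] into equal bins by sample."""
    u = (np.arange(n) + 0.5) / n
    return [np.nonzero((u >= b / n_bins) & (u < (b + 1) / n_bins))[0] for b in range(n_bins)]


def bin_predictors(epochs: list[dict], n_bins: int = N_BINS) -> BinnedPredictorTable:
    """Per-epoch per-bin means of each raw predictor; one row per epoch."""
    rows = []
    for ep in epochs:
        row = {}
        for name in ("asym", "eye"):
            v = np.asarray(ep[name], dtype=float)
            for b, idx in enumerate(_bin_slices(len(v), n_bins)):
                vals = v[idx]
                has_data = len(vals) > 0 and bool(np.isfinite(vals).any())
                row[(name, b)] = float(np.nanmean(vals)) if has_data else np.nan
        row[("label", "")] = ep["label"]
        rows.append(row)
    if not rows:
        raise AnalysisError("no backward epochs to bin")
    df = pd.DataFrame(rows)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return BinnedPredictorTable(df, n_bins)


def bin_points(epochs: list[dict], n_bins: int = N_BINS) -> list[dict]:
    """Per-bin pooled individual time points (for the separator analysis).

    Returns one dict per bin: points (n, 2) with columns (asym, eye) and
    labels (n,).  The two predictor streams are paired on the eye clock.
    """
    out = [{"points": [], "labels": []} for _ in range(n_bins)]
    for ep in epochs:
        a = np.asarray(ep["asym"], dtype=float)
        e = np.asarray(ep["eye"], dtype=float)
        n = min(len(a), len(e))
        for b, idx in enumerate(_bin_slices(n, n_bins)):
            for i in idx:
                if np.isfinite(a[i]) and np.isfinite(e[i]):
                    out[b]["points"].append((a[i], e[i]))
                    out[b]["labels"].append(ep["label"])
    for b in range(n_bins):
        out[b]["points"] = np.asarray(out[b]["points"], dtype=float).reshape(-1, 2)
        out[b]["labels"] = np.asarray(out[b]["labels"], dtype=object)
    return out


# ---------------------------------------------------------------------------
# ROC


def roc_curve(values, labels):
    """Threshold-sweep ROC for 'predict left when value > threshold'.

    Returns (fpr, tpr, auc); ties move the curve diagonally (simultaneous
    threshold crossing), so the trapezoid AUC equals U / (n1 * n2) with
    ties credited 1/2.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray([1 if l == "left" else 0 for l in labels])
    if len(v) != len(y):
        raise AnalysisError("values and labels must have equal length")
    if np.any(~np.isfinite(v)):
        raise AnalysisError("non-finite predictor values")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError("roc_curve requires both classes present")
    order = np.argsort(-v, kind="stable")
    v_sorted, y_sorted = v[order], y[order]
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    i = 0
    while i < len(v_sorted):
        j = i
        while j < len(v_sorted) and v_sorted[j] == v_sorted[i]:
            j += 1
        tp += int(y_sorted[i:j].sum())
        fp += (j - i) - int(y_sorted[i:j].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    fpr, tpr = np.asarray(fpr), np.asarray(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class RocResult:
    auc: dict  # predictor -> (n_sessions, n_bins) real AUCs
    null_auc: dict  # predictor -> (n_sessions, n_bins) median shuffled AUC
    null_distribution: dict  # predictor -> (n_sessions, n_bins, n_shuffles)
    vs_null: dict  # predictor -> list[TestResult or None] per bin
    whisker_vs_eye: list  # TestResult per bin
    pairwise_bins: dict  # predictor -> {(i, j): TestResult}
    n_bins: int


def _session_bin_aucs(table: BinnedPredictorTable, predictor: str, labels) -> np.ndarray:
    out = np.full(table.n_bins, np.nan)
    for b in range(table.n_bins):
        v = table.values(predictor, b)
        ok = np.isfinite(v)
        lab = np.asarray(labels)[ok]
        if len(set(lab)) < 2:
            continue
        _, _, out[b] = roc_curve(v[ok], lab)
    return out


def roc_analysis(
    tables: list[BinnedPredictorTable],
    n_shuffles: int = 1000,
    seed: int = 0,
    predictors: tuple[str, ...] = ("asym", "eye"),
) -> RocResult:
    """Per-session per-bin AUCs with within-session label-shuffled nulls.

    Across-session comparisons: per bin, real AUCs vs per-session median
    shuffled AUCs (Mann-Whitney U); whisker vs eye per bin; pairwise bin
    comparisons Bonferroni-corrected over the executed pairs.
    """
    rng = np.random.default_rng(seed)
    n_bins = tables[0].n_bins
    n_sessions = len(tables)
    auc = {p: np.full((n_sessions, n_bins), np.nan) for p in predictors}
    null_med = {p: np.full((n_sessions, n_bins), np.nan) for p in predictors}
    null_dist = {p: np.full((n_sessions, n_bins, n_shuffles), np.nan) for p in predictors}
    for si, table in enumerate(tables):
        labels = table.labels
        for p in predictors:
            auc[p][si] = _session_bin_aucs(table, p, labels)
        for k in range(n_shuffles):
            perm = rng.permutation(len(labels))
            shuffled = labels[perm]
            for p in predictors:
                null_dist[p][si, :, k] = _session_bin_aucs(table, p, shuffled)
        for p in predictors:
            null_med[p][si] = np.nanmedian(null_dist[p][si], axis=1)

    def _clean(a):
        return a[np.isfinite(a)]

    vs_null = {p: [] for p in predictors}
    for p in predictors:
        for b in range(n_bins):
            x, y = _clean(auc[p][:, b]), _clean(null_med[p][:, b])
            vs_null[p].append(mann_whitney_u(x, y) if len(x) and len(y) else None)
    whisker_vs_eye = []
    if set(("asym", "eye")) <= set(predictors):
        for b in range(n_bins):
            x, y = _clean(auc["asym"][:, b]), _clean(auc["eye"][:, b])
            whisker_vs_eye.append(mann_whitney_u(x, y) if len(x) and len(y) else None)
    pairwise = {p: {} for p in predictors}
    pairs = [(i, j) for i in range(n_bins) for j in range(i + 1, n_bins)]
    for p in predictors:
        for i, j in pairs:
            x, y = _clean(auc[p][:, i]), _clean(auc[p][:, j])
            if len(x) and len(y):
                r = mann_whitney_u(x, y)
                pairwise[p][(i, j)] = TestResult(
                    r.statistic,
                    bonferroni(r.p_value, len(pairs)),
                    r.method,
                    r.n,
                    correction=f"bonferroni(m={len(pairs)})",
                )
    return RocResult(auc, null_med, null_dist, vs_null, whisker_vs_eye, pairwise, n_bins)


# ---------------------------------------------------------------------------
# linear separation fidelity


@dataclass(frozen=True)
class LinearSeparator:
    weights: tuple[float, float]
    intercept: float
    fidelity: float
    method: str

    def predict(self, points) -> np.ndarray:
        """'left' on the positive side of the line, 'right' on the other."""
        pts = np.asarray(points, dtype=float)
        score = pts @ np.asarray(self.weights) + self.intercept
        return np.where(score > 0, "left", "right")


def _fidelity(score: np.ndarray, y: np.ndarray) -> float:
    """Fraction of points on their own side; side labeling chosen to favor
    the fit, so fidelity is always >= 0.5 for balanced classes."""
    acc = float(np.mean((score > 0) == (y == 1)))
    return max(acc, 1.0 - acc)


def fit_separator(points, labels, seed: int = 0) -> LinearSeparator:
    """Deterministic linear separator; fidelity = fraction correctly sided.

    Fits a fixed-seed single-layer perceptron on standardized inputs with a
    capped iteration budget, plus two deterministic fallbacks (a
    class-mean-direction cut with a 1D threshold sweep, and the degenerate
    majority separator).  The candidate with the highest fidelity wins,
    which guarantees fidelity >= max(class frequency).
    """
    pts = np.asarray(points, dtype=float)
    y = np.asarray([1 if l == "left" else 0 for l in labels])
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) != len(y):
        raise AnalysisError("fit_separator requires (n, 2) points and n labels")
    if len(set(y.tolist())) < 2:
        raise AnalysisError("fit_separator requires both classes present")
    mu = pts.mean(axis=0)
    sd = pts.std(axis=0)
    sd[sd == 0] = 1.0
    z = (pts - mu) / sd

    candidates: list[LinearSeparator] = []

    clf = Perceptron(max_iter=200, tol=None, shuffle=True, random_state=seed)
    clf.fit(z, y)
    w_z = clf.coef_[0]
    b_z = float(clf.intercept_[0])
    w = w_z / sd
    b = b_z - float(np.dot(w, mu))
    score = pts @ w + b
    candidates.append(LinearSeparator((float(w[0]), float(w[1])), float(b), _fidelity(score, y), "perceptron"))

    # class-mean direction with an exhaustive 1D threshold sweep
    dir_w = z[y == 1].mean(axis=0) - z[y == 0].mean(axis=0)
    if np.linalg.norm(dir_w) > 0:
        proj = z @ dir_w
        cuts = np.concatenate([[proj.min() - 1.0], (np.sort(np.unique(proj))[1:] + np.sort(np.unique(proj))[:-1]) / 2.0, [proj.max() + 1.0]])
        best_cut, best_f = cuts[0], -1.0
        for c in cuts:
            f = _fidelity(proj - c, y)
            if f > best_f:
                best_f, best_cut = f, c
        w = dir_w / sd
        b = -best_cut - float(np.dot(w, mu))
        score = (pts - mu) / sd @ dir_w - best_cut
        candidates.append(
            LinearSeparator((float(w[0]), float(w[1])), float(b), _fidelity(score, y), "class-mean")
        )

    # degenerate majority separator: every point on one side
    majority_f = max(float(np.mean(y)), 1.0 - float(np.mean(y)))
    candidates.append(LinearSeparator((0.0, 0.0), 1.0, majority_f, "majority"))

    return max(candidates, key=lambda c: c.fidelity)


@dataclass
class FidelityResult:
    full: list  # per bin: fidelity replicate array (refit seeds)
    null: list  # per bin: fidelity array over shuffle replicates
    partial: dict  # predictor -> per-bin fidelity arrays (that variable shuffled)
    contribution: dict  # predictor -> per-bin (median full - median partial)
    vs_null: list  # per bin: TestResult full vs null (Bonferroni-corrected)
    partial_vs_full: dict  # predictor -> per-bin TestResult
    n_bins: int


def contribution_analysis(
    bins_points: list[dict],
    n_shuffles: int = 100,
    seed: int = 0,
) -> FidelityResult:
    """Full/null/partial separation fidelities per time bin.

    The full model uses the true points; the null model shuffles both
    predictor columns relative to the labels; each partial model shuffles a
    single predictor.  All models are refit per replicate; comparisons use
    the Kruskal-Wallis test with Bonferroni correction over the executed
    comparisons (3 per bin across all bins).
    """
    rng = np.random.default_rng(seed)
    n_bins = len(bins_points)
    full, null = [], []
    partial = {"asym": [], "eye": []}
    col_of = {"asym": 0, "eye": 1}
    for b, bp in enumerate(bins_points):
        pts, labels = bp["points"], bp["labels"]
        if len(pts) == 0 or len(set(labels.tolist())) < 2:
            raise AnalysisError(f"bin {b}: need points of both classes")
        full_f = np.array(
            [fit_separator(pts, labels, seed=seed + k).fidelity for k in range(n_shuffles)]
        )
        null_f = np.empty(n_shuffles)
        part_f = {p: np.empty(n_shuffles) for p in partial}
        for k in range(n_shuffles):
            shuffled = pts.copy()
            for c in (0, 1):
                shuffled[:, c] = pts[rng.permutation(len(pts)), c]
            null_f[k] = fit_separator(shuffled, labels, seed=seed + k).fidelity
            for p, c in col_of.items():
                one = pts.copy()
                one[:, c] = pts[rng.permutation(len(pts)), c]
                part_f[p][k] = fit_separator(one, labels, seed=seed + k).fidelity
        full.append(full_f)
        null.append(null_f)
        for p in partial:
            partial[p].append(part_f[p])
    m = 3 * n_bins  # comparisons actually performed
    vs_null = []
    partial_vs_full = {p: [] for p in partial}
    for b in range(n_bins):
        r = kruskal_wallis([full[b], null[b]])
        vs_null.append(
            TestResult(r.statistic, bonferroni(r.p_value, m), r.method, r.n, f"bonferroni(m={m})")
        )
        for p in partial:
            r = kruskal_wallis([full[b], partial[p][b]])
            partial_vs_full[p].append(
                TestResult(r.statistic, bonferroni(r.p_value, m), r.method, r.n, f"bonferroni(m={m})")
            )
    contribution = {
        p: [float(np.median(full[b]) - np.median(partial[p][b])) for b in range(n_bins)]
        for p in partial
    }
    return FidelityResult(full, null, partial, contribution, vs_null, partial_vs_full, n_bins)
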