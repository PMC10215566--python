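"""Biomarker performance evaluation.

Univariate discrimination is measured by the ROC AUC (the Mann-Whitney
probability that a random case scores above a random control, ties counted
half) with a stratified bootstrap percentile confidence interval.
Multivariate panels are evaluated with a PLS-DA classifier (NIPALS, two
latent variables) inside Monte Carlo cross-validation: each repeat ranks
features by their VIP score on a stratified 2/3 training split and scores a
top-k panel on the held-out 1/3.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RocResult:
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    n_bootstrap: int = 0
    orientation: int = 1  # -1 when scores were flipped so that AUC >= 0.5


@dataclass
class PlsdaModel:
    """PLS-DA fit: NIPALS latent variables against a 0/1 class response."""

    classes: tuple[str, str]  # (negative, positive)
    feature_names: list[str]
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A, unit columns
    loadings: np.ndarray  # p x A
    scores: np.ndarray  # n x A, mutually orthogonal
    y_loadings: np.ndarray  # A
    coef: np.ndarray  # p, on the standardized X scale
    vip: np.ndarray  # p, mean squared VIP over features = 1
    dropped_features: list[str] = field(default_factory=list)

    def decision_function(self, X) -> np.ndarray:
        """Continuous predicted response on the 0/1 class coding."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean) / self.x_std
        return self.y_mean + Xs @ self.coef

    def predict(self, X) -> np.ndarray:
        """Class labels by a 0.5 cut on the fitted 0/1 response."""
        score = self.decision_function(X)
        return np.where(score >= 0.5, self.classes[1], self.classes[0])


@dataclass
class PanelEvaluation:
    panel_sizes: list[int]
    auc_mean: dict[int, float]
    auc_ci: dict[int, tuple[float, float]]
    accuracy: dict[int, float]
    importance: pd.Series  # cross-repeat averaged VIP, all features
    n_repeats: int = 0


def _split_scores(scores, labels, positive: str):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the scaled Mann-Whitney U statistic (ties count 1/2)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _roc_curve(pos: np.ndarray, neg: np.ndarray):
    """(FPR, TPR) sweep from (0,0) to (1,1), thresholds descending."""
    scores = np.concatenate([pos, neg])
    truth = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="stable")
    scores, truth = scores[order], truth[order]
    distinct = np.r_[np.where(np.diff(scores))[0], len(scores) - 1]
    tp = np.cumsum(truth)[distinct]
    fp = np.cumsum(1 - truth)[distinct]
    tpr = np.r_[0.0, tp / len(pos)]
    fpr = np.r_[0.0, fp / len(neg)]
    return fpr, tpr


def roc_auc(scores, labels, positive: str = "ALS") -> RocResult:
    """Point-estimate ROC, auto-oriented so the reported AUC is >= 0.5.

    ``orientation`` records the sign convention: -1 means lower scores
    indicate the positive class.
    """
    pos, neg = _split_scores(scores, labels, positive)
    auc = _auc_mann_whitney(pos, neg)
    orientation = 1
    if auc < 0.5:
        auc, orientation = 1.0 - auc, -1
        pos, neg = -pos, -neg
    fpr, tpr = _roc_curve(pos, neg)
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, orientation=orientation)


def bootstrap_auc(
    scores,
    labels,
    n_boot: int = 500,
    seed: int | None = None,
    positive: str = "ALS",
) -> RocResult:
    """Stratified bootstrap ROC: mean AUC with a 95% percentile CI.

    Resampling is with replacement within each class (so every draw has
    both classes); the orientation fixed by the point estimate is applied
    to all draws.
    """
    point = roc_auc(scores, labels, positive=positive)
    pos, neg = _split_scores(scores, labels, positive)
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("need >= 3 samples per class to bootstrap")
    if point.orientation == -1:
        pos, neg = -pos, -neg
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for i in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        draws[i] = _auc_mann_whitney(bp, bn)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RocResult(
        auc=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        fpr=point.fpr,
        tpr=point.tpr,
        n_bootstrap=n_boot,
        orientation=point.orientation,
    )


def correlate_discovery_validation(
    discovery_log2fc: pd.Series, validation_log2fc: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of matched discovery vs validation effect sizes."""
    shared = discovery_log2fc.index.intersection(validation_log2fc.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared proteins, found {len(shared)}"
        )
    pairs = pd.DataFrame(
        {
            "discovery_log2fc": discovery_log2fc[shared],
            "validation_log2fc": validation_log2fc[shared],
        }
    )
    r = float(stats.pearsonr(pairs.iloc[:, 0], pairs.iloc[:, 1]).statistic)
    return r, pairs


def plsda_fit(
    X,
    labels,
    n_components: int = 2,
    positive: str | None = None,
    feature_names=None,
) -> PlsdaModel:
    """Fit a PLS-DA model by NIPALS against a 0/1 class response.

    Features are standardized internally (constant features dropped with a
    warning). VIP importance satisfies mean(VIP^2) = 1 by construction.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if positive is None:
        positive = classes[-1]
    negative = [c for c in classes if c != positive][0]
    y = (labels == positive).astype(float)

    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    feature_names = list(feature_names)

    std = X.std(axis=0, ddof=1)
    keep = std > 0
    dropped = [feature_names[j] for j in range(p) if not keep[j]]
    if dropped:
        warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
    X = X[:, keep]
    feature_names = [f for f, k in zip(feature_names, keep) if k]
    p = X.shape[1]
    n_components = min(n_components, p, n - 1)

    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    Xs = (X - x_mean) / x_std
    y_mean = y.mean()
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xd, yd = Xs.copy(), yc.copy()
    actual = 0
    for a in range(n_components):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break  # response fully explained
        w /= norm
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        load = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, load)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, load, t, qa
        actual += 1
    W, P, T, q = W[:, :actual], P[:, :actual], T[:, :actual], q[:actual]

    # regression coefficients on the standardized scale
    coef = W @ np.linalg.solve(P.T @ W, q)

    # VIP: share of explained class variance carried by each feature
    ssy = q**2 * np.einsum("ij,ij->j", T, T)
    denom = ssy.sum()
    if denom <= 0:
        vip = np.ones(p)
    else:
        vip = np.sqrt(p * (W**2 @ ssy) / denom)

    return PlsdaModel(
        classes=(negative, positive),
        feature_names=feature_names,
        n_components=actual,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        scores=T,
        y_loadings=q,
        coef=coef,
        vip=vip,
        dropped_features=dropped,
    )


def _stratified_split(labels: np.ndarray, train_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        idx = rng.permutation(idx)
        k = int(round(train_frac * len(idx)))
        k = min(max(k, 2), len(idx) - 2)
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def mccv_panel_evaluation(
    X,
    labels,
    panel_sizes=(3, 5, 10, 15),
    n_repeats: int = 100,
    train_frac: float = 2.0 / 3.0,
    n_components: int = 2,
    seed: int | None = None,
    positive: str = "ALS",
    feature_names=None,
) -> PanelEvaluation:
    """Monte Carlo cross-validated panel ROC and accuracy.

    Each repeat draws a balanced stratified 2/3 training split, ranks all
    features by VIP on the training data only, then fits a PLS-DA model on
    the top-k features and scores the held-out third; AUC is computed on
    the held-out continuous response without re-orientation (so a
    signal-free panel stays near 0.5). Per panel size: mean AUC, percentile
    2.5/97.5 interval over repeats, and mean predictive accuracy; feature
    importance is the cross-repeat average VIP.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    panel_sizes = sorted(set(int(k) for k in panel_sizes))
    if any(k < 1 or k > p for k in panel_sizes):
        raise ValueError(f"panel sizes must lie in [1, {p}]")
    rng = np.random.default_rng(seed)
    aucs = {k: [] for k in panel_sizes}
    accs = {k: [] for k in panel_sizes}
    vip_sum = np.zeros(p)
    vip_n = 0
    for _ in range(n_repeats):
        tr, te = _stratified_split(labels, train_frac, rng)
        ranker = plsda_fit(
            X[tr], labels[tr], n_components=n_components, positive=positive,
            feature_names=feature_names,
        )
        vip_full = pd.Series(ranker.vip, index=ranker.feature_names).reindex(
            feature_names
        ).fillna(0.0)
        vip_sum += vip_full.to_numpy()
        vip_n += 1
        order = np.argsort(-vip_full.to_numpy(), kind="stable")
        for k in panel_sizes:
            top = order[:k]
            model = plsda_fit(
                X[tr][:, top], labels[tr],
                n_components=min(n_components, k), positive=positive,
                feature_names=[feature_names[j] for j in top],
            )
            score = model.decision_function(X[te][:, top])
            pos_mask = labels[te] == positive
            aucs[k].append(_auc_mann_whitney(score[pos_mask], score[~pos_mask]))
            accs[k].append(float(np.mean(model.predict(X[te][:, top]) == labels[te])))
    importance = pd.Series(vip_sum / vip_n, index=feature_names, name="mean_vip")
    return PanelEvaluation(
        panel_sizes=panel_sizes,
        auc_mean={k: float(np.mean(v)) for k, v in aucs.items()},
        auc_ci={
            k: tuple(np.percentile(v, [2.5, 97.5])) for k, v in aucs.items()
        },
        accuracy={k: float(np.mean(v)) for k, v in accs.items()},
        importance=importance.sort_values(ascending=False),
        n_repeats=n_repeats,
    )
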