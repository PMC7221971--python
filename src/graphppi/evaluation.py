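"""Cross-validation harness and the classification metric suite.

Metrics follow the standard confusion-count definitions: accuracy
ACC = (TP+TN)/N, sensitivity SEN = TP/(TP+FN), precision Pre = TP/(TP+FP)
and the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TN+FP)(TP+FP)(TP+FN)(TN+FN)).
Any metric with a zero denominator is reported as 0 and flagged undefined
rather than raising, so fold aggregation stays total. AUC is the rank-based
(Mann-Whitney) statistic with ties sharing rank.

`cross_validate` runs the full pipeline per fold — fused features, PCA fit
on the training fold's proteins only (leakage-safe default), pair assembly,
WSRC — on a stratified k-fold split with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from . import reduction, wsrc
from .sequence_io import PairDataset

METRIC_NAMES = ("ACC", "SEN", "MCC", "Pre", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict:
    """ACC, SEN, Pre, MCC from confusion counts; zero denominators give 0 + flag."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (c.tp + c.tn) / c.total
    sen = _safe(c.tp, c.tp + c.fn, "SEN")
    pre = _safe(c.tp, c.tp + c.fp, "Pre")
    mcc_den = np.sqrt(
        float(c.tn + c.fp) * (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn)
    )
    mcc = _safe(c.tp * c.tn - c.fp * c.fn, mcc_den, "MCC")
    return {"ACC": acc, "SEN": sen, "Pre": pre, "MCC": mcc, "undefined": undefined}


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve, ties share rank."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class PipelineConfig:
    """Knobs of the feature -> PCA -> WSRC pipeline, with defaults."""

    d: int = reduction.D_WITHIN_SPECIES
    n_windows: int = feat.N_WINDOWS
    sigma: float | None = None  # None -> median pairwise training distance
    eps: float = wsrc.DEFAULT_EPS
    squared_distance: bool = True
    invert_weights: bool = True  # locality orientation (penalise far samples)
    symmetrize: bool = False  # average scores over both pair orders
    pca_scope: str = "train"  # "train" (leakage-safe) or "all" (paper-mode)

    def to_dict(self) -> dict:
        return {
            "d": self.d, "n_windows": self.n_windows, "sigma": self.sigma,
            "eps": self.eps, "squared_distance": self.squared_distance,
            "invert_weights": self.invert_weights, "symmetrize": self.symmetrize,
            "pca_scope": self.pca_scope,
        }


@dataclass
class MetricReport:
    folds: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    pca_fitted_ids: list[tuple[str, ...]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Testing Set": f"fold {i + 1}", **{k: m[k] for k in METRIC_NAMES}}
            for i, m in enumerate(self.folds)
        ]
        rows.append({"Testing Set": "Average", **{k: self.mean[k] for k in METRIC_NAMES}})
        return pd.DataFrame(rows)


def _predict_pairs(dataset, pairs, reduced, model, config):
    X = reduction.make_pair_features(pairs, reduced)
    labels, scores = wsrc.predict(
        X, model, squared=config.squared_distance, invert_weights=config.invert_weights
    )
    if config.symmetrize:
        from .sequence_io import Pair

        flipped = [Pair(p.id_b, p.id_a, p.label) for p in pairs]
        Xf = reduction.make_pair_features(flipped, reduced)
        labels_f, scores_f = wsrc.predict(
            Xf, model, squared=config.squared_distance,
            invert_weights=config.invert_weights,
        )
        scores = (scores + scores_f) / 2.0
        labels = (scores > 0).astype(int) if set(model.classes) == {0, 1} else labels
    return labels, scores


def evaluate_split(
    dataset: PairDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    fused: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[dict, tuple[str, ...], np.ndarray, np.ndarray]:
    """Run PCA + WSRC on one train/test split of the pair list."""
    train_pairs = [dataset.pairs[i] for i in train_idx]
    test_pairs = [dataset.pairs[i] for i in test_idx]
    if config.pca_scope == "train":
        fit_ids = dataset.protein_ids(train_pairs)
    elif config.pca_scope == "all":
        fit_ids = dataset.protein_ids()
    else:
        raise ValueError(f"unknown pca_scope {config.pca_scope!r}")
    pca = reduction.fit_pca(fused.loc[fit_ids].to_numpy(), config.d, fitted_ids=fit_ids)
    all_ids = dataset.protein_ids()
    Z = reduction.transform(pca, fused.loc[all_ids].to_numpy())
    reduced = {pid: Z[i] for i, pid in enumerate(all_ids)}

    Xtr = reduction.make_pair_features(train_pairs, reduced)
    ytr = np.array([p.label for p in train_pairs])
    model = wsrc.build_model(Xtr, ytr, sigma=config.sigma, eps=config.eps)
    pred, scores = _predict_pairs(dataset, test_pairs, reduced, model, config)
    yte = np.array([p.label for p in test_pairs])

    fold = metrics(confusion(yte, pred))
    fold["AUC"] = auc(scores, yte)
    fold["n_test"] = len(yte)
    return fold, pca.fitted_ids, pred, scores


def cross_validate(
    dataset: PairDataset,
    k: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Stratified k-fold cross-validation of the full pipeline."""
    config = config or PipelineConfig()
    y = dataset.labels
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"need at least {k} pairs of class {cls} for {k}-fold CV")
    fused = feat.feature_table(dataset.proteins, n_windows=config.n_windows)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = MetricReport()
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        fold, fit_ids, _, _ = evaluate_split(dataset, train_idx, test_idx, fused, config)
        report.folds.append(fold)
        report.pca_fitted_ids.append(fit_ids)
    report.mean = {
        name: float(np.mean([f[name] for f in report.folds])) for name in METRIC_NAMES
    }
    return report
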