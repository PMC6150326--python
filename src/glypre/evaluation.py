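"""Performance metrics and the cross-validation protocols.

Metrics are sensitivity, specificity, accuracy, Matthews correlation and
ROC AUC.  The repeated stratified k-fold protocol pools confusion counts
and scores over the folds of each repeat, then reports mean and standard
deviation across repeats; leave-one-out pools all n single-sample
predictions.  A per-feature-group window-size search and per-position
class profiles (conservation, secondary-structure frequencies, mean
AAindex values) support the descriptive analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import pipeline as _pipeline
from .encoders import EncoderConfig, column_frequencies, conservation_M
from .pipeline import EncodedCorpus, PipelineConfig, fit_fold, prepare_corpus
from .seqdata_io import (
    AAIndexTable,
    LabelledDataset,
    ProteinRecord,
    SSProfile,
    WILDCARD,
)


# ---------------------------------------------------------------------------
# Confusion counts and scalar metrics


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("label vectors are not aligned")
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Sen, Spe, Acc and MCC from confusion counts.

    A ratio with a zero denominator is reported as 0, and MCC is 0 whenever
    any factor under the square root vanishes (the usual convention for
    degenerate folds).
    """
    if c.n == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sen = ratio(c.TP, c.TP + c.FN)
    spe = ratio(c.TN, c.TN + c.FP)
    acc = (c.TP + c.TN) / c.n
    denom = (
        (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    )
    mcc = ((c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)) if denom else 0.0
    return {"sen": sen, "spe": spe, "acc": acc, "mcc": float(mcc)}


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) estimator with midranks for ties."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Cross-validation protocols


@dataclass
class MetricsReport:
    """Mean and standard deviation of the five metrics over repeats."""

    k: int
    n_repeats: int
    mean: dict[str, float]
    sd: dict[str, float]
    per_repeat: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"k": self.k, "n_repeats": self.n_repeats,
                 "mean": self.mean, "sd": self.sd},
                fh, indent=2,
            )

    def to_tsv(self, path: str | Path) -> None:
        self.per_repeat.to_csv(path, sep="\t", index=False)


_METRIC_KEYS = ("sen", "spe", "acc", "mcc", "auc")


def _stratified_folds(y: np.ndarray, k: int, seed: int,
                      max_retries: int = 10) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds, redrawn with a shifted seed if a class goes missing."""
    for attempt in range(max_retries):
        s = seed + attempt * 7919
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=s)
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
            for tr, te in folds
        )
        if ok:
            if attempt:
                warnings.warn(f"fold partition redrawn {attempt} time(s)",
                              stacklevel=2)
            return folds
    raise ValueError("could not build stratified folds with both classes")


def _one_repeat(corpus: EncodedCorpus, cfg: PipelineConfig, k: int,
                seed: int) -> dict[str, float]:
    y = corpus.labels
    folds = _stratified_folds(y, k, seed)
    pooled_scores = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=int)
    if cfg.selection_scope == "global":
        # Selection once on all data (leaky; kept for protocol comparison),
        # then only the SVM is refit per fold.
        all_idx = np.arange(len(y))
        X_all, _, _, _ = _pipeline._transform_corpus(corpus, all_idx)
        from . import classifier as _clf
        for train, test in folds:
            trained = _clf.train_fixed(
                X_all[train], y[train], C=cfg.C, gamma=cfg.gamma,
                kernel=cfg.kernel, threshold=cfg.threshold, seed=seed)
            scores = _clf.predict_scores(trained, X_all[test])
            pooled_scores[test] = scores
            pooled_pred[test] = (scores >= cfg.threshold).astype(int)
    else:
        for train, test in folds:
            fold_model = fit_fold(corpus, train, cfg, seed=seed)
            scores = fold_model.predict_scores(test)
            pooled_scores[test] = scores
            pooled_pred[test] = (scores >= cfg.threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y, pooled_pred)
    out = metrics_from_counts(counts)
    out["auc"] = auc_score(pooled_scores, y)
    return out


def repeated_kfold(corpus: EncodedCorpus, cfg: PipelineConfig | None = None,
                   k: int = 10, repeats: int = 50,
                   base_seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation repeated with different seeds.

    Per repeat, confusion counts are summed and scores pooled over the k
    folds; the report gives mean and sd of each metric across repeats.
    Deterministic given ``base_seed``.
    """
    if k < 2 or repeats < 1:
        raise ValueError("need k >= 2 and repeats >= 1")
    cfg = cfg or PipelineConfig()
    records = []
    for r in range(repeats):
        records.append(_one_repeat(corpus, cfg, k, base_seed + r))
    df = pd.DataFrame(records)
    df.insert(0, "repeat", np.arange(repeats))
    mean = {m: float(df[m].mean()) for m in _METRIC_KEYS}
    sd = {m: float(df[m].std(ddof=0)) for m in _METRIC_KEYS}
    return MetricsReport(k=k, n_repeats=repeats, mean=mean, sd=sd, per_repeat=df)


def loo_cv(corpus: EncodedCorpus, cfg: PipelineConfig | None = None,
           seed: int = 0) -> MetricsReport:
    """Leave-one-out: n single-sample test folds, metrics on pooled predictions."""
    cfg = cfg or PipelineConfig()
    n = len(corpus)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    y = corpus.labels
    pooled_scores = np.empty(n)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        fold_model = fit_fold(corpus, train, cfg, seed=seed)
        pooled_scores[i] = fold_model.predict_scores(np.array([i]))[0]
    pooled_pred = (pooled_scores >= cfg.threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y, pooled_pred)
    out = metrics_from_counts(counts)
    out["auc"] = auc_score(pooled_scores, y)
    df = pd.DataFrame([out])
    df.insert(0, "repeat", [0])
    return MetricsReport(k=n, n_repeats=1, mean={m: out[m] for m in _METRIC_KEYS},
                         sd={m: 0.0 for m in _METRIC_KEYS}, per_repeat=df)


# ---------------------------------------------------------------------------
# Window-size optimization


_GROUP_FLAGS = {
    "pssf": "use_pssf",
    "ss": "use_ss",
    "aaindex": "use_aaindex",
    "cksaap": "use_cksaap",
}
_GROUP_WINDOWS = {
    "pssf": "window_pssf",
    "ss": "window_ss",
    "aaindex": "window_aaindex",
    "cksaap": "window_cksaap",
}


def optimize_window_sizes(proteins: Sequence[ProteinRecord],
                          dataset: LabelledDataset,
                          profiles: Mapping[str, SSProfile] | None = None,
                          table: AAIndexTable | None = None,
                          grid: Sequence[int] = tuple(range(11, 32, 2)),
                          cfg: PipelineConfig | None = None,
                          k: int = 10, seed: int = 0,
                          groups: Sequence[str] = ("pssf", "ss", "aaindex", "cksaap"),
                          ) -> tuple[dict[str, int], pd.DataFrame]:
    """Per-group window search: CV AUC of each group's encoding alone.

    Groups are evaluated independently; the best window per group is the
    argmax of mean pooled AUC, ties going to the smaller window.
    """
    grid = sorted(set(int(w) for w in grid))
    if not grid:
        raise ValueError("empty window grid")
    if any(w % 2 == 0 for w in grid):
        raise ValueError("window sizes must be odd")
    cfg = cfg or PipelineConfig()
    rows = []
    for group in groups:
        for w in grid:
            enc_kwargs = {flag: (g == group) for g, flag in _GROUP_FLAGS.items()}
            enc_kwargs[_GROUP_WINDOWS[group]] = w
            enc = EncoderConfig(**enc_kwargs)
            corpus = prepare_corpus(proteins, dataset, profiles, table, enc)
            sub_cfg = PipelineConfig(
                encoder=enc, C=cfg.C, gamma=cfg.gamma, kernel=cfg.kernel,
                selection_scope=cfg.selection_scope, threshold=cfg.threshold,
            )
            rep = repeated_kfold(corpus, sub_cfg, k=k, repeats=1, base_seed=seed)
            rows.append({"group": group, "window": w, "auc": rep.mean["auc"]})
    df = pd.DataFrame(rows)
    best: dict[str, int] = {}
    for group in groups:
        sub = df[df.group == group].sort_values("window")
        best[group] = int(sub.window.iloc[int(np.argmax(sub.auc.values))])
    return best, df


# ---------------------------------------------------------------------------
# Positional profiles (descriptive analyses)


def positional_profiles(proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                        dataset: LabelledDataset,
                        profiles: Mapping[str, SSProfile] | None = None,
                        table: AAIndexTable | None = None,
                        property: str = "conservation_M",
                        window: int = 31,
                        p0: float = 0.05) -> pd.DataFrame:
    """Per-position class-wise summaries as a tidy table.

    ``conservation_M``: the conservation statistic per column and class.
    ``ss_frequency``: frequency of the dominant C/H/E state per column and
    class (rows sum to 1 within a position/class).
    ``aaindex_mean``: mean z-scored index value per column, class and
    accession ('X' positions excluded).
    """
    by_id = (proteins if isinstance(proteins, Mapping)
             else {p.id: p for p in proteins})
    half = (window - 1) // 2
    offsets = list(range(-half, half + 1))
    wins = dataset.windows_at(by_id, window)
    rows = []
    if property == "conservation_M":
        for cls, label in (("positive", 1), ("negative", 0)):
            sub = [w for w, lab in zip(wins, dataset.labels) if lab == label]
            for l, off in enumerate(offsets):
                rows.append({
                    "position": off, "class": cls,
                    "value": conservation_M(column_frequencies(sub, l), p0),
                })
    elif property == "ss_frequency":
        if profiles is None:
            raise ValueError("ss_frequency needs profiles")
        for cls, label in (("positive", 1), ("negative", 0)):
            sites = [s for s, lab in zip(dataset.sites, dataset.labels)
                     if lab == label]
            for off in offsets:
                counts = {"C": 0, "H": 0, "E": 0}
                for pid, pos in sites:
                    j = pos - 1 + off
                    prof = profiles[pid]
                    if 0 <= j < len(prof):
                        counts["CHE"[int(np.argmax(prof.probs[j]))]] += 1
                total = sum(counts.values())
                for s, c in counts.items():
                    rows.append({
                        "position": off, "class": cls, "structure": s,
                        "value": c / total if total else 0.0,
                    })
    elif property == "aaindex_mean":
        if table is None:
            raise ValueError("aaindex_mean needs an AAindex table")
        ztable = table.zscored()
        from .encoders import windows_to_ints, _X_CODE
        mat = windows_to_ints(wins)
        for cls, label in (("positive", 1), ("negative", 0)):
            sub = mat[dataset.labels == label]
            for l, off in enumerate(offsets):
                col = sub[:, l]
                col = col[col != _X_CODE]
                for ai, acc in enumerate(ztable.accessions):
                    val = float(ztable.values[ai, col].mean()) if col.size else 0.0
                    rows.append({"position": off, "class": cls,
                                 "accession": acc, "value": val})
    else:
        raise ValueError(f"unknown property {property!r}")
    return pd.DataFrame(rows)
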