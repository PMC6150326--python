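"""End-to-end wiring: corpus encoding, per-fold refitting, deployable model.

The central leakage concern in site-prediction benchmarks is that the PWM,
the information-gain CKSAAP selection and any wrapper selection are all
*fitted* quantities.  ``selection_scope="fold"`` (the default, "honest"
evaluation) refits all of them inside every training fold;
``selection_scope="global"`` reproduces the common-but-leaky workflow where
selection happens once on the full dataset before cross-validation.  Both
are available and explicitly labelled so the difference can be measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd

from . import classifier, feature_selection
from .classifier import CVSpec, SVMConfig, TrainedModel
from .encoders import (
    EncoderConfig,
    FeatureLayout,
    PWMModel,
    assemble,
    build_layout,
    cksaap_matrix,
    fit_pwm,
    encode_aaindex,
    encode_ss,
    pairs_from_indices,
    position_scores_matrix,
    windows_to_ints,
)
from .seqdata_io import (
    AAIndexTable,
    LabelledDataset,
    ProteinRecord,
    SSProfile,
    extract_window,
)

_GLYPRE_SCHEMA = "glypre.model.v1"


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to train and evaluate the predictor.

    The default SVM uses fixed hyperparameters (C=1, gamma='scale'); set
    ``grid_search=True`` (with ``svm_grid``) to run the full log2 grid
    search at training time instead.
    """

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"
    grid_search: bool = False
    svm_grid: SVMConfig | None = None
    selection_scope: str = "fold"  # "fold" (honest) | "global"
    run_gfs: bool = False
    gfs_eps: float = 1e-4
    gfs_cv_k: int = 10
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.selection_scope not in ("fold", "global"):
            raise ValueError("selection_scope must be 'fold' or 'global'")


@dataclass
class EncodedCorpus:
    """Window-level encodings of a labelled dataset, computed once.

    Blocks that depend only on the window itself (SS, AAindex, full CKSAAP)
    are precomputed; blocks that depend on fitted statistics (position
    scores, the CKSAAP top-m projection) are recomputed per training fold
    from the stored integer windows.
    """

    labels: np.ndarray
    sites: list[tuple[str, int]]
    config: EncoderConfig
    pssf_ints: np.ndarray | None
    cksaap_full: np.ndarray | None
    ss_block: np.ndarray | None
    aai_block: np.ndarray | None
    accessions: tuple[str, ...] | None

    def __len__(self) -> int:
        return len(self.labels)


def prepare_corpus(proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
                   dataset: LabelledDataset,
                   profiles: Mapping[str, SSProfile] | None = None,
                   table: AAIndexTable | None = None,
                   config: EncoderConfig | None = None) -> EncodedCorpus:
    """Precompute all fold-independent feature blocks for a dataset."""
    config = config or EncoderConfig()
    by_id = (proteins if isinstance(proteins, Mapping)
             else {p.id: p for p in proteins})

    pssf_ints = None
    if config.use_pssf:
        wins = dataset.windows_at(by_id, config.window_pssf)
        pssf_ints = windows_to_ints(wins)

    cksaap_full = None
    if config.use_cksaap:
        wins = dataset.windows_at(by_id, config.window_cksaap)
        cksaap_full = cksaap_matrix(wins, config.k_max)

    ss_block = None
    if config.use_ss:
        if profiles is None:
            raise ValueError("SS group enabled but no profiles given")
        missing = sorted({pid for pid, _ in dataset.sites} - set(profiles))
        if missing:
            raise ValueError(f"missing .ss2 profiles for proteins: {missing}")
        ss_block = np.stack([
            encode_ss(profiles[pid], pos - 1, config.window_ss)
            for pid, pos in dataset.sites
        ])

    aai_block = None
    accessions = None
    if config.use_aaindex:
        if table is None:
            raise ValueError("AAindex group enabled but no table given")
        ztable = table.zscored()
        accessions = ztable.accessions
        wins = dataset.windows_at(by_id, config.window_aaindex)
        aai_block = np.stack([encode_aaindex(w, ztable) for w in wins])

    return EncodedCorpus(
        labels=np.asarray(dataset.labels, dtype=int),
        sites=list(dataset.sites),
        config=config,
        pssf_ints=pssf_ints,
        cksaap_full=cksaap_full,
        ss_block=ss_block,
        aai_block=aai_block,
        accessions=accessions,
    )


@dataclass
class FoldModel:
    """Transforms fitted on one training index set, applied to all rows."""

    pwm: PWMModel | None
    top_cksaap_idx: np.ndarray | None
    gfs_selected: list[int] | None
    trained: TrainedModel
    X: np.ndarray  # all corpus rows under this fold's transforms
    layout: FeatureLayout

    def predict_scores(self, idx: np.ndarray) -> np.ndarray:
        return classifier.predict_scores(self.trained, self.X[idx])


def _transform_corpus(corpus: EncodedCorpus, train_idx: np.ndarray
                      ) -> tuple[np.ndarray, PWMModel | None, np.ndarray | None,
                                 FeatureLayout]:
    """Fit fold-dependent transforms on ``train_idx``; encode every row."""
    cfg = corpus.config
    parts: list[np.ndarray] = []
    pwm = None
    top_idx = None
    y_train = corpus.labels[train_idx]

    if cfg.use_pssf:
        ints = corpus.pssf_ints
        pos = ints[train_idx[y_train == 1]]
        neg = ints[train_idx[y_train == 0]]
        pos_wins = ["".join("ACDEFGHIKLMNPQRSTVWYX"[c] for c in row) for row in pos]
        neg_wins = ["".join("ACDEFGHIKLMNPQRSTVWYX"[c] for c in row) for row in neg]
        pwm = fit_pwm(pos_wins, neg_wins, cfg.p0)
        parts.append(position_scores_matrix(ints, pwm))
    if cfg.use_ss:
        parts.append(corpus.ss_block)
    if cfg.use_aaindex:
        parts.append(corpus.aai_block)
    if cfg.use_cksaap:
        ranked = feature_selection.information_gain_rank(
            corpus.cksaap_full[train_idx], y_train,
            feature_selection.Discretizer("zero_nonzero"),
        )
        top_idx = ranked.order[: cfg.top_m_cksaap]
        parts.append(corpus.cksaap_full[:, top_idx])

    layout = build_layout(
        cfg,
        accessions=corpus.accessions,
        selected_pairs=(pairs_from_indices(top_idx, cfg.k_max)
                        if top_idx is not None else None),
    )
    return np.hstack(parts), pwm, top_idx, layout


def fit_fold(corpus: EncodedCorpus, train_idx: np.ndarray,
             cfg: PipelineConfig, seed: int = 0) -> FoldModel:
    """Fit transforms + SVM on a training index set (honest fold fit)."""
    train_idx = np.asarray(train_idx)
    X_all, pwm, top_idx, layout = _transform_corpus(corpus, train_idx)
    y_train = corpus.labels[train_idx]

    gfs_selected = None
    X_model = X_all
    if cfg.run_gfs:
        ranked = feature_selection.mrmr_rank(X_all[train_idx], y_train)
        result = feature_selection.greedy_forward_select(
            X_all[train_idx], y_train, ranked,
            CVSpec(k=cfg.gfs_cv_k, seed=seed, C=cfg.C, gamma=cfg.gamma,
                   kernel=cfg.kernel),
            eps=cfg.gfs_eps,
        )
        gfs_selected = result.selected
        X_model = feature_selection.apply_selection(X_all, gfs_selected)

    if cfg.grid_search:
        grid = cfg.svm_grid or SVMConfig(seed=seed, threshold=cfg.threshold)
        trained = classifier.grid_search_train(X_model[train_idx], y_train, grid)
    else:
        trained = classifier.train_fixed(
            X_model[train_idx], y_train, C=cfg.C, gamma=cfg.gamma,
            kernel=cfg.kernel, threshold=cfg.threshold, seed=seed,
        )
    return FoldModel(pwm, top_idx, gfs_selected, trained, X_model, layout)


# ---------------------------------------------------------------------------
# Deployable model


@dataclass
class GlypreModel:
    """A fully fitted predictor: encoder state + selection + calibrated SVM.

    Serializes to a single file so prediction needs only FASTA (and .ss2
    files when the secondary-structure group is active).
    """

    config: EncoderConfig
    pwm: PWMModel | None
    table: AAIndexTable | None
    selected_pairs: list[tuple[int, str]] | None
    gfs_selected: list[int] | None
    trained: TrainedModel
    layout: FeatureLayout
    threshold: float = 0.5

    @classmethod
    def fit(cls, proteins: Sequence[ProteinRecord], dataset: LabelledDataset,
            profiles: Mapping[str, SSProfile] | None = None,
            table: AAIndexTable | None = None,
            cfg: PipelineConfig | None = None, seed: int = 0) -> "GlypreModel":
        cfg = cfg or PipelineConfig()
        corpus = prepare_corpus(proteins, dataset, profiles, table, cfg.encoder)
        all_idx = np.arange(len(corpus))
        fold = fit_fold(corpus, all_idx, cfg, seed=seed)
        pairs = (pairs_from_indices(fold.top_cksaap_idx, cfg.encoder.k_max)
                 if fold.top_cksaap_idx is not None else None)
        return cls(
            config=cfg.encoder,
            pwm=fold.pwm,
            table=table.zscored() if table is not None else None,
            selected_pairs=pairs,
            gfs_selected=fold.gfs_selected,
            trained=fold.trained,
            layout=fold.layout,
            threshold=cfg.threshold,
        )

    def predict_proteins(self, proteins: Sequence[ProteinRecord],
                         profiles: Mapping[str, SSProfile] | None = None
                         ) -> pd.DataFrame:
        """Score every lysine; returns protein_id, position, score, call."""
        if self.config.use_ss:
            missing = [p.id for p in proteins
                       if profiles is None or p.id not in profiles]
            if missing:
                raise ValueError(
                    "model uses the secondary-structure group but profiles "
                    f"are missing for: {missing}"
                )
        rows = []
        feats = []
        for prot in proteins:
            profile = profiles.get(prot.id) if profiles else None
            for i, c in enumerate(prot.sequence):
                if c != "K":
                    continue
                fv = assemble(prot, i + 1, self.config, pwm=self.pwm,
                              table=self.table, profile=profile,
                              selected_pairs=self.selected_pairs)
                vec = fv.values
                if self.gfs_selected is not None:
                    vec = vec[self.gfs_selected]
                feats.append(vec)
                rows.append((prot.id, i + 1))
        if not rows:
            return pd.DataFrame(columns=["protein_id", "position", "score", "call"])
        X = np.vstack(feats)
        scores = classifier.predict_scores(self.trained, X)
        calls = (scores >= self.threshold).astype(int)
        return pd.DataFrame({
            "protein_id": [r[0] for r in rows],
            "position": [r[1] for r in rows],
            "score": scores,
            "call": calls,
        })

    def save(self, path: str | Path) -> None:
        joblib.dump({"schema": _GLYPRE_SCHEMA, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "GlypreModel":
        try:
            payload = joblib.load(path)
        except Exception as exc:
            raise ValueError(f"could not read model file {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("schema") != _GLYPRE_SCHEMA:
            raise ValueError(f"model file {path} is not a {_GLYPRE_SCHEMA} file")
        return payload["model"]
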