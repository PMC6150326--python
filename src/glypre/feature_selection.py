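"""Feature ranking and greedy forward selection.

Two rankings are provided: information gain (mutual information between a
discretized feature and the class label, used for the CKSAAP top-m step) and
mRMR under the mutual-information-difference (MID) scheme (used on the
assembled vector).  Greedy forward selection then walks the ranked list and
keeps a feature only when the cross-validated AUC of the growing subset
improves.

Mutual information is estimated on discretized features, in bits.  Two
discretization schemes are available: zero/nonzero binarization (natural for
the sparse CKSAAP compositions) and the mean +/- sigma three-bin scheme
commonly paired with mRMR for dense features.  All ties break by ascending
feature index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import classifier


# ---------------------------------------------------------------------------
# Discretization


@dataclass
class Discretizer:
    """Maps continuous features to small integer codes.

    ``zero_nonzero``: code 1 where the value is non-zero.
    ``mean_sigma_3bin``: codes 0/1/2 for value < mu - sigma, within one sigma,
    and > mu + sigma, with mu/sigma estimated per feature at fit time.
    """

    scheme: str = "zero_nonzero"
    mu_: np.ndarray | None = field(default=None, repr=False)
    sigma_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.scheme not in ("zero_nonzero", "mean_sigma_3bin"):
            raise ValueError(f"unknown discretization scheme {self.scheme!r}")

    @property
    def n_levels(self) -> int:
        return 2 if self.scheme == "zero_nonzero" else 3

    def fit(self, X: np.ndarray) -> "Discretizer":
        X = np.asarray(X, dtype=float)
        if self.scheme == "mean_sigma_3bin":
            self.mu_ = X.mean(axis=0)
            self.sigma_ = X.std(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scheme == "zero_nonzero":
            return (X != 0).astype(np.int64)
        if self.mu_ is None:
            raise ValueError("discretizer not fitted")
        lo = self.mu_ - self.sigma_
        hi = self.mu_ + self.sigma_
        return ((X >= lo).astype(np.int64) + (X > hi).astype(np.int64))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# Entropy / mutual information on discrete codes


def _entropy_bits(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.where(total > 0, total, 1), 0.0)
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1)), 0.0)
    return -(p * logp).sum(axis=axis)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return y


def mutual_information_with_labels(Xd: np.ndarray, y: np.ndarray,
                                   n_levels: int) -> np.ndarray:
    """I(x_j ; y) in bits for each discretized column of ``Xd``."""
    y = np.asarray(y)
    n = len(y)
    Hy = _entropy_bits(np.bincount(y, minlength=2))
    cond = np.zeros(Xd.shape[1])
    for v in range(n_levels):
        mask = Xd == v  # (n, p)
        n_v = mask.sum(axis=0).astype(float)
        n_v1 = mask[y == 1].sum(axis=0).astype(float)
        counts = np.stack([n_v - n_v1, n_v1], axis=-1)  # (p, 2)
        cond += (n_v / n) * _entropy_bits(counts)
    return Hy - cond


def mutual_information_columns(Xd: np.ndarray, z: np.ndarray,
                               levels_x: int, levels_z: int) -> np.ndarray:
    """I(x_j ; z) in bits between each column of ``Xd`` and the code vector ``z``."""
    n, p = Xd.shape
    mi = np.zeros(p)
    # H(x) + H(z) - H(x, z)
    Hx = np.zeros(p)
    for v in range(levels_x):
        n_v = (Xd == v).sum(axis=0) / n
        with np.errstate(divide="ignore"):
            Hx -= np.where(n_v > 0, n_v * np.log2(np.where(n_v > 0, n_v, 1)), 0.0)
    Hz = _entropy_bits(np.bincount(z, minlength=levels_z))
    Hxz = np.zeros(p)
    for vz in range(levels_z):
        sub = Xd[z == vz]
        for vx in range(levels_x):
            pj = (sub == vx).sum(axis=0) / n
            with np.errstate(divide="ignore"):
                Hxz -= np.where(pj > 0, pj * np.log2(np.where(pj > 0, pj, 1)), 0.0)
    mi = Hx + Hz - Hxz
    return np.maximum(mi, 0.0)


# ---------------------------------------------------------------------------
# Rankings


@dataclass
class RankedFeatures:
    """An ordered ranking of feature indices with per-feature criterion scores.

    ``scores`` aligns with ``order`` (``scores[i]`` is the criterion value of
    feature ``order[i]`` at the time it was ranked).
    """

    order: np.ndarray
    scores: np.ndarray
    criterion: str

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.order) != len(self.scores):
            raise ValueError("order and scores are not aligned")
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("ranking repeats feature indices")


def information_gain_rank(X: np.ndarray, y: np.ndarray,
                          discretizer: Discretizer | None = None
                          ) -> RankedFeatures:
    """Rank features by IG = H(y) - H(y | discretized x), descending.

    Ties break by ascending feature index.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows do not align with y")
    disc = discretizer or Discretizer("zero_nonzero")
    Xd = disc.fit_transform(X)
    ig = mutual_information_with_labels(Xd, y, disc.n_levels)
    order = np.lexsort((np.arange(X.shape[1]), -ig))
    return RankedFeatures(order, ig[order], "IG")


def mrmr_rank(X: np.ndarray, y: np.ndarray,
              n_select: int | None = None,
              discretizer: Discretizer | None = None) -> RankedFeatures:
    """Greedy mRMR ranking under the MID scheme.

    The first feature maximizes relevance I(x; y); each subsequent feature
    maximizes I(x; y) minus the mean mutual information with the features
    already chosen.  Deterministic, with index tie-breaking.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows do not align with y")
    p = X.shape[1]
    n_select = p if n_select is None else int(n_select)
    if not 1 <= n_select <= p:
        raise ValueError(f"n_select must be in 1..{p}")
    disc = discretizer or Discretizer("mean_sigma_3bin")
    Xd = disc.fit_transform(X)
    L = disc.n_levels

    relevance = mutual_information_with_labels(Xd, y, L)
    remaining = np.ones(p, dtype=bool)
    redundancy_sum = np.zeros(p)
    order: list[int] = []
    scores: list[float] = []
    for step in range(n_select):
        if step == 0:
            criterion = relevance.copy()
        else:
            criterion = relevance - redundancy_sum / step
        criterion = np.where(remaining, criterion, -np.inf)
        # Lowest index among near-ties (1e-12), robust to float round-off.
        best = int(np.flatnonzero(criterion >= criterion.max() - 1e-12)[0])
        order.append(best)
        scores.append(float(criterion[best]))
        remaining[best] = False
        if step < n_select - 1:
            redundancy_sum += mutual_information_columns(Xd, Xd[:, best], L, L)
    return RankedFeatures(np.array(order), np.array(scores), "mRMR")


# ---------------------------------------------------------------------------
# Greedy forward selection


@dataclass
class SelectionResult:
    """Accepted subset (in acceptance order) and the full AUC trajectory.

    ``auc_curve`` records the cross-validated AUC of every *candidate*
    evaluation, accepted or not; ``accepted`` flags which candidates were
    kept.  The best AUC never decreases at accepted steps by construction.
    """

    selected: list[int]
    auc_curve: list[float]
    accepted: list[bool]
    best_auc: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def greedy_forward_select(X: np.ndarray, y: np.ndarray,
                          ranked: RankedFeatures,
                          cv: "classifier.CVSpec | None" = None,
                          eps: float = 1e-4) -> SelectionResult:
    """Walk a ranked feature list, keeping features whose addition improves AUC.

    The first ranked feature always starts the subset; each later feature is
    kept iff the mean k-fold CV AUC of the tentative subset exceeds the best
    AUC so far by more than ``eps``.  One fixed CV partition (from the spec
    seed) is reused for every candidate so the comparison is paired.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if len(ranked.order) == 0:
        raise ValueError("empty ranked list")
    cv = cv or classifier.CVSpec()
    folds = classifier.make_folds(y, cv)

    selected: list[int] = []
    curve: list[float] = []
    accepted: list[bool] = []
    best = -np.inf
    for j in ranked.order:
        candidate = selected + [int(j)]
        auc = classifier.cross_val_auc(X[:, candidate], y, cv, folds=folds)
        curve.append(auc)
        if not selected or auc > best + eps:
            selected.append(int(j))
            best = auc
            accepted.append(True)
        else:
            accepted.append(False)
    return SelectionResult(selected, curve, accepted, best)


def apply_selection(X: np.ndarray, selected: Sequence[int]) -> np.ndarray:
    """Column projection onto ``selected``, preserving their order."""
    X = np.asarray(X)
    selected = list(selected)
    if not selected:
        raise ValueError("empty feature selection (an empty model is forbidden)")
    if min(selected) < 0 or max(selected) >= X.shape[1]:
        raise ValueError(
            f"selection index out of range 0..{X.shape[1] - 1}: {selected}"
        )
    return X[:, selected]
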