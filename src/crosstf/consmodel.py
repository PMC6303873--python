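"""Cross-species transition matrices and the naive-Bayes conservation
classifier.

Each syntenic peak carries a chromatin-state pair (state in the peak's own
species, state of the mapped orthologous interval in the other species) and
a motif-occurrence pair (bool, bool).  The K x K state-pair and 2 x 2
motif-pair frequency matrices are tabulated separately for the syntenic
conserved (SC) and syntenic unconserved (SU) classes; their smoothed log2
ratio matrices are the classifier: a peak's score is the state log-odds
cell, the motif log-odds cell, or their sum, and ranking peaks by that
score yields the ROC.

Laplace smoothing (pseudocount 1 on counts) keeps empty cells finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "PeakTransitionFeatures",
    "state_transition_matrix",
    "transition_log_ratio",
    "NBConservationModel",
    "nb_train",
    "nb_score",
    "roc_auc",
    "evaluate",
]

Mode = Literal["state_only", "motif_only", "combined"]
MODES: tuple[Mode, ...] = ("motif_only", "state_only", "combined")


@dataclass(frozen=True)
class PeakTransitionFeatures:
    """Classifier features of one syntenic peak (states are 1-based)."""

    name: str
    klass: str  # SC | SU
    state_src: int
    state_dst: int
    motif_src: bool
    motif_dst: bool

    def __post_init__(self) -> None:
        if self.klass not in ("SC", "SU"):
            raise ValueError("class must be SC or SU")
        if self.state_src < 1 or self.state_dst < 1:
            raise ValueError("state ids are 1-based")


def _count_matrix(
    feats: Sequence[PeakTransitionFeatures], K: int, which: str
) -> np.ndarray:
    if which == "state":
        mat = np.zeros((K, K))
        for f in feats:
            if f.state_src > K or f.state_dst > K:
                raise ValueError(f"state id out of range for K={K}")
            # rows: other-species (target) state, columns: own-species state
            mat[f.state_dst - 1, f.state_src - 1] += 1
    else:
        mat = np.zeros((2, 2))
        for f in feats:
            mat[int(f.motif_dst), int(f.motif_src)] += 1
    return mat


def state_transition_matrix(
    feats: Sequence[PeakTransitionFeatures], K: int
) -> np.ndarray:
    """K x K fraction-of-peaks matrix for one class (cells sum to 1).

    Rows index the target-species state, columns the source-species state.
    """
    if not feats:
        raise ValueError("empty class")
    mat = _count_matrix(feats, K, "state")
    return mat / mat.sum()


def motif_transition_matrix(
    feats: Sequence[PeakTransitionFeatures],
) -> np.ndarray:
    if not feats:
        raise ValueError("empty class")
    mat = _count_matrix(feats, 2, "motif")
    return mat / mat.sum()


def transition_log_ratio(
    counts_sc: np.ndarray, counts_su: np.ndarray, alpha: float = 1.0
) -> np.ndarray:
    """Smoothed log2 ratio of the two classes' cell fractions.

    cell = log2( ((c_sc + a) / (N_sc + D*a)) / ((c_su + a) / (N_su + D*a)) )
    with D the number of cells; antisymmetric under class swap.
    """
    if counts_sc.shape != counts_su.shape:
        raise ValueError("shape mismatch")
    if alpha <= 0:
        raise ValueError("pseudocount must be positive")
    D = counts_sc.size
    f_sc = (counts_sc + alpha) / (counts_sc.sum() + D * alpha)
    f_su = (counts_su + alpha) / (counts_su.sum() + D * alpha)
    return np.log2(f_sc / f_su)


@dataclass
class NBConservationModel:
    """Additive log-odds scorer: state-pair term + motif-pair term."""

    state_log_odds: np.ndarray  # K x K
    motif_log_odds: np.ndarray  # 2 x 2
    alpha: float = 1.0

    @property
    def n_states(self) -> int:
        return len(self.state_log_odds)


def nb_train(
    feats_sc: Sequence[PeakTransitionFeatures],
    feats_su: Sequence[PeakTransitionFeatures],
    K: int,
    alpha: float = 1.0,
) -> NBConservationModel:
    if not feats_sc or not feats_su:
        raise ValueError("both classes must be non-empty")
    state_lor = transition_log_ratio(
        _count_matrix(feats_sc, K, "state"),
        _count_matrix(feats_su, K, "state"),
        alpha,
    )
    motif_lor = transition_log_ratio(
        _count_matrix(feats_sc, 2, "motif"),
        _count_matrix(feats_su, 2, "motif"),
        alpha,
    )
    return NBConservationModel(state_lor, motif_lor, alpha)


def nb_score(
    model: NBConservationModel,
    feats: Sequence[PeakTransitionFeatures],
    mode: Mode = "combined",
) -> np.ndarray:
    scores = np.zeros(len(feats))
    for i, f in enumerate(feats):
        if f.state_src > model.n_states or f.state_dst > model.n_states:
            raise ValueError(f"state id out of range for peak {f.name}")
        s = 0.0
        if mode in ("state_only", "combined"):
            s += model.state_log_odds[f.state_dst - 1, f.state_src - 1]
        if mode in ("motif_only", "combined"):
            s += model.motif_log_odds[int(f.motif_dst), int(f.motif_src)]
        scores[i] = s
    return scores


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann–Whitney) ROC AUC; tied scores count 1/2 per pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute AUC")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def _stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def evaluate(
    feats: Sequence[PeakTransitionFeatures],
    K: int,
    protocol: str = "resubstitution",
    seed: int = 0,
    modes: Sequence[Mode] = MODES,
    alpha: float = 1.0,
) -> dict:
    """AUC per scoring mode under a protocol.

    ``protocol`` is ``"resubstitution"`` (train and score on all peaks) or
    ``"kfold:K"`` (stratified by class; the reported AUC pools the held-out
    scores of all folds).  Resubstitution is optimistically biased; both are
    reported by the pipeline.
    """
    labels = np.array([1 if f.klass == "SC" else 0 for f in feats])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need both SC and SU peaks")
    result: dict = {"protocol": protocol, "auc": {}}
    if protocol == "resubstitution":
        sc = [f for f in feats if f.klass == "SC"]
        su = [f for f in feats if f.klass == "SU"]
        model = nb_train(sc, su, K, alpha)
        for mode in modes:
            scores = nb_score(model, feats, mode)
            result["auc"][mode] = roc_auc(scores, labels)
        return result
    if protocol.startswith("kfold"):
        k = int(protocol.split(":")[1]) if ":" in protocol else 5
        if min(labels.sum(), len(labels) - labels.sum()) < k:
            raise ValueError("too few peaks per class for this many folds")
        folds = _stratified_folds(labels, k, seed)
        pooled = {mode: np.zeros(len(feats)) for mode in modes}
        for fi, test_idx in enumerate(folds):
            test_mask = np.zeros(len(feats), dtype=bool)
            test_mask[test_idx] = True
            train = [f for i, f in enumerate(feats) if not test_mask[i]]
            test = [f for i, f in enumerate(feats) if test_mask[i]]
            tr_labels = labels[~test_mask]
            if tr_labels.sum() == 0 or (tr_labels == 0).sum() == 0:
                raise ValueError(
                    f"fold {fi} lacks a class; use fewer folds"
                )
            sc = [f for f in train if f.klass == "SC"]
            su = [f for f in train if f.klass == "SU"]
            model = nb_train(sc, su, K, alpha)
            for mode in modes:
                pooled[mode][test_mask] = nb_score(model, test, mode)
        for mode in modes:
            result["auc"][mode] = roc_auc(pooled[mode], labels)
        return result
    raise ValueError(f"unknown protocol {protocol!r}")
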