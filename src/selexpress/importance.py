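"""Bootstrap simulated-annealing feature importance for operator inducibility.

Which positions/characters separate inducible from uninducible operators?
For each of ``n_bootstrap`` resamples of the training set, simulated
annealing searches binary feature masks (one-hot columns on/off) for the
subset minimizing the cross-validated error of the fold-induction
regression.  The fraction of bootstraps in which a feature lands in the
best mask is its bagged frequency, and

    importance(i, j, k) = bagged_frequency(i, j) * observed_frequency(i, j, k)

for position i, character j in {A, T, G, C, -} and class k in
{inducible, uninducible}.  Scores are normalized per (position, class) and
rendered as class-specific PWMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .pwm import PositionWeightMatrix
from .regression import ALPHABET, one_hot_encode

CLASSES = ("inducible", "uninducible")


def split_classes(fold_inductions, threshold: float = 2.0):
    """Boolean inducible mask from a fold-induction threshold rule."""
    fi = np.asarray(fold_inductions, dtype=float)
    mask = fi >= threshold
    if mask.all() or not mask.any():
        raise ValueError(
            f"threshold {threshold} leaves an empty class "
            f"({int(mask.sum())} inducible of {len(fi)})"
        )
    return mask


def observed_frequency(sequences) -> np.ndarray:
    """(aligned_length, 5) character frequencies of a sequence set."""
    seqs = [str(s).upper() for s in sequences]
    L = len(seqs[0])
    out = np.zeros((L, 5))
    for s in seqs:
        for i, c in enumerate(s):
            out[i, ALPHABET.index(c)] += 1
    return out / len(seqs)


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the mask search.

    ``t0`` is relative to the initial (all-features) objective so the
    Metropolis acceptance probability is scale-free.
    """

    t0: float = 0.10
    alpha: float = 0.95
    n_iter: int = 500


def _cv_objective(X, y, mask, inner_folds=2, seed=0,
                  svr_params=dict(C=10.0, gamma="scale", epsilon=0.1)):
    """Normalized CV mean-squared error of the regression on masked features."""
    var = float(np.var(y))
    if var == 0:
        return 1.0
    if not mask.any():
        return 1.0
    Xm = X[:, mask]
    err = 0.0
    for tr, te in KFold(inner_folds, shuffle=True, random_state=seed).split(Xm):
        est = SVR(kernel="rbf", **svr_params)
        est.fit(Xm[tr], y[tr])
        err += float(((est.predict(Xm[te]) - y[te]) ** 2).sum())
    return err / (len(y) * var)


def anneal_select(
    X: np.ndarray,
    y: np.ndarray,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    objective=None,
    initial_mask: np.ndarray | None = None,
    return_history: bool = False,
):
    """Best-ever feature mask from Metropolis single-flip annealing.

    ``objective(mask) -> float`` is minimized; the default is the
    2-fold-CV normalized MSE of a fixed-hyperparameter SVR-RBF restricted
    to the masked features.  Temperature follows ``t0 * alpha**t`` (relative
    to the starting objective); t0 = 0 gives pure hill climbing.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    sched = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    if objective is None:
        objective = lambda m: _cv_objective(X, y, m, seed=seed)
    mask = (
        np.ones(X.shape[1], dtype=bool)
        if initial_mask is None
        else np.asarray(initial_mask, dtype=bool).copy()
    )
    cur = objective(mask)
    best_mask, best_obj = mask.copy(), cur
    scale = abs(cur) or 1.0
    history = [cur]
    for t in range(sched.n_iter):
        temp = sched.t0 * scale * sched.alpha**t
        j = rng.integers(X.shape[1])
        mask[j] = ~mask[j]
        new = objective(mask)
        delta = new - cur
        if delta <= 0 or (temp > 0 and rng.random() < np.exp(-delta / temp)):
            cur = new
            if cur < best_obj:
                best_obj, best_mask = cur, mask.copy()
        else:
            mask[j] = ~mask[j]  # reject
        history.append(cur)
    if return_history:
        return best_mask, np.asarray(history)
    return best_mask


def bagged_frequency(
    X: np.ndarray,
    y: np.ndarray,
    n_bootstrap: int = 100,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-feature selection frequency across bootstrap resamples."""
    rng = np.random.default_rng(seed)
    n = len(X)
    freq = np.zeros(X.shape[1])
    for b in range(n_bootstrap):
        idx = rng.integers(n, size=n)
        sub_seed = int(rng.integers(2**31 - 1))
        freq += anneal_select(X[idx], y[idx], schedule=schedule, seed=sub_seed)
    return freq / n_bootstrap


@dataclass
class ImportanceMatrix:
    """Position x character x class importance scores."""

    bagged: np.ndarray  # (L, 5)
    observed: dict  # class -> (L, 5)
    raw_scores: dict = field(init=False)  # class -> (L, 5), bagged * observed
    scores: dict = field(init=False)  # class -> (L, 5), column-normalized

    def __post_init__(self):
        self.raw_scores = {}
        self.scores = {}
        for cls in CLASSES:
            raw = self.bagged * self.observed[cls]
            self.raw_scores[cls] = raw
            norm = raw.copy()
            for i in range(len(norm)):
                tot = norm[i].sum()
                if tot <= 0:
                    warnings.warn(
                        f"all-zero importance column at position {i} ({cls}); "
                        "falling back to uniform"
                    )
                    norm[i] = 0.2
                else:
                    norm[i] = norm[i] / tot
            self.scores[cls] = norm

    def class_pwm(self, cls: str) -> PositionWeightMatrix:
        return PositionWeightMatrix(self.scores[cls], alphabet=ALPHABET)

    def differential(self) -> pd.DataFrame:
        """(position, character) rows sorted by |inducible - uninducible| score."""
        rows = []
        L = len(self.bagged)
        for i in range(L):
            for j, ch in enumerate(ALPHABET):
                a = self.scores["inducible"][i, j]
                b = self.scores["uninducible"][i, j]
                rows.append((i, ch, a, b, a - b))
        df = pd.DataFrame(
            rows, columns=["position", "character", "inducible", "uninducible", "diff"]
        )
        return df.reindex(
            df["diff"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        """Long format: position, character, class, bagged, observed, score."""
        rows = []
        for cls in CLASSES:
            for i in range(len(self.bagged)):
                for j, ch in enumerate(ALPHABET):
                    rows.append(
                        (i, ch, cls, self.bagged[i, j], self.observed[cls][i, j],
                         self.scores[cls][i, j])
                    )
        return pd.DataFrame(
            rows, columns=["position", "character", "class", "bagged", "observed", "score"]
        )


class FeatureImportanceModel:
    """Inducible-vs-uninducible feature importance analysis.

    Parameters
    ----------
    sequences : aligned gap-filled sequences
    fold_inductions : per-sequence fold-induction values
    threshold : fold-induction cutoff assigning the inducible class
    """

    def __init__(self, sequences, fold_inductions, threshold: float = 2.0):
        self.sequences = [str(s).upper() for s in sequences]
        self.fold_inductions = np.asarray(fold_inductions, dtype=float)
        self.threshold = threshold
        self.inducible_mask = split_classes(self.fold_inductions, threshold)

    def fit(
        self,
        n_bootstrap: int = 100,
        schedule: AnnealSchedule | None = None,
        seed: int = 0,
    ) -> "ImportanceResults":
        data = one_hot_encode(self.sequences, self.fold_inductions)
        bag = bagged_frequency(
            data.X, data.targets, n_bootstrap=n_bootstrap, schedule=schedule, seed=seed
        ).reshape(data.aligned_length, 5)
        seqs = np.asarray(self.sequences, dtype=object)
        observed = {
            "inducible": observed_frequency(seqs[self.inducible_mask]),
            "uninducible": observed_frequency(seqs[~self.inducible_mask]),
        }
        matrix = ImportanceMatrix(bagged=bag, observed=observed)
        return ImportanceResults(self, matrix, n_bootstrap=n_bootstrap, seed=seed)


@dataclass
class ImportanceResults:
    model: FeatureImportanceModel
    matrix: ImportanceMatrix
    n_bootstrap: int
    seed: int

    def summary(self) -> str:
        n_ind = int(self.model.inducible_mask.sum())
        n_un = len(self.model.sequences) - n_ind
        top = self.matrix.differential().head(8)
        return "\n".join(
            [
                "Feature importance (bootstrap simulated annealing)",
                "=" * 50,
                f"classes: {n_ind} inducible / {n_un} uninducible "
                f"(threshold {self.model.threshold})",
                f"bootstraps: {self.n_bootstrap}",
                "",
                "top differential (position, character) scores:",
                top.to_string(index=False),
            ]
        )


__all__ = [
    "AnnealSchedule",
    "CLASSES",
    "FeatureImportanceModel",
    "ImportanceMatrix",
    "ImportanceResults",
    "anneal_select",
    "bagged_frequency",
    "observed_frequency",
    "split_classes",
]
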