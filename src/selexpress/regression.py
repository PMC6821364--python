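"""Sequence-to-fold-induction regression.

Gap-filled (aligned) operator sequences are one-hot encoded over the
five-character alphabet {A, T, G, C, -} and fed to support-vector
regression with an RBF kernel.  Hyperparameters are picked by inner
cross-validation, out-of-fold predictions are produced for every training
sequence under 5-fold CV, and a 10% holdout, split off before any model
sees the data, measures generalization once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR

#: Fixed encoding order of the gap-filled alphabet.
ALPHABET = "ATGC-"
_CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}

DEFAULT_PARAM_GRID = {
    "C": np.geomspace(0.1, 1000.0, 5).tolist(),
    "gamma": np.geomspace(1e-3, 10.0, 5).tolist(),
    "epsilon": [0.01, 0.1, 1.0],
}


def one_hot_encode(sequences, targets=None, ids=None) -> "EncodedDataset":
    """Binary indicator encoding, one 5-block per aligned position."""
    seqs = [str(s).upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences to encode")
    L = len(seqs[0])
    X = np.zeros((len(seqs), 5 * L), dtype=np.float64)
    for r, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError(f"sequence {r} has length {len(s)}, expected {L}")
        for i, c in enumerate(s):
            j = _CHAR_INDEX.get(c)
            if j is None:
                raise ValueError(f"illegal character {c!r} at position {i} of sequence {r}")
            X[r, 5 * i + j] = 1.0
    return EncodedDataset(
        X=X,
        targets=None if targets is None else np.asarray(targets, dtype=float),
        ids=list(ids) if ids is not None else [str(i) for i in range(len(seqs))],
        aligned_length=L,
    )


def decode_one_hot(row: np.ndarray) -> str:
    """Inverse of the encoding for a single feature row."""
    row = np.asarray(row)
    if row.size % 5:
        raise ValueError("row length must be a multiple of 5")
    L = row.size // 5
    out = []
    for i in range(L):
        block = row[5 * i : 5 * i + 5]
        if block.sum() != 1:
            raise ValueError(f"block {i} is not a one-hot indicator")
        out.append(ALPHABET[int(np.argmax(block))])
    return "".join(out)


@dataclass
class EncodedDataset:
    """One-hot matrix with targets and split bookkeeping."""

    X: np.ndarray
    targets: np.ndarray | None
    ids: list
    aligned_length: int
    holdout_mask: np.ndarray | None = None
    fold_ids: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.X)

    def make_splits(self, seed: int = 0, holdout_fraction: float = 0.10, n_folds: int = 5):
        """Assign the holdout mask and CV fold labels (in place)."""
        n = len(self)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_hold = int(round(holdout_fraction * n))
        self.holdout_mask = np.zeros(n, dtype=bool)
        self.holdout_mask[perm[:n_hold]] = True
        rest = perm[n_hold:]
        self.fold_ids = np.full(n, -1, dtype=int)
        for k, chunk in enumerate(np.array_split(rest, n_folds)):
            self.fold_ids[chunk] = k
        return self


def evaluate(predictions, targets) -> dict:
    """Pearson and Spearman correlation of predictions vs targets."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(p) == 0 or np.std(t) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return {
        "pearson": float(pearsonr(p, t).statistic),
        "spearman": float(spearmanr(p, t).statistic),
    }


class InductionRegressionModel:
    """SVR-RBF model predicting fold induction from aligned sequences."""

    def __init__(self, sequences, fold_inductions, ids=None):
        self.sequences = list(sequences)
        self.fold_inductions = np.asarray(fold_inductions, dtype=float)
        if len(self.sequences) != len(self.fold_inductions):
            raise ValueError("sequences and fold_inductions must align")
        if not np.isfinite(self.fold_inductions).all():
            raise ValueError("targets must be finite")
        self.ids = ids

    @classmethod
    def from_alignment(cls, aligned_records, labels: pd.DataFrame):
        """Build from (id, sequence) records and an id-keyed label table."""
        lab = labels.set_index(labels.columns[0])[labels.columns[1]]
        ids, seqs, fis = [], [], []
        for rid, seq in aligned_records:
            if rid not in lab.index:
                raise KeyError(f"no fold-induction label for record {rid!r}")
            ids.append(rid)
            seqs.append(seq)
            fis.append(float(lab.loc[rid]))
        return cls(seqs, fis, ids=ids)

    def fit(
        self,
        seed: int = 0,
        n_folds: int = 5,
        holdout_fraction: float = 0.10,
        inner_folds: int = 3,
        param_grid: dict | None = None,
        log_target: bool = False,
    ) -> "SequenceRegressionResults":
        if len(self.sequences) < 20:
            raise ValueError("need at least 20 sequences to train")
        grid = DEFAULT_PARAM_GRID if param_grid is None else param_grid
        data = one_hot_encode(self.sequences, self.fold_inductions, self.ids)
        data.make_splits(seed=seed, holdout_fraction=holdout_fraction, n_folds=n_folds)
        y = np.log(data.targets) if log_target else data.targets

        work = ~data.holdout_mask
        oof = np.full(len(data), np.nan)
        fold_params: list[dict] = []
        for k in range(n_folds):
            test = work & (data.fold_ids == k)
            train = work & (data.fold_ids != k)
            if test.sum() == 0:
                continue
            search = GridSearchCV(
                SVR(kernel="rbf"),
                grid,
                cv=KFold(inner_folds, shuffle=True, random_state=seed + k),
                scoring="neg_mean_squared_error",
                n_jobs=1,
            )
            search.fit(data.X[train], y[train])
            oof[test] = search.predict(data.X[test])
            fold_params.append(search.best_params_)

        final = GridSearchCV(
            SVR(kernel="rbf"),
            grid,
            cv=KFold(inner_folds, shuffle=True, random_state=seed),
            scoring="neg_mean_squared_error",
            n_jobs=1,
        )
        final.fit(data.X[work], y[work])
        holdout_pred = (
            final.predict(data.X[data.holdout_mask])
            if data.holdout_mask.any()
            else np.empty(0)
        )
        if log_target:
            oof = np.exp(oof)
            holdout_pred = np.exp(holdout_pred)
        return SequenceRegressionResults(
            model=self,
            data=data,
            oof_predictions=oof,
            holdout_predictions=holdout_pred,
            fold_params=fold_params,
            final_params=final.best_params_,
            estimator=final.best_estimator_,
            log_target=log_target,
        )


@dataclass
class SequenceRegressionResults:
    model: InductionRegressionModel
    data: EncodedDataset
    oof_predictions: np.ndarray
    holdout_predictions: np.ndarray
    fold_params: list
    final_params: dict
    estimator: SVR
    log_target: bool = False
    _metrics: dict = field(default_factory=dict, repr=False)

    @property
    def cv_metrics(self) -> dict:
        """Correlations of out-of-fold predictions (non-holdout sequences)."""
        if "cv" not in self._metrics:
            m = ~self.data.holdout_mask
            self._metrics["cv"] = evaluate(
                self.oof_predictions[m], self.data.targets[m]
            )
        return self._metrics["cv"]

    @property
    def holdout_metrics(self) -> dict:
        if "holdout" not in self._metrics:
            h = self.data.holdout_mask
            self._metrics["holdout"] = evaluate(
                self.holdout_predictions, self.data.targets[h]
            )
        return self._metrics["holdout"]

    def predict(self, sequences) -> np.ndarray:
        enc = one_hot_encode(sequences)
        pred = self.estimator.predict(enc.X)
        return np.exp(pred) if self.log_target else pred

    def scatter_table(self) -> pd.DataFrame:
        """Predicted vs experimental fold induction per sequence."""
        rows = []
        for i in range(len(self.data)):
            if self.data.holdout_mask[i]:
                pred, split = None, "holdout"
            else:
                pred, split = self.oof_predictions[i], "cv"
            rows.append((self.data.ids[i], self.data.targets[i], pred, split))
        df = pd.DataFrame(rows, columns=["id", "observed", "predicted", "split"])
        h = self.data.holdout_mask
        df.loc[h, "predicted"] = self.holdout_predictions
        return df

    def summary(self) -> str:
        cv = self.cv_metrics
        lines = [
            "Sequence -> fold-induction SVR (RBF kernel)",
            "=" * 46,
            f"sequences: {len(self.data)}  aligned length: {self.data.aligned_length}"
            f"  holdout: {int(self.data.holdout_mask.sum())}",
            f"selected hyperparameters: {self.final_params}",
            f"out-of-fold   Spearman rho = {cv['spearman']:.3f}   Pearson r = {cv['pearson']:.3f}",
        ]
        if self.data.holdout_mask.any():
            ho = self.holdout_metrics
            lines.append(
                f"holdout       Spearman rho = {ho['spearman']:.3f}   Pearson r = {ho['pearson']:.3f}"
            )
        return "\n".join(lines)


__all__ = [
    "ALPHABET",
    "DEFAULT_PARAM_GRID",
    "EncodedDataset",
    "InductionRegressionModel",
    "SequenceRegressionResults",
    "decode_one_hot",
    "evaluate",
    "one_hot_encode",
]
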