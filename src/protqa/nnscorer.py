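"""Feature assembly and the missing-feature-tolerant neural-network scorer.

Per residue, up to 47 features are assembled in a fixed order:

====== ==========================================================
index  feature
====== ==========================================================
0-5    statistical potentials (all_atom, cb_interaction, reduced,
       packing, cb_packing, torsion), spherically smoothed
6      secondary-structure agreement (smoothed)
7      accessibility agreement (smoothed)
8      relative solvent accessibility (smoothed)
9      clash score (smoothed)
10     residue count N (not smoothed)
11-18  DisCo score + 7 reliability features
19-26  full-model averages of features 0-7
27-46  one-hot amino-acid encoding
====== ==========================================================

Invalid features are encoded as NaN.  Four optional feature blocks —
torsion, SS-prediction-dependent, ACC-prediction-dependent and DisCo —
define 2^4 = 16 feature groups; an :class:`NNScorer` holds one small
feed-forward network per group and dispatches every residue to the network
matching its validity pattern, so missing inputs degrade gracefully
instead of invalidating the residue.

Networks share the topology [n, 20, 20, 20, 1] (ReLU hidden layers,
linear output clamped to [0, 1]) and are trained with RMSprop on a mean
squared error loss for 100 epochs with batch size 400, all seeded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .constants import AMINO_ACIDS
from .local_features import spherical_smooth
from .structure import Structure

logger = logging.getLogger(__name__)

N_FEATURES = 47
_AA_POS = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Optional feature blocks (column indices) in bit order.
BLOCKS = {
    "torsion": (5,),
    "ss": (6, 25),
    "acc": (7, 26),
    "disco": tuple(range(11, 19)),
}
BLOCK_ORDER = ("torsion", "ss", "acc", "disco")
_OPTIONAL_COLS = sorted(c for cols in BLOCKS.values() for c in cols)
MANDATORY_COLS = tuple(c for c in range(N_FEATURES) if c not in _OPTIONAL_COLS)
N_GROUPS = 2 ** len(BLOCK_ORDER)

SMOOTH_SIGMA = 5.0
_AVG_SOURCE = (0, 1, 2, 3, 4, 5, 6, 7)   # features averaged into 19-26


def group_columns(group: int) -> tuple:
    """Input columns of the network for a feature group (sorted)."""
    cols = list(MANDATORY_COLS)
    for bit, name in enumerate(BLOCK_ORDER):
        if group >> bit & 1:
            cols.extend(BLOCKS[name])
    return tuple(sorted(cols))


def group_of_rows(X: np.ndarray) -> np.ndarray:
    """Feature-group id per row from the NaN pattern of optional blocks."""
    g = np.zeros(len(X), dtype=int)
    for bit, name in enumerate(BLOCK_ORDER):
        cols = list(BLOCKS[name])
        valid = np.isfinite(X[:, cols]).all(axis=1)
        g |= valid.astype(int) << bit
    return g


def assemble_features(model: Structure, potential_scores: dict,
                      ss_agreement=None, acc_agreement=None,
                      rel_accessibility=None, clash=None, residue_n=None,
                      disco_result=None,
                      smooth_sigma: float = SMOOTH_SIGMA) -> np.ndarray:
    """Build the (n_residues, 47) feature matrix with NaN for invalid
    entries.  Every per-residue trace except N and the DisCo block is
    spherically smoothed before assembly; full-model averages are taken
    over residues with valid (smoothed) values."""
    n = len(model)
    X = np.full((n, N_FEATURES), np.nan)

    def smoothed(v):
        # smoothing interpolates spatially, but a residue whose raw value
        # is invalid keeps an invalid feature (validity drives dispatch)
        out = spherical_smooth(v, model, sigma=smooth_sigma)
        out[~np.isfinite(np.asarray(v, dtype=float))] = np.nan
        return out

    terms = ["all_atom", "cb_interaction", "reduced", "packing",
             "cb_packing", "torsion"]
    for col, term in enumerate(terms):
        v = potential_scores.get(term)
        if v is not None:
            X[:, col] = smoothed(np.asarray(v, dtype=float))
    if ss_agreement is not None:
        X[:, 6] = smoothed(np.asarray(ss_agreement, dtype=float))
    if acc_agreement is not None:
        X[:, 7] = smoothed(np.asarray(acc_agreement, dtype=float))
    if rel_accessibility is not None:
        X[:, 8] = smoothed(np.asarray(rel_accessibility, dtype=float))
    if clash is not None:
        X[:, 9] = smoothed(np.asarray(clash, dtype=float))
    if residue_n is not None:
        X[:, 10] = np.asarray(residue_n, dtype=float)
    if disco_result is not None:
        X[:, 11:19] = disco_result.feature_matrix()

    # full-model averages of the potential and agreement terms
    with np.errstate(invalid="ignore"):
        for k, src in enumerate(_AVG_SOURCE):
            col_vals = X[:, src]
            if np.isfinite(col_vals).any():
                X[:, 19 + k] = np.nanmean(col_vals)
            elif src <= 5:
                # potentials are a mandatory block: neutral value when a
                # term yields no observation anywhere in the model
                X[:, 19 + k] = 0.0

    for r in model:
        pos = _AA_POS.get(r.aa)
        if pos is not None:
            X[r.index, 27 + pos] = 1.0
    X[:, 27:47] = np.nan_to_num(X[:, 27:47])

    # mandatory per-residue features: impute residue-local gaps with the
    # model average of the feature (keeps the block valid)
    for col in MANDATORY_COLS:
        col_vals = X[:, col]
        bad = ~np.isfinite(col_vals)
        if bad.any():
            fill = np.nanmean(col_vals) if np.isfinite(col_vals).any() else 0.0
            X[bad, col] = fill
    return X


def mask_block(X: np.ndarray, block: str) -> np.ndarray:
    """Copy of X with one optional block invalidated (ablation helper)."""
    out = X.copy()
    out[:, list(BLOCKS[block])] = np.nan
    return out


# ---------------------------------------------------------------------------
# Minimal feed-forward network (ReLU hidden layers, linear output)
# ---------------------------------------------------------------------------

class _MLP:
    def __init__(self, sizes, rng: np.random.Generator):
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / fan_in)  # He-uniform
            self.weights.append(rng.uniform(-limit, limit,
                                            size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x):
        acts = [x]
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            if k < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        return acts

    def predict(self, x):
        return self.forward(x)[-1][:, 0]

    def train(self, x, y, *, epochs, batch_size, lr, optimizer, loss,
              rng: np.random.Generator):
        n = len(x)
        caches = [np.zeros_like(w) for w in self.weights]
        bcaches = [np.zeros_like(b) for b in self.biases]
        m1 = [np.zeros_like(w) for w in self.weights]
        bm1 = [np.zeros_like(b) for b in self.biases]
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = order[start:start + batch_size]
                xb, yb = x[batch], y[batch]
                acts = self.forward(xb)
                pred = acts[-1][:, 0]
                if loss == "mse":
                    delta = (2.0 * (pred - yb) / len(batch))[:, None]
                elif loss == "absolute":
                    delta = (np.sign(pred - yb) / len(batch))[:, None]
                else:
                    raise ValueError(f"unknown loss {loss!r}")
                grads_w, grads_b = [], []
                for k in range(len(self.weights) - 1, -1, -1):
                    grads_w.insert(0, acts[k].T @ delta)
                    grads_b.insert(0, delta.sum(axis=0))
                    if k > 0:
                        delta = (delta @ self.weights[k].T) * (acts[k] > 0)
                step += 1
                for k in range(len(self.weights)):
                    gw, gb = grads_w[k], grads_b[k]
                    if optimizer == "rmsprop":
                        caches[k] = 0.9 * caches[k] + 0.1 * gw * gw
                        bcaches[k] = 0.9 * bcaches[k] + 0.1 * gb * gb
                        self.weights[k] -= lr * gw / (np.sqrt(caches[k])
                                                      + 1e-8)
                        self.biases[k] -= lr * gb / (np.sqrt(bcaches[k])
                                                     + 1e-8)
                    elif optimizer == "adam":
                        b1, b2 = 0.9, 0.999
                        m1[k] = b1 * m1[k] + (1 - b1) * gw
                        caches[k] = b2 * caches[k] + (1 - b2) * gw * gw
                        bm1[k] = b1 * bm1[k] + (1 - b1) * gb
                        bcaches[k] = b2 * bcaches[k] + (1 - b2) * gb * gb
                        mh = m1[k] / (1 - b1 ** step)
                        vh = caches[k] / (1 - b2 ** step)
                        bmh = bm1[k] / (1 - b1 ** step)
                        bvh = bcaches[k] / (1 - b2 ** step)
                        self.weights[k] -= lr * mh / (np.sqrt(vh) + 1e-8)
                        self.biases[k] -= lr * bmh / (np.sqrt(bvh) + 1e-8)
                    else:
                        raise ValueError(f"unknown optimizer {optimizer!r}")


# ---------------------------------------------------------------------------
# NNScorer
# ---------------------------------------------------------------------------

class NNScorer(BaseEstimator):
    """Ensemble of 16 per-feature-group networks predicting per-residue
    lDDT (scikit-learn estimator interface).

    ``X`` is the (n, 47) feature matrix with NaN marking invalid features;
    the NaN pattern of the optional blocks selects the network.  Groups
    with fewer than ``min_group_rows`` training rows are not trained and
    dispatch to the richest trained sub-group at prediction time.
    """

    def __init__(self, hidden_layers=(20, 20, 20), epochs: int = 100,
                 batch_size: int = 400, lr: float = 1e-3,
                 optimizer: str = "rmsprop", loss: str = "mse",
                 seed: int = 0, min_group_rows: int = 400):
        self.hidden_layers = hidden_layers
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.optimizer = optimizer
        self.loss = loss
        self.seed = seed
        self.min_group_rows = min_group_rows

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} feature columns")
        valid_y = np.isfinite(y)
        X, y = X[valid_y], y[valid_y]
        if len(X) == 0:
            raise ValueError("no training rows with valid targets")
        row_groups = group_of_rows(X)
        self.networks_ = {}
        self.scalers_ = {}
        self.trained_groups_ = []
        for g in range(N_GROUPS):
            # rows from richer groups participate with this group's subset
            rows = (row_groups & g) == g
            cols = group_columns(g)
            if rows.sum() < max(self.min_group_rows, 2) and g != 0:
                logger.warning("feature group %d: %d rows, falls back",
                               g, int(rows.sum()))
                continue
            xg = X[rows][:, cols]
            mean = xg.mean(axis=0)
            std = xg.std(axis=0)
            std[std == 0] = 1.0
            xg = (xg - mean) / std
            seed_g = (int(self.seed) * 1000003 + g) % (2 ** 31)
            rng = np.random.default_rng(seed_g)
            net = _MLP([len(cols), *self.hidden_layers, 1], rng)
            net.train(xg, y[rows], epochs=self.epochs,
                      batch_size=self.batch_size, lr=self.lr,
                      optimizer=self.optimizer, loss=self.loss, rng=rng)
            self.networks_[g] = net
            self.scalers_[g] = (mean, std)
            self.trained_groups_.append(g)
        if not self.networks_:
            raise ValueError("no feature group could be trained")
        return self

    def _dispatch(self, group: int) -> int:
        """Trained group used for rows of *group*: the group itself, or the
        largest trained subset of its blocks (ties -> lowest id)."""
        if group in self.networks_:
            return group
        candidates = [g for g in self.networks_ if (group & g) == g]
        return max(candidates, key=lambda g: (bin(g).count("1"), -g))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        row_groups = group_of_rows(X)
        for g in np.unique(row_groups):
            use = self._dispatch(int(g))
            rows = row_groups == g
            cols = group_columns(use)
            mean, std = self.scalers_[use]
            xg = (X[rows][:, cols] - mean) / std
            out[rows] = self.networks_[use].predict(np.nan_to_num(xg))
        return np.clip(out, 0.0, 1.0)

    # -- checkpointing -----------------------------------------------------

    def to_dict(self) -> dict:
        nets = {}
        for g, net in self.networks_.items():
            mean, std = self.scalers_[g]
            nets[str(g)] = {
                "weights": [w.tolist() for w in net.weights],
                "biases": [b.tolist() for b in net.biases],
                "mean": mean.tolist(),
                "std": std.tolist(),
            }
        return {"format_version": 1, "params": self.get_params(),
                "networks": nets}

    @classmethod
    def from_dict(cls, d) -> "NNScorer":
        params = dict(d["params"])
        params["hidden_layers"] = tuple(params["hidden_layers"])
        obj = cls(**params)
        obj.networks_ = {}
        obj.scalers_ = {}
        for g_str, payload in d["networks"].items():
            g = int(g_str)
            net = _MLP.__new__(_MLP)
            net.weights = [np.asarray(w) for w in payload["weights"]]
            net.biases = [np.asarray(b) for b in payload["biases"]]
            obj.networks_[g] = net
            obj.scalers_[g] = (np.asarray(payload["mean"]),
                               np.asarray(payload["std"]))
        obj.trained_groups_ = sorted(obj.networks_)
        return obj

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "NNScorer":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Datasets and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ResidueDataset:
    """Per-residue rows with model/target provenance."""
    X: np.ndarray
    y: np.ndarray
    target_ids: np.ndarray
    model_ids: np.ndarray

    def __len__(self):
        return len(self.y)

    @staticmethod
    def concatenate(datasets) -> "ResidueDataset":
        return ResidueDataset(
            X=np.concatenate([d.X for d in datasets]),
            y=np.concatenate([d.y for d in datasets]),
            target_ids=np.concatenate([d.target_ids for d in datasets]),
            model_ids=np.concatenate([d.model_ids for d in datasets]),
        )

    def subset(self, rows) -> "ResidueDataset":
        return ResidueDataset(self.X[rows], self.y[rows],
                              self.target_ids[rows], self.model_ids[rows])


def blend_datasets(a: ResidueDataset, b: ResidueDataset,
                   fraction: float = 0.5, seed: int = 0) -> ResidueDataset:
    """Mixed training set: *fraction* of the rows of each input dataset."""
    rng = np.random.default_rng(seed)
    rows_a = rng.choice(len(a), size=int(round(fraction * len(a))),
                        replace=False)
    rows_b = rng.choice(len(b), size=int(round(fraction * len(b))),
                        replace=False)
    return ResidueDataset.concatenate([a.subset(np.sort(rows_a)),
                                       b.subset(np.sort(rows_b))])


def target_folds(target_ids, k: int, seed: int = 0) -> list:
    """Partition unique target ids into *k* folds (never splits a target)."""
    unique = sorted(set(map(str, target_ids)))
    if len(unique) < k:
        raise ValueError(f"need at least {k} targets, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    folds = [[] for _ in range(k)]
    for pos, t_idx in enumerate(order):
        folds[pos % k].append(unique[t_idx])
    return [sorted(f) for f in folds]


def cross_validate(dataset: ResidueDataset, k: int = 5, seed: int = 0,
                   train_dataset: ResidueDataset | None = None,
                   **scorer_params):
    """k-fold cross-validation split on modelling targets.

    Rows of ``train_dataset`` (defaults to *dataset*) are used for
    training, excluding the validation fold's targets; validation
    predictions are pooled over folds.  Returns (predictions aligned with
    *dataset*, list of per-fold target lists).
    """
    train_dataset = train_dataset or dataset
    folds = target_folds(dataset.target_ids, k, seed=seed)
    preds = np.full(len(dataset), np.nan)
    for fold_idx, held_out in enumerate(folds):
        held = set(held_out)
        train_rows = ~np.isin(train_dataset.target_ids, list(held))
        scorer = NNScorer(seed=seed * 31 + fold_idx, **scorer_params)
        scorer.fit(train_dataset.X[train_rows],
                   train_dataset.y[train_rows])
        val_rows = np.isin(dataset.target_ids, list(held))
        preds[val_rows] = scorer.predict(dataset.X[val_rows])
    return preds, folds
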