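"""Pathway-masked feed-forward classifier.

The model is a small dense network whose first layer is the *pathway layer*:
one node per gene set, connected only to that set's member genes.  The
connectivity is fixed by a binary :class:`~pathdeep.mask.MembershipMask`;
masking is enforced by elementwise multiplication of the first-layer weight
matrix inside the forward pass, so gradients to forbidden weights vanish
identically and those weights stay exactly zero through training.

For a standardized sample ``s`` the pre-activation value of pathway node ``i``
is the pathway index

    P_si = sum_j g_sj * W_ji + b_i

(only member genes contribute because non-member weights are zero).  A ReLU is
applied to the pathway layer before the dense head; the head ends in a single
sigmoid unit giving the case probability.  Training minimizes binary
cross-entropy with Adam, with optional early stopping on a validation
carve-out of the training fold.  Everything is plain numpy and deterministic
under fixed seeds.

The public surface follows the statsmodels convention: a :class:`PathDeep`
model object is built from data plus a mask, and :meth:`PathDeep.fit` returns
a :class:`PathDeepResults` carrying the trained parameters, accuracy helpers,
attribution indices, and ``summary()``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import ExpressionDataset
from .gmt import GeneSetCollection, intersect_with_universe
from .mask import MembershipMask, build_mask, full_mask

__all__ = [
    "TrainConfig",
    "PathDeep",
    "PathDeepResults",
    "build_fully_connected",
    "load_results",
]

logger = logging.getLogger(__name__)

DEFAULT_HEAD: tuple[int, ...] = (128, 32, 1)


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``head_spec`` lists the dense layer widths after the pathway layer and
    must end in the single sigmoid output unit, e.g. ``(128, 32, 1)``.
    ``early_stop_patience`` epochs without validation-loss improvement stop
    training early (a stratification-free random ``validation_fraction`` of
    the training fold is carved out); set patience to 0 to disable.
    """

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    validation_fraction: float = 0.1
    head_spec: tuple[int, ...] = DEFAULT_HEAD
    seed: int = 0

    def __post_init__(self) -> None:
        self.head_spec = tuple(int(h) for h in self.head_spec)
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if not (0 <= self.early_stop_patience <= max(self.max_epochs, 0)):
            raise ValueError("early_stop_patience must lie in [0, max_epochs]")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if not self.head_spec:
            raise ValueError("head_spec must not be empty")
        if self.head_spec[-1] != 1:
            raise ValueError("head_spec must end in a single output unit")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _init_params(mask: MembershipMask, head_spec: Sequence[int], seed: int
                 ) -> dict[str, np.ndarray | list]:
    """Seeded initialization; masked first-layer entries start (and stay) at 0."""
    head_spec = tuple(head_spec)
    if not head_spec or head_spec[-1] != 1:
        raise ValueError("head_spec must be non-empty and end in a single unit")
    rng = np.random.default_rng(seed)
    m = mask.matrix.astype(float)
    # He-style scale per pathway column using its in-degree
    deg = m.sum(axis=0)
    scale = np.where(deg > 0, np.sqrt(2.0 / np.maximum(deg, 1)), 0.0)
    w1 = rng.standard_normal(m.shape) * scale[None, :] * m
    b1 = np.zeros(mask.n_pathways)
    head_w: list[np.ndarray] = []
    head_b: list[np.ndarray] = []
    fan_in = mask.n_pathways
    for width in head_spec:
        head_w.append(rng.standard_normal((fan_in, width)) * np.sqrt(2.0 / fan_in))
        head_b.append(np.zeros(width))
        fan_in = width
    return {"w1": w1, "b1": b1, "head_w": head_w, "head_b": head_b}


def _clone(params: dict) -> dict:
    return {
        "w1": params["w1"].copy(),
        "b1": params["b1"].copy(),
        "head_w": [w.copy() for w in params["head_w"]],
        "head_b": [b.copy() for b in params["head_b"]],
    }


def _forward(params: dict, m: np.ndarray, x: np.ndarray
             ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return output probabilities and cached layer activations."""
    z1 = x @ (params["w1"] * m) + params["b1"]
    h = _relu(z1)
    cache = [x, z1, h]
    n_head = len(params["head_w"])
    for k in range(n_head):
        z = h @ params["head_w"][k] + params["head_b"][k]
        if k < n_head - 1:
            h = _relu(z)
            cache.extend([z, h])
        else:
            cache.append(z)
            h = expit(z)
    return h.ravel(), cache


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class _Adam:
    def __init__(self, shapes: list[tuple[int, ...]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _backward(params: dict, m: np.ndarray, cache: list[np.ndarray],
              p: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Gradients of mean BCE; first-layer gradient is multiplied by the mask."""
    n = len(y)
    x, z1, h1 = cache[0], cache[1], cache[2]
    n_head = len(params["head_w"])
    # activations entering each head layer: h1, then post-ReLU hidden ones
    hs = [h1] + [cache[3 + 2 * k + 1] for k in range(n_head - 1)]
    delta = ((p - y) / n)[:, None]  # d loss / d z_out, via sigmoid+BCE
    grads_w: list[np.ndarray] = [None] * n_head
    grads_b: list[np.ndarray] = [None] * n_head
    for k in range(n_head - 1, -1, -1):
        grads_w[k] = hs[k].T @ delta
        grads_b[k] = delta.sum(axis=0)
        if k > 0:
            z_prev = cache[3 + 2 * (k - 1)]  # pre-activation of hidden layer k-1
            delta = (delta @ params["head_w"][k].T) * (z_prev > 0)
    # back through pathway layer
    delta1 = (delta @ params["head_w"][0].T) * (z1 > 0) if n_head >= 1 else delta
    gw1 = (x.T @ delta1) * m
    gb1 = delta1.sum(axis=0)
    return [gw1, gb1] + grads_w + grads_b


class PathDeep:
    """Pathway-masked classifier bound to a dataset.

    Parameters
    ----------
    data
        Standardized :class:`ExpressionDataset`; its gene order must equal
        the mask's gene order.
    mask
        Gene x pathway connectivity (biological or random-linked).
    head_spec
        Dense widths after the pathway layer, ending in the 1-unit output.
    seed
        Seed for parameter initialization.
    """

    def __init__(self, data: ExpressionDataset, mask: MembershipMask,
                 head_spec: Sequence[int] = DEFAULT_HEAD, seed: int = 0):
        if list(data.gene_symbols) != list(mask.gene_order):
            raise ValueError("dataset gene order does not match mask gene order")
        self.data = data
        self.mask = mask
        self.head_spec = tuple(head_spec)
        self.seed = int(seed)
        self._init = _init_params(mask, self.head_spec, seed)

    @classmethod
    def from_collection(cls, data: ExpressionDataset,
                        collection: GeneSetCollection,
                        head_spec: Sequence[int] = DEFAULT_HEAD,
                        seed: int = 0) -> "PathDeep":
        """Intersect a collection with the dataset's genes, subset the columns
        to the surviving members (sorted), and build the masked model."""
        from .data import subset_genes

        reduced, retained = intersect_with_universe(collection, data.gene_symbols)
        sub = subset_genes(data, retained)
        return cls(sub, build_mask(reduced, retained), head_spec=head_spec, seed=seed)

    @property
    def initial_params(self) -> dict:
        return _clone(self._init)

    def predict_proba_with(self, params: dict, values: np.ndarray) -> np.ndarray:
        p, _ = _forward(params, self.mask.matrix.astype(float), np.asarray(values, float))
        return p

    def fit(self, train_idx: Sequence[int] | None = None,
            config: TrainConfig | None = None) -> "PathDeepResults":
        """Train from the seeded initialization on the given sample rows.

        Deterministic for a fixed (model seed, config): initialization comes
        from the model seed, batch order and the validation carve-out from
        ``config.seed``.
        """
        config = config or TrainConfig(head_spec=self.head_spec)
        if tuple(config.head_spec) != self.head_spec:
            config = TrainConfig(**{**config.__dict__, "head_spec": self.head_spec})
        idx = (np.arange(self.data.n_samples) if train_idx is None
               else np.asarray(list(train_idx), dtype=int))
        y_all = self.data.labels[idx]
        if len(np.unique(y_all)) < 2:
            raise ValueError("training fold must contain both classes")
        x_all = self.data.values[idx]

        rng = np.random.default_rng(config.seed)
        n = len(idx)
        n_val = int(round(config.validation_fraction * n))
        use_val = config.early_stop_patience > 0 and n_val >= 2
        if use_val:
            perm = rng.permutation(n)
            val_rows, tr_rows = perm[:n_val], perm[n_val:]
            if len(np.unique(y_all[tr_rows])) < 2:
                use_val = False
        if not use_val:
            tr_rows = np.arange(n)
            val_rows = np.array([], dtype=int)
        x_tr, y_tr = x_all[tr_rows], y_all[tr_rows]
        x_va, y_va = x_all[val_rows], y_all[val_rows]

        m = self.mask.matrix.astype(float)
        params = _clone(self._init)
        flat = [params["w1"], params["b1"], *params["head_w"], *params["head_b"]]
        opt = _Adam([p.shape for p in flat], lr=config.learning_rate)

        best_val = np.inf
        best_params = _clone(params)
        stale = 0
        history: list[dict] = []
        epochs_run = 0
        final_loss = np.nan
        for epoch in range(config.max_epochs):
            order = rng.permutation(len(x_tr))
            for start in range(0, len(order), config.batch_size):
                rows = order[start:start + config.batch_size]
                p, cache = _forward(params, m, x_tr[rows])
                grads = _backward(params, m, cache, p, y_tr[rows])
                opt.step(flat, grads)
            p_tr, _ = _forward(params, m, x_tr)
            final_loss = _bce(p_tr, y_tr)
            rec = {"epoch": epoch, "train_loss": final_loss}
            epochs_run = epoch + 1
            if use_val:
                p_va, _ = _forward(params, m, x_va)
                val_loss = _bce(p_va, y_va)
                rec["val_loss"] = val_loss
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_params = _clone(params)
                    stale = 0
                else:
                    stale += 1
            history.append(rec)
            logger.debug("epoch=%d train_loss=%.6f val_loss=%s", epoch, final_loss,
                         rec.get("val_loss"))
            if use_val and stale >= config.early_stop_patience:
                break
        if use_val and config.max_epochs > 0:
            params = best_params

        meta = {
            "epochs_run": epochs_run,
            "final_train_loss": final_loss,
            "init_seed": self.seed,
            "config": {**config.__dict__, "head_spec": list(config.head_spec)},
        }
        return PathDeepResults(model=self, params=params, config=config,
                               train_idx=idx, training_meta=meta, history=history)


class PathDeepResults:
    """Fitted pathway-masked classifier.

    Carries the trained parameters plus attribution helpers: per-sample
    pathway indices (pre-activation pathway-node values) and per-gene
    contribution indices (sample-averaged absolute total first-layer
    contribution of each gene).
    """

    def __init__(self, model: PathDeep, params: dict, config: TrainConfig,
                 train_idx: np.ndarray, training_meta: dict,
                 history: list[dict] | None = None):
        self.model = model
        self.params = params
        self.config = config
        self.train_idx = np.asarray(train_idx, dtype=int)
        self.training_meta = training_meta
        self.history = history or []

    # -- parameters -------------------------------------------------------
    @property
    def pathway_weights(self) -> np.ndarray:
        """Masked first-layer weights W (genes x pathways); non-members are 0."""
        return self.params["w1"] * self.model.mask.matrix

    @property
    def pathway_bias(self) -> np.ndarray:
        return self.params["b1"]

    @property
    def n_parameters(self) -> int:
        """Trainable parameters: allowed first-layer weights + all biases + head."""
        n = self.model.mask.n_edges + self.model.mask.n_pathways
        for w, b in zip(self.params["head_w"], self.params["head_b"]):
            n += w.size + b.size
        return n

    # -- prediction -------------------------------------------------------
    def _resolve(self, data: ExpressionDataset | None) -> ExpressionDataset:
        data = data if data is not None else self.model.data
        if list(data.gene_symbols) != list(self.model.mask.gene_order):
            raise ValueError("dataset gene order does not match the model mask")
        return data

    def predict_proba(self, data: ExpressionDataset | None = None,
                      idx: Sequence[int] | None = None) -> np.ndarray:
        data = self._resolve(data)
        values = data.values if idx is None else data.values[np.asarray(idx, int)]
        return self.model.predict_proba_with(self.params, values)

    def accuracy(self, idx: Sequence[int], data: ExpressionDataset | None = None,
                 threshold: float = 0.5) -> float:
        """Fraction of samples whose thresholded probability equals the label."""
        if not 0 < threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        data = self._resolve(data)
        idx = np.asarray(list(idx), dtype=int)
        if idx.size == 0:
            raise ValueError("empty evaluation set")
        p = self.predict_proba(data, idx)
        return float(np.mean((p >= threshold).astype(int) == data.labels[idx]))

    # -- attribution ------------------------------------------------------
    def pathway_index(self, data: ExpressionDataset | None = None):
        from .interpret import pathway_index

        return pathway_index(self, data)

    def contribution_index(self, data: ExpressionDataset | None = None):
        from .interpret import contribution_index

        return contribution_index(self, data)

    # -- reporting / persistence ------------------------------------------
    def summary(self) -> str:
        mk = self.model.mask
        lines = [
            "PathDeep results",
            "================",
            f"genes:               {mk.n_genes}",
            f"pathways:            {mk.n_pathways}",
            f"gene-pathway edges:  {mk.n_edges}",
            f"head spec:           {self.config.head_spec}",
            f"trainable params:    {self.n_parameters}",
            f"training samples:    {len(self.train_idx)}",
            f"epochs run:          {self.training_meta['epochs_run']}",
            f"final train loss:    {self.training_meta['final_train_loss']:.6f}",
            f"init seed:           {self.model.seed}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint (npz): mask, weights, head, training meta."""
        arrays = {
            "mask": self.model.mask.matrix,
            "w1": self.params["w1"],
            "b1": self.params["b1"],
            "train_idx": self.train_idx,
        }
        for k, (w, b) in enumerate(zip(self.params["head_w"], self.params["head_b"])):
            arrays[f"head_w{k}"] = w
            arrays[f"head_b{k}"] = b
        meta = {
            "gene_order": self.model.mask.gene_order,
            "pathway_order": self.model.mask.pathway_order,
            "n_head": len(self.params["head_w"]),
            "training_meta": self.training_meta,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8)
        np.savez(path, **arrays)


def load_results(path: str | Path, data: ExpressionDataset) -> PathDeepResults:
    """Rebuild a :class:`PathDeepResults` from a checkpoint and its dataset."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode("utf-8"))
        mask = MembershipMask(matrix=z["mask"], gene_order=meta["gene_order"],
                              pathway_order=meta["pathway_order"])
        params = {
            "w1": z["w1"], "b1": z["b1"],
            "head_w": [z[f"head_w{k}"] for k in range(meta["n_head"])],
            "head_b": [z[f"head_b{k}"] for k in range(meta["n_head"])],
        }
        train_idx = z["train_idx"]
    cfg = meta["training_meta"]["config"]
    config = TrainConfig(**{**cfg, "head_spec": tuple(cfg["head_spec"])})
    model = PathDeep(data, mask, head_spec=config.head_spec,
                     seed=meta["training_meta"]["init_seed"])
    return PathDeepResults(model=model, params=params, config=config,
                           train_idx=train_idx,
                           training_meta=meta["training_meta"])


def build_fully_connected(data: ExpressionDataset, hidden_spec: Sequence[int],
                          seed: int = 0) -> PathDeep:
    """Fully connected baseline: first hidden layer is an all-ones mask.

    ``hidden_spec`` gives all layer widths after the input, ending in the
    1-unit output, e.g. ``(64, 32, 1)``.  With identical seeds this produces
    bitwise-identical predictions to ``PathDeep`` under an all-ones mask of
    the same width, because it *is* that model.
    """
    hidden_spec = tuple(hidden_spec)
    if len(hidden_spec) < 2 or hidden_spec[-1] != 1:
        raise ValueError("hidden_spec needs >= 1 hidden width and a 1-unit output")
    mask = full_mask(data.n_genes, hidden_spec[0], gene_order=data.gene_symbols)
    return PathDeep(data, mask, head_spec=hidden_spec[1:], seed=seed)
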