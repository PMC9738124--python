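"""Hierarchy of four binary classifiers resolving one 5-way tissue label.

Node 1 separates labels {1,2} from {3,4,5}; node 2 resolves 1 vs 2; node 3
resolves 3 vs {4,5}; node 4 resolves 4 vs 5.  Each pyramid level owns its
own four nodes, trained on patches of that level's size.  Routing is a hard
argmax walk down the tree by default, with a path-probability-product
alternative.

Backends: ``tiny_cnn`` (numpy CNN, see :mod:`pygleason.nn`) and ``oracle``
(a test double that reads the ground-truth label window of each patch,
isolating the pipeline plumbing from classifier quality).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .nn import TinyConvNet
from .tiling import modal_tissue_label

__all__ = [
    "NODE_SPLITS",
    "CascadeNodeSpec",
    "TuningConfig",
    "TrainedNode",
    "LevelCascade",
    "OracleClassifier",
    "balance_training_set",
    "make_node_dataset",
    "train_node",
    "train_level_cascade",
    "patches_to_float",
    "classify_oracle",
]

#: node_id -> (negative-side labels, positive-side labels)
NODE_SPLITS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    1: ((1, 2), (3, 4, 5)),
    2: ((1,), (2,)),
    3: ((3,), (4, 5)),
    4: ((4,), (5,)),
}


@dataclasses.dataclass(frozen=True)
class CascadeNodeSpec:
    node_id: int
    input_size: int

    def __post_init__(self) -> None:
        if self.node_id not in NODE_SPLITS:
            raise ValueError(f"node_id must be in {sorted(NODE_SPLITS)}")

    @property
    def negative_set(self) -> tuple[int, ...]:
        return NODE_SPLITS[self.node_id][0]

    @property
    def positive_set(self) -> tuple[int, ...]:
        return NODE_SPLITS[self.node_id][1]

    @property
    def label_universe(self) -> tuple[int, ...]:
        return self.negative_set + self.positive_set


@dataclasses.dataclass(frozen=True)
class TuningConfig:
    """Random-search settings for one node."""

    n_trials: int = 2
    seed: int = 0
    epochs: int = 30
    patience: int = 8
    val_fraction: float = 0.25
    lr_range: tuple[float, float] = (3e-3, 1.2e-2)  # log-uniform
    dropout_range: tuple[float, float] = (0.0, 0.4)
    filter_choices: tuple[tuple[int, ...], ...] = ((6, 12), (8, 16))
    fc_choices: tuple[int, ...] = (24, 32)
    batch_choices: tuple[int, ...] = (16, 32)
    early_accept: float | None = None  # stop the search once val acc reaches this

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")

    def sample(self, rng: np.random.Generator) -> dict:
        lo, hi = np.log(self.lr_range[0]), np.log(self.lr_range[1])
        return {
            "lr": float(np.exp(rng.uniform(lo, hi))),
            "dropout": float(rng.uniform(*self.dropout_range)),
            "filters": tuple(self.filter_choices[rng.integers(len(self.filter_choices))]),
            "fc_units": int(self.fc_choices[rng.integers(len(self.fc_choices))]),
            "batch_size": int(self.batch_choices[rng.integers(len(self.batch_choices))]),
        }


def balance_training_set(
    patches_by_label: Mapping[int, Sequence],
    seed: int,
    reference_label: int = 5,
) -> dict[int, list]:
    """Subsample every class to the size of the rarest one.

    The reference class (label 5 by default, the rarest in realistic mixes)
    sets the target count; when some other class happens to be rarer the
    minimum is used so sampling stays without replacement.
    """
    counts = {int(k): len(v) for k, v in patches_by_label.items()}
    for lab in (1, 2, 3, 4, 5):
        if counts.get(lab, 0) == 0:
            raise ValueError(f"no training patches for class {lab}")
    target = min(counts[reference_label], min(counts.values()))
    rng = np.random.default_rng(seed)
    out: dict[int, list] = {}
    for lab in sorted(counts):
        items = list(patches_by_label[lab])
        idx = rng.choice(len(items), size=target, replace=False)
        out[lab] = [items[i] for i in sorted(idx)]
    return out


def patches_to_float(patches: Sequence[np.ndarray]) -> np.ndarray:
    """Stack uint8 patches to a (N,S,S,3) float array scaled to [-0.5, 0.5]."""
    x = np.stack([np.asarray(p) for p in patches]).astype(np.float32)
    return x / np.float32(255.0) - np.float32(0.5)


def make_node_dataset(
    balanced: Mapping[int, Sequence[np.ndarray]], node: CascadeNodeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel patches to the node's binary task; other labels are excluded."""
    xs, ys = [], []
    for side, labels in ((0, node.negative_set), (1, node.positive_set)):
        for lab in labels:
            for p in balanced.get(lab, ()):
                xs.append(p)
                ys.append(side)
    if 0 not in ys or 1 not in ys:
        raise ValueError(f"node {node.node_id}: one side of the binary task is empty")
    return patches_to_float(xs), np.asarray(ys, dtype=np.int64)


@dataclasses.dataclass
class TrainedNode:
    spec: CascadeNodeSpec
    net: TinyConvNet
    val_accuracy: float
    hyperparams: dict
    history: "object"  # TrainHistory of the winning trial

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(x)


def train_node(
    node: CascadeNodeSpec,
    balanced: Mapping[int, Sequence[np.ndarray]],
    tuning: TuningConfig,
) -> TrainedNode:
    """Random-search over hyperparameters; keep the best-validation trial."""
    tuning.validate()
    x, y = make_node_dataset(balanced, node)
    rng = np.random.default_rng(tuning.seed)
    n = x.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(tuning.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("not enough patches to split train/validation")
    x_tr, y_tr, x_val, y_val = x[tr_idx], y[tr_idx], x[val_idx], y[val_idx]

    best: TrainedNode | None = None
    for trial in range(tuning.n_trials):
        hp = tuning.sample(rng)
        net = TinyConvNet(
            input_shape=(node.input_size, node.input_size, 3),
            filters=hp["filters"],
            fc_units=hp["fc_units"],
            dropout=hp["dropout"],
            lr=hp["lr"],
            seed=int(rng.integers(2**31)),
        )
        net.fit(
            x_tr, y_tr, x_val, y_val,
            epochs=tuning.epochs, batch_size=hp["batch_size"], patience=tuning.patience,
        )
        acc = float((net.predict_proba(x_val).argmax(axis=1) == y_val).mean())
        cand = TrainedNode(node, net, acc, hp, net.history)
        if best is None or acc > best.val_accuracy:
            best = cand
        if tuning.early_accept is not None and best.val_accuracy >= tuning.early_accept:
            break
    assert best is not None
    return best


@dataclasses.dataclass
class LevelCascade:
    """The four trained nodes of one pyramid level."""

    input_size: int
    nodes: dict[int, TrainedNode]

    def __post_init__(self) -> None:
        if set(self.nodes) != {1, 2, 3, 4}:
            raise ValueError("a level cascade needs nodes 1..4")

    def classify(self, patches: np.ndarray, routing: str = "argmax") -> np.ndarray:
        """Assign one label in 1..5 to each patch.

        ``routing='argmax'`` walks the tree with hard decisions at each node;
        ``routing='path_product'`` multiplies branch probabilities along each
        root-to-leaf path and picks the most probable leaf.  Probability ties
        resolve toward the lower label.
        """
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected patches of size {self.input_size}, got {x.shape[1:3]}"
            )
        n = x.shape[0]
        p1 = self.nodes[1].predict_proba(x)[:, 1]
        if routing == "argmax":
            labels = np.zeros(n, dtype=np.int64)
            low = p1 <= 0.5
            if low.any():
                p2 = self.nodes[2].predict_proba(x[low])[:, 1]
                labels[low] = np.where(p2 > 0.5, 2, 1)
            high = ~low
            if high.any():
                idx_high = np.nonzero(high)[0]
                p3 = self.nodes[3].predict_proba(x[high])[:, 1]
                labels[idx_high] = 3
                deep = p3 > 0.5
                if deep.any():
                    idx_deep = idx_high[deep]
                    p4 = self.nodes[4].predict_proba(x[idx_deep])[:, 1]
                    labels[idx_deep] = np.where(p4 > 0.5, 5, 4)
            return labels
        if routing == "path_product":
            p2 = self.nodes[2].predict_proba(x)[:, 1]
            p3 = self.nodes[3].predict_proba(x)[:, 1]
            p4 = self.nodes[4].predict_proba(x)[:, 1]
            leaf = np.stack(
                [
                    (1 - p1) * (1 - p2),  # label 1
                    (1 - p1) * p2,        # label 2
                    p1 * (1 - p3),        # label 3
                    p1 * p3 * (1 - p4),   # label 4
                    p1 * p3 * p4,         # label 5
                ],
                axis=1,
            )
            return leaf.argmax(axis=1) + 1  # argmax ties -> lower label
        raise ValueError(f"unknown routing {routing!r}")


class OracleClassifier:
    """Ground-truth test double: labels a patch by its modal tissue label.

    Operates on label windows instead of pixels; patches without any tissue
    fall back to label 1.
    """

    def classify_windows(self, label_windows: Sequence[np.ndarray]) -> np.ndarray:
        out = np.empty(len(label_windows), dtype=np.int64)
        for i, win in enumerate(label_windows):
            mv, _tie = modal_tissue_label(win)
            out[i] = 1 if mv is None else mv
        return out


def classify_oracle(label_windows: Sequence[np.ndarray]) -> np.ndarray:
    return OracleClassifier().classify_windows(label_windows)


def train_level_cascade(
    input_size: int,
    balanced: Mapping[int, Sequence[np.ndarray]],
    tuning: TuningConfig,
) -> LevelCascade:
    """Train all four nodes of one level; per-node seeds derive from tuning.seed."""
    nodes: dict[int, TrainedNode] = {}
    for node_id in (1, 2, 3, 4):
        node_tuning = dataclasses.replace(
            tuning, seed=int(np.random.default_rng([tuning.seed, node_id]).integers(2**31))
        )
        nodes[node_id] = train_node(CascadeNodeSpec(node_id, input_size), balanced, node_tuning)
    return LevelCascade(input_size=input_size, nodes=nodes)


# -- serialization ----------------------------------------------------------

def save_level_cascade(cascade: LevelCascade, out_dir: Path | str) -> Path:
    """Write one npz per node plus a JSON descriptor; returns descriptor path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    desc: dict = {"input_size": cascade.input_size, "nodes": {}}
    for node_id, tn in cascade.nodes.items():
        weights_file = out_dir / f"node{node_id}_S{cascade.input_size}.npz"
        np.savez(weights_file, **tn.net.get_weights())
        desc["nodes"][str(node_id)] = {
            "weights": weights_file.name,
            "val_accuracy": tn.val_accuracy,
            "hyperparams": tn.hyperparams,
            "filters": list(tn.net.filters),
            "fc_units": tn.net.fc_units,
            "n_parameters": tn.net.n_parameters,
        }
    desc_path = out_dir / f"cascade_S{cascade.input_size}.json"
    desc_path.write_text(json.dumps(desc, indent=2))
    return desc_path


def load_level_cascade(desc_path: Path | str) -> LevelCascade:
    desc_path = Path(desc_path)
    desc = json.loads(desc_path.read_text())
    s = int(desc["input_size"])
    nodes: dict[int, TrainedNode] = {}
    for node_id_str, nd in desc["nodes"].items():
        node_id = int(node_id_str)
        hp = nd["hyperparams"]
        net = TinyConvNet(
            input_shape=(s, s, 3),
            filters=tuple(nd["filters"]),
            fc_units=int(nd["fc_units"]),
            dropout=float(hp.get("dropout", 0.0)),
            lr=float(hp.get("lr", 1e-3)),
        )
        with np.load(desc_path.parent / nd["weights"]) as z:
            net.set_weights({k: z[k] for k in z.files})
        nodes[node_id] = TrainedNode(
            CascadeNodeSpec(node_id, s), net, float(nd["val_accuracy"]), hp, net.history
        )
    return LevelCascade(input_size=s, nodes=nodes)
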