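"""Globally optimised, complexity-constrained classification trees.

Axis-aligned decision trees are fitted by an evolutionary algorithm that
searches the joint space of split variables and thresholds, instead of the
greedy node-by-node induction of CART.  Fitness is the training
misclassification rate plus a per-leaf complexity penalty, so an extra leaf
must buy a commensurate gain in accuracy; the learner therefore favours the
small, interpretable threshold models used to relate community trophic
structures to climate and to human-impact indicators.

Routing convention: ``value < threshold`` goes left, ``value >= threshold``
goes right.  Candidate thresholds are the midpoints between consecutive
distinct values of each feature in the training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "TreeModel",
    "EvolutionConfig",
    "evolve_tree",
    "predict_tree",
    "extract_thresholds",
    "greedy_baseline",
]


@dataclass
class TreeNode:
    """Internal node (var/threshold, two children) or leaf (label)."""

    var: int | None = None
    threshold: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    label: int | None = None
    n_samples: int = 0
    class_ratio: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(label=self.label, n_samples=self.n_samples,
                            class_ratio=None if self.class_ratio is None else self.class_ratio.copy())
        return TreeNode(var=self.var, threshold=self.threshold,
                        left=self.left.copy(), right=self.right.copy())

    def n_leaves(self) -> int:
        return 1 if self.is_leaf else self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        return 0 if self.is_leaf else 1 + max(self.left.depth(), self.right.depth())


@dataclass
class EvolutionConfig:
    """Hyperparameters of the evolutionary tree search."""

    population_size: int = 200
    generations: int = 500
    patience: int = 100
    tournament_size: int = 4
    p_crossover: float = 0.6
    p_threshold_mutation: float = 0.4
    p_variable_mutation: float = 0.2
    p_prune_mutation: float = 0.2
    p_grow_mutation: float = 0.4
    #: complexity penalty per leaf: one extra leaf must buy this much accuracy
    alpha: float = 0.01
    max_depth: int = 5
    min_samples_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_crossover, self.p_threshold_mutation, self.p_variable_mutation,
                  self.p_prune_mutation, self.p_grow_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class TreeModel:
    """A fitted classification tree with its training diagnostics."""

    root: TreeNode
    feature_names: list[str]
    classes: list[str]
    train_misclassification: float
    fitness: float
    config: EvolutionConfig | None = None
    fitness_history: list[float] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves()

    @property
    def depth(self) -> int:
        return self.root.depth()

    def to_json(self, path: str | Path) -> None:
        def node_dict(n: TreeNode) -> dict:
            if n.is_leaf:
                return {
                    "label": self.classes[n.label],
                    "n_samples": n.n_samples,
                    "class_ratio": None if n.class_ratio is None else n.class_ratio.tolist(),
                }
            return {
                "variable": self.feature_names[n.var],
                "threshold": n.threshold,
                "left": node_dict(n.left),
                "right": node_dict(n.right),
            }

        payload = {
            "tree": node_dict(self.root),
            "feature_names": self.feature_names,
            "classes": self.classes,
            "train_misclassification": self.train_misclassification,
            "fitness": self.fitness,
            "config": None if self.config is None else asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TreeModel":
        payload = json.loads(Path(path).read_text())
        classes = payload["classes"]
        features = payload["feature_names"]

        def parse(d: dict) -> TreeNode:
            if "label" in d:
                ratio = d.get("class_ratio")
                return TreeNode(
                    label=classes.index(d["label"]),
                    n_samples=d.get("n_samples", 0),
                    class_ratio=None if ratio is None else np.asarray(ratio),
                )
            return TreeNode(
                var=features.index(d["variable"]),
                threshold=d["threshold"],
                left=parse(d["left"]),
                right=parse(d["right"]),
            )

        cfg = payload.get("config")
        return cls(
            root=parse(payload["tree"]),
            feature_names=features,
            classes=classes,
            train_misclassification=payload["train_misclassification"],
            fitness=payload["fitness"],
            config=None if cfg is None else EvolutionConfig(**cfg),
        )


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    X = np.asarray(features, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _candidate_thresholds(X: np.ndarray) -> list[np.ndarray]:
    cands = []
    for j in range(X.shape[1]):
        u = np.unique(X[:, j])
        cands.append((u[1:] + u[:-1]) / 2.0 if len(u) > 1 else np.empty(0))
    return cands


def _route(node: TreeNode, X: np.ndarray, idx: np.ndarray, out: list) -> None:
    if node.is_leaf:
        out.append((node, idx))
        return
    goes_left = X[idx, node.var] < node.threshold
    _route(node.left, X, idx[goes_left], out)
    _route(node.right, X, idx[~goes_left], out)


def _evaluate(
    root: TreeNode,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    min_leaf: int,
) -> tuple[TreeNode, int, int]:
    """Fit leaf labels by majority and count errors.

    Splits whose children would fall below ``min_leaf`` samples are collapsed
    to leaves on the fly; the returned tree is the effective (repaired) one.
    Returns (effective tree, errors, n_leaves).
    """

    def rec(node: TreeNode, idx: np.ndarray) -> tuple[TreeNode, int, int]:
        counts = np.bincount(y[idx], minlength=n_classes)
        if not node.is_leaf:
            goes_left = X[idx, node.var] < node.threshold
            n_left = int(goes_left.sum())
            if n_left >= min_leaf and len(idx) - n_left >= min_leaf:
                left, e_l, l_l = rec(node.left, idx[goes_left])
                right, e_r, l_r = rec(node.right, idx[~goes_left])
                eff = TreeNode(var=node.var, threshold=node.threshold, left=left, right=right)
                return eff, e_l + e_r, l_l + l_r
        label = int(np.argmax(counts))
        leaf = TreeNode(
            label=label,
            n_samples=len(idx),
            class_ratio=counts / max(len(idx), 1),
        )
        return leaf, int(len(idx) - counts[label]), 1

    return rec(root, np.arange(len(y)))


def _finalize(
    root: TreeNode,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    min_leaf: int,
    feature_names: list[str],
    classes: list[str],
    alpha: float,
    config: EvolutionConfig | None,
    history: list[float],
) -> TreeModel:
    eff, errors, leaves = _evaluate(root, X, y, n_classes, min_leaf)
    # annotate internal nodes with sample counts for reporting
    def annotate(node: TreeNode, idx: np.ndarray) -> None:
        counts = np.bincount(y[idx], minlength=n_classes)
        node.n_samples = len(idx)
        node.class_ratio = counts / max(len(idx), 1)
        if not node.is_leaf:
            goes_left = X[idx, node.var] < node.threshold
            annotate(node.left, idx[goes_left])
            annotate(node.right, idx[~goes_left])

    annotate(eff, np.arange(len(y)))
    rate = errors / len(y)
    return TreeModel(
        root=eff,
        feature_names=feature_names,
        classes=classes,
        train_misclassification=rate,
        fitness=rate + alpha * leaves,
        config=config,
        fitness_history=history,
    )


# ---------------------------------------------------------------------------
# evolutionary search
# ---------------------------------------------------------------------------


def _random_tree(
    rng: np.random.Generator,
    cands: list[np.ndarray],
    max_depth: int,
    depth: int = 0,
    p_split: float = 0.7,
) -> TreeNode:
    splittable = [j for j, c in enumerate(cands) if len(c)]
    if depth >= max_depth or not splittable or rng.random() > p_split * (0.65**depth):
        return TreeNode(label=0)
    var = int(rng.choice(splittable))
    thr = float(rng.choice(cands[var]))
    return TreeNode(
        var=var,
        threshold=thr,
        left=_random_tree(rng, cands, max_depth, depth + 1, p_split),
        right=_random_tree(rng, cands, max_depth, depth + 1, p_split),
    )


def _collect_nodes(node: TreeNode, depth: int = 0) -> list[tuple[TreeNode, int]]:
    out = [(node, depth)]
    if not node.is_leaf:
        out += _collect_nodes(node.left, depth + 1)
        out += _collect_nodes(node.right, depth + 1)
    return out


def _truncate(node: TreeNode, max_depth: int, depth: int = 0) -> TreeNode:
    if node.is_leaf:
        return node
    if depth >= max_depth:
        return TreeNode(label=0)
    node.left = _truncate(node.left, max_depth, depth + 1)
    node.right = _truncate(node.right, max_depth, depth + 1)
    return node


def _mutate(
    tree: TreeNode,
    rng: np.random.Generator,
    cands: list[np.ndarray],
    cfg: EvolutionConfig,
) -> TreeNode:
    tree = tree.copy()
    nodes = _collect_nodes(tree)
    internal = [(n, d) for n, d in nodes if not n.is_leaf]

    if internal and rng.random() < cfg.p_threshold_mutation:
        node, _ = internal[rng.integers(len(internal))]
        c = cands[node.var]
        if len(c):
            i = int(np.searchsorted(c, node.threshold))
            j = int(np.clip(i + rng.integers(-3, 4), 0, len(c) - 1))
            node.threshold = float(c[j]) if rng.random() < 0.7 else float(rng.choice(c))
    if internal and rng.random() < cfg.p_variable_mutation:
        node, _ = internal[rng.integers(len(internal))]
        splittable = [j for j, c in enumerate(cands) if len(c)]
        node.var = int(rng.choice(splittable))
        node.threshold = float(rng.choice(cands[node.var]))
    if internal and rng.random() < cfg.p_prune_mutation:
        node, _ = internal[rng.integers(len(internal))]
        node.var = None
        node.left = node.right = None
        node.label = 0
    nodes = _collect_nodes(tree)
    leaves = [(n, d) for n, d in nodes if n.is_leaf]
    growable = [(n, d) for n, d in leaves if d < cfg.max_depth]
    if growable and rng.random() < cfg.p_grow_mutation:
        node, _ = growable[rng.integers(len(growable))]
        splittable = [j for j, c in enumerate(cands) if len(c)]
        if splittable:
            node.var = int(rng.choice(splittable))
            node.threshold = float(rng.choice(cands[node.var]))
            node.label = None
            node.left = TreeNode(label=0)
            node.right = TreeNode(label=0)
    return tree


def _crossover(
    a: TreeNode, b: TreeNode, rng: np.random.Generator, max_depth: int
) -> TreeNode:
    child = a.copy()
    nodes_a = _collect_nodes(child)
    nodes_b = _collect_nodes(b)
    target, depth = nodes_a[rng.integers(len(nodes_a))]
    donor, _ = nodes_b[rng.integers(len(nodes_b))]
    donor = donor.copy()
    target.var, target.threshold = donor.var, donor.threshold
    target.left, target.right, target.label = donor.left, donor.right, donor.label
    return _truncate(child, max_depth)


def evolve_tree(features, labels, config: EvolutionConfig | None = None) -> TreeModel:
    """Fit a classification tree by evolutionary search.

    A population of random trees is evolved by tournament selection, subtree
    crossover and threshold/variable/prune/grow mutations; fitness is the
    training misclassification rate plus ``alpha`` per leaf (minimised).  The
    best individual ever seen is returned; the run is deterministic given
    ``config.seed``.  Stops early when the best fitness has not improved for
    ``config.patience`` generations.
    """
    cfg = config or EvolutionConfig()
    X, feature_names = _as_matrix(features)
    y_raw = np.asarray(labels)
    classes = [str(c) for c in np.unique(y_raw)]
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[str(v)] for v in y_raw])
    n, n_classes = len(y), len(classes)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain missing values")
    if cfg.min_samples_leaf * 2 > n:
        raise ValueError("min_samples_leaf too large for the data")
    if n_classes < 2:
        # homogeneous labels: the optimal tree is a single leaf
        root = TreeNode(label=0, n_samples=n, class_ratio=np.ones(1))
        return TreeModel(root, feature_names, classes, 0.0, cfg.alpha, cfg, [cfg.alpha])

    rng = np.random.default_rng(cfg.seed)
    cands = _candidate_thresholds(X)

    def fitness_of(tree: TreeNode) -> float:
        _, errors, leaves = _evaluate(tree, X, y, n_classes, cfg.min_samples_leaf)
        return errors / n + cfg.alpha * leaves

    pop = [_random_tree(rng, cands, cfg.max_depth) for _ in range(cfg.population_size)]
    fits = np.array([fitness_of(t) for t in pop])
    best_tree = pop[int(np.argmin(fits))].copy()
    best_fit = float(fits.min())
    history = [best_fit]
    stall = 0

    for _gen in range(cfg.generations):
        new_pop = [best_tree.copy()]  # elitism
        new_fits = [best_fit]
        while len(new_pop) < cfg.population_size:
            idx = rng.integers(len(pop), size=cfg.tournament_size)
            parent = pop[idx[np.argmin(fits[idx])]]
            if rng.random() < cfg.p_crossover:
                idx2 = rng.integers(len(pop), size=cfg.tournament_size)
                mate = pop[idx2[np.argmin(fits[idx2])]]
                child = _crossover(parent, mate, rng, cfg.max_depth)
            else:
                child = parent.copy()
            child = _mutate(child, rng, cands, cfg)
            new_pop.append(child)
            new_fits.append(fitness_of(child))
        pop = new_pop
        fits = np.asarray(new_fits)
        gen_best = float(fits.min())
        if gen_best < best_fit - 1e-12:
            best_fit = gen_best
            best_tree = pop[int(np.argmin(fits))].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_fit)
        if stall >= cfg.patience:
            break

    return _finalize(
        best_tree, X, y, n_classes, cfg.min_samples_leaf,
        feature_names, classes, cfg.alpha, cfg, history,
    )


def predict_tree(model: TreeModel, features) -> np.ndarray:
    """Route samples through the tree; ties at a threshold go right (>=)."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        X = features[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature count does not match training schema")
    out = np.empty(len(X), dtype=object)
    routed: list = []
    _route(model.root, X, np.arange(len(X)), routed)
    for leaf, idx in routed:
        out[idx] = model.classes[leaf.label]
    return out.astype(str)


def extract_thresholds(model: TreeModel) -> pd.DataFrame:
    """Pre-order report of the internal splits: variable, threshold, depth,
    and each child's majority class."""

    rows: list[dict] = []

    def majority(node: TreeNode) -> str:
        if node.is_leaf:
            return model.classes[node.label]
        if node.class_ratio is not None:
            return model.classes[int(np.argmax(node.class_ratio))]
        return majority(node.left)

    def walk(node: TreeNode, depth: int) -> None:
        if node.is_leaf:
            return
        rows.append(
            {
                "variable": model.feature_names[node.var],
                "threshold": node.threshold,
                "depth": depth,
                "left_class": majority(node.left),
                "right_class": majority(node.right),
            }
        )
        walk(node.left, depth + 1)
        walk(node.right, depth + 1)

    walk(model.root, 0)
    return pd.DataFrame(rows, columns=["variable", "threshold", "depth", "left_class", "right_class"])


def greedy_baseline(features, labels, config: EvolutionConfig | None = None) -> TreeModel:
    """CART-style greedy induction under the same constraints and fitness.

    At each node the split minimising the children's misclassification count
    is chosen without lookahead; recursion stops when no split reduces the
    error, or depth/min-leaf constraints bind.  Serves as the locally-optimal
    benchmark for the evolutionary learner.
    """
    cfg = config or EvolutionConfig()
    X, feature_names = _as_matrix(features)
    y_raw = np.asarray(labels)
    classes = [str(c) for c in np.unique(y_raw)]
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[str(v)] for v in y_raw])
    n_classes = len(classes)

    def best_split(idx: np.ndarray, var: int) -> tuple[int, float] | None:
        """Minimal-error split of idx on var, vectorised over all midpoints."""
        xv = X[idx, var]
        order = np.argsort(xv, kind="stable")
        xs, ys = xv[order], y[idx][order]
        m = len(idx)
        onehot = np.zeros((m, n_classes))
        onehot[np.arange(m), ys] = 1.0
        cum = onehot.cumsum(axis=0)  # counts of each class among first i+1
        total = cum[-1]
        n_left = np.arange(1, m)
        err = (n_left - cum[:-1].max(axis=1)) + ((m - n_left) - (total - cum[:-1]).max(axis=1))
        valid = (
            (xs[1:] > xs[:-1])
            & (n_left >= cfg.min_samples_leaf)
            & (m - n_left >= cfg.min_samples_leaf)
        )
        if not valid.any():
            return None
        err = np.where(valid, err, np.inf)
        i = int(np.argmin(err))
        return int(err[i]), float((xs[i] + xs[i + 1]) / 2.0)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=n_classes)
        node_err = len(idx) - counts.max()
        if depth >= cfg.max_depth or node_err == 0:
            return TreeNode(label=int(np.argmax(counts)))
        best = None  # (err, var, thr)
        for var in range(X.shape[1]):
            res = best_split(idx, var)
            if res is not None and (best is None or res[0] < best[0]):
                best = (res[0], var, res[1])
        if best is None or best[0] >= node_err:
            return TreeNode(label=int(np.argmax(counts)))
        _, var, thr = best
        left_mask = X[idx, var] < thr
        return TreeNode(
            var=var,
            threshold=thr,
            left=build(idx[left_mask], depth + 1),
            right=build(idx[~left_mask], depth + 1),
        )

    root = build(np.arange(len(y)), 0)
    return _finalize(
        root, X, y, n_classes, cfg.min_samples_leaf,
        feature_names, classes, cfg.alpha, cfg, [],
    )
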