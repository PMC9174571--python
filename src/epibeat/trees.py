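"""Multi-class classification trees with Gini splits, plus bagging.

The estimator is deliberately minimal, mirroring how the pressure-bin
classifier is defined: axis-aligned numeric thresholds chosen to
maximize the Gini gain

    gain(D_p, f) = I(D_p) - sum_j (N_j / N) I(D_j),    I(D) = 1 - sum_k p_k^2

grown best-first until a split budget is exhausted, nodes are pure, or
no split yields positive gain; variance is reduced by bootstrap
aggregation with majority voting.  Every tie (features, thresholds,
frontier nodes, votes) breaks toward the lower index/threshold so a
fixed seed yields a bit-identical model.

No pruning and no per-split feature subsampling: model complexity is
controlled only by the split budget and the <=3-feature cap applied by
the feature-selection stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeNode",
    "TreeEnsemble",
    "gini_impurity",
    "find_best_split",
    "grow_tree",
    "fit_bagged_ensemble",
    "predict_tree",
    "predict_ensemble",
    "predict_matrix",
    "ensemble_to_json",
    "ensemble_from_json",
]


def gini_impurity(class_counts: np.ndarray) -> float:
    """Gini diversity index ``1 - sum (n_k / N)^2`` of a count vector."""
    c = np.asarray(class_counts, float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ValueError("counts must sum to a positive number")
    p = c / n
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    class_counts: np.ndarray
    impurity: float
    split_feature: int | None = None      # column index within the subset
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    @property
    def leaf_class(self) -> int:
        return int(np.argmax(self.class_counts))  # tie -> lower class


@dataclass
class TreeEnsemble:
    trees: list[TreeNode]
    feature_codes: tuple[str, ...]
    n_classes: int
    max_splits: int
    seed: int
    scheme_name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= len(self.feature_codes) <= 3:
            raise ValueError("feature subset must hold 1-3 features")
        if not self.trees:
            raise ValueError("ensemble needs at least one tree")


try:  # optional JIT of the O(n) split scan; numpy path is equivalent
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional speedup
    _njit = None


if _njit is not None:

    @_njit(cache=True)
    def _split_scan(v: np.ndarray, ys: np.ndarray, m: int):
        """Single left-to-right scan over sorted values.

        Maintains left/right class counts and their sums of squares so
        each candidate threshold costs O(1).  Returns (found, thr, gain)
        with the first (smallest) threshold attaining the maximal gain.
        """
        n = v.shape[0]
        total = np.zeros(m)
        for i in range(n):
            total[ys[i]] += 1.0
        ss_r = 0.0
        for c in range(m):
            ss_r += total[c] * total[c]
        parent = 1.0 - ss_r / (n * n)
        left = np.zeros(m)
        ss_l = 0.0
        best_gain = 0.0
        best_thr = 0.0
        found = False
        for i in range(n - 1):
            c = ys[i]
            ss_l += 2.0 * left[c] + 1.0
            ss_r += -2.0 * (total[c] - left[c]) + 1.0
            left[c] += 1.0
            if v[i] < v[i + 1]:
                nl = i + 1.0
                nr = n - nl
                imp_l = 1.0 - ss_l / (nl * nl)
                imp_r = 1.0 - ss_r / (nr * nr)
                gain = parent - (nl / n) * imp_l - (nr / n) * imp_r
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    thr = 0.5 * (v[i] + v[i + 1])
                    if thr >= v[i + 1]:
                        thr = v[i]
                    best_thr = thr
                    found = True
        return found, best_thr, best_gain


def _best_split_column(values: np.ndarray, y: np.ndarray,
                       n_classes: int) -> tuple[float | None, float]:
    """Best threshold and Gini gain for one feature column.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values; the first (smallest) threshold attaining the maximum
    gain wins.  A constant column returns ``(None, 0.0)``.
    """
    if _njit is not None:
        order = np.argsort(values, kind="stable")
        v = np.ascontiguousarray(values[order], dtype=np.float64)
        ys = np.ascontiguousarray(y[order], dtype=np.int64)
        if len(v) < 2 or v[0] == v[-1]:
            return None, 0.0
        found, thr, gain = _split_scan(v, ys, int(n_classes))
        if not found or gain <= 0:
            return None, 0.0
        return float(thr), float(gain)
    return _best_split_column_numpy(values, y, n_classes)


def _best_split_column_numpy(values: np.ndarray, y: np.ndarray,
                             n_classes: int) -> tuple[float | None, float]:
    """Pure-numpy reference implementation of the split scan."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    ys = y[order]
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return None, 0.0
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)          # counts in the left child
    total = cum[-1]
    parent_imp = gini_impurity(total)
    cut = np.flatnonzero(v[:-1] < v[1:])     # split after position i
    if cut.size == 0:
        return None, 0.0
    nl = (cut + 1).astype(float)
    nr = n - nl
    left = cum[cut]
    right = total[None, :] - left
    imp_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
    imp_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
    gain = parent_imp - (nl / n) * imp_l - (nr / n) * imp_r
    best = int(np.argmax(gain))              # first max -> smaller threshold
    if gain[best] <= 0:
        return None, 0.0
    lo, hi = v[cut[best]], v[cut[best] + 1]
    thr = 0.5 * (lo + hi)
    if thr >= hi:  # adjacent floats: midpoint rounds up, keep split valid
        thr = lo
    return float(thr), float(gain[best])


def find_best_split(rows: list[tuple[float, int]] | np.ndarray,
                    classes: np.ndarray | None = None,
                    n_classes: int | None = None
                    ) -> tuple[float | None, float]:
    """Best Gini-gain threshold for a single feature.

    Accepts either ``rows`` as (value, class) pairs or separate value /
    class arrays.  Returns ``(threshold, gain)``; ``(None, 0.0)`` for a
    constant feature.
    """
    if classes is None:
        arr = np.asarray(rows, float)
        values, y = arr[:, 0], arr[:, 1].astype(int)
    else:
        values = np.asarray(rows, float)
        y = np.asarray(classes, int)
    if len(values) < 2:
        raise ValueError("need at least 2 rows")
    m = n_classes if n_classes is not None else int(y.max()) + 1
    return _best_split_column(values, y, m)


def _node_counts(y: np.ndarray, n_classes: int) -> np.ndarray:
    return np.bincount(y, minlength=n_classes).astype(float)


def grow_tree(X: np.ndarray, y: np.ndarray, max_splits: int,
              n_classes: int | None = None) -> TreeNode:
    """Best-first tree growth under a global split budget.

    At each step the frontier leaf whose best candidate split yields the
    largest impurity reduction (weighted by its sample share) is split;
    growth stops at ``max_splits`` splits, pure leaves, or no positive
    gain.  Deterministic: ties prefer the earlier-created node, lower
    feature index, smaller threshold.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("rows must be non-empty")
    m = n_classes if n_classes is not None else int(y.max()) + 1
    n_total = len(y)

    def make_node(idx: np.ndarray) -> tuple[TreeNode, tuple | None]:
        counts = _node_counts(y[idx], m)
        node = TreeNode(class_counts=counts, impurity=gini_impurity(counts))
        if node.impurity == 0 or len(idx) < 2:
            return node, None
        best = None
        for f in range(X.shape[1]):
            thr, gain = _best_split_column(X[idx, f], y[idx], m)
            if thr is not None and (best is None or gain > best[2]):
                best = (f, thr, gain)
        if best is None:
            return node, None
        f, thr, gain = best
        weighted = gain * len(idx) / n_total
        return node, (weighted, f, thr, idx)

    root, cand = make_node(np.arange(n_total))
    frontier: list[tuple[TreeNode, tuple]] = []
    if cand is not None:
        frontier.append((root, cand))
    splits = 0
    while frontier and splits < max_splits:
        gains = [c[0] for _, c in frontier]
        pick = int(np.argmax(gains))         # tie -> earlier-created node
        node, (weighted, f, thr, idx) = frontier.pop(pick)
        go_left = X[idx, f] <= thr
        if not go_left.any() or go_left.all():  # degenerate; leave as leaf
            continue
        node.split_feature = f
        node.split_threshold = thr
        for side, sub in (("left", idx[go_left]), ("right", idx[~go_left])):
            child, child_cand = make_node(sub)
            setattr(node, side, child)
            if child_cand is not None:
                frontier.append((child, child_cand))
        splits += 1
    return root


def predict_tree(node: TreeNode, X: np.ndarray) -> np.ndarray:
    """Vectorized class prediction for a sample matrix."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    out = np.empty(len(X), int)

    def descend(nd: TreeNode, idx: np.ndarray) -> None:
        if nd.is_leaf or nd.left is None:
            out[idx] = nd.leaf_class
            return
        go_left = X[idx, nd.split_feature] <= nd.split_threshold
        descend(nd.left, idx[go_left])
        descend(nd.right, idx[~go_left])

    descend(node, np.arange(len(X)))
    return out


def fit_bagged_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    feature_codes: tuple[str, ...] | list[str],
    n_trees: int = 50,
    max_splits: int | None = None,
    seed: int = 0,
    n_classes: int | None = None,
    bootstrap: bool = True,
    scheme_name: str = "",
) -> TreeEnsemble:
    """Bootstrap-aggregated Gini trees on a <=3-feature design matrix.

    Each tree sees a with-replacement resample of size N drawn from a
    seeded generator; ``bootstrap=False`` with ``n_trees=1`` reduces to
    a single :func:`grow_tree`.  ``max_splits`` defaults to 4x the
    class count (see docs/methods.md).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) == 0:
        raise ValueError("rows must be non-empty")
    m = n_classes if n_classes is not None else int(y.max()) + 1
    if max_splits is None:
        max_splits = 4 * m
    rng = np.random.default_rng(seed)
    trees = []
    n = len(X)
    for _ in range(n_trees):
        idx = rng.integers(0, n, n) if bootstrap else np.arange(n)
        trees.append(grow_tree(X[idx], y[idx], max_splits, m))
    return TreeEnsemble(
        trees=trees,
        feature_codes=tuple(feature_codes),
        n_classes=m,
        max_splits=max_splits,
        seed=seed,
        scheme_name=scheme_name,
    )


def predict_matrix(ensemble: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Majority-vote prediction for a design matrix (tie -> lower class)."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    votes = np.zeros((len(X), ensemble.n_classes))
    for tree in ensemble.trees:
        pred = predict_tree(tree, X)
        votes[np.arange(len(X)), pred] += 1.0
    return np.argmax(votes, axis=1)


def predict_ensemble(ensemble: TreeEnsemble, x) -> int:
    """Predict the class of one feature vector.

    ``x`` may be a mapping from feature code to value (extra features
    ignored) or an array ordered like ``ensemble.feature_codes``.
    Raises ``KeyError`` naming any missing feature code.
    """
    if hasattr(x, "keys"):
        missing = [c for c in ensemble.feature_codes if c not in x]
        if missing:
            raise KeyError(f"feature(s) {missing} missing from input")
        vec = np.array([float(x[c]) for c in ensemble.feature_codes])
    else:
        vec = np.asarray(x, float)
        if vec.shape[-1] != len(ensemble.feature_codes):
            raise KeyError(
                f"expected {len(ensemble.feature_codes)} features "
                f"{ensemble.feature_codes}"
            )
    return int(predict_matrix(ensemble, vec[None, :])[0])


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def _node_to_dict(node: TreeNode) -> dict:
    d: dict = {
        "counts": node.class_counts.tolist(),
        "impurity": node.impurity,
    }
    if not node.is_leaf:
        d.update(
            feature=node.split_feature,
            threshold=node.split_threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return d


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        class_counts=np.array(d["counts"], float),
        impurity=float(d["impurity"]),
    )
    if "feature" in d:
        node.split_feature = int(d["feature"])
        node.split_threshold = float(d["threshold"])
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def ensemble_to_json(ensemble: TreeEnsemble) -> str:
    return json.dumps({
        "feature_codes": list(ensemble.feature_codes),
        "n_classes": ensemble.n_classes,
        "max_splits": ensemble.max_splits,
        "seed": ensemble.seed,
        "scheme_name": ensemble.scheme_name,
        "meta": ensemble.meta,
        "trees": [_node_to_dict(t) for t in ensemble.trees],
    }, sort_keys=True)


def ensemble_from_json(text: str) -> TreeEnsemble:
    d = json.loads(text)
    return TreeEnsemble(
        trees=[_node_from_dict(t) for t in d["trees"]],
        feature_codes=tuple(d["feature_codes"]),
        n_classes=int(d["n_classes"]),
        max_splits=int(d["max_splits"]),
        seed=int(d["seed"]),
        scheme_name=d.get("scheme_name", ""),
        meta=d.get("meta", {}),
    )
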