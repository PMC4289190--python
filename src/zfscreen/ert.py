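"""Extremely randomized trees over 768-attribute TRGB patch vectors.

Each internal node holds one pixel-level test: either thresholding a single
attribute (SIMPLETHRES) or thresholding the difference between an attribute
and one of its 8 spatial neighbors within the same channel plane
(DIFFNEIGHBOR). Following the extremely-randomized principle, both the
attribute and the threshold are drawn at random — the threshold uniformly
between the node-local minimum and maximum of the tested quantity, which
guarantees a non-degenerate split — and the best of K candidates by
normalized Shannon information gain is kept. Leaves store raw class counts
and carry ensemble-wide unique, contiguous ids so they double as
bag-of-visual-words vocabulary entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from zfscreen.subwindow import N_ATTRIBUTES, N_CHANNELS, PATCH_SIDE

SIMPLETHRES = "SIMPLETHRES"
DIFFNEIGHBOR = "DIFFNEIGHBOR"
TEST_KINDS = (SIMPLETHRES, DIFFNEIGHBOR)

MODEL_FORMAT = "zfscreen-ert"
MODEL_VERSION = 1

#: random draws per candidate before falling back to an exhaustive scan for
#: a non-constant attribute / neighbor difference.
_MAX_RANDOM_TRIES = 64


def _neighbor_table() -> np.ndarray:
    """(768, 8) table of 8-adjacent attribute indices, -1 where off-grid.

    Attributes are channel-planar: index = ch*256 + row*16 + col, so spatial
    neighbors stay within the same channel plane.
    """
    plane = PATCH_SIDE * PATCH_SIDE
    tab = np.full((N_ATTRIBUTES, 8), -1, dtype=np.int32)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for ch in range(N_CHANNELS):
        for r in range(PATCH_SIDE):
            for c in range(PATCH_SIDE):
                a = ch * plane + r * PATCH_SIDE + c
                for k, (dr, dc) in enumerate(offsets):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < PATCH_SIDE and 0 <= cc < PATCH_SIDE:
                        tab[a, k] = ch * plane + rr * PATCH_SIDE + cc
    return tab


NEIGHBOR_TABLE = _neighbor_table()


@dataclass(frozen=True)
class NodeTest:
    """A pixel test: go left iff the tested quantity is < threshold."""

    kind: str
    attr: int
    threshold: float
    neighbor_attr: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in TEST_KINDS:
            raise ValueError(f"unknown test kind {self.kind!r}")
        if not 0 <= self.attr < N_ATTRIBUTES:
            raise ValueError("attr out of range")
        if self.kind == DIFFNEIGHBOR:
            if self.neighbor_attr is None:
                raise ValueError("DIFFNEIGHBOR requires neighbor_attr")
            if self.neighbor_attr not in NEIGHBOR_TABLE[self.attr]:
                raise ValueError("neighbor_attr is not 8-adjacent to attr")

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Tested quantity for each row of X (pixel value or neighbor diff)."""
        X = np.atleast_2d(X)
        if self.kind == SIMPLETHRES:
            return X[:, self.attr]
        return X[:, self.attr] - X[:, self.neighbor_attr]


@dataclass
class TreeNode:
    """Internal node (test, left, right) or leaf (class_counts, leaf_id)."""

    test: NodeTest | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    class_counts: np.ndarray | None = None
    leaf_id: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.test is None


@dataclass(frozen=True)
class ErtParams:
    """Ensemble hyperparameters.

    T trees, K random candidate tests per node, N_min the minimum node size
    still eligible for splitting (1 for direct classification, 1000 for
    bag-of-leaves descriptors), and the node-test family.
    """

    T: int = 10
    K: int = 28
    n_min: int = 1
    test_kind: str = SIMPLETHRES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.K < 1 or self.n_min < 1:
            raise ValueError("T, K and n_min must all be >= 1")
        if self.test_kind not in TEST_KINDS:
            raise ValueError(f"unknown test kind {self.test_kind!r}")


def _draw_candidate(
    X: np.ndarray, kind: str, rng: np.random.Generator
) -> tuple[NodeTest, np.ndarray] | None:
    """Draw one valid random test at this node, or None if none exists.

    Attribute (and neighbor) are uniform among valid choices; the threshold
    is uniform in the open interval between the node-local min and max of the
    tested quantity. Tries random draws first, then scans exhaustively so the
    no-valid-test signal is exact.
    """
    n_attr = X.shape[1]
    for _ in range(_MAX_RANDOM_TRIES):
        a = int(rng.integers(n_attr))
        if kind == SIMPLETHRES:
            vals = X[:, a]
            nbr = None
        else:
            nbrs = NEIGHBOR_TABLE[a]
            nbrs = nbrs[nbrs >= 0]
            nbr = int(rng.choice(nbrs))
            vals = X[:, a] - X[:, nbr]
        lo, hi = vals.min(), vals.max()
        if lo < hi:
            thr = float(rng.uniform(lo, hi))
            return NodeTest(kind, a, thr, nbr), vals
    # exhaustive fallback: certainty about degeneracy
    if kind == SIMPLETHRES:
        valid = np.flatnonzero(X.max(axis=0) > X.min(axis=0))
        if valid.size == 0:
            return None
        a = int(rng.choice(valid))
        vals = X[:, a]
        thr = float(rng.uniform(vals.min(), vals.max()))
        return NodeTest(kind, a, thr, None), vals
    pairs = [
        (a, b)
        for a in range(n_attr)
        for b in NEIGHBOR_TABLE[a]
        if b >= 0
    ]
    A = np.array([p[0] for p in pairs])
    B = np.array([p[1] for p in pairs])
    D = X[:, A] - X[:, B]
    valid = np.flatnonzero(D.max(axis=0) > D.min(axis=0))
    if valid.size == 0:
        return None
    i = int(rng.choice(valid))
    vals = D[:, i]
    thr = float(rng.uniform(vals.min(), vals.max()))
    return NodeTest(kind, int(A[i]), thr, int(B[i])), vals


def draw_random_test(
    X: np.ndarray, kind: str, rng: np.random.Generator
) -> NodeTest | None:
    """Public wrapper of the candidate draw; None signals "make a leaf"."""
    res = _draw_candidate(np.atleast_2d(np.asarray(X)), kind, rng)
    return None if res is None else res[0]


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def split_score(left_labels: np.ndarray, right_labels: np.ndarray) -> float:
    """Normalized Shannon information gain of a binary split.

    2*I(C;S) / (H_C + H_S) where H_C is the class entropy at the node, H_S
    the entropy of the split itself and I their mutual information. 0 when
    the two sides have the parent's class proportions; maximal (1 for a
    balanced pure split) when the split fully determines the class.
    """
    left_labels = np.asarray(left_labels)
    right_labels = np.asarray(right_labels)
    if left_labels.size == 0 or right_labels.size == 0:
        raise ValueError("both sides of a split must be non-empty")
    y = np.concatenate([left_labels, right_labels])
    classes, y_enc = np.unique(y, return_inverse=True)
    k = classes.size
    nl = left_labels.size
    n = y.size
    cl = np.bincount(y_enc[:nl], minlength=k).astype(float)
    cr = np.bincount(y_enc[nl:], minlength=k).astype(float)
    h_c = _entropy(cl + cr)
    h_s = _entropy(np.array([nl, n - nl], dtype=float))
    h_c_given_s = (nl / n) * _entropy(cl) + ((n - nl) / n) * _entropy(cr)
    info = h_c - h_c_given_s
    denom = h_c + h_s
    if denom == 0:
        return 0.0
    return max(2.0 * info / denom, 0.0)


def build_tree(
    X: np.ndarray,
    y: np.ndarray,
    params: ErtParams,
    rng: np.random.Generator,
    n_classes: int | None = None,
) -> TreeNode:
    """Grow one extremely randomized tree.

    A node becomes a leaf when it is smaller than N_min, class-pure, or no
    non-degenerate test exists; otherwise the best of K random tests by
    :func:`split_score` (ties to the first drawn) partitions it.
    """
    X = np.atleast_2d(np.asarray(X))
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("need at least one sample")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    root = TreeNode()
    # explicit stack instead of recursion: C-mode trees can get deep
    stack: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        y_node = y[idx]
        counts = np.bincount(y_node, minlength=n_classes)
        if idx.size < params.n_min or np.count_nonzero(counts) <= 1:
            node.class_counts = counts
            continue
        Xn = X[idx]
        best = None
        best_score = -1.0
        for _ in range(params.K):
            cand = _draw_candidate(Xn, params.test_kind, rng)
            if cand is None:
                break
            test, vals = cand
            go_left = vals < test.threshold
            score = split_score(y_node[go_left], y_node[~go_left])
            if score > best_score:
                best_score = score
                best = (test, go_left)
        if best is None:
            node.class_counts = counts
            continue
        test, go_left = best
        node.test = test
        node.left = TreeNode()
        node.right = TreeNode()
        stack.append((node.left, idx[go_left]))
        stack.append((node.right, idx[~go_left]))
    return root


@dataclass
class Ensemble:
    """A trained forest with ensemble-wide contiguous leaf ids."""

    trees: list[TreeNode]
    params: ErtParams
    class_names: list[str]
    n_leaves: int = 0
    #: per-tree (leaf id span) — leaf ids of tree t lie in [offsets[t], offsets[t+1])
    leaf_offsets: list[int] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def leaf_distributions(self) -> np.ndarray:
        """(n_leaves, n_classes) matrix of leaf class-frequency vectors."""
        out = np.zeros((self.n_leaves, self.n_classes))
        for tree in self.trees:
            for leaf in iter_leaves(tree):
                total = leaf.class_counts.sum()
                if total > 0:
                    out[leaf.leaf_id] = leaf.class_counts / total
        return out

    def to_json(self) -> str:
        """Versioned, diff-able JSON serialization (flat node arrays)."""
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "params": {
                "T": self.params.T,
                "K": self.params.K,
                "n_min": self.params.n_min,
                "test_kind": self.params.test_kind,
                "seed": self.params.seed,
            },
            "class_names": list(self.class_names),
            "n_classes": self.n_classes,
            "n_leaves": self.n_leaves,
            "trees": [_flatten_tree(t) for t in self.trees],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "Ensemble":
        payload = json.loads(text)
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError("not a zfscreen ensemble model file")
        if payload.get("version") != MODEL_VERSION:
            raise ValueError(f"unsupported model version {payload.get('version')}")
        params = ErtParams(**payload["params"])
        trees = [_unflatten_tree(t) for t in payload["trees"]]
        ens = cls(trees, params, payload["class_names"], payload["n_leaves"])
        ens._index_leaves(renumber=False)
        return ens

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        return cls.from_json(Path(path).read_text())

    def _index_leaves(self, renumber: bool = True) -> None:
        nxt = 0
        self.leaf_offsets = []
        for tree in self.trees:
            self.leaf_offsets.append(nxt)
            for leaf in iter_leaves(tree):
                if renumber:
                    leaf.leaf_id = nxt
                nxt += 1
        self.leaf_offsets.append(nxt)
        self.n_leaves = nxt


def iter_leaves(tree: TreeNode):
    """Yield leaves of a tree in deterministic depth-first (left-first) order."""
    stack = [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            yield node
        else:
            stack.append(node.right)
            stack.append(node.left)


def _flatten_tree(tree: TreeNode) -> list[dict]:
    nodes: list[dict] = []
    stack = [(tree, -1, "")]
    while stack:
        node, parent, side = stack.pop()
        i = len(nodes)
        if parent >= 0:
            nodes[parent][side] = i
        if node.is_leaf:
            nodes.append({"counts": [int(c) for c in node.class_counts], "id": node.leaf_id})
        else:
            t = node.test
            rec = {"kind": t.kind, "attr": t.attr, "thr": t.threshold, "l": -1, "r": -1}
            if t.neighbor_attr is not None:
                rec["nbr"] = t.neighbor_attr
            nodes.append(rec)
            stack.append((node.right, i, "r"))
            stack.append((node.left, i, "l"))
    return nodes


def _unflatten_tree(nodes: list[dict]) -> TreeNode:
    objs = []
    for rec in nodes:
        if "counts" in rec:
            objs.append(TreeNode(class_counts=np.array(rec["counts"]), leaf_id=rec["id"]))
        else:
            test = NodeTest(rec["kind"], rec["attr"], rec["thr"], rec.get("nbr"))
            objs.append(TreeNode(test=test))
    for rec, obj in zip(nodes, objs):
        if "counts" not in rec:
            obj.left = objs[rec["l"]]
            obj.right = objs[rec["r"]]
    return objs[0]


def build_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    params: ErtParams,
    class_names: list[str] | None = None,
) -> Ensemble:
    """Build T trees on independent RNG substreams and number leaves globally."""
    X = np.atleast_2d(np.asarray(X))
    y = np.asarray(y, dtype=np.int64)
    if class_names is None:
        class_names = [str(c) for c in range(int(y.max()) + 1)]
    n_classes = len(class_names)
    streams = np.random.SeedSequence(params.seed & 0x7FFFFFFF).spawn(params.T)
    trees = [
        build_tree(X, y, params, np.random.default_rng(ss), n_classes=n_classes)
        for ss in streams
    ]
    ens = Ensemble(trees, params, list(class_names))
    ens._index_leaves()
    return ens


def propagate(vec: np.ndarray, tree: TreeNode) -> TreeNode:
    """Deterministic descent of one patch vector: left iff quantity < threshold."""
    vec = np.asarray(vec, dtype=np.float64).reshape(1, -1)
    node = tree
    while not node.is_leaf:
        v = node.test.evaluate(vec)[0]
        node = node.left if v < node.test.threshold else node.right
    return node


def propagate_many(X: np.ndarray, tree: TreeNode) -> np.ndarray:
    """Leaf ids reached by each row of X (vectorized frontier descent)."""
    X = np.atleast_2d(np.asarray(X))
    out = np.empty(X.shape[0], dtype=np.int64)
    stack = [(tree, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = node.leaf_id
            continue
        v = node.test.evaluate(X[idx])
        go_left = v < node.test.threshold
        stack.append((node.left, idx[go_left]))
        stack.append((node.right, idx[~go_left]))
    return out
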