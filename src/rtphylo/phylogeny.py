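"""Distance trees, column-bootstrap supports, clade collapsing, monophyly.

The tree stage is deliberately simple: percent identity from the alignment
is turned into a linear distance (1 - identity/100), a neighbor-joining
tree is built, and edge supports come from resampling alignment columns
with replacement.  Supports are fractions in [0, 1]; clades are collapsed
below a support threshold into polytomies, mirroring the convention of
collapsing at local support >= 0.96 or bootstrap >= 75%.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .core import Msa
from .derep import IdentityMatrix, pairwise_identity

logger = logging.getLogger(__name__)

#: distance assigned to pairs whose rows share no alignment columns
ZERO_OVERLAP_DISTANCE = 0.95
#: default collapse thresholds (local-support-style and bootstrap-style)
COLLAPSE_LOCAL = 0.96
COLLAPSE_BOOTSTRAP = 0.75
DEFAULT_BOOTSTRAP_REPS = 100


class SupportTree:
    """Unrooted tree with leaf labels and per-internal-edge support.

    Internally held as a rooted :class:`skbio.TreeNode` with a (possibly
    multifurcating) root; the root placement carries no meaning.  Supports
    live on internal nodes (``node.support``) and serialise as internal
    Newick labels.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        for node in root.traverse():
            if not hasattr(node, "support"):
                node.support = None

    # -- basics ----------------------------------------------------------
    @property
    def leaf_names(self) -> frozenset:
        return frozenset(t.name for t in self.root.tips())

    def copy(self) -> "SupportTree":
        new = self.root.copy()
        for src, dst in zip(self.root.traverse(), new.traverse()):
            dst.support = getattr(src, "support", None)
        return SupportTree(new)

    def internal_nodes(self) -> list[TreeNode]:
        """Non-root internal nodes; each corresponds to one internal edge
        (its subtree leaves versus the rest)."""
        return [n for n in self.root.traverse()
                if not n.is_tip() and n is not self.root]

    def n_internal_edges(self) -> int:
        return len(self.internal_nodes())

    # -- bipartitions ----------------------------------------------------
    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions, keyed by the side *not* containing an
        arbitrary fixed reference leaf (canonical under re-rooting)."""
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self.internal_nodes():
            clade = frozenset(t.name for t in node.tips())
            if len(clade) < 2 or len(clade) > len(all_leaves) - 2:
                continue
            key = all_leaves - clade if ref in clade else clade
            out[key] = node
        return out

    # -- newick ----------------------------------------------------------
    def _serialise(self, node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            inner = ",".join(self._serialise(c) for c in node.children)
            sup = getattr(node, "support", None)
            label = f"({inner})" + (f"{sup:.10g}" if sup is not None else "")
        if node.length is not None and node is not self.root:
            label += f":{node.length:.10g}"
        return label

    def to_newick(self) -> str:
        return self._serialise(self.root) + ";"

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        try:
            root = TreeNode.read(_io.StringIO(text), convert_underscores=False)
        except Exception as exc:  # skbio raises NewickFormatError subclasses
            raise ValueError(f"malformed Newick: {exc}") from exc
        root.assign_supports()
        return cls(root)

    @classmethod
    def read(cls, path) -> "SupportTree":
        return cls.from_newick(Path(path).read_text())

    def rf_distance(self, other: "SupportTree") -> float:
        """Robinson-Foulds distance (count of bipartitions not shared)."""
        a = set(self.bipartitions())
        b = set(other.bipartitions())
        if self.leaf_names != other.leaf_names:
            raise ValueError("trees have different leaf sets")
        return float(len(a ^ b))


# ---------------------------------------------------------------------------
# distances

def distance_from_identity(m: IdentityMatrix) -> DistanceMatrix:
    """Linear distance d = 1 - identity/100; zero-overlap pairs get a fixed
    large distance (0.95).  Triangle-inequality violations are logged, not
    repaired."""
    d = 1.0 - m.values / 100.0
    zero = (m.overlap == 0)
    np.fill_diagonal(zero, False)
    if zero.any():
        d[zero] = ZERO_OVERLAP_DISTANCE
    np.fill_diagonal(d, 0.0)
    n = len(m.ids)
    if n <= 60:  # cubic check only at desk scale
        viol = 0
        for k in range(n):
            viol += int((d > d[:, [k]] + d[[k], :] + 1e-9).sum())
        if viol:
            logger.info("distance matrix has triangle-inequality violations "
                        "(%d ordered triples); left unrepaired", viol)
    return DistanceMatrix(d, ids=m.ids)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the pair minimising the Q criterion; exact ties resolve to the
    lowest index pair.  Negative branch lengths are clamped to 0.  The
    result is returned rooted at the final three-way join.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=i) for i in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - (r[:, None] + r[None, :])  # exactly symmetric
        np.fill_diagonal(Q, np.inf)
        # lowest-index (i, j), i < j, among the minima
        qmin = Q.min()
        cand = np.argwhere(Q == qmin)
        i, j = min((int(a), int(b)) for a, b in cand if a < b)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], dnew[keep][:, None]]),
            np.hstack([dnew[keep], [0.0]]),
        ])
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form three-taxon resolution
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))
    return SupportTree(TreeNode(children=[a, b, c]))


# ---------------------------------------------------------------------------
# bootstrap

def _nj_from_msa(msa: Msa) -> SupportTree:
    return nj_tree(distance_from_identity(pairwise_identity(msa)))


def bootstrap_support(msa: Msa, n_reps: int = DEFAULT_BOOTSTRAP_REPS,
                      seed: int | None = None) -> SupportTree:
    """NJ tree with column-bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the full-data tree is the fraction of
    replicate trees containing its bipartition.  Deterministic given
    ``seed``; ``n_reps == 0`` leaves supports unset with a warning.
    """
    if msa.n_rows < 4:
        raise ValueError("bootstrap supports need at least 4 aligned rows")
    tree = _nj_from_msa(msa)
    if n_reps == 0:
        logger.warning("bootstrap with 0 replicates: supports left unset")
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {key: 0 for key in tree.bipartitions()}
    previous = logging.getLogger("rtphylo.derep").level
    logging.getLogger("rtphylo.derep").setLevel(logging.ERROR)
    try:
        for _ in range(n_reps):
            cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
            rep_tree = _nj_from_msa(msa.take_columns(cols))
            rep_bips = set(rep_tree.bipartitions())
            for key in counts:
                if key in rep_bips:
                    counts[key] += 1
    finally:
        logging.getLogger("rtphylo.derep").setLevel(previous)
    for key, node in tree.bipartitions().items():
        node.support = counts[key] / n_reps
    return tree


# ---------------------------------------------------------------------------
# collapsing and monophyly

def collapse(tree: SupportTree, threshold: float) -> SupportTree:
    """Contract every internal edge with support < ``threshold`` into a
    polytomy; edges at or above the threshold (and leaf edges) survive.
    The contracted edge's length is added to its children to preserve
    leaf-to-leaf path lengths."""
    out = tree.copy()
    for node in out.internal_nodes():
        sup = getattr(node, "support", None)
        if sup is not None and sup < threshold:
            parent = node.parent
            for child in list(node.children):
                if node.length is not None and child.length is not None:
                    child.length += node.length
                node.remove(child)
                parent.append(child)
            parent.remove(node)
    return out


def test_monophyly(tree: SupportTree, label_set) -> tuple[bool, float | None]:
    """Is ``label_set`` separated from all other leaves by a single edge?

    Unrooted convention: true iff some edge's bipartition equals the label
    set (or its complement).  Returns the support of that edge when set.
    Singleton sets are monophyletic by convention (support unset).
    """
    labels = frozenset(label_set)
    leaves = tree.leaf_names
    if not labels or labels == leaves:
        raise ValueError("label set must be a non-empty proper subset of leaves")
    if not labels <= leaves:
        raise ValueError(f"labels not in tree: {sorted(labels - leaves)}")
    if len(labels) == 1:
        logger.info("singleton label set %s: monophyletic by convention",
                    next(iter(labels)))
        return True, None
    complement = leaves - labels
    for node in tree.internal_nodes():
        clade = frozenset(t.name for t in node.tips())
        if clade == labels or clade == complement:
            return True, getattr(node, "support", None)
    # the root's own child partition can realise the split when the root
    # sits exactly on the separating edge
    root_sides = [frozenset(t.name for t in c.tips()) for c in tree.root.children]
    for side in root_sides:
        if side == labels or side == complement:
            return True, None
    return False, None
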