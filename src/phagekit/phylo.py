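"""Distance-based treeing: Jaccard/NJ dendrograms and co-grouping consensus.

Two treeing procedures sit at the core of the pan-genome workflow:

1. presence/absence phylogenomics — Jaccard distances between genomes'
   gene-family sets, then Saitou-Nei neighbor joining;
2. core-gene consensus — one NJ tree per single-copy core family from
   amino-acid p-distances, then a consensus obtained by counting how often
   each pair of genomes forms a cherry (sister pair) across the gene trees,
   transforming the co-grouping frequencies to distances (1 - count/n) and
   re-running neighbor joining.

Binary fingerprint (band presence) matrices, e.g. from ERIC-PCR typing, flow
through the same Jaccard + NJ code path unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "UnrootedTree",
    "CoGroupingMatrix",
    "jaccard_distances",
    "neighbor_joining",
    "core_gene_trees",
    "cogrouping_consensus",
    "rf_distance",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon list."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match label count")
        if np.any(np.isnan(self.d)):
            raise ValueError("distance matrix contains NaN entries")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(self.d))) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


class UnrootedTree:
    """Leaf-labelled unrooted tree, Newick-serializable.

    Thin wrapper over :class:`dendropy.Tree` exposing the operations the
    pipeline needs: Newick round trip, bipartitions, cherries and
    Robinson-Foulds comparison.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = False
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")

    @classmethod
    def from_newick(cls, newick: str) -> "UnrootedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
        )
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> set[str]:
        return {lf.taxon.label for lf in self._tree.leaf_node_iter()}

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the canonical side (the side not
        containing the lexicographically smallest leaf label)."""
        all_leaves = self.leaf_labels()
        ref = min(all_leaves)
        n = len(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if not 2 <= len(side) <= n - 2:
                continue
            if ref in side:
                side = frozenset(all_leaves - side)
            splits.add(side)
        return splits

    def cherries(self) -> set[frozenset[str]]:
        """Sister pairs: leaf pairs separated from the rest by one edge."""
        all_leaves = self.leaf_labels()
        n = len(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) == 2:
                out.add(side)
            if len(side) == n - 2:
                out.add(frozenset(all_leaves - side))
        return out

    def path_length_matrix(self, labels: list[str]) -> np.ndarray:
        """Leaf-to-leaf patristic distances in the order of ``labels``."""
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                )
        return out


def rf_distance(a: UnrootedTree, b: UnrootedTree) -> int:
    """Robinson-Foulds symmetric bipartition distance (0 iff identical
    unrooted topologies)."""
    if a.leaf_labels() != b.leaf_labels():
        raise ValueError("trees must share an identical leaf set")
    return len(a.bipartitions() ^ b.bipartitions())


def jaccard_distances(matrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between genomes' family sets.

    ``matrix`` is a :class:`~phagekit.pangenome.GeneFamilyMatrix` or a pair
    ``(labels, binary_matrix)`` with features in rows and taxa in columns
    (e.g. a fingerprint band matrix). Counts are reduced to presence/absence;
    d(i, j) = 1 - |Fi & Fj| / |Fi | Fj|. Two empty sets get distance 0 with
    a warning.
    """
    if hasattr(matrix, "presence"):
        labels = list(matrix.genomes)
        pres = matrix.presence.astype(bool)
    else:
        labels, raw = matrix
        labels = list(labels)
        pres = np.asarray(raw) > 0
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 genomes")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.sum(pres[:, i] | pres[:, j])
            if union == 0:
                warnings.warn(
                    f"genomes {labels[i]!r} and {labels[j]!r} both have "
                    "empty family sets; distance defined as 0",
                    stacklevel=2,
                )
                continue
            inter = np.sum(pres[:, i] & pres[:, j])
            d[i, j] = d[j, i] = 1.0 - inter / union
    return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is joined at every step; ties go to
    the lowest (i, j) index pair. Negative limb lengths are clamped to 0
    with the deficit moved to the sister branch. Exact (to numerical
    precision) on additive matrices.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.d.copy()
    # newick fragment per active node
    frags = [_quote(lbl) for lbl in dm.labels]
    active = list(range(n0))

    def fmt(x: float) -> str:
        return f"{x:.17g}"

    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(n):
            for b in range(a + 1, n):
                q = (n - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-15:
                    best = (q, a, b)
        _, a, b = best
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la = max(la, 0.0)
        lb = max(lb, 0.0)
        i, j = active[a], active[b]
        # distances from the new node to the remaining taxa
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in range(n):
            if c in (a, b):
                continue
            k = active[c]
            duk = 0.5 * (sub[a, c] + sub[b, c] - dab)
            D[new_idx, k] = D[k, new_idx] = max(duk, 0.0)
        frags.append(f"({frags[i]}:{fmt(la)},{frags[j]}:{fmt(lb)})")
        active = [k for k in active if k not in (i, j)] + [new_idx]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb, lc = _clamp_three(la, lb, lc)
    newick = (
        f"({frags[a]}:{fmt(la)},{frags[b]}:{fmt(lb)},{frags[c]}:{fmt(lc)});"
    )
    return UnrootedTree.from_newick(newick)


def _clamp_three(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    # clamp negative terminal lengths, spreading the deficit over the others
    vals = [la, lb, lc]
    for _ in range(2):
        neg = [k for k, v in enumerate(vals) if v < 0]
        if not neg:
            break
        for k in neg:
            deficit = vals[k]
            vals[k] = 0.0
            others = [m for m in range(3) if m != k]
            for m in others:
                vals[m] += deficit / 2.0
    return tuple(max(v, 0.0) for v in vals)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatched aligned (non-gap) positions between two
    protein sequences under global alignment."""
    from phagekit.pangenome import pairwise_identity, _CIGAR_RE
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    ops = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for cnt, op in _CIGAR_RE.findall(res["cigar"]):
        ops[op] += int(cnt)
    aligned = ops["="] + ops["X"] + ops["M"]
    if aligned == 0:
        return 1.0
    if ops["M"]:
        mismatches = res["editDistance"] - ops["I"] - ops["D"]
    else:
        mismatches = ops["X"]
    return mismatches / aligned


def core_gene_trees(matrix, genomes, correction: str = "none") -> list[UnrootedTree]:
    """One NJ tree per single-copy core family from amino-acid p-distances.

    ``correction="poisson"`` applies -ln(1 - p) to the p-distances before
    tree building. Returns an empty list with a warning when the matrix
    holds no single-copy core family.
    """
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    genome_ids = list(matrix.genomes)
    if len(genome_ids) < 3:
        raise ValueError("need >= 3 genomes")
    seq_by_qid = {
        f"{gid}|{gene_id}": seq
        for gid, gene_id, seq in genomes.qualified_genes()
    }
    core_rows = np.nonzero(np.all(matrix.counts == 1, axis=1))[0]
    if len(core_rows) == 0:
        warnings.warn("no single-copy core families", stacklevel=2)
        return []
    trees = []
    for row in core_rows:
        fam = matrix.families[row]
        seqs = {}
        for qid in matrix.membership[fam]:
            gid = qid.split("|", 1)[0]
            seqs[gid] = seq_by_qid[qid]
        n = len(genome_ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                p = p_distance(seqs[genome_ids[i]], seqs[genome_ids[j]])
                if correction == "poisson":
                    p = -np.log(max(1.0 - p, 1e-12))
                d[i, j] = d[j, i] = p
        trees.append(neighbor_joining(DistanceMatrix(labels=genome_ids, d=d)))
    return trees


@dataclass
class CoGroupingMatrix:
    """Counts of cherry (sister-pair) co-occurrence across gene trees."""

    labels: list[str]
    counts: np.ndarray
    n_trees: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape must match label count")
        if np.any(self.counts < 0) or np.any(self.counts > self.n_trees):
            raise ValueError("counts must lie in [0, n_trees]")
        if np.max(np.abs(np.diag(self.counts))) > 0:
            raise ValueError("diagonal must be zero")


def cogrouping_consensus(
    trees: list[UnrootedTree], transform: str = "one_minus_freq"
) -> tuple[CoGroupingMatrix, UnrootedTree]:
    """Consensus of gene trees via cherry co-grouping frequencies.

    counts(i, j) = number of trees in which {i, j} is a cherry; the
    consensus distance is 1 - counts/n_trees (``transform="one_minus_freq"``,
    the minimal monotone map from co-grouping frequency to dissimilarity),
    and the consensus topology is the NJ tree of that matrix.
    """
    if transform != "one_minus_freq":
        raise ValueError(f"unknown transform {transform!r}")
    if not trees:
        raise ValueError("need >= 1 tree")
    leaf_set = trees[0].leaf_labels()
    if len(leaf_set) < 4:
        raise ValueError("need >= 4 taxa")
    for t in trees[1:]:
        if t.leaf_labels() != leaf_set:
            raise ValueError("all trees must share an identical leaf set")
    labels = sorted(leaf_set)
    idx = {lbl: k for k, lbl in enumerate(labels)}
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    for t in trees:
        for pair in t.cherries():
            i, j = sorted(idx[lbl] for lbl in pair)
            counts[i, j] += 1
            counts[j, i] += 1
    cgm = CoGroupingMatrix(labels=labels, counts=counts, n_trees=len(trees))
    d = 1.0 - counts / len(trees)
    np.fill_diagonal(d, 0.0)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    return cgm, tree
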