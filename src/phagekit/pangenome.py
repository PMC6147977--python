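"""Gene-family (ortholog) tables from phage proteomes.

Clustering is a desk-scale surrogate for heuristic ortholog pipelines:
all-vs-all global (Needleman-Wunsch, unit costs) alignment identity, an edge
where identity and coverage clear their thresholds, families as connected
components (single linkage) or greedy cliques (complete linkage). Identity
is matches / alignment columns (gap columns count in the denominator);
coverage is the aligned fraction of the shorter sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "PhageGenomeSet",
    "GeneFamilyMatrix",
    "ClusteringParams",
    "pairwise_identity",
    "cluster_orthologs",
    "pangenome_summary",
    "PangenomeSummary",
    "identity_bins",
    "IdentityHistogram",
]

_VALID_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class PhageGenomeSet:
    """Proteomes of a set of phage genomes.

    ``genomes`` maps genome id -> list of (gene_id, protein sequence);
    ``truth`` (optional, set by the synthetic generator) maps qualified gene
    ids ``genome|gene`` to true family labels for evaluation.
    """

    genomes: dict[str, list[tuple[str, str]]]
    truth: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for gid, genes in self.genomes.items():
            seen = set()
            for gene_id, seq in genes:
                if gene_id in seen:
                    raise ValueError(
                        f"duplicate gene id {gene_id!r} in genome {gid!r}"
                    )
                seen.add(gene_id)
                if not seq:
                    raise ValueError(
                        f"empty sequence for {gid}|{gene_id}"
                    )
                if not _VALID_AA.match(seq.upper()):
                    raise ValueError(
                        f"invalid amino-acid residues in {gid}|{gene_id}"
                    )

    def qualified_genes(self) -> list[tuple[str, str, str]]:
        """All genes as (genome_id, gene_id, sequence), in input order."""
        return [
            (gid, gene_id, seq)
            for gid, genes in self.genomes.items()
            for gene_id, seq in genes
        ]

    def n_genes(self) -> dict[str, int]:
        return {gid: len(genes) for gid, genes in self.genomes.items()}


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds for the identity/coverage clustering graph."""

    min_identity: float = 0.5
    min_coverage: float = 0.5
    linkage: str = "single"  # "single" | "complete"

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.linkage not in ("single", "complete"):
            raise ValueError(
                f"linkage must be 'single' or 'complete', got {self.linkage!r}"
            )


@dataclass
class GeneFamilyMatrix:
    """Ortholog families x genomes copy-number table.

    ``counts[f, g]`` is the number of genes of family ``families[f]`` in
    genome ``genomes[g]``; ``membership`` maps family id to the qualified
    gene ids it contains. Reducing ``counts`` to presence/absence gives the
    binary matrix used for Jaccard distances.
    """

    families: list[str]
    genomes: list[str]
    counts: np.ndarray
    membership: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.families), len(self.genomes)):
            raise ValueError("counts shape must be (n_families, n_genomes)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def presence(self) -> np.ndarray:
        """Binary presence/absence matrix (families x genomes)."""
        return (self.counts > 0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.families,
                            columns=self.genomes)


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Global-alignment identity and coverage of two protein sequences.

    Returns ``(identity, coverage)`` where identity = matches / alignment
    columns and coverage = (matches + mismatches) / len(shorter).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    res = edlib.align(a, b, mode="NW", task="path")
    ops = {"=": 0, "X": 0, "I": 0, "D": 0, "M": 0}
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        ops[op] += int(n)
    if ops["M"]:  # fall back if edlib emits non-extended cigar
        matches = ops["M"] - (res["editDistance"] - ops["I"] - ops["D"])
        aligned = ops["M"]
    else:
        matches = ops["="]
        aligned = ops["="] + ops["X"]
    columns = aligned + ops["I"] + ops["D"]
    identity = matches / columns if columns else 0.0
    coverage = aligned / min(len(a), len(b))
    return identity, coverage


def cluster_orthologs(
    genomes: PhageGenomeSet, params: ClusteringParams | None = None
) -> GeneFamilyMatrix:
    """Cluster all genes of a genome set into ortholog families.

    Single linkage takes connected components of the identity/coverage
    graph; complete linkage assigns genes greedily (input order) to the
    first existing family every member of which they match. Deterministic
    given input order. Family ids are assigned in order of first member.
    """
    if params is None:
        params = ClusteringParams()
    genes = genomes.qualified_genes()
    if not genomes.genomes:
        raise ValueError("empty genome set")
    n = len(genes)
    seqs = [g[2].upper() for g in genes]
    lens = np.array([len(s) for s in seqs])

    def linked(i: int, j: int) -> bool:
        # identity <= min(len)/max(len): skip hopeless pairs cheaply
        lo, hi = sorted((lens[i], lens[j]))
        if lo / hi < params.min_identity:
            return False
        ident, cov = pairwise_identity(seqs[i], seqs[j])
        return ident >= params.min_identity and cov >= params.min_coverage

    assignment = np.full(n, -1, dtype=int)
    if params.linkage == "single":
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        rows, cols = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if linked(i, j):
                    rows.append(i)
                    cols.append(j)
        graph = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
        # relabel components by first member so ids follow input order
        order: dict[int, int] = {}
        for i in range(n):
            if labels[i] not in order:
                order[labels[i]] = len(order)
            assignment[i] = order[labels[i]]
    else:
        members: list[list[int]] = []
        for i in range(n):
            for fam_idx, fam_members in enumerate(members):
                if all(linked(i, j) for j in fam_members):
                    fam_members.append(i)
                    assignment[i] = fam_idx
                    break
            else:
                members.append([i])
                assignment[i] = len(members) - 1

    n_fam = int(assignment.max()) + 1
    genome_ids = list(genomes.genomes)
    g_index = {g: k for k, g in enumerate(genome_ids)}
    counts = np.zeros((n_fam, len(genome_ids)), dtype=int)
    membership: dict[str, list[str]] = {}
    fam_names = [f"F{k + 1:04d}" for k in range(n_fam)]
    for (genome_id, gene_id, _), fam_idx in zip(genes, assignment):
        counts[fam_idx, g_index[genome_id]] += 1
        membership.setdefault(fam_names[fam_idx], []).append(
            f"{genome_id}|{gene_id}"
        )
    return GeneFamilyMatrix(
        families=fam_names, genomes=genome_ids, counts=counts,
        membership=membership,
    )


@dataclass
class PangenomeSummary:
    """Pan-genome accounting of a gene-family matrix."""

    total_families: int
    core_single_copy: int
    singletons: dict[str, int]          # genome -> private-family count
    shared: pd.DataFrame                # genome x genome shared-family counts
    genes_per_genome: dict[str, int]


def pangenome_summary(matrix: GeneFamilyMatrix) -> PangenomeSummary:
    """Total / single-copy-core / singleton / pairwise-shared counts.

    Singletons are counted as families private to one genome (a genome's
    paralogous copies of a private family count once).
    """
    if len(matrix.families) == 0:
        raise ValueError("empty gene-family matrix")
    pres = matrix.presence
    core = int(np.sum(np.all(matrix.counts == 1, axis=1)))
    single_mask = pres.sum(axis=1) == 1
    singletons = {
        g: int(np.sum(single_mask & (pres[:, k] == 1)))
        for k, g in enumerate(matrix.genomes)
    }
    shared = pd.DataFrame(
        pres.T @ pres, index=matrix.genomes, columns=matrix.genomes
    )
    return PangenomeSummary(
        total_families=len(matrix.families),
        core_single_copy=core,
        singletons=singletons,
        shared=shared,
        genes_per_genome={
            g: int(matrix.counts[:, k].sum())
            for k, g in enumerate(matrix.genomes)
        },
    )


@dataclass
class IdentityHistogram:
    """Best-hit identity histogram of one proteome against another.

    ``counts[i]`` covers the half-open bin ``[edges[i], edges[i+1])`` except
    the top bin, which is closed; ``below`` counts query genes whose best
    hit falls under the lowest edge (including no hit at all).
    """

    edges: list[float]
    counts: list[int]
    below: int

    @property
    def total(self) -> int:
        return sum(self.counts) + self.below


DEFAULT_IDENTITY_BINS = [0.5, 0.7, 0.8, 0.9, 0.95, 1.0]


def identity_bins(
    genome_a: list[tuple[str, str]],
    genome_b: list[tuple[str, str]],
    bins: list[float] | None = None,
    min_coverage: float = 0.5,
) -> IdentityHistogram:
    """Best-hit identity of every gene of A against proteome B, binned.

    A gene's best hit is its maximum pairwise identity over genes of B
    meeting the coverage threshold (0 when B offers no such hit); ties are
    broken toward the lexicographically first gene id of B, which does not
    affect the histogram. ``bins`` are strictly increasing edges in [0, 1].
    """
    if bins is None:
        bins = list(DEFAULT_IDENTITY_BINS)
    if not genome_a:
        raise ValueError("empty query proteome")
    edges = [float(x) for x in bins]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])) or not all(
        0 <= e <= 1 for e in edges
    ):
        raise ValueError("bins must be strictly increasing within [0, 1]")

    b_sorted = sorted(genome_b, key=lambda g: g[0])
    counts = [0] * (len(edges) - 1)
    below = 0
    for _, seq_a in genome_a:
        best = 0.0
        for _, seq_b in b_sorted:
            ident, cov = pairwise_identity(seq_a.upper(), seq_b.upper())
            if cov >= min_coverage and ident > best:
                best = ident
        if best < edges[0]:
            below += 1
            continue
        placed = False
        for i in range(len(edges) - 1):
            hi_ok = best < edges[i + 1] or (
                i == len(edges) - 2 and best <= edges[-1]
            )
            if edges[i] <= best and hi_ok:
                counts[i] += 1
                placed = True
                break
        if not placed:  # identity above the top edge
            counts[-1] += 1
    return IdentityHistogram(edges=edges, counts=counts, below=below)
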