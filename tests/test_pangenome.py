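"""Ortholog clustering, pan-genome accounting and identity histograms."""

import numpy as np
import pytest

from phagekit.pangenome import (
    ClusteringParams,
    GeneFamilyMatrix,
    PhageGenomeSet,
    cluster_orthologs,
    identity_bins,
    pairwise_identity,
    pangenome_summary,
)
from phagekit.simulate import GeneEvolutionParams, simulate_pangenome, _random_protein

from conftest import two_proteomes


def _ari(genomes, matrix):
    from sklearn.metrics import adjusted_rand_score

    pred = {}
    for fam, members in matrix.membership.items():
        for qid in members:
            pred[qid] = fam
    qids = [f"{g}|{gid}" for g, gid, _ in genomes.qualified_genes()]
    return adjusted_rand_score(
        [genomes.truth[q] for q in qids], [pred[q] for q in qids]
    )


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        ident, cov = pairwise_identity("MKLV" * 20, "MKLV" * 20)
        assert ident == 1.0 and cov == 1.0

    def test_oracle_biopython_global_alignment(self, rng):
        """Alignment cost agrees with Biopython's Needleman-Wunsch under
        unit scoring, and identity matches exactly on substitution-only
        pairs (where the optimal alignment is unique and gap-free)."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 0
        aligner.mismatch_score = -1
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        for _ in range(10):
            a = _random_protein(rng, int(rng.integers(30, 60)))
            b = list(a)
            for i in rng.integers(0, len(b), 6):
                b[i] = "A"
            b = "".join(b)
            ident, cov = pairwise_identity(a, b)
            matches = sum(1 for x, y in zip(a, b) if x == y)
            assert ident == pytest.approx(matches / len(a), abs=1e-12)
            assert cov == 1.0
            # with a deletion, check the optimal alignment cost instead
            # (column counts of co-optimal alignments may differ)
            b_del = b[:10] + b[12:]
            score = aligner.align(a, b_del).score
            ident_del, _ = pairwise_identity(a, b_del)
            import edlib

            ed = edlib.align(a, b_del, mode="NW")["editDistance"]
            assert ed == -score
            assert 0 <= ident_del <= matches / len(a)


class TestClusterOrthologs:
    def test_unrelated_genes_stay_singletons(self, rng):
        genes = [(f"g{i}", _random_protein(rng, 100)) for i in range(8)]
        gs = PhageGenomeSet(genomes={"A": genes})
        matrix = cluster_orthologs(gs)
        assert len(matrix.families) == 8
        assert pangenome_summary(matrix).singletons == {"A": 8}

    def test_two_identical_proteomes_are_all_core(self):
        gs = two_proteomes(identical=True)
        matrix = cluster_orthologs(gs)
        s = pangenome_summary(matrix)
        assert s.total_families == 10
        assert s.core_single_copy == 10
        assert s.singletons == {"A": 0, "B": 0}

    def test_recovers_true_families_on_synthetic_set(self):
        gs = simulate_pangenome(GeneEvolutionParams(seed=2, divergence=0.1))
        matrix = cluster_orthologs(gs)
        assert _ari(gs, matrix) >= 0.95

    def test_partition_property(self):
        gs = simulate_pangenome(GeneEvolutionParams(seed=4))
        matrix = cluster_orthologs(gs)
        assigned = [q for fam in matrix.families
                    for q in matrix.membership[fam]]
        qids = [f"{g}|{gid}" for g, gid, _ in gs.qualified_genes()]
        assert sorted(assigned) == sorted(qids)
        # column sums equal per-genome gene counts
        for k, g in enumerate(matrix.genomes):
            assert matrix.counts[:, k].sum() == len(gs.genomes[g])

    def test_raising_identity_threshold_never_merges(self):
        gs = simulate_pangenome(GeneEvolutionParams(seed=6, divergence=0.15))
        n_low = len(cluster_orthologs(
            gs, ClusteringParams(min_identity=0.4)).families)
        n_high = len(cluster_orthologs(
            gs, ClusteringParams(min_identity=0.7)).families)
        assert n_high >= n_low

    def test_invariant_under_genome_permutation(self):
        gs = simulate_pangenome(GeneEvolutionParams(seed=8, n_core=10))
        matrix = cluster_orthologs(gs)
        rev = PhageGenomeSet(
            genomes=dict(reversed(list(gs.genomes.items()))), truth=gs.truth
        )
        matrix_rev = cluster_orthologs(rev)
        sets = lambda m: sorted(
            tuple(sorted(m.membership[f])) for f in m.families
        )
        assert sets(matrix) == sets(matrix_rev)

    def test_complete_linkage_runs(self):
        gs = two_proteomes(identical=True)
        matrix = cluster_orthologs(gs, ClusteringParams(linkage="complete"))
        assert len(matrix.families) == 10

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_orthologs(PhageGenomeSet(genomes={}))

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            PhageGenomeSet(genomes={"A": [("g1", "MK9LV")]})


class TestSummary:
    def test_counts_match_brute_force_enumeration(self, rng):
        counts = rng.integers(0, 3, size=(50, 6))
        genomes = [f"G{i}" for i in range(6)]
        matrix = GeneFamilyMatrix(
            families=[f"F{i}" for i in range(50)], genomes=genomes,
            counts=counts,
        )
        s = pangenome_summary(matrix)
        # brute force over family rows
        core = sum(1 for row in counts if all(c == 1 for c in row))
        assert s.core_single_copy == core
        for k, g in enumerate(genomes):
            brute = sum(
                1 for row in counts
                if row[k] > 0 and all(c == 0 for j, c in enumerate(row) if j != k)
            )
            assert s.singletons[g] == brute
        for i in range(6):
            for j in range(6):
                brute = sum(1 for row in counts if row[i] > 0 and row[j] > 0)
                assert s.shared.iloc[i, j] == brute

    def test_singleton_family_with_paralogs_counts_once(self):
        matrix = GeneFamilyMatrix(
            families=["F1", "F2"], genomes=["A", "B"],
            counts=np.array([[3, 0], [1, 1]]),
        )
        assert pangenome_summary(matrix).singletons == {"A": 1, "B": 0}


class TestIdentityBins:
    def test_self_comparison_fills_top_bin(self):
        gs = two_proteomes(identical=True)
        hist = identity_bins(gs.genomes["A"], gs.genomes["B"])
        assert hist.counts[-1] == 10 and hist.below == 0

    def test_empty_target_puts_all_below(self):
        gs = two_proteomes(identical=True)
        hist = identity_bins(gs.genomes["A"], [])
        assert hist.below == 10 and sum(hist.counts) == 0

    def test_histogram_matches_direct_pairwise_oracle(self, rng):
        """Binned best-hit identities equal a direct recomputation for
        pairs of known divergence."""
        from phagekit.simulate import _mutate

        pairs = []
        for _ in range(20):
            a = _random_protein(rng, 80)
            pairs.append((a, _mutate(rng, a, float(rng.uniform(0, 0.5)))))
        genome_a = [(f"a{i}", p[0]) for i, p in enumerate(pairs)]
        genome_b = [(f"b{i}", p[1]) for i, p in enumerate(pairs)]
        edges = [0.5, 0.7, 0.8, 0.9, 0.95, 1.0]
        hist = identity_bins(genome_a, genome_b, bins=edges)
        # oracle: brute-force best hit per query
        brute = [0] * (len(edges) - 1)
        below = 0
        for _, sa in genome_a:
            best = max(
                ident
                for ident, cov in (pairwise_identity(sa, sb) for _, sb in genome_b)
                if cov >= 0.5
            )
            if best < edges[0]:
                below += 1
                continue
            for i in range(len(edges) - 1):
                if edges[i] <= best and (best < edges[i + 1] or i == len(edges) - 2):
                    brute[i] += 1
                    break
        assert hist.counts == brute and hist.below == below

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            identity_bins([], [("g", "MKL")])
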