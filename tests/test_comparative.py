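"""Pairwise identity, similarity matrices, variability and NJ trees."""

import numpy as np
import pytest

from plastotype import (
    GenomeInterval,
    nj_tree,
    pairwise_identity,
    similarity_matrix,
    variable_percentage,
)
from plastotype.comparative import SimilarityMatrix, aligned_pair_identity
from plastotype.errors import CapabilityError, ContractError, FormatError
from plastotype.simulate import SyntheticSpec, build_template, mutate


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def _edit_distance_identity_oracle(a, b):
    """Full O(nm) dynamic programming with unit costs; identity = matches
    over alignment columns, recovered from the traceback."""
    from Bio.Align import PairwiseAligner

    al = PairwiseAligner()
    al.mode = "global"
    al.match_score = 0
    al.mismatch_score = -1
    al.open_gap_score = -1
    al.extend_gap_score = -1
    aln = al.align(a, b)[0]
    c = aln.counts()
    return c.identities / (c.gaps + c.identities + c.mismatches)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        s = _random_seq(0, 5000)
        assert pairwise_identity(s, s) == 1.0

    def test_substitution_only_is_exact(self):
        """10 kb with exactly 500 substitutions -> identity 0.95 exactly."""
        s = list(_random_seq(1, 10000))
        rng = np.random.default_rng(2)
        pos = rng.choice(10000, size=500, replace=False)
        for p in pos:
            s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
        assert pairwise_identity(_random_seq(1, 10000), "".join(s)) == 0.95

    def test_mutated_genome_identity_equals_recorded_count(self, template):
        rec, truth = template
        mut, truth2 = mutate(rec, truth, substitution_rate=0.03, seed=5)
        k = len(truth2.mutations)
        assert k > 0
        assert pairwise_identity(rec.sequence, mut.sequence) == 1 - k / len(rec)

    @pytest.mark.parametrize("seed", range(5))
    def test_with_indels_close_to_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_seq(seed + 10, 800)
        b = list(a)
        for _ in range(20):
            p = int(rng.integers(0, len(b) - 5))
            r = rng.random()
            if r < 0.4:
                b[p] = "ACGT"[int(rng.integers(0, 4))]
            elif r < 0.7:
                del b[p : p + int(rng.integers(1, 4))]
            else:
                b.insert(p, "ACGT"[int(rng.integers(0, 4))])
        b = "".join(b)
        assert pairwise_identity(a, b) == pytest.approx(
            _edit_distance_identity_oracle(a, b), abs=0.005
        )

    def test_symmetry(self):
        a, b = _random_seq(20, 1500), _random_seq(21, 1450)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_over_length_raises_capability_error(self):
        with pytest.raises(CapabilityError):
            pairwise_identity("A" * 60000, "A" * 60000)


class TestSimilarityMatrix:
    def test_identical_records_all_ones(self, template):
        rec, _ = template
        from plastotype.records import replace_record

        recs = []
        for i in range(3):
            r = replace_record(rec)
            r.identifier = f"T{i}"
            recs.append(r)
        mat = similarity_matrix(recs)
        assert np.allclose(mat.values, 1.0)

    def test_identity_decreases_with_divergence(self):
        """Star-simulated descendants: higher substitution rate, lower
        identity against the shared ancestor and all slower relatives."""
        rec, truth = build_template(SyntheticSpec(seed=77))
        tips = {"anc": rec}
        for name, rate in [("r01", 0.01), ("r05", 0.05), ("r10", 0.10)]:
            tips[name], _ = mutate(rec, truth, substitution_rate=rate, seed=hash(name) % 1000)
        for r in tips.values():
            r.identifier = [k for k, v in tips.items() if v is r][0]
        mat = similarity_matrix(list(tips.values()))
        assert mat.pair("anc", "r01") > mat.pair("anc", "r05") > mat.pair("anc", "r10")
        assert mat.pair("r01", "r05") > mat.pair("r01", "r10")

    def test_two_clusters_separate(self):
        """Within-cluster divergence 0.01 vs between-cluster 0.10: every
        within-cluster identity exceeds every between-cluster identity."""
        rec, truth = build_template(SyntheticSpec(seed=88))
        far, far_truth = mutate(rec, truth, substitution_rate=0.10, seed=1)
        taxa = {}
        for i in range(2):
            taxa[f"a{i}"], _ = mutate(rec, truth, substitution_rate=0.01, seed=10 + i)
            taxa[f"b{i}"], _ = mutate(far, far_truth, substitution_rate=0.01, seed=20 + i)
        for k, r in taxa.items():
            r.identifier = k
        mat = similarity_matrix(list(taxa.values()))
        within = [mat.pair("a0", "a1"), mat.pair("b0", "b1")]
        between = [mat.pair(a, b) for a in ("a0", "a1") for b in ("b0", "b1")]
        assert min(within) > max(between)
        # and the NJ tree groups each cluster as a clade
        nwk = nj_tree(mat)
        import skbio

        tree = skbio.TreeNode.read([nwk])
        a_clade = tree.lca(["a0", "a1"])
        assert {t.name for t in a_clade.tips()} == {"a0", "a1"}

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">x\nACGT\n>y\nACG\n")
        with pytest.raises(FormatError):
            similarity_matrix(p)

    def test_alignment_input_gap_convention(self, tmp_path):
        p = tmp_path / "aln.fasta"
        # 10 columns; pair x,y: 1 both-gap column dropped, 9 comparable,
        # 1 gap column + 1 mismatch among them -> 7/9
        p.write_text(">x\nACGTACGT-A\n>y\nACGTACGA--\n")
        mat = similarity_matrix(p)
        assert mat.pair("x", "y") == pytest.approx(7 / 9)
        assert aligned_pair_identity("AC-GT", "AC-GT") == 1.0


class TestVariablePercentage:
    def test_identical_rows_zero_percent(self):
        aln = [("a", "ACGTACGTAC"), ("b", "ACGTACGTAC"), ("c", "ACGTACGTAC")]
        out = variable_percentage(aln, [("whole", "non-coding", GenomeInterval(0, 10))], "a")
        assert out[0].percent_variable == 0.0

    def test_hand_counted_toy_alignment(self):
        """Five taxa, 10 columns, exactly 3 variable -> 30%."""
        aln = [
            ("ref", "ACGTACGTAC"),
            ("t1",  "ACGTACGTAC"),
            ("t2",  "TCGTACGTAC"),   # col 0 variable
            ("t3",  "ACGAACGTAC"),   # col 3 variable
            ("t4",  "ACGTACGTGC"),   # col 8 variable
        ]
        out = variable_percentage(aln, [("whole", "non-coding", GenomeInterval(0, 10))], "ref")
        assert out[0].columns == 10 and out[0].variable_columns == 3
        assert out[0].percent_variable == pytest.approx(0.30)

    def test_projection_through_reference_gaps(self):
        aln = [
            ("ref", "AC--GTAC"),
            ("t1",  "ACTTGTAC"),
            ("t2",  "ACTTGAAC"),     # one variable col inside ref positions
        ]
        out = variable_percentage(aln, [("r", "coding", GenomeInterval(0, 6))], "ref")
        assert out[0].columns == 6
        assert out[0].variable_columns == 1

    def test_region_counts_sum_to_genome_wide_count(self):
        rng = np.random.default_rng(12)
        width = 60
        rows = []
        base = rng.choice(list("ACGT"), width)
        for t in range(4):
            row = base.copy()
            idx = rng.choice(width, size=6, replace=False)
            row[idx] = [rng.choice(list("ACGT")) for _ in idx]
            rows.append((f"t{t}", "".join(row)))
        parts = [
            ("p1", "coding", GenomeInterval(0, 20)),
            ("p2", "coding", GenomeInterval(20, 45)),
            ("p3", "non-coding", GenomeInterval(45, 60)),
        ]
        whole = variable_percentage(rows, [("all", "coding", GenomeInterval(0, 60))], "t0")
        split = variable_percentage(rows, parts, "t0")
        assert sum(r.variable_columns for r in split) == whole[0].variable_columns

    def test_interval_beyond_reference_rejected(self):
        aln = [("a", "ACGT"), ("b", "ACGT")]
        with pytest.raises(Exception):
            variable_percentage(aln, [("x", "coding", GenomeInterval(0, 99))], "a")

    def test_n_treated_as_missing(self):
        aln = [("a", "ANGT"), ("b", "ACGT"), ("c", "ATGT")]
        out = variable_percentage(aln, [("w", "coding", GenomeInterval(0, 4))], "a")
        # col 1: states {N, C, T} -> C/T differ -> variable; others constant
        assert out[0].variable_columns == 1


class TestNJTree:
    def test_three_taxa_unique_topology(self):
        vals = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.85], [0.8, 0.85, 1.0]])
        nwk = nj_tree(SimilarityMatrix(["a", "b", "c"], vals))
        assert nwk.count("(") >= 1 and all(t in nwk for t in "abc")

    def test_additive_six_taxon_matrix_recovers_topology(self):
        """NJ is consistent on additive distances: recover ((a,b),(c,d),(e,f))."""
        import skbio

        true = skbio.TreeNode.read(["((a:1,b:1):2,(c:1,d:1):2,(e:1,f:1):2);"])
        taxa = ["a", "b", "c", "d", "e", "f"]
        dist = np.zeros((6, 6))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    dist[i, j] = true.find(x).distance(true.find(y))
        sim = SimilarityMatrix(taxa, 1 - dist / dist.max() * 0.5)
        got = skbio.TreeNode.read([nj_tree(sim)])
        assert got.compare_rfd(true) == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ContractError):
            nj_tree(SimilarityMatrix(["a", "b"], np.eye(2)))
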