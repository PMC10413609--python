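"""SSR, dispersed-repeat and tandem-repeat mining against brute-force oracles."""

import numpy as np
import pytest

from plastotype import (
    assign_context,
    find_long_repeats,
    find_ssrs,
    find_tandem_repeats,
    partition,
)
from plastotype._util import revcomp, smallest_period
from plastotype.errors import ParameterError
from plastotype.simulate import SyntheticSpec, plant_repeats


from _oracles import (  # noqa: E402  (sibling test helper)
    impl_repeat_keys as _impl_keys,
    plant_pairs as _plant_pairs,
    random_seq as _random_seq,
    repeat_oracle,
    ssr_oracle,
)


# ---------------------------------------------------------------------------
# SSRs


class TestFindSSRs:
    def test_mononucleotide_threshold_boundary(self):
        bg = _random_seq(3, 400)
        below = bg[:100] + "G" * 9 + bg[100:200]
        above = bg[:100] + "G" * 10 + bg[100:200]
        assert all(h.motif != "G" for h in find_ssrs(below))
        hits = [h for h in find_ssrs(above) if h.motif == "G"]
        assert len(hits) == 1 and hits[0].copy_number == 10

    def test_dinucleotide_reported_only_at_smallest_period(self):
        bg = _random_seq(4, 300)
        s = bg[:100] + "AT" * 6 + "C" + bg[100:]
        hits = [h for h in find_ssrs(s) if 95 <= h.interval.start <= 105]
        assert len(hits) == 1
        h = hits[0]
        assert (h.unit_len, h.copy_number, h.motif) == (2, 6, "AT")

    def test_motif_standardised_to_minimal_rotation(self):
        s = _random_seq(5, 100) + "TGA" * 5 + "C" + _random_seq(6, 100)
        hits = [h for h in find_ssrs(s) if h.unit_len == 3]
        assert hits and hits[0].motif == "ATG"  # min rotation of TGA

    def test_runs_broken_at_n(self):
        s = "C" * 5 + "N" + "C" * 6 + "GATTACA" * 3
        assert find_ssrs(s) == []

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            find_ssrs("ACGT" * 10, thresholds={7: 5})
        with pytest.raises(ParameterError):
            find_ssrs("ACGT" * 10, thresholds={1: 1})

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich alphabet raises the SSR density so the check is non-vacuous
        s = "".join(rng.choice(list("AATTACGT"), 3000))
        got = {(h.interval.start, h.unit_len, h.copy_number) for h in find_ssrs(s)}
        assert got == ssr_oracle(s)

    def test_planted_array_is_the_only_hit(self, template):
        rec, truth = template
        rec2, truth2 = plant_repeats(rec, truth, ssrs=[("A", 10, "LSC")])
        hits = find_ssrs(rec2.sequence)
        assert len(hits) == 1
        p = truth2.planted_ssrs[0]
        assert (hits[0].interval.start, hits[0].copy_number) == (p["start"], 10)


# ---------------------------------------------------------------------------
# dispersed repeats


class TestFindLongRepeats:
    def test_single_exact_copy_pair(self):
        core = _random_seq(7, 30)
        bg = _random_seq(8, 2000)
        s = bg[:500] + core + bg[500:1200] + core + bg[1200:]
        hits = find_long_repeats(s, circular=False)
        exact = [h for h in hits if h.mismatches == 0 and h.kind == "direct"]
        assert len(exact) == 1
        h = exact[0]
        assert h.length >= 30
        assert h.interval_a.start <= 500 <= h.interval_a.end

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_all_pairs_hamming_oracle(self, seed):
        s = _plant_pairs(seed, 2000)
        got = _impl_keys(find_long_repeats(s, circular=False))
        assert got == repeat_oracle(s)

    def test_reverse_complement_maps_hit_sets_onto_mirror(self):
        s = _plant_pairs(99, 1500)
        fwd = find_long_repeats(s, circular=False)
        rev = find_long_repeats(revcomp(s), circular=False)
        N = len(s)

        def mirror(h):
            a = (N - h.interval_b.end, N - h.interval_b.start)
            b = (N - h.interval_a.end, N - h.interval_a.start)
            return (h.kind, min(a, b)[0], max(a, b)[0], h.length, h.mismatches)

        assert {mirror(h) for h in fwd} == _impl_keys(rev)

    def test_ir_arm_match_excluded_by_default(self, template):
        rec, _ = template
        part = partition(rec)
        kept = find_long_repeats(rec.sequence, partition=part)
        assert kept == []
        raw = find_long_repeats(rec.sequence, exclude_ir_pair=False, partition=part)
        arm = max(raw, key=lambda h: h.length)
        assert arm.kind == "palindromic" and arm.length == part.ir_length

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            find_long_repeats("ACGT" * 100, min_len=0)


# ---------------------------------------------------------------------------
# tandem repeats


class TestFindTandemRepeats:
    def test_exact_array_unit7_copies4(self):
        bg = _random_seq(4, 600)
        s = bg[:200] + "GATCCGA" * 4 + bg[200:400]
        hits = [h for h in find_tandem_repeats(s) if 190 <= h.interval.start <= 210]
        assert len(hits) == 1
        assert hits[0].copies == 4.0 and len(hits[0].unit) == 7
        assert hits[0].match_fraction == 1.0

    def test_unit_below_minimum_not_reported_at_its_period(self):
        bg = _random_seq(4, 600)
        s = bg[:200] + "GATCCG" * 10 + bg[200:400]
        # the 6-mer array must not surface as a (multiple-of-)6 period report
        for h in find_tandem_repeats(s):
            assert smallest_period(h.unit) >= 7

    def test_min_unit_parameter_validated(self):
        with pytest.raises(ParameterError):
            find_tandem_repeats("ACGT" * 100, min_unit=1)

    def test_planted_corrupted_arrays_recovered(self):
        recovered = total = 0
        for seed in range(12):
            rng = np.random.default_rng([seed, 55])
            bg = _random_seq(seed + 300, 6000)
            plants, pos = [], 300
            for _ in range(5):
                u = int(rng.integers(7, 30))
                ncopy = int(rng.integers(2, 7))
                corrupt = rng.uniform(0, 0.1)
                unit = "".join(rng.choice(list("ACGT"), u))
                arr = list(unit * ncopy)
                for i in range(len(arr)):
                    if rng.random() < corrupt:
                        arr[i] = "ACGT"[int(rng.integers(0, 4))]
                arr = "".join(arr)
                bg = bg[:pos] + arr + bg[pos + len(arr):]
                plants.append((pos, pos + len(arr), u))
                pos += len(arr) + 900
            hits = find_tandem_repeats(bg)
            for a, b, u in plants:
                total += 1
                recovered += any(
                    len(h.unit) == u
                    and min(h.interval.end, b) - max(h.interval.start, a) >= 0.5 * (b - a)
                    for h in hits
                )
        assert recovered / total >= 0.95

    def test_harmonics_collapse_to_smallest_period(self):
        bg = _random_seq(21, 600)
        s = bg[:250] + "GATTACAGG" * 6 + bg[250:500]  # 9-mer, 6 copies
        overlapping = [
            h for h in find_tandem_repeats(s)
            if h.interval.start < 250 + 54 and h.interval.end > 250
        ]
        assert {len(h.unit) for h in overlapping} == {9}


# ---------------------------------------------------------------------------
# region / context labels


class TestAssignContext:
    def test_planted_hits_get_expected_labels(self, template):
        rec, truth = template
        rec2, truth2 = plant_repeats(
            rec, truth, ssrs=[("A", 10, "LSC"), ("CT", 6, "SSC")]
        )
        part = partition(rec2)
        hits = assign_context(find_ssrs(rec2.sequence), part, rec2)
        labels = {(h.motif, h.region, h.context) for h in hits}
        assert ("A", "LSC", "IGS") in labels
        assert ("CT", "SSC", "IGS") in labels

    def test_cds_and_intron_contexts(self, template):
        rec, _ = template
        part = partition(rec)
        from plastotype.repeat_mining import SSRHit
        from plastotype.records import GenomeInterval

        psba = rec.features_named("psbA")[0].exons[0]
        atpf = rec.features_named("atpF")[0]
        intron_mid = (atpf.exons[0].end + atpf.exons[1].start) // 2
        fake = [
            SSRHit("A", 1, 10, GenomeInterval(psba.start + 5, psba.start + 15)),
            SSRHit("A", 1, 10, GenomeInterval(intron_mid - 5, intron_mid + 5)),
        ]
        out = assign_context(fake, part, rec)
        assert out[0].context == "CDS"
        assert out[1].context == "intron"

    def test_ir_region_collapses_arm_labels(self, template):
        rec, _ = template
        part = partition(rec)
        from plastotype.repeat_mining import SSRHit
        from plastotype.records import GenomeInterval

        irb_mid = (part.irb.start + part.irb.end) // 2
        ira_mid = (part.ira.start + part.ira.end) // 2
        fake = [
            SSRHit("A", 1, 10, GenomeInterval(irb_mid, irb_mid + 10)),
            SSRHit("A", 1, 10, GenomeInterval(ira_mid, ira_mid + 10)),
        ]
        out = assign_context(fake, part, rec)
        assert out[0].region == out[1].region == "IR"

    def test_ir_absent_partition_labels_everything_lsc(self, typed_genomes):
        rec, _ = typed_genomes["VI"]
        part = partition(rec)
        hits = assign_context(find_ssrs(rec.sequence), part, rec)
        assert all(h.region == "LSC" for h in hits)
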