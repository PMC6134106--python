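import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st
from scipy import stats

from mitodyn.characterize import (CHI2_CRIT_P001, CHI2_CRIT_P05, MutationClass,
                                  annotate_effect, blosum62_scorer,
                                  classify_substitution, enrichment_test,
                                  most_recent_samples, private_shared_partition,
                                  spectrum_summary, spectrum_test)
from mitodyn.simulate import simulate_population


class TestClassifySubstitution:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("G", "A", MutationClass.GC_AT_TRANSITION),
        ("C", "T", MutationClass.GC_AT_TRANSITION),
        ("C", "A", MutationClass.GC_TA_TRANSVERSION),
        ("G", "T", MutationClass.GC_TA_TRANSVERSION),
        ("A", "T", MutationClass.AT_TA_TRANSVERSION),
        ("G", "C", MutationClass.GC_CG_TRANSVERSION),
    ])
    def test_known_classes(self, ref, alt, expected):
        assert classify_substitution(ref, alt) is expected

    def test_twelve_substitutions_partition_into_four_classes(self):
        tally = {m: 0 for m in MutationClass}
        for ref, alt in itertools.permutations("ACGT", 2):
            tally[classify_substitution(ref, alt)] += 1
        assert tally == {MutationClass.GC_AT_TRANSITION: 4,
                         MutationClass.GC_TA_TRANSVERSION: 4,
                         MutationClass.AT_TA_TRANSVERSION: 2,
                         MutationClass.GC_CG_TRANSVERSION: 2}

    def test_strand_symmetry(self):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for ref, alt in itertools.permutations("ACGT", 2):
            assert classify_substitution(ref, alt) is \
                classify_substitution(comp[ref], comp[alt])

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")
        with pytest.raises(ValueError):
            classify_substitution("A", "N")


class TestSpectrumSummary:
    def _frame(self, pairs):
        return pd.DataFrame([{"sample_id": f"s{i}", "position": i + 1,
                              "ref": r, "alt": a, "maf": 0.02}
                             for i, (r, a) in enumerate(pairs)])

    def test_ts_tv_ratio(self):
        calls = self._frame([("G", "A")] * 6 + [("G", "T")] * 2 + [("A", "T")])
        s = spectrum_summary(calls)
        assert s.ts_tv == pytest.approx(2.0)
        assert s.counts["GC_AT_transition"] == 6
        assert sum(s.counts.values()) == s.n_calls == 9

    def test_all_transitions_has_undefined_ts_tv(self):
        s = spectrum_summary(self._frame([("C", "T"), ("G", "A")]))
        assert s.ts_tv is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            spectrum_summary(pd.DataFrame(columns=["ref", "alt"]))

    def test_generator_round_trip_recovers_class_weights(self):
        # scale the default population up so the empirical class mixture is
        # estimated from >= 10,000 calls
        from mitodyn.simulate import PopulationParams
        params = PopulationParams(cohort_sizes=tuple(
            (a, n * 50) for a, n in PopulationParams().cohort_sizes))
        pop = simulate_population(params, seed=10)
        assert len(pop.calls) >= 10_000
        s = spectrum_summary(pop.calls)
        for frac, target in zip(
                [s.fractions[m.value] for m in MutationClass],
                (0.606, 0.319, 0.075, 0.0)):
            assert abs(frac - target) < 0.02

    def test_oxidative_burden_per_sample(self):
        calls = pd.DataFrame([
            {"sample_id": "a", "ref": "G", "alt": "T", "maf": 0.02},
            {"sample_id": "a", "ref": "C", "alt": "A", "maf": 0.02},
            {"sample_id": "b", "ref": "G", "alt": "A", "maf": 0.02},
        ])
        s = spectrum_summary(calls)
        assert s.oxidative_per_sample.to_dict() == {"a": 2}


class TestAnnotateEffect:
    def test_plus_strand_annotation_matches_brute_force_translation(self, coding_genome):
        self._check_gene(coding_genome, "GENEP")

    def test_minus_strand_annotation_matches_brute_force_translation(self, coding_genome):
        self._check_gene(coding_genome, "GENEM")

    def _check_gene(self, genome, gene_name):
        """Oracle: mutate the full gene sequence and translate both versions
        with Biopython; compare the syn/nonsyn/nonsense verdict per site."""
        feature = next(f for f in genome.features if f.name == gene_name)
        gene = genome.sequence[feature.start - 1:feature.end]
        if feature.strand == "-":
            gene = str(Seq(gene).reverse_complement())
        ref_protein = str(Seq(gene).translate(table=2))
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for pos in range(feature.start, feature.end + 1):
            ref = genome.base(pos)
            for alt in set("ACGT") - {ref}:
                ann = [a for a in annotate_effect(pos, ref, alt, genome)
                       if a.gene == gene_name][0]
                idx = (feature.end - pos) if feature.strand == "-" \
                    else (pos - feature.start)
                sub = comp[alt] if feature.strand == "-" else alt
                mutated = gene[:idx] + sub + gene[idx + 1:]
                alt_protein = str(Seq(mutated).translate(table=2))
                # compare the affected codon's residue (a random gene can
                # carry unrelated internal stops)
                aa_ref, aa_alt = ref_protein[idx // 3], alt_protein[idx // 3]
                if aa_alt == aa_ref:
                    expected = "synonymous"
                elif "*" in (aa_alt, aa_ref):
                    expected = "nonsense"
                else:
                    expected = "nonsynonymous"
                assert ann.effect == expected, (pos, ref, alt)
                assert ann.codon_position == idx % 3 + 1

    def test_vertebrate_code_tga_is_tryptophan(self, coding_genome):
        # TGG->TGA is synonymous (Trp) under the mitochondrial code, the
        # classic divergence from the standard code; verified through the
        # brute-force gene scan above, asserted directly on the code table here
        assert str(Seq("TGA").translate(table=2)) == "W"
        assert str(Seq("TGG").translate(table=2)) == "W"

    def test_noncoding_feature_and_intergenic_positions(self, coding_genome):
        cr = annotate_effect(310, coding_genome.base(310),
                             "A" if coding_genome.base(310) != "A" else "C",
                             coding_genome)
        assert cr[0].effect == "noncoding" and cr[0].gene == "CR"
        inter = annotate_effect(10, coding_genome.base(10),
                                "A" if coding_genome.base(10) != "A" else "C",
                                coding_genome)
        assert inter[0].effect == "noncoding" and inter[0].gene is None

    def test_overlapping_protein_features_emit_one_record_each(self, coding_genome):
        from mitodyn.genome import Feature, Mitogenome
        overlapped = Mitogenome(coding_genome.sequence,
                                coding_genome.features +
                                [Feature("GENEX", "protein", 60, 131, "+", 0)])
        pos = 100
        ref = overlapped.base(pos)
        alt = "A" if ref != "A" else "C"
        anns = annotate_effect(pos, ref, alt, overlapped)
        assert sorted(a.gene for a in anns) == ["GENEP", "GENEX"]

    def test_reference_mismatch_rejected(self, coding_genome):
        ref = coding_genome.base(100)
        wrong = "A" if ref != "A" else "C"
        other = ({"A", "C", "G", "T"} - {ref, wrong}).pop()
        with pytest.raises(ValueError, match="reference"):
            annotate_effect(100, wrong, other, coding_genome)

    def test_deleteriousness_only_for_nonsynonymous(self, coding_genome):
        feature = next(f for f in coding_genome.features if f.name == "GENEP")
        seen = set()
        for pos in range(feature.start, feature.end + 1):
            ref = coding_genome.base(pos)
            for alt in set("ACGT") - {ref}:
                ann = [a for a in annotate_effect(pos, ref, alt, coding_genome)
                       if a.gene == "GENEP"][0]
                seen.add(ann.effect)
                if ann.effect == "nonsynonymous":
                    assert ann.deleteriousness in ("Deleterious", "Neutral")
                else:
                    assert ann.deleteriousness == "NA"
        assert "synonymous" in seen and "nonsynonymous" in seen

    def test_blosum_scorer_labels(self):
        assert blosum62_scorer("A", "V") == "Neutral"      # BLOSUM62 = 0
        assert blosum62_scorer("W", "G") == "Deleterious"  # strongly negative


class TestSpectrumTest:
    def test_identical_samples_ks(self):
        stat, p = spectrum_test([0.01, 0.02, 0.03], [0.01, 0.02, 0.03], "ks")
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.05, 50)
        b = rng.uniform(0.05, 0.10, 50)
        for test in ("ks", "mwu"):
            _, p = spectrum_test(a, b, test)
            assert p < 0.001

    def test_mwu_exact_small_sample(self):
        # extreme ranking of 3 vs 3: exact two-sided p = 2/C(6,3) = 0.1
        _, p = spectrum_test([1, 2, 3], [4, 5, 6], "mwu")
        assert p == pytest.approx(0.1)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            spectrum_test([], [1.0], "ks")
        with pytest.raises(ValueError):
            spectrum_test([1.0], [1.0, 2.0], "ks")
        with pytest.raises(ValueError):
            spectrum_test([1.0], [2.0], "anova")


class TestEnrichmentTest:
    def test_hand_computed_two_by_two(self):
        # table ((20, 1480), (123, 13877)); Pearson formula as oracle
        res = enrichment_test(20, 1500, 143, 15500)
        obs = np.array([[20, 1480], [123, 13877]], float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / n
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert res.chi2 == pytest.approx(chi2)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_critical_value_flags(self):
        assert CHI2_CRIT_P05 == pytest.approx(stats.chi2.isf(0.05, 1), abs=5e-4)
        assert CHI2_CRIT_P001 == pytest.approx(stats.chi2.isf(0.001, 1), abs=5e-4)
        res = enrichment_test(50, 1000, 143, 15500, critical_value=CHI2_CRIT_P001)
        assert res.enriched

    def test_proportional_bin_gives_zero_statistic(self):
        # bin het fraction equals genome-wide het fraction exactly
        res = enrichment_test(10, 1000, 100, 10000)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert not res.enriched

    def test_zero_length_bin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(0, 0, 100, 10000)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 50), st.integers(100, 1000),
           st.integers(60, 200), st.integers(5000, 20000))
    def test_chi2_invariant_to_table_transposition(self, a, blen, tot, glen):
        if a > min(blen, tot):
            a = min(blen, tot)
        res = enrichment_test(a, blen, tot, glen)
        arr = np.array(res.table, float)
        chi2_t, _, _, _ = stats.chi2_contingency(arr.T, correction=False)
        chi2_s, _, _, _ = stats.chi2_contingency(arr[::-1, ::-1], correction=False)
        assert res.chi2 == pytest.approx(chi2_t) == pytest.approx(chi2_s)


class TestPrivateShared:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["individual_id", "position", "maf"])

    def test_single_individual_all_private(self):
        part = private_shared_partition(self._calls(
            [("i1", 100, 0.02), ("i1", 200, 0.05)]))
        assert part.private_fraction == 1.0
        assert part.shared_mafs.size == 0

    def test_two_carriers_make_a_site_shared(self):
        part = private_shared_partition(self._calls(
            [("i1", 100, 0.02), ("i2", 100, 0.03), ("i2", 200, 0.04)]))
        labels = dict(zip(part.sites["position"], part.sites["label"]))
        assert labels == {100: "shared", 200: "private"}
        assert sorted(part.shared_mafs) == [0.02, 0.03]

    def test_generator_round_trip_without_hotspots_is_nearly_all_private(self):
        from mitodyn.simulate import PopulationParams
        params = PopulationParams(hotspot_fraction=0.0, recapture_design=(),
                                  spike_prob=0.0)
        pop = simulate_population(params, seed=11)
        part = private_shared_partition(
            pop.calls.merge(pop.samples[["sample_id"]], on="sample_id"))
        # ~230 uniform draws over 16,211 sites: collisions are rare
        assert part.private_fraction > 0.95

    def test_most_recent_sample_reduction(self):
        samples = pd.DataFrame({
            "sample_id": ["a13", "a15", "b14"],
            "individual_id": ["a", "a", "b"],
            "year": [2013, 2015, 2014],
        })
        reduced = most_recent_samples(samples)
        assert sorted(reduced["sample_id"]) == ["a15", "b14"]
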