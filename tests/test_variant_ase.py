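"""Somatic evidence filtering, TMB and ASE classification."""

import pytest
from hypothesis import given, settings, strategies as st

from gistcin.variant_ase import (
    AseClass,
    AseObservation,
    FilterThresholds,
    SomaticVariant,
    ase_cohort_summary,
    ase_sample_summary,
    classify_ase,
    compute_tmb,
    filter_somatic,
)
from gistcin.synthetic_data import simulate_ase_table


def variant(tumour_depth=100, control_depth=60, alt=30, sample="S1"):
    return SomaticVariant(
        sample_id=sample, chrom="1", pos=100, ref="A", alt="G", gene="KIT",
        variant_class="SNV", tumour_depth=tumour_depth,
        control_depth=control_depth, tumour_alt_reads=alt,
    )


def obs(tpm, ref, alt, sample="S1"):
    return AseObservation(variant(sample=sample), gene_tpm=tpm,
                          rna_ref_count=ref, rna_alt_count=alt)


class TestFilterSomatic:
    def test_all_boundaries_inclusive(self):
        # 50x tumour, 30x control, MAF exactly 0.03 via 5/166... use depth
        # where alt/depth >= 0.03 holds exactly at the printed thresholds
        v = variant(tumour_depth=100, control_depth=30, alt=5)  # maf 0.05
        assert filter_somatic([v]) == [v]
        exact = variant(tumour_depth=50, control_depth=30, alt=5)  # maf 0.1
        assert filter_somatic([exact]) == [exact]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tumour_depth": 49, "alt": 5},
            {"control_depth": 29},
            {"tumour_depth": 200, "alt": 5},  # maf 0.025 < 0.03
            {"alt": 4},
        ],
    )
    def test_each_failing_threshold_removes(self, kwargs):
        base = {"tumour_depth": 100, "control_depth": 60, "alt": 30}
        assert filter_somatic([variant(**{**base, **kwargs})]) == []

    def test_order_preserved_and_idempotent(self):
        vs = [variant(alt=30), variant(alt=4), variant(alt=6)]
        kept = filter_somatic(vs)
        assert kept == [vs[0], vs[2]]
        assert filter_somatic(kept) == kept

    @given(
        depth_min=st.integers(0, 200),
        bump=st.integers(0, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_a_threshold_never_adds_a_variant(self, depth_min, bump):
        vs = [variant(tumour_depth=d, alt=max(5, d // 10)) for d in range(30, 200, 17)]
        lo = filter_somatic(vs, FilterThresholds(tumour_depth_min=depth_min))
        hi = filter_somatic(vs, FilterThresholds(tumour_depth_min=depth_min + bump))
        assert set(hi) <= set(lo)


class TestComputeTmb:
    def test_low_burden(self):
        out = compute_tmb(100, 50.0)
        assert out == {"tmb": 2.0, "low_tmb": True}

    def test_boundary_is_strictly_fewer_than_five(self):
        assert compute_tmb(250, 50.0) == {"tmb": 5.0, "low_tmb": False}

    def test_zero_mutations(self):
        assert compute_tmb(0, 38.0) == {"tmb": 0.0, "low_tmb": True}

    def test_bad_target_size(self):
        with pytest.raises(ValueError):
            compute_tmb(10, 0.0)


class TestClassifyAse:
    def test_gene_below_tpm_cutoff_is_not_expressed(self):
        assert classify_ase(obs(1.9, 10, 10)) is AseClass.GENE_NOT_EXPRESSED

    def test_expressed_gene_with_high_vaf(self):
        assert classify_ase(obs(10.0, 75, 25)) is AseClass.MUTATED_EXPRESSED

    def test_vaf_exactly_at_cutoff_is_not_expressed(self):
        assert classify_ase(obs(10.0, 97, 3)) is AseClass.MUTATED_NOT_EXPRESSED

    def test_tpm_exactly_at_cutoff_counts_as_expressed_gene(self):
        assert classify_ase(obs(2.0, 50, 50)) is AseClass.MUTATED_EXPRESSED

    def test_no_rna_coverage(self):
        assert classify_ase(obs(10.0, 0, 0)) is AseClass.NOT_COVERED

    def test_coverage_check_precedes_tpm(self):
        assert classify_ase(obs(0.0, 0, 0)) is AseClass.NOT_COVERED

    def test_confusion_matrix_is_diagonal_on_planted_classes(self):
        n = {
            AseClass.MUTATED_EXPRESSED: 320,
            AseClass.MUTATED_NOT_EXPRESSED: 330,
            AseClass.GENE_NOT_EXPRESSED: 250,
            AseClass.NOT_COVERED: 100,
        }
        observations, labels = simulate_ase_table(n, seed=5)
        assert [classify_ase(o) for o in observations] == labels

    def test_boundary_observations_classified_per_rules(self):
        observations, labels = simulate_ase_table({}, seed=0, include_boundaries=True)
        assert [classify_ase(o) for o in observations] == labels
        assert labels == [AseClass.MUTATED_EXPRESSED, AseClass.MUTATED_NOT_EXPRESSED]

    def test_order_permutation_does_not_change_classes(self):
        observations, labels = simulate_ase_table(
            {AseClass.MUTATED_EXPRESSED: 20, AseClass.GENE_NOT_EXPRESSED: 20}, seed=3
        )
        rev = [classify_ase(o) for o in reversed(observations)]
        assert rev == list(reversed(labels))


class TestAseSummary:
    def test_one_of_each_class(self):
        observations = [obs(10.0, 50, 50), obs(10.0, 99, 1), obs(0.5, 10, 10)]
        props = ase_sample_summary(observations)
        assert props[AseClass.MUTATED_EXPRESSED] == pytest.approx(1 / 3)
        assert props[AseClass.MUTATED_NOT_EXPRESSED] == pytest.approx(1 / 3)
        assert props[AseClass.GENE_NOT_EXPRESSED] == pytest.approx(1 / 3)

    def test_all_expressed(self):
        props = ase_sample_summary([obs(10.0, 50, 50)] * 4)
        assert props[AseClass.MUTATED_EXPRESSED] == 1.0

    def test_not_covered_excluded_from_denominator(self):
        observations = [obs(10.0, 50, 50), obs(10.0, 0, 0)]
        props = ase_sample_summary(observations)
        assert props[AseClass.MUTATED_EXPRESSED] == 1.0

    def test_planted_fractions_recovered_to_one_over_n(self):
        n = 1000
        fractions = {"expressed": 0.31, "not_expressed": 0.32, "gene_not": 0.37}
        counts = {
            AseClass.MUTATED_EXPRESSED: round(fractions["expressed"] * n),
            AseClass.MUTATED_NOT_EXPRESSED: round(fractions["not_expressed"] * n),
            AseClass.GENE_NOT_EXPRESSED: round(fractions["gene_not"] * n),
        }
        observations, _ = simulate_ase_table(counts, seed=9)
        props = ase_sample_summary(observations)
        assert props[AseClass.MUTATED_EXPRESSED] == pytest.approx(0.31, abs=1 / n)
        assert props[AseClass.MUTATED_NOT_EXPRESSED] == pytest.approx(0.32, abs=1 / n)
        assert props[AseClass.GENE_NOT_EXPRESSED] == pytest.approx(0.37, abs=1 / n)

    def test_proportions_sum_to_one_and_duplication_invariant(self):
        observations, _ = simulate_ase_table(
            {AseClass.MUTATED_EXPRESSED: 7, AseClass.GENE_NOT_EXPRESSED: 13}, seed=2
        )
        props = ase_sample_summary(observations)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
        assert ase_sample_summary(observations * 2) == props

    def test_all_not_covered_raises_with_sample_name(self):
        with pytest.raises(ValueError, match="S1"):
            ase_sample_summary([obs(10.0, 0, 0)])

    def test_cohort_summary_has_pooled_row(self):
        obs_a, _ = simulate_ase_table({AseClass.MUTATED_EXPRESSED: 10}, seed=1,
                                      sample_id="A")
        obs_b, _ = simulate_ase_table({AseClass.GENE_NOT_EXPRESSED: 30}, seed=2,
                                      sample_id="B")
        table = ase_cohort_summary(obs_a + obs_b)
        pooled = table[table["sample"] == "pooled"].iloc[0]
        assert pooled["n_covered"] == 40
        assert pooled["prop_mutated_expressed"] == pytest.approx(0.25)
        # per-sample proportions are not the pooled ones
        assert table[table["sample"] == "A"].iloc[0]["prop_mutated_expressed"] == 1.0
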