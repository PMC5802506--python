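"""Generator contracts: determinism, planted-truth consistency, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirelapse.integration import spearman
from mirelapse.profiling import normalize_counts
from mirelapse.qpcr import relative_expression_from_table
from mirelapse.survival import logrank_test
from mirelapse.synthetic import (
    component_seed,
    generate_ct_replicates,
    generate_mrna_expression,
    generate_paired_mirna_counts,
    generate_reference_expression,
    generate_survival_cohort,
    generate_target_resources,
)


class TestPairedCounts:
    def test_same_seed_bit_identical(self):
        a, _, _ = generate_paired_mirna_counts(n_mirnas=50, n_pairs=3, seed=5)
        b, _, _ = generate_paired_mirna_counts(n_mirnas=50, n_pairs=3, seed=5)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_counts_are_nonnegative_integers_with_sane_library_sizes(self):
        m, _, _ = generate_paired_mirna_counts(n_mirnas=300, n_pairs=7, depth=1e5, seed=2)
        arr = m.values.to_numpy()
        assert (arr >= 0).all() and np.allclose(arr, np.round(arr))
        lib = arr.sum(axis=0)
        assert abs(lib.mean() / 1e5 - 1) < 0.1
        assert np.all(np.abs(lib - lib.mean()) < 3 * max(lib.std(), 0.05 * lib.mean()))

    def test_null_effect_gives_zero_truth_and_centered_log2fc(self):
        m, truth, pairing = generate_paired_mirna_counts(
            n_mirnas=200, n_pairs=7, effect_log2fc=0.0, depth=5e5, seed=3
        )
        assert all(e == 0 for e in truth.de_mirnas.values())
        log2 = normalize_counts(m).values
        prim = log2[[f"{p}_primary" for p in pairing.records["patient"]]].to_numpy()
        rel = log2[[f"{p}_relapse" for p in pairing.records["patient"]]].to_numpy()
        fc = (rel - prim).mean(axis=1)
        # the shared library-size term leaves a common shift of order 0.05
        assert abs(fc.mean()) < 0.1

    def test_discovery_design_plants_13_de_mirnas(self):
        _, truth, _ = generate_paired_mirna_counts(
            n_mirnas=500, n_pairs=7, de_fraction=0.026, seed=4
        )
        assert len(truth.de_mirnas) == 13
        assert set(truth.de_mirnas) <= set(truth.mirna_universe)

    def test_planted_effect_recovered_by_mean_of_ratios(self):
        # independent oracle: per-miRNA log2 of (mean relapse CPM / mean primary CPM)
        m, truth, pairing = generate_paired_mirna_counts(
            n_mirnas=400, n_pairs=7, de_fraction=0.1, effect_log2fc=2.0,
            dispersion=0.1, depth=1e6, seed=6,
        )
        cpm = m.values / m.values.sum(axis=0) * 1e6
        prim = cpm[[f"{p}_primary" for p in pairing.records["patient"]]].mean(axis=1)
        rel = cpm[[f"{p}_relapse" for p in pairing.records["patient"]]].mean(axis=1)
        lfc = np.log2(rel / prim)
        planted = list(truth.de_mirnas)
        assert abs(np.abs(lfc[planted]).mean() - 2.0) < 0.3

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_paired_mirna_counts(n_pairs=1)
        with pytest.raises(ValueError):
            generate_paired_mirna_counts(de_fraction=1.5)
        with pytest.raises(ValueError):
            generate_paired_mirna_counts(depth=0.1)
        with pytest.raises(ValueError):
            generate_paired_mirna_counts(n_mirnas=10.5)


class TestMrnaExpression:
    def test_noiseless_unit_strength_gives_perfect_anticorrelation(self):
        m, truth, _ = generate_paired_mirna_counts(n_mirnas=60, n_pairs=7, seed=7)
        mrna = generate_mrna_expression(
            m, truth, noise_sd=0.0, n_genes=100, targets_per_mirna=5,
            strength=-1.0, seed=8,
        )
        log2 = normalize_counts(m)
        for mir, targets in truth.target_map.items():
            x = log2.values.loc[mir]
            for gene in targets:
                rho, _ = spearman(x, mrna.values.loc[gene])
                assert rho == -1.0

    def test_zero_strength_passes_filter_at_chance_level_only(self):
        m, truth, _ = generate_paired_mirna_counts(n_mirnas=40, n_pairs=7, seed=9)
        mrna = generate_mrna_expression(
            m, truth, noise_sd=0.2, n_genes=300, targets_per_mirna=10,
            strength=0.0, seed=10,
        )
        log2 = normalize_counts(m)
        n_pass = 0
        n_tested = 0
        for mir in truth.de_mirnas:
            x = log2.values.loc[mir].to_numpy()
            for gene in mrna.feature_ids:
                rho, p = spearman(x, mrna.values.loc[gene].to_numpy())
                n_tested += 1
                if rho < -0.7 and p < 0.05:
                    n_pass += 1
        # null pass probability for n=14 samples is well under 0.01
        assert n_pass <= stats.binom.ppf(0.999, n_tested, 0.01)

    def test_sample_mismatch_rejected(self):
        m, truth, _ = generate_paired_mirna_counts(n_mirnas=20, n_pairs=3, seed=11)
        sub = m.subset_samples(m.sample_ids[:-1])
        mrna = generate_mrna_expression(m, truth, n_genes=50, targets_per_mirna=2, seed=12)
        from mirelapse.integration import find_anticorrelated_pairs

        with pytest.raises(ValueError):
            find_anticorrelated_pairs(normalize_counts(sub), mrna)


class TestTargetResources:
    def _toy_truth(self, n_edges=5000, seed=0):
        from mirelapse.synthetic import SimulationTruth

        rng = np.random.default_rng(seed)
        mirnas = [f"m{i}" for i in range(50)]
        genes = [f"g{i}" for i in range(200)]
        truth = SimulationTruth(seed=seed, mirna_universe=mirnas, gene_universe=genes)
        all_edges = [(m, g) for m in mirnas for g in genes]
        idx = rng.choice(len(all_edges), size=n_edges, replace=False)
        per = {}
        for i in idx:
            m, g = all_edges[i]
            per.setdefault(m, {})[g] = -1.0
        truth.target_map = per
        return truth

    def test_perfect_resources_equal_truth(self):
        truth = self._toy_truth(200)
        res = generate_target_resources(truth, sensitivity=1.0, fp_rate=0.0, seed=1)
        assert len(res) == 5
        for r in res:
            assert r.edges == truth.true_edges()

    def test_union_coverage_matches_binomial_complement(self):
        truth = self._toy_truth(5000)
        res = generate_target_resources(truth, n_resources=5, sensitivity=0.6,
                                        fp_rate=0.0, seed=2)
        union = set().union(*(r.edges for r in res))
        coverage = len(union & truth.true_edges()) / len(truth.true_edges())
        assert abs(coverage - (1 - 0.4**5)) < 0.01

    def test_range_checks(self):
        truth = self._toy_truth(10)
        with pytest.raises(ValueError):
            generate_target_resources(truth, sensitivity=1.2)


class TestSurvivalCohort:
    def test_full_censoring_means_no_events(self):
        table, _ = generate_survival_cohort(n=50, censor_rate=1.0, seed=3)
        assert (table["event"] == 0).all()

    def test_cohort_size_and_truth_fields(self):
        table, truth = generate_survival_cohort(n=233, hazard_ratio=4.0, seed=4)
        assert len(table) == 233
        assert truth.true_hazard_ratio == 4.0

    def test_null_hazard_ratio_calibrates_logrank_type_i_error(self):
        # empirical type-I error of the log-rank test at the true cutpoint
        alpha, n_sims, n = 0.05, 500, 80
        rejections = 0
        for s in range(n_sims):
            t, _ = generate_survival_cohort(
                n=n, hazard_ratio=1.0, true_cutpoint=0.0, censor_rate=0.2, seed=s
            )
            high = t["biomarker"] > 0.0
            _, p = logrank_test(
                t.loc[~high, "time_months"], t.loc[~high, "event"],
                t.loc[high, "time_months"], t.loc[high, "event"],
            )
            rejections += p < alpha
        rate = rejections / n_sims
        ci = 2.807 * np.sqrt(alpha * (1 - alpha) / n_sims)  # 99.5% binomial band
        assert abs(rate - alpha) < ci + 1e-12

    def test_censor_rate_out_of_range(self):
        with pytest.raises(ValueError):
            generate_survival_cohort(n=10, censor_rate=1.5)


class TestCtReplicates:
    def test_noiseless_identity_rq_one(self):
        ct = generate_ct_replicates(true_rq=1.0, noise_sd=0.0, seed=5)
        rel = relative_expression_from_table(ct, calibrator="calibrator")
        assert rel[0].rq == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_quarter_gives_ddct_two(self):
        ct = generate_ct_replicates(true_rq=0.25, noise_sd=0.0, seed=6)
        rel = relative_expression_from_table(ct, calibrator="calibrator")
        assert rel[0].delta_delta_ct == pytest.approx(2.0, abs=1e-12)

    def test_noisy_mean_log2_rq_unbiased(self):
        draws = []
        for s in range(1000):
            ct = generate_ct_replicates(true_rq=0.5, noise_sd=0.2, seed=s)
            rel = relative_expression_from_table(ct, calibrator="calibrator")
            draws.append(rel[0].log2_rq)
        assert abs(np.mean(draws) - np.log2(0.5)) < 0.05


class TestReferenceAndSeeds:
    def test_reference_offsets_realized(self):
        m, _, _ = generate_paired_mirna_counts(n_mirnas=30, n_pairs=5, seed=7)
        log2 = normalize_counts(m)
        offsets = {log2.feature_ids[0]: 3.0, log2.feature_ids[1]: -2.0}
        ref = generate_reference_expression(log2, offsets, n_samples=50,
                                            noise_sd=0.1, seed=8)
        delta = log2.values.mean(axis=1) - ref.values.mean(axis=1)
        assert delta.iloc[0] == pytest.approx(3.0, abs=0.1)
        assert delta.iloc[1] == pytest.approx(-2.0, abs=0.1)
        assert abs(delta.iloc[5]) < 0.1

    def test_component_seeds_are_stable_distinct_and_in_range(self):
        a = component_seed(42, "mirna_counts")
        assert a == component_seed(42, "mirna_counts")
        assert a != component_seed(42, "mrna")
        assert 0 <= a < 2**31

    def test_truth_flat_serialization_round_trips_keys(self):
        _, truth, _ = generate_paired_mirna_counts(n_mirnas=50, n_pairs=3, seed=9)
        flat = truth.to_flat_dict()
        assert flat["seed"] == "9"
        assert sum(k.startswith("de.") for k in flat) == len(truth.de_mirnas)
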