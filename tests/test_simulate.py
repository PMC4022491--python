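"""Tests for the haplotype/cohort simulator and the scan machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pycoloc.abf import TraitSpec
from pycoloc.engine import coloc_summary_pair
from pycoloc.simulate import (
    Scenario,
    conditional_scan,
    run_power_experiment,
    scan_to_dataset,
    simulate_haplotype_panel,
    simulate_pair,
    simulate_study,
    single_snp_scan,
    standard_scenarios,
)


class TestHaplotypePanel:
    def test_deterministic_under_seed(self):
        a = simulate_haplotype_panel(20, 200, seed=5)
        b = simulate_haplotype_panel(20, 200, seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_zero_decay_gives_near_independence(self):
        panel = simulate_haplotype_panel(40, 1000, ld_decay=0.0, seed=6)
        r2 = panel.r_squared()
        off = r2[np.triu_indices(40, k=1)]
        assert off.mean() < 0.05

    def test_realised_frequencies_track_targets(self):
        panel = simulate_haplotype_panel(50, 10000, maf_range=(0.1, 0.5), seed=7)
        assert np.all(panel.frequencies > 0.08)
        assert np.all(panel.frequencies < 0.52)

    def test_ld_decays_with_distance(self, small_panel):
        r2 = small_panel.r_squared()
        q = small_panel.n_variants
        adjacent = np.diag(r2, 1).mean()
        far = np.mean([r2[i, j] for i in range(q) for j in range(i + 20, q)])
        assert adjacent > far

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_haplotype_panel(10, 200, maf_range=(0.5, 0.1))


class TestSimulateStudy:
    def test_causal_z_squared_matches_noncentral_mean(self, small_panel):
        # E[z^2] at the causal site ~ 1 + N v / (1 - v)  (noncentral chi-square)
        n, v, reps = 966, 0.10, 300
        expected = 1 + n * v / (1 - v)
        zsq = []
        for i in range(reps):
            study = simulate_study(small_panel, n, {10: v}, seed=1000 + i)
            g = study.genotypes[:, 10]
            r = np.corrcoef(g, study.phenotype)[0, 1]
            zsq.append(r**2 / (1 - r**2) * (n - 2))
        assert np.mean(zsq) == pytest.approx(expected, rel=0.15)

    def test_null_study_has_no_signal(self, small_panel):
        study = simulate_study(small_panel, 10000, {}, seed=3)
        scan = single_snp_scan(study)
        z2 = (scan["beta"] / np.sqrt(scan["varbeta"])) ** 2
        r2 = z2 / (study.n_samples - 2)
        assert np.nanmax(r2) < 0.01

    def test_realised_variance_converges_to_target(self, small_panel):
        study = simulate_study(small_panel, 50000, {5: 0.1}, seed=4)
        g = study.genotypes[:, 5]
        r2 = np.corrcoef(g, study.phenotype)[0, 1] ** 2
        assert r2 == pytest.approx(0.1, rel=0.1)

    def test_recessive_signal_detected_by_trend_test(self, small_panel):
        # even under the wrong (additive) analysis model the causal site
        # should rank far above the noise floor
        hits = 0
        reps = 40
        j = int(np.argmin(np.abs(small_panel.frequencies - 0.3)))
        for i in range(reps):
            study = simulate_study(
                small_panel, 1000, {j: 0.1}, model="recessive", seed=2000 + i
            )
            scan = single_snp_scan(study)
            p = scan["pval"].to_numpy()
            if p[j] < np.nanmedian(np.delete(p, j)):
                hits += 1
        assert hits / reps >= 0.9

    def test_excess_variance_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate_study(small_panel, 100, {0: 0.6, 1: 0.5})


class TestSingleSnpScan:
    def test_null_pvalues_uniform(self):
        panel = simulate_haplotype_panel(500, 1000, ld_decay=0.0, seed=8)
        study = simulate_study(panel, 2000, {}, seed=9)
        p = single_snp_scan(study)["pval"].dropna()
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_perfect_fit_detected(self, small_panel):
        study = simulate_study(small_panel, 500, {}, seed=10)
        g = study.genotypes[:, 3]
        study.phenotype = (g - g.mean()) / g.std()
        scan = single_snp_scan(study)
        assert scan["varbeta"].iloc[3] < 1e-12  # rounding noise only
        assert scan["pval"].iloc[3] < 1e-250 or scan["pval"].iloc[3] == 0.0

    def test_deterministic_output(self, small_panel):
        a = single_snp_scan(simulate_study(small_panel, 500, {2: 0.05}, seed=11))
        b = single_snp_scan(simulate_study(small_panel, 500, {2: 0.05}, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_monomorphic_column_flagged(self, small_panel):
        study = simulate_study(small_panel, 300, {}, seed=12)
        study.genotypes[:, 0] = 1.0
        scan = single_snp_scan(study)
        assert scan["flag"].iloc[0] == "monomorphic"
        assert np.isnan(scan["beta"].iloc[0])


class TestConditionalScan:
    def test_conditioning_on_causal_removes_signal(self):
        # after conditioning on the sole causal variant the remaining tests
        # are null; what is left of the region's signal is multiple-testing
        # noise, orders of magnitude weaker than the marginal minimum
        removed = 0
        reps = 30
        for i in range(reps):
            panel = simulate_haplotype_panel(50, 600, seed=3000 + i)
            study = simulate_study(panel, 1000, {25: 0.1}, seed=4000 + i)
            marg_min = np.nanmin(single_snp_scan(study)["pval"])
            cond_min = np.nanmin(conditional_scan(study, index_variant=25)["pval"])
            if cond_min > 1e-4 and cond_min > 1e6 * marg_min:
                removed += 1
        assert removed / reps >= 0.9

    def test_index_defaults_to_smallest_marginal_p(self, small_panel):
        study = simulate_study(small_panel, 2000, {12: 0.2}, seed=13)
        marg = single_snp_scan(study)
        expect = int(np.nanargmin(marg["pval"].to_numpy()))
        cond = conditional_scan(study)
        assert cond["flag"].iloc[expect] == "index"

    def test_uncorrelated_index_preserves_causal_z(self):
        ratios = []
        for i in range(30):
            panel = simulate_haplotype_panel(60, 600, seed=5000 + i)
            study = simulate_study(panel, 2000, {10: 0.1}, seed=6000 + i)
            marg = single_snp_scan(study)
            cond = conditional_scan(study, index_variant=55)  # far from causal
            z_m = marg["beta"][10] / np.sqrt(marg["varbeta"][10])
            z_c = cond["beta"][10] / np.sqrt(cond["varbeta"][10])
            ratios.append(abs(z_c / z_m))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.1)

    def test_stepwise_recovery_of_secondary_shared_signal(self):
        # trait 1 carries a strong private signal plus a weaker one shared
        # with trait 2; colocalisation on trait-1 statistics conditional on
        # the top SNP recovers the shared secondary association
        panel = simulate_haplotype_panel(80, 1000, seed=71)
        strong, shared = 20, 60
        study1 = simulate_study(panel, 2000, {strong: 0.2, shared: 0.1}, seed=72)
        study2 = simulate_study(panel, 5000, {shared: 0.05}, seed=73)
        marg1 = single_snp_scan(study1)
        idx = int(np.nanargmin(marg1["pval"].to_numpy()))
        assert abs(panel.positions[idx] - panel.positions[strong]) < 20 * 4000
        cond1 = conditional_scan(study1, index_variant=idx)
        assert cond1["pval"][shared] < marg1["pval"][shared] * 10  # still present
        d1 = scan_to_dataset(cond1, TraitSpec("quantitative", 2000, sdY=1.0))
        d2 = scan_to_dataset(
            single_snp_scan(study2), TraitSpec("quantitative", 5000, sdY=1.0)
        )
        res = coloc_summary_pair(d1, d2)
        assert res["PP4"] > 0.9

    def test_monomorphic_index_rejected(self, small_panel):
        study = simulate_study(small_panel, 300, {}, seed=14)
        study.genotypes[:, 4] = 0.0
        with pytest.raises(ValueError):
            conditional_scan(study, index_variant=4)


class TestScenario:
    def test_variance_budget_enforced(self):
        with pytest.raises(ValueError):
            Scenario(shared=((0.6, 0.1),), trait1_only=(0.5,))

    def test_unknown_density_mode_rejected(self):
        with pytest.raises(ValueError):
            Scenario(density="sparse")

    def test_named_scenarios_cover_all_hypotheses(self):
        sc = standard_scenarios()
        assert {"h0", "h1", "h2", "h3", "h4"} <= set(sc)


class TestPowerExperiment:
    def test_null_scenario_supports_h0(self):
        table = run_power_experiment(standard_scenarios()["h0"], n_reps=40, seed=15)
        assert table.replicates["PP0"].median() > 0.9

    def test_deterministic_under_seed(self):
        sc = standard_scenarios()["h4"]
        a = run_power_experiment(sc, n_reps=5, seed=16)
        b = run_power_experiment(sc, n_reps=5, seed=16)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_rejects_zero_replicates(self):
        with pytest.raises(ValueError):
            run_power_experiment(standard_scenarios()["h0"], n_reps=0)

    def test_summary_quantile_ordering(self):
        table = run_power_experiment(standard_scenarios()["h4"], n_reps=20, seed=17)
        q = table.quantiles()
        assert (q.loc["q10"] <= q.loc["median"]).all()
        assert (q.loc["median"] <= q.loc["q90"]).all()
        props = table.proportions_above()
        assert ((props >= 0) & (props <= 1)).all()

    def test_tag_masking_drops_causal_variant(self):
        sc = standard_scenarios()["tag-causal-absent"]
        root = np.random.SeedSequence(18)
        panel, study1, study2, mask = simulate_pair(sc, seed=root.spawn(1)[0])
        assert not mask[list(study1.causal_indices)].any()
        assert 2 <= mask.sum() < sc.n_variants
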