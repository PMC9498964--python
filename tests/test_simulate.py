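"""Parameter-recovery, null-calibration and determinism tests for the
synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitoscreen import screen, tracing
from mitoscreen.assays import bioenergetic_metrics
from mitoscreen.enrichment import preranked_enrichment, rank_genes
from mitoscreen.pca import fit_pca
from mitoscreen.simulate import (
    AssaySimConfig,
    ScreenSimConfig,
    TracingSimConfig,
    simulate_assays,
    simulate_expression,
    simulate_isotopologues,
    simulate_metastasis_counts,
    simulate_screen_counts,
    simulate_timecourse_counts,
)

NULL_EFFECTS = {"control": 1.0, "glycolytic": 1.0, "mito_respiratory": 1.0, "other": 1.0}


class TestScreenGenerator:
    def test_bit_identical_under_fixed_seed(self):
        a, _, _ = simulate_screen_counts(ScreenSimConfig(seed=11))
        b, _, _ = simulate_screen_counts(ScreenSimConfig(seed=11))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        c, _, _ = simulate_screen_counts(ScreenSimConfig(seed=12))
        assert not a.counts.equals(c.counts)

    def test_null_model_class_means_near_100(self):
        """e = 1, no bottleneck, counting noise only, high depth: ~100%.

        The class mean and its standard error are estimated empirically
        across independent simulation replicates, which accounts for the
        shared nontargeting-sum noise that a per-guide SEM misses.  High
        read depth (1e7) is used because the calibration guarantee is
        asymptotic: the ratio estimator's O(1/depth) bias must be small
        against the across-replicate SEM.
        """
        rows = []
        for seed in range(8):
            cfg = ScreenSimConfig(
                effects=NULL_EFFECTS, dispersion=0.0, read_depth=1e7, seed=seed
            )
            table, annotation, _ = simulate_screen_counts(cfg)
            rows.append(screen.quantify(table, annotation, tumor_context="flank").group_means)
        df = pd.DataFrame(rows)
        for cls in df.columns:
            assert abs(df[cls].mean() - 100.0) < 2 * df[cls].sem()

    def test_configured_depletion_effect_recovered(self):
        cfg = ScreenSimConfig(
            effects={"control": 1.0, "glycolytic": 1.0, "mito_respiratory": 0.4, "other": 1.0},
            seed=7,
        )
        table, annotation, truth = simulate_screen_counts(cfg)
        agg = screen.quantify(table, annotation, tumor_context="flank")
        assert agg.group_means["mito_respiratory"] == pytest.approx(40.0, abs=5.0)

    def test_bottleneck_inflates_between_tumor_variance(self):
        """N_b = 50 founders versus no bottleneck, across 20 seeds."""
        def tumor_variance(founders, seed):
            cfg = ScreenSimConfig(
                effects=NULL_EFFECTS, founder_population=founders, dispersion=0.0,
                n_experiments=1, tumors_per_experiment=4, seed=seed,
            )
            table, annotation, _ = simulate_screen_counts(cfg)
            freq = screen.control_normalized_frequency(table, annotation)
            rep = screen.representation_percent(
                freq[table.samples_in_context("flank")],
                freq[table.samples_in_context("in_vitro_day0")],
                annotation, table.samples,
            )
            return float(rep.representation.var(axis=1).mean())

        tight = [tumor_variance(np.inf, s) for s in range(20)]
        loose = [tumor_variance(50, s) for s in range(20)]
        assert np.mean(loose) > np.mean(tight)
        assert sum(l > t for l, t in zip(loose, tight)) >= 18

    def test_timecourse_day4_enriches_mito_respiratory(self):
        table, annotation, _ = simulate_timecourse_counts(ScreenSimConfig(seed=3))
        out = screen.timepoint_dynamics(table, annotation, days=[4, 7])
        gm4 = out[4]["representation"].group_means
        assert gm4["mito_respiratory"] > gm4["control"]
        assert gm4["mito_respiratory"] > gm4["glycolytic"]
        gm7 = out[7]["representation"].group_means
        assert gm7["mito_respiratory"] < gm4["mito_respiratory"]

    def test_metastases_not_additionally_depleted(self):
        table, annotation, pairs, _ = simulate_metastasis_counts(
            ScreenSimConfig(context="orthotopic_primary", seed=4)
        )
        freq = screen.control_normalized_frequency(
            table, annotation, screen.default_pseudocount(table)
        )
        out = screen.metastasis_analysis(freq, annotation, pairs)
        gm = out["representation"].group_means
        # classes comparable in mets (no mito-respiratory-specific depletion)
        assert gm["mito_respiratory"] / gm["control"] == pytest.approx(1.0, abs=0.25)


class TestTracingGenerator:
    def test_noise_free_zero_p13_is_exact(self):
        cfg = TracingSimConfig(p13=0.0, noise_cv=0.0, replicates=1, seed=0)
        observed, truth = simulate_isotopologues(cfg)
        for v in observed:
            key = (v.metabolite.name, v.genotype, v.condition, v.replicate)
            assert np.allclose(v.intensities, truth[key])

    def test_seed_reproducibility(self):
        a, _ = simulate_isotopologues(TracingSimConfig(seed=2))
        b, _ = simulate_isotopologues(TracingSimConfig(seed=2))
        for va, vb in zip(a, b):
            assert np.array_equal(va.intensities, vb.intensities)

    def test_correction_recovers_truth_within_l1_tolerance(self):
        """p13 = 0.0107, CV = 0.05: replicate-averaged recovered simplex is
        within L1 distance 0.02 of the configured truth on average."""
        cfg = TracingSimConfig(seed=8)
        observed, truth = simulate_isotopologues(cfg)
        recovered: dict[tuple, list] = {}
        for v in observed:
            rec = tracing.correct_natural_abundance(v, cfg.p13)
            recovered.setdefault((v.metabolite.name, v.genotype, v.condition), []).append(
                rec.intensities / rec.intensities.sum()
            )
        dists = []
        for key, fracs in recovered.items():
            t = truth[(*key, 0)]
            dists.append(np.abs(np.mean(fracs, axis=0) - t / t.sum()).sum())
        assert np.mean(dists) < 0.02

    def test_tca_metabolites_highly_glutamine_labeled_at_baseline(self):
        observed, _ = simulate_isotopologues(TracingSimConfig(seed=1))
        labeled = [
            tracing.summarize_tracing(tracing.correct_natural_abundance(v)).percent_labeled
            for v in observed
            if v.metabolite.name in ("glutamate", "succinate")
            and v.genotype == "control" and v.condition == "basal"
        ]
        assert min(labeled) > 0.8

    def test_mito_lines_have_elevated_flux_ratio(self):
        observed, _ = simulate_isotopologues(TracingSimConfig(seed=6))
        corrected = [tracing.correct_natural_abundance(v) for v in observed if v.condition == "dg2"]
        ratios = tracing.flux_ratios_by_genotype(corrected)
        ctl = np.mean([r.ratio for r in ratios["control"]])
        for g in ("c14orf2", "MALSU1", "TMEM261"):
            assert np.mean([r.ratio for r in ratios[g]]) > 2 * ctl


class TestExpressionGenerator:
    def test_null_pvalues_uniform(self):
        table, _ = simulate_expression(n_genes=2000, signal_sets={}, seed=0)
        ks = sps.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_glycolysis_signal_ranks_first(self):
        table, sets = simulate_expression(n_genes=2000, seed=1)
        ranked = rank_genes(table)
        results = preranked_enrichment(
            ranked, sets, n_perm=200, min_size=10, max_size=500, seed=1
        )
        best = max(results, key=lambda r: r.nes)
        assert best.set_id == "GLYCOLYSIS"
        assert best.es > 0
        assert best.p_value <= 0.01

    def test_seed_reproducibility(self):
        a, _ = simulate_expression(n_genes=500, seed=9)
        b, _ = simulate_expression(n_genes=500, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestAssayGenerator:
    def test_no_effects_no_noise_metrics_identical(self):
        cfg = AssaySimConfig(
            genotype_effects={"a": {"ocr": 1.0, "ecar": 1.0}, "b": {"ocr": 1.0, "ecar": 1.0}},
            seed=0,
        )
        traces, _ = simulate_assays(cfg)
        m = bioenergetic_metrics(traces)
        assert m["a"].basal_respiration == pytest.approx(m["b"].basal_respiration)
        assert m["a"].maximal_respiration == pytest.approx(m["b"].maximal_respiration)

    def test_configured_ocr_reduction_recovered(self):
        cfg = AssaySimConfig(
            genotype_effects={"control": {"ocr": 1.0, "ecar": 1.0}, "kd": {"ocr": 0.5, "ecar": 1.0}},
            noise_cv=0.05,
            seed=3,
        )
        traces, _ = simulate_assays(cfg)
        m = bioenergetic_metrics(traces)
        ratio = m["kd"].maximal_respiration / m["control"].maximal_respiration
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_radiance_ratio_exact_when_noise_free(self):
        _, triplets = simulate_assays(AssaySimConfig(seed=1))
        for t in triplets:
            assert t.central_over_left == pytest.approx(0.2)
            assert t.right_over_left == pytest.approx(0.1)

    def test_seed_reproducibility(self):
        ta, ra = simulate_assays(AssaySimConfig(noise_cv=0.1, seed=5))
        tb, rb = simulate_assays(AssaySimConfig(noise_cv=0.1, seed=5))
        assert all(x.phases == y.phases for x, y in zip(ta, tb))
        assert all(x.left_third == y.left_third for x, y in zip(ra, rb))


def test_omnibus_anova_rejects_at_nominal_rate_under_null():
    """Across simulation replicates with no effects, p < 0.05 at ~5%."""
    rejections = 0
    n_sims = 40
    for seed in range(n_sims):
        cfg = ScreenSimConfig(
            effects=NULL_EFFECTS, dispersion=0.0, n_experiments=1,
            tumors_per_experiment=3, seed=1000 + seed,
        )
        table, annotation, _ = simulate_screen_counts(cfg)
        agg = screen.quantify(table, annotation, tumor_context="flank", by="pooled")
        groups = {
            k: v
            for k, v in screen.macro_class_values(agg).items()
            if k in ("control", "glycolytic", "mito_respiratory")
        }
        from mitoscreen.stats import group_compare

        if group_compare(groups).p_value < 0.05:
            rejections += 1
    # binomial(40, 0.05): central 99% mass is 0..7
    assert rejections <= 7
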