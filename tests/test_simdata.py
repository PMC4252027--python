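"""Two-pool ribosome-loading model and synthetic experiment generator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyoccu.fracdist import np_pl_split
from polyoccu.gradient import FractionScheme, UndefinedMetricError, area, polysomal_area_pct
from polyoccu.simdata import (
    SCENARIOS,
    ExperimentDesign,
    ScenarioSpec,
    TranscriptModel,
    counts_to_profile,
    simulate_experiment,
    simulate_loading,
    simulate_transcripts,
    synthesize_trace,
)


def model(lam=2.0, s=0.0, cds=400, **kw):
    return TranscriptModel("g", cds, lam, s, 100.0, **kw)


class TestTranscriptModel:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            model(s=1.2)
        with pytest.raises(ValueError):
            model(lam=-0.1)
        with pytest.raises(ValueError):
            model(cds=5)  # capacity floor(5/10) = 0

    def test_capacity(self):
        assert model(cds=105).capacity == 10

    def test_expected_loading_monotone_in_lambda_and_s(self):
        lams = [0.5, 1.0, 2.0, 4.0]
        means = [model(lam=l, s=0.3).mean_ribosomes() for l in lams]
        assert all(a <= b for a, b in zip(means, means[1:]))
        occs = [model(lam=2.0, s=s).p_engaged() for s in (0.0, 0.3, 0.8)]
        assert occs[0] > occs[1] > occs[2]

    def test_density_on_engaged_copies_independent_of_s(self):
        # (1-s) cancels between mean loading and engaged fraction
        a, b = model(lam=2.5, s=0.1), model(lam=2.5, s=0.7)
        da = a.mean_ribosomes() / a.p_engaged()
        db = b.mean_ribosomes() / b.p_engaged()
        assert da == pytest.approx(db, rel=1e-12)


class TestSimulateLoading:
    def test_fully_sequestered_all_zero(self):
        assert np.all(simulate_loading(model(lam=2.0, s=1.0), 100, 0) == 0)

    def test_no_initiation_all_zero(self):
        assert np.all(simulate_loading(model(lam=0.0, s=0.0), 100, 0) == 0)

    def test_counts_within_capacity(self):
        m = model(lam=8.0, cds=30)  # capacity 3
        counts = simulate_loading(m, 5000, 1)
        assert counts.max() <= 3 and counts.min() >= 0

    def test_two_pool_analytic_mean(self):
        # E = (1-s)·lambda when capacity truncation is negligible
        lam, s, n = 1.2, 0.3, 100_000
        m = model(lam=lam, s=s, cds=100)  # capacity 10
        # truncation term by direct summation (independent arithmetic)
        trunc = sum(
            (k - 10) * math.exp(-lam) * lam**k / math.factorial(k) for k in range(11, 80)
        )
        assert trunc < 1e-6
        counts = simulate_loading(m, n, 7)
        mean_expected = (1 - s) * lam
        var = (1 - s) * (lam + lam**2) - mean_expected**2
        se = math.sqrt(var / n)
        assert abs(counts.mean() - mean_expected) < 3 * se

    def test_monte_carlo_matches_analytic_occupancy(self):
        m = model(lam=2.2, s=0.4)
        counts = simulate_loading(m, 100_000, 3)
        p = m.p_engaged()
        se = math.sqrt(p * (1 - p) / counts.size)
        assert abs((counts >= 1).mean() - p) < 3 * se

    def test_deterministic_given_seed(self):
        a = simulate_loading(model(), 1000, 42)
        b = simulate_loading(model(), 1000, 42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_loading(model(), 2.5, 0)
        with pytest.raises(ValueError):
            simulate_loading(model(), 0, 0)


class TestCountsToProfile:
    def test_all_zero_counts_in_fraction_one(self, scheme):
        p = counts_to_profile(np.zeros(50, dtype=int), scheme)
        assert p.abundances[0] == 50 and p.abundances[1:].sum() == 0

    def test_explicit_mapping(self):
        scheme = FractionScheme(
            boundaries=np.linspace(0, 12, 13),
            count_map={0: 1, 1: 3, 2: 6, 3: 7, 4: 8, 5: 9, 6: 10, 7: 11, 8: 11},
            count_cap=9,
        )
        p = counts_to_profile(np.array([2, 2, 2]), scheme)
        assert p.abundances[5] == 3 and p.abundances.sum() == 3

    @given(st.integers(0, 2**31 - 1))
    def test_conservation(self, seed):
        scheme = FractionScheme.default()
        counts = simulate_loading(model(lam=3.0, s=0.2), 10_000, seed % 1000)
        p = counts_to_profile(counts, scheme)
        assert p.abundances.sum() == 10_000

    def test_uncovered_count_rejected(self):
        scheme = FractionScheme(
            boundaries=np.linspace(0, 12, 13), count_map={0: 1}, count_cap=5
        )
        with pytest.raises(ValueError):
            counts_to_profile(np.array([0, 3]), scheme)


class TestSynthesizeTrace:
    def test_empty_population_is_flat_baseline(self, scheme):
        tr = synthesize_trace([], baseline=0.3, scheme=scheme)
        np.testing.assert_allclose(tr.absorbance, 0.3)
        with pytest.raises(UndefinedMetricError):
            polysomal_area_pct(
                synthesize_trace([], baseline=0.0, scheme=scheme), scheme
            )

    def test_area_proportional_to_ribosome_content(self, scheme):
        # n=3 with m copies carries the same A254 mass as n=1 with 3m copies
        m = model()
        a = synthesize_trace(
            [(m, np.full(40, 3))], baseline=0.0, scheme=scheme, subunit_area_frac=0.0
        )
        b = synthesize_trace(
            [(m, np.full(120, 1))], baseline=0.0, scheme=scheme, subunit_area_frac=0.0
        )
        assert area(a, 0, 12) == pytest.approx(area(b, 0, 12), abs=1e-9)

    def test_linearity_in_counts(self, scheme):
        hist = np.array([5.0, 3.0, 2.0, 1.0])
        t1 = synthesize_trace(hist, baseline=0.1, scheme=scheme)
        t2 = synthesize_trace(2 * hist, baseline=0.1, scheme=scheme)
        np.testing.assert_allclose(
            2 * (t1.absorbance - 0.1), t2.absorbance - 0.1, atol=1e-9
        )

    def test_invalid_parameters(self, scheme):
        with pytest.raises(ValueError):
            synthesize_trace([], peak_width=0.0, scheme=scheme)
        with pytest.raises(ValueError):
            synthesize_trace([], n_points=10, scheme=scheme)


class TestScenarioSpec:
    def test_null_requires_zero_deltas(self):
        with pytest.raises(ValueError):
            ScenarioSpec("null", delta_lambda=1.0)

    def test_release_requires_negative_delta_s(self):
        with pytest.raises(ValueError):
            ScenarioSpec("sequestration_release", delta_s=0.1, delta_lambda=-1.0)

    def test_default_release_regime_decouples_occupancy_and_density(self):
        # engaged fraction rises while per-engaged-copy loading falls
        spec = SCENARIOS["sequestration_release"]
        lam_c, s_c = spec.lambda_control, spec.s_control
        lam_t, s_t = lam_c + spec.delta_lambda, s_c + spec.delta_s
        occ = lambda lam, s: (1 - s) * (1 - math.exp(-lam))
        dens = lambda lam: lam / (1 - math.exp(-lam))
        assert occ(lam_c, s_c) == pytest.approx(0.380, abs=5e-4)
        assert occ(lam_t, s_t) == pytest.approx(0.692, abs=5e-4)
        assert dens(lam_c) == pytest.approx(3.157, abs=5e-4)
        assert dens(lam_t) == pytest.approx(2.313, abs=5e-4)


class TestSimulateExperiment:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ExperimentDesign(n_genes=10, class_mixture={"null": 0.6})

    def test_null_noiseless_ratios_are_zero(self):
        d = ExperimentDesign(
            n_genes=20, class_mixture={"null": 1.0}, noise_sd_log2=0.0, seed=3
        )
        sim = simulate_experiment(d, profiles=False, traces=False)
        m = sim.matrix.to_log2()
        for level in ("steady_state", "polysomal"):
            t = m.values[m.select(condition="sucrose", level=level)].to_numpy()
            c = m.values[m.select(condition="control", level=level)].to_numpy()
            np.testing.assert_allclose(t.mean(axis=1) - c.mean(axis=1), 0.0, atol=1e-12)

    def test_transcriptional_truth_by_construction(self):
        d = ExperimentDesign(
            n_genes=10,
            class_mixture={"transcriptional": 1.0},
            scenarios={
                "transcriptional": ScenarioSpec("transcriptional", delta_log2_abundance=2.0)
            },
            seed=4,
        )
        sim = simulate_experiment(d, profiles=False, traces=False)
        assert np.all(sim.truth["true_dlog2_sl"] == 2.0)
        np.testing.assert_allclose(sim.truth["true_dlog2_ro"], 0.0, atol=1e-12)

    def test_truth_occupancy_identity(self):
        d = ExperimentDesign(
            n_genes=30,
            class_mixture={"null": 0.5, "sequestration_release": 0.3, "initiation_up": 0.2},
            seed=5,
        )
        truth = simulate_experiment(d, profiles=False, traces=False).truth
        np.testing.assert_allclose(
            truth["true_dlog2_ro"],
            truth["true_dlog2_pl"] - truth["true_dlog2_sl"],
            atol=1e-12,
        )

    def test_release_scenario_truth_signs(self):
        d = ExperimentDesign(
            n_genes=200, class_mixture={"sequestration_release": 1.0}, seed=6
        )
        sim = simulate_experiment(d, profiles=True, traces=False)
        assert sim.truth["true_dlog2_ro"].mean() > 0
        # engaged-copy density falls: lambda drops 3 -> 2 for every gene
        assert np.all(sim.truth["lambda_treated"] < sim.truth["lambda_control"])

    def test_fully_sequestered_gene_has_all_np_signal(self, scheme):
        d = ExperimentDesign(
            n_genes=5,
            class_mixture={"null": 1.0},
            scenarios={"null": ScenarioSpec("null", s_control=1.0, lambda_control=2.0)},
            seed=7,
        )
        sim = simulate_experiment(d, traces=False)
        prof = sim.profile("control.light.1", sim.truth.index[0])
        np_pct, pl_pct = np_pl_split(prof, scheme)
        assert np_pct == 100.0 and pl_pct == 0.0

    def test_bit_identical_given_seed(self):
        d = ExperimentDesign(n_genes=15, class_mixture={"null": 1.0}, seed=11)
        a = simulate_experiment(d)
        b = simulate_experiment(d)
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for s in a.profiles:
            pd.testing.assert_frame_equal(a.profiles[s], b.profiles[s])
        for s in a.traces:
            np.testing.assert_array_equal(a.traces[s].absorbance, b.traces[s].absorbance)

    def test_gene_substreams_independent_of_population_size(self):
        small = simulate_experiment(
            ExperimentDesign(n_genes=3, class_mixture={"null": 1.0}, seed=9),
            profiles=False,
            traces=False,
        )
        large = simulate_experiment(
            ExperimentDesign(n_genes=8, class_mixture={"null": 1.0}, seed=9),
            profiles=False,
            traces=False,
        )
        np.testing.assert_allclose(
            small.matrix.values.to_numpy(), large.matrix.values.to_numpy()[:3]
        )


class TestSimulateTranscripts:
    def test_sequences_match_truth_lengths(self):
        d = ExperimentDesign(
            n_genes=10, class_mixture={"null": 0.5, "sequestration_release": 0.5}, seed=13
        )
        sim = simulate_experiment(d, profiles=False, traces=False)
        anns, planted = simulate_transcripts(sim.truth, seed=13)
        for gene, row in sim.truth.iterrows():
            assert len(anns[gene].cds) == 3 * row["cds_len_codons"]
            assert anns[gene].cds.startswith("ATG")
        # planted motif instances appear only in target-class genes
        targets = sim.truth.index[sim.truth["scenario"] == "sequestration_release"]
        assert not planted.drop(targets).any()
        for gene in planted.index[planted]:
            assert "GGAGAG" in anns[gene].utr5
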