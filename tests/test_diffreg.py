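"""Normalization and three-contrast differential statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyoccu.diffreg import (
    ExpressionMatrix,
    benjamini_hochberg,
    classify,
    differential,
    internal_standard_normalize,
    occupancy_contrast,
    spike_normalize,
    three_contrast_analysis,
)


def bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{k>=i} p_(k)·m/k, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        i = rank_pos + 1
        q[idx] = min(
            min(p[order[k - 1]] * m / k for k in range(i, m + 1)),
            1.0,
        )
    return q


def make_matrix(values, reps=3, log2=True):
    """Genes × (2 conditions × 2 levels × reps) matrix from an array."""
    cols = [
        f"{cond}.light.{level}.{r}"
        for cond in ("control", "sucrose")
        for level in ("steady_state", "polysomal")
        for r in range(1, reps + 1)
    ]
    return ExpressionMatrix.from_columns(
        pd.DataFrame(values, columns=cols, index=[f"g{i}" for i in range(len(values))]),
        log2=log2,
    )


class TestSpikeNormalize:
    def make(self, data, spikes):
        cols = [f"control.light.steady_state.{r}" for r in (1, 2, 3)]
        m = ExpressionMatrix.from_columns(
            pd.DataFrame(data, columns=cols, index=["g1", "g2"]), log2=False
        )
        return m, pd.Series(spikes, index=cols)

    def test_equal_spikes_identity(self):
        m, s = self.make([[4.0, 4.0, 4.0], [2.0, 2.0, 2.0]], [5.0, 5.0, 5.0])
        out = spike_normalize(m, s)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy(), atol=1e-12)

    def test_doubled_spike_halves_sample(self):
        m, s = self.make([[4.0, 4.0, 4.0], [2.0, 2.0, 2.0]], [5.0, 10.0, 5.0])
        out = spike_normalize(m, s).values.to_numpy()
        gm = (5.0 * 10.0 * 5.0) ** (1 / 3)
        np.testing.assert_allclose(out[0], [4 / 5 * gm, 4 / 10 * gm, 4 / 5 * gm])

    def test_spike_column_becomes_constant(self, rng):
        spikes = pd.Series(
            rng.uniform(1, 10, 3),
            index=[f"control.light.steady_state.{r}" for r in (1, 2, 3)],
        )
        m = ExpressionMatrix.from_columns(
            pd.DataFrame(
                np.vstack([rng.uniform(1, 100, 3), spikes.to_numpy()]),
                columns=spikes.index,
                index=["g1", "spikegene"],
            ),
            log2=False,
        )
        out = spike_normalize(m, spikes).values
        assert out.loc["spikegene"].std() == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_spike_rejected(self):
        m, s = self.make([[4.0, 4.0, 4.0], [2.0, 2.0, 2.0]], [5.0, 0.0, 5.0])
        with pytest.raises(ValueError):
            spike_normalize(m, s)


class TestInternalStandardNormalize:
    def test_identical_standard_profiles_reduce_to_weight_division(self):
        areas = pd.DataFrame(
            {"is1": [3.0, 3.0, 3.0], "is2": [5.0, 5.0, 5.0], "met": [10.0, 20.0, 30.0]},
            index=["s1", "s2", "s3"],
        )
        weights = pd.Series([1.0, 2.0, 4.0], index=areas.index)
        with pytest.warns(UserWarning):
            out = internal_standard_normalize(areas, ["is1", "is2"], weights)
        np.testing.assert_allclose(out["met"], [10.0, 10.0, 7.5])

    def test_pure_size_effect_equalized(self, rng):
        # standards submatrix = c_i · v: rank-1, PCA t1 recovers c_i exactly
        v = np.array([2.0, 1.0, 4.0])
        c = np.array([1.0, 3.0, 0.5, 2.0])
        areas = pd.DataFrame(
            np.column_stack([np.outer(c, v), c * 7.0]),
            index=[f"s{i}" for i in range(4)],
            columns=["is1", "is2", "is3", "met"],
        )
        out = internal_standard_normalize(areas, ["is1", "is2", "is3"])
        for col in out.columns:
            assert out[col].std() == pytest.approx(0.0, abs=1e-9)
        # eigen-decomposition oracle: scores along the dominant eigenvector
        x = areas[["is1", "is2", "is3"]].to_numpy()
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc)
        w = evecs[:, -1]
        scores = x @ w * np.sign((x @ w).mean())
        np.testing.assert_allclose(scores / scores.mean(), c / c.mean(), atol=1e-9)

    def test_unit_weights_and_identical_standards_identity(self):
        areas = pd.DataFrame(
            {"is1": [2.0, 2.0], "is2": [3.0, 3.0], "met": [5.0, 9.0]}, index=["a", "b"]
        )
        with pytest.warns(UserWarning):
            out = internal_standard_normalize(areas, ["is1", "is2"], pd.Series([1.0, 1.0], index=["a", "b"]))
        # constant standards are rescaled to geometric mean 1 -> identity
        np.testing.assert_allclose(out.to_numpy(), areas.to_numpy(), atol=1e-9)

    def test_too_few_standards_rejected(self):
        areas = pd.DataFrame({"is1": [1.0, 2.0], "met": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            internal_standard_normalize(areas, ["is1"])


class TestDifferential:
    def test_identical_groups(self):
        vals = np.tile([[5.0] * 12], (3, 1))
        res = differential(make_matrix(vals), "steady_state")
        assert np.all(res["log2fc"] == 0.0)
        assert np.all(res["pvalue"] == 1.0)

    def test_exact_fourfold(self):
        m = make_matrix(
            np.tile([2.0, 2.1, 1.9, 3.0, 3.0, 3.0, 8.0, 8.4, 7.6, 5.0, 5.0, 5.0], (2, 1)),
            log2=False,
        )
        res = differential(m, "steady_state")
        np.testing.assert_allclose(res["log2fc"], 2.0, atol=1e-12)

    def test_welch_hand_oracle(self):
        vals = np.array([[4.0, 4.1, 3.9, 0, 0, 0, 5.1, 5.3, 5.2, 0, 0, 0]]) + 1.0
        vals[:, 3:6] = 1.0
        vals[:, 9:] = 1.0
        m = make_matrix(vals)
        res = differential(m, "steady_state", var_mode="welch")
        # textbook Welch formula, evaluated independently
        t_mean, c_mean = np.mean([6.1, 6.3, 6.2]), np.mean([5.0, 5.1, 4.9])
        v_t, v_c = np.var([6.1, 6.3, 6.2], ddof=1), np.var([5.0, 5.1, 4.9], ddof=1)
        se = math.sqrt(v_t / 3 + v_c / 3)
        t = (t_mean - c_mean) / se
        df = (v_t / 3 + v_c / 3) ** 2 / ((v_t / 3) ** 2 / 2 + (v_c / 3) ** 2 / 2)
        from scipy import stats as ss

        p = 2 * ss.t.sf(abs(t), df)
        assert res["log2fc"].iloc[0] == pytest.approx(1.2, abs=1e-9)
        assert res["pvalue"].iloc[0] == pytest.approx(p, rel=1e-9)

    def test_exact_separation_flagged_as_zero_p(self):
        vals = np.tile([[1.0] * 6 + [2.0] * 6], (2, 1))
        res = differential(make_matrix(vals), "steady_state")
        assert np.all(res["pvalue"] == 0.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            differential(make_matrix(np.ones((2, 4)), reps=1), "steady_state")


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.04]), [0.04])

    def test_stepup_direct_evaluation(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_equal_collapse(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=80))
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(benjamini_hochberg(pvals), bh_oracle(pvals), atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 500)
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0, 1, 200)
        perm = rng.permutation(200)
        np.testing.assert_allclose(
            benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]), atol=1e-15
        )


class TestOccupancyContrast:
    def test_pl_tracks_sl_gives_zero(self, rng):
        sl = rng.normal(8, 1, (5, 3))
        vals = np.hstack([sl, sl + 1.0, sl + 2.0, sl + 3.0])
        res = occupancy_contrast(make_matrix(vals))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_identity_with_level_contrasts(self, rng):
        vals = rng.normal(8, 1, (20, 12))
        m = make_matrix(vals)
        ro = occupancy_contrast(m)
        sl = differential(m, "steady_state")
        pl = differential(m, "polysomal")
        np.testing.assert_allclose(
            ro["log2fc"], pl["log2fc"] - sl["log2fc"], atol=1e-12
        )

    def test_interaction_mode_same_estimate(self, rng):
        vals = rng.normal(8, 1, (10, 12))
        m = make_matrix(vals)
        a = occupancy_contrast(m, mode="ratio")
        b = occupancy_contrast(m, mode="interaction")
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-12)

    def test_unmatched_replicates_rejected(self, rng):
        cols = (
            [f"control.light.steady_state.{r}" for r in (1, 2, 3)]
            + [f"control.light.polysomal.{r}" for r in (1, 2)]
            + [f"sucrose.light.steady_state.{r}" for r in (1, 2, 3)]
            + [f"sucrose.light.polysomal.{r}" for r in (1, 2, 3)]
        )
        m = ExpressionMatrix.from_columns(
            pd.DataFrame(rng.normal(8, 1, (4, len(cols))), columns=cols), log2=True
        )
        with pytest.raises(ValueError, match="unmatched replicate"):
            occupancy_contrast(m)

    def test_release_simulation_recovers_positive_ro(self):
        from polyoccu.simdata import ExperimentDesign, simulate_experiment

        d = ExperimentDesign(
            n_genes=100, class_mixture={"sequestration_release": 1.0}, seed=21
        )
        sim = simulate_experiment(d, profiles=False, traces=False)
        res = occupancy_contrast(sim.matrix)
        assert (res["log2fc"] > 0).sum() >= 95


class TestClassify:
    def base(self, **over):
        d = {
            "log2fc_SL": [0.0],
            "padj_SL": [1.0],
            "log2fc_PL": [0.0],
            "padj_PL": [1.0],
            "log2fc_RO": [0.0],
            "padj_RO": [1.0],
        }
        d.update(over)
        return pd.DataFrame(d, index=["g1"])

    def test_all_nonsignificant_unchanged(self):
        assert classify(self.base())["class"].iloc[0] == "unchanged"

    def test_concordant_rule(self):
        diff = self.base(
            log2fc_SL=[2.0], padj_SL=[0.01], log2fc_PL=[2.0], padj_PL=[0.01], padj_RO=[0.9]
        )
        out = classify(diff)
        assert out["class"].iloc[0] == "concordant"
        assert out["dir_SL"].iloc[0] == 1

    def test_ro_changed_takes_precedence(self):
        diff = self.base(
            log2fc_SL=[2.0],
            padj_SL=[0.01],
            log2fc_PL=[-2.0],
            padj_PL=[0.01],
            log2fc_RO=[-4.0],
            padj_RO=[0.001],
        )
        assert classify(diff)["class"].iloc[0] == "RO_changed"

    def test_fold_gate_applies(self):
        diff = self.base(log2fc_RO=[0.5], padj_RO=[0.001])
        assert classify(diff)["class"].iloc[0] == "unchanged"
        assert classify(diff, ro_lfc_min=0.3)["class"].iloc[0] == "RO_changed"

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError):
            classify(self.base().drop(columns=["padj_RO"]))


class TestThreeContrastAnalysis:
    def test_gene_order_equivariance(self, rng):
        vals = rng.normal(8, 1, (30, 12))
        m = make_matrix(vals)
        res = three_contrast_analysis(m)
        perm = rng.permutation(30)
        m2 = ExpressionMatrix.from_columns(m.values.iloc[perm], log2=True)
        res2 = three_contrast_analysis(m2)
        pd.testing.assert_frame_equal(res.iloc[perm], res2)
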