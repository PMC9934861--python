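"""Selection-model fitting, evaluation, sampling, entropy and JSD.

Exhaustive oracles on fully enumerable toy backgrounds (2-letter
alphabet) pin down the Monte-Carlo estimators; parameter recovery on
energy-thinned synthetic data pins down the fit.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrselect.feature_encoding import FeatureScheme, data_marginals, \
    encode_matrix
from tcrselect.hydrophobicity import hydrophobicity_index_u
from tcrselect.repertoire_io import Clonotype, Repertoire
from tcrselect.selection_model import (BackgroundSample, SelectionModel,
                                       compare_stage_energies, evaluate,
                                       feature_enrichment_difference,
                                       fit_selection_model,
                                       hydrophobicity_score_U, load_model,
                                       model_entropy, model_jsd, sample,
                                       save_model, zero_selection_model)
from tcrselect.synthetic_data import (ToySelectionConfig,
                                      apply_soft_selection,
                                      generate_repertoire, select_by_energy)

from conftest import toy_generation_model

LN2 = math.log(2.0)


def toy_scheme():
    return FeatureScheme(["TRAV1", "TRAV2"], ["TRAJ1"],
                         include_joint_vj=False, alphabet="AC")


def handmade_model(toy_model, scheme, eps_by_name, bg_n=20_000, seed=0):
    """A toy SelectionModel with exact (enumerated) normalization Z."""
    eps = np.zeros(scheme.dimension)
    for f, e in eps_by_name.items():
        eps[scheme.index[f]] = e
    z = 0.0
    for v, j, aa, p in toy_model.enumerate_support():
        c = Clonotype(v, j, "", aa, productive=False)
        z += p * math.exp(-float(eps[scheme.encode(c)].sum()))
    bg = BackgroundSample.from_model(toy_model, bg_n, seed, scheme)
    return SelectionModel(scheme, eps, math.log(z), bg,
                          np.zeros(scheme.dimension))


def exhaustive_distribution(model, toy_model, scheme):
    """Exact P_stage over the enumerated support."""
    states, probs = [], []
    for v, j, aa, p in toy_model.enumerate_support():
        c = Clonotype(v, j, "", aa, productive=False)
        e = float(model.epsilons[scheme.encode(c)].sum())
        states.append((v, j, aa))
        probs.append(p * math.exp(-e))
    probs = np.array(probs)
    return states, probs / probs.sum()


class TestEvaluate:
    def test_zero_model_reduces_to_pgen(self, toy_model):
        scheme = toy_scheme()
        bg = BackgroundSample.from_model(toy_model, 2000, 1, scheme)
        model = zero_selection_model(bg, scheme)
        c = bg.repertoire[0]
        e, log2p = evaluate(model, c)
        assert e == 0.0
        assert log2p == pytest.approx(
            toy_model.log2_pgen(c.v_gene, c.j_gene, c.cdr3_aa))

    def test_energy_is_linear_in_active_weights(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme, {"length_4": 0.3}, bg_n=500)
        c = Clonotype("TRAV1", "TRAJ1", "", "ACCA", productive=False)
        e0, _ = evaluate(model, c)
        delta = 0.7
        model.epsilons[scheme.index["length_4"]] += delta
        e1, _ = evaluate(model, c)
        assert e1 - e0 == pytest.approx(delta)

    def test_monte_carlo_z_matches_stored_normalization(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme,
                               {"length_5": 0.8, "v_TRAV1": -0.4})
        rep = generate_repertoire(toy_model, 50_000, seed=2)
        w = np.exp(-model.energies(encode_matrix(rep, scheme)))
        se = w.std(ddof=1) / math.sqrt(len(w))
        assert abs(w.mean() - model.z) < 3 * se


class TestFit:
    def test_null_data_gives_functionally_null_model(self, default_model,
                                                     alpha_selection_scheme):
        # data drawn from the background itself: rare features pick up
        # O(1/sqrt(count)) noise energies, but the model must be null in
        # every marginal-weighted sense
        data = generate_repertoire(default_model, 50_000, seed=81)
        model = fit_selection_model(data, default_model,
                                    alpha_selection_scheme, seed=82)
        p_bg = data_marginals(model.background.X)
        weighted_rms = np.sqrt((p_bg * model.epsilons ** 2).sum() / p_bg.sum())
        assert weighted_rms < 0.1
        held_out = generate_repertoire(default_model, 20_000, seed=83)
        e = model.energies(encode_matrix(held_out, alpha_selection_scheme))
        assert e.std() < 0.2

    def test_recovers_single_planted_energy(self, default_model,
                                            alpha_selection_scheme):
        truth = {"length_12": 0.8}
        base = generate_repertoire(default_model, 60_000, seed=83)
        data = select_by_energy(base, truth, alpha_selection_scheme, seed=84)
        model = fit_selection_model(data, default_model,
                                    alpha_selection_scheme, seed=85,
                                    background_size=120_000)
        i = alpha_selection_scheme.index["length_12"]
        # gauge freedom across length features: compare eps relative to the
        # mean over well-sampled length features
        lengths = [alpha_selection_scheme.index[f"length_{L}"]
                   for L in range(10, 19) if L != 12]
        rel = model.epsilons[i] - model.epsilons[lengths].mean()
        assert rel == pytest.approx(0.8, abs=0.15)

    def test_normalization_identity_on_held_out_background(
            self, default_model, alpha_selection_scheme):
        data = generate_repertoire(default_model, 20_000, seed=86)
        cfg = ToySelectionConfig(mode="length", L0=13, h=2, seed=87)
        acc, _ = apply_soft_selection(data, cfg)
        model = fit_selection_model(acc, default_model,
                                    alpha_selection_scheme, seed=88,
                                    background_size=60_000)
        # exact on the fitting background (Z is its importance average) ...
        w_fit = np.exp(-model.energies(model.background.X))
        assert w_fit.mean() / model.z == pytest.approx(1.0, abs=1e-10)
        # ... and within Monte-Carlo error plus a small finite-background
        # bias allowance on held-out background draws
        held_out = generate_repertoire(default_model, 40_000, seed=89)
        w = np.exp(-model.energies(encode_matrix(held_out,
                                                 alpha_selection_scheme)))
        ratio = w / model.z
        se = ratio.std(ddof=1) / math.sqrt(len(ratio))
        assert abs(ratio.mean() - 1.0) < max(4 * se, 0.03)

    def test_model_marginals_match_data_at_convergence(
            self, default_model, alpha_selection_scheme):
        data = generate_repertoire(default_model, 20_000, seed=90)
        cfg = ToySelectionConfig(mode="length", L0=13, h=2, seed=91)
        acc, _ = apply_soft_selection(data, cfg)
        model = fit_selection_model(acc, default_model,
                                    alpha_selection_scheme, seed=92,
                                    background_size=60_000, l2=1e-4, tol=1e-4)
        p_data = data_marginals(acc, alpha_selection_scheme)
        resid = np.abs(model.marginals - p_data)
        # at the optimum the residual equals l2 * |eps|
        assert resid.max() < 1e-4 + 1e-4 * np.abs(model.epsilons).max()


class TestSample:
    def test_zero_model_sample_matches_background_lengths(self, toy_model):
        scheme = toy_scheme()
        bg = BackgroundSample.from_model(toy_model, 20_000, 3, scheme)
        model = zero_selection_model(bg, scheme)
        drawn = sample(model, 20_000, seed=4)
        ks = stats.ks_2samp(drawn.lengths(), bg.repertoire.lengths())
        assert ks.pvalue > 0.01

    def test_planted_length_energy_reweights_lengths(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme, {"length_5": 1.0})
        drawn = sample(model, 30_000, seed=5)
        p4, p5 = toy_model.length_probs[4], toy_model.length_probs[5]
        expected = p5 * math.exp(-1.0) / (p4 + p5 * math.exp(-1.0))
        got = (drawn.lengths() == 5).mean()
        se = math.sqrt(expected * (1 - expected) / len(drawn))
        assert abs(got - expected) < 4 * se

    def test_empty_sample(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme, {}, bg_n=500)
        assert len(sample(model, 0, seed=6)) == 0


class TestEntropyAndJSD:
    def test_uniform_toy_model_entropy_is_log2_of_support(self):
        model_gen = toy_generation_model(length_probs=pd.Series({4: 1.0}),
                                         p_a=0.5)
        model_gen.v_probs = pd.Series({"TRAV1": 0.5, "TRAV2": 0.5})
        model_gen.aa_left = {1: np.array([0.5, 0.5])}
        model_gen.aa_right = {-1: np.array([0.5, 0.5])}
        scheme = toy_scheme()
        model = handmade_model(model_gen, scheme, {})
        est = model_entropy(model, 20_000, seed=7)
        assert est.value == pytest.approx(math.log2(2 * 16), abs=3 * max(est.std, 1e-6))

    def test_entropy_matches_exhaustive_oracle(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme,
                               {"length_4": -0.5, "right_1_A": 1.2})
        _, probs = exhaustive_distribution(model, toy_model, scheme)
        exact = float(-(probs * np.log2(probs)).sum())
        est = model_entropy(model, 40_000, seed=8)
        assert abs(est.value - exact) < 3 * est.std

    def test_strong_selection_reduces_exhaustive_entropy(self, toy_model):
        scheme = toy_scheme()
        base = handmade_model(toy_model, scheme, {})
        pushed = handmade_model(toy_model, scheme, {"length_5": 4.0,
                                                    "v_TRAV1": 4.0})
        _, p0 = exhaustive_distribution(base, toy_model, scheme)
        _, p1 = exhaustive_distribution(pushed, toy_model, scheme)
        s0 = -(p0 * np.log2(p0)).sum()
        s1 = -(p1 * np.log2(p1)).sum()
        assert s1 < s0

    def test_jsd_of_identical_models_is_zero(self, toy_model):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme, {"length_4": 0.3})
        est = model_jsd(model, model, 5_000, seed=9)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_jsd_of_disjoint_models_approaches_one_bit(self, toy_model):
        scheme = toy_scheme()
        only4 = handmade_model(toy_model, scheme, {"length_5": 60.0})
        only5 = handmade_model(toy_model, scheme, {"length_4": 60.0})
        est = model_jsd(only4, only5, 5_000, seed=10)
        assert est.value == pytest.approx(1.0, abs=1e-6)

    def test_jsd_matches_exhaustive_oracle_and_is_symmetric(self, toy_model):
        scheme = toy_scheme()
        a = handmade_model(toy_model, scheme, {"length_4": 0.8})
        b = handmade_model(toy_model, scheme, {"v_TRAV1": -0.6,
                                               "right_1_C": 0.4})
        _, pa = exhaustive_distribution(a, toy_model, scheme)
        _, pb = exhaustive_distribution(b, toy_model, scheme)
        m = (pa + pb) / 2
        exact = 0.5 * float((pa * np.log2(pa / m)).sum()
                            + (pb * np.log2(pb / m)).sum())
        ab = model_jsd(a, b, 30_000, seed=11)
        ba = model_jsd(b, a, 30_000, seed=12)
        assert abs(ab.value - exact) < 3 * ab.std
        assert abs(ab.value - ba.value) < 3 * math.hypot(ab.std, ba.std)

    def test_different_backgrounds_rejected(self, toy_model):
        scheme = toy_scheme()
        a = handmade_model(toy_model, scheme, {}, seed=1)
        b = handmade_model(toy_generation_model(), scheme, {}, seed=2)
        with pytest.raises(ValueError, match="background"):
            model_jsd(a, b, 100, seed=13)


class TestStageComparison:
    def test_identical_models_fully_correlated(self, default_model,
                                               alpha_selection_scheme):
        bg = BackgroundSample.from_model(default_model, 2000, 14,
                                         alpha_selection_scheme)
        eps = {"length_12": 0.5, "v_TRAV3": -0.3}
        vec = np.zeros(alpha_selection_scheme.dimension)
        for f, e in eps.items():
            vec[alpha_selection_scheme.index[f]] = e
        model = SelectionModel(alpha_selection_scheme, vec, 0.0, bg,
                               np.zeros(alpha_selection_scheme.dimension))
        common = zero_selection_model(bg, alpha_selection_scheme)
        cmp = compare_stage_energies(model, model, common, bg.repertoire)
        assert cmp.pearson_r == pytest.approx(1.0)
        assert np.linalg.norm(cmp.principal_axis) == pytest.approx(1.0)

    def test_disjoint_planted_selections_uncorrelated(self, default_model,
                                                      alpha_selection_scheme):
        probe = generate_repertoire(default_model, 10_000, seed=15)
        bg = BackgroundSample.from_repertoire(probe, alpha_selection_scheme)
        va = np.zeros(alpha_selection_scheme.dimension)
        vb = np.zeros(alpha_selection_scheme.dimension)
        va[alpha_selection_scheme.index["v_TRAV2"]] = 1.0
        vb[alpha_selection_scheme.index["j_TRAJ3"]] = 1.0
        zeros = np.zeros(alpha_selection_scheme.dimension)
        ma = SelectionModel(alpha_selection_scheme, va, 0.0, bg, zeros)
        mb = SelectionModel(alpha_selection_scheme, vb, 0.0, bg, zeros)
        common = zero_selection_model(bg, alpha_selection_scheme)
        probe2 = generate_repertoire(default_model, 10_000, seed=16)
        cmp = compare_stage_energies(ma, mb, common, probe2)
        assert abs(cmp.pearson_r) < 0.05

    def test_small_probe_rejected(self, default_model,
                                  alpha_selection_scheme):
        probe = generate_repertoire(default_model, 50, seed=17)
        bg = BackgroundSample.from_repertoire(probe, alpha_selection_scheme)
        m = zero_selection_model(bg, alpha_selection_scheme)
        with pytest.raises(ValueError, match="probe"):
            compare_stage_energies(m, m, m, probe)


class TestEnrichmentAndHydrophobicity:
    def test_identical_models_have_zero_difference(self, toy_model):
        scheme = toy_scheme()
        m = handmade_model(toy_model, scheme, {"length_4": 0.4}, bg_n=500)
        assert np.allclose(feature_enrichment_difference(m, m), 0.0)

    def test_enrichment_difference_arithmetic(self, toy_model):
        scheme = toy_scheme()
        a = handmade_model(toy_model, scheme, {}, bg_n=500)
        b = handmade_model(toy_model, scheme, {}, bg_n=500)
        i = scheme.index["length_4"]
        a.epsilons[i], b.epsilons[i] = 0.4, 0.0
        a.marginals = np.zeros(scheme.dimension)
        b.marginals = np.zeros(scheme.dimension)
        a.marginals[i] = b.marginals[i] = 0.5
        assert feature_enrichment_difference(a, b)[i] == pytest.approx(0.2)

    def test_u_score_zero_for_null_model(self, default_model,
                                         alpha_selection_scheme):
        bg = BackgroundSample.from_model(default_model, 1000, 18,
                                         alpha_selection_scheme)
        model = zero_selection_model(bg, alpha_selection_scheme)
        assert hydrophobicity_score_U(model, data_marginals(bg.X)) == 0.0

    def test_u_score_single_term_arithmetic(self, default_model,
                                            alpha_selection_scheme):
        bg = BackgroundSample.from_model(default_model, 1000, 19,
                                         alpha_selection_scheme)
        model = zero_selection_model(bg, alpha_selection_scheme)
        i = alpha_selection_scheme.index["left_5_L"]
        model.epsilons[i] = 2.0
        marg = np.zeros(alpha_selection_scheme.dimension)
        marg[i] = 0.1
        assert hydrophobicity_score_U(model, marg) == pytest.approx(0.2)

    def test_index_u_arithmetic(self):
        assert hydrophobicity_index_u("CASSSGGDF") == 0.0
        assert hydrophobicity_index_u("CASSLLSSSF") == pytest.approx(0.2)
        assert hydrophobicity_index_u("CASSLLSSSF", region="full") \
            == pytest.approx(0.4)  # C, 2 L's and F all count

    def test_median_background_u_near_reported_value(self, default_model):
        rep = generate_repertoire(default_model, 100_000, seed=20)
        u = np.array([hydrophobicity_index_u(c) for c in rep])
        assert abs(float(np.median(u)) - 0.2) <= 0.03

    def test_hydrophobic_enrichment_lowers_u_score(self, default_model,
                                                   alpha_selection_scheme):
        rep = generate_repertoire(default_model, 40_000, seed=21)
        u = np.array([hydrophobicity_index_u(c) for c in rep])
        cfg = ToySelectionConfig(mode="hydrophobicity",
                                 u0=float(np.median(u)), h=1, seed=22)
        hi, _ = apply_soft_selection(rep, cfg)
        model = fit_selection_model(hi, default_model,
                                    alpha_selection_scheme, seed=23,
                                    background_size=100_000)
        marg = data_marginals(model.background.X)
        # enrichment = negative eps, so the selected stage scores below the
        # pre-selection model's U = 0
        assert hydrophobicity_score_U(model, marg) < 0.0


class TestSerialization:
    def test_save_load_round_trip(self, toy_model, tmp_path):
        scheme = toy_scheme()
        model = handmade_model(toy_model, scheme, {"length_4": 0.4,
                                                   "v_TRAV1": -0.2})
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path, model.background)
        assert np.allclose(back.epsilons, model.epsilons)
        assert back.log_z == pytest.approx(model.log_z)
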