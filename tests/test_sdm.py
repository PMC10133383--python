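import numpy as np
import pytest

from cohesion_delim import sdm
from cohesion_delim import synthetic_data as syn
from cohesion_delim.synthetic_data import OccurrenceSet


@pytest.fixture(scope="module")
def tiny_stack():
    return syn.simulate_climate_stack(3, (20, 20), autocorr_length=2, seed=50)


class TestThinning:
    def test_five_records_one_cell(self, tiny_stack):
        occ = OccurrenceSet(lineage="A", x=[5.1, 5.2, 5.3, 5.4, 5.49], y=[5.1] * 5)
        out = sdm.thin_occurrences(occ, tiny_stack)
        assert len(out) == 1

    def test_k_distinct_cells(self, tiny_stack):
        occ = OccurrenceSet(lineage="A", x=[0.5, 1.5, 2.5, 3.5], y=[0.5] * 4)
        out = sdm.thin_occurrences(occ, tiny_stack)
        assert len(out) == 4

    def test_first_record_retained(self, tiny_stack):
        occ = OccurrenceSet(lineage="A", x=[5.2, 5.8], y=[5.3, 5.7])
        out = sdm.thin_occurrences(occ, tiny_stack)
        assert out.x[0] == 5.2

    def test_masked_cell_dropped_with_count(self):
        stack = syn.simulate_climate_stack(1, (10, 10), autocorr_length=0, seed=51)
        stack.mask[0, 0] = False
        occ = OccurrenceSet(lineage="A", x=[0.5, 5.5], y=[9.5, 5.5])  # first on masked cell
        out = sdm.thin_occurrences(occ, stack)
        assert len(out) == 1
        assert out.provenance["n_dropped_masked"] == 1

    def test_empty_after_thinning_raises(self):
        stack = syn.simulate_climate_stack(1, (5, 5), autocorr_length=0, seed=52)
        occ = OccurrenceSet(lineage="A", x=[99.0], y=[99.0])
        with pytest.raises(ValueError, match="'A'"):
            sdm.thin_occurrences(occ, stack)


class TestBackground:
    def test_single_cell_region(self, tiny_stack):
        pts = sdm.sample_background(tiny_stack, 1, region=np.array([7]), seed=1)
        assert pts.tolist() == [7]

    def test_all_cells(self, tiny_stack):
        pts = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=2)
        assert sorted(pts.tolist()) == tiny_stack.valid_flat_indices().tolist()

    def test_seed_reproducible(self, tiny_stack):
        a = sdm.sample_background(tiny_stack, 50, seed=3)
        b = sdm.sample_background(tiny_stack, 50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_oversample_flags_with_replacement(self, tiny_stack):
        with pytest.warns(UserWarning, match="with replacement"):
            pts = sdm.sample_background(tiny_stack, tiny_stack.n_valid + 10, seed=4)
        assert pts.size == tiny_stack.n_valid + 10

    def test_empty_region_raises(self, tiny_stack):
        with pytest.raises(ValueError, match="empty"):
            sdm.sample_background(tiny_stack, 1, region=np.array([], dtype=int), seed=5)


class TestFeatures:
    env = np.random.default_rng(0).random((40, 3))

    def test_linear_count(self):
        F, names = sdm.build_features(self.env, "L")
        assert F.shape[1] == 3

    def test_lq_count(self):
        F, _ = sdm.build_features(self.env, "LQ")
        assert F.shape[1] == 6

    def test_lqp_count(self):
        # [DERIVED] combinatorial: 3 linear + 3 quadratic + C(3,2) products = 9
        F, _ = sdm.build_features(self.env, "LQP")
        assert F.shape[1] == 9

    def test_hinge_count_and_range(self):
        F, names = sdm.build_features(self.env, "H", hinge_knots=4)
        assert F.shape[1] == 3 * 2 * 4
        assert F.min() >= 0 and F.max() <= 1

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError, match="feature class"):
            sdm.build_features(self.env, "LX")

    def test_column_order_deterministic(self):
        _, names = sdm.build_features(self.env, "LQPH", hinge_knots=2)
        kinds = [n.split(":")[0] for n in names]
        order = {"L": 0, "Q": 1, "P": 2, "Hf": 3, "Hr": 3}
        assert kinds == sorted(kinds, key=order.__getitem__)


class TestFit:
    def test_null_data_large_rm_shrinks_to_uniform(self, tiny_stack):
        # [DERIVED] presences drawn uniformly carry no signal
        rng = np.random.default_rng(60)
        cells = rng.choice(tiny_stack.n_valid, 30, replace=False)
        xs, ys = tiny_stack.cell_centers()
        occ = OccurrenceSet(lineage="U", x=xs.ravel()[cells], y=ys.ravel()[cells])
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=61)
        model = sdm.fit_model(occ, bg, tiny_stack, fc="L", rm=50.0)
        assert model.k == 0
        surface = sdm.predict_surface(model, tiny_stack)
        vals = surface.raw[surface.mask]
        assert vals.max() / vals.min() < 1.05

    def test_signal_gives_positive_coefficient(self, tiny_stack):
        # presences concentrated at high values of layer 1
        flat = tiny_stack.values[0].ravel()
        cells = np.argsort(flat)[-25:]
        xs, ys = tiny_stack.cell_centers()
        occ = OccurrenceSet(lineage="S", x=xs.ravel()[cells], y=ys.ravel()[cells])
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=62)
        model = sdm.fit_model(occ, bg, tiny_stack, fc="L", rm=0.5)
        assert model.beta[0] > 0

    def test_rm_monotonicity_of_k(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 40, seed=63)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=64)
        ks = [
            sdm.fit_model(thin, bg, tiny_stack, fc="LQ", rm=rm).k
            for rm in (0.5, 1, 2, 4, 8, 16)
        ]
        assert all(a >= b for a, b in zip(ks, ks[1:]))


class TestAICc:
    def test_uniform_closed_form(self, tiny_stack):
        # k = 0 with C cells: lnL = -n ln C, AICc = 2 n ln C
        rng = np.random.default_rng(70)
        cells = rng.choice(tiny_stack.n_valid, 20, replace=False)
        xs, ys = tiny_stack.cell_centers()
        occ = OccurrenceSet(lineage="U", x=xs.ravel()[cells], y=ys.ravel()[cells])
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=71)
        model = sdm.fit_model(occ, bg, tiny_stack, fc="L", rm=100.0)
        assert model.k == 0
        assert model.aicc == pytest.approx(2 * 20 * np.log(tiny_stack.n_valid), rel=1e-9)

    def test_arithmetic_example(self):
        # n = 10, k = 3, lnL = -25 -> 6 + 50 + 24/6 = 60
        assert 2 * 3 - 2 * (-25) + 2 * 3 * 4 / (10 - 3 - 1) == pytest.approx(60.0)

    def test_invalid_when_n_too_small(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 60, seed=72)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        # force n - k - 1 <= 0 by truncating to 3 presences with >= 2 features
        small = OccurrenceSet(lineage="A", x=thin.x[:3], y=thin.y[:3])
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=73)
        model = sdm.fit_model(small, bg, tiny_stack, fc="LQ", rm=0.01)
        if model.k >= 2:
            assert not model.aicc_valid

    def test_brute_force_recomputation(self, tiny_stack, shared_niche):
        # [DERIVED] independent oracle: recompute lnL from the stored surface
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 40, seed=74)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=75)
        model = sdm.fit_model(thin, bg, tiny_stack, fc="LQ", rm=1.0)
        surface = sdm.predict_surface(model, tiny_stack)
        lnl = sum(
            np.log(surface.raw.ravel()[c]) for c in sdm.occurrence_cells(thin, tiny_stack)
        )
        k, n = model.k, model.n
        aicc = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
        assert aicc == pytest.approx(model.aicc, abs=1e-9)


class TestSelection:
    def test_single_candidate(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 40, seed=80)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=81)
        m = sdm.fit_model(thin, bg, tiny_stack, fc="L", rm=1.0)
        best, table = sdm.select_model([m])
        assert best is m
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_default_grid_has_30_models(self):
        assert len(sdm.DEFAULT_FC_GRID) * len(sdm.DEFAULT_RM_GRID) == 30

    def test_injected_better_candidate_wins(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 40, seed=82)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=83)
        models = [
            sdm.fit_model(thin, bg, tiny_stack, fc=fc, rm=rm)
            for fc in ("L", "LQ")
            for rm in (1.0, 2.0)
        ]
        ringer = sdm.fit_model(thin, bg, tiny_stack, fc="L", rm=1.0)
        ringer.aicc = min(m.aicc for m in models) - 10
        best, _ = sdm.select_model(models + [ringer])
        assert best is ringer

    def test_all_invalid_raises(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 40, seed=84)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=85)
        m = sdm.fit_model(thin, bg, tiny_stack, fc="L", rm=1.0)
        m.converged = False
        with pytest.raises(ValueError, match="invalid"):
            sdm.select_model([m])


class TestPredict:
    def test_zero_beta_uniform(self, tiny_stack, shared_niche):
        occs = syn.simulate_occurrences(tiny_stack, {"A": shared_niche}, 30, seed=90)
        thin = sdm.thin_occurrences(occs["A"], tiny_stack)
        bg = sdm.sample_background(tiny_stack, tiny_stack.n_valid, seed=91)
        model = sdm.fit_model(thin, bg, tiny_stack, fc="L", rm=1000.0)
        assert model.k == 0
        surf = sdm.predict_surface(model, tiny_stack)
        np.testing.assert_allclose(surf.raw[surf.mask], 1.0 / tiny_stack.n_valid)

    def test_raw_sums_to_one_and_logistic_bounded(self, fitted_null_pair):
        for thin, model, surf in fitted_null_pair.values():
            assert surf.raw[surf.mask].sum() == pytest.approx(1.0, abs=1e-9)
            lv = surf.logistic[surf.mask]
            assert (lv >= 0).all() and (lv <= 1).all()

    def test_monotone_with_linear_score(self, fitted_null_pair, small_stack):
        thin, model, surf = fitted_null_pair["A"]
        ctx = sdm.CellFeatureContext(small_stack, model.background_cells, model.fc, model.hinge_knots)
        score = ctx.F_cells @ model.beta
        raw = surf.raw[surf.mask]
        order = np.argsort(score)
        assert (np.diff(raw[order]) >= -1e-15).all()

    def test_mean_presence_logistic_is_half(self, fitted_null_pair):
        thin, model, surf = fitted_null_pair["A"]
        pres_logistic = surf.logistic.ravel()[model.presence_cells]
        assert pres_logistic.mean() == pytest.approx(0.5, abs=1e-6)

    def test_missing_layer_raises(self, fitted_null_pair, small_stack):
        _, model, _ = fitted_null_pair["A"]
        sub = small_stack.select_layers(small_stack.names[:2])
        with pytest.raises(ValueError, match="env3"):
            sdm.predict_surface(model, sub)

    def test_renormalization_idempotent(self, fitted_null_pair):
        _, _, surf = fitted_null_pair["A"]
        raw = surf.raw[surf.mask]
        np.testing.assert_allclose(raw / raw.sum(), raw, atol=1e-15)


class TestParameterRecovery:
    def test_single_layer_recovery(self):
        # Invariant: selected raw surface tracks true suitability (rho > 0.9)
        from scipy.stats import spearmanr

        stack = syn.simulate_climate_stack(1, (50, 50), autocorr_length=5, seed=95)
        niche = syn.NicheParams(optima=[0.5], tolerances=[0.6])
        occs = syn.simulate_occurrences(stack, {"A": niche}, 100, seed=96)
        model, surf, table = sdm.fit_sdm(occs["A"], stack, sdm.FitConfig(), seed=97)
        truth = syn.suitability_map(stack, niche)
        rho = spearmanr(surf.raw[surf.mask], truth[stack.mask]).statistic
        assert rho > 0.9
        assert len(table) == 30
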