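import numpy as np
import pytest

from phytovuln.ensemble import (
    EnsembleSDM,
    ModelReplicate,
    binarize,
    compute_tss,
    ensemble_weighted,
    find_optimal_threshold,
    fit_replicate,
    make_background,
    predict_suitability,
    split_data,
)


class TestComputeTss:
    def test_perfect_prediction(self):
        pred = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert compute_tss(pred, labels, 0.5) == pytest.approx(1.0)

    def test_hand_computed_confusion_matrix(self):
        # TP=40, FN=10, TN=35, FP=15 -> 0.8 + 0.7 - 1 = 0.5
        pred = np.concatenate([
            np.full(40, 0.9), np.full(10, 0.1),   # positives
            np.full(35, 0.1), np.full(15, 0.9),   # negatives
        ])
        labels = np.concatenate([np.ones(50), np.zeros(50)])
        assert compute_tss(pred, labels, 0.5) == pytest.approx(0.5)

    def test_constant_score_has_no_skill(self):
        pred = np.full(20, 0.4)
        labels = np.r_[np.ones(10), np.zeros(10)]
        assert compute_tss(pred, labels, 0.4) == pytest.approx(0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_tss(np.array([0.1, 0.9]), np.array([1, 1]), 0.5)


class TestFindOptimalThreshold:
    def test_separable_scores_midpoint(self):
        pred = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        thr, tss = find_optimal_threshold(pred, labels)
        assert tss == pytest.approx(1.0)
        assert thr == pytest.approx(0.5)  # midpoint of the separating gap

    def test_constant_scores_zero_tss(self):
        thr, tss = find_optimal_threshold(np.full(10, 0.3), np.r_[np.ones(5), np.zeros(5)])
        assert tss == 0.0 and thr == 0.3

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_grid(self, seed):
        """Optimal TSS equals a brute-force scan over 1,000 evenly spaced
        thresholds (within one grid step of TSS resolution)."""
        rng = np.random.default_rng(seed)
        n = 120
        labels = rng.random(n) < 0.4
        pred = np.clip(rng.normal(0.3 + 0.4 * labels, 0.25), 0, 1)
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        thr, tss = find_optimal_threshold(pred, labels)
        grid = np.linspace(pred.min() - 1e-9, pred.max() + 1e-9, 1000)
        brute = max(compute_tss(pred, labels, t) for t in grid)
        assert tss >= brute - 1e-9
        assert tss == pytest.approx(compute_tss(pred, labels, thr))

    def test_label_reversal_symmetry(self, rng):
        """Reversing labels: the best TSS of the complement problem equals
        the best TSS obtained by swapping the inequality direction, i.e.
        scanning 1 - pred."""
        n = 80
        labels = rng.random(n) < 0.5
        pred = np.clip(rng.normal(0.3 + 0.3 * labels, 0.2), 0, 1)
        _, tss_fwd = find_optimal_threshold(pred, labels)
        _, tss_rev = find_optimal_threshold(1.0 - pred, ~labels)
        assert tss_fwd == pytest.approx(tss_rev, abs=1e-9)


class TestSplitData:
    def test_seventy_thirty(self):
        p_tr, p_te, b_tr, b_te = split_data(100, 1000, seed=0)
        assert (len(p_tr), len(p_te)) == (70, 30)
        assert (len(b_tr), len(b_te)) == (700, 300)

    def test_floor_on_training_share(self):
        p_tr, p_te, _, _ = split_data(25, 100, seed=1)
        assert (len(p_tr), len(p_te)) == (17, 8)

    def test_disjoint_and_covering(self):
        p_tr, p_te, b_tr, b_te = split_data(43, 97, seed=2)
        assert not set(p_tr) & set(p_te)
        assert sorted(np.r_[p_tr, p_te]) == list(range(43))
        assert sorted(np.r_[b_tr, b_te]) == list(range(97))


class TestFitReplicate:
    @pytest.mark.parametrize("technique", ["gbm", "rf", "maxent"])
    def test_separable_data_perfect_tss(self, technique, rng):
        X = np.vstack([rng.normal(2.0, 0.3, (60, 3)), rng.normal(-2.0, 0.3, (200, 3))])
        y = np.r_[np.ones(60, bool), np.zeros(200, bool)]
        model = fit_replicate(technique, X, y, seed=0)
        pred = predict_suitability(model, X)
        assert pred.min() >= 0.0 and pred.max() <= 1.0
        _, tss = find_optimal_threshold(pred, y)
        assert tss == pytest.approx(1.0)

    def test_constant_feature_rejected(self, rng):
        X = np.ones((50, 2))
        y = np.r_[np.ones(25, bool), np.zeros(25, bool)]
        with pytest.raises(ValueError, match="degenerate|constant"):
            fit_replicate("rf", X, y)

    def test_unknown_technique_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        with pytest.raises(ValueError, match="unknown technique"):
            fit_replicate("gam", X, y)


def _rep(tss, values, scenario="present"):
    return ModelReplicate(technique="gbm", replicate_index=1, tss=tss,
                          threshold_at_max_tss=0.5,
                          suitability={scenario: np.asarray(values, dtype=float)})


class TestEnsembleWeighted:
    def test_identical_replicates_passthrough(self):
        reps = [_rep(0.8, [0.2, 0.9]), _rep(0.9, [0.2, 0.9])]
        _, _, maps = ensemble_weighted(reps)
        np.testing.assert_allclose(maps["present"], [0.2, 0.9])

    def test_tss_floor_is_strict(self):
        reps = [_rep(0.69, [1.0, 1.0]), _rep(0.71, [0.0, 0.0])]
        included, _, maps = ensemble_weighted(reps, tss_min=0.7)
        assert included == [1]
        np.testing.assert_allclose(maps["present"], [0.0, 0.0])

    def test_hand_weighted_average(self):
        a, b = np.array([0.2, 0.6]), np.array([0.4, 1.0])
        reps = [_rep(0.8, a), _rep(0.9, b)]
        _, _, maps = ensemble_weighted(reps)
        np.testing.assert_allclose(maps["present"], (0.8 * a + 0.9 * b) / 1.7)

    def test_no_passing_replicates_flags_not_modeled(self):
        included, _, maps = ensemble_weighted([_rep(0.3, [0.5])])
        assert included == [] and maps is None

    def test_order_invariance_and_bounds(self, rng):
        reps = [_rep(0.75 + 0.02 * i, rng.random(50)) for i in range(5)]
        _, _, fwd = ensemble_weighted(reps)
        _, _, rev = ensemble_weighted(list(reversed(reps)))
        np.testing.assert_allclose(fwd["present"], rev["present"])
        stack = np.array([r.suitability["present"] for r in reps])
        assert np.all(fwd["present"] >= stack.min(axis=0) - 1e-12)
        assert np.all(fwd["present"] <= stack.max(axis=0) + 1e-12)


def test_binarize_boundary_is_presence():
    assert binarize(np.array([0.5, 0.49]), 0.5).tolist() == [True, False]


class TestEnsembleSDMEndToEnd:
    @pytest.fixture(scope="class")
    def fitted(self, climate_small, species_small):
        from phytovuln import sample_occurrences
        from phytovuln.occurrences import prepare_occurrences

        occ = sample_occurrences(species_small, climate_small["present"],
                                 n_per_species=150, seed=5)
        spec = climate_small["present"].spec
        clean, _, _ = prepare_occurrences(occ, spec)
        counts = clean["species"].value_counts()
        mid = counts[(counts >= 25) & (counts <= 80)]
        sp_id = (mid if len(mid) else counts).index[0]
        sub = clean[clean["species"] == sp_id]
        cells = spec.cell_index(sub["longitude"].to_numpy(), sub["latitude"].to_numpy())
        bg = make_background(climate_small["present"], n=800, seed=6)
        sdm = EnsembleSDM(cells, climate_small, bg, species_id=sp_id, n_replicates=2)
        return sdm, sdm.fit(seed=9, store_replicate_maps=True), sp_id

    def test_summary_and_evaluation_shape(self, fitted):
        sdm, res, sp_id = fitted
        ev = res.evaluation_table()
        assert len(ev) == 6  # 2 replicates x 3 techniques
        assert set(ev["technique"]) == {"gbm", "rf", "maxent"}
        assert ((ev["tss"] >= -1) & (ev["tss"] <= 1)).all()
        s = res.summary()
        assert s["species"].iloc[0] == sp_id

    def test_ensemble_within_replicate_envelope(self, fitted):
        _, res, _ = fitted
        if res.not_modeled:
            pytest.skip("no replicate passed the TSS floor on this fixture")
        stack = np.array([res.replicates[i].suitability["present"] for i in res.included])
        assert np.all(res.suitability["present"] >= stack.min(axis=0) - 1e-12)
        assert np.all(res.suitability["present"] <= stack.max(axis=0) + 1e-12)

    def test_same_threshold_all_scenarios(self, fitted):
        _, res, _ = fitted
        if res.not_modeled:
            pytest.skip("not modeled")
        for scen in res.suitability:
            br = res.binary_range(scen)
            np.testing.assert_array_equal(br, res.suitability[scen] >= res.threshold)

    def test_fit_deterministic(self, climate_small, fitted):
        sdm, res, _ = fitted
        res2 = sdm.fit(seed=9)
        ev1, ev2 = res.evaluation_table(), res2.evaluation_table()
        np.testing.assert_allclose(ev1["tss"], ev2["tss"])
        if res.not_modeled:
            assert res2.not_modeled
        else:
            assert res2.threshold == res.threshold
            np.testing.assert_array_equal(res2.binary_range("present"),
                                          res.binary_range("present"))
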