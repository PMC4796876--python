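"""Dataset curation, evaluation metrics and the training protocol."""

import numpy as np
import pytest

import hotmusic as hm
from hotmusic.features import MutationRecord
from hotmusic.train_eval import (
    TrainConfig,
    crossvalidate,
    evaluate,
    filter_dataset,
    merge_duplicates,
    train,
)


def _rec(**kw):
    base = dict(
        protein_id="P", chain="A", position="1", wt_aa="A", mut_aa="G",
        dtm_exp=-2.0, resolution=1.8, ph=7.0,
    )
    base.update(kw)
    return MutationRecord(**base)


class TestFilterDataset:
    def test_clean_record_is_kept(self):
        kept, rejected = filter_dataset([_rec()])
        assert len(kept) == 1 and not rejected

    @pytest.mark.parametrize(
        "kw,reason",
        [
            (dict(resolution=2.8), "resolution"),
            (dict(resolution=None), "resolution"),
            (dict(dtm_exp=25.0), "dtm_magnitude"),
            (dict(dtm_exp=-20.5), "dtm_magnitude"),
            (dict(monomeric=False), "monomeric"),
            (dict(no_denaturants=False), "denaturant"),
            (dict(two_state=False), "two_state"),
            (dict(n_substitutions=2), "multi_point"),
            (dict(dtm_exp=None), "missing_dtm"),
        ],
    )
    def test_each_rule_rejects_with_its_reason(self, kw, reason):
        kept, rejected = filter_dataset([_rec(**kw)])
        assert not kept
        assert rejected[0][1] == reason

    def test_boundary_cases(self):
        kept, _ = filter_dataset([_rec(dtm_exp=20.0), _rec(dtm_exp=-20.0)])
        assert len(kept) == 2  # at most 20 degrees is still acceptable
        _, rejected = filter_dataset([_rec(resolution=2.5)])
        assert rejected[0][1] == "resolution"  # strictly below 2.5 required

    def test_first_failing_rule_labels_rejection(self):
        _, rejected = filter_dataset([_rec(monomeric=False, dtm_exp=30.0)])
        assert rejected[0][1] == "monomeric"

    def test_all_rejected_is_valid(self):
        kept, rejected = filter_dataset([_rec(two_state=False)] * 3)
        assert kept == [] and len(rejected) == 3


class TestMergeDuplicates:
    def test_ph_closest_to_seven_wins(self):
        a = _rec(ph=6.0, dtm_exp=-3.0)
        b = _rec(ph=7.0, dtm_exp=-1.0)
        merged = merge_duplicates([a, b])
        assert len(merged) == 1
        assert merged[0].dtm_exp == pytest.approx(-1.0)

    def test_equal_ph_entries_average(self):
        a = _rec(ph=7.0, dtm_exp=-2.0)
        b = _rec(ph=7.0, dtm_exp=-4.0)
        merged = merge_duplicates([a, b])
        assert merged[0].dtm_exp == pytest.approx(-3.0)
        assert merged[0].provenance

    def test_tolerance_window_includes_near_ties(self):
        a = _rec(ph=7.0, dtm_exp=-2.0)
        b = _rec(ph=7.4, dtm_exp=-4.0)
        c = _rec(ph=5.0, dtm_exp=10.0)
        merged = merge_duplicates([a, b, c], ph_tolerance=0.5)
        assert merged[0].dtm_exp == pytest.approx(-3.0)

    def test_singletons_and_distinct_mutations_untouched(self):
        a = _rec(position="1")
        b = _rec(position="2")
        merged = merge_duplicates([a, b])
        assert [m.key for m in merged] == [a.key, b.key]

    def test_missing_ph_treated_as_neutral(self):
        a = _rec(ph=None, dtm_exp=-2.0)
        b = _rec(ph=4.0, dtm_exp=-8.0)
        merged = merge_duplicates([a, b])
        assert merged[0].dtm_exp == pytest.approx(-2.0)


class TestEvaluate:
    def test_perfect_prediction(self):
        r = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.sigma == 0.0 and r.r == pytest.approx(1.0)

    def test_constant_shift(self):
        exp = np.array([0.0, 1.0, -2.0, 4.0])
        r = evaluate(exp + 1.0, exp)
        assert r.sigma == pytest.approx(1.0)
        assert r.r == pytest.approx(1.0)

    def test_trimming_removes_largest_errors_exactly(self):
        exp = np.zeros(20)
        pred = np.zeros(20)
        pred[7] = 10.0
        pred[13] = 10.0
        r = evaluate(pred, exp + 1e-9 * np.arange(20), trim_frac=0.10)
        assert r.sigma_trimmed == pytest.approx(0.0, abs=1e-7)
        assert r.sigma > 2.0

    def test_trim_count_is_floor_of_fraction(self):
        rng = np.random.default_rng(0)
        for n in (10, 19, 20, 21, 101):
            exp = rng.normal(size=n)
            pred = exp + rng.normal(size=n)
            r = evaluate(pred, exp)
            assert r.n_mut == n
            assert r.sigma_trimmed <= r.sigma

    def test_zero_variance_experiment_has_undefined_r(self):
        r = evaluate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert r.r is None

    def test_accessibility_strata(self):
        exp = np.array([1.0, 2.0, -1.0, 3.0, 0.5, -2.0])
        pred = exp + np.array([0.1, -0.1, 0.2, 0.0, 0.3, -0.2])
        acc = np.array([5.0, 10.0, 30.0, 45.0, 60.0, 90.0])
        r = evaluate(pred, exp, accessibility=acc)
        by_name = {s.name: s for s in r.strata}
        assert by_name["core"].n == 2
        assert by_name["partially_buried"].n == 2
        assert by_name["surface"].n == 2
        for s in r.strata:
            assert s.sigma >= 0
            if s.sigma_over_std is not None:
                assert s.sigma_over_std == pytest.approx(
                    s.sigma / np.std(exp[(acc >= dict(core=0, partially_buried=15,
                                                     surface=50)[s.name])
                                         & (acc < dict(core=15, partially_buried=50,
                                                       surface=1000)[s.name])])
                )


@pytest.fixture(scope="module")
def planted_linear_data():
    """Features from the real pipeline, targets from a flat-weight truth."""
    spec = hm.SyntheticSpec(n_structures=8, chain_length_range=(40, 80),
                            coupling=0.5, seed=21, n_mutations=400, noise_sd=0.0)
    cfg = hm.synthetic_descriptor_config()
    structs = [hm.structure_arrays(s, cfg) for s in hm.generate_structures(spec)]
    std = hm.derive_standard_potentials(structs, cfg)
    truth = hm.flat_truth_hot()
    ds = hm.generate_mutation_dataset(structs, truth, std, spec=spec, config=cfg)
    X = hm.feature_table([v for _, v in ds])
    y = np.array([r.dtm_exp for r, _ in ds])
    return X, y


class TestTraining:
    def test_noiseless_planted_fit_reaches_zero_error(self, planted_linear_data):
        X, y = planted_linear_data
        cfg = TrainConfig(n_restarts=2, max_iter=3000, optimizer="lbfgs",
                          early_stop_patience=300, seed=0)
        est = train(X, y, "hot", cfg)
        assert est.training_sigma_ <= 1e-3

    def test_same_seed_reproduces_parameters(self, planted_linear_data):
        X, y = planted_linear_data
        cfg = TrainConfig(n_restarts=2, max_iter=200, optimizer="adam",
                          learning_rate=0.01, early_stop_patience=50, seed=5)
        est1 = train(X, y, "hot", cfg)
        est2 = train(X, y, "hot", cfg)
        assert np.array_equal(est1.theta_, est2.theta_)

    def test_constant_zero_targets_fit_to_zero(self, planted_linear_data):
        X, _ = planted_linear_data
        y = np.zeros(len(X))
        cfg = TrainConfig(n_restarts=1, max_iter=500, optimizer="lbfgs",
                          early_stop_patience=100, seed=0)
        est = train(X, y, "hot", cfg)
        assert est.training_sigma_ == pytest.approx(0.0, abs=1e-6)

    def test_plain_gradient_descent_reduces_error(self, planted_linear_data):
        X, y = planted_linear_data
        cfg = TrainConfig(n_restarts=1, max_iter=300, optimizer="gd",
                          learning_rate=1e-5, early_stop_patience=300, seed=0)
        est = train(X, y, "hot", cfg)
        assert est.training_sigma_ < np.sqrt(np.mean(y**2))

    def test_unknown_model_kind_rejected(self, planted_linear_data):
        X, y = planted_linear_data
        with pytest.raises(ValueError, match="model kind"):
            train(X, y, "other")


class TestCrossValidation:
    def test_folds_partition_dataset(self, planted_linear_data):
        X, y = planted_linear_data
        cfg = TrainConfig(n_restarts=1, max_iter=300, optimizer="lbfgs",
                          early_stop_patience=50, seed=3, k_folds=5)
        cv = crossvalidate(X, y, "hot", cfg)
        assert (cv.fold_assignment >= 0).all()
        counts = np.bincount(cv.fold_assignment, minlength=5)
        assert counts.sum() == len(X)
        assert counts.max() - counts.min() <= 1
        assert np.isfinite(cv.oof_pred).all()

    def test_same_seed_same_folds(self, planted_linear_data):
        X, y = planted_linear_data
        cfg = TrainConfig(n_restarts=1, max_iter=50, optimizer="adam",
                          learning_rate=0.01, early_stop_patience=50, seed=9)
        cv1 = crossvalidate(X, y, "hot", cfg)
        cv2 = crossvalidate(X, y, "hot", cfg)
        assert np.array_equal(cv1.fold_assignment, cv2.fold_assignment)
        assert np.allclose(cv1.oof_pred, cv2.oof_pred)

    def test_dataset_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(np.zeros((3, 13)), np.zeros(3), "hot",
                          TrainConfig(k_folds=5))
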