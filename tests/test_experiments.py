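import numpy as np
import pandas as pd
import pytest

from foramcurve.augment import augment_set
from foramcurve.errors import SpecificationError
from foramcurve.experiments import (
    ExperimentDesign,
    LearningCurveResult,
    agreement_regression,
    build_training_sets,
    compare_early_stopping,
    fit_dice_glm,
    minimum_specimens,
    run_learning_curve,
)
from foramcurve.phantom import desk_population_spec, generate_population
from foramcurve.segnet import TrainConfig


@pytest.fixture(scope="module")
def population():
    return generate_population(desk_population_spec(seed=21))


@pytest.fixture(scope="module")
def quick_cfg():
    return TrainConfig.desk_scale(
        patch_size_vox=(8, 8, 8), stride_vox=8, steps_per_epoch=2,
        max_epochs=3, patience_epochs=3, seed=1,
    )


def result_from_medians(medians: dict) -> LearningCurveResult:
    """Build a result carrying only per-cell medians, for unit tests."""
    rows = [
        dict(size=size, arm=arm, median_dice=v) for (size, arm), v in medians.items()
    ]
    return LearningCurveResult(
        records=pd.DataFrame(), median_per_cell=pd.DataFrame(rows)
    )


class TestDesign:
    def test_validation(self):
        with pytest.raises(SpecificationError):
            ExperimentDesign(sizes=(4, 2, 1))
        with pytest.raises(SpecificationError):
            ExperimentDesign(accuracy_threshold=1.5)

    def test_paper_scale_defaults(self):
        d = ExperimentDesign()
        assert d.sizes == (1, 2, 4, 8, 16, 20)
        assert d.n_replicates == 3
        assert d.accuracy_threshold == 0.95


class TestBuildTrainingSets:
    def test_nesting(self, population):
        design = ExperimentDesign.desk_scale(sizes=(1, 2, 4), seed=5)
        sets = build_training_sets(population[0], design)
        ids = {k: [p.specimen_id for p in v] for k, v in sets.items()}
        assert set(ids[1]) <= set(ids[2]) <= set(ids[4])

    def test_six_sets_on_20_pool(self):
        pool = generate_population(
            desk_population_spec(n_specimens=20, split=(20, 0, 0), seed=1)
        )[0]
        design = ExperimentDesign(sizes=(1, 2, 4, 8, 16, 20), seed=0)
        sets = build_training_sets(pool, design)
        assert sorted(sets) == [1, 2, 4, 8, 16, 20]

    def test_augmented_arm_size4_gives_24_stacks(self, population):
        design = ExperimentDesign.desk_scale(sizes=(4,), seed=0)
        sets = build_training_sets(population[0], design)
        assert len(augment_set(sets[4])) == 24

    def test_size_exceeds_pool(self, population):
        with pytest.raises(SpecificationError):
            build_training_sets(
                population[0], ExperimentDesign(sizes=(1, 100))
            )

    def test_non_nested_sampling(self, population):
        design = ExperimentDesign.desk_scale(sizes=(2, 4), nesting=False, seed=5)
        sets = build_training_sets(population[0], design)
        assert len(sets[2]) == 2 and len(sets[4]) == 4


class TestDiceGLM:
    @staticmethod
    def simulate_records(rng, b0, b1, b2, b3, n_rep=40, noise=0.02):
        rows = []
        for size in (1, 2, 4, 8, 16):
            for arm, a in (("original", 0.0), ("augmented", 1.0)):
                eta = b0 + b1 * np.log2(size) + b2 * a + b3 * np.log2(size) * a
                for rep in range(n_rep):
                    mu = 1.0 / (1.0 + np.exp(-(eta + rng.normal(0, noise))))
                    rows.append(
                        dict(size=size, arm=arm, replicate=rep, best_val_dice=mu)
                    )
        return pd.DataFrame(rows)

    def test_recovers_known_coefficients(self, rng):
        true = dict(b0=0.5, b1=0.3, b2=0.4, b3=-0.1)
        records = self.simulate_records(rng, **true)
        result = LearningCurveResult(records=records, median_per_cell=pd.DataFrame())
        fit = fit_dice_glm(result)
        est = fit.params
        for name, key in [("const", "b0"), ("log2_size", "b1"),
                          ("augmented", "b2"), ("log2_size:augmented", "b3")]:
            assert abs(est[name] - true[key]) < 2 * fit.bse[name] + 1e-6

    def test_degenerate_all_equal(self):
        rows = [
            dict(size=s, arm=a, replicate=0, best_val_dice=0.9)
            for s in (1, 2) for a in ("original", "augmented")
        ]
        result = LearningCurveResult(
            records=pd.DataFrame(rows), median_per_cell=pd.DataFrame()
        )
        fit = fit_dice_glm(result)
        assert fit.degenerate
        assert fit.params["log2_size"] == 0.0
        assert fit.params["augmented"] == 0.0

    def test_single_arm_rejected(self):
        rows = [dict(size=s, arm="original", replicate=0, best_val_dice=0.5 + 0.01 * s)
                for s in (1, 2, 4)]
        result = LearningCurveResult(
            records=pd.DataFrame(rows), median_per_cell=pd.DataFrame()
        )
        with pytest.raises(SpecificationError):
            fit_dice_glm(result)


class TestAgreementRegression:
    def test_identity_exact(self, rng):
        manual = rng.uniform(10, 20, size=12)
        groups = np.repeat(["a", "b"], 6)
        rep = agreement_regression(manual, manual.copy(), groups)
        for _, row in rep.per_group.iterrows():
            assert row["slope"] == pytest.approx(1.0)
            assert row["r_squared"] == pytest.approx(1.0)

    def test_doubling_slope_two(self, rng):
        manual = rng.uniform(1, 5, size=8)
        rep = agreement_regression(manual, 2 * manual, np.repeat(["g"], 8))
        assert rep.per_group.loc[0, "slope"] == pytest.approx(2.0)
        assert rep.per_group.loc[0, "r_squared"] == pytest.approx(1.0)

    def test_noise_r2_matches_analytic_expectation(self, rng):
        n, sd = 3000, 0.5
        manual = rng.normal(0, 2.0, size=n)
        predicted = manual + rng.normal(0, sd, size=n)
        rep = agreement_regression(predicted=predicted, manual=manual,
                                   grouping=np.repeat(["g"], n))
        expected = 4.0 / (4.0 + sd**2)  # var_m / (var_m + var_noise)
        assert rep.per_group.loc[0, "r_squared"] == pytest.approx(expected, abs=0.02)

    def test_constant_manual_flagged(self):
        rep = agreement_regression(
            np.ones(6), np.arange(6.0), np.repeat(["g"], 6)
        )
        assert bool(rep.per_group.loc[0, "flagged"])
        assert np.isnan(rep.per_group.loc[0, "r_squared"])

    def test_group_too_small(self):
        with pytest.raises(SpecificationError):
            agreement_regression(np.arange(2.0), np.arange(2.0), np.array(["g", "g"]))

    def test_interaction_f_detects_slope_difference(self, rng):
        manual = np.tile(rng.uniform(0, 10, size=20), 2)
        predicted = np.concatenate([manual[:20], 3 * manual[20:]])
        predicted = predicted + rng.normal(0, 0.01, size=40)
        groups = np.repeat(["a", "b"], 20)
        rep = agreement_regression(manual, predicted, groups)
        assert rep.interaction_p < 1e-6


class TestMinimumSpecimens:
    def test_threshold_crossing(self):
        res = result_from_medians(
            {(1, "original"): 0.90, (2, "original"): 0.93,
             (4, "original"): 0.94, (8, "original"): 0.96}
        )
        assert minimum_specimens(res, 0.95) == {"original": 8}

    def test_never_reached(self):
        res = result_from_medians({(1, "original"): 0.5, (2, "original"): 0.6})
        assert minimum_specimens(res, 0.95) == {"original": None}

    def test_first_size_qualifies(self):
        res = result_from_medians({(1, "original"): 0.99, (2, "original"): 0.98})
        assert minimum_specimens(res, 0.95) == {"original": 1}


class TestLearningCurveSmoke:
    def test_single_cell_single_replicate(self, population, quick_cfg):
        design = ExperimentDesign.desk_scale(
            sizes=(2,), run_augmented_arm=False, n_replicates=1, seed=4
        )
        res = run_learning_curve(*population, design, quick_cfg)
        assert len(res.records) == 1
        assert res.records.loc[0, "size"] == 2
        assert (2, "original") in res.median_models
        assert res.glm_fit is None  # needs both arms and >= 2 sizes
        assert len(res.median_per_cell) == 1

    def test_records_consistent_with_medians(self, population, quick_cfg):
        design = ExperimentDesign.desk_scale(
            sizes=(1, 2), run_augmented_arm=False, n_replicates=3, seed=4
        )
        res = run_learning_curve(*population, design, quick_cfg)
        for _, row in res.median_per_cell.iterrows():
            cell = res.records[
                (res.records["size"] == row["size"])
                & (res.records["arm"] == row["arm"])
            ]
            assert row["median_dice"] == pytest.approx(
                float(cell["best_val_dice"].median())
            )


class TestEarlyStoppingComparison:
    def test_patience_equals_max_identical(self, population):
        cfg = TrainConfig.desk_scale(
            patch_size_vox=(8, 8, 8), stride_vox=8, steps_per_epoch=2,
            max_epochs=4, patience_epochs=3, seed=6,
        )
        report = compare_early_stopping(
            population[0], population[1], cfg, sizes=(1, 2)
        )
        # per-seed determinism: early history is a prefix of the full history
        for _, row in report.table.iterrows():
            if row["best_epoch_full"] <= 4 - 3:
                assert row["dice_early"] == row["dice_full"]

    def test_requires_room_for_patience(self, population):
        cfg = TrainConfig.desk_scale(
            patch_size_vox=(8, 8, 8), max_epochs=3, patience_epochs=3
        )
        with pytest.raises(SpecificationError):
            compare_early_stopping(population[0], population[1], cfg, sizes=(1,))
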