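"""Experimental design and statistics for the learning-curve analysis.

Runs the training-set-size sweep in two arms (original and orientation-
augmented), with replicate networks and median-network selection per cell;
fits the Dice-vs-size generalized linear model (logit link, quasibinomial
variance); compares early stopping against full-length training; regresses
network-derived traits on manually-derived traits per training set; and
determines the smallest training-set size reaching an accuracy threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .augment import augment_set
from .errors import SpecificationError
from .metrics import dice, volumetric_traits
from .segnet import TrainConfig, predict, train, train_replicates
from .stackio import VolumePair

ARMS = ("original", "augmented")


@dataclass
class ExperimentDesign:
    """The size × augmentation sweep."""

    sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 20)
    run_augmented_arm: bool = True
    n_replicates: int = 3
    accuracy_threshold: float = 0.95
    nesting: bool = True  #: smaller training sets are subsets of larger ones
    seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        if any(s < 1 for s in self.sizes) or list(self.sizes) != sorted(set(self.sizes)):
            raise SpecificationError("sizes must be an increasing list of integers >= 1")
        if not 0.0 < self.accuracy_threshold < 1.0:
            raise SpecificationError("accuracy_threshold must be in (0, 1)")
        if self.n_replicates < 1:
            raise SpecificationError("n_replicates must be >= 1")

    @property
    def arms(self) -> tuple[str, ...]:
        return ARMS if self.run_augmented_arm else ARMS[:1]

    @classmethod
    def desk_scale(cls, **overrides) -> "ExperimentDesign":
        values = dict(sizes=(1, 2, 4, 8))
        values.update(overrides)
        return cls(**values)


@dataclass
class GLMFit:
    """Coefficients of the Dice GLM on the logit scale."""

    params: pd.Series
    bse: pd.Series
    dispersion: float
    degenerate: bool = False  #: True when all Dice values were equal


@dataclass
class LearningCurveResult:
    """Everything recorded by the sweep."""

    records: pd.DataFrame  #: columns size, arm, replicate, best_val_dice, ...
    median_per_cell: pd.DataFrame  #: columns size, arm, median_dice
    median_models: dict = field(default_factory=dict)  #: (size, arm) -> TrainedModel
    glm_fit: GLMFit | None = None
    min_specimens: dict = field(default_factory=dict)  #: arm -> int | None
    test_pool: list = field(default_factory=list)  #: held-out specimens


def build_training_sets(
    pool: list[VolumePair], design: ExperimentDesign
) -> dict[int, list[VolumePair]]:
    """Original-arm training sets per size.

    With nesting on (default) the sets are prefixes of one fixed seeded
    ordering of the pool, so set₁ ⊂ set₂ ⊂ …; otherwise each size draws an
    independent sample.
    """
    if max(design.sizes) > len(pool):
        raise SpecificationError(
            f"largest size {max(design.sizes)} exceeds pool of {len(pool)}"
        )
    rng = np.random.default_rng(design.seed)
    sets: dict[int, list[VolumePair]] = {}
    if design.nesting:
        order = rng.permutation(len(pool))
        for size in design.sizes:
            sets[size] = [pool[i] for i in order[:size]]
    else:
        for size in design.sizes:
            idx = rng.choice(len(pool), size=size, replace=False)
            sets[size] = [pool[i] for i in idx]
    return sets


def run_learning_curve(
    train_pool: list[VolumePair],
    val_pool: list[VolumePair],
    test_pool: list[VolumePair],
    design: ExperimentDesign,
    cfg: TrainConfig,
) -> LearningCurveResult:
    """Train replicates for every (size, arm) cell and collect the records.

    Each cell trains ``design.n_replicates`` networks with seeds derived
    from (design.seed, cfg.seed, size, arm); the median-accuracy network is
    kept for downstream trait evaluation.  A failed cell is recorded with
    NaN Dice and skipped, not fatal.
    """
    sets = build_training_sets(train_pool, design)
    rows = []
    median_models: dict = {}
    for size in design.sizes:
        for arm_i, arm in enumerate(design.arms):
            pairs = sets[size]
            if arm == "augmented":
                pairs = augment_set(pairs)
            cell_seed = int(
                np.random.SeedSequence(
                    [design.seed, cfg.seed, size, arm_i]
                ).generate_state(1)[0]
                % 2**31
            )
            cell_cfg = replace(cfg, seed=cell_seed, n_replicates=design.n_replicates)
            set_id = f"{arm}_n{size}"
            try:
                models, median_model = train_replicates(
                    pairs, val_pool, cell_cfg, training_set_id=set_id
                )
            except Exception as exc:
                warnings.warn(f"cell {set_id} failed: {exc}", stacklevel=2)
                rows.append(
                    dict(size=size, arm=arm, replicate=0, best_val_dice=np.nan,
                         best_epoch=-1, n_epochs=0, n_stacks=len(pairs))
                )
                continue
            median_models[(size, arm)] = median_model
            for rep, model in enumerate(models):
                rows.append(
                    dict(
                        size=size, arm=arm, replicate=rep,
                        best_val_dice=model.best_val_dice,
                        best_epoch=model.best_epoch,
                        n_epochs=len(model.history),
                        n_stacks=len(pairs),
                    )
                )
    records = pd.DataFrame(rows)
    medians = (
        records.dropna(subset=["best_val_dice"])
        .groupby(["size", "arm"], as_index=False)["best_val_dice"]
        .median()
        .rename(columns={"best_val_dice": "median_dice"})
    )
    result = LearningCurveResult(
        records=records, median_per_cell=medians, median_models=median_models,
        test_pool=list(test_pool),
    )
    if len(design.sizes) >= 2 and len(design.arms) == 2:
        result.glm_fit = fit_dice_glm(result)
    result.min_specimens = minimum_specimens(result, design.accuracy_threshold)
    return result


def fit_dice_glm(result: LearningCurveResult) -> GLMFit:
    """Dice ~ logit-link GLM with quasibinomial variance.

    Predictors: log2(size), arm (augmented = 1), and their interaction.
    The dispersion parameter is estimated from the Pearson chi-square
    (this is what makes the binomial family "quasi").
    """
    rec = result.records.dropna(subset=["best_val_dice"])
    if rec["arm"].nunique() < 2:
        raise SpecificationError("fit_dice_glm needs both arms")
    if rec["size"].nunique() < 2:
        raise SpecificationError("fit_dice_glm needs at least 2 sizes")
    y = rec["best_val_dice"].to_numpy()
    X = pd.DataFrame(
        {
            "log2_size": np.log2(rec["size"].to_numpy(dtype=float)),
            "augmented": (rec["arm"] == "augmented").astype(float).to_numpy(),
        }
    )
    X["log2_size:augmented"] = X["log2_size"] * X["augmented"]
    X = sm.add_constant(X)
    if np.allclose(y, y[0]):
        zero = pd.Series(0.0, index=X.columns)
        logit = float(np.log(y[0] / (1 - y[0]))) if 0 < y[0] < 1 else 0.0
        zero["const"] = logit
        return GLMFit(params=zero, bse=pd.Series(np.nan, index=X.columns),
                      dispersion=0.0, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial endog
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
    return GLMFit(params=fit.params, bse=fit.bse, dispersion=float(fit.scale))


@dataclass
class EarlyStoppingReport:
    """Paired early-stop vs full-run Dice per training-set size."""

    table: pd.DataFrame  #: columns size, dice_early, dice_full
    r_squared: float
    f_stat: float
    f_pvalue: float
    identical: bool


def compare_early_stopping(
    train_pool: list[VolumePair],
    val_pool: list[VolumePair],
    cfg: TrainConfig,
    sizes: tuple[int, ...],
    design: ExperimentDesign | None = None,
) -> EarlyStoppingReport:
    """Train each size twice with identical seeds: early stopping as
    configured vs a full ``max_epochs`` run (patience disabled), and report
    the paired Dice values, their correlation R², and an F-test of the
    early→full regression."""
    if cfg.max_epochs <= cfg.patience_epochs:
        raise SpecificationError("max_epochs must exceed patience_epochs")
    design = design or ExperimentDesign(sizes=tuple(sizes), run_augmented_arm=False)
    sets = build_training_sets(train_pool, design)
    rows = []
    for size in sizes:
        full_cfg = replace(cfg, patience_epochs=cfg.max_epochs)
        early = train(sets[size], val_pool, cfg, training_set_id=f"early_n{size}")
        full = train(sets[size], val_pool, full_cfg, training_set_id=f"full_n{size}")
        rows.append(
            dict(size=size, dice_early=early.best_val_dice,
                 dice_full=full.best_val_dice,
                 best_epoch_early=early.best_epoch, best_epoch_full=full.best_epoch)
        )
    table = pd.DataFrame(rows)
    identical = bool(
        np.allclose(table["dice_early"], table["dice_full"], atol=0.0)
    )
    x = table["dice_early"].to_numpy()
    y = table["dice_full"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r2 = 1.0 if identical else np.nan
        f_stat, f_p = np.nan, np.nan
    else:
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        r2 = float(fit.rsquared)
        f_stat, f_p = float(fit.fvalue), float(fit.f_pvalue)
    return EarlyStoppingReport(
        table=table, r_squared=r2, f_stat=f_stat, f_pvalue=f_p, identical=identical
    )


@dataclass
class AgreementReport:
    """Per-group OLS of predicted on manual values, plus the pooled test for
    slope differences across groups."""

    per_group: pd.DataFrame  #: group, slope, intercept, r_squared, n, flagged
    interaction_f: float
    interaction_p: float


def agreement_regression(
    manual: np.ndarray, predicted: np.ndarray, grouping: np.ndarray
) -> AgreementReport:
    """OLS of predicted on manual within each training-set group.

    Groups with constant manual values are flagged with undefined R².  The
    pooled model tests whether slopes differ across groups (interaction
    F-test against the common-slope model).
    """
    manual = np.asarray(manual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    grouping = np.asarray(grouping)
    if not (len(manual) == len(predicted) == len(grouping)):
        raise SpecificationError("manual, predicted and grouping lengths differ")
    rows = []
    for g in pd.unique(grouping):
        m = manual[grouping == g]
        p = predicted[grouping == g]
        if len(m) < 3:
            raise SpecificationError(f"group {g!r} has fewer than 3 points")
        if np.ptp(m) == 0:
            rows.append(dict(group=g, slope=np.nan, intercept=np.nan,
                             r_squared=np.nan, n=len(m), flagged=True))
            continue
        fit = sm.OLS(p, sm.add_constant(m)).fit()
        rows.append(
            dict(group=g, slope=float(fit.params[1]), intercept=float(fit.params[0]),
                 r_squared=float(fit.rsquared), n=len(m), flagged=False)
        )
    per_group = pd.DataFrame(rows)

    df = pd.DataFrame({"manual": manual, "predicted": predicted, "group": grouping})
    if df["group"].nunique() > 1 and np.ptp(manual) > 0:
        import statsmodels.formula.api as smf

        full = smf.ols("predicted ~ manual * C(group)", data=df).fit()
        reduced = smf.ols("predicted ~ manual + C(group)", data=df).fit()
        ftest = full.compare_f_test(reduced)
        interaction_f, interaction_p = float(ftest[0]), float(ftest[1])
    else:
        interaction_f = interaction_p = np.nan
    return AgreementReport(
        per_group=per_group, interaction_f=interaction_f, interaction_p=interaction_p
    )


def minimum_specimens(
    result: LearningCurveResult, threshold: float
) -> dict[str, int | None]:
    """Smallest size whose median Dice reaches the threshold, per arm."""
    out: dict[str, int | None] = {}
    for arm in result.median_per_cell["arm"].unique():
        cell = result.median_per_cell[result.median_per_cell["arm"] == arm]
        hits = cell[cell["median_dice"] >= threshold]["size"]
        out[str(arm)] = int(hits.min()) if len(hits) else None
    return out


def evaluate_traits(
    result: LearningCurveResult, test_pool: list[VolumePair] | None = None
) -> pd.DataFrame:
    """Volumetric traits of manual vs median-network segmentations of the
    test pool, one row per (size, arm, specimen)."""
    test_pool = test_pool if test_pool is not None else result.test_pool
    rows = []
    for (size, arm), model in result.median_models.items():
        for pair in test_pool:
            pred = predict(model, pair.grey)
            man = volumetric_traits(pair.labels, pair.voxel_size_um)
            net = volumetric_traits(pred, pair.voxel_size_um)
            rows.append(
                dict(
                    size=size, arm=arm, specimen_id=pair.specimen_id,
                    dice=dice(pred, pair.labels),
                    manual_total=man.total_volume_um3,
                    predicted_total=net.total_volume_um3,
                    manual_external=man.external_volume_um3,
                    predicted_external=net.external_volume_um3,
                    manual_internal=man.internal_volume_um3,
                    predicted_internal=net.internal_volume_um3,
                    manual_calcite=man.percentage_calcite,
                    predicted_calcite=net.percentage_calcite,
                )
            )
    return pd.DataFrame(rows)


def trait_agreement_by_cell(traits: pd.DataFrame) -> pd.DataFrame:
    """R² of predicted vs manual per (size, arm) for the external-volume and
    percentage-calcite traits; rows with undefined calcite are dropped (and
    counted)."""
    rows = []
    for (size, arm), cell in traits.groupby(["size", "arm"]):
        def r2(x, y):
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0:
                return np.nan, int(ok.sum())
            fit = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
            return float(fit.rsquared), int(ok.sum())

        ext_r2, n_ext = r2(cell["manual_external"], cell["predicted_external"])
        cal_r2, n_cal = r2(
            cell["manual_calcite"].astype(float), cell["predicted_calcite"].astype(float)
        )
        rows.append(
            dict(size=size, arm=arm, external_r2=ext_r2, calcite_r2=cal_r2,
                 n_external=n_ext, n_calcite=n_cal)
        )
    return pd.DataFrame(rows)
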