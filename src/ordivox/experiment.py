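"""The full experimental protocol: hold-out, CV fraction search, the
augmentation study and its non-parametric statistical comparison.

The protocol mirrors a three-stage study design:

1. A stratified 70-30 hold-out (per class, ``floor(0.7 * N_l)`` patterns to
   training).
2. A 5-fold cross-validation over the training set comparing ReliefF,
   ordinal ReliefF and no selection across a grid of retained-voxel
   fractions, scored by mean CCR and mean MMAE; the operating point
   minimises mean MMAE (ties: higher CCR, then smaller fraction).
3. With the selected voxels fixed, an augmentation study: each configuration
   (CONF0..CONF5, RAND) is applied to the training set, the classifier
   refitted, and the untouched test set scored; stochastic configurations
   are repeated (default 30 times) and compared with a Kolmogorov-Smirnov
   normality check, a Kruskal-Wallis omnibus test with average ranks, and a
   Mann-Whitney post-hoc between the two best-ranked configurations.

Feature selection and distribution fitting always run inside the training
portion of each split; the test set is only ever scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ordivox.augmentation import (
    AugmentationPlan,
    VoxelDistributionFit,
    apply_configuration,
    fit_voxel_distributions,
)
from ordivox.feature_selection import orelieff, relieff, select_top_fraction
from ordivox.model import OrdinalLogit, OrdinalMetrics
from ordivox.volumes import OrdinalDataset

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "stratified_holdout",
    "cv_fraction_grid",
    "select_operating_point",
    "run_augmentation_study",
    "compare_configurations",
    "relative_mmae_reduction",
    "run_experiment",
]

DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.50, 0.75)


@dataclass
class ExperimentConfig:
    """Knobs of the full protocol with the study defaults."""

    holdout_fraction: float = 0.7
    cv_folds: int = 5
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    k: int = 5
    m: int | None = None  # (O)ReliefF iterations; None -> number of patterns
    repetitions: int = 30
    penalty: float = 1.0
    macrovoxel_width: int = 3
    noise_sd: float = 0.01
    configurations: tuple[str, ...] = (
        "CONF0",
        "CONF1",
        "CONF2",
        "CONF3",
        "CONF4",
        "CONF5",
        "RAND",
    )

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.repetitions < 1:
            raise ValueError("need at least 1 repetition")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")


@dataclass
class ComparisonReport:
    """Non-parametric comparison of configurations on one metric."""

    metric: str
    summary: pd.DataFrame  # per config: n, mean, sd
    normality_pvalues: dict[str, float]
    kw_statistic: float
    kw_pvalue: float
    average_ranks: dict[str, float]
    best_pair: tuple[str, str]
    mw_pvalue: float


def stratified_holdout(
    labels: np.ndarray, fraction: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class ``floor(fraction * N_l)`` patterns to training, rest to test.

    Returns sorted (train indices, test indices); a partition of all indices,
    deterministic given the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for l in np.unique(labels):
        idx = np.flatnonzero(labels == l)
        if idx.size < 2:
            warnings.warn(f"class {l} has fewer than 2 patterns", stacklevel=2)
        # floor of the exact product: guard against 0.7 * 90 = 62.999...
        n_train = int(np.floor(fraction * idx.size + 1e-9))
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _fit_score(
    train: OrdinalDataset, test: OrdinalDataset, penalty: float
) -> OrdinalMetrics:
    results = OrdinalLogit.from_dataset(train, penalty=penalty).fit()
    return results.evaluate(test.X, test.y)


def cv_fraction_grid(
    train: OrdinalDataset,
    config: ExperimentConfig,
    seed: int | None = None,
    methods: tuple[str, ...] = ("relieff", "orelieff", "none"),
) -> pd.DataFrame:
    """Cross-validated CCR/MMAE for every (method, fraction) cell.

    Selection is re-run inside each fold on fold-training data only (no
    leakage); ``"none"`` ignores the fraction grid and keeps every feature.
    Returns a tidy frame with columns ``method, fraction, mean_ccr,
    mean_mmae``.
    """
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    splitter = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=fold_seed
    )
    folds = list(splitter.split(train.X, train.y))
    selector = {"relieff": relieff, "orelieff": orelieff}

    rows = []
    for method in methods:
        if method == "none":
            scores = []
            for tr, te in folds:
                scores.append(
                    _fit_score(train.subset(tr), train.subset(te), config.penalty)
                )
            rows.append(
                {
                    "method": "none",
                    "fraction": 1.0,
                    "mean_ccr": float(np.mean([s.ccr for s in scores])),
                    "mean_mmae": float(np.mean([s.mmae for s in scores])),
                }
            )
            continue
        # rank once per fold, then sweep the fraction grid over that ranking
        per_fold = []
        for tr, te in folds:
            fold_train = train.subset(tr)
            quality = selector[method](
                fold_train,
                k=config.k,
                m=config.m,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            per_fold.append((fold_train, train.subset(te), quality))
        for p in config.fractions:
            scores = []
            for fold_train, fold_test, quality in per_fold:
                cols = select_top_fraction(quality, p)
                if cols.size == 0:
                    warnings.warn(
                        f"fraction {p} keeps 0 of {quality.n_features} features; skipped",
                        stacklevel=2,
                    )
                    break
                scores.append(
                    _fit_score(
                        fold_train.select_features(cols),
                        fold_test.select_features(cols),
                        config.penalty,
                    )
                )
            else:
                rows.append(
                    {
                        "method": method,
                        "fraction": p,
                        "mean_ccr": float(np.mean([s.ccr for s in scores])),
                        "mean_mmae": float(np.mean([s.mmae for s in scores])),
                    }
                )
    return pd.DataFrame(rows)


def select_operating_point(table: pd.DataFrame) -> tuple[str, float]:
    """Row minimising mean MMAE; ties broken by higher CCR, then smaller fraction."""
    if table.empty:
        raise ValueError("validation table is empty")
    ordered = table.sort_values(
        ["mean_mmae", "mean_ccr", "fraction"], ascending=[True, False, True]
    )
    best = ordered.iloc[0]
    return str(best["method"]), float(best["fraction"])


def run_augmentation_study(
    train: OrdinalDataset,
    test: OrdinalDataset,
    configs: tuple[str, ...],
    repetitions: int,
    seed: int | None = None,
    fits: dict[tuple[int, int], VoxelDistributionFit] | None = None,
    penalty: float = 1.0,
    noise_sd: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Score every configuration on the untouched test set.

    CONF0 is deterministic and runs once; every other configuration runs
    ``repetitions`` times with distinct derived seeds (the per-voxel fits are
    estimated once from the training set; repetitions vary only the sampling
    seed).  Returns, per configuration, a frame of (ccr, mmae) rows.
    """
    rng = np.random.default_rng(seed)
    needs_fits = [c for c in configs if c not in ("CONF0", "RAND")]
    if needs_fits and fits is None:
        raise ValueError(f"configurations {needs_fits} require per-voxel fits")
    out: dict[str, pd.DataFrame] = {}
    for config in configs:
        reps = 1 if config == "CONF0" else repetitions
        records = []
        for _ in range(reps):
            plan = AugmentationPlan(
                config=config, seed=int(rng.integers(0, 2**31 - 1))
            )
            augmented = apply_configuration(train, plan, fits=fits, noise_sd=noise_sd)
            metrics = _fit_score(augmented, test, penalty)
            records.append({"ccr": metrics.ccr, "mmae": metrics.mmae})
        out[config] = pd.DataFrame(records)
    return out


def _average_ranks(samples: dict[str, np.ndarray], lower_is_better: bool) -> dict[str, float]:
    names = list(samples)
    values = np.concatenate([samples[n] for n in names])
    ranked = stats.rankdata(values if lower_is_better else -values)
    ranks: dict[str, float] = {}
    start = 0
    for n in names:
        size = samples[n].size
        ranks[n] = float(ranked[start : start + size].mean())
        start += size
    return ranks


def compare_configurations(
    results: dict[str, pd.DataFrame | np.ndarray],
    metric: str = "mmae",
    lower_is_better: bool | None = None,
) -> ComparisonReport:
    """Non-parametric comparison of per-configuration result samples.

    Per sample: a one-sample Kolmogorov-Smirnov check against a normal with
    the sample's mean and sd.  Across samples: Kruskal-Wallis with average
    ranks (joint ranking of all values; lower rank = better).  Post hoc: a
    Mann-Whitney test between the two best-ranked configurations.
    Deterministic configurations represented by a single repetition are
    excluded from the tests (but kept in the summary).
    """
    if lower_is_better is None:
        lower_is_better = metric != "ccr"
    samples: dict[str, np.ndarray] = {}
    summary_rows = []
    for name, res in results.items():
        x = res[metric].to_numpy() if isinstance(res, pd.DataFrame) else np.asarray(res, dtype=float)
        summary_rows.append(
            {
                "configuration": name,
                "n": x.size,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            }
        )
        if x.size >= 2:
            samples[name] = x
    if len(samples) < 2:
        raise ValueError("need at least 2 configurations with >= 2 repetitions")

    normality = {}
    for name, x in samples.items():
        sd = x.std(ddof=1)
        if sd == 0:
            normality[name] = 0.0  # a point mass is certainly not normal
        else:
            normality[name] = float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)

    groups = list(samples.values())
    if np.ptp(np.concatenate(groups)) == 0:
        kw_stat, kw_p = 0.0, 1.0  # all values tied: no evidence of difference
    else:
        kw_stat, kw_p = stats.kruskal(*groups)
    ranks = _average_ranks(samples, lower_is_better)
    best = sorted(ranks, key=ranks.get)[:2]
    a, b = samples[best[0]], samples[best[1]]
    if np.ptp(np.concatenate([a, b])) == 0:
        mw_p = 1.0
    else:
        mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ComparisonReport(
        metric=metric,
        summary=pd.DataFrame(summary_rows),
        normality_pvalues=normality,
        kw_statistic=float(kw_stat),
        kw_pvalue=float(kw_p),
        average_ranks=ranks,
        best_pair=(best[0], best[1]),
        mw_pvalue=mw_p,
    )


def relative_mmae_reduction(mmae_baseline: float, mmae_augmented: float) -> float:
    """Relative MMAE improvement of augmentation over baseline, in percent."""
    if mmae_baseline <= 0:
        raise ValueError("baseline MMAE must be positive")
    return 100.0 * (mmae_baseline - mmae_augmented) / mmae_baseline


def run_experiment(
    dataset: OrdinalDataset,
    config: ExperimentConfig | None = None,
    seed: int | None = None,
    methods: tuple[str, ...] = ("relieff", "orelieff", "none"),
) -> dict:
    """The full three-stage protocol under one master seed.

    A master seed spawns per-stage seeds (split, CV/selection, fitting,
    augmentation sampling), so identical master seeds reproduce the full
    report bit-for-bit.  Returns a dict with the validation table, the chosen
    operating point, the augmentation study frames and the comparison
    reports for MMAE and CCR.
    """
    config = config or ExperimentConfig()
    master = np.random.default_rng(seed)
    split_seed, cv_seed, sel_seed, study_seed = (
        int(s) for s in master.integers(0, 2**31 - 1, size=4)
    )

    train_idx, test_idx = stratified_holdout(
        dataset.y, config.holdout_fraction, seed=split_seed
    )
    train, test = dataset.subset(train_idx), dataset.subset(test_idx)

    table = cv_fraction_grid(train, config, seed=cv_seed, methods=methods)
    method, fraction = select_operating_point(table)

    if method == "none":
        informative = train.feature_indices.copy()
        train_red, test_red = train, test
    else:
        selector = relieff if method == "relieff" else orelieff
        quality = selector(train, k=config.k, m=config.m, seed=sel_seed)
        cols = select_top_fraction(quality, fraction)
        informative = train.feature_indices[cols]
        train_red = train.select_features(cols)
        test_red = test.select_features(cols)

    needs_fits = any(
        c not in ("CONF0", "RAND") for c in config.configurations
    )
    fits = (
        fit_voxel_distributions(
            train_red,
            informative,
            w=config.macrovoxel_width,
            classes=sorted(
                {
                    l
                    for c in config.configurations
                    if c not in ("CONF0", "RAND")
                    for l in AugmentationPlan(config=c).classes_to_augment()
                }
            ),
        )
        if needs_fits
        else None
    )
    study = run_augmentation_study(
        train_red,
        test_red,
        config.configurations,
        config.repetitions,
        seed=study_seed,
        fits=fits,
        penalty=config.penalty,
        noise_sd=config.noise_sd,
    )
    return {
        "validation_table": table,
        "operating_point": (method, fraction),
        "informative_voxels": informative,
        "study": study,
        "comparison_mmae": compare_configurations(study, "mmae"),
        "comparison_ccr": compare_configurations(study, "ccr"),
    }
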