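"""Macrovoxel distribution-fitting data augmentation and baselines.

The generative idea: for every informative voxel, pool the values of its
*macrovoxel* (the width-``w`` cube centred on it, intersected with the
informative set and clipped at volume borders) across all training images of
one class.  The pooled sample is fitted by four candidate location–scale
families — alpha, generalised extreme value, Student's t and beta — by
maximum likelihood, and the family with the smallest sum of squared errors
between its density and the density-normalised histogram is kept.  A new
synthetic image of that class then draws one value per informative voxel,
independently, from the selected per-voxel distribution; independence across
voxels is the stated generative assumption.

Heavy-tailed families can emit implausible intensities, so sampling is
truncated to the pooled empirical range by bounded rejection (redraw up to
100 rounds, then clamp): voxel intensities are bounded physical measurements.

The module also provides the classical *noisy replication* baseline
(duplicate minority patterns plus N(0, sd) noise) and the study
configurations CONF0..CONF5 / RAND describing which classes are replicated
and by how much.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ordivox.volumes import OrdinalDataset, linear_index

__all__ = [
    "FAMILIES",
    "CONFIGURATIONS",
    "MacrovoxelSpec",
    "VoxelDistributionFit",
    "AugmentationPlan",
    "macrovoxel_indices",
    "pool_class_samples",
    "evaluate_pdf",
    "fit_family",
    "select_best_family",
    "fit_voxel_distributions",
    "generate_synthetic",
    "noisy_replication",
    "apply_configuration",
]

#: candidate families in fixed tie-break order
FAMILIES: tuple[str, ...] = ("alpha", "genextreme", "t_student", "beta")

_SCIPY_DIST = {
    "alpha": stats.alpha,
    "genextreme": stats.genextreme,
    "t_student": stats.t,
    "beta": stats.beta,
}

#: per-class replication factors of the study configurations (classes 0,1,2);
#: RAND is noisy replication (factor 3 on class 1), the rest use the
#: macrovoxel distribution sampler.
CONFIGURATIONS: dict[str, tuple[int, int, int]] = {
    "CONF0": (1, 1, 1),
    "CONF1": (2, 2, 2),
    "CONF2": (1, 2, 2),
    "CONF3": (1, 2, 1),
    "CONF4": (1, 1, 2),
    "CONF5": (1, 3, 1),
    "RAND": (1, 3, 1),
}


@dataclass(frozen=True)
class MacrovoxelSpec:
    """A width-``w`` cube of voxels centred on an informative voxel.

    ``member_indices`` are flattened feature indices, restricted to the
    informative set and truncated at volume borders.
    """

    center: tuple[int, int, int]
    width: int
    member_indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "member_indices", np.asarray(self.member_indices, dtype=int)
        )


@dataclass(frozen=True)
class VoxelDistributionFit:
    """A fitted per-voxel, per-class distribution.

    ``params`` holds the family's shape parameters followed by location
    ``mu`` and scale ``sigma`` (the scipy convention); ``sse`` is the sum of
    squared differences between the fitted density and the density-normalised
    histogram at bin centers; ``support`` is the empirical (min, max) of the
    pooled sample, enforced at sampling time.
    """

    family: str
    params: tuple[float, ...]
    sse: float
    support: tuple[float, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        loc, scale = self.params[-2], self.params[-1]
        if not scale > 0:
            raise ValueError("scale must be positive")
        shapes = self.params[:-2]
        if self.family == "beta" and not (shapes[0] > 0 and shapes[1] > 0):
            raise ValueError("beta requires a > 0 and b > 0")
        if self.family == "t_student" and not shapes[0] > 0:
            raise ValueError("t requires nu > 0")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")

    def frozen(self):
        """The corresponding frozen scipy distribution."""
        return _SCIPY_DIST[self.family](*self.params)

    @property
    def converged(self) -> bool:
        return np.isfinite(self.sse)


@dataclass(frozen=True)
class AugmentationPlan:
    """One study configuration: per-class replication factors plus a seed."""

    config: str
    seed: int | None = None
    factors: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.config not in CONFIGURATIONS:
            raise ValueError(
                f"unknown configuration {self.config!r}; "
                f"expected one of {sorted(CONFIGURATIONS)}"
            )
        if self.factors is None:
            object.__setattr__(self, "factors", CONFIGURATIONS[self.config])

    @property
    def uses_synthetic(self) -> bool:
        return self.config not in ("CONF0", "RAND")

    def classes_to_augment(self) -> list[int]:
        return [l for l, f in enumerate(self.factors) if f > 1]


def macrovoxel_indices(
    center: tuple[int, int, int],
    w: int,
    dims: tuple[int, int, int],
    informative: np.ndarray | set[int] | None = None,
) -> MacrovoxelSpec:
    """Feature indices of the width-``w`` cube centred on ``center``.

    All coordinates within Chebyshev radius ``(w-1)/2`` of the center,
    clipped to the volume and intersected with the informative set
    (``None`` means every voxel is informative).
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("macrovoxel width must be an odd positive integer")
    R, C, Z = (int(v) for v in dims)
    r0, c0, z0 = (int(v) for v in center)
    if not (0 <= r0 < R and 0 <= c0 < C and 0 <= z0 < Z):
        raise IndexError(f"center {center} out of bounds for dims {dims}")
    h = (w - 1) // 2
    members = [
        linear_index((r, c, z), dims)
        for z in range(max(0, z0 - h), min(Z, z0 + h + 1))
        for r in range(max(0, r0 - h), min(R, r0 + h + 1))
        for c in range(max(0, c0 - h), min(C, c0 + h + 1))
    ]
    if informative is not None:
        keep = set(int(i) for i in np.asarray(list(informative)).ravel())
        members = [i for i in members if i in keep]
    return MacrovoxelSpec(center=(r0, c0, z0), width=w, member_indices=np.array(members))


def pool_class_samples(
    dataset: OrdinalDataset, spec: MacrovoxelSpec, l: int
) -> np.ndarray:
    """Concatenate the macrovoxel's values over all class-``l`` patterns."""
    rows = np.flatnonzero(dataset.y == l)
    if rows.size == 0:
        raise ValueError(f"class {l} has no patterns to pool")
    cols = np.array([dataset.column_of(i) for i in spec.member_indices])
    if cols.size == 0:
        raise ValueError("macrovoxel has no informative members")
    return dataset.X[np.ix_(rows, cols)].ravel()


def evaluate_pdf(family: str, params: tuple[float, ...], z: np.ndarray | float) -> np.ndarray | float:
    """Closed-form density of one candidate family at ``z``.

    ``params`` are the shape parameters followed by location ``mu`` and scale
    ``sigma``; all densities are of the standardised variable
    ``x = (z - mu)/sigma`` with the 1/sigma Jacobian.  Outside a family's
    support the density is 0.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    *shapes, mu, sigma = params
    if sigma <= 0:
        raise ValueError("scale must be positive")
    x = (z - mu) / sigma
    out = np.zeros_like(x)

    if family == "alpha":
        (a,) = shapes
        sup = x > 0
        xs = x[sup]
        norm_cdf = stats.norm.cdf(a)
        out[sup] = (
            1.0 / (xs**2 * norm_cdf * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * (a - 1.0 / xs) ** 2)
        )
    elif family == "genextreme":
        (xi,) = shapes
        if xi == 0:
            out[:] = np.exp(-np.exp(-x)) * np.exp(-x)
        else:
            t = 1.0 - xi * x
            sup = t > 0
            out[sup] = np.exp(-t[sup] ** (1.0 / xi)) * t[sup] ** (1.0 / xi - 1.0)
    elif family == "t_student":
        (nu,) = shapes
        if nu <= 0:
            raise ValueError("t requires nu > 0")
        from scipy.special import gammaln

        lognorm = gammaln((nu + 1) / 2) - gammaln(nu / 2) - 0.5 * np.log(np.pi * nu)
        out[:] = np.exp(lognorm) * (1 + x**2 / nu) ** (-(nu + 1) / 2)
    elif family == "beta":
        a, b = shapes
        if a <= 0 or b <= 0:
            raise ValueError("beta requires a > 0 and b > 0")
        from scipy.special import gammaln

        sup = (x > 0) & (x < 1)
        xs = x[sup]
        lognorm = gammaln(a + b) - gammaln(a) - gammaln(b)
        out[sup] = np.exp(lognorm) * xs ** (a - 1) * (1 - xs) ** (b - 1)

    out = out / sigma
    return float(out[0]) if scalar else out


def _histogram(z: np.ndarray, bins: int | None) -> tuple[np.ndarray, np.ndarray]:
    if bins is None:
        bins = max(10, int(np.floor(np.sqrt(z.size))))
    density, edges = np.histogram(z, bins=bins, range=(z.min(), z.max()), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return density, centers


def fit_family(
    z: np.ndarray, family: str, bins: int | None = None
) -> VoxelDistributionFit:
    """Fit one family to a pooled sample by maximum likelihood.

    The SSE between the fitted density and the density-normalised histogram
    (default ``max(10, floor(sqrt(|z|)))`` bins spanning the sample range) is
    recorded for family selection; a non-converged fit carries infinite SSE
    and is thereby excluded.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size < 8:
        raise ValueError("need at least 8 values to fit a distribution")
    if np.ptp(z) == 0:
        raise ValueError("degenerate (constant) sample")
    dist = _SCIPY_DIST[family]
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            if family == "beta":
                # anchor the support just outside the sample range
                span = np.ptp(z)
                params = dist.fit(
                    z, floc=z.min() - 1e-6 * span, fscale=span * (1 + 2e-6)
                )
            else:
                params = dist.fit(z)
        density, centers = _histogram(z, bins)
        with np.errstate(all="ignore"):
            fitted = dist.pdf(centers, *params)
        if not np.all(np.isfinite(fitted)):
            sse = np.inf
        else:
            sse = float(np.sum((fitted - density) ** 2))
    except Exception:
        params = (1.0,) * dist.numargs + (0.0, 1.0)
        sse = np.inf
    if not np.isfinite(sse):
        sse = np.inf
    return VoxelDistributionFit(
        family=family,
        params=tuple(float(p) for p in params),
        sse=sse,
        support=(float(z.min()), float(z.max())),
    )


def select_best_family(z: np.ndarray, bins: int | None = None) -> VoxelDistributionFit:
    """Fit all four families and return the minimum-SSE fit.

    Ties break in the fixed order alpha, GEV, t, beta.
    """
    fits = [fit_family(z, fam, bins=bins) for fam in FAMILIES]
    best = min(fits, key=lambda f: f.sse)
    if not np.isfinite(best.sse):
        raise ValueError("all candidate family fits are degenerate")
    return best


def fit_voxel_distributions(
    dataset: OrdinalDataset,
    informative: np.ndarray,
    w: int = 3,
    classes: list[int] | None = None,
    bins: int | None = None,
) -> dict[tuple[int, int], VoxelDistributionFit]:
    """Best-family fits for every (informative voxel, class) pair.

    ``informative`` holds original (flattened-volume) feature indices;
    ``dataset.dims`` must be set so macrovoxel geometry is available.
    Returns a mapping ``(feature index, class) -> fit``.
    """
    if dataset.dims is None:
        raise ValueError("dataset must carry volume dims for macrovoxel geometry")
    informative = np.asarray(informative, dtype=int)
    if classes is None:
        classes = list(range(dataset.L))
    R, C, Z = dataset.dims
    keep = set(int(i) for i in informative)
    # column lookup once, not per macrovoxel
    col_of = {int(fi): j for j, fi in enumerate(dataset.feature_indices)}
    class_rows = {l: np.flatnonzero(dataset.y == l) for l in classes}
    fits: dict[tuple[int, int], VoxelDistributionFit] = {}
    for fi in informative:
        layer, rem = divmod(int(fi), R * C)
        row, col = divmod(rem, C)
        spec = macrovoxel_indices((row, col, layer), w, dataset.dims, keep)
        cols = np.array([col_of[int(i)] for i in spec.member_indices])
        for l in classes:
            z = dataset.X[np.ix_(class_rows[l], cols)].ravel()
            fits[(int(fi), l)] = select_best_family(z, bins=bins)
    return fits


def generate_synthetic(
    dataset: OrdinalDataset,
    fits: dict[tuple[int, int], VoxelDistributionFit],
    l: int,
    count: int,
    seed: int | np.random.Generator | None = None,
    max_rejection_rounds: int = 100,
) -> OrdinalDataset:
    """Draw ``count`` new class-``l`` patterns over the informative voxels.

    Each pattern draws one value per voxel, independently, from that voxel's
    class-``l`` fitted distribution; draws outside the fit's empirical
    [min, max] are redrawn (bounded rejection) and clamped after
    ``max_rejection_rounds`` attempts.  The returned dataset lives in the
    same (reduced) feature space as ``dataset``.
    """
    if count <= 0:
        raise ValueError("count must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = dataset.n_features
    X = np.empty((count, S))
    for j, fi in enumerate(dataset.feature_indices):
        key = (int(fi), int(l))
        if key not in fits:
            raise ValueError(f"no fitted distribution for voxel {fi}, class {l}")
        fit = fits[key]
        frozen = fit.frozen()
        lo, hi = fit.support
        draws = np.asarray(frozen.rvs(size=count, random_state=rng), dtype=float)
        bad = (draws < lo) | (draws > hi) | ~np.isfinite(draws)
        rounds = 0
        while bad.any() and rounds < max_rejection_rounds:
            draws[bad] = frozen.rvs(size=int(bad.sum()), random_state=rng)
            bad = (draws < lo) | (draws > hi) | ~np.isfinite(draws)
            rounds += 1
        np.clip(draws, lo, hi, out=draws)
        X[:, j] = draws
    return OrdinalDataset(
        X=X,
        y=np.full(count, l, dtype=int),
        L=dataset.L,
        dims=dataset.dims,
        feature_indices=dataset.feature_indices.copy(),
    )


def noisy_replication(
    dataset: OrdinalDataset,
    l: int,
    factor: int,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator | None = None,
) -> OrdinalDataset:
    """Noisy-replication oversampling baseline.

    Adds ``(factor - 1) * N_l`` patterns: sources drawn uniformly with
    replacement from class ``l``, each feature perturbed by independent
    N(0, noise_sd) noise.
    """
    if factor < 2:
        raise ValueError("replication factor must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rows = np.flatnonzero(dataset.y == l)
    if rows.size == 0:
        raise ValueError(f"class {l} has no patterns to replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_new = (factor - 1) * rows.size
    sources = rng.choice(rows, size=n_new, replace=True)
    X = dataset.X[sources] + rng.normal(0.0, noise_sd, size=(n_new, dataset.n_features))
    return OrdinalDataset(
        X=X,
        y=np.full(n_new, l, dtype=int),
        L=dataset.L,
        dims=dataset.dims,
        feature_indices=dataset.feature_indices.copy(),
    )


def _concat(base: OrdinalDataset, extras: list[OrdinalDataset]) -> OrdinalDataset:
    X = np.vstack([base.X] + [e.X for e in extras])
    y = np.concatenate([base.y] + [e.y for e in extras])
    return OrdinalDataset(
        X=X, y=y, L=base.L, dims=base.dims, feature_indices=base.feature_indices.copy()
    )


def apply_configuration(
    train: OrdinalDataset,
    plan: AugmentationPlan,
    fits: dict[tuple[int, int], VoxelDistributionFit] | None = None,
    noise_sd: float = 0.01,
) -> OrdinalDataset:
    """Apply one study configuration to a (reduced) training set.

    CONF0 returns the input unchanged; CONF1..CONF5 add synthetic patterns
    from the per-voxel fits per the plan's replication factors; RAND adds
    noisy replication with factor 3 on class 1.  Original patterns are never
    modified or removed.
    """
    if plan.config == "CONF0":
        return train
    counts = train.class_counts()
    if plan.config == "RAND":
        return _concat(
            train, [noisy_replication(train, 1, 3, noise_sd=noise_sd, seed=plan.seed)]
        )
    if fits is None:
        raise ValueError(f"configuration {plan.config} requires per-voxel fits")
    rng = np.random.default_rng(plan.seed)
    extras = []
    for l in plan.classes_to_augment():
        n_new = (plan.factors[l] - 1) * int(counts[l])
        extras.append(generate_synthetic(train, fits, l, n_new, seed=rng))
    return _concat(train, extras)
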