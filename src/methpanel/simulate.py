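"""Synthetic cohorts matched to published distributional summaries.

No per-sample data accompany the reference study, but its per-gene,
per-class five-number summaries are published.  Each gene/class is modeled
by the piecewise-linear quantile function through

    (0, min), (0.25, q25), (0.5, median), (0.75, q75), (1, max)

and sampled by inverse transform — this reproduces the printed quartiles
exactly by construction (including point masses where adjacent quantiles
coincide) and confines every draw to the printed [min, max] support.  Genes
are sampled independently within a class; real tumors are almost certainly
correlated across markers, which would only sharpen CMI class separation,
so independence is the conservative minimal assumption.

The module also provides a low-background plasma regime (cell-free DNA has
near-zero methylation in normal plasma), block-structured beta matrices for
the clustering prescreen, and the randomized age-balanced train/test split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CARCINOMA,
    MSI,
    MSI_UNKNOWN,
    MSS,
    NORMAL,
    MethylationMatrix,
    ValidationError,
)
from .clustering import BetaMatrix
from .reference import load_reference_markers
from .stats import FiveNumberSummary

logger = logging.getLogger("methpanel")

_KNOTS_U = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


# Quantile-function sampling --------------------------------------------------


@dataclass(frozen=True)
class QuantileSpec:
    """Piecewise-linear quantile function through a five-number summary."""

    gene: str
    class_label: str
    summary: FiveNumberSummary

    def quantile(self, u: np.ndarray | float) -> np.ndarray | float:
        return np.interp(u, _KNOTS_U, np.asarray(self.summary.as_tuple()))


def fit_quantile_function(
    summary: FiveNumberSummary,
    gene: str | None = None,
    class_label: str | None = None,
) -> QuantileSpec:
    """Build the interpolating quantile spec (monotonicity is enforced by
    FiveNumberSummary itself)."""
    return QuantileSpec(
        gene=gene or summary.gene or "?",
        class_label=class_label or summary.class_label or "?",
        summary=summary,
    )


def sample_gene(spec: QuantileSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-transform sample n %M values from the spec's distribution."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return np.asarray(spec.quantile(rng.random(n)), dtype=float)


# Tissue cohorts --------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic tissue cohort.

    Defaults mirror the reference training cohort: 30 carcinomas and 23
    adjacent normals, a third of carcinomas microsatellite-unstable, ages
    roughly Normal(69, 8) (carcinoma) / Normal(66, 8) (normal) truncated to
    [40, 95] years.
    """

    gene_specs: dict[str, tuple[QuantileSpec, QuantileSpec]]  # (carcinoma, normal)
    n_carcinoma: int = 30
    n_normal: int = 23
    msi_fraction: float = 1.0 / 3.0
    msi_shift: dict[str, float] = field(default_factory=dict)  # %M added in MSI
    age_mean_carcinoma: float = 69.0
    age_mean_normal: float = 66.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 95.0)
    #: quantization step of reported %M (the reference summaries are integer
    #: %M, so 1.0 emulates the assay's reporting precision; None disables).
    #: Quantized values are clipped back to the spec's [min, max] support.
    round_to: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_carcinoma < 1 or self.n_normal < 1:
            raise ValidationError("cohort sizes must be >= 1")
        if not 0.0 <= self.msi_fraction <= 1.0:
            raise ValidationError("msi_fraction must be in [0, 1]")


def default_tissue_spec(seed: int = 0, **overrides) -> CohortSpec:
    """CohortSpec parameterized by the packaged 13-gene reference summaries."""
    specs = {
        gene: (
            fit_quantile_function(ref.carcinoma, gene, CARCINOMA),
            fit_quantile_function(ref.normal, gene, NORMAL),
        )
        for gene, ref in load_reference_markers().items()
    }
    return CohortSpec(gene_specs=specs, seed=seed, **overrides)


def _quantize(
    x: np.ndarray, summary: FiveNumberSummary, step: float | None
) -> np.ndarray:
    if step is None:
        return x
    return np.clip(np.round(x / step) * step, summary.minimum, summary.maximum)


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float,
    lo: float, hi: float,
) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def generate_tissue_cohort(spec: CohortSpec) -> MethylationMatrix:
    """Sample a labeled %M matrix from a CohortSpec (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_specs)
    n_ca, n_no = spec.n_carcinoma, spec.n_normal
    sample_ids = [f"ca_{i + 1:03d}" for i in range(n_ca)] + [
        f"no_{i + 1:03d}" for i in range(n_no)
    ]
    values = np.empty((n_ca + n_no, len(genes)))
    for j, gene in enumerate(genes):
        ca_spec, no_spec = spec.gene_specs[gene]
        values[:n_ca, j] = _quantize(sample_gene(ca_spec, n_ca, rng),
                                     ca_spec.summary, spec.round_to)
        values[n_ca:, j] = _quantize(sample_gene(no_spec, n_no, rng),
                                     no_spec.summary, spec.round_to)

    classes = pd.Series(
        [CARCINOMA] * n_ca + [NORMAL] * n_no, index=sample_ids, name="class"
    )

    # MSI labels on carcinomas only (deterministic count, randomized placement)
    n_msi = round(spec.msi_fraction * n_ca)
    msi = np.array([MSI_UNKNOWN] * (n_ca + n_no), dtype=object)
    ca_order = rng.permutation(n_ca)
    msi[ca_order[:n_msi]] = MSI
    msi[ca_order[n_msi:]] = MSS
    msi[n_ca:] = MSI_UNKNOWN
    msi_series = pd.Series(msi, index=sample_ids, name="msi") if n_ca else None

    # additive MSI %M shift on the configured genes, clipped to [0, 100]
    if spec.msi_shift and n_msi:
        msi_rows = np.flatnonzero(msi[:n_ca] == MSI)
        for gene, shift in spec.msi_shift.items():
            if gene not in genes:
                raise ValidationError(f"msi_shift gene {gene!r} not in cohort")
            j = genes.index(gene)
            values[msi_rows, j] = np.clip(values[msi_rows, j] + shift, 0.0, 100.0)

    lo, hi = spec.age_range
    ages = np.concatenate([
        _truncated_normal(rng, n_ca, spec.age_mean_carcinoma, spec.age_sd, lo, hi),
        _truncated_normal(rng, n_no, spec.age_mean_normal, spec.age_sd, lo, hi),
    ])
    return MethylationMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=genes),
        class_labels=classes,
        ages=pd.Series(np.round(ages, 1), index=sample_ids, name="age"),
        msi_labels=msi_series,
    )


# Plasma cohorts --------------------------------------------------------------


@dataclass(frozen=True)
class PlasmaSpec:
    """Low-background plasma regime for cell-free DNA panels.

    Normal plasma carries almost no methylated tumor DNA: each gene's
    normal-class %M is 0 with probability ``background_zero_prob`` and
    otherwise Uniform(0, ``background_max``).  Carcinoma signal per gene is
    Gamma(``signal_shape``, ``signal_scale``) clipped to [0, 100] — modest
    per-gene levels whose panel sum separates the classes.  These defaults
    are invented operating conditions for exercising the plasma workflow,
    not a fit to any assay's chemistry.
    """

    genes: tuple[str, ...]
    n_carcinoma: int = 20
    n_normal: int = 20
    background_zero_prob: float = 0.9
    background_max: float = 2.0
    signal_shape: float = 1.2
    signal_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("plasma spec needs at least one gene")
        if not 0.0 <= self.background_zero_prob <= 1.0:
            raise ValidationError("background_zero_prob must be in [0, 1]")


def generate_plasma_cohort(spec: PlasmaSpec) -> MethylationMatrix:
    """Sample a labeled plasma %M matrix (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n_ca, n_no = spec.n_carcinoma, spec.n_normal
    genes = list(spec.genes)
    sample_ids = [f"crc_{i + 1:03d}" for i in range(n_ca)] + [
        f"ctl_{i + 1:03d}" for i in range(n_no)
    ]
    signal = np.clip(
        rng.gamma(spec.signal_shape, spec.signal_scale, size=(n_ca, len(genes))),
        0.0, 100.0,
    )
    zero = rng.random((n_no, len(genes))) < spec.background_zero_prob
    background = np.where(
        zero, 0.0, rng.uniform(0.0, spec.background_max, size=(n_no, len(genes)))
    )
    values = np.vstack([signal, background])
    return MethylationMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=genes),
        class_labels=pd.Series(
            [CARCINOMA] * n_ca + [NORMAL] * n_no, index=sample_ids, name="class"
        ),
    )


# Beta matrices for the clustering prescreen ----------------------------------


def generate_beta_matrix(
    n_diff_probes: int = 13,
    n_null_probes: int = 9,
    n_carcinoma: int = 30,
    n_normal: int = 20,
    diff_carcinoma_mean: float = 0.6,
    diff_normal_mean: float = 0.15,
    null_mean: float = 0.15,
    noise_sd: float = 0.08,
    seed: int = 0,
) -> BetaMatrix:
    """Block-structured beta matrix: a differentially methylated probe block
    (elevated carcinoma mean) plus a null block, Gaussian noise clipped to
    [0, 1].  Probe ids encode the truth (``cg_diff_*`` vs ``cg_null_*``)."""
    if n_diff_probes + n_null_probes < 1 or min(n_carcinoma, n_normal) < 1:
        raise ValidationError("invalid beta-matrix dimensions")
    rng = np.random.default_rng(seed)
    probes = [f"cg_diff_{i + 1:03d}" for i in range(n_diff_probes)] + [
        f"cg_null_{i + 1:03d}" for i in range(n_null_probes)
    ]
    samples = [f"ca_{i + 1:03d}" for i in range(n_carcinoma)] + [
        f"no_{i + 1:03d}" for i in range(n_normal)
    ]
    n_probes, n_samples = len(probes), len(samples)
    means = np.full((n_probes, n_samples), null_mean)
    means[:n_diff_probes, :n_carcinoma] = diff_carcinoma_mean
    means[:n_diff_probes, n_carcinoma:] = diff_normal_mean
    values = np.clip(means + rng.normal(0.0, noise_sd, size=means.shape), 0.0, 1.0)
    return BetaMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        class_labels=pd.Series(
            [CARCINOMA] * n_carcinoma + [NORMAL] * n_normal, index=samples
        ),
    )


# Train/test split ------------------------------------------------------------


def split_cohort(
    matrix: MethylationMatrix,
    seed: int = 0,
    max_age_diff: float = 3.0,
    max_retries: int = 50,
) -> tuple[MethylationMatrix, MethylationMatrix]:
    """Randomized train/test split stratified by class and age tertile.

    Within each (class, age-tertile) stratum samples are shuffled and dealt
    alternately, so per-stratum set sizes differ by at most one.  The split
    is re-randomized (up to ``max_retries``) until the class-wise mean-age
    difference between sets is <= ``max_age_diff`` years; if no draw
    qualifies the best one found is returned.  Without ages the split falls
    back to class-only stratification (with a warning).
    """
    rng = np.random.default_rng(seed)
    labels = matrix.class_labels
    have_ages = matrix.ages is not None and not matrix.ages.isna().any()
    if not have_ages:
        warnings.warn(
            "ages missing; falling back to class-only stratification",
            stacklevel=2,
        )

    strata: list[np.ndarray] = []
    for cls in labels.unique():
        idx = np.flatnonzero((labels == cls).to_numpy())
        if have_ages:
            ages = matrix.ages.to_numpy()[idx]
            t1, t2 = np.quantile(ages, [1 / 3, 2 / 3])
            bins = np.digitize(ages, [t1, t2])
            for b in range(3):
                part = idx[bins == b]
                if part.size:
                    strata.append(part)
        else:
            strata.append(idx)

    def one_split() -> np.ndarray:
        to_train = np.zeros(matrix.n_samples, dtype=bool)
        for part in strata:
            perm = rng.permutation(part)
            start = int(rng.integers(2))  # which set gets the odd sample
            to_train[perm[start::2]] = True
        return to_train

    def age_imbalance(to_train: np.ndarray) -> float:
        if not have_ages:
            return 0.0
        worst = 0.0
        ages = matrix.ages.to_numpy()
        for cls in labels.unique():
            m = (labels == cls).to_numpy()
            a, b = ages[m & to_train], ages[m & ~to_train]
            if a.size and b.size:
                worst = max(worst, abs(a.mean() - b.mean()))
        return worst

    best, best_diff = None, np.inf
    for _ in range(max_retries):
        cand = one_split()
        diff = age_imbalance(cand)
        if diff < best_diff:
            best, best_diff = cand, diff
        if diff <= max_age_diff:
            break
    if best_diff > max_age_diff:
        logger.warning(
            "age balance target %.1f years not met after %d retries; "
            "best difference %.2f", max_age_diff, max_retries, best_diff,
        )
    return matrix.select_samples(best), matrix.select_samples(~best)
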