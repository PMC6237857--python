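"""Simulators for every pipeline input, with full ground truth.

Three generators emulate the statistical structure the analysis assumes:

* a negative-binomial count cohort over cirrhosis/T1/T2/T3 groups with
  planted stage-trend gene clusters and per-sample library-size variation;
* peri/intra immune-phenotype labels with planted >=2-fold differentially
  expressed genes;
* a panel of "indication" expression datasets sharing one latent-factor
  driven correlated gene module (plus one dataset-specific module);
* rendered dual-stain histology images with blue fibrotic deposits and
  red cell disks at controlled distances.

Every generator is bit-reproducible from its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, ExpressionMatrix, SampleAnnotation
from .ihc_quantification import AnnotatedImage

GROUP_ORDER = ("cirrhosis", "T1", "T2", "T3")

#: Group sizes mirroring the published cohort's stage distribution
#: (30/16/40 tumors across T1/T2/T3, with a cirrhosis arm).
DEFAULT_GROUP_SIZES: Mapping[str, int] = {
    "cirrhosis": 30, "T1": 30, "T2": 16, "T3": 40,
}

TRENDS = ("down", "up_then_down", "up")


@dataclass(frozen=True)
class TrendSpec:
    """A planted trend cluster: shape, per-step effect (log2 units), size."""

    trend: str
    effect: float = 1.0
    n_genes: int = 100

    def __post_init__(self) -> None:
        if self.trend not in TRENDS:
            raise ValueError(f"unknown trend {self.trend!r}")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def offsets(self, n_groups: int) -> np.ndarray:
        """Expected log2-mean offset per ordered group."""
        e = abs(self.effect)
        steps = np.arange(n_groups, dtype=float)
        if self.trend == "down":
            return -e * steps
        if self.trend == "up":
            return e * steps
        # rise by e on the first step, then fall by e per step
        return np.concatenate(([0.0], e - e * np.arange(n_groups - 1, dtype=float)))


DEFAULT_TRENDS = (
    TrendSpec("down", 1.0, 100),
    TrendSpec("up_then_down", 1.0, 100),
    TrendSpec("up", 1.0, 100),
)


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort."""

    trend_of_gene: pd.Series  # gene -> trend name or "background"
    log2_mean: pd.DataFrame  # gene x sample expected log2 mean (incl. libsize)
    group_of_sample: pd.Series
    deg_true_l2fc: pd.Series = field(
        default_factory=lambda: pd.Series(dtype=float)
    )  # planted phenotype genes -> true shift

    @property
    def planted_trend_genes(self) -> list[str]:
        return list(self.trend_of_gene.index[self.trend_of_gene != "background"])


@dataclass(frozen=True)
class SimulatedCohort:
    counts: CountMatrix
    annotation: SampleAnnotation
    truth: CohortTruth
    nb_dispersion: float


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(
    n_genes: int = 2000,
    samples_per_group: Mapping[str, int] = DEFAULT_GROUP_SIZES,
    planted: Sequence[TrendSpec] = DEFAULT_TRENDS,
    nb_dispersion: float = 0.1,
    libsize_sigma: float = 0.2,
    baseline_log2_range: tuple[float, float] = (3.0, 8.0),
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a staged count cohort with planted trend clusters.

    Per-gene baseline log2 means are uniform over ``baseline_log2_range``;
    planted genes get trend-shaped group offsets; per-sample library-size
    offsets are N(0, libsize_sigma) in log2 units; counts are negative
    binomial at mean 2**(log2 mean) with the given dispersion.
    """
    groups = [g for g in GROUP_ORDER if g in samples_per_group]
    if not groups:
        raise ValueError("samples_per_group names no known group")
    for g in groups:
        if samples_per_group[g] < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    n_planted = sum(s.n_genes for s in planted)
    if n_planted > n_genes:
        raise ValueError("more planted genes than genes")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    sample_ids, sample_group = [], []
    for g in groups:
        for i in range(samples_per_group[g]):
            sample_ids.append(f"{g}_{i + 1:03d}")
            sample_group.append(g)
    group_of_sample = pd.Series(sample_group, index=sample_ids, name="group")

    baseline = rng.uniform(*baseline_log2_range, size=n_genes)
    offsets = np.zeros((n_genes, len(groups)))
    trend_of_gene = pd.Series("background", index=gene_ids, name="trend")
    pos = 0
    for spec in planted:
        offsets[pos:pos + spec.n_genes, :] = spec.offsets(len(groups))
        trend_of_gene.iloc[pos:pos + spec.n_genes] = spec.trend
        pos += spec.n_genes

    lib = rng.normal(0.0, libsize_sigma, size=len(sample_ids))
    gidx = np.array([groups.index(g) for g in sample_group])
    log2_mean = baseline[:, None] + offsets[:, gidx] + lib[None, :]
    counts = _nb_draw(rng, np.exp2(log2_mean), nb_dispersion)

    ann = pd.DataFrame(
        {
            "tissue_class": ["cirrhosis" if g == "cirrhosis" else "tumor"
                             for g in sample_group],
            "stage": ["NA" if g == "cirrhosis" else g for g in sample_group],
            "phenotype": "unknown",
            "cohort": "simulated",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SimulatedCohort(
        counts=CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids)),
        annotation=SampleAnnotation(ann),
        truth=CohortTruth(
            trend_of_gene=trend_of_gene,
            log2_mean=pd.DataFrame(log2_mean, index=gene_ids, columns=sample_ids),
            group_of_sample=group_of_sample,
        ),
        nb_dispersion=nb_dispersion,
    )


def simulate_phenotypes(
    cohort: SimulatedCohort,
    n_deg: int = 200,
    true_l2fc_range: tuple[float, float] = (1.0, 2.0),
    fraction_peri: float = 0.5,
    seed: int = 0,
) -> SimulatedCohort:
    """Label tumor samples peri/intra and plant up-in-peri expression shifts.

    ``n_deg`` genes (drawn from the background genes where possible, to keep
    the trend and phenotype plants disjoint) receive a per-gene log2 shift
    drawn uniformly from ``true_l2fc_range`` in the peri-tumoral samples;
    affected counts are re-drawn from the shifted negative-binomial means.
    """
    tumors = cohort.annotation.samples_with(tissue_class="tumor")
    if not tumors:
        raise ValueError("cohort has no tumor samples")
    if not 0 <= fraction_peri <= 1:
        raise ValueError("fraction_peri must be in [0, 1]")
    genes = cohort.truth.trend_of_gene
    background = list(genes.index[genes == "background"])
    pool = background if len(background) >= n_deg else list(genes.index)
    if n_deg > len(pool):
        raise ValueError(f"n_deg={n_deg} exceeds available genes ({len(pool)})")

    rng = np.random.default_rng(seed)
    n_peri = int(round(fraction_peri * len(tumors)))
    peri = set(rng.permutation(tumors)[:n_peri])
    deg_genes = sorted(rng.choice(pool, size=n_deg, replace=False))
    shifts = rng.uniform(*true_l2fc_range, size=n_deg)

    ann = cohort.annotation.data.copy()
    ann.loc[tumors, "phenotype"] = [
        "peri" if s in peri else "intra" for s in tumors
    ]

    log2_mean = cohort.truth.log2_mean.copy()
    counts = cohort.counts.data.copy()
    peri_list = [s for s in tumors if s in peri]
    if peri_list and n_deg:
        log2_mean.loc[deg_genes, peri_list] += shifts[:, None]
        new_mean = np.exp2(log2_mean.loc[deg_genes, peri_list].to_numpy())
        counts.loc[deg_genes, peri_list] = _nb_draw(
            rng, new_mean, cohort.nb_dispersion
        )

    return SimulatedCohort(
        counts=CountMatrix(counts),
        annotation=SampleAnnotation(ann),
        truth=replace(
            cohort.truth,
            log2_mean=log2_mean,
            deg_true_l2fc=pd.Series(shifts, index=deg_genes, name="true_l2fc"),
        ),
        nb_dispersion=cohort.nb_dispersion,
    )


# ---------------------------------------------------------------------------
# Multi-indication one-factor datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndicationTruth:
    shared_genes: tuple[str, ...]
    specific_genes: tuple[str, ...]
    specific_dataset: int  # index of the dataset carrying the specific module
    lambda_shared: float
    lambda_specific: float


def simulate_indications(
    n_datasets: int = 7,
    n_candidate_genes: int = 85,
    shared_module_size: int = 23,
    lambda_shared: float = 0.85,
    specific_module_size: int = 20,
    lambda_specific: float = 0.85,
    n_samples: int = 200,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], IndicationTruth]:
    """One-factor indication panel with a shared and a dataset-specific module.

    In every dataset, shared-module genes follow ``lambda*f + sqrt(1-lambda^2)*eps``
    with a per-sample latent factor f and unit-normal noise, which makes the
    population within-module pairwise correlation exactly lambda^2.  The
    specific module uses a dataset-local factor in the first dataset only and
    is pure noise elsewhere; background genes are independent noise scaled by
    ``noise_sd``.
    """
    if not (0 <= lambda_shared <= 1 and 0 <= lambda_specific <= 1):
        raise ValueError("lambda loadings must lie in [0, 1]")
    if shared_module_size + specific_module_size > n_candidate_genes:
        raise ValueError("module sizes exceed candidate gene count")
    if n_datasets < 1 or n_samples < 3:
        raise ValueError("need >=1 dataset and >=3 samples")

    rng = np.random.default_rng(seed)
    gene_ids = [f"CAND{i + 1:03d}" for i in range(n_candidate_genes)]
    shared = gene_ids[:shared_module_size]
    specific = gene_ids[shared_module_size:shared_module_size + specific_module_size]
    specific_dataset = 0

    datasets = []
    for d in range(n_datasets):
        sample_ids = [f"D{d + 1}S{j + 1:04d}" for j in range(n_samples)]
        values = rng.normal(0.0, noise_sd, size=(n_candidate_genes, n_samples))
        f_shared = rng.normal(size=n_samples)
        eps = rng.normal(size=(shared_module_size, n_samples))
        values[:shared_module_size] = (
            lambda_shared * f_shared
            + np.sqrt(1 - lambda_shared**2) * eps
        )
        if d == specific_dataset:
            f_local = rng.normal(size=n_samples)
            eps2 = rng.normal(size=(specific_module_size, n_samples))
            values[shared_module_size:shared_module_size + specific_module_size] = (
                lambda_specific * f_local
                + np.sqrt(1 - lambda_specific**2) * eps2
            )
        datasets.append(
            ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
        )
    truth = IndicationTruth(
        shared_genes=tuple(shared),
        specific_genes=tuple(specific),
        specific_dataset=specific_dataset,
        lambda_shared=lambda_shared,
        lambda_specific=lambda_specific,
    )
    return datasets, truth


# ---------------------------------------------------------------------------
# Rendered dual-stain histology
# ---------------------------------------------------------------------------

COLOR_BACKGROUND = (255, 255, 255)
COLOR_TISSUE = (230, 190, 200)  # light pink
COLOR_DEPOSIT = (60, 60, 200)  # aniline-blue collagen
COLOR_CELL = (200, 60, 40)  # DAB-red CD8 cell


@dataclass(frozen=True)
class ImageTruth:
    deposit_mask: np.ndarray  # boolean H x W
    cell_centers: tuple[tuple[float, float], ...]
    distances_um: tuple[float, ...]  # analytic distance to nearest deposit edge
    categories: tuple[str, ...]  # per cell, at the render-time cutoff
    cutoff_um: float


def _disk_mask(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rows, cols = np.ogrid[:h, :w]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def render_ihc(
    width: int = 256,
    height: int = 256,
    microns_per_pixel: float = 1.0,
    deposits: Sequence[tuple[tuple[float, float], float]] = (),
    cells: Sequence[tuple[tuple[float, float], float]] = (),
    cutoff_um: float = 5.0,
    tissue_margin_px: int = 10,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[AnnotatedImage, ImageTruth]:
    """Render a synthetic dual-stain nodule image with analytic ground truth.

    A light-pink tissue field (inset ``tissue_margin_px`` from the white
    frame) carries blue-dominant deposit disks and red-dominant cell disks,
    each given as ((row, col), radius_px).  True cell-to-deposit distances
    are computed from the disk geometry before rasterization:
    max(0, |c_cell - c_dep| - r_dep) * microns_per_pixel, infinite with no
    deposits.  Pixel noise is normal(0, noise_sd) truncated at +/-2 sd so it
    can never flip a pixel across the segmentation thresholds.
    """
    h, w = int(height), int(width)
    for (cy, cx), r in list(deposits) + list(cells):
        if not (r <= cy <= h - 1 - r and r <= cx <= w - 1 - r):
            raise ValueError(f"shape at ({cy}, {cx}) radius {r} does not fit frame")

    img = np.empty((h, w, 3), dtype=float)
    img[:] = COLOR_BACKGROUND
    m = tissue_margin_px
    if m * 2 >= min(h, w):
        raise ValueError("tissue margin leaves no tissue")
    img[m:h - m, m:w - m] = COLOR_TISSUE

    deposit_mask = np.zeros((h, w), dtype=bool)
    for center, radius in deposits:
        deposit_mask |= _disk_mask(h, w, center, radius)
    img[deposit_mask] = COLOR_DEPOSIT
    for center, radius in cells:
        img[_disk_mask(h, w, center, radius)] = COLOR_CELL

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=img.shape)
        noise = np.clip(noise, -2 * noise_sd, 2 * noise_sd)
        img = img + noise
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    distances, categories = [], []
    for (cy, cx), _ in cells:
        if deposits:
            d_px = min(
                max(0.0, float(np.hypot(cy - dy, cx - dx)) - dr)
                for (dy, dx), dr in deposits
            )
            d_um = d_px * microns_per_pixel
        else:
            d_um = float("inf")
        distances.append(d_um)
        categories.append("trapped" if d_um <= cutoff_um else "infiltrated")

    truth = ImageTruth(
        deposit_mask=deposit_mask,
        cell_centers=tuple((float(cy), float(cx)) for (cy, cx), _ in cells),
        distances_um=tuple(distances),
        categories=tuple(categories),
        cutoff_um=cutoff_um,
    )
    return AnnotatedImage(pixels=pixels, microns_per_pixel=microns_per_pixel), truth
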