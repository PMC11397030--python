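"""Synthetic cohorts with block LD, marginal GWAS statistics, array subsets
and imputation-quality degradation.

The generator reproduces the statistical structure the coverage method
assumes, not a coalescent model.  Genotypes are built from a small pool of
founder haplotypes per LD block: every individual's two haplotypes in a
block are noisy copies of random founders, so variants within a block are
strongly correlated while blocks are independent.  Fewer founders means
stronger within-block LD.  Phenotypes are quantitative with additive causal
effects, and the "discovery" summary statistics are per-variant marginal
least-squares tests on that phenotype.  Array subsets of graded density and
post-imputation info scores emulate target panels of varying coverage.

One global integer seed drives named substreams (panel / phenotype / array /
info) so each stage can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sstats

from .io_formats import ArrayVariantSet, GenotypePanel, SummaryStats, VariantKey

# ref/alt pairs avoiding strand-ambiguous (A/T, C/G) combinations, so the
# default scoring path keeps every simulated SNP
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_BLOCK_GAP_BP = 1_000_000
_SITE_SPACING_BP = 1_000


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters fully determining a simulated cohort.

    Defaults describe a cohort of the scale the method targets: a few
    hundred samples, a few hundred SNPs organised in LD blocks, a sparse
    polygenic architecture and a half-density genotyping array.

    Parameters
    ----------
    n_blocks, block_size
        Number of independent LD blocks and variants per block.
    n_founders
        Founder haplotypes per block; controls LD strength (fewer founders,
        stronger within-block correlation).
    flip_prob
        Per-site copy-error probability when an individual haplotype is
        copied from a founder; must be < 0.5.
    n_samples
        Diploid individuals in the cohort.
    n_causal
        Causal variants drawn uniformly at random.
    effect_sd
        Standard deviation of causal effect sizes (phenotype units per
        allele); environmental noise has unit variance.
    array_density
        Fraction of panel variants present on the simulated array.
    seed
        Global seed for the named substreams.
    """

    n_blocks: int = 20
    block_size: int = 25
    n_founders: int = 8
    flip_prob: float = 0.01
    n_samples: int = 600
    n_causal: int = 25
    effect_sd: float = 0.2
    array_density: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.flip_prob < 0.5):
            raise ValueError("flip_prob must be in [0, 0.5)")
        if not (0 < self.array_density <= 1):
            raise ValueError("array_density must be in (0, 1]")
        for name in ("n_blocks", "block_size", "n_founders", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_causal > self.n_blocks * self.block_size:
            raise ValueError("n_causal exceeds variant count")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def simulate_panel(scn: SyntheticScenario) -> GenotypePanel:
    """Simulate a founder-haplotype block panel.

    Per block: site allele frequencies ~ Uniform(0.05, 0.5); ``n_founders``
    founder haplotypes drawn from them; each individual's two haplotypes
    are copies of uniformly chosen founders with per-site flip probability
    ``flip_prob``.  Dosage is the haplotype sum.  Sites are spaced 1 kb
    apart within a block, with 1 Mb gaps between blocks, all on
    chromosome "1".
    """
    rng = substream(scn.seed, "panel")
    n = scn.n_samples
    variants: list[VariantKey] = []
    cols: list[np.ndarray] = []
    vid = 0
    block_span = scn.block_size * _SITE_SPACING_BP + _BLOCK_GAP_BP
    for b in range(scn.n_blocks):
        freqs = rng.uniform(0.05, 0.5, size=scn.block_size)
        founders = (rng.random((scn.n_founders, scn.block_size)) < freqs).astype(np.int8)
        picks = rng.integers(0, scn.n_founders, size=(n, 2))
        haps = founders[picks]  # (n, 2, block_size)
        if scn.flip_prob > 0:
            flips = rng.random(haps.shape) < scn.flip_prob
            haps = np.where(flips, 1 - haps, haps)
        dos = haps.sum(axis=1).astype(float)  # (n, block_size)
        start = 1 + b * block_span
        for j in range(scn.block_size):
            vid += 1
            ref, alt = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
            variants.append(VariantKey(
                chrom="1", pos=start + j * _SITE_SPACING_BP,
                rsid=f"rs{vid}", ref=ref, alt=alt,
            ))
            cols.append(dos[:, j])
    samples = [f"S{i + 1}" for i in range(n)]
    return GenotypePanel(variants=variants, samples=samples, dosages=np.column_stack(cols))


def simulate_sumstats(
    panel: GenotypePanel, scn: SyntheticScenario
) -> tuple[SummaryStats, np.ndarray]:
    """Simulate marginal discovery statistics from an additive phenotype.

    A causal set of ``scn.n_causal`` variants is drawn uniformly; causal
    effects are Normal(0, effect_sd^2); the phenotype is the additive
    genetic value plus standard normal noise.  Each variant's summary
    record is its marginal least-squares slope on the phenotype with the
    two-sided t-test p-value.  The odds-ratio column is exp(beta) purely
    for format compatibility with case-control discovery tables.

    Returns the stats and the true per-variant effect vector.
    """
    import pandas as pd

    if scn.n_causal > panel.n_variants:
        raise ValueError("n_causal exceeds panel variant count")
    rng = substream(scn.seed, "phenotype")
    D = panel.dosages
    n, m = D.shape
    true_beta = np.zeros(m)
    if scn.n_causal > 0:
        causal = rng.choice(m, size=scn.n_causal, replace=False)
        true_beta[causal] = rng.normal(0.0, scn.effect_sd, size=scn.n_causal)
    y = np.nan_to_num(D) @ true_beta + rng.normal(0.0, 1.0, size=n)

    # vectorised per-variant OLS: slope, SE, two-sided t-test
    Dc = D - np.nanmean(D, axis=0)
    yc = y - y.mean()
    sxx = np.nansum(Dc * Dc, axis=0)
    sxy = np.nansum(Dc * yc[:, None], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        resid_ss = np.nansum((yc[:, None] - slope * Dc) ** 2, axis=0)
        se = np.sqrt(resid_ss / (n - 2) / sxx)
        t = slope / se
    p = 2 * sstats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    mono = sxx <= 0
    slope[mono] = 0.0
    p[mono] = 1.0

    freqs = np.array([panel.alt_frequency(j) for j in range(m)])
    df = pd.DataFrame({
        "chrom": [v.chrom for v in panel.variants],
        "pos": [v.pos for v in panel.variants],
        "rsid": [v.rsid for v in panel.variants],
        "effect_allele": [v.alt for v in panel.variants],
        "other_allele": [v.ref for v in panel.variants],
        "beta": slope,
        "odds_ratio": np.exp(slope),
        "pvalue": p,
        "maf": np.minimum(freqs, 1 - freqs),
    })
    return SummaryStats(df), true_beta


def make_array_subset(panel: GenotypePanel, density: float, seed: int,
                      name: str | None = None) -> ArrayVariantSet:
    """Uniform random array subset of ``ceil(density * n_variants)`` variants."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = substream(seed, "array")
    m = panel.n_variants
    k = math.ceil(density * m)
    idx = np.sort(rng.choice(m, size=k, replace=False))
    return ArrayVariantSet(
        name=name or f"synthetic-array-{density:g}",
        keys=[panel.variants[i] for i in idx],
    )


def degrade_info(panel: GenotypePanel, hidden: ArrayVariantSet, seed: int) -> GenotypePanel:
    """Emulate imputation of the variants in ``hidden``.

    Hidden variants receive an info score ~ Uniform(0.5, 1.0) and their
    dosages are shrunk toward 2x allele frequency in proportion to
    (1 - info), the way low-information imputed dosages regress to the
    mean.  Typed variants keep their dosages and get info 1.0.
    """
    rng = substream(seed, "info")
    for k in hidden.keys:
        if panel.find(k) is None:
            raise ValueError(f"hidden variant {k} not in panel")
    info = np.ones(panel.n_variants)
    dos = panel.dosages.copy()
    for k in hidden.keys:
        j = panel.find(k)
        q = rng.uniform(0.5, 1.0)
        info[j] = q
        mean_d = 2.0 * panel.alt_frequency(j)
        col = dos[:, j]
        m = ~np.isnan(col)
        col[m] = q * col[m] + (1 - q) * mean_d
    return GenotypePanel(
        variants=list(panel.variants), samples=list(panel.samples),
        dosages=dos, info=info,
    )
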