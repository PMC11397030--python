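"""Variant- and sample-level quality control.

Filters, applied in a fixed order to the progressively surviving matrix:

1. sample call rate (missing fraction > ``sample_missing_max`` drops the sample)
2. variant call rate (missing fraction > ``variant_missing_max``)
3. minor allele frequency (kept iff MAF >= ``maf_min``)
4. Hardy-Weinberg exact test (dropped iff p < ``hwe_p_min``)
5. imputation info (kept iff info > ``info_min``, when the panel carries info)

Boundary semantics follow the stated criteria literally: MAF keeps
equality, HWE drops strictly below, info keeps strictly above.  MAF and
HWE may be computed on an ancestry subset of samples via ``sample_mask``
(e.g. Europeans only) while the whole panel is filtered.

The HWE test is the exact conditional test: given the allele counts, sum
the probabilities of all heterozygote counts whose conditional probability
does not exceed that of the observed table.  It is computed with the
standard stable recurrence over heterozygote counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenotypePanel, VariantKey


class UndefinedInputError(ValueError):
    """An operation was called on input with no information (e.g. all missing)."""


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults are the standard array-QC criteria."""

    maf_min: float = 0.05
    variant_missing_max: float = 0.05
    sample_missing_max: float = 0.03
    hwe_p_min: float = 1e-5
    info_min: float = 0.80

    def __post_init__(self):
        for name in ("maf_min", "variant_missing_max", "sample_missing_max",
                     "hwe_p_min", "info_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QcOutcome:
    kept_panel: GenotypePanel
    dropped_variants: list[tuple[VariantKey, str]] = field(default_factory=list)
    dropped_samples: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped_by_reason(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, r in self.dropped_variants:
            counts[r] = counts.get(r, 0) + 1
        for _, r in self.dropped_samples:
            counts[r] = counts.get(r, 0) + 1
        return counts


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Folded allele frequency min(p, 1-p), p = mean(dosage)/2 over non-missing."""
    d = np.asarray(dosages, dtype=float)
    m = ~np.isnan(d)
    if not m.any():
        raise UndefinedInputError("all dosages missing")
    p = float(d[m].mean() / 2.0)
    return min(p, 1.0 - p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, midp: bool = False) -> float:
    """Exact two-sided Hardy-Weinberg test p-value for one genotype table.

    Conditional on the observed allele counts, sums P(n_het = h) over all
    heterozygote counts h whose probability does not exceed that of the
    observed count.  ``midp`` halves the observed table's own contribution
    (reserved; off by default).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    probs = _het_distribution(n, n_rare)
    obs = probs[n_Aa] if n_Aa < len(probs) else 0.0
    # parity of n_Aa must match n_rare; a mismatched observed table is impossible
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    if midp:
        p -= 0.5 * obs
    return float(min(1.0, max(p, 0.0)))


def _het_distribution(n: int, n_rare: int) -> np.ndarray:
    """P(n_het = h | n genotypes, n_rare minor alleles), indexed by h.

    Stable recurrence: P(h+2)/P(h) = (r-h)(2n-r-h) / ((h+2)(h+1)), starting
    from the parity-matching smallest h, normalised to sum 1.  Entries with
    the wrong parity are zero.
    """
    r = n_rare
    if r == 0:
        return np.array([1.0])
    hs = np.arange(r % 2, r + 1, 2)
    h = hs[:-1].astype(float)
    steps = np.log((r - h) * (2 * n - r - h)) - np.log((h + 2) * (h + 1))
    logw = np.concatenate(([0.0], np.cumsum(steps)))
    w = np.exp(logw - logw.max())
    w /= w.sum()
    dist = np.zeros(r + 1)
    dist[hs] = w
    return dist


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    """Hard genotype counts from a dosage column (non-missing, rounded)."""
    d = col[~np.isnan(col)]
    hard = np.rint(d).astype(int)
    return int((hard == 0).sum()), int((hard == 1).sum()), int((hard == 2).sum())


def apply_qc(
    panel: GenotypePanel,
    thresholds: QcThresholds = QcThresholds(),
    sample_mask: np.ndarray | None = None,
    exclude_samples: set[str] | None = None,
) -> QcOutcome:
    """Apply the five-filter QC cascade to a panel.

    ``sample_mask`` restricts MAF and HWE computation to a sample subset
    (boolean over the input panel's samples); ``exclude_samples`` is a
    precomputed removal list (sex check, relatedness, divergent ancestry)
    applied before everything else.
    """
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise ValueError("empty panel")
    t = thresholds
    dropped_samples: list[tuple[str, str]] = []
    dropped_variants: list[tuple[VariantKey, str]] = []

    keep_s = np.ones(panel.n_samples, dtype=bool)
    if exclude_samples:
        for i, s in enumerate(panel.samples):
            if s in exclude_samples:
                keep_s[i] = False
                dropped_samples.append((s, "excluded"))

    # (1) sample call rate
    miss_s = np.isnan(panel.dosages).mean(axis=1)
    for i in np.nonzero(keep_s & (miss_s > t.sample_missing_max))[0]:
        keep_s[i] = False
        dropped_samples.append((panel.samples[i], "sample_callrate"))
    mask = None
    if sample_mask is not None:
        mask = np.asarray(sample_mask, dtype=bool)[keep_s]
    work = panel.take_samples(np.nonzero(keep_s)[0]) if not keep_s.all() else panel

    D = work.dosages
    stat_rows = slice(None) if mask is None else mask
    keep_v = np.ones(work.n_variants, dtype=bool)

    # (2) variant call rate
    miss_v = np.isnan(D).mean(axis=0)
    for j in np.nonzero(miss_v > t.variant_missing_max)[0]:
        keep_v[j] = False
        dropped_variants.append((work.variants[j], "missingness"))

    # (3) MAF, (4) HWE — on the surviving samples (optionally masked)
    for j in np.nonzero(keep_v)[0]:
        col = D[stat_rows, j]
        try:
            maf = minor_allele_frequency(col)
        except UndefinedInputError:
            keep_v[j] = False
            dropped_variants.append((work.variants[j], "missingness"))
            continue
        if maf < t.maf_min:
            keep_v[j] = False
            dropped_variants.append((work.variants[j], "maf"))
            continue
        if hwe_exact_test(*_genotype_counts(col)) < t.hwe_p_min:
            keep_v[j] = False
            dropped_variants.append((work.variants[j], "hwe"))

    # (5) info, when present
    if work.info is not None:
        for j in np.nonzero(keep_v)[0]:
            if not (work.info[j] > t.info_min):
                keep_v[j] = False
                dropped_variants.append((work.variants[j], "info"))

    kept = work.take_variants(np.nonzero(keep_v)[0])
    return QcOutcome(kept_panel=kept, dropped_variants=dropped_variants,
                     dropped_samples=dropped_samples)
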