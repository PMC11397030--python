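"""Genome-wide PGS coverage metric.

The metric quantifies how much polygenic-score information a target
genotyping platform loses.  Two clumping+thresholding scores are built
from the same discovery statistics and scored on the *same* reference
individuals:

* the **full** score, where the comprehensive reference panel serves as
  LD reference, target panel and scoring population; and
* the **target-restricted** score, where the discovery statistics are
  first restricted to the variants the target platform actually offers
  (its surviving post-QC or post-imputation variant list), then clumped
  on the reference panel and scored on the reference individuals.

The coverage metric at each discovery p-value threshold is the Pearson
correlation between the two score vectors: 1.0 means no information was
lost; low values mean the platform's variant list cannot reproduce the
comprehensive score.  Only the target platform's *variant list* is used —
its genotype values never enter the computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_formats import ArrayVariantSet, GenotypePanel, SummaryStats
from .prs import ClumpConfig, ClumpResult, EmptyScoreError, ScoreVector, clump, score, threshold

#: Discovery p-value threshold suite used throughout.
DEFAULT_THRESHOLDS = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.10, 0.20, 0.50, 1.0)


@dataclass
class MetricConfig:
    reference_panel: GenotypePanel
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    clump: ClumpConfig = field(default_factory=ClumpConfig)

    def __post_init__(self):
        self.thresholds = tuple(sorted(self.thresholds))
        if not self.thresholds:
            raise ValueError("threshold suite is empty")
        if any(not (0 < t <= 1) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class ThresholdMetric:
    threshold: float
    r: float  # nan when undefined
    n_snps_full: int
    n_snps_target: int
    undefined: bool = False


@dataclass
class CoverageMetricResult:
    per_threshold: list[ThresholdMetric]
    target_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "target": self.target_label,
            "threshold": m.threshold,
            "r": m.r,
            "n_snps_full": m.n_snps_full,
            "n_snps_target": m.n_snps_target,
            "undefined": m.undefined,
        } for m in self.per_threshold], columns=[
            "target", "threshold", "r", "n_snps_full", "n_snps_target", "undefined",
        ])

    def r_at(self, thresh: float) -> float:
        for m in self.per_threshold:
            if m.threshold == thresh:
                return m.r
        raise KeyError(f"threshold {thresh} not in result")


def _clump_once(stats: SummaryStats, cfg: MetricConfig) -> ClumpResult:
    return clump(stats, cfg.reference_panel, cfg.clump)


def full_panel_score(stats: SummaryStats, cfg: MetricConfig, thresh: float) -> ScoreVector:
    """Comprehensive-panel score: clump on the reference, threshold, score
    the reference samples."""
    return score(cfg.reference_panel, threshold(_clump_once(stats, cfg), thresh),
                 p_thresh=thresh)


def target_restricted_score(
    stats: SummaryStats, target_variants: ArrayVariantSet, cfg: MetricConfig, thresh: float
) -> ScoreVector:
    """Target-panel score: restrict the discovery statistics to the target's
    variant list, clump on the reference LD, threshold, score the reference
    samples."""
    mask = np.array([k in target_variants for k in stats.keys()])
    if not mask.any():
        raise EmptyScoreError("no discovery variant is on the target platform")
    return score(cfg.reference_panel, threshold(_clump_once(stats.restrict(mask), cfg), thresh),
                 p_thresh=thresh)


def coverage_metric(
    stats: SummaryStats,
    target_variants: ArrayVariantSet,
    cfg: MetricConfig,
    target_label: str | None = None,
) -> CoverageMetricResult:
    """Per-threshold correlation between full and target-restricted scores.

    Thresholds where either score is empty or constant are flagged
    ``undefined`` with ``r = nan`` rather than reported as zero.  Negative
    correlations (possible only in pathological restrictions) are reported
    as computed, with a warning.
    """
    full_clumped = _clump_once(stats, cfg)
    mask = np.array([k in target_variants for k in stats.keys()])
    target_clumped = None
    if mask.any():
        target_clumped = _clump_once(stats.restrict(mask), cfg)

    out: list[ThresholdMetric] = []
    for t in cfg.thresholds:
        n_full = len(threshold(full_clumped, t))
        n_target = len(threshold(target_clumped, t)) if target_clumped is not None else 0
        try:
            sv_full = score(cfg.reference_panel, full_clumped, p_thresh=t)
            if target_clumped is None:
                raise EmptyScoreError("empty target restriction")
            sv_target = score(cfg.reference_panel, target_clumped, p_thresh=t)
        except EmptyScoreError:
            out.append(ThresholdMetric(t, float("nan"), n_full, n_target, undefined=True))
            continue
        if np.ptp(sv_full.scores) == 0 or np.ptp(sv_target.scores) == 0:
            out.append(ThresholdMetric(t, float("nan"), n_full, n_target, undefined=True))
            continue
        r = float(sstats.pearsonr(sv_full.scores, sv_target.scores).statistic)
        if r < 0:
            warnings.warn(f"negative coverage metric {r:.4f} at threshold {t}")
        out.append(ThresholdMetric(t, r, sv_full.n_snps_used, sv_target.n_snps_used))
    return CoverageMetricResult(per_threshold=out,
                                target_label=target_label or target_variants.name)
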