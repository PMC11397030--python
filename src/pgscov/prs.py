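"""Clumping + thresholding polygenic-score engine.

The C+T derivation: greedy LD clumping supervised by discovery p-values
(repeatedly promote the unclaimed variant with the smallest p-value to
index status and claim every unclaimed variant on its chromosome within
the window at r^2 >= the clump threshold), then retain index SNPs at or
below a discovery p-value threshold, then score each sample as the
weighted sum of effect-allele dosages using the log-odds effect sizes.

Allele matching between a summary record and a panel variant yields one of
``same`` (effect allele is the panel ALT), ``flip`` (effect allele is the
panel REF; dosage contribution becomes 2 - d), ``ambiguous``
(strand-ambiguous A/T or C/G pair, excluded from scoring by default) or
``mismatch`` (alleles irreconcilable, never scored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypePanel, SummaryStats, VariantKey
from .ld import LdUndefinedError, r_squared


class EmptyScoreError(ValueError):
    """No usable variants remained for clumping or scoring."""


@dataclass(frozen=True)
class ClumpConfig:
    """Clumping parameters.

    ``clump_r2`` and ``clump_window_bp`` default to the PLINK clump
    defaults (r^2 0.10 within +/- 250 kb); ``p1`` caps the p-value a
    variant may have to become an index.
    """

    clump_r2: float = 0.10
    clump_window_bp: int = 250_000
    p1: float = 1.0

    def __post_init__(self):
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0, 1]")
        if self.clump_window_bp <= 0:
            raise ValueError("clump_window_bp must be positive")
        if not (0 < self.p1 <= 1):
            raise ValueError("p1 must be in (0, 1]")


@dataclass(frozen=True)
class IndexSnp:
    key: VariantKey
    effect_allele: str
    other_allele: str
    beta: float
    pvalue: float


@dataclass
class ClumpResult:
    """Index SNPs (p-value ascending) and what each one claimed."""

    index_snps: list[IndexSnp]
    clumped_away: dict[VariantKey, list[VariantKey]] = field(default_factory=dict)
    n_absent_from_panel: int = 0
    config: ClumpConfig = field(default_factory=ClumpConfig)

    def __len__(self) -> int:
        return len(self.index_snps)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "chrom": s.key.chrom, "pos": s.key.pos, "rsid": s.key.rsid,
            "effect_allele": s.effect_allele, "other_allele": s.other_allele,
            "beta": s.beta, "pvalue": s.pvalue,
            "n_clumped": len(self.clumped_away.get(s.key, [])),
            "members": ",".join(v.rsid or f"{v.chrom}:{v.pos}"
                                for v in self.clumped_away.get(s.key, [])),
        } for s in self.index_snps]
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "rsid", "effect_allele", "other_allele",
            "beta", "pvalue", "n_clumped", "members",
        ])


@dataclass
class ScoreVector:
    samples: list[str]
    scores: np.ndarray
    n_snps_used: int
    threshold: float
    n_excluded_ambiguous: int = 0
    n_excluded_mismatch: int = 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.samples),):
            raise ValueError("score length does not match sample list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.samples,
            "score": self.scores,
            "n_snps_used": self.n_snps_used,
            "threshold": self.threshold,
        })


def clump(stats: SummaryStats, ld_panel: GenotypePanel, cfg: ClumpConfig = ClumpConfig()) -> ClumpResult:
    """Greedy p-value-supervised LD clumping on a reference panel.

    Summary records absent from the LD panel are dropped (counted in
    ``n_absent_from_panel``).  Ties in p-value break by (chrom, pos)
    ascending.  Pairs with undefined LD (constant dosage) are never
    claimed.  The result is independent of input row order.
    """
    df = stats.df
    panel_idx = []
    rows = []
    n_absent = 0
    for i, key in enumerate(stats.keys()):
        j = ld_panel.find(key)
        if j is None:
            n_absent += 1
            continue
        panel_idx.append(j)
        rows.append(i)
    if not rows:
        raise EmptyScoreError("no summary-stat variant is present in the LD panel")

    sub = df.iloc[rows].reset_index(drop=True)
    panel_idx = np.asarray(panel_idx)
    order = sorted(
        range(len(sub)),
        key=lambda k: (sub["pvalue"].iat[k], sub["chrom"].iat[k], sub["pos"].iat[k]),
    )
    claimed = np.zeros(len(sub), dtype=bool)
    index_snps: list[IndexSnp] = []
    clumped_away: dict[VariantKey, list[VariantKey]] = {}

    for k in order:
        if claimed[k]:
            continue
        if sub["pvalue"].iat[k] > cfg.p1:
            break  # ordered by p; no index candidates remain
        claimed[k] = True
        key_k = ld_panel.variants[panel_idx[k]]
        snp = IndexSnp(
            key=key_k,
            effect_allele=str(sub["effect_allele"].iat[k]),
            other_allele=str(sub["other_allele"].iat[k]),
            beta=float(sub["beta"].iat[k]),
            pvalue=float(sub["pvalue"].iat[k]),
        )
        index_snps.append(snp)
        members: list[VariantKey] = []
        a = ld_panel.dosages[:, panel_idx[k]]
        for m in range(len(sub)):
            if claimed[m]:
                continue
            key_m = ld_panel.variants[panel_idx[m]]
            if key_m.chrom != key_k.chrom or abs(key_m.pos - key_k.pos) > cfg.clump_window_bp:
                continue
            try:
                r2 = r_squared(a, ld_panel.dosages[:, panel_idx[m]])
            except LdUndefinedError:
                continue
            if r2 >= cfg.clump_r2:
                claimed[m] = True
                members.append(key_m)
        clumped_away[key_k] = members

    return ClumpResult(index_snps=index_snps, clumped_away=clumped_away,
                       n_absent_from_panel=n_absent, config=cfg)


def threshold(result: ClumpResult, p_thresh: float) -> ClumpResult:
    """Retain index SNPs with p-value <= ``p_thresh`` (nested across thresholds)."""
    if not (0 < p_thresh <= 1):
        raise ValueError("p_thresh must be in (0, 1]")
    kept = [s for s in result.index_snps if s.pvalue <= p_thresh]
    return ClumpResult(
        index_snps=kept,
        clumped_away={s.key: result.clumped_away.get(s.key, []) for s in kept},
        n_absent_from_panel=result.n_absent_from_panel,
        config=result.config,
    )


_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def match_alleles(effect_allele: str, other_allele: str, variant: VariantKey) -> str:
    """Orient a summary record against a panel variant.

    Returns ``same`` (effect = ALT, other = REF), ``flip`` (effect = REF,
    other = ALT), ``ambiguous`` (strand-ambiguous A/T or C/G pair — checked
    first, since strand cannot be resolved), or ``mismatch``.
    """
    e, o = effect_allele.upper(), other_allele.upper()
    if frozenset((e, o)) in _AMBIGUOUS_PAIRS:
        return "ambiguous"
    if e == variant.alt and o == variant.ref:
        return "same"
    if e == variant.ref and o == variant.alt:
        return "flip"
    return "mismatch"


def score(
    panel: GenotypePanel,
    weights: ClumpResult,
    p_thresh: float = 1.0,
    include_ambiguous: bool = False,
    info_min: float = 0.80,
    missing_policy: str = "mean",
) -> ScoreVector:
    """Score every panel sample: sum of beta x effect-allele dosage.

    Only biallelic SNPs present in the panel with resolvable orientation
    enter the score; when the panel carries info scores, variants at
    info <= ``info_min`` are excluded.  Missing dosages are mean-imputed
    to 2x the effect-allele frequency (``missing_policy="mean"``) or
    dropped per-sample with renormalisation to the per-sample mean beta
    weight (``"omit"``).
    """
    if missing_policy not in ("mean", "omit"):
        raise ValueError("missing_policy must be 'mean' or 'omit'")
    n = panel.n_samples
    total = np.zeros(n)
    used = 0
    n_ambiguous = 0
    n_mismatch = 0
    contrib_count = np.zeros(n)

    for snp in weights.index_snps:
        if snp.pvalue > p_thresh:
            continue
        j = panel.find(snp.key)
        if j is None:
            continue
        v = panel.variants[j]
        if not v.is_biallelic_snp:
            continue
        if panel.info is not None and not (panel.info[j] > info_min):
            continue
        orient = match_alleles(snp.effect_allele, snp.other_allele, v)
        if orient == "ambiguous":
            if not include_ambiguous:
                n_ambiguous += 1
                continue
            orient = "same" if snp.effect_allele == v.alt else (
                "flip" if snp.effect_allele == v.ref else "mismatch")
        if orient == "mismatch":
            n_mismatch += 1
            continue
        d = panel.dosages[:, j].copy()
        if orient == "flip":
            d = 2.0 - d
        miss = np.isnan(d)
        if miss.any():
            if missing_policy == "mean":
                p_eff = np.nanmean(d) / 2.0
                d[miss] = 2.0 * p_eff
            else:
                d[miss] = 0.0
        total += snp.beta * d
        if missing_policy == "omit":
            contrib_count += ~miss
        used += 1

    if used == 0:
        raise EmptyScoreError("zero usable SNPs in score")
    if missing_policy == "omit":
        with np.errstate(invalid="ignore", divide="ignore"):
            total = np.where(contrib_count > 0, total * (used / contrib_count), np.nan)
    return ScoreVector(
        samples=list(panel.samples), scores=total, n_snps_used=used,
        threshold=p_thresh, n_excluded_ambiguous=n_ambiguous,
        n_excluded_mismatch=n_mismatch,
    )
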