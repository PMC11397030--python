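"""Single-variant coverage of a discovery hit list on an array or panel.

A hit is *directly* covered when the array variant set contains it (by
chromosome+position, falling back to rsid); *proxy* covered when a
high-LD substitute from the reference panel is on the array; otherwise
*missing*.  The same computation applies unchanged at any pipeline stage
(pre-QC manifest, post-QC surviving variants, post-imputation) — the stage
is caller-supplied metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import ArrayVariantSet, SummaryStats, VariantKey
from .ld import LdSearchConfig, ProxyCandidate, best_proxy


@dataclass(frozen=True)
class HitCoverage:
    hit: VariantKey
    status: str  # direct | proxy | missing
    proxy_used: ProxyCandidate | None = None
    match_via: str | None = None  # "pos" | "rsid" for direct hits
    in_reference: bool = True  # False: hit absent from the LD reference panel

    def __post_init__(self):
        if self.status == "proxy" and self.proxy_used is None:
            raise ValueError("proxy status requires proxy_used")
        if self.status == "direct" and self.proxy_used is not None:
            raise ValueError("direct status excludes proxy_used")


@dataclass
class CoverageReport:
    per_hit: list[HitCoverage]
    stage_label: str = ""

    @property
    def n_hits(self) -> int:
        return len(self.per_hit)

    @property
    def n_direct(self) -> int:
        return sum(h.status == "direct" for h in self.per_hit)

    @property
    def n_covered(self) -> int:
        return sum(h.status in ("direct", "proxy") for h in self.per_hit)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.per_hit:
            rows.append({
                "chrom": h.hit.chrom,
                "pos": h.hit.pos,
                "rsid": h.hit.rsid,
                "status": h.status,
                "match_via": h.match_via or "",
                "proxy_rsid": h.proxy_used.proxy.rsid if h.proxy_used else "",
                "proxy_r2": h.proxy_used.r2 if h.proxy_used else float("nan"),
                "proxy_distance_bp": h.proxy_used.distance_bp if h.proxy_used else "",
                "stage": self.stage_label,
            })
        return pd.DataFrame(rows, columns=[
            "chrom", "pos", "rsid", "status", "match_via", "proxy_rsid",
            "proxy_r2", "proxy_distance_bp", "stage",
        ])


def direct_coverage(
    hits: SummaryStats, available: ArrayVariantSet, stage_label: str = ""
) -> CoverageReport:
    """Direct presence of each hit on the array (statuses direct/missing only)."""
    if len(hits) == 0:
        raise ValueError("empty hit list")
    per_hit = []
    for key in hits.keys():
        via = available.match(key)
        per_hit.append(HitCoverage(
            hit=key,
            status="direct" if via else "missing",
            match_via=via,
        ))
    return CoverageReport(per_hit=per_hit, stage_label=stage_label)


def proxy_coverage(
    hits: SummaryStats,
    available: ArrayVariantSet,
    cfg: LdSearchConfig,
    stage_label: str = "",
) -> CoverageReport:
    """Coverage with LD-proxy rescue.

    Direct if the hit is on the array; else proxy if the best reference-
    panel proxy (r^2 >= cfg.r2_min, within the window) is on the array;
    else missing.  Hits absent from the reference panel cannot be rescued
    and are flagged ``in_reference=False``.
    """
    if len(hits) == 0:
        raise ValueError("empty hit list")
    per_hit = []
    for key in hits.keys():
        via = available.match(key)
        if via:
            per_hit.append(HitCoverage(hit=key, status="direct", match_via=via))
            continue
        in_ref = cfg.panel.find(key) is not None
        cand = best_proxy(key, available, cfg) if in_ref else None
        if cand is not None:
            per_hit.append(HitCoverage(hit=key, status="proxy", proxy_used=cand))
        else:
            per_hit.append(HitCoverage(hit=key, status="missing", in_reference=in_ref))
    return CoverageReport(per_hit=per_hit, stage_label=stage_label)
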