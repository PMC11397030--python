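"""Pairwise LD (r^2) and windowed proxy search on a reference panel.

LD is estimated as the squared Pearson correlation of genotype dosages —
the usual estimator on (possibly imputed) array data — over pairwise-
complete samples.  A proxy search for an index variant scans the window
around it on the same chromosome and keeps variants with r^2 at or above
the threshold, ranked by r^2 descending, then physical distance ascending,
then position ascending (tie-break for determinism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ArrayVariantSet, GenotypePanel, VariantKey


class LdUndefinedError(ValueError):
    """r^2 is undefined: fewer than 2 complete pairs or a constant vector."""


@dataclass(frozen=True)
class ProxyCandidate:
    index: VariantKey
    proxy: VariantKey
    r2: float
    distance_bp: int


@dataclass
class LdSearchConfig:
    """Proxy-search parameters against a reference panel.

    ``window_bp`` is the half-window: candidates within +/- window_bp of
    the index position are considered.
    """

    panel: GenotypePanel
    r2_min: float = 0.80
    window_bp: int = 500_000

    def __post_init__(self):
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def r_squared(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are handled pairwise-complete.  Raises
    :class:`LdUndefinedError` when fewer than two jointly non-missing
    samples remain or either vector is constant on that subset.
    """
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    m = ~(np.isnan(a) | np.isnan(b))
    if m.sum() < 2:
        raise LdUndefinedError("fewer than 2 jointly non-missing samples")
    a, b = a[m], b[m]
    va = a - a.mean()
    vb = b - b.mean()
    den = (va @ va) * (vb @ vb)
    if den <= 0:
        raise LdUndefinedError("constant dosage vector")
    r2 = float((va @ vb) ** 2 / den)
    return min(r2, 1.0)  # guard fp overshoot


def find_proxies(index: VariantKey, cfg: LdSearchConfig) -> list[ProxyCandidate]:
    """All panel variants in LD with ``index`` at r^2 >= ``cfg.r2_min``.

    Candidates are same-chromosome variants within +/- ``window_bp`` of the
    index, excluding the index itself; pairs with undefined LD (constant
    dosage) are not proxies.  Returns an empty list when the index is
    absent from the reference panel.
    """
    panel = cfg.panel
    i = panel.find(index)
    if i is None:
        return []
    anchor = panel.variants[i]
    a = panel.dosages[:, i]
    out: list[ProxyCandidate] = []
    for j, v in enumerate(panel.variants):
        if j == i or v.chrom != anchor.chrom:
            continue
        dist = abs(v.pos - anchor.pos)
        if dist > cfg.window_bp:
            continue
        try:
            r2 = r_squared(a, panel.dosages[:, j])
        except LdUndefinedError:
            continue
        if r2 >= cfg.r2_min:
            out.append(ProxyCandidate(index=anchor, proxy=v, r2=r2, distance_bp=dist))
    out.sort(key=lambda c: (-c.r2, c.distance_bp, c.proxy.pos))
    return out


def best_proxy(
    index: VariantKey, available: ArrayVariantSet, cfg: LdSearchConfig
) -> ProxyCandidate | None:
    """Highest-ranked proxy of ``index`` that is present in ``available``.

    The ranking is :func:`find_proxies` order (highest r^2, then closest);
    returns ``None`` when no kept proxy is on the array.
    """
    for cand in find_proxies(index, cfg):
        if cand.proxy in available:
            return cand
    return None


def proxy_table(candidates: list[ProxyCandidate], panel: GenotypePanel):
    """Proxy list as a DataFrame: rsids, r^2, MAFs and their mean, distance."""
    import pandas as pd

    from .qc import minor_allele_frequency

    rows = []
    for c in candidates:
        i = panel.find(c.index)
        j = panel.find(c.proxy)
        maf_i = minor_allele_frequency(panel.dosages[:, i]) if i is not None else np.nan
        maf_p = minor_allele_frequency(panel.dosages[:, j]) if j is not None else np.nan
        rows.append({
            "index_rsid": c.index.rsid or f"{c.index.chrom}:{c.index.pos}",
            "proxy_rsid": c.proxy.rsid or f"{c.proxy.chrom}:{c.proxy.pos}",
            "r2": c.r2,
            "index_maf": maf_i,
            "proxy_maf": maf_p,
            "average_maf": np.nanmean([maf_i, maf_p]),
            "distance_bp": c.distance_bp,
        })
    return pd.DataFrame(rows, columns=[
        "index_rsid", "proxy_rsid", "r2", "index_maf", "proxy_maf",
        "average_maf", "distance_bp",
    ])
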