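"""Readers and writers for the external formats the tool touches.

Genotype panels come in as VCF (plain or bgzipped, via cyvcf2) and live in
memory as a samples x variants dosage matrix.  Discovery summary statistics
and array variant lists are delimited tables read with pandas.  All reports
go out as TSV.

Coordinate convention: 1-based positions throughout (VCF convention).
Missing dosages are ``numpy.nan`` — absence, not a number in [0, 2].
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violated the expected layout (missing columns, bad values)."""


class VariantKey(NamedTuple):
    """Identity of a variant: chromosome, 1-based position, rsid, alleles.

    ``rsid`` may be the empty string.  Alleles are uppercase strings over
    {A,C,G,T}; longer strings denote indels.
    """

    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_biallelic_snp(self) -> bool:
        # multi-allelic records are split on read, so a single-ALT SNP row
        # is biallelic by construction
        return self.is_snp and self.ref != self.alt


def _validate_key(key: VariantKey) -> None:
    if not key.chrom:
        raise ValueError(f"empty chromosome in {key!r}")
    if key.pos < 1:
        raise ValueError(f"position must be >= 1, got {key.pos}")


@dataclass
class GenotypePanel:
    """Samples x variants effect-allele (ALT) dosage matrix with metadata.

    Parameters
    ----------
    variants
        Ordered variant keys, sorted by (chrom, pos).
    samples
        Sample identifiers, one per matrix row.
    dosages
        ``(n_samples, n_variants)`` float array of ALT-allele dosage in
        [0, 2]; ``nan`` marks a missing genotype.
    info
        Optional per-variant imputation quality in [0, 1] (squared
        correlation between imputed and true genotype).  ``None`` for
        directly typed panels.
    """

    variants: list[VariantKey]
    samples: list[str]
    dosages: np.ndarray
    info: np.ndarray | None = None

    _pos_index: dict = field(default=None, repr=False, compare=False)
    _rsid_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")
        for k in self.variants:
            _validate_key(k)
        order = sorted(
            range(len(self.variants)),
            key=lambda i: (_chrom_rank(self.variants[i].chrom), self.variants[i].pos),
        )
        if order != list(range(len(self.variants))):
            self.variants = [self.variants[i] for i in order]
            self.dosages = self.dosages[:, order]
            if self.info is not None:
                self.info = np.asarray(self.info, dtype=float)[order]
        if self.info is not None:
            self.info = np.asarray(self.info, dtype=float)
            if self.info.shape != (len(self.variants),):
                raise ValueError("info length does not match variant count")
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._pos_index = {}
        self._rsid_index = {}
        for i, v in enumerate(self.variants):
            self._pos_index.setdefault((v.chrom, v.pos), i)
            if v.rsid:
                self._rsid_index.setdefault(v.rsid, i)

    # -- lookups ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def find(self, key: VariantKey) -> int | None:
        """Index of ``key`` in the panel: (chrom, pos) first, rsid fallback."""
        i = self._pos_index.get((key.chrom, key.pos))
        if i is not None:
            return i
        if key.rsid:
            return self._rsid_index.get(key.rsid)
        return None

    def alt_frequency(self, j: int) -> float:
        """ALT allele frequency at variant ``j`` over non-missing samples."""
        col = self.dosages[:, j]
        m = ~np.isnan(col)
        if not m.any():
            raise ValueError(f"all dosages missing at variant {self.variants[j]}")
        return float(col[m].mean() / 2.0)

    # -- subsetting ------------------------------------------------------

    def take_variants(self, idx: Sequence[int]) -> "GenotypePanel":
        idx = list(idx)
        return GenotypePanel(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            dosages=self.dosages[:, idx].copy(),
            info=None if self.info is None else self.info[idx].copy(),
        )

    def take_samples(self, idx: Sequence[int]) -> "GenotypePanel":
        idx = list(idx)
        return GenotypePanel(
            variants=list(self.variants),
            samples=[self.samples[i] for i in idx],
            dosages=self.dosages[idx, :].copy(),
            info=None if self.info is None else self.info.copy(),
        )


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def _chrom_rank(chrom: str):
    c = chrom.removeprefix("chr")
    r = _CHROM_ORDER.get(c)
    return (0, r, "") if r is not None else (1, 0, c)


@dataclass
class SummaryStats:
    """Per-variant discovery GWAS results.

    Backed by a DataFrame with columns ``chrom, pos, rsid, effect_allele,
    other_allele, beta, odds_ratio, pvalue, maf``.  ``beta`` is the
    log-odds effect of the effect allele.
    """

    df: pd.DataFrame

    COLUMNS = (
        "chrom", "pos", "rsid", "effect_allele", "other_allele",
        "beta", "odds_ratio", "pvalue", "maf",
    )

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"summary stats missing columns: {missing}")
        df = self.df
        if ((df["pvalue"] <= 0) | (df["pvalue"] > 1)).any():
            raise ValueError("p-values outside (0, 1]")
        both = df["beta"].notna() & df["odds_ratio"].notna()
        if both.any():
            dev = np.abs(df.loc[both, "beta"] - np.log(df.loc[both, "odds_ratio"]))
            if (dev > 1e-9).any():
                raise ValueError("beta inconsistent with ln(odds_ratio)")
        dup = df.duplicated(subset=["chrom", "pos", "effect_allele", "other_allele"])
        if dup.any():
            first = df[dup].iloc[0]
            raise FormatError(
                f"duplicate summary-stat record at {first['chrom']}:{first['pos']} "
                f"{first['effect_allele']}/{first['other_allele']}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.rsid or ""),
                       str(r.other_allele), str(r.effect_allele))
            for r in self.df.itertuples()
        ]

    def restrict(self, mask: np.ndarray) -> "SummaryStats":
        return SummaryStats(self.df[np.asarray(mask, dtype=bool)].reset_index(drop=True))


@dataclass
class ArrayVariantSet:
    """A named set of variant keys with O(1) membership by (chrom, pos) and rsid.

    Emulates an array manifest or a cohort's surviving variant list; allele
    columns are optional for membership purposes.
    """

    name: str
    keys: list[VariantKey]

    def __post_init__(self):
        if not self.keys:
            raise FormatError(f"array variant set '{self.name}' is empty")
        self._by_pos = {(k.chrom, k.pos) for k in self.keys}
        self._by_rsid = {k.rsid for k in self.keys if k.rsid}

    def __len__(self) -> int:
        return len(self.keys)

    def match(self, key: VariantKey) -> str | None:
        """How ``key`` is covered: ``"pos"``, ``"rsid"`` or ``None``.

        (chrom, pos) takes precedence; rsid is the fallback, flagged so a
        caller can report rsid-only matches (e.g. genome-build slippage).
        """
        if (key.chrom, key.pos) in self._by_pos:
            return "pos"
        if key.rsid and key.rsid in self._by_rsid:
            return "rsid"
        return None

    def __contains__(self, key: VariantKey) -> bool:
        return self.match(key) is not None


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_QUALITY_FIELDS = ("R2", "DR2", "INFO")


def read_vcf(
    path: str,
    dosage_field_preference: Sequence[str] = ("DS", "GT"),
    multiallelic: str = "split",
) -> GenotypePanel:
    """Read a VCF (plain or gzipped) into a :class:`GenotypePanel`.

    Dosage is the ALT-allele count (or the ``DS`` FORMAT field when
    preferred and present).  Multi-allelic records are split into one
    biallelic row per ALT (``multiallelic="split"``) or dropped
    (``"drop"``).  An imputation-quality INFO field (R2/DR2/INFO) is
    captured into ``panel.info`` when present on every kept record.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("split", "drop"):
        raise ValueError("multiallelic must be 'split' or 'drop'")

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no samples, cannot build a dosage panel")

    variants: list[VariantKey] = []
    cols: list[np.ndarray] = []
    infos: list[float] = []
    any_info = False

    for rec in vcf:
        alts = rec.ALT or []
        if len(alts) > 1 and multiallelic == "drop":
            continue
        qual = None
        for f in _INFO_QUALITY_FIELDS:
            q = rec.INFO.get(f)
            if q is not None:
                try:
                    qual = float(q)
                except (TypeError, ValueError):
                    qual = None
                break
        ds = None
        for fld in dosage_field_preference:
            if fld == "GT":
                break
            try:
                raw = rec.format(fld)
            except KeyError:
                raw = None
            if raw is not None:
                ds = np.asarray(raw, dtype=float).reshape(len(samples), -1)
                break
        for ai, alt in enumerate(alts):
            key = VariantKey(
                chrom=str(rec.CHROM), pos=int(rec.POS),
                rsid=(rec.ID or ""), ref=str(rec.REF).upper(), alt=str(alt).upper(),
            )
            if ds is not None and ds.shape[1] >= len(alts):
                col = ds[:, ai].astype(float)
                col = np.where((col < 0) | (col > 2), np.nan, col)
            else:
                gt = np.asarray(rec.genotype.array())  # (n_samples, ploidy+1)
                alleles = gt[:, :-1]
                missing = (alleles < 0).any(axis=1)
                col = (alleles == ai + 1).sum(axis=1).astype(float)
                col[missing] = np.nan
            variants.append(key)
            cols.append(col)
            infos.append(qual if qual is not None else np.nan)
            if qual is not None:
                any_info = True
    vcf.close()

    if not variants:
        raise FormatError(f"{path}: no usable variant records")
    dos = np.column_stack(cols)
    info = np.asarray(infos) if any_info else None
    if info is not None:
        info = np.where(np.isnan(info), 1.0, info)  # untyped quality -> assume measured
    return GenotypePanel(variants=variants, samples=samples, dosages=dos, info=info)


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as a minimal VCF 4.2 with GT (and DS for fractional dosage)."""
    fractional = bool(np.any(~np.isnan(panel.dosages) & (panel.dosages % 1 != 0)))
    fmt = "GT:DS" if fractional else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if fractional:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        if panel.info is not None:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        for chrom in dict.fromkeys(v.chrom for v in panel.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 + "FORMAT\t" + "\t".join(panel.samples) + "\n")
        for j, v in enumerate(panel.variants):
            info_s = "." if panel.info is None else f"R2={panel.info[j]:.4f}"
            cells = []
            for s in range(panel.n_samples):
                d = panel.dosages[s, j]
                if np.isnan(d):
                    gt = "./."
                    ds = "."
                else:
                    hard = int(round(d))
                    gt = ("0/0", "0/1", "1/1")[hard]
                    ds = f"{d:g}"
                cells.append(f"{gt}:{ds}" if fractional else gt)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t"
                f"{info_s}\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "chrom": "chrom",
    "pos": "pos",
    "rsid": "rsid",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "odds_ratio": "odds_ratio",
    "pvalue": "pvalue",
    "maf": "maf",
}


def _read_table(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith((".csv", ".csv.gz")) else "\t"
    return pd.read_csv(path, sep=sep, dtype={"chrom": str})


def read_summary_stats(
    path: str, column_map: Mapping[str, str] | None = None
) -> tuple[SummaryStats, int]:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical names (:attr:`SummaryStats.COLUMNS`) to
    the file's column names; unmapped canonical names default to
    themselves.  Either ``beta`` or ``odds_ratio`` must resolve; the other
    is derived (beta = ln OR).  Rows with p-values outside (0, 1] are
    dropped; their count is returned alongside the stats.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = _read_table(path)

    out = pd.DataFrame()
    for canon in SummaryStats.COLUMNS:
        src = cmap.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
    mandatory = {"chrom", "pos", "effect_allele", "other_allele", "pvalue"}
    absent = sorted(mandatory - set(out.columns))
    if absent:
        raise FormatError(f"{path}: missing mandatory columns {absent}")
    if "beta" not in out.columns and "odds_ratio" not in out.columns:
        raise FormatError(f"{path}: need a beta or odds_ratio column")

    if "beta" not in out.columns:
        out["beta"] = np.log(out["odds_ratio"].astype(float))
    if "odds_ratio" not in out.columns:
        out["odds_ratio"] = np.exp(out["beta"].astype(float))
    if "rsid" not in out.columns:
        out["rsid"] = ""
    if "maf" not in out.columns:
        out["maf"] = np.nan

    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(int)
    out["rsid"] = out["rsid"].fillna("").astype(str)
    for c in ("effect_allele", "other_allele"):
        out[c] = out[c].astype(str).str.upper()
    ok = (out["pvalue"] > 0) & (out["pvalue"] <= 1)
    n_rejected = int((~ok).sum())
    out = out[ok].reset_index(drop=True)
    return SummaryStats(out[list(SummaryStats.COLUMNS)]), n_rejected


def write_summary_stats(stats: SummaryStats, path: str) -> None:
    stats.df.to_csv(path, sep="\t", index=False)


def hit_table_summary(stats: SummaryStats) -> dict:
    """Descriptive summary of a top-hits table.

    Reports the counts and ranges a hit list is usually characterised by:
    total variants, biallelic-SNP count, odds-ratio range, and the minimum
    minor allele frequency (NaN when no MAF column is populated).
    """
    df = stats.df
    n_biallelic = sum(
        len(e) == 1 and len(o) == 1 and {e, o} <= set("ACGT") and e != o
        for e, o in zip(df["effect_allele"], df["other_allele"])
    )
    maf = df["maf"].astype(float)
    return {
        "n_variants": int(len(df)),
        "n_biallelic": int(n_biallelic),
        "odds_ratio_min": float(df["odds_ratio"].min()),
        "odds_ratio_max": float(df["odds_ratio"].max()),
        "maf_min": float(maf.min()) if maf.notna().any() else float("nan"),
        "pvalue_max": float(df["pvalue"].max()),
    }


# ---------------------------------------------------------------------------
# Array variant lists (manifest-style)
# ---------------------------------------------------------------------------

def read_array_variant_list(path: str, name: str | None = None) -> tuple[ArrayVariantSet, int]:
    """Read an array manifest-like variant list.

    Needs at least an rsid column (``rsid``/``Name``/``name``/``id``) or
    chromosome+position columns (``chrom``/``Chr``, ``pos``/``MapInfo``).
    Rows carrying neither identifier are skipped; the skip count is
    returned with the set.
    """
    raw = _read_table(path)
    cols = {c.lower(): c for c in raw.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    c_rsid = pick("rsid", "name", "id", "snp")
    c_chrom = pick("chrom", "chr", "chromosome")
    c_pos = pick("pos", "position", "mapinfo", "bp")
    c_ref = pick("ref", "ref_allele", "other_allele")
    c_alt = pick("alt", "alt_allele", "effect_allele")
    if c_rsid is None and (c_chrom is None or c_pos is None):
        raise FormatError(f"{path}: need an rsid column or chrom+pos columns")

    keys: list[VariantKey] = []
    n_skipped = 0
    for _, row in raw.iterrows():
        rsid = str(row[c_rsid]) if c_rsid is not None and pd.notna(row[c_rsid]) else ""
        has_pos = (
            c_chrom is not None and c_pos is not None
            and pd.notna(row[c_chrom]) and pd.notna(row[c_pos])
        )
        if not rsid and not has_pos:
            n_skipped += 1
            continue
        keys.append(VariantKey(
            chrom=str(row[c_chrom]) if has_pos else "0",
            pos=int(row[c_pos]) if has_pos else 1,
            rsid=rsid,
            ref=str(row[c_ref]).upper() if c_ref is not None and pd.notna(row[c_ref]) else "",
            alt=str(row[c_alt]).upper() if c_alt is not None and pd.notna(row[c_alt]) else "",
        ))
    return ArrayVariantSet(name=name or os.path.basename(str(path)), keys=keys), n_skipped


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        if x != 0 and abs(x) < 1e-3:
            return f"{x:.4g}"  # keep tiny p-value thresholds legible
        return f"{x:.4f}"
    return str(x)


def write_report(report, path: str) -> None:
    """Write a report object with a ``to_frame()`` method as TSV.

    Floats are rendered at 4 decimals; NaN as ``NA``.  Writes are atomic
    (temp file + rename).
    """
    df = report.to_frame()
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_fmt(x) for x in row) + "\n")
    os.replace(tmp, path)
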