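"""Hard-filter cascade for annotated somatic variant calls.

Eleven criteria remove sequencing artifacts, germline polymorphisms and
low-confidence calls from pre-annotated variant records.  Filtering is
exhaustive rather than short-circuiting: every failed criterion is
recorded per record, so the audit table shows exactly which rule
removed each variant.

The criteria (a record FAILS when the condition holds):

1.  upstream caller filter not passed
2.  alternative-read fraction <= 5%
3.  total depth <= 5 or alternative-read depth <= 3
4.  QUAL < 30
5.  dbNSFP impact "low"
6.  common SNP (dbSNP)
7.  any population allele frequency (ExAC, ESP global, ESP6500 MAF_EA)
    above 0.001
8.  MAPQ < 40 for recurrent-in-COSMIC (>= 100 cases) or breast-cancer
    hotspot-gene variants
9.  MAPQ < 55 for all other variants (the hotspot/COSMIC-recurrent
    branch is exempt from this stricter tier)
10. variant present in more than one sample while having fewer than
    100 COSMIC cases (likely a recurrent artifact)
11. variant with zero COSMIC cases whose impact is only "moderate"

Presence in multiple samples (criterion 10) is recomputed over the
whole table, keyed by chrom/pos/ref/alt, so verdicts are independent of
record order.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable

import pandas as pd

HOTSPOT_GENES = frozenset({"TP53", "PIK3CA", "GATA3", "MAP3K1", "KMT2C"})
VALID_IMPACTS = ("high", "moderate", "low", "modifier")
ALL_CRITERIA = tuple(range(1, 12))


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call in one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    caller_pass: bool
    alt_fraction: float
    total_depth: int
    alt_depth: int
    qual: float
    mapq: float
    dbnsfp_impact: str
    is_common_snp: bool
    af_exac: float
    af_esp_global: float
    maf_ea: float
    cosmic_case_count: int
    n_samples_with_variant: int = 1

    def __post_init__(self):
        if self.total_depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.alt_depth > self.total_depth:
            raise ValueError("alt_depth cannot exceed total_depth")
        if self.dbnsfp_impact not in VALID_IMPACTS:
            raise ValueError(f"invalid dbNSFP impact {self.dbnsfp_impact!r}")
        if not 0 <= self.alt_fraction <= 1:
            raise ValueError("alt_fraction must lie in [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_criteria: tuple[int, ...]

    def __post_init__(self):
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed must mirror empty failed_criteria")


def apply_filters(
    record: VariantRecord,
    hotspot_genes: Iterable[str] = HOTSPOT_GENES,
    cosmic_recurrent_min: int = 100,
) -> FilterVerdict:
    """Evaluate all eleven criteria on one fully annotated record."""
    hotspots = set(hotspot_genes)
    r = record
    trusted = r.cosmic_case_count >= cosmic_recurrent_min or r.gene in hotspots
    failed = []
    if not r.caller_pass:
        failed.append(1)
    if r.alt_fraction <= 0.05:
        failed.append(2)
    if r.total_depth <= 5 or r.alt_depth <= 3:
        failed.append(3)
    if r.qual < 30:
        failed.append(4)
    if r.dbnsfp_impact == "low":
        failed.append(5)
    if r.is_common_snp:
        failed.append(6)
    if max(r.af_exac, r.af_esp_global, r.maf_ea) > 0.001:
        failed.append(7)
    if r.mapq < 40 and trusted:
        failed.append(8)
    if r.mapq < 55 and not trusted:
        failed.append(9)
    if r.n_samples_with_variant > 1 and r.cosmic_case_count < cosmic_recurrent_min:
        failed.append(10)
    if r.cosmic_case_count == 0 and r.dbnsfp_impact == "moderate":
        failed.append(11)
    return FilterVerdict(not failed, tuple(failed))


def filter_table(
    records: list[VariantRecord],
    hotspot_genes: Iterable[str] = HOTSPOT_GENES,
    cosmic_recurrent_min: int = 100,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Filter a variant table; returns (kept records, audit table).

    ``n_samples_with_variant`` is recomputed across the table before
    applying criterion 10, counting distinct samples per variant key.
    """
    sample_sets: dict[tuple, set] = {}
    for r in records:
        sample_sets.setdefault(r.key, set()).add(r.sample_id)
    updated = [
        replace(r, n_samples_with_variant=len(sample_sets[r.key])) for r in records
    ]
    kept, rows = [], []
    for r in updated:
        verdict = apply_filters(r, hotspot_genes, cosmic_recurrent_min)
        if verdict.passed:
            kept.append(r)
        rows.append(
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "passed": verdict.passed,
                "failed_criteria": ",".join(map(str, verdict.failed_criteria)),
            }
        )
    return kept, pd.DataFrame(rows)


_ANNOTATION_COLUMNS = [
    f.name for f in fields(VariantRecord) if f.name != "n_samples_with_variant"
]


def read_annotated_variants(annotations_tsv) -> list[VariantRecord]:
    """Read a variant annotation sidecar TSV into records.

    The TSV must carry one column per :class:`VariantRecord` field
    (``n_samples_with_variant`` optional; it is recomputed anyway).
    A missing column is an error, never a silent pass.
    """
    df = pd.read_csv(annotations_tsv, sep="\t")
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        for c in _ANNOTATION_COLUMNS:
            if pd.isna(row[c]):
                raise ValueError(
                    f"missing annotation {c!r} for "
                    f"{row['chrom']}:{row['pos']} in sample {row['sample_id']}"
                )
        records.append(
            VariantRecord(
                sample_id=str(row["sample_id"]),
                gene=str(row["gene"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                caller_pass=_as_bool(row["caller_pass"]),
                alt_fraction=float(row["alt_fraction"]),
                total_depth=int(row["total_depth"]),
                alt_depth=int(row["alt_depth"]),
                qual=float(row["qual"]),
                mapq=float(row["mapq"]),
                dbnsfp_impact=str(row["dbnsfp_impact"]),
                is_common_snp=_as_bool(row["is_common_snp"]),
                af_exac=float(row["af_exac"]),
                af_esp_global=float(row["af_esp_global"]),
                maf_ea=float(row["maf_ea"]),
                cosmic_case_count=int(row["cosmic_case_count"]),
            )
        )
    return records


def write_annotated_variants(records: list[VariantRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes", "pass")
    return bool(value)


def filter_vcf(
    vcf_in,
    annotations_tsv,
    vcf_out,
    audit_tsv,
    hotspot_genes: Iterable[str] = HOTSPOT_GENES,
) -> tuple[int, int]:
    """Filter a VCF using its annotation sidecar.

    Records in the VCF are matched to annotations by sample/chrom/pos/
    ref/alt; passing records are written to ``vcf_out`` and the full
    audit to ``audit_tsv``.  Returns (n_in, n_kept).
    """
    import pysam

    records = read_annotated_variants(annotations_tsv)
    kept, audit = filter_table(records, hotspot_genes)
    kept_keys = {r.key for r in kept}
    n_in = n_kept = 0
    with pysam.VariantFile(str(vcf_in)) as fin:
        with pysam.VariantFile(str(vcf_out), "w", header=fin.header) as fout:
            for rec in fin:
                n_in += 1
                for alt in rec.alts or ():
                    if (str(rec.chrom), int(rec.pos), rec.ref, alt) in kept_keys:
                        fout.write(rec)
                        n_kept += 1
                        break
    audit.to_csv(audit_tsv, sep="\t", index=False)
    return n_in, n_kept
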