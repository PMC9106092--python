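"""Readers, writers and consensus handling for small somatic-variant cohorts.

The study design this package targets sequences a handful of tumors (one per
patient, no matched normal pool shared across callers) and calls somatic
variants with two independent pipelines.  The per-sample unit of exchange is a
small TSV "variant matrix" holding, per variant, an identifier, the mutant and
reference read counts and the annotated gene.  Variants reported by both
callers are retained as reliable; everything downstream (spectra, phylogeny)
runs on those consensus calls.

Coordinates are 1-based and fully closed (VCF convention).  MAF-style "-"
alleles for indels are normalized on ingestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "VariantRecord",
    "SampleVariantSet",
    "CohortTable",
    "CallerOutput",
    "FormatError",
    "read_cohort_table",
    "write_cohort_table",
    "read_variant_matrix",
    "write_variant_matrix",
    "read_maf",
    "read_vcf",
    "consensus_calls",
    "vaf",
    "normalize_gene_symbol",
]

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "splice_site",
    "frameshift_ins",
    "frameshift_del",
    "silent",
    "other",
)
VARIANT_TYPES = ("SNP", "INS", "DEL")

CLINICAL_DX = ("cushing_disease", "non_functioning", "nelson")
PATH_DX = (
    "acth_carcinoma",
    "crooke_cell_adenoma",
    "silent_acth_adenoma",
    "acth_adenoma",
)

#: Symbol fixes applied on every ingestion path.  The published cohort table
#: contains "HSDB3B1" where HSD3B1 (3-beta-hydroxysteroid dehydrogenase) is
#: meant, plus stray whitespace and trailing commas.
GENE_SYMBOL_FIXES: Mapping[str, str] = {
    "HSDB3B1": "HSD3B1",
}

_DNA = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the documented column dialect."""


def normalize_gene_symbol(raw: str) -> str:
    """Strip whitespace/punctuation noise and apply the known-typo table."""
    sym = raw.strip().strip(",").strip()
    return GENE_SYMBOL_FIXES.get(sym, sym)


def _infer_variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1 and ref in _DNA and alt in _DNA:
        return "SNP"
    if ref == "-" or len(alt) > len(ref):
        return "INS"
    return "DEL"


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant observed in one sample.

    ``mut_reads``/``ref_reads`` may both be ``None`` for sources that carry no
    allele depths (e.g. a VCF without AD); such records are treated as present
    when allele-fraction filtering is applied.
    """

    variant_id: str
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    gene: str = ""
    mut_reads: int | None = None
    ref_reads: int | None = None
    variant_class: str = "other"
    variant_type: str | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if (self.mut_reads is None) != (self.ref_reads is None):
            raise ValueError("mut_reads and ref_reads must be set together")
        if self.mut_reads is not None:
            if self.mut_reads < 0 or self.ref_reads < 0:
                raise ValueError("read counts must be non-negative")
            if self.mut_reads + self.ref_reads < 1:
                raise ValueError("mut_reads + ref_reads must be >= 1")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_type is None and self.ref and self.alt:
            object.__setattr__(
                self, "variant_type", _infer_variant_type(self.ref, self.alt)
            )
        if self.variant_type is not None and self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")

    @property
    def match_key(self) -> tuple:
        """Identity used for cross-caller concordance.

        Positional identity ``(chrom, pos, ref, alt)`` when the positional
        fields exist, else the raw ``variant_id`` string.
        """
        if self.chrom is not None and self.pos is not None and self.ref and self.alt:
            return (self.chrom, self.pos, self.ref, self.alt)
        return (self.variant_id,)

    @property
    def total_reads(self) -> int | None:
        if self.mut_reads is None:
            return None
        return self.mut_reads + self.ref_reads

    def vaf(self) -> float:
        return vaf(self)


def vaf(record: VariantRecord) -> float:
    """Variant allele fraction: mutant reads over total reads at the site."""
    if record.mut_reads is None:
        raise ValueError(f"{record.variant_id}: no read counts, VAF undefined")
    total = record.mut_reads + record.ref_reads
    if total < 1:
        raise ValueError(f"{record.variant_id}: zero total reads, VAF undefined")
    return record.mut_reads / total


@dataclass
class SampleVariantSet:
    """All variants called in one sample, keyed by unique ``variant_id``."""

    sample_id: str
    records: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        dupes = self._duplicate_ids()
        if dupes:
            raise ValueError(
                f"sample {self.sample_id}: duplicate variant_id(s): {sorted(dupes)}"
            )

    def _duplicate_ids(self) -> set[str]:
        seen: set[str] = set()
        dup: set[str] = set()
        for r in self.records:
            (dup if r.variant_id in seen else seen).add(r.variant_id)
        return dup

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def match_keys(self) -> dict[tuple, VariantRecord]:
        return {r.match_key: r for r in self.records}


@dataclass(frozen=True)
class CallerOutput:
    """One caller's variant set for one sample."""

    caller_name: str
    variants: SampleVariantSet


def consensus_calls(a: SampleVariantSet, b: SampleVariantSet) -> SampleVariantSet:
    """Intersect two callers' variant sets for the same sample.

    Variants reported by both callers are the reliable calls.  Matching uses
    positional identity where available (``VariantRecord.match_key``); read
    counts and annotations in the result come from caller ``a``, the declared
    primary caller — counts are never merged across callers.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(
            f"sample_id mismatch: {a.sample_id!r} vs {b.sample_id!r}"
        )
    b_keys = set(r.match_key for r in b.records)
    kept = [r for r in a.records if r.match_key in b_keys]
    return SampleVariantSet(sample_id=a.sample_id, records=kept)


# ---------------------------------------------------------------------------
# Cohort clinical table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "tumor_id",
    "age",
    "sex",
    "clinical_dx",
    "path_dx",
    "max_diameter_mm",
    "cav_sinus_invasion",
    "vision_abnormal",
    "surgeries",
    "snv_genes",
]


@dataclass
class Tumor:
    tumor_id: str
    age: int
    sex: str
    clinical_dx: str
    path_dx: str
    max_diameter_mm: int
    cav_sinus_invasion: bool
    vision_abnormal: bool
    surgeries: str
    snv_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"{self.tumor_id}: age must be > 0")
        if self.max_diameter_mm <= 0:
            raise ValueError(f"{self.tumor_id}: max_diameter_mm must be > 0")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.tumor_id}: sex must be F or M")
        if self.clinical_dx not in CLINICAL_DX:
            raise ValueError(f"{self.tumor_id}: unknown clinical_dx {self.clinical_dx!r}")
        if self.path_dx not in PATH_DX:
            raise ValueError(f"{self.tumor_id}: unknown path_dx {self.path_dx!r}")

    @property
    def functional_status(self) -> str:
        """``silent`` for clinically non-functioning tumors, else ``functioning``."""
        return "silent" if self.clinical_dx == "non_functioning" else "functioning"


@dataclass
class CohortTable:
    """Per-tumor clinical annotations plus the recurrent-SNV gene lists."""

    tumors: list[Tumor] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.tumor_id for t in self.tumors]
        if len(set(ids)) != len(ids):
            raise ValueError("tumor_ids must be unique")

    def __len__(self) -> int:
        return len(self.tumors)

    def __iter__(self) -> Iterator[Tumor]:
        return iter(self.tumors)

    def __getitem__(self, tumor_id: str) -> Tumor:
        for t in self.tumors:
            if t.tumor_id == tumor_id:
                return t
        raise KeyError(tumor_id)

    @property
    def tumor_ids(self) -> list[str]:
        return [t.tumor_id for t in self.tumors]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tumors:
            rows.append(
                {
                    "tumor_id": t.tumor_id,
                    "age": t.age,
                    "sex": t.sex,
                    "clinical_dx": t.clinical_dx,
                    "path_dx": t.path_dx,
                    "max_diameter_mm": t.max_diameter_mm,
                    "cav_sinus_invasion": t.cav_sinus_invasion,
                    "vision_abnormal": t.vision_abnormal,
                    "surgeries": t.surgeries,
                    "snv_genes": ", ".join(sorted(t.snv_genes)),
                    "functional_status": t.functional_status,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_COLUMNS + ["functional_status"])


_BOOL_TOKENS = {
    "yes": True, "y": True, "true": True, "1": True,
    "no": False, "n": False, "false": False, "0": False,
}


def _parse_bool(token: str, row_idx: int, column: str) -> bool:
    try:
        return _BOOL_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise FormatError(
            f"row {row_idx}: cannot parse {column}={token!r} as yes/no"
        ) from None


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read the cohort clinical TSV.

    Gene symbols in ``snv_genes`` are normalized (typo table, whitespace,
    trailing commas).  Raises :class:`FormatError` naming any missing column;
    non-numeric age/diameter raise a row-indexed parse error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    tumors: list[Tumor] = []
    for idx, row in df.iterrows():
        try:
            age = int(row["age"])
            diameter = int(row["max_diameter_mm"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx}: non-numeric value: {exc}") from None
        genes = frozenset(
            normalize_gene_symbol(g)
            for g in str(row["snv_genes"]).split(",")
            if normalize_gene_symbol(g)
        )
        tumors.append(
            Tumor(
                tumor_id=str(row["tumor_id"]),
                age=age,
                sex=str(row["sex"]).strip(),
                clinical_dx=str(row["clinical_dx"]).strip(),
                path_dx=str(row["path_dx"]).strip(),
                max_diameter_mm=diameter,
                cav_sinus_invasion=_parse_bool(row["cav_sinus_invasion"], idx, "cav_sinus_invasion"),
                vision_abnormal=_parse_bool(row["vision_abnormal"], idx, "vision_abnormal"),
                surgeries=str(row["surgeries"]),
                snv_genes=genes,
            )
        )
    return CohortTable(tumors=tumors)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame()[COHORT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant matrix TSV
# ---------------------------------------------------------------------------

MATRIX_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "mut_reads",
    "ref_reads",
    "variant_class",
]

_MISSING = "."


def read_variant_matrix(path: str | Path, sample_id: str) -> SampleVariantSet:
    """Read one sample's variant matrix TSV into a :class:`SampleVariantSet`.

    The dialect is tab-delimited with header ``variant_id chrom pos ref alt
    gene mut_reads ref_reads variant_class`` and ``.`` for missing values;
    ``chrom``/``pos``/``ref``/``alt`` may be missing when ``variant_id``
    encodes them.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'variant_id'")
    records: list[VariantRecord] = []
    for idx, row in df.iterrows():
        def get(col: str) -> str | None:
            v = str(row[col]).strip() if col in df.columns else _MISSING
            return None if v in (_MISSING, "") else v

        mut, refr = get("mut_reads"), get("ref_reads")
        if (mut is None) != (refr is None):
            raise FormatError(f"{path}: row {idx}: mut_reads/ref_reads must both be set")
        try:
            mut_i = int(mut) if mut is not None else None
            ref_i = int(refr) if refr is not None else None
            pos_s = get("pos")
            pos_i = int(pos_s) if pos_s is not None else None
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx}: {exc}") from None
        if mut_i is not None and (mut_i < 0 or ref_i < 0):
            raise FormatError(f"{path}: row {idx}: negative read count")
        gene = get("gene")
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                chrom=get("chrom"),
                pos=pos_i,
                ref=get("ref"),
                alt=get("alt"),
                gene=normalize_gene_symbol(gene) if gene else "",
                mut_reads=mut_i,
                ref_reads=ref_i,
                variant_class=get("variant_class") or "other",
            )
        )
    try:
        return SampleVariantSet(sample_id=sample_id, records=records)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_variant_matrix(variants: SampleVariantSet, path: str | Path) -> None:
    rows = []
    for r in variants.records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom if r.chrom is not None else _MISSING,
                "pos": r.pos if r.pos is not None else _MISSING,
                "ref": r.ref if r.ref is not None else _MISSING,
                "alt": r.alt if r.alt is not None else _MISSING,
                "gene": r.gene or _MISSING,
                "mut_reads": r.mut_reads if r.mut_reads is not None else _MISSING,
                "ref_reads": r.ref_reads if r.ref_reads is not None else _MISSING,
                "variant_class": r.variant_class,
            }
        )
    pd.DataFrame(rows, columns=MATRIX_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Optional MAF / VCF ingestion
# ---------------------------------------------------------------------------

_MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Frame_Shift_Ins": "frameshift_ins",
    "Frame_Shift_Del": "frameshift_del",
    "Silent": "silent",
}


def _normalize_maf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # MAF marks the missing side of an indel with "-"; re-anchor to the
    # VCF-style representation with a placeholder anchor base.
    if ref == "-":
        return max(pos - 1, 1), "N", "N" + alt
    if alt == "-":
        return max(pos - 1, 1), "N" + ref, "N"
    return pos, ref, alt


def read_maf(path: str | Path, sample_id: str) -> SampleVariantSet:
    """Read a TCGA-style MAF, keeping rows for ``sample_id`` (Tumor_Sample_Barcode)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    required = [
        "Hugo_Symbol", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Tumor_Sample_Barcode",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing MAF column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        if str(row["Tumor_Sample_Barcode"]) != sample_id:
            continue
        pos, ref, alt = _normalize_maf_alleles(
            int(row["Start_Position"]),
            str(row["Reference_Allele"]),
            str(row["Tumor_Seq_Allele2"]),
        )
        chrom = str(row["Chromosome"])
        mut = row.get("t_alt_count", "")
        refr = row.get("t_ref_count", "")
        has_counts = str(mut).isdigit() and str(refr).isdigit()
        records.append(
            VariantRecord(
                variant_id=f"{chrom}:{pos}:{ref}>{alt}",
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=normalize_gene_symbol(str(row["Hugo_Symbol"])),
                mut_reads=int(mut) if has_counts else None,
                ref_reads=int(refr) if has_counts else None,
                variant_class=_MAF_CLASS_MAP.get(
                    str(row.get("Variant_Classification", "")), "other"
                ),
            )
        )
    return SampleVariantSet(sample_id=sample_id, records=records)


def read_vcf(path: str | Path, sample_id: str) -> SampleVariantSet:
    """Read a VCF 4.x file via cyvcf2, mapping AD allele depths when present.

    Records without allele depths get unset read counts and are treated as
    present by allele-fraction filtering downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_idx = vcf.samples.index(sample_id) if sample_id in vcf.samples else None
    records = []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        mut = refr = None
        if sample_idx is not None:
            try:
                ad = v.format("AD")
                if ad is not None:
                    refr = int(ad[sample_idx][0])
                    mut = int(ad[sample_idx][1])
            except (KeyError, IndexError, TypeError):
                mut = refr = None
        if mut is not None and mut + refr < 1:
            mut = refr = None
        gene = ""
        try:
            g = v.INFO.get("GENE")
            if g:
                gene = normalize_gene_symbol(str(g))
        except KeyError:
            pass
        records.append(
            VariantRecord(
                variant_id=f"{v.CHROM}:{v.POS}:{v.REF}>{alt}",
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                gene=gene,
                mut_reads=mut,
                ref_reads=refr,
            )
        )
    return SampleVariantSet(sample_id=sample_id, records=records)
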