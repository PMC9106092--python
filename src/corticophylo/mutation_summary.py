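"""Cohort-level mutation summaries.

Covers the standard exome-report panels for a small tumor cohort: variant
classification / variant type tallies, the pyrimidine-normalized six-class
substitution spectrum with its transition/transversion split, the oncoplot
gene-by-sample presence matrix, per-sample rainfall tracks with a kataegis
scan, and cohort demographics.

Kataegis is operationalized as a maximal run of at least six consecutive SNVs
on one chromosome whose mean inter-mutation distance is at most 1000 bp — the
conventional rainfall-plot criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortTable, SampleVariantSet, VariantRecord

__all__ = [
    "SnvClass",
    "GeneSampleMatrix",
    "RainfallTrack",
    "KataegisCall",
    "DemographicsSummary",
    "classify_snv",
    "titv_summary",
    "gene_sample_matrix",
    "rainfall",
    "variant_spectrum",
    "cohort_demographics",
    "SNV_CLASSES",
    "KATAEGIS_MIN_VARIANTS",
    "KATAEGIS_MAX_MEAN_IMD",
]

#: The six pyrimidine-context substitution classes, in conventional order.
SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_TRANSITIONS = frozenset({"C>T", "T>C"})
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

KATAEGIS_MIN_VARIANTS = 6
KATAEGIS_MAX_MEAN_IMD = 1000.0  # bp


@dataclass(frozen=True)
class SnvClass:
    value: str
    is_transition: bool


def classify_snv(ref: str, alt: str) -> SnvClass:
    """Classify a substitution into the pyrimidine-normalized six-class frame.

    Purine-reference substitutions are reverse-complemented so every change is
    reported from a C or T reference (G>A becomes C>T, A>G becomes T>C, ...).
    Transitions are exactly C>T and T>C.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a substitution")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    value = f"{ref}>{alt}"
    return SnvClass(value=value, is_transition=value in _TRANSITIONS)


def titv_summary(
    variants: Iterable[VariantRecord],
) -> tuple[int, int, float | None]:
    """Count transitions and transversions over the SNP-type records.

    Returns ``(ti_count, tv_count, ti_fraction)``; the fraction is ``None``
    when no SNPs are present.
    """
    ti = tv = 0
    for r in variants:
        if r.variant_type != "SNP":
            continue
        if classify_snv(r.ref, r.alt).is_transition:
            ti += 1
        else:
            tv += 1
    total = ti + tv
    return ti, tv, (ti / total if total else None)


@dataclass
class GeneSampleMatrix:
    """Oncoplot backbone: genes x samples presence matrix.

    Rows are ordered by descending carrier count with ties broken by panel
    order; columns follow the cohort's pathological-diagnosis grouping then
    tumor_id, so the layout is deterministic.
    """

    genes: list[str]
    samples: list[str]
    present: np.ndarray  # bool, genes x samples

    def carrier_counts(self) -> dict[str, int]:
        return {g: int(self.present[i].sum()) for i, g in enumerate(self.genes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present, index=self.genes, columns=self.samples)


def gene_sample_matrix(
    cohort: CohortTable, gene_panel: Sequence[str]
) -> GeneSampleMatrix:
    """Build the gene x sample presence matrix from the cohort's SNV gene lists."""
    if not list(gene_panel):
        return GeneSampleMatrix(genes=[], samples=[], present=np.zeros((0, 0), bool))
    path_order = {dx: i for i, dx in enumerate(
        ["acth_carcinoma", "crooke_cell_adenoma", "silent_acth_adenoma", "acth_adenoma"]
    )}
    tumors = sorted(
        cohort.tumors, key=lambda t: (path_order.get(t.path_dx, 99), t.tumor_id)
    )
    samples = [t.tumor_id for t in tumors]
    panel = list(gene_panel)
    present = np.array(
        [[g in t.snv_genes for t in tumors] for g in panel], dtype=bool
    )
    counts = present.sum(axis=1)
    order = sorted(range(len(panel)), key=lambda i: (-counts[i], i))
    return GeneSampleMatrix(
        genes=[panel[i] for i in order],
        samples=samples,
        present=present[order],
    )


@dataclass(frozen=True)
class KataegisCall:
    chrom: str
    start: int
    end: int
    n_variants: int
    mean_imd: float


@dataclass
class RainfallTrack:
    """Per-chromosome sorted positions and inter-mutation distances for one sample."""

    sample_id: str
    positions: dict[str, list[int]] = field(default_factory=dict)
    distances: dict[str, list[int]] = field(default_factory=dict)
    kataegis_calls: list[KataegisCall] = field(default_factory=list)
    has_zero_distance: bool = False


def _scan_kataegis(chrom: str, pos: list[int]) -> list[KataegisCall]:
    # Maximal runs of >= KATAEGIS_MIN_VARIANTS consecutive SNVs with mean
    # inter-mutation distance <= KATAEGIS_MAX_MEAN_IMD.
    calls: list[KataegisCall] = []
    n = len(pos)
    k = KATAEGIS_MIN_VARIANTS
    i = 0
    while i + k <= n:
        span = pos[i + k - 1] - pos[i]
        if span / (k - 1) <= KATAEGIS_MAX_MEAN_IMD:
            j = i + k - 1
            while j + 1 < n and (pos[j + 1] - pos[i]) / (j + 1 - i) <= KATAEGIS_MAX_MEAN_IMD:
                j += 1
            calls.append(
                KataegisCall(
                    chrom=chrom,
                    start=pos[i],
                    end=pos[j],
                    n_variants=j - i + 1,
                    mean_imd=(pos[j] - pos[i]) / (j - i),
                )
            )
            i = j + 1
        else:
            i += 1
    return calls


def rainfall(variants: SampleVariantSet) -> RainfallTrack:
    """Compute the rainfall track (inter-mutation distances) and kataegis calls.

    Only SNP records carrying chrom+pos contribute; sorting is internal, so the
    result is invariant to the input record order.
    """
    by_chrom: dict[str, list[int]] = {}
    for r in variants:
        if r.variant_type != "SNP" or r.chrom is None or r.pos is None:
            continue
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    track = RainfallTrack(sample_id=variants.sample_id)
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        dists = [b - a for a, b in zip(pos, pos[1:])]
        if any(d == 0 for d in dists):
            track.has_zero_distance = True
        track.positions[chrom] = pos
        track.distances[chrom] = dists
        track.kataegis_calls.extend(_scan_kataegis(chrom, pos))
    return track


def variant_spectrum(
    variants: Iterable[VariantRecord],
) -> dict[str, dict[str, int]]:
    """Tally variants by class, by type, and by six-class substitution spectrum."""
    by_class: dict[str, int] = {}
    by_type: dict[str, int] = {}
    by_snv_class = {c: 0 for c in SNV_CLASSES}
    for r in variants:
        by_class[r.variant_class] = by_class.get(r.variant_class, 0) + 1
        if r.variant_type is not None:
            by_type[r.variant_type] = by_type.get(r.variant_type, 0) + 1
        if r.variant_type == "SNP":
            by_snv_class[classify_snv(r.ref, r.alt).value] += 1
    return {
        "variant_class": by_class,
        "variant_type": by_type,
        "snv_class": by_snv_class,
    }


@dataclass
class DemographicsSummary:
    n: int
    mean_age: float
    sd_age: float | None
    age_range: tuple[int, int]
    mean_diameter: float
    sd_diameter: float | None
    diameter_range: tuple[int, int]
    sex_counts: dict[str, int]
    invasion_count: int
    vision_abnormal_count: int

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """The headline numbers at one-decimal reporting precision."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "mean_age": rnd(self.mean_age),
            "sd_age": rnd(self.sd_age),
            "mean_diameter": rnd(self.mean_diameter),
            "sd_diameter": rnd(self.sd_diameter),
        }


def cohort_demographics(cohort: CohortTable) -> DemographicsSummary:
    """Cohort means, sample SDs (n-1 denominator) and ranges for age and diameter."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ages = np.array([t.age for t in cohort], dtype=float)
    diam = np.array([t.max_diameter_mm for t in cohort], dtype=float)
    n = len(cohort)
    sd = lambda x: float(np.std(x, ddof=1)) if n >= 2 else None
    sex_counts: dict[str, int] = {}
    for t in cohort:
        sex_counts[t.sex] = sex_counts.get(t.sex, 0) + 1
    return DemographicsSummary(
        n=n,
        mean_age=float(ages.mean()),
        sd_age=sd(ages),
        age_range=(int(ages.min()), int(ages.max())),
        mean_diameter=float(diam.mean()),
        sd_diameter=sd(diam),
        diameter_range=(int(diam.min()), int(diam.max())),
        sex_counts=sex_counts,
        invasion_count=sum(t.cav_sinus_invasion for t in cohort),
        vision_abnormal_count=sum(t.vision_abnormal for t in cohort),
    )
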