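"""Synthetic tumor-cohort generator.

Emulates the statistical structure the rest of the package assumes: a known
rooted binary sample tree, somatic variants assigned to its edges (trunk,
internal, private), binomial read counts at ~100X depth for clonal variants,
two noisy caller outputs per sample (dropout and low-VAF false positives),
clinical covariates with optionally planted gene-feature associations, and a
cytoband CNV matrix with planted shared and group-specific columns.

Everything derives from a single integer seed; the same seed reproduces the
same cohort byte for byte.  The generator models clonal presence/absence only
— no subclonal cellular-prevalence structure — because the phylogeny stage
consumes presence calls, not allele-fraction gradients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_io import (
    CallerOutput,
    CohortTable,
    SampleVariantSet,
    Tumor,
    VariantRecord,
    write_cohort_table,
    write_variant_matrix,
)
from .cnv import CnvCall, CnvMatrix, build_cnv_matrix, write_cnv_matrix
from .mutation_summary import SNV_CLASSES
from .pti import PresenceMatrix, TreeNode, ScoredTree, to_newick

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "write_fixture_bundle",
    "DEFAULT_GENE_PANEL",
]

#: Recurrently altered genes in corticotroph tumors plus generic filler
#: symbols so simulated cohorts have a realistic panel breadth.
DEFAULT_GENE_PANEL = (
    "USP8", "TP53", "AURKA", "EGFR", "HSD3B1", "CDKN1A", "ATF7IP", "MSH3",
) + tuple(f"GENE{i:03d}" for i in range(1, 33))

_PYRIMIDINE_SUB = {
    "C>A": ("C", "A"), "C>G": ("C", "G"), "C>T": ("C", "T"),
    "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G"),
}
_TRANSITION_CLASSES = ("C>T", "T>C")
_TRANSVERSION_CLASSES = ("C>A", "C>G", "T>A", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study-like conditions.

    ``mean_depth`` defaults to 100 (the targeted sequencing depth);
    ``clonal_vaf`` 0.4 reflects a clonal heterozygous variant with moderate
    purity; false positives are injected at VAF uniform in [0.01, 0.04], below
    the default presence threshold, so thresholding rather than bookkeeping
    removes them.  ``min_edge_variants`` conditions the draw so every tree
    edge carries at least that many variants (0 = unconditioned).
    """

    n_samples: int = 10
    seed: int = 0
    trunk_variants: int = 10
    edge_variant_rate: float = 4.0
    private_variant_rate: float = 3.0
    min_edge_variants: int = 0
    mean_depth: float = 100.0
    clonal_vaf: float = 0.4
    background_error_rate: float = 0.001
    fp_rate: float = 2.0
    fn_rate: float = 0.05
    ti_bias: float = 2.0 / 3.0
    class_weights: tuple[tuple[str, float], ...] = (
        ("missense", 0.55),
        ("silent", 0.20),
        ("nonsense", 0.08),
        ("splice_site", 0.05),
        ("frameshift_ins", 0.05),
        ("frameshift_del", 0.05),
        ("other", 0.02),
    )
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL
    caller_names: tuple[str, str] = ("mutect2", "surecall")
    n_gain_regions: int = 44
    n_loss_regions: int = 72
    assoc_effects: tuple[tuple[str, str, float, float], ...] = ()
    # each effect: (gene, feature, p_feature_given_carrier, p_feature_given_noncarrier)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        for name in ("fn_rate", "clonal_vaf", "ti_bias", "background_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("trunk_variants", "edge_variant_rate", "private_variant_rate",
                     "fp_rate", "min_edge_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    tree_newick: str
    tree_root: TreeNode
    edge_of_variant: dict[str, frozenset[str]]  # variant -> clade below the edge
    presence: PresenceMatrix
    planted_gain_bands: list[str]
    planted_loss_bands: list[str]
    planted_associations: list[tuple[str, str]]


@dataclass
class SimulatedCohort:
    caller_outputs: dict[str, tuple[CallerOutput, CallerOutput]]  # by sample
    cohort: CohortTable
    cnv: CnvMatrix
    truth: GroundTruth
    config: SimulationConfig


def _random_topology(samples: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Uniform-ish random rooted binary topology by recursive random bipartition."""
    if len(samples) == 1:
        return TreeNode(clade=frozenset(samples))
    while True:
        side = rng.integers(0, 2, size=len(samples))
        if side.any() and not side.all():
            break
    left = [s for s, b in zip(samples, side) if b]
    right = [s for s, b in zip(samples, side) if not b]
    return TreeNode(
        clade=frozenset(samples),
        children=(_random_topology(left, rng), _random_topology(right, rng)),
    )


def _edges_with_clades(root: TreeNode) -> list[frozenset[str]]:
    """Clades below every edge (every non-root node) plus the trunk clade."""
    out = []
    for node in root.walk():
        out.append(node.clade)
    return out  # includes root clade (trunk) first


def _draw_substitution(rng: np.random.Generator, ti_bias: float) -> tuple[str, str]:
    if rng.random() < ti_bias:
        cls = _TRANSITION_CLASSES[rng.integers(0, 2)]
    else:
        cls = _TRANSVERSION_CLASSES[rng.integers(0, 4)]
    ref, alt = _PYRIMIDINE_SUB[cls]
    if rng.random() < 0.5:  # report on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def _depth(rng: np.random.Generator, mean_depth: float) -> int:
    return max(1, int(rng.poisson(mean_depth)))


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generative model; see the module docstring for the steps."""
    rng = np.random.default_rng(config.seed)
    samples = [f"T{i+1:02d}" for i in range(config.n_samples)]

    # (1) topology
    root = _random_topology(samples, rng)

    # (2) variant counts per edge: the trunk gets a fixed count, internal
    # edges and leaf edges draw Poisson counts, optionally floored
    clades = _edges_with_clades(root)
    n_variants_per_clade: dict[frozenset[str], int] = {}
    for clade in clades:
        if len(clade) == config.n_samples:
            k = config.trunk_variants
        elif len(clade) == 1:
            k = int(rng.poisson(config.private_variant_rate))
        else:
            k = int(rng.poisson(config.edge_variant_rate))
        if len(clade) < config.n_samples:
            k = max(k, config.min_edge_variants)
        n_variants_per_clade[clade] = n_variants_per_clade.get(clade, 0) + k

    # (3) variant identities
    class_names = tuple(c for c, _ in config.class_weights)
    class_p = np.array([w for _, w in config.class_weights], dtype=float)
    class_p = class_p / class_p.sum()
    edge_of_variant: dict[str, frozenset[str]] = {}
    records_of_variant: dict[str, VariantRecord] = {}
    used_pos: set[tuple[str, int]] = set()
    vid_counter = 0
    for clade in clades:
        for _ in range(n_variants_per_clade[clade]):
            vid_counter += 1
            while True:
                chrom = f"chr{int(rng.integers(1, 23))}"
                pos = int(rng.integers(1, 250_000_000))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    break
            ref, alt = _draw_substitution(rng, config.ti_bias)
            vclass = class_names[rng.choice(len(class_names), p=class_p)]
            gene = config.gene_panel[int(rng.integers(0, len(config.gene_panel)))]
            vid = f"{chrom}:{pos}:{ref}>{alt}"
            edge_of_variant[vid] = clade
            records_of_variant[vid] = VariantRecord(
                variant_id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, mut_reads=1, ref_reads=1, variant_class=vclass,
            )

    variant_ids = sorted(edge_of_variant)
    sample_sorted = sorted(samples)
    present_true = np.zeros((len(sample_sorted), len(variant_ids)), dtype=bool)
    for j, vid in enumerate(variant_ids):
        clade = edge_of_variant[vid]
        for s in clade:
            present_true[sample_sorted.index(s), j] = True

    # (4) read counts per (sample, variant); carriers clonal, non-carriers
    # background error — a non-carrier record is emitted only when at least
    # one mutant read was observed (a caller needs evidence to call)
    true_calls: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    for j, vid in enumerate(variant_ids):
        proto = records_of_variant[vid]
        for i, s in enumerate(sample_sorted):
            depth = _depth(rng, config.mean_depth)
            if present_true[i, j]:
                mut = int(rng.binomial(depth, config.clonal_vaf))
                mut = max(1, mut)
            else:
                mut = int(rng.binomial(depth, config.background_error_rate))
                if mut == 0:
                    continue
            true_calls[s].append(
                VariantRecord(
                    variant_id=vid, chrom=proto.chrom, pos=proto.pos,
                    ref=proto.ref, alt=proto.alt, gene=proto.gene,
                    mut_reads=mut, ref_reads=depth - mut,
                    variant_class=proto.variant_class,
                )
            )

    # (5) two caller outputs per sample: dropout plus low-VAF false positives
    caller_outputs: dict[str, tuple[CallerOutput, CallerOutput]] = {}
    for s in samples:
        per_caller = []
        for caller in config.caller_names:
            kept = [
                r for r in true_calls[s] if rng.random() >= config.fn_rate
            ]
            n_fp = int(rng.poisson(config.fp_rate))
            for _ in range(n_fp):
                while True:
                    chrom = f"chr{int(rng.integers(1, 23))}"
                    pos = int(rng.integers(1, 250_000_000))
                    if (chrom, pos) not in used_pos:
                        used_pos.add((chrom, pos))
                        break
                ref, alt = _draw_substitution(rng, config.ti_bias)
                depth = _depth(rng, config.mean_depth)
                fp_vaf = rng.uniform(0.01, 0.04)
                mut = max(1, int(round(depth * fp_vaf)))
                kept.append(
                    VariantRecord(
                        variant_id=f"{chrom}:{pos}:{ref}>{alt}",
                        chrom=chrom, pos=pos, ref=ref, alt=alt,
                        gene=config.gene_panel[
                            int(rng.integers(0, len(config.gene_panel)))
                        ],
                        mut_reads=mut, ref_reads=depth - mut,
                        variant_class="other",
                    )
                )
            kept.sort(key=lambda r: r.variant_id)
            per_caller.append(
                CallerOutput(
                    caller_name=caller,
                    variants=SampleVariantSet(sample_id=s, records=kept),
                )
            )
        caller_outputs[s] = (per_caller[0], per_caller[1])

    # (6) clinical covariates, with optional planted associations
    carrier_genes: dict[str, set[str]] = {s: set() for s in samples}
    for j, vid in enumerate(variant_ids):
        for i, s in enumerate(sample_sorted):
            if present_true[i, j]:
                carrier_genes[s].add(records_of_variant[vid].gene)
    planted = []
    tumors = []
    for s in samples:
        age = int(np.clip(round(rng.normal(38.8, 16.5)), 17, 85))
        diameter = int(np.clip(round(rng.normal(31.9, 13.0)), 10, 60))
        feature_probs = {
            "cav_sinus_invasion": 0.8,
            "vision_abnormal": 0.7,
            "functional_status": 0.6,  # P(functioning); "silent" is the complement
        }
        for gene, feature, p_car, p_non in config.assoc_effects:
            feature_probs[feature] = (
                p_car if gene in carrier_genes[s] else p_non
            )
        functional = rng.random() < feature_probs["functional_status"]
        tumors.append(
            Tumor(
                tumor_id=s,
                age=age,
                sex="F" if rng.random() < 0.9 else "M",
                clinical_dx="cushing_disease" if functional else "non_functioning",
                path_dx="acth_adenoma" if functional else "silent_acth_adenoma",
                max_diameter_mm=diameter,
                cav_sinus_invasion=bool(rng.random() < feature_probs["cav_sinus_invasion"]),
                vision_abnormal=bool(rng.random() < feature_probs["vision_abnormal"]),
                surgeries="1 TSS",
                snv_genes=frozenset(carrier_genes[s]),
            )
        )
    for gene, feature, _, _ in config.assoc_effects:
        planted.append((gene, feature))
    cohort = CohortTable(tumors=tumors)

    # (7) CNV matrix: one gain shared by everyone, the rest of the planted
    # gain/loss bands spread over random sample subsets
    bands_gain = _synthetic_bands(rng, config.n_gain_regions, used=set())
    bands_loss = _synthetic_bands(
        rng, config.n_loss_regions, used=set(bands_gain)
    )
    calls: list[CnvCall] = []
    for k, band in enumerate(bands_gain):
        if k == 0:
            carriers = samples  # universally shared gain
        else:
            carriers = [s for s in samples if rng.random() < 0.4] or [
                samples[int(rng.integers(0, len(samples)))]
            ]
        calls.extend(CnvCall(s, band, "gain") for s in carriers)
    for band in bands_loss:
        carriers = [s for s in samples if rng.random() < 0.4] or [
            samples[int(rng.integers(0, len(samples)))]
        ]
        calls.extend(CnvCall(s, band, "loss") for s in carriers)
    cnv = build_cnv_matrix(calls)

    presence = PresenceMatrix(
        samples=sample_sorted,
        variants=variant_ids,
        present=present_true,
        genes=[records_of_variant[v].gene for v in variant_ids],
    )
    truth = GroundTruth(
        tree_newick=to_newick(ScoredTree(root=root, score=0)),
        tree_root=root,
        edge_of_variant=edge_of_variant,
        presence=presence,
        planted_gain_bands=bands_gain,
        planted_loss_bands=bands_loss,
        planted_associations=planted,
    )
    return SimulatedCohort(
        caller_outputs=caller_outputs,
        cohort=cohort,
        cnv=cnv,
        truth=truth,
        config=config,
    )


def _synthetic_bands(
    rng: np.random.Generator, n: int, used: set[str]
) -> list[str]:
    """Distinct plausible cytoband labels like ``10q11.22``."""
    out: list[str] = []
    while len(out) < n:
        chrom = int(rng.integers(1, 23))
        arm = "pq"[int(rng.integers(0, 2))]
        major = int(rng.integers(1, 30))
        minor = int(rng.integers(1, 4))
        band = f"{chrom}{arm}{major}.{minor}"
        if band not in used:
            used.add(band)
            out.append(band)
    return out


def write_fixture_bundle(sim: SimulatedCohort, directory: str | Path) -> dict:
    """Write the cohort as plain-text TSVs plus a manifest with checksums.

    Emits one variant-matrix TSV per (sample, caller), the cohort table, the
    CNV matrix, the true tree in Newick, and ``manifest.json`` echoing the
    config, seed and per-file SHA-256 checksums.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for s in sorted(sim.caller_outputs):
        for co in sim.caller_outputs[s]:
            p = directory / f"{s}.{co.caller_name}.variants.tsv"
            write_variant_matrix(co.variants, p)
            files.append(p)
    cohort_path = directory / "cohort.tsv"
    write_cohort_table(sim.cohort, cohort_path)
    files.append(cohort_path)
    cnv_path = directory / "cnv_matrix.tsv"
    write_cnv_matrix(sim.cnv, cnv_path)
    files.append(cnv_path)
    tree_path = directory / "true_tree.nwk"
    tree_path.write_text(sim.truth.tree_newick + "\n")
    files.append(tree_path)

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in files
    }
    cfg = asdict(sim.config)
    manifest = {
        "config": cfg,
        "seed": sim.config.seed,
        "files": checksums,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n"
    )
    return manifest
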