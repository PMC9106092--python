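"""Shared-variant tumor phylogeny inference.

Given per-sample somatic variant profiles, build a boolean samples x variants
presence matrix (a variant is present when its allele fraction clears a
threshold) and find the rooted binary tree over the samples that maximizes the
aggregated variant count: the number of variants whose carrier set — the exact
set of samples carrying the variant — coincides with a clade of the tree.

This score realizes the intuitive clonal narrative: variants carried by every
sample sit at the tree base; a split creates two clades, each collecting the
variants private to exactly that sample subset; each variant is counted at
most once.  When the carrier sets form a laminar family (a perfect phylogeny)
the generating tree attains the upper bound (every variant assigned) and is
the unique optimum up to zero-weight rearrangements.

The optimum is computed exactly by dynamic programming over sample subsets:

    best({s}) = w({s})
    best(C)   = w(C) + max over bipartitions {A, B} of C of best(A) + best(B)

where ``w(C)`` is the number of variants whose carrier set equals ``C``.  The
bipartition sweep over all subsets costs O(3^n), comfortable for cohorts up to
a dozen or so samples; an explicit enumeration of every rooted binary leaf
topology is retained as an independent oracle for small n.

Variants whose carrier set matches no clade of the chosen tree are reported as
incompatible (homoplasy with respect to that tree); they contribute nothing to
any score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .cohort_io import SampleVariantSet

__all__ = [
    "PresenceMatrix",
    "PtiConfig",
    "TreeNode",
    "ScoredTree",
    "PhylogenyInference",
    "presence_from_counts",
    "presence_from_membership",
    "clade_weight",
    "best_tree",
    "enumerate_trees_oracle",
    "characterize_clades",
    "to_newick",
]


@dataclass(frozen=True)
class PtiConfig:
    """Parameters of the phylogeny search.

    ``af_threshold`` is the minimum variant allele fraction for a call to
    count as present (records lacking read counts always count); the search
    itself is exact, the threshold only controls which variants enter it.
    """

    af_threshold: float = 0.05
    max_exhaustive_n: int = 12
    tie_break: str = "canonical"  # or "report_all"

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_threshold <= 1.0):
            raise ValueError("af_threshold must be in [0, 1]")
        if self.tie_break not in ("canonical", "report_all"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class PresenceMatrix:
    """Samples x variants boolean presence matrix.

    ``samples`` are kept in sorted order so downstream results are invariant
    to input ordering.  Variants present in zero samples are dropped at
    construction.  ``genes`` carries the per-variant gene annotation.
    """

    samples: list[str]
    variants: list[str]
    present: np.ndarray  # bool, samples x variants
    genes: list[str]

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.samples), len(self.variants)):
            raise ValueError("presence matrix shape mismatch")
        keep = self.present.any(axis=0)
        if not keep.all():
            self.present = self.present[:, keep]
            self.variants = [v for v, k in zip(self.variants, keep) if k]
            self.genes = [g for g, k in zip(self.genes, keep) if k]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def carriers(self, variant_id: str) -> frozenset[str]:
        j = self.variants.index(variant_id)
        return frozenset(
            s for s, p in zip(self.samples, self.present[:, j]) if p
        )

    def carrier_masks(self) -> np.ndarray:
        """Per-variant carrier set encoded as a bitmask over sorted samples."""
        weights = 1 << np.arange(self.n_samples, dtype=np.int64)
        return (self.present.astype(np.int64).T * weights).sum(axis=1)


def presence_from_membership(
    membership: dict[str, dict[str, bool]] | "np.ndarray",
    samples: Sequence[str] | None = None,
    variants: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Build a :class:`PresenceMatrix` from an explicit boolean array or dict."""
    if isinstance(membership, dict):
        samples = sorted(membership)
        variants = sorted({v for row in membership.values() for v in row})
        present = np.array(
            [[bool(membership[s].get(v, False)) for v in variants] for s in samples]
        )
    else:
        if samples is None or variants is None:
            raise ValueError("samples and variants required with an array input")
        order = np.argsort(np.asarray(samples, dtype=object))
        samples = [samples[i] for i in order]
        present = np.asarray(membership, dtype=bool)[order]
        variants = list(variants)
    if genes is None:
        genes = [""] * len(variants)
    return PresenceMatrix(
        samples=list(samples), variants=list(variants),
        present=present, genes=list(genes),
    )


def presence_from_counts(
    profiles: Iterable[SampleVariantSet],
    config: PtiConfig | None = None,
) -> PresenceMatrix:
    """Threshold per-sample read counts into the boolean presence matrix.

    A variant is present in a sample iff it occurs in that sample's set and
    its allele fraction is >= ``config.af_threshold`` (strict >=, so a VAF
    exactly at the threshold passes); records without read counts count as
    present.  Variants present nowhere are dropped.
    """
    config = config or PtiConfig()
    profiles = list(profiles)
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    if len(profiles) < 2:
        raise ValueError("need at least 2 samples to build a presence matrix")
    profiles.sort(key=lambda p: p.sample_id)
    samples = [p.sample_id for p in profiles]
    variant_ids: list[str] = []
    gene_of: dict[str, str] = {}
    seen: set[str] = set()
    for p in profiles:
        for r in p:
            if r.variant_id not in seen:
                seen.add(r.variant_id)
                variant_ids.append(r.variant_id)
                gene_of[r.variant_id] = r.gene
    variant_ids.sort()
    col = {v: j for j, v in enumerate(variant_ids)}
    present = np.zeros((len(samples), len(variant_ids)), dtype=bool)
    for i, p in enumerate(profiles):
        for r in p:
            if r.mut_reads is None or r.vaf() >= config.af_threshold:
                present[i, col[r.variant_id]] = True
    return PresenceMatrix(
        samples=samples,
        variants=variant_ids,
        present=present,
        genes=[gene_of[v] for v in variant_ids],
    )


def clade_weight(matrix: PresenceMatrix, clade: Iterable[str]) -> int:
    """Number of variants carried by exactly this sample subset and no other."""
    clade = frozenset(clade)
    if not clade:
        raise ValueError("empty clade")
    unknown = clade - set(matrix.samples)
    if unknown:
        raise ValueError(f"unknown sample(s): {sorted(unknown)}")
    mask = 0
    index = {s: i for i, s in enumerate(matrix.samples)}
    for s in clade:
        mask |= 1 << index[s]
    return int(np.count_nonzero(matrix.carrier_masks() == mask))


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted binary sample tree.

    ``clade`` is the frozenset of sample_ids below (or at) the node;
    ``assigned_variants`` are the variant_ids whose carrier set equals the
    clade exactly.
    """

    clade: frozenset[str]
    children: tuple["TreeNode", "TreeNode"] | None = None
    assigned_variants: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def clade_support(self) -> int:
        return len(self.assigned_variants)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        if self.children is not None:
            for c in self.children:
                yield from c.walk()


@dataclass
class ScoredTree:
    """A scored rooted binary tree plus the variants no clade can host."""

    root: TreeNode
    score: int
    incompatible_variants: list[str] = field(default_factory=list)

    @property
    def samples(self) -> frozenset[str]:
        return self.root.clade

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def newick(self, collapse_zero_support: bool = False) -> str:
        return to_newick(self, collapse_zero_support=collapse_zero_support)


def _canonical_key(clade: frozenset[str]) -> tuple[str, ...]:
    return tuple(sorted(clade))


def _topology_key(node: TreeNode) -> tuple:
    """Hashable canonical form of a (sub)topology, ignoring scores."""
    if node.is_leaf:
        return (next(iter(node.clade)),)
    kids = sorted(
        (_topology_key(c) for c in node.children),
        key=lambda k: _flatten_key(k),
    )
    return tuple(kids)


def _flatten_key(k: tuple) -> tuple[str, ...]:
    if len(k) == 1 and isinstance(k[0], str):
        return (k[0],)
    out: list[str] = []
    for sub in k:
        out.extend(_flatten_key(sub))
    return tuple(sorted(out))


def _iter_bipartitions(mask: int) -> Iterator[tuple[int, int]]:
    """All unordered bipartitions of the bitmask; the half holding the lowest
    set bit is yielded first."""
    low = mask & -mask
    rest = mask ^ low
    # enumerate subsets of rest; A = low | subset, B = complement
    sub = rest
    while True:
        a = low | sub
        b = mask ^ sub ^ low
        if b:
            yield a, b
        if sub == 0:
            break
        sub = (sub - 1) & rest


def best_tree(matrix: PresenceMatrix, config: PtiConfig | None = None) -> ScoredTree:
    """Exact optimum of the aggregated-variant-count score by subset DP.

    Among co-optimal trees the canonical form is returned: at every internal
    node the child containing the lexicographically smallest sample comes
    first, and among co-optimal bipartitions the one whose first child has the
    lexicographically smallest sorted sample tuple wins.  With
    ``tie_break="report_all"``, use :func:`best_trees_all` instead.
    """
    config = config or PtiConfig()
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n > config.max_exhaustive_n:
        raise ValueError(
            f"{n} samples exceeds max_exhaustive_n={config.max_exhaustive_n}; "
            "raise the AF threshold or filter samples (the search is O(3^n))"
        )
    samples = matrix.samples  # already sorted
    zero_samples = [
        s for i, s in enumerate(samples) if not matrix.present[i].any()
    ]
    if zero_samples:
        warnings.warn(
            f"samples with no variants after filtering: {zero_samples}; "
            "they attach by canonical order",
            stacklevel=2,
        )
    carrier_masks = matrix.carrier_masks()
    weight: dict[int, int] = {}
    for m in carrier_masks:
        weight[int(m)] = weight.get(int(m), 0) + 1

    full = (1 << n) - 1
    best_score = np.empty(full + 1, dtype=np.int64)
    best_split: dict[int, tuple[int, int]] = {}

    def clade_names(mask: int) -> tuple[str, ...]:
        return tuple(samples[i] for i in range(n) if mask >> i & 1)

    # iterate masks in increasing popcount-compatible order (plain ascending
    # order works: any proper submask is numerically smaller)
    for mask in range(1, full + 1):
        w = weight.get(mask, 0)
        if mask & (mask - 1) == 0:  # singleton
            best_score[mask] = w
            continue
        best_val = -1
        best_ab: tuple[int, int] | None = None
        for a, b in _iter_bipartitions(mask):
            val = best_score[a] + best_score[b]
            if val > best_val:
                best_val = val
                best_ab = (a, b)
            elif val == best_val and clade_names(a) < clade_names(best_ab[0]):
                best_ab = (a, b)
        best_score[mask] = w + best_val
        best_split[mask] = best_ab

    assigned: set[str] = set()

    def build(mask: int) -> TreeNode:
        clade = frozenset(clade_names(mask))
        node = TreeNode(clade=clade)
        node.assigned_variants = sorted(
            v for v, m in zip(matrix.variants, carrier_masks) if int(m) == mask
        )
        assigned.update(node.assigned_variants)
        if mask & (mask - 1):
            a, b = best_split[mask]
            node.children = (build(a), build(b))
        return node

    root = build(full)
    incompatible = sorted(set(matrix.variants) - assigned)
    return ScoredTree(
        root=root, score=int(best_score[full]), incompatible_variants=incompatible
    )


def best_trees_all(matrix: PresenceMatrix, config: PtiConfig | None = None) -> list[ScoredTree]:
    """Every argmax topology (``tie_break="report_all"`` mode), canonical first."""
    config = config or PtiConfig()
    score, tops = enumerate_trees_oracle(matrix, limit=config.max_exhaustive_n)
    trees = [_assign_and_score(matrix, t) for t in tops]
    trees.sort(key=lambda t: _topology_key(t.root))
    return trees


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _all_topologies(samples: tuple[str, ...]) -> list[TreeNode]:
    if len(samples) == 1:
        return [TreeNode(clade=frozenset(samples))]
    first, rest = samples[0], samples[1:]
    out: list[TreeNode] = []
    # A is any proper subset of `samples` containing `first`
    for bits in range(1 << len(rest)):
        a = (first,) + tuple(s for i, s in enumerate(rest) if bits >> i & 1)
        b = tuple(s for i, s in enumerate(rest) if not bits >> i & 1)
        if not b:
            continue
        for left in _all_topologies(a):
            for right in _all_topologies(b):
                out.append(
                    TreeNode(
                        clade=frozenset(samples),
                        children=(_copy(left), _copy(right)),
                    )
                )
    return out


def _copy(node: TreeNode) -> TreeNode:
    if node.is_leaf:
        return TreeNode(clade=node.clade)
    return TreeNode(
        clade=node.clade, children=tuple(_copy(c) for c in node.children)
    )


def _score_topology(matrix: PresenceMatrix, root: TreeNode) -> int:
    weight: dict[frozenset[str], int] = {}
    index = {s: i for i, s in enumerate(matrix.samples)}
    masks = matrix.carrier_masks()
    for v, m in zip(matrix.variants, masks):
        cs = frozenset(s for s in matrix.samples if m >> index[s] & 1)
        weight[cs] = weight.get(cs, 0) + 1
    return sum(weight.get(n.clade, 0) for n in root.walk())


def _assign_and_score(matrix: PresenceMatrix, root: TreeNode) -> ScoredTree:
    root = _copy(root)
    index = {s: i for i, s in enumerate(matrix.samples)}
    carriers = {
        v: frozenset(s for s in matrix.samples if int(m) >> index[s] & 1)
        for v, m in zip(matrix.variants, matrix.carrier_masks())
    }
    clades = {n.clade: n for n in root.walk()}
    assigned: set[str] = set()
    for v, cs in carriers.items():
        if cs in clades:
            clades[cs].assigned_variants.append(v)
            assigned.add(v)
    for n in root.walk():
        n.assigned_variants.sort()
    score = sum(n.clade_support for n in root.walk())
    return ScoredTree(
        root=root,
        score=score,
        incompatible_variants=sorted(set(matrix.variants) - assigned),
    )


def enumerate_trees_oracle(
    matrix: PresenceMatrix, limit: int = 6
) -> tuple[int, list[TreeNode]]:
    """Score every rooted binary leaf-labeled topology explicitly.

    Returns the maximum score and all argmax topologies.  The number of
    topologies is (2n-3)!!, so this is restricted to small n and serves as the
    independent check on :func:`best_tree`.
    """
    n = matrix.n_samples
    if n > limit:
        raise ValueError(f"oracle limited to {limit} samples, got {n}")
    if n < 2:
        raise ValueError("need at least 2 samples")
    tops = _all_topologies(tuple(matrix.samples))
    scores = [_score_topology(matrix, t) for t in tops]
    best = max(scores)
    return best, [t for t, s in zip(tops, scores) if s == best]


# ---------------------------------------------------------------------------
# Clade characterization and Newick export
# ---------------------------------------------------------------------------

def characterize_clades(
    tree: ScoredTree, matrix: PresenceMatrix | None = None
) -> dict[frozenset[str], list[str]]:
    """Sorted gene symbols of each node's assigned variants, keyed by clade.

    Gene annotation is taken from ``matrix.genes`` when a matrix is given,
    else parsed from variant ids of the form ``...|gene`` is not attempted —
    variants without annotation yield empty strings which are dropped.
    """
    gene_of: dict[str, str] = {}
    if matrix is not None:
        gene_of = dict(zip(matrix.variants, matrix.genes))
    out: dict[frozenset[str], list[str]] = {}
    for node in tree.root.walk():
        genes = sorted(
            {g for g in (gene_of.get(v, "") for v in node.assigned_variants) if g}
        )
        out[node.clade] = genes
    return out


def _newick_node(node: TreeNode, collapse_zero_support: bool) -> str:
    if node.is_leaf:
        return next(iter(node.clade))
    parts = []
    for child in sorted(node.children, key=lambda c: min(c.clade)):
        parts.append(_newick_node(child, collapse_zero_support))
    label = "" if (collapse_zero_support and node.clade_support == 0) else str(
        node.clade_support
    )
    return f"({','.join(parts)}){label}"


def to_newick(tree: ScoredTree, collapse_zero_support: bool = False) -> str:
    """Deterministic Newick string with clade support as internal node labels.

    Children are ordered by their smallest sample_id, so any two trees with
    the same topology and assignments serialize identically regardless of the
    order samples were supplied in.
    """
    return _newick_node(tree.root, collapse_zero_support) + ";"


# ---------------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------------

class PhylogenyInference:
    """Estimator interface over the shared-variant phylogeny search.

    Parameters mirror :class:`PtiConfig`.  ``fit`` accepts either a
    :class:`PresenceMatrix` or a boolean array with ``sample_ids`` /
    ``variant_ids`` keyword arguments, and exposes the fitted tree via
    trailing-underscore attributes (``tree_``, ``score_``, ``newick_``,
    ``incompatible_variants_``).
    """

    def __init__(
        self,
        af_threshold: float = 0.05,
        max_exhaustive_n: int = 12,
        tie_break: str = "canonical",
    ) -> None:
        self.af_threshold = af_threshold
        self.max_exhaustive_n = max_exhaustive_n
        self.tie_break = tie_break

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "af_threshold": self.af_threshold,
            "max_exhaustive_n": self.max_exhaustive_n,
            "tie_break": self.tie_break,
        }

    def set_params(self, **params) -> "PhylogenyInference":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> PtiConfig:
        return PtiConfig(
            af_threshold=self.af_threshold,
            max_exhaustive_n=self.max_exhaustive_n,
            tie_break=self.tie_break,
        )

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        X,
        y=None,
        *,
        sample_ids: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "PhylogenyInference":
        if isinstance(X, PresenceMatrix):
            matrix = X
        elif isinstance(X, (list, tuple)) and X and isinstance(X[0], SampleVariantSet):
            matrix = presence_from_counts(X, self._config())
        else:
            arr = np.asarray(X, dtype=bool)
            if sample_ids is None:
                sample_ids = [f"s{i+1}" for i in range(arr.shape[0])]
            if variant_ids is None:
                variant_ids = [f"v{j+1}" for j in range(arr.shape[1])]
            matrix = presence_from_membership(
                arr, samples=sample_ids, variants=variant_ids, genes=genes
            )
        self.matrix_ = matrix
        tree = best_tree(matrix, self._config())
        self.tree_ = tree
        self.score_ = tree.score
        self.newick_ = to_newick(tree)
        self.incompatible_variants_ = list(tree.incompatible_variants)
        self.clade_genes_ = characterize_clades(tree, matrix)
        return self

    def fit_predict(self, X, y=None, **kw) -> str:
        """Fit and return the canonical Newick string."""
        return self.fit(X, y, **kw).newick_
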