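"""Cytoband-level copy-number profiles.

Per-sample gain/loss calls at cytoband resolution (the granularity GISTIC-style
tools report) are collected into a samples x cytobands matrix over
{+1 gain, 0 none, -1 loss}.  The module answers shared/exclusive-region
queries, counts the distinct gained/lost cytobands, and hierarchically
clusters samples by profile (Hamming distance, average linkage by default).

The unit of analysis is the cytoband *string*: "20p" (whole arm) and "20p13"
are distinct labels by default, with an optional arm-containment mode for
queries.  Interval arithmetic on genomic coordinates is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CnvCall",
    "CnvMatrix",
    "Dendrogram",
    "CnvProfileClustering",
    "build_cnv_matrix",
    "read_cnv_table",
    "write_cnv_matrix",
    "shared_regions",
    "count_regions",
    "cluster_samples",
    "CYTOBAND_RE",
]

CYTOBAND_RE = re.compile(r"^([0-9]{1,2}|X|Y)[pq]([0-9]+(\.[0-9]+)?)?$")

_DIRECTIONS = ("gain", "loss")
_CODE = {"gain": 1, "loss": -1}


@dataclass(frozen=True)
class CnvCall:
    """One gain/loss call: a sample, a cytoband label and a direction."""

    sample_id: str
    cytoband: str
    direction: str
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not CYTOBAND_RE.match(self.cytoband):
            raise ValueError(f"invalid cytoband label {self.cytoband!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be gain or loss, got {self.direction!r}")


@dataclass
class CnvMatrix:
    """Samples x cytobands matrix over {+1 gain, 0 none, -1 loss}."""

    samples: list[str]
    cytobands: list[str]
    values: np.ndarray  # int8, samples x cytobands

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.samples), len(self.cytobands)):
            raise ValueError("CNV matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.cytobands)

    def row(self, sample_id: str) -> np.ndarray:
        try:
            return self.values[self.samples.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None


def build_cnv_matrix(calls: Iterable[CnvCall]) -> CnvMatrix:
    """Assemble calls into the ternary matrix over all observed cytobands.

    A (sample, cytoband) pair called both gain and loss is an ingestion error
    and is reported by name.
    """
    calls = list(calls)
    seen: dict[tuple[str, str], str] = {}
    for c in calls:
        key = (c.sample_id, c.cytoband)
        prev = seen.get(key)
        if prev is not None and prev != c.direction:
            raise ValueError(
                f"conflicting gain+loss calls for sample {c.sample_id!r} "
                f"cytoband {c.cytoband!r}"
            )
        seen[key] = c.direction
    samples = sorted({c.sample_id for c in calls})
    cytobands = sorted({c.cytoband for c in calls})
    values = np.zeros((len(samples), len(cytobands)), dtype=np.int8)
    si = {s: i for i, s in enumerate(samples)}
    ci = {b: j for j, b in enumerate(cytobands)}
    for (s, b), d in seen.items():
        values[si[s], ci[b]] = _CODE[d]
    return CnvMatrix(samples=samples, cytobands=cytobands, values=values)


def read_cnv_table(path) -> CnvMatrix:
    """Read a CNV call TSV with columns ``sample_id cytoband direction [genes]``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "cytoband", "direction"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    calls = []
    for _, row in df.iterrows():
        genes = tuple(
            g.strip() for g in str(row.get("genes", "")).split(",") if g.strip()
        )
        calls.append(
            CnvCall(
                sample_id=str(row["sample_id"]),
                cytoband=str(row["cytoband"]),
                direction=str(row["direction"]).strip().lower(),
                genes=genes,
            )
        )
    return build_cnv_matrix(calls)


def write_cnv_matrix(matrix: CnvMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def _arm_of(band: str) -> str:
    m = re.match(r"^([0-9]{1,2}|X|Y)([pq])", band)
    return m.group(0)


def shared_regions(
    matrix: CnvMatrix,
    samples: Sequence[str],
    direction: str,
    arm_containment: bool = False,
) -> set[str]:
    """Cytobands with the given direction in *every* listed sample.

    With ``arm_containment=True``, a whole-arm call (e.g. "20p") in a sample
    also satisfies any sub-band of that arm (e.g. "20p13"); the default is
    strict label equality.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be gain or loss, got {direction!r}")
    if not samples:
        raise ValueError("empty sample subset")
    code = _CODE[direction]
    rows = np.array([matrix.row(s) for s in samples])
    if not arm_containment:
        hit = (rows == code).all(axis=0)
        return {b for b, h in zip(matrix.cytobands, hit) if h}
    arm_cols = {b: _arm_of(b) for b in matrix.cytobands}
    col = {b: j for j, b in enumerate(matrix.cytobands)}
    out = set()
    for b in matrix.cytobands:
        ok = True
        for r in rows:
            direct = r[col[b]] == code
            arm = arm_cols[b] in col and r[col[arm_cols[b]]] == code
            if not (direct or arm):
                ok = False
                break
        if ok:
            out.add(b)
    return out


def count_regions(matrix: CnvMatrix, direction: str) -> int:
    """Distinct cytobands showing the direction in at least one sample."""
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be gain or loss, got {direction!r}")
    return int(((matrix.values == _CODE[direction]).any(axis=0)).sum())


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hamming_distances(matrix: CnvMatrix) -> np.ndarray:
    """Pairwise Hamming distance (fraction of differing cytobands) between samples."""
    n = len(matrix.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(matrix.values[i] != matrix.values[j])
    return d


@dataclass
class Dendrogram:
    """Clustering result: scipy linkage matrix, sample order, Newick rendering."""

    samples: list[str]
    linkage: np.ndarray
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: labels[i] for i in range(n)}
    smallest: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        kids = sorted([a, b], key=lambda x: smallest[x])
        parts = []
        for c in kids:
            parts.append(f"{node[c]}:{h - height[c]:.6g}")
        idx = n + k
        node[idx] = f"({','.join(parts)})"
        height[idx] = float(h)
        smallest[idx] = min(smallest[a], smallest[b])
    return node[n + len(Z) - 1] + ";"


def cluster_samples(
    matrix: CnvMatrix,
    metric: str = "hamming",
    method: str = "average",
) -> Dendrogram:
    """Agglomeratively cluster samples by CNV profile.

    Defaults are Hamming distance on the ternary vectors with average linkage;
    Euclidean distance and complete linkage are available.  Samples are
    processed in sorted-id order so ties resolve deterministically.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    order = np.argsort(np.asarray(matrix.samples, dtype=object))
    samples = [matrix.samples[i] for i in order]
    values = matrix.values[order]
    reordered = CnvMatrix(samples=samples, cytobands=matrix.cytobands, values=values)
    if metric == "hamming":
        dist = hamming_distances(reordered)
    elif metric == "euclidean":
        diff = values[:, None, :].astype(float) - values[None, :, :].astype(float)
        dist = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return Dendrogram(
        samples=samples, linkage=Z, newick=_linkage_to_newick(Z, samples)
    )


class CnvProfileClustering:
    """sklearn-style estimator wrapping :func:`cluster_samples`.

    ``fit`` accepts a :class:`CnvMatrix` or a ternary array plus
    ``sample_ids``; fitted attributes are ``linkage_``, ``newick_``,
    ``samples_`` and ``merge_heights_``.
    """

    def __init__(self, metric: str = "hamming", method: str = "average") -> None:
        self.metric = metric
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"metric": self.metric, "method": self.method}

    def set_params(self, **params) -> "CnvProfileClustering":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, *, sample_ids: Sequence[str] | None = None):
        if isinstance(X, CnvMatrix):
            matrix = X
        else:
            arr = np.asarray(X, dtype=np.int8)
            if sample_ids is None:
                sample_ids = [f"s{i+1}" for i in range(arr.shape[0])]
            matrix = CnvMatrix(
                samples=list(sample_ids),
                cytobands=[f"band{j+1}" for j in range(arr.shape[1])],
                values=arr,
            )
        dg = cluster_samples(matrix, metric=self.metric, method=self.method)
        self.samples_ = dg.samples
        self.linkage_ = dg.linkage
        self.newick_ = dg.newick
        self.merge_heights_ = dg.merge_heights
        return self
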