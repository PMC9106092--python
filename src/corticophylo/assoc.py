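"""Variant-clinicopathology association screen.

Binary clinical features are tested against gene carrier status with the
two-tailed Fisher exact test; continuous features use the two-sample t test
(pooled-variance Student by default, Welch on request).  No multiple-testing
correction is applied — results carry an explicit ``uncorrected`` tag so the
screen's exploratory nature is visible downstream.

The Fisher p-value uses the point-probability criterion: with all margins
fixed, every admissible 2x2 table is enumerated and those whose hypergeometric
point probability does not exceed the observed table's (within a small
relative tolerance for ties) contribute to the two-sided p.  This matches the
convention of the common statistical packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_io import CohortTable
from .mutation_summary import GeneSampleMatrix

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "fisher_exact_two_tailed",
    "two_sample_t",
    "association_screen",
    "BINARY_FEATURES",
    "CONTINUOUS_FEATURES",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows variant present/absent, columns feature yes/no."""

    a: int  # present & yes
    b: int  # present & no
    c: int  # absent & yes
    d: int  # absent & no

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("all-zero table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact_two_tailed(table: ContingencyTable | Sequence[Sequence[int]]) -> float:
    """Exact two-sided Fisher p by full enumeration of the margin-fixed tables."""
    if not isinstance(table, ContingencyTable):
        (a, b), (c, d) = table
        table = ContingencyTable(a, b, c, d)
    n = table.total
    row1 = table.a + table.b
    col1 = table.a + table.c
    # a ranges over the admissible support given the margins
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    rv = stats.hypergeom(n, col1, row1)
    p_obs = rv.pmf(table.a)
    p = 0.0
    for a in range(lo, hi + 1):
        pa = rv.pmf(a)
        if pa <= p_obs * (1.0 + _TIE_RTOL):
            p += pa
    return min(1.0, float(p))


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sided two-sample t test; returns ``(t, df, p)``.

    ``pooled`` is the classical Student test with the pooled variance
    estimate; ``welch`` drops the equal-variance assumption.  Degenerate zero
    pooled variance with equal means returns ``(0, df, 1.0)`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if variant == "pooled":
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
    elif variant == "welch":
        se = math.sqrt(vx / nx + vy / ny)
        if se > 0:
            df = (vx / nx + vy / ny) ** 2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = nx + ny - 2
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se == 0.0:
        if mx == my:
            return 0.0, float(df), 1.0
        return math.inf if mx > my else -math.inf, float(df), 0.0
    t = (mx - my) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


BINARY_FEATURES = (
    "functional_status",
    "cav_sinus_invasion",
    "vision_abnormal",
    "sex",
)
CONTINUOUS_FEATURES = ("age", "max_diameter_mm")


@dataclass
class AssociationResult:
    gene: str
    feature: str
    test: str  # "fisher" or "t"
    statistic: float | None
    p_value: float | None
    group_summaries: dict = field(default_factory=dict)
    untestable: bool = False
    correction: str = "uncorrected"


def _binary_value(tumor, feature: str) -> bool:
    if feature == "functional_status":
        return tumor.functional_status == "silent"
    if feature == "sex":
        return tumor.sex == "F"
    return bool(getattr(tumor, feature))


def association_screen(
    cohort: CohortTable,
    matrix: GeneSampleMatrix,
    features: Sequence[str] | None = None,
    t_variant: str = "pooled",
) -> list[AssociationResult]:
    """One test per (gene, feature) pair.

    Binary features build a carrier-status contingency table and use the
    Fisher exact test; continuous features compare carriers vs non-carriers
    with the t test.  A feature or carrier margin with a single level makes
    the pair untestable and is flagged rather than silently dropped.
    """
    if features is None:
        features = list(BINARY_FEATURES) + list(CONTINUOUS_FEATURES)
    carrier = {
        g: {s: bool(matrix.present[i, j]) for j, s in enumerate(matrix.samples)}
        for i, g in enumerate(matrix.genes)
    }
    results: list[AssociationResult] = []
    for gene in matrix.genes:
        carries = carrier[gene]
        for feature in features:
            if feature in CONTINUOUS_FEATURES:
                x = [getattr(t, feature) for t in cohort if carries.get(t.tumor_id)]
                y = [getattr(t, feature) for t in cohort if not carries.get(t.tumor_id)]
                if len(x) < 2 or len(y) < 2:
                    results.append(
                        AssociationResult(gene, feature, "t", None, None, untestable=True)
                    )
                    continue
                t, df, p = two_sample_t(x, y, variant=t_variant)
                results.append(
                    AssociationResult(
                        gene, feature, "t", t, p,
                        group_summaries={
                            "carrier_mean": float(np.mean(x)),
                            "noncarrier_mean": float(np.mean(y)),
                            "df": df,
                        },
                    )
                )
            else:
                a = b = c = d = 0
                for t in cohort:
                    pres = carries.get(t.tumor_id, False)
                    yes = _binary_value(t, feature)
                    if pres and yes:
                        a += 1
                    elif pres:
                        b += 1
                    elif yes:
                        c += 1
                    else:
                        d += 1
                degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
                if degenerate:
                    results.append(
                        AssociationResult(
                            gene, feature, "fisher", None, None,
                            group_summaries={"table": [[a, b], [c, d]]},
                            untestable=True,
                        )
                    )
                    continue
                p = fisher_exact_two_tailed(ContingencyTable(a, b, c, d))
                results.append(
                    AssociationResult(
                        gene, feature, "fisher", None, p,
                        group_summaries={"table": [[a, b], [c, d]]},
                    )
                )
    return results
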