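import numpy as np
import pytest

from corticophylo.cohort_io import SampleVariantSet, VariantRecord
from corticophylo.datasets import (
    load_corticotroph_cnv_groups,
    load_corticotroph_cohort,
)
from corticophylo.pti import presence_from_membership


@pytest.fixture(scope="session")
def cohort():
    """The packaged 10-tumor clinical table."""
    return load_corticotroph_cohort()


@pytest.fixture(scope="session")
def cnv_groups():
    """The packaged four tumor-group CNV profiles."""
    return load_corticotroph_cnv_groups()


@pytest.fixture
def perfect_phylogeny_matrix():
    """Four samples, laminar carrier family: trunk x2, two cherries, four privates."""
    membership = {
        "s1": {"t1": True, "t2": True, "ab": True, "p1": True},
        "s2": {"t1": True, "t2": True, "ab": True, "p2": True},
        "s3": {"t1": True, "t2": True, "cd": True, "p3": True},
        "s4": {"t1": True, "t2": True, "cd": True, "p4": True},
    }
    return presence_from_membership(membership)


def random_presence(rng, n_samples, n_variants):
    """Random boolean matrix with every variant carried somewhere."""
    while True:
        arr = rng.random((n_samples, n_variants)) < 0.5
        if arr.any(axis=0).all():
            return presence_from_membership(
                arr,
                samples=[f"s{i+1}" for i in range(n_samples)],
                variants=[f"v{j+1}" for j in range(n_variants)],
            )


def make_variant(vid, chrom="chr1", pos=100, ref="C", alt="T", gene="",
                 mut=40, refr=60, vclass="missense"):
    return VariantRecord(
        variant_id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        mut_reads=mut, ref_reads=refr, variant_class=vclass,
    )


@pytest.fixture
def snp_set():
    """Small per-sample variant set with positional SNVs."""
    recs = [
        make_variant("chr1:100:C>T", pos=100, ref="C", alt="T"),
        make_variant("chr1:500:G>A", pos=500, ref="G", alt="A"),
        make_variant("chr2:100:C>G", chrom="chr2", pos=100, ref="C", alt="G"),
    ]
    return SampleVariantSet(sample_id="T01", records=recs)
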