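import math

import numpy as np
import pandas as pd
import pytest
import skbio.diversity.alpha as skbio_alpha
from hypothesis import given, settings
from hypothesis import strategies as st

from vircomp.diversity import (
    OtuTable,
    family_rollup,
    goods_coverage,
    otu_intersections,
    rarefaction_curve,
    shannon_index,
    simpson_index,
)
from vircomp.errors import (
    DepthError,
    EmptySampleError,
    InsufficientReadsError,
    LookupError_,
    ParameterError,
)

counts_strategy = st.lists(st.integers(min_value=0, max_value=200),
                           min_size=1, max_size=15).filter(lambda c: sum(c) >= 2)


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([1, 1, 1, 1], math.log(4)),   # uniform -> ln S
        ([10], 0.0),                   # single OTU
        ([2, 1, 1], 1.0397207708399179),
    ],
)
def test_shannon_point_values(counts, expected):
    H, (lci, hci) = shannon_index(counts)
    assert H == pytest.approx(expected, abs=1e-12)
    assert lci <= H <= hci


def test_shannon_matches_independent_implementation():
    rng = np.random.default_rng(7)
    for _ in range(20):
        counts = rng.integers(1, 60, size=rng.integers(1, 12))
        H, _ = shannon_index(counts)
        assert H == pytest.approx(skbio_alpha.shannon(counts, base=np.e))


def test_shannon_rejects_empty():
    with pytest.raises(EmptySampleError):
        shannon_index([0, 0])


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([10], 1.0),          # complete dominance
        ([2, 2], 4.0 / 12.0),  # ordered-pair enumeration: 4 same-OTU of 12
        ([1, 1, 1], 0.0),     # no intra-OTU pair
    ],
)
def test_simpson_point_values(counts, expected):
    D, (lci, hci) = simpson_index(counts)
    assert D == pytest.approx(expected, abs=1e-12)
    assert lci <= D <= hci


def test_simpson_equals_pair_enumeration():
    # D is the probability two reads drawn without replacement share an OTU
    rng = np.random.default_rng(3)
    for _ in range(10):
        counts = rng.integers(0, 12, size=6)
        if counts.sum() < 2:
            continue
        reads = np.repeat(np.arange(counts.size), counts)
        same = sum(
            1
            for i in range(reads.size)
            for j in range(reads.size)
            if i != j and reads[i] == reads[j]
        )
        D, _ = simpson_index(counts)
        assert D == pytest.approx(same / (reads.size * (reads.size - 1)))


def test_simpson_needs_two_reads():
    with pytest.raises(InsufficientReadsError):
        simpson_index([1])


@pytest.mark.parametrize(
    "counts,expected",
    [([5, 3, 1, 1], 80.0), ([4, 6], 100.0), ([1, 1, 1], 0.0)],
)
def test_goods_coverage(counts, expected):
    assert goods_coverage(counts) == pytest.approx(expected)
    assert goods_coverage(counts) == pytest.approx(
        skbio_alpha.goods_coverage(counts) * 100.0
    )


def test_rarefaction_exact_small_case():
    # counts [2,1], n=2: the 3 distinct subsets give richness (1+2+2)/3
    assert rarefaction_curve([2, 1], [2])[0] == pytest.approx(5.0 / 3.0)


def test_rarefaction_boundaries():
    counts = [7, 3, 2, 1]
    assert rarefaction_curve(counts, [1])[0] == pytest.approx(1.0)
    assert rarefaction_curve(counts, [13])[0] == pytest.approx(4.0)
    curve = rarefaction_curve(counts, list(range(1, 14)))
    assert (np.diff(curve) >= -1e-12).all()
    with pytest.raises(DepthError):
        rarefaction_curve(counts, [14])


def test_rarefaction_matches_resampling_mean():
    rng = np.random.default_rng(11)
    for _ in range(5):
        counts = rng.integers(0, 10, size=rng.integers(2, 10))
        counts[0] = max(counts[0], 2)
        N = counts.sum()
        n = int(rng.integers(1, N + 1))
        analytic = rarefaction_curve(counts, [n])[0]
        reads = np.repeat(np.arange(counts.size), counts)
        B = 10_000
        draws = rng.permuted(np.tile(reads, (B, 1)), axis=1)[:, :n]
        rich = (np.sort(draws, axis=1)[:, 1:] != np.sort(draws, axis=1)[:, :-1]).sum(axis=1) + 1
        mc_mean = rich.mean()
        mc_se = rich.std(ddof=1) / np.sqrt(B)
        assert abs(analytic - mc_mean) <= 3 * mc_se + 1e-9


@settings(derandomize=True, max_examples=60)
@given(counts_strategy)
def test_diversity_identities(counts):
    arr = np.asarray(counts)
    pos = arr[arr > 0]
    if pos.size == 0:
        return
    H, _ = shannon_index(arr)
    D, _ = simpson_index(arr)
    S = pos.size
    assert H <= math.log(S) + 1e-9
    if S == 1:
        assert H == pytest.approx(0.0) and D == pytest.approx(1.0)
    else:
        assert H > 0
    if (pos == pos[0]).all():
        assert H == pytest.approx(math.log(S))


@settings(derandomize=True, max_examples=60)
@given(counts_strategy)
def test_merging_otus_monotone(counts):
    arr = [c for c in counts if c > 0]
    if len(arr) < 2:
        return
    merged = [arr[0] + arr[1]] + arr[2:]
    H0, _ = shannon_index(arr)
    H1, _ = shannon_index(merged)
    D0, _ = simpson_index(arr)
    D1, _ = simpson_index(merged)
    assert H1 <= H0 + 1e-9
    assert D1 >= D0 - 1e-9


def _table(data, samples):
    return OtuTable(pd.DataFrame(data, columns=samples))


def test_otu_intersections_hand_checked():
    # presence sets {a,b}, {b,c}, {b}: core region is {b} alone
    frame = pd.DataFrame(
        {"s1": [3, 5, 0], "s2": [0, 2, 4], "s3": [0, 7, 0]},
        index=["a", "b", "c"],
    )
    regions, share = otu_intersections(OtuTable(frame))
    assert regions[frozenset({"s1", "s2", "s3"})] == 1
    assert sum(regions.values()) == 3
    assert share == pytest.approx(100.0 * (5 + 2 + 7) / 21)


def test_otu_intersections_disjoint_and_errors():
    frame = pd.DataFrame({"s1": [3, 0], "s2": [0, 2]}, index=["a", "b"])
    regions, share = otu_intersections(OtuTable(frame))
    assert frozenset({"s1", "s2"}) not in regions
    assert share == 0.0
    with pytest.raises(ParameterError):
        otu_intersections(OtuTable(pd.DataFrame({"s1": [3]}, index=["a"])))


def test_family_rollup_pooling():
    frame = pd.DataFrame({"s1": [900, 95, 5]}, index=["a", "b", "c"])
    tax = {
        "a": ("P", "FamA", "g"),
        "b": ("P", "FamB", "g"),
        "c": ("P", "FamC", "g"),
    }
    out = family_rollup(OtuTable(frame), tax, threshold=1.0)
    shares = dict(zip(out["family"], out["share_pct"]))
    assert shares == pytest.approx({"FamA": 90.0, "FamB": 9.5, "Others": 0.5})
    assert sum(shares.values()) == pytest.approx(100.0)
    # threshold 0: nothing pooled
    out0 = family_rollup(OtuTable(frame), tax, threshold=0.0)
    assert "Others" not in set(out0["family"])
    # single family
    out1 = family_rollup(
        OtuTable(pd.DataFrame({"s1": [10, 5]}, index=["a", "b"])),
        {"a": ("P", "F", "g"), "b": ("P", "F", "g")},
    )
    assert out1["share_pct"].tolist() == pytest.approx([100.0])


def test_family_rollup_missing_taxonomy_names_otu():
    frame = pd.DataFrame({"s1": [1, 1]}, index=["a", "zzz"])
    with pytest.raises(LookupError_, match="zzz"):
        family_rollup(OtuTable(frame), {"a": ("P", "F", "g")})
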