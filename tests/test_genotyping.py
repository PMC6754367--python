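"""Genotyping, classification, breakpoints, dedup and benchmarking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkco.genotyping import (
    NON_RECOMBINANT,
    RECOMBINANT,
    UNDETERMINED,
    ClassCriteria,
    GenotypeVector,
    benchmark_compare,
    call_breakpoint,
    classify_molecule,
    deduplicate_calls,
    filter_benchmark,
    genotype_molecule,
    intersect_dual_reference,
)
from linkco.io import COCall
from linkco.molecules import Molecule


def make_vector(alleles, positions=None, molecule_id="m1"):
    if positions is None:
        positions = [1_000 + 1_500 * i for i in range(len(alleles))]
    return GenotypeVector(
        molecule_id=molecule_id,
        barcode="BC1",
        chrom="chr1",
        marker_ids=tuple(f"chr1:{p}" for p in positions),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.asarray(alleles, dtype=np.int8),
        supports=np.ones(len(alleles), dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------


def test_genotype_consensus_and_omissions(grid_markers):
    mol = Molecule(
        "m1", "BC1", "chr1", 1_000, 9_000, 5, 1_000,
        allele_observations={
            "chr1:1000": [2, 0, 0],   # P1, support 2
            "chr1:3000": [0, 3, 0],   # P2, support 3
            "chr1:5000": [0, 0, 2],   # only non-parental bases: omitted
            "chr1:7000": [1, 1, 0],   # conflict: omitted
        },
    )
    vec = genotype_molecule(mol, grid_markers)
    assert vec.marker_ids == ("chr1:1000", "chr1:3000")
    assert vec.alleles.tolist() == [0, 1]
    assert vec.supports.tolist() == [2, 3]
    assert list(vec.positions) == sorted(vec.positions)


def test_genotype_uncovered_markers_absent(grid_markers):
    mol = Molecule("m1", "BC1", "chr1", 1_000, 9_000, 1, 300,
                   allele_observations={"chr1:2000": [0, 3, 0]})
    vec = genotype_molecule(mol, grid_markers)
    assert vec.marker_ids == ("chr1:2000",)
    assert vec.supports.tolist() == [3]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def oracle_classify(alleles, positions, min_markers, min_span):
    """Independent re-statement of the classification rule."""
    runs = []
    for _, group in itertools.groupby(
        range(len(alleles)), key=lambda i: alleles[i]
    ):
        idx = list(group)
        runs.append((idx[0], idx[-1]))
    if len(runs) == 1:
        lo, hi = runs[0]
        return (
            NON_RECOMBINANT if hi - lo + 1 >= min_markers else UNDETERMINED
        )
    if len(runs) == 2:
        for lo, hi in runs:
            if hi - lo + 1 < min_markers:
                return UNDETERMINED
            if positions[hi] - positions[lo] < min_span:
                return UNDETERMINED
        return RECOMBINANT
    return UNDETERMINED


@pytest.mark.parametrize("length", range(0, 9))
@pytest.mark.parametrize("spacing", [400, 1_500])
def test_classification_matches_exhaustive_enumeration(length, spacing):
    """Every allele string up to length 8, on both a wide and a narrow
    marker spacing (the narrow one makes short runs fail the span rule)."""
    criteria = ClassCriteria(min_markers_per_cluster=2, min_cluster_span=1_000)
    positions = [1_000 + spacing * i for i in range(length)]
    for alleles in itertools.product([0, 1], repeat=length):
        vec = make_vector(list(alleles), positions)
        expected = oracle_classify(alleles, positions, 2, 1_000)
        assert classify_molecule(vec, criteria) == expected, (alleles, spacing)


def test_classification_examples():
    assert classify_molecule(make_vector([0, 0, 0, 1, 1])) == RECOMBINANT
    assert classify_molecule(make_vector([0, 1, 0, 1])) == UNDETERMINED
    assert classify_molecule(make_vector([0, 0, 0, 1])) == UNDETERMINED  # 1-marker run
    assert classify_molecule(make_vector([0, 0])) == NON_RECOMBINANT
    assert classify_molecule(make_vector([])) == UNDETERMINED


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------


def test_breakpoint_between_flanking_markers():
    vec = make_vector([0, 0, 1, 1], positions=[2_000, 10_000, 16_700, 30_000])
    call = call_breakpoint(vec)
    assert (call.left_pos, call.right_pos) == (10_000, 16_700)
    assert call.resolution == 6_700
    assert (call.left_genotype, call.right_genotype) == ("P1", "P2")


def test_breakpoint_minimum_resolution_one_bp():
    vec = make_vector(
        [0, 0, 1, 1], positions=[1_000, 5_000, 5_001, 10_000]
    )
    criteria = ClassCriteria(min_markers_per_cluster=2, min_cluster_span=1_000)
    assert call_breakpoint(vec, criteria).resolution == 1


def test_breakpoint_on_non_recombinant_is_contract_violation():
    with pytest.raises(ValueError, match="recombinant"):
        call_breakpoint(make_vector([0, 0, 0]))


# ---------------------------------------------------------------------------
# dual-reference intersection
# ---------------------------------------------------------------------------


def _call(molecule_id="m1", barcode="BC1", chrom="chr1", left=10_000,
          right=16_000, pool="p"):
    return COCall(
        molecule_id=molecule_id,
        barcode=barcode,
        chrom=chrom,
        left_marker_id=f"{chrom}:{left}",
        right_marker_id=f"{chrom}:{right}",
        left_pos=left,
        right_pos=right,
        left_genotype="P1",
        right_genotype="P2",
        pool_id=pool,
    )


@pytest.fixture
def two_chrom_markers():
    from linkco.io import MarkerSet

    records = []
    for chrom in ("chr1", "chr2"):
        for p in range(1_000, 50_001, 1_000):
            records.append(
                dict(marker_id=f"{chrom}:{p}", chrom=chrom, pos=p,
                     allele_parent1="A", allele_parent2="C",
                     colinear=True, pos_alt_reference=float(p))
            )
    return MarkerSet.from_records(records)


def test_dual_reference_identical_call_kept(two_chrom_markers):
    c = _call()
    assert intersect_dual_reference([c], [_call()], two_chrom_markers) == [c]


def test_dual_reference_unconfirmed_call_dropped(two_chrom_markers):
    assert intersect_dual_reference([_call()], [], two_chrom_markers) == []
    # same barcode, far-away breakpoint: marker intervals do not overlap
    other = _call(left=40_000, right=46_000)
    assert intersect_dual_reference([_call()], [other], two_chrom_markers) == []


def test_dual_reference_different_chrom_dropped(two_chrom_markers):
    ref2 = _call(chrom="chr2")
    assert intersect_dual_reference([_call()], [ref2], two_chrom_markers) == []


def test_dual_reference_overlapping_interval_kept(two_chrom_markers):
    ref2 = _call(left=15_000, right=20_000)  # overlaps [10k,16k] in index space
    c = _call()
    assert intersect_dual_reference([c], [ref2], two_chrom_markers) == [c]


# ---------------------------------------------------------------------------
# distinct sites
# ---------------------------------------------------------------------------


def test_dedup_identical_intervals_merge():
    sites = deduplicate_calls([_call("m1"), _call("m2")])
    assert len(sites) == 1
    assert sites[0].n_members == 2
    assert (sites[0].start, sites[0].end) == (10_000, 16_000)


def test_dedup_disjoint_intervals_stay_separate():
    sites = deduplicate_calls([_call("m1"), _call("m2", left=30_000, right=35_000)])
    assert len(sites) == 2


def test_dedup_single_linkage_chain():
    a = _call("a", left=1_000, right=5_000)
    b = _call("b", left=4_000, right=9_000)
    c = _call("c", left=8_000, right=12_000)  # overlaps b, not a
    sites = deduplicate_calls([a, b, c])
    assert len(sites) == 1
    # chained cluster has empty common intersection -> union reported
    assert (sites[0].start, sites[0].end) == (1_000, 12_000)
    assert sites[0].n_members == 3


def test_dedup_intersection_interval():
    a = _call("a", left=1_000, right=6_000)
    b = _call("b", left=4_000, right=9_000)
    (site,) = deduplicate_calls([a, b])
    assert (site.start, site.end) == (4_000, 6_000)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    raw=st.lists(
        st.tuples(st.integers(1, 200), st.integers(1, 60)), min_size=1, max_size=25
    )
)
def test_dedup_matches_connected_components_oracle(raw):
    intervals = [(s * 100, (s + w) * 100) for s, w in raw]
    calls = [
        _call(f"m{i}", left=s, right=e) for i, (s, e) in enumerate(intervals)
    ]
    sites = deduplicate_calls(calls)
    from conftest import brute_force_single_linkage

    # closed intervals intersect iff gap <= 0
    components = brute_force_single_linkage(intervals, 0)
    assert len(sites) == len(components)
    got = sorted(tuple(sorted(s.member_ids)) for s in sites)
    expected = sorted(
        tuple(sorted(f"m{i}" for i in comp)) for comp in components
    )
    assert got == expected


# ---------------------------------------------------------------------------
# benchmark filtering and comparison
# ---------------------------------------------------------------------------


def _benchmark_frame(widths, chrom="chr1", gap=50_000):
    starts = np.arange(len(widths)) * gap + 10_000
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + np.asarray(widths)}
    )


def test_benchmark_filter_drops_wide_intervals():
    widths = [500] * 400 + [10_001] * 15
    bench = _benchmark_frame(widths)
    assert len(filter_benchmark(bench)) == 400


def test_benchmark_filter_keeps_exact_threshold_width():
    bench = _benchmark_frame([10_000, 10_001])
    assert len(filter_benchmark(bench)) == 1
    assert len(filter_benchmark(bench.iloc[0:0])) == 0


def test_benchmark_compare_counts_and_percentages():
    bench = _benchmark_frame([1_000] * 10)
    calls = []
    # 6 TP hitting the first 3 benchmark intervals, 2 FP elsewhere
    for i, b in enumerate(bench.itertuples(index=False)):
        if i < 3:
            calls.append(_call(f"tp{i}a", left=b.start - 500, right=b.start + 500))
            calls.append(_call(f"tp{i}b", left=b.start + 100, right=b.end + 900))
    calls.append(_call("fp1", left=2_000, right=4_000))
    calls.append(_call("fp2", left=1_000_000, right=1_005_000))
    result = benchmark_compare(calls, bench)
    assert (result.n_total, result.n_tp, result.n_fp) == (8, 6, 2)
    assert result.tp_pct == 75.0
    assert result.fp_pct == 25.0
    assert result.n_benchmark_hit == 3
    assert result.recall_pct == 30.0


def test_benchmark_compare_empty_benchmark_all_fp():
    calls = [_call("m1"), _call("m2", left=30_000, right=31_000)]
    result = benchmark_compare(calls, _benchmark_frame([]))
    assert result.n_tp == 0
    assert result.n_fp == 2
    assert result.recall_pct == 0.0


def test_benchmark_compare_padding_rescues_near_miss():
    bench = _benchmark_frame([1_000])
    near = _call("m1", left=bench.end[0] + 100, right=bench.end[0] + 900)
    assert benchmark_compare([near], bench).n_tp == 0
    assert benchmark_compare([near], bench, pad=200).n_tp == 1
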