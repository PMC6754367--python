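"""Shared fixtures: a small marker grid and alignment builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from linkco.io import BarcodedAlignment, MarkerSet


@pytest.fixture(scope="session")
def grid_markers() -> MarkerSet:
    """Markers on chr1 every 1 kb up to 100 kb; parent1 = A, parent2 = C."""
    pos = np.arange(1_000, 100_001, 1_000)
    return MarkerSet.from_records(
        dict(
            marker_id=f"chr1:{p}",
            chrom="chr1",
            pos=int(p),
            allele_parent1="A",
            allele_parent2="C",
            colinear=True,
            pos_alt_reference=float(p),
        )
        for p in pos
    )


@pytest.fixture
def make_aln():
    """Factory for alignments with explicit marker observations."""

    def build(barcode, start, end, chrom="chr1", obs=(), nbases=None):
        return BarcodedAlignment(
            barcode=barcode,
            reference_id="ref1",
            chrom=chrom,
            start=start,
            end=end,
            n_aligned_bases=nbases if nbases is not None else (end - start + 1),
            marker_observations=tuple(obs),
        )

    return build


def brute_force_single_linkage(intervals, max_gap):
    """Independent oracle: single-linkage clustering of 1-based inclusive
    intervals at a gap threshold, via union-find over all pairs."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)  # <= 0 means overlap
            if gap <= max_gap:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())
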