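"""Molecule genotyping, recombinant classification and crossover calls.

A molecule is genotyped at every marker it covers; the ordered sequence
of consensus parental alleles is then classified:

* ``non_recombinant`` — a single parental run with enough markers;
* ``recombinant`` — exactly one switch between two runs, each run
  satisfying minimum marker count and span criteria; the breakpoint is
  the interval between the two markers flanking the switch;
* ``undetermined`` — anything else (no markers, two or more switches,
  or a run failing the criteria), which covers molecules spanning two
  crossovers as well as chimeric barcode clusters.

Downstream utilities intersect calls made against both parental
reference assemblies, merge redundant calls into distinct crossover
sites, and score call sets against an independently determined
benchmark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import PARENT1, PARENT2, COCall, MarkerSet
from .molecules import Molecule
from .util import percent

log = logging.getLogger("linkco.genotyping")

NON_RECOMBINANT = "non_recombinant"
RECOMBINANT = "recombinant"
UNDETERMINED = "undetermined"


@dataclass(slots=True)
class ClassCriteria:
    """Criteria a parental-allele run must meet to support a call.

    ``min_markers_per_cluster`` and ``min_cluster_span`` guard against
    single stray markers mimicking a run; a recombinant molecule must
    show exactly one switch.
    """

    min_markers_per_cluster: int = 2
    min_cluster_span: int = 1_000

    def __post_init__(self) -> None:
        if self.min_markers_per_cluster < 1:
            raise ValueError("min_markers_per_cluster must be >= 1")
        if self.min_cluster_span < 0:
            raise ValueError("min_cluster_span must be >= 0")


@dataclass(slots=True)
class GenotypeVector:
    """Ordered unambiguous marker genotypes of one molecule."""

    molecule_id: str
    barcode: str
    chrom: str
    marker_ids: tuple
    positions: np.ndarray  # strictly increasing, 1-based
    alleles: np.ndarray    # 0 = parent 1, 1 = parent 2
    supports: np.ndarray   # read count behind each consensus

    def __len__(self) -> int:
        return len(self.marker_ids)


def genotype_molecule(molecule: Molecule, markers: MarkerSet) -> GenotypeVector:
    """Consensus parental genotype per covered marker.

    Markers observed with bases matching only one parental allele give a
    consensus with its read support; markers showing both parental
    alleles (possible when the heterozygosity filter was relaxed) or
    only non-parental bases are omitted.
    """
    entries = []
    for marker_id, (c1, c2, _) in molecule.allele_observations.items():
        if c1 > 0 and c2 == 0:
            entries.append((markers.pos_of(marker_id), marker_id, 0, c1))
        elif c2 > 0 and c1 == 0:
            entries.append((markers.pos_of(marker_id), marker_id, 1, c2))
    entries.sort()
    return GenotypeVector(
        molecule_id=molecule.molecule_id,
        barcode=molecule.barcode,
        chrom=molecule.chrom,
        marker_ids=tuple(e[1] for e in entries),
        positions=np.array([e[0] for e in entries], dtype=np.int64),
        alleles=np.array([e[2] for e in entries], dtype=np.int8),
        supports=np.array([e[3] for e in entries], dtype=np.int64),
    )


def _runs(alleles: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of constant-allele runs."""
    if len(alleles) == 0:
        return []
    switches = np.flatnonzero(np.diff(alleles)) + 1
    bounds = [0, *switches.tolist(), len(alleles)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def classify_molecule(
    vector: GenotypeVector, criteria: ClassCriteria | None = None
) -> str:
    """Label a genotype vector recombinant / non-recombinant / undetermined."""
    criteria = criteria or ClassCriteria()
    runs = _runs(vector.alleles)
    if len(runs) == 1:
        lo, hi = runs[0]
        if hi - lo >= criteria.min_markers_per_cluster:
            return NON_RECOMBINANT
        return UNDETERMINED
    if len(runs) == 2:
        for lo, hi in runs:
            if hi - lo < criteria.min_markers_per_cluster:
                return UNDETERMINED
            span = int(vector.positions[hi - 1] - vector.positions[lo])
            if span < criteria.min_cluster_span:
                return UNDETERMINED
        return RECOMBINANT
    return UNDETERMINED


def call_breakpoint(
    vector: GenotypeVector,
    criteria: ClassCriteria | None = None,
    pool_id: str = "",
) -> COCall:
    """Breakpoint interval of a recombinant genotype vector: from the
    last marker of the first run to the first marker of the second run.

    Raises :class:`ValueError` when the vector does not classify as
    recombinant (contract violation).
    """
    if classify_molecule(vector, criteria) != RECOMBINANT:
        raise ValueError(
            f"call_breakpoint requires a recombinant vector ({vector.molecule_id})"
        )
    runs = _runs(vector.alleles)
    (_, hi1), (lo2, _) = runs
    left, right = hi1 - 1, lo2
    genos = (PARENT1, PARENT2)
    return COCall(
        molecule_id=vector.molecule_id,
        barcode=vector.barcode,
        chrom=vector.chrom,
        left_marker_id=vector.marker_ids[left],
        right_marker_id=vector.marker_ids[right],
        left_pos=int(vector.positions[left]),
        right_pos=int(vector.positions[right]),
        left_genotype=genos[vector.alleles[left]],
        right_genotype=genos[vector.alleles[right]],
        pool_id=pool_id,
    )


class CallResult(NamedTuple):
    calls: list
    labels: dict        # molecule_id -> classification label
    class_counts: dict  # label -> count


def call_cos(
    molecules: Sequence[Molecule],
    markers: MarkerSet,
    criteria: ClassCriteria | None = None,
    pool_id: str = "",
) -> CallResult:
    """Genotype, classify and call breakpoints for a set of molecules."""
    criteria = criteria or ClassCriteria()
    calls, labels = [], {}
    counts = {NON_RECOMBINANT: 0, RECOMBINANT: 0, UNDETERMINED: 0}
    for mol in molecules:
        vec = genotype_molecule(mol, markers)
        label = classify_molecule(vec, criteria)
        labels[mol.molecule_id] = label
        counts[label] += 1
        if label == RECOMBINANT:
            calls.append(call_breakpoint(vec, criteria, pool_id))
    return CallResult(calls, labels, counts)


# ---------------------------------------------------------------------------
# dual-reference intersection
# ---------------------------------------------------------------------------


def intersect_dual_reference(
    calls_ref1: Sequence[COCall],
    calls_ref2: Sequence[COCall],
    markers: MarkerSet,
) -> list:
    """Keep reference-1 calls confirmed against the second reference.

    A call survives iff a call with the same barcode exists in the
    reference-2 set whose flanking-marker interval overlaps it in the
    shared marker-index space (marker IDs project to both assemblies, so
    indices are comparable; calls on different chromosomes occupy
    disjoint index ranges and can never match).  Kept calls retain their
    reference-1 coordinates.
    """
    by_barcode: dict[str, list[tuple[int, int]]] = {}
    n_unprojected = 0
    for c in calls_ref2:
        try:
            idx = (markers.marker_index(c.left_marker_id),
                   markers.marker_index(c.right_marker_id))
        except KeyError:
            n_unprojected += 1
            continue
        by_barcode.setdefault(c.barcode, []).append(idx)
    kept = []
    for c in calls_ref1:
        if not (markers.has_alt_projection(c.left_marker_id)
                and markers.has_alt_projection(c.right_marker_id)):
            n_unprojected += 1
            continue
        i1 = markers.marker_index(c.left_marker_id)
        i2 = markers.marker_index(c.right_marker_id)
        for j1, j2 in by_barcode.get(c.barcode, ()):
            if i1 <= j2 and j1 <= i2:
                kept.append(c)
                break
    if n_unprojected:
        log.info("intersect_dual_reference: %d calls lacked an alt-reference "
                 "marker projection", n_unprojected)
    return kept


# ---------------------------------------------------------------------------
# distinct sites
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class DistinctSite:
    """A cluster of crossover calls whose breakpoint intervals coincide,
    counted as one distinct crossover."""

    chrom: str
    start: int
    end: int
    n_members: int
    member_ids: tuple


def deduplicate_calls(calls: Sequence[COCall]) -> list:
    """Single-linkage merge of calls with intersecting breakpoint
    intervals into distinct crossover sites.

    The site interval is the intersection of its members' intervals (the
    tightest region consistent with all of them); if a chained cluster
    has an empty common intersection the union is reported instead.
    Member counts are recorded so users can split coincident independent
    events post hoc.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.left_pos, c.right_pos))
    sites: list[DistinctSite] = []
    cluster: list[COCall] = []
    max_right = None

    def flush() -> None:
        lo = max(c.left_pos for c in cluster)
        hi = min(c.right_pos for c in cluster)
        if lo > hi:  # empty common intersection: fall back to the union
            lo = min(c.left_pos for c in cluster)
            hi = max(c.right_pos for c in cluster)
        sites.append(
            DistinctSite(
                chrom=cluster[0].chrom,
                start=lo,
                end=hi,
                n_members=len(cluster),
                member_ids=tuple(c.molecule_id for c in cluster),
            )
        )

    for c in ordered:
        if cluster and (c.chrom != cluster[0].chrom or c.left_pos > max_right):
            flush()
            cluster = []
        max_right = c.right_pos if not cluster else max(max_right, c.right_pos)
        cluster.append(c)
    if cluster:
        flush()
    return sites


# ---------------------------------------------------------------------------
# benchmark comparison
# ---------------------------------------------------------------------------


def filter_benchmark(
    benchmark: pd.DataFrame, max_intermarker: int = 10_000
) -> pd.DataFrame:
    """Drop benchmark crossovers whose interval is wider than
    ``max_intermarker`` bp (sparse-marker regions where the breakpoint is
    poorly localized); an interval of exactly that width is kept."""
    width = benchmark["end"] - benchmark["start"]
    return benchmark[width <= max_intermarker].reset_index(drop=True)


class BenchmarkResult(NamedTuple):
    n_total: int
    n_tp: int
    n_fp: int
    tp_pct: float
    fp_pct: float
    n_benchmark: int
    n_benchmark_hit: int
    recall_pct: float


def benchmark_compare(
    calls: Sequence[COCall], benchmark: pd.DataFrame, pad: int = 0
) -> BenchmarkResult:
    """Score calls against benchmark intervals.

    A call is a true positive iff its breakpoint interval intersects at
    least one (optionally padded) benchmark interval; recall is the
    fraction of benchmark crossovers hit by at least one call.
    Percentages are rounded to one decimal, half away from zero.
    """
    if len(calls) == 0:
        log.warning("benchmark_compare: empty call set")
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(benchmark.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start - pad, row.end + pad + 1, i
        )
    n_tp = 0
    hit: set[int] = set()
    for c in calls:
        tree = trees.get(c.chrom)
        if tree is None:
            continue
        found = tree.overlap(c.left_pos, c.right_pos + 1)
        if found:
            n_tp += 1
            hit.update(iv.data for iv in found)
    n_total = len(calls)
    n_fp = n_total - n_tp
    return BenchmarkResult(
        n_total=n_total,
        n_tp=n_tp,
        n_fp=n_fp,
        tp_pct=percent(n_tp, n_total) if n_total else 0.0,
        fp_pct=percent(n_fp, n_total) if n_total else 0.0,
        n_benchmark=len(benchmark),
        n_benchmark_hit=len(hit),
        recall_pct=percent(len(hit), len(benchmark)) if len(benchmark) else 0.0,
    )
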