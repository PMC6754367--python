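"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the SAM/VCF
convention).  BED input and output are converted to and from 0-based
half-open at this boundary and nowhere else.

Two alignment dialects are supported: SAM/BAM with a barcode tag
(default ``BX``, the common linked-read convention), and a plain TSV
dialect with columns ``barcode  chrom  start  end  n_aligned_bases
observations`` where ``observations`` is a semicolon-separated list of
``marker_id=base`` pairs.  The TSV dialect lets tests and the simulator
construct inputs without BAM machinery.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("linkco.io")

#: parental genotype labels used throughout the package
PARENT1 = "P1"
PARENT2 = "P2"
#: label for an observed base that matches neither parental allele
OTHER = "other"

_MARKER_COLUMNS = [
    "marker_id",
    "chrom",
    "pos",
    "allele_parent1",
    "allele_parent2",
    "colinear",
    "pos_alt_reference",
]


@dataclass(slots=True)
class BarcodedAlignment:
    """A single barcoded alignment (one read, or one read pair emitted as
    a contiguous span by the simulator) together with the bases it
    observes at marker positions.

    Coordinates are 1-based inclusive.  ``marker_observations`` is a
    tuple of ``(marker_id, observed_base)`` pairs for the marker
    positions covered by aligned bases.
    """

    barcode: str
    reference_id: str
    chrom: str
    start: int
    end: int
    n_aligned_bases: int
    marker_observations: tuple = ()

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("alignment barcode must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"alignment start {self.start} > end {self.end} ({self.barcode})"
            )

    def validate(self, markers: "MarkerSet") -> None:
        """Check that every observed marker lies within the aligned span."""
        for marker_id, _ in self.marker_observations:
            pos = markers.pos_of(marker_id)
            if not (self.start <= pos <= self.end):
                raise ValueError(
                    f"marker {marker_id} at {pos} outside alignment "
                    f"[{self.start}, {self.end}]"
                )


class MarkerSet:
    """An ordered set of biallelic SNP markers.

    Backed by a :class:`pandas.DataFrame` with columns ``marker_id``,
    ``chrom``, ``pos`` (1-based), ``allele_parent1``, ``allele_parent2``,
    ``colinear`` and ``pos_alt_reference`` (position on the second
    parental assembly, or NaN when the marker has no projection).
    Records are kept sorted by ``(chrom, pos)``; the sort order defines a
    stable global marker index used for dual-reference call matching.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _MARKER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        df = df[_MARKER_COLUMNS].copy()
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate marker positions within a chromosome")
        if df["marker_id"].duplicated().any():
            raise ValueError("marker_id values must be unique")
        if (df["allele_parent1"] == df["allele_parent2"]).any():
            raise ValueError("parental alleles must differ at every marker")
        self._df = df
        self._index = {m: i for i, m in enumerate(df["marker_id"])}
        # plain arrays for hot per-marker lookups
        self._pos = df["pos"].to_numpy(np.int64)
        self._a1 = df["allele_parent1"].to_numpy(object)
        self._a2 = df["allele_parent2"].to_numpy(object)
        self._alt = df["pos_alt_reference"].to_numpy()
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._by_chrom[chrom] = (
                sub["pos"].to_numpy(np.int64),
                sub["marker_id"].to_numpy(object),
                sub["allele_parent1"].to_numpy(object),
                sub["allele_parent2"].to_numpy(object),
            )

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "MarkerSet":
        df = pd.DataFrame(list(records))
        if "colinear" not in df.columns:
            df["colinear"] = False
        if "pos_alt_reference" not in df.columns:
            df["pos_alt_reference"] = np.nan
        return cls(df)

    # -- basic access ---------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def pos_of(self, marker_id: str) -> int:
        return int(self._pos[self._index[marker_id]])

    def marker_index(self, marker_id: str) -> int:
        """Global ordinal of a marker in (chrom, pos) sort order."""
        return self._index[marker_id]

    def allele_pair(self, marker_id: str) -> tuple[str, str]:
        i = self._index[marker_id]
        return self._a1[i], self._a2[i]

    def classify_base(self, marker_id: str, base: str) -> str:
        """Map an observed base to ``P1``/``P2``/``other``."""
        i = self._index[marker_id]
        if base == self._a1[i]:
            return PARENT1
        if base == self._a2[i]:
            return PARENT2
        return OTHER

    def positions_in(self, chrom: str, start: int, end: int):
        """Return ``(ids, positions)`` of markers inside ``[start, end]``."""
        if chrom not in self._by_chrom:
            return np.empty(0, object), np.empty(0, np.int64)
        pos, ids, _, _ = self._by_chrom[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        return ids[lo:hi], pos[lo:hi]

    def has_alt_projection(self, marker_id: str) -> bool:
        return pd.notna(self._alt[self._index[marker_id]])


class AlignmentBatch(NamedTuple):
    """Alignments parsed from a file plus the barcode-less skip count."""

    alignments: list[BarcodedAlignment]
    n_skipped: int


# ---------------------------------------------------------------------------
# markers (VCF)
# ---------------------------------------------------------------------------


def read_markers(
    path,
    parent1_label: str | None = None,
    parent2_label: str | None = None,
) -> MarkerSet:
    """Load biallelic SNP markers from a VCF.

    Indels and multi-allelic records are skipped (with a logged count).
    When both parent labels name samples in the VCF, the parental alleles
    are taken from their homozygous genotypes; otherwise REF is assigned
    to parent 1 and ALT to parent 2.  Marker IDs are ``chrom:pos``.  No
    quality filtering is applied.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    use_gt = (
        parent1_label is not None
        and parent2_label is not None
        and parent1_label in samples
        and parent2_label in samples
    )
    records = []
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.ref, alts[0]
        if use_gt:
            try:
                g1 = rec.samples[parent1_label].alleles
                g2 = rec.samples[parent2_label].alleles
            except KeyError:  # pragma: no cover - guarded by use_gt
                n_skipped += 1
                continue
            if None in (g1 + g2) or len(set(g1)) != 1 or len(set(g2)) != 1:
                n_skipped += 1
                continue
            a1, a2 = g1[0], g2[0]
            if a1 == a2:
                n_skipped += 1
                continue
        else:
            a1, a2 = ref, alt
        records.append(
            dict(
                marker_id=f"{rec.chrom}:{rec.pos}",
                chrom=rec.chrom,
                pos=rec.pos,
                allele_parent1=a1,
                allele_parent2=a2,
                colinear=False,
                pos_alt_reference=np.nan,
            )
        )
    vf.close()
    if n_skipped:
        log.info("read_markers: skipped %d non-biallelic/indel records", n_skipped)
    if not records:
        raise ValueError(f"no usable biallelic SNPs in {path}")
    return MarkerSet(pd.DataFrame(records))


def write_markers_vcf(markers: MarkerSet, path) -> None:
    """Write a marker set as a minimal VCF (REF = parent-1 allele)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in markers.df.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in markers.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.marker_id}\t"
                f"{row.allele_parent1}\t{row.allele_parent2}\t.\tPASS\t.\n"
            )


def filter_markers_colinear(markers: MarkerSet, blocks: pd.DataFrame) -> MarkerSet:
    """Restrict markers to co-linear blocks.

    ``blocks`` uses BED columns (``chrom``, ``start``, ``end``; 0-based
    half-open) and must be non-overlapping per chromosome.  A marker is
    retained iff ``start < pos < end`` in BED coordinate numbers, so a
    marker whose 1-based position equals the block end value is excluded.
    Survivors get ``colinear=True``.
    """
    if len(blocks) == 0:
        log.warning("filter_markers_colinear: empty block list, no markers retained")
        return MarkerSet(markers.df.iloc[0:0].copy())
    _check_blocks_disjoint(blocks)
    keep = np.zeros(len(markers), dtype=bool)
    df = markers.df
    for chrom, sub in blocks.groupby("chrom"):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        mask = df["chrom"] == chrom
        pos = df.loc[mask, "pos"].to_numpy(np.int64)
        idx = np.searchsorted(starts, pos, side="left") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        keep[np.flatnonzero(mask)] = ok
    out = df[keep].copy()
    out["colinear"] = True
    return MarkerSet(out)


def _check_blocks_disjoint(blocks: pd.DataFrame) -> None:
    for chrom, sub in blocks.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"co-linear blocks overlap on {chrom}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignments(
    path,
    markers: MarkerSet,
    dialect: str | None = None,
    barcode_tag: str = "BX",
) -> AlignmentBatch:
    """Read barcoded alignments from SAM/BAM or the TSV dialect.

    One :class:`BarcodedAlignment` is produced per primary alignment;
    marker observations are derived by intersecting aligned bases with
    marker positions.  Records lacking a barcode are counted and skipped.
    The output order is the file order, so repeated reads of the same
    file are identical.
    """
    path = Path(path)
    if dialect is None:
        dialect = "sam_bam" if path.suffix.lower() in {".sam", ".bam", ".cram"} else "tsv"
    if dialect == "sam_bam":
        return _read_alignments_sam(path, markers, barcode_tag)
    if dialect == "tsv":
        return _read_alignments_tsv(path, markers)
    raise ValueError(f"unknown alignment dialect: {dialect!r}")


def _read_alignments_sam(path: Path, markers: MarkerSet, barcode_tag: str) -> AlignmentBatch:
    alignments: list[BarcodedAlignment] = []
    n_skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            try:
                barcode = read.get_tag(barcode_tag)
            except KeyError:
                n_skipped += 1
                continue
            start = read.reference_start + 1
            end = read.reference_end  # pysam reference_end is exclusive 0-based == inclusive 1-based
            chrom = read.reference_name
            ids, pos = markers.positions_in(chrom, start, end)
            obs = []
            if len(ids):
                ref2query = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True)
                }
                seq = read.query_sequence
                for mid, p in zip(ids, pos):
                    q = ref2query.get(p - 1)
                    if q is not None and seq is not None:
                        obs.append((mid, seq[q]))
            alignments.append(
                BarcodedAlignment(
                    barcode=str(barcode),
                    reference_id=af.header.get("SQ", [{}])[0].get("SN", "ref"),
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_aligned_bases=read.query_alignment_length,
                    marker_observations=tuple(obs),
                )
            )
    return AlignmentBatch(alignments, n_skipped)


_TSV_FIELDS = ["barcode", "chrom", "start", "end", "n_aligned_bases", "observations"]


def _read_alignments_tsv(path: Path, markers: MarkerSet) -> AlignmentBatch:
    alignments: list[BarcodedAlignment] = []
    n_skipped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[: len(_TSV_FIELDS)] != _TSV_FIELDS:
            raise ValueError(f"{path}: missing or malformed TSV alignment header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 columns, got {len(row)}")
            barcode = row[0]
            if not barcode:
                n_skipped += 1
                continue
            try:
                start, end, nbases = int(row[2]), int(row[3]), int(row[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate field") from exc
            obs = []
            if len(row) > 5 and row[5]:
                for item in row[5].split(";"):
                    mid, _, base = item.partition("=")
                    if not base:
                        raise ValueError(f"{path}:{lineno}: malformed observation {item!r}")
                    obs.append((mid, base))
            alignments.append(
                BarcodedAlignment(
                    barcode=barcode,
                    reference_id="ref1",
                    chrom=row[1],
                    start=start,
                    end=end,
                    n_aligned_bases=nbases,
                    marker_observations=tuple(obs),
                )
            )
    return AlignmentBatch(alignments, n_skipped)


def write_alignments_tsv(alignments: Iterable[BarcodedAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_FIELDS)
        for aln in alignments:
            obs = ";".join(f"{m}={b}" for m, b in aln.marker_observations)
            writer.writerow(
                [aln.barcode, aln.chrom, aln.start, aln.end, aln.n_aligned_bases, obs]
            )


# ---------------------------------------------------------------------------
# CO calls
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class COCall:
    """A recombinant molecule's crossover breakpoint interval.

    ``left_pos``/``right_pos`` are the (1-based) positions of the two
    markers flanking the genotype switch; their distance is the
    breakpoint resolution.
    """

    molecule_id: str
    barcode: str
    chrom: str
    left_marker_id: str
    right_marker_id: str
    left_pos: int
    right_pos: int
    left_genotype: str
    right_genotype: str
    pool_id: str = ""

    def __post_init__(self) -> None:
        if self.left_pos >= self.right_pos:
            raise ValueError("left_pos must be < right_pos")
        if self.left_genotype == self.right_genotype:
            raise ValueError("flanking genotypes must differ")

    @property
    def resolution(self) -> int:
        return self.right_pos - self.left_pos

    @property
    def midpoint(self) -> int:
        return (self.left_pos + self.right_pos) // 2


_CALL_FIELDS = [
    "molecule_id",
    "barcode",
    "chrom",
    "left_marker_id",
    "right_marker_id",
    "left_pos",
    "right_pos",
    "resolution",
    "left_genotype",
    "right_genotype",
    "pool_id",
]


def write_co_calls(calls: Sequence[COCall], tsv_path, bed_path=None) -> None:
    """Write calls as a TSV with all fields plus a BED of breakpoint
    intervals (0-based half-open).  Round-trips through
    :func:`read_co_calls`."""
    tsv_path = Path(tsv_path)
    if bed_path is None:
        bed_path = tsv_path.with_suffix(".bed")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_FIELDS)
        for c in calls:
            writer.writerow(
                [
                    c.molecule_id, c.barcode, c.chrom, c.left_marker_id,
                    c.right_marker_id, c.left_pos, c.right_pos, c.resolution,
                    c.left_genotype, c.right_genotype, c.pool_id,
                ]
            )
    with open(bed_path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.left_pos - 1}\t{c.right_pos}\t{c.molecule_id}\n")


def read_co_calls(tsv_path) -> list[COCall]:
    calls = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            calls.append(
                COCall(
                    molecule_id=row["molecule_id"],
                    barcode=row["barcode"],
                    chrom=row["chrom"],
                    left_marker_id=row["left_marker_id"],
                    right_marker_id=row["right_marker_id"],
                    left_pos=int(row["left_pos"]),
                    right_pos=int(row["right_pos"]),
                    left_genotype=row["left_genotype"],
                    right_genotype=row["right_genotype"],
                    pool_id=row["pool_id"],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BED / benchmark / methylation / misc tables
# ---------------------------------------------------------------------------


def read_bed(path) -> pd.DataFrame:
    """Read a BED3(+) file; coordinates stay 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def read_benchmark(path) -> pd.DataFrame:
    """Read benchmark CO intervals.

    ``.bed`` input is converted to 1-based inclusive; anything else is
    parsed as a headered TSV with 1-based ``chrom``, ``start``, ``end``.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = read_bed(path)
        return pd.DataFrame(
            {"chrom": bed["chrom"], "start": bed["start"] + 1, "end": bed["end"]}
        )
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df[["chrom", "start", "end"]].astype({"start": np.int64, "end": np.int64})


def write_benchmark_bed(intervals: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\n")


def read_methylation(path) -> pd.DataFrame:
    """Per-site methylation counts: ``chrom  pos  n_met  n_total`` TSV."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": np.int64, "n_met": np.int64, "n_total": np.int64},
    )
    if ((df["n_met"] < 0) | (df["n_met"] > df["n_total"])).any():
        raise ValueError("methylation track violates 0 <= n_met <= n_total")
    return df


def read_chrom_lengths(path) -> dict[str, int]:
    """Chromosome lengths from a 2-column TSV (``chrom  length``)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    return dict(zip(df["chrom"], df["length"].astype(int)))
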