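"""Molecule reconstruction from barcode-clustered alignments.

Alignments sharing a barcode that fall on the same chromosome within a
maximum gap of each other are chained into molecules; chains shorter
than a minimum length are discarded.  Reconstructed molecules are then
filtered for likely chimeras (overly long molecules, overly many reads,
or heterozygous marker genotypes), the hallmarks of two independent
molecules that received the same barcode.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .io import PARENT1, PARENT2, BarcodedAlignment, MarkerSet

log = logging.getLogger("linkco.molecules")

#: default chaining gap (bp): neighbouring read alignments of one
#: molecule must not be further apart than this
DEFAULT_MAX_GAP = 25_000
#: molecules shorter than this are discarded after chaining
DEFAULT_MIN_LENGTH = 1_000
#: chimera filter: kept molecules must be shorter than this
DEFAULT_MAX_LENGTH = 65_000
#: chimera filter: kept molecules must have fewer reads than this
DEFAULT_MAX_READS = 55


@dataclass(slots=True)
class Molecule:
    """A reconstructed long DNA molecule.

    ``allele_observations`` maps marker_id to read counts
    ``[parent1, parent2, other]`` accumulated over member alignments.
    """

    molecule_id: str
    barcode: str
    chrom: str
    start: int
    end: int
    n_reads: int
    n_aligned_bases: int
    allele_observations: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def base_coverage(self) -> float:
        return self.n_aligned_bases / self.length

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def is_heterozygous(self, min_allele_support: int = 1) -> bool:
        """True if any marker shows at least ``min_allele_support`` reads
        for *both* parental alleles."""
        for c1, c2, _ in self.allele_observations.values():
            if c1 >= min_allele_support and c2 >= min_allele_support:
                return True
        return False


class RecoveryResult(NamedTuple):
    molecules: list
    n_discarded_short: int


def recover_molecules(
    alignments: Sequence[BarcodedAlignment],
    markers: MarkerSet,
    max_gap: int = DEFAULT_MAX_GAP,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> RecoveryResult:
    """Chain same-barcode alignments into molecules.

    Within each (barcode, chromosome) group, alignments sorted by start
    are chained while the gap between the running chain end and the next
    alignment start is at most ``max_gap`` (overlapping alignments are
    always chained).  For intervals this sweep is exactly single-linkage
    clustering at the gap threshold.  Chains spanning less than
    ``min_len`` are discarded and counted; every input alignment belongs
    to exactly one chain.
    """
    order = sorted(range(len(alignments)),
                   key=lambda i: (alignments[i].barcode, alignments[i].chrom,
                                  alignments[i].start, alignments[i].end))
    molecules: list[Molecule] = []
    n_discarded = 0
    serial = 0

    def flush(chain: list[BarcodedAlignment]) -> None:
        nonlocal n_discarded, serial
        start = chain[0].start
        end = max(a.end for a in chain)
        if end - start + 1 < min_len:
            n_discarded += 1
            return
        obs: dict[str, list] = {}
        nbases = 0
        for a in chain:
            nbases += a.n_aligned_bases
            for marker_id, base in a.marker_observations:
                counts = obs.get(marker_id)
                if counts is None:
                    counts = obs[marker_id] = [0, 0, 0]
                label = markers.classify_base(marker_id, base)
                counts[0 if label == PARENT1 else 1 if label == PARENT2 else 2] += 1
        molecules.append(
            Molecule(
                molecule_id=f"{chain[0].barcode}.{serial}",
                barcode=chain[0].barcode,
                chrom=chain[0].chrom,
                start=start,
                end=end,
                n_reads=len(chain),
                n_aligned_bases=nbases,
                allele_observations=obs,
            )
        )
        serial += 1

    chain: list[BarcodedAlignment] = []
    chain_end = 0
    prev_key = None
    for i in order:
        a = alignments[i]
        key = (a.barcode, a.chrom)
        if chain and (key != prev_key or a.start - chain_end > max_gap):
            flush(chain)
            chain = []
        if not chain:
            prev_key = key
            chain_end = a.end
        chain.append(a)
        chain_end = max(chain_end, a.end)
    if chain:
        flush(chain)
    if n_discarded:
        log.info("recover_molecules: discarded %d chains < %d bp", n_discarded, min_len)
    return RecoveryResult(molecules, n_discarded)


def compute_molecule_stats(molecule: Molecule) -> tuple[int, int, float]:
    """(length, read count, base coverage) of a molecule."""
    return molecule.length, molecule.n_reads, molecule.base_coverage


class FilterResult(NamedTuple):
    kept: list
    removed: list  # (molecule, reason) pairs
    reason_counts: Counter


def filter_molecules(
    molecules: Iterable[Molecule],
    max_len: int = DEFAULT_MAX_LENGTH,
    max_reads: int = DEFAULT_MAX_READS,
    het_policy: str = "disallow",
    min_allele_support: int = 1,
) -> FilterResult:
    """Remove likely chimeric molecules.

    A molecule is removed when its length reaches ``max_len``, its read
    count reaches ``max_reads`` (the kept set satisfies the strict
    inequalities: shorter than 65 kb, fewer than 55 reads under the
    defaults), or — with ``het_policy='disallow'`` — any marker shows at
    least ``min_allele_support`` reads for both parental alleles.
    """
    if het_policy not in ("disallow", "allow"):
        raise ValueError("het_policy must be 'disallow' or 'allow'")
    kept, removed = [], []
    reasons: Counter = Counter()
    for mol in molecules:
        if mol.length >= max_len:
            reason = "length"
        elif mol.n_reads >= max_reads:
            reason = "reads"
        elif het_policy == "disallow" and mol.is_heterozygous(min_allele_support):
            reason = "heterozygous"
        else:
            kept.append(mol)
            continue
        removed.append((mol, reason))
        reasons[reason] += 1
    return FilterResult(kept, removed, reasons)


# ---------------------------------------------------------------------------
# molecule tables
# ---------------------------------------------------------------------------


def write_molecules_tsv(molecules: Iterable[Molecule], path) -> None:
    """Molecules as a TSV of scalar fields plus serialized allele
    observations (``marker_id=p1:p2:other`` items, semicolon-joined)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["molecule_id", "barcode", "chrom", "start", "end", "length",
             "n_reads", "n_aligned_bases", "base_coverage", "observations"]
        )
        for m in molecules:
            obs = ";".join(
                f"{mid}={c1}:{c2}:{c3}"
                for mid, (c1, c2, c3) in m.allele_observations.items()
            )
            writer.writerow(
                [m.molecule_id, m.barcode, m.chrom, m.start, m.end, m.length,
                 m.n_reads, m.n_aligned_bases, f"{m.base_coverage:.6g}", obs]
            )


def read_molecules_tsv(path) -> list:
    import csv

    molecules = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            obs = {}
            if row["observations"]:
                for item in row["observations"].split(";"):
                    mid, _, counts = item.partition("=")
                    c1, c2, c3 = (int(x) for x in counts.split(":"))
                    obs[mid] = [c1, c2, c3]
            molecules.append(
                Molecule(
                    molecule_id=row["molecule_id"],
                    barcode=row["barcode"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    n_reads=int(row["n_reads"]),
                    n_aligned_bases=int(row["n_aligned_bases"]),
                    allele_observations=obs,
                )
            )
    return molecules
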