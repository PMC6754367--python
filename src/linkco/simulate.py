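"""Synthetic linked-read pools of recombinant genomes with known truth.

The generator emulates the data a Chromium-style linked-read experiment
produces from bulk recombinant DNA (F2 plants or gametes of an F1
hybrid): each genome is a mosaic of the two parental haplotypes with a
Poisson number of crossovers, long molecules are drawn from the genomes
with (truncated-)exponential lengths, each molecule is covered by a
Poisson number of short read pairs, and barcodes may be shared by more
than one molecule (barcode collisions), which is the mechanism that
creates chimeric, falsely recombinant molecules downstream.

Defaults follow the characteristics of real Arabidopsis linked-read
pools: ~45 kb molecules covered by ~21 read pairs of 151 bp, and 8.3
crossovers per diploid genome (split equally over the two haploid
mosaics of an F2, or halved for a single gamete).

All randomness flows from ``SimConfig.seed`` through a single
:class:`numpy.random.Generator`; the same seed reproduces the pool
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PARENT1, PARENT2, BarcodedAlignment, MarkerSet

_BASES = np.array(list("ACGT"), dtype=object)


@dataclass
class SimConfig:
    """Parameters of a simulated linked-read pool.

    ``co_rate_per_genome`` is the expected crossover count per *diploid*
    genome; an F2 genome receives two independent haploid mosaics with
    rate ``co_rate_per_genome / 2`` each, a gamete a single one.
    ``co_density`` optionally supplies per-chromosome relative crossover
    densities on a uniform grid (any number of cells) to simulate a
    non-uniform landscape.
    """

    chrom_lengths: Mapping[str, int]
    n_molecules: int
    n_genomes: int = 50
    genome_type: str = "f2"  # "f2" or "gamete"
    co_rate_per_genome: float = 8.3
    marker_spacing: int = 300
    molecule_mean_length: float = 45_000.0
    molecule_min_length: int = 1_000
    reads_per_molecule_mean: float = 21.0
    read_length: int = 151
    molecules_per_barcode_mean: float = 1.0
    genotyping_error_rate: float = 0.0
    length_distribution: str = "exponential"  # or "lognormal"
    co_density: Mapping[str, Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.chrom_lengths, (list, tuple)):
            self.chrom_lengths = {
                f"chr{i + 1}": int(L) for i, L in enumerate(self.chrom_lengths)
            }
        self.validate()

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome is required")
        for chrom, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            if L < self.molecule_min_length:
                raise ValueError(
                    f"chromosome {chrom} ({L} bp) shorter than molecule_min_length"
                )
        for name in (
            "n_molecules", "n_genomes", "marker_spacing", "molecule_min_length",
            "read_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "co_rate_per_genome", "molecule_mean_length", "reads_per_molecule_mean",
            "molecules_per_barcode_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.molecule_mean_length <= self.molecule_min_length:
            raise ValueError("molecule_mean_length must exceed molecule_min_length")
        if not 0.0 <= self.genotyping_error_rate < 0.5:
            raise ValueError("genotyping_error_rate must be in [0, 0.5)")
        if self.genome_type not in ("f2", "gamete"):
            raise ValueError("genome_type must be 'f2' or 'gamete'")
        if self.length_distribution not in ("exponential", "lognormal"):
            raise ValueError("length_distribution must be exponential or lognormal")


@dataclass
class Haplotype:
    """One haploid parental mosaic: per chromosome, the crossover
    positions (sorted, 1-based; the switch lies between ``p`` and
    ``p+1``) and the parental label carried at position 1 (0 = parent 1,
    1 = parent 2)."""

    start_parent: dict
    co_positions: dict

    def parent_at(self, chrom: str, pos) -> np.ndarray:
        """Vectorized parental label (0/1) at 1-based position(s)."""
        cos = self.co_positions[chrom]
        n_switch = np.searchsorted(cos, np.asarray(pos), side="left")
        return (self.start_parent[chrom] + n_switch) % 2


@dataclass
class TruthRecord:
    """Ground truth of a simulated pool: the genome mosaics and a
    molecule table with provenance and a per-molecule recombinant flag
    (true iff a real crossover lies strictly inside the molecule span)."""

    haplotypes: list  # list of genomes; each genome is a list of Haplotype
    molecules: pd.DataFrame
    genome_type: str

    def co_count_per_genome(self) -> np.ndarray:
        out = []
        for genome in self.haplotypes:
            out.append(
                sum(len(h.co_positions[c]) for h in genome for c in h.co_positions)
            )
        return np.asarray(out)

    def all_co_positions(self) -> pd.DataFrame:
        rows = []
        for gi, genome in enumerate(self.haplotypes):
            for hi, hap in enumerate(genome):
                for chrom, cos in hap.co_positions.items():
                    for p in cos:
                        rows.append((gi, hi, chrom, int(p)))
        return pd.DataFrame(rows, columns=["genome", "haplotype", "chrom", "pos"])


@dataclass
class SimResult:
    markers: MarkerSet
    alignments: list
    truth: TruthRecord
    config: SimConfig


# ---------------------------------------------------------------------------
# genome + marker construction
# ---------------------------------------------------------------------------


def make_marker_grid(config: SimConfig, rng: np.random.Generator) -> MarkerSet:
    """Markers every ``marker_spacing`` bp with random distinct parental
    alleles; the alt-reference projection is the identity (co-linear toy
    genomes)."""
    frames = []
    for chrom, L in config.chrom_lengths.items():
        pos = np.arange(config.marker_spacing, L + 1, config.marker_spacing, dtype=np.int64)
        a1 = rng.integers(0, 4, size=len(pos))
        a2 = (a1 + rng.integers(1, 4, size=len(pos))) % 4
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"{chrom}:{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "allele_parent1": _BASES[a1],
                    "allele_parent2": _BASES[a2],
                    "colinear": True,
                    "pos_alt_reference": pos.astype(float),
                }
            )
        )
    return MarkerSet(pd.concat(frames, ignore_index=True))


def _sample_co_positions(
    chrom: str, L: int, n: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if config.co_density is not None and chrom in config.co_density:
        weights = np.asarray(config.co_density[chrom], dtype=float)
        weights = weights / weights.sum()
        cell = rng.choice(len(weights), size=n, p=weights)
        width = L / len(weights)
        pos = (cell + rng.random(n)) * width
        pos = np.clip(pos.astype(np.int64), 1, L - 1)
    else:
        pos = rng.integers(1, L, size=n)
    return np.sort(pos)


def simulate_genomes(config: SimConfig, rng: np.random.Generator) -> list:
    """Draw the recombinant genomes of the pool.

    Each haploid mosaic receives ``Poisson(rate * chrom_share)``
    crossovers per chromosome, where ``rate`` is half the per-diploid
    crossover rate.
    """
    total = sum(config.chrom_lengths.values())
    hap_rate = config.co_rate_per_genome / 2.0
    n_haps = 2 if config.genome_type == "f2" else 1
    genomes = []
    for _ in range(config.n_genomes):
        haps = []
        for _ in range(n_haps):
            start_parent = {}
            co_positions = {}
            for chrom, L in config.chrom_lengths.items():
                lam = hap_rate * L / total
                n_co = rng.poisson(lam)
                start_parent[chrom] = int(rng.integers(0, 2))
                co_positions[chrom] = _sample_co_positions(chrom, L, n_co, config, rng)
            haps.append(Haplotype(start_parent, co_positions))
        genomes.append(haps)
    return genomes


# ---------------------------------------------------------------------------
# library construction
# ---------------------------------------------------------------------------


def _molecule_lengths(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.length_distribution == "exponential":
        # shifted exponential == exponential truncated at the minimum
        # length, with overall mean equal to molecule_mean_length
        excess = config.molecule_mean_length - config.molecule_min_length
        lens = config.molecule_min_length + rng.exponential(excess, size=n)
    else:
        # lognormal with sigma 0.5, mean matched, floored at the minimum
        sigma = 0.5
        mu = np.log(config.molecule_mean_length) - sigma**2 / 2
        lens = np.maximum(rng.lognormal(mu, sigma, size=n), config.molecule_min_length)
    return lens.astype(np.int64)


def simulate_library(
    genomes: list,
    markers: MarkerSet,
    config: SimConfig,
    rng: np.random.Generator,
    library_id: str = "lib",
) -> tuple[list, pd.DataFrame]:
    """Draw one linked-read library (molecules, barcodes, read pairs)
    from an existing genome pool.

    Returns the barcoded alignments (one per read pair; a pair is
    emitted as a contiguous span of twice the read length, since insert
    geometry is out of scope) and the truth molecule table.
    """
    n = config.n_molecules
    chroms = list(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    n_haps = 2 if config.genome_type == "f2" else 1

    # -- molecules ------------------------------------------------------
    chrom_idx = rng.choice(len(chroms), size=n, p=chrom_len / chrom_len.sum())
    genome_idx = rng.integers(0, len(genomes), size=n)
    hap_idx = rng.integers(0, n_haps, size=n)
    lengths = np.minimum(_molecule_lengths(config, n, rng), chrom_len[chrom_idx])
    starts = 1 + (rng.random(n) * (chrom_len[chrom_idx] - lengths + 1)).astype(np.int64)
    ends = starts + lengths - 1

    # -- barcodes: each barcode carries 1 + Poisson(mean - 1) molecules -
    excess = max(config.molecules_per_barcode_mean - 1.0, 0.0)
    barcode_of = np.empty(n, dtype=np.int64)
    perm = rng.permutation(n)
    filled = 0
    bc = 0
    while filled < n:
        size = 1 + rng.poisson(excess)
        barcode_of[perm[filled : filled + size]] = bc
        filled += size
        bc += 1
    barcodes = np.array([f"BX{b:08d}" for b in barcode_of], dtype=object)

    # -- read pairs -----------------------------------------------------
    pair_span = 2 * config.read_length
    n_pairs = np.maximum(rng.poisson(config.reads_per_molecule_mean, size=n), 1)
    mol_of_pair = np.repeat(np.arange(n), n_pairs)
    span_eff = np.minimum(pair_span, lengths[mol_of_pair])
    p_start = starts[mol_of_pair] + (
        rng.random(len(mol_of_pair))
        * (lengths[mol_of_pair] - span_eff + 1)
    ).astype(np.int64)
    p_end = p_start + span_eff - 1

    # -- marker observations -------------------------------------------
    sp = config.marker_spacing
    k0 = (p_start + sp - 1) // sp
    k1 = p_end // sp
    counts = np.maximum(k1 - k0 + 1, 0)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total_obs = int(offsets[-1])
    # flatten grid indices of every (pair, marker) event
    flat = np.repeat(k0, counts) + (
        np.arange(total_obs) - np.repeat(offsets[:-1], counts)
    )
    obs_pair = np.repeat(np.arange(len(mol_of_pair)), counts)
    obs_mol = mol_of_pair[obs_pair]
    obs_chrom = chrom_idx[obs_mol]
    obs_pos = flat * sp

    # genotype each observation on its molecule's haplotype
    hap_key = genome_idx[obs_mol] * n_haps + hap_idx[obs_mol]
    parent = np.empty(total_obs, dtype=np.int8)
    order = np.argsort(hap_key * len(chroms) + obs_chrom, kind="stable")
    sorted_key = hap_key[order] * len(chroms) + obs_chrom[order]
    bounds = np.flatnonzero(np.diff(sorted_key)) + 1
    segments = np.split(np.arange(total_obs)[order], bounds)
    for seg in segments:
        if len(seg) == 0:
            continue
        g, h = divmod(int(hap_key[seg[0]]), n_haps)
        chrom = chroms[int(obs_chrom[seg[0]])]
        hap = genomes[g][h]
        parent[seg] = hap.parent_at(chrom, obs_pos[seg])
    if config.genotyping_error_rate > 0:
        flip = rng.random(total_obs) < config.genotyping_error_rate
        parent = np.where(flip, 1 - parent, parent)

    # map to bases via the marker table (grid index -> row per chrom)
    base = np.empty(total_obs, dtype=object)
    marker_ids = np.empty(total_obs, dtype=object)
    for ci, chrom in enumerate(chroms):
        ids, pos = markers.positions_in(chrom, 1, config.chrom_lengths[chrom])
        sub = markers.df[markers.df["chrom"] == chrom]
        a1 = sub["allele_parent1"].to_numpy(object)
        a2 = sub["allele_parent2"].to_numpy(object)
        sel = obs_chrom == ci
        row = obs_pos[sel] // sp - 1  # grid rows are spacing, 2*spacing, ...
        marker_ids[sel] = ids[row]
        base[sel] = np.where(parent[sel] == 0, a1[row], a2[row])

    # -- assemble alignment objects ------------------------------------
    obs_tuples = list(zip(marker_ids.tolist(), base.tolist()))
    alignments = []
    for j in range(len(mol_of_pair)):
        m = mol_of_pair[j]
        alignments.append(
            BarcodedAlignment(
                barcode=barcodes[m],
                reference_id="ref1",
                chrom=chroms[chrom_idx[m]],
                start=int(p_start[j]),
                end=int(p_end[j]),
                n_aligned_bases=int(span_eff[j]),
                marker_observations=tuple(obs_tuples[offsets[j] : offsets[j + 1]]),
            )
        )

    # -- truth table ----------------------------------------------------
    recomb = np.zeros(n, dtype=bool)
    for i in range(n):
        hap = genomes[genome_idx[i]][hap_idx[i]]
        cos = hap.co_positions[chroms[chrom_idx[i]]]
        # switch between p and p+1 is inside the span iff start <= p < end
        lo = np.searchsorted(cos, starts[i], side="left")
        hi = np.searchsorted(cos, ends[i], side="left")
        recomb[i] = hi > lo
    molecules = pd.DataFrame(
        {
            "molecule_id": [f"{library_id}:M{i:07d}" for i in range(n)],
            "genome": genome_idx,
            "haplotype": hap_idx,
            "chrom": [chroms[c] for c in chrom_idx],
            "start": starts,
            "end": ends,
            "barcode": barcodes,
            "n_read_pairs": n_pairs,
            "recombinant": recomb,
        }
    )
    return alignments, molecules


def simulate_pool(config: SimConfig) -> SimResult:
    """Generate a complete synthetic pool: markers, genomes, one library
    of barcoded alignments, and the truth record."""
    rng = np.random.default_rng(config.seed)
    markers = make_marker_grid(config, rng)
    genomes = simulate_genomes(config, rng)
    alignments, molecules = simulate_library(genomes, markers, config, rng)
    truth = TruthRecord(haplotypes=genomes, molecules=molecules,
                        genome_type=config.genome_type)
    return SimResult(markers=markers, alignments=alignments, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Monte-Carlo planning utilities
# ---------------------------------------------------------------------------


def expected_overlap_fraction(
    n_genomes: int,
    co_rate_per_genome: float,
    chrom_lengths: Mapping[str, int] | Sequence[int],
    resolution_bp: int,
    n_reps: int = 100,
    seed: int = 0,
    genome_type: str = "f2",
) -> float:
    """Monte-Carlo estimate of the fraction of independently placed
    crossover breakpoint intervals that intersect at least one other
    interval in the pool.

    Each genome contributes ``Poisson(rate)`` crossovers placed uniformly
    on the concatenated genome; every crossover is represented by an
    interval of width ``resolution_bp`` centred on it.  In small genomes
    this chance overlap is substantial and distinct-site counts
    undercount independent events.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(chrom_lengths, (list, tuple)):
        chrom_lengths = {f"chr{i+1}": int(L) for i, L in enumerate(chrom_lengths)}
    lens = np.array(list(chrom_lengths.values()), dtype=np.int64)
    if resolution_bp >= lens.min():
        raise ValueError("resolution_bp must be smaller than the shortest chromosome")
    rate = co_rate_per_genome if genome_type == "f2" else co_rate_per_genome / 2.0
    rng = np.random.default_rng(seed)
    total = lens.sum()
    bounds = np.concatenate([[0], np.cumsum(lens)])
    fractions = []
    for _ in range(n_reps):
        n_co = rng.poisson(rate, size=n_genomes).sum()
        if n_co <= 1:
            fractions.append(0.0)
            continue
        gpos = np.sort(rng.integers(0, total, size=n_co))
        chrom_of = np.searchsorted(bounds, gpos, side="right") - 1
        overlaps = np.zeros(n_co, dtype=bool)
        # neighbours on the same chromosome closer than the interval width overlap
        close = (np.diff(gpos) < resolution_bp) & (chrom_of[1:] == chrom_of[:-1])
        overlaps[1:] |= close
        overlaps[:-1] |= close
        fractions.append(overlaps.mean())
    return float(np.mean(fractions))


def expected_unique_genomes(
    dna_ng: float, genome_size_mb: float, genome_copies_per_unit: float
) -> float:
    """Expected number of distinct recombinant genomes in a DNA loading.

    1.00 ng of DNA corresponds to 10^6 Mb of sequence, so the expected
    count is ``dna_ng * 1e6 / genome_size_mb / genome_copies_per_unit``
    (e.g. three cells per pollen grain share one recombinant genome).
    """
    if dna_ng <= 0 or genome_size_mb <= 0 or genome_copies_per_unit <= 0:
        raise ValueError("all inputs must be > 0")
    return dna_ng * 1e6 / genome_size_mb / genome_copies_per_unit
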