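"""Relative recombination frequency (C^M) with matched subsampling.

The fraction of recombinant molecules in a library depends on molecule
length and coverage, so libraries are only comparable after their
molecule characteristics have been matched.  Pools are therefore
subsampled jointly: within 1 kb molecule-length bins every pool is drawn
down to the smallest per-bin count across pools, a further fraction
(default 80%) is retained per bin, and a final size/read-count filter
(30 kb / 24 reads by default, strict upper thresholds) is applied.  The
relative recombination frequency of a pool is then

    C^M = 1e6 * recombinant molecules / molecules.

The whole procedure — subsampling, crossover identification, C^M — is
repeated over replicates (default 50); the replicate mean mu and its 95%
confidence half-width ``s = t_{0.975, n-1} * sigma / sqrt(n)`` (2.0096 *
sigma / sqrt(50) at the default replicate count, sigma being the sample
standard deviation) summarise a pool, and two pools are declared
significantly different when their intervals do not overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genotyping import RECOMBINANT, ClassCriteria, classify_molecule, genotype_molecule
from .io import MarkerSet
from .molecules import Molecule

log = logging.getLogger("linkco.frequency")

DEFAULT_BIN_SIZE = 1_000
DEFAULT_THIN = 0.8
DEFAULT_FINAL_MAX_LEN = 30_000
DEFAULT_FINAL_MAX_READS = 24
DEFAULT_N_REPLICATES = 50


@dataclass
class CMEstimate:
    """Replicate-wise C^M values of one pool and their summary."""

    pool_id: str
    replicate_n_molecules: list
    replicate_n_co: list
    replicate_cms: list
    mu: float
    sigma: float
    s: float
    interval: tuple
    n_replicates: int


def _bin_pools(
    pools: Mapping[str, Sequence[Molecule]], bin_size: int
) -> tuple[dict[str, dict[int, list[int]]], list[int]]:
    """Group molecule indices by length bin; returns per-pool bins and
    the sorted union of occupied bins."""
    binned: dict[str, dict[int, list[int]]] = {}
    for pool_id, mols in pools.items():
        bins: dict[int, list[int]] = {}
        for i, mol in enumerate(mols):
            bins.setdefault(mol.length // bin_size, []).append(i)
        binned[pool_id] = bins
    all_bins = sorted({b for bins in binned.values() for b in bins})
    return binned, all_bins


def _draw_matched_indices(
    binned: Mapping[str, Mapping[int, list[int]]],
    all_bins: Sequence[int],
    thin: float,
    rng: np.random.Generator,
) -> dict[str, list[int]]:
    """One round of per-bin min-matching plus thinning; per-bin counts
    are exactly equal across pools afterwards."""
    out: dict[str, list[int]] = {pool_id: [] for pool_id in binned}
    for b in all_bins:
        m = min(len(bins.get(b, ())) for bins in binned.values())
        k = int(math.floor(thin * m))
        if k == 0:
            continue
        for pool_id, bins in binned.items():
            members = bins.get(b, [])
            idx = rng.choice(len(members), size=m, replace=False)
            idx = rng.choice(idx, size=k, replace=False)
            out[pool_id].extend(members[i] for i in idx)
    return out


def match_subsample(
    pools: Mapping[str, Sequence[Molecule]],
    bin_size: int = DEFAULT_BIN_SIZE,
    thin: float = DEFAULT_THIN,
    final_max_len: int = DEFAULT_FINAL_MAX_LEN,
    final_max_reads: int = DEFAULT_FINAL_MAX_READS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, list[Molecule]]:
    """Match molecule-length distributions across pools by subsampling.

    Per length bin each pool is sampled down (uniformly, without
    replacement) to the minimum per-bin count across pools, after which
    ``floor(thin * count)`` molecules are retained per bin — per-bin
    counts are therefore exactly equal across pools.  Finally molecules
    with ``length >= final_max_len`` or ``n_reads >= final_max_reads``
    are removed (kept molecules satisfy the strict inequalities, the
    same convention as the chimera filter).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 0 < thin <= 1:
        raise ValueError("thin must be in (0, 1]")
    binned, all_bins = _bin_pools(pools, bin_size)
    drawn = _draw_matched_indices(binned, all_bins, thin, rng)
    out: dict[str, list[Molecule]] = {}
    for pool_id, mols in pools.items():
        out[pool_id] = [
            mols[i]
            for i in drawn[pool_id]
            if mols[i].length < final_max_len and mols[i].n_reads < final_max_reads
        ]
    return out


def compute_cm(n_molecules: int, n_co_molecules: int) -> float:
    """Recombinant molecules per million molecules."""
    if n_molecules <= 0:
        raise ValueError("C^M is undefined for an empty molecule set")
    return 1e6 * n_co_molecules / n_molecules


def cm_confidence(
    replicate_cms: Sequence[float],
    pool_id: str = "",
    replicate_n_molecules: Sequence[int] | None = None,
    replicate_n_co: Sequence[int] | None = None,
) -> CMEstimate:
    """Summarise replicate C^M values.

    ``sigma`` is the sample standard deviation; the 95% confidence
    half-width is ``s = t_{0.975, n-1} * sigma / sqrt(n)``, which equals
    2.0096 * sigma / sqrt(50) at the default 50 replicates.
    """
    vals = np.asarray(replicate_cms, dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("at least two replicate values are required")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1))
    s = float(stats.t.ppf(0.975, n - 1) * sigma / math.sqrt(n))
    return CMEstimate(
        pool_id=pool_id,
        replicate_n_molecules=list(replicate_n_molecules or []),
        replicate_n_co=list(replicate_n_co or []),
        replicate_cms=vals.tolist(),
        mu=mu,
        sigma=sigma,
        s=s,
        interval=(mu - s, mu + s),
        n_replicates=n,
    )


def significantly_different(a: CMEstimate, b: CMEstimate) -> bool:
    """Two pools differ significantly iff their 95% confidence intervals
    do not overlap."""
    return a.interval[1] < b.interval[0] or b.interval[1] < a.interval[0]


def estimate_cm_pipeline(
    pools: Mapping[str, Sequence[Molecule]],
    markers: MarkerSet,
    criteria: ClassCriteria | None = None,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    bin_size: int = DEFAULT_BIN_SIZE,
    thin: float = DEFAULT_THIN,
    final_max_len: int = DEFAULT_FINAL_MAX_LEN,
    final_max_reads: int = DEFAULT_FINAL_MAX_READS,
) -> dict[str, CMEstimate]:
    """Repeated matched subsampling, crossover identification and C^M.

    Each replicate uses a sub-seed derived deterministically from
    ``seed + replicate index``, re-runs molecule classification on the
    subsampled sets, and records molecule and recombinant-molecule
    counts; the per-pool summaries carry the replicate values.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    criteria = criteria or ClassCriteria()
    # genotyping and classification of a molecule are deterministic, so
    # each molecule is labelled once; replicates re-count crossovers on
    # their own subsampled molecule sets
    recomb: dict[str, np.ndarray] = {}
    eligible: dict[str, np.ndarray] = {}
    for pool_id, mols in pools.items():
        labels = [
            classify_molecule(genotype_molecule(m, markers), criteria)
            for m in mols
        ]
        recomb[pool_id] = np.array([lab == RECOMBINANT for lab in labels])
        eligible[pool_id] = np.array(
            [m.length < final_max_len and m.n_reads < final_max_reads for m in mols]
        )
    binned, all_bins = _bin_pools(pools, bin_size)
    per_pool: dict[str, dict[str, list]] = {
        pool_id: {"n": [], "co": [], "cm": []} for pool_id in pools
    }
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        drawn = _draw_matched_indices(binned, all_bins, thin, rng)
        for pool_id, idx in drawn.items():
            idx = np.asarray(idx, dtype=np.intp)
            keep = eligible[pool_id][idx]
            n = int(keep.sum())
            n_co = int((recomb[pool_id][idx] & keep).sum())
            acc = per_pool[pool_id]
            acc["n"].append(n)
            acc["co"].append(n_co)
            acc["cm"].append(compute_cm(n, n_co))
    return {
        pool_id: cm_confidence(
            acc["cm"],
            pool_id=pool_id,
            replicate_n_molecules=acc["n"],
            replicate_n_co=acc["co"],
        )
        for pool_id, acc in per_pool.items()
    }
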