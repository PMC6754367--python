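"""Sliding-window crossover landscapes and pool comparison.

The landscape is computed in 1 Mb windows sliding in 50 kb steps.  In a
window, the crossover frequency is ``f = n / t_i`` where ``n`` is the
number of crossovers whose breakpoint midpoint falls in the window and
``t_i`` is the total crossover count on that chromosome — so landscapes
of libraries with different depths are comparable per chromosome, and on
a non-overlapping tiling the ``f`` values of a chromosome sum to one.

Two pools are compared window by window with Fisher's exact test on
(recombinant, non-recombinant) molecule counts against each of two
replicate pools; windows significant against *both* replicates are
merged into candidate difference regions.  No multiple-testing
correction is applied — concordance across the two replicates plays
that role.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("linkco.landscape")

DEFAULT_WINDOW_SIZE = 1_000_000
DEFAULT_WINDOW_STEP = 50_000


def make_windows(
    chrom_lengths: Mapping[str, int],
    size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_WINDOW_STEP,
) -> pd.DataFrame:
    """Sliding windows ``[s, s + size)`` for ``s = 1, 1 + step, ...``.

    The last window starts at the last position allowing a full window;
    a chromosome shorter than ``size`` yields a single truncated window.
    Coordinates in the returned frame are 1-based inclusive.
    """
    if size < step:
        raise ValueError("window size must be >= step")
    rows = []
    for chrom, L in chrom_lengths.items():
        n = max(1, (L - size) // step + 1) if L >= size else 1
        for k in range(n):
            s = 1 + k * step
            rows.append((chrom, s, min(s + size - 1, L)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _count_in_windows(
    windows: pd.DataFrame, points: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Count per window how many (sorted) per-chromosome positions fall
    inside it (inclusive bounds)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, sub in windows.groupby("chrom", sort=False):
        pos = points.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        lo = np.searchsorted(pos, sub["start"].to_numpy())
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        counts[sub.index.to_numpy()] = hi - lo
    return counts


def _midpoints_by_chrom(items: Iterable) -> dict[str, np.ndarray]:
    acc: dict[str, list[int]] = {}
    for it in items:
        acc.setdefault(it.chrom, []).append(it.midpoint)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in acc.items()}


def window_frequency(
    calls: Sequence,
    windows: pd.DataFrame,
    total_per_chrom: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window crossover count ``n`` and frequency ``f = n / t_i``.

    A crossover is assigned by its breakpoint-interval midpoint.
    ``total_per_chrom`` overrides the per-chromosome totals ``t_i``
    (defaults to the number of calls on each chromosome); chromosomes
    with ``t_i = 0`` get ``f = 0`` everywhere.
    """
    mids = _midpoints_by_chrom(calls)
    out = windows.copy()
    out["n"] = _count_in_windows(windows, mids)
    totals = (
        {c: len(v) for c, v in mids.items()}
        if total_per_chrom is None
        else dict(total_per_chrom)
    )
    t = out["chrom"].map(lambda c: totals.get(c, 0)).to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(t > 0, out["n"].to_numpy() / t, 0.0)
    out["f"] = f
    return out


def window_molecule_counts(
    windows: pd.DataFrame,
    recombinant_midpoints: Mapping[str, np.ndarray] | Sequence,
    non_recombinant_midpoints: Mapping[str, np.ndarray] | Sequence,
) -> pd.DataFrame:
    """Attach per-window recombinant (R) and non-recombinant (N)
    molecule counts, assigned by molecule midpoint."""

    def as_map(x):
        if isinstance(x, Mapping):
            return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in x.items()}
        return _midpoints_by_chrom(x)

    out = windows.copy()
    out["R"] = _count_in_windows(windows, as_map(recombinant_midpoints))
    out["N"] = _count_in_windows(windows, as_map(non_recombinant_midpoints))
    return out


def correlate_landscapes(
    series_a: pd.DataFrame, series_b: pd.DataFrame, column: str = "f"
) -> tuple[float, float]:
    """Genome-wide Pearson correlation of two landscapes on an identical
    window grid.  Raises on mismatched grids or zero-variance input."""
    for col in ("chrom", "start"):
        if not series_a[col].reset_index(drop=True).equals(
            series_b[col].reset_index(drop=True)
        ):
            raise ValueError("window grids differ between the two series")
    a = series_a[column].to_numpy(dtype=float)
    b = series_b[column].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance landscape: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def compare_pools_fisher(
    target: pd.DataFrame,
    replicate1: pd.DataFrame,
    replicate2: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window-wise two-sided Fisher's exact tests of the target pool
    against each replicate pool.

    Each window contributes the 2x2 table ``[[R_t, N_t], [R_r, N_r]]``;
    the window is flagged iff both p-values fall below ``alpha``.
    Windows with no molecules in any pool are skipped (logged).  Flagged
    windows that overlap or touch on the grid are merged into regions.

    Returns ``(windows_with_p, regions)``.
    """
    for rep in (replicate1, replicate2):
        if len(rep) != len(target) or not target["start"].reset_index(drop=True).equals(
            rep["start"].reset_index(drop=True)
        ):
            raise ValueError("pool window grids must be identical")
    out = target[["chrom", "start", "end", "R", "N"]].copy()
    p1 = np.ones(len(out))
    p2 = np.ones(len(out))
    skipped = 0
    rt, nt = target["R"].to_numpy(), target["N"].to_numpy()
    r1, n1 = replicate1["R"].to_numpy(), replicate1["N"].to_numpy()
    r2, n2 = replicate2["R"].to_numpy(), replicate2["N"].to_numpy()
    for i in range(len(out)):
        if rt[i] + nt[i] == 0 or r1[i] + n1[i] == 0 or r2[i] + n2[i] == 0:
            skipped += 1
            p1[i] = p2[i] = np.nan
            continue
        _, p1[i] = stats.fisher_exact([[rt[i], nt[i]], [r1[i], n1[i]]])
        _, p2[i] = stats.fisher_exact([[rt[i], nt[i]], [r2[i], n2[i]]])
    if skipped:
        log.info("compare_pools_fisher: skipped %d empty windows", skipped)
    out["p_rep1"] = p1
    out["p_rep2"] = p2
    out["flagged"] = (p1 < alpha) & (p2 < alpha)
    regions = merge_flagged_windows(out[out["flagged"]])
    return out, regions


def merge_flagged_windows(flagged: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping or adjacent flagged windows per chromosome."""
    rows = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
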