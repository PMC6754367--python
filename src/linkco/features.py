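"""Association of crossover sites with genomic features.

Crossover breakpoint midpoints are assigned to genomic categories by a
configurable decision list (first match wins); the default order is
TE -> promoter -> gene_start -> gene_end -> gene_body -> intergenic,
with the promoter defined as the 1,000 bp upstream of the transcription
start site and gene start/end as the first/last 200 bp of a gene (all
strand-aware).  Enrichment or depletion of a category is evaluated with
a permutation test against sets of midpoints placed uniformly at random
in the non-heterochromatic genome.  GC-content and DNA-methylation
associations use windowed Pearson correlation and a Welch two-sample
t-test, respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("linkco.features")

DEFAULT_ORDER = ("TE", "promoter", "gene_start", "gene_end", "gene_body", "intergenic")
DEFAULT_PROMOTER_BP = 1_000
DEFAULT_EDGE_BP = 200


def _merge_intervals(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping 1-based inclusive intervals into sorted arrays."""
    if not intervals:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    intervals.sort()
    starts, ends = [], []
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = s, e
    starts.append(cs)
    ends.append(ce)
    return np.asarray(starts, np.int64), np.asarray(ends, np.int64)


class FeatureModel:
    """Genomic feature categories derived from gene and TE annotation.

    ``genes`` needs columns ``chrom, start, end, strand``; ``tes`` needs
    ``chrom, start, end`` and optionally ``superfamily``.  Coordinates
    are 1-based inclusive.  ``heterochromatin`` intervals (same columns)
    are excluded from the permutation null.  ``order`` is the decision
    list; every position not matching an earlier category falls through
    to ``intergenic``.
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        tes: pd.DataFrame,
        chrom_lengths: Mapping[str, int],
        heterochromatin: pd.DataFrame | None = None,
        order: Sequence[str] = DEFAULT_ORDER,
        promoter_bp: int = DEFAULT_PROMOTER_BP,
        edge_bp: int = DEFAULT_EDGE_BP,
    ):
        if "intergenic" not in order:
            raise ValueError("the decision list must end in 'intergenic'")
        self.chrom_lengths = dict(chrom_lengths)
        self.order = tuple(order)
        self.promoter_bp = promoter_bp
        self.edge_bp = edge_bp
        self.genes = genes.reset_index(drop=True)
        self.tes = tes.reset_index(drop=True)
        self.heterochromatin = (
            heterochromatin.reset_index(drop=True)
            if heterochromatin is not None
            else pd.DataFrame(columns=["chrom", "start", "end"])
        )
        self._category_intervals = self._build_intervals()

    def _build_intervals(self) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
        per_cat: dict[str, dict[str, list]] = {
            c: {} for c in self.order if c != "intergenic"
        }

        def add(cat: str, chrom: str, s: int, e: int) -> None:
            if cat not in per_cat:
                return
            L = self.chrom_lengths.get(chrom)
            if L is None:
                return
            s, e = max(1, s), min(L, e)
            if s <= e:
                per_cat[cat].setdefault(chrom, []).append((s, e))

        pb, eb = self.promoter_bp, self.edge_bp
        for g in self.genes.itertuples(index=False):
            fwd = getattr(g, "strand", "+") != "-"
            if fwd:
                add("promoter", g.chrom, g.start - pb, g.start - 1)
                add("gene_start", g.chrom, g.start, g.start + eb - 1)
                add("gene_end", g.chrom, g.end - eb + 1, g.end)
            else:
                add("promoter", g.chrom, g.end + 1, g.end + pb)
                add("gene_start", g.chrom, g.end - eb + 1, g.end)
                add("gene_end", g.chrom, g.start, g.start + eb - 1)
            add("gene_body", g.chrom, g.start, g.end)
        for t in self.tes.itertuples(index=False):
            add("TE", t.chrom, t.start, t.end)
        return {
            cat: {chrom: _merge_intervals(iv) for chrom, iv in by_chrom.items()}
            for cat, by_chrom in per_cat.items()
        }

    @classmethod
    def from_gff3(
        cls,
        gff3_path,
        chrom_lengths: Mapping[str, int],
        heterochromatin: pd.DataFrame | None = None,
        gene_type: str = "gene",
        te_types: Sequence[str] = ("transposable_element",),
        superfamily_attr: str = "superfamily",
        **kwargs,
    ) -> "FeatureModel":
        """Build the model from a GFF3 annotation file."""
        import gffutils

        db = gffutils.create_db(
            str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        genes, tes = [], []
        for feat in db.all_features():
            if feat.featuretype == gene_type:
                genes.append((feat.seqid, feat.start, feat.end, feat.strand or "+"))
            elif feat.featuretype in te_types:
                fam = feat.attributes.get(superfamily_attr, ["TE"])[0]
                tes.append((feat.seqid, feat.start, feat.end, fam))
        return cls(
            genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"]),
            tes=pd.DataFrame(tes, columns=["chrom", "start", "end", "superfamily"]),
            chrom_lengths=chrom_lengths,
            heterochromatin=heterochromatin,
            **kwargs,
        )

    # -- lookup ---------------------------------------------------------

    def _in_category(self, cat: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        by_chrom = self._category_intervals.get(cat, {})
        if chrom not in by_chrom:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = by_chrom[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] <= ends[idx[ok]]
        return out

    def categorize(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Category label for each position, by decision-list order."""
        positions = np.asarray(positions, dtype=np.int64)
        L = self.chrom_lengths.get(chrom)
        if L is None or (positions < 1).any() or (positions > L).any():
            raise ValueError(f"position outside chromosome {chrom}")
        labels = np.full(len(positions), "intergenic", dtype=object)
        unassigned = np.ones(len(positions), dtype=bool)
        for cat in self.order:
            if cat == "intergenic":
                continue
            hit = self._in_category(cat, chrom, positions) & unassigned
            labels[hit] = cat
            unassigned &= ~hit
        return labels

    # -- permutation null sampling space -------------------------------

    def allowed_segments(self) -> list[tuple[str, int, int]]:
        """Non-heterochromatic genome segments (1-based inclusive)."""
        het: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.heterochromatin.groupby("chrom"):
            het[chrom] = _merge_intervals(
                [(int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
            )
        segments = []
        for chrom, L in self.chrom_lengths.items():
            cursor = 1
            starts, ends = het.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            for s, e in zip(starts, ends):
                if s > cursor:
                    segments.append((chrom, cursor, min(s - 1, L)))
                cursor = max(cursor, e + 1)
            if cursor <= L:
                segments.append((chrom, cursor, L))
        return segments

    def sample_null_positions(
        self, n: int, rng: np.random.Generator
    ) -> list[tuple[str, int]]:
        """Uniform positions over the non-heterochromatic genome."""
        segments = self.allowed_segments()
        if not segments:
            raise ValueError("no non-excluded genome to sample from")
        lens = np.array([e - s + 1 for _, s, e in segments], dtype=np.int64)
        cum = np.cumsum(lens)
        draws = rng.integers(0, cum[-1], size=n)
        seg_idx = np.searchsorted(cum, draws, side="right")
        offset = draws - (cum[seg_idx] - lens[seg_idx])
        return [
            (segments[i][0], int(segments[i][1] + o)) for i, o in zip(seg_idx, offset)
        ]


def te_superfamily_model(model: FeatureModel) -> FeatureModel:
    """A model whose categories are the TE superfamilies (decision list:
    one category per superfamily; positions outside any TE fall through
    to ``intergenic``), reusing the midpoint-assignment machinery for
    superfamily-level association tests."""
    tes = model.tes
    if "superfamily" not in tes.columns:
        raise ValueError("TE table lacks a 'superfamily' column")
    fams = sorted(tes["superfamily"].unique())
    sub = FeatureModel(
        genes=model.genes.iloc[0:0],
        tes=tes,
        chrom_lengths=model.chrom_lengths,
        heterochromatin=model.heterochromatin,
        order=(*fams, "intergenic"),
        promoter_bp=model.promoter_bp,
        edge_bp=model.edge_bp,
    )
    # rebuild per-superfamily intervals
    sub._category_intervals = {
        fam: {
            chrom: _merge_intervals(
                [
                    (int(r.start), int(r.end))
                    for r in tes[(tes["superfamily"] == fam) & (tes["chrom"] == chrom)]
                    .itertuples(index=False)
                ]
            )
            for chrom in tes.loc[tes["superfamily"] == fam, "chrom"].unique()
        }
        for fam in fams
    }
    return sub


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------


def annotate_co(
    midpoints: Sequence[tuple], model: FeatureModel
) -> tuple[list, dict]:
    """Assign each crossover midpoint ``(chrom, pos)`` to exactly one
    category; returns the per-site labels and the category proportions
    (summing to one over the assigned set)."""
    by_chrom: dict[str, list[int]] = {}
    index: dict[str, list[int]] = {}
    for i, (chrom, pos) in enumerate(midpoints):
        by_chrom.setdefault(chrom, []).append(pos)
        index.setdefault(chrom, []).append(i)
    labels = [None] * len(midpoints)
    for chrom, pos in by_chrom.items():
        cats = model.categorize(chrom, np.asarray(pos))
        for i, c in zip(index[chrom], cats):
            labels[i] = c
    props = {c: 0.0 for c in model.order}
    if labels:
        for c in labels:
            props[c] += 1
        props = {c: v / len(labels) for c, v in props.items()}
    return labels, props


def permutation_feature_test(
    observed_midpoints: Sequence[tuple],
    model: FeatureModel,
    n_sets: int = 1_000,
    set_size: int = 3_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided permutation test of category proportions.

    The observed per-category proportions are compared with the null
    distribution over ``n_sets`` sets of ``set_size`` midpoints sampled
    uniformly from the non-heterochromatic genome.  The empirical
    p-value uses the add-one rule,
    ``p = (2 * min(k_ge, k_le) + 1) / (n_sets + 1)`` capped at 1, so it
    is never exactly zero; the direction column reports enrichment or
    depletion relative to the null mean.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if len(observed_midpoints) == 0:
        raise ValueError("observed set is empty")
    rng = np.random.default_rng(seed)
    _, observed = annotate_co(observed_midpoints, model)
    null = {c: np.empty(n_sets) for c in model.order}
    for k in range(n_sets):
        _, props = annotate_co(model.sample_null_positions(set_size, rng), model)
        for c in model.order:
            null[c][k] = props[c]
    rows = []
    for c in model.order:
        obs = observed[c]
        k_ge = int((null[c] >= obs).sum())
        k_le = int((null[c] <= obs).sum())
        p = min(1.0, (2 * min(k_ge, k_le) + 1) / (n_sets + 1))
        null_mean = float(null[c].mean())
        rows.append(
            {
                "category": c,
                "observed_prop": obs,
                "null_mean_prop": null_mean,
                "p_value": p,
                "direction": "enriched" if obs > null_mean else "depleted",
            }
        )
    return pd.DataFrame(rows)


def gc_correlation(
    window_gc: Sequence[float], window_f: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of windowed GC fraction with crossover
    frequency; raises on zero variance."""
    gc = np.asarray(window_gc, dtype=float)
    f = np.asarray(window_f, dtype=float)
    if len(gc) != len(f):
        raise ValueError("GC and frequency series must share the window grid")
    if np.std(gc) == 0 or np.std(f) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    r, p = stats.pearsonr(gc, f)
    return float(r), float(p)


def window_gc_from_fasta(fasta_path, windows: pd.DataFrame) -> np.ndarray:
    """GC fraction (of unambiguous bases) per window of a reference FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    out = np.full(len(windows), np.nan)
    for i, row in enumerate(windows.itertuples(index=False)):
        seq = str(fa[row.chrom][row.start - 1 : row.end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt:
            out[i] = (seq.count("G") + seq.count("C")) / acgt
    return out


@dataclass
class MethylResult:
    mean_co: float
    mean_random: float
    t_statistic: float
    p_value: float
    n_skipped: int
    co_levels: list = field(default_factory=list)
    random_levels: list = field(default_factory=list)


def _interval_levels(
    intervals: Sequence[tuple], track: Mapping[str, tuple]
) -> tuple[list, int]:
    levels, skipped = [], 0
    for chrom, start, end in intervals:
        pos, met, tot = track.get(chrom, (None, None, None))
        if pos is None:
            skipped += 1
            continue
        lo = np.searchsorted(pos, start)
        hi = np.searchsorted(pos, end, side="right")
        n = tot[lo:hi].sum()
        if n == 0:
            skipped += 1
            continue
        levels.append(met[lo:hi].sum() / n)
    return levels, skipped


def methylation_association(
    co_intervals: Sequence[tuple],
    random_intervals: Sequence[tuple],
    track: pd.DataFrame,
) -> MethylResult:
    """Compare methylation of crossover intervals against random ones.

    The methylation level of an interval is ``M = sum(N_met) / sum(N)``
    over the cytosine sites it covers; intervals without covered sites
    are skipped (counted).  The two sets of per-interval levels are
    compared with a Welch two-sample t-test.
    """
    by_chrom: dict[str, tuple] = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("pos")
        by_chrom[chrom] = (
            sub["pos"].to_numpy(np.int64),
            sub["n_met"].to_numpy(np.int64),
            sub["n_total"].to_numpy(np.int64),
        )
    co_levels, skip1 = _interval_levels(co_intervals, by_chrom)
    rnd_levels, skip2 = _interval_levels(random_intervals, by_chrom)
    if len(co_levels) < 2 or len(rnd_levels) < 2:
        raise ValueError("need at least two covered intervals per set")
    t, p = stats.ttest_ind(co_levels, rnd_levels, equal_var=False)
    return MethylResult(
        mean_co=float(np.mean(co_levels)),
        mean_random=float(np.mean(rnd_levels)),
        t_statistic=float(t),
        p_value=float(p),
        n_skipped=skip1 + skip2,
        co_levels=co_levels,
        random_levels=rnd_levels,
    )
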