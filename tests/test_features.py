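"""Feature categories, permutation tests, GC and methylation links."""

import numpy as np
import pandas as pd
import pytest

from linkco.features import (
    FeatureModel,
    annotate_co,
    gc_correlation,
    methylation_association,
    permutation_feature_test,
    te_superfamily_model,
)

CHROM_LEN = {"chr1": 100_000}


@pytest.fixture
def model():
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 60_000],
            "end": [12_000, 63_000],
            "strand": ["+", "-"],
        }
    )
    tes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [11_500, 30_000],
            "end": [11_800, 31_500],
            "superfamily": ["Gypsy", "Helitron"],
        }
    )
    het = pd.DataFrame({"chrom": ["chr1"], "start": [80_000], "end": [90_000]})
    return FeatureModel(genes, tes, CHROM_LEN, heterochromatin=het)


def brute_force_category(model, chrom, pos):
    """Oracle: check interval membership category by category, in order."""
    pb, eb = model.promoter_bp, model.edge_bp
    members = {c: [] for c in model.order if c != "intergenic"}
    for g in model.genes.itertuples(index=False):
        if g.strand != "-":
            members["promoter"].append((g.start - pb, g.start - 1))
            members["gene_start"].append((g.start, g.start + eb - 1))
            members["gene_end"].append((g.end - eb + 1, g.end))
        else:
            members["promoter"].append((g.end + 1, g.end + pb))
            members["gene_start"].append((g.end - eb + 1, g.end))
            members["gene_end"].append((g.start, g.start + eb - 1))
        members["gene_body"].append((g.start, g.end))
    for t in model.tes.itertuples(index=False):
        members["TE"].append((t.start, t.end))
    for cat in model.order:
        if cat == "intergenic":
            return "intergenic"
        if any(s <= pos <= e for s, e in members[cat]):
            return cat


def test_category_assignment_examples(model):
    labels, props = annotate_co(
        [
            ("chr1", 9_500),    # 500 bp upstream of forward TSS -> promoter
            ("chr1", 10_150),   # position 150 of the gene -> gene_start
            ("chr1", 11_600),   # inside both TE and gene body -> TE wins
            ("chr1", 63_400),   # downstream of a minus-strand gene -> promoter
            ("chr1", 62_950),   # first 200 bp of the minus-strand gene
            ("chr1", 50_000),   # nothing nearby
        ],
        model,
    )
    assert labels == [
        "promoter", "gene_start", "TE", "promoter", "gene_start", "intergenic"
    ]
    assert sum(props.values()) == pytest.approx(1.0)


def test_category_assignment_matches_brute_force(model):
    rng = np.random.default_rng(2)
    positions = rng.integers(1, CHROM_LEN["chr1"] + 1, size=500)
    labels, _ = annotate_co([("chr1", int(p)) for p in positions], model)
    for p, got in zip(positions, labels):
        assert got == brute_force_category(model, "chr1", int(p)), p


def test_decision_list_order_dependence(model):
    reordered = FeatureModel(
        model.genes, model.tes, CHROM_LEN,
        order=("gene_body", "TE", "promoter", "gene_start", "gene_end", "intergenic"),
    )
    # same midpoint inside TE and gene body: assignment follows the list
    (label_default,), _ = annotate_co([("chr1", 11_600)], model)
    (label_reordered,), _ = annotate_co([("chr1", 11_600)], reordered)
    assert label_default == "TE"
    assert label_reordered == "gene_body"


def test_position_outside_chromosome_is_an_error(model):
    with pytest.raises(ValueError, match="outside"):
        annotate_co([("chr1", 200_000)], model)


def test_te_superfamily_model_assigns_families(model):
    fam_model = te_superfamily_model(model)
    labels, _ = annotate_co(
        [("chr1", 11_600), ("chr1", 30_500), ("chr1", 50_000)], fam_model
    )
    assert labels == ["Gypsy", "Helitron", "intergenic"]


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def test_permutation_extreme_enrichment_hits_floor_p(model):
    # all observed midpoints inside the promoter of gene 1
    observed = [("chr1", 9_100 + i) for i in range(50)]
    table = permutation_feature_test(observed, model, n_sets=100, set_size=200, seed=3)
    row = table[table["category"] == "promoter"].iloc[0]
    assert row["p_value"] == pytest.approx(1 / 101)
    assert row["direction"] == "enriched"
    assert (table["p_value"] >= 1 / 101).all()
    assert (table["p_value"] <= 1.0).all()


def test_permutation_null_sampling_respects_exclusion(model):
    pts = model.sample_null_positions(2_000, np.random.default_rng(0))
    for chrom, pos in pts:
        assert not (80_000 <= pos <= 90_000)


def test_permutation_invalid_inputs(model):
    with pytest.raises(ValueError):
        permutation_feature_test([("chr1", 1_000)], model, n_sets=0)
    with pytest.raises(ValueError):
        permutation_feature_test([], model, n_sets=10)


def test_permutation_requires_nonempty_sampling_space(model):
    full_het = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [100_000]})
    blocked = FeatureModel(model.genes, model.tes, CHROM_LEN, heterochromatin=full_het)
    with pytest.raises(ValueError, match="non-excluded"):
        blocked.sample_null_positions(10, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


def test_gc_correlation_affine_relationship():
    gc = np.linspace(0.3, 0.5, 40)
    r, _ = gc_correlation(gc, 1.0 - gc)
    assert r == pytest.approx(-1.0)
    r, _ = gc_correlation(gc, gc)
    assert r == pytest.approx(1.0)


def test_gc_correlation_shuffled_is_null():
    rng = np.random.default_rng(8)
    gc = rng.random(1_000)
    f = rng.permutation(gc)
    r, _ = gc_correlation(gc, f)
    assert abs(r) < 0.1


def test_gc_correlation_zero_variance_error():
    with pytest.raises(ValueError):
        gc_correlation(np.ones(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def _track(rng, n_sites=2_000, low_region=(1, 50_000)):
    pos = np.sort(rng.choice(np.arange(1, 100_001), size=n_sites, replace=False))
    total = rng.integers(20, 60, size=n_sites)
    level = np.where(
        (pos >= low_region[0]) & (pos <= low_region[1]), 0.05, 0.6
    )
    met = rng.binomial(total, level)
    return pd.DataFrame({"chrom": "chr1", "pos": pos, "n_met": met, "n_total": total})


def test_methylation_level_arithmetic():
    track = pd.DataFrame(
        {"chrom": ["chr1"] * 2, "pos": [100, 200], "n_met": [10, 20],
         "n_total": [40, 60]}
    )
    res = methylation_association(
        [("chr1", 50, 250), ("chr1", 50, 150)],
        [("chr1", 150, 250), ("chr1", 50, 250)],
        track,
    )
    # interval covering both sites: M = 30/100
    assert res.co_levels[0] == pytest.approx(0.3)
    assert res.co_levels[1] == pytest.approx(0.25)
    assert res.random_levels[0] == pytest.approx(20 / 60)


def test_methylation_fully_methylated_is_one():
    track = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [100, 200, 300], "n_met": [5, 7, 9],
         "n_total": [5, 7, 9]}
    )
    res = methylation_association(
        [("chr1", 1, 400), ("chr1", 50, 250)],
        [("chr1", 1, 150), ("chr1", 90, 110)],
        track,
    )
    assert res.mean_co == pytest.approx(1.0)


def test_methylation_constructed_separation_is_significant():
    rng = np.random.default_rng(4)
    track = _track(rng)
    co = [("chr1", int(s), int(s) + 2_000) for s in rng.integers(1, 45_000, size=30)]
    random_iv = [
        ("chr1", int(s), int(s) + 2_000) for s in rng.integers(1, 95_000, size=30)
    ]
    res = methylation_association(co, random_iv, track)
    assert res.mean_co < res.mean_random
    assert res.p_value < 0.01


def test_methylation_uncovered_interval_skipped():
    track = pd.DataFrame(
        {"chrom": ["chr1"] * 2, "pos": [100, 200], "n_met": [1, 2],
         "n_total": [10, 10]}
    )
    res = methylation_association(
        [("chr1", 50, 250), ("chr1", 50, 260), ("chr1", 5_000, 6_000)],
        [("chr1", 50, 250), ("chr1", 60, 260)],
        track,
    )
    assert res.n_skipped == 1


# ---------------------------------------------------------------------------
# annotation and reference file loading
# ---------------------------------------------------------------------------

_GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t10000\t12000\t.\t+\t.\tID=gene1
chr1\ttest\tgene\t60000\t63000\t.\t-\t.\tID=gene2
chr1\ttest\ttransposable_element\t30000\t31500\t.\t+\t.\tID=te1;superfamily=Helitron
chr1\ttest\texon\t10000\t10500\t.\t+\t.\tParent=gene1
"""


def test_feature_model_from_gff3(tmp_path):
    path = tmp_path / "ann.gff3"
    path.write_text(_GFF3)
    model = FeatureModel.from_gff3(path, CHROM_LEN)
    assert len(model.genes) == 2
    assert list(model.tes["superfamily"]) == ["Helitron"]
    labels, _ = annotate_co([("chr1", 30_500), ("chr1", 9_500)], model)
    assert labels == ["TE", "promoter"]


def test_window_gc_from_fasta(tmp_path):
    from linkco.features import window_gc_from_fasta
    from linkco.landscape import make_windows

    fasta = tmp_path / "ref.fa"
    fasta.write_text(">chr1\n" + "ATGC" * 250 + "AAAA" * 250 + "\n")
    windows = make_windows({"chr1": 2_000}, size=1_000, step=1_000)
    gc = window_gc_from_fasta(fasta, windows)
    assert gc[0] == pytest.approx(0.5)
    assert gc[1] == pytest.approx(0.0)
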