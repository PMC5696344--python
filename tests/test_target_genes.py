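import math

import numpy as np
import pytest

from cochip.genome_io import GeneModel, GenomicInterval, Peak
from cochip.target_genes import (assign_targets, detect_super_targets,
                                 first_exon_region, fold_change_classify,
                                 repression_enrichment, score_and_rank)

from conftest import make_reads_frame


def _gene(gene_id, chrom, strand, exons):
    return GeneModel(gene_id, chrom, strand,
                     tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons))


def _peak(chrom, start, end, name="p"):
    return Peak(GenomicInterval(chrom, start, end), name)


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def test_peak_in_intron_makes_a_target():
    g = _gene("g1", "c", "+", [(1000, 1200), (2000, 2200)])
    out = assign_targets([g], [_peak("c", 1500, 1600)])
    assert bool(out.loc[0, "has_peak"])


def test_peak_past_tes_is_not_a_target():
    g = _gene("g1", "c", "+", [(1000, 2000)])
    out = assign_targets([g], [_peak("c", 2000, 2100)])  # half-open boundary
    assert not bool(out.loc[0, "has_peak"])
    out = assign_targets([g], [_peak("c", 2000, 2100)], flank=1)
    assert bool(out.loc[0, "has_peak"])


def test_assignment_matches_bruteforce(rng):
    genes = []
    for i in range(200):
        s = int(rng.integers(0, 200_000))
        genes.append(_gene(f"g{i}", f"chr{rng.integers(1, 3)}",
                           "+" if rng.random() < 0.5 else "-",
                           [(s, s + int(rng.integers(200, 3000)))]))
    peaks = [_peak(f"chr{rng.integers(1, 3)}", int(s), int(s + rng.integers(100, 900)),
                   f"p{i}") for i, s in enumerate(rng.integers(0, 200_000, 150))]
    out = assign_targets(genes, peaks).set_index("gene_id")
    for g in genes:
        expected = any(g.span.overlaps(p.interval) for p in peaks)
        assert bool(out.loc[g.gene_id, "has_peak"]) == expected


def test_assignment_namespace_mismatch_raises():
    g = _gene("g1", "chr2L", "+", [(0, 100)])
    with pytest.raises(ValueError, match="no chromosomes"):
        assign_targets([g], [_peak("ctg_1", 0, 100)])


# ---------------------------------------------------------------------------
# first exon flooring
# ---------------------------------------------------------------------------

def test_short_plus_strand_exon_extends_downstream():
    g = _gene("g1", "c", "+", [(100, 250)])
    region = first_exon_region(g)
    assert (region.start, region.end) == (100, 300)


def test_short_minus_strand_exon_extends_downstream():
    g = _gene("g1", "c", "-", [(1000, 1150)])
    region = first_exon_region(g)
    assert (region.start, region.end) == (950, 1150)


def test_long_exon_unchanged():
    g = _gene("g1", "c", "+", [(100, 400)])
    assert first_exon_region(g) == g.first_exon


def test_floor_clipped_at_chromosome_end():
    g = _gene("g1", "c", "+", [(900, 980)])
    region = first_exon_region(g, chrom_length=1000)
    assert (region.start, region.end) == (800, 1000)


# ---------------------------------------------------------------------------
# scoring and ranking
# ---------------------------------------------------------------------------

def test_score_arithmetic_500bp_exon():
    # 20 fragments fully inside a 500-bp first exon, library 1e7 -> 20/0.5 = 40
    g = _gene("g1", "c", "+", [(10_000, 10_500)])
    starts = np.linspace(10_050, 10_200, 20).astype(int)
    reads = make_reads_frame("c", starts, starts + 36)
    from cochip.coverage_quant import quantify_region
    d = quantify_region(reads, first_exon_region(g), fragment_size=250,
                        depth_scale=1e7, library_size=10_000_000)
    assert d.density == pytest.approx(40.0)


def test_ranking_matches_bruteforce_sort(rng):
    genes, reads_rows = [], []
    pos = 0
    for i in range(300):
        pos += 3000
        L = int(rng.integers(100, 1200))
        genes.append(_gene(f"g{i:03d}", "c", "+", [(pos, pos + L)]))
        n_reads = int(rng.integers(0, 80))
        for _ in range(n_reads):
            s = int(rng.integers(pos, pos + max(L - 36, 1)))
            reads_rows.append(s)
    starts = np.array(reads_rows)
    reads = make_reads_frame("c", starts, starts + 36)
    ranked = score_and_rank(genes, reads, top_n=50)
    # oracle: independent density computation + stable descending sort
    from cochip.coverage_quant import quantify_region
    lib = len(reads)
    oracle = sorted(
        ((quantify_region(reads, first_exon_region(g), library_size=lib).density,
          g.gene_id) for g in genes),
        key=lambda t: (-t[0], t[1]))
    assert ranked["gene_id"].tolist() == [gid for _, gid in oracle]
    assert np.allclose(ranked["ash1_score"], [d for d, _ in oracle])
    assert ranked["rank"].tolist() == list(range(1, 301))
    assert ranked["in_top_n"].sum() == 50


def test_ranking_gene_order_invariance(rng):
    genes = [_gene(f"g{i}", "c", "+", [(i * 2000 + 100, i * 2000 + 600)])
             for i in range(30)]
    starts = rng.integers(0, 60_000, 2000)
    reads = make_reads_frame("c", starts, starts + 36)
    r1 = score_and_rank(genes, reads)
    perm = list(rng.permutation(30))
    r2 = score_and_rank([genes[i] for i in perm], reads)
    assert r1["gene_id"].tolist() == r2["gene_id"].tolist()


# ---------------------------------------------------------------------------
# super targets
# ---------------------------------------------------------------------------

def test_super_targets_exact_hit():
    scores = [45.0] + [5.0] * 11
    ids = [f"g{i}" for i in range(12)]
    res = detect_super_targets((ids, scores), share_threshold=0.45)
    assert res.super_target_ids == ["g0"]
    assert res.share_captured == pytest.approx(0.45)


def test_super_targets_uniform_scores_ceiling():
    ids = [f"g{i}" for i in range(200)]
    res = detect_super_targets((ids, [3.0] * 200), share_threshold=0.45)
    assert res.n_super == 90  # ceil(0.45 * 200)


def test_super_targets_geometric_prefix_of_26():
    """A score vector built so the 26-gene prefix first reaches 45% of the
    top-200 mass; verified against a cumulative-sum oracle and an exhaustive
    prefix-minimality scan."""
    n, k, thr = 200, 26, 0.45
    sup = 0.99 ** np.arange(k)
    sup = sup / sup.sum() * 0.458
    # non-super mass 0.542, decaying with first element below the last super
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(80):
        q = 0.5 * (lo + hi)
        b1 = 0.542 * (1 - q) / (1 - q ** (n - k))
        lo, hi = (q, hi) if b1 > 0.55 * sup[-1] else (lo, q)
    non = q ** np.arange(n - k)
    non = non / non.sum() * 0.542
    assert non[0] < sup[-1]
    scores = np.concatenate([sup, non]) * 1234.5
    ids = [f"g{i}" for i in range(n)]
    res = detect_super_targets((ids, scores), share_threshold=thr)
    # cumulative-sum oracle over the supplied prefix
    cum = np.cumsum(scores) / scores.sum()
    k_oracle = next(i + 1 for i in range(n) if cum[i] >= thr)
    assert res.n_super == k_oracle == k
    # minimality: every shorter prefix is below the threshold
    for j in range(res.n_super - 1):
        assert cum[j] < thr
    assert res.share_captured >= thr


def test_super_targets_share_invariant_to_rescaling():
    ids = [f"g{i}" for i in range(10)]
    scores = np.array([50, 20, 10, 5, 5, 4, 3, 1, 1, 1], dtype=float)
    r1 = detect_super_targets((ids, scores))
    r2 = detect_super_targets((ids, scores * 7.5))
    assert r1.super_target_ids == r2.super_target_ids
    assert np.allclose(r1.cumulative_share, r2.cumulative_share)


def test_super_targets_errors():
    ids = ["a", "b", "c"]
    with pytest.raises(ValueError, match="all-zero"):
        detect_super_targets((ids, [0.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="descending"):
        detect_super_targets((ids, [1.0, 5.0, 2.0]))


# ---------------------------------------------------------------------------
# expression classification
# ---------------------------------------------------------------------------

def test_fold_change_examples():
    out = fold_change_classify([10.0, 3.0, 5.0], [4.0, 6.01, 5.0], pseudocount=0.0)
    assert out["class"].tolist() == ["down", "up", "unchanged"]


def test_fold_change_matches_independent_filter(rng):
    wt = rng.random(500) * 100
    kd = rng.random(500) * 100
    out = fold_change_classify(wt, kd, pseudocount=1.0, fold=2.0)
    for w, k, c in zip(wt, kd, out["class"]):
        fc = (k + 1) / (w + 1)
        expected = "down" if fc <= 0.5 else ("up" if fc >= 2.0 else "unchanged")
        assert c == expected


def test_fold_change_negative_abundance_raises():
    with pytest.raises(ValueError, match="negative"):
        fold_change_classify([1.0, -2.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# repression enrichment
# ---------------------------------------------------------------------------

def test_enrichment_haldane_correction():
    classes = ["down"] * 10 + ["unchanged"] * 10
    sup = [True] * 10 + [False] * 10
    res = repression_enrichment(classes, sup)
    assert res["odds_ratio"] == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))


def test_enrichment_independence_table():
    classes = ["down"] * 10 + ["unchanged"] * 10
    sup = ([True] * 5 + [False] * 5) * 2
    res = repression_enrichment(classes, sup)
    assert res["odds_ratio"] == pytest.approx(1.0)
    assert res["p"] == pytest.approx(1.0)


def test_enrichment_p_matches_hypergeometric_enumeration(rng):
    """Two-sided Fisher p equals exhaustive enumeration of hypergeometric
    tables with the same margins."""
    def enum_p(a, b, c, d):
        n, r1, c1 = a + b + c + d, a + b, a + c
        def logpmf(x):
            return (math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                    + math.lgamma(n - r1 + 1) - math.lgamma(c1 - x + 1)
                    - math.lgamma(n - r1 - c1 + x + 1)
                    - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
                       - math.lgamma(n - c1 + 1)))
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        probs = {x: math.exp(logpmf(x)) for x in range(lo, hi + 1)}
        cutoff = probs[a] * (1 + 1e-7)
        return sum(p for p in probs.values() if p <= cutoff)

    for _ in range(25):
        a, b, c, d = (int(rng.integers(1, 12)) for _ in range(4))
        classes = ["down"] * (a + b) + ["unchanged"] * (c + d)
        sup = [True] * a + [False] * b + [True] * c + [False] * d
        res = repression_enrichment(classes, sup)
        assert res["p"] == pytest.approx(enum_p(a, b, c, d), rel=1e-6)


def test_enrichment_empty_margin_raises():
    with pytest.raises(ValueError, match="degenerate"):
        repression_enrichment(["down", "down"], [True, False])
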