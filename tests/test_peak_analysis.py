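import numpy as np
import pytest

from cochip.coverage_quant import CoverageTrack
from cochip.genome_io import GenomicInterval, Peak
from cochip.peak_analysis import (call_peaks_simple, correlate_intensities,
                                  dependency_analysis, metaprofile,
                                  overlap_peaks, signal_matrix,
                                  stratify_by_cofactor)

from conftest import make_reads_frame


def _peak(chrom, start, end, name):
    return Peak(GenomicInterval(chrom, start, end), name)


def _random_peaks(rng, n, prefix, size=100_000):
    starts = rng.integers(0, size, n)
    widths = rng.integers(1, 800, n)
    return [_peak(f"chr{rng.integers(1, 3)}", int(s), int(s + w), f"{prefix}{i}")
            for i, (s, w) in enumerate(zip(starts, widths))]


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def test_overlap_full_and_boundary():
    a = [_peak("c", 0, 100, "a0")]
    assert overlap_peaks(a, [_peak("c", 50, 150, "b0")]).fraction_a == 1.0
    # half-open: adjacent intervals share no base
    assert overlap_peaks(a, [_peak("c", 100, 200, "b0")]).fraction_a == 0.0


def test_overlap_matches_bruteforce_and_conserves_venn(rng):
    a = _random_peaks(rng, 500, "a")
    b = _random_peaks(rng, 500, "b")
    res = overlap_peaks(a, b)
    hit_a = sum(any(p.interval.overlaps(q.interval) for q in b) for p in a)
    hit_b = sum(any(q.interval.overlaps(p.interval) for p in a) for q in b)
    assert res.count_overlapping_a == hit_a
    assert res.count_overlapping_b == hit_b
    assert res.a_only + res.count_overlapping_a == len(a)
    assert res.b_only + res.count_overlapping_b == len(b)


def test_min_overlap_threshold(rng):
    a = [_peak("c", 0, 100, "a0")]
    b = [_peak("c", 95, 200, "b0")]
    assert overlap_peaks(a, b, min_overlap_bp=5).fraction_a == 1.0
    assert overlap_peaks(a, b, min_overlap_bp=6).fraction_a == 0.0


def test_overlap_dialect_mismatch_raises():
    a = [_peak("chr2L", 0, 100, "a0")]
    b = [_peak("scaffold_77", 0, 100, "b0")]
    with pytest.raises(ValueError, match="no chromosomes"):
        overlap_peaks(a, b)


def test_overlap_reconciles_chr_prefix():
    a = [_peak("chr2L", 0, 100, "a0")]
    b = [_peak("2L", 50, 150, "b0")]
    assert overlap_peaks(a, b).fraction_a == 1.0


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_correlation_identity_and_inversion(rng):
    x = rng.random(50) * 100
    assert correlate_intensities(x, x)[0] == pytest.approx(1.0)
    r, n = correlate_intensities(x, -x + 200, transform="none")
    assert r == pytest.approx(-1.0) and n == 50


def test_correlation_matches_covariance_formula(rng):
    x, y = rng.random(200) * 50, rng.random(200) * 50
    r, _ = correlate_intensities(x, y, transform="none")
    xc, yc = x - x.mean(), y - y.mean()
    oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
    assert r == pytest.approx(oracle)


def test_correlation_affine_invariance(rng):
    x, y = rng.random(80), rng.random(80)
    r0, _ = correlate_intensities(x, y, transform="none")
    r1, _ = correlate_intensities(3 * x + 7, 0.5 * y + 1, transform="none")
    assert r0 == pytest.approx(r1)


def test_correlation_errors():
    with pytest.raises(ValueError, match="zero variance"):
        correlate_intensities([1, 1, 1], [1, 2, 3], transform="none")
    with pytest.raises(ValueError, match="n >= 3"):
        correlate_intensities([1, 2], [3, 4])


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------

def _uniform_track(value, size=100_000, bin_size=50):
    nbins = size // bin_size
    return CoverageTrack(bin_size=bin_size, depth_scale=1e7, library_size=1000,
                         fragment_size=250, chrom_sizes={"c": size},
                         data={"c": np.full(nbins, float(value))})


def test_metaprofile_of_constant_track_is_flat():
    track = _uniform_track(3.5)
    peaks = [_peak("c", 10_000, 11_000, "p0"), _peak("c", 50_000, 50_400, "p1")]
    prof = metaprofile(peaks, track, window=2000)
    assert prof.matrix.shape == (2, 80)
    assert np.allclose(prof.mean_profile, 3.5)


def test_metaprofile_single_peak_mean_equals_row():
    track = _uniform_track(1.0)
    track.data["c"][:200] = np.arange(200.0)
    prof = metaprofile([_peak("c", 4000, 6000, "p0")], track, window=1000)
    assert np.allclose(prof.mean_profile, prof.matrix[0])


def test_metaprofile_edge_peaks_padded_with_nan():
    track = _uniform_track(2.0)
    prof = metaprofile([_peak("c", 0, 100, "p0")], track, window=2000)
    assert np.isnan(prof.matrix[0, 0])          # off-chromosome offsets
    assert prof.matrix[0, -1] == 2.0


def test_metaprofile_recovers_gaussian_kernel_amplitude(rng):
    """Peaks carrying Gaussian signal mounds: the mean profile peaks at
    offset 0 with amplitude within 10% of the kernel amplitude."""
    size, bin_size, amp, sigma = 200_000, 50, 40.0, 300.0
    nbins = size // bin_size
    v = np.zeros(nbins)
    centers = rng.integers(5000, size - 5000, 40)
    xs = (np.arange(nbins) + 0.5) * bin_size
    for c in centers:
        v += amp * np.exp(-0.5 * ((xs - c) / sigma) ** 2)
    track = CoverageTrack(bin_size=bin_size, depth_scale=1e7, library_size=1000,
                          fragment_size=250, chrom_sizes={"c": size},
                          data={"c": v})
    peaks = [_peak("c", int(c) - 200, int(c) + 200, f"p{i}")
             for i, c in enumerate(centers)]
    prof = metaprofile(peaks, track, window=2000)
    mean = prof.mean_profile
    center_idx = np.argmax(mean)
    assert abs(prof.offsets[center_idx] + bin_size / 2) <= bin_size
    assert abs(mean.max() - amp) / amp < 0.10


def test_metaprofile_all_peaks_off_chromosome_raises():
    track = _uniform_track(1.0)
    with pytest.raises(ValueError, match="no peak"):
        metaprofile([_peak("chrX", 0, 100, "p0")], track)


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

def test_signal_matrix_single_cell_matches_quantify(rng):
    from cochip.coverage_quant import quantify_region
    starts = rng.integers(0, 5000, 300)
    reads = make_reads_frame("c", starts, starts + 36,
                             strands=list(rng.choice(["+", "-"], 300)))
    peak = _peak("c", 1000, 2000, "p0")
    m = signal_matrix([peak], {"Ash1:WT": reads})
    assert m.table.loc["p0", "Ash1:WT"] == pytest.approx(
        quantify_region(reads, peak.interval).density)


def test_signal_matrix_sorting_is_input_order_invariant(rng):
    starts = rng.integers(0, 50_000, 2000)
    reads = make_reads_frame("c", starts, starts + 36,
                             strands=list(rng.choice(["+", "-"], 2000)))
    peaks = [_peak("c", int(s), int(s) + 500, f"p{i}")
             for i, s in enumerate(rng.integers(0, 49_000, 20))]
    perm = list(rng.permutation(len(peaks)))
    m1 = signal_matrix(peaks, {"a": reads}).sorted_by("a")
    m2 = signal_matrix([peaks[i] for i in perm], {"a": reads}).sorted_by("a")
    assert (m1.table.index == m2.table.index).all()
    assert np.allclose(m1.table.to_numpy(), m2.table.to_numpy())


# ---------------------------------------------------------------------------
# stratified comparison
# ---------------------------------------------------------------------------

def test_stratify_degenerate_cofactor_raises():
    with pytest.raises(ValueError, match="degenerate"):
        stratify_by_cofactor(np.arange(6.0), np.ones(6), np.arange(6.0))


def test_stratify_six_peaks_one_per_subgroup():
    cof = np.array([10, 20, 30, 1, 2, 3.0])
    pri = np.array([5, 15, 25, 6, 16, 26.0])
    sig = np.arange(6.0)
    res = stratify_by_cofactor(sig, cof, pri, n_strata=3)
    assert all(len(v) == 1 for v in res.groups.values())
    assert len(res.groups) == 6


def test_stratify_recovers_multiplicative_structure(rng):
    """signal = f(primary) x g(cofactor): the cofactor-high subgroup median
    exceeds the matched low subgroup in every primary stratum."""
    n = 300
    pri = np.exp(rng.normal(4, 1, n))
    cof = np.exp(rng.normal(3, 1, n))
    sig = pri * np.sqrt(cof) * np.exp(rng.normal(0, 0.1, n))
    res = stratify_by_cofactor(sig, cof, pri, n_strata=3)
    for s in range(3):
        assert res.median("high", s) > res.median("low", s)


# ---------------------------------------------------------------------------
# dependency analysis
# ---------------------------------------------------------------------------

def test_dependency_identity_and_scale(rng):
    wt = rng.random(100) * 50 + 50  # epsilon (1% of median) is negligible here
    dep = dependency_analysis(wt, wt)
    assert np.allclose(dep["retained"], 1.0, atol=0.02)
    dep = dependency_analysis(wt, 0.3 * wt)
    assert np.allclose(dep["retained"], 0.3, atol=0.006)
    # with an explicit epsilon of zero the identity is exact
    dep = dependency_analysis(wt, wt, epsilon=0.0)
    assert np.allclose(dep["retained"], 1.0)


def test_dependency_equivariant_under_joint_rescaling(rng):
    wt = rng.random(200) * 50 + 1
    kd = wt * rng.uniform(0.2, 0.9, 200)
    d1 = dependency_analysis(wt, kd)
    d2 = dependency_analysis(10 * wt, 10 * kd)
    assert np.allclose(d1["retained"], d2["retained"])


def test_dependency_recovers_monotone_profile(rng):
    """Planted retained fraction rising 0.5 -> 0.9 across quintiles is
    recovered within +-0.1 per stratum (5 independent draws)."""
    planted = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
    for _ in range(5):
        n = 500
        wt = np.sort(np.exp(rng.normal(4, 1, n)))
        strata = np.repeat(np.arange(5), n // 5)
        kd = wt * planted[strata] * np.exp(rng.normal(0, 0.08, n))
        dep = dependency_analysis(wt, kd)
        assert np.all(np.abs(dep["retained"].to_numpy() - planted) <= 0.1)
        assert dep.attrs["monotone_up"]


def test_dependency_all_zero_wt_raises():
    with pytest.raises(ValueError, match="all-zero"):
        dependency_analysis(np.zeros(10), np.ones(10))


# ---------------------------------------------------------------------------
# fallback peak caller
# ---------------------------------------------------------------------------

def test_call_peaks_flat_track_warns_and_returns_empty():
    track = _uniform_track(0.0, size=10_000)
    with pytest.warns(UserWarning, match="flat"):
        assert call_peaks_simple(track) == []


def test_call_peaks_single_block():
    track = _uniform_track(0.0, size=100_000)
    track.data["c"][200:210] = 50.0  # one 500-bp block
    track.data["c"] += 0.01 * np.sin(np.arange(2000))  # non-degenerate background
    peaks = call_peaks_simple(track)
    assert len(peaks) == 1
    assert peaks[0].start == 10_000 and peaks[0].end == 10_500


def test_call_peaks_recovers_planted_peaks(rng):
    """High signal-to-noise planted blocks: recall >= 0.95, precision >= 0.9."""
    size, bin_size = 500_000, 50
    nbins = size // bin_size
    v = rng.poisson(2.0, nbins).astype(float)
    truth = []
    pos = 5000
    while pos < size - 3000 and len(truth) < 40:
        w = int(rng.integers(400, 1200))
        v[pos // bin_size:(pos + w) // bin_size] += rng.uniform(40, 80)
        truth.append(_peak("c", pos, pos + w, f"t{len(truth)}"))
        pos += w + int(rng.integers(3000, 8000))
    track = CoverageTrack(bin_size=bin_size, depth_scale=1e7, library_size=1000,
                          fragment_size=250, chrom_sizes={"c": size},
                          data={"c": v})
    called = call_peaks_simple(track)
    res = overlap_peaks(truth, called)
    recall = res.fraction_a
    precision = res.fraction_b
    assert recall >= 0.95 and precision >= 0.9
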