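"""Synthetic genome / ChIP landscape / expression / kinetics generator.

Emulates the statistical structure the downstream analysis assumes, with a
machine-readable truth set for closed-loop recovery tests:

* a two-chromosome genome with non-overlapping gene models (first-exon
  lengths straddle the 200-bp scoring floor);
* 3678 Mrg15 peaks nesting 562 Ash1 peaks, 41% of which co-locate with a
  called Mrg15 peak; joint (log Ash1, log Mrg15) intensities at Ash1 peaks
  with correlation rho = 0.58 (the co-located subset is the Mrg15-high tail,
  so non-called Ash1 peaks carry continuous sub-threshold Mrg15 signal);
* condition-dependent fragment reads: Ash1 knockdown collapses Ash1 signal
  (and H3K36me2 at Ash1 peaks to background), Mrg15 knockdown halves
  H3K36me2 at Ash1 peaks and depletes Ash1 more at weak peaks than strong
  ones (retained fraction rising 0.5 -> 0.9 across wild-type quintiles);
* 398 target genes whose ranked first-exon scores put ~45% of the top-200
  mass into a planted 26-gene super-target prefix;
* expression tables with 18 planted >=2-fold down / 8 up responders after
  Ash1 knockdown, repression concentrated in super targets, and milder
  Mrg15-knockdown effects on 6 of the 8 most-repressed super targets;
* Michaelis-Menten assay tables at the n = 2, ~5% noise design.

Everything is deterministic under one master seed; each (condition,
antibody) read set uses an independent derived stream.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import GeneModel, GenomicInterval, Peak
from .kinetics import KineticsDataset, michaelis_menten
from .target_genes import first_exon_region

__all__ = [
    "SimConfig",
    "TruthSet",
    "CONDITIONS",
    "ANTIBODIES",
    "generate_annotation",
    "generate_landscape",
    "generate_reads",
    "generate_expression",
    "generate_kinetics",
]

CONDITIONS = ("WT", "Ash1KD", "Mrg15KD")
ANTIBODIES = ("Ash1", "Mrg15", "H3K36me2", "H3K27me3")
_COND_CODE = {c: i + 1 for i, c in enumerate(CONDITIONS)}
_AB_CODE = {a: i + 11 for i, a in enumerate(ANTIBODIES)}


@dataclass
class SimConfig:
    """Study-scale parameters plus generator sizing knobs.

    The headline counts/fractions default to the study conditions; sizing
    knobs (read depths, kernel widths) are documented in the methods note.
    """

    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: {"chr2L": 5_000_000,
                                                       "chr2R": 5_000_000})
    n_genes: int = 3000
    n_mrg15_peaks: int = 3678
    n_ash1_peaks: int = 562
    ash1_overlap_fraction: float = 0.41
    rho: float = 0.58
    n_targets: int = 398
    top_n: int = 200
    n_super: int = 26
    super_share: float = 0.45
    # knockdown effect sizes
    ash1_kd_retained: float = 0.1          # Ash1 signal after Ash1 KD
    ash1_kd_h3k36_retained: float = 0.0    # Ash1-peak H3K36me2 -> background
    mrg15_kd_h3k36_retained: float = 0.5
    mrg15_kd_ash1_retained_range: tuple = (0.5, 0.9)  # by WT quintile
    ash1_kd_mrg15_retained: float = 0.3    # Mrg15 at Ash1 peaks after Ash1 KD
    mrg15_kd_mrg15_retained: float = 0.2
    # expression effects
    n_down: int = 18
    n_up: int = 8
    fold: float = 2.0
    n_super_down: int = 13                 # of n_down planted inside supers
    mrg15_kd_expr_factor: float = 0.7      # on 6 of the 8 most-repressed supers
    expression_noise_sd: float = 0.1       # log-normal sigma per measured column
    # sequencing / signal sizing
    fragment_size: int = 250
    read_length: int = 36
    exon_read_mass: float = 80_000.0       # expected WT Ash1 fragments in top-N exons
    background_reads: float = 40_000.0     # uniform fragments per sample
    super_margin: float = 0.008            # cum-share margin past the threshold
    super_gap: float = 0.55                # max (rank n_super+1)/(rank n_super) score ratio
    k36_peak_to_bg: float = 20.0           # median Ash1-peak H3K36me2 vs background
    min_gene_gap: int = 900
    exon_pad: int = 300                    # Ash1 peak half-extension past first exon

    def validate(self) -> None:
        for name in ("ash1_overlap_fraction", "super_share", "ash1_kd_retained",
                     "mrg15_kd_h3k36_retained"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (self.n_super <= self.top_n <= self.n_targets):
            raise ValueError("need n_super <= top_n <= n_targets")
        if self.n_targets > self.n_ash1_peaks:
            raise ValueError("n_targets cannot exceed n_ash1_peaks")
        if self.n_down + self.n_up > self.n_targets:
            raise ValueError("n_down + n_up exceeds n_targets")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")

    def spawn_rng(self, *codes: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), *codes])


@dataclass
class TruthSet:
    """Ground truth of one simulated landscape."""

    config: SimConfig
    genes: list
    gene_table: pd.DataFrame      # gene_id, is_target, rank, is_super, exon coords, exon_reads
    ash1_peaks: pd.DataFrame      # intervals + per-factor densities + KD retention
    mrg15_peaks: pd.DataFrame     # co-located + Mrg15-only
    k36_domains: pd.DataFrame
    k27_domains: pd.DataFrame
    expression_truth: pd.DataFrame | None = None

    def ash1_peak_objects(self) -> list[Peak]:
        return [Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.name,
                     float(r.ash1_reads))
                for r in self.ash1_peaks.itertuples()]

    def mrg15_peak_objects(self) -> list[Peak]:
        return [Peak(GenomicInterval(r.chrom, int(r.start), int(r.end)), r.name,
                     float(r.reads))
                for r in self.mrg15_peaks.itertuples()]

    def super_target_ids(self) -> list[str]:
        t = self.gene_table
        return t.loc[t["is_super"], "gene_id"].tolist()

    def to_json(self, path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "counts": {
                "genes": len(self.genes),
                "ash1_peaks": len(self.ash1_peaks),
                "mrg15_peaks": len(self.mrg15_peaks),
                "targets": int(self.gene_table["is_target"].sum()),
                "super_targets": int(self.gene_table["is_super"].sum()),
            },
            "super_target_ids": self.super_target_ids(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig, rng: np.random.Generator | None = None):
    """Non-overlapping gene models: 1-8 exons, first exon log-uniform
    100-1500 bp (so both branches of the 200-bp floor occur), both strands.
    """
    config.validate()
    rng = rng or config.spawn_rng(101)
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    n_per = np.floor(config.n_genes * sizes / sizes.sum()).astype(int)
    n_per[0] += config.n_genes - n_per.sum()

    genes, gid = [], 0
    for chrom, n in zip(chroms, n_per):
        size = config.chrom_sizes[chrom]
        n_exons = rng.integers(1, 9, size=n)
        first_len = np.exp(rng.uniform(np.log(100), np.log(1500), size=n)).astype(int)
        spans = []
        exon_lists = []
        for i in range(n):
            lens = [int(first_len[i])]
            introns = []
            for _ in range(int(n_exons[i]) - 1):
                introns.append(int(rng.integers(50, 251)))
                lens.append(int(rng.integers(80, 251)))
            spans.append(sum(lens) + sum(introns))
            exon_lists.append((lens, introns))
        total_span = sum(spans)
        min_gap = config.min_gene_gap
        leftover = size - total_span - min_gap * (n + 1)
        if leftover < 0:
            raise ValueError(
                f"cannot pack {n} genes (span {total_span} bp) into {chrom} "
                f"({size} bp) at min gap {min_gap}"
            )
        raw = rng.random(n + 1)
        gaps = (min_gap + raw / raw.sum() * leftover).astype(int)
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            strand = "+" if rng.random() < 0.5 else "-"
            lens, introns = exon_lists[i]
            # exon chain left->right in genomic coordinates
            glens = lens if strand == "+" else lens[::-1]
            gintrons = introns if strand == "+" else introns[::-1]
            exons, p = [], start
            for k, L in enumerate(glens):
                exons.append(GenomicInterval(chrom, p, p + L, strand))
                p += L + (gintrons[k] if k < len(gintrons) else 0)
            gid += 1
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, tuple(exons),
                                   transcript_id=f"gene{gid:04d}.t1"))
            pos = start + spans[i]
    return genes


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

class _Occupancy:
    """Sorted, merged (hence non-overlapping) interval bookkeeping per
    chromosome; merging keeps the two-neighbor overlap check exact."""

    def __init__(self):
        self.by_chrom: dict[str, list] = {}

    def add(self, chrom, start, end):
        lst = self.by_chrom.setdefault(chrom, [])
        i = bisect.bisect_left(lst, (start, -1))
        # absorb every stored interval touching [start, end)
        j = i
        while i > 0 and lst[i - 1][1] >= start:
            i -= 1
        while j < len(lst) and lst[j][0] <= end:
            j += 1
        if i < j:
            start = min(start, lst[i][0])
            end = max(end, lst[j - 1][1])
            del lst[i:j]
        lst.insert(i, (start, end))

    def free(self, chrom, start, end, margin=0) -> bool:
        lst = self.by_chrom.get(chrom, [])
        i = bisect.bisect_left(lst, (start - margin, -1))
        for j in (i - 1, i):
            if 0 <= j < len(lst):
                s, e = lst[j]
                if min(end + margin, e) > max(start - margin, s):
                    return False
        return True


def _place_avoiding(rng, occupancy: _Occupancy, chrom_sizes, widths, margin,
                    max_tries: int = 400):
    """Random non-overlapping placement by rejection; error when infeasible."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placements = []
    for w in widths:
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            start = int(rng.integers(0, chrom_sizes[chrom] - w))
            if occupancy.free(chrom, start, start + w, margin):
                occupancy.add(chrom, start, start + w)
                placements.append((chrom, start, start + w))
                break
        else:
            raise ValueError("interval placement infeasible: genome too crowded")
    return placements


def _triangle_capture(center, half_width, region_start, region_end, frag):
    """Expected fragment-overlap fraction with a region, for fragment centers
    drawn from a symmetric triangular kernel."""
    c = np.arange(center - half_width, center + half_width + 1, dtype=float)
    wgt = 1.0 - np.abs(c - center) / half_width
    ov = np.minimum(c + frag / 2, region_end) - np.maximum(c - frag / 2, region_start)
    np.clip(ov, 0, None, out=ov)
    return float(np.sum(wgt * ov / frag) / np.sum(wgt))


def _super_shares(config: SimConfig) -> np.ndarray:
    """Planted score shares of the top_n ranking.

    The super prefix carries super_share + super_margin of the top-N mass
    with the threshold crossing strictly inside the last super gene's share;
    the first non-super score sits below super_gap x the last super score.
    """
    n_sup, n_non = config.n_super, config.top_n - config.n_super
    u = 0.99 ** np.arange(n_sup)
    sup_total = config.super_share + config.super_margin
    sup = u / u.sum() * sup_total
    if not (sup_total - sup[-1] < config.super_share <= sup_total):
        raise ValueError(
            "super-target share construction failed: threshold does not cross "
            "inside the last super gene; adjust super_margin"
        )
    non_total = 1.0 - sup_total
    b1 = config.super_gap * sup[-1]   # first non-super share (gap below supers)
    c0 = 0.3 * b1                      # share floor keeps weak peaks above bg
    c1 = b1 - c0
    if c1 + n_non * c0 >= non_total:
        raise ValueError("super-gap construction infeasible for this config")
    lo, hi = 1e-9, 1 - 1e-9           # offset-geometric: c1*q^j + c0
    for _ in range(200):
        q = 0.5 * (lo + hi)
        total = c1 * (1 - q ** n_non) / (1 - q) + n_non * c0
        if total < non_total:
            lo = q
        else:
            hi = q
    non = c1 * q ** np.arange(n_non) + c0
    non = non / non.sum() * non_total
    shares = np.concatenate([sup, non])
    assert np.all(np.diff(shares) < 1e-15)
    return shares


def generate_landscape(config: SimConfig, genes,
                       rng: np.random.Generator | None = None) -> TruthSet:
    """Place peaks, draw correlated intensities, plant the super-target
    score shape and knockdown retention profile."""
    config.validate()
    rng = rng or config.spawn_rng(102)
    n_genes = len(genes)
    if n_genes < config.n_targets:
        raise ValueError("fewer genes than requested target genes")
    frag = config.fragment_size
    genome_kb = sum(config.chrom_sizes.values()) / 1000.0

    # --- target genes and ranked score shape -------------------------------
    target_idx = rng.choice(n_genes, size=config.n_targets, replace=False)
    rank_of_pos = rng.permutation(config.n_targets)  # target position -> rank-1
    shares = _super_shares(config)
    regions_by_pos = [
        first_exon_region(genes[i], chrom_length=config.chrom_sizes[genes[i].chrom])
        for i in target_idx
    ]
    # planted shape lives in density space (the ranking statistic); expected
    # exon fragments = density x floored-exon kb, top-N mass fixed
    n_tail = config.n_targets - config.top_n
    density_shape = np.empty(config.n_targets)
    density_shape[: config.top_n] = shares
    density_shape[config.top_n:] = shares[-1] * np.clip(
        0.7 * 0.97 ** np.arange(n_tail), 0.6, None)
    len_kb_by_rank = np.empty(config.n_targets)
    len_kb_by_rank[rank_of_pos] = np.array([r.length for r in regions_by_pos]) / 1000.0
    density_scale = config.exon_read_mass / float(
        np.sum(density_shape[: config.top_n] * len_kb_by_rank[: config.top_n]))
    exon_reads = density_shape * density_scale * len_kb_by_rank

    gene_rows, ash1_rows = [], []
    occupancy = _Occupancy()
    exon_regions = {}
    for pos, gidx in enumerate(target_idx):
        g = genes[gidx]
        rank = int(rank_of_pos[pos]) + 1
        m = float(exon_reads[rank - 1])
        region = regions_by_pos[pos]
        center = (region.start + region.end) // 2
        half_w = region.length // 2 + config.exon_pad
        pk_start = max(0, center - half_w)
        pk_end = min(config.chrom_sizes[g.chrom], center + half_w)
        f_cap = _triangle_capture(center, half_w, region.start, region.end, frag)
        n_reads = m / f_cap
        len_kb = (pk_end - pk_start) / 1000.0
        occupancy.add(g.chrom, pk_start, pk_end)
        exon_regions[g.gene_id] = region
        ash1_rows.append({
            "chrom": g.chrom, "start": pk_start, "end": pk_end,
            "name": f"ash1_{len(ash1_rows) + 1:04d}", "gene_id": g.gene_id,
            "kernel_center": center, "kernel_half_width": half_w,
            "ash1_reads": n_reads, "a_density": n_reads / len_kb,
        })
        gene_rows.append({"gene_id": g.gene_id, "is_target": True, "rank": rank,
                          "is_super": rank <= config.n_super,
                          "exon_start": region.start, "exon_end": region.end,
                          "exon_reads": m})
    target_ids = {genes[i].gene_id for i in target_idx}
    for g in genes:
        if g.gene_id not in target_ids:
            gene_rows.append({"gene_id": g.gene_id, "is_target": False,
                              "rank": 0, "is_super": False,
                              "exon_start": g.first_exon.start,
                              "exon_end": g.first_exon.end, "exon_reads": 0.0})

    # gene bodies are kept clear of intergenic peaks
    for g in genes:
        s = g.span
        occupancy.add(g.chrom, s.start, s.end)

    # --- intergenic Ash1 peaks ---------------------------------------------
    n_intergenic = config.n_ash1_peaks - config.n_targets
    widths = rng.integers(600, 1201, size=n_intergenic)
    spots = _place_avoiding(rng, occupancy, config.chrom_sizes, widths, margin=250)
    for (chrom, s, e), w in zip(spots, widths):
        n_reads = float(np.clip(np.exp(rng.normal(np.log(300), 0.8)), 150, 3000))
        ash1_rows.append({
            "chrom": chrom, "start": s, "end": e,
            "name": f"ash1_{len(ash1_rows) + 1:04d}", "gene_id": "",
            "kernel_center": (s + e) // 2, "kernel_half_width": int(w) // 2,
            "ash1_reads": n_reads, "a_density": n_reads / ((e - s) / 1000.0),
        })
    ash1 = pd.DataFrame(ash1_rows)

    # --- correlated Mrg15 intensities at Ash1 peaks ------------------------
    log_a = np.log(ash1["a_density"].to_numpy())
    x = (log_a - log_a.mean()) / log_a.std()
    z = rng.normal(size=len(ash1))
    z -= z.mean() + x * np.dot(z - z.mean(), x) / np.dot(x, x)  # orthogonalize
    z /= z.std()
    sigma_m, mu_m = 0.8, np.log(150.0)
    # empirical correlation of (log a, log m) equals rho by construction
    log_m = mu_m + sigma_m * (config.rho * x + np.sqrt(1 - config.rho ** 2) * z)
    ash1["m_density"] = np.exp(log_m)
    ash1["mrg15_reads"] = ash1["m_density"] * (ash1["end"] - ash1["start"]) / 1000.0

    n_overlap = int(round(config.ash1_overlap_fraction * config.n_ash1_peaks))
    called = np.zeros(len(ash1), dtype=bool)
    called[np.argsort(-ash1["m_density"].to_numpy(), kind="stable")[:n_overlap]] = True
    ash1["is_mrg15_called"] = called

    # --- H3K36me2 at Ash1 peaks: product of both factors -------------------
    raw_k36 = np.sqrt(ash1["a_density"] * ash1["m_density"])
    bg_per_kb = config.background_reads / genome_kb
    k36_density = raw_k36 / np.median(raw_k36) * config.k36_peak_to_bg * bg_per_kb
    ash1["k36_density"] = k36_density
    ash1["k36_reads"] = k36_density * (ash1["end"] - ash1["start"]) / 1000.0

    # --- Mrg15-KD Ash1 retention by WT quintile ----------------------------
    lo, hi = config.mrg15_kd_ash1_retained_range
    order = np.argsort(np.argsort(ash1["a_density"].to_numpy(), kind="stable"))
    quintile = (order * 5 // len(ash1)).astype(int)
    ash1["wt_quintile"] = quintile
    ash1["mrg15_kd_ash1_retained"] = lo + (hi - lo) * quintile / 4.0

    # --- Mrg15 peak set -----------------------------------------------------
    mrg15_rows = []
    for r in ash1[ash1["is_mrg15_called"]].itertuples():
        shift = int(rng.integers(-200, 201))
        s = max(0, r.start + shift)
        e = min(config.chrom_sizes[r.chrom], r.end + shift)
        mrg15_rows.append({"chrom": r.chrom, "start": s, "end": e,
                           "name": f"mrg15_{len(mrg15_rows) + 1:04d}",
                           "paired_ash1": r.name, "reads": r.mrg15_reads})
    n_only = config.n_mrg15_peaks - n_overlap
    widths = rng.integers(600, 1501, size=n_only)
    # avoid all Ash1 peaks (the co-located footprints are already registered)
    mrg_occ = _Occupancy()
    for r in ash1.itertuples():
        mrg_occ.add(r.chrom, r.start, r.end)
    for row in mrg15_rows:
        mrg_occ.add(row["chrom"], row["start"], row["end"])
    spots = _place_avoiding(rng, mrg_occ, config.chrom_sizes, widths, margin=100)
    for (chrom, s, e) in spots:
        reads = float(np.clip(np.exp(rng.normal(np.log(80), 0.7)), 15, 2000))
        mrg15_rows.append({"chrom": chrom, "start": s, "end": e,
                           "name": f"mrg15_{len(mrg15_rows) + 1:04d}",
                           "paired_ash1": "", "reads": reads})
    mrg15 = pd.DataFrame(mrg15_rows)

    # --- broad H3K36me2 / H3K27me3 domains (non-Ash1 methylation) ----------
    dom_occ = _Occupancy()
    for r in ash1.itertuples():
        dom_occ.add(r.chrom, r.start, r.end)
    genome_mb = sum(config.chrom_sizes.values()) / 1e6
    n_k36_dom = max(4, int(25 * genome_mb))
    n_k27_dom = max(3, int(15 * genome_mb))
    k36_w = rng.integers(3000, 15001, size=n_k36_dom)
    spots = _place_avoiding(rng, dom_occ, config.chrom_sizes, k36_w, margin=1000)
    k36_domains = pd.DataFrame([
        {"chrom": c, "start": s, "end": e,
         "reads": float(np.exp(rng.normal(np.log(40), 0.5))) * (e - s) / 1000.0}
        for (c, s, e) in spots
    ])
    k27_w = rng.integers(3000, 10001, size=n_k27_dom)
    spots = _place_avoiding(rng, dom_occ, config.chrom_sizes, k27_w, margin=1000)
    k27_rows = [
        {"chrom": c, "start": s, "end": e, "super_gene": "",
         "reads": float(np.exp(rng.normal(np.log(30), 0.5))) * (e - s) / 1000.0}
        for (c, s, e) in spots
    ]
    # weak basal H3K27me3 over super-target gene spans (raised on Ash1 KD)
    gene_by_id = {g.gene_id: g for g in genes}
    gt = pd.DataFrame(gene_rows)
    for gene_id in gt.loc[gt["is_super"], "gene_id"]:
        span = gene_by_id[gene_id].span
        k27_rows.append({"chrom": span.chrom, "start": span.start, "end": span.end,
                         "super_gene": gene_id,
                         "reads": 10.0 * span.length / 1000.0})
    k27_domains = pd.DataFrame(k27_rows)

    return TruthSet(config=config, genes=list(genes), gene_table=gt,
                    ash1_peaks=ash1, mrg15_peaks=mrg15,
                    k36_domains=k36_domains, k27_domains=k27_domains)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _sources(truth: TruthSet, condition: str, antibody: str):
    """(centers, half_widths, kernel kinds, expected reads) for one sample.

    kind 0 = triangular kernel around a point, 1 = uniform over [start, end).
    """
    cfg = truth.config
    a = truth.ash1_peaks
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if antibody not in ANTIBODIES:
        raise ValueError(f"unknown antibody {antibody!r}")
    if antibody == "Ash1":
        lam = a["ash1_reads"].to_numpy().copy()
        if condition == "Ash1KD":
            lam *= cfg.ash1_kd_retained
        elif condition == "Mrg15KD":
            lam *= a["mrg15_kd_ash1_retained"].to_numpy()
        return (a["kernel_center"].to_numpy(), a["kernel_half_width"].to_numpy(),
                np.zeros(len(a), dtype=int), lam,
                a["chrom"].to_numpy())
    if antibody == "Mrg15":
        lam_a = a["mrg15_reads"].to_numpy().copy()
        m = truth.mrg15_peaks
        only = m[m["paired_ash1"] == ""]
        lam_o = only["reads"].to_numpy().copy()
        if condition == "Ash1KD":
            lam_a *= cfg.ash1_kd_mrg15_retained
        elif condition == "Mrg15KD":
            lam_a *= cfg.mrg15_kd_mrg15_retained
            lam_o = lam_o * cfg.mrg15_kd_mrg15_retained
        centers = np.concatenate([a["kernel_center"].to_numpy(),
                                  (only["start"] + only["end"]).to_numpy() // 2])
        hw = np.concatenate([a["kernel_half_width"].to_numpy(),
                             (only["end"] - only["start"]).to_numpy() // 2])
        chroms = np.concatenate([a["chrom"].to_numpy(), only["chrom"].to_numpy()])
        lam = np.concatenate([lam_a, lam_o])
        return centers, hw, np.zeros(len(lam), dtype=int), lam, chroms
    if antibody == "H3K36me2":
        lam_a = a["k36_reads"].to_numpy().copy()
        if condition == "Ash1KD":
            lam_a *= cfg.ash1_kd_h3k36_retained
        elif condition == "Mrg15KD":
            lam_a *= cfg.mrg15_kd_h3k36_retained
        d = truth.k36_domains
        centers = np.concatenate([(a["start"] + a["end"]).to_numpy() // 2,
                                  (d["start"] + d["end"]).to_numpy() // 2])
        hw = np.concatenate([(a["end"] - a["start"]).to_numpy() // 2,
                             (d["end"] - d["start"]).to_numpy() // 2])
        kinds = np.concatenate([np.ones(len(a), dtype=int),
                                np.ones(len(d), dtype=int)])
        lam = np.concatenate([lam_a, d["reads"].to_numpy()])
        chroms = np.concatenate([a["chrom"].to_numpy(), d["chrom"].to_numpy()])
        return centers, hw, kinds, lam, chroms
    # H3K27me3
    d = truth.k27_domains
    lam = d["reads"].to_numpy().copy()
    if condition == "Ash1KD":
        lam = np.where(d["super_gene"].to_numpy() != "", lam * 3.0, lam)
    centers = (d["start"] + d["end"]).to_numpy() // 2
    hw = (d["end"] - d["start"]).to_numpy() // 2
    return centers, hw, np.ones(len(d), dtype=int), lam, d["chrom"].to_numpy()


def expected_read_count(truth: TruthSet, condition: str, antibody: str) -> float:
    """Expected library size: signal + background + KD depth top-up."""
    cfg = truth.config
    lam = _sources(truth, condition, antibody)[3]
    lam_wt = _sources(truth, "WT", antibody)[3]
    topup = max(0.0, lam_wt.sum() - lam.sum())
    return float(lam.sum() + cfg.background_reads + topup)


def generate_reads(truth: TruthSet, condition: str, antibody: str,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample single-end reads (BED6 frame) for one (condition, antibody).

    Fragments are placed by source kernels (triangular mounds for factor
    peaks, uniform blocks for broad methylation domains) plus uniform
    background; each read is the 5' ``read_length`` bp of its fragment, so
    extension by ``fragment_size`` during analysis recovers the fragment.
    Knockdown libraries are topped up with background so every sample has
    the same expected depth.
    """
    cfg = truth.config
    centers, hw, kinds, lam, chroms = _sources(truth, condition, antibody)
    rng = rng or cfg.spawn_rng(_COND_CODE[condition], _AB_CODE[antibody])
    lam_wt = _sources(truth, "WT", antibody)[3]
    bg_lambda = cfg.background_reads + max(0.0, lam_wt.sum() - lam.sum())

    counts = rng.poisson(lam)
    total = int(counts.sum())
    src_center = np.repeat(centers, counts).astype(np.int64)
    src_hw = np.repeat(hw, counts).astype(np.float64)
    src_kind = np.repeat(kinds, counts)
    src_chrom = np.repeat(chroms, counts)
    u1, u2 = rng.random(total), rng.random(total)
    tri_off = src_hw * (u1 + u2 - 1.0)          # triangular on +-hw
    uni_off = src_hw * (2.0 * u1 - 1.0)         # uniform over the block
    frag_center = src_center + np.where(src_kind == 0, tri_off, uni_off)

    # background, spread over the genome proportional to chromosome length
    n_bg = int(rng.poisson(bg_lambda))
    chrom_names = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chrom_names], dtype=float)
    bg_idx = rng.choice(len(chrom_names), size=n_bg, p=sizes / sizes.sum())
    bg_pos = (rng.random(n_bg) * sizes[bg_idx]).astype(np.int64)
    bg_chrom = np.array(chrom_names, dtype=object)[bg_idx]

    chrom_all = np.concatenate([src_chrom, bg_chrom])
    center_all = np.concatenate([frag_center, bg_pos.astype(np.float64)])
    n = len(chrom_all)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    frag = cfg.fragment_size
    fstart = np.round(center_all - frag / 2).astype(np.int64)
    fend = fstart + frag
    sizes_map = np.array([cfg.chrom_sizes[c] for c in chrom_all])
    fstart = np.clip(fstart, 0, sizes_map - frag)
    fend = fstart + frag
    rl = cfg.read_length
    start = np.where(strand == "+", fstart, fend - rl)
    end = start + rl
    df = pd.DataFrame({"chrom": chrom_all, "start": start, "end": end,
                       "name": [f"r{i:07d}" for i in range(n)],
                       "score": 0, "strand": strand})
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(truth: TruthSet, rng: np.random.Generator | None = None,
                        noise_sd: float | None = None) -> pd.DataFrame:
    """FPKM-like expression table (wt, ash1_kd, mrg15_kd) with planted
    responders; fills ``truth.expression_truth``.

    Down-regulated genes (x <= 1/fold) are concentrated in the super
    targets; Mrg15 knockdown applies a milder factor to 6 of the 8 most
    repressed super targets.
    """
    cfg = truth.config
    rng = rng or cfg.spawn_rng(104)
    if noise_sd is None:
        noise_sd = cfg.expression_noise_sd
    gt = truth.gene_table.set_index("gene_id")
    gene_ids = [g.gene_id for g in truth.genes]
    base = np.exp(rng.normal(np.log(30), 1.0, size=len(gene_ids)))

    super_ids = [g for g in gene_ids if gt.loc[g, "is_super"]]
    top_non_super = [g for g in gene_ids
                     if gt.loc[g, "is_target"] and 0 < gt.loc[g, "rank"] <= cfg.top_n
                     and not gt.loc[g, "is_super"]]
    other_targets = [g for g in gene_ids
                     if gt.loc[g, "is_target"] and g not in super_ids]
    n_sd = min(cfg.n_super_down, cfg.n_down, len(super_ids))
    down_ids = list(rng.choice(super_ids, size=n_sd, replace=False))
    pool = [g for g in top_non_super if g not in down_ids]
    down_ids += list(rng.choice(pool, size=cfg.n_down - n_sd, replace=False))
    up_pool = [g for g in other_targets if g not in down_ids]
    up_ids = list(rng.choice(up_pool, size=cfg.n_up, replace=False))

    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in down_ids + up_ids:
        base[idx[g]] = rng.uniform(25, 80)  # keep planted classes pseudocount-safe

    # planted effects sit clear of the 2-fold boundary so the classes are
    # well defined under the default measurement noise
    ash1_factor = np.ones(len(gene_ids))
    down_factors = rng.uniform(0.10, 0.35, size=len(down_ids))
    for g, f in zip(down_ids, down_factors):
        ash1_factor[idx[g]] = f
    for g in up_ids:
        ash1_factor[idx[g]] = rng.uniform(2.8, 4.5)

    mrg15_factor = np.ones(len(gene_ids))
    down_supers = [(g, f) for g, f in zip(down_ids, down_factors) if g in super_ids]
    most_repressed = [g for g, _ in sorted(down_supers, key=lambda t: t[1])][:8]
    affected = list(rng.choice(most_repressed, size=min(6, len(most_repressed)),
                               replace=False))
    for g in affected:
        mrg15_factor[idx[g]] = cfg.mrg15_kd_expr_factor

    def noisy(values):
        if noise_sd == 0:
            return values
        return values * np.exp(rng.normal(0, noise_sd, size=len(values)))

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "wt": noisy(base),
        "ash1_kd": noisy(base * ash1_factor),
        "mrg15_kd": noisy(base * mrg15_factor),
    })
    cls = np.where(ash1_factor <= 1 / cfg.fold, "down",
                   np.where(ash1_factor >= cfg.fold, "up", "unchanged"))
    truth.expression_truth = pd.DataFrame({
        "gene_id": gene_ids, "baseline": base, "ash1_kd_factor": ash1_factor,
        "mrg15_kd_factor": mrg15_factor, "planted_class": cls,
    })
    return table


# ---------------------------------------------------------------------------
# Kinetics assays
# ---------------------------------------------------------------------------

DEFAULT_S_GRID = (0.5, 1.0, 2.0, 4.0, 8.0)  # µM nucleosome titration


def generate_kinetics(vmax: float = 10.0, km: float = 2.0,
                      s_grid=DEFAULT_S_GRID, n_replicates: int = 2,
                      noise_cv: float = 0.05,
                      rng: np.random.Generator | None = None,
                      label: str = "") -> KineticsDataset:
    """Simulated HMT titration: Michaelis-Menten rates with multiplicative
    log-normal noise (default ~5% CV), two replicate series."""
    rng = rng or np.random.default_rng(0)
    S = np.asarray(s_grid, dtype=float)
    v = michaelis_menten(S, vmax, km)
    rates = v[:, None] * np.exp(rng.normal(0, noise_cv, size=(len(S), n_replicates)))
    return KineticsDataset(S, rates, cofactor_conc_uM=0.23, label=label)
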