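import numpy as np
import pandas as pd
import pytest

from cochip.synthetic_data import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast structural tests."""
    return SimConfig(
        seed=11,
        chrom_sizes={"chr2L": 400_000, "chr2R": 400_000},
        n_genes=240,
        n_mrg15_peaks=260,
        n_ash1_peaks=60,
        ash1_overlap_fraction=0.4,
        n_targets=40,
        top_n=24,
        n_super=5,
        n_down=6,
        n_up=3,
        n_super_down=4,
        exon_read_mass=12_000.0,
        background_reads=4_000.0,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    from cochip.synthetic_data import generate_annotation, generate_landscape
    genes = generate_annotation(small_config)
    return genes, generate_landscape(small_config, genes)


def make_reads_frame(chroms, starts, ends, strands=None, names=None):
    n = len(starts)
    return pd.DataFrame({
        "chrom": chroms if not isinstance(chroms, str) else [chroms] * n,
        "start": list(starts),
        "end": list(ends),
        "name": names or [f"r{i}" for i in range(n)],
        "score": 0,
        "strand": strands if strands is not None else ["+"] * n,
    })
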