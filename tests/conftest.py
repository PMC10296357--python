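import numpy as np
import pytest
from hypothesis import settings

from ygpsp.counting import TrimSpec, build_index, count_bins, normalize_bins
from ygpsp.library import DEFAULT_FLANK5
from ygpsp.model import DegronClassifier, build_training_set
from ygpsp.psi import psi_table
from ygpsp.simulate import SimConfig, simulate_screen

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium_screen():
    """A mid-sized synthetic screen carried through counting and PSI.

    Shared across tests that need realistic data: ~1,500 tiles, 1e5
    reads/gate, default noise model.
    """
    cfg = SimConfig(
        n_proteins=40, reads_per_bin=100_000, cells_per_bin=50_000, seed=7
    )
    proteins, tiles, sim_counts, truth, reads = simulate_screen(cfg, with_reads=True)
    index = build_index(tiles)
    table, stats = count_bins(
        reads, index, TrimSpec(mode="anchor", anchor=DEFAULT_FLANK5)
    )
    table = normalize_bins(table)
    psis = psi_table(table)
    return {
        "cfg": cfg,
        "proteins": proteins,
        "tiles": tiles,
        "sim_counts": sim_counts,
        "truth": truth,
        "reads": reads,
        "counts": table,
        "stats": stats,
        "psis": psis,
    }


@pytest.fixture(scope="session")
def trained_model(medium_screen):
    tiles = medium_screen["tiles"]
    peptides = {t.peptide_id: t.peptide for t in tiles}
    ts = build_training_set(medium_screen["psis"], peptides)
    clf = DegronClassifier().fit(ts.peptides, ts.labels)
    return clf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
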