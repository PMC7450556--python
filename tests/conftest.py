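import numpy as np
import pytest

from neo3dgenome.genome_grid import BinTable, ContactMatrix, make_bin_table
from neo3dgenome.polymer import RestraintSet, generate_ensemble
from neo3dgenome.synthetic import alternating_compartment_labels, generate_hic


@pytest.fixture
def two_chrom_bins() -> BinTable:
    """1 Mb + 0.5 Mb genome at 500 kb: chr1 has 2 bins, chr2 has 1."""
    return make_bin_table([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def toy_bins_40() -> BinTable:
    """Single 40-bin chromosome at 500 kb."""
    return make_bin_table([("chr1", 40 * 500_000)])


@pytest.fixture
def two_chain_bins() -> BinTable:
    """Two chromosomes of 30 bins each (60 beads)."""
    return make_bin_table([("chr1", 30 * 500_000), ("chr2", 30 * 500_000)])


@pytest.fixture
def checkerboard_matrix(toy_bins_40) -> ContactMatrix:
    labels = alternating_compartment_labels(toy_bins_40, block=5)
    return generate_hic(toy_bins_40, labels, checkerboard_strength=3.0, seed=11)


@pytest.fixture
def small_ensemble(two_chain_bins):
    """Five optimized replicas on the 60-bead toy genome, smooth targets."""
    degree = np.concatenate(
        [np.sin(np.linspace(0, np.pi, 30)), np.cos(np.linspace(0, np.pi, 30))]
    )
    from neo3dgenome.polymer import assign_radial_targets

    targets = assign_radial_targets(degree, 2.0, 9.5)
    restraints = RestraintSet(radial_targets=targets)
    return generate_ensemble(
        two_chain_bins, restraints, n_replicas=5, base_seed=7, max_iter=400
    )
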