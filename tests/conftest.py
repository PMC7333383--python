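import numpy as np
import pytest

from screg import compendium as comp
from screg.cells import CompendiumArtifacts
from screg.genome import RegionSet, segment_genome
from screg.simulate import simulate_compendium


@pytest.fixture(scope="session")
def toy_index():
    """1000-bp single-chromosome genome with 200-bp bins."""
    return segment_genome({"chr1": 1000}, 200)


@pytest.fixture(scope="session")
def small_compendium():
    """Simulated bulk compendium with bright planted elements."""
    bulk, truth = simulate_compendium(
        n_bins=2000,
        n_samples=20,
        n_cres=400,
        n_clusters=8,
        m_dist=(2.5, 5.0),
        seed=7,
    )
    return bulk, truth


@pytest.fixture(scope="session")
def small_artifacts(small_compendium):
    """Full compendium-derived artifact bundle for the small simulation."""
    bulk, truth = small_compendium
    norm = comp.normalize_counts(bulk)
    flags = comp.detect_signal_bins(bulk, norm)
    catalog = comp.compile_cres(flags, index=bulk.index)
    effects = comp.estimate_locus_effects(
        bulk.counts[catalog.bin_indices], bulk.library_factors
    )
    hierarchy = comp.cluster_cres(
        norm.values[catalog.bin_indices], stage1_k=40, seed=0
    )
    lowvar = comp.select_low_variability(effects, per_stratum=30)
    return CompendiumArtifacts(
        catalog=catalog, effects=effects, lowvar=lowvar, hierarchy=hierarchy
    )


@pytest.fixture
def blacklist_350_360():
    return RegionSet.from_intervals([("chr1", 350, 360)])
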