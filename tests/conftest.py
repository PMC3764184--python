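import numpy as np
import pytest

from tisschip.core import GenomicInterval, ScoredPeak
from tisschip.simulate import GeneratorConfig, generate, load_bundle


def make_peak(chrom, start, end, tier=1, factor="Sd", tissue="W", score=5.0, name=""):
    return ScoredPeak(GenomicInterval(chrom, start, end, name=name),
                      factor=factor, tissue=tissue, fdr_tier=tier, score=score)


def small_generator_config(**overrides):
    """A reduced stated world for fast unit tests (same structure)."""
    defaults = dict(
        seed=0,
        n_chroms=2,
        chrom_length=500_000,
        factors=("Sd", "Hth"),
        n_peaks={"Sd": {"EA": 130, "W": 260}, "Hth": {"EA": 130, "W": 260}},
        shared_fraction={"Sd": 0.4, "Hth": 0.4},
        n_genes=160,
        n_enhancers=80,
        n_gene_sets=5,
        gene_set_size=20,
        planted_set_size=15,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("small_bundle")
    generate(small_generator_config(), d)
    return d


@pytest.fixture(scope="session")
def small_bundle(small_bundle_dir):
    return load_bundle(small_bundle_dir)


@pytest.fixture(scope="session")
def fig_bundle_dir(tmp_path_factory):
    """The full fig-mimic scenario at its default configuration."""
    d = tmp_path_factory.mktemp("fig_bundle")
    generate(GeneratorConfig(seed=0), d)
    return d


@pytest.fixture(scope="session")
def fig_bundle(fig_bundle_dir):
    return load_bundle(fig_bundle_dir)


def random_dual_tier_fixture(rng, factor="Sd", tissues=("EA", "W"),
                             genome=100_000, n1=30, extra25=15):
    """Random nested dual-tier peak sets on a toy genome.

    FDR25 = every FDR1 peak padded by 50 bp plus ``extra25`` decoys, so the
    threshold-nesting invariant holds by construction.
    """
    from tisschip.specificity import DualTierPeakSet

    sets = {}
    for tissue in tissues:
        starts = np.sort(rng.choice(np.arange(100, genome - 400, 300),
                                    size=n1, replace=False))
        fdr1 = [make_peak("chrT", int(s), int(s) + 200, tier=1,
                          factor=factor, tissue=tissue) for s in starts]
        fdr25 = [make_peak("chrT", p.start - 50, p.end + 50, tier=25,
                           factor=factor, tissue=tissue) for p in fdr1]
        d_starts = rng.integers(100, genome - 400, size=extra25)
        fdr25 += [make_peak("chrT", int(s), int(s) + 150, tier=25,
                            factor=factor, tissue=tissue) for s in d_starts]
        sets[tissue] = DualTierPeakSet(factor=factor, tissue=tissue,
                                       fdr1_peaks=fdr1, fdr25_peaks=fdr25)
    return sets
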