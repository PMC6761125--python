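import numpy as np
import pytest

from pausepoint import annotation, coverage, synthetic


@pytest.fixture(scope="session")
def small_cfg():
    """Compact study: same laws as the defaults, fewer genes."""
    cfg = synthetic.SimulationConfig()
    cfg.n_genes = 160
    return cfg


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return synthetic.simulate_study(small_cfg, seed=11)


@pytest.fixture(scope="session")
def small_contexts(small_study):
    return annotation.contexts_frame(
        annotation.neighbor_contexts(small_study.genes))


def make_gene(gene_id="g1", chrom="chr1", start=100, end=1100, strand="+",
              features=()):
    return annotation.GeneModel(gene_id, chrom, start, end, strand,
                                tuple(features))


def make_track(values, chrom="chr1", units="raw"):
    return coverage.CoverageTrack({chrom: np.asarray(values, dtype=float)},
                                  units)


@pytest.fixture
def constant_track():
    return make_track(np.full(5000, 3.0))
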