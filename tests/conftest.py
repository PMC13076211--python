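import numpy as np
import pytest

from genedecode.encoding import SubsequenceBatch, chunk
from genedecode.simulate import SyntheticGenomeSpec, make_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic genome (100 kb, 20 genes) with noiseless tracks."""
    return make_fixture(SyntheticGenomeSpec(), noise=0.0, seed=1)


@pytest.fixture(scope="session")
def small_fixture():
    """A fast 20 kb / 4 gene fixture for unit-level checks."""
    return make_fixture(
        SyntheticGenomeSpec(contig_length=20_000, n_genes=4, seed=2), noise=0.0, seed=2
    )


def concat_batches(fx) -> SubsequenceBatch:
    """All strand tracks of a fixture as one window batch."""
    bs = [chunk(fx.encodings[k], fx.labels[k]) for k in sorted(fx.labels)]
    return SubsequenceBatch(
        x=np.concatenate([b.x for b in bs]),
        y_class=np.concatenate([b.y_class for b in bs]),
        y_phase=np.concatenate([b.y_phase for b in bs]),
        mask=np.concatenate([b.mask for b in bs]),
        pad_mask=np.concatenate([b.pad_mask for b in bs]),
        origins=sum([b.origins for b in bs], []),
        window_length=bs[0].window_length,
    )


def exact_recovery(decoded, reference) -> float:
    """Fraction of reference genes reproduced with exact coordinates."""
    ref = {(m.contig_id, m.strand, m.exons, m.cds) for m in reference}
    got = {(m.contig_id, m.strand, m.exons, m.cds) for m in decoded}
    return len(ref & got) / len(ref)
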