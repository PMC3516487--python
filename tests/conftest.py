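import numpy as np
import pytest

from ratpopgen.seq_data import AlleleLabel, LocusAlignment
from ratpopgen.synthetic_data import SyntheticStudyConfig, generate_study


def make_alignment(seqs, pops=None, locus_id="toy", frame_offset=0, outgroup=None):
    """Build a LocusAlignment from raw sequences; diploid individuals are
    formed from consecutive sequence pairs within each population."""
    if pops is None:
        pops = ["P1"] * len(seqs)
    labels = []
    counters: dict[str, int] = {}
    for i, pop in enumerate(pops):
        k = counters.get(pop, 0)
        labels.append(AlleleLabel(f"{pop}_ind{k // 2}", k % 2 + 1, pop))
        counters[pop] = k + 1
    return LocusAlignment(
        locus_id=locus_id,
        sequences=list(seqs),
        allele_labels=labels,
        frame_offset=frame_offset,
        outgroup_seq=outgroup,
    )


@pytest.fixture(scope="session")
def default_corpus():
    """One default-condition synthetic corpus shared across tests."""
    config = SyntheticStudyConfig(seed=7)
    alignments, metadata, truth = generate_study(config)
    return alignments, metadata, truth


@pytest.fixture(scope="session")
def corpus_on_disk(tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    config = SyntheticStudyConfig(seed=11, n_loci=8, outgroup_divergence=0.05)
    generate_study(config, out_dir=out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
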