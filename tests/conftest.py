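import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sigkit.contexts import CatalogMatrix
from sigkit.genome import GeneInterval, SequenceGenome
from sigkit.schemas import SBS96
from sigkit.simulate import make_signature_panel


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_genome() -> SequenceGenome:
    """A small two-chromosome genome with genes on both strands.

    chr1 carries a plus-strand gene at 11-40 and a minus-strand gene at
    31-80 (so 31-40 is covered by both, resolved by interval length);
    chr2 is gene-free.
    """
    rng = np.random.default_rng(20240501)
    return SequenceGenome(
        {"chr1": random_sequence(rng, 200), "chr2": random_sequence(rng, 120)},
        genes=[
            GeneInterval("chr1", 11, 40, "+", "geneA"),
            GeneInterval("chr1", 31, 80, "-", "geneB"),
        ],
    )


@pytest.fixture(scope="session")
def panel8():
    """8 well-separated random signature profiles over SBS-96."""
    rng = np.random.default_rng(81)
    return make_signature_panel(8, SBS96, 0.4, rng)


def planted_catalog(panel, n_planted, n_samples, rng, log_mean=np.log(1000), log_sd=0.6):
    """Multinomial catalog from the first ``n_planted`` panel signatures."""
    P = panel.profiles.to_numpy()[:, :n_planted]
    counts = np.zeros((P.shape[0], n_samples), dtype=np.int64)
    truth = np.zeros((n_planted, n_samples))
    for j in range(n_samples):
        acts = np.exp(rng.normal(log_mean, log_sd, n_planted))
        truth[:, j] = acts
        mix = P @ (acts / acts.sum())
        counts[:, j] = rng.multinomial(int(round(acts.sum())), mix / mix.sum())
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    cat = CatalogMatrix(
        panel.schema,
        pd.DataFrame(counts, index=list(panel.schema.categories), columns=samples),
    )
    return cat, pd.DataFrame(truth, index=panel.names[:n_planted], columns=samples)
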