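import random

import pytest

from adrecon.design import design_primer_pairs, plan_partition
from adrecon.restriction import default_enzymes
from adrecon.seqcore import Span, revcomp
from adrecon.synthfix import SynthGenomeSpec, fixtures, synth_cassette, synth_genome
from adrecon.workflow import WORKFLOW_FORBIDDEN


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def bundle():
    return fixtures()


@pytest.fixture(scope="session")
def genome():
    """One synthetic study genome shared across the suite (seed 1)."""
    return synth_genome(SynthGenomeSpec(forbidden=list(WORKFLOW_FORBIDDEN), seed=1))


@pytest.fixture(scope="session")
def plan(genome, enzymes):
    rel = [(enzymes["NotI"], enzymes["EcoRI"]),
           (enzymes["NotI"], enzymes["EcoRV"]),
           (enzymes["NotI"], enzymes["ClaI"])]
    return plan_partition(genome, (Span(1, 2566), Span(34616, 34776)), 6, rel)


@pytest.fixture(scope="session")
def primers(genome, plan):
    return design_primer_pairs(genome, plan)


@pytest.fixture(scope="session")
def cassette_donor():
    return synth_cassette(seed=1)


def random_clean_bases(rng: random.Random, n: int, avoid=()) -> str:
    """Random sequence free of the given recognition strings (both strands)."""
    while True:
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if not any(a in s or revcomp(a) in s for a in avoid):
            return s
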