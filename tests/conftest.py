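import random

import pytest

from ampliseek.seqcore import NucSeq


@pytest.fixture
def rng():
    return random.Random(42)


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


@pytest.fixture
def random_dna_factory(rng):
    return lambda n: random_dna(rng, n)


def tile_template(template: str, read_len: int, step: int) -> list[NucSeq]:
    """Error-free reads tiling a template with fixed stagger."""
    reads = []
    i = 0
    start = 0
    while start < len(template):
        end = min(start + read_len, len(template))
        reads.append(NucSeq(f"r{i}", template[start:end]))
        if end == len(template):
            break
        start += step
        i += 1
    return reads
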