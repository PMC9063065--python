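import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wgdkit.seqio import SENSE_CODONS, CodingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cds(rng: np.random.Generator, n_codons: int, id: str = "g") -> CodingSequence:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons)
    return CodingSequence(id, "".join(SENSE_CODONS[i] for i in codons))


def mutate_cds(rng: np.random.Generator, cds: CodingSequence, p: float) -> CodingSequence:
    """Point-mutate a CDS at per-base rate p, rejecting stop codons."""
    nt = list(cds.nt)
    for i in rng.choice(len(nt), size=max(1, int(p * len(nt))), replace=False):
        ci = i // 3
        for _ in range(10):
            b = "ACGT"[rng.integers(4)]
            cand = nt.copy()
            cand[i] = b
            codon = "".join(cand[3 * ci : 3 * ci + 3])
            from wgdkit.seqio import GENETIC_CODE

            if GENETIC_CODE[codon] != "*":
                nt = cand
                break
    return CodingSequence(cds.id + "_m", "".join(nt))
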