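import re

import numpy as np
import pytest

from hormonescan.motifs import MotifPattern


def regex_positions(sequence: str, iupac: str) -> list[int]:
    """Independent motif-match oracle: regex with lookahead for overlaps."""
    pattern = "".join("[ACGT]" if c == "N" else re.escape(c) for c in iupac)
    return [m.start() for m in re.finditer(f"(?={pattern})", sequence)]


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(len(alphabet), size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)


@pytest.fixture
def nonpalindromic_motifs():
    """Synthetic non-palindromic test motifs (valid IUPAC, spacer Ns)."""
    return [
        MotifPattern("np1", "AGAACANNNAGAACA", "ARE"),
        MotifPattern("np2", "GGTCANNGGTCA", "ERE"),
        MotifPattern("np3", "ACGTNNACGG", "ARE"),
    ]
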