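import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ringkit.grammar import default_grammar


@pytest.fixture(scope="session")
def grammar():
    return default_grammar()


def build_motif(residues: str, spacers, spacer_char: str = "A") -> str:
    """Assemble a domain string from ml residues and spacer lengths."""
    parts = []
    for i, r in enumerate(residues):
        parts.append(r)
        if i < len(spacers):
            parts.append(spacer_char * spacers[i])
    return "".join(parts)


@pytest.fixture(scope="session")
def ghzfrg1_like_sequence():
    """A sequence carrying the canonical RING-H2 worked-example motif
    C-X2-C-X15-C-X1-H-X2-H-X2-C-X12-C-X2-C between inert flanks."""
    return "G" * 20 + build_motif("CCCHHCCC", (2, 15, 1, 2, 2, 12, 2)) + "G" * 20
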