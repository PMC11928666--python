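"""Shared helpers for the test suite."""

import numpy as np

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AAS), size=length))


def mutate(rng: np.random.Generator, seq: str, fraction: float) -> str:
    """Substitute a fraction of positions with random letters (homolog maker)."""
    out = list(seq)
    n_mut = int(round(fraction * len(seq)))
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        out[pos] = rng.choice(list(AAS))
    return "".join(out)
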