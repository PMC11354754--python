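"""Shared helpers: seeding, sequence utilities."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rng_for(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic per-stage generator.

    A single user-facing seed fans out to independent streams via
    ``SeedSequence([seed, *stream])`` so that each pipeline stage is
    reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. nucleotide string at the given GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction must be in [0, 1], got {gc}")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=p))
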