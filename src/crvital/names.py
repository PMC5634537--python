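"""Synthetic person names built from syllables.

Names are assembled from consonant/vowel syllable fragments, so no real
person's identity is ever embedded in generated data.  The matching stage
only needs names to behave like names: exact-comparable first names and
surnames on which an edit distance is meaningful.
"""

from __future__ import annotations

import numpy as np

_ONSETS = (
    "b", "br", "c", "ch", "d", "dr", "f", "g", "gr", "h", "j", "k", "kl",
    "l", "m", "n", "p", "pr", "r", "s", "sh", "st", "t", "th", "tr", "v", "w",
)
_VOWELS = ("a", "e", "i", "o", "u", "ai", "ea", "io", "ou")
_CODAS = ("", "l", "m", "n", "nd", "r", "rt", "s", "ss", "t", "th", "x")


def random_name(rng: np.random.Generator, n_syllables: int = 2) -> str:
    parts = []
    for k in range(n_syllables):
        onset = rng.choice(_ONSETS)
        vowel = rng.choice(_VOWELS)
        coda = rng.choice(_CODAS) if k == n_syllables - 1 else ""
        parts.append(onset + vowel + coda)
    return "".join(parts).capitalize()


def name_pool(rng: np.random.Generator, size: int, n_syllables: int = 2) -> list[str]:
    """Distinct random names; size must be feasible for the syllable space."""
    pool: set[str] = set()
    attempts = 0
    while len(pool) < size:
        pool.add(random_name(rng, n_syllables))
        attempts += 1
        if attempts > 60 * size:
            raise RuntimeError("name space too small for requested pool size")
    return sorted(pool)
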