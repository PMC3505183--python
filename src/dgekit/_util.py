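"""Small shared helpers: display rounding, sequence utilities, seeding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

DNA = "ACGT"
ANCHOR = "CATG"
TAG_LEN = 21  # CATG anchor + 17 bases

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention; banker's rounding is not used)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with half-away-from-zero rounding to `ndigits` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def rng_from(seed) -> np.random.Generator:
    """Generator from an int seed or a SeedSequence; child streams via spawn()."""
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(int(seed)))


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(int(seed)).spawn(n)
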