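"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np

WAX_CLASSES = ("PA", "FA", "HC", "AD", "WE", "AC")


def round_half_up(x: float) -> int:
    """Round half away from zero toward +inf (0.5 -> 1, 1.5 -> 2).

    Top-fraction rules such as "top 0.002% of SNPs" use k = max(1,
    round(frac * N)); Python's banker's rounding would send 0.5 to 0, so the
    conventional half-up rule is used throughout.
    """
    return int(math.floor(x + 0.5))


def top_k(frac: float, n: int) -> int:
    """Number of items selected by a top-fraction rule, never fewer than 1."""
    return max(1, round_half_up(frac * n))


def derive_seed(seed: int, *salt: int) -> int:
    """Derive an independent child seed below 2**31 from a master seed."""
    ss = np.random.SeedSequence([int(seed) % (2**31), *[int(s) % (2**31) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def check_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
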