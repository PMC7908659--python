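"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as tables are conventionally printed.

    Python's built-in ``round`` is banker's rounding; printed percentages in
    agronomy tables use half-up, so 47.365 -> 47.37 (not 47.36).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_count_frame(counts, name: str = "counts") -> pd.DataFrame:
    """Validate a genes x samples count table: numeric, finite, non-negative."""
    df = pd.DataFrame(counts)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError(f"{name} must be numeric")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if (arr < 0).any():
        raise ValueError(f"{name} contains negative entries")
    return df


def check_positive(value, name: str) -> None:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0 or not np.all(arr > 0):
        raise ValueError(f"{name} must be strictly positive")


def spawn_seed(seed_sequence: np.random.SeedSequence) -> int:
    """Derive one 31-bit child seed (stable across platforms)."""
    return int(seed_sequence.generate_state(1, dtype=np.uint32)[0] % (2**31))
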