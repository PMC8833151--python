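"""Shared helpers: seeding discipline and presentation rounding."""

from __future__ import annotations

import zlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["child_rng", "round_half_up"]


def child_rng(root_seed: int, operation: str, *keys: str) -> np.random.Generator:
    """Derive an independent random stream from a root seed.

    Each stochastic operation draws from a stream keyed by
    ``(root_seed, operation name, extra keys such as region labels)``, so
    re-running any single operation in isolation reproduces its draws
    regardless of what else ran before it.
    """
    tokens = [int(root_seed)] + [
        zlib.crc32(k.encode("utf-8")) for k in (operation, *keys)
    ]
    return np.random.default_rng(np.random.SeedSequence(tokens))


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), unlike banker's rounding.

    Used only at the reporting layer; estimator outputs stay unrounded.
    """
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
    return out if ndigits > 0 else float(int(out))
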