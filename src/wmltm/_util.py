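"""Shared helpers: deterministic seeding streams and report rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

# Named substreams hanging off a single master seed.  Every stage derives its
# generator as SeedSequence([master, stream, *counters]) so stages can be
# re-run in isolation and cohorts are stable under insertion of participants.
STREAM_DESIGN = 0
STREAM_PARTICIPANTS = 1
STREAM_RESPONSES = 2
STREAM_INFERENCE = 3

_U64 = (1 << 64) - 1


def _norm_seed(seed: int) -> int:
    """Map any Python int (including negatives) onto the uint64 entropy range."""
    return int(seed) & _U64


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the (seed, *key) substream."""
    return np.random.default_rng(np.random.SeedSequence([_norm_seed(seed), *key]))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
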