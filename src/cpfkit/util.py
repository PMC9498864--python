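"""Small shared helpers."""

from __future__ import annotations

import math
import zlib

import numpy as np

#: The 20 standard amino-acid one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Letters permitted in a protein sequence (X = unknown residue).
SEQUENCE_ALPHABET = frozenset(AA20) | {"X"}

#: Ordered taxonomic ranks used throughout the package.
RANKS = ("domain", "kingdom", "phylum", "class", "order", "family", "genus", "species")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` rounds halves to even; percentage cells in
    prevalence and motif-frequency tables instead use the conventional
    half-away-from-zero rule (e.g. 12.5 -> 13, -12.5 -> -13).
    """
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def percent(n_present: int, n_total: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round_half_away(100.0 * n_present / n_total)


def stream_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """A PCG64 generator on a named substream of a master seed.

    Streams are split with ``numpy.random.SeedSequence(seed, spawn_key=...)``
    where the spawn key is the CRC32 of each dotted key component.  The same
    (seed, keys) pair therefore yields the same stream on every platform,
    independent of call order.
    """
    spawn_key = tuple(
        k if isinstance(k, int) else zlib.crc32(k.encode("utf-8")) for k in keys
    )
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=spawn_key)))
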