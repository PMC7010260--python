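"""Binary match / don't-care patterns and spaced-word projection.

A pattern is a word over {1, 0} where '1' marks a *match position* and '0'
a *don't-care position*. Its *weight* k is the number of match positions,
its *length* the total number of symbols. A contiguous k-mer is the
degenerate pattern of k ones. First and last symbols are always match
positions, so the pattern length is well defined.

Sequence windows are projected onto the match positions: the projection of
window S[i .. i+|P|-1] is the string of characters at the match positions,
the *spaced word* at i. Positions are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["Pattern", "PatternSet", "contiguous_pattern", "random_pattern", "project"]


@dataclass(frozen=True)
class Pattern:
    """Immutable binary pattern, e.g. ``Pattern("1100101")``."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols or set(self.symbols) - {"0", "1"}:
            raise ValueError(f"pattern must be a non-empty 0/1 string: {self.symbols!r}")
        if self.symbols[0] != "1" or self.symbols[-1] != "1":
            raise ValueError(
                f"first and last pattern symbols must be match positions: {self.symbols!r}"
            )

    @cached_property
    def weight(self) -> int:
        """Number of match positions (the word weight k)."""
        return self.symbols.count("1")

    @property
    def length(self) -> int:
        return len(self.symbols)

    @cached_property
    def match_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the match positions within the pattern."""
        return tuple(i for i, c in enumerate(self.symbols) if c == "1")

    @property
    def is_contiguous(self) -> bool:
        return self.weight == self.length

    def __str__(self) -> str:
        return self.symbols

    def __len__(self) -> int:
        return self.length


def contiguous_pattern(k: int) -> Pattern:
    """The all-match pattern of weight (and length) k — plain k-mers."""
    if k < 1:
        raise ValueError(f"pattern weight must be >= 1, got {k}")
    return Pattern("1" * k)


def random_pattern(k: int, match_prob: float = 0.5, seed: int = 0) -> Pattern:
    """Draw a random pattern of weight k.

    The first symbol is forced to be a match position; subsequent symbols are
    independent Bernoulli(match_prob) draws, and generation stops at the k-th
    match symbol, so the last symbol is a match position by construction and
    the expected length is about ``1 + (k-1)/match_prob`` (≈ 2k-1 at the
    default match_prob of 0.5). Deterministic for a fixed seed.
    """
    if not 0.0 < match_prob <= 1.0:
        raise ValueError(f"match_prob must be in (0, 1], got {match_prob}")
    if k < 1 or (k < 2 and match_prob < 1.0):
        raise ValueError(
            f"weight must be >= 2 for a random pattern (got k={k}); "
            "k=1 is only possible for the contiguous pattern"
        )
    if match_prob == 1.0:
        return contiguous_pattern(k)
    rng = np.random.Generator(np.random.PCG64(seed))
    symbols = ["1"]
    matches = 1
    while matches < k:
        if rng.random() < match_prob:
            symbols.append("1")
            matches += 1
        else:
            symbols.append("0")
    return Pattern("".join(symbols))


def project(s: str, i: int, pattern: Pattern) -> str | None:
    """Spaced word of ``pattern`` at 1-based position i of s, or None.

    Returns None when the window would run past the end of s, or when any
    character at a match position is N (such words are excluded from
    counting; a don't-care N is irrelevant because it is never compared).
    """
    if i < 1:
        raise ValueError(f"positions are 1-based; got i={i}")
    if i + pattern.length - 1 > len(s):
        return None
    word = "".join(s[i - 1 + off] for off in pattern.match_offsets)
    return None if "N" in word else word


class PatternSet:
    """Lazy per-weight pattern cache shared across all genome pairs of a run.

    In ``kmer`` mode every weight maps to the contiguous pattern; in
    ``spaced`` mode each weight k gets one random pattern P_k, generated
    reproducibly from the single user seed (each weight uses an independent
    stream), so all pairs needing weight k share the same P_k.
    """

    def __init__(self, mode: str = "spaced", seed: int = 0, match_prob: float = 0.5):
        if mode not in ("kmer", "spaced"):
            raise ValueError(f"mode must be 'kmer' or 'spaced', got {mode!r}")
        self.mode = mode
        self.seed = int(seed)
        self.match_prob = float(match_prob)
        self._cache: dict[int, Pattern] = {}

    def get(self, weight: int) -> Pattern:
        if weight not in self._cache:
            if self.mode == "kmer" or weight < 2:
                self._cache[weight] = contiguous_pattern(weight)
            else:
                sub = np.random.SeedSequence(self.seed, spawn_key=(weight,))
                self._cache[weight] = random_pattern(
                    weight, self.match_prob, seed=sub.generate_state(1)[0] % (2**31)
                )
        return self._cache[weight]
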