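"""Symbolic dynamics of RR segments: the V0/V1/V2 pattern families.

The segment's full range is quantised into ``n_levels`` equal-width
bins (6 by default), every overlapping run of three symbols forms a
word, and each word is classified by its number of adjacent symbol
changes: zero changes → V0 (no variation, a sympathetic-predominance
marker), one change → V1 (mixed modulation), two changes → V2
(parasympathetic/vagal marker; like and unlike two-variation patterns
are reported merged, with the 2LV/2UV split available for
cross-checks against the source method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SymbolicConfig",
    "SymbolicProfile",
    "quantize",
    "classify_word",
    "symbolic_profile",
]

WORD_LENGTH = 3
_DEGENERATE_RANGE = 1e-9


@dataclass(frozen=True)
class SymbolicConfig:
    """Quantisation and word-forming parameters.

    ``n_levels`` (ξ) is the number of uniform amplitude bins spanning
    the segment range; ``stride`` is the step between successive words
    (1 = fully overlapping, the standard choice).  The word length is
    fixed at 3 because the family definitions assume 3-symbol words.
    """

    n_levels: int = 6
    stride: int = 1

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be at least 2")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")


@dataclass(frozen=True)
class SymbolicProfile:
    """Family occupancy of one segment.

    Percentages sum to 100; counts sum to ``n_words``.  ``v2_like_count``
    and ``v2_unlike_count`` split V2 into monotone (2LV) and
    direction-reversing (2UV) sub-patterns.
    """

    v0_pct: float
    v1_pct: float
    v2_pct: float
    v0_count: int
    v1_count: int
    v2_count: int
    v2_like_count: int
    v2_unlike_count: int
    n_words: int
    subject: str | None = None
    condition: str | None = None
    context: str | None = None

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "condition": self.condition,
            "context": self.context,
            "v0_pct": self.v0_pct,
            "v1_pct": self.v1_pct,
            "v2_pct": self.v2_pct,
            "n_words": self.n_words,
        }


def quantize(segment: np.ndarray, config: SymbolicConfig = SymbolicConfig()) -> np.ndarray:
    """Uniform full-range quantisation of a segment into ξ symbols.

    The range [min, max] is split into ξ equal-width half-open bins
    [lo, hi), the last bin closed at the maximum.  A degenerate range
    (max − min below 1 ns-scale tolerance) maps every beat to symbol 0:
    the limit of vanishing variability carries no variation patterns.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or x.size < WORD_LENGTH:
        raise ValueError("segment must be 1-D with at least 3 beats")
    lo, hi = x.min(), x.max()
    rng = hi - lo
    if rng < _DEGENERATE_RANGE:
        return np.zeros(x.size, dtype=np.int64)
    xi = config.n_levels
    symbols = np.floor((x - lo) * xi / rng).astype(np.int64)
    np.clip(symbols, 0, xi - 1, out=symbols)
    return symbols


def classify_word(word) -> str:
    """Family of a 3-symbol word by its number of adjacent changes.

    0 changes → 'V0', 1 → 'V1', 2 → 'V2'.  Like and unlike
    two-variation patterns are both 'V2' (the merged reporting
    convention).
    """
    w = tuple(word)
    if len(w) != WORD_LENGTH:
        raise ValueError(f"word must have exactly {WORD_LENGTH} symbols, got {len(w)}")
    variations = int(w[0] != w[1]) + int(w[1] != w[2])
    return ("V0", "V1", "V2")[variations]


def symbolic_profile(
    segment: np.ndarray,
    config: SymbolicConfig = SymbolicConfig(),
    *,
    subject: str | None = None,
    condition: str | None = None,
    context: str | None = None,
) -> SymbolicProfile:
    """V0/V1/V2 occupancy of a segment.

    Words are the runs ``symbols[k·stride : k·stride + 3]``; percentages
    are 100 × family count / number of words.
    """
    symbols = quantize(segment, config)
    s = config.stride
    n_words = (symbols.size - WORD_LENGTH) // s + 1
    a = symbols[: (n_words - 1) * s + 1 : s]
    b = symbols[1 : (n_words - 1) * s + 2 : s]
    c = symbols[2 : (n_words - 1) * s + 3 : s]
    d1 = a != b
    d2 = b != c
    variations = d1.astype(np.int64) + d2.astype(np.int64)
    v0 = int(np.count_nonzero(variations == 0))
    v1 = int(np.count_nonzero(variations == 1))
    two = variations == 2
    v2 = int(np.count_nonzero(two))
    # among V2 words: "like" = both changes in the same direction
    like = two & (np.sign(b - a) == np.sign(c - b))
    v2_like = int(np.count_nonzero(like))
    return SymbolicProfile(
        v0_pct=100.0 * v0 / n_words,
        v1_pct=100.0 * v1 / n_words,
        v2_pct=100.0 * v2 / n_words,
        v0_count=v0,
        v1_count=v1,
        v2_count=v2,
        v2_like_count=v2_like,
        v2_unlike_count=v2 - v2_like,
        n_words=n_words,
        subject=subject,
        condition=condition,
        context=context,
    )
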