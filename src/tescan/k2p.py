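"""Kimura two-parameter distances, substitution rates, and insertion ages.

The K2P model separates transitions (proportion P per aligned site) from
transversions (Q) and corrects both for multiple hits:

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Divergence times and rates follow from d = 2 r T, the factor 2 because two
lineages (orthologous regions, or the two LTRs of a retroelement, which
are identical copies at the moment of insertion) accumulate substitutions
independently after the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cmet import is_transition

__all__ = [
    "K2PResult",
    "DatingResult",
    "SaturationError",
    "k2p_distance",
    "divergence_time",
    "substitution_rate",
    "ltr_insertion_time",
    "count_substitutions",
    "GENIC_RATE",
    "TE_RATE",
]

# default substitution rates (per site per year): genic / low-copy context
# and transposable-element context
GENIC_RATE = 5.5e-9
TE_RATE = 1.67e-8


class SaturationError(ValueError):
    """Raised when P, Q leave the domain of the K2P log formula."""


@dataclass(frozen=True)
class K2PResult:
    P: float  # transition proportion per aligned site
    Q: float  # transversion proportion per aligned site
    d: float  # K2P distance, substitutions per site
    n_sites: int


@dataclass(frozen=True)
class DatingResult:
    rate: float  # substitutions per site per year
    time_years: float
    mode: str  # "divergence" or "insertion"
    k2p: K2PResult | None = None

    @property
    def time_my(self) -> float:
        return self.time_years / 1e6


def k2p_distance(transitions: int, transversions: int, n_sites: int) -> K2PResult:
    """K2P distance from raw substitution counts over aligned sites."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if transitions < 0 or transversions < 0:
        raise ValueError("substitution counts must be non-negative")
    P = transitions / n_sites
    Q = transversions / n_sites
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"P={P:.4g}, Q={Q:.4g} outside the K2P domain (saturated divergence)"
        )
    d = -0.5 * math.log(a * math.sqrt(b))
    return K2PResult(P, Q, d, n_sites)


def divergence_time(d: float, rate: float) -> DatingResult:
    """Years since two lineages split: T = d / (2 rate)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return DatingResult(rate, d / (2.0 * rate), "divergence")


def substitution_rate(d: float, time_years: float) -> DatingResult:
    """Per-site-per-year rate implied by distance d over time T: r = d / (2 T)."""
    if time_years <= 0:
        raise ValueError("time must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return DatingResult(d / (2.0 * time_years), time_years, "divergence")


def count_substitutions(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(n_sites, transitions, transversions) over non-gap, non-N columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "-N" or b in "-N":
            continue
        n += 1
        if a != b:
            if is_transition(a, b):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def ltr_insertion_time(ltr_a: str, ltr_b: str, rate: float) -> DatingResult:
    """Insertion age of a retroelement from its two aligned LTRs.

    The LTRs are identical copies of one template at insertion, so their
    K2P distance divided by twice the rate dates the insertion.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    n, ts, tv = count_substitutions(ltr_a, ltr_b)
    if n == 0:
        raise ValueError("no comparable (non-gap) columns between the LTRs")
    k2p = k2p_distance(ts, tv, n)
    return DatingResult(rate, k2p.d / (2.0 * rate), "insertion", k2p)
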