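"""Segment-number estimation from distorted secondary-structure fractions.

A helix contributes about four distorted (terminal) residues and a strand
about two, so the number of segments follows from the distorted contents:

    N_helix  = round(h_d · N_res / 4)
    N_strand = round(s_d · N_res / 2)

with rounding half away from zero.  The two divisors are the per-segment
distorted-residue counts conventional in CD-based segment analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError
from .refset import FractionVector

__all__ = ["SegmentEstimate", "estimate_segments", "round_half_away"]

#: distorted residues per helix segment / per strand segment
DISTORTED_PER_HELIX = 4.0
DISTORTED_PER_STRAND = 2.0


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (3.5 → 4, −3.5 → −4)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class SegmentEstimate:
    """Integer helix/strand segment counts for a chain of ``n_res`` residues."""

    n_helix: int
    n_strand: int
    n_res: int

    def __post_init__(self):
        if self.n_res < 1:
            raise InvalidParameterError("n_res must be >= 1")
        if not (0 <= self.n_helix <= math.ceil(self.n_res / DISTORTED_PER_HELIX)):
            raise InvalidParameterError(
                f"n_helix={self.n_helix} out of range for n_res={self.n_res}"
            )
        if not (0 <= self.n_strand <= math.ceil(self.n_res / DISTORTED_PER_STRAND)):
            raise InvalidParameterError(
                f"n_strand={self.n_strand} out of range for n_res={self.n_res}"
            )


def estimate_segments(f: FractionVector, n_res: int) -> SegmentEstimate:
    """Segment counts from the distorted helix/strand fractions.

    ``f.h_d`` and ``f.s_d`` are fractions of the chain (dimensionless);
    ``n_res`` the residue count.  Monotone non-decreasing in each distorted
    fraction at fixed ``n_res``.
    """
    if n_res < 1:
        raise InvalidParameterError("n_res must be >= 1")
    n_helix = round_half_away(max(f.h_d, 0.0) * n_res / DISTORTED_PER_HELIX)
    n_strand = round_half_away(max(f.s_d, 0.0) * n_res / DISTORTED_PER_STRAND)
    return SegmentEstimate(n_helix=n_helix, n_strand=n_strand, n_res=n_res)
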