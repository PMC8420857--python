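"""Content- and segment-constrained per-residue secondary-structure assignment.

Given per-residue helix/strand scores and targets derived from a CD
deconvolution (how many residues and how many segments of helix and strand
the chain should contain), this module positions the labels along the
sequence.  Labels are H (α-helix), E (β-strand) and C (everything else:
turns and unordered structures collapse into "other").

The procedure has two phases:

* **Phase 1 (greedy content matching).**  Residues are labeled H (resp. E) in
  descending helix (resp. strand) score until the residue targets are met.
  A residue claimed by both classes goes to the class with the higher score
  (ties to helix); the loser takes its next-ranked unlabeled residue; score
  ties break toward the lower sequence index.

* **Phase 2 (segment reconciliation).**  The discrepancy objective

      |n_H − t_H| + |n_E − t_E| + λ · (|seg_H − t_segH| + |seg_E − t_segE|)

  depends on the labeling only through the count tuple
  (n_H, seg_H, n_E, seg_E).  Rather than hill-climbing with local merge/split
  moves — which can stall in local optima — phase 2 solves for the count
  tuple of minimum discrepancy that is realizable on a chain of this length,
  then builds a labeling with exactly that tuple, placing segments at
  high-score positions (a greedy construction followed by score-improving
  one-position shifts).  A tuple (n_H, seg_H, n_E, seg_E) is realizable iff
  each segment count is positive exactly when its residue count is, no
  segment count exceeds its residue count, and

      n_H + n_E + max(0, |seg_H − seg_E| − 1) ≤ n_res

  (the last term counts the single-C separators needed between same-class
  segments once alternation is exhausted).  When the phase-1 labeling
  already attains the optimal objective it is returned unchanged, so a
  profile that cleanly encodes a true labeling is recovered exactly.  The
  result therefore always minimizes the discrepancy globally — when the
  targets are exactly realizable the discrepancy is 0; otherwise the
  returned labeling is the minimal-difference compromise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .errors import ConsistencyError, InvalidParameterError
from .propensity import PropensityProfile
from .refset import FractionVector
from .segments import SegmentEstimate, round_half_away
from .selcon import total_contents

__all__ = [
    "AssignConfig",
    "AssignmentTargets",
    "SSAssignment",
    "targets_from_vuvcd",
    "constrained_assign",
    "discrepancy",
    "diff_assignments",
    "region_summary",
    "run_counts",
]

logger = logging.getLogger(__name__)

_VALID = frozenset("HEC")


def run_counts(labels: str) -> tuple[int, int, int, int]:
    """(n_H, n_E, seg_H, seg_E): residue counts and maximal-run counts."""
    if set(labels) - _VALID:
        raise InvalidParameterError(f"labels must be over H/E/C, got {set(labels) - _VALID}")
    n_h = labels.count("H")
    n_e = labels.count("E")
    seg_h = seg_e = 0
    for lab, _ in groupby(labels):
        if lab == "H":
            seg_h += 1
        elif lab == "E":
            seg_e += 1
    return n_h, n_e, seg_h, seg_e


@dataclass(frozen=True)
class AssignmentTargets:
    """Residue and segment count targets for helix and strand."""

    n_h_residues: int
    n_e_residues: int
    n_h_segments: int
    n_e_segments: int
    n_res: int

    def __post_init__(self):
        vals = (
            self.n_h_residues,
            self.n_e_residues,
            self.n_h_segments,
            self.n_e_segments,
            self.n_res,
        )
        if any(v < 0 for v in vals):
            raise InvalidParameterError("targets must be non-negative")
        if self.n_h_residues + self.n_e_residues > self.n_res:
            raise InvalidParameterError("residue targets exceed chain length")
        if self.n_h_segments > self.n_h_residues or self.n_e_segments > self.n_e_residues:
            raise InvalidParameterError("segment targets exceed residue targets")


@dataclass(frozen=True)
class SSAssignment:
    """A per-residue H/E/C labeling with provenance.

    ``discrepancy`` is the objective value achieved against the targets the
    assignment was built for (None when constructed standalone).
    """

    labels: str
    targets: AssignmentTargets | None = None
    discrepancy: float | None = None
    phase1_discrepancy: float | None = None

    def __post_init__(self):
        run_counts(self.labels)  # validates the alphabet
        if self.targets is not None and len(self.labels) != self.targets.n_res:
            raise ConsistencyError("labels length must equal targets.n_res")

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> tuple[int, int, int, int]:
        return run_counts(self.labels)

    def segments(self, label: str) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of every maximal run of ``label``."""
        out = []
        pos = 1
        for lab, grp in groupby(self.labels):
            length = sum(1 for _ in grp)
            if lab == label:
                out.append((pos, pos + length - 1))
            pos += length
        return out


@dataclass(frozen=True)
class AssignConfig:
    lambda_seg: float = 1.0    # weight of one segment mismatch vs one residue mismatch
    max_polish: int = 200      # cap on score-improving one-position segment shifts


def targets_from_vuvcd(
    f: FractionVector, seg: SegmentEstimate, n_res: int
) -> AssignmentTargets:
    """Residue/segment targets from deconvolved fractions and segment counts.

    Residue targets are the rounded class totals times the chain length.
    Infeasible roundings (residue targets exceeding the chain, or segment
    counts exceeding residue counts) are resolved by decrementing the larger
    count, with a warning.
    """
    if n_res < 1:
        raise InvalidParameterError("n_res must be >= 1")
    helix, strand, _ = total_contents(f)
    n_h = round_half_away(helix * n_res)
    n_e = round_half_away(strand * n_res)
    while n_h + n_e > n_res:
        if n_h >= n_e:
            n_h -= 1
        else:
            n_e -= 1
        logger.warning("residue targets exceeded chain length; decremented to (%d, %d)", n_h, n_e)
    s_h = min(seg.n_helix, n_h)
    s_e = min(seg.n_strand, n_e)
    if s_h != seg.n_helix or s_e != seg.n_strand:
        logger.warning("segment targets capped at residue targets: (%d, %d)", s_h, s_e)
    return AssignmentTargets(n_h, n_e, s_h, s_e, n_res)


def discrepancy(
    a: SSAssignment, t: AssignmentTargets, lambda_seg: float = 1.0
) -> float:
    """Weighted L1 distance between an assignment's counts and the targets."""
    if len(a) != t.n_res:
        raise ConsistencyError("assignment length must equal targets.n_res")
    n_h, n_e, s_h, s_e = a.counts()
    return (
        abs(n_h - t.n_h_residues)
        + abs(n_e - t.n_e_residues)
        + lambda_seg * (abs(s_h - t.n_h_segments) + abs(s_e - t.n_e_segments))
    )


# ---------------------------------------------------------------------------
# Phase 1 — greedy content matching
# ---------------------------------------------------------------------------


def _phase1_greedy(p: PropensityProfile, t: AssignmentTargets) -> list[str]:
    n = len(p)
    labels = ["C"] * n
    order_h = sorted(range(n), key=lambda i: (-p.h_score[i], i))
    order_e = sorted(range(n), key=lambda i: (-p.e_score[i], i))
    need_h, need_e = t.n_h_residues, t.n_e_residues
    ih = ie = 0
    while need_h > 0 or need_e > 0:
        while ih < n and labels[order_h[ih]] != "C":
            ih += 1
        while ie < n and labels[order_e[ie]] != "C":
            ie += 1
        cand_h = order_h[ih] if (need_h > 0 and ih < n) else None
        cand_e = order_e[ie] if (need_e > 0 and ie < n) else None
        if cand_h is None and cand_e is None:
            break
        if cand_h is not None and (
            cand_e is None or p.h_score[cand_h] >= p.e_score[cand_e]
        ):
            labels[cand_h] = "H"
            need_h -= 1
        else:
            labels[cand_e] = "E"
            need_e -= 1
    return labels


# ---------------------------------------------------------------------------
# Phase 2 — optimal realizable count tuple, then realization
# ---------------------------------------------------------------------------


def _best_tuple(t: AssignmentTargets, lam: float) -> tuple[float, tuple[int, int, int, int]]:
    """Minimum discrepancy over realizable (r_h, s_h, r_e, s_e) and its argmin.

    For fixed segment counts the residue subproblem is a small piecewise-
    linear program solved in closed form; segment counts are enumerated.
    """
    n = t.n_res
    th, te, tsh, tse = t.n_h_residues, t.n_e_residues, t.n_h_segments, t.n_e_segments
    best_cost = float("inf")
    best = (0, 0, 0, 0)
    s_hi = n // 2 + 1
    for s_h in range(0, s_hi + 1):
        cost_sh = lam * abs(s_h - tsh)
        if cost_sh >= best_cost:
            # enumeration order makes cost_sh eventually monotone increasing
            if s_h > tsh:
                break
            continue
        for s_e in range(0, s_hi + 1):
            cost_s = cost_sh + lam * abs(s_e - tse)
            if cost_s >= best_cost and s_e > tse:
                break
            # lower bounds on residue counts implied by segment counts
            l_h = s_h if s_h > 0 else 0
            l_e = s_e if s_e > 0 else 0
            budget = n - max(0, abs(s_h - s_e) - 1)
            if l_h + l_e > budget:
                continue
            r_h0 = max(th, l_h) if s_h > 0 else 0
            r_e0 = max(te, l_e) if s_e > 0 else 0
            overflow = max(0, r_h0 + r_e0 - budget)
            cost_r = (
                (th if s_h == 0 else max(0, l_h - th))
                + (te if s_e == 0 else max(0, l_e - te))
                + overflow
            )
            cost = cost_s + cost_r
            if cost < best_cost - 1e-12:
                # shed overflow from strand first, then helix (deterministic)
                red_e = min(overflow, r_e0 - l_e)
                red_h = overflow - red_e
                best_cost = cost
                best = (r_h0 - red_h, s_h, r_e0 - red_e, s_e)
    return best_cost, best


def _partition(total: int, parts: int) -> list[int]:
    if parts == 0:
        return []
    base, rem = divmod(total, parts)
    return [base + 1] * rem + [base] * (parts - rem)


def _realize(
    n: int, r_h: int, s_h: int, r_e: int, s_e: int
) -> list[str]:
    """A canonical labeling with exactly the given count tuple.

    Majority-class segments are laid out left to right, alternating with
    minority-class segments, with single-C separators once the minority runs
    out; leftover C residues pad the right end.
    """
    sizes_h = _partition(r_h, s_h)
    sizes_e = _partition(r_e, s_e)
    if s_h >= s_e:
        maj_lab, maj = "H", sizes_h
        min_lab, minr = "E", sizes_e
    else:
        maj_lab, maj = "E", sizes_e
        min_lab, minr = "H", sizes_h
    blocks: list[tuple[str, int]] = []
    for i, sz in enumerate(maj):
        if i > 0:
            if i - 1 < len(minr):
                blocks.append((min_lab, minr[i - 1]))
            else:
                blocks.append(("C", 1))
        blocks.append((maj_lab, sz))
    if len(minr) == len(maj) and minr:
        blocks.append((min_lab, minr[-1]))
    labels: list[str] = []
    for lab, sz in blocks:
        labels.extend(lab * sz)
    if len(labels) > n:  # unreachable for realizable tuples
        raise InvalidParameterError("count tuple not realizable on this chain")
    labels.extend("C" * (n - len(labels)))
    return labels


def _score(labels: list[str], p: PropensityProfile) -> float:
    total = 0.0
    for i, lab in enumerate(labels):
        if lab == "H":
            total += p.h_score[i]
        elif lab == "E":
            total += p.e_score[i]
    return total


def _polish(
    labels: list[str], p: PropensityProfile, target_tuple: tuple[int, int, int, int], max_moves: int
) -> list[str]:
    """Shift segments by one position when that raises the total in-class score.

    A shift is accepted only if the count tuple is preserved (shifting into
    an adjacent same-class segment would merge runs and is thereby rejected).
    """
    n = len(labels)
    moves = 0
    improved = True
    while improved and moves < max_moves:
        improved = False
        # collect maximal runs of H/E
        runs = []
        pos = 0
        for lab, grp in groupby(labels):
            length = sum(1 for _ in grp)
            if lab in ("H", "E"):
                runs.append((lab, pos, pos + length - 1))
            pos += length
        for lab, a, b in runs:
            for delta in (-1, 1):
                na, nb = a + delta, b + delta
                if na < 0 or nb >= n:
                    continue
                entering = na if delta < 0 else nb
                if labels[entering] != "C":
                    continue
                cand = labels.copy()
                for i in range(a, b + 1):
                    cand[i] = "C"
                for i in range(na, nb + 1):
                    cand[i] = lab
                if run_counts("".join(cand)) != target_tuple:
                    continue
                if _score(cand, p) > _score(labels, p) + 1e-12:
                    labels = cand
                    moves += 1
                    improved = True
                    break
            if improved:
                break
    return labels


def constrained_assign(
    p: PropensityProfile, t: AssignmentTargets, config: AssignConfig | None = None
) -> SSAssignment:
    """Position H/E labels to match residue and segment targets.

    Returns the labeling of globally minimal discrepancy; when several
    labelings attain it, high-score placements are preferred and the result
    is deterministic for a fixed profile, targets and config.
    """
    config = config or AssignConfig()
    if len(p) != t.n_res:
        raise ConsistencyError(
            f"profile length {len(p)} != targets.n_res {t.n_res}"
        )
    lam = config.lambda_seg
    phase1 = _phase1_greedy(p, t)
    a1 = SSAssignment("".join(phase1))
    d1 = discrepancy(a1, t, lam)
    if d1 == 0:
        return SSAssignment("".join(phase1), t, 0.0, d1)

    d_star, tup = _best_tuple(t, lam)
    if d_star >= d1:  # phase 1 already optimal (its tuple is realizable)
        return SSAssignment("".join(phase1), t, d1, d1)
    r_h, s_h, r_e, s_e = tup
    labels = _realize(t.n_res, r_h, s_h, r_e, s_e)
    labels = _polish(labels, p, (r_h, r_e, s_h, s_e), config.max_polish)
    final = SSAssignment("".join(labels), t, None, d1)
    d_final = discrepancy(final, t, lam)
    return SSAssignment(final.labels, t, d_final, d1)


# ---------------------------------------------------------------------------
# Comparison and reporting
# ---------------------------------------------------------------------------


def diff_assignments(
    a: SSAssignment, b: SSAssignment, offset: int = 0
) -> list[tuple[int, str, str]]:
    """Positions where two assignments disagree.

    Positions are 1-based; a positive ``offset`` is subtracted so positions
    can be reported in the numbering of an untagged protein (e.g. offset 129
    maps construct position 219 to protein position 90).
    """
    if len(a) != len(b):
        raise ConsistencyError("assignments must have equal length")
    return [
        (i + 1 - offset, la, lb)
        for i, (la, lb) in enumerate(zip(a.labels, b.labels))
        if la != lb
    ]


def region_summary(
    a: SSAssignment, start: int, end: int
) -> dict[str, int]:
    """Segment and residue counts within a 1-based inclusive interval.

    Maximal runs intersecting the interval each count once, even when
    clipped at the interval edges.
    """
    if not (1 <= start <= end <= len(a)):
        raise InvalidParameterError(
            f"invalid range [{start}, {end}] for length {len(a)}"
        )
    helix_segments = sum(1 for s, e in a.segments("H") if s <= end and e >= start)
    strand_segments = sum(1 for s, e in a.segments("E") if s <= end and e >= start)
    window = a.labels[start - 1 : end]
    return {
        "helix_segments": helix_segments,
        "strand_segments": strand_segments,
        "helix_residues": window.count("H"),
        "strand_residues": window.count("E"),
        "other_residues": window.count("C"),
    }
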