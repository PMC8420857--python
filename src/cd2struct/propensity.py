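"""Per-residue helix/strand propensity scores.

The positional assignment stage only needs, for every residue, a real-valued
helix score and strand score; it is agnostic to where they come from.  Two
providers are bundled:

* :func:`table_propensity` — a windowed average of per-residue table values.
  The default table holds Chou–Fasman helix (Pα) and strand (Pβ) propensities;
  it is a deliberately simple stand-in for sequence-profile predictors, not a
  trained model.
* :func:`read_external_scores` — reads the de-facto ``.ss2`` three-class score
  layout (index, residue, label, C, H, E columns) produced by common
  secondary-structure predictors.

Profiles are scale-free: only the ranking of scores matters downstream, so no
normalization is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConsistencyError, InvalidParameterError, InvalidSequenceError

__all__ = [
    "CHOU_FASMAN",
    "PropensityProfile",
    "table_propensity",
    "read_external_scores",
    "write_scores",
]

#: residue → (helix propensity Pα, strand propensity Pβ); X scores 1.0/1.0
CHOU_FASMAN: dict[str, tuple[float, float]] = {
    "A": (1.42, 0.83),
    "R": (0.98, 0.93),
    "N": (0.67, 0.89),
    "D": (1.01, 0.54),
    "C": (0.70, 1.19),
    "Q": (1.11, 1.10),
    "E": (1.51, 0.37),
    "G": (0.57, 0.75),
    "H": (1.00, 0.87),
    "I": (1.08, 1.60),
    "L": (1.21, 1.30),
    "K": (1.16, 0.74),
    "M": (1.45, 1.05),
    "F": (1.13, 1.38),
    "P": (0.57, 0.55),
    "S": (0.77, 0.75),
    "T": (0.83, 1.19),
    "W": (1.08, 1.37),
    "Y": (0.69, 1.47),
    "V": (1.06, 1.70),
    "X": (1.00, 1.00),
}


@dataclass(frozen=True)
class PropensityProfile:
    """Per-residue helix and strand scores aligned to a sequence."""

    sequence: str
    h_score: np.ndarray
    e_score: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h_score, dtype=float)
        e = np.asarray(self.e_score, dtype=float)
        n = len(self.sequence)
        if h.shape != (n,) or e.shape != (n,):
            raise ConsistencyError(
                f"score arrays must have length {n} (sequence length)"
            )
        if not (np.all(np.isfinite(h)) and np.all(np.isfinite(e))):
            raise InvalidParameterError("scores must be finite")
        object.__setattr__(self, "h_score", h)
        object.__setattr__(self, "e_score", e)

    def __len__(self) -> int:
        return len(self.sequence)


def _smooth(raw: np.ndarray, window: int) -> np.ndarray:
    # centered moving average; the window shrinks at the edges
    half = window // 2
    n = raw.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = raw[lo:hi].mean()
    return out


def table_propensity(
    sequence: str,
    table: dict[str, tuple[float, float]] | None = None,
    window: int = 5,
) -> PropensityProfile:
    """Windowed per-residue propensities from a residue→(Pα, Pβ) table.

    ``window`` must be odd; at ``window=1`` the scores are the raw table
    values.  Near the chain ends the window shrinks symmetrically.
    Unknown residues other than ``X`` raise :class:`InvalidSequenceError`.
    """
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be an odd integer >= 1")
    table = table if table is not None else CHOU_FASMAN
    sequence = sequence.upper()
    bad = [(i + 1, aa) for i, aa in enumerate(sequence) if aa not in table]
    if bad:
        pos, aa = bad[0]
        raise InvalidSequenceError(f"unknown residue {aa!r} at position {pos}")
    raw_h = np.array([table[aa][0] for aa in sequence], dtype=float)
    raw_e = np.array([table[aa][1] for aa in sequence], dtype=float)
    if window == 1:
        return PropensityProfile(sequence, raw_h, raw_e)
    return PropensityProfile(sequence, _smooth(raw_h, window), _smooth(raw_e, window))


def read_external_scores(path, fasta_sequence: str | None = None) -> PropensityProfile:
    """Read a ``.ss2``-style per-residue score table.

    Data lines carry six columns: index, residue, label, C score, H score,
    E score.  Comment (``#``) and blank lines are skipped.  When
    ``fasta_sequence`` is given, residue letters are cross-checked and the
    first mismatching position reported.
    """
    path = Path(path)
    residues, h_scores, e_scores = [], [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            # tolerate predictor banner lines (e.g. "VFORMAT ...") before data
            if not residues and not parts[0].isdigit():
                continue
            raise InvalidParameterError(f"malformed score line: {raw!r}")
        residues.append(parts[1].upper())
        h_scores.append(float(parts[4]))
        e_scores.append(float(parts[5]))
    if not residues:
        raise InvalidParameterError(f"no score rows found in {path}")
    sequence = "".join(residues)
    if fasta_sequence is not None:
        fasta_sequence = fasta_sequence.upper()
        if len(fasta_sequence) != len(sequence):
            raise ConsistencyError(
                f"score table has {len(sequence)} residues but FASTA has {len(fasta_sequence)}"
            )
        for i, (a, b) in enumerate(zip(sequence, fasta_sequence)):
            if a != b:
                raise ConsistencyError(
                    f"residue mismatch at position {i + 1}: scores say {a!r}, FASTA says {b!r}"
                )
    return PropensityProfile(sequence, np.array(h_scores), np.array(e_scores))


def write_scores(profile: PropensityProfile, path, labels: str | None = None) -> None:
    """Write a profile in the ``.ss2`` dialect (scores to 6 decimals).

    The coil score column is written as ``1 − max(H, E)`` clipped to zero
    unless per-residue labels are provided, purely to keep the three-column
    layout; downstream consumers in this package ignore it.
    """
    path = Path(path)
    if labels is not None and len(labels) != len(profile):
        raise ConsistencyError("labels length must match profile length")
    lines = ["# per-residue secondary-structure scores (ss2 layout)", ""]
    for i, aa in enumerate(profile.sequence):
        lab = labels[i] if labels is not None else "C"
        h = profile.h_score[i]
        e = profile.e_score[i]
        c = max(0.0, 1.0 - max(h, e))
        lines.append(f"{i + 1:4d} {aa} {lab}   {c:.6f}  {h:.6f}  {e:.6f}")
    path.write_text("\n".join(lines) + "\n")
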