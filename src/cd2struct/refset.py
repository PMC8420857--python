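"""Reference database of proteins with known CD spectra and six-class fractions.

The deconvolution basis is a set of proteins for which both a CD spectrum and
a secondary-structure fraction vector are known (from X-ray structures).  Six
classes are used throughout, matching the ordered/distorted split of helix
and strand used in segment estimation:

    h_r  ordered (regular) α-helix        s_r  ordered (regular) β-strand
    h_d  distorted α-helix (termini)      s_d  distorted β-strand (termini)
    turn                                   unordered

The class count is a fixed property of the method, not a configuration knob.
Leave-one-out evaluation reports the pooled RMSD δ and the Pearson r between
true and re-estimated fractions over all (protein, class) pairs — the same
two scalars conventionally quoted for CD reference databases.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, InvalidParameterError
from .spectra import CDSpectrum, read_spectrum, resample_to_grid, write_spectrum

__all__ = [
    "CLASS_NAMES",
    "FractionVector",
    "ReferenceProtein",
    "ReferenceSet",
    "build_matrices",
    "loo_evaluate",
    "LOOResult",
    "read_reference_set",
    "write_reference_set",
]

logger = logging.getLogger(__name__)

CLASS_NAMES = ("h_r", "h_d", "s_r", "s_d", "turn", "unordered")
N_CLASSES = 6

#: solutions may dip slightly negative before cleanup; the conventional floor
FRACTION_FLOOR = -0.025


@dataclass(frozen=True)
class FractionVector:
    """Six secondary-structure fractions summing to one.

    Components may touch the small negative floor (−0.025) that the
    deconvolution selection rules tolerate, but the vector as a whole must
    sum to 1.  Use :meth:`from_raw` to clean up an unconstrained solution
    (clip negatives, renormalize).
    """

    h_r: float
    h_d: float
    s_r: float
    s_d: float
    turn: float
    unordered: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("fractions must be finite")
        if np.any(arr < FRACTION_FLOOR - 1e-12):
            raise InvalidParameterError(
                f"fractions must be >= {FRACTION_FLOOR}; got {arr.min():.4f}"
            )
        if abs(float(arr.sum()) - 1.0) > 1e-6:
            raise InvalidParameterError(f"fractions must sum to 1; got {arr.sum():.6f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.h_r, self.h_d, self.s_r, self.s_d, self.turn, self.unordered])

    @classmethod
    def from_array(cls, arr) -> "FractionVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_CLASSES,):
            raise InvalidParameterError(f"expected {N_CLASSES} fractions, got shape {arr.shape}")
        return cls(*[float(x) for x in arr])

    @classmethod
    def from_raw(cls, arr) -> "FractionVector":
        """Clean up an unconstrained solution: clip negatives to 0, renormalize to sum 1."""
        arr = np.clip(np.asarray(arr, dtype=float), 0.0, None)
        total = arr.sum()
        if total <= 0:
            raise InvalidParameterError("cannot normalize an all-nonpositive fraction vector")
        return cls.from_array(arr / total)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, self.as_array()))


@dataclass(frozen=True)
class ReferenceProtein:
    name: str
    spectrum: CDSpectrum
    fractions: FractionVector
    n_res: int

    def __post_init__(self):
        if self.n_res < 1:
            raise InvalidParameterError("n_res must be >= 1")


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered collection of reference proteins on a common wavelength grid.

    At least six members are required (the rank needed to resolve six
    classes).  Construction resamples every member onto ``grid``.
    """

    proteins: tuple[ReferenceProtein, ...]
    grid: np.ndarray

    def __post_init__(self):
        if len(self.proteins) < N_CLASSES:
            raise InvalidParameterError(
                f"a reference set needs >= {N_CLASSES} members, got {len(self.proteins)}"
            )
        grid = np.asarray(self.grid, dtype=float)
        resampled = tuple(
            ReferenceProtein(
                p.name,
                resample_to_grid(p.spectrum, grid),
                p.fractions,
                p.n_res,
            )
            for p in self.proteins
        )
        object.__setattr__(self, "proteins", resampled)
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.proteins)

    def names(self) -> list[str]:
        return [p.name for p in self.proteins]

    def drop(self, index: int) -> "ReferenceSet":
        """A copy without member ``index`` (for leave-one-out)."""
        kept = self.proteins[:index] + self.proteins[index + 1 :]
        return ReferenceSet(kept, self.grid)


def build_matrices(rs: ReferenceSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectra (wavelengths × proteins) and fractions (classes × proteins) tables.

    Column order follows member order in the set; the two tables share their
    columns, so permuting members permutes both identically.
    """
    names = rs.names()
    if len(set(names)) != len(names):
        raise ConsistencyError("reference protein names must be unique")
    spectra = pd.DataFrame(
        {p.name: p.spectrum.values for p in rs.proteins}, index=rs.grid
    )
    fractions = pd.DataFrame(
        {p.name: p.fractions.as_array() for p in rs.proteins}, index=list(CLASS_NAMES)
    )
    return spectra, fractions


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out evaluation summary.

    ``delta`` is the RMSD pooled over all (protein, class) pairs; ``r`` the
    Pearson correlation over the same pairs (NaN when the truth is
    degenerate, e.g. all members share one fraction vector).
    """

    delta: float
    r: float
    n_evaluated: int
    skipped: tuple[str, ...]
    degenerate_correlation: bool
    table: pd.DataFrame = field(repr=False)


def loo_evaluate(rs: ReferenceSet, config=None) -> LOOResult:
    """Leave-one-out self-evaluation of a reference set.

    Each member's spectrum is deconvolved against the remaining members and
    compared with its known fractions.  Members whose deconvolution fails
    are skipped with a warning and reported in ``skipped``.
    """
    from .selcon import SelconConfig, selcon_deconvolve
    from .errors import CD2StructError

    if len(rs) < N_CLASSES + 1:
        raise InvalidParameterError("leave-one-out needs at least 7 members")
    config = config or SelconConfig()

    rows = []
    skipped = []
    for i, prot in enumerate(rs.proteins):
        rest = rs.drop(i)
        try:
            est, _ = selcon_deconvolve(prot.spectrum, rest, config)
        except CD2StructError as exc:
            logger.warning("leave-one-out: skipping %s (%s)", prot.name, exc)
            skipped.append(prot.name)
            continue
        true_arr = prot.fractions.as_array()
        est_arr = est.as_array()
        for cls_name, t, e in zip(CLASS_NAMES, true_arr, est_arr):
            rows.append({"protein": prot.name, "class": cls_name, "true": t, "estimated": e})

    if not rows:
        raise InvalidParameterError("leave-one-out: every member failed deconvolution")
    table = pd.DataFrame(rows)
    resid = table["estimated"] - table["true"]
    delta = float(np.sqrt(np.mean(resid**2)))
    # correlation is meaningless when members carry no between-protein
    # variation (every member shares one fraction vector) or either pooled
    # series is constant
    truth_by_protein = table.pivot(index="protein", columns="class", values="true")
    degenerate = bool(
        (truth_by_protein.nunique(axis=0) <= 1).all()
        or table["true"].std(ddof=0) == 0
        or table["estimated"].std(ddof=0) == 0
    )
    if degenerate:
        r = math.nan
    else:
        from scipy.stats import pearsonr

        r = float(pearsonr(table["true"], table["estimated"]).statistic)
    n_eval = len(rs) - len(skipped)
    return LOOResult(delta, r, n_eval, tuple(skipped), degenerate, table)


# ---------------------------------------------------------------------------
# Manifest I/O — one YAML manifest naming per-protein spectrum files
# ---------------------------------------------------------------------------


def write_reference_set(rs: ReferenceSet, directory) -> Path:
    """Write a reference set as ``manifest.yaml`` plus one spectrum file per member.

    Floats are formatted with repr-level precision so a write/read/write
    round trip is byte-identical.
    """
    directory = Path(directory)
    (directory / "spectra").mkdir(parents=True, exist_ok=True)
    entries = []
    for p in rs.proteins:
        rel = f"spectra/{p.name}.tsv"
        write_spectrum(p.spectrum, directory / rel)
        entries.append(
            {
                "name": p.name,
                "n_res": int(p.n_res),
                "spectrum": rel,
                "fractions": {k: float(v) for k, v in p.fractions.as_dict().items()},
            }
        )
    manifest = {
        "grid_nm": [float(f"{w:.6g}") for w in rs.grid],
        "proteins": entries,
    }
    out = directory / "manifest.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_reference_set(manifest_path) -> ReferenceSet:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    grid = np.asarray(manifest["grid_nm"], dtype=float)
    proteins = []
    for entry in manifest["proteins"]:
        spec = read_spectrum(base / entry["spectrum"])
        frac = FractionVector(**{k: float(v) for k, v in entry["fractions"].items()})
        proteins.append(
            ReferenceProtein(entry["name"], spec, frac, int(entry["n_res"]))
        )
    return ReferenceSet(tuple(proteins), grid)
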