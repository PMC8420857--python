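"""CD spectrum data model and unit handling.

A circular dichroism spectrum is stored as the molar circular dichroism per
mean residue, Δε (M⁻¹ cm⁻¹), on a wavelength grid in nm.  Raw instrument
output (ellipticity θ in millidegrees) is converted through the standard
mean-residue-ellipticity chain

    [θ]_MRE = θ(mdeg) · MRW / (10 · l · c)      deg cm² dmol⁻¹
    Δε      = [θ]_MRE / 3298                     M⁻¹ cm⁻¹

collapsed here into a single expression with the constant 32980 = 10 · 3298,
where ``l`` is the optical path length in cm, ``c`` the protein concentration
in mg/mL and MRW the mean residue weight in g/mol.

Baseline/buffer subtraction and smoothing are assumed to have been done
upstream by the instrument pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .errors import ConsistencyError, InvalidParameterError, OutOfRangeError

__all__ = [
    "CDSpectrum",
    "SampleMeta",
    "normalize_to_delta_epsilon",
    "concentration_from_absorbance",
    "resample_to_grid",
    "read_spectrum",
    "write_spectrum",
    "read_fasta",
]

#: θ(mdeg)·MRW / (DELTA_EPS_DENOM · l(cm) · c(mg/mL)) gives Δε; 32980 = 10·3298.
DELTA_EPS_DENOM = 32980.0

WAVELENGTH_MIN = 160.0
WAVELENGTH_MAX = 320.0
DELTA_EPS_SANITY = 100.0


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata used to turn absorbance into concentration.

    ``extinction_coefficient_e1pct`` follows the E 1% convention: absorbance
    at 280 nm of a 10 mg/mL solution in a 1 cm cell, i.e. units of
    (mg/mL)⁻¹ cm⁻¹ × 10.
    """

    name: str = ""
    extinction_coefficient_e1pct: float | None = None
    n_res: int | None = None
    sequence: str | None = None

    def __post_init__(self):
        if self.n_res is not None and self.n_res < 1:
            raise InvalidParameterError("n_res must be >= 1")
        if self.sequence is not None and self.n_res is not None:
            if len(self.sequence) != self.n_res:
                raise ConsistencyError(
                    f"sequence length {len(self.sequence)} != n_res {self.n_res}"
                )


@dataclass(frozen=True)
class CDSpectrum:
    """A CD spectrum: Δε per mean residue on a wavelength grid.

    Wavelengths are normalized to ascending order internally; the original
    file order is remembered in ``meta['input_descending']`` and restored on
    write.  The grid may be irregular.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise InvalidParameterError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise InvalidParameterError("a spectrum needs at least 2 points")
        diffs = np.diff(wl)
        if np.all(diffs > 0):
            descending = False
        elif np.all(diffs < 0):
            descending = True
            wl = wl[::-1].copy()
            vals = vals[::-1].copy()
        else:
            raise InvalidParameterError("wavelengths must be strictly monotone")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise OutOfRangeError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, {WAVELENGTH_MAX:g}] nm"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError("spectrum values must be finite")
        if np.any(np.abs(vals) >= DELTA_EPS_SANITY):
            raise InvalidParameterError(
                f"|delta epsilon| must be < {DELTA_EPS_SANITY:g} (unit error upstream?)"
            )
        meta = dict(self.meta)
        meta.setdefault("input_descending", descending)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "meta", meta)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def with_values(self, values: np.ndarray) -> "CDSpectrum":
        return CDSpectrum(self.wavelengths.copy(), np.asarray(values, float), dict(self.meta))


def normalize_to_delta_epsilon(
    wavelengths,
    theta_mdeg,
    *,
    path_length_cm: float,
    concentration_mg_ml: float,
    mrw: float,
    meta: dict | None = None,
) -> CDSpectrum:
    """Convert raw ellipticity (millidegrees) to Δε per mean residue.

    Δε(λ) = θ(λ) · MRW / (32980 · l · c), with ``l`` in cm and ``c`` in mg/mL.
    The conversion is linear in θ and inversely linear in each of ``l``, ``c``.
    """
    if path_length_cm <= 0:
        raise InvalidParameterError("path_length_cm must be > 0")
    if concentration_mg_ml <= 0:
        raise InvalidParameterError("concentration_mg_ml must be > 0")
    if mrw <= 0:
        raise InvalidParameterError("mrw must be > 0")
    theta = np.asarray(theta_mdeg, dtype=float)
    values = theta * mrw / (DELTA_EPS_DENOM * path_length_cm * concentration_mg_ml)
    m = dict(meta or {})
    m.update(
        path_length_cm=path_length_cm,
        concentration_mg_ml=concentration_mg_ml,
        mrw=mrw,
        units="delta_epsilon",
    )
    return CDSpectrum(np.asarray(wavelengths, float), values, m)


def concentration_from_absorbance(
    a280: float, e1pct: float, path_length_cm: float = 1.0
) -> float:
    """Protein concentration (mg/mL) from A280 and the E 1% coefficient.

    c = 10 · A280 / (E1% · l); the factor 10 converts the 1 % (10 mg/mL)
    convention to mg/mL.
    """
    if e1pct <= 0:
        raise InvalidParameterError("e1pct must be > 0")
    if path_length_cm <= 0:
        raise InvalidParameterError("path_length_cm must be > 0")
    if a280 < 0:
        raise InvalidParameterError("a280 must be >= 0")
    return 10.0 * a280 / (e1pct * path_length_cm)


def resample_to_grid(s: CDSpectrum, grid) -> CDSpectrum:
    """Linearly interpolate a spectrum onto a new wavelength grid.

    Extrapolation is refused: every grid point must lie within the span of
    the input spectrum (a 1e-9 nm tolerance absorbs float round-off).
    Metadata is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise OutOfRangeError(
            f"grid [{grid.min():g}, {grid.max():g}] nm exceeds spectrum span [{lo:g}, {hi:g}] nm"
        )
    values = np.interp(np.clip(grid, lo, hi), s.wavelengths, s.values)
    return CDSpectrum(grid, values, dict(s.meta))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

#: header keys recognised in spectrum files (``# key: value``)
_FLOAT_META = {"path_length_cm", "concentration_mg_ml", "mrw"}
_INT_META = {"n_accumulations"}


def read_spectrum(path) -> CDSpectrum:
    """Read a two-column whitespace/tab-separated spectrum file.

    Header lines start with ``#`` and carry ``key: value`` metadata.  If the
    header declares ``units: mdeg`` the values are converted to Δε using the
    path length, concentration and MRW from the header; the default unit is
    ``delta_epsilon``.
    """
    path = Path(path)
    meta: dict = {}
    wl, vals = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key in _FLOAT_META:
                    meta[key] = float(value)
                elif key in _INT_META:
                    meta[key] = int(value)
                elif key:
                    meta[key] = value
            continue
        parts = line.split()
        if len(parts) < 2:
            raise InvalidParameterError(f"malformed spectrum line: {raw!r}")
        wl.append(float(parts[0]))
        vals.append(float(parts[1]))
    units = meta.pop("units", "delta_epsilon")
    if units == "mdeg":
        missing = _FLOAT_META - set(meta)
        if missing:
            raise InvalidParameterError(
                f"units=mdeg requires header keys {sorted(missing)}"
            )
        return normalize_to_delta_epsilon(
            wl,
            vals,
            path_length_cm=meta["path_length_cm"],
            concentration_mg_ml=meta["concentration_mg_ml"],
            mrw=meta["mrw"],
            meta=meta,
        )
    if units != "delta_epsilon":
        raise InvalidParameterError(f"unknown units {units!r}")
    meta["units"] = "delta_epsilon"
    return CDSpectrum(np.array(wl), np.array(vals), meta)


def write_spectrum(s: CDSpectrum, path) -> None:
    """Write a spectrum in the same two-column text dialect ``read_spectrum`` reads.

    Values are written as Δε; the original wavelength ordering of the source
    file is restored.
    """
    path = Path(path)
    lines = []
    for key, value in s.meta.items():
        if key in ("input_descending", "units"):
            continue
        lines.append(f"# {key}: {value}")
    lines.append("# units: delta_epsilon")
    wl, vals = s.wavelengths, s.values
    if s.meta.get("input_descending"):
        wl, vals = wl[::-1], vals[::-1]
    for w, v in zip(wl, vals):
        lines.append(f"{w:.6g}\t{v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path, record_id: str | None = None) -> tuple[str, str]:
    """Return ``(id, sequence)`` from a FASTA file.

    The first record is used unless ``record_id`` names a specific one.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidParameterError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise ConsistencyError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return rec.id, str(rec.seq).upper()
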