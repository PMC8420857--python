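"""Synthetic inputs for every pipeline stage.

Real CD reference databases pair measured spectra with crystallographic
fraction vectors; no public standard corpus exists, so testing uses
synthetic stand-ins built from six Gaussian-band basis curves — one per
fraction class — with literature-standard band positions (helix: positive
lobe near 192 nm, negative lobes near 208 and 222 nm; strand: positive near
197 nm, negative near 216 nm; unordered: strong negative near 198 nm; turns:
weak broad features).  A member's spectrum is its fraction-weighted sum of
the basis curves plus white noise, so the linear model the deconvolution
assumes holds exactly at zero noise.  These curves emulate the *statistical*
structure of a reference database, not any particular measured spectra.

Fractions are drawn from a mixture of three Dirichlet archetypes
(helix-rich, strand-rich, mixed) over the four observable totals
(helix, strand, turn, unordered); distorted sub-fractions are fixed shares
of the class totals (40 % of helix, 45 % of strand by default), mimicking
the roughly constant ratio of terminal to interior residues in real chains.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .propensity import PropensityProfile
from .refset import CLASS_NAMES, FractionVector, ReferenceProtein, ReferenceSet
from .spectra import CDSpectrum

__all__ = [
    "BasisSpectra",
    "DEFAULT_BANDS",
    "default_grid",
    "make_basis_spectra",
    "make_reference_set",
    "make_query",
    "make_planted_profile",
    "random_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: per-class Gaussian bands: (center nm, width nm, amplitude Δε)
DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "h_r": [(192.0, 5.5, 12.0), (208.0, 6.5, -8.0), (222.0, 7.5, -9.0)],
    "h_d": [(190.0, 6.5, 5.0), (205.0, 7.0, -4.0), (222.0, 9.0, -3.5)],
    "s_r": [(197.0, 6.5, 4.5), (216.0, 8.0, -3.5)],
    "s_d": [(200.0, 8.0, 2.5), (218.0, 9.0, -1.8)],
    "turn": [(183.0, 7.0, 1.8), (206.0, 10.0, 1.0)],
    "unordered": [(198.0, 7.0, -7.0), (222.0, 11.0, 0.6)],
}

#: default shares of each class total assigned to the distorted sub-class
DEFAULT_DISTORTED_SHARES = {"helix": 0.40, "strand": 0.45}

#: Dirichlet parameters over (helix, strand, turn, unordered) totals
DEFAULT_ARCHETYPES = (
    np.array([10.0, 2.0, 3.0, 5.0]),   # helix-rich
    np.array([2.0, 8.0, 4.0, 6.0]),    # strand-rich
    np.array([4.0, 4.0, 4.0, 8.0]),    # mixed / mostly other
)


def default_grid(start: float = 175.0, stop: float = 240.0, step: float = 1.0) -> np.ndarray:
    """The default analysis grid, 175–240 nm at 1 nm."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class BasisSpectra:
    """Six per-class basis curves on a common grid."""

    grid: np.ndarray
    curves: np.ndarray  # shape (len(grid), 6), columns in CLASS_NAMES order
    bands: dict = field(default_factory=dict)

    def __post_init__(self):
        curves = np.asarray(self.curves, dtype=float)
        grid = np.asarray(self.grid, dtype=float)
        if curves.shape != (grid.size, len(CLASS_NAMES)):
            raise InvalidParameterError("curves must be (grid, 6)")
        if not np.all(np.isfinite(curves)):
            raise InvalidParameterError("basis curves must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "curves", curves)

    def combine(self, fractions: FractionVector) -> np.ndarray:
        return self.curves @ fractions.as_array()


def _gaussian(grid: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((grid - center) / width) ** 2)


def make_basis_spectra(
    grid=None,
    bands: dict | None = None,
    seed: int | None = None,
    jitter: float = 0.0,
) -> BasisSpectra:
    """Sum-of-Gaussians basis curves, optionally jittered per seed.

    ``jitter`` perturbs band centers (nm, s.d. = jitter·width) and amplitudes
    (relative s.d. = jitter); at 0 the curves are the fixed defaults.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 160.0 or grid.max() > 320.0:
        raise InvalidParameterError("grid must lie within [160, 320] nm")
    bands = bands if bands is not None else DEFAULT_BANDS
    rng = np.random.default_rng(seed)
    curves = np.zeros((grid.size, len(CLASS_NAMES)))
    used_bands: dict[str, list[tuple[float, float, float]]] = {}
    for j, cls in enumerate(CLASS_NAMES):
        used = []
        for band in bands.get(cls, []):
            if len(band) != 3:
                raise InvalidParameterError(f"band {band!r} must be (center, width, amplitude)")
            center, width, amp = (float(x) for x in band)
            if width <= 0:
                raise InvalidParameterError("band width must be > 0")
            if jitter > 0:
                center = center + rng.normal(0.0, jitter * width)
                amp = amp * (1.0 + rng.normal(0.0, jitter))
            curves[:, j] += _gaussian(grid, center, width, amp)
            used.append((center, width, amp))
        used_bands[cls] = used
    return BasisSpectra(grid, curves, used_bands)


def _sample_fractions(
    rng: np.random.Generator,
    archetypes=DEFAULT_ARCHETYPES,
    distorted_shares: dict | None = None,
) -> FractionVector:
    shares = distorted_shares or DEFAULT_DISTORTED_SHARES
    alpha = archetypes[rng.integers(len(archetypes))]
    helix, strand, turn, unordered = rng.dirichlet(alpha)
    h_d = shares["helix"] * helix
    s_d = shares["strand"] * strand
    return FractionVector(
        h_r=helix - h_d,
        h_d=h_d,
        s_r=strand - s_d,
        s_d=s_d,
        turn=turn,
        unordered=unordered,
    )


def make_reference_set(
    n: int = 30,
    basis: BasisSpectra | None = None,
    noise_sigma: float = 0.02,
    seed: int | None = None,
    archetypes=DEFAULT_ARCHETYPES,
    distorted_shares: dict | None = None,
    n_res_range: tuple[int, int] = (80, 350),
) -> ReferenceSet:
    """A synthetic reference database of ``n`` proteins.

    ``noise_sigma`` is expressed as a fraction of each member's peak |Δε|;
    at 0 every spectrum is an exact linear combination of the basis curves.
    """
    if n < 6:
        raise InvalidParameterError("a reference set needs n >= 6")
    basis = basis if basis is not None else make_basis_spectra()
    rng = np.random.default_rng(seed)
    proteins = []
    for i in range(n):
        fracs = _sample_fractions(rng, archetypes, distorted_shares)
        values = basis.combine(fracs)
        peak = float(np.max(np.abs(values)))
        if noise_sigma > 0 and peak > 0:
            values = values + rng.normal(0.0, noise_sigma * peak, size=values.shape)
        n_res = int(rng.integers(n_res_range[0], n_res_range[1] + 1))
        spec = CDSpectrum(basis.grid.copy(), values, {"name": f"SYN{i + 1:03d}"})
        proteins.append(ReferenceProtein(f"SYN{i + 1:03d}", spec, fracs, n_res))
    return ReferenceSet(tuple(proteins), basis.grid)


def make_query(
    fractions: FractionVector,
    basis: BasisSpectra | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    name: str = "query",
) -> CDSpectrum:
    """A synthetic query spectrum with known true fractions."""
    basis = basis if basis is not None else make_basis_spectra()
    values = basis.combine(fractions)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        peak = float(np.max(np.abs(values)))
        values = values + rng.normal(0.0, noise_sigma * peak, size=values.shape)
    return CDSpectrum(basis.grid.copy(), values, {"name": name})


def random_sequence(n: int, seed: int | None = None) -> str:
    rng = np.random.default_rng(seed)
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=n))


def make_planted_profile(
    labels: str,
    margin: float = 2.0,
    noise_sigma: float = 0.25,
    base: float = 0.0,
    seed: int | None = None,
    sequence: str | None = None,
) -> PropensityProfile:
    """A profile that encodes a known labeling with a controllable margin.

    In-class residues score ``base + margin + noise``; out-of-class residues
    ``base + noise``.  With margin ≫ noise the true labeling is recoverable
    from the scores alone; at margin 0 the profile carries no signal.
    """
    if set(labels) - set("HEC"):
        raise InvalidParameterError("labels must be over H/E/C")
    n = len(labels)
    rng = np.random.default_rng(seed)
    sequence = sequence if sequence is not None else random_sequence(
        n, seed=None if seed is None else seed + 1
    )
    if len(sequence) != n:
        raise InvalidParameterError("sequence length must match labels length")
    h = base + rng.normal(0.0, noise_sigma, size=n)
    e = base + rng.normal(0.0, noise_sigma, size=n)
    lab_arr = np.frombuffer(labels.encode(), dtype="S1")
    h = h + margin * (lab_arr == b"H")
    e = e + margin * (lab_arr == b"E")
    return PropensityProfile(sequence, h, e)
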