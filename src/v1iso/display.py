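"""Display model and color conversions.

Models a linearized CRT-style display: a uniform gray background, three
phosphor emission spectra, and an achievable intensity range of [0, 1] per
channel (0 = phosphor off, 1 = maximum output; gamma is assumed already
corrected, so intensities are linear).  Together with a set of cone
fundamentals this determines the mapping from background-subtracted phosphor
intensities to L-, M-, and S-cone Weber contrasts, and the cone-weight
representation of a chromatically linear neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DisplayModel",
    "ConeFundamentals",
    "ConeWeights",
    "rgb_to_cone_contrast",
    "cone_contrast_matrix",
    "cone_weights_from_phosphor_vector",
    "phosphor_vector_from_cone_weights",
    "luminance_cone_weights",
    "load_curve",
    "gaussian_phosphor_display",
    "gaussian_cone_fundamentals",
    "DEFAULT_WAVELENGTHS",
]

#: default wavelength grid: 380-780 nm in 5-nm steps
DEFAULT_WAVELENGTHS = np.arange(380.0, 781.0, 5.0)


class DegenerateBackgroundError(ValueError):
    """Background produces zero excitation in at least one cone class."""


@dataclass(frozen=True)
class ConeFundamentals:
    """L, M, S spectral sensitivities on a common wavelength grid.

    ``sensitivities`` is a (3, n_wavelengths) array ordered (L, M, S);
    values are dimensionless and non-negative.
    """

    wavelengths: np.ndarray
    sensitivities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (3, wl.size):
            raise ValueError(f"expected (3, {wl.size}) sensitivities, got {s.shape}")
        if np.any(s < 0):
            raise ValueError("cone fundamentals must be non-negative")
        if np.any(s.sum(axis=1) <= 0):
            raise ValueError("each cone fundamental needs positive total energy")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "sensitivities", s)


@dataclass(frozen=True)
class DisplayModel:
    """Linearized display: gray background plus three phosphor spectra.

    ``phosphor_spectra`` is (3, n_wavelengths), rows ordered (R, G, B),
    relative energy per nm at maximum intensity.  ``background_rgb`` is the
    background intensity of each phosphor as a fraction of its maximum,
    strictly inside (0, 1) so that both increments and decrements are
    displayable.
    """

    wavelengths: np.ndarray
    phosphor_spectra: np.ndarray
    background_rgb: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, 0.5])
    )

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        spec = np.asarray(self.phosphor_spectra, dtype=float)
        bg = np.asarray(self.background_rgb, dtype=float)
        if spec.shape != (3, wl.size):
            raise ValueError(f"expected (3, {wl.size}) spectra, got {spec.shape}")
        if np.any(spec < 0):
            raise ValueError("phosphor spectra must be non-negative")
        if bg.shape != (3,) or np.any(bg <= 0) or np.any(bg >= 1):
            raise ValueError("background_rgb must lie strictly inside (0, 1)")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "phosphor_spectra", spec)
        object.__setattr__(self, "background_rgb", bg)

    def in_gamut(self, rgb: np.ndarray) -> bool:
        """True when every channel of ``rgb`` lies within [0, 1]."""
        rgb = np.asarray(rgb)
        return bool(np.all(rgb >= 0.0) and np.all(rgb <= 1.0))


@dataclass(frozen=True)
class ConeWeights:
    """Signed L, M, S weights, L1-normalized so |l| + |m| + |s| = 1."""

    l: float
    m: float
    s: float

    @classmethod
    def from_vector(cls, v) -> "ConeWeights":
        v = np.asarray(v, dtype=float)
        norm = np.abs(v).sum()
        if norm == 0:
            raise ValueError("cannot normalize an all-zero cone-weight vector")
        v = v / norm
        return cls(l=float(v[0]), m=float(v[1]), s=float(v[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.m, self.s])


def _check_shared_grid(display: DisplayModel, fundamentals: ConeFundamentals) -> None:
    if display.wavelengths.shape != fundamentals.wavelengths.shape or not np.allclose(
        display.wavelengths, fundamentals.wavelengths
    ):
        raise ValueError("display and fundamentals must share one wavelength grid")


def cone_contrast_matrix(
    display: DisplayModel, fundamentals: ConeFundamentals
) -> np.ndarray:
    """(3, 3) matrix mapping a background-subtracted RGB triplet to cone contrast.

    Row ``c``, column ``p`` of the underlying excitation matrix is the inner
    product of phosphor ``p``'s spectrum with cone ``c``'s fundamental; each
    row is then divided by the background excitation of that cone class
    (Weber normalization).
    """
    _check_shared_grid(display, fundamentals)
    # M[c, p] = <fundamental_c, spectrum_p>; excitation is linear in intensity
    excitation = fundamentals.sensitivities @ display.phosphor_spectra.T
    bg_excitation = excitation @ display.background_rgb
    if np.any(bg_excitation <= 0):
        raise DegenerateBackgroundError(
            "background yields zero excitation for at least one cone class"
        )
    return excitation / bg_excitation[:, None]


def rgb_to_cone_contrast(
    rgb_delta, display: DisplayModel, fundamentals: ConeFundamentals
) -> np.ndarray:
    """Convert a background-subtracted intensity triplet to L, M, S Weber contrast.

    Returns (dL/L_bg, dM/M_bg, dS/S_bg).  Linear in ``rgb_delta``.
    """
    rgb_delta = np.asarray(rgb_delta, dtype=float)
    return cone_contrast_matrix(display, fundamentals) @ rgb_delta


def cone_weights_from_phosphor_vector(
    v, display: DisplayModel, fundamentals: ConeFundamentals
) -> ConeWeights:
    """Cone weights equivalent to a linear phosphor-space weighting ``v``.

    A neuron whose drive is ``v . delta_rgb`` is re-expressed as weights ``w``
    acting on cone contrast, ``w . cc``, with ``cc = C @ delta_rgb``; hence
    ``w = C^{-T} v``, L1-normalized.
    """
    C = cone_contrast_matrix(display, fundamentals)
    try:
        w = np.linalg.solve(C.T, np.asarray(v, dtype=float))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological display
        raise ValueError("degenerate display: cone-contrast matrix is singular") from exc
    return ConeWeights.from_vector(w)


def phosphor_vector_from_cone_weights(
    w: ConeWeights, display: DisplayModel, fundamentals: ConeFundamentals
) -> np.ndarray:
    """Inverse of :func:`cone_weights_from_phosphor_vector` (up to scale)."""
    C = cone_contrast_matrix(display, fundamentals)
    return C.T @ w.as_array()


def luminance_cone_weights(
    luminosity_fn: np.ndarray,
    fundamentals: ConeFundamentals,
    wavelengths: np.ndarray | None = None,
) -> tuple[np.ndarray, ConeWeights]:
    """Regress a photopic luminosity function onto the cone fundamentals.

    Ordinary least squares with no intercept.  Returns the raw coefficients
    (the scale at which each fundamental contributes to luminance) together
    with their L1-normalized :class:`ConeWeights`.
    """
    y = np.asarray(luminosity_fn, dtype=float)
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.shape != fundamentals.wavelengths.shape or not np.allclose(
            wl, fundamentals.wavelengths
        ):
            raise ValueError("luminosity and fundamentals must share one grid")
    X = fundamentals.sensitivities.T  # (n_wl, 3)
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError("cone fundamentals are collinear")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef, ConeWeights.from_vector(coef)


# ---------------------------------------------------------------------------
# curve I/O and synthetic spectra


def load_curve(
    path: str | Path, wavelengths: np.ndarray = DEFAULT_WAVELENGTHS
) -> np.ndarray:
    """Read a two-column CSV (wavelength_nm, value) and resample linearly."""
    arr = np.loadtxt(path, delimiter=",", comments="#")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return np.interp(wavelengths, arr[:, 0], arr[:, 1], left=0.0, right=0.0)


def _gaussian(wl: np.ndarray, peak: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - peak) / sd) ** 2)


def gaussian_phosphor_display(
    background_rgb=(0.5, 0.5, 0.5),
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
) -> DisplayModel:
    """Self-contained stand-in display: Gaussian R/G/B phosphor bumps.

    Peaks at 610/530/465 nm with 30-nm SD, a generic CRT-like gamut.
    """
    spectra = np.stack(
        [_gaussian(wavelengths, p, 30.0) for p in (610.0, 530.0, 465.0)]
    )
    return DisplayModel(
        wavelengths=wavelengths,
        phosphor_spectra=spectra,
        background_rgb=np.asarray(background_rgb, dtype=float),
    )


def gaussian_cone_fundamentals(
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
) -> ConeFundamentals:
    """Smooth synthetic L/M/S fundamentals (peaks 565/535/440 nm).

    A stand-in for measured human cone fundamentals; peak positions and
    widths are in the physiological ballpark but these are not colorimetric
    data.
    """
    params = ((565.0, 50.0), (535.0, 45.0), (440.0, 30.0))
    s = np.stack([_gaussian(wavelengths, p, sd) for p, sd in params])
    return ConeFundamentals(wavelengths=wavelengths, sensitivities=s)
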