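"""White-noise and edge stimuli on the model display.

Phase 1 uses pixelwise truncated-Gaussian white noise on a small grid;
Phase 2 yokes the pixels of each receptive-field subfield into a
"hyperpixel" so the whole subfield modulates as a unit; Phase 3 presents
static edge images formed by linearly combining the two unit-normalized
halves of the hyperpixel STA around the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .display import DisplayModel

__all__ = [
    "StimulusMovie",
    "HyperpixelMap",
    "StimulusPlanePoint",
    "truncated_noise_sd",
    "pixel_white_noise",
    "hyperpixel_white_noise",
    "edge_stimulus",
    "project_stimulus",
    "DEFAULT_FRAME_DURATION",
    "DEFAULT_SD_FRACTION",
]

#: 75-Hz frame rate
DEFAULT_FRAME_DURATION = 1.0 / 75.0
#: noise SD as a fraction of the achievable intensity range
DEFAULT_SD_FRACTION = 0.15
#: temporal depth (frames) of all spike-triggered analyses
N_LAGS = 15


@dataclass(frozen=True)
class StimulusMovie:
    """frames x n_pixels x 3 phosphor-intensity movie in [0, 1].

    ``grid`` is (rows, cols); pixels are stored row-major.  ``pixel_size_deg``
    records the angular subtense of one pixel.
    """

    data: np.ndarray
    grid: tuple[int, int] = (10, 10)
    frame_duration: float = DEFAULT_FRAME_DURATION
    pixel_size_deg: float = 0.2

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        rows, cols = self.grid
        if d.ndim != 3 or d.shape[1] != rows * cols or d.shape[2] != 3:
            raise ValueError(
                f"expected (frames, {rows * cols}, 3) data, got {d.shape}"
            )
        object.__setattr__(self, "data", d)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class HyperpixelMap:
    """Two disjoint, non-empty pixel-index sets, one per RF subfield."""

    subfield1: tuple[int, ...]
    subfield2: tuple[int, ...]

    def __post_init__(self) -> None:
        s1 = tuple(sorted(int(i) for i in self.subfield1))
        s2 = tuple(sorted(int(i) for i in self.subfield2))
        if not s1 or not s2:
            raise ValueError("both subfields must be non-empty")
        if set(s1) & set(s2):
            raise ValueError("subfields overlap")
        object.__setattr__(self, "subfield1", s1)
        object.__setattr__(self, "subfield2", s2)

    @property
    def subfields(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        return (self.subfield1, self.subfield2)


@dataclass(frozen=True)
class StimulusPlanePoint:
    """Coordinates in the neuron-specific stimulus plane.

    ``x`` is the projection of a background-subtracted image onto the unit
    image of subfield 1, ``y`` onto subfield 2 (dimensionless contrast).
    """

    x: float
    y: float

    @property
    def r(self) -> float:
        return float(np.hypot(self.x, self.y))

    @property
    def theta(self) -> float:
        return float(np.arctan2(self.y, self.x))


def truncated_noise_sd(
    background: float, sd_fraction: float = DEFAULT_SD_FRACTION
) -> float:
    """SD actually realized by a Gaussian truncated to [0, 1].

    The sampler draws from N(background, sd_fraction) and rejects values
    outside the achievable range, which shrinks the SD slightly (negligibly
    for a mid-gray background).  Significance tests use this value.
    """
    sd = sd_fraction  # range is [0, 1], so SD = sd_fraction * range
    a = (0.0 - background) / sd
    b = (1.0 - background) / sd
    return float(stats.truncnorm.std(a, b, loc=background, scale=sd))


def _draw_truncated(
    rng: np.random.Generator, background: np.ndarray, sd: float, shape: tuple
) -> np.ndarray:
    """Rejection-sample N(background, sd) truncated to [0, 1]."""
    out = rng.normal(background, sd, size=shape)
    bad = (out < 0.0) | (out > 1.0)
    # resample out-of-gamut draws until all are inside; keeps the density a
    # renormalized Gaussian rather than piling mass at the bounds
    while np.any(bad):
        idx = np.nonzero(bad)
        out[idx] = rng.normal(np.broadcast_to(background, shape)[idx], sd)
        bad = (out < 0.0) | (out > 1.0)
    return out


def pixel_white_noise(
    n_frames: int,
    display: DisplayModel,
    sd_fraction: float = DEFAULT_SD_FRACTION,
    seed: int = 0,
    grid: tuple[int, int] = (10, 10),
    frame_duration: float = DEFAULT_FRAME_DURATION,
) -> StimulusMovie:
    """Pixelwise truncated-Gaussian white noise around the background.

    Every pixel/phosphor/frame is an independent draw with mean equal to the
    background intensity and SD ``sd_fraction`` of the [0, 1] range,
    truncated to the gamut by rejection.
    """
    if not 0.0 < sd_fraction < 0.5:
        raise ValueError("sd_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n_pix = grid[0] * grid[1]
    bg = np.broadcast_to(display.background_rgb, (n_frames, n_pix, 3))
    data = _draw_truncated(rng, bg, sd_fraction, (n_frames, n_pix, 3))
    return StimulusMovie(
        data=data, grid=grid, frame_duration=frame_duration
    )


def hyperpixel_white_noise(
    n_frames: int,
    display: DisplayModel,
    hmap: HyperpixelMap,
    sd_fraction: float = DEFAULT_SD_FRACTION,
    seed: int = 0,
    grid: tuple[int, int] = (10, 10),
    frame_duration: float = DEFAULT_FRAME_DURATION,
) -> StimulusMovie:
    """White noise yoked within each of two hyperpixels.

    Member pixels of a hyperpixel share a single RGB draw per frame (same
    truncated-Gaussian marginals as Phase 1); the two hyperpixels modulate
    independently and all other pixels stay at the background.
    """
    if not 0.0 < sd_fraction < 0.5:
        raise ValueError("sd_fraction must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n_pix = grid[0] * grid[1]
    bg3 = np.asarray(display.background_rgb, dtype=float)
    data = np.tile(bg3, (n_frames, n_pix, 1))
    # one RGB stream per hyperpixel, broadcast to every member pixel
    bg = np.broadcast_to(bg3, (n_frames, 2, 3))
    draws = _draw_truncated(rng, bg, sd_fraction, (n_frames, 2, 3))
    for k, pixels in enumerate(hmap.subfields):
        data[:, list(pixels), :] = draws[:, k : k + 1, :]
    return StimulusMovie(data=data, grid=grid, frame_duration=frame_duration)


def save_movie(movie: StimulusMovie, path) -> None:
    """Write a movie as <path>.npy with a JSON sidecar <path>.json."""
    import json
    from pathlib import Path

    base = Path(path)
    np.save(base.with_suffix(".npy"), movie.data)
    base.with_suffix(".json").write_text(
        json.dumps(
            {
                "grid": list(movie.grid),
                "frame_duration": movie.frame_duration,
                "pixel_size_deg": movie.pixel_size_deg,
            }
        )
    )


def load_movie(path) -> StimulusMovie:
    """Inverse of :func:`save_movie`."""
    import json
    from pathlib import Path

    base = Path(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    return StimulusMovie(
        data=np.load(base.with_suffix(".npy")),
        grid=tuple(meta["grid"]),
        frame_duration=meta["frame_duration"],
        pixel_size_deg=meta["pixel_size_deg"],
    )


def hyperpixel_values(movie: StimulusMovie, hmap: HyperpixelMap) -> np.ndarray:
    """(frames, 2, 3) per-hyperpixel RGB streams (mean over member pixels)."""
    out = np.empty((movie.n_frames, 2, 3))
    for k, pixels in enumerate(hmap.subfields):
        out[:, k, :] = movie.data[:, list(pixels), :].mean(axis=1)
    return out


def edge_stimulus(
    sta_halves: tuple[np.ndarray, np.ndarray],
    x: float,
    y: float,
    display: DisplayModel,
) -> tuple[np.ndarray, bool]:
    """Static image ``background + x*u1 + y*u2`` from two unit images.

    ``sta_halves`` are (n_pixels, 3) images with unit Euclidean norm and
    (for a well-formed map) disjoint spatial support.  Returns the image and
    an in-gamut flag; out-of-gamut images are flagged, not rejected.
    """
    u1, u2 = (np.asarray(u, dtype=float) for u in sta_halves)
    for u in (u1, u2):
        if not np.isclose(np.linalg.norm(u), 1.0, atol=1e-8):
            raise ValueError("sta halves must have unit Euclidean norm")
    image = display.background_rgb[None, :] + x * u1 + y * u2
    return image, display.in_gamut(image)


def project_stimulus(
    image: np.ndarray,
    sta_halves: tuple[np.ndarray, np.ndarray],
    display: DisplayModel,
) -> StimulusPlanePoint:
    """Background-subtract an image and project it onto the two unit images."""
    image = np.asarray(image, dtype=float)
    u1, u2 = (np.asarray(u, dtype=float) for u in sta_halves)
    if image.shape != u1.shape or image.shape != u2.shape:
        raise ValueError("image and sta halves must share one pixel grid")
    delta = image - display.background_rgb[None, :]
    return StimulusPlanePoint(x=float(np.sum(delta * u1)), y=float(np.sum(delta * u2)))
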