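"""Parametric model neurons with known ground truth.

Each neuron is a cascade: one spatio-temporo-chromatic linear filter per
receptive-field subfield, a pointwise subunit nonlinearity, a signed sum
across subunits, and a logistic output stage.  The same neuron answers both
open-loop queries (white-noise movie -> per-frame Bernoulli spikes, one
13.33-ms bin per frame) and closed-loop queries (static image -> Poisson
spike count over a trial), standing in for a recorded cell.

Filter convention: ``filters[i]`` has shape (15, n_pixels, 3) and applies to
the 15-frame stimulus segment ending at the current frame, oldest frame
first (index 14 = the spike-coincident frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .display import (
    ConeWeights,
    DisplayModel,
    ConeFundamentals,
    gaussian_cone_fundamentals,
    gaussian_phosphor_display,
    phosphor_vector_from_cone_weights,
)
from .stimulus import HyperpixelMap, StimulusMovie

__all__ = [
    "ModelNeuron",
    "make_neuron",
    "simulate_white_noise",
    "simulate_trial",
    "analytic_isoresponse",
    "default_hyperpixel_map",
    "PRESETS",
]

N_LAGS = 15

PRESETS = ("simple_linear", "do_linear", "rectified_subunit", "energy")


def default_hyperpixel_map(grid: tuple[int, int] = (10, 10)) -> HyperpixelMap:
    """Two adjacent 2x3-pixel subfields near the grid center."""
    rows, cols = grid
    r0 = rows // 2 - 1
    c0 = cols // 2 - 3
    sf1 = [r * cols + c for r in (r0, r0 + 1) for c in range(c0, c0 + 3)]
    sf2 = [r * cols + c for r in (r0, r0 + 1) for c in range(c0 + 3, c0 + 6)]
    return HyperpixelMap(subfield1=tuple(sf1), subfield2=tuple(sf2))


def biphasic_temporal_kernel(n_lags: int = N_LAGS) -> np.ndarray:
    """Unit-norm biphasic impulse response, peak 3 frames before the spike.

    Returned oldest-first (index ``n_lags - 1`` is the spike-coincident
    frame), matching the segment convention.
    """
    lag = np.arange(n_lags)[::-1]  # frames before the spike, oldest-first
    h = np.exp(-0.5 * ((lag - 3.0) / 1.5) ** 2) - 0.55 * np.exp(
        -0.5 * ((lag - 7.0) / 2.5) ** 2
    )
    return h / np.linalg.norm(h)


def _subunit_nl(name: str, params: dict):
    if name == "identity":
        return lambda s: s
    if name == "half_rectified":
        gp, gn = params.get("gain_pos", 1.0), params.get("gain_neg", 1.0)
        return lambda s: np.where(s > 0, gp * s, gn * s)
    if name == "squaring":
        return lambda s: np.square(s)
    raise ValueError(f"unknown subunit nonlinearity {name!r}")


@dataclass(frozen=True)
class ModelNeuron:
    """Ground-truth LN-cascade neuron over a pixel grid.

    ``r_max`` (spikes/s) scales the trial-rate logistic; ``baseline_rate``
    (spikes/s) adds stimulus-independent Poisson drive on trials.
    ``trial_gain`` converts the static-image drive through the peak filter
    slice into the logistic argument (temporal integration reduced to a
    scalar, since Phase-3 stimuli are static).
    """

    filters: np.ndarray  # (n_subunits, 15, n_pixels, 3)
    subunit_nonlinearity: str = "identity"
    nl_params: dict = field(default_factory=dict)
    combination_signs: tuple[float, ...] = (1.0, 1.0)
    c: float = -2.0
    r_max: float = 100.0
    baseline_rate: float = 10.0
    trial_gain: float = 1.0
    grid: tuple[int, int] = (10, 10)
    hmap: HyperpixelMap | None = None
    background_rgb: np.ndarray = field(
        default_factory=lambda: np.array([0.5, 0.5, 0.5])
    )
    preset: str = "custom"

    def __post_init__(self) -> None:
        f = np.asarray(self.filters, dtype=float)
        if f.ndim != 4 or f.shape[1] != N_LAGS or f.shape[3] != 3:
            raise ValueError(f"filters must be (n_sub, {N_LAGS}, n_pix, 3); got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise ValueError("filters must be finite")
        if self.r_max < 0:
            raise ValueError("r_max must be non-negative")
        object.__setattr__(self, "filters", f)

    # ----- drives -------------------------------------------------------

    @property
    def n_subunits(self) -> int:
        return self.filters.shape[0]

    @property
    def peak_lag_index(self) -> int:
        """Segment index of the temporally dominant filter slice."""
        power = np.sum(self.filters**2, axis=(0, 2, 3))
        return int(np.argmax(power))

    @property
    def peak_latency(self) -> int:
        """Frames between the dominant stimulus slice and the spike bin."""
        return N_LAGS - 1 - self.peak_lag_index

    def segment_drives(self, movie: StimulusMovie) -> np.ndarray:
        """(n_valid_frames, n_subunits) linear drives S_i for frames >= 14."""
        n = movie.n_frames
        if n < N_LAGS:
            raise ValueError("movie must have at least 15 frames")
        delta = (movie.data - self.background_rgb).reshape(n, -1)
        fmat = self.filters.reshape(self.n_subunits, N_LAGS, -1)
        out = np.zeros((n - N_LAGS + 1, self.n_subunits))
        for k in range(N_LAGS):
            out += delta[k : n - N_LAGS + 1 + k] @ fmat[:, k, :].T
        return out

    def combine(self, drives: np.ndarray) -> np.ndarray:
        """Signed sum of nonlinearly transformed subunit drives."""
        nl = _subunit_nl(self.subunit_nonlinearity, self.nl_params)
        return np.asarray(nl(drives)) @ np.asarray(self.combination_signs)

    def spike_prob(self, g: np.ndarray) -> np.ndarray:
        return expit(g + self.c)

    def image_drive(self, image: np.ndarray) -> float:
        """Logistic argument for a static image via the peak filter slice."""
        delta = np.asarray(image, dtype=float) - self.background_rgb
        k = self.peak_lag_index
        s = self.trial_gain * np.tensordot(
            self.filters[:, k, :, :], delta, axes=([1, 2], [0, 1])
        )
        return float(self.combine(s))

    def trial_rate(self, image: np.ndarray) -> float:
        """Expected firing rate (spikes/s) during a static-image trial."""
        g = self.image_drive(image)
        return float(self.r_max * expit(g + self.c) + self.baseline_rate)

    def true_halves(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-norm peak-slice images of the two subunit filters."""
        k = self.peak_lag_index
        halves = []
        for i in range(2):
            u = self.filters[i, k, :, :].copy()
            halves.append(u / np.linalg.norm(u))
        return halves[0], halves[1]

    # ----- serialization ------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "preset": self.preset,
            "filters": self.filters.tolist(),
            "subunit_nonlinearity": self.subunit_nonlinearity,
            "nl_params": self.nl_params,
            "combination_signs": list(self.combination_signs),
            "c": self.c,
            "r_max": self.r_max,
            "baseline_rate": self.baseline_rate,
            "trial_gain": self.trial_gain,
            "grid": list(self.grid),
            "hmap": [list(self.hmap.subfield1), list(self.hmap.subfield2)]
            if self.hmap
            else None,
            "background_rgb": self.background_rgb.tolist(),
        }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ModelNeuron":
        text = str(text_or_path)
        if len(text) < 4096:  # plausible filesystem path
            try:
                p = Path(text)
                if p.is_file():
                    text = p.read_text()
            except OSError:
                pass
        obj = json.loads(text)
        hmap = (
            HyperpixelMap(tuple(obj["hmap"][0]), tuple(obj["hmap"][1]))
            if obj.get("hmap")
            else None
        )
        return cls(
            filters=np.asarray(obj["filters"]),
            subunit_nonlinearity=obj["subunit_nonlinearity"],
            nl_params=obj["nl_params"],
            combination_signs=tuple(obj["combination_signs"]),
            c=obj["c"],
            r_max=obj["r_max"],
            baseline_rate=obj["baseline_rate"],
            trial_gain=obj["trial_gain"],
            grid=tuple(obj["grid"]),
            hmap=hmap,
            background_rgb=np.asarray(obj["background_rgb"]),
            preset=obj.get("preset", "custom"),
        )


def _build_filters(
    color1: np.ndarray,
    color2: np.ndarray,
    hmap: HyperpixelMap,
    grid: tuple[int, int],
    gain: float,
) -> np.ndarray:
    """Separable filters gain * temporal x spatial x color per subfield."""
    n_pix = grid[0] * grid[1]
    tk = biphasic_temporal_kernel()
    filters = np.zeros((2, N_LAGS, n_pix, 3))
    for i, (pixels, col) in enumerate(zip(hmap.subfields, (color1, color2))):
        sp = np.zeros(n_pix)
        sp[list(pixels)] = 1.0 / np.sqrt(len(pixels))
        filters[i] = gain * tk[:, None, None] * sp[None, :, None] * col[None, None, :]
    return filters


def make_neuron(
    preset: str,
    params: dict | None = None,
    seed: int = 0,
    display: DisplayModel | None = None,
    fundamentals: ConeFundamentals | None = None,
) -> ModelNeuron:
    """Construct a preset neuron.

    Presets
    -------
    simple_linear
        Cone non-opponent (achromatic) color vector; spatially opposite
        ON/OFF subfields; identity subunits.
    do_linear
        Cone-opponent color vector (default built from cone weights
        (0.5, -0.5, 0)); spatially opposite subfields; identity subunits.
    rectified_subunit
        do_linear filters with asymmetric half-rectification of each
        subunit drive (default 4:1 positive:negative gain).
    energy
        do_linear filters with squaring subunits (full-wave rectified,
        complex-cell-like).

    ``params`` may override: grid, gain, c, r_max, baseline_rate,
    trial_gain, cone_weights, gain_pos, gain_neg, hmap.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    params = dict(params or {})
    display = display or gaussian_phosphor_display()
    fundamentals = fundamentals or gaussian_cone_fundamentals()
    grid = tuple(params.pop("grid", (10, 10)))
    hmap = params.pop("hmap", None) or default_hyperpixel_map(grid)

    # color vector defined by target cone weights: non-opponent (luminance-
    # like) for the simple cell, L-M opponent otherwise
    default_cw = (0.5, 0.45, 0.05) if preset == "simple_linear" else (0.5, -0.5, 0.0)
    cw = ConeWeights.from_vector(params.pop("cone_weights", default_cw))
    v = phosphor_vector_from_cone_weights(cw, display, fundamentals)
    color1 = v / np.linalg.norm(v)
    color2 = -color1  # spatially opposite subfield prefers the inverse color

    gain = float(params.pop("gain", 2.0 if preset == "energy" else 6.0))
    filters = _build_filters(color1, color2, hmap, grid, gain)

    nl = "identity"
    nl_params: dict = {}
    if preset == "rectified_subunit":
        nl = "half_rectified"
        nl_params = {
            "gain_pos": float(params.pop("gain_pos", 1.0)),
            "gain_neg": float(params.pop("gain_neg", 0.25)),
        }
    elif preset == "energy":
        nl = "squaring"

    defaults = {"c": -3.0 if preset == "energy" else -2.5, "r_max": 100.0,
                "baseline_rate": 10.0, "trial_gain": 2.0}
    defaults.update(params)
    return ModelNeuron(
        filters=filters,
        subunit_nonlinearity=nl,
        nl_params=nl_params,
        combination_signs=(1.0, 1.0),
        grid=grid,
        hmap=hmap,
        background_rgb=np.asarray(display.background_rgb, dtype=float),
        preset=preset,
        **defaults,
    )


def simulate_white_noise(
    neuron: ModelNeuron, movie: StimulusMovie, seed: int = 0
) -> np.ndarray:
    """Per-frame spike counts (0/1) under the Bernoulli-per-frame model.

    Frame ``t >= 14`` spikes with probability ``logistic(g_t + c)`` where
    ``g_t`` is the drive of the segment [t-14, t]; earlier frames never spike.
    """
    rng = np.random.default_rng(seed)
    g = neuron.combine(neuron.segment_drives(movie))
    p = neuron.spike_prob(g)
    spikes = np.zeros(movie.n_frames, dtype=np.int64)
    spikes[N_LAGS - 1 :] = rng.random(p.size) < p
    return spikes


def simulate_trial(
    neuron: ModelNeuron,
    image: np.ndarray,
    duration_s: float = 0.3,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> int:
    """Poisson spike count for one static-image trial."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    return int(rng.poisson(neuron.trial_rate(image) * duration_s))


def analytic_isoresponse(
    neuron: ModelNeuron,
    theta: float,
    target_rate: float,
    halves: tuple[np.ndarray, np.ndarray] | None = None,
    gamut_limit: float = np.inf,
) -> tuple[float | None, bool]:
    """Ground-truth isoresponse radius along direction ``theta``.

    Finds the smallest r >= 0 with expected trial rate equal to
    ``target_rate`` for the stimulus ``background + r(cos(theta) u1 +
    sin(theta) u2)``.  Returns ``(radius, warn)``; radius is None when the
    target is unreachable within ``gamut_limit`` and ``warn`` flags a
    non-monotone drive (smallest root reported).
    """
    if target_rate <= neuron.baseline_rate:
        raise ValueError("target_rate must exceed the baseline rate")
    u1, u2 = halves if halves is not None else neuron.true_halves()
    direction = np.cos(theta) * u1 + np.sin(theta) * u2
    k = neuron.peak_lag_index
    # per-subunit drive coefficient: s_i(r) = b_i * r
    b = neuron.trial_gain * np.tensordot(
        neuron.filters[:, k, :, :], direction, axes=([1, 2], [0, 1])
    )

    def g_of_r(r: float) -> float:
        return float(neuron.combine(b * r))

    frac = (target_rate - neuron.baseline_rate) / neuron.r_max
    if not 0.0 < frac < 1.0:
        return None, False
    g_target = float(logit(frac)) - neuron.c

    r_hi = gamut_limit if np.isfinite(gamut_limit) else 1e3
    grid = np.linspace(0.0, r_hi, 512)
    vals = np.array([g_of_r(r) - g_target for r in grid])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if vals[0] == 0.0:
        return 0.0, False
    if sign_changes.size == 0:
        return None, False
    i = sign_changes[0]
    root = brentq(lambda r: g_of_r(r) - g_target, grid[i], grid[i + 1])
    warn = sign_changes.size > 1  # drive re-crosses the target further out
    return float(root), warn
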