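"""Receptive-field estimation from white-noise responses.

Phase 1: spike-triggered average over the 15 frames preceding each spike,
a chi-square test selecting the peak frame, and per-phosphor pixel z-tests
whose significant pixels are grouped into two hyperpixels (RF subfields).
Phase 2: the hyperpixel STA, an energy-weighted average of the peak frame
and its flanks, SVD separation into color and spatial weighting functions,
and a permutation test on the first principal component of the
spike-triggering ensemble orthogonal to the STA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, stats

from .display import DisplayModel
from .stimulus import HyperpixelMap, StimulusMovie, hyperpixel_values, truncated_noise_sd

__all__ = [
    "STA",
    "HyperpixelSTA",
    "RFDecomposition",
    "PC1Result",
    "EmptySTAError",
    "InsufficientSubfieldsError",
    "compute_sta",
    "compute_hyperpixel_sta",
    "select_peak_frame",
    "yoke_hyperpixels",
    "weighted_sta_decompose",
    "pc1_test",
]

N_LAGS = 15


class EmptySTAError(ValueError):
    """No usable spikes (at frame index >= 14)."""


class InsufficientSubfieldsError(ValueError):
    """Fewer than two chromatically distinct significant subfields.

    Mirrors the screening rule: such a neuron is passed over.
    """


@dataclass(frozen=True)
class STA:
    """Spike-triggered average: 15 x n_pixels x 3, oldest frame first.

    Entries are mean background-subtracted phosphor intensities of the
    spike-triggering segments.  ``stimulus_sd`` holds the per-channel SD of
    the (truncated-Gaussian) noise, used by the significance tests.
    """

    frames: np.ndarray
    n_spikes: int
    stimulus_sd: np.ndarray
    grid: tuple[int, int] = (10, 10)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] != N_LAGS or f.shape[2] != 3:
            raise ValueError(f"expected ({N_LAGS}, n_pix, 3) frames, got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise ValueError("STA entries must be finite")
        object.__setattr__(self, "frames", f)
        object.__setattr__(
            self, "stimulus_sd", np.broadcast_to(np.asarray(self.stimulus_sd, float), (3,)).copy()
        )


@dataclass(frozen=True)
class HyperpixelSTA:
    """15-frame x 2-subfield x 3-color STA plus the map that produced it."""

    frames: np.ndarray  # (15, 2, 3), oldest first
    hmap: HyperpixelMap
    n_spikes: int
    stimulus_sd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.shape != (N_LAGS, 2, 3):
            raise ValueError(f"expected ({N_LAGS}, 2, 3) frames, got {f.shape}")
        object.__setattr__(self, "frames", f)
        object.__setattr__(
            self, "stimulus_sd", np.broadcast_to(np.asarray(self.stimulus_sd, float), (3,)).copy()
        )

    @property
    def peak_frame(self) -> int:
        return int(np.argmax(np.sum(self.frames**2, axis=(1, 2))))

    @property
    def peak_latency(self) -> int:
        """Frames between the dominant stimulus slice and the spike bin."""
        return N_LAGS - 1 - self.peak_frame

    def halves(self, normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Peak-frame RGB triplets of the two subfields (optionally unit norm)."""
        out = []
        for h in range(2):
            v = self.frames[self.peak_frame, h, :].copy()
            if normalize:
                n = np.linalg.norm(v)
                if n == 0:
                    raise ValueError("degenerate (all-zero) STA half")
                v = v / n
            out.append(v)
        return out[0], out[1]


@dataclass(frozen=True)
class RFDecomposition:
    """Rank-1 color x space separation of the weighted STA."""

    color_weighting: np.ndarray  # (3,), unit norm
    spatial_weighting: np.ndarray  # (2,), unit norm
    singular_value: float
    variance_explained: float


@dataclass(frozen=True)
class PC1Result:
    eigenvalue: float
    null_eigenvalues: np.ndarray
    significant: bool
    p_value: float


def _chromatic_components(
    sig: np.ndarray, peak_frame: np.ndarray, grid: tuple[int, int]
) -> list[np.ndarray]:
    """Connected components of significant pixels, split at color reversals.

    Two significant pixels belong to the same component when they are
    8-adjacent and their peak-frame RGB vectors point to the same side
    (positive cosine).  Returns flat pixel-index arrays.
    """
    rows, cols = grid
    idx = np.nonzero(sig)[0]
    pos = {int(p): i for i, p in enumerate(idx)}
    parent = list(range(idx.size))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for p in idx:
        r, c = divmod(int(p), cols)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                q = rr * cols + cc
                if q in pos and float(peak_frame[p] @ peak_frame[q]) > 0:
                    union(pos[int(p)], pos[q])

    groups: dict[int, list[int]] = {}
    for i, p in enumerate(idx):
        groups.setdefault(find(i), []).append(int(p))
    return [np.array(sorted(g)) for g in groups.values()]


def _weighted_segment_mean(
    delta: np.ndarray, spikes: np.ndarray
) -> tuple[np.ndarray, int]:
    """Mean 15-frame segment preceding spikes, weighted by spike count.

    ``delta`` is (n_frames, ...) background-subtracted stimulus; spikes is a
    per-frame count vector.  Returns (15, ...) mean and the spike total.
    """
    n = delta.shape[0]
    w = np.asarray(spikes, dtype=float)[N_LAGS - 1 : n]
    total = w.sum()
    if total <= 0:
        raise EmptySTAError("no spikes at frame index >= 14")
    m = n - N_LAGS + 1
    flat = delta.reshape(n, -1)
    out = np.empty((N_LAGS, flat.shape[1]))
    for k in range(N_LAGS):
        out[k] = w @ flat[k : k + m] / total
    return out.reshape((N_LAGS,) + delta.shape[1:]), int(round(total))


def compute_sta(
    movie: StimulusMovie,
    spikes: np.ndarray,
    display: DisplayModel,
    sd_fraction: float = 0.15,
) -> STA:
    """Average the 15 stimulus frames preceding each spike.

    Frame ``k`` of the STA is the spike-count-weighted mean of the stimulus
    at segment position ``k`` (k = 14 is the spike-coincident frame), minus
    the background.
    """
    delta = movie.data - display.background_rgb
    frames, n_spk = _weighted_segment_mean(delta, spikes)
    sd = np.array(
        [truncated_noise_sd(b, sd_fraction) for b in display.background_rgb]
    )
    return STA(frames=frames, n_spikes=n_spk, stimulus_sd=sd, grid=movie.grid)


def compute_hyperpixel_sta(
    movie: StimulusMovie,
    spikes: np.ndarray,
    hmap: HyperpixelMap,
    display: DisplayModel,
    sd_fraction: float = 0.15,
) -> HyperpixelSTA:
    """STA of the two hyperpixel RGB streams (15 x 2 x 3)."""
    hp = hyperpixel_values(movie, hmap) - display.background_rgb
    frames, n_spk = _weighted_segment_mean(hp, spikes)
    sd = np.array(
        [truncated_noise_sd(b, sd_fraction) for b in display.background_rgb]
    )
    return HyperpixelSTA(frames=frames, hmap=hmap, n_spikes=n_spk, stimulus_sd=sd)


def peak_frame_statistics(sta: STA | HyperpixelSTA) -> np.ndarray:
    """Per-frame chi-square statistics ``n_spikes * sum_e (sta[f,e]/sd_e)^2``.

    Under the no-tuning null each STA element is Gaussian with variance
    ``sd_e^2 / n_spikes``, so the statistic is chi-square with one degree of
    freedom per element.
    """
    z2 = (sta.frames / sta.stimulus_sd) ** 2  # broadcast over color axis
    return sta.n_spikes * z2.reshape(N_LAGS, -1).sum(axis=1)


def select_peak_frame(
    sta: STA | HyperpixelSTA, alpha: float = 1e-4
) -> tuple[int, bool]:
    """Frame differing most from background, with a chi-square check.

    Returns (peak index, significant flag); the flag reports whether the
    peak frame's statistic exceeds the upper-alpha chi-square quantile with
    one degree of freedom per frame element.
    """
    stat = peak_frame_statistics(sta)
    peak = int(np.argmax(stat))
    df = sta.frames[0].size
    significant = bool(stat[peak] > stats.chi2.ppf(1.0 - alpha, df))
    return peak, significant


def yoke_hyperpixels(
    sta: STA,
    peak: int,
    alpha_pixel: float = 0.05,
    color_cos_threshold: float = 0.9,
) -> HyperpixelMap:
    """Group significant peak-frame pixels into two RF subfields.

    A pixel is significant when any phosphor's two-sided z-test rejects at
    ``alpha_pixel`` (z = STA * sqrt(n_spikes) / stimulus_sd; noise SD known,
    no multiplicity correction).  Significant pixels are grouped into
    components that are 8-connected *and* chromatically coherent (adjacent
    pixels join a component only when their peak-frame RGB vectors have
    positive cosine), since abutting subfields of opposite chromatic sign
    would otherwise fuse into one blob.  The largest component and the
    next-largest one whose mean peak-frame RGB has cosine similarity below
    ``color_cos_threshold`` with it become the two hyperpixels.
    """
    rows, cols = sta.grid
    z = sta.frames[peak] * np.sqrt(sta.n_spikes) / sta.stimulus_sd  # (n_pix, 3)
    z_crit = stats.norm.ppf(1.0 - alpha_pixel / 2.0)
    sig = (np.abs(z) > z_crit).any(axis=1)

    comps = _chromatic_components(sig, sta.frames[peak], (rows, cols))
    if len(comps) < 2:
        raise InsufficientSubfieldsError(
            f"found {len(comps)} significant subfield(s); need two with distinct color"
        )
    comps = sorted(comps, key=len, reverse=True)

    def mean_rgb(pixels: np.ndarray) -> np.ndarray:
        return sta.frames[peak, pixels, :].mean(axis=0)

    first = comps[0]
    v1 = mean_rgb(first)
    for other in comps[1:]:
        v2 = mean_rgb(other)
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        if float(v1 @ v2) / denom < color_cos_threshold:
            return HyperpixelMap(subfield1=tuple(first), subfield2=tuple(other))
    raise InsufficientSubfieldsError(
        "no second component with a distinct chromatic preference"
    )


def weighted_sta_decompose(hsta: HyperpixelSTA) -> RFDecomposition:
    """Energy-weighted peak frame, separated into color x space by SVD.

    The peak frame and its two flanking frames are averaged with weights
    proportional to each frame's sum of squared RGB intensities; the
    resulting 3 (color) x 2 (subfield) matrix is decomposed and the first
    singular pair returned.  Signs are fixed so the color vector's
    largest-magnitude entry is positive.
    """
    peak = hsta.peak_frame
    idx = [i for i in (peak - 1, peak, peak + 1) if 0 <= i < N_LAGS]
    energies = np.array([np.sum(hsta.frames[i] ** 2) for i in idx])
    if energies.sum() == 0:
        raise ValueError("degenerate all-zero weighted STA frame")
    w = energies / energies.sum()
    weighted = np.tensordot(w, hsta.frames[idx], axes=(0, 0))  # (2, 3)
    M = weighted.T  # color x subfield
    U, S, Vt = np.linalg.svd(M)
    color = U[:, 0]
    spatial = Vt[0]
    if color[np.argmax(np.abs(color))] < 0:
        color, spatial = -color, -spatial
    var = float(S[0] ** 2 / np.sum(S**2))
    return RFDecomposition(
        color_weighting=color,
        spatial_weighting=spatial,
        singular_value=float(S[0]),
        variance_explained=var,
    )


def _segment_matrix(movie: StimulusMovie, hmap: HyperpixelMap, background) -> np.ndarray:
    """(n_valid, 90) matrix of vectorized 15-frame hyperpixel segments."""
    hp = hyperpixel_values(movie, hmap) - background  # (n, 2, 3)
    flat = hp.reshape(hp.shape[0], 6)
    segs = sliding_window_view(flat, N_LAGS, axis=0)  # (n_valid, 6, 15)
    return np.ascontiguousarray(segs.transpose(0, 2, 1)).reshape(-1, N_LAGS * 6)


def _top_eig_orth_sta(gram: np.ndarray, mean: np.ndarray, n: int) -> float:
    """Largest covariance eigenvalue orthogonal to the STA direction.

    ``gram`` = X^T X over the n spike-triggering segments, ``mean`` their
    mean (the STA).  The covariance is projected onto the orthogonal
    complement of the unit STA before the eigendecomposition.
    """
    cov = gram / n - np.outer(mean, mean)
    norm = np.linalg.norm(mean)
    if norm > 0:
        u = mean / norm
        cu = cov @ u
        cov = cov - np.outer(u, cu) - np.outer(cu, u) + np.outer(u, u) * (u @ cu)
    d = cov.shape[0]
    # only the largest eigenvalue is needed
    from scipy.linalg import eigh as _eigh

    return float(_eigh(cov, eigvals_only=True, subset_by_index=(d - 1, d - 1))[0])


def pc1_test(
    movie: StimulusMovie,
    spikes: np.ndarray,
    hsta: HyperpixelSTA,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> PC1Result:
    """Permutation test on PC1 of spike-triggering segments orthogonal to the STA.

    The null distribution is obtained by circularly shifting the spike train
    relative to the stimulus (uniform shift of at least 15 frames), redoing
    the whole computation -- STA, orthogonal projection, covariance, top
    eigenvalue -- for each shift.  Significant when the observed eigenvalue
    exceeds the empirical (1 - alpha) quantile of the null.
    """
    spikes = np.asarray(spikes)
    if background is None:
        # noise movies average to the background by construction
        background = movie.data.mean(axis=(0, 1))
    segs = _segment_matrix(movie, hsta.hmap, np.asarray(background, dtype=float))
    m = segs.shape[0]
    w = spikes[N_LAGS - 1 :]
    idx = np.repeat(np.arange(m), w)  # count-weighted spike segment indices
    n_spk = idx.size
    if n_spk < 50:
        raise ValueError(f"need >= 50 spikes for the PC1 test, got {n_spk}")

    def eig_for(indices: np.ndarray) -> float:
        X = segs[indices]
        return _top_eig_orth_sta(X.T @ X, X.mean(axis=0), indices.size)

    observed = eig_for(idx)

    rng = np.random.default_rng(seed)
    if m <= 2 * N_LAGS:
        raise ValueError("movie too short for shifted null")
    shifts = rng.integers(N_LAGS, m - N_LAGS, size=n_perm)
    null = np.empty(n_perm)
    # batched gram computation in float32 (the eigensolve stays float64);
    # chunked to bound the gathered-array memory
    segs32 = segs.astype(np.float32)
    d = segs.shape[1]
    chunk = max(1, int(2.0e8 / (n_spk * d * 4)))
    for start in range(0, n_perm, chunk):
        sh = shifts[start : start + chunk]
        gathered = segs32[(idx[None, :] + sh[:, None]) % m]  # (chunk, n_spk, d)
        grams = np.einsum("cij,cik->cjk", gathered, gathered, optimize=True)
        means = gathered.mean(axis=1, dtype=np.float64)
        for j in range(sh.size):
            null[start + j] = _top_eig_orth_sta(
                grams[j].astype(np.float64), means[j], n_spk
            )

    threshold = float(np.quantile(null, 1.0 - alpha))
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PC1Result(
        eigenvalue=observed,
        null_eigenvalues=null,
        significant=bool(observed > threshold),
        p_value=float(p),
    )
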