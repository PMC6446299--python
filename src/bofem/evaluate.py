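"""Quantitative readouts: pick-vs-truth matching, ranked-peak drop-off,
Fourier ring correlation, power spectra / SSNR, and SNR conversions.

Frequencies are reported in 1/Angstrom; ring indices are single Fourier
pixels on the image's FFT grid, so ring r corresponds to
k = r / (L * pixel_size) for an L-pixel box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .flc_pick import PickSet
from .simulate import GroundTruth
from .transforms import apply_transform

logger = logging.getLogger("bofem")

__all__ = [
    "MatchResult",
    "FRCCurve",
    "match_picks",
    "dropoff_rank",
    "DropoffResult",
    "frc",
    "frc_half_crossing",
    "aligned_frc",
    "rotational_power_spectrum",
    "ring_counts",
    "ssnr",
    "single_particle_snr",
]


# ---------------------------------------------------------------------------
# Pick matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Outcome of greedy one-to-one pick/truth matching."""

    n_true: int
    n_picked: int
    true_positives: int
    false_positives: int
    false_negatives: int
    fp_fraction: float                  # percent of picks that are false
    centering_errors: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        assert self.true_positives + self.false_positives == self.n_picked
        assert self.true_positives + self.false_negatives == self.n_true


def match_picks(picks: PickSet, truth: GroundTruth, d_max: float) -> MatchResult:
    """Match picks to true centers greedily in descending rank order.

    A pick is a true positive if an as-yet-unmatched true center lies
    within ``d_max`` pixels (the closest one is consumed); otherwise it is
    a false positive.  Centering error is the matched distance.
    """
    if not d_max > 0:
        raise ValueError("d_max must be > 0")
    true_centers = np.asarray(truth.centers, dtype=np.float64).reshape(-1, 2)
    n_true = len(true_centers)
    taken = np.zeros(n_true, dtype=bool)
    errors = []
    tp = 0
    order = np.argsort(picks.rank)
    for i in order:
        p = np.array([picks.x[i], picks.y[i]])
        if n_true == 0:
            continue
        d = np.hypot(*(true_centers - p).T)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] <= d_max:
            taken[j] = True
            tp += 1
            errors.append(d[j])
    n_picked = len(picks)
    fp = n_picked - tp
    return MatchResult(
        n_true=n_true, n_picked=n_picked, true_positives=tp,
        false_positives=fp, false_negatives=n_true - tp,
        fp_fraction=100.0 * fp / n_picked if n_picked else 0.0,
        centering_errors=np.array(errors),
    )


# ---------------------------------------------------------------------------
# Ranked-peak drop-off
# ---------------------------------------------------------------------------

@dataclass
class DropoffResult:
    rank: int          # 1-based rank before the steepest drop
    drop: float
    confident: bool


def dropoff_rank(ranked_peaks: np.ndarray, smooth_window: int = 5,
                 details: bool = False) -> int | DropoffResult:
    """Rank position of the steepest single-step drop in the peak curve.

    The non-increasing peak sequence is smoothed with a moving median
    (window ``smooth_window``, edge-replicated) to suppress single-rank
    noise, then the argmax of p_r - p_{r+1} is returned (1-based).  A drop
    that does not dominate the remaining steps (e.g. a strictly linear
    sequence) is flagged low-confidence.
    """
    p = np.asarray(ranked_peaks, dtype=np.float64)
    if len(p) < 2:
        raise ValueError("need at least two ranked peaks")
    s = ndimage.median_filter(p, size=smooth_window, mode="nearest")
    drops = s[:-1] - s[1:]
    idx = int(np.argmax(drops))
    top = float(drops[idx])
    others = np.delete(drops, idx)
    scale = float(np.mean(np.abs(others))) if len(others) else 0.0
    confident = top > 3.0 * scale and top > 0
    if not confident:
        logger.info("dropoff_rank: no distinguished drop (max %.3g vs mean %.3g)",
                    top, scale)
    result = DropoffResult(rank=idx + 1, drop=top, confident=confident)
    return result if details else result.rank


# ---------------------------------------------------------------------------
# Fourier ring correlation
# ---------------------------------------------------------------------------

@dataclass
class FRCCurve:
    """Per-ring normalized correlation of two images' Fourier coefficients."""

    frequencies: np.ndarray  # 1/A, ring centers, rings 1..L//2
    values: np.ndarray       # in [-1, 1] up to float error
    counts: np.ndarray       # Fourier pixels per ring
    pixel_size: float

    @property
    def nyquist(self) -> float:
        return 0.5 / self.pixel_size


def _ring_index(n: int) -> np.ndarray:
    f = sfft.fftfreq(n) * n
    return np.rint(np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)).astype(np.int64)


def ring_counts(n: int) -> np.ndarray:
    """Fourier pixels per integer ring of an n x n image (rings 0..n//2)."""
    r = _ring_index(n)
    keep = r <= n // 2
    return np.bincount(r[keep], minlength=n // 2 + 1)


def _soft_circular_mask(n: int, radius_frac: float = 0.45,
                        edge_frac: float = 0.05) -> np.ndarray:
    c = (n - 1) / 2.0
    y, x = np.mgrid[0:n, 0:n]
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    r0, w = radius_frac * n, max(edge_frac * n, 1.0)
    m = np.clip((r - r0) / w, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * m))


def frc(img_a: np.ndarray, img_b: np.ndarray, ring_width: int = 1,
        pixel_size: float = 1.0, apply_mask: bool = True) -> FRCCurve:
    """Fourier ring correlation between two equally shaped images.

    Rings are ``ring_width`` Fourier pixels wide (default 1).  A soft
    circular mask (cosine edge, radius 0.45 x box) is applied first to
    suppress box-edge cross terms; switch off with ``apply_mask=False``.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"images must be square and same shape, got {a.shape} vs {b.shape}")
    n = a.shape[0]
    if apply_mask:
        m = _soft_circular_mask(n)
        a, b = a * m, b * m
    fa = sfft.fft2(a)
    fb = sfft.fft2(b)
    r = _ring_index(n) // ring_width
    n_rings = (n // 2) // ring_width
    keep = (r >= 0) & (r <= n_rings) & (_ring_index(n) <= n // 2)
    rk = r[keep]
    cross = np.bincount(rk, weights=(fa * np.conj(fb)).real[keep], minlength=n_rings + 1)
    pa = np.bincount(rk, weights=np.abs(fa[keep]) ** 2, minlength=n_rings + 1)
    pb = np.bincount(rk, weights=np.abs(fb[keep]) ** 2, minlength=n_rings + 1)
    counts = np.bincount(rk, minlength=n_rings + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = cross / np.sqrt(pa * pb)
    values = np.where((pa > 0) & (pb > 0), values, 0.0)
    freqs = np.arange(n_rings + 1) * ring_width / (n * pixel_size)
    # drop the DC ring; report rings 1..n//2
    return FRCCurve(frequencies=freqs[1:], values=values[1:], counts=counts[1:],
                    pixel_size=pixel_size)


def frc_half_crossing(curve: FRCCurve) -> float:
    """Lowest frequency where the FRC first falls below 0.5 (interpolated).

    Returns 0 if the curve never reaches 0.5, and the Nyquist frequency
    (logged) if it never drops below 0.5.
    """
    v = curve.values
    f = curve.frequencies
    if len(v) == 0:
        raise ValueError("empty FRC curve")
    if v[0] < 0.5:
        return 0.0
    below = np.nonzero(v < 0.5)[0]
    if len(below) == 0:
        logger.info("frc_half_crossing: curve never falls below 0.5; returning Nyquist")
        return float(curve.nyquist)
    i = int(below[0])
    f0, f1 = f[i - 1], f[i]
    v0, v1 = v[i - 1], v[i]
    return float(f0 + (0.5 - v0) * (f1 - f0) / (v1 - v0))


def aligned_frc(img: np.ndarray, ref: np.ndarray, pixel_size: float = 1.0,
                rot_step: float = 2.0, max_shift: int = 2) -> FRCCurve:
    """FRC after aligning ``img`` to ``ref`` over in-plane rotation/shift.

    Used to compare a class average (whose in-plane orientation is
    arbitrary) against a reference projection: the transform maximizing
    the masked inner product is applied to ``img`` before the FRC.
    """
    best, best_score = img, -np.inf
    m = _soft_circular_mask(img.shape[0])
    ref_m = ref * m
    for ang in np.arange(0.0, 360.0, rot_step):
        for tx in range(-max_shift, max_shift + 1):
            for ty in range(-max_shift, max_shift + 1):
                cand = apply_transform(np.asarray(img, dtype=np.float64), ang, tx, ty)
                score = float((cand * m * ref_m).sum())
                if score > best_score:
                    best_score, best = score, cand
    return frc(best, ref, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Power spectra and SNR
# ---------------------------------------------------------------------------

def rotational_power_spectrum(image: np.ndarray) -> np.ndarray:
    """Ring-averaged power spectrum |F|^2 / J, DC excluded (rings 1..n//2).

    With this normalization the per-ring means satisfy Parseval:
    sum_r profile[r] * ring_counts[r] = sum_j x_j^2 - J * mean(x)^2.
    """
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    power = np.abs(sfft.fft2(image)) ** 2 / image.size
    r = _ring_index(n)
    keep = r <= n // 2
    sums = np.bincount(r[keep], weights=power[keep], minlength=n // 2 + 1)
    counts = np.bincount(r[keep], minlength=n // 2 + 1)
    profile = sums / np.maximum(counts, 1)
    return profile[1:]


def ssnr(noisy: np.ndarray, noiseless: np.ndarray) -> np.ndarray:
    """Spectral SNR: per-ring power of the signal over that of the noise.

    Requires the simulation context where ``noisy = noiseless + noise``;
    the noise realization is recovered as the difference.  Rings with zero
    noise power come back as inf (logged).
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    noiseless = np.asarray(noiseless, dtype=np.float64)
    if noisy.shape != noiseless.shape:
        raise ValueError("micrographs must have the same shape")
    p_sig = rotational_power_spectrum(noiseless)
    p_noise = rotational_power_spectrum(noisy - noiseless)
    if np.any(p_noise == 0):
        logger.warning("ssnr: zero noise power in %d rings; SSNR is inf there",
                       int((p_noise == 0).sum()))
    with np.errstate(divide="ignore"):
        return p_sig / p_noise


def single_particle_snr(micrograph_snr: float, n_particles: int, box: int,
                        dims: tuple[int, int] | int) -> float:
    """Convert micrograph-level SNR to single-particle SNR.

    The micrograph variance dilutes the particle signal over the empty
    background, so the micrograph SNR is multiplied by the area ratio
    (micrograph area) / (n_particles * box^2), a factor > 1 whenever the
    particles do not tile the field.
    """
    if isinstance(dims, (int, np.integer)):
        area = int(dims) * int(dims)
    else:
        area = int(dims[0]) * int(dims[1])
    occupied = n_particles * box * box
    if occupied > area:
        raise ValueError("particles occupy more than the micrograph area")
    return micrograph_snr * area / occupied
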