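"""Template-matching particle picking by fast local correlation (FLC).

The locally normalized correlation between a search object S (template)
and a micrograph T under the footprint of a binary mask M is

    C_L(x) = (1 / (P * sigma_MT(x))) * sum_k S_k M_k T_{k+x}

with S normalized to zero mean and unit standard deviation under the mask,
P the number of nonzero mask points, and sigma_MT(x) the local standard
deviation of T within the mask footprint at position x,

    sigma_MT^2(x) = (1/P) sum_k M_k T_{k+x}^2 - [(1/P) sum_k M_k T_{k+x}]^2.

All three sliding sums are computed with FFT convolutions over every
position where the footprint fits entirely inside T ("valid" mode; no
padding).  Peaks of the map are extracted greedily in descending order
with euclidean exclusion, ranked, thresholded, and used to window particle
images out of the (unbinned) micrograph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal
from scipy.ndimage import maximum_filter

from .io_formats import CoordinateRecord
from .simulate import CTFParams, ctf_2d

logger = logging.getLogger("bofem")

__all__ = [
    "SearchObject",
    "LocalStats",
    "CorrelationMap",
    "PickSet",
    "ParticleStack",
    "make_disk_mask",
    "local_stats",
    "local_correlation_map",
    "find_peaks",
    "threshold_picks",
    "extract_particles",
    "phase_flip",
]


def make_disk_mask(box: int, diameter: float | None = None) -> np.ndarray:
    """Filled-disk footprint; default diameter 0.9 x box."""
    if diameter is None:
        diameter = 0.9 * box
    c = (box - 1) / 2.0
    y, x = np.mgrid[0:box, 0:box]
    return (((x - c) ** 2 + (y - c) ** 2) <= (diameter / 2.0) ** 2).astype(np.float64)


@dataclass
class SearchObject:
    """Normalized template S with binary mask M (P nonzero points)."""

    S: np.ndarray
    M: np.ndarray
    P: int

    @classmethod
    def from_template(cls, template: np.ndarray, mask: np.ndarray | None = None,
                      mask_diameter: float | None = None) -> "SearchObject":
        """Normalize a raw template to S-bar = 0, sigma_S = 1 under the mask."""
        template = np.asarray(template, dtype=np.float64)
        if mask is None:
            mask = make_disk_mask(template.shape[0], mask_diameter)
        mask = (np.asarray(mask) != 0).astype(np.float64)
        if mask.shape != template.shape:
            raise ValueError("template and mask must have the same shape")
        p = int(mask.sum())
        if p < 2:
            raise ValueError("mask must contain at least 2 nonzero points")
        inside = mask > 0
        s = template - template[inside].mean()
        std = s[inside].std()
        if std == 0:
            raise ValueError("template is constant under the mask; cannot normalize")
        s = s / std
        s[~inside] = 0.0
        return cls(S=s, M=mask, P=p)

    @property
    def is_normalized(self) -> bool:
        inside = self.M > 0
        return (abs(self.S[inside].mean()) < 1e-6
                and abs(self.S[inside].std() - 1.0) < 1e-6)


@dataclass
class LocalStats:
    """Sliding mean and standard deviation of T under the mask footprint."""

    local_mean: np.ndarray
    sigma: np.ndarray        # sigma_MT(x), clamped at 0 before sqrt
    sigma_floor: float

    @property
    def valid(self) -> np.ndarray:
        return self.sigma > self.sigma_floor


@dataclass
class CorrelationMap:
    """C_L over all valid footprint positions.

    ``values[y, x]`` corresponds to the footprint whose top-left corner is
    at (x, y) in the micrograph; the matching box center is
    (x + box//2, y + box//2).
    """

    values: np.ndarray
    valid: np.ndarray
    box: int
    micrograph_shape: tuple[int, int]


def _correlate_valid(t: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # cross-correlation = convolution with the doubly flipped kernel
    return signal.fftconvolve(t, kernel[::-1, ::-1], mode="valid")


def local_stats(t: np.ndarray, mask: np.ndarray, sigma_floor: float | None = None) -> LocalStats:
    """Sliding-window mean/std of T under M via FFT convolutions."""
    t = np.asarray(t, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    p = mask.sum()
    if p < 2:
        raise ValueError("mask must contain at least 2 nonzero points")
    s1 = _correlate_valid(t, mask) / p
    s2 = _correlate_valid(t * t, mask) / p
    var = np.maximum(s2 - s1 * s1, 0.0)  # float cancellation can go negative
    sigma = np.sqrt(var)
    if sigma_floor is None:
        sigma_floor = max(1e-6 * float(t.std()), np.finfo(np.float64).tiny)
    return LocalStats(local_mean=s1, sigma=sigma, sigma_floor=sigma_floor)


def local_correlation_map(t: np.ndarray, search: SearchObject,
                          stats: LocalStats | None = None) -> CorrelationMap:
    """FLC map of T against a normalized search object.

    Positions whose local standard deviation falls below the floor are set
    to C_L = 0 and flagged invalid.  |C_L| <= 1 everywhere else
    (Cauchy-Schwarz).
    """
    t = np.asarray(t, dtype=np.float64)
    box = search.S.shape[0]
    if t.shape[0] < search.S.shape[0] or t.shape[1] < search.S.shape[1]:
        raise ValueError("micrograph must be at least as large as the template")
    if not search.is_normalized:
        raise ValueError(
            "search object is not normalized; build it with SearchObject.from_template"
        )
    if stats is None:
        stats = local_stats(t, search.M)
    num = _correlate_valid(t, search.S * search.M)
    valid = stats.valid
    values = np.zeros_like(num)
    np.divide(num, search.P * stats.sigma, out=values, where=valid)
    values[~valid] = 0.0
    return CorrelationMap(values=values, valid=valid, box=box, micrograph_shape=t.shape)


@dataclass
class PickSet:
    """Ranked particle picks from one micrograph (box-center coordinates)."""

    x: np.ndarray
    y: np.ndarray
    peak: np.ndarray
    rank: np.ndarray
    box: int
    micrograph_id: str = ""

    def __len__(self) -> int:
        return len(self.x)

    def to_records(self) -> list[CoordinateRecord]:
        return [
            CoordinateRecord(self.micrograph_id, float(x), float(y), float(p), int(r))
            for x, y, p, r in zip(self.x, self.y, self.peak, self.rank)
        ]


def find_peaks(cmap: CorrelationMap, exclusion_radius: float, n_max: int,
               micrograph_id: str = "") -> PickSet:
    """Greedy extraction of correlation peaks.

    Local maxima (3x3 neighborhood) are visited in descending C_L order;
    a candidate within ``exclusion_radius`` (euclidean, in pixels) of an
    already accepted peak is suppressed.  Ties are broken by row-major
    scan order.  Ranks run 1..n by descending peak value.
    """
    if exclusion_radius < 1:
        raise ValueError("exclusion_radius must be >= 1")
    vals = cmap.values
    if vals.size == 0 or n_max == 0:
        return PickSet(np.empty(0), np.empty(0), np.empty(0),
                       np.empty(0, dtype=int), cmap.box, micrograph_id)
    is_max = (vals >= maximum_filter(vals, size=3, mode="nearest")) & cmap.valid
    ys, xs = np.nonzero(is_max)
    v = vals[ys, xs]
    order = np.lexsort((xs, ys, -v))  # descending value, then row-major
    ys, xs, v = ys[order], xs[order], v[order]
    if len(v) > 1 and v[0] == v[1]:
        logger.info("find_peaks: tied top peaks broken by row-major scan order")
    acc_y = np.empty(n_max, dtype=np.int64)
    acc_x = np.empty(n_max, dtype=np.int64)
    acc_v = np.empty(n_max, dtype=np.float64)
    r2 = float(exclusion_radius) ** 2
    n_acc = 0
    for i in range(len(v)):
        if n_acc >= n_max:
            break
        if n_acc:
            dy = acc_y[:n_acc] - ys[i]
            dx = acc_x[:n_acc] - xs[i]
            if np.min(dy * dy + dx * dx) < r2:
                continue
        acc_y[n_acc], acc_x[n_acc], acc_v[n_acc] = ys[i], xs[i], v[i]
        n_acc += 1
    half = cmap.box // 2
    return PickSet(
        x=acc_x[:n_acc].astype(np.float64) + half,
        y=acc_y[:n_acc].astype(np.float64) + half,
        peak=acc_v[:n_acc].copy(),
        rank=np.arange(1, n_acc + 1),
        box=cmap.box,
        micrograph_id=micrograph_id,
    )


def threshold_picks(picks: PickSet, n_keep: int | None = None,
                    peak_floor: float | None = None) -> PickSet:
    """Keep the top-n picks or those above a peak-value floor; ranks kept."""
    if (n_keep is None) == (peak_floor is None):
        raise ValueError("give exactly one of n_keep or peak_floor")
    if n_keep is not None:
        sel = slice(0, max(0, int(n_keep)))
    else:
        sel = picks.peak >= peak_floor
    return PickSet(picks.x[sel], picks.y[sel], picks.peak[sel], picks.rank[sel],
                   picks.box, picks.micrograph_id)


@dataclass
class ParticleStack:
    """Boxed particle images with per-image provenance."""

    images: np.ndarray      # (n, box, box) float32
    pixel_size: float
    micrograph_ids: list[str] = field(default_factory=list)
    centers: np.ndarray | None = None  # (n, 2) (x, y) in the source micrograph

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box(self) -> int:
        return self.images.shape[1]


def extract_particles(t: np.ndarray, picks: PickSet, box: int | None = None,
                      pixel_size: float = 1.0) -> ParticleStack:
    """Window ``box`` x ``box`` images centered on the picks, in rank order."""
    if box is None:
        box = picks.box
    half = box // 2
    ny, nx = t.shape
    images = np.empty((len(picks), box, box), dtype=np.float32)
    for i, (x, y) in enumerate(zip(picks.x, picks.y)):
        x0, y0 = int(round(x)) - half, int(round(y)) - half
        if x0 < 0 or y0 < 0 or x0 + box > nx or y0 + box > ny:
            raise ValueError(
                f"pick rank {picks.rank[i]} at ({x:.0f}, {y:.0f}) does not fit a "
                f"{box}-pixel box inside the {t.shape} micrograph"
            )
        images[i] = t[y0:y0 + box, x0:x0 + box]
    centers = np.stack([picks.x, picks.y], axis=1) if len(picks) else np.empty((0, 2))
    return ParticleStack(
        images=images, pixel_size=pixel_size,
        micrograph_ids=[picks.micrograph_id] * len(picks), centers=centers,
    )


def phase_flip(stack: ParticleStack, ctf: CTFParams) -> ParticleStack:
    """Multiply each image's Fourier transform by sign(CTF(k)).

    Applying the operation twice restores the original images; power
    spectra are unchanged.
    """
    box = stack.box
    p = CTFParams(**{**ctf.__dict__, "pixel_size": stack.pixel_size})
    s = np.sign(ctf_2d((box, box), p))
    f = sfft.rfft2(stack.images.astype(np.float64), axes=(-2, -1))
    flipped = sfft.irfft2(f * s, s=(box, box), axes=(-2, -1)).astype(np.float32)
    return ParticleStack(images=flipped, pixel_size=stack.pixel_size,
                         micrograph_ids=list(stack.micrograph_ids),
                         centers=None if stack.centers is None else stack.centers.copy())
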