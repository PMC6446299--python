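"""Particle verification by multi-reference maximum-likelihood 2D alignment.

Each particle image is modeled as a rotated/translated copy of one of K
underlying class signals plus i.i.d. Gaussian pixel noise,

    X_i = R(phi_i) A_k + sigma G_i,     phi_i = (alpha_i, x_i, y_i),

with the transformation phi_i and the class label k treated as latent
variables.  The model parameters Theta = (A_1..A_K, mixing weights, sigma,
translation-prior width xi) are estimated by expectation-maximization:
the E-step evaluates, for every particle, the posterior responsibility of
every (class, rotation, shift) on a discrete transform grid; the M-step
updates the class averages as probability-weighted averages of the
back-transformed images,

    A_k <- sum_i sum_phi P(k, phi | X_i) R^{-1}(phi) X_i / sum_i sum_phi P(k, phi | X_i),

and re-estimates sigma, the weights, and xi as probability-weighted
averages.  The rotation prior is uniform; translations carry an isotropic
Gaussian prior of width xi (normalized over the shift grid; xi = inf gives
a uniform prior).

If the posterior is forced to a point mass (sigma -> 0), the update
degenerates to hard-assignment cross-correlation alignment with a plain
average; that classic scheme is provided as :func:`cc_align` and serves as
a comparison oracle.

All heavy lifting is a single matrix product per iteration between the
particle matrix (N x J) and the transformed-reference matrix
(K*R*S x J); computations follow the dtype of the input stack (float32 in
the pipeline, float64 in small verification runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .flc_pick import ParticleStack
from .simulate import make_gaussian_circle
from .transforms import apply_inverse_transform, rotate_image, shift_image

logger = logging.getLogger("bofem")

__all__ = [
    "TransformGrid",
    "ModelState",
    "PosteriorTable",
    "EMTrace",
    "normalize_particles",
    "bin_particles",
    "make_start_references",
    "e_step",
    "m_step",
    "em_align",
    "cc_align",
]

_RESP_TRUNCATION = 1e-12
_XI_FLOOR = 0.3  # pixels; keeps the translation prior proper on the grid


@dataclass(frozen=True)
class TransformGrid:
    """Discrete sampling of in-plane transforms phi = (alpha, tx, ty)."""

    rotations: np.ndarray  # degrees
    shifts: np.ndarray     # (S, 2) integer (tx, ty)

    @classmethod
    def make(cls, rot_step: float = 5.0, max_shift: int = 3) -> "TransformGrid":
        rotations = np.arange(0.0, 360.0, rot_step)
        t = np.arange(-max_shift, max_shift + 1)
        tx, ty = np.meshgrid(t, t, indexing="xy")
        return cls(rotations=rotations, shifts=np.stack([tx.ravel(), ty.ravel()], axis=1))

    @property
    def n_rot(self) -> int:
        return len(self.rotations)

    @property
    def n_shift(self) -> int:
        return len(self.shifts)

    @property
    def size(self) -> int:
        return self.n_rot * self.n_shift


@dataclass
class ModelState:
    """Theta = (class averages, mixing weights, noise sigma, shift prior xi)."""

    A: np.ndarray         # (K, L, L)
    weights: np.ndarray   # (K,), sums to 1
    sigma: float
    xi: float = 1.5       # pixels; np.inf = uniform shift prior

    @property
    def n_classes(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("class weights must be nonnegative and sum to 1")


@dataclass
class PosteriorTable:
    """E-step responsibilities P(k, phi | X_i) on the grid, plus evidence."""

    resp: np.ndarray            # (N, K, R, S); each particle's slab sums to 1
    log_evidence: np.ndarray    # (N,)
    expected_sq_residual: float  # sum_i E[ ||X_i - R(phi) A_k||^2 ]

    @property
    def log_likelihood(self) -> float:
        return float(self.log_evidence.sum())


@dataclass
class EMTrace:
    """Per-iteration log-likelihood, sigma, weights, milestone snapshots."""

    log_likelihood: list[float] = field(default_factory=list)
    sigma: list[float] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)
    xi: list[float] = field(default_factory=list)
    snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Stack preparation
# ---------------------------------------------------------------------------

def _annulus_mask(box: int, r_inner: float, r_outer: float) -> np.ndarray:
    c = (box - 1) / 2.0
    y, x = np.mgrid[0:box, 0:box]
    r = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    return (r >= r_inner) & (r <= r_outer)


def normalize_particles(stack: ParticleStack,
                        background_annulus: tuple[float, float] | None = None) -> ParticleStack:
    """Shift/scale each image so its background annulus has mean 0, std 1.

    The annulus defaults to radii (0.4, 0.5) x box, the corner-free ring
    outside the particle.  Idempotent; a constant image (zero background
    std) is an error.
    """
    box = stack.box
    if background_annulus is None:
        background_annulus = (0.40 * box, 0.50 * box)
    mask = _annulus_mask(box, *background_annulus)
    if not mask.any():
        raise ValueError(f"background annulus {background_annulus} is empty for box {box}")
    bg = stack.images[:, mask]
    mean = bg.mean(axis=1)
    std = bg.std(axis=1)
    if np.any(std == 0):
        bad = int(np.nonzero(std == 0)[0][0])
        raise ValueError(f"image {bad} has zero background standard deviation")
    images = (stack.images - mean[:, None, None]) / std[:, None, None]
    return ParticleStack(images=images.astype(stack.images.dtype),
                         pixel_size=stack.pixel_size,
                         micrograph_ids=list(stack.micrograph_ids),
                         centers=None if stack.centers is None else stack.centers.copy())


def bin_particles(stack: ParticleStack, factor: int) -> ParticleStack:
    """Downscale by Fourier cropping; per-image mean is preserved.

    The pixel size is multiplied by ``factor``; e.g. factor 3 turns a
    180 x 180 box into 60 x 60.
    """
    if factor == 1:
        return ParticleStack(images=stack.images.copy(), pixel_size=stack.pixel_size,
                             micrograph_ids=list(stack.micrograph_ids),
                             centers=None if stack.centers is None else stack.centers.copy())
    box = stack.box
    if box % factor:
        raise ValueError(f"box {box} not divisible by binning factor {factor}")
    new = box // factor
    f = sfft.fftshift(sfft.fft2(stack.images.astype(np.float64), axes=(-2, -1)),
                      axes=(-2, -1))
    c, h = box // 2, new // 2
    cropped = f[:, c - h:c - h + new, c - h:c - h + new]
    out = sfft.ifft2(sfft.ifftshift(cropped, axes=(-2, -1)), axes=(-2, -1)).real
    out *= (new * new) / (box * box)
    return ParticleStack(images=out.astype(stack.images.dtype),
                         pixel_size=stack.pixel_size * factor,
                         micrograph_ids=list(stack.micrograph_ids),
                         centers=None if stack.centers is None else stack.centers.copy())


def make_start_references(stack: ParticleStack, mode: str, K: int, rng_seed=0,
                          gaussian_sigma: float | None = None) -> ModelState:
    """Build the K starting class averages for EM.

    Modes:

    * ``random_noise_image`` -- K distinct particles drawn from the stack;
    * ``gaussian_circle``    -- K copies of a radial Gaussian, each given a
      small seeded perturbation (1% of the reference std) so the classes
      can diverge;
    * ``unaligned_average``  -- averages of K random disjoint subsets of
      the stack (K = 1 gives the plain mean), which replicates whatever
      bias particle picking imprinted on the images.
    """
    n = len(stack)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the stack size {n}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    box = stack.box
    dtype = stack.images.dtype
    if mode == "random_noise_image":
        idx = rng.choice(n, size=K, replace=False)
        a = stack.images[idx].astype(dtype)
    elif mode == "gaussian_circle":
        if gaussian_sigma is None:
            gaussian_sigma = 0.15 * box
        base = make_gaussian_circle(box, gaussian_sigma,
                                    amplitude=float(stack.images.std()))
        a = np.repeat(base[None].astype(dtype), K, axis=0)
        a += (0.01 * base.std()) * rng.standard_normal(a.shape).astype(dtype)
    elif mode == "unaligned_average":
        perm = rng.permutation(n)
        a = np.stack([stack.images[part].mean(axis=0)
                      for part in np.array_split(perm, K)]).astype(dtype)
    else:
        raise ValueError(f"unknown start mode {mode!r}")
    sigma = float(stack.images.std())
    return ModelState(A=a, weights=np.full(K, 1.0 / K), sigma=sigma)


# ---------------------------------------------------------------------------
# EM steps
# ---------------------------------------------------------------------------

def _transformed_references(theta: ModelState, grid: TransformGrid) -> np.ndarray:
    """All R(phi) A_k on the grid: array (K, R, S, L, L)."""
    K = theta.n_classes
    L = theta.A.shape[1]
    out = np.empty((K, grid.n_rot, grid.n_shift, L, L), dtype=theta.A.dtype)
    for k in range(K):
        for r, ang in enumerate(grid.rotations):
            rot = rotate_image(theta.A[k], float(ang))
            for s, (tx, ty) in enumerate(grid.shifts):
                out[k, r, s] = shift_image(rot, int(tx), int(ty))
    return out


def _log_prior(theta: ModelState, grid: TransformGrid) -> np.ndarray:
    """log [ w_k * P(phi | xi) ] on the grid, shape (K, R, S)."""
    if np.isfinite(theta.xi):
        d2 = (grid.shifts.astype(np.float64) ** 2).sum(axis=1)
        ls = -d2 / (2.0 * theta.xi**2)
        ls -= np.log(np.exp(ls).sum())  # normalize over the shift grid
    else:
        ls = np.full(grid.n_shift, -np.log(grid.n_shift))
    lr = -np.log(grid.n_rot)
    lw = np.log(np.maximum(theta.weights, 1e-300))
    out = lw[:, None, None] + lr + ls[None, None, :]
    return np.broadcast_to(out, (len(lw), grid.n_rot, grid.n_shift)).copy()


def e_step(stack: ParticleStack, theta: ModelState, grid: TransformGrid) -> PosteriorTable:
    """Posterior responsibilities over (class, rotation, shift) per particle.

    Log-weights are the Gaussian data term -||X_i - R(phi) A_k||^2 /
    (2 sigma^2) - (J/2) log(2 pi sigma^2) plus log priors, normalized per
    particle with a log-sum-exp; the per-particle log-evidence accumulates
    the (grid-discretized) log-likelihood.
    """
    theta.validate()
    n = len(stack)
    L = stack.box
    J = L * L
    x = stack.images.reshape(n, J)
    refs = _transformed_references(theta, grid).reshape(-1, J)
    dots = x @ refs.T                       # (N, K*R*S)
    x2 = np.einsum("ij,ij->i", x, x)
    r2 = np.einsum("ij,ij->i", refs, refs)
    sq_resid = (x2[:, None] - 2.0 * dots + r2[None, :]).astype(np.float64)
    inv2s2 = 1.0 / (2.0 * theta.sigma**2)
    logw = -sq_resid * inv2s2 - 0.5 * J * np.log(2.0 * np.pi * theta.sigma**2)
    logw += _log_prior(theta, grid).reshape(1, -1)
    m = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - m)
    z = w.sum(axis=1, keepdims=True)
    log_evidence = (m[:, 0] + np.log(z[:, 0]))
    resp = w / z
    resp[resp < _RESP_TRUNCATION] = 0.0
    resp /= resp.sum(axis=1, keepdims=True)
    expected_sq = float(np.einsum("ij,ij->", resp, sq_resid))
    return PosteriorTable(
        resp=resp.reshape(n, theta.n_classes, grid.n_rot, grid.n_shift).astype(
            stack.images.dtype if stack.images.dtype == np.float64 else np.float32),
        log_evidence=log_evidence,
        expected_sq_residual=expected_sq,
    )


def m_step(stack: ParticleStack, posteriors: PosteriorTable, grid: TransformGrid,
           update_sigma: bool = True, update_xi: bool = True,
           old_theta: ModelState | None = None) -> ModelState:
    """Probability-weighted parameter updates.

    Class averages are responsibility-weighted sums of back-transformed
    images; weights are mean class responsibilities; sigma^2 is the
    probability-weighted mean squared residual per pixel; xi is the
    responsibility-weighted RMS shift.  A class whose total responsibility
    falls below 1e-6 * N is kept but flagged (see ``EMTrace.events`` /
    the reseeding policy in :func:`em_align`).
    """
    n, K, R, S = posteriors.resp.shape
    L = stack.box
    J = L * L
    x = stack.images.reshape(n, J).astype(np.float64)
    resp = posteriors.resp.reshape(n, -1).astype(np.float64)
    mass = resp.sum(axis=0).reshape(K, R, S)         # total weight per transform
    class_mass = mass.sum(axis=(1, 2))
    weights = class_mass / n

    g = (resp.T @ x).reshape(K, R, S, L, L)          # weighted image sums
    a_new = np.empty((K, L, L), dtype=np.float64)
    for k in range(K):
        acc_k = np.zeros((L, L))
        for r in range(R):
            if mass[k, r].sum() <= 0:
                continue
            acc_r = np.zeros((L, L))
            for s, (tx, ty) in enumerate(grid.shifts):
                if mass[k, r, s] <= 0:
                    continue
                acc_r += shift_image(g[k, r, s], -int(tx), -int(ty))
            acc_k += rotate_image(acc_r, -float(grid.rotations[r]))
        denom = class_mass[k]
        a_new[k] = acc_k / denom if denom > 1e-6 * n else (
            old_theta.A[k] if old_theta is not None else acc_k
        )

    if update_sigma:
        sigma = float(np.sqrt(max(posteriors.expected_sq_residual / (n * J), 1e-300)))
    else:
        sigma = old_theta.sigma if old_theta is not None else 1.0
    if update_xi:
        d2 = (grid.shifts.astype(np.float64) ** 2).sum(axis=1)
        xi = float(np.sqrt(max((mass.sum(axis=(0, 1)) * d2).sum() / (2.0 * n), _XI_FLOOR**2)))
    else:
        xi = old_theta.xi if old_theta is not None else np.inf

    dtype = stack.images.dtype
    return ModelState(A=a_new.astype(dtype), weights=weights, sigma=sigma, xi=xi)


def em_align(stack: ParticleStack, start: ModelState, grid: TransformGrid,
             max_iter: int = 100, tol: float = 1e-7,
             milestones: tuple[int, ...] = (1, 10, 50, 100),
             update_sigma: bool = True, update_xi: bool = True,
             ) -> tuple[ModelState, EMTrace, PosteriorTable]:
    """Alternate E and M steps until |dL|/|L| < tol or ``max_iter``.

    Empty classes (total responsibility < 1e-6 * N) are reseeded from the
    particle with the worst evidence; the event is logged in the trace.
    The log-likelihood is non-decreasing up to grid/interpolation effects.
    """
    theta = ModelState(A=start.A.copy(), weights=start.weights.copy(),
                       sigma=start.sigma, xi=start.xi)
    trace = EMTrace()
    post = None
    prev_l = None
    for it in range(1, max_iter + 1):
        post = e_step(stack, theta, grid)
        l = post.log_likelihood
        if not np.isfinite(l) or not np.isfinite(theta.sigma) or theta.sigma <= 0:
            trace.events.append(f"iter {it}: divergent state (L={l}, sigma={theta.sigma})")
            raise FloatingPointError(
                f"EM diverged at iteration {it}: L={l}, sigma={theta.sigma}; "
                f"trace: {trace.events}"
            )
        theta = m_step(stack, post, grid, update_sigma=update_sigma,
                       update_xi=update_xi, old_theta=theta)
        # reseed empty classes from the worst-explained particle
        n = len(stack)
        for k in range(theta.n_classes):
            if theta.weights[k] < 1e-6:
                worst = int(np.argmin(post.log_evidence))
                theta.A[k] = stack.images[worst]
                theta.weights[k] = 1.0 / n
                trace.events.append(f"iter {it}: class {k} empty, reseeded from particle {worst}")
        theta.weights = theta.weights / theta.weights.sum()
        trace.log_likelihood.append(l)
        trace.sigma.append(theta.sigma)
        trace.weights.append(theta.weights.copy())
        trace.xi.append(theta.xi)
        if it in milestones:
            trace.snapshots[it] = theta.A.copy()
        if prev_l is not None and abs(l - prev_l) < tol * abs(l):
            logger.info("em_align: converged at iteration %d (L=%.6g)", it, l)
            break
        prev_l = l
    return theta, trace, post


def cc_align(stack: ParticleStack, start_reference: np.ndarray, max_iter: int = 10,
             grid: TransformGrid | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Hard-assignment iterative cross-correlation alignment.

    Per iteration each image takes the grid transform maximizing its inner
    product with the current average, and the average is recomputed as the
    plain mean of the back-transformed images (the sigma -> 0 limit of the
    EM update).  Returns the final average and the (alpha, tx, ty) table.
    """
    if grid is None:
        grid = TransformGrid.make()
    n = len(stack)
    L = stack.box
    J = L * L
    x = stack.images.reshape(n, J)
    a = np.asarray(start_reference, dtype=stack.images.dtype)
    best = np.zeros(n, dtype=np.int64)
    for _ in range(max_iter):
        theta = ModelState(A=a[None], weights=np.ones(1), sigma=1.0)
        refs = _transformed_references(theta, grid).reshape(-1, J)
        dots = x @ refs.T
        new_best = np.argmax(dots, axis=1)
        avg = np.zeros((L, L), dtype=np.float64)
        for i in range(n):
            r, s = divmod(int(new_best[i]), grid.n_shift)
            tx, ty = grid.shifts[s]
            avg += apply_inverse_transform(stack.images[i],
                                           float(grid.rotations[r]), int(tx), int(ty))
        a = (avg / n).astype(stack.images.dtype)
        if np.array_equal(new_best, best):
            best = new_best
            break
        best = new_best
    params = np.array(
        [(float(grid.rotations[b // grid.n_shift]),
          int(grid.shifts[b % grid.n_shift][0]),
          int(grid.shifts[b % grid.n_shift][1])) for b in best],
        dtype=np.float64,
    )
    return a, params
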