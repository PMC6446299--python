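"""Shared fixtures.

Expensive simulation products (projection banks, the pure-noise control
stack, EM runs) are session-scoped so the acceptance-level tests can share
them.  Everything is generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from bofem import flc_pick, ml_align, simulate

DESK_PX = 2.0
DESK_BOX = 90


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trimer_bank_desk():
    """Six projection views of the trimer phantom, desk geometry."""
    vol = simulate.trimer_phantom_volume(DESK_PX)
    return simulate.render_projection_set(vol, n_views=6, box=DESK_BOX, rng_seed=1)


@pytest.fixture(scope="session")
def decoy_projection_desk():
    vol = simulate.decoy_phantom_volume(DESK_PX)
    return simulate.render_projection_set(vol, n_views=1, box=DESK_BOX, rng_seed=5)[0]


@pytest.fixture(scope="session")
def desk_ctf():
    return simulate.CTFParams(pixel_size=DESK_PX)


# ---------------------------------------------------------------------------
# Pure-noise control (reference-bias experiments)
# ---------------------------------------------------------------------------

NOISE_BOX = 128          # larger box = weaker per-particle selection bias
NOISE_MICS = 250         # 1024^2 Gaussian-noise fields
NOISE_PICKS_PER_MIC = 12


@pytest.fixture(scope="session")
def noise_control():
    """Particles picked from pure Gaussian noise with the decoy template.

    Mirrors the baseline control: a structured template applied to
    protein-free noise fields, keeping only the top-ranked correlation
    peaks per field.  Returns (stack, template, pixel_size).
    """
    vol = simulate.decoy_phantom_volume(DESK_PX)
    decoy = simulate.render_projection_set(vol, n_views=1, box=NOISE_BOX, rng_seed=5)[0]
    template = simulate.make_projection_template(decoy, 30.0, DESK_PX, ctf=None)
    search = flc_pick.SearchObject.from_template(template)
    rng = np.random.default_rng(20240)
    stacks = []
    for m in range(NOISE_MICS):
        mic = rng.normal(0.0, 1.0, (1024, 1024)).astype(np.float32)
        cmap = flc_pick.local_correlation_map(mic, search)
        picks = flc_pick.threshold_picks(
            flc_pick.find_peaks(cmap, NOISE_BOX // 2, 2 * NOISE_PICKS_PER_MIC,
                                micrograph_id=f"noise{m:03d}"),
            n_keep=NOISE_PICKS_PER_MIC)
        stacks.append(flc_pick.extract_particles(mic, picks, pixel_size=DESK_PX))
    stack = flc_pick.ParticleStack(
        images=np.concatenate([s.images for s in stacks]),
        pixel_size=DESK_PX,
        micrograph_ids=sum((s.micrograph_ids for s in stacks), []),
    )
    return stack, template, DESK_PX


@pytest.fixture(scope="session")
def noise_em_stack(noise_control):
    """Noise-control stack normalized and binned for EM, plus the template
    at the same scale."""
    stack, template, px = noise_control
    em_stack = ml_align.bin_particles(ml_align.normalize_particles(stack), 2)
    em_stack.images = em_stack.images[:2000]
    em_stack.micrograph_ids = em_stack.micrograph_ids[:2000]
    tmpl_small = ml_align.bin_particles(
        flc_pick.ParticleStack(template[None].astype(np.float32), px), 2).images[0]
    return em_stack, tmpl_small


@pytest.fixture(scope="session")
def noise_em_gaussian(noise_em_stack):
    stack, tmpl = noise_em_stack
    grid = ml_align.TransformGrid.make(rot_step=12.0, max_shift=2)
    start = ml_align.make_start_references(stack, "gaussian_circle", 5, rng_seed=1)
    theta, trace, post = ml_align.em_align(stack, start, grid, max_iter=20,
                                           milestones=(1, 5, 10, 20))
    return theta, trace, post


@pytest.fixture(scope="session")
def noise_em_unaligned(noise_em_stack):
    stack, tmpl = noise_em_stack
    grid = ml_align.TransformGrid.make(rot_step=12.0, max_shift=2)
    start = ml_align.make_start_references(stack, "unaligned_average", 5, rng_seed=1)
    theta, trace, post = ml_align.em_align(stack, start, grid, max_iter=20,
                                           milestones=(1, 5, 10, 20))
    return theta, trace, post
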