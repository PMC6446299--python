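"""End-to-end bi-objective-function (BOF) runs.

One scenario = one choice of picking template and EM starting reference
applied across a list of micrograph SNRs (or to pure-noise micrographs).
Each case runs simulate -> FLC pick -> rank/threshold -> extract ->
phase-flip -> normalize -> bin -> EM verify -> evaluate, and everything is
written under a results tree with a machine-readable manifest.

Scales:

* ``full`` -- the reference geometry: 4096 x 4096 micrographs at
  1.0 A/pixel, 323 particles in 180-pixel boxes, 120 micrographs.
* ``desk`` -- 2048 x 2048 at 2.0 A/pixel (the 2x-binned frame of the
  reference geometry), 3 micrographs, box 96, 80 particles; every
  mechanism is preserved at laptop cost.  SNR values in ``snr_list`` are
  always quoted at the reference (unbinned) scale and converted with
  :func:`bofem.simulate.binned_snr` when noise is added at desk
  resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluate, flc_pick, io_formats, ml_align, simulate

logger = logging.getLogger("bofem")

__all__ = ["ScenarioSpec", "run_bof", "build_templates", "expected_stack_size"]

_SCALE_PRESETS = {
    "full": dict(n_micrographs=120, dims=(4096, 4096), n_particles=323,
                 box=180, pixel_size=1.0, reference_binning=1),
    "desk": dict(n_micrographs=3, dims=(2048, 2048), n_particles=80,
                 box=96, pixel_size=2.0, reference_binning=2),
}

TEMPLATE_KINDS = ("gaussian_circle", "phantom_projection", "decoy_projection")
START_MODES = ("random_noise_image", "gaussian_circle", "unaligned_average")


@dataclass
class ScenarioSpec:
    """One BOF experiment: SNR sweep x picking template x EM start."""

    snr_list: list = field(default_factory=list)  # reference-scale micrograph SNRs
    picking_template: str = "gaussian_circle"
    mle_start: str = "gaussian_circle"
    K: int = 5
    seed: int = 0
    scale: str = "desk"
    pure_noise: bool = False
    # geometry; None = take from the scale preset
    n_micrographs: int | None = None
    dims: tuple[int, int] | None = None
    n_particles: int | None = None
    box: int | None = None
    pixel_size: float | None = None
    reference_binning: int | None = None
    n_keep: int | None = None          # picks kept per micrograph (default n_particles)
    keep_list: list | None = None      # optional external curation hook (indices kept)
    # EM settings
    run_em: bool = True
    em_bin: int = 2
    em_max_particles: int = 5000
    em_max_iter: int = 50
    em_tol: float = 1e-7
    rot_step: float = 10.0
    max_shift: int = 2
    milestones: tuple = (1, 10, 50, 100)
    keep_micrographs: bool = False

    def __post_init__(self) -> None:
        if self.scale not in _SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.picking_template not in TEMPLATE_KINDS:
            raise ValueError(f"unknown picking template {self.picking_template!r}")
        if self.mle_start not in START_MODES:
            raise ValueError(f"unknown MLE start mode {self.mle_start!r}")
        for key, value in _SCALE_PRESETS[self.scale].items():
            if getattr(self, key) is None:
                setattr(self, key, value)
        if self.n_keep is None:
            self.n_keep = self.n_particles if not self.pure_noise else 25

    def ctf(self) -> simulate.CTFParams:
        return simulate.CTFParams(pixel_size=self.pixel_size)


def expected_stack_size(n_micrographs: int, n_keep: int) -> int:
    """Particles in the assembled stack under a per-micrograph threshold."""
    return n_micrographs * n_keep


def build_templates(scenario: ScenarioSpec, rng_seed=0) -> dict[str, np.ndarray]:
    """Picking templates at the scenario geometry, contrast-matched.

    ``gaussian_circle`` is a dark radial Gaussian (sigma 0.15 x box);
    the projection templates are a trimer-phantom view and a decoy-phantom
    view, low-passed to 30 A and passed through the scenario CTF (or
    negated if the scenario carries no CTF, i.e. pure noise).
    """
    box, px = scenario.box, scenario.pixel_size
    ctf = None if scenario.pure_noise else scenario.ctf()
    rng = np.random.default_rng(rng_seed)
    gauss = -simulate.make_gaussian_circle(box, 0.15 * box)
    trimer = simulate.render_projection_set(
        simulate.trimer_phantom_volume(px), n_views=1, box=box, rng_seed=rng)[0]
    decoy = simulate.render_projection_set(
        simulate.decoy_phantom_volume(px), n_views=1, box=box, rng_seed=rng)[0]
    return {
        "gaussian_circle": gauss,
        "phantom_projection": simulate.make_projection_template(trimer, 30.0, px, ctf),
        "decoy_projection": simulate.make_projection_template(decoy, 30.0, px, ctf),
    }


def _simulate_case_micrograph(scenario: ScenarioSpec, bank: np.ndarray,
                              mic_index: int, snr,
                              noiseless_cache: dict) -> tuple[np.ndarray, simulate.GroundTruth]:
    root = np.random.SeedSequence([scenario.seed, mic_index])
    if scenario.pure_noise:
        rng = np.random.default_rng(root)
        mic = rng.normal(0.0, 1.0, scenario.dims).astype(np.float32)
        truth = simulate.GroundTruth(
            centers=np.empty((0, 2)), in_plane_angles=np.empty(0),
            projection_ids=np.empty(0, dtype=int), box=scenario.box,
            dims=scenario.dims)
        return mic, truth
    if mic_index not in noiseless_cache:
        rng = np.random.default_rng(root)
        noiseless, truth = simulate.synthesize_micrograph(
            bank, scenario.n_particles, scenario.dims, rng_seed=rng)
        noiseless = simulate.apply_ctf(noiseless, scenario.ctf())
        noiseless_cache[mic_index] = (noiseless, truth)
    noiseless, truth = noiseless_cache[mic_index]
    local_snr = simulate.binned_snr(float(snr), scenario.reference_binning)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, mic_index, int(local_snr * 1e9) % (2**31)]))
    noisy = simulate.add_noise_to_snr(noiseless, simulate.SNRSpec(local_snr), noise_rng)
    return noisy, truth


def _run_case(scenario: ScenarioSpec, snr, bank: np.ndarray, template: np.ndarray,
              case_dir: Path, noiseless_cache: dict) -> dict:
    case_dir.mkdir(parents=True, exist_ok=True)
    search = flc_pick.SearchObject.from_template(template)
    all_records: list[io_formats.CoordinateRecord] = []
    stacks = []
    matches = []
    curves = {}
    for m in range(scenario.n_micrographs):
        mic_id = f"mic{m:03d}"
        mic, truth = _simulate_case_micrograph(scenario, bank, m, snr, noiseless_cache)
        cmap = flc_pick.local_correlation_map(mic, search)
        picks = flc_pick.find_peaks(cmap, exclusion_radius=0.5 * scenario.box,
                                    n_max=2 * scenario.n_keep, micrograph_id=mic_id)
        curves[mic_id] = picks.peak.copy()
        kept = flc_pick.threshold_picks(picks, n_keep=scenario.n_keep)
        if scenario.keep_list is not None:  # external curation hook
            sel = [i for i in range(len(kept)) if i in scenario.keep_list]
            kept = flc_pick.PickSet(kept.x[sel], kept.y[sel], kept.peak[sel],
                                    kept.rank[sel], kept.box, kept.micrograph_id)
        if len(truth):
            matches.append(evaluate.match_picks(kept, truth, d_max=scenario.box / 4))
        all_records.extend(kept.to_records())
        stacks.append(flc_pick.extract_particles(mic, kept, pixel_size=scenario.pixel_size))
        if scenario.keep_micrographs:
            io_formats.write_image(case_dir / f"{mic_id}.mrc", mic, scenario.pixel_size)
    io_formats.write_coords(case_dir / "picks.tsv", all_records)
    max_len = max((len(c) for c in curves.values()), default=0)
    io_formats.write_curve(case_dir / "ranked_peaks.tsv", {
        "rank": np.arange(1, max_len + 1),
        **{mid: np.pad(c, (0, max_len - len(c)), constant_values=np.nan)
           for mid, c in curves.items()},
    })
    stack = flc_pick.ParticleStack(
        images=np.concatenate([s.images for s in stacks]),
        pixel_size=scenario.pixel_size,
        micrograph_ids=sum((s.micrograph_ids for s in stacks), []),
        centers=np.concatenate([s.centers for s in stacks]),
    )
    result: dict = {"snr": snr, "n_particles_stacked": len(stack)}
    if matches:
        fp = [m.fp_fraction for m in matches]
        result["fp_fraction_median"] = float(np.median(fp))
        result["fp_fraction_per_micrograph"] = [float(v) for v in fp]
        result["centering_error_mean"] = float(
            np.mean(np.concatenate([m.centering_errors for m in matches])))
    first_curve = next(iter(curves.values()))
    if len(first_curve) > 1:
        result["dropoff_rank"] = int(evaluate.dropoff_rank(first_curve))

    if scenario.run_em and len(stack):
        if not scenario.pure_noise:
            stack = flc_pick.phase_flip(stack, scenario.ctf())
        stack = ml_align.normalize_particles(stack)
        if scenario.em_bin > 1:
            stack = ml_align.bin_particles(stack, scenario.em_bin)
        if len(stack) > scenario.em_max_particles:
            stack.images = stack.images[: scenario.em_max_particles]
            stack.micrograph_ids = stack.micrograph_ids[: scenario.em_max_particles]
        em_seed = np.random.SeedSequence([scenario.seed, 777])
        start = ml_align.make_start_references(
            stack, scenario.mle_start, scenario.K,
            rng_seed=np.random.default_rng(em_seed))
        grid = ml_align.TransformGrid.make(scenario.rot_step, scenario.max_shift)
        theta, trace, _ = ml_align.em_align(
            stack, start, grid, max_iter=scenario.em_max_iter, tol=scenario.em_tol,
            milestones=scenario.milestones)
        io_formats.write_image(case_dir / "class_averages.mrc", theta.A,
                               stack.pixel_size)
        for it, snap in trace.snapshots.items():
            io_formats.write_image(case_dir / f"class_averages_iter{it:04d}.mrc",
                                   snap, stack.pixel_size)
        io_formats.write_curve(case_dir / "em_trace.tsv", {
            "iteration": np.arange(1, len(trace.log_likelihood) + 1),
            "log_likelihood": np.array(trace.log_likelihood),
            "sigma": np.array(trace.sigma),
        })
        # reference bias readout: converged class averages vs picking template
        tmpl_stack = flc_pick.ParticleStack(images=template[None].astype(np.float32),
                                            pixel_size=scenario.pixel_size)
        tmpl_small = ml_align.bin_particles(tmpl_stack, scenario.em_bin).images[0] \
            if scenario.em_bin > 1 else template
        frc_rows = {}
        crossings = []
        for k in range(theta.n_classes):
            curve = evaluate.frc(theta.A[k], tmpl_small, pixel_size=stack.pixel_size)
            frc_rows[f"class{k}"] = curve.values
            crossings.append(evaluate.frc_half_crossing(curve))
        io_formats.write_curve(case_dir / "frc_vs_template.tsv", {
            "frequency": curve.frequencies, **frc_rows})
        result["frc_half_crossing_vs_template"] = [float(c) for c in crossings]
        result["em_iterations"] = len(trace.log_likelihood)
        result["em_final_loglik"] = trace.log_likelihood[-1]
        result["em_sigma"] = theta.sigma
        result["em_weights"] = [float(w) for w in theta.weights]
    return result


def run_bof(scenario: ScenarioSpec, out_dir: str | Path) -> dict:
    """Run every case of a scenario; failures abort the case, not the run.

    Returns (and writes as ``manifest.json``) a manifest with the scenario
    echo and per-case outputs; re-running with identical config and seeds
    reproduces all numeric outputs bit-identically on one platform.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec_echo = asdict(scenario)
    spec_echo["dims"] = list(scenario.dims)
    manifest: dict = {"scenario": spec_echo, "cases": {}}
    cases = ["pure_noise"] if scenario.pure_noise else list(scenario.snr_list)
    if cases:
        bank = None if scenario.pure_noise else simulate.render_projection_set(
            simulate.trimer_phantom_volume(scenario.pixel_size), n_views=8,
            box=scenario.box, rng_seed=np.random.default_rng(
                np.random.SeedSequence([scenario.seed, 99])))
        template = build_templates(scenario, rng_seed=scenario.seed)[scenario.picking_template]
        noiseless_cache: dict = {}
        for case in cases:
            name = "pure_noise" if scenario.pure_noise else f"snr_{case:g}"
            logger.info("run_bof: case %s", name)
            try:
                manifest["cases"][name] = _run_case(
                    scenario, None if scenario.pure_noise else case,
                    bank, template, out_dir / name, noiseless_cache)
            except Exception as exc:  # noqa: BLE001 - case isolation by design
                logger.exception("case %s failed", name)
                manifest["cases"][name] = {"error": f"{type(exc).__name__}: {exc}"}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if manifest["cases"]:
        rows = [{"case": k, **{kk: vv for kk, vv in v.items()
                               if np.isscalar(vv)}} for k, v in manifest["cases"].items()]
        import pandas as pd
        pd.DataFrame(rows).to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    return manifest
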