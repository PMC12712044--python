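"""Synthetic short-axis cardiac phantoms and study cohorts.

No public imaging cohort backs this workflow, so every study design is
driven by a parametric phantom: an annular "myocardial wall" filled with a
stationary causal-AR texture (the same four-neighbour model the feature
engine fits, closing the parameter-recovery loop), a bright blood pool
inside, and a dark noisy background outside.  Ring and sector masks are
derived geometrically from the same specification.

Three cohort generators mirror the three study designs:

* :func:`generate_size_cohort` — three groups whose rings differ only in
  radii (hence ROI pixel count) with identical texture parameters, for the
  ROI-size invariance screen;
* :func:`generate_repeatability_cohort` — fixed images with per-reading
  mask perturbations from a simple observer model (boundary
  dilation/erosion and sector-angle jitter), for the repeatability screen;
* :func:`generate_population` — a phase/sex/age-structured population with
  configurable effect sizes, for the group-comparison machinery.

All generators are fully deterministic under their master seed (per-subject
streams are spawned from it).  Observer perturbations act on masks only,
never on images, matching a design in which only ROI placement is repeated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .quantize import GrayImage, RoiMask, annulus_mask, carve_sector

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "PopulationEffects",
    "Subject",
    "synthesize_ar_field",
    "generate_phantom",
    "generate_size_cohort",
    "generate_repeatability_cohort",
    "generate_population",
]

# Default wall texture: a strongly smoothed, near-unit-root causal AR field.
# bSSFP myocardium at ~1.4 mm in-plane resolution is locally smooth, with a
# correlation length of several pixels; these coefficients give a short-range
# pair correlation near 0.99 at offset 2 that has decayed appreciably by
# offset 5, which is what makes the long-distance co-occurrence statistics
# the sample-hungry ones.
THETA_DEFAULT = (0.66, -0.33, 0.66, 0.0)
INNOVATION_SD_DEFAULT = 1.0

SECTOR_SPAN_DEG = 120.0
SEPTAL_ANGLE_DEG = 180.0
LATERAL_ANGLE_DEG = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one short-axis phantom."""

    shape: tuple[int, int] = (128, 128)
    center: tuple[float, float] = (64.0, 64.0)
    r_inner: float = 30.0
    r_outer: float = 46.0
    theta: tuple[float, float, float, float] = THETA_DEFAULT
    innovation_sd: float = INNOVATION_SD_DEFAULT
    texture_gain: float = 60.0   # intensity units per unit of AR field
    # focal smooth-edged inclusions (trabeculae / vessel-like bumps): the
    # wall is not a pure Gaussian field; pixel pairs straddling a bump are
    # close in level at short offsets but far apart at long ones
    blob_density: float = 0.010  # bumps per wall pixel
    blob_sigma: float = 1.8      # bump width (px)
    blob_amp: float = 2.5        # bump amplitude SD, in units of field SD
    wall_base: float = 2000.0    # arbitrary intensity units
    blood_base: float = 3500.0
    background_base: float = 400.0
    noise_sd: float = 30.0       # white noise on blood pool / background
    wall_pad: float = 4.0        # textured margin beyond the nominal ring (px)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer < min(self.shape) / 2):
            raise ValueError("need 0 < r_inner < r_outer < min(shape)/2")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")


@dataclass(frozen=True)
class ObserverModel:
    """Reading-to-reading ROI placement variability.

    ``perturb_radius_px`` bounds the uniform dilation/erosion applied to
    each ring boundary per reading; ``angle_jitter_deg`` is the SD of the
    sector-placement jitter (whole-wall rings are angle-free).  Zero
    perturbation reproduces the reference masks exactly.
    """

    perturb_radius_px: float = 0.5
    angle_jitter_deg: float = 5.0


@dataclass(frozen=True)
class PopulationEffects:
    """Synthetic stand-in effect sizes for the population generator.

    These are config-declared defaults (no measured cohort backs them):
    systole thickens the wall and decorrelates the texture slightly, males
    carry a larger ring (the LV-mass analog), and texture noise drifts up
    across age bands.
    """

    es_thickness_factor: float = 1.35
    es_theta_shift: float = -0.04     # added to theta1/theta3 at ES
    es_gain_factor: float = 1.15
    male_radius_factor: float = 1.12
    age_gain_slope: float = 0.05      # fractional texture-gain step per band
    age_theta_shift: float = -0.01    # theta1/theta3 step per band
    lvm_radius_sd: float = 0.05       # between-subject ring-size scatter


@dataclass
class Subject:
    """One synthetic subject: image(s), masks, and design covariates."""

    subject_id: str
    image: GrayImage
    masks: dict[str, RoiMask]
    meta: dict = field(default_factory=dict)
    readings: dict[tuple[int, int], dict[str, RoiMask]] | None = None
    phases: dict[str, tuple[GrayImage, dict[str, RoiMask]]] | None = None


def synthesize_ar_field(
    shape: tuple[int, int],
    theta,
    innovation_sd: float,
    rng: np.random.Generator,
    burn_in: int = 32,
) -> np.ndarray:
    """Stationary causal AR field over a full raster.

    L(x,y) = t1*L(x-1,y) + t2*L(x-1,y-1) + t3*L(x,y-1) + t4*L(x+1,y-1) + e,
    synthesized by raster scan on a padded raster (transient trimmed), with
    e white Gaussian of SD ``innovation_sd``.  The recursion along each row
    is an AR(1) in the column index and is run with a linear filter, so the
    scan is vectorized row-wise.
    """
    t1, t2, t3, t4 = (float(t) for t in theta)
    H = shape[0] + burn_in
    W = shape[1] + 2 * burn_in
    e = rng.normal(0.0, innovation_sd, size=(H, W))
    L = np.zeros((H, W))
    for r in range(H):
        prev = L[r - 1] if r else np.zeros(W)
        drive = e[r] + t3 * prev
        drive[1:] += t2 * prev[:-1]
        drive[:-1] += t4 * prev[1:]
        L[r] = lfilter([1.0], [1.0, -t1], drive) if t1 else drive
    return L[burn_in:, burn_in:burn_in + shape[1]]


def _masks_for(spec: PhantomSpec,
               r_inner: float | None = None,
               r_outer: float | None = None,
               septal_angle: float = SEPTAL_ANGLE_DEG,
               lateral_angle: float = LATERAL_ANGLE_DEG) -> dict[str, RoiMask]:
    ri = spec.r_inner if r_inner is None else r_inner
    ro = spec.r_outer if r_outer is None else r_outer
    ring = annulus_mask(spec.shape, spec.center, ri, ro, "whole_wall")
    return {
        "whole_wall": ring,
        "septal": carve_sector(ring, spec.center, septal_angle,
                               SECTOR_SPAN_DEG, "septal"),
        "lateral": carve_sector(ring, spec.center, lateral_angle,
                                SECTOR_SPAN_DEG, "lateral"),
    }


def _focal_bumps(spec: PhantomSpec, ring: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Sum of Gaussian-profile bumps with N(0, blob_amp) amplitudes.

    Bump density is fixed per unit wall area (count deterministic given the
    ring size; positions drawn among ring pixels), so the inclusion load is
    an intensive texture property of the wall.
    """
    n = int(round(spec.blob_density * ring.sum()))
    out = np.zeros(spec.shape)
    if n == 0:
        return out
    ring_rc = np.argwhere(ring)
    centers = ring_rc[rng.choice(len(ring_rc), size=n, replace=False)]
    centers = centers + rng.uniform(-0.5, 0.5, size=centers.shape)
    amps = rng.normal(0.0, spec.blob_amp, size=n)
    rows, cols = np.indices(spec.shape)
    s2 = 2.0 * spec.blob_sigma**2
    for (cr, cc), a in zip(centers, amps):
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        out += a * np.exp(-d2 / s2)
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, dict[str, RoiMask]]:
    """Render one phantom image and its whole-wall/septal/lateral masks."""
    rng = np.random.default_rng(spec.seed)
    masks = _masks_for(spec)
    ring = masks["whole_wall"].mask

    # the textured band extends a margin beyond the nominal contours: real
    # myocardium has no step edge exactly at the drawn boundary, and
    # observer re-draws must disagree within wall-like tissue
    rows, cols = np.indices(spec.shape)
    r = np.hypot(rows - spec.center[0], cols - spec.center[1])
    pad_in = max(1.0, spec.r_inner - spec.wall_pad)
    band = (r >= pad_in) & (r < spec.r_outer + spec.wall_pad)
    blood = r < pad_in

    img = spec.background_base + rng.normal(0.0, spec.noise_sd, spec.shape)
    img[blood] = spec.blood_base + rng.normal(0.0, spec.noise_sd, int(blood.sum()))
    wall_tex = synthesize_ar_field(spec.shape, spec.theta,
                                   spec.innovation_sd, rng)
    wall_tex = wall_tex / wall_tex.std()
    if spec.blob_density > 0:
        wall_tex = wall_tex + _focal_bumps(spec, band, rng)
    img[band] = spec.wall_base + spec.texture_gain * wall_tex[band]
    img = np.clip(np.rint(img), 0, None).astype(np.int64)
    return GrayImage(img), masks


def _subject_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_size_cohort(
    n_per_group: int = 10,
    area_ratios=(0.6, 1.0, 1.5),
    base_spec: PhantomSpec = PhantomSpec(),
    area_jitter: float = 0.10,
    seed: int = 0,
) -> list[Subject]:
    """Three ring-size groups with identical texture parameters.

    Group ROI areas scale by ``area_ratios`` (radii by their square root);
    each subject's area is additionally jittered by up to
    ``+/- area_jitter``.  Texture parameters are shared by construction, so
    any feature-vs-area correlation reflects ROI size alone.
    """
    labels = ("low", "median", "high")
    if len(area_ratios) != len(labels):
        raise ValueError("expected three area ratios")
    seeds = _subject_seeds(seed, n_per_group * len(area_ratios))
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    out: list[Subject] = []
    k = 0
    for label, ratio in zip(labels, area_ratios):
        for i in range(n_per_group):
            scale = np.sqrt(ratio * (1.0 + rng.uniform(-area_jitter, area_jitter)))
            spec = replace(base_spec,
                           r_inner=base_spec.r_inner * scale,
                           r_outer=base_spec.r_outer * scale,
                           seed=seeds[k])
            image, masks = generate_phantom(spec)
            out.append(Subject(
                subject_id=f"{label}{i:02d}",
                image=image, masks=masks,
                meta={"size_group": label, "area_ratio": ratio,
                      "area": masks["whole_wall"].area, "seed": seeds[k]},
            ))
            k += 1
    return out


def _perturbed_masks(spec: PhantomSpec, model: ObserverModel,
                     rng: np.random.Generator) -> dict[str, RoiMask]:
    pr = model.perturb_radius_px
    di = rng.uniform(-pr, pr) if pr > 0 else 0.0
    do = rng.uniform(-pr, pr) if pr > 0 else 0.0
    ja = (rng.normal(0.0, model.angle_jitter_deg)
          if model.angle_jitter_deg > 0 else 0.0)
    jb = (rng.normal(0.0, model.angle_jitter_deg)
          if model.angle_jitter_deg > 0 else 0.0)
    return _masks_for(spec,
                      r_inner=max(2.0, spec.r_inner + di),
                      r_outer=max(spec.r_inner + di + 2.0, spec.r_outer + do),
                      septal_angle=SEPTAL_ANGLE_DEG + ja,
                      lateral_angle=LATERAL_ANGLE_DEG + jb)


def generate_repeatability_cohort(
    n: int = 30,
    observer_model: ObserverModel = ObserverModel(),
    base_spec: PhantomSpec = PhantomSpec(),
    phases: tuple[str, ...] = ("ED", "ES"),
    es_thickness_factor: float = 1.35,
    seed: int = 0,
) -> list[Subject]:
    """Fixed images, per-reading perturbed masks: obs1 x 2 reads + obs2.

    ``readings`` holds masks keyed by ``(observer, reading)``: (1, 1) is
    the reference contour (exact geometry), (1, 2) the intra-observer
    repeat, (2, 1) the second observer.  With a zero observer model all
    three are identical.
    """
    seeds = _subject_seeds(seed, n)
    out: list[Subject] = []
    for i in range(n):
        sub_ss = np.random.SeedSequence(seeds[i])
        phase_entries: dict[str, tuple] = {}
        for p_idx, phase in enumerate(phases):
            pseed = int(sub_ss.generate_state(2)[p_idx] % (2**31))
            spec = base_spec
            if phase == "ES":
                thick = (base_spec.r_outer - base_spec.r_inner) * es_thickness_factor
                spec = replace(base_spec,
                               r_inner=base_spec.r_outer - thick
                               if base_spec.r_outer - thick > 2.0 else 2.0)
            spec = replace(spec, seed=pseed)
            image, masks = generate_phantom(spec)
            obs_rng = np.random.default_rng(pseed + 1)
            readings = {
                (1, 1): masks,
                (1, 2): _perturbed_masks(spec, observer_model, obs_rng),
                (2, 1): _perturbed_masks(spec, observer_model, obs_rng),
            }
            phase_entries[phase] = (image, masks, readings)
        image, masks, readings = phase_entries[phases[0]]
        out.append(Subject(
            subject_id=f"sub{i:03d}", image=image, masks=masks,
            readings=readings,
            phases={p: (img, {"masks": mk, "readings": rd})
                    for p, (img, mk, rd) in phase_entries.items()},
            meta={"seed": seeds[i]},
        ))
    return out


AGE_BANDS = ("<=45", "46-54", "55-63", ">=64")


def generate_population(
    n: int = 600,
    effects: PopulationEffects = PopulationEffects(),
    base_spec: PhantomSpec = PhantomSpec(),
    female_fraction: float = 0.6,
    seed: int = 0,
) -> list[Subject]:
    """Phase/sex/age-structured population with an ED and an ES phantom each.

    Subjects are split into four equal age bands; sex within band follows
    ``female_fraction``.  The ring-size analog of LV mass is drawn per sex
    and restricted to within one SD of the sex mean (extreme sizes are
    redrawn), so size effects do not masquerade as texture effects.
    """
    if n % len(AGE_BANDS):
        raise ValueError("n must be divisible by the four age bands")
    per_band = n // len(AGE_BANDS)
    seeds = _subject_seeds(seed, n)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(2)[1])
    out: list[Subject] = []
    k = 0
    for band_idx, band in enumerate(AGE_BANDS):
        n_female = int(round(per_band * female_fraction))
        sexes = ["F"] * n_female + ["M"] * (per_band - n_female)
        for sex in sexes:
            sex_factor = 1.0 if sex == "F" else effects.male_radius_factor
            # LVM analog: ring scale, truncated at +/- 1 SD of its sex mean
            z = rng.normal()
            while abs(z) > 1.0:
                z = rng.normal()
            scale = sex_factor * (1.0 + effects.lvm_radius_sd * z)
            gain = base_spec.texture_gain * (1.0
                                             + effects.age_gain_slope * band_idx)
            th = list(base_spec.theta)
            th[0] += effects.age_theta_shift * band_idx
            th[2] += effects.age_theta_shift * band_idx
            sub_ss = np.random.SeedSequence(seeds[k])
            ph_seeds = sub_ss.generate_state(2) % (2**31)

            ed_spec = replace(base_spec,
                              r_inner=base_spec.r_inner * scale,
                              r_outer=base_spec.r_outer * scale,
                              texture_gain=gain, theta=tuple(th),
                              seed=int(ph_seeds[0]))
            thick = (ed_spec.r_outer - ed_spec.r_inner) * effects.es_thickness_factor
            th_es = list(th)
            th_es[0] += effects.es_theta_shift
            th_es[2] += effects.es_theta_shift
            es_spec = replace(ed_spec,
                              r_inner=max(2.0, ed_spec.r_outer - thick),
                              texture_gain=gain * effects.es_gain_factor,
                              theta=tuple(th_es), seed=int(ph_seeds[1]))

            ed_img, ed_masks = generate_phantom(ed_spec)
            es_img, es_masks = generate_phantom(es_spec)
            out.append(Subject(
                subject_id=f"pop{k:04d}",
                image=ed_img, masks=ed_masks,
                phases={"ED": (ed_img, ed_masks), "ES": (es_img, es_masks)},
                meta={"sex": sex, "age_band": band, "seed": seeds[k],
                      "lvm_scale": scale},
            ))
            k += 1
    return out


def cohort_manifest(subjects: list[Subject]) -> pd.DataFrame:
    """Flat per-subject covariate table for a generated cohort."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update(s.meta)
        rows.append(row)
    return pd.DataFrame(rows)
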