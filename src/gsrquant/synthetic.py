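"""Ground-truthed synthetic scenes for validating the pipeline.

The study's photographs are not deposited, so every pipeline stage is
exercised on procedurally generated scenes whose ground truth is known
exactly: a fabric background with the statistical structure the filters
assume, dark residue particles scattered radially around the aim point,
and optional blood overlays whose darkness depends on modality and on
whether the blood is wet or dry.

The generator encodes only *ordinal* facts observed on real material —
denim is brighter in IR than in visible light, dried blood is lighter
than wet blood in IR, wet blood under flash shows specular highlights in
visible light — not measured reflectances.  All rendering constants live
in the ``RENDER`` block below.  Everything is deterministic under
``(params, seed)``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

from .imaging import CalibratedImage, Fabric, Modality

__all__ = ["BloodState", "BloodParams", "SceneParams", "GroundTruth",
           "GenerationError", "generate_fabric_texture", "plant_particles",
           "add_blood", "generate_scene", "render_pair", "RENDER"]


class GenerationError(RuntimeError):
    """Raised when a scene cannot be realized (e.g. particles don't fit)."""


class BloodState(enum.Enum):
    WET = "wet"
    DRY = "dry"


#: Rendering constants (unit-interval intensities).  These encode ordinal
#: observations only: denim brighter in IR than VL; dry blood lighter
#: than wet in IR; blood very dark in VL with specular flash highlights.
RENDER = {
    "white_base": 0.85,
    "denim_base": {Modality.IR: 0.55, Modality.VL: 0.25},
    "tape_base": 0.92,
    "particle_intensity": (0.05, 0.15),
    "defect_intensity": 0.02,
    "blood": {
        (Modality.VL, BloodState.WET): 0.10,
        (Modality.VL, BloodState.DRY): 0.15,
        (Modality.IR, BloodState.WET): 0.35,
        (Modality.IR, BloodState.DRY): 0.55,
    },
    "highlight_intensity": 0.95,
    "gradient_amplitude": 0.05,
    "white_weave_amplitude": 0.02,
    "white_weave_frequency": 128.0,   # cycles/width -> 4 px period at 512
    "denim_twill_amplitude": 0.12,
    "denim_coarse_amplitude": 0.04,
    "denim_coarse_frequency": 2.0,
    "tape_mottle_amplitude": 0.02,
}

#: Minimum clearance between planted discs (pixels).  2.2 px between disc
#: boundaries guarantees no two particles share or 8-touch a pixel, so a
#: non-overlap scene has exactly n_particles truth components.
_CLEARANCE = 2.2


@dataclass(frozen=True)
class BloodParams:
    """Blood overlay description: state, target area fraction, droplets."""

    state: BloodState = BloodState.WET
    coverage: float = 0.15
    droplet_count: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.coverage > 0.9:
            raise ValueError("coverage > 0.9 leaves no interpretable scene")
        if self.droplet_count < 0:
            raise ValueError("droplet_count must be >= 0")


@dataclass(frozen=True)
class SceneParams:
    """Forward-model parameters of one synthetic scene.

    ``dispersion`` is the radial scale (standard deviation, pixels) of
    the isotropic Gaussian particle scatter around the scene centre;
    ``None`` defaults to 0.3 * min(height, width).  ``twill_frequency``
    is the per-axis frequency of the denim twill in cycles per image
    width (the diagonal weave period is width / (sqrt(2) * f) pixels).
    """

    fabric: Fabric = Fabric.WHITE_COTTON
    height: int = 512
    width: int = 512
    n_particles: int = 200
    particle_radius_range: tuple[float, float] = (1.0, 2.0)
    dispersion: float | None = None
    defect_radius: float | None = None
    blood: BloodParams | None = None
    noise_sd: float = 0.01
    gradient_amplitude: float = RENDER["gradient_amplitude"]
    twill_frequency: float = 90.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("scene must be at least 8x8")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        lo, hi = self.particle_radius_range
        if not (1.0 <= lo <= hi):
            raise ValueError("particle radii must satisfy 1 <= min <= max")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.defect_radius is not None and self.defect_radius <= 0:
            raise ValueError("defect_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def effective_dispersion(self) -> float:
        if self.dispersion is not None:
            return self.dispersion
        return 0.3 * min(self.height, self.width)

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene description: what a perfect detector would recover."""

    centers: np.ndarray          # (n, 2) float, (row, col)
    radii: np.ndarray            # (n,) float
    truth_mask: np.ndarray       # bool, union of particle discs minus defect
    blood_mask: np.ndarray       # bool
    defect_mask: np.ndarray      # bool

    @property
    def n_particles(self) -> int:
        return len(self.radii)


# ---------------------------------------------------------------------------
# fabric textures

def _coords(height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    return np.mgrid[0:height, 0:width].astype(np.float64)


def _illumination_gradient(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Slow (~1 cycle) illumination modulation with a random orientation."""
    if params.gradient_amplitude == 0:
        return np.zeros((params.height, params.width))
    yy, xx = _coords(params.height, params.width)
    phase = rng.uniform(0, 2 * np.pi)
    theta = rng.uniform(0, 2 * np.pi)
    u = (np.cos(theta) * xx / params.width + np.sin(theta) * yy / params.height)
    return params.gradient_amplitude * np.sin(2 * np.pi * u + phase)


def generate_fabric_texture(params: SceneParams,
                            modality: Modality | None = None) -> CalibratedImage:
    """Particle-free fabric (or tape) background.

    WHITE_COTTON: bright base with a smooth illumination gradient and a
    fine orthogonal weave.  DENIM: mid-bright base (brighter in IR than
    VL) with a periodic diagonal twill in a known high-frequency band, a
    coarse yarn modulation at a few cycles, and the same gradient.  TAPE:
    pale, nearly uniform.  Deterministic under the scene seed.
    """
    if modality is None:
        modality = {Fabric.DENIM: Modality.IR,
                    Fabric.TAPE: Modality.TAPE_SCAN}.get(params.fabric, Modality.VL)
    rng = np.random.default_rng([params.seed, 0, _modality_index(modality)])
    h, w = params.height, params.width
    yy, xx = _coords(h, w)

    if params.fabric is Fabric.WHITE_COTTON:
        base = RENDER["white_base"]
        f = RENDER["white_weave_frequency"]
        weave = RENDER["white_weave_amplitude"] * (
            np.sin(2 * np.pi * f * xx / w) + np.sin(2 * np.pi * f * yy / w)) / 2.0
        tex = base + weave + _illumination_gradient(params, rng)
    elif params.fabric is Fabric.DENIM:
        base = RENDER["denim_base"][modality] if modality in RENDER["denim_base"] \
            else RENDER["denim_base"][Modality.IR]
        f = params.twill_frequency
        twill = RENDER["denim_twill_amplitude"] * np.sin(
            2 * np.pi * f * (xx + yy) / w)
        fc = RENDER["denim_coarse_frequency"]
        coarse = RENDER["denim_coarse_amplitude"] * np.sin(
            2 * np.pi * fc * yy / w + rng.uniform(0, 2 * np.pi))
        tex = base + twill + coarse + _illumination_gradient(params, rng)
    elif params.fabric is Fabric.TAPE:
        base = RENDER["tape_base"]
        mottle = RENDER["tape_mottle_amplitude"] * np.sin(
            2 * np.pi * 3.0 * xx / w + rng.uniform(0, 2 * np.pi))
        tex = base + mottle
    else:
        raise ValueError(f"no texture model for fabric {params.fabric}")

    if params.noise_sd > 0:
        tex = tex + rng.normal(0.0, params.noise_sd, size=(h, w))
    img = CalibratedImage(np.clip(tex, 0.0, 1.0), modality=modality,
                          fabric=params.fabric)
    return img


def _modality_index(m: Modality) -> int:
    return {Modality.VL: 0, Modality.IR: 1, Modality.TAPE_SCAN: 2}[m]


# ---------------------------------------------------------------------------
# particle placement

def _sample_centres(params: SceneParams, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-scattered, frame-clipped, optionally non-overlapping discs.

    Rejection sampling with a uniform-grid occupancy index; the grid cell
    is the largest possible exclusion distance so conflicts are always in
    the 3x3 cell neighbourhood.
    """
    n = params.n_particles
    lo, hi = params.particle_radius_range
    cy, cx = params.centre
    sigma = params.effective_dispersion
    h, w = params.height, params.width
    defect_r = params.defect_radius or 0.0

    radii = rng.uniform(lo, hi, size=n)
    centres = np.empty((n, 2))
    cell = 2 * hi + _CLEARANCE
    grid: dict[tuple[int, int], list[int]] = {}
    budget = max(2000, 400 * n)
    attempts = 0
    for i in range(n):
        r = radii[i]
        while True:
            attempts += 1
            if attempts > budget:
                raise GenerationError(
                    f"could not place {n} non-overlapping particles of radius "
                    f"{lo}-{hi} in a {h}x{w} frame (dispersion {sigma:.0f}); "
                    "reduce n_particles or increase dispersion")
            y = rng.normal(cy, sigma)
            x = rng.normal(cx, sigma)
            if not (r + 1 <= y <= h - 2 - r and r + 1 <= x <= w - 2 - r):
                continue
            if defect_r and math.hypot(y - cy, x - cx) < defect_r + r + _CLEARANCE:
                continue
            if not params.allow_overlap:
                gy, gx = int(y / cell), int(x / cell)
                conflict = False
                for ny in (gy - 1, gy, gy + 1):
                    for nx in (gx - 1, gx, gx + 1):
                        for j in grid.get((ny, nx), ()):
                            dy = y - centres[j, 0]
                            dx = x - centres[j, 1]
                            if math.hypot(dy, dx) < r + radii[j] + _CLEARANCE:
                                conflict = True
                                break
                        if conflict:
                            break
                    if conflict:
                        break
                if conflict:
                    continue
                grid.setdefault((gy, gx), []).append(i)
            centres[i] = (y, x)
            break
    return centres, radii


def _disc_mask(shape: tuple[int, int], centres: np.ndarray,
               radii: np.ndarray) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r in zip(centres, radii):
        y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
        x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
        y0, x0 = max(y0, 0), max(x0, 0)
        y1, x1 = min(y1, shape[0]), min(x1, shape[1])
        if y1 <= y0 or x1 <= x0:  # disc entirely outside the frame
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    return mask


def plant_particles(bg: CalibratedImage, params: SceneParams
                    ) -> tuple[CalibratedImage, GroundTruth]:
    """Scatter dark residue discs over a background and record the truth.

    Centres follow an isotropic bivariate normal around the scene centre
    (scale = dispersion), rejection-sampled to the frame, away from the
    optional central defect, and (by default) to mutual non-overlap.
    Each particle darkens its disc to an intensity drawn from the
    particle band.  The defect, when present, is rendered as a dark hole.
    """
    shape = (bg.height, bg.width)
    if shape != (params.height, params.width):
        raise ValueError("background shape does not match scene params")
    rng = np.random.default_rng([params.seed, 1])
    pixels = bg.pixels.copy()

    defect_mask = np.zeros(shape, dtype=bool)
    if params.defect_radius:
        cy, cx = params.centre
        defect_mask = _disc_mask(shape, np.array([[cy, cx]]),
                                 np.array([params.defect_radius]))
        pixels[defect_mask] = RENDER["defect_intensity"]

    if params.n_particles == 0:
        truth = GroundTruth(np.empty((0, 2)), np.empty(0),
                            np.zeros(shape, dtype=bool),
                            np.zeros(shape, dtype=bool), defect_mask)
        return bg.with_pixels(pixels), truth

    centres, radii = _sample_centres(params, rng)
    lo_i, hi_i = RENDER["particle_intensity"]
    intensities = rng.uniform(lo_i, hi_i, size=len(radii))

    truth_mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r, inten in zip(centres, radii, intensities):
        disc = _disc_mask(shape, np.array([[cy, cx]]), np.array([r]))
        pixels[disc] = inten
        truth_mask |= disc
    truth_mask &= ~defect_mask

    truth = GroundTruth(centres, radii, truth_mask,
                        np.zeros(shape, dtype=bool), defect_mask)
    return bg.with_pixels(np.clip(pixels, 0.0, 1.0)), truth


# ---------------------------------------------------------------------------
# blood overlay

def add_blood(img: CalibratedImage, truth: GroundTruth, params: SceneParams
              ) -> tuple[CalibratedImage, GroundTruth]:
    """Overlay irregular blood blobs plus satellite droplets.

    Blob placement follows the same central scatter as the particles.
    The fill intensity depends on (modality, state): blood is very dark
    in visible light regardless of state, while in infrared dried blood
    is distinctly lighter than wet blood.  In visible light, wet blood
    additionally carries sparse specular flash highlights.
    """
    if params.blood is None or params.blood.coverage == 0:
        return img, truth
    bp = params.blood
    rng = np.random.default_rng([params.seed, 2])
    shape = (img.height, img.width)
    h, w = shape
    cy, cx = params.centre
    sigma = params.effective_dispersion

    target = bp.coverage * h * w
    blood_mask = np.zeros(shape, dtype=bool)
    base_r = max(4.0, 0.06 * min(h, w))
    for _ in range(4000):
        if blood_mask.sum() >= target:
            break
        by = np.clip(rng.normal(cy, sigma), 0, h - 1)
        bx = np.clip(rng.normal(cx, sigma), 0, w - 1)
        # one irregular blob: a few overlapping jittered discs
        k = rng.integers(3, 7)
        offs = rng.normal(0.0, base_r * 0.6, size=(k, 2))
        rr = rng.uniform(0.5 * base_r, base_r, size=k)
        blood_mask |= _disc_mask(shape, np.array([by, bx]) + offs, rr)

    # satellite droplets, scattered wider than the blobs
    droplet_centres = np.column_stack([
        np.clip(rng.normal(cy, 1.5 * sigma, bp.droplet_count), 1, h - 2),
        np.clip(rng.normal(cx, 1.5 * sigma, bp.droplet_count), 1, w - 2)])
    droplet_radii = rng.uniform(1.0, 2.5, size=bp.droplet_count)
    if bp.droplet_count:
        blood_mask |= _disc_mask(shape, droplet_centres, droplet_radii)

    level = RENDER["blood"].get((img.modality, bp.state))
    if level is None:  # tape scans carry no blood; fall back to VL rendering
        level = RENDER["blood"][(Modality.VL, bp.state)]
    pixels = img.pixels.copy()
    pixels[blood_mask] = np.clip(
        level + rng.normal(0.0, params.noise_sd, size=int(blood_mask.sum())),
        0.0, 1.0)

    if img.modality is Modality.VL and bp.state is BloodState.WET and bp.droplet_count:
        # flash reflections: one specular pixel per droplet
        for (dy, dx) in droplet_centres:
            pixels[int(round(dy)), int(round(dx))] = RENDER["highlight_intensity"]

    new_truth = replace(truth, blood_mask=blood_mask)
    return img.with_pixels(pixels), new_truth


# ---------------------------------------------------------------------------
# scene assembly

def generate_scene(params: SceneParams, modality: Modality | None = None
                   ) -> tuple[CalibratedImage, GroundTruth]:
    """Full forward model: texture -> particles -> blood.

    The particle and blood geometry streams are seeded independently of
    the modality, so rendering the same params under VL and IR yields the
    same scene geometry with modality-appropriate intensities.
    """
    bg = generate_fabric_texture(params, modality)
    img, truth = plant_particles(bg, params)
    return add_blood(img, truth, params)


def render_pair(params: SceneParams
                ) -> tuple[tuple[CalibratedImage, GroundTruth],
                           tuple[CalibratedImage, GroundTruth]]:
    """Render one scene geometry under visible light and infrared."""
    return (generate_scene(params, Modality.VL),
            generate_scene(params, Modality.IR))


# ---------------------------------------------------------------------------
# tape scans

def generate_tape_scan(params: SceneParams):
    """RGB scan of a chemically developed tape lift.

    Residue spots develop to a dark violet; the tape background is pale
    and nearly colourless.  Returns (RGBImage, GroundTruth).
    """
    from .imaging import RGBImage  # local import avoids cycle at module load

    p = replace(params, fabric=Fabric.TAPE)
    bg = generate_fabric_texture(p, Modality.TAPE_SCAN)
    img, truth = plant_particles(bg, p)
    rng = np.random.default_rng([p.seed, 3])
    v = img.pixels
    h, w = v.shape
    # pale warm background: R slightly above G above B at equal value
    rgb = np.stack([v, v * 0.985, v * 0.96], axis=2)
    # violet spots: depress green strongly, keep some red/blue
    spot = truth.truth_mask
    rgb[spot, 0] = v[spot] * 1.0
    rgb[spot, 1] = v[spot] * 0.35
    rgb[spot, 2] = v[spot] * 0.8
    return RGBImage(np.clip(rgb, 0.0, 1.0), l_pixel=None), truth
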