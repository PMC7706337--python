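"""Parametric plant renderer for the synthetic experiment.

Draws a stylised tomato plant — a vertical stem with elliptical leaves — on a
uniform mid-blue background in the three platform views (side 0°, side 90°,
top), in RGB and in NIR greyscale, as 8-bit images. The geometry is driven by
the latent plant state:

* total plant pixel area in a side view is proportional to biomass,
* vertical extent equals the latent (wilting-inclusive) height in pixels,
* leaf droop in side views and rosette spread in the top view shrink as
  turgor falls (raising top-view compactness),
* the fraction of leaf pixels drawn in the yellow (chlorotic) hue band equals
  ``chlorosis_frac`` to within rounding,
* NIR leaf intensity is an affine map of hydration.

The renderer also returns its own ground-truth masks, which downstream
segmentation is tested against.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import disk, ellipse, line

from .imaging import PlantImageSet
from .synthetic import GeneratorConfig, PlantStateTrajectory

__all__ = [
    "BACKGROUND_RGB",
    "NIR_BACKGROUND",
    "render_view",
    "render_plant_images",
    "nir_level",
]

BACKGROUND_RGB = (70, 90, 180)   # uniform mid-blue, hue far from vegetation
NIR_BACKGROUND = 20
GREEN_RGB = (40, 160, 40)        # hue 120 deg
YELLOW_RGB = (210, 180, 30)      # hue 50 deg, chlorotic band
STEM_RGB = (60, 140, 40)
N_LEAVES = 8


def nir_level(hydration: float) -> int:
    """Affine hydration -> NIR intensity map for plant pixels."""
    return int(round(np.clip(55.0 + 180.0 * hydration, 0, 255)))


def _thick_line(mask: np.ndarray, r0: float, c0: float, r1: float, c1: float) -> None:
    """Draw a 2-px-wide line segment into a boolean mask (clipped)."""
    size = mask.shape[0]
    rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    for dr, dc in ((0, 0), (0, 1), (1, 0)):
        r = np.clip(rr + dr, 0, size - 1)
        c = np.clip(cc + dc, 0, size - 1)
        mask[r, c] = True


def _side_geometry(
    size: int,
    area_px: float,
    height_px: float,
    turgor: float,
    phase: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise stem and leaves for one side view.

    Returns boolean (stem_mask, leaf_mask). Leaves are placed on alternating
    sides at distinct heights so their union area tracks the analytic target.
    """
    ground = size - 8
    height = int(round(min(height_px, ground - 2)))
    height = max(height, 4)
    col = size // 2

    w_stem = max(2, int(round(0.04 * height)))
    stem = np.zeros((size, size), dtype=bool)
    top_row = ground - height + 1
    stem[top_row : ground + 1, col - w_stem // 2 : col - w_stem // 2 + w_stem] = True
    stem_area = int(stem.sum())

    leaf_area = max(float(area_px) - stem_area, 0.0)
    leaves = np.zeros((size, size), dtype=bool)
    if leaf_area > 0:
        a_leaf = leaf_area / N_LEAVES
        a = np.sqrt(2.0 * a_leaf / np.pi)  # semi-major; b = a/2
        b = a / 2.0
        theta = np.deg2rad(10.0 + 55.0 * (1.0 - turgor))
        for i in range(N_LEAVES):
            side = 1 if (i + phase) % 2 == 0 else -1
            attach = ground - int(round(height * (i + 1) / (N_LEAVES + 1)))
            cr = attach + a * np.sin(theta)
            cc = col + side * (w_stem / 2.0 + 1.0 + a * np.cos(theta))
            rr, cc_px = ellipse(cr, cc, b, a, rotation=side * theta, shape=(size, size))
            keep = (rr <= ground) & (rr >= top_row)
            leaves[rr[keep], cc_px[keep]] = True
            # short petiole bridges the stem and the leaf's inner tip; it is
            # kept short (and mostly under the leaf) so side-view area stays
            # proportional to biomass
            pet = np.zeros_like(stem)
            _thick_line(
                pet,
                attach,
                col,
                min(attach + 0.3 * (cr - attach), ground),
                col + side * (w_stem / 2.0 + 1.0 + 0.3 * a * np.cos(theta)),
            )
            stem |= pet
    leaves &= ~stem
    return stem, leaves


def _top_geometry(
    size: int, area_px: float, turgor: float, phase_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the top-view rosette; spread shrinks as turgor falls."""
    c0 = size / 2.0
    stem = np.zeros((size, size), dtype=bool)
    rr, cc = disk((c0, c0), 2.5, shape=(size, size))
    stem[rr, cc] = True

    leaf_area = max(float(area_px) - stem.sum(), 0.0)
    leaves = np.zeros((size, size), dtype=bool)
    if leaf_area > 0:
        a = np.sqrt(2.0 * (leaf_area / N_LEAVES) / np.pi)
        b = a / 2.0
        spread = 0.35 + 0.65 * float(np.clip(turgor, 0.0, 1.0))
        dist = min(2.2 * a * spread + 0.2 * a, c0 - a - 4.0)
        for i in range(N_LEAVES):
            ang = np.deg2rad(360.0 * i / N_LEAVES + phase_deg)
            cr = c0 + dist * np.sin(ang)
            cc_ = c0 + dist * np.cos(ang)
            rr, cc_px = ellipse(cr, cc_, b, a, rotation=-ang, shape=(size, size))
            leaves[rr, cc_px] = True
            pet = np.zeros_like(stem)
            _thick_line(pet, c0, c0, cr, cc_)
            stem |= pet
    leaves &= ~stem
    return stem, leaves


def _colorize(
    stem: np.ndarray,
    leaves: np.ndarray,
    chlorosis_frac: float,
) -> np.ndarray:
    """RGB image: uniform background, green stem, leaves split green/yellow.

    The chlorotic fraction is taken from the bottom of the canopy (older
    leaves yellow first), so the yellow-pixel fraction of all leaf pixels
    equals ``chlorosis_frac`` to within one pixel of rounding.
    """
    size = stem.shape[0]
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:, :] = BACKGROUND_RGB
    img[stem] = STEM_RGB
    rr, cc = np.nonzero(leaves)
    if len(rr):
        order = np.argsort(-rr, kind="stable")  # bottom rows first
        n_yellow = int(round(float(np.clip(chlorosis_frac, 0, 1)) * len(rr)))
        yellow = order[:n_yellow]
        green = order[n_yellow:]
        img[rr[yellow], cc[yellow]] = YELLOW_RGB
        img[rr[green], cc[green]] = GREEN_RGB
    return img


def _nir_image(
    mask: np.ndarray, hydration: float, rng: np.random.Generator
) -> np.ndarray:
    size = mask.shape[0]
    img = np.full((size, size), NIR_BACKGROUND, dtype=float)
    img[mask] = nir_level(hydration)
    img[mask] += 1.5 * rng.standard_normal(int(mask.sum()))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_view(
    view: str,
    size: int,
    area_px: float,
    height_px: float,
    turgor: float,
    chlorosis_frac: float,
    hydration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one view; returns (rgb, nir, truth_mask)."""
    if view == "top":
        stem, leaves = _top_geometry(size, area_px, turgor, phase_deg=22.5)
    elif view in ("side0", "side90"):
        stem, leaves = _side_geometry(
            size, area_px, height_px, turgor, phase=0 if view == "side0" else 1
        )
    else:
        raise ValueError(f"unknown view {view!r}")
    mask = stem | leaves
    rgb = _colorize(stem, leaves, chlorosis_frac)
    nir = _nir_image(mask, hydration, rng)
    return rgb, nir, mask


def render_plant_images(
    state: PlantStateTrajectory,
    config: GeneratorConfig,
    day: int,
    rng: np.random.Generator | None = None,
) -> PlantImageSet:
    """Render the full three-view RGB+NIR image set of a plant on one day."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 303, abs(hash(state.plant_id)) % (2**31), day])
        )
    d = int(np.searchsorted(state.days, day))
    area = config.area_per_biomass_px * float(state.biomass[d])
    # drooping leaves present a smaller silhouette: side-view projected area
    # shrinks as turgor falls, so biovolume drops during wilting even while
    # structural biomass still creeps up
    side_proj = 0.55 + 0.45 * float(state.turgor[d])
    images: dict[tuple[str, str], np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for view in ("side0", "side90", "top"):
        rgb, nir, mask = render_view(
            view,
            config.image_size,
            area * (side_proj if view != "top" else 1.0),
            float(state.height_px[d]),
            float(state.turgor[d]),
            float(state.chlorosis_frac[d]),
            float(state.hydration[d]),
            rng,
        )
        images[(view, "rgb")] = rgb
        images[(view, "nir")] = nir
        masks[view] = mask
    return PlantImageSet(
        plant_id=state.plant_id, day=day, images=images, truth_masks=masks
    )
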