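"""Layered-retina OCT phantoms with ground-truth HRD annotations.

The generator emulates the features the pipeline actually keys on: a
bright inner band (NFL-like), a darker mid-retina, a bright outer band
(RPE-like), multiplicative speckle, and bright elliptical lesions of
controlled *physical* diameter on individual b-scans. Hard exudates are
rendered with an attenuated column ("back shadow") from the lesion bottom
to the RPE; small HRDs and sub-resolution noise dots cast no shadow.

Diameters are controlled in the same convention the classifier measures:
physical Feret distance between pixel centres plus one in-plane pixel
diagonal. The axial pixel run is chosen by ceiling so the rendered lesion
measures at or just above the requested diameter, which keeps every
lesion on the intended side of the 20/40 μm rule thresholds.

A second rater is simulated by perturbing the ground-truth mask
(boundary jitter, component drops, class flips).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from skimage import morphology

from .hrd_classify import (ConnectedComponent, HRDClass, classify_component,
                           physical_diameter)
from .volume_io import LabelMask, OCTVolume, topcon_spacing_um


@dataclasses.dataclass
class LayerModel:
    """Axial positions (fractions of depth) and reflectivities of the bands."""

    nfl_band: tuple[float, float] = (0.12, 0.20)
    mid_band: tuple[float, float] = (0.20, 0.72)
    rpe_band: tuple[float, float] = (0.75, 0.82)
    nfl_reflectivity: float = 0.55
    mid_reflectivity: float = 0.22
    rpe_reflectivity: float = 0.85
    vitreous_reflectivity: float = 0.04
    choroid_reflectivity: float = 0.12


@dataclasses.dataclass
class PhantomSpec:
    """Full description of one phantom volume.

    Lesion diameter ranges default to the operating definitions of the
    three particle categories: hard exudates 45-150 μm (shadow rendered),
    small HRDs 20-40 μm (no shadow), sub-threshold noise dots 8-18 μm.
    """

    shape: tuple[int, int, int] = (4, 256, 256)
    spacing_um: tuple[float, float, float] = dataclasses.field(default_factory=topcon_spacing_um)
    layers: LayerModel = dataclasses.field(default_factory=LayerModel)
    speckle_variance: float = 0.03
    n_hard_exudates: int = 4
    n_small_hrds: int = 6
    n_noise_dots: int = 5
    hard_exudate_diameter_um: tuple[float, float] = (45.0, 150.0)
    small_hrd_diameter_um: tuple[float, float] = (20.0, 40.0)
    noise_dot_diameter_um: tuple[float, float] = (8.0, 18.0)
    shadow_attenuation: float = 0.4
    hard_exudate_reflectivity: float = 0.85   # RPE-like
    small_hrd_reflectivity: float = 0.60      # NFL-like
    seed: int = 0

    def __post_init__(self):
        if self.small_hrd_diameter_um[0] < 20.0 or self.small_hrd_diameter_um[1] > 40.0:
            raise ValueError("small-HRD diameters must stay within [20, 40] μm")
        if self.hard_exudate_diameter_um[0] <= 40.0:
            raise ValueError("hard-exudate diameters must exceed 40 μm")
        if self.noise_dot_diameter_um[1] >= 20.0:
            raise ValueError("noise-dot diameters must stay below 20 μm")
        if not 0.0 < self.shadow_attenuation < 1.0:
            raise ValueError("shadow attenuation must be in (0,1)")


@dataclasses.dataclass
class LesionGT:
    """Ground truth for one rendered lesion."""

    bscan: int
    center_zx: tuple[int, int]
    diameter_um: float  # measured Feret diameter of the rendered component
    true_class: HRDClass
    shadow: bool
    n_pixels: int
    centroid_zx: tuple[float, float] = (float("nan"), float("nan"))  # exact pixel mean


@dataclasses.dataclass
class RaterNoiseSpec:
    """Perturbation model for a simulated second rater."""

    jitter_px: int = 0
    drop_probability: float = 0.0
    class_flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.drop_probability, self.class_flip_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.jitter_px < 0:
            raise ValueError("jitter must be non-negative")


def _lesion_footprint(diameter_um: float, sz: float, sx: float) -> np.ndarray:
    """Boolean (z, x) stamp whose measured Feret diameter ~= diameter_um.

    The target centre-to-centre extent is ``diameter - pixel diagonal``
    (floored at 0); the axial run is ceiled so the measured diameter never
    falls below the request.
    """
    diagonal = math.hypot(sz, sx)
    target = max(0.0, diameter_um - diagonal)
    if target <= 0:
        return np.ones((1, 1), dtype=bool)
    n_z = int(math.ceil(target / sz)) + 1
    az = max((n_z - 1) / 2.0, 1e-6)
    bx = max(target / (2.0 * sx), 1e-6)
    half_x = int(math.floor(bx))
    dz = np.arange(n_z) - (n_z - 1) / 2.0
    dx = np.arange(-half_x, half_x + 1)
    inside = (dz[:, None] / (az + 1e-9)) ** 2 + (dx[None, :] / (bx + 1e-9)) ** 2 <= 1.0 + 1e-9
    inside[:, half_x] |= True  # centre column always full height
    return inside


def _layer_image(shape_zx: tuple[int, int], layers: LayerModel) -> np.ndarray:
    nz, nx = shape_zx
    img = np.full((nz, nx), layers.vitreous_reflectivity)
    z = np.arange(nz)

    def band(frac_lo, frac_hi, value):
        lo, hi = int(frac_lo * nz), int(frac_hi * nz)
        img[(z >= lo) & (z < hi), :] = value

    band(*layers.mid_band, layers.mid_reflectivity)
    band(*layers.nfl_band, layers.nfl_reflectivity)
    band(*layers.rpe_band, layers.rpe_reflectivity)
    band(layers.rpe_band[1], 1.0, layers.choroid_reflectivity)
    return img


def generate_volume(spec: PhantomSpec) -> tuple[OCTVolume, LabelMask, list[LesionGT]]:
    """Render one phantom volume, its label mask, and per-lesion ground truth.

    Deterministic per ``spec.seed``; speckle never touches the mask. Raises
    if a requested lesion cannot be placed on the grid.
    """
    rng = np.random.default_rng(spec.seed)
    nb, nz, nx = spec.shape
    _, sz, sx = spec.spacing_um
    clean = np.stack([_layer_image((nz, nx), spec.layers)] * nb)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    occupied = np.zeros(spec.shape, dtype=bool)  # lesions + a guard margin
    rpe_top = int(spec.layers.rpe_band[0] * nz)
    mid_lo = int(spec.layers.mid_band[0] * nz)
    lesions: list[LesionGT] = []

    plan = (
        [(HRDClass.HARD_EXUDATE, spec.hard_exudate_diameter_um)] * spec.n_hard_exudates
        + [(HRDClass.SMALL_HRD, spec.small_hrd_diameter_um)] * spec.n_small_hrds
        + [(HRDClass.NOISE, spec.noise_dot_diameter_um)] * spec.n_noise_dots
    )
    for category, (dlo, dhi) in plan:
        d_req = float(rng.uniform(dlo, dhi))
        stamp = _lesion_footprint(d_req, sz, sx)
        hz, hx = stamp.shape
        # keep the whole lesion inside the mid-retina band, above the RPE
        # with room for the minimum shadow window
        z_min, z_max = mid_lo + 2, rpe_top - hz - 12
        if z_max <= z_min or hx + 2 >= nx:
            raise ValueError(
                f"lesion of {d_req:.1f} μm ({hz}x{hx} px) does not fit the "
                f"{nz}x{nx} grid's retina band")
        placed = False
        for _ in range(200):
            b = int(rng.integers(0, nb))
            z0 = int(rng.integers(z_min, z_max + 1))
            x0 = int(rng.integers(1, nx - hx - 1))
            # guard margin: keep shadows and flanks of neighbours separate
            gx = max(2, 3 * hx)
            sl_b = (b, slice(max(0, z0 - 2), min(nz, z0 + hz + 2)),
                    slice(max(0, x0 - gx), min(nx, x0 + hx + gx)))
            col_guard = (b, slice(z0, nz), slice(max(0, x0 - gx), min(nx, x0 + hx + gx)))
            if occupied[sl_b].any() or occupied[col_guard].any():
                continue
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place lesion of {d_req:.1f} μm after 200 tries")
        zz, xx = np.nonzero(stamp)
        zz, xx = zz + z0, xx + x0
        refl = (spec.hard_exudate_reflectivity if category is HRDClass.HARD_EXUDATE
                else spec.small_hrd_reflectivity)
        clean[b][zz, xx] = refl
        occupied[b][zz, xx] = True
        occupied[b, z0:nz, x0:x0 + hx] = True  # reserve the shadow column
        shadow = category is HRDClass.HARD_EXUDATE
        if shadow:
            clean[b][z0 + hz:rpe_top + (nz - rpe_top) // 3, x0:x0 + hx] *= spec.shadow_attenuation
        if category is not HRDClass.NOISE:
            labels[b][zz, xx] = category.label
        measured = physical_diameter(np.column_stack([zz, xx]), (sz, sx))
        assert classify_component(measured, shadow) is category, (
            f"rendered {category} measured {measured:.2f} μm")
        lesions.append(LesionGT(
            bscan=b, center_zx=(int(round(zz.mean())), int(round(xx.mean()))),
            diameter_um=measured, true_class=category, shadow=shadow,
            n_pixels=int(len(zz)), centroid_zx=(float(zz.mean()), float(xx.mean()))))

    if spec.speckle_variance > 0:
        k = 1.0 / spec.speckle_variance
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=spec.shape)
        voxels = np.clip(clean * speckle, 0.0, 1.0)
    else:
        voxels = np.clip(clean, 0.0, 1.0)
    return (OCTVolume(voxels, spec.spacing_um), LabelMask(labels, spec.spacing_um), lesions)


def simulate_rater(mask: LabelMask, noise: RaterNoiseSpec) -> LabelMask:
    """Perturb a label mask the way an independent human rater might.

    Per component: drop entirely with ``drop_probability``; flip class
    (hard exudate <-> small HRD) with ``class_flip_probability``; dilate or
    erode the boundary by up to ``jitter_px`` iterations. All-zero noise
    returns a mask identical to the input.
    """
    rng = np.random.default_rng(noise.seed)
    out = np.array(mask.labels, copy=True)
    if noise.jitter_px == 0 and noise.drop_probability == 0 and noise.class_flip_probability == 0:
        return LabelMask(out, mask.spacing_um, mask.origin)
    from .hrd_classify import extract_components

    for b in range(out.shape[0]):
        plane = mask.labels[b]
        comps = extract_components(plane > 0, bscan_index=b)
        new_plane = np.array(plane, copy=True)
        for comp in comps:
            zz, xx = comp.pixels[:, 0], comp.pixels[:, 1]
            cls = int(plane[zz[0], xx[0]])
            new_plane[zz, xx] = 0
            if rng.random() < noise.drop_probability:
                continue
            if rng.random() < noise.class_flip_probability:
                cls = 3 - cls  # 1 <-> 2
            sub = np.zeros(plane.shape, dtype=bool)
            sub[zz, xx] = True
            k = int(rng.integers(0, noise.jitter_px + 1))
            if k > 0:
                op = morphology.dilation if rng.random() < 0.5 else morphology.erosion
                for _ in range(k):
                    sub = op(sub, morphology.disk(1))
            nz2, nx2 = np.nonzero(sub)
            new_plane[nz2, nx2] = cls
        out[b] = new_plane
    return LabelMask(out, mask.spacing_um, mask.origin)


def generate_training_set(
    spec: PhantomSpec, n_volumes: int, seed: int | None = None,
) -> list[tuple[OCTVolume, LabelMask, list[LesionGT]]]:
    """Independent phantoms from one template spec with derived per-volume seeds."""
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    master = spec.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_volumes) % (2 ** 31)
    out = []
    for s in child_seeds:
        vspec = dataclasses.replace(spec, seed=int(s))
        out.append(generate_volume(vspec))
    return out


def lesion_table(lesions: Sequence[LesionGT]):
    """LesionGT records as a DataFrame (columns match the CSV interface)."""
    import pandas as pd

    return pd.DataFrame([{
        "bscan": l.bscan, "z_px": l.center_zx[0], "x_px": l.center_zx[1],
        "diameter_um": l.diameter_um, "class": l.true_class.value,
        "shadow": l.shadow, "n_pixels": l.n_pixels,
    } for l in lesions], columns=["bscan", "z_px", "x_px", "diameter_um",
                                  "class", "shadow", "n_pixels"])
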