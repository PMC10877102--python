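"""Synthetic DAPI/53BP1 tissue-image generator with exact ground truth.

Real ex vivo tumor-slice images are private patient data, so training,
quantification and statistics are exercised on synthetic scenes that emulate
the acquisition regime: calibrated Z-stacks, clustered/overlapping elliptical
nuclei with variable staining intensity and a dimmed center, constant
background plus Gaussian noise, and dose-dependent punctate 53BP1 foci
rendered inside nuclei (with reduced amplitude one plane above and below the
focal plane, so the 3-slice maximum projection has something to recover).
Spurious bright speckles outside nuclei are added to the foci channel only —
they have no ground-truth entry and must be removed by the nuclei overlay.

Ground truth keeps overlapping nuclei as distinct labels even though the
rendered image shows them merged: that is exactly the clustering challenge
the watershed stage has to solve.

Per-nucleus focus counts are Poisson with mean
``baseline_foci_per_nucleus + dose_Gy × foci_per_Gy_per_nucleus``.

The default geometry is a 256×256 px desk-scale scene at the acquisition
calibration (183.65/1024 ≈ 0.17935 µm/px, 1 µm z step); pass
``height_px=width_px=1024`` for full-scale scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Channel, Condition, ImageMeta, LabelMap, SemanticMask, ZStack

__all__ = ["SceneSpec", "Scene", "generate_scene", "generate_cohort", "PIXEL_SIZE_UM"]

#: acquisition pixel calibration: 183.65 µm field of view over 1024 px
PIXEL_SIZE_UM = 183.65 / 1024.0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic tissue image.

    Rates are per nucleus (foci) or per image (speckles); lengths in µm.
    """

    height_px: int = 256
    width_px: int = 256
    pixel_size_um: float = PIXEL_SIZE_UM
    n_planes: int = 5
    z_step_um: float = 1.0
    n_nuclei: int = 12
    nucleus_radius_um_mean: float = 3.4
    nucleus_radius_um_sd: float = 0.6
    overlap_fraction: float = 0.25
    center_dimming: float = 0.3
    stain_intensity_scale: float = 1.0
    background_level: float = 20.0
    noise_sd: float = 8.0
    dose_Gy: float = 0.0
    foci_per_Gy_per_nucleus: float = 2.0
    baseline_foci_per_nucleus: float = 0.5
    focus_radius_um_mean: float = 0.30
    focus_radius_um_sd: float = 0.05
    extranuclear_speckle_rate: float = 10.0
    focal_plane_index: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.focal_plane_index < self.n_planes):
            raise ValueError("focal_plane_index must lie in [0, n_planes)")
        for name in (
            "dose_Gy",
            "foci_per_Gy_per_nucleus",
            "baseline_foci_per_nucleus",
            "extranuclear_speckle_rate",
            "background_level",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if not (0 <= self.center_dimming <= 1):
            raise ValueError("center_dimming must be in [0, 1]")
        if self.stain_intensity_scale <= 0:
            raise ValueError("stain_intensity_scale must be > 0")

    @property
    def expected_foci_per_nucleus(self) -> float:
        return self.baseline_foci_per_nucleus + self.dose_Gy * self.foci_per_Gy_per_nucleus


@dataclass(frozen=True)
class Scene:
    """One realized synthetic image with its ground truth."""

    dapi: ZStack
    foci: ZStack
    gt_nuclei: LabelMap
    gt_foci: SemanticMask
    gt_foci_centers: list[tuple[int, int, int]]
    meta: ImageMeta
    spec: SceneSpec

    @property
    def gt_foci_per_nucleus(self) -> dict[int, int]:
        counts: dict[int, int] = {int(k): 0 for k in self.gt_nuclei.labels}
        for _, _, parent in self.gt_foci_centers:
            counts[parent] += 1
        return counts


@dataclass
class _Nucleus:
    label: int
    center: tuple[float, float]
    a_px: float  # semi-axis along theta
    b_px: float
    theta: float

    def rho2(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Squared normalized elliptical radius (≤1 inside)."""
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        ct, st = np.cos(self.theta), np.sin(self.theta)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        return (u / self.a_px) ** 2 + (v / self.b_px) ** 2


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator) -> list[_Nucleus]:
    """Sequential placement; a fraction of nuclei is attached to a neighbor."""
    nuclei: list[_Nucleus] = []
    h, w = spec.height_px, spec.width_px
    # with overlap disabled, demand clear separation (cleanly splittable gt);
    # otherwise allow incidental touching, as in tissue
    sep = 1.05 if spec.overlap_fraction == 0 else 0.90
    for label in range(1, spec.n_nuclei + 1):
        placed = False
        # a too-large radius draw can be unplaceable in a crowded image:
        # redraw the geometry a few times before giving up
        for _redraw in range(8):
            if placed:
                break
            r_um = max(0.3 * spec.nucleus_radius_um_mean,
                       rng.normal(spec.nucleus_radius_um_mean, spec.nucleus_radius_um_sd))
            r_px = r_um / spec.pixel_size_um
            ecc = rng.uniform(0.0, 0.3)
            a_px, b_px = r_px * (1 + ecc), r_px / (1 + ecc)
            theta = rng.uniform(0, np.pi)
            margin = a_px + 2
            if margin * 2 + 4 > min(h, w):
                raise ValueError("nucleus too large for the image")
            attach = bool(nuclei) and rng.uniform() < spec.overlap_fraction
            for _ in range(1000):
                if attach:
                    host = nuclei[rng.integers(len(nuclei))]
                    # touching-to-overlapping: centers at 75–100% of the summed radii
                    dist = (host.a_px + a_px) * rng.uniform(0.75, 1.0)
                    phi = rng.uniform(0, 2 * np.pi)
                    cr = host.center[0] + dist * np.cos(phi)
                    cc = host.center[1] + dist * np.sin(phi)
                    if not (margin <= cr < h - margin and margin <= cc < w - margin):
                        continue
                    too_close = any(
                        np.hypot(cr - n.center[0], cc - n.center[1]) < 0.70 * (n.b_px + b_px)
                        for n in nuclei
                        if n is not host
                    )
                    if too_close:
                        continue
                else:
                    cr = rng.uniform(margin, h - margin)
                    cc = rng.uniform(margin, w - margin)
                    too_close = any(
                        np.hypot(cr - n.center[0], cc - n.center[1]) < sep * (n.a_px + a_px)
                        for n in nuclei
                    )
                    if too_close:
                        continue
                nuclei.append(_Nucleus(label, (cr, cc), a_px, b_px, theta))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place nucleus {label} of {spec.n_nuclei} within image bounds"
            )
    return nuclei


def _bbox_grids(center: tuple[float, float], radius: float, shape: tuple[int, int]):
    r0 = max(0, int(np.floor(center[0] - radius)))
    r1 = min(shape[0], int(np.ceil(center[0] + radius)) + 1)
    c0 = max(0, int(np.floor(center[1] - radius)))
    c1 = min(shape[1], int(np.ceil(center[1] + radius)) + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), rows.astype(float), cols.astype(float)


def generate_scene(spec: SceneSpec, meta: ImageMeta | None = None) -> Scene:
    """Render one scene; identical spec (same seed) gives a bit-identical scene."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)
    nuclei = _place_nuclei(spec, rng)

    # ground-truth label map: later-placed nuclei win the (small) overlap zone
    gt = np.zeros(shape, dtype=np.int32)
    amp = {}
    for nuc in nuclei:
        sl, rows, cols = _bbox_grids(nuc.center, nuc.a_px + 1, shape)
        inside = nuc.rho2(rows, cols) <= 1.0
        gt[sl][inside] = nuc.label
        amp[nuc.label] = spec.stain_intensity_scale * rng.uniform(100.0, 180.0)

    # DAPI: radial profile with center dimming, peak at the focal plane
    dapi_focal = np.zeros(shape, dtype=np.float64)
    for nuc in nuclei:
        sl, rows, cols = _bbox_grids(nuc.center, nuc.a_px + 1, shape)
        rho2 = nuc.rho2(rows, cols)
        inside = rho2 <= 1.0
        profile = (1.0 - spec.center_dimming) + spec.center_dimming * rho2
        patch = np.where(inside, amp[nuc.label] * profile, 0.0)
        dapi_focal[sl] = np.maximum(dapi_focal[sl], patch)

    # foci: per-nucleus Poisson counts, puncta inside the parent's gt region
    foci_focal = np.zeros(shape, dtype=np.float64)
    foci_adjacent = np.zeros(shape, dtype=np.float64)
    gt_foci = np.zeros(shape, dtype=np.uint8)
    gt_centers: list[tuple[int, int, int]] = []
    mean_count = spec.expected_foci_per_nucleus

    def _render_punctum(center, r_px, amplitude, into_focal=True):
        sigma = max(0.6, r_px / 1.4)
        sl, rows, cols = _bbox_grids(center, 4 * sigma, shape)
        d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
        blob = amplitude * np.exp(-d2 / (2 * sigma**2))
        if into_focal:
            foci_focal[sl] += blob
        foci_adjacent[sl] += 0.45 * blob

    placed_foci: list[tuple[float, float, float]] = []
    for nuc in nuclei:
        n_foci = rng.poisson(mean_count)
        for _ in range(n_foci):
            r_px = max(0.12, rng.normal(spec.focus_radius_um_mean, spec.focus_radius_um_sd)) / spec.pixel_size_um
            for _ in range(200):
                # uniform in the parent ellipse, full 2σ footprint inside it
                rho = np.sqrt(rng.uniform())
                phi = rng.uniform(0, 2 * np.pi)
                shrink = max(0.05, 1 - (2 * max(0.6, r_px / 1.4)) / nuc.b_px)
                u = rho * shrink * nuc.a_px * np.cos(phi)
                v = rho * shrink * nuc.b_px * np.sin(phi)
                ct, st = np.cos(nuc.theta), np.sin(nuc.theta)
                cr = nuc.center[0] + u * ct - v * st
                cc = nuc.center[1] + u * st + v * ct
                ri, ci = int(round(cr)), int(round(cc))
                if not (0 <= ri < h and 0 <= ci < w):
                    continue
                # the whole gt footprint must lie in the parent's gt region
                # (interior, non-clipped foci: exact count recovery holds)
                sl, rows, cols = _bbox_grids((cr, cc), r_px + 1, shape)
                disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= r_px**2
                disk[ri - sl[0].start, ci - sl[1].start] = True
                if not np.all(gt[sl][disk] == nuc.label):
                    continue
                # keep foci mutually separated so gt components stay distinct
                if any(
                    np.hypot(cr - fr, cc - fc) < r_px + fr_px + 1.5
                    for fr, fc, fr_px in placed_foci
                ):
                    continue
                break
            else:
                continue
            _render_punctum((cr, cc), r_px, spec.stain_intensity_scale * rng.uniform(120.0, 200.0))
            gt_foci[sl][disk] = 1
            placed_foci.append((cr, cc, r_px))
            gt_centers.append((ri, ci, nuc.label))

    # extranuclear speckles: foci channel only, no ground-truth entry
    n_speckles = rng.poisson(spec.extranuclear_speckle_rate)
    for _ in range(n_speckles):
        for _ in range(200):
            cr, cc = rng.uniform(2, h - 3), rng.uniform(2, w - 3)
            ri, ci = int(round(cr)), int(round(cc))
            r0, r1 = max(0, ri - 3), min(h, ri + 4)
            c0, c1 = max(0, ci - 3), min(w, ci + 4)
            if not gt[r0:r1, c0:c1].any():
                break
        else:
            continue
        r_px = max(0.12, rng.normal(spec.focus_radius_um_mean, spec.focus_radius_um_sd)) / spec.pixel_size_um
        _render_punctum((cr, cc), r_px, spec.stain_intensity_scale * rng.uniform(120.0, 200.0))

    # assemble stacks: DAPI decays away from the focal plane; foci puncta
    # appear attenuated one plane above/below the focal plane
    z_att = {dz: 0.55 ** abs(dz) for dz in range(-spec.n_planes, spec.n_planes + 1)}
    dapi_planes = np.empty((spec.n_planes, h, w), dtype=np.float32)
    foci_planes = np.empty((spec.n_planes, h, w), dtype=np.float32)
    for z in range(spec.n_planes):
        dz = z - spec.focal_plane_index
        dapi = spec.background_level + z_att[dz] * dapi_focal
        if dz == 0:
            foci_signal = foci_focal
        elif abs(dz) == 1:
            foci_signal = foci_adjacent
        else:
            foci_signal = 0.0
        foci_ch = spec.background_level + foci_signal
        dapi_planes[z] = np.clip(dapi + rng.normal(0, spec.noise_sd, shape), 0, None)
        foci_planes[z] = np.clip(foci_ch + rng.normal(0, spec.noise_sd, shape), 0, None)

    if meta is None:
        cond = Condition.CONTROL if spec.dose_Gy == 0 else Condition.PHOTON
        meta = ImageMeta("synthetic", cond, spec.dose_Gy, 0)

    return Scene(
        dapi=ZStack(dapi_planes, spec.pixel_size_um, spec.z_step_um, Channel.DAPI),
        foci=ZStack(foci_planes, spec.pixel_size_um, spec.z_step_um, Channel.FOCI),
        gt_nuclei=LabelMap(gt, spec.pixel_size_um),
        gt_foci=SemanticMask(gt_foci, spec.pixel_size_um),
        gt_foci_centers=gt_centers,
        meta=meta,
        spec=spec,
    )


def generate_cohort(
    n_patients: int,
    images_per_condition: int,
    conditions: Sequence[tuple[Condition | str, float]],
    base_spec: SceneSpec,
    patient_sensitivity_sd: float = 0.2,
    seed: int = 0,
) -> list[Scene]:
    """Generate a patient cohort of scenes with coherent metadata.

    Each patient draws a lognormal sensitivity multiplier (log-sd
    ``patient_sensitivity_sd``) applied to ``foci_per_Gy_per_nucleus``,
    mimicking between-patient radiosensitivity differences.  Returns
    ``n_patients × len(conditions) × images_per_condition`` scenes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be ≥ 1")
    rng = np.random.default_rng(seed)
    scenes: list[Scene] = []
    for p in range(n_patients):
        sens = float(np.exp(rng.normal(0.0, patient_sensitivity_sd))) if patient_sensitivity_sd > 0 else 1.0
        pid = f"P{p + 1:02d}"
        for cond, dose in conditions:
            cond = Condition(cond)
            for i in range(images_per_condition):
                spec = replace(
                    base_spec,
                    dose_Gy=float(dose),
                    foci_per_Gy_per_nucleus=base_spec.foci_per_Gy_per_nucleus * sens,
                    seed=int(rng.integers(2**31)),
                )
                meta = ImageMeta(pid, cond, float(dose), i)
                scenes.append(generate_scene(spec, meta))
    return scenes
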