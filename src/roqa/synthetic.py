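"""Synthetic phantom volumes of labeled nuclei with ground truth.

Emulates what tube-source µCT reconstructions of antibody-silver-labeled
nuclei look like at the image level: bright, roundish ellipsoidal particles
with a dome-shaped intensity profile (brightest at the core) over a low,
optionally radially varying background, smeared by a Gaussian point-spread
surrogate and corrupted by detector noise. Aggregates of proximate nuclei
are produced on request by placing pairs close enough that the blur fuses
them — the input the watershed disintegration stage exists for. A
two-condition generator varies only the flatness distribution between arms
(rounder nuclei in the "treated" arm, mimicking a relaxed cytoskeleton)
while holding every nuisance parameter fixed.

What it does NOT emulate: tomographic streak/ring artifacts, beam-hardening
cupping beyond a smooth radial gradient, the grainy sub-voxel texture of the
silver label, and spatially correlated noise. Pipeline results on phantoms
therefore validate the geometry/statistics chain, not robustness to
reconstruction artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, special
from scipy.spatial.transform import Rotation

from .volume_io import IntensityVolume

__all__ = [
    "SceneSpec",
    "ellipsoid_surface_area",
    "generate_scene",
    "generate_two_condition_experiment",
]


@dataclass
class SceneSpec:
    """Declarative description of one phantom field of view.

    Semi-axes are drawn as: longest a ~ U[`a_range`] µm, then b = a ×
    elongation and c = b × flatness with flatness/elongation ~ truncated
    normals. `fused_pair_fraction` f turns round(f × n_nuclei) of the nuclei
    into fused pairs (each pair counts two nuclei; the companion center sits
    at `fuse_center_factor` times the sum of the directional surface radii
    along the joining line, so the two bodies interpenetrate and segment as
    one aggregate). Intensities are detector counts in 16-bit range.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.1, 1.1, 1.1)
    n_nuclei: int = 20
    a_range: tuple[float, float] = (10.0, 14.0)
    flatness_dist: tuple[float, float] = (0.45, 0.08)
    elongation_dist: tuple[float, float] = (0.80, 0.06)
    fused_pair_fraction: float = 0.0
    fuse_center_factor: float = 0.75
    peak_intensity: float = 10000.0
    intensity_sd: float = 400.0
    background: float = 1000.0
    radial_gradient: float = 0.0
    blur_sigma_um: float = 0.8
    noise_sd: float = 200.0
    noise_corr_vox: float = 0.5
    poisson_noise: bool = False
    margin_um: float = 4.0
    seed: int = 0
    allow_border: bool = field(default=False)
    render: bool = True

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not (0 <= self.fused_pair_fraction <= 0.5):
            raise ValueError("fused_pair_fraction must be in [0, 0.5]")
        if self.a_range[0] > self.a_range[1] or self.a_range[0] <= 0:
            raise ValueError("a_range must be increasing and positive")


def ellipsoid_surface_area(a: float, b: float, c: float, method: str = "exact") -> float:
    """Surface area of an ellipsoid with semi-axes a >= b >= c.

    ``method='exact'`` evaluates the Legendre elliptic-integral form;
    ``method='thomsen'`` uses the Knud Thomsen approximation (p = 1.6075,
    worst-case error about 1.06%), convenient for quick truth tables.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if c <= 0:
        raise ValueError("semi-axes must be positive")
    if method == "thomsen":
        p = 1.6075
        return 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
    if method != "exact":
        raise ValueError("method must be 'exact' or 'thomsen'")
    if a == c:  # sphere
        return 4 * math.pi * a * a
    phi = math.acos(c / a)
    m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
    F = special.ellipkinc(phi, m)
    E = special.ellipeinc(phi, m)
    s = math.sin(phi)
    return 2 * math.pi * c * c + (2 * math.pi * a * b / s) * (
        E * s * s + F * math.cos(phi) ** 2
    )


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo < v <= hi:
            return float(v)
    return float(min(max(mean, lo + 1e-6), hi))


def _sample_nucleus(rng, spec: SceneSpec):
    a = rng.uniform(*spec.a_range)
    elong = _truncated_normal(rng, *spec.elongation_dist, 0.05, 1.0)
    flat = _truncated_normal(rng, *spec.flatness_dist, 0.05, 1.0)
    b = a * elong
    c = b * flat
    rot = Rotation.random(rng=rng).as_matrix()
    peak = max(rng.normal(spec.peak_intensity, spec.intensity_sd), spec.background + 1)
    return a, b, c, rot, peak


def _place(rng, spec: SceneSpec, a: float, existing, phys_size):
    """Rejection-sample a center keeping margin from faces and other nuclei."""
    margin = 0.0 if spec.allow_border else a + spec.margin_um
    lo = np.full(3, margin)
    hi = np.asarray(phys_size) - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for requested nucleus size and margin")
    for _ in range(2000):
        center = rng.uniform(lo, hi)
        ok = all(
            np.linalg.norm(center - c0) > a + a0 + 2.0 + 2 * spec.blur_sigma_um
            for c0, a0 in existing
        )
        if ok:
            return center
    raise ValueError("could not place nucleus: packing infeasible for this spec")


def _directional_radius(u: np.ndarray, semi, rot: np.ndarray) -> float:
    """Distance from center to the ellipsoid surface along unit direction u."""
    A = rot @ np.diag([1.0 / s**2 for s in semi]) @ rot.T
    return float(1.0 / math.sqrt(u @ A @ u))


def _render_nucleus(canvas, center, semi, rot, peak, spacing):
    """Paint one ellipsoid with a dome profile peak·(1 − r²/2), r the
    normalized ellipsoidal radius; overlapping nuclei combine by max."""
    spacing = np.asarray(spacing)
    half = np.max(semi) + spacing.max()
    lo_idx = np.maximum(((center - half) / spacing - 0.5).astype(int), 0)
    hi_idx = np.minimum(
        ((center + half) / spacing + 1.5).astype(int), np.asarray(canvas.shape)
    )
    if np.any(hi_idx <= lo_idx):
        return
    grids = np.meshgrid(
        *[
            (np.arange(lo_idx[i], hi_idx[i]) + 0.5) * spacing[i] - center[i]
            for i in range(3)
        ],
        indexing="ij",
    )
    rel = np.stack(grids, axis=-1) @ rot  # world -> ellipsoid frame
    r2 = np.sum((rel / np.asarray(semi)) ** 2, axis=-1)
    inside = r2 <= 1.0
    box = tuple(slice(lo_idx[i], hi_idx[i]) for i in range(3))
    patch = np.where(inside, peak * (1.0 - 0.5 * r2), 0.0)
    canvas[box] = np.maximum(canvas[box], patch)


def generate_scene(spec: SceneSpec) -> tuple[IntensityVolume, pd.DataFrame]:
    """Render one phantom FOV and its ground-truth table.

    The truth table has one row per nucleus: center, semi-axes, rotation
    quaternion, fused-group id, and the analytic flatness / elongation /
    anisotropy / volume / sphericity implied by the semi-axes. The seed in
    the spec fully determines the output (one master seed, per-nucleus
    substreams).
    """
    ss = np.random.SeedSequence(spec.seed)
    scene_rng = np.random.default_rng(ss.spawn(1)[0])
    nuc_seeds = ss.spawn(spec.n_nuclei + 1)[1:]
    phys_size = np.asarray(spec.shape) * np.asarray(spec.spacing)

    n_pairs = int(round(spec.fused_pair_fraction * spec.n_nuclei))
    if 2 * n_pairs > spec.n_nuclei:
        raise ValueError("fused_pair_fraction too large for n_nuclei")

    canvas = np.zeros(spec.shape, dtype=np.float64)
    rows = []
    existing: list[tuple[np.ndarray, float]] = []
    nucleus_id = 0
    group_id = 0

    def add(center, a, b, c, rot, peak, gid, fused):
        nonlocal nucleus_id
        if spec.render:
            _render_nucleus(canvas, center, (a, b, c), rot, peak, spec.spacing)
        quat = Rotation.from_matrix(rot).as_quat()
        vol = (4 / 3) * math.pi * a * b * c
        rows.append(
            {
                "nucleus_id": nucleus_id,
                "group_id": gid,
                "fused": fused,
                "center_z_um": center[0],
                "center_y_um": center[1],
                "center_x_um": center[2],
                "a_um": a,
                "b_um": b,
                "c_um": c,
                "quat_x": quat[0],
                "quat_y": quat[1],
                "quat_z": quat[2],
                "quat_w": quat[3],
                "peak_intensity": peak,
                "flatness": c / b,
                "elongation": b / a,
                "anisotropy": 1 - c / a,
                "volume_um3": vol,
                "sphericity": math.pi ** (1 / 3)
                * (6 * vol) ** (2 / 3)
                / ellipsoid_surface_area(a, b, c),
            }
        )
        existing.append((np.asarray(center), a))
        nucleus_id += 1

    k = 0
    for _ in range(n_pairs):
        rng1 = np.random.default_rng(nuc_seeds[k])
        rng2 = np.random.default_rng(nuc_seeds[k + 1])
        k += 2
        a1, b1, c1, rot1, peak1 = _sample_nucleus(rng1, spec)
        a2, b2, c2, rot2, peak2 = _sample_nucleus(rng2, spec)
        center1 = _place(rng1, spec, a1 + a2, existing, phys_size)
        for _ in range(200):
            direction = rng2.normal(size=3)
            direction /= np.linalg.norm(direction)
            # center distance from the directional radii along the joining
            # line so the pair genuinely interpenetrates for any rotation
            r1 = _directional_radius(direction, (a1, b1, c1), rot1)
            r2 = _directional_radius(direction, (a2, b2, c2), rot2)
            center2 = center1 + spec.fuse_center_factor * (r1 + r2) * direction
            pad = 0.0 if spec.allow_border else a2 + spec.margin_um
            if np.all(center2 > pad) and np.all(center2 < phys_size - pad):
                break
        else:
            raise ValueError("could not place fused companion inside the volume")
        add(center1, a1, b1, c1, rot1, peak1, group_id, True)
        add(center2, a2, b2, c2, rot2, peak2, group_id, True)
        group_id += 1

    for _ in range(spec.n_nuclei - 2 * n_pairs):
        rng = np.random.default_rng(nuc_seeds[k])
        k += 1
        a, b, c, rot, peak = _sample_nucleus(rng, spec)
        center = _place(rng, spec, a, existing, phys_size)
        add(center, a, b, c, rot, peak, group_id, False)
        group_id += 1

    truth = pd.DataFrame(rows)
    if not spec.render:
        # truth-only mode for statistical replicates: placement and shape
        # sampling are identical, the image stays at the background level
        vol = IntensityVolume(
            np.full(spec.shape, spec.background, dtype=np.uint16),
            spec.spacing,
            provenance=[f"synthetic scene seed={spec.seed} (truth only)"],
        )
        return vol, truth

    bg = np.full(spec.shape, float(spec.background))
    if spec.radial_gradient:
        zz, yy, xx = np.meshgrid(
            *[np.linspace(-1, 1, n) for n in spec.shape], indexing="ij"
        )
        bg *= 1.0 + spec.radial_gradient * (yy**2 + xx**2) / 2.0
    image = np.maximum(canvas, 0) + bg

    if spec.blur_sigma_um > 0:
        sigma_vox = [spec.blur_sigma_um / s for s in spec.spacing]
        image = ndimage.gaussian_filter(image, sigma=sigma_vox)
    if spec.poisson_noise:
        image = scene_rng.poisson(np.maximum(image, 0)).astype(np.float64)
    if spec.noise_sd > 0:
        noise = scene_rng.normal(0.0, 1.0, size=spec.shape)
        if spec.noise_corr_vox > 0:
            # reconstruction noise is band-limited by the reconstruction
            # kernel; a short correlation length mimics that, renormalized
            # to the requested standard deviation
            noise = ndimage.gaussian_filter(noise, spec.noise_corr_vox)
            noise /= noise.std()
        image = image + spec.noise_sd * noise
    image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)

    vol = IntensityVolume(
        image, spec.spacing, provenance=[f"synthetic scene seed={spec.seed}"]
    )
    return vol, truth


def generate_two_condition_experiment(
    base: SceneSpec,
    control_flatness: tuple[float, float] = (0.45, 0.08),
    treated_flatness: tuple[float, float] = (0.70, 0.08),
    n_per_group: int = 300,
    seed: int = 0,
) -> dict:
    """Two-arm phantom experiment differing only in the flatness distribution.

    Each arm is split into FOVs of ``base.n_nuclei`` nuclei (memory-bounded
    rendering); nuisance parameters — sizes, intensities, blur, noise — are
    identical across arms. Returns ``{"control": [(volume, truth), ...],
    "treated": [...]}`` with per-arm seeds derived from `seed`.
    """
    if base.n_nuclei < 1:
        raise ValueError("base.n_nuclei must be >= 1")
    out: dict[str, list] = {}
    for arm_idx, (arm, flat) in enumerate(
        [("control", control_flatness), ("treated", treated_flatness)]
    ):
        scenes = []
        remaining = n_per_group
        fov = 0
        while remaining > 0:
            n = min(base.n_nuclei, remaining)
            arm_seed = (seed * 1000003 + arm_idx * 499979 + fov * 7919) % (2**31 - 1)
            sub = replace(base, n_nuclei=n, flatness_dist=flat, seed=arm_seed)
            scenes.append(generate_scene(sub))
            remaining -= n
            fov += 1
        out[arm] = scenes
    return out
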