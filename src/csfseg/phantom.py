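"""Synthetic CT-like head phantoms with ventricle-shaped CSF ground truth.

Real hydrocephalus CT cohorts are clinical data and cannot ship with the
package, so every stage of the pipeline is exercised on phantoms that
reproduce the features the method actually depends on: a bone-attenuation
skull shell around brain-attenuation tissue, a CSF compartment built from a
variable number of asymmetric ellipsoidal lobes joined through a central
channel (ventricles vary greatly in size, shape and symmetry in treated
hydrocephalus), per-tissue Gaussian HU noise, and a cohort structure in
which some patients return for follow-up exams with drifted CSF volume.
Shapes are ellipsoid unions, not anatomy — sufficient for 2D/2.5D
segmentation and volumetry, and stated as such.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume_io import CTVolume, MaskVolume

__all__ = ["PhantomConfig", "generate_phantom", "phantom_components", "generate_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, attenuation and noise parameters of one phantom exam.

    HU means/stds: air −1000, brain 30±5, CSF 7±4, bone 1000±50 — textbook
    contrast, chosen so CSF and brain both fall inside the (−100, 100)
    preprocessing window, separable but overlapping under noise. The CSF
    target is a fraction of brain voxels; lobe radii are rescaled (bounded
    retries) until the achieved fraction lands in the configured range.
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 1.5, 1.5)
    hu_air: float = -1000.0
    noise_air: float = 5.0
    hu_brain: float = 30.0
    noise_brain: float = 5.0
    hu_csf: float = 7.0
    noise_csf: float = 4.0
    hu_bone: float = 1000.0
    noise_bone: float = 50.0
    n_lobes_range: tuple[int, int] = (2, 6)
    asymmetry: float = 0.4
    lobe_radius_frac: tuple[float, float] = (0.14, 0.30)
    csf_fraction_range: tuple[float, float] = (0.03, 0.12)
    max_tries: int = 25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.csf_fraction_range
        if not (0.0 < lo < hi < 0.3):
            raise ValueError(
                f"csf_fraction_range must lie inside (0, 0.3), got {self.csf_fraction_range}"
            )
        for name in ("noise_air", "noise_brain", "noise_csf", "noise_bone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_lobes_range[0] < 1 or self.n_lobes_range[1] < self.n_lobes_range[0]:
            raise ValueError(f"invalid n_lobes_range {self.n_lobes_range}")


#: demo-scale configuration approximating a real exam grid
FULL_SCALE = PhantomConfig(shape=(240, 512, 512), spacing=(0.75, 0.45, 0.45))


def _physical_grids(config: PhantomConfig):
    z, y, x = np.indices(config.shape, dtype=np.float64)
    dz, dy, dx = config.spacing
    return z * dz, y * dy, x * dx


def _ellipsoid(grids, center, radii) -> np.ndarray:
    Z, Y, X = grids
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((Z - cz) / rz) ** 2 + ((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2 <= 1.0


def _csf_mask(grids, center, brain_radii, lobes, tube_radii, inner_frac=0.85):
    mask = np.zeros(grids[0].shape, dtype=bool)
    for lobe_center, lobe_radii in lobes:
        mask |= _ellipsoid(grids, lobe_center, lobe_radii)
        # channel: ellipsoids stamped along the segment lobe-center → brain center
        seg = np.asarray(lobe_center) - np.asarray(center)
        dist = float(np.linalg.norm(seg))
        step = max(min(tube_radii) * 0.5, 1e-6)
        n_pts = max(int(np.ceil(dist / step)) + 1, 2)
        for t in np.linspace(0.0, 1.0, n_pts):
            pt = np.asarray(center) + t * seg
            mask |= _ellipsoid(grids, pt, tube_radii)
    # CSF strictly inside the brain, away from the skull
    inner = _ellipsoid(grids, center, tuple(r * inner_frac for r in brain_radii))
    mask &= inner
    return _slice_consistent(mask)


def _slice_consistent(mask: np.ndarray, max_iters: int = 12) -> np.ndarray:
    """Iterate the 2.5D consistency relation to a fixed point.

    Voxelization of thin oblique structures can leave single-slice-thick CSF
    that no real ventricular system shows at clinical slice thickness; the
    ground-truth compartment is therefore made slice-consistent (no voxel
    disagrees with both axial neighbours) by construction.
    """
    out = mask.astype(np.uint8)
    for _ in range(max_iters):
        below, cur, above = out[:-2], out[1:-1], out[2:]
        fill = (below == 1) & (above == 1) & (cur == 0)
        clear = (below == 0) & (above == 0) & (cur == 1)
        if not fill.any() and not clear.any():
            break
        nxt = out.copy()
        nxt[1:-1][fill] = 1
        nxt[1:-1][clear] = 0
        out = nxt
    return out.astype(bool)


def _build(config: PhantomConfig):
    rng = np.random.default_rng(config.seed)
    grids = _physical_grids(config)
    extent = np.array(
        [(n - 1) * s for n, s in zip(config.shape, config.spacing)], dtype=np.float64
    )
    center = tuple(extent / 2)
    outer = tuple(extent * 0.46)
    brain_radii = tuple(r * 0.86 for r in outer)

    head = _ellipsoid(grids, center, outer)
    brain = _ellipsoid(grids, center, brain_radii)
    skull = head & ~brain

    # structures must span several slices: 1-slice-thick CSF is a grid artifact
    # (real ventricles cover tens of 1 mm slices), so z radii get a floor —
    # capped for very coarse grids where 3 slices would swallow the brain
    dz = config.spacing[0]
    min_rz = min(3.2 * dz, 0.45 * brain_radii[0])

    n_lobes = int(rng.integers(config.n_lobes_range[0], config.n_lobes_range[1] + 1))
    lobes = []
    for i in range(n_lobes):
        frac = rng.uniform(*config.lobe_radius_frac)
        # asymmetric: lobes on one lateral side systematically larger
        lateral = 1.0 + config.asymmetry if i % 2 == 0 else 1.0 - config.asymmetry
        offset = rng.uniform(-0.40, 0.40, size=3) * np.asarray(brain_radii)
        offset[2] = abs(offset[2]) * (1 if i % 2 == 0 else -1)  # split left/right
        lobe_center = tuple(np.asarray(center) + offset)
        lobe_radii = tuple(frac * lateral * r for r in brain_radii)
        lobes.append([lobe_center, lobe_radii])

    tube_r = max(0.08 * min(brain_radii), 1.2 * max(config.spacing))
    min_tube = 1.05 * max(config.spacing[1], config.spacing[2])
    brain_voxels = int(brain.sum())
    lo, hi = config.csf_fraction_range
    target = 0.5 * (lo + hi)
    scale = 1.0
    mask = None
    for _ in range(config.max_tries):
        stamped = [
            [c, (max(radii[0], min_rz), radii[1], radii[2])] for c, radii in lobes
        ]
        r_t = max(tube_r * scale, min_tube)
        tube_radii = (max(r_t, min_rz), r_t, r_t)
        mask = _csf_mask(grids, center, brain_radii, stamped, tube_radii)
        fraction = mask.sum() / brain_voxels
        if lo <= fraction <= hi:
            break
        factor = np.clip((target / max(fraction, 1e-6)) ** (1.0 / 3.0), 0.5, 2.0)
        scale *= factor
        lobes = [
            [c, tuple(min(r * factor, b) for r, b in zip(radii, brain_radii))]
            for c, radii in lobes
        ]
    else:
        raise RuntimeError(
            f"could not reach CSF fraction in {config.csf_fraction_range} "
            f"after {config.max_tries} retries (last fraction {fraction:.4f})"
        )

    template = np.full(config.shape, config.hu_air, dtype=np.float64)
    template[skull] = config.hu_bone
    template[brain] = config.hu_brain
    template[mask] = config.hu_csf
    sigma = np.full(config.shape, config.noise_air, dtype=np.float64)
    sigma[skull] = config.noise_bone
    sigma[brain] = config.noise_brain
    sigma[mask] = config.noise_csf
    noisy = template + rng.normal(0.0, 1.0, size=config.shape) * sigma
    return template, sigma, noisy, mask, brain, float(fraction)


def phantom_components(config: PhantomConfig) -> dict:
    """Noise-free template, noise map, mask and brain region (for validation)."""
    template, sigma, noisy, mask, brain, fraction = _build(config)
    return {
        "template": template,
        "sigma": sigma,
        "voxels": noisy,
        "mask": mask,
        "brain": brain,
        "csf_fraction": fraction,
    }


def generate_phantom(
    config: PhantomConfig, patient_id: str = "P00", exam_id: str = "P00-E0"
) -> tuple[CTVolume, MaskVolume]:
    """One phantom exam: CT volume with HU noise plus its exact CSF mask.

    Deterministic given ``config.seed``.
    """
    _, _, noisy, mask, _, _ = _build(config)
    ct = CTVolume(
        voxels=noisy.astype(np.float32),
        spacing=config.spacing,
        patient_id=patient_id,
        exam_id=exam_id,
    )
    truth = MaskVolume(
        labels=mask.astype(np.uint8),
        spacing=config.spacing,
        patient_id=patient_id,
        exam_id=exam_id,
    )
    return ct, truth


def generate_cohort(
    n_patients: int,
    multi_exam_patients: int,
    exams_each: int = 2,
    config: PhantomConfig | None = None,
    seed: int = 0,
    volume_drift: float = 0.2,
) -> list[tuple[str, str, CTVolume, MaskVolume]]:
    """A cohort of phantom exams with some patients scanned repeatedly.

    The first ``multi_exam_patients`` patients receive ``exams_each`` exams
    whose CSF volume grows by ``volume_drift`` (relative) per follow-up,
    emulating hydrocephalus progression between visits; remaining patients
    get one exam. Deterministic given ``seed``.
    """
    if multi_exam_patients > n_patients:
        raise ValueError("multi_exam_patients cannot exceed n_patients")
    if n_patients < 1 or exams_each < 1:
        raise ValueError("counts must be positive")
    config = config or PhantomConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_patients * exams_each)
    cohort = []
    i = 0
    for p in range(n_patients):
        pid = f"P{p:02d}"
        n_exams = exams_each if p < multi_exam_patients else 1
        base_fraction = None
        for j in range(n_exams):
            exam_seed = int(seeds[i] % (2**31))
            i += 1
            cfg = replace(config, seed=exam_seed)
            if j > 0:
                t = base_fraction * (1.0 + volume_drift) ** j
                hi_cap = 0.295
                cfg = replace(cfg, csf_fraction_range=(min(t * 0.96, hi_cap * 0.9),
                                                       min(t * 1.04, hi_cap)))
            eid = f"{pid}-E{j}"
            if j == 0:
                template_info = phantom_components(cfg)
                base_fraction = template_info["csf_fraction"]
                ct = CTVolume(
                    voxels=template_info["voxels"].astype(np.float32),
                    spacing=cfg.spacing,
                    patient_id=pid,
                    exam_id=eid,
                )
                mask = MaskVolume(
                    labels=template_info["mask"].astype(np.uint8),
                    spacing=cfg.spacing,
                    patient_id=pid,
                    exam_id=eid,
                )
            else:
                ct, mask = generate_phantom(cfg, patient_id=pid, exam_id=eid)
            cohort.append((pid, eid, ct, mask))
    return cohort
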