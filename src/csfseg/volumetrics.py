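"""CSF volume computation and exam-to-exam change — the clinical readout.

For hydrocephalus follow-up the question is not where the fluid is but how
much there is and how it changed since the previous exam, so volumes are
compared scalar-to-scalar (no registration between exams).
"""

from __future__ import annotations

from dataclasses import dataclass

from .volume_io import MaskVolume

__all__ = ["csf_volume_ml", "volume_change", "VolumeChange"]


def csf_volume_ml(mask: MaskVolume) -> float:
    """CSF volume in mL: voxel count × voxel volume (mm³) / 1000."""
    dz, dy, dx = mask.spacing
    return float(mask.labels.sum()) * dz * dy * dx / 1000.0


@dataclass(frozen=True)
class VolumeChange:
    """Change from exam A to exam B; ``delta_pct`` is None when vol(A) = 0."""

    volume_a_ml: float
    volume_b_ml: float
    delta_ml: float
    delta_pct: float | None

    def as_dict(self) -> dict:
        return {
            "volume_a_ml": self.volume_a_ml,
            "volume_b_ml": self.volume_b_ml,
            "delta_ml": self.delta_ml,
            "delta_pct": self.delta_pct,
        }


def volume_change(mask_a: MaskVolume, mask_b: MaskVolume) -> VolumeChange:
    """Volume difference B − A in mL and in percent of A.

    Grids may differ between exams; only the scalar volumes are compared.
    The percent change is undefined (None) when exam A has no CSF.
    """
    va = csf_volume_ml(mask_a)
    vb = csf_volume_ml(mask_b)
    delta = vb - va
    pct = (delta / va * 100.0) if va > 0 else None
    return VolumeChange(volume_a_ml=va, volume_b_ml=vb, delta_ml=delta, delta_pct=pct)
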