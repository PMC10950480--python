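"""Synthetic structure generators with known geometry.

Every other module is tested against these generators, so no external
coordinate files are needed. Coordinates produced by :func:`ideal_helix`
and :func:`perturb` are quantized to 3 decimals (the PDB coordinate
precision), which makes write -> read round trips exactly lossless.
:func:`apply_rigid` deliberately does *not* quantize so that rigid
transforms preserve pairwise distances to floating-point accuracy;
writing its output to a PDB file quantizes as usual.

Randomness is drawn from NumPy's PCG64 generator seeded explicitly, so a
given seed reproduces the same structure on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import StructfigError
from .structure_io import AtomRecord, Chain, Residue, StructureModel

__all__ = ["PerturbSpec", "ideal_helix", "apply_rigid", "perturb"]

# Idealized alpha-helix CA geometry: radius (Å), rise per residue (Å),
# twist per residue (degrees). Textbook values; consecutive CA-CA distance
# is sqrt(rise^2 + (2 r sin(twist/2))^2) ≈ 3.83 Å.
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0


@dataclass(frozen=True)
class PerturbSpec:
    """Isotropic Gaussian coordinate noise, optionally followed by a rigid
    transform (axis, angle in degrees, translation)."""

    sigma: float
    seed: int
    rigid: tuple[np.ndarray | tuple, float, np.ndarray | tuple] | None = None

    def __post_init__(self):
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise StructfigError(f"sigma must be finite and >= 0, got {self.sigma}")


def ideal_helix(n: int, chain_id: str = "A") -> StructureModel:
    """Poly-ALA CA-only model on an ideal alpha-helical trace, res_seq 1..n."""
    if n < 1:
        raise StructfigError(f"helix length must be >= 1, got {n}")
    twist = math.radians(HELIX_TWIST_DEG)
    chain = Chain(chain_id)
    for i in range(n):
        x = round(HELIX_RADIUS * math.cos(i * twist), 3)
        y = round(HELIX_RADIUS * math.sin(i * twist), 3)
        z = round(HELIX_RISE * i, 3)
        res = Residue("ALA", i + 1, "")
        res.atoms.append(
            AtomRecord(
                serial=i + 1,
                name="CA",
                altloc="",
                res_name="ALA",
                chain_id=chain_id,
                res_seq=i + 1,
                i_code="",
                x=x,
                y=y,
                z=z,
                occupancy=1.0,
                b_factor=0.0,
                element="C",
            )
        )
        chain.residues.append(res)
    return StructureModel(model_id="1", chains=[chain])


def rotation_from_axis_angle(axis, angle_deg: float) -> np.ndarray:
    """Proper rotation matrix about *axis* by *angle_deg* degrees."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0 or not np.isfinite(norm):
        raise StructfigError("rotation axis must be a nonzero finite vector")
    return Rotation.from_rotvec(axis / norm * math.radians(angle_deg)).as_matrix()


def apply_rigid(
    model: StructureModel, axis, angle_deg: float, translation
) -> StructureModel:
    """Rotate all coordinates about the origin, then translate.

    Residue identities and atom metadata are unchanged; pairwise distances
    are preserved to floating-point accuracy (no coordinate quantization).
    """
    rot = rotation_from_axis_angle(axis, angle_deg)
    t = np.asarray(translation, dtype=float)
    return model.map_coords(lambda xyz: xyz @ rot.T + t)


def perturb(model: StructureModel, spec: PerturbSpec) -> StructureModel:
    """Add i.i.d. Gaussian(0, sigma^2) noise per coordinate, seeded.

    The optional rigid transform of the spec is applied after the noise.
    The same spec always yields the same model; coordinates are quantized
    to 3 decimals at the end.
    """
    rng = np.random.default_rng(spec.seed)

    def transform(xyz: np.ndarray) -> np.ndarray:
        out = xyz + rng.normal(0.0, spec.sigma, size=xyz.shape)
        if spec.rigid is not None:
            axis, angle_deg, translation = spec.rigid
            rot = rotation_from_axis_angle(axis, angle_deg)
            out = out @ rot.T + np.asarray(translation, dtype=float)
        return np.round(out, 3)

    return model.map_coords(transform)
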