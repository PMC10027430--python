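"""Residue local frames and relative rigid transforms.

Each residue carries an orthonormal right-handed frame at its Cα built by
Gram–Schmidt from the Cα→C and Cα→N bond vectors (x along Cα→C, y the
orthogonalized Cα→N, z = x × y).  The relative transform between two
residues expresses the neighbor's frame orientation and Cα position in
the target residue's own coordinates, which makes every downstream
feature invariant under global rotations and translations of the
structure while remaining sensitive to mirror reflection (z = x × y
encodes chirality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import BackboneStructure, ResidueBackbone

COLLINEAR_TOL_RAD = 1e-6
ORTHONORMAL_TOL = 1e-9


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal frame at a residue's Cα; rows of ``basis`` are x, y, z."""

    origin: np.ndarray  # (3,) Å
    basis: np.ndarray   # (3, 3), rows are unit axes

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=float))

    def is_orthonormal(self, tol: float = ORTHONORMAL_TOL) -> bool:
        b = self.basis
        return (
            np.allclose(b @ b.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(b) - 1.0) <= tol
        )


@dataclass(frozen=True)
class RelativeTransform:
    """Rigid motion (R, t) locating one residue's frame in another's."""

    rotation: np.ndarray     # (3, 3) proper rotation
    translation: np.ndarray  # (3,) Å, neighbor Cα in the target frame

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )


def build_frame(residue: ResidueBackbone) -> LocalFrame:
    """Gram–Schmidt frame from the backbone atoms of one residue.

    x = unit(C − Cα); y = unit of (N − Cα) orthogonalized against x;
    z = x × y; origin = Cα.
    """
    ca = residue.ca_coord
    vc = residue.c_coord - ca
    vn = residue.n_coord - ca
    if not (np.all(np.isfinite(vc)) and np.all(np.isfinite(vn))):
        raise ValueError("non-finite backbone coordinates")
    nc = np.linalg.norm(vc)
    nn = np.linalg.norm(vn)
    if nc == 0.0 or nn == 0.0:
        raise ValueError("zero-length backbone bond vector")
    x = vc / nc
    # Angle between bond vectors; reject (anti-)parallel configurations.
    sin_angle = np.linalg.norm(np.cross(x, vn / nn))
    if sin_angle < COLLINEAR_TOL_RAD:
        raise ValueError("Cα→C and Cα→N are collinear; frame undefined")
    y = vn - (vn @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    return LocalFrame(origin=ca.copy(), basis=np.stack([x, y, z]))


def relative_transform(frame_i: LocalFrame, frame_j: LocalFrame) -> RelativeTransform:
    """Relative rigid motion of frame j seen from frame i.

    ``rotation`` maps coordinates in frame j's basis to frame i's basis
    (B_i B_jᵀ); ``translation`` is frame j's origin expressed in frame i's
    coordinates.  Both are unchanged when the whole structure is rotated
    and translated rigidly.
    """
    rot = frame_i.basis @ frame_j.basis.T
    t = frame_i.basis @ (frame_j.origin - frame_i.origin)
    return RelativeTransform(rotation=rot, translation=t)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (normalized-quaternion construction)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def apply_rigid_motion(
    structure: "BackboneStructure",
    rotation: np.ndarray,
    translation: np.ndarray,
) -> "BackboneStructure":
    """Return a copy of the structure with all atoms rigidly moved."""
    moved = [
        ResidueBackbone(
            seq_index=r.seq_index,
            n_coord=rotation @ r.n_coord + translation,
            ca_coord=rotation @ r.ca_coord + translation,
            c_coord=rotation @ r.c_coord + translation,
            native_type=r.native_type,
        )
        for r in structure.residues
    ]
    return BackboneStructure(
        residues=moved, chain_id=structure.chain_id,
        source_name=structure.source_name,
    )


def find_neighbors(
    structure: BackboneStructure, i: int, cutoff: float
) -> list[int]:
    """Positions whose Cα lies within ``cutoff`` Å of position ``i``'s Cα.

    The boundary is inclusive and the target itself excluded.  Results are
    ordered by increasing distance, ties broken by ascending position.
    Distances are quantized to 1e-6 Å before comparing and sorting:
    symmetric backbones (e.g. ideal helices) contain exactly equidistant
    neighbor pairs, and without quantization a global rigid motion's
    ~1e-13 Å rounding noise could flip their order, breaking the rigid-
    motion invariance of everything downstream.
    """
    n = len(structure)
    if not (0 <= i < n):
        raise IndexError(f"position {i} out of range for length {n}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = structure.ca_coords()
    d = np.round(np.linalg.norm(ca - ca[i], axis=1), 6)
    js = [j for j in range(n) if j != i and d[j] <= cutoff]
    js.sort(key=lambda j: (d[j], j))
    return js
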