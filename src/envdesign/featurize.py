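"""Turn a residue's local environment into a K×46 feature matrix.

Each neighbor contributes one 46-dimensional row:

* 21 channels — one-hot amino-acid type (20 canonical + unknown);
* 12 channels — the relative rigid transform, row-major flattened 3×3
  rotation followed by the 3-vector translation in Å;
* 13 channels — one-hot of the signed sequence offset j − i clipped to
  [−6, +6].  The offset-0 bin is unreachable (a residue is never its own
  neighbor) but retained so the binning is symmetric.

Neighbor types come from whatever working sequence is supplied, so during
design the features track the current sequence as it mutates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import alphabet
from .geometry import RelativeTransform, build_frame, find_neighbors, relative_transform
from .structure_io import BackboneStructure, SequenceRecord

TYPE_DIM = 21
TRANSFORM_DIM = 12
OFFSET_DIM = 13
FEATURE_DIM = TYPE_DIM + TRANSFORM_DIM + OFFSET_DIM  # 46
OFFSET_CLIP = 6  # offsets beyond ±6 share the extreme bins


@dataclass(frozen=True)
class EnvironmentNeighbor:
    """One neighbor: its type index, relative transform, sequence offset."""

    type_index: int          # 0..20 (20 = unknown)
    transform: RelativeTransform
    seq_offset: int          # j − i, never 0


@dataclass(frozen=True)
class ResidueEnvironment:
    """The neighbor set describing one target position's surroundings."""

    target_position: int
    neighbors: tuple[EnvironmentNeighbor, ...]

    def __post_init__(self):
        if any(nb.seq_offset == 0 for nb in self.neighbors):
            raise ValueError("a neighbor cannot have sequence offset 0")

    @property
    def k(self) -> int:
        return len(self.neighbors)


@dataclass(frozen=True)
class EnvironmentFeatures:
    """K×46 feature matrix for one target position."""

    matrix: np.ndarray
    target_position: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != FEATURE_DIM:
            raise ValueError(f"feature matrix must be K×{FEATURE_DIM}")
        object.__setattr__(self, "matrix", m)

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def encode_amino_acid(code: str | int) -> np.ndarray:
    """21-way one-hot for a residue type (canonical or unknown)."""
    idx = code if isinstance(code, int) else alphabet.index_of(code)
    if not (0 <= idx <= alphabet.UNKNOWN_INDEX):
        raise ValueError(f"type index {idx} outside 0..{alphabet.UNKNOWN_INDEX}")
    v = np.zeros(TYPE_DIM)
    v[idx] = 1.0
    return v


def encode_transform(transform: RelativeTransform) -> np.ndarray:
    """12-vector: row-major flattened rotation then translation (Å)."""
    return np.concatenate(
        [transform.rotation.reshape(9), transform.translation]
    )


def encode_sequence_offset(offset: int) -> np.ndarray:
    """13-way one-hot of the signed offset clipped to [−6, +6]."""
    if offset == 0:
        raise ValueError("sequence offset 0 is reserved for the target itself")
    v = np.zeros(OFFSET_DIM)
    v[int(np.clip(offset, -OFFSET_CLIP, OFFSET_CLIP)) + OFFSET_CLIP] = 1.0
    return v


def build_environment(
    structure: BackboneStructure,
    sequence: SequenceRecord,
    i: int,
    cutoff: float,
) -> ResidueEnvironment:
    """Assemble position ``i``'s environment from the current sequence.

    Neighbor order follows :func:`find_neighbors` (distance, then index).
    Raises if the position is isolated (no Cα within the cutoff): such a
    residue has no defined environment and cannot be classified.
    """
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    js = find_neighbors(structure, i, cutoff)
    if not js:
        raise ValueError(f"position {i} has no neighbor within {cutoff} Å")
    frame_i = build_frame(structure.residues[i])
    neighbors = []
    for j in js:
        frame_j = build_frame(structure.residues[j])
        neighbors.append(
            EnvironmentNeighbor(
                type_index=alphabet.index_of(sequence.sequence[j]),
                transform=relative_transform(frame_i, frame_j),
                seq_offset=j - i,
            )
        )
    return ResidueEnvironment(target_position=i, neighbors=tuple(neighbors))


def featurize(env: ResidueEnvironment) -> EnvironmentFeatures:
    """Concatenate the per-neighbor encodings into the K×46 matrix."""
    if env.k < 1:
        raise ValueError("cannot featurize an empty environment")
    rows = [
        np.concatenate(
            [
                encode_amino_acid(nb.type_index),
                encode_transform(nb.transform),
                encode_sequence_offset(nb.seq_offset),
            ]
        )
        for nb in env.neighbors
    ]
    return EnvironmentFeatures(
        matrix=np.stack(rows), target_position=env.target_position
    )
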