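"""Backbone structure I/O: read PDB/mmCIF, validate, write FASTA.

A design target is specified entirely by the N, Cα, C coordinates of each
residue; sidechain and other atoms are ignored.  Residues missing any of
the three backbone atoms cannot carry a local frame and are dropped at
read time (and reported), so every downstream module sees only complete
backbones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import alphabet

BOND_MIN_A = 0.5   # plausible Cα–N / Cα–C bond length bounds, Å
BOND_MAX_A = 3.0


@dataclass(frozen=True)
class ResidueBackbone:
    """One residue's backbone: N, Cα, C coordinates (Å) plus identity."""

    seq_index: int
    n_coord: np.ndarray
    ca_coord: np.ndarray
    c_coord: np.ndarray
    native_type: str = alphabet.UNKNOWN_CODE  # one-letter code or "X"

    def __post_init__(self):
        for name in ("n_coord", "ca_coord", "c_coord"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)


@dataclass
class BackboneStructure:
    """Ordered residues of one chain; the design target."""

    residues: list[ResidueBackbone]
    chain_id: str = "A"
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __post_init__(self):
        # Index monotonicity is a soft invariant checked by validate_backbone,
        # so malformed inputs can be reported rather than refused outright.
        if len(self.residues) < 1:
            raise ValueError("a backbone structure needs at least one residue")

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα positions."""
        return np.stack([r.ca_coord for r in self.residues])

    def native_sequence(self) -> "SequenceRecord":
        seq = "".join(r.native_type for r in self.residues)
        return SequenceRecord(identifier=self.source_name or "native", sequence=seq)


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence aligned to a structure's residues."""

    identifier: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadReport:
    """Residues kept vs dropped while reading one chain."""

    kept: int = 0
    dropped_indices: list[int] = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return len(self.dropped_indices)


def read_backbone(
    path: str | Path,
    chain: str | None = None,
    report: ReadReport | None = None,
) -> BackboneStructure:
    """Read one chain's backbone from a PDB or mmCIF file.

    Parameters
    ----------
    path
        PDB or mmCIF file (dialect detected from content).
    chain
        Chain identifier; ``None`` selects the first chain that contains at
        least one complete-backbone residue.
    report
        Optional accumulator recording kept/dropped residue counts.

    Residues missing any of N, Cα, C are dropped and their author indices
    recorded in ``report``.  Alternate locations resolve to highest
    occupancy.  Non-standard residue names with complete backbones map to
    the unknown type marker (or their canonical parent for common modified
    residues such as MSE).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    st.remove_alternative_conformations()  # keeps highest-occupancy altloc
    if len(st) == 0:
        raise ValueError(f"zero residues: no models in {path}")
    model = st[0]

    chain_ids = [ch.name for ch in model]
    if chain is not None and chain not in chain_ids:
        raise ValueError(f"chain {chain!r} not present in {path} (has {chain_ids})")

    candidates = [chain] if chain is not None else chain_ids
    for chain_id in candidates:
        residues, rep = _extract_chain(model[chain_id])
        if residues:
            if report is not None:
                report.kept = rep.kept
                report.dropped_indices = rep.dropped_indices
            return BackboneStructure(
                residues=residues, chain_id=chain_id, source_name=path.stem
            )
    raise ValueError(f"zero residues with complete N/Cα/C backbone in {path}")


def _extract_chain(ch: gemmi.Chain) -> tuple[list[ResidueBackbone], ReadReport]:
    residues: list[ResidueBackbone] = []
    report = ReadReport()
    seen: set[int] = set()
    for res in ch:
        atoms = {}
        for atom in res:
            if atom.name in ("N", "CA", "C") and atom.name not in atoms:
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
        idx = res.seqid.num
        if idx in seen:
            continue
        if len(atoms) < 3:
            report.dropped_indices.append(idx)
            continue
        try:
            type_index = alphabet.index_of(res.name)
        except KeyError:
            type_index = alphabet.UNKNOWN_INDEX
        seen.add(idx)
        residues.append(
            ResidueBackbone(
                seq_index=idx,
                n_coord=atoms["N"],
                ca_coord=atoms["CA"],
                c_coord=atoms["C"],
                native_type=alphabet.one_letter(type_index),
            )
        )
    report.kept = len(residues)
    return residues, report


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write sequences as standard FASTA, 60 columns, uppercased."""
    if not records:
        raise ValueError("no records to write")
    bio = [
        _BioSeqRecord(Seq(r.sequence.upper()), id=r.identifier, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")  # wraps at 60 columns


@dataclass(frozen=True)
class ValidationFinding:
    seq_index: int
    kind: str      # "bond_length" | "duplicate_index" | "non_finite"
    detail: str


def validate_backbone(structure: BackboneStructure) -> list[ValidationFinding]:
    """Check bond lengths, index uniqueness, and coordinate finiteness.

    Returns findings; never raises, never mutates the input.
    """
    findings: list[ValidationFinding] = []
    seen: set[int] = set()
    for r in structure.residues:
        coords = np.concatenate([r.n_coord, r.ca_coord, r.c_coord])
        if not np.all(np.isfinite(coords)):
            findings.append(
                ValidationFinding(r.seq_index, "non_finite", "non-finite coordinate")
            )
            continue
        for other, label in ((r.n_coord, "Cα–N"), (r.c_coord, "Cα–C")):
            d = float(np.linalg.norm(r.ca_coord - other))
            if not (BOND_MIN_A < d < BOND_MAX_A):
                findings.append(
                    ValidationFinding(
                        r.seq_index, "bond_length", f"{label} = {d:.3f} Å"
                    )
                )
        if r.seq_index in seen:
            findings.append(
                ValidationFinding(r.seq_index, "duplicate_index", "duplicate seq_index")
            )
        seen.add(r.seq_index)
    idx = [r.seq_index for r in structure.residues]
    for a, b in zip(idx, idx[1:]):
        if b < a:  # equal indices already reported as duplicates
            findings.append(
                ValidationFinding(b, "index_order", f"index {b} follows {a}")
            )
    return findings
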