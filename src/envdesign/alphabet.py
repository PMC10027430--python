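"""Canonical amino-acid alphabet shared by every module.

The 20 canonical types are frozen in alphabetical three-letter order
(ALA ... VAL).  Index 20 is the "unknown / non-standard" marker used for
residues whose type cannot be mapped to a canonical one.  Featurization
encodes 21 type channels; the classifier head predicts only the 20
canonical types.
"""

from __future__ import annotations

# Alphabetical by three-letter code; one source of truth.
THREE_LETTER: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
ONE_LETTER: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

N_TYPES = 20          # canonical types (classifier output)
UNKNOWN_INDEX = 20    # 21st input channel
UNKNOWN_CODE = "X"

_THREE_TO_INDEX = {c: i for i, c in enumerate(THREE_LETTER)}
_ONE_TO_INDEX = {c: i for i, c in enumerate(ONE_LETTER)}

# Common non-standard residue names mapped to their parent canonical type.
_MODIFIED_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "SEP": "SER",
    "TPO": "THR", "PTR": "TYR", "HYP": "PRO", "MLY": "LYS",
    "CSO": "CYS", "KCX": "LYS",
}


def index_of(code: str) -> int:
    """Map a one- or three-letter residue code to an alphabet index.

    Returns ``UNKNOWN_INDEX`` for the unknown marker; raises ``KeyError``
    for codes that are neither canonical, the unknown marker, nor a known
    modified-residue name.
    """
    code = code.strip().upper()
    if code in (UNKNOWN_CODE, "UNK", "XAA"):
        return UNKNOWN_INDEX
    if len(code) == 1:
        return _ONE_TO_INDEX[code]
    if code in _THREE_TO_INDEX:
        return _THREE_TO_INDEX[code]
    if code in _MODIFIED_PARENT:
        return _THREE_TO_INDEX[_MODIFIED_PARENT[code]]
    raise KeyError(f"unrecognized residue code: {code!r}")


def one_letter(index: int) -> str:
    """One-letter code for an alphabet index (``X`` for unknown)."""
    if index == UNKNOWN_INDEX:
        return UNKNOWN_CODE
    return ONE_LETTER[index]


def is_canonical(code: str) -> bool:
    try:
        return index_of(code) < N_TYPES
    except KeyError:
        return False
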