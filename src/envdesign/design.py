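"""Iterative fixed-backbone sequence design.

The design objective is the pseudo-likelihood of the sequence given the
backbone: P(S|B) ≈ Π_i P(s_i | env_i), where env_i is the 12 Å local
environment of position i.  Starting from a random (or supplied)
sequence, the loop repeatedly (i) picks a position uniformly at random,
(ii) evaluates the classifier on that position's current environment,
and (iii) reassigns the position to the argmax type.  A mutation at i
changes the environments of every residue whose neighborhood contains i,
so those positions' conditional probabilities are refreshed before the
next step.  The loop stops once no letter has changed for a window of
consecutive steps (default: one sequence length) or a step budget is
exhausted.

The pseudo-log-likelihood is tracked per step; it is *not* guaranteed to
increase monotonically — reassigning one position can lower the terms of
its neighbors — but a converged sequence is a coordinate-wise fixed
point: a full sweep over all positions changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import alphabet
from .featurize import build_environment, featurize
from .geometry import find_neighbors
from .model import ClassifierModel, confidence_score, predict_batch
from .structure_io import BackboneStructure, SequenceRecord

DEFAULT_CUTOFF_A = 12.0


@dataclass(frozen=True)
class DesignConfig:
    cutoff: float = DEFAULT_CUTOFF_A
    max_iters: int | None = None          # None → 20·n single-position steps
    convergence_window: int | None = None  # None → n
    seed: int = 0
    init: str | None = None               # given start sequence, or None → random

    def resolve(self, n: int) -> tuple[int, int]:
        max_iters = 20 * n if self.max_iters is None else self.max_iters
        window = n if self.convergence_window is None else self.convergence_window
        if max_iters < 0 or window < 1:
            raise ValueError("max_iters must be ≥ 0 and window ≥ 1")
        return max_iters, window


@dataclass(frozen=True)
class TraceEntry:
    iteration: int
    position: int
    old_type: str
    new_type: str
    pseudo_log_likelihood: float


@dataclass
class DesignState:
    """Mutable state of one design run."""

    letters: list[str]
    initial_letters: list[str]
    iteration: int = 0
    per_position_logp: np.ndarray | None = None   # ln P(s_i|env_i); NaN if isolated
    per_position_confidence: np.ndarray | None = None
    trace: list[TraceEntry] = field(default_factory=list)
    converged: bool = False

    @property
    def pseudo_log_likelihood(self) -> float:
        """Σ_i ln P(s_i | env_i) over positions with a defined environment."""
        return float(np.nansum(self.per_position_logp))

    def sequence(self, identifier: str = "design") -> SequenceRecord:
        return SequenceRecord(identifier=identifier, sequence="".join(self.letters))


def initialize_sequence(
    n: int, config: DesignConfig, identifier: str = "design"
) -> SequenceRecord:
    """Uniform i.i.d. random start, or the given sequence verbatim."""
    if n < 1:
        raise ValueError("sequence length must be positive")
    if config.init is not None:
        if len(config.init) != n:
            raise ValueError(
                f"given start sequence has length {len(config.init)}, expected {n}"
            )
        return SequenceRecord(identifier=identifier, sequence=config.init.upper())
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, alphabet.N_TYPES, size=n)
    seq = "".join(alphabet.one_letter(int(i)) for i in idx)
    return SequenceRecord(identifier=identifier, sequence=seq)


def _position_distributions(
    structure: BackboneStructure,
    letters: Sequence[str],
    positions: Sequence[int],
    model: ClassifierModel,
    cutoff: float,
) -> np.ndarray:
    """(len(positions), 20) distributions under the current sequence."""
    seq = SequenceRecord(identifier="work", sequence="".join(letters))
    feats = [
        featurize(build_environment(structure, seq, i, cutoff)) for i in positions
    ]
    return predict_batch(model, feats)


def pseudo_log_likelihood(
    sequence: SequenceRecord,
    structure: BackboneStructure,
    model: ClassifierModel,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> float:
    """Σ_i ln P(s_i | env_i) over positions with ≥1 neighbor (natural log)."""
    if len(sequence) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    positions = [
        i for i in range(len(structure)) if find_neighbors(structure, i, cutoff)
    ]
    if not positions:
        return 0.0
    probs = _position_distributions(
        structure, list(sequence.sequence), positions, model, cutoff
    )
    letters = sequence.sequence
    total = 0.0
    for row, i in zip(probs, positions):
        total += float(np.log(row[alphabet.index_of(letters[i])]))
    return total


class _Designer:
    """Bookkeeping for one design run: neighbor lists and cached log-probs."""

    def __init__(
        self,
        structure: BackboneStructure,
        model: ClassifierModel,
        cutoff: float,
        state: DesignState,
    ):
        self.structure = structure
        self.model = model
        self.cutoff = cutoff
        self.state = state
        n = len(structure)
        self.neighbors = [find_neighbors(structure, i, cutoff) for i in range(n)]
        self.designable = [i for i in range(n) if self.neighbors[i]]
        if not self.designable:
            raise ValueError("structure has zero designable positions")
        state.per_position_logp = np.full(n, np.nan)
        self._refresh(self.designable)

    def _refresh(self, positions: Sequence[int]) -> np.ndarray:
        probs = _position_distributions(
            self.structure, self.state.letters, positions, self.model, self.cutoff
        )
        for row, i in zip(probs, positions):
            self.state.per_position_logp[i] = float(
                np.log(row[alphabet.index_of(self.state.letters[i])])
            )
        return probs

    def step(self, rng: np.random.Generator) -> bool:
        """One random-position argmax reassignment; returns True if changed."""
        st = self.state
        i = self.designable[int(rng.integers(0, len(self.designable)))]
        dist = _position_distributions(
            self.structure, st.letters, [i], self.model, self.cutoff
        )[0]
        new_idx = int(np.argmax(dist))  # first maximum → lowest alphabet index
        old = st.letters[i]
        new = alphabet.one_letter(new_idx)
        st.letters[i] = new
        st.per_position_logp[i] = float(np.log(dist[new_idx]))
        if new != old:
            # positions whose environment contains i see a changed type
            self._refresh([j for j in self.neighbors[i]])
        st.iteration += 1
        st.trace.append(
            TraceEntry(
                iteration=st.iteration,
                position=i,
                old_type=old,
                new_type=new,
                pseudo_log_likelihood=st.pseudo_log_likelihood,
            )
        )
        return new != old

    def final_confidences(self) -> np.ndarray:
        conf = np.full(len(self.structure), np.nan)
        probs = self._refresh(self.designable)
        for row, i in zip(probs, self.designable):
            conf[i] = confidence_score(row)
        return conf


def design_step(
    state: DesignState,
    model: ClassifierModel,
    structure: BackboneStructure,
    rng: np.random.Generator,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> DesignState:
    """Run a single design step on an existing state (in place)."""
    designer = _Designer(structure, model, cutoff, state)
    designer.step(rng)
    return state


def design(
    structure: BackboneStructure,
    model: ClassifierModel,
    config: DesignConfig = DesignConfig(),
) -> tuple[SequenceRecord, DesignState]:
    """Design a sequence for a backbone; returns (sequence, full state).

    Stops when no mutation has changed a letter for ``convergence_window``
    consecutive steps (``state.converged = True``) or after ``max_iters``
    steps.  Positions without any neighbor inside the cutoff have no
    defined environment; they keep their initial letter and are excluded
    from selection.  Fully seeded: identical config ⇒ identical output.
    """
    n = len(structure)
    max_iters, window = config.resolve(n)
    ss = np.random.SeedSequence(config.seed)
    init_seed, step_seed = ss.spawn(2)
    init = initialize_sequence(
        n, DesignConfig(seed=init_seed.generate_state(1)[0] % 2**31,
                        init=config.init),
    )
    state = DesignState(
        letters=list(init.sequence), initial_letters=list(init.sequence)
    )
    designer = _Designer(structure, model, config.cutoff, state)
    rng = np.random.default_rng(step_seed)
    unchanged_streak = 0
    while state.iteration < max_iters:
        changed = designer.step(rng)
        unchanged_streak = 0 if changed else unchanged_streak + 1
        if unchanged_streak >= window:
            state.converged = True
            break
    state.per_position_confidence = designer.final_confidences()
    return state.sequence(identifier=f"{structure.source_name}_design"), state
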