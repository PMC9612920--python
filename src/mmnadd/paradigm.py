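"""Multi-feature oddball paradigm construction.

Two block types are generated:

* the *complex* musical multi-feature paradigm, built from four-tone Alberti
  bass patterns (lowest-highest-middle-highest) at a 205 ms stimulus onset
  asynchrony (SOA), where deviants replace the third tone of every fourth
  pattern and three standard patterns separate consecutive deviant patterns;
* the *simple* control paradigm, a classical oddball at a 400 ms SOA in which
  each deviant is preceded by 3-5 standard tones.

Both paradigms cycle through 12 chromatic pitch levels (A#2-A3) and present
seven deviant types (three single-, three double-, one triple-feature) once
per pitch level, in a seeded pseudo-random permutation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOA_COMPLEX_S = 0.205
SOA_SIMPLE_S = 0.400
N_PITCH_LEVELS = 12
ITERATIONS_COMPLEX = 3
ITERATIONS_SIMPLE = 4

#: Alberti bass pattern positions; the deviant replaces position 3 ("middle").
PATTERN_LENGTH = 4
DEVIANT_PATTERN_POSITION = 3

# Acoustic deviant magnitudes applied to the standard tones.
FREQUENCY_DEVIANT_CENTS = -35.0
INTENSITY_DEVIANT_DB = -12.0
LOCATION_DEVIANT_ITD_US = 200.0


class DeviantType(str, Enum):
    """Condition code: the standard or one of seven deviant types."""

    STD = "STD"
    F = "F"
    I = "I"
    L = "L"
    FI = "FI"
    IL = "IL"
    LF = "LF"
    FIL = "FIL"

    @property
    def constituents(self) -> frozenset["DeviantType"]:
        """Single-feature deviants this condition is composed of."""
        return _CONSTITUENTS[self]

    @property
    def n_features(self) -> int:
        return len(self.constituents)

    @classmethod
    def deviants(cls) -> tuple["DeviantType", ...]:
        """The seven deviant types, singles first."""
        return (cls.F, cls.I, cls.L, cls.FI, cls.IL, cls.LF, cls.FIL)

    @classmethod
    def combinations(cls) -> tuple["DeviantType", ...]:
        """Double and triple deviants (those with a modeled counterpart)."""
        return (cls.FI, cls.IL, cls.LF, cls.FIL)

    @classmethod
    def from_constituents(cls, features: Iterable["DeviantType"]) -> "DeviantType":
        fs = frozenset(features)
        for member in cls:
            if member is not cls.STD and _CONSTITUENTS[member] == fs:
                return member
        raise ValueError(f"no deviant type with constituents {sorted(f.value for f in fs)}")


_CONSTITUENTS = {
    DeviantType.STD: frozenset(),
    DeviantType.F: frozenset({DeviantType.F}),
    DeviantType.I: frozenset({DeviantType.I}),
    DeviantType.L: frozenset({DeviantType.L}),
    DeviantType.FI: frozenset({DeviantType.F, DeviantType.I}),
    DeviantType.IL: frozenset({DeviantType.I, DeviantType.L}),
    DeviantType.LF: frozenset({DeviantType.L, DeviantType.F}),
    DeviantType.FIL: frozenset({DeviantType.F, DeviantType.I, DeviantType.L}),
}


@dataclass(frozen=True)
class TrialEvent:
    """A single tone within a block."""

    onset_s: float
    role: str  # "standard" | "deviant"
    deviant_type: DeviantType
    pitch_index: int  # 0..11 (A#2..A3)
    pattern_position: int | None  # 1..4 in the complex paradigm, None otherwise
    is_analysis_standard: bool = False

    def __post_init__(self) -> None:
        if self.role == "deviant" and self.deviant_type is DeviantType.STD:
            raise ValueError("deviant events must carry a deviant type")
        if self.role == "standard" and self.deviant_type is not DeviantType.STD:
            raise ValueError("standard events must carry the STD code")
        if self.is_analysis_standard and self.role != "standard":
            raise ValueError("only standards can be analysis standards")


@dataclass
class BlockSequence:
    """Ordered tone schedule of one paradigm block."""

    paradigm: str  # "complex" | "simple"
    block_id: str
    events: list[TrialEvent]
    seed: int

    @property
    def soa_s(self) -> float:
        return SOA_COMPLEX_S if self.paradigm == "complex" else SOA_SIMPLE_S

    @property
    def duration_s(self) -> float:
        return len(self.events) * self.soa_s

    def deviant_counts(self) -> dict[DeviantType, int]:
        counts = {d: 0 for d in DeviantType.deviants()}
        for ev in self.events:
            if ev.role == "deviant":
                counts[ev.deviant_type] += 1
        return counts

    def to_frame(self, tuning_a4_hz: float = 440.0) -> pd.DataFrame:
        """Event-log table (one row per tone)."""
        freqs = chromatic_frequencies("A#2", "A3", tuning_a4_hz)
        rows = []
        for i, ev in enumerate(self.events):
            rows.append(
                {
                    "block_id": self.block_id,
                    "paradigm": self.paradigm,
                    "index": i,
                    "onset_s": round(ev.onset_s, 6),
                    "role": ev.role,
                    "deviant_type": ev.deviant_type.value,
                    "pitch_index": ev.pitch_index,
                    "pitch_hz": freqs[ev.pitch_index],
                    "pattern_position": -1 if ev.pattern_position is None else ev.pattern_position,
                    "is_analysis_standard": ev.is_analysis_standard,
                }
            )
        return pd.DataFrame(rows)


_NOTE_RE = re.compile(r"^([A-Ga-g])([#b]?)(-?\d+)$")
_PITCH_CLASS = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def _note_to_midi(note: str) -> int:
    m = _NOTE_RE.match(note.strip())
    if m is None:
        raise ValueError(f"unparseable note name: {note!r}")
    letter, accidental, octave = m.groups()
    pc = _PITCH_CLASS[letter.upper()]
    pc += {"#": 1, "b": -1, "": 0}[accidental]
    return 12 * (int(octave) + 1) + pc


def chromatic_frequencies(
    low_note: str, high_note: str, tuning_a4_hz: float = 440.0
) -> list[float]:
    """Equal-temperament frequencies, one per semitone from *low_note* to *high_note*.

    f = tuning * 2**(semitones_from_A4 / 12), reported to 0.01 Hz.  A#2-A3 at
    A4 = 440 Hz yields the 12 standard-tone fundamentals 116.54 ... 220.00 Hz.
    """
    if tuning_a4_hz <= 0:
        raise ValueError("tuning frequency must be positive")
    lo, hi = _note_to_midi(low_note), _note_to_midi(high_note)
    if lo > hi:
        raise ValueError(f"{low_note} is above {high_note}")
    return [round(tuning_a4_hz * 2.0 ** ((m - 69) / 12.0), 2) for m in range(lo, hi + 1)]


def cents_shift(f0_hz: float, cents: float) -> float:
    """Shift a frequency by a signed number of cents: f0 * 2**(cents/1200)."""
    if f0_hz <= 0:
        raise ValueError("f0 must be positive")
    return f0_hz * 2.0 ** (cents / 1200.0)


def _pitch_orders(rng: np.random.Generator, n_iterations: int) -> list[np.ndarray]:
    """Shuffled pitch-level orders, no identical level back-to-back across iterations."""
    orders: list[np.ndarray] = []
    last = -1
    for _ in range(n_iterations):
        order = rng.permutation(N_PITCH_LEVELS)
        while order[0] == last:
            order = rng.permutation(N_PITCH_LEVELS)
        orders.append(order)
        last = int(order[-1])
    return orders


def generate_complex_block(block_id: str, seed: int) -> BlockSequence:
    """One complex musical multi-feature block.

    3 iterations x 12 pitch levels; at each pitch level the 7 deviant types
    appear once in a seeded permutation; each deviant slot consists of 3
    standard Alberti patterns followed by one pattern whose third tone is the
    deviant.  4032 tones in total, 36 deviants per type, 826.56 s.
    """
    rng = np.random.default_rng(seed)
    events: list[TrialEvent] = []
    idx = 0
    for order in _pitch_orders(rng, ITERATIONS_COMPLEX):
        for pitch in order:
            for dev in rng.permutation(len(DeviantType.deviants())):
                dev_type = DeviantType.deviants()[dev]
                for pattern in range(4):  # 3 standard patterns + 1 deviant pattern
                    for pos in range(1, PATTERN_LENGTH + 1):
                        is_dev = pattern == 3 and pos == DEVIANT_PATTERN_POSITION
                        events.append(
                            TrialEvent(
                                onset_s=idx * SOA_COMPLEX_S,
                                role="deviant" if is_dev else "standard",
                                deviant_type=dev_type if is_dev else DeviantType.STD,
                                pitch_index=int(pitch),
                                pattern_position=pos,
                            )
                        )
                        idx += 1
    return BlockSequence("complex", block_id, events, seed)


def generate_simple_block(block_id: str, seed: int) -> BlockSequence:
    """One simple control block.

    4 iterations x 12 pitch levels x 7 deviant types; each deviant is preceded
    by 3-5 standards (uniform, seeded); SOA 400 ms.  48 deviants per type per
    block; the expected duration is 672 s (~11 min).
    """
    rng = np.random.default_rng(seed)
    events: list[TrialEvent] = []
    idx = 0
    for order in _pitch_orders(rng, ITERATIONS_SIMPLE):
        for pitch in order:
            for dev in rng.permutation(len(DeviantType.deviants())):
                dev_type = DeviantType.deviants()[dev]
                n_pre = int(rng.integers(3, 6))
                for _ in range(n_pre):
                    events.append(
                        TrialEvent(
                            onset_s=idx * SOA_SIMPLE_S,
                            role="standard",
                            deviant_type=DeviantType.STD,
                            pitch_index=int(pitch),
                            pattern_position=None,
                        )
                    )
                    idx += 1
                events.append(
                    TrialEvent(
                        onset_s=idx * SOA_SIMPLE_S,
                        role="deviant",
                        deviant_type=dev_type,
                        pitch_index=int(pitch),
                        pattern_position=None,
                    )
                )
                idx += 1
    return BlockSequence("simple", block_id, events, seed)


def mark_analysis_standards(seq: BlockSequence) -> BlockSequence:
    """Flag the standard trial retained for analysis after each deviant.

    Simple paradigm: the third standard *tone* following each deviant.
    Complex paradigm: the position-3 tone of the third standard *pattern*
    following each deviant pattern, so that analysed standards occupy the same
    within-pattern position as the deviants.  A deviant followed by fewer than
    three standards (or standard patterns) before the block ends, or before
    the next deviant, contributes no standard trial.
    """
    if not any(ev.role == "deviant" for ev in seq.events):
        logger.warning("block %s contains no deviants; nothing to mark", seq.block_id)
        return replace(seq, events=list(seq.events))

    marked: set[int] = set()
    if seq.paradigm == "simple":
        n_since_dev = -1  # -1: before any deviant
        for i, ev in enumerate(seq.events):
            if ev.role == "deviant":
                n_since_dev = 0
            elif n_since_dev >= 0:
                n_since_dev += 1
                if n_since_dev == 3:
                    marked.add(i)
                    n_since_dev = -1
    else:
        patterns = [seq.events[i : i + PATTERN_LENGTH] for i in range(0, len(seq.events), PATTERN_LENGTH)]
        starts = list(range(0, len(seq.events), PATTERN_LENGTH))
        n_since_dev = -1
        for p, pat in enumerate(patterns):
            if any(ev.role == "deviant" for ev in pat):
                n_since_dev = 0
            elif n_since_dev >= 0:
                n_since_dev += 1
                if n_since_dev == 3:
                    marked.add(starts[p] + DEVIANT_PATTERN_POSITION - 1)
                    n_since_dev = -1

    events = [
        replace(ev, is_analysis_standard=True) if i in marked else ev
        for i, ev in enumerate(seq.events)
    ]
    return replace(seq, events=events)


def paradigm_trial_table(blocks: Sequence[BlockSequence]) -> pd.DataFrame:
    """Per-(paradigm, deviant type) trial bookkeeping.

    Analysis standards are attributed to the type of the deviant they follow.
    The STD row reports the total standard-tone count per paradigm.
    """
    if not blocks:
        raise ValueError("need at least one block")
    paradigms = sorted({blk.paradigm for blk in blocks})
    rows = []
    for paradigm in paradigms:
        par_blocks = [b for b in blocks if b.paradigm == paradigm]
        duration = sum(b.duration_s for b in par_blocks)
        n_dev = {d: 0 for d in DeviantType.deviants()}
        n_anl = {d: 0 for d in DeviantType}
        n_std = 0
        for blk in par_blocks:
            last_dev: DeviantType | None = None
            for ev in blk.events:
                if ev.role == "deviant":
                    n_dev[ev.deviant_type] += 1
                    last_dev = ev.deviant_type
                else:
                    n_std += 1
                    if ev.is_analysis_standard:
                        n_anl[DeviantType.STD] += 1
                        if last_dev is not None:
                            n_anl[last_dev] += 1
                            last_dev = None
        rows.append(
            {
                "paradigm": paradigm,
                "deviant_type": DeviantType.STD.value,
                "n_deviants": 0,
                "n_standards": n_std,
                "n_analysis_standards": n_anl[DeviantType.STD],
                "total_duration_s": round(duration, 3),
            }
        )
        for d in DeviantType.deviants():
            rows.append(
                {
                    "paradigm": paradigm,
                    "deviant_type": d.value,
                    "n_deviants": n_dev[d],
                    "n_standards": 0,
                    "n_analysis_standards": n_anl[d],
                    "total_duration_s": round(duration, 3),
                }
            )
    return pd.DataFrame(rows)


def trial_plan_from_blocks(blocks: Sequence[BlockSequence]) -> dict[DeviantType, int]:
    """Per-condition analysis-trial counts implied by marked blocks.

    Deviant conditions count deviant tones; STD counts analysis standards.
    """
    plan = {d: 0 for d in DeviantType}
    for blk in blocks:
        for ev in blk.events:
            if ev.role == "deviant":
                plan[ev.deviant_type] += 1
            elif ev.is_analysis_standard:
                plan[DeviantType.STD] += 1
    return plan
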