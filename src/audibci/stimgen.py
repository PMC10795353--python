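"""Dual-stream auditory oddball stimulus sequences.

The paradigm interleaves a "yes" stream (right ear) and a "no" stream
(left ear).  Each block presents, per stream, ``n_std`` short standard
words (100 ms) and ``n_dev`` long deviant words (150 ms) in pseudo-random
order with at least two standards between consecutive deviants.  The two
streams strictly alternate, so the global onset-to-onset interval between
consecutive sounds (from either stream) is the SOA, and the spacing within
one stream is twice the SOA.  The "yes" stream leads the "no" stream by
``stream_lag`` (one SOA by default), hence a default block of
2 x (30 + 6) = 72 stimuli at SOA 250 ms lasts 72 x 0.25 = 18 s.

One block yields one yes/no answer: the listener attends one stream and
counts its deviants, and the decoder infers the attended side.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Stream",
    "Kind",
    "StimulusEvent",
    "BlockSpec",
    "SessionPlan",
    "InfeasibleDesignError",
    "MARKER_CODES",
    "CODE_TO_CONDITION",
    "BLOCK_START_MARKER",
    "BLOCK_END_MARKER",
    "STANDARD_DURATION_MS",
    "DEVIANT_DURATION_MS",
    "generate_block",
    "generate_session",
    "block_marker_table",
]


class Stream(str, enum.Enum):
    YES = "YES"
    NO = "NO"

    def other(self) -> "Stream":
        return Stream.NO if self is Stream.YES else Stream.YES


class Kind(str, enum.Enum):
    STANDARD = "STANDARD"
    DEVIANT = "DEVIANT"


STANDARD_DURATION_MS = 100
DEVIANT_DURATION_MS = 150

#: marker codes written to event channels / .vmrk files
MARKER_CODES = {
    (Stream.YES, Kind.STANDARD): 11,
    (Stream.YES, Kind.DEVIANT): 12,
    (Stream.NO, Kind.STANDARD): 21,
    (Stream.NO, Kind.DEVIANT): 22,
}
CODE_TO_CONDITION = {v: k for k, v in MARKER_CODES.items()}
BLOCK_START_MARKER = 1
BLOCK_END_MARKER = 2


class InfeasibleDesignError(ValueError):
    """Raised when the deviant-spacing constraint cannot be satisfied."""


@dataclass(frozen=True)
class StimulusEvent:
    onset: float  # seconds from block start
    stream: Stream
    kind: Kind
    sound_duration: int = 0  # ms, filled from kind if 0
    marker_code: int = 0

    def __post_init__(self):
        dur = (
            STANDARD_DURATION_MS if self.kind is Kind.STANDARD else DEVIANT_DURATION_MS
        )
        if self.sound_duration == 0:
            object.__setattr__(self, "sound_duration", dur)
        elif self.sound_duration != dur:
            raise ValueError(
                f"sound_duration {self.sound_duration} inconsistent with {self.kind}"
            )
        if self.marker_code == 0:
            object.__setattr__(self, "marker_code", MARKER_CODES[(self.stream, self.kind)])
        if self.onset < 0:
            raise ValueError("onset must be >= 0")


@dataclass(frozen=True)
class BlockSpec:
    """One 2x(n_std+n_dev)-stimulus block and its intended answer."""

    events: tuple[StimulusEvent, ...]
    soa: float  # global onset-to-onset interval, seconds
    target: Stream
    n_std_per_stream: int = 30
    n_dev_per_stream: int = 6
    stream_lag: float = 0.250

    @property
    def duration(self) -> float:
        """Stimulation time of the block: n_events x SOA seconds."""
        return len(self.events) * self.soa

    def stream_events(self, stream: Stream) -> list[StimulusEvent]:
        return [e for e in self.events if e.stream is stream]

    def validate(self) -> None:
        n_total = 2 * (self.n_std_per_stream + self.n_dev_per_stream)
        if len(self.events) != n_total:
            raise ValueError(f"expected {n_total} events, got {len(self.events)}")
        onsets = [e.onset for e in self.events]
        if sorted(onsets) != onsets or len(set(onsets)) != len(onsets):
            raise ValueError("event onsets must be strictly increasing and unique")
        for stream in Stream:
            evs = self.stream_events(stream)
            kinds = [e.kind for e in evs]
            if sum(k is Kind.STANDARD for k in kinds) != self.n_std_per_stream:
                raise ValueError(f"wrong standard count in {stream.value} stream")
            if sum(k is Kind.DEVIANT for k in kinds) != self.n_dev_per_stream:
                raise ValueError(f"wrong deviant count in {stream.value} stream")
            dev_pos = [i for i, k in enumerate(kinds) if k is Kind.DEVIANT]
            if any(b - a < 3 for a, b in zip(dev_pos, dev_pos[1:])):
                raise ValueError("deviants closer than 2 standards apart")
            diffs = np.diff([e.onset for e in evs])
            if not np.allclose(diffs, 2 * self.soa):
                raise ValueError("within-stream onsets must step by one per-stream SOA")
        first_yes = self.stream_events(Stream.YES)[0].onset
        first_no = self.stream_events(Stream.NO)[0].onset
        if not math.isclose(first_no - first_yes, self.stream_lag, abs_tol=1e-9):
            raise ValueError("yes stream must lead the no stream by stream_lag")


@dataclass(frozen=True)
class SessionPlan:
    calibration_blocks: tuple[BlockSpec, ...]
    test_blocks: tuple[BlockSpec, ...]
    soa: float
    montage_name: str = "acticap32"

    @property
    def blocks(self) -> tuple[BlockSpec, ...]:
        return self.calibration_blocks + self.test_blocks

    @property
    def targets(self) -> tuple[Stream, ...]:
        return tuple(b.target for b in self.blocks)


def _draw_deviant_positions(
    n_slots: int,
    n_dev: int,
    rng: np.random.Generator,
    min_gap: int = 3,
    forbid_edges: bool = False,
) -> np.ndarray:
    """Uniform draw of ``n_dev`` slot indices with pairwise gaps >= min_gap.

    Uses the standard bijection between gap-constrained position sets
    {p_1 < ... < p_k : p_{i+1} - p_i >= g} in [0, n) and unconstrained
    k-subsets of [0, n - (g-1)(k-1)), so the draw is exactly uniform over
    admissible placements (no rejection loop).
    """
    if n_dev == 0:
        return np.empty(0, dtype=int)
    lo, hi = (1, n_slots - 1) if forbid_edges else (0, n_slots)
    span = hi - lo - (min_gap - 1) * (n_dev - 1)
    if span < n_dev:
        raise InfeasibleDesignError(
            f"cannot place {n_dev} deviants with >= {min_gap - 1} standards "
            f"in between within {n_slots} slots"
        )
    base = np.sort(rng.choice(span, size=n_dev, replace=False))
    return base + (min_gap - 1) * np.arange(n_dev) + lo


def _stream_kinds(
    n_std: int, n_dev: int, rng: np.random.Generator, forbid_edges: bool
) -> list[Kind]:
    n_slots = n_std + n_dev
    dev_pos = set(
        _draw_deviant_positions(n_slots, n_dev, rng, forbid_edges=forbid_edges).tolist()
    )
    return [Kind.DEVIANT if i in dev_pos else Kind.STANDARD for i in range(n_slots)]


def generate_block(
    n_std: int = 30,
    n_dev: int = 6,
    soa: float = 0.250,
    stream_lag: float | None = None,
    target: Stream | str = Stream.YES,
    seed: int | None = None,
    forbid_edge_deviants: bool = False,
) -> BlockSpec:
    """Generate one pseudo-randomized dual-stream oddball block.

    Parameters
    ----------
    n_std, n_dev
        Standards and deviants per stream (defaults 30 and 6).
    soa
        Global onset-to-onset interval in seconds between consecutive
        sounds regardless of stream (0.250 s default); the within-stream
        interval is ``2 * soa``.
    stream_lag
        Lead of the yes stream over the no stream; defaults to ``soa``
        (strict alternation).
    target
        The stream the listener is instructed/intended to attend.
    seed
        Mandatory seed; deviant placement is drawn uniformly among
        admissible orderings of each stream independently.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible block generation")
    if n_std <= 0 or n_dev < 0:
        raise ValueError("counts must be positive (n_dev may be zero)")
    if soa <= 0:
        raise ValueError("soa must be positive")
    if n_dev > 0 and n_std < 2 * n_dev:
        raise InfeasibleDesignError(
            f"n_std={n_std} < 2*n_dev={2 * n_dev}: spacing constraint unsatisfiable"
        )
    target = Stream(target)
    if stream_lag is None:
        stream_lag = soa
    rng = np.random.default_rng(seed)
    kinds = {s: _stream_kinds(n_std, n_dev, rng, forbid_edge_deviants) for s in Stream}
    events = []
    for i in range(n_std + n_dev):
        for stream, offset in ((Stream.YES, 0.0), (Stream.NO, stream_lag)):
            events.append(
                StimulusEvent(
                    onset=i * 2 * soa + offset,
                    stream=stream,
                    kind=kinds[stream][i],
                )
            )
    events.sort(key=lambda e: e.onset)
    block = BlockSpec(
        events=tuple(events),
        soa=soa,
        target=target,
        n_std_per_stream=n_std,
        n_dev_per_stream=n_dev,
        stream_lag=stream_lag,
    )
    block.validate()
    return block


def _balanced_targets(n: int) -> list[Stream]:
    return [Stream.YES if i % 2 == 0 else Stream.NO for i in range(n)]


def generate_session(
    n_calibration: int = 14,
    n_test: int = 50,
    soa: float = 0.250,
    targets: list[Stream | str] | None = None,
    seed: int | None = None,
    n_std: int = 30,
    n_dev: int = 6,
    montage_name: str = "acticap32",
) -> SessionPlan:
    """Plan a session: instructed calibration blocks then test blocks.

    Per-block seeds are derived deterministically from the master seed via
    ``numpy.random.SeedSequence`` spawning, so any block can be regenerated
    independently and the whole plan is reproducible bit for bit.
    """
    if seed is None:
        raise ValueError("seed is required")
    n_blocks = n_calibration + n_test
    if targets is None:
        targets = _balanced_targets(n_calibration) + _balanced_targets(n_test)
    targets = [Stream(t) for t in targets]
    if len(targets) != n_blocks:
        raise ValueError(
            f"targets length {len(targets)} != n_calibration+n_test {n_blocks}"
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_blocks) % (2**31)
    blocks = [
        generate_block(
            n_std=n_std,
            n_dev=n_dev,
            soa=soa,
            target=t,
            seed=int(s),
        )
        for t, s in zip(targets, child_seeds)
    ]
    return SessionPlan(
        calibration_blocks=tuple(blocks[:n_calibration]),
        test_blocks=tuple(blocks[n_calibration:]),
        soa=soa,
        montage_name=montage_name,
    )


def block_marker_table(block: BlockSpec, t0: float = 0.0) -> pd.DataFrame:
    """Event list of one block as a marker table (onset_s, marker_code, ...)."""
    rows = [
        {
            "onset_s": t0 + e.onset,
            "marker_code": e.marker_code,
            "stream": e.stream.value,
            "kind": e.kind.value,
            "duration_ms": e.sound_duration,
        }
        for e in block.events
    ]
    return pd.DataFrame(rows)


def write_vmrk_lines(block: BlockSpec, fs: float, start_sample: int = 1) -> list[str]:
    """Render one block's events as BrainVision marker lines ('S 11' style)."""
    lines = []
    for i, e in enumerate(block.events, start=1):
        sample = start_sample + int(round(e.onset * fs))
        lines.append(f"Mk{i}=Stimulus,S{e.marker_code:>3},{sample},1,0")
    return lines
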