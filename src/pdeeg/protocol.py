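"""Auditory assessment protocol: blocks, trials, silences, and cognitive-load coding.

The assessment battery is a musical detection task (two difficulty levels),
a musical n-back task (two difficulty levels: 0-back and 1-back) and two
resting-state blocks.  A schedule realizes the printed trial/silence ranges
into a concrete, seeded event list which drives the EEG simulator and the
per-second condition labels used downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("rest", "detection1", "detection2", "nback0", "nback1")

#: Ordinal cognitive-load coding: rest = 0; detection level 1 and 0-back = 1
#: (low load); detection level 2 and 1-back = 2 (high load).
LOAD_CODING: dict[str, int] = {
    "rest": 0,
    "detection1": 1,
    "nback0": 1,
    "detection2": 2,
    "nback1": 2,
}


def load_level(condition: str) -> int:
    """Map a condition name to its ordinal cognitive-load level (0, 1 or 2)."""
    try:
        return LOAD_CODING[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        ) from None


@dataclass(frozen=True)
class BlockSpec:
    """Static description of one protocol block before realization.

    Parameters
    ----------
    condition : str
        One of :data:`CONDITIONS`.
    duration_s : float
        Block length in seconds.  ``None`` means the block length is set by
        its realized content (used for detection level 2, whose block length
        is not fixed by the protocol).
    n_trials_range : (int, int)
        Inclusive range of stimulus counts.
    stimulus_dur_s : float
        Length of one stimulus in seconds.
    silence_range_s : (float, float)
        Inclusive range of inter-stimulus silences.
    target_fraction_range : (float, float) or None
        For n-back blocks: admissible range of the realized target fraction.
    """

    condition: str
    duration_s: float | None
    n_trials_range: tuple[int, int]
    stimulus_dur_s: float
    silence_range_s: tuple[float, float]
    target_fraction_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.stimulus_dur_s < 0:
            raise ValueError("stimulus_dur_s must be non-negative")
        lo, hi = self.silence_range_s
        if lo > hi:
            raise ValueError("silence range min must be <= max")


@dataclass
class RealizedBlock:
    condition: str
    onset_s: float
    duration_s: float
    events: list[tuple[float, float, str]]  # (onset_s, duration_s, event_type)


@dataclass
class ProtocolSchedule:
    """A realized protocol: ordered blocks plus a flat event list."""

    blocks: list[RealizedBlock]

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))

    @property
    def event_list(self) -> list[tuple[float, float, str]]:
        out: list[tuple[float, float, str]] = []
        for b in self.blocks:
            out.extend(b.events)
        return out

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            rows.append((b.onset_s, b.duration_s, b.condition, "block"))
            for onset, dur, etype in b.events:
                rows.append((onset, dur, b.condition, etype))
        return pd.DataFrame(
            rows, columns=["onset_s", "duration_s", "condition", "event_type"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "blocks": [
                {
                    "condition": b.condition,
                    "onset_s": b.onset_s,
                    "duration_s": b.duration_s,
                    "events": b.events,
                }
                for b in self.blocks
            ]
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ProtocolSchedule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        blocks = [
            RealizedBlock(
                condition=b["condition"],
                onset_s=b["onset_s"],
                duration_s=b["duration_s"],
                events=[tuple(e) for e in b["events"]],
            )
            for b in payload["blocks"]
        ]
        return cls(blocks=blocks)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProtocolSchedule":
        df = pd.read_csv(path)
        blocks: list[RealizedBlock] = []
        for _, row in df.iterrows():
            if row.event_type == "block":
                blocks.append(
                    RealizedBlock(row.condition, row.onset_s, row.duration_s, [])
                )
            else:
                blocks[-1].events.append(
                    (float(row.onset_s), float(row.duration_s), row.event_type)
                )
        return cls(blocks=blocks)


# --------------------------------------------------------------------------
# Default block specifications (printed protocol parameters)
# --------------------------------------------------------------------------

DETECTION1 = BlockSpec("detection1", 90.0, (5, 6), 3.0, (10.0, 18.0))
DETECTION2 = BlockSpec("detection2", None, (6, 8), 1.5, (8.0, 14.0),
                       target_fraction_range=None)
NBACK0 = BlockSpec("nback0", 90.0, (9, 9), 1.5, (6.0, 11.0))
NBACK1 = BlockSpec("nback1", 90.0, (12, 14), 1.5, (4.0, 6.0),
                   target_fraction_range=(0.30, 0.40))
REST45 = BlockSpec("rest", 45.0, (0, 0), 0.0, (0.0, 0.0))
REST60 = BlockSpec("rest", 60.0, (0, 0), 0.0, (0.0, 0.0))

#: detection level 2: number of trials is not printed; default one trial per
#: instrument (violin, trumpet, flute), and the target tune plays 2-3 times.
N_DETECTION2_TRIALS = 3


def _realize_block(spec: BlockSpec, onset: float, rng: np.random.Generator,
                   n_targets: int | None = None) -> RealizedBlock:
    """Draw trial counts and silences from the printed ranges.

    Stimuli are laid out as silence / stimulus alternations starting with a
    leading silence.  If the drawn content overflows a fixed block duration
    (possible in the worst case of the printed ranges), silences are rescaled
    proportionally so the schedule fits; leftover time trails as silence.
    """
    if spec.condition == "rest":
        return RealizedBlock(spec.condition, onset, float(spec.duration_s), [])

    lo, hi = spec.n_trials_range
    n = int(rng.integers(lo, hi + 1))
    silences = rng.uniform(*spec.silence_range_s, size=n)
    content = n * spec.stimulus_dur_s + float(silences.sum())
    if spec.duration_s is None:
        duration = float(np.ceil(content))
    else:
        duration = float(spec.duration_s)
        if content > duration:
            budget = duration - n * spec.stimulus_dur_s
            silences = silences * (budget / silences.sum())

    targets: set[int] = set()
    if n_targets is not None:
        targets = set(rng.choice(n, size=n_targets, replace=False).tolist())
    elif spec.target_fraction_range is not None:
        flo, fhi = spec.target_fraction_range
        admissible = [k for k in range(n + 1) if flo <= k / n <= fhi]
        k = int(rng.choice(admissible))
        targets = set(rng.choice(n, size=k, replace=False).tolist())

    events: list[tuple[float, float, str]] = []
    t = onset
    for i in range(n):
        t += float(silences[i])
        etype = "target_stimulus" if i in targets else "stimulus"
        events.append((round(t, 6), spec.stimulus_dur_s, etype))
        t += spec.stimulus_dur_s
    return RealizedBlock(spec.condition, onset, duration, events)


def build_default_protocol(seed: int = 0) -> ProtocolSchedule:
    """Realize the full default assessment battery.

    Block order (the protocol does not fix one): rest 45 s, three 90 s
    detection-level-1 trials, three detection-level-2 trials, one 90 s
    0-back block, two 90 s 1-back blocks, rest 60 s.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    blocks: list[RealizedBlock] = []
    t = 0.0

    def add(spec: BlockSpec, n_targets: int | None = None) -> None:
        nonlocal t
        b = _realize_block(spec, t, rng, n_targets=n_targets)
        blocks.append(b)
        t += b.duration_s

    add(REST45)
    for _ in range(3):
        add(DETECTION1)
    for _ in range(N_DETECTION2_TRIALS):
        add(DETECTION2, n_targets=int(rng.integers(2, 4)))
    add(NBACK0)
    add(NBACK1)
    add(NBACK1)
    add(REST60)
    return ProtocolSchedule(blocks=blocks)


def build_compact_protocol(seed: int = 0) -> ProtocolSchedule:
    """A shortened schedule with one block per condition (~6 min).

    Used for repeated-cohort simulation sweeps where the full battery would
    be wastefully long; the five conditions and their load levels are all
    represented, so every downstream contrast remains estimable.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    blocks: list[RealizedBlock] = []
    t = 0.0
    for spec in (REST45, DETECTION1, DETECTION2, NBACK0, NBACK1, REST60):
        n_targets = int(rng.integers(2, 4)) if spec.condition == "detection2" else None
        b = _realize_block(spec, t, rng, n_targets=n_targets)
        blocks.append(b)
        t += b.duration_s
    return ProtocolSchedule(blocks=blocks)


def label_timeline(schedule: ProtocolSchedule, hop_s: float = 1.0) -> list[str]:
    """Per-window condition labels: one label per ``hop_s`` step.

    The label of a window is the condition of the block containing the
    window start; the number of labels is ``floor(total_duration / hop_s)``.
    """
    if hop_s <= 0:
        raise ValueError("hop_s must be positive")
    if not schedule.blocks:
        raise ValueError("schedule is empty")
    n = int(np.floor(schedule.total_duration_s / hop_s))
    edges = np.cumsum([0.0] + [b.duration_s for b in schedule.blocks])
    starts = np.arange(n) * hop_s
    idx = np.clip(np.searchsorted(edges, starts, side="right") - 1,
                  0, len(schedule.blocks) - 1)
    return [schedule.blocks[i].condition for i in idx]
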