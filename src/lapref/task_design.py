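"""Counterbalanced block sequences and stimulus timelines for the
seven-condition passive face-viewing paradigm.

The paradigm presents 20-s blocks of five facial-expression conditions
(angry, fearful, happy, sad, neutral) plus two baselines (phase-scrambled
faces and fixation).  Within a run, block order is counterbalanced so that
no ordered pair of conditions occurs more than once, and per-condition
block counts are as even as possible.  Face blocks contain 40 rapid face
presentations (8 identities x 5 repetitions, 200 ms on / 300 ms ISI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FACE_LABELS = ("angry", "fearful", "happy", "sad", "neutral")
BASELINE_LABELS = ("scrambled", "fixation")
ALL_LABELS = FACE_LABELS + BASELINE_LABELS

#: valence class of each condition: negative faces are avoided, happy is
#: approached, neutral faces carry no valence, baselines anchor the GLM.
VALENCE_CLASS = {
    "angry": "negative",
    "fearful": "negative",
    "sad": "negative",
    "happy": "positive",
    "neutral": "neutral",
    "scrambled": "baseline",
    "fixation": "baseline",
}

NEGATIVE_LABELS = tuple(k for k in FACE_LABELS if VALENCE_CLASS[k] == "negative")
POSITIVE_LABELS = tuple(k for k in FACE_LABELS if VALENCE_CLASS[k] == "positive")


class DesignInfeasibleError(RuntimeError):
    """No valid counterbalanced sequence exists (or none was found within
    the backtracking budget)."""


@dataclass(frozen=True)
class Condition:
    """One stimulus condition with its valence class."""

    label: str
    valence_class: str = field(default="")

    def __post_init__(self):
        if not self.valence_class:
            if self.label in VALENCE_CLASS:
                object.__setattr__(self, "valence_class", VALENCE_CLASS[self.label])
            else:
                object.__setattr__(self, "valence_class", "neutral")
        if self.label in VALENCE_CLASS and self.valence_class != VALENCE_CLASS[self.label]:
            raise ValueError(
                f"condition {self.label!r} must have valence class "
                f"{VALENCE_CLASS[self.label]!r}, got {self.valence_class!r}"
            )

    @property
    def is_face(self) -> bool:
        return self.valence_class in ("negative", "positive", "neutral") and (
            self.label not in BASELINE_LABELS
        )


def default_conditions() -> list[Condition]:
    """The seven paradigm conditions in canonical order."""
    return [Condition(lbl) for lbl in ALL_LABELS]


@dataclass
class BlockSequence:
    """An ordered run of condition blocks."""

    run_index: int
    blocks: list[Condition]
    block_duration: float = 20.0

    def __post_init__(self):
        if self.run_index < 1:
            raise ValueError("run_index must be >= 1")
        if self.block_duration <= 0:
            raise ValueError("block_duration must be positive")

    def __len__(self) -> int:
        return len(self.blocks)

    def labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    def transitions(self) -> list[tuple[str, str]]:
        lbl = self.labels()
        return list(zip(lbl[:-1], lbl[1:]))


@dataclass
class TimelineEvent:
    onset: float
    duration: float
    condition: Condition
    picture_id: str


@dataclass
class StimulusTimeline:
    """Millisecond-resolution stimulus events for one run."""

    events: list[TimelineEvent]
    total_duration: float

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for ev in self.events:
            if ev.condition.label not in seen:
                seen.append(ev.condition.label)
        return seen


@dataclass
class PairCountReport:
    """Tally of ordered condition transitions in a sequence."""

    counts: dict[tuple[str, str], int]
    flagged: list[tuple[str, str]]

    @property
    def ok(self) -> bool:
        return not self.flagged


def generate_counterbalanced_sequence(
    conditions: Sequence[Condition],
    n_blocks: int,
    seed: int,
    block_duration: float = 20.0,
    run_index: int = 1,
    first_condition: Condition | None = None,
    max_expansions: int = 10_000,
) -> BlockSequence:
    """Randomized-backtracking search for a block order in which every
    ordered pair of conditions occurs at most once and per-condition
    counts differ by at most one.

    Parameters
    ----------
    conditions
        The condition set (>= 2 distinct labels).
    n_blocks
        Sequence length; feasibility requires ``n_blocks - 1`` transitions
        to fit in the ``n * (n - 1)`` available ordered pairs.
    seed
        Seeds the candidate shuffling; identical seeds reproduce the
        identical sequence.
    first_condition
        Optionally pin the first block (used to prefix a second run with
        the first run's final condition).

    Raises
    ------
    DesignInfeasibleError
        If the preconditions fail or no sequence is found within
        ``max_expansions`` node expansions.
    """
    conds = list(conditions)
    n = len(conds)
    if n < 2:
        raise DesignInfeasibleError("need at least 2 conditions")
    if len({c.label for c in conds}) != n:
        raise DesignInfeasibleError("condition labels must be distinct")
    if n_blocks < 1:
        raise DesignInfeasibleError("n_blocks must be >= 1")
    if n_blocks - 1 > n * (n - 1):
        raise DesignInfeasibleError(
            f"{n_blocks} blocks need {n_blocks - 1} distinct ordered pairs "
            f"but only {n * (n - 1)} exist for {n} conditions"
        )
    if first_condition is not None and first_condition.label not in {c.label for c in conds}:
        raise DesignInfeasibleError("first_condition not in condition set")

    max_count = math.ceil(n_blocks / n)
    min_count = n_blocks // n
    rng = np.random.default_rng(seed)
    by_label = {c.label: c for c in conds}
    labels = [c.label for c in conds]

    expansions = 0

    def search(seq: list[str], used_pairs: set[tuple[str, str]], counts: dict[str, int]):
        nonlocal expansions
        if len(seq) == n_blocks:
            # the ceiling constraint alone can leave some condition short;
            # enforce the floor at completion
            if min(counts.values()) < min_count:
                return None
            return seq
        remaining = n_blocks - len(seq)
        # prune: conditions still below the floor must be placeable
        deficit = sum(max(min_count - counts[l], 0) for l in labels)
        if deficit > remaining:
            return None
        cand = [l for l in labels if counts[l] < max_count]
        if seq:
            prev = seq[-1]
            cand = [l for l in cand if l != prev and (prev, l) not in used_pairs]
        order = list(rng.permutation(len(cand)))
        for i in order:
            l = cand[i]
            expansions += 1
            if expansions > max_expansions:
                raise DesignInfeasibleError(
                    f"no valid sequence found within {max_expansions} expansions"
                )
            if seq:
                pair = (seq[-1], l)
                used_pairs.add(pair)
            seq.append(l)
            counts[l] += 1
            out = search(seq, used_pairs, counts)
            if out is not None:
                return out
            counts[l] -= 1
            seq.pop()
            if seq:
                used_pairs.discard((seq[-1], l))
        return None

    start = [first_condition.label] if first_condition is not None else []
    counts = {l: 0 for l in labels}
    for l in start:
        counts[l] += 1
    result = search(list(start), set(), counts)
    if result is None:
        raise DesignInfeasibleError("backtracking exhausted without a valid sequence")
    return BlockSequence(
        run_index=run_index,
        blocks=[by_label[l] for l in result],
        block_duration=block_duration,
    )


def generate_run_pair(
    conditions: Sequence[Condition],
    seed: int,
    n_blocks_run1: int = 25,
    block_duration: float = 20.0,
) -> tuple[BlockSequence, BlockSequence]:
    """Two counterbalanced runs; run 2 is 24-plus-one blocks whose extra
    first block repeats run 1's final condition, maintaining the pair
    constraint across the session boundary."""
    run1 = generate_counterbalanced_sequence(
        conditions, n_blocks_run1, seed, block_duration, run_index=1
    )
    run2 = generate_counterbalanced_sequence(
        conditions,
        n_blocks_run1,
        seed + 1,
        block_duration,
        run_index=2,
        first_condition=run1.blocks[-1],
    )
    return run1, run2


def validate_counterbalance(seq: BlockSequence) -> PairCountReport:
    """Tally every ordered condition transition; flag pairs seen twice."""
    counts: dict[tuple[str, str], int] = {}
    for pair in seq.transitions():
        counts[pair] = counts.get(pair, 0) + 1
    flagged = sorted(p for p, c in counts.items() if c > 1)
    return PairCountReport(counts=counts, flagged=flagged)


def build_timeline(
    seq: BlockSequence,
    face_display: float = 0.200,
    isi: float = 0.300,
    n_identities: int = 8,
    n_repetitions: int = 5,
    seed: int = 0,
) -> StimulusTimeline:
    """Expand a block sequence into stimulus events.

    Face blocks contain ``n_identities * n_repetitions`` presentations at
    a fixed ``face_display + isi`` inter-onset interval, ordered
    pseudorandomly with no identity shown twice in a row.  Scrambled and
    fixation blocks are single events spanning the whole block.
    """
    if face_display < 0 or isi < 0:
        raise ValueError("timing parameters must be non-negative")
    if face_display == 0:
        raise ValueError("face_display must be positive")
    if n_identities < 1 or n_repetitions < 1:
        raise ValueError("need at least one identity and one repetition")
    rng = np.random.default_rng(seed)
    ioi = face_display + isi
    n_face_events = n_identities * n_repetitions
    face_span = (n_face_events - 1) * ioi + face_display
    if face_span > seq.block_duration + 1e-9:
        raise ValueError(
            f"face presentations span {face_span:.3f} s, exceeding the "
            f"{seq.block_duration:.3f} s block"
        )
    events: list[TimelineEvent] = []
    t = 0.0
    for block in seq.blocks:
        if block.is_face:
            order = _no_repeat_shuffle(n_identities, n_repetitions, rng)
            for i, ident in enumerate(order):
                events.append(
                    TimelineEvent(
                        onset=t + i * ioi,
                        duration=face_display,
                        condition=block,
                        picture_id=f"{block.label}_f{ident + 1}",
                    )
                )
        else:
            events.append(
                TimelineEvent(
                    onset=t,
                    duration=seq.block_duration,
                    condition=block,
                    picture_id=block.label,
                )
            )
        t += seq.block_duration
    return StimulusTimeline(events=events, total_duration=t)


def _no_repeat_shuffle(n_identities: int, n_repetitions: int, rng) -> list[int]:
    """Pseudorandom order of identity indices, each repeated
    n_repetitions times, with no immediate repeats (when avoidable)."""
    if n_identities == 1:
        return [0] * n_repetitions
    counts = {i: n_repetitions for i in range(n_identities)}
    order: list[int] = []
    total = n_identities * n_repetitions
    for _ in range(total):
        cand = [i for i, c in counts.items() if c > 0]
        if order:
            non_rep = [i for i in cand if i != order[-1]]
            if non_rep:
                cand = non_rep
        # prefer the identities with most remaining shows to avoid dead ends
        top = max(counts[i] for i in cand)
        pool = [i for i in cand if counts[i] == top] if top > 1 else cand
        pick = pool[int(rng.integers(len(pool)))]
        order.append(pick)
        counts[pick] -= 1
    return order


# ---------------------------------------------------------------------------
# events TSV interchange (BIDS-style: onset, duration, trial_type, stim_id)

def timeline_to_frame(tl: StimulusTimeline) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": [e.onset for e in tl.events],
            "duration": [e.duration for e in tl.events],
            "trial_type": [e.condition.label for e in tl.events],
            "stim_id": [e.picture_id for e in tl.events],
        }
    )


def write_events_tsv(tl: StimulusTimeline, path) -> None:
    timeline_to_frame(tl).to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_events_tsv(path) -> StimulusTimeline:
    df = pd.read_csv(path, sep="\t")
    events = [
        TimelineEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            condition=Condition(str(r.trial_type)),
            picture_id=str(r.stim_id),
        )
        for r in df.itertuples()
    ]
    events.sort(key=lambda e: e.onset)
    total = max((e.onset + e.duration for e in events), default=0.0)
    return StimulusTimeline(events=events, total_duration=total)
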