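"""Keypress event logs -> per-trial viewtimes and per-category (K, H)
relative-preference coordinates.

In the offline task each picture appears for a default 6 s (plus a 2 s
decision block).  Pressing keys 1/2 lengthens viewing (approach) and keys
3/4 shortens it (avoidance); the work a subject trades for viewtime is
the dependent measure.  Relative preference theory summarises each
stimulus category by K, the signed mean number of net keypresses per
picture (positive = approach limb, negative = avoidance limb), and H,
the Shannon entropy in bits of how total keypress effort distributes
across the category's pictures — the choice-uncertainty axis of the
value graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import Condition

log = logging.getLogger(__name__)

#: default button-box mapping: keys 1 and 2 lengthen viewing, 3 and 4 shorten
DEFAULT_KEY_CLASSES: Mapping[int, str] = {1: "approach", 2: "approach", 3: "avoid", 4: "avoid"}

DEFAULT_VIEWTIME = 6.0
VIEWTIME_DELTA = 0.1
VIEWTIME_BOUNDS = (0.0, 14.0)


class MalformedEventError(ValueError):
    """A keypress event carries an unknown key class or trial index."""


@dataclass(frozen=True)
class KeypressEvent:
    subject_id: str
    trial_index: int
    picture_id: str
    category: str
    key_class: str  # "approach" | "avoid"
    timestamp: float  # seconds from trial onset

    def __post_init__(self):
        if self.timestamp < 0:
            raise MalformedEventError("event timestamp must be >= 0")
        if self.key_class not in ("approach", "avoid"):
            raise MalformedEventError(f"unknown key_class {self.key_class!r}")


@dataclass
class TrialRecord:
    picture_id: str
    category: str
    n_approach: int
    n_avoid: int
    viewtime: float


@dataclass
class CategoryValuation:
    """One point of the relative-preference value graph."""

    category: str
    K: float  # signed mean net keypresses (or viewtime deviation)
    H: float  # bits
    limb: str  # "approach" | "avoidance" | "neutral"
    n_pictures: int = 0


@dataclass
class KeypressSession:
    subject_id: str
    trials: list[TrialRecord]
    events: list[KeypressEvent] = field(default_factory=list)


def compute_viewtime(
    n_approach: int,
    n_avoid: int,
    default: float = DEFAULT_VIEWTIME,
    delta: float = VIEWTIME_DELTA,
    bounds: tuple[float, float] = VIEWTIME_BOUNDS,
) -> float:
    """Viewtime under the linear effort-for-time exchange:
    ``clamp(default + delta * (n_approach - n_avoid), bounds)``.

    The per-keypress increment and clamp are configurable; with no
    keypresses the picture shows for the 6 s default.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if n_approach < 0 or n_avoid < 0:
        raise ValueError("keypress counts must be non-negative")
    lo, hi = bounds
    return float(min(max(default + delta * (n_approach - n_avoid), lo), hi))


def tally_trial(
    events: Sequence[KeypressEvent],
    picture_id: str | None = None,
    category: str | None = None,
    **viewtime_kwargs,
) -> TrialRecord:
    """Count approach/avoid keypresses for one trial and derive viewtime.

    ``picture_id``/``category`` identify the trial when the event list is
    empty (a do-nothing trial keeps the default viewtime).
    """
    if events:
        idx = {e.trial_index for e in events}
        if len(idx) != 1:
            raise MalformedEventError("tally_trial got events from multiple trials")
        picture_id = events[0].picture_id
        category = events[0].category
    elif picture_id is None or category is None:
        raise ValueError("empty trial needs picture_id and category")
    n_app = sum(1 for e in events if e.key_class == "approach")
    n_avd = sum(1 for e in events if e.key_class == "avoid")
    return TrialRecord(
        picture_id=picture_id,
        category=category,
        n_approach=n_app,
        n_avoid=n_avd,
        viewtime=compute_viewtime(n_app, n_avd, **viewtime_kwargs),
    )


def shannon_entropy(counts: Sequence[float]) -> float:
    """Shannon entropy in bits of the distribution obtained by
    normalising non-negative counts.  Zero counts contribute nothing;
    an all-zero vector is degenerate and returns 0 with a warning."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or np.any(c < 0):
        raise ValueError("counts must be a non-empty, non-negative vector")
    total = c.sum()
    if total == 0:
        log.warning("all-zero count vector: entropy defined as 0 (degenerate)")
        return 0.0
    return float(stats.entropy(c / total, base=2))


def build_session(
    subject_id: str,
    events: Iterable[KeypressEvent],
    trial_pictures: Mapping[int, tuple[str, str]] | None = None,
    **viewtime_kwargs,
) -> KeypressSession:
    """Group events by trial into a session.  ``trial_pictures`` maps
    trial_index -> (picture_id, category) and supplies stubs for trials
    with no keypresses at all."""
    events = sorted(events, key=lambda e: (e.trial_index, e.timestamp))
    by_trial: dict[int, list[KeypressEvent]] = {}
    for e in events:
        by_trial.setdefault(e.trial_index, []).append(e)
    indices = set(by_trial)
    if trial_pictures:
        indices |= set(trial_pictures)
    trials = []
    for ti in sorted(indices):
        evs = by_trial.get(ti, [])
        if evs:
            trials.append(tally_trial(evs, **viewtime_kwargs))
        else:
            pid, cat = trial_pictures[ti]
            trials.append(tally_trial([], picture_id=pid, category=cat, **viewtime_kwargs))
    return KeypressSession(subject_id=subject_id, trials=trials, events=events)


def category_valuation(
    session: KeypressSession,
    measure: str = "keypresses",
    dead_band: float = 0.05,
    default_viewtime: float = DEFAULT_VIEWTIME,
) -> list[CategoryValuation]:
    """Per-category (K, H) points of the value graph.

    K is the mean over the category's pictures of per-trial net
    keypresses (approach minus avoid); with ``measure="viewtime"`` the
    mean viewtime deviation from the default substitutes.  H is the
    Shannon entropy of total keypress counts across the category's
    pictures.  The limb is the sign of K, with a dead band around zero
    mapping near-indifferent categories to "neutral".
    """
    if measure not in ("keypresses", "viewtime"):
        raise ValueError("measure must be 'keypresses' or 'viewtime'")
    df = session_to_frame(session)
    out: list[CategoryValuation] = []
    for cat, g in df.groupby("category", sort=True):
        per_pic = g.groupby("picture_id").agg(
            net=("net", "mean"),
            vt_dev=("vt_dev", "mean"),
            total=("total", "sum"),
        )
        if len(per_pic) == 0:
            warnings.warn(f"category {cat!r} has no pictures; skipped")
            continue
        if measure == "keypresses":
            K = float(per_pic["net"].mean())
        else:
            K = float(per_pic["vt_dev"].mean())
        H = shannon_entropy(per_pic["total"].to_numpy())
        if abs(K) <= dead_band:
            limb = "neutral"
        elif K > 0:
            limb = "approach"
        else:
            limb = "avoidance"
        out.append(CategoryValuation(category=cat, K=K, H=H, limb=limb, n_pictures=len(per_pic)))
    return out


def session_to_frame(
    session: KeypressSession, default_viewtime: float = DEFAULT_VIEWTIME
) -> pd.DataFrame:
    """Trial table with net/total keypress counts and viewtime deviation."""
    return pd.DataFrame(
        {
            "picture_id": [t.picture_id for t in session.trials],
            "category": [t.category for t in session.trials],
            "n_approach": [t.n_approach for t in session.trials],
            "n_avoid": [t.n_avoid for t in session.trials],
            "net": [t.n_approach - t.n_avoid for t in session.trials],
            "total": [t.n_approach + t.n_avoid for t in session.trials],
            "viewtime": [t.viewtime for t in session.trials],
            "vt_dev": [t.viewtime - default_viewtime for t in session.trials],
        }
    )


# ---------------------------------------------------------------------------
# CSV interchange

CSV_COLUMNS = ["subject_id", "trial_index", "picture_id", "category", "key_id", "timestamp_s"]


def write_keypress_csv(events: Iterable[KeypressEvent], path, key_classes=None) -> None:
    """Write raw events with numeric key ids (inverse of the class map)."""
    key_classes = dict(key_classes or DEFAULT_KEY_CLASSES)
    # first key id of each class, for a faithful round trip
    first_id = {}
    for kid, cls in key_classes.items():
        first_id.setdefault(cls, kid)
    rows = [
        {
            "subject_id": e.subject_id,
            "trial_index": e.trial_index,
            "picture_id": e.picture_id,
            "category": e.category,
            "key_id": first_id[e.key_class],
            "timestamp_s": e.timestamp,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_keypress_csv(path, key_classes=None) -> list[KeypressEvent]:
    key_classes = dict(key_classes or DEFAULT_KEY_CLASSES)
    df = pd.read_csv(path)
    events = []
    for r in df.itertuples():
        kid = int(r.key_id)
        if kid not in key_classes:
            raise MalformedEventError(f"unmapped key id {kid}")
        events.append(
            KeypressEvent(
                subject_id=str(r.subject_id),
                trial_index=int(r.trial_index),
                picture_id=str(r.picture_id),
                category=str(r.category),
                key_class=key_classes[kid],
                timestamp=float(r.timestamp_s),
            )
        )
    return events


def valuations_to_frame(subject_id: str, vals: Sequence[CategoryValuation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "category": [v.category for v in vals],
            "K": [v.K for v in vals],
            "H": [v.H for v in vals],
            "limb": [v.limb for v in vals],
            "n_pictures": [v.n_pictures for v in vals],
        }
    )
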