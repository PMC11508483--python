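"""Synthetic event-log generators with known statistical structure.

Two parametric generators make every pipeline stage testable without any
observational data: :func:`generate_markov_log` emits per-subject
first-order Markov chains over a behavior repertoire (the structure the
transition network extracts), and :func:`generate_interaction_log` emits
Poisson-distributed directed point events between individuals (the
structure the interaction network extracts). Both are deterministic given
their seed.

The module also provides *synthetic stand-ins* for the published cichlid
sample recordings used throughout the documentation: BORIS-style logs of
small shell-dwelling cichlids (Lamprologini) with a realistic ethogram of
aggressive, maintenance, shelter and locomotion behaviors, paired
START/STOP state events, point events and recipient-bearing interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .events import (
    NO_CATEGORY,
    STATUS_POINT,
    STATUS_START,
    STATUS_STOP,
    EventLog,
    EventRecord,
)


@dataclass
class MarkovSpec:
    """Parameters of a per-subject first-order Markov behavior chain.

    ``P[i, j]`` is the probability that behavior j follows behavior i;
    every row must sum to 1. Bout durations are exponential with the given
    per-behavior means (seconds); consecutive bouts of one subject are
    separated by a fixed small gap so that start-time order equals chain
    order.
    """

    behaviors: list[str]
    P: np.ndarray
    duration_mean: np.ndarray | float = 5.0
    n_subjects: int = 5
    bouts_per_subject: int = 100
    seed: int = 0
    categories: Mapping[str, str] = field(default_factory=dict)
    gap: float = 0.5

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.behaviors)
        if self.P.shape != (k, k):
            raise ValueError("P must be square with one row per behavior")
        if np.any(self.P < 0) or not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("P must be row-stochastic (rows sum to 1)")
        if np.isscalar(self.duration_mean):
            self.duration_mean = np.full(k, float(self.duration_mean))
        else:
            self.duration_mean = np.asarray(self.duration_mean, dtype=float)
        if np.any(self.duration_mean <= 0):
            raise ValueError("duration means must be positive")
        if self.n_subjects < 1 or self.bouts_per_subject < 1:
            raise ValueError("n_subjects and bouts_per_subject must be positive")


def generate_markov_log(spec: MarkovSpec) -> EventLog:
    """Emit START/STOP event rows for per-subject Markov behavior chains.

    Each subject's chain starts from a uniformly random behavior and runs
    for ``bouts_per_subject`` bouts; every bout becomes one START and one
    STOP row. Subjects run on a common clock from t=0, so their bouts
    interleave in the file like in a real multi-individual recording.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.behaviors)
    records: list[EventRecord] = []
    row = 0
    for s in range(spec.n_subjects):
        subject = f"s{s + 1}"
        state = int(rng.integers(k))
        t = float(rng.uniform(0, spec.gap))
        for _ in range(spec.bouts_per_subject):
            behavior = spec.behaviors[state]
            dur = float(rng.exponential(spec.duration_mean[state]))
            records.append(
                EventRecord(
                    time=t,
                    subject=subject,
                    behavior=behavior,
                    status=STATUS_START,
                    category=spec.categories.get(behavior, NO_CATEGORY),
                    row_index=row,
                )
            )
            row += 1
            records.append(
                EventRecord(
                    time=t + dur,
                    subject=subject,
                    behavior=behavior,
                    status=STATUS_STOP,
                    category=spec.categories.get(behavior, NO_CATEGORY),
                    row_index=row,
                )
            )
            row += 1
            t += dur + spec.gap
            state = int(rng.choice(k, p=spec.P[state]))
    return EventLog(records=records, source_name=f"markov-seed{spec.seed}.csv")


@dataclass
class InteractionSpec:
    """Expected directed interaction counts between individuals.

    ``rates[i, j]`` is the expected number of directed point-event
    interactions from individual i to individual j; realized counts are
    Poisson. The diagonal must be zero unless self-loops are wanted.
    """

    individuals: list[str]
    rates: np.ndarray
    behavior: str = "Ramming"
    seed: int = 0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.individuals)
        if self.rates.shape != (k, k):
            raise ValueError("rates must be square with one row per individual")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")


def generate_interaction_log(spec: InteractionSpec) -> EventLog:
    """Emit POINT events with recipients at Poisson counts per pair.

    Every individual also gets one neutral solo point event so that it
    appears in the log even when it draws no interactions.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.individuals)
    records: list[EventRecord] = []
    row = 0
    for i in range(k):
        records.append(
            EventRecord(
                time=float(rng.uniform(0, 1)),
                subject=spec.individuals[i],
                behavior="Hovering",
                status=STATUS_POINT,
                row_index=row,
            )
        )
        row += 1
    counts = rng.poisson(spec.rates)
    for i in range(k):
        for j in range(k):
            for _ in range(int(counts[i, j])):
                records.append(
                    EventRecord(
                        time=float(rng.uniform(1, 100)),
                        subject=spec.individuals[i],
                        behavior=spec.behavior,
                        status=STATUS_POINT,
                        modifier=spec.individuals[j],
                        row_index=row,
                    )
                )
                row += 1
    return EventLog(records=records, source_name=f"interaction-seed{spec.seed}.csv")


# ---------------------------------------------------------------------------
# Synthetic cichlid sample recordings

#: Ethogram of a shell-dwelling cichlid: behavior -> behavioral category.
CICHLID_ETHOGRAM: dict[str, str] = {
    "Ramming": "Aggression",
    "S-Bend": "Aggression",
    "Chasing": "Aggression",
    "Lateral display": "Aggression",
    "Mouth fighting": "Aggression",
    "Digging": "Maintenance",
    "Sand spitting": "Maintenance",
    "Shell circling": "Maintenance",
    "Shell entering": "Shelter",
    "Shell escape": "Shelter",
    "Swimming": "Locomotion",
    "Hovering": "Locomotion",
    "Fleeing": "Escape",
}

_DIRECTED = {"Ramming", "Chasing", "S-Bend", "Lateral display", "Mouth fighting"}
_POINT_BEHAVIORS = {"Sand spitting", "Shell escape"}

_ETHOGRAM_LIST = list(CICHLID_ETHOGRAM)

# Fixed per-subject repertoires for the N. multifasciatus stand-in: a
# 20-minute recording of a 7-fish group. The dominant individual "1" shows
# 11 distinct behaviors including overt aggression (Ramming) but no shell
# escapes; the subordinate "5" shows only 6, restricted to restrained
# aggression (S-Bend) plus escapes.
_MULTIFASCIATUS_REPERTOIRES: dict[str, list[str]] = {
    "1": [b for b in _ETHOGRAM_LIST if b not in ("Shell escape", "Fleeing")],
    "2": ["Digging", "Swimming", "Hovering", "S-Bend", "Shell entering",
          "Chasing", "Sand spitting", "Shell circling"],
    "3": ["Swimming", "Hovering", "Shell entering", "Digging", "S-Bend",
          "Fleeing", "Shell escape"],
    "4": ["Swimming", "Digging", "Sand spitting", "Hovering", "Shell entering",
          "Shell circling", "Chasing", "Lateral display", "Fleeing"],
    "5": ["S-Bend", "Shell escape", "Digging", "Shell entering", "Swimming",
          "Hovering"],
    "6": ["Swimming", "Hovering", "Shell entering", "Digging", "Fleeing",
          "Sand spitting", "S-Bend"],
    "7": ["Swimming", "Hovering", "Digging", "Shell entering", "Shell escape",
          "Fleeing", "Shell circling", "S-Bend"],
}

_OCELLATUS_SUBJECTS = [str(i) for i in range(1, 11)]


def _synthetic_recording(
    repertoires: Mapping[str, Sequence[str]],
    seed: int,
    source_name: str,
    duration: float = 1200.0,
) -> EventLog:
    """Assemble a BORIS-style log from fixed per-subject repertoires.

    Each subject's bout sequence starts with a shuffled copy of its full
    repertoire (so every repertoire behavior is observed regardless of the
    seed) followed by random draws; directed aggressive bouts get a random
    other group member as recipient.
    """
    rng = np.random.default_rng(seed)
    subjects = list(repertoires)
    records: list[EventRecord] = []
    row = 0
    for subject in subjects:
        repertoire = list(repertoires[subject])
        n_extra = int(rng.integers(12, 25))
        sequence = list(rng.permutation(repertoire)) + [
            repertoire[int(rng.integers(len(repertoire)))] for _ in range(n_extra)
        ]
        t = float(rng.uniform(0, 10))
        for behavior in sequence:
            category = CICHLID_ETHOGRAM[behavior]
            recipient = ""
            if behavior in _DIRECTED and rng.random() < 0.6:
                others = [s for s in subjects if s != subject]
                recipient = others[int(rng.integers(len(others)))]
            if behavior in _POINT_BEHAVIORS:
                records.append(
                    EventRecord(t, subject, behavior, STATUS_POINT,
                                recipient, category, row)
                )
                row += 1
                t += float(rng.exponential(8.0))
            else:
                dur = float(rng.exponential(7.0)) + 0.5
                records.append(
                    EventRecord(t, subject, behavior, STATUS_START,
                                recipient, category, row)
                )
                row += 1
                records.append(
                    EventRecord(t + dur, subject, behavior, STATUS_STOP,
                                recipient, category, row)
                )
                row += 1
                t += dur + float(rng.exponential(8.0))
            if t > duration:
                t = float(rng.uniform(duration * 0.8, duration))
    return EventLog(records=records, source_name=source_name)


def synthetic_multifasciatus_log(seed: int = 0) -> EventLog:
    """Synthetic stand-in for a 20-minute *Neolamprologus multifasciatus*
    group recording: 7 individuals; subject "1" exhibits 11 distinct
    behaviors and subject "5" exhibits 6, by construction, for any seed.
    """
    return _synthetic_recording(
        _MULTIFASCIATUS_REPERTOIRES, seed, "Nm_synthetic_sample.csv"
    )


def synthetic_ocellatus_log(seed: int = 0) -> EventLog:
    """Synthetic stand-in for a 20-minute *Lamprologus ocellatus* group
    recording with 10 individuals."""
    rng = np.random.default_rng(seed + 1)
    repertoires: dict[str, list[str]] = {}
    for subject in _OCELLATUS_SUBJECTS:
        size = int(rng.integers(5, 12))
        chosen = rng.choice(_ETHOGRAM_LIST, size=size, replace=False)
        repertoires[subject] = list(chosen)
    return _synthetic_recording(repertoires, seed, "Lo_synthetic_sample.csv")
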