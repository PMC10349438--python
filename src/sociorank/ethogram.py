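"""Ethogram and dyadic event-log data model.

The raw input of the pipeline is a long-format log of dyadic social
interactions: one row per observed event, coded against an ethogram that
assigns every behavior to one of two categories, *agonistic* (competitive
acts that establish dominance) or *affiliative* (non-aggressive social
contact).  Each event names an *author* (the initiating animal) and a
*receptor*, the observation period (``pre`` or ``post`` castration) and the
session (observation day, 1-5).

Events are aggregated, per category and period, into a square directed
count matrix over the full roster; agonistic behaviors (mount, fight,
headbutt) are summed before any network construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

AGONISTIC = "agonistic"
AFFILIATIVE = "affiliative"
CATEGORIES = (AGONISTIC, AFFILIATIVE)

#: Default observation periods (pre- and post-castration).
DEFAULT_PERIODS = ("pre", "post")

REQUIRED_COLUMNS = ("period", "session", "author", "receptor", "behavior")


class EventLogFormatError(ValueError):
    """The event-log file does not have the expected tabular shape."""


class EventLogValidationError(ValueError):
    """Rows are well-formed but violate ethogram or roster constraints."""


def _canon(name: str) -> str:
    # behavior matching is case-insensitive after trimming; field data entry
    # is inconsistent
    return str(name).strip().lower()


@dataclass(frozen=True)
class Ethogram:
    """Catalogue of behaviors, each mapped to exactly one category."""

    behaviors: Mapping[str, str]

    def __post_init__(self) -> None:
        canon = {}
        for name, cat in dict(self.behaviors).items():
            if cat not in CATEGORIES:
                raise EventLogValidationError(
                    f"behavior {name!r} has unknown category {cat!r}; "
                    f"expected one of {CATEGORIES}"
                )
            canon[_canon(name)] = cat
        object.__setattr__(self, "behaviors", canon)

    def category_of(self, behavior: str) -> str:
        try:
            return self.behaviors[_canon(behavior)]
        except KeyError:
            raise EventLogValidationError(
                f"behavior {behavior!r} is not in the ethogram "
                f"({sorted(self.behaviors)})"
            ) from None

    def __contains__(self, behavior: str) -> bool:
        return _canon(behavior) in self.behaviors

    def of_category(self, category: str) -> tuple[str, ...]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        return tuple(b for b, c in self.behaviors.items() if c == category)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Ethogram":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise EventLogFormatError(f"{path}: expected a behavior -> category mapping")
        return cls(mapping)


#: The study ethogram: three agonistic behaviors and one affiliative one.
DEFAULT_ETHOGRAM = Ethogram(
    {
        "mount": AGONISTIC,
        "fight": AGONISTIC,
        "headbutt": AGONISTIC,
        "head-play": AFFILIATIVE,
    }
)


@dataclass(frozen=True)
class InteractionEvent:
    """One ethogram-coded dyadic observation."""

    period: str
    session: int
    author: str
    receptor: str
    behavior: str

    def __post_init__(self) -> None:
        if self.author == self.receptor:
            raise EventLogValidationError(
                f"self-interaction: author == receptor == {self.author!r}"
            )


@dataclass(frozen=True)
class EventLog:
    """Ordered list of events plus the roster of animals under observation.

    The roster always includes animals that never interacted; exclusion of
    inactive animals is a graph-construction concern, not a logging one.
    """

    events: tuple[InteractionEvent, ...]
    roster: tuple[str, ...]
    periods: tuple[str, ...] = DEFAULT_PERIODS

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "roster", tuple(sorted(set(self.roster))))
        if self.events and len(self.roster) < 2:
            raise EventLogValidationError("roster must contain at least 2 animals")
        missing = {
            a
            for ev in self.events
            for a in (ev.author, ev.receptor)
            if a not in set(self.roster)
        }
        if missing:
            raise EventLogValidationError(
                f"animals appear in events but not in roster: {sorted(missing)}"
            )
        bad_period = [ev for ev in self.events if ev.period not in self.periods]
        if bad_period:
            raise EventLogValidationError(
                f"{len(bad_period)} events carry a period outside {self.periods}; "
                f"first offender: {bad_period[0]}"
            )

    def __len__(self) -> int:
        return len(self.events)

    def subset(self, period: str | None = None) -> "EventLog":
        if period is not None and period not in self.periods:
            raise ValueError(f"unknown period {period!r}; declared: {self.periods}")
        evs = [e for e in self.events if period is None or e.period == period]
        return EventLog(tuple(evs), self.roster, self.periods)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.period, e.session, e.author, e.receptor, e.behavior)
                for e in self.events
            ],
            columns=list(REQUIRED_COLUMNS),
        )


@dataclass(frozen=True)
class CountMatrix:
    """Directed interaction counts for one category x period over the roster.

    ``counts[i, j]`` is the number of events with author ``animals[i]`` and
    receptor ``animals[j]``.  The matrix spans the *full* roster, including
    animals with no events.
    """

    animals: tuple[str, ...]
    counts: np.ndarray
    category: str
    period: str

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = len(self.animals)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diag(c).any():
            raise ValueError("diagonal (self-interactions) must be zero")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "animals", tuple(self.animals))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def load_events(
    path: str | Path | io.TextIOBase,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
    *,
    roster: Iterable[str] | None = None,
    periods: Sequence[str] = DEFAULT_PERIODS,
    delimiter: str = ",",
) -> EventLog:
    """Read and validate a delimited event log.

    The file must have header columns period, session, author, receptor and
    behavior.  The roster defaults to the union of authors and receptors;
    pass ``roster`` explicitly to include animals that never interacted.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EventLogFormatError(f"{path}: file is empty (no header)") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogFormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    unknown = [
        (i, b) for i, b in enumerate(df["behavior"]) if b not in ethogram
    ]
    if unknown:
        rows = ", ".join(f"row {i}: {b!r}" for i, b in unknown[:10])
        raise EventLogValidationError(
            f"{len(unknown)} event(s) with behavior outside the ethogram ({rows})"
        )
    selfies = df.index[df["author"] == df["receptor"]].tolist()
    if selfies:
        raise EventLogValidationError(
            f"author == receptor in row(s) {selfies[:10]}"
        )
    events = tuple(
        InteractionEvent(
            period=str(r.period).strip(),
            session=int(r.session),
            author=str(r.author).strip(),
            receptor=str(r.receptor).strip(),
            behavior=_canon(r.behavior),
        )
        for r in df.itertuples()
    )
    if roster is None:
        roster = {a for e in events for a in (e.author, e.receptor)}
    return EventLog(events, tuple(roster), tuple(periods))


def write_events(log: EventLog, path: str | Path, *, delimiter: str = ",") -> None:
    """Write an event log back to delimited text (lossless round trip)."""
    log.to_frame().to_csv(path, sep=delimiter, index=False)


def aggregate_counts(
    log: EventLog,
    category: str,
    period: str,
    ethogram: Ethogram = DEFAULT_ETHOGRAM,
) -> CountMatrix:
    """Aggregate events of one category x period into a directed count matrix.

    For the agonistic category this implements the summation of mount,
    fight and headbutt frequencies into a single count per ordered pair.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if period not in log.periods:
        raise ValueError(f"unknown period {period!r}; declared: {log.periods}")
    animals = tuple(sorted(log.roster))
    index = {a: i for i, a in enumerate(animals)}
    counts = np.zeros((len(animals), len(animals)), dtype=int)
    for ev in log.events:
        if ev.period != period:
            continue
        if ethogram.category_of(ev.behavior) != category:
            continue
        counts[index[ev.author], index[ev.receptor]] += 1
    return CountMatrix(animals, counts, category, period)
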