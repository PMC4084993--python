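"""Typed event histories and their tabular on-disk form.

A single record type covers both vocabularies used in the package: the
biogeographic names (vicariance, dispersal, local extinction) and their
cophylogenetic analogues (cospeciation, host-switch, lineage loss).  Events
are anchored to a node or branch and dated in Ma; host switches additionally
carry donor and recipient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import DataError

__all__ = ["Event", "EVENT_TYPES", "write_events", "read_events"]

EVENT_TYPES = frozenset(
    {
        # biogeographic / simulation vocabulary
        "vicariance/cospeciation",
        "dispersal/host-switch",
        "duplication",
        "extinction/loss",
        # cophylogenetic vocabulary
        "cospeciation",
        "host-switch",
        "lineage-loss",
        "sharing",
    }
)


@dataclass
class Event:
    """One cladogenetic or anagenetic event.

    ``age`` is the (older) time of the event in Ma; for branch events whose
    timing is only known to an interval, ``age_end`` is the younger bound.
    ``subject`` is the area/host gained or lost (or retained, for sharing).
    """

    type: str
    anchor: str
    child_left: str | None = None
    child_right: str | None = None
    subject: str | None = None
    donor: str | None = None
    recipient: str | None = None
    age: float | None = None
    age_end: float | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise DataError(f"unknown event type {self.type!r}")


_COLUMNS = [f.name for f in fields(Event)]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return "%.17g" % value
    return str(value)


def write_events(history: list[Event], path, comment: str | None = None) -> None:
    """Write an event history as a TSV, one row per event."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for ev in history:
            fh.write("\t".join(_fmt(getattr(ev, c)) for c in _COLUMNS) + "\n")


def read_events(path) -> list[Event]:
    """Read back an event history written by :func:`write_events`."""
    out: list[Event] = []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\n").split("\t")
            break
        if header != _COLUMNS:
            raise DataError(f"unexpected event file header: {header}")
        for line in fh:
            if not line.rstrip("\n") or line.startswith("#"):
                continue
            vals = line.rstrip("\n").split("\t")
            kwargs = {}
            for col, val in zip(_COLUMNS, vals):
                if val == "":
                    kwargs[col] = None
                elif col in ("age", "age_end"):
                    kwargs[col] = float(val)
                else:
                    kwargs[col] = val
            out.append(Event(**kwargs))
    return out
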