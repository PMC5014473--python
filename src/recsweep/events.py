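"""The consolidated recombination-event record and its TSV round trip.

All user-facing coordinates here are 1-based inclusive; internal modules
convert from 0-based half-open at the point an event is built.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RecombinationEvent", "write_events_tsv", "read_events_tsv", "METHOD_ORDER"]

METHOD_ORDER = ["rdp", "maxchi", "chimaera", "threeseq", "siscan", "bootscan"]


@dataclass
class RecombinationEvent:
    """One inferred recombination event.

    ``recombinants`` lists every sequence judged to carry the event;
    ``minor_parent`` is the representative of the lineage that donated
    the recombinant region, ``major_parent`` the backbone lineage
    (either may be ``"unknown"``).  Breakpoints and their 95% credible
    intervals are 1-based inclusive alignment positions.
    """

    event_id: int
    recombinants: list[str]
    minor_parent: str
    major_parent: str
    begin: int
    begin_ci: tuple[int, int]
    end: int
    end_ci: tuple[int, int]
    method_p: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def region0(self) -> tuple[int, int]:
        """The event region as a 0-based half-open interval."""
        return self.begin - 1, self.end

    def best_p(self) -> float:
        return min(self.method_p.values()) if self.method_p else 1.0


_HEADER = (
    ["event_id", "recombinants", "minor_parent", "major_parent",
     "begin", "begin_ci_lo", "begin_ci_hi", "end", "end_ci_lo", "end_ci_hi"]
    + [f"p_{m}" for m in METHOD_ORDER]
    + ["warnings"]
)


def write_events_tsv(events: list[RecombinationEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HEADER)
        for ev in events:
            row = [
                ev.event_id,
                ",".join(ev.recombinants),
                ev.minor_parent,
                ev.major_parent,
                ev.begin, ev.begin_ci[0], ev.begin_ci[1],
                ev.end, ev.end_ci[0], ev.end_ci[1],
            ]
            for m in METHOD_ORDER:
                row.append(f"{ev.method_p[m]:.6g}" if m in ev.method_p else "")
            row.append(";".join(ev.warnings))
            w.writerow(row)


def read_events_tsv(path: str | Path) -> list[RecombinationEvent]:
    events = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            method_p = {}
            for m in METHOD_ORDER:
                v = row.get(f"p_{m}", "")
                if v:
                    method_p[m] = float(v)
            events.append(
                RecombinationEvent(
                    int(row["event_id"]),
                    row["recombinants"].split(",") if row["recombinants"] else [],
                    row["minor_parent"],
                    row["major_parent"],
                    int(row["begin"]),
                    (int(row["begin_ci_lo"]), int(row["begin_ci_hi"])),
                    int(row["end"]),
                    (int(row["end_ci_lo"]), int(row["end_ci_hi"])),
                    method_p,
                    row["warnings"].split(";") if row.get("warnings") else [],
                )
            )
    return events
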