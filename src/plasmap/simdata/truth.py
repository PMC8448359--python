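"""Truth-table TSV round-trip.

Coordinates are written 1-based inclusive (documented in the header);
``gap_size`` is signed: positive = deleted genome, negative = duplicated
genome, 0 = perfect junction.
"""

from __future__ import annotations

import csv

from plasmap.simdata.mutate import TruthEvent

_COLUMNS = [
    "mutant_id",
    "event_class",
    "chromosome",
    "left_breakpoint",
    "right_breakpoint",
    "gap_size",
    "partner_chromosome",
    "partner_start",
    "partner_end",
]

_HEADER_COMMENT = (
    "# Truth events; breakpoint and partner coordinates are 1-based "
    "inclusive; gap_size>0 deleted bp, gap_size<0 duplicated bp.\n"
)


def write_truth(events: list[TruthEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for ev in events:
            writer.writerow(
                [
                    ev.mutant_id,
                    ev.event_class,
                    ev.chromosome,
                    ev.left_breakpoint + 1,
                    ev.right_breakpoint + 1,
                    ev.gap_size,
                    ev.partner_chromosome,
                    ev.partner_start + 1 if ev.partner_chromosome else "",
                    ev.partner_end if ev.partner_chromosome else "",
                ]
            )


def read_truth(path) -> list[TruthEvent]:
    events = []
    with open(path, newline="") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        has_partner = bool(row["partner_chromosome"])
        events.append(
            TruthEvent(
                mutant_id=row["mutant_id"],
                event_class=row["event_class"],
                chromosome=row["chromosome"],
                left_breakpoint=int(row["left_breakpoint"]) - 1,
                right_breakpoint=int(row["right_breakpoint"]) - 1,
                gap_size=int(row["gap_size"]),
                partner_chromosome=row["partner_chromosome"],
                partner_start=int(row["partner_start"]) - 1 if has_partner else -1,
                partner_end=int(row["partner_end"]) if has_partner else -1,
            )
        )
    return events
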