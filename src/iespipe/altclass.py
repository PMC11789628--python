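"""Geometric taxonomy of alternative IES excision and per-IES rates.

An alternative excision uses a boundary pair ``(left', right')`` that
differs from the reference pair but whose excised interval overlaps the
reference interval.  With signed offsets ``dL = left' - left`` and
``dR = right' - right`` the event falls into exactly one of five
classes:

==================  ==========================================
label               sign pattern
==================  ==========================================
partial_internal    one offset zero, the other inward
partial_external    one offset zero, the other outward
internal            dL > 0 and dR < 0 (both inward)
external            dL < 0 and dR > 0 (both outward)
overlap             both offsets nonzero with the same sign
==================  ==========================================

Pairs with non-overlapping excised intervals are "detached": they are
not alternative excisions of the reference IES and are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotationError, IesAnnotation
from .junctions import EventCounts

__all__ = [
    "ALT_LABELS",
    "AltEvent",
    "DetachedEventError",
    "classify_alt",
    "events_from_counts",
    "pct_alt_per_ies",
    "event_type_shares",
    "write_events_tsv",
]

ALT_LABELS = ("partial_internal", "partial_external", "overlap", "internal", "external")


class DetachedEventError(AnnotationError):
    """The candidate excised interval does not overlap the reference IES."""


def classify_alt(
    ref: tuple[int, int], alt: tuple[int, int]
) -> str:
    """Classify one alternative boundary pair against the reference pair."""
    (l, r), (a, b) = ref, alt
    if (a, b) == (l, r):
        raise AnnotationError("alternative pair is identical to the reference")
    if not (a < r and b > l):
        raise DetachedEventError(
            f"excised interval [{a}, {b}) does not overlap reference [{l}, {r})"
        )
    dL, dR = a - l, b - r
    if dL == 0:
        return "partial_internal" if dR < 0 else "partial_external"
    if dR == 0:
        return "partial_internal" if dL > 0 else "partial_external"
    if dL > 0 and dR < 0:
        return "internal"
    if dL < 0 and dR > 0:
        return "external"
    return "overlap"


@dataclass(frozen=True)
class AltEvent:
    """One observed alternative excision variant with its read support."""

    ies_id: str
    left: int
    right: int
    dL: int
    dR: int
    count: int
    label: str

    @property
    def length(self) -> int:
        """Alternatively excised length in bp (= right - left)."""
        return self.right - self.left


def events_from_counts(
    counts: EventCounts, annotations: Sequence[IesAnnotation]
) -> list[AltEvent]:
    """Materialize classified events from the per-IES alternative tallies."""
    by_id = {a.id: a for a in annotations}
    events: list[AltEvent] = []
    for ies_id, cell in counts.per_ies.items():
        if ies_id not in by_id:
            raise KeyError(f"counts reference unknown IES id {ies_id}")
        ann = by_id[ies_id]
        for (a, b), c in sorted(cell["alt"].items()):
            label = classify_alt((ann.left_ta, ann.right_ta), (a, b))
            events.append(
                AltEvent(
                    ies_id=ies_id,
                    left=a,
                    right=b,
                    dL=a - ann.left_ta,
                    dR=b - ann.right_ta,
                    count=c,
                    label=label,
                )
            )
    return events


def pct_alt_per_ies(counts: EventCounts, mode: str = "inclusive") -> pd.Series:
    """Percentage of alternative excision events per IES.

    The denominator is the excision-supporting reads only
    (``alt + exact``), i.e. the share of excisions that used a
    non-reference boundary::

        pct = 100 * alt / (alt + exact)

    ``legacy`` mode reproduces an estimator that skips IESs whose mapped
    excision reads were *all* alternative (returns NaN for
    ``exact == 0 and alt > 0``), and therefore underestimates the mean;
    ``inclusive`` mode scores such IESs as 100%.  IESs without any
    excision read are undefined (NaN) in both modes.
    """
    if mode not in ("legacy", "inclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    out = {}
    for ies_id, cell in counts.per_ies.items():
        n_alt = sum(cell["alt"].values())
        n_exact = cell["n_minus"]
        if n_alt + n_exact == 0:
            out[ies_id] = float("nan")
        elif mode == "legacy" and n_exact == 0:
            out[ies_id] = float("nan")
        else:
            out[ies_id] = 100.0 * n_alt / (n_alt + n_exact)
    return pd.Series(out, name=f"pct_alt_{mode}")


def event_type_shares(
    events: Iterable[AltEvent], weight_by: str = "reads"
) -> pd.Series:
    """Proportion of each of the five labels among the events.

    ``weight_by="reads"`` weights each event by its read count;
    ``weight_by="variants"`` counts each distinct variant once.  Returns
    all-zero shares for an empty event list.
    """
    if weight_by not in ("reads", "variants"):
        raise ValueError(f"unknown weight_by {weight_by!r}")
    weights = dict.fromkeys(ALT_LABELS, 0.0)
    for ev in events:
        weights[ev.label] += ev.count if weight_by == "reads" else 1
    total = sum(weights.values())
    if total > 0:
        weights = {k: v / total for k, v in weights.items()}
    return pd.Series(weights, name=f"share_{weight_by}")


def write_events_tsv(
    events: Sequence[AltEvent], path: str | Path, header_comment: str = ""
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("ies_id\tleft_alt\tright_alt\tdL\tdR\tlabel\tcount\n")
        for ev in events:
            fh.write(
                f"{ev.ies_id}\t{ev.left}\t{ev.right}\t{ev.dL}\t{ev.dR}\t"
                f"{ev.label}\t{ev.count}\n"
            )
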