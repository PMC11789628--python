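"""Small RNA length/target classification and off-target window prediction.

Small RNA reads are partitioned by exact substring matching (either
strand) against three target sets in priority order: the RNAi feeding
vector, annotated IES sequences (germline-only), and the somatic (MAC)
genome.  A read matching multiple targets takes the highest priority;
reads matching none are "unmatched".  Abundances of MAC-matching
classes are conventionally normalized against the MAC-matching siRNA
class (23 nt by default).

Off-target prediction mirrors the construct-vs-transcript search used
to assess RNAi cross-silencing: maximal exact shared windows of at
least one siRNA length between a transcript and either strand of the
construct, with the number of possible siRNAs per window being
``window_len - sirna_len + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import revcomp
from .simulate import Read

__all__ = [
    "SrnaCounts",
    "OfftargetWindow",
    "classify_srna",
    "normalize_by_sirna",
    "offtarget_windows",
    "TARGET_PRIORITY",
]

TARGET_PRIORITY = ("vector", "IES", "MAC")


@dataclass
class SrnaCounts:
    """Read counts keyed by ``(length, target)`` plus the dropped tally."""

    counts: dict[tuple[int, str], int] = field(default_factory=dict)
    dropped: int = 0
    sample: str = ""
    stage: str = ""

    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, length: int, target: str) -> int:
        return self.counts.get((length, target), 0)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (length, target, count)
            for (length, target), count in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["length", "target", "count"])


def _match_any(read: str, haystack: str) -> bool:
    return read in haystack or revcomp(read) in haystack


def classify_srna(
    reads: Iterable[Read | str],
    vector_seqs: Sequence[str],
    somatic_seqs: Sequence[str],
    ies_seqs: Sequence[str],
    length_range: tuple[int, int] = (15, 35),
    sample: str = "",
    stage: str = "",
) -> SrnaCounts:
    """Classify sRNA reads by length and best-priority target.

    Matching is exact substring on either strand.  Reads outside
    ``length_range`` (inclusive bounds) are dropped and tallied, so
    ``total + dropped`` always equals the number of input reads.
    """
    # '#' cannot occur in a validated read, so it is a safe separator
    catalogs = {
        "vector": "#".join(vector_seqs),
        "IES": "#".join(ies_seqs),
        "MAC": "#".join(somatic_seqs),
    }
    out = SrnaCounts(sample=sample, stage=stage)
    lo, hi = length_range
    for r in reads:
        seq = r.seq if isinstance(r, Read) else r
        n = len(seq)
        if n < lo or n > hi:
            out.dropped += 1
            continue
        target = "unmatched"
        for t in TARGET_PRIORITY:
            if catalogs[t] and _match_any(seq, catalogs[t]):
                target = t
                break
        key = (n, target)
        out.counts[key] = out.counts.get(key, 0) + 1
    return out


def normalize_by_sirna(
    counts: SrnaCounts,
    numerator_lengths: Sequence[int] | None = None,
    sirna_length: int = 23,
) -> pd.Series:
    """MAC-matching counts per length relative to MAC-matching siRNAs.

    ``value(L) = count(L, MAC) / count(sirna_length, MAC)``.  A zero
    denominator yields NaN for every entry (undefined marker).
    """
    denom = counts.get(sirna_length, "MAC")
    if numerator_lengths is None:
        numerator_lengths = sorted(
            {length for (length, target) in counts.counts if target == "MAC"}
        )
    if denom == 0:
        values = {length: float("nan") for length in numerator_lengths}
    else:
        values = {
            length: counts.get(length, "MAC") / denom
            for length in numerator_lengths
        }
    return pd.Series(values, name="mac_norm")


@dataclass(frozen=True)
class OfftargetWindow:
    """One maximal exact shared window between transcript and construct."""

    transcript_start: int
    construct_start: int  # position on the reported strand of the construct
    length: int
    strand: str  # "+" construct as given, "-" reverse complement

    def n_sirnas(self, sirna_len: int) -> int:
        return self.length - sirna_len + 1


def offtarget_windows(
    construct: str, transcript: str, sirna_len: int = 23
) -> tuple[list[OfftargetWindow], int]:
    """Predict off-target siRNA windows shared by construct and transcript.

    Finds all maximal exact shared substrings of length >= ``sirna_len``
    between the transcript and the construct or its reverse complement
    (the feeding construct is transcribed into double-stranded RNA, so
    both strands can source siRNAs).  No mismatches are allowed.

    Returns the window list and the total number of possible siRNAs,
    ``sum(window_len - sirna_len + 1)``.
    """
    if sirna_len < 1:
        raise ValueError("sirna_len must be >= 1")
    windows: list[OfftargetWindow] = []
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    for strand, cseq in (("+", construct), ("-", revcomp(construct))):
        c = np.frombuffer(cseq.encode(), dtype=np.uint8)
        if len(t) == 0 or len(c) == 0:
            continue
        eq = t[:, None] == c[None, :]
        for offset in range(-(len(t) - 1), len(c)):
            diag = np.diagonal(eq, offset=offset)
            if len(diag) < sirna_len:
                continue
            # run-length scan of the boolean diagonal
            padded = np.concatenate([[False], diag, [False]])
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for run_start, run_end in zip(edges[::2], edges[1::2]):
                run_len = int(run_end - run_start)
                if run_len >= sirna_len:
                    if offset >= 0:
                        t_start, c_start = int(run_start), int(run_start + offset)
                    else:
                        t_start, c_start = int(run_start - offset), int(run_start)
                    windows.append(
                        OfftargetWindow(
                            transcript_start=t_start,
                            construct_start=c_start,
                            length=run_len,
                            strand=strand,
                        )
                    )
    windows.sort(key=lambda w: (w.transcript_start, w.strand, w.construct_start))
    total = sum(w.n_sirnas(sirna_len) for w in windows)
    return windows, total
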