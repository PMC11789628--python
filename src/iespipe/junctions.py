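"""Junction-sequence library and read-to-variant assignment.

Reads are assigned to per-IES excision variants by comparison against a
library of junction sequences:

* two retention junctions per IES (germline sequence spanning each TA
  boundary),
* one exact-excision junction (the somatic sequence spanning the
  excision point), and
* one alternative-excision junction per canonical candidate TA pair.

Matching is by Hamming distance over the best placement of each
junction string within the read (or its reverse complement), requiring
at least ``min_anchor`` matched bases on each side of the junction
point.  Candidate placements are discovered with an exact-seed index:
any placement with at most ``max_mismatch`` mismatches over an overlap
of >= ``2 * min_anchor`` bases must contain an exact run of at least
``(2 * min_anchor - max_mismatch) // (max_mismatch + 1)`` bases, so
seed lookup followed by masked Hamming verification is equivalent to an
exhaustive sliding scan while remaining fast on large read sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    GenomeError,
    GenomePair,
    IesAnnotation,
    canonical_alt_variants,
    junction_string,
    revcomp,
)
from .simulate import Read

__all__ = [
    "Junction",
    "JunctionLibrary",
    "EventCounts",
    "Assignment",
    "build_junction_library",
    "assign_read",
    "assign_reads",
    "count_events",
    "read_sam_sequences",
    "write_counts_tsv",
]

#: resolution order when one read ties across categories of the same IES
CATEGORY_PRIORITY = {"exact": 0, "alt": 1, "retention": 2}


@dataclass(frozen=True)
class Junction:
    """One junction string of the library."""

    ies_id: str
    kind: str  # retention_left | retention_right | exact | alt
    pair: tuple[int, int] | None  # canonical alt boundary pair, if kind == "alt"
    seq: str
    midpoint: int  # offset of the junction point within seq
    truncated: bool = False

    @property
    def category(self) -> str:
        return "retention" if self.kind.startswith("retention") else self.kind

    @property
    def variant_id(self) -> str:
        if self.kind == "alt":
            return f"alt:{self.pair[0]}-{self.pair[1]}"
        return self.kind


@dataclass
class JunctionLibrary:
    junctions: list[Junction]
    anchor_k: int
    window_W: int
    min_alt_len: int
    #: canonical_pair -> all equivalent raw pairs, per IES
    equivalents: dict[str, dict[tuple[int, int], list[tuple[int, int]]]] = field(
        default_factory=dict
    )
    _seed_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.junctions)

    def canonical_pair(self, ies_id: str, pair: tuple[int, int]) -> tuple[int, int]:
        """Map any raw alternative pair to its canonical representative."""
        for canon, members in self.equivalents.get(ies_id, {}).items():
            if pair in members:
                return canon
        raise KeyError(f"{ies_id}: {pair} is not a candidate alternative pair")

    def seed_index(self, seed_len: int) -> dict[str, list[tuple[int, int]]]:
        """Exact-seed lookup: seed string -> [(junction index, offset)]."""
        cached = self._seed_cache.get(seed_len)
        if cached is not None:
            return cached
        index: dict[str, list[tuple[int, int]]] = {}
        for j, jn in enumerate(self.junctions):
            for p in range(0, len(jn.seq) - seed_len + 1):
                index.setdefault(jn.seq[p : p + seed_len], []).append((j, p))
        self._seed_cache[seed_len] = index
        return index


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str  # assigned | ambiguous | unassigned
    ies_id: str | None = None
    category: str | None = None
    variant_id: str | None = None
    distance: int | None = None
    #: for retention assignments: which boundary junctions tied at the
    #: minimal distance ("retention_left"/"retention_right"); a read
    #: spanning both boundaries of a short IES carries both
    retention_sides: tuple[str, ...] = ()


def build_junction_library(
    pair: GenomePair,
    anchor_k: int = 25,
    window_W: int = 20,
    min_alt_len: int = 2,
) -> JunctionLibrary:
    """Build the junction library for every annotated IES.

    Candidate alternative pairs are enumerated per
    :func:`iespipe.genome.alternative_boundary_pairs` and collapsed to
    canonical variants with locally distinct excision products.  IESs
    closer than ``anchor_k`` to a scaffold edge get truncated junction
    strings, flagged on the record.
    """
    if anchor_k < 12:
        raise ValueError("anchor_k must be >= 12")
    junctions: list[Junction] = []
    equivalents: dict[str, dict[tuple[int, int], list[tuple[int, int]]]] = {}
    for ann in pair.annotations:
        seq = pair.germline[ann.scaffold]
        l, r = ann.left_ta, ann.right_ta
        for kind, center in (("retention_left", l), ("retention_right", r + 2)):
            lo = max(0, center - anchor_k)
            hi = min(len(seq), center + anchor_k)
            junctions.append(
                Junction(
                    ies_id=ann.id,
                    kind=kind,
                    pair=None,
                    seq=seq[lo:hi],
                    midpoint=center - lo,
                    truncated=(hi - lo) < 2 * anchor_k,
                )
            )
        exact_seq = junction_string(seq, l, r, anchor_k)
        junctions.append(
            Junction(
                ies_id=ann.id,
                kind="exact",
                pair=None,
                seq=exact_seq,
                midpoint=l - max(0, l - anchor_k),
                truncated=len(exact_seq) < 2 * anchor_k,
            )
        )
        variants = canonical_alt_variants(
            seq, ann, window=window_W, min_alt_len=min_alt_len, anchor_k=anchor_k
        )
        equivalents[ann.id] = variants
        for (a, b) in variants:
            alt_seq = junction_string(seq, a, b, anchor_k)
            junctions.append(
                Junction(
                    ies_id=ann.id,
                    kind="alt",
                    pair=(a, b),
                    seq=alt_seq,
                    midpoint=a - max(0, a - anchor_k),
                    truncated=len(alt_seq) < 2 * anchor_k,
                )
            )
    return JunctionLibrary(
        junctions=junctions,
        anchor_k=anchor_k,
        window_W=window_W,
        min_alt_len=min_alt_len,
        equivalents=equivalents,
    )


def _seed_len(min_anchor: int, max_mismatch: int) -> int:
    return max(4, (2 * min_anchor - max_mismatch) // (max_mismatch + 1))


def _candidate_hits(
    read: str, index: dict[str, list[tuple[int, int]]], seed_len: int
) -> set[tuple[int, int]]:
    hits: set[tuple[int, int]] = set()
    for i in range(0, len(read) - seed_len + 1):
        for j, p in index.get(read[i : i + seed_len], ()):
            hits.add((j, i - p))
    return hits


def _masked_distance(
    read: bytes, jn: Junction, jseq: bytes, offset: int, min_anchor: int
) -> int | None:
    """Hamming distance over the read/junction overlap, or None if the
    placement leaves fewer than ``min_anchor`` bases on either side of
    the junction point."""
    ov_start = max(0, offset)
    ov_end = min(len(read), offset + len(jseq))
    mid = offset + jn.midpoint
    if mid - ov_start < min_anchor or ov_end - mid < min_anchor:
        return None
    a = read[ov_start:ov_end]
    b = jseq[ov_start - offset : ov_end - offset]
    return sum(x != y for x, y in zip(a, b))


def assign_read(
    read: str | Read,
    library: JunctionLibrary,
    max_mismatch: int = 1,
    min_anchor: int = 10,
) -> Assignment:
    """Assign one read to an excision variant.

    The read is assigned to the unique variant with minimal distance
    <= ``max_mismatch``.  Ties across different IESs are ambiguous;
    ties across categories of one IES resolve by the priority
    exact > alt > retention, then by lexicographic variant id.
    """
    if not library.junctions:
        raise GenomeError("junction library is empty")
    rid, seq = (read.id, read.seq) if isinstance(read, Read) else ("read", read)
    seed_len = _seed_len(min_anchor, max_mismatch)
    index = library.seed_index(seed_len)

    best: dict[tuple[str, str, str], int] = {}
    best_dist = max_mismatch + 1
    for oriented in (seq, revcomp(seq)):
        rb = oriented.encode()
        for j, offset in _candidate_hits(oriented, index, seed_len):
            jn = library.junctions[j]
            d = _masked_distance(rb, jn, jn.seq.encode(), offset, min_anchor)
            if d is None or d > max_mismatch:
                continue
            key = (jn.ies_id, jn.category, jn.variant_id)
            if d < best.get(key, max_mismatch + 1):
                best[key] = d
            best_dist = min(best_dist, d)
    if not best:
        return Assignment(read_id=rid, status="unassigned")
    ties = sorted(k for k, d in best.items() if d == best_dist)
    ies_ids = {k[0] for k in ties}
    if len(ies_ids) > 1:
        return Assignment(read_id=rid, status="ambiguous", distance=best_dist)
    ies_id, category, variant = min(
        ties, key=lambda k: (CATEGORY_PRIORITY[k[1]], k[2])
    )
    sides = tuple(k[2] for k in ties if k[1] == "retention") if category == "retention" else ()
    return Assignment(
        read_id=rid,
        status="assigned",
        ies_id=ies_id,
        category=category,
        variant_id=variant,
        distance=best_dist,
        retention_sides=sides,
    )


def assign_reads(
    reads: Iterable[Read],
    library: JunctionLibrary,
    max_mismatch: int = 1,
    min_anchor: int = 10,
) -> list[Assignment]:
    return [
        assign_read(r, library, max_mismatch=max_mismatch, min_anchor=min_anchor)
        for r in reads
    ]


@dataclass
class EventCounts:
    """Per-IES tallies of retention, exact-excision, and alternative reads."""

    per_ies: dict[str, dict]
    n_ambiguous: int = 0
    n_unassigned: int = 0

    def n_plus(self, ies_id: str) -> int:
        return self.per_ies[ies_id]["n_plus"]

    def n_minus(self, ies_id: str) -> int:
        return self.per_ies[ies_id]["n_minus"]

    def alt(self, ies_id: str) -> dict[tuple[int, int], int]:
        return self.per_ies[ies_id]["alt"]

    def alt_total(self, ies_id: str) -> int:
        return sum(self.per_ies[ies_id]["alt"].values())

    def ies_ids(self) -> list[str]:
        return list(self.per_ies)


def count_events(
    assignments: Iterable[Assignment],
    annotations: Sequence[IesAnnotation] | None = None,
    dedupe: bool = True,
) -> EventCounts:
    """Tally assignments into per-IES event counts.

    ``n_plus`` counts distinct reads assigned to either retention
    junction; ``n_plus_left``/``n_plus_right`` tally the same reads per
    boundary (a read spanning both boundaries of a short IES counts in
    both, so retention evidence per boundary is comparable to the single
    exact-excision junction); ``n_minus`` counts exact-excision reads;
    alternative reads are tallied per canonical boundary pair.
    Duplicate read ids are counted once (lexicographically processed, so
    the tally is invariant to read order).  IESs from ``annotations``
    with no reads appear with zero counts.
    """

    def _empty() -> dict:
        return {
            "n_plus": 0,
            "n_plus_left": 0,
            "n_plus_right": 0,
            "n_minus": 0,
            "alt": {},
        }

    per_ies: dict[str, dict] = {}
    if annotations is not None:
        for ann in annotations:
            per_ies[ann.id] = _empty()
    n_ambiguous = n_unassigned = 0
    seen: set[str] = set()
    for a in sorted(assignments, key=lambda x: x.read_id):
        if dedupe:
            if a.read_id in seen:
                continue
            seen.add(a.read_id)
        if a.status == "ambiguous":
            n_ambiguous += 1
            continue
        if a.status == "unassigned":
            n_unassigned += 1
            continue
        cell = per_ies.setdefault(a.ies_id, _empty())
        if a.category == "retention":
            cell["n_plus"] += 1
            sides = a.retention_sides or (a.variant_id,)
            if "retention_left" in sides:
                cell["n_plus_left"] += 1
            if "retention_right" in sides:
                cell["n_plus_right"] += 1
        elif a.category == "exact":
            cell["n_minus"] += 1
        else:
            a_pos, b_pos = a.variant_id.removeprefix("alt:").split("-")
            pair = (int(a_pos), int(b_pos))
            cell["alt"][pair] = cell["alt"].get(pair, 0) + 1
    return EventCounts(
        per_ies=per_ies, n_ambiguous=n_ambiguous, n_unassigned=n_unassigned
    )


def read_sam_sequences(path: str | Path) -> list[Read]:
    """Extract read names and sequences from a SAM file.

    Alignments themselves are not trusted for junction calls; only the
    sequences are used, so the classification stays self-contained.
    """
    import pysam

    reads: list[Read] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                continue
            seq = rec.query_sequence
            if rec.is_reverse:
                seq = revcomp(seq)
            reads.append(Read(id=rec.query_name, seq=seq))
    return reads


def write_counts_tsv(counts: EventCounts, path: str | Path, header_comment: str = "") -> None:
    """Long-format TSV: per-IES counts with one row per alternative variant."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "ies_id\tn_plus\tn_plus_left\tn_plus_right\tn_minus\t"
            "alt_variant\talt_count\n"
        )
        for ies_id, cell in counts.per_ies.items():
            prefix = (
                f"{ies_id}\t{cell['n_plus']}\t{cell.get('n_plus_left', cell['n_plus'])}"
                f"\t{cell.get('n_plus_right', cell['n_plus'])}\t{cell['n_minus']}"
            )
            alts = sorted(cell["alt"].items())
            if not alts:
                fh.write(f"{prefix}\t.\t0\n")
            for (a, b), c in alts:
                fh.write(f"{prefix}\t{a}-{b}\t{c}\n")
        fh.write(f"# ambiguous={counts.n_ambiguous} unassigned={counts.n_unassigned}\n")
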