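"""Coordinate model for germline/somatic genomes with TA-bounded IESs.

In *Paramecium* and other ciliates the somatic (MAC) genome is produced
from a germline (MIC) genome copy by precise excision of internal
eliminated sequences (IESs).  Every IES is flanked by 5'-TA-3'
dinucleotides, and excision leaves exactly one TA at the somatic
junction.  This module fixes the coordinate conventions used throughout
the package:

* all coordinates are 0-based, half-open; GFF3 I/O converts to/from
  1-based inclusive;
* an IES is described by ``left_ta`` and ``right_ta``, the 0-based
  positions of the T of the left and right flanking TA;
* excision removes the half-open interval ``[left_ta, right_ta)``, i.e.
  the right TA survives in the somatic product;
* the reported IES length is ``excised_len = right_ta - left_ta`` and
  therefore includes exactly one TA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeError",
    "SequenceError",
    "AnnotationError",
    "IesAnnotation",
    "Liftover",
    "GenomePair",
    "revcomp",
    "excise",
    "find_ta_sites",
    "tir_length",
    "alternative_boundary_pairs",
    "junction_string",
    "canonical_alt_variants",
    "make_genome_pair",
    "read_fasta",
    "write_fasta",
    "read_ies_gff3",
    "write_ies_gff3",
    "write_ies_bed6",
]


class GenomeError(ValueError):
    """Base error for genome-model violations."""


class SequenceError(GenomeError):
    """A sequence contains characters outside the ACGT alphabet."""


class AnnotationError(GenomeError):
    """An IES annotation violates the TA-boundary or overlap invariants."""


_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_RE = re.compile(r"^[ACGT]*$")

#: feature type used in GFF3 interchange
GFF3_FEATURE_TYPE = "internal_eliminated_sequence"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_RC_TABLE)[::-1]


def validate_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase ``seq`` and reject non-ACGT characters with a named error."""
    seq = seq.upper()
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise SequenceError(
            f"{name}: invalid characters {bad!r}; only A/C/G/T are accepted"
        )
    return seq


@dataclass(frozen=True, order=True)
class IesAnnotation:
    """One IES in germline coordinates.

    Parameters
    ----------
    id :
        Stable identifier of the IES.
    scaffold :
        Name of the germline scaffold carrying the IES.
    left_ta, right_ta :
        0-based positions of the T of the left and right flanking TA.
        Excision removes ``[left_ta, right_ta)``.
    """

    scaffold: str
    left_ta: int
    right_ta: int
    id: str

    def __post_init__(self) -> None:
        if self.right_ta <= self.left_ta:
            raise AnnotationError(
                f"IES {self.id}: right_ta ({self.right_ta}) must exceed "
                f"left_ta ({self.left_ta})"
            )

    @property
    def excised_len(self) -> int:
        """Excised length in bp (= right_ta - left_ta, includes one TA)."""
        return self.right_ta - self.left_ta

    @property
    def span(self) -> tuple[int, int]:
        """Full half-open interval covering both TAs: [left_ta, right_ta + 2)."""
        return (self.left_ta, self.right_ta + 2)


class Liftover:
    """Monotone germline-to-somatic position map for one scaffold.

    Positions strictly inside an excised interval map to ``None`` (the
    "in-IES" sentinel); all other positions map to the somatic position
    obtained after removing every excised interval to their left.
    """

    def __init__(self, excised_intervals: Sequence[tuple[int, int]]):
        starts = np.asarray([s for s, _ in excised_intervals], dtype=np.int64)
        ends = np.asarray([e for _, e in excised_intervals], dtype=np.int64)
        self._starts = starts
        self._ends = ends
        self._cum = np.concatenate(
            [[0], np.cumsum(ends - starts)]
        ) if len(starts) else np.zeros(1, dtype=np.int64)

    def __call__(self, pos: int) -> int | None:
        i = int(np.searchsorted(self._starts, pos, side="right"))
        if i > 0 and pos < self._ends[i - 1]:
            return None
        return int(pos - self._cum[i])

    def in_ies(self, pos: int) -> bool:
        return self(pos) is None


@dataclass
class GenomePair:
    """Germline scaffolds, IES annotations, and the derived somatic genome."""

    germline: dict[str, str]
    annotations: list[IesAnnotation]
    somatic: dict[str, str] = field(default_factory=dict)
    liftover: dict[str, Liftover] = field(default_factory=dict)

    def annotations_on(self, scaffold: str) -> list[IesAnnotation]:
        return [a for a in self.annotations if a.scaffold == scaffold]

    @property
    def germline_length(self) -> int:
        return sum(len(s) for s in self.germline.values())

    @property
    def somatic_length(self) -> int:
        return sum(len(s) for s in self.somatic.values())

    def ies_sequence(self, ann: IesAnnotation, include_right_ta: bool = False) -> str:
        """Germline sequence of one IES.

        With ``include_right_ta`` the sequence runs through ``right_ta + 2``
        (both TAs included), which is the convention used for terminal
        inverted repeat measurement.
        """
        seq = self.germline[ann.scaffold]
        end = ann.right_ta + 2 if include_right_ta else ann.right_ta
        return seq[ann.left_ta : end]


def _check_annotations(seq: str, annotations: Sequence[IesAnnotation]) -> None:
    prev_end = -1
    prev_id = None
    for ann in annotations:
        lo, hi = ann.span
        if lo < prev_end:
            raise AnnotationError(
                f"IES {ann.id} overlaps IES {prev_id} "
                f"(interval [{lo}, {hi}) vs previous end {prev_end})"
            )
        if lo < 0 or hi > len(seq):
            raise AnnotationError(f"IES {ann.id} extends outside the scaffold")
        for pos, side in ((ann.left_ta, "left"), (ann.right_ta, "right")):
            if seq[pos : pos + 2] != "TA":
                raise AnnotationError(
                    f"IES {ann.id}: no TA at the {side} boundary "
                    f"(position {pos}: {seq[pos:pos + 2]!r})"
                )
        prev_end, prev_id = hi, ann.id


def excise(
    germline_seq: str, annotations: Sequence[IesAnnotation]
) -> tuple[str, Liftover]:
    """Remove every annotated IES from one germline scaffold.

    Annotations must be sorted and non-overlapping; each must carry a TA
    at both boundaries.  For each IES the interval
    ``[left_ta, right_ta)`` is removed so exactly one TA remains at the
    somatic junction.

    Returns
    -------
    tuple
        ``(somatic_seq, liftover)`` where ``liftover`` maps germline to
        somatic positions.
    """
    anns = sorted(annotations, key=lambda a: a.left_ta)
    _check_annotations(germline_seq, anns)
    parts: list[str] = []
    prev = 0
    for ann in anns:
        parts.append(germline_seq[prev : ann.left_ta])
        prev = ann.right_ta
    parts.append(germline_seq[prev:])
    somatic = "".join(parts)
    lift = Liftover([(a.left_ta, a.right_ta) for a in anns])
    return somatic, lift


def make_genome_pair(
    germline: Mapping[str, str], annotations: Iterable[IesAnnotation]
) -> GenomePair:
    """Validate sequences/annotations and derive the somatic genome."""
    germ = {name: validate_sequence(seq, name) for name, seq in germline.items()}
    anns = sorted(annotations, key=lambda a: (a.scaffold, a.left_ta))
    pair = GenomePair(germline=germ, annotations=anns)
    for name, seq in germ.items():
        somatic, lift = excise(seq, pair.annotations_on(name))
        pair.somatic[name] = somatic
        pair.liftover[name] = lift
    return pair


def find_ta_sites(seq: str, start: int = 0, end: int | None = None) -> list[int]:
    """All 0-based positions ``p`` in ``[start, end - 2]`` with ``seq[p:p+2] == "TA"``.

    Overlapping occurrences are both reported ("TATA" yields ``[0, 2]``).
    """
    if end is None:
        end = len(seq)
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"invalid range [{start}, {end}) for length {len(seq)}")
    out: list[int] = []
    pos = seq.find("TA", start)
    while 0 <= pos <= end - 2:
        out.append(pos)
        pos = seq.find("TA", pos + 1)
    return out


def tir_length(ies_seq: str) -> int:
    """Length of the terminal inverted repeat of an IES sequence.

    ``ies_seq`` runs from the left TA through the right TA inclusive
    (``left_ta`` .. ``right_ta + 2``), so it begins and ends with TA.
    The TIR length is the maximal ``k`` such that the length-``k`` prefix
    equals the reverse complement of the length-``k`` suffix.  TA itself
    is its own reverse complement, so the result is always >= 2 for a
    valid IES.
    """
    n = len(ies_seq)
    if n < 4:
        raise GenomeError(f"IES sequence too short for TIR measurement ({n} < 4)")
    for k in range(n, 0, -1):
        if ies_seq[:k] == revcomp(ies_seq[-k:]):
            return k
    return 0


def alternative_boundary_pairs(
    seq: str,
    ann: IesAnnotation,
    window: int = 20,
    min_alt_len: int = 2,
) -> list[tuple[int, int]]:
    """Candidate alternative TA boundary pairs for one IES.

    A candidate is a pair ``(left', right')`` of TA site positions with

    * ``left'`` in ``[left_ta - window, right_ta + 2)``,
    * ``right'`` in ``(left_ta, right_ta + window]``,
    * ``right' - left' >= min_alt_len``,
    * the pair differs from the reference pair, and
    * the excised interval ``[left', right')`` overlaps the reference
      excised interval ``[left_ta, right_ta)``.
    """
    l, r = ann.left_ta, ann.right_ta
    lefts = find_ta_sites(seq, max(0, l - window), min(len(seq), r + 2))
    rights = [
        p
        for p in find_ta_sites(seq, l + 1, min(len(seq), r + window + 2))
        if p > l
    ]
    pairs: list[tuple[int, int]] = []
    for a in lefts:
        for b in rights:
            if b - a < min_alt_len:
                continue
            if (a, b) == (l, r):
                continue
            if a < r and b > l:  # excised intervals overlap
                pairs.append((a, b))
    pairs.sort()
    return pairs


def junction_string(seq: str, left: int, right: int, anchor_k: int) -> str:
    """Sequence of the excision product around the junction.

    ``anchor_k`` bases upstream of ``left`` joined to ``anchor_k`` bases
    from ``right`` onward; truncated silently at scaffold edges.
    """
    return seq[max(0, left - anchor_k) : left] + seq[right : right + anchor_k]


def canonical_alt_variants(
    seq: str,
    ann: IesAnnotation,
    window: int = 20,
    min_alt_len: int = 2,
    anchor_k: int = 25,
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Group candidate boundary pairs whose excision products are locally identical.

    When TA sites overlap or repeat (e.g. TATA runs), distinct boundary
    pairs can yield byte-identical excision products — including pairs
    whose products equal the exact product, and boundary pairs shifted
    jointly across a TA repeat.  Such events are indistinguishable by
    any read.  Pairs are therefore keyed by the local product sequence
    over a fixed germline window (``anchor_k + window`` bases beyond
    the reference boundaries, which covers every candidate boundary
    plus full anchor context): ``seq[l - K : left'] + seq[right' : r + 2 + K]``.
    Groups whose product equals the exact-excision product are dropped
    because they are not observable as alternative events.  The
    canonical representative of each group is its lexicographically
    smallest pair.

    Returns a mapping ``canonical_pair -> sorted list of member pairs``.
    """
    key_flank = anchor_k + window
    lo = max(0, ann.left_ta - key_flank)
    hi = min(len(seq), ann.right_ta + 2 + key_flank)

    def product_key(left: int, right: int) -> str:
        return seq[lo:left] + seq[right:hi]

    exact = product_key(ann.left_ta, ann.right_ta)
    groups: dict[str, list[tuple[int, int]]] = {}
    for pair in alternative_boundary_pairs(seq, ann, window, min_alt_len):
        groups.setdefault(product_key(*pair), []).append(pair)
    out = {
        min(members): sorted(members)
        for key, members in groups.items()
        if key != exact
    }
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# standard-format I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: validated uppercase sequence}``."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = validate_sequence(str(rec.seq), rec.id)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_ies_gff3(
    annotations: Iterable[IesAnnotation], path: str | Path, source: str = "iespipe"
) -> None:
    """Write IES annotations as GFF3.

    The record covers both flanking TAs: 1-based ``start = left_ta + 1``
    and ``end = right_ta + 2``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            fh.write(
                "\t".join(
                    [
                        ann.scaffold,
                        source,
                        GFF3_FEATURE_TYPE,
                        str(ann.left_ta + 1),
                        str(ann.right_ta + 2),
                        ".",
                        "+",
                        ".",
                        f"ID={ann.id}",
                    ]
                )
                + "\n"
            )


def read_ies_gff3(path: str | Path) -> list[IesAnnotation]:
    anns: list[IesAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9 or fields[2] != GFF3_FEATURE_TYPE:
                continue
            scaffold, start, end = fields[0], int(fields[3]), int(fields[4])
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            anns.append(
                IesAnnotation(
                    scaffold=scaffold,
                    left_ta=start - 1,
                    right_ta=end - 2,
                    id=attrs.get("ID", f"{scaffold}:{start}"),
                )
            )
    anns.sort(key=lambda a: (a.scaffold, a.left_ta))
    return anns


def write_ies_bed6(annotations: Iterable[IesAnnotation], path: str | Path) -> None:
    """BED6 export of IES intervals (both TAs included)."""
    with open(path, "w") as fh:
        for ann in annotations:
            lo, hi = ann.span
            fh.write(f"{ann.scaffold}\t{lo}\t{hi}\t{ann.id}\t0\t+\n")
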