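"""Synthetic germline/somatic data generator with known ground truth.

Emulates the data types produced in a genome-editing knockdown study of
a ciliate: a germline genome carrying TA-bounded IESs with ~5 bp
terminal inverted repeats and a 10/11 bp periodic length distribution
depleted in the 34-44 bp "forbidden" band; excision-outcome molecules
(retained / exact / alternative-boundary); whole-genome reads;
~146 bp nucleosome fragments with per-IES density multipliers; and
small RNA reads in configurable length classes drawn from vector, MAC,
or IES sources.

Every stochastic step derives its random stream deterministically from
``SimConfig.seed`` so that all emitted files are byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import (
    GenomeError,
    GenomePair,
    IesAnnotation,
    canonical_alt_variants,
    make_genome_pair,
    revcomp,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Molecule",
    "Read",
    "default_length_spec",
    "sample_ies_length",
    "build_genome",
    "simulate_molecules",
    "simulate_reads",
    "simulate_nucleosome_fragments",
    "simulate_srna",
    "write_fastq",
    "write_srna_fasta",
    "write_fragments_bed",
    "read_fragments_bed",
    "parse_read_id",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def default_length_spec(
    n_comb_peaks: int = 15, decay: float = 0.85, peak_sd: float = 1.0
) -> list[tuple[float, float, float]]:
    """Default IES length mixture: ``(peak_center, peak_sd, weight)`` triples.

    Peaks at 27, 37, 48, then +10.5 bp per peak out to ~200 bp.  The
    first peak carries one third of the mass (the dominant 26-28 bp
    class); the 37 bp component carries the depleted forbidden-band
    weight (0.01); the remaining two thirds decline geometrically along
    the 10.5 bp comb, so the overall distribution decays monotonically
    with the characteristic periodicity.
    """
    spec = [(27.0, peak_sd, 0.33), (37.0, peak_sd, 0.01)]
    weights = [decay**k for k in range(n_comb_peaks)]
    total = sum(weights)
    for k, w in enumerate(weights):
        spec.append((48.0 + 10.5 * k, peak_sd, 0.66 * w / total))
    return spec


def _as_per_ies(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected scalar or length-{n} sequence")
    return arr


@dataclass
class SimConfig:
    """All knobs of the generator, with the study-like defaults.

    Probabilities are per IES (scalar values broadcast).  ``depth`` is
    fold-coverage of the molecule pool by reads; ``copies_per_ies`` is
    the number of independent excision outcomes drawn per IES.
    """

    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len: int = 20_000
    n_ies: int = 50
    length_spec: list[tuple[float, float, float]] = field(
        default_factory=default_length_spec
    )
    retention_prob: float | Sequence[float] = 0.0
    alt_prob: float | Sequence[float] = 0.01
    alt_decay: float = 0.6
    copies_per_ies: int = 10
    read_len: int = 100
    depth: float = 20.0
    error_rate: float = 0.0
    nuc_frag_mean: float = 146.0
    nuc_frag_sd: float = 15.0
    nuc_depth: float = 10.0
    density_multiplier: float | Sequence[float] = 1.0
    srna_classes: list[tuple[int, str, str, int]] = field(
        default_factory=lambda: [
            (23, "siRNA", "vector", 500),
            (23, "siRNA_mac", "MAC", 100),
            (25, "scnRNA_mac", "MAC", 200),
            (25, "scnRNA_ies", "IES", 200),
            (27, "iesRNA", "IES", 200),
        ]
    )
    # geometry of molecule windows and alternative-boundary candidates;
    # must match the detection parameters for like-for-like comparisons
    molecule_flank: int = 120
    window_W: int = 20
    min_alt_len: int = 2
    anchor_k: int = 25
    # spacing >= molecule_flank + anchor_k + min read anchor keeps each
    # molecule window free of every neighbor's junction context
    min_ies_spacing: int = 160

    def __post_init__(self) -> None:
        for name in ("n_scaffolds", "scaffold_len", "n_ies", "copies_per_ies",
                     "read_len", "molecule_flank", "anchor_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        w = np.array([t[2] for t in self.length_spec], dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("length_spec weights must be >= 0 with positive sum")
        for p in np.atleast_1d(np.asarray(self.retention_prob, dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ValueError("retention_prob must lie in [0, 1]")
        for p in np.atleast_1d(np.asarray(self.alt_prob, dtype=float)):
            if not 0.0 <= p <= 1.0:
                raise ValueError("alt_prob must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 0.0 < self.alt_decay <= 1.0:
            raise ValueError("alt_decay must lie in (0, 1]")

    def rng_children(self, n: int) -> list[np.random.Generator]:
        """Deterministic child generators derived from the config seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class Molecule:
    """One excision-outcome DNA molecule around a single IES."""

    id: str
    ies_id: str
    outcome: str  # "retained" | "exact" | "alt"
    alt_pair: tuple[int, int] | None
    seq: str
    window_start: int  # germline coordinate of the window's first base


@dataclass
class Read:
    id: str
    seq: str


@dataclass
class GroundTruth:
    """Per-IES generator parameters plus the per-molecule outcome log."""

    ies_ids: list[str]
    retention_prob: np.ndarray
    alt_prob: np.ndarray
    density_multiplier: np.ndarray
    molecules: list[Molecule] = field(default_factory=list)

    def outcome_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {
            i: {"retained": 0, "exact": 0, "alt": 0} for i in self.ies_ids
        }
        for mol in self.molecules:
            out[mol.ies_id][mol.outcome] += 1
        return out

    def molecule_by_id(self, mol_id: str) -> Molecule:
        if not hasattr(self, "_index"):
            self._index = {m.id: m for m in self.molecules}
        return self._index[mol_id]


def sample_ies_length(
    length_spec: Sequence[tuple[float, float, float]], rng: np.random.Generator
) -> int:
    """Draw one IES length (bp) from the discretized peak mixture.

    Lengths below the 26 bp minimum are clamped up to 26.
    """
    centers = np.array([t[0] for t in length_spec], dtype=float)
    sds = np.array([t[1] for t in length_spec], dtype=float)
    weights = np.array([t[2] for t in length_spec], dtype=float)
    total = weights.sum()
    if total <= 0 or np.any(weights < 0):
        raise GenomeError("length_spec is not normalizable")
    weights = weights / total
    k = rng.choice(len(weights), p=weights)
    length = int(round(rng.normal(centers[k], sds[k])))
    return max(26, length)


def _random_bases(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def build_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Generate a germline genome with placed IESs and the truth skeleton.

    IESs are placed uniformly without overlap (minimum spacing
    ``min_ies_spacing``).  Each IES gets TA boundaries, a 5 bp terminal
    inverted repeat, a planted internal TA at its midpoint (>= 3 bp from
    either boundary), and planted external TAs 8 bp outside each
    boundary so that alternative boundary candidates always exist.

    Returns
    -------
    tuple
        ``(GenomePair, GroundTruth)``.
    """
    if rng is None:
        rng = config.rng_children(1)[0]
    n_per = np.full(config.n_scaffolds, config.n_ies // max(1, config.n_scaffolds))
    n_per[: config.n_ies % max(1, config.n_scaffolds)] += 1

    germline: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    ies_counter = 0
    edge_margin = 30 + config.molecule_flank
    for s in range(config.n_scaffolds):
        name = f"scaffold_{s + 1}"
        seq = _random_bases(config.scaffold_len, rng)
        lengths = [
            sample_ies_length(config.length_spec, rng) for _ in range(int(n_per[s]))
        ]
        placements = _place_intervals(
            config.scaffold_len,
            lengths,
            spacing=config.min_ies_spacing,
            margin=edge_margin,
            rng=rng,
        )
        for left, length in placements:
            right = left + length
            _write_ies(seq, left, right, rng)
            ies_counter += 1
            annotations.append(
                IesAnnotation(
                    scaffold=name,
                    left_ta=left,
                    right_ta=right,
                    id=f"IES_{ies_counter:04d}",
                )
            )
        germline[name] = seq.tobytes().decode()
    pair = make_genome_pair(germline, annotations)
    n = len(pair.annotations)
    truth = GroundTruth(
        ies_ids=[a.id for a in pair.annotations],
        retention_prob=_as_per_ies(config.retention_prob, n, "retention_prob"),
        alt_prob=_as_per_ies(config.alt_prob, n, "alt_prob"),
        density_multiplier=_as_per_ies(
            config.density_multiplier, n, "density_multiplier"
        ),
    )
    return pair, truth


def _place_intervals(total_len, lengths, spacing, margin, rng):
    """Non-overlapping placement with uniformly distributed slack.

    The free space left after reserving every IES span plus the minimum
    spacing is split uniformly at random among the gaps (sorted uniform
    cut points), so placements are uniform subject to the constraints
    and construction never needs rejection retries.
    """
    n = len(lengths)
    if n == 0:
        return []
    usable = total_len - 2 * margin
    reserved = sum(length + 2 for length in lengths) + n * spacing
    slack = usable - reserved
    if slack < 0:
        raise GenomeError(
            f"cannot place {n} IESs totalling {sum(lengths)} bp "
            f"in a {total_len} bp scaffold with spacing {spacing}"
        )
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    placed: list[tuple[int, int]] = []
    offset = margin
    for k, length in enumerate(lengths):
        start = offset + int(cuts[k])
        placed.append((start, length))
        offset += length + 2 + spacing
    return placed


def _write_ies(seq: np.ndarray, left: int, right: int, rng: np.random.Generator):
    """Write one IES in place: TA boundaries, 5 bp TIR, planted TA sites."""
    length = right - left
    head = b"TA" + _random_bases(3, rng).tobytes()
    tail = revcomp(head.decode()).encode()  # ends with TA
    full = bytearray(_random_bases(length + 2, rng).tobytes())
    full[:5] = head
    full[-5:] = tail
    mid = length // 2
    full[mid : mid + 2] = b"TA"  # internal TA, >= 3 bp from both boundaries
    seq[left : right + 2] = np.frombuffer(bytes(full), dtype="S1")
    # external TA sites within 20 bp of each boundary
    seq[left - 8 : left - 6] = np.frombuffer(b"TA", dtype="S1")
    seq[right + 8 : right + 10] = np.frombuffer(b"TA", dtype="S1")


def alt_candidates_for(
    pair: GenomePair, ann: IesAnnotation, config: SimConfig
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Canonical alternative boundary variants for one IES under ``config``."""
    return canonical_alt_variants(
        pair.germline[ann.scaffold],
        ann,
        window=config.window_W,
        min_alt_len=config.min_alt_len,
        anchor_k=config.anchor_k,
    )


def simulate_molecules(
    pair: GenomePair,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Molecule]:
    """Draw excision outcomes and build molecule sequences.

    Per IES copy the outcome is retained with probability rho, otherwise
    alternative with probability alpha, otherwise exact.  Alternative
    boundary pairs are drawn from the canonical candidate set with
    probability proportional to ``alt_decay ** (|dL| + |dR|)``.
    Molecules are local germline windows (``molecule_flank`` bp each
    side of the IES) with the drawn excision applied.
    """
    molecules: list[Molecule] = []
    rho = dict(zip(truth.ies_ids, truth.retention_prob))
    alpha = dict(zip(truth.ies_ids, truth.alt_prob))
    for ann in pair.annotations:
        seq = pair.germline[ann.scaffold]
        w0 = max(0, ann.left_ta - config.molecule_flank)
        w1 = min(len(seq), ann.right_ta + 2 + config.molecule_flank)
        window = seq[w0:w1]
        cands = alt_candidates_for(pair, ann, config)
        cand_pairs = list(cands.keys())
        if cand_pairs:
            weights = np.array(
                [
                    config.alt_decay
                    ** (abs(a - ann.left_ta) + abs(b - ann.right_ta))
                    for a, b in cand_pairs
                ]
            )
            weights = weights / weights.sum()
        for j in range(config.copies_per_ies):
            u = rng.random()
            if u < rho[ann.id]:
                outcome, pair_ab = "retained", None
                mol_seq = window
            else:
                want_alt = rng.random() < alpha[ann.id]
                if want_alt and not cand_pairs:
                    warnings.warn(
                        f"{ann.id}: no candidate alternative TA pair; "
                        "falling back to exact excision"
                    )
                    want_alt = False
                if want_alt:
                    k = rng.choice(len(cand_pairs), p=weights)
                    pair_ab = cand_pairs[int(k)]
                    outcome = "alt"
                    a, b = pair_ab
                    mol_seq = window[: a - w0] + window[b - w0 :]
                else:
                    outcome, pair_ab = "exact", None
                    mol_seq = (
                        window[: ann.left_ta - w0] + window[ann.right_ta - w0 :]
                    )
            suffix = (
                f":{pair_ab[0]}-{pair_ab[1]}" if pair_ab is not None else ""
            )
            molecules.append(
                Molecule(
                    id=f"{ann.id}|m{j}|{outcome}{suffix}",
                    ies_id=ann.id,
                    outcome=outcome,
                    alt_pair=pair_ab,
                    seq=mol_seq,
                    window_start=w0,
                )
            )
    truth.molecules = molecules
    return molecules


def simulate_reads(
    molecules: Sequence[Molecule],
    read_len: int,
    depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> list[Read]:
    """Uniform single-end reads from molecules with substitution errors.

    Start positions are uniform over the valid placements and the read
    count per molecule is Poisson with mean
    ``depth * (len(molecule) - read_len + 1) / read_len``, so every
    valid start position carries the same expected read rate regardless
    of molecule length (for molecules much longer than a read this is
    the usual ``depth * L / read_len`` fold-coverage law).  Molecules
    shorter than ``read_len`` yield full-length copies at rate
    ``depth``.  Read ids carry molecule provenance (``<mol_id>|r<k>``).
    """
    reads: list[Read] = []
    for mol in molecules:
        length = len(mol.seq)
        if length <= read_len:
            n = rng.poisson(depth)
            starts = np.zeros(n, dtype=int)
            rl = length
        else:
            n_starts = length - read_len + 1
            n = rng.poisson(depth * n_starts / read_len)
            starts = rng.integers(0, n_starts, size=n)
            rl = read_len
        for k, s in enumerate(starts):
            seq = mol.seq[s : s + rl]
            if error_rate > 0.0:
                seq = _mutate(seq, error_rate, rng)
            reads.append(Read(id=f"{mol.id}|r{k}", seq=seq))
    return reads


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    arr = bytearray(seq.encode())
    for p in pos:
        old = arr[p]
        choices = [b for b in b"ACGT" if b != old]
        arr[p] = choices[rng.integers(0, 3)]
    return bytes(arr).decode()


def parse_read_id(read_id: str) -> dict[str, str | None]:
    """Decode the provenance embedded in simulated read ids."""
    mol_id, _, _ = read_id.rpartition("|")
    parts = mol_id.split("|")
    ies_id, _copy, outcome = parts[0], parts[1], parts[2]
    alt_pair = None
    if ":" in outcome:
        outcome, _, pair_s = outcome.partition(":")
        a, b = pair_s.split("-")
        alt_pair = (int(a), int(b))
    return {
        "molecule_id": mol_id,
        "ies_id": ies_id,
        "outcome": outcome,
        "alt_pair": alt_pair,
    }


def simulate_nucleosome_fragments(
    pair: GenomePair,
    truth: GroundTruth,
    config: SimConfig,
    rng: np.random.Generator,
    n_fragments: int | None = None,
) -> list[tuple[str, int, int]]:
    """Nucleosome-sized fragments on germline coordinates.

    Background fragments are uniform over the germline; a candidate
    overlapping IES *i* (excised interval) is kept with probability
    proportional to its density multiplier via rejection sampling.
    Fragment lengths are Normal(``nuc_frag_mean``, ``nuc_frag_sd``)
    truncated at >= 100 bp.
    """
    genome_len = pair.germline_length
    if n_fragments is None:
        n_fragments = int(config.nuc_depth * genome_len / config.nuc_frag_mean)
    scaffolds = list(pair.germline)
    lengths = np.array([len(pair.germline[s]) for s in scaffolds], dtype=float)
    scaffold_p = lengths / lengths.sum()
    mult = dict(zip(truth.ies_ids, truth.density_multiplier))
    per_scaffold = {
        s: sorted(
            (a.left_ta, a.right_ta, mult[a.id]) for a in pair.annotations_on(s)
        )
        for s in scaffolds
    }
    starts_by_scaffold = {
        s: np.array([iv[0] for iv in per_scaffold[s]]) for s in scaffolds
    }
    max_w = max(1.0, float(np.max(truth.density_multiplier, initial=1.0)))
    out: list[tuple[str, int, int]] = []
    while len(out) < n_fragments:
        batch = max(1000, int((n_fragments - len(out)) * max_w * 1.5))
        sc_idx = rng.choice(len(scaffolds), size=batch, p=scaffold_p)
        frag_len = np.maximum(
            100, np.round(rng.normal(config.nuc_frag_mean, config.nuc_frag_sd, batch))
        ).astype(int)
        u = rng.random(batch)
        for si, fl, ui in zip(sc_idx, frag_len, u):
            s = scaffolds[int(si)]
            slen = len(pair.germline[s])
            if fl >= slen:
                continue
            start = int(rng.integers(0, slen - fl + 1))
            end = start + int(fl)
            # acceptance weight = multiplier of the overlapped IES with the
            # largest base overlap (ties -> leftmost); 1.0 for background
            w = 1.0
            ivs = per_scaffold[s]
            if ivs:
                i = int(np.searchsorted(starts_by_scaffold[s], end))
                best_overlap = 0
                for l, r, m in ivs[max(0, i - 5) : i]:
                    overlap = min(end, r) - max(start, l)
                    if overlap > best_overlap:
                        best_overlap = overlap
                        w = m

            if ui < w / max_w:
                out.append((s, start, end))
                if len(out) >= n_fragments:
                    break
    return out


def simulate_srna(
    srna_classes: Sequence[tuple[int, str, str, int]],
    sources: dict[str, Sequence[str]],
    rng: np.random.Generator,
) -> list[Read]:
    """Small RNA reads: exact subsequences of the stated source sequences.

    ``srna_classes`` entries are ``(length, label, source, count)`` with
    source one of the keys of ``sources`` (typically ``vector``, ``MAC``,
    ``IES``).
    """
    reads: list[Read] = []
    for length, label, source, count in srna_classes:
        if count <= 0:
            continue
        pool = [s for s in sources[source] if len(s) >= length]
        if not pool:
            raise GenomeError(
                f"sRNA class {label}: no {source} sequence of length >= {length}"
            )
        weights = np.array([len(s) - length + 1 for s in pool], dtype=float)
        weights /= weights.sum()
        picks = rng.choice(len(pool), size=count, p=weights)
        for k, pi in enumerate(picks):
            s = pool[int(pi)]
            start = int(rng.integers(0, len(s) - length + 1))
            reads.append(
                Read(id=f"{label}|{source}|s{k}", seq=s[start : start + length])
            )
    return reads


# ---------------------------------------------------------------------------
# plain-text writers/readers for the emitted artifacts
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_srna_fasta(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")


def write_fragments_bed(
    fragments: Sequence[tuple[str, int, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for s, a, b in fragments:
            fh.write(f"{s}\t{a}\t{b}\n")


def read_fragments_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
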