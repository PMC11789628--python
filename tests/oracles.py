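"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the simplest possible code
(naive scans, double loops, sign tables) and share no logic with the
package implementation beyond the published tie-break policy.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def naive_ta_sites(seq: str, start: int, end: int) -> list[int]:
    return [p for p in range(start, end - 1) if seq[p : p + 2] == "TA"]


def naive_tir_length(ies_seq: str) -> int:
    best = 0
    for k in range(1, len(ies_seq) + 1):
        if ies_seq[:k] == rc(ies_seq[-k:]):
            best = k
    return best


def naive_alt_pairs(seq, left, right, window, min_alt_len):
    """Double loop over all TA pairs passing the candidate predicates."""
    lefts = naive_ta_sites(seq, max(0, left - window), min(len(seq), right + 2))
    rights = naive_ta_sites(seq, 0, min(len(seq), right + window + 2))
    out = []
    for a in lefts:
        for b in rights:
            if b <= left:
                continue
            if b - a < min_alt_len:
                continue
            if (a, b) == (left, right):
                continue
            if a < right and b > left:
                out.append((a, b))
    return sorted(out)


def naive_classify(ref, alt):
    """Sign-table classification of an overlapping alternative pair."""
    (l, r), (a, b) = ref, alt
    dL, dR = a - l, b - r
    table = {
        (0, -1): "partial_internal",
        (1, 0): "partial_internal",
        (0, 1): "partial_external",
        (-1, 0): "partial_external",
        (1, -1): "internal",
        (-1, 1): "external",
        (-1, -1): "overlap",
        (1, 1): "overlap",
    }
    sign = lambda v: (v > 0) - (v < 0)
    return table[(sign(dL), sign(dR))]


CATEGORY_RANK = {"exact": 0, "alt": 1, "retention": 2}


def naive_assign(read: str, junctions, max_mismatch: int, min_anchor: int):
    """Exhaustive sliding-scan read assignment.

    ``junctions`` is a sequence of objects with ``ies_id``, ``category``,
    ``variant_id``, ``seq``, and ``midpoint`` attributes.  Returns
    ``("unassigned",)``, ``("ambiguous", dist)``, or
    ``("assigned", ies, category, variant, dist)`` under the same
    published tie policy as the package (cross-IES ties ambiguous;
    within-IES category priority exact > alt > retention; then
    lexicographic variant id).
    """
    best: dict[tuple[str, str, str], int] = {}
    for oriented in (read, rc(read)):
        n = len(oriented)
        for jn in junctions:
            m = len(jn.seq)
            for offset in range(-m + 1, n):
                ov_lo = max(0, offset)
                ov_hi = min(n, offset + m)
                if ov_hi <= ov_lo:
                    continue
                mid = offset + jn.midpoint
                if mid - ov_lo < min_anchor or ov_hi - mid < min_anchor:
                    continue
                dist = sum(
                    oriented[i] != jn.seq[i - offset] for i in range(ov_lo, ov_hi)
                )
                if dist > max_mismatch:
                    continue
                key = (jn.ies_id, jn.category, jn.variant_id)
                if dist < best.get(key, max_mismatch + 1):
                    best[key] = dist
    if not best:
        return ("unassigned",)
    dmin = min(best.values())
    ties = sorted(k for k, d in best.items() if d == dmin)
    if len({k[0] for k in ties}) > 1:
        return ("ambiguous", dmin)
    ies, cat, var = min(ties, key=lambda k: (CATEGORY_RANK[k[1]], k[2]))
    return ("assigned", ies, cat, var, dmin)


def naive_shared_kmer_count(construct: str, transcript: str, k: int) -> int:
    """All (i, j, strand) exact k-mer matches between transcript and
    construct-or-reverse-complement; equals the total possible-siRNA
    count summed over maximal shared windows."""
    total = 0
    for strand_seq in (construct, rc(construct)):
        for i in range(len(transcript) - k + 1):
            kmer = transcript[i : i + k]
            for j in range(len(strand_seq) - k + 1):
                if strand_seq[j : j + k] == kmer:
                    total += 1
    return total
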