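"""Junction library construction and read-to-variant assignment."""

import random

import pytest

from iespipe.genome import GenomeError, IesAnnotation, make_genome_pair, revcomp
from iespipe.junctions import (
    Assignment,
    assign_read,
    assign_reads,
    build_junction_library,
    count_events,
)
from iespipe.simulate import (
    SimConfig,
    build_genome,
    parse_read_id,
    simulate_molecules,
    simulate_reads,
)

import oracles


@pytest.fixture(scope="module")
def pipeline_case():
    """Genome, molecules, reads, and library for a mixed-outcome run."""
    cfg = SimConfig(
        seed=23,
        n_ies=15,
        n_scaffolds=1,
        scaffold_len=10_000,
        retention_prob=0.4,
        alt_prob=0.3,
        copies_per_ies=10,
        depth=1.5,
    )
    rngs = cfg.rng_children(3)
    pair, truth = build_genome(cfg, rngs[0])
    mols = simulate_molecules(pair, truth, cfg, rngs[1])
    reads = simulate_reads(mols, cfg.read_len, cfg.depth, 0.0, rngs[2])
    library = build_junction_library(pair)
    return pair, truth, mols, reads, library


class TestLibrary:
    def test_exact_junction_equals_somatic_locally(self, small_pair_truth):
        _, pair, _ = small_pair_truth
        library = build_junction_library(pair, anchor_k=25)
        for jn in library.junctions:
            if jn.kind != "exact" or jn.truncated:
                continue
            ann = next(a for a in pair.annotations if a.id == jn.ies_id)
            som = pair.somatic[ann.scaffold]
            j = pair.liftover[ann.scaffold](ann.right_ta)
            assert jn.seq == som[j - 25 : j + 25]

    def test_ies_without_alternatives_still_gets_core_junctions(self):
        # interior and surroundings deliberately free of any extra TA
        germ = "G" * 40 + "TA" + "C" * 30 + "TA" + "G" * 40
        ann = IesAnnotation(scaffold="s", left_ta=40, right_ta=72, id="lonely")
        pair = make_genome_pair({"s": germ}, [ann])
        library = build_junction_library(pair, anchor_k=25)
        kinds = {j.kind for j in library.junctions}
        assert kinds == {"retention_left", "retention_right", "exact"}
        assert library.equivalents["lonely"] == {}

    def test_small_anchor_rejected(self, small_pair_truth):
        _, pair, _ = small_pair_truth
        with pytest.raises(ValueError, match="anchor_k"):
            build_junction_library(pair, anchor_k=8)

    def test_edge_proximal_ies_flagged_truncated(self):
        germ = "GG" + "TA" + "CCTACC" * 5 + "TA" + "G" * 60
        ann = IesAnnotation(scaffold="s", left_ta=2, right_ta=34, id="edge")
        pair = make_genome_pair({"s": germ}, [ann])
        library = build_junction_library(pair, anchor_k=25)
        left = next(j for j in library.junctions if j.kind == "retention_left")
        assert left.truncated


class TestAssignRead:
    def test_exact_junction_string_assigned_distance_zero(self, pipeline_case):
        pair, _, _, _, library = pipeline_case
        jn = next(j for j in library.junctions if j.kind == "exact")
        got = assign_read(jn.seq, library, max_mismatch=0)
        assert (got.status, got.ies_id, got.category) == ("assigned", jn.ies_id, "exact")
        assert got.distance == 0

    def test_substituted_retention_read_recovered(self, pipeline_case):
        pair, _, _, _, library = pipeline_case
        jn = next(j for j in library.junctions if j.kind == "retention_left")
        mutated = "G" + jn.seq[1:] if jn.seq[0] != "G" else "T" + jn.seq[1:]
        got = assign_read(mutated, library, max_mismatch=2)
        assert got.status == "assigned"
        assert got.category == "retention"
        # independent sliding-scan oracle agrees
        want = oracles.naive_assign(mutated, library.junctions, 2, 10)
        assert want[0] == "assigned" and want[2] == "retention"
        assert got.distance == want[4]

    def test_background_read_unassigned(self, pipeline_case):
        pair, _, _, _, library = pipeline_case
        germ = pair.germline["scaffold_1"]
        anns = pair.annotations
        # a window far from every IES
        gap_start = anns[0].right_ta + 400
        read = germ[gap_start : gap_start + 80]
        got = assign_read(read, library, max_mismatch=1)
        assert got.status == "unassigned"

    def test_reverse_complement_reads_assigned_identically(self, pipeline_case):
        _, _, _, reads, library = pipeline_case
        for r in reads[:30]:
            fwd = assign_read(r.seq, library, max_mismatch=1)
            rev = assign_read(revcomp(r.seq), library, max_mismatch=1)
            assert (fwd.status, fwd.ies_id, fwd.category, fwd.variant_id) == (
                rev.status,
                rev.ies_id,
                rev.category,
                rev.variant_id,
            )

    def test_empty_library_rejected(self):
        from iespipe.junctions import JunctionLibrary

        empty = JunctionLibrary(junctions=[], anchor_k=25, window_W=20, min_alt_len=2)
        with pytest.raises(GenomeError, match="empty"):
            assign_read("ACGT" * 20, empty, 1)

    def test_matches_naive_oracle_on_mixed_reads(self, pipeline_case):
        pair, _, mols, reads, _ = pipeline_case
        # small sub-library keeps the exhaustive oracle cheap
        sub = make_genome_pair(pair.germline, pair.annotations[:3])
        library = build_junction_library(sub)
        keep_ids = {a.id for a in sub.annotations[:3]}
        pool = [r.seq for r in reads if parse_read_id(r.id)["ies_id"] in keep_ids]
        rnd = random.Random(0)
        cases = rnd.sample(pool, 60)
        cases += [
            "".join(rnd.choice("ACGT") for _ in range(60)) for _ in range(20)
        ]
        for read in cases:
            got = assign_read(read, library, max_mismatch=1, min_anchor=10)
            want = oracles.naive_assign(read, library.junctions, 1, 10)
            assert got.status == want[0]
            if got.status == "assigned":
                assert (got.ies_id, got.category, got.variant_id, got.distance) == want[1:]


class TestCountEvents:
    def test_order_invariance_and_dedupe(self, pipeline_case):
        pair, _, _, reads, library = pipeline_case
        asg = assign_reads(reads[:300], library, 1)
        shuffled = list(asg)
        random.Random(1).shuffle(shuffled)
        a = count_events(asg, pair.annotations)
        b = count_events(shuffled, pair.annotations)
        assert a.per_ies == b.per_ies
        dup = count_events(asg + asg, pair.annotations)
        assert dup.per_ies == a.per_ies

    def test_all_retained_has_no_excision_reads(self):
        cfg = SimConfig(
            seed=5, n_ies=5, n_scaffolds=1, scaffold_len=4000,
            retention_prob=1.0, copies_per_ies=5, depth=2.0,
        )
        rngs = cfg.rng_children(3)
        pair, truth = build_genome(cfg, rngs[0])
        mols = simulate_molecules(pair, truth, cfg, rngs[1])
        reads = simulate_reads(mols, cfg.read_len, cfg.depth, 0.0, rngs[2])
        library = build_junction_library(pair)
        counts = count_events(assign_reads(reads, library, 1), pair.annotations)
        assert all(cell["n_minus"] == 0 for cell in counts.per_ies.values())
        assert all(cell["alt"] == {} for cell in counts.per_ies.values())

    def test_clean_reads_perfectly_recover_their_variant(self, pipeline_case):
        pair, _, mols, reads, library = pipeline_case
        outcome_to_category = {"retained": "retention", "exact": "exact", "alt": "alt"}
        asg = assign_reads(reads, library, max_mismatch=0)
        for a in asg:
            if a.status != "assigned":
                continue
            truth = parse_read_id(a.read_id)
            assert a.ies_id == truth["ies_id"]
            assert a.category == outcome_to_category[truth["outcome"]]
            if a.category == "alt":
                pair_got = tuple(
                    int(x) for x in a.variant_id.removeprefix("alt:").split("-")
                )
                assert pair_got == truth["alt_pair"]

    def test_proportions_track_ground_truth(self, pipeline_case):
        pair, truth, mols, reads, library = pipeline_case
        asg = assign_reads(reads, library, 1)
        counts = count_events(asg, pair.annotations)
        oc = truth.outcome_counts()
        for ies_id, cell in counts.per_ies.items():
            n_alt = sum(cell["alt"].values())
            tot = cell["n_plus"] + cell["n_minus"] + n_alt
            if tot < 20:
                continue
            true_tot = sum(oc[ies_id].values())
            p_alt = oc[ies_id]["alt"] / true_tot
            se = (p_alt * (1 - p_alt) / tot) ** 0.5
            # read-level proportions are noisier than molecule draws;
            # allow 3 SE plus the molecule-level granularity
            assert abs(n_alt / tot - p_alt) < 3 * se + 0.15
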