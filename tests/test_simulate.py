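"""Synthetic-data generator: lengths, genomes, molecules, reads, fragments, sRNAs."""

import collections

import numpy as np
import pytest

from iespipe.genome import GenomeError, find_ta_sites, tir_length
from iespipe.simulate import (
    SimConfig,
    build_genome,
    default_length_spec,
    parse_read_id,
    sample_ies_length,
    simulate_molecules,
    simulate_nucleosome_fragments,
    simulate_reads,
    simulate_srna,
    write_fastq,
)
from iespipe.genome import write_fasta, write_ies_gff3


class TestLengthSampler:
    def test_degenerate_single_peak(self, rng):
        spec = [(27.0, 0.0, 1.0)]
        assert all(sample_ies_length(spec, rng) == 27 for _ in range(100))

    def test_default_spec_depletes_forbidden_band(self, rng):
        draws = np.array(
            [sample_ies_length(default_length_spec(), rng) for _ in range(10_000)]
        )
        frac = np.mean((draws >= 34) & (draws <= 44))
        assert frac < 0.05

    def test_default_spec_mode_is_first_peak(self, rng):
        draws = [sample_ies_length(default_length_spec(), rng) for _ in range(10_000)]
        mode = collections.Counter(draws).most_common(1)[0][0]
        assert 26 <= mode <= 28

    def test_minimum_length_enforced(self, rng):
        spec = [(26.0, 3.0, 1.0)]
        assert min(sample_ies_length(spec, rng) for _ in range(500)) >= 26

    def test_unnormalizable_spec_rejected(self, rng):
        with pytest.raises(GenomeError):
            sample_ies_length([(27.0, 1.0, 0.0)], rng)


class TestBuildGenome:
    def test_no_ies_means_identical_genomes(self):
        cfg = SimConfig(seed=1, n_ies=0, n_scaffolds=1, scaffold_len=2000)
        pair, _ = build_genome(cfg)
        assert pair.somatic == pair.germline

    def test_fixed_seed_outputs_are_byte_identical(self, tmp_path):
        files = []
        for run in ("a", "b"):
            cfg = SimConfig(seed=42, n_ies=10, n_scaffolds=1, scaffold_len=6000)
            pair, _ = build_genome(cfg)
            fa = tmp_path / f"{run}.fa"
            gff = tmp_path / f"{run}.gff3"
            write_fasta(pair.germline, fa)
            write_ies_gff3(pair.annotations, gff)
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]

    def test_every_ies_has_ta_boundaries_and_tir(self, small_pair_truth):
        _, pair, _ = small_pair_truth
        for ann in pair.annotations:
            seq = pair.germline[ann.scaffold]
            assert find_ta_sites(seq, ann.left_ta, ann.left_ta + 2) == [ann.left_ta]
            assert find_ta_sites(seq, ann.right_ta, ann.right_ta + 2) == [ann.right_ta]
            assert tir_length(pair.ies_sequence(ann, include_right_ta=True)) >= 5

    def test_internal_and_external_ta_guarantees(self, small_pair_truth):
        _, pair, _ = small_pair_truth
        for ann in pair.annotations:
            seq = pair.germline[ann.scaffold]
            internal = [
                p
                for p in find_ta_sites(seq, ann.left_ta + 3, ann.right_ta - 1)
                if p >= ann.left_ta + 3
            ]
            assert internal, f"{ann.id} lacks an internal TA"
            assert find_ta_sites(seq, ann.left_ta - 20, ann.left_ta)
            assert find_ta_sites(seq, ann.right_ta + 2, ann.right_ta + 22)

    def test_infeasible_packing_raises(self):
        cfg = SimConfig(seed=0, n_ies=50, n_scaffolds=1, scaffold_len=2000)
        with pytest.raises(GenomeError, match="cannot place"):
            build_genome(cfg)


class TestMolecules:
    def _sim(self, rho, alpha, seed=2, copies=50):
        cfg = SimConfig(
            seed=seed,
            n_ies=5,
            n_scaffolds=1,
            scaffold_len=4000,
            retention_prob=rho,
            alt_prob=alpha,
            copies_per_ies=copies,
        )
        rngs = cfg.rng_children(2)
        pair, truth = build_genome(cfg, rngs[0])
        mols = simulate_molecules(pair, truth, cfg, rngs[1])
        return cfg, pair, truth, mols

    def test_all_retained_when_rho_one(self):
        _, pair, _, mols = self._sim(1.0, 0.5)
        assert {m.outcome for m in mols} == {"retained"}

    def test_all_exact_matches_somatic_window(self):
        cfg, pair, _, mols = self._sim(0.0, 0.0)
        assert {m.outcome for m in mols} == {"exact"}
        for m in mols[:10]:
            ann = next(a for a in pair.annotations if a.id == m.ies_id)
            germ = pair.germline[ann.scaffold]
            w0 = m.window_start
            w1 = w0 + len(m.seq) + ann.excised_len
            expected = germ[w0 : ann.left_ta] + germ[ann.right_ta : w1]
            assert m.seq == expected

    def test_all_alt_when_alpha_one(self):
        _, pair, _, mols = self._sim(0.0, 1.0)
        for m in mols:
            assert m.outcome == "alt"
            ann = next(a for a in pair.annotations if a.id == m.ies_id)
            seq = pair.germline[ann.scaffold]
            a, b = m.alt_pair
            assert (a, b) != (ann.left_ta, ann.right_ta)
            assert seq[a : a + 2] == "TA" and seq[b : b + 2] == "TA"

    def test_outcome_frequencies_within_three_se(self):
        rho, alpha, copies = 0.3, 0.4, 2000
        _, _, truth, mols = self._sim(rho, alpha, copies=copies)
        expected = {
            "retained": rho,
            "alt": (1 - rho) * alpha,
            "exact": (1 - rho) * (1 - alpha),
        }
        for ies_id, cnt in truth.outcome_counts().items():
            for outcome, p in expected.items():
                se = (p * (1 - p) / copies) ** 0.5
                assert abs(cnt[outcome] / copies - p) <= 3 * se + 1e-9


class TestReads:
    def test_error_free_reads_are_substrings(self, small_pair_truth, rng):
        cfg, pair, truth = small_pair_truth
        mols = simulate_molecules(pair, truth, cfg, rng)
        reads = simulate_reads(mols, 100, 1.0, 0.0, rng)
        by_id = {m.id: m for m in mols}
        for r in reads[:200]:
            mol_id = r.id.rpartition("|")[0]
            assert r.seq in by_id[mol_id].seq

    def test_read_count_follows_poisson_coverage_law(self, rng):
        from iespipe.simulate import Molecule

        length, depth, read_len = 50_000, 10.0, 100
        mol = Molecule(
            id="m|0|exact", ies_id="x", outcome="exact", alt_pair=None,
            seq="".join("ACGT"[i] for i in rng.integers(0, 4, length)),
            window_start=0,
        )
        reads = simulate_reads([mol], read_len, depth, 0.0, rng)
        lam = depth * length / read_len
        assert abs(len(reads) - lam) < 3 * lam**0.5

    def test_fixed_seed_fastq_identical(self, tmp_path, small_pair_truth):
        cfg, pair, truth = small_pair_truth
        out = []
        for run in range(2):
            rngs = cfg.rng_children(2)
            mols = simulate_molecules(pair, truth, cfg, rngs[0])
            reads = simulate_reads(mols, 100, 1.0, 0.01, rngs[1])
            path = tmp_path / f"r{run}.fastq"
            write_fastq(reads, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_substitution_rate_close_to_requested(self, rng):
        from iespipe.simulate import Molecule

        # homopolymer molecule makes per-base mismatches directly countable
        mol = Molecule(id="m|0|exact", ies_id="x", outcome="exact",
                       alt_pair=None, seq="A" * 20_000, window_start=0)
        reads = simulate_reads([mol], 100, 1.0, 0.05, rng)
        mism = sum(sum(b != "A" for b in r.seq) for r in reads)
        total = sum(len(r.seq) for r in reads)
        rate = mism / total
        assert abs(rate - 0.05) < 0.01

    def test_read_id_provenance_roundtrip(self):
        meta = parse_read_id("IES_0003|m7|alt:120-150|r2")
        assert meta["ies_id"] == "IES_0003"
        assert meta["outcome"] == "alt"
        assert meta["alt_pair"] == (120, 150)
        meta = parse_read_id("IES_0001|m0|retained|r0")
        assert meta["outcome"] == "retained"
        assert meta["alt_pair"] is None


class TestNucleosomeFragments:
    def _genome(self, multipliers, seed=4):
        cfg = SimConfig(
            seed=seed,
            n_ies=len(multipliers),
            n_scaffolds=1,
            scaffold_len=6000,
            density_multiplier=multipliers,
        )
        rngs = cfg.rng_children(2)
        pair, truth = build_genome(cfg, rngs[0])
        return cfg, pair, truth, rngs[1]

    def test_unit_multiplier_density_near_genome_mean(self):
        from iespipe.chromatin import ies_density

        cfg, pair, truth, rng = self._genome([1.0, 1.0, 1.0])
        frags = simulate_nucleosome_fragments(pair, truth, cfg, rng, n_fragments=4000)
        table = ies_density(frags, pair.annotations, pair.germline_length)
        assert np.all(np.abs(table["density"] - 1.0) < 0.4)

    def test_zero_multiplier_excludes_fragments(self):
        cfg, pair, truth, rng = self._genome([0.0, 1.0])
        frags = simulate_nucleosome_fragments(pair, truth, cfg, rng, n_fragments=2000)
        ann = pair.annotations[0]
        inside = [
            f
            for f in frags
            if f[0] == ann.scaffold
            and f[1] >= ann.left_ta
            and f[2] <= ann.right_ta
        ]
        assert inside == []

    def test_multiplier_ordering_recovered(self):
        from iespipe.chromatin import ies_density

        wins = 0
        for seed in range(20):
            cfg, pair, truth, rng = self._genome([0.5, 2.0], seed=seed)
            frags = simulate_nucleosome_fragments(
                pair, truth, cfg, rng, n_fragments=3000
            )
            t = ies_density(frags, pair.annotations, pair.germline_length)
            if t["density"].iloc[1] > t["density"].iloc[0]:
                wins += 1
        assert wins >= 19


class TestSrna:
    def test_vector_class_counts_lengths_and_exactness(self, rng):
        vector = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        reads = simulate_srna([(23, "siRNA", "vector", 100)], {"vector": [vector]}, rng)
        assert len(reads) == 100
        assert all(len(r.seq) == 23 and r.seq in vector for r in reads)

    def test_zero_count_class_absent(self, rng):
        reads = simulate_srna([(23, "siRNA", "vector", 0)], {"vector": ["ACGT" * 10]}, rng)
        assert reads == []

    def test_fixed_seed_reproducible(self):
        vector = "ACGTTACGGA" * 30
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            reads = simulate_srna([(21, "x", "vector", 50)], {"vector": [vector]}, rng)
            out.append([(r.id, r.seq) for r in reads])
        assert out[0] == out[1]
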