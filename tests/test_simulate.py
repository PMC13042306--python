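"""Synthetic community generation, fragmentation, mutation, and ablation."""

import numpy as np
import pytest

from taxsieve.paf import is_exact_match
from taxsieve.simulate import (
    MutationParams,
    NoiseModel,
    ablate_references,
    fragment_contigs,
    generate_community,
    mutate,
    read_truth_from_contigs,
    synth_paf,
    window_reads,
)


class TestGenerateCommunity:
    def test_seed_determinism(self):
        a = generate_community(n_taxa=4, seed=3)
        b = generate_community(n_taxa=4, seed=3)
        assert a.genomes == b.genomes
        assert a.contigs == b.contigs
        assert a.contig_truth == b.contig_truth

    def test_single_taxon_truth_profile_is_unit(self):
        com = generate_community(n_taxa=1, seed=0)
        for rank in com.truth_profile.ranks():
            (value,) = com.truth_profile.at_rank(rank).values()
            assert value == pytest.approx(1.0)

    def test_truth_profile_sums_to_one_per_rank(self):
        com = generate_community(n_taxa=10, seed=5)
        for rank in com.truth_profile.ranks():
            assert sum(com.truth_profile.at_rank(rank).values()) == pytest.approx(1.0)

    def test_contigs_tile_each_genome(self):
        com = generate_community(n_taxa=3, seed=7)
        for i, (ref_id, genome, taxid) in enumerate(com.genomes):
            parts = [seq for cid, seq in com.contigs if cid.startswith(f"CTG{i:02d}_")]
            assert "".join(parts) == genome

    def test_every_genome_taxid_in_taxonomy(self):
        com = generate_community(n_taxa=6, seed=1)
        for _, _, taxid in com.genomes:
            assert taxid in com.taxonomy
            assert com.taxonomy.rank_of(taxid) == "species"


class TestFragmentContigs:
    def test_single_fragment_is_whole_genome(self):
        contigs, truth = fragment_contigs("ACGTACGT", 9, n_fragments=1)
        assert contigs == [("CTG_0000", "ACGTACGT")]
        assert truth == {"CTG_0000": 9}

    def test_fragments_tile_without_overlap(self):
        genome = "ACGT" * 250
        contigs, _ = fragment_contigs(genome, 1, length_range=(100, 300), seed=4)
        assert "".join(seq for _, seq in contigs) == genome

    def test_too_many_fragments_rejected(self):
        with pytest.raises(ValueError):
            fragment_contigs("ACGT", 1, n_fragments=10)

    def test_fragment_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            fragment_contigs("ACGT" * 10, 1, length_range=(50, 100))

    def test_seed_determinism(self):
        genome = "ACGT" * 500
        a, _ = fragment_contigs(genome, 1, length_range=(100, 400), seed=9)
        b, _ = fragment_contigs(genome, 1, length_range=(100, 400), seed=9)
        assert a == b


class TestWindowReads:
    def test_exact_window_single_read(self):
        reads = window_reads([("c", "A" * 250)])
        assert [len(s) for _, s in reads] == [250]

    def test_short_tail_dropped(self):
        reads = window_reads([("c", "A" * 600)])
        assert [len(s) for _, s in reads] == [250, 250]

    def test_boundary_tail_kept(self):
        reads = window_reads([("c", "A" * 375)])
        assert [len(s) for _, s in reads] == [250, 125]

    def test_reads_reconstruct_contig_prefix(self):
        seq = "ACGTTGCA" * 100  # 800 bp -> 250+250+250 with 50 bp dropped
        reads = window_reads([("c", seq)])
        assert "".join(s for _, s in reads) == seq[:750]

    def test_read_truth_inherits_contig_taxid(self):
        reads = window_reads([("c1", "A" * 500), ("c2", "C" * 250)])
        truth = read_truth_from_contigs(reads, {"c1": 5, "c2": 9})
        assert truth == {"c1:w0": 5, "c1:w1": 5, "c2:w0": 9}


class TestMutate:
    def test_rate_zero_identity(self):
        seq = "ACGT" * 100
        assert mutate(seq, MutationParams(rate=0.0, seed=1)) == seq

    def test_seed_determinism(self):
        seq = "ACGT" * 1000
        p = MutationParams(rate=0.1, seed=33)
        assert mutate(seq, p) == mutate(seq, p)

    def test_substitution_count_within_binomial_band(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 100_000))
        rate, sub_fraction = 0.1, 1.0  # substitutions only: length preserved
        out = mutate(seq, MutationParams(rate=rate, sub_fraction=sub_fraction, seed=8))
        assert len(out) == len(seq)
        n_sub = sum(a != b for a, b in zip(seq, out))
        mean = len(seq) * rate
        sigma = (len(seq) * rate * (1 - rate)) ** 0.5
        assert abs(n_sub - mean) < 4 * sigma

    def test_indels_change_length(self):
        seq = "ACGT" * 5000
        out = mutate(seq, MutationParams(rate=0.05, sub_fraction=0.0, seed=3))
        assert len(out) != len(seq)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MutationParams(rate=0.8)


class TestSynthPaf:
    def test_perfect_model_yields_exact_records(self, balanced_community):
        com = balanced_community
        records = synth_paf(
            com.contigs, com.genomes, com.contig_truth,
            NoiseModel(kind="perfect"), taxonomy=com.taxonomy, seed=0,
        )
        assert len(records) == len(com.contigs)
        assert all(is_exact_match(r) for r in records)

    def test_partial_model_never_exact(self, balanced_community):
        com = balanced_community
        records = synth_paf(
            com.contigs, com.genomes, com.contig_truth,
            NoiseModel(kind="partial"), taxonomy=com.taxonomy, seed=0,
        )
        assert records and not any(is_exact_match(r) for r in records)

    def test_bleed_fraction_tracks_probability(self, balanced_community):
        com = balanced_community
        p = 0.3
        records = synth_paf(
            com.contigs, com.genomes, com.contig_truth,
            NoiseModel(kind="perfect", bleed_prob=p), taxonomy=com.taxonomy, seed=1,
        )
        # contigs in multi-species genera can bleed; count off-target records
        off = sum(
            1 for r in records
            if int(r.target_id.split("_")[1].split(".")[0]) != com.contig_truth[r.query_id]
        )
        eligible = sum(
            1 for cid in com.contig_truth
            if _has_genus_mate(com, com.contig_truth[cid])
        )
        mean = eligible * p
        sigma = (eligible * p * (1 - p)) ** 0.5
        assert abs(off - mean) < 4 * sigma

    def test_seed_determinism(self, balanced_community):
        com = balanced_community
        kwargs = dict(noise_model=NoiseModel(kind="partial"), taxonomy=com.taxonomy, seed=5)
        a = synth_paf(com.contigs, com.genomes, com.contig_truth, **kwargs)
        b = synth_paf(com.contigs, com.genomes, com.contig_truth, **kwargs)
        assert a == b

    def test_missing_reference_bleeds_to_genus_mates(self, balanced_community):
        com = balanced_community
        victim = com.genomes[0][2]
        reduced = [g for g in com.genomes if g[2] != victim]
        records = synth_paf(
            com.contigs, reduced, com.contig_truth,
            NoiseModel(kind="perfect"), taxonomy=com.taxonomy, seed=2,
        )
        genus = com.taxonomy.project_to_rank(victim, "genus")
        victim_contigs = [c for c, t in com.contig_truth.items() if t == victim]
        for cid in victim_contigs:
            targets = [r for r in records if r.query_id == cid]
            assert targets, "ablated contigs should bleed to genus mates"
            for rec in targets:
                taxid = int(rec.target_id.split("_")[1].split(".")[0])
                assert com.taxonomy.project_to_rank(taxid, "genus") == genus
                assert not is_exact_match(rec)


def _has_genus_mate(com, taxid):
    genus = com.taxonomy.project_to_rank(taxid, "genus")
    return any(
        t != taxid and com.taxonomy.project_to_rank(t, "genus") == genus
        for _, _, t in com.genomes
    )


class TestAblateReferences:
    REFS = [("r1", "A" * 10, 5), ("r2", "C" * 10, 5), ("r3", "G" * 10, 5),
            ("r4", "T" * 10, 5), ("r5", "A" * 10, 9)]

    def test_level_zero_identity(self):
        assert ablate_references(self.REFS, [5], 0.0) == self.REFS

    def test_full_removal(self):
        reduced = ablate_references(self.REFS, [5], 1.0)
        assert [r for r, _, t in reduced] == ["r5"]

    def test_half_removal_count_and_determinism(self):
        a = ablate_references(self.REFS, [5], 0.5, seed=4)
        b = ablate_references(self.REFS, [5], 0.5, seed=4)
        assert a == b
        assert sum(1 for _, _, t in a if t == 5) == 2

    def test_unknown_taxid_rejected(self):
        with pytest.raises(KeyError):
            ablate_references(self.REFS, [404], 0.5)
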