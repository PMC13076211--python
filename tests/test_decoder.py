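"""Candidate regions, penalties, DP decoding and GFF3 serialization."""

import math

import numpy as np
import pytest

from genedecode.dna import ContigSequence, revcomp
from genedecode.decoder import (
    CandidateRegion,
    PenaltyParams,
    decode_genome,
    decode_path,
    decode_region,
    emission_penalty,
    find_candidate_regions,
    moving_average,
    transition_penalty,
)
from genedecode.models import GeneModel, cds_phases, read_gff3, write_gff3
from genedecode.predict import PredictionTracks
from genedecode.states import build_reduced_state_space, build_state_space
from tests.conftest import exact_recovery
from tests.oracles import brute_force_min_penalty, random_instance


def intergenic_tracks(probs: np.ndarray) -> PredictionTracks:
    """Tracks with a given intergenic probability; remainder spread evenly."""
    L = probs.shape[0]
    cls = np.empty((L, 4))
    cls[:, 0] = probs
    cls[:, 1:] = ((1 - probs) / 3)[:, None]
    return PredictionTracks(cls, np.full((L, 4), 0.25), "c", "+")


class TestCandidateRegions:
    def test_moving_average_matches_direct_definition(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        for w in (1, 7, 100):
            got = moving_average(x, w)
            half = w // 2
            expected = [
                x[max(0, i - half) : min(len(x), i + (w - half))].mean()
                for i in range(len(x))
            ]
            assert np.allclose(got, expected)

    def test_all_intergenic_yields_no_regions(self):
        tracks = intergenic_tracks(np.ones(2000))
        assert find_candidate_regions(tracks) == []

    def test_low_block_found_and_matches_window_average_oracle(self):
        """A 1 kb low-intergenic block flanked by certainty-1 background gives
        exactly one region, equal to the region the moving-average definition
        selects position by position."""
        probs = np.ones(3000)
        probs[1000:2000] = 0.0
        params = PenaltyParams(intergenic_window=100, intergenic_threshold=0.5)
        regions = find_candidate_regions(intergenic_tracks(probs), params)
        assert len(regions) == 1
        avg = moving_average(probs, 100)
        oracle = np.flatnonzero(avg < 0.5)
        assert (regions[0].start, regions[0].end) == (oracle[0], oracle[-1] + 1)
        # the region tracks the block to within half a window at each edge
        assert abs(regions[0].start - 1000) <= 50
        assert abs(regions[0].end - 2000) <= 50

    def test_two_distant_blocks_give_two_regions(self):
        probs = np.ones(3000)
        probs[500:900] = 0.0
        probs[2000:2400] = 0.0
        regions = find_candidate_regions(intergenic_tracks(probs))
        assert len(regions) == 2

    def test_nearby_blocks_merge(self):
        probs = np.ones(2000)
        probs[500:800] = 0.0
        probs[860:1200] = 0.0  # gap < window
        regions = find_candidate_regions(intergenic_tracks(probs))
        assert len(regions) == 1


class TestPenalties:
    space = build_state_space()
    params = PenaltyParams()

    def test_emission_closed_forms(self):
        cds0 = self.space.by_name["reg0"]
        one_hot = np.array([0.0, 0.0, 1.0, 0.0])
        phase0 = np.array([0.0, 1.0, 0.0, 0.0])
        assert emission_penalty(cds0, one_hot, phase0, self.params) == 0.0
        half = np.array([0.25, 0.125, 0.5, 0.125])
        halfp = np.array([0.25, 0.5, 0.125, 0.125])
        assert emission_penalty(cds0, half, halfp, self.params) == pytest.approx(
            2 * math.log(2)
        )
        zero = np.array([1.0, 0.0, 0.0, 0.0])
        assert emission_penalty(cds0, zero, phase0, self.params) == pytest.approx(
            -math.log(self.params.emission_floor)
        )

    def test_non_cds_states_score_class_only(self):
        utr = self.space.by_name["UTR"]
        row = np.array([0.0, 0.5, 0.25, 0.25])
        assert emission_penalty(utr, row, np.eye(4)[0], self.params) == pytest.approx(
            math.log(2)
        )

    def trans(self, frm, to):
        return next(
            t
            for t in self.space.transitions
            if self.space.states[t.frm].name == frm and self.space.states[t.to].name == to
        )

    def test_start_codon_motif(self):
        t = self.trans("UTR", "start0")
        assert transition_penalty(t, self.space, "CCATGCC", 2, self.params) == 0.0
        assert transition_penalty(t, self.space, "CCCTGCC", 2, self.params) == math.inf

    def test_start_codon_mismatch_downstream(self):
        # "ACG" start: the A passes, but the start1 state rejects the C
        t01 = self.trans("start0", "start1")
        assert transition_penalty(t01, self.space, "ACG", 1, self.params) == math.inf
        assert transition_penalty(t01, self.space, "ATG", 1, self.params) == 0.0

    def test_donor_motifs_and_configured_gc_ag(self):
        t = self.trans("reg0", "i_start[GT_AG|reg1]")
        assert transition_penalty(t, self.space, "AGTAAG", 1, self.params) == 0.0
        tgc = self.trans("reg0", "i_start[GC_AG|reg1]")
        assert transition_penalty(tgc, self.space, "AGCAAG", 1, self.params) == math.inf
        soft = PenaltyParams(motif_penalties={"gt_ag": 0.0, "gc_ag": 4.5, "other": math.inf})
        assert transition_penalty(tgc, self.space, "AGCAAG", 1, soft) == 4.5

    def test_acceptor_motif_checked_on_exit(self):
        # intron GTAAAG: the resume base at t=6 requires AG at t-2, t-1
        t = self.trans("i_cont[GT_AG|reg1]", "reg1")
        assert transition_penalty(t, self.space, "GTAAAGC", 6, self.params) == 0.0
        assert transition_penalty(t, self.space, "GTAAACC", 6, self.params) == math.inf

    def test_out_of_bounds_checks_fail(self):
        t = self.trans("UTR", "start0")
        assert transition_penalty(t, self.space, "AT", 2, self.params) == math.inf


class TestViterbiAgainstEnumeration:
    """The DP minimum equals exhaustive path enumeration on small instances
    over the reduced grammar."""

    space = build_reduced_state_space()
    params = PenaltyParams(emission_floor=1e-3, min_cds_length=0)

    @pytest.mark.parametrize("seed", range(25))
    def test_dp_equals_brute_force(self, seed):
        seq, tracks = random_instance(seed)
        expected = brute_force_min_penalty(self.space, tracks, seq, self.params)
        got = decode_path(tracks, seq, self.params, self.space)
        if math.isinf(expected):
            assert got is None
        else:
            assert got[1] == pytest.approx(expected, rel=1e-9)


def region_for(tracks):
    return CandidateRegion(tracks.contig_id, 0, len(tracks), tracks.strand)


class TestDecoding:
    def test_perfect_input_identity(self, small_fixture):
        genes = decode_genome(small_fixture.preds, small_fixture.contigs)
        assert exact_recovery(genes, small_fixture.models) == 1.0
        for m in genes:
            assert m.validate(small_fixture.contigs[m.contig_id]) == []

    def test_all_utr_tracks_without_atg_give_zero_genes(self):
        L = 200
        cls = np.zeros((L, 4))
        cls[:, 1] = 1.0  # UTR everywhere
        tracks = PredictionTracks(cls, np.full((L, 4), 0.25), "c", "+")
        seq = ContigSequence("c", "C" * L)
        assert decode_region(region_for(tracks), tracks, seq) == []

    def test_plus_strand_only_genome_decodes_no_minus_genes(self, small_fixture):
        plus_only = [m for m in small_fixture.models if m.strand == "+"]
        from genedecode.encoding import label_contig
        from genedecode.predict import oracle_predictor

        preds = {}
        for cid, seq in small_fixture.contigs.items():
            for strand, tr in label_contig(plus_only, seq).items():
                preds[(cid, strand)] = oracle_predictor(tr, 0.0)
        genes = decode_genome(preds, small_fixture.contigs)
        assert genes and all(g.strand == "+" for g in genes)

    def test_strand_swap_mirrors_coordinates(self, small_fixture):
        """Reverse-complementing the genome and swapping the strand tracks
        mirrors every decoded interval through the coordinate map."""
        cid = "contig_1"
        L = len(small_fixture.contigs[cid])
        mirrored_seqs = {cid: small_fixture.contigs[cid].reverse_complement()}
        swapped = {
            (cid, "+"): small_fixture.preds[(cid, "-")],
            (cid, "-"): small_fixture.preds[(cid, "+")],
        }
        direct = decode_genome(small_fixture.preds, small_fixture.contigs)
        mirrored = decode_genome(swapped, mirrored_seqs)
        flip = {"+": "-", "-": "+"}

        def mapped(models):
            return {
                (
                    m.contig_id,
                    flip[m.strand],
                    tuple(sorted((L - e, L - s) for s, e in m.exons)),
                    tuple(sorted((L - e, L - s) for s, e in m.cds)),
                )
                for m in models
            }

        assert mapped(mirrored) == {
            (m.contig_id, m.strand, m.exons, m.cds) for m in direct
        }

    def test_min_cds_length_filter(self):
        # a 15-codon gene decodes under min_cds_length=0 but not the default 60
        seq = ContigSequence(
            "c", "T" * 30 + "ATG" + "GCT" * 13 + "TAA" + "T" * 30
        )
        from genedecode.encoding import label_bases
        from genedecode.predict import oracle_predictor

        gene = GeneModel("g", "c", "+", exons=((30, 75),), cds=((30, 75),))
        assert gene.validate(seq) == []
        tracks = oracle_predictor(label_bases([gene], seq), 0.0)
        relaxed = PenaltyParams(min_cds_length=0)
        assert len(decode_region(region_for(tracks), tracks, seq, relaxed)) == 1
        strict = PenaltyParams(min_cds_length=60)
        assert decode_region(region_for(tracks), tracks, seq, strict) == []

    def test_contig_mismatch_rejected(self, small_fixture):
        with pytest.raises(ValueError, match="unknown contig"):
            decode_genome(
                {("nope", "+"): small_fixture.preds[("contig_1", "+")]},
                small_fixture.contigs,
            )

    def test_decode_is_deterministic(self, small_fixture):
        a = decode_genome(small_fixture.preds, small_fixture.contigs)
        b = decode_genome(small_fixture.preds, small_fixture.contigs)
        assert [(m.gene_id, m.exons, m.cds) for m in a] == [
            (m.gene_id, m.exons, m.cds) for m in b
        ]


class TestGff3:
    def test_coordinate_convention(self, tmp_path):
        m = GeneModel("g1", "c", "+", exons=((10, 100),), cds=((10, 100),))
        path = tmp_path / "x.gff3"
        write_gff3([m], {"c": 200}, path)
        gene_row = [
            l for l in path.read_text().splitlines() if "\tgene\t" in l
        ][0].split("\t")
        assert (gene_row[3], gene_row[4]) == ("11", "100")

    def test_round_trip_preserves_models(self, small_fixture, tmp_path):
        path = tmp_path / "rt.gff3"
        lengths = {c: len(s) for c, s in small_fixture.contigs.items()}
        write_gff3(small_fixture.models, lengths, path)
        back = read_gff3(path)
        assert {(m.gene_id, m.strand, m.exons, m.cds) for m in back} == {
            (m.gene_id, m.strand, m.exons, m.cds) for m in small_fixture.models
        }

    def test_minus_strand_phases_translate_from_three_prime_end(self, default_fixture):
        multi = [
            m
            for m in default_fixture.models
            if m.strand == "-" and len(m.cds) > 1
        ]
        assert multi, "fixture should contain a spliced minus-strand gene"
        for m in multi:
            phases = cds_phases(m)
            # translation starts at the genomically-last CDS segment: phase 0
            assert phases[-1] == 0
            # each phase equals the bases to trim to reach the next codon,
            # accumulated 3' -> 5' genomically
            acc = 0
            for (s, e), ph in zip(m.cds[::-1], phases[::-1]):
                assert ph == (3 - acc % 3) % 3
                acc += e - s
            seq = default_fixture.contigs[m.contig_id]
            coding = m.coding_sequence(seq)
            assert coding.startswith("ATG") and len(coding) % 3 == 0

    def test_longest_protein_transcript_selected(self, tmp_path):
        gff = tmp_path / "iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c\tsrc\tgene\t11\t100\t.\t+\t.\tID=g1\n"
            "c\tsrc\tmRNA\t11\t100\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\tsrc\texon\t11\t100\t.\t+\t.\tParent=t1\n"
            "c\tsrc\tCDS\t11\t40\t.\t+\t0\tParent=t1\n"
            "c\tsrc\tmRNA\t11\t100\t.\t+\t.\tID=t2;Parent=g1\n"
            "c\tsrc\texon\t11\t100\t.\t+\t.\tParent=t2\n"
            "c\tsrc\tCDS\t11\t70\t.\t+\t0\tParent=t2\n"
        )
        models = read_gff3(gff)
        assert len(models) == 1
        assert models[0].cds == ((10, 70),)
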