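"""Footprint classes, region ratios, metagenes, poly(A) and spike-ins."""

import numpy as np
import pandas as pd
import pytest

from fragribo import (
    Alignment,
    FootprintClass,
    Region,
    Transcript,
    TranscriptomeModel,
    classify_footprint,
    count_polyA_tail_reads,
    find_altorfs,
    footprint_length_distribution,
    metagene_altorf,
    metagene_stop,
    motif_anchored_average,
    preprocess_reads,
    region_counts,
    short_long_ratio,
    spike_in_ratio,
    three_prime_dinucleotide,
    utr_cds_ratios,
)
from fragribo.footprints import AltORF, class_counts
from fragribo.simulate import SPIKE_INS
from fragribo.core import to_dna


def _aln(tx_id, start, end, read_len=None, read_id="r"):
    return Alignment(read_id, tx_id, start, end,
                     read_len if read_len is not None else end - start + 1, True)


class TestPreprocess:
    def test_trim_records_pretrim_length(self):
        trimmed, lengths = preprocess_reads([("r1", "ACGTACGTACGTACGT")])
        assert trimmed == [("r1", "CGTACGTACGTACGT")]
        assert lengths["r1"] == 16

    def test_no_trim_is_identity(self):
        trimmed, _ = preprocess_reads([("r1", "ACGT")], trim5=False)
        assert trimmed == [("r1", "ACGT")]

    def test_single_base_read_dropped(self):
        trimmed, lengths = preprocess_reads([("r1", "A")])
        assert trimmed == []
        assert lengths["r1"] == 1


class TestFootprintClasses:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (14, FootprintClass.OTHER),
            (15, FootprintClass.SHORT16),
            (16, FootprintClass.SHORT16),
            (18, FootprintClass.SHORT16),
            (19, FootprintClass.MID21),
            (21, FootprintClass.MID21),
            (24, FootprintClass.MID21),
            (25, FootprintClass.LONG28),
            (28, FootprintClass.LONG28),
            (34, FootprintClass.LONG28),
            (35, FootprintClass.OTHER),
        ],
    )
    def test_boundaries(self, length, expected):
        assert classify_footprint(length) == expected

    def test_short_long_ratio(self):
        assert short_long_ratio(
            {FootprintClass.SHORT16: 100, FootprintClass.LONG28: 400}
        ) == pytest.approx(0.25)
        assert short_long_ratio({FootprintClass.LONG28: 400}) == 0.0
        with pytest.raises(ValueError):
            short_long_ratio({FootprintClass.SHORT16: 10})


class TestRegionCounts:
    def test_p_site_shift(self, tiny_model):
        # 5' end at 20; P site = 32, inside CDS [30, 60)
        counts = region_counts([_aln("tx1", 20, 48)], tiny_model)
        assert counts.loc[0, "CDS_raw"] == 1
        assert counts.loc[0, "UTR5_raw"] == 0

    def test_off_transcript_assignment_dropped(self, tiny_model):
        counts = region_counts([_aln("tx1", 85, 89)], tiny_model)  # P site 97
        assert counts.attrs["n_dropped_off_transcript"] == 1
        assert counts.empty

    def test_rpm_normalization(self, tiny_model):
        alns = [_aln("tx1", 20, 48, read_id=f"r{i}") for i in range(4)]
        counts = region_counts(alns, tiny_model)
        assert counts.loc[0, "CDS_rpm"] == pytest.approx(1e6)


class TestUtrCdsRatios:
    @staticmethod
    def _counts(rows):
        df = pd.DataFrame(rows)
        for region in ("UTR5", "CDS", "UTR3"):
            df[f"{region}_rpm"] = df[f"{region}_raw"] * 1e6 / 100
        return df

    def test_ratio_and_strict_min_raw_filter(self):
        counts = self._counts([
            dict(transcript_id="a", UTR5_raw=0, CDS_raw=10, UTR3_raw=1),
            dict(transcript_id="b", UTR5_raw=0, CDS_raw=3, UTR3_raw=2),  # = 5, excluded
            dict(transcript_id="c", UTR5_raw=0, CDS_raw=4, UTR3_raw=2),  # 6 > 5, kept
        ])
        per_tx, pooled = utr_cds_ratios(counts, min_raw=5)
        assert set(per_tx.transcript_id) == {"a", "c"}
        assert per_tx.set_index("transcript_id").loc["a", "ratio"] == pytest.approx(0.1)
        assert pooled == pytest.approx((1 + 2) / (10 + 4))

    def test_zero_cds_with_region_signal_excluded(self):
        counts = self._counts([
            dict(transcript_id="a", UTR5_raw=0, CDS_raw=0, UTR3_raw=10),
            dict(transcript_id="b", UTR5_raw=0, CDS_raw=10, UTR3_raw=2),
        ])
        per_tx, _ = utr_cds_ratios(counts, min_raw=5)
        assert list(per_tx.transcript_id) == ["b"]

    def test_no_transcript_passes_is_error(self):
        counts = self._counts(
            [dict(transcript_id="a", UTR5_raw=0, CDS_raw=2, UTR3_raw=1)]
        )
        with pytest.raises(ValueError):
            utr_cds_ratios(counts, min_raw=5)


class TestMetageneStop:
    def test_uniform_coverage_gives_flat_unit_profile(self, tiny_model, tiny_tx):
        # one 5' end on every position: self-normalization yields 1.0
        alns = [
            _aln("tx1", p, min(p + 20, 90), read_id=f"r{p}")
            for p in range(tiny_tx.annotated_len)
        ]
        profile = metagene_stop(alns, tiny_model, window=(-20, 20))
        assert np.allclose(profile.value, 1.0)
        assert profile.n_transcripts == 1

    def test_offsets_beyond_transcript_contribute_nothing(self, tiny_model):
        # stop codon anchor is at 57; window extends past the 3' end (89)
        alns = [_aln("tx1", p, 90, read_id=f"r{p}") for p in range(50, 70)]
        profile = metagene_stop(alns, tiny_model, window=(-10, 40))
        off = dict(zip(profile.offsets, profile.n_per_offset))
        assert off[32] == 1  # position 89, last valid
        assert off[33] == 0  # position 90, off the transcript


class TestAltOrfs:
    def test_aug_scan_with_stop(self):
        utr = "GAATGAAATAAGC"
        seq = "G" * 12 + "ATG" + "AAA" + "TAA" + utr
        tx = Transcript("t", seq, 12, 21)
        orfs = find_altorfs(tx)
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.start == 21 + 2
        assert orf.stop == 21 + 8
        assert tx.seq[orf.start:orf.start + 3] == "ATG"

    def test_no_aug_is_empty(self):
        seq = "G" * 12 + "ATG" + "AAA" + "TAA" + "GCCGCCGCC"
        assert find_altorfs(Transcript("t", seq, 12, 21)) == []

    def test_aug_near_end_runs_into_polya(self):
        seq = "G" * 12 + "ATG" + "AAA" + "TAA" + "CCC" + "ATGA"
        orfs = find_altorfs(Transcript("t", seq, 12, 21))
        assert len(orfs) == 1
        assert orfs[0].stop is None

    def test_min_codons_filter(self):
        # AUG immediately followed by a stop: one codon before the stop
        seq = "G" * 12 + "ATG" + "AAA" + "TAA" + "CC" + "ATGTAA" + "CCCC"
        assert find_altorfs(Transcript("t", seq, 12, 21), min_codons=2) == []
        assert len(find_altorfs(Transcript("t", seq, 12, 21), min_codons=1)) == 1


class TestMetageneAltorf:
    def _setup(self):
        utr = "CC" + "ATG" + "AAAGGGCCCTTTAAAGGG" + "TAA" + "C" * 30
        seq = "G" * 30 + "ATG" + "GGG" * 5 + "TAA" + utr
        tx = Transcript("t", seq, 30, 51)
        model = TranscriptomeModel({"t": tx})
        orfs = find_altorfs(tx)
        start = 51 + 2
        assert orfs[0].start == start
        return model, orfs, start

    def test_frame_fractions_sum_to_one(self):
        model, orfs, start = self._setup()
        alns = [
            _aln("t", start - 12 + k, start - 12 + k + 27, read_id=f"r{k}")
            for k in range(0, 18)
        ]
        _, frames = metagene_altorf(alns, orfs, model)
        assert sum(frames.values()) == pytest.approx(1.0)

    def test_uniform_reads_give_equal_frames(self):
        model, orfs, start = self._setup()
        alns = [
            _aln("t", start - 12 + k, start - 12 + k + 27, read_id=f"r{k}")
            for k in range(0, 21)
        ]
        _, frames = metagene_altorf(alns, orfs, model)
        assert frames[0] == pytest.approx(1 / 3)
        assert frames[1] == pytest.approx(1 / 3)

    def test_pure_frame_zero_placement(self):
        model, orfs, start = self._setup()
        alns = [
            _aln("t", start - 12 + k, start - 12 + k + 27, read_id=f"r{k}")
            for k in range(0, 21, 3)
        ]
        _, frames = metagene_altorf(alns, orfs, model)
        assert frames[0] == 1.0


class TestMotifAnchored:
    def test_no_motif_in_region_is_error(self):
        seq = "G" * 30 + "ATG" + "GGG" * 8 + "TAA" + "C" * 30
        tx = Transcript("t", seq, 30, 60)
        model = TranscriptomeModel({"t": tx})
        with pytest.raises(ValueError):
            motif_anchored_average([], model, motif="UU", region=Region.CDS)

    def test_three_prime_ends_pile_at_offset_zero(self):
        # CDS with a single UU away from edges; 16-mers end on the second U
        inner = "GGA" * 20 + "TT" + "GCA" * 20
        seq = "G" * 40 + "ATG" + inner + "TAA" + "C" * 40
        tx = Transcript("t", seq, 40, 40 + 3 + len(inner) + 3)
        model = TranscriptomeModel({"t": tx})
        uu_second = seq.index("TT", 40) + 1
        alns = [
            _aln("t", uu_second - 15, uu_second + 1, read_len=16, read_id=f"r{i}")
            for i in range(20)
        ] + [
            _aln("t", uu_second - 5, uu_second + 11, read_len=16, read_id=f"x{i}")
            for i in range(4)
        ]
        profile = motif_anchored_average(alns, model, motif="UU")
        peak = profile.offsets[int(np.nanargmax(profile.value))]
        assert peak == 0


class TestThreePrimeDinucleotide:
    def test_single_read_ending_in_uu(self):
        seq = "G" * 30 + "ATG" + "GGGAAATT" + "G" + "TAA" + "C" * 30
        tx = Transcript("t", seq, 30, 45)
        model = TranscriptomeModel({"t": tx})
        end = seq.index("TT", 30) + 2
        out = three_prime_dinucleotide(
            [_aln("t", end - 16, end, read_len=16)], model
        )
        assert out["UU"] == 1.0
        assert sum(out.values()) == pytest.approx(1.0)

    def test_wrong_class_is_error(self, tiny_model):
        with pytest.raises(ValueError):
            three_prime_dinucleotide(
                [_aln("tx1", 10, 38, read_len=28)], tiny_model
            )


class TestPolyATailReads:
    def test_run_length_bounds(self):
        reads = [
            "CCGT" + "A" * 8,   # counted (8)
            "CCGT" + "A" * 7,   # below minimum
            "CCGT" + "A" * 18,  # counted (18)
            "CCGT" + "A" * 19,  # above maximum under closed bounds
            "CCAGCTAG",         # no run
        ]
        out = count_polyA_tail_reads(reads)
        assert out["n_polyA"] == 2
        assert out["n_unmapped"] == 5
        assert out["percent"] == pytest.approx(40.0)

    def test_open_ended_upper_bound(self):
        out = count_polyA_tail_reads(["CCGT" + "A" * 25], open_ended=True)
        assert out["n_polyA"] == 1

    def test_percent_arithmetic(self):
        reads = ["C" + "A" * 10] * 5 + ["CGCGCGCG"] * 95
        assert count_polyA_tail_reads(reads)["percent"] == pytest.approx(5.0)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            count_polyA_tail_reads([])


class TestSpikeIns:
    def test_equal_counts_give_unit_ratio(self):
        seqs = []
        for _, rna in SPIKE_INS:
            seqs += [to_dna(rna)] * 500 + [to_dna(rna)[1:]] * 500
        out = spike_in_ratio(seqs)
        assert out["ratio_18_to_30"] == pytest.approx(1.0)
        assert all(v == 1000 for v in out["per_spike"].values())

    def test_trim_offset_match_but_not_mismatch(self):
        full = to_dna(SPIKE_INS[0][1])
        out = spike_in_ratio([full, full[1:], full[:-1] + "N"])
        assert out["per_spike"]["18-mer-1"] == 2

    def test_missing_30mers_flagged(self):
        out = spike_in_ratio([to_dna(SPIKE_INS[0][1])])
        assert out["ratio_18_to_30"] is None


class TestActivationContrast:
    def test_cleavage_heavy_sample_shifts_all_stalling_readouts_up(self):
        """A cleavage-heavy condition (RNase L activated, fragments
        stabilized) shows a higher 16/28 ratio, a higher pooled 3'UTR:CDS
        ratio, and a higher poly(A)-read percentage than a near-quiescent
        one — the sign-level expectation for an activated sample."""
        from fragribo import SimConfig, generate_transcriptome, \
            simulate_cleavage, simulate_footprints
        import numpy as np

        def readouts(cleave, mix, seed):
            from conftest import alignments_from_sim
            cfg = SimConfig(seed=seed, n_reads=15_000, cleave_prob=cleave,
                            footprint_mix=mix)
            model = generate_transcriptome(cfg)
            rng = np.random.default_rng(seed)
            mols = simulate_cleavage(model, cfg, rng)
            sim = simulate_footprints(mols, model, cfg, rng)
            alns = alignments_from_sim(sim)
            ratio = short_long_ratio(class_counts(alns))
            _, pooled = utr_cds_ratios(region_counts(alns, model))
            trimmed, _ = preprocess_reads([(r, s) for r, s, _ in sim.reads])
            unmapped = set(sim.truth.loc[~sim.truth.mapped, "read_id"])
            seqs = [s for r, s in trimmed if r in unmapped]
            percent = count_polyA_tail_reads(seqs)["percent"]
            return ratio, pooled, percent

        activated = readouts(
            0.9, {"long28": 0.62, "mid21": 0.05, "short16": 0.25,
                  "polyA_tail": 0.03, "spike_in": 0.05}, 203)
        control = readouts(
            0.1, {"long28": 0.85, "mid21": 0.08, "short16": 0.015,
                  "polyA_tail": 0.005, "spike_in": 0.05}, 204)
        assert all(a > c for a, c in zip(activated, control))


class TestLengthDistribution:
    def test_point_mass_at_28(self, tiny_model):
        alns = [_aln("tx1", 10, 37, read_len=28, read_id=f"r{i}") for i in range(7)]
        frac = footprint_length_distribution(alns)
        assert frac.loc[28] == 1.0
        assert frac.sum() == pytest.approx(1.0)

    def test_counts_partition_into_classes(self, tiny_model):
        alns = [
            _aln("tx1", 10, 10 + n - 2, read_len=n, read_id=f"r{n}")
            for n in range(15, 35)
        ]
        counts = class_counts(alns)
        assert sum(counts.values()) == len(alns)
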