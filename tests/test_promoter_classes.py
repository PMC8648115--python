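"""Motif scanning, oriented sequences and promoter-type classification."""

import itertools
import re

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from promoterscope.cage_tss import PromoterRecord
from promoterscope.errors import BoundaryError, InputError, ParameterError
from promoterscope.promoter_classes import (
    ELEMENTS,
    IUPAC,
    MotifDefinition,
    classify_promoter,
    classify_set,
    load_motif_config,
    scan_consensus,
    scan_pwm,
)
from promoterscope.sequences import PromoterSequence, oriented_promoter_sequence
from promoterscope.synthetic import make_promoter_genome


# ------------------------------------------------------------- config I/O

def write_config(tmp_path, entries):
    path = tmp_path / "motifs.yaml"
    path.write_text(yaml.safe_dump({"motifs": entries}))
    return path


class TestMotifConfig:
    def test_round_trip(self, tmp_path):
        path = write_config(
            tmp_path,
            [{"name": "TATA", "mode": "consensus", "model": "STATAWAAR",
              "window_start": -33, "window_end": -20}],
        )
        (motif,) = load_motif_config(path)
        assert motif.name == "TATA"
        assert (motif.window_start, motif.window_end) == (-33, -20)

    def test_dpe_variants_are_aliases_of_one_element(self, tmp_path):
        path = write_config(
            tmp_path,
            [
                {"name": "DPE_O", "model": "KCGGTTSK",
                 "window_start": 23, "window_end": 28},
                {"name": "DPE_K", "model": "RGWYVT",
                 "window_start": 26, "window_end": 29},
            ],
        )
        motifs = load_motif_config(path)
        assert [m.element for m in motifs] == ["DPE", "DPE"]

    def test_missing_window_rejected(self, tmp_path):
        path = write_config(
            tmp_path, [{"name": "TATA", "model": "TATAAA", "window_start": -33}]
        )
        with pytest.raises(InputError, match="window_end"):
            load_motif_config(path)

    def test_placeholder_refuses_to_load(self, tmp_path):
        path = write_config(
            tmp_path,
            [{"name": "TATA", "model": "NNNN", "window_start": -33,
              "window_end": -20, "source": "placeholder"}],
        )
        with pytest.raises(InputError, match="placeholder"):
            load_motif_config(path)

    def test_unknown_iupac_letter_rejected(self, tmp_path):
        path = write_config(
            tmp_path,
            [{"name": "X", "model": "TAXA", "window_start": 0, "window_end": 1}],
        )
        with pytest.raises(InputError, match="IUPAC"):
            load_motif_config(path)


# ---------------------------------------------------- oriented sequences

class TestOrientedSequence:
    genome = {"c": "GGACGTAGG"}

    def test_plus_strand_window(self):
        seq = oriented_promoter_sequence(self.genome, "c", 4, "+", 2, 2)
        assert seq.seq == "ACGTA"
        assert seq.base_at(0) == "G"
        assert seq.base_at(-2) == "A"

    def test_minus_strand_is_reverse_complement(self):
        plus = oriented_promoter_sequence(self.genome, "c", 4, "+", 2, 2)
        minus = oriented_promoter_sequence(self.genome, "c", 4, "-", 2, 2)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert minus.seq == "".join(comp[b] for b in plus.seq[::-1])
        assert minus.base_at(0) == comp[plus.base_at(0)]

    def test_involution_under_genome_reverse_complement(self):
        rng = np.random.default_rng(3)
        chrom = "".join(rng.choice(list("ACGT"), size=200))
        comp = str.maketrans("ACGT", "TGCA")
        rc = chrom.translate(comp)[::-1]
        for strand, flipped in (("+", "-"), ("-", "+")):
            a = oriented_promoter_sequence({"c": chrom}, "c", 100, strand, 30, 20)
            b = oriented_promoter_sequence(
                {"c": rc}, "c", len(chrom) - 1 - 100, flipped, 30, 20
            )
            assert a.seq == b.seq

    def test_off_contig_raises_not_pads(self):
        with pytest.raises(BoundaryError):
            oriented_promoter_sequence(self.genome, "c", 1, "+", 5, 0)
        with pytest.raises(BoundaryError):
            oriented_promoter_sequence(self.genome, "c", 8, "+", 0, 5)


# ----------------------------------------------------------- consensus scan

def iupac_regex(pattern):
    return re.compile("".join(f"[{IUPAC[c]}]" for c in pattern))


class TestConsensusScan:
    def test_planted_match_found_in_window(self):
        rng = np.random.default_rng(4)
        bases = list(rng.choice(list("ACGT"), size=101))
        bases[50 - 30 : 50 - 30 + 6] = "TATAAA"
        seq = PromoterSequence("".join(bases), 50, 50)
        motif = MotifDefinition("TATA", "consensus", "STATAWAAR"[1:7], -33, -25)
        hits = scan_consensus(seq, motif)
        assert any(h.offset == -30 for h in hits)

    def test_window_gating_excludes_outside_match(self):
        seq = PromoterSequence("TATAAA" + "G" * 45, 25, 25)  # match at -25
        motif = MotifDefinition("TATA", "consensus", "TATAAA", -10, 10)
        assert scan_consensus(seq, motif) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_regex_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq_str = "".join(rng.choice(list("ACGT"), size=1000))
        seq = PromoterSequence(seq_str, 500, 499)
        motif = MotifDefinition("DRE", "consensus", "WATCGATW", -400, 300)
        got = {h.offset for h in scan_consensus(seq, motif)}
        rx = iupac_regex("WATCGATW")
        expected = {
            off
            for off in range(-400, 301)
            if rx.match(seq_str, off + 500)
            and rx.match(seq_str, off + 500).start() == off + 500
        }
        assert got == expected

    def test_window_past_sequence_is_boundary_error(self):
        seq = PromoterSequence("ACGTACGTA", 4, 4)
        motif = MotifDefinition("X", "consensus", "ACG", -10, 0)
        with pytest.raises(BoundaryError):
            scan_consensus(seq, motif)


# ----------------------------------------------------------------- PWM scan

def one_hot(pattern):
    pwm = np.zeros((4, len(pattern)))
    for j, b in enumerate(pattern):
        pwm["ACGT".index(b), j] = 1.0
    return pwm


class TestPwmScan:
    def test_one_hot_pwm_at_full_score_matches_exact_occurrences(self):
        seq = PromoterSequence("TTACGTTTACGTT", 6, 6)
        motif = MotifDefinition(
            "M", "pwm", one_hot("ACGT"), -6, 3, min_score_fraction=1.0
        )
        offsets = {h.offset for h in scan_pwm(seq, motif)}
        assert offsets == {-4, 2}  # ACGT at string indices 2 and 8

    def test_zero_fraction_hits_every_offset(self):
        seq = PromoterSequence("TTACGTTTACGTT", 6, 6)
        motif = MotifDefinition("M", "pwm", one_hot("ACGT"), -3, 3)
        motif.min_score_fraction = 0.0
        assert len(scan_pwm(seq, motif)) == 7

    @pytest.mark.parametrize("seed", range(3))
    def test_scores_match_independent_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        pwm = rng.dirichlet(np.ones(4), size=5).T
        seq_str = "".join(rng.choice(list("ACGT"), size=60))
        seq = PromoterSequence(seq_str, 30, 29)
        motif = MotifDefinition(
            "M", "pwm", pwm, -20, 20, min_score_fraction=0.01
        )
        hits = {h.offset: h.score for h in scan_pwm(seq, motif)}
        for off, score in hits.items():
            window = seq_str[off + 30 : off + 35]
            expected = sum(
                np.log2((pwm["ACGT".index(b), j] + 1e-3) / 0.25)
                for j, b in enumerate(window)
            )
            assert score == pytest.approx(expected)

    def test_zero_background_rejected(self):
        seq = PromoterSequence("ACGTA", 2, 2)
        motif = MotifDefinition("M", "pwm", one_hot("AC"), -1, 1)
        with pytest.raises(ParameterError):
            scan_pwm(seq, motif, background=(0.5, 0.5, 0.0, 0.0))

    def test_bad_pwm_rejected(self):
        with pytest.raises(InputError, match="sum to 1"):
            MotifDefinition("M", "pwm", np.ones((4, 3)), 0, 1)


# ------------------------------------------------------------ classification

def oracle_classify(flags):
    """Independent restatement of the inclusion/exclusion rule table."""
    tata, dpe, mte, pb, tct, dre, o1, o6, o7 = (
        flags[e] for e in ELEMENTS
    )
    labels = set()
    if tata:
        labels.add("TATA")
    if tct:
        labels.add("TCT")
    forbidden_for_dpe = tata or tct or o1 or o6 or o7 or dre
    if (dpe or mte or pb) and not forbidden_for_dpe:
        labels.add("DPE")
    forbidden_for_hk = tata or tct or mte or dpe or pb
    if (dre or o1 or o6 or o7) and not forbidden_for_hk:
        labels.add("HK")
    return labels


class TestClassifyPromoter:
    def test_exhaustive_truth_table_against_oracle(self):
        for bits in itertools.product([False, True], repeat=9):
            flags = dict(zip(ELEMENTS, bits))
            assert classify_promoter(flags) == oracle_classify(flags), flags

    def test_tata_beats_dpe(self):
        flags = {e: e in ("TATA", "DPE") for e in ELEMENTS}
        assert classify_promoter(flags) == {"TATA"}

    def test_hk_rules(self):
        only_dre = {e: e == "DRE" for e in ELEMENTS}
        assert classify_promoter(only_dre) == {"HK"}
        tct_dre = {e: e in ("TCT", "DRE") for e in ELEMENTS}
        assert classify_promoter(tct_dre) == {"TCT"}

    def test_extremes(self):
        assert classify_promoter({e: False for e in ELEMENTS}) == frozenset()
        assert classify_promoter({e: True for e in ELEMENTS}) == {"TATA", "TCT"}

    def test_dpe_and_hk_mutually_exclusive(self):
        for bits in itertools.product([False, True], repeat=9):
            labels = classify_promoter(dict(zip(ELEMENTS, bits)))
            assert not {"DPE", "HK"} <= labels


class TestClassifySet:
    def test_planted_classes_recovered(self, small_dataset, motifs):
        genome, truth, _, _ = small_dataset
        results, counts = classify_set(
            truth.promoter_records(), genome, motifs
        )
        expected = {r.gene_id: r.label for r in truth.records}
        for res in results:
            assert res.labels == {expected[res.gene_id]}
        for label in ("TATA", "DPE", "TCT", "HK"):
            assert counts[label] == 10
        assert counts["unclassified"] == 0

    def test_empty_set(self, motifs):
        results, counts = classify_set([], {"c": "ACGT" * 100}, motifs)
        assert results == []
        assert all(counts[k] == 0 for k in ("TATA", "DPE", "TCT", "HK"))

    def test_order_invariance(self, small_dataset, motifs):
        genome, truth, _, _ = small_dataset
        promoters = truth.promoter_records()
        _, counts_fwd = classify_set(promoters, genome, motifs)
        _, counts_rev = classify_set(promoters[::-1], genome, motifs)
        assert counts_fwd == counts_rev

    def test_out_of_bounds_promoters_dropped_and_counted(self, motifs):
        genome = {"c": "ACGT" * 200}
        promoters = [PromoterRecord("edge", "c", "+", 2, 10.0)]
        results, counts = classify_set(promoters, genome, motifs)
        assert results == [] and counts["dropped"] == 1

    def test_strand_flip_reproduces_labels(self, motifs):
        genome, truth, genes = make_promoter_genome(4, seed=55)
        from promoterscope.synthetic import reverse_complement_dataset

        rc_genome, rc_truth, _ = reverse_complement_dataset(genome, truth, genes)
        _, counts = classify_set(truth.promoter_records(), genome, motifs)
        _, rc_counts = classify_set(
            rc_truth.promoter_records(), rc_genome, motifs
        )
        assert counts == rc_counts

    def test_planted_tata_removes_dpe_label(self, motifs, small_dataset):
        genome, truth, _, _ = small_dataset
        dpe_rec = next(r for r in truth.records if r.label == "DPE")
        tata = next(m for m in motifs if m.name == "TATA")
        offset = (tata.window_start + tata.window_end) // 2
        chrom = list(genome[dpe_rec.chrom])
        instance = "CTATAAAAG"  # concrete TATA-box consensus match
        if dpe_rec.strand == "+":
            start = dpe_rec.tss + offset
            chrom[start : start + len(instance)] = instance
        else:
            comp = str.maketrans("ACGT", "TGCA")
            rc = instance.translate(comp)[::-1]
            start = dpe_rec.tss - offset - len(instance) + 1
            chrom[start : start + len(rc)] = rc
        mutated = {dpe_rec.chrom: "".join(chrom)}
        (result,), _ = classify_set(
            [PromoterRecord(dpe_rec.gene_id, dpe_rec.chrom, dpe_rec.strand,
                            dpe_rec.tss, dpe_rec.expression)],
            mutated,
            motifs,
        )
        assert "DPE" not in result.labels
        assert "TATA" in result.labels
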