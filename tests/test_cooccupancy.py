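"""PFM parsing, scanning, anchored windows, and over-representation stats."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import hypergeom

from anchortf.cooccupancy import (
    anchored_enrichment,
    anchored_hit_count,
    anchored_windows,
    categorize_tfs,
    dinucleotide_shuffle,
    enrichment_z,
    fisher_enrichment,
    make_promoters,
)
from anchortf.motifs import (
    MotifHit,
    PFMModel,
    information_content,
    pfm_from_consensus,
    read_jaspar,
    reverse_complement,
    scan_sequence,
)
from conftest import random_pfm, random_seq

JASPAR_SAMPLE = """\
>MA0001.1 TESTA
A  [ 10  0  0  0 ]
C  [ 0  10  0  0 ]
G  [ 0  0  10  0 ]
T  [ 0  0  0  10 ]
>MA0002.1 TESTB
C  [ 1 2 3 4 5 ]
A  [ 5 4 3 2 1 ]
T  [ 0 1 0 1 0 ]
G  [ 2 2 2 2 2 ]
"""


class TestReadJaspar:
    def test_onehot_record(self):
        models = read_jaspar(JASPAR_SAMPLE)
        assert len(models) == 2
        assert models[0].width == 4 and models[0].consensus == "ACGT"

    def test_row_order_normalized(self):
        m = read_jaspar(JASPAR_SAMPLE)[1]
        np.testing.assert_array_equal(m.counts[0], [5, 4, 3, 2, 1])  # A row
        np.testing.assert_array_equal(m.counts[2], [2, 2, 2, 2, 2])  # G row

    def test_matches_biopython_parser(self, tmp_path):
        from Bio import motifs as bio_motifs

        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_SAMPLE)
        with open(path) as fh:
            bio = bio_motifs.parse(fh, "jaspar")
        ours = read_jaspar(path)
        for b, o in zip(bio, ours):
            for i, base in enumerate("ACGT"):
                assert list(b.counts[base]) == list(o.counts[i])

    def test_ragged_rows_error_names_record(self):
        bad = ">M1 X\nA [1 2 3]\nC [1 2]\nG [1 2 3]\nT [1 2 3]\n"
        with pytest.raises(ValueError, match="ragged"):
            read_jaspar(bad)

    def test_negative_count_error_names_line(self):
        bad = ">M1 X\nA [1 2 3]\nC [1 -2 1]\nG [1 2 3]\nT [1 2 3]\n"
        with pytest.raises(ValueError, match="line 3"):
            read_jaspar(bad)


class TestInformationContent:
    def test_uniform_zero_bits(self):
        m = PFMModel("U", np.full((4, 5), 3.0), pseudocount=0.0)
        assert information_content(m) == pytest.approx(0.0)

    def test_onehot_no_pseudocount_eight_bits(self, onehot_pfm):
        m = PFMModel("O", onehot_pfm.counts, pseudocount=0.0)
        assert information_content(m) == pytest.approx(8.0)

    def test_single_column_with_pseudocount(self):
        m = PFMModel("S", np.array([[8.0], [0], [0], [0]]), pseudocount=0.25)
        assert information_content(m) == pytest.approx(1.454, abs=1e-3)


def brute_scan(seq, pfm, rel_threshold):
    """Per-window rescoring oracle, independent of the vectorized scanner."""
    lo = pfm.log_odds()
    w = pfm.width
    s_min = sum(min(lo[:, j]) for j in range(w))
    s_max = sum(max(lo[:, j]) for j in range(w))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand in "+-":
        for start in range(len(seq) - w + 1):
            window = seq[start:start + w]
            if strand == "-":
                window = reverse_complement(window)
            if any(b not in idx for b in window):
                continue
            score = sum(lo[idx[b], j] for j, b in enumerate(window))
            rel = (score - s_min) / (s_max - s_min)
            if rel >= rel_threshold:
                hits.append((start, strand, round(score, 9), round(rel, 9)))
    return sorted(hits)


class TestScanSequence:
    def test_consensus_hits_plus_strand_full_score(self):
        pfm = pfm_from_consensus("P", "TGACGTCAT")
        seq = "AATT" + "TGACGTCAT" + "CCGG"
        hits = scan_sequence(seq, pfm, 0.95)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1 and plus[0].start == 4
        assert plus[0].rel_score == pytest.approx(1.0)

    def test_reverse_complement_hits_minus_strand(self):
        pfm = pfm_from_consensus("P", "TGACGTCCT")
        seq = "AATT" + reverse_complement("TGACGTCCT") + "CCGG"
        hits = scan_sequence(seq, pfm, 0.95)
        assert len(hits) == 1 and hits[0].strand == "-" and hits[0].start == 4
        assert hits[0].rel_score == pytest.approx(1.0)

    def test_short_sequence_empty(self, onehot_pfm):
        assert scan_sequence("AC", onehot_pfm) == []

    def test_n_windows_skipped(self):
        pfm = pfm_from_consensus("P", "ACGTA")
        hits = scan_sequence("ACNTA" + "ACGTA", pfm, 0.5)
        assert all(h.start >= 3 for h in hits)

    @pytest.mark.parametrize("threshold", [0.7, 0.9])
    def test_matches_bruteforce_rescoring(self, rng, threshold):
        for i in range(5):
            pfm = random_pfm(rng, width=int(rng.integers(4, 10)), name=f"M{i}")
            seq = random_seq(rng, 300, alphabet="ACGTN")
            got = sorted(
                (h.start, h.strand, round(h.score, 9), round(h.rel_score, 9))
                for h in scan_sequence(seq, pfm, threshold)
            )
            assert got == brute_scan(seq, pfm, threshold)

    def test_strand_invariance_of_hit_count(self, rng):
        pfm = random_pfm(rng, width=6)
        seq = random_seq(rng, 400)
        n_fwd = len(scan_sequence(seq, pfm, 0.8))
        n_rc = len(scan_sequence(reverse_complement(seq), pfm, 0.8))
        assert n_fwd == n_rc

    def test_conservation_mask_restricts_hits(self):
        pfm = pfm_from_consensus("P", "ACGTAC")
        seq = "ACGTAC" * 3
        mask = np.zeros(len(seq), dtype=bool)
        mask[6:] = True  # first occurrence masked out
        hits = scan_sequence(seq, pfm, 0.99, mask=mask)
        assert all(h.start >= 6 for h in hits)


def hit(seq_id, start, width=9):
    return MotifHit(seq_id=seq_id, start=start, strand="+", score=1.0,
                    rel_score=1.0, width=width)


class TestAnchoredWindows:
    def test_single_anchor_flanks(self):
        ws = anchored_windows([hit("s", 100, width=10)], D=100, seq_lengths={"s": 500})
        assert ws.windows["s"] == [(0, 100), (110, 210)]
        assert ws.searchable_nt == 200

    def test_overlapping_flanks_counted_once(self, rng):
        anchors = [hit("s", 100, 10), hit("s", 150, 10)]
        ws = anchored_windows(anchors, D=100, seq_lengths={"s": 1000})
        covered = set()
        for fs, fe in ((100, 110), (150, 160)):
            for p in range(max(0, fs - 100), min(1000, fe + 100)):
                covered.add(p)
        for fs, fe in ((100, 110), (150, 160)):
            covered -= set(range(fs, fe))
        assert ws.searchable_nt == len(covered)
        got = {p for s, e in ws.windows["s"] for p in range(s, e)}
        assert got == covered

    def test_anchor_at_start_clipped(self):
        ws = anchored_windows([hit("s", 0, 10)], D=100, seq_lengths={"s": 500})
        assert ws.windows["s"] == [(10, 110)]

    def test_no_anchors_flagged(self):
        with pytest.warns(UserWarning, match="no anchor"):
            ws = anchored_windows([], D=100, seq_lengths={})
        assert ws.anchor_absent and ws.searchable_nt == 0


class TestAnchoredHitCount:
    def test_membership_cases(self):
        ws = anchored_windows([hit("s", 100, 10)], D=100, seq_lengths={"s": 500})
        inside = hit("s", 150, 9)
        outside = hit("s", 300, 9)
        in_footprint = hit("s", 104, 9)
        assert anchored_hit_count([inside], ws) == 1
        assert anchored_hit_count([outside], ws) == 0
        assert anchored_hit_count([in_footprint], ws) == 0

    def test_random_placement_matches_bruteforce(self, rng):
        ws = anchored_windows(
            [hit("s", int(p), 9) for p in rng.integers(0, 900, 5)],
            D=60, seq_lengths={"s": 1000},
        )
        partners = [hit("s", int(p), 7) for p in rng.integers(0, 990, 200)]
        brute = 0
        feet = ws.footprints["s"]
        for h in partners:
            in_win = any(s <= h.start < e for s, e in ws.windows["s"])
            touches_foot = any(h.start < fe and h.start + 7 > fs for fs, fe in feet)
            brute += in_win and not touches_foot
        assert anchored_hit_count(partners, ws) == brute


class TestEnrichmentZ:
    def test_equal_rates_zero(self):
        assert enrichment_z(10, 1000, 100, 10_000) == pytest.approx(0.0)

    def test_candidate_bar_scale_example(self):
        # u = 0.01, fg_nt = 10_000, fg_hits = 200 -> z = 100 / sqrt(99)
        z = enrichment_z(200, 10_000, 100, 10_000)
        assert z == pytest.approx(100 / math.sqrt(99))
        assert z >= 10.0  # crosses the Z >= 10 candidate bar

    def test_doubling_scales_by_sqrt2(self):
        z1 = enrichment_z(200, 10_000, 100, 10_000)
        z2 = enrichment_z(400, 20_000, 100, 10_000)
        assert z2 == pytest.approx(z1 * math.sqrt(2))

    def test_zero_background_sentinels(self):
        with pytest.warns(UserWarning, match="inf"):
            assert enrichment_z(5, 100, 0, 1000) == math.inf
        assert enrichment_z(0, 100, 0, 1000) == 0.0


class TestFisher:
    def test_diagonal_table_exact(self):
        assert fisher_enrichment(10, 0, 0, 10) == pytest.approx(
            1 / math.comb(20, 10)
        )

    def test_balanced_table_matches_tail_sum(self):
        p = fisher_enrichment(5, 5, 5, 5)
        expect = float(hypergeom.sf(4, 20, 10, 10))
        assert p == pytest.approx(expect)

    def test_empty_foreground_p_one(self):
        assert fisher_enrichment(0, 0, 0, 0) == 1.0
        assert fisher_enrichment(0, 5, 3, 2) == pytest.approx(
            float(hypergeom.sf(-1, 10, 3, 5))
        )


class TestCategorize:
    def r(self, tf, z):
        from anchortf.cooccupancy import EnrichmentResult

        return EnrichmentResult(tf, 1, 100, 1, 100, z)

    @pytest.mark.parametrize(
        "zp,ze,expected",
        [
            (12.0, 15.0, "both"),
            (12.0, 3.0, "promoter_only"),
            (3.0, 12.0, "enhancer_only"),
            (9.9, 9.9, "none"),
            (10.0, 10.0, "both"),  # ties at the threshold count
        ],
    )
    def test_threshold_logic(self, zp, ze, expected):
        cats = categorize_tfs([self.r("TF", zp)], [self.r("TF", ze)], 10.0)
        assert cats["TF"] == expected

    def test_missing_compartment_flagged(self):
        with pytest.warns(UserWarning, match="missing"):
            cats = categorize_tfs([self.r("TF", 12.0)], [], 10.0)
        assert cats["TF"] == "promoter_only"


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 200)
            shuf = dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_seeded_determinism(self):
        seq = "ACGTACGGTTACGATCGATCGGGATC" * 4
        a = dinucleotide_shuffle(seq, np.random.default_rng(7))
        b = dinucleotide_shuffle(seq, np.random.default_rng(7))
        assert a == b


class TestMakePromoters:
    def genome(self):
        rng = np.random.default_rng(1)
        return {"chr1": random_seq(rng, 20_000)}

    def table(self, tss, strand):
        import pandas as pd

        return pd.DataFrame(
            [{"id": "g", "chrom": "chr1", "tss": tss, "strand": strand}]
        )

    def test_plus_strand_window(self):
        out = make_promoters(self.table(10_000, "+"), 1500, 300, self.genome())
        assert (out["g"]["start"], out["g"]["end"]) == (8500, 10_300)

    def test_minus_strand_mirrored_and_revcomped(self):
        genome = self.genome()
        out = make_promoters(self.table(10_000, "-"), 1500, 300, genome)
        assert (out["g"]["start"], out["g"]["end"]) == (9700, 11_500)
        assert out["g"]["seq"] == reverse_complement(genome["chr1"][9700:11_500])

    def test_clipped_at_contig_start(self):
        out = make_promoters(self.table(100, "+"), 1500, 300, self.genome())
        assert out["g"]["start"] == 0

    def test_missing_contig_skipped(self):
        import pandas as pd

        table = pd.DataFrame(
            [{"id": "g", "chrom": "chrX", "tss": 100, "strand": "+"}]
        )
        with pytest.warns(UserWarning, match="absent"):
            assert make_promoters(table, 1500, 300, self.genome()) == {}


class TestAnchoredEnrichmentEndToEnd:
    def test_strand_invariance(self, rng):
        """Reverse-complementing every sequence leaves fg counts and z
        unchanged (windows mirror, scanning is double-stranded)."""
        anchor = pfm_from_consensus("ANC", "GGGGCGGGG")
        partner = pfm_from_consensus("PAR", "TGACCTTGA")
        seqs = {}
        for i in range(10):
            s = list(random_seq(rng, 400))
            s[100:109] = "GGGGCGGGG"
            s[150:159] = "TGACCTTGA"
            seqs[f"s{i}"] = "".join(s)
        fwd = anchored_enrichment(seqs, anchor, [partner], background="outside")
        rc = anchored_enrichment(
            {k: reverse_complement(v) for k, v in seqs.items()},
            anchor, [partner], background="outside",
        )
        assert fwd[0].fg_hits == rc[0].fg_hits
        assert fwd[0].bg_hits == rc[0].bg_hits
        assert fwd[0].z == pytest.approx(rc[0].z)

    def test_low_ic_partner_excluded(self, rng):
        anchor = pfm_from_consensus("ANC", "GGGGCGGGG")
        weak = PFMModel("WEAK", np.full((4, 6), 5.0))  # ~0 bits
        seqs = {"s": random_seq(rng, 300)}
        with pytest.warns(UserWarning, match="specificity"):
            res = anchored_enrichment(seqs, anchor, [weak], background="outside")
        assert res == []
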