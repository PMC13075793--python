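import itertools

import numpy as np
import pytest

from nucphase.io_formats import GenomeSequence, reverse_complement
from nucphase.promoter_motifs import (
    MotifHit,
    PromoterSeq,
    Pwm,
    extract_promoters,
    gc_content,
    positional_histogram,
    pwm_score_pvalue,
    scan_pwm,
    tata_fraction,
)
from nucphase.synthetic import simulate_tata_promoters

GC60_BG = np.array([0.2, 0.3, 0.3, 0.2])


class TestExtractPromoters:
    @pytest.fixture
    def genome(self, rng):
        return GenomeSequence({
            "chrI": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])})

    def test_plus_anchor_takes_upstream_forward(self, genome):
        (p,) = extract_promoters([("chrI", 600, "+")], genome)
        assert (p.genomic_start, p.genomic_end) == (100, 600)
        assert p.seq == genome.fetch("chrI", 100, 600)

    def test_minus_anchor_takes_downstream_revcomp(self, genome):
        (p,) = extract_promoters([("chrI", 600, "-")], genome)
        assert (p.genomic_start, p.genomic_end) == (601, 1101)
        assert p.seq == reverse_complement(genome.fetch("chrI", 601, 1101))

    def test_clipping_at_chromosome_start(self, genome):
        (p,) = extract_promoters([("chrI", 100, "+")], genome)
        assert (p.genomic_start, p.genomic_end) == (0, 100)

    def test_zero_base_anchor_skipped_with_warning(self, genome):
        with pytest.warns(UserWarning):
            assert extract_promoters([("chrI", 0, "+")], genome) == []

    def test_hit_offsets_round_trip_to_genomic_coordinates(self, genome):
        (p,) = extract_promoters([("chrI", 600, "-")], genome)
        offset = 123
        window = p.seq[offset:offset + 8]
        # promoter index i on a minus anchor maps to genomic end-1-i
        gstart = p.genomic_end - 1 - (offset + 7)
        assert reverse_complement(genome.fetch("chrI", gstart, gstart + 8)) == window


class TestGcContent:
    def test_extremes(self):
        per, mean = gc_content(["GGCC", "ATAT"])
        assert per == [100.0, 0.0] and mean == 50.0

    def test_reverse_complement_invariance(self, rng):
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
                for _ in range(20)]
        a, _ = gc_content(seqs)
        b, _ = gc_content([reverse_complement(s) for s in seqs])
        assert a == b

    def test_all_n_gives_nan(self):
        per, _ = gc_content(["NNNN"])
        assert np.isnan(per[0])


class TestPwm:
    def test_column_sums_validated(self):
        with pytest.raises(ValueError):
            Pwm(np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_single_column_top_score_p(self):
        pwm = Pwm(np.array([[1 - 3e-7, 1e-7, 1e-7, 1e-7]]))
        assert pwm.score_pvalue(float(pwm.log_odds().max())) == pytest.approx(0.25)

    def test_minimum_score_p_is_one(self):
        pwm = Pwm.from_consensus("TATA")
        assert pwm.score_pvalue(float(pwm.log_odds().min(axis=1).sum())) == 1.0

    @pytest.mark.parametrize("width", [2, 4, 5, 6])
    def test_dp_matches_exhaustive_enumeration(self, width, rng):
        counts = rng.gamma(1.0, 1.0, (width, 4)) * 10
        pwm = Pwm.from_counts(counts, background=np.array([0.3, 0.2, 0.3, 0.2]))
        lod = pwm.log_odds()
        bg = pwm.background
        kmers = list(itertools.product(range(4), repeat=width))
        scores = np.array([sum(lod[i, b] for i, b in enumerate(k)) for k in kmers])
        probs = np.array([np.prod([bg[b] for b in k]) for k in kmers])
        queries = rng.choice(scores, size=min(25, len(scores)), replace=False)
        for s in queries:
            p_exact = probs[scores >= s - 1e-12].sum()
            assert pwm_score_pvalue(pwm, float(s), bin_width=1e-5) == pytest.approx(
                p_exact, abs=1e-6)

    def test_jaspar_pfm_reader(self, tmp_path):
        text = ">MX0001 test\nA [ 10  0 ]\nC [ 0 10 ]\nG [ 0  0 ]\nT [ 0  0 ]\n"
        p = tmp_path / "m.pfm"
        p.write_text(text)
        pwm = Pwm.from_jaspar_pfm(p)
        assert pwm.width == 2
        assert pwm.probs[0, 0] > 0.9 and pwm.probs[1, 1] > 0.9

    def test_meme_minimal_reader(self, tmp_path):
        text = (
            "MEME version 4\n\nALPHABET= ACGT\n\nMOTIF TATA\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 20\n"
            " 0.970 0.010 0.010 0.010\n 0.010 0.010 0.010 0.970\n"
        )
        p = tmp_path / "m.meme"
        p.write_text(text)
        pwm = Pwm.from_meme(p)
        assert pwm.width == 2 and pwm.probs[0, 0] == pytest.approx(0.97, abs=1e-6)


class TestScan:
    def test_planted_word_found_in_gc_rich_carrier(self, rng):
        carrier = "".join(
            np.array(list("ACGT"))[rng.choice(4, 500, p=[0.1, 0.4, 0.4, 0.1])])
        seq = carrier[:200] + "TATAAATA" + carrier[208:]
        pwm = Pwm.from_consensus("TATAWAWR")
        hits = scan_pwm([seq], pwm, 1e-4, background=GC60_BG)
        assert any(h.offset == 200 and h.strand == "+" for h in hits)

    def test_all_c_sequence_has_no_hits(self):
        pwm = Pwm.from_consensus("TATAWAWR")
        assert scan_pwm(["C" * 300], pwm, 1e-4, background=GC60_BG) == []

    def test_windows_with_n_skipped(self):
        pwm = Pwm.from_consensus("TATAWAWR")
        seq = "C" * 100 + "TATANATA" + "C" * 100
        assert scan_pwm([seq], pwm, 1e-2, background=GC60_BG) == []

    def test_reverse_complement_symmetry(self, rng):
        carrier = "".join(
            np.array(list("ACGT"))[rng.choice(4, 400, p=[0.15, 0.35, 0.35, 0.15])])
        seq = carrier[:150] + "TATATAAA" + carrier[158:]
        pwm = Pwm.from_consensus("TATAWAWR")
        fwd = scan_pwm([seq], pwm, 1e-4, background=GC60_BG)
        rev = scan_pwm([reverse_complement(seq)], pwm, 1e-4, background=GC60_BG)
        W = pwm.width
        mirrored = {(len(seq) - h.offset - W, "-" if h.strand == "+" else "+")
                    for h in rev}
        assert {(h.offset, h.strand) for h in fwd} == mirrored

    def test_hit_count_monotone_in_threshold(self, rng):
        seqs, _, _ = simulate_tata_promoters(50, 0.5, seed=8)
        pwm = Pwm.from_consensus("TATAWAWR")
        counts = [len(scan_pwm(seqs, pwm, t, background=GC60_BG))
                  for t in (1e-6, 1e-5, 1e-4, 1e-3)]
        assert counts == sorted(counts)


class TestTataFraction:
    def test_zero_promoters_rejected(self):
        with pytest.raises(ValueError):
            tata_fraction([], Pwm.from_consensus("TATAWAWR"))

    def test_all_planted_fixture_gives_one(self):
        seqs, _, _ = simulate_tata_promoters(60, 1.0, seed=2)
        proms = [PromoterSeq(("x", 0, "+"), "x", 0, 500, s) for s in seqs]
        frac, _ = tata_fraction(proms, Pwm.from_consensus("TATAWAWR"),
                                background=GC60_BG)
        assert frac == 1.0

    def test_fraction_recovers_planting_probability(self):
        seqs, flags, _ = simulate_tata_promoters(1000, 0.2, seed=6)
        proms = [PromoterSeq(("x", 0, "+"), "x", 0, 500, s) for s in seqs]
        frac, _ = tata_fraction(proms, Pwm.from_consensus("TATAWAWR"),
                                background=GC60_BG)
        ci = 1.96 * np.sqrt(0.2 * 0.8 / 1000)
        assert abs(frac - 0.2) <= ci


class TestPositionalHistogram:
    def test_single_hit_bin_assignment(self):
        prom = PromoterSeq(("x", 0, "+"), "x", 0, 500, "A" * 500)
        # W=8: center = offset + 4; offset 448 -> center 452 -> relative -48
        hit = MotifHit(0, 448, "+", 5.0, 1e-5)
        edges, counts = positional_histogram([hit], [prom], pwm_width=8)
        assert counts.sum() == 1
        assert edges[np.argmax(counts)] == -50

    def test_mass_conservation(self):
        seqs, _, _ = simulate_tata_promoters(300, 0.5, seed=12)
        proms = [PromoterSeq(("x", 0, "+"), "x", 0, 500, s) for s in seqs]
        pwm = Pwm.from_consensus("TATAWAWR")
        hits = scan_pwm(seqs, pwm, 1e-4, background=GC60_BG)
        _, counts = positional_histogram(hits, proms, pwm.width)
        in_range = [h for h in hits
                    if -500 <= h.offset + pwm.width // 2 - 500 <= -1]
        assert counts.sum() == len(in_range)

    def test_mode_at_planted_position(self):
        seqs, _, _ = simulate_tata_promoters(500, 0.4, seed=13)
        proms = [PromoterSeq(("x", 0, "+"), "x", 0, 500, s) for s in seqs]
        pwm = Pwm.from_consensus("TATAWAWR")
        hits = scan_pwm(seqs, pwm, 1e-4, background=GC60_BG)
        edges, counts = positional_histogram(hits, proms, pwm.width)
        assert edges[np.argmax(counts)] in (-35, -30)


class TestCompositionContrast:
    def test_promoters_less_gc_than_gene_bodies_on_simulation(self, sim):
        _cfg, genome, genes, truth = sim
        anchors = [(c, p, s) for c, p, s, _ in truth.as_tss]
        proms = extract_promoters(anchors, genome)
        _, prom_gc = gc_content([p.seq for p in proms])
        island_genes = {gid for *_, gid in truth.islands}
        bodies = [genome.fetch(g.chrom, g.start, g.end)
                  for g in genes if g.id not in island_genes]
        _, body_gc = gc_content(bodies)
        assert prom_gc < body_gc
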