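import numpy as np
import pytest

from nucphase import nucleosome as nuc
from nucphase.io_formats import FragmentSet, GeneModel, GenomeSequence, StrandedTrack


@pytest.fixture
def flat_genome():
    return GenomeSequence({"chrI": "A" * 1000})


class TestMidpointDensity:
    def test_single_fragment_peaks_at_midpoint(self, flat_genome):
        frags = FragmentSet([("chrI", 100, 250)])
        d = nuc.midpoint_density(frags, flat_genome, bandwidth=20)["chrI"]
        assert np.argmax(d) == 175

    def test_integral_conserves_fragment_count(self, flat_genome):
        frags = FragmentSet([("chrI", 300, 450), ("chrI", 500, 650)])
        d = nuc.midpoint_density(frags, flat_genome, bandwidth=20)["chrI"]
        assert d.sum() == pytest.approx(2.0, rel=1e-6)

    def test_two_separated_modes(self, flat_genome):
        frags = FragmentSet([("chrI", 50, 150), ("chrI", 350, 450)])
        d = nuc.midpoint_density(frags, flat_genome, bandwidth=20)["chrI"]
        assert abs(int(np.argmax(d[:250])) - 100) <= 1
        assert abs(int(np.argmax(d[250:])) + 250 - 400) <= 1

    def test_empty_set_warns_and_returns_zero(self, flat_genome, caplog):
        d = nuc.midpoint_density(FragmentSet([]), flat_genome)
        assert d["chrI"].sum() == 0.0


class TestCallDyads:
    def test_single_mode_single_call(self, flat_genome):
        frags = FragmentSet([("chrI", 400, 550)] * 5)
        d = nuc.midpoint_density(frags, flat_genome, bandwidth=10)
        calls = nuc.call_dyads(d)
        assert [(c, p) for c, p, _ in calls.records] == [("chrI", 475)]

    def test_exclusion_keeps_leftmost_of_equal_peaks(self):
        a = np.zeros(500)
        a[200] = a[300] = 5.0  # equal peaks 100 bp apart
        calls = nuc.call_dyads({"chrI": a}, min_separation=120)
        assert [p for _, p, _ in calls.records] == [200]

    def test_min_score_filters(self):
        a = np.zeros(500)
        a[100] = 1.0
        a[400] = 5.0
        calls = nuc.call_dyads({"chrI": a}, min_score=2.0)
        assert [p for _, p, _ in calls.records] == [400]

    def test_recovery_of_planted_dyads_on_wt_simulation(self, sim, wt_dyads):
        _cfg, genome, _genes, truth = sim
        pos = {c: wt_dyads.positions(c) for c in genome.seqs}
        hits = sum(np.abs(pos[c] - p).min() <= 10 for c, p in truth.dyads)
        assert hits / len(truth.dyads) >= 0.90
        assert (len(wt_dyads) - hits) / len(truth.dyads) <= 0.10


class TestMetaplot:
    def test_uniform_track_gives_flat_profile(self):
        track = {"chrI": np.full(2000, 3.0)}
        prof = nuc.metaplot(track, [("chrI", 1000, "+")], flank=100)
        assert np.allclose(prof.mean_profile(), 3.0)

    def test_minus_strand_rows_are_flipped(self):
        a = np.zeros(2000)
        a[1010] = 1.0  # 10 bp right of the anchor in genomic coordinates
        prof = nuc.metaplot({"chrI": a}, [("chrI", 1000, "-")], flank=100)
        assert prof.rel_positions[np.argmax(prof.mean_profile())] == -10

    def test_stranded_track_reads_anchor_strand(self):
        plus = {"chrI": np.zeros(2000)}
        minus = {"chrI": np.zeros(2000)}
        minus["chrI"][990] = 2.0
        track = StrandedTrack(plus=plus, minus=minus)
        prof = nuc.metaplot(track, [("chrI", 1000, "-")], flank=50)
        assert prof.rel_positions[np.argmax(prof.mean_profile())] == 10

    def test_linearity_in_the_track(self, rng):
        t1 = {"chrI": rng.random(3000)}
        t2 = {"chrI": rng.random(3000)}
        anchors = [("chrI", 500, "+"), ("chrI", 1500, "-"), ("chrI", 2500, "+")]
        combo = {"chrI": 2.0 * t1["chrI"] + 3.0 * t2["chrI"]}
        p = nuc.metaplot(combo, anchors, 200).values
        p12 = (2.0 * nuc.metaplot(t1, anchors, 200).values
               + 3.0 * nuc.metaplot(t2, anchors, 200).values)
        assert np.allclose(p, p12)

    def test_out_of_bounds_anchors_dropped_and_all_dropped_errors(self):
        track = {"chrI": np.ones(300)}
        prof = nuc.metaplot(track, [("chrI", 150, "+"), ("chrI", 10, "+")], flank=100)
        assert len(prof.anchor_ids) == 1
        with pytest.raises(ValueError):
            nuc.metaplot(track, [("chrI", 10, "+")], flank=100)

    def test_planted_array_oscillates_at_spacing(self, sim, wt_density, wt_dyads):
        cfg, _genome, genes, truth = sim
        guest_ids = {b for _, b in truth.nested_pairs}
        hosts = [g for g in genes if g.id not in guest_ids]
        anchors, _ = nuc.plus_one_anchors(hosts, wt_dyads)
        prof = nuc.metaplot(wt_density, anchors, 800, "library-mean-1")
        score = nuc.phasing_score(prof.mean_profile())
        assert abs(score.period - cfg.nucleosome_spacing) <= 5

    def test_mirror_symmetry_of_strand_framed_profiles(self, rng):
        n = 2000
        a = rng.random(n)
        anchors = [("chrI", 400, "+"), ("chrI", 1200, "-")]
        prof = nuc.metaplot({"chrI": a}, anchors, 150)
        mirrored = {"chrI": a[::-1].copy()}
        flip = {"+": "-", "-": "+"}
        m_anchors = [("chrI", n - 1 - p, flip[s]) for _, p, s in anchors]
        prof_m = nuc.metaplot(mirrored, m_anchors, 150)
        assert np.allclose(prof.values, prof_m.values)


class TestPlusOneAnchors:
    def test_first_downstream_dyad_plus(self):
        genes = [GeneModel("g", "chrI", 1000, 3000, "+")]
        dyads = nuc.DyadCalls([("chrI", 950, 1.0), ("chrI", 1080, 1.0),
                               ("chrI", 1230, 1.0)])
        anchors, skipped = nuc.plus_one_anchors(genes, dyads)
        assert anchors == [("chrI", 1080, "+")] and skipped == 0

    def test_strand_frame_minus(self):
        genes = [GeneModel("g", "chrI", 500, 2001, "-")]  # TSS at 2000
        dyads = nuc.DyadCalls([("chrI", 1900, 1.0), ("chrI", 2050, 1.0)])
        anchors, _ = nuc.plus_one_anchors(genes, dyads)
        assert anchors == [("chrI", 1900, "-")]

    def test_gene_without_dyad_in_window_is_skipped(self):
        genes = [GeneModel("g", "chrI", 1000, 3000, "+")]
        dyads = nuc.DyadCalls([("chrI", 2500, 1.0)])
        anchors, skipped = nuc.plus_one_anchors(genes, dyads)
        assert anchors == [] and skipped == 1


class TestPhasingScore:
    def test_cosine_profile_recovers_period_and_unit_amplitude(self):
        x = np.arange(-800, 801)
        prof = np.cos(2 * np.pi * x / 150.0)
        score = nuc.phasing_score(prof)
        assert score.period == 150
        assert score.amplitude == pytest.approx(1.0, abs=0.02)

    def test_white_noise_amplitude_small(self, rng):
        score = nuc.phasing_score(rng.normal(size=1601))
        assert score.amplitude < 0.2

    def test_flat_profile_has_no_period(self):
        score = nuc.phasing_score(np.full(600, 2.5))
        assert score.amplitude == 0.0 and score.period is None

    def test_invariance_to_affine_rescaling(self, rng):
        prof = np.cos(2 * np.pi * np.arange(1601) / 150.0) + rng.normal(0, 0.2, 1601)
        s1 = nuc.phasing_score(prof)
        s2 = nuc.phasing_score(3.7 * prof + 11.0)
        assert s1.amplitude == pytest.approx(s2.amplitude, rel=1e-9)
        assert s1.period == s2.period

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            nuc.phasing_score(np.ones(100))


class TestDyadGC:
    def test_alternating_sequence_is_fifty_percent(self):
        genome = GenomeSequence({"chrI": "ATGC" * 25})
        calls = nuc.DyadCalls([("chrI", 50, 1.0)])
        assert nuc.dyad_gc(calls, genome) == [50.0]

    def test_all_a_is_zero(self):
        genome = GenomeSequence({"chrI": "A" * 100})
        calls = nuc.DyadCalls([("chrI", 50, 1.0)])
        assert nuc.dyad_gc(calls, genome) == [0.0]

    def test_n_bases_excluded(self):
        genome = GenomeSequence({"chrI": "G" * 50 + "N" * 50 + "A" * 50})
        calls = nuc.DyadCalls([("chrI", 75, 1.0)])
        (gc,) = nuc.dyad_gc(calls, genome)
        assert gc == 50.0  # window holds 25 G + 50 N + 25 A; N dropped

    def test_mutant_dyads_avoid_at_islands(self, sim, wt_dyads):
        from nucphase.synthetic import simulate_mnase

        cfg, genome, _genes, truth = sim
        frags_mut = simulate_mnase(genome, truth, "mutant", 50_000, cfg,
                                   occupancy_drop=1.0)
        mut_dyads = nuc.call_dyads(nuc.midpoint_density(frags_mut, genome))
        gc_wt = np.nanmean(nuc.dyad_gc(wt_dyads, genome))
        gc_mut = np.nanmean(nuc.dyad_gc(mut_dyads, genome))
        assert gc_mut > gc_wt
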