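import numpy as np
import pytest
from scipy import stats

from ribostall import (
    DwellModel,
    FootprintLengthDist,
    GeneCounts,
    QueueParams,
    TranscriptSet,
    ValidationError,
    build_count_tracks,
    default_codon_weights,
    default_offsets,
    generate_transcriptome,
    make_scenario,
    metagene_profile,
    simulate_footprints,
    simulate_rnaseq_counts,
)
from ribostall.codons import SENSE_CODONS, STOP_CODONS
from ribostall.synthetic import MIN_CDS_CODONS


class TestGenerateTranscriptome:
    def test_invariants_hold(self):
        ts = generate_transcriptome(3, (250, 250), seed=1)
        for tid in ts:
            t = ts[tid]
            assert t.n_codons == 250
            assert t.codons[0] == "ATG"
            assert t.codons[-1] in STOP_CODONS
            assert not any(c in STOP_CODONS for c in t.codons[:-1])

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        generate_transcriptome(5, (250, 300), seed=42, fasta_path=p1)
        generate_transcriptome(5, (250, 300), seed=42, fasta_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        generate_transcriptome(5, (250, 300), seed=1, fasta_path=p1)
        generate_transcriptome(5, (250, 300), seed=2, fasta_path=p2)
        assert p1.read_bytes() != p2.read_bytes()

    def test_tgg_fraction_matches_weights(self):
        """~2% TGG weight realizes within binomial error at >= 1e4 codons."""
        ts = generate_transcriptome(50, (250, 300), seed=3)
        internal = [c for tid in ts for c in ts[tid].codons[1:-1]]
        n = len(internal)
        assert n >= 10_000
        frac = sum(c == "TGG" for c in internal) / n
        se = np.sqrt(0.02 * 0.98 / n)
        assert abs(frac - 0.02) < 4 * se

    def test_too_short_range_rejected(self):
        with pytest.raises(ValidationError):
            generate_transcriptome(2, (MIN_CDS_CODONS - 1, 300), seed=0)


class TestScenarios:
    def test_control_preset(self):
        sc = make_scenario("control")
        assert sc.dwell.stall_factor == 1.0
        assert sc.queue.queue_prob == 0.0

    def test_h2o2_preset(self):
        sc = make_scenario("h2o2")
        assert sc.dwell.stall_codon == "TGG"
        assert sc.dwell.stall_factor == 8.0
        assert sc.queue.queue_prob == 0.3
        assert sc.queue.max_queue_depth == 2

    def test_trp_rescue_restores_control_dwell(self):
        """Tryptophan supplementation abolishes the UGG stall."""
        control = make_scenario("control")
        trp = make_scenario("h2o2_trp")
        assert trp.dwell.effective() == control.dwell.effective()
        assert trp.queue.queue_prob == 0.0

    def test_unknown_name_lists_presets(self):
        with pytest.raises(ValidationError, match="control"):
            make_scenario("banana")

    def test_invalid_override_rejected(self):
        with pytest.raises(ValidationError):
            make_scenario("h2o2", stall_factor=-1)

    def test_dwell_model_validation(self):
        with pytest.raises(ValidationError):
            DwellModel({"TGG": 1.0})
        with pytest.raises(ValidationError):
            QueueParams(queue_prob=1.5)

    def test_length_dist_default(self):
        d = FootprintLengthDist.default()
        assert d.mode == 30
        assert min(d.lengths) == 17 and max(d.lengths) == 30
        assert sum(d.probs) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_transcriptome():
    return generate_transcriptome(10, (250, 400), seed=11)


class TestSimulateFootprints:
    def test_determinism(self, small_transcriptome):
        sc = make_scenario("h2o2", n_footprints=5000, seed=5)
        a = simulate_footprints(small_transcriptome, sc)
        b = simulate_footprints(small_transcriptome, sc)
        assert a.footprints == b.footprints

    def test_count_conservation_and_bounds(self, small_transcriptome):
        sc = make_scenario("h2o2", n_footprints=20_000, seed=6)
        sim = simulate_footprints(small_transcriptome, sc)
        assert sim.n_primary + sim.n_primary_skipped == sc.n_footprints
        assert len(sim) == sim.n_primary + sim.n_queued
        for fp in sim.footprints[::37]:
            n = small_transcriptome[fp.transcript_id].n_codons
            assert 0 <= fp.start and fp.start + fp.length <= 3 * n
            assert 17 <= fp.length <= 30

    def test_uniform_dwell_counts_uniform(self, small_transcriptome):
        """Control scenario: per-codon A-site counts flat within Poisson error."""
        sc = make_scenario("control", n_footprints=200_000, seed=7)
        sim = simulate_footprints(small_transcriptome, sc)
        res = build_count_tracks(sim, default_offsets(), small_transcriptome)
        interior = np.concatenate(
            [res.tracks[t].counts[10:-10] for t in small_transcriptome]
        )
        lam = interior.mean()
        # chi-square goodness of fit vs the flat expectation
        z = (interior - lam) / np.sqrt(lam)
        assert abs(z.mean()) < 0.1
        assert np.percentile(np.abs(z), 99) < 4

    def test_stall_occupancy_matches_enumeration(self):
        """x8 TGG stall, q=0: simulated codon counts match the position-wise
        expectation computed by independent enumeration on a 1-gene toy."""
        ts = generate_transcriptome(1, (300, 300), seed=13)
        t = ts[next(iter(ts))]
        sc = make_scenario("h2o2", queue_prob=0.0, n_footprints=300_000, seed=13)
        sim = simulate_footprints(ts, sc)
        res = build_count_tracks(sim, default_offsets(), ts)
        counts = res.tracks[t.transcript_id].counts

        # enumeration oracle: expected weight per position over the placeable
        # range [5, n-5] (max length 30, offset 15), dwell 8 on TGG else 1
        n = t.n_codons
        w = np.zeros(n)
        for j in range(5, n - 4):
            if j <= n - 2:
                w[j] = 8.0 if t.codons[j] == "TGG" else 1.0
        expected = w / w.sum() * sim.n_primary

        tgg = np.array([c == "TGG" for c in t.codons])
        obs_tgg = counts[tgg].sum()
        exp_tgg = expected[tgg].sum()
        assert obs_tgg == pytest.approx(exp_tgg, rel=0.05)

        # closed form of the sampling mixture for the occupancy statistic
        placeable = slice(5, n - 4)
        a_tgg = tgg[placeable].mean()
        o_closed = 8 / (1 + 7 * a_tgg)
        f_hat = obs_tgg / counts.sum()
        o_hat = f_hat / a_tgg
        assert o_hat == pytest.approx(o_closed, rel=0.05)

    def test_queue_emission_expectation(self):
        """q=0.3, depth 2: metagene ratio ~ 1 + q^k * stall excess at -10k."""
        ts = generate_transcriptome(20, (250, 400), seed=17)
        sc = make_scenario("h2o2", n_footprints=400_000, seed=17)
        sim = simulate_footprints(ts, sc)
        res = build_count_tracks(sim, default_offsets(), ts)
        prof = metagene_profile(res.tracks, ts, "TGG")
        background = np.median(prof.density)
        assert prof.at(-10) / background == pytest.approx(1 + 0.3 * 8, rel=0.15)
        assert prof.at(-20) / background == pytest.approx(1 + 0.09 * 8, rel=0.15)
        assert prof.at(-30) / background == pytest.approx(1.0, abs=0.2)

    def test_queue_spacing_follows_footprint_length(self):
        """27-nt footprints queue at 9-codon spacing (round(L/3))."""
        ts = generate_transcriptome(20, (250, 400), seed=19)
        sc = make_scenario(
            "h2o2", n_footprints=400_000, seed=19,
            ribosome_width_codons=9,
            length_dist=FootprintLengthDist.fixed(27),
        )
        sim = simulate_footprints(ts, sc)
        res = build_count_tracks(sim, default_offsets(), ts)
        prof = metagene_profile(res.tracks, ts, "TGG")
        background = np.median(prof.density)
        assert prof.at(-9) / background > 2.0
        assert prof.at(-10) / background < 1.5


class TestSimulateRnaseq:
    def test_equal_genes_equal_counts(self):
        ts = generate_transcriptome(2, (300, 300), seed=23)
        sc = make_scenario("control", n_footprints=1000, n_rna_reads=200_000, seed=23)
        counts = simulate_rnaseq_counts(ts, sc)
        a, b = counts[0].rna_count, counts[1].rna_count
        # two-proportion check within multinomial error
        p_hat = a / (a + b)
        se = np.sqrt(0.25 / (a + b))
        assert abs(p_hat - 0.5) < 4 * se

    def test_expression_ratio_recovered(self):
        ts = generate_transcriptome(2, (300, 300), seed=29)
        ids = sorted(ts)
        sc = make_scenario(
            "control", n_footprints=1000, n_rna_reads=300_000, seed=29,
            expression={ids[0]: 3.0, ids[1]: 1.0},
        )
        counts = {c.gene_id: c.rna_count for c in simulate_rnaseq_counts(ts, sc)}
        ratio = counts[ids[0]] / counts[ids[1]]
        assert ratio == pytest.approx(3.0, rel=0.1)

    def test_determinism_and_rpf_totals(self, small_transcriptome):
        sc = make_scenario("control", n_footprints=5000, n_rna_reads=5000, seed=31)
        sim = simulate_footprints(small_transcriptome, sc)
        c1 = simulate_rnaseq_counts(small_transcriptome, sc, sim)
        c2 = simulate_rnaseq_counts(small_transcriptome, sc, sim)
        assert c1 == c2
        assert sum(c.rpf_count for c in c1) == len(sim)
        assert sum(c.rna_count for c in c1) == 5000

    def test_zero_rna_reads_rejected(self, small_transcriptome):
        sc = make_scenario("control", n_footprints=100, n_rna_reads=0, seed=1)
        with pytest.raises(ValidationError):
            simulate_rnaseq_counts(small_transcriptome, sc)


class TestSelfConsistency:
    def test_control_recovers_flat_occupancy(self):
        """Uniform dwell: downstream occupancy ~1 for all codons (scaled run)."""
        from ribostall import OccupancyConfig, average_occupancy, occupancy_by_gene

        ts = generate_transcriptome(50, (250, 500), seed=37)
        sc = make_scenario("control", n_footprints=300_000, seed=37)
        sim = simulate_footprints(ts, sc)
        res = build_count_tracks(sim, default_offsets(), ts)
        prof = average_occupancy(occupancy_by_gene(res.tracks, ts, OccupancyConfig()))
        vals = prof.table.dropna(subset=["mean_occupancy"])
        assert len(vals) == 61
        assert np.allclose(vals.mean_occupancy, 1.0, atol=0.1)

    def test_injected_dwell_recovered(self):
        """Spearman(log dwell, log occupancy) >= 0.9 for heterogeneous dwell."""
        from ribostall import OccupancyConfig, average_occupancy, occupancy_by_gene
        from dataclasses import replace

        ts = generate_transcriptome(50, (250, 500), seed=41)
        dwell = DwellModel.random(seed=41, sigma=0.5)
        sc = replace(make_scenario("control", n_footprints=300_000, seed=41), dwell=dwell)
        sim = simulate_footprints(ts, sc)
        res = build_count_tracks(sim, default_offsets(), ts)
        prof = average_occupancy(occupancy_by_gene(res.tracks, ts, OccupancyConfig()))
        est = prof.table.set_index("codon").mean_occupancy
        inj = np.array([dwell.dwell[c] for c in est.index])
        rho = stats.spearmanr(np.log(inj), np.log(est.to_numpy())).statistic
        assert rho >= 0.9
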