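import math

import numpy as np
import pytest

from polyorf.conservation import frame_periodicity
from polyorf.enrichment import enumerate_synonymous_space
from polyorf.orfs import OrfParams, predict_altorfs
from polyorf.simulate import (
    OrfPlantSpec,
    SimConfig,
    TrackSpec,
    VariantSpec,
    sample_protein_lengths,
    simulate_bundle,
    simulate_conservation_track,
    simulate_transcript,
    simulate_variants,
)
from polyorf.variants import scan_silent_altering


class TestSimulateTranscript:
    def test_determinism(self, small_config):
        b1 = simulate_bundle(small_config)
        b2 = simulate_bundle(small_config)
        assert [t.sequence for t in b1.transcripts] == [t.sequence for t in b2.transcripts]
        assert [(v.transcript_id, v.tpos, v.ref, v.alt, v.occurrence_count) for v in b1.variants] == [
            (v.transcript_id, v.tpos, v.ref, v.alt, v.occurrence_count) for v in b2.variants
        ]
        for tid in b1.tracks:
            assert np.array_equal(b1.tracks[tid].scores, b2.tracks[tid].scores)

    def test_seed_changes_sequences(self, small_config, small_bundle):
        import dataclasses

        other = simulate_bundle(dataclasses.replace(small_config, seed=43))
        assert other.transcripts[0].sequence != small_bundle.transcripts[0].sequence

    def test_planted_equals_predicted(self, small_bundle):
        """Every planted altORF is recovered and nothing else is predicted."""
        params = OrfParams(min_aa=30)
        for tr in small_bundle.transcripts:
            truth = small_bundle.truth.transcripts[tr.id]
            predicted = {o.interval: o.category for o in predict_altorfs(tr, params)}
            planted = {(p.start, p.end): p.category for p in truth.planted}
            assert predicted == planted, tr.id

    def test_planted_classes_present(self, small_bundle):
        cats = {
            p.category
            for tt in small_bundle.truth.transcripts.values()
            for p in tt.planted
        }
        assert {"uORF", "dORF", "overlap_nested", "lncRNA_orf"} <= cats

    def test_transcripts_valid(self, small_bundle):
        for tr in small_bundle.transcripts:
            assert tr.validate() == []

    def test_truth_proteins_match_sequence(self, small_bundle):
        from polyorf.core import translate

        for tr in small_bundle.transcripts:
            for p in small_bundle.truth.transcripts[tr.id].planted:
                prot, terminated = translate(tr.sequence[p.start : p.end])
                assert terminated and prot == p.protein

    def test_gc_content_close_to_target(self):
        cfg = SimConfig(
            seed=9, n_transcripts=30, n_lncrna=0, length_range=(600, 1200),
            variants=VariantSpec(n_per_transcript=0),
        )
        b = simulate_bundle(cfg)
        seq = "".join(t.sequence for t in b.transcripts)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - cfg.gc_content) < 0.02

    def test_infeasible_config_raises(self):
        cfg = SimConfig(
            seed=0, n_transcripts=1, n_lncrna=0, length_range=(300, 320),
            orfs=OrfPlantSpec(length_median_aa=250.0, min_len_aa=240, max_len_aa=300),
        )
        rng = np.random.default_rng(0)
        with pytest.raises(RuntimeError):
            simulate_transcript(cfg, rng, 0)


class TestProteinLengths:
    def test_median_near_target(self):
        rng = np.random.default_rng(4)
        lengths = sample_protein_lengths(rng, 2000, OrfPlantSpec())
        assert abs(np.median(lengths) - 45.0) / 45.0 < 0.10
        assert lengths.min() >= 30 and lengths.max() <= 300


@pytest.fixture(scope="module")
def host(small_bundle):
    tr = next(
        t for t in small_bundle.transcripts
        if t.cds and any(
            p.category.startswith("overlap")
            for p in small_bundle.truth.transcripts[t.id].planted
        )
    )
    alts = predict_altorfs(tr)
    return tr, alts, enumerate_synonymous_space(tr, alts)


class TestSimulateVariants:

    def test_null_matches_coverage(self, host):
        tr, alts, space = host
        rng = np.random.default_rng(21)
        snvs, truths = simulate_variants(tr, 10_000, 1.0, rng, space=space, altorfs=alts)
        hits = sum(t.occurrence_count * t.positional_hit for t in truths)
        n = sum(t.occurrence_count for t in truths)
        assert n == 10_000
        c = space.coverage
        se = math.sqrt(c * (1 - c) / n)
        assert abs(hits / n - c) < 3 * se

    def test_factor_zero_and_inf(self, host):
        tr, alts, space = host
        rng = np.random.default_rng(2)
        _, truths0 = simulate_variants(tr, 200, 0.0, rng, space=space, altorfs=alts)
        assert not any(t.positional_hit for t in truths0)
        _, truths_inf = simulate_variants(tr, 200, math.inf, rng, space=space, altorfs=alts)
        assert all(t.positional_hit for t in truths_inf)

    def test_truth_matches_rescan(self, small_bundle):
        """Re-deriving effects from emitted sequences reproduces the truth."""
        mrna = [t for t in small_bundle.transcripts if t.cds]
        res = scan_silent_altering(small_bundle.variants, mrna)
        got = {
            (r.snv.transcript_id, r.snv.tpos, r.snv.alt): (
                r.positional_hit, r.altering_hit, r.silent_but_altering,
            )
            for r in res.records
        }
        for vt in small_bundle.truth.variants:
            key = (vt.transcript_id, vt.tpos, vt.alt)
            assert got[key] == (vt.positional_hit, vt.altering_hit, vt.silent_but_altering)


class TestSimulateTrack:
    def test_noiseless_full_cover_delta_equals_depth(self):
        """A zero-noise track over a transcript whose footprints span frame 0
        yields delta exactly equal to the planted depth inside the ORF."""
        from polyorf.core import Transcript
        from polyorf.simulate import TranscriptTruth, PlantedOrf

        n = 300
        tr = Transcript("t", "g", "A" * n, cds=None)
        truth = TranscriptTruth(
            transcript_id="t", gene_id="g", cds=None,
            planted=[PlantedOrf(0, n, "lncRNA_orf", None, "")],
        )
        rng = np.random.default_rng(0)
        track = simulate_conservation_track(tr, truth, depth=1.0, noise_sd=0.0, rng=rng)
        res = frame_periodicity(track, n_perm=9, seed=0)
        assert res.deltas[0] == pytest.approx(1.0)
        assert res.deltas[1] == pytest.approx(-0.5)

    def test_overlapping_orfs_superpose(self):
        from polyorf.core import Transcript
        from polyorf.simulate import TranscriptTruth, PlantedOrf

        n = 30
        tr = Transcript("t", "g", "A" * n, cds=None)
        truth = TranscriptTruth(
            transcript_id="t", gene_id="g", cds=None,
            planted=[
                PlantedOrf(0, n, "lncRNA_orf", None, ""),
                PlantedOrf(0, n, "lncRNA_orf", None, ""),
            ],
        )
        rng = np.random.default_rng(0)
        track = simulate_conservation_track(tr, truth, depth=1.0, noise_sd=0.0, rng=rng)
        assert track.scores[0] == pytest.approx(2.0)
        assert track.scores[2] == pytest.approx(0.0)

    def test_negative_depth_rejected(self, small_bundle):
        tr = small_bundle.transcripts[0]
        truth = small_bundle.truth.transcripts[tr.id]
        with pytest.raises(ValueError):
            simulate_conservation_track(tr, truth, -1.0, 0.5, np.random.default_rng(0))
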