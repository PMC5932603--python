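import numpy as np
import pytest

from polyorf.core import ORF, Transcript
from polyorf.orfs import OrfParams, predict_altorfs
from polyorf.enrichment import (
    enrichment_test,
    enumerate_synonymous_space,
    summarize_table,
)
from polyorf.variants import SNV, annotate_variant, effect_on_orf, scan_silent_altering
from polyorf.orfs import canonical_orf


class TestSynonymousSpace:
    def test_minimal_cds(self):
        tr = Transcript("t", "g", "ATGAAATAA", cds=(0, 9))
        space = enumerate_synonymous_space(tr, [])
        assert (5, "G") in space.pairs  # AAA->AAG, Lys
        assert (7, "G") in space.pairs  # TAA->TGA stop swap
        assert not any(tpos < 3 for tpos, _ in space.pairs)  # start codon sterile
        assert not space.positional.any()

    def test_lncrna_rejected(self):
        with pytest.raises(ValueError):
            enumerate_synonymous_space(Transcript("t", "g", "ATGAAATAA"), [])

    def test_flags_match_effect_on_orf(self, toy_transcript):
        alts = predict_altorfs(toy_transcript, OrfParams(min_aa=2))
        space = enumerate_synonymous_space(toy_transcript, alts)
        assert space.n_pairs > 0
        for (tpos, alt), pos_flag, alt_flag in zip(
            space.pairs, space.positional, space.altering
        ):
            snv = SNV("toy", tpos, toy_transcript.sequence[tpos], alt)
            rec = annotate_variant(snv, toy_transcript, alts)
            assert rec.canonical_silent
            assert rec.positional_hit == pos_flag
            assert rec.altering_hit == alt_flag

    def test_every_pair_is_canonical_silent(self, small_bundle):
        tr = next(t for t in small_bundle.transcripts if t.cds)
        alts = predict_altorfs(tr)
        space = enumerate_synonymous_space(tr, alts)
        cds_orf = canonical_orf(tr)
        for tpos, alt in space.pairs:
            snv = SNV(tr.id, tpos, tr.sequence[tpos], alt)
            eff = effect_on_orf(snv, cds_orf, tr).effect
            assert eff in ("synonymous", "stop_retained")


def _records(transcriptome, variants, altorfs):
    return scan_silent_altering(variants, transcriptome, altorfs_by_transcript=altorfs).records


class TestEnrichmentTest:
    def test_saturated_space_gives_p_one(self):
        """With the whole CDS inside an altORF footprint, observed and null
        coincide: frac_positional 1.0, p_perm 1.0."""
        tr = Transcript("t", "g", "ATGCATGGATTGATATAA", cds=(0, 18))
        alts = [ORF("t", 0, 18, "X" * 5, True, category="overlap_nested", frame_offset_vs_cds=0)]
        # force a synthetic full-cover footprint (classification irrelevant here)
        alts[0].start, alts[0].end = 0, 18
        space = enumerate_synonymous_space(tr, alts)
        assert space.coverage == 1.0
        snvs = [SNV("t", tpos, tr.sequence[tpos], alt) for tpos, alt in space.pairs[:4]]
        recs = [annotate_variant(s, tr, alts) for s in snvs]
        res = enrichment_test(recs, [tr], {"t": alts}, n_perm=99, seed=0)
        assert res.frac_positional == 1.0
        assert res.p_perm == 1.0

    def test_zero_altorfs_gives_zero_fraction(self):
        tr = Transcript("t", "g", "CCC" + "ATGAAACCCGGGTAA" + "CCC", cds=(3, 18))
        space = enumerate_synonymous_space(tr, [])
        snvs = [SNV("t", tpos, tr.sequence[tpos], alt) for tpos, alt in space.pairs[:3]]
        recs = [annotate_variant(s, tr, []) for s in snvs]
        res = enrichment_test(recs, [tr], {"t": []}, n_perm=99, seed=0)
        assert res.frac_positional == 0.0 and res.frac_altering == 0.0

    def test_empty_records_rejected(self, small_bundle):
        mrna = [t for t in small_bundle.transcripts if t.cds]
        with pytest.raises(ValueError):
            enrichment_test([], mrna, {}, n_perm=10, seed=0)

    def test_deterministic_under_seed(self, small_bundle):
        mrna = [t for t in small_bundle.transcripts if t.cds]
        alts = {t.id: predict_altorfs(t) for t in mrna}
        recs = _records(mrna, small_bundle.variants, alts)
        r1 = enrichment_test(recs, mrna, alts, n_perm=200, seed=9)
        r2 = enrichment_test(recs, mrna, alts, n_perm=200, seed=9)
        assert (r1.p_perm, r1.p_perm_altering, r1.expected_frac) == (
            r2.p_perm,
            r2.p_perm_altering,
            r2.expected_frac,
        )

    def test_expected_frac_matches_null_mean(self, small_bundle):
        """The analytic expectation equals the Monte-Carlo mean of permuted
        fractions (law of large numbers)."""
        mrna = [t for t in small_bundle.transcripts if t.cds]
        alts = {t.id: predict_altorfs(t) for t in mrna}
        recs = _records(mrna, small_bundle.variants, alts)
        spaces = {t.id: enumerate_synonymous_space(t, alts[t.id]) for t in mrna}
        res = enrichment_test(recs, mrna, alts, n_perm=4000, seed=1, spaces=spaces)
        rng = np.random.default_rng(123)
        n_by_tid = {}
        for r in recs:
            n_by_tid[r.snv.transcript_id] = (
                n_by_tid.get(r.snv.transcript_id, 0) + r.snv.occurrence_count
            )
        sims = []
        for _ in range(4000):
            num = den = 0
            for tid, n_t in n_by_tid.items():
                sp = spaces[tid]
                num += sp.positional[rng.integers(0, sp.n_pairs, n_t)].sum()
                den += n_t
            sims.append(num / den)
        se = np.std(sims) / np.sqrt(len(sims))
        assert abs(res.expected_frac - np.mean(sims)) < 5 * se + 1e-3


class TestSummarizeTable:
    def test_arithmetic(self):
        """10 synonymous SNVs, 3 altering two altProts of 31 and 45 aa:
        pct 30.0, flag set, median length 38.0."""
        tr = Transcript("t", "g", "ATG" + "GGA" * 200 + "TAA", cds=(0, 606))
        orf_a = ORF("t", 4, 100, "M" * 31, True, category="overlap_nested")
        orf_b = ORF("t", 104, 242, "M" * 45, True, category="overlap_nested")
        assert (orf_a.length_aa, orf_b.length_aa) == (31, 45)
        space = enumerate_synonymous_space(tr, [orf_a, orf_b])
        in_a = [i for i, f in enumerate(space.altering) if f and orf_a.contains(space.pairs[i][0])]
        in_b = [i for i, f in enumerate(space.altering) if f and orf_b.contains(space.pairs[i][0])]
        miss = [i for i in range(space.n_pairs) if not space.positional[i]]
        assert len(in_a) >= 2 and len(in_b) >= 1 and len(miss) >= 7
        chosen = in_a[:2] + in_b[:1] + miss[:7]
        snvs = [SNV("t", space.pairs[i][0], tr.sequence[space.pairs[i][0]], space.pairs[i][1])
                for i in chosen]
        recs = [annotate_variant(s, tr, [orf_a, orf_b]) for s in snvs]
        table = summarize_table(recs, [tr], {"t": [orf_a, orf_b]})
        row = table[table.gene == "g"].iloc[0]
        assert row.n_syn_snvs == 10
        assert row.n_altering == 3
        assert row.pct_altering == 30.0
        assert row.gene_flag == 1.0
        assert row.median_altprot_len_aa == 38.0
        assert row.n_overlap == 2
        footer = table[table.gene == "ALL"].iloc[0]
        assert footer.n_syn_snvs == 10

    def test_truth_consistency(self, small_bundle):
        """The per-gene table matches truth-derived counts."""
        mrna = [t for t in small_bundle.transcripts if t.cds]
        alts = {t.id: predict_altorfs(t) for t in mrna}
        recs = _records(mrna, small_bundle.variants, alts)
        table = summarize_table(recs, mrna, alts).set_index("gene")
        truth_by_gene = {}
        gene_of = {t.id: t.gene_id for t in mrna}
        for vt in small_bundle.truth.variants:
            g = truth_by_gene.setdefault(gene_of[vt.transcript_id], [0, 0, 0])
            g[0] += vt.occurrence_count
            g[1] += vt.occurrence_count * vt.positional_hit
            g[2] += vt.occurrence_count * vt.altering_hit
        for gene, (n_syn, n_pos, n_alt) in truth_by_gene.items():
            row = table.loc[gene]
            assert (row.n_syn_snvs, row.n_positional, row.n_altering) == (n_syn, n_pos, n_alt)
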