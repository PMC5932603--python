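"""Permutation enrichment test: are altORF hits among canonical-synonymous
SNVs more frequent than expected by chance?

The chance model conditions on gene composition and per-transcript mutation
counts: for each transcript, the observed number of SNV occurrences is
redrawn uniformly with replacement from that transcript's *synonymous space*
— every (position, alt) pair that is synonymous (or stop-retained) in the
canonical frame.  The pooled altORF-hit fraction of each redraw forms the
null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .core import GeneticCode, ORF, STANDARD_CODE, Transcript
from .orfs import canonical_orf
from .variants import (
    ALTERING_EFFECTS,
    SILENT_EFFECTS,
    SNV,
    DualEffectRecord,
    effect_on_orf,
)

__all__ = [
    "SynonymousSpace",
    "EnrichmentResult",
    "enumerate_synonymous_space",
    "enrichment_test",
    "summarize_table",
]


@dataclass
class SynonymousSpace:
    """All canonical-synonymous (tpos, alt) pairs of one transcript.

    ``positional``/``altering`` are per-pair flags: does the pair fall within
    an altORF footprint / alter at least one altProt.
    """

    transcript_id: str
    pairs: list  # [(tpos, alt), ...]
    positional: np.ndarray
    altering: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def coverage(self) -> float:
        """Fraction of the space inside altORF footprints."""
        return float(self.positional.mean()) if self.n_pairs else 0.0

    @property
    def altering_coverage(self) -> float:
        return float(self.altering.mean()) if self.n_pairs else 0.0


def enumerate_synonymous_space(
    transcript: Transcript,
    altorfs: Iterable[ORF],
    code: GeneticCode = STANDARD_CODE,
) -> SynonymousSpace:
    """Enumerate the canonical-synonymous substitution space of a transcript."""
    if transcript.cds is None:
        raise ValueError(f"transcript {transcript.id} has no CDS")
    cds_orf = canonical_orf(transcript, code)
    altorfs = list(altorfs)
    pairs: list = []
    positional: list = []
    altering: list = []
    seq = transcript.sequence
    for tpos in range(cds_orf.start, cds_orf.end):
        ref = seq[tpos]
        for alt in "ACGT":
            if alt == ref:
                continue
            snv = SNV(transcript.id, tpos, ref, alt)
            if effect_on_orf(snv, cds_orf, transcript, code).effect not in SILENT_EFFECTS:
                continue
            overlapping = [o for o in altorfs if o.contains(tpos)]
            pairs.append((tpos, alt))
            positional.append(bool(overlapping))
            altering.append(
                any(
                    effect_on_orf(snv, o, transcript, code).effect in ALTERING_EFFECTS
                    for o in overlapping
                )
            )
    return SynonymousSpace(
        transcript_id=transcript.id,
        pairs=pairs,
        positional=np.asarray(positional, dtype=bool),
        altering=np.asarray(altering, dtype=bool),
    )


@dataclass
class EnrichmentResult:
    n_variants: int
    n_positional: int
    n_altering: int
    frac_positional: float
    frac_altering: float
    expected_frac: float
    p_perm: float
    p_perm_altering: float
    n_perm: int
    seed: int
    per_gene: Optional[pd.DataFrame] = None


def enrichment_test(
    records: Iterable[DualEffectRecord],
    transcriptome: Iterable[Transcript],
    altorfs_by_transcript: Dict[str, list],
    n_perm: int = 1000,
    seed: int = 0,
    spaces: Optional[Dict[str, SynonymousSpace]] = None,
    code: GeneticCode = STANDARD_CODE,
) -> EnrichmentResult:
    """Test observed altORF-hit fractions against the resampling null.

    ``records`` must be canonical-synonymous (others are ignored); fractions
    are occurrence-weighted.  ``p_perm`` is the +1-corrected one-sided
    empirical p-value for the positional ("fell within") fraction;
    ``p_perm_altering`` likewise for the altering fraction.
    ``expected_frac`` is the occurrence-weighted mean altORF coverage of the
    synonymous spaces — the analytic null mean of ``frac_positional``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    by_id = {t.id: t for t in transcriptome}
    records = [r for r in records if r.canonical_silent]
    if not records:
        raise ValueError("no canonical-synonymous records to test")
    if spaces is None:
        spaces = {}
    # occurrence counts per transcript, observed hit counts
    n_by_tid: Dict[str, int] = {}
    n_total = n_pos = n_alt = 0
    for rec in records:
        w = rec.snv.occurrence_count
        tid = rec.snv.transcript_id
        n_by_tid[tid] = n_by_tid.get(tid, 0) + w
        n_total += w
        n_pos += w * rec.positional_hit
        n_alt += w * rec.altering_hit
    frac_pos = n_pos / n_total
    frac_alt = n_alt / n_total

    rng = np.random.default_rng(seed)
    perm_pos = np.zeros(n_perm)
    perm_alt = np.zeros(n_perm)
    expected_num = 0.0
    n_used = 0
    for tid in sorted(n_by_tid):
        n_t = n_by_tid[tid]
        if tid not in spaces:
            transcript = by_id.get(tid)
            if transcript is None or transcript.cds is None:
                import logging

                logging.getLogger(__name__).warning(
                    "transcript %s lacks a synonymous space; excluded from null", tid
                )
                continue
            spaces[tid] = enumerate_synonymous_space(
                transcript, altorfs_by_transcript.get(tid, []), code
            )
        space = spaces[tid]
        if space.n_pairs == 0:
            continue
        draws = rng.integers(0, space.n_pairs, size=(n_perm, n_t))
        perm_pos += space.positional[draws].sum(axis=1)
        perm_alt += space.altering[draws].sum(axis=1)
        expected_num += n_t * space.coverage
        n_used += n_t
    if n_used == 0:
        raise ValueError("no transcript contributed a non-empty synonymous space")
    perm_pos /= n_used
    perm_alt /= n_used
    p_perm = (1 + int((perm_pos >= frac_pos).sum())) / (n_perm + 1)
    p_perm_altering = (1 + int((perm_alt >= frac_alt).sum())) / (n_perm + 1)
    return EnrichmentResult(
        n_variants=n_total,
        n_positional=n_pos,
        n_altering=n_alt,
        frac_positional=frac_pos,
        frac_altering=frac_alt,
        expected_frac=expected_num / n_used,
        p_perm=p_perm,
        p_perm_altering=p_perm_altering,
        n_perm=n_perm,
        seed=seed,
    )


def summarize_table(
    records: Iterable[DualEffectRecord],
    transcriptome: Iterable[Transcript],
    altorfs_by_transcript: Dict[str, list],
) -> pd.DataFrame:
    """Per-gene summary of altORFs altered by canonical-synonymous SNVs.

    One row per gene plus a pooled ``ALL`` footer row carrying the three
    headline metrics: percent of synonymous SNVs falling within an altProt,
    fraction of genes with at least one altering SNV (``gene_flag``), and the
    median length of distinct altered altProts.  Counts are
    occurrence-weighted; ``gene_flag`` is 0/1 per gene and the flagged
    fraction in the footer.
    """
    by_id = {t.id: t for t in transcriptome}
    orf_index = {
        o.orf_id: o for orfs in altorfs_by_transcript.values() for o in orfs
    }
    per_gene: Dict[str, dict] = {}
    for rec in records:
        if not rec.canonical_silent:
            continue
        transcript = by_id[rec.snv.transcript_id]
        g = per_gene.setdefault(
            transcript.gene_id,
            {"n_syn": 0, "n_pos": 0, "n_alt": 0, "altered_orfs": set()},
        )
        w = rec.snv.occurrence_count
        g["n_syn"] += w
        g["n_pos"] += w * rec.positional_hit
        g["n_alt"] += w * rec.altering_hit
        for eff in rec.altorf_effects:
            if eff.effect in ALTERING_EFFECTS:
                g["altered_orfs"].add(eff.orf_id)

    rows = []
    for gene in sorted(per_gene):
        g = per_gene[gene]
        lengths = [orf_index[o].length_aa for o in g["altered_orfs"] if o in orf_index]
        cats = [orf_index[o].category for o in g["altered_orfs"] if o in orf_index]
        rows.append(
            {
                "gene": gene,
                "n_syn_snvs": g["n_syn"],
                "n_positional": g["n_pos"],
                "pct_positional": 100.0 * g["n_pos"] / g["n_syn"],
                "n_altering": g["n_alt"],
                "pct_altering": 100.0 * g["n_alt"] / g["n_syn"],
                "gene_flag": float(g["n_alt"] > 0),
                "median_altprot_len_aa": float(np.median(lengths)) if lengths else float("nan"),
                "n_uORF": cats.count("uORF"),
                "n_dORF": cats.count("dORF"),
                "n_overlap": cats.count("overlap_nested") + cats.count("overlap_partial"),
                "n_lncRNA_orf": cats.count("lncRNA_orf"),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        all_orf_ids = set().union(*(g["altered_orfs"] for g in per_gene.values()))
        all_lengths = [orf_index[o].length_aa for o in sorted(all_orf_ids) if o in orf_index]
        n_syn = int(df["n_syn_snvs"].sum())
        footer = {
            "gene": "ALL",
            "n_syn_snvs": n_syn,
            "n_positional": int(df["n_positional"].sum()),
            "pct_positional": 100.0 * df["n_positional"].sum() / n_syn,
            "n_altering": int(df["n_altering"].sum()),
            "pct_altering": 100.0 * df["n_altering"].sum() / n_syn,
            "gene_flag": float(df["gene_flag"].mean()),
            "median_altprot_len_aa": float(np.median(all_lengths)) if all_lengths else float("nan"),
            "n_uORF": int(df["n_uORF"].sum()),
            "n_dORF": int(df["n_dORF"].sum()),
            "n_overlap": int(df["n_overlap"].sum()),
            "n_lncRNA_orf": int(df["n_lncRNA_orf"].sum()),
        }
        df = pd.concat([df, pd.DataFrame([footer])], ignore_index=True)
    return df
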