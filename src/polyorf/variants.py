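"""Frame-aware SNV consequence annotation.

A variant that is synonymous in the canonical reading frame may still change
the protein encoded by an overlapping alternative ORF.  This module
classifies each SNV's consequence in the canonical frame and in every
overlapping altORF, and flags such "silent-but-altering" events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import ORF, GeneticCode, STANDARD_CODE, STOP, Transcript, codon_position
from .orfs import OrfParams, canonical_orf, predict_altorfs

__all__ = [
    "SNV",
    "VariantEffect",
    "DualEffectRecord",
    "ScanResult",
    "SILENT_EFFECTS",
    "ALTERING_EFFECTS",
    "apply_snv",
    "effect_on_orf",
    "annotate_variant",
    "scan_silent_altering",
]

log = logging.getLogger(__name__)

#: canonical-frame effects regarded as silent
SILENT_EFFECTS = frozenset({"synonymous", "stop_retained"})
#: altORF effects regarded as protein-altering
ALTERING_EFFECTS = frozenset({"missense", "nonsense", "stop_loss", "start_loss"})
#: severity order used to pick the "most severe" alteration for reporting
_SEVERITY = ("nonsense", "stop_loss", "start_loss", "missense", "stop_retained", "synonymous", "unknown")


@dataclass
class SNV:
    """A single-nucleotide substitution in transcript space."""

    transcript_id: str
    tpos: int
    ref: str
    alt: str
    occurrence_count: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.transcript_id}:{self.tpos}")
        for b in (self.ref, self.alt):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"invalid allele {b!r}")
        if self.occurrence_count < 1:
            raise ValueError("occurrence_count must be >= 1")


@dataclass
class VariantEffect:
    orf_id: str
    effect: str
    codon_index: int
    codon_pos: int  # 1..3 within the ORF's own frame
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str


@dataclass
class DualEffectRecord:
    """Cross-frame summary for one SNV."""

    snv: SNV
    canonical_effect: Optional[VariantEffect]
    altorf_effects: list = field(default_factory=list)
    silent_but_altering: bool = False

    @property
    def canonical_silent(self) -> bool:
        return self.canonical_effect is not None and self.canonical_effect.effect in SILENT_EFFECTS

    @property
    def positional_hit(self) -> bool:
        """Does the SNV fall within any altORF footprint?"""
        return bool(self.altorf_effects)

    @property
    def altering_hit(self) -> bool:
        return any(e.effect in ALTERING_EFFECTS for e in self.altorf_effects)

    @property
    def most_severe_alteration(self) -> Optional[str]:
        effects = {e.effect for e in self.altorf_effects}
        for eff in _SEVERITY:
            if eff in effects:
                return eff
        return None


def apply_snv(seq: str, snv: SNV) -> str:
    """Return ``seq`` with the substitution applied (ref allele verified)."""
    if not (0 <= snv.tpos < len(seq)):
        raise ValueError(f"SNV position {snv.tpos} outside sequence of length {len(seq)}")
    observed = seq[snv.tpos]
    if observed != snv.ref:
        raise ValueError(
            f"ref mismatch at {snv.transcript_id}:{snv.tpos}: "
            f"expected {snv.ref}, transcript has {observed}"
        )
    return seq[: snv.tpos] + snv.alt + seq[snv.tpos + 1 :]


def effect_on_orf(
    snv: SNV,
    orf: ORF,
    transcript: Transcript,
    code: GeneticCode = STANDARD_CODE,
) -> VariantEffect:
    """Classify one SNV's consequence within one ORF.

    Classification on the ref/alt codon pair: both sense and equal ->
    synonymous; both stop -> stop_retained; sense->stop -> nonsense;
    stop->sense -> stop_loss; a change destroying the start codon ->
    start_loss; otherwise missense; any N in the codon -> unknown.
    """
    idx, cpos = codon_position(orf, snv.tpos)
    cstart = orf.start + 3 * idx
    ref_codon = transcript.sequence[cstart : cstart + 3]
    if ref_codon[cpos - 1] != snv.ref:
        raise ValueError(
            f"ref mismatch at {snv.transcript_id}:{snv.tpos}: "
            f"expected {snv.ref}, transcript has {ref_codon[cpos - 1]}"
        )
    alt_codon = ref_codon[: cpos - 1] + snv.alt + ref_codon[cpos:]
    ref_aa = code.aa(ref_codon)
    alt_aa = code.aa(alt_codon)
    if "X" in (ref_aa, alt_aa):
        effect = "unknown"
    elif ref_aa == alt_aa:
        effect = "stop_retained" if ref_aa == STOP else "synonymous"
    elif alt_aa == STOP:
        effect = "nonsense"
    elif ref_aa == STOP:
        effect = "stop_loss"
    elif idx == 0:
        effect = "start_loss"
    else:
        effect = "missense"
    return VariantEffect(
        orf_id=orf.orf_id,
        effect=effect,
        codon_index=idx,
        codon_pos=cpos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def annotate_variant(
    snv: SNV,
    transcript: Transcript,
    altorfs: Iterable[ORF],
    code: GeneticCode = STANDARD_CODE,
    cds_orf: Optional[ORF] = None,
) -> DualEffectRecord:
    """Annotate one SNV against the canonical frame and all overlapping
    altORFs.  ``cds_orf`` may carry the precomputed canonical ORF."""
    canonical = None
    if transcript.cds is not None:
        if cds_orf is None:
            cds_orf = canonical_orf(transcript, code)
        if cds_orf.contains(snv.tpos):
            canonical = effect_on_orf(snv, cds_orf, transcript, code)
    effects = [
        effect_on_orf(snv, orf, transcript, code)
        for orf in altorfs
        if orf.contains(snv.tpos)
    ]
    rec = DualEffectRecord(snv=snv, canonical_effect=canonical, altorf_effects=effects)
    rec.silent_but_altering = rec.canonical_silent and rec.altering_hit
    return rec


@dataclass
class ScanResult:
    """Records plus the summary counters of a transcriptome-wide scan."""

    records: list
    n_input: int = 0
    n_skipped: int = 0
    n_synonymous: int = 0
    n_positional_hits: int = 0
    n_altering_hits: int = 0


def scan_silent_altering(
    variants: Iterable[SNV],
    transcriptome: Iterable[Transcript],
    params: OrfParams = OrfParams(),
    code: GeneticCode = STANDARD_CODE,
    altorfs_by_transcript: Optional[dict] = None,
) -> ScanResult:
    """Annotate a variant set against predicted altORFs, transcriptome-wide.

    Counters are occurrence-weighted (a recurrent SNV listed k times counts
    k); variants on unknown transcripts are skipped with a warning and
    counted.  ``altorfs_by_transcript`` may carry precomputed predictions.
    """
    by_id = {t.id: t for t in transcriptome}
    if altorfs_by_transcript is None:
        altorfs_by_transcript = {
            tid: predict_altorfs(t, params, code) for tid, t in by_id.items()
        }
    cds_orfs = {
        tid: canonical_orf(t, code) for tid, t in by_id.items() if t.cds is not None
    }
    result = ScanResult(records=[])
    for snv in sorted(variants, key=lambda v: (v.transcript_id, v.tpos, v.alt)):
        result.n_input += snv.occurrence_count
        transcript = by_id.get(snv.transcript_id)
        if transcript is None:
            log.warning("SNV on unknown transcript %s skipped", snv.transcript_id)
            result.n_skipped += snv.occurrence_count
            continue
        rec = annotate_variant(
            snv,
            transcript,
            altorfs_by_transcript[snv.transcript_id],
            code,
            cds_orf=cds_orfs.get(snv.transcript_id),
        )
        result.records.append(rec)
        w = snv.occurrence_count
        if rec.canonical_silent:
            result.n_synonymous += w
            if rec.positional_hit:
                result.n_positional_hits += w
            if rec.altering_hit:
                result.n_altering_hits += w
    return result
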