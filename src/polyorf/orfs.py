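"""Alternative ORF enumeration and classification.

An alternative ORF (altORF) is any ATG-initiated reading frame on a mature
transcript — in the 5'UTR (uORF), 3'UTR (dORF), overlapping the canonical CDS
in a shifted frame (nested or partial), or on a lncRNA — distinct from the
annotated CDS itself.  In-frame CDS-overlapping ORFs (truncations/extensions,
frame offset 0) are not altORFs and are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core import ORF, GeneticCode, STANDARD_CODE, Transcript, translate

__all__ = [
    "OrfParams",
    "enumerate_orfs",
    "classify_orf",
    "predict_altorfs",
    "canonical_orf",
    "CATEGORIES",
]

log = logging.getLogger(__name__)

CATEGORIES = (
    "canonical",
    "uORF",
    "dORF",
    "overlap_nested",
    "overlap_partial",
    "lncRNA_orf",
)


@dataclass(frozen=True)
class OrfParams:
    """Tunable ORF-calling parameters.

    ``min_aa`` — minimum protein length in amino acids, stop excluded
    (default 30, the OpenProt-style cut-off).  ``smorf_max_aa`` tags ORFs
    shorter than 100 codons as smORFs (annotation only).  By default only the
    5'-most start per (frame, stop) is reported.
    """

    min_aa: int = 30
    require_stop: bool = True
    start_codons: frozenset = frozenset({"ATG"})
    report_all_starts: bool = False
    smorf_max_aa: int = 100

    def __post_init__(self) -> None:
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        for c in self.start_codons:
            if len(c) != 3 or set(c) - set("ACGT"):
                raise ValueError(f"invalid start codon {c!r}")


def enumerate_orfs(
    seq: str,
    params: OrfParams = OrfParams(),
    transcript_id: str = "",
    code: GeneticCode = STANDARD_CODE,
) -> list[ORF]:
    """Enumerate qualifying ORFs in all three frames of ``seq``.

    Each ORF runs from a start codon to the first in-frame stop (inclusive);
    when no stop occurs before the transcript end and ``require_stop`` is
    False, it runs to the last complete codon with ``has_stop=False``.
    Output is sorted by (start, end).
    """
    if not seq:
        return []
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")

    out: list[ORF] = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []  # open starts awaiting a stop, 5'-most first
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if code.is_stop(codon):
                out.extend(_emit(seq, starts, i + 3, True, params, transcript_id, code))
                starts = []
            elif codon in params.start_codons:
                starts.append(i)
            i += 3
        if starts and not params.require_stop:
            out.extend(_emit(seq, starts, i, False, params, transcript_id, code))
    out.sort(key=lambda o: (o.start, o.end))
    return out


def _emit(seq, starts, end, has_stop, params, transcript_id, code):
    if not params.report_all_starts:
        starts = starts[:1]
    for s in starts:
        body = seq[s : end - 3] if has_stop else seq[s:end]
        if not body:
            continue  # start codon immediately followed by stop with no body? (ATG+stop)
        protein, _ = translate(body, code)
        if len(protein) * 3 != len(body):
            # internal stop can only arise from the walk logic being wrong
            raise AssertionError("internal stop inside ORF body")  # pragma: no cover
        if len(protein) < params.min_aa:
            continue
        yield ORF(
            transcript_id=transcript_id,
            start=s,
            end=end,
            protein=protein,
            has_stop=has_stop,
        )


def classify_orf(orf: ORF, transcript: Transcript) -> str:
    """Assign an ORF its class relative to the transcript's canonical CDS.

    Also fills ``orf.frame_offset_vs_cds`` on CDS-bearing transcripts.
    Classes: lncRNA_orf (no CDS), uORF (entirely 5' of the CDS), dORF
    (entirely 3'), overlap_nested (inside the CDS), overlap_partial (crossing
    a CDS boundary), canonical (the CDS interval itself).
    """
    if not (0 <= orf.start < orf.end <= len(transcript.sequence)):
        raise ValueError(f"ORF {orf.interval} outside transcript bounds")
    if transcript.cds is None:
        orf.category = "lncRNA_orf"
        orf.frame_offset_vs_cds = None
        return orf.category
    cs, ce = transcript.cds
    orf.frame_offset_vs_cds = (orf.start - cs) % 3
    if (orf.start, orf.end) == (cs, ce):
        orf.category = "canonical"
    elif orf.end <= cs:
        orf.category = "uORF"
    elif orf.start >= ce:
        orf.category = "dORF"
    elif cs <= orf.start and orf.end <= ce:
        orf.category = "overlap_nested"
    else:
        orf.category = "overlap_partial"
    return orf.category


def canonical_orf(transcript: Transcript, code: GeneticCode = STANDARD_CODE) -> ORF:
    """The annotated CDS as an ORF object (category 'canonical')."""
    if transcript.cds is None:
        raise ValueError(f"transcript {transcript.id} has no CDS")
    s, e = transcript.cds
    protein, terminated = translate(transcript.sequence[s:e], code)
    return ORF(
        transcript_id=transcript.id,
        start=s,
        end=e,
        protein=protein,
        has_stop=terminated,
        category="canonical",
        frame_offset_vs_cds=0,
    )


def predict_altorfs(
    transcript: Transcript,
    params: OrfParams = OrfParams(),
    code: GeneticCode = STANDARD_CODE,
) -> list[ORF]:
    """Predict classified alternative ORFs on a transcript.

    Drops the canonical interval itself and any CDS-overlapping ORF in frame
    offset 0 (in-frame truncations/extensions).  Same-frame ORFs that do not
    overlap the CDS (e.g. a uORF in the CDS's absolute frame) are altORFs.
    """
    orfs = enumerate_orfs(transcript.sequence, params, transcript.id, code)
    kept = []
    cds = transcript.cds
    for orf in orfs:
        classify_orf(orf, transcript)
        if cds is not None:
            if (orf.start, orf.end) == tuple(cds):
                continue
            overlaps = orf.start < cds[1] and orf.end > cds[0]
            if overlaps and orf.frame_offset_vs_cds == 0:
                continue
        orf.is_smorf = orf.length_aa < params.smorf_max_aa
        kept.append(orf)
    return kept
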