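"""Independent oracles used by the tests.

These deliberately re-derive results by a different route than the package:
a positional brute-force ORF scanner, Biopython whole-protein translation
diffs, and direct construction of random CDS-bearing transcripts.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

from polyorf.core import Transcript
from polyorf.orfs import OrfParams

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


def brute_force_orfs(seq: str, params: OrfParams):
    """Scan every position for a start codon and walk codons to a stop.

    Returns sorted (start, end, has_stop) triples after applying the
    min-length, require-stop and 5'-most-start-per-(frame, stop) rules.
    """
    n = len(seq)
    found = []
    for i in range(n - 2):
        if seq[i : i + 3] not in params.start_codons:
            continue
        j = i
        stop_end = None
        while j + 3 <= n:
            if seq[j : j + 3] in STOPS:
                stop_end = j + 3
                break
            j += 3
        if stop_end is not None:
            end, has_stop = stop_end, True
        else:
            if params.require_stop:
                continue
            end, has_stop = i + 3 * ((n - i) // 3), False
        aa_len = (end - i) // 3 - (1 if has_stop else 0)
        if aa_len >= params.min_aa:
            found.append((i, end, has_stop))
    if not params.report_all_starts:
        first = {}
        for s, e, h in sorted(found):
            first.setdefault((s % 3, e, h), (s, e, h))
        found = list(first.values())
    return sorted(found)


def brute_force_altorfs(transcript: Transcript, params: OrfParams):
    """Brute-force enumeration plus the altORF filter rules."""
    out = []
    cds = transcript.cds
    for s, e, h in brute_force_orfs(transcript.sequence, params):
        if cds is not None:
            if (s, e) == tuple(cds):
                continue
            overlaps = s < cds[1] and e > cds[0]
            if overlaps and (s - cds[0]) % 3 == 0:
                continue
        out.append((s, e, h))
    return sorted(out)


def whole_protein_effect(snv, orf, transcript) -> str:
    """Classify an SNV by translating the whole ORF before and after.

    Uses Biopython translation; independent of the package's codon-local
    classification path.
    """
    ref_nt = transcript.sequence[orf.start : orf.end]
    rel = snv.tpos - orf.start
    assert ref_nt[rel] == snv.ref
    alt_nt = ref_nt[:rel] + snv.alt + ref_nt[rel + 1 :]
    ref_aa = str(Seq(ref_nt).translate())
    alt_aa = str(Seq(alt_nt).translate())
    j = rel // 3
    assert ref_aa[:j] == alt_aa[:j] and ref_aa[j + 1 :] == alt_aa[j + 1 :]
    r, a = ref_aa[j], alt_aa[j]
    if r == a:
        return "stop_retained" if r == "*" else "synonymous"
    if a == "*":
        return "nonsense"
    if r == "*":
        return "stop_loss"
    if j == 0:
        return "start_loss"
    return "missense"


def random_cds_transcript(rng: np.random.Generator, length: int, tid: str = "RT") -> Transcript:
    """A random-background transcript with one valid embedded CDS.

    Unlike the synthetic-data generator, incidental ORFs are left in place —
    that is the point for oracle-equivalence testing.
    """
    seq = list(rng.choice(list("ACGT"), size=length))
    max_cds = min(600, length - 12)
    cds_len = 3 * int(rng.integers(20, max_cds // 3 + 1))
    start = int(rng.integers(3, length - cds_len - 2))
    seq[start : start + 3] = list("ATG")
    for p in range(start + 3, start + cds_len - 3, 3):
        seq[p : p + 3] = list(SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))])
    seq[start + cds_len - 3 : start + cds_len] = list(STOPS[rng.integers(0, 3)])
    tr = Transcript(id=tid, gene_id=f"{tid}G", sequence="".join(seq), cds=(start, start + cds_len))
    assert tr.validate() == []
    return tr
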