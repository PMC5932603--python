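"""Standard-format I/O: FASTA+GFF3 transcriptome loading, VCF SNV projection,
bedGraph conservation tracks, and TSV/JSON/BED/FASTA result writers.

Conventions: GFF3 and VCF are 1-based and converted to the package's
internal 0-based half-open transcript space at this boundary; BED and
bedGraph are 0-based half-open.  Minus-strand genes are emitted as
sense-strand transcripts; variant alleles are complemented during
projection.  Annotation violations cause record-level rejection with
diagnostics — the run continues and a summary is logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import numpy as np

from .conservation import ConservationTrack, PeriodicityResult
from .core import CoordinateMap, Transcript, reverse_complement
from .variants import DualEffectRecord, SNV, ScanResult

log = logging.getLogger(__name__)

__all__ = [
    "load_transcriptome",
    "load_transcripts_tsv",
    "read_vcf_snvs",
    "read_bedgraph_track",
    "write_orf_table",
    "write_protein_fasta",
    "write_orf_bed",
    "write_effects_tsv",
    "write_variant_summary_tsv",
    "write_gene_report_json",
    "write_periodicity_tsv",
    "write_bedgraph",
]


# ---------------------------------------------------------------------------
# loading


def load_transcriptome(
    fasta_path,
    gff3_path,
    rejections: Optional[List[Tuple[str, str]]] = None,
) -> List[Transcript]:
    """Load spliced transcripts from a genome FASTA and a GFF3 annotation.

    Exon and CDS features must be keyed to their transcript via ``Parent``.
    Transcript invariants (ATG start, terminal stop, frame-0 CDS length) are
    enforced; violators are rejected with per-record diagnostics collected in
    ``rejections`` and logged, and the run continues.
    """
    import gffutils
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    if rejections is None:
        rejections = []
    transcripts: List[Transcript] = []
    rna_types = {"mRNA", "transcript", "lnc_RNA", "ncRNA"}
    for feat in db.all_features():
        if feat.featuretype not in rna_types:
            continue
        tid = feat.id.split(":", 1)[-1]
        parents = list(db.parents(feat, featuretype="gene"))
        gene_id = parents[0].id.split(":", 1)[-1] if parents else tid
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(feat, featuretype="exon")),
        )
        if not exons:
            rejections.append((tid, "no exon features"))
            continue
        if feat.seqid not in genome:
            rejections.append((tid, f"chromosome {feat.seqid} absent from FASTA"))
            continue
        chrom_seq = genome[feat.seqid]
        spliced = "".join(chrom_seq[s:e] for s, e in exons)
        strand = feat.strand
        if strand == "-":
            spliced = reverse_complement(spliced)
        cmap = CoordinateMap(exons, strand) if strand in "+-" else None
        cds_intervals = sorted(
            ((c.start - 1, c.end) for c in db.children(feat, featuretype="CDS")),
        )
        cds = None
        if cds_intervals:
            if cmap is None:
                rejections.append((tid, "CDS on strand-less transcript"))
                continue
            tpos = sorted(
                cmap.to_transcript(g)
                for s, e in cds_intervals
                for g in range(s, e)
            )
            if tpos != list(range(tpos[0], tpos[-1] + 1)):
                rejections.append((tid, "CDS does not project to a contiguous transcript interval"))
                continue
            cds = (tpos[0], tpos[-1] + 1)
        tr = Transcript(
            id=tid,
            gene_id=gene_id,
            sequence=spliced,
            exons=exons,
            strand=strand,
            cds=cds,
            chrom=feat.seqid,
        )
        problems = tr.validate()
        if problems:
            rejections.append((tid, "; ".join(problems)))
            continue
        transcripts.append(tr)
    if rejections:
        log.warning(
            "rejected %d transcript record(s): %s",
            len(rejections),
            "; ".join(f"{t}: {m}" for t, m in rejections[:5]),
        )
    return transcripts


def load_transcripts_tsv(
    fasta_path,
    cds_tsv_path,
    rejections: Optional[List[Tuple[str, str]]] = None,
) -> List[Transcript]:
    """Load transcript-space sequences (FASTA) plus a CDS table.

    The TSV needs columns ``transcript_id``, ``gene_id``, ``cds_start``,
    ``cds_end`` (0-based half-open, empty start/end for lncRNA).
    """
    import pandas as pd
    from Bio import SeqIO

    if rejections is None:
        rejections = []
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(cds_tsv_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    transcripts = []
    for row in table.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            rejections.append((tid, "sequence absent from FASTA"))
            continue
        cds = None
        if not (pd.isna(row.cds_start) or pd.isna(row.cds_end)):
            cds = (int(row.cds_start), int(row.cds_end))
        tr = Transcript(id=tid, gene_id=row.gene_id, sequence=seqs[tid], cds=cds)
        problems = tr.validate()
        if problems:
            rejections.append((tid, "; ".join(problems)))
            continue
        transcripts.append(tr)
    return transcripts


def read_vcf_snvs(
    path,
    transcriptome: Iterable[Transcript],
    counters: Optional[Dict[str, int]] = None,
) -> List[SNV]:
    """Read SNVs from a VCF and project them into transcript space.

    Multiallelic records are split; non-SNV and intronic/off-transcript
    records are skipped and counted.  Alleles are complemented on the minus
    strand.  Identical records aggregate into ``occurrence_count``.
    """
    from cyvcf2 import VCF

    by_chrom: Dict[str, list] = {}
    for tr in transcriptome:
        if tr.chrom is None or not tr.exons:
            continue
        by_chrom.setdefault(tr.chrom, []).append((tr, tr.coordinate_map()))
    if counters is None:
        counters = {}
    counters.setdefault("n_records", 0)
    counters.setdefault("n_non_snv", 0)
    counters.setdefault("n_unmapped", 0)
    counters.setdefault("n_ref_mismatch", 0)
    agg: Dict[Tuple[str, int, str, str], int] = {}
    for rec in VCF(str(path)):
        counters["n_records"] += 1
        pos0 = rec.POS - 1
        for alt in rec.ALT:
            if len(rec.REF) != 1 or len(alt) != 1 or set(rec.REF + alt) - set("ACGT"):
                counters["n_non_snv"] += 1
                continue
            mapped = False
            for tr, cmap in by_chrom.get(rec.CHROM, []):
                tpos = cmap.to_transcript(pos0)
                if tpos is None:
                    continue
                ref, talt = rec.REF, alt
                if tr.strand == "-":
                    ref, talt = reverse_complement(ref), reverse_complement(talt)
                if tr.sequence[tpos] != ref:
                    counters["n_ref_mismatch"] += 1
                    log.warning(
                        "VCF ref %s does not match transcript %s base %s at %d; skipped",
                        ref, tr.id, tr.sequence[tpos], tpos,
                    )
                    continue
                agg[(tr.id, tpos, ref, talt)] = agg.get((tr.id, tpos, ref, talt), 0) + 1
                mapped = True
            if not mapped:
                counters["n_unmapped"] += 1
    return [
        SNV(tid, tpos, ref, alt, occurrence_count=n)
        for (tid, tpos, ref, alt), n in sorted(agg.items())
    ]


def read_bedgraph_track(
    path,
    region: Union[str, Tuple[str, int, int]],
    interpolate: bool = False,
) -> ConservationTrack:
    """Expand a bedGraph file into a per-base conservation track.

    ``region`` is either a chromosome/transcript id (full extent) or a
    (chrom, start, end) triple, 0-based half-open.  Intervals must be sorted
    and non-overlapping; interior gaps raise unless ``interpolate`` is set,
    in which case they are filled linearly.
    """
    if isinstance(region, str):
        chrom, rstart, rend = region, None, None
    else:
        chrom, rstart, rend = region
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: malformed bedGraph line")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if c == chrom:
                rows.append((s, e, v))
    if not rows:
        raise ValueError(f"no bedGraph intervals for region {chrom!r}")
    rows.sort()
    for (s1, e1, _), (s2, _, _) in zip(rows, rows[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping bedGraph intervals at {chrom}:{s2}")
    if rstart is None:
        rstart, rend = rows[0][0], max(e for _, e, _ in rows)
    scores = np.full(rend - rstart, np.nan)
    for s, e, v in rows:
        s, e = max(s, rstart), min(e, rend)
        if s < e:
            scores[s - rstart : e - rstart] = v
    missing = np.isnan(scores)
    if missing.any():
        if not interpolate:
            first = int(np.flatnonzero(missing)[0]) + rstart
            raise ValueError(
                f"gap in conservation track {chrom} at position {first} "
                "(pass interpolate=True to fill linearly)"
            )
        if missing[0] or missing[-1]:
            raise ValueError(f"track {chrom} has a gap at a region edge; cannot interpolate")
        idx = np.arange(len(scores))
        scores[missing] = np.interp(idx[missing], idx[~missing], scores[~missing])
    return ConservationTrack(region_id=chrom, scores=scores, offset=rstart)


# ---------------------------------------------------------------------------
# writers


def _genomic_footprint(tr: Transcript, start: int, end: int) -> Tuple[str, str]:
    cmap = tr.coordinate_map()
    if cmap is None:
        return ".", "."
    g = sorted((cmap.to_genomic(start), cmap.to_genomic(end - 1)))
    return str(g[0]), str(g[1] + 1)


def write_orf_table(orfs: Iterable, transcriptome: Iterable[Transcript], path) -> None:
    """Predicted-altORF TSV (transcript-space 0-based half-open, plus the
    genomic footprint span when exon structure is known)."""
    by_id = {t.id: t for t in transcriptome}
    cols = (
        "transcript_id\tgene_id\torf_id\tstart\tend\tgenomic_start\tgenomic_end"
        "\tframe_offset\tcategory\tlength_aa\tsmorf_flag\tprotein"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for orf in orfs:
            tr = by_id[orf.transcript_id]
            gs, ge = _genomic_footprint(tr, orf.start, orf.end)
            off = "." if orf.frame_offset_vs_cds is None else str(orf.frame_offset_vs_cds)
            fh.write(
                f"{tr.id}\t{tr.gene_id}\t{orf.orf_id}\t{orf.start}\t{orf.end}\t{gs}\t{ge}"
                f"\t{off}\t{orf.category}\t{orf.length_aa}\t{int(orf.is_smorf)}\t{orf.protein}\n"
            )


def write_protein_fasta(orfs: Iterable, path) -> None:
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id} {orf.category} {orf.length_aa}aa\n{orf.protein}\n")


def write_orf_bed(orfs: Iterable, transcriptome: Iterable[Transcript], path) -> None:
    """BED6 genomic footprints (0-based half-open) of predicted ORFs."""
    by_id = {t.id: t for t in transcriptome}
    with open(path, "w") as fh:
        for orf in orfs:
            tr = by_id[orf.transcript_id]
            if tr.chrom is None or not tr.exons:
                continue
            gs, ge = _genomic_footprint(tr, orf.start, orf.end)
            fh.write(f"{tr.chrom}\t{gs}\t{ge}\t{orf.orf_id}\t0\t{tr.strand}\n")


def write_effects_tsv(records: Iterable[DualEffectRecord], path) -> None:
    """One row per (variant, ORF) effect, canonical frame included."""
    cols = (
        "transcript_id\ttpos\tref\talt\toccurrences\tframe\torf_id\teffect"
        "\tcodon_index\tcodon_pos\tref_codon\talt_codon\tref_aa\talt_aa"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for rec in records:
            v = rec.snv
            rows = []
            if rec.canonical_effect is not None:
                rows.append(("canonical", rec.canonical_effect))
            rows.extend(("altORF", e) for e in rec.altorf_effects)
            for frame_label, e in rows:
                fh.write(
                    f"{v.transcript_id}\t{v.tpos}\t{v.ref}\t{v.alt}\t{v.occurrence_count}"
                    f"\t{frame_label}\t{e.orf_id}\t{e.effect}\t{e.codon_index}\t{e.codon_pos}"
                    f"\t{e.ref_codon}\t{e.alt_codon}\t{e.ref_aa}\t{e.alt_aa}\n"
                )


def write_variant_summary_tsv(records: Iterable[DualEffectRecord], path) -> None:
    cols = (
        "transcript_id\ttpos\tref\talt\toccurrences\tcanonical_effect"
        "\tn_altorfs_hit\tmost_severe_alt_effect\tsilent_but_altering"
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for rec in records:
            v = rec.snv
            canon = rec.canonical_effect.effect if rec.canonical_effect else "."
            worst = rec.most_severe_alteration or "."
            fh.write(
                f"{v.transcript_id}\t{v.tpos}\t{v.ref}\t{v.alt}\t{v.occurrence_count}"
                f"\t{canon}\t{len(rec.altorf_effects)}\t{worst}\t{int(rec.silent_but_altering)}\n"
            )


def write_gene_report_json(
    transcriptome: Iterable[Transcript],
    altorfs_by_transcript: Dict[str, list],
    records: Iterable[DualEffectRecord],
    path,
) -> None:
    """Per-gene report: transcript length, CDS interval, altORF intervals,
    and relative SNV positions (for diagram-style rendering)."""
    recs_by_tid: Dict[str, list] = {}
    for rec in records:
        recs_by_tid.setdefault(rec.snv.transcript_id, []).append(rec)
    payload = {}
    for tr in transcriptome:
        payload[tr.gene_id] = {
            "transcript_id": tr.id,
            "length_nt": len(tr.sequence),
            "cds": list(tr.cds) if tr.cds else None,
            "altorfs": [
                {
                    "orf_id": o.orf_id,
                    "start": o.start,
                    "end": o.end,
                    "category": o.category,
                    "frame_offset": o.frame_offset_vs_cds,
                    "length_aa": o.length_aa,
                }
                for o in altorfs_by_transcript.get(tr.id, [])
            ],
            "snvs": [
                {
                    "tpos": r.snv.tpos,
                    "relative_pos": r.snv.tpos / len(tr.sequence),
                    "canonical_effect": r.canonical_effect.effect if r.canonical_effect else None,
                    "silent_but_altering": r.silent_but_altering,
                }
                for r in sorted(recs_by_tid.get(tr.id, []), key=lambda r: r.snv.tpos)
            ],
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_periodicity_tsv(results: Iterable[PeriodicityResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("region_id\tframe\tdelta\tp_value\tdetected\n")
        for res in results:
            for f in range(3):
                fh.write(
                    f"{res.region_id}\t{f}\t{res.deltas[f]:.6g}\t{res.p_values[f]:.6g}"
                    f"\t{int(f in res.detected_frames)}\n"
                )


def write_bedgraph(track: ConservationTrack, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.scores):
            p = track.offset + i
            fh.write(f"{track.region_id}\t{p}\t{p + 1}\t{v:.6f}\n")
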