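"""Seeded synthetic data: transcripts with planted altORFs, canonical-
synonymous SNV sets, and conservation tracks with codon-position-3
depression — with ground truth emitted for every fixture.

The generator stands in for tumour-variant and altORF-database inputs.  It
plants ORFs *constructively* (start codon written, body sampled without
in-frame stops, terminal stop written) and then removes incidental ORFs
above the length cut-off outside planted/canonical footprints, so the truth
table is complete by construction: ``predict_altorfs`` on an emitted
transcript returns exactly the planted set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import CoordinateMap, STANDARD_CODE, Transcript, reverse_complement
from .conservation import ConservationTrack
from .enrichment import SynonymousSpace, enumerate_synonymous_space
from .orfs import OrfParams, canonical_orf, predict_altorfs
from .variants import SNV, annotate_variant

__all__ = [
    "OrfPlantSpec",
    "VariantSpec",
    "TrackSpec",
    "SimConfig",
    "PlantedOrf",
    "TranscriptTruth",
    "VariantTruth",
    "TruthTable",
    "SimBundle",
    "simulate_transcript",
    "simulate_variants",
    "simulate_conservation_track",
    "simulate_bundle",
    "write_fixture_bundle",
    "sample_protein_lengths",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class OrfPlantSpec:
    """How many altORFs to plant per transcript, and their length law.

    Lengths are log-normal with the configured median (45 aa, the reported
    median of predicted altProts), truncated to [min_len_aa, max_len_aa].
    """

    n_uorf: int = 1
    n_dorf: int = 1
    n_nested: int = 1
    n_partial: int = 0
    n_lncrna_orf: int = 1
    length_median_aa: float = 45.0
    length_log_sigma: float = 0.35
    min_len_aa: int = 30
    max_len_aa: int = 300


@dataclass(frozen=True)
class VariantSpec:
    """Canonical-synonymous SNV draws per transcript.

    ``enrichment_factor`` weights synonymous (position, alt) pairs inside
    altORF footprints; 1 is the exact chance model, values > 1 emulate the
    observed excess of altORF hits, ``inf`` puts all weight on hits.
    """

    n_per_transcript: int = 40
    enrichment_factor: float = 2.0


@dataclass(frozen=True)
class TrackSpec:
    """Conservation-track synthesis: codon positions 1-2 of every ORF
    footprint are elevated by ``depth`` over position 3; Gaussian noise."""

    depth: float = 1.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_transcripts: int = 25
    n_lncrna: int = 5
    length_range: Tuple[int, int] = (900, 3000)
    gc_content: float = 0.5
    cds_fraction: float = 0.5
    orfs: OrfPlantSpec = OrfPlantSpec()
    variants: VariantSpec = VariantSpec()
    track: TrackSpec = TrackSpec()

    def __post_init__(self) -> None:
        if self.n_transcripts < 0 or self.n_lncrna < 0:
            raise ValueError("transcript counts must be >= 0")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0.05 <= self.cds_fraction <= 0.9):
            raise ValueError("cds_fraction out of range")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 300:
            raise ValueError("invalid length_range (min 300 nt)")
        if self.variants.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")


# ---------------------------------------------------------------------------
# truth table


@dataclass
class PlantedOrf:
    start: int
    end: int
    category: str
    frame_offset_vs_cds: Optional[int]
    protein: str


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    cds: Optional[Tuple[int, int]]
    planted: List[PlantedOrf] = field(default_factory=list)
    track_frames: set = field(default_factory=set)


@dataclass
class VariantTruth:
    transcript_id: str
    tpos: int
    ref: str
    alt: str
    occurrence_count: int
    positional_hit: bool
    altering_hit: bool
    silent_but_altering: bool


@dataclass
class TruthTable:
    transcripts: Dict[str, TranscriptTruth] = field(default_factory=dict)
    variants: List[VariantTruth] = field(default_factory=list)


@dataclass
class SimBundle:
    config: SimConfig
    transcripts: List[Transcript]
    variants: List[SNV]
    tracks: Dict[str, ConservationTrack]
    truth: TruthTable


# ---------------------------------------------------------------------------
# low-level samplers


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> List[str]:
    return list(rng.choice(list(_BASES), size=n, p=_base_probs(gc)))


def _sample_codon(
    rng: np.random.Generator,
    gc: float,
    template: Tuple[Optional[str], ...] = (None, None, None),
    forbid=(),
    allow_only=None,
) -> Optional[str]:
    """Sample one codon at base composition ``gc``, honouring frozen
    positions in ``template``; None if no admissible codon exists."""
    probs = _base_probs(gc)
    cands: List[str] = [""]
    weights: List[float] = [1.0]
    for k in range(3):
        new_c, new_w = [], []
        choices = [template[k]] if template[k] is not None else list(_BASES)
        for c, w in zip(cands, weights):
            for b in choices:
                new_c.append(c + b)
                new_w.append(w * (probs[_BASES.index(b)] if template[k] is None else 1.0))
        cands, weights = new_c, new_w
    keep = [
        (c, w)
        for c, w in zip(cands, weights)
        if c not in forbid and (allow_only is None or c in allow_only)
    ]
    if not keep:
        return None
    cands, weights = zip(*keep)
    w = np.asarray(weights, dtype=float)
    return str(rng.choice(list(cands), p=w / w.sum()))


def sample_protein_lengths(rng: np.random.Generator, n: int, spec: OrfPlantSpec) -> np.ndarray:
    """Planted altProt lengths (aa): truncated log-normal around the median."""
    draws = np.exp(rng.normal(math.log(spec.length_median_aa), spec.length_log_sigma, size=n))
    return np.clip(np.round(draws), spec.min_len_aa, spec.max_len_aa).astype(int)


# ---------------------------------------------------------------------------
# transcript synthesis


def _canonical_codons_ok(seq: List[str], cds: Tuple[int, int], lo: int, hi: int) -> bool:
    """No canonical-frame stop among CDS body codons intersecting [lo, hi)."""
    cs, ce = cds
    first = cs + 3 * max(0, (lo - cs) // 3)
    for p in range(first, min(ce - 3, hi + 2), 3):
        if p < cs + 3:
            continue  # start codon is frozen
        if "".join(seq[p : p + 3]) in _STOPS:
            return False
    return True


def _try_plant(
    seq: List[str],
    start: int,
    end: int,
    frozen: set,
    cds: Optional[Tuple[int, int]],
    rng: np.random.Generator,
    gc: float,
) -> Optional[List[str]]:
    """Write an ORF into a copy of ``seq``; None if infeasible here."""
    work = seq.copy()
    for k, b in enumerate("ATG"):
        p = start + k
        if p in frozen and work[p] != b:
            return None
        work[p] = b
    for _ in range(60):
        trial = work.copy()
        feasible = True
        for p in range(start + 3, end - 3, 3):
            tmpl = tuple(trial[p + k] if (p + k) in frozen else None for k in range(3))
            codon = _sample_codon(rng, gc, tmpl, forbid=_STOPS)
            if codon is None:
                return None
            trial[p : p + 3] = list(codon)
        p = end - 3
        tmpl = tuple(trial[p + k] if (p + k) in frozen else None for k in range(3))
        codon = _sample_codon(rng, gc, tmpl, allow_only=_STOPS)
        if codon is None:
            return None
        trial[p : p + 3] = list(codon)
        if cds is not None and not _canonical_codons_ok(trial, cds, start, end):
            continue  # altORF codons induced a canonical-frame stop; resample
        return trial
    return None


def _overlaps_any(start: int, end: int, intervals) -> bool:
    return any(start < e and end > s for s, e in intervals)


def _placement_starts(
    category: str, orf_nt: int, length: int, cds: Optional[Tuple[int, int]]
) -> List[int]:
    """All candidate start positions for a planted ORF of one class."""
    if cds is None:
        return list(range(0, length - orf_nt + 1))
    cs, ce = cds
    if category == "uORF":
        return list(range(0, cs - orf_nt + 1))
    if category == "dORF":
        return list(range(ce, length - orf_nt + 1))
    if category == "overlap_nested":
        return [
            s
            for s in range(cs + 1, ce - 3 - orf_nt + 1)
            if (s - cs) % 3 != 0 and s >= cs + 3
        ]
    if category == "overlap_partial":
        lo = max(cs + 3, ce - orf_nt + 1)
        hi = min(ce - 3, length - orf_nt)
        return [s for s in range(lo, hi + 1) if (s - cs) % 3 != 0 and s + orf_nt > ce]
    raise ValueError(f"unknown planted category {category!r}")


def _kill_extra_orf(
    seq: List[str],
    orf_start: int,
    frozen: set,
    cds: Optional[Tuple[int, int]],
    rng: np.random.Generator,
) -> bool:
    """Destroy an incidental ORF by mutating one base of its start codon."""
    for k in rng.permutation(3):
        p = orf_start + int(k)
        if p in frozen:
            continue
        old = seq[p]
        for b in rng.permutation(list(set(_BASES) - {old})):
            seq[p] = str(b)
            if cds is not None and cds[0] <= p < cds[1]:
                if not _canonical_codons_ok(seq, cds, p, p + 1):
                    continue
            return True
        seq[p] = old
    return False


def _requested_classes(spec: OrfPlantSpec, lncrna: bool) -> List[str]:
    if lncrna:
        return ["lncRNA_orf"] * spec.n_lncrna_orf
    return (
        ["overlap_nested"] * spec.n_nested
        + ["overlap_partial"] * spec.n_partial
        + ["uORF"] * spec.n_uorf
        + ["dORF"] * spec.n_dorf
    )


def simulate_transcript(
    config: SimConfig,
    rng: np.random.Generator,
    index: int = 0,
    lncrna: bool = False,
) -> Tuple[Transcript, TranscriptTruth]:
    """Generate one transcript with its planted-ORF ground truth.

    Raises ``RuntimeError`` if the configuration cannot be realised (e.g. an
    altORF class that cannot fit its host region).
    """
    spec = config.orfs
    tid = f"LNC{index:04d}.1" if lncrna else f"TX{index:04d}.1"
    gene = f"LNCG{index:04d}" if lncrna else f"GENE{index:04d}"
    for _attempt in range(30):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        if lncrna:
            cds = None
            frozen: set = set()
        else:
            cds_len = max(60, int(round(length * config.cds_fraction / 3)) * 3)
            utr_total = length - cds_len
            if utr_total < 60:
                raise RuntimeError("cds_fraction leaves no room for UTRs")
            utr5 = int(utr_total * rng.uniform(0.35, 0.65))
            cds = (utr5, utr5 + cds_len)
            frozen = set(range(utr5, utr5 + 3)) | set(range(cds[1] - 3, cds[1]))
        seq = _rand_bases(rng, length, config.gc_content)
        if cds is not None:
            cs, ce = cds
            seq[cs : cs + 3] = list("ATG")
            for p in range(cs + 3, ce - 3, 3):
                seq[p : p + 3] = list(_sample_codon(rng, config.gc_content, forbid=_STOPS))
            seq[ce - 3 : ce] = list(_sample_codon(rng, config.gc_content, allow_only=_STOPS))

        planted: List[Tuple[int, int]] = []
        ok = True
        for category in _requested_classes(spec, lncrna):
            placed = False
            for _try in range(80):
                aa = int(sample_protein_lengths(rng, 1, spec)[0])
                orf_nt = 3 * (aa + 1)
                starts = [
                    s
                    for s in _placement_starts(category, orf_nt, length, cds)
                    if not _overlaps_any(s, s + orf_nt, planted)
                ]
                if not starts:
                    continue
                s = int(starts[rng.integers(0, len(starts))])
                trial = _try_plant(seq, s, s + orf_nt, frozen, cds, rng, config.gc_content)
                if trial is None:
                    continue
                seq = trial
                planted.append((s, s + orf_nt))
                frozen |= set(range(s, s + orf_nt))
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        # incidental-ORF cleanup: predicted set must equal the planted set
        params = OrfParams(min_aa=spec.min_len_aa)
        converged = False
        for _round in range(60):
            transcript = Transcript(id=tid, gene_id=gene, sequence="".join(seq), cds=cds)
            predicted = predict_altorfs(transcript, params)
            pred_set = {o.interval for o in predicted}
            extra = pred_set - set(planted)
            missing = set(planted) - pred_set
            if not extra and not missing:
                converged = True
                break
            if missing and not extra:
                break  # a kill broke a planted ORF's context; regenerate
            killed_any = False
            for s, _e in sorted(extra):
                if _kill_extra_orf(seq, s, frozen, cds, rng):
                    killed_any = True
            if not killed_any:
                break
        if not converged:
            continue

        transcript = Transcript(id=tid, gene_id=gene, sequence="".join(seq), cds=cds)
        _attach_gene_structure(transcript, rng, index, lncrna)
        by_interval = {o.interval: o for o in predict_altorfs(transcript, params)}
        truth = TranscriptTruth(transcript_id=tid, gene_id=gene, cds=cds)
        for s, e in sorted(planted):
            orf = by_interval[(s, e)]
            truth.planted.append(
                PlantedOrf(
                    start=s,
                    end=e,
                    category=orf.category,
                    frame_offset_vs_cds=orf.frame_offset_vs_cds,
                    protein=orf.protein,
                )
            )
        truth.track_frames = {s % 3 for s, _ in planted}
        if cds is not None:
            truth.track_frames.add(cds[0] % 3)
        return transcript, truth
    raise RuntimeError(
        f"could not realise transcript {tid} under the given configuration"
    )


_CHROM = "chrS"
_INTRON = 250
_GAP = 500


def _attach_gene_structure(
    transcript: Transcript, rng: np.random.Generator, index: int, lncrna: bool
) -> None:
    """Give the transcript a two-exon genomic structure on a synthetic
    chromosome; strand alternates with index to exercise projection."""
    length = len(transcript.sequence)
    strand = "+" if index % 2 == 0 else "-"
    split = int(rng.integers(int(0.3 * length), int(0.7 * length) + 1))
    # 8 kb stride fits any locus (max 3000 nt transcript + 250 nt intron);
    # lncRNA loci sit in the second half of each stride
    offset = 1000 + index * 8000 + (4000 if lncrna else 0)
    # genomic plus-strand sequence of the locus
    if strand == "+":
        l1 = split
    else:
        l1 = length - split
    exon1 = (offset, offset + l1)
    exon2 = (offset + l1 + _INTRON, offset + l1 + _INTRON + (length - l1))
    transcript.exons = [exon1, exon2]
    transcript.strand = strand
    transcript.chrom = _CHROM


def genomic_exon_sequences(transcript: Transcript) -> List[str]:
    """Plus-strand genomic sequence of each exon, in genomic order."""
    seq = transcript.sequence
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    out = []
    acc = 0
    for s, e in transcript.exons:
        out.append(seq[acc : acc + (e - s)])
        acc += e - s
    return out


# ---------------------------------------------------------------------------
# variants and tracks


def simulate_variants(
    transcript: Transcript,
    n: int,
    enrichment_factor: float,
    rng: np.random.Generator,
    space: Optional[SynonymousSpace] = None,
    altorfs: Optional[list] = None,
) -> Tuple[List[SNV], List[VariantTruth]]:
    """Draw canonical-synonymous SNVs from the transcript's synonymous space.

    Pairs inside altORF footprints carry sampling weight
    ``enrichment_factor`` (1 = exact null, 0 = never, inf = only hits).
    Duplicate draws are aggregated into ``occurrence_count``.
    """
    if transcript.cds is None:
        raise ValueError(f"transcript {transcript.id} has no CDS")
    if altorfs is None:
        altorfs = predict_altorfs(transcript)
    if space is None:
        space = enumerate_synonymous_space(transcript, altorfs)
    if space.n_pairs == 0:
        raise ValueError(f"transcript {transcript.id} has an empty synonymous space")
    if math.isinf(enrichment_factor):
        weights = space.positional.astype(float)
    else:
        weights = np.where(space.positional, float(enrichment_factor), 1.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    draws = rng.choice(space.n_pairs, size=n, p=weights / total)
    counts: Dict[int, int] = {}
    for d in draws:
        counts[int(d)] = counts.get(int(d), 0) + 1
    cds_orf = canonical_orf(transcript)
    snvs: List[SNV] = []
    truths: List[VariantTruth] = []
    for i in sorted(counts):
        tpos, alt = space.pairs[i]
        ref = transcript.sequence[tpos]
        snv = SNV(transcript.id, tpos, ref, alt, occurrence_count=counts[i])
        rec = annotate_variant(snv, transcript, altorfs, cds_orf=cds_orf)
        assert rec.canonical_silent, "sampled SNV not canonical-synonymous"
        snvs.append(snv)
        truths.append(
            VariantTruth(
                transcript_id=transcript.id,
                tpos=tpos,
                ref=ref,
                alt=alt,
                occurrence_count=counts[i],
                positional_hit=bool(space.positional[i]),
                altering_hit=bool(space.altering[i]),
                silent_but_altering=rec.silent_but_altering,
            )
        )
    return snvs, truths


def simulate_conservation_track(
    transcript: Transcript,
    truth: TranscriptTruth,
    depth: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> ConservationTrack:
    """Gaussian-noise track with codon positions 1-2 elevated by ``depth``
    within every planted/canonical ORF footprint (additive superposition)."""
    if depth < 0 or noise_sd < 0:
        raise ValueError("depth and noise_sd must be >= 0")
    n = len(transcript.sequence)
    scores = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    footprints = [(p.start, p.end) for p in truth.planted]
    if truth.cds is not None:
        footprints.append(tuple(truth.cds))
    for s, e in footprints:
        idx = np.arange(s, e)
        scores[idx[(idx - s) % 3 != 2]] += depth
    return ConservationTrack(region_id=transcript.id, scores=scores)


# ---------------------------------------------------------------------------
# bundles


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Generate the full fixture set for one configuration, deterministically."""
    rng = np.random.default_rng(config.seed)
    transcripts: List[Transcript] = []
    truth = TruthTable()
    variants: List[SNV] = []
    tracks: Dict[str, ConservationTrack] = {}
    for i in range(config.n_transcripts):
        tr, tt = simulate_transcript(config, rng, index=i, lncrna=False)
        transcripts.append(tr)
        truth.transcripts[tr.id] = tt
    for i in range(config.n_lncrna):
        tr, tt = simulate_transcript(config, rng, index=i, lncrna=True)
        transcripts.append(tr)
        truth.transcripts[tr.id] = tt
    for tr in transcripts:
        if tr.cds is None:
            continue
        if config.variants.n_per_transcript > 0:
            snvs, vt = simulate_variants(
                tr,
                config.variants.n_per_transcript,
                config.variants.enrichment_factor,
                rng,
            )
            variants.extend(snvs)
            truth.variants.extend(vt)
    for tr in transcripts:
        tracks[tr.id] = simulate_conservation_track(
            tr, truth.transcripts[tr.id], config.track.depth, config.track.noise_sd, rng
        )
    return SimBundle(
        config=config, transcripts=transcripts, variants=variants, tracks=tracks, truth=truth
    )


def transcript_interval_to_genomic(
    cmap: CoordinateMap, start: int, end: int
) -> List[Tuple[int, int]]:
    """Project a transcript-space interval to merged genomic intervals."""
    gpos = sorted(cmap.to_genomic(t) for t in range(start, end))
    out: List[Tuple[int, int]] = []
    for g in gpos:
        if out and g == out[-1][1]:
            out[-1] = (out[-1][0], g + 1)
        else:
            out.append((g, g + 1))
    return out


def write_fixture_bundle(config: SimConfig, outdir) -> Dict[str, Path]:
    """Write a bundle as genome FASTA + GFF3 + VCF + bedGraph + truth JSON.

    The bundle round-trips losslessly through :mod:`polyorf.io`.
    Conservation tracks use transcript coordinate space (chrom column =
    transcript id).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    rng = np.random.default_rng(config.seed + 1)  # filler sequence only

    # --- genome FASTA ------------------------------------------------------
    pieces: List[str] = []
    cursor = 0
    features: List[str] = []
    for tr in sorted(bundle.transcripts, key=lambda t: t.exons[0][0]):
        exon_seqs = genomic_exon_sequences(tr)
        for (s, e), seq in zip(tr.exons, exon_seqs):
            if s > cursor:
                pieces.append("".join(_rand_bases(rng, s - cursor, config.gc_content)))
            pieces.append(seq)
            cursor = e
        features.extend(_gff3_features(tr))
    genome = "".join(pieces)
    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{_CHROM}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")

    gff_path = outdir / "annotations.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(features) + "\n")

    # --- VCF ---------------------------------------------------------------
    vcf_path = outdir / "variants.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CHROM}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        by_id = {t.id: t for t in bundle.transcripts}
        lines = []
        for snv in bundle.variants:
            tr = by_id[snv.transcript_id]
            cmap = tr.coordinate_map()
            gpos = cmap.to_genomic(snv.tpos)
            ref, alt = snv.ref, snv.alt
            if tr.strand == "-":
                ref, alt = reverse_complement(ref), reverse_complement(alt)
            for _ in range(snv.occurrence_count):
                lines.append((gpos, f"{_CHROM}\t{gpos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t."))
        for _, line in sorted(lines):
            fh.write(line + "\n")

    # --- bedGraph tracks (transcript space) --------------------------------
    bg_path = outdir / "conservation.bedgraph"
    with open(bg_path, "w") as fh:
        for tid in sorted(bundle.tracks):
            track = bundle.tracks[tid]
            for i, v in enumerate(track.scores):
                fh.write(f"{tid}\t{i}\t{i + 1}\t{v:.6f}\n")

    # --- truth -------------------------------------------------------------
    truth_path = outdir / "truth.json"
    payload = {
        "config": asdict(config),
        "transcripts": {
            tid: {
                "gene_id": tt.gene_id,
                "cds": list(tt.cds) if tt.cds else None,
                "planted": [asdict(p) for p in tt.planted],
                "track_frames": sorted(tt.track_frames),
            }
            for tid, tt in bundle.truth.transcripts.items()
        },
        "variants": [asdict(v) for v in bundle.truth.variants],
    }
    truth_path.write_text(json.dumps(payload, indent=1))

    return {
        "fasta": fasta_path,
        "gff3": gff_path,
        "vcf": vcf_path,
        "bedgraph": bg_path,
        "truth": truth_path,
    }


def _gff3_features(tr: Transcript) -> List[str]:
    """GFF3 lines (1-based inclusive) for one two-exon transcript."""
    gstart = tr.exons[0][0] + 1
    gend = tr.exons[-1][1]
    ttype = "mRNA" if tr.cds is not None else "lnc_RNA"
    lines = [
        f"{_CHROM}\tpolyorf_sim\tgene\t{gstart}\t{gend}\t.\t{tr.strand}\t.\t"
        f"ID=gene:{tr.gene_id};Name={tr.gene_id}",
        f"{_CHROM}\tpolyorf_sim\t{ttype}\t{gstart}\t{gend}\t.\t{tr.strand}\t.\t"
        f"ID=transcript:{tr.id};Parent=gene:{tr.gene_id}",
    ]
    for k, (s, e) in enumerate(tr.exons, 1):
        lines.append(
            f"{_CHROM}\tpolyorf_sim\texon\t{s + 1}\t{e}\t.\t{tr.strand}\t.\t"
            f"ID=exon:{tr.id}.{k};Parent=transcript:{tr.id}"
        )
    if tr.cds is not None:
        cmap = tr.coordinate_map()
        phase_pos = 0
        intervals = transcript_interval_to_genomic(cmap, *tr.cds)
        if tr.strand == "-":
            intervals = intervals[::-1]  # transcript 5'->3' order for phase
        for k, (s, e) in enumerate(intervals, 1):
            phase = (3 - phase_pos % 3) % 3
            lines.append(
                f"{_CHROM}\tpolyorf_sim\tCDS\t{s + 1}\t{e}\t.\t{tr.strand}\t{phase}\t"
                f"ID=cds:{tr.id}.{k};Parent=transcript:{tr.id}"
            )
            phase_pos += e - s
        if tr.strand == "-":
            # GFF3 rows conventionally sorted by genomic start
            lines[-len(intervals) :] = sorted(
                lines[-len(intervals) :], key=lambda l: int(l.split("\t")[3])
            )
    return lines
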