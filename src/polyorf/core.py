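"""Core domain model: genetic code, transcripts, ORFs, coordinate projection.

Every module in the package works in *transcript space*: 0-based, half-open
intervals on the sense strand of the mature (spliced) transcript.  Genomic
inputs (GFF3, VCF, 1-based) are converted at the I/O boundary; minus-strand
genes are reverse-complemented at load so downstream logic is strand-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Optional, Sequence

__all__ = [
    "GeneticCode",
    "STANDARD_CODE",
    "STOP",
    "Transcript",
    "ORF",
    "CoordinateMap",
    "translate",
    "reverse_complement",
    "codon_position",
]

STOP = "*"

_BASES = "TCAG"
# NCBI transl_table=1 amino acids in TCAG codon order (TTT, TTC, TTA, ...).
_TABLE1_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid table.

    ``codon_to_aa`` maps all 64 DNA trinucleotides to one-letter amino acids,
    with ``*`` marking stop codons.  The default is NCBI translation table 1
    (standard code, stops TAA/TAG/TGA).
    """

    table_id: int = 1
    codon_to_aa: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.codon_to_aa:
            object.__setattr__(self, "codon_to_aa", _standard_table())
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.codon_to_aa)}")

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls(table_id=1)

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        """Load any NCBI translation table (e.g. 2 for vertebrate mito)."""
        if table_id == 1:
            return cls.standard()
        from Bio.Data import CodonTable

        tab = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tab.forward_table)
        for stop in tab.stop_codons:
            mapping[stop] = STOP
        return cls(table_id=table_id, codon_to_aa=mapping)

    def aa(self, codon: str) -> str:
        """Translate one codon; any codon containing N yields 'X'."""
        if len(codon) != 3:
            raise ValueError(f"codon must have length 3, got {codon!r}")
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            if "N" in codon:
                return "X"
            raise ValueError(f"invalid codon {codon!r}") from None

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa.get(codon) == STOP

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, a in self.codon_to_aa.items() if a == STOP)


@lru_cache(maxsize=1)
def _standard_table() -> dict:
    codons = ["".join(c) for c in product(_BASES, repeat=3)]
    return dict(zip(codons, _TABLE1_AA))


STANDARD_CODE = GeneticCode.standard()


def translate(seq: str, code: GeneticCode = STANDARD_CODE) -> tuple[str, bool]:
    """Translate an in-frame DNA string.

    Returns ``(protein, terminated)``: translation stops at the first stop
    codon, ``terminated`` is True iff one was reached.  Codons containing N
    translate to 'X'.

    Raises ``ValueError`` on empty input or length not divisible by 3.
    """
    if not seq:
        raise ValueError("cannot translate empty sequence")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    out = []
    for i in range(0, len(seq), 3):
        aa = code.aa(seq[i : i + 3])
        if aa == STOP:
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


@dataclass
class Transcript:
    """A mature spliced transcript.

    ``sequence`` is the sense strand of the mature transcript.  ``exons`` are
    genomic 0-based half-open intervals in genomic order (may be empty for
    transcript-space-only work).  ``cds`` is the canonical CDS as a
    transcript-space half-open interval, stop codon included, or None for
    lncRNAs.
    """

    id: str
    gene_id: str
    sequence: str
    exons: list = field(default_factory=list)
    strand: Optional[str] = None
    cds: Optional[tuple] = None
    chrom: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, code: GeneticCode = STANDARD_CODE) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        problems = []
        if self.exons:
            exon_len = sum(e - s for s, e in self.exons)
            if exon_len != len(self.sequence):
                problems.append(
                    f"exon length sum {exon_len} != sequence length {len(self.sequence)}"
                )
            if self.strand not in ("+", "-"):
                problems.append(f"exons present but strand is {self.strand!r}")
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                problems.append(f"CDS {self.cds} outside [0, {len(self.sequence)})")
                return problems
            if (e - s) % 3 != 0:
                problems.append(f"CDS length {e - s} not a multiple of 3 (frame)")
            elif e - s < 6:
                problems.append(f"CDS length {e - s} < 6")
            else:
                if self.sequence[s : s + 3] != "ATG":
                    problems.append(f"CDS does not begin with ATG (got {self.sequence[s:s+3]})")
                if not code.is_stop(self.sequence[e - 3 : e]):
                    problems.append(f"CDS does not end in a stop codon (got {self.sequence[e-3:e]})")
        return problems

    def coordinate_map(self) -> Optional["CoordinateMap"]:
        if not self.exons or self.strand not in ("+", "-"):
            return None
        return CoordinateMap(self.exons, self.strand)


@dataclass
class ORF:
    """A located reading frame on a transcript.

    ``start``/``end`` are transcript-space half-open coordinates; the stop
    codon is part of the footprint when present (``has_stop``).  ``protein``
    excludes the stop.  ``frame_offset_vs_cds`` is ``(start - cds.start) % 3``
    on CDS-bearing transcripts, None otherwise.
    """

    transcript_id: str
    start: int
    end: int
    protein: str
    has_stop: bool
    category: str = "unclassified"
    frame_offset_vs_cds: Optional[int] = None
    is_smorf: bool = False

    @property
    def frame(self) -> int:
        return self.start % 3

    @property
    def length_aa(self) -> int:
        n_codons = (self.end - self.start) // 3
        return n_codons - 1 if self.has_stop else n_codons

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    def contains(self, tpos: int) -> bool:
        return self.start <= tpos < self.end


def codon_position(orf: ORF, pos: int) -> tuple[int, int]:
    """Map a transcript position inside an ORF to (codon_index, codon_pos).

    ``codon_pos`` is 1-based (1/2/3; 3 is the wobble position).
    """
    if not (orf.start <= pos < orf.end):
        raise ValueError(f"position {pos} outside ORF [{orf.start}, {orf.end})")
    off = pos - orf.start
    return off // 3, off % 3 + 1


class CoordinateMap:
    """Bidirectional genomic <-> transcript position mapping.

    Exons are genomic 0-based half-open intervals in genomic order; on the
    minus strand transcript position 0 corresponds to the *last* genomic base
    of the last exon.
    """

    def __init__(self, exons: Sequence, strand: str):
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        exons = [tuple(e) for e in exons]
        if not exons:
            raise ValueError("at least one exon required")
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"empty or inverted exon ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap or are unsorted")
        self.exons = exons
        self.strand = strand
        self.length = sum(e - s for s, e in exons)
        # cumulative plus-strand offsets of each exon start
        self._offsets = []
        acc = 0
        for s, e in exons:
            self._offsets.append(acc)
            acc += e - s

    def to_transcript(self, gpos: int) -> Optional[int]:
        """Project a genomic position; None if intronic/out of range."""
        for (s, e), off in zip(self.exons, self._offsets):
            if s <= gpos < e:
                plus = off + (gpos - s)
                return plus if self.strand == "+" else self.length - 1 - plus
        return None

    def to_genomic(self, tpos: int) -> int:
        if not (0 <= tpos < self.length):
            raise ValueError(f"transcript position {tpos} outside [0, {self.length})")
        plus = tpos if self.strand == "+" else self.length - 1 - tpos
        for (s, e), off in zip(self.exons, self._offsets):
            if off <= plus < off + (e - s):
                return s + (plus - off)
        raise AssertionError("unreachable")  # pragma: no cover
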