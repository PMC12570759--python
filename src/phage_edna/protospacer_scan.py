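"""PAM-adjacent protospacer enumeration on phage genomes.

Spacer acquisition in *S. thermophilus* requires a protospacer-adjacent
motif (PAM) next to the acquired sequence.  This module scans both
strands of a genome for all matches of a degenerate IUPAC PAM, pairs each
match with the adjacent fixed-length protospacer, counts protospacers
inside amplicon regions, maps acquired spacer sequences back to a genome,
and partitions the protospacers of two related phages into shared and
phage-unique sets (the basis of a multiplex detection design that only
reports acquisition from one phage).

Coordinates are 0-based half-open throughout; output is BED-like.

Default motifs: the CR1 array's PAM is NNAGAAW on the protospacer's
3' side and the CR3 array's is NGGNG, both with 30-nt protospacers.
These are literature conventions for strain DGCC7710, shipped as
overridable configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "DEFAULT_MOTIFS",
    "PamMotif",
    "Protospacer",
    "Region",
    "SpacerMatch",
    "scan_protospacers",
    "count_in_region",
    "map_spacers",
    "unique_protospacers",
    "UniquenessPartition",
    "read_fasta",
    "write_bed",
]

#: IUPAC nucleotide codes -> the set of concrete bases they stand for.
#: A genome "N" (unknown base) never satisfies a non-N motif position;
#: a motif "N" matches anything, including genome N.
IUPAC_CODES = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGTN",
}

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class PamMotif:
    """A degenerate PAM pattern and where it sits relative to the
    protospacer (``side``: the PAM is 3' or 5' of the protospacer)."""

    iupac: str
    side: Literal["three_prime", "five_prime"] = "three_prime"
    protospacer_len: int = 30

    def __post_init__(self) -> None:
        bad = [c for c in self.iupac.upper() if c not in IUPAC_CODES]
        if bad:
            raise ValueError(
                f"invalid IUPAC code(s) {bad} in motif {self.iupac!r}"
            )
        if self.side not in ("three_prime", "five_prime"):
            raise ValueError(f"side must be three_prime or five_prime")
        if self.protospacer_len <= 0:
            raise ValueError("protospacer_len must be > 0")

    def regex(self) -> re.Pattern:
        # Lookahead so overlapping PAM matches are all reported.
        body = "".join(f"[{IUPAC_CODES[c]}]" for c in self.iupac.upper())
        return re.compile(f"(?=({body}))")


DEFAULT_MOTIFS = {
    "cr1": PamMotif("NNAGAAW", "three_prime", 30),
    "cr3": PamMotif("NGGNG", "three_prime", 30),
}


@dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region start must precede end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Protospacer:
    """One protospacer: the interval covers the protospacer only, with the
    PAM location carried separately so amplicon containment can require
    the full protospacer+PAM footprint."""

    contig: str
    start: int
    end: int
    strand: str
    seq: str
    pam_seq: str
    pam_start: int
    pam_end: int

    @property
    def footprint(self) -> tuple[int, int]:
        """Interval spanning protospacer and PAM together."""
        return (min(self.start, self.pam_start), max(self.end, self.pam_end))


def _clean_seq(seq: str, name: str = "sequence") -> str:
    s = str(seq).upper()
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"{name} contains non-ACGTN characters: {bad}")
    return s


def scan_protospacers(genome, motif: PamMotif, contig: str | None = None) -> list[Protospacer]:
    """All PAM matches on both strands, each with its adjacent protospacer.

    ``genome`` may be a string, a ``Seq``, or a ``SeqRecord``.  Matches
    whose protospacer would run off the contig are dropped.  Overlapping
    matches are all reported; the result is sorted by (start, strand).
    """
    if hasattr(genome, "seq"):
        contig = contig or genome.id
        seq = _clean_seq(str(genome.seq), "genome")
    else:
        contig = contig or "contig"
        seq = _clean_seq(str(genome), "genome")
    n = len(seq)
    if n < motif.protospacer_len + len(motif.iupac):
        raise ValueError(
            "genome shorter than protospacer + PAM "
            f"({motif.protospacer_len} + {len(motif.iupac)})"
        )
    pattern = motif.regex()
    L = motif.protospacer_len
    m = len(motif.iupac)
    out: list[Protospacer] = []

    def emit(strand: str, pam_start: int, pam_end: int, s: int, e: int) -> None:
        if s < 0 or e > n:
            return
        sub = seq[s:e]
        pam = seq[pam_start:pam_end]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
            pam = str(Seq(pam).reverse_complement())
        out.append(
            Protospacer(contig, s, e, strand, sub, pam, pam_start, pam_end)
        )

    for match in pattern.finditer(seq):
        i = match.start()
        if motif.side == "three_prime":
            emit("+", i, i + m, i - L, i)
        else:
            emit("+", i, i + m, i + m, i + m + L)

    rc = str(Seq(seq).reverse_complement())
    for match in pattern.finditer(rc):
        j = match.start()
        pam_start, pam_end = n - (j + m), n - j
        if motif.side == "three_prime":
            # 3' of the protospacer on the minus strand = genomic left
            emit("-", pam_start, pam_end, pam_end, pam_end + L)
        else:
            emit("-", pam_start, pam_end, pam_start - L, pam_start)

    out.sort(key=lambda p: (p.start, p.strand))
    return out


def count_in_region(
    protospacers: Iterable[Protospacer],
    region: Region,
    mode: str = "contained",
) -> int:
    """Count protospacers inside a region.

    ``mode="contained"`` (default) requires the full protospacer+PAM
    footprint inside the region — an amplicon can only template a
    protospacer it fully contains.  ``mode="overlap"`` counts any
    protospacer interval overlapping the region.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    count = 0
    for p in protospacers:
        if p.contig != region.contig:
            continue
        if mode == "contained":
            lo, hi = p.footprint
            if lo >= region.start and hi <= region.end:
                count += 1
        else:
            if p.start < region.end and p.end > region.start:
                count += 1
    return count


@dataclass(frozen=True)
class SpacerMatch:
    """One placement of a spacer sequence on a genome."""

    spacer_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int


def map_spacers(
    spacers: Sequence, genome, max_mismatch: int = 0, contig: str | None = None
) -> list[SpacerMatch]:
    """Map spacer sequences back onto a genome, both strands.

    Exact matching by substring search; with ``max_mismatch > 0`` a
    sliding Hamming-distance scan (no indels — acquired spacers are exact
    copies of their protospacer up to sequencing error).  Returns every
    placement; a spacer absent from the genome simply contributes none.
    """
    if hasattr(genome, "seq"):
        contig = contig or genome.id
        gseq = _clean_seq(str(genome.seq), "genome")
    else:
        contig = contig or "contig"
        gseq = _clean_seq(str(genome), "genome")
    matches: list[SpacerMatch] = []
    for idx, spacer in enumerate(spacers):
        if hasattr(spacer, "seq"):
            sid = spacer.id
            sseq = _clean_seq(str(spacer.seq), f"spacer {spacer.id}")
        else:
            sid = f"spacer{idx}"
            sseq = _clean_seq(str(spacer), f"spacer {idx}")
        if len(sseq) > len(gseq):
            raise ValueError(f"spacer {sid!r} is longer than the genome")
        for strand, query in (
            ("+", sseq),
            ("-", str(Seq(sseq).reverse_complement())),
        ):
            if max_mismatch == 0:
                start = gseq.find(query)
                while start != -1:
                    matches.append(
                        SpacerMatch(sid, contig, start, start + len(query), strand, 0)
                    )
                    start = gseq.find(query, start + 1)
            else:
                k = len(query)
                for start in range(len(gseq) - k + 1):
                    mm = sum(
                        1 for a, b in zip(gseq[start : start + k], query) if a != b
                    )
                    if mm <= max_mismatch:
                        matches.append(
                            SpacerMatch(sid, contig, start, start + k, strand, mm)
                        )
    matches.sort(key=lambda m: (m.spacer_id, m.start, m.strand))
    return matches


@dataclass(frozen=True)
class UniquenessPartition:
    """Protospacers of two phages split by cross-genome presence."""

    unique_to_a: tuple[Protospacer, ...]
    unique_to_b: tuple[Protospacer, ...]
    shared_in_a: tuple[Protospacer, ...]
    shared_in_b: tuple[Protospacer, ...]


def unique_protospacers(phage_a, phage_b, motif: PamMotif) -> UniquenessPartition:
    """Partition each phage's protospacers by presence in the other genome.

    A protospacer is "shared" when its exact sequence occurs anywhere in
    the other genome, on either strand (a spacer with that sequence would
    be protective against both phages); otherwise it is unique to its
    phage and only protective against it.
    """

    def seq_of(genome) -> str:
        return _clean_seq(
            str(genome.seq) if hasattr(genome, "seq") else str(genome), "genome"
        )

    seq_a, seq_b = seq_of(phage_a), seq_of(phage_b)
    hay_a = seq_a + "#" + str(Seq(seq_a).reverse_complement())
    hay_b = seq_b + "#" + str(Seq(seq_b).reverse_complement())
    protos_a = scan_protospacers(phage_a, motif, contig="phage_a")
    protos_b = scan_protospacers(phage_b, motif, contig="phage_b")
    unique_a = tuple(p for p in protos_a if p.seq not in hay_b)
    shared_a = tuple(p for p in protos_a if p.seq in hay_b)
    unique_b = tuple(p for p in protos_b if p.seq not in hay_a)
    shared_b = tuple(p for p in protos_b if p.seq in hay_a)
    return UniquenessPartition(unique_a, unique_b, shared_a, shared_b)


def read_fasta(path) -> list:
    """Read FASTA records (Biopython SeqRecords, uppercased)."""
    records = list(SeqIO.parse(path, "fasta"))
    for rec in records:
        rec.seq = Seq(_clean_seq(str(rec.seq), rec.id))
    return records


def write_bed(protospacers: Iterable[Protospacer], path) -> None:
    """Write protospacers as BED-like TSV:
    contig, start, end, name, score, strand, pam_seq."""
    with open(path, "w") as fh:
        for i, p in enumerate(protospacers):
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\tprotospacer_{i}\t0\t"
                f"{p.strand}\t{p.pam_seq}\n"
            )
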