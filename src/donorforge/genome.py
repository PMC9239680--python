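"""Strand-aware gene models backed by FASTA + GFF3.

All internal coordinates are 0-based, half-open, on the forward genomic
strand; GFF3 is converted from/to its 1-based closed dialect only at the
file boundary.  Design logic elsewhere in the package works in *gene
orientation* (5'/3' relative to the transcribed strand) but stores genomic
coordinates, so every position in an output file is directly comparable to
the input annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class Interval(NamedTuple):
    """0-based half-open genomic interval."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


# intron kinds
CODING = "coding"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
MIXED = "mixed"


@dataclass(frozen=True)
class Intron:
    """An intron of one transcript, classified against that transcript's CDS.

    ``phase`` is the cumulative upstream CDS length modulo 3 and is defined
    only for coding introns (``None`` otherwise).  ``shared`` is filled in by
    :func:`shared_coding_introns` when the intron recurs, with identical
    genomic coordinates and coding classification, in every isoform.
    """

    interval: Interval
    kind: str
    phase: int | None = None
    shared: bool = False

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class TranscriptModel:
    transcript_id: str
    contig: str
    strand: str
    exons: list[Interval]  # ascending genomic order
    cds: list[Interval]  # ascending genomic order; may be empty

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)

    # -- derived geometry ------------------------------------------------
    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_span(self) -> Interval | None:
        if not self.cds:
            return None
        return Interval(self.cds[0].start, self.cds[-1].end)

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def tss(self) -> int:
        """Genomic boundary coordinate of the transcription start."""
        return self.span.start if self.strand == "+" else self.span.end

    @property
    def start_codon(self) -> int | None:
        """Genomic boundary immediately 5' of the first CDS base."""
        if not self.cds:
            return None
        return self.cds[0].start if self.strand == "+" else self.cds[-1].end

    @property
    def stop_codon(self) -> int | None:
        """Genomic boundary immediately 3' of the last CDS base."""
        if not self.cds:
            return None
        return self.cds[-1].end if self.strand == "+" else self.cds[0].start

    def exons_transcription_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def utrs(self) -> tuple[list[Interval], list[Interval]]:
        """(5'UTR, 3'UTR) exonic intervals, ascending genomic order."""
        if not self.cds:
            return [], []
        lo, hi = self.cds[0].start, self.cds[-1].end
        left: list[Interval] = []
        right: list[Interval] = []
        for ex in self.exons:
            if ex.start < lo:
                left.append(Interval(ex.start, min(ex.end, lo)))
            if ex.end > hi:
                right.append(Interval(max(ex.start, hi), ex.end))
        return (left, right) if self.strand == "+" else (right, left)

    @property
    def utr5_length(self) -> int:
        return sum(i.length for i in self.utrs()[0])

    @property
    def utr3_length(self) -> int:
        return sum(i.length for i in self.utrs()[1])


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def span(self) -> Interval:
        return Interval(
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
        )

    @property
    def is_protein_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts)

    @property
    def longest_cds_length(self) -> int:
        return max((t.cds_length for t in self.transcripts), default=0)


@dataclass
class GenomeModel:
    contigs: dict[str, str]
    genes: list[GeneModel]
    provenance: dict[str, str] = field(default_factory=dict)
    skipped_transcripts: list[tuple[str, str]] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def sequence(self, contig: str, interval: Interval, strand: str = "+") -> str:
        return extract_sequence(self, contig, interval, strand)


# ---------------------------------------------------------------------------
# sequence access
# ---------------------------------------------------------------------------

def extract_sequence(
    genome: GenomeModel, contig: str, interval: Interval, strand: str = "+"
) -> str:
    """Sequence of ``interval`` in gene orientation (revcomp for ``-``)."""
    if contig not in genome.contigs:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome.contigs[contig]
    if interval.start < 0 or interval.end > len(seq) or interval.start > interval.end:
        raise ValueError(
            f"interval {interval} out of bounds for contig {contig!r} "
            f"(length {len(seq)})"
        )
    sub = seq[interval.start : interval.end]
    return revcomp(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# intron derivation
# ---------------------------------------------------------------------------

def derive_introns(transcript: TranscriptModel) -> list[Intron]:
    """Introns of one transcript in transcription order, classified by kind.

    An intron is *coding* when the CDS reaches both the upstream exon's
    splice-donor end and the downstream exon's splice-acceptor end, i.e. it
    interrupts the reading frame.  Introns wholly 5' (3') of the CDS in gene
    orientation are 5'UTR (3'UTR) introns; anything else (possible only with
    inconsistent annotation) is ``mixed``.
    """
    if not transcript.exons:
        raise ValueError(f"{transcript.transcript_id}: transcript has no exons")
    exons = transcript.exons  # ascending
    gaps = [
        Interval(exons[i].end, exons[i + 1].start) for i in range(len(exons) - 1)
    ]
    cds = transcript.cds
    cds_ends = {c.end for c in cds}
    cds_starts = {c.start for c in cds}
    lo = cds[0].start if cds else None
    hi = cds[-1].end if cds else None

    introns: list[Intron] = []
    for gap in gaps:
        if not cds:
            kind = MIXED
        elif gap.start in cds_ends and gap.end in cds_starts:
            kind = CODING
        elif gap.end <= lo:
            kind = UTR5 if transcript.strand == "+" else UTR3
        elif gap.start >= hi:
            kind = UTR3 if transcript.strand == "+" else UTR5
        else:
            kind = MIXED
        phase = None
        if kind == CODING:
            if transcript.strand == "+":
                upstream = sum(c.length for c in cds if c.end <= gap.start)
            else:
                upstream = sum(c.length for c in cds if c.start >= gap.end)
            phase = upstream % 3
        introns.append(Intron(interval=gap, kind=kind, phase=phase))
    if transcript.strand == "-":
        introns.reverse()
    return introns


def shared_coding_introns(gene: GeneModel) -> list[Intron]:
    """Coding introns present, with identical genomic coordinates, in every
    annotated isoform of the gene.

    Non-coding transcripts are ignored for the "every isoform" quantifier
    only if the gene has no coding transcript at all (then the result is
    empty); a gene mixing coding and non-coding isoforms requires the intron
    in the coding isoforms and its absence from a non-coding isoform
    disqualifies it, per the strict shared-across-all-isoforms reading.
    """
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: gene has no transcripts")
    per_tx = [derive_introns(t) for t in gene.transcripts]
    coding_sets = [
        {i.interval: i for i in introns if i.kind == CODING} for introns in per_tx
    ]
    if not coding_sets or not all(coding_sets):
        return []
    common = set(coding_sets[0])
    for s in coding_sets[1:]:
        common &= set(s)
    shared = [
        Intron(interval=iv, kind=CODING, phase=coding_sets[0][iv].phase, shared=True)
        for iv in common
    ]
    # gene-orientation 5'->3' order
    shared.sort(key=lambda i: i.interval.start, reverse=(gene.strand == "-"))
    return shared


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def load_annotation(fasta_path: str | Path, gff3_path: str | Path) -> GenomeModel:
    """Read a genome FASTA and GFF3 annotation into a :class:`GenomeModel`.

    Transcripts whose CDS segments fall outside their exons are skipped with
    a logged warning and recorded in ``skipped_transcripts``; a feature on a
    contig missing from the FASTA is fatal.
    """
    fasta_path, gff3_path = Path(fasta_path), Path(gff3_path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    skipped: list[tuple[str, str]] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        if gf.seqid not in contigs:
            raise ValueError(
                f"gene {gf.id}: contig {gf.seqid!r} not present in FASTA"
            )
        transcripts: list[TranscriptModel] = []
        for tf in db.children(gf, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                Interval(c.start - 1, c.end)
                for c in db.children(tf, featuretype="exon", order_by="start")
            ]
            cds = [
                Interval(c.start - 1, c.end)
                for c in db.children(tf, featuretype="CDS", order_by="start")
            ]
            tx = TranscriptModel(
                transcript_id=tf.id, contig=gf.seqid, strand=gf.strand,
                exons=exons, cds=cds,
            )
            bad = [
                c for c in cds
                if not any(e.start <= c.start and c.end <= e.end for e in exons)
            ]
            if bad:
                msg = f"CDS segment(s) outside exon bounds: {bad}"
                log.warning("transcript %s skipped: %s", tf.id, msg)
                skipped.append((tf.id, msg))
                continue
            if cds and tx.cds_length % 3 != 0:
                log.warning(
                    "transcript %s: CDS length %d not divisible by 3",
                    tf.id, tx.cds_length,
                )
            transcripts.append(tx)
        if transcripts:
            genes.append(
                GeneModel(
                    gene_id=gf.id, contig=gf.seqid, strand=gf.strand,
                    transcripts=transcripts,
                )
            )
    genes.sort(key=lambda g: g.gene_id)
    return GenomeModel(
        contigs=contigs,
        genes=genes,
        provenance={"fasta": fasta_path.name, "gff3": gff3_path.name},
        skipped_transcripts=skipped,
    )


def write_fasta(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.contigs:
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gff3(genome: GenomeModel, path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS plus derived UTR features, 1-based closed."""
    lines = ["##gff-version 3"]

    def row(contig, ftype, iv: Interval, strand, attrs, phase="."):
        lines.append(
            "\t".join(
                [contig, "donorforge", ftype, str(iv.start + 1), str(iv.end),
                 ".", strand, str(phase), attrs]
            )
        )

    for g in genome.genes:
        row(g.contig, "gene", g.span, g.strand, f"ID={g.gene_id}")
        for t in g.transcripts:
            row(g.contig, "mRNA", t.span, g.strand,
                f"ID={t.transcript_id};Parent={g.gene_id}")
            for i, ex in enumerate(t.exons, 1):
                row(g.contig, "exon", ex, g.strand,
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}")
            # GFF3 CDS phase: bases to remove from this segment's 5' end
            acc = 0
            order = t.cds if g.strand == "+" else list(reversed(t.cds))
            phased = []
            for c in order:
                phased.append((c, (3 - acc % 3) % 3))
                acc += c.length
            for c, ph in sorted(phased):
                row(g.contig, "CDS", c, g.strand,
                    f"ID={t.transcript_id}.cds;Parent={t.transcript_id}", ph)
            u5, u3 = t.utrs()
            for u in u5:
                row(g.contig, "five_prime_UTR", u, g.strand,
                    f"Parent={t.transcript_id}")
            for u in u3:
                row(g.contig, "three_prime_UTR", u, g.strand,
                    f"Parent={t.transcript_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def translate(dna: str, to_stop: bool = False) -> str:
    dna = dna[: len(dna) - len(dna) % 3]  # trailing partial codon is dropped
    return str(Seq(dna).translate(to_stop=to_stop))
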