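"""Gene eligibility for intronic artificial-exon knock-ins, genome survey,
and per-gene strategy choice.

A gene is *suitable* for the intronic strategy when it has a coding intron,
shared (identical coordinates, coding in every isoform) among all annotated
isoforms, that is strictly longer than the minimum (default 100 nt) and
still leaves at least one cut position after a splice buffer is subtracted
from each side.  Genes that fail this are routed to coding-region
replacement or to the two alternative cassette placements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .genome import (
    CODING,
    UTR5,
    GeneModel,
    GenomeModel,
    Interval,
    Intron,
    derive_introns,
    shared_coding_introns,
)
from .params import DesignParameters


class Strategy(enum.Enum):
    T2AGAL4_INTRONIC = "T2AGAL4_INTRONIC"
    KOZAK_REPLACEMENT = "KOZAK_REPLACEMENT"
    SA_KOZAK_5UTR_INTRON = "SA_KOZAK_5UTR_INTRON"
    T2AGAL4_TWO_CUT = "T2AGAL4_TWO_CUT"
    UNDESIGNABLE = "UNDESIGNABLE"


# unsuitability reasons
NO_SHARED_CODING_INTRON = "no-shared-coding-intron"
ALL_SHARED_INTRONS_TOO_SHORT = "all-shared-introns-too-short"
NO_GUIDE_WINDOW = "no-guide-window"
NO_SPECIFIC_GUIDE = "no-specific-guide"


@dataclass
class SuitabilityReport:
    gene_id: str
    suitable: bool
    qualifying_introns: list[tuple[Intron, Interval]] = field(default_factory=list)
    reason: str | None = None
    n_shared_coding_introns: int = 0
    n_length_qualified: int = 0  # length criterion alone, before guide window

    def __post_init__(self) -> None:
        if self.suitable and not self.qualifying_introns:
            raise ValueError("suitable report must carry qualifying introns")


def classify_gene(
    gene: GeneModel, genome: GenomeModel, params: DesignParameters
) -> SuitabilityReport:
    """Structural suitability of one gene for the intronic strategy.

    The guide *window* of an intron is the cut-position range left after
    removing ``splice_buffer`` nt from each side; guide specificity is
    assessed later (selection may still downgrade a gene with reason
    ``no-specific-guide``).
    """
    if not gene.is_protein_coding:
        raise ValueError(f"{gene.gene_id}: non-coding gene")
    shared = shared_coding_introns(gene)
    if not shared:
        return SuitabilityReport(gene.gene_id, False, reason=NO_SHARED_CODING_INTRON)
    long_enough = [
        i for i in shared if i.length > params.min_suitable_intron_length
    ]
    if not long_enough:
        return SuitabilityReport(
            gene.gene_id, False, reason=ALL_SHARED_INTRONS_TOO_SHORT,
            n_shared_coding_introns=len(shared),
        )
    b = params.splice_buffer
    qualifying = []
    for i in long_enough:
        window = Interval(i.interval.start + b, i.interval.end - b)
        if window.length >= 1:
            qualifying.append((i, window))
    if not qualifying:
        return SuitabilityReport(
            gene.gene_id, False, reason=NO_GUIDE_WINDOW,
            n_shared_coding_introns=len(shared),
            n_length_qualified=len(long_enough),
        )
    return SuitabilityReport(
        gene.gene_id, True, qualifying_introns=qualifying,
        n_shared_coding_introns=len(shared),
        n_length_qualified=len(long_enough),
    )


SURVEY_COLUMNS = [
    "gene_id", "contig", "strand", "n_isoforms", "longest_cds_nt",
    "n_shared_coding_introns", "max_shared_coding_intron_nt",
    "n_length_qualified_introns", "suitable", "reason",
]


@dataclass
class SurveyTable:
    """Per-gene suitability rows plus the class summary.

    ``summary`` carries, per class (with/without a suitable intron), the
    gene count and the mean and median of the longest-isoform CDS length.
    """

    rows: pd.DataFrame
    summary: dict

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, columns=SURVEY_COLUMNS)


def survey(genome: GenomeModel, params: DesignParameters) -> SurveyTable:
    """Genome-wide suitability survey over all protein-coding genes.

    A gene's CDS length is that of its longest annotated CDS.  Rows are
    ordered by gene id so repeated runs are byte-identical.
    """
    records = []
    for gene in sorted(genome.genes, key=lambda g: g.gene_id):
        if not gene.is_protein_coding:
            continue
        rep = classify_gene(gene, genome, params)
        shared = shared_coding_introns(gene)
        records.append(
            {
                "gene_id": gene.gene_id,
                "contig": gene.contig,
                "strand": gene.strand,
                "n_isoforms": len(gene.transcripts),
                "longest_cds_nt": gene.longest_cds_length,
                "n_shared_coding_introns": len(shared),
                "max_shared_coding_intron_nt": max(
                    (i.length for i in shared), default=0
                ),
                "n_length_qualified_introns": rep.n_length_qualified,
                "suitable": rep.suitable,
                "reason": rep.reason or "",
            }
        )
    rows = pd.DataFrame(records, columns=SURVEY_COLUMNS)
    summary: dict = {"n_genes": len(rows), "cds_length_statistic": "longest isoform"}
    for label, suitable in (("with_suitable_intron", True),
                            ("without_suitable_intron", False)):
        sub = rows[rows["suitable"] == suitable] if len(rows) else rows
        summary[label] = {
            "count": int(len(sub)),
            "mean_cds_nt": float(sub["longest_cds_nt"].mean()) if len(sub) else None,
            "median_cds_nt": float(sub["longest_cds_nt"].median()) if len(sub) else None,
        }
    return SurveyTable(rows=rows, summary=summary)


# ---------------------------------------------------------------------------
# strategy choice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideAvailability:
    """Whether placement-rule guides were findable for the replacement
    strategy (filled in by attempting :func:`guides.select_kozak_guides`)."""

    five_prime: bool  # 5'UTR or promoter tier
    three_prime: bool  # 3'UTR or CDS-near-stop tier
    intronic: bool = True  # specific guide inside a qualifying intron


def shared_utr5_introns(gene: GeneModel, params: DesignParameters) -> list[Intron]:
    """5'UTR introns > min length with identical coordinates in all isoforms."""
    per_tx = [
        {i.interval for i in derive_introns(t) if i.kind == UTR5}
        for t in gene.transcripts
    ]
    if not per_tx or not all(per_tx):
        return []
    common = set.intersection(*per_tx)
    return sorted(
        (
            Intron(interval=iv, kind=UTR5, shared=True)
            for iv in common
            if iv.length > params.min_suitable_intron_length
        ),
        key=lambda i: i.interval.start,
    )


def choose_strategy(
    gene: GeneModel,
    report: SuitabilityReport,
    availability: GuideAvailability,
    params: DesignParameters | None = None,
) -> Strategy:
    """Route a gene to a cassette strategy given its suitability report.

    Order of preference: intronic artificial exon; coding-region replacement
    when both flanking guides are findable; splice-acceptor cassette in a
    shared 5'UTR intron; two-cut replacement through a small shared coding
    intron; otherwise undesignable.
    """
    params = params or DesignParameters()
    if report.suitable and availability.intronic:
        return Strategy.T2AGAL4_INTRONIC
    if availability.five_prime and availability.three_prime:
        return Strategy.KOZAK_REPLACEMENT
    if shared_utr5_introns(gene, params):
        return Strategy.SA_KOZAK_5UTR_INTRON
    small = [
        i
        for i in shared_coding_introns(gene)
        if i.length >= params.min_two_cut_intron_length
    ]
    if small and availability.three_prime:
        return Strategy.T2AGAL4_TWO_CUT
    return Strategy.UNDESIGNABLE
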