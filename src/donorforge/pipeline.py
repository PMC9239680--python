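"""End-to-end design pipeline: classify -> choose strategy -> select guides
-> arms -> synthesis template -> assemble -> linearize -> predict HDR."""

from __future__ import annotations

from dataclasses import dataclass

from . import fixtures
from .assembly import (
    EditedLocusPrediction,
    LinearizationReport,
    Plasmid,
    ProteinProduct,
    golden_gate,
    insert_fragment_at_ecorv,
    linearize,
    predict_hdr,
    predict_products,
)
from .donor import (
    ARCH_2XGRNA_INT200,
    ARCH_GRNA_INT200,
    ARCH_INT200,
    BACKBONE_INT200,
    DonorDesign,
    build_synthesis_template,
    extract_homology_arms,
    select_sic,
)
from .genome import GenomeModel
from .guides import (
    GuidePlan,
    GuideSelectionError,
    SelectedGuide,
    reference_transcript,
    select_intronic_guide,
    select_kozak_guides,
    select_two_cut_guides,
)
from .params import DesignParameters
from .parts import SGRNA1_TARGET, PartsLibrary
from .suitability import (
    GuideAvailability,
    Strategy,
    choose_strategy,
    classify_gene,
    shared_utr5_introns,
)


def assess_guide_availability(
    gene, genome, params: DesignParameters, report=None
) -> GuideAvailability:
    """Probe each placement rule so strategy choice can see what is findable."""
    from .guides import find_five_prime_guide, find_three_prime_guide

    five = find_five_prime_guide(gene, genome, params) is not None
    three = find_three_prime_guide(gene, genome, params) is not None
    intronic = False
    if report is not None and report.suitable:
        for intron, _ in report.qualifying_introns:
            try:
                select_intronic_guide(intron, gene, genome, params)
                intronic = True
                break
            except GuideSelectionError:
                continue
    return GuideAvailability(five_prime=five, three_prime=three,
                             intronic=intronic)


def plan_gene(
    genome: GenomeModel, gene_id: str, params: DesignParameters,
    strategy: Strategy | None = None,
) -> tuple[Strategy, GuidePlan | None, object | None]:
    """Strategy and guide plan for one gene; returns the targeted intron
    (when the strategy inserts into one) as the third element."""
    gene = genome.gene(gene_id)
    report = classify_gene(gene, genome, params)
    if strategy is None:
        avail = assess_guide_availability(gene, genome, params, report)
        strategy = choose_strategy(gene, report, avail, params)
    if strategy == Strategy.UNDESIGNABLE:
        return strategy, None, None
    if strategy == Strategy.T2AGAL4_INTRONIC:
        last_err = None
        for intron, _ in report.qualifying_introns:
            try:
                site = select_intronic_guide(intron, gene, genome, params)
            except GuideSelectionError as e:
                last_err = e
                continue
            plan = GuidePlan(strategy.value, [SelectedGuide("intronic", site)])
            return strategy, plan, intron
        raise GuideSelectionError(
            f"{gene_id}: no specific guide in any qualifying intron ({last_err})"
        )
    if strategy == Strategy.KOZAK_REPLACEMENT:
        plan = select_kozak_guides(gene, genome, params)
        return strategy, plan, None
    if strategy == Strategy.SA_KOZAK_5UTR_INTRON:
        introns = shared_utr5_introns(gene, params)
        if not introns:
            raise GuideSelectionError(f"{gene_id}: no shared 5'UTR intron")
        site = select_intronic_guide(introns[0], gene, genome, params)
        plan = GuidePlan(strategy.value, [SelectedGuide("intronic", site)])
        return strategy, plan, introns[0]
    if strategy == Strategy.T2AGAL4_TWO_CUT:
        from .genome import shared_coding_introns

        small = [i for i in shared_coding_introns(gene)
                 if i.length >= params.min_two_cut_intron_length]
        if not small:
            raise GuideSelectionError(f"{gene_id}: no cuttable coding intron")
        intron = small[-1]  # 3'-most, minimizing the residual coding region
        plan = select_two_cut_guides(gene, intron, genome, params)
        return strategy, plan, intron
    raise ValueError(strategy)


def default_architecture(strategy: Strategy, plan: GuidePlan) -> str:
    n = len(plan.guides)
    return ARCH_GRNA_INT200 if n == 1 else ARCH_2XGRNA_INT200


def design_gene(
    genome: GenomeModel,
    gene_id: str,
    params: DesignParameters,
    library: PartsLibrary | None = None,
    architecture: str | None = None,
    strategy: Strategy | None = None,
) -> DonorDesign:
    library = library or PartsLibrary()
    gene = genome.gene(gene_id)
    strategy, plan, intron = plan_gene(genome, gene_id, params, strategy)
    if plan is None:
        raise GuideSelectionError(f"{gene_id}: undesignable")
    architecture = architecture or default_architecture(strategy, plan)
    sic = select_sic(strategy, intron, library)
    tx = reference_transcript(gene)
    arms = extract_homology_arms(genome, gene, plan, params, reference_tx=tx)
    template = build_synthesis_template(architecture, arms, plan, sic,
                                        library, params)
    return DonorDesign(
        gene_id=gene_id, strategy=strategy.value, architecture=architecture,
        plan=plan, arms=arms, sic=sic, template=template,
    )


@dataclass
class SimulationResult:
    intermediate: Plasmid
    donor: Plasmid
    linearization: LinearizationReport
    edited: EditedLocusPrediction
    products: list[ProteinProduct]


def simulate_design(
    genome: GenomeModel,
    design: DonorDesign,
    library: PartsLibrary | None = None,
) -> SimulationResult:
    """Golden Gate, in-vivo linearization, HDR and product prediction for a
    finished design."""
    library = library or PartsLibrary()
    backbone = (fixtures.backbone_ok(library)
                if design.template.backbone_id == BACKBONE_INT200
                else fixtures.backbone_ok2(library))
    intermediate = insert_fragment_at_ecorv(
        backbone, design.template.sequence, f"intermediate_{design.gene_id}"
    )
    sic_plasmid = fixtures.generate_sic_plasmids(library)[design.sic.name]
    donor = golden_gate(intermediate, sic_plasmid, design.sic.enzyme)
    lin = linearize(donor, SGRNA1_TARGET, genome, design)
    edited = predict_hdr(genome, design)
    gene = genome.gene(design.gene_id)
    products = predict_products(edited, gene, design, genome)
    return SimulationResult(
        intermediate=intermediate, donor=donor, linearization=lin,
        edited=edited, products=products,
    )
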