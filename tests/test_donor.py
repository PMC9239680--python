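"""Homology arms, cassette selection, fragment architectures, feasibility,
and tag-fusion donors."""

import random

import pytest

from donorforge.donor import (
    ARCH_2XGRNA_INT200,
    ARCH_GRNA_INT200,
    ARCH_INT200,
    FeasibilityError,
    build_sic_definitions,
    build_synthesis_template,
    check_synthesis_feasibility,
    cloning_site,
    design_tag_fusion,
    extract_homology_arms,
    select_sic,
)
from donorforge.genome import Interval, Intron, extract_sequence, revcomp, translate
from donorforge.guides import reference_transcript
from donorforge.params import DesignParameters
from donorforge.parts import ENZYME_SITES, SFGFP_AA, SFGFP_DNA
from donorforge.suitability import Strategy


def test_intronic_arms_flank_the_cut_exactly(genome, truth, designs, params):
    L = params.homology_arm_length
    for row in truth.rows:
        if row.kind != "suitable":
            continue
        d = designs[row.gene_id]
        gene = genome.gene(row.gene_id)
        cut = d.plan.by_role("intronic").site.cut
        arm5, arm3 = d.arms
        if gene.strand == "+":
            assert arm5.sequence == genome.contigs[gene.contig][cut - L : cut]
            assert arm3.sequence == genome.contigs[gene.contig][cut : cut + L]
        else:
            assert arm5.sequence == revcomp(
                genome.contigs[gene.contig][cut : cut + L])
            assert arm3.sequence == revcomp(
                genome.contigs[gene.contig][cut - L : cut])


def test_kozak_arms_exclude_the_replaced_gene_body(genome, truth, designs):
    for row in truth.rows:
        if row.kind != "kozak":
            continue
        d = designs[row.gene_id]
        gene = genome.gene(row.gene_id)
        cut5 = d.plan.by_role("5prime").site.cut
        cut3 = d.plan.by_role("3prime").site.cut
        arm5, arm3 = d.arms
        # arms terminate exactly at the cuts; the gene body between them is
        # absent from the payload (string-assembly oracle)
        body = extract_sequence(
            genome, gene.contig,
            Interval(min(cut5, cut3), max(cut5, cut3)), gene.strand)
        assert body not in d.payload
        oracle = (arm5.reference + d.sic.insert + arm3.reference)
        assert d.payload == oracle  # no edits on this gene
        tx = reference_transcript(gene)
        atg_dist = abs(tx.start_codon - cut5)
        assert d.payload[arm5.length - 10 :].startswith(
            arm5.sequence[-10:]), "5' arm ends at the cut"
        assert atg_dist > 0


def test_promoter_tier_arm_extends_to_tss_with_single_pam_kill(
        genome, truth, designs, params):
    row = next(r for r in truth.rows if r.kind == "kozak_promoter")
    d = designs[row.gene_id]
    gene = genome.gene(row.gene_id)
    tx = reference_transcript(gene)
    arm5 = d.arms[0]
    assert arm5.length == params.homology_arm_length + abs(
        tx.tss - d.plan.by_role("5prime").site.cut)
    assert len(arm5.edits) == 1
    (edit,) = arm5.edits
    assert edit.reason == "pam-kill"
    assert (edit.ref, edit.alt) == ("G", "C")
    # exactly one substitution relative to the genome
    diffs = [i for i, (a, b) in enumerate(zip(arm5.sequence, arm5.reference))
             if a != b]
    assert diffs == [edit.offset]
    # the surviving guide target is destroyed in the donor arm
    site = d.plan.by_role("5prime").site.site
    assert site in arm5.reference or revcomp(site) in arm5.reference
    assert site not in arm5.sequence and revcomp(site) not in arm5.sequence


def test_kozak_junction_always_reads_arm_caaa_atg(designs):
    for d in designs.values():
        if d.sic.name != "KozakGAL4":
            continue
        arm5 = d.arms[0]
        junction = d.payload[arm5.length - 4 : arm5.length + 7]
        assert junction.endswith("CAAAATG")


def test_select_sic_matches_intron_phase(library):
    for phase in (0, 1, 2):
        intron = Intron(Interval(0, 150), "coding", phase, True)
        sic = select_sic(Strategy.T2AGAL4_INTRONIC, intron, library)
        assert sic.name == f"T2AGAL4-phase{phase}" and sic.phase == phase
    sic = select_sic(Strategy.KOZAK_REPLACEMENT, None, library)
    assert sic.name == "KozakGAL4" and sic.phase is None
    with pytest.raises(ValueError, match="phase"):
        select_sic(Strategy.T2AGAL4_INTRONIC, None, library)


def test_template_part_grammar(designs, library):
    for d in designs.values():
        roles = d.template.part_roles()
        if d.architecture == ARCH_INT200:
            assert roles == ["5'-arm", "sic-cloning-site", "3'-arm"]
        elif d.architecture == ARCH_GRNA_INT200:
            assert roles == [
                "trna-completion", "gene-sgRNA-1-spacer", "sgrna-scaffold",
                "sgrna1-target-site", "5'-arm", "sic-cloning-site", "3'-arm",
            ]
        else:
            assert roles == [
                "trna-completion", "gene-sgRNA-1-spacer", "sgrna-scaffold",
                "trna", "gene-sgRNA-2-spacer", "sgrna-scaffold",
                "sgrna1-target-site", "5'-arm", "sic-cloning-site", "3'-arm",
            ]
        spacers = [s for r, s in d.template.parts if "spacer" in r]
        assert all(len(s) == 20 for s in spacers)


def test_int200_fragment_length_is_sum_of_parts(genome, truth, params, library):
    from donorforge.pipeline import design_gene

    row = next(r for r in truth.rows if r.kind == "suitable")
    d = design_gene(genome, row.gene_id, params, architecture=ARCH_INT200)
    assert len(cloning_site(d.sic.enzyme, d.sic.overhangs)) == 30
    assert len(d.template.sequence) == 200 + 30 + 200  # 430 nt


def test_two_spacers_separated_by_one_full_trna(designs, library):
    for d in designs.values():
        if d.architecture != ARCH_2XGRNA_INT200:
            continue
        roles = d.template.part_roles()
        i1 = roles.index("gene-sgRNA-1-spacer")
        i2 = roles.index("gene-sgRNA-2-spacer")
        between = roles[i1 + 1 : i2]
        assert between.count("trna") == 1
        trna_idx = roles.index("trna")
        assert d.template.parts[trna_idx][1] == library["trna"]


def test_planted_forbidden_site_in_arm_is_fatal(designs, params, library):
    d = next(iter(designs.values()))
    import copy

    bad = copy.deepcopy(d.arms)
    bad[0].sequence = (bad[0].sequence[:50] + ENZYME_SITES["BsaI"]
                       + bad[0].sequence[56:])
    with pytest.raises(FeasibilityError, match="BsaI"):
        build_synthesis_template(d.architecture, bad, d.plan, d.sic,
                                 library, params)


def test_feasibility_flags_match_window_oracle(params):
    rng = random.Random(4)
    frag = "".join(rng.choice("ACGT") for _ in range(500))
    frag = frag[:100] + "GGTCTC" + frag[106:200] + "A" * 12 + frag[212:]
    report = check_synthesis_feasibility(frag, params)
    # oracle: recompute every flag class by brute force
    expected = set()
    for name, site in ENZYME_SITES.items():
        for motif in {site, revcomp(site)}:
            for i in range(len(frag) - 5):
                if frag[i : i + 6] == motif:
                    expected.add(("enzyme-site", i))
    i = 0
    while i < len(frag):
        j = i
        while j < len(frag) and frag[j] == frag[i]:
            j += 1
        if j - i > params.max_homopolymer:
            expected.add(("homopolymer", i))
        i = j
    w = params.gc_window
    lo, hi = params.gc_range
    for i in range(len(frag) - w + 1):
        gc = sum(b in "GC" for b in frag[i : i + w]) / w
        if not lo <= gc <= hi:
            expected.add(("gc-window", i))
    assert {(f.kind, f.position) for f in report.flags} == expected
    assert any(f.kind == "homopolymer" and f.position == 200
               for f in report.flags)


def test_clean_fragment_has_empty_report(designs, params):
    d = next(iter(designs.values()))
    cs = d.template.sequence.find(
        cloning_site(d.sic.enzyme, d.sic.overhangs))
    report = check_synthesis_feasibility(
        d.template.sequence, params, [Interval(cs, cs + 30)])
    assert report.fatal == []


# ---------------------------------------------------------------------------
# tag fusions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tag_gene():
    from donorforge import fixtures as fx

    spec = fx.FixtureSpec(seed=5, genes=[fx.GenePlan("tagfusion", cds_aa=300)])
    genome, truth = fx.generate_genome(spec)
    return genome, genome.gene(truth.rows[0].gene_id), truth.rows[0]


@pytest.mark.parametrize("placement", ["N", "C", 150])
def test_tag_fusion_translation_matches_oracle(tag_gene, library, params, placement):
    genome, gene, row = tag_gene
    tf = design_tag_fusion(gene, genome, SFGFP_DNA, placement, library, params)
    tx = gene.transcripts[0]
    native = translate("".join(
        extract_sequence(genome, gene.contig, c, gene.strand)
        for c in (tx.cds if gene.strand == "+" else list(reversed(tx.cds)))
    )).rstrip("*")
    fusion = tf.fusion_protein.rstrip("*")
    k = {"N": 1, "C": len(native)}.get(placement, placement)
    assert fusion == native[:k] + SFGFP_AA + native[k:]
    assert len(fusion) == len(native) + len(SFGFP_AA)
    if placement == "N":
        assert fusion[0] == "M" and fusion[1:].startswith(SFGFP_AA)


def test_tag_fusion_marker_is_ttaa_flanked(tag_gene, library, params):
    genome, gene, row = tag_gene
    tf = design_tag_fusion(gene, genome, SFGFP_DNA, "C", library, params)
    marker = library["pbac_ir"] + library["marker_3xp3_dsred"] + library["pbac_ir"]
    assert tf.payload_interior.endswith("TTAA" + marker)
    # the 3' arm starts at the same genomic TTAA (duplication convention)
    arm_start = extract_sequence(
        genome, gene.contig,
        Interval(tf.arm3_boundary, tf.arm3_boundary + 4) if gene.strand == "+"
        else Interval(tf.arm3_boundary - 4, tf.arm3_boundary),
        gene.strand)
    assert arm_start == "TTAA"


def test_tag_fusion_rejects_out_of_range_index(tag_gene, library, params):
    genome, gene, row = tag_gene
    with pytest.raises(ValueError, match="outside protein"):
        design_tag_fusion(gene, genome, SFGFP_DNA, 10_000, library, params)


def test_tag_fusion_without_downstream_ttaa_is_an_error(tag_gene, library, params):
    genome, gene, row = tag_gene
    with pytest.raises(ValueError, match="TTAA"):
        design_tag_fusion(gene, genome, SFGFP_DNA, "C", library, params,
                          marker_scan_window=4)
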