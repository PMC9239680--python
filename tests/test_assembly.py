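"""Golden Gate simulation, donor linearization, HDR prediction, and protein
product / molecular-weight prediction."""

import copy

import pytest

from donorforge import fixtures as fx
from donorforge.assembly import (
    AssemblyError,
    FrameInconsistencyError,
    Plasmid,
    digest,
    enumerate_ligation_products,
    golden_gate,
    insert_fragment_at_ecorv,
    linearize,
    predict_hdr,
    predict_products,
    protein_mw,
)
from donorforge.donor import DonorDesign, build_sic_definitions, cloning_site
from donorforge.genome import revcomp
from donorforge.parts import SGRNA1_TARGET, _clean_random_dna
from donorforge.pipeline import design_gene, simulate_design


@pytest.fixture(scope="module")
def sim_matrix(genome, truth, designs):
    out = {}
    for gene_id, d in designs.items():
        out[gene_id] = simulate_design(genome, d)
    return out


# ---------------------------------------------------------------------------
# Golden Gate
# ---------------------------------------------------------------------------

def _toy_intermediate(sic, name="toy_intermediate"):
    cs = cloning_site(sic.enzyme, sic.overhangs)
    seq = _clean_random_dna(180, seed=71) + cs + _clean_random_dna(140, seed=72)
    return Plasmid(name=name, seq=seq), cs


def test_golden_gate_equals_string_splice_oracle(library):
    for name, sic in build_sic_definitions(library).items():
        inter, cs = _toy_intermediate(sic)
        sic_plasmids = fx.generate_sic_plasmids(library)
        product = golden_gate(inter, sic_plasmids[name], sic.enzyme)
        # oracle: replace the cloning site with the overhang-flanked cassette
        expected = inter.seq.replace(cs, sic.insert)
        assert product.canonical() == Plasmid("o", expected).canonical()


def test_golden_gate_is_rotation_invariant(library):
    sic = build_sic_definitions(library)["KozakGAL4"]
    inter, _ = _toy_intermediate(sic)
    carrier = fx.generate_sic_plasmids(library)["KozakGAL4"]
    ref = golden_gate(inter, carrier, sic.enzyme).canonical()
    for k, j in ((37, 101), (200, 5)):
        got = golden_gate(inter.rotated(k), carrier.rotated(j), sic.enzyme)
        assert got.canonical() == ref


def test_mismatched_overhangs_give_zero_products(library):
    sic = build_sic_definitions(library)["KozakGAL4"]
    bad = copy.deepcopy(sic)
    bad.overhangs = ("TTTT", "GGGG")  # carrier releases incompatible ends
    inter, _ = _toy_intermediate(sic)
    carrier = fx.generate_sic_plasmids(library)["KozakGAL4"]
    bad_inter, _ = _toy_intermediate(bad, name="bad_intermediate")
    with pytest.raises(AssemblyError, match="found 0"):
        golden_gate(bad_inter, carrier, sic.enzyme)


def test_ligation_uniqueness_by_bruteforce_enumeration(library):
    sic = build_sic_definitions(library)["T2AGAL4-phase0"]
    inter, _ = _toy_intermediate(sic)
    carrier = fx.generate_sic_plasmids(library)["T2AGAL4-phase0"]
    frags = digest(inter, sic.enzyme) + digest(carrier, sic.enzyme)
    circles = enumerate_ligation_products(frags)
    two_source = [c for c in circles
                  if {f.origin for f in c} == {inter.name, carrier.name}]
    assert len(two_source) == 1


def test_fragment_scan_after_removing_designed_sites_is_clean(designs):
    from donorforge.parts import ENZYME_SITES

    for d in designs.values():
        cs = cloning_site(d.sic.enzyme, d.sic.overhangs)
        remainder = d.template.sequence.replace(cs, "")
        for site in ENZYME_SITES.values():
            assert site not in remainder
            assert revcomp(site) not in remainder


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

def test_linearize_releases_exact_payload(genome, designs, sim_matrix):
    for gene_id, sim in sim_matrix.items():
        d = designs[gene_id]
        assert sim.linearization.payload == d.payload
        assert d.payload in sim.linearization.released
        assert sim.linearization.n_cuts == 2
        assert sim.linearization.genome_collisions == 0


def test_donor_without_sgrna1_sites_is_an_error(genome, designs):
    d = next(iter(designs.values()))
    bare = Plasmid("bare", _clean_random_dna(800, seed=73))
    with pytest.raises(AssemblyError, match="lacks sgRNA1"):
        linearize(bare, SGRNA1_TARGET, genome, d)


def test_sgrna1_genomic_collision_is_a_hard_error(genome, designs, sim_matrix):
    gene_id, sim = next(iter(sim_matrix.items()))
    d = designs[gene_id]
    polluted = copy.deepcopy(genome)
    contig = next(iter(polluted.contigs))
    polluted.contigs[contig] = polluted.contigs[contig] + SGRNA1_TARGET
    with pytest.raises(AssemblyError, match="collides"):
        linearize(sim.donor, SGRNA1_TARGET, polluted, d)


# ---------------------------------------------------------------------------
# HDR prediction
# ---------------------------------------------------------------------------

def test_hdr_junctions_contain_arms_verbatim(designs, sim_matrix):
    for gene_id, sim in sim_matrix.items():
        d = designs[gene_id]
        e = sim.edited
        view = e.sequence if e.strand == "+" else revcomp(e.sequence)
        assert d.arms[0].sequence in view
        assert d.arms[1].sequence in view
        assert d.payload in view


def test_kozak_hdr_equals_string_splice_oracle(genome, truth, designs, sim_matrix):
    for row in truth.rows:
        if row.kind != "kozak":
            continue
        d = designs[row.gene_id]
        e = sim_matrix[row.gene_id].edited
        gene = genome.gene(row.gene_id)
        contig = genome.contigs[gene.contig]
        cut5 = d.plan.by_role("5prime").site.cut
        cut3 = d.plan.by_role("3prime").site.cut
        if gene.strand == "+":
            expected = (contig[:cut5] + d.sic.insert + contig[cut3:])
        else:
            expected = (contig[:cut3] + revcomp(d.sic.insert) + contig[cut5:])
        assert e.sequence == expected


def test_intronic_hdr_grows_the_intron_by_the_insert_length(
        genome, truth, designs, sim_matrix):
    for row in truth.rows:
        if row.kind != "suitable":
            continue
        d = designs[row.gene_id]
        e = sim_matrix[row.gene_id].edited
        gene = genome.gene(row.gene_id)
        assert len(e.sequence) == (len(genome.contigs[gene.contig])
                                   + len(d.sic.insert))


def test_hdr_is_rejected_on_an_already_edited_locus(genome, designs, sim_matrix):
    gene_id, sim = next(iter(sim_matrix.items()))
    d = designs[gene_id]
    edited_genome = copy.deepcopy(genome)
    edited_genome.contigs[sim.edited.contig] = sim.edited.sequence
    with pytest.raises(AssemblyError, match="already edited|multiple loci"):
        predict_hdr(edited_genome, d)


def test_hdr_rejects_multimapping_arms(genome, designs):
    gene_id, d = next(iter(designs.items()))
    dup = copy.deepcopy(genome)
    contig = next(iter(dup.contigs))
    arm_ref = d.arms[0].reference
    arm_genomic = arm_ref if d.arms[0].strand == "+" else revcomp(arm_ref)
    dup.contigs[contig] = dup.contigs[contig] + ("T" * 50) + arm_genomic
    with pytest.raises(AssemblyError, match="multiple loci"):
        predict_hdr(dup, d)


# ---------------------------------------------------------------------------
# products and molecular weights
# ---------------------------------------------------------------------------

def test_molecular_weight_closed_forms():
    # glycine: residue 57.05 + one water 18.02
    assert protein_mw("G") == pytest.approx(75.07, abs=0.05)
    assert protein_mw("GG") == pytest.approx(2 * 57.05 + 18.02, abs=0.1)
    assert protein_mw("AG") == pytest.approx(71.08 + 57.05 + 18.02, abs=0.1)


def test_fusion_mw_additivity_loses_one_water():
    a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    b = "MSKGEELFTGVV"
    assert protein_mw(a + b) == pytest.approx(
        protein_mw(a) + protein_mw(b) - 18.02, abs=0.05)


def test_t2a_products_split_at_npg_p(genome, truth, sim_matrix):
    for row in truth.rows:
        if row.kind not in ("suitable", "two_cut"):
            continue
        prods = sim_matrix[row.gene_id].products
        assert len(prods) == 2
        trunc, gal4 = prods
        assert trunc.sequence.endswith("NPG")
        assert gal4.sequence.startswith("P")
        assert gal4.name == "GAL4"
        assert trunc.mw_da == pytest.approx(protein_mw(trunc.sequence))


def test_kozak_products_are_gal4_alone(truth, sim_matrix):
    for row in truth.rows:
        if not row.expected_strategy.startswith(("KOZAK", "SA_KOZAK")):
            continue
        prods = sim_matrix[row.gene_id].products
        assert [p.name for p in prods] == ["GAL4"]
        assert prods[0].sequence.startswith("M")


def test_phase_matched_cassette_is_stop_free_and_mismatches_are_rejected(
        params, library):
    spec = fx.FixtureSpec(seed=5, genes=[fx.GenePlan("suitable", phase=p)
                                         for p in (0, 1, 2)])
    genome, truth = fx.generate_genome(spec)
    sics = build_sic_definitions(library)
    for row in truth.rows:
        d = design_gene(genome, row.gene_id, params)
        assert d.sic.phase == row.intron_phase
        sim = simulate_design(genome, d)  # matched phase: no error
        assert len(sim.products) == 2
        for wrong in set(range(3)) - {row.intron_phase}:
            bad = DonorDesign(d.gene_id, d.strategy, d.architecture, d.plan,
                              d.arms, sics[f"T2AGAL4-phase{wrong}"], d.template)
            edited = predict_hdr(genome, bad)
            with pytest.raises(FrameInconsistencyError):
                predict_products(edited, genome.gene(row.gene_id), bad, genome)


def test_ecorv_insertion_requires_unique_site():
    backbone = Plasmid("b", _clean_random_dna(300, seed=74) + "GATATC"
                       + _clean_random_dna(100, seed=75) + "GATATC")
    with pytest.raises(AssemblyError, match="EcoRV"):
        insert_fragment_at_ecorv(backbone, "AAAA", "x")
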