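"""Guide enumeration, the specificity screen, and positional selection rules.

The enumeration oracle is a regex scan of both strands; the screen oracle is
an exhaustive per-position Hamming comparison.  Both are written here,
independently of the implementation they check.
"""

import random
import re

import pytest

from donorforge.genome import GenomeModel, Interval, revcomp
from donorforge.guides import (
    GuideSelectionError,
    GuideSite,
    enumerate_guides,
    screen_off_targets,
    select_intronic_guide,
    select_kozak_guides,
    passing_guides,
)
from donorforge.genome import GeneModel, Intron, TranscriptModel
from donorforge.params import DesignParameters, OffTargetPolicy


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _regex_oracle(seq: str, interval: Interval):
    """Independent N20-NGG scan of both strands, keyed by (cut, strand)."""
    hits = set()
    for m in re.finditer(r"(?=([ACGT]{21}GG))", seq):
        p = m.start()
        cut = p + 17
        if interval.start <= cut < interval.end:
            hits.add((cut, "+", m.group(1)))
    for m in re.finditer(r"(?=(CC[ACGT]{21}))", seq):
        p = m.start()
        cut = p + 6
        if interval.start <= cut < interval.end:
            hits.add((cut, "-", revcomp(m.group(1))))
    return hits


def test_single_terminal_pam_gives_one_site():
    seq = "ACGTACGTACGTACGTACGTAGG"  # 20-mer + AGG
    genome = GenomeModel(contigs={"c": seq}, genes=[])
    sites = enumerate_guides(genome, "c", Interval(0, len(seq)))
    assert len(sites) == 1
    (s,) = sites
    assert (s.strand, s.start, s.pam, s.cut) == ("+", 0, "AGG", 17)
    assert s.protospacer == seq[:20]


def test_sequence_without_gg_or_cc_yields_nothing():
    seq = "ATATATAGATAGATATAGATAGATATATAGAT" * 3
    genome = GenomeModel(contigs={"c": seq}, genes=[])
    assert enumerate_guides(genome, "c", Interval(0, len(seq))) == []


@pytest.mark.parametrize("seed", range(10))
def test_enumeration_matches_regex_oracle_on_random_windows(genome, seed):
    rng = random.Random(seed)
    contig = next(iter(genome.contigs))
    seq = genome.contigs[contig]
    start = rng.randint(0, len(seq) - 2000)
    iv = Interval(start, start + 2000)
    got = {(s.cut, s.strand, s.protospacer + s.pam)
           for s in enumerate_guides(genome, contig, iv)}
    assert got == _regex_oracle(seq, iv)


def test_enumeration_order_is_deterministic(genome):
    contig = next(iter(genome.contigs))
    iv = Interval(500, 2500)
    a = enumerate_guides(genome, contig, iv)
    b = enumerate_guides(genome, contig, iv)
    assert a == b
    assert a == sorted(a, key=lambda s: (s.cut, s.strand))


# ---------------------------------------------------------------------------
# off-target screen
# ---------------------------------------------------------------------------

def _hamming_oracle(guide: GuideSite, genome: GenomeModel,
                    policy: OffTargetPolicy):
    """Exhaustive scan: every 23-mer window on both strands."""
    hits = set()
    for contig, seq in genome.contigs.items():
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for p in range(len(s) - 22):
                start = p if strand == "+" else len(s) - p - 23
                if (contig, strand, start) == (guide.contig, guide.strand,
                                               guide.start):
                    continue
                window = s[p : p + 23]
                mm = sum(a != b for a, b in zip(window[:20], guide.protospacer))
                ngg = window[22] == "G" and window[21] == "G"
                nag = window[21] == "A" and window[22] == "G"
                rule_a = (ngg or nag) and mm <= policy.max_mismatches
                seed = window[20 - policy.seed_length : 20]
                rule_b = ngg and seed == guide.protospacer[20 - policy.seed_length :]
                if rule_a or rule_b:
                    hits.add((contig, strand, start))
    return hits


def test_screen_matches_exhaustive_hamming_oracle(genome, params):
    contig = next(iter(genome.contigs))
    sites = enumerate_guides(genome, contig, Interval(3000, 3600))
    assert sites, "window unexpectedly empty"
    for site in sites[:6]:
        verdict = screen_off_targets(site, genome, params.off_target)
        got = {(h.contig, h.strand, h.start) for h in verdict.hits}
        assert got == _hamming_oracle(site, genome, params.off_target)
        assert verdict.passed == (not got)


def _planted_genome(decoy_positions=None, seed_perfect=False):
    rng = random.Random(99)
    proto = "GATCAGTACGTTAGCATCAA"  # GG/CC-free
    site = proto + "TGG"
    bg = "".join(rng.choice("AT") for _ in range(3000))  # PAM-free background
    seq = list(bg)
    seq[100 : 100 + 23] = site
    if decoy_positions is not None:
        decoy = list(site)
        for p in decoy_positions:
            decoy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy[p]]
        seq[2000 : 2000 + 23] = decoy
    if seed_perfect:
        decoy = list(site)
        for p in (0, 2, 4, 5, 7):  # 5 mismatches, all PAM-distal
            decoy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decoy[p]]
        seq[2000 : 2000 + 23] = decoy
    genome = GenomeModel(contigs={"c": "".join(seq)}, genes=[])
    guide = GuideSite("c", "+", 100, proto, "TGG")
    return genome, guide


def test_unique_planted_guide_passes():
    genome, guide = _planted_genome()
    assert screen_off_targets(guide, genome).passed


def test_two_mismatch_duplicate_fails_by_mismatch_rule():
    genome, guide = _planted_genome(decoy_positions=(1, 6))
    verdict = screen_off_targets(guide, genome)
    assert not verdict.passed
    (hit,) = verdict.hits
    assert (hit.start, hit.mismatches, hit.rule) == (2000, 2, "mismatch")


def test_distal_mismatches_with_perfect_seed_fail_by_seed_rule():
    genome, guide = _planted_genome(seed_perfect=True)
    verdict = screen_off_targets(guide, genome)
    assert not verdict.passed
    (hit,) = verdict.hits
    assert hit.mismatches == 5 and hit.rule == "seed"


def test_unanchored_guide_is_an_error():
    genome, guide = _planted_genome()
    moved = GuideSite("c", "+", 400, guide.protospacer, guide.pam)
    with pytest.raises(ValueError, match="not anchored"):
        screen_off_targets(moved, genome)


def test_fixture_decoy_fails_screen_and_selection_skips_it():
    from donorforge import fixtures as fx
    from donorforge.guides import enumerate_guides as enum

    spec = fx.FixtureSpec(seed=11, genes=[fx.GenePlan("kozak", decoy_mm=2)])
    genome, truth = fx.generate_genome(spec)
    row = truth.rows[0]
    contig = next(iter(genome.contigs))
    bad_cut = row.guide_cuts["5prime-decoyed"]
    (bad,) = [s for s in enum(genome, contig, Interval(bad_cut, bad_cut + 1))
              if s.cut == bad_cut]
    assert not screen_off_targets(bad, genome).passed
    plan = select_kozak_guides(genome.gene(row.gene_id), genome,
                               DesignParameters())
    assert plan.by_role("5prime").site.cut == row.guide_cuts["5prime"]


# ---------------------------------------------------------------------------
# placement rules
# ---------------------------------------------------------------------------

def test_intronic_selection_maximizes_distance_to_both_splice_sites(
        genome, truth, params):
    from donorforge.genome import shared_coding_introns

    for row in truth.rows:
        if row.kind != "suitable":
            continue
        gene = genome.gene(row.gene_id)
        (intron,) = shared_coding_introns(gene)
        site = select_intronic_guide(intron, gene, genome, params)
        assert site.cut == row.guide_cuts["intronic"]
        # maximin oracle over every passing candidate
        iv = intron.interval
        window = Interval(iv.start + params.splice_buffer,
                          iv.end - params.splice_buffer)
        cands = passing_guides(genome, gene.contig, window, params.off_target)
        best = max(min(c.cut - iv.start, iv.end - c.cut) for c in cands)
        assert min(site.cut - iv.start, iv.end - site.cut) == best


def test_intronic_selection_tie_break_audit(genome, truth, params):
    """Masking the winner's PAM yields the deterministic next-best site."""
    import copy

    row = next(r for r in truth.rows if r.kind == "suitable")
    gene = genome.gene(row.gene_id)
    from donorforge.genome import shared_coding_introns

    (intron,) = shared_coding_introns(gene)
    first = select_intronic_guide(intron, gene, genome, params)
    masked = copy.deepcopy(genome)
    contig = masked.contigs[gene.contig]
    pam_pos = first.start + 21 if first.strand == "+" else first.start + 1
    masked.contigs[gene.contig] = (contig[:pam_pos] + "T" + contig[pam_pos + 1:])
    iv = intron.interval
    window = Interval(iv.start + params.splice_buffer,
                      iv.end - params.splice_buffer)
    cands = passing_guides(masked, gene.contig, window, params.off_target)
    if not cands:
        with pytest.raises(GuideSelectionError):
            select_intronic_guide(intron, gene, masked, params)
        return
    second = select_intronic_guide(intron, gene, masked, params)
    expected = min(
        cands,
        key=lambda c: (-min(c.cut - iv.start, iv.end - c.cut), c.cut, c.strand),
    )
    assert second == expected


def test_guideless_intron_raises_no_specific_guide():
    seq = "A" * 300 + "ATATATAT" * 100 + "A" * 300
    tx = TranscriptModel("t", "c", "+",
                         exons=[Interval(0, 300), Interval(1100, 1400)],
                         cds=[Interval(0, 300), Interval(1100, 1400)])
    gene = GeneModel("g", "c", "+", [tx])
    genome = GenomeModel(contigs={"c": seq}, genes=[gene])
    intron = Intron(Interval(300, 1100), "coding", 0, True)
    with pytest.raises(GuideSelectionError, match="no-specific-guide"):
        select_intronic_guide(intron, gene, genome, DesignParameters())


def test_kozak_five_prime_guide_is_closest_to_start_codon(genome, truth, params):
    for row in truth.rows:
        if row.kind != "kozak":
            continue
        gene = genome.gene(row.gene_id)
        plan = select_kozak_guides(gene, genome, params)
        five = plan.by_role("5prime")
        # the fixture plants competing sites 40 and 10 nt upstream of the ATG
        assert five.site.cut == row.guide_cuts["5prime"]
        assert five.tier == "primary-site"
        assert not five.pam_kill_required


def test_kozak_fallback_tiers(genome, truth, params):
    for row in truth.rows:
        gene = genome.gene(row.gene_id)
        if row.kind == "kozak_cds_fallback":
            plan = select_kozak_guides(gene, genome, params)
            three = plan.by_role("3prime")
            assert three.tier == "cds-near-stop"
            assert three.site.cut == row.guide_cuts["3prime"]
        elif row.kind == "kozak_promoter":
            plan = select_kozak_guides(gene, genome, params)
            five = plan.by_role("5prime")
            assert five.tier == "promoter-with-pam-kill"
            assert five.pam_kill_required
            assert five.site.cut == row.guide_cuts["5prime"]


def test_selection_is_deterministic_across_runs(genome, truth, params):
    for row in truth.rows:
        if not row.expected_strategy.startswith("KOZAK"):
            continue
        gene = genome.gene(row.gene_id)
        a = select_kozak_guides(gene, genome, params)
        b = select_kozak_guides(gene, genome, params)
        assert [(g.role, g.site, g.tier) for g in a.guides] == [
            (g.role, g.site, g.tier) for g in b.guides
        ]
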