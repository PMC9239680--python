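"""Homology arms, swappable-cassette definitions, and synthesis-ready
fragment architectures.

Three fragment architectures are supported.  ``int200`` is the minimal
synthesized piece (arm - cloning site - arm); the donor-linearization guide
machinery lives entirely on the vector backbone.  ``gRNA_int200`` moves the
gene-targeting guide into the synthesized fragment, completing a split tRNA
on the backbone; ``2XgRNA_int200`` multiplexes two gene guides separated by
a full tRNA, as used for coding-region replacement which needs two cuts.

Homology arms are verbatim genomic sequence except for recorded single-base
edits that destroy a guide target surviving intact inside an arm (PAM kill
in non-coding sequence, synonymous seed substitution in coding sequence).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .genome import (
    GeneModel,
    GenomeModel,
    Interval,
    Intron,
    extract_sequence,
    revcomp,
    translate,
)
from .guides import GuidePlan, GuideSite, SelectedGuide, TIER_PROMOTER
from .params import DesignParameters
from .parts import ENZYME_SITES, PartsLibrary, _clean_random_dna
from .suitability import Strategy

BACKBONE_INT200 = "pUC57_Kan_gw_OK"
BACKBONE_GRNA = "pUC57_Kan_gw_OK2"

ARCH_INT200 = "int200"
ARCH_GRNA_INT200 = "gRNA_int200"
ARCH_2XGRNA_INT200 = "2XgRNA_int200"

# type-IIS geometry: nt between recognition site and the 4-nt overhang
ENZYME_SPACER = {"BbsI": 2, "BsaI": 1}
OVERHANG_LEN = 4


class FeasibilityError(ValueError):
    """Fragment violates a synthesis or cloning constraint."""


@dataclass(frozen=True)
class ArmEdit:
    offset: int  # within the arm, gene orientation
    ref: str
    alt: str
    reason: str  # "pam-kill" | "seed-synonymous"


@dataclass
class HomologyArm:
    side: str  # "5'" | "3'"
    sequence: str  # gene orientation, edits applied
    source: tuple[str, Interval]  # contig, genomic interval
    strand: str
    edits: list[ArmEdit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def reference(self) -> str:
        """Unedited genomic sequence of the arm (gene orientation)."""
        seq = list(self.sequence)
        for e in self.edits:
            assert seq[e.offset] == e.alt
            seq[e.offset] = e.ref
        return "".join(seq)


@dataclass
class SICDefinition:
    """A swappable integration cassette ready for Golden Gate transfer.

    ``cassette`` excludes the 4-nt overhangs; the sequence installed between
    the homology arms is ``overhangs[0] + cassette + overhangs[1]``.  For the
    Kozak cassette the left overhang *is* the CAAA Kozak sequence, so the
    assembled junction always reads ``...arm + CAAA + ATG``.
    """

    name: str
    cassette: str
    enzyme: str  # "BbsI" | "BsaI"
    overhangs: tuple[str, str]
    phase: int | None  # 0|1|2 for splice-acceptor cassettes, None otherwise
    coding: tuple[int, int] | None = None  # cassette ORF slice (pad..stop)

    @property
    def insert(self) -> str:
        return self.overhangs[0] + self.cassette + self.overhangs[1]


# ---------------------------------------------------------------------------
# SIC construction from the parts library
# ---------------------------------------------------------------------------

def build_sic_definitions(
    library: PartsLibrary, enzyme: str = "BbsI"
) -> dict[str, SICDefinition]:
    """The standard cassette set: three phase variants of the intronic
    T2A-GAL4 artificial exon, the Kozak replacement cassette, the 5'UTR-intron
    splice-acceptor variant, and the GFP protein-trap exon."""
    L = library
    sa, t2a, gal4 = L["splice_acceptor"], L["t2a"], L["gal4_orf"]
    tail = L["polya"] + L["marker_3xp3_egfp"] + L["polya"]
    out: dict[str, SICDefinition] = {}
    for phase in (0, 1, 2):
        pad = "GCA"[: (3 - phase) % 3]
        pre = L["attp"] + L["frt"] + sa
        cassette = pre + pad + t2a + gal4 + tail + L["frt"] + L["attp"]
        out[f"T2AGAL4-phase{phase}"] = SICDefinition(
            name=f"T2AGAL4-phase{phase}",
            cassette=cassette,
            enzyme=enzyme,
            overhangs=("CTTG", "AGCA"),
            phase=phase,
            coding=(len(pre), len(pre) + len(pad) + len(t2a) + len(gal4)),
        )
    kz = gal4 + L["polya"] + L["frt"] + L["marker_3xp3_egfp"] + L["polya"] + L["frt"]
    out["KozakGAL4"] = SICDefinition(
        name="KozakGAL4", cassette=kz, enzyme=enzyme,
        overhangs=(L["kozak"], "AGCA"), phase=None, coding=(0, len(gal4)),
    )
    sak = sa + L["kozak"] + gal4 + tail
    out["SA-KozakGAL4"] = SICDefinition(
        name="SA-KozakGAL4", cassette=sak, enzyme=enzyme,
        overhangs=("CTTG", "AGCA"), phase=None,
        coding=(len(sa) + len(L["kozak"]), len(sa) + len(L["kozak"]) + len(gal4)),
    )
    gfp = sa + L["sfgfp"] + L["splice_donor"]
    out["SA-GFP-SD"] = SICDefinition(
        name="SA-GFP-SD", cassette=gfp, enzyme=enzyme,
        overhangs=("CTTG", "AGCA"), phase=0,
        coding=(len(sa), len(sa) + len(L["sfgfp"])),
    )
    return out


def select_sic(
    strategy: Strategy,
    intron: Intron | None,
    library: PartsLibrary,
    enzyme: str = "BbsI",
) -> SICDefinition:
    """Pick the cassette matching the strategy (and, for intronic designs,
    the reading-frame phase of the targeted intron)."""
    sics = build_sic_definitions(library, enzyme=enzyme)
    if strategy in (Strategy.T2AGAL4_INTRONIC, Strategy.T2AGAL4_TWO_CUT):
        if intron is None or intron.phase is None:
            raise ValueError("intronic strategy requires an intron with known phase")
        name = f"T2AGAL4-phase{intron.phase}"
        if name not in sics:
            raise KeyError(f"missing phase variant {name} in library")
        return sics[name]
    if strategy == Strategy.KOZAK_REPLACEMENT:
        return sics["KozakGAL4"]
    if strategy == Strategy.SA_KOZAK_5UTR_INTRON:
        return sics["SA-KozakGAL4"]
    raise ValueError(f"no cassette for strategy {strategy}")


# ---------------------------------------------------------------------------
# homology arms
# ---------------------------------------------------------------------------

def _arm_from_interval(
    genome: GenomeModel, gene: GeneModel, side: str, iv: Interval
) -> HomologyArm:
    seq = extract_sequence(genome, gene.contig, iv, gene.strand)
    return HomologyArm(side=side, sequence=seq, source=(gene.contig, iv),
                       strand=gene.strand)


def _apply_guide_edits(
    arm: HomologyArm, plan: GuidePlan, gene: GeneModel, tx
) -> None:
    """Destroy any selected guide target that survives intact inside the arm."""
    for sel in plan.guides:
        target = sel.site.site  # protospacer+PAM, site orientation
        for oriented, pam_kill_off in ((target, 22), (revcomp(target), 0)):
            start = 0
            while True:
                p = arm.reference.find(oriented, start)
                if p < 0:
                    break
                edit_off = p + pam_kill_off
                _edit_arm(arm, edit_off, gene, tx)
                start = p + 1


def _genomic_position(arm: HomologyArm, offset: int) -> int:
    contig, iv = arm.source
    return iv.start + offset if arm.strand == "+" else iv.end - 1 - offset


def _edit_arm(arm: HomologyArm, offset: int, gene: GeneModel, tx) -> None:
    """One substitution at ``offset``: PAM kill (G->C at the PAM's second G)
    in non-coding sequence, else a synonymous change as close to the PAM as
    possible inside the protospacer seed."""
    gpos = _genomic_position(arm, offset)
    in_cds = any(c.contains(gpos) for c in tx.cds) if tx is not None else False
    seq = list(arm.sequence)
    if not in_cds:
        ref = seq[offset]
        alt = "C" if ref == "G" else "G"
        seq[offset] = alt
        arm.sequence = "".join(seq)
        arm.edits.append(ArmEdit(offset, ref, alt, "pam-kill"))
        return
    # coding: walk the seed (12 nt PAM-proximal) for a synonymous swap
    for delta in range(1, 13):
        off = offset - delta if offset >= 12 else offset + delta
        g = _genomic_position(arm, off)
        if not any(c.contains(g) for c in tx.cds):
            continue
        swap = _synonymous_swap(arm, off, gene, tx)
        if swap is not None:
            ref, alt = swap
            seq[off] = alt
            arm.sequence = "".join(seq)
            arm.edits.append(ArmEdit(off, ref, alt, "seed-synonymous"))
            return
    raise FeasibilityError(
        f"cannot silently destroy guide target inside coding arm at {offset}"
    )


def _synonymous_swap(arm, off, gene, tx) -> tuple[str, str] | None:
    gpos = _genomic_position(arm, off)
    order = tx.cds if gene.strand == "+" else list(reversed(tx.cds))
    acc = 0
    cds_index = None
    for c in order:
        local = (gpos - c.start) if gene.strand == "+" else (c.end - 1 - gpos)
        if 0 <= local < c.length:
            cds_index = acc + local
            break
        acc += c.length
    if cds_index is None:
        return None
    frame = cds_index % 3
    # reconstruct the codon from the arm when fully inside it
    codon_start_off = off - frame
    if codon_start_off < 0 or codon_start_off + 3 > len(arm.sequence):
        return None
    codon = arm.sequence[codon_start_off : codon_start_off + 3]
    aa = translate(codon)
    for base in "ACGT":
        if base == arm.sequence[off]:
            continue
        alt_codon = codon[:frame] + base + codon[frame + 1 :]
        if translate(alt_codon) == aa:
            return arm.sequence[off], base
    return None


def extract_homology_arms(
    genome: GenomeModel,
    gene: GeneModel,
    plan: GuidePlan,
    params: DesignParameters,
    reference_tx=None,
) -> tuple[HomologyArm, HomologyArm]:
    """Arms flanking the edit, in gene orientation.

    Single-cut (intronic) designs take ``homology_arm_length`` nt on each side
    of the cut.  Two-cut designs end the 5' arm at the 5' cut and start the
    3' arm at the 3' cut, deleting the intervening gene body.  A promoter-tier
    5' guide extends the 5' arm to the TSS so the cut-to-TSS promoter segment
    is restored by the donor; any guide target left intact inside an arm is
    disabled by a recorded single-base edit.
    """
    L = params.homology_arm_length
    d = 1 if gene.strand == "+" else -1
    contig_len = len(genome.contigs[gene.contig])

    def interval_upstream(boundary: int, length: int) -> Interval:
        iv = (Interval(boundary - length, boundary) if d == 1
              else Interval(boundary, boundary + length))
        _check_bounds(iv, contig_len, gene)
        return iv

    def interval_downstream(boundary: int, length: int) -> Interval:
        iv = (Interval(boundary, boundary + length) if d == 1
              else Interval(boundary - length, boundary))
        _check_bounds(iv, contig_len, gene)
        return iv

    roles = {g.role for g in plan.guides}
    if "intronic" in roles:
        cut = plan.by_role("intronic").site.cut
        arm5 = _arm_from_interval(genome, gene, "5'", interval_upstream(cut, L))
        arm3 = _arm_from_interval(genome, gene, "3'", interval_downstream(cut, L))
    else:
        five = plan.by_role("5prime") if "5prime" in roles else plan.by_role(
            "intron-near-acceptor"
        )
        three = plan.by_role("3prime")
        cut5, cut3 = five.site.cut, three.site.cut
        if five.tier == TIER_PROMOTER and reference_tx is not None:
            tss = reference_tx.tss
            iv5 = (Interval(cut5 - L, tss) if gene.strand == "+"
                   else Interval(tss, cut5 + L))
            _check_bounds(iv5, contig_len, gene)
            arm5 = _arm_from_interval(genome, gene, "5'", iv5)
        else:
            arm5 = _arm_from_interval(genome, gene, "5'", interval_upstream(cut5, L))
        arm3 = _arm_from_interval(genome, gene, "3'", interval_downstream(cut3, L))
    _apply_guide_edits(arm5, plan, gene, reference_tx)
    _apply_guide_edits(arm3, plan, gene, reference_tx)
    return arm5, arm3


def _check_bounds(iv: Interval, contig_len: int, gene: GeneModel) -> None:
    if iv.start < 0 or iv.end > contig_len:
        raise ValueError(
            f"{gene.gene_id}: homology arm {iv} runs off the contig"
        )


# ---------------------------------------------------------------------------
# cloning site and fragment architectures
# ---------------------------------------------------------------------------

_STUFFER = _clean_random_dna(8, seed=31)


def cloning_site(enzyme: str, overhangs: tuple[str, str]) -> str:
    """Two outward-cutting type-IIS sites releasing ``overhangs`` (30 nt).

    Layout: OL - spacer - reverse site - stuffer - forward site - spacer - OR.
    Digestion drops the internal stuffer (which carries both recognition
    sites) and leaves the arms ending in the cassette-compatible overhangs.
    """
    site = ENZYME_SITES[enzyme]
    spacer = ENZYME_SPACER[enzyme]
    pad = "CA"[:spacer]
    stuffer_len = 30 - 2 * (OVERHANG_LEN + spacer + 6)
    return (overhangs[0] + pad + revcomp(site) + _STUFFER[:stuffer_len]
            + site + pad + overhangs[1])


@dataclass
class FeasibilityFlag:
    kind: str  # "enzyme-site" | "homopolymer" | "gc-window"
    position: int
    detail: str


@dataclass
class FeasibilityReport:
    flags: list[FeasibilityFlag] = field(default_factory=list)

    @property
    def fatal(self) -> list[FeasibilityFlag]:
        return [f for f in self.flags if f.kind == "enzyme-site"]


def check_synthesis_feasibility(
    fragment: str,
    params: DesignParameters,
    designed: list[Interval] | None = None,
) -> FeasibilityReport:
    """Vendor-style synthesis screen: unexpected BbsI/BsaI/EcoRV sites (both
    orientations), homopolymers above the limit, and GC-extreme windows."""
    designed = designed or []
    report = FeasibilityReport()
    for name, site in ENZYME_SITES.items():
        for motif in {site, revcomp(site)}:
            start = 0
            while True:
                p = fragment.find(motif, start)
                if p < 0:
                    break
                iv = Interval(p, p + len(motif))
                if not any(dv.start <= iv.start and iv.end <= dv.end
                           for dv in designed):
                    report.flags.append(
                        FeasibilityFlag("enzyme-site", p, f"{name} ({motif})")
                    )
                start = p + 1
    run_base, run_len, run_start = "", 0, 0
    for i, b in enumerate(fragment + "$"):
        if b == run_base:
            run_len += 1
        else:
            if run_len > params.max_homopolymer:
                report.flags.append(
                    FeasibilityFlag("homopolymer", run_start,
                                    f"{run_base}x{run_len}")
                )
            run_base, run_len, run_start = b, 1, i
    w = params.gc_window
    lo, hi = params.gc_range
    if len(fragment) >= w:
        gc = [1 if b in "GC" else 0 for b in fragment]
        total = sum(gc[:w])
        for i in range(len(fragment) - w + 1):
            if i:
                total += gc[i + w - 1] - gc[i - 1]
            frac = total / w
            if not lo <= frac <= hi:
                report.flags.append(
                    FeasibilityFlag("gc-window", i, f"GC={frac:.2f}")
                )
    report.flags.sort(key=lambda f: (f.position, f.kind))
    return report


@dataclass
class SynthesisTemplate:
    architecture: str
    parts: list[tuple[str, str]]  # (role, sequence), fragment order
    backbone_id: str
    sic_name: str
    enzyme: str
    feasibility: FeasibilityReport

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.parts)

    def part_roles(self) -> list[str]:
        return [role for role, _ in self.parts]

    @property
    def checksum(self) -> str:
        return hashlib.sha256(self.sequence.encode()).hexdigest()


def build_synthesis_template(
    architecture: str,
    arms: tuple[HomologyArm, HomologyArm],
    plan: GuidePlan,
    sic: SICDefinition,
    library: PartsLibrary,
    params: DesignParameters,
) -> SynthesisTemplate:
    """Assemble the order-ready fragment for one of the three architectures.

    ``int200``: [5'arm, cloning site, 3'arm] on backbone OK (guide-1 targets
    and the U6-driven linearization guide live on the backbone).
    ``gRNA_int200`` adds, upstream: the completion of the backbone's split
    tRNA, the gene guide (spacer+scaffold), and one linearization-guide
    target site; ``2XgRNA_int200`` carries two gene guides separated by a
    full tRNA.  Fails when the fragment contains an undesigned enzyme site.
    """
    arm5, arm3 = arms
    cs = cloning_site(sic.enzyme, sic.overhangs)
    parts: list[tuple[str, str]] = []
    if architecture == ARCH_INT200:
        backbone = BACKBONE_INT200
    elif architecture in (ARCH_GRNA_INT200, ARCH_2XGRNA_INT200):
        backbone = BACKBONE_GRNA
        gene_guides = [g for g in plan.guides]
        want = 1 if architecture == ARCH_GRNA_INT200 else 2
        if len(gene_guides) < want:
            raise ValueError(
                f"{architecture} needs {want} gene guide(s), plan has "
                f"{len(gene_guides)}"
            )
        parts.append(("trna-completion", library.trna_fragment_half))
        parts.append(
            ("gene-sgRNA-1-spacer", gene_guides[0].site.protospacer)
        )
        parts.append(("sgrna-scaffold", library["sgrna_scaffold"]))
        if want == 2:
            parts.append(("trna", library["trna"]))
            parts.append(
                ("gene-sgRNA-2-spacer", gene_guides[1].site.protospacer)
            )
            parts.append(("sgrna-scaffold", library["sgrna_scaffold"]))
        parts.append(("sgrna1-target-site", library["sgrna1_target"]))
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    parts.append(("5'-arm", arm5.sequence))
    parts.append(("sic-cloning-site", cs))
    parts.append(("3'-arm", arm3.sequence))

    fragment = "".join(s for _, s in parts)
    cs_start = fragment.find(cs)
    designed = [Interval(cs_start, cs_start + len(cs))]
    report = check_synthesis_feasibility(fragment, params, designed)
    if report.fatal:
        offs = ", ".join(f"{f.detail}@{f.position}" for f in report.fatal)
        raise FeasibilityError(f"undesigned enzyme site(s) in fragment: {offs}")
    return SynthesisTemplate(
        architecture=architecture, parts=parts, backbone_id=backbone,
        sic_name=sic.name, enzyme=sic.enzyme, feasibility=report,
    )


# ---------------------------------------------------------------------------
# design record
# ---------------------------------------------------------------------------

@dataclass
class DonorDesign:
    gene_id: str
    strategy: str
    architecture: str
    plan: GuidePlan
    arms: tuple[HomologyArm, HomologyArm]
    sic: SICDefinition
    template: SynthesisTemplate

    @property
    def payload(self) -> str:
        """Gene-oriented HDR payload: 5'arm + installed cassette + 3'arm."""
        return self.arms[0].sequence + self.sic.insert + self.arms[1].sequence

    def to_record(self) -> dict:
        arm5, arm3 = self.arms
        return {
            "gene": self.gene_id,
            "strategy": self.strategy,
            "architecture": self.architecture,
            "sic": self.sic.name,
            "enzyme": self.sic.enzyme,
            "guides": [
                {
                    "role": g.role,
                    "tier": g.tier,
                    "protospacer": g.site.protospacer,
                    "pam": g.site.pam,
                    "strand": g.site.strand,
                    "cut": g.site.cut,
                    "pam_kill_required": g.pam_kill_required,
                }
                for g in self.plan.guides
            ],
            "arms": [
                {
                    "side": a.side,
                    "length": a.length,
                    "contig": a.source[0],
                    "start": a.source[1].start,
                    "end": a.source[1].end,
                    "edits": [
                        {"offset": e.offset, "ref": e.ref, "alt": e.alt,
                         "reason": e.reason}
                        for e in a.edits
                    ],
                }
                for a in (arm5, arm3)
            ],
            "fragment_length": len(self.template.sequence),
            "fragment_sha256": self.template.checksum,
            "backbone": self.template.backbone_id,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_record(), indent=2, sort_keys=True, **kw)


# ---------------------------------------------------------------------------
# tag (protein trap) fusion donors
# ---------------------------------------------------------------------------

@dataclass
class TagFusionDesign:
    gene_id: str
    placement: str  # "N" | "C" | "<aa index>"
    payload_interior: str  # gene-oriented, between the arms
    fusion_protein: str
    marker_offset: int  # within payload_interior
    tag_offset: int
    arm3_boundary: int  # gene-oriented genomic boundary where the 3' arm starts


def design_tag_fusion(
    gene: GeneModel,
    genome: GenomeModel,
    tag_dna: str,
    placement: str | int,
    library: PartsLibrary,
    params: DesignParameters,
    transcript=None,
    marker_scan_window: int = 300,
) -> TagFusionDesign:
    """Replace the coding region with an in-frame tagged version.

    ``placement`` is "N" (after the start codon), "C" (before the stop
    codon) or an integer amino-acid index k (tag inserted after residue k).
    The transformation marker (PiggyBac-IR - 3XP3-DsRed - PiggyBac-IR) is
    placed at the first TTAA at/after the 3'UTR end, with the TTAA
    duplicated on both flanks so PiggyBac excision is scarless.
    """
    if transcript is None:
        tx = max(
            (t for t in gene.transcripts if t.is_coding),
            key=lambda t: (t.cds_length, t.transcript_id),
        )
    else:
        tx = transcript
    if len(tag_dna) % 3:
        raise ValueError("tag DNA length must be a multiple of 3")
    cds_len = tx.cds_length
    n_aa = cds_len // 3 - 1  # excluding the stop codon
    if placement == "N":
        cds_nt = 3
    elif placement == "C":
        cds_nt = cds_len - 3
    else:
        k = int(placement)
        if not 1 <= k <= n_aa:
            raise ValueError(f"internal aa index {k} outside protein (1..{n_aa})")
        cds_nt = 3 * k

    # map the CDS-nt boundary to a genomic boundary (gene orientation)
    order = tx.cds if gene.strand == "+" else list(reversed(tx.cds))
    acc, gpos = 0, None
    for c in order:
        if acc + c.length >= cds_nt:
            local = cds_nt - acc
            if acc + c.length == cds_nt and c is not order[-1]:
                pass  # boundary at an exon end: insert at the junction
            gpos = c.start + local if gene.strand == "+" else c.end - local
            break
        acc += c.length
    if gpos is None:
        raise ValueError("placement beyond CDS")

    # spliced-CDS fusion protein
    spliced = "".join(
        extract_sequence(genome, gene.contig, c, gene.strand) for c in order
    )
    tagged_cds = spliced[:cds_nt] + tag_dna + spliced[cds_nt:]
    fusion = translate(tagged_cds)
    if not fusion.endswith("*") or "*" in fusion[:-1]:
        raise ValueError("tagged CDS does not translate to a single clean ORF")

    # payload interior: genomic transcript span with the tag at gpos, then
    # the marker at the first TTAA at/after the 3'UTR end (= transcript end)
    d = 1 if gene.strand == "+" else -1
    span = tx.span
    interior = extract_sequence(genome, gene.contig, span, gene.strand)
    tag_off = (gpos - span.start) if d == 1 else (span.end - gpos)
    with_tag = interior[:tag_off] + tag_dna + interior[tag_off:]
    down_iv = (Interval(span.end, min(span.end + marker_scan_window,
                                      len(genome.contigs[gene.contig])))
               if d == 1 else Interval(max(0, span.start - marker_scan_window),
                                       span.start))
    downstream = extract_sequence(genome, gene.contig, down_iv, gene.strand)
    t = downstream.find("TTAA")
    if t < 0:
        raise ValueError(
            f"{gene.gene_id}: no TTAA within {marker_scan_window} nt after "
            "the 3'UTR end for the excisable marker"
        )
    marker = library["pbac_ir"] + library["marker_3xp3_dsred"] + library["pbac_ir"]
    # payload ends with TTAA+marker; the 3' arm starts at the same genomic
    # TTAA, so the assembled allele carries the TTAA duplicated on both flanks
    payload_interior = with_tag + downstream[: t + 4] + marker
    arm3_boundary = span.end + t if d == 1 else span.start - t
    return TagFusionDesign(
        gene_id=gene.gene_id,
        placement=str(placement),
        payload_interior=payload_interior,
        fusion_protein=fusion,
        marker_offset=len(with_tag) + t + 4,
        tag_offset=tag_off,
        arm3_boundary=arm3_boundary,
    )
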