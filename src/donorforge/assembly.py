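"""In-silico cloning and knock-in outcome prediction.

Covers the three molecular steps downstream of fragment synthesis: Golden
Gate transfer of the cassette from its carrier plasmid into the synthesized
intermediate, in-vivo linearization of the assembled donor by the
backbone-only guide, and homology-directed repair at the locus, followed by
transcript/protein prediction with average molecular weights.

HDR is modeled as perfect, seamless arm-mediated repair; junctions therefore
contain the homology arms verbatim, including any recorded donor-side edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

from .donor import DonorDesign, ENZYME_SPACER, OVERHANG_LEN
from .genome import GeneModel, GenomeModel, Interval, revcomp, translate
from .params import OffTargetPolicy
from .parts import ENZYME_SITES, T2A_AA


class AssemblyError(ValueError):
    pass


@dataclass
class Plasmid:
    """Circular double-stranded DNA with named features.

    Identity is rotation-invariant: ``canonical()`` returns the
    lexicographically minimal rotation (plasmids are constructed with the
    cassette-carrying strand stored 5'->3', which fixes orientation).
    """

    name: str
    seq: str
    features: list[tuple[str, Interval, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def canonical(self) -> str:
        return _least_rotation(self.seq)

    def rotated(self, k: int) -> "Plasmid":
        k %= len(self.seq)
        return Plasmid(self.name, self.seq[k:] + self.seq[:k])


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically minimal rotation."""
    d = s + s
    f = [-1] * len(d)
    k = 0
    for j in range(1, len(d)):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return d[k : k + len(s)]


# ---------------------------------------------------------------------------
# type-IIS digestion and ligation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Frag:
    """Digestion fragment: top strand between consecutive top-strand cuts,
    with the 4-nt 5' overhang sequences at each junction."""


    top: str
    left_ov: str
    right_ov: str
    origin: str
    carries_site: bool


def _find_sites_circular(seq: str, motif: str) -> list[int]:
    n = len(seq)
    doubled = seq + seq[: len(motif) - 1]
    out, start = [], 0
    while True:
        p = doubled.find(motif, start)
        if p < 0 or p >= n:
            break
        out.append(p)
        start = p + 1
    return out


def digest(plasmid: Plasmid, enzyme: str) -> list[_Frag]:
    """Cut a circular plasmid at every type-IIS site (both orientations).

    Returns fragments between consecutive top-strand cuts, each annotated
    with its 4-nt 5' overhangs and whether it still carries a recognition
    site (such fragments are re-cuttable and never part of a final product).
    """
    site = ENZYME_SITES[enzyme]
    spacer = ENZYME_SPACER[enzyme]
    n = len(plasmid.seq)
    seq = plasmid.seq
    cuts: set[int] = set()
    for s in _find_sites_circular(seq, site):
        cuts.add((s + len(site) + spacer) % n)
    for s in _find_sites_circular(seq, revcomp(site)):
        cuts.add((s - spacer - OVERHANG_LEN) % n)
    if not cuts:
        raise AssemblyError(f"{plasmid.name}: no {enzyme} site")
    order = sorted(cuts)
    frags: list[_Frag] = []

    def circ(a: int, b: int) -> str:
        return seq[a:b] if a <= b else seq[a:] + seq[:b]

    for i, t in enumerate(order):
        t_next = order[(i + 1) % len(order)]
        top = circ(t, t_next) if len(order) > 1 else seq[t:] + seq[:t]
        left_ov = circ(t, (t + OVERHANG_LEN) % n)
        right_ov = circ(t_next, (t_next + OVERHANG_LEN) % n)
        carries = site in top or revcomp(site) in top
        frags.append(_Frag(top, left_ov, right_ov, plasmid.name, carries))
    return frags


def enumerate_ligation_products(frags: list[_Frag]) -> list[tuple[_Frag, ...]]:
    """All distinct circular ligation products over re-cut-proof fragments.

    Brute-force DFS over fragment orderings with matching overhangs; each
    fragment is used at most once per circle.  Circles are deduplicated by
    rotation of their fragment tuple.
    """
    usable = [f for f in frags if not f.carries_site]
    products: dict[tuple, tuple[_Frag, ...]] = {}

    def key(chain: tuple[_Frag, ...]) -> tuple:
        ids = tuple((f.top, f.origin) for f in chain)
        rots = [ids[i:] + ids[:i] for i in range(len(ids))]
        return min(rots)

    def dfs(chain: list[_Frag], used: set[int]) -> None:
        last = chain[-1]
        if last.right_ov == chain[0].left_ov:
            products.setdefault(key(tuple(chain)), tuple(chain))
        for j, f in enumerate(usable):
            if j in used or last.right_ov != f.left_ov:
                continue
            dfs(chain + [f], used | {j})

    for i, f in enumerate(usable):
        dfs([f], {i})
    return list(products.values())


def circle_sequence(chain: tuple[_Frag, ...]) -> str:
    return "".join(f.top for f in chain)


def golden_gate(intermediate: Plasmid, sic: Plasmid, enzyme: str) -> Plasmid:
    """One-pot digestion/ligation of the cassette into the intermediate.

    The unique valid product is the circle that carries fragments from both
    inputs and no residual recognition site; anything else (no product,
    several products, backbone re-circularization alongside) is an error
    listing everything found.
    """
    frags = digest(intermediate, enzyme) + digest(sic, enzyme)
    circles = enumerate_ligation_products(frags)
    valid = [
        c for c in circles
        if {f.origin for f in c} == {intermediate.name, sic.name}
    ]
    if len(valid) != 1:
        found = [f"{'+'.join(f.origin for f in c)} ({len(circle_sequence(c))} bp)"
                 for c in circles]
        raise AssemblyError(
            f"expected exactly one two-source product, found {len(valid)} "
            f"(all circles: {found or 'none'})"
        )
    seq = circle_sequence(valid[0])
    return Plasmid(name=f"{intermediate.name}::{sic.name}", seq=seq)


def insert_fragment_at_ecorv(backbone: Plasmid, fragment: str, name: str) -> Plasmid:
    """Directional seamless insertion of a synthesized fragment at the
    backbone's unique EcoRV marker site.

    Models the synthesis vendor's Gibson assembly: the 6-nt site only marks
    the insertion point and is replaced by the fragment, which keeps the
    backbone's split tRNA contiguous with the fragment's completing half."""
    site = ENZYME_SITES["EcoRV"]
    hits = _find_sites_circular(backbone.seq, site)
    if len(hits) != 1:
        raise AssemblyError(
            f"{backbone.name}: expected one EcoRV site, found {len(hits)}"
        )
    p = hits[0]
    seq = backbone.seq[:p] + fragment + backbone.seq[p + len(site) :]
    return Plasmid(name=name, seq=seq)


# ---------------------------------------------------------------------------
# in-vivo linearization
# ---------------------------------------------------------------------------

@dataclass
class LinearizationReport:
    released: str  # sequence between the two cuts (with short vector tails)
    payload: str  # arms + installed cassette, exact
    n_cuts: int
    genome_collisions: int


def linearize(
    donor: Plasmid,
    sgrna1_target: str,
    genome: GenomeModel,
    design: DonorDesign,
    policy: OffTargetPolicy | None = None,
) -> LinearizationReport:
    """Cut the donor at every linearization-guide target and release the HDR
    payload.  The guide must have no genomic target at all: any match under
    the off-target policy is a hard error."""
    from numpy.lib.stride_tricks import sliding_window_view

    from .guides import SITE_LEN, _encode, _scan_strand

    policy = policy or OffTargetPolicy()
    proto = sgrna1_target[:20]
    guide_enc = _encode(proto)
    collisions = 0
    for contig, seq in genome.contigs.items():
        if len(seq) < SITE_LEN:
            continue
        for strand_seq in (seq, revcomp(seq)):
            windows = sliding_window_view(_encode(strand_seq), SITE_LEN)
            _, rule_a, rule_b = _scan_strand(windows, guide_enc, policy)
            collisions += int((rule_a | rule_b).sum())
    if collisions:
        raise AssemblyError(
            f"sgRNA1 collides with genome: {collisions} site(s) under policy"
        )

    n = len(donor.seq)
    cuts: set[int] = set()
    for p in _find_sites_circular(donor.seq, sgrna1_target):
        cuts.add((p + 17) % n)
    for p in _find_sites_circular(donor.seq, revcomp(sgrna1_target)):
        cuts.add((p + SITE_LEN - 17) % n)
    if not cuts:
        raise AssemblyError("donor lacks sgRNA1 target sites")
    payload = design.payload
    # the released fragment is the inter-cut segment containing the payload
    order = sorted(cuts)
    released = None
    for i, c in enumerate(order):
        c2 = order[(i + 1) % len(order)]
        seg = donor.seq[c:c2] if c < c2 else donor.seq[c:] + donor.seq[:c2]
        if payload in seg:
            released = seg
            break
    if released is None:
        raise AssemblyError("no released fragment contains the designed payload")
    return LinearizationReport(
        released=released, payload=payload, n_cuts=len(cuts),
        genome_collisions=0,
    )


# ---------------------------------------------------------------------------
# HDR prediction
# ---------------------------------------------------------------------------

@dataclass
class EditedLocusPrediction:
    contig: str
    sequence: str  # full edited contig
    junction5: Interval  # 5' homology arm in edited coordinates
    junction3: Interval
    insert_interval: Interval  # installed cassette between the arms
    strand: str


def _occurrences(genome: GenomeModel, seq: str) -> int:
    total = 0
    for contig_seq in genome.contigs.values():
        for s in (contig_seq, revcomp(contig_seq)):
            start = 0
            while True:
                p = s.find(seq, start)
                if p < 0:
                    break
                total += 1
                start = p + 1
    return total


def predict_hdr(genome: GenomeModel, design: DonorDesign) -> EditedLocusPrediction:
    """Seamless arm-mediated repair: the genomic segment between the arm
    boundaries is replaced by the installed cassette, and the arm sequences
    (edits included) are written into the locus."""
    arm5, arm3 = design.arms
    contig = arm5.source[0]
    contig_seq = genome.contigs[contig]
    for arm in (arm5, arm3):
        ref = arm.reference
        iv = arm.source[1]
        current = contig_seq[iv.start : iv.end]
        expected = ref if arm.strand == "+" else revcomp(ref)
        if current != expected:
            raise AssemblyError(
                f"{arm.side} arm no longer matches the locus at {iv}; "
                "already edited?"
            )
        if _occurrences(genome, expected) != 1:
            raise AssemblyError(f"{arm.side} arm maps to multiple loci")
    payload_gene = design.payload
    strand = arm5.strand
    payload_genomic = payload_gene if strand == "+" else revcomp(payload_gene)
    if strand == "+":
        left, right = arm5.source[1].start, arm3.source[1].end
    else:
        left, right = arm3.source[1].start, arm5.source[1].end
    edited = contig_seq[:left] + payload_genomic + contig_seq[right:]
    if strand == "+":
        j5 = Interval(left, left + arm5.length)
        ins = Interval(j5.end, j5.end + len(design.sic.insert))
        j3 = Interval(ins.end, ins.end + arm3.length)
    else:
        j3 = Interval(left, left + arm3.length)
        ins = Interval(j3.end, j3.end + len(design.sic.insert))
        j5 = Interval(ins.end, ins.end + arm5.length)
    return EditedLocusPrediction(
        contig=contig, sequence=edited, junction5=j5, junction3=j3,
        insert_interval=ins, strand=strand,
    )


# ---------------------------------------------------------------------------
# product prediction and molecular weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinProduct:
    name: str
    sequence: str  # no stop
    mw_da: float

    @property
    def mw_kda(self) -> float:
        return round(self.mw_da / 1000.0, 1)


def protein_mw(seq: str) -> float:
    """Average molecular weight (Da): residue masses plus one water."""
    return float(molecular_weight(seq, seq_type="protein"))


class FrameInconsistencyError(ValueError):
    pass


def predict_products(
    edited: EditedLocusPrediction,
    gene: GeneModel,
    design: DonorDesign,
    genome: GenomeModel,
    transcript=None,
) -> list[ProteinProduct]:
    """Predicted protein products of the edited allele.

    Intronic/two-cut T2A designs give two products: the truncated target
    protein ending in the 2A ...NPG, and P+GAL4 from translational
    reinitiation after the ribosomal skip.  Kozak designs give GAL4 alone,
    initiated at the CAAA-ATG junction.  A premature stop upstream of the
    cassette ORF end on a phase-matched design is a frame inconsistency.
    """
    from .genome import extract_sequence
    from .guides import reference_transcript

    sic = design.sic
    if sic.coding is None:
        raise ValueError(f"cassette {sic.name} has no annotated ORF")
    c0, c1 = sic.coding
    cassette_orf = sic.cassette[c0:c1]
    if sic.name in ("KozakGAL4", "SA-KozakGAL4"):
        aa = translate(cassette_orf)
        stop = aa.find("*")
        if stop != len(aa) - 1:
            raise FrameInconsistencyError("premature stop inside cassette ORF")
        p = aa[:-1]
        return [ProteinProduct("GAL4", p, protein_mw(p))]
    if sic.name.startswith("T2AGAL4"):
        tx = transcript or reference_transcript(gene)
        up_cds = _upstream_cds_sequence(genome, gene, tx, design)
        orf = up_cds + cassette_orf
        aa = translate(orf)
        stop = aa.find("*")
        if stop != len(aa) - 1:
            raise FrameInconsistencyError(
                f"premature stop at codon {stop + 1} of {len(aa)}: cassette "
                "phase does not match the intron"
            )
        # ribosomal skip between ...NPG | P: upstream product keeps NPG
        pad = (3 - (len(up_cds) % 3)) % 3
        split = (len(up_cds) + pad) // 3 + len(T2A_AA) - 1
        trunc, gal4 = aa[:split], aa[split:-1]
        if not trunc.endswith("NPG") or not gal4.startswith("P"):
            raise FrameInconsistencyError("2A junction not at ...NPG|P")
        return [
            ProteinProduct(f"{gene.gene_id}-trunc-T2A", trunc, protein_mw(trunc)),
            ProteinProduct("GAL4", gal4, protein_mw(gal4)),
        ]
    raise ValueError(
        f"no product rule for cassette {sic.name} (GFP-exon fusions are "
        "predicted by design_tag_fusion)"
    )


def _upstream_cds_sequence(
    genome: GenomeModel, gene: GeneModel, tx, design: DonorDesign
) -> str:
    """Spliced CDS 5' of the cassette (gene orientation), up to the end of
    the 5' homology arm (= the insertion boundary)."""
    from .genome import extract_sequence

    arm5 = design.arms[0]
    boundary = arm5.source[1].end if gene.strand == "+" else arm5.source[1].start
    pieces: list[Interval] = []
    order = tx.cds if gene.strand == "+" else list(reversed(tx.cds))
    for c in order:
        if gene.strand == "+":
            if c.end <= boundary:
                pieces.append(c)
            elif c.start < boundary:
                pieces.append(Interval(c.start, boundary))
        else:
            if c.start >= boundary:
                pieces.append(c)
            elif c.end > boundary:
                pieces.append(Interval(boundary, c.end))
    return "".join(
        extract_sequence(genome, gene.contig, c, gene.strand) for c in pieces
    )
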