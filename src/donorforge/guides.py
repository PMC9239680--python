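"""SpCas9 guide-site enumeration, specificity screening, and placement rules.

Guides are 20-nt protospacers next to an NGG PAM; the blunt cut sits 3 bp
5' of the PAM (between protospacer positions 17|18).  Selection follows the
positional rules of the knock-in design method: intronic guides maximise
distance from both splice sites, 5'UTR guides cut as close as possible to
the start codon (falling back to the promoter with a PAM-kill edit), 3'UTR
guides cut close to the stop codon (falling back into the CDS end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .genome import GeneModel, GenomeModel, Interval, Intron, revcomp
from .params import DesignParameters, OffTargetPolicy

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN
CUT_OFFSET = 17  # cut boundary, protospacer-relative

# selection tiers
TIER_PRIMARY = "primary-site"
TIER_CDS_NEAR_STOP = "cds-near-stop"
TIER_PROMOTER = "promoter-with-pam-kill"


class GuideSelectionError(ValueError):
    """No guide satisfies the placement and specificity rules."""


@dataclass(frozen=True)
class GuideSite:
    contig: str
    strand: str  # genomic strand carrying the protospacer
    start: int  # genomic start of the 23-mer site (forward-strand coords)
    protospacer: str  # 5'->3' on `strand`
    pam: str

    @property
    def cut(self) -> int:
        """Genomic boundary coordinate of the blunt cut."""
        if self.strand == "+":
            return self.start + CUT_OFFSET
        return self.start + SITE_LEN - CUT_OFFSET

    @property
    def site(self) -> str:
        return self.protospacer + self.pam


@dataclass(frozen=True)
class OffTargetHit:
    contig: str
    strand: str
    start: int
    mismatches: int
    pam: str
    rule: str  # "mismatch" or "seed"


@dataclass(frozen=True)
class OffTargetVerdict:
    passed: bool
    hits: tuple[OffTargetHit, ...] = ()


@dataclass(frozen=True)
class SelectedGuide:
    role: str  # "intronic" | "5prime" | "3prime" | "intron-near-acceptor"
    site: GuideSite
    tier: str = TIER_PRIMARY
    pam_kill_required: bool = False


@dataclass
class GuidePlan:
    strategy: str
    guides: list[SelectedGuide] = field(default_factory=list)

    def by_role(self, role: str) -> SelectedGuide:
        for g in self.guides:
            if g.role == role:
                return g
        raise KeyError(role)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_guides(
    genome: GenomeModel, contig: str, interval: Interval
) -> list[GuideSite]:
    """All N20-NGG sites on either strand whose cut falls inside ``interval``.

    Deterministic order: (cut position, + strand first).
    """
    seq = genome.contigs[contig]
    out: list[GuideSite] = []
    lo = max(0, interval.start - SITE_LEN)
    hi = min(len(seq) - SITE_LEN, interval.end + SITE_LEN)
    for p in range(lo, hi + 1):
        if seq[p + 21 : p + 23] == "GG":
            cut = p + CUT_OFFSET
            if interval.start <= cut < interval.end:
                out.append(
                    GuideSite(contig, "+", p, seq[p : p + 20], seq[p + 20 : p + 23])
                )
        if seq[p : p + 2] == "CC":
            cut = p + SITE_LEN - CUT_OFFSET
            if interval.start <= cut < interval.end:
                site = revcomp(seq[p : p + SITE_LEN])
                out.append(GuideSite(contig, "-", p, site[:20], site[20:]))
    out.sort(key=lambda g: (g.cut, g.strand))
    return out


# ---------------------------------------------------------------------------
# off-target screen
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# contig strands are encoded once per string object; fixture repair replaces
# the string, which naturally invalidates the entry
_STRAND_CACHE: dict[int, tuple[str, np.ndarray, np.ndarray]] = {}


def _encoded_strands(seq: str) -> tuple[np.ndarray, np.ndarray]:
    hit = _STRAND_CACHE.get(id(seq))
    if hit is not None and hit[0] is seq:
        return hit[1], hit[2]
    fwd, rev = _encode(seq), _encode(revcomp(seq))
    if len(_STRAND_CACHE) > 8:
        _STRAND_CACHE.clear()
    _STRAND_CACHE[id(seq)] = (seq, fwd, rev)
    return fwd, rev


_G, _A = ord("G"), ord("A")


def _scan_strand(
    windows: np.ndarray, guide_enc: np.ndarray, policy: OffTargetPolicy
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window (mismatches, mismatch-rule flag, seed-rule flag)."""
    proto = windows[:, :PROTOSPACER_LEN]
    mm = (proto != guide_enc).sum(axis=1)
    ngg = (windows[:, 21] == _G) & (windows[:, 22] == _G)
    pam_ok = ngg.copy()
    for alt in policy.alternate_pams:
        if alt.upper() == "NAG":
            pam_ok |= (windows[:, 21] == _A) & (windows[:, 22] == _G)
        else:  # generic IUPAC-free alternate PAM, e.g. "NGA"
            m = np.ones(len(windows), bool)
            for i, base in enumerate(alt.upper()):
                if base != "N":
                    m &= windows[:, PROTOSPACER_LEN + i] == ord(base)
            pam_ok |= m
    rule_a = pam_ok & (mm <= policy.max_mismatches)
    seed = proto[:, PROTOSPACER_LEN - policy.seed_length :]
    seed_perfect = (
        seed == guide_enc[PROTOSPACER_LEN - policy.seed_length :]
    ).all(axis=1)
    rule_b = ngg & seed_perfect
    return mm, rule_a, rule_b


def screen_off_targets(
    guide: GuideSite, genome: GenomeModel, policy: OffTargetPolicy | None = None
) -> OffTargetVerdict:
    """Exhaustive genome scan for sites that could be cut instead of `guide`.

    Fails on (a) <= ``max_mismatches`` mismatches with an NGG/alternate PAM,
    or (b) a perfect PAM-proximal seed with NGG; the guide's own locus is
    excluded.  Raises if the guide is not anchored at its stated locus.
    """
    policy = policy or OffTargetPolicy()
    own_contig = genome.contigs.get(guide.contig, "")
    expected = guide.site if guide.strand == "+" else revcomp(guide.site)
    if own_contig[guide.start : guide.start + SITE_LEN] != expected:
        raise ValueError(
            f"guide not anchored: {guide.contig}:{guide.start} does not match "
            f"{guide.site} on strand {guide.strand}"
        )
    guide_enc = _encode(guide.protospacer)
    hits: list[OffTargetHit] = []
    for contig, seq in genome.contigs.items():
        if len(seq) < SITE_LEN:
            continue
        fwd, rev = _encoded_strands(seq)
        L = len(seq)
        for strand, arr in (("+", fwd), ("-", rev)):
            windows = sliding_window_view(arr, SITE_LEN)
            mm, rule_a, rule_b = _scan_strand(windows, guide_enc, policy)
            for p in np.nonzero(rule_a | rule_b)[0]:
                p = int(p)
                start = p if strand == "+" else L - p - SITE_LEN
                if (
                    contig == guide.contig
                    and strand == guide.strand
                    and start == guide.start
                ):
                    continue
                pam = seq[start + 20 : start + 23] if strand == "+" else revcomp(
                    seq[start : start + 3]
                )
                hits.append(
                    OffTargetHit(
                        contig, strand, start, int(mm[p]), pam,
                        "mismatch" if rule_a[p] else "seed",
                    )
                )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return OffTargetVerdict(passed=not hits, hits=tuple(hits))


def passing_guides(
    genome: GenomeModel,
    contig: str,
    interval: Interval,
    policy: OffTargetPolicy,
) -> list[GuideSite]:
    return [
        g
        for g in enumerate_guides(genome, contig, interval)
        if screen_off_targets(g, genome, policy).passed
    ]


# ---------------------------------------------------------------------------
# placement rules
# ---------------------------------------------------------------------------

def _tie_key(site: GuideSite) -> tuple[int, str]:
    return (site.cut, site.strand)  # "+" sorts before "-"


def _pick(
    candidates: list[GuideSite], objective
) -> GuideSite:
    """Best candidate by ``objective`` (smaller is better), deterministic ties."""
    return min(candidates, key=lambda g: (objective(g),) + _tie_key(g))


def select_intronic_guide(
    intron: Intron,
    gene: GeneModel,
    genome: GenomeModel,
    params: DesignParameters,
    policy: OffTargetPolicy | None = None,
) -> GuideSite:
    """Specific guide in the buffered intron window, maximising the smaller
    of the distances to the splice donor and acceptor."""
    policy = policy or params.off_target
    b = params.splice_buffer
    iv = intron.interval
    window = Interval(iv.start + b, iv.end - b)
    if window.length < 1:
        raise GuideSelectionError(
            f"intron {iv} leaves no guide window with buffer {b}"
        )
    candidates = passing_guides(genome, gene.contig, window, policy)
    if not candidates:
        raise GuideSelectionError(
            f"no-specific-guide: no passing guide cuts inside {window}"
        )

    def neg_maximin(g: GuideSite) -> int:
        d_donor = g.cut - iv.start if gene.strand == "+" else iv.end - g.cut
        d_acc = iv.end - g.cut if gene.strand == "+" else g.cut - iv.start
        return -min(d_donor, d_acc)

    return _pick(candidates, neg_maximin)


def reference_transcript(gene: GeneModel):
    """Transcript with the 5'-most TSS; ties broken by transcript id."""
    coding = [t for t in gene.transcripts if t.is_coding]
    if not coding:
        raise GuideSelectionError(f"{gene.gene_id}: no coding transcript")
    if gene.strand == "+":
        return min(coding, key=lambda t: (t.span.start, t.transcript_id))
    return min(coding, key=lambda t: (-t.span.end, t.transcript_id))


def _gene_dir(gene: GeneModel) -> int:
    return 1 if gene.strand == "+" else -1


def select_kozak_guides(
    gene: GeneModel,
    genome: GenomeModel,
    params: DesignParameters,
    policy: OffTargetPolicy | None = None,
) -> GuidePlan:
    """Two-guide plan for coding-region replacement.

    5' guide: cut in the 5'UTR, as close as possible to (and strictly
    upstream of) the start codon; fallback scans the promoter window
    upstream of the TSS, picking the cut closest to the TSS and marking a
    PAM-kill donor edit.  3' guide: cut in the 3'UTR closest to the stop
    codon; fallback cuts inside the CDS as close as possible to the stop.
    """
    policy = policy or params.off_target
    five = find_five_prime_guide(gene, genome, params, policy)
    if five is None:
        raise GuideSelectionError(
            f"{gene.gene_id}: no 5' guide (tiers exhausted: 5'UTR, promoter "
            f"{params.promoter_scan_length} nt)"
        )
    three = find_three_prime_guide(gene, genome, params, policy)
    if three is None:
        raise GuideSelectionError(
            f"{gene.gene_id}: no 3' guide (tiers exhausted: 3'UTR, CDS)"
        )
    return GuidePlan(strategy="KOZAK_REPLACEMENT", guides=[five, three])


def _gather(genome, gene, intervals: list[Interval], policy) -> list[GuideSite]:
    sites: list[GuideSite] = []
    for iv in intervals:
        sites.extend(passing_guides(genome, gene.contig, iv, policy))
    return sorted(set(sites), key=_tie_key)  # de-dup adjacent intervals


def find_five_prime_guide(
    gene: GeneModel, genome: GenomeModel, params: DesignParameters,
    policy: OffTargetPolicy | None = None,
) -> SelectedGuide | None:
    """5'UTR cut closest to (strictly upstream of) the start codon, falling
    back to the promoter window with a required PAM-kill donor edit."""
    policy = policy or params.off_target
    tx = reference_transcript(gene)
    d = _gene_dir(gene)
    utr5, _ = tx.utrs()
    start, tss = tx.start_codon, tx.tss
    cands = [g for g in _gather(genome, gene, utr5, policy)
             if (start - g.cut) * d > 0]
    if cands:
        return SelectedGuide("5prime", _pick(cands, lambda g: (start - g.cut) * d))
    if gene.strand == "+":
        win = Interval(max(0, tss - params.promoter_scan_length), tss)
    else:
        end = min(len(genome.contigs[gene.contig]),
                  tss + params.promoter_scan_length)
        win = Interval(tss, end)
    cands = passing_guides(genome, gene.contig, win, policy)
    if cands:
        return SelectedGuide(
            "5prime", _pick(cands, lambda g: (tss - g.cut) * d),
            tier=TIER_PROMOTER, pam_kill_required=True,
        )
    return None


def find_three_prime_guide(
    gene: GeneModel, genome: GenomeModel, params: DesignParameters,
    policy: OffTargetPolicy | None = None,
) -> SelectedGuide | None:
    """3'UTR cut closest to the stop codon, falling back to a CDS cut as
    close to the stop as possible."""
    policy = policy or params.off_target
    tx = reference_transcript(gene)
    d = _gene_dir(gene)
    _, utr3 = tx.utrs()
    stop = tx.stop_codon
    cands = [g for g in _gather(genome, gene, utr3, policy)
             if (g.cut - stop) * d >= 0]
    if cands:
        return SelectedGuide("3prime", _pick(cands, lambda g: (g.cut - stop) * d))
    cands = [g for g in _gather(genome, gene, tx.cds, policy)
             if (stop - g.cut) * d > 0]
    if cands:
        return SelectedGuide(
            "3prime", _pick(cands, lambda g: (stop - g.cut) * d),
            tier=TIER_CDS_NEAR_STOP,
        )
    return None


def select_two_cut_guides(
    gene: GeneModel,
    intron: Intron,
    genome: GenomeModel,
    params: DesignParameters,
    policy: OffTargetPolicy | None = None,
) -> GuidePlan:
    """Two cuts for the small-intron variant: one just upstream of a splice
    acceptor (the 3'-most nt of a coding intron) and one in the 3'UTR."""
    policy = policy or params.off_target
    iv = intron.interval
    if iv.length < params.min_two_cut_intron_length:
        raise GuideSelectionError(
            f"intron {iv} shorter than {params.min_two_cut_intron_length} nt"
        )
    # cuts with 1..w nt between the cut and the acceptor junction (a cut at
    # distance zero would destroy the splice acceptor itself)
    w = min(params.two_cut_acceptor_window, iv.length)
    if gene.strand == "+":
        window = Interval(iv.end - w, iv.end)
    else:
        window = Interval(iv.start + 1, iv.start + w + 1)
    cands = passing_guides(genome, gene.contig, window, policy)
    if not cands:
        raise GuideSelectionError(
            f"{gene.gene_id}: no guide near the acceptor of intron {iv}"
        )
    d = _gene_dir(gene)
    acceptor = iv.end if gene.strand == "+" else iv.start
    intronic = SelectedGuide(
        "intron-near-acceptor", _pick(cands, lambda g: (acceptor - g.cut) * d)
    )
    three = find_three_prime_guide(gene, genome, params, policy)
    if three is None:
        raise GuideSelectionError(f"{gene.gene_id}: no 3' guide for two-cut plan")
    return GuidePlan(strategy="T2AGAL4_TWO_CUT", guides=[intronic, three])
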