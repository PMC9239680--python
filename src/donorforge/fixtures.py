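"""Synthetic genomes, gene models, and toy cassette plasmids with known
ground truth.

Every design rule in the package is exercised against genomes built here:
multi-isoform genes with or without shared coding introns, UTRs sampled
around fly-like medians (214/224 nt), planted unique guide sites in the
regions each placement rule scans, optional mismatch decoys for the
off-target screen, and enzyme-site-free windows where homology arms will be
taken.  Background sequence is i.i.d. uniform ACGT with planted motifs (no
repeat families), which keeps the exhaustive off-target oracle exact.

Generation is deterministic for a given seed, and planted guides are
verified unique by a self-scan before emission (colliding background sites
are repaired, never the planted site).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .assembly import Plasmid
from .donor import ENZYME_SPACER, SICDefinition, build_sic_definitions
from .genome import (
    GeneModel,
    GenomeModel,
    Interval,
    TranscriptModel,
    revcomp,
    translate,
)
from .guides import SITE_LEN, screen_off_targets, GuideSite
from .params import DesignParameters, OffTargetPolicy
from .parts import ENZYME_SITES, PartsLibrary, _clean_random_dna, has_forbidden_site

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOPS
)

KINDS = (
    "suitable", "kozak", "short_intron", "no_shared", "kozak_cds_fallback",
    "kozak_promoter", "utr5_intron", "two_cut", "undesignable", "tagfusion",
)

SUITABLE_KINDS = {"suitable"}


class FixtureError(ValueError):
    pass


@dataclass
class GenePlan:
    kind: str
    name: str | None = None
    cds_aa: int | None = None  # protein length incl. Met, excl. stop
    intron_len: int | None = None
    phase: int = 0
    decoy_mm: int = 0  # >0 plants a decoy against the nearest 5'UTR site
    decoy_in_seed: bool = False
    utr5: int | None = None
    utr3: int | None = None


@dataclass
class FixtureSpec:
    seed: int
    genes: list[GenePlan]
    contig_name: str = "chrSim"
    spacer: int = 150
    promoter_pad: int = 600
    tail_pad: int = 400
    utr5_median: int = 214
    utr3_median: int = 224
    splice_buffer: int = 30


@dataclass
class TruthRow:
    gene_id: str
    kind: str
    suitable: bool
    reason: str | None
    expected_strategy: str
    guide_cuts: dict[str, int] = field(default_factory=dict)  # role -> genomic
    tiers: dict[str, str] = field(default_factory=dict)
    intron: Interval | None = None
    intron_phase: int | None = None
    cds_aa: int = 0


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def row(self, gene_id: str) -> TruthRow:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    @property
    def n_suitable(self) -> int:
        return sum(r.suitable for r in self.rows)


# ---------------------------------------------------------------------------
# low-level block editing helpers (gene-oriented coordinates)
# ---------------------------------------------------------------------------

def _rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _rand_cds(rng: random.Random, n_aa: int) -> str:
    body = "".join(rng.choice(SENSE_CODONS) for _ in range(n_aa - 1))
    return "ATG" + body + "TAA"


def _utr_len(rng: random.Random, median: int) -> int:
    return max(80, min(400, int(rng.gauss(median, 40))))


class _Block:
    """Mutable gene-oriented sequence block with bookkeeping for planted
    sites, sanitation regions, and CDS frames."""

    def __init__(self, seq: str):
        self.chars = list(seq)
        self.keep: list[Interval] = []  # never mutate inside these
        self.guide_free: list[Interval] = []  # cut positions to keep guide-free
        self.enzyme_free: list[Interval] = []  # spans to keep enzyme-site-free
        self.cds: list[Interval] = []  # for stop-safe mutations

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def seq(self) -> str:
        return "".join(self.chars)

    def write(self, start: int, s: str, keep: bool = True) -> None:
        self.chars[start : start + len(s)] = list(s)
        if keep:
            self.keep.append(Interval(start, start + len(s)))

    # -- mutation with constraints ---------------------------------------
    def _in_keep(self, pos: int) -> bool:
        return any(k.contains(pos) for k in self.keep)

    def _codon_at(self, pos: int) -> tuple[int, str] | None:
        """(codon start pos in block, codon) when pos is inside a CDS whose
        codon lies wholly within one CDS segment, else None."""
        acc = 0
        for c in sorted(self.cds):
            if c.contains(pos):
                off_in_cds = acc + (pos - c.start)
                frame = off_in_cds % 3
                start = pos - frame
                if start >= c.start and start + 3 <= c.end:
                    return start, "".join(self.chars[start : start + 3])
                return None
            acc += c.length
        return None

    def mutate(self, pos: int) -> bool:
        """Substitute the base at ``pos`` if allowed; stop-safe inside CDS."""
        if pos < 0 or pos >= len(self.chars) or self._in_keep(pos):
            return False
        cur = self.chars[pos]
        codon_info = self._codon_at(pos)
        for base in "TACG":
            if base == cur:
                continue
            if codon_info is not None:
                start, codon = codon_info
                alt = codon[: pos - start] + base + codon[pos - start + 1 :]
                if alt in STOPS:
                    continue
            self.chars[pos] = base
            return True
        return False


def _in_any(pos: int, regions: list[Interval]) -> bool:
    return any(r.start <= pos < r.end for r in regions)


def _overlaps_keep(start: int, end: int, keep: list[Interval]) -> bool:
    return any(k.overlaps(Interval(start, end)) for k in keep)


def sanitize_block(block: _Block, max_rounds: int = 400) -> None:
    """Remove unwanted guide sites (cuts inside guide-free regions) and
    enzyme recognition sites (inside enzyme-free regions), iterating to a
    fixed point since a repair can create a new motif."""
    for _ in range(max_rounds):
        changed = False
        s = block.seq
        # guide sites
        for p in range(len(s) - SITE_LEN + 1):
            if s[p + 21 : p + 23] == "GG" and _in_any(p + 17, block.guide_free):
                # keep spans are enforced per-base by mutate(); a fully
                # pinned PAM (the planted site itself) is left alone
                if block.mutate(p + 21) or block.mutate(p + 22):
                    changed = True
                    break
            if s[p : p + 2] == "CC" and _in_any(p + 6, block.guide_free):
                if block.mutate(p) or block.mutate(p + 1):
                    changed = True
                    break
        if changed:
            continue
        # enzyme sites
        motifs = set(ENZYME_SITES.values()) | {
            revcomp(m) for m in ENZYME_SITES.values()
        }
        for motif in sorted(motifs):
            p = -1
            while True:
                p = s.find(motif, p + 1)
                if p < 0:
                    break
                span = Interval(p, p + len(motif))
                if not any(span.overlaps(r) for r in block.enzyme_free):
                    continue
                for off in (3, 2, 4, 1, 5, 0):
                    if block.mutate(p + off):
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
        if not changed:
            return
    raise FixtureError("sanitizer did not converge")


def _plant_plus_site(rng: random.Random, block: _Block, cut: int) -> str:
    """Write a random forward-strand guide site so its cut lands at ``cut``.

    The protospacer is kept free of GG/CC dinucleotides (and the PAM fixed to
    AGG) so the planted 23-mer cannot spawn overlapping secondary guide sites
    that the sanitizer would be unable to disrupt."""
    start = cut - 17
    if start < 0 or start + SITE_LEN > len(block):
        raise FixtureError(f"planted site at cut {cut} outside block")
    while True:
        proto = _rand_dna(rng, 20)
        site = proto + "AGG"
        if "GG" in proto or "CC" in proto or has_forbidden_site(site):
            continue
        block.write(start, site)
        return site


def _force_pam_in_cds(block: _Block, cut: int) -> int:
    """Make an existing-sequence forward guide at ``cut`` inside the CDS by
    forcing a GG PAM via stop-safe substitutions; returns the (possibly
    shifted) cut boundary, moving 3 nt at a time toward the 5' end."""
    for shift in range(0, 30, 3):
        c = cut - shift
        ok = True
        for pos in (c + 4, c + 5):
            if block.chars[pos] == "G":
                continue
            info = block._codon_at(pos)
            if info is None:
                ok = False
                break
            start, codon = info
            alt = codon[: pos - start] + "G" + codon[pos - start + 1 :]
            if alt in STOPS:
                ok = False
                break
            block.chars[pos] = "G"
        if ok:
            # only the PAM is pinned: the sanitizer may still adjust the
            # natural protospacer to disrupt overlapping sites
            block.keep.append(Interval(c + 3, c + 6))
            return c
    raise FixtureError("could not force a CDS PAM near the stop codon")


# ---------------------------------------------------------------------------
# per-kind gene builders
# ---------------------------------------------------------------------------

@dataclass
class _BuiltGene:
    block: _Block
    isoforms: list[tuple[str, list[Interval], list[Interval]]]  # id, exons, cds
    truth: TruthRow
    decoy_template: str | None = None  # site to decoy (fails after planting)


def _build_gene(plan: GenePlan, gene_id: str, spec: FixtureSpec,
                rng: random.Random) -> _BuiltGene:
    pp, tp = spec.promoter_pad, spec.tail_pad
    u5 = plan.utr5 or _utr_len(rng, spec.utr5_median)
    u3 = plan.utr3 or _utr_len(rng, spec.utr3_median)
    n_aa = plan.cds_aa or rng.randint(160, 400)
    cds = _rand_cds(rng, n_aa + 1)  # +1: stop codon
    kind = plan.kind
    buf = spec.splice_buffer

    def finish(block_seq, isoforms, cds_ivs, truth) -> _BuiltGene:
        b = _Block(block_seq)
        b.cds = sorted(cds_ivs)
        b.keep.append(Interval(b.cds[0].start, b.cds[0].start + 3))  # ATG
        b.keep.append(Interval(b.cds[-1].end - 3, b.cds[-1].end))  # stop
        return _BuiltGene(b, isoforms, truth)

    tss = pp
    atg = tss + u5

    if kind in ("suitable", "short_intron"):
        L = plan.intron_len or (rng.randint(150, 300) if kind == "suitable"
                                else rng.randint(60, 100))
        a = 3 * rng.randint(40, min(100, n_aa - 20)) + plan.phase
        i_start, i_end = atg + a, atg + a + L
        exon1 = Interval(tss, i_start)
        exon2 = Interval(i_end, i_end + (len(cds) - a) + u3)
        cds_ivs = [Interval(atg, i_start), Interval(i_end, i_end + len(cds) - a)]
        seq = (_rand_dna(rng, pp) + _rand_dna(rng, u5) + cds[:a]
               + _rand_dna(rng, L) + cds[a:] + _rand_dna(rng, u3)
               + _rand_dna(rng, tp))
        iso = [
            ("%s.t1" % gene_id, [exon1, exon2], cds_ivs),
            ("%s.t2" % gene_id,
             [Interval(tss - 30, i_start), exon2], cds_ivs),
        ]
        if kind == "suitable":
            if L <= 100 or L - 2 * buf < 1:
                raise FixtureError(
                    f"{gene_id}: planted intron of {L} nt cannot host a "
                    "buffered guide window"
                )
            truth = TruthRow(gene_id, kind, True, None, "T2AGAL4_INTRONIC",
                             intron=Interval(i_start, i_end),
                             intron_phase=plan.phase, cds_aa=n_aa)
            g = finish(seq, iso, cds_ivs, truth)
            cut = i_start + L // 2
            _plant_plus_site(rng, g.block, cut)
            truth.guide_cuts["intronic"] = cut
            truth.tiers["intronic"] = "primary-site"
            g.block.guide_free.append(Interval(i_start + buf, i_end - buf))
            g.block.enzyme_free.append(Interval(cut - 220, cut + 220))
            return g
        # short shared intron: falls back to coding-region replacement
        truth = TruthRow(gene_id, kind, False, "all-shared-introns-too-short",
                         "KOZAK_REPLACEMENT", cds_aa=n_aa)
        g = finish(seq, iso, cds_ivs, truth)
        _plant_utr_guides(g, rng, tss, atg, cds_end=i_end + len(cds) - a,
                          u3=u3, truth=truth)
        return g

    if kind == "no_shared":
        a = 3 * rng.randint(30, 60)
        b = 3 * rng.randint(20, 40)
        L1, L2 = rng.randint(120, 200), rng.randint(120, 200)
        e1_end = atg + a
        e2_start = e1_end + L1
        e2_end = e2_start + b
        e3_start = e2_end + L2
        cds_rest = len(cds) - a - b
        e3_end = e3_start + cds_rest + u3
        seq = (_rand_dna(rng, pp) + _rand_dna(rng, u5) + cds[:a]
               + _rand_dna(rng, L1) + cds[a : a + b] + _rand_dna(rng, L2)
               + cds[a + b :] + _rand_dna(rng, u3) + _rand_dna(rng, tp))
        full_cds = [Interval(atg, e1_end), Interval(e2_start, e2_end),
                    Interval(e3_start, e3_start + cds_rest)]
        skip_cds = [Interval(atg, e1_end), Interval(e3_start, e3_start + cds_rest)]
        iso = [
            (f"{gene_id}.t1",
             [Interval(tss, e1_end), Interval(e2_start, e2_end),
              Interval(e3_start, e3_end)], full_cds),
            (f"{gene_id}.t2",
             [Interval(tss, e1_end), Interval(e3_start, e3_end)], skip_cds),
        ]
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "KOZAK_REPLACEMENT", cds_aa=len(cds) // 3 - 1)
        g = finish(seq, iso, full_cds, truth)
        _plant_utr_guides(g, rng, tss, atg, cds_end=e3_start + cds_rest,
                          u3=u3, truth=truth)
        return g

    # remaining kinds: single CDS exon geometries
    if kind == "utr5_intron":
        u5a, u5b = 120, max(60, u5 - 120)
        Lu = plan.intron_len or 160
        e1 = Interval(tss, tss + u5a)
        i_u = Interval(e1.end, e1.end + Lu)
        atg = i_u.end + u5b
        stop_end = atg + len(cds)
        e2 = Interval(i_u.end, stop_end + u3)
        seq = (_rand_dna(rng, pp) + _rand_dna(rng, u5a) + _rand_dna(rng, Lu)
               + _rand_dna(rng, u5b) + cds + _rand_dna(rng, u3)
               + _rand_dna(rng, tp))
        cds_ivs = [Interval(atg, stop_end)]
        iso = [(f"{gene_id}.t1", [e1, e2], cds_ivs)]
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "SA_KOZAK_5UTR_INTRON", intron=i_u,
                         cds_aa=len(cds) // 3 - 1)
        g = finish(seq, iso, cds_ivs, truth)
        cut = i_u.start + Lu // 2
        _plant_plus_site(rng, g.block, cut)
        truth.guide_cuts["utr5-intron"] = cut
        g.block.guide_free.append(Interval(i_u.start + buf, i_u.end - buf))
        # no 5'UTR or promoter guide may exist
        g.block.guide_free.append(Interval(tss - 500, tss + u5a))
        g.block.guide_free.append(Interval(i_u.end, atg))
        g.block.enzyme_free.append(Interval(cut - 220, cut + 220))
        return g

    if kind == "two_cut":
        L = plan.intron_len or 40
        a = 3 * rng.randint(30, 60) + plan.phase
        a -= (a - plan.phase) % 3
        i_start, i_end = atg + a, atg + a + L
        stop_end = i_end + (len(cds) - a)
        exons = [Interval(tss, i_start), Interval(i_end, stop_end + u3)]
        cds_ivs = [Interval(atg, i_start), Interval(i_end, stop_end)]
        seq = (_rand_dna(rng, pp) + _rand_dna(rng, u5) + cds[:a]
               + _rand_dna(rng, L) + cds[a:] + _rand_dna(rng, u3)
               + _rand_dna(rng, tp))
        iso = [(f"{gene_id}.t1", exons, cds_ivs)]
        truth = TruthRow(gene_id, kind, False, "all-shared-introns-too-short",
                         "T2AGAL4_TWO_CUT", intron=Interval(i_start, i_end),
                         intron_phase=plan.phase, cds_aa=len(cds) // 3 - 1)
        g = finish(seq, iso, cds_ivs, truth)
        cut_i = i_end - 10
        _plant_plus_site(rng, g.block, cut_i)
        truth.guide_cuts["intron-near-acceptor"] = cut_i
        g.block.guide_free.append(Interval(cut_i + 1, i_end))
        cut3 = stop_end + 25
        _plant_plus_site(rng, g.block, cut3)
        truth.guide_cuts["3prime"] = cut3
        truth.tiers["3prime"] = "primary-site"
        g.block.guide_free.append(Interval(stop_end, cut3))
        # no 5' guide anywhere (forces the two-cut route)
        g.block.guide_free.append(Interval(tss - 500, atg))
        g.block.enzyme_free.append(Interval(cut_i - 220, cut_i + 220))
        g.block.enzyme_free.append(Interval(cut3 - 10, cut3 + 220))
        return g

    # intronless single-exon kinds
    stop_end = atg + len(cds)
    exons = [Interval(tss, stop_end + u3)]
    cds_ivs = [Interval(atg, stop_end)]
    seq = (_rand_dna(rng, pp) + _rand_dna(rng, u5) + cds + _rand_dna(rng, u3)
           + _rand_dna(rng, tp))
    iso = [(f"{gene_id}.t1", exons, cds_ivs)]
    n_aa_out = len(cds) // 3 - 1

    if kind in ("kozak", "tagfusion"):
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "KOZAK_REPLACEMENT", cds_aa=n_aa_out)
        g = finish(seq, iso, cds_ivs, truth)
        _plant_utr_guides(g, rng, tss, atg, cds_end=stop_end, u3=u3,
                          truth=truth, extra_5prime=True)
        if plan.decoy_mm:
            # the near site gets a planted mismatch decoy and must fail the
            # screen; the far site becomes the expected selection
            g.decoy_template = _site_at_cut(g.block, truth.guide_cuts["5prime"])
            truth.guide_cuts["5prime-decoyed"] = truth.guide_cuts.pop("5prime")
            truth.guide_cuts["5prime"] = truth.guide_cuts.pop("5prime-alt")
        else:
            truth.guide_cuts.pop("5prime-alt", None)
        if kind == "tagfusion":
            # guaranteed PiggyBac TTAA right after the transcript end
            g.block.write(stop_end + u3 + 8, "TTAA")
        return g

    if kind == "kozak_cds_fallback":
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "KOZAK_REPLACEMENT", cds_aa=n_aa_out)
        g = finish(seq, iso, cds_ivs, truth)
        _plant_5prime(g, rng, tss, atg, truth)
        # 3'UTR guide-free; force a CDS guide near the stop instead
        g.block.guide_free.append(Interval(stop_end, stop_end + u3))
        cut = _force_pam_in_cds(g.block, stop_end - 15)
        truth.guide_cuts["3prime"] = cut
        truth.tiers["3prime"] = "cds-near-stop"
        g.block.guide_free.append(Interval(cut + 1, stop_end))
        g.block.enzyme_free.append(Interval(cut - 10, cut + 220))
        return g

    if kind == "kozak_promoter":
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "KOZAK_REPLACEMENT", cds_aa=n_aa_out)
        g = finish(seq, iso, cds_ivs, truth)
        g.block.guide_free.append(Interval(tss, atg))  # empty 5'UTR
        cut = tss - 120
        _plant_plus_site(rng, g.block, cut)
        truth.guide_cuts["5prime"] = cut
        truth.tiers["5prime"] = "promoter-with-pam-kill"
        g.block.guide_free.append(Interval(cut + 1, tss))
        _plant_3prime(g, rng, stop_end, truth)
        g.block.enzyme_free.append(Interval(cut - 220, tss + 20))
        return g

    if kind == "undesignable":
        truth = TruthRow(gene_id, kind, False, "no-shared-coding-intron",
                         "UNDESIGNABLE", cds_aa=n_aa_out)
        g = finish(seq, iso, cds_ivs, truth)
        g.block.guide_free.append(Interval(tss - 500, atg))
        return g

    raise FixtureError(f"unknown gene kind {plan.kind!r}")


def _plant_5prime(g: _BuiltGene, rng, tss, atg, truth) -> None:
    cut = atg - 10
    _plant_plus_site(rng, g.block, cut)
    truth.guide_cuts["5prime"] = cut
    truth.tiers["5prime"] = "primary-site"
    g.block.guide_free.append(Interval(cut + 1, atg))
    g.block.enzyme_free.append(Interval(cut - 220, cut + 10))


def _plant_3prime(g: _BuiltGene, rng, stop_end, truth) -> None:
    cut = stop_end + 25
    _plant_plus_site(rng, g.block, cut)
    truth.guide_cuts["3prime"] = cut
    truth.tiers["3prime"] = "primary-site"
    g.block.guide_free.append(Interval(stop_end, cut))
    g.block.enzyme_free.append(Interval(cut - 10, cut + 220))


def _plant_utr_guides(g, rng, tss, atg, cds_end, u3, truth,
                      extra_5prime: bool = False) -> None:
    _plant_5prime(g, rng, tss, atg, truth)
    if extra_5prime:
        cut = atg - 40
        _plant_plus_site(rng, g.block, cut)
        truth.guide_cuts["5prime-alt"] = cut
        g.block.guide_free.append(Interval(cut + 1, atg - 10))
    _plant_3prime(g, rng, cds_end, truth)


def _site_at_cut(block: _Block, cut: int) -> str:
    return block.seq[cut - 17 : cut + 6]


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _map_boundary(b: int, off: int, blen: int, strand: str) -> int:
    return off + b if strand == "+" else off + blen - b


def _map_interval(iv: Interval, off: int, blen: int, strand: str) -> Interval:
    if strand == "+":
        return Interval(off + iv.start, off + iv.end)
    return Interval(off + blen - iv.end, off + blen - iv.start)


def generate_genome(
    spec: FixtureSpec,
    policy: OffTargetPolicy | None = None,
) -> tuple[GenomeModel, TruthTable]:
    """Emit a genome model + truth table realizing ``spec``.

    Genes alternate strands; every planted guide expected to pass the screen
    is verified against the final genome, and the linearization guide is
    verified absent."""
    policy = policy or OffTargetPolicy()
    rng = random.Random(spec.seed)
    built: list[tuple[GenePlan, _BuiltGene, str]] = []
    for i, plan in enumerate(spec.genes):
        gene_id = plan.name or f"g{i + 1:03d}_{plan.kind}"
        g = _build_gene(plan, gene_id, spec, rng)
        sanitize_block(g.block, max_rounds=600)
        strand = "+" if i % 2 == 0 else "-"
        built.append((plan, g, strand))

    pieces: list[str] = []
    offset = 0
    genes: list[GeneModel] = []
    truth_rows: list[TruthRow] = []
    decoys: list[tuple[str, int]] = []  # (site template, mm) to plant later
    pieces.append(_rand_dna(rng, spec.spacer))
    offset += spec.spacer
    for plan, g, strand in built:
        blen = len(g.block)
        block_seq = g.block.seq
        piece = block_seq if strand == "+" else revcomp(block_seq)
        transcripts = []
        gid = g.truth.gene_id
        for tid, exons, cds in g.isoforms:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid, contig=spec.contig_name, strand=strand,
                    exons=[_map_interval(e, offset, blen, strand) for e in exons],
                    cds=[_map_interval(c, offset, blen, strand) for c in cds],
                )
            )
        genes.append(GeneModel(gene_id=gid, contig=spec.contig_name,
                               strand=strand, transcripts=transcripts))
        t = g.truth
        t.guide_cuts = {
            role: _map_boundary(b, offset, blen, strand)
            for role, b in t.guide_cuts.items()
        }
        if t.intron is not None:
            t.intron = _map_interval(t.intron, offset, blen, strand)
        truth_rows.append(t)
        if g.decoy_template:
            decoys.append((g.decoy_template, plan.decoy_mm))
        pieces.append(piece)
        offset += blen
        pieces.append(_rand_dna(rng, spec.spacer))
        offset += spec.spacer

    # plant requested decoys in a dedicated tail region
    tail = list(_rand_dna(rng, max(1, len(decoys)) * 80 + 80))
    decoy_spans: list[Interval] = []
    for i, (site, mm) in enumerate(decoys):
        mutated = list(site)
        positions = list(range(0, 8))  # PAM-distal mismatches
        rng.shuffle(positions)
        for p in positions[:mm]:
            mutated[p] = _rotate_base(mutated[p])
        start = 20 + i * 80
        tail[start : start + SITE_LEN] = mutated
        decoy_spans.append(Interval(offset + start, offset + start + SITE_LEN))
    pieces.append("".join(tail))

    contig = "".join(pieces)
    genome = GenomeModel(
        contigs={spec.contig_name: contig},
        genes=sorted(genes, key=lambda g: g.gene_id),
        provenance={"fixture_seed": str(spec.seed)},
    )
    _repair_collisions(genome, truth_rows, built, policy, decoy_spans)
    return genome, TruthTable(rows=truth_rows)


def _expected_pass_cuts(truth_rows, built) -> list[tuple[TruthRow, str, int]]:
    out = []
    for (plan, g, _), t in zip(built, truth_rows):
        for role, cut in t.guide_cuts.items():
            if role.endswith("-decoyed"):
                continue  # decoyed on purpose: must FAIL the screen
            out.append((t, role, cut))
    return out


def _guide_at_cut(genome: GenomeModel, contig: str, cut: int) -> GuideSite | None:
    from .guides import enumerate_guides

    for g in enumerate_guides(genome, contig, Interval(cut, cut + 1)):
        if g.cut == cut:
            return g
    return None


def _repair_collisions(genome, truth_rows, built, policy,
                       decoy_spans: list[Interval], max_rounds: int = 20) -> None:
    """Self-scan: planted guides must be unique; the linearization guide must
    be absent.  Colliding background sites are mutated in place (stop-safe
    when the collision falls inside a CDS)."""
    contig = next(iter(genome.contigs))
    keep: list[Interval] = list(decoy_spans)
    for t in truth_rows:
        for cut in t.guide_cuts.values():
            keep.append(Interval(cut - SITE_LEN, cut + SITE_LEN))
    for _ in range(max_rounds):
        dirty = False
        for t, role, cut in _expected_pass_cuts(truth_rows, built):
            site = _guide_at_cut(genome, contig, cut)
            if site is None:
                raise FixtureError(f"{t.gene_id}: planted {role} site vanished")
            verdict = screen_off_targets(site, genome, policy)
            for h in verdict.hits:
                if _fix_background_site(genome, contig, h.start, keep):
                    dirty = True
                else:
                    raise FixtureError(
                        f"{t.gene_id}: cannot repair off-target at {h.start}"
                    )
        # linearization guide must have no genomic target under the policy
        for pos in _sgrna1_hits(genome, policy):
            if _fix_background_site(genome, contig, pos - 10, keep):
                dirty = True
            else:
                raise FixtureError("cannot repair an sgRNA1 genomic collision")
        if not dirty:
            return
    raise FixtureError("collision repair did not converge")


def _fix_background_site(genome: GenomeModel, contig: str, site_start: int,
                         keep: list[Interval]) -> bool:
    """Mutate one base of a 23-mer background site, avoiding planted spans
    and never creating an in-frame stop inside any annotated CDS."""
    seq = genome.contigs[contig]
    for off in (21, 22, 10, 11, 12, 13, 14, 15):
        pos = site_start + off
        if pos < 0 or pos >= len(seq) or any(k.contains(pos) for k in keep):
            continue
        for base in "TACG":
            if base == seq[pos]:
                continue
            if _creates_stop(genome, contig, pos, base):
                continue
            genome.contigs[contig] = seq[:pos] + base + seq[pos + 1 :]
            return True
    return False


def _creates_stop(genome: GenomeModel, contig: str, pos: int, base: str) -> bool:
    seq = genome.contigs[contig]
    for gene in genome.genes:
        if gene.contig != contig:
            continue
        for tx in gene.transcripts:
            acc = 0
            order = tx.cds if gene.strand == "+" else list(reversed(tx.cds))
            for c in order:
                local = (pos - c.start) if gene.strand == "+" else (
                    c.end - 1 - pos)
                if 0 <= local < c.length:
                    frame = (acc + local) % 3
                    g0 = (pos - frame) if gene.strand == "+" else (pos + frame)
                    if gene.strand == "+":
                        codon = seq[g0 : g0 + 3]
                        codon = (codon[: pos - g0] + base + codon[pos - g0 + 1 :])
                    else:
                        codon = revcomp(seq[g0 - 2 : g0 + 1])
                        idx = g0 - pos
                        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
                        codon = codon[:idx] + comp + codon[idx + 1 :]
                    if codon in STOPS:
                        return True
                acc += c.length
    return False


def _rotate_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]


def _sgrna1_hits(genome: GenomeModel, policy: OffTargetPolicy) -> list[int]:
    import numpy as np
    from numpy.lib.stride_tricks import sliding_window_view

    from .guides import _encode, _scan_strand
    from .parts import SGRNA1_TARGET

    out = []
    proto = _encode(SGRNA1_TARGET[:20])
    for contig, seq in genome.contigs.items():
        L = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            windows = sliding_window_view(_encode(s), SITE_LEN)
            _, a, b = _scan_strand(windows, proto, policy)
            for p in np.nonzero(a | b)[0]:
                p = int(p)
                start = p if strand == "+" else L - p - SITE_LEN
                out.append(start + 10)  # a protospacer base to mutate
    return out


# ---------------------------------------------------------------------------
# canned specs
# ---------------------------------------------------------------------------

def default_spec(seed: int, n_genes: int = 20) -> FixtureSpec:
    """A mixed matrix cycling through every gene kind and all three phases."""
    cycle = [
        GenePlan("suitable", phase=0),
        GenePlan("kozak"),
        GenePlan("suitable", phase=1),
        GenePlan("short_intron"),
        GenePlan("suitable", phase=2),
        GenePlan("no_shared"),
        GenePlan("kozak_cds_fallback"),
        GenePlan("kozak_promoter"),
        GenePlan("utr5_intron"),
        GenePlan("two_cut"),
    ]
    genes = [GenePlan(**vars(cycle[i % len(cycle)])) for i in range(n_genes)]
    return FixtureSpec(seed=seed, genes=genes)


def survey_spec(seed: int, n_suitable: int = 12, n_unsuitable: int = 8) -> FixtureSpec:
    genes = [GenePlan("suitable", phase=i % 3) for i in range(n_suitable)]
    unsuit = ["short_intron", "kozak", "no_shared", "undesignable"]
    genes += [GenePlan(unsuit[i % len(unsuit)]) for i in range(n_unsuitable)]
    return FixtureSpec(seed=seed, genes=genes)


# ---------------------------------------------------------------------------
# toy plasmids
# ---------------------------------------------------------------------------

def generate_sic_plasmids(
    library: PartsLibrary | None = None, enzyme: str = "BbsI"
) -> dict[str, Plasmid]:
    """Toy cassette-carrier plasmids: the cassette sits between two type-IIS
    sites cutting outward from the backbone, so digestion releases
    overhang-flanked cassette fragments carrying no recognition site."""
    library = library or PartsLibrary()
    site = ENZYME_SITES[enzyme]
    pad = "CA"[: ENZYME_SPACER[enzyme]]
    out: dict[str, Plasmid] = {}
    for name, sic in build_sic_definitions(library, enzyme=enzyme).items():
        backbone_a = _clean_random_dna(120, seed=1000 + len(name))
        backbone_b = _clean_random_dna(80, seed=2000 + len(name))
        seq = (backbone_a + site + pad + sic.insert + revcomp(pad)
               + revcomp(site) + backbone_b)
        out[name] = Plasmid(name=f"pM37_{name}", seq=seq)
    return out


def backbone_ok(library: PartsLibrary | None = None) -> Plasmid:
    """int200 backbone: U6-driven linearization guide plus its two target
    sites flanking the EcoRV insertion point."""
    L = library or PartsLibrary()
    seq = (
        _clean_random_dna(150, seed=41)
        + L["u6_3_promoter"] + L["sgrna1_spacer"] + L["sgrna_scaffold"]
        + _clean_random_dna(60, seed=42)
        + L["sgrna1_target"] + ENZYME_SITES["EcoRV"] + revcomp(L["sgrna1_target"])
        + _clean_random_dna(150, seed=43)
    )
    return Plasmid(name="pUC57_Kan_gw_OK", seq=seq)


def backbone_ok2(library: PartsLibrary | None = None) -> Plasmid:
    """gRNA_int200 backbone: split tRNA upstream of the EcoRV point (the
    synthesized fragment completes it) and one linearization-guide target
    just downstream; the guide's own expression cassette sits elsewhere."""
    L = library or PartsLibrary()
    seq = (
        _clean_random_dna(150, seed=44)
        + L["u6_3_promoter"] + L["sgrna1_spacer"] + L["sgrna_scaffold"]
        + _clean_random_dna(60, seed=45)
        + L["u6_3_promoter"] + L.trna_backbone_half
        + ENZYME_SITES["EcoRV"] + revcomp(L["sgrna1_target"])
        + _clean_random_dna(150, seed=46)
    )
    return Plasmid(name="pUC57_Kan_gw_OK2", seq=seq)
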