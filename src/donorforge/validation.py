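"""Knock-in validation reagents: flank PCR primer pairs and smiFISH probes.

Primer pairs combine a gene-specific primer outside the homology region,
pointing toward the insert, with a cassette-specific primer pointing
outward, so a product of the expected 200-800 nt size can only come from an
on-target integration.  Melting temperatures use the SantaLucia
nearest-neighbor model (50 mM monovalent salt, 250 nM oligo).

smiFISH probes are 20-nt antisense oligos tiled 5'->3' along the mRNA; a
shared 28-nt flap is prepended to each, giving 48-mers that hybridize to a
dye-labelled X-flap oligo (the reverse complement of the flap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp

from .assembly import EditedLocusPrediction
from .donor import DonorDesign
from .genome import Interval, revcomp
from .params import DesignParameters
from .parts import FLAP, X_FLAP

PROBE_LEN = 20
FLAPPED_LEN = len(FLAP) + PROBE_LEN  # 48


class PrimerDesignError(ValueError):
    pass


def primer_tm(seq: str, na_mM: float = 50.0, oligo_nM: float = 250.0) -> float:
    """Nearest-neighbor melting temperature (degrees C)."""
    return float(MeltingTemp.Tm_NN(seq, Na=na_mM, dnac1=oligo_nM, dnac2=0))


def gc_fraction(seq: str) -> float:
    return sum(b in "GC" for b in seq) / len(seq)


def three_prime_self_complement_run(seq: str) -> int:
    """Longest 3'-terminal run whose reverse complement occurs in the primer
    (a proxy for 3'-end self-annealing)."""
    run = 0
    for k in range(1, min(10, len(seq)) + 1):
        if revcomp(seq[-k:]) in seq:
            run = k
        else:
            break
    return run


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    interval: Interval  # on the gene-oriented edited locus
    orientation: str  # "fwd" | "rev" relative to the gene-oriented sequence

    @property
    def tm(self) -> float:
        return primer_tm(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    gene_primer: Primer
    cassette_primer: Primer
    amplicon_length: int
    flank: str  # "5'" | "3'"


@dataclass
class PrimerParams:
    length_range: tuple[int, int] = (18, 25)
    tm_range: tuple[float, float] = (58.0, 62.0)
    gc_range: tuple[float, float] = (0.35, 0.65)
    max_three_prime_self: int = 4

    def acceptable(self, seq: str) -> bool:
        if "N" in seq:
            return False
        lo, hi = self.tm_range
        if not lo <= primer_tm(seq) <= hi:
            return False
        glo, ghi = self.gc_range
        if not glo <= gc_fraction(seq) <= ghi:
            return False
        return three_prime_self_complement_run(seq) <= self.max_three_prime_self


def _edited_gene_view(edited: EditedLocusPrediction) -> tuple[str, Interval, Interval, Interval]:
    """Edited contig in gene orientation with arm/insert intervals mapped."""
    seq = edited.sequence
    if edited.strand == "+":
        return seq, edited.junction5, edited.insert_interval, edited.junction3
    n = len(seq)

    def flip(iv: Interval) -> Interval:
        return Interval(n - iv.end, n - iv.start)

    return (revcomp(seq), flip(edited.junction5), flip(edited.insert_interval),
            flip(edited.junction3))


def design_validation_primers(
    edited: EditedLocusPrediction,
    design: DonorDesign,
    params: DesignParameters,
    primer_params: PrimerParams | None = None,
    cassette_primer_offset: int = 40,
) -> tuple[PrimerPair, PrimerPair]:
    """One validating pair per flank on the predicted edited locus.

    The cassette primers bind ``cassette_primer_offset`` nt inside each end
    of the installed cassette and point outward; the gene primer search
    walks outward from each homology-arm boundary, keeping the first
    qualifying primer whose amplicon stays within the configured range.
    """
    pp = primer_params or PrimerParams()
    lo_amp, hi_amp = params.validation_amplicon_range
    view, j5, ins, j3 = _edited_gene_view(edited)
    k = PROBE_LEN
    off = min(cassette_primer_offset, max(0, ins.length - k))
    cass5_iv = Interval(ins.start + off, ins.start + off + k)
    cass5 = Primer("SIC-5rev", revcomp(view[cass5_iv.start : cass5_iv.end]),
                   cass5_iv, "rev")
    cass3_iv = Interval(ins.end - off - k, ins.end - off)
    cass3 = Primer("SIC-3fwd", view[cass3_iv.start : cass3_iv.end],
                   cass3_iv, "fwd")

    pairs = []
    for flank, arm_iv, cass in (("5'", j5, cass5), ("3'", j3, cass3)):
        found = None
        for dist in range(0, params.primer_scan_window + 1):
            for n in range(pp.length_range[0], pp.length_range[1] + 1):
                if flank == "5'":
                    end = arm_iv.start - dist
                    start = end - n
                    if start < 0:
                        continue
                    seq = view[start:end]
                    amp = cass.interval.end - start
                else:
                    start = arm_iv.end + dist
                    end = start + n
                    if end > len(view):
                        continue
                    seq = revcomp(view[start:end])
                    amp = end - cass.interval.start
                if not lo_amp <= amp <= hi_amp:
                    continue
                if pp.acceptable(seq):
                    found = PrimerPair(
                        gene_primer=Primer(
                            f"{design.gene_id}-{flank}flank", seq,
                            Interval(start, end),
                            "fwd" if flank == "5'" else "rev",
                        ),
                        cassette_primer=cass,
                        amplicon_length=amp,
                        flank=flank,
                    )
                    break
            if found:
                break
        if found is None:
            raise PrimerDesignError(
                f"{design.gene_id}: no qualifying {flank} flank primer within "
                f"{params.primer_scan_window} nt of the homology arm"
            )
        pairs.append(found)
    return pairs[0], pairs[1]


# ---------------------------------------------------------------------------
# smiFISH probes
# ---------------------------------------------------------------------------

@dataclass
class ProbeParams:
    probe_length: int = PROBE_LEN
    min_gap: int = 2
    gc_range: tuple[float, float] = (0.30, 0.70)
    max_homopolymer: int = 5


@dataclass
class ProbeSet:
    gene_id: str
    probes: list[tuple[str, int]]  # (antisense 20-mer, transcript offset)
    flap: str = FLAP
    x_flap: str = X_FLAP
    dye: str = "Cy3"

    @property
    def flapped_oligos(self) -> list[str]:
        return [self.flap + p for p, _ in self.probes]

    def __len__(self) -> int:
        return len(self.probes)


def _window_ok(window: str, pp: ProbeParams) -> bool:
    lo, hi = pp.gc_range
    if not lo <= gc_fraction(window) <= hi:
        return False
    return not any(b * (pp.max_homopolymer + 1) in window for b in "ACGT")


def design_smifish_probes(
    transcript_seq: str,
    gene_id: str = "",
    n_requested: int = 48,
    probe_params: ProbeParams | None = None,
    dye: str = "Cy3",
) -> ProbeSet:
    """Greedy 5'->3' tiling of antisense probes along the mRNA.

    Windows failing the GC or homopolymer rule are slid past one base at a
    time; accepted probes are separated by at least ``min_gap`` nt.  Short
    mRNAs yield fewer than ``n_requested`` probes (the actual count is the
    length of the returned set).
    """
    pp = probe_params or ProbeParams()
    k = pp.probe_length
    if len(transcript_seq) < k:
        raise ValueError("transcript shorter than one probe footprint")
    probes: list[tuple[str, int]] = []
    pos = 0
    while pos + k <= len(transcript_seq) and len(probes) < n_requested:
        window = transcript_seq[pos : pos + k]
        if _window_ok(window, pp):
            probes.append((revcomp(window), pos))
            pos += k + pp.min_gap
        else:
            pos += 1
    if not probes:
        raise ValueError(f"{gene_id or 'transcript'}: no placeable probes")
    return ProbeSet(gene_id=gene_id, probes=probes, dye=dye)


def probe_sheet_rows(ps: ProbeSet) -> list[dict]:
    """IDT-style order sheet rows for the flapped oligo pool."""
    rows = [
        {
            "name": f"{ps.gene_id}_probe_{i + 1:02d}",
            "sequence": ps.flap + probe,
            "scale": "25nm",
            "purification": "STD",
        }
        for i, (probe, _) in enumerate(ps.probes)
    ]
    rows.append({"name": f"X-FLAP_{ps.dye}", "sequence": ps.x_flap,
                 "scale": "25nm", "purification": "HPLC"})
    return rows
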