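"""Sequence parts library for donor construction.

Ships a default set of parts sufficient to exercise every design and
simulation path: real, published short elements (Kozak context, T2A peptide,
FRT, sgRNA scaffold, smiFISH flap) and clearly synthetic stand-ins for the
long ones (GAL4 ORF, fluorescent markers, attP, PiggyBac ends, U6-3
promoter).  Stand-ins are deterministic, non-biological sequences sized well
below their real counterparts so nothing here can be mistaken for a
functional reagent; production sequences can be dropped in from a YAML file
without code changes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .genome import revcomp, translate

# type-IIS / blunt enzymes used by the donor architectures
ENZYME_SITES = {"BbsI": "GAAGAC", "BsaI": "GGTCTC", "EcoRV": "GATATC"}
FORBIDDEN_SITES = tuple(ENZYME_SITES.values())

KOZAK = "CAAA"

# viral T2A peptide; codons chosen so both shifted reading frames hit a stop
# inside the peptide or immediately after (guards frame-mismatch detection)
T2A_AA = "EGRGSLLTCGDVEENPGP"
T2A_DNA = "GAAGGAAGAGGATCATTACTTACTTGCGGTGACGTTGAAGAAAATCCTGGGCCC"

FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)
# tRNA used for multiplexed guide processing (pCFD5-style glycine tRNA)
TRNA = (
    "TGCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCCCGGCCAATGCA"
)

# smiFISH flap appended 5' of every probe; X-flap is its reverse complement
FLAP = "CCTCCTAAGTTTCGAGCTGGACTCAGTG"
X_FLAP = "CACTGAGTCCAGCTCGAAACTTAGGAGG"

# sfGFP protein (published reagent); DNA below is a synthetic back-translation
SFGFP_AA = (
    "MSKGEELFTGVVPILVELDGDVNGHKFSVRGEGEGDATNGKLTLKFICTTGKLPVPWPTLVTTLTYGVQCFSRYPDHMKR"
    "HDFFKSAMPEGYVQERTISFKDDGTYKTRAEVKFEGDTLVNRIELKGIDFKEDGNILGHKLEYNFNSHNVYITADKQKNG"
    "IKANFKIRHNVEDGSVQLADHYQQNTPIGDGPVLLPDNHYLSTQSVLSKDPNEKRDHMVLLEFVTAAGITHGMDELYK"
)

_SAFE_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAG",
    "E": "GAA", "G": "GGA", "H": "CAC", "I": "ATC", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTC", "P": "CCA", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}


_ALT_CODON = {
    "A": "GCC", "R": "AGA", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAG", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTC", "K": "AAG",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCC", "T": "ACA", "V": "GTC",
    "W": "TGG", "Y": "TAT",
}


def back_translate(protein: str) -> str:
    """Synthetic back-translation (no stop appended), kept free of the
    cloning enzymes' recognition sites by synonymous codon swaps."""
    codons = [_SAFE_CODON[a] for a in protein]
    for _ in range(2 * len(codons)):
        seq = "".join(codons)
        pos = -1
        for site in FORBIDDEN_SITES + tuple(revcomp(s) for s in FORBIDDEN_SITES):
            p = seq.find(site)
            if p >= 0 and (pos < 0 or p < pos):
                pos = p
        if pos < 0:
            return seq
        i = pos // 3
        codons[i] = _ALT_CODON[protein[i]] if codons[i] == _SAFE_CODON[protein[i]] \
            else _SAFE_CODON[protein[i]]
        if "".join(codons).find(seq[pos : pos + 6], pos - 3) == pos:
            codons[min(i + 1, len(codons) - 1)] = _ALT_CODON[
                protein[min(i + 1, len(codons) - 1)]
            ]
    raise ValueError("could not remove enzyme sites by synonymous swaps")


def has_forbidden_site(seq: str, sites: tuple[str, ...] = FORBIDDEN_SITES) -> bool:
    rc = revcomp(seq)
    return any(s in seq or s in rc for s in sites)


def _clean_random_dna(n: int, seed: int, gc_bias: float = 0.5) -> str:
    """Deterministic filler DNA free of enzyme sites and long homopolymers."""
    rng = random.Random(seed)
    bases = "ACGT"
    while True:
        seq = "".join(rng.choice(bases) for _ in range(n))
        if has_forbidden_site(seq):
            continue
        if any(b * 8 in seq for b in bases):
            continue
        return seq


def _clean_orf(n_codons: int, seed: int, prefix: str = "") -> str:
    """Deterministic stand-in ORF: ATG .. no internal stops .. stop codon.

    ``prefix`` is inserted right after the ATG (used to plant early stop
    codons in both shifted frames, so phase-mismatched installs are caught).
    """
    rng = random.Random(seed)
    codons = [c for c in _SAFE_CODON.values() if c not in ("ATG",)]
    while True:
        body = "".join(rng.choice(codons) for _ in range(n_codons - 2))
        orf = "ATG" + prefix + body + "TAA"
        if has_forbidden_site(orf):
            continue
        aa = translate(orf)
        if "*" in aa[:-1]:
            continue
        return orf


# TTAATTAAC right after ATG: Leu-Ile-Asn in frame, TAA stops in both shifts
_FRAME_GUARD = "TTAATTAAC"

GAL4_ORF = _clean_orf(100, seed=11, prefix=_FRAME_GUARD)  # ~300 nt stand-in
SFGFP_DNA = back_translate(SFGFP_AA)  # synthetic back-translation, no stop

SPLICE_ACCEPTOR = "CTCTCTTTTCCTTTTCCTTTCAG"  # toy SA, ends with the AG dinucleotide
SPLICE_DONOR = "GTAAGTATCCTTTCTT"  # toy SD, starts with the GT dinucleotide
POLYA = "AATAAA" + _clean_random_dna(24, seed=21)
ATTP = _clean_random_dna(50, seed=22)  # stand-in for the ~200 nt attP
PBAC_IR = _clean_random_dna(40, seed=23)  # stand-in PiggyBac inverted repeat
MARKER_3XP3_EGFP = _clean_orf(60, seed=24)  # stand-in 3XP3-EGFP marker
MARKER_3XP3_DSRED = _clean_orf(60, seed=25)  # stand-in 3XP3-DsRed marker
U6_3_PROMOTER = _clean_random_dna(60, seed=26)  # stand-in U6-3 promoter

# guide that targets only the donor backbone, never the genome; the fixture
# generator verifies absence from every emitted genome
SGRNA1_SPACER = "GACGTACGCGGAATACTTCG"
SGRNA1_PAM = "TGG"
SGRNA1_TARGET = SGRNA1_SPACER + SGRNA1_PAM


@dataclass
class PartsLibrary:
    """Named parts; every template references parts by these keys."""

    parts: dict[str, str] = field(default_factory=dict)
    trna_split: int = len(TRNA) // 2  # nt of tRNA carried by the backbone

    def __post_init__(self) -> None:
        defaults = {
            "kozak": KOZAK,
            "t2a": T2A_DNA,
            "gal4_orf": GAL4_ORF,
            "sfgfp": SFGFP_DNA,
            "splice_acceptor": SPLICE_ACCEPTOR,
            "splice_donor": SPLICE_DONOR,
            "polya": POLYA,
            "attp": ATTP,
            "frt": FRT,
            "pbac_ir": PBAC_IR,
            "marker_3xp3_egfp": MARKER_3XP3_EGFP,
            "marker_3xp3_dsred": MARKER_3XP3_DSRED,
            "u6_3_promoter": U6_3_PROMOTER,
            "sgrna_scaffold": SGRNA_SCAFFOLD,
            "trna": TRNA,
            "sgrna1_spacer": SGRNA1_SPACER,
            "sgrna1_target": SGRNA1_TARGET,
            "flap": FLAP,
            "x_flap": X_FLAP,
        }
        for k, v in defaults.items():
            self.parts.setdefault(k, v)
        for k, v in self.parts.items():
            if not v:
                raise ValueError(f"part {k!r} is empty")
        if self.parts["kozak"] != KOZAK and len(self.parts["kozak"]) != 4:
            raise ValueError("kozak part must be 4 nt (Golden Gate overhang)")

    def __getitem__(self, key: str) -> str:
        if key not in self.parts:
            raise KeyError(f"part {key!r} not in library")
        return self.parts[key]

    @property
    def trna_backbone_half(self) -> str:
        return self.parts["trna"][: self.trna_split]

    @property
    def trna_fragment_half(self) -> str:
        return self.parts["trna"][self.trna_split :]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PartsLibrary":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            parts={k: str(v).upper() for k, v in data.get("parts", {}).items()},
            trna_split=int(data.get("trna_split", len(TRNA) // 2)),
        )


def default_library() -> PartsLibrary:
    return PartsLibrary()
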