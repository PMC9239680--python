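"""Design parameters and configuration loading.

Every threshold the design rules use lives here so a run is fully described
by one config file.  Defaults encode the short-homology-arm donor method:
introns must exceed 100 nt, homology arms are 100-200 nt (200 by default),
and guide cuts keep a 30-nt buffer away from splice sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class OffTargetPolicy:
    """Rule-based specificity screen for SpCas9 guides.

    A candidate guide *fails* when another genomic site exists with (a) at
    most ``max_mismatches`` mismatches over the 20-mer next to an NGG or
    alternate PAM, or (b) a perfect PAM-proximal seed of ``seed_length`` nt
    next to an NGG.  This is a documented, configurable stand-in for web
    off-target finders.
    """

    max_mismatches: int = 3
    seed_length: int = 12
    alternate_pams: tuple[str, ...] = ("NAG",)

    def __post_init__(self) -> None:
        if not 0 < self.seed_length <= 20:
            raise ValueError("seed_length must be in (0, 20]")
        self.alternate_pams = tuple(self.alternate_pams)


@dataclass
class DesignParameters:
    min_suitable_intron_length: int = 100  # exclusive: intron must be > this
    homology_arm_length: int = 200  # allowed 100-200
    splice_buffer: int = 30  # nt kept clear on each side of an intron
    kozak_sequence: str = "CAAA"
    validation_amplicon_range: tuple[int, int] = (200, 800)
    promoter_scan_length: int = 500  # nt upstream of TSS for 5' fallback
    min_two_cut_intron_length: int = 23  # one protospacer + PAM
    two_cut_acceptor_window: int = 20  # cut within 3'-most nt of the intron
    primer_scan_window: int = 600  # nt beyond the arm searched for primers
    # synthesis feasibility
    max_homopolymer: int = 9
    gc_window: int = 100
    gc_range: tuple[float, float] = (0.25, 0.70)
    off_target: OffTargetPolicy = field(default_factory=OffTargetPolicy)

    def __post_init__(self) -> None:
        if not 100 <= self.homology_arm_length <= 200:
            raise ValueError("homology_arm_length must be within [100, 200]")
        lo, hi = self.validation_amplicon_range
        if lo >= hi:
            raise ValueError("validation_amplicon_range low must be < high")
        self.validation_amplicon_range = (lo, hi)
        self.gc_range = tuple(self.gc_range)  # type: ignore[assignment]


def load_params(path: str | Path | None = None, **overrides) -> DesignParameters:
    """Build :class:`DesignParameters` from an optional YAML file + overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    ot = data.pop("off_target", None)
    names = {f.name for f in dataclasses.fields(DesignParameters)} - {"off_target"}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    params = DesignParameters(**data)
    if ot is not None:
        params.off_target = OffTargetPolicy(**ot) if isinstance(ot, dict) else ot
    return params
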