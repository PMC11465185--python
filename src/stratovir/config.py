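"""Configuration objects for the synthetic community and the pipeline.

Month labels follow the sampling year of a monomictic lake: the series
starts in May, thermal stratification lasts May through December, and the
water column mixes from January to April.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

MONTHS: tuple[str, ...] = (
    "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
    "Jan", "Feb", "Mar", "Apr",
)
STRATIFIED_MONTHS: tuple[str, ...] = MONTHS[:8]

LAYERS: tuple[str, str] = ("epilimnion", "hypolimnion")


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the synthetic two-layer lake community.

    The defaults describe a guild-structured community: transient
    epilimnion specialists with short intense abundance peaks, persistent
    hypolimnion specialists occupying the deep layer through the stratified
    period, and year-round generalists, plus cellular decoy bins that the
    screening stage must reject.
    """

    n_epi_specialists: int = 60
    n_hypo_specialists: int = 30
    n_generalists: int = 30
    n_cellular_decoys: int = 10
    months: tuple[str, ...] = MONTHS
    stratified_months: tuple[str, ...] = STRATIFIED_MONTHS
    epi_peak_duration_months: int = 2
    hypo_occupancy_prob: float = 0.95
    abundance_lognormal_sigma: float = 0.5
    #: relative abundance of a guild in its home layer, arbitrary units
    epi_peak_amplitude: float = 3.0
    hypo_amplitude: float = 1.0
    generalist_amplitude: float = 0.3
    #: fraction of the home-layer amplitude leaking into the other layer
    cross_layer_leakage: float = 0.002
    genome_length_range: tuple[int, int] = (60_000, 400_000)
    max_contigs: int = 10
    #: probability that a single-contig linear GV genome gets a planted TIR
    tir_prob: float = 0.25
    reads_per_sample: int = 100_000
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_epi_specialists", "n_hypo_specialists",
                     "n_generalists", "n_cellular_decoys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not set(self.stratified_months) <= set(self.months):
            raise ValueError("stratified_months must be a subset of months")
        if not 0.0 <= self.hypo_occupancy_prob <= 1.0:
            raise ValueError("hypo_occupancy_prob must lie in [0, 1]")
        if not 0.0 <= self.cross_layer_leakage <= 1.0:
            raise ValueError("cross_layer_leakage must lie in [0, 1]")
        if not 0.0 <= self.tir_prob <= 1.0:
            raise ValueError("tir_prob must lie in [0, 1]")
        if self.epi_peak_duration_months < 1:
            raise ValueError("epi_peak_duration_months must be positive")
        if self.epi_peak_duration_months > len(self.stratified_months):
            raise ValueError(
                "epi_peak_duration_months cannot exceed the stratified period")
        if self.genome_length_range[0] <= 0:
            raise ValueError("genome lengths must be positive")

    @property
    def n_gv(self) -> int:
        return (self.n_epi_specialists + self.n_hypo_specialists
                + self.n_generalists)

    @property
    def n_total(self) -> int:
        return self.n_gv + self.n_cellular_decoys


# documented valid ranges for every pipeline threshold
_THRESHOLD_RANGES: dict[str, tuple[float, float]] = {
    "min_length_bp": (1, 10_000_000),
    "hk97_min_bitscore": (0, 10_000),
    "max_bac_completeness": (0, 100),
    "max_arc_completeness": (0, 100),
    "core_density_threshold": (0, 100),
    "ani_species_threshold": (50, 100),
    "polb_min_identity": (50, 100),
    "polb_min_coverage": (0, 1),
    "map_min_identity": (0, 1),
    "p_epi_upper": (0.5, 1),
    "p_epi_lower": (0, 0.5),
    "covered_fraction_threshold": (0, 1),
    "high_quality_completeness": (0, 100),
}


@dataclass
class PipelineConfig:
    """Every decision threshold of the pipeline plus file locations.

    Defaults are the study's printed cut-offs: genomes >50 kb with a
    nucleocytovirus marker or an HK97 MCP hit (bit score >100); CheckM
    bacterial completeness >15 or archaeal >20 flags a prokaryote; species
    are collapsed at ANI >=95%; polB capture requires >96% identity over
    >60% of the shorter gene; reads map at >=0.92 identity; P_epi >0.95 /
    <0.05 define the habitat specialists; persistence counts stratified
    months with covered fraction >20%.
    """

    min_length_bp: int = 50_000
    hk97_min_bitscore: float = 100.0
    max_bac_completeness: float = 15.0
    max_arc_completeness: float = 20.0
    core_density_threshold: float = 0.5
    ani_species_threshold: float = 95.0
    polb_min_identity: float = 96.0
    polb_min_coverage: float = 0.60
    map_min_identity: float = 0.92
    p_epi_upper: float = 0.95
    p_epi_lower: float = 0.05
    covered_fraction_threshold: float = 0.20
    high_quality_completeness: float = 90.0
    stratified_months: tuple[str, ...] = STRATIFIED_MONTHS
    seed: int = 0
    community: CommunityConfig = field(default_factory=CommunityConfig)
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(
                    f"{name}={value} outside documented range [{lo}, {hi}]")
        if self.p_epi_lower >= self.p_epi_upper:
            raise ValueError("p_epi_lower must be below p_epi_upper")
        if not set(self.stratified_months) <= set(MONTHS):
            raise ValueError("unknown month label in stratified_months")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stratified_months"] = list(self.stratified_months)
        d["community"]["months"] = list(self.community.months)
        d["community"]["stratified_months"] = list(
            self.community.stratified_months)
        d["community"]["genome_length_range"] = list(
            self.community.genome_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        comm = d.pop("community", {})
        for key in ("months", "stratified_months", "genome_length_range"):
            if key in comm:
                comm[key] = tuple(comm[key])
        if "stratified_months" in d:
            d["stratified_months"] = tuple(d["stratified_months"])
        return cls(community=CommunityConfig(**comm), **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
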