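"""Synthetic lake-community generator with known ground truth.

Emulates the study design the downstream statistics were built for: a
monthly time series over one year in a seasonally stratified lake, sampled
at two depths (epilimnion and hypolimnion, 24 samples), with a
guild-structured giant-virus community — transient epilimnion specialists,
persistent hypolimnion specialists and generalists — plus cellular decoy
bins. Every output carries its ground truth so each pipeline stage can be
scored exactly.

The generator is deliberately simple where realism is not the point: marker
genes are emitted as a hit table rather than as HMM-detectable sequence,
read sampling is Poisson, and sequences are uniform-random ACGT with
planted features (terminal inverted repeats, polB variants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import LAYERS, CommunityConfig

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

NCV_MARKERS = ("MCP", "PolB", "TFIIB", "TopoII", "A32", "SFII", "VLTF3")
CORE_GENES = tuple(f"core_{i}" for i in range(1, 21))
_DECOY_GENES = ("rpoB", "gyrA", "recA", "dnaK")

GUILDS = ("epi", "hypo", "generalist", "cellular")


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError("invalid alphabet") from exc


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


@dataclass
class GenomeSpec:
    """Ground-truth description of one synthetic genome bin."""

    mag_id: str
    length_bp: int
    n_contigs: int
    true_guild: str
    planted_markers: list[tuple[str, float]] = field(default_factory=list)
    planted_tir: tuple[int, int] | None = None  # (length bp, mismatches)
    is_circular: bool = False
    completeness_pct: float = 0.0
    bac_completeness: float = 0.0
    arc_completeness: float = 0.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.is_circular and self.n_contigs != 1:
            raise ValueError("circular genomes must be single-contig")


@dataclass
class SyntheticCommunity:
    """Bundle returned by :func:`generate_genomes`."""

    specs: list[GenomeSpec]
    contigs: dict[str, str]            # contig_id -> sequence (may be empty)
    markers: pd.DataFrame              # seq_id, gene, bit_score
    checkm: pd.DataFrame               # seq_id, bac_completeness, arc_completeness
    truth: pd.DataFrame                # mag_id, guild

    @property
    def genome_lengths(self) -> pd.Series:
        return pd.Series({s.mag_id: s.length_bp for s in self.specs},
                         name="length_bp")


def _mag_ids(config: CommunityConfig) -> list[tuple[str, str]]:
    """Deterministic (mag_id, guild) listing shared by all stages."""
    out: list[tuple[str, str]] = []
    i = 0
    for guild, n in (("epi", config.n_epi_specialists),
                     ("hypo", config.n_hypo_specialists),
                     ("generalist", config.n_generalists),
                     ("cellular", config.n_cellular_decoys)):
        for _ in range(n):
            i += 1
            out.append((f"MAG_{i:04d}", guild))
    return out


def generate_genomes(config: CommunityConfig,
                     with_sequences: bool = True) -> SyntheticCommunity:
    """Generate genome specs, contig sequences and annotation tables.

    Giant-virus guilds carry at least one of the seven nucleocytovirus
    marker genes (roughly one in ten is instead a mirusvirus with a single
    high-scoring HK97 MCP hit) and a handful of the 20 nucleocytovirus core
    genes. Cellular decoys carry housekeeping genes and high bacterial
    completeness so the prokaryote-exclusion rule must reject them. A
    fraction of single-contig GV genomes gets a planted terminal inverted
    repeat: the contig prefix equals the reverse complement of its suffix
    up to the planted number of mismatches.

    Set ``with_sequences=False`` to skip sequence materialisation when only
    lengths and tables are needed (abundance-level experiments).
    """
    members = _mag_ids(config)
    if not members:
        raise ValueError("empty community")
    rng = np.random.default_rng([config.seed, 1])

    specs: list[GenomeSpec] = []
    contigs: dict[str, str] = {}
    marker_rows: list[tuple[str, str, float]] = []

    for mag_id, guild in members:
        length = int(rng.integers(config.genome_length_range[0],
                                  config.genome_length_range[1] + 1))
        n_contigs = int(rng.integers(1, config.max_contigs + 1))
        is_circular = bool(n_contigs == 1 and rng.random() < 0.15)
        spec = GenomeSpec(mag_id=mag_id, length_bp=length,
                          n_contigs=n_contigs, true_guild=guild,
                          is_circular=is_circular)

        if guild == "cellular":
            spec.bac_completeness = float(rng.uniform(20.0, 95.0))
            spec.arc_completeness = float(rng.uniform(0.0, 10.0))
            spec.completeness_pct = 0.0
            for gene in rng.choice(_DECOY_GENES, size=2, replace=False):
                spec.planted_markers.append(
                    (str(gene), float(rng.uniform(80, 400))))
        else:
            spec.bac_completeness = float(rng.uniform(0.0, 10.0))
            spec.arc_completeness = float(rng.uniform(0.0, 10.0))
            spec.completeness_pct = float(rng.uniform(50.0, 100.0))
            if rng.random() < 0.1:  # mirusvirus: HK97 MCP only
                spec.planted_markers.append(
                    ("HK97_MCP", float(rng.uniform(120, 400))))
            else:
                n_markers = int(rng.integers(1, len(NCV_MARKERS) + 1))
                chosen = rng.choice(len(NCV_MARKERS), size=n_markers,
                                    replace=False)
                for j in sorted(chosen):
                    spec.planted_markers.append(
                        (NCV_MARKERS[j], float(rng.uniform(120, 500))))
            n_core = int(rng.integers(5, 16))
            core_idx = rng.choice(len(CORE_GENES), size=n_core, replace=False)
            for j in sorted(core_idx):
                spec.planted_markers.append(
                    (CORE_GENES[j], float(rng.uniform(60, 300))))
            if n_contigs == 1 and not is_circular and \
                    rng.random() < config.tir_prob:
                spec.planted_tir = (int(rng.integers(50, 201)), 0)

        marker_rows.extend(
            (mag_id, gene, round(score, 1))
            for gene, score in spec.planted_markers)
        specs.append(spec)

        if with_sequences:
            for cid, seq in _build_contigs(rng, spec).items():
                contigs[cid] = seq

    markers = pd.DataFrame(marker_rows,
                           columns=["seq_id", "gene", "bit_score"])
    checkm = pd.DataFrame(
        [(s.mag_id, round(s.bac_completeness, 2), round(s.arc_completeness, 2))
         for s in specs],
        columns=["seq_id", "bac_completeness", "arc_completeness"])
    truth = pd.DataFrame([(s.mag_id, s.true_guild) for s in specs],
                         columns=["mag_id", "guild"])
    return SyntheticCommunity(specs=specs, contigs=contigs, markers=markers,
                              checkm=checkm, truth=truth)


def _build_contigs(rng: np.random.Generator,
                   spec: GenomeSpec) -> dict[str, str]:
    """Split a random genome into contigs; plant the TIR on contig 1."""
    lengths = _split_lengths(rng, spec.length_bp, spec.n_contigs)
    out: dict[str, str] = {}
    for i, clen in enumerate(lengths, start=1):
        seq = random_sequence(rng, clen)
        if i == 1 and spec.planted_tir is not None:
            tir_len, n_mm = spec.planted_tir
            core = seq[tir_len:clen - tir_len]
            left = seq[:tir_len]
            right = list(reverse_complement(left))
            if n_mm:
                pos = rng.choice(tir_len, size=n_mm, replace=False)
                for p in pos:
                    alternatives = [b for b in "ACGT" if b != right[p]]
                    right[p] = alternatives[int(rng.integers(0, 3))]
            seq = left + core + "".join(right)
        out[f"{spec.mag_id}_c{i}"] = seq
    return out


def _split_lengths(rng: np.random.Generator, total: int,
                   n_parts: int) -> list[int]:
    if n_parts == 1:
        return [total]
    # random composition with every part >= 5% of an even share
    floor = max(1, total // (20 * n_parts))
    weights = rng.dirichlet(np.full(n_parts, 2.0))
    lengths = np.maximum(floor, (weights * total).astype(int))
    lengths[-1] = total - int(lengths[:-1].sum())
    if lengths[-1] < 1:  # pathological split; fall back to even parts
        lengths = np.full(n_parts, total // n_parts)
        lengths[-1] += total - int(lengths.sum())
    return [int(x) for x in lengths]


# ---------------------------------------------------------------------------
# abundance dynamics

def simulate_dynamics(
        config: CommunityConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate true abundance trajectories for every GV genome.

    Returns ``(abundance, sample_meta)``. ``abundance`` is indexed by
    mag_id with a (month, layer) column MultiIndex; ``sample_meta`` has one
    row per sample with columns month, layer, stratified.

    Guild templates: an epilimnion specialist has a single contiguous peak
    of ``epi_peak_duration_months`` in the epilimnion during stratification;
    a hypolimnion specialist occupies the hypolimnion each stratified month
    with probability ``hypo_occupancy_prob``; generalists sit in both layers
    all year. A small fixed fraction of the home-layer signal leaks into
    the other layer. During the mixing months the two layers are linearly
    interpolated toward their mean, reaching complete mixing in the final
    month. Multiplicative lognormal noise (mean 1) is applied last.
    """
    members = [(m, g) for m, g in _mag_ids(config) if g != "cellular"]
    if not members:
        raise ValueError("empty community")
    months = list(config.months)
    strat = [months.index(m) for m in config.stratified_months]
    n_strat = len(strat)
    n_months = len(months)
    rng = np.random.default_rng([config.seed, 2])

    # structural randomness is drawn before noise so that sigma=0 yields
    # the identical deterministic template
    peak_starts = {}
    occupancy = {}
    for mag_id, guild in members:
        if guild == "epi":
            peak_starts[mag_id] = int(
                rng.integers(0, n_strat - config.epi_peak_duration_months + 1))
        elif guild == "hypo":
            occupancy[mag_id] = (
                rng.random(n_strat) < config.hypo_occupancy_prob)

    leak = config.cross_layer_leakage
    epi_tpl = np.zeros((len(members), n_months))
    hypo_tpl = np.zeros((len(members), n_months))
    for row, (mag_id, guild) in enumerate(members):
        if guild == "epi":
            s = peak_starts[mag_id]
            sl = strat[s:s + config.epi_peak_duration_months]
            epi_tpl[row, sl] = config.epi_peak_amplitude
            hypo_tpl[row, sl] = config.epi_peak_amplitude * leak
        elif guild == "hypo":
            occ_months = [strat[i] for i in range(n_strat)
                          if occupancy[mag_id][i]]
            hypo_tpl[row, occ_months] = config.hypo_amplitude
            epi_tpl[row, occ_months] = config.hypo_amplitude * leak
        else:  # generalist
            epi_tpl[row, :] = config.generalist_amplitude
            hypo_tpl[row, :] = config.generalist_amplitude

    # mixing months: linear convergence of the two layers toward their mean
    mixing = [i for i in range(n_months) if i not in strat]
    for j, mi in enumerate(mixing, start=1):
        w = j / len(mixing)
        mean = 0.5 * (epi_tpl[:, mi] + hypo_tpl[:, mi])
        epi_tpl[:, mi] = (1 - w) * epi_tpl[:, mi] + w * mean
        hypo_tpl[:, mi] = (1 - w) * hypo_tpl[:, mi] + w * mean

    sigma = config.abundance_lognormal_sigma
    noise_epi = np.exp(rng.normal(0.0, sigma, size=epi_tpl.shape)
                       - 0.5 * sigma ** 2)
    noise_hypo = np.exp(rng.normal(0.0, sigma, size=hypo_tpl.shape)
                        - 0.5 * sigma ** 2)

    columns = pd.MultiIndex.from_product([months, LAYERS],
                                         names=["month", "layer"])
    values = np.empty((len(members), n_months * 2))
    values[:, 0::2] = epi_tpl * noise_epi
    values[:, 1::2] = hypo_tpl * noise_hypo
    abundance = pd.DataFrame(values, index=[m for m, _ in members],
                             columns=columns)
    abundance.index.name = "mag_id"

    sample_meta = pd.DataFrame(
        [(m, layer, m in config.stratified_months)
         for m in months for layer in LAYERS],
        columns=["month", "layer", "stratified"])
    return abundance, sample_meta


def abundance_to_reads(
        abundance: pd.DataFrame,
        genome_lengths: pd.Series | Mapping[str, int],
        config: CommunityConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Poisson read sampling from true abundances.

    Per sample, a genome's expected read count is proportional to
    abundance x genome length, normalised so that the expected total per
    sample equals ``reads_per_sample``. Coverage depth is
    ``count * read_length / genome_length`` and the covered fraction
    follows the Lander-Waterman approximation ``1 - exp(-depth)``.

    Returns ``(counts, depth, covered_fraction)`` frames shaped like the
    input abundance table.
    """
    if (abundance.values < 0).any():
        raise ValueError("abundances must be non-negative")
    lengths = pd.Series(genome_lengths).reindex(abundance.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise KeyError(f"missing genome lengths for {missing}")
    rng = np.random.default_rng([config.seed, 3])

    weights = abundance.mul(lengths, axis=0)
    totals = weights.sum(axis=0)
    mean = weights.div(totals.where(totals > 0, 1.0), axis=1) \
                  .mul(config.reads_per_sample)
    counts = pd.DataFrame(rng.poisson(mean.values),
                          index=abundance.index, columns=abundance.columns)
    depth = counts.mul(config.read_length).div(lengths, axis=0)
    covfrac = 1.0 - np.exp(-depth)
    return counts, depth, covfrac


def covered_fraction_from_depth(depth):
    """Lander-Waterman expected covered fraction, 1 - exp(-depth)."""
    return 1.0 - np.exp(-np.asarray(depth, dtype=float))


# ---------------------------------------------------------------------------
# polB divergence fixtures

@dataclass(frozen=True)
class PolbVariant:
    seq_id: str
    source_id: str
    sequence: str
    identity: float  # exact fraction of unmutated sites


def mutate_polb(reference_sequences: Mapping[str, str],
                per_site_divergence: float,
                seed: int) -> list[PolbVariant]:
    """Derive substitution-only variants with exactly known identities.

    Each site mutates independently with probability
    ``per_site_divergence`` to one of the three other bases; no indels are
    introduced, so the recorded identity (fraction of unmutated sites) is
    exact.
    """
    if not 0.0 <= per_site_divergence <= 0.5:
        raise ValueError("per_site_divergence must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    variants: list[PolbVariant] = []
    for name, ref in reference_sequences.items():
        seq = list(ref)
        hit = rng.random(len(seq)) < per_site_divergence
        n_mut = 0
        for pos in np.flatnonzero(hit):
            alternatives = [b for b in "ACGT" if b != seq[pos]]
            seq[pos] = alternatives[int(rng.integers(0, 3))]
            n_mut += 1
        identity = 1.0 - n_mut / len(seq) if seq else 1.0
        variants.append(PolbVariant(seq_id=f"{name}_var",
                                    source_id=name,
                                    sequence="".join(seq),
                                    identity=identity))
    return variants
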