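"""Giant-virus MAG screening rules and assembly-quality metrics.

Decision rules: a candidate giant-virus genome must exceed 50 kb and carry
at least one of the seven nucleocytovirus marker genes (MCP, PolB, TFIIB,
TopoII, A32, SFII, VLTF3) or a mirusvirus HK97-fold major capsid protein
hit with bit score above 100. Bins whose CheckM-style completeness exceeds
15 (bacterial) or 20 (archaeal) are treated as prokaryotes and excluded.
Nucleocytovirus membership is additionally supported by a core-gene density
index: distinct hits among 20 nucleocytovirus core genes per 100 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .synthetic import CORE_GENES, NCV_MARKERS, reverse_complement

logger = logging.getLogger(__name__)

NCV_MARKER_SET = frozenset(NCV_MARKERS)
CORE_GENE_SET = frozenset(CORE_GENES)
KNOWN_GENES = NCV_MARKER_SET | CORE_GENE_SET | {"HK97_MCP"}


@dataclass
class MagRecord:
    """One genome bin with its marker hits and completeness estimates."""

    mag_id: str
    contig_lengths: list[int]
    marker_hits: list[tuple[str, float]] = field(default_factory=list)
    completeness_pct: float = 0.0
    bac_completeness: float = 0.0
    arc_completeness: float = 0.0

    @property
    def total_length_bp(self) -> int:
        return int(sum(self.contig_lengths))


@dataclass(frozen=True)
class TirHit:
    """A terminal inverted repeat: prefix == revcomp(suffix) up to mismatches."""

    repeat_length: int
    start_offset: int
    mismatches: int


@dataclass(frozen=True)
class QualitySummary:
    tier: str
    n50: int
    n_contigs: int
    marker_count_of_7: int
    single_contig: bool


def _split_hits(marker_hits: Iterable[tuple[str, float]]):
    """Partition hits into known vocabularies, warning on unknown genes."""
    ncv, hk97, core = [], [], []
    for gene, score in marker_hits:
        if gene in NCV_MARKER_SET:
            ncv.append((gene, score))
        elif gene == "HK97_MCP":
            hk97.append((gene, score))
        elif gene in CORE_GENE_SET:
            core.append((gene, score))
        else:
            logger.warning("ignoring unknown gene name %r", gene)
    return ncv, hk97, core


def is_gv_candidate(length_bp: int,
                    marker_hits: Iterable[tuple[str, float]],
                    min_length_bp: int = 50_000,
                    hk97_min_bitscore: float = 100.0) -> bool:
    """True iff the sequence passes the giant-virus candidate screen.

    Requires length strictly above ``min_length_bp`` and either >=1 hit
    among the seven nucleocytovirus markers or an HK97 MCP hit with bit
    score strictly above ``hk97_min_bitscore``.
    """
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if length_bp <= min_length_bp:
        return False
    ncv, hk97, _ = _split_hits(marker_hits)
    if ncv:
        return True
    return any(score > hk97_min_bitscore for _, score in hk97)


def exclude_prokaryote(bac_completeness: float | None,
                       arc_completeness: float | None,
                       max_bac: float = 15.0,
                       max_arc: float = 20.0) -> bool:
    """True when the bin looks prokaryotic and must be excluded.

    Strict inequalities: bacterial completeness >15 or archaeal >20.
    Missing values are treated as 0 with a warning.
    """
    if bac_completeness is None or np.isnan(bac_completeness):
        logger.warning("missing bacterial completeness treated as 0")
        bac_completeness = 0.0
    if arc_completeness is None or np.isnan(arc_completeness):
        logger.warning("missing archaeal completeness treated as 0")
        arc_completeness = 0.0
    if not (0 <= bac_completeness <= 100 and 0 <= arc_completeness <= 100):
        raise ValueError("completeness values must lie in [0, 100]")
    return bac_completeness > max_bac or arc_completeness > max_arc


def core_gene_density(mag: MagRecord,
                      threshold: float = 0.5) -> tuple[float, bool]:
    """Distinct nucleocytovirus core genes per 100 kb, plus the verdict.

    The verdict is ``density >= threshold``. The index separates
    marker-dense viral genomes from megabase-scale cellular sequences with
    sporadic hits.
    """
    if mag.total_length_bp <= 0:
        raise ValueError("total_length_bp must be positive")
    _, _, core = _split_hits(mag.marker_hits)
    n_distinct = len({gene for gene, _ in core})
    density = n_distinct / (mag.total_length_bp / 100_000)
    return density, density >= threshold


def n50(contig_lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L sum to >= half the total."""
    if not contig_lengths:
        raise ValueError("need at least one contig")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    return lengths[-1]  # unreachable


def marker_count_of_7(marker_hits: Iterable[tuple[str, float]]) -> int:
    ncv, _, _ = _split_hits(marker_hits)
    return len({gene for gene, _ in ncv})


def quality_summary(mag: MagRecord,
                    high_quality_completeness: float = 90.0) -> QualitySummary:
    """Completeness tier, N50 and marker tally for one MAG.

    Tier is "high" above the high-quality completeness cut-off (strict,
    default >90), "medium" at >=50 and "low" below, following the MIMAG
    convention for the lower boundaries.
    """
    if not mag.contig_lengths:
        raise ValueError("need at least one contig")
    if mag.completeness_pct > high_quality_completeness:
        tier = "high"
    elif mag.completeness_pct >= 50.0:
        tier = "medium"
    else:
        tier = "low"
    return QualitySummary(tier=tier,
                          n50=n50(mag.contig_lengths),
                          n_contigs=len(mag.contig_lengths),
                          marker_count_of_7=marker_count_of_7(mag.marker_hits),
                          single_contig=len(mag.contig_lengths) == 1)


_VALID = frozenset("ACGT")


def find_tir(sequence: str,
             min_len: int = 20,
             window: int = 5000,
             max_mismatch_frac: float = 0.05) -> TirHit | None:
    """Detect a terminal inverted repeat, the signature of a linear genome.

    Returns the longest prefix length L (up to ``window``, truncated to
    half the sequence) such that the first L bases match the reverse
    complement of the last L bases with a mismatch fraction at most
    ``max_mismatch_frac``, requiring L >= ``min_len``. Coordinates are
    0-based half-open.

    For the prefix/suffix comparison at length L, position i of the
    reverse-complemented suffix is the complement of base n-1-i, so a
    single complement-mismatch profile over the window serves every L.
    """
    if set(sequence) - _VALID:
        raise ValueError("invalid alphabet")
    n = len(sequence)
    w = min(window, n // 2)
    if w < min_len:
        return None
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mism = np.fromiter(
        (sequence[i] != comp[sequence[n - 1 - i]] for i in range(w)),
        dtype=bool, count=w)
    cum = np.cumsum(mism)
    best = None
    for length in range(min_len, w + 1):
        mm = int(cum[length - 1])
        if mm / length <= max_mismatch_frac:
            best = TirHit(repeat_length=length, start_offset=0, mismatches=mm)
    return best


def poa90(protein_alignment_coverages: Sequence[float]) -> float | None:
    """Percentage of protein alignment coverages at or above 0.90.

    A proxy for unpolished indel errors: frameshifts truncate predicted
    proteins, dragging per-gene alignment coverage below 90%. Returns
    ``None`` (missing) for an empty list rather than 0.
    """
    if len(protein_alignment_coverages) == 0:
        return None
    cov = np.asarray(protein_alignment_coverages, dtype=float)
    if ((cov < 0) | (cov > 1)).any():
        raise ValueError("coverages must lie in [0, 1]")
    return float(100.0 * np.mean(cov >= 0.90))


def fragmentation_compare(group_a_values: Sequence[float],
                          group_b_values: Sequence[float],
                          ) -> tuple[float, float, float | None]:
    """Median fragmentation per group plus a two-sided Mann-Whitney U p.

    Used to compare contig counts (or N50) between two MAG catalogues.
    Groups smaller than 2 get their medians but a missing p-value.
    """
    if len(group_a_values) == 0 or len(group_b_values) == 0:
        raise ValueError("both groups must be non-empty")
    med_a = float(np.median(group_a_values))
    med_b = float(np.median(group_b_values))
    if len(group_a_values) < 2 or len(group_b_values) < 2:
        return med_a, med_b, None
    # exact U distribution where affordable and tie-free, else asymptotic
    pooled = list(group_a_values) + list(group_b_values)
    no_ties = len(set(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(group_a_values),
                                         len(group_b_values)) <= 25) \
        else "auto"
    res = stats.mannwhitneyu(group_a_values, group_b_values,
                             alternative="two-sided", method=method)
    return med_a, med_b, float(res.pvalue)


def marker_based_completeness(marker_hits: Iterable[tuple[str, float]]) -> float:
    """Fallback completeness from the 7-marker tally; never auto-substituted."""
    return marker_count_of_7(marker_hits) / 7.0 * 100.0


def screen_mag(mag: MagRecord,
               min_length_bp: int = 50_000,
               hk97_min_bitscore: float = 100.0,
               max_bac: float = 15.0,
               max_arc: float = 20.0) -> tuple[bool, str]:
    """Full screening decision for one bin: (keep, reason)."""
    if exclude_prokaryote(mag.bac_completeness, mag.arc_completeness,
                          max_bac=max_bac, max_arc=max_arc):
        return False, "prokaryote"
    if not is_gv_candidate(mag.total_length_bp, mag.marker_hits,
                           min_length_bp=min_length_bp,
                           hk97_min_bitscore=hk97_min_bitscore):
        return False, "no_gv_signal_or_short"
    return True, "gv"
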