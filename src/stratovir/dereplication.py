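"""Species-level dereplication and polB diversity-capture assessment.

Genomes are collapsed into species clusters at an average nucleotide
identity (ANI) of 95% by greedy centroid clustering on a supplied pairwise
ANI table: genomes are visited in decreasing quality-score order and join
the first representative they match at >=95% ANI, else found a new
cluster. Representatives receive four-digit serial IDs ordered by their
maximum per-sample read coverage.

Diversity capture asks what fraction of environmental polB gene clusters
is represented in the final genome catalogue, using a species-level match
rule of >96% nucleotide identity over >60% of the shorter sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SpeciesClusterSet:
    """ANI-based species clusters with representatives and serial IDs."""

    clusters: list[tuple[str, list[str]]]  # (representative, members incl. rep)
    serial_ids: dict[str, str] = field(default_factory=dict)

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    @property
    def n_genomes(self) -> int:
        return sum(len(members) for _, members in self.clusters)


def _ani_lookup(ani_table) -> dict[tuple[str, str], float]:
    """Build a symmetric ANI lookup from a long table or a pair mapping."""
    pairs: dict[tuple[str, str], float] = {}
    if isinstance(ani_table, pd.DataFrame):
        items = ani_table[["query", "subject", "ani_pct"]].itertuples(
            index=False)
    else:
        items = ((a, b, v) for (a, b), v in ani_table.items())
    for a, b, v in items:
        v = float(v)
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"ANI {v} outside [0, 100] for ({a}, {b})")
        pairs[(a, b)] = v
        pairs[(b, a)] = v
    return pairs


def cluster_species(ani_table,
                    quality_scores: Mapping[str, float],
                    ani_threshold: float = 95.0) -> SpeciesClusterSet:
    """Greedy centroid clustering at the species ANI boundary.

    ``ani_table`` is either a DataFrame with columns query/subject/ani_pct
    or a mapping ``(a, b) -> ani``; missing pairs are treated as below the
    threshold (sparse tables allowed). ``quality_scores`` orders the greedy
    visit (descending; ties broken by mag_id), so every representative is
    the best-scoring member of its cluster.
    """
    ani = _ani_lookup(ani_table)
    order = sorted(quality_scores, key=lambda m: (-quality_scores[m], m))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for genome in order:
        home = None
        for rep in reps:
            if ani.get((genome, rep), -math.inf) >= ani_threshold:
                home = rep
                break
        if home is None:
            reps.append(genome)
            members[genome] = [genome]
        else:
            members[home].append(genome)
    return SpeciesClusterSet(clusters=[(r, members[r]) for r in reps])


def drep_quality_score(completeness_pct: float, n50: int) -> float:
    """Default genome quality score: completeness + 10*log10(N50)."""
    return float(completeness_pct + 10.0 * math.log10(n50))


def assign_serial_ids(representatives: Sequence[str],
                      coverage_matrix: pd.DataFrame) -> dict[str, str]:
    """Serial IDs 0001, 0002, ... by descending maximum per-sample coverage.

    ``coverage_matrix`` is indexed by mag_id with one column per sample.
    Ties are broken lexicographically by mag_id.
    """
    missing = [r for r in representatives if r not in coverage_matrix.index]
    if missing:
        raise KeyError(f"representatives missing from coverage matrix: "
                       f"{missing}")
    max_cov = coverage_matrix.loc[list(representatives)].max(axis=1)
    ranked = sorted(representatives, key=lambda m: (-max_cov[m], m))
    return {mag: f"{i:04d}" for i, mag in enumerate(ranked, start=1)}


def species_match(identity_pct: float,
                  aligned_len: int,
                  len_query: int,
                  len_subject: int,
                  min_identity: float = 96.0,
                  min_coverage: float = 0.60) -> bool:
    """Species-level gene match: >96% identity over >60% of the shorter seq."""
    if len_query <= 0 or len_subject <= 0:
        raise ValueError("sequence lengths must be positive")
    if not 0.0 <= identity_pct <= 100.0:
        raise ValueError("identity_pct must lie in [0, 100]")
    shorter = min(len_query, len_subject)
    if aligned_len > shorter:
        raise ValueError("inconsistent alignment")
    return identity_pct > min_identity and aligned_len / shorter > min_coverage


# ---------------------------------------------------------------------------
# toy global aligner (exact Needleman-Wunsch; fixture-scale sequences only)

@dataclass(frozen=True)
class AlignmentResult:
    score: int
    matches: int
    columns: int       # total alignment columns incl. gaps
    aligned_len: int   # columns where both sequences have a residue

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 100.0


MATCH, MISMATCH, GAP = 1, -1, -2


def global_align(a: str, b: str) -> AlignmentResult:
    """Exact global dynamic-programming alignment (match +1 / mismatch -1 /
    gap -2), identity = matches / alignment columns."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return AlignmentResult(score=GAP * (n + m), matches=0,
                               columns=n + m, aligned_len=0)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    score[0, :] = GAP * np.arange(m + 1)
    score[:, 0] = GAP * np.arange(n + 1)
    sub = np.where(av[:, None] == bv[None, :], MATCH, MISMATCH)
    gap_j = GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        up = score[i - 1, 1:] + GAP
        best = np.maximum(diag, up)
        # the left-gap recurrence row[j] = max(best[j-1], row[j-1]+GAP)
        # unrolls to GAP*j + cummax(best[l-1] - GAP*l), solvable in one pass
        head = np.concatenate(([score[i, 0]], best - gap_j[1:]))
        score[i, 1:] = gap_j[1:] + np.maximum.accumulate(head)[1:]
    # traceback, preferring diagonal moves
    i, j = n, m
    matches = columns = aligned = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and \
                score[i, j] == score[i - 1, j - 1] + sub[i - 1, j - 1]:
            matches += int(av[i - 1] == bv[j - 1])
            aligned += 1
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        columns += 1
    return AlignmentResult(score=int(score[n, m]), matches=matches,
                           columns=columns, aligned_len=aligned)


def capture_fraction(polb_cluster_reps: Mapping[str, str],
                     mag_polb_sequences: Mapping[str, str],
                     alignments: pd.DataFrame | None = None,
                     min_identity: float = 96.0,
                     min_coverage: float = 0.60,
                     ) -> tuple[float, dict[str, bool]]:
    """Fraction of environmental polB clusters captured by the catalogue.

    A cluster is captured when at least one catalogue polB satisfies the
    species-level match rule against its representative. Alignment either
    uses the built-in exact global aligner or a precomputed table with
    columns rep_id, mag_seq_id, identity_pct, aligned_len.
    """
    if not polb_cluster_reps:
        raise ValueError("empty polB cluster set")
    if not mag_polb_sequences:
        logger.warning("no catalogue polB sequences; capture fraction is 0")
        return 0.0, {rep: False for rep in polb_cluster_reps}

    verdicts: dict[str, bool] = {}
    if alignments is not None:
        grouped = {k: g for k, g in alignments.groupby("rep_id")}
        for rep, rep_seq in polb_cluster_reps.items():
            captured = False
            for row in grouped.get(rep, pd.DataFrame()).itertuples():
                mag_len = len(mag_polb_sequences[row.mag_seq_id])
                if species_match(row.identity_pct, row.aligned_len,
                                 len(rep_seq), mag_len,
                                 min_identity, min_coverage):
                    captured = True
                    break
            verdicts[rep] = captured
    else:
        for rep, rep_seq in polb_cluster_reps.items():
            captured = False
            for mag_seq in mag_polb_sequences.values():
                aln = global_align(rep_seq, mag_seq)
                if species_match(aln.identity_pct, aln.aligned_len,
                                 len(rep_seq), len(mag_seq),
                                 min_identity, min_coverage):
                    captured = True
                    break
            verdicts[rep] = captured
    fraction = sum(verdicts.values()) / len(verdicts)
    return fraction, verdicts
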