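"""Abundance profiling and community dissimilarity structure.

RPKM (reads per kilobase of genome per million mapped reads) per MAG and
sample, Bray-Curtis dissimilarities between samples, a toy read mapper for
fixture-scale end-to-end runs, and within-layer dispersion comparisons
restricted to the stratified period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class AbundanceTensor:
    """Per-MAG x per-sample abundance grids plus sample metadata.

    Each grid is indexed by mag_id with a (month, layer) column
    MultiIndex; ``sample_meta`` has columns month, layer, stratified.
    """

    rpkm: pd.DataFrame | None
    depth: pd.DataFrame | None
    covered_fraction: pd.DataFrame | None
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("rpkm", "depth", "covered_fraction"):
            grid = getattr(self, name)
            if grid is not None and (grid.values < 0).any():
                raise ValueError(f"{name} contains negative values")
        if self.covered_fraction is not None and \
                (self.covered_fraction.values > 1).any():
            raise ValueError("covered fraction must lie in [0, 1]")


def rpkm(read_count: float, genome_length_bp: float,
         total_mapped_reads: float) -> float:
    """Reads per kilobase of genome per million mapped reads."""
    if genome_length_bp <= 0 or total_mapped_reads <= 0:
        raise ValueError("genome length and total mapped reads must be > 0")
    return read_count / ((genome_length_bp / 1_000)
                         * (total_mapped_reads / 1_000_000))


def rpkm_table(counts: pd.DataFrame,
               genome_lengths: pd.Series | Mapping[str, int]) -> pd.DataFrame:
    """Vectorised RPKM over a counts grid; per-sample totals from the grid."""
    lengths = pd.Series(genome_lengths).reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("missing genome lengths")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        zero = totals[totals <= 0].index.tolist()
        logger.warning("samples with zero mapped reads: %s", zero)
        totals = totals.where(totals > 0, 1.0)
    return counts.div(lengths / 1_000, axis=0).div(totals / 1_000_000, axis=1)


def bray_curtis(x_profile, y_profile) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); 0 for two zero profiles."""
    x = np.asarray(x_profile, dtype=float)
    y = np.asarray(y_profile, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("profiles must be non-negative")
    denom = float((x + y).sum())
    if denom == 0.0:
        logger.warning("both profiles all-zero; Bray-Curtis defined as 0")
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis matrix from a MAG x sample grid."""
    samples = list(profiles.columns)
    n = len(samples)
    out = np.zeros((n, n))
    vals = profiles.values
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(vals[:, i], vals[:, j])
    cols = (pd.Index(samples) if not isinstance(profiles.columns,
                                                pd.MultiIndex)
            else profiles.columns)
    return pd.DataFrame(out, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# toy read mapper

def toy_map_reads(reads: Mapping[str, str],
                  genome_sequences: Mapping[str, str],
                  min_identity: float = 0.92,
                  k: int = 15,
                  seed: int = 0):
    """Assign each read to its best-identity ungapped location.

    A k-mer index seeds candidate diagonals; each candidate is scored by
    ungapped identity over the full read, both strands are searched, reads
    below ``min_identity`` are discarded, and ties are broken uniformly at
    random under ``seed``. Fixture-scale only — study-scale mapping is done
    by external mappers and enters the pipeline as count tables.

    Returns ``(counts, mean_depth, covered_fraction)`` keyed by genome id,
    plus the number of unmapped reads, as a 4-tuple.
    """
    if not genome_sequences:
        raise ValueError("empty genome set")
    rng = np.random.default_rng(seed)

    index: dict[str, list[tuple[str, int]]] = {}
    for gid, seq in genome_sequences.items():
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((gid, pos))

    coverage = {gid: np.zeros(len(seq), dtype=np.int32)
                for gid, seq in genome_sequences.items()}
    counts = {gid: 0 for gid in genome_sequences}
    unmapped = 0

    for read in reads.values():
        best: list[tuple[str, int]] = []
        best_ident = -1.0
        for oriented in (read, reverse_complement(read)):
            L = len(oriented)
            seen: set[tuple[str, int]] = set()
            for off in range(0, max(1, L - k + 1), k):
                for gid, pos in index.get(oriented[off:off + k], ()):
                    start = pos - off
                    if start < 0 or (gid, start) in seen:
                        continue
                    seen.add((gid, start))
                    target = genome_sequences[gid][start:start + L]
                    if len(target) < L:
                        continue
                    ident = sum(a == b for a, b in zip(oriented, target)) / L
                    if ident > best_ident:
                        best_ident, best = ident, [(gid, start)]
                    elif ident == best_ident:
                        best.append((gid, start))
        if best_ident < min_identity or not best:
            unmapped += 1
            continue
        gid, start = best[int(rng.integers(0, len(best)))]
        counts[gid] += 1
        coverage[gid][start:start + len(read)] += 1

    mean_depth = {gid: float(cov.mean()) for gid, cov in coverage.items()}
    covfrac = {gid: float((cov > 0).mean()) for gid, cov in coverage.items()}
    return counts, mean_depth, covfrac, unmapped


# ---------------------------------------------------------------------------
# dispersion and composition

def sample_key(month: str, layer: str) -> str:
    return f"{month}_{layer}"


def within_layer_dispersion(beta: pd.DataFrame,
                            sample_meta: pd.DataFrame,
                            stratified_only: bool = True):
    """Within-layer pairwise dissimilarities and a Mann-Whitney comparison.

    ``beta`` is a sample x sample dissimilarity matrix whose index matches
    the (month, layer) pairs in ``sample_meta`` (either a MultiIndex or
    "month_layer" strings). Returns ``(per_layer, p_value)`` where
    ``per_layer`` maps layer -> list of pairwise values among that layer's
    (optionally stratified-only) samples.
    """
    meta = sample_meta
    if stratified_only:
        meta = meta[meta["stratified"]]
    per_layer: dict[str, list[float]] = {}
    for layer, grp in meta.groupby("layer"):
        keys = []
        for _, row in grp.iterrows():
            key = ((row["month"], row["layer"])
                   if isinstance(beta.index, pd.MultiIndex)
                   else sample_key(row["month"], row["layer"]))
            if key in beta.index:
                keys.append(key)
        if len(keys) < 2:
            logger.warning("layer %s has <2 samples; reported empty", layer)
            per_layer[layer] = []
            continue
        sub = beta.loc[keys, keys].values
        iu = np.triu_indices(len(keys), k=1)
        per_layer[layer] = [float(v) for v in sub[iu]]
    groups = [v for v in per_layer.values() if len(v) >= 2]
    if len(groups) == 2:
        p = float(stats.mannwhitneyu(groups[0], groups[1],
                                     alternative="two-sided").pvalue)
    else:
        p = None
    return per_layer, p


def composition_by_group(rpkm_grid: pd.DataFrame,
                         taxonomy: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample RPKM sums by taxonomic group (order/clade).

    MAGs missing from ``taxonomy`` fall into "unassigned". Group sums per
    sample equal the sample's total RPKM.
    """
    labels = pd.Series({m: taxonomy.get(m, "unassigned")
                        for m in rpkm_grid.index})
    return rpkm_grid.groupby(labels).sum()
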