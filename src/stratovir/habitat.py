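"""Habitat-preference classification and persistence statistics.

The habitat-specificity index P_epi of a genome is its cumulative
epilimnion RPKM divided by its cumulative RPKM in both layers over the
stratified months; P_epi > 0.95 defines an epilimnion specialist and
P_epi < 0.05 a hypolimnion specialist. Persistence is the longest run of
consecutive stratified months in which the genome's covered fraction
exceeds 20%, evaluated in the specialist's own layer. Group mean
persistence is compared with the Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

EPI = "epilimnion-specific"
HYPO = "hypolimnion-specific"
GENERALIST = "generalist"
UNCLASSIFIED = "unclassified"
LABELS = (EPI, HYPO, GENERALIST, UNCLASSIFIED)


@dataclass
class HabitatCall:
    mag_id: str
    p_epi: float | None
    label: str
    persistence_months: int | None = None


def p_epi(rpkm_epi_by_month: Mapping[str, float] | pd.Series,
          rpkm_hypo_by_month: Mapping[str, float] | pd.Series,
          stratified_months: Sequence[str]) -> float | None:
    """Habitat-specificity index over the stratified months.

    ``sum(epi) / (sum(epi) + sum(hypo))`` with sums restricted to
    ``stratified_months``; ``None`` (undefined) when the denominator is 0.
    """
    epi = pd.Series(rpkm_epi_by_month)
    hypo = pd.Series(rpkm_hypo_by_month)
    missing = [m for m in stratified_months
               if m not in epi.index or m not in hypo.index]
    if missing:
        raise ValueError(f"series misaligned: missing months {missing}")
    e = float(epi[list(stratified_months)].sum())
    h = float(hypo[list(stratified_months)].sum())
    if e < 0 or h < 0:
        raise ValueError("RPKM values must be non-negative")
    if e + h == 0:
        return None
    return e / (e + h)


def classify_habitat(p: float | None,
                     upper: float = 0.95,
                     lower: float = 0.05) -> str:
    """Map P_epi to a habitat label (strict thresholds)."""
    if p is None:
        return UNCLASSIFIED
    if not 0.0 <= p <= 1.0:
        raise ValueError("P_epi must lie in [0, 1]")
    if p > upper:
        return EPI
    if p < lower:
        return HYPO
    return GENERALIST


def persistence(covered_fraction_by_month: Mapping[str, float] | pd.Series,
                stratified_months: Sequence[str],
                threshold: float = 0.20) -> int:
    """Longest run of consecutive stratified months with covered fraction
    strictly above ``threshold``. Months outside the stratified period are
    ignored; runs do not wrap around."""
    if len(stratified_months) == 0:
        raise ValueError("empty stratified period")
    series = pd.Series(covered_fraction_by_month)
    vals = [float(series[m]) for m in stratified_months]
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("covered fractions must lie in [0, 1]")
    best = run = 0
    for v in vals:
        run = run + 1 if v > threshold else 0
        best = max(best, run)
    return best


_P_FLOOR = 1e-300  # underflow-safe minimum for degenerate zero-variance case


def welch_t(group_a: Sequence[float],
            group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    t = (ma - mb) / sqrt(sa^2/na + sb^2/nb) with Welch-Satterthwaite
    degrees of freedom; the p-value comes from the t survival function.
    Zero variance in both groups yields p = 1 for equal means and an
    underflow-safe minimal p otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(na + nb - 2), _P_FLOOR
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), float(df), max(float(p), _P_FLOOR)


# ---------------------------------------------------------------------------
# cohort-level orchestration

def classify_community(rpkm_grid: pd.DataFrame,
                       stratified_months: Sequence[str],
                       upper: float = 0.95,
                       lower: float = 0.05) -> list[HabitatCall]:
    """P_epi classification for every MAG in a (month, layer) RPKM grid."""
    calls = []
    for mag_id, row in rpkm_grid.iterrows():
        epi = row.xs("epilimnion", level="layer")
        hypo = row.xs("hypolimnion", level="layer")
        p = p_epi(epi, hypo, stratified_months)
        calls.append(HabitatCall(mag_id=mag_id, p_epi=p,
                                 label=classify_habitat(p, upper, lower)))
    return calls


def persistence_cohort(calls: Sequence[HabitatCall],
                       covfrac_grid: pd.DataFrame,
                       stratified_months: Sequence[str],
                       threshold: float = 0.20,
                       include_generalists: bool = False):
    """Persistence per specialist, computed in its own layer only.

    Epilimnion specialists are scored on epilimnion samples and
    hypolimnion specialists on hypolimnion samples. Generalists are
    excluded by default; when included, the layer with the larger
    cumulative signal is used. Returns a dict with per-group persistence
    lists, medians and the Welch comparison of group means.
    """
    groups: dict[str, list[int]] = {EPI: [], HYPO: []}
    if include_generalists:
        groups[GENERALIST] = []
    for call in calls:
        if call.label == UNCLASSIFIED:
            continue
        if call.label == GENERALIST and not include_generalists:
            continue
        row = covfrac_grid.loc[call.mag_id]
        epi = row.xs("epilimnion", level="layer")
        hypo = row.xs("hypolimnion", level="layer")
        if call.label == EPI:
            series = epi
        elif call.label == HYPO:
            series = hypo
        else:
            series = epi if epi.sum() >= hypo.sum() else hypo
        months = call.persistence_months = persistence(
            series, stratified_months, threshold)
        groups[call.label].append(months)

    medians = {label: (float(np.median(v)) if v else None)
               for label, v in groups.items()}
    if len(groups[EPI]) >= 2 and len(groups[HYPO]) >= 2:
        t, df, p = welch_t(groups[EPI], groups[HYPO])
    else:
        logger.warning("a specialist group is too small; Welch test skipped")
        t = df = p = None
    return {"groups": groups, "medians": medians,
            "welch_t": t, "welch_df": df, "welch_p": p}


def gene_sharing_partition(gene_sets_by_class: Mapping[str, set],
                           ) -> tuple[int, dict[str, int]]:
    """Shared vs class-exclusive annotation terms.

    A term is exclusive to a class when absent from every other class;
    "shared" counts terms present in both the specialist classes' union
    (epilimnion + hypolimnion) and the generalist set — terms in use
    across MAGs with and without a habitat preference.
    """
    classes = dict(gene_sets_by_class)
    required = {EPI, HYPO, GENERALIST}
    if not required <= set(classes):
        raise KeyError(f"gene sets must cover {sorted(required)}")
    exclusive = {}
    for label, terms in classes.items():
        others = set().union(*(t for l, t in classes.items() if l != label))
        exclusive[label] = len(set(terms) - others)
    shared = len((set(classes[EPI]) | set(classes[HYPO]))
                 & set(classes[GENERALIST]))
    return shared, exclusive


def round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, total: int) -> float:
    """Exact-rational percentage, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("zero total")
    q = Decimal(100 * count) / Decimal(total)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summary_report(calls: Sequence[HabitatCall],
                   quality: pd.DataFrame,
                   taxonomy: Mapping[str, str] | None = None,
                   exclude_unclassified_from_denominator: bool = False,
                   ) -> dict:
    """Headline catalogue statistics with one-decimal half-up percentages.

    ``quality`` is indexed by mag_id with columns tier, marker_count,
    n_contigs. Percentages of habitat labels use all MAGs by default;
    the all-seven-marker percentage is relative to high-quality MAGs and
    the single-contig high-quality percentage relative to all MAGs.
    """
    n_total = len(calls)
    if n_total == 0:
        raise ValueError("zero total")
    label_counts = {label: 0 for label in LABELS}
    for call in calls:
        label_counts[call.label] += 1
    denom = n_total
    if exclude_unclassified_from_denominator:
        denom = n_total - label_counts[UNCLASSIFIED]
        if denom <= 0:
            raise ValueError("zero total")
    n_specific = label_counts[EPI] + label_counts[HYPO]

    hq = quality[quality["tier"] == "high"]
    n_hq = len(hq)
    n_hq_all7 = int((hq["marker_count"] == 7).sum())
    n_hq_single = int((hq["n_contigs"] == 1).sum())

    report = {
        "n_total": n_total,
        "n_epilimnion_specific": label_counts[EPI],
        "n_hypolimnion_specific": label_counts[HYPO],
        "n_generalist": label_counts[GENERALIST],
        "n_unclassified": label_counts[UNCLASSIFIED],
        "n_niche_specific": n_specific,
        "n_high_quality": n_hq,
        "n_hq_all_seven_markers": n_hq_all7,
        "n_hq_single_contig": n_hq_single,
        "pct_niche_specific": _pct(n_specific, denom),
        "pct_epilimnion_specific": _pct(label_counts[EPI], denom),
        "pct_hypolimnion_specific": _pct(label_counts[HYPO], denom),
        "pct_high_quality": _pct(n_hq, n_total),
        "pct_hq_all_seven_markers": (_pct(n_hq_all7, n_hq) if n_hq else None),
        "pct_hq_single_contig": _pct(n_hq_single, n_total),
    }
    if taxonomy is not None:
        orders = pd.Series({c.mag_id: taxonomy.get(c.mag_id, "unassigned")
                            for c in calls})
        report["per_order_pct"] = {
            order: _pct(int(n), n_total)
            for order, n in orders.value_counts().items()}
    return report
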