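"""Normalized TIR abundance tables and the age-matched, bootstrap-subsampled
group comparison.

Per-ORF read counts are normalized to reads per kilobase of ORF per
million ORF-mapped reads (RPKM) and summed within predicted product
classes. Healthy and malnourished cohorts are compared with a two-sided
Mann-Whitney U test on age-matched subsamples, and the stability of the
verdict is summarised over bootstrap re-draws of the matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrfCountTable",
    "SampleMeta",
    "normalize_counts",
    "aggregate_by_class",
    "tir_richness",
    "age_matched_subsample",
    "compare_groups",
    "mannwhitney_p",
    "abundance_metabolite_correlation",
    "AGE_WINDOW_MONTHS",
    "N_BOOT",
]

#: Full age-match window in months (eligibility is within half-window).
AGE_WINDOW_MONTHS = 3.0
#: Bootstrap replicates of the subsampling procedure.
N_BOOT = 10_000

ALL_TIR_COLUMN = "all-TIR"


@dataclass
class OrfCountTable:
    """Sample-by-ORF read counts with ORF lengths and per-sample depth."""

    samples: list[str]
    orf_ids: list[str]
    orf_lengths_nt: np.ndarray  # nucleotides, aligned with orf_ids
    counts: np.ndarray  # samples x ORFs, non-negative integers
    total_mapped: np.ndarray  # per-sample reads mapped to all ORFs

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.orf_lengths_nt = np.asarray(self.orf_lengths_nt, dtype=float)
        self.total_mapped = np.asarray(self.total_mapped, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.orf_ids)):
            raise ValueError("counts must be samples x ORFs")
        if np.any(self.orf_lengths_nt <= 0):
            raise ValueError("ORF lengths must be positive")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if np.any(self.total_mapped < row_sums):
            bad = self.samples[int(np.argmax(self.total_mapped < row_sums))]
            raise ValueError(
                f"sample {bad!r}: total mapped reads below its TIR-ORF counts"
            )


@dataclass
class SampleMeta:
    sample_id: str
    donor_id: str
    age_months: float
    group: str  # "healthy" | "malnourished"

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError("age must be non-negative")
        if self.group not in ("healthy", "malnourished"):
            raise ValueError(f"unknown group {self.group!r}")


def normalize_counts(table: OrfCountTable) -> pd.DataFrame:
    """RPKM normalization: count / (length/1000) / (total mapped / 1e6)."""
    if np.any((table.total_mapped == 0) & (table.counts.sum(axis=1) > 0)):
        raise ValueError("sample with zero mapped total but nonzero counts")
    depth = np.where(table.total_mapped == 0, 1.0, table.total_mapped) / 1e6
    kb = table.orf_lengths_nt / 1000.0
    norm = table.counts / kb[None, :] / depth[:, None]
    return pd.DataFrame(norm, index=table.samples, columns=table.orf_ids)


def aggregate_by_class(
    norm: pd.DataFrame, classes: dict[str, str]
) -> pd.DataFrame:
    """Sum normalized abundances within product classes per sample.

    ORFs absent from ``classes`` count as ``unclassified``. The
    ``all-TIR`` column sums every TIR-containing ORF, so it equals the row
    sum over all class columns plus ``unclassified`` exactly.
    """
    labels = [classes.get(orf, "unclassified") for orf in norm.columns]
    out = norm.T.groupby(pd.Series(labels, index=norm.columns)).sum().T
    for required in ("unclassified",):
        if required not in out.columns:
            out[required] = 0.0
    out[ALL_TIR_COLUMN] = norm.sum(axis=1)
    return out


def tir_richness(hits_per_sample: dict[str, list[str]]) -> dict[str, int]:
    """Distinct TIR domain IDs per sample."""
    return {s: len(set(ids)) for s, ids in hits_per_sample.items()}


@dataclass
class MatchReport:
    matched_healthy: list[str]
    pairs: list[tuple[str, str]]  # (malnourished, healthy)
    unmatched: list[str] = field(default_factory=list)


def age_matched_subsample(
    meta: list[SampleMeta],
    window: float = AGE_WINDOW_MONTHS,
    rng: np.random.Generator | int | None = None,
) -> MatchReport:
    """Draw one age-matched healthy partner per malnourished sample.

    A healthy sample is eligible for a malnourished sample when their ages
    differ by at most half the window; draws are uniform among eligibles
    and without replacement. A random greedy pass is followed by
    augmenting-path repair, so a maximum-cardinality matching is always
    reached (in particular, a perfect matching is found whenever one
    exists). Malnourished samples that remain unmatchable are reported.
    """
    rng = np.random.default_rng(rng)
    healthy = [m for m in meta if m.group == "healthy"]
    malnourished = [m for m in meta if m.group == "malnourished"]
    if not healthy:
        raise ValueError("healthy group is empty, nothing to subsample")
    eligible = {
        m.sample_id: [
            h.sample_id
            for h in healthy
            if abs(h.age_months - m.age_months) <= window / 2.0
        ]
        for m in malnourished
    }
    match_of_healthy: dict[str, str] = {}
    # random greedy draw: one uniform pick per malnourished sample
    for m in malnourished:
        free = [h for h in eligible[m.sample_id] if h not in match_of_healthy]
        if free:
            match_of_healthy[free[rng.integers(len(free))]] = m.sample_id

    def augment(mid: str, banned: set[str]) -> bool:
        for h in eligible[mid]:
            if h in banned:
                continue
            banned.add(h)
            if h not in match_of_healthy or augment(match_of_healthy[h], banned):
                match_of_healthy[h] = mid
                return True
        return False

    matched_m = set(match_of_healthy.values())
    report = MatchReport(matched_healthy=[], pairs=[])
    for m in malnourished:
        if m.sample_id not in matched_m:
            if augment(m.sample_id, set()):
                matched_m = set(match_of_healthy.values())
            else:
                report.unmatched.append(m.sample_id)
    pair_of = {mid: h for h, mid in match_of_healthy.items()}
    for m in malnourished:
        if m.sample_id in pair_of:
            report.pairs.append((m.sample_id, pair_of[m.sample_id]))
            report.matched_healthy.append(pair_of[m.sample_id])
    return report


def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups are small and tie-free; otherwise a
    normal approximation with tie and continuity correction.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and tie_free) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass
class GroupComparison:
    class_label: str
    point_p: float
    direction: str  # "healthy_higher" | "malnourished_higher" | "none"
    boot_consistency: float
    n_boot: int
    n_healthy: int
    n_malnourished: int
    median_healthy: float
    median_malnourished: float


def compare_groups(
    class_abundance: pd.DataFrame,
    meta: list[SampleMeta],
    class_label: str,
    n_boot: int = N_BOOT,
    rng: np.random.Generator | int | None = None,
    window: float = AGE_WINDOW_MONTHS,
) -> GroupComparison:
    """Age-matched Mann-Whitney comparison of one class between groups.

    ``point_p`` is computed on a single matched draw; ``boot_consistency``
    is the fraction of ``n_boot`` independent re-draws of the matching that
    reproduce the same direction with p < 0.05.
    """
    rng = np.random.default_rng(rng)
    if class_label not in class_abundance.columns:
        raise KeyError(f"class column {class_label!r} missing")
    by_id = {m.sample_id: m for m in meta}
    values = class_abundance[class_label]

    def draw(generator: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        report = age_matched_subsample(meta, window=window, rng=generator)
        mal = [p[0] for p in report.pairs]
        hea = report.matched_healthy
        return values.loc[hea].to_numpy(float), values.loc[mal].to_numpy(float)

    x, y = draw(rng)  # healthy, malnourished
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 matched samples per group")
    point_p = mannwhitney_p(x, y)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if med_x > med_y:
        direction = "healthy_higher"
    elif med_y > med_x:
        direction = "malnourished_higher"
    else:
        direction = "none"
    consistent = 0
    for _ in range(n_boot):
        bx, by = draw(rng)
        if len(bx) < 2 or len(by) < 2:
            continue
        p = mannwhitney_p(bx, by)
        mx, my = np.median(bx), np.median(by)
        d = (
            "healthy_higher"
            if mx > my
            else ("malnourished_higher" if my > mx else "none")
        )
        if p < 0.05 and d == direction:
            consistent += 1
    return GroupComparison(
        class_label=class_label,
        point_p=point_p,
        direction=direction,
        boot_consistency=consistent / n_boot if n_boot else float("nan"),
        n_boot=n_boot,
        n_healthy=len(x),
        n_malnourished=len(y),
        median_healthy=med_x,
        median_malnourished=med_y,
    )


def abundance_metabolite_correlation(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between class abundance and metabolite level."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired observations, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
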