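"""Jukes-Cantor amino-acid distances and nearest-validated-neighbor
classification of TIR domains by NAD-hydrolase product.

The 20-state Jukes-Cantor distance is

    d = -(19/20) * ln(1 - (20/19) * p)

with p the mismatch fraction over columns where both rows carry a residue
(pairwise deletion of gapped columns). A query inherits the product label
of its nearest biochemically validated reference iff (1) the minimum
distance is at most 1.75, (2) at least 98 of the 116 match columns carry a
residue, and (3) the query has a glutamate at the catalytic column
(position 73 of the clan-level alignment). References labelled inactive
take part in the distance computation but never confer a label.
"""

from __future__ import annotations

import math

import numpy as np

from .records import (
    ACTIVE_LABELS,
    GAP,
    ClassificationResult,
    ReferencePanel,
    TrimmedRow,
)

__all__ = [
    "jc_distance",
    "classify",
    "classify_many",
    "distance_matrix",
    "MAX_JC",
    "MIN_RESIDUES",
    "CATALYTIC_COLUMN",
]

MAX_JC = 1.75
MIN_RESIDUES = 98
CATALYTIC_COLUMN = 73

_JC_SCALE = 19.0 / 20.0
_P_CEILING = 19.0 / 20.0


def _mismatch_fraction(a: str, b: str) -> tuple[float, int]:
    compared = 0
    mismatches = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        # X is ambiguity: counts as mismatching every residue, including X
        if x != y or x == "X":
            mismatches += 1
    if compared == 0:
        return math.nan, 0
    return mismatches / compared, compared


def jc_from_p(p: float) -> float:
    """Closed-form 20-state Jukes-Cantor transform of a mismatch fraction."""
    if math.isnan(p) or p >= _P_CEILING:
        return math.inf
    return -_JC_SCALE * math.log(1.0 - p / _JC_SCALE)


def jc_distance(a: TrimmedRow, b: TrimmedRow) -> float:
    """Pairwise-deletion Jukes-Cantor distance between two trimmed rows.

    Returns ``inf`` when the rows share no residue columns or the mismatch
    fraction reaches the 19/20 saturation point.
    """
    if a.M != b.M:
        raise ValueError(f"rows of unequal length: {a.M} vs {b.M}")
    p, _ = _mismatch_fraction(a.columns, b.columns)
    return jc_from_p(p)


def classify(
    query: TrimmedRow,
    panel: ReferencePanel,
    max_jc: float = MAX_JC,
    min_residues: int = MIN_RESIDUES,
    catalytic_column: int = CATALYTIC_COLUMN,
) -> ClassificationResult:
    """Assign a product label from the nearest validated reference.

    Failure reasons are reported in a fixed order: too few residues, no
    catalytic glutamate, no finite distance, distance exceeded. A query
    whose nearest reference is labelled inactive passes every gate yet
    remains unclassified: activity is only ever predicted from a validated
    active reference (reason ``nearest_reference_inactive``).
    """
    if not panel.rows:
        raise ValueError("reference panel is empty")
    best_id: str | None = None
    best_d = math.inf
    best_compared = 0
    for ref in sorted(panel.rows, key=lambda r: r.seq_id):
        p, compared = _mismatch_fraction(query.columns, ref.columns)
        d = jc_from_p(p)
        if d < best_d:
            best_d, best_id, best_compared = d, ref.seq_id, compared
    aligned = query.residue_count
    catalytic_ok = (
        len(query.columns) >= catalytic_column
        and query.columns[catalytic_column - 1] == "E"
    )
    reason = "ok"
    if aligned < min_residues:
        reason = "too_few_residues"
    elif not catalytic_ok:
        reason = "no_catalytic_glu"
    elif not math.isfinite(best_d):
        reason = "no_finite_distance"
    elif best_d > max_jc:
        reason = "distance_exceeded"
    label = "unclassified"
    if reason == "ok":
        ref_label = panel.labels[best_id]
        if ref_label in ACTIVE_LABELS:
            label = ref_label
        else:
            reason = "nearest_reference_inactive"
    return ClassificationResult(
        query_id=query.seq_id,
        nearest_ref_id=best_id,
        min_jc=best_d,
        compared_positions=best_compared,
        aligned_residues=aligned,
        catalytic_ok=catalytic_ok,
        label=label,
        reason=reason,
    )


def classify_many(
    queries: list[TrimmedRow], panel: ReferencePanel, **kwargs
) -> list[ClassificationResult]:
    return [classify(q, panel, **kwargs) for q in queries]


def distance_matrix(rows: list[TrimmedRow]) -> np.ndarray:
    """Symmetric pairwise Jukes-Cantor distance matrix (zero diagonal)."""
    n = len(rows)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jc_distance(rows[i], rows[j])
    return out


def jc_critical_mismatch(max_jc: float = MAX_JC) -> float:
    """Mismatch fraction at which the distance reaches ``max_jc``.

    Inverts the Jukes-Cantor transform: p = (19/20) * (1 - exp(-20 d / 19)).
    At d = 1.75 this is approximately 0.7995, so classification can reach
    mutants up to ~75-80% divergence.
    """
    return _JC_SCALE * (1.0 - math.exp(-max_jc / _JC_SCALE))
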