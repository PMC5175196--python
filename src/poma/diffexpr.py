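"""Differential expression: probe collapsing, Student's t-test, fold change.

Genes are called differentially expressed (DE) when the two-sided
pooled-variance t-test p-value is below ``p_cut`` (default 0.05) and the
linear fold change (case mean over control mean) is above ``fc_cut`` or
below ``1/fc_cut`` (default 2, i.e. |log2 FC| > 1). No multiple-testing
correction is applied at this stage; the raw-p cutoff is deliberate.

Input intensities are assumed linear-scale, positive and already
normalized; no normalization step is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CASE, CONTROL, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "collapse_probes",
    "gene_t_test",
    "fold_change",
    "select_de_genes",
    "de_results_frame",
]


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    p_value: float
    fold_change: float
    is_de: bool


def collapse_probes(matrix: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by averaging probe intensities.

    Each gene's per-sample intensity is the arithmetic mean of its probes'
    intensities. Probes without a gene mapping are dropped (logged count).
    """
    mapped = [p for p in matrix.values.index if p in probe_map]
    n_dropped = len(matrix.values.index) - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped probe(s)", n_dropped)
    if not mapped:
        raise ValidationError("no probes map to any gene")
    sub = matrix.values.loc[mapped]
    gene_index = pd.Index([probe_map[p] for p in mapped], name="gene")
    collapsed = sub.groupby(gene_index, sort=True).mean()
    return ExpressionMatrix(collapsed, matrix.groups)


def _pooled_t_pvalues(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Student's (pooled-variance) t-test p-values.

    Degenerate convention for zero pooled variance: p = 1.0 when the group
    means are equal, p = 0.0 when they differ (an infinitely confident
    difference under zero noise).
    """
    res = stats.ttest_ind(case, control, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        eq = np.isclose(case.mean(axis=1), control.mean(axis=1))
        p[degenerate & eq] = 1.0
        p[degenerate & ~eq] = 0.0
    return p


def gene_t_test(case_values, control_values) -> float:
    """Two-sided pooled-variance Student's t-test p-value for one gene."""
    case = np.atleast_2d(np.asarray(case_values, dtype=float))
    control = np.atleast_2d(np.asarray(control_values, dtype=float))
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError("t-test needs at least 2 values per group")
    if not (np.isfinite(case).all() and np.isfinite(control).all()):
        raise ValidationError("non-finite values in t-test input")
    return float(_pooled_t_pvalues(case, control)[0])


def fold_change(case_values, control_values) -> float:
    """Linear fold change: mean(case) / mean(control); control mean must be > 0."""
    case_mean = float(np.mean(case_values))
    control_mean = float(np.mean(control_values))
    if control_mean <= 0:
        raise ValidationError(
            "fold change undefined: control mean <= 0 (input must be linear-scale intensities)"
        )
    return case_mean / control_mean


def select_de_genes(
    matrix: ExpressionMatrix, p_cut: float = 0.05, fc_cut: float = 2.0
) -> list[DEResult]:
    """Score every gene of a (collapsed) matrix and flag DE genes.

    A gene is DE iff p < p_cut and (FC > fc_cut or FC < 1/fc_cut), all
    strict. Results are returned in the matrix's gene order; the flags
    themselves do not depend on row order.
    """
    case = matrix.group_values(CASE).to_numpy(dtype=float)
    control = matrix.group_values(CONTROL).to_numpy(dtype=float)
    p = _pooled_t_pvalues(case, control)
    control_means = control.mean(axis=1)
    if (control_means <= 0).any():
        bad = [g for g, m in zip(matrix.gene_ids, control_means) if m <= 0]
        raise ValidationError(f"control mean <= 0 for gene(s): {bad[:5]}")
    fc = case.mean(axis=1) / control_means
    is_de = (p < p_cut) & ((fc > fc_cut) | (fc < 1.0 / fc_cut))
    return [
        DEResult(g, float(pv), float(f), bool(d))
        for g, pv, f, d in zip(matrix.gene_ids, p, fc, is_de)
    ]


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tabulate DE results (gene, p, FC, is_de) for export."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "is_de": [r.is_de for r in results],
        }
    )
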