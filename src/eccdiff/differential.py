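"""Differential per-gene circle production between two sample groups.

A gene is selected when the absolute difference of group means of the
equalized PpGC values reaches the log2 threshold AND a two-sample
equal-variance Student's t-test is significant. Genes whose pooled
variance is zero are handled degenerately: unequal means give p = 0
(always significant, mirroring "infinite" fold changes), equal means
give p = 1.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .model import EccdiffError, PipelineParams
from .quantify import PpGCMatrix, WholeGeneReport

logger = logging.getLogger(__name__)

DPPGC_COLUMNS = [
    "gene",
    "mean_case",
    "mean_control",
    "diff",
    "p_value",
    "direction",
    "specific_case",
    "specific_control",
]


def student_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test with degenerate rule.

    Returns (t, p). Zero pooled variance: t = +/-inf and p = 0 when the
    means differ, t = 0 and p = 1 when they are equal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise EccdiffError("t-test requires >=2 samples per group")
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    pooled = ((len(x) - 1) * sx2 + (len(y) - 1) * sy2) / (len(x) + len(y) - 2)
    dmean = x.mean() - y.mean()
    if pooled == 0.0:
        if dmean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, dmean), 0.0
    with warnings.catch_warnings():
        # scipy warns about precision on near-constant input; degenerate
        # exact-zero variance is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def specificity_flags(matrix: PpGCMatrix, case_group: str, control_group: str) -> pd.DataFrame:
    """Per-gene group-specificity on the raw counts.

    ``specific_case`` is true iff the gene has nonzero raw signal in
    every case sample and zero in every control sample; symmetric for
    ``specific_control``.
    """
    case = matrix.raw[matrix.samples_in(case_group)]
    control = matrix.raw[matrix.samples_in(control_group)]
    return pd.DataFrame(
        {
            "specific_case": (case.min(axis=1) > 0) & (control.max(axis=1) == 0),
            "specific_control": (control.min(axis=1) > 0) & (case.max(axis=1) == 0),
        },
        index=matrix.raw.index,
    )


def select_dppgc(
    matrix: PpGCMatrix,
    params: PipelineParams,
    case_group: str,
    control_group: str,
    bh: bool = False,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Select differentially produced per-gene circles (DPpGCs).

    Selection requires |mean_case - mean_control| >= theta_dppgc on the
    equalized values AND t-test p <= alpha_dppgc. With ``bh=True`` the
    alpha gate is applied to Benjamini-Hochberg adjusted p-values
    instead of raw ones (off by default). ``alternative`` may be
    "two-sided", "greater" (case > control) or "less".

    Rows are ordered by ascending p, then descending |diff|, then gene.
    """
    case_samples = matrix.samples_in(case_group)
    control_samples = matrix.samples_in(control_group)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise EccdiffError("group with <2 samples: cannot run the t-test")
    if matrix.raw.empty:
        return pd.DataFrame(columns=DPPGC_COLUMNS)

    flags = specificity_flags(matrix, case_group, control_group)
    rows = []
    for gene in matrix.genes:
        x = matrix.equalized.loc[gene, case_samples].to_numpy(dtype=float)
        y = matrix.equalized.loc[gene, control_samples].to_numpy(dtype=float)
        t, p = student_t_test(x, y)
        if alternative != "two-sided":
            if math.isinf(t):
                one = 0.0 if (t > 0) == (alternative == "greater") else 1.0
            elif t == 0.0 and p == 1.0:
                one = 1.0
            else:
                one = p / 2 if (t > 0) == (alternative == "greater") else 1 - p / 2
            p = one
        diff = float(x.mean() - y.mean())
        rows.append(
            {
                "gene": gene,
                "mean_case": float(x.mean()),
                "mean_control": float(y.mean()),
                "diff": diff,
                "p_value": p,
                "direction": "up_in_case" if diff >= 0 else "up_in_control",
                "specific_case": bool(flags.loc[gene, "specific_case"]),
                "specific_control": bool(flags.loc[gene, "specific_control"]),
            }
        )
    table = pd.DataFrame(rows, columns=DPPGC_COLUMNS)

    gate_p = table["p_value"]
    if bh:
        gate_p = pd.Series(_benjamini_hochberg(table["p_value"].to_numpy()), index=table.index)
    selected = table[
        (table["diff"].abs() >= params.theta_dppgc) & (gate_p <= params.alpha_dppgc)
    ].copy()
    selected["_absdiff"] = selected["diff"].abs()
    selected = (
        selected.sort_values(["p_value", "_absdiff", "gene"], ascending=[True, False, True])
        .drop(columns="_absdiff")
        .reset_index(drop=True)
    )
    logger.info(
        "selected %d/%d genes at theta=%g alpha=%g",
        len(selected), len(table), params.theta_dppgc, params.alpha_dppgc,
    )
    return selected


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def fragment_vs_whole_summary(
    records: pd.DataFrame,
    whole_report: WholeGeneReport,
    groups: dict[str, str],
    case_group: str,
    control_group: str,
) -> pd.DataFrame:
    """Label each selected gene fragment_only or whole_carried.

    A selected gene is ``whole_carried`` iff it appears in the
    whole-gene list of at least one sample of its up group (the case
    group for up_in_case records, the control group otherwise);
    ``fragment_only`` otherwise.
    """
    carried_by_group: dict[str, set[str]] = {case_group: set(), control_group: set()}
    for sample_id, genes in whole_report.per_sample.items():
        g = groups.get(sample_id)
        if g in carried_by_group:
            carried_by_group[g].update(genes)

    out = records.copy()
    if out.empty:
        out["fragment_only"] = pd.Series(dtype=bool)
        return out
    up_group = out["direction"].map(
        {"up_in_case": case_group, "up_in_control": control_group}
    )
    out["fragment_only"] = [
        gene not in carried_by_group[grp]
        for gene, grp in zip(out["gene"], up_group)
    ]
    return out
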