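"""Per-feature differential expression of each patient phenotype against
healthy controls.

Each contrast (ADU vs HC, ADT vs HC, ID vs HC) is a two-sample t-test per
feature, followed by a rank-based multiple-testing adjustment

    q_i = N * p_i / R_i

where ``N`` is the number of features tested in the contrast and ``R_i``
the ascending rank of the feature's p-value (tied p-values share the
maximum rank of the tie group, so they share one q).  By default the raw
quotients are step-up monotonized — each q becomes the minimum raw quotient
at its rank or any larger rank — which makes the quantity identical to the
Benjamini-Hochberg adjusted p-value; the literal un-monotonized quotient is
available for fidelity experiments.  Features with q at or below the
threshold (default 0.05) are called differentially expressed and annotated
with their fold-change direction (U = up in the patient phenotype, D =
down).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import CASE_PHENOTYPES, ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

#: Default DEG-calling threshold on q.
Q_THRESHOLD = 0.05


def two_group_ttest(matrix: ExpressionMatrix, design: SampleDesign,
                    case_phenotype: str, equal_var: bool = False
                    ) -> pd.DataFrame:
    """Two-sided t-test of ``case_phenotype`` vs HC for every feature.

    Welch's unequal-variance test by default; ``equal_var`` switches to the
    pooled-variance Student's t.  Features where both groups have zero
    variance are degenerate: they get t = 0, p = 1 with a logged warning.

    Returns a DataFrame indexed by feature with columns ``mean_case``,
    ``mean_control``, ``log2fc``, ``t``, ``p``.
    """
    if case_phenotype == "HC":
        raise ValueError("case phenotype must differ from the HC control")
    design.validate_against(matrix)
    case_samples = design.samples(case_phenotype)
    ctrl_samples = design.samples("HC")
    case_samples = [s for s in case_samples if s in matrix.values.columns]
    ctrl_samples = [s for s in ctrl_samples if s in matrix.values.columns]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError(
            f"need >=2 samples per group for {case_phenotype} vs HC; got "
            f"{len(case_samples)} and {len(ctrl_samples)}")

    case = matrix.values[case_samples].to_numpy()
    ctrl = matrix.values[ctrl_samples].to_numpy()
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)
    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if degenerate.any():
        logger.warning("%d degenerate features (zero variance in both "
                       "groups); setting t=0, p=1", int(degenerate.sum()))
        t[degenerate] = 0.0
        p[degenerate] = 1.0

    return pd.DataFrame(
        {"mean_case": mean_case, "mean_control": mean_ctrl,
         "log2fc": mean_case - mean_ctrl, "t": t, "p": p},
        index=pd.Index(matrix.feature_ids, name="feature_id"))


def compute_qvalues(p_values, monotonize: bool = True
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based q-values ``q_i = N * p_i / R_i``.

    Ranks are ascending; ties take the maximum rank within the tie group.
    With ``monotonize`` (default) each raw quotient is replaced by the
    minimum quotient over its rank and all larger ranks (step-up), after
    which the quantity equals the Benjamini-Hochberg adjusted p-value.
    Values are clipped to at most 1.

    Returns ``(q, ranks)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([]), np.array([], dtype=int)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    ranks = stats.rankdata(p, method="max").astype(int)
    raw = n * p / ranks
    if monotonize:
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate(raw[order][::-1])[::-1]
        q = np.empty(n)
        q[order] = q_sorted
    else:
        q = raw
    return np.minimum(q, 1.0), ranks


def differential_expression(matrix: ExpressionMatrix, design: SampleDesign,
                            case_phenotype: str,
                            q_threshold: float = Q_THRESHOLD,
                            equal_var: bool = False,
                            monotonize: bool = True) -> pd.DataFrame:
    """Full per-feature DE table for one contrast.

    Adds ``rank``, ``n_tested``, ``q``, ``direction`` (U/D by fold-change
    sign; an exactly-zero fold change counts as U and is logged) and
    ``significant`` (q <= threshold) to the t-test columns.
    """
    res = two_group_ttest(matrix, design, case_phenotype,
                          equal_var=equal_var)
    q, ranks = compute_qvalues(res["p"].to_numpy(), monotonize=monotonize)
    res["rank"] = ranks
    res["n_tested"] = len(res)
    res["q"] = q
    zero_fc = res["log2fc"] == 0
    if (zero_fc & (q <= q_threshold)).any():
        logger.warning("%d significant features with log2fc == 0; "
                       "direction set to U by convention",
                       int((zero_fc & (q <= q_threshold)).sum()))
    res["direction"] = np.where(res["log2fc"] < 0, "D", "U")
    res["significant"] = res["q"] <= q_threshold
    return res


def call_degs(de_result: pd.DataFrame, threshold: float = Q_THRESHOLD
              ) -> pd.DataFrame:
    """Features with q <= threshold, ordered by (q, feature ID).

    The returned frame keeps the DE columns; split on ``direction`` for
    up/down partitions.
    """
    called = de_result[de_result["q"] <= threshold].copy()
    order = called.assign(_fid=called.index.astype(str)) \
        .sort_values(["q", "_fid"], kind="stable").index
    return called.loc[order]


def deg_ids(de_result: pd.DataFrame, threshold: float = Q_THRESHOLD,
            direction: str | None = None) -> list[str]:
    """Feature IDs called at the threshold, optionally one direction."""
    called = call_degs(de_result, threshold)
    if direction is not None:
        called = called[called["direction"] == direction]
    return list(called.index)


def de_all_contrasts(matrix: ExpressionMatrix, design: SampleDesign,
                     q_threshold: float = Q_THRESHOLD,
                     equal_var: bool = False, monotonize: bool = True
                     ) -> dict[str, pd.DataFrame]:
    """DE tables for every patient phenotype vs HC, each corrected
    independently with its own N."""
    return {phe: differential_expression(matrix, design, phe,
                                         q_threshold=q_threshold,
                                         equal_var=equal_var,
                                         monotonize=monotonize)
            for phe in CASE_PHENOTYPES}
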