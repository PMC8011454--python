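"""Microarray differential-expression screening, qPCR and ELISA quantification.

The screen follows the classic present-call workflow for two-group chip
comparisons: a probe enters the analysis only if it is called Present on
every chip of at least one group; surviving probes are filtered on a
twofold linear fold-change cut-off, then tested with a Welch (unequal
variance) t-test under Benjamini–Hochberg control of the false discovery
rate at 5%. Relative qPCR quantification is efficiency-corrected
(ratio = E_target^ΔCt_target / E_ref^ΔCt_ref), and ELISA concentrations
are read off a log-log standard curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "present_call_filter",
    "fold_change_filter",
    "welch_t",
    "bh_adjust",
    "de_screen",
    "pfaffl_ratio",
    "pfaffl_from_table",
    "signed_fold",
    "fit_loglog_standards",
    "elisa_predict",
    "elisa_fit_and_predict",
    "groups_from_columns",
]


def groups_from_columns(columns: Sequence[str], groups: Mapping[str, str] | None = None):
    """Resolve a sample→group mapping; default infers the leading letter."""
    if groups is None:
        groups = {c: c.rstrip("0123456789") for c in columns}
    labels = sorted(set(groups[c] for c in columns))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    g1 = [c for c in columns if groups[c] == labels[0]]
    g2 = [c for c in columns if groups[c] == labels[1]]
    return labels, g1, g2


def present_call_filter(calls: pd.DataFrame, groups: Mapping[str, str] | None = None) -> pd.Index:
    """Retain probes called Present on every chip of at least one group.

    Marginal and Absent calls never count toward the consensus.
    """
    if calls.isna().any().any():
        raise ValueError("call table contains missing entries")
    _, g1, g2 = groups_from_columns(calls.columns, groups)
    is_p = calls == "P"
    keep = is_p[g1].all(axis=1) | is_p[g2].all(axis=1)
    return calls.index[keep]


def fold_change_filter(
    values: pd.DataFrame,
    probes: pd.Index | None = None,
    groups: Mapping[str, str] | None = None,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Linear fold change of group means with a symmetric cut-off.

    fc = mean(group2)/mean(group1); probes are retained iff fc >= threshold
    or fc <= 1/threshold (boundary inclusive). Returns a frame with columns
    ``fc`` and ``direction`` for the retained probes.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    sub = values if probes is None else values.loc[probes]
    _, g1, g2 = groups_from_columns(values.columns, groups)
    m1 = sub[g1].mean(axis=1)
    m2 = sub[g2].mean(axis=1)
    if (m1 <= 0).any() or (m2 <= 0).any():
        raise ValueError("group means must be positive on the linear scale")
    fc = m2 / m1
    keep = (fc >= threshold) | (fc <= 1.0 / threshold)
    out = pd.DataFrame({"fc": fc[keep]})
    out["direction"] = np.where(out["fc"] >= 1.0, "up", "down")
    return out


def welch_t(group1, group2):
    """Welch's unequal-variance t-test: (t, df, two-sided p).

    The statistic is signed as mean(group1) − mean(group2) over the pooled
    standard error, with Welch–Satterthwaite degrees of freedom.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values, alpha: float = 0.05):
    """Benjamini–Hochberg step-up adjusted q-values and rejections.

    q_(i) = min over j >= i of m·p_(j)/j, capped at 1; rejection iff
    q <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= alpha


def de_screen(
    values: pd.DataFrame,
    calls: pd.DataFrame,
    groups: Mapping[str, str] | None = None,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full two-group differential-expression screen.

    Filter order is fixed: present-call consensus → twofold cut-off → Welch
    t-test with BH correction. The multiple-testing universe is the
    fold-passing list, mirroring the screen's stated staging. Returns a
    per-probe frame with fc, direction, p, q and the filter flags.
    """
    if not values.index.equals(calls.index) or list(values.columns) != list(calls.columns):
        raise ValueError("values and calls must share index and columns")
    _, g1, g2 = groups_from_columns(values.columns, groups)

    out = pd.DataFrame(index=values.index)
    m1 = values[g1].mean(axis=1)
    m2 = values[g2].mean(axis=1)
    out["fc"] = m2 / m1
    out["direction"] = np.where(out["fc"] >= 1.0, "up", "down")
    present = present_call_filter(calls, groups)
    out["passed_present"] = out.index.isin(present)
    fold = fold_change_filter(values, present, groups, fold_threshold)
    out["passed_fold"] = out.index.isin(fold.index)
    out["p_welch"] = np.nan
    out["q_bh"] = np.nan
    out["significant"] = False

    tested = out.index[out["passed_fold"]]
    if len(tested):
        a = values.loc[tested, g1].to_numpy()
        b = values.loc[tested, g2].to_numpy()
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        q, reject = bh_adjust(p, alpha)
        out.loc[tested, "p_welch"] = p
        out.loc[tested, "q_bh"] = q
        out.loc[tested, "significant"] = reject
    return out


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^ΔCt_t / E_ref^ΔCt_ref.

    ΔCt is oriented calibrator-minus-test (mean Ct of the calibrator group
    minus mean Ct of the test group), so a ratio above 1 means higher
    expression in the test group. With both efficiencies exactly 2 this
    reduces to the familiar 2^ΔΔCt form.
    """
    for e in (e_target, e_ref):
        if not (1.0 < e <= 2.2):
            raise ValueError("amplification efficiencies must lie in (1, 2.2]")
    return float(e_target**dct_target / e_ref**dct_ref)


def pfaffl_from_table(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "Rpl19",
    calibrator_group: str = "control",
    test_group: str = "test",
) -> float:
    """Pfaffl ratio from a long-format Ct table.

    Expects columns ``gene, group, efficiency, ct``; ΔCt is computed from
    group-mean Ct values with calibrator-minus-test orientation for both
    genes.
    """
    def _gene(gene):
        sub = table[table["gene"] == gene]
        if sub.empty:
            raise ValueError(f"gene {gene!r} not present in table")
        e = float(sub["efficiency"].iloc[0])
        cal = sub.loc[sub["group"] == calibrator_group, "ct"].mean()
        tst = sub.loc[sub["group"] == test_group, "ct"].mean()
        if math.isnan(cal) or math.isnan(tst):
            raise ValueError(f"gene {gene!r} lacks Ct values in one group")
        return e, cal - tst

    e_t, dct_t = _gene(target_gene)
    e_r, dct_r = _gene(reference_gene)
    return pfaffl_ratio(e_t, dct_t, e_r, dct_r)


def signed_fold(ratio: float) -> dict:
    """Signed fold value used when reporting relative expression.

    Maps an expression ratio to ratio − 1 (so 2.12× prints as +1.12-fold and
    0.39× as −0.61-fold). This reporting convention is inferred from common
    usage and flagged as such; the raw ratio and log2 ratio accompany it.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return {
        "signed_fold": ratio - 1.0,
        "ratio": ratio,
        "log2_ratio": math.log2(ratio),
        "convention": "ratio-minus-one (inferred)",
    }


@dataclass(frozen=True)
class LogLogCurve:
    """Least-squares line of log10(OD) on log10(concentration)."""

    slope: float
    intercept: float
    conc_range: tuple[float, float]
    od_range: tuple[float, float]


def fit_loglog_standards(concentrations, optical_densities) -> LogLogCurve:
    """Fit the ELISA standard curve: log10(OD) = slope·log10(conc) + intercept."""
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(optical_densities, dtype=float)
    if conc.size != od.size or conc.size < 3:
        raise ValueError("need at least 3 (concentration, OD) standards")
    if np.any(conc <= 0) or np.any(od <= 0):
        raise ValueError("concentrations and ODs must be positive")
    fit = stats.linregress(np.log10(conc), np.log10(od))
    return LogLogCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        conc_range=(float(conc.min()), float(conc.max())),
        od_range=(float(od.min()), float(od.max())),
    )


def elisa_predict(curve: LogLogCurve, sample_od) -> np.ndarray:
    """Inverse-predict concentration: conc = 10^((log10(OD) − intercept)/slope)."""
    od = np.atleast_1d(np.asarray(sample_od, dtype=float))
    if np.any(od <= 0):
        raise ValueError("optical density must be positive")
    lo, hi = curve.od_range
    if np.any((od < lo) | (od > hi)):
        warnings.warn("sample OD outside the standard range; extrapolating",
                      stacklevel=2)
    conc = 10.0 ** ((np.log10(od) - curve.intercept) / curve.slope)
    return conc if np.asarray(sample_od).ndim else float(conc[0])


def elisa_fit_and_predict(concentrations, optical_densities, sample_od):
    """Convenience wrapper: fit the log-log standard curve, then predict."""
    curve = fit_loglog_standards(concentrations, optical_densities)
    return elisa_predict(curve, sample_od)
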