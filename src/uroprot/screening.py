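"""Screening evaluation: ROC curves, AUC inference, detection at fixed FPR,
and the two-timepoint longitudinal comparison table.

The AUC is the Mann-Whitney estimator (ties count 1/2), identical to the
probability that a randomly chosen case outscores a randomly chosen
control.  Its standard error defaults to the Hanley-McNeil exponential
approximation, with DeLong's structural-components estimator available;
the 95% CI is the normal interval clipped to [0, 1] and the p-value tests
AUC = 0.5.

Detection rate at a fixed false-positive rate uses the empirical
order-statistic threshold: with ``n`` controls and target FPR ``f`` the
threshold is the ``ceil((1 - f) * n)``-th smallest control score and a
subject is called positive when its score is strictly greater, so the
achieved FPR never exceeds the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .targeted import (
    LONGITUDINAL_STARS,
    group_ratio,
    significance_stars,
    welch_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RocSummary",
    "FixedFprResult",
    "roc_points",
    "auc",
    "auc_inference",
    "delong_se",
    "sensitivity_at_fpr",
    "roc_summary",
    "longitudinal_table",
    "both_timepoint_markers",
]


@dataclass(frozen=True)
class RocSummary:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_vs_half: float
    sens_at_fpr: float
    achieved_fpr: float
    fpr_target: float
    threshold: float
    ci_method: str = "hanley"


@dataclass(frozen=True)
class FixedFprResult:
    sensitivity: float
    threshold: float
    achieved_fpr: float


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    case_mask = lab == "case"
    ctrl_mask = lab == "control"
    if not (case_mask | ctrl_mask).all():
        raise ValueError("labels must be 'case' or 'control'")
    x, y = s[case_mask], s[ctrl_mask]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one case and one control")
    return x, y


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC step curve over all distinct thresholds.

    Classification rule: positive when score >= threshold (higher score =
    more case-like).  The curve starts at (0, 0) (threshold +inf) and
    ends at (1, 1) (threshold = min score).
    """
    cases, controls = _split(scores, labels)
    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([cases, controls]))[::-1]))
    rows = []
    for thr in thresholds:
        tpr = float(np.mean(cases >= thr))
        fpr = float(np.mean(controls >= thr))
        rows.append({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return pd.DataFrame(rows)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over case-control pairs of
    1[case > control] + 0.5 * 1[tie] (midrank formula)."""
    cases, controls = _split(scores, labels)
    n1, n0 = cases.size, controls.size
    ranks = rankdata(np.concatenate([cases, controls]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_inference(
    auc_value: float, n_case: int, n_control: int
) -> tuple[float, float, float, float]:
    """(SE, CI low, CI high, p vs 0.5) via the Hanley-McNeil exponential
    approximation and a normal test, CI clipped to [0, 1]."""
    if not (0.0 <= auc_value <= 1.0):
        raise ValueError("auc must lie in [0, 1]")
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 cases and >= 2 controls for inference")
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_case - 1) * (q1 - a**2)
        + (n_control - 1) * (q2 - a**2)
    ) / (n_case * n_control)
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = float(np.clip(a - 1.96 * se, 0.0, 1.0))
    ci_high = float(np.clip(a + 1.96 * se, 0.0, 1.0))
    if se == 0.0:
        p = 1.0 if a == 0.5 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    return se, ci_low, ci_high, p


def delong_se(scores, labels) -> float:
    """DeLong structural-components standard error of the AUC."""
    cases, controls = _split(scores, labels)
    n1, n0 = cases.size, controls.size
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 cases and >= 2 controls for inference")
    # placement values
    v10 = np.array(
        [np.mean((c > controls) + 0.5 * (c == controls)) for c in cases]
    )
    v01 = np.array(
        [np.mean((cases > c) + 0.5 * (cases == c)) for c in controls]
    )
    var = v10.var(ddof=1) / n1 + v01.var(ddof=1) / n0
    return float(np.sqrt(max(var, 0.0)))


def sensitivity_at_fpr(scores, labels, fpr_target: float = 0.10) -> FixedFprResult:
    """Detection rate at a fixed false-positive rate.

    The threshold is the ceil((1 - fpr_target) * n_control)-th order
    statistic of the control scores; subjects score positive when
    strictly above it.  The achieved FPR (fraction of controls positive)
    is reported alongside and never exceeds the target.
    """
    if not (0.0 <= fpr_target <= 1.0):
        raise ValueError("fpr_target must lie in [0, 1]")
    cases, controls = _split(scores, labels)
    n0 = controls.size
    k = int(np.ceil((1.0 - fpr_target) * n0))
    if k <= 0:
        threshold = -np.inf
    else:
        threshold = float(np.sort(controls)[k - 1])
    sens = float(np.mean(cases > threshold))
    achieved = float(np.mean(controls > threshold))
    return FixedFprResult(sensitivity=sens, threshold=threshold, achieved_fpr=achieved)


def roc_summary(
    scores,
    labels,
    fpr_target: float = 0.10,
    ci_method: str = "hanley",
) -> RocSummary:
    """AUC with SE/CI/p plus detection rate at the target FPR."""
    cases, controls = _split(scores, labels)
    a = auc(scores, labels)
    if ci_method == "hanley":
        se, lo, hi, p = auc_inference(a, cases.size, controls.size)
    elif ci_method == "delong":
        se = delong_se(scores, labels)
        lo = float(np.clip(a - 1.96 * se, 0.0, 1.0))
        hi = float(np.clip(a + 1.96 * se, 0.0, 1.0))
        if se == 0.0:
            p = 1.0 if a == 0.5 else 0.0
        else:
            p = float(2.0 * stats.norm.sf(abs(a - 0.5) / se))
    else:
        raise ValueError("ci_method must be 'hanley' or 'delong'")
    fixed = sensitivity_at_fpr(scores, labels, fpr_target)
    return RocSummary(
        auc=a,
        se=se,
        ci_low=lo,
        ci_high=hi,
        p_vs_half=p,
        sens_at_fpr=fixed.sensitivity,
        achieved_fpr=fixed.achieved_fpr,
        fpr_target=fpr_target,
        threshold=fixed.threshold,
        ci_method=ci_method,
    )


def longitudinal_table(
    tables: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    alpha: float = 0.05,
    log_scale: bool = False,
    stars=LONGITUDINAL_STARS,
) -> pd.DataFrame:
    """Per-protein, per-timepoint PE/CTL ratios and Welch p-values.

    ``tables`` maps timepoint label to a samples x proteins intensity
    table; group labels come from the sample metadata.  Output columns
    per timepoint tp: ratio_{tp}, p_{tp}, significant_{tp} (p < alpha),
    stars_{tp}.  Subjects present at only one timepoint contribute to
    that timepoint alone (logged).
    """
    meta = samples.set_index("sample_id")
    timepoints = sorted(tables)
    subj_sets = {
        tp: set(meta.loc[meta.index.intersection(tables[tp].index), "subject_id"])
        for tp in timepoints
    }
    common = set.intersection(*subj_sets.values()) if subj_sets else set()
    for tp, subj in subj_sets.items():
        extra = subj - common
        if extra:
            logger.info(
                "longitudinal_table: %d subjects only partially observed (%s)",
                len(extra),
                tp,
            )
    proteins = list(tables[timepoints[0]].columns)
    out = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    for tp in timepoints:
        tab = tables[tp]
        ratios, ps = [], []
        for prot in proteins:
            vals = tab[prot].dropna()
            groups = meta.loc[vals.index, "group"]
            x = vals[groups == "case"].to_numpy()
            y = vals[groups == "control"].to_numpy()
            ratios.append(group_ratio(x, y))
            if log_scale:
                ps.append(welch_test(np.log2(x), np.log2(y))[2])
            else:
                ps.append(welch_test(x, y)[2])
        out[f"ratio_{tp}"] = ratios
        out[f"p_{tp}"] = ps
        out[f"significant_{tp}"] = np.asarray(ps) < alpha
        out[f"stars_{tp}"] = [significance_stars(p, stars) for p in ps]
    return out


def both_timepoint_markers(
    table: pd.DataFrame, require_upregulated: bool = True
) -> list[str]:
    """Proteins significant at every timepoint of a longitudinal table;
    with ``require_upregulated`` (default) the PE/CTL ratio must also
    exceed 1 at every timepoint, matching the upregulation endpoint the
    screening markers are selected for."""
    tps = [c.removeprefix("significant_") for c in table.columns if c.startswith("significant_")]
    mask = np.ones(len(table), dtype=bool)
    for tp in tps:
        mask &= table[f"significant_{tp}"].to_numpy(dtype=bool)
        if require_upregulated:
            mask &= table[f"ratio_{tp}"].to_numpy() > 1.0
    return table.index[mask].tolist()
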