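"""Discovery-stage differential abundance analysis.

The discovery stage compares label-free protein intensities between case
and control urine.  Because proteinuria inflates *every* protein in case
samples, raw fold changes carry a global shift; the pipeline therefore
centers log2 fold changes across proteins into a z-score
``z = (FC - mean(FC)) / sd(FC)`` and calls a protein regulated only when
both the centered score and an empirical-Bayes moderated test agree:
``|z| > 1.96`` and Benjamini-Hochberg ``q < 0.05`` (strict inequalities).

The moderated test shrinks per-protein residual variances toward a prior
fitted by method of moments on log residual variances (scaled inverse
chi-square prior with d0 degrees of freedom and scale s0^2); the
posterior variance is ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the statistic
is referred to a t distribution on ``d0 + d`` degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.special import digamma, polygamma
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionCriteria",
    "ModeratedTestParams",
    "filter_quantified",
    "compute_log2fc",
    "center_fold_changes",
    "estimate_variance_prior",
    "moderated_t_test",
    "adjust_bh",
    "select_regulated",
    "differential_abundance",
    "shortlist_candidates",
    "pca_scores",
    "cluster_samples",
    "SampleDendrogram",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Dual selection rule: |z| > z_abs_threshold and q < q_threshold."""

    z_abs_threshold: float = 1.96
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.z_abs_threshold <= 0 or self.q_threshold <= 0:
            raise ValueError("selection thresholds must be > 0")


@dataclass(frozen=True)
class ModeratedTestParams:
    """Variance prior: d0 prior degrees of freedom (may be inf), s0_sq scale."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or np.isnan(self.d0):
            raise ValueError("d0 must be >= 0 (np.inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def _group_columns(samples: pd.DataFrame) -> tuple[list[str], list[str]]:
    case = samples.loc[samples["group"] == "case", "sample_id"].tolist()
    ctrl = samples.loc[samples["group"] == "control", "sample_id"].tolist()
    if not case or not ctrl:
        raise ValueError("both case and control groups must be nonempty")
    return case, ctrl


def filter_quantified(
    matrix: pd.DataFrame, samples: pd.DataFrame, min_fraction: float = 0.5
) -> pd.DataFrame:
    """Keep proteins quantified in >= ``min_fraction`` of at least one
    group's samples and with >= 2 observed values in *each* group."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    case, ctrl = _group_columns(samples)
    obs_case = matrix[case].notna().sum(axis=1)
    obs_ctrl = matrix[ctrl].notna().sum(axis=1)
    frac_ok = (obs_case >= min_fraction * len(case)) | (
        obs_ctrl >= min_fraction * len(ctrl)
    )
    keep = frac_ok & (obs_case >= 2) & (obs_ctrl >= 2)
    out = matrix.loc[keep]
    if out.empty:
        warnings.warn("filter_quantified removed every protein", stacklevel=2)
    return out


def compute_log2fc(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-protein log2 fold change: mean(log2 case) - mean(log2 control),
    over observed values only.  Proteins with an empty group are excluded
    (logged)."""
    case, ctrl = _group_columns(samples)
    with np.errstate(divide="ignore"):
        logm = np.log2(matrix)
    mean_case = logm[case].mean(axis=1)
    mean_ctrl = logm[ctrl].mean(axis=1)
    n_case = logm[case].notna().sum(axis=1)
    n_ctrl = logm[ctrl].notna().sum(axis=1)
    ok = (n_case > 0) & (n_ctrl > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("compute_log2fc: excluded %d proteins with an empty group", dropped)
    out = pd.DataFrame(
        {
            "log2fc": mean_case - mean_ctrl,
            "n_case_obs": n_case,
            "n_control_obs": n_ctrl,
        }
    ).loc[ok]
    out.index.name = "protein_id"
    return out


def center_fold_changes(fcs) -> np.ndarray:
    """Center fold changes across proteins: z = (fc - mean) / sd (ddof=1).

    This removes any global shift common to all proteins — in particular
    the proteinuria-driven inflation of case intensities — so z measures
    regulation relative to the proteome-wide trend.
    """
    fc = np.asarray(fcs, dtype=float)
    if fc.size < 2:
        raise ValueError("need >= 2 fold changes to center")
    sd = fc.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: all fold changes identical (sd = 0)")
    return (fc - fc.mean()) / sd


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped at 1, in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 80) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2, df) -> ModeratedTestParams:
    """Fit (d0, s0^2) by method of moments on log residual variances.

    Under the scaled-inverse-chi-square prior, e = log(s^2) - digamma(d/2)
    + log(d/2) has mean log(s0^2) + digamma(d0/2) - log(d0/2) and variance
    trigamma(d0/2) + trigamma(d/2); matching the empirical mean and
    variance of e yields the prior.  When the empirical variance does not
    exceed the sampling contribution, d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (df > 0) & (s2 > 0) & np.isfinite(s2)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances to fit the prior")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1)
    excess = e_var - np.mean(polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        half_d0 = _trigamma_inverse(float(excess))
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(e_mean + digamma(half_d0) - np.log(half_d0)))
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq)


def moderated_t_test(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    params: ModeratedTestParams | str = "estimate",
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group t-test on log2 intensities.

    Per protein (observed values only): residual pooled variance s^2 on
    d = n_case + n_control - 2 df; posterior variance
    (d0*s0^2 + d*s^2)/(d0 + d); t = log2fc / (s_post * sqrt(1/n1 + 1/n2));
    two-sided p from t(d0 + d) (normal when d0 is infinite).

    Returns a DataFrame with log2fc, t_mod, df_total, p_raw, s2, s2_post,
    n_case_obs, n_control_obs; proteins with d < 1 are excluded (logged).
    """
    case, ctrl = _group_columns(samples)
    with np.errstate(divide="ignore"):
        logm = np.log2(matrix)
    n1 = logm[case].notna().sum(axis=1).to_numpy(dtype=float)
    n2 = logm[ctrl].notna().sum(axis=1).to_numpy(dtype=float)
    m1 = logm[case].mean(axis=1).to_numpy()
    m2 = logm[ctrl].mean(axis=1).to_numpy()
    v1 = logm[case].var(axis=1, ddof=1).to_numpy()
    v2 = logm[ctrl].var(axis=1, ddof=1).to_numpy()
    d = n1 + n2 - 2.0
    ok = (n1 >= 1) & (n2 >= 1) & (d >= 1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("moderated_t_test: excluded %d proteins with < 1 residual df", dropped)
    idx = matrix.index[ok]
    n1, n2, m1, m2, d = n1[ok], n2[ok], m1[ok], m2[ok], d[ok]
    ss1 = np.where(n1 > 1, (n1 - 1) * np.nan_to_num(v1[ok]), 0.0)
    ss2 = np.where(n2 > 1, (n2 - 1) * np.nan_to_num(v2[ok]), 0.0)
    s2 = (ss1 + ss2) / d

    if isinstance(params, str):
        if params != "estimate":
            raise ValueError("params must be ModeratedTestParams or 'estimate'")
        params = estimate_variance_prior(s2, d)
    d0, s0_sq = params.d0, params.s0_sq

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    fc = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, fc / se, np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p,
            "s2": s2,
            "s2_post": s2_post,
            "n_case_obs": n1.astype(int),
            "n_control_obs": n2.astype(int),
        },
        index=idx,
    )


def select_regulated(
    records: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> tuple[list[str], list[str]]:
    """Apply the dual rule |z| > threshold (strict) and q < threshold
    (strict); direction by the sign of z.  Returns (up, down) protein ids."""
    z = records["z"]
    q = records["q"]
    sel = (z.abs() > criteria.z_abs_threshold) & (q < criteria.q_threshold)
    up = records.index[sel & (z > 0)].tolist()
    down = records.index[sel & (z < 0)].tolist()
    return up, down


def differential_abundance(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    min_fraction: float = 0.5,
    params: ModeratedTestParams | str = "estimate",
    criteria: SelectionCriteria = SelectionCriteria(),
) -> pd.DataFrame:
    """Full discovery chain: filter -> log2FC -> z-centering -> moderated
    test -> BH -> dual-criterion direction call.

    Returns one record per retained protein with columns log2fc, z,
    p_raw, q, direction (up/down/none), n_case_obs, n_control_obs.
    """
    filtered = filter_quantified(matrix, samples, min_fraction=min_fraction)
    test = moderated_t_test(filtered, samples, params=params)
    records = test[["log2fc", "p_raw", "n_case_obs", "n_control_obs"]].copy()
    records["z"] = center_fold_changes(records["log2fc"].to_numpy())
    records["q"] = adjust_bh(records["p_raw"].to_numpy())
    up, down = select_regulated(records, criteria)
    direction = pd.Series("none", index=records.index)
    direction.loc[up] = "up"
    direction.loc[down] = "down"
    records["direction"] = direction
    records.index.name = "protein_id"
    return records[
        ["log2fc", "z", "p_raw", "q", "direction", "n_case_obs", "n_control_obs"]
    ]


def shortlist_candidates(
    up_records: pd.DataFrame,
    evidence: pd.DataFrame,
    n_select: int = 21,
) -> pd.DataFrame:
    """Rank upregulated proteins into a targeted-validation shortlist.

    Peptides carrying oxidized methionine or missed tryptic cleavages are
    excluded as quantifiers; proteins with fewer than two surviving
    peptides are dropped (two quantifier peptides are monitored per
    protein downstream).  Survivors are ranked by log2 fold change, then
    by total surviving-peptide intensity, descending; the top ``n_select``
    are returned with their two highest-intensity surviving peptides.
    """
    ok = evidence.loc[
        ~evidence["has_oxidized_met"].astype(bool)
        & (evidence["missed_cleavages"] == 0)
    ]
    ok = ok[ok["protein_id"].isin(up_records.index)]
    counts = ok.groupby("protein_id").size()
    eligible = counts.index[counts >= 2]
    if len(eligible) < n_select:
        warnings.warn(
            f"only {len(eligible)} proteins have >= 2 eligible peptides "
            f"(requested {n_select})",
            stacklevel=2,
        )
    intensity = ok.groupby("protein_id")["total_intensity"].sum()
    ranking = pd.DataFrame(
        {
            "log2fc": up_records.loc[eligible, "log2fc"],
            "total_intensity": intensity.loc[eligible],
        }
    ).sort_values(
        by=["log2fc", "total_intensity"], ascending=False, kind="mergesort"
    )
    chosen = ranking.head(n_select)
    rows = []
    for rank, (prot, rec) in enumerate(chosen.iterrows(), start=1):
        peps = ok[ok["protein_id"] == prot].sort_values(
            by=["total_intensity", "peptide_sequence"],
            ascending=[False, True],
            kind="mergesort",
        )
        rows.append(
            {
                "protein_id": prot,
                "rank": rank,
                "peptide_1": peps.iloc[0]["peptide_sequence"],
                "peptide_2": peps.iloc[1]["peptide_sequence"],
                "log2fc": float(rec["log2fc"]),
                "total_intensity": float(rec["total_intensity"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "rank",
            "peptide_1",
            "peptide_2",
            "log2fc",
            "total_intensity",
        ],
    )


def _impute_halfmin_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Complete log2 matrix: missing values at half the per-sample
    observed minimum (left-censoring surrogate, used only where complete
    vectors are required: PCA and clustering)."""
    filled = matrix.copy()
    for col in filled.columns:
        col_min = filled[col].min(skipna=True)
        fill = col_min / 2.0 if pd.notna(col_min) and col_min > 0 else 1.0
        filled[col] = filled[col].fillna(fill)
    return np.log2(filled)


def pca_scores(
    matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample scores on principal axes of the protein-centered log2 matrix.

    Returns (scores: samples x components, explained variance ratio).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA requires >= 3 samples")
    logm = _impute_halfmin_log2(matrix)
    centered = logm.sub(logm.mean(axis=1), axis=0)
    data = centered.T.to_numpy()
    max_comp = min(data.shape[0] - 1, data.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(data)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=cols),
        pd.Series(pca.explained_variance_ratio_, index=cols, name="evr"),
    )


@dataclass
class SampleDendrogram:
    """Complete-linkage merge tree over samples."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 format
    labels: list[str]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def cluster_samples(matrix: pd.DataFrame) -> SampleDendrogram:
    """Agglomerative complete-linkage clustering of samples with Euclidean
    distance on protein-centered log2 intensities."""
    if matrix.shape[1] < 2:
        raise ValueError("clustering requires >= 2 samples")
    logm = _impute_halfmin_log2(matrix)
    centered = logm.sub(logm.mean(axis=1), axis=0)
    Z = linkage(centered.T.to_numpy(), method="complete", metric="euclidean")
    return SampleDendrogram(linkage_matrix=Z, labels=list(matrix.columns))
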