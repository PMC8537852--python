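"""Targeted (PRM) quantification chain.

From transition chromatograms to protein-level group comparisons:

1. per (sample, peptide), pick the best parent/fragment transition by
   signal-to-noise (peak area over an MAD-based baseline noise estimate);
2. integrate its chromatographic peak (trapezoidal, linear-baseline
   subtracted);
3. normalize twice — first by the per-sample median of spiked iRT
   standard peptide areas (LC-MS/MS drift), then by the summed area of
   the reference-protein (biotinidase, BTD) quantifier peptides after iRT
   normalization (protein-loading / Bradford variation);
4. sum each protein's two quantifier peptides into a protein intensity;
5. compare case vs control per protein with a Welch t-test and report the
   PE/CTL ratio of group means.

Multiplying every trace of one sample by a constant leaves that sample's
protein intensities unchanged: the dual normalization cancels any purely
technical per-sample scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import PrmDesign

logger = logging.getLogger(__name__)

__all__ = [
    "PeakArea",
    "BestTransition",
    "integrate_peak",
    "pick_best_transition",
    "quantify_peptides",
    "compute_normalization",
    "apply_normalization",
    "rollup_protein",
    "welch_test",
    "group_ratio",
    "compare_groups",
    "significance_stars",
]

# star legends differ between the validation and longitudinal tables
VALIDATION_STARS = ((0.0001, "***"), (0.001, "**"), (0.05, "*"))
LONGITUDINAL_STARS = ((0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class PeakArea:
    """Integrated chromatographic peak for one trace."""

    area: float
    rt_start: float
    rt_apex: float
    rt_end: float
    is_zero: bool = False


@dataclass(frozen=True)
class BestTransition:
    transition_id: str
    score: float
    zero_area: bool = False


def integrate_peak(
    rt: np.ndarray,
    intensity: np.ndarray,
    expected_rt: float,
    window: float,
) -> PeakArea:
    """Integrate the peak nearest ``expected_rt``.

    The apex is the maximum intensity within ``window`` minutes of
    ``expected_rt``.  Boundaries extend outward from the apex to the
    first local minimum below 1% of the apex intensity, or to the window
    edge.  The area is the trapezoidal integral of the trace minus a
    linear baseline drawn between the boundary intensities, floored at 0.
    """
    rt = np.asarray(rt, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if rt.ndim != 1 or rt.shape != intensity.shape:
        raise ValueError("rt and intensity must be equal-length 1-d arrays")
    if rt.size >= 2 and not np.all(np.diff(rt) > 0):
        raise ValueError("rt must be strictly increasing")
    if window <= 0:
        raise ValueError("window must be > 0")
    in_win = np.flatnonzero(np.abs(rt - expected_rt) <= window)
    if in_win.size == 0:
        return PeakArea(0.0, expected_rt, expected_rt, expected_rt, is_zero=True)
    lo, hi = in_win[0], in_win[-1]
    apex = lo + int(np.argmax(intensity[lo : hi + 1]))
    apex_int = intensity[apex]
    if apex_int <= 0:
        return PeakArea(0.0, rt[lo], rt[apex], rt[hi], is_zero=True)
    floor = 0.01 * apex_int

    def walk(direction: int) -> int:
        edge = lo if direction < 0 else hi
        i = apex
        while i != edge:
            j = i + direction
            prev_ok = j - direction  # neighbor toward the apex
            nxt = j + direction  # neighbor away from the apex
            is_min = intensity[j] <= intensity[prev_ok] and (
                j == edge or intensity[j] <= intensity[nxt]
            )
            if is_min and intensity[j] < floor:
                return j
            i = j
        return edge

    left = walk(-1)
    right = walk(+1)
    seg_rt = rt[left : right + 1]
    seg_int = intensity[left : right + 1]
    if seg_rt.size < 2:
        return PeakArea(0.0, rt[left], rt[apex], rt[right], is_zero=True)
    baseline = np.interp(
        seg_rt, [seg_rt[0], seg_rt[-1]], [seg_int[0], seg_int[-1]]
    )
    area = float(np.trapezoid(seg_int - baseline, seg_rt))
    return PeakArea(
        area=max(area, 0.0),
        rt_start=float(rt[left]),
        rt_apex=float(rt[apex]),
        rt_end=float(rt[right]),
    )


def pick_best_transition(
    traces: pd.DataFrame,
    expected_rt: float,
    window: float,
) -> BestTransition:
    """Choose the best transition of one (sample, peptide) trace set.

    Score = integrated peak area / baseline noise, where noise is the
    scaled median absolute deviation of the off-peak signal (outside the
    integration boundaries).  Ties break to the lexicographically
    smallest transition id; all-zero traces return the first transition
    with a zero-area flag.
    """
    required = {"transition_id", "rt_min", "intensity"}
    if not required.issubset(traces.columns):
        raise ValueError(f"traces must have columns {sorted(required)}")
    scores: dict[str, float] = {}
    any_signal = False
    for tid in sorted(traces["transition_id"].unique()):
        g = traces[traces["transition_id"] == tid].sort_values("rt_min")
        rt = g["rt_min"].to_numpy(dtype=float)
        inten = g["intensity"].to_numpy(dtype=float)
        pa = integrate_peak(rt, inten, expected_rt, window)
        if pa.area > 0:
            any_signal = True
        off = inten[(rt < pa.rt_start) | (rt > pa.rt_end)]
        if off.size:
            mad = float(np.median(np.abs(off - np.median(off)))) * 1.4826
        else:
            mad = 0.0
        noise = max(mad, 1e-9)
        scores[tid] = pa.area / noise
    ids = sorted(scores)
    if not any_signal:
        return BestTransition(ids[0], 0.0, zero_area=True)
    # strict-improvement scan over lexicographically sorted ids: ties keep
    # the smallest transition id
    best = ids[0]
    for tid in ids[1:]:
        if scores[tid] > scores[best]:
            best = tid
    return BestTransition(best, scores[best])


def quantify_peptides(
    chromatograms: pd.DataFrame,
    design: PrmDesign,
    window: float = 0.5,
) -> pd.DataFrame:
    """Best-transition peak areas for every (sample, peptide).

    Returns columns sample_id, peptide_id, best_transition_id, area,
    rt_start, rt_apex, rt_end, zero_area.
    """
    expected = {t.peptide_id: t.expected_rt_min for t in design.targets}
    rows = []
    for (sample, pep), grp in chromatograms.groupby(
        ["sample_id", "peptide_id"], sort=True
    ):
        if pep not in expected:
            logger.info("quantify_peptides: skipping unknown peptide %s", pep)
            continue
        ert = expected[pep]
        best = pick_best_transition(grp, ert, window)
        g = grp[grp["transition_id"] == best.transition_id].sort_values("rt_min")
        pa = integrate_peak(
            g["rt_min"].to_numpy(float), g["intensity"].to_numpy(float), ert, window
        )
        rows.append(
            {
                "sample_id": sample,
                "peptide_id": pep,
                "best_transition_id": best.transition_id,
                "area": pa.area,
                "rt_start": pa.rt_start,
                "rt_apex": pa.rt_apex,
                "rt_end": pa.rt_end,
                "zero_area": pa.is_zero or best.zero_area,
            }
        )
    return pd.DataFrame(rows)


def compute_normalization(areas: pd.DataFrame, design: PrmDesign) -> pd.DataFrame:
    """Per-sample normalization factors.

    ``irt_median``: median of the sample's iRT standard peptide areas
    (corrects LC-MS/MS drift).  ``reference_signal``: sum of the sample's
    reference-protein (BTD) quantifier peptide areas *after* iRT
    normalization (corrects protein loading).
    """
    irt_peps = set(design.irt_peptides)
    ref_peps = {t.peptide_id for t in design.reference_targets()}
    if not irt_peps:
        raise ValueError("design has no iRT peptides")
    if not ref_peps:
        raise ValueError("design has no reference-protein peptides")
    rows = []
    for sample, g in areas.groupby("sample_id", sort=True):
        irt = g.loc[g["peptide_id"].isin(irt_peps), "area"]
        if irt.empty or not (irt > 0).any():
            raise ValueError(f"sample {sample}: no positive iRT peptide areas")
        irt_median = float(irt[irt > 0].median())
        ref = g.loc[g["peptide_id"].isin(ref_peps), "area"]
        if ref.empty or float(ref.sum()) <= 0:
            raise ValueError(
                f"sample {sample}: missing or zero reference-protein signal"
            )
        rows.append(
            {
                "sample_id": sample,
                "irt_median": irt_median,
                "reference_signal": float(ref.sum()) / irt_median,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def apply_normalization(
    areas: pd.DataFrame, factors: pd.DataFrame
) -> pd.DataFrame:
    """Dual-normalized peptide areas: (area / irt_median) / reference_signal."""
    missing = set(areas["sample_id"]) - set(factors.index)
    if missing:
        raise ValueError(f"no normalization factors for samples {sorted(missing)}")
    out = areas.copy()
    irt = factors.loc[out["sample_id"], "irt_median"].to_numpy()
    ref = factors.loc[out["sample_id"], "reference_signal"].to_numpy()
    out["normalized"] = out["area"].to_numpy() / irt / ref
    return out


def rollup_protein(
    normalized: pd.DataFrame, design: PrmDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein intensities: sum of the two quantifier peptides per protein.

    With one peptide missing (or zero-flagged) the available peptide is
    used alone and the entry is flagged partial; with both missing the
    protein is missing (NaN) for that sample.

    Returns (intensity table samples x proteins, n_peptides table).
    """
    pep_to_prot = {
        t.peptide_id: t.protein_id for t in design.quantifier_targets()
    }
    usable = normalized[normalized["peptide_id"].isin(pep_to_prot)].copy()
    if "zero_area" in usable.columns:
        usable = usable[~usable["zero_area"].astype(bool)]
    usable["protein_id"] = usable["peptide_id"].map(pep_to_prot)
    samples = sorted(normalized["sample_id"].unique())
    proteins = design.target_proteins()
    grouped = usable.groupby(["sample_id", "protein_id"])["normalized"]
    table = (
        grouped.sum().unstack().reindex(index=samples, columns=proteins)
    )
    counts = (
        grouped.size().unstack().reindex(index=samples, columns=proteins).fillna(0)
    ).astype(int)
    n_partial = int((counts == 1).to_numpy().sum())
    if n_partial:
        logger.info("rollup_protein: %d partial (single-peptide) roll-ups", n_partial)
    table.index.name = "sample_id"
    counts.index.name = "sample_id"
    return table, counts


def welch_test(case_values, control_values) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns (t, Welch-Satterthwaite df, two-sided p).  Degenerate input
    with both groups constant and equal yields (0, n1+n2-2, 1).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_test needs >= 2 values per group")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if dm == 0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return float(np.sign(dm) * np.inf), float(n1 + n2 - 2), 0.0
    t = dm / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_ratio(case_values, control_values) -> float:
    """PE/CTL ratio of group means on the intensity scale."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    cm = y.mean()
    if not cm > 0:
        raise ValueError("control group mean must be > 0")
    return float(x.mean() / cm)


def significance_stars(p: float, legend=VALIDATION_STARS) -> str:
    """Map a p-value to its star annotation per a table legend
    ((cutoff, symbol) pairs, most stringent first; p < cutoff wins)."""
    for cutoff, symbol in legend:
        if p < cutoff:
            return symbol
    return ""


def compare_groups(
    intensities: pd.DataFrame,
    samples: pd.DataFrame,
    gene_map: dict[str, str] | None = None,
    log_scale: bool = False,
    stars=VALIDATION_STARS,
) -> pd.DataFrame:
    """Per-protein case/control comparison of a samples x proteins table.

    The ratio is always the ratio of group means on the linear intensity
    scale; the Welch test runs on linear intensities by default or on
    log2 intensities with ``log_scale=True``.
    """
    meta = samples.set_index("sample_id")
    rows = []
    for prot in intensities.columns:
        vals = intensities[prot].dropna()
        groups = meta.loc[vals.index, "group"]
        x = vals[groups == "case"].to_numpy()
        y = vals[groups == "control"].to_numpy()
        if x.size < 2 or y.size < 2:
            logger.info("compare_groups: skipping %s (insufficient values)", prot)
            continue
        ratio = group_ratio(x, y)
        if log_scale:
            t, df, p = welch_test(np.log2(x), np.log2(y))
        else:
            t, df, p = welch_test(x, y)
        rows.append(
            {
                "protein_id": prot,
                "gene": (gene_map or {}).get(prot, ""),
                "ratio": ratio,
                "t": t,
                "df": df,
                "p": p,
                "significance": significance_stars(p, stars),
            }
        )
    return pd.DataFrame(rows)
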