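"""Synthetic data generators for the urine-proteomics pipeline.

Real discovery and targeted data from the underlying cohort are available
only on request, so every stage of the pipeline is exercised on synthetic
inputs with known ground truth.  Three generators are provided:

``generate_discovery_cohort``
    A label-free quantification (LFQ) protein x sample intensity matrix.
    Log2 intensities are additive: per-protein baseline + planted
    case-only differential effects + a case-only global "proteinuria"
    shift (the confounder that motivates fold-change z-centering) +
    technical noise.  Values are left-censored missing-not-at-random
    through a logistic detection curve on log2 intensity.

``generate_prm_dataset``
    Parallel-reaction-monitoring (PRM) transition chromatograms: Gaussian
    peaks on a retention-time grid whose areas are proportional to peptide
    abundance times per-sample loading and instrument-drift factors.
    Spiked iRT standard peptides carry drift only (they are added after
    protein loading is fixed); endogenous peptides carry both factors.

``generate_longitudinal_cohort``
    A two-(or more-)timepoint cohort with per-subject random intercepts
    and a per-timepoint effect schedule, emulating urine sampling at
    20-24 and 30-34 weeks of gestation.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .panels import REFERENCE_GENE, REFERENCE_PROTEIN, VALIDATION_PANEL

__all__ = [
    "ConfigError",
    "CohortConfig",
    "GroundTruth",
    "PeptideTarget",
    "PrmDesign",
    "generate_discovery_cohort",
    "generate_longitudinal_cohort",
    "generate_peptide_evidence",
    "generate_prm_abundances",
    "generate_prm_dataset",
    "build_prm_design",
]


class ConfigError(ValueError):
    """A generator configuration field is invalid (message names the field)."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic case/control discovery cohort.

    Defaults mirror the scale of the motivating study: 1108 urinary
    proteins quantified in 12 preeclampsia cases vs 12 matched controls,
    with 53 upregulated and 9 downregulated proteins planted at
    |log2 fold change| in [1.5, 3], and a ~1 log2-unit global proteinuria
    shift in cases.
    """

    n_case: int = 12
    n_control: int = 12
    n_proteins: int = 1108
    n_de_up: int = 53
    n_de_down: int = 9
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    tech_noise_log2_sd: float = 0.5
    proteinuria_log2_mean: float = 1.0
    proteinuria_log2_sd: float = 0.25
    missing_midpoint_log2: float = 16.0
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_proteins"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("n_de_up", "n_de_down"):
            if int(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_de_up + self.n_de_down > self.n_proteins:
            raise ConfigError("n_de_up + n_de_down must not exceed n_proteins")
        lo, hi = self.de_log2fc_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ConfigError("de_log2fc_range must be a finite (low, high) pair")
        for name in ("baseline_log2_sd", "tech_noise_log2_sd", "proteinuria_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.missing_slope <= 0:
            raise ConfigError("missing_slope must be > 0")


@dataclass
class GroundTruth:
    """Planted parameters returned alongside each synthetic dataset.

    ``de_log2fc`` maps protein id to the planted case-vs-control log2
    effect; ``sample_global_factor`` maps sample id to the multiplicative
    proteinuria factor; ``loading_factor`` and ``drift_factor`` are the
    per-sample technical factors of a PRM dataset (empty otherwise).
    """

    de_log2fc: dict[str, float] = field(default_factory=dict)
    sample_global_factor: dict[str, float] = field(default_factory=dict)
    loading_factor: dict[str, float] = field(default_factory=dict)
    drift_factor: dict[str, float] = field(default_factory=dict)


def _sample_ids(n_case: int, n_control: int) -> tuple[list[str], list[str]]:
    cases = [f"PE_{i + 1:02d}" for i in range(n_case)]
    controls = [f"CTL_{i + 1:02d}" for i in range(n_control)]
    return cases, controls


def make_sample_table(
    n_case: int, n_control: int, timepoint: str = ""
) -> pd.DataFrame:
    """Sample metadata table: sample_id, subject_id, group, timepoint."""
    cases, controls = _sample_ids(n_case, n_control)
    return pd.DataFrame(
        {
            "sample_id": cases + controls,
            "subject_id": ["S_" + s for s in cases + controls],
            "group": ["case"] * n_case + ["control"] * n_control,
            "timepoint": [timepoint] * (n_case + n_control),
        }
    )


def generate_discovery_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an LFQ discovery matrix with planted effects.

    Returns
    -------
    matrix : DataFrame, proteins x samples
        Raw-scale intensities, NaN = not detected (left-censored MNAR).
    samples : DataFrame
        Columns sample_id, subject_id, group, timepoint.
    truth : GroundTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_case + cfg.n_control
    proteins = [f"SP{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    samples = make_sample_table(cfg.n_case, cfg.n_control)

    n_de = cfg.n_de_up + cfg.n_de_down
    de_idx = rng.choice(cfg.n_proteins, size=n_de, replace=False)
    lo, hi = cfg.de_log2fc_range
    effects = rng.uniform(lo, hi, size=n_de)
    effects[cfg.n_de_up:] *= -1.0  # planted downregulation

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_proteins)
    shift = np.zeros(n_samples)
    shift[: cfg.n_case] = rng.normal(
        cfg.proteinuria_log2_mean, cfg.proteinuria_log2_sd, cfg.n_case
    )
    noise = rng.normal(0.0, cfg.tech_noise_log2_sd, size=(cfg.n_proteins, n_samples))

    effect_col = np.zeros(cfg.n_proteins)
    effect_col[de_idx] = effects
    is_case = np.zeros(n_samples)
    is_case[: cfg.n_case] = 1.0

    log2int = (
        baseline[:, None]
        + effect_col[:, None] * is_case[None, :]
        + shift[None, :]
        + noise
    )
    p_missing = expit((cfg.missing_midpoint_log2 - log2int) / cfg.missing_slope)
    missing = rng.random(size=log2int.shape) < p_missing

    values = np.power(2.0, log2int)
    values[missing] = np.nan
    matrix = pd.DataFrame(values, index=proteins, columns=samples["sample_id"].tolist())
    matrix.index.name = "protein_id"

    truth = GroundTruth(
        de_log2fc={proteins[i]: float(e) for i, e in zip(de_idx, effects)},
        sample_global_factor={
            s: float(2.0**h) for s, h in zip(samples["sample_id"], shift)
        },
    )
    return matrix, samples, truth


# ---------------------------------------------------------------------------
# PRM chromatograms
# ---------------------------------------------------------------------------

_DEFAULT_RT_OFFSETS = tuple(np.round(np.arange(-0.75, 0.7501, 0.01), 4))


@dataclass(frozen=True)
class PeptideTarget:
    """One monitored peptide (quantifier, iRT standard, or reference)."""

    protein_id: str
    gene: str
    peptide_id: str
    is_irt: bool = False
    is_reference: bool = False
    transitions: tuple[str, ...] = ("y4", "y5", "y6")
    expected_rt_min: float = 0.0

    def __post_init__(self) -> None:
        if self.is_irt and self.is_reference:
            raise ConfigError(
                f"peptide {self.peptide_id}: cannot be both iRT and reference"
            )
        if not self.transitions:
            raise ConfigError(f"peptide {self.peptide_id}: needs >= 1 transition")


@dataclass(frozen=True)
class PrmDesign:
    """A PRM acquisition design.

    ``rt_grid`` holds retention-time offsets (minutes) relative to each
    peptide's expected RT; every chromatogram is sampled on
    ``expected_rt + rt_grid``, so the stored traces cover a fixed window
    around each peak rather than the full LC gradient.
    """

    targets: tuple[PeptideTarget, ...]
    reference_protein: str = REFERENCE_PROTEIN
    rt_grid: tuple[float, ...] = _DEFAULT_RT_OFFSETS
    peak_sigma: float = 0.05

    def __post_init__(self) -> None:
        grid = np.asarray(self.rt_grid, dtype=float)
        if grid.size < 2 or not np.all(np.diff(grid) > 0):
            raise ConfigError("rt_grid must be strictly increasing with >= 2 points")
        if self.peak_sigma <= 0:
            raise ConfigError("peak_sigma must be > 0")
        counts: dict[str, int] = {}
        for t in self.quantifier_targets():
            counts[t.protein_id] = counts.get(t.protein_id, 0) + 1
        bad = {p: c for p, c in counts.items() if c != 2}
        if bad:
            raise ConfigError(
                f"each target protein needs exactly two quantifier peptides; got {bad}"
            )

    def irt_targets(self) -> list[PeptideTarget]:
        return [t for t in self.targets if t.is_irt]

    def quantifier_targets(self) -> list[PeptideTarget]:
        """Non-iRT peptides, including the reference protein's."""
        return [t for t in self.targets if not t.is_irt]

    def reference_targets(self) -> list[PeptideTarget]:
        return [t for t in self.targets if t.is_reference]

    def target_proteins(self) -> list[str]:
        seen: list[str] = []
        for t in self.quantifier_targets():
            if t.protein_id not in seen:
                seen.append(t.protein_id)
        return seen

    @property
    def irt_peptides(self) -> list[str]:
        return [t.peptide_id for t in self.irt_targets()]


def build_prm_design(
    panel: dict[str, tuple[str, float]] | None = None,
    n_irt: int = 11,
    n_transitions: int = 3,
    rt_start: float = 10.0,
    rt_spacing: float = 2.0,
    peak_sigma: float = 0.05,
) -> PrmDesign:
    """Build a PRM design: two quantifier peptides per panel protein, the
    BTD reference protein, and ``n_irt`` spiked iRT standard peptides.

    Expected retention times are laid out deterministically on a
    ``rt_spacing``-minute ladder starting at ``rt_start``.
    """
    if panel is None:
        panel = VALIDATION_PANEL
    transitions = tuple(f"y{4 + j}" for j in range(n_transitions))
    targets: list[PeptideTarget] = []
    rt = rt_start
    entries = list(panel.items()) + [(REFERENCE_PROTEIN, (REFERENCE_GENE, 1.0))]
    for acc, (gene, _ratio) in entries:
        for k in (1, 2):
            targets.append(
                PeptideTarget(
                    protein_id=acc,
                    gene=gene,
                    peptide_id=f"{gene}_pep{k}",
                    is_reference=(acc == REFERENCE_PROTEIN),
                    transitions=transitions,
                    expected_rt_min=round(rt, 3),
                )
            )
            rt += rt_spacing
    for i in range(n_irt):
        targets.append(
            PeptideTarget(
                protein_id="iRT",
                gene="iRT",
                peptide_id=f"iRT_{i + 1:02d}",
                is_irt=True,
                transitions=transitions,
                expected_rt_min=round(rt, 3),
            )
        )
        rt += rt_spacing
    return PrmDesign(targets=tuple(targets), peak_sigma=peak_sigma)


def generate_prm_abundances(
    design: PrmDesign,
    samples: pd.DataFrame,
    case_over_control_ratio: dict[str, float] | None = None,
    base_log2_mean: float = 17.0,
    base_log2_sd: float = 1.5,
    bio_log2_sd: float = 0.5,
    reference_log2_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """True per-sample peptide-level protein abundances (peak-height units).

    Each target protein gets a lognormal control-group base level; case
    samples are multiplied by ``case_over_control_ratio[protein]`` (1.0 if
    absent).  Per sample x protein biological variability is lognormal
    with ``bio_log2_sd``.  The reference protein varies only with
    ``reference_log2_sd`` and carries no group effect, emulating a stable
    loading control.

    Returns a samples x proteins DataFrame.
    """
    rng = np.random.default_rng(seed)
    ratios = case_over_control_ratio or {}
    proteins = design.target_proteins()
    sample_ids = samples["sample_id"].tolist()
    is_case = (samples["group"] == "case").to_numpy()
    out = np.empty((len(sample_ids), len(proteins)))
    for j, prot in enumerate(proteins):
        base = 2.0 ** rng.normal(base_log2_mean, base_log2_sd)
        sd = reference_log2_sd if prot == design.reference_protein else bio_log2_sd
        bio = 2.0 ** rng.normal(0.0, sd, size=len(sample_ids))
        eff = 1.0 if prot == design.reference_protein else float(
            ratios.get(prot, 1.0)
        )
        out[:, j] = base * bio * np.where(is_case, eff, 1.0)
    return pd.DataFrame(out, index=sample_ids, columns=proteins)


# fixed, seed-independent response structure
def _peptide_response(design: PrmDesign) -> dict[str, float]:
    resp = {}
    for prot in design.target_proteins():
        peps = [t for t in design.quantifier_targets() if t.protein_id == prot]
        for t, r in zip(peps, (0.6, 0.4)):
            resp[t.peptide_id] = r
    return resp


def _transition_shares(n: int) -> np.ndarray:
    w = 0.6 ** np.arange(n)
    return w / w.sum()


def _irt_nominal(design: PrmDesign) -> dict[str, float]:
    irt = sorted(design.irt_peptides)
    if not irt:
        return {}
    levels = np.geomspace(3e4, 3e5, len(irt))
    return {p: float(a) for p, a in zip(irt, levels)}


def generate_prm_dataset(
    design: PrmDesign,
    samples: pd.DataFrame,
    abundances: pd.DataFrame,
    *,
    loading_log2_sd: float = 0.25,
    drift_log2_sd: float = 0.25,
    noise_sd: float = 25.0,
    rt_jitter_sd: float = 0.02,
    loading_factor: dict[str, float] | None = None,
    drift_factor: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate PRM transition chromatograms.

    Each (sample, peptide, transition) trace is a Gaussian peak of height
    ``abundance * response * share * loading * drift`` (iRT peptides:
    nominal * drift only) plus half-normal baseline noise, on the design's
    RT window.  A per-sample RT jitter shifts peak apexes.  Explicit
    ``loading_factor``/``drift_factor`` maps override random draws.

    Returns the long-format ChromatogramSet (columns sample_id,
    peptide_id, transition_id, rt_min, intensity) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    sample_ids = samples["sample_id"].tolist()
    missing_samples = [s for s in sample_ids if s not in abundances.index]
    if missing_samples:
        raise ValueError(f"no abundance entries for samples {missing_samples}")
    for prot in design.target_proteins():
        if prot not in abundances.columns:
            raise ValueError(f"no abundance entry for protein {prot}")

    n_s = len(sample_ids)
    if loading_factor is None:
        loading = 2.0 ** rng.normal(0.0, loading_log2_sd, n_s)
        loading_factor = {s: float(v) for s, v in zip(sample_ids, loading)}
    else:
        loading = np.array([loading_factor[s] for s in sample_ids])
    if drift_factor is None:
        drift = 2.0 ** rng.normal(0.0, drift_log2_sd, n_s)
        drift_factor = {s: float(v) for s, v in zip(sample_ids, drift)}
    else:
        drift = np.array([drift_factor[s] for s in sample_ids])
    jitter = (
        rng.normal(0.0, rt_jitter_sd, n_s) if rt_jitter_sd > 0 else np.zeros(n_s)
    )

    offsets = np.asarray(design.rt_grid, dtype=float)
    sigma = design.peak_sigma
    resp = _peptide_response(design)
    irt_amp = _irt_nominal(design)

    frames: list[pd.DataFrame] = []
    n_pts = offsets.size
    for target in design.targets:
        if target.is_irt:
            heights = irt_amp[target.peptide_id] * drift
        else:
            ab = abundances.loc[sample_ids, target.protein_id].to_numpy(dtype=float)
            heights = ab * resp[target.peptide_id] * loading * drift
        shares = _transition_shares(len(target.transitions))
        rt_axis = target.expected_rt_min + offsets  # shared grid per peptide
        # peak center jitters per sample; the sampling grid stays fixed
        gauss = np.exp(
            -((offsets[None, :] - jitter[:, None]) ** 2) / (2.0 * sigma**2)
        )  # (n_samples, n_pts)
        for share, trans in zip(shares, target.transitions):
            signal = heights[:, None] * share * gauss
            if noise_sd > 0:
                signal = signal + np.abs(
                    rng.normal(0.0, noise_sd, size=signal.shape)
                )
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": np.repeat(sample_ids, n_pts),
                        "peptide_id": target.peptide_id,
                        "transition_id": trans,
                        "rt_min": np.tile(rt_axis, n_s),
                        "intensity": signal.ravel(),
                    }
                )
            )
    chroms = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(loading_factor=dict(loading_factor), drift_factor=dict(drift_factor))
    return chroms, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------


def generate_longitudinal_cohort(
    config: CohortConfig,
    n_timepoints: int = 2,
    effect_schedule: dict[str, list[float]] | None = None,
    subject_log2_sd: float = 0.5,
    protein_ids: list[str] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate a multi-timepoint cohort with per-subject random intercepts.

    ``effect_schedule`` maps protein id to a per-timepoint list of log2
    effects applied to case subjects (e.g. ``{"CP": [0.0, 2.0]}`` plants a
    late-only effect).  Subject intercepts (per subject x protein,
    ``subject_log2_sd``) are shared across timepoints, so within-subject
    differences reflect only the schedule, the per-sample proteinuria
    shift and technical noise.  Longitudinal matrices are complete (no
    MNAR missingness).

    Returns ({timepoint -> proteins x samples matrix}, samples, truth);
    timepoints are labeled "T1", "T2", ...
    """
    if n_timepoints < 1:
        raise ConfigError("n_timepoints must be >= 1")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if protein_ids is None:
        proteins = [f"SP{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    else:
        proteins = list(protein_ids)
    schedule = effect_schedule or {}
    unknown = sorted(set(schedule) - set(proteins))
    if unknown:
        raise ConfigError(f"effect_schedule names unknown proteins {unknown}")
    for prot, effs in schedule.items():
        if len(effs) != n_timepoints:
            raise ConfigError(
                f"effect_schedule[{prot}] must list one effect per timepoint"
            )

    n_prot = len(proteins)
    n_subj = cfg.n_case + cfg.n_control
    cases, controls = _sample_ids(cfg.n_case, cfg.n_control)
    subjects = ["S_" + s for s in cases + controls]
    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    is_case = np.array([g == "case" for g in groups], dtype=float)

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n_prot)
    intercept = rng.normal(0.0, subject_log2_sd, size=(n_prot, n_subj))

    eff = np.zeros((n_prot, n_timepoints))
    prot_index = {p: i for i, p in enumerate(proteins)}
    for prot, effs in schedule.items():
        eff[prot_index[prot], :] = effs

    matrices: dict[str, pd.DataFrame] = {}
    rows = []
    truth = GroundTruth(de_log2fc={p: list(map(float, e)) for p, e in schedule.items()})
    for t in range(n_timepoints):
        tp = f"T{t + 1}"
        shift = np.zeros(n_subj)
        if cfg.proteinuria_log2_sd > 0 or cfg.proteinuria_log2_mean != 0:
            shift[: cfg.n_case] = rng.normal(
                cfg.proteinuria_log2_mean, cfg.proteinuria_log2_sd, cfg.n_case
            )
        noise = rng.normal(0.0, cfg.tech_noise_log2_sd, size=(n_prot, n_subj))
        log2int = (
            baseline[:, None]
            + intercept
            + eff[:, t][:, None] * is_case[None, :]
            + shift[None, :]
            + noise
        )
        sample_ids = [f"{subj[2:]}_{tp}" for subj in subjects]
        matrices[tp] = pd.DataFrame(
            np.power(2.0, log2int), index=proteins, columns=sample_ids
        )
        matrices[tp].index.name = "protein_id"
        for sid, subj, grp, h in zip(sample_ids, subjects, groups, shift):
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subj,
                    "group": grp,
                    "timepoint": tp,
                }
            )
            truth.sample_global_factor[sid] = float(2.0**h)
    samples = pd.DataFrame(rows)
    return matrices, samples, truth


# ---------------------------------------------------------------------------
# Peptide-level evidence for shortlist filtering
# ---------------------------------------------------------------------------

_RESIDUES = list("ACDEFGHILNPQSTVWY")  # no K/R internally, M added explicitly


def generate_peptide_evidence(
    protein_ids: list[str],
    n_peptides_range: tuple[int, int] = (3, 6),
    p_oxidized_met: float = 0.15,
    p_missed_cleavage: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic peptide-level evidence for candidate-shortlist filtering.

    Each protein gets several tryptic-looking peptides with flags for
    oxidized methionine and missed cleavages (both exclude a peptide from
    quantifier selection) and a lognormal total intensity.
    """
    columns = [
        "protein_id",
        "peptide_sequence",
        "has_oxidized_met",
        "missed_cleavages",
        "total_intensity",
    ]
    rng = np.random.default_rng(seed)
    lo, hi = n_peptides_range
    rows = []
    for prot in protein_ids:
        n_pep = int(rng.integers(lo, hi + 1))
        for k in range(n_pep):
            length = int(rng.integers(7, 18))
            body = "".join(rng.choice(_RESIDUES, size=length))
            has_ox = bool(rng.random() < p_oxidized_met)
            missed = int(rng.random() < p_missed_cleavage)
            if has_ox:
                pos = int(rng.integers(0, length))
                body = body[:pos] + "M(ox)" + body[pos:]
            if missed:
                pos = int(rng.integers(1, length))
                body = body[:pos] + rng.choice(["K", "R"]) + body[pos:]
            seq = body + rng.choice(["K", "R"])
            rows.append(
                {
                    "protein_id": prot,
                    "peptide_sequence": seq,
                    "has_oxidized_met": has_ox,
                    "missed_cleavages": missed,
                    "total_intensity": float(2.0 ** rng.normal(20.0, 2.0)),
                }
            )
    return pd.DataFrame(rows, columns=columns)
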