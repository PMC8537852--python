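"""End-to-end study-mirroring workflows.

Three reproducible runs tie the stages together, mirroring the design of
a discovery / targeted-validation / longitudinal urine biomarker study:

- ``run_discovery_workflow``: simulate (or load) an LFQ cohort, run the
  differential-abundance chain, PCA and sample clustering, and produce
  the candidate shortlist.
- ``run_validation_workflow``: simulate PRM chromatograms for the target
  panel, quantify, dual-normalize, roll up to proteins, and emit the
  case/control comparison table.
- ``run_longitudinal_workflow``: simulate a two-timepoint cohort, emit
  the per-timepoint comparison table and ROC summaries for the screening
  markers at the configured false-positive rate.

One global seed is expanded into independent per-stage seeds, so stages
can be re-run individually without perturbing each other; every run
writes a JSON manifest echoing the configuration and the SHA-256
checksum of each output, and identical (config, seed) pairs produce
bit-identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    SelectionCriteria,
    cluster_samples,
    differential_abundance,
    pca_scores,
    shortlist_candidates,
)
from .io import sha256_file, write_ground_truth, write_intensity_matrix, write_sample_table
from .panels import (
    GENE_TO_ACCESSION,
    LONGITUDINAL_RATIOS,
    SCREENING_MARKERS,
    VALIDATION_PANEL,
)
from .screening import both_timepoint_markers, longitudinal_table, roc_points, roc_summary
from .synthetic import (
    CohortConfig,
    build_prm_design,
    generate_discovery_cohort,
    generate_longitudinal_cohort,
    generate_peptide_evidence,
    generate_prm_abundances,
    generate_prm_dataset,
    make_sample_table,
)
from .targeted import (
    LONGITUDINAL_STARS,
    VALIDATION_STARS,
    apply_normalization,
    compare_groups,
    compute_normalization,
    quantify_peptides,
    rollup_protein,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "stage_seeds",
    "run_discovery_workflow",
    "run_validation_workflow",
    "run_longitudinal_workflow",
    "run_all",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run (defaults mirror the study
    scale: 12 vs 12 discovery and validation, 10 vs 20 longitudinal,
    21-protein target panel)."""

    seed: int = 0
    discovery: CohortConfig = field(default_factory=CohortConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    min_fraction: float = 0.5
    n_candidates: int = 21
    validation_n_case: int = 12
    validation_n_control: int = 12
    validation_bio_log2_sd: float = 0.5
    longitudinal_n_case: int = 10
    longitudinal_n_control: int = 20
    longitudinal_subject_log2_sd: float = 0.4
    longitudinal_tech_noise_log2_sd: float = 0.5
    fpr_target: float = 0.10
    ci_method: str = "hanley"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "discovery" in data:
            from .io import cohort_config_from_dict

            data["discovery"] = cohort_config_from_dict(data["discovery"])
        if "criteria" in data:
            data["criteria"] = SelectionCriteria(**data["criteria"])
        return cls(**data)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Expand one global seed into independent per-stage seeds (< 2^31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _write_manifest(out_dir: Path, stage: str, config: RunConfig, outputs: list[Path]) -> Path:
    manifest = {
        "stage": stage,
        "software_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "checksums": {p.name: sha256_file(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_discovery_workflow(
    config: RunConfig, out_dir
) -> dict:
    """Simulated discovery run: cohort generation, differential abundance,
    shortlist, PCA, clustering.  Returns the in-memory results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    cohort_cfg = replace(config.discovery, seed=seeds[0])
    matrix, samples, truth = generate_discovery_cohort(cohort_cfg)

    records = differential_abundance(
        matrix,
        samples,
        min_fraction=config.min_fraction,
        criteria=config.criteria,
    )
    up = records.index[records["direction"] == "up"]
    evidence = generate_peptide_evidence(list(up), seed=seeds[1])
    shortlist = shortlist_candidates(
        records.loc[up], evidence, n_select=config.n_candidates
    )
    scores, evr = pca_scores(matrix)
    dendro = cluster_samples(matrix)

    outputs = []
    for name, writer in [
        ("matrix.tsv", lambda p: write_intensity_matrix(matrix, p)),
        ("samples.tsv", lambda p: write_sample_table(samples, p)),
        ("ground_truth.json", lambda p: write_ground_truth(truth, p)),
        ("results.tsv", lambda p: records.to_csv(p, sep="\t")),
        ("candidates.tsv", lambda p: shortlist.to_csv(p, sep="\t", index=False)),
        ("pca_scores.tsv", lambda p: scores.to_csv(p, sep="\t", index_label="sample_id")),
        ("pca_variance.tsv", lambda p: evr.to_csv(p, sep="\t", index_label="component")),
        ("dendrogram.nwk", lambda p: Path(p).write_text(dendro.to_newick() + "\n")),
    ]:
        path = out / name
        writer(path)
        outputs.append(path)
    _write_manifest(out, "discovery", config, outputs)
    return {
        "matrix": matrix,
        "samples": samples,
        "truth": truth,
        "records": records,
        "shortlist": shortlist,
        "pca_scores": scores,
        "dendrogram": dendro,
    }


def validate_shortlist(design, shortlist_proteins) -> None:
    """Raise if shortlisted proteins are absent from the PRM design."""
    targets = set(design.target_proteins())
    unmatched = sorted(set(shortlist_proteins) - targets)
    if unmatched:
        raise ValueError(f"shortlist proteins not in PRM design: {unmatched}")


def run_validation_workflow(config: RunConfig, out_dir) -> dict:
    """Simulated targeted validation run on the 21-protein panel.

    Plants the panel's observed PE/CTL ratios as true effects, simulates
    PRM chromatograms with per-sample loading and drift factors, and runs
    the full quantification chain through the Welch comparison table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    design = build_prm_design()
    samples = make_sample_table(config.validation_n_case, config.validation_n_control)
    ratios = {acc: ratio for acc, (_gene, ratio) in VALIDATION_PANEL.items()}
    abundances = generate_prm_abundances(
        design,
        samples,
        case_over_control_ratio=ratios,
        bio_log2_sd=config.validation_bio_log2_sd,
        seed=seeds[2],
    )
    chroms, truth = generate_prm_dataset(
        design, samples, abundances, seed=seeds[3]
    )
    areas = quantify_peptides(chroms, design)
    factors = compute_normalization(areas, design)
    normalized = apply_normalization(areas, factors)
    table, n_peptides = rollup_protein(normalized, design)
    panel_table = table.drop(columns=[design.reference_protein])
    gene_map = {acc: gene for acc, (gene, _r) in VALIDATION_PANEL.items()}
    comparison = compare_groups(
        panel_table, samples, gene_map=gene_map, stars=VALIDATION_STARS
    )

    outputs = []
    for name, writer in [
        ("samples.tsv", lambda p: write_sample_table(samples, p)),
        ("ground_truth.json", lambda p: write_ground_truth(truth, p)),
        ("peak_areas.tsv", lambda p: areas.to_csv(p, sep="\t", index=False)),
        ("normalization.tsv", lambda p: factors.to_csv(p, sep="\t")),
        ("protein_intensities.tsv", lambda p: table.to_csv(p, sep="\t")),
        ("comparison.tsv", lambda p: comparison.to_csv(p, sep="\t", index=False)),
    ]:
        path = out / name
        writer(path)
        outputs.append(path)
    _write_manifest(out, "validation", config, outputs)
    return {
        "design": design,
        "samples": samples,
        "truth": truth,
        "areas": areas,
        "factors": factors,
        "intensities": table,
        "n_peptides": n_peptides,
        "comparison": comparison,
    }


def run_longitudinal_workflow(config: RunConfig, out_dir) -> dict:
    """Simulated two-timepoint longitudinal run with per-timepoint
    comparison table and ROC screening summaries for the marker proteins.

    The planted per-timepoint effects are log2 of the panel's observed
    longitudinal PE/CTL ratios; the cohort carries no proteinuria shift
    (samples predate clinical onset)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    genes = list(LONGITUDINAL_RATIOS)
    schedule = {
        g: [float(np.log2(r1)), float(np.log2(r2))]
        for g, (r1, r2) in LONGITUDINAL_RATIOS.items()
    }
    cohort_cfg = CohortConfig(
        n_case=config.longitudinal_n_case,
        n_control=config.longitudinal_n_control,
        n_proteins=len(genes),
        n_de_up=0,
        n_de_down=0,
        tech_noise_log2_sd=config.longitudinal_tech_noise_log2_sd,
        proteinuria_log2_mean=0.0,
        proteinuria_log2_sd=0.0,
        seed=seeds[4],
    )
    matrices, samples, truth = generate_longitudinal_cohort(
        cohort_cfg,
        n_timepoints=2,
        effect_schedule=schedule,
        subject_log2_sd=config.longitudinal_subject_log2_sd,
        protein_ids=genes,
    )
    tables = {tp: m.T for tp, m in matrices.items()}
    ltable = longitudinal_table(tables, samples, stars=LONGITUDINAL_STARS)
    markers = both_timepoint_markers(ltable)

    roc_rows = []
    roc_point_outputs: list[tuple[str, pd.DataFrame]] = []
    meta = samples.set_index("sample_id")
    for marker in SCREENING_MARKERS:
        for tp, tab in sorted(tables.items()):
            scores = tab[marker]
            labels = meta.loc[scores.index, "group"].to_numpy()
            summ = roc_summary(
                scores.to_numpy(), labels, config.fpr_target, config.ci_method
            )
            roc_rows.append(
                {
                    "marker": marker,
                    "accession": GENE_TO_ACCESSION.get(marker, ""),
                    "timepoint": tp,
                    **dataclasses.asdict(summ),
                }
            )
            roc_point_outputs.append(
                (f"roc_points_{marker}_{tp}.tsv", roc_points(scores.to_numpy(), labels))
            )
    roc_table = pd.DataFrame(roc_rows)

    outputs = []
    for tp, m in matrices.items():
        path = out / f"matrix_{tp}.tsv"
        write_intensity_matrix(m, path)
        outputs.append(path)
    for name, writer in [
        ("samples.tsv", lambda p: write_sample_table(samples, p)),
        ("ground_truth.json", lambda p: write_ground_truth(truth, p)),
        ("longitudinal_table.tsv", lambda p: ltable.to_csv(p, sep="\t")),
        ("roc_summary.tsv", lambda p: roc_table.to_csv(p, sep="\t", index=False)),
        (
            "both_timepoint_markers.txt",
            lambda p: Path(p).write_text("\n".join(markers) + "\n"),
        ),
    ]:
        path = out / name
        writer(path)
        outputs.append(path)
    for name, pts in roc_point_outputs:
        path = out / name
        pts.to_csv(path, sep="\t", index=False)
        outputs.append(path)
    _write_manifest(out, "longitudinal", config, outputs)
    return {
        "matrices": matrices,
        "samples": samples,
        "truth": truth,
        "table": ltable,
        "markers": markers,
        "roc": roc_table,
    }


def run_all(config: RunConfig, out_dir) -> dict:
    """Run discovery, validation and longitudinal workflows under one
    seed; writes a combined top-level manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {
        "discovery": run_discovery_workflow(config, out / "discovery"),
        "validation": run_validation_workflow(config, out / "validation"),
        "longitudinal": run_longitudinal_workflow(config, out / "longitudinal"),
    }
    combined = {
        "software_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    for stage in ("discovery", "validation", "longitudinal"):
        with open(out / stage / "manifest.json", encoding="utf-8") as fh:
            combined["stages"][stage] = json.load(fh)["checksums"]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
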