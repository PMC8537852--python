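"""Readers and writers for the pipeline's plain-text table formats.

All tables are UTF-8 TSV with "." decimals.  The intensity matrix has a
header row of sample ids, a first column of protein accessions, and an
empty cell for a missing (undetected) value; chromatograms travel in
long format (sample_id, peptide_id, transition_id, rt_min, intensity);
PRM target lists carry semicolon-joined transition ids.  Ground truth
and run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CohortConfig, GroundTruth, PeptideTarget, PrmDesign

__all__ = [
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_chromatograms",
    "write_chromatograms",
    "read_prm_design",
    "write_prm_design",
    "read_ground_truth",
    "write_ground_truth",
    "sha256_file",
    "load_yaml_config",
]


class ParseError(ValueError):
    """A pipeline table failed validation (message carries the line)."""


def _check_rectangular(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        widths = {}
        for lineno, line in enumerate(fh, start=1):
            widths[lineno] = line.rstrip("\n").count("\t")
        if not widths:
            raise ParseError(f"{path}: empty file")
        expected = widths[1]
        for lineno, w in widths.items():
            if w != expected:
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({w + 1} fields, expected {expected + 1})"
                )


def read_intensity_matrix(path) -> pd.DataFrame:
    """Read a protein x sample intensity matrix (empty cell = missing)."""
    path = Path(path)
    _check_rectangular(path)
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "protein_id"
    dup = matrix.index[matrix.index.duplicated()].unique().tolist()
    if dup:
        raise ParseError(f"{path}: duplicate protein accessions {dup}")
    if matrix.columns.duplicated().any():
        dup_s = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dup_s}")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=np.inf) < 0:
        bad = matrix.index[(matrix < 0).any(axis=1)].tolist()
        raise ParseError(f"{path}: negative intensities for {bad}")
    return matrix.astype(float)


def write_intensity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label="protein_id")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "subject_id", "group", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ParseError(f"{path}: group must be case/control, got {sorted(bad)}")
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_chromatograms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "peptide_id", "transition_id", "rt_min", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: chromatogram table missing columns {sorted(missing)}")
    return df


def write_chromatograms(chroms: pd.DataFrame, path) -> None:
    chroms.to_csv(path, sep="\t", index=False)


def write_prm_design(design: PrmDesign, path) -> None:
    rows = [
        {
            "protein_id": t.protein_id,
            "gene": t.gene,
            "peptide_id": t.peptide_id,
            "is_irt": int(t.is_irt),
            "is_reference": int(t.is_reference),
            "transition_ids": ";".join(t.transitions),
            "expected_rt_min": t.expected_rt_min,
        }
        for t in design.targets
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_prm_design(
    path,
    reference_protein: str | None = None,
    rt_grid=None,
    peak_sigma: float = 0.05,
) -> PrmDesign:
    df = pd.read_csv(path, sep="\t")
    targets = tuple(
        PeptideTarget(
            protein_id=str(r.protein_id),
            gene=str(r.gene),
            peptide_id=str(r.peptide_id),
            is_irt=bool(int(r.is_irt)),
            is_reference=bool(int(r.is_reference)),
            transitions=tuple(str(r.transition_ids).split(";")),
            expected_rt_min=float(r.expected_rt_min),
        )
        for r in df.itertuples()
    )
    if reference_protein is None:
        refs = [t.protein_id for t in targets if t.is_reference]
        reference_protein = refs[0] if refs else ""
    kwargs = {"targets": targets, "reference_protein": reference_protein,
              "peak_sigma": peak_sigma}
    if rt_grid is not None:
        kwargs["rt_grid"] = tuple(rt_grid)
    return PrmDesign(**kwargs)


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return GroundTruth(**data)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a YAML mapping")
    return data


def cohort_config_from_dict(data: dict) -> CohortConfig:
    fields = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ParseError(f"unknown cohort config fields {sorted(unknown)}")
    if "de_log2fc_range" in data:
        data = dict(data)
        data["de_log2fc_range"] = tuple(data["de_log2fc_range"])
    return CohortConfig(**data)
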