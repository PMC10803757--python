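"""Readers and writers for the pipeline's plain-text formats.

Beta and detection-p matrices are TSV with a ``probe_id`` column and one
column per sample; sample sheets and annotations are CSV; ground truth is
JSON.  Values round-trip exactly (floats are written with 17 significant
digits, enough to reconstruct the double bit-for-bit).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import pandas as pd

from .synthetic import GroundTruth


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("probe_id").to_csv(path, sep="\t", float_format="%.17g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id",
                       float_precision="round_trip")


def write_sample_sheet(cohort: pd.DataFrame, path) -> None:
    cohort.rename_axis("sample_id").to_csv(path, float_format="%.17g")


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id", float_precision="round_trip")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis("probe_id").to_csv(path)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col="probe_id", dtype={"chromosome": str})
    for col in ("snp_proximal", "cross_reactive"):
        ann[col] = ann[col].astype(bool)
    return ann


def write_ground_truth(ground_truth: GroundTruth, path) -> None:
    payload = {
        "true_ga": ground_truth.true_ga.to_dict(),
        "true_cell_fractions": {
            s: row.to_dict() for s, row in ground_truth.true_cell_fractions.iterrows()
        },
        "true_group_effect": ground_truth.true_group_effect,
        "true_es_shift": ground_truth.true_es_shift,
        "true_bdnf_params": list(ground_truth.true_bdnf_params),
    }
    pathlib.Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(pathlib.Path(path).read_text())
    fractions = pd.DataFrame.from_dict(payload["true_cell_fractions"], orient="index")
    return GroundTruth(
        true_ga=pd.Series(payload["true_ga"], name="true_ga"),
        true_cell_fractions=fractions,
        true_group_effect=payload["true_group_effect"],
        true_es_shift=payload["true_es_shift"],
        true_bdnf_params=tuple(payload["true_bdnf_params"]),
    )


def write_json(obj, path) -> None:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if hasattr(o, "item"):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    pathlib.Path(path).write_text(json.dumps(obj, indent=2, default=default))
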