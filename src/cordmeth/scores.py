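"""Epigenetic scores (ES) from EWAS-derived CpG coefficient sets.

An ES summarizes, per sample, how far its methylation at a panel of
phenotype-associated CpGs deviates from the source EWAS effect sizes, in
the disease-associated direction.  Each CpG carries a reference coefficient
c_i and a direction flag; weights normalize the coefficients by their panel
mean; the raw score is the weighted directional sum

    raw(s) = sum_{i hyper} (beta(i,s) - c_i) w_i
           + sum_{i hypo } (c_i - beta(i,s)) w_i

and scores are Z-transformed over the pooled cohort so both exposure groups
share one scale.
"""

from __future__ import annotations

import dataclasses
import logging
import pathlib

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRINGENCY_THRESHOLD = 1e-5


@dataclasses.dataclass
class ESModel:
    """A phenotype's CpG panel: reference coefficients, directions, source p.

    ``probes`` has the probe id on the index and columns ``coefficient``
    (EWAS effect size on the beta scale), ``direction`` ("hyper" —
    increased methylation disease-associated — or "hypo"), and optionally
    ``p_value`` (source EWAS p).  ``weights`` is populated by
    :func:`compute_weights`.
    """

    phenotype: str
    probes: pd.DataFrame
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.probes.empty:
            raise ValueError(f"ES model {self.phenotype!r} has no probes")
        if self.probes.index.has_duplicates:
            raise ValueError(f"duplicate probe ids in ES model {self.phenotype!r}")
        bad = set(self.probes["direction"]) - {"hyper", "hypo"}
        if bad:
            raise ValueError(f"unknown directions {bad} in ES model {self.phenotype!r}")


def compute_weights(es_model: ESModel, mode: str = "absolute") -> pd.Series:
    """Per-probe weights: coefficient over panel-mean coefficient.

    ``"absolute"`` (default) uses magnitudes, w_i = |c_i| / mean_j |c_j|,
    with the disease direction carried entirely by the hyper/hypo flag —
    a signed mean near zero (mixed-direction panels) would otherwise blow
    the weights up.  ``"signed"`` is the literal reading,
    w_i = c_i / mean_j c_j, and errors when |mean c| < 1e-12.
    The weights average to 1 in the applicable mode.
    """
    c = es_model.probes["coefficient"].astype(float)
    if mode == "absolute":
        denom = c.abs().mean()
        if denom <= 1e-12:
            raise ValueError("all coefficients are (numerically) zero")
        weights = c.abs() / denom
    elif mode == "signed":
        denom = c.mean()
        if abs(denom) < 1e-12:
            raise ValueError(
                "signed weight mode is unstable: panel mean coefficient is "
                f"{denom:.3e}; use absolute mode for mixed-direction panels"
            )
        weights = c / denom
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    weights.name = "weight"
    es_model.weights = weights
    return weights


def score_samples(
    beta: pd.DataFrame,
    es_model: ESModel,
    missing_policy: str = "drop",
) -> pd.Series:
    """Raw ES per sample: weighted directional deviations, summed over CpGs.

    Missing panel probes are dropped with a warning (default) or cohort-mean
    imputed (``"impute"``); ``"strict"`` raises on any gap.
    """
    if missing_policy not in ("drop", "impute", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if es_model.weights is None:
        compute_weights(es_model)

    present = es_model.probes.index.intersection(beta.index)
    absent = es_model.probes.index.difference(beta.index)
    if missing_policy == "strict" and len(absent) > 0:
        raise ValueError(
            f"ES {es_model.phenotype!r}: {len(absent)} panel probes absent"
        )
    if len(present) == 0:
        raise ValueError(f"no probes of ES {es_model.phenotype!r} present in beta matrix")
    if len(absent) > 0:
        logger.warning(
            "ES %s: %d of %d panel probes absent (%s policy)",
            es_model.phenotype, len(absent), len(es_model.probes), missing_policy,
        )

    sub = beta.loc[present].astype(float)
    if sub.isna().any().any():
        if missing_policy == "impute":
            sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            sub = sub.dropna()
            present = sub.index

    c = es_model.probes.loc[present, "coefficient"].astype(float)
    w = es_model.weights.loc[present]
    sign = np.where(es_model.probes.loc[present, "direction"] == "hyper", 1.0, -1.0)
    contrib = (sub.sub(c, axis=0)).mul(w * sign, axis=0)
    raw = contrib.sum(axis=0)
    raw.name = f"es_{es_model.phenotype}"
    return raw


def z_transform(raw_scores: pd.Series) -> pd.Series:
    """Z-score over the pooled cohort (sample sd, n-1 denominator)."""
    if len(raw_scores) < 2:
        raise ValueError("z transform needs >= 2 samples")
    sd = float(raw_scores.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in raw scores; z transform undefined")
    z = (raw_scores - raw_scores.mean()) / sd
    z.name = raw_scores.name
    return z


def filter_by_stringency(
    es_probes: pd.DataFrame, threshold: float = STRINGENCY_THRESHOLD
) -> pd.DataFrame:
    """Keep probes whose source EWAS p-value is at least as stringent as
    ``threshold`` (inclusive: p <= threshold)."""
    if "p_value" not in es_probes.columns:
        return es_probes
    return es_probes.loc[es_probes["p_value"] <= threshold]


def read_es_csv(path: str | pathlib.Path) -> dict[str, ESModel]:
    """ES definition CSV (columns probe_id, coefficient, direction, p_value,
    phenotype); one file may carry several phenotypes."""
    table = pd.read_csv(path)
    required = {"probe_id", "coefficient", "direction", "phenotype"}
    if not required <= set(table.columns):
        raise ValueError(f"ES CSV needs columns {sorted(required)}")
    models = {}
    for phenotype, grp in table.groupby("phenotype", sort=False):
        models[str(phenotype)] = ESModel(
            phenotype=str(phenotype), probes=grp.set_index("probe_id").drop(columns="phenotype")
        )
    return models


def write_es_csv(models: dict[str, ESModel], path: str | pathlib.Path) -> None:
    frames = []
    for model in models.values():
        frame = model.probes.rename_axis("probe_id").reset_index()
        frame["phenotype"] = model.phenotype
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
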