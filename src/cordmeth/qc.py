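"""Probe-level quality filtering and between-sample normalization of beta values.

A beta matrix is a pandas DataFrame of methylation fractions in [0, 1] with
probe ids on the index and sample ids on the columns.  Filtering removes
probes on the sex chromosomes, probes near SNPs, cross-reactive probes, and
probes whose detection p-value fails in one or more samples; normalization is
full-quantile normalization onto the mean quantile curve.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

SEX_CHROMOSOMES = {"x", "y", "chrx", "chry"}


@dataclasses.dataclass
class FilterReport:
    """Counts of probes removed per criterion and retained overall."""

    n_input: int
    n_sex_chromosome: int
    n_snp_proximal: int
    n_cross_reactive: int
    n_detection_failed: int
    n_removed: int
    n_retained: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _is_sex_chromosome(chrom: pd.Series) -> pd.Series:
    return chrom.astype(str).str.strip().str.lower().isin(SEX_CHROMOSOMES)


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    fail_when: str = "ge",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove low-quality probes; samples are never touched.

    Parameters
    ----------
    beta
        Probes x samples beta matrix.
    annotation
        One row per probe (index = probe id) with columns ``chromosome``,
        ``snp_proximal`` and ``cross_reactive``; must cover every probe in
        ``beta``.
    detection_p
        Optional probe x sample detection p-values, same shape as ``beta``.
        A probe is dropped if it fails detection in one or more samples.
    p_threshold
        Detection threshold, default 0.05.
    fail_when
        ``"ge"`` (default, standard convention): a probe fails in a sample
        when detection p >= threshold.  ``"lt"`` inverts the comparison for
        pipelines whose detection statistic is oriented the other way.

    Returns
    -------
    (filtered beta, FilterReport)
    """
    missing = beta.index.difference(annotation.index)
    if len(missing) > 0:
        raise ValueError(
            "probes missing from annotation: " + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    if fail_when not in ("ge", "lt"):
        raise ValueError(f"fail_when must be 'ge' or 'lt', got {fail_when!r}")

    ann = annotation.loc[beta.index]
    sex = _is_sex_chromosome(ann["chromosome"])
    snp = ann["snp_proximal"].astype(bool)
    cross = ann["cross_reactive"].astype(bool)

    if detection_p is not None:
        dp = detection_p.loc[beta.index, beta.columns]
        failed_any = (
            (dp.values >= p_threshold) if fail_when == "ge" else (dp.values < p_threshold)
        ).any(axis=1)
        det = pd.Series(failed_any, index=beta.index)
    else:
        det = pd.Series(False, index=beta.index)

    drop = sex | snp | cross | det
    kept = beta.loc[~drop]
    report = FilterReport(
        n_input=beta.shape[0],
        n_sex_chromosome=int(sex.sum()),
        n_snp_proximal=int(snp.sum()),
        n_cross_reactive=int(cross.sum()),
        n_detection_failed=int(det.sum()),
        n_removed=int(drop.sum()),
        n_retained=kept.shape[0],
    )
    return kept, report


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Full-quantile normalization onto the mean quantile curve.

    Every sample column is mapped onto the identical sorted value multiset
    (the across-sample mean of order statistics); within-column rank order is
    preserved, and ties receive the mean of the reference values at the tied
    positions (midrank rule).
    """
    if beta.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    if beta.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix; "
                         "impute or drop missing values first")

    values = beta.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        normalized = np.empty_like(col)
        normalized[order] = reference
        # midrank tie rule: tied input values share the mean reference value
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(order, boundaries)
        for grp in groups:
            if len(grp) > 1:
                normalized[grp] = normalized[grp].mean()
        out[:, j] = normalized
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)
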