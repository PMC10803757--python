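"""Linear epigenetic-clock prediction and gestational-age acceleration.

A pediatric epigenetic clock is an affine map from CpG beta values to a
DNA-methylation gestational age (DNAmGA):

    DNAmGA(s) = intercept + sum_i w_i * beta(i, s)

Acceleration is the residual of an ordinary least-squares regression of
DNAmGA on chronological gestational age, fit on the pooled cohort so that a
group contrast in DNAmGA survives into the residuals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERCEPT_ROW = "(Intercept)"


@dataclasses.dataclass
class ClockModel:
    """Intercept plus per-CpG linear coefficients.

    ``output_units`` is ``"weeks"`` or ``"days"``; clocks that natively
    predict days are converted to weeks at prediction time so all
    downstream quantities share one unit.
    """

    name: str
    intercept: float
    coefficients: pd.Series  # index: probe ids, values: weights
    output_units: str = "weeks"

    def __post_init__(self) -> None:
        if self.output_units not in ("weeks", "days"):
            raise ValueError(f"unknown output_units {self.output_units!r}")
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate probe ids in clock coefficients")

    @property
    def probe_ids(self) -> pd.Index:
        return self.coefficients.index


@dataclasses.dataclass
class ClockCoverage:
    """Which clock probes the beta matrix covered, and how gaps were handled."""

    clock_name: str
    n_clock_probes: int
    n_present: int
    missing_probes: list[str]
    n_imputed: int
    n_dropped: int


def predict_dnam_age(
    beta: pd.DataFrame,
    clock: ClockModel,
    missing_policy: str = "impute",
) -> tuple[pd.Series, ClockCoverage]:
    """Apply the clock's linear predictor to every sample.

    ``missing_policy`` handles clock probes absent from ``beta``:

    - ``"impute"`` (default): a probe present in at least one sample but
      missing values is filled with the cohort mean; probes entirely absent
      from the matrix are dropped from the sum with a warning.
    - ``"strict"``: any absent probe raises.

    Returns the per-sample DNAmGA in weeks and a coverage report.
    """
    if missing_policy not in ("impute", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    present = clock.probe_ids.intersection(beta.index)
    absent = clock.probe_ids.difference(beta.index)
    if len(present) == 0:
        raise ValueError(f"no probes of clock {clock.name!r} present in beta matrix")
    if missing_policy == "strict" and len(absent) > 0:
        raise ValueError(
            f"clock {clock.name!r}: {len(absent)} probes absent under strict policy: "
            + ", ".join(map(str, absent[:10]))
        )

    sub = beta.loc[present].astype(float)
    n_imputed = 0
    if sub.isna().any().any():
        row_means = sub.mean(axis=1)
        if row_means.isna().any():
            all_nan = row_means.index[row_means.isna()]
            sub = sub.drop(index=all_nan)
            absent = absent.append(pd.Index(all_nan))
            present = sub.index
            if len(present) == 0:
                raise ValueError(f"no usable probes for clock {clock.name!r}")
        n_imputed = int(sub.isna().sum().sum())
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)

    if len(absent) > 0:
        logger.warning(
            "clock %s: %d of %d probes absent; dropped from the linear predictor",
            clock.name, len(absent), len(clock.probe_ids),
        )

    weights = clock.coefficients.loc[present]
    dnam = clock.intercept + sub.T.to_numpy() @ weights.to_numpy()
    if clock.output_units == "days":
        dnam = dnam / 7.0
    coverage = ClockCoverage(
        clock_name=clock.name,
        n_clock_probes=len(clock.probe_ids),
        n_present=len(present),
        missing_probes=[str(p) for p in absent],
        n_imputed=n_imputed,
        n_dropped=len(absent),
    )
    return pd.Series(dnam, index=beta.columns, name=f"dnam_ga_{clock.name}"), coverage


def compute_acceleration(dnam_ga: pd.Series, chronological_ga: pd.Series) -> pd.Series:
    """Residuals of OLS of DNAmGA on chronological GA, pooled over the cohort.

    Residuals sum to zero and are uncorrelated with chronological GA by
    construction; negative residuals are epigenetic deceleration.
    """
    ga = chronological_ga.loc[dnam_ga.index].astype(float)
    y = dnam_ga.astype(float)
    if len(y) < 3:
        raise ValueError("acceleration requires >= 3 samples")
    if float(np.var(ga.to_numpy())) == 0.0:
        raise ValueError("chronological GA is constant; regression slope unidentifiable")
    x = ga.to_numpy()
    slope, intercept = np.polyfit(x, y.to_numpy(), 1)
    resid = y.to_numpy() - (intercept + slope * x)
    return pd.Series(resid, index=dnam_ga.index, name="acceleration")


def clock_overlap(clock_a: ClockModel, clock_b: ClockModel) -> int:
    """Number of CpG probes shared by two clocks (intercepts excluded)."""
    return len(set(clock_a.probe_ids) & set(clock_b.probe_ids))


def read_clock_csv(path: str | pathlib.Path) -> ClockModel:
    """Load a clock from CSV (columns ``probe_id``, ``coefficient``; one
    reserved ``(Intercept)`` row) with an optional JSON sidecar carrying
    ``name`` and ``output_units``."""
    path = pathlib.Path(path)
    table = pd.read_csv(path)
    if not {"probe_id", "coefficient"} <= set(table.columns):
        raise ValueError(f"{path}: clock CSV needs columns probe_id, coefficient")
    is_int = table["probe_id"] == INTERCEPT_ROW
    if is_int.sum() != 1:
        raise ValueError(f"{path}: expected exactly one {INTERCEPT_ROW} row")
    intercept = float(table.loc[is_int, "coefficient"].iloc[0])
    coef = table.loc[~is_int].set_index("probe_id")["coefficient"].astype(float)

    name, units = path.stem, "weeks"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        name = meta.get("name", name)
        units = meta.get("output_units", units)
    return ClockModel(name=name, intercept=intercept, coefficients=coef, output_units=units)


def write_clock_csv(clock: ClockModel, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    rows = pd.DataFrame(
        {
            "probe_id": [INTERCEPT_ROW, *clock.coefficients.index],
            "coefficient": [clock.intercept, *clock.coefficients.to_numpy()],
        }
    )
    rows.to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps({"name": clock.name, "output_units": clock.output_units}, indent=2)
    )
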