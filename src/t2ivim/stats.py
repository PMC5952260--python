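"""Summary statistics: TE-dependence tables, percent bias of f, cohort
summaries, and repeated-measures coefficient of variation.

The repeatability CoV is the geometric form for paired repeats: all values
are natural-log transformed, the within-subject variance sigma_w^2 is the
mean over subjects of the per-subject sample variance of the log values,
and CoV(%) = 100 * sqrt(exp(sigma_w^2) - 1).  This estimator is invariant
to rescaling any subject's values by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitError, SignalSeries, fit_ivim, fit_t2ivim

__all__ = [
    "CohortSummary",
    "percent_error_f",
    "cohort_summary",
    "cov_repeated",
    "read_repeatability_csv",
    "te_dependence_table",
]


@dataclass(frozen=True)
class CohortSummary:
    parameter: str
    mean: float
    sd: float
    n: int


def percent_error_f(f_apparent: float, f_reference: float) -> float:
    """Percent overestimation of an apparent fraction over a reference.

    Returns 100 * (f_apparent - f_reference) / f_reference.
    """
    if not f_reference > 0:
        raise ValueError("f_reference must be positive")
    return 100.0 * (f_apparent - f_reference) / f_reference


def cohort_summary(values, parameter: str = "") -> CohortSummary:
    """Arithmetic mean and sample (n-1) standard deviation of estimates."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("cohort_summary requires at least 2 values")
    return CohortSummary(
        parameter=parameter,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=int(arr.size),
    )


def cov_repeated(table: pd.DataFrame | dict) -> float:
    """Repeated-measures CoV (%) on log-transformed values.

    ``table`` maps subjects to their repeated estimates: either a dict
    ``{subject: [visit values]}`` or a DataFrame with columns ``subject``
    and ``value``.  Every subject needs the same number (>= 2) of visits
    and strictly positive values.
    """
    if isinstance(table, pd.DataFrame):
        groups = {
            subj: grp["value"].to_numpy(dtype=float)
            for subj, grp in table.groupby("subject")
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in table.items()}
    if not groups:
        raise ValueError("empty repeatability table")
    counts = {len(v) for v in groups.values()}
    if len(counts) != 1 or counts.pop() < 2:
        raise ValueError(
            "every subject needs the same number of visits (>= 2)"
        )
    allvals = np.concatenate(list(groups.values()))
    if np.any(allvals <= 0):
        raise ValueError("values must be positive for the log transform")
    within = np.mean(
        [np.var(np.log(v), ddof=1) for v in groups.values()]
    )
    return float(100.0 * np.sqrt(np.expm1(within)))


def read_repeatability_csv(path, parameter: str) -> pd.DataFrame:
    """Load a long-format repeatability CSV (subject, visit, parameter,
    value) and return the rows for one parameter."""
    df = pd.read_csv(path)
    for col in ("subject", "visit", "parameter", "value"):
        if col not in df.columns:
            raise ValueError(f"repeatability CSV missing column '{col}'")
    return df[df["parameter"] == parameter].reset_index(drop=True)


def te_dependence_table(
    series: SignalSeries,
    config: FitConfig | None = None,
) -> pd.DataFrame:
    """Single-TE IVIM f per TE, the all-data T2-IVIM f, and the percent
    bias of the minimum-TE IVIM fit.

    Rows: one per TE (descending, longest TE first), then ``T2-IVIM``,
    then ``% error at TE=<min>``.  A TE whose single-TE fit fails yields a
    NaN cell rather than aborting the table.
    """
    config = config or FitConfig()
    tes = series.scheme.unique_TEs()
    if len(tes) < 2:
        raise FitError("te_dependence_table requires >= 2 distinct TEs")

    rows: list[tuple[str, float]] = []
    f_by_te: dict[float, float] = {}
    for te in sorted(tes, reverse=True):
        try:
            fit = fit_ivim(series.at_TE(te), config)
            f_by_te[te] = fit.params.f
        except FitError:
            f_by_te[te] = np.nan
        rows.append((f"{te:g}", f_by_te[te]))

    try:
        f_t2 = fit_t2ivim(series, config).params.f
    except FitError:
        f_t2 = np.nan
    rows.append(("T2-IVIM", f_t2))

    te_min = float(tes.min())
    f_min = f_by_te[te_min]
    if np.isnan(f_min) or np.isnan(f_t2) or f_t2 <= 0:
        err = np.nan
    else:
        err = percent_error_f(f_min, f_t2)
    rows.append((f"% error at TE={te_min:g}", err))

    return pd.DataFrame(rows, columns=["TE (ms)", "f"]).set_index("TE (ms)")
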