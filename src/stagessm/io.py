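"""Plain-text readers and writers for observations, covariates and results.

Formats (comma-separated, dot decimal):

* observations: columns ``cohort, stage, survey, index, sd_log`` — one row
  per observed survey index.  Cohorts are 1-based; cohort 0 is reserved for
  the initial adult-abundance observation (stage n).  Absent rows mean
  missing observations.
* covariates: long format ``cohort, vital_rate, covariate, value`` with
  vital_rate in {R, S1, S2, ...}; intercept columns are implied and
  prepended on read.
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .types import CovariateSet, Dataset, default_survey_labels

__all__ = [
    "write_observations",
    "read_observations",
    "write_covariates",
    "read_covariates",
    "read_dataset",
    "write_fit_summary",
]

_OBS_COLS = ["cohort", "stage", "survey", "index", "sd_log"]


def write_observations(data: Dataset, path) -> None:
    """Write a dataset's observed indices (and Y_init as cohort 0)."""
    rows = []
    if data.Y_init is not None:
        rows.append(
            dict(cohort=0, stage=data.n_stages,
                 survey=data.survey_of_stage[-1],
                 index=data.Y_init, sd_log=data.sigma_o_init)
        )
    ii, tt = np.nonzero(data.mask)
    for i, t in zip(ii, tt):
        rows.append(
            dict(cohort=int(t) + 1, stage=int(i) + 1,
                 survey=data.survey_of_stage[i],
                 index=data.Y[i, t], sd_log=data.sigma_o[i, t])
        )
    pd.DataFrame(rows, columns=_OBS_COLS).to_csv(path, index=False,
                                                 float_format="%.12g")


def read_observations(path):
    """Parse an observation table; returns the pieces of a Dataset.

    Returns ``(Y, sigma_o, Y_init, sigma_o_init, survey_of_stage)``; combine
    with covariates via :func:`read_dataset`.  Rows with nonpositive index
    or sd_log raise with their line number.
    """
    df = pd.read_csv(path)
    missing = set(_OBS_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for row_ix, row in df.iterrows():
        line = row_ix + 2  # header is line 1
        if row["index"] <= 0:
            raise ValueError(f"{path}:{line}: nonpositive index value")
        if row["sd_log"] <= 0:
            raise ValueError(f"{path}:{line}: nonpositive sd_log")
        if row["cohort"] < 0 or row["stage"] < 1:
            raise ValueError(f"{path}:{line}: bad cohort/stage")
    n = int(df["stage"].max())
    T = int(df["cohort"].max())
    Y = np.full((n, T), np.nan)
    sigma_o = np.full((n, T), np.nan)
    survey_of_stage = default_survey_labels(n)
    Y_init = None
    sd_init = None
    for row_ix, row in df.iterrows():
        i = int(row["stage"]) - 1
        t = int(row["cohort"])
        survey_of_stage[i] = str(row["survey"])
        if t == 0:
            if i != n - 1:
                raise ValueError(
                    f"{path}:{row_ix + 2}: cohort 0 must be stage {n}"
                )
            Y_init = float(row["index"])
            sd_init = float(row["sd_log"])
        else:
            Y[i, t - 1] = float(row["index"])
            sigma_o[i, t - 1] = float(row["sd_log"])
    # unobserved cells keep a placeholder SD (never used by the likelihood)
    sigma_o[~np.isfinite(sigma_o)] = 1.0
    return Y, sigma_o, Y_init, sd_init, survey_of_stage


def write_covariates(cov: CovariateSet, path) -> None:
    """Write design matrices (excluding intercepts) in long format."""
    rows = []
    T = cov.T
    mats = [("R", cov.w_R)] + [
        (f"S{i}", w) for i, w in enumerate(cov.w_S, start=1)
    ]
    for rate, w in mats:
        for j in range(1, w.shape[1]):
            for t in range(T):
                rows.append(
                    dict(cohort=t + 1, vital_rate=rate, covariate=f"x{j}",
                         value=w[t, j])
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_covariates(path) -> CovariateSet:
    """Assemble design matrices from the long covariate format.

    Rows may arrive in any order; a missing cohort-by-covariate cell is an
    error (no imputation).
    """
    df = pd.read_csv(path)
    need = {"cohort", "vital_rate", "covariate", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    T = int(df["cohort"].max())
    rates = sorted(df["vital_rate"].unique(),
                   key=lambda r: (-1 if r == "R" else int(r[1:])))
    mats = {}
    for rate, sub in df.groupby("vital_rate"):
        piv = sub.pivot_table(index="cohort", columns="covariate",
                              values="value", aggfunc="first")
        piv = piv.reindex(index=np.arange(1, T + 1))
        if piv.isna().any().any():
            bad = piv[piv.isna().any(axis=1)].index.tolist()
            raise ValueError(
                f"{path}: vital rate {rate}: missing covariate values for "
                f"cohorts {bad}"
            )
        mats[rate] = np.column_stack(
            [np.ones(T), piv[sorted(piv.columns)].to_numpy()]
        )
    if "R" not in mats:
        raise ValueError(f"{path}: no recruitment (R) covariates found")
    s_rates = sorted((r for r in mats if r != "R"), key=lambda r: int(r[1:]))
    return CovariateSet(mats["R"], [mats[r] for r in s_rates])


def read_dataset(obs_path, cov_path) -> Dataset:
    """Read observations and covariates into a Dataset."""
    Y, sigma_o, Y_init, sd_init, survey_of_stage = read_observations(obs_path)
    cov = read_covariates(cov_path)
    if cov.T < Y.shape[1]:
        raise ValueError("covariate table covers fewer cohorts than data")
    return Dataset(
        Y=Y, sigma_o=sigma_o, covariates=cov, Y_init=Y_init,
        sigma_o_init=sd_init, survey_of_stage=survey_of_stage,
    )


def write_fit_summary(fit, tab_path, json_path=None) -> None:
    """Write a fit as a parameter table and an optional JSON summary."""
    import json

    from .laplace import aicc

    df = fit.summary()
    fixed_rows = [
        dict(parameter=f"psi_{s} (fixed)", estimate=v, se=np.nan)
        for s, v in fit.theta_hat.psi_fixed.items()
    ]
    if fixed_rows:
        df = pd.concat([df, pd.DataFrame(fixed_rows)], ignore_index=True)
    df.to_csv(tab_path, index=False, float_format="%.8g")
    if json_path is not None:
        try:
            ic = aicc(fit)
        except ValueError:
            ic = None
        payload = dict(
            loglik=fit.loglik,
            k=fit.k,
            n_obs=fit.n_obs,
            aicc=ic,
            converged=bool(fit.converged),
            hessian_pd=bool(fit.hessian_pd),
        )
        Path(json_path).write_text(json.dumps(payload, indent=2))
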