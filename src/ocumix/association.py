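"""Education–biometry association models with robust inference.

The study design measures two eyes per person; analyses either collapse to
person means or keep per-eye rows with cluster-robust (sandwich) standard
errors over persons — operationally equivalent to the GEE-with-working-
independence fits common in ophthalmic epidemiology.  Confidence intervals
are normal-based (estimate ± 1.96·SE) and p-values two-sided normal.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort_io import FilterSpec, apply_filters, person_eye_means

Z95 = norm.ppf(0.975)

#: Table-2-style outcome set
DEFAULT_OUTCOMES = ("se", "al", "cc", "acd", "lt")

SEX_CODES = {"female": 0.0, "male": 1.0}


def _encode(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    out = table[list(cols)].copy()
    if "sex" in out.columns:
        out["sex"] = out["sex"].map(SEX_CODES)
        if out["sex"].isna().any() and table["sex"].notna().any():
            bad = table.loc[out["sex"].isna() & table["sex"].notna(), "sex"].unique()
            raise ValueError(f"unknown sex categories: {list(bad)}")
    return out.astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name the offending columns via near-zero diagonal of R in a QR
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        scale = diag.max() if diag.max() > 0 else 1.0
        collinear = [c for c, d in zip(X.columns, diag) if d < 1e-10 * scale]
        raise ValueError(f"rank-deficient design; collinear term(s): {collinear or list(X.columns)}")


def linear_assoc(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    cluster: str | None = None,
) -> pd.DataFrame:
    """Linear model of ``outcome`` on ``exposure`` + ``covariates``.

    Standard errors are heteroskedasticity-robust (HC1), or cluster-robust
    over ``cluster`` (e.g. ``person_id`` for per-eye rows).  Complete-case
    analysis; returns one row per term with
    ``estimate, se, ci_low, ci_high, p, n``.
    """
    terms = [exposure, *covariates]
    needed = [outcome, *terms] + ([cluster] if cluster else [])
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing column(s): {missing_cols}")
    data = table[needed].dropna()
    if data[outcome].count() == 0:
        raise ValueError(f"outcome {outcome!r} has no observed values")
    n = len(data)
    if n < 10 + len(terms):
        raise ValueError(f"only {n} complete cases for {outcome} ~ {terms}; need >= {10 + len(terms)}")

    X = _encode(data, terms)
    X.insert(0, "const", 1.0)
    _check_rank(X)
    y = pd.to_numeric(data[outcome]).to_numpy(float)

    model = sm.OLS(y, X)
    if cluster:
        fit = model.fit(
            cov_type="cluster", cov_kwds={"groups": data[cluster]}, use_t=False
        )
    else:
        fit = model.fit(cov_type="HC1", use_t=False)

    est, se = fit.params, fit.bse
    z = np.divide(est, se, out=np.zeros_like(est), where=se > 0)
    p = np.where(se > 0, 2 * norm.sf(np.abs(z)), np.where(est == 0, 1.0, 0.0))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": est.to_numpy(),
            "se": se.to_numpy(),
            "ci_low": est.to_numpy() - Z95 * se.to_numpy(),
            "ci_high": est.to_numpy() + Z95 * se.to_numpy(),
            "p": p,
            "n": n,
        }
    ).set_index("term")


def _prepare_person_level(table: pd.DataFrame) -> pd.DataFrame:
    if table["person_id"].duplicated().any():
        return person_eye_means(table)
    return table


def education_biometry_table(
    table: pd.DataFrame,
    grs: pd.DataFrame | None = None,
    filters: FilterSpec | None = None,
    *,
    stratify_by_sex: bool = False,
    sensitivity: dict[str, FilterSpec] | None = None,
    outcomes: Sequence[str] = DEFAULT_OUTCOMES,
    exposure: str = "education_years",
) -> pd.DataFrame:
    """Adjusted education coefficients for each biometric outcome.

    Runs :func:`linear_assoc` on person means, adjusted for age, sex and
    (when ``grs`` is given) the standardized myopia GRS, optionally per
    sex stratum and under named sensitivity filter specs.  Returns a long
    table with columns ``analysis, stratum, outcome, estimate, se,
    ci_low, ci_high, p, n``.
    """
    rows = []

    def run(label: str, spec: FilterSpec | None) -> None:
        data = table
        if spec is not None:
            data, _ = apply_filters(data, spec)
        data = _prepare_person_level(data)
        if grs is not None:
            data = data.merge(
                grs[["person_id", "z"]].rename(columns={"z": "myopia_grs"}),
                on="person_id", how="left",
            )
            covariates = ["age", "sex", "myopia_grs"]
        else:
            covariates = ["age", "sex"]

        strata: list[tuple[str, pd.DataFrame]] = [("all", data)]
        if stratify_by_sex:
            strata += [(s, data[data["sex"] == s]) for s in ("female", "male")]
        for stratum, sub in strata:
            covs = [c for c in covariates if c != "sex"] if stratum != "all" else covariates
            for outcome in outcomes:
                res = linear_assoc(sub, outcome, exposure, covs).loc[exposure]
                rows.append(
                    {"analysis": label, "stratum": stratum, "outcome": outcome, **res.to_dict()}
                )

    run("main", filters)
    for name, spec in (sensitivity or {}).items():
        run(name, spec)
    out = pd.DataFrame(rows)
    out["n"] = out["n"].astype(int)
    return out
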