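"""One-sample summary-statistic Mendelian randomization.

Genetic variants serve as instruments: per variant j, the associations of
allele dosage with the exposure (β_xj) and with the outcome (β_yj) are
estimated in the same cohort, and the causal effect of exposure on outcome
is combined across variants by four estimators —

* **IVW** — inverse-variance weighted regression of β_y on β_x through the
  origin, weights 1/se_y²; valid when every instrument is valid.
* **simple median** — median of the per-variant ratio estimates β_y/β_x.
* **weighted median** — weighted empirical median of the ratios with
  first-order weights β_x²/se_y²; consistent when ≥ 50% of the weight is
  on valid instruments.
* **MR-Egger** — weighted regression *with* an intercept; the intercept
  estimates average directional pleiotropy and its p-value is the
  pleiotropy test; SEs carry a multiplicative overdispersion factor.

Median-method standard errors come from a parametric bootstrap (β's
resampled from N(β̂, se), seed-reproducible).  Variants are oriented so
that β_x ≥ 0 (MR-Egger is orientation-sensitive; this makes its output
canonical and leaves IVW and the medians unchanged).
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .association import Z95, _encode

logger = logging.getLogger(__name__)

SNP_ASSOC_COLUMNS = ["variant_id", "beta_x", "se_x", "beta_y", "se_y", "eaf"]

#: the four bidirectional analyses: label -> (exposure, outcome, instrument score)
BIDIRECTIONAL_ANALYSES = {
    "education_on_se": ("education_years", "se", "education"),
    "se_on_education": ("se", "education_years", "myopia"),
    "education_on_al": ("education_years", "al", "education"),
    "al_on_education": ("al", "education_years", "axial_length"),
}


@dataclass
class MREstimate:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_variants: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def _wald(method: str, est: float, se: float, j: int, **extra) -> MREstimate:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = float(min(1.0, 2 * norm.sf(abs(z)))) if se > 0 else (1.0 if est == 0 else 0.0)
    return MREstimate(
        method=method, estimate=float(est), se=float(se),
        ci_low=float(est - Z95 * se), ci_high=float(est + Z95 * se),
        p=p, n_variants=j, **extra,
    )


def snp_associations(
    table: pd.DataFrame,
    dosages: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: Sequence[str] = ("age", "sex"),
    *,
    standardize_exposure: bool = True,
    variant_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-variant exposure and outcome associations in one cohort.

    For each variant, ``beta_x``/``se_x`` come from a linear model of the
    (optionally z-scored) exposure on dosage + covariates, and
    ``beta_y``/``se_y`` likewise for the outcome; computed for all
    variants at once by residualizing on the shared covariate design
    (Frisch–Waugh–Lovell).  Monomorphic variants are dropped; fewer than
    3 surviving variants is an error.
    """
    if variant_ids is None:
        variant_ids = [c for c in dosages.columns if c != "person_id"]
    else:
        variant_ids = [v for v in variant_ids if v in dosages.columns]
    if not variant_ids:
        raise ValueError("no instrument variants present in the dosage matrix")

    data = table.merge(dosages[["person_id", *variant_ids]], on="person_id", how="inner")
    data = data.dropna(subset=[exposure, outcome, *covariates]).reset_index(drop=True)
    n = len(data)
    if n < len(covariates) + 12:
        raise ValueError(f"too few complete cases (n={n}) for per-variant models")

    D = data[variant_ids].to_numpy(float)
    if np.isnan(D).any():
        col_means = np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D[idx] = col_means[idx[1]]

    x = data[exposure].to_numpy(float)
    if standardize_exposure:
        x = (x - x.mean()) / x.std(ddof=1)
    y = data[outcome].to_numpy(float)

    C = np.column_stack([np.ones(n), _encode(data, list(covariates)).to_numpy(float)]) \
        if covariates else np.ones((n, 1))
    p_cov = C.shape[1]
    # residualize everything on the covariate design
    coefD, *_ = np.linalg.lstsq(C, D, rcond=None)
    Rd = D - C @ coefD
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]

    ss_d = (Rd**2).sum(axis=0)
    poly = ss_d > 1e-12
    n_mono = int((~poly).sum())
    if n_mono:
        logger.warning("snp_associations: dropped %d monomorphic variant(s)", n_mono)
    if poly.sum() < 3:
        raise ValueError(f"only {int(poly.sum())} polymorphic instrument(s); need >= 3")
    Rd, ss_d = Rd[:, poly], ss_d[poly]
    kept = [v for v, keep in zip(variant_ids, poly) if keep]

    df = n - p_cov - 1
    bx = (Rd * rx[:, None]).sum(axis=0) / ss_d
    by = (Rd * ry[:, None]).sum(axis=0) / ss_d
    sx = np.sqrt(((rx[:, None] - bx[None, :] * Rd) ** 2).sum(axis=0) / df / ss_d)
    sy = np.sqrt(((ry[:, None] - by[None, :] * Rd) ** 2).sum(axis=0) / df / ss_d)
    eaf = data[kept].mean(axis=0).to_numpy(float) / 2.0

    flip = bx < 0
    bx, by = np.abs(bx), np.where(flip, -by, by)
    eaf = np.where(flip, 1.0 - eaf, eaf)

    out = pd.DataFrame(
        {"variant_id": kept, "beta_x": bx, "se_x": sx, "beta_y": by, "se_y": sy, "eaf": eaf}
    )
    out.attrs["n"] = n
    out.attrs["n_monomorphic_dropped"] = n_mono
    return out


def ivw(assocs: pd.DataFrame, *, random_effects: bool = False) -> MREstimate:
    """Inverse-variance weighted estimate: WLS of β_y on β_x through the origin."""
    bx, by, sy = (assocs[c].to_numpy(float) for c in ("beta_x", "beta_y", "se_y"))
    if len(bx) < 2:
        raise ValueError("IVW needs >= 2 variants")
    w = 1.0 / sy**2
    denom = (w * bx**2).sum()
    if denom == 0:
        raise ValueError("all instrument-exposure associations are zero")
    est = (w * bx * by).sum() / denom
    se = denom**-0.5
    if random_effects:
        rss = (w * (by - est * bx) ** 2).sum()
        se *= max(1.0, np.sqrt(rss / (len(bx) - 1)))
    return _wald("ivw", est, se, len(bx))


def _ratios(assocs: pd.DataFrame) -> pd.DataFrame:
    kept = assocs[assocs["beta_x"] != 0]
    n_dropped = len(assocs) - len(kept)
    if n_dropped:
        logger.warning("dropping %d variant(s) with beta_x = 0 from ratio estimators", n_dropped)
    return kept


def weighted_median_estimate(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted empirical median by linear interpolation at cumulative weight 0.5."""
    order = np.argsort(theta)
    t, w = theta[order], w[order] / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, t))


def _median_bootstrap(bx, sx, by, sy, weighted: bool, B: int, seed) -> float:
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(B, len(bx)))
    bys = rng.normal(by, sy, size=(B, len(by)))
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = bys / bxs
    out = np.empty(B)
    for b in range(B):
        t = thetas[b]
        ok = np.isfinite(t)
        if weighted:
            out[b] = weighted_median_estimate(t[ok], (bxs[b] ** 2 / sy**2)[ok])
        else:
            out[b] = np.median(t[ok])
    return float(out.std(ddof=1))


def simple_median(assocs: pd.DataFrame, B: int = 2000, seed: int | None = None) -> MREstimate:
    """Median of the per-variant ratio estimates; bootstrap SE."""
    a = _ratios(assocs)
    if len(a) < 3:
        raise ValueError("simple median needs >= 3 usable variants")
    bx, sx, by, sy = (a[c].to_numpy(float) for c in ("beta_x", "se_x", "beta_y", "se_y"))
    est = float(np.median(by / bx))
    se = _median_bootstrap(bx, sx, by, sy, weighted=False, B=B, seed=seed)
    return _wald("simple_median", est, se, len(a))


def weighted_median(assocs: pd.DataFrame, B: int = 2000, seed: int | None = None) -> MREstimate:
    """Weighted median of the ratio estimates, weights β_x²/se_y²; bootstrap SE."""
    a = _ratios(assocs)
    if len(a) < 3:
        raise ValueError("weighted median needs >= 3 usable variants")
    bx, sx, by, sy = (a[c].to_numpy(float) for c in ("beta_x", "se_x", "beta_y", "se_y"))
    est = weighted_median_estimate(by / bx, bx**2 / sy**2)
    se = _median_bootstrap(bx, sx, by, sy, weighted=True, B=B, seed=seed)
    return _wald("weighted_median", est, se, len(a))


def mr_egger(assocs: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of β_y on β_x with an intercept.

    The slope is the causal estimate; the intercept estimates average
    directional pleiotropy, its p-value being the pleiotropy test.  Both
    SEs are inflated by max(1, √(RSS_w/(J−2))).
    """
    bx, by, sy = (assocs[c].to_numpy(float) for c in ("beta_x", "beta_y", "se_y"))
    j = len(bx)
    if j < 3:
        raise ValueError("MR-Egger needs >= 3 variants")
    if np.any(bx < 0):
        raise ValueError("MR-Egger requires beta_x >= 0 orientation")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    A = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ coef
    rss_w = float((w * resid**2).sum())
    phi = max(1.0, rss_w / (j - 2))
    cov = phi * np.linalg.inv(A)
    inter, slope = coef
    se_inter, se_slope = np.sqrt(np.diag(cov))
    zi = inter / se_inter if se_inter > 0 else np.inf * np.sign(inter)
    pi = float(min(1.0, 2 * norm.sf(abs(zi)))) if se_inter > 0 else (1.0 if inter == 0 else 0.0)
    return _wald(
        "mr_egger", slope, se_slope, j,
        intercept=float(inter), intercept_se=float(se_inter), intercept_p=pi,
    )


def run_estimators(
    assocs: pd.DataFrame, *, B: int = 2000, seed: int | None = None
) -> pd.DataFrame:
    """All four estimators on one set of summary statistics, as a tidy table."""
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    results = [
        simple_median(assocs, B=B, seed=int(seeds[0])),
        weighted_median(assocs, B=B, seed=int(seeds[1])),
        ivw(assocs),
        mr_egger(assocs),
    ]
    return pd.DataFrame([r.__dict__ for r in results])


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read pre-computed per-variant summary statistics from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_ASSOC_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"summary-stats file lacks column(s): {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    return df[SNP_ASSOC_COLUMNS]


def bidirectional_mr(
    table: pd.DataFrame,
    dosages: pd.DataFrame,
    panels: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex"),
    *,
    B: int = 2000,
    seed: int | None = None,
    standardize_exposure: bool = True,
) -> pd.DataFrame:
    """The four bidirectional analyses (education ⇄ SE, education ⇄ AL).

    ``panels`` concatenates the instrument lists (column ``score_name`` in
    {"education", "myopia", "axial_length"}); each analysis uses the panel
    appropriate to its exposure and reports all four estimators plus the
    number of instruments actually used.  Returns a long Table-3-style
    report.
    """
    if "score_name" not in panels.columns:
        raise ValueError("panels must carry a score_name column")
    seeds = np.random.SeedSequence(seed).generate_state(len(BIDIRECTIONAL_ANALYSES)) % (2**31)
    frames = []
    for (label, (exposure, outcome, score)), s in zip(BIDIRECTIONAL_ANALYSES.items(), seeds):
        ids = panels.loc[panels["score_name"] == score, "variant_id"].tolist()
        if not ids:
            logger.warning("bidirectional_mr: no %r panel; skipping %s", score, label)
            continue
        assocs = snp_associations(
            table, dosages, exposure, outcome, covariates,
            standardize_exposure=standardize_exposure, variant_ids=ids,
        )
        res = run_estimators(assocs, B=B, seed=int(s))
        res.insert(0, "analysis", label)
        res.insert(1, "exposure", exposure)
        res.insert(2, "outcome", outcome)
        res["n_panel_variants"] = len(ids)
        frames.append(res)
    if not frames:
        raise ValueError("no analysis could be run (no panels intersect the dosage matrix)")
    return pd.concat(frames, ignore_index=True)
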