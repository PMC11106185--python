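"""Univariate Gaussian mixture fitting by EM with AIC/BIC model selection.

The population question this supports: does a biometric trait (axial
length, spherical equivalent) follow one Gaussian, or is it better
described as two subgroups (a "bi-Gaussian" distribution)?  Candidate
component counts are fitted by expectation–maximization and compared on
AIC = −2·logL + 2p and BIC = −2·logL + p·ln(n) with p = 3K − 1 free
parameters (K−1 weights, K means, K SDs); the minimal criterion wins and
ties go to the smaller K.

Numerical choices: responsibilities are computed in log space
(log-sum-exp); component SDs are floored at 1e−3 × sample SD to prevent
singular collapse onto a data point; the first EM start seeds component
k at the (k−0.5)/K sample quantile with equal weights and pooled SD, and
further restarts perturb those means at random — the highest-likelihood
restart is returned.  Components are reported sorted by ascending mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: relative variance floor, as a fraction of the sample SD
VARIANCE_FLOOR_FRAC = 1e-3


@dataclass(frozen=True)
class MixtureModel:
    """K-component univariate Gaussian mixture, components sorted by mean."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    def variance(self) -> float:
        w, m, s = map(np.asarray, (self.weights, self.means, self.sds))
        return float(np.dot(w, s**2 + m**2) - self.mean() ** 2)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        dens = np.zeros_like(x)
        for w, m, s in zip(self.weights, self.means, self.sds):
            dens += w * norm.pdf(x, m, s)
        return dens


@dataclass
class MixtureFit:
    model: MixtureModel
    loglik: float
    aic: float
    bic: float
    n: int
    n_iter: int
    converged: bool
    n_restarts_used: int
    loglik_path: list[float] = field(default_factory=list, repr=False)


def _log_density_matrix(x: np.ndarray, weights, means, sds) -> np.ndarray:
    """n × K matrix of log(π_k φ(x_i; μ_k, σ_k)); zero-weight columns are −inf."""
    w = np.asarray(weights, float)
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    z = (x[:, None] - np.asarray(means, float)[None, :]) / np.asarray(sds, float)[None, :]
    return logw[None, :] - 0.5 * z**2 - np.log(sds)[None, :] - 0.5 * np.log(2 * np.pi)


def mixture_loglik(values, model: MixtureModel) -> float:
    """Total log-likelihood of ``values`` under ``model`` (stable log-sum-exp)."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise ValueError("empty sample")
    lm = _log_density_matrix(x, model.weights, model.means, np.asarray(model.sds, float))
    return float(logsumexp(lm, axis=1).sum())


def _canonical(weights, means, sds) -> MixtureModel:
    order = np.argsort(means)
    return MixtureModel(
        weights=tuple(float(w) for w in np.asarray(weights)[order]),
        means=tuple(float(m) for m in np.asarray(means)[order]),
        sds=tuple(float(s) for s in np.asarray(sds)[order]),
    )


def _fit_single_start(x, means0, tol, max_iter, floor):
    k = len(means0)
    n = len(x)
    weights = np.full(k, 1.0 / k)
    means = np.asarray(means0, float).copy()
    sds = np.full(k, max(x.std(), floor))
    path: list[float] = []
    prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        lm = _log_density_matrix(x, weights, means, sds)
        lse = logsumexp(lm, axis=1)
        ll = float(lse.sum())
        path.append(ll)
        gamma = np.exp(lm - lse[:, None])            # E-step responsibilities
        nk = gamma.sum(axis=0)
        weights = nk / n
        means = (gamma * x[:, None]).sum(axis=0) / nk
        var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, floor**2))
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            converged = True
            break
        prev = ll
    final_ll = mixture_loglik(x, _canonical(weights, means, sds))
    path.append(final_ll)
    return weights, means, sds, final_ll, it, converged, path


def em_fit(
    values,
    k: int,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 4,
    seed: int | None = None,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM; best of ``n_restarts`` starts.

    ``k = 1`` bypasses EM and returns the closed-form normal MLE.  A sample
    with no variation cannot identify ``k >= 2`` components and raises.
    Non-convergence within ``max_iter`` is reported via ``converged=False``.
    """
    x = np.asarray(values, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    min_n = 2 if k == 1 else 3 * k   # K=1 is a closed-form normal MLE
    if n < min_n:
        raise ValueError(f"need n >= 3K = {3 * k}, got n = {n}" if k > 1
                         else f"need n >= 2 for the K=1 MLE, got n = {n}")

    sample_sd = x.std()
    if k == 1:
        mu, sd = float(x.mean()), float(max(sample_sd, 1e-12))
        model = MixtureModel((1.0,), (mu,), (sd,))
        ll = mixture_loglik(x, model)
        return MixtureFit(
            model=model, loglik=ll,
            aic=-2 * ll + 2 * model.n_params,
            bic=-2 * ll + model.n_params * np.log(n),
            n=n, n_iter=0, converged=True, n_restarts_used=1, loglik_path=[ll],
        )

    if sample_sd == 0:
        raise ValueError("degenerate sample (all values equal) cannot support K >= 2")

    floor = VARIANCE_FLOOR_FRAC * sample_sd
    rng = np.random.default_rng(seed)
    quantile_means = np.quantile(x, (np.arange(k) + 0.5) / k)

    best = None
    for r in range(n_restarts):
        if r == 0:
            means0 = quantile_means
        else:
            means0 = quantile_means + rng.normal(0.0, sample_sd / 2.0, size=k)
        fitted = _fit_single_start(x, means0, tol, max_iter, floor)
        if best is None or fitted[3] > best[3]:
            best = fitted
    weights, means, sds, ll, n_iter, converged, path = best
    if not converged:
        logger.warning("em_fit: K=%d did not converge in %d iterations", k, max_iter)
    model = _canonical(weights, means, sds)
    p = model.n_params
    return MixtureFit(
        model=model, loglik=ll,
        aic=-2 * ll + 2 * p, bic=-2 * ll + p * np.log(n),
        n=n, n_iter=n_iter, converged=converged,
        n_restarts_used=n_restarts, loglik_path=path,
    )


@dataclass
class SelectionResult:
    fits: dict[int, MixtureFit]
    table: pd.DataFrame          # K, loglik, aic, bic, converged
    best_aic: int
    best_bic: int
    criterion: str

    @property
    def selected(self) -> int:
        return self.best_aic if self.criterion == "aic" else self.best_bic


def select_model(
    values,
    k_candidates=(1, 2),
    criterion: str = "bic",
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 4,
    seed: int | None = None,
) -> SelectionResult:
    """Fit every candidate K and select the minimal AIC/BIC (ties → smaller K)."""
    if criterion not in ("aic", "bic", "both"):
        raise ValueError("criterion must be 'aic', 'bic' or 'both'")
    fits = {
        k: em_fit(values, k, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed)
        for k in sorted(k_candidates)
    }
    table = pd.DataFrame(
        {
            "K": list(fits),
            "loglik": [f.loglik for f in fits.values()],
            "aic": [f.aic for f in fits.values()],
            "bic": [f.bic for f in fits.values()],
            "converged": [f.converged for f in fits.values()],
        }
    )
    # idxmin on a K-sorted table breaks ties toward the smaller K
    best_aic = int(table.loc[table["aic"].idxmin(), "K"])
    best_bic = int(table.loc[table["bic"].idxmin(), "K"])
    return SelectionResult(
        fits=fits, table=table, best_aic=best_aic, best_bic=best_bic,
        criterion="bic" if criterion == "both" else criterion,
    )


def stratified_mixture_report(
    table: pd.DataFrame,
    field: str,
    strata=((0.0, 11.0), (11.0, 20.0)),
    k_candidates=(1, 2),
    *,
    min_stratum_size: int = 50,
    criterion: str = "bic",
    seed: int | None = None,
    **em_kwargs,
) -> pd.DataFrame:
    """Model selection for a biometry field, overall and within education bands.

    ``strata`` are ``(low, high)`` education-year intervals, half-open
    ``[low, high)`` except the last, which includes its upper bound.
    Strata smaller than ``min_stratum_size`` are skipped with a warning.
    """
    if field not in table.columns:
        raise ValueError(f"field {field!r} not in table")
    rows = []
    groups: list[tuple[str, pd.Series]] = [("overall", table[field])]
    edu = table["education_years"]
    for i, (lo, hi) in enumerate(strata):
        last = i == len(strata) - 1
        mask = (edu >= lo) & ((edu <= hi) if last else (edu < hi))
        groups.append((f"edu_{lo:g}_{hi:g}", table.loc[mask, field]))
    for label, series in groups:
        x = series.dropna().to_numpy()
        if label != "overall" and len(x) < min_stratum_size:
            logger.warning(
                "stratum %s has %d < %d observations; skipped", label, len(x), min_stratum_size
            )
            continue
        sel = select_model(x, k_candidates, criterion="both", seed=seed, **em_kwargs)
        row = {"stratum": label, "n": len(x), "k_aic": sel.best_aic, "k_bic": sel.best_bic}
        for k, f in sel.fits.items():
            row[f"loglik_k{k}"] = f.loglik
            row[f"aic_k{k}"] = f.aic
            row[f"bic_k{k}"] = f.bic
        rows.append(row)
    return pd.DataFrame(rows)
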