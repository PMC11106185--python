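"""Weighted genetic risk scores (GRS) from allele dosages.

A score is the per-person weighted sum of effect-allele dosages,
S_i = Σ_j d_ij β_j, over the variants shared between the dosage matrix
and an effect panel.  Because an education score mixes positive and
negative effect estimates, the positive-weight and negative-weight
sub-sums are reported alongside the total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _dosage_values(dosages: pd.DataFrame) -> pd.DataFrame:
    """Variant columns of a dosage matrix (everything but person_id), as float."""
    cols = [c for c in dosages.columns if c != "person_id"]
    return dosages[cols].astype(float)


def compute_grs(
    dosages: pd.DataFrame,
    panel: pd.DataFrame,
    *,
    missing_policy: str = "mean",
    counted_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score persons against one effect panel.

    Parameters
    ----------
    dosages
        Matrix with a ``person_id`` column and one column per variant,
        values in [0, 2] (fractional dosages from imputation allowed).
    panel
        Columns ``variant_id``, ``effect_allele``, ``weight`` (and
        optionally ``score_name``); a single score.
    missing_policy
        ``"mean"`` imputes missing dosages at the per-variant mean;
        ``"drop"`` removes persons with any missing panel dosage.
    counted_alleles
        Optional map variant_id → allele counted by the matrix.  When it
        differs from the panel's effect allele the dosage is flipped to
        ``2 − d``; strand-ambiguous pairs (A/T, C/G) raise instead of
        being guessed.

    Returns a DataFrame indexed like ``dosages`` with columns
    ``person_id, total, positive_sum, negative_sum, n_variants_used, z``;
    the number of panel variants absent from the matrix is recorded in
    ``result.attrs["n_panel_variants_dropped"]``.
    """
    if panel["variant_id"].duplicated().any():
        raise ValueError("panel variant_ids must be unique")
    shared = [v for v in panel["variant_id"] if v in dosages.columns]
    n_dropped = len(panel) - len(shared)
    if not shared:
        raise ValueError("no panel variants present in the dosage matrix")
    if n_dropped:
        logger.info("compute_grs: %d panel variant(s) not in the dosage matrix", n_dropped)

    sub = panel.set_index("variant_id").loc[shared]
    d = dosages[shared].astype(float).to_numpy(copy=True)

    with np.errstate(invalid="ignore"):
        bad = ((d < 0) | (d > 2)) & ~np.isnan(d)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage out of [0, 2] at person {dosages['person_id'].iloc[i]!r}, "
            f"variant {shared[j]!r}: {d[i, j]}"
        )

    if counted_alleles:
        for j, v in enumerate(shared):
            counted = counted_alleles.get(v)
            effect = sub.at[v, "effect_allele"]
            if counted is None or counted == effect:
                continue
            if _COMPLEMENT.get(counted) == effect:
                raise ValueError(
                    f"variant {v!r}: counted allele {counted} / effect allele {effect} "
                    "are strand-ambiguous; refusing to guess orientation"
                )
            d[:, j] = 2.0 - d[:, j]

    keep = np.ones(len(d), dtype=bool)
    if np.isnan(d).any():
        n_missing = int(np.isnan(d).sum())
        if missing_policy == "mean":
            col_means = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = col_means[idx[1]]
            logger.info("compute_grs: mean-imputed %d missing dosage(s)", n_missing)
        elif missing_policy == "drop":
            keep = ~np.isnan(d).any(axis=1)
            d = d[keep]
            logger.info("compute_grs: dropped %d person(s) with missing dosages", (~keep).sum())
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    w = sub["weight"].to_numpy(float)
    total = d @ w
    positive = d @ np.where(w > 0, w, 0.0)
    negative = d @ np.where(w < 0, w, 0.0)
    out = pd.DataFrame(
        {
            "person_id": dosages.loc[keep, "person_id"].to_numpy(),
            "total": total,
            "positive_sum": positive,
            "negative_sum": negative,
            "n_variants_used": len(shared),
        }
    )
    out["z"] = standardize_score(total) if len(out) > 1 and total.std(ddof=1) > 0 else np.nan
    out.attrs["n_panel_variants_dropped"] = n_dropped
    return out


def standardize_score(scores) -> np.ndarray:
    """Z-score with the n−1 denominator; errors on < 2 values or zero variance."""
    x = np.asarray(scores, float)
    if x.size < 2:
        raise ValueError("need at least 2 scores to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize constant scores (zero variance)")
    return (x - x.mean()) / sd
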