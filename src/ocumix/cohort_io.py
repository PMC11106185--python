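"""Cohort table I/O, validation, eye averaging, and inclusion/exclusion filters.

The cohort container is a plain :class:`pandas.DataFrame` with a canonical
column set (see :data:`CANONICAL_COLUMNS`).  Biometry is stored per eye
(``eye`` in ``{"OD", "OS"}``) or per person (``eye == "mean"`` after
:func:`person_eye_means`).  Units: spherical equivalent ``se`` in diopters,
axial length ``al``, anterior chamber depth ``acd``, corneal radius ``cc``,
lens thickness ``lt`` and white-to-white ``wtw`` in millimetres, age and
education in years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: biometry fields averaged over eyes
BIOMETRY_FIELDS = ["se", "al", "acd", "cc", "lt", "wtw"]

#: person-constant fields; conflicting values across a person's rows are an error
DEMOGRAPHIC_FIELDS = ["age", "sex", "education_years", "school_level", "vocational_level"]

CANONICAL_COLUMNS = (
    ["person_id"] + DEMOGRAPHIC_FIELDS + ["eye"] + BIOMETRY_FIELDS + ["lens_status"]
)

NUMERIC_FIELDS = ["age", "education_years"] + BIOMETRY_FIELDS

#: accepted header aliases (lower-cased) -> canonical name
HEADER_ALIASES = {
    "id": "person_id",
    "subject_id": "person_id",
    "sex_category": "sex",
    "gender": "sex",
    "education": "education_years",
    "edu_years": "education_years",
    "duration_of_education": "education_years",
    "spherical_equivalent": "se",
    "sph_equiv": "se",
    "axial_length": "al",
    "anterior_chamber_depth": "acd",
    "corneal_curvature": "cc",
    "corneal_radius": "cc",
    "lens_thickness": "lt",
    "white_to_white": "wtw",
    "lens": "lens_status",
}

#: tokens read as missing; the empty string is what write_cohort emits
NA_TOKENS = ["", "NA", "NaN", "nan"]

EDU_RANGE = (0.0, 20.0)


@dataclass(frozen=True)
class FilterSpec:
    """Inclusion/exclusion rules applied at the person level.

    ``phakic_only`` drops any person with a non-phakic eye (pseudophakic or
    aphakic, i.e. after cataract surgery).  ``max_age`` keeps persons with
    ``age <= max_age`` ("over N years old" excluded, age exactly N kept).
    ``exclude_hyperopes_above`` drops persons whose person-mean spherical
    equivalent exceeds the threshold (in diopters).
    """

    phakic_only: bool = True
    max_age: float | None = None
    exclude_hyperopes_above: float | None = None

    def __post_init__(self) -> None:
        for name in ("max_age", "exclude_hyperopes_above"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"FilterSpec.{name} must be finite when set")


def _infer_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cohort(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a cohort table from CSV/TSV.

    Header names are mapped onto the canonical field set through
    :data:`HEADER_ALIASES`.  Rows violating hard invariants (education
    outside [0, 20], unparseable numerics, duplicate ``(person_id, eye)``)
    are dropped; a row-indexed diagnostic list is attached as
    ``table.attrs["diagnostics"]``.

    Raises ``ValueError`` when ``person_id`` is absent or no education /
    biometry column is present at all.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep=_infer_sep(path, sep), dtype=str,
        na_values=NA_TOKENS, keep_default_na=False,
    )
    raw.columns = [HEADER_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in raw.columns]

    if "person_id" not in raw.columns:
        raise ValueError(f"{path}: mandatory column 'person_id' missing")
    if not any(c in raw.columns for c in BIOMETRY_FIELDS + ["education_years"]):
        raise ValueError(f"{path}: need at least one biometry or education column")

    diagnostics: list[tuple[int, str]] = []
    table = raw.copy()
    bad = pd.Series(False, index=table.index)

    for col in NUMERIC_FIELDS:
        if col not in table.columns:
            continue
        parsed = pd.to_numeric(table[col], errors="coerce")
        unparseable = parsed.isna() & table[col].notna()
        for i in table.index[unparseable]:
            diagnostics.append((int(i), f"{col}: unparseable numeric {table.at[i, col]!r}"))
        bad |= unparseable
        table[col] = parsed.astype(float)

    if "education_years" in table.columns:
        lo, hi = EDU_RANGE
        out = table["education_years"].notna() & (
            (table["education_years"] < lo) | (table["education_years"] > hi)
        )
        for i in table.index[out]:
            diagnostics.append(
                (int(i), f"education_years={table.at[i, 'education_years']} outside [{lo}, {hi}]")
            )
        bad |= out

    if "eye" in table.columns:
        dup = table.duplicated(subset=["person_id", "eye"], keep="first")
        for i in table.index[dup]:
            diagnostics.append((int(i), "duplicate (person_id, eye) row"))
        bad |= dup

    if diagnostics:
        logger.warning("read_cohort: rejected %d row(s) from %s", int(bad.sum()), path)
    table = table.loc[~bad].reset_index(drop=True)

    for col in CANONICAL_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[CANONICAL_COLUMNS]
    table.attrs["diagnostics"] = diagnostics
    return table


def write_cohort(table: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a cohort table in canonical column order; missing values as empty fields."""
    path = Path(path)
    out = table.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[CANONICAL_COLUMNS].to_csv(path, sep=_infer_sep(path, sep), index=False, na_rep="")


def person_eye_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-eye rows to one row per person.

    Each biometry field is the mean of the eyes in which it was measured —
    a single available eye passes through, a field missing in both eyes
    stays missing.  Demographics must agree across a person's rows.
    ``lens_status`` becomes the unique per-eye status, or ``"mixed"``.
    """
    if table.empty:
        out = table.copy()
        out["eye"] = out.get("eye", pd.Series(dtype=object))
        return out

    demo_cols = [c for c in DEMOGRAPHIC_FIELDS if c in table.columns]
    for col in demo_cols:
        n_unique = table.groupby("person_id")[col].nunique(dropna=True)
        conflicted = n_unique[n_unique > 1]
        if len(conflicted):
            raise ValueError(
                f"conflicting {col} within person(s): {list(conflicted.index[:5])}"
            )

    g = table.groupby("person_id", sort=True)
    out = g[demo_cols].first() if demo_cols else pd.DataFrame(index=g.size().index)
    for col in BIOMETRY_FIELDS:
        if col in table.columns:
            out[col] = g[col].mean()
    if "lens_status" in table.columns:
        n_status = g["lens_status"].nunique(dropna=True)
        first = g["lens_status"].first()  # first non-null per person
        out["lens_status"] = first.where(n_status <= 1, "mixed")
    out["eye"] = "mean"
    out = out.reset_index()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[CANONICAL_COLUMNS]


def apply_filters(
    table: pd.DataFrame, spec: FilterSpec
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply person-level inclusion/exclusion rules.

    Returns the filtered table and per-criterion exclusion counts (numbers
    of *persons*, counted independently per criterion, so their sum can
    exceed the number of persons removed when criteria overlap).
    """
    if table.empty:
        return table.copy(), {}

    persons = table["person_id"]
    excluded: dict[str, set] = {}

    if spec.phakic_only and "lens_status" in table.columns:
        nonphakic = table.loc[
            table["lens_status"].notna() & (table["lens_status"] != "phakic"), "person_id"
        ]
        excluded["lens_status"] = set(nonphakic)

    if spec.max_age is not None and "age" in table.columns:
        too_old = table.loc[table["age"].notna() & (table["age"] > spec.max_age), "person_id"]
        excluded["age"] = set(too_old)

    if spec.exclude_hyperopes_above is not None and "se" in table.columns:
        mean_se = table.groupby("person_id")["se"].mean()
        hyper = mean_se[mean_se > spec.exclude_hyperopes_above].index
        excluded["hyperopia"] = set(hyper)

    drop: set = set().union(*excluded.values()) if excluded else set()
    counts = {k: len(v) for k, v in excluded.items() if v}
    kept = table.loc[~persons.isin(drop)].reset_index(drop=True)
    if counts:
        logger.info("apply_filters: excluded %s", counts)
    return kept, counts
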