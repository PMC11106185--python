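"""End-to-end orchestration: filters → eye means → GRS → mixtures →
association table → mediation → bidirectional MR, with a reproducible
report bundle (tables, manifest, log) in an output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import education_biometry_table
from .cohort_io import FilterSpec, apply_filters, person_eye_means, read_cohort, write_cohort
from .genetics import compute_grs
from .mediation import difference_mediation
from .mixture import stratified_mixture_report
from .mr import bidirectional_mr
from .synthetic import ScenarioConfig, generate_cohort, scenario_default

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full run; exactly one of scenario / cohort_path set."""

    scenario: str | None = None
    cohort_path: str | None = None
    dosage_path: str | None = None
    panel_path: str | None = None
    n_persons: int | None = None
    seed: int = 1
    out_dir: str = "ocumix_run"
    filters: FilterSpec = field(default_factory=FilterSpec)
    mixture_fields: tuple[str, ...] = ("al", "se")
    k_candidates: tuple[int, ...] = (1, 2)
    criterion: str = "bic"
    mediation_B: int = 1000
    mr_B: int = 2000
    stratify_by_sex: bool = True
    sensitivity: bool = True
    hyperopia_cut: float = 0.75
    sensitivity_max_age: float = 70.0

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.cohort_path is None):
            raise ValueError("set exactly one of scenario / cohort_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "filters" in raw and isinstance(raw["filters"], dict):
            raw["filters"] = FilterSpec(**raw["filters"])
        for key in ("mixture_fields", "k_candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full study flow; returns the in-memory results and writes
    every table, a manifest, and a log under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ocumix")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _sub_seeds(config.seed, 6)
    results: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("load")
        if config.scenario is not None:
            scen = scenario_default(config.scenario)
            scen.seed = seeds[0]
            if config.n_persons is not None:
                scen.n_persons = config.n_persons
            cohort, dosages, panels, truth = generate_cohort(scen)
            results["scenario_config"] = scen
            truth.to_json(out / "truth.json")
        else:
            cohort = read_cohort(config.cohort_path)
            dosages = (
                pd.read_csv(config.dosage_path, sep="\t") if config.dosage_path else None
            )
            panels = pd.read_csv(config.panel_path, sep="\t") if config.panel_path else None
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", e) from e

    try:
        stage("filters")
        filtered, counts = apply_filters(cohort, config.filters)
        results["exclusions"] = counts
        (out / "exclusions.json").write_text(json.dumps(counts, indent=1))
        stage("eye_means")
        persons = person_eye_means(filtered)
        write_cohort(persons, out / "cohort_person.tsv")
        results["cohort"] = persons
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filters/eye_means", e) from e

    grs = None
    if dosages is not None and panels is not None and len(panels):
        try:
            stage("grs")
            myo = panels[panels["score_name"] == "myopia"]
            if len(myo):
                grs = compute_grs(dosages, myo)
                grs.to_csv(out / "grs_myopia.tsv", sep="\t", index=False)
            results["grs"] = grs
        except Exception as e:  # noqa: BLE001
            raise PipelineError("grs", e) from e

    try:
        stage("mixtures")
        reports = []
        for fld in config.mixture_fields:
            rep = stratified_mixture_report(
                persons, fld, k_candidates=config.k_candidates,
                criterion=config.criterion, seed=seeds[1],
            )
            rep.insert(0, "field", fld)
            reports.append(rep)
        mixture_report = pd.concat(reports, ignore_index=True)
        mixture_report.to_csv(out / "mixture_report.tsv", sep="\t", index=False)
        mixture_report.to_json(out / "mixture_report.json", orient="records", indent=1)
        results["mixture_report"] = mixture_report
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mixtures", e) from e

    try:
        stage("association")
        sens = None
        if config.sensitivity:
            sens = {
                "age_le_70": FilterSpec(max_age=config.sensitivity_max_age),
                "no_hyperopes": FilterSpec(exclude_hyperopes_above=config.hyperopia_cut),
            }
        assoc = education_biometry_table(
            persons, grs=grs, stratify_by_sex=config.stratify_by_sex, sensitivity=sens
        )
        assoc.to_csv(out / "education_biometry.tsv", sep="\t", index=False)
        results["association"] = assoc
    except Exception as e:  # noqa: BLE001
        raise PipelineError("association", e) from e

    try:
        stage("mediation")
        med_table = persons
        covs = ["age", "sex"]
        if grs is not None:
            med_table = persons.merge(
                grs[["person_id", "z"]].rename(columns={"z": "myopia_grs"}),
                on="person_id", how="left",
            )
            covs.append("myopia_grs")
        med = difference_mediation(
            med_table, "se", "education_years", "al", covs,
            B=config.mediation_B, seed=seeds[2],
        )
        (out / "mediation.json").write_text(json.dumps(med.to_dict(), indent=1))
        results["mediation"] = med
    except Exception as e:  # noqa: BLE001
        raise PipelineError("mediation", e) from e

    if dosages is not None and panels is not None and (panels["score_name"] == "education").any():
        try:
            stage("mr")
            mr_report = bidirectional_mr(
                persons, dosages, panels, B=config.mr_B, seed=seeds[3]
            )
            mr_report.to_csv(out / "mr_report.tsv", sep="\t", index=False)
            results["mr"] = mr_report
        except Exception as e:  # noqa: BLE001
            raise PipelineError("mr", e) from e

    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seed": config.seed,
        "sub_seeds": seeds,
        "versions": {
            "ocumix": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    root.removeHandler(handler)
    handler.close()
    return results
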