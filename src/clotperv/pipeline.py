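"""End-to-end orchestration: simulate → extract → classify → clot-type →
analyze, with persisted CSV intermediates so stages can be re-run
independently and a JSON run report recording every convention in force.

All randomness flows from one root seed through named substreams (cohort
draws, per-patient phantom noise), so a rerun with the same config is
byte-identical and partial reruns are stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .histology import DEFAULT_MARGIN_PCT, classify_clot_type, validate_composition
from .perviousness import (
    DEFAULT_THRESHOLD_HU,
    classify_dynamic_batch,
    to_standard,
)
from .roi import extract_phase_densities, read_roi_csv, read_volume, write_roi_csv, write_volume
from .synthetic import (
    CohortConfig,
    cohort_to_frame,
    generate_cohort,
    generate_phantom_volumes,
    read_cohort_csv,
)
from . import stats as st

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_inputs", "ALL_STAGES"]

logger = logging.getLogger("clotperv")

ALL_STAGES = ("simulate", "extract", "classify", "clot-type", "analyze")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the published conventions
    (5 HU uptake threshold, 15-point clot-type margin, BH at 0.05)."""

    out_dir: Path = Path("clotperv_out")
    stages: tuple = ALL_STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    clot_margin: float = DEFAULT_MARGIN_PCT
    bh_alpha: float = 0.05
    precision: int = 1
    skip_imaging: bool = False
    phantom_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 0.5
    seed: int | None = None  # overrides cohort.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_raw = raw.pop("cohort", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cohort = CohortConfig(**cohort_raw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(cohort=cohort, **raw)


@dataclass
class RunReport:
    stages_run: list
    record_counts: dict
    warnings: list
    conventions: dict
    outputs: list
    seed: int
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _conventions(cfg: RunConfig) -> dict:
    return {
        "uptake_threshold_hu": cfg.threshold_hu,
        "change_reading": "signed increase; decreases are never uptake",
        "washout_rule": "drop >= threshold after early uptake; categories 3/4 partition early uptake",
        "clot_type_margin_pct": cfg.clot_margin,
        "clot_type_rule": "absolute percentage-point difference, strict inequality",
        "bh_families": "pairwise category comparisons; composition Kruskal-Wallis; clot-type associations",
        "roi_aggregation": "unweighted mean of per-ROI means",
        "voxel_membership": "voxel center within sphere radius (inclusive)",
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the selected stages in order and write all intermediates."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        stages_run=[],
        record_counts={},
        warnings=[],
        conventions=_conventions(config),
        outputs=[],
        seed=config.cohort.seed,
    )

    if "simulate" in config.stages:
        _stage_simulate(config, report)
    if "extract" in config.stages:
        _stage_extract(config, report)
    if "classify" in config.stages:
        _stage_classify(config, report)
    if "clot-type" in config.stages:
        _stage_clot_type(config, report)
    if "analyze" in config.stages:
        _stage_analyze(config, report)

    report.to_json(out / "run_report.json")
    report.outputs.append(str(out / "run_report.json"))
    return report


def _record(report: RunReport, stage: str, n: int, *paths: Path) -> None:
    report.stages_run.append(stage)
    report.record_counts[stage] = n
    report.outputs.extend(str(p) for p in paths)


def _stage_simulate(cfg: RunConfig, report: RunReport) -> None:
    records = generate_cohort(cfg.cohort)
    cohort_path = cfg.out_dir / "cohort.csv"
    cohort_to_frame(records).to_csv(cohort_path, index=False)
    paths = [cohort_path]

    if not cfg.skip_imaging:
        phantom_dir = cfg.out_dir / "phantoms"
        roi_dir = cfg.out_dir / "rois"
        phantom_dir.mkdir(exist_ok=True)
        roi_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(records):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.cohort.seed, spawn_key=(1, i))
            )
            volumes, rois = generate_phantom_volumes(
                rec,
                shape=cfg.phantom_shape,
                voxel_size=cfg.voxel_size_mm,
                noise_sd=cfg.cohort.density_noise_sd,
                rng=rng,
            )
            for phase, vol in volumes.items():
                write_volume(vol, phantom_dir / f"{rec.patient_id}_{phase}.nii.gz")
            write_roi_csv(rois, roi_dir / f"{rec.patient_id}.csv")
        paths.extend([phantom_dir, roi_dir])

    cfg_path = cfg.out_dir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(
            {
                "cohort": dataclasses.asdict(cfg.cohort),
                "threshold_hu": cfg.threshold_hu,
                "clot_margin": cfg.clot_margin,
                "seed": cfg.cohort.seed,
            },
            fh,
        )
    paths.append(cfg_path)
    _record(report, "simulate", len(records), *paths)


def _stage_extract(cfg: RunConfig, report: RunReport) -> None:
    cohort = read_cohort_csv(cfg.out_dir / "cohort.csv")
    densities_path = cfg.out_dir / "densities.csv"
    if cfg.skip_imaging:
        # densities travel straight from the cohort table
        df = cohort[["patient_id", "rho_ncct", "rho_cta", "rho_ctv"]].copy()
    else:
        rows = []
        for pid in cohort["patient_id"]:
            vols = {
                phase: read_volume(cfg.out_dir / "phantoms" / f"{pid}_{phase}.nii.gz", phase)
                for phase in ("NCCT", "CTA", "CTV")
            }
            rois = read_roi_csv(cfg.out_dir / "rois" / f"{pid}.csv")
            dens = extract_phase_densities(vols["NCCT"], vols["CTA"], vols["CTV"], rois)
            rows.append(
                {
                    "patient_id": pid,
                    "rho_ncct": dens.rho_ncct,
                    "rho_cta": dens.rho_cta,
                    "rho_ctv": dens.rho_ctv,
                }
            )
        df = pd.DataFrame(rows)
    df.to_csv(densities_path, index=False)
    _record(report, "extract", len(df), densities_path)


def _stage_classify(cfg: RunConfig, report: RunReport) -> None:
    df = pd.read_csv(cfg.out_dir / "densities.csv")
    labels = classify_dynamic_batch(
        df["rho_ncct"], df["rho_cta"], df["rho_ctv"], threshold=cfg.threshold_hu
    )
    out = df.copy()
    out["tai_cta_ncct"] = df["rho_cta"] - df["rho_ncct"]
    out["tai_ctv_cta"] = df["rho_ctv"] - df["rho_cta"]
    out["tai_ctv_ncct"] = out["tai_cta_ncct"] + out["tai_ctv_cta"]
    out["dynamic_label"] = labels
    out["standard_label"] = [to_standard(l) for l in labels]
    path = cfg.out_dir / "classified.csv"
    out.to_csv(path, index=False)
    _record(report, "classify", len(out), path)


def _stage_clot_type(cfg: RunConfig, report: RunReport) -> None:
    cohort = read_cohort_csv(cfg.out_dir / "cohort.csv")
    labels = []
    for row in cohort.itertuples():
        comp = validate_composition(row.fibrin_platelet_pct, row.rbc_pct, row.wbc_pct)
        labels.append(classify_clot_type(comp, margin=cfg.clot_margin).label)
    out = cohort[["patient_id", "fibrin_platelet_pct", "rbc_pct", "wbc_pct"]].copy()
    out["clot_type"] = labels
    path = cfg.out_dir / "clot_types.csv"
    out.to_csv(path, index=False)
    _record(report, "clot-type", len(out), path)


def _stage_analyze(cfg: RunConfig, report: RunReport) -> None:
    cohort = read_cohort_csv(cfg.out_dir / "cohort.csv")
    classified = pd.read_csv(cfg.out_dir / "classified.csv")
    clot_types = pd.read_csv(cfg.out_dir / "clot_types.csv")
    df = cohort.merge(
        classified[["patient_id", "tai_cta_ncct", "tai_ctv_cta", "tai_ctv_ncct",
                    "dynamic_label", "standard_label"]],
        on="patient_id",
    ).merge(clot_types[["patient_id", "clot_type"]], on="patient_id")

    adir = cfg.out_dir / "analysis"
    adir.mkdir(exist_ok=True)

    summary = st.cohort_summary(df, precision=cfg.precision)
    summary.categorical.to_csv(adir / "summary_categorical.csv", index=False)
    summary.numeric.to_csv(adir / "summary_numeric.csv", index=False)

    tests: list[dict] = []

    def push(res: st.StatResult, family: str) -> None:
        tests.append(
            {
                "test": res.test_name,
                "family": family,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "p_adj": res.p_adjusted,
                "group_sizes": "|".join(map(str, res.group_sizes)),
                "notes": res.notes,
            }
        )

    # normality screen on ordinal variables
    for var in ("age", "nihss", "fibrin_platelet_pct", "rbc_pct", "wbc_pct"):
        if var in df.columns:
            try:
                res = st.ks_normality(df[var].dropna())
                res.test_name = f"ks_normality:{var}"
                push(res, "normality")
            except ValueError as exc:
                report.warnings.append(f"normality {var}: {exc}")

    # composition vs uptake category (one BH family)
    kw_results = []
    for var in ("fibrin_platelet_pct", "rbc_pct", "wbc_pct"):
        groups = [g[var].to_numpy() for _, g in df.groupby("dynamic_label") if len(g) > 0]
        if len(groups) >= 2:
            res = st.kruskal_wallis(groups)
            res.test_name = f"kruskal_wallis:{var}~category"
            kw_results.append(res)
    for res, q in zip(kw_results, st.bh_adjust([r.p_value for r in kw_results])):
        res.p_adjusted = q
        push(res, "composition_kw")

    # clot-type associations (one BH family)
    assoc_results = []
    for var in ("dynamic_label", "mtici"):
        table = pd.crosstab(df["clot_type"], df[var]).to_numpy()
        try:
            res = st.chi_squared_contingency(table)
            res.test_name = f"chi_squared:clot_type~{var}"
            assoc_results.append(res)
        except ValueError as exc:
            report.warnings.append(f"association clot_type~{var}: {exc}")
    for res, q in zip(assoc_results, st.bh_adjust([r.p_value for r in assoc_results])):
        res.p_adjusted = q
        push(res, "clot_type_assoc")

    # pairwise fibrin-rich comparisons across categories (own BH family)
    try:
        for res in st.pairwise_category_comparisons(df):
            push(res, "pairwise_category_fibrin")
    except ValueError as exc:
        report.warnings.append(f"pairwise comparisons: {exc}")

    pd.DataFrame(tests).to_csv(adir / "tests.csv", index=False)

    # per-category component correlations (categories with n >= 3 only)
    counts = df["dynamic_label"].value_counts()
    usable = counts[counts >= 3].index
    dropped = sorted(set(counts.index) - set(usable))
    if dropped:
        report.warnings.append(
            f"correlations skipped for categories with n < 3: {dropped}"
        )
    corr_rows = []
    if len(usable) > 0:
        try:
            for c in st.pearson_by_category(df[df["dynamic_label"].isin(usable)]):
                corr_rows.append(
                    {
                        "category": c.category,
                        "pair": f"{c.pair[0]}~{c.pair[1]}",
                        "r": c.r,
                        "strength": c.strength_label,
                        "n": c.n,
                    }
                )
        except ValueError as exc:
            report.warnings.append(f"correlations: {exc}")
    pd.DataFrame(corr_rows, columns=["category", "pair", "r", "strength", "n"]).to_csv(
        adir / "correlations.csv", index=False
    )

    with open(adir / "metadata.json", "w") as fh:
        json.dump(
            {
                "seed": cfg.cohort.seed,
                "threshold_hu": cfg.threshold_hu,
                "clot_margin_pct": cfg.clot_margin,
                "bh_alpha": cfg.bh_alpha,
                "precision": cfg.precision,
                "conventions": _conventions(cfg),
                "version": __version__,
            },
            fh,
            indent=2,
        )
    _record(
        report, "analyze", len(df),
        adir / "summary_categorical.csv", adir / "summary_numeric.csv",
        adir / "tests.csv", adir / "correlations.csv", adir / "metadata.json",
    )


# ---------------------------------------------------------------------------
# Input validation


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str
    context: str = ""


def validate_inputs(out_dir: str | Path, config: RunConfig | None = None) -> list[Finding]:
    """Schema and consistency checks on a pipeline working directory.

    Reports findings instead of raising: missing files, malformed CSV
    schemas, composition sums off by more than the tolerance, and phase
    volumes on mismatched grids (a co-registration precondition violation).
    """
    out_dir = Path(out_dir)
    findings: list[Finding] = []

    cohort_path = out_dir / "cohort.csv"
    cohort = None
    if not cohort_path.exists():
        findings.append(Finding("error", "cohort.csv not found", str(cohort_path)))
    else:
        try:
            cohort = read_cohort_csv(cohort_path)
        except ValueError as exc:
            findings.append(Finding("error", str(exc), str(cohort_path)))

    if cohort is not None:
        comp_cols = {"fibrin_platelet_pct", "rbc_pct", "wbc_pct"}
        if comp_cols <= set(cohort.columns):
            for row in cohort.itertuples():
                try:
                    validate_composition(
                        row.fibrin_platelet_pct, row.rbc_pct, row.wbc_pct
                    )
                except ValueError as exc:
                    findings.append(
                        Finding(
                            "error",
                            f"composition invalid: {exc}",
                            f"patient_id={row.patient_id} columns={sorted(comp_cols)}",
                        )
                    )
        else:
            findings.append(
                Finding("warning", "cohort.csv lacks composition columns", str(cohort_path))
            )

        phantom_dir = out_dir / "phantoms"
        if phantom_dir.exists():
            for pid in cohort["patient_id"]:
                vols = {}
                for phase in ("NCCT", "CTA", "CTV"):
                    p = phantom_dir / f"{pid}_{phase}.nii.gz"
                    if not p.exists():
                        findings.append(
                            Finding("error", f"missing {phase} volume", f"patient_id={pid}")
                        )
                        continue
                    vols[phase] = read_volume(p, phase)
                if len(vols) == 3:
                    ref = vols["NCCT"]
                    for phase in ("CTA", "CTV"):
                        v = vols[phase]
                        if v.voxels.shape != ref.voxels.shape or not np.allclose(
                            v.affine, ref.affine, atol=1e-6
                        ):
                            findings.append(
                                Finding(
                                    "error",
                                    f"{phase} volume grid differs from NCCT; "
                                    "co-registration precondition violated",
                                    f"patient_id={pid}",
                                )
                            )
    return findings
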