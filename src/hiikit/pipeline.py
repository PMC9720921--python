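"""Batch orchestration: per-case measurement, cohort analysis, fixture suite.

Every report is JSON-first and embeds the fully resolved run configuration,
so a result can always be traced back to the thresholds and smoothing
settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import (
    COHORT_COLUMNS,
    CohortParams,
    fit_logistic,
    hosmer_lemeshow,
    roc_youden,
    select_for_multivariate,
    simulate_cohort,
    summarize_baseline,
)
from .hii import ExpansionRule, compute_hii_for_mask
from .phantoms import (
    make_ellipsoid_phantom,
    make_lobulated_phantom,
    make_sphere_phantom,
    resample_to_slices,
)
from .segmentation import SegmentationConfig, apply_exclusion_mask, segment_hematoma
from .volume_io import read_dicom_series, read_mask_nifti, read_nifti, write_volume

__all__ = ["RunConfig", "run_case", "run_cohort", "make_fixtures"]

UNIVARIATE_CANDIDATES = [
    "age", "female", "alcohol", "smoking", "hypertension", "diabetes",
    "gcs", "onset_to_ct_h", "baseline_volume_mL", "hii",
]


@dataclass
class RunConfig:
    hu_low: float = 40.0
    hu_high: float = 100.0
    component_rule: str = "largest"
    seed_point: tuple | None = None
    min_component_voxels: int = 1
    antialias_sigma_vox: float = 1.2
    taubin_iterations: int = 0          # 0 = mesh smoothing off
    taubin_passband: float = 0.1
    relative_expansion_threshold: float = 0.33
    absolute_expansion_threshold_mL: float = 12.5
    seed: int | None = None

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            hu_low=self.hu_low,
            hu_high=self.hu_high,
            component_rule=self.component_rule,
            seed_point=self.seed_point,
            min_component_voxels=self.min_component_voxels,
        )

    def expansion_rule(self) -> ExpansionRule:
        return ExpansionRule(
            relative_threshold=self.relative_expansion_threshold,
            absolute_threshold_mL=self.absolute_expansion_threshold_mL,
        )

    def as_dict(self) -> dict:
        return asdict(self)


def _read_any(path: str):
    if os.path.isdir(path):
        return read_dicom_series(path)
    return read_nifti(path)


def run_case(input_path: str, exclusion_path: str | None = None, config: RunConfig | None = None) -> dict:
    """Measure one case: read → segment → exclude → surface → ShapeMetrics.

    Returns the per-case report dict (also what the CLI writes as JSON).
    """
    config = config or RunConfig()
    volume = _read_any(input_path)
    mask = segment_hematoma(volume, config.segmentation())
    warnings = []
    if exclusion_path is not None:
        exclusion = read_mask_nifti(exclusion_path)
        if exclusion.count() == 0:
            warnings.append("exclusion mask is empty; it has no effect")
        mask = apply_exclusion_mask(mask, exclusion)
        if mask.count() == 0:
            raise ValueError("exclusion mask removed the entire segmentation")
    if mask.count() < 64:
        warnings.append(
            f"segmented object spans only {mask.count()} voxels; shape metrics at this "
            "resolution are unreliable"
        )
    metrics = compute_hii_for_mask(
        mask,
        antialias_sigma_vox=config.antialias_sigma_vox,
        taubin_iterations=config.taubin_iterations,
        taubin_passband=config.taubin_passband,
    )
    report = {
        "case_id": os.path.basename(os.path.normpath(input_path)),
        "input": str(input_path),
        "exclusion": str(exclusion_path) if exclusion_path else None,
        "voxel_count": mask.count(),
        **{k: float(v) for k, v in metrics.as_dict().items()},
        "warnings": warnings,
        "config": config.as_dict(),
        "hiikit_version": __version__,
    }
    return report


def run_cohort(table: str | pd.DataFrame, config: RunConfig | None = None) -> dict:
    """The full cohort chain: baseline table → crude ORs → P<0.1 selection →
    adjusted model → Hosmer–Lemeshow → ROC with Youden cutoff."""
    config = config or RunConfig()
    df = pd.read_csv(table) if isinstance(table, (str, os.PathLike)) else table.copy()
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if df["expansion"].nunique() != 2:
        raise ValueError("outcome 'expansion' must contain both classes")

    baseline = summarize_baseline(df, group_by="expansion")

    univariate = {}
    for var in UNIVARIATE_CANDIDATES:
        res = fit_logistic(df, outcome="expansion", predictors=[var])
        univariate[var] = res
    uni_p = {var: res.p_values[var] for var, res in univariate.items()}
    selected = select_for_multivariate(uni_p, alpha=0.1)
    adjusted = fit_logistic(df, outcome="expansion", predictors=selected) if len(selected) >= 1 else None

    report = {
        "n": int(len(df)),
        "n_expansion": int(df["expansion"].sum()),
        "baseline_table": baseline.to_dict(orient="records"),
        "univariate": {var: res.as_dict() for var, res in univariate.items()},
        "selected_for_multivariate": selected,
        "config": config.as_dict(),
        "hiikit_version": __version__,
    }
    if adjusted is not None:
        hl_stat, hl_p, hl_groups = hosmer_lemeshow(
            adjusted.fitted_probabilities, df["expansion"].to_numpy()
        )
        report["adjusted"] = adjusted.as_dict()
        report["hosmer_lemeshow"] = {"statistic": hl_stat, "p_value": hl_p, "groups": hl_groups}
    roc = roc_youden(df["hii"].to_numpy(float), df["expansion"].to_numpy(int))
    report["roc_hii"] = roc.as_dict()
    return report


def render_cohort_text(report: dict) -> str:
    """Plain-text rendering of a cohort report (baseline + OR tables + ROC)."""
    lines = [f"Cohort analysis (n={report['n']}, expansion {report['n_expansion']})", ""]
    lines.append(f"{'variable':<20}{'no expansion':>20}{'expansion':>20}{'p':>10}  test")
    for row in report["baseline_table"]:
        lines.append(
            f"{row['variable']:<20}{row['group0']:>20}{row['group1']:>20}"
            f"{row['p_value']:>10.3f}  {row['test']}"
        )
    lines.append("")
    lines.append(f"{'variable':<20}{'crude OR (95% CI)':>28}{'p':>10}")
    for var, res in report["univariate"].items():
        o = res["odds_ratios"][var]
        lines.append(
            f"{var:<20}{o['or']:>10.3f} ({o['ci_low']:.3f}-{o['ci_high']:.3f})"
            f"{res['p_values'][var]:>12.4f}"
        )
    if "adjusted" in report:
        lines.append("")
        lines.append(f"Adjusted model ({', '.join(report['selected_for_multivariate'])}):")
        adj = report["adjusted"]
        for var in adj["predictors"]:
            o = adj["odds_ratios"][var]
            lines.append(
                f"{var:<20}{o['or']:>10.3f} ({o['ci_low']:.3f}-{o['ci_high']:.3f})"
                f"{adj['p_values'][var]:>12.4f}"
            )
        hl = report["hosmer_lemeshow"]
        lines.append(f"Hosmer-Lemeshow: chi2={hl['statistic']:.2f}, p={hl['p_value']:.3f}")
    roc = report["roc_hii"]
    lines.append("")
    lines.append(
        f"ROC (HII): AUC={roc['auc']:.3f} (95% CI {roc['auc_ci'][0]:.3f}-{roc['auc_ci'][1]:.3f}), "
        f"Youden cutoff={roc['youden_cutoff']:.1f} "
        f"(sens {roc['sensitivity_at_cutoff']:.2f}, spec {roc['specificity_at_cutoff']:.2f})"
    )
    return "\n".join(lines)


FIXTURE_MANIFEST = [
    "sphere_r20_sp0.5",
    "ellipsoid_a10_b10_c10",
    "ellipsoid_a20_b10_c10",
    "ellipsoid_a40_b10_c10",
    "lobulated_n5",
    "sphere_r20_sliced_5mm",
]


def make_fixtures(output_dir: str, seed: int = 0) -> list[str]:
    """Write the standard phantom suite (NIfTI + truth JSON sidecars).

    Deterministic under ``seed``; only the lobulated phantom actually uses
    randomness. Returns the list of fixture names written.
    """
    os.makedirs(output_dir, exist_ok=True)
    phantoms = {}
    vol, truth = make_sphere_phantom(20.0, 0.5)
    phantoms["sphere_r20_sp0.5"] = (vol, truth)
    for a in (10.0, 20.0, 40.0):
        v, t = make_ellipsoid_phantom(a, 10.0, 10.0, 0.5)
        phantoms[f"ellipsoid_a{a:.0f}_b10_c10"] = (v, t)
    v, t = make_lobulated_phantom(
        n_lobes=5, lobe_radius_range_mm=(5.0, 8.0), center_spread_mm=8.0,
        spacing_mm=0.5, seed=seed,
    )
    phantoms["lobulated_n5"] = (v, t)
    iso, truth_iso = make_sphere_phantom(20.0, 1.0)
    phantoms["sphere_r20_sliced_5mm"] = (resample_to_slices(iso, 5.0), truth_iso)

    written = []
    for name, (vol, truth) in phantoms.items():
        write_volume(vol, os.path.join(output_dir, f"{name}.nii.gz"))
        with open(os.path.join(output_dir, f"{name}.truth.json"), "w") as fh:
            json.dump(truth.as_dict(), fh, indent=2)
        written.append(name)
    assert written == FIXTURE_MANIFEST
    return written
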