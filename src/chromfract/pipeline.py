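"""End-to-end orchestration: manifests → per-nucleus/per-case tables →
survival reports.

These functions are the library face of the command-line pipeline: they
consume and produce plain DataFrames (written as CSV by the CLI), so
synthetic and real runs are interchangeable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aggregation import CaseSummary, stabilization_index, summarize_case
from .fractal import analyze_nucleus
from .imaging import NucleusSurface, load_nucleus
from .morphometry import analyze_mask
from .survival import (
    backward_stepwise,
    bootstrap_stability,
    cox_fit,
    km_logrank,
    ward_cutpoint,
)

__all__ = ["RunConfig", "FeatureRun", "SurvivalReport",
           "run_features", "run_features_from_arrays", "run_survival"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs shared by the pipeline stages.

    ``pixel_size_um`` has no default: µm² areas are meaningless without
    the acquisition calibration, which the operator must supply.  The
    fractal estimates are pixel-unit computations and ignore it.
    """

    pixel_size_um: float
    e_max: int = 30
    perimeter_estimator: str = "crofton4"
    p_in: float = 0.05
    p_out: float = 0.10
    n_boot: int = 100
    seed: int = 0
    stabilization_tol: float = 0.005
    stabilization_window: int = 5

    def __post_init__(self) -> None:
        if self.e_max < 2:
            raise ValueError("e_max must be >= 2")
        if not (0 < self.p_in < 1 and 0 < self.p_out < 1):
            raise ValueError("p_in and p_out must lie in (0, 1)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class FeatureRun:
    per_nucleus: pd.DataFrame
    per_case: pd.DataFrame
    summaries: dict
    failures: pd.DataFrame


def _summaries_to_frame(summaries: Mapping[str, CaseSummary],
                        config: RunConfig) -> pd.DataFrame:
    rows = []
    for cs in summaries.values():
        idx = stabilization_index(
            cs.cum_mean_fd,
            tol=config.stabilization_tol,
            window=min(config.stabilization_window, cs.n_cells),
        )
        rows.append(
            dict(
                case_id=cs.case_id,
                n_cells=cs.n_cells,
                mean_fd=cs.mean_fd,
                mean_r2=cs.mean_r2,
                mean_area_um2=cs.mean_area_um2,
                mean_form_factor=cs.mean_form_factor,
                stabilization_index=-1 if idx is None else idx,
                low_count=cs.low_count,
            )
        )
    return pd.DataFrame(rows)


def run_features(manifest, config: RunConfig) -> FeatureRun:
    """Compute per-nucleus and per-case features from a manifest.

    ``manifest`` is a DataFrame or CSV path with columns
    ``case_id, image_path, mask_path``; rows are processed in order
    (acquisition order within each case).  Unreadable rows are collected
    into ``failures`` and the remaining results are still produced.
    """
    if isinstance(manifest, (str, os.PathLike)):
        manifest = pd.read_csv(manifest)
    required = {"case_id", "image_path", "mask_path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    nucleus_rows, failures, per_case_inputs = [], [], {}
    for _, row in manifest.iterrows():
        try:
            surface = load_nucleus(
                row["image_path"], row["mask_path"], config.pixel_size_um
            )
            fr = analyze_nucleus(surface, e_max=config.e_max)
            mr = analyze_mask(
                surface.mask, config.pixel_size_um,
                estimator=config.perimeter_estimator,
            )
        except Exception as exc:  # recorded, not fatal
            failures.append(dict(case_id=row["case_id"],
                                 image_path=row["image_path"],
                                 error=str(exc)))
            continue
        nucleus_rows.append(
            dict(
                case_id=row["case_id"],
                image_path=row["image_path"],
                fd=fr.fd,
                r_squared=fr.r_squared,
                n_points=len(fr.series),
                area_px=mr.area_px,
                area_um2=mr.area_um2,
                perimeter_px=mr.perimeter_px,
                form_factor=mr.form_factor,
            )
        )
        per_case_inputs.setdefault(row["case_id"], []).append((fr, mr))
    summaries = {
        cid: summarize_case(cid, results)
        for cid, results in per_case_inputs.items()
    }
    return FeatureRun(
        per_nucleus=pd.DataFrame(nucleus_rows),
        per_case=_summaries_to_frame(summaries, config),
        summaries=summaries,
        failures=pd.DataFrame(failures,
                              columns=["case_id", "image_path", "error"]),
    )


def run_features_from_arrays(
    cases: Mapping[str, Sequence[tuple[np.ndarray, np.ndarray]]],
    config: RunConfig,
) -> FeatureRun:
    """In-memory variant of :func:`run_features` for synthetic cohorts."""
    per_case_inputs = {}
    nucleus_rows = []
    for cid, pairs in cases.items():
        for j, (gray, mask) in enumerate(pairs):
            surface = NucleusSurface(gray=gray, mask=mask,
                                     pixel_size_um=config.pixel_size_um)
            fr = analyze_nucleus(surface, e_max=config.e_max)
            mr = analyze_mask(surface.mask, config.pixel_size_um,
                              estimator=config.perimeter_estimator)
            per_case_inputs.setdefault(cid, []).append((fr, mr))
            nucleus_rows.append(
                dict(case_id=cid, image_path=f"<memory:{cid}/{j}>",
                     fd=fr.fd, r_squared=fr.r_squared,
                     n_points=len(fr.series), area_px=mr.area_px,
                     area_um2=mr.area_um2, perimeter_px=mr.perimeter_px,
                     form_factor=mr.form_factor)
            )
    summaries = {cid: summarize_case(cid, res)
                 for cid, res in per_case_inputs.items()}
    return FeatureRun(
        per_nucleus=pd.DataFrame(nucleus_rows),
        per_case=_summaries_to_frame(summaries, config),
        summaries=summaries,
        failures=pd.DataFrame(columns=["case_id", "image_path", "error"]),
    )


@dataclass
class SurvivalReport:
    univariate: pd.DataFrame
    final_model: object
    stability: object
    fd_cutpoint: float
    km_fd_groups: object
    km_coordinates: pd.DataFrame
    cohort: pd.DataFrame


#: univariate candidates and whether their univariate Cox fit is
#: stratified by ISS stage (the texture features are; clinical ones not)
UNIVARIATE_PLAN: Sequence[tuple[str, Optional[str]]] = (
    ("iss_stage", None),
    ("very_poor_group", None),
    ("n_cytogenetic_abnormalities", None),
    ("mean_fd", "iss_stage"),
    ("mean_r2", "iss_stage"),
)


def run_survival(
    case_table,
    clinical_table,
    config: RunConfig,
    allow_partial: bool = False,
) -> SurvivalReport:
    """Join per-case features with the clinical table and run the full
    prognostic chain: univariate Cox screen, backward stepwise selection
    over the candidates with univariate p ≤ p_out, bootstrap stability,
    Ward dichotomization of mean FD with a Kaplan–Meier comparison."""
    if isinstance(case_table, (str, os.PathLike)):
        case_table = pd.read_csv(case_table)
    if isinstance(clinical_table, (str, os.PathLike)):
        clinical_table = pd.read_csv(clinical_table)
    unmatched = set(case_table["case_id"]) ^ set(clinical_table["case_id"])
    if unmatched and not allow_partial:
        raise ValueError(
            f"{len(unmatched)} case ids unmatched between feature and "
            f"clinical tables: {sorted(unmatched)[:10]}"
        )
    cohort = clinical_table.merge(
        case_table[["case_id", "mean_fd", "mean_r2",
                    "mean_area_um2", "mean_form_factor"]],
        on="case_id",
        how="inner",
    )
    cohort["event"] = cohort["event"].astype(bool)

    uni_rows = []
    candidates = []
    for term, strata in UNIVARIATE_PLAN:
        try:
            fit = cox_fit(cohort, [term], strata=strata)
        except Exception as exc:
            uni_rows.append(dict(term=term, column="<failed>", B=np.nan,
                                 p=np.nan, stratified_by=strata or "",
                                 error=str(exc)))
            continue
        min_p = min(fit.p_values.values())
        for col, b in fit.coefficients.items():
            uni_rows.append(dict(term=term, column=col, B=b,
                                 p=fit.p_values[col],
                                 stratified_by=strata or "", error=""))
        if min_p <= config.p_out:
            candidates.append(term)
    univariate = pd.DataFrame(uni_rows)
    if not candidates:
        candidates = ["mean_fd"]  # always examine the texture feature

    final_model = backward_stepwise(
        cohort, candidates, p_in=config.p_in, p_out=config.p_out
    )
    stability = bootstrap_stability(
        cohort, candidates, n_boot=config.n_boot, seed=config.seed,
        p_in=config.p_in, p_out=config.p_out,
    )
    cut = ward_cutpoint(cohort["mean_fd"].to_numpy())
    labels = np.where(cohort["mean_fd"] > cut, "high FD", "low FD")
    km = km_logrank(cohort, labels)
    km_rows = []
    for g, curve in km.curves.items():
        for t, s in curve.iloc[:, 0].items():
            km_rows.append(dict(group=str(g), time_months=float(t),
                                survival=float(s)))
    return SurvivalReport(
        univariate=univariate,
        final_model=final_model,
        stability=stability,
        fd_cutpoint=cut,
        km_fd_groups=km,
        km_coordinates=pd.DataFrame(km_rows),
        cohort=cohort,
    )
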