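"""Pipeline orchestration: simulate -> motor -> patterns -> classify.

Runs the analysis chain from a single configuration with stage toggles,
writes CSV/JSON outputs per stage, and emits a RunRecord (config hash, seed,
version, per-stage wall time, warnings) next to every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aal import MotorROISet, MOTOR_LABELS
from .classify import nested_loocv
from .io import load_cohort, save_cohort
from .motor import correlate_off_with_updrs, motor_eigenvariate_scores, \
    on_off_subnetwork_test, seed_posthoc_tests
from .patterns import correlate_patterns_with_cognition, elbow_components, \
    pca_patterns, vectorize_edges
from .synthetic import CohortSpec, T_SCORE_NAMES, generate_fc_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str = "dbsnet_out"
    manifest: str | None = None  # load an existing cohort instead of simulating
    metadata: str | None = None
    simulate: bool = True
    motor: bool = True
    patterns: bool = True
    classify: bool = True
    n_subjects: int = 43
    roi_count: int = 90
    q: float = 0.05
    covariate_columns: tuple = ("age", "gender")
    repetitions: int = 100
    criterion: str = "mean"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must lie in (0, 1)")


@dataclass
class RunRecord:
    config_hash: str
    seed: int
    version: str
    stage_seconds: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _covariate_matrix(meta: pd.DataFrame, columns) -> np.ndarray | None:
    if not columns:
        return None
    cols = []
    for c in columns:
        v = meta[c]
        if v.dtype == object:
            v = (v == "F").astype(float)  # 0/1 indicator for gender
        cols.append(v.to_numpy(dtype=float))
    return np.column_stack(cols)


def run_pipeline(config: PipelineConfig) -> RunRecord:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True, default=str)
    record = RunRecord(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        seed=config.seed,
        version=__version__,
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        t0 = time.perf_counter()
        if config.simulate:
            spec = CohortSpec(n_subjects=config.n_subjects,
                              roi_count=config.roi_count, seed=config.seed)
            cohort = generate_fc_cohort(spec)
            save_cohort(cohort, out / "cohort")
            subjects, bands, meta = cohort.subjects, cohort.bands, cohort.metadata
        elif config.manifest:
            subjects, bands, _labels, meta = load_cohort(config.manifest, config.metadata)
        else:
            raise ValueError("either simulate=True or a manifest path is required")
        record.stage_seconds["load"] = round(time.perf_counter() - t0, 3)

        covars = _covariate_matrix(meta, config.covariate_columns)
        rois = _motor_rois(subjects, bands)

        if config.motor:
            t0 = time.perf_counter()
            results, mask, summaries = on_off_subnetwork_test(
                subjects, bands, rois, covariates=covars, q=config.q
            )
            band_names = [b.name for b in bands]
            table = pd.DataFrame(
                {
                    "band": band_names,
                    "statistic": [results[b].statistic for b in band_names],
                    "p": [results[b].p_value for b in band_names],
                    "significant": mask,
                }
            )
            table.to_csv(out / "motor_band_tests.csv", index=False)
            corr_rows = []
            for k, name in enumerate(band_names):
                if not mask[k]:
                    continue
                posthoc, ph_mask = seed_posthoc_tests(
                    subjects, name, rois, covariates=covars, q=config.q
                )
                pd.DataFrame(
                    {
                        "roi": list(rois.labels),
                        "p": [posthoc[lab].p_value for lab in rois.labels],
                        "significant": ph_mask,
                    }
                ).to_csv(out / f"motor_seed_posthoc_{name}.csv", index=False)
                _on, s_off, summ = motor_eigenvariate_scores(subjects, name, rois)
                res = correlate_off_with_updrs(
                    s_off, meta["updrs_diff"].to_numpy(), covariates=covars
                )
                corr_rows.append(
                    {"band": name, "rho": res.effect, "p": res.p_value, "n": res.n,
                     "variance_explained": summ.variance_explained}
                )
                np.savetxt(out / f"motor_loadings_{name}.csv",
                           summ.loading_matrix(len(rois.labels)), delimiter=",")
            if corr_rows:
                pd.DataFrame(corr_rows).to_csv(out / "motor_updrs_correlation.csv",
                                               index=False)
            record.stage_seconds["motor"] = round(time.perf_counter() - t0, 3)

        if config.patterns:
            t0 = time.perf_counter()
            grids = []
            for band in bands:
                on_rows = np.asarray(
                    [vectorize_edges(s.fc[(band.name, "ON")].values).values
                     for s in subjects]
                )
                pr = pca_patterns(on_rows, band=band.name)
                n_sel = elbow_components(pr.variance_explained, repetitions=100,
                                         seed=config.seed)
                pr.n_selected = n_sel
                pd.DataFrame(
                    {"component": np.arange(pr.variance_explained.size),
                     "variance_explained": pr.variance_explained}
                ).to_csv(out / f"scree_{band.name}.csv", index=False)
                t_frame = pd.DataFrame(
                    {k: [s.t_scores.get(k, np.nan) for s in subjects]
                     for k in T_SCORE_NAMES}
                )
                grid = correlate_patterns_with_cognition(
                    pr.scores[:, :n_sel], t_frame, covariates=covars, q=config.q
                )
                grid.insert(0, "band", band.name)
                grids.append(grid)
            pd.concat(grids, ignore_index=True).to_csv(
                out / "pattern_cognition_correlations.csv", index=False
            )
            if len(subjects[0].fc[(bands[0].name, "OFF")].values) == 90:
                from .aal import AAL90_LABELS, hemisphere_lobe_ordering, lobe_of

                order = hemisphere_lobe_ordering()
                pd.DataFrame(
                    {
                        "position": np.arange(len(order)),
                        "roi_index": order,
                        "roi_label": [AAL90_LABELS[i] for i in order],
                        "lobe": [lobe_of(AAL90_LABELS[i]) for i in order],
                    }
                ).to_csv(out / "figure_roi_ordering.csv", index=False)
            record.stage_seconds["patterns"] = round(time.perf_counter() - t0, 3)

        if config.classify:
            t0 = time.perf_counter()
            report = nested_loocv(
                subjects, bands, repetitions=config.repetitions,
                seed=config.seed, criterion=config.criterion, C=config.svm_c,
            )
            (out / "classification_report.json").write_text(
                json.dumps(
                    {
                        "ppv": report.ppv,
                        "npv": report.npv,
                        "sensitivity": report.sensitivity,
                        "specificity": report.specificity,
                        "final_threshold": report.final_threshold,
                        "chosen_thresholds": report.chosen_thresholds,
                        "n_profile_edges": len(report.final_profile),
                        "n_unclassifiable": report.n_unclassifiable,
                    },
                    indent=1,
                )
            )
            pd.DataFrame(
                [
                    {"band": e.band, "roi_i": e.edge[0], "roi_j": e.edge[1],
                     "direction": e.direction}
                    for e in report.final_profile.entries
                ]
            ).to_csv(out / "final_profile.csv", index=False)
            record.stage_seconds["classify"] = round(time.perf_counter() - t0, 3)

        record.warnings = [str(w.message) for w in caught]

    (out / "run_record.json").write_text(json.dumps(asdict(record), indent=1))
    return record


def _motor_rois(subjects, bands) -> MotorROISet:
    """Motor ROI set matched to the cohort's parcellation size."""
    n = subjects[0].fc[(bands[0].name, "OFF")].values.shape[0]
    if n >= 90:
        from .aal import AAL90_LABELS
        return MotorROISet.from_labels(list(AAL90_LABELS))
    return MotorROISet(
        labels=MOTOR_LABELS,
        indices=tuple(range(14)),
    )
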