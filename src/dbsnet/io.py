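"""Cohort serialization: metadata CSV, delimited FC matrices, JSON manifest.

A cohort on disk is a directory with ``metadata.csv`` (one row per subject),
one tab-delimited matrix file per subject/band/condition with ROI labels as
the header row, a ``manifest.json`` tying files to bands and conditions, and
— for synthetic cohorts only — a ``ground_truth.json`` that no analysis
stage ever reads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BandSpec, FCMatrix
from .synthetic import SubjectRecord, SyntheticCohort, T_SCORE_NAMES

__all__ = ["save_cohort", "load_cohort", "GROUND_TRUTH_FILE"]

GROUND_TRUTH_FILE = "ground_truth.json"


def _matrix_filename(sub_id: str, band: str, condition: str) -> str:
    return f"{sub_id}_band-{band}_cond-{condition}.tsv"


def save_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort directory; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    files = {}
    header = "\t".join(cohort.roi_labels)
    for sub in cohort.subjects:
        for (band, cond), fc in sub.fc.items():
            name = _matrix_filename(sub.id, band, cond)
            np.savetxt(out / name, fc.values, delimiter="\t", header=header,
                       comments="", fmt="%.8g")
            files[f"{sub.id}|{band}|{cond}"] = name
    manifest = {
        "roi_labels": list(cohort.roi_labels),
        "bands": [{"name": b.name, "lo": b.lo, "hi": b.hi} for b in cohort.bands],
        "conditions": ["ON", "OFF"],
        "subjects": [s.id for s in cohort.subjects],
        "metadata": "metadata.csv",
        "files": files,
        "seed": cohort.spec.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / GROUND_TRUTH_FILE).write_text(json.dumps(cohort.ground_truth, indent=1))
    return out / "manifest.json"


def load_cohort(manifest_path, metadata_path=None):
    """Load subjects from a cohort directory; validates every FC matrix.

    Returns (subjects, bands, roi_labels, metadata frame). Matrix symmetry,
    range, and zero diagonal are enforced on load; a violation raises with
    the offending file named.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    bands = tuple(BandSpec(b["name"], b["lo"], b["hi"]) for b in manifest["bands"])
    roi_labels = tuple(manifest["roi_labels"])
    meta_file = Path(metadata_path) if metadata_path else root / manifest["metadata"]
    meta = pd.read_csv(meta_file)
    meta = meta.set_index("id", drop=False)

    subjects = []
    for sub_id in manifest["subjects"]:
        if sub_id not in meta.index:
            raise KeyError(f"subject {sub_id} missing from {meta_file}")
        row = meta.loc[sub_id]
        fc = {}
        for band in bands:
            for cond in manifest["conditions"]:
                key = f"{sub_id}|{band.name}|{cond}"
                if key not in manifest["files"]:
                    raise KeyError(f"manifest lacks an entry for {key}")
                path = root / manifest["files"][key]
                if not path.exists():
                    raise FileNotFoundError(f"manifest references missing file {path}")
                values = np.loadtxt(path, delimiter="\t", skiprows=1)
                try:
                    fc[(band.name, cond)] = FCMatrix(values, band=band, condition=cond)
                except ValueError as err:
                    raise ValueError(f"invalid FC matrix in {path}: {err}") from err
        updrs_on, updrs_off = int(row["updrs_on"]), int(row["updrs_off"])
        if "updrs_diff" in row and int(row["updrs_diff"]) != updrs_on - updrs_off:
            raise ValueError(f"subject {sub_id}: inconsistent updrs_diff on load")
        subjects.append(
            SubjectRecord(
                id=sub_id,
                age=float(row["age"]),
                gender=str(row["gender"]),
                updrs_on=updrs_on,
                updrs_off=updrs_off,
                t_scores={k: float(row[f"t_{k}"]) for k in T_SCORE_NAMES
                          if f"t_{k}" in row},
                fc=fc,
            )
        )
    return subjects, bands, roi_labels, meta.reset_index(drop=True)
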