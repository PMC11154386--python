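"""Plain-text readers and writers for the pipeline's on-disk formats.

Cohorts are stored as one tab-separated channel-by-sample matrix per
measure per subject (no header), a JSON event/metadata sidecar per
subject, and a cohort-level manifest. Feature tables, rankings, QC
reports and post hoc tables are TSV with headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Event, Recording
from .qc import ChannelQCReport
from .synth import Cohort, SubjectData

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_qc_reports",
    "write_feature_table",
    "read_feature_table",
    "write_ranking",
    "write_cv_report",
]

_MEASURE_FILES = {"HBO2": "hbo2", "HHB": "hhb"}


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write `<subject>_<measure>.tsv` matrices, `<subject>_events.json`
    sidecars and a `manifest.json`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "sampling_rate": cohort.protocol.sampling_rate,
        "n_channels": cohort.protocol.n_channels,
        "subjects": [],
    }
    for sub in cohort.subjects:
        for rec, tag in ((sub.hbo2, "hbo2"), (sub.hhb, "hhb")):
            np.savetxt(
                out / f"{sub.subject_id}_{tag}.tsv",
                rec.data,
                delimiter="\t",
                fmt="%.6g",
            )
        sidecar = {
            "subject_id": sub.subject_id,
            "sampling_rate": sub.hbo2.sampling_rate,
            "events": [ev.to_dict() for ev in sub.hbo2.events],
            "faulty_channels": sub.truth.get("faulty_channels", []),
            "artifact_channels": sub.truth.get("artifact_channels", []),
            "condition_order": sub.truth.get("condition_order", []),
        }
        (out / f"{sub.subject_id}_events.json").write_text(
            json.dumps(sidecar, indent=1)
        )
        manifest["subjects"].append(sub.subject_id)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(indir: str | Path) -> list[SubjectData]:
    """Read a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    subjects = []
    for sid in manifest["subjects"]:
        sidecar = json.loads((indir / f"{sid}_events.json").read_text())
        events = [Event(**ev) for ev in sidecar["events"]]
        fs = sidecar["sampling_rate"]
        recs = {}
        for measure, tag in _MEASURE_FILES.items():
            data = np.loadtxt(indir / f"{sid}_{tag}.tsv", delimiter="\t", ndmin=2)
            recs[measure] = Recording(
                measure=measure,
                data=data,
                sampling_rate=fs,
                events=events,
                subject_id=sid,
            )
        truth = {
            "faulty_channels": sidecar.get("faulty_channels", []),
            "artifact_channels": sidecar.get("artifact_channels", []),
            "condition_order": sidecar.get("condition_order", []),
        }
        subjects.append(SubjectData(sid, recs["HBO2"], recs["HHB"], truth))
    return subjects


def write_qc_reports(reports: list[ChannelQCReport], outdir: str | Path) -> Path:
    """Per-channel TSV plus a JSON cohort summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "subject": r.subject_id,
            "channel": c.channel,
            "rr_value": c.rr_value,
            "retained": c.retained,
            "reject_reason": c.reject_reason,
        }
        for r in reports
        for c in r.channels
    ]
    pd.DataFrame(rows).to_csv(out / "qc_channels.tsv", sep="\t", index=False)
    summary = {
        r.subject_id: {
            "n_input_channels": r.n_input_channels,
            "n_retained": r.n_retained,
            "removed_fraction": r.removed_fraction,
            "subject_excluded": r.subject_excluded,
            "retained_indices": r.retained_indices,
        }
        for r in reports
    }
    (out / "qc_summary.json").write_text(json.dumps(summary, indent=1))
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ranking(ranking, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "rank": i + 1,
            "feature": f,
            "score": ranking.scores[f],
            "relevance": ranking.relevance[f],
            "redundancy": ranking.redundancy[f],
        }
        for i, f in enumerate(ranking.ordered_features)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_cv_report(report, outdir: str | Path, tag: str = "cv") -> Path:
    """JSON with per-fold confusions plus a TSV summary row."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "class_labels": list(report.class_labels),
        "mean": report.mean,
        "std": report.std,
        "pooled_confusion": report.pooled_confusion.tolist(),
        "folds": [
            {
                "held_out_subject": f.held_out_subject,
                "confusion": f.confusion.tolist(),
                "metrics": f.metrics,
                "selected_features": f.selected_features,
            }
            for f in report.folds
        ],
    }
    (out / f"{tag}_report.json").write_text(json.dumps(payload, indent=1))
    summary = pd.DataFrame(
        [
            {
                metric: f"{report.mean[metric]:.2f} ± {report.std[metric]:.2f}"
                for metric in ("accuracy", "sensitivity", "specificity", "f1")
            }
        ]
    )
    summary.to_csv(out / f"{tag}_summary.tsv", sep="\t", index=False)
    return out
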