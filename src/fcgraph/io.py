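"""Plain-text readers/writers for the pipeline's file dialects.

Time series: TSV, T rows x N columns, header = node ids, with a JSON
sidecar for acquisition metadata.  Motion: 6-column whitespace-delimited
text (mm, mm, mm, rad, rad, rad).  Connectivity matrices and metric/result
tables: TSV/CSV.  All writers are deterministic (fixed float format), so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fcgraph.preprocess import MotionParams, NuisanceSet, RoiTimeSeries

FLOAT_FMT = "%.10g"


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    path = Path(path)
    header = "\t".join(str(i) for i in range(ts.n_nodes))
    np.savetxt(path, ts.data, fmt=FLOAT_FMT, delimiter="\t", header=header, comments="")
    meta = {
        "subject_id": ts.subject_id,
        "visit_id": ts.visit_id,
        "tr": ts.tr,
        "n_discarded_lead": ts.n_discarded_lead,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_timeseries(path) -> RoiTimeSeries:
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return RoiTimeSeries(
        data=data,
        tr=float(meta.get("tr", 1.0)),
        subject_id=meta.get("subject_id", ""),
        visit_id=meta.get("visit_id", ""),
        n_discarded_lead=int(meta.get("n_discarded_lead", 0)),
    )


def write_motion(motion: MotionParams, path) -> None:
    np.savetxt(path, motion.params, fmt=FLOAT_FMT, delimiter=" ")


def read_motion(path) -> MotionParams:
    return MotionParams(params=np.loadtxt(path))


def write_nuisance(nuis: NuisanceSet, path) -> None:
    np.savetxt(path, nuis.regressors, fmt=FLOAT_FMT, delimiter="\t")


def read_nuisance(path) -> NuisanceSet:
    return NuisanceSet(regressors=np.loadtxt(path, delimiter="\t"))


def write_connectivity(cm, path) -> None:
    n = cm.n_nodes
    df = pd.DataFrame(cm.weights, index=range(n), columns=range(n))
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="node_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort in the same dialects the real-data loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (subject, visit), ts in sorted(cohort.timeseries.items()):
        stem = f"{subject}_{visit}"
        write_timeseries(ts, out / f"{stem}_ts.tsv")
        write_motion(cohort.motion[(subject, visit)], out / f"{stem}_motion.txt")
        write_nuisance(cohort.nuisance[(subject, visit)], out / f"{stem}_nuisance.tsv")
    cohort.covariates.to_csv(out / "covariates.csv", index=False, float_format=FLOAT_FMT)
    atlas = cohort.config.atlas
    atlas.table.to_csv(out / "atlas.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
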