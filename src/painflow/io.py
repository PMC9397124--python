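"""On-disk format contracts: tab-separated tables throughout.

Per-run time series are TSVs with one row per TR and one column per node
label; confounds use the fMRIPrep column dialect; events are BIDS-style
(onset, duration, trial_type); the partition and the study manifest are
plain TSVs.  Long-format TSV is the universal inter-stage format for metric
and result tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CommunityPartition, ParcelRun, RunRecord, StudyBundle

MANIFEST_NAME = "manifest.tsv"
PARTITION_NAME = "partition.tsv"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(bundle: StudyBundle, outdir) -> Path:
    """Write a study bundle as a directory of TSVs; returns the manifest path.

    Layout: one ``<subject>_<site>_run-<k>_{timeseries,confounds,events}.tsv``
    triple per run, plus ``partition.tsv`` and ``manifest.tsv`` (one row per
    run with subject, group, age, site, run and relative file paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in bundle.records:
        run = rec.run
        stem = run.key
        ts_path = f"{stem}_timeseries.tsv"
        conf_path = f"{stem}_confounds.tsv"
        ev_path = f"{stem}_events.tsv"
        ts = pd.DataFrame(run.signals.T, columns=run.node_labels)
        write_tsv(ts, outdir / ts_path)
        write_tsv(rec.confounds, outdir / conf_path)
        write_tsv(rec.events, outdir / ev_path)
        rows.append(
            {
                "subject": run.subject,
                "group": run.group,
                "age": bundle.age_of(run.subject),
                "site": run.site,
                "run": run.run,
                "tr_seconds": run.tr_seconds,
                "timeseries": ts_path,
                "confounds": conf_path,
                "events": ev_path,
            }
        )
    write_tsv(bundle.partition.to_frame(), outdir / PARTITION_NAME)
    write_tsv(pd.DataFrame(rows), outdir / MANIFEST_NAME)
    if bundle.truth:
        (outdir / "truth.json").write_text(json.dumps(bundle.truth, indent=2))
    return outdir / MANIFEST_NAME


def load_study(directory) -> StudyBundle:
    """Load a study bundle from a directory written by :func:`write_study`.

    Every referenced file must exist and parse; a missing file fails
    immediately, naming the run.
    """
    directory = Path(directory)
    manifest = read_tsv(directory / MANIFEST_NAME)
    required = {"subject", "group", "age", "site", "run", "tr_seconds",
                "timeseries", "confounds", "events"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest is missing columns: {sorted(missing_cols)}")
    partition = CommunityPartition.from_frame(read_tsv(directory / PARTITION_NAME))

    records = []
    for _, row in manifest.iterrows():
        key = f"{row['subject']}_{row['site']}_run-{row['run']}"
        for col in ("timeseries", "confounds", "events"):
            if not (directory / row[col]).exists():
                raise FileNotFoundError(
                    f"run {key}: manifest references missing file {row[col]!r}"
                )
        ts = read_tsv(directory / row["timeseries"])
        run = ParcelRun(
            signals=ts.to_numpy().T,
            node_labels=list(ts.columns),
            tr_seconds=float(row["tr_seconds"]),
            subject=str(row["subject"]),
            group=str(row["group"]),
            site=str(row["site"]),
            run=int(row["run"]),
        )
        records.append(
            RunRecord(
                run=run,
                confounds=read_tsv(directory / row["confounds"]),
                events=read_tsv(directory / row["events"]),
            )
        )
    subject_rows = manifest[["subject", "group", "age"]].drop_duplicates("subject")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return StudyBundle(
        records=records,
        partition=partition,
        manifest=subject_rows.reset_index(drop=True),
        truth=truth,
    )
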