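"""Nuisance regression and motion-based run exclusion.

The confound set regressed from every parcel series: six head-motion
parameters and their derivatives, six anatomical-noise components, white
matter, CSF, and framewise displacement — plus an intercept, so residuals
are mean-zero (a prerequisite for correlation-based connectivity).  Runs
whose mean framewise displacement exceeds 0.5 are excluded before analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import ParcelRun, RunRecord

FD_COLUMN = "framewise_displacement"
DEFAULT_FD_THRESHOLD = 0.5


def qc_exclude_runs(
    records: list[RunRecord], fd_threshold: float = DEFAULT_FD_THRESHOLD
) -> tuple[list[RunRecord], pd.DataFrame]:
    """Drop runs whose mean framewise displacement strictly exceeds the threshold.

    Returns the kept records and a report listing every input run with its
    mean FD and kept/dropped status (kept + dropped partition the input).
    A record without an FD column fails, naming the run.
    """
    kept, rows = [], []
    for rec in records:
        if FD_COLUMN not in rec.confounds.columns:
            raise ValueError(
                f"run {rec.run.key}: confound table has no "
                f"'{FD_COLUMN}' column"
            )
        mean_fd = float(rec.confounds[FD_COLUMN].mean())
        keep = not mean_fd > fd_threshold  # strict: exactly-at-threshold kept
        if keep:
            kept.append(rec)
        rows.append(
            {
                "subject": rec.run.subject,
                "site": rec.run.site,
                "run": rec.run.run,
                "mean_fd": mean_fd,
                "kept": keep,
            }
        )
    return kept, pd.DataFrame(rows)


def regress_confounds(run: ParcelRun, confounds: pd.DataFrame) -> ParcelRun:
    """OLS-residualize every node series on the full confound set plus intercept.

    Exact-duplicate confound columns are dropped before fitting.  If the
    design is still rank-deficient the call fails listing the collinear
    columns.  Residuals are mean-zero and orthogonal to every retained
    regressor.
    """
    if len(confounds) != run.n_trs:
        raise ValueError(
            f"run {run.key}: confounds have {len(confounds)} rows, "
            f"run has {run.n_trs} TRs"
        )
    arr = confounds.to_numpy(dtype=float)
    seen: dict[bytes, int] = {}
    keep_cols = []
    for j, col in enumerate(confounds.columns):
        if np.ptp(arr[:, j]) == 0:
            continue  # constant column: redundant with the intercept
        key = arr[:, j].tobytes()
        if key not in seen:
            seen[key] = j
            keep_cols.append(col)
    conf = confounds[keep_cols]
    names = ["intercept"] + list(conf.columns)
    X = np.column_stack([np.ones(run.n_trs), conf.to_numpy(dtype=float)])

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved: those whose removal restores full rank
        collinear = []
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(names[j])
        raise ValueError(
            f"run {run.key}: confound design is rank-deficient after "
            f"duplicate-dropping; collinear columns: {collinear}"
        )

    beta, *_ = np.linalg.lstsq(X, run.signals.T, rcond=None)
    residuals = run.signals.T - X @ beta
    return dataclasses.replace(run, signals=residuals.T)
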