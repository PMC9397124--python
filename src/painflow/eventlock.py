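"""Event-locked binning of metric time series around stimulus onsets.

Each stimulus onset is mapped to the TR during which stimulation begins
(floor of onset / TR).  Around each onset TR o, the six bins
{o-2, o-1, o, o+1, o+2, o+3} are extracted; trials whose window leaves the
run are dropped (never padded) and counted.  Per subject and site, values
are averaged trials -> runs -> site (nested), or with trials of both runs
pooled in the sensitivity mode.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_BINS = (-2, 3)


def onsets_to_trs(
    events: pd.DataFrame, tr_seconds: float, condition: str | None = "painful"
) -> np.ndarray:
    """Onset TR indices of the events matching ``condition``.

    ``condition=None`` keeps every event.  The onset maps to
    ``floor(onset / tr_seconds)`` — the TR during which stimulation begins.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    sel = events if condition is None else events[events["trial_type"] == condition]
    onsets = sel["onset"].to_numpy(dtype=float)
    if (onsets < 0).any():
        raise ValueError("negative event onset")
    return np.floor(onsets / tr_seconds).astype(int)


def bin_events(
    series: np.ndarray,
    onset_idx: np.ndarray,
    n_trs: int,
    bins: tuple[int, int] = DEFAULT_BINS,
) -> tuple[np.ndarray, int]:
    """Per-trial peristimulus windows from a unit x TR metric matrix.

    Returns ``(trials, n_dropped)`` where ``trials`` has shape
    (n_kept, n_units, n_bins) holding, for each surviving onset o, the TRs
    ``o + bins[0] .. o + bins[1]``.  Trials whose window falls partly outside
    ``[0, n_trs)`` are dropped and counted.  Zero surviving trials is an
    error.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    onset_idx = np.asarray(onset_idx, dtype=int)
    if onset_idx.size and (onset_idx.min() < 0 or onset_idx.max() >= n_trs):
        raise ValueError("onset indices must lie within [0, n_trs)")
    lo, hi = bins
    offsets = np.arange(lo, hi + 1)
    keep = (onset_idx + lo >= 0) & (onset_idx + hi <= n_trs - 1)
    kept = onset_idx[keep]
    if kept.size == 0:
        raise ValueError(
            f"no trials survive the peristimulus window {bins} in a "
            f"{n_trs}-TR run"
        )
    windows = kept[:, None] + offsets[None, :]  # (n_kept, n_bins)
    trials = series[:, windows]  # (n_units, n_kept, n_bins)
    return np.moveaxis(trials, 1, 0), int((~keep).sum())


def average_trials_and_runs(
    run_trials: list[np.ndarray], mode: str = "nested"
) -> tuple[np.ndarray, dict]:
    """Collapse one subject/site's per-run trial arrays to a unit x bin mean.

    ``"nested"`` (default): mean over trials within each run, then mean of
    the site's runs — a subject left with a single run after QC exclusion
    still contributes, flagged ``single_run``.  ``"pooled"`` pools all
    trials of the site's runs into one mean.
    """
    if not run_trials:
        raise ValueError("no runs to average")
    if mode == "nested":
        run_means = [t.mean(axis=0) for t in run_trials]
        value = np.mean(run_means, axis=0)
    elif mode == "pooled":
        value = np.concatenate(run_trials, axis=0).mean(axis=0)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    meta = {
        "n_runs": len(run_trials),
        "n_trials": int(sum(t.shape[0] for t in run_trials)),
        "single_run": len(run_trials) == 1,
    }
    return value, meta


def event_locked_frame(
    values: np.ndarray,
    unit_labels: list[str],
    bins: tuple[int, int],
    *,
    subject: str,
    group: str,
    site: str,
    level: str,
    metric: str,
    meta: dict,
) -> pd.DataFrame:
    """Long-format rows (subject, site, level, unit, metric, bin, value, ...)."""
    lo, hi = bins
    bin_labels = list(range(lo, hi + 1))
    units = np.repeat(unit_labels, len(bin_labels))
    return pd.DataFrame(
        {
            "subject": subject,
            "group": group,
            "site": site,
            "level": level,
            "unit": units,
            "metric": metric,
            "bin": np.tile(bin_labels, len(unit_labels)),
            "value": np.asarray(values, dtype=float).ravel(),
            "n_trials": meta.get("n_trials"),
            "single_run": meta.get("single_run", False),
        }
    )
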