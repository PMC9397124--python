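"""End-to-end orchestration: denoise -> TVC -> metrics -> event-locking -> stats.

``run_all`` executes the full analysis on a :class:`StudyBundle` (in memory
or loaded from a study directory), at both spatial scales (community and
nodal) and for both contrasts (group and site), writing long-format TSVs and
a provenance record when an output directory is given.  All computation is
deterministic given the inputs and the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import StudyBundle
from .denoise import qc_exclude_runs, regress_confounds
from .eventlock import (
    average_trials_and_runs,
    bin_events,
    event_locked_frame,
    onsets_to_trs,
)
from .groupstats import group_contrast_table, site_contrast_table
from .io import load_study, write_tsv
from .netmetrics import community_medians, extract_nodes, node_metric_series
from .tvc import flow_from_run


@dataclass
class ResultsBundle:
    """Everything the pipeline computes for one study."""

    qc_report: pd.DataFrame
    event_locked: pd.DataFrame  # long format, all levels/metrics/sites
    stats: dict[tuple[str, str, str], pd.DataFrame]  # (contrast, level, metric)
    config: PipelineConfig
    provenance: dict = field(default_factory=dict)


def _metric_units(bundle: StudyBundle, config: PipelineConfig):
    nodes = list(config.nodes) if config.nodes else []
    return nodes


def run_all(
    study: StudyBundle | str | Path,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> ResultsBundle:
    """Run the whole pipeline on a study bundle or study directory.

    Stages: QC run exclusion (mean FD), confound regression, jackknife
    correlation + flow standardization, PC / within-module z per TR,
    community medians and nodal extraction, event-locked binning around
    painful onsets with nested trial/run averaging per site, then the group
    ANCOVA and the site mixed model per unit x post-onset bin with BH-FDR.
    Any stage failure aborts naming the stage and the offending run.
    """
    config = config or PipelineConfig()
    bundle = load_study(study) if not isinstance(study, StudyBundle) else study
    partition = bundle.partition

    kept, qc_report = qc_exclude_runs(bundle.records, config.fd_threshold)
    if not kept:
        raise RuntimeError("qc: every run was excluded by the FD criterion")

    requested_nodes = _metric_units(bundle, config)
    rows = []
    # accumulate per-(subject, site) lists of per-run trial arrays
    acc: dict[tuple, dict[str, dict[str, list[np.ndarray]]]] = {}
    unit_labels: dict[str, list[str]] = {}
    for rec in kept:
        run = rec.run
        try:
            clean = regress_confounds(run, rec.confounds)
            flow = flow_from_run(clean.signals, clean.node_labels, clean.tr_seconds)
            node_metrics = node_metric_series(flow, partition, config.z_signed)
            onsets = onsets_to_trs(rec.events, config.tr_seconds, config.condition)
            level_series: dict[str, tuple[np.ndarray, list[str]]] = {}
            for metric in config.metrics:
                if "community" in config.levels:
                    med, comm_labels = community_medians(
                        node_metrics[metric], partition
                    )
                    level_series[("community", metric)] = (med, comm_labels)
                if "nodal" in config.levels and requested_nodes:
                    series, labels = extract_nodes(
                        node_metrics[metric], partition.node_labels, requested_nodes
                    )
                    level_series[("nodal", metric)] = (series, labels)
            for (level, metric), (series, labels) in level_series.items():
                unit_labels[level] = labels
                trials, _ = bin_events(series, onsets, run.n_trs, config.bins)
                slot = acc.setdefault((run.subject, run.site), {})
                slot.setdefault((level, metric), []).append(trials)
        except Exception as err:
            raise RuntimeError(f"pipeline failed on run {run.key}: {err}") from err

    for (subject, site), per_lm in acc.items():
        group = bundle.group_of(subject)
        for (level, metric), run_trials in per_lm.items():
            value, meta = average_trials_and_runs(run_trials, config.averaging)
            rows.append(
                event_locked_frame(
                    value,
                    unit_labels[level],
                    config.bins,
                    subject=subject,
                    group=group,
                    site=site,
                    level=level,
                    metric=metric,
                    meta=meta,
                )
            )
    elm = pd.concat(rows, ignore_index=True)

    stats: dict[tuple[str, str, str], pd.DataFrame] = {}
    for level in config.levels:
        if level == "nodal" and not requested_nodes:
            continue
        for metric in config.metrics:
            if "group" in config.contrasts:
                stats[("group", level, metric)] = group_contrast_table(
                    elm,
                    metric,
                    level,
                    config.group_contrast_site,
                    bundle.manifest,
                    config.analysis_bins,
                    config.fdr_family,
                    config.alpha,
                )
            if "site" in config.contrasts:
                stats[("site", level, metric)] = site_contrast_table(
                    elm,
                    metric,
                    level,
                    config.site_contrast_group,
                    bundle.manifest,
                    config.analysis_bins,
                    config.fdr_family,
                    config.alpha,
                )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "painflow_version": __version__,
        "n_runs_in": len(bundle.records),
        "n_runs_kept": len(kept),
    }
    results = ResultsBundle(
        qc_report=qc_report,
        event_locked=elm,
        stats=stats,
        config=config,
        provenance=provenance,
    )
    if outdir is not None:
        write_results(results, outdir)
    return results


def write_results(results: ResultsBundle, outdir: str | Path) -> Path:
    """Write all result tables, each stamped with the configuration hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = results.provenance["config_hash"]
    qc = results.qc_report.copy()
    qc["config_hash"] = h
    write_tsv(qc, outdir / "qc_report.tsv")
    elm = results.event_locked.copy()
    elm["config_hash"] = h
    write_tsv(elm, outdir / "event_locked.tsv")
    for (contrast, level, metric), table in results.stats.items():
        t = table.copy()
        t["config_hash"] = h
        write_tsv(t, outdir / f"stats_{contrast}_{level}_{metric}.tsv")
    (outdir / "provenance.json").write_text(
        json.dumps(results.provenance, indent=2, sort_keys=True)
    )
    return outdir


def check_config_hash(directory: str | Path) -> str:
    """Verify all outputs in a directory share one config hash; return it."""
    directory = Path(directory)
    hashes = set()
    for path in sorted(directory.glob("*.tsv")):
        df = pd.read_csv(path, sep="\t", usecols=lambda c: c == "config_hash")
        hashes.update(df["config_hash"].unique())
    if len(hashes) > 1:
        raise ValueError(
            f"outputs in {directory} mix configurations: {sorted(hashes)}"
        )
    if not hashes:
        raise ValueError(f"no stamped outputs found in {directory}")
    return hashes.pop()
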