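"""Synthetic evoked-pain fMRI studies with known ground-truth network dynamics.

No raw data from the emulated study are available, so every pipeline stage is
exercised on simulated studies whose integration dynamics are known by
construction.  A study consists of, per subject, four runs (two stimulation
sites x two runs): a parcellated signal matrix from a modular factor model,
an fMRIPrep-dialect confound table, and a jittered event table of painful and
non-painful pressure stimuli.  Painful events transiently raise the weight of
a global factor shared by all nodes, which elevates between-community
coupling in a hemodynamically lagged window — more strongly in the "patient"
group.  See :class:`painflow.config.SimConfig` for the signal model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import CommunityPartition, ParcelRun, RunRecord, StudyBundle

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
#: head-radius (mm) used to convert rotations to arc length in FD
FD_HEAD_RADIUS_MM = 50.0

_SITES = ("joint", "thumb")
_RUNS_PER_SITE = 2


def simulate_events(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one run's jittered stimulus schedule.

    Inter-onset intervals are uniform on ``cfg.isi_range_s`` (the first onset
    is offset from the run start by one such draw).  Exactly ``cfg.n_painful``
    of the ``cfg.n_events_per_run`` events are labelled painful, in
    pseudo-randomized order.  Unless ``cfg.allow_edge_events``, schedules
    whose last onset leaves less than 3 TRs of run are redrawn, so intervals
    stay uniform conditional on the schedule fitting the run.
    """
    n = cfg.n_events_per_run
    lo, hi = cfg.isi_range_s
    if n * lo > cfg.run_duration_s:
        raise ValueError(
            f"run too short for {n} events: minimum schedule needs "
            f"{n * lo:.1f} s but the run lasts {cfg.run_duration_s:.1f} s"
        )
    limit = cfg.run_duration_s - (0 if cfg.allow_edge_events else 3 * cfg.tr_seconds)
    for _ in range(10_000):
        onsets = np.cumsum(rng.uniform(lo, hi, size=n))
        if onsets[-1] <= limit:
            break
    else:
        raise ValueError(
            f"could not fit {n} events with intervals in [{lo}, {hi}] s into a "
            f"{cfg.run_duration_s:.1f} s run (limit {limit:.1f} s)"
        )
    labels = np.array(["painful"] * cfg.n_painful
                      + ["non-painful"] * (n - cfg.n_painful), dtype=object)
    rng.shuffle(labels)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(n, cfg.stim_duration_s),
            "trial_type": labels,
        }
    )


def _boosted_weight(cfg: SimConfig, events: pd.DataFrame, boost: float) -> np.ndarray:
    """Per-TR global-factor variance weight a(t), boosted after painful onsets.

    The boost covers the closed TR interval
    ``[onset_tr + hemo_lag_trs, onset_tr + hemo_lag_trs + boost_window_trs]``,
    clipped to the run.
    """
    a = np.full(cfg.n_trs, cfg.between_r)
    painful = events.loc[events["trial_type"] == "painful", "onset"]
    for onset in painful:
        start = int(onset // cfg.tr_seconds) + cfg.hemo_lag_trs
        stop = start + cfg.boost_window_trs + 1  # closed interval
        a[max(start, 0): min(stop, cfg.n_trs)] += boost
    return a


def simulate_run(
    cfg: SimConfig,
    group: str,
    events: pd.DataFrame,
    rng: np.random.Generator,
    confound_signal: np.ndarray | None = None,
    *,
    subject: str = "sub-00",
    site: str = "joint",
    run: int = 1,
) -> ParcelRun:
    """Generate one run's node x TR signal matrix from the modular factor model.

    ``confound_signal`` is a unit-variance per-TR composite (typically built
    from the run's simulated motion) mixed in with weight
    ``cfg.confound_loading``; pass ``None`` for confound-free signals.
    """
    boost = cfg.event_boost_patient if group == "RA" else cfg.event_boost_control
    a = _boosted_weight(cfg, events, boost)
    # the boost reallocates coupling from the community factor to the global
    # factor: between-community correlation rises to between_r + boost while
    # within-community correlation stays at within_r — an integration change,
    # not a global amplitude change (which per-edge standardization would
    # erase from the participation coefficient)
    b = cfg.within_r - a
    w = cfg.confound_loading if confound_signal is not None else 0.0
    resid = 1.0 - cfg.within_r - w
    if b.min() < 0 or resid < 0:
        raise ValueError(
            "variance budget exceeded during boost: a(t) peaks at "
            f"{a.max():.3f} with confound loading {w:.3f} "
            f"(within_r={cfg.within_r}, between_r={cfg.between_r}, "
            f"boost={boost})"
        )

    membership = np.repeat(np.arange(cfg.n_communities), cfg.community_sizes)
    g = rng.standard_normal(cfg.n_trs)
    f = rng.standard_normal((cfg.n_communities, cfg.n_trs))
    eps = rng.standard_normal((cfg.n_nodes, cfg.n_trs))
    x = (
        np.sqrt(a)[None, :] * g[None, :]
        + np.sqrt(b)[None, :] * f[membership]
        + np.sqrt(resid) * eps
    )
    if w > 0:
        x += np.sqrt(w) * confound_signal[None, :]

    return ParcelRun(
        signals=x,
        node_labels=node_labels(cfg),
        tr_seconds=cfg.tr_seconds,
        subject=subject,
        group=group,
        site=site,
        run=run,
    )


def simulate_confounds(
    cfg: SimConfig,
    n_trs: int,
    rng: np.random.Generator,
    bad_run: bool = False,
) -> pd.DataFrame:
    """Simulate an fMRIPrep-dialect confound table.

    Motion parameters are smooth AR(1) series (translations in mm, rotations
    in radians); their ``*_derivative1`` columns are backward differences with
    a zero first row; six ``a_comp_cor_*`` components are white noise;
    ``white_matter`` and ``csf`` are AR(1).  ``framewise_displacement`` sums
    absolute backward differences of the six motion series, rotations scaled
    to arc length on a 50 mm sphere.  ``bad_run`` inflates motion so the mean
    FD exceeds 0.5, exercising the QC exclusion rule.
    """
    if n_trs < 2:
        raise ValueError("need at least 2 TRs to form motion derivatives")
    phi = 0.9
    scale = 8.0 if bad_run else 1.0

    def ar1(sd: float, n_series: int) -> np.ndarray:
        innov = rng.standard_normal((n_series, n_trs)) * sd
        out = np.empty_like(innov)
        out[:, 0] = innov[:, 0] / np.sqrt(1 - phi**2)
        for t in range(1, n_trs):
            out[:, t] = phi * out[:, t - 1] + innov[:, t]
        return out

    trans = ar1(0.02 * scale, 3)  # mm
    rot = ar1(0.0004 * scale, 3)  # radians
    motion = np.vstack([trans, rot])

    table = {}
    for name, series in zip(MOTION_COLUMNS, motion):
        table[name] = series
    for name, series in zip(MOTION_COLUMNS, motion):
        deriv = np.diff(series, prepend=series[0])
        table[f"{name}_derivative1"] = deriv
    for k in range(6):
        table[f"a_comp_cor_{k:02d}"] = rng.standard_normal(n_trs)
    table["white_matter"] = ar1(0.5, 1)[0]
    table["csf"] = ar1(0.5, 1)[0]
    table["framewise_displacement"] = framewise_displacement(motion)
    return pd.DataFrame(table)


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-convention FD from a (6, n_trs) motion array (3 trans, 3 rot).

    Sum of absolute backward differences; rotational differences (radians)
    are converted to mm of arc on a 50 mm-radius sphere.  First element 0.
    """
    diffs = np.abs(np.diff(motion, axis=1))
    fd = diffs[:3].sum(axis=0) + FD_HEAD_RADIUS_MM * diffs[3:].sum(axis=0)
    return np.concatenate([[0.0], fd])


def node_labels(cfg: SimConfig) -> list[str]:
    """Node names carrying their community, e.g. ``SalVentAttn_003``."""
    labels = []
    for comm, size in zip(cfg.community_labels, cfg.community_sizes):
        labels.extend(f"{comm}_{i + 1:03d}" for i in range(size))
    return labels


def make_partition(cfg: SimConfig) -> CommunityPartition:
    communities = np.repeat(cfg.community_labels, cfg.community_sizes)
    return CommunityPartition(node_labels=node_labels(cfg), communities=communities)


def default_nodal_selection(cfg: SimConfig, n_nodes: int = 6) -> list[str]:
    """Six nodes standing in for the pain-relevant regions (bilateral anterior
    and posterior insula, anterior cingulate): drawn from the salience and
    somatomotor communities of the synthetic parcellation."""
    labels = node_labels(cfg)
    sal = [l for l in labels if l.startswith("SalVentAttn_")][: n_nodes - 2]
    som = [l for l in labels if l.startswith("SomMot_")][:2]
    return (sal + som)[:n_nodes]


def _motion_composite(confounds: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance composite of the motion series, the signal-space trace of
    head motion that the confound regression should remove."""
    m = confounds[MOTION_COLUMNS].to_numpy().T
    m = (m - m.mean(axis=1, keepdims=True))
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    m /= sd
    weights = rng.standard_normal(m.shape[0])
    comp = weights @ m
    csd = comp.std()
    return comp / csd if csd > 0 else comp


def simulate_study(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    bad_runs: list[tuple[str, str, int]] | None = None,
) -> StudyBundle:
    """Generate a full study bundle: all subjects, runs, confounds, events.

    ``bad_runs`` lists (subject, site, run) triples whose motion is inflated
    past the FD exclusion threshold.  With a fixed ``cfg.seed`` (and no
    explicit ``rng``) the bundle is bit-identical across calls.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bad = set(bad_runs or [])

    n_total = cfg.n_patients + cfg.n_controls
    subjects = [f"sub-{i + 1:02d}" for i in range(n_total)]
    groups = ["RA"] * cfg.n_patients + ["HC"] * cfg.n_controls
    ages = rng.uniform(*cfg.age_range, size=n_total)

    records: list[RunRecord] = []
    for subject, group in zip(subjects, groups):
        for site in _SITES:
            for run_idx in range(1, _RUNS_PER_SITE + 1):
                events = simulate_events(cfg, rng)
                confounds = simulate_confounds(
                    cfg, cfg.n_trs, rng, bad_run=(subject, site, run_idx) in bad
                )
                composite = (
                    _motion_composite(confounds, rng)
                    if cfg.confound_loading > 0
                    else None
                )
                run = simulate_run(
                    cfg,
                    group,
                    events,
                    rng,
                    confound_signal=composite,
                    subject=subject,
                    site=site,
                    run=run_idx,
                )
                records.append(RunRecord(run=run, confounds=confounds, events=events))

    manifest = pd.DataFrame({"subject": subjects, "group": groups, "age": ages})
    truth = {
        "event_boost": {"RA": cfg.event_boost_patient, "HC": cfg.event_boost_control},
        "hemo_lag_trs": cfg.hemo_lag_trs,
        "boost_window_trs": cfg.boost_window_trs,
        "within_r": cfg.within_r,
        "between_r": cfg.between_r,
    }
    return StudyBundle(
        records=records,
        partition=make_partition(cfg),
        manifest=manifest,
        truth=truth,
    )
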