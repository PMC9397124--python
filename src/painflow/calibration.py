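"""Monte-Carlo calibration harnesses: type-I error under the null, power under boost.

Two study-level experiments, both driven by the synthetic generator and the
full analysis pipeline:

* :func:`null_calibration` — repeated studies with *zero* event boost in both
  groups; under this global null the group ANCOVA p-values should be uniform
  (raw rejections at ~alpha) and a Benjamini–Hochberg family should produce
  at least one false discovery in ~alpha of studies.
* :func:`effect_recovery` — repeated studies with a patient-only boost; the
  community-median PC group contrast should flag the bins covered by the
  hemodynamically lagged boost window, and the detected-bin pattern should
  track the injected lag.

Studies are scaled down relative to the emulated design (fewer subjects and
nodes) so a few hundred replicates run on one CPU; the study geometry
(4 runs, 160 TRs, 30 events) is kept.
"""

from __future__ import annotations


import numpy as np
import pandas as pd

from .config import PipelineConfig, SimConfig
from .pipeline import run_all
from .simulate import simulate_study

#: reduced-size study used by the Monte-Carlo experiments
CALIBRATION_STUDY = dict(n_patients=12, n_controls=12, n_nodes=70)

_PC_COMMUNITY = PipelineConfig(
    levels=("community",), contrasts=("group",), metrics=("pc",)
)


def _study_seed(base_seed: int, i: int) -> int:
    return int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0] % (2**31))


def run_one_study(cfg: SimConfig) -> pd.DataFrame:
    """Simulate one study and return its community-PC group-contrast table."""
    bundle = simulate_study(cfg)
    results = run_all(bundle, _PC_COMMUNITY)
    return results.stats[("group", "community", "pc")]


def null_calibration(
    n_studies: int, base_seed: int = 0, **cfg_overrides
) -> pd.DataFrame:
    """Repeated zero-boost studies; one row per study with rejection counts.

    Columns: ``study``, ``n_cells``, ``n_raw_sig`` (raw p < 0.05),
    ``n_fdr_sig`` (BH-adjusted p < 0.05), ``any_fdr_sig``.
    """
    rows = []
    for i in range(n_studies):
        cfg = SimConfig(
            **{
                **CALIBRATION_STUDY,
                "event_boost_patient": 0.0,
                "event_boost_control": 0.0,
                "seed": _study_seed(base_seed, i),
                **cfg_overrides,
            }
        )
        table = run_one_study(cfg)
        rows.append(
            {
                "study": i,
                "n_cells": len(table),
                "n_raw_sig": int((table["p"] < 0.05).sum()),
                "n_fdr_sig": int(table["significant"].sum()),
                "any_fdr_sig": bool(table["significant"].any()),
            }
        )
    return pd.DataFrame(rows)


def effect_recovery(
    n_studies: int,
    base_seed: int = 0,
    event_boost_patient: float = 0.15,
    **cfg_overrides,
) -> pd.DataFrame:
    """Repeated patient-only-boost studies; per-bin detection indicators.

    Columns: ``study``, ``boosted_bins`` (the post-onset bins the injected
    boost window covers), ``sig_bin_<b>`` (any community FDR-significant at
    bin b) for each analysed bin, and ``detected`` (any significance at a
    boosted bin).
    """
    rows = []
    for i in range(n_studies):
        cfg = SimConfig(
            **{
                **CALIBRATION_STUDY,
                "event_boost_patient": event_boost_patient,
                "event_boost_control": 0.0,
                "seed": _study_seed(base_seed, i),
                **cfg_overrides,
            }
        )
        table = run_one_study(cfg)
        boosted = boosted_bins(cfg)
        row: dict = {"study": i, "boosted_bins": tuple(boosted)}
        for b in sorted(table["bin"].unique()):
            row[f"sig_bin_{b}"] = bool(
                table.loc[table["bin"] == b, "significant"].any()
            )
        row["detected"] = any(row[f"sig_bin_{b}"] for b in boosted)
        rows.append(row)
    return pd.DataFrame(rows)


def boosted_bins(cfg: SimConfig, analysis_bins: tuple[int, ...] = (0, 1, 2, 3)) -> list[int]:
    """Post-onset bins covered by the boost window [lag, lag + window]."""
    lo = cfg.hemo_lag_trs
    hi = cfg.hemo_lag_trs + cfg.boost_window_trs
    return [b for b in analysis_bins if lo <= b <= hi]
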