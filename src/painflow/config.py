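"""Configuration objects for the synthetic study generator and the analysis pipeline.

Two dataclasses carry every tunable of the package:

* :class:`SimConfig` — the design of a simulated pressure-pain fMRI study
  (sample sizes, run geometry, event schedule, modular covariance, the
  event-locked coupling boost and its hemodynamic lag).
* :class:`PipelineConfig` — the analysis choices (QC threshold, event-locked
  bin window, condition filter, nodal selection, FDR family, averaging mode).

Both validate eagerly: an invalid field raises ``ValueError`` before any
simulation or analysis stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import yaml

#: Canonical labels of the seven large-scale resting-state communities.
CANONICAL_COMMUNITIES = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)

#: Parcel counts of the seven communities in the 400-node atlas the study
#: design uses; proportions are reused when ``n_nodes`` differs from 400.
_CANONICAL_SIZES_400 = (61, 77, 46, 47, 26, 52, 91)


def proportional_community_sizes(n_nodes: int, n_communities: int) -> list[int]:
    """Split ``n_nodes`` into ``n_communities`` parts.

    For 7 communities the split follows the canonical atlas proportions;
    otherwise it is as even as possible.  Remainders go to the largest parts
    first so the result is deterministic and sums exactly to ``n_nodes``.
    """
    if n_communities == 7:
        weights = _CANONICAL_SIZES_400
    else:
        weights = (1,) * n_communities
    total = sum(weights)
    raw = [n_nodes * w / total for w in weights]
    sizes = [int(x) for x in raw]
    # distribute the remainder by largest fractional part, ties by index
    order = sorted(range(n_communities), key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[: n_nodes - sum(sizes)]:
        sizes[i] += 1
    return sizes


@dataclass
class SimConfig:
    """Design parameters of a simulated evoked-pain fMRI study.

    Defaults reproduce the emulated study: 28 patients (RA) and 22 controls
    (HC), four runs per subject (two stimulation sites x two runs), 160
    volumes at TR = 3 s, 30 jittered pressure events per run (15 painful,
    15 non-painful, 2.5 s each, inter-onset interval uniform on 10-20 s),
    and a 7-community modular correlation structure over 400 nodes.

    The signal model is a three-factor decomposition: node *i* in community
    *c* at volume *t* is

    ``x = sqrt(a(t)) * g(t) + sqrt(b(t)) * f_c(t) + sqrt(w) * m(t)
    + sqrt(1 - within_r - w) * eps_i(t)``

    with a global factor ``g``, community factors ``f_c``, a motion/confound
    composite ``m`` (weight ``w = confound_loading``) and node noise, all
    unit-variance white draws.  Baseline ``a = between_r`` and
    ``b = within_r - a`` so that nodes correlate at ``within_r`` within and
    ``between_r`` between communities.  For the volumes in the closed window
    ``[onset + hemo_lag_trs, onset + hemo_lag_trs + boost_window_trs]`` after
    each *painful* onset, ``a(t)`` is raised by the group's ``event_boost``
    and ``b(t)`` lowered in step: between-community coupling rises to
    ``between_r + boost`` while within-community coupling stays at
    ``within_r`` — a transient shift toward integration, the quantity the
    participation coefficient measures.
    """

    n_patients: int = 28
    n_controls: int = 22
    n_nodes: int = 400
    n_communities: int = 7
    community_sizes: Sequence[int] | None = None
    n_trs: int = 160
    tr_seconds: float = 3.0
    n_events_per_run: int = 30
    n_painful: int = 15
    stim_duration_s: float = 2.5
    isi_range_s: tuple[float, float] = (10.0, 20.0)
    within_r: float = 0.35
    between_r: float = 0.05
    event_boost_patient: float = 0.15
    event_boost_control: float = 0.05
    hemo_lag_trs: int = 1
    boost_window_trs: int = 2
    confound_loading: float = 0.1
    age_range: tuple[float, float] = (23.0, 72.0)
    seed: int = 0
    #: permit events whose peristimulus window leaves the run (exercises the
    #: trial-dropping rule downstream)
    allow_edge_events: bool = False

    def __post_init__(self) -> None:
        if self.community_sizes is None:
            self.community_sizes = proportional_community_sizes(
                self.n_nodes, self.n_communities
            )
        self.community_sizes = list(self.community_sizes)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if min(self.n_patients + self.n_controls, self.n_nodes, self.n_trs) <= 0:
            raise ValueError("sample sizes, node count and TR count must be positive")
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        if len(self.community_sizes) != self.n_communities:
            raise ValueError(
                f"community_sizes has {len(self.community_sizes)} entries, "
                f"expected {self.n_communities}"
            )
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError(
                f"community_sizes sum to {sum(self.community_sizes)}, "
                f"expected n_nodes = {self.n_nodes}"
            )
        if any(s < 1 for s in self.community_sizes):
            raise ValueError("every community needs at least one node")
        if not 0 < self.n_painful <= self.n_events_per_run:
            raise ValueError("need 0 < n_painful <= n_events_per_run")
        if self.stim_duration_s <= 0:
            raise ValueError("stim_duration_s must be positive")
        lo, hi = self.isi_range_s
        if not 0 < lo <= hi:
            raise ValueError("isi_range_s must satisfy 0 < min <= max")
        if not 0 <= self.between_r < self.within_r <= 1:
            raise ValueError("need within_r > between_r >= 0 and within_r <= 1")
        if self.event_boost_patient < 0 or self.event_boost_control < 0:
            raise ValueError("event boosts must be non-negative")
        if not 0 <= self.confound_loading < 1:
            raise ValueError("confound_loading must lie in [0, 1)")
        boost = max(self.event_boost_patient, self.event_boost_control)
        if self.between_r + boost > self.within_r:
            raise ValueError(
                "boost budget exceeded: between_r + max event boost = "
                f"{self.between_r + boost:.3f} > within_r = {self.within_r:.3f} "
                "(the boost reallocates community-factor weight to the global "
                "factor, so boosted between-community coupling cannot exceed "
                "the within-community level)"
            )
        if self.within_r + self.confound_loading > 1:
            raise ValueError(
                "variance budget exceeded: within_r + confound_loading = "
                f"{self.within_r + self.confound_loading:.3f} > 1 (model "
                "covariance would not be positive semi-definite)"
            )
        if self.hemo_lag_trs < 0 or self.boost_window_trs < 0:
            raise ValueError("hemo_lag_trs and boost_window_trs must be >= 0")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min < max")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def run_duration_s(self) -> float:
        return self.n_trs * self.tr_seconds

    @property
    def community_labels(self) -> list[str]:
        if self.n_communities == 7:
            return list(CANONICAL_COMMUNITIES)
        return [f"Comm{i + 1}" for i in range(self.n_communities)]


@dataclass
class PipelineConfig:
    """Analysis choices for the evoked-pain network pipeline.

    ``bins`` is the peristimulus window in TRs relative to the onset TR;
    the default ``(-2, 3)`` yields the six bins -2..+3 of which only
    0..+3 (onset and after-onset) enter the statistics. ``fdr_family``
    controls the size of the Benjamini-Hochberg family: ``"per-table"``
    (default) corrects across units x analysed bins within one
    metric/level/contrast table; an integer overrides the family size m
    (for sensitivity analyses of the correction).
    """

    tr_seconds: float = 3.0
    fd_threshold: float = 0.5
    bins: tuple[int, int] = (-2, 3)
    condition: str = "painful"
    nodes: Sequence[str] | None = None
    fdr_family: str | int = "per-table"
    alpha: float = 0.05
    z_signed: bool = False
    averaging: str = "nested"  # trials -> runs -> site; "pooled" pools trials
    group_contrast_site: str = "joint"
    site_contrast_group: str = "RA"
    metrics: Sequence[str] = ("pc", "z")
    levels: Sequence[str] = ("community", "nodal")
    contrasts: Sequence[str] = ("group", "site")
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.fd_threshold < 0:
            raise ValueError("fd_threshold must be non-negative")
        lo, hi = self.bins
        if lo > 0 or hi < 0 or hi <= lo:
            raise ValueError("bins must span the onset, e.g. (-2, 3)")
        if self.averaging not in ("nested", "pooled"):
            raise ValueError("averaging must be 'nested' or 'pooled'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if isinstance(self.fdr_family, int) and self.fdr_family < 1:
            raise ValueError("integer fdr_family must be >= 1")
        unknown = set(self.metrics) - {"pc", "z"}
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        unknown = set(self.levels) - {"community", "nodal"}
        if unknown:
            raise ValueError(f"unknown levels: {sorted(unknown)}")
        unknown = set(self.contrasts) - {"group", "site"}
        if unknown:
            raise ValueError(f"unknown contrasts: {sorted(unknown)}")

    @property
    def bin_labels(self) -> list[int]:
        return list(range(self.bins[0], self.bins[1] + 1))

    @property
    def analysis_bins(self) -> list[int]:
        """Bins entering the statistics: onset and after-onset only."""
        return [b for b in self.bin_labels if b >= 0]

    def config_hash(self) -> str:
        """Stable hash of the configuration, stamped into every output."""
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def load_config(path, kind: str = "pipeline"):
    """Load a :class:`SimConfig` or :class:`PipelineConfig` from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cls = {"pipeline": PipelineConfig, "sim": SimConfig}[kind]
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {kind} config keys: {sorted(unknown)}")
    for key in ("isi_range_s", "age_range", "bins"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return cls(**data)
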