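"""In-memory containers shared across pipeline stages.

The pipeline's unit of work is one fMRI run: a parcellated signal matrix
(:class:`ParcelRun`) paired with its nuisance-regressor table and its event
table (:class:`RunRecord`).  A whole simulated or loaded study is a
:class:`StudyBundle`.  Connectivity lives in a :class:`FlowTensor`, one
symmetric node x node slice per TR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ParcelRun:
    """One run's node x TR parcellated BOLD matrix with its study labels."""

    signals: np.ndarray  # (n_nodes, n_trs)
    node_labels: list[str]
    tr_seconds: float
    subject: str
    group: str  # "RA" | "HC"
    site: str  # "joint" | "thumb"
    run: int

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D node x TR matrix")
        if self.signals.shape[0] != len(self.node_labels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.node_labels)} node labels"
            )
        if self.signals.shape[1] < 2:
            raise ValueError("a run needs at least 2 TRs")
        if not np.isfinite(self.signals).all():
            raise ValueError("signals contain missing or non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_trs(self) -> int:
        return self.signals.shape[1]

    @property
    def key(self) -> str:
        return f"{self.subject}_{self.site}_run-{self.run}"


@dataclass
class CommunityPartition:
    """Static node -> community assignment, shared by every time point."""

    node_labels: list[str]
    communities: np.ndarray  # community label per node, aligned to node_labels

    def __post_init__(self) -> None:
        self.communities = np.asarray(self.communities, dtype=object)
        if len(self.node_labels) != self.communities.shape[0]:
            raise ValueError("one community label required per node")
        if len(self.community_labels) < 2:
            raise ValueError("a partition needs at least 2 communities")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def community_labels(self) -> list[str]:
        """Distinct community labels in order of first appearance."""
        return list(pd.unique(self.communities))

    def indicator(self) -> np.ndarray:
        """(n_nodes, n_communities) 0/1 membership matrix."""
        labels = self.community_labels
        ind = np.zeros((self.n_nodes, len(labels)))
        for j, lab in enumerate(labels):
            ind[self.communities == lab, j] = 1.0
        return ind

    def membership_index(self) -> np.ndarray:
        """Integer community index per node (into :attr:`community_labels`)."""
        pos = {lab: j for j, lab in enumerate(self.community_labels)}
        return np.array([pos[c] for c in self.communities], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_index": np.arange(self.n_nodes),
                "node_label": self.node_labels,
                "community_label": self.communities,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommunityPartition":
        df = df.sort_values("node_index")
        return cls(
            node_labels=list(df["node_label"]),
            communities=df["community_label"].to_numpy(),
        )


@dataclass
class RunRecord:
    """A run with its aligned confound and event tables."""

    run: ParcelRun
    confounds: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.confounds) != self.run.n_trs:
            raise ValueError(
                f"run {self.run.key}: confound table has {len(self.confounds)} "
                f"rows but the run has {self.run.n_trs} TRs"
            )


@dataclass
class StudyBundle:
    """A complete multi-subject study: runs, partition, manifest, ground truth."""

    records: list[RunRecord]
    partition: CommunityPartition
    manifest: pd.DataFrame  # subject, group, age
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_subject: dict[str, list[RunRecord]] = {}
        seen = set()
        for rec in self.records:
            r = rec.run
            k = (r.subject, r.site, r.run)
            if k in seen:
                raise ValueError(f"duplicate subject/site/run combination: {k}")
            seen.add(k)
            per_subject.setdefault(r.subject, []).append(rec)
        missing = set(per_subject) - set(self.manifest["subject"])
        if missing:
            raise ValueError(f"runs reference subjects absent from manifest: {sorted(missing)}")

    @property
    def subjects(self) -> list[str]:
        return list(self.manifest["subject"])

    def group_of(self, subject: str) -> str:
        row = self.manifest.loc[self.manifest["subject"] == subject]
        return str(row["group"].iloc[0])

    def age_of(self, subject: str) -> float:
        row = self.manifest.loc[self.manifest["subject"] == subject]
        return float(row["age"].iloc[0])


@dataclass
class FlowTensor:
    """Standardized jackknife-correlation connectivity: one slice per TR.

    ``values[t]`` is the symmetric node x node flow matrix at TR ``t``.
    After standardization every edge's time series has mean 0 and SD 1;
    undefined edge-timepoints (zero-variance leave-one-out sub-series) are
    NaN and propagate as missing into the network metrics.  The diagonal is
    NaN and never consumed downstream.
    """

    values: np.ndarray  # (n_trs, n_nodes, n_nodes)
    node_labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must have shape (n_trs, n_nodes, n_nodes)")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError("node_labels length must match the node axis")

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]
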