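"""Per-timepoint integration and segregation metrics on flow connectivity.

Two node-level quantities, evaluated on every TR slice of the flow tensor
against a static community partition:

* **Participation coefficient (PC)** — ``PC_i = 1 - sum_s (k_is / k_i)**2``
  where ``k_is`` is node *i*'s positive strength into community *s* and
  ``k_i`` its total positive strength; 0 when all positive strength stays in
  one community, approaching ``1 - 1/N_M`` for a uniform spread over the
  ``N_M`` communities.  Only positive edges enter; an isolated node
  (``k_i = 0``) is assigned PC = 0.
* **Within-module degree z-score (z)** — node *i*'s strength into its own
  community, standardized (population SD) against that quantity's
  distribution over the community's members at the same TR, so every
  community's mean z is exactly 0 at every TR.

Community-level summaries are the medians of PC or z over each community's
member nodes; the nodal level extracts configured single nodes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CommunityPartition, FlowTensor

_SYM_TOL = 1e-8


def _positive_weights(W: np.ndarray, signed: bool) -> np.ndarray:
    """Replace undefined entries by 0 and, unless signed, drop non-positive edges.

    Undefined (NaN) edge-timepoints simply do not contribute: each node's
    metric at a TR is computed over its defined edges.
    """
    if signed:
        return np.where(np.isfinite(W), W, 0.0)
    with np.errstate(invalid="ignore"):  # NaN > 0 is False: undefined edges drop
        return np.where(W > 0, W, 0.0)


def _check_symmetric(W: np.ndarray) -> None:
    finite = np.isfinite(W) & np.isfinite(np.swapaxes(W, -1, -2))
    diff = np.where(finite, W - np.swapaxes(W, -1, -2), 0.0)
    if np.abs(diff).max(initial=0.0) > _SYM_TOL:
        raise ValueError("connectivity matrix is not symmetric")


def _community_strengths(
    W: np.ndarray, partition: CommunityPartition, signed: bool, check: bool = True
) -> np.ndarray:
    """(T, N, C) positive strength of each node into each community."""
    if W.shape[-1] != partition.n_nodes:
        raise ValueError("partition does not cover the matrix's nodes")
    if check:
        _check_symmetric(W)
    Wp = _positive_weights(W, signed=signed)
    t, n = Wp.shape[0], Wp.shape[1]
    return (Wp.reshape(t * n, n) @ partition.indicator()).reshape(t, n, -1)


def _pc_from_strengths(k_is: np.ndarray) -> np.ndarray:
    k = k_is.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = k_is / k[:, :, None]
        pc = 1.0 - (frac**2).sum(axis=2)
    return np.where(k > 0, pc, 0.0)


def participation_coefficient(
    W: np.ndarray, partition: CommunityPartition
) -> np.ndarray:
    """PC per node for one symmetric node x node slice (or a (T, N, N) stack).

    Negative, zero and undefined edges are discarded; nodes with no positive
    strength get PC = 0.
    """
    W = np.asarray(W, dtype=float)
    stacked = W.ndim == 3
    if not stacked:
        W = W[None]
    pc = _pc_from_strengths(_community_strengths(W, partition, signed=False))
    return pc if stacked else pc[0]


def within_module_z(
    W: np.ndarray, partition: CommunityPartition, signed: bool = False
) -> np.ndarray:
    """Within-module degree z-score per node for one slice (or a (T, N, N) stack).

    ``signed=True`` keeps negative flow weights in the strength sums (a
    sensitivity mode); the default mirrors the positive-edge rule used for PC.
    A community whose within-strengths have zero spread (including singleton
    communities) gets z = 0 for all members.
    """
    W = np.asarray(W, dtype=float)
    stacked = W.ndim == 3
    if not stacked:
        W = W[None]
    k_is = _community_strengths(W, partition, signed=signed)
    z = _z_from_strengths(k_is, partition)
    return z if stacked else z[0]


def _z_from_strengths(k_is: np.ndarray, partition: CommunityPartition) -> np.ndarray:
    ind = partition.indicator()  # (N, C)
    members = partition.membership_index()
    # (T, N): strength restricted to the node's own community
    k_own = k_is[:, np.arange(k_is.shape[1]), members]

    sizes = ind.sum(axis=0)  # (C,)
    mean_c = (k_own @ ind) / sizes  # (T, C)
    var_c = (k_own**2 @ ind) / sizes - mean_c**2
    sd_c = np.sqrt(np.maximum(var_c, 0.0))  # population SD
    mu = mean_c[:, members]
    sd = sd_c[:, members]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (k_own - mu) / sd
    return np.where(sd > 0, z, 0.0)


def node_metric_series(
    flow: FlowTensor, partition: CommunityPartition, z_signed: bool = False
) -> dict[str, np.ndarray]:
    """PC and z for every node at every TR of a flow tensor.

    Returns ``{"pc": (N, T), "z": (N, T)}`` matrices aligned to
    ``flow.node_labels``.
    """
    if flow.node_labels != partition.node_labels:
        raise ValueError("flow tensor and partition node labels disagree")
    # symmetry holds by construction for tensors from standardize_flow
    k_is = _community_strengths(flow.values, partition, signed=False, check=False)
    pc = _pc_from_strengths(k_is).T
    if z_signed:
        k_is = _community_strengths(flow.values, partition, signed=True, check=False)
    z = _z_from_strengths(k_is, partition).T
    return {"pc": pc, "z": z}


def community_medians(
    node_values: np.ndarray, partition: CommunityPartition
) -> tuple[np.ndarray, list[str]]:
    """Median over each community's member nodes, per TR.

    ``node_values`` is (N, T); returns ((C, T) medians, community labels).
    Undefined node values are ignored; a community with no defined member
    value at a TR yields a NaN entry.
    """
    node_values = np.asarray(node_values, dtype=float)
    labels = partition.community_labels
    out = np.empty((len(labels), node_values.shape[1]))
    all_defined = np.isfinite(node_values).all()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for j, lab in enumerate(labels):
            block = node_values[partition.communities == lab]
            out[j] = np.median(block, axis=0) if all_defined else np.nanmedian(
                block, axis=0
            )
    return out, labels


def extract_nodes(
    node_values: np.ndarray, node_labels: list[str], requested: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Metric series for the configured nodes (e.g. the six pain-relevant areas).

    Duplicates collapse to one series (with a warning); an unknown label
    fails listing valid labels.
    """
    unknown = [r for r in requested if r not in node_labels]
    if unknown:
        preview = ", ".join(node_labels[:10])
        raise ValueError(
            f"unknown node labels {unknown}; valid labels start with: {preview}, ..."
        )
    seen: list[str] = []
    for r in requested:
        if r in seen:
            warnings.warn(f"duplicate node label {r!r} requested; using one series")
        else:
            seen.append(r)
    idx = [node_labels.index(r) for r in seen]
    return np.asarray(node_values, dtype=float)[idx], seen
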