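"""Time-varying connectivity via the jackknife correlation.

The jackknife correlation attributes a connectivity estimate to each single
time point t: the Pearson correlation of two series computed over all time
points *except* t, multiplied by -1.  Removing a time point at which two
series co-fluctuate strongly lowers the leave-one-out correlation, so after
negation a strongly coupled time point maps to a relatively *high* value —
the sign flip restores "positive association at t -> positive estimate at t".
Each edge's jackknife series is then z-scored across the run's TRs, giving
unit-variance "flow" estimates comparable across edges.
"""

from __future__ import annotations

import numpy as np

from .containers import FlowTensor

#: relative tolerance below which a leave-one-out variance counts as zero
_VAR_TOL = 1e-12


def jackknife_correlation(signals: np.ndarray, chunk: int = 32) -> np.ndarray:
    """Leave-one-timepoint-out negated Pearson correlation for every node pair.

    Parameters
    ----------
    signals : (n_nodes, n_trs) array
        Parcel time series; ``n_trs >= 3``.
    chunk : int
        Number of TR slices computed per vectorized block (memory knob only).

    Returns
    -------
    (n_trs, n_nodes, n_nodes) array; slice ``t`` holds
    ``-corr(x_i without t, x_j without t)``, symmetric in (i, j).  The
    diagonal is NaN, as are all entries of node/timepoint combinations whose
    leave-one-out sub-series has zero variance (a node constant everywhere
    except possibly at t) — such undefined estimates propagate as missing,
    never as silent zeros.

    Notes
    -----
    Per-node centering and unit-norm scaling (to which the correlation is
    invariant) reduce the leave-one-out update to

    ``r_t(i,j) = (C_ij - T/(T-1) * x_it * x_jt) / sqrt(v_i(t) * v_j(t))``,

    with ``C = X X'`` on the normalized data and
    ``v_i(t) = 1 - T/(T-1) * x_it**2``, computed for all t at once.
    """
    X = np.asarray(signals, dtype=float)
    if X.ndim != 2:
        raise ValueError("signals must be a 2-D node x TR matrix")
    n, T = X.shape
    if T < 3:
        raise ValueError(f"jackknife correlation needs >= 3 TRs, got {T}")

    amplitude = np.abs(X).max(axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    # constant series leave only rounding residue after centering: flag any
    # node whose variation is negligible relative to its magnitude
    degenerate_node = norms[:, 0] <= amplitude * T * 1e-14
    norms[degenerate_node] = 1.0
    X = X / norms

    C = X @ X.T
    scale = T / (T - 1)
    v = 1.0 - scale * X**2  # (n, T) leave-one-out variance (up to (T-1) factor)
    bad = v < _VAR_TOL  # zero-variance leave-one-out sub-series
    v_safe = np.where(bad, 1.0, v)

    out = np.empty((T, n, n))
    for start in range(0, T, chunk):
        sl = slice(start, min(start + chunk, T))
        xb = X[:, sl]  # (n, tb)
        num = C[None, :, :] - scale * np.einsum("it,jt->tij", xb, xb)
        sd = np.sqrt(v_safe[:, sl]).T  # (tb, n)
        block = -num / (sd[:, :, None] * sd[:, None, :])
        out[sl] = block

    np.clip(out, -1.0, 1.0, out=out)
    # undefined entries: diagonal, degenerate nodes, zero-variance loo points
    idx = np.arange(n)
    out[:, idx, idx] = np.nan
    if degenerate_node.any():
        out[:, degenerate_node, :] = np.nan
        out[:, :, degenerate_node] = np.nan
    if bad.any():
        tt, nodes = np.nonzero(bad.T)
        out[tt, nodes, :] = np.nan
        out[tt, :, nodes] = np.nan
    return out


def standardize_flow(
    raw: np.ndarray,
    node_labels: list[str] | None = None,
    tr_seconds: float = 1.0,
) -> FlowTensor:
    """Z-score each edge's jackknife series across its run's TRs.

    Standardization is per edge, within run, over the full TR axis (sample
    SD).  Edges whose series has zero variance, or fewer than 2 defined time
    points, become all-NaN and are flagged via the returned tensor's missing
    entries.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[1] != raw.shape[2]:
        raise ValueError("raw tensor must have shape (n_trs, n_nodes, n_nodes)")
    n = raw.shape[1]
    if node_labels is None:
        node_labels = [f"node_{i}" for i in range(n)]

    T = raw.shape[0]
    idx = np.arange(n)
    diag_only_nan = (
        np.isnan(raw[:, idx, idx]).all()
        and np.isnan(raw).sum() == T * n
    )
    if diag_only_nan and T >= 2:
        # common case: every off-diagonal edge fully defined
        off = raw.copy()
        off[:, idx, idx] = 0.0
        mean = off.sum(axis=0) / T
        centered = off - mean[None]
        ss = np.einsum("tij,tij->ij", centered, centered)
        defined = np.full((n, n), T)
        defined[idx, idx] = 0
    else:
        finite = np.isfinite(raw)
        defined = finite.sum(axis=0)  # (n, n)
        filled = np.where(finite, raw, 0.0)
        cnt = np.maximum(defined, 1)
        mean = filled.sum(axis=0) / cnt
        centered = np.where(finite, raw - mean[None], 0.0)
        ss = np.einsum("tij,tij->ij", centered, centered)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(np.maximum(ss, 0.0) / np.maximum(defined - 1, 1))
        ok = (defined >= 2) & (sd > 0)
        z = (raw - mean[None]) / np.where(ok, sd, np.nan)[None]
    return FlowTensor(values=z, node_labels=list(node_labels), tr_seconds=tr_seconds)


def flow_from_run(signals: np.ndarray, node_labels: list[str],
                  tr_seconds: float) -> FlowTensor:
    """Convenience: jackknife correlation followed by per-edge standardization."""
    return standardize_flow(jackknife_correlation(signals), node_labels, tr_seconds)


def flow_to_long_frame(flow: FlowTensor):
    """Export a flow tensor as a long-format table (i, j, t, flow), i < j."""
    import pandas as pd

    n = flow.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    frames = []
    for t in range(flow.n_trs):
        frames.append(
            pd.DataFrame(
                {
                    "i": [flow.node_labels[a] for a in iu],
                    "j": [flow.node_labels[b] for b in ju],
                    "t": t,
                    "flow": flow.values[t, iu, ju],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
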