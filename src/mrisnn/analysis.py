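"""Post-hoc interpretation of a trained reservoir.

The *activation degree* of a neuron averages its incoming plus outgoing
weights over its neighbourhood (self-loop counted), giving a per-neuron
summary of learned connectivity whose spatial pattern stabilises as
training converges.  Snapshots export membrane potentials, firing counts
and the degree map as (x, y, z, value) tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError


@dataclass
class ActivationDegreeMap:
    """Per-neuron activation degree D at a snapshot epoch."""

    d: np.ndarray
    epoch: int = -1

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("activation degree must be finite")


def activation_degree(W, graph, epoch=-1):
    """D_i = sum_{j in N_i} (w_ij + w_ji) / |N_i| (self-loop included)."""
    if W.n != graph.n_neurons:
        raise ContractError("weights and graph disagree on neuron count")
    both = np.where(graph.adjacency, W.values + W.values.T, 0.0)
    counts = graph.adjacency.sum(axis=1)
    return ActivationDegreeMap(both.sum(axis=1) / counts, epoch=epoch)


def snapshot(model, epoch=None):
    """Per-neuron (x, y, z, v, spikes, D, channel) table.

    With ``epoch`` given, uses the state captured at that training epoch
    (the model must have been fitted with ``snapshot_epochs`` containing
    it); otherwise the post-training state.
    """
    model._check_fitted()
    layout = model.layout_
    if epoch is None:
        v = model.state_.v
        spikes = model.spike_counts_
        W = model.weights_
        ep = len(model.cost_trace_) - 1
    else:
        if epoch not in model.snapshots_:
            raise ValidationError(f"no snapshot stored for epoch {epoch}")
        snap = model.snapshots_[epoch]
        v, spikes, W = snap["v"], snap["spike_counts"], snap["weights"]
        ep = epoch
    adm = activation_degree(W, model.graph_, epoch=ep)
    channel = np.array([""] * layout.n_neurons, dtype=object)
    for name, nid in layout.observed_index.items():
        channel[nid] = name
    return pd.DataFrame({
        "id": np.arange(layout.n_neurons),
        "x": layout.positions[:, 0],
        "y": layout.positions[:, 1],
        "z": layout.positions[:, 2],
        "v_mv": v,
        "spikes": spikes,
        "D": adm.d,
        "channel": channel,
    })


def convergence_trace(snapshots, tol=1e-3, patience=10):
    """L2 distance between consecutive activation-degree maps.

    Returns (distances, converged): ``converged`` is True when the distance
    stays below ``tol`` for ``patience`` consecutive intervals.
    """
    if len(snapshots) < 2:
        raise ValidationError("need at least two snapshots")
    maps = [s.d if isinstance(s, ActivationDegreeMap) else np.asarray(s, float)
            for s in snapshots]
    n = maps[0].shape[0]
    if any(m.shape[0] != n for m in maps):
        raise ContractError("snapshots differ in length")
    dist = np.array([np.linalg.norm(maps[k + 1] - maps[k])
                     for k in range(len(maps) - 1)])
    below = dist < tol
    converged = False
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= patience:
            converged = True
            break
    return dist, converged


def scatter_projection(table, value="D", plane="xy", ax=None):
    """2D scatter of a snapshot table coloured by a per-neuron value."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    a, b = plane[0], plane[1]
    sc = ax.scatter(table[a], table[b], c=table[value], s=12, cmap="viridis")
    ax.set_xlabel(f"{a} (mm)")
    ax.set_ylabel(f"{b} (mm)")
    ax.figure.colorbar(sc, ax=ax, label=value)
    return ax
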