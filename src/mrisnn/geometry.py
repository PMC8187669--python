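"""Spatial construction of the reservoir.

A reservoir is laid out inside a personal head geometry given as a 3D point
cloud (millimetres).  Electrode positions of a 10-20 montage anchor the
*observed* neurons: each channel is assigned the nearest unused cloud point,
so the observed neurons sit where the EEG was (or would be) recorded.  The
remaining *hidden* neurons are drawn uniformly from the rest of the cloud.

Connectivity is purely spatial: neuron ``j`` is a neighbour of ``i`` whenever
their Euclidean distance is at most a threshold ``T`` (default 70 mm), and
every neuron is its own neighbour (self-feedback edge).  Weights exist only
on neighbourhood edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import distance_matrix

from .errors import PlacementError, ValidationError

DEFAULT_NEIGHBORHOOD_MM = 70.0


@dataclass
class HeadPointCloud:
    """Candidate neuron positions extracted from a head volume mesh (mm)."""

    points: np.ndarray
    source_tag: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("point cloud must be an (n, 3) array")
        if self.points.shape[0] < 1:
            raise ValidationError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise ValidationError("point cloud contains non-finite coordinates")
        uniq = np.unique(self.points, axis=0)
        if uniq.shape[0] != self.points.shape[0]:
            raise ValidationError("point cloud contains duplicate points")

    def __len__(self):
        return self.points.shape[0]


@dataclass
class ElectrodeMontage:
    """Named 10-20 electrode positions in head coordinates (mm)."""

    names: list
    positions: np.ndarray

    def __post_init__(self):
        self.names = list(self.names)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != self.positions.shape[0]:
            raise ValidationError("montage names and positions differ in length")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("montage positions must be (m, 3)")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("montage channel names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("montage positions contain non-finite values")

    def __len__(self):
        return len(self.names)

    def subset(self, names):
        idx = [self.names.index(n) for n in names]
        return ElectrodeMontage(list(names), self.positions[idx])

    def position_of(self, name):
        return self.positions[self.names.index(name)]


@dataclass
class NeuronLayout:
    """Positions plus observed/hidden and excitatory/inhibitory labelling."""

    positions: np.ndarray
    observed_index: dict  # channel name -> neuron id
    is_inhibitory: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.is_inhibitory = np.asarray(self.is_inhibitory, dtype=bool)
        n = self.positions.shape[0]
        if self.is_inhibitory.shape != (n,):
            raise ValidationError("is_inhibitory length must equal neuron count")
        ids = list(self.observed_index.values())
        if len(set(ids)) != len(ids):
            raise ValidationError("two channels map to the same neuron id")

    @property
    def n_neurons(self):
        return self.positions.shape[0]

    @property
    def n_observed(self):
        return len(self.observed_index)

    @property
    def n_hidden(self):
        return self.n_neurons - self.n_observed

    @property
    def channel_names(self):
        return list(self.observed_index.keys())

    @property
    def observed_ids(self):
        """Neuron ids of observed neurons, in channel order."""
        return np.array(list(self.observed_index.values()), dtype=int)

    @property
    def observed_mask(self):
        mask = np.zeros(self.n_neurons, dtype=bool)
        mask[self.observed_ids] = True
        return mask


@dataclass
class NeighborhoodGraph:
    """Distance-thresholded adjacency with guaranteed self-loops."""

    threshold_mm: float
    distances: np.ndarray
    adjacency: np.ndarray = field(default=None)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        if self.adjacency is None:
            adj = self.distances <= self.threshold_mm
            np.fill_diagonal(adj, True)
            self.adjacency = adj
        self.adjacency = np.asarray(self.adjacency, dtype=bool)

    @property
    def n_neurons(self):
        return self.distances.shape[0]

    def neighbors(self, i):
        """The set N_i, including i itself."""
        return np.flatnonzero(self.adjacency[i])


def place_neurons(cloud, montage, n_neurons, frac_inhibitory=0.2, seed=0,
                  inhibitory_scope="hidden"):
    """Assign reservoir neurons to cloud points, anchoring observed neurons.

    Each montage channel (in montage order) greedily takes the nearest cloud
    point not already taken; the remaining ``n_neurons - n_channels`` hidden
    neurons are sampled without replacement, uniformly, from the unused
    points.  ``floor(frac_inhibitory * n_neurons)`` neurons are labelled
    inhibitory, drawn uniformly among the hidden population by default —
    observed neurons act as measurement ports whose injected signal should
    not be sign-inverted (``inhibitory_scope='all'`` draws over everyone).
    """
    if inhibitory_scope not in ("hidden", "all"):
        raise ValidationError("inhibitory_scope must be 'hidden' or 'all'")
    if len(montage) == 0:
        raise ValidationError("montage is empty")
    if np.all(np.isnan(montage.positions)):
        raise ValidationError("montage positions are all NaN")
    if n_neurons > len(cloud):
        raise PlacementError(
            f"cannot place {n_neurons} neurons in a {len(cloud)}-point cloud"
        )
    if len(montage) > n_neurons:
        raise PlacementError("more montage channels than neurons")

    rng = np.random.default_rng(seed)
    pts = cloud.points
    taken = np.zeros(len(cloud), dtype=bool)
    chosen = []
    observed_index = {}
    for k, name in enumerate(montage.names):
        d = np.linalg.norm(pts - montage.positions[k], axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d))
        if not np.isfinite(d[j]):
            raise PlacementError("ran out of unused cloud points for electrodes")
        taken[j] = True
        observed_index[name] = k  # ids 0..m-1 are observed, in channel order
        chosen.append(j)

    remaining = np.flatnonzero(~taken)
    n_hidden = n_neurons - len(montage)
    hidden = rng.choice(remaining, size=n_hidden, replace=False)
    chosen.extend(int(h) for h in hidden)

    positions = pts[np.array(chosen, dtype=int)]
    n_inh = int(np.floor(frac_inhibitory * n_neurons))
    if inhibitory_scope == "hidden":
        pool = np.arange(len(montage), n_neurons)
        n_inh = min(n_inh, pool.size)
    else:
        pool = np.arange(n_neurons)
    inh_ids = rng.choice(pool, size=n_inh, replace=False)
    is_inhibitory = np.zeros(n_neurons, dtype=bool)
    is_inhibitory[inh_ids] = True
    return NeuronLayout(positions, observed_index, is_inhibitory)


def build_neighborhoods(layout, threshold_mm=DEFAULT_NEIGHBORHOOD_MM):
    """N_i = {j : D_ij <= T} plus the self-feedback edge i in N_i."""
    if threshold_mm <= 0:
        raise ValidationError("neighborhood threshold must be positive")
    d = distance_matrix(layout.positions, layout.positions)
    return NeighborhoodGraph(threshold_mm, d)


def init_weights(graph, layout, observed_init_scale=1e-3, seed=0,
                 observed_init="uniform", hidden_init="zero",
                 hidden_init_scale=1.0):
    """Initial weight matrix on the neighbourhood graph.

    Hidden rows start at exactly zero.  Observed rows start either at zero
    (``observed_init='zero'``, the literal published initialisation, under
    which the W-transposed form of the gradient update is a fixed point) or
    uniform in ``(-scale, +scale)`` excluding zero (default).

    Hidden rows start at zero by default; ``hidden_init='smallworld'``
    instead gives every hidden-row edge a fixed synaptic efficacy of
    ``hidden_init_scale`` (negative for inhibitory presynaptic columns),
    realising the small-world-style neighbourhood coupling so spikes can
    propagate into the hidden population before plasticity has acted.
    """
    from .plasticity import WeightMatrix  # deferred: avoid import cycle

    if observed_init not in ("uniform", "zero"):
        raise ValidationError("observed_init must be 'uniform' or 'zero'")
    if hidden_init not in ("zero", "smallworld"):
        raise ValidationError("hidden_init must be 'zero' or 'smallworld'")
    n = graph.n_neurons
    if n != layout.n_neurons:
        raise ValidationError("graph and layout disagree on neuron count")
    values = np.zeros((n, n))
    if observed_init == "uniform":
        rng = np.random.default_rng(seed)
        for i in layout.observed_ids:
            row = rng.uniform(-observed_init_scale, observed_init_scale, size=n)
            while np.any(row == 0.0):  # pragma: no cover - measure-zero event
                row[row == 0.0] = rng.uniform(
                    -observed_init_scale, observed_init_scale, size=np.sum(row == 0.0)
                )
            # inhibitory presynaptic neurons act non-positively from the start
            row = np.where(layout.is_inhibitory, -np.abs(row), row)
            values[i] = np.where(graph.adjacency[i], row, 0.0)
    if hidden_init == "smallworld":
        # couple hidden rows to their *observed* neighbours only; hidden-to-
        # hidden edges keep the zero initialisation (plasticity grows them),
        # which prevents runaway recurrent excitation in the hidden pool
        sign = np.where(layout.is_inhibitory, -1.0, 1.0)
        hid = ~layout.observed_mask
        col = np.zeros(n)
        col[layout.observed_ids] = 1.0
        values[hid] = np.where(
            graph.adjacency[hid],
            hidden_init_scale * sign[None, :] * col[None, :], 0.0
        )
    return WeightMatrix(values, graph.adjacency.copy())
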