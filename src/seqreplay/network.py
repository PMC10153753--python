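"""Network construction: random EE connectivity with fixed in-degree.

The excitatory population is split into ``M`` disjoint subpopulations of
``n_E`` neurons each (neuron ``i`` belongs to subpopulation ``i // n_E``).
Every excitatory neuron receives exactly ``K_EE`` excitatory inputs drawn
uniformly at random without replacement from the other excitatory neurons
(no autapses, no multapses). The single inhibitory neuron is connected
all-to-all with the excitatory population in both directions with fixed
weights; those edges are implicit and carried by the parameters, not by the
edge list.

Edges are stored flat, sorted by presynaptic neuron, with a CSR-style
pointer for fast delivery of outgoing spikes, plus an index that groups the
same edges by postsynaptic neuron for the plasticity updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = ["Network", "build_network"]


@dataclass
class Network:
    """Excitatory-to-excitatory connectivity and per-edge plastic weights.

    Attributes
    ----------
    edge_pre, edge_post : int32 arrays, shape (n_edges,)
        Endpoints of every EE edge, sorted by ``edge_pre``.
    edge_weight : float64 array, shape (n_edges,)
        Current synaptic weights in pA (mutated in place during training).
    pre_ptr : int64 array, shape (N_E + 1,)
        ``edge_*[pre_ptr[j]:pre_ptr[j+1]]`` are the outgoing edges of ``j``.
    post_order : int64 array, shape (n_edges,)
        Edge indices grouped by postsynaptic neuron.
    post_ptr : int64 array, shape (N_E + 1,)
        ``post_order[post_ptr[i]:post_ptr[i+1]]`` index the incoming edges
        of neuron ``i``.
    subpop_of : int32 array, shape (N_E,)
        Subpopulation index of every excitatory neuron.
    """

    N_E: int
    M: int
    edge_pre: np.ndarray
    edge_post: np.ndarray
    edge_weight: np.ndarray
    pre_ptr: np.ndarray
    post_order: np.ndarray
    post_ptr: np.ndarray
    subpop_of: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def n_E(self) -> int:
        return self.N_E // self.M

    @property
    def n_edges(self) -> int:
        return self.edge_pre.size

    def subpop_slice(self, k: int) -> slice:
        """Contiguous index range of the neurons in subpopulation ``k``."""
        return slice(k * self.n_E, (k + 1) * self.n_E)

    def out_edges(self, j: int) -> slice:
        return slice(self.pre_ptr[j], self.pre_ptr[j + 1])

    def in_edge_idx(self, i: int) -> np.ndarray:
        return self.post_order[self.post_ptr[i]:self.post_ptr[i + 1]]

    def in_degrees(self) -> np.ndarray:
        return np.diff(self.post_ptr)

    def copy(self) -> "Network":
        return Network(
            N_E=self.N_E, M=self.M,
            edge_pre=self.edge_pre, edge_post=self.edge_post,
            edge_weight=self.edge_weight.copy(),
            pre_ptr=self.pre_ptr, post_order=self.post_order,
            post_ptr=self.post_ptr, subpop_of=self.subpop_of, seed=self.seed,
        )

    def weight_matrix(self) -> np.ndarray:
        """Dense (pre, post) weight matrix; absent edges are zero."""
        W = np.zeros((self.N_E, self.N_E))
        W[self.edge_pre, self.edge_post] = self.edge_weight
        return W

    def weight_hash(self) -> int:
        return hash(self.edge_weight.tobytes())


def build_network(params: ModelParams, seed: int) -> Network:
    """Draw a network realization: connectivity and initial weights.

    Each postsynaptic neuron independently samples ``K_EE`` distinct
    presynaptic partners (excluding itself); initial weights are uniform on
    ``[J0_min, J0_max]``. Identical seeds produce identical networks.
    """
    n = params.N_E
    k = params.K_EE
    if k >= n:
        raise ValueError(
            f"in-degree K_EE={k} exceeds the available presynaptic pool ({n - 1})"
        )
    ss = np.random.SeedSequence(seed)
    rng_conn, rng_w = [np.random.default_rng(s) for s in ss.spawn(2)]

    if k > 0:
        # sample K_EE of N_E-1 candidates per row via partial Fisher-Yates
        # (vectorized: random keys, partition); candidates exclude self.
        pres = np.empty((n, k), dtype=np.int32)
        keys = rng_conn.random((n, n - 1))
        part = np.argpartition(keys, k, axis=1)[:, :k].astype(np.int32)
        rows = np.arange(n, dtype=np.int32)[:, None]
        # candidate c maps to neuron c if c < row else c + 1 (skip self)
        pres = part + (part >= rows)
        edge_post = np.repeat(np.arange(n, dtype=np.int32), k)
        edge_pre = pres.ravel()
        order = np.argsort(edge_pre, kind="stable")
        edge_pre = edge_pre[order]
        edge_post = edge_post[order]
        edge_weight = rng_w.uniform(
            params.plasticity.J0_min, params.plasticity.J0_max, size=edge_pre.size
        )
    else:
        edge_pre = np.empty(0, dtype=np.int32)
        edge_post = np.empty(0, dtype=np.int32)
        edge_weight = np.empty(0, dtype=float)

    pre_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(edge_pre, minlength=n), out=pre_ptr[1:])
    post_order = np.argsort(edge_post, kind="stable")
    post_ptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(edge_post, minlength=n), out=post_ptr[1:])

    subpop_of = (np.arange(n) // params.n_E).astype(np.int32)
    return Network(
        N_E=n, M=params.M,
        edge_pre=edge_pre, edge_post=edge_post, edge_weight=edge_weight,
        pre_ptr=pre_ptr, post_order=post_order, post_ptr=post_ptr,
        subpop_of=subpop_of, seed=seed,
    )
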