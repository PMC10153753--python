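"""Plain-text serialization of networks and stimulus schedules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inputs import StimulusSchedule
from .network import Network
from .params import ModelParams

__all__ = ["save_network", "load_network", "save_schedule", "load_schedule"]


def save_network(net: Network, path, params: ModelParams | None = None) -> None:
    """Edge-list text file: pre, post, weight_pA, delay_ms, kind.

    Only the explicit (plastic) EE edges are listed; the all-to-all IE/EI
    connections and the background-source assignments are defined by the
    parameters and are not part of the realization. A ``.npz`` suffix
    selects a binary container instead (large runs).
    """
    if str(path).endswith(".npz"):
        np.savez_compressed(
            path, N_E=net.N_E, M=net.M, seed=net.seed if net.seed is not None else -1,
            edge_pre=net.edge_pre, edge_post=net.edge_post, edge_weight=net.edge_weight,
        )
        return
    d_EE = params.d_EE if params is not None else 2.0
    df = pd.DataFrame({
        "pre": net.edge_pre, "post": net.edge_post,
        "weight_pA": net.edge_weight,
        "delay_ms": np.full(net.n_edges, d_EE),
        "kind": "EE",
    })
    with open(path, "w") as fh:
        fh.write(f"# N_E={net.N_E} M={net.M} seed={net.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def load_network(path) -> Network:
    if str(path).endswith(".npz"):
        z = np.load(path)
        return _assemble(int(z["N_E"]), int(z["M"]), z["edge_pre"], z["edge_post"],
                         z["edge_weight"], int(z["seed"]))
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return _assemble(int(meta["N_E"]), int(meta["M"]),
                     df.pre.to_numpy(np.int32), df.post.to_numpy(np.int32),
                     df.weight_pA.to_numpy(float), seed)


def _assemble(N_E, M, pre, post, weight, seed) -> Network:
    order = np.argsort(pre, kind="stable")
    pre, post, weight = pre[order], post[order], weight[order]
    pre_ptr = np.zeros(N_E + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=N_E), out=pre_ptr[1:])
    post_order = np.argsort(post, kind="stable")
    post_ptr = np.zeros(N_E + 1, dtype=np.int64)
    np.cumsum(np.bincount(post, minlength=N_E), out=post_ptr[1:])
    subpop_of = (np.arange(N_E) // (N_E // M)).astype(np.int32)
    return Network(N_E=N_E, M=M, edge_pre=pre.astype(np.int32),
                   edge_post=post.astype(np.int32), edge_weight=weight.astype(float),
                   pre_ptr=pre_ptr, post_order=post_order, post_ptr=post_ptr,
                   subpop_of=subpop_of, seed=seed)


def save_schedule(schedule: StimulusSchedule, path) -> None:
    df = pd.DataFrame({"time_ms": schedule.times_ms, "subpopulation": schedule.subpops})
    with open(path, "w") as fh:
        fh.write(f"# duration_ms={schedule.duration_ms}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_schedule(path) -> StimulusSchedule:
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        df = pd.read_csv(fh, sep="\t")
    return StimulusSchedule(df.time_ms.to_numpy(float),
                            df.subpopulation.to_numpy(np.int32),
                            float(meta["duration_ms"]))
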