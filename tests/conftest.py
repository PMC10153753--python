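import numpy as np
import pytest

from seqreplay import ModelParams, build_network, make_fixture
from seqreplay.network import Network


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def default_net(default_params):
    return build_network(default_params, seed=1)


@pytest.fixture()
def micro():
    return make_fixture("micro", seed=3)


def make_manual_net(N_E: int, M: int, edges, weights) -> Network:
    """Hand-built network from an explicit (pre, post) edge list."""
    pre = np.asarray([e[0] for e in edges], dtype=np.int32)
    post = np.asarray([e[1] for e in edges], dtype=np.int32)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(pre, kind="stable")
    pre, post, w = pre[order], post[order], w[order]
    pre_ptr = np.zeros(N_E + 1, dtype=np.int64)
    np.cumsum(np.bincount(pre, minlength=N_E), out=pre_ptr[1:])
    post_order = np.argsort(post, kind="stable")
    post_ptr = np.zeros(N_E + 1, dtype=np.int64)
    np.cumsum(np.bincount(post, minlength=N_E), out=post_ptr[1:])
    subpop_of = (np.arange(N_E) // (N_E // M)).astype(np.int32)
    return Network(N_E=N_E, M=M, edge_pre=pre, edge_post=post, edge_weight=w,
                   pre_ptr=pre_ptr, post_order=post_order, post_ptr=post_ptr,
                   subpop_of=subpop_of, seed=None)
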