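import numpy as np
import pytest

from clmdca import PottsParameters


def random_params(rng, length, q, scale=0.5):
    p = PottsParameters.zeros(length, q)
    p.h = rng.normal(0.0, scale, (length, q))
    p.e = rng.normal(0.0, scale, p.e.shape)
    return p


def random_msa(rng, m, length, q):
    return rng.integers(0, q, size=(m, length))


def fd_gradient_max_rel_error(fn, params, n_checks, rng, eps=1e-5):
    """Max relative error of the analytic gradient vs central differences."""
    vec = params.to_vector()
    grad = fn(params).gradient.to_vector()
    idx = rng.choice(vec.size, size=min(n_checks, vec.size), replace=False)
    worst = 0.0
    for k in idx:
        vp, vm = vec.copy(), vec.copy()
        vp[k] += eps
        vm[k] -= eps
        fp = fn(PottsParameters.from_vector(vp, params.length, params.q)).value
        fm = fn(PottsParameters.from_vector(vm, params.length, params.q)).value
        numeric = (fp - fm) / (2.0 * eps)
        scale = max(abs(numeric), 1e-6)
        worst = max(worst, abs(numeric - grad[k]) / scale)
    return worst


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
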