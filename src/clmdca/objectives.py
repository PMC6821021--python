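"""Log-likelihood objectives of the Potts model and their exact gradients.

Three objectives are provided, all as mean per-sequence log-likelihoods in
nats over a (possibly reweighted) alignment:

* ``exact_loglik`` -- the actual likelihood, with the global partition
  function computed by brute-force enumeration of all q**L configurations
  (only feasible for tiny models; guarded by a capacity cap).
* ``pseudo_loglik`` -- the pseudo-likelihood: for every sequence, the sum
  over sites i of log P(X_i = x_i | X_{-i} = x_{-i}).
* ``pairwise_composite_loglik`` -- the pairwise composite likelihood: the
  sum over all site pairs {i, j} of log P(X_i, X_j = x_i, x_j | rest), each
  pair conditional normalised over the q*q joint states of the pair.  Value
  and gradient cost O(M * L^2 * q^2).
* ``composite_loglik`` -- the general composite likelihood over an arbitrary
  family of site subsets; conditionals are normalised by enumerating q**|c|
  states per subset.  The singleton family reproduces the pseudo-likelihood,
  the all-pairs family the pairwise composite likelihood, and the single
  full subset the actual likelihood.

The key piece of bookkeeping shared by the tractable objectives is the
per-sequence field vector

    F_i^m(a) = h_i(a) + sum_{k != i} e_ik(a, x_k^m),

from which every site conditional is a softmax over a and every pair
conditional needs only F_i, F_j and an e_ij correction for the doubly
counted background term.  The pair partition function is factorised as
Z_ij = sum_ab exp(u_a) K_ab exp(v_b) with K = exp(e_ij), so no M*q*q
tensor of probabilities is ever materialised.

Gradients are exact for each objective (data moments minus model moments
under the corresponding conditionals) and are returned in the same shape as
the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .potts_model import PottsParameters, pair_index, pair_list

#: refuse to enumerate more configurations than this
ENUMERATION_CAP = 5_000_000


class CapacityError(ValueError):
    """Raised when an objective would require enumerating too many states."""


@dataclass
class SubsetFamily:
    """A family of site subsets defining a general composite likelihood."""

    subsets: list

    def __post_init__(self):
        clean = []
        for c in self.subsets:
            c = tuple(sorted(int(i) for i in c))
            if len(c) == 0:
                raise ValueError("subsets must be nonempty")
            if len(set(c)) != len(c):
                raise ValueError(f"duplicate index within subset {c}")
            clean.append(c)
        self.subsets = clean

    @property
    def order(self) -> int:
        return max(len(c) for c in self.subsets)

    @classmethod
    def singletons(cls, length: int) -> "SubsetFamily":
        return cls([(i,) for i in range(length)])

    @classmethod
    def all_pairs(cls, length: int) -> "SubsetFamily":
        return cls([tuple(p) for p in pair_list(length)])

    @classmethod
    def full(cls, length: int) -> "SubsetFamily":
        return cls([tuple(range(length))])


@dataclass
class ObjectiveValue:
    """An objective value (nats, mean per sequence) and its gradient."""

    value: float
    gradient: PottsParameters


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _as_matrix(aln) -> np.ndarray:
    mat = getattr(aln, "sequences", aln)
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError("alignment must be an (M, L) matrix")
    return mat.astype(np.intp, copy=False)


def _norm_weights(weights, m: int) -> np.ndarray:
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(getattr(weights, "weights", weights), dtype=np.float64)
        if w.shape != (m,):
            raise ValueError(f"weights must have length {m}, got {w.shape}")
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    return w


def _check_inputs(params: PottsParameters, mat: np.ndarray):
    if mat.shape[1] != params.length:
        raise ValueError(
            f"alignment has L={mat.shape[1]} but model has L={params.length}"
        )
    if mat.max() >= params.q or mat.min() < 0:
        raise ValueError("alignment symbol code out of range for this model")


def _one_hot(mat: np.ndarray, q: int) -> np.ndarray:
    m, length = mat.shape
    x1 = np.zeros((m, length, q))
    np.put_along_axis(x1, mat[:, :, None], 1.0, axis=2)
    return x1


def _site_fields(params: PottsParameters, x1_flat: np.ndarray) -> np.ndarray:
    """F[m, i, a] = h_i(a) + sum_{k != i} e_ik(a, x_k^m), via one BLAS matmul."""
    w = params.coupling_block_matrix()
    f = params.h.ravel()[None, :] + x1_flat @ w
    return f.reshape(x1_flat.shape[0], params.length, params.q)


def _weighted_pair_counts(mat, wn, pairs, q) -> np.ndarray:
    """Data moments f_ij(a, b) = sum_m wn_m [x_i = a][x_j = b] for all pairs."""
    counts = np.empty((len(pairs), q, q))
    for p, (i, j) in enumerate(pairs):
        idx = mat[:, i] * q + mat[:, j]
        counts[p] = np.bincount(idx, weights=wn, minlength=q * q).reshape(q, q)
    return counts


# ---------------------------------------------------------------------------
# exact likelihood (brute-force enumeration)
# ---------------------------------------------------------------------------

def _enumerate_configs(length: int, q: int) -> np.ndarray:
    n = q ** length
    if n > ENUMERATION_CAP:
        raise CapacityError(
            f"q**L = {n} exceeds the enumeration cap ({ENUMERATION_CAP}); "
            "use the pseudo or pairwise composite objective instead"
        )
    return np.stack(
        np.unravel_index(np.arange(n), (q,) * length), axis=1
    ).astype(np.intp)


def _config_energies(params: PottsParameters, configs: np.ndarray) -> np.ndarray:
    pairs = pair_list(params.length)
    en = params.h[np.arange(params.length), configs].sum(axis=1)
    for p, (i, j) in enumerate(pairs):
        en += params.e[p, configs[:, i], configs[:, j]]
    return en


def exact_loglik(params: PottsParameters, aln, weights=None) -> ObjectiveValue:
    """Mean log-likelihood with the partition function from full enumeration.

    Only feasible while q**L stays under :data:`ENUMERATION_CAP`; larger
    models raise :class:`CapacityError`.
    """
    mat = _as_matrix(aln)
    _check_inputs(params, mat)
    m, length = mat.shape
    q = params.q
    wn = _norm_weights(weights, m)
    configs = _enumerate_configs(length, q)
    energies = _config_energies(params, configs)
    log_z = float(logsumexp(energies))
    data_energy = float(_config_energies(params, mat) @ wn)
    value = data_energy - log_z

    probs = np.exp(energies - log_z)
    pairs = pair_list(length)
    grad = PottsParameters.zeros(length, q)
    for i in range(length):
        data_f = np.bincount(mat[:, i], weights=wn, minlength=q)
        model_f = np.bincount(configs[:, i], weights=probs, minlength=q)
        grad.h[i] = data_f - model_f
    data_pair = _weighted_pair_counts(mat, wn, pairs, q)
    for p, (i, j) in enumerate(pairs):
        idx = configs[:, i] * q + configs[:, j]
        model_pair = np.bincount(idx, weights=probs, minlength=q * q).reshape(q, q)
        grad.e[p] = data_pair[p] - model_pair
    return ObjectiveValue(value, grad)


# ---------------------------------------------------------------------------
# pseudo-likelihood
# ---------------------------------------------------------------------------

def pseudo_loglik(params: PottsParameters, aln, weights=None) -> ObjectiveValue:
    """Mean pseudo-log-likelihood: per-site conditionals given all other sites."""
    mat = _as_matrix(aln)
    _check_inputs(params, mat)
    m, length = mat.shape
    q = params.q
    wn = _norm_weights(weights, m)
    x1 = _one_hot(mat, q)
    x1_flat = x1.reshape(m, length * q)
    f = _site_fields(params, x1_flat)
    lse = logsumexp(f, axis=2)
    f_obs = np.take_along_axis(f, mat[:, :, None], axis=2)[:, :, 0]
    value = float(wn @ (f_obs - lse).sum(axis=1))

    p_cond = np.exp(f - lse[:, :, None])
    resid = (x1 - p_cond) * wn[:, None, None]
    grad = PottsParameters.zeros(length, q)
    grad.h = resid.sum(axis=0)
    # site i's conditional contributes (delta - p)_ia * [x_j = b] to e_ij
    g = resid.reshape(m, length * q).T @ x1_flat
    g4 = g.reshape(length, q, length, q)
    pairs = pair_list(length)
    ii, jj = pairs[:, 0], pairs[:, 1]
    grad.e = g4[ii, :, jj, :] + g4[jj, :, ii, :].transpose(0, 2, 1)
    return ObjectiveValue(value, grad)


# ---------------------------------------------------------------------------
# pairwise composite likelihood
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@_njit(cache=True)
def _pairwise_kernel(e, exp_e, cmax, mat, wn, f, pairs, pidx):  # pragma: no cover
    m_seq, length = mat.shape
    q = f.shape[2]
    n_pairs = pairs.shape[0]
    value = 0.0
    dh = np.zeros((length, q))
    de = np.zeros((n_pairs, q, q))
    eu = np.empty(q)
    ev = np.empty(q)
    # per-sequence scratch: pair marginals of each pair's two sites, and the
    # per-site sum of marginals over all pair conditionals containing it
    qp_i = np.empty((n_pairs, q))
    qp_j = np.empty((n_pairs, q))
    q_site = np.empty((length, q))
    for m in range(m_seq):
        w = wn[m]
        for i in range(length):
            for a in range(q):
                q_site[i, a] = 0.0
        for p in range(n_pairs):
            i = pairs[p, 0]
            j = pairs[p, 1]
            xi = mat[m, i]
            xj = mat[m, j]
            umax = -1e300
            vmax = -1e300
            for a in range(q):
                ua = f[m, i, a] - e[p, a, xj]
                eu[a] = ua
                if ua > umax:
                    umax = ua
                va = f[m, j, a] - e[p, xi, a]
                ev[a] = va
                if va > vmax:
                    vmax = va
            for a in range(q):
                # clamp to avoid subnormal results (libm slow path)
                ua = eu[a] - umax
                eu[a] = np.exp(ua) if ua > -700.0 else 0.0
                va = ev[a] - vmax
                ev[a] = np.exp(va) if va > -700.0 else 0.0
            z = 0.0
            for a in range(q):
                qp_j[p, a] = 0.0
            for a in range(q):
                s = 0.0
                for b in range(q):
                    t = exp_e[p, a, b] * ev[b]
                    s += t
                    qp_j[p, b] += eu[a] * t
                qp_i[p, a] = eu[a] * s
                z += eu[a] * s
            inv = 1.0 / z
            value += w * (
                f[m, i, xi] + f[m, j, xj] - e[p, xi, xj]
                - (np.log(z) + umax + vmax + cmax[p])
            )
            dh[i, xi] += w
            dh[j, xj] += w
            for a in range(q):
                qp_i[p, a] *= inv
                qp_j[p, a] *= inv
                q_site[i, a] += qp_i[p, a]
                q_site[j, a] += qp_j[p, a]
                dh[i, a] -= w * qp_i[p, a]
                dh[j, a] -= w * qp_j[p, a]
            de[p, xi, xj] += w
            for a in range(q):
                wa = w * eu[a] * inv
                for b in range(q):
                    de[p, a, b] -= wa * exp_e[p, a, b] * ev[b]
        # background terms: e_ij also enters (at the observed symbol of the
        # partner column) every pair conditional {i, k} and {j, k}, k outside
        for p in range(n_pairs):
            i = pairs[p, 0]
            j = pairs[p, 1]
            xi = mat[m, i]
            xj = mat[m, j]
            de[p, xi, xj] += 2.0 * (length - 2) * w
            for a in range(q):
                de[p, a, xj] -= w * (q_site[i, a] - qp_i[p, a])
                de[p, xi, a] -= w * (q_site[j, a] - qp_j[p, a])
    return value, dh, de


def _pairwise_composite_compiled(params, mat, wn, f) -> ObjectiveValue:
    length, q = params.length, params.q
    pairs = pair_list(length).astype(np.int64)
    pidx = np.zeros((length, length), dtype=np.int64)
    for p, (i, j) in enumerate(pairs):
        pidx[i, j] = pidx[j, i] = p
    cmax = params.e.max(axis=(1, 2))
    exp_e = np.exp(np.maximum(params.e - cmax[:, None, None], -700.0))
    value, dh, de = _pairwise_kernel(
        params.e, exp_e, cmax, mat.astype(np.int64), wn, f, pairs, pidx
    )
    return ObjectiveValue(float(value), PottsParameters(dh, de))


def pairwise_composite_loglik(
    params: PottsParameters, aln, weights=None, engine: str | None = None
) -> ObjectiveValue:
    """Mean pairwise composite log-likelihood over all site pairs.

    Each term is the conditional probability of the observed pair
    (x_i, x_j) given the remaining sites, normalised by the pair partition
    function Z_ij summed over all q*q joint states.

    ``engine`` selects the implementation: "compiled" (numba, the default
    when numba is importable) or "numpy" (pure vectorised reference).  Both
    compute identical values and gradients.
    """
    if engine is None:
        engine = "compiled" if _HAVE_NUMBA else "numpy"
    mat = _as_matrix(aln)
    if engine == "compiled":
        _check_inputs(params, mat)
        m = mat.shape[0]
        wn = _norm_weights(weights, m)
        x1_flat = _one_hot(mat, params.q).reshape(m, params.length * params.q)
        f = _site_fields(params, x1_flat)
        return _pairwise_composite_compiled(params, mat, wn, f)
    if engine != "numpy":
        raise ValueError(f"unknown engine {engine!r}")
    _check_inputs(params, mat)
    m, length = mat.shape
    q = params.q
    wn = _norm_weights(weights, m)
    x1 = _one_hot(mat, q)
    x1_flat = x1.reshape(m, length * q)
    f = _site_fields(params, x1_flat)
    pairs = pair_list(length)
    rows = np.arange(m)

    f_single = x1 * wn[:, None, None]
    data_f = f_single.sum(axis=0)                       # (L, q)
    data_pair = _weighted_pair_counts(mat, wn, pairs, q)

    value = 0.0
    # q_sum[m, i, a] accumulates the model pair-marginals of site i over all
    # pair conditionals {i, j} containing it
    q_sum = np.zeros((length, m, q))
    de = np.empty((len(pairs), q, q))
    s_corr = np.empty((len(pairs), q, q))  # in-pair part of the cross term
    chunk = max(1, min(len(pairs), 4_000_000 // (m * q)))
    for start in range(0, len(pairs), chunk):
        sl = slice(start, min(start + chunk, len(pairs)))
        ii, jj = pairs[sl, 0], pairs[sl, 1]
        b = len(ii)
        barange = np.arange(b)
        eij = params.e[sl]                              # (b, q, q)
        xi, xj = mat[:, ii], mat[:, jj]                 # (m, b)
        u = f[:, ii, :] - eij[barange[None, :], :, xj]  # (m, b, q)
        v = f[:, jj, :] - eij[barange[None, :], xi, :]
        umax = u.max(axis=2)
        vmax = v.max(axis=2)
        eu = np.exp(u - umax[:, :, None])               # (m, b, q)
        ev = np.exp(v - vmax[:, :, None])
        c = eij.max(axis=(1, 2))
        k = np.exp(eij - c[:, None, None])              # (b, q, q)
        eu_t = np.ascontiguousarray(eu.transpose(1, 0, 2))   # (b, m, q)
        ev_t = np.ascontiguousarray(ev.transpose(1, 0, 2))
        t1 = eu_t @ k                                   # (b, m, q_b)
        t2 = ev_t @ k.transpose(0, 2, 1)                # (b, m, q_a)
        z = (t1 * ev_t).sum(axis=2)                     # (b, m)
        log_z = np.log(z) + umax.T + vmax.T + c[:, None]
        u_obs = u[rows[:, None], barange[None, :], xi]  # (m, b)
        v_obs = v[rows[:, None], barange[None, :], xj]
        e_obs = eij[barange[None, :], xi, xj]
        value += float(wn @ (u_obs + v_obs + e_obs - log_z.T).sum(axis=1))
        qi = eu_t * t2 / z[:, :, None]                  # (b, m, q)
        qj = ev_t * t1 / z[:, :, None]
        np.add.at(q_sum, ii, qi)
        np.add.at(q_sum, jj, qj)
        a_w = eu_t * (wn[None, :] / z)[:, :, None]
        de[sl] = data_pair[sl] - k * (a_w.transpose(0, 2, 1) @ ev_t)
        x1i = np.ascontiguousarray(x1[:, ii, :].transpose(1, 0, 2))
        x1j = np.ascontiguousarray(x1[:, jj, :].transpose(1, 0, 2))
        wq = wn[None, :, None]
        s_corr[sl] = (qi * wq).transpose(0, 2, 1) @ x1j + x1i.transpose(
            0, 2, 1
        ) @ (qj * wq)
    q_sum = q_sum.transpose(1, 0, 2)                    # (m, L, q)

    grad = PottsParameters.zeros(length, q)
    grad.h = (length - 1) * data_f - np.einsum("m,mia->ia", wn, q_sum)
    # cross terms: e_ij also appears (at the observed background symbol) in
    # every pair conditional {i, k} and {j, k} with k outside the pair
    g1 = (q_sum.reshape(m, length * q) * wn[:, None]).T @ x1_flat
    g1 = g1.reshape(length, q, length, q)
    ii, jj = pairs[:, 0], pairs[:, 1]
    t_i = g1[ii, :, jj, :]
    t_j = g1[jj, :, ii, :].transpose(0, 2, 1)
    grad.e = de + (2 * length - 4) * data_pair - t_i - t_j + s_corr
    return ObjectiveValue(value, grad)


# ---------------------------------------------------------------------------
# general composite likelihood over an arbitrary subset family
# ---------------------------------------------------------------------------

def composite_loglik(
    params: PottsParameters, aln, weights=None, family: SubsetFamily | None = None
) -> ObjectiveValue:
    """Mean composite log-likelihood over an arbitrary family of site subsets.

    For every subset c the conditional P(X_c = x_c | rest) is normalised by
    enumerating all q**|c| joint states of the subset, so subset sizes are
    limited by :data:`ENUMERATION_CAP`.  This generality is what permits
    3rd- and higher-order composite likelihoods at toy scale.
    """
    if family is None:
        raise ValueError("a SubsetFamily is required")
    mat = _as_matrix(aln)
    _check_inputs(params, mat)
    m, length = mat.shape
    q = params.q
    wn = _norm_weights(weights, m)
    for c in family.subsets:
        if max(c) >= length:
            raise ValueError(f"subset {c} out of range for L={length}")
    x1 = _one_hot(mat, q)
    x1_flat = x1.reshape(m, length * q)
    f = _site_fields(params, x1_flat)
    e4 = params.coupling_block_matrix().reshape(length, q, length, q)

    value = 0.0
    grad = PottsParameters.zeros(length, q)
    for c in family.subsets:
        s = len(c)
        assign = _enumerate_configs(s, q) if s > 1 else np.arange(q)[:, None]
        n_assign = assign.shape[0]
        # energy of each candidate assignment of the subset given the rest
        en = np.zeros((m, n_assign))
        for idx, ci in enumerate(c):
            en += f[:, ci, :][:, assign[:, idx]]
            for jdx, cj in enumerate(c):
                if jdx == idx:
                    continue
                b = e4[ci, :, cj, :]
                # remove the in-subset background term double counted in F
                en -= b[assign[:, idx]][:, mat[:, cj]].T
        for idx in range(s):
            for jdx in range(idx + 1, s):
                b = e4[c[idx], :, c[jdx], :]
                en += b[assign[:, idx], assign[:, jdx]][None, :]
        lse = logsumexp(en, axis=1)
        # index of the observed assignment in mixed-radix order
        obs = np.zeros(m, dtype=np.intp)
        for idx, ci in enumerate(c):
            obs = obs * q + mat[:, ci]
        value += float(wn @ (en[np.arange(m), obs] - lse))

        gamma = np.exp(en - lse[:, None])               # (m, n_assign)
        onehot_a = np.zeros((n_assign, s, q))
        np.put_along_axis(onehot_a, assign[:, :, None], 1.0, axis=2)
        marg = np.einsum("mt,tsq->msq", gamma, onehot_a)
        resid = (x1[:, list(c), :] - marg) * wn[:, None, None]
        for idx, ci in enumerate(c):
            grad.h[ci] += resid[:, idx, :].sum(axis=0)
            # couplings to sites outside the subset (background symbols)
            for k in range(length):
                if k in c:
                    continue
                block = resid[:, idx, :].T @ x1[:, k, :]
                if ci < k:
                    grad.e[pair_index(ci, k, length)] += block
                else:
                    grad.e[pair_index(k, ci, length)] += block.T
        for idx in range(s):
            for jdx in range(idx + 1, s):
                ci, cj = c[idx], c[jdx]
                gw = wn @ gamma
                pair_model = np.einsum(
                    "t,ta,tb->ab", gw, onehot_a[:, idx, :], onehot_a[:, jdx, :]
                )
                data_block = (x1[:, ci, :] * wn[:, None]).T @ x1[:, cj, :]
                grad.e[pair_index(ci, cj, length)] += data_block - pair_model
    return ObjectiveValue(value, grad)


# ---------------------------------------------------------------------------
# L2 penalty
# ---------------------------------------------------------------------------

def add_l2_penalty(
    obj: ObjectiveValue,
    params: PottsParameters,
    lambda_h: float = 0.0,
    lambda_e: float = 0.0,
) -> ObjectiveValue:
    """Subtract a ridge penalty lambda_h*sum(h^2) + lambda_e*sum(e^2).

    Each coupling matrix is stored (and penalised) once per unordered pair.
    The gradient is adjusted by -2*lambda*param elementwise.
    """
    if lambda_h < 0 or lambda_e < 0:
        raise ValueError("penalty strengths must be nonnegative")
    value = obj.value - lambda_h * float((params.h ** 2).sum()) - lambda_e * float(
        (params.e ** 2).sum()
    )
    grad = PottsParameters(
        obj.gradient.h - 2.0 * lambda_h * params.h,
        obj.gradient.e - 2.0 * lambda_e * params.e,
    )
    return ObjectiveValue(value, grad)
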