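"""Synthetic alignments from known Potts models, for end-to-end validation.

A planted model has a handful of strongly coupled column pairs (low-rank
coupling matrices of controlled Frobenius norm) against a background of
zero couplings, so which pairs are "contacts" is known by construction.
Alignments are drawn by single-site Gibbs sampling -- by default one
independent chain per sequence, which removes autocorrelation between rows
(real alignments violate row independence through phylogeny; emulating that
is deliberately out of scope, which is exactly why the reweighting module
exists for real data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import Alignment
from .potts_model import PottsParameters, pair_index


@dataclass
class PlantedModel:
    """A Potts model with a known set of strongly coupled pairs."""

    params: PottsParameters
    contact_pairs: set
    seed: int


def make_planted_model(
    length: int,
    q: int,
    n_contacts: int,
    coupling_scale: float = 3.0,
    field_scale: float = 0.3,
    seed: int = 0,
) -> PlantedModel:
    """Build a sparse-coupling Potts model with ``n_contacts`` planted pairs.

    Fields are independent Normal(0, field_scale).  Each planted pair gets a
    random rank-2 coupling matrix rescaled to Frobenius norm
    ``coupling_scale``; all other pairs are exactly zero, so the planted
    pairs dominate every coupling-strength ranking by construction.
    """
    n_pairs = length * (length - 1) // 2
    if n_contacts > n_pairs:
        raise ValueError(
            f"requested {n_contacts} contacts but only {n_pairs} pairs exist"
        )
    rng = np.random.default_rng(seed)
    params = PottsParameters.zeros(length, q)
    params.h = rng.normal(0.0, field_scale, size=(length, q))
    chosen = rng.choice(n_pairs, size=n_contacts, replace=False)
    pairs = [(i, j) for i in range(length) for j in range(i + 1, length)]
    contact_pairs = set()
    for p in chosen:
        u = rng.normal(size=(q, 2))
        v = rng.normal(size=(2, q))
        mat = u @ v
        mat *= coupling_scale / np.linalg.norm(mat)
        params.e[p] = mat
        contact_pairs.add(pairs[p])
    return PlantedModel(params, contact_pairs, int(seed))


def gibbs_sample_msa(
    model: PlantedModel | PottsParameters,
    n_sequences: int,
    burn_in: int = 100,
    thinning: int = 10,
    seed: int = 0,
    independent_chains: bool = True,
) -> Alignment:
    """Draw an alignment from the model by single-site Gibbs sweeps.

    With ``independent_chains`` (default) every sequence is the endpoint of
    its own chain after ``burn_in`` sweeps; otherwise a single chain is
    thinned by ``thinning`` sweeps between kept samples.  Deterministic
    given ``seed``.
    """
    params = model.params if isinstance(model, PlantedModel) else model
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if burn_in < 0 or thinning < 0:
        raise ValueError("burn_in and thinning must be nonnegative")
    length, q = params.length, params.q
    w_block = params.coupling_block_matrix()            # (L*q, L*q), sym
    rng = np.random.default_rng(seed)

    def sweep(state):
        # state: (n_chains, L); resample each site in fixed order, keeping a
        # one-hot copy so each conditional is a single BLAS product
        n = state.shape[0]
        onehot = np.zeros((n, length * q))
        onehot[np.arange(n)[:, None], np.arange(length)[None, :] * q + state] = 1.0
        for i in range(length):
            # logits[n, a] = h_i(a) + sum_{k != i} e_ik(a, x_k)
            logits = params.h[i][None, :] + onehot @ w_block[:, i * q : (i + 1) * q]
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            new = (probs.cumsum(axis=1) < u).sum(axis=1)
            onehot[np.arange(n), i * q + state[:, i]] = 0.0
            onehot[np.arange(n), i * q + new] = 1.0
            state[:, i] = new
        return state

    if independent_chains:
        state = rng.integers(0, q, size=(n_sequences, length))
        for _ in range(burn_in):
            state = sweep(state)
        samples = state
    else:
        state = rng.integers(0, q, size=(1, length))
        for _ in range(burn_in):
            state = sweep(state)
        rows = [state[0].copy()]
        while len(rows) < n_sequences:
            for _ in range(max(thinning, 1)):
                state = sweep(state)
            rows.append(state[0].copy())
        samples = np.stack(rows)
    ids = [f"sample{k}" for k in range(n_sequences)]
    from .msa_io import ALPHABET

    return Alignment(samples.astype(np.int8), ids=ids, alphabet=ALPHABET[:q])


def exact_distribution(params: PottsParameters) -> np.ndarray:
    """Exact configuration probabilities by enumeration (tiny models only)."""
    from .objectives import _config_energies, _enumerate_configs

    configs = _enumerate_configs(params.length, params.q)
    en = _config_energies(params, configs)
    en -= en.max()
    p = np.exp(en)
    return p / p.sum()


def recovery_benchmark(
    length: int = 30,
    q: int = 8,
    n_contacts: int = 40,
    n_sequences: int = 2000,
    objective: str = "pairwise_composite",
    seed: int = 0,
    coupling_scale: float = 3.0,
    field_scale: float = 0.3,
    burn_in: int = 100,
    max_iterations: int = 100,
    gradient_tolerance: float = 1e-3,
) -> dict:
    """Plant a model, sample an MSA, fit, and score planted-pair recovery.

    Returns a report with ``precision_at_n_contacts``: the fraction of the
    top ``n_contacts`` pairs (ranked by fitted Frobenius coupling strength,
    all separations) that were planted.  Deterministic given ``seed``.
    """
    from .contact_eval import rank_contacts
    from .estimation import PottsDCA

    ss = np.random.SeedSequence(seed)
    model_seed, sample_seed = (int(s) for s in ss.generate_state(2) >> 1)
    model = make_planted_model(
        length, q, n_contacts, coupling_scale, field_scale, seed=model_seed
    )
    aln = gibbs_sample_msa(model, n_sequences, burn_in=burn_in, seed=sample_seed)
    est = PottsDCA(
        objective=objective,
        max_iterations=max_iterations,
        gradient_tolerance=gradient_tolerance,
    )
    est.fit(aln)
    ranked = rank_contacts(est.coupling_scores_, min_separation=1)
    top = ranked.entries[:n_contacts]
    hits = sum(1 for i, j, _ in top if (i, j) in model.contact_pairs)
    return {
        "length": length,
        "q": q,
        "n_contacts": n_contacts,
        "n_sequences": n_sequences,
        "objective": objective,
        "seed": int(seed),
        "n_eff": est.n_eff_,
        "converged": est.converged_,
        "iterations": est.n_iter_,
        "precision_at_n_contacts": hits / n_contacts,
    }
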