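"""Maximum-likelihood admixture inference with Evanno ΔK model choice.

Fits the standard admixture model: accession ``i`` draws each of its
two allele copies at locus ``l`` from gene pool ``k`` with probability
``q_ik``, and a copy from pool ``k`` is the alternative allele with
probability ``p_kl``.  The binomial log-likelihood

    L = sum_{i,l} [ g_il log(sum_k q_ik p_kl)
                  + (2 - g_il) log(sum_k q_ik (1 - p_kl)) ]

(missing calls skipped) is maximised by an EM algorithm whose updates
are guaranteed monotone.  This is a maximum-likelihood stand-in for
Bayesian MCMC structure inference: the point estimates of Q and P are
the same quantities, and replicate log-likelihoods play the role of
the model log-probability in the Evanno ΔK statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import MISSING, GenotypeMatrix, group_indices

_P_EPS = 1e-6  # keep pool frequencies away from {0,1}


@dataclass
class AdmixtureFit:
    """One EM fit: membership matrix Q, pool frequencies P, likelihood."""

    K: int
    Q: np.ndarray                    # accessions x K, row-stochastic
    P: np.ndarray                    # K x loci in [eps, 1-eps]
    loglik: float
    seed: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)


def _loglik(g, valid, Q, P) -> float:
    f = np.clip(Q @ P, _P_EPS, 1.0 - _P_EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(valid, g * np.log(f) + (2.0 - g) * np.log1p(-f), 0.0)
    return float(ll.sum())


def fit_admixture(gm: GenotypeMatrix, K: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-6) -> AdmixtureFit:
    """EM fit of the admixture likelihood from a seeded random start.

    Stops when the log-likelihood improves by less than ``tol`` or
    after ``max_iter`` iterations.  ``K = 1`` reduces to the panel
    allele frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_accessions:
        raise ValueError(f"K={K} exceeds the {gm.n_accessions} accessions")
    rng = np.random.default_rng(seed)
    calls = gm.calls
    valid = calls != MISSING
    g = np.where(valid, calls, 0).astype(np.float64)
    n, L = g.shape
    n_valid = 2.0 * valid.sum(axis=1)  # allele copies per accession

    # start near the panel frequencies with pool-specific jitter
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(valid.sum(axis=0) > 0,
                        g.sum(axis=0) / np.maximum(2.0 * valid.sum(axis=0), 1.0),
                        0.5)
    P = np.clip(pbar[None, :] + rng.uniform(-0.1, 0.1, size=(K, L)),
                _P_EPS, 1.0 - _P_EPS)
    Q = rng.dirichlet(np.ones(K), size=n)

    trace = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = np.clip(Q @ P, _P_EPS, 1.0 - _P_EPS)
        A = np.where(valid, g / f, 0.0)
        B = np.where(valid, (2.0 - g) / (1.0 - f), 0.0)
        # responsibilities folded into multiplicative updates
        QA = Q * (A @ P.T + B @ (1.0 - P).T)     # n x K
        P_num = P * (Q.T @ A)                     # K x L
        P_den = P_num + (1.0 - P) * (Q.T @ B)
        Q = QA / np.maximum(n_valid[:, None], 1.0)
        Q = Q / Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(P_den > 0, P_num / np.maximum(P_den, 1e-300), P)
        P = np.clip(P, _P_EPS, 1.0 - _P_EPS)
        ll = _loglik(g, valid, Q, P)
        trace.append(ll)
        if ll - ll_old < tol and it > 1:
            converged = True
            break
        ll_old = ll
    return AdmixtureFit(K, Q, P, trace[-1], seed, it, converged,
                        np.asarray(trace))


def align_replicates(
    fits: list[AdmixtureFit],
) -> tuple[list[tuple[int, ...]], np.ndarray, np.ndarray]:
    """Align pool labels across replicate fits of the same K.

    Exhaustive search over column permutations for K <= 8, Hungarian
    assignment above, minimising ``sum |Q_ref - Q_rep[:, perm]|``
    against the first replicate.  Returns the permutations, the
    consensus (mean aligned Q, re-normalised) and the matrix of mean
    absolute differences between aligned replicates.
    """
    if len(fits) < 2:
        raise ValueError("need at least two replicates to align")
    K = fits[0].K
    if any(f.K != K for f in fits):
        raise ValueError("replicates have mixed K")
    ref = fits[0].Q
    perms: list[tuple[int, ...]] = []
    aligned = []
    for f in fits:
        if K <= 8:
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(K)):
                cost = np.abs(ref - f.Q[:, perm]).sum()
                if cost < best_cost:
                    best, best_cost = perm, cost
            perm = best
        else:
            cost = np.array([[np.abs(ref[:, a] - f.Q[:, b]).sum()
                              for b in range(K)] for a in range(K)])
            _, cols = linear_sum_assignment(cost)
            perm = tuple(int(c) for c in cols)
        perms.append(perm)
        aligned.append(f.Q[:, perm])
    consensus = np.mean(aligned, axis=0)
    consensus = consensus / consensus.sum(axis=1, keepdims=True)
    m = len(aligned)
    sim = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            sim[a, b] = np.abs(aligned[a] - aligned[b]).mean()
    return perms, consensus, sim


def evanno_delta_k(loglik_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK from a table of log-likelihoods (index K, one column per replicate).

    ``ΔK = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K))``,
    defined for interior K only.  Zero replicate spread yields an
    infinite ΔK with a warning.  The chosen K maximises ΔK.
    """
    tab = loglik_table.sort_index()
    ks = tab.index.to_numpy()
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >= 3 consecutive K values")
    if tab.shape[1] < 2:
        raise ValueError("need >= 2 replicates per K")
    vals = tab.to_numpy(dtype=float)
    mean_l = vals.mean(axis=1)
    sd_l = vals.std(axis=1, ddof=1)
    second = np.abs(vals[2:] - 2.0 * vals[1:-1] + vals[:-2]).mean(axis=1)
    delta = np.full(len(ks), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta[1:-1] = second / sd_l[1:-1]
    if np.any(sd_l[1:-1] == 0):
        warnings.warn("zero replicate spread at some K; ΔK infinite there",
                      stacklevel=2)
    out = pd.DataFrame({"K": ks, "mean_loglik": mean_l, "sd_loglik": sd_l,
                        "delta_k": delta})
    interior = out["delta_k"].iloc[1:-1]
    if interior.notna().any() and np.nanmax(interior.to_numpy()) > 0:
        chosen = int(out.loc[interior.idxmax(), "K"])
    else:
        chosen = None
        warnings.warn("no ΔK peak (flat likelihood profile)", stacklevel=2)
    out.attrs["chosen_k"] = chosen
    return out


def assign_memberships(Q: np.ndarray, threshold: float = 0.8) -> list[str]:
    """Per-accession label: ``pool_<k>`` if max membership >= threshold, else admixed."""
    Q = np.asarray(Q, dtype=float)
    labels = []
    for row in Q:
        k = int(row.argmax())
        labels.append(f"pool_{k + 1}" if row[k] >= threshold else "admixed")
    return labels


def pool_proportions_by_group(Q: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean pool membership per breeding-period group (rows sum to 1)."""
    merged = Q.join(meta.set_index("accession_id")["group"], how="inner")
    if merged["group"].isna().any() or len(merged) == 0:
        raise ValueError("metadata does not cover the Q matrix accessions")
    props = merged.groupby("group", sort=False).mean(numeric_only=True)
    return props.div(props.sum(axis=1), axis=0)


def run_admixture_grid(
    gm: GenotypeMatrix,
    k_values=range(1, 17),
    n_replicates: int = 6,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[dict[int, list[AdmixtureFit]], pd.DataFrame]:
    """Replicated fits over a K range plus the ΔK table.

    Replicate seeds are derived deterministically from ``seed`` so the
    whole grid is reproducible; the study-scale defaults are K = 1..16
    with six replicates each.
    """
    fits: dict[int, list[AdmixtureFit]] = {}
    rows = {}
    for K in k_values:
        fits[K] = [
            fit_admixture(gm, K, seed=(seed * 7919 + 1009 * K + r) % (2**31),
                          max_iter=max_iter, tol=tol)
            for r in range(n_replicates)
        ]
        rows[K] = [f.loglik for f in fits[K]]
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "K"
    delta = evanno_delta_k(table) if len(rows) >= 3 else None
    return fits, delta
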