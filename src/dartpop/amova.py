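"""Distance-based analysis of molecular variance (AMOVA).

Partitions the total molecular variance of a panel, expressed through
squared pairwise distances, into among-group and within-group
components (Excoffier's sums of squares), with the fixation statistic
``Phi_ST = sigma2_among / (sigma2_among + sigma2_within)`` and a label
permutation test.  The unequal-sample-size coefficient ``n0 =
(N - sum n_g^2 / N) / (k - 1)`` scales the among-group mean square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int
    permuted_phi: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        d = {k: getattr(self, k) for k in (
            "ss_among", "ss_within", "df_among", "df_within",
            "sigma2_among", "sigma2_within", "pct_among", "pct_within",
            "phi_st", "p_value", "n_permutations", "seed")}
        return pd.DataFrame([d])


def _ss_within(d2: np.ndarray, group_of: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for g in labels:
        ix = np.flatnonzero(group_of == g)
        ss += d2[np.ix_(ix, ix)].sum() / (2.0 * ix.size)
    return ss


def _phi(d2: np.ndarray, group_of: np.ndarray, labels, n, k, n0,
         df_within) -> tuple[float, float, float]:
    ss_w = _ss_within(d2, group_of, labels)
    ss_t = d2.sum() / (2.0 * n)
    ss_a = ss_t - ss_w
    s2_w = ss_w / df_within
    s2_a = (ss_a / (k - 1) - s2_w) / n0
    s2_a = max(s2_a, 0.0)
    phi = s2_a / (s2_a + s2_w) if (s2_a + s2_w) > 0 else 0.0
    return phi, ss_a, ss_w


def amova(D: DistanceMatrix, groups, n_permutations: int = 999,
          seed: int = 0) -> AmovaResult:
    """AMOVA over a distance matrix and a group label per accession.

    ``groups`` is a sequence of labels aligned with ``D.accession_ids``.
    The p-value uses the ``(b + 1)/(m + 1)`` form over label
    permutations with ``Phi_ST >= observed``.
    """
    group_of = np.asarray([str(g) for g in groups], dtype=object)
    n = D.values.shape[0]
    if group_of.size != n:
        raise ValueError("one group label per accession required")
    labels, counts = np.unique(group_of, return_counts=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        bad = labels[counts < 2][0]
        raise ValueError(f"group {bad!r} has fewer than two accessions")
    d2 = D.values**2
    df_among, df_within = k - 1, n - k
    n0 = (n - (counts**2).sum() / n) / (k - 1)

    phi_obs, ss_a, ss_w = _phi(d2, group_of, labels, n, k, n0, df_within)
    s2_w = ss_w / df_within
    s2_a = max((ss_a / df_among - s2_w) / n0, 0.0)
    total = s2_a + s2_w

    rng = np.random.default_rng(seed)
    perm_phi = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(group_of)
        perm_phi[b], _, _ = _phi(d2, perm, labels, n, k, n0, df_within)
    p = (np.sum(perm_phi >= phi_obs) + 1.0) / (n_permutations + 1.0)

    return AmovaResult(
        ss_among=ss_a, ss_within=ss_w,
        df_among=df_among, df_within=df_within,
        sigma2_among=s2_a, sigma2_within=s2_w,
        pct_among=100.0 * s2_a / total if total > 0 else 0.0,
        pct_within=100.0 * s2_w / total if total > 0 else 100.0,
        phi_st=phi_obs, p_value=float(p),
        n_permutations=n_permutations, seed=seed,
        permuted_phi=perm_phi,
    )
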