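"""Identity-by-descent estimation and duplicate-accession detection.

The method-of-moments estimator follows the PLINK approach: for every
accession pair, the counts of loci identical-by-state at 0, 1 and 2
alleles are compared with their expectations under the panel's allele
frequencies, yielding estimates of the probabilities of sharing 0, 1
or 2 alleles identical by descent.  The summary statistic is
``PI-HAT = P(IBD=2) + P(IBD=1)/2``.  Negative component estimates are
truncated to 0 and the triple renormalised.

Duplicate accessions are the connected components of the graph whose
edges join pairs with PI-HAT above a cutoff (default 0.95); a
multi-evidence verdict table combines passport flags, genetic
distance, population-structure assignment and IBD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix
from .types import MISSING, GenotypeMatrix

#: pairs with fewer jointly non-missing loci than this are low-confidence
MIN_JOINT_LOCI = 50


@dataclass
class IbdMatrix:
    """Symmetric PI-HAT matrix with unit diagonal."""

    pihat: np.ndarray
    accession_ids: list[str]
    low_confidence: np.ndarray = None  # boolean mask of under-covered pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pihat, index=self.accession_ids,
                            columns=self.accession_ids)


def ibd_pihat(gm: GenotypeMatrix,
              allele_freqs: np.ndarray | None = None) -> IbdMatrix:
    """Method-of-moments PI-HAT for all accession pairs.

    ``allele_freqs`` defaults to frequencies estimated from the full
    panel; loci that are monomorphic (or missing a frequency) are
    excluded since they carry no IBD information.
    """
    from .diversity import allele_freq

    if allele_freqs is None:
        allele_freqs, _ = allele_freq(gm)
    p = np.asarray(allele_freqs, dtype=float)
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    calls = gm.calls[:, usable]
    p = p[usable]
    q = 1.0 - p

    valid = (calls != MISSING).astype(np.float64)
    g0 = ((calls == 0) * valid).astype(np.float64)
    g1 = ((calls == 1) * valid).astype(np.float64)
    g2 = ((calls == 2) * valid).astype(np.float64)

    # observed IBS class counts per pair
    n_joint = valid @ valid.T
    n_ibs0 = g0 @ g2.T + g2 @ g0.T
    n_ibs2 = g0 @ g0.T + g1 @ g1.T + g2 @ g2.T
    n_ibs1 = n_joint - n_ibs0 - n_ibs2

    # per-locus IBS-class expectations given IBD state (HWE moments)
    e0_z0 = 2.0 * p**2 * q**2
    e1_z0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_z0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e1_z1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e2_z1 = p**3 + q**3 + p * q

    # pair-specific expectation sums over jointly non-missing loci
    E0_z0 = (valid * e0_z0) @ valid.T
    E1_z0 = (valid * e1_z0) @ valid.T
    E2_z0 = (valid * e2_z0) @ valid.T
    E1_z1 = (valid * e1_z1) @ valid.T
    E2_z1 = (valid * e2_z1) @ valid.T

    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = np.where(E0_z0 > 0, n_ibs0 / np.maximum(E0_z0, 1e-300), 0.0)
        z1 = np.where(E1_z1 > 0,
                      (n_ibs1 - z0 * E1_z0) / np.maximum(E1_z1, 1e-300), 0.0)
        z2 = np.where(n_joint > 0,
                      (n_ibs2 - z0 * E2_z0 - z1 * E2_z1)
                      / np.maximum(n_joint, 1.0), np.nan)
    z = np.stack([z0, z1, z2])
    z = np.clip(z, 0.0, None)
    total = z.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(total > 0, z / np.maximum(total, 1e-300), np.nan)
    pihat = z[2] + 0.5 * z[1]
    pihat = np.clip(pihat, 0.0, 1.0)
    pihat = (pihat + pihat.T) / 2.0
    np.fill_diagonal(pihat, 1.0)
    low = n_joint < MIN_JOINT_LOCI
    np.fill_diagonal(low, False)
    return IbdMatrix(pihat, list(gm.accession_ids), low)


def duplicate_clusters(ibd: IbdMatrix, cutoff: float = 0.95) -> list[list[str]]:
    """Connected components of the PI-HAT > cutoff graph, size >= 2 only."""
    adj = (ibd.pihat > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        members = [ibd.accession_ids[i] for i in np.flatnonzero(labels == c)]
        if len(members) >= 2:
            out.append(sorted(members))
    return sorted(out)


def duplicate_verdict(
    meta: pd.DataFrame,
    D: DistanceMatrix,
    Q: pd.DataFrame,
    clusters: list[list[str]],
    d_low: float = 0.05,
) -> pd.DataFrame:
    """Multi-evidence verdict table for duplicate candidate groups.

    Candidates are the passport-flagged duplicate groups plus every IBD
    cluster.  For each: ``passport`` (all members share a passport
    duplicate flag), ``distance_low`` (all pairwise distances below
    ``d_low``), ``structure_same`` (identical dominant gene pool) and
    ``ibd_high`` (all members inside one IBD cluster).  The final
    verdict requires the three genetic columns; passport data are
    informative only.
    """
    ids = set(D.accession_ids)
    if not set(meta["accession_id"]).issubset(ids) or not set(Q.index).issuperset(ids):
        raise ValueError("inputs cover different accession sets")
    order = {a: i for i, a in enumerate(D.accession_ids)}
    passport_groups = {
        str(g): sorted(sub["accession_id"])
        for g, sub in meta.dropna(subset=["duplicate_group"])
        .groupby("duplicate_group")
    }
    candidates: dict[frozenset, str] = {}
    for name, members in passport_groups.items():
        candidates[frozenset(members)] = f"passport:{name}"
    for i, members in enumerate(clusters):
        candidates.setdefault(frozenset(members), f"ibd:{i + 1}")

    cluster_sets = [frozenset(c) for c in clusters]
    passport_sets = [frozenset(m) for m in passport_groups.values()]
    rows = []
    for members_set, label in sorted(candidates.items(),
                                     key=lambda kv: sorted(kv[0])):
        members = sorted(members_set)
        idx = [order[a] for a in members]
        pair_d = [D.values[i, j] for k, i in enumerate(idx)
                  for j in idx[k + 1:]]
        distance_low = bool(pair_d) and all(d < d_low for d in pair_d)
        dominant = Q.loc[members].to_numpy().argmax(axis=1)
        structure_same = len(set(dominant.tolist())) == 1
        ibd_high = any(members_set <= c for c in cluster_sets)
        passport = any(members_set <= pset for pset in passport_sets)
        rows.append({
            "candidate": label,
            "accessions": ";".join(members),
            "passport": passport,
            "distance_low": distance_low,
            "structure_same": structure_same,
            "ibd_high": ibd_high,
            "verdict": distance_low and structure_same and ibd_high,
        })
    return pd.DataFrame(rows)
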