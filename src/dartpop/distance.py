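"""Jaccard genetic distances, group summaries and principal coordinates.

Each biallelic locus expands to two presence bits — reference allele
present (call 0 or 1) and alternative allele present (call 1 or 2) —
mirroring the two-row 0/1 report the genotypes arrive in.  A
heterozygote therefore shares one bit with either homozygote, so a
0-vs-1 pair contributes distance 0.5 at that locus, not 1.  Pairwise
distances are computed over loci non-missing in both accessions.

PCoA is classical metric scaling: double-center ``-D^2/2``,
eigendecompose, keep the positive eigenvalues and scale eigenvectors
by the square root of their eigenvalue.  Negative eigenvalues
(non-Euclidean residue) are dropped without correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .types import MISSING, GenotypeMatrix, group_indices


@dataclass
class DistanceMatrix:
    """Symmetric accession-by-accession distance matrix in [0, 1]."""

    values: np.ndarray
    accession_ids: list[str]
    metric: str = "jaccard"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.accession_ids) != n:
            raise ValueError("distance matrix shape/id mismatch")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix not symmetric")
        if np.nanmax(np.abs(np.diag(self.values))) > 1e-12:
            raise ValueError("distance matrix diagonal not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)


def jaccard_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distance on the two-bit-per-locus expansion.

    ``d = 1 - |both present| / |either present|`` over loci
    non-missing in both accessions; 0 when no informative bits.  Pairs
    with zero jointly non-missing loci get nan with a warning.
    """
    if gm.n_accessions < 2:
        raise ValueError("need at least two accessions")
    calls = gm.calls
    valid = (calls != MISSING).astype(np.float64)
    ref = np.isin(calls, (0, 1)).astype(np.float64)
    alt = np.isin(calls, (1, 2)).astype(np.float64)
    # masked bits already carry the validity of their own accession;
    # products then carry joint validity
    both = ref @ ref.T + alt @ alt.T
    either = (ref @ valid.T + valid @ ref.T - ref @ ref.T
              + alt @ valid.T + valid @ alt.T - alt @ alt.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(either > 0, both / np.maximum(either, 1.0), 1.0)
    joint = valid @ valid.T
    if (joint == 0).any():
        warnings.warn("accession pair(s) share no non-missing loci; "
                      "distance reported as nan", stacklevel=2)
        d[joint == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0, out=d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, list(gm.accession_ids))


def group_distance_summary(D: DistanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Min/max pairwise distance per breeding-period group and overall.

    Ties are broken by lexicographic accession-id pair.  Singleton
    groups are flagged with nan extremes.
    """
    ids = D.accession_ids
    order = {a: i for i, a in enumerate(ids)}
    rows = []

    def extremes(index: list[int]) -> dict:
        if len(index) < 2:
            return {"min": np.nan, "min_pair": "", "max": np.nan, "max_pair": ""}
        best_min = best_max = None
        for ai in range(len(index)):
            for bi in range(ai + 1, len(index)):
                i, j = index[ai], index[bi]
                pair = tuple(sorted((ids[i], ids[j])))
                d = D.values[i, j]
                if np.isnan(d):
                    continue
                if best_min is None or (d, pair) < best_min:
                    best_min = (d, pair)
                if best_max is None or (-d, pair) < best_max:
                    best_max = (-d, pair)
        return {"min": best_min[0], "min_pair": "-".join(best_min[1]),
                "max": -best_max[0], "max_pair": "-".join(best_max[1])}

    for grp, sub in meta.groupby("group", sort=False):
        index = [order[a] for a in sub["accession_id"] if a in order]
        rows.append({"group": str(grp), **extremes(index)})
    rows.append({"group": "total", **extremes(list(range(len(ids))))})
    return pd.DataFrame(rows)


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame      # accessions x kept axes
    eigenvalues: np.ndarray        # all positive eigenvalues, descending
    percent_variance: np.ndarray   # per positive axis, sums to 100

    @property
    def full_coordinates(self) -> np.ndarray:
        """Coordinates on every positive axis (for reconstruction checks)."""
        return self._full

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for ax in range(self.coordinates.shape[1]):
            for acc, val in self.coordinates.iloc[:, ax].items():
                recs.append({"accession_id": acc, "axis": ax + 1,
                             "coordinate": val,
                             "pct_variance": self.percent_variance[ax]})
        return pd.DataFrame(recs)


def pcoa(D: DistanceMatrix, n_axes: int = 3) -> PcoaResult:
    """Classical scaling of a distance matrix.

    Raises on missing distances (impute or subset first).  Percent
    variance is relative to the sum of positive eigenvalues only.
    """
    dv = D.values
    if np.isnan(dv).any():
        raise ValueError("distance matrix has missing entries; "
                         "impute or subset accessions first")
    n = dv.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dv**2) @ J
    B = (B + B.T) / 2.0
    w, v = eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10 * max(abs(w[0]), 1.0)
    w_pos, v_pos = w[pos], v[:, pos]
    coords = v_pos * np.sqrt(w_pos)
    pct = 100.0 * w_pos / w_pos.sum() if w_pos.size else np.array([])
    k = min(n_axes, coords.shape[1])
    res = PcoaResult(
        pd.DataFrame(coords[:, :k], index=D.accession_ids,
                     columns=[f"PCo{i + 1}" for i in range(k)]),
        w_pos, pct,
    )
    res._full = coords
    return res
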