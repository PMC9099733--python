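"""Per-locus and aggregated diversity statistics.

Implements the marker-diversity toolkit for pooled-sample biallelic
SNP panels: the diversity form of the polymorphism information
content, observed heterozygosity, Nei's unbiased expected
heterozygosity, the fixation index, Hurlbert rarefaction allelic
richness, per-cultivar heterogeneity and transition/transversion
accounting.

Conventions
-----------
* PIC is the diversity index ``1 - p^2 - q^2`` (biallelic maximum 0.5),
  not Botstein's index (maximum 0.375) — the former matches the range
  this panel type reports.
* The fixation index divides by unbiased He: ``F = (uHe - Ho) / uHe``
  with the convention ``F = 0`` at monomorphic loci.
* ``n`` in the unbiased correction counts accessions with a
  non-missing call, the pooled samples being treated as diploid
  individuals (that is how the genotype table is coded).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .reference import SNP_CHANGES, TRANSITIONS
from .types import CHROMOSOMES, MISSING, GenotypeMatrix, group_indices

_CHANGE_RE = re.compile(r"^([ACGT])>([ACGT])$")


# ---------------------------------------------------------------------------
# per-locus primitives

def allele_freq(
    gm: GenotypeMatrix, accession_subset: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Alternative-allele frequency and diploid sample size per locus.

    ``p = (2 * n_hom_alt + n_het) / (2 * n_non_missing)``; loci with no
    non-missing call in the subset get ``p = nan`` and ``n = 0``.

    Returns
    -------
    (p, n) : per-locus frequency and count of non-missing accessions.
    """
    calls = gm.calls if accession_subset is None else gm.calls[accession_subset]
    if calls.shape[0] == 0:
        raise ValueError("accession subset is empty")
    valid = calls != MISSING
    n = valid.sum(axis=0)
    alt = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
    return p, n


def pic(p: np.ndarray) -> np.ndarray:
    """Polymorphism information content, diversity form ``1 - p^2 - q^2``."""
    p = np.asarray(p, dtype=float)
    return 1.0 - p**2 - (1.0 - p) ** 2


def observed_het(
    gm: GenotypeMatrix, accession_subset: np.ndarray | None = None
) -> np.ndarray:
    """Per-locus observed heterozygosity: share of non-missing calls that are het."""
    calls = gm.calls if accession_subset is None else gm.calls[accession_subset]
    if calls.shape[0] == 0:
        raise ValueError("accession subset is empty")
    valid = calls != MISSING
    n = valid.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / np.maximum(n, 1), np.nan)


def unbiased_he(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Nei's unbiased expected heterozygosity ``(2n/(2n-1)) (1 - p^2 - q^2)``.

    Undefined (nan) where ``n < 1``.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 1.0 - p**2 - (1.0 - p) ** 2
        out = np.where(n >= 1, 2.0 * n / np.maximum(2.0 * n - 1.0, 1e-300) * he,
                       np.nan)
    return out


def fixation_index(ho, uhe):
    """Fixation index ``F = (uHe - Ho)/uHe``; 0 where uHe = 0 (monomorphic)."""
    ho = np.asarray(ho, dtype=float)
    uhe = np.asarray(uhe, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(uhe > 0, (uhe - ho) / np.where(uhe > 0, uhe, 1.0), 0.0)
        f = np.where(np.isnan(uhe) | np.isnan(ho), np.nan, f)
    if f.ndim == 0:
        return float(f)
    return f


# ---------------------------------------------------------------------------
# rarefaction allelic richness

def rarefied_allele_count(copy_counts: np.ndarray, g: int) -> float:
    """Hurlbert rarefaction: expected allele count in a subsample of g copies.

    ``AR = sum_a [1 - C(N - N_a, g) / C(N, g)]`` with ``N`` total copies
    and ``N_a`` copies of allele ``a``.
    """
    counts = np.asarray(copy_counts, dtype=float)
    counts = counts[counts > 0]
    N = counts.sum()
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    if N < g:
        raise ValueError(f"sample of {int(N)} copies cannot be rarefied to {g}")
    return float(np.sum(1.0 - _comb_ratio(N - counts, N, g)))


def _comb_ratio(m: np.ndarray, N: float, g: int) -> np.ndarray:
    """C(m, g) / C(N, g), elementwise, 0 where m < g."""
    m = np.asarray(m, dtype=float)
    out = np.zeros_like(m)
    ok = m >= g
    if np.any(ok):
        num = gammaln(m[ok] + 1) - gammaln(g + 1) - gammaln(m[ok] - g + 1)
        den = gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
        out[ok] = np.exp(num - den)
    return out


def allelic_richness(
    gm: GenotypeMatrix,
    groups: dict[str, np.ndarray],
    g: int | None = None,
) -> pd.Series:
    """Mean rarefied allele count per breeding-period group.

    ``g`` defaults to twice the smallest group's accession count (the
    standard convention: rarefy to the smallest sample's allele-copy
    number).  Loci with fewer than ``g`` non-missing copies in a group
    are skipped for that group.
    """
    if g is None:
        g = 2 * min(len(ix) for ix in groups.values())
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    out = {}
    for name, ix in groups.items():
        p, n = allele_freq(gm, ix)
        copies = 2.0 * n
        alt = p * copies
        ref = copies - alt
        usable = copies >= g
        ar = np.full(gm.n_loci, np.nan)
        ratio_ref = _comb_ratio_vec(copies - ref, copies, g)
        ratio_alt = _comb_ratio_vec(copies - alt, copies, g)
        ar[usable] = ((1.0 - ratio_ref) + (1.0 - ratio_alt))[usable]
        out[name] = float(np.nanmean(ar))
    return pd.Series(out, name="allelic_richness")


def _comb_ratio_vec(m: np.ndarray, N: np.ndarray, g: int) -> np.ndarray:
    """Vectorised C(m, g)/C(N, g) with per-element N; 0 where m < g."""
    m = np.asarray(m, dtype=float)
    N = np.asarray(N, dtype=float)
    out = np.zeros_like(m)
    ok = (m >= g) & (N >= g)
    num = gammaln(m[ok] + 1) - gammaln(m[ok] - g + 1)
    den = gammaln(N[ok] + 1) - gammaln(N[ok] - g + 1)
    out[ok] = np.exp(num - den)
    return out


# ---------------------------------------------------------------------------
# cultivar heterogeneity and locus accounting

def cultivar_heterogeneity(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-accession observed heterozygosity across loci.

    For pooled samples of a selfing crop this measures intra-cultivar
    heterogeneity: the share of loci at which the pooled seedlings
    carry both alleles.  Accessions with no non-missing calls are
    flagged with ``ho = nan``.
    """
    valid = gm.calls != MISSING
    n = valid.sum(axis=1)
    het = (gm.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return (pd.DataFrame({"accession_id": gm.accession_ids, "ho": ho,
                          "n_loci": n})
            .sort_values("ho", ascending=False, kind="mergesort")
            .reset_index(drop=True))


def homozygous_locus_fraction(
    gm: GenotypeMatrix,
    info: pd.DataFrame | None = None,
    by_chromosome: bool = False,
) -> float | pd.Series:
    """Share of loci with no heterozygous call among their non-missing calls."""
    het_free = (gm.calls != 1).all(axis=0)
    if not by_chromosome:
        return float(het_free.mean())
    if info is None:
        raise ValueError("per-chromosome fractions require locus info")
    chrom = info["chromosome"].to_numpy()
    out = {c: float(het_free[chrom == c].mean())
           for c in CHROMOSOMES if (chrom == c).any()}
    out["all"] = float(het_free.mean())
    return pd.Series(out, name="homozygous_locus_fraction")


# ---------------------------------------------------------------------------
# SNP substitution-type accounting

@dataclass
class SnpTypeTable:
    """Counts of the 12 ordered substitution classes, per chromosome and total.

    The first four classes (A>G, G>A, C>T, T>C) are transitions; the
    rest are transversions.
    """

    counts: pd.DataFrame  # rows = SNP_CHANGES, columns = chromosomes present

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "SnpTypeTable":
        counts = counts.reindex(index=list(SNP_CHANGES)).fillna(0).astype(int)
        return cls(counts)

    @property
    def totals(self) -> pd.Series:
        """Total loci per chromosome column plus an 'Total' entry."""
        per_chrom = self.counts.sum(axis=0)
        per_chrom.loc["Total"] = per_chrom.sum()
        return per_chrom

    def _with_total(self) -> pd.DataFrame:
        tab = self.counts.copy()
        tab.insert(0, "Total", tab.sum(axis=1))
        return tab

    @property
    def ts_count(self) -> pd.Series:
        return self._with_total().iloc[:4].sum(axis=0)

    @property
    def tv_count(self) -> pd.Series:
        return self._with_total().iloc[4:].sum(axis=0)

    @property
    def pct_ts(self) -> pd.Series:
        tot = self.ts_count + self.tv_count
        return 100.0 * self.ts_count / tot

    @property
    def pct_tv(self) -> pd.Series:
        return 100.0 - self.pct_ts

    @property
    def ts_tv_ratio(self) -> pd.Series:
        return self.ts_count / self.tv_count

    def to_frame(self) -> pd.DataFrame:
        """Full display table: counts plus %Ts / %Tv / Ts/Tv summary rows."""
        tab = self._with_total().astype(float)
        tab.loc["%Ts"] = self.pct_ts
        tab.loc["%Tv"] = self.pct_tv
        tab.loc["Ts/Tv"] = self.ts_tv_ratio
        return tab.reset_index(names="change")


def snp_type_table(info: pd.DataFrame) -> SnpTypeTable:
    """Tabulate substitution classes from locus metadata.

    Raises ``ValueError`` naming the first locus whose ``change``
    string is not of the form ``X>Y`` with distinct bases.
    """
    changes = info["change"].astype(str)
    for lid, ch in zip(info["locus_id"], changes):
        m = _CHANGE_RE.match(ch)
        if not m or m.group(1) == m.group(2):
            raise ValueError(f"locus {lid!r} has malformed change {ch!r}")
    tab = (pd.crosstab(changes, info["chromosome"])
           .reindex(index=list(SNP_CHANGES), fill_value=0))
    cols = [c for c in CHROMOSOMES if c in tab.columns]
    return SnpTypeTable.from_counts(tab[cols])


# ---------------------------------------------------------------------------
# grouped summaries

def summarise(gm: GenotypeMatrix,
              accession_subset: np.ndarray | None = None) -> dict[str, float]:
    """Mean PIC, Ho, uHe and F (from means) over loci for one accession set."""
    p, n = allele_freq(gm, accession_subset)
    ho = observed_het(gm, accession_subset)
    uhe = unbiased_he(p, n)
    defined = n > 0
    mean_ho = float(np.nanmean(ho[defined])) if defined.any() else np.nan
    mean_uhe = float(np.nanmean(uhe[defined])) if defined.any() else np.nan
    mean_pic = float(np.nanmean(pic(p)[defined])) if defined.any() else np.nan
    f = fixation_index(mean_ho, mean_uhe)
    n_acc = gm.n_accessions if accession_subset is None else len(accession_subset)
    return {
        "pic": mean_pic, "ho": mean_ho, "uhe": mean_uhe, "f": float(f),
        "n_loci": int(defined.sum()), "n_accessions": int(n_acc),
    }


def group_summaries(gm: GenotypeMatrix, info: pd.DataFrame,
                    meta: pd.DataFrame) -> pd.DataFrame:
    """Diversity summaries per chromosome, per period group and per cell.

    Returns a tidy table with one row per scope: ``panel``,
    ``chromosome:<c>``, ``group:<g>`` and ``group:<g>|chromosome:<c>``.
    Cells with no loci are reported with ``n_loci = 0`` and nan values.
    """
    missing = set(meta["accession_id"]) - set(gm.accession_ids)
    if missing:
        raise ValueError(f"metadata names unknown accessions: {sorted(missing)}")
    groups = group_indices(meta, gm)
    if any(len(ix) == 0 for ix in groups.values()):
        raise ValueError("every group must be non-empty")
    chrom = info["chromosome"].to_numpy()
    rows = []

    def add(scope: str, sub_gm: GenotypeMatrix, acc_ix=None):
        if sub_gm.n_loci == 0:
            rows.append({"scope": scope, "pic": np.nan, "ho": np.nan,
                         "uhe": np.nan, "f": np.nan, "n_loci": 0,
                         "n_accessions": 0})
            return
        rows.append({"scope": scope, **summarise(sub_gm, acc_ix)})

    add("panel", gm)
    for c in CHROMOSOMES:
        ix = np.flatnonzero(chrom == c)
        if ix.size:
            add(f"chromosome:{c}", gm.take_loci(ix))
    for gname, acc_ix in groups.items():
        add(f"group:{gname}", gm, acc_ix)
        for c in CHROMOSOMES:
            ix = np.flatnonzero(chrom == c)
            if ix.size:
                add(f"group:{gname}|chromosome:{c}", gm.take_loci(ix), acc_ix)
    return pd.DataFrame(rows)
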