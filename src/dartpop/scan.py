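"""Genome scans: sliding-window tracks, FST, unique-allele turnover.

Windows sample the chromosome rather than tile it: centers are evenly
spread over the full assembled length and each window spans a fixed
width around its center (half-open on the right), so neighbouring
windows may overlap or leave gaps depending on chromosome length.
The between-group FST is the two-population Wright/Nei form
``(HT - mean(HS)) / HT`` computed from group allele frequencies; the
10th-power transform sharpens genome-scan plots by suppressing the
low-FST background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import allele_freq, pic
from .types import CHROMOSOMES, GenotypeMatrix, group_indices


@dataclass
class WindowTrack:
    """Per-chromosome sliding-window statistic values."""

    chromosome: str
    centers_bp: np.ndarray
    half_width_bp: float
    values: np.ndarray = field(default=None)
    counts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.centers_bp = np.asarray(self.centers_bp, dtype=float)
        if np.any(np.diff(self.centers_bp) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if self.values is None:
            self.values = np.full(self.centers_bp.size, np.nan)
        if self.counts is None:
            self.counts = np.zeros(self.centers_bp.size, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chromosome": self.chromosome,
            "center_bp": self.centers_bp,
            "value": self.values,
            "n_loci": self.counts,
        })

    def to_bedgraph(self) -> pd.DataFrame:
        """BedGraph rows (0-based half-open) for genome-browser export."""
        start = np.maximum(self.centers_bp - self.half_width_bp, 0).astype(int)
        end = (self.centers_bp + self.half_width_bp).astype(int)
        keep = ~np.isnan(self.values)
        return pd.DataFrame({
            "chromosome": self.chromosome,
            "start": start[keep], "end": end[keep],
            "value": self.values[keep],
        })


def make_windows(chromosome_length_bp: float, chromosome: str = "",
                 n_positions: int = 250,
                 width_bp: float = 500_000) -> WindowTrack:
    """Window skeleton: ``n_positions`` centers evenly spread along the chromosome.

    Centers run from ``width/2`` to ``length - width/2`` inclusive;
    each window is ``[center - width/2, center + width/2)``.
    """
    if chromosome_length_bp <= width_bp:
        raise ValueError("chromosome shorter than one window")
    centers = np.linspace(width_bp / 2.0,
                          chromosome_length_bp - width_bp / 2.0,
                          int(n_positions))
    return WindowTrack(chromosome, centers, width_bp / 2.0)


def window_reduce(skeleton: WindowTrack, positions_bp: np.ndarray,
                  values: np.ndarray | None = None,
                  reducer: str = "mean") -> WindowTrack:
    """Fill a window skeleton by reducing per-locus values inside each window.

    ``reducer`` is ``"mean"`` (ignores nan values) or ``"count"``
    (ignores ``values``).  Empty windows get a nan value and count 0.
    """
    positions = np.asarray(positions_bp, dtype=float)
    if reducer not in ("mean", "count"):
        raise ValueError(f"unknown reducer {reducer!r}")
    if reducer == "mean":
        if values is None or len(values) != len(positions):
            raise ValueError("values must align with positions for mean reduce")
        values = np.asarray(values, dtype=float)
    order = np.argsort(positions, kind="mergesort")
    pos_sorted = positions[order]
    lo = skeleton.centers_bp - skeleton.half_width_bp
    hi = skeleton.centers_bp + skeleton.half_width_bp
    left = np.searchsorted(pos_sorted, lo, side="left")
    right = np.searchsorted(pos_sorted, hi, side="left")  # right edge excluded
    out_vals = np.full(skeleton.centers_bp.size, np.nan)
    out_counts = right - left
    if reducer == "count":
        out_vals = out_counts.astype(float)
        out_vals[out_counts == 0] = np.nan
    else:
        vals_sorted = values[order]
        for i, (a, b) in enumerate(zip(left, right)):
            if b > a:
                out_vals[i] = np.nanmean(vals_sorted[a:b])
    return WindowTrack(skeleton.chromosome, skeleton.centers_bp,
                       skeleton.half_width_bp, out_vals,
                       out_counts.astype(int))


def fst_per_locus(gm: GenotypeMatrix, group_a: np.ndarray,
                  group_b: np.ndarray) -> np.ndarray:
    """Two-group Wright FST per locus, ``(HT - HS̄)/HT``, clipped to [0, 1].

    ``HT = 2 p̄ (1 - p̄)`` with ``p̄`` the unweighted mean of the two
    group frequencies and ``HS̄`` the mean of the groups'
    ``2 p (1 - p)``.  Loci entirely missing in one group get nan.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    pa, na = allele_freq(gm, np.asarray(group_a))
    pb, nb = allele_freq(gm, np.asarray(group_b))
    pbar = (pa + pb) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * pa * (1.0 - pa) + 2.0 * pb * (1.0 - pb)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    fst[(na == 0) | (nb == 0)] = np.nan
    return fst


def fst_transform(fst_values: np.ndarray, power: int = 10) -> np.ndarray:
    """Elementwise power transform (default 10th) of FST values in [0, 1]."""
    vals = np.asarray(fst_values, dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("FST values must lie in [0, 1]")
    return vals**power


def unique_alleles(gm: GenotypeMatrix, info: pd.DataFrame,
                   group_earlier: np.ndarray, group_later: np.ndarray,
                   threshold: float = 0.25) -> pd.DataFrame:
    """Count alleles lost/gained between two breeding-period groups.

    An allele (ref or alt, per locus) is LOST when its frequency is
    ``>= threshold`` in the earlier group and exactly 0 among the later
    group's non-missing calls; GAINED is symmetric.  Counts are
    aggregated by chromosome (unassigned loci included as their own
    row) plus a ``total`` row.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ge = np.asarray(group_earlier)
    gl = np.asarray(group_later)
    if ge.size == 0 or gl.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(ge, gl).size:
        raise ValueError("groups must be disjoint")
    pe, ne = allele_freq(gm, ge)
    pl, nl = allele_freq(gm, gl)
    defined = (ne > 0) & (nl > 0)
    lost = np.zeros(gm.n_loci, dtype=int)
    gained = np.zeros(gm.n_loci, dtype=int)
    for freq_e, freq_l in ((pe, pl), (1.0 - pe, 1.0 - pl)):  # alt then ref allele
        lost += (defined & (freq_e >= threshold) & (freq_l == 0)).astype(int)
        gained += (defined & (freq_l >= threshold) & (freq_e == 0)).astype(int)
    chrom = info["chromosome"].to_numpy()
    rows = []
    for c in CHROMOSOMES:
        m = chrom == c
        if m.any():
            rows.append({"chromosome": c, "n_lost": int(lost[m].sum()),
                         "n_gained": int(gained[m].sum())})
    rows.append({"chromosome": "total", "n_lost": int(lost.sum()),
                 "n_gained": int(gained.sum())})
    out = pd.DataFrame(rows)
    out["threshold"] = threshold
    return out


def unique_allele_mask(gm: GenotypeMatrix, group: np.ndarray,
                       others: np.ndarray,
                       threshold: float = 0.25) -> np.ndarray:
    """Per-locus flag: locus carries an allele unique to ``group``.

    Unique means frequency >= threshold in ``group`` and exactly 0 in
    ``others``; used for the per-group unique-SNP window tracks.
    """
    pg, ng = allele_freq(gm, np.asarray(group))
    po, no = allele_freq(gm, np.asarray(others))
    defined = (ng > 0) & (no > 0)
    mask = np.zeros(gm.n_loci, dtype=bool)
    for fg, fo in ((pg, po), (1.0 - pg, 1.0 - po)):
        mask |= defined & (fg >= threshold) & (fo == 0)
    return mask


def selection_scan_report(
    gm: GenotypeMatrix, info: pd.DataFrame, meta: pd.DataFrame,
    earliest_group: str, latest_group: str,
    chromosome_lengths_bp: dict[str, float],
    n_positions: int = 250, width_bp: float = 500_000,
    power: int = 10, unique_threshold: float = 0.25,
) -> dict[str, list[WindowTrack]]:
    """Window tracks contrasting the earliest and latest breeding periods.

    Returns five track sets over the assigned chromosomes: transformed
    ``fst^power`` between the two groups, mean PIC within each group,
    and counts of loci carrying group-unique alleles for each group.
    """
    groups = group_indices(meta, gm)
    for g in (earliest_group, latest_group):
        if g not in groups or len(groups[g]) == 0:
            raise ValueError(f"group {g!r} is missing or empty")
    ga, gb = groups[earliest_group], groups[latest_group]
    fst10 = fst_transform(np.nan_to_num(fst_per_locus(gm, ga, gb), nan=0.0),
                          power)
    pa, _ = allele_freq(gm, ga)
    pb, _ = allele_freq(gm, gb)
    uniq_a = unique_allele_mask(gm, ga, gb, unique_threshold)
    uniq_b = unique_allele_mask(gm, gb, ga, unique_threshold)
    chrom = info["chromosome"].to_numpy()
    pos = info["position_bp"].to_numpy(dtype=float)
    out: dict[str, list[WindowTrack]] = {
        "fst_transformed": [], "pic_earliest": [], "pic_latest": [],
        "unique_earliest": [], "unique_latest": [],
    }
    for c, length in chromosome_lengths_bp.items():
        m = (chrom == c) & ~np.isnan(pos)
        if not m.any():
            continue
        skel = make_windows(length, c, n_positions, width_bp)
        cpos = pos[m]
        out["fst_transformed"].append(
            window_reduce(skel, cpos, fst10[m], "mean"))
        out["pic_earliest"].append(window_reduce(skel, cpos, pic(pa)[m], "mean"))
        out["pic_latest"].append(window_reduce(skel, cpos, pic(pb)[m], "mean"))
        out["unique_earliest"].append(
            window_reduce(skel, cpos[uniq_a[m]], None, "count"))
        out["unique_latest"].append(
            window_reduce(skel, cpos[uniq_b[m]], None, "count"))
    return out


def tracks_to_frame(tracks: list[WindowTrack]) -> pd.DataFrame:
    """Concatenate window tracks into one tidy DataFrame."""
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)
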