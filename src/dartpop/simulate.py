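"""Synthetic pooled-sample SNP panels with a recorded ground truth.

The generator emulates the study design of a gene-bank cultivar
survey: a fixed number of ancestral gene pools, accessions assigned to
breeding-period groups whose genetic makeup is biased toward
period-specific pools, each accession genotyped as a DNA pool of a few
(default eight) inbred seedlings, near-identical duplicate accessions,
and localized allele-frequency sweeps on designated chromosomes.

Model
-----
* Ancestral allele frequency ``p0`` per locus ~ Uniform(0.05, 0.95).
* Pool frequencies follow a Balding–Nichols beta around ``p0`` with
  drift parameter ``pool_divergence`` (the F of the beta).
* Each accession draws a Dirichlet pool-membership vector ``Q*``,
  concentrated on its period group's focal pools.
* Seedlings are fully inbred homozygotes.  At a fraction
  ``heterogeneity_by_group[g]`` of loci the accession's pool of
  seedlings is drawn independently from its mixture frequency (so the
  pooled call is heterozygous whenever the seedlings disagree);
  elsewhere the pool is clonal and the call is the shared homozygote.
* Duplicates are copies of an existing accession with at most 0.5% of
  calls re-drawn; sweeps fix the alternative allele in the affected
  groups over a positional window.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import SNP_CHANGES, chromosome_lengths_bp, snp_change_probabilities
from .types import MISSING, PERIOD_GROUPS, GenotypeMatrix


def _default_loci() -> dict[str, int]:
    return {c: 200 for c in ("1H", "2H", "3H", "4H", "5H", "6H", "7H")} | {"Un": 50}


def _default_sweeps() -> list[tuple]:
    return [
        ("5H", 120e6, 40e6, ("1990-1999", "post-2000")),
        ("3H", 200e6, 30e6, ("post-2000",)),
    ]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic panel.

    Defaults mirror the emulated survey: 11 gene pools, five breeding
    period groups of 13/14/18/26/12 accessions (83 in total), ~1,450
    loci over chromosomes 1H–7H plus unassigned, 8-seedling pools, and
    sweeps on 5H and 3H affecting the most recent periods.  Group
    heterogeneity declines with breeding period, reproducing the drop
    in intra-cultivar variability of modern cultivars.
    """

    n_pools: int = 11
    group_sizes: tuple[int, ...] = (13, 14, 18, 26, 12)
    group_labels: tuple[str, ...] = PERIOD_GROUPS
    loci_per_chromosome: dict[str, int] = field(default_factory=_default_loci)
    pool_divergence: float = 0.15
    heterogeneity_by_group: tuple[float, ...] = (0.16, 0.12, 0.09, 0.06, 0.03)
    n_duplicate_pairs: int = 3
    sweep_spec: list[tuple] = field(default_factory=_default_sweeps)
    seedlings_per_pool: int = 8
    missing_rate: float = 0.005
    frac_low_rep_avg: float = 0.02
    frac_low_call_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pool_divergence < 1.0:
            raise ValueError("pool_divergence must lie in (0, 1)")
        if any(s <= 0 for s in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if self.seedlings_per_pool < 1:
            raise ValueError("seedlings_per_pool must be >= 1")
        if len(self.group_sizes) != len(self.group_labels):
            raise ValueError("group_sizes and group_labels length mismatch")
        if len(self.heterogeneity_by_group) != len(self.group_sizes):
            raise ValueError("one heterogeneity value per group required")
        for chrom, *_ in self.sweep_spec:
            if chrom not in self.loci_per_chromosome or chrom == "Un":
                raise ValueError(f"sweep chromosome {chrom!r} not simulated")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a generated panel."""

    ancestral_freq: np.ndarray          # loci
    pool_freq: np.ndarray               # pools x loci
    q_star: np.ndarray                  # accessions x pools
    duplicate_pairs: list[tuple[str, str]]
    sweep_locus_ids: list[str]


def _edge_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Positions denser toward chromosome ends (mixture of two edge betas)."""
    u = rng.beta(0.6, 2.2, size=n)
    flip = rng.random(n) < 0.5
    u = np.where(flip, 1.0 - u, u)
    pos = np.sort(np.unique((1 + u * (length - 1)).astype(np.int64)))
    while pos.size < n:  # top up after unique() collisions
        extra = (1 + rng.random(n - pos.size) * (length - 1)).astype(np.int64)
        pos = np.sort(np.unique(np.concatenate([pos, extra])))
    return pos[:n]


def generate_panel(
    cfg: SimConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a panel: genotypes, locus info, accession metadata, truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    lengths = chromosome_lengths_bp()

    # --- loci -------------------------------------------------------------
    chroms, positions = [], []
    for chrom, n in cfg.loci_per_chromosome.items():
        chroms += [chrom] * n
        if chrom == "Un":
            positions += [np.nan] * n
        else:
            positions += list(_edge_positions(rng, n, lengths[chrom]))
    n_loci = len(chroms)
    locus_ids = [f"L{i + 1:05d}" for i in range(n_loci)]
    change_probs = snp_change_probabilities()
    changes = rng.choice(list(SNP_CHANGES), size=n_loci,
                         p=change_probs.to_numpy())

    # --- ancestral and pool frequencies -----------------------------------
    p0 = rng.uniform(0.05, 0.95, size=n_loci)
    F = cfg.pool_divergence
    a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
    pool_freq = np.clip(rng.beta(a, b, size=(cfg.n_pools, n_loci)),
                        1e-3, 1 - 1e-3)

    # --- accessions and their pool memberships ----------------------------
    n_acc = int(sum(cfg.group_sizes))
    acc_ids = [f"ACC{i + 1:03d}" for i in range(n_acc)]
    group_of = np.repeat(np.arange(len(cfg.group_sizes)), cfg.group_sizes)
    # round-robin focal pools per period group bias the Dirichlet
    alpha = np.full((len(cfg.group_sizes), cfg.n_pools), 0.2)
    for g in range(len(cfg.group_sizes)):
        focal = np.arange(cfg.n_pools) % len(cfg.group_sizes) == g
        alpha[g, focal] += 3.0
    q_star = np.vstack([rng.dirichlet(alpha[g]) for g in group_of])
    mix_freq = q_star @ pool_freq  # accession x locus alt frequency

    # --- pooled seedling calls --------------------------------------------
    s = cfg.seedlings_per_pool
    het_site = (rng.random((n_acc, n_loci))
                < np.asarray(cfg.heterogeneity_by_group)[group_of][:, None])
    x = rng.binomial(s, mix_freq)            # alt seedlings if independent
    clone_alt = rng.random((n_acc, n_loci)) < mix_freq
    calls = np.where(
        het_site,
        np.where(x == 0, 0, np.where(x == s, 2, 1)),
        np.where(clone_alt, 2, 0),
    ).astype(np.int8)

    # --- sweeps: fix the alt allele in the affected groups ----------------
    chrom_arr = np.asarray(chroms)
    pos_arr = np.asarray(positions, dtype=float)
    label_to_g = {lab: g for g, lab in enumerate(cfg.group_labels)}
    sweep_loci: set[int] = set()
    for chrom, center, width, groups in cfg.sweep_spec:
        lmask = (chrom_arr == chrom) & (np.abs(pos_arr - center) <= width / 2)
        gset = [label_to_g[g] for g in groups]
        amask = np.isin(group_of, gset)
        calls[np.ix_(amask, np.flatnonzero(lmask))] = 2
        sweep_loci.update(np.flatnonzero(lmask).tolist())

    # --- duplicates: copies with <= 0.5% of calls re-drawn ----------------
    dup_pairs: list[tuple[str, str]] = []
    dup_group = np.array([""] * n_acc, dtype=object)
    used: set[int] = set()
    for d in range(cfg.n_duplicate_pairs):
        candidates = [i for i in range(n_acc) if i not in used]
        src = int(rng.choice(candidates))
        same_grp = [i for i in candidates
                    if i != src and group_of[i] == group_of[src]]
        if not same_grp:
            continue
        dst = int(rng.choice(same_grp))
        used.update((src, dst))
        q_star[dst] = q_star[src]      # a duplicate is the same cultivar
        mix_freq[dst] = mix_freq[src]
        calls[dst] = calls[src]
        n_perturb = int(np.floor(0.005 * n_loci))
        if n_perturb:
            ix = rng.choice(n_loci, size=n_perturb, replace=False)
            calls[dst, ix] = np.where(rng.random(n_perturb) < mix_freq[src, ix],
                                      2, 0)
        dup_pairs.append((acc_ids[src], acc_ids[dst]))
        dup_group[[src, dst]] = f"dup{d + 1}"

    # --- missingness and quality metadata ---------------------------------
    miss = rng.random((n_acc, n_loci)) < cfg.missing_rate
    calls[miss] = MISSING
    rep_avg = rng.uniform(0.95, 1.0, size=n_loci)
    low_rep = rng.random(n_loci) < cfg.frac_low_rep_avg
    rep_avg[low_rep] = rng.uniform(0.80, 0.9499, size=low_rep.sum())
    call_rate = rng.uniform(0.95, 1.0, size=n_loci)
    low_cr = rng.random(n_loci) < cfg.frac_low_call_rate
    call_rate[low_cr] = rng.uniform(0.80, 0.9499, size=low_cr.sum())

    info = pd.DataFrame({
        "locus_id": locus_ids, "chromosome": chroms, "position_bp": pos_arr,
        "change": changes, "rep_avg": np.round(rep_avg, 4),
        "call_rate": np.round(call_rate, 4),
    })
    meta = pd.DataFrame({
        "accession_id": acc_ids,
        "cultivar": [f"CV{i + 1:03d}" for i in range(n_acc)],
        "group": [cfg.group_labels[g] for g in group_of],
        "duplicate_group": [d if d else None for d in dup_group],
    })
    gm = GenotypeMatrix(calls, acc_ids, locus_ids)
    truth = SimTruth(p0, pool_freq, q_star, dup_pairs,
                     [locus_ids[i] for i in sorted(sweep_loci)])
    return gm, info, meta, truth


# ---------------------------------------------------------------------------
# fixed toy panel for unit tests and examples

_TOY_CALLS = np.array([
    # L01 L02 L03 L04 L05 L06 L07 L08 L09 L10 L11 L12
    [0, 0, 1, 2, 0, 1, 0, 2, 1, 0, 2, 1],   # A1
    [0, 2, 0, 1, 1, 1, 0, 2, 2, 1, 0, 0],   # A2
    [2, 0, 0, 0, 2, 1, 0, 1, 0, 1, 1, 2],   # A3
    [2, 2, 0, 2, 0, 1, 1, 0, 1, 0, 1, 0],   # A4
    [1, 0, 0, 1, 1, 1, 2, 0, 2, 2, 0, 1],   # A5
    [1, 0, 0, 1, 1, 1, 2, 0, 2, 2, 0, 1],   # A6 (identical to A5)
], dtype=np.int8)


def toy_panel() -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Fixed hand-written 6-accession x 12-locus panel with known statistics.

    Locus L01 has calls (0, 0, 2, 2, 1, 1): alt frequency 0.5 and
    observed heterozygosity 1/3.  Accessions A5 and A6 are identical
    (Jaccard distance 0).  Exactly one locus (L02) has no heterozygous
    call.
    """
    gm = GenotypeMatrix(
        _TOY_CALLS.copy(),
        [f"A{i}" for i in range(1, 7)],
        [f"L{i:02d}" for i in range(1, 13)],
    )
    chroms = ["1H"] * 4 + ["2H"] * 4 + ["5H"] * 3 + ["Un"]
    pos = [10e6, 20e6, 30e6, 40e6, 15e6, 25e6, 35e6, 45e6,
           12e6, 22e6, 32e6, np.nan]
    changes = ["A>G", "C>T", "G>A", "T>C", "A>C", "C>G",
               "G>T", "T>A", "A>G", "C>T", "G>C", "A>T"]
    info = pd.DataFrame({
        "locus_id": gm.locus_ids, "chromosome": chroms, "position_bp": pos,
        "change": changes, "rep_avg": 0.99, "call_rate": 1.0,
    })
    meta = pd.DataFrame({
        "accession_id": gm.accession_ids,
        "cultivar": [f"Toy{i}" for i in range(1, 7)],
        "group": ["old", "old", "mid", "mid", "new", "new"],
        "duplicate_group": [None, None, None, None, "dup1", "dup1"],
    })
    return gm, info, meta
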