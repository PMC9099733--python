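"""Core-collection extraction: minimum accession subset covering all alleles.

The M (maximisation) strategy reduces to a set-cover problem: every
(locus, allele) class observed in the panel — heterozygotes counting
as carrying both alleles — must be present in the selected subset.
The solver is an admissible best-first search (A*): states are
partial selections ordered by ``g + h`` where ``g`` is the number of
accessions chosen and ``h = ceil(uncovered / best single-accession
gain)`` never overestimates the remaining cost, so exhausting the
frontier proves minimality.  A greedy solution seeds the pruning
bound, and a configurable frontier cap degrades gracefully to greedy
completion when the exact search would outgrow memory (the mode is
recorded on the result).

Allele classes private to one accession force that accession into
every cover; these are selected up front.  Class sets are stored as
packed uint64 bit masks so candidate gains are evaluated in one
vectorised pass per expansion.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .types import GenotypeMatrix


@dataclass
class CoreSet:
    """Result of a core-collection extraction."""

    accession_ids: list[str]       # selected, in selection order
    coverage: float                # fraction of panel allele classes covered
    mode: str                      # "exact" or "beam"
    n_classes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0, 1]")


def _class_bits(gm: GenotypeMatrix) -> np.ndarray:
    """Boolean accessions x classes matrix over observed (locus, allele) classes."""
    calls = gm.calls
    ref = np.isin(calls, (0, 1))
    alt = np.isin(calls, (1, 2))
    bits = np.concatenate([ref, alt], axis=1)
    return bits[:, bits.any(axis=0)]


def _pack(bits: np.ndarray) -> np.ndarray:
    """Pack boolean rows into uint64 words."""
    packed8 = np.packbits(bits, axis=-1)
    pad = (-packed8.shape[-1]) % 8
    if pad:
        packed8 = np.concatenate(
            [packed8, np.zeros(packed8.shape[:-1] + (pad,), dtype=np.uint8)],
            axis=-1)
    return np.ascontiguousarray(packed8).view(np.uint64)


def _popcount(words: np.ndarray) -> np.ndarray:
    return np.bitwise_count(words).sum(axis=-1).astype(np.int64)


def coverage(gm: GenotypeMatrix, subset: list[str]) -> float:
    """Fraction of the panel's allele classes present in ``subset``."""
    if not subset:
        return 0.0
    bits = _class_bits(gm)
    idx = gm.accession_indices(subset)
    return float(bits[idx].any(axis=0).sum() / bits.shape[1])


def _greedy(masks: np.ndarray, covered: np.ndarray, target_count: int,
            chosen: list[int], order_rank: np.ndarray) -> list[int]:
    """Greedy completion: always add the accession covering most new classes.

    Ties break toward the lexicographically smallest accession id
    (encoded in ``order_rank``).
    """
    sel = list(chosen)
    in_sel = np.zeros(masks.shape[0], dtype=bool)
    in_sel[sel] = True
    cov_count = _popcount(covered[None, :])[0]
    while cov_count < target_count:
        gains = _popcount(masks | covered) - cov_count
        gains[in_sel] = -1
        best_gain = gains.max()
        if best_gain <= 0:
            break
        cand = np.flatnonzero(gains == best_gain)
        best = cand[np.argmin(order_rank[cand])]
        sel.append(int(best))
        in_sel[best] = True
        covered = covered | masks[best]
        cov_count += best_gain
    return sel


def extract_core(gm: GenotypeMatrix, beam_width: int = 10_000,
                 max_nodes: int = 50_000) -> CoreSet:
    """Smallest accession subset retaining every observed allele class.

    Ties among equal-size solutions break toward the lexicographically
    smallest accession-id set.  ``beam_width`` caps the search
    frontier; when exceeded (or after ``max_nodes`` expansions) the
    search degrades to the best cover found so far plus greedy
    completion, and the result mode is ``"beam"`` instead of
    ``"exact"``.
    """
    bits = _class_bits(gm)
    n, n_classes = bits.shape
    ids = gm.accession_ids
    if n == 1:
        return CoreSet(list(ids), 1.0, "exact", n_classes)

    masks = _pack(bits)                       # n x words
    target = np.bitwise_or.reduce(masks, axis=0)
    target_count = int(_popcount(target[None, :])[0])
    order = sorted(range(n), key=lambda i: ids[i])       # lexicographic
    order_rank = np.empty(n, dtype=int)
    for r, i in enumerate(order):
        order_rank[i] = r
    pos_of_rank = np.array(order)             # rank -> accession index

    # accessions carrying a private class are mandatory
    carriers = bits.sum(axis=0)
    private = np.flatnonzero(carriers == 1)
    mandatory = sorted(set(np.flatnonzero(bits[:, private].any(axis=1))),
                       key=lambda i: ids[i])
    base_cover = np.zeros_like(target)
    for i in mandatory:
        base_cover = base_cover | masks[i]

    best_sel = _greedy(masks, base_cover, target_count, list(mandatory),
                       order_rank)
    best_size = len(best_sel)
    mode = "exact"

    def ids_key(sel) -> list[str]:
        return sorted(ids[i] for i in sel)

    # state: (f, g, sorted-id tuple, covered words, last rank, chosen tuple)
    frontier = []
    if _popcount(base_cover[None, :])[0] < target_count:
        gains0 = _popcount(masks | base_cover) - _popcount(base_cover[None, :])[0]
        h0 = -(-int(target_count - _popcount(base_cover[None, :])[0])
               // max(int(gains0.max()), 1))
        frontier = [(len(mandatory) + h0, len(mandatory),
                     tuple(ids_key(mandatory)), base_cover, -1,
                     tuple(mandatory))]
    expansions = 0
    while frontier:
        f, g_cost, _tie, covered, last_rank, chosen = heapq.heappop(frontier)
        if f >= best_size:      # bound: cannot improve on the incumbent
            continue
        expansions += 1
        if expansions > max_nodes:
            mode = "beam"
            break
        cov_count = int(_popcount(covered[None, :])[0])
        new_covers = masks | covered                       # n x words
        gains = _popcount(new_covers) - cov_count
        max_gain = int(gains.max())
        if max_gain == 0:
            continue
        chosen_set = set(chosen)
        for rank in range(last_rank + 1, n):
            i = int(pos_of_rank[rank])
            if i in chosen_set or gains[i] == 0:
                continue
            new_g = g_cost + 1
            new_count = cov_count + int(gains[i])
            if new_count == target_count:
                cand = list(chosen) + [i]
                if new_g < best_size or (new_g == best_size
                                         and ids_key(cand) < ids_key(best_sel)):
                    best_size, best_sel = new_g, cand
                continue
            rem = target_count - new_count
            new_f = new_g + -(-rem // max_gain)   # parent max_gain: admissible
            if new_f >= best_size:
                continue
            heapq.heappush(frontier, (
                new_f, new_g, tuple(ids_key(list(chosen) + [i])),
                new_covers[i], rank, chosen + (i,)))
        if len(frontier) > beam_width:
            mode = "beam"
            frontier = heapq.nsmallest(beam_width // 2, frontier)
            heapq.heapify(frontier)

    final_cover = np.zeros_like(target)
    for i in best_sel:
        final_cover = final_cover | masks[i]
    cov = int(_popcount(final_cover[None, :])[0]) / target_count
    if cov < 1.0:   # degraded below full coverage: greedy top-up
        best_sel = _greedy(masks, final_cover, target_count, best_sel,
                           order_rank)
        cov, mode = 1.0, "beam"
    return CoreSet([ids[i] for i in best_sel], cov, mode, n_classes)
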