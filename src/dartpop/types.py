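"""Core containers for the pooled-sample SNP panel.

Genotype calls are coded per accession x locus as
``0`` (reference homozygote), ``1`` (heterozygous / mixed pool),
``2`` (alternative homozygote) and ``-1`` (missing).  In a pooled
DNA sample of a selfing crop a ``1`` call means the seedlings in the
pool disagree in allele content, i.e. the cultivar is internally
heterogeneous at that locus.

Locus metadata and accession metadata travel as plain pandas
DataFrames with documented column contracts (see :data:`LOCUS_COLUMNS`
and :data:`META_COLUMNS`); analysis functions index them positionally
against the genotype matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing call
MISSING: int = -1

#: recognised chromosome labels; "Un" = unassigned to a chromosome
CHROMOSOMES: tuple[str, ...] = ("1H", "2H", "3H", "4H", "5H", "6H", "7H", "Un")

#: required columns of a locus-information DataFrame
LOCUS_COLUMNS: tuple[str, ...] = (
    "locus_id", "chromosome", "position_bp", "change", "rep_avg", "call_rate",
)

#: required columns of an accession-metadata DataFrame
META_COLUMNS: tuple[str, ...] = (
    "accession_id", "cultivar", "group", "duplicate_group",
)

#: the five breeding-period group labels, oldest first
PERIOD_GROUPS: tuple[str, ...] = (
    "pre-1945", "1945-1969", "1970-1989", "1990-1999", "post-2000",
)


@dataclass
class GenotypeMatrix:
    """Accessions x loci integer genotype calls.

    Parameters
    ----------
    calls
        ``(n_accessions, n_loci)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    accession_ids
        Unique accession identifiers, one per row.
    locus_ids
        Unique locus identifiers, one per column.
    """

    calls: np.ndarray
    accession_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        n, m = self.calls.shape
        if len(self.accession_ids) != n:
            raise ValueError(
                f"{len(self.accession_ids)} accession ids for {n} rows")
        if len(self.locus_ids) != m:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {m} columns")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus ids are not unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(
                f"invalid genotype codes present: {np.unique(self.calls[bad])}")

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.calls == MISSING

    def accession_indices(self, ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[str(a)] for a in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown accession id {exc.args[0]!r}") from None

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the loci at positional ``index``."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[:, index],
            list(self.accession_ids),
            [self.locus_ids[i] for i in index],
        )

    def take_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.calls[index, :],
            [self.accession_ids[i] for i in index],
            list(self.locus_ids),
        )


def validate_locus_info(info: pd.DataFrame) -> pd.DataFrame:
    """Check the locus-information contract and normalise chromosome labels.

    Blank / NA / "unknown" chromosome labels normalise to ``"Un"``;
    unassigned loci carry no position.  Raises ``ValueError`` naming the
    offending label or locus on contract violations.
    """
    missing_cols = set(LOCUS_COLUMNS) - set(info.columns)
    if missing_cols:
        raise ValueError(f"locus info missing columns: {sorted(missing_cols)}")
    info = info.copy().reset_index(drop=True)
    chrom = info["chromosome"].astype(object)
    chrom = chrom.where(~chrom.isna(), "Un")
    chrom = chrom.astype(str).str.strip()
    chrom = chrom.replace({"": "Un", "NA": "Un", "na": "Un",
                           "Unknown": "Un", "unknown": "Un", "UN": "Un"})
    unknown = sorted(set(chrom) - set(CHROMOSOMES))
    if unknown:
        raise ValueError(f"unknown chromosome label(s): {unknown}")
    info["chromosome"] = chrom
    pos = pd.to_numeric(info["position_bp"], errors="coerce")
    info["position_bp"] = pos.where(info["chromosome"] != "Un", np.nan)
    assigned = info["chromosome"] != "Un"
    if (pos[assigned] < 1).any():
        bad = info.loc[assigned & (pos < 1), "locus_id"].iloc[0]
        raise ValueError(f"locus {bad!r} has position < 1")
    if info["locus_id"].duplicated().any():
        dup = info.loc[info["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValueError(f"duplicate locus id {dup!r}")
    for col in ("rep_avg", "call_rate"):
        vals = pd.to_numeric(info[col])
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
        info[col] = vals
    return info


def group_indices(meta: pd.DataFrame, gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Map each breeding-period group label to accession row indices."""
    order = {a: i for i, a in enumerate(gm.accession_ids)}
    out: dict[str, np.ndarray] = {}
    for grp, sub in meta.groupby("group", sort=False):
        out[str(grp)] = np.array(
            [order[a] for a in sub["accession_id"] if a in order], dtype=int)
    return out
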