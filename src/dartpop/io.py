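"""Reading and writing the DArTseq two-row SNP dialect, quality filters.

The two-row ("codominant") report encodes each biallelic locus as two
consecutive CSV rows of 0/1 presence scores — first the reference
allele row, then the alternative allele row — preceded by per-locus
metadata columns.  A row pair collapses to one genotype call per
accession::

    ref  alt   call
     1    0     0   reference homozygote
     0    1     2   alternative homozygote
     1    1     1   heterozygous (mixed pool)
     0    0    -1   missing

Quality filtering removes loci with low reproducibility (RepAvg),
low call rate, or low minor allele frequency, attributing each removal
to the first criterion failed, and reports the accounting.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CHROMOSOMES, MISSING, GenotypeMatrix, validate_locus_info

#: metadata columns preceding the per-accession score columns
_META_COLS = ["locus_id", "chromosome", "position_bp", "change",
              "rep_avg", "call_rate"]


class MalformedFileError(ValueError):
    """The file does not follow the two-row dialect."""


@dataclass
class FilterConfig:
    """Locus quality thresholds; boundary values are kept (removal is strict <)."""

    min_rep_avg: float = 0.95
    min_call_rate: float = 0.95
    min_maf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_rep_avg", "min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    """Accounting of a filtering pass; counts sum to the input locus count."""

    n_input: int
    n_removed_rep: int
    n_removed_callrate: int
    n_removed_maf: int
    n_kept: int
    kept_by_chromosome: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (self.n_removed_rep + self.n_removed_callrate
                 + self.n_removed_maf + self.n_kept)
        if total != self.n_input:
            raise ValueError("filter report counts do not sum to n_input")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("removed_rep_avg", self.n_removed_rep),
            ("removed_call_rate", self.n_removed_callrate),
            ("removed_maf", self.n_removed_maf),
            ("kept", self.n_kept),
        ]
        rows += [(f"kept_{c}", n) for c, n in self.kept_by_chromosome.items()]
        return pd.DataFrame(rows, columns=["criterion", "n_loci"])


def read_dartseq_tworow(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a two-row DArTseq CSV into a genotype matrix and locus info.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        Genotypes coded 0/1/2/missing, and a locus-information table
        with columns ``locus_id, chromosome, position_bp, change,
        rep_avg, call_rate`` aligned to the matrix columns.
    """
    raw = pd.read_csv(path, dtype={"chromosome": str})
    missing_cols = [c for c in _META_COLS if c not in raw.columns]
    if missing_cols:
        raise MalformedFileError(f"missing metadata columns: {missing_cols}")
    acc_cols = [c for c in raw.columns if c not in _META_COLS]
    if not acc_cols:
        raise MalformedFileError("no accession score columns found")
    if len(raw) % 2:
        raise MalformedFileError(
            f"odd number of locus rows ({len(raw)}); "
            "each locus must appear as a ref/alt row pair")

    ref = raw.iloc[0::2].reset_index(drop=True)
    alt = raw.iloc[1::2].reset_index(drop=True)
    if not (ref["locus_id"].values == alt["locus_id"].values).all():
        bad = ref.loc[ref["locus_id"].values != alt["locus_id"].values,
                      "locus_id"].iloc[0]
        raise MalformedFileError(
            f"row pair mismatch at locus {bad!r}: ref and alt rows "
            "must be consecutive and share the locus id")

    scores_ref = ref[acc_cols].to_numpy()
    scores_alt = alt[acc_cols].to_numpy()
    for name, arr in (("ref", scores_ref), ("alt", scores_alt)):
        if not np.isin(arr, (0, 1)).all():
            raise MalformedFileError(f"{name} rows contain non-0/1 scores")

    # (ref, alt) -> call: (1,0)->0, (0,1)->2, (1,1)->1, (0,0)->missing
    calls = np.full(scores_ref.shape, MISSING, dtype=np.int8)
    calls[(scores_ref == 1) & (scores_alt == 0)] = 0
    calls[(scores_ref == 0) & (scores_alt == 1)] = 2
    calls[(scores_ref == 1) & (scores_alt == 1)] = 1

    info = validate_locus_info(ref[_META_COLS])
    gm = GenotypeMatrix(calls.T, acc_cols, list(info["locus_id"]))
    return gm, info


def write_dartseq_tworow(gm: GenotypeMatrix, info: pd.DataFrame,
                         path: str | Path) -> Path:
    """Write a panel in the two-row dialect (inverse of the reader)."""
    info = validate_locus_info(info)
    if list(info["locus_id"]) != gm.locus_ids:
        raise ValueError("locus info not aligned with genotype matrix")
    calls = gm.calls.T  # loci x accessions
    ref = np.isin(calls, (0, 1)).astype(int)
    alt = np.isin(calls, (1, 2)).astype(int)
    n_loci = gm.n_loci
    meta = info.loc[info.index.repeat(2)].reset_index(drop=True)
    scores = np.empty((2 * n_loci, gm.n_accessions), dtype=int)
    scores[0::2] = ref
    scores[1::2] = alt
    out = pd.concat(
        [meta, pd.DataFrame(scores, columns=gm.accession_ids)], axis=1)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def filter_loci(
    gm: GenotypeMatrix,
    info: pd.DataFrame,
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, FilterReport]:
    """Remove low-quality loci; single pass, first-failed-criterion attribution.

    Criteria in order: reproducibility (RepAvg), call rate, minor
    allele frequency.  MAF is computed from the non-missing calls over
    all accessions, counting two allele copies per homozygote and one
    of each per heterozygote.  Boundary values equal to a threshold
    are kept.
    """
    cfg = cfg or FilterConfig()
    info = validate_locus_info(info)
    if len(info) != gm.n_loci:
        raise ValueError("locus info not aligned with genotype matrix")

    calls = gm.calls
    valid = calls != MISSING
    n_copies = 2 * valid.sum(axis=0)
    alt_copies = np.where(valid, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt_copies / np.maximum(n_copies, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)

    fail_rep = info["rep_avg"].to_numpy() < cfg.min_rep_avg
    fail_call = info["call_rate"].to_numpy() < cfg.min_call_rate
    # monomorphic-by-missingness loci have undefined MAF; treat as failing
    fail_maf = ~(maf >= cfg.min_maf)

    removed_rep = fail_rep
    removed_call = ~fail_rep & fail_call
    removed_maf = ~fail_rep & ~fail_call & fail_maf
    kept = ~(removed_rep | removed_call | removed_maf)

    kept_idx = np.flatnonzero(kept)
    if kept_idx.size == 0:
        warnings.warn("all loci removed by filtering; returning empty panel",
                      stacklevel=2)
    gm_out = gm.take_loci(kept_idx)
    info_out = info.iloc[kept_idx].reset_index(drop=True)
    by_chrom = {c: int((info_out["chromosome"] == c).sum())
                for c in CHROMOSOMES if (info_out["chromosome"] == c).any()}
    report = FilterReport(
        n_input=gm.n_loci,
        n_removed_rep=int(removed_rep.sum()),
        n_removed_callrate=int(removed_call.sum()),
        n_removed_maf=int(removed_maf.sum()),
        n_kept=int(kept.sum()),
        kept_by_chromosome=by_chrom,
    )
    return gm_out, info_out, report


def write_table(obj, path: str | Path, format: str = "csv") -> Path:
    """Write a pipeline result table as CSV or JSON.

    Accepts DataFrames, result dataclasses exposing ``to_frame()``,
    plain dicts (JSON only) and mappings of scalars.  Floats are
    written to 12 significant digits so re-reading is lossless at that
    precision.
    """
    path = Path(path)
    if hasattr(obj, "to_frame") and not isinstance(obj, pd.Series):
        obj = obj.to_frame()
    if format == "csv":
        if isinstance(obj, pd.Series):
            obj = obj.to_frame().reset_index()
        if not isinstance(obj, pd.DataFrame):
            raise TypeError(f"cannot write {type(obj).__name__} as CSV")
        obj.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        if isinstance(obj, pd.DataFrame):
            payload = obj.to_dict(orient="records")
        elif dataclasses.is_dataclass(obj):
            payload = dataclasses.asdict(obj)
        else:
            payload = obj
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o).__name__}")
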