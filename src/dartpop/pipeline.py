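"""End-to-end pipeline: simulate or load a panel, run every analysis stage.

Stage order: filter -> diversity -> snp_types -> windows ->
unique_alleles -> distance -> pcoa -> amova -> admixture ->
duplicates -> core.  Every stage writes plain CSV; a JSON manifest
records parameters, derived seeds and per-stage output row counts.
A single global seed fans out to per-stage seeds by fixed offsets so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import (align_replicates, assign_memberships,
                        pool_proportions_by_group, run_admixture_grid)
from .amova import amova
from .core import extract_core
from .diversity import (allele_freq, group_summaries, observed_het, pic,
                        cultivar_heterogeneity, homozygous_locus_fraction,
                        snp_type_table)
from .distance import group_distance_summary, jaccard_distance, pcoa
from .io import FilterConfig, filter_loci, read_dartseq_tworow, write_table
from .reference import chromosome_lengths_bp
from .relatedness import duplicate_clusters, duplicate_verdict, ibd_pihat
from .scan import (make_windows, selection_scan_report, tracks_to_frame,
                   unique_alleles, window_reduce)
from .simulate import SimConfig, generate_panel
from .types import GenotypeMatrix, group_indices

log = logging.getLogger("dartpop")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Exactly one of (``input_genotypes`` + ``input_meta``) or
    ``simulation`` must be given.
    """

    input_genotypes: str | None = None
    input_meta: str | None = None
    simulation: SimConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_window_positions: int = 250
    window_width_bp: float = 500_000
    unique_thresholds: tuple[float, ...] = (0.25, 0.05)
    k_min: int = 1
    k_max: int = 6
    admixture_replicates: int = 3
    admixture_max_iter: int = 300
    admixture_tol: float = 1e-4
    membership_threshold: float = 0.8
    ibd_cutoff: float = 0.95
    d_low: float = 0.05
    amova_permutations: int = 999
    out_dir: str = "dartpop_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.input_genotypes is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of input files or a simulation block is required")
        if has_files and self.input_meta is None:
            raise ValueError("accession metadata file is required with inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if "sweep_spec" in sim:
                sim["sweep_spec"] = [
                    (s[0], float(s[1]), float(s[2]), tuple(s[3]))
                    for s in sim["sweep_spec"]]
            if "loci_per_chromosome" in sim:
                sim["loci_per_chromosome"] = dict(sim["loci_per_chromosome"])
            for tup_key in ("group_sizes", "group_labels",
                            "heterogeneity_by_group"):
                if tup_key in sim:
                    sim[tup_key] = tuple(sim[tup_key])
            raw["simulation"] = SimConfig(**sim)
        if "filter" in raw and raw["filter"] is not None:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "unique_thresholds" in raw:
            raw["unique_thresholds"] = tuple(raw["unique_thresholds"])
        return cls(**raw)


def _ordered_groups(meta: pd.DataFrame) -> list[str]:
    """Group labels in order of first appearance (metadata is period-ordered)."""
    return list(dict.fromkeys(meta["group"].astype(str)))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dartpop", "version": __version__,
        "seed": cfg.seed, "parameters": _cfg_dict(cfg), "stages": {},
    }
    stage_name = "load"
    t0 = time.time()
    try:
        # ------------------------------------------------------------ load
        if cfg.simulation is not None:
            gm, info, meta, truth = generate_panel(cfg.simulation)
            log.info("simulated panel: %d accessions x %d loci",
                     gm.n_accessions, gm.n_loci)
        else:
            gm, info = read_dartseq_tworow(cfg.input_genotypes)
            meta = pd.read_csv(cfg.input_meta)
            log.info("loaded panel: %d accessions x %d loci",
                     gm.n_accessions, gm.n_loci)
        manifest["stages"]["load"] = {
            "n_accessions": gm.n_accessions, "n_loci": gm.n_loci}

        # ---------------------------------------------------------- filter
        stage_name = "filter"
        gm, info, report = filter_loci(gm, info, cfg.filter)
        f = write_table(report, out / "filter_report.csv")
        _record(manifest, "filter", [f], n_kept=report.n_kept)
        log.info("filter: kept %d of %d loci", report.n_kept, report.n_input)

        groups = group_indices(meta, gm)
        group_order = _ordered_groups(meta)
        lengths = chromosome_lengths_bp()

        # ------------------------------------------------------- diversity
        stage_name = "diversity"
        summaries = group_summaries(gm, info, meta)
        het = cultivar_heterogeneity(gm)
        hom = homozygous_locus_fraction(gm, info, by_chromosome=True)
        files = [write_table(summaries, out / "diversity_summaries.csv"),
                 write_table(het, out / "cultivar_heterogeneity.csv"),
                 write_table(hom.rename_axis("scope").reset_index(),
                             out / "homozygous_locus_fraction.csv")]
        _record(manifest, "diversity", files, rows=len(summaries))

        # ------------------------------------------------------- snp_types
        stage_name = "snp_types"
        snp_tab = snp_type_table(info)
        files = [write_table(snp_tab.to_frame(), out / "snp_types.csv")]
        _record(manifest, "snp_types", files,
                total=int(snp_tab.totals["Total"]))

        # --------------------------------------------------------- windows
        stage_name = "windows"
        p, _ = allele_freq(gm)
        ho = observed_het(gm)
        chrom = info["chromosome"].to_numpy()
        pos = info["position_bp"].to_numpy(dtype=float)
        tracks = {"density": [], "pic": [], "ho": []}
        for c, length in lengths.items():
            m = (chrom == c) & ~np.isnan(pos)
            if not m.any():
                continue
            skel = make_windows(length, c, cfg.n_window_positions,
                                cfg.window_width_bp)
            tracks["density"].append(
                window_reduce(skel, pos[m], None, "count"))
            tracks["pic"].append(window_reduce(skel, pos[m], pic(p)[m], "mean"))
            tracks["ho"].append(window_reduce(skel, pos[m], ho[m], "mean"))
        files = [write_table(tracks_to_frame(v), out / f"windows_{k}.csv")
                 for k, v in tracks.items()]
        _record(manifest, "windows", files)

        # -------------------------------------------------- unique_alleles
        stage_name = "unique_alleles"
        ua_frames = []
        for thr in cfg.unique_thresholds:
            for earlier, later in zip(group_order[:-1], group_order[1:]):
                ua = unique_alleles(gm, info, groups[earlier], groups[later],
                                    threshold=thr)
                ua.insert(0, "pair", f"{earlier} vs {later}")
                ua_frames.append(ua)
        ua_all = pd.concat(ua_frames, ignore_index=True)
        files = [write_table(ua_all, out / "unique_alleles.csv")]
        # selection scan contrasting the extreme periods
        scan_tracks = selection_scan_report(
            gm, info, meta, group_order[0], group_order[-1], lengths,
            cfg.n_window_positions, cfg.window_width_bp)
        for key, trs in scan_tracks.items():
            files.append(write_table(tracks_to_frame(trs),
                                     out / f"scan_{key}.csv"))
        _record(manifest, "unique_alleles", files, rows=len(ua_all))

        # -------------------------------------------------------- distance
        stage_name = "distance"
        D = jaccard_distance(gm)
        dist_summary = group_distance_summary(D, meta)
        files = [write_table(D.to_frame().reset_index(names="accession_id"),
                             out / "jaccard_distance.csv"),
                 write_table(dist_summary, out / "distance_summary.csv")]
        _record(manifest, "distance", files)

        # ------------------------------------------------------------ pcoa
        stage_name = "pcoa"
        ord_res = pcoa(D, n_axes=3)
        files = [write_table(ord_res, out / "pcoa_coordinates.csv")]
        _record(manifest, "pcoa", files,
                pct_first_three=float(ord_res.percent_variance[:3].sum()))

        # ----------------------------------------------------------- amova
        stage_name = "amova"
        am = amova(D, meta.set_index("accession_id").loc[
            D.accession_ids, "group"], cfg.amova_permutations,
            seed=cfg.seed + 1)
        files = [write_table(am, out / "amova.csv"),
                 write_table(pd.DataFrame({"phi_perm": am.permuted_phi}),
                             out / "amova_permutations.csv")]
        _record(manifest, "amova", files, pct_within=am.pct_within)
        log.info("amova: %.1f%% within / %.1f%% among groups",
                 am.pct_within, am.pct_among)

        # ------------------------------------------------------- admixture
        stage_name = "admixture"
        fits, delta = run_admixture_grid(
            gm, range(cfg.k_min, cfg.k_max + 1), cfg.admixture_replicates,
            seed=cfg.seed + 2, max_iter=cfg.admixture_max_iter,
            tol=cfg.admixture_tol)
        chosen_k = delta.attrs.get("chosen_k") if delta is not None else None
        if chosen_k is None:
            chosen_k = cfg.k_max
        _, consensus, _ = align_replicates(fits[chosen_k])
        Q = pd.DataFrame(consensus, index=gm.accession_ids,
                         columns=[f"pool_{i + 1}" for i in range(chosen_k)])
        memberships = pd.DataFrame({
            "accession_id": gm.accession_ids,
            "assignment": assign_memberships(consensus,
                                             cfg.membership_threshold)})
        props = pool_proportions_by_group(Q, meta)
        files = [write_table(Q.reset_index(names="accession_id"),
                             out / "admixture_q.csv"),
                 write_table(memberships, out / "admixture_assignments.csv"),
                 write_table(props.reset_index(), out / "pool_proportions.csv")]
        if delta is not None:
            files.append(write_table(delta, out / "delta_k.csv"))
        _record(manifest, "admixture", files, chosen_k=int(chosen_k))
        log.info("admixture: chosen K = %d", chosen_k)

        # ------------------------------------------------------ duplicates
        stage_name = "duplicates"
        ibd = ibd_pihat(gm)
        clusters = duplicate_clusters(ibd, cfg.ibd_cutoff)
        verdicts = duplicate_verdict(meta, D, Q, clusters, cfg.d_low)
        files = [write_table(ibd.to_frame().reset_index(names="accession_id"),
                             out / "ibd_pihat.csv"),
                 write_table(verdicts, out / "duplicate_verdicts.csv")]
        _record(manifest, "duplicates", files, n_clusters=len(clusters))

        # ------------------------------------------------------------ core
        stage_name = "core"
        core = extract_core(gm)
        core_tab = pd.DataFrame({
            "accession_id": gm.accession_ids,
            "selected": [a in set(core.accession_ids)
                         for a in gm.accession_ids],
            "order": [core.accession_ids.index(a) + 1
                      if a in set(core.accession_ids) else 0
                      for a in gm.accession_ids]})
        files = [write_table(core_tab, out / "core_collection.csv")]
        _record(manifest, "core", files, core_size=len(core.accession_ids),
                coverage=core.coverage, mode=core.mode)
        log.info("core collection: %d of %d accessions (coverage %.3f)",
                 len(core.accession_ids), gm.n_accessions, core.coverage)

    except Exception as exc:
        manifest["failed_stage"] = stage_name
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _record(manifest: dict, stage: str, files: list[Path], **extra) -> None:
    manifest["stages"][stage] = {
        "outputs": [f.name for f in files], **extra}


def _cfg_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("simulation") is not None:
        d["simulation"] = {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in d["simulation"].items()}
        d["simulation"]["sweep_spec"] = [
            [s[0], s[1], s[2], list(s[3])]
            for s in cfg.simulation.sweep_spec]
    return json.loads(json.dumps(d, default=str))
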