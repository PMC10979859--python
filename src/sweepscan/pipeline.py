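"""End-to-end orchestration of the resistance-association workflow.

Stages: kinship QC -> sib dedup -> selection scans (H12, dH12, H1X) ->
windowed FST -> peak calling -> phenotype-permutation filter ->
haplotype-cluster filter -> coverage-HMM CNV calls -> marker and
stepwise association -> SNP-wise + windowed GWAS. Every stage writes a
TSV under the run directory, and a manifest records the configuration
hash, seeds and package version so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import fdr_select, marker_tests, snp_gwas, stepwise_build, windowed_gwas
from .cnv import CoverageHMMParams, carrier_table, decode_all, gene_copy_number_table
from .core_io import (
    CoverageMatrix,
    DataError,
    GeneRegion,
    GenotypeSet,
    HaplotypeSet,
    SampleTable,
    read_coverage,
    read_regions,
    read_sample_table,
    read_vcf,
)
from .differentiation import (
    candidate_windows_above,
    centile_peak_threshold,
    fst_peak_threshold,
    fst_scan,
    fst_scan_sib_averaged,
    make_fst_recompute,
    make_h12_recompute,
    permutation_filter,
)
from .hapclust import filter_peaks_by_cluster
from .kinship import dedup_sibs, find_sib_groups, flag_contaminated, king_kinship
from .selection import delta_h12, h12_scan, h1x_scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All inputs, thresholds and seeds of a pipeline run.

    Thresholds default to the workflow's standard constants: KING 0.185,
    tree cut height 0.001, minimum cluster 20 haplotypes, 500 phenotype
    permutations with 99% retention, FST mode rule and 95th/98th centile
    rules, MAC >= 5, FDR Q = 1%, top-1000 SNPs / 100 kb / >= 10 hits.
    """

    vcf: str = ""
    sample_table: str = ""
    coverage: str = ""
    regions: str = ""
    outdir: str = "sweepscan_run"
    # grouping
    phenotype_column: str = "phenotype"
    location_column: str = "location"
    # exclusions for kinship (e.g. inversion regions)
    kinship_exclude: list[dict] = field(default_factory=list)
    # windows & thresholds
    window_size: int = 1000
    king_threshold: float = 0.185
    cut_height: float = 0.001
    min_cluster_size: int = 20
    n_perm: int = 500
    retain_quantile: float = 0.99
    h12_centile: float = 98.0
    pbs_centile: float = 95.0
    centile_multiplier: float = 3.0
    min_mac: int = 5
    fdr_q: float = 0.01
    gwas_top_n: int = 1000
    gwas_window_bp: int = 100_000
    gwas_min_hits: int = 10
    cluster_alpha: float = 0.05
    n_sib_perm: int = 100
    hmm_sigma: float = 0.5
    hmm_transition_p: float = 1e-4
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _exclude_regions(cfg: RunConfig) -> list[GeneRegion]:
    return [
        GeneRegion(
            name=r.get("name", f"excl_{i}"),
            contig=r["contig"],
            start=int(r["start"]),
            end=int(r["end"]),
        )
        for i, r in enumerate(cfg.kinship_exclude)
    ]


def run_pipeline(
    cfg: RunConfig,
    g: Optional[GenotypeSet] = None,
    h: Optional[HaplotypeSet] = None,
    cov: Optional[CoverageMatrix] = None,
    st: Optional[SampleTable] = None,
    regions: Optional[list[GeneRegion]] = None,
) -> dict:
    """Run all stages; returns the result bundle and writes TSV outputs.

    Inputs may be passed in memory (as from the synthetic generator) or
    read from the paths in ``cfg``.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    stage = "load"
    try:
        if g is None or h is None:
            g, h = read_vcf(cfg.vcf)
        if st is None:
            st = read_sample_table(cfg.sample_table)
        if cov is None and cfg.coverage:
            cov = read_coverage(cfg.coverage)
        if regions is None and cfg.regions:
            regions = read_regions(cfg.regions)
        regions = regions or []

        stage = "kinship"
        kin = king_kinship(g, _exclude_regions(cfg))
        sib_groups = find_sib_groups(kin, cfg.king_threshold)
        contaminated = flag_contaminated(kin, g)
        kin.to_frame().to_csv(out / "kinship.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(grp.group_id, m) for grp in sib_groups for m in grp.members],
            columns=["group_id", "sample_id"],
        ).to_csv(out / "sib_groups.tsv", sep="\t", index=False)
        bundle["sib_groups"] = sib_groups
        bundle["contaminated"] = contaminated

        stage = "dedup"
        keep_st = st.subset([s for s in st.sample_ids if s not in contaminated])
        retained = dedup_sibs(keep_st, sib_groups, seed=cfg.seed)
        bundle["retained"] = retained
        st_r = st.subset(retained)
        g_r = g.take_samples(retained)
        h_r = h.take_samples(retained)

        stage = "selection_scans"
        res_ids = st_r.group_ids(cfg.phenotype_column, "resistant")
        sus_ids = st_r.group_ids(cfg.phenotype_column, "susceptible")
        h_res = h_r.take_samples(res_ids)
        h_sus = h_r.take_samples(sus_ids)
        h12_res = h12_scan(h_res, cfg.window_size, label="resistant")
        dh12 = delta_h12(h_res, h_sus, cfg.window_size)
        h12_res.to_frame().to_csv(out / "h12_resistant.tsv", sep="\t", index=False)
        dh12.to_frame().to_csv(out / "delta_h12.tsv", sep="\t", index=False)
        bundle["h12"] = h12_res
        bundle["delta_h12"] = dh12
        locations = sorted(set(st_r.df[cfg.location_column]))
        if len(locations) == 2:
            ids_a = st_r.group_ids(cfg.location_column, locations[0])
            ids_b = st_r.group_ids(cfg.location_column, locations[1])
            if ids_a and ids_b:
                track = h1x_scan(
                    h_r.take_samples(ids_a), h_r.take_samples(ids_b), cfg.window_size
                )
                track.to_frame().to_csv(out / "h1x.tsv", sep="\t", index=False)
                bundle["h1x"] = track

        stage = "fst_scan"
        if sib_groups:
            fst_track = fst_scan_sib_averaged(
                g, st.subset([s for s in st.sample_ids if s not in contaminated]),
                sib_groups, n_perm=cfg.n_sib_perm, seed=cfg.seed,
                window_size=cfg.window_size,
            )
        else:
            fst_track = fst_scan(
                g_r, res_ids, sus_ids, window_size=cfg.window_size
            )
        fst_track.to_frame().to_csv(out / "fst.tsv", sep="\t", index=False)
        bundle["fst"] = fst_track

        stage = "peaks"
        # the permutation filter recomputes plain (non-sib-averaged) FST on
        # the deduplicated cohort, so candidates are re-anchored there
        fst_plain = fst_scan(g_r, res_ids, sus_ids, window_size=cfg.window_size)
        _, fst_thresh = fst_peak_threshold(fst_plain.values)
        fst_cand_idx = candidate_windows_above(fst_plain, fst_thresh)
        fst_cand = [fst_plain.windows[i] for i in fst_cand_idx]
        recompute = make_fst_recompute(
            g_r, st_r, fst_cand, fst_plain.labels["site_idx"]
        )
        fst_peaks = permutation_filter(
            fst_plain.values[fst_cand_idx], fst_cand, st_r, recompute,
            n_perm=cfg.n_perm, retain_quantile=cfg.retain_quantile,
            seed=cfg.seed, statistic="fst",
        )
        fst_peaks = filter_peaks_by_cluster(
            fst_peaks, h_r, st_r, cut_height=cfg.cut_height,
            min_size=cfg.min_cluster_size, alpha=cfg.cluster_alpha,
        )
        fst_peaks.to_frame().to_csv(out / "fst_peaks.tsv", sep="\t", index=False)
        bundle["fst_peaks"] = fst_peaks

        h12_thresh = centile_peak_threshold(
            h12_res.values, cfg.h12_centile, cfg.centile_multiplier
        )
        h12_cand_idx = candidate_windows_above(
            h12_res, min(h12_thresh, 1.0 - 1e-9), positive_only=True
        )
        h12_cand = [h12_res.windows[i] for i in h12_cand_idx]
        h12_peaks = permutation_filter(
            h12_res.values[h12_cand_idx], h12_cand, st_r,
            make_h12_recompute(h_r, st_r, h12_cand),
            n_perm=cfg.n_perm, retain_quantile=cfg.retain_quantile,
            seed=cfg.seed + 1, statistic="h12",
        )
        h12_peaks.to_frame().to_csv(out / "h12_peaks.tsv", sep="\t", index=False)
        bundle["h12_peaks"] = h12_peaks

        stage = "cnv"
        markers = None
        if cov is not None and regions:
            params = CoverageHMMParams(
                sigma=cfg.hmm_sigma, transition_p=cfg.hmm_transition_p
            )
            states = decode_all(cov, params)
            calls = gene_copy_number_table(cov, regions, states=states)
            calls.to_frame().to_csv(out / "copy_number.tsv", sep="\t", index=False)
            carriers = carrier_table(calls)
            carriers.to_csv(out / "cnv_carriers.tsv", sep="\t", index=False)
            bundle["copy_number"] = calls
            order = [calls.samples.index(s) for s in retained]
            markers = pd.DataFrame(
                {
                    f"{gene}_carrier": calls.carrier[order, j].astype(float)
                    for j, gene in enumerate(calls.genes)
                }
            )

        stage = "association"
        if markers is not None:
            mt = marker_tests(st_r, markers)
            mt.to_csv(out / "marker_tests.tsv", sep="\t", index=False)
            sw = stepwise_build(st_r, markers)
            pd.DataFrame(
                sw.steps, columns=["marker", "lrt_p", "log_likelihood"]
            ).to_csv(out / "stepwise.tsv", sep="\t", index=False)
            bundle["marker_tests"] = mt
            bundle["stepwise"] = sw

        stage = "gwas"
        gwas = snp_gwas(g_r, st_r, min_mac=cfg.min_mac)
        gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
        sig = fdr_select(gwas, q=cfg.fdr_q)
        sig.to_csv(out / "gwas_significant.tsv", sep="\t", index=False)
        wins = windowed_gwas(
            gwas, top_n=cfg.gwas_top_n, window_bp=cfg.gwas_window_bp,
            min_hits=cfg.gwas_min_hits,
        )
        wins.to_csv(out / "gwas_windows.tsv", sep="\t", index=False)
        bundle["gwas"] = gwas
        bundle["gwas_significant"] = sig
        bundle["gwas_windows"] = wins

        stage = "manifest"
        manifest = {
            "config_hash": cfg.digest(),
            "config": dataclasses.asdict(cfg),
            "seed": cfg.seed,
            "version": __version__,
            "n_samples": len(st.sample_ids),
            "n_sites": g.n_sites,
            "n_retained": len(retained),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
    except (PipelineError, DataError):
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return bundle
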