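"""End-to-end orchestration: filter → scan → karyotype → breakpoints →
LD profile → inversion comparisons.

``run_pipeline`` is the in-memory engine; ``run_all`` wraps it with input
loading (VCF or simulation config), TSV outputs and a JSON run manifest.
A single run seed fans out to per-stage seeds by a fixed hash of the stage
name, so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .breakpoint_estimation import (AssociationResult, CoordinateEstimate,
                                    association_scan, estimate_coordinates)
from .genotype_io import (ChromosomeTable, GenotypeMatrix, read_chrom_table,
                          read_vcf, write_vcf)
from .inversion_scan import (CandidateRegion, InsufficientResolutionError,
                             PCAResult, WindowStat, chromosome_pca,
                             detect_candidate_regions,
                             windowed_weight_variance)
from .inversion_comparisons import InversionPairResult, pairwise_inversion_tests
from .karyotyping import GENOTYPE_CODE, InversionCall, karyotype_component
from .ld_profile import (LDCorrelation, collect_pair_arrays,
                         weight_ld_correlation, windowed_median_r2)
from .simulate import (InversionSpec, SimulationConfig, SimulationTruth,
                       chrom_table_for, simulate_dataset, write_truth)
from .variant_filtering import FilterReport, filter_variants, ld_prune

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    return (zlib.crc32(f"{stage}:{seed}".encode()) ^ seed) % (2**31)


@dataclass
class PipelineResult:
    gm: GenotypeMatrix
    chrom_table: ChromosomeTable
    filter_report: FilterReport
    pca: dict[str, PCAResult]
    windows: list[WindowStat]
    regions: list[CandidateRegion]
    inversions: list[InversionCall]
    associations: dict[str, list[AssociationResult]]
    coordinates: dict[str, CoordinateEstimate]
    ld_windows: dict[str, list[WindowStat]]
    ld_correlations: list[LDCorrelation]
    pair_results: list[InversionPairResult]
    truth: SimulationTruth | None = None

    def retained(self) -> list[InversionCall]:
        return [inv for inv in self.inversions if inv.retained]


DEFAULTS: dict[str, dict] = {
    "filter": {"maf_min": 0.1, "max_missing_frac": 0.5,
               "prune_window_bp": 14_000, "prune_step_bp": 9_000,
               "prune_r2": 0.05},
    "scan": {"n_components": 5, "window_bp": 10_000, "step_bp": 7_500,
             "min_snps": 3, "flag_quantile": 0.75, "flag_fold": 5.0,
             "min_run": 10, "max_gap": 2},
    "karyotype": {"top_fraction": 0.01, "min_cluster_size": 3,
                  "min_mean_membership": 0.8, "spacing_window": (0.3, 0.7)},
    "breakpoints": {"alpha": 0.05, "merge_gap_bp": 1_000_000},
    "ld": {"max_dist": 12_000, "min_dist": 0, "window_frac": 0.005,
           "step_frac": 0.0025, "min_pairs": 5},
    "compare": {"alpha": 0.05, "min_shared": 10},
}


def _params(config: dict, stage: str) -> dict:
    merged = dict(DEFAULTS[stage])
    merged.update(config.get(stage, {}) or {})
    return merged


def run_pipeline(gm: GenotypeMatrix, chrom_table: ChromosomeTable,
                 config: dict | None = None, seed: int = 0,
                 truth: SimulationTruth | None = None) -> PipelineResult:
    """Run every analysis stage on an in-memory genotype matrix."""
    config = config or {}
    f = _params(config, "filter")
    s = _params(config, "scan")
    k = _params(config, "karyotype")
    b = _params(config, "breakpoints")
    ld = _params(config, "ld")
    cmp_p = _params(config, "compare")

    report = FilterReport()
    gm = filter_variants(gm, f["maf_min"], f["max_missing_frac"], report)
    gm = ld_prune(gm, f["prune_window_bp"], f["prune_step_bp"],
                  f["prune_r2"], report)

    pca: dict[str, PCAResult] = {}
    windows: list[WindowStat] = []
    regions: list[CandidateRegion] = []
    candidate_components: list[tuple[str, int, CandidateRegion]] = []
    for chrom in gm.chromosomes():
        res = chromosome_pca(gm, chrom, s["n_components"])
        pca[chrom] = res
        for comp in range(1, res.n_components + 1):
            ws = windowed_weight_variance(res, comp, s["window_bp"],
                                          s["step_bp"], s["min_snps"])
            windows.extend(ws)
            try:
                regs = detect_candidate_regions(
                    ws, s["flag_quantile"], s["flag_fold"],
                    s["min_run"], s["max_gap"])
            except InsufficientResolutionError:
                logger.warning("%s C%d: too few valued windows; skipped",
                               chrom, comp)
                continue
            regions.extend(regs)
            if regs:
                candidate_components.append((chrom, comp, regs[0]))

    inversions: list[InversionCall] = []
    for chrom, comp, top_region in candidate_components:
        inv = karyotype_component(
            gm, pca[chrom], comp, region=top_region,
            top_fraction=k["top_fraction"],
            seed=stage_seed(seed, f"karyotype:{chrom}:{comp}"),
            min_cluster_size=k["min_cluster_size"],
            min_mean_membership=k["min_mean_membership"],
            spacing_window=tuple(k["spacing_window"]))
        inversions.append(inv)

    associations: dict[str, list[AssociationResult]] = {}
    coordinates: dict[str, CoordinateEstimate] = {}
    sample_index = {sid: i for i, sid in enumerate(gm.sample_ids)}
    for inv in inversions:
        if not inv.retained:
            continue
        phenotype = np.zeros(gm.n_samples)
        for c in inv.calls:
            phenotype[sample_index[c.sample_id]] = GENOTYPE_CODE[c.genotype]
        res = association_scan(gm, inv.chrom, phenotype, b["alpha"])
        associations[inv.inversion_id] = res
        est = estimate_coordinates(res, inv.inversion_id, b["merge_gap_bp"])
        if est is not None:
            coordinates[inv.inversion_id] = est

    ld_windows: dict[str, list[WindowStat]] = {}
    ld_correlations: list[LDCorrelation] = []
    for chrom in gm.chromosomes():
        pairs = collect_pair_arrays(gm, chrom, ld["max_dist"], ld["min_dist"])
        ld_windows[chrom] = windowed_median_r2(
            pairs, chrom, chrom_table[chrom], ld["window_frac"],
            ld["step_frac"], ld["min_pairs"])
        for inv in inversions:
            if inv.chrom == chrom and inv.retained:
                corr = weight_ld_correlation(ld_windows[chrom], pca[chrom],
                                             inv.component)
                if corr is not None:
                    ld_correlations.append(corr)

    retained = [inv for inv in inversions if inv.retained]
    pair_results: list[InversionPairResult] = []
    if len(retained) >= 2:
        pair_results = pairwise_inversion_tests(
            retained, cmp_p["alpha"], cmp_p["min_shared"])

    return PipelineResult(
        gm=gm, chrom_table=chrom_table, filter_report=report, pca=pca,
        windows=windows, regions=regions, inversions=inversions,
        associations=associations, coordinates=coordinates,
        ld_windows=ld_windows, ld_correlations=ld_correlations,
        pair_results=pair_results, truth=truth)


def _load_input(config: dict) -> tuple[GenotypeMatrix, ChromosomeTable,
                                       SimulationTruth | None]:
    sim_cfg = config.get("simulate")
    inp = config.get("input", {}) or {}
    if sim_cfg:
        sc = simulation_config_from_dict(sim_cfg)
        gm, truth = simulate_dataset(sc)
        return gm, chrom_table_for(sc), truth
    vcf_path = inp.get("vcf")
    if not vcf_path:
        raise ValueError("config needs either input.vcf or a simulate section")
    gm, table = read_vcf(vcf_path, inp.get("region"))
    if inp.get("chrom_table"):
        table = read_chrom_table(inp["chrom_table"])
    for chrom in gm.chromosomes():
        if chrom not in table:
            raise ValueError(f"no length for chromosome {chrom!r}; supply "
                             "input.chrom_table or VCF contig headers")
    return gm, table, None


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    invs = [InversionSpec(**inv) for inv in d.get("inversions", [])]
    kwargs = {key: val for key, val in d.items() if key != "inversions"}
    if "background_maf_range" in kwargs:
        kwargs["background_maf_range"] = tuple(kwargs["background_maf_range"])
    return SimulationConfig(inversions=invs, **kwargs)


def _w(path: Path, header: str, rows) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_outputs(result: PipelineResult, out_dir: str | Path,
                  config: dict, seed: int) -> None:
    """Write all stage TSVs, the consolidated report, and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _w(out / "filter_report.tsv", "stage\tn_before\tn_after",
       result.filter_report.stages)
    _w(out / "scan_windows.tsv", "chrom\tcomponent\tstart\tend\tn_snps\tvariance",
       ((w.chrom, w.component, w.start, w.end, w.n_snps,
         "NA" if w.value is None else f"{w.value:.6g}")
        for w in result.windows))
    _w(out / "scan_regions.tsv", "chrom\tcomponent\tstart\tend\tpeak_value\tn_windows",
       ((r.chrom, r.component, r.start, r.end, f"{r.peak_value:.6g}",
         r.n_windows) for r in result.regions))
    _w(out / "karyotype_calls.tsv",
       "sample\tinversion_id\tgenotype\tm_AA\tm_AB\tm_BB\tmds1",
       ((c.sample_id, c.inversion_id, c.genotype,
         f"{c.memberships[0]:.6f}", f"{c.memberships[1]:.6f}",
         f"{c.memberships[2]:.6f}", f"{c.mds1:.6g}")
        for inv in result.inversions for c in inv.calls))
    _w(out / "karyotype_summary.tsv",
       "inversion_id\tn_AA\tn_AB\tn_BB\tinv_maf\tF\tretained\treason",
       ((inv.inversion_id, *inv.counts, f"{inv.inv_maf:.6f}",
         f"{inv.f_index:.6f}", inv.retained, inv.reason or "ok")
        for inv in result.inversions))
    _w(out / "breakpoints.tsv",
       "inversion_id\tchrom\tcomponent\tstart\tend\tlength\tn_significant",
       ((inv.inversion_id, inv.chrom, inv.component, est.start, est.end,
         est.end - est.start, est.n_significant)
        for inv in result.retained()
        for est in ([result.coordinates[inv.inversion_id]]
                    if inv.inversion_id in result.coordinates else [])))
    _w(out / "ld_windows.tsv", "chrom\tstart\tend\tn_pairs\tmedian_r2",
       ((w.chrom, w.start, w.end, w.n_snps,
         "NA" if w.value is None else f"{w.value:.6g}")
        for ws in result.ld_windows.values() for w in ws))
    _w(out / "ld_correlations.tsv", "chrom\tcomponent\trho\tp\tn_windows",
       ((c.chrom, c.component, f"{c.rho:.6f}", f"{c.p_value:.4g}",
         c.n_windows) for c in result.ld_correlations))
    _w(out / "inversion_pairs.tsv",
       "inv_a\tinv_b\tn_shared\trho\tp_raw\tp_fdr\tchi2\tchi2_p\tsignificant",
       ((p.inversion_a, p.inversion_b, p.n_shared, f"{p.rho:.6f}",
         f"{p.p_raw:.4g}", f"{p.p_fdr:.4g}", f"{p.chi2:.6g}",
         f"{p.chi2_p:.4g}", p.significant) for p in result.pair_results))
    # consolidated report: one row per retained inversion
    _w(out / "inversions_report.tsv",
       "chrom\tcomponent\tinversion_id\tstart\tend\tlength\t"
       "inv_maf\tF\tn_AA\tn_AB\tn_BB",
       ((inv.chrom, inv.component, inv.inversion_id,
         *( (est.start, est.end, est.end - est.start)
            if (est := result.coordinates.get(inv.inversion_id)) else
            ("NA", "NA", "NA")),
         f"{inv.inv_maf:.6f}", f"{inv.f_index:.6f}", *inv.counts)
        for inv in result.retained()))

    manifest = {
        "invscan_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "stages": {
            "filter": result.filter_report.stages,
            "n_snps_final": result.gm.n_snps,
            "n_samples_final": result.gm.n_samples,
            "n_candidate_regions": len(result.regions),
            "n_inversions_called": len(result.inversions),
            "n_inversions_retained": len(result.retained()),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_all(config: dict, out_dir: str | Path) -> PipelineResult:
    """Load input per config, run every stage, write outputs; returns the
    in-memory result as well."""
    seed = int(config.get("seed", 0))
    gm, chrom_table, truth = _load_input(config)
    result = run_pipeline(gm, chrom_table, config, seed=seed, truth=truth)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if truth is not None:
        write_truth(truth, out / "truth_karyotypes.tsv",
                    out / "truth_inversions.tsv")
        write_vcf(result.gm, str(out / "pruned.vcf"), chrom_table)
    write_outputs(result, out, config, seed)
    return result
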