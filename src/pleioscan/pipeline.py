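"""End-to-end orchestration: simulate -> scan -> classify -> annotate -> infer.

Thin glue over the analysis modules so the command-line interface, the test
suite and reproduction scripts all run the identical code path. The central
product is the per-window annotation table (trait count, mean PVE, mean
connectivity, gene count, recombination rate, dS) aligned with the
parallelism calls on one shared window grid, fed to the permutation and
rank-association engine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, fst, inference, parallelism, qtl, simulate, tracks
from .grid import WindowGrid
from .simulate import GenotypeDataset, SimConfig

__all__ = [
    "scan_dataset",
    "scan_counts_frame",
    "annotate_windows",
    "analyze",
    "end_to_end",
]

log = logging.getLogger(__name__)


def scan_dataset(
    dataset: GenotypeDataset, grid: WindowGrid, min_sites: int = 3
) -> pd.DataFrame:
    """Window F_ST matrix (windows x pairs) from an in-memory dataset."""
    cols = {}
    for i, pair in enumerate(dataset.pairs):
        a, bc, variable = fst.wc_components(
            dataset.counts[i, :, 0, :], dataset.counts[i, :, 1, :]
        )
        sites = pd.DataFrame(
            {"chrom": dataset.chrom, "pos": dataset.pos, "a": a, "bc": bc,
             "variable": variable}
        )
        wf = fst.window_fst(sites, grid, min_sites=min_sites)
        cols[pair] = wf["fst"].to_numpy()
        log.info(
            "pair %s: genome-wide mean F_ST %.4f over %d windows",
            pair, np.nanmean(cols[pair]), int(np.isfinite(cols[pair]).sum()),
        )
    return pd.DataFrame(cols, index=grid.windows.index)


def scan_counts_frame(
    counts: pd.DataFrame, grid: WindowGrid, min_sites: int = 3
) -> pd.DataFrame:
    """Window F_ST matrix from a tidy genotype-count table (all pairs)."""
    cols = {}
    for pair, sub in counts.groupby("pair", sort=True):
        wf = fst.scan_pair(sub, grid, min_sites=min_sites)
        cols[pair] = wf["fst"].to_numpy()
    return pd.DataFrame(cols, index=grid.windows.index)


def annotate_windows(
    grid: WindowGrid,
    qtl_records: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    expression_genes: pd.DataFrame | None = None,
    track_genes: pd.DataFrame | None = None,
    gmap: pd.DataFrame | None = None,
    ds_path=None,
    soft_power: int | None = None,
    zero_as_missing: bool = True,
) -> pd.DataFrame:
    """Build the merged per-window annotation table from available inputs.

    Any input left as None simply yields missing columns; the contrast
    engine skips metrics without data.
    """
    ann = pd.DataFrame(index=grid.windows.index)
    for col in inference.METRIC_COLUMNS:
        ann[col] = np.nan

    if qtl_records is not None:
        q = qtl.curate_and_assign(qtl_records, grid, zero_as_missing=zero_as_missing)
        ann["trait_count"] = q["trait_count"]
        ann["mean_pve"] = q["mean_pve"]

    if expression is not None:
        logm = coexpression.preprocess_expression(expression)
        if soft_power is None:
            diag = coexpression.select_soft_power(
                logm, powers=(1, 2, 4, 6, 8, 10, 12)
            )
            beta = diag.beta
            log.info("selected soft power %d", beta)
        else:
            beta = soft_power
        k = coexpression.total_connectivity(logm, beta)
        ann["mean_connectivity"] = coexpression.window_connectivity(
            k, expression_genes, grid
        )

    if track_genes is not None:
        ann["gene_count"] = tracks.gene_density(track_genes, grid)
    if gmap is not None:
        ann["recomb_cm_per_mbp"] = tracks.recombination_rate(gmap, grid)
    if ds_path is not None:
        ann["ds"] = tracks.load_ds_track(ds_path, grid)
    return ann


def analyze(
    fst_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    outlier_quantile: float = 0.95,
    min_pairs: int = 2,
    n_iter: int = 10_000,
    seed: int | None = None,
    restrict: str | None = None,
) -> dict:
    """Classify windows and run every class contrast and rank association."""
    flags = parallelism.call_outliers(fst_matrix, quantile=outlier_quantile)
    calls = parallelism.classify_parallel(flags, min_pairs=min_pairs)
    rank = parallelism.mean_rank(fst_matrix)
    report = inference.run_contrasts(
        annotation, calls, mean_fst_rank=rank, n_iter=n_iter, seed=seed,
        restrict=restrict,
    )
    return {"calls": calls, "mean_fst_rank": rank, "report": report}


def end_to_end(
    config: SimConfig,
    n_iter: int = 10_000,
    seed: int | None = None,
    soft_power: int | None = 6,
    min_sites: int = 3,
    outlier_quantile: float = 0.95,
    min_pairs: int = 2,
    with_tracks: bool = True,
) -> dict:
    """Simulate a full study and run the complete analysis on it.

    Returns truth table, F_ST matrix, calls, annotation and the contrast
    report. ``seed`` controls the permutation stream only; the generator is
    driven by ``config.seed``.
    """
    truth = simulate.make_truth(config)
    grid = config.grid()
    dataset = simulate.simulate_genotypes(truth, config)
    fst_matrix = scan_dataset(dataset, grid, min_sites=min_sites)

    qtl_records = simulate.simulate_qtl_table(truth, config)
    expr, genes = simulate.simulate_expression(truth, config)
    if with_tracks:
        gmap, ds_frame, track_genes = simulate.simulate_tracks(truth, config)
    else:
        gmap = ds_frame = track_genes = None

    ann = pd.DataFrame(index=grid.windows.index)
    for col in inference.METRIC_COLUMNS:
        ann[col] = np.nan
    q = qtl.curate_and_assign(qtl_records, grid)
    ann["trait_count"] = q["trait_count"]
    ann["mean_pve"] = q["mean_pve"]
    logm = coexpression.preprocess_expression(expr)
    beta = soft_power
    if beta is None:
        beta = coexpression.select_soft_power(
            logm, powers=(1, 2, 4, 6, 8, 10, 12)
        ).beta
    k = coexpression.total_connectivity(logm, beta)
    ann["mean_connectivity"] = coexpression.window_connectivity(k, genes, grid)
    if with_tracks:
        ann["gene_count"] = tracks.gene_density(track_genes, grid)
        ann["recomb_cm_per_mbp"] = tracks.recombination_rate(gmap, grid)
        ds = ds_frame.set_index(
            grid.windows.index
        )["ds"]
        ann["ds"] = ds

    result = analyze(
        fst_matrix, ann, outlier_quantile=outlier_quantile,
        min_pairs=min_pairs, n_iter=n_iter, seed=seed,
    )
    result.update(
        truth=truth, grid=grid, fst_matrix=fst_matrix, annotation=ann,
        soft_power=beta,
    )
    return result


def write_report(result: dict, outdir, config: SimConfig | None = None) -> None:
    """Serialize an analysis result to JSON + TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = inference.report_to_frame(result["report"])
    frame.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    payload = {"metrics": json.loads(frame.to_json(orient="records"))}
    if config is not None:
        payload["config"] = asdict(config)
    if "soft_power" in result:
        payload["soft_power"] = result["soft_power"]
    from . import __version__

    payload["version"] = __version__
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
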