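"""Synthetic study generator: replicate ecotype pairs with known ground truth.

Emulates the statistical structure the scan-and-contrast pipeline assumes —
replicate population pairs genotyped at sparse SNPs, a QTL table, an
expression matrix, gene annotation and covariate tracks — with elevated
divergence, trait counts and coexpression connectivity implanted into a
known set of "parallel" windows so that parameter-recovery tests can compare
pipeline output against the truth table.

Divergence uses the Balding–Nichols model: each population's allele
frequency at a SNP is drawn from Beta(p0(1-F)/F, (1-p0)(1-F)/F) around an
ancestral frequency p0, with F = ``F_selected`` for the (window, pair)
combinations the truth table flags and ``F_background`` elsewhere. Only the
marginal F_ST structure matters to a window scan, so this is the simplest
model with a tunable F_ST expectation — no linkage or demography is
simulated.

One master seed drives everything; each component (truth, genotypes, QTL,
expression, tracks) gets its own child stream at a fixed offset so
components can be regenerated independently and fixture files are
byte-identical for a fixed (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import WindowGrid

__all__ = [
    "SimConfig",
    "make_truth",
    "simulate_genotypes",
    "simulate_qtl_table",
    "simulate_expression",
    "simulate_tracks",
    "GenotypeDataset",
]

CLASS_PARALLEL = "parallel"
CLASS_SINGLE = "single_pair_outlier"
CLASS_BACKGROUND = "background"

# fixed spawn-key offsets of the per-component random streams
_STREAM = {"truth": 0, "genotypes": 1, "qtl": 2, "expression": 3, "tracks": 4}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the conditions of the stream–lake survey the pipeline
    targets: 16 replicate pairs of 24 diploids per population scanned in
    50-kb windows (5 chromosomes x 25 Mb = 2,500 windows), ~34% of windows
    carrying QTL with a nonparallel mean of 1.5 mapped traits and a 2-fold
    elevation in parallel windows, gene density 3.1 per window, and a
    coexpression network whose parallel-window genes carry loadings raised
    enough for a 1.2-fold connectivity elevation.
    """

    n_pairs: int = 16
    n_diploids_per_population: int = 24
    n_chromosomes: int = 5
    chromosome_length: int = 25_000_000
    window_size: int = 50_000
    snps_per_window: int = 5
    F_background: float = 0.05
    F_selected: float = 0.5
    prop_parallel: float = 0.12
    prop_single: float = 0.05
    parallel_pairs_min: int = 2
    parallel_pairs_max: int = 4
    qtl_window_prob: float = 0.34
    lambda_base: float = 0.5
    pleiotropy_effect: float = 2.0
    pve_median: float = 9.0
    pve_sigma: float = 0.5
    duplicate_qtl_frac: float = 0.10
    n_genes: int = 7_750
    n_samples: int = 100
    n_modules: int = 75
    loading_low: float = 0.55
    loading_high: float = 0.75
    hub_effect: float = 0.026
    genes_per_window_mean: float = 3.1
    marker_spacing: int = 250_000
    recomb_shape: float = 4.0
    recomb_mean_cm_per_mbp: float = 4.0
    ds_mean: float = 0.92
    ds_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.F_background < 1 or not 0 < self.F_selected < 1:
            raise ValueError("fixation indices must lie in (0, 1)")
        if self.prop_parallel + self.prop_single > 1:
            raise ValueError("prop_parallel + prop_single must not exceed 1")
        if self.chromosome_length % self.window_size:
            raise ValueError("window_size must divide chromosome_length")
        if self.parallel_pairs_min < 2:
            raise ValueError("parallel windows need >= 2 selected pairs")
        if not 0 <= self.hub_effect < 1:
            raise ValueError("hub_effect must lie in [0, 1)")
        if self.loading_high + self.hub_effect >= 1:
            raise ValueError("hub_effect pushes a loading to >= 1")
        if self.pleiotropy_effect < 1:
            raise ValueError("pleiotropy_effect must be >= 1")

    @property
    def n_windows(self) -> int:
        return self.n_chromosomes * (self.chromosome_length // self.window_size)

    @property
    def pair_ids(self) -> list[str]:
        return [f"pair{i + 1:02d}" for i in range(self.n_pairs)]

    def grid(self) -> WindowGrid:
        sizes = {
            f"chr{c + 1}": self.chromosome_length
            for c in range(self.n_chromosomes)
        }
        return WindowGrid.from_chrom_sizes(sizes, self.window_size)

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAM[component],))
        )


def _lambda_parallel(config: SimConfig) -> float:
    # chosen so class means of 1 + Poisson(lambda) scale by pleiotropy_effect
    return config.pleiotropy_effect * (1 + config.lambda_base) - 1


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Assign every window a class and, if selected, its diverging pairs.

    Returns a frame indexed by window id with ``true_class``,
    ``selected_pairs`` (tuple of pair ids), ``implanted_trait_rate`` (the
    expected trait count of a QTL-bearing window of that class) and
    ``implanted_hub_weight`` (the extra factor loading of its genes).
    """
    rng = config.rng("truth")
    w = config.n_windows
    n_par = round(config.prop_parallel * w)
    n_single = round(config.prop_single * w)
    order = rng.permutation(w)
    classes = np.full(w, CLASS_BACKGROUND, dtype=object)
    classes[order[:n_par]] = CLASS_PARALLEL
    classes[order[n_par:n_par + n_single]] = CLASS_SINGLE

    pair_ids = np.array(config.pair_ids, dtype=object)
    selected: list[tuple[str, ...]] = []
    kmax = min(config.parallel_pairs_max, config.n_pairs)
    kmin = min(config.parallel_pairs_min, kmax)
    for cls in classes:
        if cls == CLASS_PARALLEL:
            k = int(rng.integers(kmin, kmax + 1))
        elif cls == CLASS_SINGLE:
            k = 1
        else:
            selected.append(())
            continue
        selected.append(tuple(sorted(rng.choice(pair_ids, size=k, replace=False))))

    lam_par = _lambda_parallel(config)
    rate = np.where(classes == CLASS_PARALLEL, 1 + lam_par, 1 + config.lambda_base)
    hub = np.where(classes == CLASS_PARALLEL, config.hub_effect, 0.0)
    return pd.DataFrame(
        {
            "true_class": classes,
            "selected_pairs": selected,
            "implanted_trait_rate": rate,
            "implanted_hub_weight": hub,
        },
        index=pd.RangeIndex(w, name="window_id"),
    )


@dataclass(frozen=True)
class GenotypeDataset:
    """Diploid genotype counts for every pair at shared SNP positions.

    ``counts[i, s, p]`` holds (nAA, nAa, naa) for pair i, site s, population
    p in {0: popA, 1: popB}.
    """

    chrom: np.ndarray
    pos: np.ndarray
    pairs: list[str]
    counts: np.ndarray  # (n_pairs, n_sites, 2, 3) int

    POPS = ("popA", "popB")

    def to_frame(self) -> pd.DataFrame:
        """Tidy counts table (chrom, pos, pair, pop, nAA, nAa, naa)."""
        n_sites = self.pos.size
        frames = []
        for i, pair in enumerate(self.pairs):
            for p, pop in enumerate(self.POPS):
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": self.chrom,
                            "pos": self.pos,
                            "pair": pair,
                            "pop": pop,
                            "nAA": self.counts[i, :, p, 0],
                            "nAa": self.counts[i, :, p, 1],
                            "naa": self.counts[i, :, p, 2],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)

    def write_counts_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_vcf(self, directory) -> list[Path]:
        """One uncompressed VCF per pair; samples are popA_i01... popB_i01...

        Counts are expanded to individuals in deterministic block order
        (homozygous reference first); individuals are exchangeable so the
        assignment is arbitrary.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        chrom_order = list(dict.fromkeys(self.chrom.tolist()))
        paths = []
        for i, pair in enumerate(self.pairs):
            n = int(self.counts[i, 0, 0].sum())
            samples = [
                f"{pop}_i{j + 1:02d}" for pop in self.POPS for j in range(n)
            ]
            path = directory / f"{pair}.vcf"
            with open(path, "w") as fh:
                fh.write("##fileformat=VCFv4.2\n")
                for c in chrom_order:
                    fh.write(f"##contig=<ID={c}>\n")
                fh.write(
                    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
                )
                fh.write(
                    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                    + "\t".join(samples) + "\n"
                )
                for s in range(self.pos.size):
                    gts = []
                    for p in range(2):
                        naa, nhet, nalt = self.counts[i, s, p]
                        gts.extend(["0/0"] * naa + ["0/1"] * nhet + ["1/1"] * nalt)
                    fh.write(
                        f"{self.chrom[s]}\t{self.pos[s] + 1}\t.\tA\tT\t.\tPASS"
                        f"\t.\tGT\t" + "\t".join(gts) + "\n"
                    )
            paths.append(path)
        return paths


def simulate_genotypes(truth: pd.DataFrame, config: SimConfig) -> GenotypeDataset:
    """Draw genotype counts for every pair under the Balding–Nichols model.

    Per SNP and pair, an ancestral frequency p0 ~ Uniform(0.05, 0.95) is
    drawn; each population's frequency comes from the Balding–Nichols Beta
    with F = ``F_selected`` where (window, pair) is flagged in the truth
    table and ``F_background`` otherwise; genotype counts then follow
    Hardy–Weinberg sampling of the population's diploids (the multinomial
    equivalent of Binomial(2, p) per individual).
    """
    if len(truth) != config.n_windows:
        raise ValueError("truth table does not match config window count")
    rng = config.rng("genotypes")
    grid = config.grid()
    n_sites = config.n_windows * config.snps_per_window

    # sorted distinct positions per window
    offsets = np.sort(
        rng.integers(0, config.window_size, size=(config.n_windows,
                                                  config.snps_per_window)),
        axis=1,
    )
    starts = grid.windows["start"].to_numpy()
    pos = (starts[:, None] + offsets).ravel()
    chrom = np.repeat(grid.windows["chrom"].to_numpy(), config.snps_per_window)

    # F per (pair, window) from the truth table
    pair_index = {p: i for i, p in enumerate(config.pair_ids)}
    F_pw = np.full((config.n_pairs, config.n_windows), config.F_background)
    for w, sel in enumerate(truth["selected_pairs"]):
        for p in sel:
            F_pw[pair_index[p], w] = config.F_selected
    F = np.repeat(F_pw, config.snps_per_window, axis=1)  # (n_pairs, n_sites)

    p0 = rng.uniform(0.05, 0.95, size=(config.n_pairs, n_sites))
    shape_a = p0 * (1 - F) / F
    shape_b = (1 - p0) * (1 - F) / F
    freq = rng.beta(shape_a[..., None], shape_b[..., None],
                    size=(config.n_pairs, n_sites, 2))
    pvals = np.stack(
        [freq**2, 2 * freq * (1 - freq), (1 - freq) ** 2], axis=-1
    )
    pvals /= pvals.sum(axis=-1, keepdims=True)
    counts = rng.multinomial(config.n_diploids_per_population, pvals)
    return GenotypeDataset(
        chrom=chrom, pos=pos.astype(np.int64), pairs=config.pair_ids,
        counts=counts,
    )


def simulate_qtl_table(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate a QTL table with elevated trait counts in parallel windows.

    Each window carries QTL with probability ``qtl_window_prob``; a
    QTL-bearing window receives 1 + Poisson(lambda) distinct traits with
    lambda elevated in parallel windows so class means scale by
    ``pleiotropy_effect``. PVE is log-normal with median ``pve_median``
    percent; each trait's confidence interval is contained in its window. A
    ``duplicate_qtl_frac`` fraction of records is duplicated (same trait,
    same window, different PVE) to exercise downstream curation.
    """
    rng = config.rng("qtl")
    grid = config.grid()
    lam_par = _lambda_parallel(config)
    categories = np.array(
        ["behaviour/sensory", "body shape", "body size", "defensive armour",
         "feeding morphology", "pigmentation", "respiration", "swimming"],
        dtype=object,
    )
    rows = []
    bearing = rng.random(config.n_windows) < config.qtl_window_prob
    for w in np.flatnonzero(bearing):
        lam = lam_par if truth.loc[w, "true_class"] == CLASS_PARALLEL else (
            config.lambda_base
        )
        n_traits = 1 + rng.poisson(lam)
        win = grid.windows.iloc[w]
        for t in range(n_traits):
            lo = int(rng.integers(win["start"], win["end"] - 1))
            hi = int(rng.integers(lo, win["end"]))
            pve = float(
                np.exp(rng.normal(math.log(config.pve_median), config.pve_sigma))
            )
            rows.append(
                {
                    "trait": f"trait_w{w}_{t}",
                    "category": rng.choice(categories),
                    "chrom": win["chrom"],
                    "ci_start": lo,
                    "ci_end": hi,
                    "flank_start": np.nan,
                    "flank_end": np.nan,
                    "pve": pve,
                    "study": "sim_study_1",
                    "cross": "sim_cross_1",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["trait", "category", "chrom", "ci_start", "ci_end",
                 "flank_start", "flank_end", "pve", "study", "cross"],
    )
    if len(df) and config.duplicate_qtl_frac > 0:
        n_dup = int(round(config.duplicate_qtl_frac * len(df)))
        if n_dup:
            dup = df.iloc[
                rng.choice(len(df), size=n_dup, replace=False)
            ].copy()
            dup["pve"] = np.exp(
                rng.normal(math.log(config.pve_median), config.pve_sigma, n_dup)
            )
            dup["study"] = "sim_study_2"
            df = pd.concat([df, dup], ignore_index=True)
    return df


def simulate_expression(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Modular expression with raised loadings for genes in parallel windows.

    Each gene belongs to one latent module; its log-scale expression is
    ``w_g * ME_m + sqrt(1 - w_g^2) * eps`` (factor and noise standard
    normal), with the loading ``w_g`` drawn uniformly from
    [loading_low, loading_high] plus ``hub_effect`` for genes whose window
    is parallel. Values are shifted by a per-gene baseline and exponentiated
    onto an FPKM-like positive scale, so log2(x + 1) preprocessing recovers
    the latent scale.

    Returns (FPKM genes x samples, gene annotation with chrom/start/end).
    """
    if config.n_samples < 10:
        raise ValueError("correlation estimation needs >= 10 samples")
    rng = config.rng("expression")
    grid = config.grid()
    G, S = config.n_genes, config.n_samples

    chrom_ids = grid.chroms
    gchrom = np.array(chrom_ids, dtype=object)[
        rng.integers(0, len(chrom_ids), size=G)
    ]
    gmid = rng.integers(1_000, config.chromosome_length - 1_000, size=G)
    widx = grid.locate(gchrom, gmid)
    parallel_windows = set(
        truth.index[truth["true_class"] == CLASS_PARALLEL]
    )
    in_parallel = np.array([w in parallel_windows for w in widx])

    module = rng.integers(0, config.n_modules, size=G)
    w = rng.uniform(config.loading_low, config.loading_high, size=G)
    w = w + np.where(in_parallel, config.hub_effect, 0.0)
    if np.any(w >= 1):
        raise ValueError("hub_effect pushed a loading to >= 1")

    me = rng.standard_normal((config.n_modules, S))
    eps = rng.standard_normal((G, S))
    z = w[:, None] * me[module] + np.sqrt(1 - w**2)[:, None] * eps
    baseline = rng.uniform(2.0, 8.0, size=G)
    fpkm = np.maximum(2.0 ** (z + baseline[:, None]) - 1.0, 0.0)

    gene_ids = [f"gene{g + 1:05d}" for g in range(G)]
    samples = [f"sample{s + 1:03d}" for s in range(S)]
    expr = pd.DataFrame(fpkm, index=gene_ids, columns=samples)
    genes = pd.DataFrame(
        {
            "chrom": gchrom,
            "start": gmid - 1_000,
            "end": gmid + 1_000,
        },
        index=pd.Index(gene_ids, name="name"),
    )
    return expr, genes


def simulate_tracks(
    truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genetic map, per-window dS track, and a gene annotation for density.

    The map places markers every ``marker_spacing`` bp with per-interval
    recombination rates Gamma-distributed around
    ``recomb_mean_cm_per_mbp``; cM positions are the cumulative sum, hence
    monotone. dS per window is Normal(ds_mean, ds_sd) truncated to (0, 2).
    Gene counts per window are Poisson(``genes_per_window_mean``) with
    uniform positions inside the window.

    Returns (map frame ``chrom, bp, cM``, dS frame ``chrom, window_start,
    ds``, gene annotation frame).
    """
    rng = config.rng("tracks")
    grid = config.grid()

    map_rows = []
    for chrom in grid.chroms:
        length = grid.chrom_length(chrom)
        bps = np.arange(0, length + 1, config.marker_spacing)
        if bps[-1] != length:
            bps = np.append(bps, length)
        scale = config.recomb_mean_cm_per_mbp / config.recomb_shape
        rates = rng.gamma(config.recomb_shape, scale, size=len(bps) - 1)
        cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(bps) / 1e6)])
        map_rows.append(pd.DataFrame({"chrom": chrom, "bp": bps, "cM": cm}))
    gmap = pd.concat(map_rows, ignore_index=True)

    ds = rng.normal(config.ds_mean, config.ds_sd, size=grid.n_windows)
    bad = (ds <= 0) | (ds >= 2)
    while bad.any():  # truncation by redraw
        ds[bad] = rng.normal(config.ds_mean, config.ds_sd, size=int(bad.sum()))
        bad = (ds <= 0) | (ds >= 2)
    ds_frame = pd.DataFrame(
        {
            "chrom": grid.windows["chrom"],
            "window_start": grid.windows["start"],
            "ds": ds,
        }
    )

    counts = rng.poisson(config.genes_per_window_mean, size=grid.n_windows)
    rows = []
    gid = 0
    for w, c in enumerate(counts):
        win = grid.windows.iloc[w]
        for _ in range(c):
            mid = int(rng.integers(win["start"], win["end"]))
            half = min(500, mid - 0, grid.chrom_length(win["chrom"]) - mid)
            rows.append(
                (win["chrom"], max(mid - half, 0), mid + half, f"cds{gid:06d}")
            )
            gid += 1
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    genes = genes.set_index("name")
    return gmap, ds_frame, genes


def null_config(config: SimConfig) -> SimConfig:
    """A copy of ``config`` with every implanted effect switched off."""
    return replace(
        config,
        F_selected=config.F_background,
        pleiotropy_effect=1.0,
        hub_effect=0.0,
    )


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["selected_pairs"] = out["selected_pairs"].map(",".join)
    out.to_csv(path, sep="\t")


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="window_id")
    df["selected_pairs"] = df["selected_pairs"].fillna("").map(
        lambda s: tuple(s.split(",")) if s else ()
    )
    return df
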