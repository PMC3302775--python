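"""Genome-wide linkage disequilibrium: pairwise r² and D', distance-class
summaries, the P95 background threshold, decay-model fitting and
marker-density estimation, and the sample-composition experiments.

Accessions are haploid-coded, so two-locus haplotype frequencies are
observed directly (complete-case counting over accessions non-missing at
both markers; no phase estimation is needed).  Marker pairs on different
chromosomes estimate the background LD generated by population structure
alone; the 95th percentile of their r² (P95) is the threshold above
which LD at linked pairs is considered significant.

Decay with physical distance d follows the drift model
E(r²) = 1 / (1 + 4*a*d) with the composite parameter a = Ne*rho
(effective population size times per-bp recombination rate); inverting
it at a target r² gives the decay distance, and genome size divided by
that distance gives the marker count needed for association scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import BiallelicGenotypeMatrix, MarkerMap
from .diversity import dissimilarity_matrix
from .tree import mlst_subset

__all__ = [
    "pairwise_ld",
    "p95_threshold",
    "bin_ld_summary",
    "fit_ld_decay",
    "LDDecayFit",
    "LDFitError",
    "markers_required",
    "MarkerRequirement",
    "sampling_experiment",
    "SamplingExperimentResult",
    "DISTANCE_BINS",
]

#: Right edges of the distance classes (bp); bins are (left, right].
DISTANCE_BINS = [
    (0, 10_000, "0-10 kb"),
    (10_000, 50_000, "10-50 kb"),
    (50_000, 100_000, "50-100 kb"),
    (100_000, 1_000_000, "100 kb-1 Mb"),
    (1_000_000, 10_000_000, "1 Mb-10 Mb"),
    (10_000_000, 100_000_000, "10 Mb-100 Mb"),
]


def pairwise_ld(
    gm: BiallelicGenotypeMatrix,
    marker_map: MarkerMap,
    require_filtered: bool = True,
) -> pd.DataFrame:
    """All-pairs r² and D' over mapped markers.

    Returns a DataFrame with one row per retained pair: marker ids,
    chromosomes, ``same_chromosome``, ``dist_bp`` (NaN for
    inter-chromosomal pairs), ``n_obs`` complete observations, ``r2``
    and ``dprime``.  Pairs monomorphic in their complete-case subset are
    skipped; the count is stored in ``df.attrs["n_skipped"]``.

    ``require_filtered`` asserts the standard pre-filter (MAF >= 0.05,
    missing fraction < 0.2); pass False for subset re-analyses where
    frequencies may drift below the thresholds.
    """
    chrom_of = marker_map.chromosome_of()
    pos_of = marker_map.position_of()
    mapped = [m for m in gm.marker_ids if m in chrom_of]
    if len(mapped) < gm.n_markers:
        warnings.warn(
            f"{gm.n_markers - len(mapped)} markers missing from the map were dropped",
            stacklevel=2,
        )
    gm = gm.subset_markers(mapped) if len(mapped) < gm.n_markers else gm
    if require_filtered:
        if (gm.maf() < 0.05 - 1e-12).any() or (gm.missing_fraction() >= 0.2).any():
            raise ValueError(
                "genotype matrix must be pre-filtered (MAF >= 0.05, missing < 0.2); "
                "call filter_markers first or pass require_filtered=False"
            )

    X = gm.calls
    M = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)
    n_obs = M.T @ M  # complete cases per pair
    c11 = A.T @ A  # both present
    c1_ = A.T @ M  # first present, second observed
    c_1 = M.T @ A
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = c1_ / n_obs
        pB = c_1 / n_obs
        pAB = c11 / n_obs
        D = pAB - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D**2 / denom, np.nan)
        dmax = np.where(
            D > 0,
            np.minimum(pA * (1 - pB), (1 - pA) * pB),
            np.minimum(pA * pB, (1 - pA) * (1 - pB)),
        )
        dprime = np.where((denom > 0) & (dmax > 0), np.abs(D) / dmax, np.nan)
        dprime = np.where((denom > 0) & (dmax <= 0), 0.0, dprime)

    m = gm.n_markers
    iu, ju = np.triu_indices(m, k=1)
    chroms = np.array([chrom_of[mk] for mk in gm.marker_ids], dtype=object)
    pos = np.array([pos_of[mk] for mk in gm.marker_ids], dtype=np.int64)
    same = chroms[iu] == chroms[ju]
    dist = np.where(same, np.abs(pos[iu] - pos[ju]), np.nan)
    r2v = r2[iu, ju]
    ok = ~np.isnan(r2v)
    n_skipped = int((~ok).sum())
    df = pd.DataFrame(
        {
            "marker_i": np.array(gm.marker_ids, dtype=object)[iu[ok]],
            "marker_j": np.array(gm.marker_ids, dtype=object)[ju[ok]],
            "chrom_i": chroms[iu[ok]],
            "chrom_j": chroms[ju[ok]],
            "same_chromosome": same[ok],
            "dist_bp": dist[ok],
            "n_obs": n_obs[iu, ju][ok].astype(int),
            "r2": r2v[ok],
            "dprime": dprime[iu, ju][ok],
        }
    )
    df.attrs["n_skipped"] = n_skipped
    return df


def p95_threshold(ld: pd.DataFrame) -> float:
    """95th percentile (linear interpolation) of r² over
    inter-chromosomal pairs only."""
    inter = ld.loc[~ld["same_chromosome"], "r2"].to_numpy()
    if inter.size == 0:
        raise ValueError("no inter-chromosomal pairs; cannot set a background threshold")
    if inter.size < 20:
        raise ValueError(f"only {inter.size} inter-chromosomal pairs (need >= 20)")
    return float(np.percentile(inter, 95, method="linear"))


def bin_ld_summary(ld: pd.DataFrame, p95: float) -> pd.DataFrame:
    """Distance-class summary: pair count, mean and SD of r², and the
    proportion of pairs with r² strictly greater than the P95 threshold.

    Linked bins are left-open right-closed on distance; a final
    ``interchromosomal`` row summarizes unlinked pairs.  The P95 value
    used is stored in ``out.attrs["p95"]``.
    """
    rows = []
    linked = ld[ld["same_chromosome"]]
    for lo, hi, label in DISTANCE_BINS:
        sel = linked[(linked["dist_bp"] > lo) & (linked["dist_bp"] <= hi)]
        rows.append(_bin_row(label, sel["r2"].to_numpy(), p95))
    inter = ld.loc[~ld["same_chromosome"], "r2"].to_numpy()
    rows.append(_bin_row("interchromosomal", inter, p95))
    out = pd.DataFrame(rows)
    out.attrs["p95"] = p95
    return out


def _bin_row(label: str, r2: np.ndarray, p95: float) -> dict:
    return {
        "bin": label,
        "n_pairs": int(r2.size),
        "mean_r2": float(r2.mean()) if r2.size else np.nan,
        "sd_r2": float(r2.std(ddof=1)) if r2.size > 1 else np.nan,
        "prop_significant": float((r2 > p95).mean()) if r2.size else np.nan,
    }


class LDFitError(RuntimeError):
    """Decay fit failed; carries the best grid value found."""

    def __init__(self, message: str, best_grid_a: float):
        super().__init__(f"{message} (best grid value a={best_grid_a:.3g})")
        self.best_grid_a = best_grid_a


@dataclass
class LDDecayFit:
    """Fitted composite decay parameter a = Ne*rho (per bp)."""

    a: float
    achieved_tolerance: float
    n_pairs: int

    def expected_r2(self, dist_bp: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + 4.0 * self.a * np.asarray(dist_bp, dtype=float))


def fit_ld_decay(ld: pd.DataFrame) -> LDDecayFit:
    """Nonlinear least squares of r² on 1/(1 + 4*a*d) over linked pairs.

    ``a`` is initialized by a log-spaced grid search over 1e-8..1e-2 and
    refined by Levenberg-Marquardt in log10(a) (keeping a positive).  If
    the fitted curve cannot beat the best constant fit (no distance
    dependence in the data), an :class:`LDFitError` is raised carrying
    the best grid value.
    """
    linked = ld[ld["same_chromosome"]]
    d = linked["dist_bp"].to_numpy(dtype=float)
    r2 = linked["r2"].to_numpy(dtype=float)
    if np.unique(d).size < 10:
        raise ValueError("need >= 10 linked pairs with distinct distances")

    def model(log10a):
        return 1.0 / (1.0 + 4.0 * 10.0**log10a * d)

    grid = np.linspace(-8, -2, 61)
    sse = np.array([np.sum((model(g) - r2) ** 2) for g in grid])
    best = grid[int(np.argmin(sse))]
    res = least_squares(lambda t: model(t[0]) - r2, x0=[best], method="lm")
    a = float(10.0 ** res.x[0])
    fit_sse = float(np.sum(res.fun**2))
    const_sse = float(np.sum((r2 - r2.mean()) ** 2))
    if not res.success or fit_sse >= const_sse:
        raise LDFitError(
            "decay model does not improve on a constant fit", 10.0**best
        )
    # achieved tolerance: scale of the last step's gradient, akin to an
    # nls convergence tolerance
    tol = float(np.abs(res.grad).max()) if res.grad is not None else np.nan
    return LDDecayFit(a=a, achieved_tolerance=tol, n_pairs=int(d.size))


@dataclass
class MarkerRequirement:
    """Decay distance at an r² threshold and the implied marker count."""

    r2_threshold: float
    decay_distance_bp: float
    n_markers: float
    n_markers_ceil: int


def markers_required(
    fit_a: float, r2_threshold: float, genome_size_bp: int = 736_000_000
) -> MarkerRequirement:
    """Invert E(r²)=1/(1+4*a*d) at ``r2_threshold`` and divide the genome
    size by the resulting decay distance d* = (1/r² - 1)/(4a)."""
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must be in (0, 1)")
    if fit_a <= 0:
        raise ValueError("fit_a must be positive")
    d_star = (1.0 / r2_threshold - 1.0) / (4.0 * fit_a)
    n = genome_size_bp / d_star
    return MarkerRequirement(
        r2_threshold=r2_threshold,
        decay_distance_bp=d_star,
        n_markers=n,
        n_markers_ceil=int(np.ceil(n)),
    )


@dataclass
class SamplingExperimentResult:
    """Per-size LD statistics for a sub-sampling strategy."""

    strategy: str
    per_rep: pd.DataFrame  # size, rep, p95, full-panel r2 correlation
    bin_summaries: dict[tuple[int, int], pd.DataFrame]  # (size, rep) -> summary
    full_p95: float
    full_bins: pd.DataFrame

    def p95_by_size(self) -> pd.DataFrame:
        return (
            self.per_rep.groupby("size")["p95"].agg(["mean", "std", "count"]).reset_index()
        )


def sampling_experiment(
    gm: BiallelicGenotypeMatrix,
    marker_map: MarkerMap,
    sizes: list[int],
    strategy: str = "random",
    n_reps: int = 10,
    seed: int | None = None,
    index: str = "simple_matching",
) -> SamplingExperimentResult:
    """Effect of sample composition on LD statistics.

    For each requested size, accessions are drawn either at random
    (``n_reps`` independent subsets) or with the deterministic MLST
    core-sampling procedure (one subset per size; a single MLST run down
    to the smallest size yields all larger cores since removals are
    nested).  For each subset the full pairwise r² table, the P95
    threshold, the distance-class summary and the Pearson correlation of
    the subset r² vector with the full-panel r² vector (over shared
    pairs) are computed.
    """
    if any(s > gm.n_accessions for s in sizes):
        raise ValueError("subset sizes must not exceed the panel size")
    if strategy == "mlst" and n_reps > 1:
        warnings.warn("MLST is deterministic; n_reps > 1 is redundant", stacklevel=2)
        n_reps = 1
    rng = np.random.default_rng(seed)
    full_ld = pairwise_ld(gm, marker_map, require_filtered=False)
    full_p95 = p95_threshold(full_ld)
    full_bins = bin_ld_summary(full_ld, full_p95)
    full_r2 = full_ld.set_index(["marker_i", "marker_j"])["r2"]

    if strategy == "mlst":
        diss = dissimilarity_matrix(gm, index)
        path = mlst_subset(diss, min(sizes))

    records = []
    summaries: dict[tuple[int, int], pd.DataFrame] = {}
    for size in sizes:
        for rep in range(n_reps):
            if strategy == "random":
                chosen = [
                    gm.accession_ids[i]
                    for i in rng.choice(gm.n_accessions, size=size, replace=False)
                ]
            elif strategy == "mlst":
                chosen = path.retained_at(size, list(gm.accession_ids))
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
            sub = gm.subset_accessions(chosen)
            ld = pairwise_ld(sub, marker_map, require_filtered=False)
            p95 = p95_threshold(ld)
            summaries[(size, rep)] = bin_ld_summary(ld, p95)
            sub_r2 = ld.set_index(["marker_i", "marker_j"])["r2"]
            shared = full_r2.index.intersection(sub_r2.index)
            corr = (
                float(np.corrcoef(full_r2.loc[shared], sub_r2.loc[shared])[0, 1])
                if len(shared) > 2
                else np.nan
            )
            records.append(
                {"size": size, "rep": rep, "p95": p95, "full_panel_r2_correlation": corr}
            )
    return SamplingExperimentResult(
        strategy=strategy,
        per_rep=pd.DataFrame(records),
        bin_summaries=summaries,
        full_p95=full_p95,
        full_bins=full_bins,
    )


def plot_decay(
    ld: pd.DataFrame, fit: LDDecayFit | None = None, path: str | None = None
):
    """Scatter of linked-pair r² against distance with the fitted decay
    curve overlaid; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    linked = ld[ld["same_chromosome"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(linked["dist_bp"], linked["r2"], s=4, alpha=0.3, label="marker pairs")
    if fit is not None:
        grid = np.logspace(
            np.log10(max(linked["dist_bp"].min(), 1)), np.log10(linked["dist_bp"].max()), 200
        )
        ax.plot(grid, fit.expected_r2(grid), "r-", label=f"1/(1+4ad), a={fit.a:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("distance (bp)")
    ax.set_ylabel("r²")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
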