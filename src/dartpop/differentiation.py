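"""Weir-Cockerham differentiation and island-model Fst-outlier scanning.

Theta (the Weir-Cockerham Fst estimator) is computed from allele-frequency
variance components for haploid-coded samples: with r groups of sizes n_i
and allele frequencies p_i at a locus,

    p_bar = sum n_i p_i / sum n_i
    MSP   = sum n_i (p_i - p_bar)^2 / (r - 1)
    MSG   = sum n_i p_i (1 - p_i) / sum (n_i - 1)
    n_c   = (sum n_i - sum n_i^2 / sum n_i) / (r - 1)
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

Multi-locus (and pairwise-group) estimates are ratios of numerator and
denominator components summed over loci, and over alleles for
multi-allelic input.  Significance comes from permuting group labels
over accessions.

The outlier scan builds a neutral envelope in the spirit of the
FDIST/island-model approach: loci are simulated under a
Balding-Nichols/binomial island model calibrated (by bisection on the
divergence parameter) so that the mean simulated theta matches the
trimmed mean of the observed per-locus thetas; loci are then classified
against He-conditional quantiles of the simulated (He, theta) cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .core import (
    UNASSIGNED,
    BiallelicGenotypeMatrix,
    GroupAssignment,
    MultiAllelicGenotypeMatrix,
)

__all__ = [
    "FstResult",
    "wc_fst",
    "fst_permutation_test",
    "NeutralEnvelope",
    "simulate_neutral_envelope",
    "OutlierCall",
    "classify_outliers",
]


def _theta_components(n: np.ndarray, p: np.ndarray):
    """Per-locus numerator/denominator of haploid Weir-Cockerham theta.

    ``n`` and ``p`` are (r groups x L loci); groups absent at a locus
    carry n = 0 and are excluded there.  Returns (num, den, valid) with
    valid False where theta is undefined (fewer than 2 groups with data,
    no within-group degrees of freedom, or locus monomorphic overall).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    present = n >= 1
    r = present.sum(axis=0)
    n_tot = np.where(present, n, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = np.where(present, n * p, 0.0).sum(axis=0) / n_tot
        msp = np.where(present, n * (p - p_bar) ** 2, 0.0).sum(axis=0) / (r - 1)
        df_within = np.where(present, n - 1, 0.0).sum(axis=0)
        msg = np.where(present, n * p * (1 - p), 0.0).sum(axis=0) / df_within
        n_c = (n_tot - np.where(present, n**2, 0.0).sum(axis=0) / n_tot) / (r - 1)
        num = msp - msg
        den = msp + (n_c - 1) * msg
    polymorphic = (p_bar > 0) & (p_bar < 1)
    valid = (r >= 2) & (df_within > 0) & polymorphic & np.isfinite(den)
    return num, den, valid, p_bar


def _group_freq_tables(gm, members: dict[int, list[str]]):
    """Per-group non-missing counts and allele frequencies.

    Bi-allelic input yields one (n, p) layer; multi-allelic input yields
    one layer per allele label (variance components are later summed
    over layers).
    """
    if isinstance(gm, BiallelicGenotypeMatrix):
        n = np.empty((len(members), gm.n_markers))
        p = np.empty((len(members), gm.n_markers))
        for gi, (g, ids) in enumerate(members.items()):
            sub = gm.subset_accessions(ids).calls
            n[gi] = (~np.isnan(sub)).sum(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p[gi] = np.nanmean(sub, axis=0)
        return [(n, np.nan_to_num(p))]
    # multi-allelic: indicator layer per allele
    layers = []
    alle = gm.alleles
    index = {a: i for i, a in enumerate(gm.accession_ids)}
    rows_by_group = {g: [index[a] for a in ids] for g, ids in members.items()}
    all_labels = sorted(
        {str(a) for a in alle.ravel() if a is not None}
    )
    obs = ~np.equal(alle, None)
    n = np.empty((len(members), gm.n_loci))
    for gi, (g, ids) in enumerate(members.items()):
        n[gi] = obs[rows_by_group[g]].sum(axis=0)
    for lab in all_labels:
        ind = (alle == lab).astype(float)
        p = np.empty((len(members), gm.n_loci))
        for gi, (g, ids) in enumerate(members.items()):
            rows = rows_by_group[g]
            with np.errstate(divide="ignore", invalid="ignore"):
                p[gi] = ind[rows].sum(axis=0) / n[gi]
        layers.append((n, np.nan_to_num(p)))
    return layers


@dataclass
class FstResult:
    """Global, per-locus and pairwise-group Weir-Cockerham theta."""

    marker_ids: list[str]
    per_locus_theta: np.ndarray  # NaN where undefined
    per_locus_he: np.ndarray  # pooled expected heterozygosity
    global_theta: float
    pairwise: pd.DataFrame  # symmetric group x group matrix
    group_sizes: dict[int, int]
    n_loci_used: int


def _ratio_of_sums(num, den, valid) -> float:
    if not valid.any():
        return float("nan")
    return float(num[valid].sum() / den[valid].sum())


def wc_fst(
    gm,
    groups: GroupAssignment,
    unassigned_policy: str = "exclude",
) -> FstResult:
    """Weir-Cockerham theta at the global, per-locus and pairwise level.

    Unassigned accessions are excluded (the only supported policy).
    Loci monomorphic across all included accessions are excluded from
    the multi-locus sums.
    """
    if unassigned_policy != "exclude":
        raise ValueError("only the 'exclude' unassigned policy is supported")
    members = {g: groups.members(g) for g in groups.groups()}
    members = {g: ids for g, ids in members.items() if len(ids) >= 2}
    if len(members) < 2:
        raise ValueError("need at least 2 groups with at least 2 members each")
    layers = _group_freq_tables(gm, members)
    marker_ids = (
        list(gm.marker_ids) if isinstance(gm, BiallelicGenotypeMatrix) else list(gm.locus_ids)
    )
    L = len(marker_ids)

    num_sum = np.zeros(L)
    den_sum = np.zeros(L)
    any_valid = np.zeros(L, dtype=bool)
    he = np.zeros(L)
    n_tot_ref = None
    for n, p in layers:
        num, den, valid, p_bar = _theta_components(n, p)
        num_sum += np.where(valid, num, 0.0)
        den_sum += np.where(valid, den, 0.0)
        any_valid |= valid
        n_tot = n.sum(axis=0)
        he += np.where(n_tot > 0, (n_tot * p_bar**2).clip(0), 0.0) / np.where(
            n_tot > 0, n_tot, 1
        )
        n_tot_ref = n_tot
    # pooled He = 1 - sum_a p_bar_a^2 (bi-allelic: add the absence allele)
    if isinstance(gm, BiallelicGenotypeMatrix):
        (n, p) = layers[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_pool = (n * p).sum(axis=0) / n.sum(axis=0)
        he = 1.0 - p_pool**2 - (1 - p_pool) ** 2
    else:
        he = 1.0 - he

    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(any_valid, num_sum / den_sum, np.nan)
    global_theta = _ratio_of_sums(num_sum, den_sum, any_valid)

    group_ids = list(members)
    pw = pd.DataFrame(np.nan, index=group_ids, columns=group_ids, dtype=float)
    for i, g1 in enumerate(group_ids):
        for g2 in group_ids[i + 1 :]:
            sub = {g1: members[g1], g2: members[g2]}
            pair_layers = _group_freq_tables(gm, sub)
            ns = np.zeros(L)
            ds = np.zeros(L)
            vs = np.zeros(L, dtype=bool)
            for n, p in pair_layers:
                num, den, valid, _ = _theta_components(n, p)
                ns += np.where(valid, num, 0.0)
                ds += np.where(valid, den, 0.0)
                vs |= valid
            pw.loc[g1, g2] = pw.loc[g2, g1] = _ratio_of_sums(ns, ds, vs)
    return FstResult(
        marker_ids=marker_ids,
        per_locus_theta=per_locus,
        per_locus_he=he,
        global_theta=global_theta,
        pairwise=pw,
        group_sizes={g: len(ids) for g, ids in members.items()},
        n_loci_used=int(any_valid.sum()),
    )


def fst_permutation_test(
    gm,
    groups: GroupAssignment,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Permutation p-values for global and pairwise theta.

    Group labels are permuted over the included accessions;
    p = (1 + #{theta_perm >= theta_obs}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs = wc_fst(gm, groups)
    included = [a for a in gm.accession_ids if groups.assignments.get(a, UNASSIGNED) != UNASSIGNED]
    labels = [groups.group_of(a) for a in included]
    group_ids = list(obs.pairwise.index)
    count_global = 0
    count_pair = pd.DataFrame(0, index=group_ids, columns=group_ids, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ga = GroupAssignment.from_labels(included, [int(g) for g in perm])
        sub = gm.subset_accessions(included) if isinstance(gm, BiallelicGenotypeMatrix) else gm
        res = wc_fst(sub, ga)
        if res.global_theta >= obs.global_theta:
            count_global += 1
        for i, g1 in enumerate(group_ids):
            for g2 in group_ids[i + 1 :]:
                if res.pairwise.loc[g1, g2] >= obs.pairwise.loc[g1, g2]:
                    count_pair.loc[g1, g2] += 1
    p_global = (1 + count_global) / (1 + n_perm)
    p_pair = pd.DataFrame(np.nan, index=group_ids, columns=group_ids, dtype=float)
    for i, g1 in enumerate(group_ids):
        for g2 in group_ids[i + 1 :]:
            p = (1 + count_pair.loc[g1, g2]) / (1 + n_perm)
            p_pair.loc[g1, g2] = p_pair.loc[g2, g1] = p
    return {"global": p_global, "pairwise": p_pair, "observed": obs}


@dataclass
class NeutralEnvelope:
    """He-conditional neutral quantiles of theta from island-model simulation."""

    k_demes: int
    deme_n: int
    n_loci: int
    f_cal: float
    tail: float
    seed: int | None
    bin_edges: np.ndarray  # He edges, len n_bins + 1
    lower: np.ndarray  # per-bin lower theta quantile
    upper: np.ndarray  # per-bin upper theta quantile
    sim_he: np.ndarray
    sim_theta: np.ndarray
    achieved_mean_theta: float

    def bin_of(self, he: np.ndarray) -> np.ndarray:
        """He -> bin index, clamped to the covered range."""
        idx = np.searchsorted(self.bin_edges, he, side="right") - 1
        return np.clip(idx, 0, len(self.lower) - 1)


def _simulate_island_thetas(
    f: float, n_loci: int, k: int, deme_n: int, rng: np.random.Generator
):
    """One island-model locus cloud at divergence f: Balding-Nichols deme
    frequencies, binomial haploid sampling, Weir-Cockerham theta."""
    p0 = rng.uniform(0.01, 0.99, size=n_loci)
    scale = (1 - f) / f
    pk = rng.beta(
        np.broadcast_to(p0 * scale, (k, n_loci)),
        np.broadcast_to((1 - p0) * scale, (k, n_loci)),
    )
    pk = np.clip(pk, 1e-12, 1 - 1e-12)
    counts = rng.binomial(deme_n, pk)
    p_hat = counts / deme_n
    n = np.full((k, n_loci), float(deme_n))
    num, den, valid, p_bar = _theta_components(n, p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(valid, num / den, np.nan)
    he = 1.0 - p_bar**2 - (1 - p_bar) ** 2
    keep = valid & np.isfinite(theta)
    return he[keep], theta[keep]


def simulate_neutral_envelope(
    observed: FstResult,
    n_loci: int = 50_000,
    k_demes: int | None = None,
    deme_n: int = 50,
    tail: float = 0.01,
    n_he_bins: int = 20,
    seed: int | None = None,
    target_mean_fst: float | None = None,
) -> NeutralEnvelope:
    """Neutral (He, theta) envelope calibrated to the observed differentiation.

    The target is the 5%-trimmed mean of the observed per-locus thetas
    (robust to the outliers the scan is looking for).  The divergence
    parameter is found by bisection so that the mean simulated theta
    lands within ±0.005 of the target; each bisection evaluation
    simulates the full locus cloud from the same seed.  Simulated loci
    are then split into ``n_he_bins`` equal-count He bins and the
    ``tail`` / 1 - ``tail`` theta quantiles stored per bin.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    if k_demes is None:
        k_demes = len(observed.group_sizes)
    if k_demes < 2:
        raise ValueError("need at least 2 demes")
    if target_mean_fst is None:
        thetas = observed.per_locus_theta
        thetas = thetas[np.isfinite(thetas)]
        if thetas.size == 0:
            raise ValueError("no finite per-locus theta available for calibration")
        target_mean_fst = float(trim_mean(thetas, 0.05))

    def mean_theta(f: float):
        rng = np.random.default_rng(seed)
        he, th = _simulate_island_thetas(f, n_loci, k_demes, deme_n, rng)
        return float(th.mean()), he, th

    lo, hi = 1e-4, 0.99
    m_lo, *_ = mean_theta(lo)
    m_hi, *_ = mean_theta(hi)
    if not (m_lo <= target_mean_fst <= m_hi):
        raise RuntimeError(
            f"cannot bracket target mean Fst {target_mean_fst:.4f}: "
            f"simulated range [{m_lo:.4f}, {m_hi:.4f}]"
        )
    f_mid, m_mid, he, th = lo, m_lo, None, None
    for _ in range(60):
        f_mid = 0.5 * (lo + hi)
        m_mid, he, th = mean_theta(f_mid)
        if abs(m_mid - target_mean_fst) <= 0.004:
            break
        if m_mid < target_mean_fst:
            lo = f_mid
        else:
            hi = f_mid
    if abs(m_mid - target_mean_fst) > 0.005:
        raise RuntimeError(
            f"calibration failed: mean theta {m_mid:.4f} vs target {target_mean_fst:.4f}"
        )

    order = np.argsort(he, kind="stable")
    he_s, th_s = he[order], th[order]
    splits = np.array_split(np.arange(he_s.size), n_he_bins)
    edges = [he_s[idx[0]] for idx in splits if idx.size] + [he_s[-1]]
    edges = np.asarray(edges, dtype=float)
    edges[0], edges[-1] = -np.inf, np.inf  # clamp out-of-range He to end bins
    lower = np.array([np.quantile(th_s[idx], tail) for idx in splits if idx.size])
    upper = np.array([np.quantile(th_s[idx], 1 - tail) for idx in splits if idx.size])
    return NeutralEnvelope(
        k_demes=k_demes,
        deme_n=deme_n,
        n_loci=n_loci,
        f_cal=f_mid,
        tail=tail,
        seed=seed,
        bin_edges=edges,
        lower=lower,
        upper=upper,
        sim_he=he_s,
        sim_theta=th_s,
        achieved_mean_theta=m_mid,
    )


@dataclass
class OutlierCall:
    """Classification of one locus against the neutral envelope."""

    marker_id: str
    fst: float
    he: float
    quantile_position: float  # P(simulated theta < observed theta | He bin)
    classification: str  # diversifying / balancing / neutral


def classify_outliers(observed: FstResult, env: NeutralEnvelope) -> list[OutlierCall]:
    """Call each locus diversifying (theta above the upper quantile of
    its He bin), balancing (below the lower quantile) or neutral.

    The reported quantile position is the fraction of simulated loci in
    the bin with theta below the observed value.  Loci with undefined
    theta (monomorphic) are skipped.
    """
    calls: list[OutlierCall] = []
    # precompute bin membership of the simulated cloud
    sim_bins = env.bin_of(env.sim_he)
    by_bin = [np.sort(env.sim_theta[sim_bins == b]) for b in range(len(env.lower))]
    for mk, th, he in zip(observed.marker_ids, observed.per_locus_theta, observed.per_locus_he):
        if not np.isfinite(th):
            continue
        b = int(env.bin_of(np.array([he]))[0])
        sims = by_bin[b]
        qpos = float(np.searchsorted(sims, th, side="left") / sims.size) if sims.size else np.nan
        if th > env.upper[b]:
            cls = "diversifying"
        elif th < env.lower[b]:
            cls = "balancing"
        else:
            cls = "neutral"
        calls.append(OutlierCall(mk, float(th), float(he), qpos, cls))
    return calls
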