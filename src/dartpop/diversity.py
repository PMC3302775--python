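"""Diversity statistics and dissimilarity indices.

Expected heterozygosity (gene diversity) with a bootstrap standard
deviation, hypergeometric rarefaction of allelic and private allelic
richness, and the pairwise dissimilarity indices used for tree building
and data-resolution analysis (simple matching / Sokal & Michener, and
Dice on band data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .core import (
    UNASSIGNED,
    BiallelicGenotypeMatrix,
    DissimilarityMatrix,
    GroupAssignment,
    MultiAllelicGenotypeMatrix,
)

__all__ = [
    "DiversityResult",
    "expected_heterozygosity",
    "rarefied_allelic_richness",
    "rarefied_private_allelic_richness",
    "allele_counts_by_group",
    "group_diversity",
    "dissimilarity_matrix",
    "equivalent_biallelic_count",
]


def _per_locus_allele_freqs(gm, locus: int) -> np.ndarray | None:
    """Allele frequency vector for one locus over non-missing calls."""
    if isinstance(gm, BiallelicGenotypeMatrix):
        col = gm.calls[:, locus]
        col = col[~np.isnan(col)]
        if col.size == 0:
            return None
        p = col.mean()
        return np.array([p, 1.0 - p])
    col = gm.alleles[:, locus]
    labels = [a for a in col if a is not None]
    if not labels:
        return None
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    return counts / counts.sum()


def _per_locus_he(gm) -> np.ndarray:
    n_loci = gm.n_markers if isinstance(gm, BiallelicGenotypeMatrix) else gm.n_loci
    he = np.full(n_loci, np.nan)
    for j in range(n_loci):
        freqs = _per_locus_allele_freqs(gm, j)
        if freqs is not None:
            he[j] = 1.0 - np.sum(freqs**2)
    return he


@dataclass
class DiversityResult:
    """He (mean over loci) with bootstrap SD, plus rarefied richness."""

    group: int | str
    n_accessions: int
    he_mean: float
    he_boot_sd: float
    total_alleles: int | None = None
    allelic_richness: float | None = None
    private_allelic_richness: float | None = None
    rarefaction_g: int | None = None


def _subset_group(gm, members: Sequence[str]):
    if isinstance(gm, BiallelicGenotypeMatrix):
        return gm.subset_accessions(members)
    index = {a: i for i, a in enumerate(gm.accession_ids)}
    rows = [index[a] for a in members]
    return MultiAllelicGenotypeMatrix(list(members), list(gm.locus_ids), gm.alleles[rows])


def expected_heterozygosity(
    gm,
    groups: GroupAssignment | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    unbiased: bool = False,
) -> list[DiversityResult]:
    """Mean-over-loci gene diversity He = 1 - sum(p_a^2) per group.

    The bootstrap SD resamples loci with replacement (He is a mean over
    loci, so the SD accompanies that mean).  ``unbiased`` applies the
    n/(n-1) small-sample correction per locus; off by default, matching
    the plain gene-diversity estimator.
    """
    rng = np.random.default_rng(seed)
    units: list[tuple[int | str, Sequence[str]]] = []
    if groups is None:
        units.append(("ALL", list(gm.accession_ids)))
    else:
        for g in groups.groups():
            units.append((g, groups.members(g)))
    results = []
    for label, members in units:
        if len(members) == 0:
            warnings.warn(f"group {label!r} has no members; omitted", stacklevel=2)
            continue
        sub = _subset_group(gm, members)
        he = _per_locus_he(sub)
        if unbiased:
            if isinstance(sub, BiallelicGenotypeMatrix):
                n = (~np.isnan(sub.calls)).sum(axis=0)
            else:
                n = np.array(
                    [sum(a is not None for a in sub.alleles[:, j]) for j in range(sub.n_loci)]
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                he = np.where(n > 1, he * n / (n - 1), he)
        he = he[~np.isnan(he)]
        if he.size == 0:
            warnings.warn(f"group {label!r} has no scorable locus; omitted", stacklevel=2)
            continue
        boots = rng.integers(0, he.size, size=(n_boot, he.size))
        boot_means = he[boots].mean(axis=1)
        results.append(
            DiversityResult(
                group=label,
                n_accessions=len(members),
                he_mean=float(he.mean()),
                he_boot_sd=float(boot_means.std(ddof=1)),
            )
        )
    return results


def rarefied_allelic_richness(allele_counts: Mapping[str, int] | Sequence[int], g: int) -> float:
    """Expected number of alleles in a random subsample of ``g`` gene copies.

    For allele counts N_a summing to N this is the hypergeometric
    expectation  sum_a [1 - C(N - N_a, g) / C(N, g)].
    """
    counts = list(allele_counts.values()) if isinstance(allele_counts, Mapping) else list(allele_counts)
    counts = [int(c) for c in counts if c > 0]
    N = sum(counts)
    if not 1 <= g <= N:
        raise ValueError(f"rarefaction size g={g} must be in [1, N={N}]")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - c, g) / denom if N - c >= g else 1.0 for c in counts))


def rarefied_private_allelic_richness(
    counts_by_group: Mapping[int | str, Mapping[str, int]], g: int
) -> dict[int | str, float]:
    """Expected number of private alleles in subsamples of ``g`` genes per group.

    pi_j(g) = sum_a (1 - Q_jag) * prod_{j' != j} Q_j'ag  with
    Q_jag = C(N_j - N_ja, g) / C(N_j, g), the probability that allele a
    is absent from a g-gene subsample of group j.
    """
    groups = list(counts_by_group)
    totals = {j: sum(counts_by_group[j].values()) for j in groups}
    for j, N in totals.items():
        if g > N:
            raise ValueError(f"g={g} exceeds the {N} gene copies of group {j!r}")
    alleles = sorted({a for j in groups for a in counts_by_group[j]})

    def q_absent(j, a):
        N = totals[j]
        c = counts_by_group[j].get(a, 0)
        if N - c < g:
            return 0.0
        return comb(N - c, g) / comb(N, g)

    out: dict[int | str, float] = {}
    for j in groups:
        total = 0.0
        for a in alleles:
            qj = q_absent(j, a)
            prod = 1.0
            for j2 in groups:
                if j2 != j:
                    prod *= q_absent(j2, a)
            total += (1.0 - qj) * prod
        out[j] = total
    return out


def allele_counts_by_group(gm, groups: GroupAssignment) -> list[dict[int | str, dict[str, int]]]:
    """Per-locus allele counts within each assigned group.

    Returns a list (one entry per locus) of {group: {allele: count}}
    over non-missing calls; presence/absence calls use labels "1"/"0".
    """
    per_locus = []
    n_loci = gm.n_markers if isinstance(gm, BiallelicGenotypeMatrix) else gm.n_loci
    members = {g: groups.members(g) for g in groups.groups()}
    subs = {g: _subset_group(gm, m) for g, m in members.items() if m}
    for j in range(n_loci):
        locus: dict[int | str, dict[str, int]] = {}
        for g, sub in subs.items():
            if isinstance(sub, BiallelicGenotypeMatrix):
                col = sub.calls[:, j]
                col = col[~np.isnan(col)]
                counts = {"1": int((col == 1).sum()), "0": int((col == 0).sum())}
                counts = {a: c for a, c in counts.items() if c > 0}
            else:
                labels = [a for a in sub.alleles[:, j] if a is not None]
                vals, cnts = (
                    np.unique(np.asarray(labels, dtype=object), return_counts=True)
                    if labels
                    else ([], [])
                )
                counts = {str(a): int(c) for a, c in zip(vals, cnts)}
            locus[g] = counts
        per_locus.append(locus)
    return per_locus


def group_diversity(
    gm,
    groups: GroupAssignment,
    g: int | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[DiversityResult]:
    """Full per-group diversity report: He (bootstrap SD), total allele
    count, rarefied allelic richness and rarefied private allelic
    richness, averaged over loci.

    ``g`` defaults to the smallest group's gene count (all groups then
    compared at an equal standardized sample size).
    """
    he_results = {r.group: r for r in expected_heterozygosity(gm, groups, n_boot, seed)}
    counts = allele_counts_by_group(gm, groups)
    group_ids = groups.groups()
    if g is None:
        # smallest per-group non-missing count over loci
        min_n = None
        for locus in counts:
            for gid in group_ids:
                n = sum(locus.get(gid, {}).values())
                if n > 0:
                    min_n = n if min_n is None else min(min_n, n)
        g = max(1, min_n or 1)
    results = []
    for gid in group_ids:
        richness, private, total_alleles, n_loci = 0.0, 0.0, 0, 0
        for locus in counts:
            own = locus.get(gid, {})
            if sum(own.values()) < g:
                continue
            other_ok = {j: c for j, c in locus.items() if sum(c.values()) >= g}
            if gid not in other_ok or len(other_ok) < 2:
                continue
            richness += rarefied_allelic_richness(own, g)
            private += rarefied_private_allelic_richness(other_ok, g)[gid]
            total_alleles += len(own)
            n_loci += 1
        base = he_results.get(gid)
        if base is None or n_loci == 0:
            continue
        results.append(
            DiversityResult(
                group=gid,
                n_accessions=base.n_accessions,
                he_mean=base.he_mean,
                he_boot_sd=base.he_boot_sd,
                total_alleles=total_alleles,
                allelic_richness=richness / n_loci,
                private_allelic_richness=private / n_loci,
                rarefaction_g=g,
            )
        )
    return results


def dissimilarity_matrix(gm, index: str = "simple_matching") -> DissimilarityMatrix:
    """Pairwise accession dissimilarities with pairwise deletion of missing calls.

    ``simple_matching`` (the Sokal & Michener index, also used for
    allele-label data): d = 1 - matches / comparable.  ``dice`` (band
    data only): d = 1 - 2a / (2a + b + c) with a = shared presences and
    b, c the discordant counts.  A pair with no comparable marker gets a
    missing entry and a warning.
    """
    if isinstance(gm, MultiAllelicGenotypeMatrix):
        if index != "simple_matching":
            raise ValueError("multi-allelic data supports only the simple matching index")
        n, m = gm.n_accessions, gm.n_loci
        d = np.zeros((n, n))
        obs = ~np.equal(gm.alleles, None)
        for i in range(n):
            for j in range(i + 1, n):
                both = obs[i] & obs[j]
                comp = int(both.sum())
                if comp == 0:
                    warnings.warn(
                        f"no comparable locus for pair ({gm.accession_ids[i]}, {gm.accession_ids[j]})",
                        stacklevel=2,
                    )
                    d[i, j] = d[j, i] = np.nan
                    continue
                matches = int((gm.alleles[i][both] == gm.alleles[j][both]).sum())
                d[i, j] = d[j, i] = 1.0 - matches / comp
        return DissimilarityMatrix(list(gm.accession_ids), d)

    X = gm.calls
    M = (~np.isnan(X)).astype(float)
    A = np.nan_to_num(X)  # 1 where present, 0 elsewhere
    comparable = M @ M.T
    n11 = A @ A.T
    n00 = (M - A) @ (M - A).T
    if index == "simple_matching":
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 1.0 - (n11 + n00) / comparable
    elif index == "dice":
        bc = comparable - n11 - n00
        with np.errstate(divide="ignore", invalid="ignore"):
            d = 1.0 - 2 * n11 / (2 * n11 + bc)
            d = np.where(bc == 0, 0.0, d)  # no discordance: agrees with simple matching
    else:
        raise ValueError(f"unknown index {index!r}")
    if (comparable == 0).any():
        warnings.warn("accession pair(s) with no comparable marker", stacklevel=2)
        d = np.where(comparable == 0, np.nan, d)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0, out=d)
    return DissimilarityMatrix(list(gm.accession_ids), d)


def equivalent_biallelic_count(m: float, k: float) -> float:
    """Bi-allelic marker equivalent of m multi-allelic loci with a mean
    of k alleles per locus: m * (k - 1)."""
    if m < 1 or k < 1:
        raise ValueError("need m >= 1 loci and k >= 1 alleles per locus")
    return m * (k - 1)
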