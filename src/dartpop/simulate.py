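"""Synthetic structured populations of inbred (haploid-coded) accessions.

The generator emulates a worldwide germplasm core sample: a few genetic
groups of unequal size, dominant bi-allelic markers on several
chromosomes, allele-frequency differentiation between groups at a
configurable Fst, distance-decaying linkage disequilibrium, a MAF
spectrum bounded away from zero, and missing calls at random.

Model, per locus:

* ancestral frequency  p0 ~ Uniform(maf_floor, 1 - maf_floor);
* group frequencies    p_k ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F)
  (the Balding-Nichols model: E[p_k] = p0, Var[p_k] = F p0 (1-p0));
* each group carries H founder haplotypes; founder f of group k gets
  allele 1 at marker j iff u_fj < p_kj, where the uniforms u_fj are
  shared across groups.  Marginally every founder allele is
  Bernoulli(p_k); jointly the H founders behave as ancestral lineages
  common to all groups whose fixation probabilities have drifted apart,
  so the drift LD they carry is aligned across groups and survives
  pooling over the structured panel (as it does in real germplasm that
  shares haplotypes by descent).
* every accession chromosome is a mosaic of its group's founders, with
  switch events forming a Poisson process of rate c per bp along the
  chromosome.  Shared founder segments generate LD that decays with
  physical distance at scale ~1/c towards the structure-driven
  background.

The founder bottleneck adds a little drift on top of the
Balding-Nichols spread (damped by the lineage coupling); keep H large
when F itself must be hit closely.

Replicate ancestry (Q) matrices with Dirichlet noise and optional label
permutation, and spiked outlier loci (diversifying / balancing), round
out the test bench for the downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BiallelicGenotypeMatrix, GroupAssignment, MarkerMap, QMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_population",
    "simulate_q_replicates",
    "spike_outliers",
]

_DIRICHLET_EPS = 1e-6  # keeps Dirichlet concentrations strictly positive


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror a worldwide sorghum-like core sample: 6 groups of
    unequal size (137 assigned accessions), 1100 markers on 10
    chromosomes of 73.6 Mb (a 736 Mb genome), between-group Fst 0.4,
    10 founder haplotypes per group, founder-mosaic switch rate 2e-6
    per bp (LD decay scale ~0.5 Mb), MAF floor 0.05 on the ancestral
    frequency, and 10% missing calls.
    """

    n_groups: int = 6
    group_sizes: tuple[int, ...] = (38, 28, 22, 10, 15, 24)
    n_chromosomes: int = 10
    chromosome_length_bp: int = 73_600_000
    n_markers: int = 1100
    target_fst: float = 0.4
    founder_haplotypes_per_group: int = 10
    per_bp_switch_rate: float = 2e-6
    maf_floor: float = 0.05
    missing_rate: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.group_sizes) != self.n_groups:
            raise ValueError(
                f"group_sizes has {len(self.group_sizes)} entries for {self.n_groups} groups"
            )
        if sum(self.group_sizes) < 2:
            raise ValueError("need at least 2 accessions in total")
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if self.founder_haplotypes_per_group < 2:
            raise ValueError("need at least 2 founder haplotypes per group")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        per_chrom = -(-self.n_markers // self.n_chromosomes)  # ceil
        if per_chrom > self.chromosome_length_bp:
            raise ValueError("chromosome too short for the requested marker count")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated panel."""

    group_labels: list[int]  # per accession, 1..K
    q: QMatrix  # one-hot ancestry
    ancestral_freqs: np.ndarray  # per locus p0
    group_freqs: np.ndarray  # K x n_markers Balding-Nichols draws
    outlier_loci: dict[str, dict] = field(default_factory=dict)  # marker -> {mode, fst}

    def group_assignment(self) -> GroupAssignment:
        return GroupAssignment.from_labels(self.q.accession_ids, self.group_labels)


def _marker_layout(cfg: SyntheticConfig, rng: np.random.Generator):
    """Uniform, sorted, unique marker positions; markers split as evenly
    as possible across chromosomes."""
    base, extra = divmod(cfg.n_markers, cfg.n_chromosomes)
    chrom_sizes = [base + (1 if c < extra else 0) for c in range(cfg.n_chromosomes)]
    marker_ids, chroms, positions, chrom_index = [], [], [], []
    for c, size in enumerate(chrom_sizes):
        pos = np.sort(
            rng.choice(cfg.chromosome_length_bp, size=size, replace=False) + 1
        )
        for p in pos:
            marker_ids.append(f"m{len(marker_ids) + 1:05d}")
            chroms.append(f"chr{c + 1}")
            positions.append(int(p))
            chrom_index.append(c)
    return marker_ids, chroms, np.array(positions, dtype=np.int64), np.array(chrom_index)


def simulate_population(
    cfg: SyntheticConfig,
) -> tuple[BiallelicGenotypeMatrix, MarkerMap, SyntheticTruth]:
    """Simulate a structured panel; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    K, H, m = cfg.n_groups, cfg.founder_haplotypes_per_group, cfg.n_markers
    marker_ids, chrom_labels, positions, chrom_index = _marker_layout(cfg, rng)

    F = cfg.target_fst
    p0 = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=m)
    scale = (1 - F) / F
    pk = rng.beta(p0 * scale, (1 - p0) * scale, size=(K, m))
    pk = np.clip(pk, 1e-9, 1 - 1e-9)

    lineage_u = rng.random((H, m))  # shared across groups: common ancestral lineages
    accession_ids, labels, rows = [], [], []
    for k in range(K):
        founders = (lineage_u < pk[k]).astype(float)
        n_k = cfg.group_sizes[k]
        calls_k = np.empty((n_k, m))
        for c in range(cfg.n_chromosomes):
            cols = np.where(chrom_index == c)[0]
            if cols.size == 0:
                continue
            gaps = np.diff(positions[cols]).astype(float)
            p_switch = 1.0 - np.exp(-cfg.per_bp_switch_rate * gaps)
            # founder path per accession: switch events draw a fresh
            # founder uniformly; the first marker always draws fresh
            switch = np.ones((n_k, cols.size), dtype=bool)
            if cols.size > 1:
                switch[:, 1:] = rng.random((n_k, cols.size - 1)) < p_switch
            draws = rng.integers(0, H, size=(n_k, cols.size))
            pos_idx = np.where(switch, np.arange(cols.size), 0)
            last_switch = np.maximum.accumulate(pos_idx, axis=1)
            founder_path = np.take_along_axis(draws, last_switch, axis=1)
            calls_k[:, cols] = founders[founder_path, cols[None, :]]
        for i in range(n_k):
            accession_ids.append(f"G{k + 1}_{i + 1:03d}")
            labels.append(k + 1)
        rows.append(calls_k)
    calls = np.vstack(rows)

    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = np.nan

    gm = BiallelicGenotypeMatrix(accession_ids, marker_ids, calls)
    mmap = MarkerMap(marker_ids, chrom_labels, positions)
    q = np.zeros((len(accession_ids), K))
    q[np.arange(len(accession_ids)), np.array(labels) - 1] = 1.0
    truth = SyntheticTruth(
        group_labels=labels,
        q=QMatrix(list(accession_ids), q),
        ancestral_freqs=p0,
        group_freqs=pk,
    )
    return gm, mmap, truth


def simulate_q_replicates(
    truth_q: QMatrix,
    concentration: float,
    permute_labels: bool = False,
    n_runs: int = 1,
    seed: int | None = None,
) -> list[QMatrix]:
    """Noisy replicate ancestry matrices, as if from repeated clustering runs.

    Row i of each run is drawn from Dirichlet(concentration * q_i + eps);
    with ``permute_labels`` one random permutation of the K cluster
    labels is applied to the whole run (label switching).
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        q = np.empty_like(truth_q.q)
        for i in range(truth_q.n_accessions):
            alpha = concentration * truth_q.q[i] + _DIRICHLET_EPS
            q[i] = rng.dirichlet(alpha)
        if permute_labels:
            perm = rng.permutation(truth_q.K)
            q = q[:, perm]
        runs.append(QMatrix(list(truth_q.accession_ids), q))
    return runs


def spike_outliers(
    gm: BiallelicGenotypeMatrix,
    truth: SyntheticTruth,
    loci: list[str],
    mode: str = "diversifying",
    seed: int | None = None,
) -> tuple[BiallelicGenotypeMatrix, SyntheticTruth]:
    """Overwrite selected loci with selection-like frequency patterns.

    ``diversifying``: groups alternate near-fixed frequencies (0.99 /
    0.01), giving a per-locus differentiation around 0.96 — the pattern
    of divergent selection fixing alternate alleles.  ``balancing``:
    every group frequency is set to 0.5, driving the locus-specific
    differentiation towards zero while diversity stays maximal.  The
    original missingness pattern of each locus is preserved; truth is
    updated with the spiked loci and their divergence parameter.
    """
    if mode not in ("diversifying", "balancing"):
        raise ValueError(f"unknown spike mode {mode!r}")
    if not loci:
        return gm, truth
    rng = np.random.default_rng(seed)
    index = {mk: j for j, mk in enumerate(gm.marker_ids)}
    calls = gm.calls.copy()
    labels = np.array(truth.group_labels)
    group_freqs = truth.group_freqs.copy()
    outliers = dict(truth.outlier_loci)
    K = group_freqs.shape[0]
    for mk in loci:
        if mk not in index:
            raise KeyError(f"unknown locus {mk!r}")
        j = index[mk]
        if mode == "diversifying":
            freqs = np.where(np.arange(K) % 2 == 0, 0.99, 0.01)
        else:
            freqs = np.full(K, 0.5)
        missing = np.isnan(calls[:, j])
        for k in range(K):
            rows = np.where(labels == k + 1)[0]
            calls[rows, j] = (rng.random(rows.size) < freqs[k]).astype(float)
        calls[missing, j] = np.nan
        group_freqs[:, j] = freqs
        var = float(np.var(freqs))
        pbar = float(np.mean(freqs))
        fst = var / (pbar * (1 - pbar)) if 0 < pbar < 1 else 1.0
        outliers[mk] = {"mode": mode, "divergence": fst}
    new_truth = replace(truth, group_freqs=group_freqs, outlier_loci=outliers)
    return (
        BiallelicGenotypeMatrix(list(gm.accession_ids), list(gm.marker_ids), calls),
        new_truth,
    )
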