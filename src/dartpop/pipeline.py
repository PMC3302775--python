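"""Configuration-driven end-to-end orchestration.

Runs the analysis chain (simulate or load -> filter -> diversity ->
ancestry concordance -> MLST core sampling -> LD -> Fst -> outlier scan)
with per-stage seeds derived deterministically from a master seed, a
config-hash stamp on every output file, and a JSON run report of
per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, diversity, concordance, differentiation, ld as ldmod, simulate, tree

logger = logging.getLogger("dartpop")

#: Stage-specific filter thresholds: structure-type analyses drop markers
#: with >= 10% missing data; LD analyses use < 20% missing and MAF >= 0.05.
STRUCTURE_MAX_MISSING = 0.10
LD_MAX_MISSING = 0.20
LD_MIN_MAF = 0.05
MEMBERSHIP_THRESHOLD = 0.6


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    out_dir: str = "dartpop_run"
    seed: int = 0
    # either synthetic generation ...
    synthetic: dict | None = None
    # ... or input files
    genotypes: str | None = None
    marker_map: str | None = None
    q_matrix: str | None = None
    # stage thresholds
    structure_max_missing: float = STRUCTURE_MAX_MISSING
    ld_max_missing: float = LD_MAX_MISSING
    ld_min_maf: float = LD_MIN_MAF
    membership_threshold: float = MEMBERSHIP_THRESHOLD
    # stage toggles and knobs
    stages: tuple[str, ...] = (
        "filter",
        "diversity",
        "concordance",
        "mlst",
        "ld",
        "fst",
        "outliers",
    )
    mlst_target_n: int = 100
    sampling_sizes: tuple[int, ...] = ()
    n_boot: int = 1000
    n_perm: int = 1000
    envelope_loci: int = 50_000
    envelope_deme_n: int = 50
    envelope_tail: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.ld_min_maf <= 0.5:
            raise ValueError("ld_min_maf must be in [0, 0.5]")
        for name in ("structure_max_missing", "ld_max_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.membership_threshold < 1:
            raise ValueError("membership_threshold must be in (0, 1)")
        if self.synthetic is None and self.genotypes is None:
            raise ValueError("config needs either a synthetic block or a genotypes path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stages", "sampling_sizes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        """Fingerprint of the analysis-relevant settings (the output
        location does not change what is computed)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha1(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _stamp_and_write(df: pd.DataFrame, path: Path, cfg_hash: str, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep=sep, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run report.

    Any stage error aborts with a stage-named message; outputs written
    before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    report: dict = {"config_hash": cfg_hash, "seed": cfg.seed, "stages": {}}
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        if cfg.synthetic is not None:
            stage = "simulate"
            sim_cfg = simulate.SyntheticConfig(
                **{**cfg.synthetic, "seed": cfg.stage_seed("simulate")}
            )
            gm, mmap, truth = simulate.simulate_population(sim_cfg)
            core.write_biallelic_genotypes(gm, out / "genotypes.csv")
            mmap.write(out / "marker_map.tsv")
            truth.q.write(out / "truth_q.csv")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "config_hash": cfg_hash,
                        "group_labels": truth.group_labels,
                        "outlier_loci": truth.outlier_loci,
                    },
                    fh,
                    indent=1,
                )
            q = truth.q
            report["stages"]["simulate"] = {
                "n_accessions": gm.n_accessions,
                "n_markers": gm.n_markers,
            }
        else:
            stage = "load"
            gm = core.read_biallelic_genotypes(cfg.genotypes)
            mmap = core.read_marker_map(cfg.marker_map) if cfg.marker_map else None
            q = core.read_q_matrix(cfg.q_matrix) if cfg.q_matrix else None
            report["stages"]["load"] = {
                "n_accessions": gm.n_accessions,
                "n_markers": gm.n_markers,
            }
        logger.info("input: %d accessions x %d markers", gm.n_accessions, gm.n_markers)

        groups = (
            concordance.assign_groups(q, cfg.membership_threshold) if q is not None else None
        )

        # ------------------------------------------------------------ filter
        gm_structure = gm
        gm_ld = gm
        if "filter" in cfg.stages:
            stage = "filter"
            gm_structure = core.filter_markers(gm, cfg.structure_max_missing, 0.0)
            gm_ld = core.filter_markers(gm, cfg.ld_max_missing, cfg.ld_min_maf)
            report["stages"]["filter"] = {
                "structure_markers": gm_structure.n_markers,
                "ld_markers": gm_ld.n_markers,
            }
            logger.info(
                "filter: %d structure markers, %d LD markers",
                gm_structure.n_markers,
                gm_ld.n_markers,
            )

        # --------------------------------------------------------- diversity
        if "diversity" in cfg.stages and groups is not None:
            stage = "diversity"
            rows = diversity.group_diversity(
                gm_structure, groups, n_boot=cfg.n_boot, seed=cfg.stage_seed("diversity")
            )
            df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
            _stamp_and_write(df, out / "diversity.tsv", cfg_hash)
            report["stages"]["diversity"] = {"n_groups": len(rows)}

        # ------------------------------------------------------- concordance
        if "concordance" in cfg.stages and q is not None:
            stage = "concordance"
            reps = simulate.simulate_q_replicates(
                q,
                concentration=100.0,
                permute_labels=True,
                n_runs=2,
                seed=cfg.stage_seed("concordance"),
            )
            rows = []
            for mode in ("quantitative", "thresholded"):
                res = concordance.ancestry_dissimilarity(
                    reps[0], reps[1], mode=mode, threshold=cfg.membership_threshold
                )
                rows.append({"mode": mode, "average_dissimilarity": res.average})
            _stamp_and_write(pd.DataFrame(rows), out / "concordance.tsv", cfg_hash)
            report["stages"]["concordance"] = {"n_runs_compared": 2}

        # -------------------------------------------------------------- mlst
        mlst_core = None
        if "mlst" in cfg.stages and gm_structure.n_markers:
            stage = "mlst"
            diss = diversity.dissimilarity_matrix(gm_structure, "simple_matching")
            target = min(cfg.mlst_target_n, gm.n_accessions)
            res = tree.mlst_subset(diss, target)
            mlst_core = res.retained
            nwk = tree.nj_tree(diss).to_newick()
            (out / "nj_tree.nwk").write_text(f"[config_hash={cfg_hash}]\n{nwk}\n")
            pd.DataFrame({"removed_in_order": res.removed}).pipe(
                _stamp_and_write, out / "mlst_removed.tsv", cfg_hash
            )
            report["stages"]["mlst"] = {"core_size": len(res.retained)}

        # ---------------------------------------------------------------- ld
        if "ld" in cfg.stages and mmap is not None and gm_ld.n_markers >= 2:
            stage = "ld"
            table = ldmod.pairwise_ld(gm_ld, mmap)
            p95 = ldmod.p95_threshold(table)
            bins = ldmod.bin_ld_summary(table, p95)
            _stamp_and_write(table, out / "ld_pairs.tsv", cfg_hash)
            _stamp_and_write(bins, out / "ld_bins.tsv", cfg_hash)
            fit_info = {}
            try:
                fit = ldmod.fit_ld_decay(table)
                req = {
                    str(t): dataclasses.asdict(ldmod.markers_required(fit.a, t))
                    for t in (0.1, 0.3)
                }
                fit_info = {"a": fit.a, "markers_required": req}
            except (ldmod.LDFitError, ValueError) as exc:
                fit_info = {"error": str(exc)}
            with open(out / "ld_fit.json", "w") as fh:
                json.dump({"config_hash": cfg_hash, **fit_info}, fh, indent=1)
            report["stages"]["ld"] = {
                "n_pairs": len(table),
                "p95": p95,
                **({"a": fit_info.get("a")} if "a" in fit_info else {}),
            }
            if cfg.sampling_sizes:
                for strategy in ("random", "mlst"):
                    res = ldmod.sampling_experiment(
                        gm_ld,
                        mmap,
                        sizes=[s for s in cfg.sampling_sizes if s < gm.n_accessions],
                        strategy=strategy,
                        seed=cfg.stage_seed(f"sampling-{strategy}"),
                    )
                    _stamp_and_write(
                        res.per_rep, out / f"sampling_{strategy}.tsv", cfg_hash
                    )

        # --------------------------------------------------------------- fst
        fst_res = None
        if "fst" in cfg.stages and groups is not None:
            stage = "fst"
            fst_res = differentiation.wc_fst(gm_ld, groups)
            perm = differentiation.fst_permutation_test(
                gm_ld, groups, n_perm=max(cfg.n_perm, 100), seed=cfg.stage_seed("fst")
            )
            pw = fst_res.pairwise.copy()
            pw.index.name = "group"
            with open(out / "fst.json", "w") as fh:
                json.dump(
                    {
                        "config_hash": cfg_hash,
                        "global_theta": fst_res.global_theta,
                        "global_p": perm["global"],
                        "pairwise_theta": json.loads(pw.to_json()),
                    },
                    fh,
                    indent=1,
                )
            report["stages"]["fst"] = {
                "global_theta": fst_res.global_theta,
                "n_loci_used": fst_res.n_loci_used,
            }

        # ----------------------------------------------------------- outliers
        if "outliers" in cfg.stages and fst_res is not None:
            stage = "outliers"
            env = differentiation.simulate_neutral_envelope(
                fst_res,
                n_loci=cfg.envelope_loci,
                deme_n=cfg.envelope_deme_n,
                tail=cfg.envelope_tail,
                seed=cfg.stage_seed("outliers"),
            )
            calls = differentiation.classify_outliers(fst_res, env)
            df = pd.DataFrame([dataclasses.asdict(c) for c in calls])
            _stamp_and_write(df, out / "outliers.tsv", cfg_hash)
            n_div = int((df["classification"] == "diversifying").sum()) if len(df) else 0
            n_bal = int((df["classification"] == "balancing").sum()) if len(df) else 0
            report["stages"]["outliers"] = {
                "f_cal": env.f_cal,
                "diversifying": n_div,
                "balancing": n_bal,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
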