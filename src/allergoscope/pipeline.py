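"""End-to-end run orchestration.

Stages (scan -> profile -> conserve -> serology -> diagnose) communicate
only via files in the run directory, so every intermediate is
inspectable and each stage is testable in isolation.  A YAML config
carries paths, thresholds, transforms and seeds; when it requests
synthetic inputs, the generators produce them (plus truth tables) as a
preliminary stage.  Every threshold actually applied is logged at INFO.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import conservation, diagnostics, profiling, serology, simulate
from .io import (
    load_allergen_db,
    read_cohort,
    read_fasta,
    read_tpm_table,
    write_cohort,
    write_fasta,
    write_tpm_table,
)
from .scan import ScanThresholds, hits_from_frame, scan_transcriptome

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    output_dir: Path
    seed: int = 0
    synthetic: bool = True
    inputs: dict[str, Path] = field(default_factory=dict)
    min_identity_pct: float = 50.0
    min_subject_coverage_pct: float = 90.0
    id_thresh: float = 70.0
    abund_thresh: float = 0.01
    min_samples: int = 3
    sige_cutoff: float = 0.35
    sige_transform: str = "raw"  # raw | log
    conservation_columns: str = "all"  # all | consensus
    ofc_targets: list[str] = field(default_factory=lambda: ["grass_carp", "salmon"])
    max_subset_size: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        thresholds = raw.get("thresholds", {})
        transforms = raw.get("transforms", {})
        diagnosis = raw.get("diagnosis", {})
        cfg = cls(
            output_dir=Path(raw.get("output_dir", "allergoscope_run")),
            seed=int(raw.get("seed", 0)),
            synthetic=bool(raw.get("synthetic", "inputs" not in raw)),
            inputs={k: Path(v) for k, v in raw.get("inputs", {}).items()},
            min_identity_pct=float(thresholds.get("min_identity_pct", 50.0)),
            min_subject_coverage_pct=float(thresholds.get("min_subject_coverage_pct", 90.0)),
            id_thresh=float(thresholds.get("id_thresh", 70.0)),
            abund_thresh=float(thresholds.get("abund_thresh", 0.01)),
            min_samples=int(thresholds.get("min_samples", 3)),
            sige_cutoff=float(thresholds.get("sige_cutoff", 0.35)),
            sige_transform=str(transforms.get("sige_correlation", "raw")),
            conservation_columns=str(transforms.get("conservation_columns", "all")),
            ofc_targets=list(diagnosis.get("targets", ["grass_carp", "salmon"])),
            max_subset_size=int(diagnosis.get("max_subset_size", 5)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.min_identity_pct <= 100:
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not 0 <= self.min_subject_coverage_pct <= 100:
            raise ValueError("min_subject_coverage_pct must be in [0, 100]")
        if self.sige_transform not in ("raw", "log"):
            raise ValueError("sige_correlation transform must be 'raw' or 'log'")
        if self.conservation_columns not in ("all", "consensus"):
            raise ValueError("conservation_columns must be 'all' or 'consensus'")
        if not self.synthetic:
            required = {"transcripts", "tpm", "allergen_db", "msa", "sige", "ofc"}
            missing = required - set(self.inputs)
            if missing:
                raise FileNotFoundError(f"config lacks input paths: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input {key!r}: {path} does not exist")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kwargs)


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    db, meta = simulate.generate_reference_db(seed=cfg.seed)
    tset = simulate.generate_transcriptome_set(db, seed=cfg.seed + 1)
    cohort, truth = simulate.generate_cohort(seed=cfg.seed + 2)
    write_fasta(db, outdir / "allergens.fasta")
    _write(meta, outdir / "allergen_meta.tsv", index=False)
    write_fasta(tset.transcripts, outdir / "transcripts.fasta")
    write_tpm_table(tset.tpm, outdir / "tpm.tsv")
    _write(tset.truth, outdir / "transcript_truth.tsv", index=False)
    outgroups = simulate.family_outgroups(db, "PV", seed=cfg.seed + 3)
    write_fasta(
        simulate.family_msa(db, "PV", truth=tset.truth, extra=outgroups),
        outdir / "pv_msa.fasta",
    )
    write_cohort(cohort, outdir / "sige.tsv", outdir / "ofc.tsv")
    with open(outdir / "cohort_truth.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "rho_within": truth.rho_within, "rho_between": truth.rho_between,
                "sigma": truth.sigma, "beta": truth.beta, "alpha": truth.alpha,
                "mu": truth.mu, "seed": truth.seed,
            },
            fh, indent=1, sort_keys=True,
        )
    cfg.inputs = {
        "transcripts": outdir / "transcripts.fasta",
        "tpm": outdir / "tpm.tsv",
        "allergen_db": outdir / "allergens.fasta",
        "msa": outdir / "pv_msa.fasta",
        "sige": outdir / "sige.tsv",
        "ofc": outdir / "ofc.tsv",
    }
    return {
        "n_allergens": len(db),
        "n_transcripts": len(tset.transcripts),
        "n_samples": tset.tpm.shape[1],
        "n_subjects": len(cohort.subjects),
    }


def _stage_scan(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    thresholds = ScanThresholds(
        min_identity_pct=cfg.min_identity_pct,
        min_subject_coverage_pct=cfg.min_subject_coverage_pct,
    )
    logger.info(
        "scan thresholds: identity >= %.1f%%, subject coverage > %.1f%%",
        thresholds.min_identity_pct, thresholds.min_subject_coverage_pct,
    )
    transcripts = read_fasta(cfg.inputs["transcripts"], alphabet="nucleotide")
    db = load_allergen_db(cfg.inputs["allergen_db"], cfg.inputs.get("allergen_metadata"))
    result = scan_transcriptome(transcripts, db, thresholds)
    _write(result.to_frame(), outdir / "hits.tsv", index=False)
    return {
        "n_transcripts": len(transcripts),
        "n_hits": len(result.hits),
        "n_assigned_transcripts": len(result.primary),
    }


def _stage_profile(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    hits = hits_from_frame(pd.read_csv(outdir / "hits.tsv", sep="\t"))
    tpm = read_tpm_table(cfg.inputs["tpm"])
    matrix = profiling.aggregate_allergen_expression(hits, tpm)
    _write(matrix.tpm_sum, outdir / "allergen_tpm.tsv", index_label="allergen")
    _write(matrix.rel_abundance, outdir / "rel_abundance.tsv", index_label="allergen")
    logger.info(
        "true-allergen filter: identity > %.1f%%, abundance > %.3f in >= %d samples",
        cfg.id_thresh, cfg.abund_thresh, cfg.min_samples,
    )
    retained = profiling.filter_true_allergens(
        matrix, id_thresh=cfg.id_thresh, abund_thresh=cfg.abund_thresh,
        min_samples=cfg.min_samples,
    )
    (outdir / "true_allergens.txt").write_text("\n".join(retained) + "\n", encoding="utf-8")
    order, cumulative = profiling.top_allergens(matrix, k=6)
    _write(
        pd.DataFrame({"sample": cumulative.index, "top6_share": cumulative.to_numpy()}),
        outdir / "top6_share.tsv", index=False,
    )
    iso_rows = []
    for name in matrix.allergens:
        for sample in matrix.samples:
            try:
                ranking = profiling.rank_isoforms(hits, tpm, name, sample)
            except (ValueError, KeyError):
                continue
            for rank, (tid, val) in enumerate(zip(ranking.transcript_ids, ranking.tpms), 1):
                if val > 0:
                    iso_rows.append(
                        {"allergen": name, "sample": sample, "rank": rank,
                         "transcript": tid, "tpm": val}
                    )
    _write(pd.DataFrame(iso_rows), outdir / "isoforms.tsv", index=False)

    fish_rel = profiling.fish_means(matrix.rel_abundance)
    grouping = profiling.cluster_fish(fish_rel)
    _write(grouping.correlation, outdir / "corr_matrix.tsv", index_label="fish")
    _write(
        pd.DataFrame(sorted(grouping.labels.items()), columns=["fish", "group"]),
        outdir / "groups.tsv", index=False,
    )
    return {
        "n_allergens": len(matrix.allergens),
        "n_true_allergens": len(retained),
        "top_allergen": order[0] if order else None,
        "groups": {g: sorted(f for f, gg in grouping.labels.items() if gg == g)
                   for g in ("PV-high", "PV-low")},
    }


def _stage_conserve(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    msa = read_fasta(cfg.inputs["msa"], alphabet="aligned-protein")
    profile = conservation.conservation_profile(msa, columns=cfg.conservation_columns)
    scores, freqs = conservation.profile_to_frames(profile)
    _write(scores, outdir / "conservation_scores.tsv", index=False)
    _write(freqs, outdir / "column_freqs.tsv", index=False)
    (outdir / "consensus.fasta").write_text(
        ">consensus\n" + "\n".join(
            profile.consensus[i : i + 60] for i in range(0, len(profile.consensus), 60)
        ) + "\n",
        encoding="utf-8",
    )
    return {
        "n_sequences": len(profile.msa_ids),
        "consensus_length": len(profile.consensus),
        "score_range": [float(scores["conservation_score"].min()),
                        float(scores["conservation_score"].max())],
    }


def _stage_serology(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    cohort = read_cohort(cfg.inputs["sige"], cfg.inputs["ofc"])
    logger.info("sensitization cutoff: sIgE > %.2f kUA/L", cfg.sige_cutoff)
    sensitized = serology.sensitization_filter(cohort, cutoff=cfg.sige_cutoff)
    sige_corr = serology.sige_correlation_matrix(sensitized, transform=cfg.sige_transform)
    _write(sige_corr, outdir / "sige_corr.tsv", index_label="analyte")

    expr_corr = pd.read_csv(outdir / "corr_matrix.tsv", sep="\t", index_col=0)
    groups_df = pd.read_csv(outdir / "groups.tsv", sep="\t")
    groups = dict(zip(groups_df["fish"], groups_df["group"]))
    pairs = serology.pair_correlations(expr_corr, sige_corr, groups)
    _write(serology.pairs_to_frame(pairs), outdir / "pairs.tsv", index=False)
    w_stat, p_wb = serology.within_between_test(pairs)
    assoc = serology.expression_sige_association(pairs)
    return {
        "n_subjects": len(cohort.subjects),
        "n_sensitized": len(sensitized.subjects),
        "within_between_W": w_stat,
        "within_between_p": p_wb,
        "association_r": assoc.pearson_r,
        "association_p": assoc.p_value,
        "association_slope": assoc.slope,
        "n_pairs": assoc.n_pairs,
    }


def _stage_diagnose(cfg: RunConfig, outdir: Path) -> dict[str, Any]:
    cohort = read_cohort(cfg.inputs["sige"], cfg.inputs["ofc"])
    cohort = serology.sensitization_filter(cohort, cutoff=cfg.sige_cutoff)
    summary: dict[str, Any] = {}
    for fish in cfg.ofc_targets:
        report = diagnostics.panel_evaluation(
            cohort, fish, max_size=cfg.max_subset_size
        )
        _write(report.single_auc, outdir / f"auc_single_{fish}.tsv", index=False)
        with_t = report.with_target.to_frame().assign(panel="with_target")
        without_t = report.without_target.to_frame().assign(panel="without_target")
        _write(pd.concat([with_t, without_t]), outdir / f"subsets_{fish}.tsv", index=False)
        summary[fish] = {
            "n_subjects": report.n_subjects,
            "n_allergic": report.n_allergic,
            "target_auc": report.target_auc,
            "best_single": report.single_auc.iloc[0]["analyte"],
            "best_single_auc": float(report.single_auc.iloc[0]["auc"]),
            "max_panel_auc": max(report.with_target.aucs),
        }
    return summary


_STAGES = [
    ("scan", _stage_scan),
    ("profile", _stage_profile),
    ("conserve", _stage_conserve),
    ("serology", _stage_serology),
    ("diagnose", _stage_diagnose),
]


def run_all(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage in order; returns (and writes) the run report.

    A stage failure aborts the run with :class:`StageError` naming the
    stage.  With fixed config and seed, re-running yields byte-identical
    result tables.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": cfg.seed, "stages": {}}
    stages = ([("simulate", _stage_simulate)] if cfg.synthetic else []) + _STAGES
    for name, fn in stages:
        logger.info("stage %s starting", name)
        try:
            report["stages"][name] = fn(cfg, outdir)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise StageError(name, exc) from exc
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
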