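"""End-to-end synthetic pipeline driver.

Runs simulate -> phenotype -> pqtl-screen -> carrier-screen ->
protective-screen on one seed and emits a single JSON report whose every
number is recomputable from the stage files written alongside it.  Reports
contain no timestamps, so identical config and seed give byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .carrier_screen import CarrierProfile, call_phenotype_reliability, find_modifier_hits
from .io import (
    read_phenotype_table,
    read_variant_calls,
    write_group_table,
    write_phenotype_report,
    write_phenotype_table,
    write_summary_stats,
    write_vcf,
    read_summary_stats,
)
from .phenotyping import GenotypeModel, phenotype_cohort
from .pqtl_screen import (
    ScreenThresholds,
    bonferroni_select,
    filter_candidates,
    large_effect_subset,
    summarize_genes,
)
from .protective_screen import RecurrenceWindow, run_protective_screen
from .synth_cohort import (
    CohortConfig,
    PlantedEffect,
    generate_assay_panel,
    generate_cohort,
    generate_genotype_matrix,
    generate_pqtl_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


DEFAULT_PLANTED = (
    PlantedEffect("mut00001", "GENENEG", beta=-1.217, carrier_fraction=0.015),
    PlantedEffect("mut00002", "GENEPOS", beta=1.100, carrier_fraction=0.02),
)


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    n_individuals: int = 2000
    n_null_pqtl: int = 2000
    pqtl_n_samples: int = 35_559
    n_high: int = 15
    n_low: int = 44
    n_background_variants: int = 200
    planted_exclusive: int = 42
    missing_rate: float = 0.0
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    window: RecurrenceWindow = field(default_factory=RecurrenceWindow)
    max_missing: float = 0.05
    min_maf: float = 0.05
    maf_before_exclusive: bool = False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline; returns the run report dict and
    writes it (plus every stage file) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # -- simulate --------------------------------------------------------
    stage = "simulate"
    try:
        cohort_cfg = CohortConfig(n_individuals=config.n_individuals, seed=config.seed)
        cohort = generate_assay_panel(generate_cohort(cohort_cfg), cohort_cfg)
        from .phenotyping import PhenotypeRecord

        records = [
            PhenotypeRecord(
                sample_id=i.sample_id,
                id_genotype=i.id_genotype,
                y215c_copies=i.y215c_copies,
                assay_9b9=i.assay_9b9,
                assay_1g12=i.assay_1g12,
                assay_5b3=i.assay_5b3,
            )
            for i in cohort
        ]
        write_phenotype_table(records, out / "phenotypes.tsv")

        stats_table = generate_pqtl_table(
            config.n_null_pqtl,
            list(DEFAULT_PLANTED),
            n_samples=config.pqtl_n_samples,
            seed=config.seed,
        )
        write_summary_stats(stats_table, out / "summary_stats.tsv")

        matrix = generate_genotype_matrix(
            n_high=config.n_high,
            n_low=config.n_low,
            n_background_variants=config.n_background_variants,
            planted_exclusive=config.planted_exclusive,
            recurrence_range=(config.window.min_carriers, config.window.max_carriers),
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        write_vcf(matrix, out / "genotypes.vcf")
        write_group_table(matrix.group, out / "groups.tsv")
        report["stages"][stage] = {
            "n_individuals": len(cohort),
            "n_summary_stats": len(stats_table),
            "n_variants": matrix.n_variants,
            "n_planted_exclusive": config.planted_exclusive,
        }
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise PipelineError(stage, str(exc)) from exc

    # -- phenotype -------------------------------------------------------
    stage = "phenotype"
    try:
        records = read_phenotype_table(out / "phenotypes.tsv")
        controls = [r for r in records if r.y215c_copies == 0]
        control_sets = {
            name: [getattr(r, name) for r in controls if getattr(r, name) is not None]
            for name in ("assay_9b9", "assay_1g12", "assay_5b3")
        }
        model = GenotypeModel()
        phenotypes = phenotype_cohort(records, control_sets, model)
        write_phenotype_report(phenotypes, out / "phenotype_report.tsv")
        bins: dict[str, int] = {}
        for p in phenotypes:
            bins[p.bin] = bins.get(p.bin, 0) + 1
        report["stages"][stage] = {
            "n_phenotyped": len(phenotypes),
            "n_controls": len(controls),
            "bin_counts": dict(sorted(bins.items())),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- pqtl screen -----------------------------------------------------
    stage = "pqtl-screen"
    try:
        stats_records = read_summary_stats(out / "summary_stats.tsv")
        candidates = filter_candidates(stats_records, config.thresholds)
        shortlist = bonferroni_select(candidates, config.thresholds)
        large = large_effect_subset(candidates, config.thresholds)
        summary = summarize_genes(shortlist)
        write_summary_stats(candidates, out / "refined_list.tsv")
        report["stages"][stage] = {
            "n_input": len(stats_records),
            "n_candidates": len(candidates),
            "n_bonferroni": len(shortlist),
            "n_large_effect": len(large),
            "n_genes": summary.n_genes,
            "thresholds": {
                "nominal_p": config.thresholds.nominal_p,
                "beta_abs_min": config.thresholds.beta_abs_min,
                "bonferroni_p": config.thresholds.bonferroni_p,
                "large_beta_abs": config.thresholds.large_beta_abs,
            },
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- carrier screen --------------------------------------------------
    stage = "carrier-screen"
    try:
        matrix = read_variant_calls(out / "genotypes.vcf")
        pheno_by_id = {p.sample_id: p for p in phenotypes}
        carriers = [r for r in records if r.y215c_copies > 0]
        calls: dict[str, int] = {}
        for r in carriers:
            hits = (
                find_modifier_hits(matrix, r.sample_id, candidates)
                if r.sample_id in matrix.sample_ids
                else []
            )
            profile = CarrierProfile(
                sample_id=r.sample_id,
                phenotype=pheno_by_id.get(r.sample_id),
                modifier_hits=hits,
            )
            call = call_phenotype_reliability(profile).call
            calls[call] = calls.get(call, 0) + 1
        report["stages"][stage] = {
            "n_carriers": len(carriers),
            "reliability_calls": dict(sorted(calls.items())),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- protective screen -----------------------------------------------
    stage = "protective-screen"
    try:
        from .io import read_group_table

        matrix.group = read_group_table(out / "groups.tsv")
        results, recurrent, screen_report = run_protective_screen(
            matrix,
            max_missing=config.max_missing,
            min_maf=config.min_maf,
            window=config.window,
            maf_before_exclusive=config.maf_before_exclusive,
        )
        planted_ids = {v for v in matrix.variant_ids if v.startswith("ex")}
        recovered = {r.variant_id for r in recurrent}
        report["stages"][stage] = {
            "n_tested": screen_report.n_tested,
            "lambda_gc": round(screen_report.lambda_gc, 6)
            if screen_report.n_tested
            else None,
            "n_exclusive": screen_report.n_exclusive,
            "n_recurrent": screen_report.n_recurrent,
            "n_recurrent_genes": screen_report.n_recurrent_genes,
            "n_planted": len(planted_ids),
            "n_planted_recovered": len(planted_ids & recovered),
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
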