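"""End-to-end pipeline: score, test, summarise and report.

``run_pipeline`` takes hemisegment/lumen tables (from files or presets)
plus a list of pairwise genotype comparisons and writes four tidy reports:

* ``cohort_fractions.csv`` — pooled defect fractions per genotype x class x range;
* ``permutation_tests.csv`` — pairwise randomization-test results;
* ``segment_summaries.csv`` — per-segment CC summaries (A2/A8, both lineages)
  with Welch tests and BCa intervals against the first (reference) genotype;
* ``lumen_comparisons.csv`` — heart-proper vs posterior-aorta Welch tests.

plus a human-readable ``summary.txt``.  The pipeline is a pure function of
(inputs, config): reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, Field

from .classical import bca_mean_difference_ci, compare_region_widths, one_way_anova, welch_t_test
from .permutation import compare_genotypes
from .scoring import DefectClass, cohort_defect_fraction, segment_cc_values
from .tables import EmbryoTable, LumenMeasurement, read_hemisegment_table, read_lumen_table
from .simulate import generate_embryo_table, preset_configs

log = logging.getLogger("heartscore")


class Comparison(BaseModel):
    genotype_a: str  # reference (indicator 0)
    genotype_b: str
    defect_class: DefectClass
    segment_range: str = "A2_A8"


class RunConfig(BaseModel):
    """Declarative configuration of one full pipeline run."""

    presets: List[str] = Field(default_factory=list)  # synthetic inputs by preset name
    hemisegment_table: Optional[str] = None  # or a real table on disk
    lumen_table: Optional[str] = None
    comparisons: List[Comparison] = Field(default_factory=list)
    n_permutations: int = Field(10_000, ge=1)
    seed: int = 0
    alternative: str = "two_sided"
    segment_summaries: List[Tuple[str, str]] = Field(
        default_factory=lambda: [("A2", "svp"), ("A2", "tin"), ("A8", "svp"), ("A8", "tin")]
    )
    output_dir: str = "results"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> Tuple[EmbryoTable, List[LumenMeasurement]]:
    tables: List[EmbryoTable] = []
    lumen: List[LumenMeasurement] = []
    if config.presets:
        known = preset_configs()
        for i, name in enumerate(config.presets):
            if name not in known:
                raise ValueError(f"unknown preset {name!r}; available: {sorted(known)}")
            bundle = generate_embryo_table(known[name], seed=config.seed + i)
            tables.append(bundle.table)
            lumen.extend(bundle.lumen)
    if config.hemisegment_table:
        tables.append(read_hemisegment_table(config.hemisegment_table))
    if config.lumen_table:
        lumen.extend(read_lumen_table(config.lumen_table))
    if not tables:
        raise ValueError("no inputs: give presets and/or a hemisegment table path")
    table = tables[0]
    for t in tables[1:]:
        table = table.extend(t)
    return table, lumen


def _validate(config: RunConfig, table: EmbryoTable) -> None:
    present = set(table.genotypes())
    for cmp in config.comparisons:
        for g in (cmp.genotype_a, cmp.genotype_b):
            if g not in present:
                raise ValueError(
                    f"comparison references genotype {g!r} absent from input (present: {sorted(present)})"
                )


def run_pipeline(config: RunConfig) -> Dict[str, pd.DataFrame]:
    """Execute the full analysis; returns the report frames and writes them
    (plus summary.txt) under ``config.output_dir``."""
    table, lumen = _load_inputs(config)
    _validate(config, table)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("run config hash %s; genotypes %s", chash, table.genotypes())

    # (a) cohort defect fractions
    frac_rows = []
    for genotype in table.genotypes():
        for dclass in DefectClass:
            for rng_name in ("A2_A8", "A3_A8"):
                f = cohort_defect_fraction(table, genotype, dclass, rng_name)
                frac_rows.append(
                    {
                        "genotype": genotype,
                        "defect_class": dclass.value,
                        "segment_range": rng_name,
                        "n_embryos": len(table.embryo_ids(genotype)),
                        "defective": f.defective,
                        "scored": f.scored,
                        "fraction": f.fraction,
                    }
                )
    fractions = pd.DataFrame(frac_rows)

    # (b) pairwise permutation tests
    test_rows = []
    for k, cmp in enumerate(config.comparisons):
        seed_k = config.seed * 10_000 + k  # per-comparison substream, logged
        res = compare_genotypes(
            table,
            cmp.genotype_a,
            cmp.genotype_b,
            cmp.defect_class,
            cmp.segment_range,
            n_permutations=config.n_permutations,
            seed=seed_k,
            alternative=config.alternative,
        )
        log.info(
            "permutation %s vs %s [%s, %s]: beta1=%.4f p=%.6g (N=%d, seed=%d)",
            cmp.genotype_a, cmp.genotype_b, cmp.defect_class.value, cmp.segment_range,
            res.observed_beta1, res.p_value, res.n_permutations, seed_k,
        )
        test_rows.append(
            {
                "genotype_a": cmp.genotype_a,
                "genotype_b": cmp.genotype_b,
                "defect_class": cmp.defect_class.value,
                "segment_range": cmp.segment_range,
                "beta1": res.observed_beta1,
                "n_permutations": res.n_permutations,
                "n_exceed": res.n_exceed,
                "p_value": res.p_value,
                "alternative": res.alternative,
                "seed": seed_k,
            }
        )
    tests = pd.DataFrame(test_rows)

    # (c) segment CC summaries with classical stats vs the reference genotype
    genotypes = table.genotypes()
    ref = genotypes[0]
    seg_rows = []
    for segment, lineage in config.segment_summaries:
        per_geno = {g: segment_cc_values(table, g, segment, lineage) for g in genotypes}
        groups = [v for v in per_geno.values() if len(v) >= 2]
        anova_p = None
        if len(groups) >= 2:
            try:
                anova_p = one_way_anova(groups).p_value
            except ValueError:
                anova_p = None  # degenerate within-group variance
        for g in genotypes:
            vals = per_geno[g]
            if not vals:
                continue
            row = {
                "segment": segment,
                "lineage": lineage,
                "genotype": g,
                "n_segments": len(vals),
                "mean": round(float(pd.Series(vals).mean()), 1),
                "sd": float(pd.Series(vals).std(ddof=1)),
                "anova_p_all_genotypes": anova_p,
                "welch_p_vs_ref": None,
                "bca_diff_low": None,
                "bca_diff_high": None,
            }
            if g != ref and len(vals) >= 3 and len(per_geno[ref]) >= 3:
                try:
                    row["welch_p_vs_ref"] = welch_t_test(vals, per_geno[ref]).p_value
                except ValueError:
                    pass
                ci = bca_mean_difference_ci(vals, per_geno[ref], n_boot=5000, seed=config.seed)
                if not ci.degenerate:
                    row["bca_diff_low"] = ci.lower
                    row["bca_diff_high"] = ci.upper
            seg_rows.append(row)
    segments = pd.DataFrame(seg_rows)

    # (d) lumen region comparison per genotype
    lumen_rows = []
    lumen_genotypes = sorted({m.genotype for m in lumen})
    for g in lumen_genotypes:
        res = compare_region_widths(lumen, g)
        lumen_rows.append(
            {
                "genotype": g,
                "n_embryos": res.n_x,
                "heart_proper_mean_um": res.mean_x,
                "posterior_aorta_mean_um": res.mean_y,
                "welch_t": res.statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
            }
        )
    lumen_df = pd.DataFrame(lumen_rows)

    reports = {
        "cohort_fractions": fractions,
        "permutation_tests": tests,
        "segment_summaries": segments,
        "lumen_comparisons": lumen_df,
    }
    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    _write_summary(outdir / "summary.txt", config, chash, reports)
    return reports


def _write_summary(path: Path, config: RunConfig, chash: str, reports: Dict[str, pd.DataFrame]) -> None:
    lines = [
        f"heartscore pipeline report (config hash {chash}, seed {config.seed}, "
        f"N={config.n_permutations} permutations)",
        "",
    ]
    for name, df in reports.items():
        lines.append(f"== {name} ==")
        lines.append(df.to_string(index=False) if len(df) else "(empty)")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
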