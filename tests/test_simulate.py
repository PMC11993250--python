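"""Statistical and contractual properties of the synthetic cohort generator."""

import io
import math

import numpy as np
import pytest
from pydantic import ValidationError

from heartscore import (
    DefectClass,
    PhenotypeConfig,
    RateModel,
    classify_hemisegment,
    cohort_defect_fraction,
    cohort_responses,
    generate_embryo_table,
    generate_lumen_table,
    generate_null_pair,
    preset_configs,
    read_hemisegment_table,
    write_hemisegment_table,
)
from heartscore.simulate import LumenModel, MagnitudeModel


def _defect_matrix(table, genotype, dclass):
    """embryos x hemisegments binary defect indicators (complete cohorts)."""
    rows = []
    for r in cohort_responses(table, genotype, dclass, "A2_A8"):
        recs = table.select(genotype=genotype, embryo_id=r.embryo_id)
        rows.append([classify_hemisegment(rec).has(dclass) for rec in recs])
    return np.array(rows, dtype=float)


def anova_icc(matrix: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation ICC(1) over embryo clusters."""
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((matrix - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestDeterminism:
    def test_bit_identical_regeneration(self):
        cfg = preset_configs()["trr_like"]
        a = generate_embryo_table(cfg, seed=99)
        b = generate_embryo_table(cfg, seed=99)
        assert a.table.records == b.table.records
        assert a.lumen == b.lumen

    def test_extending_a_cohort_preserves_existing_embryos(self):
        cfg = preset_configs()["trr_like"]
        small = generate_embryo_table(cfg.model_copy(update={"n_embryos": 5}), seed=7)
        large = generate_embryo_table(cfg.model_copy(update={"n_embryos": 10}), seed=7)
        small_ids = set(r.embryo_id for r in small.table)
        assert [r for r in large.table if r.embryo_id in small_ids] == list(small.table)


class TestGeneratedStructure:
    def test_wild_type_cohort_is_complete_and_defect_free(self, wild_bundle):
        assert len(wild_bundle.table) == 15 * 14
        for dclass in DefectClass:
            assert cohort_defect_fraction(wild_bundle.table, "wild_type", dclass).defective == 0

    def test_penetrant_a2_single_svp(self, trx_bundle):
        a2 = trx_bundle.table.select(segments=("A2",))
        assert len(a2) == 30
        assert all(r.svp_count == 1 for r in a2)

    def test_tables_pass_io_validation_round_trip(self):
        bundle = generate_embryo_table(preset_configs()["set1_like"], seed=3)
        buf = io.StringIO()
        write_hemisegment_table(bundle.table, buf)
        back = read_hemisegment_table(io.StringIO(buf.getvalue()))
        assert back.records == bundle.table.records

    def test_missingness_removes_records(self):
        cfg = preset_configs()["wild_type"].model_copy(update={"missingness": 0.2})
        bundle = generate_embryo_table(cfg, seed=5)
        assert len(bundle.table) < 210

    def test_counts_clamped_non_negative(self):
        cfg = PhenotypeConfig(
            genotype="g",
            n_embryos=30,
            symmetric=RateModel(mean=0.9, icc=0.0),
            asymmetric=RateModel(mean=0.9, icc=0.0),
            symmetric_magnitude=MagnitudeModel(probs={-4: 1.0}),
            asymmetric_magnitude=MagnitudeModel(probs={-4: 1.0}),
        )
        bundle = generate_embryo_table(cfg, seed=1)
        assert all(r.svp_count >= 0 and r.tin_count >= 0 for r in bundle.table)

    def test_svp_capped_unless_supernumerary_allowed(self):
        base = dict(
            genotype="g", n_embryos=30,
            asymmetric=RateModel(mean=1.0, icc=0.0),
            asymmetric_magnitude=MagnitudeModel(probs={2: 1.0}),
        )
        capped = generate_embryo_table(PhenotypeConfig(**base), seed=2)
        assert max(r.svp_count for r in capped.table) == 4
        free = generate_embryo_table(
            PhenotypeConfig(**base, svp_supernumerary_allowed=True), seed=2
        )
        assert max(r.svp_count for r in free.table) >= 4


class TestBetaBinomialCalibration:
    def test_marginal_defect_fraction_matches_mean_rate(self):
        m = 0.2
        cfg = PhenotypeConfig(genotype="g", n_embryos=500, symmetric=RateModel(mean=m, icc=0.3))
        bundle = generate_embryo_table(cfg, seed=13)
        frac = cohort_defect_fraction(bundle.table, "g", DefectClass.SYMMETRIC).fraction
        se = math.sqrt(m * (1 - m) / (500 * 14)) * math.sqrt(1 + 13 * 0.3)  # design effect
        assert abs(frac - m) <= 3 * se

    def test_intra_embryo_correlation_matches_icc(self):
        rho = 0.3
        cfg = PhenotypeConfig(genotype="g", n_embryos=500, symmetric=RateModel(mean=0.3, icc=rho))
        bundle = generate_embryo_table(cfg, seed=17)
        mat = _defect_matrix(bundle.table, "g", DefectClass.SYMMETRIC)
        assert anova_icc(mat) == pytest.approx(rho, abs=0.05)

    def test_zero_icc_gives_binomial_variance(self):
        m = 0.3
        cfg = PhenotypeConfig(genotype="g", n_embryos=800, symmetric=RateModel(mean=m, icc=0.0))
        bundle = generate_embryo_table(cfg, seed=19)
        props = np.array([r.proportion for r in cohort_responses(bundle.table, "g", DefectClass.SYMMETRIC)])
        expected_var = m * (1 - m) / 14
        # chi-square spread of a sample variance at n=800: ~3 relative SE
        assert props.var(ddof=1) == pytest.approx(expected_var, rel=0.25)

    def test_null_pair_shares_the_generative_process(self):
        cfg = PhenotypeConfig(genotype="null", n_embryos=200, symmetric=RateModel(mean=0.15, icc=0.2))
        a, b = generate_null_pair(cfg, 200, 200, seed=23)
        fa = cohort_defect_fraction(a.table, a.config.genotype, DefectClass.SYMMETRIC).fraction
        fb = cohort_defect_fraction(b.table, b.config.genotype, DefectClass.SYMMETRIC).fraction
        assert abs(fa - fb) < 0.05


class TestLumenGenerator:
    def test_zero_sd_is_exact(self):
        cfg = PhenotypeConfig(
            genotype="g", n_embryos=4,
            lumen=LumenModel(aorta_mean=0.66, aorta_sd=0.0, heart_mean=2.18, heart_sd=0.0),
        )
        ms = generate_lumen_table(cfg, seed=0)
        assert all(m.diameter == 0.66 for m in ms if m.position in ("A2", "A3", "A4"))
        assert all(m.diameter == 2.18 for m in ms if m.position in ("A6", "A7"))

    def test_diameters_positive_even_for_noisy_narrow_lumen(self):
        cfg = PhenotypeConfig(
            genotype="g", n_embryos=50,
            lumen=LumenModel(aorta_mean=0.2, aorta_sd=0.3, heart_mean=0.2, heart_sd=0.3),
        )
        assert all(m.diameter > 0 for m in generate_lumen_table(cfg, seed=1))

    def test_seeded_determinism(self):
        cfg = preset_configs()["wild_type"]
        assert generate_lumen_table(cfg, seed=4) == generate_lumen_table(cfg, seed=4)


class TestPresets:
    def test_preset_names_are_stable(self):
        assert set(preset_configs()) == {"wild_type", "trx_like", "trr_like", "set1_like"}

    def test_trx_preset_phenotype_flags(self):
        cfg = preset_configs()["trx_like"]
        assert cfg.a2_single_svp_penetrance == 1.0
        assert cfg.a8_tin_surplus is not None
        assert cfg.asymmetric.mean == 0.0 and cfg.symmetric.mean > 0

    def test_trr_and_set1_elevate_both_classes(self):
        cfgs = preset_configs()
        for name in ("trr_like", "set1_like"):
            assert cfgs[name].symmetric.mean > 0
            assert cfgs[name].asymmetric.mean > 0
            assert cfgs[name].svp_supernumerary_allowed


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(symmetric=dict(mean=1.5)),
            dict(symmetric=dict(mean=0.1, icc=1.0)),
            dict(a2_single_svp_penetrance=2.0),
            dict(segments=["A9"]),
            dict(a8_tin_surplus={1: 0.5}),  # probabilities must sum to 1
            dict(lumen=dict(aorta_mean=-1.0)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises((ValidationError, ValueError)):
            PhenotypeConfig(genotype="g", **kwargs)
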