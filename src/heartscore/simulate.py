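"""Synthetic cohort generator.

Emulates the structure of a per-hemisegment scoring spreadsheet: bilateral
A2-A8 hemisegment CC counts for a cohort of embryos of one genotype, with
the two statistical features the downstream analysis depends on:

* **within-embryo correlation of defects** — each embryo draws a per-class
  defect probability from a Beta distribution with mean ``m`` and
  intra-class correlation ``rho`` (shapes a = m(1-rho)/rho,
  b = (1-m)(1-rho)/rho; rho = 0 degenerates to a shared fixed rate), then
  each hemisegment's defect indicator is Bernoulli at the embryo's rate —
  the classic beta-binomial clustering model with ICC rho = 1/(a+b+1);
* **deterministic genotype-specific phenotypes** — applied after the
  stochastic defects so penetrance-1 phenotypes are exact: the A2
  single-Svp reduction (svp_count forced to 1) and a distribution of
  supernumerary Tin CCs added in A8.

Each embryo uses an independent substream derived from (seed, domain,
embryo index), so enlarging a cohort never perturbs the embryos already
generated, and regeneration from (config, seed) is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .blueprint import ROWS, SEGMENTS, reference_blueprint
from .tables import EmbryoTable, HemisegmentRecord, LumenMeasurement


class RateModel(BaseModel):
    """Per-defect-class beta-binomial rate: mean defect rate and
    intra-embryo correlation."""

    mean: float = Field(0.0, ge=0.0, le=1.0)
    icc: float = Field(0.0, ge=0.0, lt=1.0)

    def draw_embryo_rate(self, rng: np.random.Generator) -> float:
        m, rho = self.mean, self.icc
        if rho == 0.0 or m in (0.0, 1.0):
            return m
        a = m * (1 - rho) / rho
        b = (1 - m) * (1 - rho) / rho
        return float(rng.beta(a, b))


class MagnitudeModel(BaseModel):
    """Distribution of the signed count deviation given that a defect
    occurred (support: nonzero integers)."""

    probs: Dict[int, float] = Field(default_factory=lambda: {1: 0.4, -1: 0.4, 2: 0.1, -2: 0.1})

    @field_validator("probs")
    @classmethod
    def _check(cls, v):
        if not v:
            raise ValueError("magnitude distribution is empty")
        if 0 in v:
            raise ValueError("a defect magnitude of 0 is not a defect")
        if any(p < 0 for p in v.values()):
            raise ValueError("negative probability")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"magnitude probabilities sum to {total}, not 1")
        return v

    def draw(self, rng: np.random.Generator) -> int:
        deltas = sorted(self.probs)
        p = np.array([self.probs[d] for d in deltas])
        return int(rng.choice(deltas, p=p / p.sum()))


class AnteriorModel(BaseModel):
    """Anterior-aorta CC count per row: rounded normal, clamped >= 0."""

    mean: float = Field(12.0, ge=0)
    sd: float = Field(0.0, ge=0)

    def draw(self, rng: np.random.Generator) -> int:
        return max(0, int(round(rng.normal(self.mean, self.sd)))) if self.sd > 0 else int(round(self.mean))


class LumenModel(BaseModel):
    """Region lumen-diameter model (µm); draws truncated at 0."""

    aorta_mean: float = Field(0.66, gt=0)
    aorta_sd: float = Field(0.1, ge=0)
    heart_mean: float = Field(2.18, gt=0)
    heart_sd: float = Field(0.1, ge=0)

    def draw(self, rng: np.random.Generator, region: str) -> float:
        mean, sd = (
            (self.aorta_mean, self.aorta_sd) if region == "aorta" else (self.heart_mean, self.heart_sd)
        )
        if sd == 0:
            return mean
        while True:  # truncate at 0; negligible mass there for sane params
            d = float(rng.normal(mean, sd))
            if d > 0:
                return d


class PhenotypeConfig(BaseModel):
    """Full generator configuration for one genotype's cohort."""

    genotype: str
    n_embryos: int = Field(15, ge=1)
    segments: Tuple[str, ...] = SEGMENTS
    rows: Tuple[str, ...] = ROWS
    symmetric: RateModel = RateModel()  # Tin-count defects
    asymmetric: RateModel = RateModel()  # Svp-count defects
    symmetric_magnitude: MagnitudeModel = MagnitudeModel()
    asymmetric_magnitude: MagnitudeModel = MagnitudeModel()
    a2_single_svp_penetrance: float = Field(0.0, ge=0.0, le=1.0)
    a8_tin_surplus: Optional[Dict[int, float]] = None  # distribution over added Tin CCs
    svp_supernumerary_allowed: bool = False  # cap svp_count at 4 when False
    anterior: AnteriorModel = AnteriorModel()
    lumen: LumenModel = LumenModel()
    missingness: float = Field(0.0, ge=0.0, lt=1.0)
    seed: Optional[int] = None

    @field_validator("segments", "rows", mode="before")
    @classmethod
    def _tupled(cls, v):
        return tuple(v)

    @model_validator(mode="after")
    def _check_labels(self):
        bad = [s for s in self.segments if s not in SEGMENTS]
        if bad:
            raise ValueError(f"unknown segments {bad}")
        bad = [r for r in self.rows if r not in ROWS]
        if bad:
            raise ValueError(f"unknown rows {bad}")
        if self.a8_tin_surplus is not None:
            if any(k < 0 for k in self.a8_tin_surplus):
                raise ValueError("A8 Tin surplus must be non-negative")
            total = sum(self.a8_tin_surplus.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"A8 surplus probabilities sum to {total}, not 1")
        return self


@dataclass
class CohortBundle:
    """One generated cohort: the hemisegment table, its lumen measurements,
    the generating config and the master seed actually used."""

    table: EmbryoTable
    lumen: List[LumenMeasurement]
    config: PhenotypeConfig
    seed: int


def _rng(seed: int, domain: int, index: int) -> np.random.Generator:
    # independent named substream; domain 0 = counts, 1 = lumen
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(domain, index)))


def _draw_surplus(dist: Dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys])
    return int(rng.choice(keys, p=p / p.sum()))


def _generate_embryo(
    config: PhenotypeConfig, embryo_id: str, rng: np.random.Generator
) -> List[HemisegmentRecord]:
    bp = reference_blueprint()
    p_sym = config.symmetric.draw_embryo_rate(rng)
    p_asym = config.asymmetric.draw_embryo_rate(rng)
    anterior = {row: config.anterior.draw(rng) for row in config.rows}
    records: List[HemisegmentRecord] = []
    for row in config.rows:
        for segment in config.segments:
            # draw everything before applying missingness so the per-record
            # stream layout is independent of which records survive
            tin = bp.expected_tin[segment]
            svp = bp.expected_svp[segment]
            if rng.random() < p_sym:
                tin = max(0, tin + config.symmetric_magnitude.draw(rng))
            if rng.random() < p_asym:
                svp = svp + config.asymmetric_magnitude.draw(rng)
                svp = max(0, svp if config.svp_supernumerary_allowed else min(svp, 4))
            # deterministic phenotypes override stochastic defects
            if segment == "A2" and config.a2_single_svp_penetrance > 0:
                if config.a2_single_svp_penetrance >= 1.0 or rng.random() < config.a2_single_svp_penetrance:
                    svp = 1
            if segment == "A8" and config.a8_tin_surplus is not None:
                tin = bp.expected_tin["A8"] + _draw_surplus(config.a8_tin_surplus, rng)
            missing = config.missingness > 0 and rng.random() < config.missingness
            if missing:
                continue
            records.append(
                HemisegmentRecord(
                    genotype=config.genotype,
                    embryo_id=embryo_id,
                    row=row,
                    segment=segment,
                    svp_count=svp,
                    tin_count=tin,
                    anterior_cc_count=anterior[row] if segment == "A2" else None,
                )
            )
    return records


def generate_embryo_table(config: PhenotypeConfig, seed: Optional[int] = None) -> CohortBundle:
    """Generate a full cohort (hemisegment table + lumen table)."""
    master = seed if seed is not None else (config.seed if config.seed is not None else 0)
    records: List[HemisegmentRecord] = []
    for i in range(config.n_embryos):
        embryo_id = f"{config.genotype}_e{i + 1:03d}"
        records.extend(_generate_embryo(config, embryo_id, _rng(master, 0, i)))
    table = EmbryoTable(records=records, provenance=f"synthetic:{config.genotype}:seed={master}")
    lumen = generate_lumen_table(config, seed=master)
    return CohortBundle(table=table, lumen=lumen, config=config, seed=master)


def generate_lumen_table(config: PhenotypeConfig, seed: Optional[int] = None) -> List[LumenMeasurement]:
    """Five positive diameters per embryo: A2-A4 from the posterior-aorta
    distribution, A6-A7 from the heart-proper distribution."""
    master = seed if seed is not None else (config.seed if config.seed is not None else 0)
    out: List[LumenMeasurement] = []
    for i in range(config.n_embryos):
        rng = _rng(master, 1, i)
        embryo_id = f"{config.genotype}_e{i + 1:03d}"
        for pos in ("A2", "A3", "A4"):
            out.append(LumenMeasurement(config.genotype, embryo_id, pos, config.lumen.draw(rng, "aorta")))
        for pos in ("A6", "A7"):
            out.append(LumenMeasurement(config.genotype, embryo_id, pos, config.lumen.draw(rng, "heart")))
    return out


def generate_null_pair(
    config: PhenotypeConfig, n_a: int, n_b: int, seed: int
) -> Tuple[CohortBundle, CohortBundle]:
    """Two cohorts from the identical generative process (labels aside);
    the harness for type-I-error studies."""
    cfg_a = config.model_copy(update={"genotype": f"{config.genotype}_nullA", "n_embryos": n_a})
    cfg_b = config.model_copy(update={"genotype": f"{config.genotype}_nullB", "n_embryos": n_b})
    return (
        generate_embryo_table(cfg_a, seed=seed * 2),
        generate_embryo_table(cfg_b, seed=seed * 2 + 1),
    )


def preset_configs() -> Dict[str, PhenotypeConfig]:
    """Named phenotype presets.

    ``wild_type`` is defect-free with the dilated heart proper (region
    lumen means 0.66 / 2.18 µm).  ``trx_like`` elevates only the symmetric
    (Tin) defect rate, forces the fully penetrant A2 single-Svp phenotype,
    adds supernumerary A8 Tin CCs and loses the heart-proper dilation.
    ``trr_like`` and ``set1_like`` elevate both defect classes and permit
    supernumerary Svp CCs.  ICC values are framework parameters (no
    empirical estimate exists), fixed at 0.3.
    """
    rho = 0.3
    return {
        "wild_type": PhenotypeConfig(
            genotype="wild_type",
            symmetric=RateModel(mean=0.0, icc=rho),
            asymmetric=RateModel(mean=0.0, icc=rho),
            anterior=AnteriorModel(mean=12.2, sd=0.8),
            lumen=LumenModel(aorta_mean=0.66, aorta_sd=0.1, heart_mean=2.18, heart_sd=0.1),
        ),
        "trx_like": PhenotypeConfig(
            genotype="trx_like",
            symmetric=RateModel(mean=0.25, icc=rho),
            asymmetric=RateModel(mean=0.0, icc=rho),
            a2_single_svp_penetrance=1.0,
            a8_tin_surplus={0: 0.1, 1: 0.5, 2: 0.3, 3: 0.1},
            svp_supernumerary_allowed=False,
            anterior=AnteriorModel(mean=12.6, sd=0.9),
            lumen=LumenModel(aorta_mean=0.66, aorta_sd=0.1, heart_mean=0.66, heart_sd=0.1),
        ),
        "trr_like": PhenotypeConfig(
            genotype="trr_like",
            symmetric=RateModel(mean=0.15, icc=rho),
            asymmetric=RateModel(mean=4 / 30, icc=rho),
            svp_supernumerary_allowed=True,
            anterior=AnteriorModel(mean=12.2, sd=0.8),
            lumen=LumenModel(aorta_mean=0.66, aorta_sd=0.1, heart_mean=2.0, heart_sd=0.15),
        ),
        "set1_like": PhenotypeConfig(
            genotype="set1_like",
            symmetric=RateModel(mean=0.15, icc=rho),
            asymmetric=RateModel(mean=7 / 30, icc=rho),
            svp_supernumerary_allowed=True,
            anterior=AnteriorModel(mean=12.2, sd=0.8),
            lumen=LumenModel(aorta_mean=0.66, aorta_sd=0.1, heart_mean=2.0, heart_sd=0.15),
        ),
    }
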