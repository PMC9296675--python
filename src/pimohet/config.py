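"""Simulation and pipeline configuration.

Defaults describe the cohort the package emulates: ~94 prostatectomy
patients with one or two 6 mm index-lesion punch biopsies each, a
whole-mount section per patient, Illumina-style probe expression in two
extraction-kit batches (45 vs 96 samples), ordinal pathologist hypoxia
scores 1-5 from two raters, and exponential time-to-event outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

from .errors import ConfigurationError


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass
class HypoxiaFieldConfig:
    """Spatially correlated hypoxia field inside the index lesion.

    ``target_median_hf`` is the cohort median whole-mount hypoxic fraction
    (default 0.27, the observed median of the emulated cohort).
    ``within_lesion_sd`` sets the weight of the coarse (biopsy-scale) field
    component and thereby the spread of biopsy HF around the whole-mount HF;
    0 gives a spatially fine-grained field so any punch is representative.
    """

    target_median_hf: float = 0.27
    spatial_corr_length_px: float = 16.0
    within_lesion_sd: float = 0.10

    def validate(self) -> None:
        _require(0.0 < self.target_median_hf < 1.0, "hypoxia_field.target_median_hf", "must be in (0, 1)")
        _require(self.spatial_corr_length_px > 0, "hypoxia_field.spatial_corr_length_px", "must be positive")
        _require(0.0 <= self.within_lesion_sd <= 1.0, "hypoxia_field.within_lesion_sd", "must be in [0, 1]")


@dataclass
class StainModelConfig:
    """Optical-density model of pimonidazole (DAB) staining.

    The generating segmentation threshold is the midpoint of the hypoxic and
    background mean ODs.  Per-section stain amplitude varies by the
    multiplicative factor range ``section_scale_range`` (staining-batch
    variation), which is what makes the threshold identifiable from ordinal
    scores during calibration.
    """

    od_hypoxic_mean: float = 0.8
    od_background_mean: float = 0.2
    od_noise_sd: float = 0.02
    section_scale_range: tuple[float, float] = (0.4, 2.0)

    @property
    def od_threshold(self) -> float:
        return 0.5 * (self.od_hypoxic_mean + self.od_background_mean)

    def validate(self) -> None:
        _require(self.od_hypoxic_mean > 0, "stain_model.od_hypoxic_mean", "must be positive")
        _require(self.od_background_mean >= 0, "stain_model.od_background_mean", "must be non-negative")
        _require(
            self.od_hypoxic_mean > self.od_background_mean,
            "stain_model.od_hypoxic_mean",
            "must exceed od_background_mean",
        )
        _require(self.od_noise_sd >= 0, "stain_model.od_noise_sd", "must be non-negative")
        lo, hi = self.section_scale_range
        _require(0 < lo <= hi, "stain_model.section_scale_range", "must satisfy 0 < low <= high")


@dataclass
class ExpressionModelConfig:
    """Probe-level log2 expression model.

    ``effect_size`` is the log2 shift per unit (standardised) latent hypoxia
    on every signature gene; ``kit_offset`` is the additive batch offset of
    kit-A (RNeasy-like) samples on every probe; ``fraction_kit_a`` defaults
    to 45/141 as in the emulated series.  ``n_genes`` defaults to 2000, a
    scaled-down stand-in for a ~47k-transcript array.

    ``local_fraction`` controls what the latent hypoxia driving expression
    tracks: 0 means a purely lesion-wide transcriptional phenotype (every
    biopsy of a patient shares it), 1 means the biopsy's own local hypoxic
    fraction.  The default 0.3 encodes that the signature reflects a
    persistent, largely lesion-wide programme with a modest local
    component — the property that makes a multi-gene score reproducible
    across biopsies even when pimonidazole staining is patchy.
    """

    n_genes: int = 2000
    n_signature_genes: int = 32
    effect_size: float = 0.5
    gene_noise_sd: float = 0.5
    kit_offset: float = 0.3
    fraction_kit_a: float = 45.0 / 141.0
    local_fraction: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def validate(self) -> None:
        _require(self.n_genes > 0, "expression_model.n_genes", "must be positive")
        _require(self.n_signature_genes > 0, "expression_model.n_signature_genes", "must be positive")
        _require(
            self.n_signature_genes <= self.n_genes,
            "expression_model.n_signature_genes",
            "must not exceed n_genes",
        )
        _require(self.gene_noise_sd >= 0, "expression_model.gene_noise_sd", "must be non-negative")
        _require(0.0 <= self.fraction_kit_a <= 1.0, "expression_model.fraction_kit_a", "must be in [0, 1]")
        _require(0.0 <= self.local_fraction <= 1.0, "expression_model.local_fraction", "must be in [0, 1]")
        _require(self.baseline_sd >= 0, "expression_model.baseline_sd", "must be non-negative")


@dataclass
class ClinicalModelConfig:
    """Logistic / ordered-latent links from true whole-mount HF (z-scored)
    to clinical markers.  Each pair is (intercept, slope) on the log-odds or
    latent scale.  Defaults give marginal prevalences close to the emulated
    cohort: ~10% node-positive, ~50% ISUP >= 3, ~68% pT >= 3.
    """

    lymph_node: tuple[float, float] = (-2.6, 1.2)
    isup: tuple[float, float] = (0.0, 0.8)
    pt_stage: tuple[float, float] = (0.8, 0.7)
    psa_log_median: float = math.log(8.8)
    psa_log_sd: float = 0.6

    def validate(self) -> None:
        _require(self.psa_log_sd >= 0, "clinical_model.psa_log_sd", "must be non-negative")


@dataclass
class SurvivalModelConfig:
    """Exponential proportional-hazards outcome model (time unit: years)."""

    baseline_rate: float = 0.05
    log_hr_per_unit_score: float = math.log(2.0)
    censoring_rate: float = 0.03
    max_follow_up: float = 10.0

    def validate(self) -> None:
        _require(self.baseline_rate > 0, "survival_model.baseline_rate", "must be positive")
        _require(self.censoring_rate >= 0, "survival_model.censoring_rate", "must be non-negative")
        _require(self.max_follow_up > 0, "survival_model.max_follow_up", "must be positive")


@dataclass
class SimulationConfig:
    """Full synthetic-cohort configuration.

    Whole-mount sections are rendered at ``image_size_px`` square with
    ``pixel_size_um`` micrometres per pixel (default 192 px at 200 um/px, a
    down-sampled stand-in for slide scans); 6 mm biopsy punches then have a
    radius of 3000/pixel_size_um pixels.  ``score_noise`` is the symmetric
    +-1 ordinal misclassification probability per rater (default calibrated
    so two raters agree with kappa ~= 0.80).
    """

    n_patients: int = 94
    fraction_paired: float = 47.0 / 94.0
    image_size_px: int = 192
    pixel_size_um: float = 200.0
    lesion_radius_range: tuple[float, float] = (45.0, 70.0)
    hypoxia_field: HypoxiaFieldConfig = field(default_factory=HypoxiaFieldConfig)
    stain_model: StainModelConfig = field(default_factory=StainModelConfig)
    score_noise: float = 0.085
    n_raters: int = 2
    expression_model: ExpressionModelConfig = field(default_factory=ExpressionModelConfig)
    clinical_model: ClinicalModelConfig = field(default_factory=ClinicalModelConfig)
    survival_model: SurvivalModelConfig = field(default_factory=SurvivalModelConfig)
    seed: int = 0

    @property
    def biopsy_radius_px(self) -> float:
        """6 mm punch diameter -> radius in pixels."""
        return 3000.0 / self.pixel_size_um

    def validate(self) -> None:
        _require(self.n_patients > 0, "n_patients", "must be positive")
        _require(0.0 <= self.fraction_paired <= 1.0, "fraction_paired", "must be in [0, 1]")
        _require(self.image_size_px >= 32, "image_size_px", "must be at least 32")
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be positive")
        lo, hi = self.lesion_radius_range
        _require(0 < lo <= hi, "lesion_radius_range", "must satisfy 0 < low <= high")
        _require(
            hi <= self.image_size_px / 2 - 2,
            "lesion_radius_range",
            "lesion must fit inside the whole-mount image",
        )
        _require(
            self.biopsy_radius_px < lo,
            "pixel_size_um",
            "biopsy punch radius must be smaller than the smallest lesion radius",
        )
        _require(0.0 <= self.score_noise <= 1.0, "score_noise", "must be in [0, 1]")
        _require(self.n_raters >= 1, "n_raters", "must be at least 1")
        self.hypoxia_field.validate()
        self.stain_model.validate()
        self.expression_model.validate()
        self.clinical_model.validate()
        self.survival_model.validate()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        sub = {
            "hypoxia_field": HypoxiaFieldConfig,
            "stain_model": StainModelConfig,
            "expression_model": ExpressionModelConfig,
            "clinical_model": ClinicalModelConfig,
            "survival_model": SurvivalModelConfig,
        }
        for key, klass in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = klass(**{k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()})
        for key in ("lesion_radius_range",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)
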