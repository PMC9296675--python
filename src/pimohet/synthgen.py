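"""Seeded synthetic-cohort generator with recorded ground truth.

The generator emulates the structure of a prostatectomy hypoxia study: per
patient one whole-mount section with an outlined index lesion, one or two
6 mm punch biopsies from that lesion, ordinal pathologist hypoxia scores
from two raters, probe-level log2 expression in two extraction-kit batches,
clinical markers linked to true hypoxia, and exponential time-to-event
outcomes driven by the latent hypoxia score.  Every planted quantity is
recorded in :class:`GroundTruthRecord` so downstream stages have a recovery
target without re-simulation.

Spatial model.  The within-lesion hypoxia field is
``H = (z_micro + w * z_coarse) / sqrt(1 + w^2)`` where ``z_micro`` is a
stratified (ordered-dither) fine-grained component — so that with ``w = 0``
any biopsy punch is exactly representative of the lesion — and ``z_coarse``
is a smoothed Gaussian random field with the configured correlation length.
``w = 5 * within_lesion_sd`` approximately makes ``within_lesion_sd`` the
standard deviation of biopsy HF around the whole-mount HF at mid-range HF.
A pixel is truly hypoxic iff ``H`` exceeds the per-patient cut ``c`` placed
at the empirical ``(1 - HF)`` quantile of ``H`` over the lesion.

Stain model.  DAB optical density is ``t* + amp_s * (H - c) + noise`` inside
the lesion, where ``t*`` is the generating segmentation threshold (midpoint
of the hypoxic and background mean ODs) and ``amp_s`` varies per section
(staining-batch variation).  Because the amplitude pivots at ``t*``, a pixel
is stained above threshold exactly when it is truly hypoxic, and the
between-section amplitude spread is what makes ``t*`` identifiable by the
rank-correlation calibration in :mod:`pimohet.histoquant`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from ._rng import patient_seed_sequences, split_rngs
from .config import SimulationConfig
from .errors import GeometryError
from .histoquant import SectionImage
from .sigscore import ProbeExpressionMatrix, SignatureGeneSet

# stain OD unit vectors (rows: haematoxylin, DAB, residual), inverse of the
# deconvolution basis used by histoquant
from skimage.color import rgb_from_hdx

_MICRO_TILE = 16  # ordered-dither tile edge for the stratified fine component
_HEM_BASE_OD = 0.30
_BIOPSY_PAD_PX = 6


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class BiopsyTruth:
    biopsy_id: str
    order_label: str  # "T1" | "T2"
    center_px: tuple[float, float]
    true_hf_biopsy: float
    latent_hypoxia: float = float("nan")  # z-scored across the cohort, filled late


@dataclass
class GroundTruthRecord:
    patient_id: str
    patient_index: int
    true_hf_wholemount: float
    lesion_center_px: tuple[float, float]
    lesion_radius_px: float
    field_cut: float  # per-patient cut on the standardized field
    biopsies: list[BiopsyTruth] = field(default_factory=list)
    true_gene_score_driver: float = float("nan")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: list[GroundTruthRecord]
    images: list[SectionImage]
    pathologist_scores: pd.DataFrame  # section_id, rater_id, score
    expression: ProbeExpressionMatrix
    sample_sheet: pd.DataFrame  # sample_id, patient_id, order_label, kit
    clinical: pd.DataFrame  # indexed by patient_id
    survival: pd.DataFrame  # indexed by patient_id: time, event
    signature: SignatureGeneSet

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.truth:
            for b in rec.biopsies:
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "biopsy_id": b.biopsy_id,
                        "order_label": b.order_label,
                        "true_hf_wholemount": rec.true_hf_wholemount,
                        "true_hf_biopsy": b.true_hf_biopsy,
                        "latent_hypoxia": b.latent_hypoxia,
                        "true_gene_score_driver": rec.true_gene_score_driver,
                    }
                )
        return pd.DataFrame(rows)

    def content_hash(self) -> str:
        """SHA-256 over the cohort's serialised tables and image payloads."""
        h = hashlib.sha256()
        h.update(self.truth_frame().round(12).to_csv(index=False).encode())
        h.update(self.pathologist_scores.to_csv(index=False).encode())
        h.update(self.expression.values.round(10).to_csv().encode())
        h.update(self.sample_sheet.to_csv(index=False).encode())
        h.update(self.clinical.round(10).to_csv().encode())
        h.update(self.survival.round(10).to_csv().encode())
        for img in self.images:
            h.update(img.section_id.encode())
            h.update(np.ascontiguousarray(img.pixels).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# spatial field


def _bayer_matrix(n: int) -> np.ndarray:
    """Classic recursive ordered-dither index matrix of edge n (power of 2)."""
    m = np.array([[0, 2], [3, 1]])
    while m.shape[0] < n:
        m = np.block([[4 * m, 4 * m + 2], [4 * m + 3, 4 * m + 1]])
    return m


_BAYER = _bayer_matrix(_MICRO_TILE)


def _micro_component(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Stratified fine-grained standard-normal field.

    Each 16x16 tile contains every dither level once (jittered within its
    1/256 band), so the field's local empirical distribution is uniform: a
    biopsy-sized disk always samples the whole marginal, making the ``w=0``
    lesion exactly homogeneous at punch scale.
    """
    tiles_y = -(-shape[0] // _MICRO_TILE)
    tiles_x = -(-shape[1] // _MICRO_TILE)
    base = np.tile(_BAYER, (tiles_y, tiles_x))[: shape[0], : shape[1]].astype(float)
    jitter = rng.uniform(0.0, 1.0, size=base.shape)
    u = (base + jitter) / (_MICRO_TILE**2)
    # random per-patient phase so tiles do not align across patients
    u = np.roll(u, shift=(rng.integers(_MICRO_TILE), rng.integers(_MICRO_TILE)), axis=(0, 1))
    return special.ndtri(np.clip(u, 1e-9, 1 - 1e-9))


def _coarse_component(shape: tuple[int, int], corr_length_px: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed Gaussian random field, standardised; correlation length ~ 2 sigma."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=corr_length_px / 2.0, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def hypoxia_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Standardised within-lesion hypoxia field on the whole-mount grid."""
    shape = (config.image_size_px, config.image_size_px)
    w = 5.0 * config.hypoxia_field.within_lesion_sd
    micro = _micro_component(shape, rng)
    if w == 0:
        return micro
    coarse = _coarse_component(shape, config.hypoxia_field.spatial_corr_length_px, rng)
    return (micro + w * coarse) / np.sqrt(1.0 + w * w)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _median_matched_beta(n: int, median: float, rng: np.random.Generator) -> np.ndarray:
    """Beta(2, b) draws with b chosen so the theoretical median equals
    ``median`` (Kerman's median approximation (a - 1/3)/(a + b - 2/3))."""
    b = (5.0 / 3.0) / median - 4.0 / 3.0
    return rng.beta(2.0, b, size=n)


# ---------------------------------------------------------------------------
# truth generation


def generate_truth(config: SimulationConfig) -> list[GroundTruthRecord]:
    """Sample lesion geometry, true hypoxic fractions, biopsy placements and
    per-biopsy latent hypoxia for every patient."""
    config.validate()
    rngs = split_rngs(config.seed)
    t_rng = rngs["truth"]
    n = config.n_patients
    n_paired = int(round(config.fraction_paired * n))
    paired = np.zeros(n, dtype=bool)
    paired[t_rng.permutation(n)[:n_paired]] = True
    radii = t_rng.uniform(*config.lesion_radius_range, size=n)
    hfs = _median_matched_beta(n, config.hypoxia_field.target_median_hf, t_rng)
    field_seeds = patient_seed_sequences(config.seed, "field", n)

    center = (config.image_size_px / 2.0, config.image_size_px / 2.0)
    r_b = config.biopsy_radius_px
    records: list[GroundTruthRecord] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        H = hypoxia_field(config, np.random.default_rng(field_seeds[i]))
        lesion = _disk_mask(H.shape, center, radii[i])
        cut = float(np.quantile(H[lesion], 1.0 - hfs[i]))
        hypoxic = H > cut
        true_hf = float(hypoxic[lesion].mean())

        n_biopsies = 2 if paired[i] else 1
        centers = _place_biopsies(t_rng, center, radii[i], r_b, n_biopsies)
        biopsies = []
        for j, c in enumerate(centers):
            disk = _disk_mask(H.shape, c, r_b)
            biopsies.append(
                BiopsyTruth(
                    biopsy_id=f"{pid}-T{j + 1}",
                    order_label=f"T{j + 1}",
                    center_px=c,
                    true_hf_biopsy=float(hypoxic[disk].mean()),
                )
            )
        records.append(
            GroundTruthRecord(
                patient_id=pid,
                patient_index=i,
                true_hf_wholemount=true_hf,
                lesion_center_px=center,
                lesion_radius_px=float(radii[i]),
                field_cut=cut,
                biopsies=biopsies,
            )
        )

    # Latent hypoxia driving expression: a mixture of the lesion-wide HF
    # (the persistent transcriptional phenotype shared by both biopsies) and
    # the biopsy's own local HF, z-scored across all biopsies of the cohort.
    lf = config.expression_model.local_fraction
    raw = np.array(
        [(1.0 - lf) * rec.true_hf_wholemount + lf * b.true_hf_biopsy
         for rec in records for b in rec.biopsies]
    )
    mu, sd = raw.mean(), raw.std()
    sd = sd if sd > 0 else 1.0
    k = 0
    for rec in records:
        for b in rec.biopsies:
            b.latent_hypoxia = float((raw[k] - mu) / sd)
            k += 1
        rec.true_gene_score_driver = rec.biopsies[0].latent_hypoxia  # T1 is representative
    return records


def _place_biopsies(
    rng: np.random.Generator,
    lesion_center: tuple[float, float],
    lesion_radius: float,
    biopsy_radius: float,
    n_biopsies: int,
    max_tries: int = 500,
) -> list[tuple[float, float]]:
    """Uniform non-overlapping disk placements fully inside the lesion;
    the first accepted placement is labelled T1."""
    reach = lesion_radius - biopsy_radius
    if reach <= 0:
        raise GeometryError("biopsy punch does not fit inside the lesion")
    # A centrally placed first punch can make a second non-overlapping punch
    # geometrically impossible, so placement restarts from scratch after a
    # run of consecutive rejections rather than retrying forever.
    centers: list[tuple[float, float]] = []
    consecutive_rejects = 0
    for _ in range(max_tries):
        if len(centers) == n_biopsies:
            break
        r = reach * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = (lesion_center[0] + r * np.sin(theta), lesion_center[1] + r * np.cos(theta))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2 * biopsy_radius + 1 for c in centers):
            centers.append(cand)
            consecutive_rejects = 0
        else:
            consecutive_rejects += 1
            if consecutive_rejects >= 25:
                centers.clear()
                consecutive_rejects = 0
    if len(centers) < n_biopsies:
        raise GeometryError(
            f"could not place {n_biopsies} non-overlapping punches in lesion radius {lesion_radius:.0f}px"
        )
    return centers


# ---------------------------------------------------------------------------
# section rendering


def _od_to_rgb(hem_od: np.ndarray, dab_od: np.ndarray) -> np.ndarray:
    od = np.stack([hem_od, dab_od, np.zeros_like(dab_od)], axis=-1)
    transmittance = np.power(10.0, -(od.reshape(-1, 3) @ rgb_from_hdx)).reshape(od.shape)
    return np.clip(np.round(255.0 * transmittance), 0, 255).astype(np.uint8)


def render_sections(
    truth: GroundTruthRecord, config: SimulationConfig
) -> list[SectionImage]:
    """Render the whole-mount section and one image per biopsy punch.

    Deterministic given the config seed: the patient's field and stain
    streams are re-derived from the recorded patient index.
    """
    field_seed = patient_seed_sequences(config.seed, "field", config.n_patients)[truth.patient_index]
    stain_root = patient_seed_sequences(config.seed, "stain", config.n_patients)[truth.patient_index]
    stain_seeds = stain_root.spawn(1 + len(truth.biopsies))

    H = hypoxia_field(config, np.random.default_rng(field_seed))
    lesion = _disk_mask(H.shape, truth.lesion_center_px, truth.lesion_radius_px)
    sm = config.stain_model
    t_star = sm.od_threshold

    # whole-mount: tissue is a prostate-sized ellipse containing the lesion
    half = config.image_size_px / 2.0
    yy, xx = np.ogrid[: config.image_size_px, : config.image_size_px]
    tissue = ((yy - half) / (half - 2)) ** 2 + ((xx - half) / (half - 1)) ** 2 <= 1.0
    tissue |= lesion
    images = [
        _render_one(
            H, tissue, lesion, truth.field_cut, sm, np.random.default_rng(stain_seeds[0]),
            section_id=f"{truth.patient_id}-WM", section_kind="whole_mount",
            pixel_size_um=config.pixel_size_um, lesion_mask_out=lesion,
        )
    ]
    r_b = config.biopsy_radius_px
    for k, b in enumerate(truth.biopsies):
        cy, cx = b.center_px
        pad = int(np.ceil(r_b)) + _BIOPSY_PAD_PX
        y0, x0 = int(round(cy)) - pad, int(round(cx)) - pad
        size = 2 * pad
        Hc = H[y0 : y0 + size, x0 : x0 + size]
        disk = _disk_mask(Hc.shape, (cy - y0, cx - x0), r_b)
        images.append(
            _render_one(
                Hc, disk, disk, truth.field_cut, sm, np.random.default_rng(stain_seeds[1 + k]),
                section_id=b.biopsy_id, section_kind="biopsy",
                pixel_size_um=config.pixel_size_um, lesion_mask_out=None,
            )
        )
    return images


def _render_one(
    H: np.ndarray,
    tissue: np.ndarray,
    stain_region: np.ndarray,
    cut: float,
    sm,
    rng: np.random.Generator,
    section_id: str,
    section_kind: str,
    pixel_size_um: float,
    lesion_mask_out: np.ndarray | None,
) -> SectionImage:
    scale = rng.uniform(*sm.section_scale_range)
    amp = scale * (sm.od_hypoxic_mean - sm.od_background_mean) / 2.0
    dab = np.zeros_like(H)
    dab[stain_region] = sm.od_threshold + amp * (H[stain_region] - cut)
    out_region = tissue & ~stain_region
    dab[out_region] = 0.4 * sm.od_background_mean
    dab[tissue] += rng.normal(0.0, sm.od_noise_sd, size=int(tissue.sum()))
    dab = np.clip(dab, 0.0, 2.0)
    dab[~tissue] = 0.0
    hem = np.zeros_like(H)
    hem[tissue] = _HEM_BASE_OD + rng.normal(0.0, 0.02, size=int(tissue.sum()))
    hem = np.clip(hem, 0.0, 2.0)
    pixels = _od_to_rgb(hem, dab)
    pixels[~tissue] = 255
    return SectionImage(
        pixels=pixels,
        section_kind=section_kind,  # type: ignore[arg-type]
        section_id=section_id,
        pixel_size_um=pixel_size_um,
        tissue_mask=tissue,
        lesion_mask=lesion_mask_out,
    )


# ---------------------------------------------------------------------------
# pathologist scores


def simulate_scores(truths: list[GroundTruthRecord], config: SimulationConfig) -> pd.DataFrame:
    """Ordinal 1-5 hypoxia scores for every section from ``n_raters`` raters.

    The true score is the quintile bin of the section's true HF within its
    section-kind group; each rater independently misreads it one level up or
    down (symmetric) with probability ``score_noise``, clipped to 1-5.
    """
    rng = split_rngs(config.seed)["scores"]
    sections: list[tuple[str, float, str]] = []
    for rec in truths:
        sections.append((f"{rec.patient_id}-WM", rec.true_hf_wholemount, "whole_mount"))
        for b in rec.biopsies:
            sections.append((b.biopsy_id, b.true_hf_biopsy, "biopsy"))
    df = pd.DataFrame(sections, columns=["section_id", "hf", "kind"])
    rows = []
    for kind, grp in df.groupby("kind"):
        cuts = np.quantile(grp["hf"].to_numpy(), [0.2, 0.4, 0.6, 0.8])
        true_scores = 1 + (grp["hf"].to_numpy()[:, None] > cuts[None, :]).sum(axis=1)
        for sec_id, s_true in zip(grp["section_id"], true_scores):
            for r in range(config.n_raters):
                s = int(s_true)
                if rng.uniform() < config.score_noise:
                    s += int(rng.choice([-1, 1]))
                rows.append({"section_id": sec_id, "rater_id": f"R{r + 1}", "score": int(np.clip(s, 1, 5))})
    return pd.DataFrame(rows).sort_values(["section_id", "rater_id"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truths: list[GroundTruthRecord], config: SimulationConfig
) -> tuple[ProbeExpressionMatrix, pd.DataFrame, SignatureGeneSet]:
    """Probe-level log2 expression for every biopsy.

    Signature-gene probes are shifted by ``effect_size * latent_hypoxia``;
    every 10th gene carries 2 probes and every 40th a 3rd (with their own
    additive offsets and noise scales) to exercise the IQR probe collapse;
    kit-A samples are offset by ``kit_offset`` on every probe.
    Returns (matrix, sample sheet, planted signature gene set).
    """
    em = config.expression_model
    rng = split_rngs(config.seed)["expression"]
    biopsies = [b for rec in truths for b in rec.biopsies]
    patients = [rec.patient_id for rec in truths for _ in rec.biopsies]
    sample_ids = [b.biopsy_id for b in biopsies]
    latent = np.array([b.latent_hypoxia for b in biopsies])
    n_samples = len(sample_ids)

    genes = [f"g{i + 1:04d}" for i in range(em.n_genes)]
    signature_genes = tuple(genes[: em.n_signature_genes])
    baselines = rng.normal(em.baseline_mean, em.baseline_sd, size=em.n_genes)

    probe_rows, gene_of_probe, offsets, noise_scales = [], [], [], []
    for i, g in enumerate(genes):
        n_probes = 3 if (i + 1) % 40 == 0 else (2 if (i + 1) % 10 == 0 else 1)
        for p in range(n_probes):
            probe_rows.append(f"{g}_p{p + 1}")
            gene_of_probe.append(g)
            offsets.append(0.0 if p == 0 else rng.normal(0.0, 0.3))
            noise_scales.append(1.0 if p == 0 else rng.uniform(0.6, 1.6))
    offsets = np.array(offsets)
    noise_scales = np.array(noise_scales)
    base_of_probe = np.array([baselines[genes.index(g)] for g in gene_of_probe])
    is_sig = np.array([g in set(signature_genes) for g in gene_of_probe])

    values = (
        base_of_probe[:, None]
        + offsets[:, None]
        + np.where(is_sig[:, None], em.effect_size * latent[None, :], 0.0)
        + noise_scales[:, None] * rng.normal(0.0, em.gene_noise_sd, size=(len(probe_rows), n_samples))
    )
    n_kit_a = int(round(em.fraction_kit_a * n_samples))
    kit = np.full(n_samples, "B", dtype=object)
    kit[rng.permutation(n_samples)[:n_kit_a]] = "A"
    values[:, kit == "A"] += em.kit_offset

    matrix = ProbeExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probe_rows, name="probe_id"), columns=sample_ids),
        probe_map=pd.Series(gene_of_probe, index=probe_rows, name="gene_id"),
        kit=pd.Series(kit, index=sample_ids, name="kit"),
    )
    # planted per-probe parameters, attached as generator ground truth
    matrix.probe_info = pd.DataFrame(
        {"gene_id": gene_of_probe, "offset": offsets, "noise_scale": noise_scales},
        index=pd.Index(probe_rows, name="probe_id"),
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "patient_id": patients,
            "order_label": [b.order_label for b in biopsies],
            "kit": kit,
        }
    )
    return matrix, sheet, SignatureGeneSet(name="synthetic32", gene_ids=signature_genes)


# ---------------------------------------------------------------------------
# clinical markers and survival


def simulate_outcomes(
    truths: list[GroundTruthRecord],
    gene_scores: pd.Series,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical markers (logistic / ordered-latent on true whole-mount HF)
    and exponential proportional-hazards survival driven by the per-patient
    score.  ``gene_scores`` is indexed by patient_id (one score each)."""
    cm, sm = config.clinical_model, config.survival_model
    c_rng = split_rngs(config.seed)["clinical"]
    s_rng = split_rngs(config.seed)["survival"]
    pids = [rec.patient_id for rec in truths]
    missing = set(pids) - set(gene_scores.index)
    if missing:
        raise GeometryError(f"no gene score for patients: {sorted(missing)[:5]}")
    hf = np.array([rec.true_hf_wholemount for rec in truths])
    z = (hf - hf.mean()) / (hf.std() if hf.std() > 0 else 1.0)

    ln = c_rng.uniform(size=len(pids)) < special.expit(cm.lymph_node[0] + cm.lymph_node[1] * z)
    # ordered-latent draws; cut points from the emulated cohort's marginal
    # ISUP (8/42/24/15/11%) and pT (32/67/1%) distributions
    isup_lat = cm.isup[0] + cm.isup[1] * z + c_rng.standard_normal(len(pids))
    isup_cuts = np.sqrt(1 + cm.isup[1] ** 2) * stats.norm.ppf([0.08, 0.50, 0.74, 0.89])
    isup = 1 + (isup_lat[:, None] > isup_cuts[None, :]).sum(axis=1)
    pt_lat = cm.pt_stage[0] * 0 + cm.pt_stage[1] * z + c_rng.standard_normal(len(pids))
    pt_cuts = np.sqrt(1 + cm.pt_stage[1] ** 2) * stats.norm.ppf([0.32, 0.99])
    pt = 2 + (pt_lat[:, None] > pt_cuts[None, :]).sum(axis=1)
    psa = np.exp(c_rng.normal(cm.psa_log_median + 0.2 * z, cm.psa_log_sd))

    clinical = pd.DataFrame(
        {
            "lymph_node": np.where(ln, "pos", "neg"),
            "isup_group": isup.astype(int),
            "pt_stage": pt.astype(int),
            "psa": psa,
            "lymph_node_positive": ln,
            "isup_high": isup >= 3,
            "pt_high": pt >= 3,
        },
        index=pd.Index(pids, name="patient_id"),
    )

    score = gene_scores.loc[pids].to_numpy(dtype=float)
    rate = sm.baseline_rate * np.exp(sm.log_hr_per_unit_score * score)
    t_event = s_rng.exponential(1.0 / rate)
    if sm.censoring_rate > 0:
        t_cens = s_rng.exponential(1.0 / sm.censoring_rate, size=len(pids))
    else:
        t_cens = np.full(len(pids), np.inf)
    t_cens = np.minimum(t_cens, sm.max_follow_up)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame(
        {"time": np.maximum(time, 1e-6), "event": event},
        index=pd.Index(pids, name="patient_id"),
    )
    return clinical, survival


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(config: SimulationConfig, render_images: bool = True) -> SyntheticCohort:
    """Generate a complete synthetic cohort (deterministic given the seed).

    ``render_images=False`` skips RGB section rendering (truth, scores,
    expression and outcomes are unchanged) for simulation studies that do
    not exercise the imaging stage.
    """
    truths = generate_truth(config)
    images: list[SectionImage] = []
    if render_images:
        for rec in truths:
            images.extend(render_sections(rec, config))
    scores = simulate_scores(truths, config)
    expression, sheet, signature = simulate_expression(truths, config)
    driver = pd.Series(
        {rec.patient_id: rec.true_gene_score_driver for rec in truths}, name="driver"
    )
    clinical, survival = simulate_outcomes(truths, driver, config)
    return SyntheticCohort(
        config=config,
        truth=truths,
        images=images,
        pathologist_scores=scores,
        expression=expression,
        sample_sheet=sheet,
        clinical=clinical,
        survival=survival,
        signature=signature,
    )


# ---------------------------------------------------------------------------
# on-disk format


def write_cohort(cohort: SyntheticCohort, outdir: str | Path, write_images: bool = True) -> None:
    """Write the cohort in the package's documented plain-file layout:
    images as 8-bit RGB TIFF + single-channel PNG masks, expression as TSV
    (probes x samples) + probe-map TSV, everything else as CSV."""
    import tifffile
    from PIL import Image

    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    cohort.truth_frame().to_csv(out / "truth.csv", index=False)
    cohort.pathologist_scores.to_csv(out / "scores.csv", index=False)
    cohort.sample_sheet.to_csv(out / "samples.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv")
    cohort.survival.to_csv(out / "survival.csv")
    cohort.expression.values.to_csv(out / "expression.tsv", sep="\t")
    cohort.expression.probe_map.rename_axis("probe_id").to_csv(out / "probe_map.tsv", sep="\t")
    with open(out / "signature.txt", "w") as fh:
        fh.write("# planted synthetic signature genes\n")
        fh.writelines(g + "\n" for g in cohort.signature.gene_ids)
    with open(out / "config.json", "w") as fh:
        json.dump(cohort.config.to_dict(), fh, indent=2, default=list)
    if write_images:
        for img in cohort.images:
            tifffile.imwrite(out / "images" / f"{img.section_id}.tiff", img.pixels)
            if img.tissue_mask is not None:
                Image.fromarray((img.tissue_mask * 255).astype(np.uint8)).save(
                    out / "images" / f"{img.section_id}_tissue.png"
                )
            if img.lesion_mask is not None:
                Image.fromarray((img.lesion_mask * 255).astype(np.uint8)).save(
                    out / "images" / f"{img.section_id}_lesion.png"
                )
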