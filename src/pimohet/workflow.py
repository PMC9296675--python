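"""End-to-end study pipeline: simulate -> quantify -> score -> heterogeneity
-> concordance -> prognosis, with the biopsy inclusion filter and a single
structured report.

Stages communicate through files with documented schemas (each stage is
independently re-runnable on user-supplied tables in the same shapes), and
every stage contributes a patient-accounting entry so that n + exclusions at
each step equals n entering it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, concordance, heterogeneity, histoquant, prognosis, sigscore
from .config import SimulationConfig
from .errors import ConfigurationError, DataError, PimohetError
from .synthgen import SyntheticCohort, generate_cohort


def apply_inclusion_criteria(annotations: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    """Biopsy inclusion rule: keep a biopsy iff its section shows at least
    75% malignant glands and less than 50% stroma.  Unannotated biopsies are
    excluded with reason "unannotated", never silently kept.

    Returns (included biopsy ids, exclusion table with reasons).
    """
    need = {"biopsy_id", "malignant_gland_fraction", "stroma_fraction"}
    if not need <= set(annotations.columns):
        raise DataError(f"annotations need columns {sorted(need)}")
    included, excluded = [], []
    for _, row in annotations.iterrows():
        glands, stroma = row["malignant_gland_fraction"], row["stroma_fraction"]
        if pd.isna(glands) or pd.isna(stroma):
            excluded.append({"biopsy_id": row["biopsy_id"], "reason": "unannotated"})
            continue
        if not (0 <= glands <= 1 and 0 <= stroma <= 1):
            raise DataError(f"{row['biopsy_id']}: fractions must lie in [0, 1]")
        if glands < 0.75:
            excluded.append({"biopsy_id": row["biopsy_id"], "reason": f"malignant glands {glands:.2f} < 0.75"})
        elif stroma >= 0.50:
            excluded.append({"biopsy_id": row["biopsy_id"], "reason": f"stroma {stroma:.2f} not < 0.50"})
        else:
            included.append(str(row["biopsy_id"]))
    return included, pd.DataFrame(excluded, columns=["biopsy_id", "reason"])


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: synthetic (a :class:`SimulationConfig`) or user
    data (paths to tables in the documented shapes).  ``hf_wm_csv`` /
    ``hf_biopsy_csv`` substitute the imaging stage with precomputed
    hypoxic-fraction tables.
    """

    simulation: SimulationConfig | None = None
    out_dir: str | Path = "pimohet-out"
    seed: int | None = None
    run_imaging: bool = True
    run_expression: bool = True
    run_heterogeneity: bool = True
    run_concordance: bool = True
    run_prognosis: bool = True
    classification_percentile: float = 50.0
    bh_variant: str = "paper"
    km_percentile: float = 67.0
    scan_percentiles: tuple[float, ...] = tuple(range(10, 95, 5))
    hf_wm_csv: str | Path | None = None
    hf_biopsy_csv: str | Path | None = None
    inclusion_csv: str | Path | None = None

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is None:
            raise ConfigurationError("simulation: pipeline currently requires a synthetic input mode")
        sim = self.simulation
        if self.seed is not None:
            sim = SimulationConfig.from_dict({**sim.to_dict(), "seed": self.seed})
        return sim


@dataclass
class StudyReport:
    payload: dict[str, Any]
    warnings: list[str] = dc_field(default_factory=list)
    accounting: list[dict[str, Any]] = dc_field(default_factory=list)

    def to_json(self) -> str:
        doc = {"report": self.payload, "warnings": self.warnings, "patient_accounting": self.accounting}
        return json.dumps(doc, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Index)):
        return list(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _config_hash(config: PipelineConfig, sim: SimulationConfig) -> str:
    # out_dir is where results land, not what they are; exclude it so the
    # same analysis in two directories hashes identically
    items = {k: v for k, v in config.__dict__.items() if k != "out_dir"}
    blob = json.dumps({"pipeline": str(sorted(items.items(), key=lambda kv: kv[0])),
                       "simulation": sim.to_dict()}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run all enabled stages in dependency order and write the report.

    Stage outputs land as CSV under ``out_dir``; the JSON report references
    them.  Re-running with the same config and seed reproduces the payload
    byte-identically (no timestamps are embedded).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_simulation()
    report = StudyReport(payload={})
    report.payload["metadata"] = {
        "package_version": __version__,
        "seed": sim.seed,
        "config_hash": _config_hash(config, sim),
    }

    stage = "simulate"
    try:
        cohort = generate_cohort(sim, render_images=config.run_imaging)
        report.accounting.append({"stage": stage, "n_in": sim.n_patients, "n_out": len(cohort.truth), "excluded": 0})

        hf_wm, hf_biopsy = _stage_imaging(config, cohort, out, report)
        stage = "score"
        scores = _stage_expression(config, cohort, out, report)
        sheet = cohort.sample_sheet

        stage = "heterogeneity"
        if config.run_heterogeneity and hf_biopsy is not None and scores is not None:
            _stage_heterogeneity(hf_biopsy, scores, sheet, out, report)
        stage = "concordance"
        if config.run_concordance and hf_wm is not None and hf_biopsy is not None and scores is not None:
            _stage_concordance(config, cohort, hf_wm, hf_biopsy, scores, sheet, out, report)
        stage = "prognosis"
        if config.run_prognosis and scores is not None:
            _stage_prognosis(config, cohort, scores, sheet, out, report)
    except PimohetError as err:
        raise PimohetError(f"stage {stage!r} failed: {err}") from err

    (out / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_imaging(config, cohort: SyntheticCohort, out: Path, report: StudyReport):
    from .io import read_values_csv

    if not config.run_imaging:
        hf_wm = read_values_csv(config.hf_wm_csv) if config.hf_wm_csv else None
        hf_biopsy = read_values_csv(config.hf_biopsy_csv) if config.hf_biopsy_csv else None
        report.warnings.append("imaging stage disabled; hypoxic fractions read from supplied tables")
        return hf_wm, hf_biopsy

    inclusion_note = "all synthetic biopsies satisfy the inclusion rule by construction"
    if config.inclusion_csv is not None:
        included, excl = apply_inclusion_criteria(pd.read_csv(config.inclusion_csv))
        excl.to_csv(out / "excluded_biopsies.csv", index=False)
        inclusion_note = f"{len(included)} biopsies included, {len(excl)} excluded"
        keep = set(included)
    else:
        keep = None

    wm_images = [i for i in cohort.images if i.section_kind == "whole_mount"]
    bx_images = [i for i in cohort.images if i.section_kind == "biopsy"]
    if keep is not None:
        n_in = len(bx_images)
        bx_images = [i for i in bx_images if i.section_id in keep]
        report.accounting.append(
            {"stage": "inclusion_filter", "n_in": n_in, "n_out": len(bx_images), "excluded": n_in - len(bx_images)}
        )

    thresholds, results = {}, {}
    for kind, images in (("whole_mount", wm_images), ("biopsy", bx_images)):
        maps = [histoquant.compute_stain_map(img) for img in images]
        regions = [
            img.lesion_mask if kind == "whole_mount" else m.tissue_mask
            for img, m in zip(images, maps)
        ]
        thr = histoquant.calibrate_threshold(maps, regions, cohort.pathologist_scores, kind)
        thresholds[kind] = thr
        results[kind] = [
            histoquant.quantify_hf(m, thr, r, region="lesion" if kind == "whole_mount" else "whole_section")
            for m, r in zip(maps, regions)
        ]

    hf_wm = pd.Series(
        {r.section_id.removesuffix("-WM"): r.fraction for r in results["whole_mount"]}, name="hf_wm"
    )
    hf_biopsy = pd.Series({r.section_id: r.fraction for r in results["biopsy"]}, name="hf_biopsy")
    hf_wm.rename_axis("patient_id").reset_index().to_csv(out / "hf_wholemount.csv", index=False)
    hf_biopsy.rename_axis("sample_id").reset_index().to_csv(out / "hf_biopsy.csv", index=False)

    corr = histoquant.evaluate_against_scores(results["whole_mount"], cohort.pathologist_scores)
    report.payload["imaging"] = {
        "thresholds": {
            k: {"value": t.value,
                **{kk: vv for kk, vv in t.calibration.items() if kk not in ("grid", "objective_curve")}}
            for k, t in thresholds.items()
        },
        "hf_wm_vs_pathologist_score": {"r": corr.r, "p": corr.p, "n": corr.n},
        "median_hf_wm": float(hf_wm.median()),
        "inclusion": inclusion_note,
        "files": ["hf_wholemount.csv", "hf_biopsy.csv"],
    }
    report.accounting.append(
        {"stage": "imaging", "n_in": len(cohort.images), "n_out": len(hf_wm) + len(hf_biopsy), "excluded": 0}
    )
    return hf_wm, hf_biopsy


def _stage_expression(config, cohort: SyntheticCohort, out: Path, report: StudyReport):
    if not config.run_expression:
        return None
    harmonized = sigscore.harmonize_kits(cohort.expression)
    genes = sigscore.collapse_probes(harmonized)
    table = sigscore.compute_gene_score(genes, cohort.signature, cohort_id="synthetic-cohort")
    df = table.to_frame().merge(cohort.sample_sheet[["sample_id", "patient_id"]], on="sample_id")
    df.to_csv(out / "gene_scores.csv", index=False)
    report.payload["gene_score"] = {
        "signature": table.signature_name,
        "n_signature_genes": table.n_signature_genes,
        "n_found": table.n_found,
        "n_samples": int(table.scores.size),
        "files": ["gene_scores.csv"],
    }
    report.accounting.append(
        {"stage": "score", "n_in": len(cohort.expression.sample_ids), "n_out": int(table.scores.size), "excluded": 0}
    )
    return table.scores


def _stage_heterogeneity(hf_biopsy, scores, sheet, out: Path, report: StudyReport):
    pairs_hf = heterogeneity.pair_from_samples(hf_biopsy, sheet, "hf_biopsy")
    pairs_sc = heterogeneity.pair_from_samples(scores, sheet, "gene_score")
    common = pairs_hf.data.index.intersection(pairs_sc.data.index)
    pairs_hf = heterogeneity.PairedMeasurements("hf_biopsy", pairs_hf.data.loc[common])
    pairs_sc = heterogeneity.PairedMeasurements("gene_score", pairs_sc.data.loc[common])
    sum_hf = heterogeneity.summarize(pairs_hf)
    sum_sc = heterogeneity.summarize(pairs_sc)
    comp = heterogeneity.compare_measures(sum_hf, sum_sc)
    pd.DataFrame(
        {
            "relative_difference_hf": sum_hf.relative_difference,
            "relative_difference_score": sum_sc.relative_difference,
        }
    ).rename_axis("patient_id").to_csv(out / "heterogeneity.csv")
    report.payload["heterogeneity"] = {
        "n_pairs": sum_hf.n_pairs,
        "hf_biopsy": {"median_relative_difference": float(sum_hf.relative_difference.median()),
                      "ordered_pair_r": sum_hf.ordered_pair_r},
        "gene_score": {"median_relative_difference": float(sum_sc.relative_difference.median()),
                       "ordered_pair_r": sum_sc.ordered_pair_r},
        "mann_whitney_p": comp.nominal_p,
        "ordering_note": sum_hf.ordering_note,
        "files": ["heterogeneity.csv"],
    }
    report.accounting.append(
        {"stage": "heterogeneity", "n_in": int(len(common)), "n_out": sum_hf.n_pairs, "excluded": 0}
    )


def _stage_concordance(config, cohort, hf_wm, hf_biopsy, scores, sheet, out: Path, report: StudyReport):
    rep = concordance.select_representative_biopsy(sheet)
    rep_map = rep.set_index("patient_id")["sample_id"]
    hf_bx_pat = hf_biopsy.reindex(rep_map.to_numpy())
    hf_bx_pat.index = rep_map.index
    score_pat = scores.reindex(rep_map.to_numpy())
    score_pat.index = rep_map.index

    rule = concordance.ClassificationRule(percentile=config.classification_percentile)
    cls_wm = concordance.classify_by_cutoff(hf_wm.dropna(), rule, "hf_wm")
    cls_bx = concordance.classify_by_cutoff(hf_bx_pat.dropna(), rule, "hf_biopsy")
    cls_sc = concordance.classify_by_cutoff(score_pat.dropna(), rule, "gene_score")
    overlap = concordance.three_way_overlap(cls_wm, cls_bx, cls_sc)
    (out / "overlap.json").write_text(json.dumps(
        {"venn": overlap.venn, "agreement": overlap.agreement, "n": len(overlap.patients)},
        indent=2, sort_keys=True))

    comparisons = []
    for name, values in (("hf_wm", hf_wm), ("hf_biopsy", hf_bx_pat), ("gene_score", score_pat)):
        comparisons.extend(
            concordance.compare_groups_by_markers(
                values.dropna(), cohort.clinical, variable=name, bh_variant=config.bh_variant
            )
        )
    comp_df = pd.DataFrame([c.__dict__ for c in comparisons])
    comp_df.to_csv(out / "group_comparisons.csv", index=False)

    corr_bx = concordance.pearson_correlation(
        hf_wm.reindex(hf_bx_pat.index).dropna(), hf_bx_pat.reindex(hf_wm.index).dropna()
    )
    corr_sc = concordance.pearson_correlation(
        hf_wm.reindex(score_pat.index).dropna(), score_pat.reindex(hf_wm.index).dropna()
    )
    report.payload["concordance"] = {
        "classification_percentile": config.classification_percentile,
        "cutoffs": {"hf_wm": cls_wm.cutoff, "hf_biopsy": cls_bx.cutoff, "gene_score": cls_sc.cutoff},
        "n_more_by_hf_wm": cls_wm.n_more,
        "n_less_by_hf_wm": cls_wm.n_less,
        "agreement_with_hf_wm": overlap.agreement,
        "venn": overlap.venn,
        "hf_biopsy_vs_hf_wm_r": corr_bx.r,
        "gene_score_vs_hf_wm_r": corr_sc.r,
        "bh_variant": config.bh_variant,
        "files": ["overlap.json", "group_comparisons.csv"],
    }
    report.accounting.append(
        {"stage": "concordance", "n_in": int(hf_wm.size), "n_out": len(overlap.patients),
         "excluded": int(hf_wm.size) - len(overlap.patients)}
    )


def _stage_prognosis(config, cohort, scores, sheet, out: Path, report: StudyReport):
    rep = concordance.select_representative_biopsy(sheet)
    rep_map = rep.set_index("patient_id")["sample_id"]
    score_pat = scores.reindex(rep_map.to_numpy())
    score_pat.index = rep_map.index
    data = cohort.survival.join(cohort.clinical[["isup_high", "pt_high"]]).join(score_pat.rename("gene_score"))
    data = data.dropna()
    data[["isup_high", "pt_high"]] = data[["isup_high", "pt_high"]].astype(int)

    covs = ["gene_score", "isup_high", "pt_high"]
    uni = prognosis.fit_cox(data, covs, mode="univariate")
    multi = prognosis.fit_cox(data, covs, mode="multivariate")
    pd.concat([uni.to_frame(), multi.to_frame()]).to_csv(out / "cox_fits.csv", index=False)

    cutoff = float(np.quantile(score_pat.to_numpy(), config.km_percentile / 100.0))
    grouping = (data["gene_score"] > cutoff).map({True: "high", False: "low"})
    km = prognosis.km_logrank(data, grouping)
    scan = prognosis.scan_cutoffs(data["gene_score"], data, percentiles=config.scan_percentiles)
    scan.table.to_csv(out / "cutoff_scan.csv", index=False)
    for entry in scan.skipped:
        report.warnings.append(f"cut-off scan skipped percentile {entry['percentile']}: {entry['reason']}")
    report.payload["prognosis"] = {
        "cox": {
            "univariate": [e.__dict__ for e in uni.effects],
            "multivariate": [e.__dict__ for e in multi.effects],
            "selection_note": multi.selection_note,
            "n": multi.n, "n_events": multi.n_events,
        },
        "km": {"percentile": config.km_percentile, "cutoff": cutoff,
               "logrank_statistic": km.statistic, "logrank_p": km.p,
               "group_sizes": {g: int((grouping == g).sum()) for g in km.group_labels}},
        "cutoff_scan": {"n_evaluated": int(len(scan.table)), "n_skipped": len(scan.skipped),
                        "min_p": float(scan.table["p"].min()),
                        "optimism_note": scan.optimism_note},
        "files": ["cox_fits.csv", "cutoff_scan.csv"],
    }
    report.accounting.append(
        {"stage": "prognosis", "n_in": int(cohort.survival.shape[0]), "n_out": int(len(data)),
         "excluded": int(cohort.survival.shape[0]) - int(len(data))}
    )
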