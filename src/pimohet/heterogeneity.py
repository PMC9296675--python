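"""Intra-lesion heterogeneity statistics on biopsy pairs.

Two summary statistics per measure (biopsy hypoxic fraction, gene score, or
a single gene's expression): the *relative difference* — the unsigned
within-pair difference divided by the overall range of the measure across
all biopsies entering the comparison — and the *ordered-pair correlation* —
Pearson r of the higher against the lower value of each pair.  Ordering by
(max, min) inflates r relative to a random within-pair ordering; the flag
is carried in the summary metadata because published heterogeneity analyses plot
exactly this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import GroupComparison, mann_whitney_test
from .errors import AlignmentError, DataError, DegenerateDataError, SampleSizeError
from .sigscore import GeneExpressionMatrix, SignatureGeneSet


@dataclass
class PairedMeasurements:
    """Per-patient (value_T1, value_T2) rows for one measure."""

    measure_name: str
    data: pd.DataFrame  # index patient_id, columns value_t1, value_t2

    def __post_init__(self) -> None:
        need = {"value_t1", "value_t2"}
        if not need <= set(self.data.columns):
            raise DataError(f"paired table must have columns {sorted(need)}")
        if self.data.index.has_duplicates:
            raise DataError("one row per patient required")
        if not np.isfinite(self.data[["value_t1", "value_t2"]].to_numpy()).all():
            raise DataError("non-finite paired values")

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def all_values(self) -> np.ndarray:
        return self.data[["value_t1", "value_t2"]].to_numpy().ravel()


def pair_from_samples(
    values: pd.Series,
    sample_sheet: pd.DataFrame,
    measure_name: str = "measure",
) -> PairedMeasurements:
    """Assemble T1/T2 pairs from per-sample values and the sample sheet,
    keeping only patients with both biopsies measured."""
    sheet = sample_sheet.set_index("sample_id")
    rows = {}
    for patient, grp in sheet.groupby("patient_id"):
        labels = dict(zip(grp["order_label"], grp.index))
        if "T1" in labels and "T2" in labels:
            s1, s2 = labels["T1"], labels["T2"]
            if s1 in values.index and s2 in values.index:
                rows[patient] = (float(values[s1]), float(values[s2]))
    data = pd.DataFrame.from_dict(rows, orient="index", columns=["value_t1", "value_t2"])
    data.index.name = "patient_id"
    return PairedMeasurements(measure_name=measure_name, data=data.sort_index())


@dataclass
class HeterogeneitySummary:
    measure_name: str
    n_pairs: int
    overall_range: float
    relative_difference: pd.Series  # patient_id -> |dT| / overall_range, in [0, 1]
    ordered_pair_r: float | None = None
    ordered_pair_p: float | None = None
    ordering_note: str = "r computed on (pair max, pair min); ordering inflates r vs random pair order"


def relative_differences(pairs: PairedMeasurements) -> HeterogeneitySummary:
    """Per-pair |v_T1 - v_T2| divided by the overall (max - min) of all
    biopsies entering this analysis."""
    if pairs.n_pairs < 2:
        raise SampleSizeError("need at least 2 pairs")
    allv = pairs.all_values
    overall_range = float(allv.max() - allv.min())
    if overall_range == 0:
        raise DegenerateDataError(f"{pairs.measure_name}: overall range is zero")
    rel = (pairs.data["value_t1"] - pairs.data["value_t2"]).abs() / overall_range
    rel.name = "relative_difference"
    return HeterogeneitySummary(
        measure_name=pairs.measure_name,
        n_pairs=pairs.n_pairs,
        overall_range=overall_range,
        relative_difference=rel,
    )


def ordered_pair_correlation(pairs: PairedMeasurements) -> tuple[float, float]:
    """Pearson r (and two-sided p) of the per-pair maximum against the
    per-pair minimum; invariant to within-pair label swaps."""
    from .concordance import pearson_correlation

    if pairs.n_pairs < 3:
        raise SampleSizeError("need at least 3 pairs")
    arr = pairs.data[["value_t1", "value_t2"]].to_numpy()
    hi = arr.max(axis=1)
    lo = arr.min(axis=1)
    res = pearson_correlation(hi, lo)
    return res.r, res.p


def summarize(pairs: PairedMeasurements) -> HeterogeneitySummary:
    """Full heterogeneity summary: relative differences + ordered-pair r."""
    summary = relative_differences(pairs)
    r, p = ordered_pair_correlation(pairs)
    summary.ordered_pair_r = r
    summary.ordered_pair_p = p
    return summary


def compare_measures(rel_a: HeterogeneitySummary, rel_b: HeterogeneitySummary) -> GroupComparison:
    """Mann-Whitney comparison of two measures' relative-difference vectors,
    restricted (enforced) to the same patients."""
    ia, ib = rel_a.relative_difference.index, rel_b.relative_difference.index
    if set(ia) != set(ib):
        only_a = sorted(set(ia) - set(ib))
        only_b = sorted(set(ib) - set(ia))
        raise AlignmentError(
            f"patient sets differ: only in {rel_a.measure_name}: {only_a[:5]}; "
            f"only in {rel_b.measure_name}: {only_b[:5]}"
        )
    a = rel_a.relative_difference.to_numpy()
    b = rel_b.relative_difference.loc[ia].to_numpy()
    u, p = mann_whitney_test(a, b)
    return GroupComparison(
        variable="relative_difference",
        marker=f"{rel_a.measure_name}_vs_{rel_b.measure_name}",
        n_a=a.size, n_b=b.size, u_statistic=u, nominal_p=p,
    )


def per_gene_heterogeneity(
    genes: GeneExpressionMatrix,
    sample_sheet: pd.DataFrame,
    signature: SignatureGeneSet,
    score: pd.Series | None = None,
) -> pd.DataFrame:
    """Heterogeneity of every signature gene (plus, optionally, the gene
    score itself) across biopsy pairs: one row per gene with the median
    relative difference and the ordered-pair Pearson r.

    Supports the "a multi-gene score is more reproducible than most of its
    constituent genes" comparison.
    """
    rows = []
    items: list[tuple[str, pd.Series]] = []
    for gene in signature.gene_ids:
        if gene in genes.values.index:
            items.append((gene, genes.values.loc[gene]))
    if score is not None:
        items.append(("gene_score", score))
    for name, values in items:
        pairs = pair_from_samples(values, sample_sheet, measure_name=name)
        if pairs.n_pairs < 3:
            raise AlignmentError(f"{name}: fewer than 3 resolvable biopsy pairs")
        summary = summarize(pairs)
        rows.append(
            {
                "measure": name,
                "n_pairs": summary.n_pairs,
                "median_relative_difference": float(summary.relative_difference.median()),
                "ordered_pair_r": summary.ordered_pair_r,
                "ordered_pair_p": summary.ordered_pair_p,
            }
        )
    return pd.DataFrame(rows).set_index("measure")
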