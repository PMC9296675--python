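"""Dichotomous hypoxia classification, cross-assay agreement and the group
statistics used throughout the analysis.

The two Benjamini-Hochberg variants deserve a word.  The standard step-up
procedure enforces monotonicity of adjusted values (``adj_(i) = min_{j>=i}
p_(j)*m/j``).  Some published analyses instead report the raw per-rank
quantity ``p_i * m / rank_i`` capped at 1, which can violate that
monotonicity (e.g. an adjusted 0.0048 for nominal 0.0016 next to 0.0045
for 0.003).  The per-rank form is the default here (``variant="paper"``,
named for that reporting style); the standard step-up is available as
``variant="standard"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    DataError,
    DegenerateDataError,
    InputError,
    SampleSizeError,
)

MarkerLabel = Literal["more", "less"]


# ---------------------------------------------------------------------------
# classification


@dataclass
class ClassificationRule:
    """Cut-off rule: exactly one of ``percentile`` (in (0,100)) or
    ``absolute`` must be set.  Values strictly greater than the cut-off are
    labelled "more" (more hypoxic).  Percentile cut-offs use linear
    interpolation of order statistics on the declared reference population.
    """

    percentile: float | None = None
    absolute: float | None = None
    reference_population: str = "all"

    def __post_init__(self) -> None:
        if (self.percentile is None) == (self.absolute is None):
            raise DataError("exactly one of percentile / absolute must be set")
        if self.percentile is not None and not 0.0 < self.percentile < 100.0:
            raise DataError("percentile must be in (0, 100)")

    @property
    def cutoff_kind(self) -> str:
        return "percentile" if self.percentile is not None else "absolute"


@dataclass
class HypoxiaClassification:
    assay_name: str
    labels: pd.Series  # patient_id -> "more" | "less"
    cutoff: float
    rule: ClassificationRule

    @property
    def n_more(self) -> int:
        return int((self.labels == "more").sum())

    @property
    def n_less(self) -> int:
        return int((self.labels == "less").sum())


def classify_by_cutoff(
    values: pd.Series,
    rule: ClassificationRule,
    assay_name: str = "assay",
    reference_values: pd.Series | None = None,
) -> HypoxiaClassification:
    """Label each patient "more"/"less" hypoxic by the rule's cut-off.

    ``reference_values`` is the population the percentile cut-off is computed
    on (may be a superset of ``values``, e.g. a cohort-wide median applied to
    the subset with all assays available); defaults to ``values``.
    """
    values = pd.Series(values).astype(float)
    if values.isna().any():
        raise DataError(f"{assay_name}: missing values cannot be classified")
    if values.index.has_duplicates:
        raise DataError(f"{assay_name}: duplicate patient ids")
    if rule.percentile is not None:
        ref = values if reference_values is None else pd.Series(reference_values).astype(float)
        if ref.nunique() < 2:
            raise DegenerateDataError(f"{assay_name}: all reference values identical under a percentile rule")
        cutoff = float(np.quantile(ref.to_numpy(), rule.percentile / 100.0))
    else:
        cutoff = float(rule.absolute)  # type: ignore[arg-type]
    labels = pd.Series(np.where(values.to_numpy() > cutoff, "more", "less"), index=values.index, name=assay_name)
    return HypoxiaClassification(assay_name=assay_name, labels=labels, cutoff=cutoff, rule=rule)


@dataclass
class OverlapSummary:
    """Three-assay agreement against a reference classification.

    ``venn`` maps each reference class to the counts of the four agreement
    patterns of the other two assays ("both", "only_<a2>", "only_<a3>",
    "neither" agree with the reference).
    """

    patients: list[str]
    reference: str
    venn: dict[str, dict[str, int]]
    agreement: dict[str, float]
    excluded: list[str] = field(default_factory=list)


def three_way_overlap(
    ref: HypoxiaClassification,
    a2: HypoxiaClassification,
    a3: HypoxiaClassification,
) -> OverlapSummary:
    """Venn-style overlap of two assays with a reference, per reference class."""
    common = ref.labels.index.intersection(a2.labels.index).intersection(a3.labels.index)
    if len(common) == 0:
        raise AlignmentError("no patients shared by the three classifications")
    everything = ref.labels.index.union(a2.labels.index).union(a3.labels.index)
    excluded = sorted(everything.difference(common).astype(str))
    r, x2, x3 = (c.labels.loc[common] for c in (ref, a2, a3))
    venn: dict[str, dict[str, int]] = {}
    for cls in ("more", "less"):
        sel = r == cls
        both = int(((x2 == cls) & (x3 == cls) & sel).sum())
        only2 = int(((x2 == cls) & (x3 != cls) & sel).sum())
        only3 = int(((x2 != cls) & (x3 == cls) & sel).sum())
        neither = int(((x2 != cls) & (x3 != cls) & sel).sum())
        venn[cls] = {
            "n_reference": int(sel.sum()),
            "both_agree": both,
            f"only_{a2.assay_name}": only2,
            f"only_{a3.assay_name}": only3,
            "neither": neither,
        }
    agreement = {
        a2.assay_name: float((x2 == r).mean()),
        a3.assay_name: float((x3 == r).mean()),
    }
    return OverlapSummary(
        patients=sorted(common.astype(str)),
        reference=ref.assay_name,
        venn=venn,
        agreement=agreement,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# group statistics


def mann_whitney_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when n1+n2 <= 12 and there are no ties, the
    normal approximation with tie correction (and continuity correction)
    otherwise.  Returns (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(
    p_values: Sequence[float],
    variant: Literal["paper", "standard"] = "paper",
) -> np.ndarray:
    """Benjamini-Hochberg adjustment over one family.

    ``paper`` (default): per-rank ``min(1, p_i * m / rank_i)`` without the
    step-up monotonicity pass; tied p-values share the largest rank.
    ``standard``: the usual step-up procedure (monotone adjusted values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise InputError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    if variant == "standard":
        return multipletests(p, method="fdr_bh")[1]
    if variant != "paper":
        raise InputError(f"unknown BH variant: {variant!r}")
    ranks = stats.rankdata(p, method="max")
    return np.minimum(1.0, p * p.size / ranks)


@dataclass
class GroupComparison:
    variable: str
    marker: str
    n_a: int
    n_b: int
    u_statistic: float
    nominal_p: float
    adjusted_p: float | None = None
    family: str | None = None
    bh_variant: str | None = None


def compare_groups_by_markers(
    values: pd.Series,
    clinical: pd.DataFrame,
    markers: Sequence[str] = ("lymph_node_positive", "isup_high", "pt_high"),
    variable: str = "value",
    bh_variant: Literal["paper", "standard"] = "paper",
) -> list[GroupComparison]:
    """Mann-Whitney tests of one measured variable across each binary
    clinical marker, BH-adjusted as one family (one family per variable,
    matching one test per clinical marker)."""
    values = pd.Series(values).astype(float)
    common = values.index.intersection(clinical.index)
    results = []
    for marker in markers:
        flags = clinical.loc[common, marker].astype(bool)
        v = values.loc[common]
        a, b = v[flags].to_numpy(), v[~flags].to_numpy()
        if a.size == 0 or b.size == 0:
            # marker not testable in this cohort (e.g. no node-positive
            # patients); recorded, excluded from the BH family
            u, p = float("nan"), float("nan")
        else:
            u, p = mann_whitney_test(a, b)
        results.append(
            GroupComparison(
                variable=variable, marker=marker, n_a=a.size, n_b=b.size,
                u_statistic=u, nominal_p=p, family=variable, bh_variant=bh_variant,
            )
        )
    tested = [r for r in results if not np.isnan(r.nominal_p)]
    adjusted = bh_adjust([r.nominal_p for r in tested], variant=bh_variant)
    for res, adj in zip(tested, adjusted):
        res.adjusted_p = float(adj)
    return results


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError("x and y must have equal length")
    if x.size < 3:
        raise SampleSizeError("Pearson correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in correlation input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


@dataclass
class AgreementKappa:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> AgreementKappa:
    """Unweighted Cohen's kappa from the raters' cross-tabulation."""
    a = pd.Series(list(ratings_a))
    b = pd.Series(list(ratings_b))
    if a.size != b.size:
        raise AlignmentError("raters must score the same items")
    if a.size < 2:
        raise InputError("kappa needs at least 2 items")
    cats = sorted(set(a) | set(b))
    table = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    n = float(a.size)
    po = float(np.trace(table.to_numpy())) / n
    pe = float((table.sum(axis=1).to_numpy() * table.sum(axis=0).to_numpy()).sum()) / n**2
    kappa = 1.0 if pe >= 1.0 else (po - pe) / (1.0 - pe)
    return AgreementKappa(kappa=float(kappa), observed_agreement=po, expected_agreement=pe, n_items=int(n))


# ---------------------------------------------------------------------------
# representative-biopsy selection


def select_representative_biopsy(sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """One sample per patient: the first-collected biopsy (T1) where a pair
    exists, the single biopsy otherwise.  Fails fast on duplicate T1 labels
    or on multi-biopsy patients with no order labels (no silent choice).
    """
    required = {"sample_id", "patient_id", "order_label"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise DataError(f"sample sheet missing columns: {sorted(missing)}")
    chosen = []
    for patient, grp in sample_sheet.groupby("patient_id", sort=True):
        if len(grp) == 1:
            chosen.append(grp.iloc[0])
            continue
        t1 = grp[grp["order_label"] == "T1"]
        if len(t1) == 0:
            raise DataError(f"patient {patient}: multiple biopsies but no T1 label")
        if len(t1) > 1:
            raise DataError(f"patient {patient}: duplicate T1 labels")
        chosen.append(t1.iloc[0])
    return pd.DataFrame(chosen).reset_index(drop=True)
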