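"""Hypoxia gene-signature scoring from probe-level expression.

Pipeline: (optional) quantile normalisation -> extraction-kit harmonisation
(median-centre kit-A probes onto kit-B) -> probe-to-gene collapse by highest
interquartile range -> per-sample gene score, defined as the mean over
signature genes of the median-centred log2 expression, with probe medians
taken over the full analysis cohort supplied.  Scores are cohort-relative:
higher means a more hypoxic transcriptional phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, DataError, InputError, LabellingError

KIT_A = "A"  # RNeasy-like
KIT_B = "B"  # miRNeasy-like (harmonisation reference)


@dataclass
class ProbeExpressionMatrix:
    """Probe x sample expression, log2 scale.

    ``probe_map`` maps probe_id -> gene_id; probes absent from the map are
    carried but never collapsed.  ``kit`` labels each sample "A"/"B" (or is
    None for single-batch data).  Linear-scale input must be declared via
    ``from_linear`` — silent auto-detection is deliberately not offered.
    """

    values: pd.DataFrame
    probe_map: pd.Series | None = None
    kit: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate probe_ids")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample_ids")
        if self.values.isna().any().any():
            raise DataError("missing expression values; impute or filter before ingestion")
        if self.kit is not None:
            self.kit = self.kit.reindex(self.values.columns)
            if self.kit.isna().any():
                missing = self.kit[self.kit.isna()].index.tolist()
                raise LabellingError(f"kit label missing for samples: {missing[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_linear(cls, values: pd.DataFrame, offset: float = 1.0, **kw) -> "ProbeExpressionMatrix":
        """Ingest linear-scale intensities, applying log2(x + offset)."""
        if (values < 0).any().any():
            raise DataError("negative linear intensities")
        return cls(values=np.log2(values + offset), **kw)


@dataclass
class GeneExpressionMatrix:
    """Gene x sample log2 expression with one chosen probe per gene."""

    values: pd.DataFrame
    provenance: pd.Series  # gene_id -> probe_id chosen

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene_ids after collapse")


@dataclass
class SignatureGeneSet:
    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise DataError(f"signature {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataError(f"signature {self.name!r} has duplicate gene ids")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "SignatureGeneSet":
        """One gene id per line; '#' starts a comment."""
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    genes.append(line)
        return cls(name=name or str(path), gene_ids=tuple(genes))

    @classmethod
    def default(cls) -> "SignatureGeneSet":
        """The bundled 32-gene default slot.

        The shipped list is a synthetic stand-in naming the generator's
        planted signature genes (the published 32-gene identities are not
        redistributed here); replace it with your own file for real data.
        """
        path = resources.files("pimohet.data") / "signature_synthetic32.txt"
        return cls.from_file(str(path), name="synthetic32")


@dataclass
class GeneScoreTable:
    scores: pd.Series  # sample_id -> score (log2 units, cohort-relative)
    signature_name: str
    n_signature_genes: int
    n_found: int
    missing_genes: tuple[str, ...]
    centring_cohort: str

    def to_frame(self) -> pd.DataFrame:
        return self.scores.rename("score").rename_axis("sample_id").reset_index()


# ---------------------------------------------------------------------------
# operations


def quantile_normalize(matrix: ProbeExpressionMatrix) -> ProbeExpressionMatrix:
    """Force every sample onto the across-sample mean order-statistic
    distribution, preserving within-sample ranks (ties get the mean of the
    order statistics they span)."""
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        warnings.warn("quantile normalisation of a single sample is the identity", stacklevel=2)
        return ProbeExpressionMatrix(matrix.values.copy(), matrix.probe_map, matrix.kit)
    mean_order = np.sort(X, axis=0).mean(axis=1)
    positions = np.arange(1, X.shape[0] + 1, dtype=float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, mean_order)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ProbeExpressionMatrix(values, matrix.probe_map, matrix.kit)


def harmonize_kits(matrix: ProbeExpressionMatrix) -> ProbeExpressionMatrix:
    """Centre every probe's kit-A median onto its kit-B median.

    Kit-B (miRNeasy-like) samples are the reference and are untouched; with
    a single kit present the matrix is returned unchanged.  Idempotent.
    """
    if matrix.kit is None:
        return ProbeExpressionMatrix(matrix.values.copy(), matrix.probe_map, None)
    kit = matrix.kit
    bad = sorted(set(kit.unique()) - {KIT_A, KIT_B})
    if bad:
        raise LabellingError(f"unknown kit labels: {bad}")
    a_cols = kit[kit == KIT_A].index
    b_cols = kit[kit == KIT_B].index
    if len(a_cols) == 0 or len(b_cols) == 0:
        return ProbeExpressionMatrix(matrix.values.copy(), matrix.probe_map, kit.copy())
    values = matrix.values.copy()
    shift = values[b_cols].median(axis=1) - values[a_cols].median(axis=1)
    values[a_cols] = values[a_cols].add(shift, axis=0)
    return ProbeExpressionMatrix(values, matrix.probe_map, kit.copy())


def collapse_probes(
    matrix: ProbeExpressionMatrix,
    probe_map: pd.Series | None = None,
) -> GeneExpressionMatrix:
    """One probe per gene, chosen by the largest across-sample IQR
    (75th - 25th percentile, linear interpolation); IQR ties break to the
    lexicographically smallest probe_id.  Deterministic under any probe
    ordering."""
    pmap = probe_map if probe_map is not None else matrix.probe_map
    if pmap is None:
        raise DataError("no probe map available for collapse")
    pmap = pmap.reindex(matrix.values.index).dropna()
    if pmap.empty:
        raise DataError("probe map covers no probe in the matrix")
    q75 = matrix.values.quantile(0.75, axis=1)
    q25 = matrix.values.quantile(0.25, axis=1)
    iqr = (q75 - q25).loc[pmap.index]
    choice = (
        pd.DataFrame({"gene": pmap.to_numpy(), "iqr": iqr.to_numpy()}, index=pmap.index)
        .rename_axis("probe")
        .reset_index()
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True], kind="mergesort")
        .groupby("gene", sort=True)
        .first()
    )
    values = matrix.values.loc[choice["probe"].to_numpy()]
    values.index = choice.index
    return GeneExpressionMatrix(values=values, provenance=choice["probe"])


def compute_gene_score(
    genes: GeneExpressionMatrix,
    signature: SignatureGeneSet,
    min_fraction: float = 1.0,
    cohort_id: str = "analysis-cohort",
) -> GeneScoreTable:
    """Per-sample signature score.

    score(s) = mean over signature genes g of (x[g, s] - median_s' x[g, s']),
    with medians over all samples of the supplied (full analysis-cohort)
    matrix.  By default every signature gene must be present
    (``min_fraction=1.0``); relaxing it averages over the found genes and
    records the missing ones.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise InputError("min_fraction must be in (0, 1]")
    wanted = list(signature.gene_ids)
    present = [g for g in wanted if g in genes.values.index]
    missing = tuple(g for g in wanted if g not in genes.values.index)
    if len(present) < min_fraction * len(wanted):
        raise CoverageError(
            f"signature {signature.name!r}: {len(missing)} of {len(wanted)} genes missing: "
            f"{list(missing)[:10]}"
        )
    sub = genes.values.loc[present]
    centred = sub.sub(sub.median(axis=1), axis=0)
    scores = centred.mean(axis=0)
    scores.name = "score"
    return GeneScoreTable(
        scores=scores,
        signature_name=signature.name,
        n_signature_genes=len(wanted),
        n_found=len(present),
        missing_genes=missing,
        centring_cohort=cohort_id,
    )
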