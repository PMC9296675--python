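"""Prognostic evaluation of a biomarker: Cox proportional-hazards models,
Kaplan-Meier curves with log-rank tests, and a percentile cut-off scan.

Conventions (documented because toy oracles in the test suite must use the
same rules): ties in event times are handled by the Efron approximation;
confidence intervals and p-values for Cox coefficients are Wald-based; the
cut-off scan walks a percentile grid and its minimum p-value is flagged as
optimistically biased rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import DataError, DegenerateDataError, InputError

ALPHA = 0.05


def validate_survival(dataset: pd.DataFrame, covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Contract check for a survival table: time > 0, event in {0, 1}, no
    missing covariate values among those to be fitted."""
    need = {"time", "event"} | set(covariates)
    missing = need - set(dataset.columns)
    if missing:
        raise DataError(f"survival table missing columns: {sorted(missing)}")
    if (dataset["time"] <= 0).any():
        raise DataError("all survival times must be positive")
    if not dataset["event"].isin([0, 1]).all():
        raise DataError("event must be 0 or 1")
    if covariates and dataset[list(covariates)].isna().any().any():
        raise DataError("missing covariate values in fitted model")
    return dataset


@dataclass
class CovariateEffect:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    mode: Literal["univariate", "multivariate"]
    effects: list[CovariateEffect]
    n: int
    n_events: int
    selection_note: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"covariate": e.covariate, "HR": e.hr, "CI_low": e.ci_low,
                 "CI_high": e.ci_high, "P": e.p, "mode": self.mode}
                for e in self.effects
            ]
        )


def _fit_one(dataset: pd.DataFrame, covariates: list[str]) -> list[CovariateEffect]:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(dataset[["time", "event"] + covariates], duration_col="time", event_col="event")
    s = cph.summary
    return [
        CovariateEffect(
            covariate=c,
            hr=float(s.loc[c, "exp(coef)"]),
            ci_low=float(s.loc[c, "exp(coef) lower 95%"]),
            ci_high=float(s.loc[c, "exp(coef) upper 95%"]),
            p=float(s.loc[c, "p"]),
        )
        for c in covariates
    ]


def _stepwise_selection(dataset: pd.DataFrame, covariates: list[str], direction: str) -> set[str]:
    """Wald-p stepwise selection at ALPHA; returns the selected covariate set."""
    if direction == "forward":
        selected: list[str] = []
        while True:
            remaining = [c for c in covariates if c not in selected]
            if not remaining:
                break
            trials = []
            for c in remaining:
                effects = _fit_one(dataset, selected + [c])
                p = next(e.p for e in effects if e.covariate == c)
                trials.append((p, c))
            best_p, best_c = min(trials)
            if best_p < ALPHA:
                selected.append(best_c)
            else:
                break
        return set(selected)
    # backward
    selected = list(covariates)
    while selected:
        effects = _fit_one(dataset, selected)
        worst = max(effects, key=lambda e: e.p)
        if worst.p >= ALPHA and len(selected) > 1:
            selected.remove(worst.covariate)
        elif worst.p >= ALPHA:
            return set()
        else:
            break
    return set(selected)


def fit_cox(
    dataset: pd.DataFrame,
    covariates: Sequence[str],
    mode: Literal["univariate", "multivariate"] = "univariate",
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Wald CIs).

    Univariate mode fits each covariate in its own model; multivariate mode
    fits them jointly and additionally reports whether forward and backward
    Wald-p stepwise selection at alpha = 0.05 agree.
    """
    covariates = list(covariates)
    if not covariates:
        raise InputError("no covariates supplied")
    dataset = validate_survival(dataset, covariates)
    n_events = int(dataset["event"].sum())
    if n_events < 2:
        raise InputError("need at least 2 events to fit a Cox model")
    for c in covariates:
        if dataset[c].nunique() < 2:
            raise DegenerateDataError(f"covariate {c!r} is constant")
    if mode == "univariate":
        effects = [e for c in covariates for e in _fit_one(dataset, [c])]
        note = None
    elif mode == "multivariate":
        effects = _fit_one(dataset, covariates)
        fwd = _stepwise_selection(dataset, covariates, "forward")
        bwd = _stepwise_selection(dataset, covariates, "backward")
        if fwd == bwd:
            note = f"forward and backward selection agree: {sorted(fwd)}"
        else:
            note = f"forward selects {sorted(fwd)}, backward selects {sorted(bwd)}"
    else:
        raise InputError(f"unknown mode {mode!r}")
    return CoxFit(mode=mode, effects=effects, n=len(dataset), n_events=n_events, selection_note=note)


@dataclass
class KMComparison:
    group_labels: list[str]
    survival_curves: dict[str, pd.DataFrame]  # per group: time, survival, at_risk, events
    statistic: float
    p: float

    def at_risk_table(self, times: Sequence[float]) -> pd.DataFrame:
        """Number of patients at risk per group at the requested times."""
        rows = {}
        for g, curve in self.survival_curves.items():
            rows[g] = [int((curve.attrs["entry_times"] >= t).sum()) for t in times]
        return pd.DataFrame(rows, index=pd.Index(times, name="time")).T


def km_logrank(dataset: pd.DataFrame, grouping: pd.Series) -> KMComparison:
    """Kaplan-Meier estimates per group plus the log-rank test across groups."""
    dataset = validate_survival(dataset)
    grouping = pd.Series(grouping).reindex(dataset.index)
    if grouping.isna().any():
        raise DataError("grouping missing for some subjects")
    labels = sorted(grouping.unique(), key=str)
    if len(labels) < 2:
        raise InputError("need at least 2 groups")
    if int(dataset["event"].sum()) == 0:
        raise InputError("no events in dataset")
    curves: dict[str, pd.DataFrame] = {}
    for g in labels:
        sub = dataset[grouping == g]
        if len(sub) == 0:
            raise InputError(f"group {g!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        curve = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].to_numpy(),
                "observed_events": kmf.event_table["observed"].to_numpy(),
            }
        )
        curve.attrs["entry_times"] = sub["time"].to_numpy()
        curves[str(g)] = curve
    res = multivariate_logrank_test(dataset["time"], grouping.astype(str), dataset["event"])
    return KMComparison(
        group_labels=[str(g) for g in labels],
        survival_curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
    )


@dataclass
class CutoffScanResult:
    """Log-rank p over a percentile grid of score cut-offs.

    The minimum p over the grid is an optimistically biased quantity because
    the cut-off is selected on the same data it is tested on; consumers get
    the flag, not a correction.
    """

    percentiles: list[float]
    table: pd.DataFrame  # percentile, cutoff, n_low, n_high, statistic, p
    skipped: list[dict] = field(default_factory=list)
    optimism_note: str = (
        "minimum p over the scan is optimistically biased (cut-off selected on the tested data); "
        "p-values are not multiplicity-adjusted"
    )

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]


def scan_cutoffs(
    scores: pd.Series,
    dataset: pd.DataFrame,
    percentiles: Sequence[float] = tuple(range(10, 95, 5)),
    min_group_size: int = 5,
) -> CutoffScanResult:
    """Dichotomise the score at each percentile of its distribution and run
    the log-rank test; cut-offs leaving a group below ``min_group_size``
    are skipped with a warning entry."""
    scores = pd.Series(scores).reindex(dataset.index)
    if scores.isna().any():
        raise DataError("score missing for some subjects")
    rows, skipped = [], []
    for q in percentiles:
        cutoff = float(np.quantile(scores.to_numpy(), q / 100.0))
        high = scores > cutoff
        n_high, n_low = int(high.sum()), int((~high).sum())
        if min(n_high, n_low) < min_group_size:
            skipped.append({"percentile": q, "cutoff": cutoff, "n_low": n_low, "n_high": n_high,
                            "reason": f"group below {min_group_size} subjects"})
            continue
        km = km_logrank(dataset, high.map({True: "high", False: "low"}))
        rows.append({"percentile": q, "cutoff": cutoff, "n_low": n_low, "n_high": n_high,
                     "statistic": km.statistic, "p": km.p})
    if not rows:
        raise InputError("every cut-off on the grid was skipped")
    return CutoffScanResult(percentiles=list(percentiles), table=pd.DataFrame(rows), skipped=skipped)
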