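"""Survival-validated merging of sample clusters into a two-level risk dichotomy.

The cluster with the lowest Kaplan-Meier survival at a fixed horizon (default
24 months) is designated the ultra-high-risk (UHR) group; the remaining
clusters are pooled. The dichotomy is validated with a log-rank test and a
Cox proportional-hazards fit (hazard ratio with normal-approximation 95% CI),
and a secondary log-rank test between the pooled clusters checks that they
are not themselves separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .bicluster import BiclusterModel
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "SurvivalFit",
    "SubtypeResult",
    "km_estimate",
    "logrank",
    "cox_fit",
    "define_uhr",
]

UHR_LABEL = "UHR"
HR_LABEL = "HR"


@dataclass
class SurvivalFit:
    """Summary of a proportional-hazards fit for one or more covariates."""

    beta: pd.Series
    hr: pd.Series
    ci95: pd.DataFrame  # columns lo, hi
    p: pd.Series
    covariates: list[str]
    n: int
    n_events: int

    def single(self) -> tuple[float, float, tuple[float, float], float]:
        """(beta, hr, (lo, hi), p) of the first covariate — convenience."""
        c = self.covariates[0]
        return (
            float(self.beta[c]),
            float(self.hr[c]),
            (float(self.ci95.loc[c, "lo"]), float(self.ci95.loc[c, "hi"])),
            float(self.p[c]),
        )


@dataclass
class SubtypeResult:
    """UHR/HR dichotomy with the survival evidence that justifies it."""

    uhr_cluster: int
    labels: pd.Series  # UHR/HR per sample
    logrank_p: float
    logrank_stat: float
    km_at: dict  # subtype -> KM survival at the horizon
    fit: SurvivalFit | None
    horizon: float
    k_group_logrank_p: float
    non_uhr_logrank_p: float | None
    km_by_cluster: dict = field(default_factory=dict)
    unstable: bool = False


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise DegenerateInputError("empty survival data")
    if (t < 0).any():
        raise ValidationError("negative survival times")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("event indicator must be 0/1")
    return t, e


def km_estimate(time, event, horizon: float) -> float:
    """Product-limit survival estimate S(horizon).

    With no censoring this equals the empirical fraction of subjects whose
    event time exceeds the horizon; with all subjects censored it stays at 1.
    """
    if horizon < 0:
        raise ValidationError(f"horizon must be >= 0, got {horizon}")
    t, e = _check_survival(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return float(kmf.predict(horizon))


def restricted_mean(time, event, upto: float | None = None) -> float:
    """Area under the KM curve up to ``upto`` (defaults to last observed time)."""
    t, e = _check_survival(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]  # step function; index starts at 0, S=1
    cap = float(t.max()) if upto is None else float(upto)
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    keep = times <= cap
    times, surv = times[keep], surv[keep]
    times = np.append(times, cap)
    return float(np.sum(surv * np.diff(times)))


def logrank(time, event, group) -> tuple[float, float]:
    """Log-rank test across 2+ groups: returns (chi-square statistic, p)."""
    t, e = _check_survival(time, event)
    g = np.asarray(group)
    levels = pd.unique(g)
    if levels.size < 2:
        raise DegenerateInputError("log-rank needs >= 2 groups")
    if e.sum() == 0:
        raise DegenerateInputError("log-rank needs >= 1 event")
    if levels.size == 2:
        a = g == levels[0]
        res = logrank_test(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    else:
        res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(df: pd.DataFrame, covariates: list[str],
            time_col: str = "os_months", event_col: str = "os_event") -> SurvivalFit:
    """Cox proportional-hazards partial-likelihood fit.

    95% CI uses the normal approximation ``exp(beta +/- 1.96 * se)``. Raises
    on constant covariates (no information) and on too few events.
    """
    data = df[[time_col, event_col, *covariates]].copy()
    _check_survival(data[time_col], data[event_col])
    n_events = int(data[event_col].sum())
    if n_events < len(covariates) + 1:
        raise DegenerateInputError(
            f"{n_events} events cannot support {len(covariates)} covariate(s)"
        )
    for c in covariates:
        if data[c].nunique() < 2:
            raise DegenerateInputError(f"covariate {c!r} is constant: no information")

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise DegenerateInputError(f"Cox fit failed: {exc}") from exc

    beta = cph.params_
    se = cph.standard_errors_
    ci = pd.DataFrame(
        {"lo": np.exp(beta - 1.96 * se), "hi": np.exp(beta + 1.96 * se)},
        index=beta.index,
    )
    return SurvivalFit(
        beta=beta,
        hr=np.exp(beta),
        ci95=ci,
        p=cph.summary["p"],
        covariates=list(covariates),
        n=len(data),
        n_events=n_events,
    )


def define_uhr(
    model: BiclusterModel | np.ndarray,
    clinical: pd.DataFrame,
    horizon: float = 24.0,
    time_col: str = "os_months",
    event_col: str = "os_event",
    adjust: list[str] | None = None,
    stability_gap: float = 0.02,
) -> SubtypeResult:
    """Designate the worst-surviving cluster as UHR and validate the split.

    ``model`` may be a fitted :class:`BiclusterModel` or a raw label array
    aligned with ``clinical``'s rows. The worst cluster is the one with the
    lowest KM survival at ``horizon``; ties are broken by the lower restricted
    mean survival. The result carries the UHR-vs-rest log-rank test and Cox
    hazard ratio, the k-group log-rank test, and the secondary log-rank test
    among the pooled (non-UHR) clusters. When the KM gap between the two worst
    clusters at the horizon is below ``stability_gap`` the result is flagged
    ``unstable``.
    """
    labels = model.sample_labels if isinstance(model, BiclusterModel) else np.asarray(model)
    if len(labels) != len(clinical):
        raise ValidationError(
            f"{len(labels)} cluster labels for {len(clinical)} clinical rows"
        )
    t, e = _check_survival(clinical[time_col], clinical[event_col])

    clusters = np.unique(labels)
    km_by_cluster: dict[int, float] = {}
    rmst: dict[int, float] = {}
    for c in clusters:
        mask = labels == c
        km_by_cluster[int(c)] = km_estimate(t[mask], e[mask], horizon)
        rmst[int(c)] = restricted_mean(t[mask], e[mask], upto=horizon)

    order = sorted(km_by_cluster, key=lambda c: (km_by_cluster[c], rmst[c], c))
    uhr = order[0]
    unstable = (
        len(order) > 1
        and km_by_cluster[order[1]] - km_by_cluster[uhr] < stability_gap
    )

    is_uhr = labels == uhr
    subtype = pd.Series(
        np.where(is_uhr, UHR_LABEL, HR_LABEL),
        index=clinical.index,
        name="subtype",
    )

    lr_stat, lr_p = logrank(t, e, subtype.to_numpy())
    if clusters.size > 2:
        _, k_p = logrank(t, e, labels)
    else:
        k_p = lr_p

    non_uhr_p: float | None = None
    rest = clusters[clusters != uhr]
    if rest.size >= 2:
        mask = ~is_uhr
        _, non_uhr_p = logrank(t[mask], e[mask], labels[mask])

    fit_df = clinical[[time_col, event_col]].copy()
    fit_df["uhr"] = is_uhr.astype(int)
    covs = ["uhr"] + list(adjust or [])
    for c in adjust or []:
        fit_df[c] = clinical[c]
    try:
        fit = cox_fit(fit_df, covs, time_col=time_col, event_col=event_col)
    except DegenerateInputError:
        fit = None

    km_at = {
        UHR_LABEL: km_estimate(t[is_uhr], e[is_uhr], horizon),
        HR_LABEL: km_estimate(t[~is_uhr], e[~is_uhr], horizon),
    }
    return SubtypeResult(
        uhr_cluster=int(uhr),
        labels=subtype,
        logrank_p=lr_p,
        logrank_stat=lr_stat,
        km_at=km_at,
        fit=fit,
        horizon=horizon,
        k_group_logrank_p=k_p,
        non_uhr_logrank_p=non_uhr_p,
        km_by_cluster=km_by_cluster,
        unstable=bool(unstable),
    )
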