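"""Recovery classification and its association with transplant outcomes.

A patient-site is a *recoverer* when the weighted UniFrac distance between
its preconditioning (P) and E30 samples is strictly below 0.5; with either
sample missing the call is unevaluable. Associations with survival use a
landmark design: patients whose follow-up ends before their own E30
evaluation day never enter a fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .containers import ValidationError, sample_lookup
from .hazards import CoxModel, FineGrayModel, HazardFit, HazardResults

__all__ = [
    "RecoveryCall",
    "classify_recovery",
    "spearman",
    "apply_landmark",
    "cox_univariate",
    "finegray_univariate",
    "multivariate_adjust",
    "km_and_cif",
]


@dataclass
class RecoveryCall:
    patient: str
    site: str
    distance_P_E30: float
    recovered: bool | None
    evaluable: bool


def classify_recovery(
    d: DistanceMatrix, meta: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Recovery calls per patient-site: recovered iff d(P, E30) < threshold."""
    lookup = sample_lookup(meta)
    present = set(d.ids)
    rows = []
    for (patient, site), _ in meta.groupby(["patient", "site"], sort=True):
        s_p = lookup.get((str(patient), str(site), "P"))
        s_e30 = lookup.get((str(patient), str(site), "E30"))
        if s_p in present and s_e30 in present:
            dist = float(d[s_p, s_e30])
            rows.append(
                RecoveryCall(str(patient), str(site), dist, dist < threshold, True)
            )
        else:
            rows.append(RecoveryCall(str(patient), str(site), np.nan, None, False))
    return pd.DataFrame([vars(r) for r in rows])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need paired vectors of length >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def apply_landmark(
    records: pd.DataFrame, landmark_days: dict[str, float] | float
) -> tuple[pd.DataFrame, list[str]]:
    """Landmark exclusion: drop patients whose follow-up ends before their
    recovery-evaluation day (their own E30 sampling day).

    ``landmark_days`` is either one day for everyone or a per-patient map.
    Returns (retained records, excluded patient ids).
    """
    recs = records.copy()
    if isinstance(landmark_days, dict):
        lm = recs["patient"].astype(str).map(
            {str(k): v for k, v in landmark_days.items()}
        )
        if lm.isna().any():
            missing = recs.loc[lm.isna(), "patient"].tolist()
            raise ValidationError(f"no landmark day for patients: {missing}")
    else:
        lm = pd.Series(float(landmark_days), index=recs.index)
    keep = recs["time"] >= lm
    excluded = recs.loc[~keep, "patient"].astype(str).tolist()
    return recs[keep].reset_index(drop=True), excluded


def _binarize(records: pd.DataFrame, event_of_interest: int | None) -> pd.DataFrame:
    out = records.copy()
    if event_of_interest is None:  # overall survival: any event counts
        out["event"] = (out["event"] > 0).astype(int)
    else:  # cause-specific: other causes censored
        out["event"] = (out["event"] == event_of_interest).astype(int)
    return out


def cox_univariate(
    records: pd.DataFrame,
    covariate: str,
    landmark_days: dict[str, float] | float | None = None,
    event_of_interest: int | None = None,
) -> HazardFit:
    """Univariate Cox PH fit (Efron ties) with optional landmark exclusion.

    ``event_of_interest=None`` treats any event as the endpoint (overall
    survival); an integer code fits the cause-specific hazard of that code.
    """
    recs, excluded = (
        apply_landmark(records, landmark_days)
        if landmark_days is not None
        else (records, [])
    )
    res = CoxModel(_binarize(recs, event_of_interest), [covariate]).fit()
    fit = res.fit_for(covariate)
    fit.excluded = excluded
    return fit


def finegray_univariate(
    records: pd.DataFrame,
    covariate: str,
    event_of_interest: int = 1,
    landmark_days: dict[str, float] | float | None = None,
) -> HazardFit:
    """Univariate Fine-Gray subdistribution-hazard fit.

    Competing events keep their code; with zero competing events the
    estimate equals the Cox estimate on the same data.
    """
    recs, excluded = (
        apply_landmark(records, landmark_days)
        if landmark_days is not None
        else (records, [])
    )
    res = FineGrayModel(
        recs, [covariate], event_of_interest=event_of_interest
    ).fit()
    fit = res.fit_for(covariate)
    fit.excluded = excluded
    if (recs["event"].isin([0, event_of_interest])).all():
        fit.note = "no competing events: coincides with Cox"
    return fit


def multivariate_adjust(
    records: pd.DataFrame,
    primary: str,
    confounders: list[str],
    alpha: float = 0.05,
    model: str = "cox",
    event_of_interest: int | None = None,
    landmark_days: dict[str, float] | float | None = None,
) -> tuple[HazardResults, list[str]]:
    """Adjusted fit of ``primary``, correcting for the confounders that are
    univariately associated with the outcome at p < alpha.

    Returns the joint fit and the selected confounder list. With no
    significant confounder the joint model contains only the primary
    covariate (i.e. equals the univariate fit).
    """
    recs, excluded = (
        apply_landmark(records, landmark_days)
        if landmark_days is not None
        else (records, [])
    )
    selected = []
    for c in confounders:
        if model == "cox":
            f = cox_univariate(recs, c, event_of_interest=event_of_interest)
        else:
            f = finegray_univariate(
                recs, c, event_of_interest=event_of_interest or 1
            )
        if f.p < alpha:
            selected.append(c)
    covs = [primary] + selected
    # collinearity flag: rank-deficient design
    X = recs[covs].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(covs):
        raise ValidationError(f"collinear covariates in {covs}")
    if model == "cox":
        res = CoxModel(_binarize(recs, event_of_interest), covs).fit()
    else:
        res = FineGrayModel(
            recs, covs, event_of_interest=event_of_interest or 1
        ).fit()
    res.excluded = excluded
    return res, selected


def km_and_cif(records: pd.DataFrame, group_col: str) -> dict:
    """Kaplan-Meier survival and Aalen-Johansen cumulative incidence curves
    per group.

    Returns {group: {"km": DataFrame(time, survival), "cif": {cause:
    DataFrame(time, cif)}}}. KM treats any event as the endpoint; the CIF is
    estimated per cause with the others competing.
    """
    from lifelines import AalenJohansenFitter, KaplanMeierFitter

    out: dict = {}
    causes = sorted(c for c in records["event"].unique() if c > 0)
    for g, sub in records.groupby(group_col):
        entry: dict = {}
        km = KaplanMeierFitter()
        km.fit(sub["time"], (sub["event"] > 0).astype(int))
        entry["km"] = pd.DataFrame(
            {
                "time": km.survival_function_.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
        entry["cif"] = {}
        for cause in causes:
            aj = AalenJohansenFitter(calculate_variance=False)
            aj.fit(sub["time"], sub["event"], event_of_interest=cause)
            cif = aj.cumulative_density_
            entry["cif"][cause] = pd.DataFrame(
                {"time": cif.index.to_numpy(), "cif": cif.iloc[:, 0].to_numpy()}
            )
        out[g] = entry
    return out
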