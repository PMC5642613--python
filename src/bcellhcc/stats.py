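"""Survival and count statistics shared by the validation and IHC stages.

Kaplan-Meier estimation and the log-rank test wrap lifelines; rank and
correlation tests wrap scipy.stats. The binary-covariate Cox model is
implemented here directly (Newton iteration on the partial likelihood
with Efron or Breslow tie handling) so that the tie method, convergence
rule and monotone-likelihood behaviour are fully specified; lifelines
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

from .errors import DegenerateInputError, ConvergenceError, \
    MonotoneLikelihoodError
from .records import (GroupAssignment, IHCCountRecord, SurvivalRecord,
                      HIGH, LOW, REGIONS, attach_groups)

log = logging.getLogger("bcellhcc")

Z975 = float(sps.norm.ppf(0.975))


# --------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve as a step-function table."""

    times: np.ndarray      # distinct observed times, ascending
    survival: np.ndarray   # S(t) just after each time
    at_risk: np.ndarray    # subjects at risk entering each time
    events: np.ndarray     # deaths at each time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times,
                             "survival": self.survival,
                             "at_risk": self.at_risk,
                             "events": self.events})


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate (ties: events before censorings)."""
    if not records:
        raise DegenerateInputError("no survival records")
    t = np.array([r.time_months for r in records])
    e = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    # keep rows where something was observed (drops the synthetic t=0
    # entry row unless records genuinely sit at time 0)
    table = kmf.event_table[kmf.event_table["removed"] > 0]
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy()
    return KMCurve(times, surv, table["at_risk"].to_numpy(),
                   table["observed"].to_numpy())


def logrank_test(a: list[SurvivalRecord],
                 b: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    if not a or not b:
        raise DegenerateInputError("both groups must be nonempty")
    events = sum(r.event for r in a) + sum(r.event for r in b)
    if events == 0:
        raise DegenerateInputError("log-rank needs >= 1 event overall")
    res = _ll_logrank(
        np.array([r.time_months for r in a]),
        np.array([r.time_months for r in b]),
        event_observed_A=np.array([r.event for r in a]),
        event_observed_B=np.array([r.event for r in b]),
    )
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------------------
# Cox proportional hazards, one binary covariate
# --------------------------------------------------------------------------

@dataclass
class HazardRatioEstimate:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    n_events_exposed: int
    n_events_reference: int

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise DegenerateInputError("CI does not bracket the HR")


def cox_hr(records: list[SurvivalRecord], *, exposed: str = LOW,
           ties: str = "efron", max_iter: int = 100,
           tol: float = 1e-8) -> HazardRatioEstimate:
    """Hazard ratio of ``exposed`` vs the other group.

    Partial-likelihood Newton iteration for a single binary covariate
    (x = 1 for the exposed group), stopping when |gradient| < ``tol``.
    ``ties`` selects Efron (default) or Breslow handling of tied event
    times. Wald 95% CI on the log scale.
    """
    if ties not in ("efron", "breslow"):
        raise DegenerateInputError(f"unknown tie method {ties!r}")
    groups = {r.group for r in records}
    if None in groups:
        raise DegenerateInputError("every record needs a group label")
    if len(groups) != 2:
        raise DegenerateInputError(f"need exactly 2 groups, got {groups}")
    if exposed not in groups:
        raise DegenerateInputError(f"exposed group {exposed!r} absent")
    t = np.array([r.time_months for r in records])
    d = np.array([r.event for r in records])
    x = np.array([1.0 if r.group == exposed else 0.0 for r in records])
    ev_exp = int(d[x == 1].sum())
    ev_ref = int(d[x == 0].sum())
    if ev_exp == 0 or ev_ref == 0:
        raise MonotoneLikelihoodError(
            f"no events in one group (exposed: {ev_exp}, reference: "
            f"{ev_ref}); the partial likelihood is monotone and the "
            f"hazard ratio diverges"
        )

    event_times = np.unique(t[d == 1])
    # per event time: risk-set and tied-death composition
    risk1 = [(t >= u).astype(float) @ x for u in event_times]
    risk_n = [float((t >= u).sum()) for u in event_times]
    tied1 = [float(x[(t == u) & (d == 1)].sum()) for u in event_times]
    tied_n = [float(((t == u) & (d == 1)).sum()) for u in event_times]

    beta = 0.0
    for _ in range(max_iter):
        grad = 0.0
        info = 0.0
        eb = np.exp(beta)
        for r1, rn, s1, dn in zip(risk1, risk_n, tied1, tied_n):
            r0 = rn - r1
            d0 = dn - s1
            grad += s1
            n_terms = int(dn) if ties == "efron" else 1
            for l in range(n_terms):
                frac = l / dn if ties == "efron" else 0.0
                num = (r1 - frac * s1) * eb
                den = r0 - frac * d0 + num
                term = num / den
                grad -= term
                info += term * (1.0 - term)
            if ties == "breslow" and dn > 1:
                # Breslow: d identical terms at the full risk set
                num = r1 * eb
                den = r0 + num
                term = num / den
                grad -= term * (dn - 1)
                info += term * (1.0 - term) * (dn - 1)
        if abs(grad) < tol:
            break
        if info <= 0:
            raise ConvergenceError("non-positive information")
        beta += grad / info
        if abs(beta) > 50:
            raise MonotoneLikelihoodError(
                "hazard-ratio estimate diverged (|log HR| > 50)"
            )
    else:
        raise ConvergenceError(
            f"Cox Newton iteration did not converge in {max_iter} steps"
        )
    se = 1.0 / np.sqrt(info)
    return HazardRatioEstimate(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        log_hr_se=float(se),
        n_events_exposed=ev_exp,
        n_events_reference=ev_ref,
    )


# --------------------------------------------------------------------------
# descriptive statistics and simple tests
# --------------------------------------------------------------------------

def mean_sem(values) -> tuple[float, float | None, int]:
    """(mean, SEM, n); SEM = sample sd / sqrt(n), undefined (None) at n=1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DegenerateInputError("mean of empty sequence")
    mean = float(v.mean())
    if v.size == 1:
        return mean, None, 1
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    return mean, sem, int(v.size)


def split_high_low(values: dict) -> GroupAssignment:
    """Mean-split dichotomization: strictly above the mean -> high,
    at or below -> low."""
    if len(values) < 2:
        raise DegenerateInputError("mean split needs >= 2 patients")
    arr = np.array(list(values.values()), dtype=float)
    if np.all(arr == arr[0]):
        raise DegenerateInputError("all values equal; no split possible")
    threshold = float(arr.mean())
    labels = {k: (HIGH if v > threshold else LOW) for k, v in values.items()}
    return GroupAssignment(labels, "mean_split",
                           rule=f"value > mean ({threshold:.4g}) -> high")


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U of the first sample).

    Exact p by enumeration when n_a * n_b <= 400 and there are no ties
    across the pooled sample, otherwise the normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size * b.size <= 400 and no_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("need equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateInputError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    return float(sps.fisher_exact(np.asarray(table))[1])


# --------------------------------------------------------------------------
# region-stratified IHC analysis
# --------------------------------------------------------------------------

@dataclass
class RegionSurvival:
    assignment: GroupAssignment
    chi2: float
    p: float
    km_high: KMCurve
    km_low: KMCurve


@dataclass
class IHCReport:
    """Full region-stratified output of the IHC stage."""

    summary: dict        # marker -> region -> (mean, sem, n)
    comparisons: dict    # marker -> (region_a, region_b) -> (stat, p)
    survival: dict       # marker -> region -> RegionSurvival
    correlations: dict   # ((marker, region), (marker, region)) -> (r, p)
    clinical: dict       # covariate -> p (vs Im high/low split)
    positivity: dict     # immunoglobulin -> region -> dict
    n_patients: int
    excluded_patients: list


def _patient_region_means(records: list[IHCCountRecord], marker: str
                          ) -> pd.DataFrame:
    rows = {}
    for r in records:
        if r.marker == marker:
            rows.setdefault(r.patient_id, {})[r.region] = r.mean_count
    return pd.DataFrame.from_dict(rows, orient="index")


def ihc_region_analysis(records: list[IHCCountRecord],
                        survival: list[SurvivalRecord], *,
                        markers=("CD20", "CD79a"),
                        paired_regions: bool = False,
                        im_split_marker: str = "CD20") -> IHCReport:
    """Region-stratified B-cell count analysis.

    Per marker: per-region mean +/- SEM; pairwise region comparisons
    (Mann-Whitney by default, Wilcoxon signed-rank when
    ``paired_regions``); mean-split high/low per region followed by a
    log-rank survival comparison; cross-marker/region Pearson
    correlations; association of the Im high/low split with binary
    clinical covariates (Fisher exact; continuous covariates via
    Mann-Whitney); Kappa/IgM positivity fractions per region compared
    between Im-high and Im-low patients.
    """
    surv_by_id = {r.patient_id: r for r in survival}
    frames = {}
    excluded: set = set()
    for marker in markers:
        df = _patient_region_means(records, marker)
        incomplete = df.index[df.isna().any(axis=1)].tolist() \
            if not df.empty else []
        missing_region = [r for r in REGIONS if r not in df.columns]
        if missing_region:
            raise DegenerateInputError(
                f"marker {marker}: no records for region(s) {missing_region}"
            )
        if incomplete:
            log.info("marker %s: excluding %d patients with missing "
                     "regions", marker, len(incomplete))
            excluded.update(incomplete)
            df = df.dropna()
        frames[marker] = df

    summary = {m: {r: mean_sem(frames[m][r]) for r in REGIONS}
               for m in markers}

    comparisons = {}
    for m in markers:
        comparisons[m] = {}
        for ra, rb in (("Im", "Tu"), ("Im", "Sd"), ("Tu", "Sd")):
            if paired_regions:
                res = sps.wilcoxon(frames[m][ra], frames[m][rb])
                comparisons[m][(ra, rb)] = (float(res.statistic),
                                            float(res.pvalue))
            else:
                comparisons[m][(ra, rb)] = mann_whitney(frames[m][ra],
                                                        frames[m][rb])

    survival_out = {}
    for m in markers:
        survival_out[m] = {}
        for r in REGIONS:
            ga = split_high_low(frames[m][r].to_dict())
            grouped = attach_groups(survival, ga)
            hi = [s for s in grouped if s.group == HIGH]
            lo = [s for s in grouped if s.group == LOW]
            chi2, p = logrank_test(hi, lo)
            survival_out[m][r] = RegionSurvival(
                ga, chi2, p, km_estimate(hi), km_estimate(lo))

    series = {(m, r): frames[m][r] for m in markers for r in REGIONS}
    keys = list(series)
    correlations = {}
    for i, ka in enumerate(keys):
        for kb in keys[i + 1:]:
            aligned = pd.concat([series[ka], series[kb]], axis=1,
                                join="inner")
            correlations[(ka, kb)] = pearson_correlation(
                aligned.iloc[:, 0], aligned.iloc[:, 1])

    im_split = survival_out[im_split_marker]["Im"].assignment
    clinical = _clinical_associations(records, im_split, im_split_marker)
    positivity = _positivity_analysis(records, im_split, im_split_marker)

    n_patients = len(frames[markers[0]])
    return IHCReport(summary, comparisons, survival_out, correlations,
                     clinical, positivity, n_patients, sorted(excluded))


def _clinical_associations(records, im_split: GroupAssignment,
                           marker: str) -> dict:
    per_patient: dict = {}
    for r in records:
        if r.patient_id in im_split.labels and r.covariates:
            per_patient.setdefault(r.patient_id, {}).update(r.covariates)
    if not per_patient:
        return {}
    cov = pd.DataFrame.from_dict(per_patient, orient="index")
    labels = pd.Series({p: im_split.labels[p] for p in cov.index})
    out = {}
    for col in cov.columns:
        vals = cov[col].dropna()
        lab = labels.loc[vals.index]
        numeric = pd.to_numeric(vals, errors="coerce")
        distinct = numeric.dropna().unique()
        if numeric.notna().all() and len(set(distinct)) > 2:
            # continuous covariate
            _, p = mann_whitney(numeric[lab == HIGH], numeric[lab == LOW])
        else:
            binary = vals.astype(str)
            levels = sorted(binary.unique())
            if len(levels) != 2:
                continue
            table = [[int(((binary == lev) & (lab == g)).sum())
                      for g in (HIGH, LOW)] for lev in levels]
            p = fisher_exact_2x2(table)
        out[col] = p
    return out


def _positivity_analysis(records, im_split: GroupAssignment,
                         marker: str) -> dict:
    out = {}
    for ig_attr, ig_name in (("kappa_positive", "kappa"),
                             ("igm_positive", "igm")):
        by_region = {}
        for region in REGIONS:
            flags = {}
            for r in records:
                val = getattr(r, ig_attr)
                if (r.marker == marker and r.region == region
                        and val is not None
                        and r.patient_id in im_split.labels):
                    flags[r.patient_id] = bool(val)
            if not flags:
                continue
            hi = [v for p, v in flags.items()
                  if im_split.labels[p] == HIGH]
            lo = [v for p, v in flags.items()
                  if im_split.labels[p] == LOW]
            table = [[sum(hi), len(hi) - sum(hi)],
                     [sum(lo), len(lo) - sum(lo)]]
            by_region[region] = {
                "frac_positive_high": sum(hi) / len(hi) if hi else np.nan,
                "frac_positive_low": sum(lo) / len(lo) if lo else np.nan,
                "p": fisher_exact_2x2(table) if hi and lo else np.nan,
            }
        if by_region:
            out[ig_name] = by_region
    return out
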