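"""Survival evaluation of risk scores under left truncation and competing risks.

Cause-specific Cox models (Efron ties) on either the age timescale with risk
intervals (entry_age, event_age] or the follow-up timescale; Harrell's
c-statistic with an O(n log n) sweep that equals the pairwise definition;
the Aalen–Johansen estimator of cause-specific cumulative incidence with
death as the competing event; percentile-strata hazard ratios; effect
attenuation; interaction tests; cross-score high-risk classification; and
regression scans of score–covariate associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .scores import ScoreSet
from .training import LogisticFit, _fit_logit

log = logging.getLogger(__name__)

DAY = 1.0 / 365.25


# ------------------------------------------------------------------- types

@dataclass
class SurvivalFit:
    """Per-covariate log hazard ratios with Wald CIs from a Cox fit."""

    table: pd.DataFrame  # index covariate: coef, se, hr, ci_low, ci_high, pvalue
    timescale: str
    n: int
    n_events: int
    ties: str = "efron"
    model: object | None = field(default=None, repr=False)

    def ratio(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])


@dataclass
class CIFCurve:
    """Cause-specific cumulative incidence at its jump ages, with 95% CIs.

    ``cif`` is the cause-of-interest curve; ``cif_competing`` and ``survival``
    complete the probability balance: cif + cif_competing + survival = 1 at
    every jump.
    """

    stratum: str
    times: np.ndarray
    cif: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    cif_competing: np.ndarray
    survival: np.ndarray

    def cif_at(self, age: float) -> float:
        """Step-function value of the CIF at ``age`` (0 before the first jump)."""
        i = np.searchsorted(self.times, age, side="right") - 1
        return float(self.cif[i]) if i >= 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum": self.stratum, "age": self.times, "cif": self.cif,
            "lo": self.lo, "hi": self.hi,
        })


@dataclass(frozen=True)
class StrataSpec:
    """Named percentile intervals of a score; [lo, hi) except hi=100 closed."""

    intervals: dict[str, tuple[float, float]]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.intervals:
            raise ValueError(f"reference stratum {self.reference!r} undefined")
        spans = sorted(self.intervals.values())
        for (a, b) in spans:
            if not (0.0 <= a < b <= 100.0):
                raise ValueError(f"bad percentile interval ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise ValueError("percentile intervals must be disjoint")

    def assign(self, values: np.ndarray) -> pd.Series:
        """Stratum label per value; NaN outside all intervals.

        Cutpoints are empirical quantiles (linear interpolation) of ``values``.
        """
        values = np.asarray(values, float)
        out = pd.Series(pd.NA, index=np.arange(len(values)), dtype="object")
        for name, (lo, hi) in self.intervals.items():
            lo_v = np.percentile(values, lo)
            hi_v = np.percentile(values, hi)
            mask = (values >= lo_v) & ((values <= hi_v) if hi >= 100.0
                                       else (values < hi_v))
            out[mask & out.isna().to_numpy()] = name
        return out


TOP5_VS_BOTTOM50 = StrataSpec({"bottom50": (0, 50), "top5": (95, 100)},
                              reference="bottom50")
TOP5_VS_REST = StrataSpec({"rest": (0, 95), "top5": (95, 100)},
                          reference="rest")
FIG2_STRATA = StrataSpec(
    {"q1": (0, 25), "q2": (25, 50), "q3": (50, 75), "p75_85": (75, 85),
     "p85_95": (85, 95), "top5": (95, 100)}, reference="q1")


# --------------------------------------------------------------- Cox fits

def _risk_intervals(cohort: pd.DataFrame, timescale: str
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(entry, exit, event) on the requested timescale; competing deaths censor."""
    if timescale not in ("age", "followup"):
        raise ValueError(f"unknown timescale {timescale!r}")
    if "prevalent" in cohort.columns and (cohort["prevalent"] == 1).any():
        raise ValueError("incident analysis requires prevalent cases to be "
                         "excluded first")
    entry = cohort["entry_age"].to_numpy(float)
    exit_ = cohort["event_age"].to_numpy(float)
    event = cohort["bc_event"].to_numpy(int)
    bad = exit_ < entry
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows with event_age < entry_age")
    tied = exit_ <= entry
    if tied.any():
        log.info("perturbed %d zero-length risk intervals by +1 day",
                 int(tied.sum()))
        exit_ = np.where(tied, entry + DAY, exit_)
    if timescale == "followup":
        exit_ = exit_ - entry
        entry = np.zeros_like(entry)
    return entry, exit_, event


def fit_cox(cohort: pd.DataFrame, covariates: Sequence[str],
            timescale: str = "age") -> SurvivalFit:
    """Cause-specific Cox partial-likelihood fit with Efron tie handling.

    ``timescale='age'`` uses (entry_age, event_age] risk intervals (left
    truncation); ``'followup'`` uses (0, event_age - entry_age]. Competing
    deaths are censored; prevalent rows must already be excluded.
    """
    covariates = list(covariates)
    for c in covariates:
        x = cohort[c].to_numpy(float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in covariate {c!r}")
    entry, exit_, event = _risk_intervals(cohort, timescale)
    if event.sum() == 0:
        raise ValueError("no events in the analysis set")
    df = pd.DataFrame({c: cohort[c].to_numpy(float) for c in covariates})
    df["_T"], df["_E"] = exit_, event
    kwargs = {}
    if timescale == "age":
        df["_entry"] = entry
        kwargs["entry_col"] = "_entry"
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_T", event_col="_E", **kwargs)
    coef = cph.params_.loc[covariates]
    se = cph.standard_errors_.loc[covariates]
    table = pd.DataFrame({
        "coef": coef, "se": se, "hr": np.exp(coef),
        "ci_low": np.exp(coef - 1.96 * se),
        "ci_high": np.exp(coef + 1.96 * se),
        "pvalue": 2.0 * sps.norm.sf(np.abs(coef / se)),
    })
    return SurvivalFit(table, timescale=timescale, n=len(df),
                       n_events=int(event.sum()), model=cph)


# ------------------------------------------------------------- concordance

class _Fenwick:
    __slots__ = ("n", "t")

    def __init__(self, n: int) -> None:
        self.n = n
        self.t = [0] * (n + 1)

    def add(self, i: int, v: int) -> None:
        i += 1
        while i <= self.n:
            self.t[i] += v
            i += i & (-i)

    def prefix(self, i: int) -> int:  # sum of [0, i]
        i += 1
        s = 0
        while i > 0:
            s += self.t[i]
            i -= i & (-i)
        return s


def _concordance_naive(entry, time, event, risk) -> tuple[float, float]:
    """O(n^2) pairwise definition; the oracle for the fast sweep."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i or entry[j] >= time[i]:
                continue
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc, comp


def _concordance_fast(entry, time, event, risk) -> tuple[float, float]:
    """O(n log n) sweep over event times with a Fenwick tree on risk ranks."""
    n = len(time)
    ranks = sps.rankdata(risk, method="dense").astype(int) - 1
    n_ranks = int(ranks.max()) + 1
    bit = _Fenwick(n_ranks)
    in_bit = 0
    by_entry = np.argsort(entry, kind="mergesort")
    by_exit = np.argsort(time, kind="mergesort")
    conc = comp = 0.0
    ei = 0  # pointer into by_entry
    k = 0
    while k < n:
        t = time[by_exit[k]]
        while ei < n and entry[by_entry[ei]] < t:
            bit.add(ranks[by_entry[ei]], 1)
            in_bit += 1
            ei += 1
        grp = []
        while k < n and time[by_exit[k]] == t:
            grp.append(by_exit[k])
            k += 1
        for i in grp:  # leave the risk set
            bit.add(ranks[i], -1)
            in_bit -= 1
        events = [i for i in grp if event[i]]
        cens = [i for i in grp if not event[i]]
        for i in events:
            less = bit.prefix(ranks[i] - 1) if ranks[i] > 0 else 0
            eq = bit.prefix(ranks[i]) - less
            comp += in_bit
            conc += less + 0.5 * eq
            for j in cens:  # censored exactly at t are still comparable
                if entry[j] < t:
                    comp += 1
                    if risk[i] > risk[j]:
                        conc += 1
                    elif risk[i] == risk[j]:
                        conc += 0.5
    return conc, comp


def harrells_c(cohort: pd.DataFrame, risk_col: str,
               timescale: str = "followup") -> float:
    """Harrell's concordance for a risk column, honoring left truncation.

    A pair is comparable when the earlier (event) subject fails while the
    other is at risk and survives longer (censored at the same time counts);
    tied risks score 1/2.
    """
    entry, time, event = _risk_intervals(cohort, timescale)
    risk = cohort[risk_col].to_numpy(float)
    conc, comp = _concordance_fast(entry, time, event, risk)
    if comp == 0:
        raise ValueError("no comparable pairs")
    return conc / comp


def c_increment(cohort: pd.DataFrame, base_col: str, score_col: str,
                timescale: str = "followup") -> tuple[float, float, float]:
    """(c_base, c_joint, delta): concordance gain from adding a score.

    c_base uses the Cox linear predictor of the base covariate alone; c_joint
    the linear predictor of base + score.
    """
    fit_b = fit_cox(cohort, [base_col], timescale=timescale)
    lp_b = (cohort[base_col].to_numpy(float)
            * fit_b.table.loc[base_col, "coef"])
    x = cohort[base_col].to_numpy(float)
    s = cohort[score_col].to_numpy(float)
    A = np.column_stack([np.ones_like(x), x])
    resid = s - A @ np.linalg.lstsq(A, s, rcond=None)[0]
    if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(s), 1.0):
        # the added score carries no information beyond the base covariate
        log.info("c_increment: score collinear with base; delta is 0")
        tmp = cohort.copy()
        tmp["_lp_b"] = lp_b
        c_base = harrells_c(tmp, "_lp_b", timescale=timescale)
        return c_base, c_base, 0.0
    fit_j = fit_cox(cohort, [base_col, score_col], timescale=timescale)
    lp_j = (cohort[base_col].to_numpy(float) * fit_j.table.loc[base_col, "coef"]
            + cohort[score_col].to_numpy(float)
            * fit_j.table.loc[score_col, "coef"])
    tmp = cohort.copy()
    tmp["_lp_b"], tmp["_lp_j"] = lp_b, lp_j
    c_base = harrells_c(tmp, "_lp_b", timescale=timescale)
    c_joint = harrells_c(tmp, "_lp_j", timescale=timescale)
    return c_base, c_joint, c_joint - c_base


# -------------------------------------------------------- Aalen–Johansen

def _aj(entry: np.ndarray, time: np.ndarray, cause: np.ndarray,
        stratum: str = "all") -> CIFCurve:
    """Aalen–Johansen CIF for cause 1 with cause 2 competing, left-truncated.

    Risk set at t: entry < t <= exit. Pointwise 95% CIs use an Aalen-type
    variance (covariance terms between jumps omitted) on the log scale.
    """
    ev_times = np.unique(time[cause > 0])
    entry_s = np.sort(entry)
    exit_s = np.sort(time)
    S_prev = 1.0
    cif1 = np.zeros(len(ev_times))
    cif2 = np.zeros(len(ev_times))
    surv = np.zeros(len(ev_times))
    var1 = np.zeros(len(ev_times))
    acc1 = acc2 = v1 = 0.0
    for k, t in enumerate(ev_times):
        at_risk = (np.searchsorted(entry_s, t, side="left")
                   - np.searchsorted(exit_s, t, side="left"))
        sel = time == t
        d1 = int((cause[sel] == 1).sum())
        d2 = int((cause[sel] == 2).sum())
        d = d1 + d2
        if at_risk <= 0:
            cif1[k], cif2[k], surv[k], var1[k] = acc1, acc2, S_prev, v1
            continue
        acc1 += S_prev * d1 / at_risk
        acc2 += S_prev * d2 / at_risk
        v1 += S_prev ** 2 * d1 * max(at_risk - d1, 0) / at_risk ** 3
        S_prev *= 1.0 - d / at_risk
        cif1[k], cif2[k], surv[k], var1[k] = acc1, acc2, S_prev, v1
    se = np.sqrt(var1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cif1 > 0, 1.96 * se / cif1, 0.0)
    lo = np.where(cif1 > 0, cif1 * np.exp(-ratio), 0.0)
    hi = np.where(cif1 > 0, np.minimum(cif1 * np.exp(ratio), 1.0), 0.0)
    return CIFCurve(stratum, ev_times, cif1, lo, hi, cif2, surv)


def aalen_johansen(cohort: pd.DataFrame, score_col: str | None = None,
                   strata: StrataSpec | None = None) -> dict[str, CIFCurve]:
    """Cause-specific cumulative incidence per score stratum (age timescale).

    Death is the competing event; other exits censor. With no strata a single
    curve labelled 'all' is returned. Empty strata are omitted with a warning.
    """
    entry, exit_, event = _risk_intervals(cohort, "age")
    death = cohort["death_event"].to_numpy(int)
    cause = np.where(event == 1, 1, np.where(death == 1, 2, 0))
    if strata is None:
        return {"all": _aj(entry, exit_, cause)}
    if score_col is None:
        raise ValueError("strata require a score column")
    labels = strata.assign(cohort[score_col].to_numpy(float))
    out = {}
    for name in strata.intervals:
        mask = (labels == name).to_numpy()
        if mask.sum() == 0:
            log.warning("aalen_johansen: empty stratum %s omitted", name)
            continue
        out[name] = _aj(entry[mask], exit_[mask], cause[mask], stratum=name)
    return out


def stratified_hr(cohort: pd.DataFrame, score_col: str,
                  strata: StrataSpec) -> SurvivalFit:
    """Cox hazard ratios of score strata against the reference stratum.

    Percentile cutpoints are computed on the full analysis sample; rows
    outside every interval are dropped; age timescale with left truncation.
    """
    labels = strata.assign(cohort[score_col].to_numpy(float))
    if (labels == strata.reference).sum() == 0:
        raise ValueError(f"reference stratum {strata.reference!r} is empty")
    keep = labels.notna().to_numpy()
    sub = cohort.loc[keep].copy()
    lab = labels[keep]
    names = [n for n in strata.intervals if n != strata.reference]
    for n in names:
        sub[n] = (lab == n).astype(float).to_numpy()
    return fit_cox(sub, names, timescale="age")


def age_at_risk_level(cif: CIFCurve, level: float) -> float | None:
    """Smallest jump age at which the CIF reaches ``level``; None if never."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    idx = np.nonzero(cif.cif >= level)[0]
    return float(cif.times[idx[0]]) if idx.size else None


# ----------------------------------------------------- secondary analyses

def attenuation(fit_unadjusted, fit_adjusted, term: str | None = None,
                log_scale: bool = False) -> float:
    """Percent attenuation of an exposure's ratio after adjustment.

    Accepts SurvivalFit/LogisticFit objects (with ``term`` naming the shared
    exposure) or raw ratio floats. Default is the ratio scale
    100*(R_u - R_a)/R_u; ``log_scale`` switches to the log-ratio scale.
    """
    def _ratio(fit):
        if isinstance(fit, (int, float)):
            return float(fit)
        if term is None:
            raise ValueError("term is required with fit objects")
        try:
            return fit.ratio(term)
        except KeyError:
            raise ValueError(f"exposure {term!r} missing from fit")

    r_u, r_a = _ratio(fit_unadjusted), _ratio(fit_adjusted)
    if log_scale:
        return 100.0 * (np.log(r_u) - np.log(r_a)) / np.log(r_u)
    return 100.0 * (r_u - r_a) / r_u


def interaction_test(cohort: pd.DataFrame, score_col: str, modifier_col: str,
                     timescale: str = "followup") -> float:
    """Wald p-value for the product term in a Cox model with both main effects."""
    x = cohort[score_col].to_numpy(float)
    m = cohort[modifier_col].to_numpy(float)
    prod = x * m
    A = np.column_stack([np.ones_like(x), x, m])
    resid = prod - A @ np.linalg.lstsq(A, prod, rcond=None)[0]
    if np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(prod), 1.0):
        raise ValueError("product term is collinear with the main effects")
    sub = cohort.copy()
    sub["_prod"] = prod
    fit = fit_cox(sub, [score_col, modifier_col, "_prod"], timescale=timescale)
    return float(fit.table.loc["_prod", "pvalue"])


def cross_classify(scoreset: ScoreSet, components: Sequence[str],
                   cut: float = 95.0) -> dict:
    """High/non-high classification agreement across three scores.

    Each sample is 'high' for a score when it reaches the ``cut`` percentile
    of that score. Returns counts (and percentages) of samples high in exactly
    0..3 scores, per-score and per-pair overlap counts, and the 'at least one'
    total.
    """
    components = list(components)
    if len(components) != 3:
        raise ValueError("exactly three score components are required")
    t = scoreset.table
    high = np.column_stack([
        t[c].to_numpy(float) >= np.percentile(t[c].to_numpy(float), cut)
        for c in components])
    n = len(t)
    k = high.sum(axis=1)
    counts = {f"exactly_{i}": int((k == i).sum()) for i in range(4)}
    out = {
        "n": n, "cut": cut, "components": components, **counts,
        "at_least_one": int((k >= 1).sum()),
        "per_score": {c: int(high[:, i].sum())
                      for i, c in enumerate(components)},
        "pair_overlap": {
            f"{components[i]}&{components[j]}":
                int((high[:, i] & high[:, j]).sum())
            for i in range(3) for j in range(i + 1, 3)},
    }
    out["percent"] = {key: 100.0 * counts[key] / n for key in counts}
    out["percent"]["at_least_one"] = 100.0 * out["at_least_one"] / n
    return out


def association_scan(scoreset: ScoreSet, cohort: pd.DataFrame,
                     covariates: Sequence[tuple],
                     score_names: Sequence[str] | None = None) -> pd.DataFrame:
    """Regress each declared covariate on each standardized score.

    ``covariates`` entries are (name, kind[, adjust_age]) with kind in
    {'continuous', 'binary', 'tte'}: linear, logistic, or Cox (the covariate
    column being the event indicator, timed by entry/event age). Estimates are
    per score SD; Benjamini–Hochberg q-values are added per scan.
    """
    score_names = list(score_names or scoreset.names)
    rows = []
    for spec in covariates:
        name, kind = spec[0], spec[1]
        adjust_age = bool(spec[2]) if len(spec) > 2 else False
        if kind not in ("continuous", "binary", "tte"):
            raise ValueError(f"undeclared covariate type {kind!r} for {name}")
        for s in score_names:
            sc = scoreset.table.loc[cohort["sample_id"], s].to_numpy()
            if kind == "tte":
                sub = cohort.copy()
                sub[s] = sc
                sub["bc_event"] = cohort[name].to_numpy(int)
                sub["death_event"] = 0
                if "prevalent" in sub.columns:
                    sub = sub[sub["prevalent"] == 0]
                fit = fit_cox(sub, [s], timescale="age")
                r = fit.table.loc[s]
                est, se, p = r["coef"], r["se"], r["pvalue"]
            else:
                y = cohort[name].to_numpy(float)
                ok = np.isfinite(y) & np.isfinite(sc)
                X = pd.DataFrame({"score": sc[ok]})
                if adjust_age:
                    X["age"] = cohort["entry_age"].to_numpy(float)[ok]
                if kind == "continuous":
                    res = sm.OLS(y[ok], sm.add_constant(X)).fit()
                    est, se, p = (res.params["score"], res.bse["score"],
                                  res.pvalues["score"])
                else:
                    fit = _fit_logit(y[ok], X)
                    r = fit.table.loc["score"]
                    est, se, p = r["coef"], r["se"], r["pvalue"]
            rows.append((s, name, kind, est, se, est - 1.96 * se,
                         est + 1.96 * se, p))
    out = pd.DataFrame(rows, columns=[
        "score", "covariate", "kind", "estimate", "se", "ci_low", "ci_high",
        "pvalue"])
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def plot_cif(curves: dict[str, CIFCurve], path=None, title: str = ""):
    """Optional step-plot of per-stratum cumulative incidence curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for name, c in curves.items():
        ax.step(c.times, 100 * c.cif, where="post", label=name)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("cumulative incidence (%)")
    ax.legend()
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
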