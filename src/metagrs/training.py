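"""Threshold selection, metaGRS combination, and association power.

The best p-value cutoff per summary-statistics source is chosen by the
smallest association p-value in an age-adjusted logistic regression on a
prevalent case-control training set. Component scores are combined into a
metaGRS as a weighted sum of standardized components, the weight of each being
its marginal log odds ratio per SD from the training model (a joint model is
available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .scores import ScoreSet

log = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    """Per-term logistic-regression estimates (log-OR scale)."""

    table: pd.DataFrame  # index term: coef, se, or_, ci_low, ci_high, pvalue
    n: int
    converged: bool = True

    def ratio(self, term: str) -> float:
        return float(self.table.loc[term, "or_"])


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> LogisticFit:
    Xc = sm.add_constant(X, has_constant="add")
    with np.errstate(all="ignore"):
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    coef, se = res.params, res.bse
    ok = bool(res.mle_retvals.get("converged", True)) and \
        bool(np.all(np.isfinite(se)))
    table = pd.DataFrame({
        "coef": coef, "se": se, "or_": np.exp(coef),
        "ci_low": np.exp(coef - 1.96 * se),
        "ci_high": np.exp(coef + 1.96 * se),
        "pvalue": res.pvalues,
    })
    return LogisticFit(table, n=len(y), converged=ok)


@dataclass
class SelectionResult:
    """Per-candidate association estimates and the smallest-p winner."""

    table: pd.DataFrame  # label, or_per_sd, ci_low, ci_high, pvalue,
    #                      n_variants, excluded
    winner: str


@dataclass
class MetaWeights:
    """Component names with their training-set log-OR-per-SD weights."""

    components: list[str]
    weights: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    training_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if len(self.weights) != len(self.components):
            raise ValueError("one weight per component is required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("meta weights must be finite")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metaGRS weights; training_id={self.training_id}\n")
            pd.DataFrame({
                "component": self.components, "weight": self.weights,
                "se": self.se, "pvalue": self.pvalues,
            }).to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaWeights":
        training_id = ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "training_id=" in first:
                training_id = first.strip().split("training_id=")[-1]
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(list(df["component"]), df["weight"].to_numpy(),
                   df["se"].to_numpy(), df["pvalue"].to_numpy(),
                   training_id=training_id)


def select_best_threshold(scoreset: ScoreSet, labels: pd.Series,
                          age: pd.Series,
                          candidates: Sequence[str]) -> SelectionResult:
    """Pick the candidate score with the smallest age-adjusted logistic p-value.

    ``labels``/``age`` are indexed by sample id; candidate columns must be
    standardized so ORs are per SD. Empty candidates (zero variants) are
    skipped; non-converged / separated fits are flagged and excluded from
    winning.
    """
    ids = labels.index
    y = labels.loc[ids].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    rows = []
    for name in candidates:
        nv = scoreset.meta.get(name, {}).get("n_variants")
        if nv == 0:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, 0, True))
            continue
        if not scoreset.is_standardized(name):
            raise ValueError(f"candidate {name} is not standardized")
        X = pd.DataFrame({
            "score": scoreset.table.loc[ids, name].to_numpy(),
            "age": age.loc[ids].to_numpy(float),
        })
        try:
            fit = _fit_logit(y, X)
        except Exception as exc:  # separation and friends
            log.warning("candidate %s failed to fit: %s", name, exc)
            rows.append((name, np.nan, np.nan, np.nan, np.nan, nv, True))
            continue
        r = fit.table.loc["score"]
        excluded = not fit.converged
        if excluded:
            log.warning("candidate %s flagged (non-converged/separated)", name)
        rows.append((name, r["or_"], r["ci_low"], r["ci_high"], r["pvalue"],
                     nv, excluded))
    table = pd.DataFrame(rows, columns=[
        "label", "or_per_sd", "ci_low", "ci_high", "pvalue", "n_variants",
        "excluded"])
    valid = table[~table["excluded"] & table["pvalue"].notna()]
    if valid.empty:
        raise ValueError("no valid candidate to select")
    winner = valid.sort_values("pvalue", kind="mergesort").iloc[0]["label"]
    return SelectionResult(table, winner=winner)


def fit_metagrs(scoreset: ScoreSet, labels: pd.Series, age: pd.Series,
                components: Sequence[str], joint: bool = False,
                training_id: str = "") -> MetaWeights:
    """Training-set log-OR-per-SD weights for the metaGRS combination.

    Default is the marginal construction: one age-adjusted logistic model per
    component, its score coefficient becoming the component's weight.
    ``joint=True`` fits all components in one model instead.
    """
    ids = labels.index
    y = labels.loc[ids].to_numpy(float)
    for c in components:
        if c not in scoreset.names:
            raise ValueError(f"component {c} missing from score set")
        if not scoreset.is_standardized(c):
            raise ValueError(f"component {c} is not standardized")
    agev = age.loc[ids].to_numpy(float)
    if joint:
        X = pd.DataFrame({c: scoreset.table.loc[ids, c].to_numpy()
                          for c in components})
        X["age"] = agev
        fit = _fit_logit(y, X)
        rows = fit.table.loc[list(components)]
        return MetaWeights(list(components), rows["coef"].to_numpy(),
                           rows["se"].to_numpy(), rows["pvalue"].to_numpy(),
                           training_id=training_id)
    w, se, p = [], [], []
    for c in components:
        X = pd.DataFrame({"score": scoreset.table.loc[ids, c].to_numpy(),
                          "age": agev})
        fit = _fit_logit(y, X)
        w.append(fit.table.loc["score", "coef"])
        se.append(fit.table.loc["score", "se"])
        p.append(fit.table.loc["score", "pvalue"])
    return MetaWeights(list(components), np.array(w), np.array(se),
                       np.array(p), training_id=training_id)


def combine(scoreset: ScoreSet, meta: MetaWeights, name: str = "metaGRS",
            reference_ids: Sequence | None = None) -> np.ndarray:
    """Weighted sum of standardized components, restandardized on the reference.

    Adds the combined column to ``scoreset`` and returns its values.
    """
    for c in meta.components:
        if c not in scoreset.names:
            raise ValueError(f"component {c} missing from score set")
        if not scoreset.is_standardized(c):
            raise ValueError(f"component {c} is not standardized")
    z = np.zeros(len(scoreset.table))
    for c, w in zip(meta.components, meta.weights):
        z = z + w * scoreset.table[c].to_numpy()
    scoreset.add(name, z, components=list(meta.components))
    scoreset.standardize(name, reference_ids)
    return scoreset.table[name].to_numpy()


def rank_components(cohort: pd.DataFrame, scoreset: ScoreSet,
                    components: Sequence[str],
                    timescale: str = "age") -> list[str]:
    """Order components by strength of incident-disease association (Cox p).

    Used to choose the top-k members of the smaller metaGRS variants; the
    cohort must be the incident analysis set.
    """
    from .surveval import fit_cox

    pvals = {}
    for c in components:
        df = cohort.copy()
        df[c] = scoreset.table.loc[df["sample_id"], c].to_numpy()
        fit = fit_cox(df, [c], timescale=timescale)
        pvals[c] = float(fit.table.loc[c, "pvalue"])
    return sorted(components, key=lambda c: (pvals[c], c))


def power_curve(n_cases: int, n_controls: int, or_per_sd: float,
                alpha: float = 0.05) -> float:
    """Two-sided Wald power for a standardized predictor in logistic regression.

    Uses the case-control variance approximation SE = sqrt(1/n_cases +
    1/n_controls): power = Phi(|log OR|/SE - z_{1-a/2}) +
    Phi(-|log OR|/SE - z_{1-a/2}); equals alpha at OR = 1.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("counts must be positive")
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    se = np.sqrt(1.0 / n_cases + 1.0 / n_controls)
    delta = abs(np.log(or_per_sd)) / se
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return float(sps.norm.cdf(delta - z) + sps.norm.cdf(-delta - z))
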