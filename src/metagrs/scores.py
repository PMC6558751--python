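"""SNP selection (LD pruning + p-value thresholding) and per-sample scores.

A genetic risk score is the linear combination GRS_i = sum_j beta_j * X_ij of
risk-allele dosages over an LD-pruned, p-value-thresholded variant set. Pruning
is greedy clumping in ascending p-value order: a variant is accepted iff its
squared dosage correlation with every already-accepted variant within a base-
pair window on the same chromosome stays at or below r2_max.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .simcohort import GenotypePanel
from .sumstats import LOG_OR, SummaryStats, WeightSet

log = logging.getLogger(__name__)

#: 22-cutoff default grid; includes 5e-5 and 5e-4 (typical winning cutoffs for
#: scores built from a small-cohort and a large meta-analysis source).
DEFAULT_THRESHOLDS: tuple[float, ...] = (
    5e-8, 1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3,
    0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0)


def validate_threshold_grid(grid: Sequence[float]) -> tuple[float, ...]:
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(not (0.0 < g <= 1.0) for g in grid):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return grid


class ScoreResult(NamedTuple):
    values: np.ndarray
    n_used: int
    n_skipped: int


class ScoreSet:
    """Named per-sample score columns with standardization bookkeeping.

    Standardization moments (mean, sd) are computed on a reference sample set
    and stored, so they can be re-applied to held-out samples.
    """

    def __init__(self, sample_ids: Sequence) -> None:
        self.table = pd.DataFrame(
            index=pd.Index(np.asarray(sample_ids), name="sample_id"))
        self._moments: dict[str, tuple[float, float]] = {}
        self.meta: dict[str, dict] = {}

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)

    def add(self, name: str, values: np.ndarray, n_variants: int | None = None,
            **meta) -> None:
        values = np.asarray(values, float)
        if len(values) != len(self.table):
            raise ValueError(f"{name}: length mismatch")
        self.table[name] = values
        self.meta[name] = {"n_variants": n_variants, **meta}
        self._moments.pop(name, None)

    def standardize(self, name: str, reference_ids: Sequence | None = None) -> None:
        """Center/scale ``name`` using moments from ``reference_ids`` only."""
        ref = (self.table[name] if reference_ids is None
               else self.table.loc[reference_ids, name])
        mean, sd = float(ref.mean()), float(ref.std(ddof=1))
        if not sd > 0:
            raise ValueError(f"{name}: zero standard deviation on reference set")
        self.table[name] = (self.table[name] - mean) / sd
        self._moments[name] = (mean, sd)

    def is_standardized(self, name: str) -> bool:
        return name in self._moments

    def moments(self, name: str) -> tuple[float, float]:
        return self._moments[name]

    def apply_moments(self, name: str, values: np.ndarray) -> np.ndarray:
        """Standardize new values with the stored reference moments."""
        mean, sd = self._moments[name]
        return (np.asarray(values, float) - mean) / sd

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "ScoreSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        out = cls(df.index.to_numpy())
        for c in df.columns:
            out.add(c, df[c].to_numpy())
        return out


def ld_prune(stats: SummaryStats, panel: GenotypePanel,
             r2_max: float = 0.1, window_bp: int = 1_000_000) -> list[str]:
    """Greedy p-value-ordered clumping on the panel's dosages.

    Returns accepted variant ids in acceptance order; every pair of accepted
    variants within ``window_bp`` on the same chromosome has r^2 <= r2_max.
    Ties in p-value break by (chrom, pos, id). Zero-variance variants are
    excluded (their correlation is undefined).
    """
    if not (0.0 < r2_max < 1.0):
        raise ValueError("r2_max must lie in (0, 1)")
    v = panel.variants
    idx = pd.Index(v["id"])
    t = stats.table[stats.table["id"].isin(idx)]
    if len(t) < len(stats.table):
        log.info("ld_prune: %d variants absent from panel ignored",
                 len(stats.table) - len(t))
    order = t.sort_values(["pvalue", "chrom", "pos", "id"],
                          kind="mergesort")

    X = panel.dosages.astype(float)
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X)
    X = X - X.mean(axis=0)
    norms = np.sqrt((X ** 2).sum(axis=0))

    accepted: dict[int, list[tuple[int, int]]] = {}  # chrom -> [(pos, col)]
    out: list[str] = []
    n_zero = 0
    for _, row in order.iterrows():
        col = idx.get_loc(row["id"])
        if norms[col] == 0:
            n_zero += 1
            continue
        chrom, pos = int(row["chrom"]), int(row["pos"])
        ok = True
        for p2, c2 in accepted.get(chrom, ()):
            if abs(pos - p2) <= window_bp:
                r = X[:, col] @ X[:, c2] / (norms[col] * norms[c2])
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            accepted.setdefault(chrom, []).append((pos, col))
            out.append(row["id"])
    if n_zero:
        log.info("ld_prune: excluded %d zero-variance variants", n_zero)
    return out


def threshold_subsets(stats: SummaryStats, kept: Sequence[str],
                      grid: Sequence[float] = DEFAULT_THRESHOLDS,
                      provenance: str = "") -> list[WeightSet]:
    """One weight set per p-value cutoff, nested along the grid.

    Each set holds the kept variants with p <= cutoff, weighted by their
    log-OR-scale beta. Empty subsets are retained (with a warning) so the
    selection stage can skip them explicitly.
    """
    grid = validate_threshold_grid(grid)
    if stats.scale != LOG_OR:
        raise ValueError("weights require log-OR-scale statistics; "
                         "apply linear_to_logor first")
    t = stats.table.set_index("id")
    kept = list(kept)
    missing = [k for k in kept if k not in t.index]
    if missing:
        raise ValueError(f"kept variants absent from stats: {missing[:5]}")
    sub = t.loc[kept]
    out = []
    for cutoff in grid:
        sel = sub[sub["pvalue"] <= cutoff]
        if sel.empty:
            log.warning("threshold_subsets: empty weight set at p<=%g", cutoff)
        out.append(WeightSet(
            pd.DataFrame({"id": sel.index.to_numpy(),
                          "effect_allele": sel["effect_allele"].to_numpy(),
                          "weight": sel["beta"].to_numpy(float)}),
            provenance=provenance or "thresholded",
            p_threshold=cutoff))
    return out


def compute_scores(panel: GenotypePanel, weights: WeightSet,
                   missing_policy: str = "mean_impute") -> ScoreResult:
    """Per-sample weighted dosage sum over the weight set's variants.

    Weight-set variants absent from the panel are skipped and counted; a
    mismatched effect allele for a shared id raises (harmonize first). Missing
    dosages contribute 2*af*weight under ``mean_impute`` or 0 under ``drop``
    (no renormalization).
    """
    if missing_policy not in ("mean_impute", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    idx = pd.Index(panel.variants["id"])
    pos = idx.get_indexer(weights.table["id"])
    present = pos >= 0
    n_skipped = int((~present).sum())
    if present.sum() == 0:
        raise ValueError("no overlapping variants between weights and panel")
    pos = pos[present]
    wt = weights.table[present]
    pe = panel.variants["effect_allele"].to_numpy()[pos]
    mism = wt["effect_allele"].to_numpy() != pe
    if mism.any():
        raise ValueError(
            f"effect-allele mismatch for {list(wt['id'].to_numpy()[mism][:5])}; "
            "run harmonize_alleles first")
    X = panel.dosages[:, pos].astype(float)
    if missing_policy == "mean_impute":
        af = panel.variants["af"].to_numpy()[pos]
        X = np.where(np.isnan(X), 2.0 * af, X)
    else:
        X = np.nan_to_num(X, nan=0.0)
    values = X @ wt["weight"].to_numpy(float)
    if n_skipped:
        log.info("compute_scores: %d weight-set variants absent from panel",
                 n_skipped)
    return ScoreResult(values, int(present.sum()), n_skipped)
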