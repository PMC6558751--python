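"""Synthetic biobank generator.

Emulates the statistical structure a polygenic-score survival analysis assumes:
LD-structured genotype dosages (latent-Gaussian copula blocks with a calibrated
within-block dosage correlation), sparse causal effects scaled to a target
hazard ratio per score SD, a proportional-hazards onset model on the age
timescale with Gompertz competing mortality, left truncation at recruitment,
score-linked family history, a clinical absolute-risk covariate that is
independent of genotype given family history, and sampling-noise-bearing GWAS
summary statistics on either the linear or the log-OR scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit, logit

from .sumstats import LINEAR, LOG_OR, SummaryStats, WeightSet

log = logging.getLogger(__name__)

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


# ---------------------------------------------------------------- containers

@dataclass(frozen=True)
class LDBlockSpec:
    """Block-structured LD: equicorrelated blocks, independence between blocks.

    ``within_r`` is the target pairwise *dosage* correlation inside a block
    (the quantity an r^2 pruning filter operates on).
    """

    n_blocks: int
    block_size: int
    within_r: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be positive")
        if not (0.0 <= self.within_r < 1.0):
            raise ValueError("within_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class EffectModel:
    """Sparse per-allele effects, optionally rescaled to a per-SD hazard ratio."""

    n_causal: int
    effect_sd: float = 0.1
    per_sd_hr: float | None = None

    def __post_init__(self) -> None:
        if self.n_causal < 0:
            raise ValueError("n_causal must be nonnegative")
        if self.per_sd_hr is not None and self.per_sd_hr <= 0:
            raise ValueError("per_sd_hr must be positive")


@dataclass(frozen=True)
class GompertzHazard:
    """Hazard rate(age) = rate0 * exp(slope * age)."""

    rate0: float
    slope: float = 0.0

    def cumhaz(self, age):
        age = np.asarray(age, float)
        if self.slope == 0.0:
            return self.rate0 * age
        return self.rate0 / self.slope * (np.exp(self.slope * age) - 1.0)

    def inverse_cumhaz(self, h):
        h = np.asarray(h, float)
        if self.slope == 0.0:
            with np.errstate(divide="ignore"):
                return np.where(self.rate0 > 0, h / max(self.rate0, 1e-300), np.inf)
        return np.log1p(h * self.slope / self.rate0) / self.slope


@dataclass(frozen=True)
class OnsetModel:
    """Age-scale onset model: Weibull baseline, competing death, truncation.

    The baseline cumulative hazard is (age/scale)^shape; ``baseline_scale=None``
    requests numerical calibration from ``target_cif70`` (the population
    cause-specific cumulative incidence at age 70, death competing). Entry ages
    are uniform on ``recruitment_age_range``; each subject carries an
    administrative censoring age min(admin_censor_age, entry + U(followup)).
    ``followup_range=None`` disables per-subject follow-up censoring.
    """

    baseline_shape: float = 3.0
    baseline_scale: float | None = None
    target_cif70: float | None = 0.051
    recruitment_age_range: tuple[float, float] = (30.0, 70.0)
    followup_range: tuple[float, float] | None = (4.0, 13.0)
    admin_censor_age: float = 85.0
    death_hazard: GompertzHazard | None = GompertzHazard(1e-5, 0.1)

    def __post_init__(self) -> None:
        if self.baseline_shape <= 0:
            raise ValueError("baseline_shape must be positive")
        if self.baseline_scale is not None and self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        if self.target_cif70 is not None and not (0 < self.target_cif70 < 1):
            raise ValueError("target_cif70 must lie in (0, 1)")

    def cumhaz(self, age):
        self._need_scale()
        return (np.asarray(age, float) / self.baseline_scale) ** self.baseline_shape

    def inverse_cumhaz(self, h):
        self._need_scale()
        return self.baseline_scale * np.asarray(h, float) ** (1.0 / self.baseline_shape)

    def _need_scale(self) -> None:
        if self.baseline_scale is None:
            raise ValueError("baseline_scale is not set; calibrate first")


@dataclass(frozen=True)
class FamilyHistoryModel:
    """Family history linked to the true score: logit(P) = logit(base) + b*z."""

    base_prob: float = 0.08
    log_or_per_sd: float = 0.35
    unknown_prob: float = 0.15


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix with ordered variant metadata.

    Dosages lie in [0, 2]; NaN marks missing. ``variants`` columns:
    id, chrom, pos, effect_allele, other_allele, af (frequency of the dosage
    allele).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match metadata")
        d = self.dosages
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------- genotypes

def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(Z1<h, Z2<k) for standard bivariate normals, vectorized over (h, k).

    Plackett's identity: Phi2 = Phi(h)Phi(k) + int_0^rho phi2(h,k;r) dr,
    evaluated by Gauss–Legendre quadrature.
    """
    h, k = np.asarray(h, float), np.asarray(k, float)
    base = sps.norm.cdf(h) * sps.norm.cdf(k)
    if rho == 0.0:
        return base
    nodes, wts = np.polynomial.legendre.leggauss(24)
    r = 0.5 * rho * (nodes + 1.0)
    w = 0.5 * rho * wts
    r2 = 1.0 - r ** 2
    hh, kk = h[:, None], k[:, None]
    dens = np.exp(-(hh ** 2 + kk ** 2 - 2.0 * r * hh * kk) / (2.0 * r2)) \
        / (2.0 * np.pi * np.sqrt(r2))
    return base + dens @ w


def _latent_rho(target_r: float, mafs: np.ndarray) -> float:
    """Latent Gaussian correlation whose thresholded alleles have mean pairwise
    correlation target_r over the block's MAF pairs."""
    if target_r <= 0.0:
        return 0.0
    mafs = np.asarray(mafs, float)
    m = len(mafs)
    iu, ju = np.triu_indices(m, 1)
    if iu.size == 0:
        iu, ju = np.array([0]), np.array([0])
    if iu.size > 40:  # evenly spaced pair subsample keeps this O(1)
        sel = np.linspace(0, iu.size - 1, 40).astype(int)
        iu, ju = iu[sel], ju[sel]
    ti, tj = sps.norm.ppf(mafs[iu]), sps.norm.ppf(mafs[ju])
    pi, pj = mafs[iu], mafs[ju]
    denom = np.sqrt(pi * (1 - pi) * pj * (1 - pj))

    def mean_corr(rho: float) -> float:
        joint = _bvn_cdf(ti, tj, rho)
        return float(((joint - pi * pj) / denom).mean())

    lo, hi = target_r, 1.0 - 1e-9
    if mean_corr(hi) < target_r:  # unreachable, cap at maximum
        return hi
    return optimize.brentq(lambda r: mean_corr(r) - target_r, lo, hi,
                           xtol=1e-6)


def simulate_genotypes(n_samples: int, ld: LDBlockSpec, seed: int) -> GenotypePanel:
    """Draw LD-structured dosages via a per-block latent-Gaussian copula.

    Each haplotype's latent vector is equicorrelated within a block with a
    correlation solved so the *dosage* correlation approximates ``ld.within_r``;
    blocks are independent. Alleles are thresholded at the quantile of a MAF
    drawn from ``ld.maf_range``; two haplotypes sum to the dosage.
    Deterministic given ``seed``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(seed)
    nb, bs = ld.n_blocks, ld.block_size
    mafs = rng.uniform(*ld.maf_range, size=nb * bs)
    dosages = np.empty((n_samples, nb * bs), dtype=np.float32)
    for b in range(nb):
        sl = slice(b * bs, (b + 1) * bs)
        rho = _latent_rho(ld.within_r, mafs[sl])
        thr = sps.norm.ppf(mafs[sl])
        d = np.zeros((n_samples, bs), dtype=np.float32)
        for _hap in range(2):
            shared = rng.standard_normal((n_samples, 1))
            noise = rng.standard_normal((n_samples, bs))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            d += (z < thr)
        dosages[:, sl] = d

    # allele pairs cycle deterministically so panels simulated from the same
    # LD spec under different seeds describe the same variants
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(nb * bs)]
    chrom = np.array([(b % 22) + 1 for b in range(nb) for _ in range(bs)])
    pos = np.empty(nb * bs, dtype=np.int64)
    for b in range(nb):
        cyc = b // 22  # blocks sharing a chromosome sit >> window apart
        pos[b * bs:(b + 1) * bs] = 1_000_000 + cyc * 50_000_000 + \
            np.arange(bs) * 5_000
    variants = pd.DataFrame({
        "id": [f"rs{i + 1}" for i in range(nb * bs)],
        "chrom": chrom,
        "pos": pos,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "af": dosages.mean(axis=0) / 2.0,
    })
    sample_ids = np.array([f"S{i + 1:06d}" for i in range(n_samples)])
    return GenotypePanel(dosages, variants, sample_ids)


# ------------------------------------------------------------------ effects

def true_scores(panel: GenotypePanel, weights: WeightSet) -> np.ndarray:
    """Raw weighted dosage sum of the weight set's variants (missing -> 2*af)."""
    if weights.n_variants == 0:
        return np.zeros(panel.n_samples)
    idx = pd.Index(panel.variants["id"])
    pos = idx.get_indexer(weights.table["id"])
    if (pos < 0).any():
        missing = weights.table["id"].to_numpy()[pos < 0]
        raise ValueError(f"weights reference variants absent from panel: "
                         f"{list(missing[:5])}")
    X = panel.dosages[:, pos].astype(float)
    af = panel.variants["af"].to_numpy()[pos]
    X = np.where(np.isnan(X), 2.0 * af, X)
    return X @ weights.table["weight"].to_numpy(float)


def simulate_effects(panel: GenotypePanel, model: EffectModel,
                     seed: int) -> WeightSet:
    """Assign sparse causal per-allele effects on the panel's variants.

    Exactly ``n_causal`` variants receive N(0, effect_sd^2) weights. When
    ``per_sd_hr`` is set, weights are rescaled so the SD of the raw score
    equals log(per_sd_hr) — i.e. one score-SD corresponds to that hazard
    ratio; per_sd_hr=1 yields all-zero weights.
    """
    if model.n_causal > panel.n_variants:
        raise ValueError("n_causal exceeds the number of panel variants")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(panel.n_variants, size=model.n_causal,
                             replace=False))
    w = rng.normal(0.0, model.effect_sd, size=model.n_causal)
    sub = panel.variants.iloc[idx]
    ws = WeightSet(
        pd.DataFrame({"id": sub["id"].to_numpy(),
                      "effect_allele": sub["effect_allele"].to_numpy(),
                      "weight": w}),
        provenance="simulated-truth")
    if model.per_sd_hr is not None and model.n_causal > 0:
        target = np.log(model.per_sd_hr)
        if target == 0.0:
            ws.table["weight"] = 0.0
        else:
            s = true_scores(panel, ws).std()
            if s == 0:
                raise ValueError("true score has zero variance; cannot rescale")
            ws.table["weight"] *= target / s
    return ws


# ------------------------------------------------------------- onset model

def calibrate_baseline(onset: OnsetModel, eta: np.ndarray,
                       age: float = 70.0, max_eta_sample: int = 4000) -> OnsetModel:
    """Solve the Weibull baseline scale so the population cause-specific
    cumulative incidence at ``age`` equals ``onset.target_cif70``.

    The CIF is evaluated semi-analytically: for a subsample of relative-risk
    values exp(eta), integrate h0(a)e^eta * exp(-H0(a)e^eta - Hd(a)) over a
    fine age grid and average.
    """
    if onset.target_cif70 is None:
        raise ValueError("target_cif70 is not set")
    eta = np.asarray(eta, float)
    if len(eta) > max_eta_sample:
        step = len(eta) // max_eta_sample
        eta = eta[::step][:max_eta_sample]
    E = np.exp(eta)[:, None]
    grid = np.linspace(0.0, age, 701)
    hd = (onset.death_hazard.cumhaz(grid)
          if onset.death_hazard is not None else np.zeros_like(grid))
    k = onset.baseline_shape

    def cif(scale: float) -> float:
        u = grid / scale
        H0 = u ** k
        h0 = np.zeros_like(grid)
        h0[1:] = k / scale * u[1:] ** (k - 1.0)
        integrand = h0[None, :] * E * np.exp(-H0[None, :] * E - hd[None, :])
        return float(np.trapezoid(integrand, grid, axis=1).mean())

    lo, hi = age / 5.0, age * 200.0
    f_lo, f_hi = cif(lo) - onset.target_cif70, cif(hi) - onset.target_cif70
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            f"target_cif70={onset.target_cif70} unreachable with "
            f"baseline_shape={onset.baseline_shape} and the given death hazard")
    scale = optimize.brentq(lambda s: cif(s) - onset.target_cif70, lo, hi,
                            xtol=1e-4)
    return replace(onset, baseline_scale=float(scale))


def simulate_survival(eta: np.ndarray, onset: OnsetModel, seed: int,
                      sample_ids: Sequence | None = None) -> pd.DataFrame:
    """Draw entry, onset, death and censoring ages for log relative risks eta.

    Onset is inverted from the baseline cumulative hazard scaled by exp(eta);
    the observed event age is min(onset, death, censoring). Subjects dead
    before their recruitment age are excluded (left truncation); subjects with
    onset at or before entry are retained with ``prevalent=1``.
    Deterministic given ``seed``.
    """
    eta = np.asarray(eta, float)
    n = len(eta)
    rng = np.random.default_rng(seed)
    if onset.baseline_scale is None:
        onset = calibrate_baseline(onset, eta)

    lo, hi = onset.recruitment_age_range
    entry = rng.uniform(lo, hi, size=n)
    u = rng.uniform(size=n)
    onset_age = onset.inverse_cumhaz(-np.log(u) * np.exp(-eta))
    if onset.death_hazard is not None and onset.death_hazard.rate0 > 0:
        v = rng.uniform(size=n)
        death_age = onset.death_hazard.inverse_cumhaz(-np.log(v))
    else:
        death_age = np.full(n, np.inf)
    if onset.followup_range is not None:
        fu = rng.uniform(*onset.followup_range, size=n)
        censor_age = np.minimum(onset.admin_censor_age, entry + fu)
    else:
        censor_age = np.full(n, onset.admin_censor_age)

    alive_at_entry = death_age > entry
    ids = (np.asarray(sample_ids) if sample_ids is not None
           else np.array([f"S{i + 1:06d}" for i in range(n)]))

    entry, onset_age, death_age, censor_age, eta_k, ids = (
        a[alive_at_entry] for a in
        (entry, onset_age, death_age, censor_age, eta, ids))

    prevalent = onset_age <= entry
    t = np.minimum(np.minimum(onset_age, death_age), censor_age)
    bc = (onset_age <= t) & ~prevalent
    death = (death_age <= t) & ~bc & ~prevalent
    event_age = np.where(prevalent, onset_age, t)

    return pd.DataFrame({
        "sample_id": ids,
        "entry_age": entry,
        "event_age": event_age,
        "bc_event": np.where(prevalent, 1, bc.astype(int)),
        "death_event": death.astype(int),
        "prevalent": prevalent.astype(int),
    })


def simulate_cohort(panel: GenotypePanel, weights: WeightSet,
                    onset: OnsetModel,
                    fh_model: FamilyHistoryModel | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Full phenotype/covariate table for a genotype panel.

    Event history follows :func:`simulate_survival` with eta the centered true
    score. Family history (0/1, 2 = unknown) is drawn with log-odds increasing
    in the standardized true score. ``clinical_risk`` is a Gail-style absolute
    risk built from entry age, reproductive covariates and family history only
    — independent of genotype given family history.
    """
    fh_model = fh_model or FamilyHistoryModel()
    g = true_scores(panel, weights)
    eta = g - g.mean()
    if onset.baseline_scale is None and onset.target_cif70 is not None:
        onset = calibrate_baseline(onset, eta)
    df = simulate_survival(eta, onset, seed=seed, sample_ids=panel.sample_ids)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    kept = pd.Index(panel.sample_ids).get_indexer(df["sample_id"])
    eta_k = eta[kept]
    sd = eta_k.std()
    z = eta_k / sd if sd > 0 else np.zeros_like(eta_k)
    n = len(df)

    p_fh = expit(logit(fh_model.base_prob) + fh_model.log_or_per_sd * z)
    fh = (rng.uniform(size=n) < p_fh).astype(int)
    unknown = rng.uniform(size=n) < fh_model.unknown_prob
    fh = np.where(unknown, 2, fh)

    df["sex"] = "F"
    df["family_history"] = fh
    df["age_menarche"] = np.clip(rng.normal(13.0, 1.5, size=n), 9, 18).round(1)
    first_birth = np.clip(rng.normal(25.0, 4.0, size=n), 15, 45).round(1)
    nullip = rng.uniform(size=n) < 0.15
    df["age_first_birth"] = np.where(nullip, np.nan, first_birth)
    df["bmi"] = np.clip(rng.normal(26.0, 4.0, size=n), 15, 50).round(1)
    df["smoking"] = (rng.uniform(size=n) < 0.25).astype(int)
    post = df["entry_age"].to_numpy() > 50
    meno = np.clip(rng.normal(50.0, 3.0, size=n), 40, 60).round(1)
    df["age_menopause"] = np.where(post, meno, np.nan)
    for i in range(4):
        df[f"pc{i + 1}"] = rng.standard_normal(n)

    # toy Gail-style 10-year absolute risk: age, menarche, parity, family history
    lin = (-5.2
           + 0.035 * (df["entry_age"].to_numpy() - 50.0)
           + 0.25 * (df["age_menarche"].to_numpy() < 12)
           + 0.15 * (np.nan_to_num(df["age_first_birth"].to_numpy(), nan=26.0) > 30)
           + 0.10 * nullip
           + 0.55 * (fh == 1)
           + rng.normal(0.0, 0.25, size=n))
    df["clinical_risk"] = expit(lin)
    return df


def simulate_score_cohort(n_samples: int, per_sd_hr: float,
                          onset: OnsetModel | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Survival cohort for a standard-normal risk score with a given per-SD HR.

    Draws score ~ N(0,1), sets eta = log(per_sd_hr) * score, calibrates the
    baseline to the onset model's population CIF target, and returns the
    event table of :func:`simulate_survival` with the score attached.
    """
    onset = onset or OnsetModel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    z = rng.standard_normal(n_samples)
    eta = np.log(per_sd_hr) * z
    if onset.baseline_scale is None:
        onset = calibrate_baseline(onset, eta)
    df = simulate_survival(eta, onset, seed=seed)
    orig = df["sample_id"].str[1:].astype(int).to_numpy() - 1
    df["score"] = z[orig]
    return df


# ----------------------------------------------------------- summary stats

def simulate_gwas_sumstats(weights: WeightSet, panel: GenotypePanel,
                           n_cases: int, n_controls: int,
                           scale: str = LOG_OR, seed: int = 0,
                           noise: float = 1.0) -> SummaryStats:
    """Emulate discovery-GWAS summary statistics for the panel's variants.

    Per-variant estimates are the true log-OR effect (zero off the causal set)
    plus Gaussian noise with the analytic case-control standard error
    1/sqrt(2 f(1-f) N phi(1-phi)); p-values are two-sided Wald. ``noise=0``
    gives estimates exactly equal to the truth while keeping the analytic SE.
    Linear-scale output multiplies beta and se by phi(1-phi), so
    :func:`metagrs.sumstats.linear_to_logor` inverts it exactly.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    if scale not in (LINEAR, LOG_OR):
        raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(seed)
    v = panel.variants
    w = np.zeros(panel.n_variants)
    if weights.n_variants:
        pos = pd.Index(v["id"]).get_indexer(weights.table["id"])
        if (pos < 0).any():
            raise ValueError("weights reference variants absent from panel")
        w[pos] = weights.table["weight"].to_numpy(float)

    f = np.clip(v["af"].to_numpy(float), 0.01, 0.99)
    N = n_cases + n_controls
    phi = n_cases / N
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * N * phi * (1.0 - phi))
    est = w + noise * rng.standard_normal(panel.n_variants) * se
    zed = est / se
    p = np.clip(2.0 * sps.norm.sf(np.abs(zed)), 1e-320, 1.0)
    if scale == LINEAR:
        c = phi * (1.0 - phi)
        est, se = est * c, se * c
    table = pd.DataFrame({
        "id": v["id"].to_numpy(),
        "chrom": v["chrom"].to_numpy(),
        "pos": v["pos"].to_numpy(),
        "effect_allele": v["effect_allele"].to_numpy(),
        "other_allele": v["other_allele"].to_numpy(),
        "eaf": v["af"].to_numpy(float),
        "beta": est,
        "se": se,
        "pvalue": p,
    })
    return SummaryStats(table, scale=scale, n_cases=n_cases,
                        n_controls=n_controls)


# -------------------------------------------------------------------- I/O

def write_panel_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF with a per-sample DS dosage field.

    REF is the non-dosage (other) allele, ALT the dosage (effect) allele, so DS
    counts ALT copies. Missing dosages are '.'.
    """
    v = panel.variants
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Alternate allele frequency">\n')
        for c in sorted(v["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.sample_ids)) + "\n")
        for j in order:
            row = v.iloc[j]
            ds = panel.dosages[:, j]
            dss = "\t".join("." if np.isnan(x) else f"{x:g}" for x in ds)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t"
                     f"AF={row['af']:.6g}\tDS\t{dss}\n")


def read_panel_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF with a DS dosage FORMAT field (falls back to GT hard calls)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = np.array(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        try:
            ds = np.asarray(var.format("DS"), float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.genotypes)[:, :2]
            ds = np.where((gt < 0).any(axis=1), np.nan, gt.sum(axis=1)).astype(float)
        af = var.INFO.get("AF")
        rows.append({
            "id": var.ID, "chrom": int(var.CHROM), "pos": var.POS,
            "effect_allele": var.ALT[0], "other_allele": var.REF,
            "af": float(af) if af is not None else np.nanmean(ds) / 2.0,
        })
        cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols).astype(np.float32)
    return GenotypePanel(dosages, variants, sample_ids)


def write_panel_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Write a sample x variant dosage matrix plus a .variants.tsv sidecar."""
    path = Path(path)
    df = pd.DataFrame(panel.dosages, columns=panel.variants["id"],
                      index=pd.Index(panel.sample_ids, name="sample_id"))
    df.to_csv(path, sep="\t", float_format="%g", na_rep="NA")
    panel.variants.to_csv(path.with_suffix(path.suffix + ".variants"),
                          sep="\t", index=False, float_format="%.10g")


def read_panel_tsv(path: str | Path,
                   variants_path: str | Path | None = None) -> GenotypePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    vp = variants_path or path.with_suffix(path.suffix + ".variants")
    variants = pd.read_csv(vp, sep="\t", dtype={"id": str})
    variants = (variants.set_index("id").loc[df.columns]
                .rename_axis("id").reset_index())
    return GenotypePanel(df.to_numpy(np.float32), variants,
                         df.index.to_numpy())


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
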