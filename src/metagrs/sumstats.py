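"""GWAS summary statistics and score weight files.

Reading, validation, allele harmonization against a genotype panel, and the
transformation of linear-model (BLUP/LMM) coefficients to log odds ratios for
a binary trait: with case fraction phi, beta_logOR = beta_linear / (phi*(1-phi)),
applied jointly to the effect and its standard error so Wald z-scores are
preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LINEAR = "linear"
LOG_OR = "log_or"

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}

#: canonical column -> default header name in delimited summary-stats files
DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
}

_REQUIRED = ("id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
             "beta", "se", "pvalue")


@dataclass
class SummaryStats:
    """Per-variant association records on a declared effect scale.

    ``table`` holds one row per variant with canonical columns
    (id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue);
    ``scale`` is 'linear' or 'log_or' and applies uniformly.
    """

    table: pd.DataFrame
    scale: str
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG_OR):
            raise ValueError(f"unknown effect scale {self.scale!r}")
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns {missing}")
        t = self.table
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].unique()
            raise ValueError(f"duplicated variant ids: {list(dups[:10])}")
        p = t["pvalue"].to_numpy(float)
        if len(t) and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
            raise ValueError("p-values must lie in (0, 1]")
        se = t["se"].to_numpy(float)
        if len(t) and np.any(~(se > 0)):
            raise ValueError("standard errors must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.table)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    scale: str = LOG_OR,
    n_cases: int | None = None,
    n_controls: int | None = None,
    info_min: float | None = None,
) -> SummaryStats:
    """Read delimited summary statistics, dropping malformed rows with a log entry.

    ``column_map`` maps canonical names (see DEFAULT_COLUMNS keys) to the file's
    headers; unspecified entries fall back to the defaults. Rows with missing
    beta/se/p, p outside (0,1], non-positive se, or non-ACGT alleles are dropped
    and counted. Duplicated variant ids raise. ``info_min`` optionally filters on
    an INFO imputation-quality column when present.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", comment="#", dtype={cols["id"]: str},
                     float_precision="round_trip")
    rename = {v: k for k, v in cols.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cannot resolve required columns {missing}")

    for c in ("pos", "eaf", "beta", "se", "pvalue"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n0 = len(df)
    df = df.dropna(subset=["beta", "se", "pvalue"])
    n_missing = n0 - len(df)

    bad_p = (df["pvalue"] <= 0) | (df["pvalue"] > 1) | (df["se"] <= 0)
    n_badp = int(bad_p.sum())
    df = df[~bad_p]

    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    ok = ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES)
    n_alleles = int((~ok).sum())
    df = df[ok].assign(effect_allele=ea[ok], other_allele=oa[ok])

    n_info = 0
    if info_min is not None and "INFO" in df.columns:
        keep = pd.to_numeric(df["INFO"], errors="coerce") >= info_min
        n_info = int((~keep).sum())
        df = df[keep]

    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].unique()
        raise ValueError(f"{path}: duplicated variant ids {list(dups[:10])}")
    if n_missing or n_badp or n_alleles or n_info:
        log.info(
            "read_sumstats(%s): dropped %d missing, %d invalid p/se, "
            "%d non-ACGT, %d low-INFO rows", path, n_missing, n_badp,
            n_alleles, n_info,
        )
    df = df.reset_index(drop=True)
    return SummaryStats(df, scale=scale, n_cases=n_cases, n_controls=n_controls)


def write_sumstats(stats: SummaryStats, path: str | Path) -> None:
    """Write tab-delimited summary statistics with the default headers."""
    out = stats.table[list(_REQUIRED)].rename(
        columns={k: v for k, v in DEFAULT_COLUMNS.items()}
    )
    with open(path, "w") as fh:
        fh.write(f"# scale={stats.scale} n_cases={stats.n_cases} "
                 f"n_controls={stats.n_controls}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def linear_to_logor(
    stats: SummaryStats,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> SummaryStats:
    """Convert linear-scale effects on a binary trait to log odds ratios.

    Divides beta and se by phi*(1-phi), phi = n_cases/(n_cases+n_controls).
    P-values are unchanged (the transform preserves z = beta/se).
    """
    if stats.scale == LOG_OR:
        raise ValueError("summary statistics are already on the log-OR scale")
    n_cases = n_cases if n_cases is not None else stats.n_cases
    n_controls = n_controls if n_controls is not None else stats.n_controls
    if not n_cases or not n_controls or n_cases <= 0 or n_controls <= 0:
        raise ValueError("positive n_cases and n_controls are required")
    phi = n_cases / (n_cases + n_controls)
    c = phi * (1.0 - phi)
    t = stats.table.copy()
    t["beta"] = t["beta"] / c
    t["se"] = t["se"] / c
    return SummaryStats(t, scale=LOG_OR, n_cases=n_cases, n_controls=n_controls)


def harmonize_alleles(
    stats: SummaryStats,
    panel,
    drop_palindromic: bool = False,
) -> tuple[SummaryStats, dict]:
    """Orient effect alleles onto the panel's dosage (effect) allele.

    Variants absent from the panel are dropped. Where the stats effect allele is
    the panel's other allele, beta is negated and eaf complemented. A/T and C/G
    pairs are dropped when ``drop_palindromic``. Irreconcilable allele pairs are
    dropped and logged. Matching is by id, with a (chrom, pos, allele-set)
    fallback for ids the panel does not know. Returns the harmonized stats and a
    report of counts; applying the operation twice equals applying it once.
    """
    pv = panel.variants
    t = stats.table.copy()
    report = {"n_input": len(t)}

    pidx = pv.set_index("id")
    in_panel = t["id"].isin(pidx.index)
    # fallback: recover panel ids by position where the allele sets agree
    if (~in_panel).any():
        bypos = pv.set_index(["chrom", "pos"])
        sub = t.loc[~in_panel]
        for i, row in sub.iterrows():
            key = (row["chrom"], row["pos"])
            if key in bypos.index:
                cand = bypos.loc[[key]]
                for _, c in cand.iterrows():
                    if {row["effect_allele"], row["other_allele"]} == \
                            {c["effect_allele"], c["other_allele"]}:
                        t.at[i, "id"] = c["id"] if "id" in c else cand.index[0]
                        in_panel.at[i] = True
                        break
    report["n_absent"] = int((~in_panel).sum())
    t = t[in_panel.to_numpy()]

    pe = pidx.loc[t["id"], "effect_allele"].to_numpy()
    po = pidx.loc[t["id"], "other_allele"].to_numpy()
    se_, so_ = t["effect_allele"].to_numpy(), t["other_allele"].to_numpy()

    same = (se_ == pe) & (so_ == po)
    swapped = (se_ == po) & (so_ == pe)
    bad = ~(same | swapped)
    report["n_irreconcilable"] = int(bad.sum())
    if bad.any():
        log.info("harmonize_alleles: dropped %d variants with irreconcilable "
                 "allele pairs", int(bad.sum()))

    t = t[~bad]
    swapped = swapped[~bad]
    t.loc[swapped, "beta"] = -t.loc[swapped, "beta"].to_numpy()
    t.loc[swapped, "eaf"] = 1.0 - t.loc[swapped, "eaf"].to_numpy()
    ea = t["effect_allele"].to_numpy().copy()
    t.loc[swapped, "effect_allele"] = t.loc[swapped, "other_allele"].to_numpy()
    t.loc[swapped, "other_allele"] = ea[swapped]
    report["n_flipped"] = int(swapped.sum())

    if drop_palindromic:
        pal = np.array(
            [frozenset((a, b)) in _PALINDROMIC
             for a, b in zip(t["effect_allele"], t["other_allele"])]
        )
        report["n_palindromic"] = int(pal.sum())
        t = t[~pal]
    else:
        report["n_palindromic"] = 0

    report["n_output"] = len(t)
    out = SummaryStats(t.reset_index(drop=True), scale=stats.scale,
                       n_cases=stats.n_cases, n_controls=stats.n_controls)
    return out, report


@dataclass
class WeightSet:
    """A score definition: per-variant effect allele and log-OR-scale weight."""

    table: pd.DataFrame  # columns: id, effect_allele, weight
    provenance: str = ""
    p_threshold: float | None = None

    def __post_init__(self) -> None:
        need = [c for c in ("id", "effect_allele", "weight")
                if c not in self.table.columns]
        if need:
            raise ValueError(f"weight set missing columns {need}")
        w = self.table["weight"].to_numpy(float)
        if len(w) and not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if self.table["id"].duplicated().any():
            raise ValueError("duplicated variant ids in weight set")

    @property
    def n_variants(self) -> int:
        return len(self.table)


def read_weightset(path: str | Path) -> WeightSet:
    """Read a PLINK-style 3-column (variant, effect allele, weight) score file.

    A header line is optional and detected by a non-numeric third field. A
    sidecar ``<path>.json`` written by :func:`write_weightset` restores
    provenance and the p-value threshold.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty weight file")
    start = 0
    first = lines[0].split()
    if len(first) < 3:
        raise ValueError(f"{path}: expected 3 columns (variant, allele, weight)")
    try:
        float(first[2])
    except ValueError:
        start = 1  # header line
    for ln_no, ln in enumerate(lines[start:], start=start + 1):
        f = ln.split()
        if len(f) < 3:
            raise ValueError(f"{path}:{ln_no}: expected 3 columns")
        try:
            w = float(f[2])
        except ValueError:
            raise ValueError(f"{path}:{ln_no}: non-numeric weight {f[2]!r}")
        rows.append((f[0], f[1].upper(), w))
    if not rows:
        raise ValueError(f"{path}: no weight records")
    df = pd.DataFrame(rows, columns=["id", "effect_allele", "weight"])
    provenance, p_threshold = path.name, None
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.loads(side.read_text())
        provenance = meta.get("provenance", provenance)
        p_threshold = meta.get("p_threshold")
    return WeightSet(df, provenance=provenance, p_threshold=p_threshold)


def write_weightset(ws: WeightSet, path: str | Path) -> None:
    """Write the PLINK-compatible 3-column file plus a JSON provenance sidecar."""
    path = Path(path)
    ws.table[["id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.17g")
    meta = {"provenance": ws.provenance, "p_threshold": ws.p_threshold,
            "n_variants": ws.n_variants}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
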