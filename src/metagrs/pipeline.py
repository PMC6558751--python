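"""End-to-end workflow: simulate -> build scores -> select -> combine -> evaluate.

Every stage writes its artifacts under the output directory and the manifest
records seeds, parameters and file hashes; rerunning with the same config
reproduces all stochastic outputs bit-for-bit, and a deleted intermediate is
regenerated identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simcohort, scores as scores_mod, sumstats as ss_mod
from . import surveval, training
from .scores import DEFAULT_THRESHOLDS, ScoreSet, compute_scores, ld_prune, \
    threshold_subsets
from .simcohort import EffectModel, FamilyHistoryModel, LDBlockSpec, \
    OnsetModel, simulate_cohort, simulate_effects, simulate_genotypes, \
    simulate_gwas_sumstats
from .sumstats import harmonize_alleles, linear_to_logor, read_sumstats, \
    read_weightset, write_sumstats, write_weightset
from .surveval import FIG2_STRATA, StrataSpec, aalen_johansen, \
    age_at_risk_level, c_increment, cross_classify, fit_cox, harrells_c, \
    interaction_test, stratified_hr

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for the full workflow.

    With no input paths the pipeline simulates its own biobank (panel, cohort,
    two discovery summary-statistics sources, two 'published' multigenic weight
    files). Paths, when given, replace the corresponding simulated inputs.
    """

    outdir: str = "metagrs_run"
    seed: int = 7
    # synthetic inputs
    n_samples: int = 20000
    n_blocks: int = 60
    block_size: int = 8
    within_r: float = 0.35
    n_causal: int = 120
    per_sd_hr: float = 1.65
    onco_design: tuple[int, int] = (122_977, 105_974)   # cases, controls
    uk_design: tuple[int, int] = (7_480, 329_679)
    multigenic_sizes: tuple[int, int] = (70, 75)
    multigenic_noise: float = 0.3   # relative weight noise of published scores
    # score construction
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    r2_max: float = 0.1
    window_bp: int = 1_000_000
    # training split
    n_train_controls: int = 2000
    # optional real inputs
    genotypes_path: str | None = None
    cohort_path: str | None = None
    sumstats_paths: dict | None = None   # label -> {path, scale, n_cases, n_controls}
    weight_paths: dict | None = None     # label -> path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for k in ("onco_design", "uk_design", "multigenic_sizes", "thresholds"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seed(base: int, label: str) -> int:
    h = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "files": {}}
    stage = "simulate"
    try:
        bundle = _stage_inputs(config, out, manifest)
        stage = "build-scores"
        _stage_scores(config, out, manifest, bundle)
        stage = "select"
        _stage_select(config, out, manifest, bundle)
        stage = "combine"
        _stage_combine(config, out, manifest, bundle)
        stage = "evaluate"
        _stage_evaluate(config, out, manifest, bundle)
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
        raise PipelineError(stage, exc) from exc
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return manifest


# ------------------------------------------------------------------ stages

def _stage_inputs(cfg: PipelineConfig, out: Path, manifest: dict) -> dict:
    b: dict = {}
    if cfg.genotypes_path:
        b["panel"] = (simcohort.read_panel_vcf(cfg.genotypes_path)
                      if str(cfg.genotypes_path).endswith(".vcf")
                      else simcohort.read_panel_tsv(cfg.genotypes_path))
    else:
        ld = LDBlockSpec(cfg.n_blocks, cfg.block_size, cfg.within_r)
        b["panel"] = simulate_genotypes(cfg.n_samples, ld,
                                        seed=_seed(cfg.seed, "panel"))
    panel = b["panel"]

    truth = simulate_effects(panel, EffectModel(cfg.n_causal,
                                                per_sd_hr=cfg.per_sd_hr),
                             seed=_seed(cfg.seed, "effects"))
    b["truth"] = truth
    write_weightset(truth, out / "truth_weights.txt")

    if cfg.cohort_path:
        b["cohort"] = simcohort.read_cohort(cfg.cohort_path)
    else:
        b["cohort"] = simulate_cohort(panel, truth, OnsetModel(),
                                      FamilyHistoryModel(),
                                      seed=_seed(cfg.seed, "cohort"))
    simcohort.write_cohort(b["cohort"], out / "cohort.tsv")

    b["sumstats"] = {}
    if cfg.sumstats_paths:
        for label, spec in cfg.sumstats_paths.items():
            ss = read_sumstats(spec["path"], scale=spec.get("scale", "log_or"),
                               n_cases=spec.get("n_cases"),
                               n_controls=spec.get("n_controls"))
            if ss.scale == ss_mod.LINEAR:
                ss = linear_to_logor(ss)
            b["sumstats"][label] = harmonize_alleles(
                ss, panel, drop_palindromic=True)[0]
    else:
        onco = simulate_gwas_sumstats(truth, panel, *cfg.onco_design,
                                      scale="log_or",
                                      seed=_seed(cfg.seed, "onco"))
        uk_lin = simulate_gwas_sumstats(truth, panel, *cfg.uk_design,
                                        scale="linear",
                                        seed=_seed(cfg.seed, "uk"))
        write_sumstats(onco, out / "sumstats_onco.tsv")
        write_sumstats(uk_lin, out / "sumstats_uk_linear.tsv")
        uk = linear_to_logor(uk_lin)
        b["sumstats"] = {"ONCO": harmonize_alleles(onco, panel)[0],
                         "UK": harmonize_alleles(uk, panel)[0]}

    b["published"] = {}
    if cfg.weight_paths:
        for label, path in cfg.weight_paths.items():
            b["published"][label] = read_weightset(path)
    else:
        # emulate previously published multigenic scores: the largest true
        # effects, observed with independent study noise
        rng = np.random.default_rng(_seed(cfg.seed, "published"))
        tt = truth.table.assign(absw=lambda d: d["weight"].abs())
        tt = tt.sort_values("absw", ascending=False)
        for label, size in zip(("GRS70", "GRS75"), cfg.multigenic_sizes):
            size = min(size, len(tt))
            sub = tt.iloc[:size]
            w = sub["weight"].to_numpy() * (
                1.0 + cfg.multigenic_noise * rng.standard_normal(size))
            ws = ss_mod.WeightSet(
                pd.DataFrame({"id": sub["id"].to_numpy(),
                              "effect_allele": sub["effect_allele"].to_numpy(),
                              "weight": w}),
                provenance=f"published-{label}")
            write_weightset(ws, out / f"published_{label}.txt")
            b["published"][label] = ws
    manifest["stages"]["simulate"] = {
        "n_samples": panel.n_samples, "n_variants": panel.n_variants,
        "n_cohort": len(b["cohort"]),
        "n_prevalent": int(b["cohort"]["prevalent"].sum()),
        "n_incident": int(((b["cohort"]["bc_event"] == 1)
                           & (b["cohort"]["prevalent"] == 0)).sum()),
    }
    return b


def _stage_scores(cfg: PipelineConfig, out: Path, manifest: dict,
                  b: dict) -> None:
    panel, cohort = b["panel"], b["cohort"]
    candidates: dict[str, list] = {}
    pruned: dict[str, list[str]] = {}
    for label, ss in b["sumstats"].items():
        kept = ld_prune(ss, panel, r2_max=cfg.r2_max, window_bp=cfg.window_bp)
        pruned[label] = kept
        candidates[label] = threshold_subsets(ss, kept, cfg.thresholds,
                                              provenance=label)
    b["candidates"] = candidates

    scoreset = ScoreSet(panel.sample_ids)
    for label, wss in candidates.items():
        for ws in wss:
            name = f"{label}@{ws.p_threshold:g}"
            if ws.n_variants == 0:
                scoreset.add(name, np.zeros(panel.n_samples), n_variants=0)
                continue
            res = compute_scores(panel, ws)
            scoreset.add(name, res.values, n_variants=ws.n_variants)
    for label, ws in b["published"].items():
        res = compute_scores(panel, _orient(ws, panel))
        scoreset.add(label, res.values, n_variants=ws.n_variants)
    b["scoreset"] = scoreset
    manifest["stages"]["build-scores"] = {
        "n_candidates": sum(len(v) for v in candidates.values()),
        "pruned_per_source": {k: len(v) for k, v in pruned.items()},
    }


def _orient(ws, panel):
    """Flip published weights onto the panel's dosage allele by id."""
    pv = panel.variants.set_index("id")
    t = ws.table[ws.table["id"].isin(pv.index)].copy()
    pe = pv.loc[t["id"], "effect_allele"].to_numpy()
    po = pv.loc[t["id"], "other_allele"].to_numpy()
    flip = t["effect_allele"].to_numpy() == po
    t.loc[flip, "weight"] = -t.loc[flip, "weight"].to_numpy()
    t.loc[flip, "effect_allele"] = pe[flip]
    keep = (t["effect_allele"].to_numpy() == pe)
    return ss_mod.WeightSet(t[keep].reset_index(drop=True),
                            provenance=ws.provenance,
                            p_threshold=ws.p_threshold)


def _stage_select(cfg: PipelineConfig, out: Path, manifest: dict,
                  b: dict) -> None:
    cohort, scoreset = b["cohort"], b["scoreset"]
    rng = np.random.default_rng(_seed(cfg.seed, "controls"))
    prevalent = cohort[cohort["prevalent"] == 1]
    pool = cohort[(cohort["prevalent"] == 0) & (cohort["bc_event"] == 0)]
    n_controls = min(cfg.n_train_controls, len(pool))
    controls = pool.iloc[np.sort(rng.choice(len(pool), n_controls,
                                            replace=False))]
    train = pd.concat([prevalent, controls])
    b["train_ids"] = train["sample_id"].to_numpy()
    labels = pd.Series(np.r_[np.ones(len(prevalent)), np.zeros(len(controls))],
                       index=b["train_ids"])
    age = pd.Series(train["entry_age"].to_numpy(), index=b["train_ids"])

    winners = {}
    selections = {}
    for label in b["candidates"]:
        names = [f"{label}@{ws.p_threshold:g}" for ws in b["candidates"][label]]
        for n in names:
            if scoreset.meta[n].get("n_variants") and \
                    not scoreset.is_standardized(n):
                try:
                    scoreset.standardize(n, b["train_ids"])
                except ValueError:
                    scoreset.meta[n]["n_variants"] = 0
        sel = training.select_best_threshold(scoreset, labels, age, names)
        sel.table.to_csv(out / f"selection_{label}.tsv", sep="\t", index=False,
                         float_format="%.10g")
        winners[label] = sel.winner
        selections[label] = sel
    b["labels"], b["age"], b["winners"] = labels, age, winners
    manifest["stages"]["select"] = {"winners": winners}


def _stage_combine(cfg: PipelineConfig, out: Path, manifest: dict,
                   b: dict) -> None:
    cohort, scoreset = b["cohort"], b["scoreset"]
    components = list(b["published"]) + list(b["winners"].values())
    for c in components:
        if not scoreset.is_standardized(c):
            scoreset.standardize(c, b["train_ids"])

    incident = cohort[(cohort["prevalent"] == 0)
                      & ~cohort["sample_id"].isin(b["train_ids"])].copy()
    b["incident"] = incident
    order = training.rank_components(incident, scoreset, components)
    meta4 = training.fit_metagrs(scoreset, b["labels"], b["age"], components,
                                 training_id="prevalent-cc")
    meta3 = training.fit_metagrs(scoreset, b["labels"], b["age"], order[:3],
                                 training_id="prevalent-cc")
    meta2 = training.fit_metagrs(scoreset, b["labels"], b["age"], order[:2],
                                 training_id="prevalent-cc")
    for name, mw in (("metaGRS_4", meta4), ("metaGRS_3", meta3),
                     ("metaGRS_2", meta2)):
        mw.to_tsv(out / f"{name}_weights.tsv")
        training.combine(scoreset, mw, name=name, reference_ids=b["train_ids"])
    b["components"] = components
    b["all_scores"] = components + ["metaGRS_4", "metaGRS_3", "metaGRS_2"]
    scoreset.to_tsv(out / "scores.tsv")
    manifest["stages"]["combine"] = {"component_ranking": order}


def _stage_evaluate(cfg: PipelineConfig, out: Path, manifest: dict,
                    b: dict) -> None:
    scoreset = b["scoreset"]
    incident = b["incident"].copy()
    ids = incident["sample_id"]
    for s in b["all_scores"]:
        vals = scoreset.table.loc[ids, s].to_numpy()
        sd = vals.std(ddof=1)
        incident[s] = (vals - vals.mean()) / sd  # per-SD on the analysis set
    cr = incident["clinical_risk"].to_numpy(float)
    incident["clinical_risk"] = (cr - cr.mean()) / cr.std(ddof=1)

    rows = []
    for s in b["all_scores"]:
        crude = fit_cox(incident, [s], timescale="followup")
        adj = fit_cox(incident, [s, "clinical_risk"], timescale="followup")
        c = harrells_c(incident, s, timescale="followup")
        c_base, c_joint, delta = c_increment(incident, "clinical_risk", s,
                                             timescale="followup")
        p_int = interaction_test(incident, s, "clinical_risk",
                                 timescale="followup")
        r = crude.table.loc[s]
        ra = adj.table.loc[s]
        rows.append((s, r["hr"], r["ci_low"], r["ci_high"], r["pvalue"],
                     ra["hr"], c, c_base, c_joint, delta, p_int))
    table1 = pd.DataFrame(rows, columns=[
        "score", "hr_per_sd", "ci_low", "ci_high", "pvalue",
        "hr_per_sd_adj_clinical", "harrells_c", "c_clinical",
        "c_clinical_plus_score", "c_increment", "p_interaction"])
    table1.to_csv(out / "table1.tsv", sep="\t", index=False,
                  float_format="%.6g")

    best = "metaGRS_2"
    strata_fit = stratified_hr(incident, best, FIG2_STRATA)
    strata_fit.table.to_csv(out / "strata_hr.tsv", sep="\t",
                            float_format="%.6g")
    curves = aalen_johansen(incident, best, FIG2_STRATA)
    curves["all"] = aalen_johansen(incident)["all"]
    pd.concat([c.to_frame() for c in curves.values()]).to_csv(
        out / "cif_curves.tsv", sep="\t", index=False, float_format="%.6g")
    ages5 = {k: age_at_risk_level(c, 0.05) for k, c in curves.items()}

    cross = cross_classify(scoreset, b["all_scores"][:2] + [best], cut=95.0)
    (out / "cross_classification.json").write_text(
        json.dumps(cross, indent=1, default=str))

    fh = (incident["family_history"] == 1).astype(float)
    incident["_fh"] = fh
    fit_u = fit_cox(incident, ["_fh"], timescale="age")
    fit_a = fit_cox(incident, ["_fh", best], timescale="age")
    att = surveval.attenuation(fit_u, fit_a, term="_fh")

    scan = surveval.association_scan(
        scoreset, incident,
        [("age_menarche", "continuous", True), ("bmi", "continuous", True),
         ("smoking", "binary", True), ("death_event", "tte")],
        score_names=b["all_scores"])
    scan.to_csv(out / "association_scan.tsv", sep="\t", index=False,
                float_format="%.6g")

    manifest["stages"]["evaluate"] = {
        "n_incident": len(incident),
        "n_events": int(incident["bc_event"].sum()),
        "cif70": {k: c.cif_at(70.0) for k, c in curves.items()},
        "age_at_5pct": ages5,
        "fh_attenuation_pct": att,
    }


# ------------------------------------------------------------------ report

def report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run (values read from the TSVs)."""
    out = Path(outdir)
    man_path = out / "manifest.json"
    if not man_path.exists():
        raise ValueError(f"{out}: no manifest.json; run the pipeline first")
    man = json.loads(man_path.read_text())
    lines = ["metaGRS pipeline report", "=" * 40]
    sim = man["stages"].get("simulate", {})
    lines.append(f"cohort: {sim.get('n_cohort')} women, "
                 f"{sim.get('n_prevalent')} prevalent / "
                 f"{sim.get('n_incident')} incident cases")
    sel = man["stages"].get("select", {}).get("winners", {})
    for k, v in sel.items():
        lines.append(f"selected threshold [{k}]: {v}")
    t1 = out / "table1.tsv"
    if t1.exists():
        df = pd.read_csv(t1, sep="\t")
        lines.append("")
        lines.append("score            HR/SD  95% CI          c      dC(clin)")
        for _, r in df.iterrows():
            lines.append(
                f"{r['score']:<16s} {r['hr_per_sd']:5.2f}  "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f})     "
                f"{r['harrells_c']:.3f}  {r['c_increment']:+.3f}")
    else:
        lines.append("[table1.tsv missing — evaluate stage skipped]")
    cif = man["stages"].get("evaluate", {}).get("cif70")
    if cif:
        lines.append("")
        lines.append("cumulative incidence at age 70 (%):")
        for k, v in cif.items():
            lines.append(f"  {k:<10s} {100 * v:5.1f}")
    return "\n".join(lines)
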