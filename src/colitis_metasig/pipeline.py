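"""End-to-end orchestration: simulate -> normalize -> DE -> metasignature ->
overlap -> open field -> group statistics -> gene-phenotype correlation.

A run is configured by a YAML file (validated with pydantic), is fully
deterministic under its seed, and writes every stage's outputs plus a
machine-readable JSON run report with parameter echoes, output checksums
and headline counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import counts as counts_mod
from . import diffexp, genepheno, metasig, openfield, statgate, synthdata

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = [
    "simulate",
    "normalize",
    "de",
    "metasig",
    "overlap",
    "openfield",
    "stats",
    "correlate",
]


class CountsSection(BaseModel):
    n_genes: int = 1000
    n_per_group: int = 5
    baseline_log_mean: float = 5.5
    baseline_log_sd: float = 1.0
    dispersion: float = 0.2
    n_perturbed: int = 100
    lfc_magnitude: float = 1.5
    library_size_cv: float = 0.3


class NormSection(BaseModel):
    min_reads: int = 10
    mode: str = "sequential"
    quantile: float = 0.75
    quantile_genes: str = "present"


class DESection(BaseModel):
    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    dispersion_method: str = "pooled_mom"


class BiosetsSection(BaseModel):
    n_lists: int = 18
    n_genes_universe: int = 1000
    planted_penetrance: float = 0.7
    noise_rate: float = 0.02
    fc_mean: float = 2.5
    fc_sigma_log: float = 0.2
    # fraction of mapped planted DE genes whose human orthologs seed the
    # planted bioset signature (ties the two species' truths together)
    de_signature_fraction: float = 0.6


class MetasigSection(BaseModel):
    list_fc_min: float = 1.5
    list_p_max: float = 0.05
    min_votes: int = 9
    mean_fc_min: float = 2.0
    direction_rule: str = "strict_all"


class OrthologSection(BaseModel):
    mapped_fraction: float = 0.81


class BeamGroup(BaseModel):
    rear_rate: float
    rear_duration_mean: float
    rear_duration_sd: float = 0.5
    ambulation_rate: float
    fine_rate: float = 10.0


class BeamsSection(BaseModel):
    session_length: float = 3600.0
    # DSS animals rear less, for shorter bouts, and ambulate less
    control: BeamGroup = Field(
        default_factory=lambda: BeamGroup(
            rear_rate=2.0, rear_duration_mean=1.5, ambulation_rate=20.0
        )
    )
    dss: BeamGroup = Field(
        default_factory=lambda: BeamGroup(
            rear_rate=1.0, rear_duration_mean=0.8, ambulation_rate=14.0
        )
    )


class StatsSection(BaseModel):
    alpha: float = 0.05
    outlier_sd: float = 2.0
    grubbs_alpha: float = 0.05
    metrics: list[str] = Field(
        default_factory=lambda: [
            "rears",
            "xy_ambulation",
            "normalized_rears",
            "avg_rear_duration",
        ]
    )


class CorrelateSection(BaseModel):
    metric: str = "avg_rear_duration"
    method: str = "pearson"
    k: int = 25


class RunConfig(BaseModel):
    seed: int = 0
    out_dir: str = "results/run"
    stages: list[str] = Field(default_factory=lambda: list(ALL_STAGES))
    counts_path: str | None = None  # use an existing count matrix instead of simulating
    groups_path: str | None = None
    counts: CountsSection = Field(default_factory=CountsSection)
    norm: NormSection = Field(default_factory=NormSection)
    de: DESection = Field(default_factory=DESection)
    biosets: BiosetsSection = Field(default_factory=BiosetsSection)
    metasig: MetasigSection = Field(default_factory=MetasigSection)
    orthologs: OrthologSection = Field(default_factory=OrthologSection)
    beams: BeamsSection = Field(default_factory=BeamsSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    correlate: CorrelateSection = Field(default_factory=CorrelateSection)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, BaseModel):
        return _jsonable(obj.model_dump())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the run report.

    Identical config + seed reruns produce byte-identical outputs. A stage
    failure aborts downstream stages; the partial report (with the failure
    recorded) is still written before the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "counts": {}, "warnings": []}

    # pre-flight: referenced input paths must exist before any stage runs
    for p in (cfg.counts_path, cfg.groups_path):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")

    state: dict[str, Any] = {}

    def record(stage: str, params: Any, outputs: list[Path]) -> None:
        report["stages"][stage] = {
            "params": _jsonable(params),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    def write_report() -> None:
        with open(out / "run_report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")

    try:
        for stage in [s for s in ALL_STAGES if s in cfg.stages]:
            _STAGE_FUNCS[stage](cfg, out, state, report, record)
    except Exception as e:  # partial report with the failure recorded
        report["failure"] = {"stage": stage, "error": f"{type(e).__name__}: {e}"}
        write_report()
        raise
    write_report()
    return report


def _stage_simulate(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    outputs = []
    if cfg.counts_path is not None:
        groups = None
        if cfg.groups_path:
            gdf = pd.read_csv(cfg.groups_path, sep="\t", index_col=0)
            groups = gdf.iloc[:, 0]
        m = counts_mod.read_counts(cfg.counts_path, groups=groups)
        truth: dict[str, str] = {}
    else:
        ccfg = synthdata.CountSimConfig(seed=cfg.seed, **cfg.counts.model_dump())
        m, truth = synthdata.simulate_counts(ccfg)
    state["counts"], state["counts_truth"] = m, truth
    counts_mod.write_counts(m, out / "counts.tsv")
    outputs.append(out / "counts.tsv")
    with open(out / "counts_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    outputs.append(out / "counts_truth.json")

    omap = synthdata.simulate_ortholog_map(
        list(m.genes), cfg.orthologs.mapped_fraction, seed=cfg.seed + 1
    )
    state["orthologs"] = omap
    omap.pairs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    outputs.append(out / "orthologs.tsv")

    # plant the bioset signature on human orthologs of a fraction of the
    # perturbed mouse genes, so the species overlap has a real signal
    rng = np.random.default_rng(cfg.seed + 2)
    mapped = omap.map_genes(sorted(truth))
    candidates = sorted(g for g in truth if g in mapped)
    n_seed = int(round(cfg.biosets.de_signature_fraction * len(candidates)))
    chosen = list(rng.choice(candidates, size=n_seed, replace=False)) if n_seed else []
    signature = {mapped[g][0]: truth[g] for g in chosen}
    bcfg = synthdata.BiosetSimConfig(
        n_lists=cfg.biosets.n_lists,
        n_genes_universe=cfg.biosets.n_genes_universe,
        planted_signature=signature,
        planted_penetrance=cfg.biosets.planted_penetrance,
        fc_magnitude_dist=synthdata.FcDist(cfg.biosets.fc_mean, cfg.biosets.fc_sigma_log),
        noise_rate=cfg.biosets.noise_rate,
        seed=cfg.seed + 3,
    )
    biosets, sig_truth = synthdata.simulate_biosets(bcfg)
    state["biosets"], state["bioset_truth"] = biosets, sig_truth
    state["bioset_universe"] = bcfg.universe
    bdir = out / "biosets"
    bdir.mkdir(exist_ok=True)
    for b in biosets:
        metasig.write_bioset(b, bdir / f"{b.study_id}.tsv")
        outputs.append(bdir / f"{b.study_id}.tsv")
    with open(out / "bioset_truth.json", "w") as fh:
        json.dump(sig_truth, fh, indent=2, sort_keys=True)
    outputs.append(out / "bioset_truth.json")

    streams, beam_truth = [], {}
    sdir = out / "beams"
    sdir.mkdir(exist_ok=True)
    if state["counts"].groups is None:
        raise ValueError("count matrix must carry group labels for behavioral stages")
    for i, (animal, group) in enumerate(state["counts"].groups.items()):
        grp = cfg.beams.dss if group == "dss" else cfg.beams.control
        bscfg = synthdata.BeamSimConfig(
            session_length=cfg.beams.session_length,
            seed=cfg.seed + 100 + i,
            **grp.model_dump(),
        )
        stream, truth_panel = synthdata.simulate_beam_stream(bscfg, animal_id=animal)
        streams.append(stream)
        beam_truth[animal] = truth_panel
        openfield.write_stream(stream, sdir / f"{animal}.csv")
        outputs.append(sdir / f"{animal}.csv")
    state["streams"], state["beam_truth"] = streams, beam_truth
    with open(out / "beam_truth.json", "w") as fh:
        json.dump(_jsonable(beam_truth), fh, indent=2, sort_keys=True)
    outputs.append(out / "beam_truth.json")

    record("simulate", cfg.model_dump(include={"counts", "biosets", "beams", "orthologs"}), outputs)
    report["counts"]["n_genes"] = int(len(state["counts"].genes))
    report["counts"]["n_planted_de"] = len(truth)
    report["counts"]["n_planted_signature"] = len(sig_truth)


def _stage_normalize(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    m = state["counts"]
    normalized, factors = counts_mod.normalize(
        m,
        min_reads=cfg.norm.min_reads,
        mode=cfg.norm.mode,  # type: ignore[arg-type]
        quantile=cfg.norm.quantile,
        quantile_genes=cfg.norm.quantile_genes,  # type: ignore[arg-type]
    )
    state["normalized"] = normalized
    normalized.to_csv(out / "normalized.tsv", sep="\t", index_label="gene")
    factors.to_frame().to_csv(out / "factors.tsv", sep="\t", index_label="sample")
    record("normalize", cfg.norm, [out / "normalized.tsv", out / "factors.tsv"])


def _stage_de(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    decfg = diffexp.DEConfig(
        fc_threshold=cfg.de.fc_threshold,
        p_threshold=cfg.de.p_threshold,
        dispersion_method=cfg.de.dispersion_method,  # type: ignore[arg-type]
        min_reads=cfg.norm.min_reads,
    )
    de = diffexp.run_de(
        state["counts"], "control", "dss", decfg, normalized=state.get("normalized")
    )
    state["de"] = de
    de.to_csv(out / "de.tsv", sep="\t", index_label="gene")
    record("de", cfg.de, [out / "de.tsv"])
    report["counts"]["genes_tested"] = int(de["tested"].sum())
    report["counts"]["genes_significant"] = int(de["significant"].sum())


def _stage_metasig(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    mcfg = metasig.MetasigConfig(
        list_fc_min=cfg.metasig.list_fc_min,
        list_p_max=cfg.metasig.list_p_max,
        min_votes=cfg.metasig.min_votes,
        n_lists=cfg.biosets.n_lists,
        mean_fc_min=cfg.metasig.mean_fc_min,
        direction_rule=cfg.metasig.direction_rule,  # type: ignore[arg-type]
    )
    sig = metasig.derive_metasignature(state["biosets"], mcfg)
    state["metasig"] = sig
    sig.to_csv(out / "metasignature.tsv", sep="\t", index=False)
    record("metasig", cfg.metasig, [out / "metasignature.tsv"])
    report["counts"]["metasignature_size"] = int(len(sig))


def _stage_overlap(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    de, sig, omap = state["de"], state["metasig"], state["orthologs"]
    de_genes = de.index[de["significant"]].tolist()
    de_dirs = {g: de.loc[g, "direction"] for g in de_genes}
    sig_dirs = dict(zip(sig["gene"], sig["direction"]))
    # universe: genes measurable in both species through the map
    universe = omap.mapped_set(state["counts"].genes) & set(state["bioset_universe"])
    res = metasig.overlap(
        de_genes,
        sig["gene"],
        omap,
        universe,
        directions_a=de_dirs,
        directions_b=sig_dirs,
    )
    state["overlap"] = res
    with open(out / "overlap.json", "w") as fh:
        json.dump(_jsonable(res), fh, indent=2, sort_keys=True)
    record("overlap", {"universe_size": len(universe)}, [out / "overlap.json"])
    report["counts"]["overlap_size"] = res.n_overlap


def _stage_openfield(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    panels = [openfield.compute_metrics(s) for s in state["streams"]]
    state["metrics"] = panels
    wide = openfield.metrics_frame(panels)
    wide["group"] = state["counts"].groups.loc[wide.index]
    state["metrics_frame"] = wide
    wide.to_csv(out / "openfield_metrics.csv")
    record("openfield", {}, [out / "openfield_metrics.csv"])


def _stage_stats(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    wide = state["metrics_frame"]
    scfg = statgate.StatsConfig(
        alpha=cfg.stats.alpha,
        outlier_sd=cfg.stats.outlier_sd,
        grubbs_alpha=cfg.stats.grubbs_alpha,
    )
    results = {}
    for metric in cfg.stats.metrics:
        sub = wide[[metric, "group"]].dropna()
        a = sub.loc[sub["group"] == "control", metric].to_numpy()
        b = sub.loc[sub["group"] == "dss", metric].to_numpy()
        rep = statgate.compare_two_groups(a, b, scfg, labels=("control", "dss"))
        results[metric] = {
            "test": rep.test,
            "statistic": rep.statistic,
            "p": rep.p,
            "branch": rep.branch,
            "n_excluded": len(rep.exclusions),
            "mean_control": float(a.mean()),
            "mean_dss": float(b.mean()),
        }
    state["stats"] = results
    with open(out / "stats.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
    record("stats", cfg.stats, [out / "stats.json"])


def _stage_correlate(cfg: RunConfig, out: Path, state: dict, report: dict, record) -> None:
    wide = state["metrics_frame"]
    pheno = wide[cfg.correlate.metric]
    de = state["de"]
    subset = de.index[de["significant"]].tolist() or None
    ranking = genepheno.correlate_genes(
        state["normalized"],
        pheno,
        gene_subset=subset,
        method=cfg.correlate.method,  # type: ignore[arg-type]
        k=cfg.correlate.k,
    )
    state["correlation"] = ranking
    tbl = ranking.table.copy()
    tbl["sign"] = np.where(tbl["r"] > 0, "positive", np.where(tbl["r"] < 0, "negative", "zero"))
    tbl.to_csv(out / "correlation.tsv", sep="\t", index_label="gene")
    ranking.top_positive.to_csv(out / "correlation_top_positive.tsv", sep="\t", index_label="gene")
    ranking.top_negative.to_csv(out / "correlation_top_negative.tsv", sep="\t", index_label="gene")
    record(
        "correlate",
        cfg.correlate,
        [out / "correlation.tsv", out / "correlation_top_positive.tsv", out / "correlation_top_negative.tsv"],
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "de": _stage_de,
    "metasig": _stage_metasig,
    "overlap": _stage_overlap,
    "openfield": _stage_openfield,
    "stats": _stage_stats,
    "correlate": _stage_correlate,
}
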