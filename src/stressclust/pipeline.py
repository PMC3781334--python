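"""End-to-end orchestration: generate -> calls -> cluster -> enrich -> motifs.

Each stage writes its outputs before the next starts, a failure halts the
run with the stage name while preserving earlier outputs, and the manifest
records seed, thresholds, row counts, timings and a sha256 checksum per
output file, so every run is self-describing and byte-reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calls as _calls
from . import enrichment as _enrichment
from . import io as _io
from . import motifs as _motifs
from . import profiles as _profiles
from . import synthetic as _synthetic
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)

STAGES = ("generate", "calls", "cluster", "enrich", "motifs")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "stressclust_run"
    seed: int = 0
    fold: float = 1.5
    alpha: float = 0.05
    fdr: float = 0.05
    z_min: float = 10.0
    fisher_max: float = 0.01
    rel_threshold: float = 0.85
    window: int = 2000
    matrix: str | None = None       # external inputs; None -> synthetic stage
    samples: str | None = None
    promoters: str | None = None
    tss: str | None = None
    pwms: str | None = None
    annotations: str | None = None
    generator: dict = field(default_factory=dict)
    taxonomy_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.fold < 1.0:
            raise ConfigError("fold must be >= 1")
        for name in ("alpha", "fdr", "fisher_max"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1]")
        if not 0.0 < self.rel_threshold <= 1.0:
            raise ConfigError("rel_threshold must be in (0, 1]")
        if self.window <= 0:
            raise ConfigError("window must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    import math

    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tau = math.log2(config.fold)
    manifest: dict = {
        "version": __version__, "seed": config.seed,
        "thresholds": {"fold": config.fold, "tau_log2": tau,
                       "alpha": config.alpha, "fdr": config.fdr,
                       "z_min": config.z_min, "fisher_max": config.fisher_max,
                       "rel_threshold": config.rel_threshold,
                       "window": config.window},
        "stages": [],
    }
    state: dict = {}

    def record(stage, outputs, counts, t0):
        entry = {"stage": stage, "status": "ok",
                 "seconds": round(_time.monotonic() - t0, 3),
                 "counts": counts,
                 "outputs": {str(p): _sha256(Path(p)) for p in outputs}}
        manifest["stages"].append(entry)
        logger.info("stage %-8s ok  %s", stage, counts)

    def run_stage(stage, fn):
        t0 = _time.monotonic()
        try:
            outputs, counts = fn()
        except Exception as exc:
            manifest["stages"].append({"stage": stage, "status": "failed",
                                       "error": str(exc)})
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, outputs, counts, t0)

    def stage_generate():
        gen_cfg = _synthetic.GeneratorConfig(seed=config.seed, **config.generator)
        pwms = _synthetic.default_pwms()
        outputs = []
        if config.matrix and config.samples:
            matrix, samples = _io.read_expression(config.matrix, config.samples)
            truth = None
        else:
            design = _synthetic.generate_design(gen_cfg)
            matrix, truth = _synthetic.generate_expression(gen_cfg, design)
            samples = design
            _io.write_expression(matrix, outdir / "expression.tsv")
            _io.write_samples(samples, outdir / "samples.tsv")
            outputs += [outdir / "expression.tsv", outdir / "samples.tsv"]
        if config.promoters and config.tss:
            promoters = _synthetic.read_promoters_fasta(config.promoters)
            tss_df = _motifs.read_tss_bed(config.tss)
        elif truth is not None:
            promoters, tss_df = _synthetic.generate_promoters(gen_cfg, truth, pwms)
            _synthetic.write_promoters_fasta(promoters, outdir / "promoters.fa")
            _synthetic.write_tss_bed(tss_df, outdir / "tss.bed")
            outputs += [outdir / "promoters.fa", outdir / "tss.bed"]
        else:
            promoters, tss_df = None, None
        if config.pwms:
            pwms = _motifs.read_jaspar_pfm(config.pwms)
        else:
            _motifs.write_jaspar_pfm(pwms, outdir / "pwms.pfm")
            outputs.append(outdir / "pwms.pfm")
        if config.annotations:
            annotations = _enrichment.read_annotations(config.annotations)
        elif truth is not None:
            annotations = _synthetic.generate_annotations(gen_cfg, truth)
            _synthetic.write_annotations(annotations, outdir / "annotations.tsv")
            outputs.append(outdir / "annotations.tsv")
        else:
            annotations = None
        if truth is not None:
            truth.write(outdir / "truth")
            outputs += [outdir / "truth_profiles.tsv", outdir / "truth_pathways.tsv",
                        outdir / "truth_motif_sites.tsv"]
        state.update(matrix=matrix, samples=samples, promoters=promoters,
                     tss=tss_df, pwms=pwms, annotations=annotations, truth=truth)
        return outputs, {"genes": len(matrix), "samples": len(samples)}

    def stage_calls():
        calls = _calls.call_comparisons(state["matrix"], state["samples"],
                                        tau=tau, alpha=config.alpha)
        path = outdir / "calls.tsv"
        calls.to_csv(path, sep="\t", index=False)
        state["calls"] = calls
        return [path], {"rows": len(calls)}

    def stage_cluster():
        taxonomy_profiles = dict(_profiles.DEFAULT_GROUP_PROFILES)
        for label, prof in config.taxonomy_overrides.items():
            taxonomy_profiles[label] = tuple(prof)
        taxonomy = _profiles.GroupTaxonomy(profiles=taxonomy_profiles)
        profiles = _profiles.assign_profiles(state["calls"])
        table, counts = _profiles.label_groups(profiles, taxonomy)
        heat = _profiles.build_heatmap_matrix(state["matrix"], state["samples"],
                                              tau=tau, alpha=config.alpha,
                                              calls=state["calls"])
        gpath, cpath, hpath = (outdir / "groups.tsv", outdir / "group_counts.tsv",
                               outdir / "heatmap.tsv")
        table.to_csv(gpath, sep="\t")
        counts.to_csv(cpath, sep="\t")
        heat.to_csv(hpath, sep="\t")
        state["groups"] = table
        return [gpath, cpath, hpath], {"labeled": int(table["group"].notna().sum()),
                                       "heatmap_rows": len(heat)}

    def stage_enrich():
        if state.get("annotations") is None:
            return [], {"skipped": "no annotations"}
        enr = _enrichment.enrich_groups(state["groups"], state["annotations"])
        path = outdir / "enrichment.tsv"
        enr.to_csv(path, sep="\t", index=False)
        tops = []
        for group, sub in enr.groupby("group"):
            top = _enrichment.top_pathways(sub, fdr=config.fdr)
            tops.append(top)
        top_df = pd.concat(tops, ignore_index=True) if tops else enr.iloc[:0]
        tpath = outdir / "enrichment_top.tsv"
        top_df.to_csv(tpath, sep="\t", index=False)
        return [path, tpath], {"tests": len(enr),
                               "significant": int((enr["q_value"] < config.fdr).sum())}

    def stage_motifs():
        if state.get("promoters") is None:
            return [], {"skipped": "no promoters"}
        tss_map = dict(zip(state["tss"]["name"],
                           state["tss"]["start"] - 0))  # BED start = TSS base
        scan = _motifs.scan_promoters(state["pwms"], state["promoters"], tss_map,
                                      window=config.window,
                                      rel_threshold=config.rel_threshold)
        hpath = outdir / "motif_hits.tsv"
        scan.hits.to_csv(hpath, sep="\t", index=False)
        background = sorted(state["promoters"])
        results = []
        for group, sub in state["groups"].dropna(subset=["group"]).groupby("group"):
            res = _motifs.single_site_analysis(scan, set(sub.index), background,
                                               z_min=config.z_min,
                                               fisher_max=config.fisher_max)
            res.insert(0, "group", group)
            results.append(res)
        res_df = pd.concat(results, ignore_index=True)
        epath = outdir / "motif_enrichment.tsv"
        res_df.to_csv(epath, sep="\t", index=False)
        return [hpath, epath], {"hits": len(scan.hits),
                                "passing": int(res_df["passes"].sum())}

    for stage, fn in (("generate", stage_generate), ("calls", stage_calls),
                      ("cluster", stage_cluster), ("enrich", stage_enrich),
                      ("motifs", stage_motifs)):
        run_stage(stage, fn)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
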