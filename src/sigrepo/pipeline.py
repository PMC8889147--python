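"""End-to-end pipeline orchestration.

A run directory is populated stage by stage:

* ``simulate``  — synthetic universe (expression, gene sets, library, KB,
  images, dose-response plate, proteomic panel, ground-truth manifest)
* ``dge``       — gene-level statistics for NAFL/Healthy and NASH/Healthy
* ``gsa``       — directional gene-set analysis per contrast
* ``connect``   — connectivity screen of the library against the disease query
* ``repurpose`` — pathway groups, candidate table, tox filter, network
* ``quantify``  — image + plate quantification of the synthetic assay arm
* ``cluster``   — mode-of-action clustering of the proteomic panel
* ``all``       — everything above, in order

Every output table carries a header comment with the run's parameter hash;
identical config + seed give identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays, connectivity, diffexpr, gsa, imaging, io, moa, repositioning, simulate
from .simulate import SimulationConfig

log = logging.getLogger("sigrepo")

STAGES = ("simulate", "dge", "gsa", "connect", "repurpose", "quantify", "cluster")


@dataclass
class PipelineConfig:
    """Flat run configuration; every field has a workable default."""

    outdir: str = "run"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    contrasts: tuple[tuple[str, str], ...] = (("NAFL", "Healthy"), ("NASH", "Healthy"))
    fc_cut: float = 1.0
    p_cut: float = 0.05
    gsa_methods: tuple[str, ...] = gsa.ALL_METHODS
    gsa_B: int = 999
    gsa_min_size: int = 5
    gsa_max_fraction: float = 0.5
    alpha: float = 0.05
    connect_B: int = 999
    tag_size: int = 50
    clin_policy: str = "union"
    cluster_k: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "gsa_methods" in raw:
            raw["gsa_methods"] = tuple(raw["gsa_methods"])
        return cls(sim=sim, **raw)

    def params_hash(self) -> str:
        obj = dataclasses.asdict(self)
        obj.pop("outdir", None)  # the hash covers parameters, not where they land
        blob = json.dumps(obj, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {path.name}; run stage {stage!r} first")
    return path


def run_pipeline(config: PipelineConfig, mode: str = "all") -> Path:
    """Execute the requested stage(s); returns the run directory."""
    if mode != "all" and mode not in STAGES:
        raise ValueError(f"unknown mode {mode!r}; valid: {('all',) + STAGES}")
    stages = STAGES if mode == "all" else (mode,)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.params_hash()
    header = f"params_hash={h} seed={config.seed}"
    manifest: dict = {"params_hash": h, "seed": config.seed, "stages": {}}
    mpath = out / "run_manifest.json"
    if mpath.exists():
        manifest.update(json.loads(mpath.read_text()))
        manifest["params_hash"] = h

    for stage in stages:
        t0 = time.perf_counter()
        counts = _STAGE_FUNCS[stage](config, out, header)
        dt = time.perf_counter() - t0
        log.info("stage %-9s done in %.2fs: %s", stage, dt, counts)
        manifest["stages"][stage] = {"seconds": round(dt, 3), **counts}
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return out


# ------------------------------------------------------------------- stages

def _stage_simulate(config: PipelineConfig, out: Path, header: str) -> dict:
    sim = dataclasses.replace(config.sim, seed=config.seed)
    dataset, truth = simulate.gen_expression_cohort(sim)
    collection = simulate.gen_gene_sets(sim, truth)
    library = simulate.gen_signature_library(truth, sim)
    kb = simulate.gen_compound_knowledgebase(truth, sim, collection)
    io.write_expression(dataset, out / "expression.tsv", out / "metadata.tsv", header)
    io.write_gmt(collection, out / "gene_sets.gmt", header)
    io.write_signature_library(library, out / "library.tsv", header)
    io.write_compound_kb(kb, out / "kb.tsv", header)

    channels, img_truth = simulate.gen_microscopy_image(sim)
    simulate.write_image_channels(channels, out / "field")
    truth.nuclei_centers = img_truth.nuclei_centers
    truth.droplets = img_truth.droplets
    truth.total_droplet_intensity = img_truth.total_droplet_intensity

    doses = np.geomspace(0.1, 100.0, 8)
    plate = simulate.gen_dose_response(
        {"top": 100.0, "bottom": 0.0, "c50": 10.0, "slope": 1.0},
        doses, noise_sd=1.0, seed=config.seed, n_replicates=3)
    plate.to_csv(out / "viability.csv", index=False)
    truth.dose_response_params["default"] = {"top": 100.0, "bottom": 0.0,
                                             "c50": 10.0, "slope": 1.0}

    panel, labels = simulate.gen_proteomic_panel(seed=config.seed)
    panel.to_csv(out / "proteomics.csv")
    truth.proteomic_labels = [int(v) for v in labels]
    truth.to_json(out / "truth.json")
    return {"genes": sim.n_genes, "gene_sets": len(collection),
            "compounds": len(library), "images": 1}


def _stage_dge(config: PipelineConfig, out: Path, header: str) -> dict:
    _require(out / "expression.tsv", "simulate", "dge")
    dataset = io.read_expression(out / "expression.tsv", out / "metadata.tsv")
    n = 0
    for test, control in config.contrasts:
        est = diffexpr.ModeratedTTest(contrast=(test, control),
                                      fc_cut=config.fc_cut, p_cut=config.p_cut)
        est.fit(dataset)
        est.to_tsv(out / f"gene_stats_{test}_vs_{control}.tsv", header)
        n += len(est.results_)
    return {"contrasts": len(config.contrasts), "gene_rows": n}


def _read_gene_stats(out: Path, test: str, control: str) -> pd.DataFrame:
    path = _require(out / f"gene_stats_{test}_vs_{control}.tsv", "dge", "gsa/connect")
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def _stage_gsa(config: PipelineConfig, out: Path, header: str) -> dict:
    _require(out / "gene_sets.gmt", "simulate", "gsa")
    collection = io.read_gmt(out / "gene_sets.gmt")
    n_sig = 0
    for test, control in config.contrasts:
        table = _read_gene_stats(out, test, control)
        est = gsa.DirectionalGSA(methods=config.gsa_methods, B=config.gsa_B,
                                 min_size=config.gsa_min_size,
                                 max_fraction=config.gsa_max_fraction,
                                 alpha=config.alpha, seed=config.seed)
        est.fit(table, collection)
        est.to_tsv(out / f"gsa_{test}_vs_{control}.tsv", header)
        n_sig += len(est.significant_)
    return {"contrasts": len(config.contrasts), "significant_sets": n_sig}


def _stage_connect(config: PipelineConfig, out: Path, header: str) -> dict:
    _require(out / "library.tsv", "simulate", "connect")
    library = io.read_signature_library(out / "library.tsv")
    test, control = config.contrasts[0]
    table = _read_gene_stats(out, test, control)
    query = connectivity.query_from_gene_stats(table, tag_size=config.tag_size)
    io.write_query_signature(query, out / "query.json")
    screen = connectivity.ConnectivityScreen(alpha=config.alpha, B=config.connect_B,
                                             seed=config.seed)
    screen.fit_screen(library, query)
    screen.to_tsv(out / "connectivity.tsv", header)
    return {"compounds": len(screen.results_),
            "selected": int(screen.results_["selected"].sum())}


def _stage_repurpose(config: PipelineConfig, out: Path, header: str) -> dict:
    collection = io.read_gmt(_require(out / "gene_sets.gmt", "simulate", "repurpose"))
    kb = io.read_compound_kb(_require(out / "kb.tsv", "simulate", "repurpose"))
    screen = pd.read_csv(_require(out / "connectivity.tsv", "connect", "repurpose"),
                         sep="\t", comment="#")
    clin = []
    for test, control in config.contrasts:
        df = pd.read_csv(_require(out / f"gsa_{test}_vs_{control}.tsv", "gsa", "repurpose"),
                         sep="\t", comment="#")
        clin.append(set(df.loc[df["significant"] == 1, "set"]))
    # steatogens: mimicker-role compounds stand in for the in vitro steatogens
    truth = simulate.GroundTruthManifest.from_json(_require(out / "truth.json",
                                                            "simulate", "repurpose"))
    steatogens = [c for c, r in truth.compound_roles.items() if r == "mimicker"] or kb.compounds()[:1]
    groups = repositioning.build_pathway_groups(clin, kb, collection, steatogens,
                                                clin_policy=config.clin_policy)
    candidates = repositioning.select_candidates([screen], kb, collection, groups)
    candidates, n_excluded = repositioning.apply_tox_filter(candidates)
    io._write_with_header(out / "candidates.tsv", candidates.to_csv(sep="\t", index=False),
                          header)
    repositioning.export_network(candidates, kb, collection, groups,
                                 path_json=out / "network.json", path_sif=out / "network.sif")
    summary = {
        "n_pathways_to_target": len(groups.p_target),
        "n_candidates": int((candidates["status"] == "candidate").sum()),
        "n_excluded_tox": n_excluded,
        "n_rejected": int((candidates["status"] == "rejected").sum()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary


def _stage_quantify(config: PipelineConfig, out: Path, header: str) -> dict:
    import tifffile

    nuc = tifffile.imread(_require(out / "field_nuclei.tif", "simulate", "quantify"))
    drop = tifffile.imread(_require(out / "field_droplets.tif", "simulate", "quantify"))
    q = imaging.quantify_image(nuc.astype(float), drop.astype(float))
    plate = io.read_plate_table(_require(out / "viability.csv", "simulate", "quantify"))
    fit = assays.fit_dose_response(plate["dose"], plate["value"])
    quant = {**{k: v for k, v in q.items()},
             "ic10": fit.ic10, "ic10_extrapolated": fit.extrapolated, "flat": fit.flat}
    io._write_with_header(out / "quantification.tsv",
                          pd.DataFrame([quant]).to_csv(sep="\t", index=False), header)
    return {"n_nuclei": q["n_nuclei"], "n_droplets": q["n_droplets"]}


def _stage_cluster(config: PipelineConfig, out: Path, header: str) -> dict:
    panel = pd.read_csv(_require(out / "proteomics.csv", "simulate", "cluster"), index_col=0)
    est = moa.ModeOfActionClusterer(k=config.cluster_k, seed=config.seed)
    est.fit(panel)
    io._write_with_header(out / "cluster_labels.tsv",
                          est.labels_.rename("cluster").rename_axis("treatment")
                          .to_frame().to_csv(sep="\t"), header)
    io._write_with_header(out / "embedding.tsv",
                          est.embedding_.rename_axis("treatment").to_csv(sep="\t"), header)
    (out / "variance_fractions.json").write_text(
        json.dumps({"variance_fractions": [float(v) for v in est.variance_fractions_],
                    "chosen_k": int(est.chosen_k_)}, indent=1) + "\n")
    return {"treatments": len(panel), "k": config.cluster_k, "chosen_k": int(est.chosen_k_)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "dge": _stage_dge,
    "gsa": _stage_gsa,
    "connect": _stage_connect,
    "repurpose": _stage_repurpose,
    "quantify": _stage_quantify,
    "cluster": _stage_cluster,
}
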