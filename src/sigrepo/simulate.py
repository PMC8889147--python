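"""Synthetic-universe generators with known ground truth.

Every input the pipeline consumes can be generated here: a three-group
(Healthy / NAFL / NASH) expression cohort with planted differentially
expressed pathway genes, GMT gene-set collections, a ranked compound-profile
library containing planted signature reversers and mimickers among random
decoys, a compound knowledgebase with hepatotoxicity flags, two-channel
fluorescence images with planted nuclei and lipid droplets, four-parameter
logistic dose-response plates, and multiplex proteomic panels drawn from
known cluster centroids.

All generators are pure functions of ``(config, seed)``: the same inputs
produce byte-identical outputs. A :class:`GroundTruthManifest` records every
planted feature so recovery can be scored without regenerating anything.

Statistical structure of the expression cohort
----------------------------------------------
Per-gene residual variances are drawn from a scaled inverse chi-square law
``s0_sq * d0 / chisq(d0)`` — the conjugate prior assumed by empirical-Bayes
variance shrinkage — so the shrinkage estimator downstream can be tested
against known hyperparameters. Planted genes are shifted by
``+/- effect_log2fc`` in both disease groups relative to Healthy.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompoundKB,
    ExpressionDataset,
    GeneSetCollection,
    QuerySignature,
    ReferenceProfile,
    SignatureLibrary,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic universe.

    Defaults describe a desk-scale cohort comparable to small clinical
    microarray series (tens of samples, a few thousand probes), with an
    effect size of 1.5 log2 units for planted genes and a moderately
    informative variance prior (d0=4, s0_sq=0.05, i.e. residual sd ~0.22
    on the log2 scale).
    """

    n_genes: int = 2000
    group_sizes: tuple[int, int, int] = (8, 8, 8)  # Healthy, NAFL, NASH
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_gene_sets: int = 60
    set_size_range: tuple[int, int] = (10, 40)
    n_planted_pathways: int = 11
    effect_log2fc: float = 1.5
    variance_prior: tuple[float, float] = (4.0, 0.05)  # (d0, s0_sq)
    n_library_compounds: int = 110
    n_reversers: int = 5
    n_mimickers: int = 5
    rank_jitter: float = 0.0
    tag_size: int = 50
    tox_fraction: float = 0.3
    # image geometry
    image_width: int = 512
    image_height: int = 512
    n_nuclei: int = 12
    n_droplets: int = 40
    nucleus_radius: float = 12.0
    droplet_radius: float = 3.0
    nucleus_intensity: float = 20000.0
    droplet_intensity: float = 15000.0
    background: float = 100.0
    noise_sd: float = 0.0
    touching_pair: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.group_sizes) != 3 or any(g < 2 for g in self.group_sizes):
            raise ValueError("group_sizes must be a triple with every group >= 2")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ValueError(f"set_size_range {self.set_size_range} infeasible for {self.n_genes} genes")
        if self.n_planted_pathways < 0:
            raise ValueError("n_planted_pathways must be non-negative")
        if self.n_planted_pathways > self.n_gene_sets:
            raise ValueError("cannot plant more pathways than gene sets")
        if self.tag_size >= self.n_genes:
            raise ValueError("tag_size must be smaller than n_genes")
        d0, s0 = self.variance_prior
        if d0 <= 0 or s0 <= 0:
            raise ValueError("variance_prior components must be positive")
        if self.n_reversers + self.n_mimickers > self.n_library_compounds:
            raise ValueError("n_reversers + n_mimickers exceeds n_library_compounds")
        if not 0.0 <= self.tox_fraction <= 1.0:
            raise ValueError("tox_fraction must lie in [0, 1]")


@dataclass
class GroundTruthManifest:
    """Planted features of a synthetic universe, sufficient to score recovery."""

    planted_genes: dict[str, float] = field(default_factory=dict)  # gene -> signed log2 effect
    true_variances: dict[str, float] = field(default_factory=dict)
    planted_pathways: list[str] = field(default_factory=list)
    compound_roles: dict[str, str] = field(default_factory=dict)  # reverser|mimicker|decoy
    tox_compounds: list[str] = field(default_factory=list)
    nuclei_centers: list[tuple[float, float]] = field(default_factory=list)
    droplets: list[dict] = field(default_factory=list)  # center, radius, intensity
    total_droplet_intensity: float = 0.0
    dose_response_params: dict[str, dict] = field(default_factory=dict)
    proteomic_labels: list[int] = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        obj = json.loads(Path(path).read_text())
        obj["nuclei_centers"] = [tuple(c) for c in obj.get("nuclei_centers", [])]
        return cls(**obj)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{i:0{width}d}" for i in range(n)]


# ------------------------------------------------------------------ expression

def gen_expression_cohort(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruthManifest]:
    """Simulate a Healthy/NAFL/NASH cohort with planted DE pathway genes.

    Gene values are normal around a gene-specific baseline with variance
    drawn from the scaled inverse chi-square prior; planted genes (the union
    of the planted pathways' cores) are shifted by ``+/- effect_log2fc`` in
    the NAFL and NASH groups. The sign is constant within each planted
    pathway's core block and alternates across pathways (even-indexed
    pathways up, odd down), so planted pathways are direction-pure while the
    overall signature carries both up and down arms.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_h, n_f, n_s = config.group_sizes
    samples = (
        [f"H{i:02d}" for i in range(n_h)]
        + [f"F{i:02d}" for i in range(n_f)]
        + [f"S{i:02d}" for i in range(n_s)]
    )
    status = ["Healthy"] * n_h + ["NAFL"] * n_f + ["NASH"] * n_s

    d0, s0_sq = config.variance_prior
    true_var = s0_sq * d0 / rng.chisquare(d0, size=config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # choose planted genes: cores of the planted pathways (assigned in
    # gen_gene_sets, which uses the same deterministic layout)
    planted_idx = _planted_gene_indices(config)
    core, _ = _planted_layout(config)
    effects = np.zeros(config.n_genes)
    signs = np.where((planted_idx // max(core, 1)) % 2 == 0, 1.0, -1.0)
    effects[planted_idx] = signs * config.effect_log2fc

    n_total = len(samples)
    noise = rng.normal(size=(config.n_genes, n_total)) * np.sqrt(true_var)[:, None]
    values = baseline[:, None] + noise
    disease_cols = np.array([s != "Healthy" for s in status])
    values[:, disease_cols] += effects[:, None]

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    dataset = ExpressionDataset(values=df, status=pd.Series(status, index=samples))
    truth = GroundTruthManifest(
        planted_genes={genes[i]: float(effects[i]) for i in planted_idx},
        true_variances={g: float(v) for g, v in zip(genes, true_var)},
    )
    return dataset, truth


def _planted_layout(config: SimulationConfig) -> tuple[int, int]:
    """(core genes per planted pathway, total planted genes)."""
    lo, hi = config.set_size_range
    core = max(2, min(lo, hi) // 2 * 2)  # even so signs balance within a pathway-pair layout
    core = min(core, lo)
    return core, core * config.n_planted_pathways


def _planted_gene_indices(config: SimulationConfig) -> np.ndarray:
    """Deterministic block of planted gene indices at the front of the universe.

    Pathway p owns the contiguous core block [p*core, (p+1)*core); effects
    alternate in sign across the global planted order, so each planted
    pathway ends up with a dominant direction determined by its block.
    """
    core, total = _planted_layout(config)
    total = min(total, config.n_genes)
    return np.arange(total)


# -------------------------------------------------------------------- gene sets

def gen_gene_sets(config: SimulationConfig,
                  truth: GroundTruthManifest | None = None) -> GeneSetCollection:
    """Generate a gene-set collection with the planted pathways up front.

    Planted pathway ``p`` contains its contiguous core block of planted
    genes plus random filler genes drawn from the non-planted remainder;
    decoy sets are uniform random draws. Core blocks carry one effect sign
    each (even-indexed pathways all-up, odd all-down, matching the cohort
    generator), so planted pathways are direction-pure. When ``truth`` is
    given, the planted pathway names are recorded in the manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_genes)
    lo, hi = config.set_size_range
    core, _total = _planted_layout(config)

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    non_planted = np.arange(min(_planted_layout(config)[1], config.n_genes), config.n_genes)

    for p in range(config.n_planted_pathways):
        start = p * core
        block = list(range(start, min(start + core, config.n_genes)))
        size = int(rng.integers(lo, hi + 1))
        n_fill = max(0, size - len(block))
        fill = rng.choice(non_planted, size=min(n_fill, len(non_planted)), replace=False)
        name = f"PLANTED_{p:02d}"
        sets[name] = [genes[i] for i in block] + [genes[i] for i in sorted(fill)]
        descriptions[name] = "planted"

    for q in range(config.n_gene_sets - config.n_planted_pathways):
        size = int(rng.integers(lo, hi + 1))
        # decoys draw from the non-planted remainder so they are true nulls
        pick = rng.choice(non_planted, size=min(size, len(non_planted)), replace=False)
        name = f"DECOY_{q:03d}"
        sets[name] = [genes[i] for i in sorted(pick)]
        descriptions[name] = "decoy"

    collection = GeneSetCollection(sets=sets, descriptions=descriptions)
    if truth is not None:
        truth.planted_pathways = [n for n in sets if descriptions[n] == "planted"]
    return collection


def planted_signature(truth: GroundTruthManifest) -> QuerySignature:
    """The disease signature implied by the planted effects (up/down gene lists)."""
    up = sorted(g for g, e in truth.planted_genes.items() if e > 0)
    down = sorted(g for g, e in truth.planted_genes.items() if e < 0)
    return QuerySignature(up=up, down=down)


# ------------------------------------------------------------ signature library

def gen_signature_library(truth: GroundTruthManifest, config: SimulationConfig) -> SignatureLibrary:
    """Build a ranked-profile library with planted reversers and mimickers.

    A *mimicker* ranks the disease's up-genes near the top of its profile and
    the down-genes near the bottom (its perturbation looks like the disease);
    a *reverser* does the converse; decoys are uniform random permutations.
    ``rank_jitter`` perturbs the rank keys with Gaussian noise of that
    standard deviation (in rank units) before re-sorting.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    genes = _gene_ids(config.n_genes)
    sig = planted_signature(truth)
    up_idx = np.array([genes.index(g) for g in sig.up], dtype=np.int64)
    down_idx = np.array([genes.index(g) for g in sig.down], dtype=np.int64)

    profiles: dict[str, ReferenceProfile] = {}
    roles: dict[str, str] = {}

    n_special = config.n_reversers + config.n_mimickers
    for i in range(config.n_library_compounds):
        if i < config.n_reversers:
            name, role = f"REV_{i:02d}", "reverser"
        elif i < n_special:
            name, role = f"MIM_{i - config.n_reversers:02d}", "mimicker"
        else:
            name, role = f"DEC_{i - n_special:03d}", "decoy"
        key = rng.uniform(0.0, 1.0, size=config.n_genes)  # base random order
        if role == "reverser":
            key[up_idx] += 10.0  # disease-up genes pushed to the bottom
            key[down_idx] -= 10.0  # disease-down genes pulled to the top
        elif role == "mimicker":
            key[up_idx] -= 10.0
            key[down_idx] += 10.0
        if config.rank_jitter > 0:
            order = np.argsort(key, kind="stable")
            rank_key = np.empty(config.n_genes)
            rank_key[order] = np.arange(config.n_genes, dtype=float)
            key = rank_key + rng.normal(0.0, config.rank_jitter, size=config.n_genes)
        order = np.argsort(key, kind="stable")
        profiles[name] = ReferenceProfile(compound=name, ranking=[genes[j] for j in order])
        roles[name] = role

    truth.compound_roles = roles
    return SignatureLibrary(profiles=profiles)


# ----------------------------------------------------------------- compound KB

def gen_compound_knowledgebase(truth: GroundTruthManifest, config: SimulationConfig,
                               collection: GeneSetCollection) -> CompoundKB:
    """Targets + tox flags per library compound.

    Reversers and mimickers are guaranteed targets inside planted pathways:
    the planted pathways are dealt round-robin over the mimickers and,
    separately, over the reversers, so that each active role jointly covers
    every planted pathway — mirroring how the in vitro steatogens' pooled
    targets span all of the disease-shared pathways. Decoys draw targets
    uniformly. ``floor(tox_fraction*n)`` compounds are flagged hepatotoxic,
    chosen among decoys first so planted actives survive the exclusion step
    by default.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    genes = _gene_ids(config.n_genes)
    planted_names = [n for n in collection if collection.descriptions.get(n) == "planted"]
    truth.planted_pathways = planted_names

    # deal planted pathways round-robin within each active role
    anchor_sets: dict[str, list[str]] = {}
    for role in ("mimicker", "reverser"):
        role_members = [c for c, r in truth.compound_roles.items() if r == role]
        for j, pathway in enumerate(planted_names):
            if role_members:
                anchor_sets.setdefault(role_members[j % len(role_members)], []).append(pathway)

    targets: dict[str, list[str]] = {}
    for name, role in truth.compound_roles.items():
        n_t = int(rng.integers(2, 6))
        picks = [genes[i] for i in rng.choice(len(genes), size=n_t, replace=False)]
        if role in ("reverser", "mimicker"):
            anchors = [
                collection.members(p)[int(rng.integers(len(collection.members(p))))]
                for p in anchor_sets.get(name, [])
            ]
            picks = sorted(set(anchors)) + [g for g in picks if g not in anchors][: max(1, n_t - len(anchors))]
        targets[name] = picks

    n_flag = math.floor(config.tox_fraction * len(targets))
    decoys = [c for c, r in truth.compound_roles.items() if r == "decoy"]
    actives = [c for c, r in truth.compound_roles.items() if r != "decoy"]
    flag_order = list(rng.permutation(decoys)) + list(rng.permutation(actives))
    flagged = flag_order[:n_flag]
    tox = {c: (c in flagged) for c in targets}
    truth.tox_compounds = sorted(flagged)
    return CompoundKB(targets=targets, tox=tox,
                      tox_source={c: "synthetic-toxdb" for c in flagged})


# ---------------------------------------------------------------------- images

def _disk(canvas: np.ndarray, cy: float, cx: float, radius: float, intensity: float,
          edge: float = 1.0) -> float:
    """Add a disk with a sigmoid-smoothed edge to ``canvas`` in place.

    Returns the disk's core mass: the added intensity over pixels at or
    above half-maximum (the droplet proper, excluding the soft rim).
    """
    h, w = canvas.shape
    pad = int(radius + 6 * edge) + 2
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    profile = 1.0 / (1.0 + np.exp((r - radius) / max(edge, 1e-6)))
    canvas[y0:y1, x0:x1] += intensity * profile
    return float(intensity * profile[profile >= 0.5].sum())


def gen_microscopy_image(config: SimulationConfig) -> tuple[dict[str, np.ndarray], GroundTruthManifest]:
    """Two-channel synthetic fluorescence field: nuclei + lipid droplets.

    Nuclei are large smooth disks (Hoechst-like channel) with a minimum
    centre separation of 2.5 radii, unless ``touching_pair`` is set, in which
    case exactly one pair is placed at 1.5 radii so their disks overlap.
    Droplets are small bright disks (Nile-Red-like channel). Additive
    Gaussian noise of ``noise_sd`` is applied to both channels. Returns the
    channels (float arrays, clipped non-negative) and a manifest recording
    counts, centres, and the total planted droplet intensity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 4)
    h, w = config.image_height, config.image_width
    nuc = np.full((h, w), config.background, dtype=float)
    drop = np.full((h, w), config.background, dtype=float)

    margin = config.nucleus_radius + 5
    min_sep = 2.5 * config.nucleus_radius
    centers: list[tuple[float, float]] = []
    n_place = config.n_nuclei - (2 if config.touching_pair else 0)
    attempts = 0
    while len(centers) < n_place:
        attempts += 1
        if attempts > 200 * max(config.n_nuclei, 1):
            raise RuntimeError("could not place nuclei without overlap; canvas too small")
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    if config.touching_pair:
        # one overlapping pair, still separated from everyone else
        while True:
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            ang = rng.uniform(0, 2 * np.pi)
            d = 1.5 * config.nucleus_radius
            cy2, cx2 = cy + d * np.sin(ang), cx + d * np.cos(ang)
            if not (margin <= cy2 <= h - margin and margin <= cx2 <= w - margin):
                continue
            ok = all(
                (cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2
                and (cy2 - y) ** 2 + (cx2 - x) ** 2 >= min_sep**2
                for y, x in centers
            )
            if ok:
                centers.extend([(cy, cx), (cy2, cx2)])
                break
    for cy, cx in centers:
        _disk(nuc, cy, cx, config.nucleus_radius, config.nucleus_intensity, edge=1.5)

    droplets = []
    total_intensity = 0.0
    drop_centers: list[tuple[float, float]] = []
    drop_sep = 3.0 * config.droplet_radius + 3.0  # keep droplets resolvable
    attempts = 0
    while len(drop_centers) < config.n_droplets:
        attempts += 1
        if attempts > 200 * max(config.n_droplets, 1):
            raise RuntimeError("could not place droplets without overlap; canvas too small")
        cy = rng.uniform(config.droplet_radius + 2, h - config.droplet_radius - 2)
        cx = rng.uniform(config.droplet_radius + 2, w - config.droplet_radius - 2)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= drop_sep**2 for y, x in drop_centers):
            drop_centers.append((cy, cx))
    for cy, cx in drop_centers:
        core = _disk(drop, cy, cx, config.droplet_radius, config.droplet_intensity, edge=0.15)
        total_intensity += core
        droplets.append({"center": [float(cy), float(cx)],
                         "radius": float(config.droplet_radius),
                         "intensity": float(core)})

    if config.noise_sd > 0:
        nuc += rng.normal(0.0, config.noise_sd, size=nuc.shape)
        drop += rng.normal(0.0, config.noise_sd, size=drop.shape)
    nuc = np.clip(nuc, 0, None)
    drop = np.clip(drop, 0, None)

    truth = GroundTruthManifest(
        nuclei_centers=[(float(y), float(x)) for y, x in centers],
        droplets=droplets,
        total_droplet_intensity=float(total_intensity),
    )
    return {"nuclei": nuc, "droplets": drop}, truth


def write_image_channels(channels: dict[str, np.ndarray], prefix) -> list[Path]:
    """Write each channel as a 16-bit grayscale TIFF next to ``prefix``."""
    import tifffile

    paths = []
    for name, arr in channels.items():
        p = Path(f"{prefix}_{name}.tif")
        tifffile.imwrite(p, np.clip(arr, 0, 65535).astype(np.uint16))
        paths.append(p)
    return paths


# ----------------------------------------------------------------- dose-response

def four_pl(dose: np.ndarray, top: float, bottom: float, c50: float, slope: float) -> np.ndarray:
    """Four-parameter logistic: y = bottom + (top - bottom)/(1 + (x/c50)^slope)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / c50) ** slope)


def gen_dose_response(params: dict, doses, noise_sd: float = 0.0, seed: int = 0,
                      n_replicates: int = 1) -> pd.DataFrame:
    """Viability plate table from a 4PL truth plus Gaussian noise.

    ``params`` holds keys top, bottom, c50, slope (viability %, dose units).
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 5:
        raise ValueError("at least 5 dose levels required")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        y = four_pl(doses, params["top"], params["bottom"], params["c50"], params["slope"])
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=y.shape)
        for d, v in zip(doses, y):
            rows.append({"condition": "dose", "replicate": rep, "dose": float(d),
                         "value": float(v)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------- proteomic panel

def gen_proteomic_panel(n_treatments_per_cluster: int = 5, n_analytes: int = 37,
                        n_clusters: int = 4, separation: float = 10.0,
                        noise_sd: float = 1.0, seed: int = 0
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Treatments x analytes matrix drawn from k centroids + isotropic noise.

    Defaults mirror a 17-plex phospho-protein + 20-plex cytokine panel and
    four mode-of-action clusters. Returns (matrix, true labels).
    """
    if n_clusters < 1 or n_analytes < 2:
        raise ValueError("need >= 1 cluster and >= 2 analytes")
    rng = np.random.default_rng(seed)
    centroids = rng.normal(0.0, separation * noise_sd, size=(n_clusters, n_analytes))
    rows, labels = [], []
    for k in range(n_clusters):
        block = centroids[k] + rng.normal(0.0, noise_sd, size=(n_treatments_per_cluster, n_analytes))
        rows.append(block)
        labels.extend([k] * n_treatments_per_cluster)
    X = np.vstack(rows)
    idx = [f"T{i:02d}" for i in range(X.shape[0])]
    cols = [f"A{j:02d}" for j in range(n_analytes)]
    return pd.DataFrame(X, index=idx, columns=cols), np.asarray(labels)
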