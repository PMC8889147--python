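"""Pathway-group intersection and candidate-compound selection.

The screening logic combines three pathway groups:

* ``P_clin`` — pathways significantly deregulated in the patient cohorts
  (directional GSA output), aggregated across datasets/contrasts;
* ``P_stea`` — pathways containing targets of the in vitro steatogens;
* ``P_dr``  — per candidate compound, the pathways containing its targets.

The *pathways-to-target* are the intersection ``P_clin ∩ P_stea``. A
compound becomes a candidate when (a) a connectivity screen selected it
(significant p, nonzero score, either sign) and (b) its own pathways
overlap the pathways-to-target — the backward trace from pathway to
compound. Hepatotoxic candidates are then excluded using the knowledgebase
flags, and screening outcomes are summarised as a hit rate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .datatypes import CompoundKB, GeneSetCollection


@dataclass
class PathwayGroups:
    """The three pathway groups and their intersection."""

    p_clin: set[str]
    p_stea: set[str]
    p_target: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.p_target = self.p_clin & self.p_stea


def compound_pathways(kb: CompoundKB, sets: GeneSetCollection, compound: str) -> set[str]:
    """All sets containing >= 1 target gene of ``compound``.

    Membership (not enrichment) defines "affected": a pathway is affected
    if any pooled target gene belongs to it. Unresolvable targets are
    dropped with a warning.
    """
    if compound not in kb.targets:
        raise KeyError(f"unknown compound {compound!r}")
    universe = {g for name in sets for g in sets.members(name)}
    targets = kb.targets[compound]
    resolved = [g for g in targets if g in universe]
    if len(resolved) < len(targets):
        dropped = sorted(set(targets) - set(resolved))
        warnings.warn(f"{compound}: {len(dropped)} target(s) not in any gene set, dropped",
                      stacklevel=2)
    return sets.sets_containing(resolved)


def build_pathway_groups(clinical_significant: list[set[str]], kb: CompoundKB,
                         sets: GeneSetCollection, steatogens: list[str],
                         clin_policy: str = "union") -> PathwayGroups:
    """Assemble P_clin, P_stea and their intersection.

    ``clinical_significant`` holds one set of significant pathway names per
    dataset x contrast; ``clin_policy`` aggregates them by ``union``
    (default) or ``intersection``. ``P_stea`` is the union of
    :func:`compound_pathways` over the steatogens.
    """
    if not clinical_significant:
        raise ValueError("need at least one clinical GSA result")
    if not steatogens:
        raise ValueError("need at least one steatogen")
    if clin_policy == "union":
        p_clin = set().union(*clinical_significant)
    elif clin_policy == "intersection":
        p_clin = set.intersection(*map(set, clinical_significant))
    else:
        raise ValueError(f"unknown clin_policy {clin_policy!r}; use 'union' or 'intersection'")
    p_stea = set()
    for s in steatogens:
        p_stea |= compound_pathways(kb, sets, s)
    groups = PathwayGroups(p_clin=p_clin, p_stea=p_stea)
    if not groups.p_target:
        warnings.warn("no pathways-to-target: clinical and steatogen pathway groups are disjoint",
                      stacklevel=2)
    return groups


def select_candidates(screens: list[pd.DataFrame], kb: CompoundKB,
                      sets: GeneSetCollection, groups: PathwayGroups) -> pd.DataFrame:
    """Candidate table from one or more connectivity screens.

    A compound is a candidate iff it was selected in at least one screen
    AND its pathways overlap the pathways-to-target; selected compounds
    without overlap are recorded as ``rejected``. Ranking: |score|
    descending, overlap size descending, compound id ascending.

    Columns: compound, score (best by |.|), sign, p, overlap (';'-joined
    pathway names), n_overlap, tox_flag, status.
    """
    if not screens:
        raise ValueError("need at least one screen result")
    best: dict[str, tuple[float, float]] = {}
    for df in screens:
        for _, row in df.iterrows():
            if not row["selected"]:
                continue
            c = row["compound"]
            if c not in best or abs(row["score"]) > abs(best[c][0]):
                best[c] = (float(row["score"]), float(row["p"]))
    rows = []
    for c, (score, p) in best.items():
        overlap = sorted(compound_pathways(kb, sets, c) & groups.p_target)
        status = "candidate" if overlap else "rejected"
        rows.append({
            "compound": c, "score": score, "sign": int(math.copysign(1, score)) if score else 0,
            "p": p, "overlap": ";".join(overlap), "n_overlap": len(overlap),
            "tox_flag": bool(kb.tox.get(c, False)), "status": status,
        })
    cols = ["compound", "score", "sign", "p", "overlap", "n_overlap", "tox_flag", "status"]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return df
    df["_abs"] = df["score"].abs()
    df = (df.sort_values(["_abs", "n_overlap", "compound"], ascending=[False, False, True],
                         kind="stable")
          .drop(columns="_abs").reset_index(drop=True))
    return df


def apply_tox_filter(candidates: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Mark hepatotoxic candidates as ``excluded-tox``; return (table, n_excluded).

    Only rows with status ``candidate`` are eligible for exclusion; the
    returned count is the number newly excluded.
    """
    out = candidates.copy()
    mask = (out["status"] == "candidate") & out["tox_flag"]
    out.loc[mask, "status"] = "excluded-tox"
    n_excluded = int(mask.sum())
    if n_excluded and (out["status"] == "candidate").sum() == 0:
        warnings.warn("every candidate was excluded as hepatotoxic", stacklevel=2)
    return out, n_excluded


def export_network(candidates: pd.DataFrame, kb: CompoundKB, sets: GeneSetCollection,
                   groups: PathwayGroups, path_json=None, path_sif=None) -> dict:
    """Compound-gene-pathway graph behind the candidate table.

    Nodes are typed compound / gene / pathway with role attributes; edges
    are ``targets`` (compound -> gene) and ``member-of`` (gene -> pathway,
    restricted to pathways-to-target plus overlap pathways). Node and edge
    lists are sorted, so serialisation is deterministic.
    """
    nodes: dict[str, dict] = {}
    edges: list[tuple[str, str, str]] = []
    for pth in sorted(groups.p_target):
        nodes[pth] = {"id": pth, "type": "pathway", "role": "pathway-to-target"}
    keep = candidates[candidates["status"].isin(["candidate", "excluded-tox"])]
    for _, row in keep.iterrows():
        c = row["compound"]
        nodes[c] = {"id": c, "type": "compound", "role": "candidate"}
        overlap = set(row["overlap"].split(";")) if row["overlap"] else set()
        for g in sorted(kb.targets.get(c, [])):
            for pth in sorted(overlap):
                if g in sets.members(pth):
                    nodes.setdefault(g, {"id": g, "type": "gene", "role": "target"})
                    edges.append((c, "targets", g))
                    edges.append((g, "member-of", pth))
    edges = sorted(set(edges))
    net = {"nodes": sorted(nodes.values(), key=lambda n: (n["type"], n["id"])),
           "edges": [{"source": s, "type": t, "target": g} for s, t, g in edges]}
    if path_json is not None:
        Path(path_json).write_text(json.dumps(net, indent=1) + "\n")
    if path_sif is not None:
        Path(path_sif).write_text("".join(f"{s}\t{t}\t{g}\n" for s, t, g in edges))
    return net


def screening_summary(outcomes: dict[str, str]) -> dict:
    """Counts and hit rate from in vitro screening outcomes.

    ``outcomes`` maps compound -> one of {positive, negative, aggravating}.
    The hit rate is 100 * positives / screened, *truncated* (floored) to one
    decimal place — e.g. 6 of 21 gives 28.5.
    """
    if not outcomes:
        raise ValueError("no screened compounds")
    valid = {"positive", "negative", "aggravating"}
    bad = {v for v in outcomes.values() if v not in valid}
    if bad:
        raise ValueError(f"unknown outcome categories: {sorted(bad)}")
    n = len(outcomes)
    counts = {cat: sum(1 for v in outcomes.values() if v == cat) for cat in sorted(valid)}
    rate = math.floor(1000.0 * counts["positive"] / n) / 10.0
    return {"n_screened": n, **counts, "hit_rate_percent": rate}
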