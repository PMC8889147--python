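"""Readers and writers for the plain-text interchange formats.

Formats:

* expression matrix TSV — first column ``gene``, remaining columns samples
* sample metadata TSV — columns ``sample``, ``status``
* GMT — one set per line: name, description, tab-separated members
* signature library TSV — columns ``compound``, ``ranking`` (comma-separated
  gene ids, rank 1 first)
* compound KB TSV — columns ``compound``, ``targets`` (semicolon-separated),
  ``tox_flag`` (0/1), optional ``tox_source``
* query signature JSON — ``{"up": [...], "down": [...]}``
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .datatypes import (
    CompoundKB,
    ExpressionDataset,
    GeneSetCollection,
    QuerySignature,
    ReferenceProfile,
    SignatureLibrary,
)


# ---------------------------------------------------------------- expression

def read_expression(path_matrix, path_metadata) -> ExpressionDataset:
    """Load an expression matrix TSV plus its sample-metadata TSV.

    Sample identifiers must agree between the two files; mismatches raise
    with the offending ids listed.
    """
    values = pd.read_csv(path_matrix, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(path_metadata, sep="\t", comment="#")
    if not {"sample", "status"}.issubset(meta.columns):
        raise ValueError("metadata must have columns 'sample' and 'status'")
    status = meta.set_index("sample")["status"]
    extra_meta = sorted(set(status.index) - set(values.columns))
    extra_mat = sorted(set(values.columns) - set(status.index))
    if extra_meta or extra_mat:
        raise ValueError(
            f"sample mismatch between matrix and metadata; only in metadata: "
            f"{extra_meta}; only in matrix: {extra_mat}"
        )
    status = status.reindex(values.columns)
    return ExpressionDataset(values=values, status=status)


def write_expression(dataset: ExpressionDataset, path_matrix, path_metadata,
                     header: str | None = None) -> None:
    _write_with_header(path_matrix, dataset.values.rename_axis("gene").to_csv(sep="\t"), header)
    meta = pd.DataFrame({"sample": dataset.samples, "status": dataset.status.to_numpy()})
    _write_with_header(path_metadata, meta.to_csv(sep="\t", index=False), header)


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file; malformed lines raise with their line number."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()]
    n_parsed = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        sets[name] = members
        descriptions[name] = desc
        n_parsed += 1
    if n_parsed == 0:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path, header: str | None = None) -> None:
    lines = []
    if header:
        lines.append(f"# {header}")
    for name in collection:
        lines.append("\t".join([name, collection.descriptions.get(name, "na"), *collection.members(name)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------- signature library

def read_signature_library(path) -> SignatureLibrary:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"compound", "ranking"}.issubset(df.columns):
        raise ValueError("library TSV must have columns 'compound' and 'ranking'")
    profiles = {}
    for _, row in df.iterrows():
        profiles[row["compound"]] = ReferenceProfile(
            compound=row["compound"], ranking=row["ranking"].split(",")
        )
    return SignatureLibrary(profiles=profiles)


def write_signature_library(library: SignatureLibrary, path, header: str | None = None) -> None:
    rows = [{"compound": c, "ranking": ",".join(library[c].ranking)} for c in library]
    _write_with_header(path, pd.DataFrame(rows, columns=["compound", "ranking"]).to_csv(sep="\t", index=False), header)


# -------------------------------------------------------------- compound KB

def read_compound_kb(path) -> CompoundKB:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"compound": str, "targets": str})
    if not {"compound", "targets", "tox_flag"}.issubset(df.columns):
        raise ValueError("KB TSV must have columns 'compound', 'targets', 'tox_flag'")
    targets, tox, src = {}, {}, {}
    for _, row in df.iterrows():
        c = row["compound"]
        t = row["targets"]
        targets[c] = [] if pd.isna(t) or t == "" else t.split(";")
        tox[c] = bool(int(row["tox_flag"]))
        if "tox_source" in df.columns and not pd.isna(row.get("tox_source")):
            src[c] = str(row["tox_source"])
    return CompoundKB(targets=targets, tox=tox, tox_source=src)


def write_compound_kb(kb: CompoundKB, path, header: str | None = None) -> None:
    rows = [
        {
            "compound": c,
            "targets": ";".join(kb.targets[c]),
            "tox_flag": int(kb.tox.get(c, False)),
            "tox_source": kb.tox_source.get(c, ""),
        }
        for c in kb.compounds()
    ]
    cols = ["compound", "targets", "tox_flag", "tox_source"]
    _write_with_header(path, pd.DataFrame(rows, columns=cols).to_csv(sep="\t", index=False), header)


# ------------------------------------------------------------ query signature

def read_query_signature(path) -> QuerySignature:
    obj = json.loads(Path(path).read_text())
    return QuerySignature(up=list(obj["up"]), down=list(obj["down"]))


def write_query_signature(query: QuerySignature, path) -> None:
    Path(path).write_text(json.dumps({"up": query.up, "down": query.down}, indent=1) + "\n")


# ------------------------------------------------------------------ utilities

def _write_with_header(path, csv_text: str, header: str | None) -> None:
    """Write tabular text, optionally preceded by a '# ...' comment line."""
    prefix = f"# {header}\n" if header else ""
    Path(path).write_text(prefix + csv_text)


def read_plate_table(path) -> pd.DataFrame:
    """Plate CSV with columns well, condition, replicate, value (extra kept)."""
    df = pd.read_csv(path, comment="#")
    required = {"condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV must have at least columns {sorted(required)}")
    return df
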