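"""Core in-memory containers shared across pipeline stages.

The pipeline moves a small number of objects between stages: a labelled
expression matrix, a named collection of gene sets, a library of ranked
compound profiles, a query signature (up/down gene tags), and a compound
knowledgebase (targets + hepatotoxicity flags). All of them are thin,
validated wrappers over pandas/numpy structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the three cohort labels used throughout: healthy controls, simple
#: steatosis (NAFL), and steatohepatitis (NASH)
STATUS_LABELS = ("Healthy", "NAFL", "NASH")


@dataclass
class ExpressionDataset:
    """Genes x samples log2-intensity matrix with a health-status label per sample.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample identifier,
        entries on the log2 scale.
    status : pandas.Series
        Sample identifier -> status label, one of ``STATUS_LABELS``.
    """

    values: pd.DataFrame
    status: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if not self.values.columns.equals(pd.Index(self.status.index)):
            missing = set(self.values.columns).symmetric_difference(self.status.index)
            raise ValueError(f"sample ids differ between matrix and metadata: {sorted(missing)}")
        bad = set(self.status.unique()) - set(STATUS_LABELS)
        if bad:
            raise ValueError(f"unknown status labels: {sorted(bad)}; expected {STATUS_LABELS}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, label: str) -> pd.Index:
        """Sample ids carrying the given status label."""
        if label not in STATUS_LABELS:
            raise ValueError(f"unknown status label {label!r}; expected one of {STATUS_LABELS}")
        return self.samples[(self.status == label).to_numpy()]


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways), GMT-compatible.

    ``sets`` maps a pathway name to a list of member gene identifiers;
    ``descriptions`` carries the GMT description field (collection/source
    tag by convention).
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "na")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name]

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Drop members outside ``universe`` (and sets left empty)."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            m = [g for g in members if g in uni]
            if m:
                kept[name] = m
        return GeneSetCollection(kept, {n: self.descriptions[n] for n in kept})

    def sets_containing(self, genes) -> set[str]:
        """Names of sets containing at least one of ``genes``."""
        gs = set(genes)
        return {name for name, members in self.sets.items() if gs.intersection(members)}


@dataclass
class ReferenceProfile:
    """A compound's perturbational profile: a complete ranking of the universe.

    ``ranking`` lists gene identifiers from rank 1 (most up-regulated by the
    compound) to rank n (most down-regulated).
    """

    compound: str
    ranking: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ranking)) != len(self.ranking):
            raise ValueError(f"profile for {self.compound!r} is not a permutation (duplicate genes)")

    @property
    def n(self) -> int:
        return len(self.ranking)

    def ranks_of(self, genes) -> np.ndarray:
        """1-based ranks of ``genes``, ascending. Unknown gene -> KeyError."""
        pos = {g: i + 1 for i, g in enumerate(self.ranking)}
        try:
            r = np.array(sorted(pos[g] for g in genes), dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} absent from profile universe") from None
        return r


@dataclass
class SignatureLibrary:
    """Collection of :class:`ReferenceProfile`, one per compound."""

    profiles: dict[str, ReferenceProfile]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, compound: str) -> ReferenceProfile:
        return self.profiles[compound]


@dataclass
class QuerySignature:
    """A disease/steatogen signature: ordered up-tag and down-tag gene sets."""

    up: list[str]
    down: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up and down tags overlap: {sorted(overlap)[:5]}")


@dataclass
class CompoundKB:
    """Compound knowledgebase: target genes and hepatotoxicity flags.

    Emulates the DrugBank-style pooling of target/enzyme/transporter/carrier
    genes per compound plus ToxDB/LiverTox-style exclusion flags, as local
    input data rather than live lookups.
    """

    targets: dict[str, list[str]]
    tox: dict[str, bool]
    tox_source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.targets:
            self.tox.setdefault(c, False)

    def compounds(self) -> list[str]:
        return list(self.targets)

    def resolved_targets(self, compound: str, universe) -> list[str]:
        """Targets of ``compound`` present in ``universe`` (others dropped)."""
        if compound not in self.targets:
            raise KeyError(f"unknown compound {compound!r}")
        uni = set(universe)
        return [g for g in self.targets[compound] if g in uni]
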