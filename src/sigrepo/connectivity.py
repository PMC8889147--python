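"""Kolmogorov-Smirnov connectivity scoring against ranked compound profiles.

A query signature (up-tag and down-tag gene sets) is scored against a
compound's complete gene ranking with the running-sum K-S enrichment score
used by the original connectivity-map construction. For a tag of size t
whose members sit at ranks V(1) < ... < V(t) in a universe of n genes:

    a  = max_j ( j/t - V(j)/n )
    b  = max_j ( V(j)/n - (j-1)/t )
    ES = a   if a >= b   (tag concentrated near the top, ES > 0)
       = -b  otherwise   (tag concentrated near the bottom, ES < 0)

ES lies in [-1, 1]; ES = -1 is attained by a single tag gene at the very
bottom. The combined connectivity score contrasts the up- and down-tag
scores: compounds whose profile pushes the up-tag toward the top and the
down-tag toward the bottom *mimic* the query (score > 0); the converse
*reverses* it (score < 0); same-sign tag scores are called null (score 0).

Significance comes from a tag-permutation null: random disjoint tag sets of
the same sizes rescored on the same profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import QuerySignature, ReferenceProfile, SignatureLibrary


def ks_enrichment(ranks, n: int) -> float:
    """K-S enrichment score of a tag whose members sit at ``ranks`` (1-based).

    ``ranks`` need not be pre-sorted; they must be distinct integers in
    [1, n]. Ties between the two running maxima resolve to the positive
    branch ``a``.
    """
    V = np.sort(np.asarray(ranks, dtype=np.int64))
    t = V.size
    if t == 0:
        raise ValueError("empty tag set")
    if t > n or V[0] < 1 or V[-1] > n or np.unique(V).size != t:
        raise ValueError("ranks must be distinct integers in [1, n]")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - V / n))
    b = float(np.max(V / n - (j - 1) / t))
    return a if a >= b else -b


def _ks_batch(V_sorted: np.ndarray, n: int) -> np.ndarray:
    """Vectorised :func:`ks_enrichment` over a (B, t) matrix of sorted ranks."""
    B, t = V_sorted.shape
    j = np.arange(1, t + 1, dtype=float)[None, :]
    a = (j / t - V_sorted / n).max(axis=1)
    b = (V_sorted / n - (j - 1) / t).max(axis=1)
    return np.where(a >= b, a, -b)


def connectivity_score(profile: ReferenceProfile, query: QuerySignature
                       ) -> tuple[float, float, float]:
    """(ES_up, ES_down, combined score) of a query against one profile.

    The combined score is 0 when the tag scores share a sign (or either is
    zero); otherwise (ES_up - ES_down) / 2, which stays in [-1, 1] and is
    antisymmetric under swapping the up and down tags.
    """
    if not query.up or not query.down:
        raise ValueError("combined scoring needs non-empty up and down tags")
    es_up = ks_enrichment(profile.ranks_of(query.up), profile.n)
    es_down = ks_enrichment(profile.ranks_of(query.down), profile.n)
    if es_up * es_down >= 0:
        score = 0.0
    else:
        score = (es_up - es_down) / 2.0
    return es_up, es_down, score


def _combined_from_tags(es_up: np.ndarray, es_down: np.ndarray) -> np.ndarray:
    return np.where(es_up * es_down >= 0, 0.0, (es_up - es_down) / 2.0)


def permutation_p(profile: ReferenceProfile, tag_sizes: tuple[int, int],
                  observed_score: float, B: int = 999, seed: int = 0,
                  exhaustive: bool = False) -> float:
    """Two-sided tag-permutation p for a combined connectivity score.

    The null rescoring draws B random *disjoint* (up, down) tag sets of the
    given sizes on the same profile; p = (1 + #{|null| >= |obs|}) / (B + 1).
    ``exhaustive=True`` enumerates every disjoint tag placement instead
    (tiny universes only) and returns the exact tail fraction.
    """
    t_up, t_down = tag_sizes
    n = profile.n
    if t_up + t_down > n:
        raise ValueError("tag sizes exceed the universe")
    if exhaustive:
        from itertools import combinations

        null = []
        ranks = np.arange(1, n + 1)
        for up in combinations(ranks, t_up):
            rest = [r for r in ranks if r not in up]
            for down in combinations(rest, t_down):
                null.append(_combined_from_tags(
                    _ks_batch(np.array([up]), n), _ks_batch(np.array([down]), n))[0])
        null = np.asarray(null)
        return float(np.mean(np.abs(null) >= abs(observed_score)))
    if B < 99:
        raise ValueError("B must be >= 99 for a stable permutation p")
    rng = np.random.default_rng(seed)
    # B disjoint pairs: take the first t_up + t_down entries of a random order
    r = rng.random((B, n))
    take = np.argpartition(r, t_up + t_down - 1, axis=1)[:, : t_up + t_down]
    # ranks are 1-based positions in the profile; the index IS the rank-1
    up_ranks = np.sort(take[:, :t_up], axis=1) + 1
    down_ranks = np.sort(take[:, t_up:], axis=1) + 1
    null = _combined_from_tags(_ks_batch(up_ranks, n), _ks_batch(down_ranks, n))
    return (1 + int(np.sum(np.abs(null) >= abs(observed_score)))) / (B + 1)


@dataclass
class ConnectivityResult:
    """Per-compound connectivity outcome of a library screen."""

    compound: str
    es_up: float
    es_down: float
    score: float
    p: float
    selected: bool


class ConnectivityScreen(BaseEstimator):
    """Screen a ranked-profile library against a query signature.

    ``fit`` stores the library; ``screen`` (or ``fit_screen``) scores every
    compound, attaches a tag-permutation p, and flags compounds that are
    significant at ``alpha`` with a nonzero score — both signs are retained,
    so mimickers (score > 0) and reversers (score < 0) are all flagged.

    Attributes after ``screen``:

    results_ : DataFrame with columns compound, es_up, es_down, score, p,
        selected — sorted by |score| descending, compound ascending.
    """

    def __init__(self, alpha: float = 0.05, B: int = 999, seed: int = 0):
        self.alpha = alpha
        self.B = B
        self.seed = seed

    def fit(self, library: SignatureLibrary, y=None):
        self.library_ = library
        return self

    def screen(self, query: QuerySignature) -> pd.DataFrame:
        if not hasattr(self, "library_"):
            raise RuntimeError("fit the screen on a library first")
        if len(self.library_) == 0:
            warnings.warn("empty signature library: nothing to screen", stacklevel=2)
            self.results_ = pd.DataFrame(
                columns=["compound", "es_up", "es_down", "score", "p", "selected"]
            )
            return self.results_
        rows = []
        sizes = (len(query.up), len(query.down))
        for i, compound in enumerate(sorted(self.library_.profiles)):
            profile = self.library_[compound]
            es_up, es_down, score = connectivity_score(profile, query)
            p = permutation_p(profile, sizes, score, B=self.B,
                              seed=(self.seed + 1000003 * i) & 0x7FFFFFFF)
            rows.append(ConnectivityResult(compound, es_up, es_down, score, p,
                                           bool(p < self.alpha and score != 0.0)))
        df = pd.DataFrame([r.__dict__ for r in rows])
        df = df.sort_values(["score", "compound"], key=lambda s: -s.abs() if s.name == "score" else s,
                            kind="stable").reset_index(drop=True)
        self.results_ = df
        return df

    def fit_screen(self, library: SignatureLibrary, query: QuerySignature) -> pd.DataFrame:
        return self.fit(library).screen(query)

    def to_tsv(self, path, header: str | None = None) -> None:
        from .io import _write_with_header

        _write_with_header(path, self.results_.to_csv(sep="\t", index=False), header)


def screen_library(library: SignatureLibrary, query: QuerySignature,
                   alpha: float = 0.05, B: int = 999, seed: int = 0) -> pd.DataFrame:
    """Functional wrapper over :class:`ConnectivityScreen`."""
    return ConnectivityScreen(alpha=alpha, B=B, seed=seed).fit_screen(library, query)


def query_from_gene_stats(table: pd.DataFrame, tag_size: int = 50) -> QuerySignature:
    """Build a query signature from a gene-statistics table.

    The up tag is the ``tag_size`` genes with the largest moderated t, the
    down tag the ``tag_size`` most negative; this is how a steatogen's (or
    the disease's) expression signature is posed as a connectivity query.
    """
    if 2 * tag_size > len(table):
        raise ValueError("tag_size too large for the gene universe")
    ordered = table.sort_values("t_mod", kind="stable")
    down = list(ordered.index[:tag_size])
    up = list(ordered.index[-tag_size:])
    return QuerySignature(up=up, down=down)
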