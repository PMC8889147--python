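"""Directional gene-set analysis with method consensus.

Each gene set is scored by nine gene-set statistics drawn from the three
canonical functional-class-scoring families:

* signed-t methods — ``mean``, ``median``, ``sum``, ``maxmean`` of the
  moderated t values of the member genes;
* p-value methods — ``fisher`` (-2*sum(log p)), ``stouffer``
  (sum(z)/sqrt(k)), ``reporter`` (universe-standardised mean z), and
  ``tailstrength`` (Taylor-Tibshirani tail strength) on member p-values;
* rank method — ``wilcoxon`` (standardised rank-sum of the member t ranks
  against the complement).

Significance comes from a gene-sampling permutation null (random gene sets
of identical size), evaluated in five directionality classes:

* ``distinct up`` / ``distinct down`` — right/left tails of the
  signed-statistic null (one-sided member p-values for the p methods);
* ``mixed up`` / ``mixed down`` — the statistic restricted to the member
  genes of the corresponding sign, against nulls drawn from the same-sign
  portion of the universe with matched subset size;
* ``non-directional`` — the statistic on |t| (two-sided p-values), right
  tail.

Null index draws are keyed by (seed, set, universe size, subset size) only
— never by direction — so flipping the sign of every gene t swaps the
up/down p-values exactly.

Consensus across methods: within each class, sets are ranked per method by
p (ascending, average ranks on ties); the consensus rank is the median rank
across methods and the consensus p the median p. A set's assigned class is
the argmin of its consensus p, ties resolved toward ``non-directional``.
"""

from __future__ import annotations

import warnings
import zlib
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

CLASSES = ("distinct up", "mixed up", "non-directional", "mixed down", "distinct down")

T_METHODS = ("mean", "median", "sum", "maxmean")
P_METHODS = ("fisher", "stouffer", "reporter", "tailstrength")
RANK_METHODS = ("wilcoxon",)
ALL_METHODS = T_METHODS + P_METHODS + RANK_METHODS

_EPS = 1e-300


# ------------------------------------------------------------- raw statistics

def _stat_t(method: str, M: np.ndarray) -> np.ndarray:
    """Row-wise signed-t statistics on a (B, k) member matrix."""
    if method == "mean":
        return M.mean(axis=1)
    if method == "median":
        return np.median(M, axis=1)
    if method == "sum":
        return M.sum(axis=1)
    if method == "maxmean":
        pos = np.clip(M, 0.0, None).mean(axis=1)
        neg = np.clip(-M, 0.0, None).mean(axis=1)
        return np.where(pos >= neg, pos, -neg)
    raise ValueError(f"unknown signed-t method {method!r}")


def _stat_p(method: str, M: np.ndarray, z_mean: float = 0.0, z_sd: float = 1.0) -> np.ndarray:
    """Row-wise p-value statistics on a (B, k) member matrix of p-values."""
    k = M.shape[1]
    P = np.clip(M, _EPS, 1.0)
    if method == "fisher":
        return -2.0 * np.log(P).sum(axis=1)
    if method == "stouffer":
        return stats.norm.isf(np.clip(P, _EPS, 1 - 1e-16)).sum(axis=1) / np.sqrt(k)
    if method == "reporter":
        z = stats.norm.isf(np.clip(P, _EPS, 1 - 1e-16))
        return (z.mean(axis=1) - z_mean) * np.sqrt(k) / max(z_sd, 1e-12)
    if method == "tailstrength":
        S = np.sort(P, axis=1)
        j = np.arange(1, k + 1)
        return (1.0 - S * (k + 1) / j).mean(axis=1)
    raise ValueError(f"unknown p-value method {method!r}")


def _stat_rank(M: np.ndarray, m: int) -> np.ndarray:
    """Standardised Wilcoxon rank-sum on a (B, k) matrix of ranks in 1..m."""
    k = M.shape[1]
    W = M.sum(axis=1)
    mu = k * (m + 1) / 2.0
    sd = np.sqrt(k * (m - k) * (m + 1) / 12.0) if m > k else 1.0
    return (W - mu) / max(sd, 1e-12)


def set_statistic(table: pd.DataFrame, members, method: str) -> float:
    """Deterministic gene-set statistic for one method.

    ``table`` is a gene-statistics table (columns ``t_mod`` and ``p``
    indexed by gene); ``members`` the gene identifiers of the set (must
    resolve). Signed-t methods use the moderated t, p-value methods the raw
    two-sided p, the rank method the rank of t within the whole universe.
    """
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {list(ALL_METHODS)}")
    members = list(members)
    missing = [g for g in members if g not in table.index]
    if missing:
        raise KeyError(f"set members missing from the gene universe: {missing[:5]}")
    if method in T_METHODS:
        M = table.loc[members, "t_mod"].to_numpy(dtype=float)[None, :]
        return float(_stat_t(method, M)[0])
    if method in P_METHODS:
        p_all = np.clip(table["p"].to_numpy(dtype=float), _EPS, 1 - 1e-16)
        z_all = stats.norm.isf(p_all)
        M = table.loc[members, "p"].to_numpy(dtype=float)[None, :]
        return float(_stat_p(method, M, z_mean=float(z_all.mean()), z_sd=float(z_all.std(ddof=1)))[0])
    t = table["t_mod"].to_numpy(dtype=float)
    ranks = stats.rankdata(t)
    pos = {g: i for i, g in enumerate(table.index)}
    M = np.array([[ranks[pos[g]] for g in members]], dtype=float)
    return float(_stat_rank(M, len(t))[0])


# ------------------------------------------------------ permutation machinery

def _null_indices(rng: np.random.Generator, B: int, m: int, k: int) -> np.ndarray:
    """(B, k) index matrix: B random k-subsets of range(m), no replacement."""
    r = rng.random((B, m))
    return np.argpartition(r, k - 1, axis=1)[:, :k]


def _all_subsets(m: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(m), k)), dtype=np.intp)


def _emp_p(null: np.ndarray, obs: float, tail: str, exact: bool) -> float:
    """Empirical permutation p with the 1/(B+1) floor (or exact fraction)."""
    if tail == "right":
        hits = int(np.sum(null >= obs))
    else:
        hits = int(np.sum(null <= obs))
    if exact:
        return hits / null.size
    return (1 + hits) / (null.size + 1)


def _context_seed(seed: int, set_name: str, m: int, k: int) -> np.random.Generator:
    # direction-free key: sign flips swap which context a class reads from,
    # but the draws for a given (m, k) are identical either way
    crc = zlib.crc32(set_name.encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc, m, k]))


def permutation_class_p(table: pd.DataFrame, members, B: int = 999, seed: int = 0,
                        methods=ALL_METHODS, exhaustive: bool = False,
                        set_name: str = "") -> pd.DataFrame:
    """Five directionality-class p-values per method for one gene set.

    Returns a DataFrame indexed by method with one column per class in
    ``CLASSES``. ``exhaustive=True`` enumerates every k-subset of the
    universe instead of sampling B of them (tiny universes only) and uses
    the exact tail fraction rather than the add-one estimate.
    """
    if B < 99 and not exhaustive:
        raise ValueError("B must be >= 99 for a stable permutation p")
    members = list(members)
    idx = table.index.get_indexer(members)
    if (idx < 0).any():
        missing = [g for g, i in zip(members, idx) if i < 0]
        raise KeyError(f"set members missing from the gene universe: {missing[:5]}")

    t = table["t_mod"].to_numpy(dtype=float)
    p_raw = table["p"].to_numpy(dtype=float)
    # one-sided member p-values derived from the two-sided p and the sign of t
    p_up = np.where(t > 0, p_raw / 2.0, 1.0 - p_raw / 2.0)
    p_down = np.where(t < 0, p_raw / 2.0, 1.0 - p_raw / 2.0)
    G = t.size
    k = len(members)

    z_of = lambda p: stats.norm.isf(np.clip(p, _EPS, 1 - 1e-16))
    moments = {
        "up": (float(z_of(p_up).mean()), float(z_of(p_up).std(ddof=1))),
        "down": (float(z_of(p_down).mean()), float(z_of(p_down).std(ddof=1))),
        "two": (float(z_of(p_raw).mean()), float(z_of(p_raw).std(ddof=1))),
    }

    out = pd.DataFrame(1.0, index=list(methods), columns=list(CLASSES))

    def draws(m: int, kk: int) -> np.ndarray:
        if exhaustive:
            return _all_subsets(m, kk)
        rng = _context_seed(seed, set_name, m, kk)
        return _null_indices(rng, B, m, kk)

    # ---- distinct + non-directional: universe-wide null of size k
    J = draws(G, k)

    def fill(cls: str, method: str, obs: float, null: np.ndarray, tail: str) -> None:
        out.loc[method, cls] = _emp_p(null, obs, tail, exhaustive)

    rank_all = stats.rankdata(t)
    rank_abs = stats.rankdata(np.abs(t))
    for method in methods:
        if method in T_METHODS:
            null_s = _stat_t(method, t[J])
            obs_s = _stat_t(method, t[idx][None, :])[0]
            fill("distinct up", method, obs_s, null_s, "right")
            fill("distinct down", method, obs_s, null_s, "left")
            null_a = _stat_t(method, np.abs(t)[J])
            obs_a = _stat_t(method, np.abs(t)[idx][None, :])[0]
            fill("non-directional", method, obs_a, null_a, "right")
        elif method in P_METHODS:
            for cls, pv, key in (("distinct up", p_up, "up"), ("distinct down", p_down, "down"),
                                 ("non-directional", p_raw, "two")):
                zm, zs = moments[key]
                null_s = _stat_p(method, pv[J], zm, zs)
                obs_s = _stat_p(method, pv[idx][None, :], zm, zs)[0]
                fill(cls, method, obs_s, null_s, "right")
        else:  # wilcoxon
            null_s = _stat_rank(rank_all[J], G)
            obs_s = _stat_rank(rank_all[idx][None, :], G)[0]
            fill("distinct up", method, obs_s, null_s, "right")
            fill("distinct down", method, obs_s, null_s, "left")
            null_a = _stat_rank(rank_abs[J], G)
            obs_a = _stat_rank(rank_abs[idx][None, :], G)[0]
            fill("non-directional", method, obs_a, null_a, "right")

    # ---- mixed classes: sign-restricted subset against same-sign universe
    for cls, sign in (("mixed up", 1), ("mixed down", -1)):
        uni = np.flatnonzero(sign * t > 0)
        sub = np.array([i for i in idx if sign * t[i] > 0], dtype=np.intp)
        if sub.size == 0 or uni.size < 2 or sub.size >= uni.size:
            continue  # p stays 1: no genes of this sign to test
        st = sign * t  # positive over the relevant universe
        pv = p_up if sign > 0 else p_down
        zm = float(z_of(pv[uni]).mean())
        zs = float(z_of(pv[uni]).std(ddof=1)) if uni.size > 1 else 1.0
        Jm = draws(uni.size, sub.size)
        rank_sub = stats.rankdata(st[uni])
        sub_local = np.searchsorted(uni, sub)
        for method in methods:
            if method in T_METHODS:
                null_s = _stat_t(method, st[uni][Jm])
                obs_s = _stat_t(method, st[sub][None, :])[0]
            elif method in P_METHODS:
                null_s = _stat_p(method, pv[uni][Jm], zm, zs)
                obs_s = _stat_p(method, pv[sub][None, :], zm, zs)[0]
            else:
                null_s = _stat_rank(rank_sub[Jm], uni.size)
                obs_s = _stat_rank(rank_sub[sub_local][None, :], uni.size)[0]
            fill(cls, method, obs_s, null_s, "right")

    return out


# -------------------------------------------------------- consensus + classes

def classify_directionality(class_p: pd.Series) -> str:
    """Class of minimum p, with directional-dominance tie resolution.

    With permutation p-values a strongly direction-pure set floors at
    1/(B+1) in its distinct class *and* in the non-directional class, so a
    naive argmin cannot separate "coordinated up" from "directionless".
    Ties at the minimum are therefore resolved by which side carries the
    evidence: if only up-side classes (distinct/mixed up) tie with the
    minimum, the most specific up class wins (distinct before mixed);
    symmetrically for down. If both sides tie — balanced enrichment — or
    only the non-directional class attains the minimum, the set is
    ``non-directional``.
    """
    p = class_p.reindex(list(CLASSES))
    best = float(p.min())
    tied = {c for c in CLASSES if p[c] == best}
    up = tied & {"distinct up", "mixed up"}
    down = tied & {"distinct down", "mixed down"}
    if up and down:
        return "non-directional"
    if up:
        return "distinct up" if "distinct up" in up else "mixed up"
    if down:
        return "distinct down" if "distinct down" in down else "mixed down"
    return "non-directional"


def consensus_rank(p_by_method: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median rank and median p across methods, per set per class.

    ``p_by_method`` maps set name -> (method x class) p-value frame.
    Returns (consensus_p, consensus_rank), both set x class frames.
    """
    sets = list(p_by_method)
    cons_p = pd.DataFrame(index=sets, columns=list(CLASSES), dtype=float)
    cons_r = pd.DataFrame(index=sets, columns=list(CLASSES), dtype=float)
    if not sets:
        return cons_p, cons_r
    methods = p_by_method[sets[0]].index
    for cls in CLASSES:
        # sets x methods matrix of p-values
        P = pd.DataFrame({m: [p_by_method[s].loc[m, cls] for s in sets] for m in methods},
                         index=sets)
        ranks = P.rank(axis=0, method="average")
        cons_r[cls] = ranks.median(axis=1)
        cons_p[cls] = P.median(axis=1)
    return cons_p, cons_r


def significant_pathways(consensus_p: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sets whose best-class BH-adjusted consensus p is <= alpha.

    BH adjustment is applied within each class across sets; a set is
    reported with its assigned class and that class's adjusted p.
    """
    from statsmodels.stats.multitest import multipletests

    if consensus_p.empty:
        return pd.DataFrame(columns=["class", "p", "p_adj"])
    adj = consensus_p.copy()
    for cls in CLASSES:
        _, padj, _, _ = multipletests(consensus_p[cls].to_numpy(dtype=float), method="fdr_bh")
        adj[cls] = padj
    rows = []
    for s in consensus_p.index:
        cls = classify_directionality(consensus_p.loc[s])
        rows.append({"set": s, "class": cls, "p": consensus_p.loc[s, cls],
                     "p_adj": adj.loc[s, cls]})
    df = pd.DataFrame(rows).set_index("set")
    return df[df["p_adj"] <= alpha]


class DirectionalGSA(BaseEstimator):
    """Directional gene-set analysis over a collection, with consensus.

    Parameters
    ----------
    methods : sequence of method names (default: all nine).
    B : permutations per null (gene sampling), >= 99.
    min_size, max_fraction : set-size bounds; out-of-bounds sets are
        skipped with a warning, not an error.
    alpha : significance level on BH-adjusted consensus p.
    seed : base seed for all null draws.

    Attributes
    ----------
    class_p_ : dict set -> (method x class) permutation p-values.
    consensus_p_, consensus_rank_ : set x class frames.
    assigned_class_ : Series set -> directionality class.
    significant_ : frame of selected sets (class, p, p_adj).
    skipped_ : list of (set, reason).
    """

    def __init__(self, methods=ALL_METHODS, B: int = 999, min_size: int = 5,
                 max_fraction: float = 0.5, alpha: float = 0.05, seed: int = 0):
        self.methods = methods
        self.B = B
        self.min_size = min_size
        self.max_fraction = max_fraction
        self.alpha = alpha
        self.seed = seed

    def fit(self, table: pd.DataFrame, collection, y=None):
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; valid: {list(ALL_METHODS)}")
        universe = set(table.index)
        max_size = int(self.max_fraction * len(universe))
        class_p: dict[str, pd.DataFrame] = {}
        skipped: list[tuple[str, str]] = []
        for name in collection:
            members = [g for g in collection.members(name) if g in universe]
            if len(members) < self.min_size or len(members) > max_size:
                reason = (f"size {len(members)} outside [{self.min_size}, {max_size}]")
                skipped.append((name, reason))
                warnings.warn(f"skipping gene set {name!r}: {reason}", stacklevel=2)
                continue
            class_p[name] = permutation_class_p(
                table, members, B=self.B, seed=self.seed,
                methods=self.methods, set_name=name,
            )
        cons_p, cons_r = consensus_rank(class_p)
        self.class_p_ = class_p
        self.consensus_p_ = cons_p
        self.consensus_rank_ = cons_r
        self.assigned_class_ = pd.Series(
            {s: classify_directionality(cons_p.loc[s]) for s in cons_p.index}, dtype=object
        )
        self.significant_ = significant_pathways(cons_p, alpha=self.alpha)
        self.skipped_ = skipped
        return self

    def significant_sets(self) -> set[str]:
        return set(self.significant_.index)

    def to_tsv(self, path, header: str | None = None) -> None:
        from .io import _write_with_header

        rows = []
        for s in self.consensus_p_.index:
            cls = self.assigned_class_[s]
            rows.append({
                "set": s,
                "class": cls,
                "p": self.consensus_p_.loc[s, cls],
                "consensus_rank": self.consensus_rank_.loc[s, cls],
                "significant": int(s in self.significant_.index),
                **{f"p_{c.replace(' ', '_')}": self.consensus_p_.loc[s, c] for c in CLASSES},
            })
        _write_with_header(path, pd.DataFrame(rows).to_csv(sep="\t", index=False), header)
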