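"""Query-gene coexpression networks: Spearman edges rescored by mutual rank.

The workflow around a set of query genes (e.g. the expansin genes of one
phylogenetic group) is:

1. :func:`spearman_query_vs_all` — Spearman rho and two-sided p-value of each
   query against every other gene in the matrix;
2. :func:`call_edges` — keep pairs with ``|rho| > 0.95`` and ``p < 1e-5``,
   signed positive/negative;
3. :func:`mutual_rank_table` — MR(ab) = sqrt(Rank(a->b) * Rank(b->a)), the
   geometric mean of the two directed ranks of a pair, each rank taken by
   descending |rho| among all scored partners of the ranking gene;
4. :func:`apply_mr_reliability` — flag as reliable the edges whose MR falls
   in the smallest top fraction (default 1%) of all scored pairs.

Smaller MR means stronger mutual coexpression; MR(ab) = 1 only when each gene
is the other's single best partner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Edge",
    "CoexpressionNetwork",
    "spearman_query_vs_all",
    "spearman_exact_pvalue",
    "call_edges",
    "rank_partners",
    "mutual_rank",
    "mutual_rank_table",
    "apply_mr_reliability",
    "shared_partners",
    "cross_species_network_overlap",
    "write_edge_list",
]

EDGE_COLUMNS = ["query", "partner", "rho", "pvalue", "sign", "mr", "reliable"]


@dataclass(frozen=True)
class Edge:
    query: str
    partner: str
    rho: float
    pvalue: float
    sign: str
    mr: float = math.nan
    reliable: bool = False


@dataclass
class CoexpressionNetwork:
    """Edge table around a query-gene seed set, plus node annotations.

    ``edges`` has columns ``query, partner, rho, pvalue, sign, mr, reliable``;
    ``node_annotations`` (optional) is indexed by gene id with columns such as
    ``tf_family`` and ``lncrna_flag``.
    """

    edges: pd.DataFrame
    query_genes: list[str]
    node_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns: {missing}")
        extra = set(self.edges["query"]) - set(self.query_genes)
        if extra:
            raise ValueError(f"edges from non-query genes: {sorted(extra)}")
        if (self.edges["query"] == self.edges["partner"]).any():
            raise ValueError("self-edges are not allowed")

    def partners_of(self, query: str, reliable_only: bool = False) -> set[str]:
        sub = self.edges[self.edges["query"] == query]
        if reliable_only:
            sub = sub[sub["reliable"]]
        return set(sub["partner"])

    def to_networkx(self) -> nx.Graph:
        """Export with GraphML-compatible attribute names."""
        g = nx.Graph()
        for q in self.query_genes:
            g.add_node(q, is_query=True)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.query,
                row.partner,
                rho=float(row.rho),
                pvalue=float(row.pvalue),
                sign=row.sign,
                mr=float(row.mr),
                reliable=bool(row.reliable),
            )
        if self.node_annotations is not None:
            for gene, ann in self.node_annotations.iterrows():
                if gene in g:
                    for key, val in ann.items():
                        if pd.notna(val):
                            g.nodes[gene][str(key)] = val
        return g


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Column-wise average ranks of a gene x sample array (ranks across samples)."""
    return np.apply_along_axis(stats.rankdata, 1, values)


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation t = rho*sqrt((n-2)/(1-rho^2)).

    |rho| = 1 gives p = 0, which passes any p threshold.
    """
    rho = np.asarray(rho, dtype=float)
    p = np.zeros_like(rho)
    finite = np.abs(rho) < 1.0
    t = rho[finite] * np.sqrt((n - 2) / (1.0 - rho[finite] ** 2))
    p[finite] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(rho)] = np.nan
    return p


def spearman_exact_pvalue(x: Iterable[float], y: Iterable[float]) -> float:
    """Exact two-sided permutation p-value for Spearman rho (n <= 9 only).

    Enumerates all n! pairings of the observed rank vectors and counts
    permutations whose |rho| is at least the observed |rho|.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n > 9:
        raise ValueError("exact permutation p-value limited to n <= 9")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_pearson(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(_pearson(rx, ry[list(perm)]))
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt((a @ a) * (b @ b))
    if den == 0:
        return math.nan
    return float(a @ b / den)


def spearman_query_vs_all(m, queries: Iterable[str]) -> pd.DataFrame:
    """Spearman rho and p for every (query, partner) pair, partner != query.

    Requires a log2-scale matrix with at least 4 samples. Partners whose
    profile has zero variance get ``rho = NaN`` and are excluded from edge
    calling and ranking downstream. Ties receive average ranks.
    """
    if m.scale_tag != "log2":
        raise ValueError("correlations are computed on the log2-scale matrix")
    m.require_samples(4)
    queries = list(queries)
    missing = [q for q in queries if q not in m.values.index]
    if missing:
        raise KeyError(f"query genes absent from matrix: {missing}")
    genes = list(m.values.index)
    rho = _spearman_matrix(m.values.to_numpy(dtype=float))
    n = m.shape[1]
    gi = {g: i for i, g in enumerate(genes)}
    rows = []
    for q in queries:
        i = gi[q]
        for j, partner in enumerate(genes):
            if j == i:
                continue
            rows.append((q, partner, rho[i, j]))
    out = pd.DataFrame(rows, columns=["query", "partner", "rho"])
    out["pvalue"] = _spearman_p(out["rho"].to_numpy(), n)
    return out


def _spearman_matrix(values: np.ndarray) -> np.ndarray:
    """All-vs-all Spearman rho; zero-variance rows give NaN rows/columns."""
    ranks = _rank_columns(values)
    sd = ranks.std(axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe = norm.copy()
    safe[safe == 0] = 1.0
    unit = centered / safe[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    degenerate = sd == 0
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def call_edges(
    corr: pd.DataFrame,
    rho_threshold: float = 0.95,
    p_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Retain pairs with |rho| strictly above the threshold and p below it.

    Sign is ``positive`` iff rho > 0. Rows with undefined rho are dropped.
    The result keeps the edge-table schema with MR/reliable unset.
    """
    ok = corr.dropna(subset=["rho", "pvalue"])
    ok = ok[(ok["rho"].abs() > rho_threshold) & (ok["pvalue"] < p_threshold)]
    edges = ok.copy()
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    edges["mr"] = np.nan
    edges["reliable"] = False
    return edges[EDGE_COLUMNS].reset_index(drop=True)


def rank_partners(corr: pd.DataFrame, query: str, signed: bool = False) -> pd.Series:
    """Rank a query's scored partners: rank 1 = strongest, average ranks on ties.

    By default strength is |rho| so strong negative partners rank highly;
    ``signed=True`` ranks by rho itself. Undefined rho is excluded first.
    """
    sub = corr[corr["query"] == query].dropna(subset=["rho"])
    if sub.empty:
        raise ValueError(f"query {query!r} has no scored partners")
    key = sub["rho"] if signed else sub["rho"].abs()
    # Spearman rho is rank-based and takes rational values, so exact ties are
    # common; round before ranking so mathematically equal correlations tie
    # regardless of floating-point summation order
    ranks = stats.rankdata(-np.round(key.to_numpy(), 12))
    return pd.Series(ranks, index=sub["partner"].to_numpy(), name="rank")


def mutual_rank(rank_ab: float, rank_ba: float) -> float:
    """Geometric mean of the two directed ranks; MR >= 1."""
    if rank_ab < 1 or rank_ba < 1:
        raise ValueError("ranks must be >= 1")
    return math.sqrt(rank_ab * rank_ba)


def mutual_rank_table(m, queries: Iterable[str], signed: bool = False) -> pd.DataFrame:
    """MR for every scored (query, partner) pair of the matrix.

    Rank(a->b) is the position of b among ALL scored partners of a (not only
    edge-passing ones), by descending |rho| (or rho when ``signed``), average
    ranks on ties. Genes with zero-variance profiles are excluded.
    Returns columns ``query, partner, rank_qp, rank_pq, mr``.
    """
    if m.scale_tag != "log2":
        raise ValueError("mutual ranks are computed on the log2-scale matrix")
    queries = list(queries)
    genes = list(m.values.index)
    gi = {g: i for i, g in enumerate(genes)}
    missing = [q for q in queries if q not in gi]
    if missing:
        raise KeyError(f"query genes absent from matrix: {missing}")
    rho = _spearman_matrix(m.values.to_numpy(dtype=float))
    key = rho if signed else np.abs(rho)
    scored = ~np.isnan(rho).all(axis=1)
    # directed ranks: for gene i, rank of every other scored gene by strength
    nrows = len(genes)
    rank = np.full((nrows, nrows), np.nan)
    for i in range(nrows):
        if not scored[i]:
            continue
        others = [j for j in range(nrows) if j != i and scored[j] and not np.isnan(key[i, j])]
        if not others:
            continue
        vals = np.round(key[i, others], 12)  # tie mathematically equal rhos
        r = stats.rankdata(-vals)
        for pos, j in enumerate(others):
            rank[i, j] = r[pos]
    rows = []
    for q in queries:
        i = gi[q]
        for j, partner in enumerate(genes):
            if j == i or np.isnan(rank[i, j]) or np.isnan(rank[j, i]):
                continue
            rows.append((q, partner, rank[i, j], rank[j, i], mutual_rank(rank[i, j], rank[j, i])))
    return pd.DataFrame(rows, columns=["query", "partner", "rank_qp", "rank_pq", "mr"])


def apply_mr_reliability(
    edges: pd.DataFrame,
    all_pairs_mr: pd.DataFrame,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Mark edges reliable when their MR is in the smallest ``top_fraction``.

    The cutoff is the k-th smallest MR over the N scored pairs with
    k = ceil(top_fraction * N); ties at the cutoff are all included. The MR
    universe counts each unordered pair once.
    """
    if all_pairs_mr.empty:
        raise ValueError("empty mutual-rank table")
    dedup = all_pairs_mr.copy()
    dedup["_pair"] = [frozenset((q, p)) for q, p in zip(dedup["query"], dedup["partner"])]
    pair_mr = dedup.groupby("_pair")["mr"].first()
    n_pairs = len(pair_mr)
    k = math.ceil(top_fraction * n_pairs)
    cutoff = np.sort(pair_mr.to_numpy())[k - 1]
    out = edges.copy()
    lut = dict(pair_mr)
    mrs = []
    for q, p in zip(out["query"], out["partner"]):
        pair = frozenset((q, p))
        if pair not in lut:
            raise KeyError(f"edge ({q}, {p}) missing from the mutual-rank table")
        mrs.append(lut[pair])
    out["mr"] = mrs
    out["reliable"] = out["mr"] <= cutoff
    return out


def shared_partners(net: CoexpressionNetwork) -> tuple[pd.DataFrame, pd.Series]:
    """Per query pair, the number of partners coexpressed with both.

    Also returns per-partner breadth: how many query genes each partner
    connects to (breadth 1 = coexpressed with one query only).
    """
    if net.edges.empty and not net.query_genes:
        raise ValueError("empty network")
    psets = {q: net.partners_of(q) for q in net.query_genes}
    rows = []
    for a, b in itertools.combinations(net.query_genes, 2):
        rows.append((a, b, len(psets[a] & psets[b])))
    pairs = pd.DataFrame(rows, columns=["query_a", "query_b", "shared"])
    breadth = net.edges.groupby("partner")["query"].nunique()
    breadth.name = "n_queries"
    return pairs, breadth


def cross_species_network_overlap(
    netA: CoexpressionNetwork,
    netB: CoexpressionNetwork,
    pairs: Mapping[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Edges of netA whose ortholog-mapped image is an edge of netB, same sign.

    ``pairs`` maps species-A gene ids to species-B ids (or is an ortholog
    pair table with ``gene_a``/``gene_b`` columns). Genes without an ortholog
    are unmatched by definition. Edge matching is on the unordered pair.
    """
    if isinstance(pairs, pd.DataFrame):
        mapping = dict(zip(pairs["gene_a"], pairs["gene_b"]))
    else:
        mapping = dict(pairs)
    b_edges = {
        (frozenset((row.query, row.partner)), row.sign)
        for row in netB.edges.itertuples(index=False)
    }
    keep = []
    for idx, row in enumerate(netA.edges.itertuples(index=False)):
        qb = mapping.get(row.query)
        pb = mapping.get(row.partner)
        if qb is None or pb is None:
            continue
        if (frozenset((qb, pb)), row.sign) in b_edges:
            keep.append(idx)
    return netA.edges.iloc[keep].reset_index(drop=True)


def write_edge_list(net: CoexpressionNetwork, path, header_comment: str | None = None) -> None:
    """Write the edge table as TSV (query_id, partner_id, rho, pvalue, sign, mr, reliable)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out = net.edges.rename(columns={"query": "query_id", "partner": "partner_id"})
        out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
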