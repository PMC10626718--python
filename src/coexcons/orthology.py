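"""Highly-similar ortholog pairing and domain-based family screening.

A pair of genes from two species is a "highly similar ortholog" pair when
(1) each is the other's best BLASTP hit at e-value < 1e-5 in both directions
(reciprocal best hit, RBH), and (2) both genes belong to the same orthogroup.
Family candidates (e.g. expansins) are additionally required to carry every
characteristic conserved domain (DPBB_1 and Expansin_C by default).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "read_hit_table",
    "read_orthogroups",
    "read_domain_table",
    "collapse_hsps",
    "best_hits",
    "reciprocal_best_hits",
    "pair_orthologs",
    "screen_family_candidates",
    "normalize_domain_name",
]

HIT_COLUMNS = ["query", "subject", "evalue", "bitscore"]


def read_hit_table(
    path,
    columns: Mapping[str, int] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read BLAST tabular (outfmt-6-style) hits for one comparison direction.

    ``columns`` maps ``query``/``subject``/``evalue``/``bitscore`` to 0-based
    column positions; the default is the standard outfmt 6 layout
    (qseqid=0, sseqid=1, evalue=10, bitscore=11). Multiple HSPs per
    (query, subject) are collapsed to the minimal-e-value / maximal-bitscore
    row at load time.
    """
    pos = {"query": 0, "subject": 1, "evalue": 10, "bitscore": 11}
    if columns:
        pos.update(columns)
    raw = pd.read_csv(path, sep=sep, header=None, comment="#")
    hits = pd.DataFrame(
        {
            "query": raw.iloc[:, pos["query"]].astype(str),
            "subject": raw.iloc[:, pos["subject"]].astype(str),
            "evalue": raw.iloc[:, pos["evalue"]].astype(float),
            "bitscore": raw.iloc[:, pos["bitscore"]].astype(float),
        }
    )
    return collapse_hsps(hits)


def collapse_hsps(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per (query, subject): minimal e-value, then maximal bitscore."""
    if (hits["evalue"] < 0).any():
        raise ValueError("negative e-value in hit table")
    ordered = hits.sort_values(
        ["query", "subject", "evalue", "bitscore"],
        ascending=[True, True, True, False],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["query", "subject"], keep="first").reset_index(drop=True)


def best_hits(hits: pd.DataFrame, emax: float = 1e-5) -> dict[str, str]:
    """Best passing subject per query.

    Hits with e-value >= ``emax`` are discarded before selection, so a query
    whose best raw hit fails the gate gets no entry rather than its
    second-best. Ties on e-value break by maximal bitscore, then by
    lexicographically smallest subject id.
    """
    if hits.empty:
        raise ValueError("empty hit table")
    passing = hits[hits["evalue"] < emax]
    ordered = passing.sort_values(
        ["query", "evalue", "bitscore", "subject"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = ordered.drop_duplicates("query", keep="first")
    return dict(zip(top["query"], top["subject"]))


def reciprocal_best_hits(
    ab: pd.DataFrame, ba: pd.DataFrame, emax: float = 1e-5
) -> pd.DataFrame:
    """Pairs (a, b) where a's best hit is b and b's best hit is a.

    The e-value gate applies in both directions. Output is one-to-one by
    construction, with the supporting e-values recorded, sorted by gene_a.
    """
    fwd = best_hits(ab, emax=emax) if not ab.empty else {}
    rev = best_hits(ba, emax=emax) if not ba.empty else {}
    e_ab = dict(zip(zip(ab["query"], ab["subject"]), ab["evalue"]))
    e_ba = dict(zip(zip(ba["query"], ba["subject"]), ba["evalue"]))
    rows = [
        (a, b, e_ab[(a, b)], e_ba[(b, a)])
        for a, b in fwd.items()
        if rev.get(b) == a
    ]
    rows.sort()
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue_ab", "evalue_ba"])


def read_orthogroups(path, sep: str = "\t") -> pd.DataFrame:
    """Read an Orthofinder-style orthogroups table.

    Layout: header row with species names, then one row per orthogroup —
    orthogroup id followed by a comma-separated gene list per species.
    Returns a long-format table (orthogroup_id, species, gene). A gene may
    belong to at most one orthogroup.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    og_col = raw.columns[0]
    rows = []
    for _, row in raw.iterrows():
        og = row[og_col]
        for species in raw.columns[1:]:
            cell = row[species]
            if pd.isna(cell) or not str(cell).strip():
                continue
            for gene in str(cell).split(","):
                gene = gene.strip()
                if gene:
                    rows.append((og, species, gene))
    out = pd.DataFrame(rows, columns=["orthogroup_id", "species", "gene"])
    dup = out[out.duplicated("gene", keep=False)]
    multi = dup.groupby("gene")["orthogroup_id"].nunique()
    offenders = sorted(multi[multi > 1].index)
    if offenders:
        raise ValueError(f"genes in more than one orthogroup: {offenders}")
    return out.drop_duplicates(["orthogroup_id", "gene"]).reset_index(drop=True)


def _orthogroup_of(og: pd.DataFrame) -> dict[str, str]:
    return dict(zip(og["gene"], og["orthogroup_id"]))


def pair_orthologs(rbh: pd.DataFrame, og: pd.DataFrame) -> pd.DataFrame:
    """Retain RBH pairs whose two genes share an orthogroup.

    A pair where either gene is missing from every orthogroup is dropped
    (membership is required, not just non-contradiction). Output columns:
    gene_a, gene_b, orthogroup_id, evalue_ab, evalue_ba.
    """
    group_of = _orthogroup_of(og)
    rows = []
    for row in rbh.itertuples(index=False):
        ga = group_of.get(row.gene_a)
        gb = group_of.get(row.gene_b)
        if ga is not None and ga == gb:
            rows.append((row.gene_a, row.gene_b, ga, row.evalue_ab, row.evalue_ba))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "orthogroup_id", "evalue_ab", "evalue_ba"]
    )


def read_domain_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a (gene, domain, evalue) TSV of per-gene domain annotations."""
    out = pd.read_csv(path, sep=sep, dtype={0: str, 1: str}, comment="#")
    out.columns = ["gene", "domain", "evalue"][: len(out.columns)]
    if (out["domain"].astype(str).str.strip() == "").any():
        raise ValueError("empty domain name in domain table")
    return out


def normalize_domain_name(name: str) -> str:
    """Case-insensitive with '-' and '_' treated as equivalent."""
    return name.strip().lower().replace("-", "_")


def screen_family_candidates(
    candidates: Iterable[str],
    domains: pd.DataFrame,
    required: Sequence[str] = ("DPBB_1", "Expansin_C"),
) -> list[str]:
    """Keep candidates that carry every required conserved domain.

    A candidate passes when the domain table has at least one row for each
    required domain name (matched case-insensitively, '-'=='_'). The result
    preserves the input candidate order.
    """
    req = {normalize_domain_name(d) for d in required}
    by_gene: dict[str, set[str]] = {}
    for gene, dom in zip(domains["gene"], domains["domain"]):
        by_gene.setdefault(str(gene), set()).add(normalize_domain_name(str(dom)))
    return [g for g in candidates if req <= by_gene.get(g, set())]
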