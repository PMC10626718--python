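"""End-to-end orchestration: simulate/load -> filter -> networks -> orthologs -> EC.

One :class:`RunConfig` carries every threshold of the analysis with the
published defaults (mean FPKM 0.1, CV 0.5, |rho| 0.95, p 1e-5, MR top 1%,
e-value 1e-5, EC tolerance 0.1). Outputs are deterministic: identical
(inputs, config, seed) produce byte-identical files, and every output file
starts with a header comment carrying the tool version, a config hash and
the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpr import (
    CoexpressionNetwork,
    apply_mr_reliability,
    call_edges,
    mutual_rank_table,
    shared_partners,
    spearman_query_vs_all,
    write_edge_list,
)
from .ec import (
    compare_ec_distributions,
    ec_from_paired,
    ec_quantile_placement,
)
from .expr import (
    filter_expression,
    log_transform,
    read_expression_matrix,
    write_expression_matrix,
)
from .orthology import pair_orthologs, reciprocal_best_hits
from .simulate import (
    SimulationConfig,
    orthogroups_to_wide,
    simulate_expression,
    simulate_orthology_tables,
    simulate_species_pair,
)

__all__ = ["RunConfig", "PRESETS", "run_coexpression_stage", "run_conservation_stage", "run_all"]

logger = logging.getLogger(__name__)

# Named simulation presets. `paper-small` is the desk-scale analog of the
# study design: 4 query groups (phylogenetic groups I-IV), species A profiled
# over 5 tissues x 2 replicates, species B over 6 conditions. Noise is set to
# 0.15 so that, at this small sample count, within-module gene pairs can clear
# the stringent |rho| > 0.95 and p < 1e-5 gates and yield non-trivial networks.
PRESETS: dict[str, SimulationConfig] = {
    "paper-small": SimulationConfig(
        n_genes=200,
        n_modules=4,
        n_conditions_a=5,
        n_conditions_b=6,
        replicates_per_condition=2,
        conserved_fraction=0.5,
        noise_sd=0.15,
        loading_scale=2.0,
        queries_per_module=3,
    ),
}


@dataclass(frozen=True)
class RunConfig:
    """All pipeline inputs and thresholds; defaults are the published values."""

    preset: str | None = "paper-small"
    matrix_path: str | None = None
    queries_path: str | None = None  # TSV: gene_id <tab> group
    min_mean: float = 0.1
    min_cv: float = 0.5
    rho_threshold: float = 0.95
    p_threshold: float = 1e-5
    mr_top_fraction: float = 0.01
    evalue_max: float = 1e-5
    tolerance: float = 0.1
    max_iter: int = 100
    decoy_rate: float = 0.3
    average_replicates: bool = False
    out_dir: str = "coexcons_out"
    seed: int = 7
    strict: bool = False

    def __post_init__(self) -> None:
        if self.preset is None and self.matrix_path is None:
            raise ValueError("either a simulation preset or input paths are required")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}")
        for name, lo, hi in [
            ("min_mean", 0.0, np.inf), ("min_cv", 0.0, np.inf),
            ("rho_threshold", 0.0, 1.0), ("p_threshold", 0.0, 1.0),
            ("mr_top_fraction", 0.0, 1.0), ("evalue_max", 0.0, 1.0),
            ("tolerance", 0.0, np.inf),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is not part
        of what determines the results)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def header(self) -> str:
        return f"coexcons v{__version__} config={self.config_hash()} seed={self.seed}"

    def sim_config(self) -> SimulationConfig:
        base = PRESETS[self.preset]
        return dataclasses.replace(base, seed=self.seed)


def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


class _RunLog:
    """Structured stage log: goes to the logger and to a deterministic file."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def event(self, stage: str, message: str, _level: int = logging.INFO, **counts) -> None:
        detail = " ".join(f"{k}={v}" for k, v in counts.items())
        line = f"[{stage}] {message}" + (f" {detail}" if detail else "")
        self.lines.append(line)
        logger.log(_level, line)

    def write(self, path: Path, header: str) -> None:
        path.write_text(f"# {header}\n" + "".join(f"{l}\n" for l in self.lines))


def _load_inputs(cfg: RunConfig, log: _RunLog):
    """Expression matrix + query groups, from the preset or from files."""
    if cfg.preset is not None:
        matrix, truth = simulate_expression(cfg.sim_config())
        groups = {m: list(gs) for m, gs in truth.query_genes.items()}
        log.event("input", f"simulated preset {cfg.preset}",
                  genes=matrix.shape[0], samples=matrix.shape[1])
        return matrix, groups, truth
    matrix = read_expression_matrix(cfg.matrix_path)
    q = pd.read_csv(cfg.queries_path, sep="\t", header=None, names=["gene", "group"],
                    dtype=str, comment="#")
    groups = {g: list(sub["gene"]) for g, sub in q.groupby("group", sort=True)}
    log.event("input", f"loaded {cfg.matrix_path}",
              genes=matrix.shape[0], samples=matrix.shape[1])
    return matrix, groups, None


def run_coexpression_stage(cfg: RunConfig, out_dir: Path | None = None, log: _RunLog | None = None):
    """Per query group: filtered matrix -> Spearman edges -> MR reliability.

    Returns ``(networks, summary)`` where ``networks`` maps group label to
    :class:`CoexpressionNetwork` and ``summary`` is a per-query table with
    partner counts and the exactly-one-query vs multi-query partner split.
    """
    log = log or _RunLog()
    matrix, groups, _ = _load_inputs(cfg, log)
    if not cfg.average_replicates:
        log.event("filter", "replicates kept as independent samples (no averaging)")
    filtered, report = filter_expression(matrix, min_mean=cfg.min_mean, min_cv=cfg.min_cv)
    log.event("filter", "expression filter applied",
              input=matrix.shape[0], removed=len(report), survivors=filtered.shape[0])
    logm = log_transform(filtered)
    kept = set(logm.gene_ids)
    networks: dict = {}
    summary_rows = []
    for group in sorted(groups, key=str):
        queries = [q for q in groups[group] if q in kept]
        lost = [q for q in groups[group] if q not in kept]
        if lost:
            log.event("coexpr", f"group {group}: queries removed by filter", lost=len(lost))
        if not queries:
            log.event("coexpr", f"group {group}: no surviving query genes, empty network",
                      _level=logging.WARNING)
            networks[group] = CoexpressionNetwork(
                edges=pd.DataFrame(columns=["query", "partner", "rho", "pvalue", "sign", "mr", "reliable"]),
                query_genes=[],
            )
            continue
        corr = spearman_query_vs_all(logm, queries)
        edges = call_edges(corr, rho_threshold=cfg.rho_threshold, p_threshold=cfg.p_threshold)
        mr = mutual_rank_table(logm, queries)
        if not edges.empty:
            edges = apply_mr_reliability(edges, mr, top_fraction=cfg.mr_top_fraction)
        net = CoexpressionNetwork(edges=edges, query_genes=queries)
        networks[group] = net
        _, breadth = shared_partners(net)
        n_single = int((breadth == 1).sum())
        n_multi = int((breadth > 1).sum())
        for q in queries:
            summary_rows.append(
                (group, q, len(net.partners_of(q)), len(net.partners_of(q, reliable_only=True)))
            )
        log.event("coexpr", f"group {group}: network built",
                  queries=len(queries), edges=len(edges),
                  reliable=int(edges["reliable"].sum()) if len(edges) else 0,
                  partners_single_query=n_single, partners_multi_query=n_multi)
    summary = pd.DataFrame(
        summary_rows, columns=["group", "query", "n_partners", "n_reliable_partners"]
    )
    if out_dir is not None:
        write_expression_matrix(filtered, out_dir / "expression_filtered.tsv", cfg.header())
        _write_tsv(report, out_dir / "removal_report.tsv", cfg.header())
        for group, net in networks.items():
            write_edge_list(net, out_dir / f"network_group{group}.edges.tsv", cfg.header())
        _write_tsv(summary, out_dir / "network_summary.tsv", cfg.header())
    return networks, summary


def run_conservation_stage(cfg: RunConfig, out_dir: Path | None = None, log: _RunLog | None = None):
    """Ortholog pairing + iterative EC + distribution comparison.

    With a simulation preset: generates a species pair and matching
    hit/orthogroup/domain tables, recovers ortholog pairs through the
    RBH + orthogroup procedure, runs the iterative EC on the recovered pairs,
    and contrasts the EC distributions of truly conserved vs scrambled pairs
    (Mann-Whitney U) plus the placement of the planted family subset against
    the genome-wide top-5% EC cutoff.
    """
    log = log or _RunLog()
    if cfg.preset is None:
        raise NotImplementedError("conservation stage currently runs from a simulation preset")
    sim = cfg.sim_config()
    paired, truth = simulate_species_pair(sim)
    hits_ab, hits_ba, og_long, domains = simulate_orthology_tables(
        truth, decoy_rate=cfg.decoy_rate, seed=cfg.seed
    )
    rbh = reciprocal_best_hits(hits_ab, hits_ba, emax=cfg.evalue_max)
    pair_set = pair_orthologs(rbh, og_long)
    log.event("orthology", "ortholog pairing",
              hits_ab=len(hits_ab), hits_ba=len(hits_ba),
              rbh=len(rbh), pairs=len(pair_set))
    if len(pair_set) < 4:
        raise ValueError(f"ortholog pair set too small for EC: {len(pair_set)} < 4")
    # restrict the paired matrices to the recovered pairs, preserving order
    recovered = set(zip(pair_set["gene_a"], pair_set["gene_b"]))
    mask = [tuple(p) in recovered for p in truth.ortholog_map]
    sel = np.flatnonzero(mask)
    from .ec import PairedExpression

    paired_used = PairedExpression(
        pairs=paired.pairs.iloc[sel].reset_index(drop=True),
        matrix_a=paired.matrix_a.iloc[sel],
        matrix_b=paired.matrix_b.iloc[sel],
    )
    result = ec_from_paired(paired_used, tolerance=cfg.tolerance, max_iter=cfg.max_iter)
    if cfg.strict and not result.converged:
        raise RuntimeError(f"EC did not converge within {cfg.max_iter} iterations")
    log.event("ec", "iterative EC finished",
              pairs=paired_used.n_pairs, iterations=result.n_iterations,
              converged=result.converged)
    genes_a = list(paired_used.pairs["gene_a"])
    cons_mask = np.array([truth.conserved_pair[g] for g in genes_a])
    ec_cons = result.ec[cons_mask]
    ec_scr = result.ec[~cons_mask]
    mw = compare_ec_distributions(ec_cons, ec_scr)
    fam = [i for i, g in enumerate(genes_a) if g in set(truth.family_genes)]
    frac_top5 = (
        ec_quantile_placement(result.ec, result.ec[fam], q=0.95) if fam else float("nan")
    )
    report = pd.DataFrame(
        {
            "gene_a": genes_a,
            "gene_b": list(paired_used.pairs["gene_b"]),
            "ec_final": result.ec,
            "ec_initial": result.ec_initial,
            "n_iterations": result.n_iterations,
            "converged": result.converged,
        }
    )
    summary = pd.DataFrame(
        [
            ("speciesA-speciesB", "conserved_truth", mw.n1, mw.median1, mw.u_statistic, mw.pvalue, ""),
            ("speciesA-speciesB", "scrambled_truth", mw.n2, mw.median2, mw.u_statistic, mw.pvalue, ""),
            ("speciesA-speciesB", "planted_family", len(fam),
             float(np.median(result.ec[fam])) if fam else float("nan"), "", "", f"{frac_top5:.6g}"),
        ],
        columns=["species_pair", "gene_set", "n", "median_ec", "mw_u", "p_value", "frac_top5"],
    )
    log.event("ec", "EC distribution comparison",
              median_conserved=f"{mw.median1:.4f}", median_scrambled=f"{mw.median2:.4f}",
              mw_p=f"{mw.pvalue:.3g}", family_frac_top5=f"{frac_top5:.4f}")
    if out_dir is not None:
        _write_tsv(hits_ab, out_dir / "hits_ab.tsv", cfg.header())
        _write_tsv(hits_ba, out_dir / "hits_ba.tsv", cfg.header())
        _write_tsv(orthogroups_to_wide(og_long), out_dir / "orthogroups.tsv", cfg.header())
        _write_tsv(domains, out_dir / "domains.tsv", cfg.header())
        _write_tsv(pair_set, out_dir / "ortholog_pairs.tsv", cfg.header())
        _write_tsv(report, out_dir / "ec_report.tsv", cfg.header())
        _write_tsv(summary, out_dir / "ec_summary.tsv", cfg.header())
    return result, report, summary


def run_all(cfg: RunConfig) -> Path:
    """Run both stages, write all outputs and the run log; returns the out dir."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog()
    log.event("run", f"coexcons v{__version__}", config=cfg.config_hash(), seed=cfg.seed)
    run_coexpression_stage(cfg, out_dir=out_dir, log=log)
    run_conservation_stage(cfg, out_dir=out_dir, log=log)
    with open(out_dir / "config.yaml", "w") as fh:
        fh.write(f"# {cfg.header()}\n")
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    log.write(out_dir / "run.log", cfg.header())
    return out_dir
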