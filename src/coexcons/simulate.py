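"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes, not
read-level data: tissue-specific expression programs induce coexpression
modules within a species, and ortholog pairs that share a program across
species are "conserved". The model is a linear latent-factor model on the
log2 scale:

    log2-signal(g, s) = baseline + loading * activity(module(g), condition(s))
                        + noise,      FPKM = 2^signal - 1 (floored at 0)

Module activities are drawn from a standard normal and then decorrelated
across modules within each species (QR orthogonalization over the condition
panel), so tissue programs are mutually distinct even in small panels;
replicate columns share the condition's activity and differ only in noise. A fraction
of genes is "flat" (no module loading) to exercise the coefficient-of-
variation filter. For a species pair, the condition panels are drawn
independently per species — deliberately NOT matched, because the EC
statistic exists to compare species whose tissue panels differ. A conserved
pair keeps its module in both species; a scrambled pair gets an
independently drawn module in species B, so module co-membership of two
genes carries no cross-species information under the null.

Everything is a pure function of (config, seed): same inputs, byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ec import PairedExpression
from .expr import ExpressionMatrix
from .orthology import collapse_hsps

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_expression",
    "simulate_species_pair",
    "simulate_orthology_tables",
    "orthogroups_to_wide",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults mirror the study shape at desk scale: species A profiled over
    5 tissue conditions with 2 biological replicates each, species B over 6
    conditions without replication; log2-scale module loadings of 2 over a
    baseline of 3 give FPKM in the tens with strongly tissue-driven variation,
    and noise_sd = 0.25 is the per-cell log2 measurement noise.

    ``n_modules = None`` (the default) plants one expression program per
    condition of the smaller panel — the maximal program diversity the panel
    can resolve; tissue-driven coexpression means each profiled condition
    class carries its own program.
    """

    n_genes: int = 200
    n_modules: int | None = None
    n_conditions_a: int = 5
    n_conditions_b: int = 6
    replicates_per_condition: int = 2
    conserved_fraction: float = 0.5
    noise_sd: float = 0.25
    loading_scale: float = 2.0
    baseline_log2_mean: float = 3.0
    flat_fraction: float = 0.1
    queries_per_module: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_genes >= self.modules >= 1):
            raise ValueError("need n_genes >= n_modules >= 1")
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must be in [0, 1]")
        if self.noise_sd <= 0 or self.loading_scale <= 0:
            raise ValueError("noise_sd and loading_scale must be positive")
        if not 0.0 <= self.flat_fraction < 1.0:
            raise ValueError("flat_fraction must be in [0, 1)")
        if self.n_conditions_a < 2 or self.n_conditions_b < 2:
            raise ValueError("need at least 2 conditions per species")
        if self.modules > min(self.n_conditions_a, self.n_conditions_b) - 1:
            raise ValueError(
                "n_modules must be below the condition count of both species "
                "(centred programs span at most n_conditions - 1 dimensions)"
            )
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")

    @property
    def modules(self) -> int:
        """Resolved module count: the maximal program diversity of the panel
        (one less than the smaller species' condition count)."""
        if self.n_modules is not None:
            return self.n_modules
        return max(min(self.n_conditions_a, self.n_conditions_b) - 1, 1)


@dataclass
class SimulationTruth:
    """Planted ground truth enabling recovery tests."""

    module_of_gene_a: dict[str, int]
    module_of_gene_b: dict[str, int] = field(default_factory=dict)
    conserved_pair: dict[str, bool] = field(default_factory=dict)  # keyed by gene_a
    ortholog_map: list[tuple[str, str]] = field(default_factory=list)
    query_genes: dict[int, list[str]] = field(default_factory=dict)  # module -> genes
    flat_genes: list[str] = field(default_factory=list)
    family_genes: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def all_queries(self) -> list[str]:
        return [g for mod in sorted(self.query_genes) for g in self.query_genes[mod]]


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _signal(
    rng: np.random.Generator,
    modules: np.ndarray,
    loadings: np.ndarray,
    n_conditions: int,
    replicates: int,
    n_modules: int,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, list[str]]:
    """Log2-scale signal matrix and sample labels for one species."""
    if n_modules > n_conditions - 1:
        raise ValueError(
            f"cannot plant {n_modules} distinct programs in {n_conditions} conditions"
        )
    # distinct module programs: a Gaussian draw, mean-centred and
    # orthogonalized (QR against the constant vector), rescaled so each
    # activity vector has the norm of a standard-normal vector; programs are
    # then exactly uncorrelated across the panel
    basis = np.column_stack([np.ones(n_conditions), rng.standard_normal((n_conditions, n_modules))])
    q, _ = np.linalg.qr(basis)
    activity = q[:, 1:].T * np.sqrt(n_conditions)
    n_genes = len(modules)
    cols = []
    labels = []
    for c in range(n_conditions):
        for r in range(replicates):
            noise = rng.normal(0.0, cfg.noise_sd, size=n_genes)
            col = cfg.baseline_log2_mean + loadings * activity[modules, c] + noise
            cols.append(col)
            labels.append(f"cond{c + 1:02d}_rep{r + 1}" if replicates > 1 else f"cond{c + 1:02d}")
    return np.column_stack(cols), labels


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """One species' FPKM matrix with planted modules and flat genes.

    Flat genes carry no module loading, so their coefficient of variation is
    small and the expression filter should remove them; module genes get the
    full loading and survive. Query genes (the seed set for network
    construction) are the first ``queries_per_module`` non-flat genes of each
    module.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names("gA", cfg.n_genes)
    modules = np.arange(cfg.n_genes) % cfg.modules
    n_flat = int(round(cfg.flat_fraction * cfg.n_genes))
    flat_idx = rng.choice(cfg.n_genes, size=n_flat, replace=False) if n_flat else np.array([], dtype=int)
    loadings = np.full(cfg.n_genes, cfg.loading_scale)
    loadings[flat_idx] = 0.0
    signal, labels = _signal(
        rng, modules, loadings, cfg.n_conditions_a, cfg.replicates_per_condition,
        cfg.modules, cfg,
    )
    fpkm = np.maximum(np.exp2(signal) - 1.0, 0.0)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=genes, columns=labels), scale_tag="fpkm"
    )
    flat_set = {genes[i] for i in flat_idx}
    queries: dict[int, list[str]] = {}
    for m in range(cfg.modules):
        members = [g for g, mod in zip(genes, modules) if mod == m and g not in flat_set]
        queries[m] = members[: cfg.queries_per_module]
    truth = SimulationTruth(
        module_of_gene_a=dict(zip(genes, (int(m) for m in modules))),
        query_genes=queries,
        flat_genes=sorted(flat_set),
        family_genes=[g for mod in sorted(queries) for g in queries[mod]],
        config=cfg,
    )
    return matrix, truth


def simulate_species_pair(cfg: SimulationConfig) -> tuple[PairedExpression, SimulationTruth]:
    """Row-aligned log2 expression for n ortholog pairs in two species.

    A ``conserved_fraction`` of pairs keeps its module identity in species B;
    the rest get a module drawn independently and uniformly over all modules,
    so under the null (conserved_fraction = 0) module co-membership of two
    genes is uncorrelated between species and EC is centred on zero. A
    scrambled pair may land on its own module by chance (probability
    1/n_modules); its truth label stays "scrambled". Condition panels are
    independent between species. Matrices are on the log2 scale, ready for
    correlation.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    genes_a = _gene_names("gA", n)
    genes_b = _gene_names("gB", n)
    modules_a = np.arange(n) % cfg.modules
    n_cons = int(round(cfg.conserved_fraction * n))
    cons_idx = rng.choice(n, size=n_cons, replace=False)
    conserved = np.zeros(n, dtype=bool)
    conserved[cons_idx] = True
    modules_b = modules_a.copy()
    scrambled = np.flatnonzero(~conserved)
    modules_b[scrambled] = rng.integers(0, cfg.modules, size=len(scrambled))
    loadings = np.full(n, cfg.loading_scale)
    sig_a, labels_a = _signal(
        rng, modules_a, loadings, cfg.n_conditions_a, cfg.replicates_per_condition,
        cfg.modules, cfg,
    )
    sig_b, labels_b = _signal(
        rng, modules_b, loadings, cfg.n_conditions_b, 1, cfg.modules, cfg
    )
    pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    paired = PairedExpression(
        pairs=pairs,
        matrix_a=pd.DataFrame(sig_a, index=genes_a, columns=[f"A_{s}" for s in labels_a]),
        matrix_b=pd.DataFrame(sig_b, index=genes_b, columns=[f"B_{s}" for s in labels_b]),
    )
    queries: dict[int, list[str]] = {}
    for m in range(cfg.modules):
        members = [g for g, mod in zip(genes_a, modules_a) if mod == m]
        queries[m] = members[: cfg.queries_per_module]
    truth = SimulationTruth(
        module_of_gene_a=dict(zip(genes_a, (int(m) for m in modules_a))),
        module_of_gene_b=dict(zip(genes_b, (int(m) for m in modules_b))),
        conserved_pair=dict(zip(genes_a, (bool(c) for c in conserved))),
        ortholog_map=list(zip(genes_a, genes_b)),
        query_genes=queries,
        family_genes=[g for mod in sorted(queries) for g in queries[mod]],
        config=cfg,
    )
    return paired, truth


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float, size=None):
    return np.power(10.0, rng.uniform(lo_exp, hi_exp, size=size))


def simulate_orthology_tables(
    truth: SimulationTruth,
    decoy_rate: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Hit tables (both directions), orthogroups and domains for a planted map.

    True pairs receive mutual hits with e-values log-uniform in
    [1e-50, 1e-10]. Decoys never displace a true best hit (their e-values are
    strictly worse than every true hit) and come in three flavours, each
    defeated by a different rule of the pairing procedure:

    - one-directional hits to a wrong partner (violate reciprocity),
    - high-bitscore hits with e-value in [1e-4, 1e-2] (fail the e-value gate),
    - extra gene pairs that ARE reciprocal best hits but sit in different
      orthogroups (fail the same-orthogroup requirement).

    Orthogroups hold one true pair each; contaminating extra genes are spread
    over existing orthogroups. The domain table plants both required expansin
    domains (DPBB-1, Expansin_C) on ``truth.family_genes``; other genes carry
    unrelated domains or a single required one.

    Returns ``(hits_ab, hits_ba, orthogroups_long, domain_table)`` where the
    orthogroup table is in long format (orthogroup_id, species, gene).
    """
    if not truth.ortholog_map:
        raise ValueError("truth has no ortholog map")
    if not 0.0 <= decoy_rate <= 1.0:
        raise ValueError("decoy_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = truth.ortholog_map
    n = len(pairs)
    ab_rows: list[tuple[str, str, float, float]] = []
    ba_rows: list[tuple[str, str, float, float]] = []
    for a, b in pairs:
        ab_rows.append((a, b, float(_loguniform(rng, -50, -10)), float(rng.uniform(200, 800))))
        ba_rows.append((b, a, float(_loguniform(rng, -50, -10)), float(rng.uniform(200, 800))))
    # decoys worse than every true hit (true e <= 1e-10 < 1e-9 <= decoy e)
    for i, (a, b) in enumerate(pairs):
        if n > 1 and rng.random() < decoy_rate:
            j = int(rng.choice([x for x in range(n) if x != i]))
            ab_rows.append((a, pairs[j][1], float(_loguniform(rng, -9, -6)), float(rng.uniform(80, 150))))
        if n > 1 and rng.random() < decoy_rate:
            j = int(rng.choice([x for x in range(n) if x != i]))
            ba_rows.append((b, pairs[j][0], float(_loguniform(rng, -9, -6)), float(rng.uniform(80, 150))))
        if rng.random() < decoy_rate:
            j = int(rng.choice([x for x in range(n) if x != i])) if n > 1 else i
            ab_rows.append((a, pairs[j][1], float(_loguniform(rng, -4, -2)), float(rng.uniform(400, 900))))
    # reciprocal-but-wrong-orthogroup decoys among extra genes
    n_extra = max(2, int(round(decoy_rate * n / 2)))
    extra_a = [f"xA{i:04d}" for i in range(1, n_extra + 1)]
    extra_b = [f"xB{i:04d}" for i in range(1, n_extra + 1)]
    for xa, xb in zip(extra_a, extra_b):
        ab_rows.append((xa, xb, float(_loguniform(rng, -40, -10)), float(rng.uniform(200, 800))))
        ba_rows.append((xb, xa, float(_loguniform(rng, -40, -10)), float(rng.uniform(200, 800))))
    hits_ab = collapse_hsps(pd.DataFrame(ab_rows, columns=["query", "subject", "evalue", "bitscore"]))
    hits_ba = collapse_hsps(pd.DataFrame(ba_rows, columns=["query", "subject", "evalue", "bitscore"]))

    og_rows: list[tuple[str, str, str]] = []
    for i, (a, b) in enumerate(pairs):
        og = f"OG{i:05d}"
        og_rows.append((og, "species_a", a))
        og_rows.append((og, "species_b", b))
    # contaminate: each extra gene joins some true pair's orthogroup, and the
    # two halves of an extra RBH pair always land in different orthogroups
    for k, (xa, xb) in enumerate(zip(extra_a, extra_b)):
        ia = int(rng.integers(0, n))
        ib = int((ia + 1 + rng.integers(0, max(n - 1, 1))) % n) if n > 1 else ia
        og_rows.append((f"OG{ia:05d}", "species_a", xa))
        if n > 1:
            og_rows.append((f"OG{ib:05d}", "species_b", xb))
    orthogroups = pd.DataFrame(og_rows, columns=["orthogroup_id", "species", "gene"])

    family = set(truth.family_genes)
    dom_rows: list[tuple[str, str, float]] = []
    other_domains = ["Pkinase", "MYB_DNA-bind", "WD40", "LRR_8"]
    for a, _ in pairs:
        if a in family:
            dom_rows.append((a, "DPBB_1", float(_loguniform(rng, -30, -10))))
            dom_rows.append((a, "Expansin_C", float(_loguniform(rng, -30, -10))))
        else:
            dom_rows.append((a, other_domains[int(rng.integers(0, len(other_domains)))],
                             float(_loguniform(rng, -20, -5))))
            if rng.random() < 0.1:  # near-miss: one required domain only
                dom_rows.append((a, "DPBB_1", float(_loguniform(rng, -20, -5))))
    domains = pd.DataFrame(dom_rows, columns=["gene", "domain", "evalue"])
    return hits_ab, hits_ba, orthogroups, domains


def orthogroups_to_wide(og_long: pd.DataFrame) -> pd.DataFrame:
    """Long (orthogroup_id, species, gene) -> Orthofinder-style wide table."""
    species = sorted(og_long["species"].unique())
    rows = []
    for og, sub in og_long.groupby("orthogroup_id", sort=True):
        row = {"Orthogroup": og}
        for sp in species:
            genes = sub.loc[sub["species"] == sp, "gene"]
            row[sp] = ", ".join(genes)
        rows.append(row)
    return pd.DataFrame(rows, columns=["Orthogroup", *species])
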