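"""Synthetic inputs: toy pathways, regulation tables, expression
cohorts with planted subpathway effects, and activity-linked survival.

The generator emulates the structure of an RPKM-like tumor cohort:
log-normal baseline expression shared across a tumor and a normal
group, a multiplicative fold change planted on the member genes and
lncRNAs of chosen subpathways in the tumor group, and censored
exponential survival times whose hazard follows a chosen subpathway's
normalized activity. One master seed fixes every artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from subspa import activity as act
from subspa import mining
from subspa.errors import InputError, SubspaError
from subspa.pathway_io import PathwayGraph, RegulationTable

_MAX_CONNECT_RETRIES = 1000


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults give a small multi-pathway cohort: 3 connected pathways of
    12 genes, 40 lncRNAs regulating 3 genes each, 30 tumor vs 30 normal
    samples, a 4-fold planted expression effect, and survival with a
    log-hazard slope of 0.8 per activity z-unit at ~30% censoring.
    """

    seed: int
    n_pathways: int = 3
    genes_per_pathway: int = 12
    edge_prob: float = 0.25
    n_lncrnas: int = 40
    regs_per_lncrna: int = 3
    n_tumor: int = 30
    n_normal: int = 30
    effect_subpathways: tuple = ()   # empty: the driver plants the first mined one
    effect_fold: float = 4.0
    expr_log_mean: float = 1.0
    expr_log_sd: float = 1.0
    cox_beta: float = 0.8
    baseline_hazard: float = 0.05    # events per day at activity 0
    censor_rate: float = 0.3
    k: int = 3
    min_genes: int = 3
    min_lncrnas: int = 2

    def __post_init__(self):
        positive = ["n_pathways", "genes_per_pathway", "n_lncrnas",
                    "regs_per_lncrna", "n_tumor", "n_normal"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise InputError(f"SimConfig.{name} must be positive")
        if self.effect_fold <= 0 or self.baseline_hazard <= 0:
            raise InputError("effect_fold and baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise InputError("censor_rate must lie in [0, 1)")


def _child_rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Pathways and regulations
# ---------------------------------------------------------------------------

def generate_pathways(config: SimConfig, rng=None) -> list:
    """Connected Erdos-Renyi gene graphs, one per pathway."""
    import networkx as nx

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pathways = []
    for p in range(config.n_pathways):
        pid = f"path:sim{p + 1:04d}"
        genes = [f"g{p + 1:02d}{i:03d}" for i in range(config.genes_per_pathway)]
        for attempt in range(_MAX_CONNECT_RETRIES):
            g = nx.Graph()
            g.add_nodes_from(genes)
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if rng.random() < config.edge_prob:
                        g.add_edge(genes[i], genes[j])
            if nx.is_connected(g):
                break
        else:
            raise SubspaError(
                f"could not generate a connected pathway of {len(genes)} genes "
                f"at edge_prob={config.edge_prob}"
            )
        pathways.append(PathwayGraph(pid, f"Simulated pathway {p + 1}", g))
    return pathways


def generate_regulations(config: SimConfig, pathways: list, rng=None) -> RegulationTable:
    """Each lncRNA regulates ``regs_per_lncrna`` distinct pathway genes."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    all_genes = sorted({g for p in pathways for g in p.graph.nodes})
    n_targets = min(config.regs_per_lncrna, len(all_genes))
    pairs = set()
    for i in range(config.n_lncrnas):
        lnc = f"lnc{i + 1:03d}"
        targets = rng.choice(len(all_genes), size=n_targets, replace=False)
        for t in targets:
            pairs.add((lnc, all_genes[t]))
    return RegulationTable(frozenset(pairs))


def write_kgml(pathway: PathwayGraph, path) -> None:
    """Serialize a pathway as minimal KGML (one gene entry per node)."""
    from lxml import etree

    root = etree.Element("pathway", name=pathway.pathway_id, title=pathway.name)
    ids = {g: str(i + 1) for i, g in enumerate(sorted(pathway.graph.nodes))}
    for gene, eid in ids.items():
        etree.SubElement(root, "entry", id=eid, name=gene, type="gene")
    for u, v in sorted(pathway.graph.edges, key=lambda e: tuple(sorted(e))):
        u, v = sorted((u, v))
        rel = etree.SubElement(root, "relation", entry1=ids[u], entry2=ids[v],
                               type="PPrel")
        etree.SubElement(rel, "subtype", name="interaction", value="--")
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Expression and survival
# ---------------------------------------------------------------------------

def generate_expression(
    config: SimConfig,
    effect_subpathways: list,
    gene_ids: list,
    lnc_ids: list,
    rng=None,
) -> tuple:
    """Log-normal baseline expression with planted tumor effects.

    Returns ``(gene_df, lnc_df, design_df)``. Tumor samples have the
    expression of every member (gene or lncRNA) of each effect
    subpathway multiplied by ``effect_fold``; normal samples are
    untouched. The design frame carries ``condition`` per sample.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tumor = [f"T{i + 1:03d}" for i in range(config.n_tumor)]
    normal = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    samples = tumor + normal
    features = list(gene_ids) + list(lnc_ids)
    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd,
                         size=(len(features), len(samples)))
    data = pd.DataFrame(base, index=features, columns=samples)
    planted = set()
    for sub in effect_subpathways:
        planted |= set(sub.components)
    planted &= set(features)
    if planted:
        data.loc[sorted(planted), tumor] *= config.effect_fold
    design = pd.DataFrame(
        {"condition": ["tumor"] * len(tumor) + ["normal"] * len(normal)},
        index=samples,
    )
    return data.loc[list(gene_ids)], data.loc[list(lnc_ids)], design


def generate_survival(activity_row: pd.Series, config: SimConfig, rng=None) -> pd.DataFrame:
    """Censored exponential survival with hazard tied to activity.

    Event times are exponential with rate
    ``baseline_hazard * exp(cox_beta * activity)``; censoring times are
    uniform on (0, m] with m tuned by bisection so the expected censored
    fraction matches ``censor_rate``.
    """
    x = activity_row.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InputError("activity values must be finite")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rates = config.baseline_hazard * np.exp(config.cox_beta * x)
    times = rng.exponential(1.0 / rates)
    if config.censor_rate == 0:
        event = np.ones(len(x), dtype=int)
        obs = times
    else:
        m = _censor_bound(rates, config.censor_rate)
        censor = rng.uniform(0.0, m, size=len(x))
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    obs = np.maximum(obs, 1e-9)  # survival times must be strictly positive
    return pd.DataFrame(
        {"time": obs, "event": event}, index=list(activity_row.index)
    )


def _censor_bound(rates: np.ndarray, target: float) -> float:
    """Bisection for m with mean_i P(U(0,m) < Exp(rate_i)) = target."""

    def censored_fraction(m):
        lm = rates * m
        return float(np.mean((1.0 - np.exp(-lm)) / lm))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SimData:
    """Everything one simulated cohort produced, plus ground truth."""

    config: SimConfig
    pathways: list
    regulations: RegulationTable
    subpathways: list
    gene_expr: pd.DataFrame
    lnc_expr: pd.DataFrame
    design: pd.DataFrame
    clinical: pd.DataFrame
    profile: act.ActivityProfile
    effect_subpathway_ids: list = field(default_factory=list)
    hazard_covariate: pd.Series | None = None  # tumor-sample z used in the hazard

    def manifest(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_subpathways": len(self.subpathways),
            "effect_subpathways": list(self.effect_subpathway_ids),
            "samples": {
                "tumor": sorted(self.design.index[self.design["condition"] == "tumor"]),
                "normal": sorted(self.design.index[self.design["condition"] == "normal"]),
            },
        }


def generate_dataset(config: SimConfig) -> SimData:
    """Generate a full coherent cohort from one master seed.

    Pathways are mined into subpathways first; if the config names no
    effect subpathways, the first mined subpathway is planted. Survival
    hazard follows the normalized activity of the first planted
    subpathway computed on tumor samples.
    """
    rngs = _child_rngs(config.seed, 4)
    pathways = generate_pathways(config, rngs[0])
    regs = generate_regulations(config, pathways, rngs[1])
    mcfg = mining.MiningConfig(k=config.k, min_genes=config.min_genes,
                               min_lncrnas=config.min_lncrnas)
    subpathways = []
    for pg in pathways:
        subpathways.extend(mining.build_subpathways(pg, regs, mcfg))
    if not subpathways:
        raise SubspaError("simulation produced no subpathway passing the size filter")
    by_id = {s.subpathway_id: s for s in subpathways}
    if config.effect_subpathways:
        missing = [i for i in config.effect_subpathways if i not in by_id]
        if missing:
            raise InputError(f"unknown effect subpathway id(s): {missing}")
        effects = [by_id[i] for i in config.effect_subpathways]
    else:
        effects = [subpathways[0]]
    gene_ids = sorted({g for p in pathways for g in p.graph.nodes})
    lnc_ids = sorted(regs.lncrnas)
    gene_expr, lnc_expr, design = generate_expression(
        config, effects, gene_ids, lnc_ids, rngs[2]
    )
    merged = act.merge_profiles(gene_expr, lnc_expr)
    profile = act.profile(merged, subpathways)
    tumor = list(design.index[design["condition"] == "tumor"])
    anchor = profile.spa_norm.loc[effects[0].subpathway_id, tumor]
    # re-normalize within the tumor group so the hazard slope is per z-unit
    sd = anchor.std(ddof=1)
    anchor_z = (anchor - anchor.mean()) / (sd if sd > 0 else 1.0)
    clinical = generate_survival(anchor_z, config, rngs[3])
    return SimData(
        config=config, pathways=pathways, regulations=regs,
        subpathways=subpathways, gene_expr=gene_expr, lnc_expr=lnc_expr,
        design=design, clinical=clinical, profile=profile,
        effect_subpathway_ids=[s.subpathway_id for s in effects],
        hazard_covariate=anchor_z,
    )
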