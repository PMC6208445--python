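"""Synthetic floral regulatory data with planted, exportable ground truth.

The generator emulates the study conditions of the real dataset: 15
master regulators, 144 expressed miRNA genes and 674 stage-responsive TF
genes connected by 422 TF->miRNA binding edges and 273 miRNA->TF
silencing edges, with 11 autoregulators; a 4-stage expression series with
replicates and log-normal noise; per-TF per-stage ChIP peaks whose
summits fall within 3 kb of target TSSs; a 3-domain x 2-stage translatome
with planted organ categories; a PPI table with configurable enrichment
among co-targeted TF pairs; and a sparse linear binding-to-fold-change
regression problem.  Every planted feature is recorded in a
:class:`SyntheticTruth` so downstream results can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ExpressionTable, GeneRecord, GenomicInterval, PeakRecord
from .domains import DomainExpressionTable, CATEGORIES
from .network import MetaNetwork
from .regress import RegressionDataset

# The 15 ChIP-profiled master regulators of the floral program.
MASTER_REGULATORS = (
    "FLC", "FLM", "SVP", "SOC1", "LFY", "AP1", "AP2", "AP3",
    "PI", "SEP3", "AG", "BLR", "JAG", "ETT", "RGA",
)
# The 11 TFs used for domain-specific binding and the regression model.
SELECTED_TFS = (
    "AG", "AP1", "AP2", "AP3", "BLR", "PI", "SEP3", "LFY", "JAG", "ETT", "RGA",
)


@dataclass
class GeneratorConfig:
    """All knobs of the generator; defaults mirror the study's scale."""

    seed: int = 0
    # network scale
    n_regulators: int = 15
    n_mirnas: int = 144
    n_de_tfs: int = 674
    n_other_genes: int = 2500
    edges_tf_mirna: int = 422
    edges_mirna_tf: int = 273
    edges_tf_tf: int = 1500
    n_extra_binding: int = 3000  # regulator->other-gene peaks, outside the network
    n_planted_ffls: int = 50
    autoregulation_count: int = 11
    n_hub_genes: int = 10
    hub_in_degree: int = 10
    closure_avoidance: bool = False
    # expression series
    stages: tuple[str, ...] = ("S0", "S2", "S4", "S8")
    n_replicates: int = 3
    noise_cv: float = 0.2
    de_fold_change: float = 4.0
    degree_dynamics_slope: float = 0.3  # extra fold change per extra bound TF
    # FFL dynamics
    dynamic_ffl_fraction: float = 0.733  # the 99/135 study fraction
    binding_change_fold: float = 4.0
    # peaks
    peak_length: int = 200
    tss_window: int = 2500  # summit placement, safely inside the 3 kb rule
    decoy_peak_rate: float = 0.1
    gene_spacing: int = 10_000
    gene_length: int = 2000
    n_chromosomes: int = 5
    # domain translatome
    domain_counts: dict = field(
        default_factory=lambda: {
            "AP1_specific": 250,
            "AP3_specific": 150,
            "AG_specific": 250,
            "AP1_AP3_common": 200,
            "AP3_AG_common": 163,
        }
    )
    n_null_domain_genes: int = 1000
    domain_effect_fold: float = 4.0
    domain_stages: tuple[str, ...] = ("S4", "S6")
    bound_fraction_target: float = 0.669  # the 678/1013 study fraction
    # PPI
    ppi_density: float = 0.05
    ppi_enrichment_factor: float = 5.0
    # regression
    regression_n_genes: int = 678
    regression_noise_sd: float = 0.5
    regression_beta: dict = field(
        default_factory=lambda: {"ETT": 1.0, "BLR": -1.0, "AG": 0.5, "AP1": -0.5}
    )

    def regulator_names(self) -> list[str]:
        if self.n_regulators == len(MASTER_REGULATORS):
            return list(MASTER_REGULATORS)
        return [f"REG{i:02d}" for i in range(1, self.n_regulators + 1)]

    def mirna_names(self) -> list[str]:
        return [f"MIR{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def tf_target_names(self) -> list[str]:
        return [f"TF{i:04d}" for i in range(1, self.n_de_tfs + 1)]

    def other_gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_other_genes + 1)]

    def validate(self) -> None:
        if self.n_planted_ffls > min(self.n_mirnas, self.n_de_tfs):
            raise ValueError("more planted FFLs than available miRNAs/targets")
        if self.n_planted_ffls > self.edges_tf_mirna:
            raise ValueError("planted FFLs exceed TF->miRNA edge budget")
        if self.n_planted_ffls > self.edges_mirna_tf:
            raise ValueError("planted FFLs exceed miRNA->TF edge budget")
        if self.autoregulation_count > self.n_regulators:
            raise ValueError("autoregulation count exceeds regulator count")
        if self.n_hub_genes * self.hub_in_degree > self.edges_tf_tf:
            raise ValueError("hub edges exceed TF->TF edge budget")
        if self.hub_in_degree > self.n_regulators:
            raise ValueError("hub in-degree exceeds regulator count")


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to score every pipeline stage."""

    planted_ffls: list[tuple[str, str, str]] = field(default_factory=list)
    incidental_ffls: list[tuple[str, str, str]] = field(default_factory=list)
    dynamic_ffls: set = field(default_factory=set)
    dynamic_evidence: dict = field(default_factory=dict)  # triple -> mirna|binding
    edge_signs: dict = field(default_factory=dict)  # (src, tgt) -> +|-
    autoregulators: set = field(default_factory=set)
    hub_genes: set = field(default_factory=set)
    extra_binding: list = field(default_factory=list)  # regulator->other edges
    de_genes: set = field(default_factory=set)
    domain_category: dict = field(default_factory=dict)
    true_beta: dict = field(default_factory=dict)
    ppi_pairs: set = field(default_factory=set)
    enriched_sim_pairs: set = field(default_factory=set)

    @property
    def all_ffls(self) -> list[tuple[str, str, str]]:
        return sorted(set(self.planted_ffls) | set(self.incidental_ffls))

    @property
    def dynamic_fraction(self) -> float:
        if not self.planted_ffls:
            return 0.0
        return len(self.dynamic_ffls) / len(self.planted_ffls)

    def to_json(self, path) -> None:
        payload = {
            "planted_ffls": [list(t) for t in self.planted_ffls],
            "incidental_ffls": [list(t) for t in self.incidental_ffls],
            "dynamic_ffls": sorted(list(t) for t in self.dynamic_ffls),
            "dynamic_evidence": {
                "|".join(k): v for k, v in self.dynamic_evidence.items()
            },
            "edge_signs": {"|".join(k): v for k, v in self.edge_signs.items()},
            "autoregulators": sorted(self.autoregulators),
            "hub_genes": sorted(self.hub_genes),
            "extra_binding": [list(e) for e in self.extra_binding],
            "de_genes": sorted(self.de_genes),
            "domain_category": self.domain_category,
            "true_beta": self.true_beta,
            "ppi_pairs": sorted(sorted(p) for p in self.ppi_pairs),
            "enriched_sim_pairs": sorted(sorted(p) for p in self.enriched_sim_pairs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive stream per generator stage
    return np.random.default_rng([config.seed % (2**31), stream])


def _closes_ffl(net: MetaNetwork, kind: str, u: str, v: str) -> bool:
    """Would adding edge u->v of the given kind close a new FFL triple?"""
    if kind == "tf_mirna":  # u regulator, v miRNA
        bound = net.successors(u, "binds")
        return any(t in bound for t in net.successors(v, "silences"))
    if kind == "tf_tf":  # u regulator, v TF gene
        for m in net.successors(u, "binds"):
            if "miRNA" in net.roles(m) and v in net.successors(m, "silences"):
                return True
        return False
    if kind == "mirna_tf":  # u miRNA, v TF gene
        for r in net.graph.predecessors(u):
            if net.graph[r][u]["etype"] == "binds" and net.has_edge(r, v, "binds"):
                return True
        return False
    raise ValueError(kind)


def generate_network(
    config: GeneratorConfig,
) -> tuple[MetaNetwork, SyntheticTruth]:
    """Build the meta-network with planted FFLs, hubs and autoregulation.

    Edge counts match the configuration exactly; planted FFLs use
    pairwise-disjoint miRNAs and targets so their dynamic status can be
    assigned independently.  All FFLs present in the emitted graph
    (planted plus incidental closures) are enumerated into the truth.
    """
    config.validate()
    rng = _rng(config, 1)
    regs = config.regulator_names()
    mirnas = config.mirna_names()
    tfs = config.tf_target_names()

    net = MetaNetwork()
    for r in regs:
        net.add_node(r, {"regulator", "tf_target"})
    for m in mirnas:
        net.add_node(m, {"miRNA"})
    for t in tfs:
        net.add_node(t, {"tf_target"})

    truth = SyntheticTruth()

    # planted FFLs: disjoint miRNAs and targets; regulators reused freely
    ffl_mirnas = list(rng.choice(mirnas, size=config.n_planted_ffls, replace=False))
    ffl_targets = list(rng.choice(tfs, size=config.n_planted_ffls, replace=False))
    for i in range(config.n_planted_ffls):
        r = regs[int(rng.integers(len(regs)))]
        m, t = ffl_mirnas[i], ffl_targets[i]
        net.add_edge(r, m, "binds")
        net.add_edge(r, t, "binds")
        net.add_edge(m, t, "silences")
        truth.planted_ffls.append((r, m, t))

    # autoregulation self-edges
    for r in rng.choice(regs, size=config.autoregulation_count, replace=False):
        net.add_edge(str(r), str(r), "binds")
        truth.autoregulators.add(str(r))

    # planted hub targets: high in-degree from distinct regulators
    hub_pool = [t for t in tfs if t not in set(ffl_targets)]
    hubs = list(rng.choice(hub_pool, size=config.n_hub_genes, replace=False))
    for h in hubs:
        for r in rng.choice(regs, size=config.hub_in_degree, replace=False):
            if not net.has_edge(str(r), h):
                net.add_edge(str(r), h, "binds")
        truth.hub_genes.add(h)

    def fill(kind: str, sources: list[str], targets: list[str], n_goal: int,
             n_have: int, etype: str) -> None:
        attempts = 0
        n = n_have
        while n < n_goal:
            attempts += 1
            if attempts > 200 * n_goal:
                raise RuntimeError(f"cannot place {kind} edges (too dense)")
            u = sources[int(rng.integers(len(sources)))]
            v = targets[int(rng.integers(len(targets)))]
            if u == v or net.has_edge(u, v):
                continue
            if config.closure_avoidance and _closes_ffl(net, kind, u, v):
                continue
            net.add_edge(u, v, etype)
            n += 1

    n_tf_mirna = sum(
        1 for _, v in net.edges_of_type("binds") if "miRNA" in net.roles(v)
    )
    # binds-to-TF count includes planted direct arms and hub edges but not
    # autoregulatory self-edges
    n_tf_tf = sum(
        1
        for u, v in net.edges_of_type("binds")
        if u != v and "miRNA" not in net.roles(v)
    )
    fill("tf_mirna", regs, mirnas, config.edges_tf_mirna, n_tf_mirna, "binds")
    fill("tf_tf", regs, tfs, config.edges_tf_tf, n_tf_tf, "binds")
    n_silence = len(net.edges_of_type("silences"))
    fill("mirna_tf", mirnas, tfs + regs, config.edges_mirna_tf, n_silence,
         "silences")

    # brute-force enumeration of every FFL actually present
    planted = set(truth.planted_ffls)
    found = []
    for r in regs:
        bound = net.successors(r, "binds")
        for m in bound:
            if "miRNA" not in net.roles(m):
                continue
            for t in net.successors(m, "silences"):
                if t in bound and t != r:
                    found.append((r, m, t))
    truth.incidental_ffls = sorted(set(found) - planted)

    # extra regulator->other-gene binding, realized only as peaks
    others = config.other_gene_names()
    seen: set[tuple[str, str]] = set()
    while len(seen) < config.n_extra_binding and others:
        r = regs[int(rng.integers(len(regs)))]
        g = others[int(rng.integers(len(others)))]
        seen.add((r, g))
    truth.extra_binding = sorted(seen)

    net.validate()
    return net, truth


def _profile_shape(
    rng: np.random.Generator, n_stages: int, fold: float
) -> np.ndarray:
    """A stage trajectory with max/min ratio exactly ``fold``."""
    kind = rng.choice(["up", "down", "pulse"])
    span = np.linspace(0.0, 1.0, n_stages)
    if kind == "up":
        shape = fold**span
    elif kind == "down":
        shape = fold ** (1.0 - span)
    else:
        peak = int(rng.integers(1, n_stages - 1))
        shape = np.ones(n_stages)
        shape[peak] = fold
    return shape


def _lognormal_noise(
    rng: np.random.Generator, shape: tuple, cv: float
) -> np.ndarray:
    if cv <= 0:
        return np.ones(shape)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=shape)


def generate_expression(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    network: MetaNetwork | None = None,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Stage-series mRNA and miRNA abundance tables.

    Regulators and planted DE TF genes get trajectories with the
    configured fold change; when the network is supplied, a TF gene's
    fold change grows with the number of regulators binding it
    (``degree_dynamics_slope``), emulating the observed coupling of
    combinatorial binding and expression dynamics.  Planted FFL arms copy
    (or mirror) the regulator's shape so the arm signs are known; miRNAs
    of planted dynamic-via-expression loops change >= the DE threshold,
    all other miRNAs stay flat.  Replicate noise is log-normal with the
    configured CV.  Dynamic-loop assignments are recorded into the truth
    here.
    """
    rng = _rng(config, 2)
    n_stages = len(config.stages)
    samples = [
        (s, r + 1) for s in config.stages for r in range(config.n_replicates)
    ]

    regs = config.regulator_names()
    tfs = config.tf_target_names()
    others = config.other_gene_names()
    mirnas = config.mirna_names()

    base = {
        g: float(rng.lognormal(np.log(20), 1.0))
        for g in regs + tfs + others + mirnas
    }
    # stage-responsive TF genes are, by construction, detectably expressed:
    # floor their baseline so the planted fold change survives the
    # downstream pseudocount
    for g in regs + tfs:
        base[g] = max(base[g], 10.0)
    in_degree: dict[str, int] = {}
    if network is not None:
        for u, v in network.edges_of_type("binds"):
            if u != v:
                in_degree[v] = in_degree.get(v, 0) + 1

    shapes: dict[str, np.ndarray] = {}
    for r in regs:
        shapes[r] = _profile_shape(rng, n_stages, config.de_fold_change)
    for t in tfs:
        fold = config.de_fold_change * (
            1 + config.degree_dynamics_slope * max(0, in_degree.get(t, 1) - 1)
        )
        shapes[t] = _profile_shape(rng, n_stages, min(fold, 64.0))
    for g in others:
        shapes[g] = np.ones(n_stages)
    for m in mirnas:
        shapes[m] = np.ones(n_stages)
    truth.de_genes = set(regs) | set(tfs)

    # choose dynamic loops and their evidence channel; plant the signals
    n_dyn = int(round(config.dynamic_ffl_fraction * len(truth.planted_ffls)))
    order = list(truth.planted_ffls)
    dyn_idx = rng.choice(len(order), size=n_dyn, replace=False)
    for j, i in enumerate(sorted(dyn_idx)):
        r, m, t = order[i]
        truth.dynamic_ffls.add((r, m, t))
        if j % 2 == 0:
            # dynamic via miRNA expression: shape follows +/- the regulator;
            # the baseline is floored so the planted fold change survives
            # the downstream pseudocount
            sign = "+" if rng.random() < 0.5 else "-"
            shapes[m] = shapes[r] if sign == "+" else 1.0 / shapes[r]
            base[m] = max(base[m], 20.0)
            truth.dynamic_evidence[(r, m, t)] = "mirna_expression_change"
            truth.edge_signs[(r, m)] = sign
        else:
            truth.dynamic_evidence[(r, m, t)] = "binding_change"

    # plant direct-arm signs for every loop target
    for r, m, t in truth.planted_ffls:
        sign = "+" if rng.random() < 0.5 else "-"
        shapes[t] = shapes[r] if sign == "+" else 1.0 / shapes[r]
        truth.edge_signs[(r, t)] = sign

    def table(genes: list[str]) -> ExpressionTable:
        values = np.zeros((len(genes), len(samples)))
        for i, g in enumerate(genes):
            means = base[g] * shapes[g]
            row = np.repeat(means, config.n_replicates)
            values[i] = row * _lognormal_noise(rng, row.shape, config.noise_cv)
        return ExpressionTable(list(genes), list(samples), values)

    return table(regs + tfs + others), table(mirnas)


def generate_annotation(config: GeneratorConfig) -> list[GeneRecord]:
    """Gene coordinates: one gene per 10 kb slot, round-robin chromosomes."""
    rng = _rng(config, 3)
    regs = set(config.regulator_names())
    mirnas = set(config.mirna_names())
    genes = (
        config.regulator_names()
        + config.tf_target_names()
        + config.mirna_names()
        + config.other_gene_names()
    )
    slot = {c: 0 for c in range(config.n_chromosomes)}
    records = []
    for i, g in enumerate(genes):
        c = i % config.n_chromosomes
        start = slot[c] * config.gene_spacing
        slot[c] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            GeneRecord(
                gene_id=g,
                interval=GenomicInterval(
                    f"chr{c + 1}", start, start + config.gene_length, strand
                ),
                gene_class="miRNA_precursor" if g in mirnas else "protein_coding",
                is_tf=g in regs or g.startswith("TF"),
            )
        )
    return records


def generate_peaks(
    config: GeneratorConfig,
    truth: SyntheticTruth,
    network: MetaNetwork,
    annotation: list[GeneRecord],
) -> dict[tuple[str, str], list[PeakRecord]]:
    """Per-(TF, stage) peak lists realizing every binding edge.

    Each binds edge (network plus extra off-network binding) yields one
    peak per stage with summit within the TSS window.  Edges of planted
    dynamic-via-binding loops ramp their score by the configured fold
    across stages; all other planted-loop edges are held constant; the
    rest jitter mildly (well under the dynamic threshold).  Decoy peaks
    land mid-gap, beyond 3 kb of any TSS.
    """
    rng = _rng(config, 4)
    by_id = {g.gene_id: g for g in annotation}
    stages = config.stages
    n_stages = len(stages)

    dynamic_binding_edges: set[tuple[str, str]] = set()
    constant_edges: set[tuple[str, str]] = set()
    for triple in truth.planted_ffls:
        r, m, t = triple
        if truth.dynamic_evidence.get(triple) == "binding_change":
            # ramp the regulator->miRNA arm; keep the direct arm constant
            dynamic_binding_edges.add((r, m))
            constant_edges.add((r, t))
        else:
            constant_edges.update([(r, m), (r, t)])

    # self-edges included: an autoregulator's peak at its own promoter
    binds_edges = list(network.edges_of_type("binds")) + list(
        truth.extra_binding
    )

    peaks: dict[tuple[str, str], list[PeakRecord]] = {}
    for u, v in binds_edges:
        gene = by_id[v]
        tss = gene.tss
        offset = int(rng.integers(-config.tss_window, config.tss_window + 1))
        # clamp near chromosome start; distance to TSS only shrinks
        summit = max(config.peak_length // 2, tss + offset)
        start = summit - config.peak_length // 2
        end = start + config.peak_length
        base_score = float(rng.uniform(5, 50))
        if (u, v) in dynamic_binding_edges:
            mult = config.binding_change_fold ** np.linspace(0, 1, n_stages)
        elif (u, v) in constant_edges:
            mult = np.ones(n_stages)
        else:
            mult = rng.uniform(0.9, 1.1, size=n_stages)
        for si, stage in enumerate(stages):
            peaks.setdefault((u, stage), []).append(
                PeakRecord(
                    interval=GenomicInterval(gene.interval.chrom, start, end),
                    tf=u,
                    stage=stage,
                    score=round(base_score * float(mult[si]), 4),
                    summit_offset=summit - start,
                )
            )

    # decoys: mid-gap, > 3 kb from every TSS given the 10 kb spacing
    n_decoys = int(round(config.decoy_peak_rate * len(binds_edges)))
    all_genes = list(by_id.values())
    for _ in range(n_decoys):
        g = all_genes[int(rng.integers(len(all_genes)))]
        summit = g.interval.start + config.gene_spacing - 4000
        start = summit - config.peak_length // 2
        tf = config.regulator_names()[int(rng.integers(config.n_regulators))]
        stage = stages[int(rng.integers(n_stages))]
        peaks.setdefault((tf, stage), []).append(
            PeakRecord(
                interval=GenomicInterval(
                    g.interval.chrom, start, start + config.peak_length
                ),
                tf=tf,
                stage=stage,
                score=float(rng.uniform(5, 50)),
                summit_offset=config.peak_length // 2,
            )
        )
    for plist in peaks.values():
        plist.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return peaks


def generate_domain_translatome(
    config: GeneratorConfig, truth: SyntheticTruth, network: MetaNetwork
) -> DomainExpressionTable:
    """Translatome with planted organ categories and binding coupling.

    Category genes are drawn so that the configured fraction is bound by
    >= 2 distinct regulators (counting network binds edges plus the
    off-network binding realized only as peaks), emulating the observed
    coupling between domain specificity and combinatorial TF occupancy.
    Domain effects are planted at the configured fold at both stages;
    null genes are flat.
    """
    rng = _rng(config, 5)
    bound_by: dict[str, set[str]] = {}
    for u, v in truth.extra_binding:
        bound_by.setdefault(v, set()).add(u)
    for u, v in network.edges_of_type("binds"):
        if u != v:
            bound_by.setdefault(v, set()).add(u)
    candidates = set(config.other_gene_names()) | set(config.tf_target_names())
    pool_multibound = sorted(
        g for g, tfs in bound_by.items() if len(tfs) >= 2 and g in candidates
    )
    # the non-multibound remainder: bound by <2 TFs (or unbound)
    pool_rest = sorted(
        g for g in candidates
        if len(bound_by.get(g, ())) < 2
    )

    n_cat = sum(config.domain_counts.values())
    n_mb = int(round(config.bound_fraction_target * n_cat))
    n_mb = min(n_mb, len(pool_multibound))
    chosen_mb = list(rng.choice(pool_multibound, size=n_mb, replace=False))
    chosen_rest = list(
        rng.choice(pool_rest, size=n_cat - n_mb, replace=False)
    )
    cat_genes = chosen_mb + chosen_rest
    rng.shuffle(cat_genes)

    i = 0
    for cat, n in config.domain_counts.items():
        for g in cat_genes[i : i + n]:
            truth.domain_category[g] = cat
        i += n
    null_pool = sorted(set(pool_rest) - set(cat_genes))
    null_genes = list(
        rng.choice(null_pool, size=config.n_null_domain_genes, replace=False)
    )
    for g in null_genes:
        truth.domain_category[g] = "none"

    genes = sorted(truth.domain_category)
    samples = [
        (d, s, r + 1)
        for d in ("AP1", "AP3", "AG")
        for s in config.domain_stages
        for r in range(config.n_replicates)
    ]
    f = config.domain_effect_fold
    mult = {
        "AP1_specific": {"AP1": f, "AP3": 1, "AG": 1},
        "AP3_specific": {"AP1": 1, "AP3": f, "AG": 1},
        "AG_specific": {"AP1": 1, "AP3": 1, "AG": f},
        "AP1_AP3_common": {"AP1": f, "AP3": f, "AG": 1},
        "AP3_AG_common": {"AP1": 1, "AP3": f, "AG": f},
        "none": {"AP1": 1, "AP3": 1, "AG": 1},
    }
    values = np.zeros((len(genes), len(samples)))
    for i, g in enumerate(genes):
        base = float(rng.lognormal(np.log(20), 0.8))
        m = mult[truth.domain_category[g]]
        row = np.array([base * m[d] for d, _, _ in samples])
        values[i] = row * _lognormal_noise(rng, row.shape, config.noise_cv)
    return DomainExpressionTable(genes, samples, values)


def generate_ppi(
    config: GeneratorConfig, truth: SyntheticTruth, network: MetaNetwork
) -> set[frozenset]:
    """PPI pairs over the TF target pool, enriched among SIM pairs.

    Co-targeted (SIM) pairs enter with probability density x factor, all
    other target pairs with the background density; factor 1 gives a
    homogeneous null.
    """
    import itertools

    rng = _rng(config, 6)
    targets_by_reg = {
        r: sorted(
            t
            for t in network.successors(r, "binds")
            if t != r and network.roles(t) & {"tf_target", "regulator"}
        )
        for r in sorted(network.nodes_with_role("regulator"))
    }
    pool = sorted(set().union(*targets_by_reg.values()))
    sim_pairs: set[frozenset] = set()
    for targets in targets_by_reg.values():
        for a, b in itertools.combinations(targets, 2):
            sim_pairs.add(frozenset((a, b)))

    p_sim = min(1.0, config.ppi_density * config.ppi_enrichment_factor)
    ppi: set[frozenset] = set()
    for pair in sorted(sim_pairs, key=sorted):
        if rng.random() < p_sim:
            ppi.add(pair)
    # background pairs by count, then rejection-sampled uniformly
    n_pool = len(pool)
    n_total_pairs = n_pool * (n_pool - 1) // 2
    n_bg_target = rng.binomial(n_total_pairs - len(sim_pairs), config.ppi_density)
    bg: set[frozenset] = set()
    attempts = 0
    while len(bg) < n_bg_target and attempts < 50 * n_bg_target + 100:
        attempts += 1
        i, j = rng.integers(0, n_pool, size=2)
        if i == j:
            continue
        pair = frozenset((pool[i], pool[j]))
        if pair in sim_pairs or pair in bg:
            continue
        bg.add(pair)
    ppi |= bg
    truth.ppi_pairs = set(ppi)
    truth.enriched_sim_pairs = sim_pairs if config.ppi_enrichment_factor != 1 else set()
    return ppi


def generate_regression(
    config: GeneratorConfig, truth: SyntheticTruth
) -> RegressionDataset:
    """Sparse linear fold-change problem: X ~ N(0,1), Y = X beta + eps."""
    rng = _rng(config, 7)
    features = list(SELECTED_TFS)
    beta = np.array([config.regression_beta.get(f, 0.0) for f in features])
    truth.true_beta = {f: float(b) for f, b in zip(features, beta)}
    n = config.regression_n_genes
    X = rng.standard_normal((n, len(features)))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = X @ beta + config.regression_noise_sd * rng.standard_normal(n)
    genes = [f"RG{i:04d}" for i in range(1, n + 1)]
    return RegressionDataset(
        genes=genes, feature_names=features, X=X, y=y, comparison="AP1-vs-AG"
    )


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, plus its ground truth."""

    config: GeneratorConfig
    network: MetaNetwork
    truth: SyntheticTruth
    annotation: list[GeneRecord]
    peaks: dict
    expression: ExpressionTable
    mirna_expression: ExpressionTable
    mirna_targets: pd.DataFrame
    translatome: DomainExpressionTable
    ppi: set
    regression: RegressionDataset


def generate_all(config: GeneratorConfig) -> SyntheticBundle:
    """Run every generator stage in dependency order."""
    network, truth = generate_network(config)
    expression, mirna_expression = generate_expression(config, truth, network)
    annotation = generate_annotation(config)
    peaks = generate_peaks(config, truth, network, annotation)
    translatome = generate_domain_translatome(config, truth, network)
    ppi = generate_ppi(config, truth, network)
    regression = generate_regression(config, truth)
    mirna_targets = pd.DataFrame(
        sorted(network.edges_of_type("silences")), columns=["source", "target"]
    )
    return SyntheticBundle(
        config=config,
        network=network,
        truth=truth,
        annotation=annotation,
        peaks=peaks,
        expression=expression,
        mirna_expression=mirna_expression,
        mirna_targets=mirna_targets,
        translatome=translatome,
        ppi=ppi,
        regression=regression,
    )


# ---------------------------------------------------------------------------
# scoring helpers: (output, truth) -> precision/recall or error


def score_sets(found: Iterable, expected: Iterable) -> dict[str, float]:
    found, expected = set(found), set(expected)
    tp = len(found & expected)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(expected) if expected else 1.0
    return {"precision": precision, "recall": recall, "tp": tp}


def score_domain_calls(calls, truth: SyntheticTruth) -> dict[str, float]:
    """Recovery of planted categories and false-call rate on null genes."""
    truth_cat = truth.domain_category
    planted = {g for g, c in truth_cat.items() if c != "none"}
    nulls = {g for g, c in truth_cat.items() if c == "none"}
    by_gene = {c.gene_id: c.category for c in calls}
    recovered = sum(
        1 for g in planted if by_gene.get(g) == truth_cat[g]
    )
    false_calls = sum(1 for g in nulls if by_gene.get(g, "none") != "none")
    return {
        "recovery": recovered / len(planted) if planted else 1.0,
        "false_call_rate": false_calls / len(nulls) if nulls else 0.0,
    }
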