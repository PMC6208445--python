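"""Floral-domain-specific gene calls and floral-quartet target sets.

Translatome abundances from the AP1 (sepal), AP3 (petal/stamen boundary)
and AG (stamen/carpel) expression domains at stages S4 and S6 are screened
per stage with a one-way ANOVA across domains (log2, pseudocounted) plus a
>2-fold change filter, then assigned to one of five organ categories from
the pairwise fold-change pattern of the domain means:

* X_specific         mean(X) > 2x both other domains (X in AP1, AP3, AG)
* AP1_AP3_common     AP1 and AP3 both > 2x AG, neither > 2x the other (petal)
* AP3_AG_common      AP3 and AG both > 2x AP1, neither > 2x the other (stamen)

The floral quartet model fixes the tetrameric TF complexes per organ;
organ target sets are intersections of the member TFs' ChIP target sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .targets import hypergeometric_coregulation

DOMAINS = ("AP1", "AP3", "AG")
STAGES = ("S4", "S6")
CATEGORIES = (
    "AP1_specific", "AP3_specific", "AG_specific",
    "AP1_AP3_common", "AP3_AG_common", "none",
)

# Floral quartet model: tetrameric MADS complexes per organ (SEP3 in all).
QUARTET_COMPLEXES: dict[str, frozenset] = {
    "sepal": frozenset({"AP1", "SEP3"}),
    "petal": frozenset({"AP1", "AP3", "PI", "SEP3"}),
    "stamen": frozenset({"AP3", "PI", "AG", "SEP3"}),
    "carpel": frozenset({"AG", "SEP3"}),
}


@dataclass
class DomainExpressionTable:
    """Genes x (domain, stage, replicate) translatome abundances."""

    genes: list[str]
    samples: list[tuple[str, str, int]]  # (domain, stage, replicate)
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("matrix shape does not match gene/sample lists")
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        for d in DOMAINS:
            for s in self.stages:
                if not self.columns(d, s):
                    raise ValueError(f"missing replicates for domain {d} stage {s}")

    @property
    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, s, _ in self.samples:
            seen.setdefault(s)
        return list(seen)

    def columns(self, domain: str, stage: str) -> list[int]:
        return [
            i for i, (d, s, _) in enumerate(self.samples)
            if d == domain and s == stage
        ]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{d}_{s}_rep{r}" for d, s, r in self.samples]
        return pd.DataFrame(self.values, index=self.genes, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DomainExpressionTable":
        samples = []
        for col in df.columns:
            domain, stage, rep = col.split("_")
            samples.append((domain, stage, int(rep.removeprefix("rep"))))
        return cls(list(df.index.astype(str)), samples, df.values)


@dataclass(frozen=True)
class DomainCall:
    gene_id: str
    category: str
    anova_p: float
    max_fc: float
    stage_support: str  # S4 | S6 | both | none


def _stage_category(dom_means: dict[str, float], fc_cut: float) -> str:
    m = {d: dom_means[d] for d in DOMAINS}

    def gt(a: str, b: str) -> bool:
        return m[a] > fc_cut * m[b]

    for x, y, z in (("AP1", "AP3", "AG"), ("AP3", "AP1", "AG"), ("AG", "AP1", "AP3")):
        if gt(x, y) and gt(x, z):
            return f"{x}_specific"
    if gt("AP1", "AG") and gt("AP3", "AG") and not gt("AP1", "AP3") and not gt("AP3", "AP1"):
        return "AP1_AP3_common"
    if gt("AP3", "AP1") and gt("AG", "AP1") and not gt("AP3", "AG") and not gt("AG", "AP3"):
        return "AP3_AG_common"
    return "none"


def call_domain_genes(
    table: DomainExpressionTable,
    p_cut: float = 0.05,
    fc_cut: float = 2.0,
    pseudocount: float = 1.0,
) -> list[DomainCall]:
    """Classify genes into the five floral-organ domain categories.

    Per stage: one-way ANOVA across the three domains on log2 of
    pseudocounted replicate values; a gene passes when the ANOVA p is
    below ``p_cut`` and the largest pairwise ratio of domain means
    exceeds ``fc_cut``.  The category comes from the passing stage; a
    gene passing at both stages must agree, otherwise it is set to none.
    """
    stages = table.stages
    reps_ok = all(
        len(table.columns(d, s)) >= 2 for d in DOMAINS for s in stages
    )
    if not reps_ok:
        warnings.warn(
            "fewer than 2 replicates: fold-change-only mode, ANOVA skipped",
            stacklevel=2,
        )
    logv = np.log2(table.values + pseudocount)

    calls = []
    for i, gene in enumerate(table.genes):
        per_stage: dict[str, tuple[str, float, float]] = {}
        for s in stages:
            groups = [logv[i, table.columns(d, s)] for d in DOMAINS]
            dom_means = {
                d: float(table.values[i, table.columns(d, s)].mean() + pseudocount)
                for d in DOMAINS
            }
            mx, mn = max(dom_means.values()), min(dom_means.values())
            fc = mx / mn
            if reps_ok:
                if all(np.ptp(g) == 0 for g in groups) and len(
                    {g[0] for g in groups}
                ) == 1:
                    p = 1.0
                else:
                    with np.errstate(invalid="ignore"):
                        p = float(stats.f_oneway(*groups).pvalue)
                    if np.isnan(p):
                        p = 1.0
            else:
                p = 0.0  # FC-only mode
            if p < p_cut and fc > fc_cut:
                per_stage[s] = (_stage_category(dom_means, fc_cut), p, fc)

        passing = {s: v for s, v in per_stage.items() if v[0] != "none"}
        if not passing:
            best_p = min((v[1] for v in per_stage.values()), default=1.0)
            best_fc = max((v[2] for v in per_stage.values()), default=1.0)
            calls.append(DomainCall(gene, "none", best_p, best_fc, "none"))
            continue
        cats = {v[0] for v in passing.values()}
        if len(passing) == 2 and len(cats) > 1:
            # conflicting categories across stages -> no call
            calls.append(
                DomainCall(
                    gene, "none",
                    min(v[1] for v in passing.values()),
                    max(v[2] for v in passing.values()),
                    "both",
                )
            )
            continue
        support = "both" if len(passing) == 2 else next(iter(passing))
        calls.append(
            DomainCall(
                gene,
                next(iter(cats)),
                min(v[1] for v in passing.values()),
                max(v[2] for v in passing.values()),
                support,
            )
        )
    return calls


def stage_anova_pvalues(
    table: DomainExpressionTable, stage: str, pseudocount: float = 1.0
) -> np.ndarray:
    """Per-gene one-way ANOVA p across the three domains at one stage.

    The raw per-test screen used inside :func:`call_domain_genes`; exposed
    so its calibration can be checked directly on null data.
    """
    logv = np.log2(table.values + pseudocount)
    cols = {d: table.columns(d, stage) for d in DOMAINS}
    out = np.ones(len(table.genes))
    for i in range(len(table.genes)):
        groups = [logv[i, cols[d]] for d in DOMAINS]
        with np.errstate(invalid="ignore"):
            p = stats.f_oneway(*groups).pvalue
        out[i] = 1.0 if np.isnan(p) else float(p)
    return out


def quartet_targets(
    target_sets: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Organ target sets as intersections of quartet-member target sets."""
    out = {}
    for organ, members in QUARTET_COMPLEXES.items():
        missing = sorted(m for m in members if m not in target_sets)
        if missing:
            raise KeyError(
                f"missing target sets for {organ} complex members: {missing}"
            )
        sets = [target_sets[m] for m in sorted(members)]
        out[organ] = set.intersection(*sets)
    return out


@dataclass(frozen=True)
class BoundFractionResult:
    n_called: int
    n_bound: int
    fraction: float
    enrichment_p: float


def bound_fraction(
    calls: Iterable[DomainCall],
    target_sets: Mapping[str, set[str]],
    universe: set[str],
    min_tfs: int = 2,
) -> BoundFractionResult:
    """Fraction of domain-specific genes bound by >= ``min_tfs`` TFs.

    Also reports a hypergeometric p for the enrichment of multi-TF-bound
    genes among the called genes relative to the universe.
    """
    called = {c.gene_id for c in calls if c.category != "none"}
    if not called:
        raise ValueError("no domain-specific genes called")
    n_bound_by: dict[str, int] = {}
    for tf, targets in target_sets.items():
        for g in targets:
            n_bound_by[g] = n_bound_by.get(g, 0) + 1
    multibound = {g for g, n in n_bound_by.items() if n >= min_tfs} & universe
    hit = called & multibound
    p = hypergeometric_coregulation(called & universe, multibound, universe)
    return BoundFractionResult(
        n_called=len(called),
        n_bound=len(hit),
        fraction=len(hit) / len(called),
        enrichment_p=p,
    )
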