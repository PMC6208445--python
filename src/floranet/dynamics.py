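"""Stage-series expression statistics and binding-degree analyses.

Differential expression over the stage series is called with a simple,
self-contained surrogate: a gene is DE when its maximum absolute log2
fold change between any two stage means is >= 1 (two-fold) and a one-way
ANOVA across stages passes a Benjamini-Hochberg FDR of 0.05.  Externally
computed DE labels can be supplied instead and then take precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable
from .targets import TargetAssignment, hypergeometric_coregulation


@dataclass(frozen=True)
class StageProfile:
    gene_id: str
    stage_means: tuple[float, ...]
    max_abs_log2fc: float
    de_flag: bool
    de_fdr: float


def max_abs_log2fc(means: Sequence[float], pseudocount: float = 1.0) -> float:
    """Largest |log2 ratio| between any two pseudocounted stage means."""
    m = np.asarray(means, dtype=float) + pseudocount
    if np.any(m <= 0):
        raise ValueError("stage means + pseudocount must be positive")
    logs = np.log2(m)
    return float(logs.max() - logs.min())


def stage_profiles(
    expr: ExpressionTable,
    pseudocount: float = 1.0,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[StageProfile]:
    """Per-gene stage means, max |log2 FC|, and DE flag.

    With >= 2 replicates per stage the DE flag combines the fold-change
    filter with a per-gene one-way ANOVA across stages (on log2 of
    pseudocounted values) corrected by Benjamini-Hochberg across genes.
    With single replicates only the fold-change filter applies (warned).
    """
    stages = expr.stages
    if len(stages) < 2:
        raise ValueError("need at least two stages for stage profiles")
    cols = {s: expr.stage_columns(s) for s in stages}
    have_reps = all(len(c) >= 2 for c in cols.values())
    if not have_reps:
        warnings.warn(
            "single replicate in at least one stage: DE called on fold "
            "change only",
            stacklevel=2,
        )

    means = expr.stage_means().values  # genes x stages
    fcs = np.array(
        [max_abs_log2fc(means[i], pseudocount) for i in range(len(expr.genes))]
    )

    if have_reps:
        logv = np.log2(expr.values + pseudocount)
        pvals = np.ones(len(expr.genes))
        for i in range(len(expr.genes)):
            groups = [logv[i, cols[s]] for s in stages]
            if all(np.ptp(g) == 0 for g in groups) and len(
                {g[0] for g in groups}
            ) == 1:
                pvals[i] = 1.0  # completely constant gene
                continue
            with np.errstate(invalid="ignore"):
                pvals[i] = stats.f_oneway(*groups).pvalue
        pvals = np.nan_to_num(pvals, nan=1.0)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        de = (fcs >= fc_threshold) & (fdr < fdr_threshold)
    else:
        fdr = np.ones(len(expr.genes))
        de = fcs >= fc_threshold

    return [
        StageProfile(
            gene_id=g,
            stage_means=tuple(means[i]),
            max_abs_log2fc=float(fcs[i]),
            de_flag=bool(de[i]),
            de_fdr=float(fdr[i]),
        )
        for i, g in enumerate(expr.genes)
    ]


def overlap_de_targets(
    de_genes: set[str], target_genes: set[str], universe: set[str]
) -> float:
    """Hypergeometric p for the overlap of DE genes with TF targets."""
    return hypergeometric_coregulation(de_genes, target_genes, universe)


def mannwhitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p.

    Exact U distribution for small tie-free samples, otherwise the normal
    approximation with tie correction (scipy's automatic switch).
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def degree_vs_dynamics(
    assignments: Iterable[TargetAssignment],
    profiles: Sequence[StageProfile],
    bins: Sequence[int] = (1, 2, 3, 4, 5),
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Expression dynamics as a function of the number of bound TFs.

    Genes are grouped by the number of distinct TFs bound (the last bin is
    open-ended, "k+"); each group's median max |log2 FC| is reported with
    a two-sided Mann-Whitney p against the previous group.
    """
    bins = sorted(bins)
    if not bins:
        raise ValueError("empty degree grouping")
    degree: dict[str, set[str]] = {}
    for a in assignments:
        degree.setdefault(a.gene_id, set()).add(a.tf)
    fc_by_gene = {p.gene_id: p.max_abs_log2fc for p in profiles}

    groups: dict[int, list[float]] = {b: [] for b in bins}
    for gene, tfs in degree.items():
        if gene not in fc_by_gene:
            continue
        d = len(tfs)
        # snap to largest bin <= d (last bin open-ended)
        eligible = [b for b in bins if b <= d]
        if not eligible:
            continue
        key = bins[-1] if d >= bins[-1] else max(eligible)
        groups[key].append(fc_by_gene[gene])

    rows = []
    prev: list[float] | None = None
    for i, b in enumerate(bins):
        vals = groups[b]
        label = f"{b}+" if i == len(bins) - 1 else str(b)
        testable = (
            prev is not None
            and len(vals) >= min_group_size
            and len(prev) >= min_group_size
        )
        p = mannwhitney_two_sided(prev, vals) if testable else np.nan
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "median_max_abs_log2fc": float(np.median(vals)) if vals else np.nan,
                "mw_p_vs_previous": p,
                "testable": bool(testable),
            }
        )
        prev = vals
    return pd.DataFrame(rows)


def _bipartite_swap(
    edges: list[tuple[str, str]], rng: np.random.Generator, n_factor: float = 10.0
) -> list[tuple[str, str]]:
    """Degree-preserving double-edge swaps on a bipartite TF->gene edge list."""
    edges = list(edges)
    present = set(edges)
    n_attempts = int(np.ceil(n_factor * len(edges)))
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if (a, d) in present or (c, b) in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add((a, d))
        present.add((c, b))
        edges[i], edges[j] = (a, d), (c, b)
    return edges


def hub_degree_null(
    assignments: Iterable[TargetAssignment],
    n_random: int = 100,
    seed: int | None = None,
    method: str = "resample",
) -> pd.DataFrame:
    """Observed regulators-per-gene distribution vs a randomized null.

    ``method="resample"`` (default) keeps every TF's out-degree and the
    gene universe but redraws each TF's targets uniformly, so gene
    in-degrees follow the random-attachment expectation — the comparison
    that makes hub genes (bound by many TFs) stand out.  ``method="swap"``
    uses double-edge swaps preserving both degree sequences; under that
    null the per-in-degree histogram is invariant by construction, so it
    serves as a structural control (null identical to observed).
    Returns one row per in-degree with the observed gene count and the
    null mean and standard deviation.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if method not in ("resample", "swap"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    edges = sorted({(a.tf, a.gene_id) for a in assignments})
    genes_universe = sorted({g for _, g in edges})
    out_degree: dict[str, int] = {}
    for tf, _ in edges:
        out_degree[tf] = out_degree.get(tf, 0) + 1

    def counts(edge_list: list[tuple[str, str]]) -> dict[int, int]:
        indeg: dict[str, int] = {}
        for _, g in edge_list:
            indeg[g] = indeg.get(g, 0) + 1
        out: dict[int, int] = {}
        for d in indeg.values():
            out[d] = out.get(d, 0) + 1
        return out

    observed = counts(edges)
    max_d = max(observed) if observed else 0
    samples = []
    for _ in range(n_random):
        if method == "swap":
            shuffled = _bipartite_swap(edges, rng)
        else:
            shuffled = []
            for tf, k in out_degree.items():
                picks = rng.choice(len(genes_universe), size=k, replace=False)
                shuffled.extend((tf, genes_universe[i]) for i in picks)
        c = counts(shuffled)
        max_d = max(max_d, max(c, default=0))
        samples.append(c)
    null = np.zeros((n_random, max_d + 1))
    for r, c in enumerate(samples):
        for d, n in c.items():
            null[r, d] = n
    rows = []
    for d in range(1, max_d + 1):
        rows.append(
            {
                "degree": d,
                "observed": observed.get(d, 0),
                "null_mean": float(null[:, d].mean()),
                "null_sd": float(null[:, d].std(ddof=1)) if n_random > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
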