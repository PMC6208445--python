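"""Peak-to-gene target assignment and TF co-binding statistics.

A gene is a target of a TF when a binding event lies within a window
(default 3 kb) of the gene's transcription start site.  The binding point
is the peak summit when reported, otherwise the interval midpoint; the
window bound is inclusive and symmetric around the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GeneRecord, PeakRecord

DEFAULT_WINDOW = 3000


@dataclass(frozen=True)
class TargetAssignment:
    """One (TF, stage, gene) binding call.

    ``distance`` is signed: negative means the binding point lies 5' of the
    TSS on the gene's strand.  ``score`` is the maximum peak score among
    the supporting peaks; ``distance`` the closest.
    """

    tf: str
    stage: str
    gene_id: str
    distance: int
    score: float


@dataclass(frozen=True)
class PairwiseOverlapStat:
    tf_a: str
    tf_b: str
    jaccard: float
    cobinding_p: float | None = None
    coregulation_p: float | None = None


def assign_targets(
    peaks: Iterable[PeakRecord],
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> list[TargetAssignment]:
    """Assign peaks to genes whose TSS lies within ``window`` bp.

    Returns one record per (tf, stage, gene): max score, min |distance|.
    Output order is deterministic (sorted by tf, stage, gene_id) and does
    not depend on peak input order.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    # genes sorted by TSS per chromosome for bisection
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_arrays: dict[str, np.ndarray] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.tss)
        tss_arrays[chrom] = np.array([g.tss for g in glist])

    best: dict[tuple[str, str, str], tuple[float, int]] = {}
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in by_chrom:
            continue
        ref = peak.reference_point
        tss = tss_arrays[chrom]
        lo = int(np.searchsorted(tss, ref - window, side="left"))
        hi = int(np.searchsorted(tss, ref + window, side="right"))
        for g in by_chrom[chrom][lo:hi]:
            offset = ref - g.tss
            if abs(offset) > window:
                continue
            # signed distance is strand-aware: negative = upstream of TSS
            distance = -offset if g.interval.strand == "-" else offset
            key = (peak.tf, peak.stage, g.gene_id)
            prev = best.get(key)
            if prev is None:
                best[key] = (peak.score, distance)
            else:
                score = max(prev[0], peak.score)
                dist = distance if abs(distance) < abs(prev[1]) else prev[1]
                best[key] = (score, dist)

    return [
        TargetAssignment(tf=k[0], stage=k[1], gene_id=k[2], distance=v[1], score=v[0])
        for k, v in sorted(best.items())
    ]


def classify_targets(
    assignments: Iterable[TargetAssignment],
    genes: Sequence[GeneRecord],
) -> dict[str, dict[str, int]]:
    """Per-TF counts of distinct target genes by class {TF, MIR, other}."""
    lookup = {g.gene_id: g for g in genes}
    targets: dict[str, set[str]] = {}
    for a in assignments:
        if a.gene_id not in lookup:
            raise KeyError(f"assigned gene {a.gene_id!r} absent from annotation")
        targets.setdefault(a.tf, set()).add(a.gene_id)
    counts: dict[str, dict[str, int]] = {}
    for tf, gene_ids in targets.items():
        c = {"TF": 0, "MIR": 0, "other": 0}
        for gid in gene_ids:
            g = lookup[gid]
            if g.gene_class == "miRNA_precursor":
                c["MIR"] += 1
            elif g.is_tf:
                c["TF"] += 1
            else:
                c["other"] += 1
        counts[tf] = c
    return counts


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = [list(ivs[0])]
        for start, end in ivs[1:]:
            if start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _covered_bp(merged: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for ivs in merged.values() for s, e in ivs)


def _intersect_bp(
    a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]
) -> int:
    total = 0
    for chrom in set(a) & set(b):
        ia, ib = a[chrom], b[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            lo = max(ia[i][0], ib[j][0])
            hi = min(ia[i][1], ib[j][1])
            if hi > lo:
                total += hi - lo
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
    return total


def jaccard_cobinding(
    peaks_a: Iterable[PeakRecord], peaks_b: Iterable[PeakRecord]
) -> float:
    """Base-pair Jaccard index between two TFs' merged peak sets.

    |intersection bp| / |union bp| after per-TF interval merging.
    """
    ma = _merge_intervals(
        (p.interval.chrom, p.interval.start, p.interval.end) for p in peaks_a
    )
    mb = _merge_intervals(
        (p.interval.chrom, p.interval.start, p.interval.end) for p in peaks_b
    )
    inter = _intersect_bp(ma, mb)
    union = _covered_bp(ma) + _covered_bp(mb) - inter
    if union == 0:
        raise ValueError("Jaccard undefined: both peak sets are empty")
    return inter / union


def hypergeometric_coregulation(
    targets_a: set[str], targets_b: set[str], universe: set[str]
) -> float:
    """One-sided over-representation p-value for target-set overlap.

    P(X >= k) for X ~ Hypergeom(N=|universe|, K=|targets_a|, n=|targets_b|)
    with k the observed overlap, i.e. the survival function at k-1.
    """
    if not targets_a <= universe or not targets_b <= universe:
        raise ValueError("target sets must be subsets of the universe")
    N, K, n = len(universe), len(targets_a), len(targets_b)
    k = len(targets_a & targets_b)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pairwise_overlap_stats(
    peaks_by_tf: Mapping[str, list[PeakRecord]],
    targets_by_tf: Mapping[str, set[str]],
    universe: set[str],
) -> list[PairwiseOverlapStat]:
    """All-pairs co-binding Jaccard and co-regulation hypergeometric tests."""
    tfs = sorted(set(peaks_by_tf) | set(targets_by_tf))
    out = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1 :]:
            jac = float("nan")
            if a in peaks_by_tf and b in peaks_by_tf:
                try:
                    jac = jaccard_cobinding(peaks_by_tf[a], peaks_by_tf[b])
                except ValueError:
                    pass
            coreg = None
            if a in targets_by_tf and b in targets_by_tf:
                coreg = hypergeometric_coregulation(
                    targets_by_tf[a], targets_by_tf[b], universe
                )
            out.append(
                PairwiseOverlapStat(tf_a=a, tf_b=b, jaccard=jac, coregulation_p=coreg)
            )
    return out


def assignments_to_frame(assignments: Iterable[TargetAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tf": a.tf,
                "stage": a.stage,
                "gene_id": a.gene_id,
                "distance": a.distance,
                "score": a.score,
            }
            for a in assignments
        ],
        columns=["tf", "stage", "gene_id", "distance", "score"],
    )


def frame_to_assignments(df) -> list[TargetAssignment]:
    return [
        TargetAssignment(
            tf=row.tf,
            stage=row.stage,
            gene_id=row.gene_id,
            distance=int(row.distance),
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]
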