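"""miRNA-mediated feed-forward loops: enumeration, coherence, dynamics.

A feed-forward loop (FFL) here is a triple (regulator, miRNA, target TF)
in which the master regulator binds both the miRNA locus and the miRNA's
target TF gene, while the miRNA silences that target.  The miRNA arm is
always repressive; the loop is *coherent* when the sign of the indirect
path (regulator -> miRNA -| target) agrees with the sign of the direct
regulator -> target arm, and *dynamic* when either the miRNA's expression
changes across stages or the regulator's binding level at either locus
does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import StageProfile
from .io import ExpressionTable
from .network import MetaNetwork
from .targets import TargetAssignment

SIGNS = ("+", "-", "unknown")


@dataclass(frozen=True)
class FFLRecord:
    regulator: str
    mirna: str
    target: str
    sign_rm: str = "unknown"  # regulator -> miRNA arm
    sign_rt: str = "unknown"  # regulator -> target arm
    coherence: str = "unknown"
    dynamic: bool = False
    evidence: str = "none"
    target_is_regulator: bool = False

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.regulator, self.mirna, self.target)


def find_ffls(network: MetaNetwork) -> list[FFLRecord]:
    """Enumerate all FFL triples, ordered lexicographically.

    A triple qualifies when binds edges regulator->miRNA and
    regulator->target and a silences edge miRNA->target all exist, with
    the target distinct from the regulator.
    """
    regulators = network.nodes_with_role("regulator")
    if not (regulators and network.nodes_with_role("miRNA")):
        raise ValueError("network lacks regulator or miRNA nodes")
    out = []
    for r in sorted(regulators):
        bound = network.successors(r, "binds")
        for m in sorted(bound):
            if "miRNA" not in network.roles(m):
                continue
            for t in sorted(network.successors(m, "silences")):
                if t in bound and t != r:
                    out.append(
                        FFLRecord(
                            regulator=r,
                            mirna=m,
                            target=t,
                            target_is_regulator="regulator" in network.roles(t),
                        )
                    )
    return out


def _corr_sign(x: Sequence[float], y: Sequence[float], min_abs_r: float) -> str:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return "unknown"
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) < min_abs_r:
        return "unknown"
    return "+" if r > 0 else "-"


def infer_edge_signs(
    ffls: Iterable[FFLRecord],
    expr: ExpressionTable,
    mirna_expr: ExpressionTable | None = None,
    min_abs_r: float = 0.5,
    sign_overrides: Mapping[tuple[str, str], str] | None = None,
) -> list[FFLRecord]:
    """Assign regulatory signs from stage-mean Pearson correlation.

    The sign of an arm is the sign of the correlation of the two genes'
    stage-mean profiles when |r| >= ``min_abs_r``, else unknown.  miRNA
    abundances may live in a separate table.  ``sign_overrides`` maps
    (source, target) to an explicit sign and wins over inference.
    """
    means = expr.stage_means()
    mirna_means = mirna_expr.stage_means() if mirna_expr is not None else means
    overrides = dict(sign_overrides or {})

    def profile(gene: str, table: pd.DataFrame) -> np.ndarray | None:
        if gene in table.index:
            return table.loc[gene].values
        return None

    out = []
    for ffl in ffls:
        sign_rm = overrides.get((ffl.regulator, ffl.mirna))
        if sign_rm is None:
            pr = profile(ffl.regulator, means)
            pm = profile(ffl.mirna, mirna_means)
            sign_rm = (
                _corr_sign(pr, pm, min_abs_r)
                if pr is not None and pm is not None and len(pr) >= 3
                else "unknown"
            )
        sign_rt = overrides.get((ffl.regulator, ffl.target))
        if sign_rt is None:
            pr = profile(ffl.regulator, means)
            pt = profile(ffl.target, means)
            sign_rt = (
                _corr_sign(pr, pt, min_abs_r)
                if pr is not None and pt is not None and len(pr) >= 3
                else "unknown"
            )
        out.append(replace(ffl, sign_rm=sign_rm, sign_rt=sign_rt))
    return out


def classify_coherence(ffl: FFLRecord) -> FFLRecord:
    """Coherent when the indirect path sign equals the direct arm sign.

    The miRNA arm is fixed repressive, so the indirect path sign is the
    opposite of sign_rm; any unknown arm leaves coherence unknown.
    """
    if ffl.sign_rm == "unknown" or ffl.sign_rt == "unknown":
        return replace(ffl, coherence="unknown")
    indirect = "-" if ffl.sign_rm == "+" else "+"
    coherence = "coherent" if indirect == ffl.sign_rt else "incoherent"
    return replace(ffl, coherence=coherence)


def classify_dynamic(
    ffl: FFLRecord,
    mirna_profiles: Mapping[str, StageProfile],
    binding_by_stage: Iterable[TargetAssignment] | pd.DataFrame,
    fc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> FFLRecord:
    """Flag a loop as developmentally dynamic.

    Dynamic when the loop's miRNA is differentially expressed across
    stages OR the regulator's binding score at the miRNA or target locus
    changes by >= ``fc_threshold`` log2 units between any two stages
    (pseudocounted).  The evidence field records which criterion fired.
    """
    if isinstance(binding_by_stage, pd.DataFrame):
        binding_df = binding_by_stage
    else:
        from .targets import assignments_to_frame

        binding_df = assignments_to_frame(binding_by_stage)

    mirna_de = False
    prof = mirna_profiles.get(ffl.mirna)
    if prof is not None:
        mirna_de = prof.de_flag

    binding_change = False
    loop_edges = binding_df[
        (binding_df["tf"] == ffl.regulator)
        & (binding_df["gene_id"].isin([ffl.mirna, ffl.target]))
    ]
    has_stage_data = len(loop_edges) > 0 and loop_edges["stage"].nunique() > 1
    for _, grp in loop_edges.groupby("gene_id"):
        scores = grp["score"].values + pseudocount
        if len(scores) > 1:
            fc = np.log2(scores.max()) - np.log2(scores.min())
            if fc >= fc_threshold:
                binding_change = True
    if prof is None and not has_stage_data:
        warnings.warn(
            f"no stage-resolved data for loop {ffl.triple}; dynamic=False",
            stacklevel=2,
        )
    if mirna_de and binding_change:
        evidence = "both"
    elif mirna_de:
        evidence = "mirna_expression_change"
    elif binding_change:
        evidence = "binding_change"
    else:
        evidence = "none"
    return replace(ffl, dynamic=mirna_de or binding_change, evidence=evidence)


def annotate_ffls(
    network: MetaNetwork,
    expr: ExpressionTable,
    mirna_expr: ExpressionTable | None,
    mirna_profiles: Mapping[str, StageProfile],
    binding_by_stage: pd.DataFrame,
    min_abs_r: float = 0.5,
    fc_threshold: float = 1.0,
) -> list[FFLRecord]:
    """End-to-end: enumerate, sign, classify coherence and dynamics."""
    ffls = find_ffls(network)
    ffls = infer_edge_signs(ffls, expr, mirna_expr, min_abs_r)
    ffls = [classify_coherence(f) for f in ffls]
    return [
        classify_dynamic(f, mirna_profiles, binding_by_stage, fc_threshold)
        for f in ffls
    ]


def ffls_to_frame(ffls: Iterable[FFLRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": f.regulator,
                "mirna": f.mirna,
                "target": f.target,
                "sign_rm": f.sign_rm,
                "sign_rt": f.sign_rt,
                "coherence": f.coherence,
                "dynamic": f.dynamic,
                "evidence": f.evidence,
                "target_is_regulator": f.target_is_regulator,
            }
            for f in ffls
        ],
        columns=[
            "regulator", "mirna", "target", "sign_rm", "sign_rt",
            "coherence", "dynamic", "evidence", "target_is_regulator",
        ],
    )
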