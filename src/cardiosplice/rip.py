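"""RIP pull-down enrichment and intersection with splicing calls.

Enrichment contrasts disease immunoprecipitation libraries against
control immunoprecipitation libraries on normalized counts: the fold
change of group means per feature, with a pooled-variance t-test.  A
feature is called bound when its fold change exceeds 1 at P below the
threshold.  Bound features are then intersected, at the gene level,
with differential-splicing calls to yield the bound-and-spliced set and
a per-chromosome summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from cardiosplice.de import normalize_counts, size_factors
from cardiosplice.psi import DeltaPsiRecord


@dataclass(frozen=True)
class RipRecord:
    feature_id: str  # gene or gene:part key
    fold_change: float
    t_stat: float
    p_value: float
    bound: bool


def rip_enrich(
    ip_case_counts: pd.DataFrame,
    ip_ctrl_counts: pd.DataFrame,
    p_threshold: float = 0.05,
    normalize: bool = True,
) -> list[RipRecord]:
    """Per-feature enrichment of case-IP over control-IP libraries.

    Both count frames are features x samples; features present on only
    one side are skipped.  With ``normalize`` (default) a joint
    median-of-ratios normalization across all IP libraries is applied
    first.  Records are sorted by fold change, descending.
    """
    if ip_case_counts.shape[1] < 2 or ip_ctrl_counts.shape[1] < 2:
        raise ValueError("need at least two IP libraries per side")
    shared = ip_case_counts.index.intersection(ip_ctrl_counts.index)
    case = ip_case_counts.loc[shared]
    ctrl = ip_ctrl_counts.loc[shared]
    if normalize:
        joint = pd.concat([case, ctrl], axis=1)
        joint = normalize_counts(joint, size_factors(joint))
        case = joint[ip_case_counts.columns]
        ctrl = joint[ip_ctrl_counts.columns]

    records = []
    for feat in shared:
        c = case.loc[feat].to_numpy(dtype=float)
        k = ctrl.loc[feat].to_numpy(dtype=float)
        mc, mk = c.mean(), k.mean()
        fc = (mc + 0.5) / (mk + 0.5) if (mc == 0 or mk == 0) else mc / mk
        if c.var(ddof=1) == 0.0 and k.var(ddof=1) == 0.0:
            t = 0.0 if mc == mk else math.copysign(math.inf, mc - mk)
            p = 1.0 if mc == mk else 0.0
        else:
            res = stats.ttest_ind(c, k, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        records.append(
            RipRecord(
                feature_id=str(feat),
                fold_change=float(fc),
                t_stat=t,
                p_value=p,
                bound=bool(p < p_threshold and fc > 1),
            )
        )
    records.sort(key=lambda r: r.fold_change, reverse=True)
    return records


def _gene_of(feature_id: str) -> str:
    return feature_id.split(":", 1)[0]


def bound_and_spliced(
    rip_records: Sequence[RipRecord],
    delta_psi_records: Sequence[DeltaPsiRecord],
    p_max: float = 0.05,
    gene_contigs: Mapping[str, str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Genes both bound in the pull-down and differentially spliced.

    A gene counts as bound when any of its features is bound (RIP P <
    p_max, fold change > 1) and as spliced when any of its parts has
    differential-PSI P < p_max.  Returns the intersection set and a
    per-chromosome count table (empty when no contig map is given).
    """
    if not rip_records or not delta_psi_records:
        raise ValueError("both evidence inputs must be non-empty")
    bound_genes = {
        _gene_of(r.feature_id)
        for r in rip_records
        if r.p_value < p_max and r.fold_change > 1
    }
    spliced_genes = {
        _gene_of(r.part_id) for r in delta_psi_records if r.p_value < p_max
    }
    rip_genes = {_gene_of(r.feature_id) for r in rip_records}
    psi_genes = {_gene_of(r.part_id) for r in delta_psi_records}
    if not rip_genes & psi_genes:
        raise ValueError("no gene id shared between RIP and splicing tables")
    both = bound_genes & spliced_genes

    if gene_contigs:
        counts: dict[str, int] = {}
        for g in both:
            contig = gene_contigs.get(g, "unknown")
            counts[contig] = counts.get(contig, 0) + 1
        summary = pd.DataFrame(
            sorted(counts.items()), columns=["contig", "n_genes"]
        )
    else:
        summary = pd.DataFrame(columns=["contig", "n_genes"])
    return both, summary


def rip_to_frame(records: Sequence[RipRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "fold_change": r.fold_change,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "bound": r.bound,
            }
            for r in records
        ]
    )
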