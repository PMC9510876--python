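"""Count normalization, differential expression and candidate nomination.

Libraries are made comparable by median-of-ratios size factors: each
sample's factor is the median, over genes expressed in every sample, of
the ratio of its count to the gene's geometric mean across samples.
Per-gene differential expression between disease and control uses the
pooled-variance (Student) two-sample t-test on normalized counts with a
raw two-sided P threshold; screen candidates are genes that are both
heart-enriched (HSS filter) and significantly regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cardiosplice.hss import HssRecord

FC_PSEUDOCOUNT = 0.5  # added to both group means when either mean is zero


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Only genes with a positive count in every sample enter the median.
    Raises if no gene qualifies (advice: densify or use a pseudo-reference).
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; median-of-ratios "
            "needs at least one — consider a pseudo-reference fallback"
        )
    sub = arr[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.exp(np.log(sub) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


@dataclass(frozen=True)
class DeRecord:
    gene_id: str
    mean_case: float
    mean_ctrl: float
    fold_change: float
    log2_fold_change: float
    t_stat: float
    p_value: float  # nan when pooled variance is zero
    direction: str  # "up" | "down" | "ns"
    degenerate: bool  # zero pooled variance; excluded from candidate calls


def _pooled_t(case: np.ndarray, ctrl: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(case, ctrl, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def de_ttest(
    norm_counts: pd.DataFrame,
    case_ids: Sequence[str],
    ctrl_ids: Sequence[str],
    p_threshold: float = 0.05,
    welch: bool = False,
) -> list[DeRecord]:
    """Student's t-test per gene on normalized counts, case vs control.

    Fold change is the ratio of normalized group means (case/control);
    a pseudocount of ``FC_PSEUDOCOUNT`` is added to both means when
    either is zero.  Genes with zero pooled variance get an undefined P
    and are flagged degenerate.
    """
    for sid in list(case_ids) + list(ctrl_ids):
        if sid not in norm_counts.columns:
            raise KeyError(f"sample {sid!r} not in count matrix")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least two samples per group")

    case = norm_counts[list(case_ids)].to_numpy(dtype=float)
    ctrl = norm_counts[list(ctrl_ids)].to_numpy(dtype=float)
    records = []
    for gene, c_row, k_row in zip(norm_counts.index, case, ctrl):
        mc, mk = float(c_row.mean()), float(k_row.mean())
        if mc == 0.0 or mk == 0.0:
            fc = (mc + FC_PSEUDOCOUNT) / (mk + FC_PSEUDOCOUNT)
        else:
            fc = mc / mk
        degenerate = c_row.var(ddof=1) == 0.0 and k_row.var(ddof=1) == 0.0
        if degenerate and mc == mk:
            t, p = 0.0, float("nan")
        elif degenerate:
            t, p = math.copysign(math.inf, mc - mk), float("nan")
        elif welch:
            res = stats.ttest_ind(c_row, k_row, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        else:
            t, p = _pooled_t(c_row, k_row)
        if degenerate or not (p < p_threshold):
            direction = "ns"
        else:
            direction = "up" if fc > 1 else "down"
        records.append(
            DeRecord(
                gene_id=str(gene),
                mean_case=mc,
                mean_ctrl=mk,
                fold_change=fc,
                log2_fold_change=math.log2(fc),
                t_stat=t,
                p_value=p,
                direction=direction,
                degenerate=degenerate,
            )
        )
    return records


@dataclass(frozen=True)
class CandidateRecord:
    gene_id: str
    hss: float
    fold_change: float
    p_value: float
    enriched: bool
    regulated: bool

    @property
    def verdict(self) -> bool:
        return self.enriched and self.regulated


def nominate_candidates(
    hss_records: Sequence[HssRecord],
    de_records: Sequence[DeRecord],
    hss_min: float = 3.0,
    p_max: float = 0.05,
) -> list[CandidateRecord]:
    """Join enrichment and regulation evidence into screen candidates.

    verdict = (HSS >= hss_min) and (P < p_max).  Output sorted by P then
    by |log2 fold change| descending; degenerate DE records never pass.
    """
    hss_by_gene = {r.gene_id: r for r in hss_records}
    joined = [d for d in de_records if d.gene_id in hss_by_gene]
    if not joined:
        unmatched = sorted(d.gene_id for d in de_records)[:10]
        raise ValueError(
            f"no gene id shared between HSS and DE tables; DE ids start {unmatched}"
        )
    out = []
    for d in joined:
        h = hss_by_gene[d.gene_id]
        regulated = (not d.degenerate) and bool(d.p_value < p_max)
        out.append(
            CandidateRecord(
                gene_id=d.gene_id,
                hss=h.hss,
                fold_change=d.fold_change,
                p_value=d.p_value,
                enriched=h.hss >= hss_min,
                regulated=regulated,
            )
        )
    out.sort(
        key=lambda c: (
            c.p_value if not math.isnan(c.p_value) else math.inf,
            -abs(math.log2(c.fold_change)),
        )
    )
    return out


def regulation_counts(candidates: Sequence[CandidateRecord]) -> dict[str, int]:
    """Count up- vs down-regulated genes among significant records."""
    up = sum(1 for c in candidates if c.regulated and c.fold_change > 1)
    down = sum(1 for c in candidates if c.regulated and c.fold_change < 1)
    return {"up": up, "down": down}


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the 2^-dCt method against a reference gene."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)
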