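"""Percent-spliced-in quantification and differential splicing.

For each exonic part, reads are split into inclusion evidence (coverage
assigned to the part, plus splice junctions abutting one of its
boundaries) and exclusion evidence (junctions whose intron spans the
whole part).  PSI is inclusion over total evidence; in the default
length-normalized mode inclusion is divided by the number of read
placements overlapping the part (part length + read length - 1) and
exclusion by the number of junction-spanning placements (read length -
1), so that parts of different lengths are comparable.  Differential
splicing between conditions is the pooled-variance t-test on per-sample
PSI values.  Retention indices summarize splice-product ratios of an
intron-retention region (largest, intron-containing isoform vs the
spliced middle and small products).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cardiosplice.annotation import ExonicPart

_SJ_STRAND = {0: ".", 1: "+", 2: "-"}


@dataclass(frozen=True)
class JunctionRecord:
    """One intron interval (0-based half-open) with a per-sample read count."""

    contig: str
    start: int
    end: int
    strand: str
    sample_id: str
    count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"junction start {self.start} >= end {self.end}")
        if self.count < 0:
            raise ValueError("junction count must be non-negative")


def read_junctions(path: str, dialect: str, sample_id: str = "sample") -> list[JunctionRecord]:
    """Read splice junctions from a BED6 intron file or an SJ tab file.

    ``bed6-intron``: chrom, start, end, name, score(=read count), strand,
    already 0-based half-open.  ``sj-tab``: contig, 1-based inclusive
    intron start and end, strand code (0 unstranded / 1 + / 2 -), then
    the unique-read count in column 7 (intron motif and annotation flags
    in columns 5-6 are ignored).
    """
    if dialect not in {"bed6-intron", "sj-tab"}:
        raise ValueError(f"unknown junction dialect {dialect!r}")
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed6-intron":
                    contig, start, end, _name, score, strand = fields[:6]
                    rec = JunctionRecord(
                        contig, int(start), int(end), strand, sample_id, int(score)
                    )
                else:
                    contig = fields[0]
                    start = int(fields[1]) - 1  # 1-based inclusive -> half-open
                    end = int(fields[2])
                    strand = _SJ_STRAND[int(fields[3])]
                    count = int(fields[6])
                    rec = JunctionRecord(contig, start, end, strand, sample_id, count)
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed junction line ({exc})") from exc
            records.append(rec)
    return records


def junctions_to_frame(records: Iterable[JunctionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "sample_id": r.sample_id,
                "count": r.count,
            }
            for r in records
        ],
        columns=["contig", "start", "end", "strand", "sample_id", "count"],
    )


@dataclass(frozen=True)
class PsiRecord:
    part_id: str
    sample_id: str
    inclusion_raw: float
    exclusion_raw: float
    inclusion_norm: float
    exclusion_norm: float
    psi: float  # nan when no evidence

    @property
    def defined(self) -> bool:
        return not math.isnan(self.psi)


def compute_psi(
    parts: Sequence[ExonicPart],
    junctions: pd.DataFrame,
    part_coverage: pd.DataFrame,
    read_length: int = 100,
    mode: str = "length-normalized",
) -> list[PsiRecord]:
    """PSI per part per sample from junction and coverage evidence.

    Parameters
    ----------
    parts
        Flattened exonic parts.
    junctions
        Frame with columns contig, start, end, strand, sample_id, count
        (introns, 0-based half-open).
    part_coverage
        Parts (index = part_id) x samples matrix of reads assigned to
        each part.
    read_length
        Library read length; used only by the normalized mode.
    mode
        ``length-normalized`` (default) or ``raw``.

    A junction is exclusion evidence for a part when its intron spans
    the whole part (boundary coincidence included, so the splice
    junction of a retained intron counts as exclusion); a junction
    ending at the part's start or starting at its end is inclusion
    support.  Junctions on contigs absent from the parts are skipped.
    """
    if mode not in {"raw", "length-normalized"}:
        raise ValueError(f"unknown PSI mode {mode!r}")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if mode == "length-normalized" and read_length <= 1:
        raise ValueError("length-normalized mode needs read_length > 1")

    samples = list(part_coverage.columns)
    part_contigs = {p.contig for p in parts}
    jx = junctions[junctions["contig"].isin(part_contigs)]

    # index junctions per (contig, sample) for the containment/abut scan
    grouped: dict[tuple[str, str], pd.DataFrame] = {
        key: df for key, df in jx.groupby(["contig", "sample_id"])
    }

    records: list[PsiRecord] = []
    for part in parts:
        for sample in samples:
            cov = float(part_coverage.at[part.part_id, sample]) if part.part_id in part_coverage.index else 0.0
            df = grouped.get((part.contig, sample))
            inc_j = exc = 0.0
            if df is not None:
                s = df["start"].to_numpy()
                e = df["end"].to_numpy()
                c = df["count"].to_numpy(dtype=float)
                contains = (s <= part.start) & (e >= part.end)
                abuts = (e == part.start) | (s == part.end)
                exc = float(c[contains].sum())
                inc_j = float(c[abuts & ~contains].sum())
            inc = cov + inc_j
            if mode == "raw":
                inc_n, exc_n = inc, exc
            else:
                inc_n = inc / (part.length + read_length - 1)
                exc_n = exc / (read_length - 1)
            denom = inc_n + exc_n
            psi = inc_n / denom if denom > 0 else float("nan")
            records.append(
                PsiRecord(part.part_id, sample, inc, exc, inc_n, exc_n, psi)
            )
    return records


def psi_to_frame(records: Iterable[PsiRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "part_id": r.part_id,
                "sample_id": r.sample_id,
                "inclusion_raw": r.inclusion_raw,
                "exclusion_raw": r.exclusion_raw,
                "inclusion_norm": r.inclusion_norm,
                "exclusion_norm": r.exclusion_norm,
                "psi": r.psi,
            }
            for r in records
        ]
    )


@dataclass(frozen=True)
class DeltaPsiRecord:
    part_id: str
    mean_psi_case: float
    mean_psi_ctrl: float
    delta_psi: float
    t_stat: float
    p_value: float
    n_case: int
    n_ctrl: int


def delta_psi_test(
    psi_records: Sequence[PsiRecord],
    case_ids: Sequence[str],
    ctrl_ids: Sequence[str],
    min_defined: int | None = None,
) -> tuple[list[DeltaPsiRecord], dict[str, str]]:
    """Pooled-variance t-test of PSI between conditions, part by part.

    Undefined PSI values are dropped per sample; a part is tested only
    when each group retains at least ``min_defined`` values (default:
    every sample of the group).  Skipped parts are reported with a
    reason.  Results are sorted by gene id then part index.
    """
    by_part: dict[str, dict[str, float]] = {}
    for r in psi_records:
        by_part.setdefault(r.part_id, {})[r.sample_id] = r.psi

    results: list[DeltaPsiRecord] = []
    skipped: dict[str, str] = {}
    for part_id in sorted(by_part):
        vals = by_part[part_id]
        case = np.array([vals[s] for s in case_ids if s in vals and not math.isnan(vals[s])])
        ctrl = np.array([vals[s] for s in ctrl_ids if s in vals and not math.isnan(vals[s])])
        need_case = len(case_ids) if min_defined is None else min_defined
        need_ctrl = len(ctrl_ids) if min_defined is None else min_defined
        if len(case) < max(2, need_case) or len(ctrl) < max(2, need_ctrl):
            skipped[part_id] = (
                f"insufficient defined PSI values (case {len(case)}, ctrl {len(ctrl)})"
            )
            continue
        if case.var(ddof=1) == 0.0 and ctrl.var(ddof=1) == 0.0:
            if case.mean() == ctrl.mean():
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, case.mean() - ctrl.mean()), 0.0
        else:
            res = stats.ttest_ind(case, ctrl, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        results.append(
            DeltaPsiRecord(
                part_id=part_id,
                mean_psi_case=float(case.mean()),
                mean_psi_ctrl=float(ctrl.mean()),
                delta_psi=float(case.mean() - ctrl.mean()),
                t_stat=t,
                p_value=p,
                n_case=len(case),
                n_ctrl=len(ctrl),
            )
        )
    results.sort(key=lambda r: _part_sort_key(r.part_id))
    return results, skipped


def _part_sort_key(part_id: str) -> tuple[str, int]:
    gene, _, idx = part_id.rpartition(":")
    try:
        return gene, int(idx)
    except ValueError:
        return part_id, 0


def retention_index(
    large: float, middle: float, small: float
) -> tuple[float, float, float]:
    """Splice-product ratios for an intron-retention region.

    Returns (large/middle, large/small, large/(large+middle+small)); the
    last is the retention PSI, i.e., the fraction of product carrying
    the retained introns.  All-zero input yields NaNs.
    """
    if min(large, middle, small) < 0:
        raise ValueError("isoform counts must be non-negative")
    total = large + middle + small
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    r_lm = large / middle if middle > 0 else (math.inf if large > 0 else 0.0)
    r_ls = large / small if small > 0 else (math.inf if large > 0 else 0.0)
    return r_lm, r_ls, large / total


def spliced_set_overlap(
    set_a: Iterable[str], set_b: Iterable[str]
) -> dict[str, object]:
    """Set algebra of two differentially-spliced gene sets with counts."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return {
        "intersection": inter,
        "only_a": a - b,
        "only_b": b - a,
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
    }
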