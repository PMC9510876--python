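"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes an operation's expected output from first
principles (per-base labelling, exhaustive k-mer checks, the textbook
t formula) without touching the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from cardiosplice.annotation import TranscriptModel


def flatten_by_base(transcripts) -> list[tuple[int, int, frozenset[str]]]:
    """Label every base with its supporting transcript set and merge
    maximal runs of equal support."""
    lo = min(s for t in transcripts for s, _ in t.exons)
    hi = max(e for t in transcripts for _, e in t.exons)
    support = []
    for pos in range(lo, hi):
        cover = frozenset(
            t.transcript_id
            for t in transcripts
            if any(s <= pos < e for s, e in t.exons)
        )
        support.append(cover)
    runs: list[tuple[int, int, frozenset[str]]] = []
    for i, cover in enumerate(support):
        pos = lo + i
        if not cover:
            continue
        if runs and runs[-1][1] == pos and runs[-1][2] == cover:
            runs[-1] = (runs[-1][0], pos + 1, cover)
        else:
            runs.append((pos, pos + 1, cover))
    return runs


def random_gene(
    rng: np.random.Generator,
    gene_id: str,
    max_transcripts: int = 5,
    max_exons: int = 8,
) -> list[TranscriptModel]:
    """A random small gene; within a transcript, exons are separated by
    introns of length >= 1."""
    n_tx = int(rng.integers(1, max_transcripts + 1))
    strand = str(rng.choice(["+", "-"]))
    transcripts = []
    for t in range(n_tx):
        n_ex = int(rng.integers(1, max_exons + 1))
        pos = int(rng.integers(0, 20))
        exons = []
        for _ in range(n_ex):
            start = pos
            end = start + int(rng.integers(1, 30))
            exons.append((start, end))
            pos = end + int(rng.integers(1, 20))  # intron length >= 1
        transcripts.append(
            TranscriptModel(gene_id, f"{gene_id}_T{t}", "chr1", strand, tuple(exons))
        )
    return transcripts


def pooled_t_by_hand(case, ctrl) -> tuple[float, float]:
    """Student's two-sample t from the definition, P from the t CDF."""
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    n1, n2 = len(case), len(ctrl)
    sp2 = ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / (n1 + n2 - 2)
    t = (case.mean() - ctrl.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def scan_uwaa_by_brute_force(sequence: str) -> list[int]:
    """Check every 4-mer of the T->U-mapped sequence against the motif."""
    rna = sequence.upper().replace("T", "U")
    hits = []
    for i in range(len(rna) - 3):
        k = rna[i : i + 4]
        if k[0] == "U" and k[1] in "AU" and k[2] == "A" and k[3] == "A":
            hits.append(i)
    return hits
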