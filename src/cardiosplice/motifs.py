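"""UWAA motif scanning and motif-ablating mutagenesis.

STAR-family splicing regulators recognize short AU-rich elements of the
form U-W-A-A (W = A or U).  The scanner reports every, possibly
overlapping, 4-mer position matching the motif; occurrence summaries by
exon/intron region and a mutagenesis helper for minigene design (ablate
selected motifs, then prove by full rescan that no new motif arose)
complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

MOTIF_LENGTH = 4
_ALPHABET = set("ACGTUN")
_W = {"A", "U"}


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based
    matched: str  # the 4-mer as it appears in the input
    region: str  # exon/intron/... label, "unknown" without annotation


def _normalize(sequence: str) -> str:
    """Uppercase and map DNA T to RNA U; validate the alphabet."""
    up = sequence.upper()
    for i, ch in enumerate(up):
        if ch not in _ALPHABET:
            raise ValueError(f"invalid symbol {ch!r} at position {i}")
    return up.replace("T", "U")


def _is_uwaa(kmer: str) -> bool:
    return (
        len(kmer) == MOTIF_LENGTH
        and kmer[0] == "U"
        and kmer[1] in _W
        and kmer[2] == "A"
        and kmer[3] == "A"
    )


def scan_uwaa(
    sequence: str,
    regions: Sequence[tuple[int, int, str]] | None = None,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All (overlapping) UWAA matches in ascending position order.

    ``regions`` is an optional list of (start, end, label) intervals
    (0-based half-open); a hit is labelled by the region containing its
    start position.  N never matches.
    """
    rna = _normalize(sequence)
    hits = []
    for i in range(len(rna) - MOTIF_LENGTH + 1):
        if _is_uwaa(rna[i : i + MOTIF_LENGTH]):
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=i,
                    matched=sequence[i : i + MOTIF_LENGTH],
                    region=_region_label(i, regions),
                )
            )
    return hits


def _region_label(pos: int, regions: Sequence[tuple[int, int, str]] | None) -> str:
    if not regions:
        return "unknown"
    for start, end, label in regions:
        if start <= pos < end:
            return label
    return "unknown"


def motif_occurrence_by_region(
    hits: Iterable[MotifHit], regions: Sequence[tuple[int, int, str]]
) -> dict[str, int]:
    """Count hits per region label, assigning each hit by its start.

    Region intervals must not overlap; every label appears in the
    output even with zero hits.
    """
    ordered = sorted(regions)
    for (s1, e1, l1), (s2, _e2, l2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping regions {l1!r} and {l2!r}")
    counts = {label: 0 for _, _, label in regions}
    for hit in hits:
        label = _region_label(hit.start, regions)
        if label in counts:
            counts[label] += 1
        else:
            counts[label] = counts.get(label, 0) + 1
    return counts


_DEFAULT_SUBS = [("C", "G"), ("C", "C"), ("G", "C"), ("G", "G")]


def mutate_motifs(
    sequence: str,
    hit_subset: Sequence[int],
    scheme: str = "ca-cg",
) -> tuple[str, dict[str, object]]:
    """Ablate the UWAA motifs starting at the given positions.

    The default scheme replaces the two A's at motif positions 3-4 with
    C and G; if that substitution would create a new UWAA anywhere, the
    alternatives (C,C), (G,C), (G,G) are tried in order.  A full rescan
    verifies that the selected motifs are gone and that no new motif
    was created; the report carries the remaining hit positions.
    """
    if scheme != "ca-cg":
        raise ValueError(f"unknown mutation scheme {scheme!r}")
    rna = _normalize(sequence)
    is_dna = "T" in sequence.upper()
    original_hits = {h.start for h in scan_uwaa(sequence)}
    for pos in hit_subset:
        if pos not in original_hits:
            raise ValueError(f"no UWAA motif starts at position {pos}")

    allowed_after = original_hits - set(hit_subset)
    seq = list(rna)
    pending = sorted(hit_subset)
    for k, pos in enumerate(pending):
        not_yet_mutated = set(pending[k + 1 :])
        ok = False
        for a, b in _DEFAULT_SUBS:
            trial = seq.copy()
            trial[pos + 2], trial[pos + 3] = a, b
            new_hits = {h.start for h in scan_uwaa("".join(trial))}
            if new_hits <= allowed_after | not_yet_mutated:
                seq = trial
                ok = True
                break
        if not ok:
            raise ValueError(
                f"no substitution ablates the motif at {pos} without creating a new one"
            )

    mutated = "".join(seq)
    final_hits = {h.start for h in scan_uwaa(mutated)}
    if is_dna:
        mutated = mutated.replace("U", "T")
    report = {
        "mutated_positions": sorted(hit_subset),
        "remaining_hits": sorted(final_hits),
        "new_motifs_created": sorted(final_hits - allowed_after),
        "ablation_verified": not (final_hits - allowed_after)
        and not (final_hits & set(hit_subset)),
    }
    return mutated, report
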