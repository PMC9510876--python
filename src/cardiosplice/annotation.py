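"""Gene-model flattening into disjoint exonic parts.

Overlapping transcripts of a gene are segmented into *exonic parts*:
maximal intervals supported by a constant set of transcripts.  Parts are
the counting bins of all exon-level analyses (PSI, exon correlation);
a part supported by only a subset of a gene's transcripts is flagged
alternative.

Coordinates are 0-based half-open internally; GTF (1-based inclusive)
is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from gffutils.feature import feature_from_line

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: its gene, contig, strand and sorted exon intervals."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        exons = tuple(sorted(self.exons))
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"[{s1},{e1}) and starting at {s2}"
                )
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e}) in {self.transcript_id}")
        object.__setattr__(self, "exons", exons)


@dataclass(frozen=True)
class ExonicPart:
    """A disjoint counting bin of a flattened gene model."""

    gene_id: str
    part_index: int  # 1-based, ascending along the genome
    contig: str
    start: int
    end: int
    strand: str
    transcripts: frozenset[str]
    is_alternative: bool

    @property
    def part_id(self) -> str:
        """``geneID:NNN`` with the index zero-padded to three digits."""
        return f"{self.gene_id}:{self.part_index:03d}"

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon features of a GTF file into transcript models.

    Only ``exon`` features are used; they must carry ``gene_id`` and
    ``transcript_id`` attributes.  1-based inclusive coordinates become
    0-based half-open.  Returns transcripts grouped by gene, exons sorted.
    """
    exons: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise ValueError(f"{path}:{lineno}: exon without gene_id")
            if feat.strand not in _STRANDS:
                raise ValueError(
                    f"{path}:{lineno}: unknown strand symbol {feat.strand!r}"
                )
            key = (attrs["gene_id"][0], attrs["transcript_id"][0])
            rec = exons.setdefault(
                key, {"contig": feat.seqid, "strand": feat.strand, "ivals": []}
            )
            rec["ivals"].append((feat.start - 1, feat.end))

    models = []
    for (gene_id, tx_id), rec in exons.items():
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx_id,
                contig=rec["contig"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["ivals"])),
            )
        )
    models.sort(key=lambda t: (t.gene_id, t.transcript_id))
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str) -> None:
    """Serialize transcript models as GTF exon lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            for start, end in tx.exons:
                fh.write(
                    "\t".join(
                        [
                            tx.contig,
                            "cardiosplice",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";',
                        ]
                    )
                    + "\n"
                )


def flatten_gene(transcripts: Sequence[TranscriptModel]) -> list[ExonicPart]:
    """Segment one gene's overlapping transcripts into disjoint exonic parts.

    A boundary sweep over all exon end-points yields elementary intervals;
    each interval covered by at least one exon becomes a part supported by
    exactly the transcripts whose exons cover it.  Every exon boundary of
    every transcript therefore coincides with a part boundary, parts are
    pairwise disjoint and their union equals the union of the gene's exons.
    Part indices ascend with genomic coordinate regardless of strand.
    """
    if not transcripts:
        return []
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts from multiple genes: {sorted(gene_ids)}")
    contigs = {t.contig for t in transcripts}
    if len(contigs) > 1:
        raise ValueError(
            f"gene {next(iter(gene_ids))} has transcripts on mixed contigs: "
            f"{sorted(contigs)}"
        )
    strands = {t.strand for t in transcripts}
    if len(strands) > 1:
        raise ValueError(f"mixed strands within gene {next(iter(gene_ids))}")

    gene_id = transcripts[0].gene_id
    contig = transcripts[0].contig
    strand = transcripts[0].strand
    all_tx = frozenset(t.transcript_id for t in transcripts)

    boundaries = sorted({b for t in transcripts for s, e in t.exons for b in (s, e)})
    parts: list[ExonicPart] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        if lo == hi:  # zero-length intervals from shared boundaries are dropped
            continue
        support = frozenset(
            t.transcript_id
            for t in transcripts
            if any(s <= lo and hi <= e for s, e in t.exons)
        )
        if not support:
            continue
        parts.append(
            ExonicPart(
                gene_id=gene_id,
                part_index=len(parts) + 1,
                contig=contig,
                start=lo,
                end=hi,
                strand=strand,
                transcripts=support,
                is_alternative=support != all_tx,
            )
        )
    return parts


def flatten_all(transcripts: Iterable[TranscriptModel]) -> list[ExonicPart]:
    """Flatten every gene independently; genes are never merged."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    parts: list[ExonicPart] = []
    for gene_id in sorted(by_gene):
        parts.extend(flatten_gene(by_gene[gene_id]))
    return parts


def parts_by_id(parts: Iterable[ExonicPart]) -> dict[str, ExonicPart]:
    return {p.part_id: p for p in parts}
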