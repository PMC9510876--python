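"""Readers and writers for the pipeline's tabular and sequence formats.

All result tables are TSV with an optional commented header (``# key=value``
lines) recording tool version, seed and thresholds; ``read_table`` skips
those lines, so write followed by read is the identity on the table.
Junctions are emitted as BED6 (0-based half-open intron, score = read
count) or SJ tab (1-based inclusive, strand code); sequences as FASTA
via Biopython.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from cardiosplice.annotation import ExonicPart

_SJ_CODE = {".": 0, "+": 1, "-": 2}


def write_table(
    frame: pd.DataFrame,
    path: str,
    meta: Mapping[str, object] | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_table(path: str, index_col: int | str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_table_meta(path: str) -> dict[str, str]:
    """The ``# key=value`` header of a result table."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_junctions_bed(junctions: pd.DataFrame, path: str) -> None:
    """BED6: one line per junction row, score = read count."""
    cols = ["contig", "start", "end", "strand", "count"]
    with open(path, "w") as fh:
        for i, (contig, start, end, strand, count) in enumerate(
            zip(*(junctions[c] for c in cols))
        ):
            fh.write(f"{contig}\t{start}\t{end}\tJ{i}\t{count}\t{strand}\n")


def write_junctions_sj(junctions: pd.DataFrame, path: str) -> None:
    """SJ tab: contig, 1-based inclusive start/end, strand code, motif 0,
    annotation 0, unique reads, multi-mapped 0, overhang 0."""
    cols = ["contig", "start", "end", "strand", "count"]
    with open(path, "w") as fh:
        for contig, start, end, strand, count in zip(*(junctions[c] for c in cols)):
            code = _SJ_CODE[strand]
            fh.write(f"{contig}\t{start + 1}\t{end}\t{code}\t0\t0\t{count}\t0\t0\n")


def write_parts_table(parts: Iterable[ExonicPart], path: str) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "part_id": p.part_id,
                "contig": p.contig,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "transcripts": "+".join(sorted(p.transcripts)),
                "is_alternative": p.is_alternative,
            }
            for p in parts
        ]
    )
    write_table(frame, path)


def write_parts_bed(parts: Iterable[ExonicPart], path: str) -> None:
    with open(path, "w") as fh:
        for p in parts:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.part_id}\t0\t{p.strand}\n")


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_regions_bed(path: str) -> list[tuple[int, int, str]]:
    """Region annotation BED (start, end, label) for motif summaries."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                start, end = int(fields[1]), int(fields[2])
                label = fields[3] if len(fields) > 3 else f"region_{lineno}"
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            regions.append((start, end, label))
    return regions
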