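"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of real input at study scale — a
53-tissue RPKM matrix with heart-enriched genes, two-condition exonic
part/junction counts with planted PSI shifts and retained introns, RIP
pull-down counts with planted binding enrichment, and intronic
sequences with planted UWAA motifs — and returns alongside it a
``SimTruth`` record of the planted parameters, so downstream stages are
testable by parameter recovery.

Noise models (the real studies start from sequencing data, so these
are the standard choices for count data): log-normal tissue abundances,
Poisson totals with a Binomial inclusion/exclusion split for splicing
evidence (optionally Gamma-Poisson overdispersed totals), and Poisson
RIP library counts.  All draws come from one ``numpy`` generator
seeded from the single config seed; identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cardiosplice.annotation import ExonicPart, TranscriptModel, flatten_all

#: the multi-tissue panel emulated by the tissue generator
N_TISSUES_DEFAULT = 53
HEART_LABEL_DEFAULT = "heart_left_ventricle"


def default_tissue_names(n: int = N_TISSUES_DEFAULT) -> list[str]:
    """A heart label, an atrial-appendage label, and generic others."""
    names = [HEART_LABEL_DEFAULT, "heart_atrial_appendage"]
    names += [f"tissue_{i:02d}" for i in range(n - 2)]
    return names[:n]


@dataclass(frozen=True)
class SimTruth:
    """Planted parameters of a simulation, keyed by feature id."""

    seed: int
    planted: Mapping[str, object]
    extras: Mapping[str, object] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": list(self.planted), "value": [repr(v) for v in self.planted.values()]}
        )


# ---------------------------------------------------------------------------
# multi-tissue expression


@dataclass(frozen=True)
class TissueSimConfig:
    n_genes: int
    tissue_names: Sequence[str] = field(default_factory=default_tissue_names)
    heart_label: str = HEART_LABEL_DEFAULT
    baseline_log_mean: float = math.log(5.0)  # background around 5 RPKM
    baseline_log_sd: float = 1.0
    planted_enriched: Sequence[tuple[str, float]] = ()
    atrial_label: str | None = "heart_atrial_appendage"
    atrial_factor_scale: float = 1.0  # planted atrial enrichment = factor * scale
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.heart_label not in self.tissue_names:
            raise ValueError(f"heart label {self.heart_label!r} not among tissues")
        if len(set(self.tissue_names)) != len(self.tissue_names):
            raise ValueError("duplicate tissue names")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(f <= 0 for _, f in self.planted_enriched):
            raise ValueError("enrichment factors must be > 0")
        if len(self.planted_enriched) > self.n_genes:
            raise ValueError("more planted genes than genes")
        ids = [g for g, _ in self.planted_enriched]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate planted gene ids: {sorted(ids)}")


def simulate_tissue_matrix(config: TissueSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Genes x tissues RPKM-like matrix with planted heart enrichment.

    Background: per-gene log-normal baseline shared by all tissues,
    multiplied by per-cell log-normal noise of sd ``noise_sd``.  For a
    planted gene the heart column (and, when configured, the atrial
    column) is multiplied by the enrichment factor.
    """
    rng = np.random.default_rng(config.seed)
    tissues = list(config.tissue_names)
    planted = dict(config.planted_enriched)
    gene_ids = [f"gene_{i:04d}" for i in range(config.n_genes)]
    # planted ids may name arbitrary genes; unknown ids extend the panel check
    unknown = [g for g in planted if g not in gene_ids]
    if unknown:
        # replace trailing generic ids with the requested ones
        for i, g in enumerate(unknown):
            gene_ids[config.n_genes - len(unknown) + i] = g

    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    )
    noise = (
        np.exp(rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(tissues))))
        if config.noise_sd > 0
        else np.ones((config.n_genes, len(tissues)))
    )
    matrix = baseline[:, None] * noise
    heart_col = tissues.index(config.heart_label)
    atrial_col = (
        tissues.index(config.atrial_label)
        if config.atrial_label and config.atrial_label in tissues
        else None
    )
    for gid, factor in planted.items():
        row = gene_ids.index(gid)
        matrix[row, heart_col] *= factor
        if atrial_col is not None:
            matrix[row, atrial_col] *= factor * config.atrial_factor_scale

    frame = pd.DataFrame(matrix, index=gene_ids, columns=tissues)
    truth = SimTruth(
        seed=config.seed,
        planted={g: f for g, f in planted.items()},
        extras={"heart_label": config.heart_label},
    )
    return frame, truth


# ---------------------------------------------------------------------------
# two-condition splicing counts


@dataclass(frozen=True)
class PlantedSplice:
    part_id: str
    psi_ctrl: float
    delta_psi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi_ctrl <= 1.0:
            raise ValueError("psi_ctrl must lie in [0, 1]")
        if not 0.0 <= self.psi_ctrl + self.delta_psi <= 1.0:
            raise ValueError("psi_ctrl + delta_psi must lie in [0, 1]")


@dataclass(frozen=True)
class SpliceSimConfig:
    transcripts: Sequence[TranscriptModel]
    n_case: int = 4
    n_ctrl: int = 4
    read_length: int = 100
    depth_per_event: float = 100.0
    planted_events: Sequence[PlantedSplice] = ()
    dispersion: float = 0.0  # Gamma-Poisson overdispersion of event totals
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_ctrl < 2:
            raise ValueError("need at least two samples per condition")
        if self.depth_per_event <= 0:
            raise ValueError("depth_per_event must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def cassette_gene(
    gene_id: str,
    contig: str = "chr1",
    strand: str = "+",
    offset: int = 0,
    exon_length: int = 100,
    intron_length: int = 200,
) -> list[TranscriptModel]:
    """A three-exon gene whose middle exon is skipped by one isoform."""
    e = exon_length
    i = intron_length
    a = (offset, offset + e)
    b = (offset + e + i, offset + 2 * e + i)
    c = (offset + 2 * e + 2 * i, offset + 3 * e + 2 * i)
    t_inc = TranscriptModel(gene_id, f"{gene_id}_T1", contig, strand, (a, b, c))
    t_skip = TranscriptModel(gene_id, f"{gene_id}_T2", contig, strand, (a, c))
    return [t_inc, t_skip]


def retention_gene(
    gene_id: str,
    contig: str = "chr1",
    strand: str = "+",
    offset: int = 0,
    exon_length: int = 100,
    intron_length: int = 200,
) -> list[TranscriptModel]:
    """A two-exon gene with an isoform retaining the intervening intron."""
    e = exon_length
    i = intron_length
    a = (offset, offset + e)
    b = (offset + e + i, offset + 2 * e + i)
    t_spliced = TranscriptModel(gene_id, f"{gene_id}_T1", contig, strand, (a, b))
    t_retained = TranscriptModel(
        gene_id, f"{gene_id}_T2", contig, strand, ((offset, offset + 2 * e + i),)
    )
    return [t_spliced, t_retained]


@dataclass(frozen=True)
class AnnotationBundle:
    transcripts: tuple[TranscriptModel, ...]
    parts: tuple[ExonicPart, ...]


def _nb_total(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Poisson totals, Gamma-mixed when dispersion > 0 (variance m + d m^2)."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def simulate_splice_counts(
    config: SpliceSimConfig,
) -> tuple[AnnotationBundle, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Per-condition junction and part-coverage counts with planted PSI.

    For each planted part and sample the number of informative splicing
    events is Poisson(depth); inclusion events are Binomial(n, psi) and
    the remainder are exclusion events, recorded as reads on the
    junction spanning the part (the intron between its flanking parts).
    Inclusion events are recorded as coverage on the part.  Unplanted
    parts receive constitutive coverage (psi 1, no skipping junction).

    Returns (annotation bundle, junction table, part-coverage table,
    truth).  Junction table columns: contig, start, end, strand,
    sample_id, count.  Coverage table: parts x samples.  Sample ids are
    ``case_0..``/``ctrl_0..``; truth stores psi per planted part per
    condition plus sample-condition assignments.
    """
    rng = np.random.default_rng(config.seed)
    parts = flatten_all(config.transcripts)
    by_id = {p.part_id: p for p in parts}
    by_gene: dict[str, list[ExonicPart]] = {}
    for p in parts:
        by_gene.setdefault(p.gene_id, []).append(p)

    planted = {e.part_id: e for e in config.planted_events}
    for pid in planted:
        if pid not in by_id:
            raise ValueError(
                f"planted part {pid!r} not derivable from the annotation; "
                f"available: {sorted(by_id)[:5]}..."
            )

    def skip_junction(part: ExonicPart) -> tuple[int, int]:
        """Intron between the planted part's flanking parts."""
        siblings = by_gene[part.gene_id]
        idx = next(i for i, q in enumerate(siblings) if q.part_id == part.part_id)
        if idx == 0 or idx == len(siblings) - 1:
            raise ValueError(
                f"planted part {part.part_id} has no flanking parts for a skip junction"
            )
        return siblings[idx - 1].end, siblings[idx + 1].start

    samples = [f"case_{i}" for i in range(config.n_case)] + [
        f"ctrl_{i}" for i in range(config.n_ctrl)
    ]
    conditions = ["case"] * config.n_case + ["ctrl"] * config.n_ctrl

    coverage = pd.DataFrame(
        0, index=[p.part_id for p in parts], columns=samples, dtype=int
    )
    junction_rows: list[dict] = []
    truth_planted: dict[str, object] = {}

    for part in parts:
        event = planted.get(part.part_id)
        if event is not None:
            js, je = skip_junction(part)
            truth_planted[part.part_id] = {
                "psi_ctrl": event.psi_ctrl,
                "psi_case": event.psi_ctrl + event.delta_psi,
                "delta_psi": event.delta_psi,
            }
        for sample, condition in zip(samples, conditions):
            n = int(_nb_total(rng, config.depth_per_event, config.dispersion, 1)[0])
            if event is None:
                coverage.at[part.part_id, sample] = n
                continue
            psi = event.psi_ctrl + (event.delta_psi if condition == "case" else 0.0)
            inclusion = int(rng.binomial(n, psi)) if n > 0 else 0
            exclusion = n - inclusion
            coverage.at[part.part_id, sample] = inclusion
            # the skip junction row is emitted even at count 0 so every
            # sample shares the same junction grid
            junction_rows.append(
                {
                    "contig": part.contig,
                    "start": js,
                    "end": je,
                    "strand": part.strand,
                    "sample_id": sample,
                    "count": exclusion,
                }
            )

    junctions = pd.DataFrame(
        junction_rows, columns=["contig", "start", "end", "strand", "sample_id", "count"]
    )
    truth = SimTruth(
        seed=config.seed,
        planted=truth_planted,
        extras={
            "samples": dict(zip(samples, conditions)),
            "case_ids": samples[: config.n_case],
            "ctrl_ids": samples[config.n_case :],
        },
    )
    bundle = AnnotationBundle(tuple(config.transcripts), tuple(parts))
    return bundle, junctions, coverage, truth


# ---------------------------------------------------------------------------
# RIP pull-down counts


@dataclass(frozen=True)
class RipSimConfig:
    n_features: int
    planted_bound: Sequence[tuple[str, float]] = ()
    library_size: float = 1e5
    n_ip_case: int = 3
    n_ip_ctrl: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.library_size <= 0:
            raise ValueError("library sizes must be > 0")
        if any(f <= 0 for _, f in self.planted_bound):
            raise ValueError("enrichment factors must be > 0")
        if self.n_ip_case < 2 or self.n_ip_ctrl < 2:
            raise ValueError("need at least two IP libraries per side")


def simulate_rip_counts(
    config: RipSimConfig, feature_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """IP-case and IP-control count tables with planted binding enrichment.

    Every feature has the same base concentration; in the case
    libraries a planted feature's Poisson mean is multiplied by its
    enrichment factor.  Library sizes are equal by construction, so the
    expectation of the normalized fold change equals the factor.
    """
    rng = np.random.default_rng(config.seed)
    if feature_ids is None:
        feature_ids = [f"feat_{i:04d}" for i in range(config.n_features)]
    elif len(feature_ids) != config.n_features:
        raise ValueError("feature_ids length must equal n_features")
    feature_ids = list(feature_ids)
    planted = dict(config.planted_bound)
    unknown = set(planted) - set(feature_ids)
    if unknown:
        raise ValueError(f"planted features not in the feature panel: {sorted(unknown)}")

    base = config.library_size / config.n_features
    factors = np.array([planted.get(f, 1.0) for f in feature_ids])
    case = rng.poisson(
        base * factors[:, None], size=(config.n_features, config.n_ip_case)
    )
    ctrl = rng.poisson(base, size=(config.n_features, config.n_ip_ctrl))
    case_df = pd.DataFrame(
        case, index=feature_ids, columns=[f"ip_case_{i}" for i in range(config.n_ip_case)]
    )
    ctrl_df = pd.DataFrame(
        ctrl, index=feature_ids, columns=[f"ip_ctrl_{i}" for i in range(config.n_ip_ctrl)]
    )
    truth = SimTruth(seed=config.seed, planted=planted)
    return case_df, ctrl_df, truth


# ---------------------------------------------------------------------------
# motif-bearing sequences


def simulate_motif_sequence(
    length: int, planted_positions: Sequence[int], seed: int = 0
) -> tuple[str, SimTruth]:
    """RNA sequence with UWAA motifs at exactly the planted positions.

    The background is uniform over A/C/G/U; accidental UWAA matches are
    removed by rejection (a background base inside the offending 4-mer
    is resampled to C or G), so a scan recovers exactly the planted
    positions.  Planted positions must be >= 4 apart and in bounds.
    """
    positions = sorted(int(p) for p in planted_positions)
    for p, q in zip(positions, positions[1:]):
        if q - p < 4:
            raise ValueError(f"planted positions {p} and {q} overlap (< 4 apart)")
    if positions and (positions[0] < 0 or positions[-1] + 4 > length):
        raise ValueError("planted positions out of bounds")

    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGU"), size=length))
    planted_spans = set()
    for p in positions:
        w = rng.choice(["A", "U"])
        seq[p : p + 4] = ["U", w, "A", "A"]
        planted_spans.update(range(p, p + 4))

    from cardiosplice.motifs import scan_uwaa  # local import avoids a cycle

    wanted = set(positions)
    for _ in range(10 * length + 100):
        hits = {h.start for h in scan_uwaa("".join(seq))}
        spurious = hits - wanted
        if not spurious:
            break
        pos = min(spurious)
        # resample one background base inside the offending 4-mer
        editable = [i for i in range(pos, pos + 4) if i not in planted_spans]
        i = editable[int(rng.integers(len(editable)))]
        seq[i] = str(rng.choice(["C", "G"]))
    else:
        raise RuntimeError("rejection sampling failed to remove accidental motifs")

    truth = SimTruth(seed=seed, planted={f"pos_{p}": p for p in positions})
    return "".join(seq), truth
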