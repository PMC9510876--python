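"""End-to-end screen: enrichment x regulation, then splicing follow-up.

``run_screen`` chains the stages — heart-specificity scoring,
differential expression, candidate nomination, then (when the inputs
are present) PSI / differential splicing, RIP enrichment with the
bound-and-spliced intersection, and the per-exon correlation profile —
and writes one TSV per stage plus a run manifest.

``simulate_screen_inputs`` builds a coherent simulated study with one
planted heart-enriched, up-regulated splicing factor, a block of
planted bound-and-differentially-spliced genes, and one planted
retained intron, so the whole screen is checkable by recovery of the
planted truth.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from cardiosplice import __version__
from cardiosplice.correlation import CorrelationProfile, exon_factor_correlation, profile_to_frame
from cardiosplice.de import (
    CandidateRecord,
    de_ttest,
    nominate_candidates,
    normalize_counts,
    regulation_counts,
    size_factors,
)
from cardiosplice.hss import compute_hss, records_to_frame
from cardiosplice.io import write_table
from cardiosplice.psi import (
    DeltaPsiRecord,
    PsiRecord,
    compute_psi,
    delta_psi_test,
    psi_to_frame,
)
from cardiosplice.rip import RipRecord, bound_and_spliced, rip_enrich, rip_to_frame
from cardiosplice.simulate import (
    AnnotationBundle,
    PlantedSplice,
    RipSimConfig,
    SimTruth,
    SpliceSimConfig,
    TissueSimConfig,
    cassette_gene,
    retention_gene,
    simulate_rip_counts,
    simulate_splice_counts,
    simulate_tissue_matrix,
)

logger = logging.getLogger("cardiosplice")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    heart_label: str = "heart_left_ventricle"
    hss_threshold: float = 3.0
    de_p_threshold: float = 0.05
    psi_p_threshold: float = 0.05
    psi_mode: str = "raw"  # simulated counts are event-level; use
    # "length-normalized" for placement-level coverage
    read_length: int = 100
    hss_epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.de_p_threshold <= 1 or not 0 < self.psi_p_threshold <= 1:
            raise ValueError("P thresholds must lie in (0, 1]")
        if self.hss_threshold < 0:
            raise ValueError("hss threshold must be non-negative")


@dataclass
class ScreenInputs:
    tissue_matrix: pd.DataFrame  # genes x tissues
    de_counts: pd.DataFrame  # genes x samples (raw counts)
    case_ids: list[str]
    ctrl_ids: list[str]
    annotation: AnnotationBundle | None = None
    junctions: pd.DataFrame | None = None
    part_coverage: pd.DataFrame | None = None
    splice_case_ids: list[str] = field(default_factory=list)
    splice_ctrl_ids: list[str] = field(default_factory=list)
    rip_case_counts: pd.DataFrame | None = None
    rip_ctrl_counts: pd.DataFrame | None = None
    correlation_factor: str | None = None  # gene id to correlate against
    correlation_gene: str | None = None  # gene whose parts are profiled


@dataclass
class ScreenResult:
    hss: pd.DataFrame
    de: pd.DataFrame
    candidates: list[CandidateRecord]
    regulation: dict[str, int]
    psi: list[PsiRecord] | None = None
    delta_psi: list[DeltaPsiRecord] | None = None
    rip: list[RipRecord] | None = None
    bound_spliced: set[str] | None = None
    chromosome_summary: pd.DataFrame | None = None
    correlation: CorrelationProfile | None = None

    @property
    def top_candidate(self) -> CandidateRecord | None:
        nominated = [c for c in self.candidates if c.verdict]
        return nominated[0] if nominated else None


def run_screen(
    inputs: ScreenInputs, config: PipelineConfig, out_dir: str | None = None
) -> ScreenResult:
    """Execute the screen; optionally write per-stage TSVs and a manifest."""
    logger.info("screen: HSS stage (%d genes)", len(inputs.tissue_matrix))
    hss_records = compute_hss(
        inputs.tissue_matrix,
        inputs.tissue_matrix.columns[0]
        if config.heart_label not in inputs.tissue_matrix.columns
        else config.heart_label,
        epsilon=config.hss_epsilon,
        threshold=config.hss_threshold,
    )

    logger.info("screen: DE stage (%d genes)", len(inputs.de_counts))
    norm = normalize_counts(inputs.de_counts, size_factors(inputs.de_counts))
    de_records = de_ttest(
        norm, inputs.case_ids, inputs.ctrl_ids, p_threshold=config.de_p_threshold
    )
    candidates = nominate_candidates(
        hss_records,
        de_records,
        hss_min=config.hss_threshold,
        p_max=config.de_p_threshold,
    )
    regulation = regulation_counts(candidates)
    if not any(c.verdict for c in candidates):
        logger.warning("screen: no candidate passes both filters")

    result = ScreenResult(
        hss=records_to_frame(hss_records),
        de=pd.DataFrame(
            {
                "gene_id": [d.gene_id for d in de_records],
                "mean_case": [d.mean_case for d in de_records],
                "mean_ctrl": [d.mean_ctrl for d in de_records],
                "fold_change": [d.fold_change for d in de_records],
                "log2_fold_change": [d.log2_fold_change for d in de_records],
                "t_stat": [d.t_stat for d in de_records],
                "p_value": [d.p_value for d in de_records],
                "direction": [d.direction for d in de_records],
            }
        ),
        candidates=candidates,
        regulation=regulation,
    )

    if inputs.annotation is not None and inputs.part_coverage is not None:
        logger.info("screen: PSI stage (%d parts)", len(inputs.annotation.parts))
        psi_records = compute_psi(
            list(inputs.annotation.parts),
            inputs.junctions,
            inputs.part_coverage,
            read_length=config.read_length,
            mode=config.psi_mode,
        )
        dpsi, skipped = delta_psi_test(
            psi_records, inputs.splice_case_ids, inputs.splice_ctrl_ids
        )
        if skipped:
            logger.info("screen: %d parts skipped in delta-PSI", len(skipped))
        result.psi = psi_records
        result.delta_psi = dpsi

        if inputs.rip_case_counts is not None:
            logger.info("screen: RIP stage (%d features)", len(inputs.rip_case_counts))
            rip_records = rip_enrich(
                inputs.rip_case_counts,
                inputs.rip_ctrl_counts,
                p_threshold=config.de_p_threshold,
            )
            gene_contigs = {
                p.gene_id: p.contig for p in inputs.annotation.parts
            }
            both, summary = bound_and_spliced(
                rip_records, dpsi, p_max=config.psi_p_threshold, gene_contigs=gene_contigs
            )
            result.rip = rip_records
            result.bound_spliced = both
            result.chromosome_summary = summary

        if inputs.correlation_factor and inputs.correlation_gene:
            gene = inputs.correlation_gene
            part_ids = [
                p.part_id for p in inputs.annotation.parts if p.gene_id == gene
            ]
            shared = inputs.splice_case_ids + inputs.splice_ctrl_ids
            factor = inputs.de_counts.loc[inputs.correlation_factor]
            if set(shared) <= set(factor.index):
                result.correlation = exon_factor_correlation(
                    inputs.part_coverage.loc[part_ids, shared],
                    factor[shared],
                    gene_id=gene,
                    factor_id=inputs.correlation_factor,
                )
            else:
                logger.warning(
                    "screen: correlation skipped (factor samples do not match)"
                )

    if out_dir is not None:
        _write_outputs(result, config, out_dir)
    return result


def _write_outputs(result: ScreenResult, config: PipelineConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    meta = {
        "tool": "cardiosplice",
        "version": __version__,
        "seed": config.seed,
        "hss_threshold": config.hss_threshold,
        "de_p_threshold": config.de_p_threshold,
        "psi_p_threshold": config.psi_p_threshold,
        "psi_mode": config.psi_mode,
    }
    write_table(result.hss, os.path.join(out_dir, "hss.tsv"), meta)
    write_table(result.de, os.path.join(out_dir, "de.tsv"), meta)
    cand = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in result.candidates],
            "hss": [c.hss for c in result.candidates],
            "fold_change": [c.fold_change for c in result.candidates],
            "p_value": [c.p_value for c in result.candidates],
            "enriched": [c.enriched for c in result.candidates],
            "regulated": [c.regulated for c in result.candidates],
            "verdict": [c.verdict for c in result.candidates],
        }
    )
    write_table(cand, os.path.join(out_dir, "candidates.tsv"), meta)
    if result.psi is not None:
        write_table(psi_to_frame(result.psi), os.path.join(out_dir, "psi.tsv"), meta)
    if result.delta_psi is not None:
        dpsi = pd.DataFrame(
            {
                "part_id": [r.part_id for r in result.delta_psi],
                "mean_psi_case": [r.mean_psi_case for r in result.delta_psi],
                "mean_psi_ctrl": [r.mean_psi_ctrl for r in result.delta_psi],
                "delta_psi": [r.delta_psi for r in result.delta_psi],
                "t_stat": [r.t_stat for r in result.delta_psi],
                "p_value": [r.p_value for r in result.delta_psi],
            }
        )
        write_table(dpsi, os.path.join(out_dir, "delta_psi.tsv"), meta)
    if result.rip is not None:
        write_table(rip_to_frame(result.rip), os.path.join(out_dir, "rip.tsv"), meta)
    if result.bound_spliced is not None:
        write_table(
            pd.DataFrame({"gene_id": sorted(result.bound_spliced)}),
            os.path.join(out_dir, "bound_and_spliced.tsv"),
            meta,
        )
        write_table(
            result.chromosome_summary,
            os.path.join(out_dir, "per_chromosome.tsv"),
            meta,
        )
    if result.correlation is not None:
        write_table(
            profile_to_frame(result.correlation),
            os.path.join(out_dir, "correlation.tsv"),
            meta,
        )
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump({**meta, "outputs": sorted(os.listdir(out_dir))}, fh)


# ---------------------------------------------------------------------------
# the packaged simulated study


@dataclass(frozen=True)
class ScreenTruth:
    factor_gene: str
    bound_spliced_genes: frozenset[str]
    retained_intron_part: str
    tissue: SimTruth
    splice: SimTruth
    rip: SimTruth


def simulate_screen_inputs(
    seed: int,
    n_background_genes: int = 300,
    n_splice_genes: int = 40,
    n_bound_spliced: int = 25,
    enrichment_factor: float = 8.0,
    de_fold_change: float = 1.9,
    delta_psi: float = 0.3,
    rip_factor: float = 8.0,
    depth: float = 1000.0,
    n_case: int = 4,
    n_ctrl: int = 4,
) -> tuple[ScreenInputs, ScreenTruth]:
    """A coherent simulated study for the end-to-end screen.

    Plants (i) one heart-enriched, up-regulated splicing-factor gene in
    the tissue matrix and the bulk DE counts, (ii) ``n_bound_spliced``
    genes carrying both a differential-splicing event (one of them a
    retained intron with the largest planted shift) and RIP binding
    enrichment, and (iii) null splicing events and unbound features as
    background.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    factor_gene = "FACTOR1"
    tissue_cfg = TissueSimConfig(
        n_genes=n_background_genes,
        planted_enriched=((factor_gene, enrichment_factor),),
        baseline_log_sd=1.0,
        noise_sd=0.2,
        seed=sub[0],
    )
    tissue, tissue_truth = simulate_tissue_matrix(tissue_cfg)

    # bulk DE counts over the same gene panel
    de_rng = np.random.default_rng(sub[1])
    genes = list(tissue.index)
    samples = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_ctrl)]
    base = de_rng.uniform(50, 500, size=len(genes))
    means = np.tile(base[:, None], (1, len(samples)))
    factor_row = genes.index(factor_gene)
    means[factor_row, :n_case] *= de_fold_change
    de_counts = pd.DataFrame(
        de_rng.poisson(means), index=genes, columns=samples
    )

    # splicing study: cassette genes, one retention gene
    splice_genes = [f"sgene_{i:03d}" for i in range(n_splice_genes - 1)]
    transcripts = []
    for i, g in enumerate(splice_genes):
        transcripts.extend(cassette_gene(g, contig="chr1", offset=i * 2000))
    retention_gid = "sgene_ret"
    transcripts.extend(
        retention_gene(retention_gid, contig="chr1", offset=n_splice_genes * 2000)
    )

    spliced_gene_ids = splice_genes[: n_bound_spliced - 1] + [retention_gid]
    planted_events = [
        PlantedSplice(f"{g}:002", psi_ctrl=0.4, delta_psi=delta_psi)
        for g in splice_genes[: n_bound_spliced - 1]
    ]
    # the retained intron carries the largest planted shift
    retained_part = f"{retention_gid}:002"
    planted_events.append(
        PlantedSplice(retained_part, psi_ctrl=0.3, delta_psi=min(0.99 - 0.3, delta_psi + 0.1))
    )
    # null events in some unbound genes keep the spliced call honest
    for g in splice_genes[n_bound_spliced - 1 : n_bound_spliced + 9]:
        planted_events.append(PlantedSplice(f"{g}:002", psi_ctrl=0.5, delta_psi=0.0))

    splice_cfg = SpliceSimConfig(
        transcripts=transcripts,
        n_case=n_case,
        n_ctrl=n_ctrl,
        depth_per_event=depth,
        planted_events=planted_events,
        seed=sub[2],
    )
    bundle, junctions, coverage, splice_truth = simulate_splice_counts(splice_cfg)

    # the RIP panel is genome-wide: the splice genes plus unbound
    # background features, so bound features stay a small minority and
    # median-of-ratios normalization is anchored on the unbound majority
    rip_background = [f"bg_{i:04d}" for i in range(200)]
    rip_panel = splice_genes + [retention_gid] + rip_background
    rip_cfg = RipSimConfig(
        n_features=len(rip_panel),
        planted_bound=tuple((g, rip_factor) for g in spliced_gene_ids),
        library_size=1e5,
        seed=sub[3],
    )
    rip_case, rip_ctrl, rip_truth = simulate_rip_counts(rip_cfg, feature_ids=rip_panel)

    inputs = ScreenInputs(
        tissue_matrix=tissue,
        de_counts=de_counts,
        case_ids=samples[:n_case],
        ctrl_ids=samples[n_case:],
        annotation=bundle,
        junctions=junctions,
        part_coverage=coverage,
        splice_case_ids=splice_truth.extras["case_ids"],
        splice_ctrl_ids=splice_truth.extras["ctrl_ids"],
        rip_case_counts=rip_case,
        rip_ctrl_counts=rip_ctrl,
        correlation_factor=None,
        correlation_gene=None,
    )
    truth = ScreenTruth(
        factor_gene=factor_gene,
        bound_spliced_genes=frozenset(spliced_gene_ids),
        retained_intron_part=retained_part,
        tissue=tissue_truth,
        splice=splice_truth,
        rip=rip_truth,
    )
    return inputs, truth
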