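"""Recovery and calibration benchmarks run at the study's conditions.

Each function simulates data with the synthetic generators at fixed,
documented conditions (sample sizes, depths, effect sizes mirroring the
screen design), runs the corresponding pipeline stage, and measures
recovery of the planted truth or the calibration of the test.  They
back both the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cardiosplice.de import de_ttest, normalize_counts, size_factors
from cardiosplice.hss import compute_hss, filter_enriched
from cardiosplice.pipeline import PipelineConfig, run_screen, simulate_screen_inputs
from cardiosplice.psi import compute_psi, delta_psi_test
from cardiosplice.simulate import (
    PlantedSplice,
    SpliceSimConfig,
    TissueSimConfig,
    cassette_gene,
    simulate_splice_counts,
    simulate_tissue_matrix,
)


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def hss_recovery_rate(
    seed: int,
    n_seeds: int = 20,
    n_genes: int = 1000,
    n_planted: int = 50,
    factor: float = 8.0,
    noise_sd: float = 0.2,
    threshold: float = 3.0,
) -> float:
    """Fraction of replicates where the planted heart-enriched set is
    exactly the HSS >= threshold set."""
    hits = 0
    for s in _spawn(seed, n_seeds):
        planted = tuple((f"hot_{i}", factor) for i in range(n_planted))
        cfg = TissueSimConfig(
            n_genes=n_genes, planted_enriched=planted, noise_sd=noise_sd, seed=s
        )
        matrix, truth = simulate_tissue_matrix(cfg)
        records = compute_hss(matrix, cfg.heart_label)
        kept = {r.gene_id for r in filter_enriched(records, threshold)}
        if kept == set(truth.planted):
            hits += 1
    return hits / n_seeds


def hss_noise_free_value(factor: float = 10.0) -> float:
    """HSS of one gene planted at ``factor`` over a unit background,
    without noise or pseudocount."""
    cfg = TissueSimConfig(
        n_genes=5,
        planted_enriched=(("gene_0000", factor),),
        baseline_log_mean=0.0,
        baseline_log_sd=0.0,
        noise_sd=0.0,
        atrial_label=None,
        seed=0,
    )
    matrix, _ = simulate_tissue_matrix(cfg)
    records = compute_hss(matrix, cfg.heart_label, epsilon=0.0)
    return next(r.hss for r in records if r.gene_id == "gene_0000")


def de_null_fpr(
    seed: int, n_genes: int = 1000, n_case: int = 4, n_ctrl: int = 4
) -> float:
    """Fraction of null genes called at P < 0.05 (type-I calibration)."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(20, 500, size=n_genes)
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
    counts = pd.DataFrame(
        rng.poisson(base[:, None], size=(n_genes, len(samples))),
        columns=samples,
        index=[f"g{i}" for i in range(n_genes)],
    )
    norm = normalize_counts(counts, size_factors(counts))
    records = de_ttest(norm, samples[:n_case], samples[n_case:])
    ps = np.array([r.p_value for r in records if not r.degenerate])
    return float(np.mean(ps < 0.05))


def psi_recovery_error(
    seed: int, depth: float = 1e4, psi_values: tuple[float, ...] = (0.2, 0.5, 0.8)
) -> float:
    """Max |pooled PSI - planted psi| across planted values at depth."""
    worst = 0.0
    for s, psi in zip(_spawn(seed, len(psi_values)), psi_values):
        cfg = SpliceSimConfig(
            transcripts=cassette_gene("G"),
            planted_events=[PlantedSplice("G:002", psi_ctrl=psi, delta_psi=0.0)],
            depth_per_event=depth,
            seed=s,
        )
        bundle, junctions, coverage, _ = simulate_splice_counts(cfg)
        records = compute_psi(list(bundle.parts), junctions, coverage, mode="raw")
        pooled = np.mean([r.psi for r in records if r.part_id == "G:002"])
        worst = max(worst, abs(pooled - psi))
    return worst


def delta_psi_power(
    seed: int,
    n_seeds: int = 20,
    delta: float = 0.3,
    depth: float = 1000.0,
    n_case: int = 4,
    n_ctrl: int = 4,
) -> float:
    """Fraction of replicates where the planted shift is detected at P < 0.05."""
    hits = 0
    for s in _spawn(seed, n_seeds):
        cfg = SpliceSimConfig(
            transcripts=cassette_gene("G"),
            planted_events=[PlantedSplice("G:002", psi_ctrl=0.4, delta_psi=delta)],
            depth_per_event=depth,
            n_case=n_case,
            n_ctrl=n_ctrl,
            seed=s,
        )
        bundle, junctions, coverage, truth = simulate_splice_counts(cfg)
        records = compute_psi(list(bundle.parts), junctions, coverage, mode="raw")
        results, _ = delta_psi_test(
            records, truth.extras["case_ids"], truth.extras["ctrl_ids"]
        )
        rec = next(r for r in results if r.part_id == "G:002")
        if rec.p_value < 0.05:
            hits += 1
    return hits / n_seeds


def delta_psi_null_fpr(seed: int, n_parts: int = 1000, depth: float = 1000.0) -> float:
    """Fraction of null parts called at P < 0.05."""
    transcripts = []
    events = []
    for i in range(n_parts):
        gid = f"n{i:03d}"
        transcripts.extend(cassette_gene(gid, offset=i * 2000))
        events.append(PlantedSplice(f"{gid}:002", psi_ctrl=0.5, delta_psi=0.0))
    cfg = SpliceSimConfig(
        transcripts=transcripts,
        planted_events=events,
        depth_per_event=depth,
        seed=seed,
    )
    bundle, junctions, coverage, truth = simulate_splice_counts(cfg)
    records = compute_psi(list(bundle.parts), junctions, coverage, mode="raw")
    results, _ = delta_psi_test(
        records, truth.extras["case_ids"], truth.extras["ctrl_ids"]
    )
    tested = [r for r in results if r.part_id.endswith(":002")]
    return float(np.mean([r.p_value < 0.05 for r in tested]))


def screen_recovery(seed: int, n_seeds: int = 20) -> dict[str, float]:
    """End-to-end screen: rate of (i) the planted factor topping the
    candidate list and (ii) exact recovery of the bound-and-spliced set."""
    top_hits = set_hits = 0
    for s in _spawn(seed, n_seeds):
        inputs, truth = simulate_screen_inputs(s)
        result = run_screen(inputs, PipelineConfig(seed=s))
        top = result.top_candidate
        if top is not None and top.gene_id == truth.factor_gene:
            top_hits += 1
        if result.bound_spliced == set(truth.bound_spliced_genes):
            set_hits += 1
    return {
        "factor_top_rate": top_hits / n_seeds,
        "bound_spliced_exact_rate": set_hits / n_seeds,
    }


def motif_scan_agreement(seed: int, max_length: int = 10_000, n_seqs: int = 30) -> float:
    """Fraction of random sequences where the scanner equals the
    exhaustive 4-mer check (lengths up to ``max_length``)."""
    from cardiosplice.motifs import scan_uwaa

    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_seqs):
        length = int(rng.integers(10, max_length + 1)) if i else max_length
        seq = "".join(rng.choice(list("ACGU"), size=length))
        got = [h.start for h in scan_uwaa(seq)]
        rna = seq
        expected = [
            j
            for j in range(length - 3)
            if rna[j] == "U" and rna[j + 1] in "AU" and rna[j + 2] == "A" and rna[j + 3] == "A"
        ]
        if got == expected:
            agree += 1
    return agree / n_seqs


def motif_mutate_rescan_hits(seed: int, n_constructions: int = 100) -> int:
    """Total hits remaining after mutating every motif in random
    motif-bearing constructions (expected: 0)."""
    from cardiosplice.motifs import mutate_motifs, scan_uwaa
    from cardiosplice.simulate import simulate_motif_sequence

    rng = np.random.default_rng(seed)
    leftover = 0
    for _ in range(n_constructions):
        n = int(rng.integers(1, 6))
        positions = sorted(
            int(p) for p in rng.choice(range(0, 196, 5), size=n, replace=False)
        )
        seq, _ = simulate_motif_sequence(200, positions, seed=int(rng.integers(2**31)))
        mutated, _ = mutate_motifs(seq, positions)
        leftover += len(scan_uwaa(mutated))
    return leftover
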