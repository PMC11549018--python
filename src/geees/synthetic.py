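"""Synthetic paired multiome data with planted gene-enhancer couplings.

The generator emulates the structure the scoring methods consume: sparse
overdispersed expression counts (negative binomial with multiplicative
dropout), near-binary sparse accessibility (Bernoulli-binarized), genomic
coordinates placing each gene's candidate peaks inside a +/-500 kb TSS window
(plus out-of-window distractors and a promoter peak), and a configurable
fraction of genes carrying one planted enhancer. For a planted pair, a latent
per-cell activity U_c drives both modalities:

    P(enhancer accessible in cell c) = base_rate + strength * U_c   (clipped)
    E[expression count in cell c]    = nb_mean * (1 + strength * U_c)

so expression and accessibility co-vary across cells with a tunable coupling
``strength`` in [0, 1]; decoy peaks are independent Bernoulli(base_rate). The
latent activity is bimodal — a fraction ``active_fraction`` of cells carries
the regulatory program with graded activity U_c ~ Uniform(0.5, 1), the rest
have U_c = 0 — mimicking an on/off program with cell-to-cell variation in the
"on" state rather than a continuum.
Optional cell sub-populations restrict each planted coupling to one
population, leaving the pair null elsewhere. A truth table of planted pairs
and a derived (optionally incomplete) gold-standard file accompany the
matrices. Everything is driven by one mandatory seed: the same seed gives
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_model import AccessibilityMatrix, ExpressionMatrix, write_matrix_market

__all__ = ["SimConfig", "SimResult", "simulate", "simulate_null_pair", "write_fixture"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic multiome generator."""

    seed: int
    n_cells: int = 500
    n_genes: int = 50
    peaks_per_gene: int = 10
    n_distal_peaks: int = 2  # per gene, outside the window (distractors)
    window: int = 500_000
    planted_fraction: float = 0.5
    strength: float = 0.8
    active_fraction: float = 0.5  # cells carrying a planted gene's program
    nb_mean: float = 5.0
    nb_dispersion: float = 8.0  # NB size parameter; smaller = more overdispersed
    dropout: float = 0.1
    base_rate: float = 0.1
    promoter_base: float = 0.2
    n_subpopulations: int = 1
    planted_placement: str = "uniform"  # or "near": planted closer than decoys
    gold_fraction: float = 1.0  # fraction of planted pairs the gold standard detects
    gold_decoy_fraction: float = 0.3  # fraction of decoy peaks the gold standard
    # "detects" as enhancers of some other gene (yields labeled negatives)
    gene_spacing: int = 2_100_000  # keeps TSS windows of adjacent genes disjoint

    def __post_init__(self) -> None:
        for name in (
            "planted_fraction",
            "strength",
            "active_fraction",
            "dropout",
            "base_rate",
            "promoter_base",
            "gold_fraction",
            "gold_decoy_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("need at least one cell and one gene")
        if self.gene_spacing <= 2 * self.window:
            raise ValueError("gene_spacing must exceed 2*window to keep windows disjoint")
        if self.planted_placement not in {"uniform", "near"}:
            raise ValueError(f"unknown planted_placement {self.planted_placement!r}")


@dataclass
class SimResult:
    expr: ExpressionMatrix
    acc: AccessibilityMatrix
    truth: pd.DataFrame  # planted pairs: gene_id, peak_index, population
    gold: pd.DataFrame  # chrom, start, end, gene_id (possibly incomplete)
    populations: np.ndarray = field(default=None)


def _nb_counts(rng, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate(config: SimConfig) -> SimResult:
    """Generate one paired dataset under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    C, G, E = config.n_cells, config.n_genes, config.peaks_per_gene
    margin = 10_000  # peaks stay clear of the window edge and the promoter
    if config.window <= 6 * margin:
        raise ValueError("window too small for the peak geometry")

    populations = rng.integers(0, config.n_subpopulations, size=C)
    gene_ids = np.array([f"gene{g:03d}" for g in range(G)], dtype=object)
    tss_pos = 1_500_000 + config.gene_spacing * np.arange(G)
    strands = np.where(np.arange(G) % 2 == 0, "+", "-")
    tss = pd.DataFrame(
        {"chrom": "chr1", "tss": tss_pos, "strand": strands}, index=pd.Index(gene_ids, name="gene_id")
    )

    n_planted = int(round(config.planted_fraction * G))
    planted_genes = np.sort(rng.choice(G, size=n_planted, replace=False))
    planted_set = set(planted_genes.tolist())

    peak_rows = []  # (chrom, start, end)
    peak_role = []  # (gene, kind) bookkeeping for truth construction
    for g in range(G):
        t = int(tss_pos[g])
        # promoter peak inside the strand-aware promoter window
        peak_rows.append(("chr1", t - 50, t + 150))
        peak_role.append((g, "promoter"))
        planted_slot = rng.integers(0, E) if g in planted_set else -1
        used = set()
        for j in range(E):
            near = config.planted_placement == "near" and j == planted_slot
            lo, hi = (5_000, 50_000) if near else (
                (100_000, config.window - margin)
                if config.planted_placement == "near"
                else (5_000, config.window - margin)
            )
            while True:
                d = int(rng.integers(lo, hi))
                sign = -1 if rng.random() < 0.5 else 1
                mid = t + sign * d
                # peak callers emit disjoint peaks within a sample: keep
                # midpoints farther apart than the maximal width
                if all(abs(mid - u) >= 900 for u in used):
                    used.add(mid)
                    break
            w = int(rng.integers(200, 800))
            peak_rows.append(("chr1", mid - w // 2, mid - w // 2 + w))
            peak_role.append((g, "planted" if j == planted_slot else "decoy"))
        for _ in range(config.n_distal_peaks):
            while True:
                d = int(rng.integers(config.window + 100_000, config.window + 500_000))
                sign = -1 if rng.random() < 0.5 else 1
                mid = t + sign * d
                if all(abs(mid - u) >= 900 for u in used):
                    used.add(mid)
                    break
            w = int(rng.integers(200, 800))
            peak_rows.append(("chr1", mid - w // 2, mid - w // 2 + w))
            peak_role.append((g, "distal"))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])
    n_peaks = len(peaks)

    # latent per-gene activity: bimodal on/off program with graded "on" level,
    # restricted to one population when several exist
    U = np.zeros((G, C))
    active_pop = np.full(G, -1)
    for i, g in enumerate(planted_genes):
        on = rng.random(C) < config.active_fraction
        u = np.where(on, rng.uniform(0.5, 1.0, size=C), 0.0)
        if config.n_subpopulations > 1:
            pop = int(i % config.n_subpopulations)
            u = np.where(populations == pop, u, 0.0)
            active_pop[g] = pop
        U[g] = u

    # expression: NB around a latent-modulated mean, with multiplicative dropout
    mean = config.nb_mean * (1.0 + config.strength * U)
    expr_counts = _nb_counts(rng, mean, config.nb_dispersion)
    if config.dropout > 0:
        keep = rng.random(expr_counts.shape) >= config.dropout
        expr_counts = expr_counts * keep

    # accessibility: Bernoulli, planted peaks driven by the gene's latent activity
    acc_counts = np.zeros((n_peaks, C), dtype=np.int64)
    truth_rows = []
    for p, (g, kind) in enumerate(peak_role):
        if kind == "promoter":
            prob = np.clip(config.promoter_base + config.strength * U[g], 0.0, 1.0)
        elif kind == "planted":
            prob = np.clip(config.base_rate + config.strength * U[g], 0.0, 1.0)
            truth_rows.append((gene_ids[g], p, int(active_pop[g])))
        else:
            prob = np.full(C, config.base_rate)
        acc_counts[p] = rng.random(C) < prob

    expr = ExpressionMatrix(sp.csr_matrix(expr_counts), gene_ids,
                            np.array([f"cell{c:04d}" for c in range(C)], dtype=object), tss)
    acc = AccessibilityMatrix(sp.csr_matrix(acc_counts), peaks, expr.cell_ids.copy())
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "peak_index", "population"])

    if config.gold_fraction >= 1.0 or truth.empty:
        detected = truth
    else:
        n_keep = int(round(config.gold_fraction * len(truth)))
        keep_idx = np.sort(rng.choice(len(truth), size=n_keep, replace=False))
        detected = truth.iloc[keep_idx]
    gold_rows = [
        (
            peaks["chrom"].iat[int(p)],
            int(peaks["start"].iat[int(p)]),
            int(peaks["end"].iat[int(p)]),
            g,
        )
        for g, p in zip(detected["gene_id"], detected["peak_index"])
    ]
    # gold standards also harbor enhancers whose (reported) target is another
    # gene; those make a gene's own decoy peaks labelable as negatives
    if G > 1 and config.gold_decoy_fraction > 0:
        for p, (g, kind) in enumerate(peak_role):
            if kind == "decoy" and rng.random() < config.gold_decoy_fraction:
                other = int(rng.integers(0, G - 1))
                other = other + 1 if other >= g else other
                gold_rows.append(
                    (
                        peaks["chrom"].iat[p],
                        int(peaks["start"].iat[p]),
                        int(peaks["end"].iat[p]),
                        gene_ids[other],
                    )
                )
    gold = pd.DataFrame(gold_rows, columns=["chrom", "start", "end", "gene_id"])
    return SimResult(expr, acc, truth, gold, populations)


def simulate_null_pair(C: int, base_rate: float, seed: int):
    """One fully independent (expression, accessibility) vector pair for
    type-I-error checks: NB expression, Bernoulli accessibility."""
    if C < 50:
        raise ValueError("need at least 50 cells for a meaningful null pair")
    rng = np.random.default_rng(seed)
    y = _nb_counts(rng, np.full(C, 2.0), 2.0)
    a = (rng.random(C) < base_rate).astype(np.int64)
    return y, a


def write_fixture(result: SimResult, out_dir) -> dict:
    """Write a SimResult as plain-text files (MTX triplets, BED, TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_matrix": out / "expression.mtx",
        "expr_features": out / "genes.txt",
        "expr_barcodes": out / "barcodes.txt",
        "acc_matrix": out / "accessibility.mtx",
        "acc_features": out / "peaks.txt",
        "acc_barcodes": out / "acc_barcodes.txt",
        "peaks_bed": out / "peaks.bed",
        "genes_tsv": out / "genes.tsv",
        "truth": out / "truth.tsv",
        "gold": out / "gold_standard.tsv",
    }
    write_matrix_market(result.expr, paths["expr_matrix"], paths["expr_features"], paths["expr_barcodes"])
    write_matrix_market(result.acc, paths["acc_matrix"], paths["acc_features"], paths["acc_barcodes"])
    result.acc.peaks.to_csv(paths["peaks_bed"], sep="\t", header=False, index=False)
    result.expr.tss.reset_index().to_csv(paths["genes_tsv"], sep="\t", index=False)
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    result.gold.to_csv(paths["gold"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
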