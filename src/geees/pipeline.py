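"""End-to-end benchmarking: every method x distance adjustment x gold standard.

``benchmark_all`` runs the full method panel (cell-specific score, marginal
correlation, the three stability-selection regressions, the distance baseline,
plus any externally imported score tables) on one aligned dataset, applies the
exponential distance adjustment to each, and evaluates every resulting score
table against every gold standard and their union, producing a long-format
metrics table and per-gold method rankings. A run manifest records the
configuration, seeds, input checksums, per-stage timings and outputs so a run
can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import aggregate_gold, compute_auroc_aupr, label_pairs
from .core import GEEES
from .data_model import MultiomeData
from .distance import DistanceBaseline, adjust
from .marginal import MarginalCorrelation
from .regression import StabilitySelection

__all__ = ["RunManifest", "benchmark_all", "import_scarlink_scores", "method_panel"]


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    seed: int
    input_checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def add_checksum(self, name: str, path) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        self.input_checksums[name] = h.hexdigest()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def import_scarlink_scores(fdr_table: pd.DataFrame, acc, pairs) -> pd.DataFrame:
    """Map an external gene x genomic-tile FDR table to candidate-pair scores.

    The pair score is the maximum of 1 - FDR over all same-gene tiles that
    overlap the candidate enhancer; pairs with no overlapping tile score 0.
    ``fdr_table`` needs columns gene_id, chrom, start, end, fdr.
    """
    required = {"gene_id", "chrom", "start", "end", "fdr"}
    if not required.issubset(fdr_table.columns):
        raise ValueError(f"FDR table needs columns {sorted(required)}")
    by_gene = {g: t for g, t in fdr_table.groupby("gene_id")}
    peaks = acc.peaks
    scores = np.zeros(len(pairs.table))
    for i, (_, row) in enumerate(pairs.table.iterrows()):
        tiles = by_gene.get(row["gene_id"])
        if tiles is None:
            continue
        p = peaks.iloc[int(row["peak_index"])]
        hit = (
            (tiles["chrom"].to_numpy() == p["chrom"])
            & (tiles["start"].to_numpy() < p["end"])
            & (tiles["end"].to_numpy() > p["start"])
        )
        if hit.any():
            scores[i] = float((1.0 - tiles["fdr"].to_numpy(dtype=float)[hit]).max())
    out = pairs.table[["gene_id", "peak_index"]].copy()
    out["score"] = scores
    out["method"] = "scarlink"
    return out


def method_panel(seed: int = 0, n_subsamples: int = 100, k: int = 30, m_background: int = 200):
    """The default estimator panel, keyed by method name."""
    return {
        "geees": GEEES(k=k),
        "marginal": MarginalCorrelation(m_background=m_background, random_state=seed),
        "adaptive": StabilitySelection("adaptive", n_subsamples=n_subsamples, random_state=seed),
        "sequential": StabilitySelection("sequential", n_subsamples=n_subsamples, random_state=seed),
        "multi_response": StabilitySelection(
            "multi_response", n_subsamples=n_subsamples, random_state=seed
        ),
        "distance": DistanceBaseline(),
    }


def benchmark_all(
    data: MultiomeData,
    gold_standards: dict[str, pd.DataFrame],
    methods: dict | None = None,
    external_scores: dict[str, pd.DataFrame] | None = None,
    seed: int = 0,
    epsilon: float = 0.05,
    d0: float = 200_000.0,
    manifest: RunManifest | None = None,
):
    """Run every method with and without distance adjustment against every
    gold standard and the aggregated union.

    Returns (metrics, rankings, score_tables, manifest). A failing method is
    recorded in the manifest and the rest proceed.
    """
    if not gold_standards:
        raise ValueError("need at least one gold standard")
    if manifest is None:
        manifest = RunManifest(config={"epsilon": epsilon, "d0": d0}, seed=seed)
    methods = method_panel(seed) if methods is None else methods

    tables: dict[tuple[str, bool], pd.DataFrame] = {}
    for name, est in methods.items():
        t0 = time.perf_counter()
        try:
            est.fit(data)
            tables[(name, False)] = est.pair_scores_
        except Exception as exc:  # record, keep going
            manifest.errors[name] = f"{exc}\n{traceback.format_exc(limit=3)}"
            continue
        manifest.timings[name] = time.perf_counter() - t0
    for name, tab in (external_scores or {}).items():
        tables[(name, False)] = tab
    for (name, _), tab in list(tables.items()):
        tables[(name, True)] = adjust(tab, data.pairs, epsilon, d0)

    golds = dict(gold_standards)
    if len(gold_standards) > 1:
        golds["aggregated"] = aggregate_gold(list(gold_standards.values()))
    labels = {gname: label_pairs(data.pairs, data.acc.peaks, g) for gname, g in golds.items()}

    rows = []
    for (name, adjusted), tab in tables.items():
        # score tables may cover a gene subset; align labels by pair identity
        key = pd.MultiIndex.from_frame(tab[["gene_id", "peak_index"]])
        full_key = data.pairs.pair_labels()
        pos = pd.Series(np.arange(len(full_key)), index=full_key)
        for gname, lab in labels.items():
            aligned = pd.Series(
                lab.to_numpy()[pos.loc[key].to_numpy()], index=tab.index
            )
            try:
                auroc, aupr = compute_auroc_aupr(tab, aligned)
            except ValueError:
                auroc = aupr = np.nan
            rows.append((name, adjusted, gname, auroc, aupr))
    metrics = pd.DataFrame(rows, columns=["method", "adjusted", "gold", "auroc", "aupr"])

    rankings = (
        metrics.dropna()
        .assign(rank=lambda d: d.groupby(["gold", "adjusted"])["auroc"].rank(ascending=False))
        .sort_values(["gold", "adjusted", "rank"])
        .reset_index(drop=True)
    )
    return metrics, rankings, tables, manifest
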