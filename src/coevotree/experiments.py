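"""Benchmark experiments: coupling recovery, null calibration, span sweep.

These drive the synthetic generator through the full score-and-evaluate
pipeline and summarize classifier performance.  Replicate seeds are
derived deterministically from a master seed so whole experiments are
reproducible from one integer.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluation import filter_scored, mcc_curve, roc
from .mirrortree import score_all
from .simulate import SimulationConfig, generate_benchmark

__all__ = [
    "derive_seed",
    "benchmark_metrics",
    "coupling_recovery",
    "null_calibration",
    "span_sweep",
]


def derive_seed(master: int, index: int) -> int:
    """Replicate seed from a master seed, kept below 2**31."""
    return int((master * 100_003 + 7 * index + 1) % (2**31 - 1))


def benchmark_metrics(config: SimulationConfig, model: str = "jtt") -> dict:
    """Generate, score and evaluate one benchmark.

    Returns AUC, peak MCC and threshold, the per-class score mean/sd,
    and the number of scored pairs.
    """
    benchmark = generate_benchmark(config)
    scores = score_all(benchmark.pair_table, benchmark.alignments, model=model)
    scored = filter_scored(scores)
    roc_res = roc(scored)
    mcc_res = mcc_curve(scored)
    by_label = scored.groupby("label")["r"]
    return {
        "auc": roc_res.auc,
        "peak_mcc": mcc_res.peak_mcc,
        "peak_threshold": mcc_res.peak_threshold,
        "mean_r": by_label.mean().to_dict(),
        "sd_r": by_label.std(ddof=1).to_dict(),
        "n_scored": len(scored),
        "scores": scored,
    }


def coupling_recovery(
    master_seed: int,
    n_replicates: int = 5,
    config: SimulationConfig | None = None,
    model: str = "jtt",
) -> dict:
    """Mean AUC of coupled benchmarks over replicate seeds."""
    if config is None:
        config = SimulationConfig()
    aucs, peaks, n_total = [], [], 0
    for i in range(n_replicates):
        m = benchmark_metrics(
            replace(config, seed=derive_seed(master_seed, i)), model=model
        )
        aucs.append(m["auc"])
        peaks.append(m["peak_mcc"])
        n_total += m["n_scored"]
    return {
        "mean_auc": float(np.mean(aucs)),
        "aucs": aucs,
        "mean_peak_mcc": float(np.mean(peaks)),
        "n_pairs": n_total,
    }


def null_calibration(
    master_seed: int, n_replicates: int = 5, config: SimulationConfig | None = None
) -> dict:
    """Mean AUC when both classes are generated with coupling 0."""
    if config is None:
        config = SimulationConfig()
    return coupling_recovery(
        master_seed + 1,
        n_replicates=n_replicates,
        config=replace(config, coupling=0.0),
    )


def span_sweep(
    master_seed: int,
    depths: tuple[float, ...] = (0.2, 1.0, 2.0),
    n_replicates: int = 3,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """AUC and interacting-score spread as tree depth varies.

    Benchmarks at different depths share replicate seeds, so the
    comparison across depths is paired (same topologies and rate
    draws, rescaled).  Returns one row per depth with the mean AUC and
    the mean within-replicate sd of interacting-pair scores.
    """
    if config is None:
        config = SimulationConfig()
    rows = []
    for depth in depths:
        aucs, sds = [], []
        for i in range(n_replicates):
            m = benchmark_metrics(
                replace(config, depth=depth, seed=derive_seed(master_seed, i))
            )
            aucs.append(m["auc"])
            sds.append(m["sd_r"]["interacting"])
        rows.append(
            {
                "depth": depth,
                "mean_auc": float(np.mean(aucs)),
                "sd_interacting": float(np.mean(sds)),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
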