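"""End-to-end pipeline: simulate (optional) -> score -> evaluate.

A run is driven by a :class:`RunConfig`, echoed verbatim into the
output directory so that any run can be reconstructed from its
artifacts.  Identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .evaluation import (
    bin_by_conservation,
    density_summary,
    filter_scored,
    mcc_curve,
    roc,
    span_vs_score,
    stratify_by_span,
)
from .io import (
    load_alignment_dir,
    read_clade_table,
    read_lca_times,
    read_pair_table,
    write_config_echo,
    write_table_tsv,
)
from .mirrortree import DEFAULT_MIN_COMMON, common_species, score_all
from .simulate import SimulationConfig, generate_benchmark, write_fixture

__all__ = ["RunConfig", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    out_dir: str
    seed: int = 0
    simulate: SimulationConfig | None = None
    pairs: str | None = None
    aln_dir: str | None = None
    model: str = "jtt"
    min_common: int = DEFAULT_MIN_COMMON
    bin_width: float = 0.02
    clades: str | None = None
    lca_times: str | None = None
    make_plots: bool = False
    log_level: str = "INFO"

    def echo_dict(self) -> dict:
        d = asdict(self)
        sim = d.pop("simulate")
        flat = {f"run.{k}": v for k, v in d.items()}
        if sim is not None:
            flat.update({f"simulate.{k}": v for k, v in sim.items()})
        return flat


def write_report(
    scores: pd.DataFrame,
    report_dir,
    bin_width: float = 0.02,
    species_sets=None,
    clade_paths=None,
    lca_times=None,
    make_plots: bool = False,
) -> list[str]:
    """Write the evaluation report for a score table; returns paths."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    paths: list[str] = []
    scored = filter_scored(scores)
    status_counts = scores["status"].value_counts().to_dict()
    summary_rows = [{"metric": f"n_status_{k}", "value": v} for k, v in sorted(status_counts.items())]
    summary_rows.insert(0, {"metric": "n_pairs", "value": len(scores)})

    evaluable = set(scored["label"]) == {"interacting", "noninteracting"}
    if evaluable:
        roc_res = roc(scored)
        mcc_res = mcc_curve(scored)
        summary_rows += [
            {"metric": "auc", "value": roc_res.auc},
            {"metric": "peak_mcc", "value": mcc_res.peak_mcc},
            {"metric": "peak_threshold", "value": mcc_res.peak_threshold},
        ]
        roc_tab = pd.DataFrame(
            {"threshold": roc_res.thresholds, "fpr": roc_res.fpr, "tpr": roc_res.tpr}
        )
        write_table_tsv(roc_tab, report_dir / "roc.tsv")
        paths.append(str(report_dir / "roc.tsv"))
        mcc_tab = pd.DataFrame(
            {
                "threshold": mcc_res.thresholds,
                "mcc": mcc_res.mcc,
                "sensitivity": mcc_res.sensitivity,
                "specificity": mcc_res.specificity,
            }
        )
        write_table_tsv(mcc_tab, report_dir / "mcc_curve.tsv")
        paths.append(str(report_dir / "mcc_curve.tsv"))
        dens = density_summary(scored)
        dens_rows = []
        for label, d in dens.items():
            summary_rows.append({"metric": f"density_mode_{label}", "value": d["mode"]})
            for g, v in zip(d["grid"], d["density"]):
                dens_rows.append({"label": label, "r": g, "density": v})
        write_table_tsv(pd.DataFrame(dens_rows), report_dir / "density.tsv")
        paths.append(str(report_dir / "density.tsv"))
    else:
        logger.info("score table lacks both classes; classifier metrics skipped")

    bins = bin_by_conservation(scored, width=bin_width)
    write_table_tsv(bins, report_dir / "conservation_bins.tsv")
    paths.append(str(report_dir / "conservation_bins.tsv"))

    if clade_paths is not None and species_sets is not None and evaluable:
        strat = stratify_by_span(scored, species_sets, clade_paths)
        strat_rows = [
            {
                "category": cat,
                "n": len(strat.tables[cat]),
                "auc": strat.roc[cat].auc if strat.roc[cat] else float("nan"),
            }
            for cat in strat.categories
        ]
        write_table_tsv(pd.DataFrame(strat_rows), report_dir / "strata.tsv")
        paths.append(str(report_dir / "strata.tsv"))
    if lca_times is not None and species_sets is not None:
        spans = span_vs_score(scored, species_sets, lca_times)
        write_table_tsv(spans, report_dir / "span.tsv")
        paths.append(str(report_dir / "span.tsv"))

    summary = pd.DataFrame(summary_rows, columns=["metric", "value"])
    write_table_tsv(summary, report_dir / "summary.tsv")
    paths.append(str(report_dir / "summary.tsv"))

    if make_plots and evaluable:
        paths += _write_plots(scored, roc_res, mcc_res, report_dir)
    return paths


def _write_plots(scored, roc_res, mcc_res, report_dir) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    dens = density_summary(scored)
    fig, ax = plt.subplots()
    for label, d in dens.items():
        ax.plot(d["grid"], d["density"], label=label)
    ax.set_xlabel("correlation score r")
    ax.set_ylabel("density")
    ax.legend()
    fig.savefig(report_dir / "density.png", dpi=120)
    plt.close(fig)
    paths.append(str(report_dir / "density.png"))

    fig, ax = plt.subplots()
    ax.plot(roc_res.fpr, roc_res.tpr)
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {roc_res.auc:.3f}")
    fig.savefig(report_dir / "roc.png", dpi=120)
    plt.close(fig)
    paths.append(str(report_dir / "roc.png"))

    fig, ax = plt.subplots()
    ax.plot(mcc_res.thresholds, mcc_res.mcc, label="MCC")
    ax.plot(mcc_res.thresholds, mcc_res.sensitivity, label="sensitivity")
    ax.plot(mcc_res.thresholds, mcc_res.specificity, label="specificity")
    ax.axvline(mcc_res.peak_threshold, ls="--", c="grey")
    ax.set_xlabel("score threshold")
    ax.legend()
    fig.savefig(report_dir / "mcc.png", dpi=120)
    plt.close(fig)
    paths.append(str(report_dir / "mcc.png"))
    return paths


def run_pipeline(config: RunConfig) -> int:
    """Execute simulate (optional) -> score -> evaluate.

    Writes a config echo, a manifest, the score table and the report
    into ``config.out_dir``.  Returns 0 on success; on failure the
    partial artifacts are kept alongside a FAILED marker and a nonzero
    status is returned.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level.upper())
    manifest: list[str] = []
    try:
        write_config_echo(config.echo_dict(), out_dir / "config.txt")
        manifest.append(str(out_dir / "config.txt"))

        if config.simulate is not None:
            benchmark = generate_benchmark(config.simulate)
            data_dir = out_dir / "data"
            manifest += write_fixture(benchmark, data_dir)
            pair_table = benchmark.pair_table
            store = benchmark.alignments
        else:
            if not config.pairs or not config.aln_dir:
                raise ValueError("need either a simulate block or pairs + aln_dir")
            pair_table = read_pair_table(config.pairs)
            store = load_alignment_dir(config.aln_dir)

        scores = score_all(
            pair_table, store, model=config.model, min_common=config.min_common
        )
        write_table_tsv(scores, out_dir / "scores.tsv")
        manifest.append(str(out_dir / "scores.tsv"))

        species_sets = None
        clade_paths = read_clade_table(config.clades) if config.clades else None
        lca_times = read_lca_times(config.lca_times) if config.lca_times else None
        if clade_paths is not None or lca_times is not None:
            species_sets = {
                (row.protein_a, row.protein_b): common_species(
                    store[row.protein_a], store[row.protein_b]
                )
                for row in pair_table.itertuples(index=False)
                if row.protein_a in store and row.protein_b in store
            }

        manifest += write_report(
            scores,
            out_dir / "report",
            bin_width=config.bin_width,
            species_sets=species_sets,
            clade_paths=clade_paths,
            lca_times=lca_times,
            make_plots=config.make_plots,
        )

        status_counts = scores["status"].value_counts().to_dict()
        log_lines = [f"coevotree {__version__}", f"seed={config.seed}"]
        log_lines += [f"status.{k}={v}" for k, v in sorted(status_counts.items())]
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
        manifest.append(str(out_dir / "run.log"))

        rel = sorted(str(Path(p).relative_to(out_dir)) for p in manifest)
        (out_dir / "manifest.txt").write_text("\n".join(rel) + "\n")
        return 0
    except Exception:
        logger.exception("pipeline failed; partial artifacts kept in %s", out_dir)
        (out_dir / "FAILED").write_text("pipeline failed; see log\n")
        return 1
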