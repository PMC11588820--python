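"""Execute a full analysis run: tables, summary, curve, plots, log."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
import pandas as pd

from .config import RunConfig
from .optimizer import optimize_design, power_sweep, summarize
from .seasonal_sim import simulate_seasonal_curve

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

__all__ = ["run"]

log = logging.getLogger("seasonpower")


def _write_curve_plot(curve, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(curve.times, curve.values, marker="o", ms=3, lw=1.2)
    ax.set_xlabel("time")
    ax.set_ylabel("population")
    ax.set_title("Seasonal curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_power_plot(table, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, level in enumerate(table.power_levels):
        ax.plot(table.k_grid, table.cells[i], lw=1.2,
                label=f"{level:g}%")
    ax.set_xlabel("repeated measurements")
    ax.set_ylabel("number of sites")
    ax.set_title("Power curves")
    ax.legend(fontsize=7, ncol=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the analysis and write all outputs into ``outdir``.

    Returns a mapping of artefact names to the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    if log.level == logging.NOTSET:
        log.setLevel(logging.INFO)

    try:
        return _run_logged(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_logged(config: RunConfig, outdir: Path) -> dict[str, Path]:
    for key, value in sorted(config.to_mapping().items()):
        log.info("parameter %s = %r", key, value)

    spec = config.study_spec()
    model = config.seasonal_model()

    table = power_sweep(spec, model, config.k)
    design = optimize_design(spec, model, config.k)
    summary = summarize(spec, model, config.k)
    log.info("optimal design: k=%d, locations=%d, effort=%d",
             design.k, design.n_locations, design.effort)

    paths: dict[str, Path] = {}

    paths["design_table"] = outdir / "design_table.csv"
    table.to_frame().to_csv(paths["design_table"], float_format="%.10g")

    paths["summary"] = outdir / "summary.csv"
    pd.DataFrame([{
        "optimal_k": summary.optimal_k,
        "optimal_n_locations": summary.optimal_n_locations,
        "sampling_effort": summary.optimal_k * summary.optimal_n_locations,
        "total_sampling_correlated": summary.total_sampling_correlated,
        "total_sampling_independent": summary.total_sampling_independent,
        "variance_ratio": summary.variance_ratio,
    }]).to_csv(paths["summary"], index=False, float_format="%.10g")

    curve = simulate_seasonal_curve(config.curve_spec(), model)
    paths["seasonal_curve"] = outdir / "seasonal_curve.csv"
    pd.DataFrame({"time": curve.times, "population": curve.values}).to_csv(
        paths["seasonal_curve"], index=False, float_format="%.10g")

    paths["seasonal_curve_plot"] = outdir / "seasonal_curve.png"
    _write_curve_plot(curve, paths["seasonal_curve_plot"])
    paths["power_curves_plot"] = outdir / "power_curves.png"
    _write_power_plot(table, paths["power_curves_plot"])

    paths["log"] = outdir / "run.log"
    return paths
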