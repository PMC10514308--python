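"""End-to-end orchestration: quantify -> gate -> tally -> fit -> errors ->
metrics -> compare, plus the band-count -> relative-shift pipeline.

Reports embed the resolved configuration, the seed and a config hash so a
run is reproducible from its report alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ArgumentError, BurstfishError, ParseError, StageError
from .inference import (
    FitOptions,
    NascentTally,
    active_inactive_ratio,
    build_histogram,
    burst_metrics,
    compare_fits,
    fit_two_state,
    goodness_of_fit,
    monte_carlo_errors,
)
from .nucshift import BandReadCounts, relative_shift, summarize_titration
from .smfish import gate_crystal_cells
from .synthetic import Scenario, simulate_cell_table

__all__ = ["RunConfig", "run_burst_pipeline", "run_nucshift_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    ``cell_tables`` maps genotype -> CSV path; alternatively ``scenario``
    simulates the tables in-memory.  ``reference`` names the genotype used
    as the fold-change reference.  All stage options have working defaults.
    """

    seed: int = 0
    output_dir: str | None = None
    # burst pipeline inputs
    cell_tables: dict = field(default_factory=dict)  # genotype -> csv path
    scenario: Scenario | None = None
    reference: str | None = None
    count_column: str = "count"
    single_transcript_intensity: float | None = None  # intensity -> count
    nascent_threshold: float | None = None  # absolute intensity threshold
    gate_policy: str = "otsu"
    manual_gate_threshold: float | None = None
    binning_rule: str = "fd"
    bin_width: float | None = None
    n_reps: int = 50  # Monte-Carlo error replicates
    mrna_half_life: float | None = None  # optional absolute-rate conversion
    fit_options: FitOptions = field(default_factory=FitOptions)
    # nucshift pipeline inputs
    band_counts: str | None = None  # csv path
    control_template: str = "601"
    input_lane: str = "input"
    pseudocount: float = 1.0
    lane_order: list | None = None

    def resolved(self) -> dict:
        d = {
            "seed": self.seed,
            "reference": self.reference,
            "count_column": self.count_column,
            "single_transcript_intensity": self.single_transcript_intensity,
            "nascent_threshold": self.nascent_threshold,
            "gate_policy": self.gate_policy,
            "manual_gate_threshold": self.manual_gate_threshold,
            "binning_rule": self.binning_rule,
            "bin_width": self.bin_width,
            "n_reps": self.n_reps,
            "mrna_half_life": self.mrna_half_life,
            "cell_tables": {g: str(p) for g, p in self.cell_tables.items()},
            "scenario": self.scenario.to_dict() if self.scenario else None,
            "band_counts": str(self.band_counts) if self.band_counts else None,
            "control_template": self.control_template,
            "input_lane": self.input_lane,
            "pseudocount": self.pseudocount,
            "lane_order": self.lane_order,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.scenario is not None:
        table = simulate_cell_table(config.scenario)
        return {g: grp.reset_index(drop=True) for g, grp in table.groupby("genotype")}
    if not config.cell_tables:
        raise ArgumentError("config needs cell_tables paths or a scenario")
    out = {}
    for genotype, path in config.cell_tables.items():
        if not Path(path).exists():
            raise ArgumentError(f"cell table for {genotype!r} not found: {path}")
        try:
            out[genotype] = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
    return out


def _effective_single_intensity(config: RunConfig) -> float | None:
    """Simulated runs inherit the scenario's ground-truth intensity scale
    unless an explicit calibration value is given."""
    if config.single_transcript_intensity is not None:
        return config.single_transcript_intensity
    if config.scenario is not None:
        return config.scenario.single_transcript_intensity
    return None


def _counts_and_tally(table: pd.DataFrame, config: RunConfig):
    """Gate crystal cells, extract counts and the nascent tally."""
    if "marker_intensity" in table.columns:
        gated = gate_crystal_cells(
            table,
            policy=config.gate_policy,
            manual_threshold=config.manual_gate_threshold,
        )
        crystal = gated[gated["gate_label"] == "crystal"]
    else:
        crystal = table
    if len(crystal) == 0:
        raise ArgumentError("no crystal cells after gating")

    if config.count_column in crystal.columns:
        counts = crystal[config.count_column].to_numpy(dtype=float)
    elif "total_intensity" in crystal.columns:
        i1 = _effective_single_intensity(config)
        if not i1 or i1 <= 0:
            raise ArgumentError(
                "intensity input requires single_transcript_intensity"
            )
        counts = crystal["total_intensity"].to_numpy(dtype=float) / i1
    else:
        raise ArgumentError(
            f"table has neither {config.count_column!r} nor 'total_intensity'"
        )

    if "nascent_flag" in crystal.columns:
        nas = crystal["nascent_flag"].astype(bool).to_numpy()
    elif "nascent_intensity" in crystal.columns:
        thr = config.nascent_threshold
        if thr is None:
            i1 = _effective_single_intensity(config) or 1.0
            thr = 3.0 * i1  # bright foci: > 3 single transcripts
        nas = crystal["nascent_intensity"].to_numpy(dtype=float) > thr
    else:
        raise ArgumentError("table lacks nascent_flag / nascent_intensity")
    tally = NascentTally(int(nas.sum()), int(len(crystal) - nas.sum()))
    return counts, tally


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_burst_pipeline(config: RunConfig) -> dict:
    """Full burst analysis; returns (and optionally writes) the report dict."""
    report: dict = {
        "pipeline": "burst",
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "genotypes": {},
        "stages": [],
    }
    outdir = Path(config.output_dir) if config.output_dir else None

    def _fail(stage: str, exc: Exception):
        if outdir:
            _write_json(outdir / "partial_report.json", report)
        raise StageError(stage, str(exc)) from exc

    try:
        tables = _load_tables(config)
    except Exception as exc:
        _fail("load", exc)
    report["stages"].append({"load": {g: len(t) for g, t in tables.items()}})

    fits = {}
    for genotype, table in tables.items():
        try:
            counts, tally = _counts_and_tally(table, config)
        except Exception as exc:
            _fail(f"tally[{genotype}]", exc)
        try:
            hist = build_histogram(
                counts, rule=config.binning_rule, width=config.bin_width
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_two_state(hist, tally, config.fit_options)
                mc = monte_carlo_errors(
                    fit, n_reps=config.n_reps, seed=config.seed,
                    options=config.fit_options,
                )
                gof = goodness_of_fit(fit, hist)
        except Exception as exc:
            _fail(f"fit[{genotype}]", exc)
        fits[genotype] = fit
        entry = fit.to_dict()
        entry["tally"] = {"n_nascent": tally.n_nascent, "n_empty": tally.n_empty,
                          "ratio": active_inactive_ratio(tally)}
        entry["monte_carlo"] = mc.to_dict()
        entry["burst_metrics"] = burst_metrics(fit.params).to_dict()
        if config.mrna_half_life:
            from .inference import to_absolute_rates

            entry["absolute_rates"] = to_absolute_rates(
                fit.params, config.mrna_half_life
            ).to_dict()
        report["genotypes"][genotype] = entry
        report["stages"].append(
            {f"fit[{genotype}]": {"n_cells": hist.n_cells, "n_bins": hist.n_bins}}
        )

    reference = config.reference or sorted(fits)[0]
    if reference not in fits:
        _fail("compare", ArgumentError(f"reference genotype {reference!r} missing"))
    report["fold_changes"] = {}
    for genotype, fit in fits.items():
        if genotype == reference:
            continue
        try:
            fc = compare_fits(fits[reference], fit, labels=(reference, genotype))
        except Exception as exc:
            _fail("compare", exc)
        report["fold_changes"][genotype] = fc.to_dict()

    if outdir:
        _write_json(outdir / "burst_report.json", report)
    return report


def run_nucshift_pipeline(config: RunConfig) -> dict:
    """Band counts -> relative shifts (both bands present) -> titration summary."""
    report: dict = {
        "pipeline": "nucshift",
        "version": __version__,
        "seed": config.seed,
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "bands": {},
    }
    outdir = Path(config.output_dir) if config.output_dir else None

    def _fail(stage: str, exc: Exception):
        if outdir:
            _write_json(outdir / "partial_report.json", report)
        raise StageError(stage, str(exc)) from exc

    if config.band_counts is None:
        _fail("load", ArgumentError("config.band_counts CSV path is required"))
    try:
        counts = BandReadCounts.from_csv(
            config.band_counts,
            control_template=config.control_template,
            input_lane=config.input_lane,
        )
    except BurstfishError:
        raise
    except Exception as exc:
        _fail("load", exc)

    for band in counts.bands:
        try:
            shifts = relative_shift(counts, band=band, pseudocount=config.pseudocount)
            lanes = [l for l in (config.lane_order or counts.lanes)
                     if l != config.input_lane]
            summary = (
                summarize_titration(shifts, lanes) if len(lanes) >= 2 else None
            )
        except Exception as exc:
            _fail(f"shift[{band}]", exc)
        report["bands"][band] = {
            "pseudocount": config.pseudocount,
            "shifts": shifts.table.to_dict(orient="records"),
            "summary": summary.to_dict(orient="records")
            if summary is not None
            else None,
        }
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            shifts.to_csv(outdir / f"relative_shift_{band}.csv")
    if outdir:
        _write_json(outdir / "nucshift_report.json", report)
    return report
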