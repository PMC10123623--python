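"""End-to-end analysis pipeline and trajectory reports.

``run_pipeline`` takes a declarative config (YAML file or dict), obtains
spectra (from disk or a synthetic preset), computes the per-condition GP
trajectory, spot-averages each condition, runs the global two-band fit, and
writes a machine-readable report bundle: GP trajectory, band parameters,
population-fraction trajectories, per-spectrum goodness of fit, plus a run
record with the package version, seed and config hash.  With noise off or a
fixed seed, rerunning from the embedded config reproduces the report
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import decomposition, gp_analysis as gp_mod, preprocess, synthetic
from .decomposition import FitBounds
from .spectra_io import SpectrumSet, read_spectra

__all__ = ["PipelineError", "ReportBundle", "run_pipeline", "compare_trajectories"]

log = logging.getLogger("laurdanspec")

SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "schema_version": SCHEMA_VERSION,
    "input": {"simulate": {"preset": "dehydration", "spots": 10, "noise": True,
                           "seed": 0}},
    "gp": {"blue": 440.0, "red": 490.0, "window": 5, "min_spots": None},
    "average": {"min_spots": None},
    "bounds": {},
    "output_dir": None,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _package_version() -> str:
    try:
        return version("laurdanspec")
    except PackageNotFoundError:
        return "unknown"


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _merge_defaults(config: dict) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        # the input section is atomic: a user-specified source replaces the
        # default simulate block instead of inheriting parts of it
        if k != "input" and isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


@dataclass
class ReportBundle:
    """Numerical outputs of one pipeline run (the contract; plots are not)."""

    config: dict
    gp_table: pd.DataFrame
    fraction_table: pd.DataFrame
    bands: dict
    run_info: dict
    axis_kind: str = "custom"
    truth: dict = field(default_factory=dict)

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gp_table.to_csv(outdir / "gp_trajectory.csv", index=False,
                             float_format="%.10g")
        self.fraction_table.to_csv(outdir / "fractions.csv", index=False,
                                   float_format="%.10g")
        with open(outdir / "global_fit.json", "w") as fh:
            json.dump(self.bands, fh, indent=2, sort_keys=True)
        record = {"config": self.config, "run_info": self.run_info,
                  "axis_kind": self.axis_kind, "truth": self.truth}
        with open(outdir / "run.json", "w") as fh:
            json.dump(record, fh, indent=2, sort_keys=True, default=str)
        return outdir

    @classmethod
    def load(cls, outdir) -> "ReportBundle":
        outdir = Path(outdir)
        with open(outdir / "run.json") as fh:
            record = json.load(fh)
        with open(outdir / "global_fit.json") as fh:
            bands = json.load(fh)
        gp_table = pd.read_csv(outdir / "gp_trajectory.csv")
        fraction_table = pd.read_csv(outdir / "fractions.csv")
        for t in (gp_table, fraction_table):
            for col in t.columns:
                if col not in ("n_spots",):
                    t[col] = t[col].astype(float)
        return cls(
            config=record["config"],
            gp_table=gp_table,
            fraction_table=fraction_table,
            bands=bands,
            run_info=record["run_info"],
            axis_kind=record["axis_kind"],
            truth=record.get("truth", {}),
        )


def _load_input(cfg: dict):
    spec = cfg["input"]
    if "simulate" in spec and spec["simulate"]:
        sim = dict(spec["simulate"])
        config = synthetic.make_config(
            preset=sim.get("preset", "dehydration"),
            spots=int(sim.get("spots", 10)),
            noise=bool(sim.get("noise", True)),
            seed=int(sim.get("seed", 0)),
        )
        sset, truth = synthetic.generate(config)
        return sset, truth
    if "path" in spec:
        return read_spectra(spec["path"], dialect=spec.get("dialect", "csv")), {}
    raise PipelineError("stage input: config needs input.simulate or input.path")


def run_pipeline(config: "dict | str | Path") -> ReportBundle:
    """Run GP + global decomposition end to end and return the report."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge_defaults(config)

    try:
        sset, truth = _load_input(cfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc
    n_spots = min(len(sset.select(c)) for c in sset.conditions)
    log.info("input: %d spectra, %d conditions (%s axis)",
             len(sset), len(sset.conditions), sset.axis_kind)

    gp_cfg = cfg["gp"]
    gp_min = gp_cfg["min_spots"] or min(gp_mod.DEFAULT_MIN_SPOTS, n_spots)
    try:
        trajectory = gp_mod.gp_trajectory(
            sset, min_spots=gp_min, lambda_blue=gp_cfg["blue"],
            lambda_red=gp_cfg["red"], window_points=gp_cfg["window"],
        )
    except Exception as exc:
        raise PipelineError(f"stage gp: {exc}") from exc

    avg_min = cfg["average"]["min_spots"] or min(preprocess.DEFAULT_MIN_SPOTS, n_spots)
    try:
        averaged = SpectrumSet(
            [preprocess.average_spots(sset, c, min_spots=avg_min)
             for c in sset.conditions],
            axis_kind=sset.axis_kind, conditions=list(sset.conditions),
        )
    except Exception as exc:
        raise PipelineError(f"stage average: {exc}") from exc

    try:
        bounds = FitBounds(**{k: tuple(v) for k, v in cfg["bounds"].items()})
        gfit = decomposition.fit_global(averaged, bounds=bounds)
    except Exception as exc:
        raise PipelineError(f"stage decompose: {exc}") from exc
    fractions = decomposition.population_fractions(gfit)
    fractions["individual_r2"] = [gfit.individual_r2[c] for c in gfit.conditions]

    bands = {
        "peak_long_nm": gfit.peak_long_nm,
        "peak_short_nm": gfit.peak_short_nm,
        "nu_m_long": gfit.nu_m_long,
        "nu_m_short": gfit.nu_m_short,
        "converged": gfit.converged,
        "per_condition": {str(c): gfit.models[c].to_dict() for c in gfit.conditions},
    }
    run_info = {
        "package_version": _package_version(),
        "config_hash": _config_hash(cfg),
        "seed": cfg["input"].get("simulate", {}).get("seed"),
        "n_spectra": len(sset),
        "n_conditions": len(sset.conditions),
    }
    report = ReportBundle(
        config=cfg, gp_table=trajectory.table, fraction_table=fractions,
        bands=bands, run_info=run_info, axis_kind=sset.axis_kind, truth=truth,
    )
    if cfg.get("output_dir"):
        report.save(cfg["output_dir"])
        log.info("report written to %s", cfg["output_dir"])
    return report


def compare_trajectories(report_a: ReportBundle, report_b: ReportBundle) -> pd.DataFrame:
    """Aligned per-condition GP and fraction differences (a minus b).

    Both reports must share a condition-axis kind.  Conditions present in
    only one report are kept and flagged in the ``only_in`` column.
    """
    if report_a.axis_kind != report_b.axis_kind:
        raise PipelineError(
            f"incompatible condition axes: {report_a.axis_kind!r} vs "
            f"{report_b.axis_kind!r}"
        )

    def table(report):
        t = report.gp_table[["condition", "mean_gp"]].merge(
            report.fraction_table[["condition", "fraction_long"]], on="condition"
        )
        return t

    merged = table(report_a).merge(
        table(report_b), on="condition", how="outer", suffixes=("_a", "_b"),
        sort=True,
    )
    merged["gp_diff"] = merged["mean_gp_a"] - merged["mean_gp_b"]
    merged["fraction_long_diff"] = (
        merged["fraction_long_a"] - merged["fraction_long_b"]
    )
    only = []
    for _, row in merged.iterrows():
        if pd.isna(row["mean_gp_a"]):
            only.append("b")
        elif pd.isna(row["mean_gp_b"]):
            only.append("a")
        else:
            only.append("")
    merged["only_in"] = only
    return merged
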