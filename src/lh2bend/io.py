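"""Table formats, run configuration and the end-to-end pipeline.

All tables are comma-delimited UTF-8 with one header row and units
embedded in the column names (``diameter_nm``, ``tau_ns``, ...).  Fit
reports are JSON.  Every pipeline run writes a manifest echoing the
resolved configuration and seed, so any run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exciton import DisorderModel, bending_sweep, ellipticity_sweep
from .fitting import (
    REQUIRED_COLUMNS,
    LifetimeSizeModel,
    LifetimeSizeResults,
    LifetimeTable,
)
from .synthetic import SyntheticConfig, generate_lifetime_table


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def read_lifetime_table(path) -> LifetimeTable:
    """Read a delimited lifetime table, validating header and units."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty lifetime table: {path}") from exc
    unit_hints = {
        "tau_ps": "tau_ns",
        "tau_us": "tau_ns",
        "diameter_um": "diameter_nm",
        "diameter_a": "diameter_nm",
    }
    for bad, good in unit_hints.items():
        if bad in frame.columns:
            raise ValueError(
                f"column {bad!r} uses an unsupported unit; "
                f"convert to {good!r}"
            )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"lifetime table missing column(s): {', '.join(missing)}"
        )
    return LifetimeTable(frame)


def write_lifetime_table(table: LifetimeTable, path) -> None:
    """Write a lifetime table (12 significant digits, lossless round trip)."""
    table.data.to_csv(path, index=False, float_format="%.12g")


def write_report(results: LifetimeSizeResults, path) -> None:
    """Write a structured JSON fit report."""
    Path(path).write_text(json.dumps(results.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_STAGES = ("synth", "fit", "exciton_sweep")


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Unknown keys in any block are rejected; every run writes
    ``manifest.json`` echoing the resolved configuration and seed.
    """

    stages: tuple[str, ...] = ("synth", "fit")
    seed: int = 0
    outdir: str = "lh2bend_run"
    synth: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    exciton: dict = field(default_factory=dict)

    _FIT_KEYS = ("input", "d_high", "d_low", "r0", "scan_boundaries")
    _EXCITON_KEYS = (
        "sweep",
        "sphere_diameters",
        "epsilons",
        "epsilon",
        "gamma",
        "n_realizations",
    )

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _STAGES:
                raise ValueError(
                    f"unknown stage {stage!r}; expected one of {_STAGES}"
                )
        synth_keys = {f.name for f in dataclasses.fields(SyntheticConfig)}
        for block, allowed in (
            (self.synth, synth_keys),
            (self.fit, set(self._FIT_KEYS)),
            (self.exciton, set(self._EXCITON_KEYS)),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(
                    f"unknown configuration key(s): {sorted(unknown)}"
                )

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "stages" in raw:
            raw = dict(raw, stages=tuple(raw["stages"]))
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("configuration file must hold a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "stages": list(self.stages),
            "seed": self.seed,
            "outdir": self.outdir,
            "synth": dict(self.synth),
            "fit": dict(self.fit),
            "exciton": dict(self.exciton),
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return artifact paths.

    Stages: ``synth`` writes a synthetic lifetime table; ``fit`` fits a
    lifetime table (the synth output by default) and writes a JSON
    report; ``exciton_sweep`` writes a bending or ellipticity sweep
    table.  Stage failures raise :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if "synth" in config.stages:
        try:
            synth_kwargs = dict(config.synth)
            synth_kwargs.setdefault("seed", config.seed)
            table = generate_lifetime_table(SyntheticConfig(**synth_kwargs))
            path = outdir / "lifetime_table.csv"
            write_lifetime_table(table, path)
            artifacts["synth"] = str(path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("synth", str(exc)) from exc

    if "fit" in config.stages:
        try:
            fit_opts = dict(config.fit)
            source = fit_opts.pop("input", None) or artifacts.get("synth")
            if source is None:
                raise ValueError("fit stage needs an input table")
            scan = bool(fit_opts.pop("scan_boundaries", False))
            table = read_lifetime_table(source)
            model = LifetimeSizeModel(table, **fit_opts)
            results = model.fit(scan_boundaries=scan)
            path = outdir / "fit_report.json"
            write_report(results, path)
            artifacts["fit"] = str(path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc

    if "exciton_sweep" in config.stages:
        try:
            opts = dict(config.exciton)
            sweep = opts.pop("sweep", "bending")
            disorder = DisorderModel(
                gamma=float(opts.pop("gamma", 125.0)),
                n_realizations=int(opts.pop("n_realizations", 200)),
                seed=config.seed,
            )
            if sweep == "bending":
                diameters = opts.pop(
                    "sphere_diameters", list(np.geomspace(40, 400, 8))
                )
                epsilon = float(opts.pop("epsilon", 0.057))
                frame = bending_sweep(
                    diameters, epsilon=epsilon, disorder=disorder
                )
            elif sweep == "ellipticity":
                epsilons = opts.pop("epsilons", list(np.linspace(0, 0.1, 6)))
                frame, fit_stats = ellipticity_sweep(
                    epsilons, disorder=disorder
                )
                frame.attrs["linear_fit"] = fit_stats
            else:
                raise ValueError(f"unknown sweep {sweep!r}")
            path = outdir / f"exciton_{sweep}_sweep.csv"
            frame.to_csv(path, index=False, float_format="%.12g")
            artifacts["exciton_sweep"] = str(path)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("exciton_sweep", str(exc)) from exc

    manifest = {
        "package": "lh2bend",
        "version": __version__,
        "config": config.to_dict(),
        "artifacts": artifacts,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = str(manifest_path)
    return artifacts
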