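"""Experiment orchestration: config handling, fixtures and the full pipeline.

``run_full_pipeline`` chains the package end to end — stochastic two-path
ensemble, equation-free coefficient estimation, reduced-model
re-simulation, and the stationary Fokker-Planck decision metrics — and
writes tidy CSV artifacts plus a JSON report.  The default
``ExperimentConfig`` reproduces the canonical experiment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .efa_reduction import (
    estimate_drift_diffusion,
    simulate_ou,
    simulate_reduced,
    time_average_coefficients,
)
from .fpe_analysis import splitting_probability, potential, stationary_density
from .network_model import (
    ResponseParams,
    maze_network,
    two_path_network,
    write_network,
)
from .twopath_sde import ForcingSpec, TwoPathParams, correctness, risk_ratio, run_ensemble

__all__ = [
    "ExperimentConfig",
    "PipelineError",
    "run_full_pipeline",
    "make_fixtures",
]

log = logging.getLogger("physarum")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass(frozen=True)
class ExperimentConfig:
    """Run controls on top of :class:`TwoPathParams`; defaults = canonical run."""

    params: TwoPathParams = field(default_factory=TwoPathParams)
    n_paths: int = 5000
    base_seed: int = 42
    bin_width: float = 0.04
    reduced_paths: int = 500
    reduced_seed_offset: int = 1

    # -- TOML round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        p = self.params
        return {
            "response": dataclasses.asdict(p.response),
            "forcing": dataclasses.asdict(p.forcing),
            "twopath": {
                "L1": p.L1,
                "L2": p.L2,
                "noise": p.noise,
                "D1_0": p.D1_0,
                "D2_0": p.D2_0,
                "dt": p.step,
                "t_end": p.t_end,
            },
            "run": {
                "n_paths": self.n_paths,
                "base_seed": self.base_seed,
                "bin_width": self.bin_width,
                "reduced_paths": self.reduced_paths,
                "reduced_seed_offset": self.reduced_seed_offset,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        params = TwoPathParams(
            response=ResponseParams(**data["response"]),
            forcing=ForcingSpec(**data["forcing"]),
            **data["twopath"],
        )
        return cls(params=params, **data["run"])

    def to_toml(self, path: str | Path) -> None:
        Path(path).write_text(_emit_toml(self.to_dict()))

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))


def _emit_toml(data: dict) -> str:
    """Minimal TOML writer for the flat section/scalar layout used here."""
    lines: list[str] = []
    for section, values in data.items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            if isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, (int, float)):
                lines.append(f"{key} = {val!r}")
            else:
                lines.append(f'{key} = "{val}"')
        lines.append("")
    return "\n".join(lines)


def run_full_pipeline(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute simulate -> EFA -> reduced model -> FPE and report the metrics.

    Returns a JSON-serialisable report with the risk ratio, terminal
    ensemble statistics, reduced-model agreement, and the splitting-
    probability decision metrics.  With ``out_dir`` set, tidy CSV artifacts
    and ``report.json`` are written; a stage failure raises
    :class:`PipelineError` naming the stage, leaving earlier artifacts on
    disk.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    p = config.params

    stage = "ensemble"
    try:
        log.info("stage %s: %d paths, seed %d", stage, config.n_paths, config.base_seed)
        ens = run_ensemble(p, config.n_paths, config.base_seed, record="full")
        if out is not None:
            pd.DataFrame(
                {"t": ens.times, "mean_c": ens.mean_c, "sd_c": ens.sd_c}
            ).to_csv(out / "ensemble_summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - report the stage, keep artifacts
        raise PipelineError(stage, exc) from exc

    c0 = correctness(p.D1_0, p.D2_0)
    fractions = ens.fractions
    report: dict = {
        "risk_ratio": risk_ratio(p.forcing),
        "c0": c0,
        "n_paths": config.n_paths,
        "base_seed": config.base_seed,
        "terminal_mean_c": ens.terminal_mean_c,
        "terminal_sd_c": float(np.std(ens.terminal_c)),
        "fraction_path1": fractions["path1"],
        "fraction_path2": fractions["path2"],
        "fraction_undecided": fractions["undecided"],
        "decided": bool(abs(ens.terminal_mean_c) >= 0.5),
    }

    stage = "efa"
    try:
        log.info("stage %s: bin width %.3f", stage, config.bin_width)
        table = estimate_drift_diffusion(ens, bin_width=config.bin_width)
        coeffs = time_average_coefficients(table)
        if out is not None:
            table.to_csv(out / "coefficients.csv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "reduced"
    try:
        reduced_seed = config.base_seed + config.reduced_seed_offset
        log.info("stage %s: %d paths, seed %d", stage, config.reduced_paths, reduced_seed)
        red = simulate_reduced(
            table, c0, config.reduced_paths, p.t_end, seed=reduced_seed,
            mode="regime",
        )
        report["reduced_terminal_mean_c"] = red.terminal_mean_c
        report["reduced_seed"] = reduced_seed
        if out is not None:
            pd.DataFrame(
                {"t": red.times, "mean_c": red.mean_c, "sd_c": red.sd_c}
            ).to_csv(out / "reduced_summary.csv", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "fpe"
    try:
        log.info("stage %s", stage)
        prof = splitting_probability(coeffs)
        pot = potential(coeffs)
        dens = stationary_density(coeffs)
        report.update(
            {
                "decision_point": prof.decision_point,
                "integral_p_plus_mid": prof.integral_mid,
                "residual_revision": prof.residual_revision,
            }
        )
        if out is not None:
            pd.DataFrame(
                {
                    "c": prof.grid,
                    "p_plus": prof.p_plus,
                    "p_minus": prof.p_minus,
                    "potential_norm": pot.normalized,
                    "stationary_density": dens.pi,
                }
            ).to_csv(out / "fpe_grids.csv", index=False)
            (out / "report.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return report


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Write deterministic fixture files; returns the paths written.

    Kinds: ``two-path`` (canonical two-tube network plus its TOML config),
    ``maze`` (small maze arena as an edge-list file), ``ou-process``
    (Ornstein-Uhlenbeck sample paths for estimator validation).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if kind == "two-path":
        cfg = ExperimentConfig(base_seed=seed)
        path = out / "twopath_config.toml"
        cfg.to_toml(path)
        written.append(path)
        net_path = out / "twopath_network.txt"
        write_network(two_path_network(), net_path)
        written.append(net_path)
    elif kind == "maze":
        net_path = out / "maze_network.txt"
        write_network(maze_network(), net_path)
        written.append(net_path)
    elif kind == "ou-process":
        x = simulate_ou(seed=seed, n_paths=50, n_steps=400)
        frame = pd.DataFrame(
            x.T, columns=[f"path{i}" for i in range(x.shape[0])]
        )
        frame.insert(0, "t", np.arange(x.shape[1]) * 0.01)
        path = out / "ou_process.csv"
        frame.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
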