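"""Run configuration, serialization and reproducibility glue.

A :class:`RunConfig` collects every knob of an evolutionary run.  Defaults
follow the baseline simulation setting (population size ``N = 100``, cost
``c = 1``, continuation probability ``delta = 0.999``, selection strength
``beta = 1``).  Configurations round-trip losslessly through either JSON or
a flat ``key=value`` text file; explicit keyword overrides take precedence
over file values.

Output files use a fixed column order and 10-significant-digit float
formatting so that identical configurations produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

from .evolution import EvoParams, Trajectory, average_cooperation_rate, strategy_density_grid
from .games import GameSpec, build_donation_game, build_snowdrift_game
from .payoff_memory import MemoryModel

__all__ = ["RunConfig", "parse_config", "write_summary"]

_FLOAT_FMT = "{:.10g}"


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated parameterization of one evolutionary run."""

    game: str = "donation"
    b: float = 3.0
    c: float = 1.0
    delta: float = 0.999
    beta: float = 1.0
    N: int = 100
    memory: str = "perfect"
    k: int = 1
    m: int = 1
    space: str = "reactive"
    steps: int = 100_000
    seed: int = 0
    burnin: float = 0.1
    bins: int = 50
    out: str = "run"

    def __post_init__(self) -> None:
        if self.game not in ("donation", "snowdrift"):
            raise ValueError(f"game: unknown game {self.game!r}")
        if not (0 < self.c < self.b):
            raise ValueError(f"b/c: need 0 < c < b, got b={self.b}, c={self.c}")
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta: {self.delta} outside [0, 1)")
        if self.beta < 0:
            raise ValueError(f"beta: {self.beta} must be >= 0")
        if self.N < 2:
            raise ValueError(f"N: {self.N} must be >= 2")
        if self.memory not in ("perfect", "lastk", "gameavg"):
            raise ValueError(f"memory: unknown model {self.memory!r}")
        if self.k < 1 or self.m < 1:
            raise ValueError("k/m: recall window sizes must be >= 1")
        if self.space not in ("reactive", "memory1"):
            raise ValueError(f"space: unknown strategy space {self.space!r}")
        if self.steps < 1:
            raise ValueError(f"steps: {self.steps} must be >= 1")
        if not (0.0 <= self.burnin < 1.0):
            raise ValueError(f"burnin: {self.burnin} outside [0, 1)")
        if self.bins < 2:
            raise ValueError(f"bins: {self.bins} must be >= 2")

    def game_spec(self) -> GameSpec:
        builder = build_donation_game if self.game == "donation" else build_snowdrift_game
        return builder(self.b, self.c)

    def memory_model(self) -> MemoryModel:
        if self.memory == "perfect":
            return MemoryModel("perfect")
        if self.memory == "gameavg":
            return MemoryModel("game_average")
        return MemoryModel("last_rounds", k=self.k, m=self.m)

    def evo_params(self) -> EvoParams:
        return EvoParams(
            N=self.N,
            beta=self.beta,
            delta=self.delta,
            game=self.game_spec(),
            memory=self.memory_model(),
            strategy_space="reactive" if self.space == "reactive" else "memory_one",
            T=self.steps,
            seed=self.seed,
        )


def parse_config(path: Optional[Union[str, Path]] = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional file plus overrides.

    The file may be JSON (an object of known keys) or a flat text file of
    ``key=value`` lines (``#`` comments allowed).  Unknown keys and
    out-of-range values raise ``ValueError`` naming the offending field;
    keyword overrides win over file values.
    """
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        stripped = text.lstrip()
        if stripped.startswith("{"):
            values = json.loads(text)
        else:
            for line_no, line in enumerate(text.splitlines(), 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {line_no}: expected key=value, got {line!r}")
                key, _, raw = line.partition("=")
                values[key.strip()] = raw.strip()
    values.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(values) - set(known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    coerced = {}
    for f in fields(RunConfig):
        if f.name not in values:
            continue
        raw = values[f.name]
        if f.name in ("game", "memory", "space", "out"):
            coerced[f.name] = str(raw)
        elif f.name in ("N", "k", "m", "steps", "seed", "bins"):
            coerced[f.name] = int(raw)
        else:
            coerced[f.name] = float(raw)
    return RunConfig(**coerced)


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


def write_summary(traj: Trajectory, config: RunConfig, prefix: Union[str, Path]) -> dict:
    """Write ``<prefix>.summary.json``, ``<prefix>.trajectory.tsv`` and
    ``<prefix>.density.tsv`` for a completed run; returns the summary dict.

    The summary reports the burn-in-adjusted cooperation rate, the mean
    generosity among conditionally cooperative residents (those with
    ``p >= 0.9``, sojourn-weighted), and acceptance counts.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    coop = average_cooperation_rate(traj, burn_in=config.burnin)
    p = traj.strategies[:, 1]
    q = traj.strategies[:, 2]
    w = traj.sojourns.astype(float)
    coop_mask = p >= 0.9
    mean_generosity = (
        float((q[coop_mask] * w[coop_mask]).sum() / w[coop_mask].sum())
        if coop_mask.any()
        else float("nan")
    )
    from . import __version__

    summary = {
        "cooperation_rate": coop,
        "mean_generosity_p_ge_0.9": mean_generosity,
        "accepted_invasions": int(traj.accepted.sum()),
        "epochs": int(len(traj.sojourns)),
        "total_steps": traj.total_steps,
        "seed": config.seed,
        "burnin": config.burnin,
        "package_version": __version__,
        "config": asdict(config),
    }
    with open(f"{prefix}.summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cols = (
        ["y", "p", "q"]
        if config.space == "reactive"
        else ["y", "p_cc", "p_cd", "p_dc", "p_dd"]
    )
    with open(f"{prefix}.trajectory.tsv", "w") as fh:
        fh.write("\t".join(["step"] + cols + ["accepted", "sojourn"]) + "\n")
        step = 0
        for row, soj, acc in zip(traj.strategies, traj.sojourns, traj.accepted):
            vals = row[:3] if config.space == "reactive" else row[:5]
            fh.write(
                "\t".join(
                    [str(step)]
                    + [_fmt(v) for v in vals]
                    + ["1" if acc else "0", str(int(soj))]
                )
                + "\n"
            )
            step += int(soj)

    density = strategy_density_grid(traj, bins=config.bins)
    with open(f"{prefix}.density.tsv", "w") as fh:
        fh.write("# sojourn-weighted density over (p, q); rows index p bins\n")
        for row in density:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return summary
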