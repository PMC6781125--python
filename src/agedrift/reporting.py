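"""Experiment orchestration: metric tables, Ne-vs-T sweeps, drift comparisons.

Three canonical experiments, each a plain function returning tidy pandas
objects (CSV/JSON are the canonical outputs; plotting is deliberately left
to the user):

* :func:`metrics_table` — one demography-summary row per population.
* :func:`run_ne_sweep` — Felsenstein Ne against generation time as the
  reproductive schedule is displaced across the age range.
* :func:`run_drift_experiment` — stochastic drift simulations over a grid
  of (population, shift, selection) cells with cross-population summaries.

Every output can be stamped with the resolved configuration and its hash so
a run is reproducible bit-for-bit from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .fecundity import FecunditySchedule, gaussian_schedule, shift_schedule
from .demography import summarize_demography, net_reproduction, felsenstein_ne
from .drift import SimulationConfig, TrajectoryResult, run_simulation, summarize

log = logging.getLogger("agedrift")

__all__ = [
    "ExperimentConfig",
    "metrics_table",
    "run_ne_sweep",
    "run_drift_experiment",
    "config_hash",
]

Population = tuple[LifeTable, FecunditySchedule]


@dataclass(frozen=True)
class ExperimentConfig:
    """A drift-experiment grid: populations × shifts × selection values."""

    shifts: tuple = (0.0,)
    selection: tuple = (0.0,)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | None = None


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def default_populations(k: int = 101) -> dict[str, Population]:
    """The three headline synthetic populations with the standard schedule."""
    from .synthetic import make_fixture

    pops = {}
    for name, family in [
        ("type1_modern", "type1_modern"),
        ("type1_preindustrial", "type1_preindustrial"),
        ("type2", "type2"),
    ]:
        lt = make_fixture(family, k=k)
        pops[name] = (lt, gaussian_schedule(lt))
    return pops


def metrics_table(
    populations: dict[str, Population], N_total: float = 1000.0, **modes
) -> pd.DataFrame:
    """One demography-summary row per population."""
    rows = []
    for name, (lt, fs) in populations.items():
        row = {"population": name}
        row.update(summarize_demography(lt, fs, N_total=N_total, **modes).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_ne_sweep(
    populations: dict[str, Population],
    shifts,
    N_total: float = 1000.0,
    s_mode: str = "survival",
    v_mode: str = "fisher",
) -> pd.DataFrame:
    """(population, shift, T, Ne) rows across a sweep of schedule shifts.

    Invalid cells (e.g. a shift leaving no reproductive mass) are recorded
    with NaN rather than dropped.
    """
    rows = []
    for name, (lt, fs) in populations.items():
        Nnb = N_total / lt.l.sum()
        for delta in shifts:
            row = {"population": name, "shift": float(delta), "Nnb": Nnb}
            try:
                fshift = shift_schedule(lt, fs, delta) if delta else fs
                _, T, _ = net_reproduction(lt, fshift)
                row["T"] = T
                row["Ne"] = felsenstein_ne(
                    lt, fshift, Nnb, s_mode=s_mode, v_mode=v_mode
                )
            except ValueError as err:
                log.warning("ne-sweep cell %s shift=%s invalid: %s", name, delta, err)
                row["T"] = np.nan
                row["Ne"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def run_drift_experiment(
    populations: dict[str, Population], cfg: ExperimentConfig
) -> tuple[dict[tuple, TrajectoryResult], pd.DataFrame]:
    """Run the simulation over every (population, shift, s) cell.

    Returns the raw results keyed by cell and the cross-cell comparison
    table. Per-cell failures are logged and excluded from the table, never
    silently dropped. When ``cfg.out_dir`` is set, mean trajectories,
    final-time values and the summary are written there alongside the
    resolved configuration.
    """
    results: dict[tuple, TrajectoryResult] = {}
    for name, (lt, fs) in populations.items():
        for delta in cfg.shifts:
            for s in cfg.selection:
                sim = replace(cfg.simulation, shift=float(delta), s=float(s))
                key = (name, float(delta), float(s))
                try:
                    results[key] = run_simulation(lt, fs, sim)
                except ValueError as err:
                    log.error("drift cell %s failed: %s", key, err)
    table = summarize({f"{n}|shift={d:+g}|s={s:g}": r for (n, d, s), r in results.items()})
    if cfg.out_dir is not None:
        _write_outputs(cfg, results, table)
    return results, table


def _write_outputs(cfg, results, table) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = {
        "shifts": list(cfg.shifts),
        "selection": list(cfg.selection),
        "simulation": asdict(cfg.simulation),
    }
    resolved["hash"] = config_hash(resolved)
    (out / "config.json").write_text(json.dumps(resolved, indent=2))
    table.assign(config_hash=resolved["hash"]).to_csv(out / "summary.csv", index=False)
    for (name, delta, s), res in results.items():
        stem = f"{name}_shift{delta:+g}_s{s:g}"
        pd.DataFrame(
            {"year": np.arange(1, res.mean_het.size + 1), "mean_het": res.mean_het}
        ).to_csv(out / f"{stem}_mean_trajectory.csv", index=False)
        pd.DataFrame({"final_het": res.final}).to_csv(
            out / f"{stem}_final.csv", index=False
        )
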