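"""Action execution, simulation journaling and parameter scanning.

Actions run in document order and thread state: ``generate_network``
produces the reaction network, ``simulate_ode``/``simulate_ssa`` integrate
from the current concentrations (which they update), ``setParameter`` and
``setConcentration`` mutate state between simulations, ``save``/
``resetConcentrations`` snapshot and restore.  Every simulation writes a
journal directory named ``<model>_<stamp>`` containing the model copy, a
log, and NET/GDAT/CDAT results.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import expr as _expr
from .model import BnglError, Diagnostic, Model
from .netio import write_net
from .network import ReactionNetwork, generate_network
from .parser import parse_species_pattern
from .patterns import canonical_form
from .serializer import serialize_model
from .simulate import simulate_ode, simulate_ssa
from .timeseries import write_timeseries


@dataclass
class RunState:
    network: Optional[ReactionNetwork] = None
    concentrations: Optional[np.ndarray] = None
    overrides: dict[str, float] = field(default_factory=dict)
    saved: Optional[np.ndarray] = None
    journal_dirs: list[Path] = field(default_factory=list)
    log: list[str] = field(default_factory=list)


def _stamp(explicit: Optional[str]) -> str:
    if explicit is not None:
        return explicit
    return _dt.datetime.now().strftime("%Y-%m-%dT%H-%M-%S")


def _ensure_network(model: Model, state: RunState, args: dict) -> None:
    if state.network is None or args:
        max_iter = int(float(args.get("max_iter", 100)))
        max_agg = int(float(args.get("max_agg", 10)))
        state.network = generate_network(model, max_iter=max_iter,
                                         max_agg=max_agg)
        state.concentrations = np.array(
            state.network.initial_amounts(state.overrides))
        state.log.append(
            f"generate_network: {len(state.network.species)} species, "
            f"{len(state.network.reactions)} reactions"
            + (f" (truncated: {state.network.truncation_reason})"
               if state.network.truncated else ""))


def _journal(model: Model, state: RunState, root: Path, stamp: str,
             species_ts, obs_ts) -> Path:
    run_dir = root / f"{model.name}_{stamp}"
    i = 1
    while run_dir.exists():
        i += 1
        run_dir = root / f"{model.name}_{stamp}_{i}"
    run_dir.mkdir(parents=True)
    (run_dir / "model.bngl").write_text(serialize_model(model))
    (run_dir / "model.net").write_text(write_net(state.network))
    (run_dir / "model.cdat").write_text(write_timeseries(species_ts))
    (run_dir / "model.gdat").write_text(write_timeseries(obs_ts))
    (run_dir / "run.log").write_text("\n".join(state.log) + "\n")
    state.journal_dirs.append(run_dir)
    return run_dir


def run_actions(model: Model, journal_root, stamp: Optional[str] = None,
                default_seed: int = 0) -> RunState:
    """Execute the model's actions block, journaling each simulation."""
    root = Path(journal_root)
    state = RunState()
    for action in model.actions:
        if not action.supported:
            state.log.append(f"skipped unsupported action: {action.verb}")
            continue
        args = action.arguments
        if action.verb == "generate_network":
            _ensure_network(model, state, args)
        elif action.verb in ("simulate_ode", "simulate_ssa"):
            _ensure_network(model, state, {})
            t_end = float(args.get("t_end", 10))
            n_steps = int(float(args.get("n_steps", 100)))
            y0 = state.concentrations
            if action.verb == "simulate_ode":
                sp_ts, obs_ts = simulate_ode(
                    state.network, t_end, n_steps,
                    atol=float(args.get("atol", 1e-9)),
                    rtol=float(args.get("rtol", 1e-8)),
                    overrides=state.overrides, y0=y0)
            else:
                sp_ts, obs_ts = simulate_ssa(
                    state.network, t_end, n_steps,
                    seed=int(float(args.get("seed", default_seed))),
                    overrides=state.overrides, y0=y0)
            state.concentrations = sp_ts.values[-1].copy()
            state.log.append(f"{action.verb}: t_end={t_end} "
                             f"n_steps={n_steps}")
            _journal(model, state, root, _stamp(stamp), sp_ts, obs_ts)
        elif action.verb == "setParameter":
            name, value = _two_args(action)
            if name not in model.parameters:
                raise BnglError(Diagnostic(
                    "error", f"setParameter: unknown parameter {name!r}",
                    action.line))
            state.overrides[name] = float(_expr.evaluate(
                value, model.parameters, state.overrides))
            state.log.append(f"setParameter {name} = {state.overrides[name]}")
        elif action.verb == "setConcentration":
            name, value = _two_args(action)
            _ensure_network(model, state, {})
            canon = canonical_form(parse_species_pattern(name))
            for sp in state.network.species:
                if sp.canonical == canon:
                    state.concentrations[sp.index - 1] = float(
                        _expr.evaluate(value, model.parameters,
                                       state.overrides))
                    break
            else:
                raise BnglError(Diagnostic(
                    "error", f"setConcentration: species {name!r} not in "
                    "network", action.line))
            state.log.append(f"setConcentration {name} = {value}")
        elif action.verb == "saveConcentrations":
            if state.concentrations is not None:
                state.saved = state.concentrations.copy()
            state.log.append("saveConcentrations")
        elif action.verb == "resetConcentrations":
            if state.saved is not None:
                state.concentrations = state.saved.copy()
            state.log.append("resetConcentrations")
        elif action.verb == "parameter_scan":
            name = args.get("parameter") or args.get("0")
            values = [float(v) for v in
                      str(args.get("values", "")).split(";") if v]
            scan = parameter_scan(model, name, values, journal_root=root,
                                  stamp=stamp,
                                  t_end=float(args.get("t_end", 10)),
                                  n_steps=int(float(args.get("n_steps",
                                                             100))))
            state.journal_dirs.extend(scan.journal_dirs)
            state.log.append(f"parameter_scan {name}: {len(values)} values")
    return state


def _two_args(action) -> tuple[str, str]:
    items = list(action.arguments.items())
    named = {k: v for k, v in items if not k.isdigit()}
    pos = [v for k, v in items if k.isdigit()]
    if len(pos) >= 2:
        return pos[0].strip('"'), pos[1]
    if len(named) >= 1 and pos:
        k, v = next(iter(named.items()))
        return k, v
    if len(items) >= 2:
        return items[0][1], items[1][1]
    if len(items) == 1:
        return items[0][0], items[0][1]
    raise BnglError(Diagnostic(
        "error", f"action {action.verb} needs two arguments", action.line))


@dataclass
class ScanResult:
    parameter: str
    values: list[float]
    summary: "object"            # pandas DataFrame: final observables
    journal_dirs: list[Path] = field(default_factory=list)


def parameter_scan(model: Model, parameter: str, values,
                   journal_root="journal", stamp: Optional[str] = None,
                   t_end: float = 10.0, n_steps: int = 100,
                   max_iter: int = 100, max_agg: int = 10,
                   method: str = "ode", seed: int = 0) -> ScanResult:
    """One simulation per parameter value, each journaled; the summary
    table holds the final observable values per scan value."""
    import pandas as pd
    if parameter not in model.parameters:
        raise BnglError(Diagnostic(
            "error", f"unknown scan parameter {parameter!r}"))
    root = Path(journal_root)
    result = ScanResult(parameter, [float(v) for v in values], None)
    rows = []
    for i, value in enumerate(result.values):
        state = RunState(overrides={parameter: float(value)})
        _ensure_network(model, state, {"max_iter": max_iter,
                                       "max_agg": max_agg})
        if method == "ode":
            sp_ts, obs_ts = simulate_ode(state.network, t_end, n_steps,
                                         overrides=state.overrides)
        else:
            sp_ts, obs_ts = simulate_ssa(state.network, t_end, n_steps,
                                         seed=seed + i,
                                         overrides=state.overrides)
        state.log.append(f"scan {parameter}={value}")
        run_dir = _journal(model, state, root,
                           _stamp(stamp) + f"_{parameter}_{i}", sp_ts,
                           obs_ts)
        result.journal_dirs.append(run_dir)
        rows.append(dict(zip(obs_ts.labels, obs_ts.values[-1])))
    result.summary = pd.DataFrame(rows, index=pd.Index(result.values,
                                                       name=parameter))
    return result
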