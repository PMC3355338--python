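"""Mass-action simulation of generated reaction networks.

ODE integration uses a stiff-capable SciPy solver over the mass-action
right-hand side assembled from the network's reactions (rate constant ×
statistical factor × product of reactant concentrations).  The stochastic
path is the Gillespie direct method with propensities using falling
factorials for repeated reactants, recorded on the same uniform output
grid the ODE uses (``n_steps + 1`` points including t = 0).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import BnglError, Diagnostic
from .network import ReactionNetwork
from .timeseries import TimeSeries


def _grid(t_end: float, n_steps: int) -> np.ndarray:
    return np.linspace(0.0, float(t_end), int(n_steps) + 1)


def _group_matrix(net: ReactionNetwork) -> tuple[np.ndarray, list[str]]:
    labels = list(net.observable_groups)
    w = np.zeros((len(labels), len(net.species)))
    for gi, name in enumerate(labels):
        for idx, weight in net.observable_groups[name]:
            w[gi, idx - 1] = weight
    return w, labels


def _compile(net: ReactionNetwork, overrides=None):
    """Stoichiometry and rate arrays for the mass-action right-hand side."""
    n_sp = len(net.species)
    k = np.array(net.rate_constants(overrides))
    reactant_idx = [np.array([i - 1 for i in r.reactants], dtype=int)
                    for r in net.reactions]
    stoich = np.zeros((n_sp, len(net.reactions)))
    for j, r in enumerate(net.reactions):
        for i in r.reactants:
            stoich[i - 1, j] -= 1
        for i in r.products:
            stoich[i - 1, j] += 1
    return k, reactant_idx, stoich


def species_labels(net: ReactionNetwork) -> list[str]:
    return [s.canonical for s in net.species]


def simulate_ode(net: ReactionNetwork, t_end: float, n_steps: int = 100,
                 atol: float = 1e-9, rtol: float = 1e-8,
                 overrides: Optional[dict] = None,
                 y0: Optional[np.ndarray] = None
                 ) -> tuple[TimeSeries, TimeSeries]:
    """Deterministic trajectory; returns (species series, observable series)."""
    k, reactant_idx, stoich = _compile(net, overrides)
    if y0 is None:
        y0 = np.array(net.initial_amounts(overrides), dtype=float)
    times = _grid(t_end, n_steps)
    n_rxn = len(net.reactions)

    if all(len(idx) <= 2 for idx in reactant_idx):
        # vectorized bimolecular path: sentinel index -> constant 1
        n_sp = len(net.species)
        r1 = np.array([idx[0] if len(idx) > 0 else n_sp
                       for idx in reactant_idx], dtype=int)
        r2 = np.array([idx[1] if len(idx) > 1 else n_sp
                       for idx in reactant_idx], dtype=int)

        def rhs(_t, y):
            yext = np.append(y, 1.0)
            return stoich @ (k * yext[r1] * yext[r2])
    else:
        def rhs(_t, y):
            flux = k.copy()
            for j in range(n_rxn):
                for i in reactant_idx[j]:
                    flux[j] *= y[i]
            return stoich @ flux

    if n_rxn == 0:
        values = np.tile(y0, (len(times), 1))
        sol_ok, diags = True, []
    else:
        sol = solve_ivp(rhs, (0.0, float(t_end)), y0, method="LSODA",
                        t_eval=times, atol=atol, rtol=rtol)
        sol_ok = sol.success
        diags = [] if sol.success else [
            Diagnostic("error", f"ODE solver failed: {sol.message}")]
        if sol.success:
            values = sol.y.T
        else:
            values = np.full((len(times), len(y0)), np.nan)
            values[:sol.y.shape[1], :] = sol.y.T
    species_ts = TimeSeries(times, values, species_labels(net),
                            solver_ok=sol_ok, diagnostics=diags)
    w, labels = _group_matrix(net)
    obs_ts = TimeSeries(times, values @ w.T, labels, solver_ok=sol_ok,
                        diagnostics=list(diags))
    return species_ts, obs_ts


def simulate_ssa(net: ReactionNetwork, t_end: float, n_steps: int = 100,
                 seed: int = 0, overrides: Optional[dict] = None,
                 y0: Optional[np.ndarray] = None
                 ) -> tuple[TimeSeries, TimeSeries]:
    """Gillespie direct-method trajectory on the output grid.

    Initial amounts are rounded to integers (with a warning when the
    rounding is not exact).  Fixed ``seed`` gives bit-identical reruns.
    """
    rng = np.random.default_rng(seed)
    k, reactant_idx, stoich = _compile(net, overrides)
    if y0 is None:
        y0 = np.array(net.initial_amounts(overrides), dtype=float)
    diags: list[Diagnostic] = []
    if not np.allclose(y0, np.round(y0)):
        diags.append(Diagnostic(
            "warning", "non-integral initial amounts rounded for SSA"))
    y = np.round(y0).astype(np.int64)
    times = _grid(t_end, n_steps)
    out = np.zeros((len(times), len(y)))
    n_rxn = len(net.reactions)
    t = 0.0
    next_rec = 0

    def propensities():
        a = k.copy()
        for j in range(n_rxn):
            idx = reactant_idx[j]
            if len(idx) == 1:
                a[j] *= y[idx[0]]
            elif len(idx) == 2:
                if idx[0] == idx[1]:
                    a[j] *= y[idx[0]] * (y[idx[0]] - 1)
                else:
                    a[j] *= y[idx[0]] * y[idx[1]]
            else:
                for pos, i in enumerate(idx):
                    a[j] *= max(y[i] - list(idx[:pos]).count(i), 0)
        return np.maximum(a, 0.0)

    stoich_cols = [stoich[:, j].astype(np.int64) for j in range(n_rxn)]
    while next_rec < len(times):
        a = propensities() if n_rxn else np.zeros(0)
        a0 = a.sum()
        if not np.isfinite(a0):
            raise BnglError(Diagnostic("error", "propensity overflow in SSA"))
        if a0 <= 0:
            break
        t += rng.exponential(1.0 / a0)
        while next_rec < len(times) and times[next_rec] <= t:
            out[next_rec] = y
            next_rec += 1
        if next_rec >= len(times):
            break
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0, a0),
                                side="right"))
        j = min(j, n_rxn - 1)
        y = y + stoich_cols[j]
    while next_rec < len(times):
        out[next_rec] = y
        next_rec += 1
    species_ts = TimeSeries(times, out, species_labels(net),
                            diagnostics=diags)
    w, labels = _group_matrix(net)
    obs_ts = TimeSeries(times, out @ w.T, labels, diagnostics=list(diags))
    return species_ts, obs_ts
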