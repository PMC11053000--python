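"""ODE simulation and steady-state computation for the stress network.

The system is stiff in the stressed regime (fast cytokine turnover
against slow antioxidant-pool dynamics), so trajectories are integrated
with an implicit BDF method.  Steady states are found by a damped
Newton/hybrid root solve on the right-hand side with the two
phosphorylation-pool conservation constraints substituted in, falling
back to long-horizon integration when the root solve strays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import KineticParameters
from .species import IDX, N_SPECIES, SPECIES, SpeciesState, validate_array
from .topology import ACTIVATE, INHIBIT, NetworkTopology

__all__ = [
    "rhs",
    "simulate",
    "steady_state",
    "fold_change",
    "Trajectory",
    "IntegrationError",
    "SteadyStateError",
    "CompiledModel",
]

#: default solver tolerances (recorded in every Trajectory's metadata)
RTOL = 1e-8
ATOL = 1e-10
#: steady-state residual tolerance: ||rhs||_inf < SS_TOL * max(1, ||x||_inf)
SS_TOL = 1e-8
#: fallback integration horizon for steady-state search, in days
SS_HORIZON = 200.0


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """No steady state within tolerance; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def _hill(x: np.ndarray, K: np.ndarray, n: np.ndarray) -> np.ndarray:
    xp = np.maximum(x, 0.0)
    xn = (xp / K) ** n
    return xn / (1.0 + xn)


class CompiledModel:
    """Array-compiled form of (params, topology) for fast RHS evaluation."""

    def __init__(self, params: KineticParameters, topology: NetworkTopology | None = None):
        params.validate()
        if topology is not None:
            for key, ek in params.edges.items():
                if key not in topology:
                    raise ValueError(f"edge {key[0]}->{key[1]} absent from topology")
                if topology.sign(*key) != ek.sign:
                    raise ValueError(f"edge {key[0]}->{key[1]} sign mismatch with topology")
        self.params = params

        self.basal = np.zeros(N_SPECIES)
        self.deg = np.zeros(N_SPECIES)
        for name, r in params.species.items():
            self.basal[IDX[name]] = r.basal
            self.deg[IDX[name]] = r.deg

        act = [(IDX[s], IDX[t], ek.w, ek.K, ek.n)
               for (s, t), ek in params.edges.items() if ek.sign == ACTIVATE]
        inh = [(IDX[s], IDX[t], ek.K, ek.n)
               for (s, t), ek in params.edges.items() if ek.sign == INHIBIT]
        self.act_src = np.array([a[0] for a in act], dtype=int)
        self.act_tgt = np.array([a[1] for a in act], dtype=int)
        self.act_w = np.array([a[2] for a in act])
        self.act_K = np.array([a[3] for a in act])
        self.act_n = np.array([a[4] for a in act])
        self.inh_src = np.array([a[0] for a in inh], dtype=int)
        self.inh_tgt = np.array([a[1] for a in inh], dtype=int)
        self.inh_K = np.array([a[2] for a in inh])
        self.inh_n = np.array([a[3] for a in inh])

        # pools: (unphospho idx, phospho idx, driver idx, total, kph, K, n, kdeph)
        self.pools = []
        for uname, p in params.pools.items():
            pname = "p" + uname  # irs -> pirs, akt -> pakt
            self.pools.append(
                (IDX[uname], IDX[pname], IDX[p.driver],
                 p.total, p.kph, p.K, p.n, p.kdeph)
            )

    # -----------------------------------------------------------------
    def rhs(self, x: np.ndarray) -> np.ndarray:
        prod = self.basal.copy()
        if self.act_src.size:
            np.add.at(prod, self.act_tgt,
                      self.act_w * _hill(x[self.act_src], self.act_K, self.act_n))
        if self.inh_src.size:
            rep = 1.0 / (1.0 + (np.maximum(x[self.inh_src], 0.0) / self.inh_K) ** self.inh_n)
            # multiple inhibitors on one node compose multiplicatively
            for i in range(self.inh_src.size):
                prod[self.inh_tgt[i]] *= rep[i]
        ddt = prod - self.deg * x
        for iu, ip, idrv, total, kph, K, n, kdeph in self.pools:
            flux = kph * _hill(x[idrv], K, n) * max(x[iu], 0.0) - kdeph * max(x[ip], 0.0)
            ddt[iu] = -flux
            ddt[ip] = flux
        return ddt

    def pool_state(self, split: float = 0.5) -> dict[str, float]:
        """Initial pool partition consistent with the conserved totals."""
        out = {}
        for iu, ip, _, total, *_ in self.pools:
            out[SPECIES[iu]] = total * (1 - split)
            out[SPECIES[ip]] = total * split
        return out

    def default_guess(self) -> np.ndarray:
        """Crude fixed point ignoring interactions: basal/deg, pools half-split."""
        x = np.zeros(N_SPECIES)
        nz = self.deg > 0
        x[nz] = self.basal[nz] / self.deg[nz]
        for iu, ip, _, total, *_ in self.pools:
            x[iu] = total / 2
            x[ip] = total / 2
        return x


@dataclass
class Trajectory:
    """Time-indexed states from one integration run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    metadata: dict = field(default_factory=dict)

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.states[i])

    @property
    def final(self) -> SpeciesState:
        return self.state_at(-1)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, IDX[name]]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def _as_array(state) -> np.ndarray:
    if isinstance(state, SpeciesState):
        return state.to_array()
    return np.asarray(state, dtype=float)


def rhs(state, params: KineticParameters, topology: NetworkTopology | None = None) -> np.ndarray:
    """Time derivative of the state under the given kinetics.

    Non-negativity preserving: any species at zero with non-negative
    regulators has derivative >= 0.  The (irs, pirs) and (akt, pakt)
    rows sum to zero exactly (pool conservation).
    """
    x = _as_array(state)
    validate_array(np.where(np.isfinite(x), np.maximum(x, 0), x))  # finiteness check
    cm = CompiledModel(params, topology)
    return cm.rhs(x)


def simulate(
    state0,
    params: KineticParameters,
    topology: NetworkTopology | None = None,
    duration: float = 35.0,
    output_grid: Sequence[float] | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the network for ``duration`` days from ``state0``.

    Uses the implicit BDF method (the system is stiff under stress).
    The returned trajectory starts exactly at ``state0``; integration
    tolerances are recorded in ``Trajectory.metadata``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    x0 = _as_array(state0)
    validate_array(x0)
    if output_grid is None:
        t_eval = np.linspace(0.0, duration, 101)
    else:
        t_eval = np.asarray(output_grid, dtype=float)
        if t_eval.min() < 0 or t_eval.max() > duration:
            raise ValueError("output grid must lie within [0, duration]")
    cm = CompiledModel(params, topology)
    sol = solve_ivp(
        lambda t, x: cm.rhs(x),
        (0.0, duration),
        x0,
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"ODE solver failed: {sol.message}", last_time=last)
    return Trajectory(
        times=sol.t,
        states=sol.y.T.copy(),
        metadata={"solver": "BDF", "rtol": rtol, "atol": atol},
    )


def _ss_residual(cm: CompiledModel, x: np.ndarray) -> np.ndarray:
    """RHS with pool-conservation rows substituted for root finding."""
    r = cm.rhs(x)
    for iu, ip, _, total, *_ in cm.pools:
        r[iu] = x[iu] + x[ip] - total  # pins the conserved total
    return r


def steady_state(
    params: KineticParameters,
    topology: NetworkTopology | None = None,
    guess=None,
    tol: float = SS_TOL,
) -> SpeciesState:
    """Deterministic steady state of the network.

    Root-solves the stationarity conditions (with pool totals pinned),
    verified by ``||rhs||_inf < tol * max(1, ||x||_inf)``; falls back to
    integrating ``SS_HORIZON`` days when the root solve leaves the
    physical (non-negative) orthant.  Bit-stable for fixed parameters.
    """
    cm = CompiledModel(params, topology)
    x0 = cm.default_guess() if guess is None else _as_array(guess)

    best_resid = np.inf
    for attempt in range(3):
        sol = root(lambda x: _ss_residual(cm, x), x0, method="hybr")
        x = sol.x
        resid = float(np.abs(cm.rhs(np.maximum(x, 0.0))).max())
        scale = max(1.0, float(np.abs(x).max()))
        if resid < tol * scale and x.min() > -1e-9:
            xq = np.maximum(x, 0.0)
            return SpeciesState.from_array(xq)
        best_resid = min(best_resid, resid)
        # relax towards the attractor, then retry the root solve
        traj = simulate(np.maximum(x0 if attempt == 0 else x, 0.0), params, topology,
                        duration=SS_HORIZON, output_grid=[0.0, SS_HORIZON],
                        rtol=1e-8, atol=1e-12)
        x0 = np.maximum(traj.states[-1], 0.0)
        resid = float(np.abs(cm.rhs(x0)).max())
        if resid < tol * max(1.0, float(np.abs(x0).max())):
            return SpeciesState.from_array(x0)
        best_resid = min(best_resid, resid)
    raise SteadyStateError(
        f"no steady state within tolerance {tol}; final residual {best_resid:.3e}",
        residual=best_resid,
    )


def fold_change(pre_value: float, post_value: float) -> float:
    """Ratio ``pre/post`` of a marker between two conditions."""
    if post_value == 0:
        raise ZeroDivisionError("post value is zero; fold change undefined")
    if pre_value <= 0 or post_value < 0:
        raise ValueError("fold change requires positive marker values")
    return pre_value / post_value
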