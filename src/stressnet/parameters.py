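"""Kinetic parameters: rate constants, edge kinetics, pools, stress gains.

The rate law for an ordinary species ``x`` is

    dx/dt = [ b_x + sum_a w_a * hill(src_a; K_a, n_a) ]
            * prod_i 1 / (1 + (src_i / K_i)^n_i)   -  d_x * x

where the sum runs over activating edges into ``x`` and the product over
inhibiting edges, ``hill(s; K, n) = s^n / (K^n + s^n)``.  The two
phosphorylation pools (IRS/pIRS, AKT/pAKT) interconvert with a
driver-dependent forward rate and a constant back rate, conserving the
pool total.

All rates are per day; concentrations are in the units declared in
:mod:`stressnet.species`.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .species import SPECIES, InvalidStateError
from .topology import ACTIVATE, INHIBIT, Edge, NetworkTopology


class InvalidParameterError(ValueError):
    """A rate constant is non-finite, non-positive or otherwise out of range."""


@dataclass
class SpeciesRates:
    """Basal production (units/day) and first-order degradation (1/day)."""

    basal: float
    deg: float


@dataclass
class EdgeKinetics:
    """Kinetics of one signed edge.

    ``w`` is the maximal flux contributed by an activating edge (ignored
    for inhibiting edges), ``K`` the half-saturation constant and ``n``
    the Hill coefficient (>= 1).
    """

    sign: str
    K: float
    n: float = 1.0
    w: float = 0.0


@dataclass
class PoolKinetics:
    """Two-state phosphorylation pool (e.g. IRS <-> pIRS).

    forward flux = kph * hill(driver; K, n) * unphosphorylated
    back flux    = kdeph * phosphorylated
    """

    total: float
    driver: str
    kph: float
    K: float
    n: float
    kdeph: float


@dataclass
class StressGains:
    """Calibration constants mapping stress severities onto parameters.

    * ``alpha_inf``   - scales the LPS -> NF-kB activation weight
    * ``beta_keap1``  - scales KEAP1 production (suppressing NRF2)
    * ``beta_sod``    - divides SOD basal production
    * ``beta_ros``    - scales basal ROS generation
    * ``gamma_irs``   - scales IRS serine-phosphorylation rate
    * ``gamma_akt``   - scales AKT phosphorylation rate
    """

    alpha_inf: float = 1.0
    beta_keap1: float = 1.0
    beta_sod: float = 1.0
    beta_ros: float = 1.0
    gamma_irs: float = 1.0
    gamma_akt: float = 1.0


@dataclass
class KineticParameters:
    """Complete kinetic parameterisation of the network."""

    species: dict[str, SpeciesRates]
    edges: dict[tuple[str, str], EdgeKinetics]
    pools: dict[str, PoolKinetics] = field(default_factory=dict)
    stress_gains: StressGains = field(default_factory=StressGains)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        for name in SPECIES:
            if name in ("pirs", "pakt"):
                continue  # governed by pools
            if name not in self.species and name not in self.pools:
                raise InvalidParameterError(f"missing rates for species '{name}'")
        for name, r in self.species.items():
            if name not in SPECIES:
                raise InvalidParameterError(f"unknown species '{name}'")
            if not np.isfinite(r.basal) or r.basal < 0:
                raise InvalidParameterError(f"basal rate of '{name}' invalid: {r.basal!r}")
            if not np.isfinite(r.deg) or r.deg <= 0:
                raise InvalidParameterError(f"degradation rate of '{name}' invalid: {r.deg!r}")
        for (src, tgt), ek in self.edges.items():
            label = f"{src}->{tgt}"
            if ek.sign not in (ACTIVATE, INHIBIT):
                raise InvalidParameterError(f"edge '{label}' has bad sign {ek.sign!r}")
            if not np.isfinite(ek.K) or ek.K <= 0:
                raise InvalidParameterError(f"edge '{label}' half-saturation invalid: {ek.K!r}")
            if not np.isfinite(ek.n) or ek.n < 1:
                raise InvalidParameterError(f"edge '{label}' Hill coefficient invalid: {ek.n!r}")
            if ek.sign == ACTIVATE and (not np.isfinite(ek.w) or ek.w < 0):
                raise InvalidParameterError(f"edge '{label}' weight invalid: {ek.w!r}")
        for pname, p in self.pools.items():
            for attr in ("total", "kph", "K", "kdeph"):
                v = getattr(p, attr)
                if not np.isfinite(v) or v <= 0:
                    raise InvalidParameterError(f"pool '{pname}' {attr} invalid: {v!r}")
            if p.n < 1:
                raise InvalidParameterError(f"pool '{pname}' Hill coefficient invalid: {p.n!r}")
        for fname, v in asdict(self.stress_gains).items():
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"stress gain '{fname}' invalid: {v!r}")

    # -- derived topology -------------------------------------------------
    def topology(self) -> NetworkTopology:
        return NetworkTopology(
            edges=tuple(Edge(s, t, ek.sign) for (s, t), ek in self.edges.items())
        )

    def copy(self) -> "KineticParameters":
        return copy.deepcopy(self)

    # -- multipliers (population heterogeneity) ---------------------------
    def scaled(self, multipliers: Mapping[str, float]) -> "KineticParameters":
        """Return a copy with named parameters multiplied by factors.

        Keys are dotted paths, e.g. ``species.ros.basal``,
        ``edge.lps->nfkb.w``, ``pool.irs.kph``, ``stress.alpha_inf``.
        """
        p = self.copy()
        for path, factor in multipliers.items():
            if not np.isfinite(factor) or factor <= 0:
                raise InvalidParameterError(f"multiplier for '{path}' invalid: {factor!r}")
            kind, _, rest = path.partition(".")
            if kind == "species":
                name, _, attr = rest.partition(".")
                setattr(p.species[name], attr, getattr(p.species[name], attr) * factor)
            elif kind == "edge":
                key, _, attr = rest.partition(".")
                src, _, tgt = key.partition("->")
                ek = p.edges[(src, tgt)]
                setattr(ek, attr, getattr(ek, attr) * factor)
            elif kind == "pool":
                name, _, attr = rest.partition(".")
                setattr(p.pools[name], attr, getattr(p.pools[name], attr) * factor)
            elif kind == "stress":
                setattr(p.stress_gains, rest, getattr(p.stress_gains, rest) * factor)
            else:
                raise InvalidParameterError(f"unknown parameter path '{path}'")
        return p

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": {k: asdict(v) for k, v in self.species.items()},
            "edges": {
                f"{s}->{t}": asdict(ek) for (s, t), ek in self.edges.items()
            },
            "pools": {k: asdict(v) for k, v in self.pools.items()},
            "stress_gains": asdict(self.stress_gains),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        species = {k: SpeciesRates(**v) for k, v in d["species"].items()}
        edges = {}
        for key, ev in d["edges"].items():
            src, _, tgt = key.partition("->")
            edges[(src, tgt)] = EdgeKinetics(**ev)
        pools = {k: PoolKinetics(**v) for k, v in d.get("pools", {}).items()}
        gains = StressGains(**d.get("stress_gains", {}))
        return cls(species=species, edges=edges, pools=pools, stress_gains=gains)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "KineticParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KineticParameters):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _defaults_dir() -> Path:
    return Path(__file__).parent / "_defaults"


def healthy_parameters() -> KineticParameters:
    """The shipped calibrated healthy parameter set.

    Its steady state satisfies all healthy biomarker ranges; applying the
    full-severity stress scenario reproduces the calibrated stressed
    condition.
    """
    return KineticParameters.from_json(_defaults_dir() / "model_params.json")


def healthy_state_array() -> np.ndarray:
    """The cached healthy steady state shipped with the default parameters."""
    d = json.loads((_defaults_dir() / "healthy_state.json").read_text())
    return np.array([d[name] for name in SPECIES], dtype=float)
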