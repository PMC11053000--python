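"""Construction of the structural parameter set.

The network's kinetic parameters are organised so that the healthy
steady state is exact by construction: every edge is specified by the
*fraction* of its target's healthy gross production that it contributes,
together with its half-saturation constant and Hill coefficient.  Edge
weights and basal rates are then solved from the prescribed healthy
state:

    P* = d * x* / prod(repression factors at healthy state)
    w_e = frac_e * P* / hill(src*; K_e, n_e)
    b   = P* * (1 - sum of fracs)

This module holds the structural design (which the calibration stages
re-build with adjusted knobs); the shipped calibrated parameter file in
``_defaults/`` is generated from it by ``scripts/build_defaults.py``.
"""

from __future__ import annotations

from .parameters import (
    EdgeKinetics,
    KineticParameters,
    PoolKinetics,
    SpeciesRates,
    StressGains,
)
from .topology import ACTIVATE, INHIBIT

#: prescribed healthy steady state (model units; tnfa pg/mL, cortisol ng/mL)
HEALTHY_TARGETS: dict[str, float] = {
    "nfkb": 1.0, "tnfa": 1.0e-4, "il6": 1.0, "il10": 1.0, "lps": 1.0,
    "stat3": 1.0, "jak1": 1.0, "mapk": 1.0,
    "nrf2": 1.0, "keap1": 1.0, "ros": 1.0, "sod": 1.0, "cat": 1.0,
    "gpx": 1.0, "gsh": 1.0, "mda": 1.0,
    "pi3k": 1.0, "mtor": 1.0, "ampk": 1.0, "foxo1_cyt": 1.0,
    "hif1a": 1.0, "crh": 1.0, "acth": 1.0, "cortisol": 10.0,
    "renin": 1.0, "ang2": 1.0, "aldosterone": 1.0,
    "insulin": 1.0, "glucagon": 1.0, "glucose": 5.0,
}

#: healthy phosphorylated fraction of the IRS and AKT pools
POOL_TOTALS = {"irs": 1.0, "akt": 1.0}
POOL_PHOSPHO_HEALTHY = {"irs": 0.2, "akt": 0.2}
POOL_DRIVERS = {"irs": "insulin", "akt": "pi3k"}

#: degradation rates (1/day); uniform turnover of one day
DEG_RATE = 1.0

#: structural edge table: (src, tgt, sign, frac, K, n).
#: ``frac`` is the share of the target's healthy gross production
#: contributed by the edge (None for inhibiting edges).
EDGE_SPECS: list[tuple[str, str, str, float | None, float, float]] = [
    # inflammatory arm; the LPS -> NF-kB edge is an ultrasensitive switch
    ("lps", "nfkb", ACTIVATE, 0.85, 2.0, 4.0),
    ("il10", "nfkb", INHIBIT, None, 3.0, 1.0),
    ("nfkb", "tnfa", ACTIVATE, 0.80, 100.0, 1.0),
    ("nfkb", "il6", ACTIVATE, 0.70, 100.0, 1.0),
    ("nfkb", "mapk", ACTIVATE, 0.60, 50.0, 1.0),
    ("mapk", "il6", ACTIVATE, 0.10, 50.0, 1.0),
    ("il6", "jak1", ACTIVATE, 0.80, 40.0, 1.0),
    ("jak1", "stat3", ACTIVATE, 0.80, 20.0, 1.0),
    ("stat3", "il10", ACTIVATE, 0.60, 20.0, 1.0),
    # oxidative arm
    ("keap1", "nrf2", INHIBIT, None, 1.0, 2.0),
    ("nrf2", "sod", ACTIVATE, 0.70, 1.0, 2.0),
    ("nrf2", "cat", ACTIVATE, 0.60, 1.0, 1.0),
    ("nrf2", "gpx", ACTIVATE, 0.60, 1.0, 1.0),
    ("nrf2", "gsh", ACTIVATE, 0.50, 1.0, 1.0),
    ("sod", "ros", INHIBIT, None, 0.5, 2.0),
    ("gsh", "ros", INHIBIT, None, 1.0, 1.0),
    ("ros", "mda", ACTIVATE, 0.80, 5.0, 1.0),
    # insulin-signalling arm
    ("insulin", "pi3k", ACTIVATE, 0.50, 1.0, 1.0),
    ("pakt", "foxo1_cyt", ACTIVATE, 0.80, 1.0, 1.0),
    ("pakt", "mtor", ACTIVATE, 0.50, 1.0, 1.0),
    ("ampk", "mtor", INHIBIT, None, 2.0, 1.0),
    ("foxo1_cyt", "lps", ACTIVATE, 0.80, 10.0, 1.0),
    # HPA axis
    ("ros", "hif1a", ACTIVATE, 0.80, 5.0, 1.0),
    ("hif1a", "crh", ACTIVATE, 0.45, 3.0, 1.0),
    ("il6", "crh", ACTIVATE, 0.45, 30.0, 1.0),
    ("crh", "acth", ACTIVATE, 0.90, 12.0, 1.0),
    ("acth", "cortisol", ACTIVATE, 0.50, 6.25, 2.0),
    # renin-angiotensin axis
    ("tnfa", "renin", ACTIVATE, 0.35, 0.01, 1.0),
    ("cortisol", "renin", ACTIVATE, 0.22, 40.0, 2.0),
    ("renin", "ang2", ACTIVATE, 0.80, 20.0, 1.0),
    ("ang2", "aldosterone", ACTIVATE, 0.80, 10.0, 1.0),
]


def _hill(x: float, K: float, n: float) -> float:
    xn = (x / K) ** n
    return xn / (1.0 + xn)


def build_structural(
    edge_overrides: dict[tuple[str, str], dict] | None = None,
    stress_gains: StressGains | None = None,
) -> KineticParameters:
    """Build the parameter set from the structural tables.

    ``edge_overrides`` maps ``(src, tgt)`` to replacement entries for
    the ``frac`` / ``K`` / ``n`` columns (used by the calibration
    stages); the healthy steady state stays exact for any override.
    """
    overrides = edge_overrides or {}
    specs = []
    for src, tgt, sign, frac, K, n in EDGE_SPECS:
        o = overrides.get((src, tgt), {})
        specs.append((src, tgt, sign,
                      o.get("frac", frac), o.get("K", K), o.get("n", n)))

    # repression factors and activation fractions per target at x*
    rep: dict[str, float] = {}
    frac_sum: dict[str, float] = {}
    for src, tgt, sign, frac, K, n in specs:
        if sign == INHIBIT:
            rep[tgt] = rep.get(tgt, 1.0) / (1.0 + (HEALTHY_TARGETS[src] / K) ** n)
        else:
            frac_sum[tgt] = frac_sum.get(tgt, 0.0) + frac
    for tgt, s in frac_sum.items():
        if s >= 1.0:
            raise ValueError(f"activation fractions into '{tgt}' must sum below 1 (got {s})")

    species: dict[str, SpeciesRates] = {}
    for name, xstar in HEALTHY_TARGETS.items():
        gross = DEG_RATE * xstar / rep.get(name, 1.0)
        species[name] = SpeciesRates(
            basal=gross * (1.0 - frac_sum.get(name, 0.0)), deg=DEG_RATE
        )

    edges: dict[tuple[str, str], EdgeKinetics] = {}
    for src, tgt, sign, frac, K, n in specs:
        if sign == INHIBIT:
            edges[(src, tgt)] = EdgeKinetics(sign=sign, K=K, n=n)
        else:
            src_h = (POOL_TOTALS[src[1:]] * POOL_PHOSPHO_HEALTHY[src[1:]]
                     if src in ("pirs", "pakt") else HEALTHY_TARGETS[src])
            gross = DEG_RATE * HEALTHY_TARGETS[tgt] / rep.get(tgt, 1.0)
            edges[(src, tgt)] = EdgeKinetics(
                sign=sign, K=K, n=n, w=frac * gross / _hill(src_h, K, n)
            )

    pools: dict[str, PoolKinetics] = {}
    for pname, total in POOL_TOTALS.items():
        phos = POOL_PHOSPHO_HEALTHY[pname] * total
        unphos = total - phos
        driver = POOL_DRIVERS[pname]
        K, n = 1.0, 1.0
        kdeph = 1.0
        kph = kdeph * phos / (_hill(HEALTHY_TARGETS[driver], K, n) * unphos)
        pools[pname] = PoolKinetics(total=total, driver=driver,
                                    kph=kph, K=K, n=n, kdeph=kdeph)

    params = KineticParameters(
        species=species, edges=edges, pools=pools,
        stress_gains=stress_gains or StressGains(),
    )
    params.validate()
    return params


def healthy_state_targets() -> dict[str, float]:
    """The prescribed healthy steady state including pool species."""
    out = dict(HEALTHY_TARGETS)
    for pname, total in POOL_TOTALS.items():
        phos = POOL_PHOSPHO_HEALTHY[pname] * total
        out["p" + pname] = phos
        out[pname] = total - phos
    return out
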