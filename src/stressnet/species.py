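"""Species registry and state container for the stress-signalling network.

The model tracks activities/concentrations of the molecular species that
link the four stress axes: inflammatory (LPS -> NF-kB -> TNF-a / IL-6),
oxidative (NRF2-KEAP1 -> SOD/CAT/GPx/GSH vs ROS), mental (HPA axis:
CRH -> ACTH -> cortisol, fed by HIF-1a and IL-6) and physical
(renin -> angiotensin II -> aldosterone, read out as blood pressure).

Units are fixed per field: TNF-a in pg/mL, cortisol in ng/mL, everything
else in abstract model units normalised so that the healthy steady state
of most species is close to 1.  They are never rescaled internally; the
clinical read-outs (ROS production %, SBP, PSS) are derived from this
state by :mod:`stressnet.biomarkers`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterator

import numpy as np

#: Canonical species ordering.  The state vector, parameter files and CSV
#: trajectory columns all follow this order.
SPECIES: tuple[str, ...] = (
    # inflammatory core
    "nfkb", "tnfa", "il6", "il10", "lps", "stat3", "jak1", "mapk",
    # oxidative core
    "nrf2", "keap1", "ros", "sod", "cat", "gpx", "gsh", "mda",
    # insulin signalling (phospho-pools conserve irs+pirs and akt+pakt)
    "irs", "pirs", "akt", "pakt", "pi3k", "mtor", "ampk", "foxo1_cyt",
    # HPA axis
    "hif1a", "crh", "acth", "cortisol",
    # renin-angiotensin system
    "renin", "ang2", "aldosterone",
    # metabolic context
    "insulin", "glucagon", "glucose",
)

N_SPECIES = len(SPECIES)

#: index lookup, species name -> position in the state vector
IDX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Display units for reporting.  Species without a clinical unit are in
#: dimensionless model units ("mu").
UNITS: dict[str, str] = {name: "mu" for name in SPECIES}
UNITS["tnfa"] = "pg/mL"
UNITS["cortisol"] = "ng/mL"


class InvalidStateError(ValueError):
    """Raised when a state or parameter value is non-finite or negative."""


@dataclass
class SpeciesState:
    """Concentrations/activities of all modelled species at one time point.

    All fields are non-negative reals.  ``irs + pirs`` and ``akt + pakt``
    are conserved pool totals along any trajectory.
    """

    nfkb: float = 0.0
    tnfa: float = 0.0
    il6: float = 0.0
    il10: float = 0.0
    lps: float = 0.0
    stat3: float = 0.0
    jak1: float = 0.0
    mapk: float = 0.0
    nrf2: float = 0.0
    keap1: float = 0.0
    ros: float = 0.0
    sod: float = 0.0
    cat: float = 0.0
    gpx: float = 0.0
    gsh: float = 0.0
    mda: float = 0.0
    irs: float = 0.0
    pirs: float = 0.0
    akt: float = 0.0
    pakt: float = 0.0
    pi3k: float = 0.0
    mtor: float = 0.0
    ampk: float = 0.0
    foxo1_cyt: float = 0.0
    hif1a: float = 0.0
    crh: float = 0.0
    acth: float = 0.0
    cortisol: float = 0.0
    renin: float = 0.0
    ang2: float = 0.0
    aldosterone: float = 0.0
    insulin: float = 0.0
    glucagon: float = 0.0
    glucose: float = 0.0

    def __post_init__(self) -> None:
        if tuple(f.name for f in fields(self)) != SPECIES:
            raise AssertionError("SpeciesState fields out of sync with SPECIES")

    # -- array conversion -------------------------------------------------
    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "SpeciesState":
        x = np.asarray(x, dtype=float)
        if x.shape != (N_SPECIES,):
            raise InvalidStateError(
                f"state vector must have shape ({N_SPECIES},), got {x.shape}"
            )
        return cls(**{name: float(x[i]) for i, name in enumerate(SPECIES)})

    def validate(self) -> None:
        """Raise :class:`InvalidStateError` naming the first offending field."""
        for name in SPECIES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidStateError(f"species '{name}' is not finite: {v!r}")
            if v < 0:
                raise InvalidStateError(f"species '{name}' is negative: {v!r}")

    def __iter__(self) -> Iterator[tuple[str, float]]:
        for name in SPECIES:
            yield name, getattr(self, name)

    def replace(self, **kwargs: float) -> "SpeciesState":
        """Return a copy with the given fields overridden."""
        d = dict(self)
        d.update(kwargs)
        return SpeciesState(**d)


def validate_array(x: np.ndarray) -> None:
    """Array-level counterpart of :meth:`SpeciesState.validate`."""
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        raise InvalidStateError(
            f"species '{SPECIES[int(np.argmax(bad))]}' is not finite"
        )
    neg = x < 0
    if neg.any():
        raise InvalidStateError(
            f"species '{SPECIES[int(np.argmax(neg))]}' is negative"
        )
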