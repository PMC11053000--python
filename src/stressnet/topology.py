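"""Signed interaction topology of the stress network.

The topology is a directed signed edge list.  It is fixed at
construction; kinetic strengths for each edge live in
:class:`stressnet.parameters.KineticParameters`.  Activating edges add a
saturating (Hill) production term to the target; inhibiting edges
multiply the target's production by a repression factor.

Two phosphorylation pools (IRS/pIRS and AKT/pAKT) are handled as
two-state interconversions that conserve the pool total; their drivers
are listed in the parameter set rather than as plain edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .species import SPECIES

ACTIVATE = "activate"
INHIBIT = "inhibit"


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # ACTIVATE or INHIBIT

    def __post_init__(self) -> None:
        if self.source not in SPECIES:
            raise ValueError(f"unknown source species '{self.source}'")
        if self.target not in SPECIES:
            raise ValueError(f"unknown target species '{self.target}'")
        if self.sign not in (ACTIVATE, INHIBIT):
            raise ValueError(f"edge sign must be activate/inhibit, got '{self.sign}'")


#: The default signed edges of the network.  Each is traceable to a
#: qualitative statement about the underlying biology: LPS activates
#: NF-kB; NF-kB drives TNF-a and IL-6; IL-10 represses NF-kB; KEAP1
#: represses NRF2 while NRF2 induces the antioxidant arm (SOD, CAT, GPx,
#: GSH) which clears ROS; ROS drives MDA and HIF-1a; the HPA axis runs
#: HIF-1a/IL-6 -> CRH -> ACTH -> cortisol; TNF-a engages the
#: renin-angiotensin axis ending in aldosterone (blood pressure is a
#: derived read-out); and insulin signalling feeds inflammation through
#: pAKT-driven cytosolic FOXO1 accumulation triggering LPS activation.
DEFAULT_EDGES: tuple[tuple[str, str, str], ...] = (
    # inflammatory arm
    ("lps", "nfkb", ACTIVATE),
    ("il10", "nfkb", INHIBIT),
    ("nfkb", "tnfa", ACTIVATE),
    ("nfkb", "il6", ACTIVATE),
    ("nfkb", "mapk", ACTIVATE),
    ("mapk", "il6", ACTIVATE),
    ("il6", "jak1", ACTIVATE),
    ("jak1", "stat3", ACTIVATE),
    ("stat3", "il10", ACTIVATE),
    # oxidative arm
    ("keap1", "nrf2", INHIBIT),
    ("nrf2", "sod", ACTIVATE),
    ("nrf2", "cat", ACTIVATE),
    ("nrf2", "gpx", ACTIVATE),
    ("nrf2", "gsh", ACTIVATE),
    ("sod", "ros", INHIBIT),
    ("gsh", "ros", INHIBIT),
    ("ros", "mda", ACTIVATE),
    # insulin-signalling arm (pool drivers are separate; see parameters)
    ("insulin", "pi3k", ACTIVATE),
    ("pakt", "foxo1_cyt", ACTIVATE),
    ("pakt", "mtor", ACTIVATE),
    ("foxo1_cyt", "lps", ACTIVATE),
    ("ampk", "mtor", INHIBIT),
    # HPA axis (mental stress)
    ("ros", "hif1a", ACTIVATE),
    ("hif1a", "crh", ACTIVATE),
    ("il6", "crh", ACTIVATE),
    ("crh", "acth", ACTIVATE),
    ("acth", "cortisol", ACTIVATE),
    # renin-angiotensin axis (physical stress); cortisol contributes a
    # glucocorticoid-hypertension drive
    ("tnfa", "renin", ACTIVATE),
    ("cortisol", "renin", ACTIVATE),
    ("renin", "ang2", ACTIVATE),
    ("ang2", "aldosterone", ACTIVATE),
)


@dataclass(frozen=True)
class NetworkTopology:
    """Immutable directed signed edge list."""

    edges: tuple[Edge, ...] = field(
        default_factory=lambda: tuple(Edge(*e) for e in DEFAULT_EDGES)
    )

    def __contains__(self, key: tuple[str, str]) -> bool:
        return any((e.source, e.target) == key for e in self.edges)

    def sign(self, source: str, target: str) -> str:
        for e in self.edges:
            if (e.source, e.target) == (source, target):
                return e.sign
        raise KeyError(f"no edge {source} -> {target}")

    def incoming(self, target: str) -> list[Edge]:
        return [e for e in self.edges if e.target == target]

    @property
    def nodes(self) -> set[str]:
        s: set[str] = set()
        for e in self.edges:
            s.add(e.source)
            s.add(e.target)
        return s


def default_topology() -> NetworkTopology:
    return NetworkTopology()
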