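"""Bell-model FnIII domain unfolding and its contour-length bookkeeping.

A folded FnIII module under tension ``f`` unfolds stochastically with a
force-accelerated rate ``k(f) = k0 * exp(f * delta_x / (kB*T))``.  Per
Monte-Carlo time step ``dt`` the unfolding probability is the first-order
form ``p = min(1, k(f) * dt)``, which for the simulation's 0.73 ms step
agrees with the exponential-survival form to O(p^2).

Bookkeeping per unfolding event: the folded backbone loses 3.5 nm of
contour (the footprint of the folded beta-sandwich along the chain) and a
new 32 nm strand with 0.42 nm persistence length — an unstructured amino
acid chain — is inserted in series.  The net contour gain is therefore
28.5 nm, 23.75% of the 120 nm folded dimer contour.  Unfolded domains
never refold.

The dimer carries two copies of each of the 15 unique FnIII types.  Rate
parameters exist for only some types; the rest alias FnIII-12 (see
``data/domain_params.yaml``, which is plain YAML and editable).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .polymer_core import DEFAULT_CONTEXT, ThermalContext, SerialChain, WLCSegment

__all__ = [
    "FOLDED_CONTOUR_NM",
    "FOLDED_PERSISTENCE_NM",
    "UNFOLDED_SEGMENT_NM",
    "UNFOLDED_PERSISTENCE_NM",
    "FOLD_CONTOUR_LOSS_NM",
    "NET_CONTOUR_GAIN_NM",
    "DOMAIN_COPIES_PER_DIMER",
    "DomainParams",
    "DomainState",
    "DomainTable",
    "MoleculeState",
    "load_domain_table",
    "default_domain_table",
    "new_molecule",
    "unfold_probability",
    "poll_unfolding",
    "apply_unfolding",
    "init_unfolded",
    "UNFOLDED_PRESETS",
]

FOLDED_CONTOUR_NM = 120.0
FOLDED_PERSISTENCE_NM = 14.0
UNFOLDED_SEGMENT_NM = 32.0
UNFOLDED_PERSISTENCE_NM = 0.42
FOLD_CONTOUR_LOSS_NM = 3.5
NET_CONTOUR_GAIN_NM = UNFOLDED_SEGMENT_NM - FOLD_CONTOUR_LOSS_NM  # 28.5
DOMAIN_COPIES_PER_DIMER = 2

#: Which domains start unfolded in the relaxed fiber for the named presets.
#: Preset 4 is "four domains carrying FnIII-12 parameters": the two genuine
#: FnIII-12 copies plus both copies of the first FnIII-12-aliased type.
UNFOLDED_PRESETS: dict[int, tuple[str, ...]] = {
    0: (),
    4: ("FnIII-12", "FnIII-12", "FnIII-6", "FnIII-6"),
    8: (
        "FnIII-2",
        "FnIII-2",
        "T-FnIII-3",
        "T-FnIII-3",
        "FnIII-9",
        "FnIII-9",
        "FnIII-12",
        "FnIII-12",
    ),
}


@dataclass(frozen=True)
class DomainParams:
    """Bell parameters of one FnIII type: zero-force rate and rupture length."""

    name: str
    k0: float  # 1/s
    delta_x: float  # nm

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError(f"{self.name}: k0 must be > 0, got {self.k0}")
        if not self.delta_x > 0:
            raise ValueError(f"{self.name}: delta_x must be > 0, got {self.delta_x}")


@dataclass
class DomainState:
    params: DomainParams
    folded: bool = True


@dataclass(frozen=True)
class DomainTable:
    """Per-type Bell parameters plus the types flagged initially unfolded."""

    params: Mapping[str, DomainParams]
    initially_unfolded: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.params.values())


@dataclass
class MoleculeState:
    """A fibronectin dimer: folded backbone WLC + unfolded strands + domains.

    Invariants maintained by :func:`apply_unfolding`:
    ``backbone.contour_length == 120 - 3.5 * n_unfolded`` and
    ``total_contour_length == 120 + 28.5 * n_unfolded``.
    """

    backbone: WLCSegment
    unfolded_segments: list[WLCSegment]
    domains: list[DomainState]
    # cached per-domain arrays for the vectorized unfolding poll
    _k0: np.ndarray = field(repr=False, default=None)
    _dx: np.ndarray = field(repr=False, default=None)
    _folded: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._k0 is None:
            self._k0 = np.array([d.params.k0 for d in self.domains])
            self._dx = np.array([d.params.delta_x for d in self.domains])
            self._folded = np.array([d.folded for d in self.domains])

    @property
    def n_unfolded(self) -> int:
        return len(self.unfolded_segments)

    @property
    def total_contour_length(self) -> float:
        return self.backbone.contour_length + sum(
            s.contour_length for s in self.unfolded_segments
        )

    def to_chain(self) -> SerialChain:
        return SerialChain([self.backbone, *self.unfolded_segments])


def _parse_table(doc: dict, origin: str) -> DomainTable:
    rows = doc.get("domains")
    if not isinstance(rows, list) or not rows:
        raise ValueError(f"{origin}: expected a non-empty 'domains' list")
    raw: dict[str, dict] = {}
    for row in rows:
        name = row.get("name")
        if not name:
            raise ValueError(f"{origin}: every row needs a 'name'")
        raw[str(name)] = row
    params: dict[str, DomainParams] = {}
    initially: list[str] = []
    for name, row in raw.items():
        target = row
        seen = {name}
        while "alias" in target:
            alias = str(target["alias"])
            if alias in seen or alias not in raw:
                raise ValueError(f"{origin}: bad alias chain for '{name}'")
            seen.add(alias)
            target = raw[alias]
        params[name] = DomainParams(
            name=name,
            k0=float(target["k0_per_s"]),
            delta_x=float(target["delta_x_nm"]),
        )
        if row.get("initially_unfolded", False):
            initially.extend([name] * DOMAIN_COPIES_PER_DIMER)
    return DomainTable(params=params, initially_unfolded=tuple(initially))


def load_domain_table(path) -> DomainTable:
    """Read a per-type Bell parameter table from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_table(doc, str(path))


def default_domain_table() -> DomainTable:
    """The packaged default table (see ``data/domain_params.yaml``)."""
    res = importlib.resources.files("fnfiber").joinpath("data/domain_params.yaml")
    doc = yaml.safe_load(res.read_text())
    return _parse_table(doc, "domain_params.yaml")


def new_molecule(
    table: DomainTable | None = None,
    contour_length: float = FOLDED_CONTOUR_NM,
    persistence_length: float = FOLDED_PERSISTENCE_NM,
) -> MoleculeState:
    """A pristine dimer: 120 nm folded backbone, 30 foldable domains.

    Domain order is fixed (two adjacent copies of each type, in table
    order) so that seeded runs are reproducible.
    """
    table = table if table is not None else default_domain_table()
    domains = [
        DomainState(params=p)
        for p in table.params.values()
        for _ in range(DOMAIN_COPIES_PER_DIMER)
    ]
    return MoleculeState(
        backbone=WLCSegment(contour_length, persistence_length),
        unfolded_segments=[],
        domains=domains,
    )


def unfold_probability(
    f: float,
    d: DomainParams,
    dt: float,
    ctx: ThermalContext = DEFAULT_CONTEXT,
) -> float:
    """Bell unfolding probability in one time step: min(1, k0 e^{f dx/kT} dt)."""
    if f < 0:
        raise ValueError(f"tension must be >= 0, got {f}")
    if dt < 0:
        raise ValueError(f"time step must be >= 0, got {dt}")
    return min(1.0, d.k0 * np.exp(f * d.delta_x / ctx.kt) * dt)


def poll_unfolding(
    mol: MoleculeState,
    f: float,
    dt: float,
    rng: np.random.Generator,
    ctx: ThermalContext = DEFAULT_CONTEXT,
) -> list[int]:
    """Poll every folded domain once at tension ``f``; return event indices.

    One uniform draw is consumed per domain (folded or not, in fixed
    molecule order) so the random stream advances identically regardless
    of the unfolding history.  Events are *not* applied here; feed them to
    :func:`apply_unfolding`.
    """
    if f < 0:
        raise ValueError(f"tension must be >= 0, got {f}")
    if dt < 0:
        raise ValueError(f"time step must be >= 0, got {dt}")
    draws = rng.random(len(mol.domains))
    if not mol._folded.any():
        return []
    p = np.minimum(1.0, mol._k0 * np.exp(f * mol._dx / ctx.kt) * dt)
    hits = mol._folded & (draws < p)
    return [int(i) for i in np.nonzero(hits)[0]]


def apply_unfolding(mol: MoleculeState, event: int) -> MoleculeState:
    """Unfold one domain in place: backbone -3.5 nm, +32 nm unfolded strand."""
    d = mol.domains[event]
    if not d.folded:
        raise ValueError(f"domain {event} ({d.params.name}) is already unfolded")
    mol.backbone = WLCSegment(
        mol.backbone.contour_length - FOLD_CONTOUR_LOSS_NM,
        mol.backbone.persistence_length,
    )
    mol.unfolded_segments.append(
        WLCSegment(UNFOLDED_SEGMENT_NM, UNFOLDED_PERSISTENCE_NM)
    )
    d.folded = False
    mol._folded[event] = False
    return mol


def init_unfolded(
    mol: MoleculeState, preset: int | Sequence[str]
) -> MoleculeState:
    """Start the named domains unfolded (presets 0 / 4 / 8 or a name list).

    Uses the same bookkeeping as :func:`apply_unfolding`; requires a
    pristine molecule.
    """
    if mol.n_unfolded:
        raise ValueError("init_unfolded requires a pristine molecule")
    if isinstance(preset, int):
        try:
            names = UNFOLDED_PRESETS[preset]
        except KeyError:
            raise ValueError(
                f"preset must be one of {sorted(UNFOLDED_PRESETS)} "
                f"(or a list of domain names), got {preset}"
            ) from None
    else:
        names = tuple(preset)
    for name in names:
        for i, d in enumerate(mol.domains):
            if d.folded and d.params.name == name:
                apply_unfolding(mol, i)
                break
        else:
            raise ValueError(f"no folded domain named '{name}' left to unfold")
    return mol
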