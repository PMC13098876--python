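"""Nuclide physical data: half-lives, mean emission energies, decay chains.

The package ships a human-readable fixture table (``data/nuclides.csv``)
with per-decay mean energies Δ by radiation class (the MIRD convention:
yield-weighted sums over emission lines, MeV per decay), decay daughters
with branching fractions, and half-lives, drawn from standard nuclear-data
compilations (source recorded per row).  Nothing is fetched at runtime.

Chain accounting assumes progeny decay where the parent decays (no
redistribution), so at equilibrium each chain member undergoes
``cumulative_branching`` decays per parent decay and chain-level energies
are branching-weighted sums over members.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources

__all__ = [
    "RadiationClass",
    "EmissionSummary",
    "NuclideRecord",
    "DecayChainSpec",
    "UnknownNuclideError",
    "get_nuclide",
    "mean_energy_per_decay",
    "build_chain",
    "chain_energy_per_decay",
    "chain_alpha_count",
]

LN2 = math.log(2.0)


class RadiationClass(str, Enum):
    """MIRD-style emission classes carried by the fixture."""

    ALPHA = "alpha"
    BETA_MEAN = "beta_mean"
    CONVERSION_ELECTRON = "conversion_electron"
    PHOTON = "photon"


#: Classes whose energy is carried by charged particles (self-absorbed in
#: the sphere model by default).
CHARGED_CLASSES = frozenset(
    {RadiationClass.ALPHA, RadiationClass.BETA_MEAN, RadiationClass.CONVERSION_ELECTRON}
)
ALL_CLASSES = frozenset(RadiationClass)


class UnknownNuclideError(KeyError):
    """Raised when a symbol is not in the embedded nuclide table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"nuclide not in table: {self.symbol!r}"


@dataclass(frozen=True)
class EmissionSummary:
    """Mean energy emitted per decay in one radiation class.

    ``delta`` is the yield-weighted sum over all lines of the class,
    in MeV per decay (the Δ of the S-value sum).
    """

    radiation_class: RadiationClass
    delta: float  # MeV/decay

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class NuclideRecord:
    """Physical data for one nuclide.

    ``daughters`` holds ``(symbol, branching_fraction, decay_mode)``
    triples; branching fractions of an unstable nuclide sum to 1.
    ``decay_mode`` is the mode of that branch ("alpha", "beta", "ec") and
    is used for chain-level alpha bookkeeping.
    """

    symbol: str
    half_life_s: float
    emissions: tuple[EmissionSummary, ...]
    beta_emax_mev: float
    daughters: tuple[tuple[str, float, str], ...]
    stable: bool

    def __post_init__(self):
        if self.stable:
            if self.daughters:
                raise ValueError(f"stable nuclide {self.symbol} has daughters")
        else:
            if not self.half_life_s > 0:
                raise ValueError(f"{self.symbol}: half_life_s must be > 0")
            total = sum(b for _, b, _ in self.daughters)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.symbol}: branching fractions sum to {total}, expected 1"
                )
            for d, b, _ in self.daughters:
                if not 0 < b <= 1:
                    raise ValueError(f"{self.symbol}->{d}: branching {b} outside (0,1]")
        seen = [e.radiation_class for e in self.emissions]
        if len(seen) != len(set(seen)):
            raise ValueError(f"{self.symbol}: duplicate radiation class")

    @property
    def decay_constant(self) -> float:
        """λ = ln2 / t½ in 1/s (inf is never returned; stable raises)."""
        if self.stable:
            raise ValueError(f"{self.symbol} is stable: no decay constant")
        return LN2 / self.half_life_s


@dataclass(frozen=True)
class DecayChainSpec:
    """A parent nuclide and its progeny down to a stable terminus.

    ``members`` are ``(symbol, cumulative_branching)`` pairs, parent first
    with cumulative branching 1; cumulative branching of a member is the
    number of its decays per parent decay under the no-redistribution /
    equilibrium assumption.
    """

    parent: str
    members: tuple[tuple[str, float], ...]
    terminal: str

    def __post_init__(self):
        if self.members:
            if self.members[0] != (self.parent, 1.0):
                raise ValueError("chain must start with (parent, 1.0)")
        elif self.terminal != self.parent:
            raise ValueError("empty chain only valid for a stable parent")
        for sym, cb in self.members:
            if not 0 < cb <= 1 + 1e-12:
                raise ValueError(f"{sym}: cumulative branching {cb} outside (0,1]")

    def cumulative_branching(self, symbol: str) -> float:
        for sym, cb in self.members:
            if sym == symbol:
                return cb
        raise KeyError(f"{symbol} not in chain of {self.parent}")


def _fixture_rows() -> list[dict]:
    with resources.files("spheredose.data").joinpath("nuclides.csv").open() as fh:
        return list(csv.DictReader(fh))


@lru_cache(maxsize=1)
def _load_table() -> dict[str, NuclideRecord]:
    records: dict[str, NuclideRecord] = {}
    by_symbol: dict[str, list[dict]] = {}
    for row in _fixture_rows():
        by_symbol.setdefault(row["symbol"], []).append(row)
    for symbol, rows in by_symbol.items():
        half_life = None
        emissions = []
        daughters = []
        emax = 0.0
        for row in rows:
            if row["half_life_s"]:
                half_life = float(row["half_life_s"])
            if row["beta_emax_mev"]:
                emax = float(row["beta_emax_mev"])
            if row["class"]:
                emissions.append(
                    EmissionSummary(RadiationClass(row["class"]), float(row["delta_mev"]))
                )
            if row["daughter"]:
                daughters.append((row["daughter"], float(row["branching"]), row["mode"]))
        records[symbol] = NuclideRecord(
            symbol=symbol,
            half_life_s=half_life if half_life is not None else math.inf,
            emissions=tuple(emissions),
            beta_emax_mev=emax,
            daughters=tuple(daughters),
            stable=half_life is None,
        )
    return records


def get_nuclide(symbol: str) -> NuclideRecord:
    """Look up a nuclide by symbol (e.g. ``"Ac-225"``) in the fixture table."""
    table = _load_table()
    try:
        return table[symbol]
    except KeyError:
        raise UnknownNuclideError(symbol) from None


def available_nuclides() -> tuple[str, ...]:
    return tuple(sorted(_load_table()))


def mean_energy_per_decay(
    nuclide: NuclideRecord,
    classes: frozenset[RadiationClass] | set[RadiationClass] = ALL_CLASSES,
) -> float:
    """Σ Δ over the requested radiation classes, MeV per decay.

    ``classes`` must be a non-empty subset of :class:`RadiationClass`;
    a nuclide emitting nothing in those classes contributes 0.
    """
    if not classes:
        raise ValueError("classes must be a non-empty set of radiation classes")
    wanted = {RadiationClass(c) for c in classes}
    return sum(e.delta for e in nuclide.emissions if e.radiation_class in wanted)


def build_chain(parent: str) -> DecayChainSpec:
    """Expand a nuclide's decay chain breadth-first down to stability.

    Cumulative branching of each member sums branch-fraction products
    over all paths from the parent.  Raises on a cyclic fixture.
    """
    root = get_nuclide(parent)
    if root.stable:
        return DecayChainSpec(parent=parent, members=(), terminal=parent)

    # topological order with cycle detection (DFS, three-color)
    order: list[str] = []
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def visit(sym: str) -> None:
        if state.get(sym) == 2:
            return
        if state.get(sym) == 1:
            raise ValueError(f"cycle detected in decay fixture at {sym}")
        state[sym] = 1
        rec = get_nuclide(sym)
        for dsym, _frac, _mode in rec.daughters:
            visit(dsym)
        state[sym] = 2
        order.append(sym)

    visit(parent)
    order.reverse()  # parents before daughters

    cumulative: dict[str, float] = {sym: 0.0 for sym in order}
    cumulative[parent] = 1.0
    for sym in order:
        rec = get_nuclide(sym)
        for dsym, frac, _mode in rec.daughters:
            cumulative[dsym] += cumulative[sym] * frac

    stables = [s for s in order if get_nuclide(s).stable]
    if len(stables) != 1:  # pragma: no cover - fixture integrity
        raise ValueError(f"chain of {parent} has {len(stables)} stable termini")
    members = tuple((s, cumulative[s]) for s in order if not get_nuclide(s).stable)
    return DecayChainSpec(parent=parent, members=members, terminal=stables[0])


def chain_energy_per_decay(
    chain: DecayChainSpec,
    classes: frozenset[RadiationClass] | set[RadiationClass] = ALL_CLASSES,
    equilibrium: bool = True,
) -> float:
    """Mean energy emitted by the whole chain per parent decay, MeV.

    Under the equilibrium / no-redistribution assumption each member
    decays ``cumulative_branching`` times per parent decay, so the chain
    energy is the branching-weighted sum of member Δ values.  Only the
    equilibrium mode is implemented.
    """
    if not equilibrium:
        raise NotImplementedError(
            "pre-equilibrium (Bateman) chain energies are not implemented"
        )
    return sum(
        cb * mean_energy_per_decay(get_nuclide(sym), classes)
        for sym, cb in chain.members
    )


def chain_alpha_count(chain: DecayChainSpec) -> float:
    """Expected number of alpha decays per parent decay.

    Each member contributes its alpha branch fraction weighted by its
    cumulative branching.  For Ac-225 every path to stable Bi-209 crosses
    exactly four alpha steps, so the count is 4.
    """
    total = 0.0
    for sym, cb in chain.members:
        rec = get_nuclide(sym)
        alpha_frac = sum(b for _, b, mode in rec.daughters if mode == "alpha")
        total += cb * alpha_frac
    return total
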