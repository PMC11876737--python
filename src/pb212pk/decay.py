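"""Decay-chain physics for the ²¹²Pb series.

The chain ²¹²Pb → ²¹²Bi → {²¹²Po (β branch), ²⁰⁸Tl (α branch)} → ²⁰⁸Pb
is solved in closed form with the Bateman equations, generalised to
branching by enumerating decay paths. Activities use A = λN. Times are
plain floats in hours relative to a per-study epoch; wall-clock strings
are parsed at the I/O boundary, never here.

Why this matters downstream: a dose calibrator responds to the whole
chain (it integrates ionisation current from every emission), while a
γ-counter windowed on the 238 keV line sees essentially the parent only.
``chain_activity_ratio`` quantifies the difference between those two
views of the same source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import half_life_hours, load_nuclear_data

LN2 = math.log(2.0)

#: 1 μCi = 37 kBq exactly; factors are Bq per unit.
_BQ_PER_UNIT = {
    "Bq": 1.0,
    "kBq": 1e3,
    "MBq": 1e6,
    "GBq": 1e9,
    "uCi": 3.7e4,
    "μCi": 3.7e4,
    "mCi": 3.7e7,
    "Ci": 3.7e10,
}

# relative λ spacing below which the Bateman denominators are treated as
# degenerate and the matrix-exponential limiting form is used instead
_DEGENERACY_RTOL = 1e-10


def decay_factor(elapsed_h: float, half_life_h: float) -> float:
    """Fraction of activity remaining after ``elapsed_h`` hours.

    Returns 2^(−elapsed/half_life); multiplicative in elapsed time.
    """
    if half_life_h <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_h}")
    if elapsed_h < 0:
        raise ValueError(f"elapsed time must be non-negative, got {elapsed_h}")
    return 2.0 ** (-elapsed_h / half_life_h)


def convert_activity(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear activity-unit conversion (1 μCi = 37 kBq)."""
    try:
        f, t = _BQ_PER_UNIT[from_unit], _BQ_PER_UNIT[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown activity unit {exc.args[0]!r}") from None
    return value * f / t


@dataclass(frozen=True)
class Nuclide:
    """A chain member: half-life in hours plus branching to daughters."""

    name: str
    half_life_h: float | None  # None for a stable nuclide
    branches: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.stable:
            if self.branches:
                raise ValueError(f"stable nuclide {self.name} cannot branch")
        else:
            if self.half_life_h <= 0:
                raise ValueError(f"{self.name}: half-life must be positive")
            total = sum(f for _, f in self.branches)
            if self.branches and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: branching fractions sum to {total}, not 1"
                )
            if any(not 0 <= f <= 1 for _, f in self.branches):
                raise ValueError(f"{self.name}: branching fraction outside [0,1]")

    @property
    def stable(self) -> bool:
        return self.half_life_h is None

    @property
    def lam(self) -> float:
        """Decay constant in 1/h (0 for stable)."""
        return 0.0 if self.stable else LN2 / self.half_life_h


@dataclass(frozen=True)
class NuclideChain:
    """Acyclic decay network rooted at one nuclide."""

    nuclides: tuple[Nuclide, ...]
    root: str

    def __post_init__(self) -> None:
        names = {n.name for n in self.nuclides}
        if len(names) != len(self.nuclides):
            raise ValueError("duplicate nuclide names in chain")
        if self.root not in names:
            raise ValueError(f"root {self.root!r} not in chain")
        for nuc in self.nuclides:
            for daughter, _ in nuc.branches:
                if daughter not in names:
                    raise ValueError(
                        f"{nuc.name} branches to unknown nuclide {daughter!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(name: str) -> None:
            if state.get(name) == 1:
                raise ValueError("decay chain contains a cycle")
            if state.get(name) == 2:
                return
            state[name] = 1
            for daughter, _ in self[name].branches:
                visit(daughter)
            state[name] = 2

        for nuc in self.nuclides:
            visit(nuc.name)

    def __getitem__(self, name: str) -> Nuclide:
        for nuc in self.nuclides:
            if nuc.name == name:
                return nuc
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(n.name == name for n in self.nuclides)

    def decay_paths(self, source: str, target: str) -> list[list[tuple[str, float]]]:
        """All decay paths source→target as [(nuclide, branch-fraction-in), ...]."""
        paths: list[list[tuple[str, float]]] = []

        def walk(name: str, acc: list[tuple[str, float]]) -> None:
            if name == target:
                paths.append(acc)
                # a nuclide cannot reappear downstream (acyclic), stop here
                return
            for daughter, frac in self[name].branches:
                walk(daughter, acc + [(daughter, frac)])

        walk(source, [(source, 1.0)])
        return paths


def pb212_chain() -> NuclideChain:
    """The default ²¹²Pb chain from the pinned constants table."""
    nucs = []
    for rec in load_nuclear_data()["nuclides"]:
        if rec.get("stable"):
            nucs.append(Nuclide(rec["name"], None))
        else:
            nucs.append(
                Nuclide(
                    rec["name"],
                    half_life_hours(rec["name"]),
                    tuple((b["daughter"], b["fraction"]) for b in rec["branches"]),
                )
            )
    return NuclideChain(tuple(nucs), root="pb212")


@dataclass
class Inventory:
    """Atom counts per nuclide at a moment in time (hours from epoch)."""

    atoms: dict[str, float] = field(default_factory=dict)
    time_h: float = 0.0

    def __post_init__(self) -> None:
        for name, n in self.atoms.items():
            if n < 0:
                raise ValueError(f"negative atom count for {name}")

    def activity_bq(self, chain: NuclideChain, name: str) -> float:
        """Activity of one nuclide in Bq (λ in 1/s × atoms)."""
        lam_per_s = chain[name].lam / 3600.0
        return lam_per_s * self.atoms.get(name, 0.0)

    def total_atoms(self) -> float:
        return sum(self.atoms.values())

    @classmethod
    def from_activity(
        cls, chain: NuclideChain, name: str, activity_bq: float, time_h: float = 0.0
    ) -> "Inventory":
        """Inventory holding one nuclide at a given activity."""
        lam_per_s = chain[name].lam / 3600.0
        if lam_per_s == 0:
            raise ValueError(f"{name} is stable; activity is undefined")
        return cls({name: activity_bq / lam_per_s}, time_h)


def _bateman_term(lams: np.ndarray, t: float) -> float:
    """N_n(t)/N_1(0) along one path with decay constants ``lams``.

    Classic Bateman product-sum; the last entry may be 0 (stable sink).
    Falls back to a matrix exponential of the path's bidiagonal rate
    matrix when two constants are numerically degenerate.
    """
    n = len(lams)
    if n == 1:
        return math.exp(-lams[0] * t)
    scale = max(lams.max(), 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(lams[i] - lams[j]) < _DEGENERACY_RTOL * scale:
                return _bateman_term_degenerate(lams, t)
    coef = float(np.prod(lams[:-1]))
    s = 0.0
    for i in range(n):
        denom = 1.0
        for j in range(n):
            if j != i:
                denom *= lams[j] - lams[i]
        # exp underflows to 0 for the very fast members (e.g. 212Po); fine
        s += math.exp(-lams[i] * t) / denom
    return coef * s


def _bateman_term_degenerate(lams: np.ndarray, t: float) -> float:
    from scipy.linalg import expm

    n = len(lams)
    m = np.zeros((n, n))
    for i in range(n):
        m[i, i] = -lams[i]
        if i + 1 < n:
            m[i + 1, i] = lams[i]
    return float(expm(m * t)[n - 1, 0])


def bateman_evolve(
    chain: NuclideChain, initial: Inventory, elapsed_h: float
) -> Inventory:
    """Closed-form evolution of an inventory through the decay chain.

    Branching fractions multiply along each decay path; total atoms
    (including the stable sink) are conserved.
    """
    if elapsed_h < 0:
        raise ValueError("elapsed time must be non-negative")
    for name in initial.atoms:
        if name not in chain:
            raise KeyError(f"nuclide {name!r} absent from chain")
    out = {n.name: 0.0 for n in chain.nuclides}
    for source, n0 in initial.atoms.items():
        if n0 == 0:
            continue
        if chain[source].stable:
            out[source] += n0
            continue
        for nuc in chain.nuclides:
            for path in chain.decay_paths(source, nuc.name):
                lams = np.array([chain[name].lam for name, _ in path])
                branch = math.prod(frac for _, frac in path)
                out[nuc.name] += n0 * branch * _bateman_term(lams, elapsed_h)
    out = {k: max(v, 0.0) for k, v in out.items()}
    return Inventory(out, initial.time_h + elapsed_h)


def chain_activity_ratio(chain: NuclideChain, state: Inventory) -> float:
    """Total unstable activity divided by root activity.

    1.0 for a freshly purified parent; ≈3.21 for the default ²¹²Pb chain
    at transient equilibrium — the factor a gross-response instrument
    sees relative to a parent-only γ window.
    """
    root_act = state.activity_bq(chain, chain.root)
    if root_act <= 0:
        raise ValueError("root activity must be positive")
    total = sum(
        state.activity_bq(chain, nuc.name)
        for nuc in chain.nuclides
        if not nuc.stable
    )
    return total / root_act
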