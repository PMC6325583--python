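"""Exact mass-isotopomer-distribution (MID) arithmetic.

An MID is the vector of relative abundances M0..MK of a fragment's
isotopologues, where Mk carries k heavy (here: carbon-13) isotopes.  The
model is carbon-only: every carbon position is an independent Bernoulli
trial, so a homogeneous population of molecules with isotopic abundance
``p`` over its labelable positions produces a binomial MID over those
positions, convolved with a binomial natural-abundance background over the
remaining (non-labelable plus derivatization) carbons.

Which positions are labelable depends on the tracer: bicarbonate labeling
can reach every analyte carbon, whereas [2-13C]acetate labels only the
even-numbered acyl carbons of a fatty acid, i.e. half of them.
Derivatization carbons (the FAME methyl, TMS groups) are always at natural
abundance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: Terrestrial natural abundance of carbon-13 (IUPAC representative value).
P13C_NATURAL = 0.0107

#: Normalization tolerance for MID vectors.
NORM_TOL = 1e-9


class DomainError(ValueError):
    """An argument is outside the model's domain."""


class ContractError(ValueError):
    """An input violates an operation's contract (e.g. unnormalized MID)."""


@dataclass(frozen=True)
class FragmentSpec:
    """A measured analyte fragment.

    Parameters
    ----------
    name
        Identifier, e.g. ``"galactose"`` or ``"16:0"``.
    n_analyte_carbons
        Carbons of the analyte backbone (16 for palmitate, 6 for galactose,
        3 for glycerol).
    n_labelable
        Positions the tracer can occupy: all analyte carbons for
        bicarbonate labeling, the N/2 even-numbered acyl carbons for
        [2-13C]acetate labeling.
    n_derivatization_carbons
        Carbons added by derivatization (FAME methyl, TMS groups); always
        at natural abundance.
    """

    name: str
    n_analyte_carbons: int
    n_labelable: int
    n_derivatization_carbons: int = 0

    def __post_init__(self) -> None:
        for f in ("n_analyte_carbons", "n_labelable", "n_derivatization_carbons"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"{f} must be a non-negative integer, got {v!r}")
        if self.n_labelable > self.n_analyte_carbons:
            raise DomainError(
                f"n_labelable ({self.n_labelable}) exceeds n_analyte_carbons "
                f"({self.n_analyte_carbons})"
            )

    @property
    def n_total_carbons(self) -> int:
        """All carbons of the derivatized fragment."""
        return self.n_analyte_carbons + self.n_derivatization_carbons

    @property
    def n_background(self) -> int:
        """Carbons fixed at natural abundance: non-labelable + derivatization."""
        return (self.n_analyte_carbons - self.n_labelable) + self.n_derivatization_carbons


@dataclass(frozen=True)
class LabelPopulation:
    """One isotopomer population: isotopic abundance ``p`` over labelable
    positions and mixture fraction ``f`` of the pool it accounts for."""

    p: float
    f: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise DomainError(f"isotopic abundance p must be in [0, 1], got {self.p}")
        if not 0.0 <= self.f <= 1.0:
            raise DomainError(f"mixture fraction f must be in [0, 1], got {self.f}")


@dataclass
class MIDVector:
    """A mass-isotopomer distribution M0..MK for one fragment.

    ``masses[k]`` is the relative abundance of the isotopologue carrying k
    heavy carbons.  When ``normalized``, entries are non-negative and sum
    to 1 within ``NORM_TOL``.
    """

    masses: np.ndarray
    fragment: FragmentSpec | None = None
    normalized: bool = field(default=True)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1:
            raise ContractError("MID masses must be a 1-D vector")
        if np.any(self.masses < -NORM_TOL):
            raise ContractError("MID masses must be non-negative")
        self.masses = np.clip(self.masses, 0.0, None)
        if self.normalized and abs(self.masses.sum() - 1.0) > 1e-6:
            raise ContractError(
                f"MID marked normalized but sums to {self.masses.sum():.6g}"
            )

    def __len__(self) -> int:
        return len(self.masses)

    def normalize(self) -> "MIDVector":
        total = self.masses.sum()
        if total <= 0:
            raise ContractError("cannot normalize an all-zero MID")
        return MIDVector(self.masses / total, self.fragment, normalized=True)

    def mean_shift(self) -> float:
        """First moment: the average number of heavy carbons per molecule."""
        return float(np.arange(len(self.masses)) @ self.masses)


def natural_abundance_mid(n_carbons: int, p_nat: float = P13C_NATURAL) -> MIDVector:
    """Binomial natural-abundance MID of ``n_carbons`` unlabeled carbons.

    Entry k is the probability that k of the carbons are 13C when each is
    independently 13C with probability ``p_nat``.
    """
    if not isinstance(n_carbons, (int, np.integer)) or n_carbons < 0:
        raise DomainError(f"n_carbons must be a non-negative integer, got {n_carbons!r}")
    if not 0.0 <= p_nat < 1.0:
        raise DomainError(f"p_nat must be in [0, 1), got {p_nat}")
    masses = stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, p_nat)
    return MIDVector(masses / masses.sum())


def _binom_pmf(n: int, p: float) -> np.ndarray:
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return pmf / pmf.sum()


def population_mid(
    fragment: FragmentSpec, pop: LabelPopulation, p_nat: float = P13C_NATURAL
) -> MIDVector:
    """MID of a single homogeneous population on ``fragment``.

    Binomial(n_labelable, pop.p) over the labelable positions, convolved
    with binomial(n_background, p_nat) over the positions the tracer cannot
    reach.  Length is n_total_carbons + 1.
    """
    if not 0.0 <= p_nat < 1.0:
        raise DomainError(f"p_nat must be in [0, 1), got {p_nat}")
    labeled = _binom_pmf(fragment.n_labelable, pop.p)
    background = _binom_pmf(fragment.n_background, p_nat)
    masses = np.convolve(labeled, background)
    return MIDVector(masses / masses.sum(), fragment)


def convolve_mids(a: MIDVector, b: MIDVector) -> MIDVector:
    """Convolve two normalized MIDs (the MID of the combined molecule)."""
    for name, m in (("a", a), ("b", b)):
        if abs(m.masses.sum() - 1.0) > 1e-6:
            raise ContractError(f"operand {name} is not normalized")
    masses = np.convolve(a.masses, b.masses)
    return MIDVector(masses / masses.sum())


def mixture_mid(
    fragment: FragmentSpec,
    populations: Sequence[LabelPopulation],
    p_nat: float = P13C_NATURAL,
) -> MIDVector:
    """MID of a mixture of populations; fractions must sum to 1."""
    if not populations:
        raise DomainError("mixture requires at least one population")
    total_f = sum(pop.f for pop in populations)
    if abs(total_f - 1.0) > NORM_TOL * len(populations) + 1e-9:
        raise DomainError(f"mixture fractions sum to {total_f}, expected 1")
    masses = np.zeros(fragment.n_total_carbons + 1)
    for pop in populations:
        masses += pop.f * population_mid(fragment, pop, p_nat).masses
    return MIDVector(masses / masses.sum(), fragment)


# Fragments measured in the study: TMS-derivatized methyl galactoside and
# glycerol (backbone carbons only by default) and FAMEs.  Bicarbonate
# labeling reaches every analyte carbon; acetate labeling only the N/2
# even-numbered acyl carbons.
def default_fragments() -> dict[str, FragmentSpec]:
    """Fragment definitions shipped with the package, keyed by name."""
    with resources.files("plastidlabel.data").joinpath("fragments.csv").open() as fh:
        return {f.name: f for f in read_fragments(fh)}


def read_fragments(fh: Iterable[str]) -> list[FragmentSpec]:
    """Read FragmentSpecs from a CSV with columns
    name,n_analyte_carbons,n_labelable,n_derivatization_carbons."""
    rows = [r for r in csv.DictReader(line for line in fh if not line.startswith("#"))]
    return [
        FragmentSpec(
            name=r["name"],
            n_analyte_carbons=int(r["n_analyte_carbons"]),
            n_labelable=int(r["n_labelable"]),
            n_derivatization_carbons=int(r.get("n_derivatization_carbons") or 0),
        )
        for r in rows
    ]
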