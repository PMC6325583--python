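"""Decompose observed MIDs into unlabeled and labeled isotopomer populations.

An observed MID is modeled as a mixture of a natural-abundance (unlabeled)
population and one or more labeled populations, each characterized by an
isotopic abundance ``p`` over the labelable carbon positions.  Populations
with ``p`` above a threshold (0.5 by default) are counted as *highly
labeled* — newly synthesized material — and their summed mixture fraction,
in percent of the whole pool, is the quantity the turnover-rate tables are
built from.

Two estimators are provided, because the mixture model can be inverted in
two natural ways:

``strip`` (default)
    Subtract the largest feasible multiple of the natural-abundance MID,
    then read populations off the residual mass shifts, assigning shift k
    the nominal abundance k / n_labelable.

``fit``
    Nonnegative least squares over a grid of candidate population MIDs
    (one per grid ``p`` plus the natural population); fractions are the
    fitted weights.

On noiseless single-population data the two agree; on noisy or genuinely
multi-population data they need not, and both are exposed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import optimize

from .mid import (
    NORM_TOL,
    P13C_NATURAL,
    ContractError,
    DomainError,
    FragmentSpec,
    LabelPopulation,
    MIDVector,
    natural_abundance_mid,
    population_mid,
)

#: Candidate isotopic abundances for the grid estimator: 0.05 steps to 1.0.
DEFAULT_P_GRID: tuple[float, ...] = tuple(np.round(np.arange(1, 21) * 0.05, 2))

#: Fitted mixture fractions below this are dropped.
DROP_TOL = 1e-4

#: Feasibility slack for the stripping scalar on noiseless data.
STRIP_TOL = 1e-9


@dataclass
class DeconvolutionResult:
    """Populations and summary fractions for one observed MID.

    ``populations[0]`` is always the unlabeled population (p = p_nat).
    Fractions are percentages of the whole pool.  ``residual_norm`` is the
    estimator's goodness-of-fit: the clipped (unexplained negative) mass
    for the stripping estimator, the sum of squared MID residuals for the
    grid fit.
    """

    fragment: FragmentSpec
    populations: list[LabelPopulation]
    highly_labeled_fraction: float
    total_labeled_fraction: float
    residual_norm: float
    method: str = "strip"
    threshold: float = 0.5
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total_f = sum(p.f for p in self.populations)
        if abs(total_f - 1.0) > 1e-6:
            raise ContractError(f"population fractions sum to {total_f}, expected 1")
        if self.highly_labeled_fraction > self.total_labeled_fraction + 1e-9:
            raise ContractError("highly labeled fraction exceeds total labeled")
        if self.residual_norm < 0:
            raise ContractError("residual_norm must be non-negative")


def strip_natural_abundance(
    observed: MIDVector,
    fragment: FragmentSpec,
    p_nat: float = P13C_NATURAL,
    tol: float = STRIP_TOL,
) -> tuple[float, MIDVector, float]:
    """Remove the largest feasible natural-abundance component.

    Finds the largest scalar ``alpha`` (capped at 1) such that
    ``observed - alpha * natural`` stays elementwise above ``-tol``, clips
    the difference to non-negative and renormalizes it.

    Returns
    -------
    (f_unlabeled, residual, clipped_mass)
        ``f_unlabeled`` is ``alpha``; ``residual`` is the renormalized
        labeled component (all-zero when the observation is fully
        explained by natural abundance); ``clipped_mass`` is the total
        negative mass removed by clipping (zero on noiseless data).
    """
    n = fragment.n_total_carbons
    if len(observed) != n + 1:
        raise DomainError(
            f"observed MID has length {len(observed)}, fragment "
            f"{fragment.name!r} requires {n + 1}"
        )
    obs = observed.masses
    nat = natural_abundance_mid(n, p_nat).masses
    mask = nat > 0
    alpha = float(min(np.min((obs[mask] + tol) / nat[mask]), 1.0))
    diff = obs - alpha * nat
    clipped = float(-diff[diff < 0].sum())
    residual = np.clip(diff, 0.0, None)
    total = residual.sum()
    if total <= max(tol, 10 * np.finfo(float).eps):
        return 1.0, MIDVector(np.zeros(n + 1), fragment, normalized=False), clipped
    return alpha, MIDVector(residual / total, fragment), clipped


def classify_isotopomers(
    residual: MIDVector,
    fragment: FragmentSpec,
    threshold: float = 0.5,
    *,
    f_unlabeled: float,
    clipped_mass: float = 0.0,
    p_nat: float = P13C_NATURAL,
) -> DeconvolutionResult:
    """Assign residual mass shifts to labeled populations by nominal abundance.

    Each shift k carries nominal isotopic abundance ``p_k = k / n_labelable``
    (capped at 1).  Shifts with ``p_k`` strictly above ``threshold`` count
    as highly labeled; shifts with ``0 < p_k <= threshold`` form the less
    densely labeled population.  All fractions are percentages of the
    whole pool, i.e. scaled by ``1 - f_unlabeled``.
    """
    labeled_total = 1.0 - f_unlabeled
    res = residual.masses
    has_mass = res.sum() > 0
    if fragment.n_labelable == 0 and has_mass:
        raise DomainError(
            f"fragment {fragment.name!r} has no labelable positions but the "
            "residual carries labeled mass"
        )
    populations = [LabelPopulation(p=p_nat, f=f_unlabeled)]
    highly_share = 0.0
    if has_mass:
        shifts = np.arange(len(res))
        p_k = np.minimum(shifts / fragment.n_labelable, 1.0)
        for k in shifts[res > 0]:
            populations.append(LabelPopulation(p=float(p_k[k]), f=labeled_total * res[k]))
        highly_share = float(res[p_k > threshold].sum())
    return DeconvolutionResult(
        fragment=fragment,
        populations=populations,
        highly_labeled_fraction=100.0 * labeled_total * highly_share,
        total_labeled_fraction=100.0 * labeled_total,
        residual_norm=clipped_mass,
        method="strip",
        threshold=threshold,
    )


def deconvolve_strip(
    observed: MIDVector,
    fragment: FragmentSpec,
    p_nat: float = P13C_NATURAL,
    threshold: float = 0.5,
    tol: float = STRIP_TOL,
) -> DeconvolutionResult:
    """Stripping estimator: strip_natural_abundance then classify_isotopomers."""
    f_unlab, residual, clipped = strip_natural_abundance(observed, fragment, p_nat, tol)
    return classify_isotopomers(
        residual, fragment, threshold,
        f_unlabeled=f_unlab, clipped_mass=clipped, p_nat=p_nat,
    )


def fit_mixture(
    observed: MIDVector,
    fragment: FragmentSpec,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    p_nat: float = P13C_NATURAL,
    threshold: float = 0.5,
    drop_tol: float = DROP_TOL,
) -> DeconvolutionResult:
    """Grid mixture estimator: nonnegative least squares over candidate MIDs.

    The design matrix has one column per grid abundance plus the natural
    population; NNLS weights, renormalized to sum to 1, are the mixture
    fractions.  Populations with fitted fraction below ``drop_tol`` are
    removed (the unlabeled population is always kept).
    """
    if len(p_grid) == 0:
        raise DomainError("p_grid must be nonempty")
    grid = []
    for p in p_grid:
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"grid abundance {p} outside [0, 1]")
        if any(abs(p - q) < 1e-12 for q in grid) or abs(p - p_nat) < 1e-12:
            warnings.warn(f"duplicate grid abundance {p} dropped", stacklevel=2)
            continue
        grid.append(float(p))
    n = fragment.n_total_carbons
    if len(observed) != n + 1:
        raise DomainError(
            f"observed MID has length {len(observed)}, fragment "
            f"{fragment.name!r} requires {n + 1}"
        )
    candidates = [LabelPopulation(p=p_nat)] + [LabelPopulation(p=p) for p in grid]
    design = np.column_stack(
        [population_mid(fragment, pop, p_nat).masses for pop in candidates]
    )
    weights, rnorm = optimize.nnls(design, observed.masses)
    total_w = weights.sum()
    if total_w <= 0:
        raise DomainError("degenerate fit: all mixture weights zero")
    fractions = weights / total_w

    kept = [(candidates[0].p, fractions[0])]
    kept += [
        (pop.p, fr)
        for pop, fr in zip(candidates[1:], fractions[1:])
        if fr >= drop_tol
    ]
    norm = sum(fr for _, fr in kept)
    populations = [LabelPopulation(p=p, f=fr / norm) for p, fr in kept]

    f_unlabeled = populations[0].f
    highly = sum(pop.f for pop in populations[1:] if pop.p > threshold)
    return DeconvolutionResult(
        fragment=fragment,
        populations=populations,
        highly_labeled_fraction=100.0 * highly,
        total_labeled_fraction=100.0 * (1.0 - f_unlabeled),
        residual_norm=float(rnorm**2),
        method="fit",
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_mid_table(
    fh: Iterable[str], fragments: dict[str, FragmentSpec]
) -> list[tuple[str, MIDVector]]:
    """Read an MID CSV: sample_id,fragment_name,m0,m1,...,mK (ragged rows).

    Each row's intensity vector is normalized on read.  Returns
    ``(sample_id, mid)`` pairs; the fragment is attached to each MID.
    """
    out: list[tuple[str, MIDVector]] = []
    reader = csv.reader(line for line in fh if line.strip() and not line.startswith("#"))
    header = next(reader)
    if header[:2] != ["sample_id", "fragment_name"]:
        raise ContractError("MID CSV must start with sample_id,fragment_name columns")
    for i, row in enumerate(reader, start=2):
        sample, frag_name = row[0], row[1]
        if frag_name not in fragments:
            raise DomainError(f"row {i}: unknown fragment {frag_name!r}")
        frag = fragments[frag_name]
        values = np.array([float(v) for v in row[2:] if v != ""], dtype=float)
        if len(values) != frag.n_total_carbons + 1:
            raise DomainError(
                f"row {i}: fragment {frag_name!r} needs "
                f"{frag.n_total_carbons + 1} intensities, got {len(values)}"
            )
        out.append((sample, MIDVector(values, frag, normalized=False).normalize()))
    return out


def deconvolve_table(
    mids: Sequence[tuple[str, MIDVector]],
    method: str = "strip",
    p_nat: float = P13C_NATURAL,
    threshold: float = 0.5,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
) -> pd.DataFrame:
    """Deconvolve many (sample, MID) pairs into a tidy result table."""
    rows = []
    for sample, mid in mids:
        frag = mid.fragment
        if frag is None:
            raise ContractError("each MID must carry its FragmentSpec")
        if method == "strip":
            result = deconvolve_strip(mid, frag, p_nat, threshold)
        elif method == "fit":
            result = fit_mixture(mid, frag, p_grid, p_nat, threshold)
        else:
            raise DomainError(f"unknown method {method!r}")
        rows.append(
            {
                "sample_id": sample,
                "fragment_name": frag.name,
                "method": result.method,
                "f_unlabeled": result.populations[0].f,
                "total_labeled_pct": result.total_labeled_fraction,
                "highly_labeled_pct": result.highly_labeled_fraction,
                "residual_norm": result.residual_norm,
                "populations": ";".join(
                    f"{pop.p:.6g}:{pop.f:.6g}" for pop in result.populations[1:]
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "fragment_name",
            "method",
            "f_unlabeled",
            "total_labeled_pct",
            "highly_labeled_pct",
            "residual_norm",
            "populations",
        ],
    )


def write_results(df: pd.DataFrame, fh: TextIO) -> None:
    df.to_csv(fh, index=False)
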