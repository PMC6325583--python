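"""Incorporation, turnover, specific-radioactivity and degradation rates.

Converts labeled fractions (from MID deconvolution) and radiotracer
incorporations into per-pool rate quantities, all normalized per mg
chlorophyll.  The turnover model is a steady-state pool with constant
input and output, whose labeled fraction after labeling time t follows
f(t) = 1 - exp(-k t); inverting at a single timepoint gives

    k = -ln(1 - f) / t      [h^-1]

The growth/degradation decomposition uses the identity
turnover = specific growth rate + degradation rate, with the specific
growth rate mu = ln(2) / doubling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .mid import DomainError

#: dpm per mCi (1 Ci = 2.22e12 disintegrations per minute).
DPM_PER_MCI = 2.22e9


@dataclass(frozen=True)
class PoolSpec:
    """A metabolite or lipid pool.

    content
        Pool size in nmol per mg chlorophyll.
    carbon_number
        Carbons per molecule (lipid tables; e.g. 43 for MGDG assuming a
        C18/C16 species).
    c2_units
        Acetate-derived C2 units per molecule (fatty-acid tables; 7 for
        14:0, 8 for 16:0, 9 for 18:0).
    """

    name: str
    content: float
    carbon_number: Optional[int] = None
    c2_units: Optional[int] = None

    def __post_init__(self) -> None:
        if self.content < 0:
            raise DomainError(f"pool content must be >= 0, got {self.content}")
        if self.carbon_number is not None and self.carbon_number < 1:
            raise DomainError("carbon_number must be >= 1 when set")
        if self.c2_units is not None and self.c2_units < 1:
            raise DomainError("c2_units must be >= 1 when set")


@dataclass(frozen=True)
class LabelMeasurement:
    """One labeling observation for a pool.

    Either a stable-isotope labeled fraction (percent of the pool highly
    labeled), a radiotracer incorporation (pmol 14C per mg chlorophyll per
    hour), or both; missing quantities are None ("nd" in input tables).
    """

    pool: str
    labeled_fraction_pct: Optional[float] = None
    incorporation_pmol: Optional[float] = None
    label_time: float = 1.0

    def __post_init__(self) -> None:
        if self.labeled_fraction_pct is not None and not (
            0.0 <= self.labeled_fraction_pct < 100.0
        ):
            raise DomainError(
                f"labeled fraction must be in [0, 100)%, got {self.labeled_fraction_pct}"
            )
        if self.incorporation_pmol is not None and self.incorporation_pmol < 0:
            raise DomainError("incorporation must be >= 0")
        if self.label_time <= 0:
            raise DomainError("label_time must be > 0")


@dataclass
class RateResult:
    """Derived quantities for one pool (fields unused by a table kind are None)."""

    pool: str
    incorporation_rate: Optional[float] = None  # nmol . mg^-1 chl . h^-1
    turnover_rate: Optional[float] = None  # h^-1
    carbon_content: Optional[float] = None  # umol C . mg^-1 chl
    c2_content: Optional[float] = None  # nmol C2 . mg^-1 chl
    specific_radioactivity: Optional[float] = None  # x1e-6 labeled-carbon fraction
    degradation_rate: Optional[float] = None  # h^-1
    below_growth: bool = False
    rounded: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ExperimentConfig:
    """Experiment-level constants."""

    p_nat: float = 0.0107
    label_time: float = 1.0  # h
    doubling_time: float = 12.0  # h
    specific_growth_rate: Optional[float] = None  # h^-1; ln2/doubling_time if None
    substrate_specific_activity: float = 58.8  # mCi . mmol^-1

    def __post_init__(self) -> None:
        if self.specific_growth_rate is not None and self.doubling_time:
            mu = math.log(2.0) / self.doubling_time
            if abs(self.specific_growth_rate - mu) > 5e-3:
                raise DomainError(
                    "specific_growth_rate inconsistent with doubling_time "
                    f"({self.specific_growth_rate} vs ln2/Td = {mu:.4f})"
                )

    @property
    def growth_rate(self) -> float:
        if self.specific_growth_rate is not None:
            return self.specific_growth_rate
        return growth_rate_from_doubling(self.doubling_time)


# ---------------------------------------------------------------------------
# Scalar operations (the printed tables' footnote formulas)
# ---------------------------------------------------------------------------

def incorporation_rate(
    pool_content: float, labeled_fraction_pct: float, label_time: float = 1.0
) -> float:
    """Pool content x labeled fraction / labeling time (nmol mg^-1 chl h^-1)."""
    if pool_content < 0:
        raise DomainError("pool content must be >= 0")
    if not 0.0 <= labeled_fraction_pct < 100.0:
        raise DomainError(f"labeled fraction must be in [0, 100)%, got {labeled_fraction_pct}")
    return pool_content * labeled_fraction_pct / 100.0 / label_time


def turnover_rate(labeled_fraction_pct: float, label_time: float = 1.0) -> float:
    """k = -ln(1 - f) / t for labeled fraction f (steady-state pool model)."""
    if not 0.0 <= labeled_fraction_pct < 100.0:
        raise DomainError(
            f"labeled fraction must be in [0, 100)% for a finite turnover, "
            f"got {labeled_fraction_pct}"
        )
    return -math.log1p(-labeled_fraction_pct / 100.0) / label_time


def carbon_content(lipid_content: float, carbon_number: int) -> float:
    """nmol lipid x carbons/molecule -> umol C per mg chlorophyll."""
    if lipid_content < 0 or carbon_number < 0:
        raise DomainError("inputs must be >= 0")
    return carbon_number * lipid_content / 1000.0


def specific_radioactivity_lipid(
    incorporation_pmol: float, carbon_content_umol: float
) -> float:
    """14C / (14C + 12C) on the x1e-6 scale (pmol label per umol carbon)."""
    if carbon_content_umol <= 0:
        raise DomainError("carbon content must be > 0")
    return incorporation_pmol / carbon_content_umol


def c2_content(fa_content: float, c2_units: int) -> float:
    """nmol fatty acid x C2 units/molecule -> nmol C2 per mg chlorophyll."""
    if fa_content < 0 or c2_units < 0:
        raise DomainError("inputs must be >= 0")
    return fa_content * c2_units


def specific_radioactivity_fa(incorporation_pmol: float, c2_content_nmol: float) -> float:
    """14C / total acetate units on the x1e-6 scale: 1000 x pmol / nmol C2."""
    if c2_content_nmol <= 0:
        raise DomainError("C2 content must be > 0")
    return 1000.0 * incorporation_pmol / c2_content_nmol


def growth_rate_from_doubling(doubling_time: float) -> float:
    """Specific growth rate mu = ln(2) / doubling time (h^-1)."""
    if doubling_time <= 0:
        raise DomainError("doubling time must be > 0")
    return math.log(2.0) / doubling_time


def degradation_rate(turnover: float, growth: float) -> tuple[float, bool]:
    """Degradation = turnover - growth, floored at 0.

    Returns ``(rate, below_growth)``; the flag marks pools whose apparent
    turnover is below the specific growth rate (seen in vitro, where
    downstream metabolism is arrested) rather than raising.
    """
    if turnover < 0 or growth < 0:
        raise DomainError("rates must be >= 0")
    if turnover < growth:
        return 0.0, True
    return turnover - growth, False


def dpm_to_pmol(dpm: float, specific_activity: float = 58.8) -> float:
    """Convert raw counts to pmol of substrate.

    specific_activity is in mCi/mmol; with 2.22e9 dpm per mCi this reduces
    to dpm / (2.22 x specific_activity) pmol.
    """
    if specific_activity <= 0:
        raise DomainError("specific activity must be > 0")
    if dpm <= 0:
        raise DomainError("dpm must be > 0")
    return dpm / (specific_activity * DPM_PER_MCI / 1e9)


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

TABLE_KINDS = ("bicarbonate_lipid", "bicarbonate_mid", "acetate_fa", "acetate_mid")


def round_printed(value: float, decimals: int) -> float:
    """Round-half-even at a fixed number of decimals, as printed tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


def decimals_of(printed: str) -> int:
    """Number of decimal places shown in a printed value string."""
    printed = printed.strip()
    return len(printed.split(".")[1]) if "." in printed else 0


def build_rate_table(
    pools: Sequence[PoolSpec],
    measurements: Sequence[LabelMeasurement],
    config: ExperimentConfig,
    table_kind: str,
) -> list[RateResult]:
    """Assemble per-pool rate results with the columns of one table kind.

    bicarbonate_lipid:  carbon content + specific radioactivity (radiotracer).
    acetate_fa:         C2 content + specific radioactivity (radiotracer).
    bicarbonate_mid / acetate_mid:
                        incorporation + turnover (stable-isotope fractions),
                        plus the growth/degradation decomposition.
    """
    if table_kind not in TABLE_KINDS:
        raise DomainError(f"unknown table kind {table_kind!r}")
    by_name = {p.name: p for p in pools}
    out: list[RateResult] = []
    for m in measurements:
        if m.pool not in by_name:
            raise DomainError(f"measurement references unknown pool {m.pool!r}")
        pool = by_name[m.pool]
        r = RateResult(pool=pool.name)
        if table_kind == "bicarbonate_lipid":
            if pool.carbon_number is None:
                raise DomainError(f"pool {pool.name!r} lacks carbon_number")
            r.carbon_content = carbon_content(pool.content, pool.carbon_number)
            if m.incorporation_pmol is not None:
                r.specific_radioactivity = specific_radioactivity_lipid(
                    m.incorporation_pmol, r.carbon_content
                )
        elif table_kind == "acetate_fa":
            if pool.c2_units is None:
                raise DomainError(f"pool {pool.name!r} lacks c2_units")
            r.c2_content = c2_content(pool.content, pool.c2_units)
            if m.incorporation_pmol is not None:
                r.specific_radioactivity = specific_radioactivity_fa(
                    m.incorporation_pmol, r.c2_content
                )
        else:  # *_mid: stable-isotope labeled fractions
            if m.labeled_fraction_pct is not None:
                r.incorporation_rate = incorporation_rate(
                    pool.content, m.labeled_fraction_pct, m.label_time
                )
                r.turnover_rate = turnover_rate(m.labeled_fraction_pct, m.label_time)
                r.degradation_rate, r.below_growth = degradation_rate(
                    r.turnover_rate, config.growth_rate
                )
        out.append(r)
    return out


def rate_table_frame(results: Sequence[RateResult]) -> pd.DataFrame:
    """Tidy DataFrame of rate results (full precision)."""
    return pd.DataFrame(
        [
            {
                "pool": r.pool,
                "incorporation_rate": r.incorporation_rate,
                "turnover_rate": r.turnover_rate,
                "carbon_content": r.carbon_content,
                "c2_content": r.c2_content,
                "specific_radioactivity": r.specific_radioactivity,
                "degradation_rate": r.degradation_rate,
                "below_growth": r.below_growth,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_pools(fh: Iterable[str]) -> list[PoolSpec]:
    """Pool CSV: name,content_nmol_per_mg_chl,carbon_number,c2_units."""
    df = pd.read_csv(_strip_comments(fh))
    pools = []
    for _, row in df.iterrows():
        pools.append(
            PoolSpec(
                name=str(row["name"]),
                content=float(row["content_nmol_per_mg_chl"]),
                carbon_number=_opt_int(row.get("carbon_number")),
                c2_units=_opt_int(row.get("c2_units")),
            )
        )
    return pools


def read_measurements(fh: Iterable[str]) -> list[LabelMeasurement]:
    """Measurement CSV: pool,labeled_fraction_pct,incorporation_pmol,label_time_h."""
    df = pd.read_csv(_strip_comments(fh))
    out = []
    for _, row in df.iterrows():
        out.append(
            LabelMeasurement(
                pool=str(row["pool"]),
                labeled_fraction_pct=_opt_float(row.get("labeled_fraction_pct")),
                incorporation_pmol=_opt_float(row.get("incorporation_pmol")),
                label_time=_opt_float(row.get("label_time_h")) or 1.0,
            )
        )
    return out


def _strip_comments(fh: Iterable[str]):
    import io

    return io.StringIO("".join(line for line in fh if not line.startswith("#")))


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, str) and not v.strip()) or pd.isna(v):
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(f)
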