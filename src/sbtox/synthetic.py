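"""Synthetic stand-ins for the external registry fixtures.

The analysis consumes three inputs that, in practice, come from national
registries: an age-indexed background-mortality life table, an
age-at-diagnosis incidence mix for ages 25-99 and an age-indexed baseline
utility curve.  This module generates synthetic fixtures with the same
statistical structure so the full pipeline runs with no download:

* mortality: Gompertz-Makeham hazard, ``qx(a) = 1 - exp(-(lam + A e^{B a}))``,
  with defaults giving a remaining life expectancy of roughly 15 years at
  age 70 (in the range of a contemporary Western European population);
* incidence: a discretized unimodal (Gaussian-kernel) age distribution,
  peaked at 70 — the typical late-adult mode of rectal-cancer diagnosis;
* utility: a non-increasing population norm curve in [0, 1], linear (or
  logistic) decline from ``u_young`` at 25 to ``u_old`` at 100.

The generators are deterministic closed forms; exact replication of any
specific national registry is explicitly not claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import LifeTable
from .valuation import UtilityCurve

__all__ = [
    "SyntheticConfig",
    "make_life_table",
    "make_incidence_mix",
    "make_utility_curve",
    "Fixtures",
    "default_fixtures",
    "write_fixtures",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic fixture generators."""

    makeham: float = 0.0005          # age-independent hazard (per year)
    gompertz_a: float = 2e-5         # baseline senescent hazard
    gompertz_b: float = 0.095        # log-slope of senescent hazard (per year)
    incidence_mode: float = 70.0     # modal age at diagnosis
    incidence_spread: float = 12.0   # Gaussian spread in years (0 = point mass)
    u_young: float = 0.90            # baseline utility at age 25
    u_old: float = 0.65              # baseline utility at age 100
    utility_shape: str = "linear"    # or "logistic"
    seed: int = 0                    # kept for interface stability (closed forms)

    def __post_init__(self) -> None:
        if self.makeham < 0 or self.gompertz_a < 0 or self.gompertz_b < 0:
            raise ValueError("mortality hazard parameters must be >= 0")
        if not 25 <= self.incidence_mode <= 99:
            raise ValueError("incidence_mode must lie in [25, 99]")
        if self.incidence_spread < 0:
            raise ValueError("incidence_spread must be >= 0")
        if not 0.0 <= self.u_old <= self.u_young <= 1.0:
            raise ValueError("require 0 <= u_old <= u_young <= 1")
        if self.utility_shape not in ("linear", "logistic"):
            raise ValueError(f"unknown utility_shape {self.utility_shape!r}")


def make_life_table(cfg: SyntheticConfig | None = None) -> LifeTable:
    """Gompertz-Makeham life table for ages 0-100."""
    cfg = cfg or SyntheticConfig()
    ages = np.arange(0, 101)
    hazard = cfg.makeham + cfg.gompertz_a * np.exp(cfg.gompertz_b * ages)
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    if np.any(qx[:60] > 0.99):
        warnings.warn("life-table configuration saturates (qx ~ 1) before age 60")
    return LifeTable(ages, qx)


def make_incidence_mix(cfg: SyntheticConfig | None = None) -> pd.DataFrame:
    """Normalized unimodal age-at-diagnosis weights over ages 25-99."""
    cfg = cfg or SyntheticConfig()
    ages = np.arange(25, 100)
    if cfg.incidence_spread == 0:
        w = (ages == int(round(cfg.incidence_mode))).astype(float)
    else:
        w = np.exp(-0.5 * ((ages - cfg.incidence_mode) / cfg.incidence_spread) ** 2)
    w = w / w.sum()
    return pd.DataFrame({"age": ages, "weight": w})


def make_utility_curve(cfg: SyntheticConfig | None = None) -> UtilityCurve:
    """Non-increasing baseline utility over ages 25-100."""
    cfg = cfg or SyntheticConfig()
    ages = np.arange(25, 101, dtype=float)
    if cfg.utility_shape == "linear":
        u = cfg.u_young + (cfg.u_old - cfg.u_young) * (ages - 25.0) / 75.0
    else:
        # logistic decline centred in late adulthood, bounded by the endpoints
        z = 1.0 / (1.0 + np.exp((ages - 70.0) / 10.0))
        u = cfg.u_old + (cfg.u_young - cfg.u_old) * z
        u = np.minimum.accumulate(u)
    return UtilityCurve(ages, u)


@dataclass(frozen=True)
class Fixtures:
    """The three external inputs bundled together."""

    life_table: LifeTable
    incidence: pd.DataFrame
    utilities: UtilityCurve


def default_fixtures(cfg: SyntheticConfig | None = None) -> Fixtures:
    cfg = cfg or SyntheticConfig()
    return Fixtures(
        life_table=make_life_table(cfg),
        incidence=make_incidence_mix(cfg),
        utilities=make_utility_curve(cfg),
    )


def write_fixtures(out_dir: str | Path, cfg: SyntheticConfig | None = None) -> dict[str, Path]:
    """Write ``life_table.csv``, ``incidence.csv`` and ``utilities.csv``.

    Real registry extracts with the same schema (``age,qx`` / ``age,weight``
    / ``age,utility``) can be dropped into the same slots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = default_fixtures(cfg)
    paths = {
        "life_table": out / "life_table.csv",
        "incidence": out / "incidence.csv",
        "utilities": out / "utilities.csv",
    }
    fx.life_table.to_csv(paths["life_table"])
    fx.incidence.to_csv(paths["incidence"], index=False)
    fx.utilities.to_csv(paths["utilities"])
    return paths
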