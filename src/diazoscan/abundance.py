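"""Nitrogenase relative abundance, TN:TP ratios, and the quadratic response.

Relative frequency is reported as a percentage of the metagenomic library:
``100 * nifH_hits / library_size``. The nutrient response is modelled as a
degree-2 polynomial of the TN:TP mass ratio, fitted by ordinary least
squares per layer; its turning point is the vertex ``x* = -b / (2a)``,
a maximum when ``a < 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AbundanceRecord:
    sample_id: str
    date: str
    layer: str
    nifh_hits: int
    library_size: int
    per_taxon: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.per_taxon.values()) != self.nifh_hits:
            raise ValueError(
                f"{self.sample_id}: per-taxon counts do not sum to nifH hits"
            )

    @property
    def frequency(self) -> float:
        return relative_frequency(self.nifh_hits, self.library_size)


@dataclass(frozen=True)
class EnvRecord:
    date: str
    layer: str
    tn_ppb: float
    tp_ppb: float
    tdn_ppb: float | None = None
    tdp_ppb: float | None = None

    @property
    def tn_tp_ratio(self) -> float | None:
        return tn_tp_ratio(self.tn_ppb, self.tp_ppb)


@dataclass(frozen=True)
class QuadraticFit:
    a: float
    b: float
    c: float
    rss: float
    n: int
    layer: str = ""

    @property
    def vertex(self) -> float | None:
        """Turning point -b/(2a); None when the fit is effectively linear."""
        if abs(self.a) < 1e-12:
            return None
        return -self.b / (2.0 * self.a)

    @property
    def is_maximum(self) -> bool:
        return self.a < 0


def relative_frequency(hits: int, library_size: int) -> float:
    """Percent of library reads assigned to nifH: 100 * hits / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if not 0 <= hits <= library_size:
        raise ValueError("hits must lie in [0, library_size]")
    return 100.0 * hits / library_size


def composition(per_taxon: Mapping[str, int | float]) -> dict[str, float]:
    """Per-taxon proportions of the nifH-assigned pool (sum to 1)."""
    if any(v < 0 for v in per_taxon.values()):
        raise ValueError("negative taxon count")
    total = float(sum(per_taxon.values()))
    if total <= 0:
        raise ValueError("composition of an all-zero count vector is undefined")
    return {taxon: v / total for taxon, v in per_taxon.items()}


def tn_tp_ratio(tn_ppb: float | None, tp_ppb: float | None) -> float | None:
    """TN:TP mass ratio; None when either nutrient is missing."""
    if tn_ppb is None or tp_ppb is None:
        return None
    if isinstance(tn_ppb, float) and math.isnan(tn_ppb):
        return None
    if isinstance(tp_ppb, float) and math.isnan(tp_ppb):
        return None
    if tn_ppb <= 0 or tp_ppb <= 0:
        raise ValueError("TN and TP must be positive when present")
    return tn_ppb / tp_ppb


def fit_quadratic(
    x: Sequence[float], y: Sequence[float], layer: str = ""
) -> QuadraticFit:
    """OLS fit of ``y = a x^2 + b x + c`` on the Vandermonde design."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if np.allclose(x, x[0]):
        raise ValueError("design is rank deficient: all x values are equal")
    if np.unique(x).size < 3:
        raise ValueError("design is rank deficient: fewer than 3 distinct x values")
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    return QuadraticFit(
        a=float(coeffs[0]),
        b=float(coeffs[1]),
        c=float(coeffs[2]),
        rss=float(resid @ resid),
        n=int(x.size),
        layer=layer,
    )


def read_env_table(path) -> pd.DataFrame:
    """Read an environmental TSV (date, layer, TN_ppb, TP_ppb, TDN_ppb,
    TDP_ppb) and append the tn_tp_ratio column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["tn_tp_ratio"] = df["TN_ppb"] / df["TP_ppb"]
    return df


def build_abundance_table(
    records: Sequence[AbundanceRecord], env: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Tabulate per-sample frequencies (percent) with optional env merge."""
    taxa = sorted({t for r in records for t in r.per_taxon})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "date": r.date,
            "layer": r.layer,
            "nifH_hits": r.nifh_hits,
            "library_size": r.library_size,
            "frequency_pct": r.frequency,
        }
        for t in taxa:
            row[f"n_{t}"] = r.per_taxon.get(t, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if env is not None:
        df = df.merge(env, on=["date", "layer"], how="left")
    return df


def fit_layers(table: pd.DataFrame) -> dict[str, QuadraticFit]:
    """Fit the frequency ~ TN:TP quadratic independently per layer."""
    fits: dict[str, QuadraticFit] = {}
    for layer, sub in table.groupby("layer"):
        sub = sub.dropna(subset=["tn_tp_ratio"])
        if len(sub) >= 4:
            fits[layer] = fit_quadratic(
                sub["tn_tp_ratio"].to_numpy(),
                sub["frequency_pct"].to_numpy(),
                layer=layer,
            )
    return fits
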