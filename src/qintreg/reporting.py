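"""WHO cut-off classification, prevalence tables and effect significance.

Under the 2006 WHO child growth standard a child is *overweight* when
``2 <= BMIAZ <= 3`` and *obese* when ``BMIAZ > 3`` (the boundary value 3 is
overweight: the two published cut-offs leave no other consistent assignment).
Prevalence tables report per-survey-year counts and percentages rounded
half-up to one decimal, the display convention of DHS-style reports.

Structured spatial effects are summarised per region by the posterior mean,
an equal-tailed credible interval and a three-way significance code:
``+1`` when the interval lies entirely above zero, ``-1`` entirely below,
``0`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping
import warnings

import numpy as np
import pandas as pd

from .synthetic import AnalysisDataset

__all__ = [
    "classify_bmiaz",
    "prevalence_table",
    "prevalence_from_counts",
    "RegionEffectSummary",
    "classify_region_effects",
]

NOT_OVERWEIGHT = "not_overweight"
OVERWEIGHT = "overweight"
OBESE = "obese"


def classify_bmiaz(z):
    """Classify BMIAZ value(s) into not_overweight / overweight / obese."""
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("BMIAZ must be finite")
    out = np.where(arr > 3, OBESE,
                   np.where(arr >= 2, OVERWEIGHT, NOT_OVERWEIGHT))
    return str(out) if out.ndim == 0 else out


def _round1(x: float) -> float:
    """Half-up rounding to one decimal (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prevalence_from_counts(total: int, overweight: int, obese: int) -> dict[str, float]:
    """Percentages from printed counts: overweight, obese and combined."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {
        "overweight_pct": _round1(100.0 * overweight / total),
        "obese_pct": _round1(100.0 * obese / total),
        "combined_pct": _round1(100.0 * (overweight + obese) / total),
    }


def prevalence_table(data: AnalysisDataset) -> pd.DataFrame:
    """Per-year prevalence of overweight and obesity.

    Columns: year, total, overweight (count), overweight_pct, obese (count),
    obese_pct, combined_pct.  Years with zero records are omitted with a
    warning.
    """
    df = data.df
    if len(df) == 0:
        raise ValueError("dataset is empty")
    status = classify_bmiaz(df["bmiaz"].to_numpy())
    rows = []
    for year, idx in df.groupby("year").groups.items():
        sub = status[df.index.get_indexer(idx)]
        total = len(sub)
        if total == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"year {year} has no records; omitted")
            continue
        n_over = int(np.sum(sub == OVERWEIGHT))
        n_obese = int(np.sum(sub == OBESE))
        rows.append({
            "year": int(year), "total": total,
            "overweight": n_over,
            "overweight_pct": _round1(100.0 * n_over / total),
            "obese": n_obese,
            "obese_pct": _round1(100.0 * n_obese / total),
            "combined_pct": _round1(100.0 * (n_over + n_obese) / total),
        })
    return pd.DataFrame(rows).sort_values("year", ignore_index=True)


@dataclass(frozen=True)
class RegionEffectSummary:
    region_id: str
    mean: float
    lower: float
    upper: float
    code: int  # +1 / 0 / -1


def classify_region_effects(
    spatial_draws: Mapping[str, np.ndarray] | tuple[list[str], np.ndarray],
    level: float = 0.95,
) -> list[RegionEffectSummary]:
    """Three-way significance coding of structured spatial effects.

    ``spatial_draws`` is either a mapping region -> draw vector or a
    ``(labels, draws)`` pair with a (draws x regions) matrix.  The code is
    ``+1`` iff the equal-tailed interval's lower bound is > 0, ``-1`` iff its
    upper bound is < 0, else ``0``.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if isinstance(spatial_draws, tuple):
        labels, draws = spatial_draws
        items = [(lab, draws[:, j]) for j, lab in enumerate(labels)]
    else:
        items = list(spatial_draws.items())
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    out = []
    for region, d in items:
        d = np.asarray(d, dtype=float)
        if d.size < 2:
            raise ValueError(f"need >= 2 draws for region {region!r}")
        lower, upper = float(np.quantile(d, lo)), float(np.quantile(d, hi))
        code = 1 if lower > 0 else (-1 if upper < 0 else 0)
        out.append(RegionEffectSummary(str(region), float(d.mean()),
                                       lower, upper, code))
    return out
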