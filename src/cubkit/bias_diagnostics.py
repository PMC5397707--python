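"""Mutation-vs-selection diagnostics.

The ENc-GC3s null curve (expected ENc under pure compositional bias), the
relative ENc deviation histogram, parity-rule-2 (PR2) coordinates over the
eight four-codon families, and the neutrality (GC12 on GC3) regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable
from .genetics import CODON_INDEX, PR2_FAMILIES


def expected_enc(s):
    """Wright's null curve: expected ENc at synonymous GC3 fraction ``s``.

        ENc_exp = 2 + s + 29 / (s^2 + (1-s)^2)

    Accepts a scalar or array; raises outside [0, 1].
    """
    arr = np.asarray(s, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("GC3s must lie in [0, 1]")
    val = 2.0 + arr + 29.0 / (arr**2 + (1.0 - arr) ** 2)
    return float(val) if np.isscalar(s) else val


@dataclass
class EncDeviation:
    """Per-gene observed vs curve-expected ENc and their relative deviation."""

    enc_obs: float
    enc_exp: float

    @property
    def rel_dev(self) -> float:
        if not (self.enc_exp > 0) or math.isnan(self.enc_obs):
            return math.nan
        return (self.enc_exp - self.enc_obs) / self.enc_exp


def enc_deviation(enc_obs, gc3s) -> pd.DataFrame:
    """Vectorised (ENc_exp - ENc_obs) / ENc_exp for aligned per-gene arrays."""
    obs = pd.Series(enc_obs, dtype=float)
    s = pd.Series(gc3s, dtype=float).reindex(obs.index)
    exp = pd.Series(expected_enc(s.fillna(0.5).values), index=obs.index)
    exp[s.isna()] = np.nan
    rel = (exp - obs) / exp
    return pd.DataFrame({"enc_obs": obs, "enc_exp": exp, "rel_dev": rel})


def enc_deviation_histogram(
    rel_devs: Iterable[float], bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of relative ENc deviations in half-open bins anchored at 0.

    Bins are [k*w, (k+1)*w); returns (bin_edges, counts) with counts
    summing to the number of defined deviations.
    """
    x = np.asarray([v for v in rel_devs if not math.isnan(v)], dtype=float)
    if x.size == 0:
        raise ValueError("no defined deviations")
    lo = math.floor(x.min() / bin_width)
    hi = math.floor(x.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    idx = np.floor(x / bin_width).astype(int) - lo
    counts = np.bincount(idx, minlength=hi - lo)
    return edges, counts


@dataclass
class Pr2Point:
    """PR2 coordinates of one gene: x = G3/(G3+C3), y = A3/(A3+T3).

    Third-position tallies are restricted to the 32 codons of the eight
    four-codon families (Leu -> CUN, Ser -> UCN, Arg -> CGN only). Either
    coordinate is NaN when its denominator is zero.
    """

    x: float
    y: float
    n_codons_used: int


def pr2_coordinates(counts: CodonCountTable) -> Pr2Point:
    tall = {b: 0 for b in "ACGT"}
    used = 0
    for cods in PR2_FAMILIES.values():
        for c in cods:
            n = int(counts.counts[CODON_INDEX[c]])
            tall[c[2]] += n
            used += n
    gc = tall["G"] + tall["C"]
    at = tall["A"] + tall["T"]
    return Pr2Point(
        x=tall["G"] / gc if gc else math.nan,
        y=tall["A"] / at if at else math.nan,
        n_codons_used=used,
    )


@dataclass
class Pr2Summary:
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    quadrant_counts: dict[str, int]
    n: int


def pr2_summary(points: Sequence[Pr2Point]) -> Pr2Summary:
    """Means, SDs and quadrant occupancy (split at 0.5) of defined PR2 points."""
    xy = np.array(
        [(p.x, p.y) for p in points if not (math.isnan(p.x) or math.isnan(p.y))]
    )
    if xy.size == 0:
        raise ValueError("no defined PR2 points")
    x, y = xy[:, 0], xy[:, 1]
    quads = {
        "upper_right": int(((x >= 0.5) & (y >= 0.5)).sum()),
        "upper_left": int(((x < 0.5) & (y >= 0.5)).sum()),
        "lower_left": int(((x < 0.5) & (y < 0.5)).sum()),
        "lower_right": int(((x >= 0.5) & (y < 0.5)).sum()),
    }
    return Pr2Summary(
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        quadrant_counts=quads,
        n=len(x),
    )


@dataclass
class NeutralityFit:
    """OLS of GC12 on GC3 with the neutral-point (OP) intersection.

    slope ~ 1 indicates complete neutrality (mutation dominates all codon
    positions equally); slope ~ 0 indicates complete selective constraint
    on the first two positions. OP = intercept / (1 - slope) is where the
    regression crosses the GC12 = GC3 diagonal; reported both as a
    fraction and on the percentage scale.
    """

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def op_point(self) -> float:
        if abs(1.0 - self.slope) < 1e-12:
            return math.nan
        return self.intercept / (1.0 - self.slope)

    @property
    def op_point_percent(self) -> float:
        return 100.0 * self.op_point

    @property
    def slope_stderr(self) -> float:
        return self._stderr

    _stderr: float = math.nan


def neutrality_fit(gc3, gc12) -> NeutralityFit:
    """Ordinary least squares of per-gene GC12 against GC3."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 genes with defined GC12 and GC3")
    res = stats.linregress(x, y)
    fit = NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(x),
    )
    fit._stderr = float(res.stderr)
    return fit
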