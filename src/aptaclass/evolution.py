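"""Round-wise enrichment summaries and the saturating-exponential fit.

For each SELEX round the module reports the fraction of "winning" aptamers
(predicted class label 2) and the mean fold free energy E.  Across rounds
the winning fraction is fitted with the saturating exponential
f(r) = a·(1 − exp(−b·(r−1))) — the simplest curve consistent with
exponential enrichment that approaches a plateau, anchored so that round 1
(the naive pool) starts near zero — where a is the plateau fraction and b
the enrichment rate per round.  A logistic alternative is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .pool_io import Pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoundSummary:
    round_index: int
    n_sequences: int
    winning_fraction: float
    mean_E: float


@dataclass(frozen=True)
class EnrichmentFit:
    a: float  # plateau fraction
    b: float  # enrichment rate per round
    r_squared: float
    form: str = "saturating_exp"

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if self.form == "logistic":
            return self.a / (1 + np.exp(-self.b * (r - 1)))
        return self.a * (1 - np.exp(-self.b * (r - 1)))


def summarize_rounds(
    predictions: Mapping[str, int],
    pool: Pool,
    energies: Mapping[str, float],
) -> list[RoundSummary]:
    """One :class:`RoundSummary` per round present, ordered by round.

    ``predictions`` and ``energies`` map ``record.key`` to the predicted
    class label and the fold free energy.
    """
    out = []
    for rnd in sorted(pool.rounds_present):
        recs = pool.by_round(rnd)
        if not recs:  # pragma: no cover - rounds_present guarantees records
            logger.warning("round %d has no records; omitted", rnd)
            continue
        missing = [r.key for r in recs if r.key not in predictions or r.key not in energies]
        if missing:
            raise ValueError(f"missing prediction/energy for {missing[:5]}")
        frac = float(np.mean([predictions[r.key] == 2 for r in recs]))
        mean_e = float(np.mean([energies[r.key] for r in recs]))
        out.append(RoundSummary(rnd, len(recs), frac, mean_e))
    return out


def _saturating(r, a, b):
    return a * (1 - np.exp(-b * (r - 1)))


def _logistic(r, a, b):
    return a / (1 + np.exp(-b * (r - 1)))


def fit_enrichment(
    summaries: Sequence[RoundSummary] | None = None,
    rounds: Sequence[int] | None = None,
    fractions: Sequence[float] | None = None,
    form: str = "saturating_exp",
) -> EnrichmentFit:
    """Nonlinear least-squares fit of the enrichment curve.

    Accepts either round summaries or explicit (rounds, fractions) arrays.
    Multistart initialization over the rate parameter; raises if no start
    converges.
    """
    if summaries is not None:
        rounds = [s.round_index for s in summaries]
        fractions = [s.winning_fraction for s in summaries]
    if rounds is None or fractions is None:
        raise ValueError("need summaries or (rounds, fractions)")
    r = np.asarray(rounds, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(r) < 4:
        raise ValueError("enrichment fit needs at least 4 rounds")
    if np.ptp(f) < 1e-12:
        warnings.warn("constant fraction series; enrichment rate is degenerate")
    func = _logistic if form == "logistic" else _saturating

    best = None
    a0 = max(float(f.max()), 1e-3)
    for b0 in (0.05, 0.1, 0.3, 0.5, 1.0, 2.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    func,
                    r,
                    f,
                    p0=(a0, b0),
                    bounds=([1e-6, 1e-9], [1.05, 50.0]),
                    maxfev=10000,
                )
        except RuntimeError:
            continue
        resid = f - func(r, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise RuntimeError("enrichment fit failed to converge from any start")
    (a, b), sse = best
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return EnrichmentFit(a=float(a), b=float(b), r_squared=r2, form=form)


@dataclass(frozen=True)
class EnergyTrend:
    series: tuple[tuple[int, float], ...]  # (round, mean_E)
    decreasing_fraction: float  # fraction of adjacent pairs with falling mean_E


def mean_energy_trend(summaries: Sequence[RoundSummary]) -> EnergyTrend:
    """Mean-E-per-round series and how consistently it decreases."""
    if len(summaries) < 2:
        raise ValueError("trend needs at least 2 rounds")
    ordered = sorted(summaries, key=lambda s: s.round_index)
    series = tuple((s.round_index, s.mean_E) for s in ordered)
    drops = [series[i + 1][1] < series[i][1] for i in range(len(series) - 1)]
    return EnergyTrend(series=series, decreasing_fraction=float(np.mean(drops)))


def fraction_monotonicity(summaries: Sequence[RoundSummary]) -> float:
    """Spearman rank correlation of winning fraction against round index."""
    ordered = sorted(summaries, key=lambda s: s.round_index)
    rho, _ = spearmanr(
        [s.round_index for s in ordered], [s.winning_fraction for s in ordered]
    )
    return float(rho)
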