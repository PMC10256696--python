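"""Occupancy-normalised firing-rate coding tests for striatal neurons.

For a neuron recorded in one session, let ``N1``/``N2`` be its spike
counts inside a maze region (lateral descent, central stem, first
straight, ...) under two future-path conditions, and ``d1``/``d2`` the
time the animal spent in the region under each condition.  If the
neuron does not distinguish the conditions, ``(N1, N2)`` is multinomial
with ``n = N1 + N2`` and cell probabilities proportional to the
occupancies, ``p = (d1/(d1+d2), d2/(d1+d2))``.  The coding test is the
chi-square goodness-of-fit test of that null (1 degree of freedom, no
continuity correction).

Neurons are excluded ("not possible") when either occupancy is zero or
when the minimum expected count ``n * min(p)`` is below 5 — the
standard chi-square validity rule, which also screens out neurons with
very low firing rates in the region.  Raw p-values of the possible
neurons in one region/condition-pair are Benjamini–Hochberg adjusted;
a neuron is *coding* when its adjusted p-value is below 0.05.

Region-level comparisons: one-sample Kolmogorov–Smirnov tests of the
p-value distribution against uniform(0, 1), two-sample KS tests between
regions, and exact McNemar tests on paired coding statuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NeuronCountRecord",
    "CodingResult",
    "coding_test",
    "adjust_bh",
    "analyze_region",
    "ks_uniformity",
    "ks_two_sample",
    "mcnemar",
    "simulate_spike_records",
    "records_to_frame",
    "frame_to_records",
    "region_summary",
]

CODING_ALPHA = 0.05
MIN_EXPECTED = 5.0


@dataclass(frozen=True)
class NeuronCountRecord:
    """Spike counts and occupancies of one neuron, region, condition pair."""

    neuron_id: str
    region_id: str
    condition_pair_id: str
    n1: int
    n2: int
    d1: float
    d2: float

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.n1 != int(self.n1) or self.n2 != int(self.n2):
            raise ValueError("spike counts must be non-negative integers")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("occupancy durations must be non-negative")


@dataclass(frozen=True)
class CodingResult:
    neuron_id: str
    eligible: bool
    exclusion_reason: str  # "eligible" | "zero-duration" | "low-expected"
    p_value: float | None
    adjusted_p: float | None = None
    coding: bool = False


def coding_test(record: NeuronCountRecord) -> CodingResult:
    """Chi-square test of occupancy-proportional spike counts (raw stage).

    Returns an ineligible result (p_value ``None``) when an occupancy is
    zero or the minimum expected count falls below 5; otherwise the
    upper-tail p-value of the 1-df chi-square statistic.
    """
    if record.d1 == 0.0 or record.d2 == 0.0:
        return CodingResult(record.neuron_id, False, "zero-duration", None)
    d = record.d1 + record.d2
    p1, p2 = record.d1 / d, record.d2 / d
    n = record.n1 + record.n2
    if n * min(p1, p2) < MIN_EXPECTED:
        return CodingResult(record.neuron_id, False, "low-expected", None)
    expected = np.array([n * p1, n * p2])
    statistic, p_value = stats.chisquare([record.n1, record.n2], f_exp=expected)
    return CodingResult(record.neuron_id, True, "eligible", float(p_value))


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def analyze_region(records) -> list:
    """Run the full per-region pipeline: raw tests, BH, coding calls.

    ``records`` are all candidate neurons of ONE region/condition pair
    (the BH family the multiplicity correction is applied over).
    """
    raw = [coding_test(r) for r in records]
    eligible = [c for c in raw if c.eligible]
    adjusted = adjust_bh([c.p_value for c in eligible]) if eligible else []
    adj_iter = iter(adjusted)
    out = []
    for c in raw:
        if not c.eligible:
            out.append(c)
            continue
        adj = float(next(adj_iter))
        out.append(
            CodingResult(
                c.neuron_id, True, "eligible", c.p_value, adj, adj < CODING_ALPHA
            )
        )
    return out


def ks_uniformity(p_values) -> float:
    """One-sample KS p-value of the p-values against uniform(0, 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 p-values for the uniformity test")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(stats.kstest(p, "uniform").pvalue)


def ks_two_sample(p_values_x, p_values_y) -> float:
    """Two-sample KS p-value comparing two regions' p-value c.d.f.s."""
    x = np.asarray(list(p_values_x), dtype=float)
    y = np.asarray(list(p_values_y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 p-values per sample")
    return float(stats.ks_2samp(x, y).pvalue)


def mcnemar(status_x, status_y, exact: bool = True) -> tuple:
    """Exact McNemar test on paired coding statuses of the same neurons.

    Returns ``(p_value, degenerate)``; ``degenerate`` flags a table with
    no discordant pairs, for which the p-value is 1 by convention.  Set
    ``exact=False`` for the asymptotic chi-square version with
    continuity correction (coding-neuron counts here are typically
    small, so the exact binomial test is the default).
    """
    x = np.asarray(list(status_x), dtype=bool)
    y = np.asarray(list(status_y), dtype=bool)
    if x.shape != y.shape:
        raise ValueError("paired status vectors must have equal length")
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    if b + c == 0:
        return 1.0, True
    table = np.array([[int(np.sum(x & y)), b], [c, int(np.sum(~x & ~y))]])
    result = _sm_mcnemar(table, exact=exact, correction=not exact)
    return float(result.pvalue), False


def simulate_spike_records(
    n_neurons: int,
    coding_fraction: float = 0.2,
    base_rate: float = 5.0,
    rate_ratio: float = 3.0,
    mean_duration: float = 10.0,
    duration_sigma: float = 0.3,
    region_id: str = "central_stem",
    condition_pair_id: str = "left_vs_right",
    seed: int = 0,
) -> list:
    """Synthetic spike-count records with a known coding subpopulation.

    Occupancies are lognormal around ``mean_duration`` seconds; spike
    counts are Poisson(rate x occupancy).  A coding neuron fires at
    ``base_rate x rate_ratio`` under condition 2; ``rate_ratio=1`` gives
    a pure null population for calibration checks.
    """
    rng = np.random.default_rng(seed)
    n_coding = int(round(coding_fraction * n_neurons))
    records = []
    for i in range(n_neurons):
        is_coding = i < n_coding
        d1 = float(mean_duration * rng.lognormal(0.0, duration_sigma))
        d2 = float(mean_duration * rng.lognormal(0.0, duration_sigma))
        r2 = base_rate * (rate_ratio if is_coding else 1.0)
        records.append(
            NeuronCountRecord(
                neuron_id=f"n{i:04d}{'c' if is_coding else ''}",
                region_id=region_id,
                condition_pair_id=condition_pair_id,
                n1=int(rng.poisson(base_rate * d1)),
                n2=int(rng.poisson(r2 * d2)),
                d1=d1,
                d2=d2,
            )
        )
    return records


# -- tabular interface -------------------------------------------------------

_COLUMNS = ["neuron", "region", "condition_pair", "N1", "N2", "d1", "d2"]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.neuron_id, r.region_id, r.condition_pair_id, r.n1, r.n2, r.d1, r.d2)
            for r in records
        ],
        columns=_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list:
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"neural CSV is missing columns: {sorted(missing)}")
    return [
        NeuronCountRecord(
            str(row.neuron),
            str(row.region),
            str(row.condition_pair),
            int(row.N1),
            int(row.N2),
            float(row.d1),
            float(row.d2),
        )
        for row in frame.itertuples()
    ]


def region_summary(records) -> dict:
    """Per region/condition-pair tabulation of possible and coding neurons,
    with the KS uniformity p-value of the eligible raw p-values."""
    frame = records_to_frame(records)
    summary = {}
    for (region, pair), group in frame.groupby(["region", "condition_pair"]):
        group_records = frame_to_records(group)
        results = analyze_region(group_records)
        eligible = [c for c in results if c.eligible]
        entry = {
            "candidates": len(results),
            "possible": len(eligible),
            "coding": sum(c.coding for c in eligible),
        }
        if len(eligible) >= 2:
            entry["ks_uniformity_p"] = ks_uniformity([c.p_value for c in eligible])
        summary[f"{region}/{pair}"] = entry
    return summary
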