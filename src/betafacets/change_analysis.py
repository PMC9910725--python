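"""Scenario-to-historical change summaries.

Per basin pair, the change in an index is the scenario value minus the
historical value (Delta).  Negative Delta of beta-diversity across pairs is
the signature of biotic homogenization.  Summaries include percent change of
pair means, sign-quadrant fractions of the joint taxonomic/functional
deltas, turnover/nestedness shares of total beta-diversity, and paired
scenario-vs-historical tests (Wilcoxon signed-rank and paired t; both are
reported because either may be encountered in published summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .taxonomic_beta import PairwiseBetaTable

COMPONENTS = ("beta", "turnover", "nestedness")


class DegenerateTestError(ValueError):
    """The paired test is undefined (e.g. all differences zero)."""


@dataclass
class DeltaTable:
    """Per-pair scenario-minus-historical changes for one facet."""

    facet: str
    scenario: str
    basin_pairs: list[tuple[str, str]]
    values: np.ndarray  # n_pairs x 3: dbeta, dturnover, dnestedness

    @property
    def dbeta(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def dturnover(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def dnestedness(self) -> np.ndarray:
        return self.values[:, 2]

    def component(self, name: str) -> np.ndarray:
        return self.values[:, COMPONENTS.index(name)]


@dataclass(frozen=True)
class PairedTestResult:
    statistic_name: str  # "Z" or "t"
    statistic: float
    p: float
    n: int


@dataclass(frozen=True)
class QuadrantFractions:
    """Percentages of pairs by joint sign of (taxonomic, functional) deltas.

    Strict signs; pairs with an exact zero on either axis are reported in
    ``ties`` rather than folded into a quadrant.  The five numbers sum to
    100.
    """

    neg_neg: float
    pos_neg: float
    neg_pos: float
    pos_pos: float
    ties: float


def pair_deltas(scen: PairwiseBetaTable, hist: PairwiseBetaTable) -> DeltaTable:
    """Element-wise scenario minus historical over identically ordered pairs."""
    if scen.facet != hist.facet:
        raise ValueError(f"facet mismatch: {scen.facet} vs {hist.facet}")
    if scen.basin_pairs != hist.basin_pairs:
        raise ValueError("basin-pair sets or ordering differ between tables")
    return DeltaTable(
        facet=scen.facet,
        scenario=scen.scenario,
        basin_pairs=list(scen.basin_pairs),
        values=scen.values - hist.values,
    )


def mean_percent_change(scen: PairwiseBetaTable, hist: PairwiseBetaTable,
                        component: str) -> float:
    """100 * (mean(scen) - mean(hist)) / mean(hist) for one component.

    Computed on means of pairs (not the mean of per-pair percent changes).
    """
    k = COMPONENTS.index(component)
    mh = float(hist.values[:, k].mean())
    if mh == 0:
        raise ZeroDivisionError(f"historical mean of {component} is zero")
    ms = float(scen.values[:, k].mean())
    return 100.0 * (ms - mh) / mh


def quadrant_fractions(d_td: np.ndarray, d_fd: np.ndarray) -> QuadrantFractions:
    """Sign-quadrant percentages of paired taxonomic/functional deltas."""
    d_td = np.asarray(d_td, dtype=float)
    d_fd = np.asarray(d_fd, dtype=float)
    if d_td.shape != d_fd.shape:
        raise ValueError("delta vectors must have equal length")
    n = d_td.size
    tie = (d_td == 0) | (d_fd == 0)
    pct = lambda mask: 100.0 * int(mask.sum()) / n
    return QuadrantFractions(
        neg_neg=pct(~tie & (d_td < 0) & (d_fd < 0)),
        pos_neg=pct(~tie & (d_td > 0) & (d_fd < 0)),
        neg_pos=pct(~tie & (d_td < 0) & (d_fd > 0)),
        pos_pos=pct(~tie & (d_td > 0) & (d_fd > 0)),
        ties=pct(tie),
    )


def component_shares(table: PairwiseBetaTable) -> tuple[float, float]:
    """(turnover %, nestedness %) of mean total beta-diversity."""
    mb = float(table.beta.mean())
    if mb == 0:
        raise ZeroDivisionError("mean beta is zero")
    return (
        100.0 * float(table.turnover.mean()) / mb,
        100.0 * float(table.nestedness.mean()) / mb,
    )


def paired_test(hist: np.ndarray, scen: np.ndarray,
                method: str = "wilcoxon_signed_rank") -> PairedTestResult:
    """Paired scenario-vs-historical test on per-pair index values.

    ``wilcoxon_signed_rank`` reports the normal-approximation Z statistic;
    ``paired_t`` reports Student's t.  Differences are scenario minus
    historical.  All-zero differences are degenerate for the signed-rank
    test; zero-variance nonzero differences are degenerate for the t test.
    Identical vectors under ``paired_t`` return t = 0, p = 1 by convention.
    """
    hist = np.asarray(hist, dtype=float)
    scen = np.asarray(scen, dtype=float)
    if hist.shape != scen.shape or hist.ndim != 1 or hist.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = scen - hist
    n = hist.size
    if method == "wilcoxon_signed_rank":
        if np.all(diff == 0):
            raise DegenerateTestError("all paired differences are zero")
        res = stats.wilcoxon(diff, method="approx")
        return PairedTestResult("Z", float(res.zstatistic), float(res.pvalue), n)
    if method == "paired_t":
        if np.all(diff == 0):
            return PairedTestResult("t", 0.0, 1.0, n)
        if np.std(diff, ddof=1) <= 1e-12 * np.abs(diff).max():
            raise DegenerateTestError(
                "paired differences have zero variance (nonzero shift)"
            )
        res = stats.ttest_rel(scen, hist)
        return PairedTestResult("t", float(res.statistic), float(res.pvalue), n)
    raise ValueError(f"unknown method {method!r}")
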