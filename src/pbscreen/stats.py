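"""Screen statistics: panel enrichment, binned distributions, cell-cycle exit.

Panel enrichment asks whether k of the n candidate-panel genes falling
in a set of K mutated genes (out of a universe of N genes, default
20,000) is more overlap than chance: the upper-tail hypergeometric
probability P(X >= k).  The exact sum is computed in log space; a
resampling null (drawing n genes without replacement) provides an
independent Monte-Carlo route to the same quantity.

Binned-distribution comparisons score per-animal fractions of labeled
cells across cortical bins (CP, IZ, VZ/SVZ, optionally WM) and compare
conditions with a one-sided two-sample t test, optionally one-way ANOVA
with Bonferroni-corrected pairwise post hocs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from ._util import InputError

DEFAULT_UNIVERSE = 20_000
DEFAULT_BINS = ("CP", "IZ", "VZ/SVZ")


@dataclass
class EnrichmentInput:
    N: int  # gene universe
    K: int  # mutated-gene set size
    n: int  # panel size
    k: int  # observed overlap

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise InputError("k: must satisfy 0 <= k <= min(n, K)")
        if self.K > self.N:
            raise InputError("K: must satisfy K <= N")
        if self.n > self.N:
            raise InputError("n: must satisfy n <= N")
        if min(self.N, self.K, self.n) < 0:
            raise InputError("N, K, n must be non-negative")


@dataclass
class EnrichmentResult:
    p_upper: float
    expected_overlap: float
    method: str  # 'exact_sum' or 'resampling'
    inp: EnrichmentInput
    n_resamples: int | None = None
    seed: int | None = None


def _log_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log C(K,i) + log C(N-K,n-i) - log C(N,n) via gammaln."""

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(K, i) + logC(N - K, n - i) - logC(N, n)


def hypergeom_upper_tail(inp: EnrichmentInput) -> EnrichmentResult:
    """Exact P(X >= k) under hypergeometric(N, K, n), summed in log space."""
    lo = max(inp.k, inp.n - (inp.N - inp.K))
    hi = min(inp.n, inp.K)
    if lo > hi:
        p = 0.0
    else:
        i = np.arange(lo, hi + 1, dtype=float)
        p = float(np.exp(logsumexp(_log_pmf(i, inp.N, inp.K, inp.n))))
    return EnrichmentResult(
        p_upper=min(1.0, max(0.0, p)),
        expected_overlap=inp.n * inp.K / inp.N,
        method="exact_sum",
        inp=inp,
    )


def _sample_without_replacement(rng: np.random.Generator, N: int, n: int) -> set[int]:
    """Floyd's algorithm: n distinct integers from range(N) in O(n)."""
    chosen: set[int] = set()
    for j in range(N - n, N):
        t = int(rng.integers(0, j + 1))
        chosen.add(j if t in chosen else t)
    return chosen


def resampling_null(
    inp: EnrichmentInput, n_resamples: int = 100_000, seed: int | None = 0
) -> EnrichmentResult:
    """Monte-Carlo upper tail: draw n genes from N (first K marked), count
    resamples with overlap >= k.  Uses the add-one correction
    p = (successes + 1) / (R + 1) so p is never exactly zero."""
    if n_resamples < 1000:
        raise InputError("n_resamples: must be >= 1000")
    if seed is not None and not isinstance(seed, (int, np.integer)):
        raise InputError("seed: must be an integer or None")
    rng = np.random.default_rng(seed)
    successes = 0
    for _ in range(n_resamples):
        draw = _sample_without_replacement(rng, inp.N, inp.n)
        overlap = sum(1 for x in draw if x < inp.K)
        if overlap >= inp.k:
            successes += 1
    return EnrichmentResult(
        p_upper=(successes + 1) / (n_resamples + 1),
        expected_overlap=inp.n * inp.K / inp.N,
        method="resampling",
        inp=inp,
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Binned neuronal distributions


def bin_fractions(
    cells: pd.DataFrame, bins: tuple[str, ...] = DEFAULT_BINS
) -> pd.DataFrame:
    """Per-animal bin fractions from a per-cell table (animal, condition, bin).

    Animals with zero cells are excluded with a warning.  Fractions sum
    to 1 per animal.  Also usable with a WM bin appended.
    """
    bad = set(cells["bin"]) - set(bins)
    if bad:
        raise InputError(f"bin: unknown labels {sorted(bad)}")
    rows = []
    for (animal, condition), grp in cells.groupby(["animal", "condition"], sort=True):
        total = len(grp)
        if total == 0:  # defensive; groupby never yields empty groups
            warnings.warn(f"animal {animal}: zero cells, excluded")
            continue
        counts = grp["bin"].value_counts()
        row = {"animal": animal, "condition": condition, "n_cells": total}
        for b in bins:
            row[b] = counts.get(b, 0) / total
        rows.append(row)
    return pd.DataFrame(rows)


def condition_summary(fractions: pd.DataFrame, bins=DEFAULT_BINS) -> pd.DataFrame:
    """Condition-level mean and s.d. of per-animal fractions."""
    return fractions.groupby("condition")[list(bins)].agg(["mean", "std"])


def compare_conditions(
    fractions: pd.DataFrame,
    control: str,
    bins: tuple[str, ...] = DEFAULT_BINS,
    directions: dict[str, str] | None = None,
    anova: bool = False,
) -> pd.DataFrame:
    """One-sided two-sample t tests of each condition vs the control, per bin.

    The default alternative expects treatments to accumulate cells in
    the deep bins (VZ/SVZ, IZ 'greater') at the expense of the cortical
    plate (CP 'less'); directions are configurable.  With `anova=True`
    and >= 3 conditions a one-way ANOVA p and Bonferroni-corrected
    pairwise p values are appended per bin.
    """
    directions = directions or {"CP": "less", "IZ": "greater", "VZ/SVZ": "greater",
                                "WM": "greater"}
    conditions = sorted(set(fractions["condition"]))
    if control not in conditions:
        raise InputError(f"control condition {control!r} not present")
    if len(conditions) < 2:
        raise InputError("need at least two conditions to compare")
    ctrl = fractions[fractions["condition"] == control]
    rows = []
    n_tests = (len(conditions) - 1) * len(bins)
    for cond in conditions:
        if cond == control:
            continue
        trt = fractions[fractions["condition"] == cond]
        if len(trt) < 2 or len(ctrl) < 2:
            raise InputError("need >= 2 animals per condition")
        for b in bins:
            x, y = trt[b].to_numpy(), ctrl[b].to_numpy()
            if np.std(x) == 0 and np.std(y) == 0:
                raise InputError(f"bin {b}: zero variance in both groups, t undefined")
            res = sps.ttest_ind(x, y, alternative=directions.get(b, "greater"))
            row = {"condition": cond, "bin": b, "t": float(res.statistic),
                   "p_one_sided": float(res.pvalue),
                   "mean_treatment": float(x.mean()), "mean_control": float(y.mean())}
            if anova and len(conditions) >= 3:
                groups = [fractions[fractions["condition"] == c][b].to_numpy()
                          for c in conditions]
                row["anova_p"] = float(sps.f_oneway(*groups).pvalue)
                row["p_bonferroni"] = min(1.0, row["p_one_sided"] * n_tests)
            rows.append(row)
    return pd.DataFrame(rows)


def cell_cycle_exit_ratio(n_gfp_brdu: int, n_gfp_brdu_ki67neg: int) -> float:
    """Fraction of BrdU+ electroporated cells that are Ki67- 24 h later.

    The ratio of cells that left the cycle: (GFP+ BrdU+ Ki67-) / (GFP+ BrdU+).
    """
    if n_gfp_brdu <= 0:
        raise InputError("n_gfp_brdu: must be positive")
    if not 0 <= n_gfp_brdu_ki67neg <= n_gfp_brdu:
        raise InputError("n_gfp_brdu_ki67neg: must be within [0, n_gfp_brdu]")
    return n_gfp_brdu_ki67neg / n_gfp_brdu
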