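"""Structure–function statistics for scored variant sets.

Covers the analyses that relate residual scores to experimental activity:
conservative/non-conservative substitution classes, per-class mean residual
scores with a Welch t-test, residual-score binning with chi-square
contingency tests, Fisher's exact test for general r×c tables, and the
CMP-vs-RES regression with quadrant classification of residue positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: six physicochemical groups; replacements within a group are conservative
CONSERVATION_GROUPS: tuple[tuple[str, ...], ...] = (
    ("A", "S", "T", "G", "P"),
    ("D", "E", "N", "Q"),
    ("R", "K", "H"),
    ("F", "Y", "W"),
    ("V", "L", "I", "M"),
    ("C",),
)

_GROUP_OF = {aa: gi for gi, group in enumerate(CONSERVATION_GROUPS)
             for aa in group}


def classify_substitution(native: str, replacement: str) -> str:
    """'C' (conservative) for an intragroup replacement, else 'NC'."""
    try:
        same = _GROUP_OF[native] == _GROUP_OF[replacement]
    except KeyError as exc:
        raise ValueError(f"invalid amino acid code {exc.args[0]!r}") from None
    return "C" if same else "NC"


def class_mean_residuals(variants: pd.DataFrame) -> pd.DataFrame:
    """Mean residual score per activity class and substitution subclass.

    ``variants`` needs columns native, replacement, residual_score and
    activity (U/A). Returns rows for U and A crossed with All/C/NC, with
    counts; empty subgroups report NaN means.
    """
    df = variants.copy()
    df["substitution_class"] = [
        classify_substitution(n, r)
        for n, r in zip(df["native"], df["replacement"])]
    rows = []
    for activity in ("U", "A"):
        sub = df[df["activity"] == activity]
        for cls in ("All", "C", "NC"):
            part = sub if cls == "All" else \
                sub[sub["substitution_class"] == cls]
            rows.append({
                "activity": activity, "substitution_class": cls,
                "n": len(part),
                "mean_residual_score": float(part["residual_score"].mean())
                if len(part) else float("nan")})
    return pd.DataFrame(rows)


def two_sample_t_test(scores_a: Sequence[float],
                      scores_b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided unequal-variance t-test; returns (t, p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square of an r×c count table, no continuity correction.

    Returns (chi2, df, p). Zero row or column marginals are an error.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("zero marginal row or column")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def _log_table_prob(table: np.ndarray, lg_margins: float) -> float:
    """log multivariate hypergeometric probability of one table."""
    return lg_margins - sum(math.lgamma(x + 1) for x in table.ravel())


def _fisher_exact_enumerate(table: np.ndarray) -> float:
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    lg_margins = (sum(math.lgamma(r + 1) for r in rows)
                  + sum(math.lgamma(c + 1) for c in cols)
                  - math.lgamma(n + 1))
    obs_logp = _log_table_prob(table, lg_margins)
    cutoff = obs_logp + 1e-7  # tolerate round-off on equal-probability tables
    total = 0.0

    def rec(row_idx: int, col_rem: tuple[int, ...], logp_partial: float):
        nonlocal total
        if row_idx == len(rows) - 1:
            logp = logp_partial - sum(math.lgamma(c + 1) for c in col_rem)
            if logp <= cutoff:
                total += math.exp(logp)
            return
        r = rows[row_idx]

        def fill(col: int, remaining: int, rem: list[int], lp: float):
            if col == len(cols) - 1:
                if remaining <= rem[col]:
                    rem2 = tuple(rem[k] - (remaining if k == col else 0)
                                 for k in range(len(cols)))
                    rec(row_idx + 1, rem2,
                        lp - math.lgamma(remaining + 1))
                return
            for x in range(min(remaining, rem[col]) + 1):
                rem[col] -= x
                fill(col + 1, remaining - x, rem, lp - math.lgamma(x + 1))
                rem[col] += x

        fill(0, r, list(col_rem), logp_partial)

    rec(0, tuple(cols), lg_margins)
    return min(total, 1.0)


def _fisher_exact_montecarlo(table: np.ndarray, n_draws: int,
                             seed: int) -> float:
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    lg_margins = (sum(math.lgamma(r + 1) for r in rows)
                  + sum(math.lgamma(c + 1) for c in cols)
                  - math.lgamma(n + 1))
    obs = _log_table_prob(table, lg_margins)
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(rows, cols)
    hits = 0
    drawn = 0
    batch = 100_000
    while drawn < n_draws:
        k = min(batch, n_draws - drawn)
        samples = sampler.rvs(k, random_state=rng)
        logps = lg_margins - np.vectorize(math.lgamma)(
            samples.reshape(k, -1) + 1).sum(axis=1)
        hits += int((logps <= obs + 1e-7).sum())
        drawn += k
    # add-one estimator keeps p in (0, 1]
    return (hits + 1) / (n_draws + 1)


@dataclass(frozen=True)
class FisherResult:
    p: float
    method: str          # "exact" or "monte-carlo"
    n_draws: int | None = None
    seed: int | None = None


def fisher_exact_rxc(table, mode: str = "auto", n_draws: int = 1_000_000,
                     seed: int = 0, exact_max_total: int = 30) -> FisherResult:
    """Two-sided Fisher exact test for an r×c contingency table.

    The p-value is the total probability, under the multivariate
    hypergeometric null with fixed margins, of all tables no more probable
    than the observed one. Small tables (total count ≤ ``exact_max_total``)
    are enumerated exhaustively; larger ones fall back to a seeded Monte
    Carlo over Patefield-sampled tables (method flagged in the result).
    All-zero rows/columns are dropped first (they leave p unchanged).
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or min(t.shape) == 1:
        return FisherResult(p=1.0, method="exact")
    if mode not in ("auto", "exact", "monte-carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" or (mode == "auto" and t.sum() <= exact_max_total):
        return FisherResult(p=_fisher_exact_enumerate(t), method="exact")
    return FisherResult(p=_fisher_exact_montecarlo(t, n_draws, seed),
                        method="monte-carlo", n_draws=n_draws, seed=seed)


RESIDUAL_BINS = (-1.0, 0.0, 1.0)
RESIDUAL_BIN_LABELS = ("(-inf,-1)", "[-1,0)", "[0,1)", "[1,inf)")


def bin_residual_scores(scores, breakpoints: Sequence[float] = RESIDUAL_BINS
                        ) -> np.ndarray:
    """Assign scores to the intervals (−∞,b1), [b1,b2), …, [bk,∞).

    With the default breakpoints (−1, 0, 1) this reproduces the four
    left-closed/right-open residual-score clusters. Returns bin indices
    0..len(breakpoints).
    """
    return np.digitize(np.asarray(scores, dtype=float),
                       np.asarray(breakpoints, dtype=float), right=False)


def activity_residual_table(variants: pd.DataFrame,
                            breakpoints: Sequence[float] = RESIDUAL_BINS
                            ) -> pd.DataFrame:
    """2×k contingency table: activity classes × residual-score bins."""
    bins = bin_residual_scores(variants["residual_score"], breakpoints)
    labels = RESIDUAL_BIN_LABELS if tuple(breakpoints) == RESIDUAL_BINS else \
        [f"bin{i}" for i in range(len(breakpoints) + 1)]
    out = pd.DataFrame(0, index=["U", "A"], columns=list(labels))
    for activity, b in zip(variants["activity"], bins):
        out.loc[activity, labels[b]] += 1
    return out


def assign_quadrant(x: float, y: float) -> str:
    """Cartesian quadrant, counterclockwise from (+, +); zeros go positive."""
    if x >= 0 and y >= 0:
        return "Q1"
    if x < 0 and y >= 0:
        return "Q2"
    if x < 0 and y < 0:
        return "Q3"
    return "Q4"


def quadrant_table(q_wt: Mapping[int, float], cmp: Mapping[int, float],
                   annotations: Mapping[int, str]) -> pd.DataFrame:
    """Cross-tabulate residue categories against CMP-vs-RES plot quadrants.

    The plot convention is x = native residue environment score q_wt,
    y = CMP. Only positions present in ``annotations`` are counted.
    """
    quads = ("Q1", "Q2", "Q3", "Q4")
    cats = sorted(set(annotations.values()))
    out = pd.DataFrame(0, index=list(quads), columns=cats)
    for pos, cat in annotations.items():
        out.loc[assign_quadrant(q_wt[pos], cmp[pos]), cat] += 1
    return out


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False  # True when y has zero variance


def cmp_res_regression(q_wt: Sequence[float],
                       cmp: Sequence[float]) -> RegressionResult:
    """OLS of CMP on RES; R² is the squared Pearson correlation."""
    x = np.asarray(q_wt, dtype=float)
    y = np.asarray(cmp, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        slope = 0.0 if np.ptp(x) > 0 else float("nan")
        return RegressionResult(slope=slope, intercept=float(y.mean()),
                                r_squared=0.0, degenerate=True)
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))
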