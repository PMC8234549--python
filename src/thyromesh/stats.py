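"""Design and analysis machinery of the randomized informed-consent trial.

Covers the power/sample-size calculation for a two-group comparison, 1:1
permuted-block randomization, Welch's t-test computed from printed summary
statistics (mean ± SD, n), Fisher's exact test on r x c contingency tables
by exhaustive enumeration with the probability-ordering two-sided rule, and
scoring/summarization of the two patient questionnaires:

* the first questionnaire has 12 items rated 1-5 grouped into four
  categories (general knowledge, benefits of surgery, risks of surgery,
  satisfaction), three items each, so a category score lies in 3..15;
* the second has 4 items rated 1-5 plus a forced choice of the single most
  helpful item.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "WelchResult",
    "CATEGORIES",
    "sample_size_two_group",
    "block_randomize",
    "welch_t_from_summary",
    "fisher_exact",
    "score_questionnaire",
    "compare_arms",
    "summarize_second_questionnaire",
]

CATEGORIES = ("general_knowledge", "benefits", "risks", "satisfaction")

#: first-questionnaire layout: items 1-3 knowledge, 4-6 benefits,
#: 7-9 risks, 10-12 satisfaction
CATEGORY_ITEMS = {
    "general_knowledge": (0, 1, 2),
    "benefits": (3, 4, 5),
    "risks": (6, 7, 8),
    "satisfaction": (9, 10, 11),
}

SECOND_QUESTIONNAIRE_ITEMS = (
    "understanding the disease",
    "understanding the operation",
    "understanding the complications",
    "overall satisfaction",
)


@dataclass(frozen=True)
class SummaryStats:
    """Printed per-group summary: mean ± SD of n observations."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def _two_sample_t_power(n_per_group: int, d: float, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    ncp = d * math.sqrt(n_per_group / 2.0)
    return float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_group(
    diff: float = 20.0,
    sd: float = 25.0,
    power: float = 0.80,
    alpha_two_sided: float = 0.05,
    dropout: float = 0.15,
) -> int:
    """Per-group sample size for a two-sample t-test, inflated for dropout.

    The effect size is ``d = diff / sd`` (an absolute between-group
    difference of 20% of the mean against an SD of 25% of the mean gives
    d = 0.8); ``n0`` is the smallest per-group n whose noncentral-t power
    reaches the target, and the returned allocation is
    ``ceil(n0 * (1 + dropout))`` (26 -> 29.9 -> 30 at the defaults).
    """
    if not 0 < power < 1 or not 0 < alpha_two_sided < 1 or not 0 <= dropout < 1:
        raise ValueError("power and alpha must be in (0,1); dropout in [0,1)")
    if sd <= 0 or diff / sd <= 0:
        raise ValueError("effect size d = diff/sd must be > 0")
    d = diff / sd
    n = 2
    while _two_sample_t_power(n, d, alpha_two_sided) < power:
        n += 1
        if n > 10**6:
            raise RuntimeError("sample size search did not converge")
    return math.ceil(n * (1 + dropout))


def block_randomize(
    n: int, block_size: int = 4, arms: int = 2, seed: int = 0
) -> list[int]:
    """1:1 (or 1:...:1) permuted-block allocation sequence of arm indices.

    Every complete consecutive block contains each arm exactly
    ``block_size / arms`` times, with the within-block order a uniform
    random permutation; a trailing partial block is the prefix of one more
    permuted block.  Deterministic under ``seed``.
    """
    if block_size % arms:
        raise ValueError(f"block size {block_size} not divisible by {arms} arms")
    rng = np.random.default_rng(seed)
    block = np.repeat(np.arange(arms), block_size // arms)
    out: list[int] = []
    while len(out) < n:
        out.extend(rng.permutation(block).tolist())
    return out[:n]


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> WelchResult:
    """Welch's two-sided t-test from per-group mean, SD and n.

    ``t = (ma - mb) / sqrt(sa^2/na + sb^2/nb)`` with Welch-Satterthwaite
    degrees of freedom.  Two degenerate identical groups (both SDs zero,
    equal means) return p = 1 by convention.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        if a.mean == b.mean:
            return WelchResult(0.0, float(a.n + b.n - 2), 1.0)
        return WelchResult(math.inf if a.mean > b.mean else -math.inf, float(a.n + b.n - 2), 0.0)
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


_DEFAULT_TABLE_CAP = 2_000_000


def fisher_exact(table: Sequence[Sequence[int]], table_cap: int = _DEFAULT_TABLE_CAP) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    Exhaustively enumerates all tables with the observed margins and sums
    the probabilities (multivariate hypergeometric under fixed margins) of
    every table whose probability does not exceed the observed table's,
    with relative tolerance 1e-7 — the probability-ordering convention used
    for published p-values.  Enumeration beyond ``table_cap`` candidate
    tables raises with advice to fall back to Monte Carlo.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of nonnegative counts")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    if n < 1:
        raise ValueError("table must contain at least one observation")
    # log-probability of a table under fixed margins:
    # log P = sum(log r_i!) + sum(log c_j!) - log n! - sum(log x_ij!)
    lgam = math.lgamma
    const = sum(lgam(r + 1) for r in row_sums) + sum(lgam(c + 1) for c in col_sums) - lgam(n + 1)

    def log_p(cells: np.ndarray) -> float:
        return const - sum(lgam(x + 1) for x in cells.flat)

    obs_lp = log_p(obs)
    thresh = obs_lp + 1e-7  # relative tolerance on the probability scale

    r, c = obs.shape
    total = 0.0
    count = 0

    # depth-first over rows; each row is an integer composition bounded by
    # the remaining column sums
    def rec_rows(i: int, cols_left: np.ndarray, acc: list[np.ndarray]):
        nonlocal total, count
        if i == r - 1:
            cells = np.vstack(acc + [cols_left])
            count += 1
            if count > table_cap:
                raise RuntimeError(
                    f"fisher_exact enumeration exceeded {table_cap} tables; "
                    "use a Monte Carlo approximation for tables this large"
                )
            lp = log_p(cells)
            if lp <= thresh:
                total += math.exp(lp)
            return
        for row in _compositions(int(row_sums[i]), cols_left):
            rec_rows(i + 1, cols_left - row, acc + [row])

    def _compositions(s: int, caps: np.ndarray):
        """All nonnegative integer vectors summing to s with per-cell caps."""
        k = len(caps)

        def rec(j: int, rem: int, cur: list[int]):
            if j == k - 1:
                if rem <= caps[j]:
                    yield np.array(cur + [rem], dtype=np.int64)
                return
            lo = max(0, rem - int(caps[j + 1 :].sum()))
            hi = min(int(caps[j]), rem)
            for v in range(lo, hi + 1):
                yield from rec(j + 1, rem - v, cur + [v])

        yield from rec(0, s, [])

    rec_rows(0, col_sums.copy(), [])
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------


def score_questionnaire(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-patient category scores for the first questionnaire.

    ``responses`` needs columns ``id``, ``arm`` and ``item1`` .. ``item12``
    (scores 1-5).  Each category score is the sum of its three items, so it
    lies in 3..15.  Missing or out-of-range items raise.
    """
    item_cols = [f"item{i}" for i in range(1, 13)]
    missing = [c for c in ("id", "arm", *item_cols) if c not in responses.columns]
    if missing:
        raise ValueError(f"responses missing columns: {missing}")
    items = responses[item_cols]
    if items.isna().any().any():
        raise ValueError("missing item scores")
    if ((items < 1) | (items > 5)).any().any():
        raise ValueError("item scores must be in 1..5")
    out = responses[["id", "arm"]].copy()
    for cat, idxs in CATEGORY_ITEMS.items():
        out[cat] = items.iloc[:, list(idxs)].sum(axis=1)
    return out


def compare_arms(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-category arm comparison (Welch's t from the arm summaries).

    ``scored`` is the output of :func:`score_questionnaire`; both arms must
    be present.  Returns one row per category with per-arm mean ± SD and
    the Welch t, df and two-sided p.
    """
    arms = sorted(scored["arm"].unique())
    if len(arms) != 2:
        raise ValueError(f"need exactly 2 arms; got {arms}")
    rows = []
    for cat in CATEGORIES:
        summaries = []
        for arm in arms:
            vals = scored.loc[scored["arm"] == arm, cat].to_numpy(dtype=float)
            summaries.append(
                SummaryStats(float(vals.mean()), float(vals.std(ddof=1)), len(vals))
            )
        res = welch_t_from_summary(summaries[0], summaries[1])
        rows.append(
            {
                "category": cat,
                f"mean_{arms[0]}": summaries[0].mean,
                f"sd_{arms[0]}": summaries[0].sd,
                f"mean_{arms[1]}": summaries[1].mean,
                f"sd_{arms[1]}": summaries[1].sd,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def summarize_second_questionnaire(responses: pd.DataFrame) -> dict:
    """Item means ± SD and forced-choice percentages for the follow-up form.

    ``responses`` needs ``item1`` .. ``item4`` (ratings 1-5) and ``choice``
    (1-based index of the most helpful item).  Percentages are
    ``100 * count / total`` rounded to 1 decimal place.
    """
    if len(responses) == 0:
        raise ValueError("empty response set")
    item_cols = [f"item{i}" for i in range(1, 5)]
    missing = [c for c in (*item_cols, "choice") if c not in responses.columns]
    if missing:
        raise ValueError(f"responses missing columns: {missing}")
    items = responses[item_cols]
    if ((items < 1) | (items > 5)).any().any():
        raise ValueError("item ratings must be in 1..5")
    choice = responses["choice"].astype(int)
    if ((choice < 1) | (choice > 4)).any():
        raise ValueError("forced choice must reference items 1..4")
    total = len(responses)
    pct = {
        SECOND_QUESTIONNAIRE_ITEMS[k - 1]: round(100.0 * int((choice == k).sum()) / total, 1)
        for k in range(1, 5)
    }
    means = {
        SECOND_QUESTIONNAIRE_ITEMS[i]: {
            "mean": float(items.iloc[:, i].mean()),
            "sd": float(items.iloc[:, i].std(ddof=1)) if total > 1 else 0.0,
        }
        for i in range(4)
    }
    return {"n": total, "item_ratings": means, "forced_choice_pct": pct}


def compare_second_items(responses: pd.DataFrame, item_a: int, item_b: int) -> WelchResult:
    """Paired two-sided t-test between two follow-up items across patients.

    Ratings of items ``item_a`` and ``item_b`` (1-based) are compared
    within patients; returns t, df = n-1 and the two-sided p.  Identical
    columns give p = 1 by convention.
    """
    cols = [f"item{item_a}", f"item{item_b}"]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise ValueError(f"responses missing columns: {missing}")
    diff = (responses[cols[0]] - responses[cols[1]]).to_numpy(dtype=float)
    n = len(diff)
    if n < 2:
        raise ValueError("paired comparison needs >= 2 patients")
    sd = diff.std(ddof=1)
    if sd == 0:
        return WelchResult(0.0 if diff.mean() == 0 else math.copysign(math.inf, diff.mean()),
                           float(n - 1), 1.0 if diff.mean() == 0 else 0.0)
    t = diff.mean() / (sd / math.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return WelchResult(float(t), float(n - 1), p)


def second_questionnaire_from_counts(counts: Sequence[int]) -> dict:
    """Forced-choice percentages straight from per-item counts.

    Convenience for published tallies (e.g. 38/9/6/0 of 53 -> 71.7 / 17.0 /
    11.3 / 0.0); same rounding as :func:`summarize_second_questionnaire`.
    """
    counts = [int(c) for c in counts]
    if len(counts) != 4 or min(counts) < 0 or sum(counts) == 0:
        raise ValueError("need 4 nonnegative counts with a positive total")
    total = sum(counts)
    return {
        SECOND_QUESTIONNAIRE_ITEMS[i]: round(100.0 * counts[i] / total, 1) for i in range(4)
    }
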