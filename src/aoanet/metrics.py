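"""Item scoring, group summaries, the AoA gap, and the covariance analysis.

Per-item "error" is the summed squared error of the network's output against
the item's binary phonological target; decoded whole-word correctness (the
readout pronunciation equals the target exactly) is kept alongside as an
alternative 0/1 metric.

The covariance analysis mirrors the item-analysis design used on reading
errors: an OLS fit of error on intercept + frequency + consistency + grade
dummies, with sequential (Type-I) sums of squares in the order frequency,
consistency, grade, each F-tested against the residual mean square.  A
1-df linear-trend contrast over the grade factor (entered after the
covariates) is reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import codec
from .lexicon import Lexicon
from .network import NetworkState, forward_batch


def evaluate(net: NetworkState, lexicon: Lexicon) -> pd.DataFrame:
    """Clean forward pass over the whole lexicon.

    Returns one row per item with columns word_id, grade, frequency,
    consistency, sse, correct.  Deterministic given net and lexicon.
    """
    X, T = codec.encode_lexicon(lexicon)
    if X.shape[1] != net.n_in or T.shape[1] != net.n_out:
        raise ValueError(
            f"lexicon encoding ({X.shape[1]}->{T.shape[1]}) does not match "
            f"network ({net.n_in}->{net.n_out})"
        )
    _, O = forward_batch(net, X)
    sse = ((O - T) ** 2).sum(axis=1)
    decoded = codec.decode_phonology_batch(O, lexicon.n_phonemes)
    targets = np.array([it.pronunciation for it in lexicon])
    correct = (decoded == targets).all(axis=1)
    return pd.DataFrame(
        {
            "word_id": lexicon.word_ids,
            "grade": [it.grade for it in lexicon],
            "frequency": [it.frequency for it in lexicon],
            "consistency": [it.consistency for it in lexicon],
            "sse": sse,
            "correct": correct,
        }
    )


def aoa_gap(
    results: pd.DataFrame,
    early_ids: Iterable[str],
    late_ids: Iterable[str],
    error_col: str = "sse",
) -> float:
    """mean(error | late) - mean(error | early); positive = AoA advantage."""
    early_ids, late_ids = set(early_ids), set(late_ids)
    if not early_ids or not late_ids:
        raise ValueError("both groups must be nonempty")
    if early_ids & late_ids:
        raise ValueError("early and late groups must be disjoint")
    by_id = results.set_index("word_id")[error_col]
    early = by_id.loc[list(early_ids)]
    late = by_id.loc[list(late_ids)]
    return float(late.mean() - early.mean())


def group_summary(results: pd.DataFrame, error_col: str = "sse") -> pd.DataFrame:
    """Per-grade N, mean and sample SD (n-1 denominator) plus a Total row."""
    if len(results) == 0:
        raise ValueError("empty results")
    rows = []
    for grade, sub in results.groupby("grade"):
        vals = sub[error_col].to_numpy(dtype=float)
        rows.append(
            {
                "group": f"grade{grade}",
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    vals = results[error_col].to_numpy(dtype=float)
    rows.append(
        {
            "group": "total",
            "n": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd"])


@dataclass
class AnovaTable:
    """Sequential ANCOVA table plus the linear-trend contrast for the factor."""

    table: pd.DataFrame  # rows: covariates, factor, Error; columns: SS, df, MS, F, p
    trend_F: float
    trend_p: float
    grade_means: pd.Series

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.table.to_string()


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def ancova(
    records: pd.DataFrame,
    error_col: str = "error",
    covariates: Sequence[str] = ("frequency", "consistency"),
    factor: str = "grade",
) -> AnovaTable:
    """Analysis of covariance with sequential (Type-I) sums of squares.

    Terms enter in the order: covariates (as given), then the factor as
    dummy variables.  Each term's F is its mean square over the residual
    mean square of the full model.  With 327 items, 2 covariates and a
    5-level factor this yields factor df 4 and error df 320.
    """
    df = records
    n = len(df)
    y = df[error_col].to_numpy(dtype=float)
    levels = np.sort(df[factor].unique())
    g = len(levels)
    c = len(covariates)
    if g < 2:
        raise ValueError("factor needs at least 2 levels")
    if n <= g + c + 1:
        raise ValueError("too few records for the requested design")

    # nested design matrices: intercept, +covariate..., +factor dummies
    blocks: List[np.ndarray] = [np.ones((n, 1))]
    names: List[str] = []
    for cov in covariates:
        blocks.append(df[cov].to_numpy(dtype=float).reshape(-1, 1))
        names.append(cov.capitalize())
    dummies = np.stack([(df[factor].to_numpy() == lv).astype(float) for lv in levels[1:]], axis=1)
    blocks.append(dummies)
    names.append("AoA")
    term_df = [1] * c + [g - 1]

    X_full = np.hstack(blocks)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates or empty level)")

    rss_seq = []
    X = blocks[0]
    rss_seq.append(_rss(y, X))
    for b in blocks[1:]:
        X = np.hstack([X, b])
        rss_seq.append(_rss(y, X))

    err_df = n - X_full.shape[1]
    err_ss = rss_seq[-1]
    err_ms = err_ss / err_df

    rows = []
    for i, (name, d) in enumerate(zip(names, term_df)):
        ss = rss_seq[i] - rss_seq[i + 1]
        ms = ss / d
        F = ms / err_ms
        p = float(stats.f.sf(F, d, err_df))
        rows.append({"source": name, "SS": ss, "df": d, "MS": ms, "F": F, "p": p})
    rows.append(
        {"source": "Error", "SS": err_ss, "df": err_df, "MS": err_ms, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows, columns=["source", "SS", "df", "MS", "F", "p"])

    # linear-trend contrast: numeric factor codes entered after the covariates
    codes = df[factor].to_numpy(dtype=float)
    X_cov = np.hstack(blocks[: c + 1])
    X_trend = np.hstack([X_cov, (codes - codes.mean()).reshape(-1, 1)])
    ss_trend = _rss(y, X_cov) - _rss(y, X_trend)
    trend_F = (ss_trend / 1.0) / err_ms
    trend_p = float(stats.f.sf(trend_F, 1, err_df))

    grade_means = df.groupby(factor)[error_col].mean()
    return AnovaTable(table=table, trend_F=float(trend_F), trend_p=trend_p, grade_means=grade_means)


# --------------------------------------------------------------------------
# sigmoid-saturation diagnostics


def saturation_profile(net: NetworkState, X: np.ndarray) -> dict:
    """Mean |net input| and mean logistic slope o(1-o) of the output units.

    As training drives output net inputs away from 0 toward the sigmoid's
    tails, the slope — and with it the network's plasticity — shrinks.
    """
    X = np.asarray(X, dtype=float)
    H, O = forward_batch(net, X)
    net_in = H @ net.W_ho.T + net.b_o
    return {
        "mean_abs_net_input": float(np.mean(np.abs(net_in))),
        "mean_slope": float(np.mean(O * (1.0 - O))),
    }
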