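"""Regression-table construction: RT transform, trial filters, predictors.

Reaction times are strongly right-skewed; they are modelled on the negative
reciprocal scale ``RTinv = -1000/RT`` (a negative response rate, so that
larger values still mean slower responses).  Trials outside (100, 2000] ms,
time-outs, and the literal stimulus strings 'null'/'nan' are excluded.

Right-skewed predictors are natural-log transformed, with 0.002 added first
whenever the column contains zeros.  Predictors with a genuine spike at zero
(frequency, neighbourhood size, semantic relatedness) get the indicator
expansion ``b + b*log(p)``: a 0/1 indicator for nonzero, and the log value
gated by that indicator, so the zero rows carry no undefined values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forms import levenshtein_neighbourhood_size

LOG_BACKOFF = 0.002
RT_MIN_MS = 100.0
RT_MAX_MS = 2000.0


def rt_transform(rt):
    """``RTinv = -1000/RT`` (ms); strictly increasing in RT and negative."""
    rt = np.asarray(rt, dtype=np.float64)
    if np.any(rt <= 0):
        raise ValueError("reaction times must be positive")
    out = -1000.0 / rt
    return float(out) if out.ndim == 0 else out


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop trials per the exclusion rules; report counts per rule.

    Rules, applied in order: stimulus literally 'null' or 'nan'; time-out
    responses (a truthy ``timeout`` column, if present); RT <= 100 ms or
    RT > 2000 ms.  Idempotent.
    """
    report = {"bad_stimulus": 0, "timeout": 0, "rt_low": 0, "rt_high": 0}
    if len(table) == 0:
        return table.copy(), report
    keep = pd.Series(True, index=table.index)

    bad = table["stimulus"].astype(str).str.lower().isin(["null", "nan"])
    report["bad_stimulus"] = int(bad.sum())
    keep &= ~bad

    if "timeout" in table.columns:
        to = table["timeout"].astype(bool) & keep
        report["timeout"] = int(to.sum())
        keep &= ~to

    rt = table["rt"].astype(float)
    low = (rt <= RT_MIN_MS) & keep
    report["rt_low"] = int(low.sum())
    keep &= ~low
    high = (rt > RT_MAX_MS) & keep
    report["rt_high"] = int(high.sum())
    keep &= ~high
    return table.loc[keep].copy(), report


def log_with_backoff(x) -> np.ndarray:
    """Natural log, adding 0.002 first if (and only if) the column has zeros."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("log transform requires nonnegative values")
    if np.any(x == 0):
        return np.log(x + LOG_BACKOFF)
    return np.log(x)


def zero_indicator_expand(p) -> tuple[np.ndarray, np.ndarray]:
    """Indicator + gated-log expansion for a zero-spiked nonnegative column.

    Returns ``(b, b_x_logp)`` where ``b`` is 1 for nonzero entries and the
    second column is ``b * log(p)`` with the (irrelevant) log of zero entries
    set to 0, so the model matrix never contains undefined values.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("expansion requires nonnegative values")
    b = (p != 0).astype(np.float64)
    logp = np.zeros_like(p)
    nz = p != 0
    logp[nz] = np.log(p[nz])
    return b, b * logp


def scale_trial_number(t) -> np.ndarray:
    """Centre and scale to unit variance (population sd convention)."""
    t = np.asarray(t, dtype=np.float64)
    sd = t.std()
    if sd == 0:
        raise ValueError("constant trial-number column cannot be scaled")
    return (t - t.mean()) / sd


def build_regression_table(
    measure_table: pd.DataFrame,
    frequencies: dict[str, float] | None = None,
    reference_lexicon: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-trial regression table from a measure table.

    Adds: ``rt_inv``; per-subject scaled trial number; word length; the
    frequency predictors ``in_bnc`` + ``in_bnc_x_log_frequency`` (presence in
    the supplied frequency list with nonzero count); the neighbourhood
    predictors ``has_neighbours`` + ``has_neighbours_x_log_nsize`` against the
    reference lexicon; log-transformed model measures with the
    ``has_neighbours_path`` expansion for semantic relatedness.  Trials are
    filtered first; the exclusion report is attached as ``.attrs['exclusions']``.
    """
    table, report = filter_trials(measure_table)
    table = table.copy()
    table["rt_inv"] = rt_transform(table["rt"].to_numpy())
    table["trial_scaled"] = (
        table.groupby("subject")["trial"].transform(lambda t: scale_trial_number(t.to_numpy()))
    )
    table["word_length"] = table["stimulus"].astype(str).str.len().astype(float)
    table["response_word"] = (table["response"] == "word").astype(float)
    table["response_nonword"] = 1.0 - table["response_word"]

    freq = np.array(
        [float((frequencies or {}).get(s, 0.0)) for s in table["stimulus"]], dtype=np.float64
    )
    b, bx = zero_indicator_expand(freq)
    table["in_bnc"] = b
    table["in_bnc_x_log_frequency"] = bx

    if reference_lexicon is not None:
        lex = set(reference_lexicon)
        nsize_by_stim = {
            s: float(levenshtein_neighbourhood_size(s, lex))
            for s in table["stimulus"].unique()
        }
        nsize = np.array([nsize_by_stim[s] for s in table["stimulus"]])
    else:
        nsize = np.zeros(len(table))
    b, bx = zero_indicator_expand(nsize)
    table["has_neighbours"] = b
    table["has_neighbours_x_log_nsize"] = bx

    table["log_semantic_density"] = log_with_backoff(
        np.clip(table["semantic_density"].to_numpy(), 0.0, None)
    )
    table["log_cue_activation_diversity"] = log_with_backoff(
        table["cue_activation_diversity"].to_numpy()
    )
    b, bx = zero_indicator_expand(table["fsr"].to_numpy())
    table["has_neighbours_path"] = b
    table["has_path_x_log_fsr"] = bx
    table.attrs["exclusions"] = report
    return table
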