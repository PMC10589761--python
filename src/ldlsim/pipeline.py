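"""End-to-end analysis: simulate, build regression tables, fit, compare.

This module glues the stages into the reproducible pipeline used by the CLI
and by the learning-detection study: simulate each subject's experiment in
dynamic and static mode, generate (or take) reaction times, estimate the
AR(1) coefficient per subject and response subset from a classical
no-autocorrelation model, fit the model families on prewhitened data, and
compare them by AIC across subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import Lexicon, TrialSimulator, run_experiment
from .gam import (
    AdditiveModel,
    FitSummary,
    ModelComparison,
    compare_models,
    estimate_rho,
    fit_additive_model,
    nonword_model_spec,
    tally_across_subjects,
    word_model_spec,
)
from .prep import build_regression_table
from .synth import SynthConfig, gen_rts, make_experiment


def gen_frequencies(
    words: list[str], seed: int = 0, present_fraction: float = 0.9
) -> dict[str, float]:
    """Zipf-like synthetic corpus frequencies; a fraction of words is absent.

    Emulates a corpus frequency list: counts fall off as 1/rank, and some
    words are missing (count 0), so the 'present in corpus' indicator varies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    ranks = rng.permutation(len(words)) + 1
    present = rng.random(len(words)) < present_fraction
    return {
        w: float(np.round(1e5 / r)) if p else 0.0
        for w, r, p in zip(words, ranks, present)
    }


def simulate_both_modes(
    words: list[str],
    S: np.ndarray,
    trials: pd.DataFrame,
    stimuli: list[str] | None = None,
    eta_fg: float | None = None,
    eta_d: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Measure tables from one shared prior, with and without learning."""
    kw = {}
    if eta_fg is not None:
        kw["eta_fg"] = eta_fg
    if eta_d is not None:
        kw["eta_d"] = eta_d
    sim = TrialSimulator(mode="dynamic", **kw).fit(words, S, stimuli=stimuli)
    dynamic = sim.transform(trials)
    static = run_experiment(trials, sim.prior_, "static", sim.lexicon_)
    return {"dynamic": dynamic, "static": static}


def subject_rho(
    table: pd.DataFrame, spec, session_col: str = "session"
) -> float:
    """AR(1) coefficient from the residuals of a no-autocorrelation fit."""
    model = AdditiveModel(spec=spec, rho=0.0, session_col=session_col).fit(table)
    return estimate_rho(model.residuals_, model.sessions_)


def fit_families_for_subject(
    subject,
    subset: str,
    tables: dict[str, pd.DataFrame],
) -> dict[str, FitSummary]:
    """Classical, static and dynamic fits for one subject and response subset.

    ``tables`` maps simulation mode ('static'/'dynamic') to that subject's
    regression table restricted to the subset (word or nonword trials).
    The classical family is fitted on the static table (its predictors do
    not involve model measures, so the choice is immaterial); rho comes from
    the classical no-AR fit and is shared by all families.
    """
    spec_of = word_model_spec if subset == "word" else nonword_model_spec
    # restrict both modes to their common complete cases so AICs compare
    # identical rows (undefined measures can differ between modes)
    cols = {
        mode: [
            c
            for c in set(spec_of("classical").columns())
            | set(spec_of("dynamic_dlm" if mode == "dynamic" else "static_dlm").columns())
            if c in tables[mode].columns
        ]
        for mode in tables
    }
    keep = np.logical_and.reduce(
        [tables[mode][cols[mode]].notna().all(axis=1).to_numpy() for mode in ("static", "dynamic")]
    )
    tables = {mode: t.loc[t.index[keep]] for mode, t in tables.items()}
    rho = subject_rho(tables["static"], spec_of("classical"))
    out: dict[str, FitSummary] = {}
    for family, mode in [
        ("classical", "static"),
        ("static_dlm", "static"),
        ("dynamic_dlm", "dynamic"),
    ]:
        summ = fit_additive_model(spec_of(family), tables[mode], rho=rho)
        summ.subject = subject
        summ.response_subset = subset
        out[family] = summ
    return out


def run_learning_detection(
    cfg: SynthConfig, alpha: float = 0.001
) -> dict:
    """Full scaled-down learning-detection study on synthetic data.

    Generates one experiment under ``cfg`` (whose ``learning`` flag fixes
    whether RTs are driven by dynamic or static measures), simulates every
    subject in both modes, fits classical/static/dynamic families per
    subject for word and nonword trials, and tallies dynamic-vs-static AIC
    comparisons.
    """
    exp = make_experiment(cfg)
    words, nonwords, S, trials = exp["words"], exp["nonwords"], exp["S"], exp["trials"]
    stimuli = words + nonwords
    measures = simulate_both_modes(words, S, trials, stimuli=stimuli)
    with_rt = gen_rts(trials, measures[cfg.learning], cfg)
    freqs = gen_frequencies(words, seed=cfg.seed)
    reg: dict[str, pd.DataFrame] = {}
    for mode in ("static", "dynamic"):
        m = measures[mode].copy()
        m["rt"] = with_rt["rt"].to_numpy()
        reg[mode] = build_regression_table(m, frequencies=freqs, reference_lexicon=set(words))

    fits: list[FitSummary] = []
    comparisons: dict[str, list[ModelComparison]] = {"word": [], "nonword": []}
    for subject in sorted(reg["static"]["subject"].unique()):
        for subset in ("word", "nonword"):
            tables = {
                mode: reg[mode][
                    (reg[mode]["subject"] == subject) & (reg[mode]["lexicality"] == subset)
                ]
                for mode in ("static", "dynamic")
            }
            fam = fit_families_for_subject(subject, subset, tables)
            fits.extend(fam.values())
            comparisons[subset].append(compare_models(fam["static_dlm"], fam["dynamic_dlm"]))

    tallies = {
        subset: tally_across_subjects(
            comparisons[subset],
            [f for f in fits if f.response_subset == subset and f.label == "dynamic_dlm"],
            alpha=alpha,
        )
        for subset in ("word", "nonword")
    }
    # subject-level verdict: AICs of a subject's word and nonword fits add,
    # so a subject counts as a dynamic win when the summed AIC favours the
    # dynamic family across both response subsets
    per_subject: dict = {}
    for subset in ("word", "nonword"):
        for c in comparisons[subset]:
            per_subject[c.subject] = per_subject.get(c.subject, 0.0) + c.delta_aic
    deltas = np.array(list(per_subject.values()))
    tallies["combined"] = {
        "pct_b_better": float(100.0 * np.mean(deltas > 0)),
        "mean_delta_aic": float(deltas.mean()),
        "per_subject_delta_aic": {int(k): float(v) for k, v in per_subject.items()},
    }
    return {
        "config": cfg,
        "measures": measures,
        "trials": with_rt,
        "fits": fits,
        "comparisons": comparisons,
        "tallies": tallies,
    }
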