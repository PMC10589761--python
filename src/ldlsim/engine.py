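"""Trial-by-trial simulation of a lexical decision experiment.

Each trial unfolds in a fixed order: (A) the stimulus is encoded as a
trigram cue vector ``c``; (B) comprehension predicts ``s_hat = c @ F``;
(C) the lexicality network predicts ``d = c @ D``; (D) the production
feedback loop regenerates ``c_hat = s_hat @ G``; (E) the processing measures
are computed from these *pre-update* vectors.  Only then, in dynamic mode,
are F, G and D updated with the Widrow-Hoff rule, and the evolving nonword
vector updated if the response was "nonword".

The target semantic vector for updating F and G depends on stimulus
lexicality and the participant's response:

==========  ==============  =========================
lexicality  response=word   response=nonword
==========  ==============  =========================
word        word's vector   nonword vector ``n``
nonword     word centroid   nonword vector ``n``
==========  ==============  =========================

The nonword vector obeys the recurrence ``n <- (n + s_hat)/2`` applied at
the end of every nonword-response trial, so at the next nonword-response
trial the target is 50% the most recent nonword prediction, 25% the one
before, and so on.

Static mode runs the same steps A-E but never mutates the mappings, so each
stimulus always yields the same measures (and yes-activation is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import measures as M
from .embeddings import word_centroid
from .forms import TrigramIndex, build_cue_matrix, build_trigram_index, coltheart_neighbours
from .mappings import (
    DEFAULT_ETA_D,
    DEFAULT_ETA_FG,
    MappingState,
    estimate_endstate,
    init_state,
)

TRIAL_COLUMNS = ["subject", "trial", "block", "session", "stimulus", "lexicality", "response", "rt"]

MEASURE_COLUMNS = [
    "semantic_density",
    "fsr",
    "has_neighbours_path",
    "c_precision",
    "cue_activation_diversity",
    "yes_activation",
]


@dataclass
class Lexicon:
    """Static experiment-wide context shared by every simulated subject.

    ``words`` are the items with embeddings (rows of ``S``); the cue index
    covers *all* stimuli (words and nonwords) so every trial can be encoded.
    """

    words: list[str]
    S: np.ndarray
    index: TrigramIndex
    C_words: np.ndarray
    centroid: np.ndarray
    cue_vectors: dict[str, np.ndarray]
    neighbour_rows: dict[str, np.ndarray]

    @classmethod
    def build(
        cls, words: list[str], S: np.ndarray, stimuli: list[str] | None = None
    ) -> "Lexicon":
        """Build cue coding and neighbour structure for an experiment.

        ``stimuli`` lists every string that can occur in a trial (defaults to
        the word list); Coltheart neighbours are looked up in the word list.
        """
        S = np.asarray(S, dtype=np.float64)
        if len(words) != S.shape[0]:
            raise ValueError("word list and semantic matrix must be row-aligned")
        stimuli = list(dict.fromkeys((stimuli if stimuli is not None else list(words))))
        index = build_trigram_index(list(words) + stimuli)
        C_words, _ = build_cue_matrix(words, index)
        C_stim, _ = build_cue_matrix(stimuli, index)
        cue_vectors = {s: C_stim[i] for i, s in enumerate(stimuli)}
        for i, w in enumerate(words):
            cue_vectors.setdefault(w, C_words[i])
        word_pos = {w: i for i, w in enumerate(words)}
        neighbour_rows = {
            s: np.array(sorted(word_pos[n] for n in coltheart_neighbours(s, word_pos)), dtype=np.intp)
            for s in cue_vectors
        }
        return cls(
            words=list(words),
            S=S,
            index=index,
            C_words=C_words,
            centroid=word_centroid(S),
            cue_vectors=cue_vectors,
            neighbour_rows=neighbour_rows,
        )

    def prior_state(self, eta_fg: float = DEFAULT_ETA_FG, eta_d: float = DEFAULT_ETA_D) -> MappingState:
        """Endstate F and G over the word lexicon; D and n start at zero."""
        return init_state(self.C_words, self.S, eta_fg=eta_fg, eta_d=eta_d)

    def word_row(self, word: str) -> int:
        try:
            return self.words.index(word)
        except ValueError:
            raise KeyError(f"no embedding row for stimulus {word!r}") from None


def select_target_semantics(
    lexicality: str,
    response: str,
    s_word: np.ndarray | None,
    centroid: np.ndarray,
    n: np.ndarray,
) -> np.ndarray:
    """Target semantic vector for the F/G updates after a trial."""
    if response == "nonword":
        return n
    if response != "word":
        raise ValueError(f"response must be 'word' or 'nonword', got {response!r}")
    if lexicality == "word":
        if s_word is None:
            raise ValueError("word stimulus requires its semantic vector")
        return s_word
    if lexicality == "nonword":
        return centroid
    raise ValueError(f"lexicality must be 'word' or 'nonword', got {lexicality!r}")


def update_nonword_vector(n: np.ndarray, s_hat_current: np.ndarray) -> np.ndarray:
    """Recency-weighted nonword semantic target: ``(n + s_hat)/2``."""
    return 0.5 * (np.asarray(n, dtype=np.float64) + np.asarray(s_hat_current, dtype=np.float64))


def _measures_for(
    c: np.ndarray,
    s_hat: np.ndarray,
    c_hat: np.ndarray,
    d: float,
    lexicon: Lexicon,
    F: np.ndarray,
    stimulus: str,
    dynamic: bool,
    density_top: int,
    tour_budget: int,
    closed_tour: bool,
) -> dict[str, float]:
    try:
        dens = M.semantic_density(s_hat, lexicon.S, n_top=min(density_top, lexicon.S.shape[0]))
    except M.UndefinedMeasureError:
        dens = np.nan
    rows = lexicon.neighbour_rows.get(stimulus)
    if rows is None:
        rows = np.array(
            sorted(lexicon.words.index(n) for n in coltheart_neighbours(stimulus, lexicon.words)),
            dtype=np.intp,
        )
    s_hat_nb = lexicon.C_words[rows] @ F if len(rows) else None
    fsr, has_path = M.form_driven_semantic_relatedness(
        s_hat, s_hat_nb, closed=closed_tour, exact_budget=tour_budget
    )
    try:
        cprec = M.c_precision(c, c_hat)
    except M.UndefinedMeasureError:
        cprec = np.nan
    return {
        "semantic_density": dens,
        "fsr": fsr,
        "has_neighbours_path": has_path,
        "c_precision": cprec,
        "cue_activation_diversity": M.cue_activation_diversity(c_hat),
        "yes_activation": d if dynamic else np.nan,
    }


def run_trial(
    state: MappingState,
    trial: pd.Series | dict,
    mode: str,
    lexicon: Lexicon,
    density_top: int = M.DEFAULT_DENSITY_TOP,
    tour_budget: int = M.DEFAULT_TOUR_BUDGET,
    closed_tour: bool = True,
) -> tuple[dict[str, float], MappingState]:
    """Simulate one trial; returns the measure row and the next state.

    In static mode the returned state *is* the input state, untouched.
    """
    if mode not in ("dynamic", "static"):
        raise ValueError(f"mode must be 'dynamic' or 'static', got {mode!r}")
    stimulus = trial["stimulus"]
    lexicality = trial["lexicality"]
    response = trial["response"]
    c = lexicon.cue_vectors.get(stimulus)
    if c is None:
        from .forms import encode_cue_vector

        c = encode_cue_vector(stimulus, lexicon.index)
    s_hat = c @ state.F
    d = float(c @ state.D)
    c_hat = s_hat @ state.G
    row = _measures_for(
        c, s_hat, c_hat, d, lexicon, state.F, stimulus,
        dynamic=(mode == "dynamic"), density_top=density_top,
        tour_budget=tour_budget, closed_tour=closed_tour,
    )
    if mode == "static":
        return row, state

    s_word = lexicon.S[lexicon.word_row(stimulus)] if lexicality == "word" else None
    target = select_target_semantics(lexicality, response, s_word, lexicon.centroid, state.n)
    new = state.copy()
    # parallel Widrow-Hoff updates, all from pre-update predictions
    new.F += np.outer(c, (target - s_hat)) * state.eta_fg
    new.G += np.outer(target, (c - target @ state.G)) * state.eta_fg
    r = 1 if response == "word" else 0
    new.D += c * ((r - d) * state.eta_d)
    if response == "nonword":
        new.n = update_nonword_vector(state.n, s_hat)
    return row, new


def _validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns and c != "rt"]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for _, grp in trials.groupby("subject", sort=False):
        t = grp["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("trial indices must be strictly increasing within subject")


def run_experiment(
    trials: pd.DataFrame,
    prior: MappingState,
    mode: str,
    lexicon: Lexicon,
    density_top: int = M.DEFAULT_DENSITY_TOP,
    tour_budget: int = M.DEFAULT_TOUR_BUDGET,
    closed_tour: bool = True,
) -> pd.DataFrame:
    """Fold :func:`run_trial` over an ordered trial table.

    Each subject restarts from a copy of the same prior state, so subjects
    are simulated in isolation.  Returns the trial table with the measure
    columns appended.
    """
    _validate_trials(trials)
    out = []
    for _, grp in trials.groupby("subject", sort=False):
        state = prior.copy()
        static_cache: dict[str, dict[str, float]] = {}
        for trial in grp.to_dict("records"):
            if mode == "static" and trial["stimulus"] in static_cache:
                row = dict(static_cache[trial["stimulus"]])
            else:
                row, state = run_trial(
                    state, trial, mode, lexicon,
                    density_top=density_top, tour_budget=tour_budget, closed_tour=closed_tour,
                )
                if mode == "static":
                    static_cache[trial["stimulus"]] = row
            out.append(row)
    res = trials.reset_index(drop=True).copy()
    for col in MEASURE_COLUMNS:
        res[col] = [r[col] for r in out]
    return res


class TrialSimulator(BaseEstimator, TransformerMixin):
    """Simulate lexical decision experiments from a fitted lexicon.

    scikit-learn style transformer: :meth:`fit` takes the word list and its
    semantic matrix (plus, optionally, the full stimulus list so nonwords
    can be encoded) and estimates the prior endstate mappings;
    :meth:`transform` turns a trial table into a per-trial measure table.

    Parameters
    ----------
    mode : {'dynamic', 'static'}
        Whether mappings are updated after each trial.
    eta_fg, eta_d : float
        Widrow-Hoff learning rates for F/G and for D.
    density_top : int
        Number of nearest semantic neighbours entering semantic density.
    tour_budget : int
        Maximum instance size solved exactly by the tour search.
    closed_tour : bool
        Closed-cycle (default) vs open-path semantic relatedness.
    """

    def __init__(
        self,
        mode: str = "dynamic",
        eta_fg: float = DEFAULT_ETA_FG,
        eta_d: float = DEFAULT_ETA_D,
        density_top: int = M.DEFAULT_DENSITY_TOP,
        tour_budget: int = M.DEFAULT_TOUR_BUDGET,
        closed_tour: bool = True,
    ):
        self.mode = mode
        self.eta_fg = eta_fg
        self.eta_d = eta_d
        self.density_top = density_top
        self.tour_budget = tour_budget
        self.closed_tour = closed_tour

    def fit(self, words, S, stimuli=None):
        """Estimate endstate mappings for the word lexicon.

        Parameters
        ----------
        words : sequence of str
            Words with embeddings, row-aligned with ``S``.
        S : array (n_words, d)
            Semantic matrix.
        stimuli : sequence of str, optional
            All strings that may occur as stimuli (defaults to ``words``);
            the trigram index is built over their union.
        """
        if self.mode not in ("dynamic", "static"):
            raise ValueError(f"mode must be 'dynamic' or 'static', got {self.mode!r}")
        self.lexicon_ = Lexicon.build(list(words), np.asarray(S, dtype=np.float64), stimuli)
        self.prior_ = self.lexicon_.prior_state(eta_fg=self.eta_fg, eta_d=self.eta_d)
        return self

    def transform(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Per-trial measure table for an ordered trial table."""
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("TrialSimulator must be fitted before transform")
        return run_experiment(
            trials, self.prior_, self.mode, self.lexicon_,
            density_top=self.density_top, tour_budget=self.tour_budget,
            closed_tour=self.closed_tour,
        )
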