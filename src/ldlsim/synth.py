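"""Synthetic lexical decision experiments with known generative structure.

The generator emulates the structure of a megastudy-style lexical decision
experiment at toy scale: a small artificial lexicon of letter strings,
length-matched nonwords built by 1-2 letter substitutions, cluster-
structured Gaussian embeddings (so semantic density varies across words),
interleaved word/nonword trial sequences split into blocks and sessions,
binary responses with a configurable error rate, and reaction times built
*additively from the model's own processing measures* plus session-
restarted AR(1) noise.  Because the generative recipe is the mirror image
of the regression models, the presence or absence of trial-to-trial
learning in the generated RTs is a known ground truth that the analysis
pipeline should recover.

The whole experiment is a pure function of :class:`SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .prep import LOG_BACKOFF, scale_trial_number

#: default additive recipe on the rt_inv scale, the generative mirror of the
#: per-subset regression models: c-precision contributes on word trials only
#: and semantic relatedness on nonword trials only, matching which measures
#: the respective models carry.  Signs and *relative* magnitudes follow the
#: empirical effect hierarchy (yes-activation strongest, c-precision
#: weakest); the common scale is set so the measure-driven component
#: explains a realistic share (~15-20%) of rt_inv variance at the toy
#: lexicon's measure ranges
DEFAULT_COEFFICIENTS = {
    "intercept": -2.0,
    "trial_scaled": -0.05,
    "word_length": 0.12,
    "log_semantic_density": -0.21,
    "log_cue_activation_diversity": 0.17,
    "c_precision": 0.25,  # word trials only
    "log_fsr": 0.09,  # nonword trials only
    "yes_activation": -0.70,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic experiment."""

    n_words: int = 200
    min_len: int = 3
    max_len: int = 6
    alphabet: str = "abcdefghijkl"
    dim: int = 20
    n_clusters: int = 8
    n_subjects: int = 20
    trials_per_subject: int = 2000
    block_size: int = 500
    n_sessions: int = 4
    error_rate: float = 0.05
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    rho: float = 0.3
    noise_sd: float = 0.25
    learning: str = "dynamic"  # generative source of the RT recipe measures
    seed: int = 0

    def __post_init__(self):
        if not (len(self.alphabet) >= 2 and self.n_words > 0 and self.dim > 0):
            raise ValueError("need >=2 alphabet symbols and positive counts")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if self.learning not in ("dynamic", "static"):
            raise ValueError("learning flag must be 'dynamic' or 'static'")


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, salt]))


def gen_lexicon(cfg: SynthConfig, rng: np.random.Generator | None = None) -> list[str]:
    """``n_words`` unique random letter strings within the length range."""
    rng = rng or _rng(cfg, 1)
    letters = list(cfg.alphabet)
    possible = sum(len(letters) ** L for L in range(cfg.min_len, cfg.max_len + 1))
    if cfg.n_words > possible:
        raise ValueError(f"cannot draw {cfg.n_words} unique strings from {possible} possible")
    out: dict[str, None] = {}
    while len(out) < cfg.n_words:
        L = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        out.setdefault("".join(rng.choice(letters, size=L)), None)
    return list(out)


def gen_nonwords(
    words: list[str], cfg: SynthConfig, rng: np.random.Generator | None = None,
    max_tries: int = 200,
) -> list[str]:
    """One length-matched nonword per word, differing in 1-2 letter positions."""
    if not words:
        raise ValueError("word list is empty")
    rng = rng or _rng(cfg, 2)
    letters = list(cfg.alphabet)
    lexicon = set(words)
    taken: set[str] = set()
    out = []
    for w in words:
        for _ in range(max_tries):
            n_subs = int(rng.integers(1, min(2, len(w)) + 1))
            pos = rng.choice(len(w), size=n_subs, replace=False)
            chars = list(w)
            for p in pos:
                chars[p] = rng.choice([c for c in letters if c != w[p]])
            cand = "".join(chars)
            if cand not in lexicon and cand not in taken:
                out.append(cand)
                taken.add(cand)
                break
        else:
            raise RuntimeError(f"could not build a nonword for {w!r} in {max_tries} tries")
    return out


def gen_embeddings(cfg: SynthConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Cluster-structured Gaussian semantic matrix (n_words x dim)."""
    rng = rng or _rng(cfg, 3)
    centres = rng.normal(0.0, 1.0, size=(cfg.n_clusters, cfg.dim))
    labels = rng.integers(0, cfg.n_clusters, size=cfg.n_words)
    return centres[labels] + rng.normal(0.0, 0.35, size=(cfg.n_words, cfg.dim))


def gen_trials(
    words: list[str], nonwords: list[str], cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-subject interleaved word/nonword trial tables with blocks/sessions."""
    rng = rng or _rng(cfg, 4)
    half = cfg.trials_per_subject // 2
    reps_w = -(-half // len(words))  # ceil
    reps_n = -(-(cfg.trials_per_subject - half) // len(nonwords))
    frames = []
    n_blocks = -(-cfg.trials_per_subject // cfg.block_size)
    blocks_per_session = -(-n_blocks // cfg.n_sessions)
    for subj in range(1, cfg.n_subjects + 1):
        stims = (list(words) * reps_w)[:half] + (list(nonwords) * reps_n)[
            : cfg.trials_per_subject - half
        ]
        lex = ["word"] * half + ["nonword"] * (cfg.trials_per_subject - half)
        order = rng.permutation(cfg.trials_per_subject)
        trial = np.arange(1, cfg.trials_per_subject + 1)
        block = (trial - 1) // cfg.block_size
        frames.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "trial": trial,
                    "block": block + 1,
                    "session": block // blocks_per_session + 1,
                    "stimulus": np.asarray(stims, dtype=object)[order],
                    "lexicality": np.asarray(lex, dtype=object)[order],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_responses(
    trials: pd.DataFrame, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Responses equal lexicality except for seeded flips at the error rate."""
    rng = rng or _rng(cfg, 5)
    out = trials.copy()
    flip = rng.random(len(out)) < cfg.error_rate
    other = {"word": "nonword", "nonword": "word"}
    out["response"] = [
        other[lx] if f else lx for lx, f in zip(out["lexicality"], flip)
    ]
    return out


def _recipe_rt_inv(measures: pd.DataFrame, cfg: SynthConfig) -> np.ndarray:
    """Deterministic part of the RT recipe, from (transformed) measures.

    Mirrors the per-subset regression models: every trial carries the trial
    trend, word length, semantic density and cue activation diversity;
    c-precision contributes on word trials only and (log) form-driven
    semantic relatedness on nonword trials only; yes-activation contributes
    wherever the simulation provides it (dynamic mode).
    """
    coef = cfg.coefficients
    # stimuli whose trigrams are absent from every word have undefined
    # (zero-vector) measures before learning; treat them as zero signal
    sd = np.nan_to_num(
        np.clip(measures["semantic_density"].to_numpy(dtype=np.float64), 0.0, None)
    )
    log_sd = np.log(sd + LOG_BACKOFF) if np.any(sd == 0) else np.log(sd)
    cad = np.nan_to_num(measures["cue_activation_diversity"].to_numpy(dtype=np.float64))
    log_cad = np.log(cad + LOG_BACKOFF) if np.any(cad == 0) else np.log(cad)
    cprec = np.nan_to_num(measures["c_precision"].to_numpy(dtype=np.float64))
    fsr = np.clip(measures["fsr"].to_numpy(dtype=np.float64), 0.0, None)
    log_fsr = np.where(fsr > 0, np.log(np.where(fsr > 0, fsr, 1.0)), 0.0)
    is_word = (measures["lexicality"] == "word").to_numpy(dtype=np.float64)
    length = measures["stimulus"].astype(str).str.len().to_numpy(dtype=np.float64)
    trial_scaled = (
        measures.groupby("subject")["trial"]
        .transform(lambda t: scale_trial_number(t.to_numpy()))
        .to_numpy()
    )
    rt_inv = (
        coef["intercept"]
        + coef["trial_scaled"] * trial_scaled
        + coef.get("word_length", 0.0) * (length - length.mean())
        + coef["log_semantic_density"] * log_sd
        + coef["log_cue_activation_diversity"] * log_cad
        + coef["c_precision"] * cprec * is_word
        + coef.get("log_fsr", 0.0) * log_fsr * (1.0 - is_word)
    )
    ya = measures["yes_activation"].to_numpy(dtype=np.float64)
    if not np.all(np.isnan(ya)):  # static simulations carry no yes-activation
        rt_inv = rt_inv + coef["yes_activation"] * np.nan_to_num(ya)
    return rt_inv


def session_ar1_noise(
    sessions: np.ndarray, rho: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise restarted at every session boundary."""
    innov_sd = sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    eps = np.empty(len(sessions))
    prev = 0.0
    for i in range(len(sessions)):
        if i == 0 or sessions[i] != sessions[i - 1]:
            prev = rng.normal(0.0, sd)
        else:
            prev = rho * prev + rng.normal(0.0, innov_sd)
        eps[i] = prev
    return eps


def gen_rts(
    trials: pd.DataFrame, measures: pd.DataFrame, cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach RTs generated additively from measures plus AR(1) noise.

    ``measures`` must be the trial table with measure columns appended (as
    produced by the trial engine in the mode named by ``cfg.learning``), in
    the same row order as ``trials``.
    """
    rng = rng or _rng(cfg, 6)
    rt_inv = _recipe_rt_inv(measures, cfg)
    noise = np.concatenate(
        [
            session_ar1_noise(grp["session"].to_numpy(), cfg.rho, cfg.noise_sd, rng)
            for _, grp in measures.groupby("subject", sort=False)
        ]
    )
    rt_inv = rt_inv + noise
    if np.any(rt_inv >= 0):
        raise ValueError("RT recipe produced nonnegative rt_inv; adjust coefficients")
    rt = np.clip(-1000.0 / rt_inv, 100.0 + 1e-9, 2000.0)
    out = trials.copy()
    out["rt"] = rt
    return out


def make_experiment(cfg: SynthConfig) -> dict:
    """Generate lexicon, embeddings, trials and responses (RTs need measures).

    Returns a dict with keys ``words``, ``nonwords``, ``S`` and ``trials``
    (responses included, RT column absent — it is added by :func:`gen_rts`
    once the trial engine has produced measures in the configured mode).
    """
    words = gen_lexicon(cfg)
    nonwords = gen_nonwords(words, cfg)
    S = gen_embeddings(cfg)
    trials = gen_responses(gen_trials(words, nonwords, cfg), cfg)
    return {"words": words, "nonwords": nonwords, "S": S, "trials": trials}
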