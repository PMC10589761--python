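"""Linear discriminative mappings and their error-driven updates.

Three linear networks connect form and meaning:

* ``F`` (trigrams x dims) maps a cue vector to a predicted semantic vector,
  ``s_hat = c @ F`` (comprehension);
* ``G`` (dims x trigrams) maps a semantic vector back to a predicted form
  vector, ``c_hat = s @ G`` (the production feedback loop);
* ``D`` (trigrams,) maps a cue vector to scalar support for a "word"
  response, ``d = c @ D`` (lexicality).

The endstate of learning is the least-squares solution (minimum-norm when
the cue matrix is rank-deficient, which trigram matrices routinely are).
Incremental learning uses the Widrow-Hoff delta rule, e.g. for
comprehension::

    F <- F + c.T (s - c F) eta

Default learning rates: 0.001 for F and G, 0.01 for D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

#: default Widrow-Hoff learning rate for the form<->meaning mappings F and G
DEFAULT_ETA_FG = 0.001
#: default Widrow-Hoff learning rate for the form->lexicality mapping D
DEFAULT_ETA_D = 0.01


@dataclass
class MappingState:
    """The evolving state of one simulated participant's lexicon.

    Holds the three mappings plus the evolving nonword target vector ``n``
    (the running semantic representation of the 'nonword' category) and the
    two learning rates.
    """

    F: np.ndarray
    G: np.ndarray
    D: np.ndarray
    n: np.ndarray
    eta_fg: float = DEFAULT_ETA_FG
    eta_d: float = DEFAULT_ETA_D

    def __post_init__(self) -> None:
        n_cues, dim = self.F.shape
        if self.G.shape != (dim, n_cues):
            raise ValueError(f"G shape {self.G.shape} inconsistent with F {self.F.shape}")
        if self.D.shape != (n_cues,):
            raise ValueError(f"D shape {self.D.shape} inconsistent with F {self.F.shape}")
        if self.n.shape != (dim,):
            raise ValueError(f"n shape {self.n.shape} inconsistent with F {self.F.shape}")

    @property
    def n_cues(self) -> int:
        return self.F.shape[0]

    @property
    def dim(self) -> int:
        return self.F.shape[1]

    def copy(self) -> "MappingState":
        return MappingState(
            F=self.F.copy(), G=self.G.copy(), D=self.D.copy(), n=self.n.copy(),
            eta_fg=self.eta_fg, eta_d=self.eta_d,
        )


def estimate_endstate(C: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Endstate-of-learning mappings ``F`` and ``G`` by least squares.

    ``F`` minimises ||C F - S||_F and ``G`` minimises ||S G - C||_F, both with
    the minimum-norm convention under rank deficiency (``numpy.linalg.lstsq``).
    """
    C = np.asarray(C, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if C.ndim != 2 or S.ndim != 2 or C.shape[0] != S.shape[0]:
        raise ValueError(f"row-aligned 2-D matrices required, got {C.shape} and {S.shape}")
    F = np.linalg.lstsq(C, S, rcond=None)[0]
    G = np.linalg.lstsq(S, C, rcond=None)[0]
    return F, G


def init_state(
    C: np.ndarray,
    S: np.ndarray,
    eta_fg: float = DEFAULT_ETA_FG,
    eta_d: float = DEFAULT_ETA_D,
) -> MappingState:
    """Prior knowledge: endstate F and G; D and the nonword vector start at zero.

    D starts at zero because deciding 'nonword' is a task-specific
    metalinguistic skill assumed absent before the experiment; likewise the
    nonword semantic target only comes into being during the experiment.
    """
    F, G = estimate_endstate(C, S)
    return MappingState(
        F=F, G=G,
        D=np.zeros(C.shape[1]),
        n=np.zeros(S.shape[1]),
        eta_fg=eta_fg, eta_d=eta_d,
    )


def comprehend(c: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Predicted semantic vector ``s_hat = c @ F``."""
    return np.asarray(c, dtype=np.float64) @ F


def produce(s: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Predicted form vector ``c_hat = s @ G``."""
    return np.asarray(s, dtype=np.float64) @ G


def update_F(state: MappingState, c: np.ndarray, target_s: np.ndarray) -> MappingState:
    """Widrow-Hoff update of the comprehension mapping (out of place).

    Only rows of ``F`` with a non-zero cue change.
    """
    err = target_s - comprehend(c, state.F)
    F = state.F + np.outer(c, err) * state.eta_fg
    return replace(state, F=F)


def update_G(state: MappingState, target_s: np.ndarray, c: np.ndarray) -> MappingState:
    """Widrow-Hoff update of the production mapping (out of place)."""
    err = c - produce(target_s, state.G)
    G = state.G + np.outer(target_s, err) * state.eta_fg
    return replace(state, G=G)


def update_D(state: MappingState, c: np.ndarray, r: int) -> MappingState:
    """Widrow-Hoff update of the lexicality mapping toward response ``r``.

    ``r`` is the participant's response (1 = word, 0 = nonword), not the true
    lexicality: without feedback, only the participant's own decision is
    available as a teaching signal.  The prediction ``d = c @ D`` uses the
    pre-update ``D``.
    """
    if r not in (0, 1):
        raise ValueError(f"response code must be 0 or 1, got {r!r}")
    d = float(np.asarray(c, dtype=np.float64) @ state.D)
    D = state.D + np.asarray(c, dtype=np.float64) * ((r - d) * state.eta_d)
    return replace(state, D=D)


def comprehension_accuracy(
    S_hat: np.ndarray, S: np.ndarray, k: int = 5, metric: str = "cosine"
) -> float:
    """Fraction of rows whose target is among the k nearest semantic vectors.

    Row ``i`` counts as correct when row ``i`` of ``S`` is among the ``k``
    most similar rows of ``S`` to the prediction ``S_hat[i]``.  Similarity is
    cosine by default; ``metric="correlation"`` centres the vectors first.
    """
    S_hat = np.asarray(S_hat, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if S_hat.shape != S.shape:
        raise ValueError("predicted and target matrices must be row-aligned")
    if not 1 <= k <= S.shape[0]:
        raise ValueError(f"k={k} out of range for {S.shape[0]} rows")
    if metric == "correlation":
        S_hat = S_hat - S_hat.mean(axis=1, keepdims=True)
        S = S - S.mean(axis=1, keepdims=True)
    elif metric != "cosine":
        raise ValueError(f"unknown metric {metric!r}")
    sims = cosine_similarity(S_hat, S)
    # indices of the k largest similarities per row
    top = np.argpartition(-sims, kth=k - 1, axis=1)[:, :k]
    hits = (top == np.arange(S.shape[0])[:, None]).any(axis=1)
    return float(hits.mean())
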