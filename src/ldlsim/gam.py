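"""Per-subject additive models with session-restarted AR(1) residuals.

The response (``rt_inv``) of one subject forms a time series whose residuals
are lag-1 autocorrelated.  Following the standard generalized-least-squares
device, the model is fitted on prewhitened data: within each session, row t
is replaced by ``row_t - rho * row_{t-1}`` (response and design columns
alike), with the first row of every session left untouched.  ``rho`` is
estimated once per subject and response subset from the residuals of a
classical-predictor model fitted without autocorrelation, and then reused
for every model family, so AIC values are comparable across families.

Smooth terms are penalized cubic B-splines (second-derivative penalty,
sum-to-zero constrained); smoothing parameters are selected by GCV.
``AIC = -2 loglik + 2 (EDF + 1)`` with the Gaussian log-likelihood at the
MLE of the residual variance and EDF the trace of the hat matrix.  Model
families are compared per subject by AIC; the relative likelihood of the
better model is ``exp(|dAIC|/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, null_space
from sklearn.base import BaseEstimator, RegressorMixin

from statsmodels.gam.smooth_basis import BSplines

__all__ = [
    "SmoothTerm", "LinearTerm", "TensorTerm", "ModelSpec", "FitSummary",
    "ModelComparison", "AdditiveModel", "estimate_rho", "prewhiten",
    "fit_additive_model", "compare_models", "tally_across_subjects",
    "word_model_spec", "nonword_model_spec", "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("classical", "static_dlm", "dynamic_dlm", "dynamic_dlm_no_yesact")

_LAMBDA_GRID = 10.0 ** np.arange(-3.0, 7.0)
_GCV_GAMMA = 1.4  # EDF inflation in the GCV score


@dataclass(frozen=True)
class LinearTerm:
    """A strictly parametric column (factor codes and indicators included)."""

    var: str

    @property
    def name(self) -> str:
        return self.var


@dataclass(frozen=True)
class SmoothTerm:
    """Penalized spline of one predictor, optionally gated by a 0/1 column."""

    var: str
    by: str | None = None
    k: int = 10

    @property
    def name(self) -> str:
        return f"s({self.var})" if self.by is None else f"s({self.var},by={self.by})"


@dataclass(frozen=True)
class TensorTerm:
    """Tensor-product interaction smooth of two predictors."""

    var1: str
    var2: str
    by: str | None = None
    k: int = 5

    @property
    def name(self) -> str:
        base = f"te({self.var1},{self.var2})"
        return base if self.by is None else f"te({self.var1},{self.var2},by={self.by})"


@dataclass(frozen=True)
class ModelSpec:
    """A named predictor set for one response subset."""

    label: str
    terms: tuple
    response: str = "rt_inv"

    def columns(self) -> list[str]:
        cols: list[str] = [self.response]
        for t in self.terms:
            if isinstance(t, LinearTerm):
                cols.append(t.var)
            elif isinstance(t, SmoothTerm):
                cols.append(t.var)
                if t.by:
                    cols.append(t.by)
            else:
                cols.extend([t.var1, t.var2])
                if t.by:
                    cols.append(t.by)
        return list(dict.fromkeys(cols))


@dataclass
class FitSummary:
    """Portable summary of one fitted model."""

    label: str
    aic: float
    edf: float
    pvalues: dict[str, float]
    rho: float
    n: int
    converged: bool
    subject: object = None
    response_subset: str | None = None


@dataclass
class ModelComparison:
    """AIC comparison of two fits on the same rows."""

    subject: object
    label_a: str
    label_b: str
    delta_aic: float  # AIC_a - AIC_b; positive favours b
    relative_likelihood: float
    better: str


def estimate_rho(residuals, sessions) -> float:
    """Pooled lag-1 autocorrelation of residuals, restarted at session breaks.

    Pairs straddling a session boundary are excluded from the numerator; the
    denominator is the total sum of squares, as in the sample ACF.
    """
    r = np.asarray(residuals, dtype=np.float64)
    s = np.asarray(sessions)
    if r.shape != s.shape or r.ndim != 1:
        raise ValueError("residuals and sessions must be aligned 1-D arrays")
    same = s[1:] == s[:-1]
    if not same.any():
        raise ValueError("no within-session lag-1 pairs available")
    r = r - r.mean()
    num = float(np.sum(r[1:][same] * r[:-1][same]))
    den = float(np.sum(r * r))
    if den == 0.0:
        raise ValueError("zero-variance residuals")
    return num / den


def _session_starts(sessions) -> np.ndarray:
    s = np.asarray(sessions)
    starts = np.ones(len(s), dtype=bool)
    starts[1:] = s[1:] != s[:-1]
    return starts


def prewhiten(y, X, rho: float, sessions) -> tuple[np.ndarray, np.ndarray]:
    """AR(1) prewhitening of response and design, restarted per session."""
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    starts = _session_starts(sessions)
    yw = y.copy()
    Xw = X.copy()
    inner = ~starts
    yw[inner] -= rho * y[np.flatnonzero(inner) - 1]
    Xw[inner] -= rho * X[np.flatnonzero(inner) - 1]
    return yw, Xw


def _constrain(B: np.ndarray, penalties: list[np.ndarray]):
    """Apply a sum-to-zero constraint, returning the reduced basis/penalties."""
    cmean = B.mean(axis=0, keepdims=True)
    Z = null_space(cmean)
    return B @ Z, [Z.T @ S @ Z for S in penalties], Z


class _Block:
    """One design block: columns, penalties (possibly none), and metadata."""

    def __init__(self, name, X, penalties, builder):
        self.name = name
        self.X = X
        self.penalties = penalties  # list of (k,k) matrices sharing the block
        self.builder = builder  # callable df -> block columns (for predict)


def _spline_block(df: pd.DataFrame, term: SmoothTerm):
    x = df[term.var].to_numpy(dtype=np.float64)
    distinct = np.unique(x).size
    if distinct < 4:
        # too few support points for a spline: penalized (ridge) linear
        # column, so degenerate predictors shrink instead of aliasing
        col = (x - x.mean())[:, None]
        builder = lambda new, mu=x.mean(): (new[term.var].to_numpy(dtype=np.float64) - mu)[:, None]
        X, pens = col, [np.eye(1)]
        if term.by is not None:
            b = df[term.by].to_numpy(dtype=np.float64)
            X = X * b[:, None]
            inner = builder
            builder = lambda new, f=inner: f(new) * new[term.by].to_numpy(dtype=np.float64)[:, None]
        return _Block(term.name, X, pens, builder)
    k = int(min(term.k, max(4, distinct - 1)))
    bs = BSplines(x, df=[k], degree=[3], include_intercept=True)
    B, pens, Z = _constrain(bs.basis, [bs.penalty_matrices[0]])
    # double-penalty shrinkage: a ridge on the same block lets the penalty
    # null space (the linear direction) shrink away when a term is inert
    pens = pens + [np.eye(B.shape[1])]

    def builder(new, bs=bs, Z=Z):
        Xn = bs.transform(new[term.var].to_numpy(dtype=np.float64)[:, None]) @ Z
        if term.by is not None:
            Xn = Xn * new[term.by].to_numpy(dtype=np.float64)[:, None]
        return Xn

    if term.by is not None:
        B = B * df[term.by].to_numpy(dtype=np.float64)[:, None]
    return _Block(term.name, B, pens, builder)


def _tensor_block(df: pd.DataFrame, term: TensorTerm):
    x1 = df[term.var1].to_numpy(dtype=np.float64)
    x2 = df[term.var2].to_numpy(dtype=np.float64)
    k1 = int(min(term.k, max(4, np.unique(x1).size - 1)))
    k2 = int(min(term.k, max(4, np.unique(x2).size - 1)))
    bs1 = BSplines(x1, df=[k1], degree=[3], include_intercept=True)
    bs2 = BSplines(x2, df=[k2], degree=[3], include_intercept=True)
    B1, B2 = bs1.basis, bs2.basis
    B = (B1[:, :, None] * B2[:, None, :]).reshape(len(df), k1 * k2)
    S1 = np.kron(bs1.penalty_matrices[0], np.eye(k2))
    S2 = np.kron(np.eye(k1), bs2.penalty_matrices[0])
    B, pens, Z = _constrain(B, [S1, S2])
    pens = pens + [np.eye(B.shape[1])]  # double-penalty shrinkage

    def builder(new, bs1=bs1, bs2=bs2, Z=Z, k1=k1, k2=k2):
        b1 = bs1.transform(new[term.var1].to_numpy(dtype=np.float64)[:, None])
        b2 = bs2.transform(new[term.var2].to_numpy(dtype=np.float64)[:, None])
        Xn = (b1[:, :, None] * b2[:, None, :]).reshape(len(new), k1 * k2) @ Z
        if term.by is not None:
            Xn = Xn * new[term.by].to_numpy(dtype=np.float64)[:, None]
        return Xn

    if term.by is not None:
        B = B * df[term.by].to_numpy(dtype=np.float64)[:, None]
    return _Block(term.name, B, pens, builder)


class AdditiveModel(BaseEstimator, RegressorMixin):
    """Penalized-spline additive regression with AR(1) prewhitening.

    scikit-learn style estimator over a tidy per-trial DataFrame: ``fit``
    takes the table (which must contain every column the spec names plus,
    when ``rho != 0``, the session column), builds the design, prewhitens
    it, selects smoothing parameters by GCV and stores ``aic_``, ``edf_``,
    ``pvalues_`` and the coefficients.

    Parameters
    ----------
    spec : ModelSpec
        Response name and term list.
    rho : float
        AR(1) coefficient used for prewhitening (0 disables).
    session_col : str
        Column defining autocorrelation restarts.
    """

    def __init__(self, spec: ModelSpec, rho: float = 0.0, session_col: str = "session"):
        self.spec = spec
        self.rho = rho
        self.session_col = session_col

    # -- design -----------------------------------------------------------
    def _build_blocks(self, df: pd.DataFrame) -> list[_Block]:
        blocks = [
            _Block("(Intercept)", np.ones((len(df), 1)), [], lambda new: np.ones((len(new), 1)))
        ]
        for term in self.spec.terms:
            if isinstance(term, LinearTerm):
                v = term.var
                blocks.append(
                    _Block(
                        term.name,
                        df[v].to_numpy(dtype=np.float64)[:, None],
                        [],
                        lambda new, v=v: new[v].to_numpy(dtype=np.float64)[:, None],
                    )
                )
            elif isinstance(term, SmoothTerm):
                blocks.append(_spline_block(df, term))
            elif isinstance(term, TensorTerm):
                blocks.append(_tensor_block(df, term))
            else:
                raise TypeError(f"unknown term {term!r}")
        return blocks

    # -- fitting ----------------------------------------------------------
    def fit(self, df: pd.DataFrame, y=None):
        cols = self.spec.columns()
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        use = df.dropna(subset=cols)
        if self.rho != 0.0 and self.session_col not in use.columns:
            raise ValueError(f"prewhitening requires a {self.session_col!r} column")
        use = use.reset_index(drop=True)
        if len(use) < 10:
            raise ValueError("too few complete-case rows to fit")
        self.n_obs_ = len(use)
        self.blocks_ = self._build_blocks(use)
        X = np.hstack([b.X for b in self.blocks_])
        yvec = use[self.spec.response].to_numpy(dtype=np.float64)

        unpen_cols = np.concatenate(
            [np.full(b.X.shape[1], not b.penalties) for b in self.blocks_]
        )
        X_unpen = X[:, unpen_cols]
        rank = np.linalg.matrix_rank(X_unpen)
        if rank < X_unpen.shape[1]:
            aliased = [b.name for b in self.blocks_ if not b.penalties]
            raise ValueError(f"rank-deficient parametric design among terms {aliased}")

        sessions = (
            use[self.session_col].to_numpy() if self.session_col in use.columns
            else np.zeros(len(use))
        )
        if self.rho != 0.0:
            yw, Xw = prewhiten(yvec, X, self.rho, sessions)
        else:
            yw, Xw = yvec, X

        # assemble full-size penalty matrices, one lambda per penalty
        p = Xw.shape[1]
        offsets = np.cumsum([0] + [b.X.shape[1] for b in self.blocks_])
        S_full: list[np.ndarray] = []
        self._pen_owner_: list[int] = []
        for bi, b in enumerate(self.blocks_):
            for S in b.penalties:
                Sf = np.zeros((p, p))
                sl = slice(offsets[bi], offsets[bi + 1])
                Sf[sl, sl] = S
                S_full.append(Sf)
                self._pen_owner_.append(bi)

        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)
        n = len(yw)

        def solve(lams):
            A = XtX.copy()
            for lam, S in zip(lams, S_full):
                A += lam * S
            try:
                cf = cho_factor(A + 1e-10 * np.eye(p))
            except np.linalg.LinAlgError:
                return None
            beta = cho_solve(cf, Xty)
            H = cho_solve(cf, XtX)  # A^{-1} X'X
            edf = float(np.trace(H))
            rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 1e-12)
            return beta, edf, rss, cf

        def gcv(lams):
            out = solve(lams)
            if out is None:
                return np.inf, None
            _, edf, rss, _ = out
            # gamma > 1 counters GCV's tendency to undersmooth, which would
            # otherwise make post-selection AIC optimistic for larger models
            denom = max(n - _GCV_GAMMA * edf, 1.0)
            return n * rss / denom**2, out

        lams = np.ones(len(S_full))
        best, best_out = gcv(lams)
        if S_full:
            for _ in range(3):  # coordinate-descent sweeps over the grid
                improved = False
                for j in range(len(S_full)):
                    for cand in _LAMBDA_GRID:
                        trial = lams.copy()
                        trial[j] = cand
                        val, out = gcv(trial)
                        if val < best - 1e-10:
                            best, best_out, lams = val, out, trial
                            improved = True
                if not improved:
                    break
        beta, edf, rss, cf = best_out
        self.residuals_ = yw - Xw @ beta  # prewhitened-scale residuals
        self.sessions_ = sessions
        self.lambdas_ = lams
        self.coef_ = beta
        self.edf_ = edf
        self.rss_ = rss
        self.sigma2_ = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * self.sigma2_) + 1.0)
        self.aic_ = float(-2.0 * loglik + 2.0 * (edf + 1.0))
        self.converged_ = True

        # per-term EDF and approximate Wald p-values
        Ainv_XtX = cho_solve(cf, XtX)
        cov = self.sigma2_ * cho_solve(cf, XtX @ cho_solve(cf, np.eye(p)).T)
        self.edf_by_term_ = {}
        self.pvalues_ = {}
        for bi, b in enumerate(self.blocks_):
            sl = slice(offsets[bi], offsets[bi + 1])
            term_edf = float(np.trace(Ainv_XtX[sl, sl]))
            self.edf_by_term_[b.name] = term_edf
            if b.name == "(Intercept)":
                continue
            bvec = beta[sl]
            Vb = cov[sl, sl]
            r = max(int(round(term_edf)), 1)
            Vinv = np.linalg.pinv(Vb, rcond=1e-10)
            wald = float(bvec @ Vinv @ bvec)
            self.pvalues_[b.name] = float(stats.chi2.sf(wald, df=r))
        self._offsets_ = offsets
        return self

    # -- prediction -------------------------------------------------------
    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = np.hstack([b.builder(df) for b in self.blocks_])
        return X @ self.coef_

    def partial_effect(self, term_name: str, df: pd.DataFrame) -> np.ndarray:
        """Contribution of one term to the linear predictor on new data."""
        for bi, b in enumerate(self.blocks_):
            if b.name == term_name:
                sl = slice(self._offsets_[bi], self._offsets_[bi + 1])
                return b.builder(df) @ self.coef_[sl]
        raise KeyError(f"no term named {term_name!r}")

    def summary(self, subject=None, response_subset=None) -> FitSummary:
        return FitSummary(
            label=self.spec.label,
            aic=self.aic_,
            edf=self.edf_,
            pvalues=dict(self.pvalues_),
            rho=self.rho,
            n=self.n_obs_,
            converged=self.converged_,
            subject=subject,
            response_subset=response_subset,
        )


def fit_additive_model(
    spec: ModelSpec, table: pd.DataFrame, rho: float = 0.0, session_col: str = "session"
) -> FitSummary:
    """Fit one spec to one subject's regression table; return its summary."""
    model = AdditiveModel(spec=spec, rho=rho, session_col=session_col)
    model.fit(table)
    return model.summary()


def compare_models(fit_a: FitSummary, fit_b: FitSummary) -> ModelComparison:
    """AIC comparison; relative likelihood of the better model is exp(|dAIC|/2)."""
    if fit_a.n != fit_b.n:
        raise ValueError(f"fits use different row counts: {fit_a.n} vs {fit_b.n}")
    delta = fit_a.aic - fit_b.aic
    return ModelComparison(
        subject=fit_a.subject,
        label_a=fit_a.label,
        label_b=fit_b.label,
        delta_aic=delta,
        relative_likelihood=float(np.exp(abs(delta) / 2.0)),
        better=fit_b.label if delta > 0 else fit_a.label,
    )


def tally_across_subjects(
    comparisons: list[ModelComparison],
    fits: list[FitSummary] | None = None,
    alpha: float = 0.001,
) -> dict:
    """Cross-subject summary: win rates, mean AIC difference, term reliability."""
    out: dict = {}
    if comparisons:
        deltas = np.array([c.delta_aic for c in comparisons])
        wins = np.array([c.better == c.label_b for c in comparisons])
        out["pct_b_better"] = float(100.0 * wins.mean())
        out["mean_delta_aic"] = float(deltas.mean())
    if fits:
        terms: dict[str, list[float]] = {}
        for f in fits:
            for name, p in f.pvalues.items():
                terms.setdefault(name, []).append(p)
        out["reliability_pct"] = {
            name: float(100.0 * np.mean(np.asarray(ps) < alpha)) for name, ps in terms.items()
        }
    return out


# -- canonical per-subset model specs -------------------------------------

def word_model_spec(family: str) -> ModelSpec:
    """Predictor set for word trials under one model family."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    terms: list = [
        SmoothTerm("trial_scaled", k=20),
        LinearTerm("in_bnc"),
        SmoothTerm("in_bnc_x_log_frequency", by="in_bnc", k=10),
        SmoothTerm("word_length", k=5),
        LinearTerm("response_word"),
    ]
    if family == "classical":
        terms += [
            LinearTerm("has_neighbours"),
            SmoothTerm("has_neighbours_x_log_nsize", by="has_neighbours", k=10),
        ]
    else:
        terms += [
            SmoothTerm("log_semantic_density", k=10),
            SmoothTerm("log_cue_activation_diversity", by="response_word", k=10),
            SmoothTerm("log_cue_activation_diversity", by="response_nonword", k=10),
            SmoothTerm("c_precision", k=10),
        ]
        if family == "dynamic_dlm":
            terms.append(SmoothTerm("yes_activation", k=10))
    return ModelSpec(label=family, terms=tuple(terms))


def nonword_model_spec(family: str) -> ModelSpec:
    """Predictor set for nonword trials under one model family."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    terms: list = [
        SmoothTerm("trial_scaled", k=20),
        SmoothTerm("word_length", k=5),
        LinearTerm("response_word"),
    ]
    if family == "classical":
        terms += [
            LinearTerm("has_neighbours"),
            SmoothTerm("has_neighbours_x_log_nsize", by="has_neighbours", k=10),
        ]
    else:
        terms += [
            LinearTerm("has_neighbours_path"),
            SmoothTerm("has_path_x_log_fsr", by="has_neighbours_path", k=10),
            # main effects alongside the by-response tensors: with a tensor
            # gated by a sparse factor level, omitted main effects are
            # under-fitted and leak into any correlated extra regressor,
            # which would bias family comparisons
            SmoothTerm("log_cue_activation_diversity", k=8),
            SmoothTerm("log_semantic_density", k=8),
            TensorTerm("log_cue_activation_diversity", "log_semantic_density",
                       by="response_nonword", k=4),
            TensorTerm("log_cue_activation_diversity", "log_semantic_density",
                       by="response_word", k=4),
        ]
        if family == "dynamic_dlm":
            terms.append(SmoothTerm("yes_activation", k=10))
    return ModelSpec(label=family, terms=tuple(terms))
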