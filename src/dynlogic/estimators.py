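"""Scikit-learn style estimators over the dynamic-logic engine.

:class:`DynamicLogicMixture` fits spatial scenes (2-D points or
raster-derived pixel weights): a uniform clutter component plus blob /
parabola components, with annealed vagueness and optional structural
adaptation.  :class:`BernoulliMixtureDL` fits feature-vector data x[n, i] in
[0, 1] with a mixture of product-Bernoulli components started from the vague
p ~ 0.5 state.

Both follow the sklearn mixture API: ``fit`` / ``predict`` /
``predict_proba`` / ``score_samples`` / ``score``, fitted attributes with a
trailing underscore, and full ``get_params`` / ``set_params`` support so they
compose with pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .engine import (
    EngineConfig,
    associations,
    log_similarity,
    run_dl,
)
from .families import component_log_likelihood
from .observations import Domain, ObservationSet

__all__ = ["DynamicLogicMixture", "BernoulliMixtureDL"]


def _logsumexp_rows(lj: np.ndarray) -> np.ndarray:
    from scipy.special import logsumexp

    return logsumexp(lj, axis=0)


class _DLBase(DensityMixin, BaseEstimator):
    def _config(self) -> EngineConfig:
        seed = self.random_state if self.random_state is not None else 0
        return EngineConfig(
            dt=self.dt,
            convergence_tol=self.convergence_tol,
            max_iterations=self.max_iterations,
            anneal_factor=self.anneal_factor,
            initial_vagueness=self.initial_vagueness,
            floor_min=self.floor_min,
            structure_penalty=self.structure_penalty,
            structure_check_period=self.structure_check_period,
            settle_iterations=self.settle_iterations,
            adapt=self.adapt,
            seed=int(seed),
        )

    def _finish_fit(self, report, obs: ObservationSet):
        self.report_ = report
        self.mixture_ = report.mixture
        self.components_ = report.mixture.components
        self.weights_ = np.array([c.r for c in self.components_])
        self.n_components_ = report.mixture.M
        self.n_iter_ = len(report.trace)
        self.lower_bound_ = report.final_ll()
        self.converged_ = report.convergence_reason == "similarity_stopped_increasing"
        return self

    def _log_joint(self, obs: ObservationSet) -> np.ndarray:
        rows = [
            np.log(max(c.r, 1e-300)) + component_log_likelihood(c, obs)
            for c in self.components_
        ]
        return np.vstack(rows)

    def predict_proba(self, X):
        """Posterior association probabilities f(m|n), shape (N, M)."""
        check_is_fitted(self)
        obs = self._as_observations(X)
        return associations(self.mixture_, obs).T

    def predict(self, X):
        """Hard assignment: index of the most associated component."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X):
        """Per-observation log-density ln sum_m r(m) l(n|m)."""
        check_is_fitted(self)
        obs = self._as_observations(X)
        return _logsumexp_rows(self._log_joint(obs))

    def score(self, X, y=None):
        """Mean per-observation log-density (sklearn mixture convention)."""
        return float(np.mean(self.score_samples(X)))


class DynamicLogicMixture(_DLBase):
    """Vague-to-crisp mixture estimation for 2-D scenes.

    Parameters mirror :class:`dynlogic.engine.EngineConfig`; ``families`` is
    the initial component stack (a clutter component is always included).
    ``domain`` fixes the scene rectangle; when ``None`` it is inferred from
    the data bounding box at fit time.

    Attributes (after ``fit``): ``components_``, ``weights_``,
    ``n_components_``, ``n_iter_``, ``lower_bound_``, ``converged_``,
    ``report_`` (the full :class:`dynlogic.engine.RunReport`).
    """

    def __init__(
        self,
        families=("blob",),
        domain=None,
        dt=1.0,
        convergence_tol=1e-6,
        max_iterations=200,
        anneal_factor=0.9,
        initial_vagueness=0.5,
        floor_min=1.0,
        structure_penalty=None,
        structure_check_period=5,
        settle_iterations=10,
        adapt=True,
        random_state=None,
    ):
        self.families = families
        self.domain = domain
        self.dt = dt
        self.convergence_tol = convergence_tol
        self.max_iterations = max_iterations
        self.anneal_factor = anneal_factor
        self.initial_vagueness = initial_vagueness
        self.floor_min = floor_min
        self.structure_penalty = structure_penalty
        self.structure_check_period = structure_check_period
        self.settle_iterations = settle_iterations
        self.adapt = adapt
        self.random_state = random_state

    def _as_observations(self, X, sample_weight=None) -> ObservationSet:
        X = np.asarray(X, dtype=float)
        if isinstance(X, ObservationSet):
            return X
        if self.domain is not None:
            dom = self.domain if isinstance(self.domain, Domain) else Domain(*self.domain)
        else:
            dom = getattr(self, "domain_", None) or Domain(
                float(np.max(X[:, 0])) * 1.05 + 1e-9,
                float(np.max(X[:, 1])) * 1.05 + 1e-9,
            )
        n = len(X)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        return ObservationSet(
            ids=np.arange(n), weights=w, dialect="points", positions=X, domain=dom
        )

    def fit(self, X, y=None, sample_weight=None):
        """Fit the mixture to positions ``X`` (N, 2) with optional weights."""
        if isinstance(X, ObservationSet):
            obs = X
        else:
            X = validate_data(self, X, ensure_min_samples=2)
            if X.shape[1] != 2:
                raise ValueError("DynamicLogicMixture expects 2-D positions")
            obs = self._as_observations(X, sample_weight)
        self.domain_ = obs.domain
        report = run_dl(obs, self._config(), families=list(self.families))
        return self._finish_fit(report, obs)


class BernoulliMixtureDL(_DLBase):
    """Dynamic-logic mixture of product-Bernoulli components.

    ``n_components`` bernoulli components are started from the maximally
    vague state p ~ 0.5 and crisped by annealing the variance floor while
    the damped EM iterations maximize the similarity.  ``lexicon`` together
    with ``feature_blocks`` implements the dual-model layout: the "language"
    feature block is initialized crisply from the lexicon rows and exempted
    from the vagueness clamp, while the "cognitive" block is learned from the
    vague state.
    """

    def __init__(
        self,
        n_components=2,
        dt=1.0,
        convergence_tol=1e-6,
        max_iterations=200,
        anneal_factor=0.9,
        initial_vagueness=0.5,
        floor_min=1.0,
        structure_penalty=None,
        structure_check_period=5,
        settle_iterations=10,
        adapt=False,
        feature_blocks=None,
        lexicon=None,
        random_state=None,
    ):
        self.n_components = n_components
        self.dt = dt
        self.convergence_tol = convergence_tol
        self.max_iterations = max_iterations
        self.anneal_factor = anneal_factor
        self.initial_vagueness = initial_vagueness
        self.floor_min = floor_min
        self.structure_penalty = structure_penalty
        self.structure_check_period = structure_check_period
        self.settle_iterations = settle_iterations
        self.adapt = adapt
        self.feature_blocks = feature_blocks
        self.lexicon = lexicon
        self.random_state = random_state

    def _as_observations(self, X, sample_weight=None) -> ObservationSet:
        if isinstance(X, ObservationSet):
            return X
        X = np.asarray(X, dtype=float)
        n = len(X)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        return ObservationSet(
            ids=np.arange(n),
            weights=w,
            dialect="features",
            features=X,
            feature_blocks=self.feature_blocks,
        )

    def fit(self, X, y=None, sample_weight=None):
        """Fit to feature vectors ``X`` (N, K) with values in [0, 1]."""
        if not isinstance(X, ObservationSet):
            X = validate_data(self, X)
        obs = self._as_observations(X, sample_weight)
        lex = None if self.lexicon is None else np.asarray(self.lexicon, float)
        report = run_dl(
            obs,
            self._config(),
            families=["bernoulli"] * int(self.n_components),
            lexicon=lex,
        )
        self._finish_fit(report, obs)
        self.p_ = np.vstack(
            [c.params["p"] for c in self.components_ if c.family == "bernoulli"]
        )
        return self
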