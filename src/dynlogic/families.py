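"""Top-down model families: likelihoods l(n|m) and their weighted M-step rules.

Four families are supported:

clutter
    uniform density 1/area over the scene domain — absorbs background noise;
blob
    bivariate Gaussian with free mean and covariance;
parabola
    a parabolic arc of half-extent U with an isotropic transverse Gaussian of
    sd sigma; the density is the arc-average of the transverse Gaussian,
    l(x) = (1/2U) * int_{-U}^{U} g_sigma(x - c(u)) du, evaluated by fixed-node
    Gauss-Legendre quadrature (default 64 nodes);
bernoulli
    independent Bernoulli features, P(x|p) = prod_i p_i^x_i (1-p_i)^(1-x_i),
    computed in log space with probabilities clamped to [eps, 1-eps].

Each family's M-step computes the responsibility-weighted maximizer theta_EM
and takes the damped step theta <- theta + dt * (theta_EM - theta); dt = 1
reproduces a standard EM step.  Scale parameters (blob covariance eigenvalues,
parabola transverse variance, bernoulli variance p(1-p)) are clamped from
below by the component's current *vagueness floor*, the quantity the engine
anneals to drive the vague-to-crisp process.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .observations import Domain, ObservationSet

__all__ = [
    "ComponentState",
    "MixtureState",
    "FamilyError",
    "BERNOULLI_EPS",
    "clutter_likelihood",
    "blob_likelihood",
    "parabola_likelihood",
    "bernoulli_likelihood",
    "component_log_likelihood",
    "n_free_params",
    "m_step",
    "canonicalize_parabola",
]

BERNOULLI_EPS = 1e-6
PARABOLA_QUAD_NODES = 64


class FamilyError(ValueError):
    """Raised for invalid component parameters."""


@dataclass
class ComponentState:
    """One top-down model component.

    ``params`` is family-specific:

    - blob: ``mean`` (2,), ``cov`` (2, 2)
    - parabola: ``vertex`` (2,), ``curvature`` a >= 0, ``rotation`` in
      [0, 2pi), ``half_extent`` U > 0, ``sigma`` > 0
    - bernoulli: ``p`` (K,) in [eps, 1-eps]
    - clutter: {}

    ``r`` is the mixture weight ("proportion of signals m"); ``vagueness`` is
    the current variance floor (length^2 for geometric families, probability
    variance for bernoulli).  ``crisp_mask``, if set on a bernoulli component,
    marks feature indices exempt from the vagueness clamp (the crisp
    "language" block of a dual model).
    """

    id: int
    family: str
    params: dict
    r: float
    vagueness: float = 0.0
    starved: bool = False
    crisp_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("clutter", "blob", "parabola", "bernoulli"):
            raise FamilyError(f"unknown family {self.family!r}")
        if not 0.0 <= self.r <= 1.0 + 1e-12:
            raise FamilyError(f"component {self.id}: weight r={self.r} outside [0,1]")
        self.params = {
            k: (np.asarray(v, dtype=float) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
            for k, v in self.params.items()
        }
        self._validate()

    def _validate(self) -> None:
        p = self.params
        if self.family == "blob":
            cov = np.asarray(p["cov"], dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise FamilyError(f"component {self.id}: blob covariance not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise FamilyError(
                    f"component {self.id}: blob covariance not positive definite"
                )
        elif self.family == "parabola":
            if not p["sigma"] > 0:
                raise FamilyError(f"component {self.id}: parabola sigma must be > 0")
            if not p["half_extent"] > 0:
                raise FamilyError(f"component {self.id}: parabola half_extent must be > 0")
        elif self.family == "bernoulli":
            prob = np.asarray(p["p"], dtype=float)
            if np.any(prob < 0) or np.any(prob > 1):
                raise FamilyError(f"component {self.id}: bernoulli p outside [0,1]")

    def copy(self) -> "ComponentState":
        return copy.deepcopy(self)

    def to_record(self) -> dict:
        """JSON-serializable record (see schemas/component.schema.json)."""
        params = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.params.items()
        }
        return {
            "id": self.id,
            "family": self.family,
            "parameters": params,
            "r": self.r,
            "vagueness": self.vagueness,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ComponentState":
        return cls(
            id=rec["id"],
            family=rec["family"],
            params=rec["parameters"],
            r=rec["r"],
            vagueness=rec.get("vagueness", 0.0),
        )


@dataclass
class MixtureState:
    """The full set of top-down components plus domain geometry."""

    components: list[ComponentState]
    domain: Domain | None = None
    iteration: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        r_sum = sum(c.r for c in self.components)
        if self.components and abs(r_sum - 1.0) > 1e-9:
            raise FamilyError(f"mixture weights sum to {r_sum}, expected 1")
        if sum(c.family == "clutter" for c in self.components) > 1:
            raise FamilyError("at most one clutter component allowed")

    @property
    def M(self) -> int:
        return len(self.components)

    def copy(self) -> "MixtureState":
        return MixtureState(
            components=[c.copy() for c in self.components],
            domain=self.domain,
            iteration=self.iteration,
        )

    def clutter_index(self) -> int | None:
        for j, c in enumerate(self.components):
            if c.family == "clutter":
                return j
        return None

    def normalize_weights(self) -> None:
        total = sum(c.r for c in self.components)
        for c in self.components:
            c.r = c.r / total

    def to_records(self) -> list[dict]:
        return [c.to_record() for c in self.components]


# ---------------------------------------------------------------------------
# Likelihoods.  The log versions are the workhorses; the public linear-space
# functions are thin exponentials over them.

_LOG_2PI = np.log(2.0 * np.pi)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def parabola_curve(params: dict, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    local = np.stack([u, params["curvature"] * u * u], axis=-1)
    return local @ _rotation(params["rotation"]).T + np.asarray(params["vertex"])


def log_clutter(positions: np.ndarray, domain: Domain) -> np.ndarray:
    positions = np.atleast_2d(positions)
    if not domain.contains(positions).all():
        raise FamilyError("position outside the clutter domain")
    return np.full(len(positions), -np.log(domain.area))


def log_blob(positions: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    positions = np.atleast_2d(positions)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise FamilyError("singular blob covariance")
    d = positions - mean
    sol = np.linalg.solve(cov, d.T).T
    maha = np.einsum("ni,ni->n", d, sol)
    return -0.5 * (maha + logdet) - _LOG_2PI


@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of a (N,2) and b (G,2)."""
    return (
        (a * a).sum(axis=1)[:, None]
        - 2.0 * (a @ b.T)
        + (b * b).sum(axis=1)[None, :]
    )


def log_parabola(
    positions: np.ndarray, params: dict, n_nodes: int = PARABOLA_QUAD_NODES
) -> np.ndarray:
    """Log of the arc-averaged transverse Gaussian density.

    Quadrature: ``n_nodes`` Gauss-Legendre nodes on [-U, U]; the node count is
    part of the run provenance.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    U = float(params["half_extent"])
    sigma = float(params["sigma"])
    if sigma <= 0 or U <= 0:
        raise FamilyError("parabola sigma and half_extent must be positive")
    x, wq = _leggauss(n_nodes)
    nodes = parabola_curve(params, U * x)  # (Q, 2)
    d2 = _pairwise_sq_dists(positions, nodes)  # (N, Q)
    # log[(1/2U) * sum_q wq*U * g_sigma(d_q)]; stable weighted logsumexp
    log_g = (-0.5 / sigma**2) * d2
    peak = log_g.max(axis=1, keepdims=True)
    s = np.exp(log_g - peak) @ (0.5 * wq)
    return (
        peak[:, 0] + np.log(np.maximum(s, 1e-300)) - _LOG_2PI - np.log(sigma**2)
    )


def log_bernoulli(features: np.ndarray, p: np.ndarray) -> np.ndarray:
    features = np.atleast_2d(features)
    p = np.asarray(p, dtype=float)
    if features.shape[1] != p.shape[0]:
        raise FamilyError(
            f"feature dimension {features.shape[1]} != parameter dimension {p.shape[0]}"
        )
    pc = np.clip(p, BERNOULLI_EPS, 1.0 - BERNOULLI_EPS)
    return features @ np.log(pc) + (1.0 - features) @ np.log1p(-pc)


def clutter_likelihood(position, domain: Domain) -> float | np.ndarray:
    """Uniform background density 1/area(domain)."""
    out = np.exp(log_clutter(position, domain))
    return float(out[0]) if np.ndim(position) == 1 else out


def blob_likelihood(position, mean, cov) -> float | np.ndarray:
    """Bivariate Gaussian density."""
    out = np.exp(log_blob(position, mean, cov))
    return float(out[0]) if np.ndim(position) == 1 else out


def parabola_likelihood(position, params: dict, n_nodes: int = PARABOLA_QUAD_NODES):
    """Arc-averaged transverse Gaussian density of a parabolic component."""
    out = np.exp(log_parabola(position, params, n_nodes))
    return float(out[0]) if np.ndim(position) == 1 else out


def bernoulli_likelihood(feature_vector, p) -> float | np.ndarray:
    """Product Bernoulli probability, computed in log space."""
    out = np.exp(log_bernoulli(feature_vector, p))
    return float(out[0]) if np.ndim(feature_vector) == 1 else out


def component_log_likelihood(comp: ComponentState, obs: ObservationSet) -> np.ndarray:
    """Dispatch l(n|m) in log space for all observations."""
    if comp.family == "clutter":
        return log_clutter(obs.positions, obs.domain)
    if comp.family == "blob":
        return log_blob(obs.positions, comp.params["mean"], comp.params["cov"])
    if comp.family == "parabola":
        return log_parabola(obs.positions, comp.params)
    return log_bernoulli(obs.features, comp.params["p"])


def n_free_params(comp: ComponentState) -> int:
    """Free parameters per component, excluding the mixture weight."""
    if comp.family == "clutter":
        return 0
    if comp.family == "blob":
        return 5  # mean (2) + symmetric covariance (3)
    if comp.family == "parabola":
        return 6  # vertex (2) + curvature + rotation + half_extent + sigma
    return int(np.asarray(comp.params["p"]).shape[0])


# ---------------------------------------------------------------------------
# M-steps


def canonicalize_parabola(params: dict) -> dict:
    """Resolve the (curvature, rotation) identifiability: a >= 0, rotation in
    [0, 2pi).  (a, rot) and (-a, rot + pi) describe the same curve."""
    a = float(params["curvature"])
    rot = float(params["rotation"])
    if a < 0:
        a, rot = -a, rot + np.pi
    rot = rot % (2.0 * np.pi)
    out = dict(params)
    out["curvature"] = a
    out["rotation"] = rot
    return out


def _clamp_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _bernoulli_clamp(p: np.ndarray, floor: float, crisp_mask=None) -> np.ndarray:
    """Clamp p so the per-feature variance p(1-p) stays above ``floor`` (and
    inside [eps, 1-eps]); crisp features are exempt from the variance floor."""
    p = np.clip(p, BERNOULLI_EPS, 1.0 - BERNOULLI_EPS)
    if floor <= BERNOULLI_EPS * (1.0 - BERNOULLI_EPS):
        return p
    half_width = np.sqrt(max(0.25 - floor, 0.0))
    lo, hi = 0.5 - half_width, 0.5 + half_width
    clamped = np.clip(p, lo, hi)
    if crisp_mask is not None:
        clamped = np.where(crisp_mask, p, clamped)
    return clamped


def _nearest_u(positions: np.ndarray, params: dict, n_grid: int = 65) -> np.ndarray:
    """Nearest-curve-point arc parameter for every position.

    Dense-grid argmin followed by two Newton steps on the squared distance,
    so points lying exactly on the curve resolve to their true parameter to
    machine precision."""
    U = float(params["half_extent"])
    a = float(params["curvature"])
    R = _rotation(float(params["rotation"]))
    grid = np.linspace(-U, U, n_grid)
    pts = parabola_curve(params, grid)  # (G, 2)
    d2 = _pairwise_sq_dists(positions, pts)
    u = grid[np.argmin(d2, axis=1)]
    cpp = R @ np.array([0.0, 2.0 * a])  # curve second derivative (constant)
    for _ in range(2):
        c = parabola_curve(params, u)
        cp = np.stack([np.ones_like(u), 2.0 * a * u], axis=-1) @ R.T
        d = positions - c
        grad = -2.0 * np.einsum("ni,ni->n", d, cp)
        hess = 2.0 * (np.einsum("ni,ni->n", cp, cp) - d @ cpp)
        step = np.where(hess > 1e-12, grad / np.maximum(hess, 1e-12), 0.0)
        u = np.clip(u - step, -U, U)
    return u


def _parabola_q(positions, wf, params) -> float:
    """Responsibility-weighted expected log-likelihood of a parabola."""
    return float(wf @ log_parabola(positions, params))


def _parabola_m_step(
    comp: ComponentState,
    obs: ObservationSet,
    wf: np.ndarray,
    dt: float,
    loglik: np.ndarray | None = None,
) -> ComponentState:
    """One damped Gauss-Newton step on (vertex, curvature, rotation) from
    nearest-curve-point residuals, then re-estimation of half_extent and sigma
    from the weighted arc-parameter spread and transverse residual sd.

    The step is accepted only if the weighted expected log-likelihood does not
    decrease; on decrease the step is halved (up to 8 times), else no update.
    """
    params = dict(comp.params)
    pos = obs.positions
    sw = wf.sum()
    floor_sd = np.sqrt(max(comp.vagueness, 0.0))
    if loglik is not None:
        q0 = float(wf @ np.nan_to_num(loglik, neginf=-1e30))
    else:
        q0 = _parabola_q(pos, wf, params)

    u = _nearest_u(pos, params)
    c = parabola_curve(params, u)
    e = pos - c  # (N, 2) residuals
    a, rot = params["curvature"], params["rotation"]
    R = _rotation(rot)
    dR = np.array(
        [[-np.sin(rot), -np.cos(rot)], [np.cos(rot), -np.sin(rot)]]
    )
    N = len(pos)
    J = np.zeros((N, 2, 4))
    J[:, 0, 0] = 1.0  # d c / d vertex_x
    J[:, 1, 1] = 1.0  # d c / d vertex_y
    J[:, :, 2] = np.stack([u * 0.0, u * u], axis=-1) @ R.T  # d c / d a
    J[:, :, 3] = np.stack([u, a * u * u], axis=-1) @ dR.T  # d c / d rotation
    sq = np.sqrt(np.maximum(wf, 0.0))
    A = (J * sq[:, None, None]).reshape(2 * N, 4)
    b = (e * sq[:, None]).reshape(2 * N)
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)

    theta0 = np.array([params["vertex"][0], params["vertex"][1], a, rot])

    def rebuilt(step: float) -> dict:
        th = theta0 + step * delta
        cand = dict(params)
        cand["vertex"] = np.array([th[0], th[1]])
        cand["curvature"] = float(th[2])
        cand["rotation"] = float(th[3])
        # re-estimate extent and transverse scale under the moved curve
        u2 = _nearest_u(pos, cand)
        rms_u = np.sqrt(max(float(wf @ (u2 * u2)) / sw, 1e-12))
        U_em = np.sqrt(3.0) * rms_u  # uniform[-U, U] has rms U/sqrt(3)
        # nearest-point residuals are transverse (the along-curve component is
        # absorbed by u), so they carry one Gaussian dof, not two
        e2 = pos - parabola_curve(cand, u2)
        sigma_em = np.sqrt(max(float(wf @ (e2 * e2).sum(axis=1)) / sw, 0.0))
        U_new = max(params["half_extent"] + dt * (U_em - params["half_extent"]), 1e-6)
        # arcs of interest span at most about a third of the scene: without a
        # cap a parabola can stretch into a second background model
        if obs.domain is not None:
            U_new = min(U_new, 0.35 * obs.domain.scale)
        cand["half_extent"] = float(U_new)
        sigma_new = params["sigma"] + dt * (sigma_em - params["sigma"])
        cand["sigma"] = float(max(sigma_new, floor_sd, 1e-6))
        return canonicalize_parabola(cand)

    step = dt
    for _ in range(9):  # initial step + up to 8 halvings
        cand = rebuilt(step)
        if _parabola_q(pos, wf, cand) >= q0 - 1e-12:
            return replace(comp, params=cand, starved=False)
        step *= 0.5
    # geometry rejected; retry scale-only update (step 0), else keep everything
    cand = rebuilt(0.0)
    if _parabola_q(pos, wf, cand) >= q0 - 1e-12:
        return replace(comp, params=cand, starved=False)
    return replace(comp, params=canonicalize_parabola(params), starved=False)


def m_step(
    comp: ComponentState,
    obs: ObservationSet,
    responsibilities: np.ndarray,
    dt: float = 1.0,
    loglik: np.ndarray | None = None,
) -> ComponentState:
    """Damped EM update of one component.

    ``responsibilities`` are f(m|n) for this component; observation weights
    are taken from ``obs``.  With dt = 1 the update is an exact EM M-step.
    A component whose responsibility mass is zero is returned unchanged with
    ``starved=True`` — the signal consumed by structural adaptation.
    ``loglik``, when provided, is this component's current per-observation
    log-likelihood (reused to avoid recomputation in the parabola step).
    """
    if not 0.0 < dt <= 1.0:
        raise FamilyError(f"dt must be in (0, 1], got {dt}")
    f = np.asarray(responsibilities, dtype=float)
    if np.any(f < -1e-12) or np.any(f > 1.0 + 1e-12):
        raise FamilyError("responsibilities must lie in [0, 1]")
    wf = obs.weights * f
    sw = float(wf.sum())
    if comp.family == "clutter":
        return replace(comp, starved=False)
    if sw <= 0.0:
        return replace(comp, starved=True)

    if comp.family == "bernoulli":
        p_em = (wf @ obs.features) / sw
        p_old = np.asarray(comp.params["p"], dtype=float)
        p_new = p_old + dt * (p_em - p_old)
        p_new = _bernoulli_clamp(p_new, comp.vagueness, comp.crisp_mask)
        return replace(comp, params={"p": p_new}, starved=False)

    if comp.family == "blob":
        mean_em = (wf @ obs.positions) / sw
        d = obs.positions - mean_em
        cov_em = (d * wf[:, None]).T @ d / sw
        mean_old = np.asarray(comp.params["mean"], dtype=float)
        cov_old = np.asarray(comp.params["cov"], dtype=float)
        mean_new = mean_old + dt * (mean_em - mean_old)
        cov_new = cov_old + dt * (cov_em - cov_old)
        cov_new = _clamp_cov(cov_new, max(comp.vagueness, 1e-9))
        return replace(
            comp, params={"mean": mean_new, "cov": cov_new}, starved=False
        )

    return _parabola_m_step(comp, obs, wf, dt, loglik)
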