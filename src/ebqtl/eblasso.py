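"""Empirical-Bayes Lasso solver.

The model is a sparse Bayesian linear regression with a three-level
hierarchical shrinkage prior: normal coefficients with per-effect
variances ``v_j = sigma2_j``, independent exponential priors on the
variances with common rate ``lambda``, and a Gamma(a, b) hyperprior on
``lambda``.  Inference maximizes the exponential-penalized marginal
likelihood over the variances by cyclic coordinate ascent, with the
noise variance ``sigma2_e`` and ``lambda`` refreshed once per sweep.

Per-coordinate objective in ``v >= 0`` for a candidate column with
sparsity factor ``s`` and quality factor ``q``::

    l(v) = -1/2 log(1 + v s) + 1/2 q^2 v / (1 + v s) - lambda v

The closed-form maximizer is zero iff ``q^2 <= s + 2 lambda``; otherwise
``v* = (u - 1)/s`` where ``u`` is the positive root of
``lambda u^2 + s u / 2 - q^2 / 2 = 0`` (or ``u = q^2/s`` at lambda = 0,
the relevance-vector-machine limit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, stats

from .design import (ColumnMaterializer, DesignSpec, EffectDescriptor,
                     descriptor_to_index, index_to_descriptor)
from .maps import GenotypeMatrix, PhenotypeVector

logger = logging.getLogger(__name__)

LAMBDA_FLOOR = 1e-10
#: relative floor on sigma2_e (times var(y)) against degenerate inputs
NOISE_FLOOR_REL = 1e-10


@dataclass(frozen=True)
class PriorSpec:
    """Gamma(a, b) hyperprior on the exponential rate lambda.

    ``a`` may be negative (improper prior); ``b`` must be positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("b must be > 0")


@dataclass
class FitControls:
    tol: float = 1e-4
    max_sweeps: int = 50
    block_size: int = 4096
    seed: Optional[int] = None
    track_objective: bool = True
    max_active_warn: Optional[int] = None  # defaults to n
    #: initial exponential rate; None uses the posterior-mode formula at
    #: the empty state, (a - 1)/b floored
    lambda_init: Optional[float] = None
    #: admission gate on q^2/s for inactive columns, calibrated to the
    #: candidate multiplicity (None: auto at one expected pure-noise
    #: admission among k candidates; 0 disables).  Without it the
    #: posterior-mode lambda admits noise wholesale on k >> n designs
    #: and the noise variance collapses.
    admission_zsq: Optional[float] = None
    #: after convergence, re-optimize each active effect over columns
    #: whose bins lie within this many positions of the current ones
    #: (same family); 0 disables.  Greedy sweeps lock in slightly
    #: mislocalized columns on strongly correlated maps; this local
    #: exchange move repairs them.
    polish_radius: int = 8


@dataclass
class SQFactors:
    """Sparsity/quality factors of one candidate column, own-contribution
    removed from the marginal covariance."""

    s: float
    q: float


@dataclass
class EBlassoFit:
    """Sparse posterior summary returned by :func:`fit`."""

    active: list[tuple[EffectDescriptor, float]]  # (descriptor, sigma2_j)
    active_idx: np.ndarray                        # linear column indices
    beta_hat: np.ndarray
    Sigma: np.ndarray
    mu: float
    sigma2_e: float
    lam: float
    prior: PriorSpec
    objective_trace: list[float] = field(default_factory=list)
    trace_sweeps: list[int] = field(default_factory=list)
    converged: bool = False
    n_sweeps: int = 0
    spec: Optional[DesignSpec] = None

    @property
    def n_active(self) -> int:
        return len(self.active)


def coordinate_update(s: float, q: float, lam: float) -> float:
    """Unique maximizer of the per-coordinate objective over v >= 0."""
    if s <= 0:
        raise ValueError(f"degenerate column reached the solver (s={s})")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    q2 = q * q
    if q2 <= s + 2.0 * lam:
        return 0.0
    if lam == 0.0:
        return (q2 - s) / (s * s)
    u = (-0.5 * s + math.sqrt(0.25 * s * s + 2.0 * lam * q2)) / (2.0 * lam)
    return max((u - 1.0) / s, 0.0)


def _posterior(XtX: np.ndarray, Xty: np.ndarray, sigma2: np.ndarray,
               sigma2_e: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior (Sigma, beta) and Cholesky of the precision matrix."""
    A = XtX / sigma2_e + np.diag(1.0 / sigma2)
    try:
        cho = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "active-set system is not positive definite; remove collinear "
            "effects or restart with stronger shrinkage") from exc
    Sigma = linalg.cho_solve(cho, np.eye(A.shape[0]))
    beta = linalg.cho_solve(cho, Xty) / sigma2_e
    return Sigma, beta, cho[0]


def posterior_summary(X_active: np.ndarray, y_centered: np.ndarray,
                      sigma2: Sequence[float],
                      sigma2_e: float) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the active coefficients.

    ``Sigma = (X'X/sigma2_e + diag(1/sigma2_j))^-1`` and
    ``beta = Sigma X'y / sigma2_e``.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if X_active.shape[1] != sigma2.size:
        raise ValueError("sigma2 length must match active columns")
    Sigma, beta, _ = _posterior(X_active.T @ X_active,
                                X_active.T @ y_centered, sigma2, sigma2_e)
    return beta, Sigma


def compute_sq(x: np.ndarray, X_active: np.ndarray,
               sigma2: Sequence[float], sigma2_e: float,
               y_centered: np.ndarray,
               active_position: Optional[int] = None) -> SQFactors:
    """Sparsity/quality factors of one candidate column.

    Uses the Woodbury identity through the active-set posterior; if the
    column is itself active (``active_position`` given), its own
    contribution is removed so the factors describe the leave-that-
    column-out covariance.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    M = sigma2.size
    if M == 0:
        S = float(x @ x) / sigma2_e
        Q = float(x @ y_centered) / sigma2_e
    else:
        _, beta, cho = _posterior(X_active.T @ X_active,
                                  X_active.T @ y_centered, sigma2, sigma2_e)
        g = X_active.T @ x
        w = linalg.solve_triangular(cho, g, lower=True)
        S = (float(x @ x) - float(w @ w) / sigma2_e) / sigma2_e
        resid = y_centered - X_active @ beta
        Q = float(x @ resid) / sigma2_e
    if active_position is not None:
        v = float(sigma2[active_position])
        denom = 1.0 - v * S
        if denom <= 1e-12:
            denom = 1e-12
        S, Q = S / denom, Q / denom
    return SQFactors(s=S, q=Q)


def update_noise_variance(resid: np.ndarray, n: int, Sigma: np.ndarray,
                          sigma2: np.ndarray, var_y: float) -> float:
    """Stationary-point refresh of the residual variance.

    ``sigma2_e = ||resid||^2 / (n - M + sum_j Sigma_jj / sigma2_j)``,
    falling back to ``||resid||^2 / n`` on a non-positive denominator and
    floored at ``NOISE_FLOOR_REL * var_y``.
    """
    rss = float(resid @ resid)
    M = sigma2.size
    if M == 0:
        denom = float(n)
    else:
        denom = n - M + float(np.sum(np.diag(Sigma) / sigma2))
        if denom <= 0:
            logger.warning("noise-variance denominator <= 0; falling back "
                           "to ||resid||^2 / n")
            denom = float(n)
    return max(rss / denom, NOISE_FLOOR_REL * var_y, np.finfo(float).tiny)


def update_lambda(n_active: int, sigma2_sum: float, prior: PriorSpec) -> float:
    """Posterior-mode refresh of the exponential rate.

    Counts only active effects: ``lambda = (M + a - 1)/(sum sigma2_j + b)``
    floored at ``LAMBDA_FLOOR``.
    """
    return max(LAMBDA_FLOOR,
               (n_active + prior.a - 1.0) / (sigma2_sum + prior.b))


class _ActiveSet:
    """Bookkeeping for the active columns during a fit."""

    def __init__(self, n: int):
        self.idx: list[int] = []
        self.sigma2: list[float] = []
        self.X = np.empty((n, 0))
        self.pos: dict[int, int] = {}
        # posterior cache
        self.Sigma = np.empty((0, 0))
        self.beta = np.empty(0)
        self.cho: Optional[np.ndarray] = None
        self.resid: Optional[np.ndarray] = None

    @property
    def M(self) -> int:
        return len(self.idx)

    def add(self, lin_idx: int, x: np.ndarray, v: float) -> None:
        self.pos[lin_idx] = self.M
        self.idx.append(lin_idx)
        self.sigma2.append(v)
        self.X = np.column_stack([self.X, x])

    def remove(self, lin_idx: int) -> None:
        p = self.pos.pop(lin_idx)
        self.idx.pop(p)
        self.sigma2.pop(p)
        self.X = np.delete(self.X, p, axis=1)
        for k2, p2 in self.pos.items():
            if p2 > p:
                self.pos[k2] = p2 - 1

    def refresh(self, y_centered: np.ndarray, sigma2_e: float) -> None:
        if self.M == 0:
            self.Sigma = np.empty((0, 0))
            self.beta = np.empty(0)
            self.cho = None
            self.resid = y_centered.copy()
            return
        sig = np.asarray(self.sigma2)
        self.Sigma, self.beta, self.cho = _posterior(
            self.X.T @ self.X, self.X.T @ y_centered, sig, sigma2_e)
        self.resid = y_centered - self.X @ self.beta


def penalized_marginal_loglik(active: _ActiveSet, y_centered: np.ndarray,
                              sigma2_e: float, lam: float) -> float:
    """log N(y | 0, C) - lambda * sum(v_j), C = s2e I + X diag(v) X'.

    Additive constants (including the per-column log lambda of the
    exponential prior, whose count is fixed at k) are dropped.
    """
    n = y_centered.size
    if active.M == 0:
        logdet_c = n * math.log(sigma2_e)
        quad = float(y_centered @ y_centered) / sigma2_e
        pen = 0.0
    else:
        sig = np.asarray(active.sigma2)
        # |C| = s2e^n * prod(v) * |A|, A the posterior precision
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(active.cho))))
        logdet_c = n * math.log(sigma2_e) + float(np.sum(np.log(sig))) + logdet_a
        quad = (float(y_centered @ y_centered)
                - float((active.X.T @ y_centered) @ active.beta)) / sigma2_e
        pen = lam * float(np.sum(sig))
    return -0.5 * (logdet_c + quad) - pen


def _batch_sq(Xb: np.ndarray, active: _ActiveSet,
              sigma2_e: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized S, Q for a block of candidate columns at current state."""
    colsq = np.einsum("ij,ij->j", Xb, Xb)
    if active.M == 0:
        S = colsq / sigma2_e
        Q = (Xb.T @ active.resid) / sigma2_e
    else:
        Gm = active.X.T @ Xb
        S = (colsq - np.einsum("ij,ij->j", Gm, active.Sigma @ Gm) / sigma2_e) \
            / sigma2_e
        Q = (Xb.T @ active.resid) / sigma2_e
    return S, Q


def _neighbor_columns(desc: EffectDescriptor, m: int, radius: int,
                      include_interactions: bool) -> list[int]:
    """Linear indices of same-family columns with one bin moved <= radius."""
    out = []
    if desc.is_main:
        for i2 in range(max(1, desc.i - radius),
                        min(m, desc.i + radius) + 1):
            if i2 != desc.i:
                out.append(descriptor_to_index(
                    EffectDescriptor(desc.family, i2, i2), m,
                    include_interactions))
        return out
    for i2 in range(max(1, desc.i - radius), min(m, desc.i + radius) + 1):
        if i2 != desc.i and i2 < desc.j:
            out.append(descriptor_to_index(
                EffectDescriptor(desc.family, i2, desc.j), m,
                include_interactions))
    for j2 in range(max(1, desc.j - radius), min(m, desc.j + radius) + 1):
        if j2 != desc.j and desc.i < j2:
            out.append(descriptor_to_index(
                EffectDescriptor(desc.family, desc.i, j2), m,
                include_interactions))
    return out


def _coord_obj(s: float, q: float, lam: float, v: float) -> float:
    return (-0.5 * math.log1p(v * s) + 0.5 * q * q * v / (1.0 + v * s)
            - lam * v)


def _polish(act: _ActiveSet, mat: ColumnMaterializer, spec: DesignSpec,
            yc: np.ndarray, sigma2_e: float, lam: float,
            radius: int, max_passes: int = 3) -> int:
    """Local exchange refinement of the active set at fixed hyperparameters.

    Each active effect is re-optimized against same-family columns whose
    bins lie within ``radius`` positions; the column maximizing the
    per-coordinate penalized likelihood (computed leave-that-effect-out)
    replaces it when strictly better.  Returns the number of swaps.
    """
    n_swaps = 0
    for _ in range(max_passes):
        changed = False
        for lin in list(act.idx):
            desc = index_to_descriptor(lin, spec.m, spec.include_interactions)
            cands = [c for c in _neighbor_columns(desc, spec.m, radius,
                                                  spec.include_interactions)
                     if c not in act.pos and c not in spec.excluded_columns]
            if not cands:
                continue
            p = act.pos[lin]
            x_cur = act.X[:, p].copy()
            act.remove(lin)
            act.refresh(yc, sigma2_e)
            f = compute_sq(x_cur, act.X, act.sigma2, sigma2_e, yc)
            v_cur = coordinate_update(f.s, f.q, lam) if f.s > 0 else 0.0
            best = (lin, x_cur, v_cur,
                    _coord_obj(f.s, f.q, lam, v_cur) if f.s > 0 else 0.0)
            for c_lin in cands:
                x = mat.column(c_lin)
                f = compute_sq(x, act.X, act.sigma2, sigma2_e, yc)
                if f.s <= 0:
                    continue
                v = coordinate_update(f.s, f.q, lam)
                if v <= 0:
                    continue
                obj = _coord_obj(f.s, f.q, lam, v)
                if obj > best[3] + 1e-10:
                    best = (c_lin, x, v, obj)
            if best[2] > 0:
                act.add(best[0], best[1], best[2])
            act.refresh(yc, sigma2_e)
            if best[0] != lin or best[2] <= 0:
                changed = True
                n_swaps += 1
        if not changed:
            break
    return n_swaps


def fit(G: GenotypeMatrix, y: PhenotypeVector, spec: DesignSpec,
        prior: PriorSpec, controls: Optional[FitControls] = None) -> EBlassoFit:
    """Cyclic coordinate-ascent fit of the sparse shrinkage regression.

    Sweeps run over every candidate column in layout order, in blocks;
    each column receives the closed-form coordinate update (add when the
    maximizer is positive and the column inactive, update when active,
    delete when the maximizer hits zero).  ``sigma2_e`` and ``lambda``
    are refreshed once per sweep.  Convergence requires one full sweep
    with stable membership and a maximal relative variance change below
    ``tol``.
    """
    if controls is None:
        controls = FitControls()
    yv = np.asarray(y.values, dtype=float)
    n = yv.size
    if n != G.n:
        raise ValueError("phenotype / genotype size mismatch")
    mu = float(yv.mean())
    yc = yv - mu
    var_y = float(yc @ yc) / n if n else 0.0
    if var_y <= 0:
        raise ValueError("phenotype has zero variance")
    sigma2_e = var_y
    act = _ActiveSet(n)
    act.refresh(yc, sigma2_e)

    mat = ColumnMaterializer(G, spec.include_interactions)
    if spec.excluded_columns:
        keep = np.setdiff1d(np.arange(spec.k),
                            np.fromiter(spec.excluded_columns, dtype=np.int64))
    else:
        keep = np.arange(spec.k)

    # admission gate: a pure-noise column has q^2/s ~ chi^2(1), so
    # requiring q^2/s above the 1/(2k) normal tail quantile squared keeps
    # the expected number of false admissions among k candidates near one
    if controls.admission_zsq is None:
        zsq_gate = float(stats.norm.isf(0.5 / max(keep.size, 2)) ** 2)
    else:
        zsq_gate = max(controls.admission_zsq, 0.0)

    if controls.lambda_init is not None:
        lam = max(controls.lambda_init, LAMBDA_FLOOR)
    else:
        lam = update_lambda(0, 0.0, prior)

    trace: list[float] = []
    trace_sweeps: list[int] = []
    converged = False
    max_active_warn = controls.max_active_warn or n
    sweep = 0
    for sweep in range(1, controls.max_sweeps + 1):
        membership_changed = False
        max_rel_change = 0.0
        n_changes = 0
        for lo in range(0, keep.size, controls.block_size):
            idx_chunk = keep[lo:lo + controls.block_size]
            Xb = mat.columns(idx_chunk)
            S, Q = _batch_sq(Xb, act, sigma2_e)
            for t in range(idx_chunk.size):
                jlin = int(idx_chunk[t])
                Sj, Qj = float(S[t]), float(Q[t])
                p = act.pos.get(jlin)
                if p is not None:
                    v_old = act.sigma2[p]
                    denom = 1.0 - v_old * Sj
                    if denom <= 1e-12:
                        denom = 1e-12
                    s, q = Sj / denom, Qj / denom
                else:
                    v_old = 0.0
                    s, q = Sj, Qj
                if s <= 0.0:
                    # numerically degenerate under current posterior; skip
                    continue
                v_new = coordinate_update(s, q, lam)
                if p is not None:
                    if v_new <= 0.0:
                        changed = True
                    else:
                        rel = abs(v_new - v_old) / v_old
                        max_rel_change = max(max_rel_change, rel)
                        changed = rel >= 1e-12
                elif v_new > 0.0:
                    changed = q * q > s * zsq_gate
                else:
                    changed = False
                if not changed:
                    continue
                x_l = Xb[:, t]
                # exact rank-one refresh of the cached S/Q for the rest of
                # the block: C_new = C + dv * x_l x_l', via b = C^-1 x_l
                if act.M == 0:
                    b_vec = x_l / sigma2_e
                else:
                    b_vec = (x_l - act.X @ (act.Sigma @ (act.X.T @ x_l))
                             / sigma2_e) / sigma2_e
                S_l = float(x_l @ b_vec)
                Q_l = float(b_vec @ yc)
                dv = v_new - v_old
                ro_denom = 1.0 + dv * S_l
                if t + 1 < idx_chunk.size and abs(ro_denom) > 1e-300:
                    c = Xb[:, t + 1:].T @ b_vec
                    S[t + 1:] -= dv * c * c / ro_denom
                    Q[t + 1:] -= dv * c * Q_l / ro_denom
                # apply the membership / variance change
                if p is not None and v_new <= 0.0:
                    act.remove(jlin)
                    membership_changed = True
                elif p is not None:
                    act.sigma2[p] = v_new
                else:
                    act.add(jlin, x_l, v_new)
                    membership_changed = True
                act.refresh(yc, sigma2_e)
                n_changes += 1
                if controls.track_objective:
                    trace.append(penalized_marginal_loglik(
                        act, yc, sigma2_e, lam))
                    trace_sweeps.append(sweep)
        if act.M > max_active_warn:
            logger.warning("active set size %d exceeds %d (n)", act.M,
                           max_active_warn)
        # per-sweep hyperparameter refreshes
        sig = np.asarray(act.sigma2)
        sigma2_e = update_noise_variance(act.resid, n, act.Sigma, sig, var_y)
        lam = update_lambda(act.M, float(sig.sum()), prior)
        act.refresh(yc, sigma2_e)
        logger.debug("sweep %d: M=%d changes=%d max_rel=%.3g sigma2_e=%.4g "
                     "lambda=%.4g", sweep, act.M, n_changes, max_rel_change,
                     sigma2_e, lam)
        if not membership_changed and max_rel_change < controls.tol:
            converged = True
            break
    if not converged:
        logger.warning("fit did not converge in %d sweeps", controls.max_sweeps)

    if controls.polish_radius > 0 and act.M > 0:
        n_swaps = _polish(act, mat, spec, yc, sigma2_e, lam,
                          controls.polish_radius)
        if n_swaps:
            logger.debug("polish: %d local exchange(s)", n_swaps)
            sig = np.asarray(act.sigma2)
            sigma2_e = update_noise_variance(act.resid, n, act.Sigma, sig,
                                             var_y)
            lam = update_lambda(act.M, float(sig.sum()), prior)
            act.refresh(yc, sigma2_e)

    descriptors = [index_to_descriptor(j, spec.m, spec.include_interactions)
                   for j in act.idx]
    return EBlassoFit(
        active=list(zip(descriptors, [float(v) for v in act.sigma2])),
        active_idx=np.asarray(act.idx, dtype=np.int64),
        beta_hat=act.beta.copy(),
        Sigma=act.Sigma.copy(),
        mu=mu,
        sigma2_e=float(sigma2_e),
        lam=float(lam),
        prior=prior,
        objective_trace=trace,
        trace_sweeps=trace_sweeps,
        converged=converged,
        n_sweeps=sweep,
        spec=spec,
    )


def predict(fit_result: EBlassoFit, G: GenotypeMatrix) -> np.ndarray:
    """Predicted phenotypes for (possibly new) individuals."""
    spec = fit_result.spec
    if spec is None:
        raise ValueError("fit carries no design spec")
    if fit_result.n_active == 0:
        return np.full(G.n, fit_result.mu)
    mat = ColumnMaterializer(G, spec.include_interactions)
    X = mat.columns(fit_result.active_idx)
    return fit_result.mu + X @ fit_result.beta_hat
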