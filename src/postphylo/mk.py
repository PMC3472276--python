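"""Binary-trait Markov (Mk) likelihood, model fitting and ancestral states.

A binary character (here: habitat, 0 = soft bottom, 1 = hard bottom)
evolves along a chronogram under a 2-state continuous-time Markov chain
with rates ``q01`` (0 to 1) and ``q10`` (1 to 0) per unit branch time.
Two model classes are supported: ER (equal rates, ``q01 == q10``, one
free parameter) and ARD (all rates different, two free parameters),
compared by a likelihood-ratio test against a chi-square with one
degree of freedom, and by AIC.

The likelihood is Felsenstein's pruning algorithm with the binary
closed-form transition kernel; ancestral states are marginal posteriors
from a standard down/up (inside/outside) pass.  A vectorised batch path
(:func:`mk_loglik_batch`, :func:`fit_mk_batch`) evaluates many trait
replicates on one fixed tree simultaneously, which is what makes
simulation studies (rate recovery, LRT null calibration) cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .tree import Chronogram, TreeError

__all__ = [
    "MkModel",
    "transition_matrix",
    "mk_loglik",
    "mk_loglik_batch",
    "fit_mk",
    "fit_mk_batch",
    "lrt_pvalue",
    "aic",
    "marginal_ancestral_states",
    "read_trait_table",
    "write_ancestral_table",
]

RATE_LO = 1e-8
RATE_HI = 1e3

ModelClass = Literal["ER", "ARD"]


@dataclass(frozen=True)
class MkModel:
    """2-state Markov model: rates per unit branch time plus a root prior.

    ``root_prior`` is either a probability pair for states (0, 1) or the
    string ``"stationary"`` meaning ``(q10, q01) / (q01 + q10)``.
    """

    q01: float
    q10: float
    model_class: ModelClass = "ARD"
    root_prior: tuple[float, float] | str = (0.5, 0.5)

    def __post_init__(self):
        for q in (self.q01, self.q10):
            if not math.isfinite(q) or q < 0:
                raise ValueError(f"rates must be finite and >= 0, got {q}")
        if self.model_class == "ER" and self.q01 != self.q10:
            raise ValueError("ER model requires q01 == q10")
        if self.model_class not in ("ER", "ARD"):
            raise ValueError(f"unknown model class {self.model_class!r}")
        if isinstance(self.root_prior, str):
            if self.root_prior != "stationary":
                raise ValueError(f"unknown root prior {self.root_prior!r}")
        else:
            p = self.root_prior
            if len(p) != 2 or abs(p[0] + p[1] - 1.0) > 1e-12 or min(p) < 0:
                raise ValueError(f"root prior must sum to 1, got {p}")

    def prior_vector(self) -> np.ndarray:
        if self.root_prior == "stationary":
            s = self.q01 + self.q10
            if s == 0.0:
                return np.array([0.5, 0.5])
            return np.array([self.q10 / s, self.q01 / s])
        return np.asarray(self.root_prior, dtype=float)


def transition_matrix(model: MkModel, t: float) -> np.ndarray:
    """``P(t) = exp(Qt)`` for the binary chain, in closed form."""
    if t < 0:
        raise ValueError(f"branch duration must be >= 0, got {t}")
    q01, q10 = model.q01, model.q10
    s = q01 + q10
    if s == 0.0:
        return np.eye(2)
    e = math.exp(-s * t)
    p0 = q10 / s  # stationary mass on state 0
    p1 = q01 / s
    return np.array(
        [[p0 + p1 * e, p1 * (1.0 - e)],
         [p0 * (1.0 - e), p1 + p0 * e]]
    )


# ----------------------------------------------------------------------
# tree preparation shared by scalar and batch paths


class _Pruner:
    """Flattened postorder traversal of a bifurcating chronogram."""

    def __init__(self, chrono: Chronogram):
        chrono.require_bifurcating()
        self.chrono = chrono
        self.tip_order = [n.label for n in chrono.tips]
        self.tip_slot = {lab: i for i, lab in enumerate(self.tip_order)}
        n_nodes = len(chrono.nodes)
        self.n_nodes = n_nodes
        self.n_tips = len(self.tip_order)
        # postorder internal nodes with child node-indices and durations
        self.internal: list[tuple[int, int, int, float, float]] = []
        self.node_is_tip = np.zeros(n_nodes, dtype=bool)
        self.tip_of_node = np.full(n_nodes, -1, dtype=int)
        for node in chrono.postorder():
            if node.is_tip:
                self.node_is_tip[node.index] = True
                self.tip_of_node[node.index] = self.tip_slot[node.label]
            else:
                l, r = node.children
                self.internal.append(
                    (node.index, l.index, r.index,
                     node.age - l.age, node.age - r.age)
                )
        self.root_index = chrono.root.index

    def tip_state_matrix(self, traits: np.ndarray) -> np.ndarray:
        """(R, n_tips) integer states -> (R, n_tips, 2) indicator partials."""
        R = traits.shape[0]
        L = np.zeros((R, self.n_tips, 2))
        L[..., 0] = traits == 0
        L[..., 1] = traits == 1
        return L


def _traits_to_matrix(pruner: _Pruner, trait: Mapping[str, int]) -> np.ndarray:
    missing = [lab for lab in pruner.tip_order if lab not in trait]
    if missing:
        raise TreeError("missing tip state(s): " + ", ".join(sorted(missing)))
    states = np.array([trait[lab] for lab in pruner.tip_order])
    if not np.isin(states, (0, 1)).all():
        bad = sorted(set(int(s) for s in states) - {0, 1})
        raise ValueError(f"binary trait states must be 0 or 1, found {bad}")
    return states[None, :]


def _branch_probs(q01: np.ndarray, q10: np.ndarray, t: float):
    """Closed-form kernel entries for one branch, vectorised over rates."""
    s = q01 + q10
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.exp(-s * t)
        p0 = np.where(s > 0, q10 / np.where(s > 0, s, 1.0), 0.5)
    p1 = 1.0 - p0
    # rows of P(t): [p0 + p1 e, p1(1-e)], [p0(1-e), p1 + p0 e]
    return p0 + p1 * e, p1 * (1.0 - e), p0 * (1.0 - e), p1 + p0 * e


def _loglik_core(
    pruner: _Pruner,
    tipL: np.ndarray,
    q01: np.ndarray,
    q10: np.ndarray,
    prior: np.ndarray,
) -> np.ndarray:
    """Pruning over the tree for R replicates at once.

    tipL: (R, n_tips, 2); q01, q10: scalars or (R,); prior: (2,) or (R, 2).
    Returns (R,) log-likelihoods.
    """
    R = tipL.shape[0]
    q01 = np.broadcast_to(np.asarray(q01, dtype=float), (R,))
    q10 = np.broadcast_to(np.asarray(q10, dtype=float), (R,))
    partial = [None] * pruner.n_nodes
    for idx in range(pruner.n_nodes):
        if pruner.node_is_tip[idx]:
            partial[idx] = tipL[:, pruner.tip_of_node[idx], :]
    logscale = np.zeros(R)
    for node, l, r, tl, tr in pruner.internal:
        Ll, Lr = partial[l], partial[r]
        a, b, c, d = _branch_probs(q01, q10, tl)
        left = np.empty((R, 2))
        left[:, 0] = a * Ll[:, 0] + b * Ll[:, 1]
        left[:, 1] = c * Ll[:, 0] + d * Ll[:, 1]
        a, b, c, d = _branch_probs(q01, q10, tr)
        right = np.empty((R, 2))
        right[:, 0] = a * Lr[:, 0] + b * Lr[:, 1]
        right[:, 1] = c * Lr[:, 0] + d * Lr[:, 1]
        prod = left * right
        scale = prod.max(axis=1)
        scale = np.where(scale > 0, scale, 1.0)
        partial[node] = prod / scale[:, None]
        logscale += np.log(scale)
    rootL = partial[pruner.root_index]
    prior = np.atleast_2d(prior)
    lik = (rootL * prior).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def _loglik_scalar(
    pruner: _Pruner, states: np.ndarray, q01: float, q10: float, prior
) -> float:
    """Single-replicate pruning with plain floats (hot path for fitting)."""
    n = pruner.n_nodes
    p0v = [0.0] * n
    p1v = [0.0] * n
    for idx in range(n):
        if pruner.node_is_tip[idx]:
            s = states[pruner.tip_of_node[idx]]
            p0v[idx] = 1.0 if s == 0 else 0.0
            p1v[idx] = 1.0 if s == 1 else 0.0
    s = q01 + q10
    if s > 0:
        pi0 = q10 / s
        pi1 = q01 / s
    logscale = 0.0
    for node, l, r, tl, tr in pruner.internal:
        if s > 0:
            e = math.exp(-s * tl)
            a = pi0 + pi1 * e
            d = pi1 + pi0 * e
            left0 = a * p0v[l] + (pi1 - pi1 * e) * p1v[l]
            left1 = (pi0 - pi0 * e) * p0v[l] + d * p1v[l]
            e = math.exp(-s * tr)
            a = pi0 + pi1 * e
            d = pi1 + pi0 * e
            right0 = a * p0v[r] + (pi1 - pi1 * e) * p1v[r]
            right1 = (pi0 - pi0 * e) * p0v[r] + d * p1v[r]
        else:
            left0, left1 = p0v[l], p1v[l]
            right0, right1 = p0v[r], p1v[r]
        v0 = left0 * right0
        v1 = left1 * right1
        m = v0 if v0 > v1 else v1
        if m > 0.0:
            v0 /= m
            v1 /= m
            logscale += math.log(m)
        p0v[node] = v0
        p1v[node] = v1
    lik = prior[0] * p0v[pruner.root_index] + prior[1] * p1v[pruner.root_index]
    return math.log(lik) + logscale if lik > 0 else -math.inf


# ----------------------------------------------------------------------
# public likelihood API


def mk_loglik(chrono: Chronogram, trait: Mapping[str, int], model: MkModel) -> float:
    """Log-likelihood of a binary trait on a bifurcating chronogram."""
    pruner = _Pruner(chrono)
    traits = _traits_to_matrix(pruner, trait)
    return _loglik_scalar(
        pruner, traits[0], model.q01, model.q10, model.prior_vector()
    )


def mk_loglik_batch(
    chrono: Chronogram,
    traits: np.ndarray,
    q01: np.ndarray | float,
    q10: np.ndarray | float,
    root_prior: tuple[float, float] | str = (0.5, 0.5),
    tip_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Log-likelihoods of R trait replicates on one tree, vectorised.

    ``traits`` is an (R, n_tips) integer array whose columns follow
    ``tip_order`` (default: the tree's own tip order, the ``tip_order``
    attribute of the returned value of :func:`tip_order_of`).
    """
    pruner = _Pruner(chrono)
    if tip_order is not None and list(tip_order) != pruner.tip_order:
        perm = [list(tip_order).index(lab) for lab in pruner.tip_order]
        traits = traits[:, perm]
    tipL = pruner.tip_state_matrix(np.asarray(traits))
    R = traits.shape[0]
    if root_prior == "stationary":
        q01a = np.broadcast_to(np.asarray(q01, dtype=float), (R,))
        q10a = np.broadcast_to(np.asarray(q10, dtype=float), (R,))
        s = q01a + q10a
        prior = np.where(
            s[:, None] > 0,
            np.stack([q10a, q01a], axis=1) / np.where(s[:, None] > 0, s[:, None], 1.0),
            0.5,
        )
    else:
        prior = np.asarray(root_prior, dtype=float)
    return _loglik_core(pruner, tipL, q01, q10, prior)


def tip_order_of(chrono: Chronogram) -> list[str]:
    """Tip label order used by the batch likelihood for this tree."""
    return [n.label for n in chrono.tips]


# ----------------------------------------------------------------------
# fitting


def fit_mk(
    chrono: Chronogram,
    trait: Mapping[str, int],
    model_class: ModelClass = "ARD",
    root_prior: tuple[float, float] | str = (0.5, 0.5),
    n_starts: int = 5,
) -> tuple[MkModel, float]:
    """Maximum-likelihood Mk fit under ER (1-D) or ARD (2-D).

    Rates are optimised on a log scale within [1e-8, 1e3] with a coarse
    grid plus multi-start local searches; the ER optimum seeds one ARD
    start so the ARD likelihood can never fall below the ER one.
    """
    pruner = _Pruner(chrono)
    traits = _traits_to_matrix(pruner, trait)
    tip_states = traits[0]
    states = set(int(s) for s in tip_states)
    if len(states) == 1:
        import warnings

        warnings.warn(
            "trait is constant across tips: rate estimate lies at the lower bound",
            stacklevel=2,
        )

    def prior_for(q01, q10):
        if root_prior == "stationary":
            s = q01 + q10
            return np.array([q10 / s, q01 / s]) if s > 0 else np.array([0.5, 0.5])
        return np.asarray(root_prior, dtype=float)

    def nll_er(logq):
        q = float(np.exp(logq))
        return -_loglik_scalar(pruner, tip_states, q, q, prior_for(q, q))

    def nll_ard(x):
        q01 = float(np.exp(np.clip(x[0], math.log(RATE_LO), math.log(RATE_HI))))
        q10 = float(np.exp(np.clip(x[1], math.log(RATE_LO), math.log(RATE_HI))))
        return -_loglik_scalar(pruner, tip_states, q01, q10, prior_for(q01, q10))

    lo, hi = math.log(RATE_LO), math.log(RATE_HI)
    grid = np.linspace(lo, hi, 23)
    grid_vals = np.array([nll_er(g) for g in grid])

    # ER: local bounded searches around the best grid points
    order = np.argsort(grid_vals)
    best_q, best_nll = float(np.exp(grid[order[0]])), float(grid_vals[order[0]])
    for g in grid[order[:n_starts]]:
        res = optimize.minimize_scalar(
            nll_er, bounds=(max(lo, g - 2.0), min(hi, g + 2.0)),
            method="bounded", options={"xatol": 1e-10},
        )
        if res.fun < best_nll:
            best_q, best_nll = float(np.exp(res.x)), float(res.fun)
    er_model = MkModel(best_q, best_q, "ER", root_prior)
    if model_class == "ER":
        return er_model, -best_nll

    # ARD: multi-start Nelder-Mead seeded from the grid and the ER optimum
    logq_er = math.log(best_q)
    starts = [
        (logq_er, logq_er),
        (float(grid[order[0]]), float(grid[order[0]])),
        (logq_er + 1.0, logq_er - 1.0),
        (logq_er - 1.0, logq_er + 1.0),
        (math.log(1.0), math.log(1.0)),
    ][: max(n_starts, 1)]
    best_x, best_f = (logq_er, logq_er), best_nll
    for x0 in starts:
        res = optimize.minimize(
            nll_ard, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if res.fun < best_f - 1e-13 or (res.fun < best_f):
            best_x, best_f = tuple(res.x), float(res.fun)
    if not np.isfinite(best_f):
        raise RuntimeError("Mk fit failed to converge from all starts")
    q01 = float(np.exp(np.clip(best_x[0], lo, hi)))
    q10 = float(np.exp(np.clip(best_x[1], lo, hi)))
    return MkModel(q01, q10, "ARD", root_prior), -best_f


def fit_mk_batch(
    chrono: Chronogram,
    traits: np.ndarray,
    model_class: ModelClass = "ARD",
    root_prior: tuple[float, float] | str = (0.5, 0.5),
    n_iter: int = 60,
    n_sweeps: int = 4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ML fits of R trait replicates on one fixed tree.

    Returns ``(q01_hat, q10_hat, loglik)`` arrays of length R.  ER uses
    a golden-section search on the log rate; ARD then refines by
    coordinate descent (golden section per coordinate) from the ER
    optimum, so ARD log-likelihoods never fall below ER ones.
    """
    pruner = _Pruner(chrono)
    tipL = pruner.tip_state_matrix(np.asarray(traits))
    R = tipL.shape[0]
    prior = np.asarray(root_prior, dtype=float) if root_prior != "stationary" else None

    def ll(q01, q10):
        if prior is None:
            s = q01 + q10
            pr = np.where(
                s[:, None] > 0,
                np.stack([q10, q01], axis=1) / np.where(s[:, None] > 0, s[:, None], 1.0),
                0.5,
            )
        else:
            pr = prior
        return _loglik_core(pruner, tipL, q01, q10, pr)

    lo, hi = math.log(RATE_LO), math.log(RATE_HI)

    def golden(f, a, b, iters):
        gr = (math.sqrt(5.0) - 1.0) / 2.0
        a = np.full(R, a) if np.isscalar(a) else a.copy()
        b = np.full(R, b) if np.isscalar(b) else b.copy()
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc, fd = f(c), f(d)
        for _ in range(iters):
            go_left = fc >= fd  # maximise: keep [a, d] when f(c) >= f(d)
            b = np.where(go_left, d, b)
            a = np.where(go_left, a, c)
            c = b - gr * (b - a)
            d = a + gr * (b - a)
            fc, fd = f(c), f(d)
        x = 0.5 * (a + b)
        return x, f(x)

    # ER stage
    logq, ll_er = golden(lambda x: ll(np.exp(x), np.exp(x)), lo, hi, n_iter)
    if model_class == "ER":
        q = np.exp(logq)
        return q, q, ll_er

    x0, x1 = logq.copy(), logq.copy()
    best = ll(np.exp(x0), np.exp(x1))
    for sweep in range(n_sweeps):
        # full-range bracket on the first sweep, then local refinement
        if sweep == 0:
            a0 = np.full_like(x0, lo)
            b0 = np.full_like(x0, hi)
            iters = n_iter
        else:
            a0 = np.clip(x0 - 1.5, lo, hi)
            b0 = np.clip(x0 + 1.5, lo, hi)
            iters = max(n_iter // 2, 30)
        x0, best = golden(lambda x: ll(np.exp(x), np.exp(x1)), a0, b0, iters)
        if sweep == 0:
            a1 = np.full_like(x1, lo)
            b1 = np.full_like(x1, hi)
        else:
            a1 = np.clip(x1 - 1.5, lo, hi)
            b1 = np.clip(x1 + 1.5, lo, hi)
        x1, best = golden(lambda x: ll(np.exp(x0), np.exp(x)), a1, b1, iters)

    # damped Newton polish: coordinate descent alone crawls along the
    # correlated (q01, q10) ridge typical of near-symmetric traits
    h = 1e-4
    for _ in range(12):
        f0 = ll(np.exp(x0), np.exp(x1))
        fpp = ll(np.exp(x0 + h), np.exp(x1))
        fmp = ll(np.exp(x0 - h), np.exp(x1))
        fqp = ll(np.exp(x0), np.exp(x1 + h))
        fqm = ll(np.exp(x0), np.exp(x1 - h))
        fxy = ll(np.exp(x0 + h), np.exp(x1 + h))
        g0 = (fpp - fmp) / (2 * h)
        g1 = (fqp - fqm) / (2 * h)
        h00 = (fpp - 2 * f0 + fmp) / h**2
        h11 = (fqp - 2 * f0 + fqm) / h**2
        h01 = (fxy - fpp - fqp + f0) / h**2
        det = h00 * h11 - h01 * h01
        concave = (h00 < 0) & (det > 0)
        safe_det = np.where(det != 0, det, 1.0)
        s0 = np.where(concave, -(h11 * g0 - h01 * g1) / safe_det, 0.0)
        s1 = np.where(concave, -(h00 * g1 - h01 * g0) / safe_det, 0.0)
        norm = np.maximum(np.abs(s0), np.maximum(np.abs(s1), 1e-300))
        scale = np.where(norm > 1.0, 1.0 / norm, 1.0)
        t0 = np.clip(x0 + s0 * scale, lo, hi)
        t1 = np.clip(x1 + s1 * scale, lo, hi)
        f_new = ll(np.exp(t0), np.exp(t1))
        improve = f_new > f0
        x0 = np.where(improve, t0, x0)
        x1 = np.where(improve, t1, x1)
        if not improve.any():
            break
    best = ll(np.exp(x0), np.exp(x1))
    # fall back to the ER solution where the 2-D search did not beat it
    worse = best < ll_er
    x0 = np.where(worse, logq, x0)
    x1 = np.where(worse, logq, x1)
    best = np.maximum(best, ll_er)
    return np.exp(x0), np.exp(x1), best


# ----------------------------------------------------------------------
# model comparison


def lrt_pvalue(loglik_null: float, loglik_alt: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic ``D = 2 (lnL_alt - lnL_null)`` and its
    upper-tail chi-square probability with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if loglik_alt < loglik_null - 1e-9:
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}: "
            "models are not nested or fits did not converge"
        )
    d = max(0.0, 2.0 * (loglik_alt - loglik_null))
    return d, float(stats.chi2.sf(d, df))


def aic(loglik: float, k: int) -> float:
    return 2.0 * k - 2.0 * loglik


# ----------------------------------------------------------------------
# marginal ancestral states


def marginal_ancestral_states(
    chrono: Chronogram, trait: Mapping[str, int], model: MkModel
) -> dict[int, tuple[float, float]]:
    """Marginal posterior state probabilities at every internal node.

    Down pass: Felsenstein partials conditional on the data below each
    node.  Up pass: outside partials combining the root prior, the
    complementary subtree and the connecting branches.  The marginal at
    a node is the normalised product of the two.  Keys are node indices
    of ``chrono.nodes``; each value pair sums to 1.
    """
    pruner = _Pruner(chrono)
    traits = _traits_to_matrix(pruner, trait)
    tipL = pruner.tip_state_matrix(traits)[0]  # (n_tips, 2)
    prior = model.prior_vector()

    n = pruner.n_nodes
    down = np.zeros((n, 2))
    for idx in range(n):
        if pruner.node_is_tip[idx]:
            down[idx] = tipL[pruner.tip_of_node[idx]]
    P: dict[int, np.ndarray] = {}
    for node, l, r, tl, tr in pruner.internal:
        P[l] = transition_matrix(model, tl)
        P[r] = transition_matrix(model, tr)
        prod = (P[l] @ down[l]) * (P[r] @ down[r])
        m = prod.max()
        down[node] = prod / m if m > 0 else prod

    up = np.zeros((n, 2))
    up[pruner.root_index] = prior
    for node, l, r, tl, tr in reversed(pruner.internal):
        for child, sib in ((l, r), (r, l)):
            sib_msg = P[sib] @ down[sib]
            g = (up[node] * sib_msg) @ P[child]
            m = g.max()
            up[child] = g / m if m > 0 else g

    out: dict[int, tuple[float, float]] = {}
    for node in chrono.nodes:
        if node.is_tip:
            continue
        w = up[node.index] * down[node.index]
        total = w.sum()
        if total <= 0:
            raise RuntimeError("zero marginal likelihood at an internal node")
        out[node.index] = (float(w[0] / total), float(w[1] / total))
    return out


# ----------------------------------------------------------------------
# tabular I/O


def read_trait_table(path) -> dict[str, int]:
    """2-column TSV (tip label, state in {0,1}); '#' lines are comments."""
    trait: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated fields")
            label, state = parts
            if state not in ("0", "1"):
                raise ValueError(f"{path}:{line_no}: state must be 0 or 1, got {state!r}")
            if label in trait:
                raise ValueError(f"{path}:{line_no}: duplicate tip {label!r}")
            trait[label] = int(state)
    return trait


def write_ancestral_table(
    chrono: Chronogram,
    marginals: dict[int, tuple[float, float]],
    path,
    header_lines: Sequence[str] = (),
) -> None:
    """Per-internal-node TSV: sorted descendant tips, P(0), P(1)."""
    clades = chrono.clade_sets()
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("node_tips\tp_state0\tp_state1\n")
        for idx, (p0, p1) in sorted(marginals.items()):
            tips = ",".join(sorted(clades[idx]))
            fh.write(f"{tips}\t{p0:.6f}\t{p1:.6f}\n")
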