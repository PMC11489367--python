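"""Binomial-logit mixed model with independent random intercepts.

Laplace-approximation maximum likelihood: for fixed random-effect
standard deviations the joint mode over (beta, u) is found by penalised
Newton iterations, and the marginal log-likelihood is the Laplace
integral over the random effects; the outer optimisation over the
log-sds uses Nelder-Mead.  Wald standard errors come from the
fixed-effect block of the joint Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

_SIGMA_FLOOR = 1e-6


@dataclass
class GlmmResult:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    vc_names: list[str]
    sigmas: np.ndarray           # random-intercept standard deviations
    loglik: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "coefficients": {
                n: {"estimate": float(b), "se": float(s), "z": float(z),
                    "p": float(p)}
                for n, b, s, z, p in zip(self.names, self.beta, self.se,
                                         self.zvalues, self.pvalues)
            },
            "random_effects": {n: float(s) for n, s in zip(self.vc_names, self.sigmas)},
            "loglik": self.loglik,
            "converged": self.converged,
            "flags": self.flags,
        }


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, int]:
    levels, idx = np.unique(labels, return_inverse=True)
    Z = np.zeros((labels.size, levels.size))
    Z[np.arange(labels.size), idx] = 1.0
    return Z, levels.size


def _joint_mode(M, y, m, pen_diag, z0):
    """Penalised Newton for the joint (beta, u) mode; returns (z, H, ok)."""
    z = z0.copy()
    ok = False
    obj_old = -np.inf
    for _ in range(100):
        eta = M @ z
        p = expit(eta)
        ll = float(y @ eta - m @ np.logaddexp(0.0, eta)) - 0.5 * float(z @ (pen_diag * z))
        grad = M.T @ (y - m * p) - pen_diag * z
        W = m * p * (1 - p)
        H = (M.T * W) @ M + np.diag(pen_diag)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return z, H, False
        # step halving on the penalised objective
        t = 1.0
        for _ in range(30):
            z_new = z + t * step
            eta_n = M @ z_new
            ll_new = float(y @ eta_n - m @ np.logaddexp(0.0, eta_n)) \
                - 0.5 * float(z_new @ (pen_diag * z_new))
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        z = z_new
        if abs(ll_new - obj_old) < 1e-10 * (1 + abs(ll_new)):
            ok = True
            break
        obj_old = ll_new
    eta = M @ z
    p = expit(eta)
    W = m * p * (1 - p)
    H = (M.T * W) @ M + np.diag(pen_diag)
    return z, H, ok


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    trials: np.ndarray,
    groups: dict[str, np.ndarray],
    names: list[str] | None = None,
) -> GlmmResult:
    """Fit successes/trials with logit link, fixed design ``X`` and one
    random intercept per entry of ``groups`` (name -> label array)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(trials, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    flags: list[str] = []

    Zs, qs = [], []
    vc_names = list(groups)
    for gname, labels in groups.items():
        Z, q = _indicator(np.asarray(labels))
        if q < 2:
            flags.append(f"random term {gname!r} has <2 levels; variance degenerate")
        Zs.append(Z)
        qs.append(q)
    M = np.hstack([X] + Zs)
    q_total = sum(qs)

    def pen_vector(sigmas):
        pen = np.zeros(p + q_total)
        off = p
        for q, s in zip(qs, sigmas):
            pen[off:off + q] = 1.0 / max(s, _SIGMA_FLOOR) ** 2
            off += q
        return pen

    state = {"z": np.zeros(p + q_total), "ok": True}

    def neg_laplace(log_sigmas):
        sigmas = np.exp(np.clip(log_sigmas, -14.0, 5.0))
        pen = pen_vector(sigmas)
        z, H, ok = _joint_mode(M, y, m, pen, state["z"])
        if ok:
            state["z"] = z
        eta = M @ z
        ll = float(y @ eta - m @ np.logaddexp(0.0, eta))
        off = p
        for q, s in zip(qs, sigmas):
            u = z[off:off + q]
            s2 = max(s, _SIGMA_FLOOR) ** 2
            ll -= 0.5 * float(u @ u) / s2 + 0.5 * q * np.log(s2)
            off += q
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e10
        return -(ll - 0.5 * logdet)

    res = minimize(neg_laplace, np.log([0.3] * len(qs)), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
    sigmas = np.exp(np.clip(res.x, -14.0, 5.0))
    pen = pen_vector(sigmas)
    z, H, newton_ok = _joint_mode(M, y, m, pen, state["z"])
    beta = z[:p]
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags.append("singular Hessian at optimum")
    converged = bool(res.success and newton_ok)
    if not converged:
        flags.append("optimiser did not fully converge; best-found values returned")
    if np.any(np.abs(beta) > 15):
        flags.append("extreme coefficient magnitude suggests separation")
        converged = False
    zvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    pvals = 2 * norm.sf(np.abs(zvals))
    return GlmmResult(
        names=names, beta=beta, se=se, zvalues=zvals, pvalues=pvals,
        vc_names=vc_names, sigmas=np.where(sigmas <= 10 * _SIGMA_FLOOR, 0.0, sigmas),
        loglik=-float(res.fun), converged=converged, flags=flags,
    )
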