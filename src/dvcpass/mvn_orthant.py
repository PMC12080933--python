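"""Orthant probabilities of 2-D and 4-D normal distributions.

This module is the likelihood engine for every correlation estimator in the
package.  A joint response pattern across the passes of a double-pass (or
quasi-quadruple-pass) experiment corresponds to an orthant of the normalized
joint decision variable: each pass contributes a sign constraint (comparison
chosen = decision variable above its criterion).  The probability of a
pattern is the multivariate-normal mass of that orthant.

Three evaluation routes are provided, all deterministic:

* dimension 2 — closed form via Owen's T function (machine precision);
* dimension 4 with the *two-group* correlation structure used by the
  quadruple-pass analyses (two passes per experiment or per observer) — an
  exact single-common-factor reduction followed by Gauss-Hermite quadrature,
  valid on the entire positive-semidefinite region;
* dimension 4 with an arbitrary correlation matrix — Genz-style sequential
  sampling on a scrambled Sobol sequence with a fixed seed and an error
  estimate, refined until the accuracy target is met.

The canonical ordering of response patterns is binary counting with
``-`` = 0 and ``+`` = 1 and pass 1 as the most significant bit, e.g. for two
passes: ``--, -+, +-, ++``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import qmc

__all__ = [
    "OrthantProblem",
    "orthant_prob",
    "pattern_probs",
    "build_quad_corr",
    "bvn_cdf",
    "bvn_orthant",
    "quad_pattern_probs",
    "pattern_labels",
]

_RHO_EDGE = 1.0 - 1e-12


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X1 < h, X2 < k)`` with correlation rho.

    Evaluated in closed form through Owen's T function; accurate to near
    machine precision and fully vectorized.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    out = np.empty(h.shape, dtype=float)

    hi = rho >= _RHO_EDGE
    lo = rho <= -_RHO_EDGE
    mid = ~(hi | lo)
    if np.any(hi):  # comonotone limit
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):  # antithetic limit
        out[lo] = np.clip(ndtr(h[lo]) + ndtr(k[lo]) - 1.0, 0.0, 1.0)
    if np.any(mid):
        out[mid] = _bvn_mid(h[mid], k[mid], rho[mid])
    if out.ndim == 0:
        return float(out)
    return out


def _bvn_mid(h, k, rho):
    r = np.sqrt(1.0 - rho * rho)
    zh = h != 0.0
    zk = k != 0.0
    # Owen's formula terms; the h==0 / k==0 limits are T(0, +/-inf) = +/-1/4.
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = np.where(zh, (k - rho * h) / np.where(zh, h * r, 1.0), 0.0)
        ak = np.where(zk, (h - rho * k) / np.where(zk, k * r, 1.0), 0.0)
    th = np.where(zh, owens_t(h, ah), 0.25 * np.sign(k))
    tk = np.where(zk, owens_t(k, ak), 0.25 * np.sign(h))
    both_zero = ~zh & ~zk
    beta = np.where((h * k > 0) | (both_zero | ((h * k == 0) & (h + k >= 0))), 0.0, 0.5)
    val = 0.5 * (ndtr(h) + ndtr(k)) - th - tk - beta
    if np.any(both_zero):
        val = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), val)
    return np.clip(val, 0.0, 1.0)


def bvn_orthant(mean1, mean2, rho, sign1, sign2, crit1=0.0, crit2=0.0):
    """``P(s1 (X1 - c1) > 0 and s2 (X2 - c2) > 0)`` for a correlated normal pair.

    Signs are +/-1 (+ = comparison chosen, i.e. decision variable above the
    criterion).  Means are on the normalized (d-prime) scale.
    """
    s1 = np.asarray(sign1, dtype=float)
    s2 = np.asarray(sign2, dtype=float)
    return bvn_cdf(s1 * (np.asarray(mean1) - crit1),
                   s2 * (np.asarray(mean2) - crit2),
                   s1 * s2 * np.asarray(rho))


def _bvn_equal_upper(h, rho):
    """``P(Z1 > -h, Z2 > -h)`` for standard normals with correlation rho.

    Identity: Phi2(h, h, rho) = Phi(h) - 2 T(h, sqrt((1-rho)/(1+rho))).
    """
    rho = np.clip(rho, -_RHO_EDGE, _RHO_EDGE)
    a = np.sqrt((1.0 - rho) / (1.0 + rho))
    return np.clip(ndtr(h) - 2.0 * owens_t(h, a), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Problem container and generic evaluation
# ---------------------------------------------------------------------------

@dataclass
class OrthantProblem:
    """A sign-constrained region of a 2-D or 4-D normal distribution.

    ``pattern`` holds one entry of ``+1``/``-1`` per pass; coordinate i is
    constrained above (+) or below (-) its criterion.
    """

    mean_z: np.ndarray
    corr: np.ndarray
    pattern: np.ndarray
    criteria_z: np.ndarray | None = None

    def __post_init__(self):
        self.mean_z = np.atleast_1d(np.asarray(self.mean_z, dtype=float))
        self.corr = np.asarray(self.corr, dtype=float)
        self.pattern = np.atleast_1d(np.asarray(self.pattern, dtype=float))
        d = self.mean_z.size
        if d not in (2, 4):
            raise ValueError(f"only dimensions 2 and 4 are supported, got {d}")
        if self.corr.shape != (d, d):
            raise ValueError("correlation matrix shape does not match the mean")
        if self.pattern.size != d:
            raise ValueError("pattern length must equal the dimension")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")
        if self.criteria_z is None:
            self.criteria_z = np.zeros(d)
        else:
            self.criteria_z = np.atleast_1d(np.asarray(self.criteria_z, dtype=float))

    @property
    def dim(self) -> int:
        return self.mean_z.size


def orthant_prob(problem: OrthantProblem, *, gh_order: int = 64,
                 tol: float = 1e-5, qmc_seed: int = 9001) -> float:
    """Probability of the orthant described by ``problem``.

    Deterministic.  Absolute accuracy is ~1e-12 in dimension 2, better than
    1e-6 in dimension 4 for two-group matrices, and ``tol`` (default 1e-5)
    for general 4-D matrices.
    """
    m, C, s, c = problem.mean_z, problem.corr, problem.pattern, problem.criteria_z
    if problem.dim == 2:
        return float(bvn_orthant(m[0], m[1], C[0, 1], s[0], s[1], c[0], c[1]))
    grp = _two_group_params(C)
    if grp is not None:
        return float(_two_group_orthant(m, s, c, *grp, gh_order=gh_order))
    return _genz_orthant(m, C, s, c, tol=tol, seed=qmc_seed)


def pattern_probs(mean_z, corr, criteria_z=None, **kw) -> np.ndarray:
    """Probabilities of all ``2**dim`` response patterns, canonical order.

    Binary counting with ``-`` = 0, ``+`` = 1, pass 1 most significant.  The
    vector sums to 1 (up to the evaluation accuracy).
    """
    mean_z = np.atleast_1d(np.asarray(mean_z, dtype=float))
    d = mean_z.size
    out = np.empty(2 ** d)
    for j in range(2 ** d):
        out[j] = orthant_prob(
            OrthantProblem(mean_z, corr, _pattern_from_index(j, d), criteria_z), **kw)
    return out


def pattern_labels(dim: int) -> list[str]:
    """Canonical pattern strings, e.g. ``['--', '-+', '+-', '++']`` for dim 2."""
    return ["".join("+" if b else "-" for b in _bits(j, dim)) for j in range(2 ** dim)]


def _bits(j: int, dim: int):
    return [(j >> (dim - 1 - i)) & 1 for i in range(dim)]


def _pattern_from_index(j: int, dim: int) -> np.ndarray:
    return np.array([1.0 if b else -1.0 for b in _bits(j, dim)])


# ---------------------------------------------------------------------------
# Two-group 4x4 matrices (quadruple-pass structure)
# ---------------------------------------------------------------------------

def build_quad_corr(rho_flat: float, rho_nat: float, rho_cross: float) -> np.ndarray:
    """Correlation matrix across the four passes of two double-pass experiments.

    Pass order is (flat pass 1, flat pass 2, natural pass 1, natural pass 2):
    within-experiment correlations on the block diagonals, the
    cross-experiment correlation everywhere else.  The same family serves the
    between-observer analysis with (rho11, rho22, rho12).

    Raises ``ValueError`` naming the violated bound if the triple is not
    jointly positive semidefinite: the requirement is ``rho_flat <= 1``,
    ``rho_nat <= 1`` and ``(1+rho_flat)(1+rho_nat) >= 4 rho_cross**2``.
    """
    a, b, c = float(rho_flat), float(rho_nat), float(rho_cross)
    for name, v in (("rho_flat", a), ("rho_nat", b), ("rho_cross", c)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [-1, 1]")
    if (1.0 + a) * (1.0 + b) < 4.0 * c * c - 1e-12:
        raise ValueError(
            f"(1+rho_flat)(1+rho_nat)={(1 + a) * (1 + b):.6g} < "
            f"4*rho_cross^2={4 * c * c:.6g}: matrix not positive semidefinite")
    return np.array([[1.0, a, c, c],
                     [a, 1.0, c, c],
                     [c, c, 1.0, b],
                     [c, c, b, 1.0]])


def _two_group_params(C: np.ndarray):
    """Return (a, b, c) if C has the two-group structure, else None."""
    a, b, c = C[0, 1], C[2, 3], C[0, 2]
    if (abs(C[0, 3] - c) < 1e-12 and abs(C[1, 2] - c) < 1e-12
            and abs(C[1, 3] - c) < 1e-12):
        return float(a), float(b), float(c)
    return None


def _factor_loadings(a: float, b: float, c: float) -> tuple[float, float]:
    """Loadings (lf, ln) of the shared factor with lf*ln = c.

    Conditioning on the factor decorrelates the two pass-pairs; the split is
    chosen so both residual pair correlations stay in [-1, 1] over the whole
    PSD region (lf^2 <= (1+a)/2, ln^2 <= (1+b)/2).
    """
    if c == 0.0:
        return 0.0, 0.0
    ratio = np.sqrt((1.0 + a) / max(1.0 + b, 1e-15))
    lf2 = min(abs(c) * ratio, 1.0 - 1e-12)
    ln2 = min(c * c / lf2, 1.0 - 1e-12)
    return float(np.sqrt(lf2)), float(np.sign(c) * np.sqrt(ln2))


from functools import lru_cache


@lru_cache(maxsize=8)
def _gh_nodes(order: int):
    x, w = np.polynomial.hermite.hermgauss(order)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)  # for integrals against N(0,1)


def _two_group_orthant(mean, sign, crit, a, b, c, gh_order=64):
    """Orthant probability under the two-group correlation, general means."""
    lf, ln = _factor_loadings(a, b, c)
    u, w = _gh_nodes(gh_order)
    p = w.copy()
    for (i1, i2, lam, rho_in) in ((0, 1, lf, a), (2, 3, ln, b)):
        resid_sd = np.sqrt(max(1.0 - lam * lam, 1e-15))
        rho_resid = np.clip((rho_in - lam * lam) / max(1.0 - lam * lam, 1e-15),
                            -1.0, 1.0)
        h1 = sign[i1] * (mean[i1] + lam * u - crit[i1]) / resid_sd
        h2 = sign[i2] * (mean[i2] + lam * u - crit[i2]) / resid_sd
        p = p * bvn_cdf(h1, h2, sign[i1] * sign[i2] * rho_resid)
    return p.sum()


def quad_pattern_probs(dprime_flat, dprime_nat, rho_flat, rho_nat, rho_cross,
                       gh_order: int = 48) -> np.ndarray:
    """All 16 pattern probabilities for the quasi-quadruple-pass model.

    Vectorized over comparison levels: ``dprime_flat`` and ``dprime_nat`` are
    arrays of normalized means (one per level, shared by the two passes of
    the corresponding experiment; criteria are zero).  Returns an array of
    shape ``(n_levels, 16)`` in canonical pattern order.

    This is the hot path of the maximum-likelihood fits: conditional on the
    shared factor each pass-pair collapses to an equal-mean bivariate orthant
    with an Owen's-T closed form, so one likelihood evaluation costs a few
    vectorized special-function calls.
    """
    df = np.atleast_1d(np.asarray(dprime_flat, dtype=float))
    dn = np.atleast_1d(np.asarray(dprime_nat, dtype=float))
    if df.shape != dn.shape:
        raise ValueError("dprime_flat and dprime_nat must have the same length")
    a, b, c = float(rho_flat), float(rho_nat), float(rho_cross)
    lf, ln = _factor_loadings(a, b, c)
    u, w = _gh_nodes(gh_order)  # (K,)

    def group_probs(means, lam, rho_in):
        resid_var = max(1.0 - lam * lam, 1e-15)
        rho_resid = min(max((rho_in - lam * lam) / resid_var, -_RHO_EDGE),
                        _RHO_EDGE)
        h = (means[:, None] + lam * u[None, :]) / np.sqrt(resid_var)  # (L, K)
        ph = ndtr(h)
        t_const = np.sqrt((1.0 - rho_resid) / (1.0 + rho_resid))
        pp = ph - 2.0 * owens_t(h, t_const)          # P(++ | u)
        out = np.empty(h.shape + (4,))               # order (--, -+, +-, ++)
        out[..., 0] = pp + 1.0 - 2.0 * ph            # symmetry
        out[..., 1] = out[..., 2] = ph - pp
        out[..., 3] = pp
        return out

    gf = group_probs(df, lf, a)
    gn = group_probs(dn, ln, b)
    # integrate product over the factor: (L, 4, 4) -> (L, 16)
    probs = np.einsum("k,lkf,lkn->lfn", w, gf, gn).reshape(df.size, 16)
    return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# General 4-D fallback: Genz sequential sampling on scrambled Sobol points
# ---------------------------------------------------------------------------

def _genz_orthant(mean, C, sign, crit, tol=1e-5, seed=9001, max_pow=17):
    # region sign*(X - crit) > 0  <=>  Y = sign*X standard-normal-correlated
    # with corr S C S, lower bounds sign*(crit - mean)
    s = np.asarray(sign, dtype=float)
    Cs = C * np.outer(s, s)
    lower = s * (np.asarray(crit) - np.asarray(mean))
    w_eig, V = np.linalg.eigh(Cs)
    if w_eig.min() < 1e-10:
        warnings.warn("near-singular correlation matrix; eigenvalues floored",
                      RuntimeWarning)
        w_eig = np.maximum(w_eig, 1e-10)
        Cs = V @ np.diag(w_eig) @ V.T
        d = np.sqrt(np.diag(Cs))
        Cs = Cs / np.outer(d, d)
    L = np.linalg.cholesky(Cs)
    n = len(lower)
    n_rep = 8
    m = 10
    while True:
        vals = np.empty(n_rep)
        for r in range(n_rep):
            pts = qmc.Sobol(n - 1, scramble=True, seed=seed + r).random_base2(m)
            vals[r] = _genz_eval(lower, L, pts)
        est = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(n_rep)
        if 3.5 * se < tol or m >= max_pow:
            if 3.5 * se >= tol:
                warnings.warn(f"orthant tolerance {tol} not certified "
                              f"(error estimate {3.5 * se:.2e})", RuntimeWarning)
            return float(np.clip(est, 0.0, 1.0))
        m += 1


def _genz_eval(lower, L, pts):
    # Genz sequential transformation for P(Y > lower), Y ~ N(0, L L^T).
    npts = pts.shape[0]
    n = len(lower)
    eps = 1e-15
    d = np.full(npts, ndtr(lower[0] / L[0, 0]))
    prob = 1.0 - d
    y = np.empty((npts, n - 1))
    for i in range(1, n):
        u = d + pts[:, i - 1] * np.clip(1.0 - d, 0.0, 1.0)
        y[:, i - 1] = ndtri(np.clip(u, eps, 1.0 - eps))
        t = (lower[i] - y[:, :i] @ L[i, :i]) / L[i, i]
        d = ndtr(t)
        prob = prob * (1.0 - d)
    return prob.mean()
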