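"""Kinship-structured linear mixed model engine.

Fits, by ML or REML, the model

    y ~ N(X beta,  sigma_kin^2 * Z K Z' + sigma_e^2 * I)

where ``K`` is a (block-diagonal) kinship matrix over individuals and
``Z`` is the person incidence matrix of a single random intercept per
individual.  Fitting profiles out ``beta`` and the overall scale so
that only the variance ratio ``delta = sigma_kin^2 / sigma_e^2`` needs
a one-dimensional search; each likelihood evaluation is O(n) after a
one-off per-pedigree eigendecomposition of ``Z K Z'``.

The same engine covers person-level models (one row per person,
``Z = I``), including the second-stage regression of predicted random
intercepts on a SNP, and exposes a vectorised per-SNP scanner that
freezes the variance ratio at a null fit (GRAMMAR/EMMAX-style fast
mode).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .pedkin import KinshipMatrix

__all__ = [
    "ModelData",
    "VarianceComponents",
    "FitResult",
    "fit_lmm",
    "wald_test",
    "blup",
    "SnpScanner",
]

_DELTA_GRID = np.concatenate([[0.0], np.logspace(-6.0, 6.0, 64)])
_RATIO_TOL = 1e-8
_VAR_FLOOR = 1e-30


@dataclass
class ModelData:
    """Response, design and random-effect structure for one model fit.

    ``person_index[r]`` gives, for observation row ``r``, the position
    of its individual in ``K.ids``.  Several rows may map to the same
    individual (repeated measures); a person-level model maps each row
    to a distinct individual.
    """

    y: np.ndarray
    X: np.ndarray
    person_index: np.ndarray
    K: KinshipMatrix
    xnames: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.person_index = np.asarray(self.person_index, dtype=np.intp)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.person_index.shape[0] != n:
            raise ValueError("y, X and person_index must have matching length")
        if self.person_index.min(initial=0) < 0 or (
            n and self.person_index.max() >= self.K.n
        ):
            raise ValueError("person_index must index rows of K")
        if self.xnames is None:
            self.xnames = [f"x{j}" for j in range(self.X.shape[1])]
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design matrix X is rank deficient")


@dataclass
class VarianceComponents:
    var_kin: float
    var_resid: float

    @property
    def ratio(self) -> float:
        return self.var_kin / max(self.var_resid, _VAR_FLOOR)


@dataclass
class FitResult:
    """Estimates from one mixed-model fit."""

    beta_hat: np.ndarray
    se: np.ndarray
    vc: VarianceComponents
    loglik: float
    blups: np.ndarray          # per K individual; 0 for unobserved ones
    converged: bool
    criterion: str
    xnames: list[str]
    boundary: bool = False
    degenerate: bool = False
    n_obs: int = 0
    beta_cov: np.ndarray = field(default=None, repr=False)

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.xnames:
            raise KeyError(f"unknown coefficient {name!r}")
        j = self.xnames.index(name)
        return float(self.beta_hat[j]), float(self.se[j])


class Rotation:
    """Per-pedigree eigendecomposition of ``G = Z K Z'``.

    Depends only on (K, person_index), not on X or y, so it is computed
    once and reused across per-SNP refits on the same sample.
    """

    def __init__(self, K: KinshipMatrix, person_index: np.ndarray):
        person_index = np.asarray(person_index, dtype=np.intp)
        n = person_index.shape[0]
        # group observation rows by pedigree block of their individual
        block_of = np.empty(K.n, dtype=np.intp)
        self._block_slices_K: list[slice] = []
        for b, (fid, sl) in enumerate(K.blocks.items()):
            block_of[sl] = b
            self._block_slices_K.append(sl)
        obs_block = block_of[person_index]
        self.perm = np.argsort(obs_block, kind="stable")
        self.n = n
        self.K = K
        self.person_index = person_index
        pi_perm = person_index[self.perm]
        self.eigvals = np.empty(n)
        self.blocks: list[tuple[slice, np.ndarray, np.ndarray]] = []
        start = 0
        for b in np.unique(obs_block):
            rows = np.flatnonzero(obs_block[self.perm] == b)
            m = rows.shape[0]
            sl = slice(start, start + m)
            persons = pi_perm[sl]
            G = K.values[np.ix_(persons, persons)]
            lam, U = np.linalg.eigh(G)
            lam = np.clip(lam, 0.0, None)  # PSD up to round-off
            self.eigvals[sl] = lam
            self.blocks.append((sl, U, persons))
            start += m
        if start != n:
            raise AssertionError("block partition lost rows")

    def rotate(self, A: np.ndarray) -> np.ndarray:
        """Return ``U' A`` (block-wise), with rows in permuted order."""
        A = np.asarray(A, dtype=float)
        Ap = A[self.perm]
        out = np.empty_like(Ap, dtype=float)
        for sl, U, _ in self.blocks:
            out[sl] = U.T @ Ap[sl]
        return out

    def unrotate_to_persons(self, v: np.ndarray) -> np.ndarray:
        """Map a rotated observation-space vector back and sum to persons.

        Computes ``Z' U v`` indexed by K individual (length K.n).
        """
        out = np.zeros(self.K.n)
        for sl, U, persons in self.blocks:
            back = U @ v[sl]
            np.add.at(out, persons, back)
        return out


def _profile(
    delta: float,
    yt: np.ndarray,
    Xt: np.ndarray,
    lam: np.ndarray,
    criterion: str,
):
    """Profiled log-likelihood at variance ratio delta, plus GLS pieces."""
    n, p = Xt.shape
    w = 1.0 / (1.0 + delta * lam)
    XtW = Xt * w[:, None]
    A = XtW.T @ Xt
    b = XtW.T @ yt
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return -np.inf, None
    r = yt - Xt @ beta
    S = float(np.dot(r * w, r))
    logdetH = float(np.sum(np.log1p(delta * lam)))
    if criterion == "ML":
        s2 = max(S / n, _VAR_FLOOR)
        ll = -0.5 * (n * (math.log(2 * math.pi * s2) + 1.0) + logdetH)
    else:  # REML
        s2 = max(S / max(n - p, 1), _VAR_FLOOR)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, None
        ll = -0.5 * (
            (n - p) * (math.log(2 * math.pi * s2) + 1.0) + logdetH + logdetA
        )
    return ll, (beta, s2, A, w, S)


def fit_lmm(
    data: ModelData,
    criterion: str = "ML",
    rotation: Rotation | None = None,
) -> FitResult:
    """Maximise the (restricted) likelihood over (beta, var_kin, var_resid).

    The variance ratio is located on a 64-point log grid spanning
    [1e-6, 1e6] (plus the OLS boundary at 0) and refined by bounded
    Brent search; fits that end on the grid boundary are flagged, not
    raised.  Standard errors come from the inverse expected information
    of the GLS step at the variance-component optimum.
    """
    if criterion not in ("ML", "REML"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rot = rotation if rotation is not None else Rotation(data.K, data.person_index)
    yt = rot.rotate(data.y)
    Xt = rot.rotate(data.X)
    lam = rot.eigvals
    n, p = Xt.shape

    lls = np.array([_profile(d, yt, Xt, lam, criterion)[0] for d in _DELTA_GRID])
    k = int(np.argmax(lls))
    boundary = k == len(_DELTA_GRID) - 1
    if k == 0:
        delta_hat, converged = 0.0, True
    else:
        lo = _DELTA_GRID[max(k - 1, 1)]
        hi = _DELTA_GRID[min(k + 1, len(_DELTA_GRID) - 1)]
        if lo >= hi:
            delta_hat, converged = float(_DELTA_GRID[k]), True
        else:
            res = optimize.minimize_scalar(
                lambda t: -_profile(math.exp(t), yt, Xt, lam, criterion)[0],
                bounds=(math.log(lo), math.log(hi)),
                method="bounded",
                options={"xatol": _RATIO_TOL},
            )
            converged = bool(res.success)
            delta_hat = float(math.exp(res.x))
            # guard: Brent should not be worse than the grid point
            if -res.fun < lls[k]:
                delta_hat = float(_DELTA_GRID[k])
        # compare the boundary delta=0 against the refined interior optimum
        if _profile(0.0, yt, Xt, lam, criterion)[0] >= _profile(
            delta_hat, yt, Xt, lam, criterion
        )[0]:
            delta_hat = 0.0

    ll, pieces = _profile(delta_hat, yt, Xt, lam, criterion)
    if pieces is None:
        raise np.linalg.LinAlgError("singular GLS system at the optimum")
    beta, s2, A, w, S = pieces
    degenerate = S / n < _VAR_FLOOR * 1e6
    # Wald SEs use the residual-df-corrected scale (equals the REML scale;
    # under ML it removes the O(p/n) downward bias of S/n)
    beta_cov = np.linalg.inv(A) * max(S / max(n - p, 1), _VAR_FLOOR)
    se = np.sqrt(np.clip(np.diag(beta_cov), 0.0, None))
    vc = VarianceComponents(var_kin=delta_hat * s2, var_resid=s2)
    fit = FitResult(
        beta_hat=beta,
        se=se,
        vc=vc,
        loglik=float(ll),
        blups=np.zeros(data.K.n),
        converged=converged,
        criterion=criterion,
        xnames=list(data.xnames),
        boundary=boundary,
        degenerate=degenerate,
        n_obs=n,
        beta_cov=beta_cov,
    )
    fit.blups = blup(fit, data, rotation=rot)
    return fit


def blup(fit: FitResult, data: ModelData, rotation: Rotation | None = None) -> np.ndarray:
    """Predicted random intercepts ``alpha_hat = s2_kin K Z' V^-1 (y - X beta)``.

    Returned per K individual (zero for individuals without
    observations), computed block-wise.
    """
    rot = rotation if rotation is not None else Rotation(data.K, data.person_index)
    if fit.vc.var_kin <= 0.0:
        return np.zeros(data.K.n)
    r = data.y - data.X @ fit.beta_hat
    rt = rot.rotate(r)
    w = 1.0 / (fit.vc.var_resid + fit.vc.var_kin * rot.eigvals)
    vinv_r_persons = rot.unrotate_to_persons(rt * w)  # Z' V^-1 r
    out = np.zeros(data.K.n)
    for fid, sl in data.K.blocks.items():
        out[sl] = fit.vc.var_kin * (data.K.values[sl, sl] @ vinv_r_persons[sl])
    return out


def wald_test(fit: FitResult, coef: str) -> tuple[float, float, float]:
    """Two-sided Wald test of one fixed effect against zero.

    ``z = estimate / se`` referred to the standard normal (equivalently
    ``z^2`` to chi-square with 1 df).  Returns (estimate, se, p).
    """
    est, se = fit.coef(coef)
    if not np.isfinite(se) or se <= 0.0:
        return est, se, 1.0
    z = est / se
    p = float(stats.chi2.sf(z * z, df=1))
    return est, se, max(p, np.finfo(float).tiny)


class SnpScanner:
    """Vectorised per-SNP Wald scan with variance ratio frozen at a null fit.

    The null model (covariates only) is fitted once; each SNP is then
    tested by weighted least squares in the rotated coordinates, with
    the residual scale re-estimated per SNP.  This is the fast mode used
    for genome-scale null calibration runs; the exact mode refits the
    variance components per SNP.
    """

    def __init__(self, data: ModelData, criterion: str = "ML",
                 rotation: Rotation | None = None):
        self.rot = rotation if rotation is not None else Rotation(data.K, data.person_index)
        self.null_fit = fit_lmm(data, criterion=criterion, rotation=self.rot)
        self.criterion = criterion
        self.n, self.p = data.X.shape
        delta = self.null_fit.vc.ratio
        self.w = 1.0 / (1.0 + delta * self.rot.eigvals)
        self.yt = self.rot.rotate(data.y)
        self.Xt = self.rot.rotate(data.X)
        XtW = self.Xt * self.w[:, None]
        self.XtWX = XtW.T @ self.Xt
        self.XtWy = XtW.T @ self.yt
        self.bhat0 = np.linalg.solve(self.XtWX, self.XtWy)
        r = self.yt - self.Xt @ self.bhat0
        self.S0 = float(np.dot(r * self.w, r))
        self.Wy = self.w * self.yt

    def scan(self, dosages_obs: np.ndarray, chunk: int = 2048):
        """Test each column of ``dosages_obs`` (observation rows x SNPs).

        Returns (effect, se, p, monomorphic) arrays.  Zero-variance SNPs
        are flagged monomorphic with effect 0 and p 1.
        """
        dosages_obs = np.asarray(dosages_obs, dtype=float)
        if dosages_obs.ndim == 1:
            dosages_obs = dosages_obs[:, None]
        m = dosages_obs.shape[1]
        effect = np.zeros(m)
        se = np.full(m, np.inf)
        pval = np.ones(m)
        mono = np.zeros(m, dtype=bool)
        dof = self.n - (self.p + 1)  # residual df with the SNP column
        for s0 in range(0, m, chunk):
            sl = slice(s0, min(s0 + chunk, m))
            G = dosages_obs[:, sl]
            mono_c = np.ptp(G, axis=0) <= 0.0
            Gt = self.rot.rotate(G)
            A = (self.Xt * self.w[:, None]).T @ Gt            # p x m
            C = np.linalg.solve(self.XtWX, A)
            num = Gt.T @ self.Wy - A.T @ self.bhat0           # g'W y residualised
            den = np.einsum("ij,ij->j", Gt * self.w[:, None], Gt) - np.einsum(
                "ij,ij->j", A, C
            )
            ok = (den > 1e-12) & ~mono_c
            beta_s = np.zeros(den.shape[0])
            beta_s[ok] = num[ok] / den[ok]
            rss = np.maximum(self.S0 - beta_s**2 * den, _VAR_FLOOR)
            s2 = rss / max(dof, 1)
            se_c = np.full(den.shape[0], np.inf)
            se_c[ok] = np.sqrt(s2[ok] / den[ok])
            z2 = np.zeros(den.shape[0])
            z2[ok] = (beta_s[ok] / se_c[ok]) ** 2
            p_c = stats.chi2.sf(z2, df=1)
            p_c[~ok] = 1.0
            effect[sl] = beta_s
            se[sl] = se_c
            pval[sl] = np.maximum(p_c, np.finfo(float).tiny)
            mono[sl] = mono_c
        return effect, se, pval, mono
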