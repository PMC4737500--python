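"""Multi-component REML engine for family-structured variance partitioning.

Fits the linear mixed model

    y = X beta + sum_c u_c + eps,   u_c ~ N(0, K_c sigma2_c),
    V = sum_c K_c sigma2_c + I sigma2_e,

by restricted maximum likelihood, where the kernels K_c are any subset of
{GRM_g, GRM_kin, ERM_Family, ERM_Sib, ERM_Couple} (codes G, K, F, S, C) and
a residual identity component is always present.

Numerics: fixed effects are projected out once (thin-QR null-space basis),
so each restricted likelihood is an ordinary Gaussian likelihood in n - p
dimensions with kernels projected once per dataset.  Updates are
average-information (AI) Newton steps with a few expectation-maximisation
warm-up iterations and step-halving; single-kernel models use an exact
eigendecomposition fast path with the same update equations.  Variance-scale
standard errors come from the inverse AI matrix; ratio standard errors from
the delta method with the full sampling covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .errors import ConfigurationError, NumericalError
from .relmat import RelationshipMatrix, grm_eigenvectors, grm_prune

__all__ = [
    "CANONICAL_ORDER",
    "COMPONENT_KINDS",
    "ModelSpec",
    "FitResult",
    "build_fixed_effects",
    "REMLWorkspace",
    "reml_fit",
    "wald_test",
    "h2_vs_cutoff",
]

CANONICAL_ORDER = "GKFSC"
COMPONENT_KINDS = {
    "G": "GRM_g",
    "K": "GRM_kin",
    "F": "ERM_Family",
    "S": "ERM_Sib",
    "C": "ERM_Couple",
}
KIND_TO_CODE = {v: k for k, v in COMPONENT_KINDS.items()}


@dataclass(frozen=True)
class ModelSpec:
    """An ordered subset of the five component codes (residual implied)."""

    components: tuple[str, ...]

    @classmethod
    def parse(cls, code: str) -> "ModelSpec":
        """Parse a model string such as ``"GKC"`` (order-insensitive)."""
        seen = []
        for ch in code.upper():
            if ch not in COMPONENT_KINDS:
                raise ConfigurationError(
                    f"unknown component {ch!r}; valid codes are G, K, F, S, C")
            if ch in seen:
                raise ConfigurationError(f"duplicate component {ch!r} in {code!r}")
            seen.append(ch)
        ordered = tuple(c for c in CANONICAL_ORDER if c in seen)
        return cls(ordered)

    @property
    def code(self) -> str:
        return "".join(self.components) or "E"

    def drop(self, comp: str) -> "ModelSpec":
        if comp not in self.components:
            raise ValueError(f"{comp!r} not in model {self.code!r}")
        return ModelSpec(tuple(c for c in self.components if c != comp))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclass
class FitResult:
    """REML estimates for one model on one dataset.

    ``sigma2``/``se_sigma2`` and ``ratios``/``se_ratios`` are aligned to
    ``components + ("residual",)``; ratios are shares of the summed
    variance and sum to one.
    """

    components: tuple[str, ...]
    sigma2: np.ndarray
    se_sigma2: np.ndarray
    ratios: np.ndarray
    se_ratios: np.ndarray
    logL: float
    n: int
    n_fixed: int
    n_iter: int
    converged: bool
    ai: np.ndarray
    sigma2_cov: np.ndarray
    beta: np.ndarray | None = None
    fixed_names: list[str] | None = None

    def _index(self, comp: str) -> int:
        if comp == "residual":
            return len(self.components)
        return self.components.index(comp)

    def sigma2_of(self, comp: str) -> float:
        return float(self.sigma2[self._index(comp)])

    def se_of(self, comp: str) -> float:
        return float(self.se_sigma2[self._index(comp)])

    def ratio_of(self, comp: str) -> float:
        return float(self.ratios[self._index(comp)])

    def ratio_se_of(self, comp: str) -> float:
        return float(self.se_ratios[self._index(comp)])

    @property
    def h2_gkin(self) -> float:
        """Total heritability: SNP plus pedigree-associated shares."""
        return sum(self.ratio_of(c) for c in ("G", "K") if c in self.components)

    def to_hsq_text(self) -> str:
        """GCTA .hsq-style report: one row per component plus summaries."""
        lines = ["Source\tVariance\tSE\tRatio\tRatio_SE"]
        names = [f"V({c})" for c in self.components] + ["V(e)"]
        for name, s2, se, r, rse in zip(
                names, self.sigma2, self.se_sigma2, self.ratios, self.se_ratios):
            lines.append(f"{name}\t{s2:.6f}\t{se:.6f}\t{r:.6f}\t{rse:.6f}")
        lines.append(f"Vp\t{self.sigma2.sum():.6f}")
        if any(c in self.components for c in "GK"):
            lines.append(f"h2_gkin\t{self.h2_gkin:.6f}")
        lines.append(f"logL\t{self.logL:.6f}")
        lines.append(f"n\t{self.n}")
        lines.append(f"iterations\t{self.n_iter}")
        lines.append(f"converged\t{self.converged}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fixed-effect design
# ---------------------------------------------------------------------------


def build_fixed_effects(
    pheno,
    pcs: np.ndarray | None = None,
    covariates: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effect design matrix.

    ``covariates`` selects among ``sex`` (adds sex, age, age^2, sex*age when
    age is also present), ``age``, ``clinic`` (one-hot, reference level
    dropped) and ``simd`` (standardised, plus its square); ``None``
    auto-selects whichever of these columns the table has.  ``pcs`` columns
    (ancestry/structure eigenvectors) are appended last.  Collinear columns
    are dropped with a warning; a design with no usable column raises.
    """
    cols: list[np.ndarray] = [np.ones(len(pheno))]
    names: list[str] = ["intercept"]

    if covariates is None:
        covariates = [c for c in ("sex", "age", "clinic", "simd")
                      if c in pheno.columns]
    else:
        for c in covariates:
            if c not in pheno.columns:
                raise KeyError(f"covariate {c!r} not in phenotype table")

    have = set(covariates)
    if "sex" in have:
        cols.append(pheno["sex"].to_numpy(float))
        names.append("sex")
    if "age" in have:
        age = pheno["age"].to_numpy(float)
        cols += [age, age ** 2]
        names += ["age", "age2"]
        if "sex" in have:
            cols.append(pheno["sex"].to_numpy(float) * age)
            names.append("sex_age")
    if "clinic" in have:
        levels = sorted(pheno["clinic"].dropna().unique())
        for lev in levels[1:]:
            cols.append((pheno["clinic"] == lev).to_numpy(float))
            names.append(f"clinic_{lev}")
    if "simd" in have:
        simd = pheno["simd"].to_numpy(float)
        z = (simd - np.nanmean(simd)) / np.nanstd(simd)
        cols += [z, z ** 2]
        names += ["simd", "simd2"]

    X = np.column_stack(cols)
    if pcs is not None:
        X = np.column_stack([X, pcs])
        names += [f"pc{j + 1}" for j in range(pcs.shape[1])]

    keep = _independent_columns(X)
    if not keep.any():
        raise ConfigurationError("fixed-effect design has rank zero")
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping collinear fixed-effect column(s): {dropped}",
                      stacklevel=2)
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def _independent_columns(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Boolean mask of a maximal linearly independent column subset."""
    obs = np.isfinite(X).all(axis=1)
    Xo = X[obs] if obs.any() else X
    _, r, piv = sla.qr(Xo, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = rtol * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[piv[:rank]] = True
    return keep


# ---------------------------------------------------------------------------
# likelihood evaluators
# ---------------------------------------------------------------------------


class _DenseEval:
    """Dense-path evaluation of the projected restricted likelihood.

    Traces use an explicit inverse (Cholesky + dpotri), which makes the
    per-iteration cost essentially independent of the number of kernels.
    """

    def __init__(self, mats: list[np.ndarray], ytil: np.ndarray):
        self.mats = mats
        self.y = ytil
        self.q = ytil.size

    def __call__(self, theta: np.ndarray):
        v = np.eye(self.q) * theta[-1]
        for m, t in zip(self.mats, theta[:-1]):
            v += m * t
        c, low = sla.cho_factor(v, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        vinv, info = sla.lapack.dpotri(c, lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        vinv = np.tril(vinv) + np.tril(vinv, -1).T
        alpha = vinv @ self.y
        yva = float(self.y @ alpha)
        k = len(self.mats)
        ws = [m @ alpha for m in self.mats] + [alpha]
        qf = np.array([float(alpha @ w) for w in ws[:-1]] + [float(alpha @ alpha)])
        tr = np.array([float(np.sum(vinv * m)) for m in self.mats]
                      + [float(np.trace(vinv))])
        b = np.column_stack(ws)
        ai = 0.5 * (b.T @ vinv @ b)
        return logdet, yva, qf, tr, ai


class _DiagEval:
    """Single-kernel fast path in the kernel's eigenbasis (O(q) per call)."""

    def __init__(self, d: np.ndarray, z: np.ndarray):
        self.d = d
        self.z2 = z * z
        self.q = z.size

    def __call__(self, theta: np.ndarray):
        v = theta[0] * self.d + theta[1]
        if (v <= 0).any():
            raise np.linalg.LinAlgError("projected covariance not PD")
        logdet = float(np.log(v).sum())
        z2v = self.z2 / v
        z2v2 = z2v / v
        z2v3 = z2v2 / v
        yva = float(z2v.sum())
        d = self.d
        qf = np.array([float((d * z2v2).sum()), float(z2v2.sum())])
        tr = np.array([float((d / v).sum()), float((1.0 / v).sum())])
        ai = 0.5 * np.array([
            [float((d * d * z2v3).sum()), float((d * z2v3).sum())],
            [float((d * z2v3).sum()), float(z2v3.sum())],
        ])
        return logdet, yva, qf, tr, ai


# ---------------------------------------------------------------------------
# workspace and fitting
# ---------------------------------------------------------------------------


class REMLWorkspace:
    """Pre-projected kernels for repeated fits on a fixed (X, kernels) pair.

    Building the workspace performs the fixed-effect null-space projection
    and kernel projections once; :meth:`fit` then handles any phenotype
    vector and any component subset, which is what the simulation studies
    and the stepwise selection exploit.
    """

    def __init__(self, X: np.ndarray, kernels: Mapping[str, np.ndarray],
                 fixed_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] <= X.shape[1]:
            raise ConfigurationError("X must be n x p with n > p")
        keep = _independent_columns(X)
        if not keep.all():
            X = X[:, keep]
            if fixed_names:
                fixed_names = [n for n, k in zip(fixed_names, keep) if k]
        self.X = X
        self.fixed_names = fixed_names
        n, p = X.shape
        qfull, r = np.linalg.qr(X, mode="complete")
        self.q2 = qfull[:, p:]
        self.logdet_xtx = 2.0 * float(np.log(np.abs(np.diag(r[:p, :p]))).sum())
        self.n, self.p = n, p
        self.kernels = {c: np.asarray(k, dtype=float) for c, k in kernels.items()}
        self.proj: dict[str, np.ndarray] = {}
        self._eig: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def _projected(self, comp: str) -> np.ndarray:
        if comp not in self.proj:
            k = self.kernels[comp]
            m = self.q2.T @ k @ self.q2
            self.proj[comp] = 0.5 * (m + m.T)
        return self.proj[comp]

    def _eigen(self, comp: str) -> tuple[np.ndarray, np.ndarray]:
        if comp not in self._eig:
            d, u = np.linalg.eigh(self._projected(comp))
            self._eig[comp] = (d, u)
        return self._eig[comp]

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        y: np.ndarray,
        components: Sequence[str] | ModelSpec | str,
        constrained: bool = True,
        start: np.ndarray | None = None,
        max_iter: int = 100,
        tol_logl: float = 1e-8,
        tol_param: float = 1e-6,
        n_em: int = 3,
        compute_beta: bool = True,
    ) -> FitResult:
        """REML-fit the given component subset to phenotype ``y``.

        ``constrained`` (default) projects components that drift negative to
        zero and refits the remainder; the unconstrained mode admits
        negative component variances (as long as V stays positive definite),
        which keeps simulation means unbiased.  ``start`` warm-starts the
        variance vector (components + residual); the default is an equal
        split of the projected phenotypic variance.
        """
        if isinstance(components, ModelSpec):
            comps = components.components
        elif isinstance(components, str):
            comps = ModelSpec.parse(components).components
        else:
            comps = tuple(components)
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ConfigurationError("y length does not match workspace")
        if not np.isfinite(y).all():
            raise ConfigurationError(
                "y contains missing values; align complete cases first "
                "(see reml_fit)")
        if self.n <= self.p + len(comps):
            raise ConfigurationError("too few observations for this model")

        ytil = self.q2.T @ y
        q = ytil.size
        s2p = float(ytil @ ytil) / q
        k = len(comps)
        if start is not None:
            theta = np.asarray(start, dtype=float).copy()
            if theta.shape != (k + 1,):
                raise ConfigurationError("start must have one entry per "
                                         "component plus residual")
            n_em = min(n_em, 1)
        else:
            theta = np.full(k + 1, s2p / (k + 1))

        if constrained:
            result = self._fit_constrained(
                ytil, comps, theta, s2p, max_iter, tol_logl, tol_param, n_em)
        else:
            result = self._fit_core(
                ytil, comps, theta, s2p, max_iter, tol_logl, tol_param, n_em,
                allow_negative=True, floor_residual=False)
        theta, logL, n_iter, converged, ai = result

        if not converged:
            warnings.warn(
                f"REML did not converge in {n_iter} iterations for model "
                f"{''.join(comps) or 'E'}", stacklevel=2)

        cov = _robust_inverse(ai)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        total = float(theta.sum())
        ratios = theta / total
        jac = (np.eye(k + 1) * total - theta[:, None]) / total ** 2
        ratio_cov = jac @ cov @ jac.T
        se_r = np.sqrt(np.clip(np.diag(ratio_cov), 0.0, None))

        beta = None
        if compute_beta:
            beta = self._gls_beta(y, comps, theta)

        return FitResult(
            components=comps, sigma2=theta, se_sigma2=se, ratios=ratios,
            se_ratios=se_r, logL=logL, n=self.n, n_fixed=self.p,
            n_iter=n_iter, converged=converged, ai=ai, sigma2_cov=cov,
            beta=beta, fixed_names=self.fixed_names)

    # -- internals --------------------------------------------------------

    def _evaluator(self, comps: tuple[str, ...], ytil: np.ndarray):
        if len(comps) == 1:
            d, u = self._eigen(comps[0])
            return _DiagEval(d, u.T @ ytil)
        mats = [self._projected(c) for c in comps]
        return _DenseEval(mats, ytil)

    def _fit_constrained(self, ytil, comps, theta, s2p,
                         max_iter, tol_logl, tol_param, n_em):
        """Project-to-zero-and-refit handling of boundary components."""
        k = len(comps)
        if k == 0:
            return self._fit_core(ytil, comps, theta, s2p, max_iter,
                                  tol_logl, tol_param, n_em,
                                  allow_negative=False)
        active = list(range(k))
        theta_full = theta.copy()
        total_iter = 0
        conv = True
        floor_val = 1e-6 * s2p
        while True:
            sub = tuple(comps[i] for i in active)
            t0 = np.clip(np.append(theta_full[active], theta_full[-1]),
                         floor_val, None)
            t, _, it, conv, _ = self._fit_core(
                ytil, sub, t0, s2p, max_iter, tol_logl, tol_param, n_em,
                allow_negative=False)
            total_iter += it
            comp_t = t[:-1]
            at_floor = comp_t <= 2.0 * floor_val
            if not at_floor.any():
                theta_full[:] = 0.0
                theta_full[active] = comp_t
                theta_full[-1] = t[-1]
                break
            # project boundary components to zero, refit the remainder warm
            keep = [a for a, f in zip(active, at_floor) if not f]
            for a, f in zip(active, at_floor):
                if f:
                    theta_full[a] = 0.0
            theta_full[keep] = comp_t[~at_floor]
            theta_full[-1] = t[-1]
            active = keep
            n_em = 1
            if not active:
                t, _, it, _, _ = self._fit_core(
                    ytil, (), theta_full[-1:], s2p, max_iter, tol_logl,
                    tol_param, 0, allow_negative=False)
                total_iter += it
                theta_full[:-1] = 0.0
                theta_full[-1] = t[0]
                break
        # final logL and AI over the full component set (SEs, Wald tests)
        ev = self._evaluator(comps, ytil)
        logdet, yva, qf, tr, ai = ev(theta_full)
        logL = -0.5 * (ytil.size * np.log(2 * np.pi) + logdet + yva
                       + self.logdet_xtx)
        return theta_full, logL, total_iter, conv, ai

    def _fit_core(self, ytil, comps, theta, s2p,
                  max_iter, tol_logl, tol_param, n_em, allow_negative,
                  floor_residual=True):
        """AI-REML iteration with EM warm-up and step-halving.

        ``allow_negative`` admits negative component variances;
        ``floor_residual`` keeps the residual variance strictly positive
        (off in fully unconstrained fits, where only positive definiteness
        of V limits the parameters).
        """
        q = ytil.size
        if not comps:
            # residual-only model: closed form sigma2 = y'y / q
            t = np.array([float(ytil @ ytil) / q])
            logL = _residual_only_logl(ytil, t[0], self.logdet_xtx)
            ai = np.array([[0.5 * qf_e3(ytil, t[0])]])
            return t, logL, 0, True, ai

        ev = self._evaluator(tuple(comps), ytil)
        floor = 1e-10 * s2p

        def try_eval(t):
            if floor_residual and t[-1] <= floor:
                return None
            try:
                return ev(t)
            except np.linalg.LinAlgError:
                return None

        state = try_eval(theta)
        if state is None:
            raise NumericalError("V not positive definite at the start values")
        logdet, yva, qf, tr, ai = state
        logL = -0.5 * (q * np.log(2 * np.pi) + logdet + yva + self.logdet_xtx)

        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            score = -0.5 * (tr - qf)
            if it <= n_em:
                delta = theta ** 2 * (qf - tr) / q
            else:
                delta = None
                if not allow_negative:
                    # active set: keep boundary components pinned when the
                    # gradient still points outward, and take the Newton
                    # step in the free coordinates only
                    pinned = (theta <= 1.5e-6 * s2p) & (score < 0.0)
                    if pinned.any() and not pinned.all():
                        free = ~pinned
                        delta = np.zeros_like(theta)
                        delta[free] = _solve_ai(
                            ai[np.ix_(free, free)], score[free])
                if delta is None:
                    delta = _solve_ai(ai, score)
                # cap pathological steps from a near-singular AI matrix
                cap = 5.0 * max(s2p, float(np.abs(theta).max()))
                biggest = float(np.abs(delta).max())
                if biggest > cap:
                    delta = delta * (cap / biggest)
            step = 1.0
            accepted = None
            for _ in range(30):
                prop = theta + step * delta
                if not allow_negative:
                    # boundary handling: pin at a small positive floor so a
                    # component can still recover in later iterations
                    prop = np.maximum(prop, 1e-6 * s2p)
                res = try_eval(prop)
                if res is not None:
                    logdet_n, yva_n, qf_n, tr_n, ai_n = res
                    logL_n = -0.5 * (q * np.log(2 * np.pi) + logdet_n + yva_n
                                     + self.logdet_xtx)
                    # tolerate small transient decreases: AI steps are not
                    # strictly monotone away from the optimum, and halving
                    # on noise-level dips costs a full re-evaluation
                    if (logL_n >= logL - 1e-6 * (1.0 + abs(logL))
                            or it <= n_em):
                        accepted = (prop, logL_n, qf_n, tr_n, ai_n)
                        break
                step *= 0.5
            if accepted is None and not allow_negative:
                # the AI direction projected onto the boundary may not be an
                # ascent direction; the EM update is monotone and respects
                # positivity, so use it as a safe fallback
                em_prop = np.maximum(theta + theta ** 2 * (qf - tr) / q,
                                     1e-6 * s2p)
                res = try_eval(em_prop)
                if res is not None:
                    logdet_n, yva_n, qf_n, tr_n, ai_n = res
                    logL_n = -0.5 * (q * np.log(2 * np.pi) + logdet_n + yva_n
                                     + self.logdet_xtx)
                    accepted = (em_prop, logL_n, qf_n, tr_n, ai_n)
            if accepted is None:
                raise NumericalError(
                    f"V not positive definite after step-halving at "
                    f"iteration {it}")
            prop, logL_n, qf, tr, ai = accepted
            dl = abs(logL_n - logL) / max(1.0, abs(logL_n))
            dp = np.max(np.abs(prop - theta) / np.maximum(np.abs(prop), 1e-8 * s2p))
            theta, logL = prop, logL_n
            if it > n_em and dl < tol_logl and dp < tol_param:
                converged = True
                break
        return theta, logL, it, converged, ai

    def _gls_beta(self, y, comps, theta):
        v = np.eye(self.n) * theta[-1]
        for c, t in zip(comps, theta[:-1]):
            if t != 0.0:
                v += self.kernels[c] * t
        c, low = sla.cho_factor(v, lower=True, check_finite=False)
        vx = sla.cho_solve((c, low), self.X, check_finite=False)
        xtvx = self.X.T @ vx
        return np.linalg.solve(xtvx, vx.T @ y)


def qf_e3(ytil: np.ndarray, s2: float) -> float:
    """y' V^-3 y for V = s2 I (residual-only AI entry)."""
    return float(ytil @ ytil) / s2 ** 3


def _residual_only_logl(ytil: np.ndarray, s2: float, logdet_xtx: float) -> float:
    q = ytil.size
    return -0.5 * (q * np.log(2 * np.pi) + q * np.log(s2)
                   + float(ytil @ ytil) / s2 + logdet_xtx)


def _solve_ai(ai: np.ndarray, score: np.ndarray) -> np.ndarray:
    try:
        delta = np.linalg.solve(ai, score)
        if np.isfinite(delta).all():
            return delta
    except np.linalg.LinAlgError:
        pass
    ridge = 1e-8 * max(np.trace(ai) / ai.shape[0], 1e-300)
    for _ in range(12):
        try:
            delta = np.linalg.solve(ai + ridge * np.eye(ai.shape[0]), score)
            if np.isfinite(delta).all():
                return delta
        except np.linalg.LinAlgError:
            pass
        ridge *= 10.0
    raise NumericalError("average-information matrix is singular")


def _robust_inverse(ai: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(ai)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    matrices: Sequence[RelationshipMatrix],
    **opts,
) -> FitResult:
    """One-shot REML fit from relationship matrices.

    ``matrices`` must share the workspace's row order with ``y`` and ``X``;
    their ``kind`` tags determine the component codes.  Rows with missing
    ``y`` or ``X`` entries are dropped jointly from all inputs (a single V
    must be coherent across components).  For repeated fits on the same
    dataset build a :class:`REMLWorkspace` instead.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    obs = np.isfinite(y) & np.isfinite(X).all(axis=1)
    kernels = {}
    for m in matrices:
        code = KIND_TO_CODE.get(m.kind)
        if code is None:
            raise ConfigurationError(f"matrix kind {m.kind!r} has no model code")
        kernels[code] = m.values[np.ix_(obs, obs)] if not obs.all() else m.values
    comps = tuple(c for c in CANONICAL_ORDER if c in kernels)
    ws = REMLWorkspace(X[obs], kernels)
    return ws.fit(y[obs], comps, **opts)


def wald_test(fit: FitResult, component: str) -> float:
    """Two-sided Wald p-value for one variance component.

    The statistic ``(sigma2 / se)^2`` is referred to chi-square(1); an
    estimate of exactly zero gives p = 1.
    """
    s2 = fit.sigma2_of(component)
    se = fit.se_of(component)
    if s2 == 0.0:
        return 1.0
    if se <= 0.0:
        raise NumericalError(
            f"component {component!r} has zero SE; Wald test undefined")
    stat = (s2 / se) ** 2
    return float(stats.chi2.sf(stat, df=1))


def h2_vs_cutoff(
    y: np.ndarray,
    X: np.ndarray,
    grm: RelationshipMatrix,
    cutoffs: Sequence[float],
    n_pcs: int = 20,
    min_n: int = 50,
    reuse_pcs: bool = False,
    constrained: bool = True,
):
    """SNP-heritability of model 'G' across relatedness-pruned subsets.

    For each cutoff the GRM is greedily pruned so no pair exceeds it, the
    structure eigenvectors are recomputed on the subset (unless
    ``reuse_pcs``), and model 'G' is refitted.  Returns a DataFrame with
    columns cutoff, n_retained, h2g, se.
    """
    import pandas as pd

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    pos = {iid: i for i, iid in enumerate(grm.ids)}
    global_pcs = grm_eigenvectors(grm, min(n_pcs, grm.n)) if reuse_pcs else None
    rows = []
    for cutoff in cutoffs:
        ids = grm_prune(grm, cutoff)
        if len(ids) < min_n:
            warnings.warn(f"cutoff {cutoff}: only {len(ids)} individuals "
                          f"retained (< {min_n}); skipped", stacklevel=2)
            continue
        idx = np.array([pos[i] for i in ids])
        sub = grm.subset(ids)
        if reuse_pcs:
            pcs = global_pcs[idx]
        else:
            pcs = grm_eigenvectors(sub, min(n_pcs, sub.n - 1))
        Xs = np.column_stack([X[idx], pcs])
        ws = REMLWorkspace(Xs, {"G": sub.values})
        fit = ws.fit(y[idx], ("G",), constrained=constrained)
        rows.append({
            "cutoff": cutoff,
            "n_retained": len(ids),
            "h2g": fit.ratio_of("G"),
            "se": fit.ratio_se_of("G"),
        })
    return pd.DataFrame(rows)
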