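"""Model enumeration, boundary-corrected likelihood-ratio tests and the
backward stepwise selection of variance components.

A variance component tested at zero lies on the boundary of its parameter
space, so the LRT null distribution is the equal mixture
0.5 * chi2(0) + 0.5 * chi2(1); the selection loop removes, at each step, the
component that is non-significant for both the Wald test and the LRT and
has the highest Wald p-value, until every remaining component is
significant for at least one test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
import numpy as np
import pandas as pd
from scipy import stats

from .errors import FamvcError, NumericalError
from .vcengine import (
    CANONICAL_ORDER,
    FitResult,
    ModelSpec,
    REMLWorkspace,
    wald_test,
)

__all__ = ["enumerate_models", "lrt", "stepwise_select", "SelectionTrace",
           "SelectionStep"]


def enumerate_models() -> list[ModelSpec]:
    """All 31 non-empty subsets of {G, K, F, S, C} in canonical order.

    Listed by increasing size, lexicographically within each size by
    canonical component order, so the listing is deterministic.
    """
    out = []
    for r in range(1, 6):
        for combo in combinations(CANONICAL_ORDER, r):
            out.append(ModelSpec(combo))
    return out


def lrt(full: FitResult, reduced: FitResult) -> float:
    """Boundary-mixture LRT p-value for one extra variance component.

    ``p = 0.5 * P(chi2_1 >= LR)`` with ``LR = 2 (logL_full - logL_reduced)``
    clamped at zero (so LR = 0 gives exactly 0.5, the mixture's point mass).
    """
    if not set(reduced.components) < set(full.components):
        raise ValueError(
            f"models {reduced.components} and {full.components} are not "
            "strictly nested")
    lr = 2.0 * (full.logL - reduced.logL)
    if lr < -1e-6:
        warnings.warn(
            f"likelihood ratio {lr:.3g} is negative beyond tolerance; "
            "the full model may not have converged", stacklevel=2)
    lr = max(lr, 0.0)
    return float(0.5 * stats.chi2.sf(lr, df=1))


@dataclass
class SelectionStep:
    """One round of the backward selection."""

    model: ModelSpec
    fit: FitResult
    wald_p: dict[str, float]
    lrt_p: dict[str, float]  # NaN = not computed or reduced fit failed
    removed: str | None


@dataclass
class SelectionTrace:
    """Full record of a stepwise selection run."""

    steps: list[SelectionStep] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def final_model(self) -> ModelSpec:
        return self.steps[-1].model

    @property
    def final_fit(self) -> FitResult:
        return self.steps[-1].fit

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.steps):
            for c in s.model.components:
                rows.append({
                    "step": i,
                    "model": s.model.code,
                    "component": c,
                    "wald_p": s.wald_p.get(c, np.nan),
                    "lrt_p": s.lrt_p.get(c, np.nan),
                    "action": "removed" if s.removed == c else "kept",
                })
            if not s.model.components:
                rows.append({"step": i, "model": "E", "component": "residual",
                             "wald_p": np.nan, "lrt_p": np.nan,
                             "action": "kept"})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def report(self) -> str:
        lines = [f"Stepwise selection (alpha = {self.alpha})"]
        for i, s in enumerate(self.steps):
            lines.append(f"step {i}: model {s.model.code}")
            for c in s.model.components:
                lp = s.lrt_p.get(c, np.nan)
                lp_s = "NA" if np.isnan(lp) else f"{lp:.4g}"
                lines.append(f"    {c}: wald_p={s.wald_p[c]:.4g} lrt_p={lp_s}")
            lines.append(f"  -> removed: {s.removed or 'none'}")
        lines.append(f"final model: {self.final_model.code}")
        return "\n".join(lines) + "\n"


def stepwise_select(
    workspace: REMLWorkspace,
    y: np.ndarray,
    alpha: float = 0.05,
    start_model: str | ModelSpec = "GKFSC",
    lrt_mode: str = "lazy",
    **fit_opts,
) -> SelectionTrace:
    """Backward selection from the full five-component model.

    At each step the current model is fitted (constrained REML); every
    component gets a Wald p-value and an LRT p-value against the model with
    that single component dropped.  The component that is non-significant
    for *both* tests at ``alpha`` and has the highest Wald p-value is
    removed; the loop ends when each remaining component is significant for
    at least one test (or the model is empty).  A reduced model that fails
    to fit or converge records an LRT of NA and the Wald test alone governs
    that component.

    ``lrt_mode="lazy"`` (default) only fits reduced models for components
    whose Wald test is already non-significant — components with Wald
    p <= alpha are significant for at least one test whatever the LRT says,
    so the selection path is identical to ``lrt_mode="all"``, which fills in
    the complete LRT column of the trace.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if lrt_mode not in ("lazy", "all"):
        raise ValueError(f"lrt_mode must be 'lazy' or 'all', got {lrt_mode!r}")
    model = start_model if isinstance(start_model, ModelSpec) \
        else ModelSpec.parse(start_model)
    fit_opts.setdefault("constrained", True)

    try:
        fit = workspace.fit(y, model, **fit_opts)
    except FamvcError as exc:
        raise NumericalError(
            f"initial full-model ({model.code}) fit failed: {exc}") from exc

    trace = SelectionTrace(alpha=alpha)
    while True:
        wald_p = {c: wald_test(fit, c) for c in model.components}
        lrt_p: dict[str, float] = {}
        reduced_fits: dict[str, FitResult] = {}
        for c in model.components:
            if lrt_mode == "lazy" and wald_p[c] <= alpha:
                lrt_p[c] = np.nan  # not needed: Wald already significant
                continue
            sub = model.drop(c)
            red = _try_fit(workspace, y, sub, fit, **fit_opts)
            if red is None:
                lrt_p[c] = np.nan  # NA: Wald alone governs this component
            else:
                reduced_fits[c] = red
                lrt_p[c] = lrt(fit, red)

        removable = [
            c for c in model.components
            if wald_p[c] > alpha and (np.isnan(lrt_p[c]) or lrt_p[c] > alpha)
        ]
        # never triggered in lazy mode for Wald-significant components: their
        # lrt_p is NaN but they fail the wald_p > alpha requirement
        if not removable or not model.components:
            trace.steps.append(SelectionStep(model, fit, wald_p, lrt_p, None))
            break
        best_p = max(wald_p[c] for c in removable)
        # highest Wald p; ties broken towards the later canonical component
        drop = [c for c in removable if wald_p[c] == best_p][-1]
        if drop == "G":
            warnings.warn(
                "removing the SNP-genetic component G from the model",
                stacklevel=2)
        trace.steps.append(SelectionStep(model, fit, wald_p, lrt_p, drop))
        model = model.drop(drop)
        next_fit = reduced_fits.get(drop)
        if next_fit is None:
            next_fit = _try_fit(workspace, y, model, fit, **fit_opts)
            if next_fit is None:
                raise NumericalError(
                    f"model {model.code} failed to fit after removing {drop}")
        fit = next_fit
        if not model.components:
            trace.steps.append(SelectionStep(model, fit, {}, {}, None))
            break
    return trace


def _try_fit(workspace, y, model, parent_fit, **fit_opts):
    """Warm-started fit of a reduced model; None on failure/non-convergence."""
    start = _warm_start(parent_fit, model)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = workspace.fit(y, model, start=start, **fit_opts)
    except FamvcError:
        return None
    return fit if fit.converged else None


def _warm_start(parent: FitResult, model: ModelSpec) -> np.ndarray:
    """Start values for a nested model: parent estimates with the dropped
    components' variance folded into the residual."""
    theta = []
    dropped = 0.0
    for c, s2 in zip(parent.components, parent.sigma2[:-1]):
        if c in model.components:
            theta.append(max(s2, 1e-4 * parent.sigma2.sum()))
        else:
            dropped += max(s2, 0.0)
    theta.append(parent.sigma2[-1] + dropped)
    return np.array(theta)
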