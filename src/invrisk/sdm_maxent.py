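"""Presence-background maximum-entropy habitat-suitability model.

The model fits a Gibbs distribution q_lambda(x) = exp(lambda . f(x)) / Z
over a background sample of landscape cells, choosing the weights to
maximise the L1-penalised presence log-likelihood

    (1/n) sum_i lambda . f(x_i)  -  log Z_lambda  -  sum_j beta_j |lambda_j|

where f(x) are features derived from the environmental covariates and
beta_j = reg_multiplier * s_j / sqrt(n) with s_j the presence standard
deviation of feature j.  This is the classical maxent formulation for
presence-only species distribution modelling: at the optimum the model's
feature expectations match the presence means to within the
regularisation box (the KKT condition |E_q[f_j] - mean_pres f_j| <=
beta_j), and the L1 penalty drives uninformative feature weights to
exactly zero.

Features default to linear + quadratic terms of each covariate, scaled
to [0, 1] by the background minima/maxima (hinge features are available
but off by default).  Prediction uses the logistic transform
p = c q~ / (1 + c q~) with q~ the normalised Gibbs density and
c = exp(H) the exponential of the fitted distribution's entropy, so a
cell indistinguishable from average background scores 0.5.

The penalised objective is convex; it is minimised by FISTA (accelerated
proximal gradient with backtracking line search and restart), with the
L1 term handled exactly by soft-thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .grids import ClimateStack, Layer


class MaxentError(ValueError):
    pass


@dataclass
class FeatureExpansion:
    """Pure feature map: covariates -> scaled linear/quadratic(/hinge) features.

    Scaling constants are the background minima and maxima, stored at
    fit time; transform clamps to [0, 1] so projection onto climates
    outside the training range never extrapolates feature values.
    """

    variables: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    hinge: bool = False
    n_hinge_knots: int = 5

    @classmethod
    def fit(
        cls,
        background: np.ndarray,
        variables: Sequence[str],
        hinge: bool = False,
        n_hinge_knots: int = 5,
    ) -> "FeatureExpansion":
        background = np.asarray(background, dtype=float)
        if background.ndim != 2 or background.shape[1] != len(variables):
            raise MaxentError("background matrix must be cells x variables")
        return cls(
            variables=list(variables),
            mins=background.min(axis=0),
            maxs=background.max(axis=0),
            hinge=hinge,
            n_hinge_knots=n_hinge_knots,
        )

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.maxs > self.mins, self.maxs - self.mins, 1.0)
        return np.clip((X - self.mins) / span, 0.0, 1.0)

    @property
    def feature_names(self) -> list[str]:
        names = [v for v in self.variables] + [f"{v}^2" for v in self.variables]
        if self.hinge:
            knots = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
            names += [f"hinge({v},{k:.3f})" for v in self.variables for k in knots]
        return names

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.variables):
            raise MaxentError(
                f"expected {len(self.variables)} covariate columns, got {X.shape}"
            )
        Z = self._scale(X)
        feats = [Z, Z**2]
        if self.hinge:
            knots = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
            feats.append(
                np.concatenate(
                    [np.maximum(Z - k, 0.0) / (1.0 - k) for k in knots], axis=1
                )
            )
        return np.concatenate(feats, axis=1)


@dataclass
class FitTrace:
    n_iter: int
    objective: float
    converged: bool
    objectives: list[float] = field(default_factory=list)


@dataclass
class MaxentModel:
    """Fitted maxent model: weights, regularisation and normalising constants."""

    expansion: FeatureExpansion
    lam: np.ndarray
    beta: np.ndarray
    reg_multiplier: float
    logZ: float  # log sum_bg exp(lam . f)
    entropy: float  # H of q over the background
    n_background: int
    presence_means: np.ndarray
    background_expectations: np.ndarray
    seed: int | None = None
    trace: FitTrace | None = None

    @property
    def feature_names(self) -> list[str]:
        return self.expansion.feature_names

    def raw_density(self, X: np.ndarray) -> np.ndarray:
        """Normalised Gibbs density q~(x) = exp(lam . f(x) - logZ)."""
        F = self.expansion.transform(X)
        return np.exp(F @ self.lam - self.logZ)

    def logistic(self, X: np.ndarray) -> np.ndarray:
        """Logistic suitability p = c q~ / (1 + c q~), c = exp(H)."""
        F = self.expansion.transform(X)
        # compute in log space: p = 1 / (1 + exp(-(H + lam.f - logZ)))
        eta = self.entropy + F @ self.lam - self.logZ
        return 1.0 / (1.0 + np.exp(-eta))

    def kkt_violation(self) -> float:
        """max_j (|E_q[f_j] - presence mean_j| - beta_j); <= 0 at a clean optimum."""
        gap = np.abs(self.background_expectations - self.presence_means) - self.beta
        return float(gap.max())

    # -- serialisation (structured text so runs are reproducible) ----------

    def to_json(self) -> str:
        d = {
            "variables": self.expansion.variables,
            "mins": self.expansion.mins.tolist(),
            "maxs": self.expansion.maxs.tolist(),
            "hinge": self.expansion.hinge,
            "n_hinge_knots": self.expansion.n_hinge_knots,
            "feature_names": self.feature_names,
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "logZ": self.logZ,
            "entropy": self.entropy,
            "n_background": self.n_background,
            "presence_means": self.presence_means.tolist(),
            "background_expectations": self.background_expectations.tolist(),
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        exp = FeatureExpansion(
            variables=d["variables"],
            mins=np.array(d["mins"]),
            maxs=np.array(d["maxs"]),
            hinge=d["hinge"],
            n_hinge_knots=d["n_hinge_knots"],
        )
        return cls(
            expansion=exp,
            lam=np.array(d["lam"]),
            beta=np.array(d["beta"]),
            reg_multiplier=d["reg_multiplier"],
            logZ=d["logZ"],
            entropy=d["entropy"],
            n_background=d["n_background"],
            presence_means=np.array(d["presence_means"]),
            background_expectations=np.array(d["background_expectations"]),
            seed=d.get("seed"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "MaxentModel":
        return cls.from_json(Path(path).read_text())


def sample_background(
    stack: ClimateStack, n: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of n distinct valid cells; (rows, cols) arrays.

    If the stack has fewer than n valid cells, all of them are used (a
    warning is emitted).
    """
    valid = stack.joint_valid_mask()
    rows, cols = np.nonzero(valid)
    n_valid = rows.size
    if n_valid == 0:
        raise MaxentError("stack has no valid cells to sample")
    if n >= n_valid:
        if n > n_valid:
            import warnings

            warnings.warn(
                f"requested {n} background cells but only {n_valid} valid cells "
                "exist; using all of them",
                stacklevel=2,
            )
        return rows, cols
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_valid, size=n, replace=False)
    idx.sort()
    return rows[idx], cols[idx]


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit_maxent(
    presences: np.ndarray,
    background: np.ndarray,
    expansion: FeatureExpansion | None = None,
    variables: Sequence[str] | None = None,
    reg_multiplier: float = 1.0,
    beta_floor: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 5000,
    seed: int | None = None,
) -> MaxentModel:
    """Fit the penalised maxent model.

    Parameters
    ----------
    presences, background
        Either raw covariate matrices (cells x variables; an expansion
        is then fitted on the background) or, when ``expansion`` is
        given, matrices for that expansion's variables.
    reg_multiplier
        Scales every beta_j; 0 disables regularisation, large values
        shrink all weights to zero.
    tol
        Relative objective-change convergence criterion.
    """
    presences = np.asarray(presences, dtype=float)
    background = np.asarray(background, dtype=float)
    if presences.ndim != 2 or background.ndim != 2:
        raise MaxentError("presence and background matrices must be 2-D")
    if len(presences) < 1:
        raise MaxentError("need at least one presence")
    if len(background) < 2:
        raise MaxentError("need at least two background cells")
    if reg_multiplier < 0:
        raise MaxentError("reg_multiplier must be >= 0")

    if expansion is None:
        if variables is None:
            variables = [f"v{j}" for j in range(background.shape[1])]
        expansion = FeatureExpansion.fit(background, variables)
    Fp = expansion.transform(presences)
    Fb = expansion.transform(background)
    n, m = Fp.shape

    p_mean = Fp.mean(axis=0)
    s = Fp.std(axis=0)
    beta = reg_multiplier * np.maximum(s, beta_floor) / np.sqrt(n)

    def smooth(lam: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Negative unpenalised log-likelihood, its gradient, and q."""
        eta = Fb @ lam
        logZ = logsumexp(eta)
        q = np.exp(eta - logZ)
        g = Fb.T @ q - p_mean
        return logZ - float(p_mean @ lam), g, q

    def objective(lam: np.ndarray) -> float:
        eta = Fb @ lam
        return float(logsumexp(eta) - p_mean @ lam + beta @ np.abs(lam))

    lam = np.zeros(m)
    y = lam.copy()
    t_mom = 1.0
    L = 1.0
    f_y, g_y, _ = smooth(y)
    obj = objective(lam)
    objectives = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # backtracking proximal step from the momentum point y
        while True:
            lam_new = _soft_threshold(y - g_y / L, beta / L)
            diff = lam_new - y
            f_new = smooth(lam_new)[0]
            if f_new <= f_y + g_y @ diff + 0.5 * L * float(diff @ diff) + 1e-12:
                break
            L *= 2.0
            if L > 1e12:
                break
        obj_new = objective(lam_new)
        if obj_new > obj:  # restart momentum if acceleration overshoots
            y = lam.copy()
            t_mom = 1.0
            f_y, g_y, _ = smooth(y)
            lam_new = _soft_threshold(y - g_y / L, beta / L)
            obj_new = objective(lam_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = lam_new + ((t_mom - 1.0) / t_new) * (lam_new - lam)
        lam, t_mom = lam_new, t_new
        f_y, g_y, _ = smooth(y)
        objectives.append(obj_new)
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            converged = True
            obj = obj_new
            break
        obj = obj_new
        L = max(L / 2.0, 1e-10)  # allow the step size to grow back

    eta = Fb @ lam
    logZ = float(logsumexp(eta))
    q = np.exp(eta - logZ)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxentModel(
        expansion=expansion,
        lam=lam,
        beta=beta,
        reg_multiplier=reg_multiplier,
        logZ=logZ,
        entropy=entropy,
        n_background=len(background),
        presence_means=p_mean,
        background_expectations=Fb.T @ q,
        seed=seed,
        trace=FitTrace(n_iter=it, objective=obj, converged=converged, objectives=objectives),
    )


def predict_suitability(
    model: MaxentModel, stack: ClimateStack, raw: bool = False
) -> Layer:
    """Project a fitted model onto a climate stack.

    Returns the logistic suitability layer in [0, 1] (or the raw
    normalised density when ``raw``); cells missing any covariate are
    nodata.
    """
    missing = [v for v in model.expansion.variables if v not in stack]
    if missing:
        raise MaxentError(f"stack is missing covariate layer(s): {', '.join(missing)}")
    sub = stack.subset(model.expansion.variables)
    valid = sub.joint_valid_mask()
    rows, cols = np.nonzero(valid)
    X = sub.extract(rows, cols)
    vals = model.raw_density(X) if raw else model.logistic(X)
    out = np.full((stack.spec.n_rows, stack.spec.n_cols), np.nan)
    out[rows, cols] = vals
    return Layer(spec=stack.spec, name="suitability_raw" if raw else "suitability", values=out)


def presence_features_matrix(
    stack: ClimateStack, occ, variables: Sequence[str]
) -> np.ndarray:
    """Covariate matrix at occurrence cells (valid cells only)."""
    sub = stack.subset(variables)
    valid = sub.joint_valid_mask()
    rows, cols = [], []
    for idx in occ.cell_indices(stack.spec):
        if idx is not None and valid[idx]:
            rows.append(idx[0])
            cols.append(idx[1])
    if not rows:
        raise MaxentError(f"no valid presence cells for species {occ.species!r}")
    return sub.extract(np.array(rows), np.array(cols))
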