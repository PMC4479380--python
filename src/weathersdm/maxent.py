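"""Maximum-entropy presence-background model.

The model estimates a probability distribution ``q(x)`` over background
cell-months that maximises entropy subject to matching the presence sample's
feature means, which is equivalent to the L1-penalised log-linear fit

    max_l  (1/m) sum_i log q_l(x_i)  -  sum_j b_j |l_j|,
    q_l(x) = exp(sum_j l_j f_j(x)) / sum_background exp(sum_j l_j f_j(x)),

with per-feature penalties ``b_j = beta_multiplier * s_j / sqrt(m)`` (``s_j``
the background standard deviation of feature ``j``, ``m`` the presence count).
Features are linear, quadratic and pairwise-product transforms of the climatic
covariates, min-max scaled to [0, 1] on the background (hinge and threshold
classes are deliberately not offered: smooth features give more general,
ecologically plausible response curves).

The *logistic output* maps the raw distribution to a 0-1 suitability via the
fitted distribution's entropy H:  ``e^H q(x) / (1 + e^H q(x))``, which equals
0.5 where a presence is no more likely than at an average background point.

Usage follows the Model/Results convention::

    model = MaxentModel(presence_df, background_df, covariates=[...])
    res = model.fit()
    res.params, res.summary(), res.predict(new_df)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "MaxentResults",
    "MaxentConvergenceError",
    "EvalReport",
    "auc",
    "permutation_importance",
    "select_window_per_variable",
    "correlation_screen",
    "cross_validate",
]

DEFAULT_FEATURE_CLASSES = ("linear", "quadratic", "product")


class MaxentConvergenceError(RuntimeError):
    """Raised when the optimiser exhausts max_iter; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class FeatureSpec:
    """Feature definitions and their background-derived scaling constants."""

    def __init__(
        self,
        covariates: list[str],
        classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES,
        lo: np.ndarray | None = None,
        hi: np.ndarray | None = None,
    ):
        unknown = set(classes) - {"linear", "quadratic", "product"}
        if unknown:
            raise ValueError(f"unsupported feature classes: {sorted(unknown)}")
        self.covariates = list(covariates)
        self.classes = tuple(classes)
        self.names = self._feature_names()
        self.lo = lo
        self.hi = hi

    def _feature_names(self) -> list[str]:
        names = []
        c = self.covariates
        if "linear" in self.classes:
            names += list(c)
        if "quadratic" in self.classes:
            names += [f"{v}^2" for v in c]
        if "product" in self.classes:
            names += [f"{a}*{b}" for i, a in enumerate(c) for b in c[i + 1:]]
        return names

    def raw(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.covariates].to_numpy(float)
        blocks = []
        if "linear" in self.classes:
            blocks.append(X)
        if "quadratic" in self.classes:
            blocks.append(X**2)
        if "product" in self.classes:
            k = X.shape[1]
            iu = np.triu_indices(k, 1)
            blocks.append(X[:, iu[0]] * X[:, iu[1]])
        return np.hstack(blocks)

    @classmethod
    def from_background(
        cls,
        background: pd.DataFrame,
        covariates: list[str] | None = None,
        classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES,
    ) -> "FeatureSpec":
        """Fix feature scaling (and drop constant features) from the background."""
        if covariates is None:
            covariates = list(background.columns)
        spec = cls(covariates, classes)
        F = spec.raw(background)
        lo, hi = F.min(axis=0), F.max(axis=0)
        const = hi <= lo
        if const.any():
            dropped = [n for n, c in zip(spec.names, const) if c]
            warnings.warn(
                f"dropping {len(dropped)} constant feature(s): {dropped}",
                stacklevel=2,
            )
            spec.names = [n for n, c in zip(spec.names, const) if not c]
            spec._keep = ~const
        else:
            spec._keep = np.ones(F.shape[1], dtype=bool)
        spec.lo = lo[spec._keep]
        spec.hi = hi[spec._keep]
        return spec

    def transform(self, table: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Scaled feature matrix in [0, 1] (values outside the background
        range are clamped to the bound)."""
        if self.lo is None:
            raise ValueError("scaling constants unset; build via from_background")
        F = self.raw(table)[:, self._keep]
        F = (F - self.lo) / (self.hi - self.lo)
        if clamp:
            np.clip(F, 0.0, 1.0, out=F)
        return F

    # serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "classes": list(self.classes),
            "names": self.names,
            "lo": self.lo.tolist(),
            "hi": self.hi.tolist(),
            "keep": self._keep.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpec":
        spec = cls(d["covariates"], tuple(d["classes"]))
        spec.names = list(d["names"])
        spec._keep = np.asarray(d["keep"], dtype=bool)
        spec.lo = np.asarray(d["lo"], dtype=float)
        spec.hi = np.asarray(d["hi"], dtype=float)
        return spec


class MaxentModel:
    """Maximum-entropy presence-background model.

    Parameters
    ----------
    presence, background : DataFrame
        Covariate tables (rows: presence records / background points).
    covariates : list of str, optional
        Columns to use; defaults to all shared columns of ``background``.
    feature_classes : tuple of str
        Subset of {"linear", "quadratic", "product"}.
    beta_multiplier : float
        Scales the per-feature L1 penalty ``beta_j = s_j / sqrt(m)``.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        background: pd.DataFrame,
        covariates: list[str] | None = None,
        feature_classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES,
        beta_multiplier: float = 1.0,
        feature_spec: FeatureSpec | None = None,
    ):
        if covariates is None:
            covariates = list(background.columns)
        if len(presence) < 2:
            raise ValueError("need at least 2 presence records")
        if len(background) < 2:
            raise ValueError("need at least 2 background points")
        self.covariates = list(covariates)
        self.presence = presence
        self.background = background
        self.beta_multiplier = float(beta_multiplier)
        self.spec = feature_spec or FeatureSpec.from_background(
            background, self.covariates, feature_classes
        )
        self.F_presence = self.spec.transform(presence)
        self.F_background = self.spec.transform(background, clamp=False)
        m = len(presence)
        s = self.F_background.std(axis=0, ddof=1)
        self.beta = self.beta_multiplier * s / np.sqrt(m)

    # ------------------------------------------------------------------
    def _objective(self, lam: np.ndarray) -> tuple[float, np.ndarray]:
        """Smooth part of the negative penalised objective and its gradient."""
        eta = self.F_background @ lam
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        fbar = self.F_presence.mean(axis=0)
        val = lz - fbar @ lam
        grad = self.F_background.T @ q - fbar
        return val, grad

    def penalized_objective(self, lam: np.ndarray) -> float:
        val, _ = self._objective(lam)
        return float(val + self.beta @ np.abs(lam))

    def fit(
        self, tol: float = 1e-9, max_iter: int = 1000, start: np.ndarray | None = None
    ) -> "MaxentResults":
        """Fit by L-BFGS-B on the split ``lam = a - b`` (a, b >= 0) formulation,
        which renders the L1 penalty smooth on the feasible orthant."""
        J = len(self.spec.names)
        theta0 = np.zeros(2 * J)
        if start is not None:
            theta0[:J] = np.clip(start, 0, None)
            theta0[J:] = np.clip(-start, 0, None)
        trace: list[float] = []

        def fun(theta):
            a, b = theta[:J], theta[J:]
            val, grad = self._objective(a - b)
            pen = self.beta @ (a + b)
            return val + pen, np.concatenate([grad + self.beta, -grad + self.beta])

        def cb(theta):
            trace.append(self.penalized_objective(theta[:J] - theta[J:]))

        res = minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * J),
            callback=cb,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        if res.status == 1:  # iteration limit
            raise MaxentConvergenceError(
                f"maxent fit did not converge in {max_iter} iterations", trace
            )
        lam = res.x[:J] - res.x[J:]
        return MaxentResults(self, lam, objective_trace=trace)


class MaxentResults:
    """Fitted maximum-entropy model: coefficients, normaliser, entropy."""

    def __init__(self, model: MaxentModel, lam: np.ndarray, objective_trace=None):
        self.model = model
        self.params = pd.Series(lam, index=model.spec.names, name="lambda")
        self.objective_trace = list(objective_trace or [])
        eta = model.F_background @ lam
        self.logZ = float(logsumexp(eta))
        self.q_background = np.exp(eta - self.logZ)
        q = self.q_background
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
        self.objective = model.penalized_objective(lam)

    # ------------------------------------------------------------------
    @property
    def nobs_presence(self) -> int:
        return len(self.model.presence)

    @property
    def nobs_background(self) -> int:
        return len(self.model.background)

    def loglike(self) -> float:
        """Mean presence log-likelihood under the raw distribution."""
        fbar = self.model.F_presence.mean(axis=0)
        return float(fbar @ self.params.to_numpy() - self.logZ)

    def linear_predictor(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        F = table if isinstance(table, np.ndarray) else self.model.spec.transform(table)
        return F @ self.params.to_numpy()

    def raw(self, table) -> np.ndarray:
        """Raw distribution value q(x), normalised over the training background."""
        return np.exp(self.linear_predictor(table) - self.logZ)

    def predict(self, table, output: str = "logistic") -> np.ndarray:
        """Suitability for new covariate rows.

        ``output='raw'`` gives q(x); ``'logistic'`` gives
        ``e^H q / (1 + e^H q)`` with H the entropy of the fitted background
        distribution (0.5 at an average background point).
        """
        q = self.raw(table)
        if output == "raw":
            return q
        if output == "logistic":
            z = np.exp(self.entropy) * q
            return z / (1.0 + z)
        raise ValueError(f"unknown output {output!r}")

    def training_scores(self) -> tuple[np.ndarray, np.ndarray]:
        lam = self.params.to_numpy()
        lp_p = self.model.F_presence @ lam
        lp_b = self.model.F_background @ lam
        z = lambda lp: 1.0 / (1.0 + np.exp(-(self.entropy + lp - self.logZ)))
        return z(lp_p), z(lp_b)

    def auc(self) -> float:
        """Training AUC (presences vs background)."""
        p, b = self.training_scores()
        return auc(p, b)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"presences: {self.nobs_presence:>8d}    background: {self.nobs_background}",
            f"features:  {len(self.params):>8d}    classes: {', '.join(self.model.spec.classes)}",
            f"beta multiplier: {self.model.beta_multiplier:.3g}",
            f"entropy H: {self.entropy:.4f}    mean presence loglik: {self.loglike():.4f}",
            f"training AUC: {self.auc():.4f}",
            "-" * 57,
            f"{'feature':<35}{'lambda':>12}",
        ]
        lam = self.params[self.params.abs() > 1e-10]
        for name, v in lam.sort_values(key=np.abs, ascending=False).items():
            lines.append(f"{name:<35}{v:>12.4f}")
        if len(lam) == 0:
            lines.append("(all coefficients zero)")
        return "\n".join(lines)

    # serialisation -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "feature_spec": self.model.spec.to_dict(),
            "lambda": self.params.to_numpy().tolist(),
            "logZ": self.logZ,
            "entropy": self.entropy,
            "beta_multiplier": self.model.beta_multiplier,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class FrozenMaxentModel:
    """Prediction-only model reloaded from JSON serialisation."""

    def __init__(self, spec: FeatureSpec, lam: np.ndarray, logZ: float,
                 entropy: float):
        self.spec = spec
        self.params = pd.Series(lam, index=spec.names, name="lambda")
        self.logZ = float(logZ)
        self.entropy = float(entropy)
        self.covariates = spec.covariates

    @classmethod
    def from_json(cls, path) -> "FrozenMaxentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            FeatureSpec.from_dict(d["feature_spec"]),
            np.asarray(d["lambda"], dtype=float),
            d["logZ"],
            d["entropy"],
        )

    def predict(self, table: pd.DataFrame, output: str = "logistic") -> np.ndarray:
        F = self.spec.transform(table)
        q = np.exp(F @ self.params.to_numpy() - self.logZ)
        if output == "raw":
            return q
        if output == "logistic":
            z = np.exp(self.entropy) * q
            return z / (1.0 + z)
        raise ValueError(f"unknown output {output!r}")


# ----------------------------------------------------------------------
def auc(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background point.

    Mann-Whitney formulation with ties counted one half.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([p, b]))
    rp = ranks[: p.size].sum()
    return float((rp - p.size * (p.size + 1) / 2.0) / (p.size * b.size))


def permutation_importance(
    results: MaxentResults,
    presence: pd.DataFrame | None = None,
    background: pd.DataFrame | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_perm: int = 1,
    permutation: np.ndarray | None = None,
) -> pd.Series:
    """Per-covariate permutation importance, normalised to sum to 100.

    For each covariate the values are permuted jointly across the pooled
    presence + background rows, features are rebuilt with the *original*
    scaling constants, and the drop in training AUC is recorded;
    ``max(0, drop)`` is averaged over ``n_perm`` permutations.  A single
    permutation is the default (matching common practice); increase
    ``n_perm`` for stability.  ``permutation`` injects an explicit pooled-row
    index array (a test hook; the identity permutation gives zero drop).
    """
    model = results.model
    presence = model.presence if presence is None else presence
    background = model.background if background is None else background
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = model.covariates
    lam = results.params.to_numpy()

    def scores(p_df, b_df):
        Fp = model.spec.transform(p_df)
        Fb = model.spec.transform(b_df, clamp=False)
        return Fp @ lam, Fb @ lam

    sp, sb = scores(presence[cov], background[cov])
    auc0 = auc(sp, sb)
    m = len(presence)
    pooled = pd.concat([presence[cov], background[cov]], ignore_index=True)
    drops = {}
    for var in cov:
        vals = []
        for _ in range(n_perm):
            perm = rng.permutation(len(pooled)) if permutation is None else permutation
            shuffled = pooled.copy()
            shuffled[var] = pooled[var].to_numpy()[perm]
            sp_, sb_ = scores(shuffled.iloc[:m], shuffled.iloc[m:])
            vals.append(auc0 - auc(sp_, sb_))
        drops[var] = max(0.0, float(np.mean(vals)))
    out = pd.Series(drops, name="permutation_importance")
    total = out.sum()
    if total <= 0:
        warnings.warn(
            "all permutation AUC drops are zero; reporting equal shares",
            stacklevel=2,
        )
        return pd.Series(100.0 / len(cov), index=out.index, name=out.name)
    return 100.0 * out / total


def select_window_per_variable(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    base_names: list[str] | None = None,
    window_lengths: tuple[int, int] = (12, 36),
    seed: int | None = None,
    beta_multiplier: float = 1.0,
    n_perm: int = 1,
    **fit_kwargs,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Choose the 12- or 36-month version of each covariate.

    Fits the full model on both window versions of every variable, computes
    permutation importances, and keeps the higher-importance version of each;
    ties keep the 12-month (shorter-memory) version.  Returns
    ``(choice, table)`` where ``choice`` maps base name -> chosen column.
    """
    La, Lb = window_lengths
    if base_names is None:
        base_names = sorted(
            {c[: -len(f"_{La}m")] for c in background.columns if c.endswith(f"_{La}m")}
        )
    cols = [f"{b}_{L}m" for b in base_names for L in window_lengths]
    model = MaxentModel(
        presence[cols], background[cols], covariates=cols,
        beta_multiplier=beta_multiplier,
    )
    res = model.fit(**fit_kwargs)
    imp = permutation_importance(res, seed=seed, n_perm=n_perm)
    rows = []
    choice = {}
    for b in base_names:
        ia, ib = imp[f"{b}_{La}m"], imp[f"{b}_{Lb}m"]
        chosen = f"{b}_{La}m" if ia >= ib else f"{b}_{Lb}m"
        choice[b] = chosen
        rows.append({"variable": b, f"imp_{La}m": ia, f"imp_{Lb}m": ib,
                     "chosen": chosen})
    return choice, pd.DataFrame(rows)


def correlation_screen(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    threshold: float = 0.85,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson correlations on the pooled table; |r| >= threshold
    flagged (report-only: nothing is dropped automatically)."""
    if columns is None:
        columns = [c for c in background.columns if c in presence.columns]
    if len(columns) < 2:
        raise ValueError("need at least two covariates to screen")
    pooled = pd.concat([presence[columns], background[columns]], ignore_index=True)
    corr = pooled.corr(method="pearson")
    rows = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = corr.loc[a, b]
            rows.append({"var1": a, "var2": b, "r": r,
                         "flagged": bool(abs(r) >= threshold)})
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Cross-validation summary, optionally with importances and correlations."""

    mean_auc: float
    sd_auc: float
    fold_aucs: list[float]
    k: int
    importance: pd.Series | None = None
    correlations: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    covariates: list[str] | None = None,
    beta_multiplier: float = 1.0,
    **fit_kwargs,
) -> EvalReport:
    """k-fold cross-validation over presences (background reused in full).

    Presences are randomly partitioned into k folds; each fold's AUC is the
    held-out presences scored against the complete background.
    """
    m = len(presence)
    if k > m:
        raise ValueError(f"k={k} exceeds number of presences ({m})")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    aucs = []
    for hold in folds:
        train = np.setdiff1d(order, hold)
        model = MaxentModel(
            presence.iloc[train], background, covariates=covariates,
            beta_multiplier=beta_multiplier,
        )
        res = model.fit(**fit_kwargs)
        sp = res.linear_predictor(presence.iloc[hold])
        sb = res.linear_predictor(background)
        aucs.append(auc(sp, sb))
    aucs = [float(a) for a in aucs]
    return EvalReport(
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)) if k > 1 else 0.0,
        fold_aucs=aucs,
        k=k,
    )
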