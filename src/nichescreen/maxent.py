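"""Presence/background maximum-entropy niche model.

The model is a Gibbs density over a background sample: suitability is driven
by a linear predictor η(x) = β·f(x) over expanded features (linear,
quadratic, hinge, product) of min-max-normalized covariates, and the raw
output is exp(η)/Z with Z summed over the background.  Coefficients maximize
the presence log-likelihood under that density with per-feature L1 penalties
scaled by a regularization multiplier (RM), which yields sparse models; the
penalized problem is solved by active-set coordinate descent with a joint
Newton polish (see ``_solver``), deterministically.

Logistic output follows the entropy/default-prevalence-0.5 convention:
``p = e^H·raw / (1 + e^H·raw)`` where H is the entropy of the fitted raw
distribution over the background sample, so a featureless model predicts 0.5
everywhere.  Complementary log-log output is available as an option.

No numerical parity with any particular Java MaxEnt release is promised;
the model family and its tuning semantics (feature classes, RM) are the
same, which is what the screening and calibration workflow relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

from . import _solver
from .metrics import auc

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the optimizer exhausts max_iter; carries last grad norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(message)
        self.grad_norm = grad_norm


class DegenerateDataError(ValueError):
    """Raised when the data cannot support a fit (e.g. all covariates constant)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# L1 penalty schedule: interpolation tables of beta vs presence sample size,
# following the shape of the published MaxEnt defaults (smaller samples get
# heavier penalties).  Keyed by feature-class group.
DEFAULT_BETA_TABLES: dict[str, list[tuple[float, float]]] = {
    "lqp": [(0, 1.0), (10, 1.0), (30, 0.2), (100, 0.05)],
    "hinge": [(0, 0.5)],  # constant
}


@dataclass(frozen=True)
class EngineConfig:
    """Settings for one model fit.

    Defaults are the standard screening configuration: feature classes
    LQHP, RM 1.0, 10-replicate cross-validation, 10,000 background points.
    """

    feature_classes: tuple[str, ...] = ("L", "Q", "H", "P")
    rm: float = 1.0
    n_replicates: int = 10
    n_background: int = 10000
    n_hinge_knots: int = 16
    seed: int = 0
    convergence_tol: float = 1e-6
    kkt_rel: float = 5e-3
    max_iter: int = 3000
    n_permutations: int = 3
    beta_tables: dict = field(default_factory=lambda: dict(DEFAULT_BETA_TABLES))

    def __post_init__(self) -> None:
        fcs = tuple(fc.upper() for fc in self.feature_classes)
        object.__setattr__(self, "feature_classes", fcs)
        unknown = set(fcs) - {"L", "Q", "H", "P"}
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")
        if self.rm <= 0:
            raise ValueError("rm must be positive")

    def with_fc(self, fc: str) -> "EngineConfig":
        """Copy of this config with feature classes given as e.g. 'LQH'."""
        return replace(self, feature_classes=tuple(fc.upper()))


def beta_for(sample_size: int, group: str, tables: dict) -> float:
    """Interpolated penalty multiplier for a feature-class group."""
    table = tables[group]
    xs = [t[0] for t in table]
    ys = [t[1] for t in table]
    return float(np.interp(sample_size, xs, ys))


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One expanded feature: its class, source variable(s) and knot."""

    name: str
    kind: str  # "linear" | "quadratic" | "product" | "hinge_fwd" | "hinge_rev"
    variables: tuple[str, ...]
    knot: float | None = None


@dataclass
class FeatureMap:
    """Feature descriptors plus the normalization that produced them.

    ``lo``/``hi`` are the per-variable min/max over the presence+background
    rows used at fit time; ``design`` re-applies the same normalization to
    new raw covariates, so prediction is consistent with training.
    """

    variables: list[str]
    lo: np.ndarray
    hi: np.ndarray
    features: list[Feature]

    def normalize(self, raw: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return (raw - self.lo) / span

    def design(self, raw: np.ndarray) -> np.ndarray:
        """Build the design matrix for raw (unnormalized) covariate rows.

        Features are evaluated block-wise (consecutive runs of the same
        kind and source variable share one vectorized expression).
        """
        z = self.normalize(raw)
        cols = np.empty((z.shape[0], len(self.features)))
        for kind, vjs, start, knots in self._blocks():
            if kind == "linear":
                cols[:, start : start + len(vjs)] = z[:, vjs]
            elif kind == "quadratic":
                cols[:, start : start + len(vjs)] = z[:, vjs] ** 2
            elif kind == "product":
                a, b = vjs
                cols[:, start] = z[:, a] * z[:, b]
            elif kind == "hinge_fwd":
                t = knots
                x = z[:, vjs[0] : vjs[0] + 1]
                cols[:, start : start + t.size] = np.maximum(0.0, (x - t) / (1.0 - t))
            else:  # hinge_rev
                t = knots
                x = z[:, vjs[0] : vjs[0] + 1]
                cols[:, start : start + t.size] = np.maximum(0.0, (t - x) / t)
        return cols

    def update_columns(self, cols: np.ndarray, z: np.ndarray, var_j: int) -> None:
        """Recompute in place the design columns that depend on variable j.

        ``z`` is the normalized covariate matrix; only blocks sourcing
        variable ``var_j`` are touched (used by permutation importance,
        where one variable changes at a time).
        """
        for kind, vjs, start, knots in self._blocks():
            if kind in ("linear", "quadratic"):
                hits = np.flatnonzero(np.asarray(vjs) == var_j)
                for h in hits:
                    col = z[:, var_j]
                    cols[:, start + h] = col if kind == "linear" else col ** 2
            elif kind == "product":
                a, b = vjs
                if var_j in (a, b):
                    cols[:, start] = z[:, a] * z[:, b]
            elif vjs[0] == var_j:
                t = knots
                x = z[:, var_j : var_j + 1]
                if kind == "hinge_fwd":
                    cols[:, start : start + t.size] = np.maximum(0.0, (x - t) / (1.0 - t))
                else:
                    cols[:, start : start + t.size] = np.maximum(0.0, (t - x) / t)

    def _blocks(self):
        """Grouped evaluation plan for ``design`` (cached)."""
        plan = getattr(self, "_plan", None)
        if plan is not None:
            return plan
        var_idx = {v: j for j, v in enumerate(self.variables)}
        plan = []
        k = 0
        n = len(self.features)
        while k < n:
            f = self.features[k]
            if f.kind in ("linear", "quadratic"):
                vjs = [var_idx[f.variables[0]]]
                while (
                    k + len(vjs) < n
                    and self.features[k + len(vjs)].kind == f.kind
                ):
                    vjs.append(var_idx[self.features[k + len(vjs)].variables[0]])
                plan.append((f.kind, np.array(vjs), k, None))
                k += len(vjs)
            elif f.kind == "product":
                plan.append(
                    ("product", (var_idx[f.variables[0]], var_idx[f.variables[1]]), k, None)
                )
                k += 1
            else:  # hinge runs share kind and source variable
                knots = [f.knot]
                while (
                    k + len(knots) < n
                    and self.features[k + len(knots)].kind == f.kind
                    and self.features[k + len(knots)].variables == f.variables
                ):
                    knots.append(self.features[k + len(knots)].knot)
                plan.append((f.kind, [var_idx[f.variables[0]]], k, np.array(knots)))
                k += len(knots)
        self._plan = plan
        return plan

    def __len__(self) -> int:
        return len(self.features)


def hinge_knots(n_knots: int) -> np.ndarray:
    """n equally spaced knots strictly inside (0, 1)."""
    return np.arange(1, n_knots + 1) / (n_knots + 1)


def build_feature_map(
    variables: Sequence[str],
    lo: np.ndarray,
    hi: np.ndarray,
    config: EngineConfig,
) -> FeatureMap:
    """Enumerate features for non-constant variables under the config's FCs.

    Constant variables (zero range over the fitting rows) contribute no
    features and are logged.
    """
    variables = list(variables)
    active = [v for j, v in enumerate(variables) if hi[j] > lo[j]]
    skipped = [v for v in variables if v not in active]
    if skipped:
        logger.warning("constant variables skipped in feature expansion: %s", skipped)
    feats: list[Feature] = []
    fcs = set(config.feature_classes)
    if "L" in fcs:
        feats += [Feature(f"L({v})", "linear", (v,)) for v in active]
    if "Q" in fcs:
        feats += [Feature(f"Q({v})", "quadratic", (v,)) for v in active]
    if "P" in fcs:
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                feats.append(
                    Feature(f"P({active[a]},{active[b]})", "product", (active[a], active[b]))
                )
    if "H" in fcs:
        for v in active:
            for t in hinge_knots(config.n_hinge_knots):
                feats.append(Feature(f"Hf({v},{t:.4f})", "hinge_fwd", (v,), knot=float(t)))
            for t in hinge_knots(config.n_hinge_knots):
                feats.append(Feature(f"Hr({v},{t:.4f})", "hinge_rev", (v,), knot=float(t)))
    return FeatureMap(variables=variables, lo=np.asarray(lo, float), hi=np.asarray(hi, float), features=feats)


def expand_features(
    values: np.ndarray, config: EngineConfig, variables: Sequence[str] | None = None
) -> tuple[np.ndarray, FeatureMap]:
    """Design matrix + FeatureMap for already-normalized values in [0, 1]."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if variables is None:
        variables = [f"v{j + 1}" for j in range(values.shape[1])]
    lo = np.zeros(values.shape[1])
    hi = np.ones(values.shape[1])
    rng = values.max(axis=0) - values.min(axis=0)
    hi = np.where(rng > 0, hi, lo)  # constant columns -> zero span -> skipped
    fmap = build_feature_map(variables, lo, hi, config)
    return fmap.design(values), fmap


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class NicheModel:
    """A fitted maximum-entropy niche model."""

    feature_map: FeatureMap
    coefficients: np.ndarray
    log_z: float            # log partition over the training background
    entropy_h: float        # entropy of the fitted raw distribution
    k_params: int           # nonzero coefficients
    training_auc: float
    config: EngineConfig
    n_presences: int
    n_background: int
    permutation_importance: dict[str, float] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return self.feature_map.variables

    def eta(self, raw_values: np.ndarray) -> np.ndarray:
        return self.feature_map.design(raw_values) @ self.coefficients

    def predict_raw(self, raw_values: np.ndarray) -> np.ndarray:
        """Raw output: exp(η)/Z with Z from the training background."""
        return np.exp(self.eta(raw_values) - self.log_z)

    # -- plain-text sidecar -------------------------------------------------

    def to_text(self) -> str:
        lines = ["# nichescreen model v1"]
        lines.append("variables\t" + "\t".join(self.variables))
        lines.append("lo\t" + "\t".join(repr(float(v)) for v in self.feature_map.lo))
        lines.append("hi\t" + "\t".join(repr(float(v)) for v in self.feature_map.hi))
        lines.append(f"log_z\t{float(self.log_z)!r}")
        lines.append(f"entropy_h\t{float(self.entropy_h)!r}")
        lines.append(f"n_presences\t{self.n_presences}")
        lines.append(f"n_background\t{self.n_background}")
        for f, c in zip(self.feature_map.features, self.coefficients):
            knot = "" if f.knot is None else repr(float(f.knot))
            lines.append(f"feature\t{f.kind}\t{','.join(f.variables)}\t{knot}\t{float(c)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, config: EngineConfig | None = None) -> "NicheModel":
        config = config or EngineConfig()
        variables: list[str] = []
        lo = hi = None
        scalars: dict[str, float] = {}
        feats: list[Feature] = []
        coefs: list[float] = []
        for line in text.strip().splitlines():
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            key = parts[0]
            if key == "variables":
                variables = parts[1:]
            elif key == "lo":
                lo = np.array([float(v) for v in parts[1:]])
            elif key == "hi":
                hi = np.array([float(v) for v in parts[1:]])
            elif key in ("log_z", "entropy_h"):
                scalars[key] = float(parts[1])
            elif key in ("n_presences", "n_background"):
                scalars[key] = int(parts[1])
            elif key == "feature":
                kind, vs, knot, coef = parts[1], parts[2], parts[3], parts[4]
                kv = None if knot == "" else float(knot)
                feats.append(Feature(f"{kind}({vs})", kind, tuple(vs.split(",")), knot=kv))
                coefs.append(float(coef))
        fmap = FeatureMap(variables=variables, lo=lo, hi=hi, features=feats)
        coef_arr = np.array(coefs)
        return cls(
            feature_map=fmap,
            coefficients=coef_arr,
            log_z=scalars["log_z"],
            entropy_h=scalars["entropy_h"],
            k_params=int(np.count_nonzero(coef_arr)),
            training_auc=float("nan"),
            config=config,
            n_presences=int(scalars["n_presences"]),
            n_background=int(scalars["n_background"]),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _penalties(x_pres: np.ndarray, fmap: FeatureMap, config: EngineConfig) -> np.ndarray:
    """Per-feature L1 weights: rm · beta_class(m) · sd_j / sqrt(m)."""
    m = x_pres.shape[0]
    sd = x_pres.std(axis=0, ddof=0)
    sd = np.maximum(sd, 1e-3)  # floor for presence-constant features
    lam = np.empty(len(fmap))
    for j, f in enumerate(fmap.features):
        group = "hinge" if f.kind.startswith("hinge") else "lqp"
        lam[j] = config.rm * beta_for(m, group, config.beta_tables) * sd[j] / np.sqrt(m)
    return lam


def _solve_penalized(
    x_pres: np.ndarray,
    x_bg: np.ndarray,
    lam: np.ndarray,
    tol: float,
    max_iter: int,
    beta0: np.ndarray | None = None,
    kkt_rel: float = 5e-3,
) -> np.ndarray:
    """Minimize -fbar·β + logsumexp(X_bg β) + Σ λ|β| (see ``_solver``)."""
    beta, diag = _solver.solve(x_pres, x_bg, lam, tol, max_iter, beta0=beta0, kkt_rel=kkt_rel)
    if not diag.converged:
        # accept near-solutions whose KKT violation is small on the λ scale
        kkt_scale = max(float(lam.max()), tol)
        if diag.kkt <= 0.05 * kkt_scale or diag.last_step < 100 * tol:
            logger.info(
                "solver stopped at iteration cap with KKT violation %.2e; accepted",
                diag.kkt,
            )
            return beta
        raise ConvergenceError(
            f"no convergence in {diag.n_iter} iterations "
            f"(last step {diag.last_step:.2e}, KKT violation {diag.kkt:.2e})",
            grad_norm=diag.kkt,
        )
    return beta


def fit(
    presence_cov: np.ndarray,
    background_cov: np.ndarray,
    config: EngineConfig | None = None,
    variables: Sequence[str] | None = None,
    warm_start: np.ndarray | None = None,
) -> NicheModel:
    """Fit the penalized maximum-entropy model.

    ``presence_cov`` and ``background_cov`` are raw covariate matrices with
    one column per variable; rows containing NaN are dropped (logged).
    Deterministic under (config, data).
    """
    config = config or EngineConfig()
    presence_cov = np.atleast_2d(np.asarray(presence_cov, dtype=float))
    background_cov = np.atleast_2d(np.asarray(background_cov, dtype=float))
    if variables is None:
        variables = [f"v{j + 1}" for j in range(presence_cov.shape[1])]
    pres_ok = ~np.isnan(presence_cov).any(axis=1)
    bg_ok = ~np.isnan(background_cov).any(axis=1)
    if (~pres_ok).any() or (~bg_ok).any():
        logger.info(
            "fit: dropped %d presence and %d background rows with missing covariates",
            int((~pres_ok).sum()), int((~bg_ok).sum()),
        )
    presence_cov = presence_cov[pres_ok]
    background_cov = background_cov[bg_ok]
    if presence_cov.shape[0] < 2:
        raise DegenerateDataError("need at least 2 valid presence rows")

    combined = np.vstack([presence_cov, background_cov])
    lo = combined.min(axis=0)
    hi = combined.max(axis=0)
    fmap = build_feature_map(variables, lo, hi, config)
    if len(fmap) == 0:
        raise DegenerateDataError("all covariates constant; no features to fit")
    x_pres = fmap.design(presence_cov)
    x_bg = fmap.design(background_cov)
    lam = _penalties(x_pres, fmap, config)
    if warm_start is not None and warm_start.shape[0] != len(fmap):
        warm_start = None
    beta = _solve_penalized(
        x_pres, x_bg, lam,
        tol=config.convergence_tol, max_iter=config.max_iter, beta0=warm_start,
        kkt_rel=config.kkt_rel,
    )

    eta_bg = x_bg @ beta
    log_z = float(logsumexp(eta_bg))
    log_raw = eta_bg - log_z
    raw = np.exp(log_raw)
    entropy_h = float(-(raw * log_raw).sum())
    eta_pres = x_pres @ beta
    return NicheModel(
        feature_map=fmap,
        coefficients=beta,
        log_z=log_z,
        entropy_h=entropy_h,
        k_params=int(np.count_nonzero(beta)),
        training_auc=auc(eta_pres, eta_bg),
        config=config,
        n_presences=x_pres.shape[0],
        n_background=x_bg.shape[0],
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_logistic(
    model: NicheModel, raw_values: np.ndarray, output: str = "logistic"
) -> np.ndarray:
    """Suitability in [0, 1] (logistic by default, 'cloglog' optional).

    NaN rows (missing covariates) propagate to NaN outputs.
    """
    raw_values = np.atleast_2d(np.asarray(raw_values, dtype=float))
    ok = ~np.isnan(raw_values).any(axis=1)
    out = np.full(raw_values.shape[0], np.nan)
    if ok.any():
        log_raw = model.eta(raw_values[ok]) - model.log_z
        z = model.entropy_h + log_raw
        if output == "logistic":
            out[ok] = expit(z)
        elif output == "cloglog":
            out[ok] = -np.expm1(-np.exp(z))
        else:
            raise ValueError(f"unknown output type {output!r}")
    return out


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(
    model: NicheModel,
    presence_cov: np.ndarray,
    background_cov: np.ndarray,
    seed: int,
    n_permutations: int | None = None,
) -> dict[str, float]:
    """Percent importance per source variable by training-AUC drop.

    Each variable's raw values are permuted jointly across the combined
    presence+background rows; the drop in training AUC (floored at zero,
    averaged over repeats) is normalized so importances sum to 100.  If
    every drop is zero an all-zero map is returned with a warning.
    """
    n_perm = n_permutations or model.config.n_permutations
    presence_cov = np.atleast_2d(np.asarray(presence_cov, dtype=float))
    background_cov = np.atleast_2d(np.asarray(background_cov, dtype=float))
    m = presence_cov.shape[0]
    combined = np.vstack([presence_cov, background_cov])
    ok = ~np.isnan(combined).any(axis=1)
    combined = combined[ok]
    is_pres = np.zeros(ok.sum(), dtype=bool)
    is_pres[: int(ok[:m].sum())] = True

    fmap = model.feature_map
    z = fmap.normalize(combined)
    base_cols = fmap.design(combined)
    eta_all = base_cols @ model.coefficients
    base = auc(eta_all[is_pres], eta_all[~is_pres])
    rng = np.random.default_rng(seed)
    drops = {}
    cols = base_cols.copy()
    for j, var in enumerate(model.variables):
        zj = z[:, j].copy()
        acc = 0.0
        for _ in range(n_perm):
            # permuting the normalized column equals permuting the raw one
            z[:, j] = rng.permutation(zj)
            fmap.update_columns(cols, z, j)
            eta_p = cols @ model.coefficients
            acc += max(0.0, base - auc(eta_p[is_pres], eta_p[~is_pres]))
        z[:, j] = zj
        fmap.update_columns(cols, z, j)
        drops[var] = acc / n_perm
    total = sum(drops.values())
    if total <= 0:
        logger.warning("permutation importance: all AUC drops zero; returning zeros")
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


# ---------------------------------------------------------------------------
# Replicate cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ReplicateStat:
    train_auc: float
    test_auc: float
    importance: dict[str, float]


@dataclass
class CrossValResult:
    replicates: list[ReplicateStat]
    mean_train_auc: float
    mean_test_auc: float
    mean_importance: dict[str, float]
    full_model: NicheModel | None


def cross_validate(
    presence_cov: np.ndarray,
    background_cov: np.ndarray,
    config: EngineConfig | None = None,
    variables: Sequence[str] | None = None,
    fit_full: bool = True,
) -> CrossValResult:
    """k-fold replicate cross-validation over presences.

    Presences are shuffled (seeded) into ``config.n_replicates`` folds; each
    replicate trains on the complement and is evaluated on the held-out fold
    against the full background.  Reported AUC and permutation importance
    are replicate means.  The fold count is reduced (with a warning) if
    there are too few presences.
    """
    config = config or EngineConfig()
    presence_cov = np.atleast_2d(np.asarray(presence_cov, dtype=float))
    background_cov = np.atleast_2d(np.asarray(background_cov, dtype=float))
    pres_ok = ~np.isnan(presence_cov).any(axis=1)
    presence_cov = presence_cov[pres_ok]
    m = presence_cov.shape[0]
    k = min(config.n_replicates, m)
    if k < config.n_replicates:
        logger.warning("cross_validate: reducing replicates from %d to %d", config.n_replicates, k)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)

    # the full-data fit doubles as a warm start for every fold; when the
    # caller only needs replicate means, folds chain warm starts instead
    full_model: NicheModel | None = None
    if fit_full or k == 1:
        full_model = fit(presence_cov, background_cov, config, variables=variables)

    stats: list[ReplicateStat] = []
    if k == 1:
        assert full_model is not None
        imp = permutation_importance(
            full_model, presence_cov, background_cov, seed=config.seed,
        )
        full_model.permutation_importance = imp
        stats.append(ReplicateStat(full_model.training_auc, full_model.training_auc, imp))
    else:
        warm = None if full_model is None else full_model.coefficients
        for r, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            model = fit(
                presence_cov[train_idx], background_cov, config,
                variables=variables, warm_start=warm,
            )
            if full_model is None:
                warm = model.coefficients
            eta_bg = model.eta(background_cov)
            test_auc = auc(model.eta(presence_cov[test_idx]), eta_bg)
            imp = permutation_importance(
                model, presence_cov[train_idx], background_cov,
                seed=config.seed + 7919 * (r + 1),
            )
            stats.append(ReplicateStat(model.training_auc, test_auc, imp))

    all_vars = stats[0].importance.keys()
    mean_imp = {
        v: float(np.mean([s.importance.get(v, 0.0) for s in stats])) for v in all_vars
    }
    # replicates with all-zero drops would otherwise deflate the mean below 100
    imp_total = sum(mean_imp.values())
    if imp_total > 0:
        mean_imp = {v: 100.0 * x / imp_total for v, x in mean_imp.items()}
    result = CrossValResult(
        replicates=stats,
        mean_train_auc=float(np.mean([s.train_auc for s in stats])),
        mean_test_auc=float(np.mean([s.test_auc for s in stats])),
        mean_importance=mean_imp,
        full_model=full_model,
    )
    if full_model is not None:
        full_model.permutation_importance = mean_imp
    return result
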