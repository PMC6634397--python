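"""Latent class analysis for multivariate categorical indicators.

The model is the classical categorical finite mixture

    P(y_i) = sum_c pi_c  prod_j rho_{c,j,y_ij},

with class prevalences ``pi`` and per-class item-response probabilities
``rho``.  Estimation is by EM over the collapsed table of unique response
patterns (exact, and fast for the modest pattern counts that categorical
indicator sets produce), with multiple random restarts.  Model comparison
uses BIC, sample-size-adjusted BIC and consistent AIC:

    BIC  = -2 l + k ln n
    aBIC = -2 l + k ln((n + 2) / 24)
    cAIC = -2 l + k (ln n + 1)
    k    = (C - 1) + C * sum_j (R_j - 1)

Utilities cover posterior class probabilities, modal assignment, class
separation diagnostics, label-switching resolution against a reference
parameter set, and forward sampling from a parameter set.

Numerical notes: EM iterations use exact M-step updates (so the
log-likelihood trajectory is provably non-decreasing); the returned
parameters are floored at ``rho_floor`` (default 1e-6) and renormalized
once at exit so that posterior evaluation on unseen response patterns never
hits log(0).  Levels are 0-based integers.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from ._util import sample_categorical, sample_categorical_by_class
from .config import INDICATOR_ITEMS, CohortConfig

__all__ = [
    "IndicatorSpec",
    "LCAParameters",
    "LCAFitResult",
    "ModelSelection",
    "default_indicator_spec",
    "params_from_config",
    "log_likelihood",
    "em_fit",
    "fit_statistics",
    "select_model",
    "posterior_matrix",
    "assign_classes",
    "class_separation",
    "match_classes",
    "sample_indicators",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """Ordered indicator items with level counts and variable-group labels."""

    names: tuple[str, ...]
    n_levels: tuple[int, ...]
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("indicator names must be unique")
        if any(r < 2 for r in self.n_levels):
            raise ValueError("every indicator needs at least 2 levels")
        if not self.groups:
            object.__setattr__(self, "groups", self.names)

    @property
    def n_items(self) -> int:
        return len(self.names)


def default_indicator_spec() -> IndicatorSpec:
    names, levels, groups = zip(*INDICATOR_ITEMS)
    return IndicatorSpec(names=names, n_levels=levels, groups=groups)


@dataclass
class LCAParameters:
    """Class prevalences ``pi`` (C,) and item-response ``rho`` (per item, C x R_j)."""

    pi: np.ndarray
    rho: list[np.ndarray]
    item_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = [np.asarray(r, dtype=float) for r in self.rho]
        if not self.item_names:
            self.item_names = tuple(f"item_{j}" for j in range(len(self.rho)))
        if abs(self.pi.sum() - 1.0) > 1e-9 or (self.pi < 0).any():
            raise ValueError("pi must be a probability vector")
        for j, r in enumerate(self.rho):
            if r.shape[0] != self.pi.size:
                raise ValueError(f"rho[{j}] must have one row per class")
            if np.abs(r.sum(axis=1) - 1.0).max() > 1e-9 or (r < 0).any():
                raise ValueError(f"rho[{j}] rows must be distributions")

    @property
    def n_classes(self) -> int:
        return int(self.pi.size)

    @property
    def n_items(self) -> int:
        return len(self.rho)

    @property
    def n_parameters(self) -> int:
        """k = (C-1) + C * sum_j (R_j - 1)."""
        C = self.n_classes
        return (C - 1) + C * sum(r.shape[1] - 1 for r in self.rho)

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "rho": {name: r.tolist() for name, r in zip(self.item_names, self.rho)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LCAParameters":
        names = tuple(d["rho"].keys())
        return cls(pi=np.asarray(d["pi"]), rho=[np.asarray(d["rho"][n]) for n in names], item_names=names)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "LCAParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def params_from_config(config: CohortConfig) -> LCAParameters:
    """The generating-truth LCA parameters embedded in a cohort config."""
    names = tuple(item for item, _l, _g in INDICATOR_ITEMS)
    return LCAParameters(
        pi=np.asarray(config.class_prevalences),
        rho=[np.asarray(config.item_response[n]) for n in names],
        item_names=names,
    )


@dataclass
class LCAFitResult:
    params: LCAParameters
    loglik: float
    n_params: int
    bic: float
    abic: float
    caic: float
    n_iter: int
    n_starts: int
    converged: bool
    seed: int
    n_obs: int
    loglik_path: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# Likelihood machinery (collapsed over unique response patterns)
# ---------------------------------------------------------------------------

def _as_matrix(data) -> np.ndarray:
    arr = np.asarray(data, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("indicator data must be a 2-D (n x J) integer array")
    if (arr < 0).any():
        raise ValueError("indicator levels must be nonnegative integers")
    return arr


def _collapse(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    patterns, inverse, counts = np.unique(arr, axis=0, return_inverse=True, return_counts=True)
    return patterns, counts.astype(float), inverse


def _pattern_class_loglik(patterns: np.ndarray, params: LCAParameters) -> np.ndarray:
    """(C x P) matrix of log prod_j rho_{c,j,y_pj}."""
    C, P = params.n_classes, patterns.shape[0]
    if patterns.shape[1] != params.n_items:
        raise ValueError(
            f"data has {patterns.shape[1]} items but params describe {params.n_items}"
        )
    L = np.zeros((C, P))
    with np.errstate(divide="ignore"):
        for j, r in enumerate(params.rho):
            levels = patterns[:, j]
            if levels.max() >= r.shape[1]:
                raise ValueError(f"item {params.item_names[j]!r} has out-of-range levels")
            L += np.log(r)[:, levels]
    return L


def log_likelihood(data, params: LCAParameters) -> float:
    """Observed-data log-likelihood sum_i log sum_c pi_c prod_j rho_{c,j,y_ij}."""
    arr = _as_matrix(data)
    patterns, w, _ = _collapse(arr)
    L = _pattern_class_loglik(patterns, params)
    with np.errstate(divide="ignore"):
        lp = logsumexp(L + np.log(params.pi)[:, None], axis=0)
    return float(w @ lp)


def fit_statistics(loglik: float, k: int, n: int) -> tuple[float, float, float]:
    """(BIC, aBIC, cAIC) for a fitted model."""
    if n <= 0:
        raise ValueError("n must be positive")
    bic = -2.0 * loglik + k * np.log(n)
    abic = -2.0 * loglik + k * np.log((n + 2) / 24.0)
    caic = -2.0 * loglik + k * (np.log(n) + 1.0)
    return float(bic), float(abic), float(caic)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _em_single(
    patterns: np.ndarray,
    w: np.ndarray,
    n_levels: list[int],
    C: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[np.ndarray], float, int, bool, list[float]]:
    n = float(w.sum())
    J = patterns.shape[1]
    pi = np.full(C, 1.0 / C)
    rho = [rng.dirichlet(np.ones(R), size=C) for R in n_levels]
    path: list[float] = []
    prev = -np.inf
    converged = False
    onehots = [np.eye(n_levels[j])[patterns[:, j]] for j in range(J)]  # P x R_j
    for it in range(1, max_iter + 1):
        L = np.zeros((C, patterns.shape[0]))
        with np.errstate(divide="ignore"):
            for j in range(J):
                L += np.log(rho[j])[:, patterns[:, j]]
            logpost = L + np.log(pi)[:, None]
        norm = logsumexp(logpost, axis=0)
        ll = float(w @ norm)
        path.append(ll)
        resp = np.exp(logpost - norm[None, :]) * w[None, :]  # C x P
        cw = resp.sum(axis=1)  # class weights
        pi = cw / n
        for j in range(J):
            counts = resp @ onehots[j]  # C x R_j
            tot = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                rho[j] = np.where(tot > 0, counts / np.maximum(tot, 1e-300), 1.0 / n_levels[j])
        if np.isfinite(prev) and abs(ll - prev) <= tol * (1.0 + abs(prev)):
            converged = True
            break
        prev = ll
    return pi, rho, path[-1], len(path), converged, path


def em_fit(
    data,
    C: int,
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
    rho_floor: float = 1e-6,
    item_names: tuple[str, ...] | None = None,
    n_levels: list[int] | None = None,
) -> LCAFitResult:
    """Best-of-``n_starts`` EM fit of a C-class model; deterministic given seed.

    ``n_levels`` defaults to ``max(level)+1`` per item (pass explicitly when a
    level may be unobserved).  Non-convergence returns ``converged=False``
    with the best solution found.
    """
    arr = _as_matrix(data)
    if arr.shape[0] == 0:
        raise ValueError("empty indicator data")
    if C < 1:
        raise ValueError("C must be >= 1")
    if arr.shape[0] < C:
        raise ValueError(f"need at least C={C} observations")
    patterns, w, _ = _collapse(arr)
    if n_levels is None:
        n_levels = [int(patterns[:, j].max()) + 1 for j in range(arr.shape[1])]
        n_levels = [max(r, 2) for r in n_levels]
    rng = np.random.default_rng(seed)
    best = None
    for _start in range(max(n_starts, 1)):
        pi, rho, ll, n_iter, conv, path = _em_single(
            patterns, w, n_levels, C, rng, max_iter, tol
        )
        if best is None or ll > best[2]:
            best = (pi, rho, ll, n_iter, conv, path)
    pi, rho, ll, n_iter, conv, path = best
    if rho_floor > 0:
        rho = [np.clip(r, rho_floor, None) for r in rho]
        rho = [r / r.sum(axis=1, keepdims=True) for r in rho]
        pi = np.clip(pi, rho_floor, None)
        pi = pi / pi.sum()
    names = item_names or tuple(f"item_{j}" for j in range(arr.shape[1]))
    params = LCAParameters(pi=pi, rho=rho, item_names=names)
    ll_final = log_likelihood(arr, params)
    n = arr.shape[0]
    k = params.n_parameters
    bic, abic, caic = fit_statistics(ll_final, k, n)
    return LCAFitResult(
        params=params, loglik=ll_final, n_params=k, bic=bic, abic=abic, caic=caic,
        n_iter=n_iter, n_starts=max(n_starts, 1), converged=conv, seed=seed,
        n_obs=n, loglik_path=np.asarray(path),
    )


@dataclass
class ModelSelection:
    fits: list[LCAFitResult]
    c_values: list[int]
    selected: int
    rationale: str


def select_model(
    data,
    c_range=range(1, 9),
    n_starts: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
    elbow_threshold: float = 0.01,
    item_names: tuple[str, ...] | None = None,
    n_levels: list[int] | None = None,
) -> ModelSelection:
    """Fit every C in ``c_range`` and select by BIC minimum / elbow.

    The default selection is the BIC-minimizing C.  When BIC is still
    decreasing at the top of the range (the minimum sits at the largest C,
    so the sweep has not revealed an interior optimum), the relative-elbow
    rule applies instead: scanning C ascending, the smallest C is selected
    at which the relative improvement to the next model,
    (BIC(C) - BIC(C+1)) / |BIC(C)|, falls below ``elbow_threshold``.  The
    full fit table is always available for human review.
    """
    cs = sorted(c_range)
    if not cs:
        raise ValueError("c_range must be non-empty")
    fits = []
    for C in cs:
        try:
            fits.append(
                em_fit(data, C, n_starts=n_starts, max_iter=max_iter, tol=tol,
                       seed=seed + 101 * C, item_names=item_names, n_levels=n_levels)
            )
        except Exception as exc:
            raise RuntimeError(f"EM failed for C={C}: {exc}") from exc
    bics = np.array([f.bic for f in fits])
    arg = int(np.argmin(bics))
    selected = cs[arg]
    rationale = f"BIC minimum at C={selected}"
    if arg == len(cs) - 1 and len(cs) > 1:
        # BIC still decreasing at the top of the range: fall back to the elbow
        for i in range(len(cs) - 1):
            improvement = (bics[i] - bics[i + 1]) / abs(bics[i])
            if improvement < elbow_threshold:
                selected = cs[i]
                rationale = (
                    f"BIC decreasing through C={cs[-1]}; relative improvement from "
                    f"C={cs[i]} to C={cs[i + 1]} is {improvement:.4f} < {elbow_threshold}; "
                    f"selected C={cs[i]}"
                )
                break
        else:
            rationale = f"BIC decreasing through the range; selected C={selected}"
    return ModelSelection(fits=fits, c_values=cs, selected=selected, rationale=rationale)


# ---------------------------------------------------------------------------
# Posteriors, assignment, diagnostics
# ---------------------------------------------------------------------------

def posterior_matrix(data, params: LCAParameters) -> np.ndarray:
    """n x C posterior membership probabilities (rows sum to 1)."""
    arr = _as_matrix(data)
    patterns, _w, inverse = _collapse(arr)
    L = _pattern_class_loglik(patterns, params)
    with np.errstate(divide="ignore"):
        logpost = L + np.log(params.pi)[:, None]
    post = np.exp(logpost - logsumexp(logpost, axis=0)[None, :])
    return post.T[inverse]


def assign_classes(posterior: np.ndarray) -> np.ndarray:
    """Modal class per row (0-based); ties break toward the lowest index."""
    return np.argmax(np.asarray(posterior), axis=1).astype(np.int64)


def class_separation(posterior: np.ndarray, labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """Per-class mean and SD of the assigned-class posterior probability."""
    posterior = np.asarray(posterior)
    labels = np.asarray(labels)
    out: dict[int, tuple[float, float]] = {}
    for c in range(posterior.shape[1]):
        mask = labels == c
        if not mask.any():
            warnings.warn(f"class {c + 1} has no assigned encounters; separation undefined")
            continue
        vals = posterior[mask, c]
        out[c] = (float(vals.mean()), float(vals.std()))
    return out


def match_classes(fitted: LCAParameters, reference: LCAParameters) -> np.ndarray:
    """Permutation resolving label switching: entry c is the fitted class
    matched to reference class c, minimizing total L1 distance between
    item-response profiles (optimal assignment; equals exhaustive search)."""
    if fitted.n_classes != reference.n_classes:
        raise ValueError("class counts differ")
    C = fitted.n_classes
    cost = np.zeros((C, C))
    for j in range(fitted.n_items):
        rf, rr = fitted.rho[j], reference.rho[j]
        cost += np.abs(rr[:, None, :] - rf[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(C, dtype=np.int64)
    perm[rows] = cols
    return perm


def _match_classes_bruteforce(fitted: LCAParameters, reference: LCAParameters) -> np.ndarray:
    """Exhaustive-search twin of :func:`match_classes` (test oracle)."""
    C = fitted.n_classes
    cost = np.zeros((C, C))
    for j in range(fitted.n_items):
        cost += np.abs(reference.rho[j][:, None, :] - fitted.rho[j][None, :, :]).sum(axis=2)
    best, best_perm = np.inf, None
    for perm in itertools.permutations(range(C)):
        total = cost[np.arange(C), perm].sum()
        if total < best:
            best, best_perm = total, perm
    return np.asarray(best_perm, dtype=np.int64)


def sample_indicators(
    params: LCAParameters, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-sample (indicator matrix, 0-based true classes) from a model."""
    rng = np.random.default_rng(seed)
    classes = sample_categorical(rng, params.pi, n)
    cols = [sample_categorical_by_class(rng, r, classes) for r in params.rho]
    return np.column_stack(cols), classes
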