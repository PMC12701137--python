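"""Binary metaheuristic wrapper feature selection.

A feature subset is a bit mask over the columns of a feature matrix; its
quality is the wrapper fitness

    fitness(mask) = 1 - ACC(mask)

where ACC is the stratified cross-validated accuracy of a k-nearest-neighbour
classifier restricted to the masked columns (k = 1 by default). Three
seeded stochastic searches minimize this fitness — binary particle swarm
optimization (sigmoid transfer), an independent-Bernoulli ant colony scheme
with a Fisher-score heuristic, and a binary grey wolf optimizer — alongside
an exhaustive enumeration oracle for small dimensionalities.

All searches keep best-so-far bookkeeping with strict-improvement updates,
so the per-iteration fitness trace is non-increasing and fully reproducible
from the seeds. Fitness evaluations are memoized per search; ``n_evaluations``
counts distinct masks actually cross-validated.

Estimator front-ends (:class:`PSOSelector`, :class:`ACOSelector`,
:class:`GWOSelector`, :class:`ExhaustiveSelector`) follow the sklearn
``SelectorMixin`` contract (``fit`` / ``transform`` / ``get_support``) and
compose with pipelines; the module-level ``*_select`` functions are thin
wrappers over them for :class:`~leukoselect.features.FeatureMatrix` inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import DegenerateSelectionError, FoldError, SizeGuardError
from .features import FeatureMatrix

__all__ = [
    "FitnessSpec",
    "PsoParams",
    "AcoParams",
    "GwoParams",
    "SelectionResult",
    "FitnessEvaluator",
    "fitness",
    "pso_select",
    "aco_select",
    "gwo_select",
    "exhaustive_select",
    "select",
    "PSOSelector",
    "ACOSelector",
    "GWOSelector",
    "ExhaustiveSelector",
    "SELECTOR_REGISTRY",
]


@dataclass(frozen=True)
class FitnessSpec:
    """How a mask's wrapper fitness is evaluated."""

    evaluator: str = "knn"
    k: int = 1
    cv_folds: int = 5
    rng_seed: int = 0
    empty_mask_fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.evaluator != "knn":
            raise ValueError("only the knn evaluator is supported")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1 (tie avoidance)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0.0 <= self.empty_mask_fitness <= 1.0):
            raise ValueError("empty_mask_fitness must lie in [0, 1]")


@dataclass(frozen=True)
class PsoParams:
    """Canonical binary PSO constants (Kennedy–Eberhart velocity rule)."""

    swarm_size: int = 25
    iterations: int = 50
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    v_max: float = 4.0
    transfer: str = "sigmoid"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2 or self.iterations < 1:
            raise ValueError("swarm_size >= 2 and iterations >= 1 required")
        if not (0.0 <= self.w <= 1.0) or self.c1 <= 0 or self.c2 <= 0 or self.v_max <= 0:
            raise ValueError("require w in [0,1], c1, c2 > 0, v_max > 0")
        if self.transfer != "sigmoid":
            raise ValueError("only the sigmoid transfer function is supported")


@dataclass(frozen=True)
class AcoParams:
    """Independent-Bernoulli subset ACO with iteration-best deposit."""

    n_ants: int = 25
    iterations: int = 50
    alpha: float = 1.0
    beta: float = 1.0
    rho: float = 0.2
    tau0: float = 1.0
    q: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants < 2 or self.iterations < 1:
            raise ValueError("n_ants >= 2 and iterations >= 1 required")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")


@dataclass(frozen=True)
class GwoParams:
    """Binary grey wolf optimizer with a linearly decaying exploration coefficient."""

    pack_size: int = 25
    iterations: int = 50
    a_start: float = 2.0
    a_end: float = 0.0
    transfer: str = "sigmoid"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pack_size < 3 or self.iterations < 1:
            raise ValueError("pack_size >= 3 and iterations >= 1 required")
        if not (self.a_start >= self.a_end >= 0.0):
            raise ValueError("require a_start >= a_end >= 0")
        if self.transfer != "sigmoid":
            raise ValueError("only the sigmoid transfer function is supported")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection run: best mask, fitness, and convergence trace."""

    selector: str
    mask: np.ndarray
    best_fitness: float
    trace: tuple[float, ...]
    n_evaluations: int
    params: dict
    seed: int
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=np.int8)
        object.__setattr__(self, "mask", mask)
        trace = tuple(float(t) for t in self.trace)
        object.__setattr__(self, "trace", trace)
        if any(b - a > 1e-12 for a, b in zip(trace, trace[1:])):
            raise ValueError("trace must be non-increasing (best-so-far bookkeeping)")
        if trace and abs(self.best_fitness - trace[-1]) > 1e-12:
            raise ValueError("best_fitness must equal the final trace entry")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def selected_names(self, feature_names: Sequence[str]) -> list[str]:
        return [n for n, b in zip(feature_names, self.mask) if b]

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        out = {
            "selector": self.selector,
            "params": self.params,
            "mask": [int(b) for b in self.mask],
            "best_fitness": float(self.best_fitness),
            "trace": list(self.trace),
            "n_evaluations": int(self.n_evaluations),
            "seed": int(self.seed),
        }
        if feature_names is not None:
            out["feature_names_selected"] = self.selected_names(feature_names)
        return out


# ---------------------------------------------------------------------------
# fitness


class FitnessEvaluator:
    """Memoized wrapper fitness 1 - ACC for masks over a fixed (X, y).

    Folds are stratified and seeded by ``spec.rng_seed`` so a mask's fitness
    is a pure function of (X, y, spec). Leave-one-out is used when
    ``cv_folds`` equals the sample count.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, spec: FitnessSpec):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y)
        self.spec = spec
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if spec.cv_folds == n:
            cv = LeaveOneOut()
        else:
            counts = np.unique(self.y, return_counts=True)[1]
            if counts.min() < spec.cv_folds:
                raise FoldError(
                    f"smallest class has {counts.min()} samples, fewer than cv_folds={spec.cv_folds}"
                )
            cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.rng_seed)
        self._folds = list(cv.split(self.X, self.y))  # folds fixed once; fitness is pure in the mask
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (self.X.shape[1],):
            raise ValueError("mask length must equal the number of features")
        if not mask.any():
            return self.spec.empty_mask_fitness  # convention: worst, no evaluation spent
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            Xm = self.X[:, mask]
            fold_accs = []
            for train, test in self._folds:
                knn = KNeighborsClassifier(n_neighbors=self.spec.k)
                knn.fit(Xm[train], self.y[train])
                fold_accs.append(float(np.mean(knn.predict(Xm[test]) == self.y[test])))
            self._cache[key] = 1.0 - float(np.mean(fold_accs))
            self.n_evaluations += 1
        return self._cache[key]


def _as_xy(features: FeatureMatrix | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.labels
    X, y = features
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def fitness(mask: Sequence[int], features: FeatureMatrix | tuple, spec: FitnessSpec | None = None) -> float:
    """Wrapper fitness 1 - ACC of one mask (see :class:`FitnessEvaluator`)."""
    X, y = _as_xy(features)
    return FitnessEvaluator(X, y, spec or FitnessSpec())(np.asarray(mask))


# ---------------------------------------------------------------------------
# search cores


def _pso_core(evaluate: Callable, d: int, params: PsoParams) -> SelectionResult:
    rng = np.random.default_rng(params.rng_seed)
    n = params.swarm_size
    X = (rng.random((n, d)) < 0.5).astype(np.int8)
    V = rng.uniform(-params.v_max, params.v_max, size=(n, d))

    fits = np.array([evaluate(x) for x in X])
    pbest, pbest_f = X.copy(), fits.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = [gbest_f]

    for _ in range(params.iterations):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        V = params.w * V + params.c1 * r1 * (pbest - X) + params.c2 * r2 * (gbest - X)
        np.clip(V, -params.v_max, params.v_max, out=V)
        U = rng.random((n, d))
        X = (expit(V) > U).astype(np.int8)
        fits = np.array([evaluate(x) for x in X])
        improved = fits < pbest_f  # strict: ties keep the incumbent
        pbest[improved] = X[improved]
        pbest_f[improved] = fits[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace.append(gbest_f)

    return SelectionResult("pso", gbest, gbest_f, tuple(trace), 0, asdict(params), params.rng_seed)


def _fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature Fisher discriminant score, rescaled to (0, 1]."""
    classes = np.unique(y)
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        num += len(Xc) * (Xc.mean(axis=0) - grand) ** 2
        den += len(Xc) * Xc.var(axis=0)
    scores = num / np.maximum(den, 1e-12)
    top = scores.max()
    if top <= 0:
        return np.ones_like(scores)
    return 0.05 + 0.95 * scores / top


def _bit_flip_refine(mask: np.ndarray, f: float, evaluate: Callable) -> tuple[np.ndarray, float]:
    """First-improvement single-bit-flip hill climb (skips the empty mask)."""
    mask = mask.copy()
    improved = True
    while improved:
        improved = False
        for j in range(len(mask)):
            candidate = mask.copy()
            candidate[j] ^= 1
            if not candidate.any():
                continue
            fc = evaluate(candidate)
            if fc < f:
                mask, f, improved = candidate, fc, True
    return mask, f


def _aco_core(evaluate: Callable, d: int, params: AcoParams, eta: np.ndarray) -> SelectionResult:
    rng = np.random.default_rng(params.rng_seed)
    tau = np.full(d, params.tau0, dtype=np.float64)
    best_mask: np.ndarray | None = None
    best_f = np.inf
    trace: list[float] = []
    skipped = 0

    for _ in range(params.iterations):
        attract = tau**params.alpha * eta**params.beta
        p = attract / (attract + 1.0)
        ants = (rng.random((params.n_ants, d)) < p).astype(np.int8)
        nonempty = ants.any(axis=1)
        if not nonempty.any():
            skipped += 1
            warnings.warn("every ant produced an empty mask; iteration skipped", stacklevel=2)
            trace.append(best_f if np.isfinite(best_f) else 1.0)
            tau *= 1.0 - params.rho
            continue
        fits = np.array([evaluate(a) if ne else np.inf for a, ne in zip(ants, nonempty)])
        it_best = int(np.argmin(fits))
        # bit-flip refinement of the iteration champion guards against
        # pheromone stagnation (the standard ACO + local-search coupling)
        refined, refined_f = _bit_flip_refine(ants[it_best], float(fits[it_best]), evaluate)
        if refined_f < best_f:
            best_mask, best_f = refined, refined_f
        tau *= 1.0 - params.rho
        tau[refined.astype(bool)] += params.q * (1.0 - refined_f)
        trace.append(best_f)

    if best_mask is None:
        raise DegenerateSelectionError("all ants produced empty masks in every iteration")
    return SelectionResult(
        "aco", best_mask, best_f, tuple(trace), 0, asdict(params), params.rng_seed,
        aux={"skipped_iterations": skipped, "final_pheromone": tau.tolist()},
    )


def _gwo_core(evaluate: Callable, d: int, params: GwoParams) -> SelectionResult:
    rng = np.random.default_rng(params.rng_seed)
    n = params.pack_size
    pos = rng.uniform(-1.0, 1.0, size=(n, d))
    masks = (expit(pos) > rng.random((n, d))).astype(np.int8)
    fits = np.array([evaluate(m) for m in masks])

    order = np.argsort(fits, kind="stable")[:3]
    leaders_pos = pos[order].copy()
    leaders_mask = masks[order].copy()
    leaders_f = fits[order].astype(float).copy()
    trace = [float(leaders_f[0])]
    hierarchy = [tuple(leaders_f)]

    denom = max(params.iterations - 1, 1)
    for t in range(params.iterations):
        a = params.a_start + (params.a_end - params.a_start) * (t / denom)
        estimates = np.empty((3, n, d))
        for i in range(3):
            r1 = rng.random((n, d))
            r2 = rng.random((n, d))
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            D = np.abs(C * leaders_pos[i] - pos)
            estimates[i] = leaders_pos[i] - A * D
        pos = estimates.mean(axis=0)
        masks = (expit(pos) > rng.random((n, d))).astype(np.int8)
        fits = np.array([evaluate(m) for m in masks])
        # cascade wolves into the alpha/beta/delta hierarchy (strict improvement)
        for i in range(n):
            f = float(fits[i])
            if f < leaders_f[0]:
                leaders_f[1:] = leaders_f[:2]
                leaders_pos[1:] = leaders_pos[:2]
                leaders_mask[1:] = leaders_mask[:2]
                leaders_f[0], leaders_pos[0], leaders_mask[0] = f, pos[i].copy(), masks[i].copy()
            elif f < leaders_f[1]:
                leaders_f[2], leaders_pos[2], leaders_mask[2] = leaders_f[1], leaders_pos[1], leaders_mask[1]
                leaders_f[1], leaders_pos[1], leaders_mask[1] = f, pos[i].copy(), masks[i].copy()
            elif f < leaders_f[2]:
                leaders_f[2], leaders_pos[2], leaders_mask[2] = f, pos[i].copy(), masks[i].copy()
        trace.append(float(leaders_f[0]))
        hierarchy.append(tuple(leaders_f))

    return SelectionResult(
        "gwo", leaders_mask[0], float(leaders_f[0]), tuple(trace), 0,
        asdict(params), params.rng_seed, aux={"hierarchy_trace": hierarchy},
    )


def _exhaustive_core(evaluate: Callable, d: int, max_features: int) -> SelectionResult:
    if d > max_features:
        raise SizeGuardError(f"{d} features exceed the exhaustive-search guard of {max_features}")
    all_masks = [tuple((code >> j) & 1 for j in range(d)) for code in range(1, 2**d)]
    # evaluation order realizes the tie-break: fewer features first, then lexicographic
    all_masks.sort(key=lambda m: (sum(m), m))
    best_mask: np.ndarray | None = None
    best_f = np.inf
    trace: list[float] = []
    for m in all_masks:
        f = evaluate(np.asarray(m, dtype=np.int8))
        if f < best_f:
            best_mask, best_f = np.asarray(m, dtype=np.int8), float(f)
        trace.append(best_f)
    assert best_mask is not None
    return SelectionResult(
        "exhaustive", best_mask, best_f, tuple(trace), 0, {"max_features": max_features}, 0
    )


def _run(core: Callable, features, fitness_spec: FitnessSpec | None, **core_kwargs) -> SelectionResult:
    X, y = _as_xy(features)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    evaluator = FitnessEvaluator(X, y, fitness_spec or FitnessSpec())
    result = core(evaluator, X.shape[1], **core_kwargs)
    object.__setattr__(result, "n_evaluations", evaluator.n_evaluations)
    return result


def pso_select(features, fitness_spec: FitnessSpec | None = None, params: PsoParams | None = None) -> SelectionResult:
    """Binary PSO search for the minimum-fitness feature mask."""
    return _run(_pso_core, features, fitness_spec, params=params or PsoParams())


def aco_select(features, fitness_spec: FitnessSpec | None = None, params: AcoParams | None = None) -> SelectionResult:
    """Subset-ACO search with Fisher-score heuristic and iteration-best deposit."""
    X, y = _as_xy(features)
    eta = _fisher_scores(X, y)
    return _run(_aco_core, features, fitness_spec, params=params or AcoParams(), eta=eta)


def gwo_select(features, fitness_spec: FitnessSpec | None = None, params: GwoParams | None = None) -> SelectionResult:
    """Binary grey-wolf search guided by the alpha/beta/delta hierarchy."""
    return _run(_gwo_core, features, fitness_spec, params=params or GwoParams())


def exhaustive_select(features, fitness_spec: FitnessSpec | None = None, max_features: int = 20) -> SelectionResult:
    """Evaluate every non-empty mask; ties broken by fewer features, then lexicographically."""
    if max_features > 20:
        raise SizeGuardError("max_features may not exceed 20")
    return _run(_exhaustive_core, features, fitness_spec, max_features=max_features)


def select(selector: str, features, fitness_spec: FitnessSpec | None = None, params=None) -> SelectionResult:
    """Dispatch by selector name ('pso', 'aco', 'gwo', 'exhaustive')."""
    try:
        fn = SELECTOR_REGISTRY[selector]
    except KeyError:
        raise ValueError(f"unknown selector {selector!r}; known: {sorted(SELECTOR_REGISTRY)}") from None
    if params is None:
        return fn(features, fitness_spec)
    return fn(features, fitness_spec, params)


SELECTOR_REGISTRY = {
    "pso": pso_select,
    "aco": aco_select,
    "gwo": gwo_select,
    "exhaustive": exhaustive_select,
}


# ---------------------------------------------------------------------------
# sklearn estimator front-ends


class _BaseWrapperSelector(SelectorMixin, BaseEstimator):
    """Shared fit/transform plumbing for the metaheuristic selectors."""

    def __init__(self, k=1, cv_folds=5, empty_mask_fitness=1.0, random_state=0):
        self.k = k
        self.cv_folds = cv_folds
        self.empty_mask_fitness = empty_mask_fitness
        self.random_state = random_state

    def _fitness_spec(self) -> FitnessSpec:
        return FitnessSpec(
            k=self.k,
            cv_folds=self.cv_folds,
            rng_seed=self.random_state,
            empty_mask_fitness=self.empty_mask_fitness,
        )

    def _select(self, X, y) -> SelectionResult:  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.result_ = self._select(X, y)
        self.support_ = self.result_.mask.astype(bool)
        self.best_fitness_ = self.result_.best_fitness
        self.trace_ = self.result_.trace
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class PSOSelector(_BaseWrapperSelector):
    """Binary particle swarm wrapper feature selector (sklearn interface)."""

    def __init__(self, swarm_size=25, iterations=50, w=0.7, c1=1.5, c2=1.5, v_max=4.0,
                 k=1, cv_folds=5, empty_mask_fitness=1.0, random_state=0):
        super().__init__(k=k, cv_folds=cv_folds, empty_mask_fitness=empty_mask_fitness,
                         random_state=random_state)
        self.swarm_size = swarm_size
        self.iterations = iterations
        self.w = w
        self.c1 = c1
        self.c2 = c2
        self.v_max = v_max

    def _select(self, X, y):
        params = PsoParams(swarm_size=self.swarm_size, iterations=self.iterations, w=self.w,
                           c1=self.c1, c2=self.c2, v_max=self.v_max, rng_seed=self.random_state)
        return pso_select((X, y), self._fitness_spec(), params)


class ACOSelector(_BaseWrapperSelector):
    """Ant-colony wrapper feature selector (sklearn interface)."""

    def __init__(self, n_ants=25, iterations=50, alpha=1.0, beta=1.0, rho=0.2, tau0=1.0, q=1.0,
                 k=1, cv_folds=5, empty_mask_fitness=1.0, random_state=0):
        super().__init__(k=k, cv_folds=cv_folds, empty_mask_fitness=empty_mask_fitness,
                         random_state=random_state)
        self.n_ants = n_ants
        self.iterations = iterations
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self.tau0 = tau0
        self.q = q

    def _select(self, X, y):
        params = AcoParams(n_ants=self.n_ants, iterations=self.iterations, alpha=self.alpha,
                           beta=self.beta, rho=self.rho, tau0=self.tau0, q=self.q,
                           rng_seed=self.random_state)
        return aco_select((X, y), self._fitness_spec(), params)


class GWOSelector(_BaseWrapperSelector):
    """Grey-wolf wrapper feature selector (sklearn interface)."""

    def __init__(self, pack_size=25, iterations=50, a_start=2.0, a_end=0.0,
                 k=1, cv_folds=5, empty_mask_fitness=1.0, random_state=0):
        super().__init__(k=k, cv_folds=cv_folds, empty_mask_fitness=empty_mask_fitness,
                         random_state=random_state)
        self.pack_size = pack_size
        self.iterations = iterations
        self.a_start = a_start
        self.a_end = a_end

    def _select(self, X, y):
        params = GwoParams(pack_size=self.pack_size, iterations=self.iterations,
                           a_start=self.a_start, a_end=self.a_end, rng_seed=self.random_state)
        return gwo_select((X, y), self._fitness_spec(), params)


class ExhaustiveSelector(_BaseWrapperSelector):
    """Exact enumeration selector; the verification oracle for small d."""

    def __init__(self, max_features=20, k=1, cv_folds=5, empty_mask_fitness=1.0, random_state=0):
        super().__init__(k=k, cv_folds=cv_folds, empty_mask_fitness=empty_mask_fitness,
                         random_state=random_state)
        self.max_features = max_features

    def _select(self, X, y):
        return exhaustive_select((X, y), self._fitness_spec(), max_features=self.max_features)
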