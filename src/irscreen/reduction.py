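"""Feature extraction and variable selection: PCA, SPA and GA.

All three reduce the wavenumber dimension before discriminant analysis.
PCA extracts orthogonal score directions; the successive projections
algorithm (SPA) and the genetic algorithm (GA) select subsets of the
original wavenumbers, leaving the data space untouched.

SPA and GA are both driven by the same validation cost

    G = (1/N_V) * sum_n g_n,
    g_n = r^2(x_n, m_I(n)) / min_{I(m) != I(n)} r^2(x_n, m_I(m)),

where r^2 is the squared Mahalanobis distance, m_I(n) the mean of sample
x_n's true class and the denominator the distance to the closest wrong
class centre.  Small G means validation samples sit close to their own
class and far from the others; the GA fitness is 1/G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: covariance regularization: add lam*I with lam = REG_FACTOR*trace/dim
#: whenever the smallest eigenvalue falls below REG_EIG_FLOOR
REG_FACTOR = 1e-6
REG_EIG_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# Class statistics and the Mahalanobis cost
# ---------------------------------------------------------------------------


@dataclass
class ClassStatistics:
    """Class means and (pooled / per-class) covariances on a variable subset."""

    classes: np.ndarray
    means: np.ndarray  # (n_classes, p)
    pooled_cov: np.ndarray  # (p, p), regularized
    class_covs: np.ndarray  # (n_classes, p, p), regularized
    regularization: float = 0.0  # lambda actually added to the pooled cov


def regularize_covariance(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Ridge a covariance matrix to positive definiteness if needed.

    Adds ``lam * I`` with ``lam = 1e-6 * trace / dim`` whenever the smallest
    eigenvalue is below 1e-10.  Returns (matrix, lambda applied).
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    min_eig = float(np.linalg.eigvalsh(C)[0])
    if min_eig < REG_EIG_FLOOR:
        lam = REG_FACTOR * np.trace(C) / C.shape[0]
        if lam <= 0:  # zero-trace degenerate matrix: fall back to floor
            lam = REG_EIG_FLOOR
        logger.debug("regularizing covariance: min eig %.3g, lambda %.3g", min_eig, lam)
        return C + lam * np.eye(C.shape[0]), float(lam)
    return C, 0.0


def fit_class_statistics(X: np.ndarray, y: np.ndarray) -> ClassStatistics:
    """Class means, pooled covariance (df-weighted) and per-class covariances."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    p = X.shape[1]
    means = np.empty((classes.size, p))
    covs = np.empty((classes.size, p, p))
    pooled = np.zeros((p, p))
    total_df = 0
    for k, c in enumerate(classes):
        Xk = X[y == c]
        if Xk.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[k] = Xk.mean(axis=0)
        Ck = np.cov(Xk, rowvar=False, ddof=1).reshape(p, p)
        covs[k] = Ck
        pooled += (Xk.shape[0] - 1) * Ck
        total_df += Xk.shape[0] - 1
    pooled /= total_df
    pooled, lam = regularize_covariance(pooled)
    covs = np.stack([regularize_covariance(C)[0] for C in covs])
    return ClassStatistics(classes=classes, means=means, pooled_cov=pooled,
                           class_covs=covs, regularization=lam)


def mahalanobis_sq(x: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> float:
    """Squared Mahalanobis distance (x - mean)^T C^{-1} (x - mean)."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(mean, dtype=float)
    C = np.atleast_2d(np.asarray(covariance, dtype=float))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance not positive definite after regularization"
        ) from exc
    w = np.linalg.solve(L, d.T if d.ndim > 1 else d)
    return float(np.sum(w * w)) if d.ndim == 1 else np.sum(w * w, axis=0)


@dataclass
class CostEvaluation:
    """The validation cost G, its per-sample terms g_n, and N_V."""

    G: float
    g_values: np.ndarray
    n_validation: int
    flagged: np.ndarray  # samples whose wrong-class distance was 0 (g_n = inf)

    @property
    def fitness(self) -> float:
        """1/G, the quantity SPA/GA maximize (capped when G underflows)."""
        if self.G <= 0:
            return np.inf
        return 1.0 / self.G


def cost_g(X_val: np.ndarray, y_val: np.ndarray, stats: ClassStatistics) -> CostEvaluation:
    """Validation cost G: mean over samples of own/wrong Mahalanobis ratio.

    Distances use the pooled training covariance on the candidate variables.
    A validation point exactly at a wrong-class mean gives g_n = +inf and is
    flagged rather than raising.
    """
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_val = np.asarray(y_val)
    L = np.linalg.cholesky(stats.pooled_cov)
    # distances to every class mean, all samples at once
    d2 = np.empty((X_val.shape[0], stats.classes.size))
    for k in range(stats.classes.size):
        w = np.linalg.solve(L, (X_val - stats.means[k]).T)
        d2[:, k] = np.sum(w * w, axis=0)
    own_col = np.searchsorted(stats.classes, y_val)
    own = d2[np.arange(X_val.shape[0]), own_col]
    wrong = np.where(
        np.arange(stats.classes.size)[None, :] == own_col[:, None], np.inf, d2
    ).min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(wrong > 0, own / wrong, np.inf)
    g = np.where((own == 0) & (wrong == 0), np.inf, g)
    flagged = wrong == 0
    if flagged.any():
        logger.warning("cost_g: %d validation sample(s) at a wrong-class mean", flagged.sum())
    return CostEvaluation(G=float(np.mean(g)), g_values=g,
                          n_validation=X_val.shape[0], flagged=flagged)


# ---------------------------------------------------------------------------
# Reduction model container
# ---------------------------------------------------------------------------


@dataclass
class ReductionModel:
    """Either a wavenumber subset (spa/ga) or a PC basis (pca)."""

    kind: str  # 'pca' | 'spa' | 'ga'
    selected: Optional[np.ndarray] = None  # sorted unique variable indices
    mean: Optional[np.ndarray] = None  # pca training mean
    components: Optional[np.ndarray] = None  # (n_components, p) orthonormal rows
    explained_variance: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "pca":
            return (X - self.mean) @ self.components.T
        return X[:, self.selected]

    def to_json_dict(self) -> dict:
        out = {"kind": self.kind, "provenance": self.provenance}
        if self.selected is not None:
            out["selected"] = [int(i) for i in self.selected]
        if self.components is not None:
            out["mean"] = self.mean.tolist()
            out["components"] = self.components.tolist()
            out["explained_variance"] = self.explained_variance.tolist()
        return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_fit(X_train: np.ndarray, n_components: int) -> ReductionModel:
    """PCA of the training matrix: mean-centred SVD basis.

    Loadings are orthonormal, ordered by decreasing explained variance, and
    sign-fixed so that each component's largest-magnitude element is
    positive.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}], got {n_components}")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    components = Vt[:n_components]
    # sign convention: largest-|.| loading element positive
    flip = np.sign(components[np.arange(n_components),
                              np.argmax(np.abs(components), axis=1)])
    flip[flip == 0] = 1.0
    components = components * flip[:, None]
    explained = (s[:n_components] ** 2) / (n - 1)
    return ReductionModel(kind="pca", mean=mean, components=components,
                          explained_variance=explained,
                          provenance={"n_components": n_components})


def pca_transform(model: ReductionModel, X: np.ndarray) -> np.ndarray:
    return model.transform(X)


def choose_pca_components(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_components: int = 20,
) -> ReductionModel:
    """Pick the PC count in 1..max_components minimizing validation cost G."""
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    limit = min(max_components, X_train.shape[0] - 1, X_train.shape[1])
    best = None
    for k in range(1, limit + 1):
        model = pca_fit(X_train, k)
        stats = fit_class_statistics(model.transform(X_train), y_train)
        G = cost_g(model.transform(X_val), y_val, stats).G
        if best is None or G < best[0]:
            best = (G, model)
    G, model = best
    model.provenance["validation_G"] = G
    return model


# ---------------------------------------------------------------------------
# SPA — successive projections algorithm
# ---------------------------------------------------------------------------


def spa_chain(X: np.ndarray, start: int, max_vars: int,
              norm_floor: float = 1e-12) -> list[int]:
    """Projection chain from one starting variable.

    At each step the variable whose column has the largest norm after
    orthogonal projection onto the complement of the span of the chosen
    columns is appended.  Chains truncate (with a log message) when every
    remaining projected norm is ~0 (collinear exhaustion).
    """
    R = np.array(X, dtype=float)  # residual columns, updated in place
    n, p = R.shape
    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    for _ in range(max_vars - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv < norm_floor:
            logger.info("SPA chain from %d truncated: collinear exhaustion", start)
            break
        v = v / nv
        R -= np.outer(v, v @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < norm_floor:
            logger.info("SPA chain from %d truncated: collinear exhaustion", start)
            break
        chain.append(nxt)
        available[nxt] = False
    return chain


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_vars: int = 30,
) -> ReductionModel:
    """Successive projections algorithm variable selection.

    Builds a projection chain from every starting variable, scores every
    chain prefix (lengths 1..max_vars) with the validation cost G, and
    returns the prefix with minimal G.  Ties prefer the shorter prefix, then
    the lower starting index.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n, p = X_train.shape
    max_vars = min(max_vars, n - 1, p)
    if max_vars < 1:
        raise ValueError("max_vars must be >= 1 after clipping to data size")
    best = None  # (G, prefix_len, start, selected)
    for start in range(p):
        chain = spa_chain(X_train, start, max_vars)
        for length in range(1, len(chain) + 1):
            sel = chain[:length]
            stats = fit_class_statistics(X_train[:, sel], y_train)
            G = cost_g(X_val[:, sel], y_val, stats).G
            key = (G, length, start)
            if best is None or key < best[0]:
                best = (key, sel)
    (G, length, start), sel = best
    return ReductionModel(
        kind="spa",
        selected=np.array(sorted(sel), dtype=int),
        provenance={"start": start, "chain_prefix": list(sel),
                    "validation_G": G, "max_vars": max_vars},
    )


# ---------------------------------------------------------------------------
# GA — genetic algorithm wavelength selection
# ---------------------------------------------------------------------------


@dataclass
class GAParams:
    """GA operator settings.

    Defaults follow common chemometric practice for wavelength selection:
    100 generations of 200 chromosomes, crossover probability 0.60, mutation
    probability 0.10 spread over the chromosome length (per-bit rate
    0.10/length), elitism of one, and three independent realizations from
    different random initial populations, keeping the fittest final solution.
    """

    generations: int = 100
    population: int = 200
    p_crossover: float = 0.60
    p_mutation: float = 0.10  # per-chromosome budget; per-bit rate = p_mutation/length
    realizations: int = 3
    elitism: int = 1
    init_active: int = 30  # expected active bits in initial chromosomes
    seed: int = 0


def _ga_fitness(chrom: np.ndarray, X_train, y_train, X_val, y_val) -> float:
    sel = np.nonzero(chrom)[0]
    stats = fit_class_statistics(X_train[:, sel], y_train)
    G = cost_g(X_val[:, sel], y_val, stats).G
    if G <= 0:
        return np.inf
    return 1.0 / G


def _roulette(rng: np.random.Generator, fitness: np.ndarray, size: int) -> np.ndarray:
    f = np.array(fitness, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        return rng.integers(0, f.size, size=size)
    cap = 10.0 * f[finite].max() if f[finite].max() > 0 else 1.0
    f[~finite] = cap
    f = np.clip(f, 0.0, None)
    total = f.sum()
    if total <= 0:
        return rng.integers(0, f.size, size=size)
    return rng.choice(f.size, size=size, p=f / total)


def ga_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    params: GAParams | None = None,
) -> ReductionModel:
    """Genetic-algorithm wavelength selection maximizing fitness 1/G.

    Binary chromosomes over wavenumbers; fitness-proportional (roulette)
    parent selection, single-point crossover, per-bit mutation, elitism of
    one.  Runs ``params.realizations`` independent populations and returns
    the fittest final chromosome.  Empty chromosomes are repaired by
    activating one random bit.  Deterministic given ``params.seed``.
    """
    params = params or GAParams()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    p = X_train.shape[1]
    p_bit = params.p_mutation / p
    master = np.random.default_rng(params.seed)
    realization_seeds = master.integers(0, 2**31 - 1, size=params.realizations)

    best_overall = None  # (fitness, chrom, history, realization)
    for r, rseed in enumerate(realization_seeds):
        rng = np.random.default_rng(int(rseed))
        pop = (rng.random((params.population, p)) < params.init_active / p)
        for c in range(params.population):
            if not pop[c].any():
                pop[c, rng.integers(0, p)] = True
        fitness = np.array([
            _ga_fitness(c, X_train, y_train, X_val, y_val) for c in pop
        ])
        history = [float(np.max(fitness))]
        for _ in range(params.generations):
            elite_idx = int(np.argmax(fitness))
            elite = pop[elite_idx].copy()
            parents = _roulette(rng, fitness, params.population)
            children = pop[parents].copy()
            # single-point crossover on consecutive pairs
            for a in range(0, params.population - 1, 2):
                if rng.random() < params.p_crossover:
                    cut = int(rng.integers(1, p))
                    tail_a = children[a, cut:].copy()
                    children[a, cut:] = children[a + 1, cut:]
                    children[a + 1, cut:] = tail_a
            mut = rng.random(children.shape) < p_bit
            children ^= mut
            for c in range(params.population):
                if not children[c].any():
                    children[c, rng.integers(0, p)] = True
            children[0] = elite  # elitism of one
            pop = children
            fitness = np.array([
                _ga_fitness(c, X_train, y_train, X_val, y_val) for c in pop
            ])
            history.append(float(np.max(fitness)))
        gen_best = int(np.argmax(fitness))
        cand = (float(fitness[gen_best]), pop[gen_best].copy(), history, r)
        if best_overall is None or cand[0] > best_overall[0]:
            best_overall = cand
    fit, chrom, history, r = best_overall
    return ReductionModel(
        kind="ga",
        selected=np.nonzero(chrom)[0].astype(int),
        provenance={
            "fitness": fit,
            "validation_G": (1.0 / fit) if np.isfinite(fit) and fit > 0 else 0.0,
            "best_fitness_history": history,
            "realization": r,
            "params": {
                "generations": params.generations,
                "population": params.population,
                "p_crossover": params.p_crossover,
                "p_mutation": params.p_mutation,
                "realizations": params.realizations,
                "init_active": params.init_active,
                "seed": params.seed,
            },
        },
    )
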