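"""Latent class analysis for one-hot modifier matrices.

The model is a finite mixture of independent Bernoulli indicators
("latent class analysis" for categorical data): each gesture case belongs
to exactly one unobserved class k with weight pi_k, and, given the class,
every indicator column d is an independent Bernoulli(theta_kd). Fitting is
EM to a MAP estimate under weak symmetric smoothing priors
(Beta(a, a) on theta, Dirichlet(a) on pi, a = 1.01 by default) so
parameters stay off the 0/1 boundary; ``prior_strength=1.0`` gives plain
maximum likelihood with numerical clipping.

Model choice follows the constrained procedure used for morph discovery:
for K between 1 and the number of distinct observed modifier combinations,
run several random restarts, keep the best per K, require (a) the modal
class assignment to be a deterministic function of the combination and
(b) every class to contain at least ``min_cluster_n`` cases, and among the
surviving candidates pick the lowest BIC. K = 1 is always eligible, so a
solution always exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_is_fitted


class LatentClassAnalysis(DensityMixin, BaseEstimator):
    """Mixture of independent Bernoulli indicators, fitted by (MAP) EM.

    Parameters
    ----------
    n_classes : int
        Number of latent classes K (>= 1).
    max_iter : int
        EM iteration cap.
    tol : float
        Convergence threshold on the absolute change of the objective.
    prior_strength : float
        Symmetric Beta/Dirichlet parameter ``a``; 1.01 gives light MAP
        smoothing, 1.0 plain maximum likelihood.
    random_state : int or numpy Generator seed material
        Controls the random responsibility initialisation.

    Attributes
    ----------
    weights_ : ndarray of shape (K,)
        Class weights pi (sum to 1).
    theta_ : ndarray of shape (K, D)
        Class-conditional indicator probabilities.
    loglik_ : float
        Observed-data log-likelihood at the final parameters.
    objective_trace_ : list of float
        Per-iteration MAP objective (loglik + log prior); non-decreasing.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, n_classes: int = 2, max_iter: int = 1000,
                 tol: float = 1e-6, prior_strength: float = 1.01,
                 random_state=0):
        self.n_classes = n_classes
        self.max_iter = max_iter
        self.tol = tol
        self.prior_strength = prior_strength
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _validate_X(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a nonempty 2-D array")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary (0/1 indicators)")
        return X.astype(np.float64)

    def _log_components(self, U: np.ndarray) -> np.ndarray:
        """log pi_k + log p(u | theta_k) for unique rows U; shape (n, K)."""
        eps = 1e-12
        th = np.clip(self.theta_, eps, 1 - eps)
        log_th, log_1mth = np.log(th), np.log1p(-th)
        ll = U @ log_th.T + (1.0 - U) @ log_1mth.T
        return ll + np.log(np.clip(self.weights_, eps, None))

    def _log_prior(self) -> float:
        a = self.prior_strength
        if a <= 1.0:
            return 0.0
        eps = 1e-12
        th = np.clip(self.theta_, eps, 1 - eps)
        pi = np.clip(self.weights_, eps, None)
        return float(
            (a - 1.0) * (np.log(th).sum() + np.log1p(-th).sum() + np.log(pi).sum())
        )

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        X = self._validate_X(X)
        n, D = X.shape
        K = self.n_classes
        if K < 1:
            raise ValueError("n_classes must be >= 1")
        if K > n:
            raise ValueError(f"n_classes={K} exceeds number of rows {n}")

        # compress identical rows: the likelihood only depends on unique
        # modifier combinations and their counts
        U, inverse, counts = np.unique(X, axis=0, return_inverse=True,
                                       return_counts=True)
        w = counts.astype(np.float64)
        rng = np.random.default_rng(self.random_state)

        # random responsibility initialisation over unique rows
        resp = rng.dirichlet(np.ones(K), size=len(U))
        a = self.prior_strength
        prior_add = max(a - 1.0, 0.0)
        trace: list[float] = []
        prev = -np.inf
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            # M step (MAP)
            wk = (resp * w[:, None]).sum(axis=0)              # (K,)
            self.weights_ = (wk + prior_add) / (w.sum() + prior_add * K)
            num = (resp * w[:, None]).T @ U                   # (K, D)
            self.theta_ = (num + prior_add) / (wk[:, None] + 2.0 * prior_add)
            # E step
            log_comp = self._log_components(U)                # (U, K)
            log_mix = logsumexp(log_comp, axis=1)
            obj = float(w @ log_mix) + self._log_prior()
            trace.append(obj)
            resp = np.exp(log_comp - log_mix[:, None])
            if abs(obj - prev) < self.tol:
                self.converged_ = True
                prev = obj
                break
            prev = obj

        self.n_iter_ = len(trace)
        self.objective_trace_ = trace
        log_comp = self._log_components(U)
        self.loglik_ = float(w @ logsumexp(log_comp, axis=1))
        self._unique_rows_ = U
        self.n_features_in_ = D
        return self

    def score_rows(self, X) -> np.ndarray:
        """Per-row log-likelihood log p(x)."""
        check_is_fitted(self, "theta_")
        X = self._validate_X(X)
        return logsumexp(self._log_components(X), axis=1)

    def score(self, X, y=None) -> float:
        return float(self.score_rows(X).sum())

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class membership probabilities, shape (n, K)."""
        check_is_fitted(self, "theta_")
        X = self._validate_X(X)
        log_comp = self._log_components(X)
        log_mix = logsumexp(log_comp, axis=1, keepdims=True)
        return np.exp(log_comp - log_mix)

    def predict(self, X) -> np.ndarray:
        """Modal class per row; ties break to the lowest class index."""
        # argmax takes the first maximum, which is the documented tie-break
        return np.argmax(self.predict_proba(X), axis=1)

    def bic(self, X) -> float:
        """BIC = -2 loglik + p ln(n), p = (K-1) + K*D; lower is better."""
        check_is_fitted(self, "loglik_")
        X = self._validate_X(X)
        return compute_bic(self.loglik_, self.n_classes, X.shape[1], X.shape[0])


def compute_bic(loglik: float, K: int, D: int, n: int) -> float:
    """Bayesian information criterion for a K-class, D-indicator LCA fit."""
    if n <= 0:
        raise ValueError("n must be positive")
    p = (K - 1) + K * D
    return -2.0 * loglik + p * np.log(n)


def fit_lca_em(X, K: int, seed=0, max_iter: int = 1000, tol: float = 1e-6,
               prior_strength: float = 1.01) -> LatentClassAnalysis:
    """Functional wrapper: one EM run at fixed K."""
    return LatentClassAnalysis(
        n_classes=K, max_iter=max_iter, tol=tol,
        prior_strength=prior_strength, random_state=seed,
    ).fit(X)


def assign_classes(fit: LatentClassAnalysis, X) -> np.ndarray:
    """Modal posterior assignment (ties to the lowest class index)."""
    return fit.predict(X)


# ---------------------------------------------------------------------------
# constrained solution selection
# ---------------------------------------------------------------------------

def check_deterministic(assignments, combo_ids) -> bool:
    """True iff every observed combination maps to exactly one class."""
    seen: dict = {}
    for c, k in zip(combo_ids, assignments):
        if seen.setdefault(c, k) != k:
            return False
    return True


@dataclass
class Candidate:
    """One (K, best restart) candidate with its constraint-check outcome."""

    K: int
    restart: int
    seed: int
    loglik: float
    bic: float
    eligible: bool
    rejection_reasons: list[str] = field(default_factory=list)


@dataclass
class SolutionChoice:
    """The selected morph solution for one gesture action."""

    fit: LatentClassAnalysis
    assignments: np.ndarray
    candidate_log: list[Candidate]
    accepted: bool = True

    @property
    def K(self) -> int:
        return self.fit.n_classes


def _em_restarts(X: np.ndarray, K: int, seeds: list[int], max_iter: int,
                 tol: float, prior_strength: float):
    """Run all random restarts of EM at one K as a single batched loop.

    Returns (best restart index, weights, theta, loglik, trace of the best
    restart, n_iter, converged flags). Identical rows are compressed to
    unique combinations with counts; all restarts iterate together until
    each has converged (or the cap is hit), which is numerically identical
    to running them one by one.
    """
    U, counts = np.unique(X, axis=0, return_counts=True)
    w = counts.astype(np.float64)
    Un, D = U.shape
    R = len(seeds)
    a = prior_strength
    prior_add = max(a - 1.0, 0.0)
    eps = 1e-12

    resp = np.stack([
        np.random.default_rng(s).dirichlet(np.ones(K), size=Un) for s in seeds
    ])                                                       # (R, Un, K)
    traces = np.full((max_iter, R), np.nan)
    prev = np.full(R, -np.inf)
    done = np.zeros(R, dtype=bool)
    n_total = w.sum()
    weights = theta = None
    it = 0
    for it in range(max_iter):
        rw = resp * w[None, :, None]
        wk = rw.sum(axis=1)                                  # (R, K)
        weights = (wk + prior_add) / (n_total + prior_add * K)
        theta = (np.einsum("ruk,ud->rkd", rw, U) + prior_add) / (
            wk[:, :, None] + 2.0 * prior_add
        )
        th = np.clip(theta, eps, 1 - eps)
        ll = (np.einsum("ud,rkd->ruk", U, np.log(th))
              + np.einsum("ud,rkd->ruk", 1.0 - U, np.log1p(-th))
              + np.log(np.clip(weights, eps, None))[:, None, :])
        log_mix = logsumexp(ll, axis=2)                      # (R, Un)
        obj = log_mix @ w
        if prior_add > 0:
            obj = obj + (a - 1.0) * (
                np.log(th).sum(axis=(1, 2)) + np.log1p(-th).sum(axis=(1, 2))
                + np.log(np.clip(weights, eps, None)).sum(axis=1)
            )
        traces[it] = obj
        resp = np.exp(ll - log_mix[:, :, None])
        done |= np.abs(obj - prev) < tol
        prev = obj
        if done.all():
            break

    loglik = log_mix @ w                                     # (R,)
    best = int(np.argmax(loglik))
    trace = traces[: it + 1, best].tolist()
    return best, weights[best], theta[best], float(loglik[best]), trace, \
        it + 1, done


def restart_seed(master_seed: int, K: int, restart: int) -> int:
    """Deterministic per-(K, restart) seed derived from the master seed.

    Uses a SeedSequence keyed on (master_seed, K, restart), folded to a
    31-bit integer.
    """
    ss = np.random.SeedSequence([int(master_seed), int(K), int(restart)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def select_morph_solution(dataset, restarts: int = 10, min_cluster_n: int = 5,
                          master_seed: int = 0, max_iter: int = 1000,
                          tol: float = 1e-6, prior_strength: float = 1.01,
                          max_classes: int | None = None) -> SolutionChoice:
    """Fit K = 1..Kmax with random restarts and pick the constrained best.

    Kmax is the number of distinct observed modifier-level combinations
    (optionally capped by ``max_classes``). Per K the best restart by
    log-likelihood is kept; a candidate is eligible when its modal
    assignment is deterministic per combination and every class holds at
    least ``min_cluster_n`` cases. The eligible candidate with the lowest
    BIC wins; K = 1 is always eligible, so a solution always exists.

    Parameters
    ----------
    dataset : ActionDataset
    """
    X, _ = dataset.one_hot()
    n, D = X.shape
    combos = dataset.combinations
    kmax = min(dataset.n_combinations, n)
    if max_classes is not None:
        kmax = min(kmax, max_classes)

    log: list[Candidate] = []
    best_fit: dict[int, LatentClassAnalysis] = {}
    for K in range(1, kmax + 1):
        seeds = [restart_seed(master_seed, K, r) for r in range(restarts)]
        r_best, weights, theta, loglik, trace, n_iter, conv = _em_restarts(
            X, K, seeds, max_iter=max_iter, tol=tol,
            prior_strength=prior_strength,
        )
        best = LatentClassAnalysis(
            n_classes=K, max_iter=max_iter, tol=tol,
            prior_strength=prior_strength, random_state=seeds[r_best],
        )
        best.weights_, best.theta_ = weights, theta
        best.loglik_, best.objective_trace_ = loglik, trace
        best.n_iter_, best.converged_ = n_iter, bool(conv[r_best])
        best.n_features_in_ = D
        best_seed, best_restart = seeds[r_best], r_best
        assignments = best.predict(X)
        reasons: list[str] = []
        sizes = np.bincount(assignments, minlength=K)
        if K > 1:
            if not check_deterministic(assignments, combos):
                reasons.append("non-deterministic")
            if sizes.min() < min_cluster_n:
                reasons.append("min_cluster_n")
        log.append(Candidate(
            K=K, restart=best_restart, seed=best_seed,
            loglik=best.loglik_, bic=compute_bic(best.loglik_, K, D, n),
            eligible=not reasons, rejection_reasons=reasons,
        ))
        best_fit[K] = best

    eligible = [c for c in log if c.eligible]
    chosen = min(eligible, key=lambda c: (c.bic, c.K))
    fit = best_fit[chosen.K]
    return SolutionChoice(
        fit=fit, assignments=fit.predict(X), candidate_log=log, accepted=True,
    )
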