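"""Pareto scaling, NIPALS PLS-DA, q2 cross-validation, VIP scores and
permutation validation.

The discriminant model is PLS1 regression on a centred 0/1 group response.
Predictive ability is summarised by q2 = 1 - PRESS/SS from stratified 7-fold
cross-validation (one seventh of the samples withheld per round); q2 > 0.4
is the conventional significance threshold in biological modelling.  Model
validity is further checked by refitting under random group relabelling and
requiring the genuine q2 to exceed the 95th percentile of the permuted ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScaledMatrix",
    "PLSDAModel",
    "VIPResult",
    "PermutationResult",
    "InsufficientDataError",
    "GroupingError",
    "RankError",
    "StratificationError",
    "UndefinedVIPError",
    "pareto_scale",
    "fit_plsda",
    "q2_cross_validate",
    "choose_n_components",
    "vip_scores",
    "permutation_validate",
    "Q2_SIGNIFICANCE_THRESHOLD",
]

#: Conventional q2 threshold for a biologically significant PLS-DA model.
Q2_SIGNIFICANCE_THRESHOLD = 0.4

_TINY = 1e-12


class InsufficientDataError(ValueError):
    pass


class GroupingError(ValueError):
    pass


class RankError(ValueError):
    pass


class StratificationError(ValueError):
    pass


class UndefinedVIPError(ValueError):
    pass


@dataclass
class ScaledMatrix:
    """A column-scaled data matrix together with the parameters to undo it."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    scaling_name: str = "pareto"
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def reconstruct(self) -> np.ndarray:
        """Invert the scaling (checks the stored parameters are faithful)."""
        div = np.where(self.zero_variance, 1.0, np.sqrt(self.column_sds))
        return self.values * div + self.column_means

    def apply_to(self, X: np.ndarray) -> np.ndarray:
        """Scale new rows with the stored (training) parameters."""
        div = np.where(self.zero_variance, 1.0, np.sqrt(self.column_sds))
        return (np.asarray(X, dtype=float) - self.column_means) / div


def pareto_scale(X: np.ndarray) -> ScaledMatrix:
    """Pareto scaling: centre each column, divide by the square root of its SD.

    Pareto scaling (x' = (x - mean)/sqrt(sd), sample SD with n-1) damps the
    dominance of intense resonances without blowing up baseline noise the way
    unit-variance scaling does.  Zero-variance columns are centred, left
    unscaled (divisor 1) and flagged, so bucket indexing stays stable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    if X.shape[0] < 2:
        raise InsufficientDataError("Pareto scaling needs at least 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = sds <= _TINY
    div = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, sds)))
    return ScaledMatrix((X - means) / div, means, sds, "pareto", zero)


# ---------------------------------------------------------------------------
# NIPALS PLS1


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequential NIPALS for a single centred response.

    Per component: w = X'y normalised, t = Xw, p = X't/(t't), c = y't/(t't),
    then X and y are deflated.  Returns (W, P, T, c).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    c = np.zeros(n_components)
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm <= _TINY:
            raise RankError(f"component {a + 1} exceeds the rank of X")
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt <= _TINY:
            raise RankError(f"component {a + 1} has a degenerate score vector")
        pvec = X.T @ t / tt
        ca = float(y @ t) / tt
        X = X - np.outer(t, pvec)
        y = y - ca * t
        W[:, a], P[:, a], T[:, a], c[a] = w, pvec, t, ca
    return W, P, T, c


@dataclass
class PLSDAModel:
    """A fitted two-group PLS-DA model (NIPALS PLS1 on a centred 0/1 response)."""

    n_components: int
    weights: np.ndarray  # variables x components, unit-norm columns
    loadings: np.ndarray  # variables x components
    scores: np.ndarray  # samples x components
    y_loadings: np.ndarray  # (components,)
    y_encoding: dict
    y_mean: float
    scaling: ScaledMatrix
    r2y: float
    q2: float | None = None

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predicted (continuous) 0/1 response for new unscaled rows."""
        Xs = self.scaling.apply_to(np.atleast_2d(X_raw))
        return self.y_mean + self._scores_for(Xs) @ self.y_loadings

    def _scores_for(self, Xs: np.ndarray) -> np.ndarray:
        T = np.zeros((Xs.shape[0], self.n_components))
        X = Xs.copy()
        for a in range(self.n_components):
            t = X @ self.weights[:, a]
            X = X - np.outer(t, self.loadings[:, a])
            T[:, a] = t
        return T


def _encode_groups(y: Sequence) -> tuple[np.ndarray, dict]:
    labels = np.asarray(y)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise GroupingError(f"exactly two groups required, got {uniq}")
    counts = {g: int((labels == g).sum()) for g in uniq}
    for g, n in counts.items():
        if n < 2:
            raise GroupingError(f"group {g!r} has {n} sample(s); need at least 2")
    encoding = {uniq[0]: 0.0, uniq[1]: 1.0}
    return np.array([encoding[v] for v in labels.tolist()]), encoding


def fit_plsda(X, y: Sequence, n_components: int = 1) -> PLSDAModel:
    """Fit a two-group PLS-DA model on a scaled matrix.

    ``X`` is a :class:`ScaledMatrix` (from :func:`pareto_scale`); a raw array
    is Pareto-scaled first.  The response is the 0/1 group indicator (groups
    in sorted label order), centred before regression; q2 is left unset and
    is computed by :func:`q2_cross_validate`.
    """
    if not isinstance(X, ScaledMatrix):
        X = pareto_scale(np.asarray(X, dtype=float))
    y01, encoding = _encode_groups(y)
    if y01.size != X.values.shape[0]:
        raise GroupingError("y length does not match the number of rows in X")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    y_mean = float(y01.mean())
    yc = y01 - y_mean
    W, P, T, c = _nipals_pls1(X.values, yc, n_components)
    resid = yc - T @ c
    ssy = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ssy if ssy > _TINY else 0.0
    return PLSDAModel(n_components, W, P, T, c, encoding, y_mean, X, r2y)


# ---------------------------------------------------------------------------
# Cross-validation


def _stratified_folds(
    y01: np.ndarray, n_folds: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Round-robin fold assignment within each group, in input order.

    Deterministic by default; a seeded shuffle of each group's order is
    applied when ``rng`` is given.
    """
    folds = np.empty(y01.size, dtype=int)
    for g in np.unique(y01):
        idx = np.flatnonzero(y01 == g)
        if rng is not None:
            idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def q2_cross_validate(
    X: np.ndarray,
    y: Sequence,
    n_folds: int = 7,
    n_components: int = 1,
    shuffle_seed: int | None = None,
) -> float:
    """Cross-validated q2 = 1 - PRESS/SS of a Pareto-scaled PLS-DA model.

    ``X`` is the raw (unscaled) bucket matrix: scaling is refit inside every
    training fold so no information leaks from withheld samples.  Folds are
    assigned round-robin within each group; SS is the total squared deviation
    of the 0/1 response from its overall mean.
    """
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_groups(y)
    if y01.size != X.shape[0]:
        raise GroupingError("y length does not match the number of rows in X")
    if n_folds > X.shape[0]:
        raise ValueError("n_folds cannot exceed the number of samples")
    rng = None if shuffle_seed is None else np.random.default_rng(shuffle_seed)
    folds = _stratified_folds(y01, n_folds, rng)

    ss = float(np.sum((y01 - y01.mean()) ** 2))
    press = 0.0
    for k in range(n_folds):
        test = folds == k
        if not test.any():
            continue
        train = ~test
        y_tr = y01[train]
        if np.unique(y_tr).size < 2:
            raise StratificationError(f"training fold {k} lost an entire group")
        scaled = pareto_scale(X[train])
        W, P, _, c = _nipals_pls1(scaled.values, y_tr - y_tr.mean(), n_components)
        Xs_te = scaled.apply_to(X[test])
        t_pred = np.zeros((Xs_te.shape[0], n_components))
        Z = Xs_te
        for a in range(n_components):
            t = Z @ W[:, a]
            Z = Z - np.outer(t, P[:, a])
            t_pred[:, a] = t
        y_hat = y_tr.mean() + t_pred @ c
        press += float(np.sum((y01[test] - y_hat) ** 2))
    return 1.0 - press / ss


def choose_n_components(
    X: np.ndarray,
    y: Sequence,
    max_components: int = 5,
    min_gain: float = 0.01,
    n_folds: int = 7,
) -> tuple[int, float]:
    """Optional auto-rule: add components while the incremental q2 gain
    is at least ``min_gain``.  Returns (n_components, q2).  One component
    is the package default; this helper is for exploratory use."""
    best_a = 1
    best_q2 = q2_cross_validate(X, y, n_folds, 1)
    for a in range(2, max_components + 1):
        try:
            q2 = q2_cross_validate(X, y, n_folds, a)
        except RankError:
            break
        if q2 - best_q2 < min_gain:
            break
        best_a, best_q2 = a, q2
    return best_a, best_q2


# ---------------------------------------------------------------------------
# VIP


@dataclass
class VIPResult:
    """Variable-importance-in-projection scores and the selected variables."""

    vip: np.ndarray
    selected: np.ndarray  # indices with vip strictly above the threshold
    threshold: float


def vip_scores(model: PLSDAModel, threshold: float = 2.0) -> VIPResult:
    """VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a).

    SSY_a = c_a^2 t_a't_a is the response variance explained by component a.
    mean(VIP^2) = 1 by construction; selection is strict (vip > threshold).
    """
    p = model.weights.shape[0]
    ssy = model.y_loadings**2 * np.einsum("ia,ia->a", model.scores, model.scores)
    total = float(ssy.sum())
    if total <= _TINY:
        raise UndefinedVIPError("model explains no response variance; VIP undefined")
    wnorm2 = model.weights**2 / np.maximum(np.sum(model.weights**2, axis=0), _TINY)
    vip = np.sqrt(p * (wnorm2 @ ssy) / total)
    return VIPResult(vip, np.flatnonzero(vip > threshold), threshold)


# ---------------------------------------------------------------------------
# Permutation validation


@dataclass
class PermutationResult:
    """Genuine q2 against the null distribution from random relabelling."""

    genuine_q2: float
    permuted_q2: np.ndarray
    threshold_q2: float
    significant: bool
    seed: int
    n_perm: int

    @property
    def percentile(self) -> float:
        """Fraction of permuted q2 values strictly below the genuine q2."""
        return float(np.mean(self.permuted_q2 < self.genuine_q2))


def permutation_validate(
    X: np.ndarray,
    y: Sequence,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    n_components: int = 1,
) -> PermutationResult:
    """Pseudo-Monte-Carlo model validation by random group reassignment.

    Group labels are permuted uniformly at random (group sizes preserved) and
    the full scale-fit-q2 pipeline — including fold re-stratification on the
    permuted labels — is rerun for each of the ``n_perm`` permutations.  The
    model is significant when the genuine q2 strictly exceeds the empirical
    95th percentile (nearest-rank) of the permuted q2 values.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    labels = np.asarray(y)
    genuine = q2_cross_validate(X, labels, n_folds, n_components)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = q2_cross_validate(X, rng.permutation(labels), n_folds, n_components)
    rank = math.ceil(0.95 * n_perm)  # nearest-rank percentile
    threshold = float(np.sort(permuted)[rank - 1])
    return PermutationResult(genuine, permuted, threshold, genuine > threshold, seed, n_perm)
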