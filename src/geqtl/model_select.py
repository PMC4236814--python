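"""Choice of the number of extracted genetic factors.

A k-fold (default 7) cross-validation computes, for each candidate factor
count r = 0..max, the predicted residual sum of squares over held-out
samples; root mean PRESS = sqrt(PRESS / (n * t)).  The PRESS-minimizing r is
then challenged by van der Voet's randomization test: every smaller model
whose cross-validated squared residuals are not significantly worse is
admissible, and the final model is the smallest admissible one.  This guards
against keeping factors that only fit noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import GeneBlockPLS


@dataclass
class PressCurve:
    """Cross-validated PRESS profile over candidate factor counts.

    ``residuals[r]`` is the n x t matrix of held-out residuals at r factors.
    ``p_values[r]`` is the van der Voet p of model r against the
    PRESS-minimizing model (1.0 for the minimizer itself).
    """

    factor_counts: np.ndarray
    root_mean_press: np.ndarray
    fold_assignment: np.ndarray
    residuals: dict[int, np.ndarray] = field(default_factory=dict)
    p_values: dict[int, float] = field(default_factory=dict)
    argmin: int = 0
    selected: int = 0


def assign_folds(n: int, k_folds: int, scheme: str = "interleaved", seed: int | None = None) -> np.ndarray:
    """Fold labels 0..k-1; 'interleaved' puts sample i in fold i mod k."""
    if scheme == "interleaved":
        return np.arange(n) % k_folds
    if scheme == "seeded_random":
        rng = np.random.default_rng(seed)
        folds = np.arange(n) % k_folds
        rng.shuffle(folds)
        return folds
    raise ValueError(f"unknown fold scheme {scheme!r}")


def van_der_voet_test(
    residuals_candidate: np.ndarray,
    residuals_reference: np.ndarray,
    n_randomizations: int = 2000,
    seed: int | None = None,
) -> float:
    """Randomization test: are the candidate's CV squared residuals worse?

    The statistic is C = sum of (candidate^2 - reference^2) over all
    (sample, response) cells; the null randomly swaps the paired squared
    residuals within each cell (a sign flip of the difference) and the
    one-sided p is the proportion of randomized statistics >= the observed.
    """
    rc = np.asarray(residuals_candidate, dtype=float)
    rr = np.asarray(residuals_reference, dtype=float)
    if rc.shape != rr.shape:
        raise ValueError(f"residual shapes differ: {rc.shape} vs {rr.shape}")
    if n_randomizations < 100:
        warnings.warn("fewer than 100 randomizations: p-value will be unstable")
    d = (rc ** 2 - rr ** 2).ravel()
    c_obs = d.sum()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_randomizations, d.size)) * 2 - 1
    null = signs @ d
    return float(np.mean(null >= c_obs - 1e-12))


def cv_press(
    S_block,
    T_block,
    max_factors: int | None = None,
    k_folds: int = 7,
    fold_scheme: str = "interleaved",
    seed: int | None = None,
    n_randomizations: int = 2000,
    alpha: float = 0.10,
) -> PressCurve:
    """Cross-validated PRESS curve with van der Voet p-values and selection.

    r = 0 (training-mean prediction) is always a candidate.  Centering and
    scaling are recomputed inside each training fold so held-out residuals
    are honest.
    """
    S = np.asarray(S_block, dtype=float)
    T = np.asarray(T_block, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    n, t = T.shape[0], T.shape[1]
    if n < k_folds:
        raise ValueError(f"n={n} < k_folds={k_folds}")
    folds = assign_folds(n, k_folds, fold_scheme, seed)
    if min(np.bincount(folds, minlength=k_folds)) < 1:
        raise ValueError("empty fold; use fewer folds")
    min_train = n - int(np.max(np.bincount(folds)))
    if min_train < 2:
        raise ValueError("a training fold has < 2 samples; use fewer folds")

    if max_factors is None:
        max_factors = min(S.shape[1], t, n - 1, 10)
    # every training fold must support the full candidate range
    r_max = max_factors
    residuals = {r: np.zeros((n, t)) for r in range(max_factors + 1)}
    for f in range(k_folds):
        test = folds == f
        train = ~test
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GeneBlockPLS(n_factors=max_factors).fit(S[train], T[train])
        r_max = min(r_max, model.n_factors_)
        for r in range(model.n_factors_ + 1):
            pred = model.predict(S[test], n_factors=r)
            residuals[r][test] = T[test] - pred
        # factor counts the fold could not extract fall back to its maximum
        for r in range(model.n_factors_ + 1, max_factors + 1):
            pred = model.predict(S[test], n_factors=model.n_factors_)
            residuals[r][test] = T[test] - pred

    counts = np.arange(r_max + 1)
    rmp = np.array([np.sqrt((residuals[r] ** 2).sum() / (n * t)) for r in counts])
    argmin = int(np.argmin(rmp))
    curve = PressCurve(
        factor_counts=counts,
        root_mean_press=rmp,
        fold_assignment=folds,
        residuals={r: residuals[r] for r in counts},
        argmin=argmin,
    )
    rng = np.random.default_rng(seed)
    curve.p_values[argmin] = 1.0
    for r in range(argmin):
        curve.p_values[r] = van_der_voet_test(
            residuals[r], residuals[argmin],
            n_randomizations=n_randomizations, seed=int(rng.integers(2**31)),
        )
    curve.selected = select_n_factors(curve, alpha=alpha)
    return curve


def select_n_factors(curve: PressCurve, alpha: float = 0.10) -> int:
    """Smallest factor count not significantly worse than the PRESS minimizer."""
    for r in range(curve.argmin):
        if curve.p_values.get(r, 0.0) >= alpha:
            return r
    return curve.argmin
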