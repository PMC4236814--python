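"""Gene-based partial least squares linking an S-gene SNP block to a T-gene
transcript block.

The model writes the SNP block S (n x s) and transcript block T (n x t) as
linear models of r paired latent factors,

    S = F_S L_S + E_S,     T = F_S (L_F L_T) + E_T',

with F_S = S W_S and F_T = T W_T chosen per factor to maximize cov(F_S, F_T),
extracted by NIPALS with both blocks deflated on the X-score.  The implied
prediction model is T = S B_PLS + E_PLS.  An S-gene/T-gene association is
summarized by the factor score (canonical) correlation corr(F_S, F_T) and by
the proportion of each block's variation the factors explain.

``GeneBlockPLS`` follows the scikit-learn estimator protocol (fit / predict /
get_params) so it composes with pipelines and model selection.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin


def impute_missing(block: np.ndarray, column_ids=None) -> np.ndarray:
    """Replace missing genotype codes by the column mean of observed values.

    Raises if a column is entirely missing, naming the SNP when ids are given.
    """
    X = np.array(block, dtype=float)
    if X.ndim != 2:
        raise ValueError("block must be 2-D")
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        j = int(np.nonzero(all_missing)[0][0])
        name = column_ids[j] if column_ids is not None else f"column {j}"
        raise ValueError(f"cannot impute fully-missing column: {name}")
    if np.isnan(X).any():
        means = np.nanmean(X, axis=0)
        idx = np.nonzero(np.isnan(X))
        X[idx] = means[idx[1]]
    return X


class GeneBlockPLS(BaseEstimator, RegressorMixin):
    """NIPALS partial least squares between a SNP block and a transcript block.

    Parameters
    ----------
    n_factors : int or None
        Number of latent factors r to extract.  None uses
        min(s, t, n-1, max_factors_cap); extraction also stops early when the
        residual X-block variation falls below ``tol``.
    scale : bool
        Center and unit-variance scale both blocks with training statistics.
    tol : float
        NIPALS score-convergence tolerance and residual-variation floor.
    max_iter : int
        Iteration cap per factor; non-convergence is accepted with a warning.
    max_factors_cap : int
        Upper bound on the automatic factor count (keeps cross-validated
        model selection affordable).

    Attributes
    ----------
    x_weights_, y_weights_ : (s, r), (t, r) — W_S and W_T, unit columns,
        sign-canonicalized (largest-magnitude entry positive).
    x_scores_, y_scores_ : (n, r) — F_S and F_T.
    x_loadings_ : (s, r) — columns of L_S' (S regressed on F_S).
    y_loadings_ : (t, r) — columns of (L_F L_T)' (T regressed on F_S).
    coef_ : (s, t) — B_PLS on the scaled space; ``predict`` applies the
        centering/scaling transforms around it.
    explained_x_ratio_, explained_y_ratio_ : (r,) per-factor proportions of
        block variation explained.
    canonical_correlations_ : (r,) corr(F_S[:, k], F_T[:, k]); NaN flags a
        zero-variance score.
    n_factors_ : int, factors actually extracted.
    """

    def __init__(self, n_factors=None, scale=True, tol=1e-10, max_iter=500,
                 max_factors_cap=10):
        self.n_factors = n_factors
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter
        self.max_factors_cap = max_factors_cap

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        n, s = X.shape
        if Y.shape[0] != n:
            raise ValueError(f"sample mismatch: X has {n} rows, Y has {Y.shape[0]}")
        if n < 3:
            raise ValueError("need at least 3 samples")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ValueError("missing values must be imputed upstream")
        t = Y.shape[1]

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        if self.scale:
            self.x_std_ = X.std(axis=0, ddof=1)
            self.y_std_ = Y.std(axis=0, ddof=1)
        else:
            self.x_std_ = np.ones(s)
            self.y_std_ = np.ones(t)

        # zero-variance columns carry no information; drop internally
        self.x_active_ = self.x_std_ > 0
        self.y_active_ = self.y_std_ > 0
        if not self.x_active_.all():
            warnings.warn(f"dropping {int((~self.x_active_).sum())} zero-variance X columns")
        if not self.y_active_.all():
            warnings.warn(f"dropping {int((~self.y_active_).sum())} zero-variance Y columns")
        xa = np.nonzero(self.x_active_)[0]
        ya = np.nonzero(self.y_active_)[0]
        X0 = (X[:, xa] - self.x_mean_[xa]) / self.x_std_[xa]
        Y0 = (Y[:, ya] - self.y_mean_[ya]) / self.y_std_[ya]

        sa, ta = X0.shape[1], Y0.shape[1]
        r_max = min(sa, ta, n - 1, self.max_factors_cap)
        if self.n_factors is not None:
            if self.n_factors < 0:
                raise ValueError("n_factors must be >= 0")
            r_max = min(self.n_factors, min(sa, n - 1))
        if sa == 0 or ta == 0:
            r_max = 0
        ss_x_total = float((X0 ** 2).sum())
        ss_y_total = float((Y0 ** 2).sum())

        W, C, P, Q, F, U, cancors = [], [], [], [], [], [], []
        ex_x, ex_y = [], []
        Xk, Yk = X0.copy(), Y0.copy()
        for _ in range(r_max):
            if (Xk ** 2).sum() < self.tol * max(ss_x_total, 1.0):
                break  # X-block exhausted
            u = Yk[:, int(np.argmax(Yk.var(axis=0)))].copy()
            if u @ u < self.tol:
                break  # no Y variation left to correlate with
            f = np.zeros(n)
            for _it in range(self.max_iter):
                w = Xk.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w /= nw
                f_new = Xk @ w
                c = Yk.T @ f_new
                nc = np.linalg.norm(c)
                if nc == 0:
                    f = f_new
                    c = np.zeros(ta)
                    u = np.zeros(n)
                    break
                c /= nc
                u = Yk @ c
                if np.linalg.norm(f_new - f) < self.tol * max(np.linalg.norm(f_new), 1.0):
                    f = f_new
                    break
                f = f_new
            else:
                warnings.warn("NIPALS factor did not converge within max_iter")
            ff = f @ f
            if ff < self.tol:
                break
            # sign canonicalization: largest-|.| X-weight entry positive
            jmax = int(np.argmax(np.abs(w)))
            if w[jmax] < 0:
                w, f, c, u = -w, -f, -c, -u
            p = Xk.T @ f / ff            # row of L_S
            q = Yk.T @ f / ff            # row of L_F L_T
            Xk = Xk - np.outer(f, p)
            Yk = Yk - np.outer(f, q)
            W.append(w); C.append(c); P.append(p); Q.append(q); F.append(f); U.append(u)
            ex_x.append(float(ff * (p @ p) / ss_x_total) if ss_x_total > 0 else 0.0)
            ex_y.append(float(ff * (q @ q) / ss_y_total) if ss_y_total > 0 else 0.0)
            sf = f.std()
            su = u.std()
            if sf > 0 and su > 0:
                cancors.append(float(np.corrcoef(f, u)[0, 1]))
            else:
                cancors.append(float("nan"))

        r = len(W)
        self.n_factors_ = r
        self.n_samples_, self.n_x_, self.n_y_ = n, s, t

        def expand(cols, active, dim):
            out = np.zeros((dim, r))
            if cols:
                out[np.nonzero(active)[0], :] = np.column_stack(cols)
            return out

        self.x_weights_ = expand(W, self.x_active_, s)
        self.y_weights_ = expand(C, self.y_active_, t)
        self.x_loadings_ = expand(P, self.x_active_, s)
        self.y_loadings_ = expand(Q, self.y_active_, t)
        self.x_scores_ = np.column_stack(F) if F else np.zeros((n, 0))
        self.y_scores_ = np.column_stack(U) if U else np.zeros((n, 0))
        self.explained_x_ratio_ = np.array(ex_x)
        self.explained_y_ratio_ = np.array(ex_y)
        self.canonical_correlations_ = np.array(cancors)
        self.coef_ = self._coef(r)
        return self

    def _coef(self, n_factors: int) -> np.ndarray:
        """B_PLS on the scaled space using the first ``n_factors`` factors."""
        s, t = self.n_x_, self.n_y_
        r = int(n_factors)
        if r == 0:
            return np.zeros((s, t))
        W = self.x_weights_[:, :r]
        P = self.x_loadings_[:, :r]
        Q = self.y_loadings_[:, :r]
        # (L_S)^-1 (L_F L_T) in the factor space: rotations W (P'W)^-1 Q'
        PtW = P.T @ W
        B = W @ np.linalg.solve(PtW, Q.T)
        return B

    def predict(self, X, n_factors: int | None = None) -> np.ndarray:
        """Predict the transcript block from new SNP codes.

        ``n_factors`` truncates the factor space; 0 predicts the training
        mean of every probe.
        """
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_x_:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {self.n_x_}")
        r = self.n_factors_ if n_factors is None else int(n_factors)
        if r > self.n_factors_:
            raise ValueError(f"n_factors={r} exceeds extracted factors {self.n_factors_}")
        B = self.coef_ if r == self.n_factors_ else self._coef(r)
        std = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        X0 = (X - self.x_mean_) / std
        Y0 = X0 @ B
        return self.y_mean_ + Y0 * self.y_std_

    def transform(self, X) -> np.ndarray:
        """Project new SNP codes onto the extracted X-scores (F_S)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        std = np.where(self.x_std_ > 0, self.x_std_, 1.0)
        X0 = (X - self.x_mean_) / std
        W = self.x_weights_
        P = self.x_loadings_
        if self.n_factors_ == 0:
            return np.zeros((X.shape[0], 0))
        R = W @ np.linalg.inv(P.T @ W)
        return X0 @ R

    def canonical_correlation(self, factor: int = 0) -> float:
        """corr(F_S, F_T) of one factor (0-based); NaN flags zero variance."""
        if not hasattr(self, "canonical_correlations_"):
            raise RuntimeError("model is not fitted")
        if factor >= self.n_factors_:
            raise ValueError(f"factor {factor} >= extracted count {self.n_factors_}")
        return float(self.canonical_correlations_[factor])


def fit_pls(S_block, T_block, max_factors=None, tol=1e-10, max_iter=500) -> GeneBlockPLS:
    """Functional wrapper: fit a GeneBlockPLS on one S-gene/T-gene pair."""
    return GeneBlockPLS(n_factors=max_factors, tol=tol, max_iter=max_iter).fit(S_block, T_block)
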