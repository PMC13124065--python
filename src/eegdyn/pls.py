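"""Mean-centered Task-PLS with permutation and bootstrap inference.

Given per-observation metric vectors (rows = (subject, condition)
observations, columns = metric elements), the method forms the group x
condition cell-mean matrix, removes the grand mean, and takes its SVD
M = U S V'. Each latent variable (LV) pairs a *task salience* (a contrast
over design cells, column of U) with a *brain salience* (an element loading
pattern, column of V); S_l^2 / sum(S^2) is the fraction of design-related
covariance the LV explains. LV significance is assessed by permuting rows
across cells without replacement; element reliability by resampling subjects
with replacement within cells (bootstrap ratio = observed salience / SD of
Procrustes-aligned replicate saliences, with |ratio| > 2.5758 marking the
two-tailed 99% standard-normal criterion). Brain scores project each
observation onto a brain salience, giving a per-subject expression of the
contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

#: Two-tailed 99% standard-normal critical value used to flag reliable elements.
BOOTSTRAP_RATIO_THRESHOLD = float(stats.norm.ppf(0.995))  # 2.5758...


def condition_mean_matrix(
    X: np.ndarray,
    groups: np.ndarray,
    conditions: np.ndarray,
    group_order,
    condition_order,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Grand-mean-centered cell-mean matrix (cells x elements).

    Rows are ordered group-major: (g1,c1), (g1,c2), ..., (g2,c1), ...
    Missing elements (NaN) are excluded from the means element-wise.
    Returns (centered matrix, grand mean row, cell labels).
    """
    X = np.asarray(X, dtype=float)
    cells = [(g, c) for g in group_order for c in condition_order]
    M = np.empty((len(cells), X.shape[1]))
    for row, (g, c) in enumerate(cells):
        mask = (groups == g) & (conditions == c)
        if not mask.any():
            raise ValueError(f"empty design cell (group={g!r}, condition={c!r})")
        with np.errstate(invalid="ignore"):
            M[row] = np.nanmean(X[mask], axis=0)
    grand = M.mean(axis=0)
    return M - grand, grand, cells


def pls_svd(M: np.ndarray, n_components: int | None = None):
    """SVD of the centered cell matrix with a deterministic sign convention.

    Returns (U, S, V) with M ~= U diag(S) V' truncated to
    min(cells - 1, n_elements) components; the largest-magnitude element of
    each V column is made positive.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("cell matrix contains non-finite entries")
    if np.allclose(M, 0.0):
        raise ValueError("centered cell matrix is all zero: no effects to "
                         "decompose")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    rank_cap = min(M.shape[0] - 1, M.shape[1])
    k = rank_cap if n_components is None else min(n_components, rank_cap)
    U, S, V = U[:, :k], S[:k], Vt[:k].T
    # sign convention: dominant element of each brain salience positive
    for l in range(k):
        peak = np.argmax(np.abs(V[:, l]))
        if V[peak, l] < 0:
            U[:, l] *= -1.0
            V[:, l] *= -1.0
    return U, S, V


def _procrustes_rotation(V_rep: np.ndarray, V_obs: np.ndarray) -> np.ndarray:
    """Orthogonal rotation R minimizing ||V_rep R - V_obs||_F."""
    P, _, Qt = np.linalg.svd(V_rep.T @ V_obs, full_matrices=False)
    return P @ Qt


class MeanCenteredTaskPLS(BaseEstimator):
    """Mean-centered Task-PLS estimator (scikit-learn interface).

    Parameters
    ----------
    n_perm : permutation samples for LV significance (0 disables).
    n_boot : bootstrap samples for element reliability (0 disables).
    random_state : seed for both resampling schemes.
    permute_within_subject : when True, permutation shuffles condition labels
        within subject instead of unrestricted row permutation.

    Attributes (after ``fit(X, y)`` with y two columns: group, condition)
    ----------
    task_saliences_ : (n_cells, n_lv) design contrasts U.
    singular_values_ : (n_lv,) nonincreasing S.
    brain_saliences_ : (n_elements, n_lv) element loadings V.
    covariance_explained_ : S^2 / sum(S^2).
    pvalues_ : permutation p per LV (add-one estimator).
    bootstrap_ratios_ : (n_elements, n_lv).
    brain_scores_ : (n_obs, n_lv) projections of each observation.
    score_cell_means_ : (n_cells, n_lv) normalized cell-mean brain scores
        (mean-centered across cells, divided by the singular value).
    score_cell_cis_ : (n_cells, n_lv, 2) bootstrap 95% percentile CIs of the
        normalized cell means.
    """

    def __init__(self, n_perm: int = 1000, n_boot: int = 500,
                 random_state: int | None = None,
                 permute_within_subject: bool = False):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state
        self.permute_within_subject = permute_within_subject

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, subjects=None):
        """Fit on observations X (rows = subject x condition) and labels y.

        ``y`` is (n_obs, 2): column 0 group labels, column 1 condition
        labels. ``subjects`` (optional, n_obs) enables within-subject
        permutation and subject-level bootstrap resampling; defaults to one
        subject per row within each cell.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.ndim != 2 or y.shape != (X.shape[0], 2):
            raise ValueError("X must be 2-D and y must be (n_obs, 2) of "
                             "(group, condition) labels")
        groups = y[:, 0].astype(str)
        conditions = y[:, 1].astype(str)
        if subjects is None:
            subjects = np.arange(X.shape[0]).astype(str)
        subjects = np.asarray(subjects).astype(str)

        self.group_order_ = tuple(pd.unique(groups))
        self.condition_order_ = tuple(pd.unique(conditions))
        X = self._drop_sparse_elements(X)

        M, grand, cells = condition_mean_matrix(
            X, groups, conditions, self.group_order_, self.condition_order_)
        U, S, V = pls_svd(M)
        self.cell_labels_ = cells
        self.grand_mean_ = grand
        self.cell_matrix_ = M
        self.task_saliences_ = U
        self.singular_values_ = S
        self.brain_saliences_ = V
        self.n_lv_ = S.size
        self.covariance_explained_ = S**2 / np.sum(S**2)

        rng = np.random.default_rng(self.random_state)
        self._groups, self._conditions, self._subjects = groups, conditions, subjects
        self._X = X
        if self.n_perm:
            self.pvalues_ = self._permutation_test(X, groups, conditions,
                                                   subjects, rng)
        if self.n_boot:
            (self.bootstrap_ratios_, self.score_cell_cis_,
             self.n_boot_dropped_) = self._bootstrap_test(
                X, groups, conditions, subjects, rng)
        self.brain_scores_ = self.transform(X)
        self.score_cell_means_ = self._normalized_cell_means(
            self.brain_scores_, groups, conditions)
        return self

    def _drop_sparse_elements(self, X: np.ndarray,
                              max_missing_frac: float = 0.2) -> np.ndarray:
        missing = np.isnan(X).mean(axis=0)
        keep = missing <= max_missing_frac
        self.element_mask_ = keep
        if not keep.all():
            logger.warning("dropping %d/%d elements missing in more than %d%% "
                           "of rows", int((~keep).sum()), keep.size,
                           int(100 * max_missing_frac))
        return X[:, keep]

    # -- projections --------------------------------------------------------

    def transform(self, X):
        """Brain scores: centered rows projected on the brain saliences."""
        check_is_fitted(self, "brain_saliences_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.element_mask_.size and not self.element_mask_.all():
            X = X[:, self.element_mask_]
        if X.shape[1] != self.brain_saliences_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} elements; model was fitted on "
                f"{self.brain_saliences_.shape[0]}")
        Xc = np.where(np.isnan(X), 0.0, X - self.grand_mean_)
        return Xc @ self.brain_saliences_

    def _normalized_cell_means(self, scores, groups, conditions):
        means = np.empty((len(self.cell_labels_), self.n_lv_))
        for row, (g, c) in enumerate(self.cell_labels_):
            mask = (groups == g) & (conditions == c)
            means[row] = scores[mask].mean(axis=0)
        means = means - means.mean(axis=0)
        return means / self.singular_values_

    # -- resampling ---------------------------------------------------------

    def _permutation_test(self, X, groups, conditions, subjects, rng):
        S_obs = self.singular_values_
        exceed = np.zeros_like(S_obs)
        n = X.shape[0]
        for _ in range(self.n_perm):
            if self.permute_within_subject:
                perm = np.arange(n)
                for s in np.unique(subjects):
                    idx = np.flatnonzero(subjects == s)
                    perm[idx] = rng.permutation(idx)
            else:
                perm = rng.permutation(n)
            M, _, _ = condition_mean_matrix(
                X[perm], groups, conditions,
                self.group_order_, self.condition_order_)
            if np.allclose(M, 0.0):
                continue  # permuted singular values all zero: never exceed
            _, S_perm, _ = pls_svd(M)
            k = min(S_perm.size, S_obs.size)
            exceed[:k] += S_perm[:k] >= S_obs[:k]
        return (exceed + 1.0) / (self.n_perm + 1.0)

    def _bootstrap_test(self, X, groups, conditions, subjects, rng):
        V_obs = self.brain_saliences_
        n_cells = len(self.cell_labels_)
        V_reps = np.empty((self.n_boot, *V_obs.shape))
        cell_means = np.empty((self.n_boot, n_cells, self.n_lv_))
        cell_subject_rows: list[list[np.ndarray]] = []
        for g, c in self.cell_labels_:
            mask = (groups == g) & (conditions == c)
            subj_in_cell = pd.unique(subjects[mask])
            cell_subject_rows.append(
                [np.flatnonzero(mask & (subjects == s)) for s in subj_in_cell])
        dropped = 0
        b = 0
        attempts = 0
        while b < self.n_boot and attempts < 2 * self.n_boot + 100:
            attempts += 1
            rows = []
            for per_subject in cell_subject_rows:
                take = rng.integers(0, len(per_subject), len(per_subject))
                rows.extend(np.concatenate([per_subject[t] for t in take]))
            rows = np.asarray(rows)
            Xb, gb, cb = X[rows], groups[rows], conditions[rows]
            Mb, grand_b, _ = condition_mean_matrix(
                Xb, gb, cb, self.group_order_, self.condition_order_)
            if np.allclose(Mb, 0.0):
                dropped += 1
                continue
            Ub, Sb, Vb = pls_svd(Mb, n_components=self.n_lv_)
            if Vb.shape[1] < self.n_lv_:
                dropped += 1
                continue
            R = _procrustes_rotation(Vb, V_obs)
            # replicate saliences carry their singular values: the brain
            # salience is proportional to element/contrast covariance, and
            # the unit-norm constraint alone would hide amplitude variance
            V_reps[b] = (Vb * Sb) @ R
            scores_b = np.where(np.isnan(Xb), 0.0, Xb - grand_b) @ (Vb @ R)
            means = np.empty((n_cells, self.n_lv_))
            for row, (g, c) in enumerate(self.cell_labels_):
                mask = (gb == g) & (cb == c)
                means[row] = scores_b[mask].mean(axis=0)
            means = means - means.mean(axis=0)
            cell_means[b] = means / self.singular_values_
            b += 1
        if b < self.n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        if dropped > 0.05 * self.n_boot:
            logger.warning("bootstrap: %d degenerate replicates dropped", dropped)
        sd = V_reps.std(axis=0, ddof=1)
        scaled_obs = V_obs * self.singular_values_
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(sd > 0, scaled_obs / np.where(sd > 0, sd, 1.0),
                              np.inf)
        cis = np.stack(
            [np.percentile(cell_means, 2.5, axis=0),
             np.percentile(cell_means, 97.5, axis=0)], axis=-1)
        return ratios, cis, dropped

    # -- reporting ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """One row per latent variable: S, covariance fraction, permutation p."""
        check_is_fitted(self, "singular_values_")
        return pd.DataFrame({
            "lv": np.arange(1, self.n_lv_ + 1),
            "singular_value": self.singular_values_,
            "covariance_explained": self.covariance_explained_,
            "p_perm": getattr(self, "pvalues_", np.full(self.n_lv_, np.nan)),
        })
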