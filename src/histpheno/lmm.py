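"""REML linear mixed models for unbalanced historical trial data.

The model is the additive decomposition used throughout the pipeline,

    y = mu + g (accession) + a (year) + t (experiment) + v (convariety)
        + g:t (accession x experiment) + e,

with any term assignable to a fixed, random or excluded role per stage.
Variance components are estimated by direct numerical maximisation of the
restricted log-likelihood, profiled over the fixed effects and the residual
variance, and parameterised on log variance ratios gamma_k = sigma2_k /
sigma2_e.  All quantities are evaluated through the mixed-model equations:
with M = [X Z], A = M'M and C(gamma) = A + blockdiag(0, Gamma^{-1}),

    -2 l_R(gamma) = (n - p) log(y'Py) + sum_k q_k log(gamma_k) + log|C| + const,

where y'Py = y'y - b' C^{-1} b with b = M'y.  This needs one Cholesky of the
(p + q) x (p + q) coefficient matrix per likelihood evaluation and is exact
for arbitrary crossed, unbalanced designs.  Components whose ratio collapses
to the lower optimisation bound are snapped to exactly zero (the boundary
solution).  Fixed-effect estimates, random-effect predictions (BLUPs),
conditional residuals and the fixed-effect covariance all come from the same
equations at the converged components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "MixedModelREML",
    "SpecificationError",
    "reml_fit",
    "reduce_model",
    "fit_blues",
]

_TERMS = ("accession", "year", "experiment", "convariety", "accession:experiment")


class SpecificationError(ValueError):
    """A model term cannot be fitted as specified (e.g. single level)."""


@dataclass
class ModelSpec:
    """Role assignment for the terms of the trial model.

    ``roles`` maps term name -> ``"fixed"``, ``"random"`` or ``"excluded"``;
    the intercept is always fixed and included.  The accession x experiment
    interaction may only be included when both main terms are.
    """

    roles: Dict[str, str] = field(default_factory=dict)
    residual_structure: str = "homogeneous"

    def __post_init__(self) -> None:
        for term, role in self.roles.items():
            if role not in ("fixed", "random", "excluded"):
                raise ValueError(f"bad role {role!r} for term {term!r}")
        inter = self.roles.get("accession:experiment", "excluded")
        if inter != "excluded":
            for parent in ("accession", "experiment"):
                if self.roles.get(parent, "excluded") == "excluded":
                    raise ValueError(
                        "accession:experiment requires both accession and "
                        "experiment to be included"
                    )
        if self.residual_structure not in ("homogeneous", "per-year"):
            raise ValueError("residual_structure must be homogeneous or per-year")

    def fixed_terms(self) -> Tuple[str, ...]:
        return tuple(t for t, r in self.roles.items() if r == "fixed")

    def random_terms(self) -> Tuple[str, ...]:
        return tuple(t for t, r in self.roles.items() if r == "random")

    def without(self, term: str) -> "ModelSpec":
        roles = {t: r for t, r in self.roles.items() if t != term}
        # Dropping a main effect also drops its interaction.
        if term in ("accession", "experiment"):
            roles.pop("accession:experiment", None)
        return ModelSpec(roles=roles, residual_structure=self.residual_structure)


def _term_labels(df: pd.DataFrame, term: str) -> pd.Series:
    if ":" in term:
        a, b = term.split(":")
        return df[a].astype(str) + ":" + df[b].astype(str)
    return df[term].astype(str)


class MixedModelREML(BaseEstimator):
    """REML fit of a crossed mixed model on a long-format record table.

    Parameters
    ----------
    fixed : sequence of str
        Categorical fixed terms (column names, or ``"a:b"`` interactions).
        An intercept is always included first.
    random : sequence of str
        Categorical random terms.
    response : str
        Column holding the observations.
    tol : float
        Convergence tolerance on the relative change of the restricted
        log-likelihood criterion.
    max_iter : int
        Optimiser iteration cap (scaled by the number of components for the
        simplex fallback).
    log_ratio_bounds : (float, float)
        Search bounds on log(sigma2_k / sigma2_e).

    Attributes
    ----------
    variance_components_ : dict
        Term -> sigma2 estimate, plus ``"residual"``.
    fixed_effects_ : pandas.Series
        Estimates indexed by ``(term, level)`` labels; intercept first.
    fixed_se_ : pandas.Series
        Standard errors for the fixed effects.
    random_effects_ : dict
        Term -> :class:`pandas.Series` of BLUPs indexed by level.
    residuals_ : numpy.ndarray
        Conditional residuals in input row order.
    loglik_ : float
        Restricted log-likelihood at the optimum.
    converged_ : bool
    n_records_ : int
    dropped_levels_ : list of str
        Fixed design columns dropped to restore full rank.
    """

    def __init__(
        self,
        fixed: Sequence[str] = (),
        random: Sequence[str] = (),
        response: str = "value",
        tol: float = 1e-8,
        max_iter: int = 200,
        log_ratio_bounds: Tuple[float, float] = (-30.0, 30.0),
    ):
        self.fixed = tuple(fixed)
        self.random = tuple(random)
        self.response = response
        self.tol = tol
        self.max_iter = max_iter
        self.log_ratio_bounds = log_ratio_bounds

    # ------------------------------------------------------------------ build
    def _build_design(self, df: pd.DataFrame):
        n = len(df)
        x_cols = [np.ones(n)]
        x_names: List[Tuple[str, str]] = [("intercept", "")]
        self._fixed_levels: Dict[str, List[str]] = {}
        for term in self.fixed:
            lab = _term_labels(df, term)
            levels = sorted(lab.unique())
            if len(levels) < 2:
                raise SpecificationError(
                    f"fixed term {term!r} has a single level ({levels[0]!r})"
                )
            self._fixed_levels[term] = levels
            for lev in levels[1:]:  # drop-first coding
                x_cols.append((lab == lev).to_numpy(float))
                x_names.append((term, lev))
        X = np.column_stack(x_cols)

        # Restore full rank by dropping trailing aliased columns (incremental
        # pivotless Cholesky on the Gram matrix; exact one-hot dependencies).
        G = X.T @ X
        p_all = X.shape[1]
        kept: List[int] = []
        L = np.zeros((p_all, p_all))
        dropped: List[str] = []
        for j in range(p_all):
            k = len(kept)
            gj = G[kept, j] if kept else np.empty(0)
            cj = sla.solve_triangular(L[:k, :k], gj, lower=True) if k else gj
            d = G[j, j] - cj @ cj
            if d > 1e-8 * max(G[j, j], 1.0):
                L[k, :k] = cj
                L[k, k] = np.sqrt(d)
                kept.append(j)
            else:
                dropped.append(f"{x_names[j][0]}[{x_names[j][1]}]")
        X = X[:, kept]
        x_names = [x_names[j] for j in kept]

        z_blocks: List[sp.csr_matrix] = []
        z_meta: List[Tuple[str, List[str]]] = []
        for term in self.random:
            lab = _term_labels(df, term)
            levels = sorted(lab.unique())
            if len(levels) < 2:
                raise SpecificationError(
                    f"random term {term!r} has a single level ({levels[0]!r})"
                )
            idx = pd.Categorical(lab, categories=levels).codes
            Z = sp.csr_matrix(
                (np.ones(n), (np.arange(n), idx)), shape=(n, len(levels))
            )
            z_blocks.append(Z)
            z_meta.append((term, levels))
        return X, x_names, dropped, z_blocks, z_meta

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y=None) -> "MixedModelREML":
        """Fit the model on a record table (one trait)."""
        df = X
        yv = df[self.response].to_numpy(float)
        if not np.all(np.isfinite(yv)):
            raise ValueError("non-finite response values")
        Xd, x_names, dropped, z_blocks, z_meta = self._build_design(df)
        n, p = Xd.shape
        q_sizes = [Z.shape[1] for Z in z_blocks]
        if n <= p:
            raise SpecificationError(
                f"no residual degrees of freedom (n={n}, fixed rank={p})"
            )

        M = sp.hstack([sp.csr_matrix(Xd)] + z_blocks, format="csr") if z_blocks else None
        if M is not None:
            A = np.asarray((M.T @ M).todense())
            b = M.T @ yv
        else:
            A = Xd.T @ Xd
            b = Xd.T @ yv
        yy = yv @ yv
        K = len(z_blocks)
        offs = np.cumsum([p] + q_sizes)

        # Degenerate data (OLS already fits exactly): all components zero.
        beta0 = sla.cho_solve(
            sla.cho_factor(A[:p, :p], lower=True), b[:p], check_finite=False
        )
        rss0 = yy - b[:p] @ beta0
        degenerate = rss0 <= 1e-12 * max(yy, 1.0)
        _BIG = 1e300

        def crit(theta: np.ndarray):
            """-2 restricted log-likelihood up to an additive constant."""
            d = np.zeros(A.shape[0])
            for k in range(K):
                d[offs[k] : offs[k + 1]] = np.exp(-theta[k])
            C = A + np.diag(d)
            try:
                cf = sla.cho_factor(C, lower=True, check_finite=False)
            except sla.LinAlgError:
                return _BIG, None, None
            s = sla.cho_solve(cf, b, check_finite=False)
            ypy = yy - b @ s
            if ypy <= 0:
                return _BIG, None, None
            logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
            val = (
                (n - p) * np.log(ypy)
                + float(np.dot(q_sizes, theta))
                + logdetC
            )
            return val, s, cf

        lo, hi = self.log_ratio_bounds
        converged = True
        if K == 0 or degenerate:
            theta = np.full(K, lo)
        elif K == 1:
            res = optimize.minimize_scalar(
                lambda t: crit(np.array([t]))[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-11, "maxiter": max(self.max_iter, 500)},
            )
            theta = np.array([res.x])
            converged = bool(res.success)
        else:
            x0 = np.zeros(K)
            res = optimize.minimize(
                lambda t: crit(np.clip(t, lo, hi))[0],
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-9,
                    "fatol": self.tol,
                    "maxiter": self.max_iter * 50 * K,
                    "maxfev": self.max_iter * 50 * K,
                },
            )
            theta = np.clip(res.x, lo, hi)
            converged = bool(res.success)

        # Snap boundary components to exactly zero and refit the equations
        # without them (gamma -> 0 removes the term from the model).
        gamma = np.exp(theta)
        zero = gamma < 1e-7
        active = [k for k in range(K) if not zero[k]]
        keep_cols = np.concatenate(
            [np.arange(p)] + [np.arange(offs[k], offs[k + 1]) for k in active]
        ).astype(int) if K else np.arange(p)
        A_f = A[np.ix_(keep_cols, keep_cols)]
        b_f = b[keep_cols]
        d = np.zeros(len(keep_cols))
        pos = p
        for k in active:
            d[pos : pos + q_sizes[k]] = 1.0 / gamma[k]
            pos += q_sizes[k]
        C = A_f + np.diag(d)
        cf = sla.cho_factor(C, lower=True, check_finite=False)
        s = sla.cho_solve(cf, b_f, check_finite=False)
        ypy = yy - b_f @ s
        sigma2_e = ypy / (n - p)
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        sum_q_log_gamma = float(
            sum(q_sizes[k] * np.log(gamma[k]) for k in active)
        )
        if sigma2_e <= 0 or degenerate:
            # Perfect fit: the restricted likelihood is unbounded above.
            sigma2_e = max(sigma2_e, 0.0)
            self.loglik_ = np.inf
        else:
            m2ll = (
                (n - p) * np.log(2 * np.pi * sigma2_e)
                + sum_q_log_gamma
                + logdetC
                + (n - p)
            )
            self.loglik_ = -0.5 * m2ll

        beta = s[:p]
        self.fixed_effects_ = pd.Series(
            beta, index=[f"{t}[{l}]" if l else t for t, l in x_names]
        )
        Cinv = sla.cho_solve(cf, np.eye(len(keep_cols)), check_finite=False)
        self._fixed_cov = sigma2_e * Cinv[:p, :p]
        self.fixed_se_ = pd.Series(
            np.sqrt(np.clip(np.diag(self._fixed_cov), 0, None)),
            index=self.fixed_effects_.index,
        )

        self.variance_components_ = {}
        self.random_effects_ = {}
        pos = p
        fitted = Xd @ beta
        for k in range(K):
            term, levels = z_meta[k]
            if k in active:
                u = s[pos : pos + q_sizes[k]]
                pos += q_sizes[k]
                self.variance_components_[term] = float(gamma[k] * sigma2_e)
                fitted = fitted + z_blocks[k] @ u
            else:
                u = np.zeros(q_sizes[k])
                self.variance_components_[term] = 0.0
            self.random_effects_[term] = pd.Series(u, index=levels)
        self.variance_components_["residual"] = float(sigma2_e)

        self.residuals_ = yv - fitted
        self.converged_ = converged
        self.n_records_ = n
        self.df_residual_ = n - p
        self.dropped_levels_ = dropped
        self._x_names = x_names
        self._p = p
        self._q_sizes = q_sizes
        self._row_index = df.index.to_numpy()
        self._fixed_shares = {
            term: _term_labels(df, term).value_counts(normalize=True).to_dict()
            for term in self.fixed
        }
        return self

    # ----------------------------------------------------------- diagnostics
    def per_group_residual_variance(self, groups) -> pd.Series:
        """Per-group residual variances from a second pass over the fit.

        Group means of squared conditional residuals are rescaled by a common
        factor so that their pooled value equals the REML residual variance —
        an implicit degrees-of-freedom correction for both the fixed-effect
        rank and the BLUP shrinkage.
        """
        g = pd.Series(np.asarray(groups), name="group")
        sq = pd.Series(self.residuals_**2)
        overall = sq.mean()
        scale = self.variance_components_["residual"] / overall if overall > 0 else 1.0
        return sq.groupby(g.values).mean() * scale

    def fixed_level_means(self, term: str) -> pd.DataFrame:
        """Population-level means mu + effect for each level of a fixed term.

        Other fixed categorical terms are averaged with weights equal to their
        record shares; random terms contribute zero (their BLUP mean).
        Returns a frame with columns ``estimate`` and ``se``.
        """
        if term not in self._fixed_levels:
            raise SpecificationError(f"{term!r} is not a fixed term of this fit")
        names = self._x_names
        p = self._p
        base = np.zeros(p)
        base[0] = 1.0
        for j, (t, lev) in enumerate(names):
            if t not in ("intercept", term):
                # population-averaged: weight by record share of the level
                base[j] = self._fixed_shares.get(t, {}).get(lev, 0.0)
        levels = self._fixed_levels[term]
        rows = np.tile(base, (len(levels), 1))
        for i, lev in enumerate(levels):
            for j, (t, l) in enumerate(names):
                if t == term:
                    rows[i, j] = 1.0 if l == lev else 0.0
        est = rows @ self.fixed_effects_.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", rows, self._fixed_cov, rows))
        return pd.DataFrame({"estimate": est, "se": se}, index=levels)

    def wald_test(self, term: str) -> Tuple[float, int, float]:
        """Joint Wald chi-square test that all effects of a fixed term are 0."""
        idx = [j for j, (t, _) in enumerate(self._x_names) if t == term]
        if not idx:
            raise SpecificationError(f"{term!r} has no estimable fixed effects")
        beta = self.fixed_effects_.to_numpy()[idx]
        V = self._fixed_cov[np.ix_(idx, idx)]
        stat = float(beta @ np.linalg.solve(V, beta))
        dof = len(idx)
        return stat, dof, float(stats.chi2.sf(stat, dof))


# --------------------------------------------------------------------- wrappers
def _spec_to_lists(spec: ModelSpec) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    return spec.fixed_terms(), spec.random_terms()


def reml_fit(records: pd.DataFrame, spec: ModelSpec, **kwargs) -> MixedModelREML:
    """Fit the trial model for one trait under the given role assignment."""
    fixed, random = _spec_to_lists(spec)
    model = MixedModelREML(fixed=fixed, random=random, **kwargs)
    return model.fit(records)


def reduce_model(
    records: pd.DataFrame,
    full: ModelSpec,
    candidate_term: str,
    alpha: float = 0.05,
    **kwargs,
) -> ModelSpec:
    """Drop ``candidate_term`` from ``full`` when it does not earn its keep.

    Fixed terms are tested with a joint Wald test; random terms with a REML
    likelihood-ratio test against the model without the term, using the
    boundary-corrected null mixture 0.5*chi2_0 + 0.5*chi2_1.  A random term
    whose inclusion prevents convergence is likewise dropped.
    """
    role = full.roles.get(candidate_term, "excluded")
    if role == "excluded":
        return full
    reduced = full.without(candidate_term)
    if role == "fixed":
        fit = reml_fit(records, full, **kwargs)
        _, _, p = fit.wald_test(candidate_term)
        return reduced if p >= alpha else full
    fit_full = reml_fit(records, full, **kwargs)
    fit_red = reml_fit(records, reduced, **kwargs)
    if not fit_full.converged_ and fit_red.converged_:
        return reduced
    lr = max(0.0, 2.0 * (fit_full.loglik_ - fit_red.loglik_))
    p = 0.5 * stats.chi2.sf(lr, 1) if lr > 0 else 1.0
    return reduced if p >= alpha else full


def fit_blues(
    records: pd.DataFrame,
    include_gt: bool = False,
    experiment_fixed: bool = True,
    all_accessions: Optional[Iterable[str]] = None,
    **kwargs,
) -> Tuple[pd.DataFrame, List[str]]:
    """Best linear unbiased estimates of accession means.

    Fits the trial model with accession fixed and year random (convariety
    excluded so that accession differences are retained); the experiment term
    and the accession x experiment interaction enter only when at least two
    experiment levels are present.  Returns a frame indexed by accession with
    columns ``estimate, se, n_records`` plus the list of accessions requested
    via ``all_accessions`` that have no surviving records.
    """
    df = records[records["status"] == "kept"] if "status" in records.columns else records
    if df["accession_id"].nunique() == 1:
        # degenerate but legal: the BLUE of a lone accession is its mean
        acc = df["accession_id"].iloc[0]
        v = df["value"].to_numpy(float)
        se = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
        out = pd.DataFrame(
            {"estimate": [float(v.mean())], "se": [se], "n_records": [len(v)]},
            index=pd.Index([acc], name="accession_id"),
        )
        missing = sorted(set(all_accessions) - {acc}) if all_accessions else []
        return out, missing
    fixed = ["accession_id"]
    random = ["year"] if df["year"].nunique() > 1 else []
    if "experiment" in df.columns and df["experiment"].nunique() > 1:
        if experiment_fixed:
            fixed.append("experiment")
        else:
            random.append("experiment")
        if include_gt:
            random.append("accession_id:experiment")
    model = MixedModelREML(fixed=fixed, random=random, **kwargs)
    model.fit(df)
    means = model.fixed_level_means("accession_id")
    counts = df.groupby("accession_id").size()
    out = means.join(counts.rename("n_records"))
    out.index.name = "accession_id"
    missing: List[str] = []
    if all_accessions is not None:
        missing = sorted(set(all_accessions) - set(out.index))
    out.attrs["model"] = model
    return out, missing
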