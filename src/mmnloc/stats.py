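"""Group-statistics layer: rank tests, AUROC, multiplicity control, the
empirical-Bayes screen and partial rank correlations.

Per test unit (grid point or dipole) the patient and control value
distributions are compared by the Mann-Whitney U test; the AUROC is the
U statistic normalised by n₁·n₂, oriented so that AUROC > 0.5 means the
patient values are higher.  Screening over many units uses
Benjamini-Hochberg FDR at 10% followed by the empirical-Bayes two-groups
model (:mod:`mmnloc.ebi`) for per-unit posteriors and achieved power.
Dipole-level families use a Bonferroni threshold and bootstrap AUROC
intervals.  Associations with neuropsychology scores use partial Spearman
correlation (rank-residualised on age and speech score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .ebi import EbiFit, ebi_fit

__all__ = [
    "mann_whitney",
    "auroc",
    "bootstrap_auroc",
    "bonferroni_threshold",
    "bh_fdr",
    "ebi_fit",
    "EbiFit",
    "PartialCorrResult",
    "spearman_partial",
    "GroupComparison",
    "GroupStatsResults",
    "assemble_stats",
]

EXACT_MAX_N = 12  # exact U enumeration up to this total sample size


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i < y_j} + ½·#ties — the 'y larger' orientation."""
    ranks = rankdata(np.concatenate([x, y]))
    ry = ranks[x.size :].sum()
    return float(ry - y.size * (y.size + 1) / 2.0)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p.

    U counts pairs with the y-value larger (ties count one half).  The
    p-value is by exact permutation enumeration when n₁+n₂ ≤ 12, otherwise
    by the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        dev = abs(u - mu)
        hits = total = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            u_p = _u_statistic(pooled[mask], pooled[~mask])
            hits += abs(u_p - mu) >= dev - 1e-12
            total += 1
        return u, hits / total
    ties = np.unique(np.concatenate([x, y]), return_counts=True)[1]
    n = n1 + n2
    tie_term = (ties**3 - ties).sum() / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if sigma == 0:
        return u, 1.0
    zval = (abs(u - mu) - 0.5) / sigma
    return u, float(2 * norm.sf(max(zval, 0.0)))


def auroc(x, y) -> float:
    """Area under the ROC curve: P(y > x) + ½ P(y = x) = U / (n₁ n₂)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    return _u_statistic(x, y) / (x.size * y.size)


def _auroc_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for (B, n1) vs (B, n2) samples."""
    ranks = rankdata(np.concatenate([X, Y], axis=1), axis=1)
    ry = ranks[:, X.shape[1] :].sum(axis=1)
    n2 = Y.shape[1]
    return (ry - n2 * (n2 + 1) / 2.0) / (X.shape[1] * n2)


def bootstrap_auroc(
    x, y, B: int = 10000, seed: int = 0, ci: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """AUROC with bootstrap percentile CI and a permutation p-value.

    Subjects are resampled with replacement within each group for the CI;
    the p-value is the two-sided tail of the group-label permutation null of
    |AUROC − 0.5| (add-one rule).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if B < 100:
        raise ValueError("B must be >= 100")
    a_obs = auroc(x, y)
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, x.size, size=(B, x.size))]
    by = y[rng.integers(0, y.size, size=(B, y.size))]
    boots = _auroc_rows(bx, by)
    alpha = 1 - ci
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    pooled = np.concatenate([x, y])
    perm = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
    a_perm = _auroc_rows(perm[:, : x.size], perm[:, x.size :])
    p = (1.0 + np.sum(np.abs(a_perm - 0.5) >= abs(a_obs - 0.5) - 1e-12)) / (B + 1.0)
    return a_obs, (float(lo), float(hi)), float(p)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr(pvals, q: float = 0.10, mask=None) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery flags at level q.

    ``mask`` marks valid units; masked-out (undefined) units are excluded
    from the family size and reported as non-discoveries.
    """
    p = np.asarray(pvals, float)
    valid = np.ones(p.shape, bool) if mask is None else np.asarray(mask, bool)
    if np.any((p[valid] < 0) | (p[valid] > 1)) or np.any(~np.isfinite(p[valid])):
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.shape, bool)
    if valid.any():
        flags[valid] = multipletests(p[valid], alpha=q, method="fdr_bh")[0]
    return flags


@dataclass
class PartialCorrResult:
    rho: float
    p: float
    n: int
    covariates: list


def spearman_partial(x, y, covariates=None) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed; the x- and y-ranks are residualised
    on the covariate ranks (with intercept) by least squares and the Pearson
    correlation of the residuals is returned, with a t-test on n − 2 − k
    degrees of freedom.  With no covariates this is exactly the ordinary
    Spearman correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = (
        np.empty((x.size, 0))
        if covariates is None
        else np.atleast_2d(np.asarray(covariates, float))
    )
    if C.shape[0] != x.size and C.shape[1] == x.size:
        C = C.T
    k = C.shape[1]
    n = x.size
    if y.size != n or C.shape[0] != n:
        raise ValueError("x, y and covariates must have equal length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(C)):
        raise ValueError("missing values are not supported")
    if n < k + 3:
        raise ValueError("need at least k + 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    design = np.column_stack([np.ones(n)] + [rankdata(C[:, j]) for j in range(k)])
    rx_res = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry_res = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((rx_res**2).sum() * (ry_res**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined (residuals constant)")
    rho = float(np.clip((rx_res * ry_res).sum() / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        tval = rho * np.sqrt(dof / (1.0 - rho**2))
        p = float(2 * t_dist.sf(abs(tval), dof))
    return PartialCorrResult(rho=rho, p=p, n=n, covariates=list(range(k)))


# ---------------------------------------------------------------------------
# per-unit group comparison


class GroupComparison:
    """Mann-Whitney / AUROC / FDR / empirical-Bayes screen over test units.

    Parameters
    ----------
    values : (n_subjects, n_units) array or DataFrame
        One measurement per subject per unit (dipole power, region ratio...).
    groups : sequence of str
        Group label per subject; exactly two distinct labels.
    group_order : (str, str)
        (reference, test) — AUROC > 0.5 means the *test* group is higher.
    unit_meta : DataFrame, optional
        Per-unit metadata (coordinates, region) carried into the output.
    q : float
        BH-FDR level for the screening flags.
    n_boot : int
        If > 0, bootstrap AUROC intervals are computed per unit (use only
        for small families such as the four dipoles).
    """

    def __init__(
        self,
        values,
        groups,
        group_order: tuple[str, str] = ("control", "patient"),
        unit_meta: pd.DataFrame | None = None,
        q: float = 0.10,
        use_ebi: bool = True,
        n_boot: int = 0,
        seed: int = 0,
    ):
        if isinstance(values, pd.DataFrame):
            unit_ids = list(values.columns)
            values = values.to_numpy(float)
        else:
            values = np.asarray(values, float)
            unit_ids = list(range(values.shape[1]))
        groups = np.asarray(groups)
        if groups.shape[0] != values.shape[0]:
            raise ValueError("one group label per subject required")
        for g in group_order:
            if (groups == g).sum() < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        self.values = values
        self.groups = groups
        self.group_order = group_order
        self.unit_ids = unit_ids
        self.unit_meta = unit_meta
        self.q = q
        self.use_ebi = use_ebi
        self.n_boot = n_boot
        self.seed = seed

    def fit(self) -> "GroupStatsResults":
        ref, test = self.group_order
        X = self.values[self.groups == ref]
        Y = self.values[self.groups == test]
        n1, n2 = X.shape[0], Y.shape[0]
        n_units = self.values.shape[1]
        valid = ~np.isnan(self.values).any(axis=0)
        U = np.full(n_units, np.nan)
        p = np.full(n_units, np.nan)
        a = np.full(n_units, np.nan)
        ci = np.full((n_units, 2), np.nan)
        pb = np.full(n_units, np.nan)
        for j in np.flatnonzero(valid):
            U[j], p[j] = mann_whitney(X[:, j], Y[:, j])
            a[j] = U[j] / (n1 * n2)
            if self.n_boot:
                _, ci_j, pb[j] = bootstrap_auroc(
                    X[:, j], Y[:, j], B=self.n_boot, seed=self.seed + j
                )
                ci[j] = ci_j
        flags = bh_fdr(np.where(valid, p, 1.0), q=self.q, mask=valid)

        # tie-corrected z-scores of the U statistics for the EBI layer
        z = np.full(n_units, np.nan)
        for j in np.flatnonzero(valid):
            ties = np.unique(self.values[:, j], return_counts=True)[1]
            n = n1 + n2
            tie_term = (ties**3 - ties).sum() / (n * (n - 1))
            sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
            z[j] = 0.0 if sigma == 0 else (U[j] - n1 * n2 / 2.0) / sigma

        ebi = None
        posterior = np.full(n_units, np.nan)
        lfdr = np.full(n_units, np.nan)
        if self.use_ebi and valid.sum() >= 100:
            try:
                ebi = ebi_fit(z[valid])
            except ValueError as exc:
                # e.g. heavily discrete z from very small groups
                warnings.warn(f"empirical-Bayes fit skipped: {exc}", RuntimeWarning)
            else:
                posterior[valid] = ebi.posterior
                lfdr[valid] = ebi.local_fdr
        table = pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "U": U,
                "p": p,
                "fdr_flag": flags,
                "auroc": a,
                "auroc_lo": ci[:, 0],
                "auroc_hi": ci[:, 1],
                "p_boot": pb,
                "z": z,
                "posterior": posterior,
                "local_fdr": lfdr,
                "defined": valid,
            }
        )
        if self.unit_meta is not None:
            table = pd.concat(
                [self.unit_meta.reset_index(drop=True), table], axis=1
            )
        return GroupStatsResults(self, table, ebi)


class GroupStatsResults:
    """Per-unit statistics table plus the fitted empirical-Bayes model."""

    def __init__(self, model: GroupComparison, table: pd.DataFrame, ebi: EbiFit | None):
        self.model = model
        self.table = table
        self.ebi = ebi

    @property
    def n_discoveries(self) -> int:
        return int(self.table["fdr_flag"].sum())

    def summary(self) -> str:
        t = self.table
        ref, test = self.model.group_order
        lines = [
            f"Group comparison: {test} vs {ref} "
            f"({(self.model.groups == test).sum()} vs {(self.model.groups == ref).sum()} subjects, "
            f"{int(t['defined'].sum())} units)",
            f"  BH-FDR (q={self.model.q:g}): {self.n_discoveries} discoveries",
        ]
        if self.ebi is not None:
            lines.append(
                f"  EBI: p0={self.ebi.p0:.3f}, null=N({self.ebi.null_mean:.2f}, "
                f"{self.ebi.null_sd:.2f}²), achieved power={self.ebi.achieved_power:.2f}"
            )
        top = t.loc[t["defined"]].nlargest(3, "auroc")
        for _, row in top.iterrows():
            lines.append(
                f"  unit {row['unit_id']}: AUROC={row['auroc']:.3f}, p={row['p']:.2e}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def assemble_stats(
    values,
    groups,
    unit_meta: pd.DataFrame | None = None,
    q: float = 0.10,
    group_order: tuple[str, str] = ("control", "patient"),
    use_ebi: bool = True,
    n_boot: int = 0,
    seed: int = 0,
) -> GroupStatsResults:
    """Functional wrapper around :class:`GroupComparison`."""
    return GroupComparison(
        values,
        groups,
        group_order=group_order,
        unit_meta=unit_meta,
        q=q,
        use_ebi=use_ebi,
        n_boot=n_boot,
        seed=seed,
    ).fit()
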