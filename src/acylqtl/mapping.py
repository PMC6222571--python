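"""Single-marker regression scans, Bonferroni thresholds, stepwise covariates.

The scan fits, for each marker i, the ordinary least-squares model

    phenotype = b0 + b1 * SNP_i + sum_k bk * Q_k + e

where SNP_i is the numeric genotype code (0/1/2) and Q_k are previously
selected marker covariates.  Significance of b1 is the two-sided t-test
(df = n_used - model rank).  Samples with a missing genotype or phenotype are
dropped pairwise per marker.  Markers that are monomorphic among the used
samples, or collinear with the covariate set, are assigned p = 1 and flagged.

The genome-wide threshold is the Bonferroni correction alpha / n_tests; a
relaxed exploratory threshold (e.g. p < 1e-4) is just another
:class:`Threshold`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTraitError, InvalidInputError
from .genotypes import GenotypeMatrix

_P_FLOOR = 1e-300  # perfect fits would otherwise give p = 0 exactly


@dataclass(frozen=True)
class Threshold:
    """A per-test significance level with family-wise bookkeeping."""

    alpha: float
    n_tests: int
    per_test_p: float
    minus_log10: float

    @classmethod
    def from_per_test_p(cls, p: float) -> "Threshold":
        """Exploratory threshold stated directly as a per-test p-value."""
        if not 0 < p < 1:
            raise InvalidInputError("per-test p must lie in (0, 1)")
        return cls(alpha=p, n_tests=1, per_test_p=p, minus_log10=-math.log10(p))


def bonferroni(alpha: float = 0.05, n_tests: int = 1) -> Threshold:
    """Family-wise threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise InvalidInputError("n_tests must be >= 1")
    p = alpha / n_tests
    return Threshold(alpha=alpha, n_tests=n_tests, per_test_p=p, minus_log10=-math.log10(p))


@dataclass
class ScanResult:
    """Per-marker scan output for one trait under one covariate set."""

    table: pd.DataFrame  # chrom, pos, beta, p, minus_log10_p, n_used, flag
    covariates: list[int] = field(default_factory=list)
    trait: str = "trait"
    chrom_lengths: dict[int, int] | None = None

    def top_marker(self) -> int:
        """Row index of the most significant marker; ties broken by coordinate."""
        t = self.table
        order = np.lexsort(
            (t["pos"].to_numpy(), t["chrom"].to_numpy(), t["p"].to_numpy())
        )
        return int(order[0])


def _finalize(beta, t_stat, df, n_used, flags):
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t_stat), np.maximum(df, 1))
    p = np.where(flags != "", 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), _P_FLOOR, 1.0)
    beta = np.where(flags != "", np.nan, beta)
    return beta, p


def scan_single_marker(
    g: GenotypeMatrix,
    y,
    covariates: list[int] | tuple[int, ...] = (),
    trait: str = "trait",
) -> ScanResult:
    """OLS scan of every marker against a trait vector.

    ``covariates`` are row indices into the same genotype matrix whose codes
    enter the model alongside each tested marker.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (g.n_samples,):
        raise InvalidInputError("trait length does not match sample count")
    finite_y = y[np.isfinite(y)]
    if finite_y.size == 0 or np.ptp(finite_y) == 0:
        raise DegenerateTraitError("trait is constant (or empty) across samples")

    X = g.codes
    m, n = X.shape
    cov_idx = list(covariates)
    C = X[cov_idx] if cov_idx else np.empty((0, n))

    any_missing = (
        np.isnan(y).any() or np.isnan(X).any() or (len(cov_idx) and np.isnan(C).any())
    )
    if not cov_idx:
        beta, p, n_used, flags = _scan_simple_masked(X, y)
    elif not any_missing:
        beta, p, n_used, flags = _scan_fwl(X, y, C, cov_idx)
    else:
        beta, p, n_used, flags = _scan_loop(X, y, C, cov_idx)

    table = pd.DataFrame(
        {
            "chrom": g.markers.chroms,
            "pos": g.markers.positions,
            "beta": beta,
            "p": p,
            "minus_log10_p": -np.log10(p),
            "n_used": n_used,
            "flag": flags,
        }
    )
    return ScanResult(
        table=table,
        covariates=cov_idx,
        trait=trait,
        chrom_lengths=dict(g.markers.chrom_lengths),
    )


def _scan_simple_masked(X: np.ndarray, y: np.ndarray):
    """Vectorised simple regression with pairwise-complete masking."""
    m, n = X.shape
    valid = ~np.isnan(X) & ~np.isnan(y)[None, :]
    n_used = valid.sum(axis=1).astype(float)
    Xv = np.where(valid, X, 0.0)
    Yv = np.where(valid, y[None, :], 0.0)
    Sx = Xv.sum(1)
    Sy = Yv.sum(1)
    Sxx = (Xv * Xv).sum(1)
    Sxy = (Xv * Yv).sum(1)
    Syy = (Yv * Yv).sum(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sxx_c = Sxx - Sx * Sx / n_used
        Sxy_c = Sxy - Sx * Sy / n_used
        Syy_c = Syy - Sy * Sy / n_used
        beta = Sxy_c / Sxx_c
        sse = np.maximum(Syy_c - beta * Sxy_c, 0.0)
        df = n_used - 2.0
        se2 = sse / df / Sxx_c
        t_stat = beta / np.sqrt(se2)

    scale = np.maximum(Sxx, 1.0)
    flags = np.full(m, "", dtype=object)
    flags[n_used < 3] = "insufficient_n"
    flags[(n_used >= 3) & (Sxx_c <= 1e-12 * scale)] = "monomorphic"
    beta, p = _finalize(beta, t_stat, df, n_used, flags)
    return beta, p, n_used.astype(int), flags


def _orth_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of [1, C.T] (n x (1+k))."""
    n = C.shape[1]
    M = np.column_stack([np.ones(n)] + [C[i] for i in range(C.shape[0])])
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    return u[:, :rank]


def _scan_fwl(X: np.ndarray, y: np.ndarray, C: np.ndarray, cov_idx: list[int]):
    """Complete-data scan with covariates via Frisch-Waugh-Lovell projection."""
    m, n = X.shape
    Q = _orth_basis(C)
    r = Q.shape[1]
    y_t = y - Q @ (Q.T @ y)
    X_t = X - (X @ Q) @ Q.T
    Sxx = (X_t * X_t).sum(1)
    Sxy = X_t @ y_t
    Syy = float(y_t @ y_t)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = Sxy / Sxx
        sse = np.maximum(Syy - beta * Sxy, 0.0)
        df = float(n - r - 1)
        t_stat = beta / np.sqrt(sse / df / Sxx)

    raw_scale = np.maximum((X * X).sum(1), 1.0)
    flags = np.full(m, "", dtype=object)
    flags[Sxx <= 1e-10 * raw_scale] = "collinear"
    flags[[i for i in cov_idx]] = "collinear"
    if n - r - 1 < 1:
        flags[:] = "insufficient_n"
    beta, p = _finalize(beta, t_stat, np.full(m, df), n, flags)
    return beta, p, np.full(m, n, dtype=int), flags


def _scan_loop(X: np.ndarray, y: np.ndarray, C: np.ndarray, cov_idx: list[int]):
    """Per-marker OLS with pairwise-complete rows (covariate case with missing)."""
    m, n = X.shape
    beta = np.full(m, np.nan)
    t_stat = np.full(m, np.nan)
    df_arr = np.zeros(m)
    n_used = np.zeros(m, dtype=int)
    flags = np.full(m, "", dtype=object)
    cov_ok = ~np.isnan(C).any(axis=0) if len(C) else np.ones(n, dtype=bool)
    base_valid = np.isfinite(y) & cov_ok
    for i in range(m):
        v = base_valid & ~np.isnan(X[i])
        nu = int(v.sum())
        n_used[i] = nu
        k = C.shape[0]
        if nu < k + 3:
            flags[i] = "insufficient_n"
            continue
        D = np.column_stack(
            [np.ones(nu), X[i, v]] + [C[j, v] for j in range(k)]
        )
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            x_c = X[i, v] - X[i, v].mean()
            if float(x_c @ x_c) <= 1e-12 * max(float((X[i, v] ** 2).sum()), 1.0):
                flags[i] = "monomorphic"
            else:
                flags[i] = "collinear"
            continue
        coef, res, _, _ = np.linalg.lstsq(D, y[v], rcond=None)
        fitted = D @ coef
        sse = float(((y[v] - fitted) ** 2).sum())
        dof = nu - D.shape[1]
        if dof < 1:
            flags[i] = "insufficient_n"
            continue
        xtx_inv = np.linalg.inv(D.T @ D)
        se = math.sqrt(max(sse / dof, 0.0) * xtx_inv[1, 1])
        beta[i] = coef[1]
        df_arr[i] = dof
        t_stat[i] = coef[1] / se if se > 0 else np.inf
    beta, p = _finalize(beta, t_stat, df_arr, n_used, flags)
    return beta, p, n_used, flags


@dataclass
class StepwiseResult:
    """All scan rounds plus the markers selected as QTL, in selection order."""

    rounds: list[ScanResult]
    selected: list[int]  # marker row indices
    threshold: Threshold


def stepwise_scan(
    g: GenotypeMatrix,
    y,
    threshold: Threshold,
    max_qtl: int = 10,
    trait: str = "trait",
) -> StepwiseResult:
    """Forward covariate selection: rescan with each selected top marker as Q.

    Round 1 scans with no covariates; while the top marker is significant at
    the per-test threshold and fewer than ``max_qtl`` markers are selected,
    the top marker joins the covariate set and the scan repeats.  Ties on p
    are broken by genomic coordinate (chromosome, then position).
    """
    if max_qtl < 1:
        raise InvalidInputError("max_qtl must be >= 1")
    rounds: list[ScanResult] = []
    selected: list[int] = []
    while True:
        res = scan_single_marker(g, y, covariates=selected, trait=trait)
        rounds.append(res)
        top = res.top_marker()
        if res.table.loc[top, "p"] < threshold.per_test_p and len(selected) < max_qtl:
            selected.append(top)
            continue
        break
    return StepwiseResult(rounds=rounds, selected=selected, threshold=threshold)


def significant_interval(
    result: ScanResult, threshold: Threshold, chromosome: int
) -> tuple[int, int] | None:
    """Span (min bp, max bp) of threshold-passing markers on one chromosome."""
    t = result.table
    sig = t[(t["chrom"] == chromosome) & (t["p"] < threshold.per_test_p)]
    if sig.empty:
        return None
    return int(sig["pos"].min()), int(sig["pos"].max())


def manhattan_export(result: ScanResult, threshold: Threshold) -> pd.DataFrame:
    """Per-marker table with a cumulative genome coordinate for plotting.

    Attaches the threshold line value in ``DataFrame.attrs['threshold_minus_log10']``.
    """
    t = result.table.copy()
    lengths = result.chrom_lengths or {
        int(c): int(t.loc[t["chrom"] == c, "pos"].max()) for c in t["chrom"].unique()
    }
    offset = 0
    offsets = {}
    for c in sorted(lengths):
        offsets[c] = offset
        offset += lengths[c]
    t["cum_pos"] = t["pos"] + t["chrom"].map(offsets)
    t["significant"] = t["p"] < threshold.per_test_p
    out = t[["chrom", "pos", "cum_pos", "minus_log10_p", "significant"]]
    out.attrs["threshold_minus_log10"] = threshold.minus_log10
    return out


def manhattan_plot(df: pd.DataFrame, threshold: Threshold, path) -> None:
    """Scatter the cumulative-coordinate table with the threshold line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    for i, (chrom, grp) in enumerate(df.groupby("chrom")):
        ax.scatter(
            grp["cum_pos"], grp["minus_log10_p"], s=6,
            color=("tab:blue", "tab:orange")[i % 2],
        )
    ax.axhline(threshold.minus_log10, color="red", ls="--", lw=1)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
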