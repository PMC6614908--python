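"""Single-SNP association scans, conditional regression, and LD metrics.

The scan is ordinary least squares of the phenotype on each site's dosage
(0-2 real values; dosages rather than best-guess genotypes for imputed
data).  Closed-form normal equations are used throughout — the same
arithmetic the rest of the package (J-test, Bayes factors, stepwise
selection) builds on.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import AssocResult, GenotypeDataset, HaplotypePanel, LDStats, PhenotypeVector

__all__ = ["scan", "ld_metrics", "conditional_regression", "ols_single"]

_ZERO_VAR_TOL = 1e-12


def _phenotype_values(y) -> np.ndarray:
    if isinstance(y, PhenotypeVector):
        return y.values
    return np.asarray(y, dtype=np.float64)


def ols_single(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """Simple-regression fit of ``y`` on ``x`` with an intercept.

    Returns ``(beta, se, t, p, r2, intercept)``; used both directly and as
    the scalar reference for the vectorized scan.
    """
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx < _ZERO_VAR_TOL:
        return (np.nan,) * 5 + (float(y.mean()),)
    sxy = float(xc @ yc)
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = syy - beta * sxy
    df = n - 2
    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(sigma2 / sxx)
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * stats.t.sf(abs(t), df) if df > 0 else np.nan
    r2 = beta * sxy / syy if syy > 0 else np.nan
    return beta, se, t, p, r2, float(y.mean() - beta * x.mean())


def _rank_order(
    p: np.ndarray, t: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Ascending p, ties by descending |t|, then by position; NaNs excluded."""
    valid = np.flatnonzero(np.isfinite(p))
    keys = np.lexsort(
        (positions[valid], -np.abs(t[valid]), p[valid])
    )
    return valid[keys]


def scan(data: GenotypeDataset, y) -> AssocResult:
    """Per-site OLS association scan of phenotype on dosage.

    Zero-variance (monomorphic) sites are flagged with NaN statistics and
    excluded from the ranking.
    """
    yv = _phenotype_values(y)
    n = data.n_samples
    if len(yv) != n:
        raise ValueError("phenotype length must match sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")

    X = data.dosages
    xc = X - X.mean(axis=0, keepdims=True)
    yc = yv - yv.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    df = n - 2

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > _ZERO_VAR_TOL, sxy / np.maximum(sxx, _ZERO_VAR_TOL), np.nan)
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r2 = np.clip(beta * sxy / syy, 0.0, 1.0) if syy > 0 else np.full_like(beta, np.nan)
    intercept = yv.mean() - beta * X.mean(axis=0)

    positions = data.sites["position"].to_numpy()
    order = _rank_order(p, t, positions)
    return AssocResult(
        site_ids=data.site_ids,
        beta=beta,
        se=se,
        t_stat=t,
        p_value=p,
        r2=r2,
        intercept=intercept,
        n_used=n,
        order=order,
    )


def conditional_regression(
    data: GenotypeDataset,
    y,
    condition_ids: list[str],
    collinearity_cap: float = 0.9,
) -> AssocResult:
    """Association of each remaining site conditional on a set of SNPs.

    Equivalent to, per remaining site, OLS of y on that site plus all
    conditioned sites, reported as the conditional test of the site's
    coefficient (computed by residualizing both y and the candidate
    dosages on the conditioned design — the Frisch-Waugh identity).

    An empty ``condition_ids`` reduces exactly to :func:`scan`.
    """
    if not condition_ids:
        return scan(data, y)
    yv = _phenotype_values(y)
    n = data.n_samples
    cond_idx = [data.site_index(s) for s in condition_ids]

    # collinearity screen among the conditioned SNPs
    if len(cond_idx) > 1:
        Xc = data.dosages[:, cond_idx]
        cc = np.corrcoef(Xc, rowvar=False) ** 2
        for i in range(len(cond_idx)):
            for j in range(i + 1, len(cond_idx)):
                if cc[i, j] >= collinearity_cap:
                    raise ValueError(
                        "conditioned SNPs are collinear: "
                        f"{condition_ids[i]} vs {condition_ids[j]} "
                        f"(r2={cc[i, j]:.3f} >= cap {collinearity_cap})"
                    )

    c = len(cond_idx)
    design = np.column_stack([np.ones(n), data.dosages[:, cond_idx]])
    coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
    y_res = yv - design @ coef

    rest = np.setdiff1d(np.arange(data.n_sites), cond_idx)
    Xr = data.dosages[:, rest]
    coefs, *_ = np.linalg.lstsq(design, Xr, rcond=None)
    X_res = Xr - design @ coefs

    df = n - c - 2
    sxx = np.einsum("ij,ij->j", X_res, X_res)
    sxy = X_res.T @ y_res
    syy = float(y_res @ y_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > _ZERO_VAR_TOL, sxy / np.maximum(sxx, _ZERO_VAR_TOL), np.nan)
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        r2 = np.clip(beta * sxy / syy, 0.0, 1.0) if syy > 0 else np.full_like(beta, np.nan)

    positions = data.sites["position"].to_numpy()[rest]
    order = _rank_order(p, t, positions)
    return AssocResult(
        site_ids=data.site_ids[rest],
        beta=beta,
        se=se,
        t_stat=t,
        p_value=p,
        r2=r2,
        intercept=np.full_like(beta, np.nan),
        n_used=n,
        order=order,
    )


def _ld_from_hap_freqs(f: np.ndarray) -> LDStats:
    f_ab, f_aB, f_Ab, f_AB = f[3], f[2], f[1], f[0]
    p_a = f_AB + f_Ab  # freq of '1' allele at site A
    p_b = f_AB + f_aB
    d = f_AB - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom if denom > 0 else 0.0
    return LDStats(d=float(d), d_prime=float(min(d_prime, 1.0)), r2=float(min(r2, 1.0)), hap_freqs=f)


def _em_hap_freqs(ga: np.ndarray, gb: np.ndarray, max_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies from unphased genotypes.

    Only the double heterozygote is phase-ambiguous.  Start at linkage
    equilibrium; iterate the standard E step splitting double hets between
    the coupling (AB/ab) and repulsion (Ab/aB) configurations.
    """
    n = len(ga)
    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[int(i), int(j)] += 1
    p_a = ga.mean() / 2.0
    p_b = gb.mean() / 2.0
    # f = [f_AB, f_Ab, f_aB, f_ab] with A/B the '1' alleles
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    n_dh = counts[1, 1]
    # known haplotype counts contributed by unambiguous genotypes
    base = np.zeros(4)
    base[0] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    base[1] = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    base[2] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[3] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    total = 2.0 * n
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        w = f[0] * f[3] / denom if denom > 0 else 0.5
        new = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def ld_metrics(data_or_panel, site_a: str, site_b: str) -> LDStats:
    """Two-locus LD (D, D', r2) between two sites.

    Uses phased haplotype counts when available (a :class:`HaplotypePanel`,
    or a :class:`GenotypeDataset` carrying its simulated haplotypes);
    otherwise estimates haplotype frequencies from unphased hard calls by
    EM.  The D' = 1 / low-r2 configuration — one of the four haplotype
    classes missing, with different allele frequencies at the two sites —
    is the signature of a masking SNP.
    """
    if isinstance(data_or_panel, HaplotypePanel):
        haps = data_or_panel.alleles
        ia = data_or_panel.site_index(site_a)
        ib = data_or_panel.site_index(site_b)
    else:
        data: GenotypeDataset = data_or_panel
        ia = data.site_index(site_a)
        ib = data.site_index(site_b)
        haps = data.haplotypes

    if haps is not None:
        a = haps[:, ia].astype(np.int64)
        b = haps[:, ib].astype(np.int64)
        if a.min() == a.max() or b.min() == b.max():
            raise ValueError("both sites must be polymorphic")
        h = len(a)
        f = np.array(
            [
                np.sum((a == 1) & (b == 1)),
                np.sum((a == 1) & (b == 0)),
                np.sum((a == 0) & (b == 1)),
                np.sum((a == 0) & (b == 0)),
            ],
            dtype=np.float64,
        ) / h
    else:
        ga = np.rint(data.dosages[:, ia])
        gb = np.rint(data.dosages[:, ib])
        if ga.min() == ga.max() or gb.min() == gb.max():
            raise ValueError("both sites must be polymorphic")
        f = _em_hap_freqs(ga, gb)
    return _ld_from_hap_freqs(f)
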