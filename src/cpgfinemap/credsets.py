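"""Three constructors of 95% credible sets under a single-causal assumption.

* J-test: a frequentist confidence set built from Davidson-MacKinnon
  non-nested regression tests of the top SNP against each rival SNP.
* PPA: per-SNP Bayes factors (Wakefield's approximate BF by default)
  normalized locus-wide into posterior probabilities of association and
  accumulated to the nominal level.
* MCMC counting: a spike-and-slab Gibbs sampler over a sparse linear
  model; the top included variant is recorded every ``thin``-th iteration
  and sites are accumulated by count share.

All three hard-wire the single-causal-variant assumption, and all three
apply the same complete-LD rule: sites indistinguishable on the analyzed
data (r^2 = 1) are treated as one unit — tested once, counted together,
and admitted to the set together.
"""

from __future__ import annotations

import logging

import numpy as np
from numba import njit
from scipy import stats

from . import assoc
from .core import BayesFactorSet, CredibleSet, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "complete_ld_groups",
    "jtest_credible_set",
    "compute_bayes_factors",
    "ppa_credible_set",
    "spike_slab_sampler",
    "count_credible_set",
    "mcmc_credible_set",
]

_COMPLETE_LD_TOL = 1e-9


def complete_ld_groups(data: GenotypeDataset, tol: float = _COMPLETE_LD_TOL) -> np.ndarray:
    """Group id per site; sites with dosage r^2 >= 1 - tol share a group."""
    X = data.dosages
    M = X.shape[1]
    sd = X.std(axis=0)
    group = np.arange(M)

    def find(i):
        while group[i] != i:
            group[i] = group[group[i]]
            i = group[i]
        return i

    poly = np.flatnonzero(sd > 0)
    if len(poly) > 1:
        C = np.corrcoef(X[:, poly], rowvar=False)
        r2 = C * C
        for a in range(len(poly)):
            for b in range(a + 1, len(poly)):
                if r2[a, b] >= 1.0 - tol:
                    ra, rb = find(poly[a]), find(poly[b])
                    if ra != rb:
                        group[max(ra, rb)] = min(ra, rb)
    return np.array([find(i) for i in range(M)])


def _lambda_pvalue(y: np.ndarray, x_n: np.ndarray, fitted: np.ndarray) -> float:
    """p-value of the fitted-values coefficient in y ~ 1 + x_n + fitted."""
    n = len(y)
    X = np.column_stack([np.ones(n), x_n, fitted])
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        # x_n collinear with the fitted values (e.g. complete LD with the
        # top SNP): lambda is unidentified; treat as non-significant
        return 1.0
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - 3
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * XtX_inv[2, 2])
    if se == 0:
        return 0.0
    t = coef[2] / se
    return float(2.0 * stats.t.sf(abs(t), df))


def jtest_credible_set(
    data: GenotypeDataset, y, alpha: float = 0.05
) -> CredibleSet:
    """Confidence set from sequential J-tests of the top SNP vs rivals.

    The SNPs are ranked by association strength.  The top SNP enters the
    set.  For N = 2, 3, ... the N-th best SNP is regressed on the
    phenotype together with the fitted values of the top-SNP regression;
    if the fitted-values coefficient is significant at the
    Bonferroni-corrected level alpha/(N-1) — i.e. the top SNP explains
    significantly more variance than rival N — the procedure stops and
    rival N (and everything ranked below) is excluded; otherwise rival N
    joins the set.  Complete-LD partners are tested once and admitted or
    excluded together.  ``evidence`` holds each member's marginal p-value.
    """
    yv = assoc._phenotype_values(y)
    res = assoc.scan(data, yv)
    groups = complete_ld_groups(data)
    ranked = res.order
    if len(ranked) == 0:
        raise ValueError("no polymorphic sites to fine-map")

    top_idx = ranked[0]
    x1 = data.dosages[:, top_idx]
    fitted = res.intercept[top_idx] + res.beta[top_idx] * x1

    members: list[int] = []
    seen_groups: set[int] = set()

    def admit(rep: int) -> None:
        g = groups[rep]
        seen_groups.add(g)
        for i in np.flatnonzero(groups == g):
            members.append(int(i))

    admit(top_idx)
    n_test = 1  # N - 1, number of comparisons performed
    for idx in ranked[1:]:
        if groups[idx] in seen_groups:
            continue
        p_lambda = _lambda_pvalue(yv, data.dosages[:, idx], fitted)
        threshold = alpha / n_test
        n_test += 1
        if p_lambda < threshold:
            break
        admit(int(idx))

    members_arr = np.array(members)
    # keep ranking order within the set for readability
    rank_of = {int(i): k for k, i in enumerate(ranked)}
    members_arr = members_arr[np.argsort([rank_of.get(int(i), len(ranked)) for i in members_arr])]
    return CredibleSet(
        method="jtest",
        level=1.0 - alpha,
        members=[str(data.site_ids[i]) for i in members_arr],
        evidence=res.p_value[members_arr],
    )


def compute_bayes_factors(
    data: GenotypeDataset,
    y,
    W: float = 0.5,
    model: str = "wakefield_abf",
) -> BayesFactorSet:
    """Per-site log10 Bayes factor of the single-SNP model against the null.

    ``model='wakefield_abf'`` (default) uses Wakefield's approximation from
    the OLS estimate and its variance V = se^2:

        ABF = sqrt(V / (V + W)) * exp(z^2 W / (2 (V + W)))

    with ``W`` the prior variance of the effect size.  The default
    W = 0.5 (phenotype standardized internally by the caller's scale) is
    deliberately wide to accommodate the very large effects typical of
    CpG-SNP methylation QTL.  ``model='conjugate_exact'`` evaluates the
    exact marginal-likelihood ratio under a conjugate normal prior
    beta ~ N(0, W sigma^2) with flat intercept and Jeffreys sigma^2.
    Zero-variance sites get log10 BF = 0 with a warning.
    """
    if W <= 0:
        raise ValueError("prior variance W must be positive")
    yv = assoc._phenotype_values(y)
    res = assoc.scan(data, yv)
    M = data.n_sites
    log10_bf = np.zeros(M)

    if model == "wakefield_abf":
        for i in range(M):
            if not np.isfinite(res.beta[i]):
                logger.warning("zero-variance site %s: BF set to 1", data.site_ids[i])
                continue
            V = res.se[i] ** 2
            z2 = (res.beta[i] / res.se[i]) ** 2
            log10_bf[i] = 0.5 * np.log10(V / (V + W)) + (
                z2 * W / (2.0 * (V + W))
            ) / np.log(10.0)
    elif model == "conjugate_exact":
        n = data.n_samples
        yc = yv - yv.mean()
        syy = float(yc @ yc)
        for i in range(M):
            x = data.dosages[:, i]
            xc = x - x.mean()
            sxx = float(xc @ xc)
            if sxx < 1e-12:
                logger.warning("zero-variance site %s: BF set to 1", data.site_ids[i])
                continue
            sxy = float(xc @ yc)
            rss_w = syy - sxy * sxy / (sxx + 1.0 / W)
            log10_bf[i] = -0.5 * np.log10(1.0 + W * sxx) - ((n - 1) / 2.0) * np.log10(
                rss_w / syy
            )
    else:
        raise ValueError(f"unknown Bayes factor model: {model!r}")
    return BayesFactorSet(site_ids=data.site_ids, log10_bf=log10_bf, W=W, model=model)


def ppa_credible_set(bfs: BayesFactorSet, level: float = 0.95) -> CredibleSet:
    """Credible set by cumulative posterior probability of association.

    PPA_i = BF_i / sum_j BF_j (computed in log space); SNPs are added in
    descending PPA until the cumulative probability reaches ``level``.
    Minimal by construction: dropping the last member breaks the bound.
    """
    if len(bfs.log10_bf) == 0:
        raise ValueError("empty Bayes factor set")
    l = bfs.log10_bf * np.log(10.0)
    l = l - l.max()
    w = np.exp(l)
    ppa = w / w.sum()
    order = np.lexsort((np.arange(len(ppa)), -ppa))
    cum = 0.0
    members, evid = [], []
    for i in order:
        members.append(str(bfs.site_ids[i]))
        evid.append(ppa[i])
        cum += ppa[i]
        if cum >= level - 1e-12:
            break
    return CredibleSet(method="ppa", level=level, members=members, evidence=np.array(evid))


@njit(cache=True)
def _gibbs_top_counts(
    G, Xty, yty, n, group_id, n_iter, burn_in, thin, seed
):  # pragma: no cover
    """Spike-and-slab Gibbs sampler; returns per-site top-variant counts.

    G = X'X and Xty = X'y on standardized dosages (zero-variance sites
    carry all-zero rows).  Inclusion indicators get prior pi ~ Beta(1, M);
    slab variance sigma_b^2 ~ InvGamma(2, 1); residual variance has a
    Jeffreys prior.  At every ``thin``-th post-burn-in iteration the
    included site with the largest |beta| is counted, together with its
    complete-LD partners.
    """
    np.random.seed(seed)
    M = G.shape[0]
    beta = np.zeros(M)
    gamma = np.zeros(M, dtype=np.uint8)
    r = Xty.copy()
    sigma_e2 = yty / n
    sigma_b2 = 1.0
    pi = 1.0 / M
    counts = np.zeros(M, dtype=np.int64)

    for it in range(n_iter):
        k = 0
        for j in range(M):
            gjj = G[j, j]
            if gjj <= 0.0:
                continue
            r_j = r[j] + gjj * beta[j]
            v = 1.0 / (gjj / sigma_e2 + 1.0 / sigma_b2)
            mu = v * r_j / sigma_e2
            log_odds = (
                np.log(pi / (1.0 - pi))
                + 0.5 * np.log(v / sigma_b2)
                + 0.5 * mu * mu / v
            )
            if log_odds > 35.0:
                p_inc = 1.0
            elif log_odds < -35.0:
                p_inc = 0.0
            else:
                p_inc = 1.0 / (1.0 + np.exp(-log_odds))
            new_beta = 0.0
            if np.random.random() < p_inc:
                new_beta = mu + np.sqrt(v) * np.random.standard_normal()
                gamma[j] = 1
                k += 1
            else:
                gamma[j] = 0
            d = new_beta - beta[j]
            if d != 0.0:
                for m in range(M):
                    r[m] -= G[m, j] * d
                beta[j] = new_beta

        # residual variance (Jeffreys): SSR from the included set
        ssr = yty
        sb = 0.0
        for j in range(M):
            if gamma[j] == 1:
                ssr -= 2.0 * beta[j] * Xty[j]
                sb += beta[j] * beta[j]
                for l in range(M):
                    if gamma[l] == 1:
                        ssr += beta[j] * G[j, l] * beta[l]
        if ssr < 1e-12:
            ssr = 1e-12
        sigma_e2 = ssr / (2.0 * np.random.gamma(n / 2.0, 1.0))
        # slab variance: InvGamma(2, 1) prior
        sigma_b2 = (1.0 + 0.5 * sb) / np.random.gamma(2.0 + 0.5 * k, 1.0)
        # inclusion probability: Beta(1, M) prior
        pi = np.random.beta(1.0 + k, M + M - k)
        if pi < 1e-12:
            pi = 1e-12
        if pi > 1.0 - 1e-12:
            pi = 1.0 - 1e-12

        if it >= burn_in and (it - burn_in) % thin == 0:
            best = -1
            best_abs = -1.0
            for j in range(M):
                if gamma[j] == 1 and abs(beta[j]) > best_abs:
                    best_abs = abs(beta[j])
                    best = j
            if best >= 0:
                g = group_id[best]
                for j in range(M):
                    if group_id[j] == g:
                        counts[j] += 1
    return counts


def spike_slab_sampler(
    data: GenotypeDataset,
    y,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Run the sparse-model Gibbs sampler; return per-site top-variant counts.

    Dosages are standardized (and the phenotype scaled to unit variance) so
    the slab prior is on a comparable scale across sites; "largest effect"
    means largest |beta| on standardized genotypes.  Deterministic given
    ``seed``.  If no site is ever included the counts are all zero and a
    warning is logged.
    """
    if n_iter < thin:
        raise ValueError("n_iter must be >= thin")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    yv = assoc._phenotype_values(y)
    ysd = yv.std()
    ys = (yv - yv.mean()) / (ysd if ysd > 0 else 1.0)
    X = data.dosages
    sd = X.std(axis=0)
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    G = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)
    groups = complete_ld_groups(data)
    counts = _gibbs_top_counts(
        G,
        Xty,
        yty,
        data.n_samples,
        groups.astype(np.int64),
        int(n_iter),
        int(burn_in),
        int(thin),
        int(seed) % (2**31 - 1),
    )
    if counts.sum() == 0:
        logger.warning("spike_slab_sampler: no site was ever included (degenerate)")
    return counts


def count_credible_set(
    counts: np.ndarray,
    site_ids,
    positions=None,
    level: float = 0.95,
) -> CredibleSet:
    """Credible set by cumulative top-variant count share.

    Sites are added in descending count order (count ties broken by
    position) until member counts reach ``level`` of the total.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count is zero; sampler was degenerate")
    site_ids = np.asarray(site_ids, dtype=object)
    if positions is None:
        positions = np.arange(len(site_ids))
    positions = np.asarray(positions)
    order = np.lexsort((positions, -counts))
    cum = 0.0
    members, evid = [], []
    for i in order:
        members.append(str(site_ids[i]))
        evid.append(counts[i])
        cum += counts[i]
        if cum / total >= level - 1e-12:
            break
    return CredibleSet(
        method="mcmc_count", level=level, members=members, evidence=np.array(evid)
    )


def mcmc_credible_set(
    data: GenotypeDataset,
    y,
    level: float = 0.95,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    thin: int = 10,
    seed: int = 0,
) -> CredibleSet:
    """Convenience wrapper: sampler + count accumulation in one call."""
    counts = spike_slab_sampler(data, y, n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
    return count_credible_set(
        counts, data.site_ids, data.sites["position"].to_numpy(), level=level
    )
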