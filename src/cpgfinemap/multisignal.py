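"""Detection of multiple independent association signals at a locus.

Two procedures, both on individual-level data:

* forward selection — repeatedly condition on the accumulated top SNPs and
  stop when no remaining site passes the genome-wide threshold;
* stepwise joint selection — alternating forward (conditional scan) and
  backward (joint-model pruning) steps with a multicollinearity screen,
  the individual-level analogue of summary-statistic conditional-and-joint
  analysis.

On a locus with a single causal variant both return one signal; a masking
configuration (D' = 1 with an allele-frequency difference) also yields one
signal, located at the masking SNP rather than the causal one.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import assoc
from .core import ConditionalResult, GenotypeDataset

__all__ = ["forward_selection", "stepwise_joint_selection"]

GENOME_WIDE_P = 5e-8


def _max_r2_with(data: GenotypeDataset, idx: int, chosen: list[int]) -> float:
    if not chosen:
        return 0.0
    x = data.dosages[:, idx]
    r2 = 0.0
    for c in chosen:
        r = np.corrcoef(x, data.dosages[:, c])[0, 1]
        r2 = max(r2, r * r)
    return r2


def _joint_pvalues(data: GenotypeDataset, yv: np.ndarray, chosen: list[int]) -> np.ndarray:
    """Per-SNP p-values from the joint OLS fit of all chosen SNPs."""
    n = data.n_samples
    X = np.column_stack([np.ones(n), data.dosages[:, chosen]])
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ yv)
    resid = yv - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv)[1:])
    t = coef[1:] / se
    return 2.0 * stats.t.sf(np.abs(t), df)


def forward_selection(
    data: GenotypeDataset,
    y,
    threshold: float = GENOME_WIDE_P,
    collinearity_cap: float = 0.9,
) -> ConditionalResult:
    """Forward conditional selection of independent signals.

    Round 1 is the unconditional scan; while the best (conditional)
    p-value stays below ``threshold`` the corresponding site joins the
    conditioned set and the scan is repeated conditioning on all chosen
    sites.  A candidate collinear with the chosen set (r^2 >= cap) is
    skipped with a warning recorded in its round.
    """
    yv = assoc._phenotype_values(y)
    chosen: list[int] = []
    rounds: list[dict] = []
    while True:
        cond_ids = [str(data.site_ids[i]) for i in chosen]
        res = assoc.conditional_regression(data, yv, cond_ids, collinearity_cap)
        picked = None
        skipped = []
        for idx in res.order:
            site = str(res.site_ids[idx])
            p = res.p_value[idx]
            if not np.isfinite(p) or p >= threshold:
                break
            full_idx = data.site_index(site)
            if _max_r2_with(data, full_idx, chosen) >= collinearity_cap:
                skipped.append(site)
                continue
            picked = (site, full_idx, float(p))
            break
        rounds.append(
            {
                "conditioned": cond_ids,
                "top_site": picked[0] if picked else None,
                "p": picked[2] if picked else (
                    float(res.p_value[res.order[0]]) if len(res.order) else np.nan
                ),
                "skipped_collinear": skipped,
            }
        )
        if picked is None:
            break
        chosen.append(picked[1])
    return ConditionalResult(
        signals=[str(data.site_ids[i]) for i in chosen],
        rounds=rounds,
        method="forward",
        threshold=threshold,
    )


def stepwise_joint_selection(
    data: GenotypeDataset,
    y,
    threshold: float = GENOME_WIDE_P,
    collinearity_cap: float = 0.9,
    max_rounds: int = 50,
) -> ConditionalResult:
    """Stepwise (forward + backward) joint selection of independent signals.

    Alternates a forward step (conditional scan; admit the best site if it
    passes ``threshold`` and the collinearity screen) with a backward step
    (joint fit of the chosen set; drop any member whose joint p-value is
    at or above ``threshold``) until the chosen set stabilizes.
    """
    yv = assoc._phenotype_values(y)
    chosen: list[int] = []
    rounds: list[dict] = []
    history = []
    for _ in range(max_rounds):
        prev = list(chosen)

        # forward step
        cond_ids = [str(data.site_ids[i]) for i in chosen]
        res = assoc.conditional_regression(data, yv, cond_ids, collinearity_cap)
        added = None
        skipped = []
        for idx in res.order:
            site = str(res.site_ids[idx])
            p = res.p_value[idx]
            if not np.isfinite(p) or p >= threshold:
                break
            full_idx = data.site_index(site)
            if _max_r2_with(data, full_idx, chosen) >= collinearity_cap:
                skipped.append(site)
                continue
            added = (site, full_idx, float(p))
            break
        if added is not None:
            chosen.append(added[1])

        # backward step: joint model, drop non-significant members
        dropped = []
        if len(chosen) > 1:
            while len(chosen) > 1:
                pvals = _joint_pvalues(data, yv, chosen)
                worst = int(np.argmax(pvals))
                if pvals[worst] >= threshold:
                    dropped.append(str(data.site_ids[chosen[worst]]))
                    chosen.pop(worst)
                else:
                    break

        rounds.append(
            {
                "conditioned": cond_ids,
                "top_site": added[0] if added else None,
                "p": added[2] if added else np.nan,
                "dropped": dropped,
                "skipped_collinear": skipped,
            }
        )
        if chosen == prev:
            break
        state = tuple(sorted(chosen))
        if state in history and chosen != prev:
            raise RuntimeError(
                f"stepwise selection is oscillating between sets; last states: "
                f"{history[-3:]} -> {state}"
            )
        history.append(state)
    else:
        raise RuntimeError(f"stepwise selection did not stabilize in {max_rounds} rounds")

    return ConditionalResult(
        signals=[str(data.site_ids[i]) for i in chosen],
        rounds=rounds,
        method="stepwise_joint",
        threshold=threshold,
    )
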