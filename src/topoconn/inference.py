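"""Group-level inference on barcode slopes and single-linkage matrices.

Three analyses:

* a two-sample t test comparing per-subject barcode slopes between
  groups (global connectivity);
* a permutation test on every single-linkage distance (SLD), building a
  null by reassigning whole subjects to pseudo-groups of the original
  sizes and recomputing the per-edge group mean difference -- 10,000
  permutations and an uncorrected alpha of 0.001 by default;
* Pearson correlations between selected edges' SLDs and clinical
  covariates, with a Bonferroni-corrected threshold alpha / family_size.

Permutation p-values use the add-one estimator
``(1 + #{|null| >= |observed|}) / (B + 1)`` and so are never exactly 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtration import SingleLinkageMatrix

__all__ = [
    "SlopeComparison",
    "EdgePermutationResult",
    "ClinicalCorrelationResult",
    "compare_barcode_slopes",
    "slm_permutation_test",
    "clinical_correlations",
    "bonferroni_alpha",
]


@dataclass(frozen=True)
class SlopeComparison:
    """Independent-samples t test on barcode slopes."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    group_means: tuple[float, float]
    equal_var: bool


@dataclass(frozen=True)
class EdgePermutationResult:
    """Edge-wise permutation test on SLDs.

    ``table`` has one row per unordered ROI pair i < j with columns
    roi_i, roi_j, label_i, label_j, observed_diff (group2 - group1 mean
    SLD), p_value, significant.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    alpha: float
    group_sizes: tuple[int, int]
    method: str

    def significant_edges(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


@dataclass(frozen=True)
class ClinicalCorrelationResult:
    """Pearson correlations of edge SLDs with clinical covariates.

    ``table`` columns: roi_i, roi_j, covariate, r, p_value, n, valid,
    significant (at the Bonferroni-corrected threshold).
    """

    table: pd.DataFrame
    alpha: float
    family_size: int

    @property
    def corrected_alpha(self) -> float:
        return self.alpha / self.family_size


def bonferroni_alpha(alpha: float, family_size: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / family_size."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be a positive integer")
    return alpha / family_size


def compare_barcode_slopes(
    slopes_a: "list[float] | np.ndarray",
    slopes_b: "list[float] | np.ndarray",
    equal_var: bool = True,
) -> SlopeComparison:
    """Two-sample t test on per-subject barcode slopes.

    Student's pooled-variance test by default (``equal_var=False`` for
    Welch).  Two-sided p value.

    Raises
    ------
    ValueError
        If either group has fewer than 2 slopes, or the pooled variance
        is zero (both groups constant).
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 slopes")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance: both groups are constant")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        dof = float(a.size + b.size - 2)
    else:
        dof = float(res.df)
    return SlopeComparison(
        t_statistic=float(res.statistic),
        degrees_of_freedom=dof,
        p_value=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        equal_var=equal_var,
    )


def _stack_upper(slms: "list[SingleLinkageMatrix]") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = slms[0].roi_labels
    for s in slms[1:]:
        if s.roi_labels != labels:
            raise ValueError("all SLMs must share identical ROI labels")
    p = len(labels)
    iu, ju = np.triu_indices(p, k=1)
    x = np.stack([s.values[iu, ju] for s in slms])
    return x, iu, ju


def slm_permutation_test(
    slms_a: "list[SingleLinkageMatrix]",
    slms_b: "list[SingleLinkageMatrix]",
    n_permutations: int = 10_000,
    alpha: float = 0.001,
    seed: int | None = None,
    method: str = "subjects",
    exhaustive: bool = False,
) -> EdgePermutationResult:
    """Permutation test of group mean SLD differences, edge by edge.

    The observed statistic per edge is ``mean SLD(group 2) - mean
    SLD(group 1)``.  The null is built by randomly reassigning subjects
    to pseudo-groups of the original sizes and recomputing the statistic
    (``method="subjects"``, the default, which preserves within-subject
    edge dependence).  ``method="edgewise"`` instead shuffles each edge's
    values across subjects independently -- a sensitivity-analysis
    variant only.  With ``exhaustive=True`` all distinct group
    assignments are enumerated instead of sampled (subjects method only;
    p values are then exact and invariant to subject order).

    Two-sided p per edge uses the add-one rule; significance is
    ``p < alpha`` uncorrected (default alpha 0.001).
    """
    if not slms_a or not slms_b:
        raise ValueError("both groups must be nonempty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method not in ("subjects", "edgewise"):
        raise ValueError(f"unknown permutation method {method!r}")
    na, nb = len(slms_a), len(slms_b)
    x, iu, ju = _stack_upper(list(slms_a) + list(slms_b))
    n = na + nb
    observed = x[na:].mean(axis=0) - x[:na].mean(axis=0)
    abs_obs = np.abs(observed)
    # exceedance counted with a tiny tolerance so re-creations of the
    # observed statistic along a different float path still count as ties
    thresh = abs_obs - 1e-12

    if exhaustive:
        if method != "subjects":
            raise ValueError("exhaustive enumeration requires method='subjects'")
        count = np.zeros_like(observed)
        total = 0
        for combo in itertools.combinations(range(n), na):
            in_a = np.zeros(n, dtype=bool)
            in_a[list(combo)] = True
            diff = x[~in_a].mean(axis=0) - x[in_a].mean(axis=0)
            count += np.abs(diff) >= thresh
            total += 1
        pvals = count / total
        n_perm_used = total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(observed)
        # weights turning a row-permutation into the group-mean difference
        base_w = np.concatenate(
            [np.full(na, -1.0 / na), np.full(nb, 1.0 / nb)]
        )
        chunk = 2000
        done = 0
        while done < n_permutations:
            m = min(chunk, n_permutations - done)
            idx = np.argsort(rng.random((m, n)), axis=1)
            w = np.zeros((m, n))
            np.put_along_axis(w, idx, np.broadcast_to(base_w, (m, n)), axis=1)
            if method == "edgewise":
                # shuffle each edge independently: new draw of idx per edge
                null = np.empty((m, x.shape[1]))
                for e in range(x.shape[1]):
                    perm = np.argsort(rng.random((m, n)), axis=1)
                    null[:, e] = np.take_along_axis(
                        np.broadcast_to(x[:, e], (m, n)), perm, axis=1
                    ) @ base_w
            else:
                null = w @ x
            exceed += (np.abs(null) >= thresh).sum(axis=0)
            done += m
        pvals = (1.0 + exceed) / (n_permutations + 1.0)
        n_perm_used = n_permutations

    labels = slms_a[0].roi_labels
    table = pd.DataFrame(
        {
            "roi_i": iu,
            "roi_j": ju,
            "label_i": [labels[i] for i in iu],
            "label_j": [labels[j] for j in ju],
            "observed_diff": observed,
            "p_value": pvals,
            "significant": pvals < alpha,
        }
    )
    return EdgePermutationResult(
        table=table,
        n_permutations=n_perm_used,
        seed=seed,
        alpha=alpha,
        group_sizes=(na, nb),
        method="exhaustive" if exhaustive else method,
    )


def clinical_correlations(
    slms: "list[SingleLinkageMatrix]",
    edges: "list[tuple[int, int]]",
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> ClinicalCorrelationResult:
    """Pearson correlation of each edge's SLD with each clinical covariate.

    ``slms`` and ``covariates`` rows must align one-to-one by subject
    (same order).  ``family_size`` defaults to the number of (edge,
    covariate) pairs tested; best practice is to declare it
    explicitly.  Degenerate correlations (constant SLD or covariate) are
    flagged ``valid=False`` with NaN r, never silently dropped.
    """
    if len(slms) != len(covariates):
        raise ValueError("one covariate row per SLM required")
    if len(slms) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cov_names = list(covariates.columns)
    if family_size is None:
        family_size = len(edges) * len(cov_names)
    if family_size < 1:
        raise ValueError("family_size must be a positive integer")
    corrected = alpha / family_size
    labels = slms[0].roi_labels
    rows = []
    for i, j in edges:
        i, j = (i, j) if i < j else (j, i)
        sld = np.array([s.values[i, j] for s in slms])
        for name in cov_names:
            y = covariates[name].to_numpy(dtype=float)
            valid = sld.std() > 0 and y.std() > 0
            if valid:
                r, p = stats.pearsonr(sld, y)
            else:
                r, p = math.nan, math.nan
            rows.append(
                {
                    "roi_i": i,
                    "roi_j": j,
                    "label_i": labels[i],
                    "label_j": labels[j],
                    "covariate": name,
                    "r": float(r),
                    "p_value": float(p),
                    "n": len(sld),
                    "valid": bool(valid),
                    "significant": bool(valid and p < corrected),
                }
            )
    return ClinicalCorrelationResult(
        table=pd.DataFrame(rows), alpha=alpha, family_size=family_size
    )
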