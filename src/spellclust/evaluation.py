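"""Partition comparison and within-cluster homogeneity summaries.

Covers the machinery used to compare the spell-based and latent-class
phenotype allocations: the adjusted Rand index, transition (alluvial-input)
tables, the fraction of subjects changing allocation after optimal label
alignment, and per-cluster distributional profiles of the spell variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .exceptions import ValidationError
from .features import FEATURE_COLUMNS, FeatureTable

__all__ = [
    "adjusted_rand",
    "transition_table",
    "changed_fraction",
    "homogeneity_profile",
]


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    C = np.zeros((ua.size, ub.size))
    np.add.at(C, (ia, ib), 1.0)
    return C


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two partitions (permutation model).

    1 means identical up to relabeling; the expectation under independent
    random labelings is 0 and negative values indicate below-chance
    agreement.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("labelings must have equal length")
    n = a.size
    if n < 2:
        raise ValidationError("need at least 2 subjects")
    C = _contingency(a, b)
    sum_ij = comb(C, 2).sum()
    sum_a = comb(C.sum(axis=1), 2).sum()
    sum_b = comb(C.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def transition_table(a, b, names_a=None, names_b=None) -> pd.DataFrame:
    """Counts of subjects per (cluster in a, cluster in b) cell.

    This is the numeric input behind an alluvial plot of phenotype
    membership transitions between two models; marginals equal cluster sizes.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("labelings must have equal length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    C = np.zeros((ua.size, ub.size), dtype=int)
    np.add.at(C, (ia, ib), 1)
    index = list(names_a) if names_a is not None else [str(x) for x in ua]
    columns = list(names_b) if names_b is not None else [str(x) for x in ub]
    if len(index) != ua.size or len(columns) != ub.size:
        raise ValidationError("names do not match the number of observed clusters")
    return pd.DataFrame(C, index=index, columns=columns)


def changed_fraction(a, b) -> float:
    """Fraction of subjects whose label differs after optimal alignment.

    Cluster numbers from independent fits are arbitrary, so b's labels are
    first permuted to maximize agreement with a (optimal assignment on the
    contingency table); the fraction of disagreements under that best
    matching is returned. Requires the same number of clusters.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("labelings must have equal length")
    ua = np.unique(a)
    ub = np.unique(b)
    if ua.size != ub.size:
        raise ValidationError(
            f"partitions have different cluster counts ({ua.size} vs {ub.size})"
        )
    C = _contingency(a, b)
    rows, cols = linear_sum_assignment(-C)
    agree = C[rows, cols].sum()
    return float(1.0 - agree / a.size)


def homogeneity_profile(
    features: FeatureTable, assignment
) -> tuple[pd.DataFrame, float]:
    """Per-cluster distribution summaries of the six spell variables.

    For categorical variables the profile lists counts per category; for
    quantitative variables a five-number quantile summary over observed
    values. The scalar heterogeneity score averages, over clusters and
    variables, the within-cluster variance normalized by the overall
    variance (quantitative) or the non-modal share (categorical); identical
    vectors within every cluster give a score of 0.
    """
    labels = np.asarray(assignment)
    if labels.shape[0] != features.n_subjects:
        raise ValidationError("assignment length does not match features")
    df = features.data
    categorical = {"spell_type"}
    rows = []
    scores = []
    for c in np.unique(labels):
        mask = labels == c
        for var in FEATURE_COLUMNS:
            x = df.loc[mask, var].to_numpy(dtype=float)
            if var in categorical:
                vals, counts = np.unique(x, return_counts=True)
                for v, cnt in zip(vals, counts):
                    rows.append(
                        {"cluster": c, "variable": var, "stat": f"count[{int(v)}]",
                         "value": float(cnt)}
                    )
                scores.append(1.0 - counts.max() / counts.sum())
            else:
                obs = x[~np.isnan(x)]
                if obs.size == 0:
                    rows.append(
                        {"cluster": c, "variable": var, "stat": "n_observed", "value": 0.0}
                    )
                    continue
                qs = np.quantile(obs, [0.0, 0.25, 0.5, 0.75, 1.0])
                for name, q in zip(("min", "q25", "median", "q75", "max"), qs):
                    rows.append(
                        {"cluster": c, "variable": var, "stat": name, "value": float(q)}
                    )
                overall = df[var].to_numpy(dtype=float)
                overall = overall[~np.isnan(overall)]
                ov = np.var(overall)
                scores.append(float(np.var(obs) / ov) if ov > 0 else 0.0)
    return pd.DataFrame(rows), float(np.mean(scores)) if scores else 0.0
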