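"""Mixed-data dissimilarity between spell-feature vectors.

The six spell variables mix quantitative (ages, counts, durations) and
categorical (spell type) components, and the age variables are structurally
missing for never-wheezers. The dissimilarity is a normalized Gower-type
distance in the Wishart mixed-data tradition:

    d(i,j)^2 = sum_k  delta_ijk * w_k * g_k(i,j)  /  sum_k delta_ijk * w_k

where delta_ijk = 1 iff variable k is observed for both subjects,
g_k = ((x_ik - x_jk) / s_k)^2 for quantitative variables (s_k the sample
standard deviation fitted on the table), and g_k = 1[x_ik != x_jk] for
categorical variables. Pairwise deletion handles missing ages natively; as
a consequence the triangle inequality is not guaranteed.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import NoComparableVariablesError, ValidationError
from .features import FEATURE_COLUMNS, FeatureTable

__all__ = [
    "VariableSpec",
    "DistanceMatrix",
    "default_specs",
    "fit_scales",
    "pairwise_distance",
    "cross_distance",
    "binary_sequence_distance",
    "save_distance",
    "load_distance",
]


@dataclass(frozen=True)
class VariableSpec:
    """How one variable enters the distance: kind, weight, fitted scale."""

    name: str
    kind: str  # "quantitative" | "categorical"
    weight: float = 1.0
    scale: float | None = None  # fitted sample SD (quantitative only)

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "categorical"):
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.weight < 0:
            raise ValidationError(f"{self.name}: weight must be >= 0")
        if self.scale is not None and self.scale <= 0:
            raise ValidationError(f"{self.name}: scale must be > 0")


def default_specs(spell_type_kind: str = "categorical") -> list[VariableSpec]:
    """Unit-weight specs for the six spell variables.

    ``spell_type_kind`` may be set to ``"quantitative"`` as a sensitivity
    switch treating the 0/1/2 spell-type code as ordered.
    """
    kinds = dict.fromkeys(FEATURE_COLUMNS, "quantitative")
    kinds["spell_type"] = spell_type_kind
    return [VariableSpec(name, kinds[name]) for name in FEATURE_COLUMNS]


def fit_scales(features: FeatureTable, specs: list[VariableSpec]) -> list[VariableSpec]:
    """Fit per-variable scales (sample SD, ddof=1) on the observed values.

    A zero-variance quantitative variable gets no scale; its contribution is
    defined as 0 and a warning is emitted.
    """
    fitted = []
    for spec in specs:
        if spec.kind != "quantitative":
            fitted.append(spec)
            continue
        x = features.data[spec.name].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if sd == 0.0:
            warnings.warn(
                f"variable {spec.name!r} has zero variance; its distance "
                "contribution is defined as 0",
                stacklevel=2,
            )
            fitted.append(replace(spec, scale=None))
        else:
            fitted.append(replace(spec, scale=sd))
    return fitted


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.isfinite(v).all():
            raise ValidationError("distance matrix has non-finite entries")
        if (v < 0).any():
            raise ValidationError("distances must be nonnegative")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix not symmetric within 1e-12")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distance(
    features: FeatureTable, specs: list[VariableSpec] | None = None
) -> DistanceMatrix:
    """Compute the mixed-data distance matrix over a feature table.

    Scales are fitted on the input table unless already present on the
    specs. Raises if some pair of subjects shares no observed variable with
    positive weight.
    """
    if specs is None:
        specs = default_specs()
    names = {s.name for s in specs}
    if names != set(FEATURE_COLUMNS):
        raise ValidationError(f"specs must cover exactly {FEATURE_COLUMNS}")
    if not any(s.weight > 0 for s in specs):
        raise ValidationError("at least one variable weight must be positive")
    needs_fit = any(s.kind == "quantitative" and s.scale is None for s in specs)
    if needs_fit:
        specs = fit_scales(features, specs)

    X = features.data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    ordered = [next(s for s in specs if s.name == name) for name in FEATURE_COLUMNS]

    # spell features take few distinct values (<= 2^T patterns), so compute
    # on unique rows and expand; NaN is mapped to a sentinel for uniquing only
    key = np.where(np.isnan(X), -np.inf, X)
    _, uidx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    U = X[uidx]
    u = U.shape[0]

    num = np.zeros((u, u))
    den = np.zeros((u, u))
    for col, spec in enumerate(ordered):
        if spec.weight == 0:
            continue
        x = U[:, col]
        obs = ~np.isnan(x)
        delta = np.outer(obs, obs).astype(float)
        xs = np.where(obs, x, 0.0)
        if spec.kind == "quantitative":
            if spec.scale is None:  # zero variance: counted, contributes 0
                g = np.zeros((u, u))
            else:
                diff = (xs[:, None] - xs[None, :]) / spec.scale
                g = diff * diff
        else:
            g = (xs[:, None] != xs[None, :]).astype(float)
        num += spec.weight * delta * g
        den += spec.weight * delta

    bad = den <= 0
    np.fill_diagonal(bad, False)
    if bad.any():
        ui, uj = np.argwhere(bad)[0]
        i = int(np.flatnonzero(inverse == ui)[0])
        j = int(np.flatnonzero(inverse == uj)[0])
        raise NoComparableVariablesError(
            f"subjects {features.subject_ids[i]!r} and {features.subject_ids[j]!r} "
            "share no observed variable"
        )
    with np.errstate(invalid="ignore"):
        du = np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    du = 0.5 * (du + du.T)  # enforce exact symmetry against fp noise
    np.fill_diagonal(du, 0.0)
    d = du[np.ix_(inverse, inverse)]
    return DistanceMatrix(d)


def cross_distance(
    features_a: FeatureTable, features_b: FeatureTable, specs: list[VariableSpec]
) -> np.ndarray:
    """Distances from each row of ``features_a`` to each row of ``features_b``.

    ``specs`` must carry fitted scales (fit them on the training table), so
    new subjects — e.g. enumerated sequences in an audit, or held-out cases
    assigned to existing medoids — are measured on the training geometry.
    """
    for s in specs:
        if s.kind == "quantitative" and s.scale is None and s.weight > 0:
            raise ValidationError(f"spec {s.name!r} has no fitted scale")
    A = features_a.data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    B = features_b.data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    ordered = [next(s for s in specs if s.name == name) for name in FEATURE_COLUMNS]
    num = np.zeros((A.shape[0], B.shape[0]))
    den = np.zeros_like(num)
    for col, spec in enumerate(ordered):
        if spec.weight == 0:
            continue
        xa, xb = A[:, col], B[:, col]
        delta = np.outer(~np.isnan(xa), ~np.isnan(xb)).astype(float)
        xa0, xb0 = np.nan_to_num(xa), np.nan_to_num(xb)
        if spec.kind == "quantitative":
            if spec.scale is None:
                g = np.zeros_like(num)
            else:
                diff = (xa0[:, None] - xb0[None, :]) / spec.scale
                g = diff * diff
        else:
            g = (xa0[:, None] != xb0[None, :]).astype(float)
        num += spec.weight * delta * g
        den += spec.weight * delta
    if (den <= 0).any():
        raise NoComparableVariablesError("a pair shares no observed variable")
    return np.sqrt(num / den)


def binary_sequence_distance(table) -> DistanceMatrix:
    """Simple-matching (Hamming) distance between raw binary wheeze sequences.

    The control analysis that clusters the yes/no indicators directly,
    bypassing the spell transformation; requires complete data.
    """
    X = np.asarray(table.data, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("binary-sequence distance requires complete data")
    key = X.astype(int)
    _, uidx, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    U = X[uidx]
    mism = (U[:, None, :] != U[None, :, :]).mean(axis=2)
    return DistanceMatrix(mism[np.ix_(inverse, inverse)])


def save_distance(D: DistanceMatrix, path) -> str:
    """Persist as a small binary: int64 n, then the float64 strict lower triangle."""
    n = D.n
    tril = D.values[np.tril_indices(n, k=-1)]
    with open(path, "wb") as fh:
        fh.write(struct.pack("<q", n))
        fh.write(tril.astype("<f8").tobytes())
    return str(path)


def load_distance(path) -> DistanceMatrix:
    with open(path, "rb") as fh:
        (n,) = struct.unpack("<q", fh.read(8))
        tril = np.frombuffer(fh.read(), dtype="<f8")
    if tril.size != n * (n - 1) // 2:
        raise ValidationError(f"{path}: payload does not match n={n}")
    v = np.zeros((n, n))
    v[np.tril_indices(n, k=-1)] = tril
    return DistanceMatrix(v + v.T)
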