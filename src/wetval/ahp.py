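"""Analytic hierarchy process (AHP): service-function weights from pairwise comparisons.

Beneficiaries of coastal wetland services are stratified into levels (local,
provincial, national, global). Each level supplies a reciprocal pairwise
comparison matrix over the services, and a further matrix compares the levels
themselves. Priorities are extracted as the normalized principal right
eigenvector of each matrix (power iteration); the comprehensive weight of a
service is the level-weighted sum of its per-level weights.

Consistency is measured by CI = (λ_max − n)/(n − 1) and CR = CI/RI(n) using
Saaty's random-index table; matrices with CR above a threshold (default 0.1)
are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ValidationError

# Saaty random consistency index, n = 1..10. Standard AHP constants.
RANDOM_INDEX = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
                6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}

#: Default CR acceptance threshold.
CR_THRESHOLD = 0.1

_POWER_TOL = 1e-12
_POWER_MAX_ITER = 10_000

RECIPROCAL_TOL = 1e-9


class ConsistencyError(ValidationError):
    """A pairwise matrix failed the CR acceptance threshold."""


@dataclass
class PairwiseMatrix:
    """A reciprocal pairwise-comparison matrix over labelled items."""

    items: list[str]
    a: np.ndarray
    name: str = "matrix"

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.items)
        if self.a.shape != (n, n):
            raise ValidationError(f"{self.name}: matrix shape {self.a.shape} does not match "
                                  f"{n} items")
        if np.any(self.a <= 0):
            raise ValidationError(f"{self.name}: all judgments must be > 0")
        if not np.allclose(np.diag(self.a), 1.0, atol=RECIPROCAL_TOL):
            raise ValidationError(f"{self.name}: diagonal must be 1")
        if not np.allclose(self.a * self.a.T, 1.0, atol=1e-6):
            raise ValidationError(f"{self.name}: matrix is not reciprocal "
                                  f"(a[j][i] must equal 1/a[i][j])")


@dataclass
class AhpHierarchy:
    """Level comparison matrix plus one service matrix per beneficiary level."""

    level_matrix: PairwiseMatrix
    service_matrices: dict[str, PairwiseMatrix]

    def __post_init__(self) -> None:
        if set(self.level_matrix.items) != set(self.service_matrices):
            raise ValidationError("service matrices must cover exactly the levels "
                                  "of the level matrix")
        label_sets = {frozenset(m.items) for m in self.service_matrices.values()}
        if len(label_sets) != 1:
            raise ValidationError("service label sets must be identical across levels")


@dataclass
class WeightVector:
    """Service → weight map with per-matrix consistency ratios.

    ``weights`` may carry raw (un-normalized) values, e.g. published table
    entries; :meth:`normalized` rescales to sum 1.
    """

    weights: dict[str, float]
    consistency: dict[str, float] = field(default_factory=dict)
    lambda_max: float | None = None

    def normalized(self) -> "WeightVector":
        total = sum(self.weights.values())
        if total <= 0:
            raise ValidationError("cannot normalize: weights sum to a non-positive value")
        return WeightVector(
            weights={k: v / total for k, v in self.weights.items()},
            consistency=dict(self.consistency),
            lambda_max=self.lambda_max,
        )

    def __getitem__(self, service: str) -> float:
        return self.weights[service]


def _principal_eigenvector(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Power iteration for the Perron vector of a positive matrix."""
    n = a.shape[0]
    v = np.full(n, 1.0 / n)
    for _ in range(_POWER_MAX_ITER):
        w = a @ v
        w /= w.sum()
        if np.max(np.abs(w - v)) < _POWER_TOL:
            v = w
            break
        v = w
    lam = float(np.mean((a @ v) / v))
    return v, lam


def eigen_weights(m: PairwiseMatrix) -> WeightVector:
    """Priorities of one pairwise matrix: normalized principal eigenvector + CR.

    For a perfectly consistent matrix (a[i][j] = w_i/w_j) this recovers w
    exactly and CR = 0.
    """
    n = len(m.items)
    if n < 2:
        raise ValidationError(f"{m.name}: need at least 2 items to prioritize")
    v, lam = _principal_eigenvector(m.a)
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX.get(n, RANDOM_INDEX[10])
    cr = 0.0 if ri == 0.0 else ci / ri
    return WeightVector(
        weights=dict(zip(m.items, v.tolist())),
        consistency={m.name: cr},
        lambda_max=lam,
    )


def composite_weights(
    h: AhpHierarchy,
    cr_threshold: float = CR_THRESHOLD,
    enforce_consistency: bool = True,
) -> WeightVector:
    """Comprehensive service weights: Σ_levels levelweight_l × serviceweight_{l,s}.

    Every matrix must pass CR ≤ ``cr_threshold`` unless ``enforce_consistency``
    is disabled. The result is renormalized to sum 1.
    """
    if len(h.level_matrix.items) == 1:  # degenerate single-level hierarchy
        level_wv = WeightVector(weights={h.level_matrix.items[0]: 1.0},
                                consistency={h.level_matrix.name: 0.0})
    else:
        level_wv = eigen_weights(h.level_matrix)
    consistency = dict(level_wv.consistency)
    per_level: dict[str, WeightVector] = {}
    for level in h.level_matrix.items:
        wv = eigen_weights(h.service_matrices[level])
        consistency.update(wv.consistency)
        per_level[level] = wv

    if enforce_consistency:
        for name, cr in consistency.items():
            if cr > cr_threshold:
                raise ConsistencyError(
                    f"matrix {name!r} fails consistency: CR = {cr:.4f} > {cr_threshold}"
                )

    services = h.service_matrices[h.level_matrix.items[0]].items
    composite = {
        s: sum(level_wv[level] * per_level[level][s] for level in h.level_matrix.items)
        for s in services
    }
    return WeightVector(weights=composite, consistency=consistency).normalized()


def geometric_mean_matrix(matrices: list[PairwiseMatrix]) -> PairwiseMatrix:
    """Element-wise geometric mean of several respondents' matrices (utility)."""
    if not matrices:
        raise ValidationError("need at least one matrix")
    items = matrices[0].items
    for m in matrices[1:]:
        if m.items != items:
            raise ValidationError("all matrices must share the same item ordering")
    stack = np.stack([m.a for m in matrices])
    return PairwiseMatrix(items=list(items), a=np.exp(np.mean(np.log(stack), axis=0)),
                          name="geometric_mean")


# ---------------------------------------------------------------------------
# Published comprehensive weights (case-study fixture)

#: Comprehensive service-function weights as published for the coastal-wetland
#: case study. Raw values (sum ≈ 0.9991 from rounding); renormalize on use.
TABLE_WEIGHTS_RAW: dict[str, float] = {
    "Food production": 0.1344,
    "Raw material production": 0.1037,
    "Bioproductivity": 0.068,
    "Water conservation": 0.1255,
    "The water quality purification": 0.1185,
    "Wave revetment": 0.1296,
    "Promote silting epeirogenic": 0.0593,
    "Carbon sequestration": 0.0481,
    "The atmosphere to adjust": 0.0910,
    "Leisure travel": 0.1210,
}


def published_weights() -> WeightVector:
    """The ten published comprehensive weights, verbatim (un-normalized).

    When a hierarchy is supplied to :func:`composite_weights`, computed weights
    supersede this fixture.
    """
    return WeightVector(weights=dict(TABLE_WEIGHTS_RAW), consistency={})


# ---------------------------------------------------------------------------
# I/O

def read_pairwise_csv(path, name: str = "matrix") -> PairwiseMatrix:
    """Read a labelled square pairwise matrix (first column = item labels)."""
    df = pd.read_csv(path, index_col=0)
    items = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != items:
        raise ValidationError(f"{name}: row and column labels must match")
    return PairwiseMatrix(items=items, a=df.to_numpy(dtype=float), name=name)


def write_weights(wv: WeightVector, path) -> None:
    rows = [{"service": s, "weight": w} for s, w in wv.weights.items()]
    df = pd.DataFrame(rows)
    if wv.consistency:
        df["max_cr"] = max(wv.consistency.values())
    df.to_csv(path, index=False)


def read_weights(path) -> WeightVector:
    df = pd.read_csv(path)
    return WeightVector(weights={str(r["service"]): float(r["weight"])
                                 for r in df.to_dict("records")})
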