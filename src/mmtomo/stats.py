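"""Statistical moments of anisotropy maps and two-group diagnostics.

The texture of an anisotropy map is summarized by four raw moments

    Z1 = mean(OA),  Z2 = mean(OA²),
    Z3 = Z2⁻³ · mean(OA³),  Z4 = Z2⁻⁴ · mean(OA⁴),

whose higher orders amplify small between-class differences of weakly
anisotropic media (for OA ~ 1e-3 they exceed Z1,2 by orders of magnitude).
A classical centered mode (mean / standard deviation / skewness / kurtosis)
is available but is never the default.  Diagnosis is a scalar threshold on
one moment of one observable, scored by sensitivity, specificity and
balanced accuracy; carcinoma is the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MomentVector",
    "ContingencyCounts",
    "DiagnosticResult",
    "StabilityReport",
    "moments",
    "classify",
    "grade",
    "cohort_summary",
    "stability_check",
]


@dataclass(frozen=True)
class MomentVector:
    """Z1..Z4 of one observable map at one phase plane."""

    z1: float
    z2: float
    z3: float
    z4: float
    observable: str = ""
    phase_plane: float = float("nan")
    n_pixels: int = 1
    mode: str = "raw"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a moment vector needs at least one pixel")
        if self.mode == "raw" and self.z2 < 0:
            raise ValueError("Z2 is a mean of squares and cannot be negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.z1, self.z2, self.z3, self.z4])

    def __getitem__(self, order: int) -> float:
        if order not in (1, 2, 3, 4):
            raise IndexError("moment order must be 1..4")
        return float(self.as_array()[order - 1])


@dataclass(frozen=True)
class ContingencyCounts:
    """a/b: correct/missed carcinoma calls; c/d: correct/missed adenoma."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each group needs at least one sample")


@dataclass(frozen=True)
class DiagnosticResult:
    """Threshold-rule performance; Ac = (Se+Sp)/2 by construction."""

    se: float
    sp: float
    ac: float
    counts: ContingencyCounts
    threshold: float
    direction: str  # "ge": call carcinoma when value >= threshold
    scheme: str
    grade: str


def moments(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    observable: str = "",
    phase_plane: float = float("nan"),
    mode: str = "raw",
) -> MomentVector:
    """First- to fourth-order moments of a map over its valid pixels.

    ``raw`` (default) evaluates the power moments Z1..Z4 literally; NaN
    pixels and pixels excluded by ``mask`` are dropped.  With an all-zero
    map Z2 = 0 and the higher orders are set to 0 by convention, with the
    vector flagged degenerate.  ``centered`` gives mean, standard deviation
    and the classical (Pearson) skewness and kurtosis.
    """
    x = np.asarray(values, dtype=float).ravel()
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool).ravel()]
    x = x[np.isfinite(x)]
    if x.size < 1:
        raise ValueError("moments need at least one valid pixel")
    if mode == "raw":
        z1 = float(np.mean(x))
        z2 = float(np.mean(x**2))
        degenerate = z2 == 0.0
        if degenerate:
            warnings.warn("all-zero map: Z3, Z4 set to 0 by convention", stacklevel=2)
            z3 = z4 = 0.0
        else:
            z3 = float(np.mean(x**3) / z2**3)
            z4 = float(np.mean(x**4) / z2**4)
    elif mode == "centered":
        z1 = float(np.mean(x))
        sd = float(np.std(x))
        z2 = sd
        degenerate = sd == 0.0
        if degenerate:
            warnings.warn("constant map: skewness/kurtosis set to 0", stacklevel=2)
            z3 = z4 = 0.0
        else:
            c = x - z1
            z3 = float(np.mean(c**3) / sd**3)
            z4 = float(np.mean(c**4) / sd**4)
    else:
        raise ValueError(f"unknown moments mode {mode!r}")
    return MomentVector(
        z1, z2, z3, z4,
        observable=observable,
        phase_plane=phase_plane,
        n_pixels=int(x.size),
        mode=mode,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# threshold diagnosis
# ---------------------------------------------------------------------------

def _best_rule(pos: np.ndarray, neg: np.ndarray) -> tuple[float, str]:
    """Threshold and direction maximizing resubstitution balanced accuracy.

    Candidates are midpoints of adjacent pooled values (plus outer guards);
    ties at the threshold go to the carcinoma (positive) side.  Tie-breaks
    between rules are deterministic: lowest threshold, "ge" before "le".
    """
    pooled = np.unique(np.concatenate([pos, neg]))
    if pooled.size == 1:
        cands = np.array([pooled[0]])
    else:
        mids = 0.5 * (pooled[:-1] + pooled[1:])
        step = np.min(np.diff(pooled))
        cands = np.concatenate([[pooled[0] - step], mids, [pooled[-1] + step]])
    best_key = (-1.0, -np.inf, -1)
    best = (0.0, "ge")
    for t in cands:
        for di, direction in enumerate(("ge", "le")):
            if direction == "ge":
                se = np.mean(pos >= t)
                sp = np.mean(neg < t)
            else:
                se = np.mean(pos <= t)
                sp = np.mean(neg > t)
            ac = 0.5 * (se + sp)
            key = (ac, -t, -di)  # prefer higher Ac, then lower t, then "ge"
            if key > best_key:
                best_key = key
                best = (float(t), direction)
    return best


def _apply_rule(x: np.ndarray, t: float, direction: str) -> np.ndarray:
    return x >= t if direction == "ge" else x <= t


def classify(
    values_carcinoma: np.ndarray,
    values_adenoma: np.ndarray,
    scheme: str = "loo",
) -> DiagnosticResult:
    """Scalar-threshold diagnosis between two cohorts of moment values.

    ``loo`` (default): leave-one-out — the rule is refit without each
    sample, which is then scored out-of-bag.  ``resubstitution``: a single
    rule fit and scored on all samples.  Returns Se = a/(a+b)·100,
    Sp = c/(c+d)·100 and Ac = (Se+Sp)/2 with the contingency counts.
    """
    pos = np.asarray(values_carcinoma, dtype=float).ravel()
    neg = np.asarray(values_adenoma, dtype=float).ravel()
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each group needs at least two samples")
    if np.array_equal(np.sort(pos), np.sort(neg)) and np.unique(pos).size == 1:
        warnings.warn("identical degenerate groups; accuracy is chance level", stacklevel=2)
    t_full, dir_full = _best_rule(pos, neg)
    if scheme == "resubstitution":
        pos_call = _apply_rule(pos, t_full, dir_full)
        neg_call = _apply_rule(neg, t_full, dir_full)
    elif scheme == "loo":
        pos_call = np.empty(pos.size, dtype=bool)
        neg_call = np.empty(neg.size, dtype=bool)
        for i in range(pos.size):
            t, d = _best_rule(np.delete(pos, i), neg)
            pos_call[i] = _apply_rule(pos[i : i + 1], t, d)[0]
        for i in range(neg.size):
            t, d = _best_rule(pos, np.delete(neg, i))
            neg_call[i] = _apply_rule(neg[i : i + 1], t, d)[0]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    counts = ContingencyCounts(
        a=int(pos_call.sum()),
        b=int((~pos_call).sum()),
        c=int((~neg_call).sum()),
        d=int(neg_call.sum()),
    )
    se = 100.0 * counts.a / (counts.a + counts.b)
    sp = 100.0 * counts.c / (counts.c + counts.d)
    ac = 0.5 * (se + sp)
    return DiagnosticResult(
        se=se,
        sp=sp,
        ac=ac,
        counts=counts,
        threshold=t_full,
        direction=dir_full,
        scheme=scheme,
        grade=grade(ac),
    )


def grade(ac: float) -> str:
    """Balanced-accuracy grade: Satisfactory 70-80, Good 81-90,
    Excellent 91-100, Unsatisfactory below 70 (Ac rounded to the nearest
    integer first, which closes the 80-81 and 90-91 gaps)."""
    if not (0.0 <= ac <= 100.0):
        raise ValueError("balanced accuracy must lie in [0, 100]")
    r = int(np.rint(ac))
    if r < 70:
        return "Unsatisfactory"
    if r <= 80:
        return "Satisfactory"
    if r <= 90:
        return "Good"
    return "Excellent"


def cohort_summary(
    cohort: list[MomentVector], ddof: int = 1
) -> dict[str, np.ndarray]:
    """Per-moment mean and standard deviation over a cohort.

    ``ddof=1`` (default) gives the sample standard deviation; 0 the
    population one.  Returns {"mean": (4,), "std": (4,), "n": int}.
    """
    if len(cohort) < 2:
        raise ValueError("cohort_summary needs at least two samples")
    z = np.stack([mv.as_array() for mv in cohort])
    return {
        "mean": z.mean(axis=0),
        "std": z.std(axis=0, ddof=ddof),
        "n": len(cohort),
    }


@dataclass(frozen=True)
class StabilityReport:
    max_variance: float
    per_moment: np.ndarray  # (4,) max variance over folds per moment
    bound: float
    passed: bool


def stability_check(
    cohort: list[MomentVector], k: int = 6, bound: float = 0.025
) -> StabilityReport:
    """Cross-validation stability of the cohort moments.

    Splits the cohort into k folds and recomputes the per-moment variance on
    each complementary (training) subset; the maximum over folds and moments
    is compared against the σ² bound (0.025 by default, the level at which a
    cohort of this size is considered statistically reliable).
    """
    if len(cohort) < 2:
        raise ValueError("stability_check needs at least two samples")
    k = min(k, len(cohort))
    z = np.stack([mv.as_array() for mv in cohort])
    idx = np.arange(len(cohort))
    per_moment = np.zeros(4)
    for fold in np.array_split(idx, k):
        train = np.setdiff1d(idx, fold)
        if train.size < 2:
            continue
        v = z[train].var(axis=0, ddof=1)
        per_moment = np.maximum(per_moment, v)
    max_v = float(per_moment.max())
    return StabilityReport(
        max_variance=max_v,
        per_moment=per_moment,
        bound=bound,
        passed=bool(max_v <= bound),
    )
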