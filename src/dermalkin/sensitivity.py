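"""Latin hypercube sampling and partial rank correlation sensitivity analysis.

The uncertainty of the eleven physiological parameters is propagated through
the model by stratified sampling: each parameter's uniform range is divided
into ``n`` equal-probability intervals, each interval is used exactly once
(sampling without replacement), and the interval midpoint — the average value
of the uniform distribution restricted to the interval — is assigned.  Only
the per-parameter permutations are random, so sorted sample columns are
deterministic.

The sensitivity index is the partial rank correlation coefficient (PRCC):
all columns are rank-transformed, the parameter of interest and the output
are each regressed on the remaining parameters' ranks, and the PRCC is the
Pearson correlation of the two residual vectors.  Significance uses a
two-sided Student's t-test with ``df = n - 2 - k_controlled`` degrees of
freedom (the convention that discounts one degree per controlled covariate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bac import BACProfile
from .metrics import DEFAULT_ZERO_THRESHOLD, compute_metrics
from .params import (
    VARIED_PARAMETERS,
    ModelParameters,
    ParameterUncertainty,
    default_parameters,
    default_uncertainty,
)
from .simulate import DEFAULT_TAIL_H, SimulationResult, simulate

__all__ = [
    "LHSDesign",
    "SensitivityResult",
    "lhs_sample",
    "prcc",
    "prcc_matrix_inverse",
    "prcc_significance",
    "run_sensitivity",
    "run_nine_profiles",
]

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = ("Cg_max", "WOmax", "T_PD_h", "T_ZD_h")

#: Extra run length (h) past blood zero for sensitivity draws: slow corners
#: of the parameter box can roughly double the tail time constant, so the
#: default 8 h margin is doubled here.
SENSITIVITY_TAIL_H = 2.0 * DEFAULT_TAIL_H


@dataclass(frozen=True)
class LHSDesign:
    """A Latin hypercube design: which stratum each run uses, per parameter.

    ``strata[i, j]`` is the stratum index of run ``i`` for parameter ``j``
    (parameters in canonical order); ``values`` holds the corresponding
    stratum midpoints.  Every column of ``strata`` is a permutation of
    ``0..n-1``.
    """

    n_samples: int
    strata: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        n, k = self.strata.shape
        if n != self.n_samples or k != len(VARIED_PARAMETERS):
            raise ValueError("design shape mismatch")
        for j in range(k):
            if not np.array_equal(np.sort(self.strata[:, j]), np.arange(n)):
                raise ValueError(
                    f"column {VARIED_PARAMETERS[j]} is not a permutation of the strata"
                )


def lhs_sample(u: ParameterUncertainty | None = None, n: int = 50,
               seed: int | np.random.Generator | None = None
               ) -> tuple[LHSDesign, list[ModelParameters]]:
    """Draw a Latin hypercube sample of ``n`` parameter sets.

    Each parameter's range is split into ``n`` equal-probability intervals;
    the ``n`` values are the interval midpoints in a seed-determined random
    order, permuted independently per parameter (in canonical parameter
    order, so results are platform-reproducible).  Non-sampled fields stay
    at their fixed constants.
    """
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    u = u or default_uncertainty()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(VARIED_PARAMETERS)
    strata = np.empty((n, k), dtype=np.int64)
    values = np.empty((n, k))
    for j, name in enumerate(VARIED_PARAMETERS):
        lo, hi = u.bounds(name)
        width = (hi - lo) / n
        perm = rng.permutation(n)
        strata[:, j] = perm
        values[:, j] = lo + (perm + 0.5) * width
    design = LHSDesign(n_samples=n, strata=strata, values=values,
                       seed=seed if isinstance(seed, int) else None)
    param_sets = [
        ModelParameters(**dict(zip(VARIED_PARAMETERS, row))) for row in values
    ]
    return design, param_sets


def _rank_matrix(X: np.ndarray) -> np.ndarray:
    return np.column_stack([stats.rankdata(col) for col in X.T])


def prcc(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Partial rank correlation of each column of ``X`` with ``y``.

    For each parameter ``j``, the rank-transformed ``x_j`` and ``y`` are both
    regressed (with intercept) on the ranks of the other ``k-1`` columns; the
    PRCC is the Pearson correlation of the residuals.  Ties get average
    ranks.  A constant ``y`` yields all-zero coefficients with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValueError("y must have one entry per row of X")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 samples (n={n}, k={k})")
    if np.ptp(y) == 0.0:
        logger.warning("constant output: PRCC undefined, returning zeros")
        return np.zeros(k)
    R = _rank_matrix(X)
    ry = stats.rankdata(y)
    out = np.empty(k)
    for j in range(k):
        Z = np.column_stack([np.ones(n), np.delete(R, j, axis=1)])
        coef_x, *_ = np.linalg.lstsq(Z, R[:, j], rcond=None)
        coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
        res_x = R[:, j] - Z @ coef_x
        res_y = ry - Z @ coef_y
        out[j] = float(np.corrcoef(res_x, res_y)[0, 1])
    return out


def prcc_matrix_inverse(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent PRCC computation via the inverse rank-correlation matrix.

    With ``C`` the Pearson correlation matrix of all rank columns (the k
    parameters plus the output) and ``C^-1 = (c^{ij})``, the partial
    correlation of column ``j`` with the output is
    ``-c^{jy} / sqrt(c^{jj} c^{yy})``.  Algebraically identical to the
    residual-regression route; kept as a cross-check oracle.
    """
    X = np.asarray(X, dtype=float)
    R = np.column_stack([_rank_matrix(X), stats.rankdata(y)])
    C = np.corrcoef(R, rowvar=False)
    Cinv = np.linalg.inv(C)
    k = X.shape[1]
    return np.array([
        -Cinv[j, k] / np.sqrt(Cinv[j, j] * Cinv[k, k]) for j in range(k)
    ])


def prcc_significance(r: float | np.ndarray, n: int, k_controlled: int
                      ) -> float | np.ndarray:
    """Two-sided p-value for a PRCC being nonzero.

    ``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k_controlled``;
    ``|r| = 1`` maps to ``p = 0`` by convention.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0):
        raise ValueError("correlation magnitude cannot exceed 1")
    df = n - 2 - k_controlled
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom: n={n}, k={k_controlled}")
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    return float(p) if p.ndim == 0 else p


@dataclass
class SensitivityResult:
    """PRCC matrix (parameters x outputs) with p-values and the raw ensemble."""

    prcc: pd.DataFrame            #: 11x4, rows in canonical parameter order
    p_values: pd.DataFrame        #: matching two-sided p-values
    significance: pd.DataFrame    #: 0 (n.s.) or the strictest level met: 0.05/0.01/0.001
    design: LHSDesign
    parameter_sets: list[ModelParameters]
    metrics: pd.DataFrame         #: one row per simulation, the four outputs
    profile: BACProfile
    trajectories: list[SimulationResult] | None = None
    n_effective: int = 0
    failed_runs: list[int] = field(default_factory=list)


def run_sensitivity(profile: BACProfile, u: ParameterUncertainty | None = None,
                    n: int = 50, seed: int | None = None, *,
                    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
                    keep_trajectories: bool = False,
                    **sim_kwargs) -> SensitivityResult:
    """One full sensitivity analysis: LHS draw, ``n`` simulations, PRCC.

    Each of the ``n`` parameter sets is simulated under the same imposed
    blood profile; the four outputs are extracted and the PRCC of every
    parameter against every output is computed with its two-sided p-value.
    Failed simulations are logged, excluded, and the sample size adjusted.
    The result is bit-identical for a given seed.
    """
    u = u or default_uncertainty()
    design, param_sets = lhs_sample(u, n, seed)
    sim_kwargs.setdefault("horizon_h", profile.zero_time() + SENSITIVITY_TAIL_H)

    rows, ok_idx, failed = [], [], []
    trajectories = [] if keep_trajectories else None
    for i, p in enumerate(param_sets):
        try:
            result = simulate(profile, p, **sim_kwargs)
            m = compute_metrics(result, profile, zero_threshold=zero_threshold)
            if m.is_degenerate:
                raise RuntimeError(m.degenerate_reason)
        except Exception as exc:
            logger.warning("LHS run %d failed (%s); excluding it", i, exc)
            failed.append(i)
            continue
        rows.append({"Cg_max": m.C_g_max, "WOmax": m.WO_max,
                     "T_PD_h": m.T_PD, "T_ZD_h": m.T_ZD})
        ok_idx.append(i)
        if keep_trajectories:
            trajectories.append(result)

    metrics = pd.DataFrame(rows, index=ok_idx)
    n_eff = len(ok_idx)
    X = design.values[ok_idx, :]
    k = X.shape[1]

    prcc_mat = np.column_stack([prcc(X, metrics[c].to_numpy()) for c in OUTPUT_COLUMNS])
    p_mat = prcc_significance(prcc_mat, n_eff, k - 1)
    levels = np.zeros_like(p_mat)
    for level in (0.05, 0.01, 0.001):
        levels = np.where(p_mat < level, level, levels)

    idx = list(VARIED_PARAMETERS)
    cols = list(OUTPUT_COLUMNS)
    return SensitivityResult(
        prcc=pd.DataFrame(prcc_mat, index=idx, columns=cols),
        p_values=pd.DataFrame(p_mat, index=idx, columns=cols),
        significance=pd.DataFrame(levels, index=idx, columns=cols),
        design=design,
        parameter_sets=param_sets,
        metrics=metrics,
        profile=profile,
        trajectories=trajectories,
        n_effective=n_eff,
        failed_runs=failed,
    )


def run_nine_profiles(u: ParameterUncertainty | None = None, n: int = 50,
                      seed: int = 0, **kwargs) -> dict[tuple[float, float], SensitivityResult]:
    """The nine-profile design: absorption 0.5/1/2 h crossed with peak
    0.02/0.05/0.10 g/dL, using seeds ``seed+0 .. seed+8`` so the set is
    reproducible as a whole."""
    combos = [(a, b) for a in (0.5, 1.0, 2.0) for b in (0.02, 0.05, 0.10)]
    out = {}
    for i, (abs_t, bmax) in enumerate(combos):
        profile = BACProfile.triangular(abs_t, bmax)
        out[(abs_t, bmax)] = run_sensitivity(profile, u, n, seed + i, **kwargs)
    return out
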