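"""Climate-causality testing, method chosen by the series' linearity class.

Nonlinear series are tested with convergent cross mapping (CCM): the driver
is estimated from the response's reconstructed attractor, and causality
requires both (i) cross-map skill on all data significantly greater than
zero and (ii) convergence, i.e. higher mean skill at the maximum library
size than at the minimum.  Library sizes follow the nominal 20/500
convention; libraries are sampled with replacement, which is the only
reading under which a 500-point library is computable from a 34-year
series.

Linear-stochastic series are tested with a bivariate VAR(1): Granger
causality (does the driver's lagged value improve prediction of the
response?) and instantaneous causality (contemporaneous dependence through
the residual covariance).  A driver is causal when either test is
significant; no multiple-testing correction is applied, accepting the
higher type-I rate in exchange for power on short series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.api import VAR

from .climate import ClimateMetricSet
from .edm import SeriesDiagnosis, embed, phase_randomize
from .preprocess import PreparedSeries

__all__ = [
    "CausalityResult",
    "ccm_test",
    "var_granger_test",
    "lake_causality",
    "DEFAULT_LIB_SIZES",
    "DEFAULT_N_SAMPLES",
]

DEFAULT_LIB_SIZES = (20, 500)
DEFAULT_N_SAMPLES = 100


@dataclass
class CausalityResult:
    lake_id: str
    metric_name: str
    method: str  # "ccm" | "var"
    causal: bool
    causal_mode: str  # ccm | granger_only | instantaneous_only | both | none
    ccm_rho_full: float = np.nan
    ccm_rho_min_lib: float = np.nan
    ccm_rho_max_lib: float = np.nan
    ccm_p: float = np.nan
    granger_p: float = np.nan
    instantaneous_p: float = np.nan
    untestable: bool = False


def _cross_map_skill(D: np.ndarray, driver: np.ndarray, k: int, lib_idx=None) -> float:
    """Pearson skill of cross-map estimates of ``driver`` from the response
    manifold whose pairwise distances are ``D``.

    ``lib_idx`` restricts neighbor candidates to a library sample (indices
    with replacement, duplicates allowed); the target point itself is never
    its own neighbor.
    """
    m = D.shape[0]
    if lib_idx is None:
        lib_idx = np.arange(m)
    Dl = D[:, lib_idx].astype(float)
    Dl[lib_idx[None, :] == np.arange(m)[:, None]] = np.inf
    if Dl.shape[1] < k:
        return np.nan
    nbr = np.argpartition(Dl, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(Dl, nbr, axis=1)
    if not np.isfinite(d).all():
        return np.nan
    d_min = np.maximum(d.min(axis=1, keepdims=True), 1e-12)
    w = np.exp(-d / d_min)
    zero_min = d.min(axis=1) < 1e-12
    if zero_min.any():
        w[zero_min] = (d[zero_min] < 1e-12).astype(float)
    est = (w * driver[lib_idx][nbr]).sum(axis=1) / w.sum(axis=1)
    if est.std() == 0 or driver.std() == 0:
        return np.nan
    return float(np.corrcoef(est, driver)[0, 1])


def ccm_test(
    response: PreparedSeries | np.ndarray,
    driver: np.ndarray,
    E: int,
    metric_name: str = "",
    lib_sizes: tuple[int, int] = DEFAULT_LIB_SIZES,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_significance_surrogates: int = 100,
    seed=None,
    alpha: float = 0.05,
) -> CausalityResult:
    """Convergent cross mapping of one driver from one response series.

    Causal iff (i) the full-library cross-map skill is significantly greater
    than zero against a null of phase-randomized drivers (which preserves
    the driver's autocorrelation, so autocorrelation-induced spurious skill
    does not count as signal), and (ii) the skill converges: the mean skill
    at the maximum library size exceeds the 95th percentile of the sampled
    skills at the minimum.
    """
    x = response.edm_values if isinstance(response, PreparedSeries) else np.asarray(response, float)
    lake_id = response.lake_id if isinstance(response, PreparedSeries) else ""
    d = np.asarray(driver, dtype=float)
    if d.size != x.size:
        raise ValueError("driver and response must be aligned on the same years")
    if d.std() == 0:
        return CausalityResult(lake_id, metric_name, "ccm", False, "none", untestable=True)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    V = embed(x, E)
    dv = d[E - 1 :]  # driver value contemporaneous with each embedded vector
    m = V.shape[0]
    diff = V[:, None, :] - V[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    k = E + 1

    rho_full = _cross_map_skill(D, dv, k)
    surr = phase_randomize(dv, n_significance_surrogates, rng)
    null = np.array([_cross_map_skill(D, s, k) for s in surr])
    null = null[np.isfinite(null)]
    p_full = float((1.0 + np.sum(null >= rho_full)) / (null.size + 1.0))

    skills = {}
    for L in lib_sizes:
        vals = []
        for _ in range(n_samples):
            lib = rng.integers(0, m, size=L)
            s = _cross_map_skill(D, dv, k, lib)
            if np.isfinite(s):
                vals.append(s)
        skills[L] = np.asarray(vals)
    s_min, s_max = skills[min(lib_sizes)], skills[max(lib_sizes)]
    rho_min = float(s_min.mean()) if s_min.size else np.nan
    rho_max = float(s_max.mean()) if s_max.size else np.nan

    # convergence must exceed library-sampling noise: the mean skill at the
    # largest library has to clear the 95th percentile of the sampled skills
    # at the smallest (a bare ">" is a coin flip under the null)
    convergent = (
        s_min.size > 0
        and np.isfinite(rho_max)
        and rho_max > float(np.quantile(s_min, 1.0 - alpha))
    )
    causal = bool(p_full < alpha and convergent)
    return CausalityResult(
        lake_id,
        metric_name,
        "ccm",
        causal,
        "ccm" if causal else "none",
        ccm_rho_full=rho_full,
        ccm_rho_min_lib=rho_min,
        ccm_rho_max_lib=rho_max,
        ccm_p=p_full,
    )


def var_granger_test(
    response: PreparedSeries | np.ndarray,
    driver: np.ndarray,
    metric_name: str = "",
    lag: int = 1,
    alpha: float = 0.05,
) -> CausalityResult:
    """Bivariate VAR(1) Granger and instantaneous causality of one driver.

    The VAR is fit by equation-wise OLS; the Granger test is an F test that
    the driver's lag coefficient in the response equation is zero, and the
    instantaneous test is a Wald test of zero residual cross-covariance.
    """
    x = response.edm_values if isinstance(response, PreparedSeries) else np.asarray(response, float)
    lake_id = response.lake_id if isinstance(response, PreparedSeries) else ""
    d = np.asarray(driver, dtype=float)
    if d.size != x.size:
        raise ValueError("driver and response must be aligned on the same years")
    if d.std() == 0 or x.std() == 0:
        return CausalityResult(lake_id, metric_name, "var", False, "none", untestable=True)
    data = np.column_stack([x, d])
    try:
        res = VAR(data).fit(maxlags=lag, trend="c")
        granger_p = float(res.test_causality(0, [1], kind="f").pvalue)
        inst_p = float(res.test_inst_causality(1).pvalue)
    except np.linalg.LinAlgError:
        return CausalityResult(lake_id, metric_name, "var", False, "none", untestable=True)
    g = granger_p < alpha
    i = inst_p < alpha
    mode = "both" if (g and i) else "granger_only" if g else "instantaneous_only" if i else "none"
    return CausalityResult(
        lake_id,
        metric_name,
        "var",
        bool(g or i),
        mode,
        granger_p=granger_p,
        instantaneous_p=inst_p,
    )


def lake_causality(
    diagnosis: SeriesDiagnosis,
    prepared: PreparedSeries,
    metrics: ClimateMetricSet,
    lib_sizes: tuple[int, int] = DEFAULT_LIB_SIZES,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed=None,
    alpha: float = 0.05,
) -> tuple[list[CausalityResult], bool]:
    """Test one lake against all 16 climate metrics with the method its
    linearity class prescribes; unpredictable/degenerate lakes are not
    tested.  Returns (results, climate_causal)."""
    if diagnosis.linearity in ("unpredictable", "degenerate"):
        return [], False
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    results: list[CausalityResult] = []
    for name, series in metrics.testable_metrics().items():
        if diagnosis.linearity == "nonlinear":
            r = ccm_test(
                prepared,
                series,
                diagnosis.best_E,
                metric_name=name,
                lib_sizes=lib_sizes,
                n_samples=n_samples,
                seed=rng,
                alpha=alpha,
            )
        else:
            r = var_granger_test(prepared, series, metric_name=name, alpha=alpha)
        results.append(r)
    return results, any(r.causal for r in results)
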