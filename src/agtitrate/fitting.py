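"""Global fitting of binding models to CSP titrations.

The observable model under fast exchange is, for residue r reporting on
site s at titration point j,

    CSP_rj = ddmax_r * theta_s(L_tot_j; Kd's)

The fit minimizes sum_rj [(CSP_obs - CSP_model)/sigma]^2 jointly over the
shared dissociation constants and the per-residue saturation amplitudes
ddmax_r.  Kd's are optimized in log10 space (affinities span two orders of
magnitude); for any fixed Kd vector the amplitudes enter linearly and are
profiled out in closed form (variable projection, clamped at 0), so the
nonlinear search runs over 1-2 parameters only.  Multistart from
log-uniform draws guards against local optima of the sequential model.

Uncertainties come two ways: covariance-based standard errors from the
Gauss-Newton approximation at the optimum, and percentile intervals from a
residual-resampling bootstrap.  Model discrimination (hyperbolic
identical-sites vs sigmoidal sequential curves) uses AICc.  Stoichiometry
is read off tight-binding titrations as the breakpoint of a continuous
two-segment piecewise-linear fit (rising limb through the origin plus a
plateau).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .equilibria import (
    SITE1,
    SITE2,
    IdenticalSitesModel,
    OneSiteModel,
    SequentialTwoSiteModel,
    solve_mass_balance,
)
from .peaklist import FLAG_FAST, CSPProfile, TitrationSeries

__all__ = [
    "FitSpec",
    "FitResult",
    "StoichiometryEstimate",
    "fit_model",
    "bootstrap_uncertainty",
    "select_model",
    "estimate_stoichiometry",
    "assign_sites_from_clusters",
]

MODEL_FAMILIES = ("one_site", "identical_sites", "sequential")


@dataclass
class FitSpec:
    """Specification of one global fit."""

    model_family: str
    n_sites: int = 2
    site_map: dict[int, str] | None = None
    kd_bounds: tuple[float, float] = (1e-9, 1e-1)
    noise_sd: float = 0.003
    n_starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(
                f"model_family must be one of {MODEL_FAMILIES}, got {self.model_family!r}"
            )
        lo, hi = self.kd_bounds
        if not (0 < lo < hi):
            raise ValueError(f"kd bounds must satisfy 0 < lo < hi, got {self.kd_bounds}")

    @property
    def n_kd(self) -> int:
        return 2 if self.model_family == "sequential" else 1

    def build_model(self, kds):
        if self.model_family == "one_site":
            return OneSiteModel(kd=float(kds[0]))
        if self.model_family == "identical_sites":
            return IdenticalSitesModel(kd=float(kds[0]), n_sites=self.n_sites)
        return SequentialTwoSiteModel(kd1=float(kds[0]), kd2=float(kds[1]))


@dataclass
class FitResult:
    """Outcome of a global fit (best of all multistarts)."""

    model_family: str
    kd: np.ndarray
    kd_se: np.ndarray
    amplitudes: dict[int, float]
    amplitude_se: dict[int, float]
    chi2: float
    rss: float
    aicc: float
    n_obs: int
    n_params: int
    residues: list[int]
    site_map: dict[int, str]
    start_chi2: list[float]
    n_converged: int
    seed: int
    warnings: list[str] = field(default_factory=list)
    kd_ci95: list[tuple[float, float]] | None = None
    bootstrap_kds: np.ndarray | None = None
    # fit context retained for bootstrap refits
    _ctx: dict | None = field(default=None, repr=False)


def _fit_data(profile: CSPProfile, series: TitrationSeries, spec: FitSpec):
    """Assemble (residues, site labels, observed CSP matrix, L_tot, P_tot).

    Intermediate/lost residues are excluded (their CSPs are not population
    averages).  If the profile carries significance flags, only significant
    fast-exchange residues enter; otherwise all fast residues do.  The free
    state contributes no residuals.
    """
    flags = profile.exchange_flag
    any_sig = any(profile.significant.values())
    residues = []
    for r in profile.residues:
        if flags.get(r, FLAG_FAST) != FLAG_FAST:
            continue
        if spec.site_map is not None and r not in spec.site_map:
            continue
        if spec.site_map is None and any_sig and not profile.significant.get(r, False):
            continue
        residues.append(r)
    if not residues:
        raise ValueError("no fast-exchange residues available for fitting")
    site_map = (
        {r: spec.site_map[r] for r in residues}
        if spec.site_map is not None
        else {r: SITE1 for r in residues}
    )
    model_sites = spec.build_model([1e-6] * spec.n_kd).site_names
    bad = {s for s in site_map.values() if s not in model_sites}
    if bad:
        raise ValueError(f"site labels {sorted(bad)} unknown to model {spec.model_family}")
    for s in (model_sites if spec.model_family == "sequential" else [SITE1]):
        if s not in set(site_map.values()) and spec.model_family == "sequential":
            raise ValueError(f"no residues assigned to {s}")

    name = series.receptor_names[0]
    l_tot = np.array([pt.ligand_total for pt in series.points[1:]])
    p_tot = np.array([pt.receptor_totals[name] for pt in series.points[1:]])
    if l_tot.size < 2:
        raise ValueError("need at least 2 titration points beyond the free state")
    y = np.array([profile.csp[profile.index(r), 1:] for r in residues])
    return residues, site_map, y, l_tot, p_tot


def _theta_matrix(spec: FitSpec, kds, l_tot: np.ndarray, p_tot: np.ndarray):
    """Per-site occupancies at every titration point (vectorized in points)."""
    model = spec.build_model(kds)
    free_l = solve_mass_balance(
        lambda L: p_tot * model.bound_per_receptor(L), l_tot
    )
    return model.occupancies(free_l)


def _project_amplitudes(theta_rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form non-negative per-residue amplitudes given occupancies."""
    denom = np.sum(theta_rows * theta_rows, axis=1)
    num = np.sum(theta_rows * y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return np.maximum(amp, 0.0)


def fit_model(profile: CSPProfile, series: TitrationSeries, spec: FitSpec) -> FitResult:
    """Global multistart fit of ``spec``'s model family to a CSP profile."""
    residues, site_map, y, l_tot, p_tot = _fit_data(profile, series, spec)
    sigma = spec.noise_sd
    lo, hi = np.log10(spec.kd_bounds)

    def residuals(log_kd: np.ndarray) -> np.ndarray:
        occ = _theta_matrix(spec, 10.0**log_kd, l_tot, p_tot)
        theta_rows = np.array([occ[site_map[r]] for r in residues])
        amp = _project_amplitudes(theta_rows, y)
        return ((y - amp[:, None] * theta_rows) / sigma).ravel()

    rng = np.random.default_rng(spec.seed)
    starts = rng.uniform(lo, hi, size=(spec.n_starts, spec.n_kd))
    best = None
    start_chi2: list[float] = []
    n_converged = 0
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            start_chi2.append(math.inf)
            continue
        chi2 = 2.0 * res.cost
        start_chi2.append(chi2)
        if res.status > 0:
            n_converged += 1
        if best is None or chi2 < best[0] - 1e-10 or (
            abs(chi2 - best[0]) <= 1e-10 and res.x[0] < best[1].x[0]
        ):
            best = (chi2, res)
    if best is None or not math.isfinite(best[0]):
        raise RuntimeError(f"all {spec.n_starts} starts failed; chi2 per start: {start_chi2}")
    if n_converged == 0:
        raise RuntimeError("no multistart converged; chi2 per start: " + str(start_chi2))
    chi2, res = best

    kds = 10.0 ** res.x
    occ = _theta_matrix(spec, kds, l_tot, p_tot)
    theta_rows = np.array([occ[site_map[r]] for r in residues])
    amp = _project_amplitudes(theta_rows, y)
    fitted = amp[:, None] * theta_rows
    raw_resid = y - fitted
    n_obs = y.size
    n_params = spec.n_kd + len(residues)

    # Gauss-Newton covariance of the projected problem; scaled by reduced chi2.
    dof = max(n_obs - n_params, 1)
    s2 = chi2 / dof
    jtj = res.jac.T @ res.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:
        se_log = np.full(spec.n_kd, np.nan)
    kd_se = kds * math.log(10.0) * se_log
    denom = np.sum(theta_rows**2, axis=1)
    amp_se = sigma * math.sqrt(s2) / np.sqrt(np.maximum(denom, 1e-300))

    aicc = _aicc(chi2, n_params, n_obs)
    return FitResult(
        model_family=spec.model_family,
        kd=kds,
        kd_se=kd_se,
        amplitudes=dict(zip(residues, amp)),
        amplitude_se=dict(zip(residues, amp_se)),
        chi2=chi2,
        rss=float(np.sum(raw_resid**2)),
        aicc=aicc,
        n_obs=n_obs,
        n_params=n_params,
        residues=residues,
        site_map=site_map,
        start_chi2=start_chi2,
        n_converged=n_converged,
        seed=spec.seed,
        _ctx={
            "spec": spec, "y": y, "fitted": fitted, "l_tot": l_tot,
            "p_tot": p_tot, "x_opt": res.x.copy(),
        },
    )


def _aicc(chi2: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return chi2 + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def bootstrap_uncertainty(fit: FitResult, n_boot: int = 200, seed: int = 0) -> FitResult:
    """Residual-resampling bootstrap percentile intervals for the Kd's.

    Synthetic datasets are the fitted surface plus residuals resampled with
    replacement; each is refit from the original optimum (single start).
    Attaches 2.5/97.5 percentile intervals; deterministic given ``seed``.
    """
    if fit._ctx is None:
        raise ValueError("fit carries no context for bootstrapping")
    ctx = fit._ctx
    spec: FitSpec = ctx["spec"]
    y, fitted = ctx["y"], ctx["fitted"]
    l_tot, p_tot = ctx["l_tot"], ctx["p_tot"]
    site_map, residues = fit.site_map, fit.residues
    sigma = spec.noise_sd
    resid = (y - fitted).ravel()
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(spec.kd_bounds)

    kds_out = np.empty((n_boot, spec.n_kd))
    n_fail = 0
    for b in range(n_boot):
        y_b = fitted + rng.choice(resid, size=resid.size, replace=True).reshape(y.shape)

        def residuals(log_kd: np.ndarray) -> np.ndarray:
            occ = _theta_matrix(spec, 10.0**log_kd, l_tot, p_tot)
            theta_rows = np.array([occ[site_map[r]] for r in residues])
            amp = _project_amplitudes(theta_rows, y_b)
            return ((y_b - amp[:, None] * theta_rows) / sigma).ravel()

        res = least_squares(
            residuals, ctx["x_opt"], bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10,
        )
        if res.status <= 0:
            n_fail += 1
        kds_out[b] = 10.0 ** res.x

    out = replace(fit)
    out.bootstrap_kds = kds_out
    out.kd_ci95 = [
        (float(np.percentile(kds_out[:, i], 2.5)), float(np.percentile(kds_out[:, i], 97.5)))
        for i in range(spec.n_kd)
    ]
    out.warnings = list(fit.warnings)
    if n_fail > 0.2 * n_boot:
        out.warnings.append(f"{n_fail}/{n_boot} bootstrap refits failed to converge")
    return out


def select_model(
    profile: CSPProfile, series: TitrationSeries, candidates: list[FitSpec]
) -> list[tuple[FitSpec, FitResult | None, float]]:
    """Fit every candidate and rank by AICc (ascending; NaN = unrankable).

    Returns [(spec, result, delta_aicc)] sorted best-first; a candidate with
    too few residuals for AICc (n <= k+1) ranks last with delta NaN.
    """
    if len(candidates) < 2 and len(candidates) != 1:
        raise ValueError("need at least one candidate")
    fits: list[tuple[FitSpec, FitResult | None]] = []
    for spec in candidates:
        try:
            fits.append((spec, fit_model(profile, series, spec)))
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"candidate {spec.model_family}: {exc}", stacklevel=2)
            fits.append((spec, None))
    def key(item):
        _, fr = item
        return math.inf if fr is None or not math.isfinite(fr.aicc) else fr.aicc
    ranked = sorted(fits, key=key)
    best_aicc = key(ranked[0])
    out = []
    for spec, fr in ranked:
        a = key((spec, fr))
        delta = a - best_aicc if math.isfinite(a) else math.nan
        out.append((spec, fr, delta))
    return out


@dataclass
class StoichiometryEstimate:
    """Breakpoint-based binding stoichiometry (ligand equivalents per receptor)."""

    n_est: float
    breakpoints: dict[int, float]
    method: str = "two_segment_piecewise_linear"
    excluded: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n_est > 0:
            raise ValueError("n_est must be positive")


def _piecewise_sse(ratios: np.ndarray, y: np.ndarray, b: float) -> tuple[float, float]:
    """Best slope and SSE of the model y = s*min(ratio, b)."""
    m = np.minimum(ratios, b)
    denom = float(m @ m)
    s = float(m @ y) / denom if denom > 0 else 0.0
    r = y - s * m
    return s, float(r @ r)


def _fit_breakpoint(ratios: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Breakpoint and slope of the two-segment fit, grid scan + local refine."""
    grid = np.linspace(ratios[1], ratios[-1], 201)
    sses = [_piecewise_sse(ratios, y, b)[1] for b in grid]
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda b: _piecewise_sse(ratios, y, b)[1], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        b = float(res.x)
    else:
        b = float(grid[i])
    s, _ = _piecewise_sse(ratios, y, b)
    return b, s


def estimate_stoichiometry(
    profile: CSPProfile,
    series: TitrationSeries,
    saturating_residues: list[int] | None = None,
) -> StoichiometryEstimate:
    """Stoichiometry as the median per-residue breakpoint of CSP vs molar ratio.

    Valid in the tight-binding regime (P_tot >> Kd), where each curve rises
    linearly to a sharp plateau at the stoichiometric equivalence point.
    Residues whose final slope exceeds 10% of their initial slope have not
    saturated and are excluded.
    """
    flags = profile.exchange_flag
    any_sig = any(profile.significant.values())
    if saturating_residues is None:
        saturating_residues = [
            r for r in profile.residues
            if flags.get(r, FLAG_FAST) == FLAG_FAST
            and (not any_sig or profile.significant.get(r, False))
        ]
    ratios = np.asarray(profile.molar_ratios, dtype=float)
    warns: list[str] = []
    excluded: list[int] = []
    breakpoints: dict[int, float] = {}
    for r in saturating_residues:
        y = profile.csp[profile.index(r)]
        if np.any(np.isnan(y)):
            excluded.append(r)
            continue
        if y[-1] <= 0:
            excluded.append(r)
            continue
        init_slope = y[1] / ratios[1] if ratios[1] > 0 else np.inf
        final_slope = (y[-1] - y[-2]) / (ratios[-1] - ratios[-2])
        if init_slope <= 0 or final_slope > 0.1 * init_slope:
            excluded.append(r)
            msg = f"residue {r} not saturated (final slope > 10% of initial)"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        b, s = _fit_breakpoint(ratios, y)
        breakpoints[r] = b
        # corner rounding beyond ~Kd/P_tot = 0.05 leaves the observed CSP
        # visibly below the sharp-corner prediction near the breakpoint
        j = int(np.argmin(np.abs(ratios - b)))
        if s * min(ratios[j], b) > 0 and y[j] < 0.85 * s * min(ratios[j], b):
            msg = (
                f"residue {r}: rounded breakpoint suggests Kd/P_tot > 0.05; "
                "stoichiometry estimate may be biased"
            )
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
    if not breakpoints:
        raise ValueError("no saturating residues; cannot estimate stoichiometry")
    return StoichiometryEstimate(
        n_est=float(np.median(list(breakpoints.values()))),
        breakpoints=breakpoints,
        excluded=excluded,
        warnings=warns,
    )


def assign_sites_from_clusters(
    profile: CSPProfile, clusters: list[list[int]]
) -> dict[int, str]:
    """Map residue clusters to sequential-model sites by saturation order.

    The cluster whose mean normalized CSP curve crosses half-saturation at
    the lower molar ratio is the first-filling high-affinity site (site1);
    the other is site2.  Exactly two clusters are required.
    """
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(clusters)}")
    ratios = np.asarray(profile.molar_ratios, dtype=float)

    def half_ratio(cluster: list[int]) -> float:
        rows = []
        for r in cluster:
            if profile.exchange_flag.get(r, FLAG_FAST) != FLAG_FAST:
                continue
            y = profile.csp[profile.index(r)]
            if np.any(np.isnan(y)) or y[-1] <= 0:
                continue
            rows.append(y / y[-1])
        if not rows:
            return math.inf
        mean = np.mean(rows, axis=0)
        above = np.nonzero(mean >= 0.5)[0]
        if above.size == 0:
            return math.inf
        j = above[0]
        if j == 0:
            return float(ratios[0])
        # linear interpolation across the crossing
        f = (0.5 - mean[j - 1]) / (mean[j] - mean[j - 1])
        return float(ratios[j - 1] + f * (ratios[j] - ratios[j - 1]))

    h = [half_ratio(c) for c in clusters]
    first = int(np.argmin(h))
    out: dict[int, str] = {}
    for r in clusters[first]:
        out[r] = SITE1
    for r in clusters[1 - first]:
        out[r] = SITE2
    return out
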