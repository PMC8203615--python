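"""Global nonlinear regression of kinetic mechanisms to trace datasets.

The workflow mirrors standard progress-curve / stopped-flow practice:

1. exponential-phase analysis of individual traces (:func:`fit_exponentials`),
2. fitting the observed-rate laws to the rate-vs-[S] dependence to obtain
   starting estimates (:func:`fit_rate_dependence`),
3. global Levenberg-Marquardt regression of the full mass-action model to all
   traces jointly (:func:`fit_global`), with residuals normalized per point
   by sigma,
4. profile-chi2 confidence contours (:func:`confidence_contour`) and
   mechanism discrimination (:func:`compare_mechanisms`),
5. decay half-life fitting for flash/glow characterization (:func:`fit_decay`).

chi2 thresholds follow the ratio convention chi2_min/chi2 >= threshold
(0.9 for steady-state, 0.95 for transient analyses by convention here); the
absolute delta-chi2 convention is available via ``convention="delta"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq, curve_fit, least_squares

from .mechanisms import (
    MechanismKind,
    MechanismSpec,
    ObservationModel,
    RateConstantSet,
    make_mechanism,
    observe_trace,
    simulate_mechanism,
)

__all__ = [
    "Trace",
    "TraceDataset",
    "ExponentialPhases",
    "RateDependenceFit",
    "FitResult",
    "ConfidenceContour",
    "DecayFit",
    "estimate_sigma",
    "fit_exponentials",
    "fit_rate_dependence",
    "fit_global",
    "minimize_residual",
    "confidence_contour",
    "compare_mechanisms",
    "fit_decay",
]

_RATE_NAMES = ("k_plus1", "k_minus1", "k_plus2", "k_minus2", "k_plus3", "k_minus3")


@dataclass
class Trace:
    """One measured (or synthetic) time course with its known concentrations."""

    trace_id: str
    time: np.ndarray           # s, strictly increasing
    signal: np.ndarray
    E0: float                  # uM
    S0: float                  # uM
    observable: str = "LUMINESCENCE_CUMULATIVE"
    replicate: int = 0
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"trace {self.trace_id}: time must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class TraceDataset:
    traces: list[Trace]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("dataset must contain at least one trace")

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


def estimate_sigma(signal: np.ndarray, tail_fraction: float = 0.25) -> float:
    """Constant per-trace noise estimate from high-time residual scatter.

    Uses the second-difference estimator on the trailing portion of the trace,
    where the underlying curve is smoothest; robust to the residual trend.
    """
    signal = np.asarray(signal, dtype=float)
    n_tail = max(int(len(signal) * tail_fraction), 4)
    tail = signal[-n_tail:]
    d2 = np.diff(tail, n=2)
    sd = float(np.std(d2) / np.sqrt(6.0)) if len(d2) else 0.0
    floor = max(float(np.max(np.abs(signal))), 1.0) * 1e-9
    return max(sd, floor)


# ---------------------------------------------------------------------------
# exponential-phase analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialPhases:
    """F(t) = F_SS + sum_i A_i * exp(-k_i * t), phases ordered fast-first."""

    F_SS: float
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]

    @property
    def n_phases(self) -> int:
        return len(self.rates)

    @property
    def k_fast(self) -> float:
        return self.rates[0]

    @property
    def k_slow(self) -> float:
        return self.rates[-1]

    @property
    def k_obs(self) -> float:
        if self.n_phases != 1:
            raise ValueError("k_obs is defined for single-phase fits")
        return self.rates[0]

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.F_SS)
        for A, k in zip(self.amplitudes, self.rates):
            out = out + A * np.exp(-k * t)
        return out


def _linear_coeffs(t: np.ndarray, y: np.ndarray, rates: np.ndarray):
    X = np.column_stack([np.ones_like(t)] + [np.exp(-k * t) for k in rates])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, resid


def fit_exponentials(
    time: np.ndarray, signal: np.ndarray, n_phases: int = 2
) -> ExponentialPhases:
    """Least-squares single/double exponential fit by variable projection.

    Rates are optimized in log space over a deterministic log-spaced grid of
    starting guesses spanning the data's time scale; offset and amplitudes
    are solved linearly at each step.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    if len(t) < 3 * (2 * n_phases + 1):
        raise ValueError(
            f"need at least {3 * (2 * n_phases + 1)} points for a {n_phases}-phase fit"
        )
    span = float(np.ptp(y))
    if span == 0 or span < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        raise ValueError("signal is constant: no decaying phase identifiable")

    t0 = t - t[0]
    t_span = t0[-1]
    dt_min = float(np.min(np.diff(t0)))
    k_lo, k_hi = 0.5 / t_span, 2.0 / dt_min

    def objective(log_k: np.ndarray) -> np.ndarray:
        _, resid = _linear_coeffs(t0, y, np.exp(log_k))
        return resid

    grid = np.geomspace(k_lo, k_hi, 6)
    if n_phases == 1:
        starts = [[k] for k in grid]
    else:
        starts = [[grid[i], grid[j]] for i in range(len(grid)) for j in range(i + 1, len(grid))]

    best = None
    for s in starts:
        res = least_squares(objective, np.log(s), method="lm", xtol=1e-14, ftol=1e-14)
        ssr = float(np.sum(res.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, res.x)
    rates = np.exp(best[1])
    coef, _ = _linear_coeffs(t0, y, rates)
    order = np.argsort(-rates)
    rates = rates[order]
    amps = coef[1:][order]
    # amplitudes refer to t = time[0]; re-reference to absolute t = 0
    amps_abs = amps * np.exp(rates * t[0])
    if n_phases == 2 and (
        abs(rates[0] - rates[1]) < 1e-6 * rates[0]
        or np.min(np.abs(amps)) < 1e-6 * span
    ):
        raise ValueError(
            "double-exponential fit is degenerate (coincident rates or vanishing "
            "amplitude): the data support a single phase"
        )
    return ExponentialPhases(
        F_SS=float(coef[0]),
        amplitudes=tuple(float(a) for a in amps_abs),
        rates=tuple(float(k) for k in rates),
    )


# ---------------------------------------------------------------------------
# observed-rate-vs-concentration fits (starting estimates for global fits)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateDependenceFit:
    rates: RateConstantSet
    A_lim: float | None = None
    K_d: float | None = None


def fit_rate_dependence(
    S: np.ndarray,
    kind: MechanismKind | str,
    k_fast: np.ndarray | None = None,
    k_slow: np.ndarray | None = None,
    k_obs: np.ndarray | None = None,
    amplitude: np.ndarray | None = None,
) -> RateDependenceFit:
    """Fit the observed-rate laws to rate-vs-[S] tables.

    Induced fit: the fast phase is linear in [S] (slope k+1, intercept k-1);
    the slow phase is hyperbolic with plateau k+2 + k-2 and offset k-2.
    Conformational selection: fast phase slope k+2, intercept k-1; the slow
    phase follows the printed CS law in k+1, k-2.  One-step: k_obs linear in
    [S]; the amplitude, when given, follows A = A_lim*[S]/(K_d + [S]).
    """
    kind = MechanismKind(kind)
    S = np.asarray(S, dtype=float)
    if len(np.unique(S)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")

    def _linfit(rate_arr, what):
        rate_arr = np.asarray(rate_arr, dtype=float)
        if np.ptp(rate_arr) == 0:
            raise ValueError(f"all {what} values identical: dependence on [S] absent")
        slope, intercept = np.polyfit(S, rate_arr, 1)
        return max(float(slope), 0.0), max(float(intercept), 0.0)

    if kind is MechanismKind.ONE_STEP:
        if k_obs is None:
            raise ValueError("one-step fit requires k_obs values")
        k1, km1 = _linfit(k_obs, "k_obs")
        A_lim = K_d = None
        if amplitude is not None:
            amp = np.asarray(amplitude, dtype=float)
            popt, _ = curve_fit(
                lambda s, al, kd: al * s / (kd + s), S, amp,
                p0=[float(np.max(amp)), float(np.median(S))],
                maxfev=10000,
            )
            A_lim, K_d = float(popt[0]), float(popt[1])
        return RateDependenceFit(
            RateConstantSet(k_plus1=k1, k_minus1=km1), A_lim=A_lim, K_d=K_d
        )

    if k_fast is None or k_slow is None:
        raise ValueError("two-step mechanisms require k_fast and k_slow values")
    kf = np.asarray(k_fast, dtype=float)
    ks = np.asarray(k_slow, dtype=float)

    if kind is MechanismKind.INDUCED_FIT:
        k1, km1 = _linfit(kf, "k_fast")
        if km1 == 0:
            raise ValueError("fast-phase intercept k-1 fitted to zero; slow-phase law undefined")
        K1 = k1 / km1

        def slow_law(s, k2, km2):
            return k2 * K1 * s / (K1 * s + 1.0) + km2

        p0 = [max(float(np.ptp(ks)), 1e-3), max(float(np.min(ks)), 1e-3)]
        popt, _ = curve_fit(slow_law, S, ks, p0=p0, bounds=(0, np.inf), maxfev=10000)
        return RateDependenceFit(
            RateConstantSet(k_plus1=k1, k_minus1=km1,
                            k_plus2=float(popt[0]), k_minus2=float(popt[1]))
        )

    if kind is MechanismKind.CONF_SELECTION:
        k2, km1 = _linfit(kf, "k_fast")
        if km1 == 0:
            raise ValueError("fast-phase intercept k-1 fitted to zero; slow-phase law undefined")

        def slow_law(s, k1, km2):
            K1 = k1 / km1
            return k1 * (K1 * k2 * s + km2) / (k1 * K1 * k2 * s + km2)

        p0 = [max(float(np.max(ks)), 1e-3), max(float(np.min(ks)), 1e-3)]
        popt, _ = curve_fit(slow_law, S, ks, p0=p0, bounds=(0, np.inf), maxfev=10000)
        return RateDependenceFit(
            RateConstantSet(k_plus1=float(popt[0]), k_minus1=km1,
                            k_plus2=k2, k_minus2=float(popt[1]))
        )

    raise ValueError(f"no observed-rate law for {kind.value}")


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    estimates: dict[str, float]
    stderr: dict[str, float | None]
    chi2: float
    dof: int
    success: bool
    message: str = ""
    scale_f: float | None = None
    conc_factors: dict[str, float] | None = None
    _residual: object = None   # callable(lmfit.Parameters) -> residual vector
    _params: object = None     # lmfit.Parameters at the optimum

    @property
    def redchi(self) -> float:
        return self.chi2 / max(self.dof, 1)


def minimize_residual(
    residual, params: lmfit.Parameters, max_nfev: int | None = None,
    n_restarts: int = 5, restart_seed: int = 0,
) -> FitResult:
    """Levenberg-Marquardt minimization with seeded multi-start fallback.

    `residual` maps an ``lmfit.Parameters`` to the sigma-normalized residual
    vector; chi2 is its squared norm.
    """
    def _run(p0):
        return lmfit.minimize(residual, p0, method="leastsq", max_nfev=max_nfev)

    out = _run(params.copy())
    best = out
    # an evaluation-budget stop still yields a usable optimum; restart only
    # on a genuine failure
    budget_stop = max_nfev is not None and out.nfev >= max_nfev
    if not np.isfinite(out.chisqr) or (not out.success and not budget_stop):
        rng = np.random.default_rng(restart_seed)
        for _ in range(n_restarts):
            p = params.copy()
            for name in p:
                if p[name].vary and p[name].value != 0:
                    p[name].value *= float(np.exp(rng.normal(0, 0.5)))
            try:
                cand = _run(p)
            except Exception:
                continue
            if cand.success and (not best.success or cand.chisqr < best.chisqr):
                best = cand
    est = {k: float(v.value) for k, v in best.params.items()}
    err = {
        k: (float(v.stderr) if v.stderr is not None else None)
        for k, v in best.params.items()
    }
    return FitResult(
        estimates=est, stderr=err, chi2=float(best.chisqr),
        dof=int(best.ndata - best.nvarys), success=bool(best.success),
        message=str(best.message), _residual=residual, _params=best.params.copy(),
    )


def _default_starts(
    dataset: TraceDataset, spec: MechanismSpec, obs: ObservationModel
) -> dict[str, float]:
    """Heuristic starting values for progress-curve fits.

    The scale f is pinned by endpoints (cumulative signal -> S0 at completion);
    initial-rate Michaelis-Menten analysis of the early curve gives kcat and
    Km seeds; Kp is seeded at Km (no product-inhibition information a priori).
    """
    starts: dict[str, float] = {}
    if obs.kind == "LUMINESCENCE_CUMULATIVE":
        f0 = float(np.median([tr.signal[-1] / tr.S0 for tr in dataset if tr.S0 > 0]))
        f0 = max(f0, 1e-9)
        starts["f"] = f0
        v0, s0 = [], []
        for tr in dataset:
            y = tr.signal / f0  # product, uM
            # initial velocity from a through-origin quadratic over the
            # early (<25% completion) part of the progress curve
            mask = y <= 0.25 * y[-1]
            n_early = max(int(np.sum(mask)), 3)
            tt, yy = tr.time[:n_early], y[:n_early]
            X = np.column_stack([tt, tt**2])
            coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
            slope = coef[0]
            if slope > 0:
                v0.append(slope)
                s0.append(tr.S0)
        if len(set(s0)) >= 3:
            try:
                popt, _ = curve_fit(
                    lambda s, vmax, km: vmax * s / (km + s), s0, v0,
                    p0=[max(v0), np.median(s0)], bounds=(0, np.inf), maxfev=5000,
                )
                E0 = float(np.median([tr.E0 for tr in dataset]))
                if E0 > 0 and popt[0] > 0 and popt[1] > 0:
                    starts["k_plus2"] = popt[0] / E0
                    starts["k_minus1"] = 100.0 * popt[1]
                    starts["k_plus3"] = 100.0 * popt[1]  # Kp ~ Km seed
            except RuntimeError:
                pass
    return starts


def fit_global(
    dataset: TraceDataset,
    spec: MechanismSpec,
    obs: ObservationModel,
    free_params: list[str],
    fixed_params: dict[str, float] | None = None,
    starts: dict[str, float] | None = None,
    adjust_conc: bool = False,
    max_nfev: int | None = None,
) -> FitResult:
    """Fit one parameter set jointly to all traces by numerical integration.

    `free_params` picks from the mechanism's rate-constant names plus "f",
    "a", "b".  `fixed_params`/`starts` override the values in `spec`/`obs`.
    With ``adjust_conc=True`` a per-trace multiplicative substrate-
    concentration factor, box-bounded to [0.95, 1.05], absorbs small pipetting
    errors.  Residuals are (data - model)/sigma; sigma per trace defaults to
    :func:`estimate_sigma`.
    """
    fixed_params = dict(fixed_params or {})
    kind = spec.kind
    free = list(free_params)
    mech_names = [n for n in _RATE_NAMES if getattr(spec.rates, n) is not None]
    user_starts = dict(starts or {})
    auto = _default_starts(dataset, spec, obs)

    params = lmfit.Parameters()
    for name in mech_names:
        base = fixed_params.get(name, user_starts.get(name, auto.get(name)))
        if base is None:
            base = spec.rates.get(name)
        params.add(name, value=float(base), vary=name in free, min=0.0)
    for name, default in (("f", obs.f), ("a", obs.a), ("b", obs.b)):
        if name in free or name in fixed_params or (
            name == "f" or obs.kind == "FLUORESCENCE"
        ):
            base = fixed_params.get(name, user_starts.get(name, auto.get(name, default)))
            params.add(name, value=float(base), vary=name in free,
                       min=1e-12 if name == "f" else 0.0)
    cf_names = {}
    for i, tr in enumerate(dataset):
        if adjust_conc:
            nm = f"cf{i}"
            params.add(nm, value=1.0, vary=True, min=0.95, max=1.05)
            cf_names[tr.trace_id] = nm

    sigmas = [
        tr.sigma if tr.sigma is not None else np.full_like(tr.signal, estimate_sigma(tr.signal))
        for tr in dataset
    ]
    # traces sharing initial conditions and grid reuse one ODE solution
    groups: dict[tuple, list[int]] = {}
    for i, tr in enumerate(dataset):
        key = (tr.E0, tr.S0, tr.time.tobytes()) if not adjust_conc else (i,)
        groups.setdefault(key, []).append(i)
    traces = list(dataset)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        rates = RateConstantSet(**{
            n: float(p[n].value) for n in mech_names
        })
        mech = make_mechanism(kind, rates)
        om = ObservationModel(
            kind=obs.kind,
            f=float(p["f"].value) if "f" in p else obs.f,
            a=float(p["a"].value) if "a" in p else obs.a,
            b=float(p["b"].value) if "b" in p else obs.b,
            mechanism_kind=kind,
        )
        out = []
        for key, idxs in groups.items():
            tr0 = traces[idxs[0]]
            cf = float(p[cf_names[tr0.trace_id]].value) if tr0.trace_id in cf_names else 1.0
            t = tr0.time
            grid = t if t[0] == 0.0 else np.concatenate([[0.0], t])
            try:
                traj = simulate_mechanism(
                    mech, {"E": tr0.E0, "S": tr0.S0 * cf}, grid,
                    rtol=1e-8, atol=1e-10,
                )
                _, model = observe_trace(traj, om)
            except RuntimeError:
                model = np.full(len(grid), 1e6)
            if t[0] != 0.0:
                model = model[1:]
            for i in idxs:
                out.append((traces[i].signal - model) / sigmas[i])
        return np.concatenate(out)

    # deterministic start sweep: heuristic seeds can sit in a wrong chi2
    # basin, so unless the caller pinned the starts, also try the free rate
    # constants scaled down/up and keep the best optimum
    sweep: list[dict[str, float]] = [{}]
    if not user_starts:
        free_rates = [n for n in mech_names if n in free]
        sweep += [{n: fac for n in free_rates} for fac in (0.3, 3.0)]
    fr = None
    for mults in sweep:
        p = params.copy()
        for name, fac in mults.items():
            if p[name].value > 0:
                p[name].value *= fac
        cand = minimize_residual(residual, p, max_nfev=max_nfev)
        if fr is None or cand.chi2 < fr.chi2:
            fr = cand
    fr.scale_f = fr.estimates.get("f")
    if adjust_conc:
        fr.conc_factors = {
            tid: fr.estimates[nm] for tid, nm in cf_names.items()
        }
    return fr


# ---------------------------------------------------------------------------
# confidence contours
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceContour:
    param: str
    estimate: float
    threshold: float
    values: np.ndarray
    chi2: np.ndarray
    lower: float | None
    upper: float | None
    convention: str = "ratio"

    @property
    def ratio(self) -> np.ndarray:
        return np.min(self.chi2) / self.chi2


def _profile_point(residual, params, name, value) -> float:
    p = params.copy()
    p[name].set(value=value, vary=False)
    if not any(p[k].vary for k in p):
        return float(np.sum(residual(p) ** 2))
    out = lmfit.minimize(residual, p, method="leastsq")
    return float(out.chisqr)


def confidence_contour(
    fit: FitResult,
    param: str,
    threshold: float,
    n_grid: int = 12,
    max_expand: int = 8,
    convention: str = "ratio",
) -> ConfidenceContour:
    """Profile-chi2 confidence bounds for one parameter.

    The parameter is scanned on each side of its estimate with all other free
    parameters re-optimized at every grid point.  With the ratio convention
    the acceptable region is chi2_min/chi2(theta) >= threshold; bounds are
    located by linear interpolation of chi2 across the crossing.  A side whose
    profile never crosses within the scan is reported as open-ended (None).
    With ``convention="delta"`` the acceptable region is
    chi2 <= chi2_min + threshold (absolute delta-chi2 units).
    """
    if convention == "ratio" and not (0.0 < threshold <= 1.0):
        raise ValueError("ratio threshold must be in (0, 1]")
    if fit._residual is None or fit._params is None:
        raise ValueError("fit does not carry a refittable residual")
    est = fit.estimates[param]
    chi2_min = fit.chi2
    if convention == "ratio":
        chi2_limit = chi2_min / threshold
    else:
        chi2_limit = chi2_min + threshold
    if convention == "ratio" and threshold == 1.0:
        return ConfidenceContour(
            param=param, estimate=est, threshold=threshold,
            values=np.array([est]), chi2=np.array([chi2_min]),
            lower=est, upper=est, convention=convention,
        )

    err = fit.stderr.get(param)
    step0 = err if err else max(abs(est) * 0.05, 1e-8)

    pmin = fit._params[param].min

    def scan(direction: int):
        vals, chis = [], []
        step = step0
        v = est
        for _ in range(n_grid + max_expand):
            v = v + direction * step
            if np.isfinite(pmin) and v < pmin:
                v = pmin
            c = _profile_point(fit._residual, fit._params, param, v)
            vals.append(v)
            chis.append(c)
            if c > chi2_limit:
                break
            if np.isfinite(pmin) and v == pmin:
                break
            step *= 1.6
        return np.array(vals), np.array(chis)

    lo_v, lo_c = scan(-1)
    hi_v, hi_c = scan(+1)

    def crossing(vals, chis):
        if len(vals) == 0 or chis[-1] <= chi2_limit:
            return None  # open-ended within the scan
        # interpolate on sqrt(chi2 - chi2_min), which is linear in the
        # parameter for a locally quadratic profile
        inside_v, inside_c = est, chi2_min
        for v, c in zip(vals, chis):
            if c > chi2_limit:
                num = np.sqrt(chi2_limit - chi2_min) - np.sqrt(inside_c - chi2_min)
                den = np.sqrt(c - chi2_min) - np.sqrt(inside_c - chi2_min)
                w = num / den if den > 0 else 1.0
                return float(inside_v + w * (v - inside_v))
            inside_v, inside_c = v, c
        return None

    lower = crossing(lo_v, lo_c)
    upper = crossing(hi_v, hi_c)
    values = np.concatenate([lo_v[::-1], [est], hi_v])
    chi2s = np.concatenate([lo_c[::-1], [chi2_min], hi_c])
    return ConfidenceContour(
        param=param, estimate=est, threshold=threshold,
        values=values, chi2=chi2s, lower=lower, upper=upper,
        convention=convention,
    )


# ---------------------------------------------------------------------------
# mechanism discrimination
# ---------------------------------------------------------------------------

def compare_mechanisms(
    dataset: TraceDataset,
    candidates: list[dict],
    contour_threshold: float = 0.95,
    contour_params: bool = False,
    max_nfev: int | None = None,
) -> list[dict]:
    """Fit each candidate mechanism and rank by fit quality and identifiability.

    Candidates are ordered by chi2 per degree of freedom, except that a
    candidate with unconstrained free rate constants (standard error missing
    or exceeding the estimate — the regression cannot pin the parameter down)
    ranks below every fully constrained one; this mirrors discrimination
    practice, where a nested over-parameterized mechanism matches chi2 but
    leaves its extra constants undetermined.  Each candidate dict needs keys
    ``name``, ``spec``, ``obs``, ``free`` and optionally ``fixed``/``starts``.
    Candidates that fail to fit are ranked last with the failure recorded
    rather than dropped.  With ``contour_params=True`` each free rate
    constant additionally gets a bounded/unbounded profile-contour flag.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate mechanisms to compare")
    rows = []
    for cand in candidates:
        row = {"name": cand["name"], "failed": False, "failure": None}
        try:
            fr = fit_global(
                dataset, cand["spec"], cand["obs"], cand["free"],
                fixed_params=cand.get("fixed"), starts=cand.get("starts"),
                max_nfev=max_nfev,
            )
            unconstrained = []
            for pname in cand["free"]:
                if pname in ("f", "a", "b"):
                    continue
                err, val = fr.stderr.get(pname), fr.estimates[pname]
                if err is None or not np.isfinite(err) or err >= max(abs(val), 1e-12):
                    unconstrained.append(pname)
            row.update(chi2=fr.chi2, dof=fr.dof, redchi=fr.redchi, fit=fr,
                       unconstrained=unconstrained,
                       n_unconstrained=len(unconstrained))
            if contour_params:
                flags = {}
                for pname in cand["free"]:
                    if pname in ("f", "a", "b"):
                        continue
                    cc = confidence_contour(fr, pname, contour_threshold)
                    flags[pname] = (cc.lower is not None) and (cc.upper is not None)
                row["contour_bounded"] = flags
        except Exception as exc:  # failed candidates stay in the ranking
            row.update(chi2=np.inf, dof=0, redchi=np.inf, fit=None,
                       failed=True, failure=str(exc),
                       unconstrained=[], n_unconstrained=0)
        rows.append(row)
    rows.sort(key=lambda r: (r["failed"], r["n_unconstrained"], r["redchi"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    if len(rows) >= 2 and np.isfinite(rows[0]["redchi"]):
        rows[0]["tie"] = bool(
            np.isclose(rows[0]["redchi"], rows[1]["redchi"], rtol=1e-9, atol=1e-12)
        )
    return rows


# ---------------------------------------------------------------------------
# bioluminescence decay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    model: str                 # "exponential" | "logistic"
    params: dict[str, float]
    t_half: float              # s
    ssr: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "exponential":
            return self.params["I0"] * np.exp(-self.params["k"] * t)
        tau, h = self.params["tau"], self.params["h"]
        return self.params["I0"] / (1.0 + (np.maximum(t, 0.0) / tau) ** h)


def fit_decay(time: np.ndarray, signal: np.ndarray, model: str = "exponential") -> DecayFit:
    """Fit a luminescence decay and report the signal half-life t_1/2.

    Exponential: I(t) = I0*exp(-k*t), t_1/2 = ln2/k.  Logistic:
    I(t) = I0/(1 + (t/tau)^h) with t_1/2 solved numerically as the time at
    which the fitted curve reaches half its initial amplitude.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if np.any(y <= 0):
        raise ValueError("decay signal must be positive")
    n_edge = max(len(y) // 10, 2)
    if np.mean(y[:n_edge]) <= np.mean(y[-n_edge:]):
        raise ValueError("signal shows no overall decay; refusing to fit a decay model")

    half = y[0] / 2.0
    below = np.nonzero(y < half)[0]
    t_half_guess = float(t[below[0]]) if len(below) else float(t[-1] / 2)
    t_half_guess = max(t_half_guess, float(t[1] if t[0] == 0 else t[0]))

    if model == "exponential":
        popt, _ = curve_fit(
            lambda tt, I0, k: I0 * np.exp(-k * tt), t, y,
            p0=[y[0], np.log(2) / t_half_guess], maxfev=10000,
        )
        I0, k = float(popt[0]), float(popt[1])
        if k <= 0:
            raise ValueError("fitted decay rate is non-positive")
        fitres = DecayFit("exponential", {"I0": I0, "k": k}, np.log(2) / k, 0.0)
    elif model == "logistic":
        popt, _ = curve_fit(
            lambda tt, I0, tau, h: I0 / (1.0 + (tt / tau) ** h),
            t[t > 0], y[t > 0],
            p0=[y[0], t_half_guess, 2.0],
            bounds=([0, 1e-12, 0.1], [np.inf, np.inf, 50.0]), maxfev=10000,
        )
        I0, tau, h = (float(v) for v in popt)
        func = lambda tt: I0 / (1.0 + (tt / tau) ** h) - I0 / 2.0
        t_half = float(brentq(func, 1e-12, 1e6 * tau))
        fitres = DecayFit("logistic", {"I0": I0, "tau": tau, "h": h}, t_half, 0.0)
    else:
        raise ValueError("model must be 'exponential' or 'logistic'")
    ssr = float(np.sum((y - fitres.evaluate(t)) ** 2))
    return DecayFit(fitres.model, fitres.params, fitres.t_half, ssr)
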