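"""1:1 Langmuir SPR kinetics: sensorgram simulation and global fitting.

The single-site bimolecular model A + B = AB gives, for constant analyte
concentration C during association,

    dR/dt = ka·C·(Rmax − R) − kd·R
    R(t)  = Req·(1 − exp(−kobs·t)),   Req = Rmax·C/(C + KD),  kobs = ka·C + kd

and exponential decay R(t) = R(t_assoc)·exp(−kd·(t − t_assoc)) during
dissociation.  KD = kd/ka.  Fitting is global: one (ka, kd, Rmax) shared
across all concentrations of a series, as in single-KD reporting from
biosensor software.  Mass-transport limitation, baseline drift and bulk
refractive-index jumps are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LangmuirParams",
    "Sensorgram",
    "FitResult",
    "PAPER_DESIGN_CONCENTRATIONS",
    "DEFAULT_T_ASSOC",
    "DEFAULT_T_DISSOC",
    "langmuir_response",
    "simulate_sensorgram",
    "fit_langmuir",
]

#: five-point concentration series of the assay design this package mirrors
PAPER_DESIGN_CONCENTRATIONS: tuple[float, ...] = (25e-9, 50e-9, 250e-9, 1e-6, 4e-6)
DEFAULT_T_ASSOC = 60.0
DEFAULT_T_DISSOC = 300.0


@dataclass(frozen=True)
class LangmuirParams:
    """Rate constants and capacity of the 1:1 model; KD = kd/ka."""

    ka: float  # M^-1 s^-1
    kd: float  # s^-1
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0 or self.rmax <= 0:
            raise ValueError("ka, kd and Rmax must all be positive")

    @property
    def kd_eq(self) -> float:
        """Equilibrium dissociation constant K_D in M."""
        return self.kd / self.ka


@dataclass(frozen=True)
class Sensorgram:
    """One response-vs-time trace at a single analyte concentration."""

    concentration: float  # M
    times: np.ndarray  # s
    responses: np.ndarray  # RU
    t_assoc: float = DEFAULT_T_ASSOC

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if t.shape != r.shape:
            raise ValueError("times/responses shape mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.concentration < 0:
            raise ValueError("negative analyte concentration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "responses", r)


@dataclass(frozen=True)
class FitResult:
    """Global-fit output: point estimates, SEs, residual norm, warnings."""

    params: LangmuirParams
    kd_eq: float
    se_ka: float
    se_kd: float
    se_rmax: float
    se_kd_eq: float
    residual_norm: float
    n_points: int
    warnings: tuple[str, ...] = ()


def langmuir_response(
    p: LangmuirParams, conc: float, times, t_assoc: float = DEFAULT_T_ASSOC
) -> np.ndarray:
    """Noise-free closed-form response at the given sample times."""
    t = np.asarray(times, dtype=float)
    if conc < 0:
        raise ValueError("negative analyte concentration")
    if conc == 0:
        return np.zeros_like(t)
    kobs = p.ka * conc + p.kd
    req = p.rmax * conc / (conc + p.kd_eq)
    r = np.where(
        t <= t_assoc,
        req * (1.0 - np.exp(-kobs * np.clip(t, 0.0, None))),
        req
        * (1.0 - np.exp(-kobs * t_assoc))
        * np.exp(-p.kd * np.maximum(t - t_assoc, 0.0)),
    )
    return r


def simulate_sensorgram(
    p: LangmuirParams,
    conc: float,
    t_assoc: float = DEFAULT_T_ASSOC,
    t_dissoc: float = DEFAULT_T_DISSOC,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Sensorgram:
    """Simulate one sensorgram, optionally with Gaussian read noise.

    ``seed`` may be an int or a Generator; noise_sd = 0 gives the exact
    closed-form curve.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_response(p, conc, times, t_assoc)
    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(concentration=conc, times=times, responses=r, t_assoc=t_assoc)


def _initial_guess(series: list[Sensorgram]) -> tuple[float, float, float]:
    """SPR fitting heuristics: kd from the dissociation tail's log-linear
    slope, ka from kobs-vs-C regression, Rmax from the largest response."""
    kd_estimates = []
    kobs_pairs = []
    r_end_max = 0.0
    for sg in series:
        diss = sg.times > sg.t_assoc
        t_d = sg.times[diss]
        r_d = sg.responses[diss]
        pos = r_d > 0
        if pos.sum() >= 3:
            slope = np.polyfit(t_d[pos], np.log(r_d[pos]), 1)[0]
            if slope < 0:
                kd_estimates.append(-slope)
        assoc = sg.times <= sg.t_assoc
        t_a = sg.times[assoc]
        r_a = sg.responses[assoc]
        r_end = r_a[-1] if len(r_a) else 0.0
        r_end_max = max(r_end_max, float(r_end))
        # crude kobs: time to reach (1 - 1/e) of the end response
        if r_end > 0:
            frac = r_a / r_end
            above = np.nonzero(frac >= 1 - 1 / np.e)[0]
            if len(above) and t_a[above[0]] > 0:
                kobs_pairs.append((sg.concentration, 1.0 / t_a[above[0]]))
    kd0 = float(np.median(kd_estimates)) if kd_estimates else 1e-3
    if len(kobs_pairs) >= 2:
        c, k = np.array(kobs_pairs).T
        ka0 = max(float(np.polyfit(c, k, 1)[0]), 1e2)
    else:
        ka0 = 1e5
    kd0 = max(kd0, 1e-6)
    # occupancy correction at the highest concentration
    c_max = max(sg.concentration for sg in series)
    occ = c_max / (c_max + kd0 / ka0)
    rmax0 = max(r_end_max / max(occ, 1e-6), 1e-3)
    return ka0, kd0, rmax0


def fit_langmuir(series) -> FitResult:
    """Global nonlinear least-squares fit of the 1:1 Langmuir model.

    All sensorgrams share one (ka, kd, Rmax); KD = kd/ka.  Optimisation is
    over log-parameters to enforce positivity.  Standard errors come from
    the Gauss-Newton covariance at the optimum; the KD SE by the delta
    method.  Emits identifiability warnings for narrow concentration
    series.
    """
    series = list(series)
    if not series:
        raise ValueError("empty sensorgram series")
    warns: list[str] = []
    concs = [sg.concentration for sg in series if sg.concentration > 0]
    if not concs:
        raise ValueError("no nonzero analyte concentrations")
    if len(concs) < 2 or max(concs) / min(concs) <= 10:
        warns.append(
            "concentration series spans ≤ 1 order of magnitude; "
            "ka and Rmax may be poorly identified"
        )
    all_r = np.concatenate([sg.responses for sg in series])
    if not np.all(np.isfinite(all_r)):
        raise ValueError("non-finite responses")
    if np.allclose(all_r, 0.0):
        raise ValueError("all responses are zero; nothing to fit")

    ka0, kd0, rmax0 = _initial_guess(series)
    x0 = np.log([ka0, kd0, rmax0])

    def residuals(x):
        p = LangmuirParams(*np.exp(x))
        return np.concatenate(
            [
                langmuir_response(p, sg.concentration, sg.times, sg.t_assoc)
                - sg.responses
                for sg in series
            ]
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(residuals, x0, method="trf", xtol=1e-12, ftol=1e-12)
    ka, kd, rmax = np.exp(sol.x)
    params = LangmuirParams(ka=ka, kd=kd, rmax=rmax)

    n = sol.fun.size
    dof = max(n - 3, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jac = sol.jac  # d residual / d log-param
    try:
        cov_log = s2 * np.linalg.inv(jac.T @ jac)
        se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        # delta method: se(p) = p * se(log p); log KD = log kd - log ka
        var_log_kdeq = (
            cov_log[1, 1] + cov_log[0, 0] - 2.0 * cov_log[0, 1]
        )
        se = (ka * se_log[0], kd * se_log[1], rmax * se_log[2])
        se_kdeq = params.kd_eq * float(np.sqrt(max(var_log_kdeq, 0.0)))
    except np.linalg.LinAlgError:
        se = (float("nan"),) * 3
        se_kdeq = float("nan")
        warns.append("singular Jacobian; standard errors unavailable")

    return FitResult(
        params=params,
        kd_eq=params.kd_eq,
        se_ka=se[0],
        se_kd=se[1],
        se_rmax=se[2],
        se_kd_eq=se_kdeq,
        residual_norm=float(np.linalg.norm(sol.fun)),
        n_points=n,
        warnings=tuple(warns),
    )
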