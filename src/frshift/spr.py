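"""Single-cycle SPR sensorgram simulation and kinetic fitting.

Single-cycle kinetics injects an increasing analyte concentration series
over an immobilized ligand without regenerating the surface between
injections, then follows a long dissociation.  Binding follows mass-action
models: the 1:1 Langmuir model

    dR/dt = ka1*C*(Rmax - R) - kd1*R,        Kd = kd1/ka1

and a two-state (conformational change) model A+B <-> AB <-> AB* with
forward/back rates ka2, kd2 for the second step and response R_AB + R_AB*;
its equilibrium dissociation constant is (kd1/ka1)*(kd2/(kd2+ka2)).

Within each constant-concentration phase both models are linear ODEs, so
trajectories are computed exactly (scalar exponential for 1:1, 2x2
eigendecomposition for two-state) and evaluated directly on the requested
time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError

#: The default single-cycle injection series (molar), low to high.
DEFAULT_CONCENTRATIONS = (7.5e-9, 22e-9, 66e-9, 200e-9, 600e-9)
DEFAULT_INJECTION_TIME = 60.0  # s
DEFAULT_DISSOCIATION_TIME = 600.0  # s

MODELS = ("langmuir_1to1", "two_state")


@dataclass(frozen=True)
class InjectionSchedule:
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    injection_time: float = DEFAULT_INJECTION_TIME
    dissociation_time: float = DEFAULT_DISSOCIATION_TIME
    flow_note: str = ""

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "concentrations", conc)
        if not conc or any(c <= 0 for c in conc):
            raise InputError("concentrations must be positive")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise InputError("single-cycle concentrations must increase")
        if self.injection_time <= 0 or self.dissociation_time <= 0:
            raise InputError("phase durations must be positive")

    def phases(self):
        """(t_start, t_end, concentration) tuples, dissociation last (C=0)."""
        out, t = [], 0.0
        for c in self.concentrations:
            out.append((t, t + self.injection_time, c))
            t += self.injection_time
        out.append((t, t + self.dissociation_time, 0.0))
        return out

    @property
    def total_time(self) -> float:
        return len(self.concentrations) * self.injection_time + self.dissociation_time


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray  # s
    response: np.ndarray  # RU
    schedule: InjectionSchedule

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.size != r.size:
            raise InputError("time and response lengths differ")
        if np.any(np.diff(t) <= 0):
            raise InputError("time must strictly increase")
        if not np.all(np.isfinite(r)):
            raise InputError("response contains non-finite values")


@dataclass(frozen=True)
class KineticModelParams:
    model: str
    ka1: float  # M^-1 s^-1
    kd1: float  # s^-1
    rmax: float  # RU
    ka2: float | None = None  # s^-1 (two-state only)
    kd2: float | None = None  # s^-1 (two-state only)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise InputError(f"unknown model {self.model!r}")
        rates = [self.ka1, self.kd1, self.rmax]
        if self.model == "two_state":
            if self.ka2 is None or self.kd2 is None:
                raise InputError("two-state model needs ka2 and kd2")
            rates += [self.ka2, self.kd2]
        if any((r is None) or (r <= 0) or not np.isfinite(r) for r in rates):
            raise InputError("all rates and rmax must be positive and finite")

    @property
    def kd_equilibrium(self) -> float:
        """Equilibrium dissociation constant (M)."""
        kd = self.kd1 / self.ka1
        if self.model == "two_state":
            kd *= self.kd2 / (self.kd2 + self.ka2)
        return kd


@dataclass(frozen=True)
class KineticFit:
    params: KineticModelParams
    kd_equilibrium: float  # M
    residual_rms: float  # RU
    converged: bool


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _response_1to1(params: KineticModelParams, schedule: InjectionSchedule, times):
    out = np.empty_like(times)
    state = 0.0
    for t0, t1, c in schedule.phases():
        b = params.ka1 * c + params.kd1
        r_inf = params.ka1 * c * params.rmax / b
        mask = (times >= t0) & (times <= t1)
        out[mask] = r_inf + (state - r_inf) * np.exp(-b * (times[mask] - t0))
        state = r_inf + (state - r_inf) * np.exp(-b * (t1 - t0))
    return out


def _response_two_state(params: KineticModelParams, schedule: InjectionSchedule, times):
    out = np.empty_like(times)
    state = np.zeros(2)  # (R_AB, R_AB*)
    for t0, t1, c in schedule.phases():
        kc = params.ka1 * c
        mat = np.array(
            [
                [-(kc + params.kd1 + params.ka2), params.kd2 - kc],
                [params.ka2, -params.kd2],
            ]
        )
        forcing = np.array([kc * params.rmax, 0.0])
        # steady state: mat @ x_ss + forcing = 0; det(mat) != 0 for kd1,kd2 > 0
        x_ss = np.linalg.solve(mat, -forcing)
        eigvals, eigvecs = np.linalg.eig(mat.astype(complex))
        coeff = np.linalg.solve(eigvecs, (state - x_ss).astype(complex))
        mask = (times >= t0) & (times <= t1)
        trel = times[mask] - t0

        def propagate(t):
            decay = np.exp(eigvals[:, None] * np.atleast_1d(t)[None, :])  # (2, nt)
            return x_ss + (eigvecs @ (coeff[:, None] * decay)).T.real

        traj = propagate(trel)
        out[mask] = traj.sum(axis=1)
        state = propagate(np.array([t1 - t0]))[0]
    return out


def model_response(params: KineticModelParams, schedule: InjectionSchedule, times):
    """Noise-free model response on an arbitrary time grid."""
    times = np.asarray(times, dtype=float)
    if params.model == "langmuir_1to1":
        return _response_1to1(params, schedule, times)
    return _response_two_state(params, schedule, times)


def simulate_sensorgram(
    params: KineticModelParams,
    schedule: InjectionSchedule = InjectionSchedule(),
    dt: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sensorgram:
    """Simulate a single-cycle sensorgram sampled every ``dt`` seconds."""
    if dt <= 0 or dt > 0.1:
        raise InputError("dt must be in (0, 0.1] s")
    times = np.arange(0.0, schedule.total_time + dt / 2, dt)
    response = model_response(params, schedule, times)
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=response.size)
    return Sensorgram(times, response, schedule)


def subtract_baseline(gram: Sensorgram, intercept: float, drift: float = 0.0) -> Sensorgram:
    """Remove a constant-plus-drift baseline (reference/blank subtraction)."""
    return replace(gram, response=gram.response - (intercept + drift * gram.time))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_BOUNDS = {
    "ka1": (1e2, 1e9),
    "kd1": (1e-6, 1.0),
    "rmax": (1e-2, 1e5),
    "ka2": (1e-6, 1.0),
    "kd2": (1e-6, 1.0),
}


def _heuristic_guess(data: Sensorgram, model: str) -> KineticModelParams:
    """Initial parameters from plateau height and dissociation decay."""
    rmax = max(1.2 * float(np.max(data.response)), 1.0)
    # decay rate from the dissociation tail (log-linear fit where R > 0)
    t0 = data.schedule.phases()[-1][0]
    mask = data.time >= t0
    t_tail, r_tail = data.time[mask], data.response[mask]
    kd1 = 1e-2
    pos = r_tail > max(1e-3, 0.02 * rmax)
    if pos.sum() > 10:
        slope = np.polyfit(t_tail[pos], np.log(r_tail[pos]), 1)[0]
        if slope < 0:
            kd1 = float(np.clip(-slope, *_BOUNDS["kd1"]))
    # ka from assuming the top injection approaches half-saturation
    c_top = data.schedule.concentrations[-1]
    ka1 = float(np.clip(kd1 / c_top, *_BOUNDS["ka1"]))
    if model == "langmuir_1to1":
        return KineticModelParams("langmuir_1to1", ka1, kd1, rmax)
    return KineticModelParams("two_state", ka1, kd1, rmax, ka2=1e-3, kd2=1e-2)


def _pack(params: KineticModelParams):
    names = ["ka1", "kd1", "rmax"]
    if params.model == "two_state":
        names += ["ka2", "kd2"]
    return names, np.log10([getattr(params, n) for n in names])


def _unpack(model: str, names, x) -> KineticModelParams:
    values = dict(zip(names, 10.0 ** np.asarray(x)))
    return KineticModelParams(model, **values)


def fit_kinetics(
    data: Sensorgram,
    model: str = "langmuir_1to1",
    initial_guess: KineticModelParams | None = None,
    max_points: int = 2000,
) -> KineticFit:
    """Least-squares kinetic fit of a single-cycle sensorgram.

    Parameters are optimized in log space within broad physical bounds.
    Non-convergence (including signal-free data) is reported through the
    ``converged`` flag, never as an exception.
    """
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}")
    if len(data.schedule.concentrations) < 2:
        raise InputError("fit needs at least two injection phases")
    guess = initial_guess or _heuristic_guess(data, model)
    if guess.model != model:
        raise InputError("initial guess model does not match requested model")

    # thin very dense traces to keep the optimization cheap
    stride = max(1, data.time.size // max_points)
    t_fit, r_fit = data.time[::stride], data.response[::stride]

    amplitude = float(np.max(r_fit) - np.min(r_fit))
    if amplitude < 1e-6:
        return KineticFit(guess, guess.kd_equilibrium, float(np.std(r_fit)), False)

    names, x0 = _pack(guess)
    lower = np.log10([_BOUNDS[n][0] for n in names])
    upper = np.log10([_BOUNDS[n][1] for n in names])
    x0 = np.clip(x0, lower, upper)

    def residuals(x):
        p = _unpack(model, names, x)
        return model_response(p, data.schedule, t_fit) - r_fit

    try:
        result = least_squares(
            residuals, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12
        )
        params = _unpack(model, names, result.x)
        rms = float(np.sqrt(np.mean(result.fun**2)))
        converged = bool(result.success) and np.isfinite(result.cost)
    except Exception:
        params, rms, converged = guess, float("nan"), False
    return KineticFit(params, params.kd_equilibrium, rms, converged)


# ---------------------------------------------------------------------------
# CSV / sidecar-config I/O
# ---------------------------------------------------------------------------


def write_sensorgram_csv(gram: Sensorgram, path) -> None:
    body = np.column_stack([gram.time, gram.response])
    np.savetxt(path, body, delimiter=",", header="time_s,response_RU", comments="", fmt="%.6g")


def read_sensorgram_csv(path, schedule: InjectionSchedule) -> Sensorgram:
    raw = np.loadtxt(path, delimiter=",", skiprows=1)
    return Sensorgram(raw[:, 0], raw[:, 1], schedule)


def write_schedule_config(schedule: InjectionSchedule, path) -> None:
    lines = [
        "concentrations_nM = " + ",".join(f"{c * 1e9:g}" for c in schedule.concentrations),
        f"injection_time_s = {schedule.injection_time:g}",
        f"dissociation_time_s = {schedule.dissociation_time:g}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_schedule_config(path) -> InjectionSchedule:
    values = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    try:
        conc = tuple(float(c) * 1e-9 for c in values["concentrations_nM"].split(","))
        return InjectionSchedule(
            concentrations=conc,
            injection_time=float(values["injection_time_s"]),
            dissociation_time=float(values["dissociation_time_s"]),
        )
    except KeyError as exc:
        raise InputError(f"schedule config missing key {exc}") from exc
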