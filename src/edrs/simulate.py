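"""Forward simulation of spontaneous breathing under PS and NAVA.

The generative model is the single-compartment equation of motion with a
patient-effort pressure source:

    R_rs * Q(t) + (E_lung + E_chest) * V(t) + P_mus(t) = P_aw(t) - PEEP

where the muscular pressure P_mus(t) is non-positive (effort lowers pleural
pressure) and is realised as a half-sine over the neural inspiratory time.
The demand-elastance ground truth follows as E_demand(t) = P_mus(t)/V(t) and
the analytic lumped elastance as

    E_drs(t) = E_lung + E_chest + P_mus(t)/V(t),

so any estimator fed the emitted pressure/flow waveforms can be checked
against an exact generating truth.

Controllers
-----------
* **PS** — square pressure support: once the patient's effort drives flow
  through the trigger threshold (or immediately, machine-triggered, for a
  passive patient) the ventilator raises pressure toward PEEP + ps_level
  with a short exponential rise, holds it for a fixed machine inspiratory
  time, then releases exponentially.
* **NAVA** — proportional assist: pressure tracks the diaphragm activity,
  ``paw = PEEP + nava_gain * Eadi(t)`` with Eadi proportional to the neural
  drive, so delivery follows the effort's half-sine profile and inherits its
  breath-to-breath variability.

Breath-to-breath variability has three physiological sources, all lognormal:
neural effort amplitude (``pmus_amplitude_cv``), neural inspiratory time
(``t_neural_cv``) and neuromechanical coupling — the ratio of mechanical to
neural amplitude (``coupling_cv``).  Under PS the steady, identical support
entrains the patient and damps all three (``ps_entrainment`` multiplies the
CVs); NAVA transmits the natural drive variability into the delivered
pressure.  This reproduces the clinically observed contrast: wider
breath-to-breath elastance bands under NAVA than under PS.

The state is advanced with an implicit trapezoidal update on the emitted
sampling grid, the same quadrature rule a downstream estimator applies when
re-integrating the emitted flow.  The generative identity
``(paw - PEEP - R*Q)/V = E_drs(t)`` therefore holds exactly (to float
rounding) at every emitted sample.  Setting ``n_substeps > 1`` integrates
on a finer internal grid instead, which makes the truth a near-continuous
reference so that an estimator's quadrature error can be shown to shrink
with the sampling interval.  Gaussian measurement noise is added to the
emitted pressure/flow only; the ground truth stays noise free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, SimulationError
from .io import WaveformRecord

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of one simulated session.

    The defaults describe a partially assisted adult ICU patient: moderately
    stiff respiratory system (E_lung + E_chest = 30 cmH2O/L), airway
    resistance 5 cmH2O*s/L, PEEP 5 cmH2O, pressure support 10 cmH2O above
    PEEP (NAVA gain matched so the mean breath peaks at the same support),
    effort of 6 cmH2O peak over a 0.8 s neural inspiration at 15 breaths/min.
    The seed fully determines the output.
    """

    e_lung: float = 25.0            # cmH2O/L
    e_chest: float = 5.0            # cmH2O/L
    rrs_true: float = 5.0           # cmH2O*s/L
    peep: float = 5.0               # cmH2O
    mode: str = "PS"                # "PS" | "NAVA"
    ps_level: float = 10.0          # cmH2O above PEEP
    nava_gain: float | None = None  # cmH2O/uV; None = matched to ps_level
    pmus_amplitude_mean: float = 6.0  # cmH2O (peak effort)
    pmus_amplitude_cv: float = 0.25   # breath-to-breath lognormal CV
    t_neural: float = 0.8           # s (neural inspiratory time)
    resp_rate: float = 15.0         # breaths/min
    n_breaths: int = 30
    dt: float = 0.01                # s (emitted sampling interval)
    noise_sd_paw: float = 0.15      # cmH2O
    noise_sd_flow: float = 0.01     # L/s
    seed: int = 0
    # second-order physiology / controller detail
    t_neural_cv: float = 0.12       # lognormal CV of neural timing
    coupling_cv: float = 0.2        # lognormal CV of neuromechanical coupling
    ps_entrainment: float = 0.5     # CV damping factor under PS
    eadi_scale: float = 2.0         # uV per cmH2O of neural drive
    trigger_flow: float = 0.05      # L/s, PS flow trigger
    ps_rise_time: float = 0.08      # s, support pressurisation time constant
    ps_release_time: float = 0.06   # s, support release time constant
    pre_roll: float = 1.0           # s of baseline before the first breath
    n_substeps: int = 1             # internal substeps per emitted sample;
                                    # 1 = quadrature-matched to the estimator,
                                    # >1 = near-continuous reference solution

    @property
    def e_passive(self) -> float:
        """Passive respiratory-system elastance E_lung + E_chest."""
        return self.e_lung + self.e_chest

    @property
    def period(self) -> float:
        """Breath period, seconds."""
        return 60.0 / self.resp_rate

    def validate(self) -> "SimConfig":
        if min(self.e_lung, self.e_chest, self.rrs_true, self.dt) <= 0:
            raise ParameterError("e_lung, e_chest, rrs_true and dt must be positive")
        if self.pmus_amplitude_mean < 0:
            raise ParameterError("pmus_amplitude_mean must be non-negative")
        if self.n_breaths < 1:
            raise ParameterError("n_breaths must be at least 1")
        if self.mode not in ("PS", "NAVA"):
            raise ParameterError(f"mode must be PS or NAVA, got {self.mode!r}")
        if self.t_neural <= 0 or self.t_neural >= self.period:
            raise ParameterError("t_neural must be positive and below the breath period")
        if self.resp_rate <= 0:
            raise ParameterError("resp_rate must be positive")
        if self.n_substeps < 1:
            raise ParameterError("n_substeps must be at least 1")
        if self.pre_roll <= 0:
            raise ParameterError("pre_roll must be positive")
        return self


@dataclass
class SyntheticTruth:
    """Noise-free generating state of one simulated session.

    Arrays are per emitted sample.  ``edrs_true`` is the analytic lumped
    elastance ``e_passive + p_mus/volume`` (NaN where the volume is too
    small for the ratio to be meaningful) and ``e_demand_true`` its
    non-positive demand component.
    """

    time: np.ndarray
    p_mus: np.ndarray
    volume: np.ndarray
    flow: np.ndarray
    paw: np.ndarray
    eadi: np.ndarray
    edrs_true: np.ndarray
    e_demand_true: np.ndarray
    trigger_times: np.ndarray          # effort onsets, s
    ps_trigger_delays: np.ndarray      # support delay after effort onset (PS)
    amplitudes: np.ndarray             # mechanical effort amplitudes, cmH2O
    neural_amplitudes: np.ndarray      # neural drive amplitudes, cmH2O
    t_neural_per_breath: np.ndarray    # s
    e_passive: float
    config: SimConfig = field(repr=False)


def pmus_profile(t, amplitude: float, t_neural: float):
    """Half-sine muscular pressure: -amplitude*sin(pi*t/t_neural) on
    [0, t_neural], zero outside.  Non-positive everywhere."""
    if amplitude < 0:
        raise ParameterError("amplitude must be non-negative")
    if t_neural <= 0:
        raise ParameterError("t_neural must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(
        (t >= 0.0) & (t <= t_neural),
        -amplitude * np.sin(np.pi * np.clip(t, 0.0, t_neural) / t_neural),
        0.0,
    )
    return out if out.ndim else float(out)


@njit(cache=False)
def _session_kernel(
    paw_d, q, v, pm,            # output arrays, length n_out (paw_d = paw - peep)
    trig_t,                     # per-breath support trigger time (s after onset); NaN = untriggered
    dt, nsub, pre_roll, period, n_breaths,
    tn, a_m, supp,              # per-breath: neural time, mech amplitude, NAVA peak support
    t_mach, mode_ps,
    e_total, rrs, ps_level, q_trig, tau_rise, tau_rel,
):
    n_out = paw_d.shape[0]
    h = dt / nsub
    a = h * e_total / (2.0 * rrs)
    V = 0.0
    F1 = 0.0
    p1 = 0.0
    m1 = 0.0
    nsteps = (n_out - 1) * nsub
    for k in range(nsteps):
        F0 = F1
        t1 = (k + 1) * h
        tb = t1 - pre_roll
        b = -1
        tau = 0.0
        if tb >= 0.0:
            b = int(tb // period)
            if b >= n_breaths:
                b = -1
            else:
                tau = tb - b * period
        p1 = 0.0
        m1 = 0.0
        if b >= 0:
            if tau < tn[b]:
                s_eff = math.sin(math.pi * tau / tn[b])
                m1 = -a_m[b] * s_eff
            else:
                s_eff = 0.0
            if mode_ps:
                tt = trig_t[b]
                if tt == tt:  # triggered
                    s = tau - tt
                    if s >= 0.0:
                        if s < t_mach:
                            p1 = ps_level * (1.0 - math.exp(-s / tau_rise))
                        else:
                            p_end = ps_level * (1.0 - math.exp(-t_mach / tau_rise))
                            p1 = p_end * math.exp(-(s - t_mach) / tau_rel)
            else:
                if tau < tn[b]:
                    p1 = supp[b] * s_eff
        F1 = p1 - m1
        V = (V * (1.0 - a) + (h / (2.0 * rrs)) * (F0 + F1)) / (1.0 + a)
        if V < -1e-6:
            return k
        Q1 = (p1 - e_total * V - m1) / rrs
        if mode_ps and b >= 0 and trig_t[b] != trig_t[b]:
            if Q1 >= q_trig and tau < tn[b]:
                trig_t[b] = tau
        if (k + 1) % nsub == 0:
            i = (k + 1) // nsub
            paw_d[i] = p1
            q[i] = Q1
            v[i] = V
            pm[i] = m1
    return -1


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean lognormal multipliers with the given coefficient of variation."""
    z = rng.standard_normal(n)
    if cv <= 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def simulate_session(config: SimConfig) -> tuple[WaveformRecord, SyntheticTruth]:
    """Simulate one session; return noisy waveforms plus noise-free truth.

    Output is bit-reproducible for a given config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_b = config.n_breaths
    period = config.period
    mode_ps = config.mode == "PS"

    damp = config.ps_entrainment if mode_ps else 1.0
    amp_n = config.pmus_amplitude_mean * _lognormal_factors(
        rng, n_b, config.pmus_amplitude_cv * damp
    )
    tn = config.t_neural * _lognormal_factors(rng, n_b, config.t_neural_cv * damp)
    tn = np.minimum(tn, 0.9 * period)  # never let effort outlast the cycle
    coupling = _lognormal_factors(rng, n_b, config.coupling_cv * damp)
    amp_m = amp_n * coupling

    if config.nava_gain is None:
        if config.eadi_scale * config.pmus_amplitude_mean > 0:
            gain = config.ps_level / (config.eadi_scale * config.pmus_amplitude_mean)
        else:
            gain = 0.0
    else:
        gain = config.nava_gain
    supp = gain * config.eadi_scale * amp_n  # NAVA peak pressure above PEEP

    duration = config.pre_roll + n_b * period
    n_out = int(round(duration / config.dt)) + 1
    paw_d = np.zeros(n_out)
    flow = np.zeros(n_out)
    volume = np.zeros(n_out)
    p_mus = np.zeros(n_out)
    trig_t = np.full(n_b, np.nan)
    trig_t[amp_m <= 1e-12] = 0.0  # passive breaths are machine-triggered

    status = _session_kernel(
        paw_d, flow, volume, p_mus, trig_t,
        float(config.dt), int(config.n_substeps), float(config.pre_roll),
        float(period), int(n_b),
        tn, amp_m, supp,
        float(config.t_neural), mode_ps,
        float(config.e_passive), float(config.rrs_true), float(config.ps_level),
        float(config.trigger_flow), float(config.ps_rise_time),
        float(config.ps_release_time),
    )
    if status >= 0:
        raise SimulationError(
            f"negative volume at internal step {status} "
            f"(t = {status * config.dt / config.n_substeps:.4f} s): "
            "non-physical configuration"
        )

    time = np.arange(n_out) * config.dt
    paw = config.peep + paw_d

    # Eadi channel: proportional to the *neural* drive.
    tb = time - config.pre_roll
    b_idx = np.clip(np.floor_divide(tb, period).astype(int), 0, n_b - 1)
    tau = tb - b_idx * period
    in_effort = (tb >= 0.0) & (tau < tn[b_idx])
    eadi = np.zeros(n_out)
    eadi[in_effort] = (
        config.eadi_scale
        * amp_n[b_idx[in_effort]]
        * np.sin(np.pi * tau[in_effort] / tn[b_idx[in_effort]])
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        demand = np.where(volume > 1e-9, p_mus / volume, np.nan)
    edrs_true = config.e_passive + demand

    paw_noisy = paw + rng.normal(0.0, config.noise_sd_paw, n_out) \
        if config.noise_sd_paw > 0 else paw.copy()
    flow_noisy = flow + rng.normal(0.0, config.noise_sd_flow, n_out) \
        if config.noise_sd_flow > 0 else flow.copy()

    record = WaveformRecord(
        patient_id="synthetic",
        mode=config.mode,
        sample_interval=config.dt,
        time=time,
        paw=paw_noisy,
        flow=flow_noisy,
        eadi=eadi,
    ).validate()
    truth = SyntheticTruth(
        time=time,
        p_mus=p_mus,
        volume=volume,
        flow=flow,
        paw=paw,
        eadi=eadi,
        edrs_true=edrs_true,
        e_demand_true=demand,
        trigger_times=config.pre_roll + np.arange(n_b) * period,
        ps_trigger_delays=trig_t,
        amplitudes=amp_m,
        neural_amplitudes=amp_n,
        t_neural_per_breath=tn,
        e_passive=config.e_passive,
        config=config,
    )
    return record, truth


def paired_mode_sessions(
    base: SimConfig, seed_ps: int | None = None, seed_nava: int | None = None
):
    """Simulate the same synthetic patient under PS and then NAVA.

    Patient parameters are shared; only the controller changes (and the
    seeds, mirroring two separate recording periods).
    """
    seed_ps = base.seed if seed_ps is None else seed_ps
    seed_nava = base.seed + 1 if seed_nava is None else seed_nava
    ps = simulate_session(replace(base, mode="PS", seed=seed_ps))
    nava = simulate_session(replace(base, mode="NAVA", seed=seed_nava))
    return ps, nava
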