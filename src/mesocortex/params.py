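"""Neuron, synapse, delay and drive parameters of the spiking model.

Defaults are the model's standard parameterization: leaky integrate-and-fire
neurons with exponential postsynaptic currents, human-derived membrane
parameters (C_m = 220 pF excitatory / 100 pF inhibitory, threshold 25 mV
above rest, tau_m lowered to 10 ms for the in vivo high-conductance state),
0.1 mV mean postsynaptic potentials with relative SD 10%, inhibition g = 5
times stronger, log-normal delays with 50% relative SD, and an external
Poisson drive whose mean input is fixed relative to rheobase.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "NeuronParams",
    "SynapseModelParams",
    "DelayParams",
    "ExternalDriveParams",
    "psp_to_psc",
    "external_poisson_rate",
    "exponential_psc_eta_factor",
]


@dataclasses.dataclass
class NeuronParams:
    tau_m: float = 10.0  # ms
    c_m_exc: float = 220.0  # pF
    c_m_inh: float = 100.0  # pF
    v_th: float = -45.0  # mV
    e_l: float = -70.0  # mV (= reset potential)
    tau_r: float = 2.0  # ms, absolute refractory period
    tau_s: float = 2.0  # ms, synaptic current time constant
    #: optional coefficients of variation for log-normally distributed
    #: parameters, keys like "v_th", "c_m_exc", "tau_m_exc"; empty = fixed
    cv_table: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.tau_m, self.c_m_exc, self.c_m_inh, self.tau_s, self.tau_r) <= 0:
            raise ValueError("time constants and capacitances must be positive")
        if self.v_th <= self.e_l:
            raise ValueError("threshold must lie above the leak potential")

    def c_m(self, is_exc: bool) -> float:
        return self.c_m_exc if is_exc else self.c_m_inh

    @property
    def v_reset(self) -> float:
        return self.e_l


@dataclasses.dataclass
class SynapseModelParams:
    psp_mean: float = 0.1  # mV
    psp_rel_sd: float = 0.1
    g: float = 5.0  # relative inhibitory strength
    l4e_to_l23e_factor: float = 2.0  # within-area 4E -> 2/3E weight boost
    chi: float = 1.0  # inter-areal scaling (1 = base, 2.5 = best-fitting)
    chi_i: float = 2.0  # additional inter-areal scaling onto inhibitory targets
    ext_scale_5e: float = 1.05  # external-drive weight scaling, layer 5E
    ext_scale_6e: float = 1.15  # external-drive weight scaling, layer 6E

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if any(v <= 0 for v in vals.values()):
            raise ValueError("synapse parameters must be positive")


@dataclasses.dataclass
class DelayParams:
    d_e: float = 1.5  # ms, local delay of excitatory-source connections
    d_i: float = 0.75  # ms, local delay of inhibitory-source connections
    rel_sd: float = 0.5  # relative SD of the truncated log-normal
    v_t: float = 3.5  # m/s, inter-areal conduction velocity (mm/ms)
    dt: float = 0.1  # ms, simulation step

    def __post_init__(self) -> None:
        if min(self.d_e, self.d_i, self.v_t, self.dt) <= 0:
            raise ValueError("delay parameters must be positive")


@dataclasses.dataclass
class ExternalDriveParams:
    eta_ext: float = 1.1  # mean input relative to rheobase
    w_ext: float = 0.1  # mV, mean external PSP
    #: If True, the Poisson rate is rescaled so that the true mean current of
    #: the exponential postsynaptic currents equals eta x rheobase. The
    #: printed rate formula treats each PSP as an instantaneous w*tau_m
    #: voltage kick, which for exponential currents overshoots the intended
    #: mean by the factor eps^(-eps/(1-eps)), eps = tau_s/tau_m (about 1.50
    #: for the default time constants).
    strict_eta: bool = False


def psp_to_psc(psp: float, c_m: float, tau_m: float, tau_s: float) -> float:
    """Convert a postsynaptic-potential amplitude (mV) to a current (pA).

    PSC = PSP * (C_m / tau_m) * eps^(-1/(1-eps)) with eps = tau_s/tau_m;
    the returned amplitude produces a PSP whose peak equals ``psp`` under the
    exponential-current LIF subthreshold dynamics.
    """
    if tau_m <= 0 or tau_s <= 0 or c_m <= 0:
        raise ValueError("time constants and capacitance must be positive")
    if tau_s == tau_m:
        raise ValueError("conversion factor is singular for tau_s == tau_m")
    eps = tau_s / tau_m
    return psp * (c_m / tau_m) * eps ** (-1.0 / (1.0 - eps))


def exponential_psc_eta_factor(tau_m: float, tau_s: float) -> float:
    """Overshoot factor of the printed drive formula for exponential PSCs."""
    eps = tau_s / tau_m
    return eps ** (-eps / (1.0 - eps))


def external_poisson_rate(
    drive: ExternalDriveParams,
    neuron: NeuronParams,
    k_ext: float,
) -> float:
    """Rate (spikes/s) of each of the ``k_ext`` external Poisson sources.

    nu = (V_th - E_L) * eta / (tau_m * w_ext * K); by construction
    nu * K * w_ext * tau_m = eta * (V_th - E_L) for any K, i.e. the summed
    drive is fixed relative to the threshold distance (rheobase). In strict
    mode the rate is divided by the exponential-PSC overshoot factor so the
    realized mean current equals eta x rheobase exactly.
    """
    if k_ext <= 0:
        raise ValueError("k_ext must be positive")
    nu_per_ms = (
        (neuron.v_th - neuron.e_l)
        * drive.eta_ext
        / (neuron.tau_m * drive.w_ext * k_ext)
    )
    nu = nu_per_ms * 1e3  # 1/ms -> spikes/s
    if drive.strict_eta:
        nu /= exponential_psc_eta_factor(neuron.tau_m, neuron.tau_s)
    return float(nu)


def draw_weights(
    n: int,
    mean_pa: float,
    rel_sd: float,
    sign: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` synaptic weights from a sign-truncated normal distribution.

    Normal(mean, rel_sd * |mean|); draws with the wrong sign are redrawn
    (not clipped), so the sample mean stays close to the nominal mean.
    ``sign`` is +1 for excitatory and -1 for inhibitory sources; ``mean_pa``
    carries the sign already and must agree with ``sign``.
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be nonnegative")
    if sign not in (-1, 1) or sign * mean_pa < 0:
        raise ValueError("sign must be +-1 and agree with the mean")
    out = rng.normal(mean_pa, rel_sd * abs(mean_pa), size=n)
    if rel_sd > 0:
        bad = (sign * out) <= 0
        while bad.any():
            out[bad] = rng.normal(mean_pa, rel_sd * abs(mean_pa), size=int(bad.sum()))
            bad = (sign * out) <= 0
    return out


def draw_delays(
    n: int,
    mean_ms: float,
    rel_sd: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` transmission delays in integer simulation steps.

    Truncated log-normal with mean ``mean_ms`` and SD ``rel_sd * mean_ms``;
    draws below ``dt`` are redrawn before rounding to the nearest step, so
    every delay is at least one step.
    """
    if mean_ms <= 0:
        raise ValueError("mean delay must be positive")
    if rel_sd == 0:
        return np.full(n, max(1, int(round(mean_ms / dt))), dtype=np.int32)
    sigma2 = np.log1p(rel_sd**2)
    mu = np.log(mean_ms) - 0.5 * sigma2
    sigma = np.sqrt(sigma2)
    out = rng.lognormal(mu, sigma, size=n)
    bad = out < dt
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = out < dt
    return np.maximum(np.round(out / dt), 1).astype(np.int32)
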