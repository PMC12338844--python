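"""E. coli chemotaxis models I-III: ground-truth tumbling-fraction generators.

All three models share the Monod-Wyman-Changeux (MWC) receptor-cluster
description.  The cluster activity is logistic in the total free energy,

    A(m, s) = 1 / (1 + exp(N_r F_A(m, s))),
    F_A(m, s) = alpha (m0 - m) + ln(1 + s / K_I) - ln(1 + s / K_A),

with methylation level m, ligand concentration s (uM), receptor cooperativity
N_r, and dissociation constants K_I < K_A of the inactive/active conformations.
Methylation adapts slowly via CheR/CheB kinetics,

    dm/dt = k_R (1 - A) - k_B A,

so the adapted activity A* = k_R / (k_R + k_B) is independent of s (perfect
adaptation).  Downstream, CheY-P follows the kinase activity,

    dY_p/dt = k_a A(m, s) - Y_p / tau_Z,

with relaxation time tau_Z = 0.5 s, and the motor maps CheY-P to a tumbling
fraction through a Hill function.

* Model I   (one slow variable):   CheY-P slaved to its quasi-steady state
  Y_qss = k_a tau_Z A;  f = F_I(m, s) = Hill(Y_qss(m, s)).
* Model II  (slow m, fast Y_p):    f = F_II(Y_p) = Hill(Y_p).
* Model III (two comparable-speed variables): FliM motor-ring remodeling
  tracks CheY-P with timescale tau_M similar to methylation, producing the
  characteristic overshoot during adaptation;
  f = F_III(m, FliM, s) = Hill(Y_qss(m, s) * FliM / FliM0).

The module also evaluates the analytic stimulus-gradient threshold

    S_g = Dn / max_{s,m} | (dH2/dn |_{n_ss})^{-1}  d n_ss / d s |

below which the fast variable of Model II stays within Dn of its
quasi-steady state and a single-internal-variable description suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from runtumble.preprocess import TimeSeriesRecord
from runtumble.stimuli import SignalTrace

__all__ = [
    "EcoliParams",
    "free_energy",
    "receptor_activity",
    "yp_qss",
    "dnss_ds",
    "model_rhs",
    "output_map",
    "steady_state",
    "simulate",
    "analytic_Sg",
]

_MODEL_IDS = ("I", "II", "III")


@dataclass(frozen=True)
class EcoliParams:
    """Parameters shared by chemotaxis Models I-III.

    Receptor constants follow the standard MWC description for Tar/MeAsp
    (N_r = 6, alpha = 1.7, K_I = 18.2 uM, K_A = 3000 uM); methylation rates
    are equal so the adapted activity is 1/2 and the adapted methylation level
    for s in [0, 2] uM spans [1, 1.07].  The CheY-P production scale ``k_a``
    is calibrated so the analytic gradient threshold S_g(Dn = 0.1) over that
    reference box is 0.59 uM/s.
    """

    model_id: str = "II"
    N_r: float = 6.0          # receptor cluster size (dimensionless)
    alpha: float = 1.7        # free energy per methyl group (kT)
    m0: float = 1.0           # reference methylation level
    K_I: float = 18.2         # uM, inactive-state dissociation constant
    K_A: float = 3000.0       # uM, active-state dissociation constant
    k_R: float = 0.01         # 1/s, methylation rate (CheR)
    k_B: float = 0.01         # 1/s, demethylation rate (CheB)
    k_a: float = 8.3          # uM/s, CheY-P production scale
    tau_Z: float = 0.5        # s, CheY-P relaxation timescale (Model II)
    K_Y: float = 2.93         # uM, motor Hill constant
    hill_n: float = 4.0       # motor Hill coefficient
    fliM0: float = 30.0       # FliM subunits at steady state (Model III)
    kappa: float = 40.0       # FliM subunits per uM CheY-P deviation
    tau_M: float = 8.0        # s, FliM remodeling timescale (Model III)
    m_range: tuple[float, float] = (1.0, 1.07)
    s_range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_IDS:
            raise ValueError(f"model_id must be one of {_MODEL_IDS}")
        if not self.K_I < self.K_A:
            raise ValueError("requires K_I < K_A")
        for name in ("N_r", "alpha", "K_I", "K_A", "k_R", "k_B", "k_a",
                     "tau_Z", "K_Y", "hill_n", "fliM0", "tau_M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def activity_star(self) -> float:
        """Adapted receptor activity, independent of s."""
        return self.k_R / (self.k_R + self.k_B)

    @property
    def yp_star(self) -> float:
        """Adapted CheY-P level."""
        return self.k_a * self.tau_Z * self.activity_star


def free_energy(m, s, params: EcoliParams):
    """Total free energy F_A(m, s) per receptor (units of kT)."""
    s = np.asarray(s, float)
    if np.any(s < 0):
        raise ValueError("stimulus concentration must be non-negative")
    return (
        params.alpha * (params.m0 - np.asarray(m, float))
        + np.log1p(s / params.K_I)
        - np.log1p(s / params.K_A)
    )


def receptor_activity(m, s, params: EcoliParams):
    """MWC activity A(m, s) = 1 / (1 + exp(N_r F_A)); strictly in (0, 1)."""
    return expit(-params.N_r * free_energy(m, s, params))


def yp_qss(m, s, params: EcoliParams):
    """Quasi-steady CheY-P level n_ss(m, s) = k_a tau_Z A(m, s)."""
    return params.k_a * params.tau_Z * receptor_activity(m, s, params)


def dnss_ds(m, s, params: EcoliParams):
    """Analytic d n_ss / d s.

    With A logistic in N_r F_A, dA/ds = -N_r A (1 - A) dF_A/ds and
    dF_A/ds = 1/(K_I + s) - 1/(K_A + s).
    """
    a = receptor_activity(m, s, params)
    dfa = 1.0 / (params.K_I + np.asarray(s, float)) - 1.0 / (params.K_A + np.asarray(s, float))
    return -params.k_a * params.tau_Z * params.N_r * a * (1.0 - a) * dfa


def _hill(y, params: EcoliParams):
    y = np.maximum(np.asarray(y, float), 0.0)
    return y**params.hill_n / (y**params.hill_n + params.K_Y**params.hill_n)


def _fliM_target(m, s, params: EcoliParams):
    """FliM remodeling set point; decreases when CheY-P rises above baseline."""
    return np.maximum(params.fliM0 + params.kappa * (params.yp_star - yp_qss(m, s, params)), 0.0)


def _activity_scalar(m: float, s: float, params: EcoliParams) -> float:
    x = params.N_r * (
        params.alpha * (params.m0 - m) + math.log1p(s / params.K_I) - math.log1p(s / params.K_A)
    )
    if x > 500.0:
        return math.exp(-x)
    return 1.0 / (1.0 + math.exp(x))


def model_rhs(model_id: str, state: tuple, s: float, params: EcoliParams) -> tuple:
    """Time derivatives of the internal state for the given model."""
    a = _activity_scalar(float(state[0]), float(s), params)
    dm = params.k_R * (1.0 - a) - params.k_B * a
    if model_id == "I":
        if len(state) != 1:
            raise ValueError("Model I state is (m,)")
        return (float(dm),)
    if len(state) != 2:
        raise ValueError(f"Model {model_id} state is (m, n)")
    m, n = state
    if model_id == "II":
        dn = params.k_a * a - n / params.tau_Z
        return (float(dm), float(dn))
    if model_id == "III":
        target = max(params.fliM0 + params.kappa * (params.yp_star - params.k_a * params.tau_Z * a), 0.0)
        dn = (target - n) / params.tau_M
        return (float(dm), float(dn))
    raise ValueError(f"unknown model_id {model_id!r}")


def output_map(model_id: str, state: tuple, s: float, params: EcoliParams):
    """Tumbling fraction f in [0, 1] for the given internal state."""
    if model_id == "I":
        (m,) = state
        return _hill(yp_qss(m, s, params), params)
    m, n = state
    if model_id == "II":
        return _hill(n, params)
    if model_id == "III":
        return _hill(yp_qss(m, s, params) * n / params.fliM0, params)
    raise ValueError(f"unknown model_id {model_id!r}")


def steady_state(model_id: str, s: float, params: EcoliParams) -> tuple:
    """Exact fixed point of the internal dynamics at constant stimulus s.

    The methylation equation is linear in A, so the adapted activity is
    A* = k_R / (k_R + k_B) and m* follows in closed form from F_A(m*, s) = F*
    with F* = ln(1/A* - 1) / N_r.
    """
    a_star = params.activity_star
    f_star = math.log(1.0 / a_star - 1.0) / params.N_r
    fl = math.log1p(s / params.K_I) - math.log1p(s / params.K_A)
    m_star = params.m0 + (fl - f_star) / params.alpha
    if model_id == "I":
        return (m_star,)
    if model_id == "II":
        return (m_star, params.yp_star)
    if model_id == "III":
        return (m_star, params.fliM0)
    raise ValueError(f"unknown model_id {model_id!r}")


def simulate(
    model_id: str,
    trace: SignalTrace,
    params: EcoliParams | None = None,
    dt_sim: float = 0.01,
    record_dt: float | None = None,
) -> TimeSeriesRecord:
    """Forward-Euler simulation of a chemotaxis model along a stimulus trace.

    The state starts at the exact steady state of s(t_min); the solver steps
    at ``dt_sim`` and records (t, s, f) on the trace grid (``record_dt``
    defaults to the trace spacing and must be an integer multiple of
    ``dt_sim``).  The recorded response is noiseless.
    """
    params = params or EcoliParams(model_id=model_id)
    record_dt = trace.dt if record_dt is None else record_dt
    n_sub = int(round(record_dt / dt_sim))
    if n_sub < 1 or abs(n_sub * dt_sim - record_dt) > 1e-9 * record_dt:
        raise ValueError("record_dt must be an integer multiple of dt_sim")
    if model_id == "II" and dt_sim >= params.tau_Z:
        raise ValueError("dt_sim must be < tau_Z for Model II stability")

    t_grid = trace.t
    n_rec = len(t_grid)
    # Stimulus at every substep, evaluated in one vectorized call.
    t_sim = t_grid[0] + dt_sim * np.arange((n_rec - 1) * n_sub + 1)
    if trace.func is not None:
        s_sim = np.asarray(trace.func.value(t_sim), float)
    else:
        s_sim = np.interp(t_sim, trace.t, trace.s)
    s_sim_list = s_sim.tolist()

    state = steady_state(model_id, float(s_sim_list[0]), params)
    f = np.empty(n_rec)
    f[0] = float(output_map(model_id, state, s_sim_list[0], params))
    k = 0
    for i in range(n_rec - 1):
        for _ in range(n_sub):
            deriv = model_rhs(model_id, state, s_sim_list[k], params)
            state = tuple(x + dt_sim * d for x, d in zip(state, deriv))
            k += 1
        if not all(math.isfinite(x) for x in state) or abs(state[0]) > 1e3:
            raise RuntimeError(
                f"forward-Euler instability detected at t={t_grid[i]:.3f} (state={state}); reduce dt_sim"
            )
        f[i + 1] = float(output_map(model_id, state, s_sim_list[k], params))
    return TimeSeriesRecord(
        t=t_grid.copy(),
        s=trace.s.copy(),
        f=f,
        s_prime=trace.s_prime.copy(),
        s_doubleprime=trace.s_doubleprime.copy(),
        jump_times=trace.jump_times.copy(),
        kink_times=trace.kink_times.copy(),
        provenance={"model_id": model_id, "dt_sim": dt_sim},
    )


def analytic_Sg(
    params: EcoliParams,
    delta_n: float = 0.1,
    s_range: tuple[float, float] | None = None,
    m_range: tuple[float, float] | None = None,
    n_grid: int = 201,
    refine: bool = True,
) -> float:
    """Analytic gradient threshold S_g (stimulus units / s) for Model II.

    S_g = Dn / max_{(s, m) in box} |(dH2/dn)^{-1} d n_ss/d s|.  For the CheY-P
    equation dH2/dn = -1/tau_Z, so the maximand is tau_Z |d n_ss/d s| with the
    analytic derivative from :func:`dnss_ds`.  The maximum is located by a
    dense grid search followed by a local grid refinement.
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be positive")
    s_range = params.s_range if s_range is None else s_range
    m_range = params.m_range if m_range is None else m_range

    def gmax_on(s_lo, s_hi, m_lo, m_hi, n):
        s = np.linspace(s_lo, s_hi, n)
        m = np.linspace(m_lo, m_hi, n)
        S, M = np.meshgrid(s, m)
        g = params.tau_Z * np.abs(dnss_ds(M, S, params))
        k = np.unravel_index(np.argmax(g), g.shape)
        return float(g[k]), float(S[k]), float(M[k])

    g, s_at, m_at = gmax_on(*s_range, *m_range, n_grid)
    if not np.isfinite(g) or g <= 0:
        raise ValueError("non-finite or degenerate maximand over the given box")
    if refine and s_range[0] < s_range[1] and m_range[0] < m_range[1]:
        ds = (s_range[1] - s_range[0]) / (n_grid - 1)
        dm = (m_range[1] - m_range[0]) / (n_grid - 1)
        g2, _, _ = gmax_on(
            max(s_range[0], s_at - ds), min(s_range[1], s_at + ds),
            max(m_range[0], m_at - dm), min(m_range[1], m_at + dm),
            n_grid,
        )
        g = max(g, g2)
    return delta_n / g
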