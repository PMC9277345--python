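"""Workload and latency-based performance models of the compute node.

Workload model
--------------
The per-step workload measure is the average number of spike events per
simulation step,

    nu_bar_k = N * nu_bar * h,

with N the network size, nu_bar the population-mean firing rate (spks/s)
and h the step size (s).  Because every spike streams a fixed-size
presynaptic packet, the per-node connection count

    C^M = eps * N / M

(eps: connection probability, M: number of nodes) is independent of the
network size, which makes nu_bar_k the natural throughput currency.

Performance model
-----------------
A step in which no neuron fires costs ``L_Sigma = IL_N + L_SYNC`` clock
cycles (pipeline iteration plus synchronisation); the acceleration
factor against biological real time is then bounded by

    F_S^MAX = h * f_clk / L_Sigma.

A step processing spike events additionally pays the spike path
(serialisation, stream initiation, ring-buffer drain, pipeline restart
and re-fill, and half an iteration for the expected spike position):

    L_Sigma^SE = L_RD + L_ODE + IL_N/2 + L_SE + L_IDS + L_RB + L_SYNC^SE

plus ``L_DS`` memory-stream cycles per spike event.  Blending the
spiking and non-spiking cases linearly below one event per step gives
the two-branch forms ``f_s`` (isolated node) and, adding a fixed
inter-node transmission latency ``L_COM = f_clk * T_COM`` and a
per-spike communication surcharge ``alpha * L_COM``, ``f_c`` (cluster
operation).  The relative losses ``P_S`` (node-local spike processing)
and ``P_C`` (communication) decompose the total loss ``P_TOT`` against
``F_S^MAX`` exactly.

Calibration: the spike-path components are carried as a single
calibrated sum (``l_spike_base = 49`` cycles, excluding IL_N/2) chosen
so that at f_clk = 200 MHz and h = 0.1 ms the prototype design yields
L_Sigma = 67 and L_Sigma^SE = 81 cycles — the totals consistent with
the published characterisation of the prototype hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd


@dataclass(frozen=True)
class LatencyConfig:
    """Clock-cycle latencies and design parameters of one configuration."""

    f_clk: float = 200e6       # Hz
    h: float = 1e-4            # s (0.1 ms)
    il_n: int = 64             # ODE pipeline iteration latency, cycles
    l_sync: int = 3            # end-of-step synchronisation, cycles
    l_spike_base: int = 49     # L_RD+L_ODE+L_SE+L_IDS+L_RB+L_SYNC^SE, cycles
    l_ds: int = 110            # per-spike-event data stream latency, cycles
    t_com: float = 500e-9      # inter-node transmission latency time, s
    alpha: float = 0.05        # per-spike communication factor
    l_startup: int = 20        # L_RD + L_ODE pipeline fill (finite-k form only)

    def __post_init__(self):
        for name in ("f_clk", "h", "il_n", "l_sync", "l_spike_base",
                     "l_ds", "t_com", "alpha", "l_startup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def cycles_per_step(self) -> float:
        """Cycle budget h * f_clk of one biological step (20000 at defaults)."""
        return round(self.h * self.f_clk)

    @property
    def l_sigma(self) -> float:
        """Non-spiking step latency IL_N + L_SYNC."""
        return self.il_n + self.l_sync

    @property
    def l_sigma_se(self) -> float:
        """Spiking step latency including the expected IL_N/2 spike position."""
        return self.l_spike_base + self.il_n / 2

    @property
    def l_com(self) -> float:
        """Transmission latency in clock cycles, f_clk * T_COM."""
        return self.f_clk * self.t_com


@dataclass(frozen=True)
class ParamSet:
    """One design-space point (a column of the published parameter table)."""

    name: str
    ds: int
    p: int
    n_p: int
    il_n: int
    l_ds: int

    def latency_config(self, base: LatencyConfig = LatencyConfig()) -> LatencyConfig:
        return replace(base, il_n=self.il_n, l_ds=self.l_ds)


PARAM_SETS = {
    "prototype": ParamSet("prototype", ds=2, p=16, n_p=64, il_n=64, l_ds=110),
    "high_ds": ParamSet("high_ds", ds=16, p=16, n_p=64, il_n=64, l_ds=14),
    "high_proc": ParamSet("high_proc", ds=16, p=32, n_p=32, il_n=32, l_ds=14),
    "low_proc": ParamSet("low_proc", ds=16, p=8, n_p=128, il_n=128, l_ds=14),
}


@dataclass(frozen=True)
class WorkloadSpec:
    """A network workload: size, firing rate, connectivity, duration."""

    n: int
    nu_bar: float
    eps: float = 0.1
    m: int = 1
    t: float = 1.0
    h: float = 1e-4

    @property
    def k_degree(self) -> float:
        return self.eps * self.n

    @property
    def nu_bar_k(self) -> float:
        return nu_bar_k(self.n, self.nu_bar, self.h)

    @property
    def c_per_node(self) -> float:
        return c_per_node(self.eps, self.n, self.m)


# ---------------------------------------------------------------------------
# Workload model
# ---------------------------------------------------------------------------

def nu_bar_k(n: int, nu_bar: float, h: float) -> float:
    """Average spike events per step: N * nu_bar * h."""
    if n < 0 or nu_bar < 0 or h < 0:
        raise ValueError("workload arguments must be >= 0")
    return n * nu_bar * h


def c_per_node(eps: float, n: int, m: int = 1) -> float:
    """Per-node connections of a source neuron: eps * N / M."""
    if m < 1:
        raise ValueError("node count must be >= 1")
    return eps * n / m


# ---------------------------------------------------------------------------
# Performance model
# ---------------------------------------------------------------------------

def f_s_max(cfg: LatencyConfig, k_steps: int | None = None) -> float:
    """Maximum single-node acceleration factor (no spikes, no communication).

    With ``k_steps`` the finite-run form including the pipeline fill
    cost is evaluated; otherwise the k >> 1 limit h*f_clk / L_Sigma.
    """
    if cfg.l_sigma == 0:
        raise ZeroDivisionError("L_Sigma must be positive")
    if k_steps is None:
        return cfg.cycles_per_step / cfg.l_sigma
    return (k_steps * cfg.cycles_per_step
            / (cfg.l_startup + k_steps * cfg.l_sigma))


def f_s(cfg: LatencyConfig, nu_k: float) -> float:
    """Isolated-node acceleration factor at workload ``nu_k`` spikes/step."""
    if nu_k < 0:
        raise ValueError("workload must be >= 0")
    budget = cfg.cycles_per_step
    if nu_k < 1:
        denom = nu_k * (cfg.l_sigma_se + cfg.l_ds) + (1 - nu_k) * cfg.l_sigma
    else:
        denom = cfg.l_sigma_se + nu_k * cfg.l_ds
    return budget / denom


def f_c_max(cfg: LatencyConfig) -> float:
    """Maximum acceleration factor with inter-node communication."""
    return cfg.cycles_per_step / (cfg.l_sigma + cfg.l_com)


def f_c(cfg: LatencyConfig, nu_k: float) -> float:
    """Cluster acceleration factor at workload ``nu_k`` spikes/step."""
    if nu_k < 0:
        raise ValueError("workload must be >= 0")
    budget = cfg.cycles_per_step
    if nu_k < 1:
        denom = (nu_k * (cfg.l_sigma_se + cfg.l_ds + cfg.alpha * cfg.l_com)
                 + (1 - nu_k) * cfg.l_sigma + cfg.l_com)
    else:
        denom = (cfg.l_sigma_se + nu_k * (cfg.l_ds + cfg.alpha * cfg.l_com)
                 + cfg.l_com)
    return budget / denom


def perf_loss(cfg: LatencyConfig, nu_k: float) -> tuple[float, float, float]:
    """Relative performance losses (P_TOT, P_S, P_C) in percent.

    P_TOT = (1 - F_C/F_S^MAX) * 100 splits exactly into the node-local
    spike-processing loss P_S and the communication loss P_C.
    """
    fmax = f_s_max(cfg)
    fs = f_s(cfg, nu_k)
    fc = f_c(cfg, nu_k)
    p_s = (1 - fs / fmax) * 100.0
    p_c = (fs - fc) / fmax * 100.0
    return p_s + p_c, p_s, p_c


WORKLOADS = (0.0, 1.0, 10.0, 20.0)


def table1(paramsets=None, base: LatencyConfig = LatencyConfig()) -> pd.DataFrame:
    """Acceleration factors F_S and F_C at the four reference workloads.

    Returns a DataFrame with one column per parameter set and rows
    FS_MAX, FS(1), FS(10), FS(20), FC_MAX, FC(1), FC(10), FC(20),
    rounded to one decimal.
    """
    paramsets = paramsets or PARAM_SETS
    rows = ["FS_MAX", "FS(1.0)", "FS(10.0)", "FS(20.0)",
            "FC_MAX", "FC(1.0)", "FC(10.0)", "FC(20.0)"]
    data = {}
    for name, ps in paramsets.items():
        cfg = ps.latency_config(base)
        col = [f_s_max(cfg), f_s(cfg, 1.0), f_s(cfg, 10.0), f_s(cfg, 20.0),
               f_c_max(cfg), f_c(cfg, 1.0), f_c(cfg, 10.0), f_c(cfg, 20.0)]
        data[name] = [round(x, 1) for x in col]
    return pd.DataFrame(data, index=rows)
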