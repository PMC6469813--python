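"""Synchronous stochastic dynamics of the lattice network.

Each neuron carries a synaptic current ``I`` and a spiking-rate variable
``R_S``, both with exponential decay (time constants ``tau_I = 9 ms`` for
currents; ``tau_P = 9 ms`` excitatory / ``12 ms`` inhibitory for the rate).
Per 1-ms step, with ``S`` the previous step's binary spike vector:

    I(t+dt)   = (I(t) + W^T S(t)) * (1 - dt/tau_I)
    R_S(t+dt) = (R_S(t) + I(t)) * (1 - dt/tau_P) + P0 * dt/tau_P
    P_spike   = clip(R_S(t+dt), 0, 1)            (0 below threshold, 1 above)

Spiking neurons have ``R_S`` reset to -2 (excitatory) or -20 (inhibitory).
``P0 = 1e-6`` for excitatory neurons (a weak Poisson drive keeping the
network out of a true absorbing state) and 0 for inhibitory ones.  Note the
rate update consumes the *previous* step's current, the simultaneous-update
reading of the right-hand sides; set ``current_feed="post"`` to feed the
freshly decayed current instead.

The population activity ``A(t) = sum_i S_i(t)`` is the series every
downstream analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .topology import NetworkTopology

DT = 1.0  # ms
TAU_I = 9.0  # ms, synaptic current decay
TAU_P_EXC = 9.0  # ms, rate-variable decay, excitatory
TAU_P_INH = 12.0
P0_EXC = 1e-6  # background spiking probability per step, excitatory only
P0_INH = 0.0
RESET_EXC = -2.0
RESET_INH = -20.0


@dataclass
class NeuronState:
    I: np.ndarray
    R_S: np.ndarray
    S: np.ndarray  # bool

    @classmethod
    def zeros(cls, n: int) -> "NeuronState":
        return cls(I=np.zeros(n), R_S=np.zeros(n), S=np.zeros(n, dtype=bool))


@dataclass
class SimulationTrace:
    """Population activity A(t) at dt = 1 ms plus the run's provenance."""

    A: np.ndarray
    dt: float
    params: dict = field(default_factory=dict)
    seed: int = 0
    raster: np.ndarray | None = None  # optional (t, neuron) pairs

    @property
    def n_steps(self) -> int:
        return len(self.A)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("activity", data=self.A)
            d.attrs["dt_ms"] = self.dt
            d.attrs["seed"] = self.seed
            for k, v in self.params.items():
                d.attrs[k] = v
            if self.raster is not None:
                f.create_dataset("raster", data=self.raster)

    @classmethod
    def load(cls, path) -> "SimulationTrace":
        with h5py.File(path, "r") as f:
            d = f["activity"]
            params = {k: v for k, v in d.attrs.items() if k not in ("dt_ms", "seed")}
            raster = f["raster"][:] if "raster" in f else None
            return cls(A=d[:], dt=float(d.attrs["dt_ms"]), params=params,
                       seed=int(d.attrs.get("seed", 0)), raster=raster)

    def save_text(self, path) -> None:
        """Single-column text export of A(t)."""
        np.savetxt(path, self.A, fmt="%d")


def step(
    state: NeuronState,
    topology: NetworkTopology,
    rng: np.random.Generator,
    current_feed: str = "previous",
) -> NeuronState:
    """One synchronous update of all neurons (reference implementation).

    Order: current update (from previous spikes), rate update (from the
    previous step's current), spike draw, reset.  One uniform draw per neuron
    in fixed neuron order.
    """
    is_exc = topology.is_excitatory
    tau_p = np.where(is_exc, TAU_P_EXC, TAU_P_INH)
    p0 = np.where(is_exc, P0_EXC, P0_INH)

    I_new = (state.I + topology.weights.T @ state.S) * (1.0 - DT / TAU_I)
    feed = state.I if current_feed == "previous" else I_new
    R_new = (state.R_S + feed) * (1.0 - DT / tau_p) + p0 * DT / tau_p

    if not (np.all(np.isfinite(I_new)) and np.all(np.isfinite(R_new))):
        raise FloatingPointError("non-finite neuron state: parameter blow-up")

    p_spike = np.clip(R_new, 0.0, 1.0)  # Heaviside gate: R_S <= 0 never spikes
    spiked = rng.random(len(p_spike)) < p_spike
    R_new[spiked] = np.where(is_exc[spiked], RESET_EXC, RESET_INH)
    return NeuronState(I=I_new, R_S=R_new, S=spiked)


@njit(cache=True, inline="always")
def _splitmix64(z):  # pragma: no cover - numba
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _run_kernel(indptr, indices, weights, is_exc, n_steps, seed,
                feed_previous, record_raster):  # pragma: no cover - numba
    # xorshift128+ stream seeded via splitmix64: the per-neuron-step uniform
    # draw dominates the run time, so a cheap inline generator is used
    s0 = _splitmix64(np.uint64(seed))
    s1 = _splitmix64(s0)
    if s0 == 0 and s1 == 0:
        s1 = np.uint64(1)
    inv53 = 1.0 / 9007199254740992.0  # 2^-53
    n = is_exc.size
    I = np.zeros(n)
    R = np.zeros(n)
    S = np.zeros(n, np.bool_)
    inp = np.zeros(n)
    A = np.zeros(n_steps, np.int64)
    decay_i = 1.0 - DT / TAU_I
    decay_p = np.empty(n)
    p0term = np.empty(n)
    reset = np.empty(n)
    for i in range(n):
        if is_exc[i]:
            decay_p[i] = 1.0 - DT / TAU_P_EXC
            p0term[i] = P0_EXC * DT / TAU_P_EXC
            reset[i] = RESET_EXC
        else:
            decay_p[i] = 1.0 - DT / TAU_P_INH
            p0term[i] = P0_INH * DT / TAU_P_INH
            reset[i] = RESET_INH
    raster_t = []
    raster_i = []
    for t in range(n_steps):
        inp[:] = 0.0
        for j in range(n):
            if S[j]:
                for k in range(indptr[j], indptr[j + 1]):
                    inp[indices[k]] += weights[k]
        a = 0
        for i in range(n):
            I_new = (I[i] + inp[i]) * decay_i
            if -1e-30 < I_new < 1e-30:
                I_new = 0.0  # flush decayed currents before they go denormal
            feed = I[i] if feed_previous else I_new
            R_new = (R[i] + feed) * decay_p[i] + p0term[i]
            I[i] = I_new
            p = R_new
            if p > 1.0:
                p = 1.0
            # one draw per neuron with spiking potential, fixed neuron order
            if p <= 0.0:
                S[i] = False
                R[i] = R_new
                continue
            x = s0
            y = s1
            s0 = y
            x ^= (x << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
            s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
            u = float((s0 + s1) >> np.uint64(11)) * inv53
            if u < p:
                S[i] = True
                R[i] = reset[i]
                a += 1
                if record_raster:
                    raster_t.append(t)
                    raster_i.append(i)
            else:
                S[i] = False
                R[i] = R_new
        A[t] = a
    nr = len(raster_t)
    raster = np.empty((nr, 2), np.int64)
    for k in range(nr):
        raster[k, 0] = raster_t[k]
        raster[k, 1] = raster_i[k]
    return A, I, R, raster


def simulate(
    topology: NetworkTopology,
    n_steps: int,
    seed: int = 0,
    current_feed: str = "previous",
    record_raster: bool = False,
    discard_transient: int = 0,
) -> SimulationTrace:
    """Run the network from a zeroed state for ``n_steps`` 1-ms steps.

    Identical ``(topology, n_steps, seed)`` produce identical traces.
    ``discard_transient`` drops that many initial steps from the returned
    activity (off by default).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    w = topology.weights.tocsr()
    A, I, R, raster = _run_kernel(
        w.indptr, w.indices, w.data, topology.is_excitatory,
        n_steps, seed, current_feed == "previous", record_raster,
    )
    if not (np.all(np.isfinite(I)) and np.all(np.isfinite(R))):
        raise FloatingPointError("non-finite neuron state: parameter blow-up")
    if discard_transient:
        A = A[discard_transient:]
        if record_raster:
            raster = raster[raster[:, 0] >= discard_transient]
    params = dict(
        L=topology.L, ell=topology.ell, r_E=topology.r_E, r_I=topology.r_I,
        disorder_seed=topology.seed, n_steps=n_steps,
        tau_I=TAU_I, tau_P_exc=TAU_P_EXC, tau_P_inh=TAU_P_INH,
        P0_exc=P0_EXC, current_feed=current_feed,
    )
    return SimulationTrace(A=A, dt=DT, params=params, seed=seed,
                           raster=raster if record_raster else None)
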