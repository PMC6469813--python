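"""Disordered two-dimensional excitatory-inhibitory lattice networks.

Neurons sit on an ``L x L`` square lattice with open boundaries.  75% of the
sites are excitatory and 25% inhibitory, assigned by a seeded permutation.
Each neuron projects only within the ``ell x ell`` square centred on it
(Chebyshev neighbourhood, self excluded), favouring targets at short
Euclidean distance ``r`` with relative probability ``exp(-r / a0)`` where
``a0 = 1`` is the nearest-neighbour spacing.  The connectivity fractions
``r_E`` (excitatory) and ``r_I`` (inhibitory) set the fraction of the
in-range neighbourhood each neuron connects to.

Two sampling rules are provided:

* ``degree_model="fixed"`` (default): each neuron connects to
  ``k ~ frac * N_local`` targets (stochastically rounded) drawn without
  replacement with weights ``exp(-r)``, so realized connectivity equals the
  stated fraction with minimal disorder in the out-degrees.
* ``degree_model="bernoulli"``: each in-range target is connected
  independently with probability ``p(r) = min(1, C * exp(-r))``; ``C``
  normalizes either the mean per-target probability to the fraction
  (``normalization="mean"``, with one renormalization pass compensating
  capped entries) or the summed probability (``normalization="sum"``, the
  single-expected-connection reading, far too sparse to oscillate).

Synaptic weights are fixed by the (pre, post) type pair:
``W_EE = 0.02``, ``W_EI = 0.011`` (excitatory pre), and
``W_IE = W_II = -2`` (inhibitory pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import sparse

W_EE = 0.02
W_EI = 0.011
W_IE = -2.0
W_II = -2.0

A0 = 1.0  # nearest-neighbour distance setting the decay scale of p(r)


@dataclass
class NetworkTopology:
    """One disorder realization of the lattice network.

    ``weights[j, i]`` is the synaptic weight from presynaptic neuron ``j``
    to postsynaptic neuron ``i``; neuron indices are row-major over the
    lattice.
    """

    L: int
    ell: int
    r_E: float
    r_I: float
    exc_fraction: float
    seed: int
    neuron_type: np.ndarray = field(repr=False)  # bool, True = excitatory
    weights: sparse.csr_matrix = field(repr=False)

    @property
    def n_neurons(self) -> int:
        return self.L * self.L

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.neuron_type

    def save(self, path) -> None:
        """Serialize to HDF5: neuron types plus a COO weight list."""
        coo = self.weights.tocoo()
        with h5py.File(path, "w") as f:
            g = f.create_group("topology")
            g.attrs.update(
                L=self.L, ell=self.ell, r_E=self.r_E, r_I=self.r_I,
                exc_fraction=self.exc_fraction, seed=self.seed,
            )
            g.create_dataset("is_excitatory", data=self.neuron_type)
            g.create_dataset("pre_index", data=coo.row.astype(np.int64))
            g.create_dataset("post_index", data=coo.col.astype(np.int64))
            g.create_dataset("weight", data=coo.data)

    @classmethod
    def load(cls, path) -> "NetworkTopology":
        with h5py.File(path, "r") as f:
            g = f["topology"]
            a = g.attrs
            n = int(a["L"]) ** 2
            w = sparse.coo_matrix(
                (g["weight"][:], (g["pre_index"][:], g["post_index"][:])),
                shape=(n, n),
            ).tocsr()
            return cls(
                L=int(a["L"]), ell=int(a["ell"]), r_E=float(a["r_E"]),
                r_I=float(a["r_I"]), exc_fraction=float(a["exc_fraction"]),
                seed=int(a["seed"]), neuron_type=g["is_excitatory"][:].astype(bool),
                weights=w,
            )


def neighborhood_offsets(ell: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dx, dy, r) for all in-range offsets, self excluded.

    The candidate set is the ``ell x ell`` Chebyshev square; ``r`` is the
    Euclidean distance in lattice units.
    """
    h = (ell - 1) // 2
    dx, dy = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    dx, dy = dx.ravel(), dy.ravel()
    keep = (dx != 0) | (dy != 0)
    dx, dy = dx[keep], dy[keep]
    return dx, dy, np.hypot(dx, dy)


def _connection_probs(r: np.ndarray, frac: float, normalization: str) -> np.ndarray:
    """Per-target probabilities min(1, C e^{-r/a0}) for one presynaptic neuron.

    With ``normalization="mean"`` (default) C is set so that sum(p) equals
    ``frac * len(r)``; capped entries are compensated by one renormalization
    pass over the uncapped ones.  ``"sum"`` sets sum(p) = frac (the literal
    single-connection-in-expectation reading).
    """
    decay = np.exp(-r / A0)
    target = frac * len(r) if normalization == "mean" else frac
    C = target / decay.sum()
    p = np.minimum(1.0, C * decay)
    # one compensation pass: push mass lost to the cap onto uncapped targets
    deficit = target - p.sum()
    if deficit > 1e-12:
        free = p < 1.0
        if free.any():
            p[free] = np.minimum(1.0, p[free] + deficit * decay[free] / decay[free].sum())
    return np.clip(p, 0.0, 1.0)


def build_network(
    L: int,
    ell: int = 7,
    r_E: float = 0.12,
    r_I: float = 0.60,
    exc_fraction: float = 0.75,
    seed: int = 0,
    degree_model: str = "fixed",
    normalization: str = "mean",
) -> NetworkTopology:
    """Sample one disorder realization of the lattice network.

    Parameters
    ----------
    L : lattice side (the network has ``L**2`` neurons).
    ell : side of the local interaction square; must be odd and ``<= L``.
    r_E, r_I : excitatory / inhibitory connectivity fractions in (0, 1]:
        the fraction of in-range neighbours each neuron connects to.
    exc_fraction : fraction of excitatory neurons (0.75 in the reference model).
    seed : disorder seed; fixes both type assignment and connection sampling.
    degree_model : "fixed" (default) or "bernoulli"; see the module docstring.
    normalization : "mean" (default) or "sum"; Bernoulli model only.
    """
    if ell % 2 == 0 or ell < 1:
        raise ValueError(f"ell must be odd and >= 1, got {ell}")
    if L < ell:
        raise ValueError(f"need L >= ell, got L={L}, ell={ell}")
    for name, val in (("r_E", r_E), ("r_I", r_I)):
        if not (0.0 < val <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {val}")
    if normalization not in ("mean", "sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if degree_model not in ("fixed", "bernoulli"):
        raise ValueError(f"unknown degree_model {degree_model!r}")

    rng = np.random.default_rng(seed)
    n = L * L
    n_exc = int(round(exc_fraction * n))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[rng.permutation(n)[:n_exc]] = True

    dx, dy, r_all = neighborhood_offsets(ell)
    log_w_all = -r_all / A0

    # Cache per-(mask-signature, type) probability vectors: border neurons
    # reuse the same truncated neighbourhoods many times.
    prob_cache: dict[tuple, np.ndarray] = {}

    rows, cols, data = [], [], []
    xs, ys = np.divmod(np.arange(n), L)
    for j in range(n):
        x, y = xs[j], ys[j]
        tx, ty = x + dx, y + dy
        valid = (tx >= 0) & (tx < L) & (ty >= 0) & (ty < L)
        frac = r_E if is_exc[j] else r_I
        if degree_model == "fixed":
            n_local = int(valid.sum())
            k_mean = frac * n_local
            k = int(k_mean) + (rng.random() < (k_mean - int(k_mean)))
            if k == 0:
                continue
            # weighted sampling without replacement (Gumbel top-k)
            keys = log_w_all[valid] + rng.gumbel(size=n_local)
            hit = np.zeros(n_local, dtype=bool)
            hit[np.argpartition(-keys, k - 1)[:k]] = True
        else:
            key = (valid.tobytes(), frac)
            p = prob_cache.get(key)
            if p is None:
                p = _connection_probs(r_all[valid], frac, normalization)
                prob_cache[key] = p
            hit = rng.random(p.size) < p
        targets = (tx[valid] * L + ty[valid])[hit]
        if targets.size:
            w_to_exc = W_EE if is_exc[j] else W_IE
            w_to_inh = W_EI if is_exc[j] else W_II
            rows.append(np.full(targets.size, j))
            cols.append(targets)
            data.append(np.where(is_exc[targets], w_to_exc, w_to_inh))

    if rows:
        w = sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()
    else:
        w = sparse.csr_matrix((n, n))

    return NetworkTopology(
        L=L, ell=ell, r_E=r_E, r_I=r_I, exc_fraction=exc_fraction,
        seed=seed, neuron_type=is_exc, weights=w,
    )
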