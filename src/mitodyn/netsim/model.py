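"""Stochastic lattice model of a muscle-fiber mitochondrial network.

The fiber is discretised into one compartment per (sarcomere column x
transverse row).  Compartments are joined by longitudinal and transverse
edges; edges appear (fusion) and disappear (fission) as independent
two-state Markov channels, and activated tracer mixes deterministically
between compartments that are currently connected:

    da_i/dt = d_intra * sum_{j ~ i, edge present} (a_j - a_i)

Total tracer is conserved exactly (flux-form integration); membrane
potential is static under `evolve`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "FiberGeometry",
    "SimParams",
    "MitoNetworkState",
    "build_lattice",
    "photoactivate",
    "evolve",
    "EXACT_MAX_PAIRS",
]

#: largest number of candidate edges for which the exact event-driven
#: scheme is the default; larger networks use fixed-step tau-leaping.
EXACT_MAX_PAIRS = 500

#: tau-leap step bound: at most this flip probability per edge per step.
TAU_LEAP_MAX_HAZARD = 0.01

#: RK4 sub-step bound for the mixing integrator, as a fraction of the
#: real-axis stability limit for the worst-case Laplacian eigenvalue.
_RK4_DT_LIMIT = 2.5


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class FiberGeometry:
    """Lattice geometry of a simulated fiber.

    Parameters
    ----------
    n_long : int
        Number of sarcomere columns along the fiber axis (>= 8).
    n_trans : int
        Number of transverse compartment rows (>= 3).
    sarcomere_length : float
        Physical pitch of one column/row in micrometres (default 2.2).
    pixel_size : float
        Micrometres per rendered pixel; a sarcomere must span at least
        four pixels.
    """

    n_long: int
    n_trans: int
    sarcomere_length: float = 2.2
    pixel_size: float = 0.25

    def __post_init__(self) -> None:
        _require(int(self.n_long) == self.n_long and self.n_long >= 8,
                 "n_long", "must be an integer >= 8")
        _require(int(self.n_trans) == self.n_trans and self.n_trans >= 3,
                 "n_trans", "must be an integer >= 3")
        _require(math.isfinite(self.sarcomere_length) and self.sarcomere_length > 0,
                 "sarcomere_length", "must be finite and > 0")
        _require(math.isfinite(self.pixel_size) and self.pixel_size > 0,
                 "pixel_size", "must be finite and > 0")
        _require(self.pixel_size <= self.sarcomere_length / 4,
                 "pixel_size", "a sarcomere must span at least 4 pixels")

    @property
    def n_nodes(self) -> int:
        return self.n_long * self.n_trans

    @property
    def length_um(self) -> float:
        """Fiber extent along the longitudinal axis."""
        return self.n_long * self.sarcomere_length

    @property
    def width_um(self) -> float:
        """Fiber extent along the transverse axis."""
        return self.n_trans * self.sarcomere_length

    @property
    def n_pairs(self) -> int:
        return lattice_pairs(self.n_trans, self.n_long)[0].size

    def node_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_um, y_um) center coordinates of every node, flat-indexed."""
        rows, cols = np.divmod(np.arange(self.n_nodes), self.n_long)
        L = self.sarcomere_length
        return (cols + 0.5) * L, (rows + 0.5) * L


@lru_cache(maxsize=32)
def lattice_pairs(n_trans: int, n_long: int) -> tuple[np.ndarray, np.ndarray]:
    """All lattice-adjacent node pairs (i, j), horizontal edges first.

    Horizontal edge (row, col)-(row, col+1) has index row*(n_long-1)+col;
    vertical edge (row, col)-(row+1, col) has index
    n_h + row*n_long + col.  Renderers rely on this ordering.
    """
    ids = np.arange(n_trans * n_long, dtype=np.int64).reshape(n_trans, n_long)
    pi = np.concatenate([ids[:, :-1].ravel(), ids[:-1, :].ravel()])
    pj = np.concatenate([ids[:, 1:].ravel(), ids[1:, :].ravel()])
    pi.setflags(write=False)
    pj.setflags(write=False)
    return pi, pj


@dataclass(frozen=True)
class SimParams:
    """Rate parameters of the network model (all rates per minute).

    d_intra : mixing rate between connected neighbor compartments.
    k_fus : fusion rate per absent lattice-neighbor pair.
    k_fis : fission rate per existing edge.
    p_frag0 : fraction of lattice edges absent at t=0.
    aggregate_density : expected protein aggregates per 100 um of fiber.
    depol_at_aggregate : fractional reduction of potential at aggregate
        nodes.
    global_depol : fractional reduction of potential everywhere (FCCP).
    seed : random seed used by :func:`build_lattice`.
    """

    d_intra: float
    k_fus: float
    k_fis: float
    p_frag0: float = 0.0
    aggregate_density: float = 0.0
    depol_at_aggregate: float = 0.0
    global_depol: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_intra", "k_fus", "k_fis"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, name,
                     "rate must be finite and >= 0")
        _require(math.isfinite(self.p_frag0) and 0 <= self.p_frag0 < 1,
                 "p_frag0", "must be in [0, 1)")
        _require(math.isfinite(self.aggregate_density) and self.aggregate_density >= 0,
                 "aggregate_density", "must be finite and >= 0")
        for name in ("depol_at_aggregate", "global_depol"):
            v = getattr(self, name)
            _require(math.isfinite(v) and 0 <= v <= 1, name,
                     "must be in [0, 1]")


@dataclass
class MitoNetworkState:
    """Network state: topology, tracer content, membrane potential."""

    geometry: FiberGeometry
    edge_present: np.ndarray       # bool, one per lattice pair
    tracer: np.ndarray             # float, per node, >= 0
    potential: np.ndarray          # float, per node, in [0, 1]
    aggregate_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    time: float = 0.0

    def copy(self) -> "MitoNetworkState":
        return MitoNetworkState(
            geometry=self.geometry,
            edge_present=self.edge_present.copy(),
            tracer=self.tracer.copy(),
            potential=self.potential.copy(),
            aggregate_nodes=self.aggregate_nodes.copy(),
            time=self.time,
        )

    @property
    def total_tracer(self) -> float:
        return float(self.tracer.sum())

    def n_components(self) -> int:
        """Connected components of the current topology."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        g = self.geometry
        pi, pj = lattice_pairs(g.n_trans, g.n_long)
        on = self.edge_present
        adj = coo_matrix(
            (np.ones(int(on.sum())), (pi[on], pj[on])),
            shape=(g.n_nodes, g.n_nodes),
        )
        n, _ = connected_components(adj, directed=False)
        return int(n)


def build_lattice(geometry: FiberGeometry, params: SimParams) -> MitoNetworkState:
    """Initial network state.

    Every lattice-neighbor edge is present except an independently
    removed fraction ``p_frag0``.  Tracer starts at zero; potential
    starts at ``1 - global_depol`` everywhere and is further reduced by
    ``depol_at_aggregate`` at Poisson-placed aggregate nodes.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pi, _ = lattice_pairs(geometry.n_trans, geometry.n_long)
    edge_present = rng.random(pi.size) >= params.p_frag0

    tracer = np.zeros(geometry.n_nodes)
    potential = np.full(geometry.n_nodes, 1.0 - params.global_depol)

    n_agg = int(rng.poisson(params.aggregate_density * geometry.length_um / 100.0))
    n_agg = min(n_agg, geometry.n_nodes)
    if n_agg > 0:
        agg = rng.choice(geometry.n_nodes, size=n_agg, replace=False)
        agg.sort()
        potential[agg] *= 1.0 - params.depol_at_aggregate
    else:
        agg = np.empty(0, dtype=np.int64)

    return MitoNetworkState(
        geometry=geometry,
        edge_present=edge_present,
        tracer=tracer,
        potential=potential,
        aggregate_nodes=agg.astype(np.int64),
        time=0.0,
    )


def photoactivate(state: MitoNetworkState, roi: tuple[float, float, float, float]
                  ) -> MitoNetworkState:
    """Set tracer to 1 in every node whose center lies inside ``roi``.

    ``roi`` is ``(x0, y0, x1, y1)`` in micrometres, x along the fiber
    axis.  The elapsed time is reset to zero.  An ROI that does not
    intersect the fiber extent is rejected; an ROI that intersects but
    contains no node center simply activates nothing.
    """
    x0, y0, x1, y1 = roi
    g = state.geometry
    if x1 < x0 or y1 < y0:
        raise ValueError("roi: degenerate rectangle (x1 < x0 or y1 < y0)")
    if x1 < 0 or x0 > g.length_um or y1 < 0 or y0 > g.width_um:
        raise ValueError("roi: does not intersect the fiber")

    cx, cy = g.node_centers()
    inside = (cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
    out = state.copy()
    out.tracer[inside] = 1.0
    out.time = 0.0
    return out


def _mix(a: np.ndarray, pi: np.ndarray, pj: np.ndarray, d: float, dt: float) -> np.ndarray:
    """Advance the mixing ODE by ``dt`` on a fixed edge set (flux form).

    RK4 with sub-steps inside the linear stability limit.  Flux-form
    updates conserve the total exactly up to floating-point rounding.
    """
    if dt <= 0 or d == 0 or pi.size == 0:
        return a
    n = a.size

    def rhs(x: np.ndarray) -> np.ndarray:
        df = d * (x[pj] - x[pi])
        return np.bincount(pi, weights=df, minlength=n) - \
            np.bincount(pj, weights=df, minlength=n)

    # Laplacian spectral radius is bounded by 2 * max degree (= 8).
    h_max = _RK4_DT_LIMIT / (8.0 * d)
    n_sub = max(1, int(math.ceil(dt / h_max)))
    h = dt / n_sub
    for _ in range(n_sub):
        k1 = rhs(a)
        k2 = rhs(a + 0.5 * h * k1)
        k3 = rhs(a + 0.5 * h * k2)
        k4 = rhs(a + h * k3)
        a = a + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return a


def evolve(state: MitoNetworkState, params: SimParams, t_end: float,
           rng: np.random.Generator | None = None,
           method: str = "auto") -> MitoNetworkState:
    """Advance the network to ``t_end`` minutes.

    Stochastic topology events (fission of present edges at ``k_fis``,
    fusion of absent lattice pairs at ``k_fus``) are interleaved with
    deterministic tracer mixing.  ``method`` is ``"exact"`` (event
    driven), ``"tauleap"`` (fixed-step with per-edge flip hazard
    <= 1% per step) or ``"auto"`` (exact at or below
    ``EXACT_MAX_PAIRS`` candidate edges).  Potential is untouched.
    """
    if t_end <= state.time:
        raise ValueError(f"t_end: must exceed current state time {state.time}")
    if method not in ("auto", "exact", "tauleap"):
        raise ValueError(f"method: unknown scheme {method!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    g = state.geometry
    pi, pj = lattice_pairs(g.n_trans, g.n_long)
    if method == "auto":
        method = "exact" if pi.size <= EXACT_MAX_PAIRS else "tauleap"

    out = state.copy()
    present = out.edge_present
    a = out.tracer
    total0 = a.sum()
    t = out.time
    k_fis, k_fus, d = params.k_fis, params.k_fus, params.d_intra

    def mix_span(a: np.ndarray, dt: float) -> np.ndarray:
        on = present
        return _mix(a, pi[on], pj[on], d, dt)

    if method == "exact":
        while t < t_end:
            n_on = int(present.sum())
            n_off = present.size - n_on
            total_rate = k_fis * n_on + k_fus * n_off
            if total_rate == 0:
                a = mix_span(a, t_end - t)
                t = t_end
                break
            dt = rng.exponential(1.0 / total_rate)
            if t + dt >= t_end:
                a = mix_span(a, t_end - t)
                t = t_end
                break
            a = mix_span(a, dt)
            t += dt
            if rng.random() < k_fis * n_on / total_rate:
                which = np.flatnonzero(present)
                present[which[rng.integers(which.size)]] = False
            else:
                which = np.flatnonzero(~present)
                present[which[rng.integers(which.size)]] = True
    else:
        k_max = max(k_fis, k_fus)
        if k_max == 0:
            a = mix_span(a, t_end - t)
            t = t_end
        else:
            tau0 = TAU_LEAP_MAX_HAZARD / k_max
            while t < t_end - 1e-12:
                tau = min(tau0, t_end - t)
                r = rng.random(present.size)
                p_cut = -math.expm1(-k_fis * tau)
                p_join = -math.expm1(-k_fus * tau)
                flip = np.where(present, r < p_cut, r < p_join)
                present ^= flip
                a = mix_span(a, tau)
                t += tau

    if a.min() < -1e-9:
        raise RuntimeError(
            f"integrator instability: tracer reached {a.min():.3e}")
    np.clip(a, 0.0, None, out=a)
    # flux-form integration keeps this far below the contract of 1e-9
    if total0 > 0:
        drift = abs(a.sum() - total0) / total0
        if drift > 1e-9:
            raise RuntimeError(f"tracer conservation violated: {drift:.3e}")

    out.tracer = a
    out.edge_present = present
    out.time = float(t_end)
    return out


def _unchecked_geometry(n_long: int, n_trans: int,
                        sarcomere_length: float = 2.2,
                        pixel_size: float = 0.25) -> FiberGeometry:
    """Geometry without the minimum-size validation.

    Testing seam: oracle comparisons run on networks of <= 4 nodes,
    below the fiber-scale minima enforced by :class:`FiberGeometry`.
    """
    g = object.__new__(FiberGeometry)
    object.__setattr__(g, "n_long", n_long)
    object.__setattr__(g, "n_trans", n_trans)
    object.__setattr__(g, "sarcomere_length", sarcomere_length)
    object.__setattr__(g, "pixel_size", pixel_size)
    return g


def steady_state_params(params: SimParams) -> SimParams:
    """Same dynamics with p_frag0 set to the fission/fusion fixed point."""
    tot = params.k_fis + params.k_fus
    p = params.k_fis / tot if tot > 0 else params.p_frag0
    return replace(params, p_frag0=min(p, 1.0 - 1e-9))
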