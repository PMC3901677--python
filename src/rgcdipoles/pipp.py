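"""Pairwise interacting point process (PIPP) and its OPM-modulated variant.

The PIPP places ON and OFF cells so that the probability of a configuration
is a product of pairwise interaction values: soft parametric repulsion
within a polarity, and a hard step at the soma diameter between polarities.
The modulated process (mPIPP) multiplies the ON–OFF step by a von-Mises
kernel exp(β(cos 2Δ − 1)) whenever the pair is closer than the dipole
distance d, where Δ is the difference between the pair's implied dipole
orientation and the orientation-preference map at the pair midpoint.  β = 0
recovers the plain PIPP exactly.

Simulation follows a Monte-Carlo sweep scheme: cells start from a binomial
(Poisson-with-fixed-n) pattern, and each sweep proposes one uniform
candidate position per cell, accepting it with probability equal to the
product of its interaction values against all other cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import InteractionParams, MPIPPConfig, PairRepulsion, PointMosaic, validate_window
from .opm import OrientationField

__all__ = [
    "SimulationState",
    "intra_interaction",
    "inter_step",
    "angular_modulation",
    "modulated_inter_interaction",
    "acceptance_probability",
    "simulate_mpipp",
    "generate_moire_hexagonal",
]

#: packing fraction of the densest hard-disc packing; used for feasibility checks
_MAX_PACKING = 0.9069


@dataclass
class SimulationState:
    """Bookkeeping for one Monte-Carlo run."""

    mosaic: PointMosaic
    sweep_index: int = 0
    rng: Optional[np.random.Generator] = None
    acceptance_counts: Dict[str, int] = field(default_factory=lambda: {"on": 0, "off": 0})
    proposal_counts: Dict[str, int] = field(default_factory=lambda: {"on": 0, "off": 0})

    def acceptance_rate(self, polarity: str) -> float:
        prop = self.proposal_counts[polarity]
        return self.acceptance_counts[polarity] / prop if prop else float("nan")


def intra_interaction(dist, pair: PairRepulsion):
    """Soft repulsion 1 − exp(−((t − δ)/φ)^α) for t > δ, 0 inside δ.

    Continuous and nondecreasing in distance; vectorized.
    """
    if pair.phi is None or pair.alpha is None:
        raise ValueError("intra-mosaic interaction requires phi and alpha")
    t = np.asarray(dist, dtype=float)
    out = np.zeros_like(t)
    outside = t > pair.delta
    out[outside] = 1.0 - np.exp(-(((t[outside] - pair.delta) / pair.phi) ** pair.alpha))
    return float(out) if out.ndim == 0 else out


def inter_step(dist, soma_diameter: float):
    """Hard step: 0 when two cells are less than the soma diameter apart.

    The boundary is inclusive: cells exactly one soma diameter apart are
    allowed (value 1).
    """
    t = np.asarray(dist, dtype=float)
    out = (t >= soma_diameter).astype(float)
    return float(out) if out.ndim == 0 else out


def angular_modulation(delta_theta, beta: float):
    """Von-Mises alignment kernel exp(β(cos 2Δ − 1)).

    Equals 1 at perfect alignment, exp(−2β) at orthogonality; π-periodic in
    Δ; identically 1 at β = 0.
    """
    if not beta >= 0:
        raise ValueError("beta must be >= 0")
    d = np.asarray(delta_theta, dtype=float)
    out = np.exp(beta * (np.cos(2.0 * d) - 1.0))
    return float(out) if out.ndim == 0 else out


def _pair_orientation(dx, dy):
    """Orientation orthogonal to a connecting vector, in [0, π)."""
    return (np.arctan2(dy, dx) + 0.5 * np.pi) % np.pi


def modulated_inter_interaction(x_on, x_off, opm: OrientationField,
                                cfg: MPIPPConfig, soma_diameter: float) -> float:
    """ON–OFF interaction with orientation modulation inside d_mod.

    Pairs closer than the soma diameter are forbidden (0).  Pairs between
    the soma diameter and d_mod are weighted by the alignment of the implied
    dipole orientation with the OPM at the pair midpoint; beyond d_mod the
    plain step value 1 applies.  Midpoints outside the OPM footprint are
    evaluated at the nearest in-bounds pixel.
    """
    x_on = np.asarray(x_on, dtype=float)
    x_off = np.asarray(x_off, dtype=float)
    d = float(np.hypot(*(x_off - x_on)))
    if d < soma_diameter:
        return 0.0
    if d >= cfg.d_mod or cfg.beta == 0:
        return 1.0
    theta = _pair_orientation(x_off[0] - x_on[0], x_off[1] - x_on[1])
    local = float(opm.sample(0.5 * (x_on + x_off))[0])
    return float(angular_modulation(theta - local, cfg.beta))


def _acceptance_value(cand: np.ndarray, same: np.ndarray, self_index: Optional[int],
                      pair: PairRepulsion, opp: np.ndarray, soma: float,
                      beta: float, d_mod: float,
                      opm: Optional[OrientationField]) -> float:
    """Product of all interaction values at a candidate position.

    ``same`` holds all same-polarity positions (``self_index`` excluded),
    ``opp`` all opposite-polarity positions.
    """
    value = 1.0
    if same.shape[0]:
        d = np.hypot(same[:, 0] - cand[0], same[:, 1] - cand[1])
        if self_index is not None:
            d[self_index] = np.inf
        if np.any(d <= pair.delta):
            return 0.0
        value *= float(np.prod(1.0 - np.exp(-(((d - pair.delta) / pair.phi) ** pair.alpha))))
    if opp.shape[0]:
        d = np.hypot(opp[:, 0] - cand[0], opp[:, 1] - cand[1])
        if np.any(d < soma):
            return 0.0
        if beta > 0 and opm is not None:
            close = d < d_mod
            if np.any(close):
                pts = opp[close]
                theta = _pair_orientation(pts[:, 0] - cand[0], pts[:, 1] - cand[1])
                local = opm.sample(0.5 * (pts + cand))
                value *= float(np.prod(np.exp(beta * (np.cos(2.0 * (theta - local)) - 1.0))))
    return value


def acceptance_probability(candidate, cell_index: int, polarity: str,
                           state: SimulationState, opm: Optional[OrientationField],
                           params: InteractionParams, cfg: MPIPPConfig) -> float:
    """Probability of accepting *candidate* for one cell of the mosaic.

    The product over all other same-polarity cells of the soft repulsion,
    times the product over all opposite-polarity cells of the (modulated)
    step interaction, evaluated at the candidate; always in [0, 1].
    """
    cand = np.asarray(candidate, dtype=float).reshape(2)
    mosaic = state.mosaic
    same = mosaic.points(polarity)
    opp = mosaic.points("off" if polarity == "on" else "on")
    if not 0 <= cell_index < same.shape[0]:
        raise ValueError(f"cell_index {cell_index} out of range for {polarity} mosaic")
    return _acceptance_value(cand, same, cell_index, params.pair(polarity),
                             opp, params.soma_diameter, cfg.beta, cfg.d_mod, opm)


def _check_packing(n: int, delta: float, area: float, label: str) -> None:
    if n == 0:
        return
    packing = n * np.pi * (delta / 2.0) ** 2 / area
    if packing > _MAX_PACKING:
        raise ValueError(
            f"infeasible packing for {label}: {n} cells with exclusion radius "
            f"{delta} µm exceed the maximum hard-disc density in the window"
        )


def simulate_mpipp(window, n_on: int, n_off: int, params: InteractionParams,
                   opm: Optional[OrientationField] = None,
                   cfg: Optional[MPIPPConfig] = None,
                   return_state: bool = False):
    """Simulate an (m)PIPP mosaic by Monte-Carlo sweeps.

    Cells are initially positioned uniformly at random; each of
    ``cfg.n_sweeps`` iterations sweeps all ON cells and then all OFF cells,
    proposing one uniform candidate per cell and accepting it with
    :func:`acceptance_probability` (the old position is kept on rejection).
    Bit-reproducible for a fixed seed.  With β = 0 the OPM is never
    consulted and the process is exactly the plain PIPP.

    Returns the final :class:`PointMosaic`, or ``(mosaic, state)`` when
    *return_state* is true (acceptance diagnostics live on the state).
    """
    if cfg is None:
        cfg = MPIPPConfig()
    x0, x1, y0, y1 = validate_window(window)
    area = (x1 - x0) * (y1 - y0)
    _check_packing(n_on, params.on_on.delta, area, "ON mosaic")
    _check_packing(n_off, params.off_off.delta, area, "OFF mosaic")
    _check_packing(n_on + n_off, params.soma_diameter, area, "combined mosaic")
    if not cfg.d_mod > params.soma_diameter:
        raise ValueError("d_mod must exceed the ON-OFF soma diameter")
    if cfg.beta > 0:
        if opm is None:
            raise ValueError("an OPM is required for beta > 0")
        if not opm.covers(window):
            raise ValueError(
                f"OPM footprint {opm.extent} does not cover the window {window}"
            )
    rng = np.random.default_rng(cfg.seed)

    def _uniform(n):
        pts = rng.random((n, 2))
        pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
        pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
        return pts

    on = _uniform(n_on)
    off = _uniform(n_off)
    state = SimulationState(PointMosaic(on, off, (x0, x1, y0, y1)), rng=rng)
    soma = params.soma_diameter
    beta, d_mod = cfg.beta, cfg.d_mod
    for sweep in range(cfg.n_sweeps):
        for pts, opp, pair, label in ((on, off, params.on_on, "on"),
                                      (off, on, params.off_off, "off")):
            n = pts.shape[0]
            for i in range(n):
                cand = np.array([x0 + rng.random() * (x1 - x0),
                                 y0 + rng.random() * (y1 - y0)])
                p = _acceptance_value(cand, pts, i, pair, opp, soma, beta, d_mod, opm)
                state.proposal_counts[label] += 1
                if p > 0 and rng.random() < p:
                    pts[i] = cand
                    state.acceptance_counts[label] += 1
        state.sweep_index = sweep + 1
    mosaic = PointMosaic(on, off, (x0, x1, y0, y1))
    state.mosaic = mosaic
    if return_state:
        return mosaic, state
    return mosaic


def _hex_lattice(window, a: float, pad: float) -> np.ndarray:
    """Hexagonal lattice with constant *a* covering the padded window."""
    x0, x1, y0, y1 = window
    row_h = a * np.sqrt(3.0) / 2.0
    rows = np.arange(np.floor((y0 - pad) / row_h), np.ceil((y1 + pad) / row_h) + 1)
    cols = np.arange(np.floor((x0 - pad) / a), np.ceil((x1 + pad) / a) + 1)
    pts = []
    for j in rows:
        shift = 0.5 * a if int(j) % 2 else 0.0
        xs = cols * a + shift
        ys = np.full_like(xs, j * row_h)
        pts.append(np.column_stack([xs, ys]))
    return np.vstack(pts)


def generate_moire_hexagonal(window, lattice_const: float,
                             positional_noise_sd: float,
                             relative_rotation: float, seed: int = 0,
                             offset: Optional[Tuple[float, float]] = None) -> PointMosaic:
    """Two noisy hexagonal lattices as a Moiré-interference contrast fixture.

    ON points sit on a hexagonal lattice; OFF points on a second lattice
    shifted by *offset* (default: half a cell along x) and rotated by
    *relative_rotation* about the window centre.  Both are jittered by
    isotropic Gaussian noise and clipped to the window.  A small relative
    rotation α produces a spatially periodic dipole-orientation pattern
    with Moiré period ≈ lattice_const / (2 sin(α/2)).
    """
    if not lattice_const > 0:
        raise ValueError("lattice_const must be > 0")
    if positional_noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    win = validate_window(window)
    x0, x1, y0, y1 = win
    if offset is None:
        offset = (lattice_const / 2.0, 0.0)
    rng = np.random.default_rng(seed)
    pad = 2 * lattice_const + 4 * positional_noise_sd
    on = _hex_lattice(win, lattice_const, pad)
    off = _hex_lattice(win, lattice_const, pad) + np.asarray(offset, dtype=float)
    center = np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])
    c, s = np.cos(relative_rotation), np.sin(relative_rotation)
    rot = np.array([[c, -s], [s, c]])
    off = (off - center) @ rot.T + center
    if positional_noise_sd > 0:
        on = on + rng.normal(0.0, positional_noise_sd, on.shape)
        off = off + rng.normal(0.0, positional_noise_sd, off.shape)

    def _clip(pts):
        keep = ((pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                & (pts[:, 1] >= y0) & (pts[:, 1] <= y1))
        return pts[keep]

    return PointMosaic(_clip(on), _clip(off), win)
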