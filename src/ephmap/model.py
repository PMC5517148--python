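"""Growth-cone guidance model: potential evaluation and terminal dynamics.

Fiber terminals are circular discs carrying Gaussian-shaped sensor
distributions (EphA receptors ``R_F`` and ephrin-A ligands ``L_F``).  They
perform a random walk on the target field biased toward minimizing a
guidance potential ``D``, the absolute log-ratio of total reverse to total
forward signaling.  Two adaptation modes modulate the sensors over time:

* ``coadaptation`` — a single coefficient ``a`` (driven by the recent
  history of ``D``) multiplies *both* sensor species, while a Hookian
  resetting force pulls each back to its baseline.  The ``R_F/L_F`` ratio,
  the terminal's topographic identity, is preserved exactly.
* ``canonical`` — each sensor independently relaxes toward the local target
  cue level (negative feedback per channel), which destroys the ratio.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .gradients import TargetField

__all__ = [
    "ModelParams",
    "FiberTerminal",
    "SimulationResult",
    "SimulationError",
    "fiber_weight",
    "terminal_footprint",
    "guidance_potential",
    "adaptation_coefficient",
    "resetting_force",
    "apply_coadaptation",
    "apply_canonical_adaptation",
    "propose_and_move",
    "simulate",
]

logger = logging.getLogger(__name__)

SENSOR_FLOOR = 1e-9

#: Candidate unit displacements, order (+x, -x, +y, -y).
_DIRECTIONS = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])


class SimulationError(RuntimeError):
    """Raised when the dynamics produce non-finite state."""


@dataclass(frozen=True)
class ModelParams:
    """All dynamical constants of the model.

    Defaults reproduce the global parameter set used throughout the
    simulated experiments: n = 200 terminals, i = 30000 iterations,
    mu = 0.006, lambda = 0.0045, h = 10.
    """

    mu: float = 0.006
    lam: float = 0.0045
    h: int = 10
    n_terminals: int = 200
    n_iterations: int = 30000
    C0: float = 1.0
    j_onset: int = 10000
    ramp_len: int = 5000
    ramp: bool = True
    q_x: float = 0.37
    beta: float = 3.5
    kappa: float = 0.05
    sigma_frac: float = 0.5
    adaptation_mode: str = "coadaptation"
    seed: int = 0
    record_stride: int = 100

    def __post_init__(self) -> None:
        if self.adaptation_mode not in ("coadaptation", "canonical", "none"):
            raise ValueError(f"unknown adaptation_mode {self.adaptation_mode!r}")
        if not (0.0 <= self.q_x <= 1.0):
            raise ValueError("q_x must lie in [0, 1]")
        if self.h < 1 or self.n_iterations < 1 or self.n_terminals < 1:
            raise ValueError("h, n_terminals and n_iterations must be positive")
        if self.mu < 0 or self.lam < 0 or self.C0 < 0 or self.kappa < 0:
            raise ValueError("rate constants must be non-negative")

    def replace(self, **overrides) -> "ModelParams":
        return dataclasses.replace(self, **overrides)


@dataclass
class FiberTerminal:
    """A growth-cone agent on the target field.

    The center is a continuous coordinate; the disc (default radius 3.5,
    i.e. diameter about seven unit squares) defines the sensor footprint.
    """

    center: Tuple[float, float]
    origin_u: float
    R_F0: float
    L_F0: float
    R_F: float = 0.0
    L_F: float = 0.0
    radius: float = 3.5
    D_history: List[float] = dc_field(default_factory=list)
    mobile: bool = True
    knockin_R: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.R_F0 <= 0 or self.L_F0 <= 0:
            raise ValueError("baseline sensor amounts must be positive")
        if self.R_F == 0.0:
            self.R_F = self.R_F0
        if self.L_F == 0.0:
            self.L_F = self.L_F0


@dataclass
class SimulationResult:
    """Strided per-iteration record of a simulation run.

    ``sensors[t, k]`` is ``(R_F, L_F)`` of terminal ``k`` at recorded
    iteration ``iterations[t]``; ``max_x`` tracks the running maximum of
    every terminal's x-coordinate over the *whole* run (not just recorded
    frames), which the gap/entry metrics rely on.
    """

    iterations: np.ndarray          # (T,)
    positions: np.ndarray           # (T, n, 2)
    sensors: np.ndarray             # (T, n, 2) -> (R_F, L_F)
    potentials: np.ndarray          # (T, n)
    max_x: np.ndarray               # (n,)
    origin_u: np.ndarray            # (n,)
    baselines: np.ndarray           # (n, 2) -> (R_F0, L_F0)
    labels: np.ndarray              # (n,) str
    mobile: np.ndarray              # (n,) bool
    params: ModelParams
    scenario_tag: str = ""
    analysis_hints: Dict[str, float] = dc_field(default_factory=dict)

    @property
    def n_terminals(self) -> int:
        return self.positions.shape[1]

    @property
    def final_positions(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def final_x(self) -> np.ndarray:
        return self.positions[-1, :, 0]

    def to_frame(self):
        """Tidy long-format record (one row per iteration x terminal)."""
        import pandas as pd

        T, n, _ = self.positions.shape
        it = np.repeat(self.iterations, n)
        tid = np.tile(np.arange(n), T)
        return pd.DataFrame(
            {
                "iteration": it,
                "terminal_id": tid,
                "origin_u": np.tile(self.origin_u, T),
                "label": np.tile(self.labels, T),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "R_F": self.sensors[:, :, 0].ravel(),
                "L_F": self.sensors[:, :, 1].ravel(),
                "D": self.potentials.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def fiber_weight(iteration: int, params: ModelParams) -> float:
    """Weight C(i) of trans fiber-fiber signals at iteration ``i``.

    Rises linearly from 0 to ``C0`` between ``j_onset`` and
    ``j_onset + ramp_len`` (mimicking the developmental increase in terminal
    number/size); with the ramp switched off it is constant ``C0``.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if not params.ramp:
        return params.C0
    frac = (iteration - params.j_onset) / params.ramp_len
    return params.C0 * float(np.clip(frac, 0.0, 1.0))


def _footprint_arrays(
    cx: float,
    cy: float,
    radius: float,
    sigma: float,
    width: int,
    height: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices (ix, iy) and normalized Gaussian weights of one footprint."""
    lo_x = int(math.floor(cx - radius))
    hi_x = int(math.ceil(cx + radius))
    lo_y = int(math.floor(cy - radius))
    hi_y = int(math.ceil(cy + radius))
    ix = np.arange(max(lo_x, 0), min(hi_x + 1, width))
    iy = np.arange(max(lo_y, 0), min(hi_y + 1, height))
    if ix.size == 0 or iy.size == 0:
        return np.empty(0, int), np.empty(0, int), np.empty(0)
    gx, gy = np.meshgrid(ix, iy)
    dx = gx + 0.5 - cx
    dy = gy + 0.5 - cy
    d2 = dx * dx + dy * dy
    inside = d2 <= radius * radius
    w = np.where(inside, np.exp(-d2 / (2.0 * sigma * sigma)), 0.0)
    keep = w > 0.0
    return gx[keep], gy[keep], w[keep]


def terminal_footprint(
    terminal: FiberTerminal,
    field: TargetField,
    params: Optional[ModelParams] = None,
) -> Dict[Tuple[int, int], float]:
    """Truncated-Gaussian weight of each unit square under the disc.

    Weights cover squares whose centers lie within the disc and inside the
    field, with unit peak amplitude at the disc center, so that per-square
    sensor density is ``weight * (R_F or L_F)``.  Peak (rather than sum)
    normalization keeps cis and fiber-fiber signal densities on the same
    scale as the target cues, which is what makes the model's single-fiber
    reduced form ``D = |ln(1/(L_T/L_F + 1))|`` come out on a single-square
    footprint.  An empty map flags an off-field terminal.
    """
    params = params or ModelParams()
    sigma = params.sigma_frac * terminal.radius
    cx, cy = terminal.center
    gx, gy, w = _footprint_arrays(
        cx, cy, terminal.radius, sigma, field.width, field.height
    )
    return {(int(x), int(y)): float(wt) for x, y, wt in zip(gx, gy, w)}


def guidance_potential(
    terminal: FiberTerminal,
    field: TargetField,
    others: Iterable[FiberTerminal] = (),
    C: float = 0.0,
    params: Optional[ModelParams] = None,
) -> float:
    """Guidance potential D of one terminal (reference implementation).

    ``D = | ln( sum_x L_F(x) [R_T(x) + R_F(x) + C R_f(x)]
                / sum_x R_F(x) [L_T(x) + L_F(x) + C L_f(x)] ) |``

    summed over the footprint squares, where ``R_f``/``L_f`` are the
    per-square sensor densities of all *other* terminals (plus resident
    fields).  D >= 0, and D = 0 exactly when total reverse equals total
    forward signaling.  The simulation engine evaluates the same quantity
    in vectorized form.
    """
    params = params or ModelParams()
    fp = terminal_footprint(terminal, field, params)
    if not fp:
        logger.warning("terminal at %s has empty footprint (off-field)",
                       terminal.center)
        return float("inf")
    # per-square densities of the other terminals
    Rf: Dict[Tuple[int, int], float] = {}
    Lf: Dict[Tuple[int, int], float] = {}
    for other in others:
        if other is terminal:
            continue
        ofp = terminal_footprint(other, field, params)
        for sq, w in ofp.items():
            Rf[sq] = Rf.get(sq, 0.0) + w * other.R_F
            Lf[sq] = Lf.get(sq, 0.0) + w * other.L_F
    num = 0.0
    den = 0.0
    for (ix, iy), w in fp.items():
        R_T = field.R_T[iy, ix]
        L_T = field.L_T[iy, ix]
        rf = Rf.get((ix, iy), 0.0)
        lf = Lf.get((ix, iy), 0.0)
        if field.resident_R_f is not None:
            rf += field.resident_R_f[iy, ix]
        if field.resident_L_f is not None:
            lf += field.resident_L_f[iy, ix]
        num += terminal.L_F * w * (R_T + terminal.R_F * w + C * rf)
        den += terminal.R_F * w * (L_T + terminal.L_F * w + C * lf)
    if num <= 0.0 or den <= 0.0:
        logger.warning("terminal at %s has no forward/reverse drive",
                       terminal.center)
        return float("inf")
    return abs(math.log(num / den))


def adaptation_coefficient(
    history: Sequence[float],
    params: ModelParams,
) -> float:
    """Common adaptation coefficient a(i) from the recent history of D.

    ``a = 1 + ln(1 + mu * sum_k k D(i-h+k) / sum_k k)`` with k = 1..h;
    weights increase linearly toward the most recent value.  Histories
    shorter than h are padded with leading zeros (naive start), so a >= 1
    always.
    """
    h = params.h
    hist = np.asarray(history, dtype=float)
    if hist.size > h:
        raise ValueError(f"history holds {hist.size} > h = {h} values")
    if np.any(hist < 0):
        raise SimulationError("negative guidance potential in history")
    padded = np.zeros(h)
    if hist.size:
        padded[h - hist.size:] = hist
    k = np.arange(1, h + 1, dtype=float)
    weighted = float(np.dot(k, padded) / k.sum())
    return 1.0 + math.log(1.0 + params.mu * weighted)


def resetting_force(S: float, S0: float, params: ModelParams) -> float:
    """Hookian resetting force f = lambda (S0 - S); opposes deflection."""
    return params.lam * (S0 - S)


def apply_coadaptation(
    terminal: FiberTerminal,
    a: float,
    params: ModelParams,
) -> FiberTerminal:
    """Co-adaptation sensor update S <- a S + lambda (S0 - S).

    The *same* coefficient is applied to both channels in the same
    iteration, so the relative deflection from baseline is identical for
    receptors and ligands and the ratio R_F/L_F never changes.
    """
    if a < 1.0:
        raise ValueError("adaptation coefficient must be >= 1")
    R = a * terminal.R_F + resetting_force(terminal.R_F, terminal.R_F0, params)
    L = a * terminal.L_F + resetting_force(terminal.L_F, terminal.L_F0, params)
    if R <= 0.0 or L <= 0.0:  # cannot occur for a >= 1, lam < 1
        logger.warning("sensor driven non-positive; clamping")
    terminal.R_F = max(R, SENSOR_FLOOR)
    terminal.L_F = max(L, SENSOR_FLOOR)
    return terminal


def apply_canonical_adaptation(
    terminal: FiberTerminal,
    local_R_T: float,
    local_L_T: float,
    params: ModelParams,
) -> FiberTerminal:
    """Independent per-channel relaxation toward the local target levels."""
    R = terminal.R_F + params.kappa * (local_R_T - terminal.R_F)
    L = terminal.L_F + params.kappa * (local_L_T - terminal.L_F)
    terminal.R_F = max(R, SENSOR_FLOOR)
    terminal.L_F = max(L, SENSOR_FLOOR)
    return terminal


def _move_base_probs(cue_free: bool, q_x: float) -> np.ndarray:
    if cue_free:
        rest = (1.0 - q_x) / 3.0
        return np.array([q_x, rest, rest, rest])
    return np.full(4, 0.25)


def propose_and_move(
    terminal: FiberTerminal,
    field: TargetField,
    others: Iterable[FiberTerminal],
    C: float,
    params: ModelParams,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """One biased random-walk step (reference implementation).

    Candidates are the four unit displacements; direction ``d`` is chosen
    with probability proportional to ``base(d) * exp(-beta D(candidate))``.
    Base probabilities are uniform except on cue-free squares, where the
    forward bias ``q_x`` applies.  Candidates leaving the field are
    rejected and the probability mass renormalized; if every candidate is
    off-field the terminal stays put.
    """
    if not terminal.mobile:
        return terminal.center
    cx, cy = terminal.center
    sq_x = min(int(cx), field.width - 1)
    sq_y = min(int(cy), field.height - 1)
    cue_free = bool(field.cue_free_mask[sq_y, sq_x])
    base = _move_base_probs(cue_free, params.q_x)
    others = list(others)
    logits = np.full(4, -np.inf)
    for d, (dx, dy) in enumerate(_DIRECTIONS):
        nx, ny = cx + dx, cy + dy
        if not (0.0 <= nx <= field.width and 0.0 <= ny <= field.height):
            continue
        probe = dataclasses.replace(terminal, center=(nx, ny),
                                    D_history=list(terminal.D_history))
        D = guidance_potential(probe, field, others, C, params)
        logits[d] = math.log(base[d]) - params.beta * D
    m = logits.max()
    if not np.isfinite(m):
        return terminal.center
    p = np.exp(logits - m)
    p /= p.sum()
    choice = int(np.searchsorted(np.cumsum(p), rng.uniform()))
    dx, dy = _DIRECTIONS[min(choice, 3)]
    terminal.center = (cx + dx, cy + dy)
    return terminal.center


# ---------------------------------------------------------------------------
# vectorized simulation engine
# ---------------------------------------------------------------------------

def _window_weights(
    px: np.ndarray,                # (P, n) candidate center x
    py: np.ndarray,                # (P, n)
    sq_cx: np.ndarray,             # (n, K) x-centers of the window squares
    sq_cy: np.ndarray,             # (n, K)
    valid: np.ndarray,             # (n, K, K) in-bounds mask (rows y, cols x)
    radius: float,
    sigma: float,
) -> np.ndarray:
    """Peak-normalized truncated-Gaussian weights, shape (P, n, K, K)."""
    dx = sq_cx[None, :, None, :] - px[:, :, None, None]     # (P, n, 1, K)
    dy = sq_cy[None, :, :, None] - py[:, :, None, None]     # (P, n, K, 1)
    d2 = dx * dx + dy * dy
    w = np.exp(-d2 / (2.0 * sigma * sigma))
    w *= (d2 <= radius * radius)
    w *= valid[None]
    return w


def simulate(
    scenario,
    params: Optional[ModelParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Run the full per-iteration dynamics for a scenario.

    Per iteration and terminal: evaluate D, append it to the history,
    compute the adaptation coefficient, apply the active adaptation mode's
    sensor update, then take one biased random-walk step.  All terminals
    are updated synchronously (fiber-fiber fields are rebuilt once per
    iteration from the pre-move state).  Identical ``(seed, params,
    scenario)`` yield a bit-identical result.

    ``scenario`` must provide ``field``, ``terminals``, ``params_overrides``,
    ``analysis_hints`` and ``tag`` (see :mod:`ephmap.scenarios`).
    """
    base = params or ModelParams()
    overrides = dict(getattr(scenario, "params_overrides", {}) or {})
    p = base.replace(**overrides)
    if rng is None:
        rng = np.random.default_rng(p.seed)

    field: TargetField = scenario.field
    terminals: List[FiberTerminal] = list(scenario.terminals)
    n = len(terminals)
    if n == 0:
        raise ValueError("scenario has no terminals")
    W, H = field.width, field.height

    pos = np.array([t.center for t in terminals], dtype=float)      # (n, 2)
    sens = np.array([[t.R_F, t.L_F] for t in terminals], dtype=float)
    base0 = np.array([[t.R_F0, t.L_F0] for t in terminals], dtype=float)
    mobile = np.array([t.mobile for t in terminals], dtype=bool)
    origin_u = np.array([t.origin_u for t in terminals], dtype=float)
    labels = np.array([t.label for t in terminals], dtype=object)
    radius = float(terminals[0].radius)
    sigma = p.sigma_frac * radius

    # window geometry: enough squares around the current center to cover
    # the footprints of all four candidate positions
    m = int(math.ceil(radius + 1.5))
    offs = np.arange(-m, m + 1)
    K = offs.size
    k_lin = np.arange(1, p.h + 1, dtype=float)
    k_norm = k_lin / k_lin.sum()
    hist = np.zeros((n, p.h))
    for i, t in enumerate(terminals):
        tail = np.asarray(t.D_history[-p.h:], dtype=float)
        if tail.size:
            hist[i, p.h - tail.size:] = tail

    res_R = field.resident_R_f
    res_L = field.resident_L_f
    cue_free = field.cue_free_mask
    Lt_flat = field.L_T.ravel()
    Rt_flat = field.R_T.ravel()

    stride = max(1, int(p.record_stride))
    rec_iters: List[int] = []
    rec_pos: List[np.ndarray] = []
    rec_sens: List[np.ndarray] = []
    rec_D: List[np.ndarray] = []
    max_x = pos[:, 0].copy()

    for it in range(p.n_iterations):
        C = fiber_weight(it, p)

        base_ix = np.floor(pos[:, 0]).astype(int)[:, None] + offs   # (n, K)
        base_iy = np.floor(pos[:, 1]).astype(int)[:, None] + offs
        inb_x = (base_ix >= 0) & (base_ix < W)
        inb_y = (base_iy >= 0) & (base_iy < H)
        valid = inb_y[:, :, None] & inb_x[:, None, :]               # (n, K, K)
        cix = np.clip(base_ix, 0, W - 1)
        ciy = np.clip(base_iy, 0, H - 1)
        flat = ciy[:, :, None] * W + cix[:, None, :]                # (n, K, K)
        sq_cx = base_ix + 0.5
        sq_cy = base_iy + 0.5

        # candidate centers: current + four unit displacements
        cand = pos[None, :, :] + np.concatenate(
            ([[[0.0, 0.0]]], _DIRECTIONS[:, None, :]), axis=0
        )                                                            # (5, n, 2)
        w = _window_weights(cand[:, :, 0], cand[:, :, 1],
                            sq_cx, sq_cy, valid, radius, sigma)      # (5,n,K,K)
        w0 = w[0]

        # fiber-fiber cue fields from every terminal's current footprint
        fidx = flat.ravel()
        wf = w0.reshape(n, -1)
        Rfld = np.bincount(fidx, weights=(sens[:, 0:1] * wf).ravel(),
                           minlength=H * W)
        Lfld = np.bincount(fidx, weights=(sens[:, 1:2] * wf).ravel(),
                           minlength=H * W)
        if res_R is not None:
            Rfld += res_R.ravel()
        if res_L is not None:
            Lfld += res_L.ravel()

        flat2 = flat.reshape(n, -1)
        w2 = w.reshape(5, n, -1)
        Rt_g = Rt_flat[flat2] * valid.reshape(n, -1)
        Lt_g = Lt_flat[flat2] * valid.reshape(n, -1)
        Rf_g = Rfld[flat2] * valid.reshape(n, -1)
        Lf_g = Lfld[flat2] * valid.reshape(n, -1)

        sum_Rt = np.einsum("pnk,nk->pn", w2, Rt_g)
        sum_Lt = np.einsum("pnk,nk->pn", w2, Lt_g)
        sum_Rf = np.einsum("pnk,nk->pn", w2, Rf_g)
        sum_Lf = np.einsum("pnk,nk->pn", w2, Lf_g)
        sum_w2 = np.einsum("pnk,pnk->pn", w2, w2)        # self-overlap
        sum_ww0 = np.einsum("pnk,nk->pn", w2, w2[0])     # overlap with own field

        R_F, L_F = sens[:, 0], sens[:, 1]
        # own contribution is part of the bincount fields; subtract it
        num = L_F * (sum_Rt[0] + R_F * sum_w2[0]
                     + C * np.maximum(sum_Rf[0] - R_F * sum_ww0[0], 0.0))
        den = R_F * (sum_Lt[0] + L_F * sum_w2[0]
                     + C * np.maximum(sum_Lf[0] - L_F * sum_ww0[0], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            D_cur = np.abs(np.log(num / den))
        D_cur = np.where((num <= 0) | (den <= 0), np.inf, D_cur)

        if not np.all(np.isfinite(D_cur)):
            bad = int(np.argmax(~np.isfinite(D_cur)))
            raise SimulationError(
                f"non-finite guidance potential at iteration {it}, terminal "
                f"{bad}: pos={pos[bad]}, sensors={sens[bad]}"
            )

        hist[:, :-1] = hist[:, 1:]
        hist[:, -1] = D_cur

        if p.adaptation_mode == "coadaptation":
            a = 1.0 + np.log1p(p.mu * (hist @ k_norm))
            upd = a[:, None] * sens + p.lam * (base0 - sens)
            sens[mobile] = np.maximum(upd[mobile], SENSOR_FLOOR)
        elif p.adaptation_mode == "canonical":
            wtot = np.maximum(w2[0].sum(axis=1), 1e-300)
            loc = np.stack([sum_Rt[0] / wtot, sum_Lt[0] / wtot], axis=1)
            upd = sens + p.kappa * (loc - sens)
            sens[mobile] = np.maximum(upd[mobile], SENSOR_FLOOR)

        # movement: softmax over candidates with updated own sensors
        R_F, L_F = sens[:, 0], sens[:, 1]
        num_c = L_F * (sum_Rt[1:] + R_F * sum_w2[1:]
                       + C * np.maximum(sum_Rf[1:] - R_F * sum_ww0[1:], 0.0))
        den_c = R_F * (sum_Lt[1:] + L_F * sum_w2[1:]
                       + C * np.maximum(sum_Lf[1:] - L_F * sum_ww0[1:], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            D_cand = np.abs(np.log(num_c / den_c))
        D_cand = np.where((num_c <= 0) | (den_c <= 0), np.inf, D_cand)  # (4, n)

        on_free = cue_free[
            np.minimum(pos[:, 1].astype(int), H - 1),
            np.minimum(pos[:, 0].astype(int), W - 1),
        ]
        bprob = np.full((4, n), 0.25)
        rest = (1.0 - p.q_x) / 3.0
        bprob[0, on_free] = p.q_x
        bprob[1:, on_free] = rest

        ok = (
            (cand[1:, :, 0] >= 0.0) & (cand[1:, :, 0] <= W)
            & (cand[1:, :, 1] >= 0.0) & (cand[1:, :, 1] <= H)
        )
        with np.errstate(divide="ignore"):
            logits = np.log(bprob) - p.beta * D_cand
        logits = np.where(ok, logits, -np.inf)
        mx = logits.max(axis=0)
        movable = mobile & np.isfinite(mx)
        prob = np.exp(logits - np.where(np.isfinite(mx), mx, 0.0))
        prob = np.where(np.isfinite(logits), prob, 0.0)
        tot = prob.sum(axis=0)
        prob = np.divide(prob, tot, out=np.zeros_like(prob), where=tot > 0)
        draws = rng.uniform(size=n)
        cum = np.cumsum(prob, axis=0)
        choice = np.minimum((draws[None, :] > cum).sum(axis=0), 3)
        step = _DIRECTIONS[choice]
        pos[movable] += step[movable]
        np.maximum(max_x, pos[:, 0], out=max_x)

        if (it + 1) % 1000 == 0:
            logger.debug("iteration %d/%d: mean D %.4f", it + 1,
                         p.n_iterations, float(np.mean(D_cur)))
        if (it + 1) % stride == 0 or it == p.n_iterations - 1:
            rec_iters.append(it)
            rec_pos.append(pos.copy())
            rec_sens.append(sens.copy())
            rec_D.append(D_cur.copy())

    # write the final state back onto the terminal objects
    for i, t in enumerate(terminals):
        t.center = (float(pos[i, 0]), float(pos[i, 1]))
        t.R_F = float(sens[i, 0])
        t.L_F = float(sens[i, 1])
        t.D_history = list(hist[i])

    hints = dict(getattr(scenario, "analysis_hints", {}) or {})
    hints.setdefault("field_width", float(W))
    hints.setdefault("field_height", float(H))

    return SimulationResult(
        iterations=np.array(rec_iters),
        positions=np.array(rec_pos),
        sensors=np.array(rec_sens),
        potentials=np.array(rec_D),
        max_x=max_x,
        origin_u=origin_u,
        baselines=base0,
        labels=labels,
        mobile=mobile,
        params=p,
        scenario_tag=getattr(scenario, "tag", ""),
        analysis_hints=hints,
    )
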