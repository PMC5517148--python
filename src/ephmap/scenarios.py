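"""Builders assembling target field + terminal population + parameter
overrides for each simulated experiment.

Conventions: the target x-axis runs anterior (x = 0) to posterior; a
terminal of retinal origin ``u`` (0 nasal, 1 temporal) balances its
signaling at the ideal position ``x* = W (1 - u)`` (temporal -> anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np

from .gradients import GradientSpec, TargetField, build_target_field, retinal_sensor_levels
from .model import FiberTerminal

__all__ = [
    "Scenario",
    "ConfigurationError",
    "mapping_scenario",
    "gap_assay_scenario",
    "tectal_entry_scenario",
    "knockin_scenario",
    "innervation_scenario",
    "ideal_position",
]

_CUE_NAMES = ("ephrin", "Eph")


class ConfigurationError(ValueError):
    """Invalid scenario configuration."""


@dataclass
class Scenario:
    field: TargetField
    terminals: List[FiberTerminal]
    params_overrides: Dict = dc_field(default_factory=dict)
    analysis_hints: Dict[str, float] = dc_field(default_factory=dict)
    tag: str = ""

    def __post_init__(self) -> None:
        for key, val in self.analysis_hints.items():
            if key.endswith(("_start", "_end")) and not (
                0 <= val <= self.field.width
            ):
                raise ConfigurationError(
                    f"analysis hint {key}={val} outside field [0, "
                    f"{self.field.width}]"
                )
        declared = self.params_overrides.get("n_terminals")
        if declared is not None and declared != len(self.terminals):
            raise ConfigurationError(
                f"{len(self.terminals)} terminals but n_terminals={declared}"
            )

    def to_dict(self) -> Dict:
        """Structural dump (round-trips through YAML/JSON)."""
        f = self.field
        d = {
            "field": {
                "width": f.width,
                "height": f.height,
                "L_T": np.asarray(f.L_T).tolist(),
                "R_T": np.asarray(f.R_T).tolist(),
            },
            "terminals": [
                {
                    "center": [float(t.center[0]), float(t.center[1])],
                    "origin_u": t.origin_u,
                    "R_F0": t.R_F0,
                    "L_F0": t.L_F0,
                    "R_F": t.R_F,
                    "L_F": t.L_F,
                    "radius": t.radius,
                    "mobile": t.mobile,
                    "knockin_R": t.knockin_R,
                    "label": t.label,
                }
                for t in self.terminals
            ],
            "params_overrides": dict(self.params_overrides),
            "analysis_hints": dict(self.analysis_hints),
            "tag": self.tag,
        }
        if f.resident_L_f is not None:
            d["field"]["resident_L_f"] = np.asarray(f.resident_L_f).tolist()
        if f.resident_R_f is not None:
            d["field"]["resident_R_f"] = np.asarray(f.resident_R_f).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "Scenario":
        fd = d["field"]
        field = TargetField(
            width=fd["width"],
            height=fd["height"],
            L_T=np.asarray(fd["L_T"], dtype=float),
            R_T=np.asarray(fd["R_T"], dtype=float),
            resident_L_f=(
                np.asarray(fd["resident_L_f"], dtype=float)
                if "resident_L_f" in fd else None
            ),
            resident_R_f=(
                np.asarray(fd["resident_R_f"], dtype=float)
                if "resident_R_f" in fd else None
            ),
        )
        terminals = [
            FiberTerminal(
                center=tuple(t["center"]),
                origin_u=t["origin_u"],
                R_F0=t["R_F0"],
                L_F0=t["L_F0"],
                R_F=t["R_F"],
                L_F=t["L_F"],
                radius=t["radius"],
                mobile=t["mobile"],
                knockin_R=t["knockin_R"],
                label=t["label"],
            )
            for t in d["terminals"]
        ]
        return cls(
            field=field,
            terminals=terminals,
            params_overrides=dict(d.get("params_overrides", {})),
            analysis_hints=dict(d.get("analysis_hints", {})),
            tag=d.get("tag", ""),
        )


def adapted_sensor_scale(
    level: float,
    params: Optional["object"] = None,
    radius: float = 3.5,
) -> float:
    """Equilibrium co-adaptation scale of a terminal dwelling on a plateau.

    A lone terminal sitting on a homogeneous cue field of the given level
    settles where the adaptation gain balances the resetting pull,
    ``ln(1 + mu D(g)) = lambda (1 - 1/g)`` with
    ``D(g) = ln(1 + level / (g s))`` and ``s`` the footprint's relative
    cis efficiency ``sum w^2 / sum w``.  Used to pre-adapt populations
    that grew on the cue before the simulated observation window.
    """
    from scipy.optimize import brentq

    from .model import ModelParams, _footprint_arrays

    p = params or ModelParams()
    sigma = p.sigma_frac * radius
    big = 100
    _, _, w = _footprint_arrays(big / 2, big / 2, radius, sigma, big, big)
    s = float(np.sum(w * w) / np.sum(w))
    if level <= 0:
        return 1.0

    def excess(g):
        D = np.log1p(level / (g * s))
        return np.log1p(p.mu * D) - p.lam * (1.0 - 1.0 / g)

    if excess(1.0 + 1e-9) <= 0:
        return 1.0
    return float(brentq(excess, 1.0 + 1e-9, 1e6))


def ideal_position(u, width: float):
    """Ideal anterior-posterior target position for retinal origin ``u``."""
    return width * (1.0 - np.asarray(u, dtype=float))


def _counter_field(width: int, height: int,
                   steepness: float = 3.0) -> TargetField:
    """Standard tectal counter-gradient field (ephrin-A posterior-high)."""
    return build_target_field(
        width, height,
        L_spec=GradientSpec(shape="exponential_counter", rising=True,
                            steepness=steepness),
        R_spec=GradientSpec(shape="exponential_counter", rising=False,
                            steepness=steepness),
    )


def _sample_origins(n: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Equally sampled retinal origins on [lo, hi]."""
    return lo + (hi - lo) * (np.arange(n) + 0.5) / n


def _make_terminal(u: float, x: float, y: float, label: str = "",
                   mobile: bool = True, scale: float = 1.0,
                   baseline_scale: float = 1.0) -> FiberTerminal:
    # `scale` deflects the current sensors only (decays back via the
    # resetting force); `baseline_scale` also moves the S(0) anchor.
    R0, L0 = retinal_sensor_levels(u)
    return FiberTerminal(
        center=(x, y),
        origin_u=float(u),
        R_F0=R0 * baseline_scale,
        L_F0=L0 * baseline_scale,
        R_F=R0 * baseline_scale * scale,
        L_F=L0 * baseline_scale * scale,
        mobile=mobile,
        label=label,
    )


def _scatter(rng: np.random.Generator, n: int, x_lo: float, x_hi: float,
             height: int) -> np.ndarray:
    xs = rng.uniform(x_lo, x_hi, size=n)
    ys = rng.uniform(1.0, height - 1.0, size=n)
    return np.stack([xs, ys], axis=1)


def mapping_scenario(
    n: int = 200,
    adaptation_mode: str = "coadaptation",
    seed: int = 0,
    width: int = 50,
    height: int = 8,
    n_iterations: int = 30000,
    u_lo: float = 0.0,
    u_hi: float = 1.0,
) -> Scenario:
    """Topographic mapping on the counter-graded 50 x 8 target field.

    Terminals are sampled equally from the retinal origin interval and
    placed uniformly at random on the field; the fiber-fiber ramp is
    active.
    """
    if n < 1:
        raise ConfigurationError("need at least one terminal")
    rng = np.random.default_rng(seed)
    field = _counter_field(width, height)
    origins = _sample_origins(n, u_lo, u_hi)
    centers = _scatter(rng, n, 1.0, width - 1.0, height)
    terminals = [
        _make_terminal(u, x, y)
        for u, (x, y) in zip(origins, centers)
    ]
    return Scenario(
        field=field,
        terminals=terminals,
        params_overrides={
            "n_terminals": n,
            "n_iterations": n_iterations,
            "adaptation_mode": adaptation_mode,
            "ramp": True,
            "seed": seed,
        },
        analysis_hints={},
        tag=f"mapping_{adaptation_mode}",
    )


def gap_assay_scenario(
    first_cue: str = "ephrin",
    second_cue: str = "ephrin",
    gap: int = 20,
    naive: bool = False,
    n: int = 12,
    n_iterations: int = 2000,
    seed: int = 0,
    level: float = 4.0,
    width: int = 200,
    height: int = 8,
    corridor: int = 20,
    field1_width: int = 30,
    start_zone: float = 10.0,
    origin_u: float = 0.5,
) -> Scenario:
    """Simulated in-vitro gap assay on a 200 x 8 step-function field.

    Two plateaus of level 4 separated by ``gap`` cue-free units.  Naive
    terminals start on the corridor before the first field; adapted
    terminals start on the trailing ``start_zone`` units of the first
    field with their sensors pre-set to the on-field adaptation
    equilibrium (they grew on that substrate before the observation
    window).  The fiber-fiber ramp is switched off (C = C0 = 1) and the
    cue-free forward bias q_x applies.
    """
    if first_cue not in _CUE_NAMES or second_cue not in _CUE_NAMES:
        raise ConfigurationError(f"cue must be one of {_CUE_NAMES}")
    if gap < 0:
        raise ConfigurationError("gap must be >= 0")
    f1_start = corridor
    f1_end = f1_start + field1_width
    f2_start = f1_end + gap
    if f2_start >= width:
        raise ConfigurationError(
            f"gap {gap} leaves no room for the second field on width {width}"
        )
    segs1 = (f1_start / width, f1_end / width, level)
    segs2 = (f2_start / width, 1.0, level)
    L_segs = tuple(
        s for s, cue in ((segs1, first_cue), (segs2, second_cue))
        if cue == "ephrin"
    )
    R_segs = tuple(
        s for s, cue in ((segs1, first_cue), (segs2, second_cue))
        if cue == "Eph"
    )
    field = build_target_field(
        width, height,
        L_spec=GradientSpec(shape="step", segments=L_segs) if L_segs
        else GradientSpec(shape="none"),
        R_spec=GradientSpec(shape="step", segments=R_segs) if R_segs
        else GradientSpec(shape="none"),
    )
    rng = np.random.default_rng(seed)
    if naive:
        centers = _scatter(rng, n, 1.0, corridor - 1.0, height)
        scale = 1.0
    else:
        centers = _scatter(rng, n, f1_end - start_zone, f1_end - 1.0, height)
        scale = adapted_sensor_scale(level)
    terminals = [
        _make_terminal(origin_u, x, y, scale=scale) for (x, y) in centers
    ]
    return Scenario(
        field=field,
        terminals=terminals,
        params_overrides={
            "n_terminals": n,
            "n_iterations": n_iterations,
            "ramp": False,
            "C0": 1.0,
            "seed": seed,
            "record_stride": 50,
        },
        analysis_hints={
            "first_field_start": float(f1_start),
            "first_field_end": float(f1_end),
            "gap_start": float(f1_end),
            "second_field_start": float(f2_start),
        },
        tag=(
            f"gap_{first_cue}_{second_cue}_g{gap}"
            + ("_naive" if naive else "_adapted")
        ),
    )


def tectal_entry_scenario(
    n: int = 200,
    deflection: float = 30.0,
    seed: int = 0,
    corridor: int = 5,
    target_width: int = 50,
    height: int = 8,
    n_iterations: int = 30000,
    tectal_steepness: float = 3.0,
    retinal_steepness: float = 1.0,
) -> Scenario:
    """Entry into a graded target field from a cue-free corridor.

    The target counter-gradient is steeper than the retinal one, so the
    reverse-signaling (EphA) boundary at the anterior entrance exceeds
    every fiber's own ephrin/Eph balance ratio and repels naive terminals
    of all origins.  The adapted population has both sensors of every
    terminal deflected by ``deflection`` (ratio preserved, cis signaling
    dominating, hence desensitized); ``deflection = 1`` is the naive
    control.  Fiber-fiber ramp off, q_x forward bias on the corridor.
    """
    if deflection < 1:
        raise ConfigurationError("deflection must be >= 1")
    width = corridor + target_width
    graded = _counter_field(target_width, height, steepness=tectal_steepness)
    L = np.zeros((height, width))
    R = np.zeros((height, width))
    L[:, corridor:] = graded.L_T
    R[:, corridor:] = graded.R_T
    field = TargetField(width=width, height=height, L_T=L, R_T=R)
    rng = np.random.default_rng(seed)
    origins = _sample_origins(n)
    centers = _scatter(rng, n, 1.0, corridor - 1.0, height)
    retinal = GradientSpec(shape="exponential_counter",
                           steepness=retinal_steepness)
    terminals = []
    for u, (x, y) in zip(origins, centers):
        R0, L0 = retinal_sensor_levels(u, retinal)
        terminals.append(FiberTerminal(
            center=(x, y), origin_u=float(u),
            R_F0=R0, L_F0=L0,
            R_F=R0 * deflection, L_F=L0 * deflection,
        ))
    return Scenario(
        field=field,
        terminals=terminals,
        params_overrides={
            "n_terminals": n,
            "n_iterations": n_iterations,
            "ramp": False,
            "C0": 0.0,
            "seed": seed,
        },
        analysis_hints={"target_start": float(corridor)},
        tag=f"entry_x{deflection:g}",
    )


def knockin_scenario(
    R_ki: float,
    n: int = 200,
    seed: int = 0,
    n_iterations: int = 30000,
    **mapping_kwargs,
) -> Scenario:
    """EphA knock-in in every second fiber of a mapping scenario.

    Knock-in fibers gain ``R_ki`` receptor on top of their graded baseline;
    their axonal ligand is reduced reciprocally to the receptor increase,
    ``L_F0 <- L_F0 / (1 + R_ki / R_F0)``.
    """
    if R_ki < 0:
        raise ConfigurationError("R_ki must be >= 0")
    scn = mapping_scenario(n=n, seed=seed, n_iterations=n_iterations,
                           **mapping_kwargs)
    for i, t in enumerate(scn.terminals):
        if i % 2 == 1 and R_ki > 0:
            base_R = t.R_F0
            t.knockin_R = R_ki
            t.R_F0 = base_R + R_ki
            t.L_F0 = t.L_F0 / (1.0 + R_ki / base_R)
            t.R_F = t.R_F0
            t.L_F = t.L_F0
            t.label = "ki"
        else:
            t.label = "wt"
    scn.tag = f"knockin_Rki{R_ki:g}"
    return scn


_INNERVATION_VARIANTS = (
    "single_fibers", "expansion", "no_expansion_remnants",
    "compression", "mismatch", "reversal",
)


def _resident_population(
    rng: np.random.Generator,
    n: int,
    width: int,
    height: int,
    u_lo: float = 0.0,
    u_hi: float = 1.0,
) -> List[FiberTerminal]:
    """Frozen, properly mapped fibers occupying their ideal positions."""
    origins = _sample_origins(n, u_lo, u_hi)
    xs = np.clip(ideal_position(origins, width), 1.0, width - 1.0)
    ys = rng.uniform(1.0, height - 1.0, size=n)
    return [
        _make_terminal(u, x, y, label="resident", mobile=False)
        for u, x, y in zip(origins, xs, ys)
    ]


def innervation_scenario(
    variant: str,
    seed: int = 0,
    n: Optional[int] = None,
    n_iterations: int = 30000,
    height: int = 8,
) -> Scenario:
    """Retinal-subset / target-size manipulation experiments.

    Variants: ``single_fibers`` (one randomly chosen fiber per run; pool
    runs over seeds), ``expansion`` (nasal half retina on a full field),
    ``no_expansion_remnants`` (idem, plus a frozen full resident
    innervation), ``compression`` (full retina on an anterior half field),
    ``mismatch`` (nasal half retina on an anterior half field) and
    ``reversal`` (nasal fibers growing into a field holding a properly
    mapped frozen nasal projection; fiber-fiber onset advanced to
    j = 2000).
    """
    if variant not in _INNERVATION_VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose from {_INNERVATION_VARIANTS}"
        )
    rng = np.random.default_rng(seed)
    width = 50
    # plasticity experiments need fiber-fiber signals to outgrow the target
    # cues once C(i) has ramped up (C0 exposed for sensitivity checks)
    overrides = {"n_iterations": n_iterations, "ramp": True, "seed": seed,
                 "C0": 10.0}
    hints: Dict[str, float] = {}

    if variant == "single_fibers":
        field = _counter_field(width, height)
        u = float(rng.uniform())
        x, y = _scatter(rng, 1, 1.0, width - 1.0, height)[0]
        terminals = [_make_terminal(u, x, y)]
        overrides["n_terminals"] = 1
    elif variant == "expansion":
        n = n or 100
        field = _counter_field(width, height)
        origins = _sample_origins(n, 0.0, 0.5)
        centers = _scatter(rng, n, 1.0, width - 1.0, height)
        terminals = [_make_terminal(u, x, y)
                     for u, (x, y) in zip(origins, centers)]
        overrides["n_terminals"] = n
    elif variant == "no_expansion_remnants":
        n = n or 100
        field = _counter_field(width, height)
        residents = _resident_population(rng, 2 * n, width, height)
        origins = _sample_origins(n, 0.0, 0.5)
        centers = _scatter(rng, n, 1.0, width - 1.0, height)
        terminals = [_make_terminal(u, x, y)
                     for u, (x, y) in zip(origins, centers)] + residents
        overrides["n_terminals"] = len(terminals)
    elif variant in ("compression", "mismatch"):
        full = _counter_field(width, height)
        half_w = width // 2
        field = TargetField(
            width=half_w, height=height,
            L_T=full.L_T[:, :half_w].copy(),
            R_T=full.R_T[:, :half_w].copy(),
        )
        if variant == "compression":
            n = n or 200
            origins = _sample_origins(n, 0.0, 1.0)
        else:
            n = n or 100
            origins = _sample_origins(n, 0.0, 0.5)
        centers = _scatter(rng, n, 1.0, half_w - 1.0, height)
        terminals = [_make_terminal(u, x, y)
                     for u, (x, y) in zip(origins, centers)]
        overrides["n_terminals"] = n
        width = half_w
    else:  # reversal
        n = n or 100
        field = _counter_field(width, height)
        residents = _resident_population(rng, n, width, height, 0.0, 0.5)
        origins = _sample_origins(n, 0.0, 0.5)
        centers = _scatter(rng, n, 1.0, width - 1.0, height)
        terminals = [_make_terminal(u, x, y, label="new")
                     for u, (x, y) in zip(origins, centers)] + residents
        overrides["n_terminals"] = len(terminals)
        overrides["j_onset"] = 2000
    return Scenario(
        field=field,
        terminals=terminals,
        params_overrides=overrides,
        analysis_hints=hints,
        tag=f"innervation_{variant}",
    )
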