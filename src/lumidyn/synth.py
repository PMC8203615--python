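"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its arguments and an integer seed, and
records its ground truth so recovery tests can compare against it.  Default
designs emulate the study conditions: steady-state progress curves at five
substrate concentrations in triplicate; stopped-flow fluorescence traces at
ten substrate concentrations with seven replicates; decay traces at 2.2 uM
substrate and 0.05 uM enzyme; 96-well plates with four negative and four
positive control wells and substrate injection 10 s into the reading; and
low-rank-plus-noise descriptor/activity matrices with n = 25 variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anm import CaStructure
from .fitting import Trace, TraceDataset
from .mechanisms import (
    MechanismKind,
    MechanismSpec,
    ObservationModel,
    observe_trace,
    simulate_mechanism,
)
from .screening import PlateReading, PLSDataset, Well

__all__ = [
    "NoiseSpec",
    "PlateLayoutSpec",
    "gen_kinetic_dataset",
    "gen_plate",
    "gen_toy_structure",
    "gen_pls_data",
    "gen_decay_trace",
    "STEADY_STATE_DESIGN",
    "TRANSIENT_DESIGN",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: sd = level*|signal| + floor (proportional) or
    sd = level (additive); the floor keeps sigma positive for zero signal."""

    kind: str = "gaussian_proportional"
    level: float = 0.01
    floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_proportional", "gaussian_additive"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")

    def sigma(self, signal: np.ndarray) -> np.ndarray:
        if self.kind == "gaussian_proportional":
            return self.level * np.abs(signal) + self.floor
        return np.full_like(signal, self.level + self.floor)

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.level == 0:
            return np.array(signal, dtype=float, copy=True)
        return signal + rng.normal(0.0, self.sigma(signal))


@dataclass(frozen=True)
class KineticDesign:
    S_concentrations: tuple[float, ...]   # uM
    E0: float                             # uM
    n_replicates: int
    t_max: float                          # s
    n_points: int = 80

    def __post_init__(self) -> None:
        if not self.S_concentrations or self.n_replicates < 1 or self.n_points < 4:
            raise ValueError("invalid kinetic design")


# study-style defaults: 5 substrate concentrations in triplicate for
# progress curves; 10 concentrations with 7 replicates for stopped flow
STEADY_STATE_DESIGN = KineticDesign(
    S_concentrations=(0.5, 1.0, 2.2, 5.0, 10.0), E0=0.05,
    n_replicates=3, t_max=600.0, n_points=80,
)
TRANSIENT_DESIGN = KineticDesign(
    S_concentrations=(5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 55.0, 70.0, 85.0, 100.0),
    E0=1.0, n_replicates=7, t_max=0.5, n_points=100,
)


def gen_kinetic_dataset(
    spec: MechanismSpec,
    obs: ObservationModel,
    design: KineticDesign,
    noise: NoiseSpec,
) -> TraceDataset:
    """Simulate a multi-concentration replicate dataset with noise.

    Ground truth (rate constants, observation scale, design) is stored in
    ``dataset.meta`` for recovery tests.
    """
    rng = np.random.default_rng(noise.seed)
    traces = []
    t = np.linspace(0.0, design.t_max, design.n_points)
    for S0 in design.S_concentrations:
        traj = simulate_mechanism(spec, {"E": design.E0, "S": S0}, t)
        _, clean = observe_trace(traj, obs)
        for rep in range(design.n_replicates):
            sig = noise.apply(clean, rng)
            traces.append(Trace(
                trace_id=f"S{S0:g}_r{rep}",
                time=t, signal=sig, E0=design.E0, S0=S0,
                observable=obs.kind, replicate=rep,
                sigma=noise.sigma(clean) if noise.level > 0 else None,
            ))
    return TraceDataset(traces=traces, meta={
        "true_rates": spec.rates.to_dict(),
        "mechanism": spec.kind.value,
        "obs": {"kind": obs.kind, "f": obs.f, "a": obs.a, "b": obs.b},
        "design": design,
        "noise": noise,
    })


@dataclass(frozen=True)
class PlateLayoutSpec:
    """96-well-style layout: control wells plus variants with known relative
    activities; baseline-then-step signal around the injection event."""

    variant_activities: tuple[float, ...]       # relative to positive control
    n_negative: int = 4
    n_positive: int = 4
    injection_time: float = 10.0                # s
    t_max: float = 30.0
    n_points: int = 61
    baseline: float = 10.0                      # counts, instrument background
    positive_step: float = 80.0                 # counts, positive-control jump

    def __post_init__(self) -> None:
        if self.n_negative < 1 or self.n_positive < 1:
            raise ValueError("layout needs at least one negative and one positive well")


def gen_plate(
    layout: PlateLayoutSpec,
    noise: NoiseSpec,
    spike_wells: dict[str, float] | None = None,
) -> PlateReading:
    """Baseline-then-step plate signal scaled per well by its true activity.

    ``spike_wells`` plants single-point outliers (well id -> spike height
    added to one post-injection point) to exercise the Tukey filtering.
    Ground truth is attached as the ``truth`` attribute.
    """
    rng = np.random.default_rng(noise.seed)
    t = np.linspace(0.0, layout.t_max, layout.n_points)
    step = (t >= layout.injection_time).astype(float)
    wells = []

    def make(well_id, role, activity):
        clean = layout.baseline + activity * layout.positive_step * step
        sig = noise.apply(clean, rng) if noise.level > 0 else clean.copy()
        if spike_wells and well_id in spike_wells:
            post = np.nonzero(t >= layout.injection_time + 0.2)[0]
            sig[post[len(post) // 2]] += spike_wells[well_id]
        wells.append(Well(well_id=well_id, role=role, signal=sig))

    for i in range(layout.n_negative):
        make(f"neg{i + 1}", "negative", 0.0)
    for i in range(layout.n_positive):
        make(f"pos{i + 1}", "positive", 1.0)
    for i, act in enumerate(layout.variant_activities):
        make(f"var{i + 1}", "variant", act)

    plate = PlateReading(time=t, wells=wells, injection_time=layout.injection_time)
    plate.truth = {"activities": dict(zip(
        [f"var{i + 1}" for i in range(len(layout.variant_activities))],
        layout.variant_activities,
    ))}
    return plate


def gen_toy_structure(
    n: int, geometry: str = "helix", jitter: float = 0.0, seed: int = 0,
    label: str | None = None,
) -> CaStructure:
    """Ideal-geometry Calpha trace for network-model tests.

    ``helix``: 1.5 A rise and 100 degrees twist per residue, 2.3 A radius.
    ``extended``: zigzag strand with 3.5 A spacing.  ``two-domain``: two
    helices joined by a short linker, offset in space.
    """
    rng = np.random.default_rng(seed)
    if geometry == "helix":
        if n < 4:
            raise ValueError("helix needs n >= 4 for a non-collinear trace")
        coords = _helix(n)
    elif geometry == "extended":
        if n < 3:
            raise ValueError("need n >= 3")
        i = np.arange(n)
        # zigzag strand with a gentle out-of-plane wave so the contact
        # network is genuinely three-dimensional
        coords = np.column_stack([
            3.3 * i, 1.0 * (i % 2), 0.8 * np.sin(0.9 * i),
        ])
    elif geometry == "two-domain":
        if n < 8:
            raise ValueError("two-domain geometry needs n >= 8")
        n1 = n // 2
        a = _helix(n1)
        # second lobe offset but still within spring-network contact range
        b = _helix(n - n1) + np.array([8.0, 3.0, a[-1, 2] + 4.0])
        coords = np.vstack([a, b])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    keys = [("A", i + 1, "") for i in range(n)]
    return CaStructure(residue_keys=keys, coords=coords,
                       label=label or f"toy-{geometry}-{n}")


def _helix(n: int) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([
        2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i,
    ])


def gen_pls_data(
    n: int = 25,
    p: int = 10,
    q: int = 1,
    n_latent: int = 1,
    noise_x: float = 0.05,
    noise_y: float = 0.05,
    seed: int = 0,
) -> PLSDataset:
    """Low-rank-plus-noise descriptor/activity matrices.

    X = scores @ loadings.T + noise, Y = scores @ coefficients + noise; the
    generating scores/loadings/coefficients are stored as the ``truth``
    attribute.  Defaults mirror a 25-variant, 10-descriptor screen.
    """
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n, n_latent))
    P_load = rng.normal(size=(p, n_latent))
    C = rng.normal(size=(n_latent, q))
    X = T @ P_load.T + noise_x * rng.normal(size=(n, p))
    Y = T @ C + noise_y * rng.normal(size=(n, q))
    data = PLSDataset(X=X, Y=Y)
    data.truth = {"scores": T, "loadings": P_load, "coefficients": C}
    return data


def gen_decay_trace(
    model: str = "exponential",
    t_half: float = 100.0,
    I0: float = 1000.0,
    hill: float = 2.0,
    duration: float | None = None,
    n_points: int = 200,
    noise: NoiseSpec = NoiseSpec(level=0.0),
    S0: float = 2.2,
    E0: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic bioluminescence decay trace (default condition: 2.2 uM
    substrate, 0.05 uM enzyme).

    Exponential: I = I0*exp(-ln2 * t/t_half); logistic: I = I0/(1+(t/tau)^h)
    with tau = t_half.  Returns (time, signal, truth).
    """
    rng = np.random.default_rng(noise.seed)
    duration = duration or 8.0 * t_half
    t = np.linspace(0.0, duration, n_points)
    if model == "exponential":
        clean = I0 * np.exp(-np.log(2.0) * t / t_half)
    elif model == "logistic":
        clean = I0 / (1.0 + (t / t_half) ** hill)
    else:
        raise ValueError("model must be 'exponential' or 'logistic'")
    sig = noise.apply(clean, rng) if noise.level > 0 else clean
    sig = np.maximum(sig, 1e-9 * I0)  # decay fits require positive signal
    truth = {"model": model, "t_half": t_half, "I0": I0, "hill": hill,
             "S0_uM": S0, "E0_uM": E0}
    return t, sig, truth
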