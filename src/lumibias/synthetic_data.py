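"""Seeded synthetic plate-assay generator.

No raw traces from the emulated study design are public, so the pipeline is
exercised end-to-end on simulated plates that reproduce its statistical
structure: a decade concentration series from 1 pM to 25 µM, duplicate
wells, at least three independent experiments, reference agonists present in
every experiment, matched solvent controls per condition, and 2 h of
post-agonist monitoring.

Trace model
-----------
Each well's expected signal is a slowly decaying baseline plus, after
injection, an agonist term with a rise-then-decay envelope::

    f(t) = B exp(-kd t)                                   t < t_inj
    f(t) = B exp(-kd t)
           + B E occ(c) (1 - exp(-kr (t-t_inj))) exp(-kd (t-t_inj))   t >= t_inj

where ``occ(c) = c^h / (c^h + EC50^h)`` is fractional receptor occupancy
(Hill coefficient h, default 1) and ``E`` the compound's efficacy as a
fraction of the reference agonist's.  The agonist AUC is therefore exactly
``B E occ(c) I`` with a closed-form ``I``, so the downstream normalized AUC
lies on a logistic in concentration that can be checked analytically.

Noise has three components matching the correction steps the real pipeline
applies: a per-well multiplicative lognormal factor (interwell variability),
additive Gaussian read noise per reading, and a per-experiment
multiplicative lognormal scale (day-to-day signal differences).

Randomness is split counter-style: each well draws from a generator seeded
by ``SeedSequence(master_seed, spawn_key=(experiment, pathway, compound,
concentration index, replicate))``, so adding compounds or concentrations
never perturbs existing wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    PATHWAYS,
    VARIANT_WT,
    VARIANTS,
    PlateExperiment,
    TimeLuminescenceTrace,
    WellAnnotation,
)

#: The in-well decade series of the emulated design, ascending (molar):
#: 1 pM, 10 pM, 100 pM, 1 nM, 10 nM, 100 nM, 1 µM, 10 µM, 25 µM.
DEFAULT_CONCENTRATIONS = (
    1e-12, 1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 2.5e-5,
)


@dataclass(frozen=True)
class CompoundSpec:
    """Generative ground truth for one compound.

    ``true_ec50`` maps pathway → molar EC50; ``true_emax`` maps pathway →
    efficacy in % of the reference agonist's maximal response (the reference
    itself is specified with 100, or its observed value on that scale).
    """

    name: str
    true_ec50: dict[str, float]
    true_emax: dict[str, float]
    hill: float = 1.0

    def __post_init__(self) -> None:
        for p, v in self.true_ec50.items():
            if p not in PATHWAYS:
                raise ValueError(f"unknown pathway {p!r} in {self.name}")
            if v <= 0:
                raise ValueError(f"true_EC50 must be > 0 (got {v} for {self.name}/{p})")
        for p, v in self.true_emax.items():
            if v < 0:
                raise ValueError(f"true_Emax must be >= 0 (got {v} for {self.name}/{p})")
        if self.hill <= 0:
            raise ValueError(f"hill slope must be > 0 (got {self.hill})")

    def occupancy(self, concentration: float, pathway: str) -> float:
        """Fractional occupancy c^h / (c^h + EC50^h); 0 at c = 0."""
        if concentration < 0:
            raise ValueError(f"negative concentration {concentration}")
        if concentration == 0:
            return 0.0
        ec50 = self.true_ec50[pathway]
        ch = concentration**self.hill
        return ch / (ch + ec50**self.hill)


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes: all sigmas ≥ 0; zeros give a deterministic plate.

    ``well_sigma`` and ``experiment_sigma`` scale the *whole* trace and are
    therefore (by design) removed by interwell correction — they exist to
    exercise exactly the variability the correction steps target.
    ``response_sigma`` scales only the agonist term per well (variable
    effector expression), so it survives correction and is what gives
    realistic spread to fitted parameters and per-experiment β values.
    ``read_sigma`` is additive instrument noise per reading, in counts.
    """

    well_sigma: float = 0.1  # lognormal sigma of the per-well scale
    read_sigma: float = 50.0  # additive Gaussian sigma per reading (counts)
    experiment_sigma: float = 0.2  # lognormal sigma of the per-experiment scale
    response_sigma: float = 0.15  # lognormal sigma of the per-well agonist amplitude

    def __post_init__(self) -> None:
        if min(self.well_sigma, self.read_sigma, self.experiment_sigma, self.response_sigma) < 0:
            raise ValueError("noise sigmas must be nonnegative")


@dataclass(frozen=True)
class KineticModel:
    """Baseline level (counts) and rise/decay rates (1/s) of the trace model."""

    baseline: float = 1e4
    rise_rate: float = 1.0 / 300.0  # signal develops over ~5 min
    decay_rate: float = 1.0 / 3600.0  # substrate consumption over ~1 h

    def __post_init__(self) -> None:
        if self.baseline <= 0 or self.rise_rate <= 0 or self.decay_rate <= 0:
            raise ValueError("kinetic parameters must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of a simulated study."""

    compounds: tuple[CompoundSpec, ...]
    reference: str
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    n_experiments: int = 3
    n_replicate_wells: int = 2
    read_interval: float = 60.0
    equilibration_duration: float = 600.0
    post_injection_duration: float = 7200.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    kinetic: KineticModel = field(default_factory=KineticModel)
    pathways: tuple[str, ...] = PATHWAYS
    receptor_variant: str = VARIANT_WT
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.compounds, list):
            object.__setattr__(self, "compounds", tuple(self.compounds))
        if isinstance(self.concentrations, list):
            object.__setattr__(self, "concentrations", tuple(self.concentrations))
        names = [c.name for c in self.compounds]
        if self.reference not in names:
            raise ValueError(f"reference {self.reference!r} not among compounds {names}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names")
        concs = np.asarray(self.concentrations, dtype=float)
        if np.any(concs <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(concs) <= 0):
            raise ValueError("concentrations must be sorted ascending")
        if self.n_experiments < 1 or self.n_replicate_wells < 1:
            raise ValueError("n_experiments and n_replicate_wells must be >= 1")
        if min(self.read_interval, self.equilibration_duration, self.post_injection_duration) <= 0:
            raise ValueError("durations and read interval must be positive")
        if self.receptor_variant not in VARIANTS:
            raise ValueError(f"unknown receptor variant {self.receptor_variant!r}")

    @property
    def time_grid(self) -> np.ndarray:
        total = self.equilibration_duration + self.post_injection_duration
        return np.arange(0.0, total + 0.5 * self.read_interval, self.read_interval)

    @property
    def injection_time(self) -> float:
        return self.equilibration_duration

    def compound(self, name: str) -> CompoundSpec:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    def wells_per_experiment(self) -> int:
        per_pathway = len(self.compounds) * (
            len(self.concentrations) * self.n_replicate_wells + self.n_replicate_wells
        )
        return len(self.pathways) * per_pathway


def expected_components(
    spec: SimulationSpec, compound: CompoundSpec, concentration: float, pathway: str
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (baseline, agonist) components on the spec's time grid."""
    t = spec.time_grid
    kin = spec.kinetic
    base = kin.baseline * np.exp(-kin.decay_rate * t)
    dt = t - spec.injection_time
    post = dt >= 0
    occ = compound.occupancy(concentration, pathway)
    eff = compound.true_emax.get(pathway, 0.0) / 100.0
    agonist = np.zeros_like(t)
    agonist[post] = (
        kin.baseline
        * eff
        * occ
        * (1.0 - np.exp(-kin.rise_rate * dt[post]))
        * np.exp(-kin.decay_rate * dt[post])
    )
    return base, agonist


def expected_trace(
    spec: SimulationSpec, compound: CompoundSpec, concentration: float, pathway: str
) -> np.ndarray:
    """Noise-free expected luminescence on the spec's time grid."""
    base, agonist = expected_components(spec, compound, concentration, pathway)
    return base + agonist


def _well_rng(spec: SimulationSpec, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=spawn_key))


def simulate_experiment(spec: SimulationSpec, experiment_index: int) -> PlateExperiment:
    """Simulate one independent experiment (both pathways, all wells).

    Deterministic given ``(spec.seed, experiment_index)``.  Each condition's
    solvent-control wells (concentration 0) are included per pathway and
    compound, duplicated like the test wells.
    """
    if experiment_index < 0:
        raise ValueError("experiment_index must be >= 0")
    exp_id = f"E{experiment_index + 1}"
    # per-experiment scale factor: spawn key reserved at pathway slot 2**20
    exp_rng = _well_rng(spec, experiment_index, 2**20)
    exp_scale = float(np.exp(spec.noise.experiment_sigma * exp_rng.standard_normal()))

    t = spec.time_grid
    wells: list[tuple[WellAnnotation, TimeLuminescenceTrace]] = []
    for ip, pathway in enumerate(spec.pathways):
        for ic, comp in enumerate(spec.compounds):
            # concentration index 0 encodes the solvent control
            for jc, conc in enumerate((0.0, *spec.concentrations)):
                for rep in range(spec.n_replicate_wells):
                    rng = _well_rng(spec, experiment_index, ip, ic, jc, rep)
                    base, agonist = expected_components(spec, comp, conc, pathway)
                    well_scale = float(
                        np.exp(spec.noise.well_sigma * rng.standard_normal())
                    )
                    resp_scale = float(
                        np.exp(spec.noise.response_sigma * rng.standard_normal())
                    )
                    values = (base + agonist * resp_scale) * exp_scale * well_scale
                    if spec.noise.read_sigma > 0:
                        values = values + spec.noise.read_sigma * rng.standard_normal(t.size)
                    values = np.clip(values, 0.0, None)
                    ann = WellAnnotation(
                        compound=comp.name,
                        concentration=conc,
                        pathway=pathway,
                        receptor_variant=spec.receptor_variant,
                        experiment_id=exp_id,
                        replicate=rep + 1,
                        is_solvent_control=(conc == 0.0),
                    )
                    trace = TimeLuminescenceTrace(
                        times=t.copy(), values=values, injection_time=spec.injection_time
                    )
                    wells.append((ann, trace))
    return PlateExperiment(
        wells=wells, experiment_id=exp_id, receptor_variant=spec.receptor_variant
    )


def simulate_study(spec: SimulationSpec) -> list[PlateExperiment]:
    """Simulate ``spec.n_experiments`` independent experiments."""
    return [simulate_experiment(spec, i) for i in range(spec.n_experiments)]


def table_like_study_spec(
    seed: int = 0,
    noise: NoiseModel | None = None,
    n_experiments: int = 3,
) -> SimulationSpec:
    """A ready-made study emulating published potency/efficacy profiles.

    Contains an LSD-like reference (potent, balanced), a strongly
    βarr2-biased N-benzylphenethylamine-like compound (full βarr2 agonist,
    weak partial miniGαq agonist) and a high-efficacy unbiased-leaning
    compound, with EC50/Emax values on the scale reported for this compound
    class.
    """
    compounds = (
        CompoundSpec(
            name="REF",
            true_ec50={"barr2": 12.9e-9, "miniGq": 13.2e-9},
            true_emax={"barr2": 99.7, "miniGq": 100.0},
        ),
        CompoundSpec(
            name="CPD-A",  # 4a-like: βarr2-preferring partial Gq agonist
            true_ec50={"barr2": 11.1e-9, "miniGq": 48.8e-9},
            true_emax={"barr2": 112.0, "miniGq": 28.0},
        ),
        CompoundSpec(
            name="CPD-B",  # 6a-like: high-efficacy, mildly βarr2-preferring
            true_ec50={"barr2": 2.75e-9, "miniGq": 8.59e-9},
            true_emax={"barr2": 150.0, "miniGq": 123.0},
        ),
    )
    return SimulationSpec(
        compounds=compounds,
        reference="REF",
        n_experiments=n_experiments,
        noise=noise if noise is not None else NoiseModel(),
        seed=seed,
    )
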