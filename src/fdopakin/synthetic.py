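"""Synthetic dynamic 18F-FDOPA cohorts for end-to-end testing.

Generates complete subjects — carotid blood curve, tumor TACs under both
frame schedules, healthy-brain reference TAC — with IDH-group-dependent
2TCM kinetics and a count-statistics noise proxy, so that every
downstream fitting and comparison stage can be exercised without
patient data.

Group kinetics are scenario parameters, not estimates of any real
cohort: wild-type-like tumors are comparatively reversible (tissue
follows the declining plasma curve, early TTP), mutant-like tumors trap
tracer (k3 >> k4, rising late phase, late/absent peak), so that
noiseless time-to-peaks straddle roughly 18 min.  The default cohort
size is 14 mutant / 23 wild-type.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning (PCG64), so a fixed seed yields
byte-identical cohorts across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import compartmental, input_function, tac

__all__ = [
    "BloodCurveSpec",
    "ParamDist",
    "GroupKinetics",
    "NoiseModel",
    "DEFAULT_KINETICS",
    "DEFAULT_BLOOD",
    "blood_model_from_spec",
    "generate_blood_curve",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class BloodCurveSpec:
    """Shape of the (uncorrected) carotid blood curve.

    Linear rise from (0, 0) to the peak, tri-exponential decay after it;
    amplitude fractions sum to 1 so the curve is continuous at the peak.
    """

    # default peak sits on a 5-s frame midpoint (42.5 s) so that the fitted
    # tri-exponential anchor coincides with the generating one
    peak_time_min: float = 42.5 / 60.0
    peak_suv: float = 12.0
    amp_fractions: tuple = (0.55, 0.35, 0.10)
    decay_rates_per_min: tuple = (3.0, 0.35, 0.03)

    def __post_init__(self) -> None:
        if not (0 < self.peak_time_min < 30):
            raise ValueError("peak time must lie inside the acquisition")
        if abs(sum(self.amp_fractions) - 1.0) > 1e-9:
            raise ValueError("amplitude fractions must sum to 1")
        if min(self.decay_rates_per_min) <= 0 or self.peak_suv <= 0:
            raise ValueError("decay rates and peak value must be positive")


def blood_model_from_spec(spec: BloodCurveSpec) -> input_function.BloodFitModel:
    """Exact continuous blood curve corresponding to a generator spec."""
    amps = spec.peak_suv * np.asarray(spec.amp_fractions)
    return input_function.BloodFitModel(
        peak_time_min=spec.peak_time_min,
        node_times_min=np.array([0.0, spec.peak_time_min]),
        node_values=np.array([0.0, spec.peak_suv]),
        amplitudes=amps,
        rates=np.asarray(spec.decay_rates_per_min, dtype=float),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian TAC noise with variance proportional to value/duration.

    ``scale`` is the noise s.d. on a frame of SUV 1 and 60-s duration
    (the uniform-protocol reference frame); shorter frames and hotter
    voxels are noisier per the count-statistics proxy
    sd = scale * sqrt(max(value, floor) * 60 / duration_s).
    """

    scale: float = 0.05
    value_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def apply(self, curve: tac.TAC, rng: np.random.Generator) -> tac.TAC:
        if self.scale == 0:
            return curve
        sd = self.scale * np.sqrt(
            np.maximum(curve.values, self.value_floor) * 60.0 / curve.schedule.frame_duration
        )
        return tac.TAC(curve.schedule, curve.values + rng.normal(0.0, sd), curve.region_label)


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal kinetic parameter: mean * (1 + cv * z), redrawn while <= 0."""

    mean: float
    cv: float = 0.15

    def draw(self, rng: np.random.Generator) -> float:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        value = 0.0
        while value <= 0:
            value = self.mean * (1.0 + self.cv * rng.standard_normal())
        return value


@dataclass(frozen=True)
class GroupKinetics:
    """Per-group 2TCM distributions plus one-tissue reference-region kinetics."""

    k1: ParamDist
    k2: ParamDist
    k3: ParamDist
    k4: ParamDist
    vb: ParamDist
    k1_ref: ParamDist = ParamDist(0.09)
    k2_ref: ParamDist = ParamDist(0.09)
    vb_ref: ParamDist = ParamDist(0.04)

    def draw_tumor(self, rng) -> compartmental.TCMParams:
        return compartmental.TCMParams(
            self.k1.draw(rng), self.k2.draw(rng), self.k3.draw(rng), self.k4.draw(rng), self.vb.draw(rng)
        )

    def draw_reference(self, rng) -> compartmental.TCMParams:
        return compartmental.TCMParams(self.k1_ref.draw(rng), self.k2_ref.draw(rng), 0.0, 0.0, self.vb_ref.draw(rng))


#: scenario defaults: reversible wild-type kinetics (early peak, declining
#: late phase) vs trapping mutant kinetics (rising late phase)
DEFAULT_KINETICS = {
    "wild_type": GroupKinetics(
        k1=ParamDist(0.15), k2=ParamDist(0.30), k3=ParamDist(0.13), k4=ParamDist(0.030), vb=ParamDist(0.05)
    ),
    "mutant": GroupKinetics(
        k1=ParamDist(0.12), k2=ParamDist(0.30), k3=ParamDist(0.18), k4=ParamDist(0.012), vb=ParamDist(0.04)
    ),
}

DEFAULT_BLOOD = BloodCurveSpec()


def generate_blood_curve(
    spec: BloodCurveSpec,
    schedule: tac.FrameSchedule | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> tac.TAC:
    """Frame-averaged carotid blood TAC (input-function schedule by default)."""
    schedule = schedule or tac.make_schedule(tac.PROTOCOL_INPUT_FUNCTION)
    model = blood_model_from_spec(spec)
    curve = tac.TAC(schedule, model.frame_averages(schedule), tac.REGION_BLOOD)
    if noise is not None and noise.scale > 0:
        rng = np.random.default_rng(rng)
        curve = noise.apply(curve, rng)
    return curve


@dataclass(frozen=True)
class SubjectTruth:
    """Generating quantities of one synthetic subject."""

    tumor_params: compartmental.TCMParams
    reference_params: compartmental.TCMParams
    blood_spec: BloodCurveSpec
    plasma_model: input_function.PlasmaInputModel


def _jitter_blood(spec: BloodCurveSpec, rng: np.random.Generator) -> BloodCurveSpec:
    return replace(
        spec,
        peak_suv=spec.peak_suv * (1.0 + 0.1 * rng.standard_normal()),
        peak_time_min=float(np.clip(spec.peak_time_min * (1.0 + 0.1 * rng.standard_normal()), 0.2, 2.0)),
    )


def generate_subject(
    group: str,
    kinetics: GroupKinetics | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sub-000",
    blood_spec: BloodCurveSpec = DEFAULT_BLOOD,
    return_truth: bool = False,
):
    """Generate one subject of the requested group ('mutant' or 'wild_type').

    Tumor TACs are simulated under both frame schedules with the 2TCM,
    the reference TAC with one-tissue kinetics, and the blood TAC on the
    input-function schedule; group sets the IDH label.
    """
    if group not in DEFAULT_KINETICS:
        raise ValueError(f"unknown group {group!r}")
    kinetics = kinetics or DEFAULT_KINETICS[group]
    noise = noise or NoiseModel(scale=0.0)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)

    spec = _jitter_blood(blood_spec, rng)
    blood_model = blood_model_from_spec(spec)
    plasma = input_function.build_plasma_input(blood_model, input_function.InputFunctionConfig())
    tumor_params = kinetics.draw_tumor(rng)
    ref_params = kinetics.draw_reference(rng)

    sched_if = tac.make_schedule(tac.PROTOCOL_INPUT_FUNCTION)
    sched_uni = tac.make_schedule(tac.PROTOCOL_UNIFORM)

    tacs = {}
    tacs[(tac.REGION_BLOOD, tac.PROTOCOL_INPUT_FUNCTION)] = noise.apply(
        tac.TAC(sched_if, blood_model.frame_averages(sched_if), tac.REGION_BLOOD), rng
    )
    for sched, protocol in ((sched_if, tac.PROTOCOL_INPUT_FUNCTION), (sched_uni, tac.PROTOCOL_UNIFORM)):
        tumor = compartmental.tcm_forward(tumor_params, plasma.plasma_fdopa, plasma.whole_blood, sched)
        tacs[(tac.REGION_TUMOR, protocol)] = noise.apply(tumor, rng)
    brain = compartmental.tcm_forward(ref_params, plasma.plasma_fdopa, plasma.whole_blood, sched_uni)
    brain = tac.TAC(sched_uni, brain.values, tac.REGION_BRAIN)
    tacs[(tac.REGION_BRAIN, tac.PROTOCOL_UNIFORM)] = noise.apply(brain, rng)

    record = tac.SubjectRecord(subject_id, idh_mutant=(group == "mutant"), tacs=tacs)
    if return_truth:
        return record, SubjectTruth(tumor_params, ref_params, spec, plasma)
    return record


def generate_cohort(
    n_mutant: int = 14,
    n_wildtype: int = 23,
    kinetics: dict | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    return_truth: bool = False,
):
    """Generate a reproducible labelled cohort (default 14 mutant / 23 wild-type).

    Per-subject seeds are spawned from the master seed, so subject i is
    identical no matter how many other subjects are generated.
    """
    kinetics = kinetics or DEFAULT_KINETICS
    noise = noise or NoiseModel(scale=0.05)
    groups = ["mutant"] * n_mutant + ["wild_type"] * n_wildtype
    seqs = np.random.SeedSequence(seed).spawn(len(groups))
    records, truths = [], []
    for i, (group, seq) in enumerate(zip(groups, seqs)):
        out = generate_subject(
            group,
            kinetics=kinetics[group],
            noise=noise,
            seed=seq,
            subject_id=f"sub-{i:03d}",
            return_truth=True,
        )
        records.append(out[0])
        truths.append(out[1])
    if return_truth:
        return records, truths
    return records
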