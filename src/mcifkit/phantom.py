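"""Digital-rat phantom: ground-truth parameters and simulated study data.

Generates everything a full study provides -- contaminated blood-pool and
myocardium TACs on the 23-frame/60-min schedule, 35 regional brain TACs
binned into four super regions (cerebellum, frontal cortex, hippocampus,
striatum), and 12 arterial blood samples -- from known ground-truth
parameters, so every stage of the pipeline can be tested against truth
without animal data.

Parameter ranges are chosen to resemble a fasted adult rat under anesthesia:
bolus blood peak of a few hundred kBq/cc, cerebral Ki in the 0.02-0.03 1/min
range, cerebral blood-volume fractions of a few percent.

Noise model: independent zero-mean Gaussian per frame with
SD_i = sigma0 * sqrt(value_i / duration_i) -- the standard count-statistics
surrogate for reconstructed frames (variance proportional to activity,
inversely to frame length) -- and proportional noise (CV) on arterial
samples, reflecting gamma-counter repeatability.  Negative noisy values are
retained (clipping would bias low-activity frames); TACs carry an
``allow_negative`` flag instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dualoutput import DualOutputParams, SpilloverParams, model_idif_frames, model_myo_frames
from .compartment import TwoTissueParams
from .input_function import DEFAULT_SAMPLE_TIMES, FengInput
from .regional import RegionKiParams, model_region_frames
from .tac import (
    DEFAULT_FRAMING,
    BloodSampleSeries,
    FrameSchedule,
    TimeActivityCurve,
    build_frame_schedule,
    write_samples,
    write_tac,
)

__all__ = [
    "PhantomConfig",
    "NoiseConfig",
    "PhantomTruth",
    "StudyData",
    "SUPER_REGIONS",
    "generate_truth",
    "simulate_study",
    "make_study_fixture",
    "sigma0_for_peak_noise",
]

#: 35 atlas-style VOIs binned into the four super regions.
SUPER_REGIONS: dict[str, tuple[str, ...]] = {
    "cerebellum": ("cerebellum_L", "cerebellum_R", "cerebellar_vermis"),
    "frontal_cortex": (
        "frontal_cortex_L", "frontal_cortex_R", "motor_cortex_L", "motor_cortex_R",
        "cingulate_cortex_L", "cingulate_cortex_R", "orbitofrontal_cortex_L",
        "orbitofrontal_cortex_R", "prelimbic_cortex_L", "prelimbic_cortex_R",
        "insular_cortex_L", "insular_cortex_R",
    ),
    "hippocampus": (
        "hippocampus_dorsal_L", "hippocampus_dorsal_R", "hippocampus_ventral_L",
        "hippocampus_ventral_R", "subiculum_L", "subiculum_R",
        "entorhinal_cortex_L", "entorhinal_cortex_R",
    ),
    "striatum": (
        "caudate_putamen_L", "caudate_putamen_R", "accumbens_core_L", "accumbens_core_R",
        "accumbens_shell_L", "accumbens_shell_R", "globus_pallidus_L", "globus_pallidus_R",
        "olfactory_tubercle_L", "olfactory_tubercle_R", "septum_L", "septum_R",
    ),
}

ALL_VOIS: tuple[str, ...] = tuple(v for members in SUPER_REGIONS.values() for v in members)


@dataclass
class PhantomConfig:
    """Uniform draw ranges for ground-truth parameters (units as labeled)."""

    # arterial input (bolus peak ~150-350 kBq/cc, 60-min AUC ~1000-2000 kBq*min/cc)
    a1_range: tuple[float, float] = (2000.0, 4000.0)   # kBq/cc/min
    a2_range: tuple[float, float] = (20.0, 40.0)       # kBq/cc
    a3_range: tuple[float, float] = (10.0, 20.0)       # kBq/cc
    lam1_range: tuple[float, float] = (3.0, 6.0)       # 1/min
    lam2_range: tuple[float, float] = (0.3, 0.8)       # 1/min
    lam3_range: tuple[float, float] = (0.01, 0.02)     # 1/min
    tau_range: tuple[float, float] = (0.1, 0.4)        # min
    # myocardial kinetics
    myo_k1_range: tuple[float, float] = (0.2, 0.6)     # 1/min
    myo_k2_range: tuple[float, float] = (0.2, 0.6)
    myo_k3_range: tuple[float, float] = (0.05, 0.15)
    myo_k4: float = 0.0
    # heart contamination
    s_mb_range: tuple[float, float] = (0.1, 0.3)
    s_bm_range: tuple[float, float] = (0.1, 0.3)
    r_b_range: tuple[float, float] = (0.7, 0.95)
    r_m_range: tuple[float, float] = (0.6, 0.9)
    # cerebral regions
    region_k1_range: tuple[float, float] = (0.05, 0.2)
    region_k2_range: tuple[float, float] = (0.1, 0.4)
    region_k3_range: tuple[float, float] = (0.02, 0.12)
    region_tbv_range: tuple[float, float] = (0.0, 0.03)
    volume_range_mm3: tuple[float, float] = (15.0, 120.0)
    regions: tuple[str, ...] = ALL_VOIS


@dataclass
class NoiseConfig:
    """Frame-noise scale sigma0 (kBq^1/2 cc^-1/2 min^1/2) and sample CV."""

    sigma0: float = 0.0
    sample_cv: float = 0.03
    proportional_sqrt: bool = True  # SD_i = sigma0*sqrt(value/duration)


@dataclass(frozen=True)
class PhantomTruth:
    dual: DualOutputParams
    regions: dict[str, RegionKiParams]
    volumes_mm3: dict[str, float]
    seed: int

    def region_ki(self, label: str) -> float:
        return self.regions[label].Ki


@dataclass(frozen=True)
class StudyData:
    pet_idif: TimeActivityCurve
    pet_myo: TimeActivityCurve
    region_tacs: dict[str, TimeActivityCurve]
    arterial: BloodSampleSeries
    schedule: FrameSchedule


def _u(rng: np.random.Generator, rg: tuple[float, float]) -> float:
    return float(rng.uniform(*rg))


def generate_truth(seed: int, config: PhantomConfig | None = None) -> PhantomTruth:
    """Draw one rat's ground-truth parameter set; deterministic per seed."""
    cfg = config or PhantomConfig()
    if not cfg.regions:
        raise ValueError("phantom needs at least one brain region")
    rng = np.random.default_rng(seed)
    feng = FengInput(
        A1=_u(rng, cfg.a1_range), A2=_u(rng, cfg.a2_range), A3=_u(rng, cfg.a3_range),
        lam1=_u(rng, cfg.lam1_range), lam2=_u(rng, cfg.lam2_range),
        lam3=_u(rng, cfg.lam3_range), tau=_u(rng, cfg.tau_range),
    )
    dual = DualOutputParams(
        input=feng,
        kinetics=TwoTissueParams(
            _u(rng, cfg.myo_k1_range), _u(rng, cfg.myo_k2_range),
            _u(rng, cfg.myo_k3_range), cfg.myo_k4,
        ),
        contamination=SpilloverParams(
            S_mb=_u(rng, cfg.s_mb_range), S_bm=_u(rng, cfg.s_bm_range),
            r_b=_u(rng, cfg.r_b_range), r_m=_u(rng, cfg.r_m_range),
        ),
    )
    regions = {
        name: RegionKiParams(
            K1=_u(rng, cfg.region_k1_range), k2=_u(rng, cfg.region_k2_range),
            k3=_u(rng, cfg.region_k3_range), TBV=_u(rng, cfg.region_tbv_range),
        )
        for name in cfg.regions
    }
    volumes = {name: _u(rng, cfg.volume_range_mm3) for name in cfg.regions}
    return PhantomTruth(dual=dual, regions=regions, volumes_mm3=volumes, seed=seed)


def sigma0_for_peak_noise(
    values: np.ndarray, durations: np.ndarray, peak_fraction: float
) -> float:
    """sigma0 that makes the peak frame's noise SD = peak_fraction * peak value."""
    i = int(np.argmax(values))
    peak = float(values[i])
    if peak <= 0:
        raise ValueError("peak value must be positive")
    return peak_fraction * peak / np.sqrt(peak / float(durations[i]))


def simulate_study(
    truth: PhantomTruth,
    schedule: FrameSchedule | None = None,
    sample_times: np.ndarray | None = None,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
) -> StudyData:
    """Forward-simulate one study: contaminated heart TACs, brain TACs, samples.

    Noiseless frame values come from the dual-output and regional model
    equations; arterial samples are the true input evaluated at the draw
    times.  Noise is added per :class:`NoiseConfig`; ``seed`` defaults to the
    truth's own seed so repeated calls are bit-identical.
    """
    schedule = schedule or build_frame_schedule(DEFAULT_FRAMING)
    times = np.asarray(sample_times if sample_times is not None else DEFAULT_SAMPLE_TIMES, float)
    if times.max() > schedule.ends[-1] + 1e-9:
        raise ValueError("arterial sample time beyond scan end")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    idif = model_idif_frames(truth.dual, schedule)
    myo = model_myo_frames(truth.dual, schedule)
    regions = {
        name: model_region_frames(p, truth.dual.input, schedule)
        for name, p in truth.regions.items()
    }
    arterial = truth.dual.input(times)

    durations = schedule.durations

    def add_noise(values: np.ndarray) -> np.ndarray:
        if noise.sigma0 <= 0:
            return values
        sd = noise.sigma0 * np.sqrt(np.maximum(values, 0.0) / durations)
        return values + rng.normal(0.0, 1.0, size=values.shape) * sd

    noisy = noise.sigma0 > 0
    idif_n, myo_n = add_noise(idif), add_noise(myo)
    regions_n = {name: add_noise(v) for name, v in regions.items()}
    if noise.sample_cv > 0:
        arterial = arterial * (1.0 + noise.sample_cv * rng.normal(size=arterial.shape))

    return StudyData(
        pet_idif=TimeActivityCurve(schedule, idif_n, "pet_idif", allow_negative=noisy),
        pet_myo=TimeActivityCurve(schedule, myo_n, "pet_myo", allow_negative=noisy),
        region_tacs={
            name: TimeActivityCurve(schedule, v, name, allow_negative=noisy)
            for name, v in regions_n.items()
        },
        arterial=BloodSampleSeries(times, arterial),
        schedule=schedule,
    )


def _truth_to_dict(truth: PhantomTruth) -> dict:
    return {
        "seed": truth.seed,
        "input": asdict(truth.dual.input),
        "kinetics": asdict(truth.dual.kinetics),
        "contamination": asdict(truth.dual.contamination),
        "regions": {k: asdict(v) for k, v in truth.regions.items()},
        "volumes_mm3": truth.volumes_mm3,
    }


def truth_from_dict(payload: dict) -> PhantomTruth:
    return PhantomTruth(
        dual=DualOutputParams(
            input=FengInput(**payload["input"]),
            kinetics=TwoTissueParams(**payload["kinetics"]),
            contamination=SpilloverParams(**payload["contamination"]),
        ),
        regions={k: RegionKiParams(**v) for k, v in payload["regions"].items()},
        volumes_mm3={k: float(v) for k, v in payload["volumes_mm3"].items()},
        seed=int(payload["seed"]),
    )


def make_study_fixture(
    out_dir: str | Path,
    seed: int,
    noise: NoiseConfig | None = None,
    config: PhantomConfig | None = None,
) -> dict:
    """Write a complete one-rat study to disk; returns the manifest dict.

    Layout: ``idif.csv``, ``myo.csv``, ``samples.csv``, ``regions/<voi>.csv``,
    ``super_regions.json`` (map + volumes), ``truth.json`` and
    ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "regions").mkdir(parents=True, exist_ok=True)
    truth = generate_truth(seed, config)
    study = simulate_study(truth, noise=noise)

    write_tac(study.pet_idif, out / "idif.csv")
    write_tac(study.pet_myo, out / "myo.csv")
    write_samples(study.arterial, out / "samples.csv")
    for name, tac in study.region_tacs.items():
        write_tac(tac, out / "regions" / f"{name}.csv")
    (out / "super_regions.json").write_text(
        json.dumps(
            {"map": {k: list(v) for k, v in SUPER_REGIONS.items()},
             "volumes_mm3": truth.volumes_mm3},
            indent=2,
        )
    )
    (out / "truth.json").write_text(json.dumps(_truth_to_dict(truth), indent=2))
    manifest = {
        "seed": seed,
        "noise": asdict(noise or NoiseConfig()),
        "n_frames": len(study.schedule),
        "n_regions": len(study.region_tacs),
        "n_samples": len(study.arterial),
        "files": ["idif.csv", "myo.csv", "samples.csv", "super_regions.json", "truth.json"]
        + [f"regions/{n}.csv" for n in study.region_tacs],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
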