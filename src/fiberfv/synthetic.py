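"""Synthetic skinned-fiber studies with known ground truth.

Generates complete in-silico single-fiber experiments — per-fiber Hill
parameters drawn from species × fiber-type distributions, and simulated
force-clamp release traces — so the whole extraction/fitting/QC/statistics
pipeline can be exercised and validated against ground truth.

The default population emulates a two-species comparison (85 human fibers
from vastus lateralis, 49 bonobo fibers spread over five muscles; types I
and II) with group means and dispersions taken from published group
summaries (mean ± SEM with n; SD is reconstructed as SEM·√n).  Fiber size
and strength are coupled: specific tension declines exponentially with
cross-sectional area, ST = 18.4·exp(−5·10⁻⁵·FCSA) N·cm⁻² with lognormal
scatter, and Po = ST·FCSA/100 µN, reproducing the observed negative
size–tension relationship.

Each fiber undergoes four series of four isotonic releases.  Traces are
phenomenological realizations of the fiber's true Hill curve: a clamp at
fraction ℓ of the current Po shortens at velocity b(1−ℓ)/(ℓ+k) FL·s⁻¹
(k = a/Po), corrupted by multiplicative velocity noise.  Po runs down
between series and the sarcomere set point drifts, occasionally tripping
the quality-control rules exactly as real fibers do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import truncnorm

from .hill import FiberMorphology, HillParameters
from .traces import ReleaseTrace

__all__ = [
    "GroupSpec",
    "PopulationSpec",
    "ReleaseProtocol",
    "NoiseSpec",
    "FiberGroundTruth",
    "FiberExperiment",
    "SyntheticStudy",
    "StudyConfig",
    "REFERENCE_GROUP_MEANS",
    "default_population_spec",
    "sample_population",
    "simulate_release_experiment",
    "make_study",
    "write_study",
    "read_study",
]

# Emulation targets: group means (± SEM, n) of the reference comparative
# study. SEM/n pairs: morphology variables use the FCSA n, contractile
# variables the (smaller) post-QC n.
REFERENCE_GROUP_MEANS = {
    ("bonobo", "I"): dict(
        n_fcsa=18, n_contractile=16,
        fcsa=7648.0, fcsa_sem=790.0,
        st=10.7, st_sem=0.8,
        po=750.0, po_sem=60.0,
        vmax=0.295, vmax_sem=0.020,
        a_over_po=0.119, a_over_po_sem=0.020,
        power=0.028, power_sem=0.005,
        specific_power=1.99, specific_power_sem=0.28,
    ),
    ("bonobo", "II"): dict(
        n_fcsa=31, n_contractile=22,
        fcsa=9654.0, fcsa_sem=593.0,
        st=12.1, st_sem=0.7,
        po=1116.0, po_sem=70.0,
        vmax=0.770, vmax_sem=0.032,
        a_over_po=0.195, a_over_po_sem=0.008,
        power=0.129, power_sem=0.018,
        specific_power=7.73, specific_power_sem=0.64,
    ),
    ("human", "I"): dict(
        n_fcsa=39, n_contractile=39,
        fcsa=5840.0, fcsa_sem=378.0,
        st=14.1, st_sem=0.5,
        po=791.0, po_sem=45.0,
        vmax=0.373, vmax_sem=0.010,
        a_over_po=0.066, a_over_po_sem=0.003,
        power=0.021, power_sem=0.002,
        specific_power=2.03, specific_power_sem=0.12,
    ),
    ("human", "II"): dict(
        n_fcsa=46, n_contractile=46,
        fcsa=7037.0, fcsa_sem=375.0,
        st=13.7, st_sem=0.5,
        po=966.0, po_sem=38.0,
        vmax=0.939, vmax_sem=0.026,
        a_over_po=0.099, a_over_po_sem=0.003,
        power=0.074, power_sem=0.005,
        specific_power=6.85, specific_power_sem=0.36,
    ),
}

# Muscle-of-origin sampling counts for bonobo fibers (VL, biceps brachii,
# soleus, adductor magnus, hamstring); humans are all vastus lateralis.
BONOBO_MUSCLE_COUNTS = {"VL": 26, "BB": 4, "SOL": 1, "ADD": 9, "HAM": 8}

# truncation bounds of the generating normals, as multiples of the mean
TRUNC_LO, TRUNC_HI = 0.05, 3.0


@dataclass(frozen=True)
class GroupSpec:
    """Sampling distribution for one species × fiber-type group."""

    species: str
    fiber_type: str
    n: int
    fcsa_mean: float
    fcsa_sd: float
    vmax_mean: float
    vmax_sd: float
    a_over_po_mean: float
    a_over_po_sd: float
    st_mean: float
    st_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        for nm in ("fcsa", "vmax", "a_over_po", "st"):
            if getattr(self, nm + "_mean") <= 0 or getattr(self, nm + "_sd") < 0:
                raise ValueError(f"{nm}: mean must be > 0 and SD >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Population the generator samples fibers from."""

    groups: tuple[GroupSpec, ...]
    fiber_length_range: tuple[float, float] = (0.70, 3.97)  # mm, uniform
    sl_setpoint_range: tuple[float, float] = (2.53, 2.69)  # µm, uniform
    muscle_proportions: dict = field(default_factory=dict)  # per species
    couple_st_fcsa: bool = True
    st_scale: float = 18.4  # N·cm⁻² at FCSA -> 0
    st_decay: float = 5e-5  # per µm²
    st_sigma: float = 0.20  # lognormal scatter of ST around the trend
    rundown_mean: float = 0.02  # fraction of Po lost per series
    rundown_sd: float = 0.012
    rundown_max: float = 0.20
    sl_drift_sd: float = 0.025  # µm per series, zero-mean

    def __post_init__(self) -> None:
        for sp, props in self.muscle_proportions.items():
            tot = sum(props.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"muscle proportions for {sp} sum to {tot}, not 1")

    @property
    def n_fibers(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass(frozen=True)
class ReleaseProtocol:
    """Force-clamp release protocol applied to every fiber."""

    n_series: int = 4
    releases_per_series: int = 4
    clamp_levels: tuple[float, ...] = (0.05, 0.15, 0.30, 0.50)  # × current Po
    step_duration_s: float = 0.150
    trace_duration_s: float = 0.160
    sampling_hz: float = 1000.0
    max_series_shortening: float = 0.20  # fraction of initial length

    def __post_init__(self) -> None:
        if len(self.clamp_levels) != self.releases_per_series:
            raise ValueError("clamp_levels must match releases_per_series")
        if any(not (0 < c < 1) for c in self.clamp_levels):
            raise ValueError("clamp levels must lie in (0, 1)")
        if self.trace_duration_s < self.step_duration_s:
            raise ValueError("trace must cover the full step duration")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated experiments."""

    velocity_sd_frac: float = 0.03  # multiplicative on the release velocity
    force_sd_frac: float = 0.01  # relative, on force samples and Po readings
    sl_noise_um: float = 0.01  # additive on sarcomere readings
    length_noise_mm: float = 1e-4  # additive white noise on the length channel

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class FiberGroundTruth:
    fiber_id: str
    species: str
    muscle: str
    fiber_type: str
    morph: FiberMorphology
    true_params: HillParameters
    rundown_rate: float  # fraction of Po lost per series transition
    sl_drift: float  # µm per series, signed


@dataclass
class FiberExperiment:
    """Simulated (or loaded) measurements for one fiber."""

    fiber_id: str
    species: str
    muscle: str
    fiber_type: str
    morph: FiberMorphology
    po_readings: list  # µN, one per series (first = reference)
    sl_readings: list  # µm, one per series (first = set point)
    releases: list  # ReleaseTrace


@dataclass
class SyntheticStudy:
    fibers: list  # FiberExperiment
    ground_truth: list  # FiberGroundTruth
    seed: int
    spec: PopulationSpec
    protocol: ReleaseProtocol
    noise: NoiseSpec


@dataclass(frozen=True)
class StudyConfig:
    population: PopulationSpec
    protocol: ReleaseProtocol = ReleaseProtocol()
    noise: NoiseSpec = NoiseSpec()


def default_population_spec(rundown_mean: float | None = None,
                            sl_drift_sd: float | None = None) -> PopulationSpec:
    """The default two-species emulation population (85 + 49 fibers)."""
    groups = []
    for (species, ftype), m in REFERENCE_GROUP_MEANS.items():
        nc = m["n_contractile"]
        nf = m["n_fcsa"]
        groups.append(
            GroupSpec(
                species=species,
                fiber_type=ftype,
                n=nf,
                fcsa_mean=m["fcsa"], fcsa_sd=m["fcsa_sem"] * np.sqrt(nf),
                vmax_mean=m["vmax"], vmax_sd=m["vmax_sem"] * np.sqrt(nc),
                a_over_po_mean=m["a_over_po"],
                a_over_po_sd=m["a_over_po_sem"] * np.sqrt(nc),
                st_mean=m["st"], st_sd=m["st_sem"] * np.sqrt(nf),
            )
        )
    tot = sum(BONOBO_MUSCLE_COUNTS.values())
    props = {k: v / tot for k, v in BONOBO_MUSCLE_COUNTS.items()}
    kwargs = {}
    if rundown_mean is not None:
        kwargs["rundown_mean"] = rundown_mean
    if sl_drift_sd is not None:
        kwargs["sl_drift_sd"] = sl_drift_sd
    return PopulationSpec(
        groups=tuple(groups),
        muscle_proportions={"human": {"VL": 1.0}, "bonobo": props},
        **kwargs,
    )


def _trunc_dist(mean: float, sd: float):
    lo, hi = TRUNC_LO * mean, TRUNC_HI * mean
    if sd <= 0:
        return None
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if a >= b:
        raise ValueError("impossible truncation bounds")
    return truncnorm(a, b, loc=mean, scale=sd)


def _sample_trunc(rng, mean: float, sd: float, size: int) -> np.ndarray:
    dist = _trunc_dist(mean, sd)
    if dist is None:
        return np.full(size, mean)
    return dist.rvs(size=size, random_state=rng)


def truncated_mean(mean: float, sd: float) -> float:
    """Analytic mean of the truncated generating normal (the true target
    a consistent estimator of the group mean should recover)."""
    dist = _trunc_dist(mean, sd)
    return mean if dist is None else float(dist.mean())


def generating_means(spec: PopulationSpec) -> dict:
    """Per-group analytic means of the generating distributions."""
    out = {}
    for g in spec.groups:
        out[(g.species, g.fiber_type)] = {
            "fcsa": truncated_mean(g.fcsa_mean, g.fcsa_sd),
            "vmax": truncated_mean(g.vmax_mean, g.vmax_sd),
            "a_over_po": truncated_mean(g.a_over_po_mean, g.a_over_po_sd),
            "st": truncated_mean(g.st_mean, g.st_sd),
        }
    return out


def sample_population(spec: PopulationSpec, seed) -> list:
    """Draw a fiber population (ground truth only) from the spec.

    Group sizes are exact; continuous variables come from normals truncated
    at 0.05× and 3× the mean.  With coupling enabled, specific tension
    follows the exponential size–tension trend with lognormal scatter and
    Po = ST·FCSA/100; otherwise ST is sampled from its own truncated normal.
    Deterministic for a given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    fibers: list[FiberGroundTruth] = []
    idx = 0
    for g in spec.groups:
        fcsa = _sample_trunc(rng, g.fcsa_mean, g.fcsa_sd, g.n)
        vmax = _sample_trunc(rng, g.vmax_mean, g.vmax_sd, g.n)
        k = _sample_trunc(rng, g.a_over_po_mean, g.a_over_po_sd, g.n)
        if spec.couple_st_fcsa:
            st = spec.st_scale * np.exp(-spec.st_decay * fcsa) * np.exp(
                rng.normal(0.0, spec.st_sigma, g.n)
            )
        else:
            st = _sample_trunc(rng, g.st_mean, g.st_sd, g.n)
        fl = rng.uniform(*spec.fiber_length_range, g.n)
        sl = rng.uniform(*spec.sl_setpoint_range, g.n)
        rd_lo = (0.0 - spec.rundown_mean) / max(spec.rundown_sd, 1e-12)
        rd_hi = (spec.rundown_max - spec.rundown_mean) / max(spec.rundown_sd, 1e-12)
        if spec.rundown_sd > 0:
            rundown = truncnorm.rvs(rd_lo, rd_hi, loc=spec.rundown_mean,
                                    scale=spec.rundown_sd, size=g.n,
                                    random_state=rng)
        else:
            rundown = np.full(g.n, spec.rundown_mean)
        drift = rng.normal(0.0, spec.sl_drift_sd, g.n)
        props = spec.muscle_proportions.get(g.species, {"VL": 1.0})
        muscles = rng.choice(list(props.keys()), size=g.n,
                             p=list(props.values()))
        for i in range(g.n):
            idx += 1
            po = st[i] * fcsa[i] / 100.0  # µN from N·cm⁻² and µm²
            fibers.append(
                FiberGroundTruth(
                    fiber_id=f"F{idx:04d}",
                    species=g.species,
                    muscle=str(muscles[i]),
                    fiber_type=g.fiber_type,
                    morph=FiberMorphology(
                        fcsa=float(fcsa[i]),
                        fiber_length=float(fl[i]),
                        sarcomere_length=float(sl[i]),
                    ),
                    true_params=HillParameters(
                        po=float(po), a=float(k[i] * po),
                        b=float(vmax[i] * k[i]),
                    ),
                    rundown_rate=float(rundown[i]),
                    sl_drift=float(drift[i]),
                )
            )
    return fibers


def simulate_release_experiment(
    truth: FiberGroundTruth,
    protocol: ReleaseProtocol = ReleaseProtocol(),
    noise: NoiseSpec = NoiseSpec(),
    seed=0,
) -> FiberExperiment:
    """Simulate the full release protocol for one fiber.

    Each series starts with an isometric Po re-measurement at the current
    (run-down) force capacity, then applies each clamp level.  The force-
    velocity relation scales with rundown at constant a/Po and Vmax, so a
    clamp at fraction ℓ of the *current* Po shortens at the fixed fraction
    b(1−ℓ)/(ℓ+k) regardless of rundown.  The fiber is restretched to its
    original length between series.  Bit-deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    params = truth.true_params
    k = params.a_over_po
    l0 = truth.morph.fiber_length
    sl0 = truth.morph.sarcomere_length

    dt = 1.0 / protocol.sampling_hz
    n_samp = int(round(protocol.trace_duration_s / dt)) + 1
    t = np.arange(n_samp) * dt

    po_readings, sl_readings, releases = [], [], []
    for s in range(protocol.n_series):
        po_cur = params.po * (1.0 - truth.rundown_rate) ** s
        sl_cur = sl0 + s * truth.sl_drift
        po_readings.append(
            float(po_cur * (1.0 + rng.normal(0.0, noise.force_sd_frac)))
            if noise.force_sd_frac > 0 else float(po_cur)
        )
        sl_readings.append(
            float(sl_cur + rng.normal(0.0, noise.sl_noise_um))
            if noise.sl_noise_um > 0 else float(sl_cur)
        )
        length = l0
        for j, lvl in enumerate(protocol.clamp_levels):
            if lvl >= 1:
                raise ValueError("clamp level must be < 1")
            v_true = params.b * (1.0 - lvl) / (lvl + k)  # FL·s⁻¹
            # restretch mid-series rather than let a shortening bout run past
            # the cap (protects the striation pattern on very fast fibers)
            planned = (l0 - length) / l0 + v_true * protocol.trace_duration_s
            if planned > protocol.max_series_shortening:
                length = l0
            v = v_true
            if noise.velocity_sd_frac > 0:
                v = max(0.0, v_true * (1.0 + rng.normal(0.0, noise.velocity_sd_frac)))
            f_clamp = lvl * po_cur
            force = np.full(n_samp, f_clamp)
            if noise.force_sd_frac > 0:
                force = force + rng.normal(0.0, noise.force_sd_frac * f_clamp, n_samp)
            length_ch = length - v * l0 * t
            if noise.length_noise_mm > 0:
                length_ch = length_ch + rng.normal(0.0, noise.length_noise_mm, n_samp)
            sarc_ch = sl_cur * (length - v * l0 * t) / l0
            releases.append(
                ReleaseTrace(
                    time_s=t.copy(),
                    force_uN=force,
                    length_mm=length_ch,
                    sarcomere_um=sarc_ch,
                    clamp_level=lvl,
                    series=s,
                    index=j,
                )
            )
            length = length - v * l0 * protocol.trace_duration_s
    return FiberExperiment(
        fiber_id=truth.fiber_id,
        species=truth.species,
        muscle=truth.muscle,
        fiber_type=truth.fiber_type,
        morph=truth.morph,
        po_readings=po_readings,
        sl_readings=sl_readings,
        releases=releases,
    )


def make_study(config: StudyConfig, seed: int) -> SyntheticStudy:
    """Generate a full synthetic study (population + all experiments)."""
    ss = np.random.SeedSequence(seed)
    pop_ss, exp_ss = ss.spawn(2)
    truths = sample_population(config.population, pop_ss)
    fiber_seeds = exp_ss.spawn(len(truths))
    fibers = [
        simulate_release_experiment(tr, config.protocol, config.noise, fs)
        for tr, fs in zip(truths, fiber_seeds)
    ]
    return SyntheticStudy(
        fibers=fibers,
        ground_truth=truths,
        seed=seed,
        spec=config.population,
        protocol=config.protocol,
        noise=config.noise,
    )


# -- interchange format ------------------------------------------------------

_TRACE_HEADER = "time_s\tforce_uN\tlength_mm\tsarcomere_um"


def _write_trace(trace: ReleaseTrace, path: Path) -> None:
    cols = np.column_stack(
        [trace.time_s, trace.force_uN, trace.length_mm, trace.sarcomere_um]
    )
    np.savetxt(path, cols, fmt="%.10g", delimiter="\t",
               header=_TRACE_HEADER, comments="")


def read_trace(path, clamp_level=None, series=None, index=None) -> ReleaseTrace:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return ReleaseTrace(
        time_s=data[:, 0], force_uN=data[:, 1], length_mm=data[:, 2],
        sarcomere_um=data[:, 3], clamp_level=clamp_level,
        series=series, index=index,
    )


def write_study(study: SyntheticStudy, outdir) -> Path:
    """Write manifest.json plus one TSV per release; returns the manifest path."""
    outdir = Path(outdir)
    tracedir = outdir / "traces"
    tracedir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": study.seed, "fibers": []}
    for exp in study.fibers:
        rels = []
        for tr in exp.releases:
            fname = f"{exp.fiber_id}_s{tr.series}_r{tr.index}.tsv"
            _write_trace(tr, tracedir / fname)
            rels.append(
                {"series": tr.series, "index": tr.index,
                 "clamp_level": tr.clamp_level, "file": f"traces/{fname}"}
            )
        manifest["fibers"].append(
            {
                "fiber_id": exp.fiber_id,
                "species": exp.species,
                "muscle": exp.muscle,
                "fiber_type": exp.fiber_type,
                "fcsa_um2": exp.morph.fcsa,
                "fiber_length_mm": exp.morph.fiber_length,
                "sarcomere_um": exp.morph.sarcomere_length,
                "po_readings_uN": list(exp.po_readings),
                "sl_readings_um": list(exp.sl_readings),
                "releases": rels,
            }
        )
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_study(studydir) -> list:
    """Load experiments written by :func:`write_study` (list of FiberExperiment)."""
    studydir = Path(studydir)
    manifest = json.loads((studydir / "manifest.json").read_text())
    fibers = []
    for m in manifest["fibers"]:
        releases = [
            read_trace(studydir / r["file"], clamp_level=r["clamp_level"],
                       series=r["series"], index=r["index"])
            for r in m["releases"]
        ]
        fibers.append(
            FiberExperiment(
                fiber_id=m["fiber_id"],
                species=m["species"],
                muscle=m["muscle"],
                fiber_type=m["fiber_type"],
                morph=FiberMorphology(
                    fcsa=m["fcsa_um2"],
                    fiber_length=m["fiber_length_mm"],
                    sarcomere_length=m["sarcomere_um"],
                ),
                po_readings=list(m["po_readings_uN"]),
                sl_readings=list(m["sl_readings_um"]),
                releases=releases,
            )
        )
    return fibers
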