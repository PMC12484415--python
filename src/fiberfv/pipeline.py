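"""End-to-end study pipeline: generate → extract → fit → QC → derive →
summarize → compare.

``run_pipeline`` takes a :class:`RunConfig`, generates (or loads) a study,
extracts per-release velocities, fits each fiber's Hill curve, applies the
quality-control rules, derives normalized quantities, and produces a study
summary: per-group mean ± SEM tables over accepted fibers, size–strength
regressions (Po and specific tension vs FCSA in linear / logarithmic /
exponential forms), group-mean force–velocity/power curve samples, two-way
ANOVAs and a forward stepwise regression for the determinants of specific
power.  Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as fvstats
from .hill import mean_group_curves
from .model import fit_hill
from .synthetic import (
    FiberExperiment,
    GroupSpec,
    NoiseSpec,
    PopulationSpec,
    ReleaseProtocol,
    StudyConfig,
    default_population_spec,
    make_study,
    read_study,
)
from .traces import QCThresholds, apply_qc, extract_release_velocity

__all__ = [
    "RunConfig",
    "StudySummary",
    "run_pipeline",
    "process_fiber",
    "analyze_fibers",
    "summarize_groups",
    "size_strength_regressions",
    "load_deposited_study",
]

RESPONSES = ("fcsa", "po", "specific_tension", "vmax", "a_over_po",
             "max_power", "specific_power")


@dataclass(frozen=True)
class RunConfig:
    """Reproducible pipeline configuration."""

    seed: int
    population: PopulationSpec = field(default_factory=default_population_spec)
    protocol: ReleaseProtocol = ReleaseProtocol()
    noise: NoiseSpec = NoiseSpec()
    qc: QCThresholds = QCThresholds()
    po_mode: str = "fixed"
    ss_type: int = 3
    entry_alpha: float = 0.10

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is None:
            if "seed" not in raw:
                raise ValueError("config must carry a seed (or pass --seed)")
            seed = int(raw["seed"])
        pop_raw = raw.get("population")
        if pop_raw is None:
            population = default_population_spec()
        else:
            groups = tuple(GroupSpec(**g) for g in pop_raw.pop("groups"))
            mp = pop_raw.pop("muscle_proportions",
                             default_population_spec().muscle_proportions)
            population = PopulationSpec(groups=groups, muscle_proportions=mp,
                                        **pop_raw)
        return cls(
            seed=seed,
            population=population,
            protocol=ReleaseProtocol(**raw.get("protocol", {})),
            noise=NoiseSpec(**raw.get("noise", {})),
            qc=QCThresholds(**raw.get("qc", {})),
            po_mode=raw.get("po_mode", "fixed"),
            ss_type=int(raw.get("ss_type", 3)),
            entry_alpha=float(raw.get("entry_alpha", 0.10)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudySummary:
    """All study-level outputs of one pipeline run."""

    fiber_table: pd.DataFrame  # one row per fiber (accepted and rejected)
    group_summary: pd.DataFrame  # mean ± SEM per (species, fiber_type)
    anova: dict  # response -> AnovaResult
    posthoc: dict  # response -> list[PosthocContrast] (when interaction sig.)
    stepwise: "fvstats.StepwiseResult"
    curves: pd.DataFrame  # group-mean FV/FP curve samples
    regressions: pd.DataFrame  # size-strength regression fits
    seed: int
    config_hash: str


def process_fiber(exp: FiberExperiment,
                  step_duration: float = 0.150,
                  regression_window: float = 0.100) -> list:
    """Extract one fiber's (force, velocity) points from its release traces."""
    return [
        extract_release_velocity(tr, exp.morph.fiber_length,
                                 step_duration=step_duration,
                                 regression_window=regression_window)
        for tr in exp.releases
    ]


def analyze_fibers(fibers: list, qc: QCThresholds = QCThresholds(),
                   po_mode: str = "fixed",
                   step_duration: float = 0.150,
                   regression_window: float = 0.100) -> pd.DataFrame:
    """Extract, fit, QC and derive for every fiber; one row per fiber."""
    rows = []
    for exp in fibers:
        try:
            points = process_fiber(exp, step_duration, regression_window)
            fit = fit_hill(points, po_measured=exp.po_readings[0],
                           po_mode=po_mode)
            qcres = apply_qc(exp.po_readings, exp.sl_readings, fit.r2, qc)
            derived = fit.derive(exp.morph)
        except Exception as e:  # pragma: no cover - stage diagnostics
            raise RuntimeError(f"[fiber {exp.fiber_id}] {e}") from e
        rows.append(
            {
                "fiber_id": exp.fiber_id,
                "species": exp.species,
                "muscle": exp.muscle,
                "fiber_type": exp.fiber_type,
                "n_points": fit.n_points,
                "fcsa": exp.morph.fcsa,
                "fiber_length": exp.morph.fiber_length,
                "po": fit.params.po,
                "a": fit.params.a,
                "b": fit.params.b,
                "a_over_po": derived.a_over_po,
                "vmax": derived.vmax,
                "r2": fit.r2,
                "converged": fit.converged,
                "specific_tension": derived.specific_tension,
                "max_power": derived.max_power,
                "specific_power": derived.specific_power,
                "accepted": qcres.accepted,
                "reasons": ";".join(qcres.reasons),
                "po_drop": qcres.po_drop_observed,
                "sl_change": qcres.sl_change_observed,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(fiber_table: pd.DataFrame,
                     accepted_only: bool = True) -> pd.DataFrame:
    """Group mean ± SEM table over (by default) QC-accepted fibers.

    SEM = SD/√n with SD the n−1 sample standard deviation; a single-fiber
    group reports no SEM (NaN) and an emptied group keeps its row with n=0.
    """
    data = fiber_table[fiber_table["accepted"]] if accepted_only else fiber_table
    rows = []
    group_keys = fiber_table.groupby(["species", "fiber_type"],
                                     observed=True).groups.keys()
    for species, ftype in sorted(group_keys):
        sub = data[(data["species"] == species) & (data["fiber_type"] == ftype)]
        row = {"species": species, "fiber_type": ftype, "n": len(sub)}
        for var in RESPONSES:
            vals = np.asarray(sub[var], dtype=float) if len(sub) else np.array([])
            row[f"{var}_mean"] = float(vals.mean()) if vals.size else np.nan
            row[f"{var}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan


def size_strength_regressions(fiber_table: pd.DataFrame) -> pd.DataFrame:
    """Po-vs-FCSA and ST-vs-FCSA regressions in three functional forms.

    Forms: linear ``y = c0 + c1·x``, logarithmic ``y = c0 + c1·ln x`` and
    exponential ``y = c0·exp(c1·x)`` (fitted in log space).  Fitted pooled
    and per fiber type; ``r2`` is computed in the response's original space
    and ``r2_alt`` in log space for the exponential form.
    """
    frames = []
    accepted = fiber_table[fiber_table["accepted"]]
    scopes = [("pooled", accepted)] + [
        (f"type_{t}", accepted[accepted["fiber_type"] == t])
        for t in sorted(accepted["fiber_type"].unique())
    ]
    for scope, sub in scopes:
        x = np.asarray(sub["fcsa"], dtype=float)
        for response in ("po", "specific_tension"):
            y = np.asarray(sub[response], dtype=float)
            for form in ("linear", "logarithmic", "exponential"):
                if form == "linear":
                    c1, c0 = np.polyfit(x, y, 1)
                    pred = c0 + c1 * x
                    r2, r2_alt = _r2(y, pred), np.nan
                elif form == "logarithmic":
                    c1, c0 = np.polyfit(np.log(x), y, 1)
                    pred = c0 + c1 * np.log(x)
                    r2, r2_alt = _r2(y, pred), np.nan
                else:
                    c1, logc0 = np.polyfit(x, np.log(y), 1)
                    c0 = float(np.exp(logc0))
                    pred = c0 * np.exp(c1 * x)
                    r2 = _r2(y, pred)
                    r2_alt = _r2(np.log(y), logc0 + c1 * x)
                frames.append(
                    {"scope": scope, "response": response, "form": form,
                     "n": x.size, "c0": float(c0), "c1": float(c1),
                     "r2": float(r2), "r2_alt": float(r2_alt)}
                )
    return pd.DataFrame(frames)


def group_mean_curves(group_summary: pd.DataFrame,
                      n_points: int = 201) -> pd.DataFrame:
    """Figure-style group-average FV/FP curve samples from the summary table."""
    groups = []
    for _, row in group_summary.iterrows():
        if row["n"] < 1 or not np.isfinite(row["a_over_po_mean"]):
            continue
        groups.append(
            (
                f"{row['species']}_{row['fiber_type']}",
                row["po_mean"],
                row["vmax_mean"],
                row["a_over_po_mean"],
                row["fiber_length_mean"] if "fiber_length_mean" in row else 1.0,
            )
        )
    return mean_group_curves(groups, n_points=n_points)


def run_pipeline(config: RunConfig, outdir=None,
                 study_dir=None) -> StudySummary:
    """Run the full pipeline; optionally write all artifacts to ``outdir``.

    ``study_dir`` loads a previously written study (manifest + traces)
    instead of generating one, so user-supplied trace tables in the
    interchange format run through the identical path.
    """
    if study_dir is not None:
        fibers = read_study(study_dir)
    else:
        study = make_study(
            StudyConfig(population=config.population, protocol=config.protocol,
                        noise=config.noise),
            config.seed,
        )
        fibers = study.fibers

    fiber_table = analyze_fibers(
        fibers, qc=config.qc, po_mode=config.po_mode,
        step_duration=config.protocol.step_duration_s,
    )
    group_summary = summarize_groups(fiber_table)
    # fiber-length means for absolute power curves
    acc = fiber_table[fiber_table["accepted"]]
    fl_means = acc.groupby(["species", "fiber_type"], observed=True)[
        "fiber_length"].mean()
    group_summary["fiber_length_mean"] = [
        fl_means.get((r["species"], r["fiber_type"]), np.nan)
        for _, r in group_summary.iterrows()
    ]

    anova, posthoc = {}, {}
    for resp in RESPONSES:
        try:
            res = fvstats.two_way_anova(acc, resp, ss_type=config.ss_type)
        except ValueError as e:
            raise RuntimeError(f"[anova:{resp}] {e}") from e
        anova[resp] = res
        if res.effects["interaction"].p < 0.05:
            posthoc[resp] = fvstats.bonferroni_posthoc(acc, resp)

    stepwise = fvstats.stepwise_regression(
        acc, "specific_power",
        candidates=("species", "fiber_type", "specific_tension", "vmax",
                    "a_over_po"),
        entry_alpha=config.entry_alpha,
    )
    curves = group_mean_curves(group_summary)
    regressions = size_strength_regressions(fiber_table)

    summary = StudySummary(
        fiber_table=fiber_table,
        group_summary=group_summary,
        anova=anova,
        posthoc=posthoc,
        stepwise=stepwise,
        curves=curves,
        regressions=regressions,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    if outdir is not None:
        write_summary(summary, outdir)
    return summary


def write_summary(summary: StudySummary, outdir) -> None:
    """Write all study artifacts as delimited text + a JSON run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    summary.fiber_table.to_csv(outdir / "fiber_results.tsv", **fmt)
    qc_cols = ["fiber_id", "species", "fiber_type", "accepted", "reasons",
               "po_drop", "sl_change", "r2"]
    summary.fiber_table[qc_cols].to_csv(outdir / "qc_report.tsv", **fmt)
    summary.group_summary.to_csv(outdir / "group_summary.tsv", **fmt)
    pd.concat(
        [res.to_frame().assign(response=resp)
         for resp, res in summary.anova.items()],
        ignore_index=True,
    ).to_csv(outdir / "anova.tsv", **fmt)
    ph_rows = [
        {"response": resp, "cell_a": "/".join(c.cell_a),
         "cell_b": "/".join(c.cell_b), "mean_a": c.mean_a, "mean_b": c.mean_b,
         "t": c.t, "p_raw": c.p_raw, "p_adjusted": c.p_adjusted}
        for resp, cons in summary.posthoc.items() for c in cons
    ]
    pd.DataFrame(ph_rows).to_csv(outdir / "posthoc.tsv", **fmt)
    sw_rows = [
        {"step": i + 1, "predictor": name, "entry_p": p, "r2_adj": r2}
        for i, (name, p, r2) in enumerate(summary.stepwise.steps)
    ]
    pd.DataFrame(sw_rows).to_csv(outdir / "stepwise.tsv", **fmt)
    summary.curves.to_csv(outdir / "curves.tsv", **fmt)
    summary.regressions.to_csv(outdir / "regressions.tsv", **fmt)
    log = {
        "seed": summary.seed,
        "config_hash": summary.config_hash,
        "n_fibers": int(len(summary.fiber_table)),
        "n_accepted": int(summary.fiber_table["accepted"].sum()),
        "stepwise_entered": summary.stepwise.entered,
        "stepwise_coefficients": summary.stepwise.coefficients,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1,
                                                    sort_keys=True))


def load_deposited_study(path):
    """Reader stub for externally deposited single-fiber datasets.

    Attach a converter here that maps an external per-release trace archive
    onto the interchange format (``manifest.json`` + per-release TSVs, see
    :func:`fiberfv.synthetic.write_study`); :func:`run_pipeline` then runs
    unchanged via its ``study_dir`` argument.
    """
    raise NotImplementedError(
        "no external dataset reader is bundled; convert the deposited data "
        "to the manifest + trace TSV interchange format and use "
        "run_pipeline(study_dir=...)"
    )
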