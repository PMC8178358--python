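"""Full-pipeline orchestration: validity gate → agreement → screening accuracy.

Stage order mirrors the validation logic: descriptive statistics, a
normality-and-geometry gate that drops NCIT distances whose readings are
non-normal or whose measurement spot outgrows the forehead, Bland–Altman
agreement on the surviving distance(s), an offset model, synthesis of NCIT
readings for a reference cohort, threshold accuracy tables and an ROC curve.
The orchestration performs no arithmetic of its own — every number in the
report comes from the stage modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from . import agreement as agr
from . import device as dev
from . import screening as scr
from . import synth
from .types import Cohort, ConfidenceSpec, OffsetModel, PairedRecord, RunConfig

__all__ = ["PipelineReport", "GateDecision", "run_pipeline", "PipelineError"]

log = logging.getLogger("feverscreen")


class PipelineError(RuntimeError):
    """The pipeline cannot proceed (e.g. every distance failed the gate)."""


@dataclass(frozen=True)
class GateDecision:
    """Why a distance was kept or excluded from method comparison."""

    distance: str
    normality_rejected: bool
    spot_inadequate: bool
    spot_diameter_in: float
    excluded: bool
    reasons: tuple[str, ...]


@dataclass
class PipelineReport:
    """Everything the pipeline computed, at full precision."""

    seed: int
    config: Mapping[str, Any]
    summaries: dict[str, agr.SummaryStats] = field(default_factory=dict)
    normality: dict[str, dict[str, agr.NormalityResult]] = field(default_factory=dict)
    gate: dict[str, GateDecision] = field(default_factory=dict)
    agreement: dict[str, agr.AgreementResult] = field(default_factory=dict)
    offset_model: OffsetModel | None = None
    study_specificity: dict[str, scr.ConfusionMetrics] = field(default_factory=dict)
    cohort_accuracy: dict[str, scr.ConfusionMetrics] = field(default_factory=dict)
    roc: scr.RocCurve | None = None
    equal_error: tuple[float, float] | None = None


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive per-stage integer seeds (< 2^31) from the single run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1, np.uint32)[0] % (2**31)) for child in ss.spawn(n)]


def run_pipeline(
    config: RunConfig,
    *,
    study_spec: synth.StudyGenSpec | None = None,
    cohort_spec: synth.CohortGenSpec | None = None,
    records: list[PairedRecord] | None = None,
    cohort: Cohort | None = None,
    device: dev.DeviceSpec = dev.FLUKE_561,
    forehead_extent_in: float = dev.DEFAULT_FOREHEAD_EXTENT_IN,
) -> PipelineReport:
    """Run the full analysis; all randomness derives from ``config.seed``.

    Inputs are either synthetic generator specs or pre-loaded data (records /
    cohort); synthetic specs are re-seeded from the run seed so a single
    integer reproduces the whole report.
    """
    s_study, s_cohort, s_sim, s_lillie = _spawn_seeds(config.seed, 4)

    if records is None:
        spec = study_spec or synth.StudyGenSpec()
        spec = synth.StudyGenSpec(
            n=spec.n, ref_mean=spec.ref_mean, ref_sd=spec.ref_sd,
            ref_bounds=spec.ref_bounds, profiles=spec.profiles, seed=s_study,
        )
        records = synth.generate_paired_study(spec)
    distances = list(records[0].t_ncit.keys())

    report = PipelineReport(seed=config.seed, config={
        "fever_cut_ref": config.fever_cut_ref,
        "distances": dict(config.distances),
        "mc_reps": config.mc_reps,
        "device": device.name,
    })

    # Stage 1: descriptive statistics per measurement method.
    samples: dict[str, np.ndarray] = {"ref": np.array([r.t_ref for r in records])}
    for d in distances:
        samples[d] = np.array([r.t_ncit[d] for r in records])
    for label, x in samples.items():
        report.summaries[label] = agr.summarize(x)

    # Stage 2: normality gate plus spot-size adequacy.
    for i, (label, x) in enumerate(samples.items()):
        report.normality[label] = {
            "lilliefors": agr.lilliefors_test(x, config.mc_reps, seed=s_lillie + i),
            "anderson_darling": agr.anderson_darling_test(x),
        }
    for d in distances:
        rejected = any(r.reject_at_5pct for r in report.normality[d].values())
        dist_ft = config.distances.get(d)
        if dist_ft is None or device.ds_ratio is None:
            spot_in, inadequate = float("nan"), False
        else:
            spot = dev.spot_diameter(dev.Length(dist_ft, "ft"), device.ds_ratio)
            ok, _ = dev.spot_adequate(spot, dev.Length(forehead_extent_in, "in"))
            spot_in, inadequate = spot.inches, not ok
        reasons = tuple(
            r for r, hit in (
                ("non-normal", rejected), ("spot-inadequate", inadequate)
            ) if hit
        )
        report.gate[d] = GateDecision(
            distance=d, normality_rejected=rejected, spot_inadequate=inadequate,
            spot_diameter_in=spot_in, excluded=bool(reasons), reasons=reasons,
        )
        if reasons:
            log.info("distance %s excluded: %s", d, ", ".join(reasons))

    surviving = [d for d in distances if not report.gate[d].excluded]
    if not surviving:
        raise PipelineError(
            "every NCIT distance failed the validity gate: "
            + "; ".join(f"{d}: {', '.join(report.gate[d].reasons)}" for d in distances)
        )

    # Stage 3: Bland-Altman on surviving distances; offset model from the
    # closest surviving distance (shortest distance = smallest spot).
    conf = ConfidenceSpec(df=len(records) - 1)
    for d in surviving:
        report.agreement[d] = agr.bland_altman(records, d, conf)
    primary = min(surviving, key=lambda d: config.distances.get(d, float("inf")))
    model = agr.fit_offset_model(report.agreement[primary])
    report.offset_model = model

    # Stage 4: specificity of the study sample itself (healthy, all afebrile
    # unless a reference reading crosses the cut).
    thresholds = {
        "lower": scr.screening_threshold(config.fever_cut_ref, model, -model.loa_halfwidth),
        "mid": scr.screening_threshold(config.fever_cut_ref, model, 0.0),
        "upper": scr.screening_threshold(config.fever_cut_ref, model, model.loa_halfwidth),
    }
    for name, thr in thresholds.items():
        report.study_specificity[name] = scr.classify(
            samples["ref"], samples[primary], config.fever_cut_ref, thr.t_star_ir
        )

    # Stage 5: reference cohort (synthetic unless supplied) and simulated NCIT.
    if cohort is None:
        cspec = cohort_spec or synth.CohortGenSpec()
        cspec = synth.CohortGenSpec(
            n=cspec.n, mean=cspec.mean, sd=cspec.sd, febrile_cut=cspec.febrile_cut,
            tail_mode=cspec.tail_mode, target_prevalence=cspec.target_prevalence,
            seed=s_cohort,
        )
        cohort = synth.generate_reference_cohort(cspec)
    elif cohort.source_scale == "oral":
        cohort = synth.oral_to_tat(cohort)
    ref = np.asarray(cohort.temps, dtype=float)
    sim = synth.simulate_ncit(ref, model, seed=s_sim)

    for name, thr in thresholds.items():
        report.cohort_accuracy[name] = scr.classify(
            ref, sim, config.fever_cut_ref, thr.t_star_ir
        )

    # Stage 6: ROC and the equal-error operating point.
    report.roc = scr.roc_curve(ref, sim, config.fever_cut_ref)
    try:
        report.equal_error = scr.equal_error_threshold(report.roc)
    except scr.NoCrossingError:
        report.equal_error = None

    return report
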