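"""Raw trace → normalized AUC response processing.

The response metric of the assay is the area under each well's 2 h
post-agonist time–luminescence curve.  Processing follows a fixed order:

1. ``correct_interwell`` — divide each trace by its mean pre-injection
   signal, removing well-to-well differences in cell number and substrate
   loading.
2. ``compute_auc`` — trapezoidal area under the corrected trace over the
   post-injection window.
3. ``subtract_solvent`` — subtract the mean AUC of the matching
   solvent-control wells (agonist-free, same condition) from each test
   well's AUC.
4. ``normalize_to_reference`` — express corrected AUCs in % of the
   reference agonist's maximal response within the same experiment
   (reference max is arbitrarily set to 100%).

Calling a stage before its prerequisite raises :class:`PipelineOrderError`.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .types import (
    AUCResponse,
    DegenerateWellError,
    MissingControlError,
    MissingReferenceError,
    PipelineOrderError,
    PlateExperiment,
    TimeLuminescenceTrace,
    group_by,
)

logger = logging.getLogger(__name__)

#: Default post-injection integration window (seconds): the full 2 h trace.
DEFAULT_AUC_WINDOW_S = 7200.0


def correct_interwell(
    trace: TimeLuminescenceTrace, equilibration_window: float | None = None
) -> TimeLuminescenceTrace:
    """Divide a trace by its mean pre-injection value.

    ``equilibration_window`` is the length (seconds) of the pre-injection
    window, ending at the injection time, over which the mean is taken;
    ``None`` uses the full equilibration phase.  The corrected trace has
    pre-injection mean exactly 1, so wells become comparable regardless of
    per-well expression or loading differences.

    Raises
    ------
    DegenerateWellError
        If the pre-injection mean is zero or negative (dead well); such
        wells are excluded downstream.
    ValueError
        If the window contains no reading.
    """
    t_inj = trace.injection_time
    start = trace.times[0] if equilibration_window is None else t_inj - equilibration_window
    mask = (trace.times >= start) & (trace.times <= t_inj)
    if not np.any(mask):
        raise ValueError("equilibration window contains no readings")
    pre_mean = float(np.mean(trace.values[mask]))
    if pre_mean <= 0:
        raise DegenerateWellError(
            f"pre-injection mean {pre_mean} is not positive; well cannot be corrected"
        )
    return trace.with_values(trace.values / pre_mean, corrected=True)


def compute_auc(
    trace: TimeLuminescenceTrace, window: tuple[float, float] | None = None
) -> float:
    """Trapezoidal area under the trace over ``window`` (seconds).

    The default window runs from the injection time to injection + 2 h,
    clipped to the end of the trace if the recording is shorter.  Window
    endpoints falling between samples are handled by linear interpolation,
    so the integral is exact for piecewise-linear signals.

    Raises ``ValueError`` for an explicit window outside the trace span.
    """
    if window is None:
        start = trace.injection_time
        end = min(trace.injection_time + DEFAULT_AUC_WINDOW_S, float(trace.times[-1]))
    else:
        start, end = float(window[0]), float(window[1])
        if start < trace.times[0] or end > trace.times[-1]:
            raise ValueError(
                f"window [{start}, {end}] outside trace span "
                f"[{trace.times[0]}, {trace.times[-1]}]"
            )
    if end <= start:
        raise ValueError(f"empty integration window [{start}, {end}]")
    inner = (trace.times > start) & (trace.times < end)
    ts = np.concatenate(([start], trace.times[inner], [end]))
    vs = np.interp(ts, trace.times, trace.values)
    return float(np.trapezoid(vs, ts))


def process_experiment(
    experiment: PlateExperiment,
    equilibration_window: float | None = None,
    auc_window: tuple[float, float] | None = None,
) -> list[AUCResponse]:
    """Interwell-correct every well and compute its raw AUC.

    Degenerate wells (non-positive pre-injection mean) are logged and
    excluded rather than propagated as errors, matching how dead wells are
    handled on real plates.
    """
    responses: list[AUCResponse] = []
    for ann, trace in experiment.wells:
        try:
            corrected = correct_interwell(trace, equilibration_window)
        except DegenerateWellError as exc:
            logger.warning("excluding degenerate well %s: %s", ann, exc)
            continue
        responses.append(
            AUCResponse(
                annotation=ann,
                auc_raw=compute_auc(corrected, auc_window),
                from_corrected_trace=True,
            )
        )
    return responses


def _control_key(ann) -> tuple:
    return (ann.experiment_id, ann.pathway, ann.receptor_variant, ann.compound)


def subtract_solvent(responses: Sequence[AUCResponse]) -> list[AUCResponse]:
    """Subtract the mean matched solvent-control AUC from each test well.

    Controls are matched on (experiment, pathway, receptor variant,
    compound); they are consumed by the subtraction and not emitted.

    Raises
    ------
    PipelineOrderError
        If any response was computed from an uncorrected trace.
    MissingControlError
        If a test well has no matching control, naming the condition.
    """
    for r in responses:
        if not r.from_corrected_trace:
            raise PipelineOrderError(
                "subtract_solvent requires interwell-corrected AUCs; "
                "run correct_interwell first"
            )
    controls = group_by(
        [r for r in responses if r.annotation.is_solvent_control],
        lambda r: _control_key(r.annotation),
    )
    out: list[AUCResponse] = []
    for r in responses:
        if r.annotation.is_solvent_control:
            continue
        key = _control_key(r.annotation)
        if key not in controls:
            raise MissingControlError(f"no solvent control matching condition {key}")
        ctrl_mean = float(np.mean([c.auc_raw for c in controls[key]]))
        out.append(
            AUCResponse(
                annotation=r.annotation,
                auc_raw=r.auc_raw,
                auc_corrected=r.auc_raw - ctrl_mean,
                from_corrected_trace=True,
            )
        )
    return out


def normalize_to_reference(
    responses: Sequence[AUCResponse],
    reference: str,
    plateau_concentration: float | None = None,
) -> list[AUCResponse]:
    """Express corrected AUCs in % of the reference agonist's maximum.

    The reference maximal response is the mean corrected AUC of the
    reference agonist's wells at its top plateau concentration — the highest
    tested concentration unless ``plateau_concentration`` designates one —
    computed separately per experiment and pathway (the reference agonist is
    included in every experiment precisely so each can be normalized on its
    own scale).  If the designated plateau wells are missing, the maximum of
    the reference's per-concentration mean AUCs is used and a warning logged.

    Negative corrected AUCs are retained; clipping them would bias the
    bottom of downstream concentration–response fits.
    """
    for r in responses:
        if r.auc_corrected is None:
            raise PipelineOrderError(
                "normalize_to_reference requires solvent-subtracted AUCs; "
                "run subtract_solvent first"
            )
    groups = group_by(
        responses,
        lambda r: (r.annotation.experiment_id, r.annotation.pathway, r.annotation.receptor_variant),
    )
    out: list[AUCResponse] = []
    for key, group in groups.items():
        ref_wells = [r for r in group if r.annotation.compound == reference]
        if not ref_wells:
            raise MissingReferenceError(
                f"reference agonist {reference!r} absent from experiment/pathway {key}"
            )
        by_conc = group_by(ref_wells, lambda r: r.annotation.concentration)
        plateau = plateau_concentration if plateau_concentration is not None else max(by_conc)
        if plateau in by_conc:
            ref_max = float(np.mean([r.auc_corrected for r in by_conc[plateau]]))
        else:
            logger.warning(
                "no reference wells at plateau concentration %g in %s; "
                "falling back to the maximal per-concentration mean",
                plateau,
                key,
            )
            ref_max = max(
                float(np.mean([r.auc_corrected for r in g])) for g in by_conc.values()
            )
        if ref_max == 0:
            raise MissingReferenceError(
                f"reference maximal response is zero in {key}; cannot normalize"
            )
        for r in group:
            out.append(
                AUCResponse(
                    annotation=r.annotation,
                    auc_raw=r.auc_raw,
                    auc_corrected=r.auc_corrected,
                    response_normalized=100.0 * r.auc_corrected / ref_max,
                    from_corrected_trace=True,
                )
            )
    return out


def process_study(
    experiments: Iterable[PlateExperiment],
    reference: str,
    equilibration_window: float | None = None,
    auc_window: tuple[float, float] | None = None,
    plateau_concentration: float | None = None,
) -> list[AUCResponse]:
    """Run the full correct → AUC → subtract → normalize chain on a study."""
    responses: list[AUCResponse] = []
    for exp in experiments:
        responses.extend(process_experiment(exp, equilibration_window, auc_window))
    return normalize_to_reference(
        subtract_solvent(responses), reference, plateau_concentration
    )
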