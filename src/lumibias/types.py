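"""Core domain types shared across the pipeline.

The pipeline works on kinetic luminescence plate assays of GPCR effector
recruitment (split-luciferase complementation): each well holds cells
expressing a receptor fused to one luciferase fragment and an effector
(β-arrestin-2 or a miniGαq sensor) fused to the other, so receptor
activation produces luminescence.  A well is described by its annotation
(compound, in-well concentration, pathway, receptor variant, experiment,
replicate) plus its time–luminescence trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PATHWAY_ARR = "barr2"
PATHWAY_GQ = "miniGq"
PATHWAYS = (PATHWAY_ARR, PATHWAY_GQ)

VARIANT_WT = "WT"
VARIANT_S159A = "S159A"
VARIANTS = (VARIANT_WT, VARIANT_S159A)


class LumibiasError(Exception):
    """Base class for pipeline errors."""


class DegenerateWellError(LumibiasError):
    """A well whose pre-injection signal cannot anchor interwell correction."""


class PipelineOrderError(LumibiasError):
    """A processing stage was invoked before its prerequisite stage."""


class MissingControlError(LumibiasError):
    """A test well has no matching solvent-control well."""


class MissingReferenceError(LumibiasError):
    """The reference agonist is absent from an experiment."""


class PlateParseError(LumibiasError):
    """A plate CSV file violates the long-format schema."""


@dataclass(frozen=True)
class WellAnnotation:
    """Metadata identifying one well of a recruitment assay plate.

    ``concentration`` is the in-well molar concentration; solvent-control
    wells carry concentration 0 and ``is_solvent_control=True`` (the two are
    required to agree).  ``compound`` on a control well names the condition
    the control accompanies.
    """

    compound: str
    concentration: float
    pathway: str
    receptor_variant: str
    experiment_id: str
    replicate: int
    is_solvent_control: bool = False

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}; expected one of {PATHWAYS}")
        if self.receptor_variant not in VARIANTS:
            raise ValueError(
                f"unknown receptor variant {self.receptor_variant!r}; expected one of {VARIANTS}"
            )
        if self.concentration < 0:
            raise ValueError(f"negative concentration {self.concentration!r}")
        if self.is_solvent_control != (self.concentration == 0):
            raise ValueError(
                "is_solvent_control must hold exactly when concentration == 0 "
                f"(got concentration={self.concentration}, "
                f"is_solvent_control={self.is_solvent_control})"
            )

    @property
    def condition(self) -> tuple:
        """Key identifying the experimental condition, ignoring replicate."""
        return (
            self.experiment_id,
            self.pathway,
            self.receptor_variant,
            self.compound,
            self.concentration,
        )


@dataclass
class TimeLuminescenceTrace:
    """One well's luminescence readings over time.

    ``times`` are seconds since the start of the plate read and span an
    equilibration phase followed by agonist injection at ``injection_time``
    and a monitoring phase (2 h in the emulated design).
    ``interwell_corrected`` records whether the trace has been divided by
    its pre-injection mean; downstream stages check it to enforce the
    processing order.
    """

    times: np.ndarray
    values: np.ndarray
    injection_time: float
    interwell_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 3:
            raise ValueError("a trace needs at least 3 readings")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("luminescence values must be nonnegative")
        if not (self.times[0] <= self.injection_time <= self.times[-1]):
            raise ValueError("injection_time must lie within the recorded time range")
        if np.count_nonzero(self.times > self.injection_time) < 2:
            raise ValueError("need at least 2 post-injection readings")

    def with_values(self, values: np.ndarray, *, corrected: bool | None = None) -> "TimeLuminescenceTrace":
        return TimeLuminescenceTrace(
            times=self.times.copy(),
            values=np.asarray(values, dtype=float),
            injection_time=self.injection_time,
            interwell_corrected=self.interwell_corrected if corrected is None else corrected,
        )


@dataclass
class PlateExperiment:
    """All wells of one independent experiment (one biological replicate).

    Both recruitment assays (βarr2 and miniGαq) run back-to-back with the
    same dilutions, so wells from both pathways share one experiment.
    Invariants: all traces share the time grid, and every test condition has
    a matching solvent-control well in the same experiment and pathway.
    """

    wells: list[tuple[WellAnnotation, TimeLuminescenceTrace]]
    experiment_id: str
    receptor_variant: str

    def __post_init__(self) -> None:
        if self.receptor_variant not in VARIANTS:
            raise ValueError(f"unknown receptor variant {self.receptor_variant!r}")
        if not self.wells:
            raise ValueError("an experiment must contain at least one well")
        grid = self.wells[0][1].times
        for ann, trace in self.wells:
            if ann.experiment_id != self.experiment_id:
                raise ValueError(
                    f"well {ann} labelled {ann.experiment_id!r} inside experiment "
                    f"{self.experiment_id!r}"
                )
            if trace.times.shape != grid.shape or not np.array_equal(trace.times, grid):
                raise ValueError("all traces in an experiment must share the time grid")
        controls = {
            (a.pathway, a.receptor_variant, a.compound)
            for a, _ in self.wells
            if a.is_solvent_control
        }
        for ann, _ in self.wells:
            if ann.is_solvent_control:
                continue
            key = (ann.pathway, ann.receptor_variant, ann.compound)
            if key not in controls:
                raise ValueError(
                    f"condition {key} in experiment {self.experiment_id!r} has no "
                    "matching solvent-control well"
                )

    def annotations(self) -> list[WellAnnotation]:
        return [a for a, _ in self.wells]


@dataclass
class AUCResponse:
    """Per-well response at successive processing stages.

    ``auc_raw`` is the trapezoidal area under the (interwell-corrected)
    post-injection trace; ``auc_corrected`` appears after solvent
    subtraction; ``response_normalized`` (in % of the reference agonist's
    maximal response) appears after normalization.  Stages populate their
    field and later stages require it, which pins the processing order.
    """

    annotation: WellAnnotation
    auc_raw: float
    auc_corrected: float | None = None
    response_normalized: float | None = None
    from_corrected_trace: bool = True


def group_by(items: Sequence, key) -> dict:
    out: dict = {}
    for item in items:
        out.setdefault(key(item), []).append(item)
    return out
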