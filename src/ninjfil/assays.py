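"""Membrane-permeabilization assay normalizations.

All quantifications used downstream of the wet-lab readouts are simple,
explicit formulas; they are collected here so they are tested once and used
everywhere:

* percent-of-controls (LDH lysis %, propidium-iodide uptake %):
  100 * (sample - negative) / (full - negative);
* proteoliposome dithionite-quench permeability:
  100 - 200 * (F_dit - F_triton) / (F_initial - F_triton), where a sealed
  symmetric liposome quenches only its outer leaflet (50% signal loss -> 0%
  permeability) and a fully permeable one quenches both (-> 100%);
* liposome dye release %: 100 * (sample - diluent) / (triton - diluent);
* DRAQ7 influx normalization (F_t - F_i)/F_i with lysis onset defined as
  the first time the normalized value exceeds 1;
* spatial-inhomogeneity normalization D_t - D_i.

Out-of-range percentages are reported unclamped with a flag; clamping would
discard quality-control information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidModelError

PHASE_BASELINE = "baseline"
PHASE_DITHIONITE = "post_dithionite"
PHASE_TRITON = "post_triton"


@dataclass
class AssayValues:
    """Endpoint signals: sample, negative control, and 100% (full) control."""

    sample: float
    negative_control: float
    full_control: float

    def validate(self) -> None:
        if self.full_control == self.negative_control:
            raise InvalidModelError(
                "full control equals negative control; percentage is undefined"
            )


@dataclass
class PercentResult:
    value: float
    out_of_range: bool


def percent_of_controls(v: AssayValues) -> PercentResult:
    """Linear percent-of-controls rescaling (LDH lysis %, PI uptake %)."""
    v.validate()
    pct = 100.0 * (v.sample - v.negative_control) / (v.full_control - v.negative_control)
    return PercentResult(value=float(pct), out_of_range=not (0.0 <= pct <= 100.0))


def dye_release_percent(
    sample_signal: float, diluent_signal: float, triton_signal: float
) -> PercentResult:
    """Liposome dye release normalized to the Triton (full release) endpoint."""
    if triton_signal == diluent_signal:
        raise InvalidModelError("triton signal equals diluent signal")
    pct = 100.0 * (sample_signal - diluent_signal) / (triton_signal - diluent_signal)
    return PercentResult(value=float(pct), out_of_range=not (0.0 <= pct <= 100.0))


@dataclass
class AssayTrace:
    """A fluorescence time course with per-point phase annotations.

    ``time`` in seconds, strictly increasing; ``phase`` is one label per
    point ('baseline', 'post_dithionite', 'post_triton' for the dithionite
    quench protocol, or 'pre'/'post' where applicable).
    """

    time: np.ndarray
    signal: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.signal = np.asarray(self.signal, float)
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
        if len(self.time) != len(self.signal):
            raise InvalidModelError("time and signal differ in length")
        if len(self.time) == 0:
            raise InvalidModelError("empty trace")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidModelError("time must be strictly increasing")

    def phase_plateau(self, name: str, final_fraction: float = 0.2) -> float:
        """Plateau estimate: median of the final ``final_fraction`` of a phase."""
        if self.phase is None:
            raise InvalidModelError("trace has no phase annotations")
        mask = self.phase == name
        n = int(mask.sum())
        if n == 0:
            raise InvalidModelError(f"trace has no {name!r} phase")
        values = self.signal[mask]
        tail = max(1, int(round(final_fraction * n)))
        return float(np.median(values[-tail:]))

    @classmethod
    def read_csv(cls, path) -> "AssayTrace":
        df = pd.read_csv(path)
        phase = df["phase"].to_numpy() if "phase" in df.columns else None
        return cls(time=df["time_s"].to_numpy(), signal=df["signal"].to_numpy(), phase=phase)

    def to_csv(self, path) -> None:
        out = {"time_s": self.time, "signal": self.signal}
        if self.phase is not None:
            out["phase"] = self.phase
        pd.DataFrame(out).to_csv(path, index=False)


def liposome_permeability(trace: AssayTrace, final_fraction: float = 0.2) -> float:
    """Dithionite-quench permeability % of a three-phase proteoliposome trace.

    permeability = 100 - 200 * (F_dit - F_triton) / (F_initial - F_triton),
    with each F estimated as the plateau (median of the final 20%) of its
    phase: baseline, after dithionite addition, after Triton X-100.
    """
    f_initial = trace.phase_plateau(PHASE_BASELINE, final_fraction)
    f_dit = trace.phase_plateau(PHASE_DITHIONITE, final_fraction)
    f_triton = trace.phase_plateau(PHASE_TRITON, final_fraction)
    return permeability_from_levels(f_initial, f_dit, f_triton)


def permeability_from_levels(f_initial: float, f_dit: float, f_triton: float) -> float:
    """Permeability % from the three plateau levels directly."""
    if f_initial == f_triton:
        raise InvalidModelError("F_initial equals F_triton; permeability is undefined")
    return float(100.0 - 200.0 * (f_dit - f_triton) / (f_initial - f_triton))


@dataclass
class Draq7Result:
    """Normalized DRAQ7 influx trace and lysis onset."""

    time: np.ndarray
    normalized: np.ndarray  # (F_t - F_i) / F_i
    onset_time: float | None
    time_relative: np.ndarray | None  # time - onset_time when onset found


def draq7_normalize_and_onset(trace: AssayTrace, threshold: float = 1.0) -> Draq7Result:
    """Normalize a DRAQ7 trace to its initial intensity and locate lysis onset.

    normalized_t = (F_t - F_i)/F_i with F_i the first point; onset is the
    first time the normalized value strictly exceeds ``threshold`` (a
    doubling of nuclear intensity for the default 1). Times are also
    returned re-zeroed at onset when one is found.
    """
    f_i = trace.signal[0]
    if f_i == 0:
        raise InvalidModelError("initial intensity F_i is zero; cannot normalize")
    normalized = (trace.signal - f_i) / f_i
    above = np.flatnonzero(normalized > threshold)
    if len(above) == 0:
        return Draq7Result(time=trace.time, normalized=normalized,
                           onset_time=None, time_relative=None)
    onset = float(trace.time[above[0]])
    return Draq7Result(
        time=trace.time,
        normalized=normalized,
        onset_time=onset,
        time_relative=trace.time - onset,
    )


@dataclass
class InhomogeneitySeries:
    """Spatial-distribution inhomogeneity over time (externally computed D values)."""

    time: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.d = np.asarray(self.d, float)
        if len(self.time) != len(self.d) or len(self.d) == 0:
            raise InvalidModelError("series must be non-empty with matching lengths")

    @property
    def d_i(self) -> float:
        return float(self.d[0])


def inhomogeneity_normalize(series: InhomogeneitySeries) -> np.ndarray:
    """Normalize an inhomogeneity series to its initial value: D_t - D_i."""
    return series.d - series.d_i


@dataclass
class PlateLayout:
    """Plate-reader values in tidy form with roles sample/negative/full."""

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def read_csv(cls, path) -> "PlateLayout":
        df = pd.read_csv(path)
        needed = {"sample", "value", "role"}
        if not needed <= set(df.columns):
            raise InvalidModelError(f"plate CSV needs columns {sorted(needed)}")
        return cls(df=df)

    def percentages(self) -> pd.DataFrame:
        """Percent-of-controls for every row with role 'sample'."""
        neg = self.df.loc[self.df["role"] == "negative", "value"].mean()
        full = self.df.loc[self.df["role"] == "full", "value"].mean()
        rows = []
        for _, row in self.df[self.df["role"] == "sample"].iterrows():
            res = percent_of_controls(
                AssayValues(sample=row["value"], negative_control=neg, full_control=full)
            )
            rows.append(
                {"sample": row["sample"], "percent": res.value,
                 "out_of_range": res.out_of_range}
            )
        return pd.DataFrame(rows)
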