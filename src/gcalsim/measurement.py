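"""Dependent variables: contrast response, orientation maps, tuning histograms.

Measurement is a pure read-out: gratings are presented with plasticity and
homeostasis untouched (no state mutation anywhere on this path), and summary
quantities mirror the standard map-measurement practice — per-unit orientation
preference and selectivity by vector summation over a battery of oriented
gratings (angles doubled, responses aggregated over phases by maximum), and an
activation-weighted histogram of preferences whose shape diagnostics (excess
kurtosis, peak location, bimodality) quantify orientation-tuning broadening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelState, present
from .stimuli import GratingSpec, cs_battery, grating, map_battery

__all__ = [
    "ContrastResponseTable",
    "OrientationMapResult",
    "TuningHistogram",
    "contrast_response",
    "orientation_map",
    "tuning_histogram",
    "weighted_excess_kurtosis",
    "measure_state",
]


def _render(state: ModelState, spec: GratingSpec) -> np.ndarray:
    return grating(spec, state.sheets["retina"])


def contrast_response(
    state: ModelState,
    battery: list[GratingSpec] | None = None,
    model_id: str | None = None,
) -> pd.DataFrame:
    """Mean/max/std V1 activation for each grating of the battery.

    Returns a tidy table keyed by (model_id, spatial_frequency, contrast,
    orientation).  The mean is taken over *all* V1 units.  The state is not
    modified.
    """
    battery = battery if battery is not None else cs_battery(state.config.measurement)
    rows = []
    for spec in battery:
        v1 = present(state, _render(state, spec))
        rows.append(
            {
                "model_id": model_id,
                "spatial_frequency": spec.spatial_frequency,
                "contrast": spec.contrast,
                "orientation": spec.orientation,
                "mean_activation": float(v1.mean()),
                "max_activation": float(v1.max()),
                "std_activation": float(v1.std()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OrientationMapResult:
    """Per-unit orientation preference and selectivity, plus raw responses."""

    preference: np.ndarray  # (n, n) angles in [0, pi); NaN where undefined
    selectivity: np.ndarray  # (n, n) vector-sum magnitude in [0, 1]
    defined: np.ndarray  # (n, n) bool, False where all responses were zero
    orientations: np.ndarray  # battery orientations
    responses: np.ndarray  # (n_orientations, n, n) phase-aggregated responses

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())


def orientation_map(state: ModelState, battery: list[GratingSpec] | None = None) -> OrientationMapResult:
    """Measure the orientation preference/selectivity map.

    Presents the map battery (orientations x phases), aggregates each unit's
    response over phases by the maximum, and computes preference and
    selectivity by vector summation with doubled angles.  Deterministic given
    the state; the state is unchanged.
    """
    battery = battery if battery is not None else map_battery(state.config.measurement)
    by_ori: dict[float, np.ndarray] = {}
    for spec in battery:
        v1 = present(state, _render(state, spec))
        key = float(spec.orientation) % np.pi
        if key in by_ori:
            np.maximum(by_ori[key], v1, out=by_ori[key])
        else:
            by_ori[key] = v1.copy()
    oris = np.array(sorted(by_ori))
    resp = np.stack([by_ori[o] for o in oris])
    z = np.tensordot(np.exp(2j * oris), resp, axes=(0, 0))
    total = resp.sum(axis=0)
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        selectivity = np.where(defined, np.abs(z) / np.where(defined, total, 1.0), 0.0)
        preference = np.mod(np.angle(z) / 2.0, np.pi)
    preference = np.where(defined, preference, np.nan)
    return OrientationMapResult(
        preference=preference,
        selectivity=selectivity,
        defined=defined,
        orientations=oris,
        responses=resp,
    )


def weighted_excess_kurtosis(values: np.ndarray, weights: np.ndarray) -> float:
    """Fisher excess kurtosis of a weighted sample (normal => 0).

    Treats the angles as plain linear values, matching the histogram's linear
    radians axis.
    """
    w = np.asarray(weights, dtype=float).ravel()
    x = np.asarray(values, dtype=float).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    m = (w * x).sum() / total
    d = x - m
    m2 = (w * d**2).sum() / total
    if m2 == 0:
        return 0.0
    m4 = (w * d**4).sum() / total
    return float(m4 / m2**2 - 3.0)


@dataclass
class TuningHistogram:
    """Activation-weighted orientation tuning histogram and shape diagnostics."""

    bin_edges: np.ndarray  # n_bins + 1 edges over [0, pi)
    weights: np.ndarray  # per-bin summed activation
    excess_kurtosis: float
    peak_orientation: float  # argmax bin center, radians
    peak_shifted: bool  # peak more than one bin from pi/2
    bimodal: bool
    trough_fraction: float = 0.8

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _detect_bimodality(hist: np.ndarray, trough_fraction: float) -> bool:
    """Two substantial local maxima separated by a sufficiently deep trough.

    Candidate peaks must reach at least a quarter of the histogram maximum
    (prominence floor against bin jaggedness); the distribution is bimodal if
    the trough between two candidates dips below ``trough_fraction`` of the
    lower one.
    """
    n = len(hist)
    if n == 0 or hist.max() <= 0:
        return False
    floor = 0.25 * hist.max()
    peaks = [
        i
        for i in range(n)
        if hist[i] >= floor
        and (i == 0 or hist[i] >= hist[i - 1])
        and (i == n - 1 or hist[i] > hist[i + 1])
    ]
    if len(peaks) < 2:
        return False
    for ai, a in enumerate(peaks):
        for b in peaks[ai + 1 :]:
            trough = hist[a + 1 : b].min() if b > a + 1 else min(hist[a], hist[b])
            if trough < trough_fraction * min(hist[a], hist[b]):
                return True
    return False


def tuning_histogram(
    omap: OrientationMapResult,
    v1_activity: np.ndarray,
    n_bins: int = 36,
    trough_fraction: float = 0.8,
) -> TuningHistogram:
    """Activation-weighted histogram of orientation preferences.

    Each unit contributes its activation (to the probe grating, by default the
    medium-frequency 80%-contrast vertical stimulus) at its preferred
    orientation.  Excess kurtosis is computed on the activation-weighted sample
    of preference angles; the peak is the argmax bin center; bimodality is a
    declared trough heuristic reported alongside the raw histogram.
    """
    act = np.asarray(v1_activity, dtype=float)
    ok = omap.defined & (act > 0)
    w = act[ok]
    angles = omap.preference[ok]
    if w.sum() <= 0:
        raise ValueError("undefined histogram: total activation weight is zero")
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    hist, _ = np.histogram(angles, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = float(centers[int(np.argmax(hist))])
    bin_width = np.pi / n_bins
    return TuningHistogram(
        bin_edges=edges,
        weights=hist,
        excess_kurtosis=weighted_excess_kurtosis(angles, w),
        peak_orientation=peak,
        peak_shifted=bool(abs(peak - np.pi / 2) > bin_width + 1e-12),
        bimodal=_detect_bimodality(hist, trough_fraction),
        trough_fraction=trough_fraction,
    )


@dataclass
class MeasurementResult:
    """Bundle of all post-training read-outs for one model checkpoint."""

    contrast_table: pd.DataFrame
    omap: OrientationMapResult
    histogram: TuningHistogram
    probe_activity: np.ndarray = field(repr=False, default=None)


def measure_state(state: ModelState, model_id: str | None = None) -> MeasurementResult:
    """Full test battery: contrast response, orientation map, tuning histogram."""
    m = state.config.measurement
    table = contrast_response(state, model_id=model_id)
    omap = orientation_map(state)
    probe = present(
        state,
        _render(
            state,
            GratingSpec(
                spatial_frequency=m.histogram_frequency,
                contrast=m.histogram_contrast,
            ),
        ),
    )
    hist = tuning_histogram(
        omap, probe, n_bins=m.n_bins, trough_fraction=m.bimodality_trough_fraction
    )
    return MeasurementResult(
        contrast_table=table, omap=omap, histogram=hist, probe_activity=probe
    )
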