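"""Quantitation of in vitro binding assays.

Two assays are covered: DNase I footprinting, where a protein-bound DNA
stretch is protected from nuclease cleavage and shows up as a dip in
fragment intensity relative to a no-protein control; and the gel mobility
shift assay (EMSA), where the fraction of probe in the shifted
protein-DNA complex band, titrated over protein concentration, traces an
equilibrium binding curve. The binding model is a single-site hyperbola
f([P]) = [P] / ([P] + Kd), fitted by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize_scalar

__all__ = [
    "FootprintTrace",
    "ProtectedRegion",
    "BindingCurve",
    "AffinityEstimate",
    "call_protected_regions",
    "fraction_bound",
    "fit_binding",
]


@dataclass(frozen=True)
class FootprintTrace:
    """Paired intensity traces (no-protein control vs. protein-bound)."""

    label: str
    positions: np.ndarray  # contiguous integers
    control_intensity: np.ndarray
    bound_intensity: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        if len(pos) != len(self.control_intensity) or len(pos) != len(self.bound_intensity):
            raise ValueError(f"{self.label}: channel lengths differ")
        if len(pos) > 1 and not np.all(np.diff(pos) == 1):
            raise ValueError(f"{self.label}: positions must increase by 1")
        if np.any(np.asarray(self.control_intensity) < 0) or np.any(
            np.asarray(self.bound_intensity) < 0
        ):
            raise ValueError(f"{self.label}: intensities must be non-negative")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "FootprintTrace":
        df = pd.read_csv(path)
        missing = [c for c in ("position", "control", "bound") if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing footprint columns {missing}")
        return cls(
            label or str(path),
            df["position"].to_numpy(int),
            df["control"].to_numpy(float),
            df["bound"].to_numpy(float),
        )


@dataclass(frozen=True)
class ProtectedRegion:
    start: int  # trace coordinates, inclusive
    end: int
    mean_protection_ratio: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BindingCurve:
    protein_concentrations: np.ndarray  # nM
    fraction_bound: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.protein_concentrations, float)
        frac = np.asarray(self.fraction_bound, float)
        if len(conc) != len(frac):
            raise ValueError("concentration and fraction arrays differ in length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "BindingCurve":
        df = pd.read_csv(path)
        if "fraction_bound" in df.columns:
            frac = df["fraction_bound"].to_numpy(float)
        elif {"free", "complex"} <= set(df.columns):
            frac = np.array(
                [fraction_bound(f, c) for f, c in zip(df["free"], df["complex"])]
            )
        else:
            raise ValueError(f"{path}: need fraction_bound or free+complex columns")
        return cls(df["concentration_nM"].to_numpy(float), frac)


@dataclass(frozen=True)
class AffinityEstimate:
    kd_nM: float
    rss: float
    converged: bool


# ---------------------------------------------------------------------------
# footprints


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def call_protected_regions(
    trace: FootprintTrace,
    ratio_threshold: float = 0.5,
    min_len: int = 8,
    smooth_window: int = 3,
    merge_gap: int = 2,
) -> list[ProtectedRegion]:
    """Call stretches protected from cleavage in a bound-vs-control trace.

    Both channels are lightly smoothed and normalized to unit mean; the
    per-position ratio bound/control is thresholded and maximal
    sub-threshold runs become regions. Normalization is two-pass: a first
    pass finds candidate protected windows, whose positions are then
    excluded from the normalizing means so deep protection does not bias
    the baseline. Nearby runs (gap <= ``merge_gap``) are merged before the
    minimum-length filter.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    control = np.asarray(trace.control_intensity, float)
    bound = np.asarray(trace.bound_intensity, float)
    if not np.any(control > 0):
        raise ValueError(f"{trace.label}: all-zero control channel")

    ctrl_s = uniform_filter1d(control, smooth_window, mode="nearest")
    bound_s = uniform_filter1d(bound, smooth_window, mode="nearest")

    def ratio_given(baseline_mask: np.ndarray) -> np.ndarray:
        c_norm = ctrl_s / ctrl_s[baseline_mask].mean()
        b_norm = bound_s / bound_s[baseline_mask].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(c_norm > 0, b_norm / np.maximum(c_norm, 1e-12), np.inf)
        return r

    all_positions = np.ones_like(control, dtype=bool)
    ratio1 = ratio_given(all_positions)
    candidate = ratio1 <= ratio_threshold
    baseline = ~candidate
    if not baseline.any() or not bound_s[baseline].mean() > 0:
        baseline = all_positions
    ratio = ratio_given(baseline)

    below = ratio <= ratio_threshold
    runs = _runs(below)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    regions = []
    offset = int(trace.positions[0])
    for s, e in merged:
        if e - s + 1 >= min_len:
            regions.append(
                ProtectedRegion(
                    start=offset + s,
                    end=offset + e,
                    mean_protection_ratio=float(ratio[s : e + 1].mean()),
                )
            )
    return regions


def regions_to_frame(regions: Sequence[ProtectedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [r.length for r in regions],
            "mean_protection_ratio": [r.mean_protection_ratio for r in regions],
        }
    )


# ---------------------------------------------------------------------------
# binding curves


def fraction_bound(free_band: float, complex_band: float) -> float:
    """Fraction of probe in the complex band: complex / (free + complex)."""
    if free_band < 0 or complex_band < 0:
        raise ValueError("band intensities must be non-negative")
    total = free_band + complex_band
    if total == 0:
        raise ValueError("free and complex bands are both zero")
    return complex_band / total


def hyperbolic(conc, kd):
    """Single-site equilibrium occupancy f([P]) = [P] / ([P] + Kd)."""
    conc = np.asarray(conc, float)
    return conc / (conc + kd)


def fit_binding(curve: BindingCurve) -> AffinityEstimate:
    """Least-squares Kd for the single-site model.

    The search is bounded to (0, 10 x max concentration]; an estimate
    pinned to the upper bound, or a curve with no binding signal, is
    reported as non-converged rather than raising.
    """
    conc = np.asarray(curve.protein_concentrations, float)
    frac = np.asarray(curve.fraction_bound, float)
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if not np.any(frac > 0):
        rss = float(np.sum(frac**2))
        return AffinityEstimate(kd_nM=float("nan"), rss=rss, converged=False)

    upper = 10.0 * conc.max()

    def sse(kd: float) -> float:
        return float(np.sum((frac - hyperbolic(conc, kd)) ** 2))

    res = minimize_scalar(sse, bounds=(1e-9, upper), method="bounded")
    kd = float(res.x)
    converged = bool(res.success and kd < 0.999 * upper)
    return AffinityEstimate(kd_nM=kd, rss=float(res.fun), converged=converged)
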