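"""Competition, persistence and growth statistics for barcoded libraries.

The central readout of a pooled adhesion competition is the change in each
strain's relative read percentage between the input mixture (T0) and the
recovered adherent fraction (TF), written delta% (TF - T0). Percentages are
computed over whitelist reads only, so deltas within a sample pair sum to
zero (compositional closure). Washed wells are compared against unwashed
control wells per strain with a two-tailed unpaired t-test (Welch by
default); p-values are reported unadjusted, with an optional
Benjamini-Hochberg column.

Also provided: CFU-based adhesion/competition ratios, the recombinant
recovery fold change, the gastrointestinal clearance rate (absolute slope
of log10 CFU per day over a fit window, with detection-limit handling) and
the exponential growth rate in doublings per hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demux import SampleCounts


@dataclass(frozen=True)
class ClearanceFit:
    """Log-linear clearance fit: rate is |slope| in log10 CFU per day."""

    slope: float
    intercept: float
    clearance_rate: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class GrowthFit:
    """Exponential-phase fit: rate is the slope of log2(OD) in doublings/h."""

    rate: float
    intercept: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class CFUSeries:
    """A colony-count time course for one subject, with a detection limit."""

    subject_id: str
    days: tuple[float, ...]
    cfu_per_100mg: tuple[float, ...]
    detection_limit: float | None = None

    def below_detection(self) -> tuple[bool, ...]:
        if self.detection_limit is None:
            return tuple(False for _ in self.cfu_per_100mg)
        return tuple(c < self.detection_limit for c in self.cfu_per_100mg)

    def fit_clearance(self, **kwargs) -> "ClearanceFit":
        return clearance_rate(
            self.days, self.cfu_per_100mg, self.detection_limit, **kwargs
        )


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time course (hours) for one culture."""

    time_h: tuple[float, ...]
    od600: tuple[float, ...]

    def fit_rate(self, window: tuple[float, float] | None = None) -> "GrowthFit":
        return growth_rate(self.time_h, self.od600, window=window)


def delta_percent(t0: SampleCounts, tf: SampleCounts) -> pd.DataFrame:
    """Per-strain delta% (TF - T0) between two samples sharing a whitelist.

    Returns a tidy frame with columns ``percent_t0``, ``percent_tf`` and
    ``delta_percent``; deltas sum to zero by construction.
    """
    p0, pf = t0.percentages(), tf.percentages()
    if set(p0) != set(pf):
        if not set(p0) & set(pf):
            raise ValueError("samples share no whitelist strains")
        raise ValueError(
            f"samples do not share a whitelist: "
            f"{sorted(set(p0) ^ set(pf))} present on one side only"
        )
    strains = sorted(p0)
    df = pd.DataFrame(
        {
            "strain": strains,
            "percent_t0": [p0[s] for s in strains],
            "percent_tf": [pf[s] for s in strains],
        }
    )
    df["delta_percent"] = df["percent_tf"] - df["percent_t0"]
    return df


def summarize_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error (sd / sqrt(n)) of replicate values; n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standard error undefined for fewer than 2 replicates")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = False,
) -> tuple[float, float, float]:
    """Two-tailed unpaired t-test (Welch by default): (t, df, p).

    Two zero-variance groups with equal means return t=0, p=1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2 if equal_variance else float(a.size - 1)
        return 0.0, float(df), 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)


def competition_table(
    washed: Mapping[str, Sequence[float]],
    unwashed: Mapping[str, Sequence[float]],
    equal_variance: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-strain replicate summary and washed-vs-unwashed t-tests.

    ``washed``/``unwashed`` map strain -> replicate delta% values. A strain
    is flagged ``reduced_adhesion`` when its washed deltas are significantly
    *below* the unwashed control (p < 0.05 and negative shift); closure
    pushes small positive spillover onto non-affected strains, which is not
    evidence of an adhesion defect. Optional BH-adjusted p column.
    """
    if set(washed) != set(unwashed):
        raise ValueError("washed and unwashed tables must cover the same strains")
    rows = []
    for strain in sorted(washed):
        mw, sw = summarize_replicates(washed[strain])
        mu, su = summarize_replicates(unwashed[strain])
        t, df, p = unpaired_t_test(washed[strain], unwashed[strain], equal_variance)
        rows.append(
            {
                "strain": strain,
                "mean_washed": mw,
                "sem_washed": sw,
                "mean_unwashed": mu,
                "sem_unwashed": su,
                "t": t,
                "df": df,
                "p_value": p,
                "reduced_adhesion": bool(p < 0.05 and mw < mu),
            }
        )
    out = pd.DataFrame(rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def relative_adhesion(
    input_cfu: float, recovered_cfu: float, control_percent: float
) -> tuple[float, float]:
    """Percent adhesion and percent relative to a control strain's percent."""
    if input_cfu <= 0:
        raise ValueError("input CFU must be positive")
    if control_percent == 0:
        raise ValueError("control percent adhesion of 0 leaves relative adhesion undefined")
    percent = 100.0 * recovered_cfu / input_cfu
    if percent > 100.0:
        warnings.warn(
            f"recovered CFU exceeds input CFU (adhesion {percent:.1f}%)",
            stacklevel=2,
        )
    return percent, 100.0 * percent / control_percent


def competition_ratio(total_cfu: float, marker_cfu: float) -> float:
    """Marker:non-marker ratio where the non-marker count is total - marker.

    Used when one competitor carries a selectable marker (e.g. rifampicin
    resistance): plate totals minus marker-resistant counts give the other
    strain. Returns ``inf`` (with a warning) when the non-marker count is 0.
    """
    if marker_cfu < 0 or total_cfu < 0:
        raise ValueError("CFU counts must be nonnegative")
    if marker_cfu > total_cfu:
        raise ValueError("marker CFU cannot exceed total CFU")
    other = total_cfu - marker_cfu
    if other == 0:
        warnings.warn("non-marker count is zero; ratio is infinite", stacklevel=2)
        return float("inf")
    return marker_cfu / other


def ratio_fold_change(ratio_tf: float, ratio_t0: float) -> float:
    """Fold change of the competition ratio across timepoints (TF / T0)."""
    if ratio_t0 == 0:
        raise ValueError("T0 ratio of 0 leaves the fold change undefined")
    return ratio_tf / ratio_t0


def recovery_fold_change(
    patch_recombinant_fraction: float, direct_efficiency: float
) -> tuple[float, int]:
    """Enrichment of recombinant recovery under co-selection screening.

    Ratio of the recombinant fraction among pre-selected (marker-repaired)
    colonies to the direct recombineering efficiency; returned raw and
    rounded to the nearest integer fold.
    """
    for name, v in (
        ("patch_recombinant_fraction", patch_recombinant_fraction),
        ("direct_efficiency", direct_efficiency),
    ):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    fold = patch_recombinant_fraction / direct_efficiency
    return fold, int(round(fold))


def clearance_rate(
    days: Sequence[float],
    cfu_per_100mg: Sequence[float],
    detection_limit: float | None = None,
    window: tuple[float, float] = (0.0, 5.0),
    lod_policy: Literal["half_lod", "drop"] = "half_lod",
) -> ClearanceFit:
    """Clearance rate = |slope| of log10(CFU/100 mg) vs day within a window.

    Points below the detection limit inside the window are substituted
    with LOD/2 (``half_lod``) or dropped; a trailing run of consecutive
    below-LOD days is always excluded (once the organism is cleared,
    further censored days carry no slope information).
    """
    d = np.asarray(days, dtype=float)
    c = np.asarray(cfu_per_100mg, dtype=float)
    if d.size != c.size:
        raise ValueError("days and CFU arrays must have equal length")
    if np.any(np.diff(d) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    in_win = (d >= window[0]) & (d <= window[1])
    d, c = d[in_win], c[in_win]
    if detection_limit is not None:
        below = c < detection_limit
        # drop trailing consecutive censored days
        last_detected = int(np.max(np.nonzero(~below)[0])) if np.any(~below) else -1
        d, c, below = d[: last_detected + 1], c[: last_detected + 1], below[: last_detected + 1]
        if lod_policy == "half_lod":
            c = np.where(below, detection_limit / 2.0, c)
        elif lod_policy == "drop":
            d, c = d[~below], c[~below]
        else:
            raise ValueError(f"unknown lod_policy {lod_policy!r}")
    if d.size < 2:
        raise ValueError("need >= 2 usable timepoints inside the fit window")
    if np.any(c <= 0):
        raise ValueError("CFU values must be positive to take log10")
    res = stats.linregress(d, np.log10(c))
    return ClearanceFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        clearance_rate=abs(float(res.slope)),
        window=window,
        n_points=int(d.size),
    )


def growth_rate(
    time_h: Sequence[float],
    od600: Sequence[float],
    window: tuple[float, float] | None = None,
) -> GrowthFit:
    """Growth rate in doublings/h: slope of log2(OD600) vs time in a window."""
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.size != od.size:
        raise ValueError("time and OD arrays must have equal length")
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, od = t[sel], od[sel]
    else:
        window = (float(t.min()), float(t.max())) if t.size else (0.0, 0.0)
    if t.size < 3:
        raise ValueError("need >= 3 points inside the fit window")
    if np.any(od <= 0):
        raise ValueError("OD values inside the window must be positive")
    res = stats.linregress(t, np.log2(od))
    return GrowthFit(
        rate=float(res.slope),
        intercept=float(res.intercept),
        window=window,
        n_points=int(t.size),
    )
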