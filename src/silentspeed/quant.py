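"""Assay-level quantifications.

Boltzmann sigmoidal fits of thermal-aggregation melt curves (T_a = the
temperature at which half the protein remains membrane-soluble),
decay time courses relative to t0, western-blot band normalization
(B+C over the geometric mean of NPT and ACTB, wild-type = 100%),
ddCt relative expression, standard-curve qPCR efficiency, two-channel
tRNA-microarray ratio normalization with spike-in rescaling, and
integer-truncated classification proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .assay_synth import boltzmann
from .errors import ValidationError

__all__ = ["BoltzmannFit", "RelativeExpression", "fit_boltzmann",
           "decay_timecourse", "normalize_expression", "ddct",
           "efficiency_from_slope", "microarray_relative_abundance",
           "classification_proportion"]


@dataclass
class BoltzmannFit:
    """Fitted melt curve: midpoint T_a, slope, plateaus, fit quality."""

    ta_c: float
    ta_se_c: float
    slope_c: float
    top: float
    bottom: float
    r_squared: float
    flagged: bool = False            # True when the data are not sigmoidal
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bottom >= self.top:
            raise ValidationError("bottom plateau must lie below top plateau")


@dataclass
class RelativeExpression:
    sample: str
    percent_of_reference: float
    normalizers: tuple
    band_b: float | None = None
    band_c: float | None = None

    @property
    def c_over_b(self) -> float | None:
        if self.band_b in (None, 0) or self.band_c is None:
            return None
        return self.band_c / self.band_b


def fit_boltzmann(melt: pd.DataFrame, min_r_squared: float = 0.5) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid fit of a melt curve.

    Input columns: temperature_c, soluble_fraction (fractions relative
    to the 37 degC point; a replicate column is optional and simply
    pooled).  All four parameters (T_a, slope, top, bottom) are fitted;
    T_a must land inside the fitted temperature range.  Clearly
    non-sigmoidal data (R^2 below ``min_r_squared``) yield a flagged
    result rather than an exception.
    """
    required = {"temperature_c", "soluble_fraction"}
    if not required.issubset(melt.columns):
        raise ValidationError(f"melt curve needs columns {sorted(required)}")
    t = melt["temperature_c"].to_numpy(float)
    f = melt["soluble_fraction"].to_numpy(float)
    if len(np.unique(t)) < 5:
        raise ValidationError("need >= 5 temperatures spanning the transition")

    def model(x, ta, slope, top, bottom):
        return boltzmann(x, ta, slope, top, bottom)

    span = t.max() - t.min()
    p0 = (float(np.median(t)), max(span / 20.0, 0.5), float(f.max()),
          float(f.min()))
    bounds = ([t.min(), 1e-3, -np.inf, -np.inf],
              [t.max(), span, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(model, t, f, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise ValidationError(f"Boltzmann fit did not converge: {exc}") from exc
    ta, slope, top, bottom = popt
    if bottom > top:        # sign-degenerate solution: swap and flip slope
        top, bottom, slope = bottom, top, -slope
    resid = f - model(t, *popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    return BoltzmannFit(float(ta), se, float(slope), float(top), float(bottom),
                        r2, flagged=r2 < min_r_squared)


def decay_timecourse(signal: pd.DataFrame, t0: float | None = None) -> pd.DataFrame:
    """Percent of the t0 signal remaining at each time point.

    Input columns: time, signal.  ``t0`` defaults to the earliest time
    point; its signal must be positive (it becomes 100%).
    """
    if not {"time", "signal"}.issubset(signal.columns):
        raise ValidationError("time course needs columns time, signal")
    df = signal.sort_values("time", ignore_index=True)
    if t0 is None:
        t0 = float(df["time"].iloc[0])
    ref = df.loc[df["time"] == t0, "signal"]
    if ref.empty:
        raise ValidationError(f"no measurement at t0 = {t0}")
    ref_val = float(ref.mean())
    if ref_val <= 0:
        raise ValidationError("t0 signal must be positive")
    out = df.copy()
    out["percent_remaining"] = 100.0 * out["signal"] / ref_val
    return out


def normalize_expression(bands: pd.DataFrame, reference_sample: str,
                         normalizer_cols=("npt", "actb")) -> list[RelativeExpression]:
    """Total expression (B + C) over normalizers, reference sample = 100%.

    ``bands`` columns: sample, band_b, band_c, plus one column per
    normalizer.  Multiple normalizers are combined by geometric mean
    (pass a single name for single-normalizer mode).  The result is
    invariant to any global multiplicative factor applied to all raw
    intensities of a lane.
    """
    needed = {"sample", "band_b", "band_c", *normalizer_cols}
    if not needed.issubset(bands.columns):
        raise ValidationError(f"band table needs columns {sorted(needed)}")
    if reference_sample not in set(bands["sample"]):
        raise ValidationError(f"reference sample {reference_sample!r} absent")
    values = {}
    for row in bands.itertuples():
        norms = np.array([getattr(row, c) for c in normalizer_cols], float)
        if np.any(norms <= 0):
            raise ValidationError(f"sample {row.sample}: zero normalizer")
        gm = float(np.exp(np.mean(np.log(norms))))
        values[row.sample] = ((row.band_b + row.band_c) / gm,
                              row.band_b, row.band_c)
    ref = values[reference_sample][0]
    out = []
    for sample, (v, b, c) in values.items():
        out.append(RelativeExpression(sample, 100.0 * v / ref,
                                      tuple(normalizer_cols), b, c))
    return out


def ddct(ct_table: pd.DataFrame, target_gene: str, reference_gene: str,
         reference_sample: str) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    Duplicate wells are averaged; dCt = Ct(target) - Ct(reference gene)
    per sample; ddCt = dCt(sample) - dCt(reference sample); fold =
    2^(-ddCt); percent = 100 * fold.
    """
    needed = {"sample", "gene", "ct"}
    if not needed.issubset(ct_table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(needed)}")
    mean_ct = ct_table.groupby(["sample", "gene"])["ct"].mean().unstack()
    for g in (target_gene, reference_gene):
        if g not in mean_ct.columns:
            raise ValidationError(f"gene {g!r} absent from Ct table")
    if reference_sample not in mean_ct.index or \
            mean_ct.loc[reference_sample].isna().any():
        raise ValidationError(f"missing reference Ct for {reference_sample!r}")
    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    ddct_vals = dct - dct[reference_sample]
    fold = np.power(2.0, -ddct_vals)
    return pd.DataFrame({"sample": mean_ct.index, "delta_ct": dct.to_numpy(),
                         "delta_delta_ct": ddct_vals.to_numpy(),
                         "fold_change": fold.to_numpy(),
                         "percent_of_reference": 100.0 * fold.to_numpy()})


def efficiency_from_slope(slope: float) -> int:
    """qPCR efficiency (%) from the standard-curve slope magnitude.

    efficiency = (10^(1/slope) - 1) * 100, rounded to the nearest
    integer percent; a slope of 1/log10(2) ~ 3.32 cycles per decade is
    exactly 100% (doubling per cycle).
    """
    if slope <= 0:
        raise ValidationError("slope magnitude must be positive")
    return int(round((10.0 ** (1.0 / slope) - 1.0) * 100.0))


def microarray_relative_abundance(signals: pd.DataFrame,
                                  min_probes: int = 2) -> pd.DataFrame:
    """Per-tRNA Cy3/Atto647 ratios rescaled so spike-in standards equal 1.

    Input columns: trna, cy3, atto647, is_spike_in.  Each tRNA's ratio
    is median(Cy3)/median(Atto647) over its replicate probes; the mean
    spike-in ratio is then divided out, making the result invariant to
    any uniform gain difference between the channels.
    """
    needed = {"trna", "cy3", "atto647", "is_spike_in"}
    if not needed.issubset(signals.columns):
        raise ValidationError(f"signal table needs columns {sorted(needed)}")
    rows = []
    for trna, g in signals.groupby("trna"):
        if len(g) < min_probes:
            raise ValidationError(
                f"tRNA {trna!r}: {len(g)} probes (need >= {min_probes})")
        med_a = float(g["atto647"].median())
        if med_a <= 0:
            raise ValidationError(f"tRNA {trna!r}: nonpositive reference signal")
        rows.append((trna, float(g["cy3"].median()) / med_a,
                     bool(g["is_spike_in"].iloc[0]), len(g)))
    df = pd.DataFrame(rows, columns=["trna", "ratio", "is_spike_in", "n_probes"])
    spikes = df.loc[df["is_spike_in"], "ratio"]
    if spikes.empty or np.any(spikes <= 0):
        raise ValidationError("spike-in probes absent or with zero signal")
    df["ratio"] = df["ratio"] / float(spikes.mean())
    return df


def classification_proportion(counts: dict) -> dict:
    """Category percentages, truncated to whole percent.

    Truncation (not rounding) matches the convention that 12 of 27 is
    reported as 44% and 15 of 27 as 55%.
    """
    if any(v < 0 for v in counts.values()):
        raise ValidationError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("total count must be positive")
    return {k: int(100 * v // total) for k, v in counts.items()}
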