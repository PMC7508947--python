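"""EEG spectral analysis: Welch PSD, band-power summation, Pre-normalization.

The experiment records cortical EEG (1 kHz) around an optogenetic stimulation
epoch, with the recording annotated into Pre / Stim / Post periods.  For each
period a power spectral density is estimated with Welch's method, summed over
a set of named frequency bands, and each band sum is normalized by the same
band's sum in the Pre period so that periods can be compared within animal.

Band scheme (defaults): delta 0.5-4, theta 5-8, alpha 8-12, beta 15-30,
low gamma 38-43, high gamma 50-80 Hz.  Band edges are inclusive at both ends,
exactly as the scheme is printed; the 8 Hz bin is therefore counted in both
theta and alpha.  "Band power" here means the sum of PSD bins inside the band
(not the integral over Hz); the Pre-normalization cancels the convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import AnalysisError, ParameterError

PERIOD_LABELS = ("Pre", "Stim", "Post")

_EDGE_EPS = 1e-9  # absolute tolerance when matching FFT bin frequencies to band edges


@dataclass(frozen=True)
class BandScheme:
    """Ordered set of named frequency bands, each ``(name, lo_hz, hi_hz)``."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ParameterError(f"band {name!r}: lo ({lo}) must be < hi ({hi})")
            if lo < 0:
                raise ParameterError(f"band {name!r}: negative lower edge")

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def max_edge(self) -> float:
        return max(hi for _, _, hi in self.bands)


DEFAULT_BANDS = BandScheme(
    (
        ("delta", 0.5, 4.0),
        ("theta", 5.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 15.0, 30.0),
        ("low_gamma", 38.0, 43.0),
        ("high_gamma", 50.0, 80.0),
    )
)


@dataclass
class EEGRecording:
    """A single-channel EEG trace with ordered period annotations.

    Parameters
    ----------
    trace : array
        Voltage samples, arbitrary units.
    fs : float
        Sampling rate in Hz.
    periods : sequence of (label, start_s, end_s)
        Non-overlapping annotated intervals within the trace extent.
        Labels are typically "Pre", "Stim", "Post".
    """

    trace: np.ndarray
    fs: float
    periods: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 1:
            raise ParameterError("trace must be one-dimensional")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        self.periods = tuple((str(l), float(a), float(b)) for l, a, b in self.periods)
        total_s = len(self.trace) / self.fs
        prev_end = -np.inf
        for label, start, end in sorted(self.periods, key=lambda p: p[1]):
            if not 0 <= start < end <= total_s + _EDGE_EPS:
                raise ParameterError(
                    f"period {label!r} [{start}, {end}] s outside trace extent "
                    f"[0, {total_s:.3f}] s"
                )
            if start < prev_end - _EDGE_EPS:
                raise ParameterError(f"period {label!r} overlaps the previous period")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return len(self.trace) / self.fs

    def period_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.periods)

    def period_slice(self, label: str) -> np.ndarray:
        """Return the samples of the named period."""
        for plabel, start, end in self.periods:
            if plabel == label:
                i0 = int(round(start * self.fs))
                i1 = int(round(end * self.fs))
                return self.trace[i0:i1]
        raise AnalysisError(f"no period labeled {label!r} in recording")


@dataclass
class BandPowerResult:
    """Per (period, band) summed PSD and its Pre-normalized value.

    ``table`` is a long-format DataFrame with columns
    ``period, band, power, normalized``.
    """

    table: pd.DataFrame

    def value(self, period: str, band: str, column: str = "normalized") -> float:
        row = self.table[(self.table["period"] == period) & (self.table["band"] == band)]
        if row.empty:
            raise KeyError(f"no entry for period={period!r}, band={band!r}")
        return float(row[column].iloc[0])


def welch_psd(
    rec: EEGRecording,
    period_label: str,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window_name: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of one annotated period.

    Defaults: 2 s Hann segments with 50% overlap, constant detrend per
    segment (DC offset is an acquisition artifact).  2 s segments give
    0.5 Hz resolution, enough to resolve the 38-43 Hz band and the 0.5 Hz
    delta edge.

    Returns ``(frequencies_hz, psd)``; frequency resolution is
    ``1 / segment_s``.
    """
    if segment_s <= 0:
        raise ParameterError("segment_s must be positive")
    if not 0 <= overlap_frac < 1:
        raise ParameterError("overlap_frac must be in [0, 1)")
    x = rec.period_slice(period_label)
    nperseg = int(round(segment_s * rec.fs))
    if len(x) < nperseg:
        raise AnalysisError(
            f"period {period_label!r} ({len(x) / rec.fs:.3f} s) is shorter than "
            f"one Welch segment ({segment_s} s)"
        )
    freqs, psd = signal.welch(
        x,
        fs=rec.fs,
        window=window_name,
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    scheme: BandScheme = DEFAULT_BANDS,
) -> dict[str, float]:
    """Sum PSD bins within each band (edges inclusive at both ends)."""
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    nyquist = freqs[-1]
    out: dict[str, float] = {}
    for name, lo, hi in scheme:
        if hi > nyquist + _EDGE_EPS:
            raise AnalysisError(
                f"band {name!r} upper edge {hi} Hz exceeds the spectral extent "
                f"({nyquist} Hz)"
            )
        mask = (freqs >= lo - _EDGE_EPS) & (freqs <= hi + _EDGE_EPS)
        if not mask.any():
            warnings.warn(
                f"band {name!r} [{lo}, {hi}] Hz contains no frequency bins",
                stacklevel=2,
            )
            out[name] = 0.0
        else:
            out[name] = float(psd[mask].sum())
    return out


def band_power_table(
    rec: EEGRecording,
    scheme: BandScheme = DEFAULT_BANDS,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window_name: str = "hann",
) -> pd.DataFrame:
    """Band powers of every annotated period; long format (period, band, power)."""
    rows = []
    for label in rec.period_labels():
        freqs, psd = welch_psd(rec, label, segment_s, overlap_frac, window_name)
        for band, power in band_power(freqs, psd, scheme).items():
            rows.append({"period": label, "band": band, "power": power})
    return pd.DataFrame(rows)


def normalize_to_pre(table: pd.DataFrame, pre_label: str = "Pre") -> BandPowerResult:
    """Divide every band power by the same band's power in the Pre period.

    By construction every normalized Pre value is exactly 1.  Normalization is
    invariant to rescaling the whole trace by any positive constant.
    """
    if pre_label not in set(table["period"]):
        raise AnalysisError(f"no {pre_label!r} period in band-power table")
    pre = table[table["period"] == pre_label].set_index("band")["power"]
    zero = pre[pre <= 0]
    if len(zero):
        raise AnalysisError(
            "zero Pre-period power in band(s): " + ", ".join(map(repr, zero.index))
        )
    out = table.copy()
    out["normalized"] = out["power"].to_numpy() / pre.loc[out["band"]].to_numpy()
    return BandPowerResult(table=out)


def analyze_recording(
    rec: EEGRecording,
    scheme: BandScheme = DEFAULT_BANDS,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window_name: str = "hann",
) -> BandPowerResult:
    """Welch PSD -> band sums -> Pre-normalization, for one recording."""
    return normalize_to_pre(
        band_power_table(rec, scheme, segment_s, overlap_frac, window_name)
    )


def compare_periods(
    values: pd.DataFrame,
    band: str,
    value_col: str = "normalized",
    period_col: str = "period",
    alpha: float = 0.05,
):
    """One-way ANOVA + Tukey HSD across periods on per-animal normalized powers.

    ``values`` is long format with one row per (animal, period) for the chosen
    band (a ``band`` column, if present, is filtered on).  Delegates to
    :func:`optoplaque.stats.one_way_anova_hsd`.
    """
    from .stats import one_way_anova_hsd

    df = values
    if "band" in df.columns:
        df = df[df["band"] == band]
    if df.empty:
        raise AnalysisError(f"no observations for band {band!r}")
    return one_way_anova_hsd(
        df[value_col].to_numpy(), df[period_col].to_numpy(), alpha=alpha
    )
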