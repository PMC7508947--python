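"""Stimulus-locked single-unit modulation analysis.

Sorted units (spike times plus waveform and cluster-quality metrics) are
quality-gated on isolation distance, classified as narrow- or broad-spiking
by trough-to-peak duration, and tested per unit for firing-rate modulation
by optical pulses: for every pulse the spike count inside the pulse window
is paired with the count in an equally long pre-stimulus window, and the two
count samples are compared with a two-sided Wilcoxon rank-sum test.  Units
with p below alpha (default 0.005) are called activated or suppressed by the
sign of the mean count difference.  Population results are summarized as
counts and percentages per region and cell class.

The rank-sum p-value is exact (full permutation distribution, midranks, so
ties are handled exactly) when the combined number of pulse windows is <= 25,
and a tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError, ParameterError

DEFAULT_ALPHA = 0.005
DEFAULT_MIN_ISOLATION = 20.0
#: Trough-to-peak boundary between narrow- and broad-spiking cells, in ms,
#: as used by the source protocol.  Config-exposed everywhere it is consumed;
#: see docs/methods.md for a discussion of this value.
DEFAULT_TTP_THRESHOLD_MS = 3.5
EXACT_MAX_N = 25  # combined sample size up to which the exact distribution is used


@dataclass
class SortedUnit:
    """A spike-sorted single unit entering the pipeline.

    Spike sorting itself is upstream; units arrive with spike times (s),
    the trough-to-peak duration of the mean waveform (ms), and the isolation
    distance cluster-quality metric.
    """

    unit_id: str
    region: str
    spike_times_s: np.ndarray
    trough_to_peak_ms: float
    isolation_distance: float

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise ParameterError("spike_times_s must be one-dimensional")
        if len(self.spike_times_s) > 1 and not np.all(
            np.diff(self.spike_times_s) > 0
        ):
            raise ParameterError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if self.isolation_distance < 0:
            raise ParameterError("isolation_distance must be >= 0")


@dataclass
class StimProtocol:
    """Optical pulse train: onsets, pulse duration and the pre-stimulus window.

    The paired-window design requires that each pulse's pre-stimulus window
    not reach back into the previous pulse, i.e. inter-onset intervals must
    be at least ``pulse_duration_s + pre_window_s``.
    """

    pulse_onsets_s: np.ndarray
    pulse_duration_s: float
    pre_window_s: float = 0.050

    def __post_init__(self) -> None:
        self.pulse_onsets_s = np.asarray(self.pulse_onsets_s, dtype=float)
        if self.pulse_onsets_s.ndim != 1 or len(self.pulse_onsets_s) == 0:
            raise ParameterError("protocol must contain at least one pulse onset")
        if not np.all(np.diff(self.pulse_onsets_s) > 0):
            raise ParameterError("pulse onsets must be strictly increasing")
        if self.pulse_duration_s <= 0 or self.pre_window_s <= 0:
            raise ParameterError("pulse_duration_s and pre_window_s must be positive")
        min_ioi = self.pulse_duration_s + self.pre_window_s
        if len(self.pulse_onsets_s) > 1:
            ioi = np.diff(self.pulse_onsets_s)
            if ioi.min() < min_ioi - 1e-12:
                raise ParameterError(
                    f"minimum inter-onset interval {ioi.min():.4f} s is shorter than "
                    f"pulse_duration_s + pre_window_s = {min_ioi:.4f} s"
                )

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_s)


@dataclass
class UnitModulation:
    """Per-unit test outcome."""

    unit_id: str
    region: str
    cell_class: str  # "narrow" | "broad"
    p_value: float
    direction: str  # "activated" | "suppressed" | "none"


def quality_filter(
    units: list[SortedUnit], min_isolation_distance: float = DEFAULT_MIN_ISOLATION
) -> list[SortedUnit]:
    """Keep units with isolation distance >= threshold (boundary inclusive)."""
    return [u for u in units if u.isolation_distance >= min_isolation_distance]


def classify_waveform(
    trough_to_peak_ms: float, threshold_ms: float = DEFAULT_TTP_THRESHOLD_MS
) -> str:
    """Classify a waveform as ``"narrow"`` (< threshold) or ``"broad"`` (>= threshold).

    A duration exactly at the threshold is broad, by convention.
    """
    if trough_to_peak_ms <= 0:
        raise ParameterError(
            f"trough-to-peak duration must be positive, got {trough_to_peak_ms}"
        )
    if threshold_ms <= 0:
        raise ParameterError("threshold_ms must be positive")
    return "narrow" if trough_to_peak_ms < threshold_ms else "broad"


def pulse_window_counts(
    unit: SortedUnit, protocol: StimProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse spike counts in the stimulation and pre-stimulus windows.

    Windows are half-open: stim = [onset, onset + pulse_duration),
    pre = [onset - pre_window, onset).  Returns ``(stim_counts, pre_counts)``,
    one entry per pulse.
    """
    t = unit.spike_times_s
    on = protocol.pulse_onsets_s
    stim = np.searchsorted(t, on + protocol.pulse_duration_s, side="left") - (
        np.searchsorted(t, on, side="left")
    )
    pre = np.searchsorted(t, on, side="left") - np.searchsorted(
        t, on - protocol.pre_window_s, side="left"
    )
    return stim.astype(int), pre.astype(int)


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p over the full permutation distribution.

    Uses midranks, so tied observations are handled exactly; p is the
    probability (over all C(n1+n2, n1) assignments) of a rank sum at least as
    far from its mean as the observed one.  A shift-algorithm dynamic program
    over doubled midranks (integers) keeps the computation polynomial.
    """
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks2 = np.rint(sps.rankdata(np.concatenate([x, y])) * 2).astype(int)
    s_obs = int(ranks2[:n1].sum())
    max_s = int(ranks2.sum())
    # dp[j, s] = number of j-subsets of the ranks seen so far with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_s + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in ranks2:
        for j in range(n1, 0, -1):
            dp[j, r:] += dp[j - 1, : max_s + 1 - r]
    dist = dp[n1]
    mu2 = n1 * (n + 1)  # mean doubled-rank sum under the null
    dev = abs(s_obs - mu2)
    sums = np.arange(max_s + 1)
    tail = int(dist[np.abs(sums - mu2) >= dev].sum())
    total = math.comb(n, n1)
    return tail / total


def modulation_test(
    unit: SortedUnit,
    protocol: StimProtocol,
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = EXACT_MAX_N,
) -> tuple[float, str]:
    """Two-sided rank-sum test of per-pulse stim vs pre-stimulus spike counts.

    Returns ``(p_value, direction)`` with direction "activated", "suppressed"
    or "none".  A direction other than "none" is only assigned when
    ``p_value < alpha``.  If no spikes fall in any window on either side the
    unit is trivially unmodulated (p = 1).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    stim, pre = pulse_window_counts(unit, protocol)
    if stim.max(initial=0) == 0 and pre.max(initial=0) == 0:
        return 1.0, "none"
    if np.all(stim == stim[0]) and np.all(pre == stim[0]):
        # identical constant counts: no information, exact p would be 1 anyway
        return 1.0, "none"
    if len(stim) + len(pre) <= exact_max_n:
        p = _exact_ranksum_p(stim.astype(float), pre.astype(float))
    else:
        p = float(
            sps.mannwhitneyu(
                stim, pre, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    if p < alpha:
        diff = float(stim.mean() - pre.mean())
        if diff > 0:
            return p, "activated"
        if diff < 0:
            return p, "suppressed"
    return p, "none"


def truncate_pct(numerator: int, denominator: int) -> str:
    """Percentage truncated (not rounded) to one decimal, as a string."""
    if denominator <= 0:
        raise ParameterError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    return f"{math.floor(pct * 10) / 10:.1f}"


def round_pct(numerator: int, denominator: int) -> str:
    """Percentage rounded half-away-from-zero to one decimal, as a string."""
    if denominator <= 0:
        raise ParameterError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    return f"{math.floor(pct * 10 + 0.5) / 10:.1f}"


def summarize_population(results: list[UnitModulation]) -> pd.DataFrame:
    """Population summary per (region, cell class) plus per-region totals.

    For every group the summary gives total unit count, counts and raw
    fractions of activated/suppressed/unmodulated units, and one-decimal
    percentage strings in both conventions: truncated (``pct_*_trunc``,
    matching how the source protocol prints proportions) and
    round-half-away-from-zero (``pct_*_round``).
    """
    if not results:
        raise AnalysisError("no unit results to summarize")
    df = pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in results],
            "region": [r.region for r in results],
            "cell_class": [r.cell_class for r in results],
            "direction": [r.direction for r in results],
        }
    )
    rows = []
    groups = [(region, "all") for region in sorted(df["region"].unique())]
    groups += sorted(
        {(r, c) for r, c in zip(df["region"], df["cell_class"])}, key=str
    )
    for region, cls in groups:
        sub = df[df["region"] == region]
        if cls != "all":
            sub = sub[sub["cell_class"] == cls]
        n = len(sub)
        n_act = int((sub["direction"] == "activated").sum())
        n_sup = int((sub["direction"] == "suppressed").sum())
        row = {
            "region": region,
            "cell_class": cls,
            "n_total": n,
            "n_activated": n_act,
            "n_suppressed": n_sup,
            "n_unmodulated": n - n_act - n_sup,
            "frac_activated": n_act / n,
            "frac_suppressed": n_sup / n,
            "frac_unmodulated": (n - n_act - n_sup) / n,
        }
        for key, count in (("activated", n_act), ("suppressed", n_sup)):
            row[f"pct_{key}_trunc"] = truncate_pct(count, n)
            row[f"pct_{key}_round"] = round_pct(count, n)
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_units(
    units: list[SortedUnit],
    protocol: StimProtocol,
    alpha: float = DEFAULT_ALPHA,
    min_isolation_distance: float = DEFAULT_MIN_ISOLATION,
    ttp_threshold_ms: float = DEFAULT_TTP_THRESHOLD_MS,
) -> tuple[list[UnitModulation], pd.DataFrame]:
    """Full chain: quality gate -> classify -> per-unit test -> summary."""
    kept = quality_filter(units, min_isolation_distance)
    if not kept:
        raise AnalysisError("no units pass the isolation-distance gate")
    results = []
    for u in kept:
        p, direction = modulation_test(u, protocol, alpha=alpha)
        results.append(
            UnitModulation(
                unit_id=u.unit_id,
                region=u.region,
                cell_class=classify_waveform(u.trough_to_peak_ms, ttp_threshold_ms),
                p_value=p,
                direction=direction,
            )
        )
    return results, summarize_population(results)
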