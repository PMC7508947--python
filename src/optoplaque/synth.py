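"""Synthetic-data generators for every pipeline input.

Generates, with the statistical structure the downstream analyses assume:

* EEG — 1/f ("pink") background noise per period, with an optional narrowband
  component near 40 Hz added during the Stim period and optional attenuation
  of delta-band (0.5-4 Hz) power during Stim, emulating optogenetic gamma
  entrainment and the arousal-related delta reduction.
* Spike trains — homogeneous Poisson units whose rate is multiplied by a
  per-unit factor inside 50 ms light pulses (50 ms on / 450 ms off probe
  regime by default), with waveform and isolation metadata attached.
* Micrographs — dim noisy background plus bright compact blobs (isotropic
  Gaussian profile truncated at 3 sigma, optionally blurred by a Gaussian
  PSF) with ground-truth centers and areas, emulating thiazine-red-stained
  plaques.
* Group tables — long-format per-animal / per-region / per-section plaque
  densities with multiplicative lognormal noise and per-region treated/control
  effect multipliers.

Every generator is a pure function of its params (including the seed):
the same params produce bit-identical output.  Background and injected EEG
components use independent child streams of the seed, so the background is
unchanged when only the injected-component amplitude changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .exceptions import ParameterError, PlacementError
from .plaques import GENOTYPE_CONTROL, GENOTYPE_TREATED, MicrographROI
from .spikes import SortedUnit, StimProtocol

#: Brain regions analyzed histologically (the eight of the main two-way
#: comparison plus the two hippocampal subfields examined separately).
DEFAULT_REGIONS = ("ACA", "mPFC", "S1", "ENT", "DG", "SUB", "SEP", "TH", "CA1", "CA3")

#: Low-gamma analysis band; the injected-component amplitude is specified
#: relative to the background RMS inside this band (see SynthEEGParams).
GAMMA_REFERENCE_BAND = (38.0, 43.0)

#: Frequency resolution of the default analysis (2 s Welch segments).  The
#: analysis sums closed-interval PSD bins, so its band sum integrates an
#: effective extra half bin of a continuous spectrum at each edge; the
#: generator's reference variance uses the same effective support so that
#: injected power matches background band power as the analysis measures it.
ANALYSIS_BIN_HZ = 0.5


# --------------------------------------------------------------------------- EEG


@dataclass(frozen=True)
class SynthEEGParams:
    """Parameters of the synthetic EEG generator.

    ``gamma_amplitude_rel`` is the ratio of the injected narrowband RMS to the
    background RMS *within the low-gamma analysis band* (38-43 Hz) of the Stim
    period.  With this convention the injected power equals
    ``gamma_amplitude_rel**2`` times the background low-gamma power, so the
    Pre-normalized Stim low-gamma power is ~ ``1 + gamma_amplitude_rel**2``
    (exactly 2 for ``gamma_amplitude_rel=1``); 0 emulates a control animal.

    ``delta_attenuation_stim`` multiplies delta-band (0.5-4 Hz) *power* of the
    Stim-period background (<= 1; 1 = no change), emulating the arousal-related
    delta reduction.

    ``highpass_hz`` zeroes background content below the cutoff (default
    0.5 Hz), emulating the acquisition high-pass.  Without it the 1/f
    background's total variance is dominated by near-DC components outside
    every analysis band, which would make per-period RMS normalization (and
    hence Pre-normalized band powers) needlessly noisy.

    Durations default to 300 s per period: long enough for ~2% band-power
    sampling error with 2 s Welch segments while keeping simulations fast.
    """

    duration_pre_s: float = 300.0
    duration_stim_s: float = 300.0
    duration_post_s: float = 300.0
    fs: float = 1000.0
    background_exponent: float = 1.0
    gamma_center_hz: float = 40.0
    gamma_bandwidth_hz: float = 1.0
    gamma_amplitude_rel: float = 0.0
    delta_attenuation_stim: float = 1.0
    highpass_hz: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.duration_pre_s, self.duration_stim_s, self.duration_post_s) <= 0:
            raise ParameterError("all period durations must be positive")
        if self.fs <= 2 * 80.0:
            raise ParameterError(
                f"fs = {self.fs} Hz cannot resolve the high-gamma band (need > 160 Hz)"
            )
        if self.gamma_amplitude_rel < 0:
            raise ParameterError("gamma_amplitude_rel must be >= 0")
        if not 0 < self.delta_attenuation_stim <= 1:
            raise ParameterError("delta_attenuation_stim must be in (0, 1]")
        if self.gamma_bandwidth_hz <= 0 or self.gamma_center_hz <= 0:
            raise ParameterError("gamma center/bandwidth must be positive")
        if self.highpass_hz < 0:
            raise ParameterError("highpass_hz must be >= 0")


def _shaped_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    exponent: float,
    band_scale: tuple[tuple[float, float], float] | None = None,
    highpass_hz: float = 0.0,
) -> np.ndarray:
    """Unit-RMS noise with amplitude spectrum ~ 1/f^(exponent/2).

    ``band_scale = ((lo, hi), power_factor)`` multiplies the power inside
    [lo, hi] Hz by ``power_factor`` before synthesis; content below
    ``highpass_hz`` is removed.  Realized (not just expected) RMS is
    normalized to 1.
    """
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[freqs < highpass_hz] = 0.0
    if band_scale is not None:
        (lo, hi), factor = band_scale
        sel = (freqs >= lo) & (freqs <= hi)
        amp[sel] *= np.sqrt(factor)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS noise with a flat spectrum confined to [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ParameterError(f"band [{lo}, {hi}] Hz contains no resolvable frequency")
    spec = np.zeros(len(freqs), dtype=complex)
    spec[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_variance(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Variance of the [lo, hi] Hz content of ``x`` (rFFT bin sum, Parseval)."""
    n = len(x)
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    power = np.abs(spec) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    sel = (freqs >= lo) & (freqs <= hi)
    return float(power[sel].sum())


def generate_eeg(params: SynthEEGParams) -> EEGRecording:
    """Generate a Pre/Stim/Post-annotated synthetic EEG trace.

    The three periods have independent 1/f backgrounds of unit RMS.  During
    Stim a band-limited component (``gamma_bandwidth_hz`` wide, centered at
    ``gamma_center_hz``) is added with RMS equal to ``gamma_amplitude_rel``
    times the realized background RMS in the 38-43 Hz reference band, and the
    background's delta power is scaled by ``delta_attenuation_stim``.
    Deterministic given the seed; the background is identical across different
    ``gamma_amplitude_rel`` values at the same seed.
    """
    p = params
    ss = np.random.SeedSequence(p.seed)
    rng_pre, rng_stim, rng_post, rng_gamma = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n_pre = int(round(p.duration_pre_s * p.fs))
    n_stim = int(round(p.duration_stim_s * p.fs))
    n_post = int(round(p.duration_post_s * p.fs))

    pre = _shaped_noise(
        n_pre, p.fs, rng_pre, p.background_exponent, highpass_hz=p.highpass_hz
    )
    stim_bg = _shaped_noise(
        n_stim,
        p.fs,
        rng_stim,
        p.background_exponent,
        band_scale=((0.5, 4.0), p.delta_attenuation_stim)
        if p.delta_attenuation_stim != 1.0
        else None,
        highpass_hz=p.highpass_hz,
    )
    post = _shaped_noise(
        n_post, p.fs, rng_post, p.background_exponent, highpass_hz=p.highpass_hz
    )

    stim = stim_bg
    if p.gamma_amplitude_rel > 0:
        lo = p.gamma_center_hz - p.gamma_bandwidth_hz / 2.0
        hi = p.gamma_center_hz + p.gamma_bandwidth_hz / 2.0
        ref_lo = GAMMA_REFERENCE_BAND[0] - ANALYSIS_BIN_HZ / 2.0
        ref_hi = GAMMA_REFERENCE_BAND[1] + ANALYSIS_BIN_HZ / 2.0
        ref_var = _band_variance(stim_bg, p.fs, ref_lo, ref_hi)
        injected = _bandlimited_noise(n_stim, p.fs, lo, hi, rng_gamma)
        stim = stim_bg + p.gamma_amplitude_rel * np.sqrt(ref_var) * injected

    trace = np.concatenate([pre, stim, post])
    t1 = n_pre / p.fs
    t2 = (n_pre + n_stim) / p.fs
    t3 = (n_pre + n_stim + n_post) / p.fs
    return EEGRecording(
        trace=trace,
        fs=p.fs,
        periods=(("Pre", 0.0, t1), ("Stim", t1, t2), ("Post", t2, t3)),
    )


# ------------------------------------------------------------------------ spikes


def _broadcast(value, n: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if len(arr) != n:
        raise ParameterError(f"{name} must be scalar or length n_units ({n})")
    return arr


@dataclass(frozen=True)
class SynthSpikeParams:
    """Parameters of the Poisson spike-train generator.

    Per-unit fields (``baseline_rate_hz``, ``rate_ratio``,
    ``trough_to_peak_ms``, ``isolation_distance``, ``region``) accept a scalar
    (broadcast to all units) or a length-``n_units`` sequence.  ``rate_ratio``
    is the stim/baseline firing-rate multiplier inside light pulses (> 1
    activated, < 1 suppressed, 1 unmodulated).  The default pulse regime is
    the 50 ms on / 450 ms off probe protocol.
    """

    n_units: int = 1
    baseline_rate_hz: object = 10.0
    rate_ratio: object = 1.0
    trough_to_peak_ms: object = 0.5
    isolation_distance: object = 30.0
    region: object = "BF"
    n_pulses: int = 500
    pulse_on_ms: float = 50.0
    pulse_off_ms: float = 450.0
    pad_s: float = 1.0  # silence-free padding before the first and after the last pulse
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ParameterError("n_units must be >= 1")
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if self.pulse_on_ms <= 0 or self.pulse_off_ms <= 0:
            raise ParameterError("pulse_on_ms and pulse_off_ms must be positive")
        if np.any(self.rates < 0):
            raise ParameterError("baseline rates must be >= 0")
        if np.any(self.ratios <= 0):
            raise ParameterError("rate ratios must be > 0")

    @property
    def rates(self) -> np.ndarray:
        return _broadcast(self.baseline_rate_hz, self.n_units, "baseline_rate_hz")

    @property
    def ratios(self) -> np.ndarray:
        return _broadcast(self.rate_ratio, self.n_units, "rate_ratio")

    def modulation_classes(self) -> list[str]:
        """Ground-truth class per unit, derived from the rate ratio."""
        out = []
        for r in self.ratios:
            out.append("activated" if r > 1 else "suppressed" if r < 1 else "unmodulated")
        return out


def _poisson_interval_spikes(
    rng: np.random.Generator, starts: np.ndarray, lengths: np.ndarray, rate: float
) -> np.ndarray:
    """Homogeneous Poisson spikes over a set of disjoint intervals (vectorized)."""
    if rate <= 0:
        return np.empty(0)
    counts = rng.poisson(rate * lengths)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    offsets = rng.random(total)
    return np.repeat(starts, counts) + offsets * np.repeat(lengths, counts)


def generate_spike_data(
    params: SynthSpikeParams,
) -> tuple[list[SortedUnit], StimProtocol]:
    """Generate Poisson units with multiplicative rate modulation inside pulses.

    Each unit fires at its baseline rate outside pulses and at
    ``baseline * rate_ratio`` inside pulses.  Spikes exactly at interval
    boundaries are resolved by the half-open interval construction.
    Deterministic given the seed.
    """
    p = params
    on_s = p.pulse_on_ms / 1000.0
    off_s = p.pulse_off_ms / 1000.0
    period = on_s + off_s
    onsets = p.pad_s + np.arange(p.n_pulses) * period
    total_s = p.pad_s + p.n_pulses * period + p.pad_s

    gap_starts = np.concatenate([[0.0], onsets + on_s])
    gap_ends = np.concatenate([onsets, [total_s]])
    gap_lengths = gap_ends - gap_starts

    rates = p.rates
    ratios = p.ratios
    ttp = _broadcast(p.trough_to_peak_ms, p.n_units, "trough_to_peak_ms")
    iso = _broadcast(p.isolation_distance, p.n_units, "isolation_distance")
    regions = (
        [str(p.region)] * p.n_units
        if isinstance(p.region, str)
        else [str(r) for r in p.region]
    )
    if len(regions) != p.n_units:
        raise ParameterError("region must be scalar or length n_units")

    rng = np.random.default_rng(p.seed)
    units = []
    for i in range(p.n_units):
        base = _poisson_interval_spikes(rng, gap_starts, gap_lengths, rates[i])
        pulsed = _poisson_interval_spikes(
            rng, onsets, np.full(p.n_pulses, on_s), rates[i] * ratios[i]
        )
        times = np.sort(np.concatenate([base, pulsed]))
        # strictly increasing: collisions are measure-zero but guard anyway
        if len(times) > 1:
            dup = np.diff(times) <= 0
            while dup.any():
                times = np.delete(times, np.nonzero(dup)[0] + 1)
                dup = np.diff(times) <= 0
        units.append(
            SortedUnit(
                unit_id=f"u{i:04d}",
                region=regions[i],
                spike_times_s=times,
                trough_to_peak_ms=float(ttp[i]),
                isolation_distance=float(iso[i]),
            )
        )
    protocol = StimProtocol(
        pulse_onsets_s=onsets, pulse_duration_s=on_s, pre_window_s=min(0.050, off_s)
    )
    return units, protocol


# ------------------------------------------------------------------------ images


@dataclass(frozen=True)
class SynthImageParams:
    """Parameters of the synthetic micrograph generator.

    Blobs have an isotropic Gaussian intensity profile truncated at 3 sigma
    with sigma = radius / 3, so the blob support is a disk of the stated
    radius and ground-truth areas are pixel counts of that disk.  Peak
    intensities are drawn uniformly from ``plaque_peak_intensity`` (above
    background); defaults give a peak-to-noise ratio of at least 10 over the
    Gaussian background (mean 1000, SD 200).
    """

    height_px: int = 512
    width_px: int = 512
    n_plaques: int = 25
    plaque_radius_px: tuple[float, float] = (5.0, 9.0)
    plaque_peak_intensity: tuple[float, float] = (3000.0, 6000.0)
    background_mean: float = 1000.0
    background_sd: float = 200.0
    psf_sigma_px: float = 1.0
    min_center_separation_px: float = 40.0
    noise: str = "gaussian"  # "gaussian" | "poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_plaques < 0:
            raise ParameterError("n_plaques must be >= 0")
        lo_r, hi_r = self.plaque_radius_px
        if not 0 < lo_r <= hi_r:
            raise ParameterError("plaque_radius_px must satisfy 0 < lo <= hi")
        if hi_r > min(self.height_px, self.width_px) / 2:
            raise ParameterError("plaque radius exceeds image half-extent")
        lo_i, hi_i = self.plaque_peak_intensity
        if not self.background_mean < lo_i <= hi_i:
            raise ParameterError("peak intensities must exceed background_mean")
        if self.background_sd < 0 or self.background_mean < 0:
            raise ParameterError("background mean/sd must be >= 0")
        if self.noise not in ("gaussian", "poisson"):
            raise ParameterError("noise must be 'gaussian' or 'poisson'")


def _place_centers(
    rng: np.random.Generator, p: SynthImageParams, margin: float
) -> np.ndarray:
    """Rejection-sample blob centers with a minimum pairwise separation."""
    centers: list[tuple[float, float]] = []
    max_tries = 10_000 * max(p.n_plaques, 1)
    tries = 0
    while len(centers) < p.n_plaques:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {p.n_plaques} blobs with separation "
                f">= {p.min_center_separation_px} px in a "
                f"{p.height_px}x{p.width_px} image"
            )
        r = margin + rng.random() * (p.height_px - 2 * margin)
        c = margin + rng.random() * (p.width_px - 2 * margin)
        if all(
            (r - r0) ** 2 + (c - c0) ** 2 >= p.min_center_separation_px**2
            for r0, c0 in centers
        ):
            centers.append((r, c))
    return np.array(centers).reshape(-1, 2)


def generate_micrograph(
    params: SynthImageParams,
) -> tuple[MicrographROI, pd.DataFrame]:
    """Generate one synthetic micrograph plus ground truth.

    Returns ``(roi, ground_truth)`` where ground truth has one row per blob
    with columns ``x_px, y_px`` (center, x = column) and ``area_px`` (pixel
    count of the truncated blob support, before blur and noise).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    margin = p.plaque_radius_px[1]
    centers = _place_centers(rng, p, margin)

    clean = np.zeros((p.height_px, p.width_px), dtype=float)
    rows = []
    yy, xx = np.mgrid[0 : p.height_px, 0 : p.width_px]
    for r0, c0 in centers:
        radius = p.plaque_radius_px[0] + rng.random() * (
            p.plaque_radius_px[1] - p.plaque_radius_px[0]
        )
        peak = p.plaque_peak_intensity[0] + rng.random() * (
            p.plaque_peak_intensity[1] - p.plaque_peak_intensity[0]
        )
        sigma = radius / 3.0
        d2 = (yy - r0) ** 2 + (xx - c0) ** 2
        support = d2 <= radius**2
        clean[support] += peak * np.exp(-d2[support] / (2.0 * sigma**2))
        rows.append(
            {
                "x_px": c0,
                "y_px": r0,
                "area_px": int(support.sum()),
                "radius_px": radius,
            }
        )
    ground_truth = pd.DataFrame(rows, columns=["x_px", "y_px", "area_px", "radius_px"])

    image = clean
    if p.psf_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        image = gaussian_filter(image, p.psf_sigma_px)
    if p.noise == "gaussian":
        image = image + p.background_mean + rng.normal(0.0, p.background_sd, image.shape)
        image = np.clip(image, 0.0, None)
    else:
        image = rng.poisson(np.clip(image + p.background_mean, 0.0, None)).astype(float)
    roi = MicrographROI(image=image)
    return roi, ground_truth


def blob_support_mask(params: SynthImageParams, ground_truth: pd.DataFrame) -> np.ndarray:
    """Union of the ground-truth blob supports (noise- and blur-free mask)."""
    yy, xx = np.mgrid[0 : params.height_px, 0 : params.width_px]
    mask = np.zeros((params.height_px, params.width_px), dtype=bool)
    for _, row in ground_truth.iterrows():
        d2 = (yy - row["y_px"]) ** 2 + (xx - row["x_px"]) ** 2
        mask |= d2 <= row["radius_px"] ** 2
    return mask


# ------------------------------------------------------------------- group table


@dataclass(frozen=True)
class SynthGroupParams:
    """Parameters of the per-animal / per-region / per-section density tables.

    ``effect_multiplier`` maps region -> treated/control mean ratio (scalar =
    all regions); ``control_density_mean`` likewise sets per-region control
    means.  ``animal_cv`` is the coefficient of variation of a multiplicative
    lognormal factor drawn once per animal (shared across that animal's
    regions and sections); ``section_cv`` applies independently to every
    observation.  With ``animal_cv=0`` observations are iid within cells,
    the regime in which per-section ANOVA is exactly calibrated.
    """

    n_animals_per_group: int = 3
    regions: tuple[str, ...] = DEFAULT_REGIONS
    control_density_mean: object = 1.0
    effect_multiplier: object = 1.0
    animal_cv: float = 0.0
    section_cv: float = 0.15
    sections_per_region: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 2:
            raise ParameterError("n_animals_per_group must be >= 2")
        if self.sections_per_region < 1:
            raise ParameterError("sections_per_region must be >= 1")
        if self.animal_cv < 0 or self.section_cv < 0:
            raise ParameterError("CVs must be >= 0")
        for region in self.regions:
            if self._lookup(self.effect_multiplier, region) <= 0:
                raise ParameterError(f"effect multiplier for {region!r} must be > 0")
            if self._lookup(self.control_density_mean, region) <= 0:
                raise ParameterError(f"control mean for {region!r} must be > 0")

    @staticmethod
    def _lookup(value, region: str) -> float:
        if isinstance(value, dict):
            return float(value.get(region, 1.0))
        return float(value)

    def multiplier(self, region: str) -> float:
        return self._lookup(self.effect_multiplier, region)

    def control_mean(self, region: str) -> float:
        return self._lookup(self.control_density_mean, region)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_group_table(params: SynthGroupParams) -> pd.DataFrame:
    """Long-format table (animal_id, genotype, region, section, density).

    Expected treated/control mean ratio per region equals the effect
    multiplier; all noise is multiplicative mean-1 lognormal.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    for genotype in (GENOTYPE_CONTROL, GENOTYPE_TREATED):
        for a in range(p.n_animals_per_group):
            animal_id = f"{'C' if genotype == GENOTYPE_CONTROL else 'T'}{a + 1}"
            animal_factor = float(_lognormal_factor(rng, p.animal_cv, 1)[0])
            for region in p.regions:
                mean = p.control_mean(region)
                if genotype == GENOTYPE_TREATED:
                    mean *= p.multiplier(region)
                section_factors = _lognormal_factor(
                    rng, p.section_cv, p.sections_per_region
                )
                for s in range(p.sections_per_region):
                    rows.append(
                        {
                            "animal_id": animal_id,
                            "genotype": genotype,
                            "region": region,
                            "section": s + 1,
                            "density": mean * animal_factor * section_factors[s],
                        }
                    )
    return pd.DataFrame(rows)
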