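"""Physics-based synthetic device model.

Simulates per-LED emission spectra (reflected excitation line plus
fluorescence plus detector noise), the auto-integration loop that drives
the detector to a target fraction of saturation, and full raw scans in
the device's 18,192-row tabular dialect.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

EMISSION_MIN_NM = 185.0
EMISSION_MAX_NM = 655.0
N_EMISSION_PIXELS = 1516
N_LEDS = 12
LED_MIN_NM = 255.0
LED_MAX_NM = 400.0
ROWS_PER_SCAN = N_LEDS * N_EMISSION_PIXELS  # 18192

_GAUSS_K = 4.0 * np.log(2.0)  # exp(-K ((x-c)/fwhm)^2) has the stated FWHM

# fine reference grid used to normalize emission profiles to unit area
_REF_GRID = np.linspace(EMISSION_MIN_NM, EMISSION_MAX_NM, 4701)


def default_emission_axis() -> np.ndarray:
    """Uniform 1516-point emission wavelength grid on [185, 655] nm."""
    return np.linspace(EMISSION_MIN_NM, EMISSION_MAX_NM, N_EMISSION_PIXELS)


def default_led_wavelengths() -> tuple[float, ...]:
    """12 LED center wavelengths evenly spaced on [255, 400] nm."""
    return tuple(np.linspace(LED_MIN_NM, LED_MAX_NM, N_LEDS))


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-_GAUSS_K * ((x - center) / fwhm) ** 2)


@dataclass(frozen=True)
class DeviceConfig:
    """Optical and detector parameters of the simulated device.

    ``led_power`` is the reflected-peak count rate (counts per unit
    exposure) of a blank at brightness 1. ``reflectance_path_factor``
    (k_r) and ``secondary_filter_factor`` (k_s) are the effective
    Beer-Lambert exponents for the double-pass reflectance attenuation
    and the secondary inner-filter re-absorption of emitted light.
    """

    led_wavelengths: tuple[float, ...] = field(default_factory=default_led_wavelengths)
    led_bandwidth_fwhm: float = 12.0
    led_power: float = 800.0
    emission_points: int = N_EMISSION_PIXELS
    emission_span: tuple[float, float] = (EMISSION_MIN_NM, EMISSION_MAX_NM)
    saturation_level: float = 65535.0
    target_saturation_fraction: float = 0.8
    reflectance_path_factor: float = 2.0
    secondary_filter_factor: float = 0.5
    noise_floor: float = 2.0
    shot_noise_scale: float = 0.25
    start_integration: float = 1.0
    max_integration: float = 1.0e5
    integration_iterations_cap: int = 8

    def __post_init__(self) -> None:
        leds = tuple(float(w) for w in self.led_wavelengths)
        object.__setattr__(self, "led_wavelengths", leds)
        if len(leds) != N_LEDS:
            raise ValueError(f"exactly {N_LEDS} LED wavelengths required, got {len(leds)}")
        if any(b <= a for a, b in zip(leds, leds[1:])):
            raise ValueError("LED wavelengths must be strictly increasing")
        if min(leds) < LED_MIN_NM or max(leds) > LED_MAX_NM:
            raise ValueError(f"LED wavelengths must lie in [{LED_MIN_NM}, {LED_MAX_NM}] nm")
        if self.emission_points != N_EMISSION_PIXELS:
            raise ValueError(
                f"emission axis must have exactly {N_EMISSION_PIXELS} points "
                f"(so {N_LEDS} x {N_EMISSION_PIXELS} = {ROWS_PER_SCAN} rows per scan)"
            )
        if not 0.0 < self.target_saturation_fraction < 1.0:
            raise ValueError("target_saturation_fraction must be in (0, 1)")
        if self.saturation_level <= 0 or self.max_integration <= 0:
            raise ValueError("saturation_level and max_integration must be positive")
        if self.integration_iterations_cap < 1:
            raise ValueError("integration_iterations_cap must be >= 1")

    @property
    def emission_axis(self) -> np.ndarray:
        lo, hi = self.emission_span
        return np.linspace(lo, hi, self.emission_points)


@dataclass(frozen=True)
class FluorophoreSpec:
    """Parametric optics of one compound.

    Absorption and emission are sums of Gaussian bands given as
    ``(center_nm, fwhm_nm, amplitude)`` triples. The absorption
    amplitude is the decadic extinction coefficient at the band center
    in mL mg^-1 cm^-1; the emission profile is normalized to unit area
    over [185, 655] nm, so ``emission_profile`` returns a density per nm.
    """

    name: str
    absorption_bands: tuple[tuple[float, float, float], ...]
    emission_bands: tuple[tuple[float, float, float], ...]
    quantum_yield: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "absorption_bands", tuple(tuple(map(float, b)) for b in self.absorption_bands)
        )
        object.__setattr__(
            self, "emission_bands", tuple(tuple(map(float, b)) for b in self.emission_bands)
        )
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError(f"{self.name}: quantum_yield must be in (0, 1]")
        if not self.emission_bands:
            raise ValueError(f"{self.name}: at least one emission band required")
        for c, w, a in self.absorption_bands + self.emission_bands:
            if w <= 0 or a < 0:
                raise ValueError(f"{self.name}: band widths must be > 0, amplitudes >= 0")
        if self.absorption_bands:
            abs_max = max(self.absorption_bands, key=lambda b: b[2])[0]
            em_com = float(
                np.trapezoid(self._raw_emission(_REF_GRID) * _REF_GRID, _REF_GRID)
                / np.trapezoid(self._raw_emission(_REF_GRID), _REF_GRID)
            )
            if em_com <= abs_max:
                raise ValueError(f"{self.name}: emission mass must lie redward of absorption max")

    def _raw_emission(self, wavelengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wavelengths, dtype=float)
        for c, w, a in self.emission_bands:
            out += a * _gaussian(wavelengths, c, w)
        return out

    def absorption(self, wavelengths) -> np.ndarray:
        """Extinction coefficient epsilon(lambda), mL mg^-1 cm^-1."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for c, w, a in self.absorption_bands:
            out += a * _gaussian(wl, c, w)
        return out

    def emission_profile(self, wavelengths) -> np.ndarray:
        """Unit-area emission density f(lambda) on [185, 655] nm."""
        wl = np.asarray(wavelengths, dtype=float)
        return self._raw_emission(wl) / _emission_norm(self)


@functools.lru_cache(maxsize=512)
def _emission_norm(spec: FluorophoreSpec) -> float:
    area = float(np.trapezoid(spec._raw_emission(_REF_GRID), _REF_GRID))
    if area <= 0:
        raise ValueError(f"{spec.name}: emission profile has zero area")
    return area


@dataclass(frozen=True)
class SampleSpec:
    """A sample as concentration-weighted fluorophore components.

    An empty component list is the blank solvent. ``solvent_baseline``
    is the relative diffuse reflectance of the blank; ``path_length``
    is the effective optical path in cm.
    """

    components: tuple[tuple[FluorophoreSpec, float], ...] = ()
    solvent_baseline: float = 1.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        for spec, conc in self.components:
            if conc < 0:
                raise ValueError(f"{spec.name}: concentration must be >= 0 (got {conc})")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    @property
    def is_blank(self) -> bool:
        return len(self.components) == 0 or all(c == 0 for _, c in self.components)


def total_absorbance(sample: SampleSpec, wavelength) -> np.ndarray | float:
    """Decadic absorbance A(lambda) = path_length * sum_i eps_i(lambda) c_i.

    Additive over components; zero for the blank. Raises ``ValueError``
    for wavelengths outside the [185, 655] nm emission span.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < EMISSION_MIN_NM) or np.any(wl > EMISSION_MAX_NM):
        raise ValueError(
            f"wavelength outside [{EMISSION_MIN_NM}, {EMISSION_MAX_NM}] nm: {wavelength}"
        )
    out = np.zeros_like(wl)
    for spec, conc in sample.components:
        out = out + spec.absorption(wl) * conc
    out = out * sample.path_length
    return float(out) if np.ndim(wavelength) == 0 else out


@dataclass(frozen=True)
class EmissionSpectrum:
    """One LED channel: 1516 detector counts plus exposure settings."""

    led_index: int
    intensities: np.ndarray
    integration_time: float
    brightness: float
    saturated_flag: bool = False
    underexposed: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.led_index < N_LEDS:
            raise ValueError(f"led_index must be in [0, {N_LEDS})")
        if len(self.intensities) != N_EMISSION_PIXELS:
            raise ValueError(f"intensities must have {N_EMISSION_PIXELS} values")
        if not 0.0 <= self.brightness <= 1.0:
            raise ValueError("brightness must be in [0, 1]")


def _fluorescence_field(sample: SampleSpec, lam_ex: float, axis: np.ndarray,
                        config: DeviceConfig) -> np.ndarray:
    """Noise-free, exposure-free fluorescence term F(lambda) for one LED."""
    a_ex = total_absorbance(sample, lam_ex)
    if a_ex <= 0:
        return np.zeros_like(axis)
    shares = np.array([spec.absorption(lam_ex) * conc * sample.path_length
                       for spec, conc in sample.components])
    weights = shares / shares.sum()
    emit = np.zeros_like(axis)
    for (spec, _conc), w in zip(sample.components, weights):
        if w > 0:
            emit += w * spec.quantum_yield * spec.emission_profile(axis)
    a_em = total_absorbance(sample, axis)
    return (config.led_power * (1.0 - 10.0 ** (-a_ex)) * emit
            * 10.0 ** (-config.secondary_filter_factor * a_em))


def _reflectance_field(sample: SampleSpec, lam_ex: float, axis: np.ndarray,
                       config: DeviceConfig) -> np.ndarray:
    """Reflected LED line attenuated by the pseudoabsorption exponent."""
    a_ex = total_absorbance(sample, lam_ex)
    line = _gaussian(axis, lam_ex, config.led_bandwidth_fwhm)
    return (config.led_power * sample.solvent_baseline * line
            * 10.0 ** (-config.reflectance_path_factor * a_ex))


def simulate_channel(
    sample: SampleSpec,
    led_index: int,
    config: DeviceConfig,
    integration_time: float,
    brightness: float = 1.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> EmissionSpectrum:
    """Simulate one LED channel at a fixed exposure.

    counts = clip(t * b * [R(lambda) + F(lambda)] + noise, 0, saturation)
    with R the attenuated reflected LED line, F the inner-filtered
    fluorescence, and zero-mean Gaussian noise whose variance is
    noise_floor^2 + shot_noise_scale * signal.
    """
    if not 0 <= led_index < N_LEDS:
        raise ValueError(f"led_index must be in [0, {N_LEDS})")
    if integration_time <= 0:
        raise ValueError(f"integration_time must be positive, got {integration_time}")
    if not 0.0 <= brightness <= 1.0:
        raise ValueError("brightness must be in [0, 1]")
    axis = config.emission_axis
    lam_ex = config.led_wavelengths[led_index]
    field_rate = (_reflectance_field(sample, lam_ex, axis, config)
                  + _fluorescence_field(sample, lam_ex, axis, config))
    signal = integration_time * brightness * field_rate
    if config.noise_floor > 0 or config.shot_noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sigma = np.sqrt(config.noise_floor ** 2
                        + config.shot_noise_scale * np.clip(signal, 0.0, None))
        raw = signal + rng.normal(0.0, 1.0, signal.shape) * sigma
    else:
        raw = signal
    saturated = bool(np.any(raw > config.saturation_level))
    return EmissionSpectrum(
        led_index=led_index,
        intensities=np.clip(raw, 0.0, config.saturation_level),
        integration_time=float(integration_time),
        brightness=float(brightness),
        saturated_flag=saturated,
    )


def auto_integrate(
    sample: SampleSpec,
    led_index: int,
    config: DeviceConfig,
    seed=None,
    brightness: float = 1.0,
    tolerance: float = 0.02,
) -> EmissionSpectrum:
    """Drive the integration time toward the target saturation fraction.

    Starting from ``config.start_integration``, the exposure is rescaled
    multiplicatively, t <- t * (target * saturation / peak), assuming a
    linear detector, until the brightest pixel lies within ``tolerance``
    of ``target_saturation_fraction`` (at most
    ``integration_iterations_cap`` iterations). If the target cannot be
    reached by ``max_integration`` — e.g. an all-dark sample — the
    spectrum at the capped exposure is returned with ``underexposed``
    set. Never divides by zero.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    target_frac = config.target_saturation_fraction
    target_counts = target_frac * config.saturation_level
    dark_level = max(3.0 * config.noise_floor, 1e-12)
    t = config.start_integration
    spectrum = None
    for _ in range(config.integration_iterations_cap):
        child = ss.spawn(1)[0]
        spectrum = simulate_channel(sample, led_index, config, t, brightness,
                                    rng=np.random.default_rng(child))
        peak = float(spectrum.intensities.max())
        frac = peak / config.saturation_level
        if abs(frac - target_frac) <= tolerance:
            return spectrum
        if peak <= dark_level:
            t_next = config.max_integration
        else:
            t_next = t * (target_counts / peak)
        t_next = min(t_next, config.max_integration)
        if t_next == t:
            break  # capped: cannot improve further
        t = t_next
    peak = float(spectrum.intensities.max())
    under = peak < (target_frac - tolerance) * config.saturation_level
    return replace(spectrum, underexposed=bool(under))


@dataclass(frozen=True)
class RawScan:
    """One full device scan: 18,192 rows x 5 fields, 12 LED blocks of 1516.

    Column arrays are row-aligned; within each contiguous LED block the
    led_index, integration_time and brightness are constant.
    """

    led_index: np.ndarray
    emission_nm: np.ndarray
    intensity: np.ndarray
    integration_time: np.ndarray
    brightness: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = (self.led_index, self.emission_nm, self.intensity,
                self.integration_time, self.brightness)
        lengths = {len(c) for c in cols}
        if lengths != {ROWS_PER_SCAN}:
            raise ValueError(f"scan must have exactly {ROWS_PER_SCAN} rows, got {lengths}")
        for lo, led in zip(range(0, ROWS_PER_SCAN, N_EMISSION_PIXELS), range(N_LEDS)):
            block = slice(lo, lo + N_EMISSION_PIXELS)
            for name, col in (("led_index", self.led_index),
                              ("integration_time", self.integration_time),
                              ("brightness", self.brightness)):
                vals = np.unique(np.asarray(col)[block])
                if len(vals) != 1:
                    raise ValueError(f"block {led}: {name} not constant")
            if int(self.led_index[lo]) != led:
                raise ValueError(f"block {led}: unexpected led_index {self.led_index[lo]}")

    @property
    def n_rows(self) -> int:
        return ROWS_PER_SCAN

    @property
    def n_fields(self) -> int:
        return 5

    def block(self, led: int) -> slice:
        if not 0 <= led < N_LEDS:
            raise ValueError(f"led must be in [0, {N_LEDS})")
        return slice(led * N_EMISSION_PIXELS, (led + 1) * N_EMISSION_PIXELS)

    def iter_blocks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray, float, float]]:
        for led in range(N_LEDS):
            b = self.block(led)
            yield (led, self.emission_nm[b], self.intensity[b],
                   float(self.integration_time[b.start]), float(self.brightness[b.start]))

    @classmethod
    def from_spectra(cls, spectra: Sequence[EmissionSpectrum], axis: np.ndarray,
                     metadata: dict | None = None) -> "RawScan":
        if len(spectra) != N_LEDS:
            raise ValueError(f"expected {N_LEDS} channel spectra, got {len(spectra)}")
        led = np.repeat(np.arange(N_LEDS), N_EMISSION_PIXELS)
        nm = np.tile(np.asarray(axis, dtype=float), N_LEDS)
        inten = np.concatenate([s.intensities for s in spectra])
        t = np.repeat([s.integration_time for s in spectra], N_EMISSION_PIXELS)
        b = np.repeat([s.brightness for s in spectra], N_EMISSION_PIXELS)
        return cls(led, nm, inten, t, b, metadata or {})


def acquire_scan(sample: SampleSpec, config: DeviceConfig, seed=None,
                 sample_id: str = "") -> RawScan:
    """Full scan: auto-integrate each of the 12 LEDs in ascending order.

    Deterministic given ``seed`` (an int or a ``SeedSequence`` entropy
    tuple); each LED channel draws from an independently spawned stream.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(N_LEDS)
    spectra = [auto_integrate(sample, led, config, seed=children[led])
               for led in range(N_LEDS)]
    meta = {"seed": seed, "sample_id": sample_id}
    return RawScan.from_spectra(spectra, config.emission_axis, meta)
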