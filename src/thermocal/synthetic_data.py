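"""Synthetic spectra with the statistical structure the analysis assumes.

The generator produces Gaussian-band absorbance spectra that are

* affine in solute concentration at every axis point (Beer-Lambert),
* smoothly temperature dependent, through quadratic polynomials for band
  centre shift, width change, fractional height change and baseline drift,
* corrupted by i.i.d. Gaussian replicate noise.

Two modes are provided.  ``realistic`` lets band centres and widths move
with temperature, so the per-temperature loadings are only approximately
polynomial in T -- this exercises the robustness of the correction.
``linearized`` freezes centres and widths and keeps only the quadratic
height/baseline scaling, making the data exactly rank-2 (one solute plus
one background component) with loadings exactly quadratic in T; on such
data loading space standardization is provably exact.

The module also ships the study's experiment builders: the 40-sample
calibration design over 4-20 g/100 g solvent and -10..75 deg C, the two
validation points (5 g/100 g at 20 deg C, 15 g/100 g at 65 deg C) and the
stepped-heating slurry experiment (holds 0..70 deg C in 10 deg C steps)
whose supernatant tracks a van 't Hoff ground-truth solubility curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DesignError
from .spectra_core import (
    WAVELENGTH_NM,
    WAVENUMBER_CM,
    SpectralAxis,
    SpectralDataset,
    SpectrumMeta,
)

Quad = tuple[float, float, float]

#: temperature range (deg C) over which configurations are checked for
#: axis support; matches the calibration design space.
DESIGN_TEMP_RANGE = (-10.0, 75.0)


def _quad(coeffs: Sequence[float], t: float) -> float:
    k0, k1, k2 = coeffs
    return k0 + k1 * t + k2 * t * t


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band and its quadratic temperature sensitivities.

    ``height0`` is absorbance per (g/100 g solvent) for solute bands and
    absolute absorbance for solvent/background bands.  ``dcenter`` and
    ``dwidth`` are quadratic coefficients (in T, deg C) of additive shifts
    in axis units; ``dheight`` gives a quadratic *fractional* height
    change, i.e. height(T) = height0 * (1 + dheight(T)).
    """

    center0: float
    width0: float
    height0: float
    species: str  # "solute" | "solvent"
    dcenter: Quad = (0.0, 0.0, 0.0)
    dwidth: Quad = (0.0, 0.0, 0.0)
    dheight: Quad = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.species not in ("solute", "solvent"):
            raise ConfigurationError(f"unknown band species {self.species!r}")
        if not self.width0 > 0:
            raise ConfigurationError("band width0 must be > 0")

    def center_at(self, t: float, linearized: bool = False) -> float:
        return self.center0 if linearized else self.center0 + _quad(self.dcenter, t)

    def width_at(self, t: float, linearized: bool = False) -> float:
        w = self.width0 if linearized else self.width0 + _quad(self.dwidth, t)
        if not w > 0:
            raise ConfigurationError(
                f"band at {self.center0} has non-positive width at {t} degC"
            )
        return w

    def height_at(self, t: float) -> float:
        return self.height0 * (1.0 + _quad(self.dheight, t))


@dataclass(frozen=True)
class InstrumentConfig:
    """Axis, band set, baseline drift and noise of a simulated instrument.

    ``baseline_offset``/``baseline_slope`` are quadratic coefficients in T
    of a linear-in-axis baseline  b(u, T) = offset(T) + slope(T) * u,
    with u the axis coordinate rescaled to [0, 1].
    """

    axis: SpectralAxis
    bands: tuple[BandSpec, ...]
    baseline_offset: Quad = (0.0, 0.0, 0.0)
    baseline_slope: Quad = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    n_replicates: int = 1
    mode: str = "realistic"  # "realistic" | "linearized"

    def __post_init__(self) -> None:
        if not any(b.species == "solute" for b in self.bands):
            raise ConfigurationError("configuration needs at least one solute band")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.mode not in ("realistic", "linearized"):
            raise ConfigurationError(f"unknown generator mode {self.mode!r}")
        object.__setattr__(self, "bands", tuple(self.bands))

    @property
    def linearized(self) -> bool:
        return self.mode == "linearized"


@dataclass(frozen=True)
class SolubilityModel:
    """Van 't Hoff-type ground-truth solubility  S(T) = exp(A - B / T_K).

    ``A`` is dimensionless, ``B`` is in Kelvin; ``metastable_factor`` is
    the supersaturation ratio up to which clear (metastable) solutions are
    assumed possible when deriving designs.
    """

    A: float = 8.1
    B: float = 1600.0
    metastable_factor: float = 1.6

    def __post_init__(self) -> None:
        if self.metastable_factor < 1:
            raise ConfigurationError("metastable_factor must be >= 1")

    def solubility(self, temperature: float) -> float:
        return solubility_at(self, temperature)


def solubility_at(model: SolubilityModel, temperature) -> float | np.ndarray:
    """Equilibrium concentration (g/100 g solvent) at ``temperature`` deg C."""
    t_k = np.asarray(temperature, dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ConfigurationError("temperature must be above absolute zero")
    out = np.exp(model.A - model.B / t_k)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationDesign:
    """Concentrations and the temperatures at which each is measured."""

    entries: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.entries]
        if len(set(concs)) != len(concs):
            raise DesignError("design concentrations must be unique")
        for c, temps in self.entries:
            if len(set(temps)) != len(temps):
                raise DesignError(f"duplicate temperature for concentration {c}")
        object.__setattr__(
            self, "entries", tuple((c, tuple(t)) for c, t in self.entries)
        )

    @property
    def n_samples(self) -> int:
        return sum(len(temps) for _, temps in self.entries)

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(c for c, _ in self.entries)

    def pairs(self) -> list[tuple[float, float]]:
        return [(c, t) for c, temps in self.entries for t in temps]


#: the full stepped-cooling temperature grid of the calibration design
DESIGN_TEMPERATURES = (-10.0, 0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 75.0)


def table1_design() -> CalibrationDesign:
    """The 40-sample calibration design.

    Concentrations 4, 8 and 12 g/100 g solvent are measured at all ten
    temperatures -10..75 deg C (these are the metastable-zone-limited
    levels used for fitting the temperature-correction model); 16 g/100 g
    only at 30..75 deg C and 20 g/100 g only at 50..75 deg C, because at
    lower temperatures those solutions would nucleate.
    """
    t_all = DESIGN_TEMPERATURES
    return CalibrationDesign(
        entries=(
            (4.0, t_all),
            (8.0, t_all),
            (12.0, t_all),
            (16.0, tuple(t for t in t_all if t >= 30.0)),
            (20.0, tuple(t for t in t_all if t >= 50.0)),
        )
    )


#: concentrations used to fit the temperature-correction (LSS) model
LSS_INPUT_CONCENTRATIONS = (4.0, 8.0, 12.0)

#: the two validation experiments: (concentration g/100 g, temperature degC)
VALIDATION_POINTS = ((5.0, 20.0), (15.0, 65.0))


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def clean_spectrum(config: InstrumentConfig, concentration: float, temperature: float) -> np.ndarray:
    """Noise-free spectrum at (concentration, temperature)."""
    if concentration < 0:
        raise ConfigurationError("concentration must be >= 0")
    v = config.axis.values
    lo, hi = v[0], v[-1]
    u = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    out = _quad(config.baseline_offset, temperature) + _quad(
        config.baseline_slope, temperature
    ) * u
    for band in config.bands:
        c = band.center_at(temperature, config.linearized)
        w = band.width_at(temperature, config.linearized)
        if c - 3 * w < lo or c + 3 * w > hi:
            raise ConfigurationError(
                f"band centred at {c:.1f} (width {w:.1f}) leaves axis support "
                f"[{lo:g}, {hi:g}] at {temperature} degC"
            )
        amp = band.height_at(temperature)
        if band.species == "solute":
            amp *= concentration
        out = out + amp * np.exp(-0.5 * ((v - c) / w) ** 2)
    return out


def simulate_spectrum(
    config: InstrumentConfig,
    concentration: float,
    temperature: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One noisy spectrum; identical seed gives an identical vector."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = clean_spectrum(config, concentration, temperature)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=x.size)
    return x


def _replicate_block(
    config: InstrumentConfig,
    concentration: float | None,
    true_concentration: float,
    temperature: float,
    sample_id: str,
    role: str,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> tuple[np.ndarray, list[SpectrumMeta]]:
    rows = []
    meta = []
    for rep in range(1, config.n_replicates + 1):
        rows.append(simulate_spectrum(config, true_concentration, temperature, rng))
        meta.append(
            SpectrumMeta(
                sample_id=sample_id,
                concentration=concentration,
                temperature=temperature,
                time=t0 + 60.0 * (rep - 1),
                replicate=rep,
                role=role,
            )
        )
    return np.vstack(rows), meta


def generate_calibration_set(
    design: CalibrationDesign, config: InstrumentConfig, seed: int = 0
) -> SpectralDataset:
    """Replicate spectra for every (concentration, temperature) design pair.

    The design is taken literally (no censoring by solubility): metastable
    clear solutions are part of the calibration space.  Replicates within
    a sample differ only by noise.
    """
    rng = np.random.default_rng(seed)
    blocks, meta = [], []
    for c, temps in design.entries:
        for t in temps:
            X, m = _replicate_block(
                config, c, c, t, f"cal_c{c:g}_t{t:g}", "calibration", rng
            )
            blocks.append(X)
            meta.extend(m)
    return SpectralDataset(
        axis=config.axis, intensities=np.vstack(blocks), meta=meta
    )


def generate_validation_set(
    config: InstrumentConfig,
    seed: int = 0,
    points: Sequence[tuple[float, float]] = VALIDATION_POINTS,
) -> SpectralDataset:
    """Replicate spectra for the validation points (default: the two
    constant-temperature validation experiments)."""
    rng = np.random.default_rng(seed)
    blocks, meta = [], []
    for c, t in points:
        X, m = _replicate_block(
            config, c, c, t, f"val_c{c:g}_t{t:g}", "validation", rng
        )
        blocks.append(X)
        meta.extend(m)
    return SpectralDataset(axis=config.axis, intensities=np.vstack(blocks), meta=meta)


# ---------------------------------------------------------------------------
# slurry heating experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoldWindow:
    """One constant-temperature hold: [start, end] seconds at ``setpoint`` degC."""

    start: float
    end: float
    setpoint: float


@dataclass(frozen=True)
class TemperatureProfile:
    """Ordered hold windows of a stepped heating profile."""

    holds: tuple[HoldWindow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "holds", tuple(self.holds))

    def to_dict(self) -> dict:
        return {
            "holds": [
                {"start": h.start, "end": h.end, "setpoint": h.setpoint}
                for h in self.holds
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemperatureProfile":
        return cls(
            holds=tuple(
                HoldWindow(float(h["start"]), float(h["end"]), float(h["setpoint"]))
                for h in d["holds"]
            )
        )


def generate_slurry_experiment(
    config: InstrumentConfig,
    sol: SolubilityModel,
    hold_temps: Sequence[float] = tuple(range(0, 80, 10)),
    hold_duration: float = 1800.0,
    spectra_per_hold: int = 10,
    kinetics_tau: float = 300.0,
    seed: int = 0,
    ramp_rate: float = 5.0 / 60.0,
) -> tuple[SpectralDataset, TemperatureProfile]:
    """Stepped-heating slurry experiment with excess solid throughout.

    During each hold the supernatant concentration relaxes exponentially
    (time constant ``kinetics_tau`` seconds) from its value at the end of
    the previous hold toward the equilibrium solubility S(T_hold); the
    slurry enters the profile pre-equilibrated at the first hold
    temperature.  Ramps run at ``ramp_rate`` deg C/s (default 5 deg C/min)
    and one mid-ramp spectrum is recorded per ramp.  Metadata carry the
    true supernatant concentration so recovery can be tested.
    """
    hold_temps = [float(t) for t in hold_temps]
    if len(hold_temps) < 1 or any(
        b <= a for a, b in zip(hold_temps, hold_temps[1:])
    ):
        raise ConfigurationError("hold_temps must be strictly increasing")
    if hold_duration <= 0 or spectra_per_hold < 1:
        raise ConfigurationError("hold_duration and spectra_per_hold must be positive")
    if kinetics_tau < 0:
        raise ConfigurationError("kinetics_tau must be >= 0")

    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    meta: list[SpectrumMeta] = []
    holds: list[HoldWindow] = []

    t_clock = 0.0
    conc = solubility_at(sol, hold_temps[0])  # pre-equilibrated at first hold
    prev_temp = hold_temps[0]
    for h_idx, t_hold in enumerate(hold_temps):
        if h_idx > 0:
            ramp_time = abs(t_hold - prev_temp) / ramp_rate
            # one spectrum half-way up the ramp; supernatant unchanged there
            mid_time = t_clock + 0.5 * ramp_time
            mid_temp = 0.5 * (prev_temp + t_hold)
            rows.append(simulate_spectrum(config, conc, mid_temp, rng))
            meta.append(
                SpectrumMeta(
                    sample_id=f"slurry_ramp{h_idx}",
                    concentration=float(conc),
                    temperature=mid_temp,
                    time=mid_time,
                    replicate=1,
                    role="slurry",
                )
            )
            t_clock += ramp_time
        start = t_clock
        end = start + hold_duration
        s_eq = solubility_at(sol, t_hold)
        c_entry = conc
        for j in range(1, spectra_per_hold + 1):
            dt = hold_duration * j / spectra_per_hold
            if kinetics_tau == 0:
                c_now = s_eq
            else:
                c_now = s_eq + (c_entry - s_eq) * math.exp(-dt / kinetics_tau)
            rows.append(simulate_spectrum(config, c_now, t_hold, rng))
            meta.append(
                SpectrumMeta(
                    sample_id=f"slurry_hold{h_idx}",
                    concentration=float(c_now),
                    temperature=t_hold,
                    time=start + dt,
                    replicate=1,
                    role="slurry",
                )
            )
        conc = c_now
        holds.append(HoldWindow(start=start, end=end, setpoint=t_hold))
        t_clock = end
        prev_temp = t_hold

    dataset = SpectralDataset(
        axis=config.axis, intensities=np.vstack(rows), meta=meta
    )
    return dataset, TemperatureProfile(holds=tuple(holds))


# ---------------------------------------------------------------------------
# default instrument configurations
# ---------------------------------------------------------------------------

def default_uv_config(
    mode: str = "realistic", noise_sd: float = 0.0015, n_replicates: int = 5
) -> InstrumentConfig:
    """Default UV instrument: 200-320 nm at 1 nm.

    A single solute band at 244 nm dominates, with a mostly linear ~5 nm
    red-shift and a mild height loss across -10..75 deg C; a weaker
    background band at 272 nm (residual solvent absorption against the
    solvent-referenced background) and a slow baseline drift provide the
    second spectroscopically significant component, so a two-factor
    temperature-correction model is required, as in the study system.
    """
    axis = SpectralAxis(kind=WAVELENGTH_NM, values=np.arange(200.0, 321.0, 1.0))
    bands = (
        BandSpec(
            center0=244.0,
            width0=12.0,
            height0=0.048,
            species="solute",
            dcenter=(0.0, 0.05, 0.0002),
            dwidth=(0.0, 0.02, 0.0),
            dheight=(0.0, -0.0015, 0.0),
        ),
        BandSpec(
            center0=272.0,
            width0=15.0,
            height0=0.10,
            species="solvent",
            dcenter=(0.0, 0.005, 0.0),
            dheight=(0.0, -0.001, 0.0),
        ),
    )
    return InstrumentConfig(
        axis=axis,
        bands=bands,
        baseline_offset=(0.0, 2e-4, 1e-6),
        baseline_slope=(0.0, -1e-4, 0.0),
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        mode=mode,
    )


def default_ir_config(
    mode: str = "realistic", noise_sd: float = 0.0008, n_replicates: int = 5
) -> InstrumentConfig:
    """Default mid-IR instrument: 650-1900 cm^-1 at 4 cm^-1.

    Solute carbonyl/alkene stretches near 1765 and 1695 cm^-1 shift
    noticeably with temperature; solvent bands near 1620, 1375 and
    920 cm^-1 are comparatively temperature-insensitive.
    """
    axis = SpectralAxis(kind=WAVENUMBER_CM, values=np.arange(650.0, 1901.0, 4.0))
    bands = (
        BandSpec(1765.0, 12.0, 0.020, "solute",
                 dcenter=(0.0, -0.06, 0.0), dwidth=(0.0, 0.03, 0.0),
                 dheight=(0.0, -0.002, 0.0)),
        BandSpec(1695.0, 10.0, 0.015, "solute",
                 dcenter=(0.0, -0.05, 0.0), dheight=(0.0, -0.0015, 0.0)),
        BandSpec(1200.0, 14.0, 0.012, "solute",
                 dcenter=(0.0, 0.03, 0.0), dheight=(0.0, -0.001, 0.0)),
        BandSpec(1115.0, 18.0, 0.010, "solute",
                 dheight=(0.0, -0.001, 0.0)),
        BandSpec(1620.0, 25.0, 0.30, "solvent",
                 dcenter=(0.0, 0.01, 0.0), dheight=(0.0, -0.0004, 0.0)),
        BandSpec(1375.0, 10.0, 0.25, "solvent",
                 dheight=(0.0, -0.0003, 0.0)),
        BandSpec(920.0, 8.0, 0.20, "solvent",
                 dheight=(0.0, -0.0003, 0.0)),
    )
    return InstrumentConfig(
        axis=axis,
        bands=bands,
        baseline_offset=(0.0, 1e-4, 0.0),
        baseline_slope=(0.0, -5e-5, 0.0),
        noise_sd=noise_sd,
        n_replicates=n_replicates,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# configuration (de)serialisation for the CLI
# ---------------------------------------------------------------------------

def config_to_dict(config: InstrumentConfig) -> dict:
    return {
        "axis": {
            "kind": config.axis.kind,
            "values": [float(v) for v in config.axis.values],
        },
        "bands": [
            {
                "center0": b.center0,
                "width0": b.width0,
                "height0": b.height0,
                "species": b.species,
                "dcenter": list(b.dcenter),
                "dwidth": list(b.dwidth),
                "dheight": list(b.dheight),
            }
            for b in config.bands
        ],
        "baseline_offset": list(config.baseline_offset),
        "baseline_slope": list(config.baseline_slope),
        "noise_sd": config.noise_sd,
        "n_replicates": config.n_replicates,
        "mode": config.mode,
    }


def config_from_dict(d: dict) -> InstrumentConfig:
    axis = SpectralAxis(kind=d["axis"]["kind"], values=np.asarray(d["axis"]["values"], float))
    bands = tuple(
        BandSpec(
            center0=float(b["center0"]),
            width0=float(b["width0"]),
            height0=float(b["height0"]),
            species=b["species"],
            dcenter=tuple(b.get("dcenter", (0, 0, 0))),
            dwidth=tuple(b.get("dwidth", (0, 0, 0))),
            dheight=tuple(b.get("dheight", (0, 0, 0))),
        )
        for b in d["bands"]
    )
    return InstrumentConfig(
        axis=axis,
        bands=bands,
        baseline_offset=tuple(d.get("baseline_offset", (0, 0, 0))),
        baseline_slope=tuple(d.get("baseline_slope", (0, 0, 0))),
        noise_sd=float(d.get("noise_sd", 0.0)),
        n_replicates=int(d.get("n_replicates", 1)),
        mode=d.get("mode", "realistic"),
    )


def solubility_to_dict(model: SolubilityModel) -> dict:
    return {"A": model.A, "B": model.B, "metastable_factor": model.metastable_factor}


def solubility_from_dict(d: dict) -> SolubilityModel:
    return SolubilityModel(
        A=float(d.get("A", 8.1)),
        B=float(d.get("B", 1600.0)),
        metastable_factor=float(d.get("metastable_factor", 1.6)),
    )
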