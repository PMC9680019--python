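"""End-to-end workflows: the four-variant calibration comparison and
solubility-curve determination with bias analysis.

``run_calibration_comparison`` reproduces the structure of the study's
model comparison: a global model on raw spectra, a global model on first
derivatives, a global model on temperature-corrected (LSS) spectra, and
an isothermal local model as the benchmark with temperature effects
absent.  Each variant is cross-validated (random subsets, grouped by
sample), its latent-variable count selected, and both validation samples
predicted; the result is a machine-readable report with one row per
variant.

``predict_solubility_curve`` applies a fitted chain (preprocess ->
optional LSS correction -> PLS) to the final spectrum of each hold of a
stepped-heating slurry experiment, yielding solubility versus temperature;
``bias_metrics`` compares such a curve against a reference on the same
temperature grid, and ``fit_vant_hoff`` recovers the two-parameter
ln S ~ 1/T_K representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    CoverageError,
    DesignError,
    ParameterError,
    PipelineError,
)
from .lss import LSSModel, apply_lss_dataset, fit_lss
from .pls import (
    CVConfig,
    PLSModel,
    PredictionSummary,
    fit_pls,
    pls_predict,
    prediction_summary,
    random_subset_cv,
    regression_metrics,
)
from .preprocess import PreprocessSpec
from .spectra_core import SpectralDataset
from .synthetic_data import (
    LSS_INPUT_CONCENTRATIONS,
    SolubilityModel,
    TemperatureProfile,
    solubility_at,
)

VARIANT_LABELS = ("global_raw", "global_deriv", "global_lss", "local_isothermal")


@dataclass(frozen=True)
class ModelVariantSpec:
    """One calibration strategy to be benchmarked."""

    label: str
    preprocess: PreprocessSpec
    lss_enabled: bool = False
    lss_input_concentrations: tuple[float, ...] = ()
    lss_k: int = 2
    local_temperature: float | None = None
    t_target: float = 50.0

    def __post_init__(self) -> None:
        if self.label not in VARIANT_LABELS:
            raise ParameterError(f"label must be one of {VARIANT_LABELS}")
        if self.label == "local_isothermal" and self.local_temperature is None:
            raise ParameterError("local_isothermal requires local_temperature")
        if self.lss_enabled and not self.lss_input_concentrations:
            raise ParameterError("lss_enabled requires lss_input_concentrations")


def default_uv_variants(
    range_lo: float = 218.0, range_hi: float = 285.0, t_target: float = 50.0
) -> list[ModelVariantSpec]:
    """UV strategy set: raw, 15-point first derivative, LSS on absorbance
    (fitted on the three lower concentrations), local at 50 degC."""
    raw = PreprocessSpec(range_lo, range_hi)
    deriv = PreprocessSpec(range_lo, range_hi, sg_window=15)
    return [
        ModelVariantSpec("global_raw", raw),
        ModelVariantSpec("global_deriv", deriv),
        ModelVariantSpec(
            "global_lss", raw, lss_enabled=True,
            lss_input_concentrations=LSS_INPUT_CONCENTRATIONS, t_target=t_target,
        ),
        ModelVariantSpec("local_isothermal", raw, local_temperature=t_target),
    ]


def default_ir_variants(
    range_lo: float = 709.0, range_hi: float = 1831.0, t_target: float = 50.0
) -> list[ModelVariantSpec]:
    """IR strategy set: raw, 7-point first derivative, LSS on the first
    derivative, local (first derivative) at 50 degC."""
    raw = PreprocessSpec(range_lo, range_hi)
    deriv = PreprocessSpec(range_lo, range_hi, sg_window=7)
    return [
        ModelVariantSpec("global_raw", raw),
        ModelVariantSpec("global_deriv", deriv),
        ModelVariantSpec(
            "global_lss", deriv, lss_enabled=True,
            lss_input_concentrations=LSS_INPUT_CONCENTRATIONS, t_target=t_target,
        ),
        ModelVariantSpec("local_isothermal", deriv, local_temperature=t_target),
    ]


@dataclass
class PredictionChain:
    """A full prediction pipeline: preprocess -> [LSS to t_target] -> PLS."""

    preprocess: PreprocessSpec
    pls: PLSModel
    lss_model: LSSModel | None = None
    t_target: float | None = None

    def transform(self, dataset: SpectralDataset) -> SpectralDataset:
        ds = self.preprocess.apply(dataset)
        if self.lss_model is not None:
            ds = apply_lss_dataset(self.lss_model, ds, self.t_target)
        if (
            self.pls.preprocessing_tag is not None
            and ds.preprocessing != self.pls.preprocessing_tag
        ):
            raise PipelineError(
                f"chain produced tag {ds.preprocessing!r} but the PLS model was "
                f"trained on {self.pls.preprocessing_tag!r}"
            )
        return ds

    def predict(self, dataset: SpectralDataset) -> np.ndarray:
        ds = self.transform(dataset)
        return pls_predict(self.pls, ds.intensities)

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "pls": self.pls.to_dict(),
            "lss": None if self.lss_model is None else self.lss_model.to_dict(),
            "t_target": self.t_target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionChain":
        return cls(
            preprocess=PreprocessSpec.from_dict(d["preprocess"]),
            pls=PLSModel.from_dict(d["pls"]),
            lss_model=None if d.get("lss") is None else LSSModel.from_dict(d["lss"]),
            t_target=d.get("t_target"),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PredictionChain":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class VariantResult:
    """Table row for one variant: complexity, calibration and CV metrics,
    and a prediction summary per validation sample."""

    label: str
    chosen_lv: int
    rmsec: float
    r2_cal: float
    rmsecv: float
    r2_cv: float
    validation: dict[str, PredictionSummary]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "chosen_lv": self.chosen_lv,
            "rmsec": self.rmsec,
            "r2_cal": self.r2_cal,
            "rmsecv": self.rmsecv,
            "r2_cv": self.r2_cv,
            "validation": {k: v.to_dict() for k, v in self.validation.items()},
        }


@dataclass
class ModelReport:
    """Comparison of calibration variants; serialisable as JSON or CSV."""

    variants: list[VariantResult]
    chains: dict[str, PredictionChain] = field(default_factory=dict, repr=False)

    def __getitem__(self, label: str) -> VariantResult:
        for v in self.variants:
            if v.label == label:
                return v
        raise KeyError(label)

    def to_dict(self) -> dict:
        return {"variants": [v.to_dict() for v in self.variants]}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for v in self.variants:
            row: dict = {
                "label": v.label,
                "LVs": v.chosen_lv,
                "RMSEC": v.rmsec,
                "R2_cal": v.r2_cal,
                "RMSECV": v.rmsecv,
                "R2_cv": v.r2_cv,
            }
            for name, s in v.validation.items():
                for metric, value in s.to_dict().items():
                    row[f"{name}_{metric}"] = value
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _prepare_variant(
    cal: SpectralDataset,
    val: SpectralDataset,
    variant: ModelVariantSpec,
) -> tuple[SpectralDataset, SpectralDataset, LSSModel | None]:
    ds = variant.preprocess.apply(cal)
    vds = variant.preprocess.apply(val)
    lss_model = None
    if variant.lss_enabled:
        conc = ds.concentrations
        mask = np.zeros(ds.n_spectra, dtype=bool)
        for c in variant.lss_input_concentrations:
            mask |= np.isclose(conc, c)
        if not mask.any():
            raise DesignError("no spectra at the designated LSS input concentrations")
        lss_model = fit_lss(ds.subset(mask), K=variant.lss_k, t_ref=variant.t_target,
                            t_target=variant.t_target)
        ds = apply_lss_dataset(lss_model, ds, variant.t_target)
        vds = apply_lss_dataset(lss_model, vds, variant.t_target)
    if variant.local_temperature is not None:
        temps = ds.temperatures
        mask = np.isclose(temps, variant.local_temperature)
        if not mask.any():
            raise DesignError(
                f"no calibration spectra at {variant.local_temperature} degC for the local model"
            )
        local = ds.subset(mask)
        all_concs = {m.concentration for m in ds.meta}
        local_concs = {m.concentration for m in local.meta}
        if local_concs != all_concs:
            raise DesignError(
                "isothermal slice does not cover all calibration concentrations"
            )
        ds = local
    return ds, vds, lss_model


def run_calibration_comparison(
    cal: SpectralDataset,
    val: SpectralDataset,
    variants: list[ModelVariantSpec] | None = None,
    cv: CVConfig | None = None,
) -> ModelReport:
    """Benchmark calibration variants on one calibration/validation pair.

    For each variant: preprocess; optionally fit the temperature
    correction on the designated concentrations only and transform the
    whole set to the target temperature; optionally restrict to the
    isothermal slice; cross-validate, select the latent-variable count,
    refit on all training data and summarise predictions of each
    validation sample.
    """
    variants = default_uv_variants() if variants is None else variants
    cv = CVConfig() if cv is None else cv

    results: list[VariantResult] = []
    chains: dict[str, PredictionChain] = {}
    for variant in variants:
        ds, vds, lss_model = _prepare_variant(cal, val, variant)
        X, y = ds.intensities, ds.y()
        cvres = random_subset_cv(X, y, ds.meta, cv)
        k = cvres.chosen_lv
        model = fit_pls(X, y, k, preprocessing_tag=ds.preprocessing)
        rmsec, r2_cal = regression_metrics(y, pls_predict(model, X))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        res_k = cvres.residuals[:, :, k - 1]
        r2_cv = 1.0 - float(np.sum(res_k**2)) / (res_k.shape[0] * ss_tot)

        validation: dict[str, PredictionSummary] = {}
        v_ids = [m.sample_id for m in vds.meta]
        for sid in sorted(set(v_ids)):
            rows = [i for i, s in enumerate(v_ids) if s == sid]
            truth = vds.meta[rows[0]].concentration
            if truth is None:
                raise DesignError(f"validation sample {sid} has unknown concentration")
            preds = pls_predict(model, vds.intensities[rows])
            validation[sid] = prediction_summary(preds, truth)

        results.append(
            VariantResult(
                label=variant.label,
                chosen_lv=k,
                rmsec=rmsec,
                r2_cal=r2_cal,
                rmsecv=float(cvres.rmsecv[k - 1]),
                r2_cv=r2_cv,
                validation=validation,
            )
        )
        chains[variant.label] = PredictionChain(
            preprocess=variant.preprocess,
            pls=model,
            lss_model=lss_model,
            t_target=variant.t_target if lss_model is not None else None,
        )
    return ModelReport(variants=results, chains=chains)


# ---------------------------------------------------------------------------
# solubility determination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolubilityCurve:
    """Solubility (g/100 g solvent) versus temperature (deg C)."""

    temperatures: np.ndarray
    concentrations: np.ndarray
    method_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        c = np.asarray(self.concentrations, float)
        if t.size != c.size:
            raise ParameterError("temperatures and concentrations differ in length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("curve temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "concentrations", c)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.temperatures.tolist(), self.concentrations.tolist()))


@dataclass(frozen=True)
class BiasSummary:
    """Per-temperature bias (predicted - reference), its mean, and its
    range (max - min)."""

    temperatures: np.ndarray
    biases: np.ndarray
    mean_bias: float
    bias_range: float


def extract_hold_endpoints(
    dataset: SpectralDataset, profile: TemperatureProfile
) -> SpectralDataset:
    """One spectrum per hold: the latest-timestamped spectrum within each
    hold window, its metadata temperature set to the hold setpoint.
    Spectra acquired during ramps fall outside every window and are
    excluded."""
    times = dataset.times
    rows: list[int] = []
    new_meta = []
    for h in profile.holds:
        in_hold = np.flatnonzero((times >= h.start) & (times <= h.end))
        if in_hold.size == 0:
            raise CoverageError(
                f"no spectra in hold [{h.start:g}, {h.end:g}] s at {h.setpoint:g} degC"
            )
        i = int(in_hold[np.argmax(times[in_hold])])
        rows.append(i)
        new_meta.append(replace(dataset.meta[i], temperature=h.setpoint))
    out = dataset.subset(rows)
    out.meta = new_meta
    return out


def predict_solubility_curve(
    chain: PredictionChain,
    endpoints: SpectralDataset,
    method_label: str = "spectroscopic",
) -> SolubilityCurve:
    """Predict the supernatant concentration of each hold endpoint."""
    if endpoints.n_spectra == 0:
        return SolubilityCurve(np.empty(0), np.empty(0), method_label)
    preds = chain.predict(endpoints)
    temps = endpoints.temperatures
    order = np.argsort(temps)
    return SolubilityCurve(temps[order], np.asarray(preds)[order], method_label)


def reference_curve(
    sol: SolubilityModel,
    temperatures,
    method_label: str = "ground_truth",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SolubilityCurve:
    """Reference solubility curve from the ground-truth model, optionally
    with measurement noise (stands in for gravimetric/transmittance
    reference measurements)."""
    temps = np.asarray(temperatures, float)
    conc = solubility_at(sol, temps)
    if noise_sd > 0:
        conc = conc + np.random.default_rng(seed).normal(0, noise_sd, temps.size)
    return SolubilityCurve(temps, conc, method_label)


def bias_metrics(predicted: SolubilityCurve, reference: SolubilityCurve) -> BiasSummary:
    """Per-temperature biases of a predicted curve against a reference on
    the identical temperature grid (no interpolation)."""
    if not np.array_equal(predicted.temperatures, reference.temperatures):
        raise AlignmentError("curves are not on the same temperature grid")
    biases = predicted.concentrations - reference.concentrations
    return BiasSummary(
        temperatures=predicted.temperatures.copy(),
        biases=biases,
        mean_bias=float(biases.mean()),
        bias_range=float(biases.max() - biases.min()),
    )


def fit_vant_hoff(curve: SolubilityCurve) -> SolubilityModel:
    """Least-squares fit of ln S against 1/T_K: slope -B, intercept A."""
    if curve.temperatures.size < 2:
        raise ParameterError("van 't Hoff fit needs at least 2 points")
    if np.any(curve.concentrations <= 0):
        raise ParameterError("van 't Hoff fit requires positive concentrations")
    inv_tk = 1.0 / (curve.temperatures + 273.15)
    slope, intercept = np.polyfit(inv_tk, np.log(curve.concentrations), 1)
    return SolubilityModel(A=float(intercept), B=float(-slope))
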