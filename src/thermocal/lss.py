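"""Loading space standardization (LSS): temperature correction of spectra.

The model assumes that at every temperature t the spectra of a family of
samples factor as  X(t) = S P(t)^T, with composition scores S that do not
depend on temperature and loadings P(t) whose entries vary smoothly --
here quadratically -- with t.  Fitting proceeds by

1. stacking, for each temperature t_m in the design, the matrix X_m of
   spectra with a fixed row ordering (composition-major, replicate-minor);
2. an SVD of the reference-temperature block, X_ref = U S V^T, whose first
   K left factors define the temperature-independent reference scores
   G = U_K S_K;
3. regressing every other temperature block on those scores,
   P_m = X_m^T G (G^T G)^{-1};
4. an ordinary least-squares quadratic fit of each loading entry p_jk
   against standardized temperature over the design temperatures.

To standardize a spectrum measured at t_m to a target temperature t*:
project it onto the modelled loadings P(t_m) to get scores s, carry the
projection residual over unchanged, and rebuild on P(t*):

    out = s P(t*)^T + (x - s P(t_m)^T).

On noise-free data that are exactly rank-K with exactly quadratic
loadings, the corrected spectrum equals the true spectrum at the target
temperature to numerical precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConditioningError,
    DesignError,
    IdentifiabilityError,
    ParameterError,
    PipelineError,
    RankError,
)
from .spectra_core import SpectralAxis, SpectralDataset, SpectrumMeta

logger = logging.getLogger(__name__)

#: condition-number threshold above which score projection is refused
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class FactorDiagnostics:
    """Singular values of the reference block and their cumulative
    squared-value variance fractions."""

    singular_values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if s.size == 0:
            raise ParameterError("diagnostics need at least one singular value")
        if np.any(s < 0) or np.any(np.diff(s) > 0):
            raise ParameterError("singular values must be non-increasing and >= 0")
        object.__setattr__(self, "singular_values", s)

    @property
    def variance_explained(self) -> np.ndarray:
        s2 = self.singular_values**2
        total = s2.sum()
        if total == 0:
            return np.zeros_like(s2)
        return np.cumsum(s2) / total


def select_n_components(
    diag: FactorDiagnostics, variance_threshold: float = 0.995
) -> int:
    """Smallest K whose cumulative variance fraction reaches the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ParameterError("variance_threshold must be in (0, 1]")
    frac = diag.variance_explained
    reached = np.flatnonzero(frac >= variance_threshold - 1e-15)
    if reached.size == 0:
        return int(np.count_nonzero(diag.singular_values > 0))
    return int(reached[0]) + 1


@dataclass
class LSSModel:
    """Fitted temperature-correction model.

    ``coeffs[j, k, :]`` are (a0, a1, a2) with loading
    p_jk(t) = a0 + a1*t~ + a2*t~^2 and t~ = (t - temp_mean)/temp_sd.
    ``ref_scores`` are the temperature-independent composition scores of
    the fitting samples; ``fitted_loadings[m]`` is the regression loading
    matrix of the m-th design temperature (diagnostic, used to assess the
    quadratic fit).
    """

    K: int
    temps_used: np.ndarray  # distinct design temperatures, ascending
    t_ref: float
    t_target: float
    ref_scores: np.ndarray  # (N_rows, K)
    coeffs: np.ndarray  # (p, K, 3)
    temp_mean: float
    temp_sd: float
    axis: SpectralAxis
    preprocessing_tag: str
    diagnostics: FactorDiagnostics | None = None
    fitted_loadings: np.ndarray | None = None  # (M, p, K)

    def standardize_temperature(self, t) -> np.ndarray | float:
        return (np.asarray(t, dtype=float) - self.temp_mean) / self.temp_sd

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "K": self.K,
            "temps_used": self.temps_used.tolist(),
            "t_ref": self.t_ref,
            "t_target": self.t_target,
            "ref_scores": self.ref_scores.tolist(),
            "coeffs": self.coeffs.tolist(),
            "temp_mean": self.temp_mean,
            "temp_sd": self.temp_sd,
            "axis": {"kind": self.axis.kind, "values": self.axis.values.tolist()},
            "preprocessing_tag": self.preprocessing_tag,
        }
        if self.diagnostics is not None:
            d["singular_values"] = self.diagnostics.singular_values.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LSSModel":
        diag = (
            FactorDiagnostics(np.asarray(d["singular_values"], float))
            if "singular_values" in d
            else None
        )
        return cls(
            K=int(d["K"]),
            temps_used=np.asarray(d["temps_used"], float),
            t_ref=float(d["t_ref"]),
            t_target=float(d["t_target"]),
            ref_scores=np.asarray(d["ref_scores"], float),
            coeffs=np.asarray(d["coeffs"], float),
            temp_mean=float(d["temp_mean"]),
            temp_sd=float(d["temp_sd"]),
            axis=SpectralAxis(
                kind=d["axis"]["kind"], values=np.asarray(d["axis"]["values"], float)
            ),
            preprocessing_tag=d["preprocessing_tag"],
            diagnostics=diag,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "LSSModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _cells(dataset: SpectralDataset):
    """Group row indices by (concentration, temperature), replicate-sorted."""
    temps = sorted({m.temperature for m in dataset.meta})
    concs = sorted({m.concentration for m in dataset.meta if m.concentration is not None})
    if len(concs) == 0:
        raise DesignError("LSS fitting requires known concentrations")
    if any(m.concentration is None for m in dataset.meta):
        raise DesignError("LSS fitting dataset contains unknown concentrations")
    cell: dict[tuple[float, float], list[int]] = {
        (c, t): [] for c in concs for t in temps
    }
    for i, m in enumerate(dataset.meta):
        cell[(m.concentration, m.temperature)].append(i)
    for key, idx in cell.items():
        if not idx:
            raise DesignError(
                f"no spectra for concentration {key[0]:g} at {key[1]:g} degC; "
                "every composition must be measured at every temperature"
            )
        idx.sort(key=lambda i: (dataset.meta[i].replicate, dataset.meta[i].time))
    return temps, concs, cell


def fit_lss(
    dataset: SpectralDataset,
    K: int,
    t_ref: float,
    t_target: float | None = None,
) -> LSSModel:
    """Fit an LSS model on a complete composition x temperature design.

    Every composition must be present at every temperature; cells with
    extra replicates are truncated to the dataset-wide minimum replicate
    count so all temperature blocks share one row ordering (the number of
    spectra per sample is determined by the minimum available, as in the
    underlying acquisition protocol).
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    temps, concs, cell = _cells(dataset)
    if len(temps) < 3:
        raise IdentifiabilityError(
            f"quadratic temperature model needs >= 3 distinct temperatures, got {len(temps)}"
        )
    if not any(np.isclose(t_ref, t) for t in temps):
        raise DesignError(f"reference temperature {t_ref} not among design temperatures")
    t_ref = float(temps[int(np.argmin([abs(t - t_ref) for t in temps]))])
    r_min = min(len(idx) for idx in cell.values())

    n_rows = len(concs) * r_min
    p = len(dataset.axis)
    if K > min(n_rows, p):
        raise RankError(f"K={K} exceeds min(rows={n_rows}, columns={p})")

    def block(t: float) -> np.ndarray:
        rows = []
        for c in concs:
            rows.extend(cell[(c, t)][:r_min])
        return dataset.intensities[rows]

    X_ref = block(t_ref)
    U, s, Vt = np.linalg.svd(X_ref, full_matrices=False)
    if s[K - 1] <= s[0] * 1e-12:
        raise RankError(
            f"reference block has rank < {K} (singular values {s[:K]})"
        )
    # sign convention: largest-magnitude element of each loading positive
    for k in range(K):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    ref_scores = U[:, :K] * s[:K]

    M = len(temps)
    loadings = np.empty((M, p, K))
    for m, t in enumerate(temps):
        coef, *_ = np.linalg.lstsq(ref_scores, block(t), rcond=None)  # (K, p)
        loadings[m] = coef.T

    temps_arr = np.asarray(temps, dtype=float)
    temp_mean = float(temps_arr.mean())
    temp_sd = float(temps_arr.std())
    t_std = (temps_arr - temp_mean) / temp_sd
    D = np.column_stack([np.ones(M), t_std, t_std**2])
    beta, *_ = np.linalg.lstsq(D, loadings.reshape(M, p * K), rcond=None)  # (3, p*K)
    coeffs = np.moveaxis(beta.reshape(3, p, K), 0, 2)  # (p, K, 3)

    return LSSModel(
        K=K,
        temps_used=temps_arr,
        t_ref=t_ref,
        t_target=float(t_ref if t_target is None else t_target),
        ref_scores=ref_scores,
        coeffs=coeffs,
        temp_mean=temp_mean,
        temp_sd=temp_sd,
        axis=dataset.axis,
        preprocessing_tag=dataset.preprocessing,
        diagnostics=FactorDiagnostics(s),
        fitted_loadings=loadings,
    )


def loading_matrix_at(model: LSSModel, temperature: float) -> np.ndarray:
    """Loading matrix P (p x K) at a temperature, by entrywise polynomial
    evaluation in standardized temperature."""
    lo, hi = model.temps_used[0], model.temps_used[-1]
    if temperature < lo or temperature > hi:
        logger.info(
            "extrapolating loadings to %.6g degC outside fitted range [%g, %g]",
            temperature, lo, hi,
        )
    t = model.standardize_temperature(temperature)
    a = model.coeffs
    return a[:, :, 0] + a[:, :, 1] * t + a[:, :, 2] * t * t


def apply_lss(
    model: LSSModel,
    spectrum: np.ndarray,
    measured_t: float,
    target_t: float | None = None,
) -> np.ndarray:
    """Standardize one spectrum from its measured temperature to a target.

    Scores are estimated against the modelled loadings at the measured
    temperature; the out-of-plane residual is preserved unchanged, so the
    transform only moves the K-factor part of the spectrum.
    """
    target_t = model.t_target if target_t is None else float(target_t)
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size != len(model.axis):
        raise PipelineError(
            f"spectrum length {x.size} does not match model axis length {len(model.axis)}"
        )
    if measured_t == target_t:
        return x.copy()
    P_m = loading_matrix_at(model, measured_t)
    PtP = P_m.T @ P_m
    if np.linalg.cond(PtP) > CONDITION_LIMIT:
        raise ConditioningError(
            f"loading matrix at {measured_t} degC is numerically singular"
        )
    scores = np.linalg.solve(PtP, P_m.T @ x)
    residual = x - P_m @ scores
    P_t = loading_matrix_at(model, target_t)
    return P_t @ scores + residual


def apply_lss_dataset(
    model: LSSModel,
    dataset: SpectralDataset,
    target_t: float | None = None,
) -> SpectralDataset:
    """Standardize every spectrum using its own metadata temperature.

    The preprocessing tag is extended with ``:lss{target}`` so downstream
    models can verify they were trained on equivalently treated data.
    """
    target_t = model.t_target if target_t is None else float(target_t)
    if dataset.preprocessing != model.preprocessing_tag:
        raise PipelineError(
            f"dataset tag {dataset.preprocessing!r} does not match the tag the "
            f"model was fitted on ({model.preprocessing_tag!r})"
        )
    if dataset.axis != model.axis:
        raise PipelineError("dataset axis does not match model axis")
    out = np.empty_like(dataset.intensities)
    temps = dataset.temperatures
    for t in np.unique(temps):
        rows = np.flatnonzero(temps == t)
        if t == target_t:
            out[rows] = dataset.intensities[rows]
            continue
        P_m = loading_matrix_at(model, float(t))
        PtP = P_m.T @ P_m
        if np.linalg.cond(PtP) > CONDITION_LIMIT:
            raise ConditioningError(
                f"loading matrix at {t} degC is numerically singular"
            )
        scores = np.linalg.solve(PtP, P_m.T @ dataset.intensities[rows].T)  # (K, n)
        residual = dataset.intensities[rows] - (P_m @ scores).T
        P_t = loading_matrix_at(model, target_t)
        out[rows] = (P_t @ scores).T + residual
    return SpectralDataset(
        axis=dataset.axis,
        intensities=out,
        meta=list(dataset.meta),
        preprocessing=f"{dataset.preprocessing}:lss{target_t:g}",
    )
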