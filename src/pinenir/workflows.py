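"""End-to-end workflows: PLS quantification of lipid parameters, PLS-DA
species discrimination from spectra, and PLS-DA on replicate-level chemical
values — each following the same protocol: constrained 70/30 split, grid
search by leave-one-sample-out CV on the calibration rows only, then a
single projection of the untouched validation rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (DEFAULT_CLASS_ORDER, PLSDAModel, PLSModel,
                           Provenance, fit_pls1, fit_plsda, predict_pls,
                           predict_plsda)
from .metrics import (ConfusionMatrix, RegressionReport, confusion, r_squared,
                      rer, rmse)
from .model_selection import (SearchResult, SplitPlan, cross_validate,
                              grid_search, make_split)
from .preprocess import (Autoscale, FittedPreprocessor, PreprocessSpec,
                         apply_stateless, fit_apply)
from .spectra_io import PARAMETERS, SpectraSet, subset_regions

__all__ = ["run_calibrate", "run_discriminate", "run_discriminate_chemical",
           "extract_coefficients", "CalibrationResult", "DiscriminationResult",
           "ChemicalDiscriminationResult"]


def _param_seed(seed: int, idx: int) -> int:
    return (int(seed) * 1009 + 7 * idx + 1) % (2 ** 31)


@dataclass
class CalibrationResult:
    reports: list[RegressionReport]
    models: dict[str, PLSModel]
    splits: dict[str, SplitPlan]
    searches: dict[str, SearchResult]
    skipped: list[str] = field(default_factory=list)


def run_calibrate(s: SpectraSet, parameters: list[str] | None = None,
                  seed: int = 0, region_combos=None, specs=None,
                  max_lv: int = 10,
                  group_replicates: bool = False) -> CalibrationResult:
    """Calibrate a PLS model per reference parameter.

    For each parameter: range-constrained 70/30 split (re-drawn per
    parameter, since the constraint is parameter-specific) -> grid search
    over region combinations and preprocessing pipelines on the calibration
    rows -> final fit at the winning (combo, preprocessing, LV) -> one
    projection of the validation rows. The report row carries RMSEC,
    RMSECV, RMSEP, R2 of calibration and prediction, and the range error
    ratio computed over the parameter's full reference range.
    """
    if s.reference is None:
        raise ValueError("calibration needs a reference table")
    requested = list(parameters) if parameters is not None else list(PARAMETERS)

    res = CalibrationResult([], {}, {}, {})
    for idx, param in enumerate(requested):
        if param not in s.reference.columns:
            warnings.warn(f"reference table lacks {param!r}; skipped", stacklevel=2)
            res.skipped.append(param)
            continue
        split = make_split(s, "regression", param, seed=_param_seed(seed, idx),
                           group_replicates=group_replicates)
        cal_rows, val_rows = split.rows(s)
        search = grid_search(s, cal_rows, "regression", param,
                             region_combos=region_combos, specs=specs,
                             max_lv=max_lv)

        sub = subset_regions(s, search.best_combo)
        Xcal = apply_stateless(search.best_spec, sub.absorbance[cal_rows],
                               sub.block_boundaries)
        Xval = apply_stateless(search.best_spec, sub.absorbance[val_rows],
                               sub.block_boundaries)
        y = s.reference_values(param)
        prov = Provenance(search.best_combo, search.best_spec.label(), param)
        model = fit_pls1(Xcal, y[cal_rows], search.best_n_lv, provenance=prov)

        y_cal_hat = predict_pls(model, Xcal)
        y_val_hat = predict_pls(model, Xval)
        y_min = float(np.min(y))
        y_max = float(np.max(y))
        rmsep = rmse(y[val_rows], y_val_hat)
        res.reports.append(RegressionReport(
            parameter=param, n_lv=model.n_lv, region_combo=search.best_combo,
            preprocess=search.best_spec.label(),
            rmsec=rmse(y[cal_rows], y_cal_hat), rmsecv=search.criterion,
            rmsep=rmsep, r2_c=r_squared(y[cal_rows], y_cal_hat),
            r2_p=r_squared(y[val_rows], y_val_hat),
            rer=rer(y_max, y_min, rmsep)))
        res.models[param] = model
        res.splits[param] = split
        res.searches[param] = search
    return res


@dataclass
class DiscriminationResult:
    confusion: ConfusionMatrix
    model: PLSDAModel
    split: SplitPlan
    search: SearchResult
    coefficients: pd.DataFrame


def run_discriminate(s: SpectraSet, seed: int = 0, region_combos=None,
                     specs=None, max_lv: int = 10,
                     group_replicates: bool = False,
                     class_labels=DEFAULT_CLASS_ORDER) -> DiscriminationResult:
    """Discriminate species from spectra: proportional split, grid search on
    calibration CV percent-correct, final PLS-DA, validation confusion
    matrix, and the per-wavenumber regression-coefficient vectors."""
    if s.species is None:
        raise ValueError("discrimination needs species labels")
    split = make_split(s, "discrimination", seed=seed,
                       group_replicates=group_replicates)
    cal_rows, val_rows = split.rows(s)
    present = set(s.species[cal_rows])
    missing = [c for c in class_labels if c in set(s.species) and c not in present]
    if missing:
        raise ValueError(f"species absent from calibration: {missing}")

    search = grid_search(s, cal_rows, "discrimination",
                         region_combos=region_combos, specs=specs,
                         max_lv=max_lv, class_labels=class_labels)
    sub = subset_regions(s, search.best_combo)
    Xcal = apply_stateless(search.best_spec, sub.absorbance[cal_rows],
                           sub.block_boundaries)
    Xval = apply_stateless(search.best_spec, sub.absorbance[val_rows],
                           sub.block_boundaries)
    prov = Provenance(search.best_combo, search.best_spec.label(), "species")
    model = fit_plsda(Xcal, s.species[cal_rows], search.best_n_lv,
                      class_labels, provenance=prov)
    cm = confusion(s.species[val_rows], predict_plsda(model, Xval),
                   [c for c in class_labels if c in set(s.species)])
    coef = extract_coefficients(model, sub.wavenumbers)
    return DiscriminationResult(cm, model, split, search, coef)


@dataclass
class ChemicalDiscriminationResult:
    confusion: ConfusionMatrix
    model: PLSDAModel
    split: SplitPlan
    chosen_n_lv: int
    parameter_ranking: list[str]
    coefficient_magnitudes: pd.Series
    preprocessor: FittedPreprocessor

    @property
    def top_parameter(self) -> str:
        return self.parameter_ranking[0]


def run_discriminate_chemical(s: SpectraSet,
                              chemical: pd.DataFrame | None = None,
                              seed: int = 0, max_lv: int = 10,
                              group_replicates: bool = False,
                              class_labels=DEFAULT_CLASS_ORDER
                              ) -> ChemicalDiscriminationResult:
    """PLS-DA on the replicate-level chemical-value matrix.

    The chemical matrix has one row per spectrum (replicate assay values
    are used directly, not averaged); it is autoscaled on the calibration
    rows and the latent-variable count is chosen by leave-one-sample-out
    CV. No region or preprocessing grid applies. The regression-coefficient
    magnitudes (L2 norm across class columns, on the autoscaled predictors)
    rank the parameters by discriminative influence.
    """
    if s.species is None:
        raise ValueError("discrimination needs species labels")
    if chemical is None:
        if s.reference is None:
            raise ValueError("no chemical table and no reference values")
        chemical = s.reference.reindex(s.sample_id).set_axis(
            pd.Index(s.spectrum_id, name="spectrum_id"))
    if chemical.shape[1] < 2:
        raise ValueError("chemical discrimination needs >= 2 parameters")
    chemical = chemical.reindex([str(i) for i in s.spectrum_id])
    if chemical.isna().any().any():
        raise ValueError("chemical table does not cover every spectrum")
    X = chemical.to_numpy(float)

    split = make_split(s, "discrimination", seed=seed,
                       group_replicates=group_replicates)
    cal_rows, val_rows = split.rows(s)

    spec = PreprocessSpec((Autoscale(),))
    cv = cross_validate(X[cal_rows], s.species[cal_rows], s.sample_id[cal_rows],
                        spec, max_lv=min(max_lv, X.shape[1]),
                        mode="discrimination", class_labels=class_labels)
    fp, Xcal, Xval = fit_apply(spec, X[cal_rows], X[val_rows])
    prov = Provenance((), "autoscale", "species")
    model = fit_plsda(Xcal, s.species[cal_rows], cv.chosen_n_lv,
                      class_labels, provenance=prov)
    cm = confusion(s.species[val_rows], predict_plsda(model, Xval),
                   [c for c in class_labels if c in set(s.species)])
    mag = pd.Series(np.linalg.norm(model.B, axis=1), index=chemical.columns,
                    name="coefficient_magnitude")
    ranking = list(mag.sort_values(ascending=False, kind="mergesort").index)
    return ChemicalDiscriminationResult(cm, model, split, cv.chosen_n_lv,
                                        ranking, mag, fp)


def extract_coefficients(model: PLSModel | PLSDAModel,
                         wavenumbers: np.ndarray) -> pd.DataFrame:
    """Per-wavenumber regression coefficients of a fitted model.

    Returns a DataFrame with a ``wavenumber`` column and one coefficient
    column per response (``coefficient`` for PLS1, ``coefficient_<class>``
    per class for PLS-DA). Rows follow the model's retained columns, so
    gaps between region blocks are explicit in the wavenumber sequence.
    """
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if isinstance(model, PLSDAModel):
        if wavenumbers.size != model.B.shape[0]:
            raise ValueError("wavenumber grid does not match model width")
        df = pd.DataFrame({"wavenumber": wavenumbers})
        for j, c in enumerate(model.class_labels):
            df[f"coefficient_{c}"] = model.B[:, j]
        return df
    if wavenumbers.size != model.b.size:
        raise ValueError("wavenumber grid does not match model width")
    return pd.DataFrame({"wavenumber": wavenumbers, "coefficient": model.b})


def top_coefficient_wavenumbers(coef: pd.DataFrame, n: int = 5) -> np.ndarray:
    """Wavenumbers of the ``n`` largest coefficient magnitudes (L2 across
    response columns for multi-response models)."""
    cols = [c for c in coef.columns if c.startswith("coefficient")]
    mag = np.linalg.norm(coef[cols].to_numpy(float), axis=1)
    order = np.argsort(mag)[::-1][:n]
    return coef["wavenumber"].to_numpy(float)[order]
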