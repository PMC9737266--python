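"""Model-optimization protocol: constrained 70/30 calibration/validation
splits, leave-one-sample-out cross-validation, and exhaustive grid search
over spectral-region combinations x preprocessing pipelines x latent
variables.

Protocol notes
--------------
* Splits are drawn at the *spectrum* level by default, so replicates of one
  sample may straddle calibration and validation (this reproduces the
  protocol reference counts — 33/4/4 calibration spectra from 48/6/6 — which
  are not divisible by 3). ``group_replicates=True`` gives the leakage-safe
  sample-level variant.
* Regression splits are rejection-resampled until every validation value of
  the target parameter lies inside the calibration range; discrimination
  splits take ``floor(0.7 * n)`` spectra per class.
* Cross-validation folds group by sample: each fold holds out all
  calibration-resident replicate spectra of one sample. Column statistics
  (centering/autoscaling) are refit inside every fold; the row-wise
  operators (SNV, Savitzky-Golay) use no cross-spectrum information and are
  applied once up front.
* Selection: lowest RMSECV, then lowest RMSEC, then fewer LVs, then fewer
  regions, then grid order (regression); highest CV percent-correct with the
  mirrored tiebreaks (discrimination). The validation set is never touched
  during the search.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import (DEFAULT_CLASS_ORDER, fit_pls1, fit_plsda,
                           plsda_scores, predict_pls, predict_plsda)
from .metrics import rmse
from .preprocess import (DEFAULT_SPEC_GRID, PreprocessSpec, apply_stateless,
                         fit_apply)
from .spectra_io import REGION_NAMES, SpectraSet, subset_regions

__all__ = ["SplitPlan", "make_split", "CVResult", "cross_validate",
           "SearchResult", "grid_search", "all_region_combos"]

MAX_SPLIT_DRAWS = 10_000


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    calibration_ids: tuple
    validation_ids: tuple
    seed: int
    mode: str  # "regression" | "discrimination"
    parameter: str | None = None

    def rows(self, s: SpectraSet) -> tuple[np.ndarray, np.ndarray]:
        pos = {sid: i for i, sid in enumerate(s.spectrum_id)}
        cal = np.asarray([pos[i] for i in self.calibration_ids], dtype=int)
        val = np.asarray([pos[i] for i in self.validation_ids], dtype=int)
        return cal, val


def _range_ok(y_cal: np.ndarray, y_val: np.ndarray) -> bool:
    return bool(y_val.min() >= y_cal.min() and y_val.max() <= y_cal.max())


def make_split(s: SpectraSet, mode: str, parameter: str | None = None,
               seed: int = 0, cal_fraction: float = 0.7,
               group_replicates: bool = False) -> SplitPlan:
    """Random 70/30 calibration/validation split with the protocol constraints.

    ``mode="discrimination"``: per-class proportional split,
    ``floor(cal_fraction * n_class)`` units into calibration.
    ``mode="regression"``: rejection-resampling (up to 10,000 draws) until
    validation values of ``parameter`` lie within the calibration range;
    if that fails, the units holding the global min and max are forced into
    calibration and the rest resampled.
    """
    if mode not in ("regression", "discrimination"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)

    if group_replicates:
        units = np.asarray(s.samples(), dtype=object)
    else:
        units = s.spectrum_id
    n = units.size

    def expand(chosen_units) -> tuple:
        if not group_replicates:
            return tuple(chosen_units)
        mask = np.isin(s.sample_id, list(chosen_units))
        return tuple(s.spectrum_id[mask])

    if mode == "discrimination":
        if s.species is None:
            raise ValueError("discrimination split needs species labels")
        if group_replicates:
            sp = pd.Series(s.species, index=s.sample_id).groupby(level=0).first()
            unit_species = sp.reindex(units).to_numpy(object)
        else:
            unit_species = s.species
        cal_units: list = []
        for cls in dict.fromkeys(unit_species):
            members = units[unit_species == cls]
            k = int(np.floor(cal_fraction * members.size))
            perm = rng.permutation(members.size)
            cal_units.extend(members[perm[:k]])
        cal_set = set(cal_units)
        val_units = [u for u in units if u not in cal_set]
        return SplitPlan(expand(cal_units), expand(val_units), seed, mode)

    # regression
    if parameter is None:
        raise ValueError("regression split needs a target parameter")
    if group_replicates:
        y_unit = s.reference[parameter].reindex(units).to_numpy(float)
    else:
        y_unit = s.reference_values(parameter)
    n_cal = int(np.floor(cal_fraction * n))
    if n_cal < 2 or n - n_cal < 1:
        raise ValueError(f"cannot split {n} units at fraction {cal_fraction}")

    for _ in range(MAX_SPLIT_DRAWS):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        if _range_ok(y_unit[cal], y_unit[val]):
            return SplitPlan(expand(units[cal]), expand(units[val]),
                             seed, mode, parameter)
    # fallback: force extreme-value units into calibration, resample the rest
    forced = np.asarray([int(np.argmin(y_unit)), int(np.argmax(y_unit))])
    forced = np.unique(forced)
    rest = np.setdiff1d(np.arange(n), forced)
    k = n_cal - forced.size
    for _ in range(MAX_SPLIT_DRAWS):
        perm = rng.permutation(rest.size)
        cal = np.concatenate([forced, rest[perm[:k]]])
        val = rest[perm[k:]]
        if _range_ok(y_unit[cal], y_unit[val]):
            return SplitPlan(expand(units[cal]), expand(units[val]),
                             seed, mode, parameter)
    raise ValueError(
        f"range-constrained split unsatisfiable for parameter {parameter!r}")


# ---------------------------------------------------------------------------
# Leave-one-sample-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    curve: np.ndarray          # RMSECV (regression) or %correct per LV, index k-1
    chosen_n_lv: int
    mode: str
    null_score: float | None = None  # 0-LV RMSECV (mean-only predictor)

    @property
    def best_score(self) -> float:
        return float(self.curve[self.chosen_n_lv - 1])


def _truncated_max_lv(max_lv: int, n_rows: int, n_cols: int) -> int:
    # per-fold training rank bound: min(n_fold_rows - 1, p)
    cap = max(1, min(n_rows - 1, n_cols))
    if max_lv > cap:
        warnings.warn(f"max_lv={max_lv} exceeds feasible rank {cap}; truncated",
                      stacklevel=3)
        return cap
    return max_lv


def cross_validate(X: np.ndarray, y_or_labels, sample_ids,
                   spec: PreprocessSpec, max_lv: int,
                   mode: str = "regression",
                   block_boundaries: tuple[int, ...] = (),
                   class_labels=DEFAULT_CLASS_ORDER) -> CVResult:
    """Leave-one-sample-out CV over LV counts 1..max_lv for one candidate.

    Folds are the distinct ``sample_ids``; each fold leaves out every
    replicate spectrum of one sample. Returns the per-LV pooled RMSECV
    (regression) or percent-correct (discrimination) and the chosen LV
    (optimum; ties resolve to the smallest LV).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sample_ids = np.asarray(sample_ids, dtype=object)
    folds = list(dict.fromkeys(sample_ids))
    if len(folds) < 3:
        raise ValueError("cross-validation needs >= 3 distinct samples")
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")

    # Row-wise operators use no cross-spectrum statistics: apply once.
    Xs = apply_stateless(spec, X, block_boundaries)
    tail_spec = PreprocessSpec(
        (spec.stateful_step(),) if spec.stateful_step() else ())

    min_fold_train = min(sample_ids.size - int(np.sum(sample_ids == f))
                         for f in folds)
    max_lv = _truncated_max_lv(max_lv, min_fold_train, Xs.shape[1])

    if mode == "regression":
        y = np.asarray(y_or_labels, dtype=float).ravel()
        pred = np.zeros((max_lv, y.size))
        pred0 = np.zeros(y.size)
        for f in folds:
            out = sample_ids == f
            _, Xtr, Xte = fit_apply(tail_spec, Xs[~out], Xs[out])
            if Xte is None:
                Xte = Xs[out]
            m = fit_pls1(Xtr, y[~out], max_lv)
            pred0[out] = m.y_mean
            for k in range(1, max_lv + 1):
                kk = min(k, m.n_lv)
                pred[k - 1, out] = predict_pls(m, Xte, kk)
        curve = np.asarray([rmse(y, pred[k]) for k in range(max_lv)])
        chosen = int(np.argmin(curve)) + 1
        return CVResult(curve, chosen, mode, null_score=rmse(y, pred0))

    if mode != "discrimination":
        raise ValueError(f"unknown CV mode {mode!r}")
    labels = np.asarray(y_or_labels, dtype=object)
    correct = np.zeros(max_lv)
    for f in folds:
        out = sample_ids == f
        if len(set(labels[~out])) < 2:
            continue  # fold would leave a single-class training set
        _, Xtr, Xte = fit_apply(tail_spec, Xs[~out], Xs[out])
        if Xte is None:
            Xte = Xs[out]
        m = fit_plsda(Xtr, labels[~out], max_lv, class_labels)
        for k in range(1, max_lv + 1):
            kk = min(k, m.n_lv)
            scores = plsda_scores(m, Xte, kk)
            idx = np.argmax(scores, axis=1)
            hit = np.asarray([class_labels[i] for i in idx], object) == labels[out]
            correct[k - 1] += int(hit.sum())
    curve = 100.0 * correct / labels.size
    chosen = int(np.argmax(curve)) + 1
    return CVResult(curve, chosen, mode)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def all_region_combos() -> list[tuple[str, ...]]:
    """All 31 non-empty subsets of the five regions, smallest first."""
    out: list[tuple[str, ...]] = []
    for r in range(1, len(REGION_NAMES) + 1):
        out.extend(itertools.combinations(REGION_NAMES, r))
    return out


@dataclass
class SearchResult:
    best_combo: tuple[str, ...]
    best_spec: PreprocessSpec
    best_n_lv: int
    criterion: float                 # RMSECV or CV %correct of the winner
    table: pd.DataFrame = field(repr=False)
    mode: str = "regression"


def grid_search(s: SpectraSet, calibration_rows: np.ndarray, mode: str,
                parameter: str | None = None,
                region_combos: list[tuple[str, ...]] | None = None,
                specs: list[PreprocessSpec | str] | None = None,
                max_lv: int = 10,
                class_labels=DEFAULT_CLASS_ORDER) -> SearchResult:
    """Exhaustive search over (region combo x preprocessing) candidates.

    Each candidate is scored by leave-one-sample-out CV on the calibration
    rows only; the validation rows of the enclosing split are never seen.
    """
    if region_combos is None:
        region_combos = all_region_combos()
    if specs is None:
        specs = list(DEFAULT_SPEC_GRID)
    specs = [PreprocessSpec.parse(sp) if isinstance(sp, str) else sp
             for sp in specs]

    cal = s.take(np.asarray(calibration_rows))
    if mode == "regression":
        y = cal.reference_values(parameter)
    elif mode == "discrimination":
        if cal.species is None:
            raise ValueError("discrimination search needs species labels")
        y = cal.species
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    rows = []
    for ci, combo in enumerate(region_combos):
        sub = subset_regions(cal, combo)
        for si, spec in enumerate(specs):
            cv = cross_validate(sub.absorbance, y, sub.sample_id, spec,
                                max_lv, mode, sub.block_boundaries,
                                class_labels)
            Xs = _stateless(spec, sub)
            rec = {"combo": combo, "combo_label": " + ".join(combo),
                   "spec": spec, "spec_label": spec.label(),
                   "n_lv": cv.chosen_n_lv, "_combo_order": ci, "_spec_order": si,
                   "n_regions": len(combo)}
            if mode == "regression":
                m = fit_pls1(Xs, y, cv.chosen_n_lv)
                rec["rmsecv"] = cv.best_score
                rec["rmsec"] = rmse(y, predict_pls(m, Xs))
            else:
                m = fit_plsda(Xs, y, cv.chosen_n_lv, class_labels)
                hit = predict_plsda(m, Xs) == y
                rec["cv_pct_correct"] = cv.best_score
                rec["cal_pct_correct"] = 100.0 * float(np.mean(hit))
            rows.append(rec)

    table = pd.DataFrame(rows)
    if mode == "regression":
        keys = ["rmsecv", "rmsec", "n_lv", "n_regions", "_combo_order", "_spec_order"]
        ascending = [True] * 6
        crit_col = "rmsecv"
    else:
        keys = ["cv_pct_correct", "cal_pct_correct", "n_lv", "n_regions",
                "_combo_order", "_spec_order"]
        ascending = [False, False, True, True, True, True]
        crit_col = "cv_pct_correct"
    best = table.sort_values(keys, ascending=ascending, kind="mergesort").iloc[0]
    public = table.drop(columns=["_combo_order", "_spec_order"])
    return SearchResult(best_combo=tuple(best["combo"]), best_spec=best["spec"],
                        best_n_lv=int(best["n_lv"]),
                        criterion=float(best[crit_col]), table=public, mode=mode)


def _stateless(spec: PreprocessSpec, sub: SpectraSet) -> np.ndarray:
    return apply_stateless(spec, sub.absorbance, sub.block_boundaries,
                           sub.spectrum_id)
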