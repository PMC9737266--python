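"""Composable spectral preprocessing: SNV, Savitzky-Golay, centering, autoscaling.

The model-optimization grid composes at most one Savitzky-Golay filter with
an optional SNV, in that order (the convention behind labels such as
``SG(15,2,1) + SNV``), followed by mean-centering which is always applied
before latent-variable modelling. SNV and SG act row-wise and carry no
fitted state; mean-centering and autoscaling estimate column statistics on
the calibration rows only, so they are the train/apply boundary.

Savitzky-Golay filtering is applied independently within each contiguous
wavenumber block (region subsetting records block boundaries): a local
polynomial smoother must never straddle a spectral gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SNV", "SavGol", "MeanCenter", "Autoscale",
    "PreprocessSpec", "FittedPreprocessor",
    "snv", "snv_rows", "savgol_blocks", "fit_apply",
    "DEFAULT_SPEC_GRID",
]


class DegenerateSpectrumError(ValueError):
    """A spectrum with zero variance cannot be SNV-normalized."""


# ---------------------------------------------------------------------------
# Step types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNV:
    """Standard normal variate: per-spectrum (row) centering and scaling to
    unit sample standard deviation (denominator n-1). Removes multiplicative
    scatter and additive offsets."""

    def label(self) -> str:
        return "SNV"


@dataclass(frozen=True)
class SavGol:
    """Savitzky-Golay filter: ``width``-point moving window, local polynomial
    of order ``polyorder``, returning the ``deriv``-th derivative with
    respect to sample index (the constant grid step makes this proportional
    to the derivative in cm^-1)."""

    width: int
    polyorder: int = 2
    deriv: int = 0

    def __post_init__(self):
        if self.width % 2 == 0 or self.width <= self.polyorder:
            raise ValueError(
                f"SG width must be odd and > polyorder; got ({self.width}, {self.polyorder})")
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("SG derivative order must be <= polynomial order")

    def label(self) -> str:
        return f"SG({self.width},{self.polyorder},{self.deriv})"


@dataclass(frozen=True)
class MeanCenter:
    """Column-wise centering; statistics fitted on calibration rows only."""

    def label(self) -> str:
        return "MC"


@dataclass(frozen=True)
class Autoscale:
    """Column-wise centering and scaling to unit sample sd (fitted state)."""

    def label(self) -> str:
        return "AS"


_STATEFUL = (MeanCenter, Autoscale)


@dataclass(frozen=True)
class PreprocessSpec:
    """Ordered pipeline of spectral operators.

    Stateless steps (SNV, SavGol) may appear in any order; MeanCenter or
    Autoscale, if present, must come last — they are the only steps with
    fitted (calibration-derived) state.
    """

    steps: tuple = ()

    def __post_init__(self):
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        for i, st in enumerate(steps):
            if isinstance(st, _STATEFUL) and i != len(steps) - 1:
                raise ValueError("MeanCenter/Autoscale must be the last step")

    # -- the serialization the reports use: "SG(15,2,1) + SNV", "none" -----
    def label(self) -> str:
        stateless = [s.label() for s in self.steps if not isinstance(s, _STATEFUL)]
        return " + ".join(stateless) if stateless else "none"

    def __str__(self) -> str:
        parts = [s.label() for s in self.steps]
        return " + ".join(parts) if parts else "none"

    @classmethod
    def parse(cls, text: str) -> "PreprocessSpec":
        """Parse labels like ``"SG(15,2,1) + SNV"``, ``"snv"``, ``"none"``.

        Case-insensitive; ``+`` separates steps; ``MC``/``mean center`` and
        ``AS``/``autoscale`` are accepted for the fitted steps.
        """
        text = text.strip()
        if not text or text.lower() == "none":
            return cls(())
        steps: list = []
        for part in text.split("+"):
            tok = part.strip().lower().replace(" ", "")
            if tok == "snv":
                steps.append(SNV())
            elif tok in ("mc", "meancenter", "meancentered", "meancentre"):
                steps.append(MeanCenter())
            elif tok in ("as", "autoscale", "autoscaled"):
                steps.append(Autoscale())
            else:
                m = re.fullmatch(r"sg\((\d+),(\d+),(\d+)\)", tok)
                if not m:
                    raise ValueError(f"cannot parse preprocessing step {part.strip()!r}")
                steps.append(SavGol(int(m[1]), int(m[2]), int(m[3])))
        return cls(tuple(steps))

    def stateless_steps(self) -> tuple:
        return tuple(s for s in self.steps if not isinstance(s, _STATEFUL))

    def stateful_step(self):
        tail = [s for s in self.steps if isinstance(s, _STATEFUL)]
        return tail[0] if tail else None


# The six preprocessing labels exercised during model search (beyond the
# always-applied mean-centering of the modelling step itself).
DEFAULT_SPEC_GRID: tuple[str, ...] = (
    "none",
    "SNV",
    "SG(15,2,1)",
    "SG(15,2,0) + SNV",
    "SG(15,2,1) + SNV",
    "SG(15,2,2) + SNV",
)


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def snv(x: np.ndarray) -> np.ndarray:
    """SNV-transform a single spectrum to mean 0, sample sd 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("zero-variance spectrum in SNV")
    return (x - x.mean()) / sd


def snv_rows(X: np.ndarray, spectrum_id=None) -> np.ndarray:
    """Row-wise SNV over the full (concatenated-region) vector of each spectrum."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = spectrum_id[bad[0]] if spectrum_id is not None else f"row {bad[0]}"
        raise DegenerateSpectrumError(f"zero-variance spectrum in SNV: {name}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def savgol_blocks(X: np.ndarray, step: SavGol,
                  block_boundaries: tuple[int, ...] = ()) -> np.ndarray:
    """Apply a Savitzky-Golay filter per contiguous block of columns.

    Edge points are evaluated from the least-squares polynomial fitted over
    the nearest full window, so output width equals input width and the
    filter is exact on polynomials of degree <= polyorder everywhere.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X)
    start = 0
    for end in list(block_boundaries) + [X.shape[1]]:
        width = end - start
        if width < step.width:
            raise ValueError(
                f"region block of {width} columns (cols {start}:{end}) shorter "
                f"than SG window {step.width}")
        out[:, start:end] = savgol_filter(
            X[:, start:end], window_length=step.width, polyorder=step.polyorder,
            deriv=step.deriv, delta=1.0, axis=1, mode="interp")
        start = end
    return out


def apply_stateless(spec: PreprocessSpec, X: np.ndarray,
                    block_boundaries: tuple[int, ...] = (),
                    spectrum_id=None) -> np.ndarray:
    """Apply the row-wise (unfitted) steps of ``spec`` in order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    for st in spec.stateless_steps():
        if isinstance(st, SNV):
            X = snv_rows(X, spectrum_id)
        elif isinstance(st, SavGol):
            X = savgol_blocks(X, st, block_boundaries)
        else:  # pragma: no cover - guarded by PreprocessSpec
            raise TypeError(st)
    return X


@dataclass
class FittedPreprocessor:
    """A PreprocessSpec plus the column statistics estimated on calibration
    rows (means for MeanCenter/Autoscale, sds for Autoscale)."""

    spec: PreprocessSpec
    block_boundaries: tuple[int, ...] = field(default_factory=tuple)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def transform(self, X: np.ndarray, spectrum_id=None) -> np.ndarray:
        X = apply_stateless(self.spec, X, self.block_boundaries, spectrum_id)
        if self.column_means is not None:
            if X.shape[1] != self.column_means.size:
                raise ValueError("column count does not match fitted statistics")
            X = X - self.column_means
        if self.column_sds is not None:
            X = X / self.column_sds
        return X


def fit_apply(spec: PreprocessSpec, X_cal: np.ndarray,
              X_new: np.ndarray | None = None,
              block_boundaries: tuple[int, ...] = (),
              cal_ids=None, new_ids=None):
    """Fit ``spec`` on calibration spectra and apply it to both sets.

    Stateless steps are applied row-wise to each set identically; column
    statistics (MeanCenter/Autoscale) are estimated from the transformed
    calibration rows only and applied to both — new data is scaled by the
    calibration sds, never its own.

    Returns ``(FittedPreprocessor, X_cal_t, X_new_t)`` (``X_new_t`` is None
    when no new data was given).
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    if X_cal.shape[0] == 0:
        raise ValueError("empty calibration matrix")
    Xc = apply_stateless(spec, X_cal, block_boundaries, cal_ids)
    fp = FittedPreprocessor(spec=spec, block_boundaries=tuple(block_boundaries))
    tail = spec.stateful_step()
    if tail is not None:
        fp.column_means = Xc.mean(axis=0)
        Xc = Xc - fp.column_means
        if isinstance(tail, Autoscale):
            sds = np.atleast_2d(Xc).std(axis=0, ddof=1)
            if np.any(sds == 0):
                j = int(np.flatnonzero(sds == 0)[0])
                raise ValueError(f"zero-variance column {j} under autoscaling")
            fp.column_sds = sds
            Xc = Xc / sds
    Xn = None
    if X_new is not None and np.asarray(X_new).size:
        Xn = fp.transform(np.atleast_2d(np.asarray(X_new, float)), new_ids)
    return fp, Xc, Xn
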