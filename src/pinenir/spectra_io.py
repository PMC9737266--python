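"""Reading, writing, validation and spectral-region subsetting of NIR spectra.

The data model mirrors a bench FT-NIR acquisition of ground seed samples:
reflectance-derived absorbance spectra on a fixed wavenumber grid
(10,000 -> 4,000 cm^-1 at 8 cm^-1 steps), each sample measured in
triplicate, with per-sample wet-chemistry reference values (total fat,
fatty-acid profile, vitamin E) and a species label.

On disk a :class:`SpectraSet` is a triple of plain CSV files:

* spectra:   header ``wavenumber,<spectrum_id_1>,...``; one column per spectrum
* metadata:  columns ``spectrum_id,sample_id,replicate,species``
* reference: ``sample_id,<parameter>,...`` (one row per sample)

A minimal JCAMP-DX reader (single ``##XYDATA=(X++(Y..Y))`` block) is
provided for instrument exports; output is always CSV.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "REGIONS",
    "REGION_NAMES",
    "TABLE_RANGES",
    "PARAMETERS",
    "FATTY_ACID_FAMILIES",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "read_jcamp",
    "subset_regions",
    "validate_reference",
]

# Spectral regions (cm^-1, inclusive bounds) used throughout model search.
# R1/R3 cover the informative C-H combination/first-overtone intervals;
# R2/R4 contain the strong water bands; R5 the noisy second-overtone end.
REGIONS: dict[str, tuple[float, float]] = {
    "R1": (4016.0, 4961.0),
    "R2": (4964.0, 5423.0),
    "R3": (5427.0, 6079.0),
    "R4": (6083.0, 7776.0),
    "R5": (7780.0, 9975.0),
}
REGION_NAMES: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")

# Observed min/max of each reference parameter across the 20-sample seed set.
# Units: total fat g/100 g; fatty acids relative %; vitamin E mg/kg of seeds.
TABLE_RANGES: dict[str, tuple[float, float]] = {
    "TotalFat": (13.6, 33.7),
    "C14:0": (0.0406, 0.0796),
    "C16:0": (5.20, 5.64),
    "C16:1": (0.0552, 0.0895),
    "C17:0": (0.0607, 0.0770),
    "C18:0": (3.10, 4.08),
    "C18:1n9c": (21.7, 27.1),
    "C18:2n6c": (60.6, 64.8),
    "C18:3n3": (0.81, 1.58),
    "C20:0": (0.470, 0.639),
    "C20:1n9": (0.634, 1.02),
    "C20:2": (0.385, 0.889),
    "C22:0": (0.215, 0.319),
    "C24:0": (0.0848, 0.480),
    "SFA": (9.54, 10.3),
    "MUFA": (22.8, 27.9),
    "PUFA": (61.0, 66.2),
    "VitaminE": (125.0, 260.0),
}
PARAMETERS: tuple[str, ...] = tuple(TABLE_RANGES)

FATTY_ACID_FAMILIES: dict[str, tuple[str, ...]] = {
    "SFA": ("C14:0", "C16:0", "C17:0", "C18:0", "C20:0", "C22:0", "C24:0"),
    "MUFA": ("C16:1", "C18:1n9c", "C20:1n9"),
    "PUFA": ("C18:2n6c", "C18:3n3", "C20:2"),
}

SPECIES: tuple[str, ...] = ("Aleppo", "Maritime", "Brutia")

_GRID_RTOL = 1e-6  # relative tolerance on wavenumber-step constancy


def default_grid(start: float = 10_000.0, stop: float = 4_000.0,
                 step: float = 8.0) -> np.ndarray:
    """Descending instrument wavenumber grid (751 points by default)."""
    n = int(round((start - stop) / step)) + 1
    return start - step * np.arange(n)


class SpectraFormatError(ValueError):
    """Malformed spectra file: bad grid, missing values, shape mismatch."""


class JoinError(ValueError):
    """Spectrum identifiers do not match between files."""


@dataclass
class SpectraSet:
    """In-memory container for a set of NIR spectra plus sample metadata.

    ``absorbance`` is (n_spectra, n_wavenumbers) with wavenumbers stored
    strictly descending. ``block_boundaries`` holds the column indices at
    which a new contiguous wavenumber block starts (empty for a single
    block); region subsetting populates it so that windowed operators never
    smooth across a gap.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    spectrum_id: np.ndarray
    sample_id: np.ndarray
    replicate_idx: np.ndarray
    species: np.ndarray | None = None
    reference: pd.DataFrame | None = None
    block_boundaries: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.spectrum_id = np.asarray(self.spectrum_id, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate_idx = np.asarray(self.replicate_idx, dtype=int)
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        n, p = self.absorbance.shape
        if self.wavenumbers.shape != (p,):
            raise SpectraFormatError(
                f"wavenumber count {self.wavenumbers.size} != spectral width {p}")
        for name, arr in (("spectrum_id", self.spectrum_id),
                          ("sample_id", self.sample_id),
                          ("replicate_idx", self.replicate_idx)):
            if arr.shape != (n,):
                raise SpectraFormatError(f"{name} length {arr.size} != n_spectra {n}")
        if self.species is not None and self.species.shape != (n,):
            raise SpectraFormatError("species length mismatch")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("missing or non-finite intensities")
        d = np.diff(self.wavenumbers)
        if d.size and not np.all(d < 0):
            raise SpectraFormatError("wavenumbers not strictly descending")
        self._check_grid_regularity()
        if len(set(self.spectrum_id)) != n:
            raise SpectraFormatError("duplicate spectrum ids")
        self._check_replicate_consistency()

    def _check_grid_regularity(self) -> None:
        # Each contiguous block must have a constant step (rel tol 1e-6);
        # across block gaps the step may jump.
        for block in np.split(np.arange(self.wavenumbers.size),
                              list(self.block_boundaries)):
            if block.size < 3:
                continue
            d = np.diff(self.wavenumbers[block])
            step = d.mean()
            if np.any(np.abs(d - step) > abs(step) * _GRID_RTOL):
                raise SpectraFormatError("irregular wavenumber grid within a block")

    def _check_replicate_consistency(self) -> None:
        if self.species is not None:
            per = pd.Series(self.species, index=self.sample_id)
            if (per.groupby(level=0).nunique() > 1).any():
                raise SpectraFormatError("inconsistent species within a sample")
        if self.reference is not None:
            missing = sorted(set(self.sample_id) - set(self.reference.index))
            if missing:
                raise JoinError(f"samples without reference values: {missing}")

    # -- conveniences -------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def samples(self) -> list:
        """Distinct sample ids in order of first appearance."""
        return list(dict.fromkeys(self.sample_id))

    def rows_for_sample(self, sample: str) -> np.ndarray:
        return np.flatnonzero(self.sample_id == sample)

    def take(self, rows: np.ndarray) -> "SpectraSet":
        """Row subset (spectra); wavenumber grid unchanged."""
        rows = np.asarray(rows)
        return replace(
            self,
            absorbance=self.absorbance[rows],
            spectrum_id=self.spectrum_id[rows],
            sample_id=self.sample_id[rows],
            replicate_idx=self.replicate_idx[rows],
            species=None if self.species is None else self.species[rows],
        )

    def reference_values(self, parameter: str) -> np.ndarray:
        """Per-spectrum reference value for ``parameter`` (replicates share it)."""
        if self.reference is None:
            raise ValueError("SpectraSet carries no reference table")
        if parameter not in self.reference.columns:
            raise KeyError(f"unknown reference parameter {parameter!r}")
        return self.reference[parameter].reindex(self.sample_id).to_numpy(float)


# ---------------------------------------------------------------------------
# CSV / JCAMP input
# ---------------------------------------------------------------------------

def read_jcamp(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, str]:
    """Parse a single-block JCAMP-DX file with ``##XYDATA=(X++(Y..Y))``.

    Returns ``(x, y, title)``. Only the fixed-abscissa tabular form is
    supported; the X column of each line is the abscissa of the first Y,
    subsequent Y values advance by the implied step.
    """
    title = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    xs: list[float] = []
    ys: list[float] = []
    in_table = False
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                if key == "TITLE" and value.strip():
                    title = value.strip()
                in_table = key == "XYDATA"
                if key == "END":
                    break
                continue
            if in_table:
                fields = line.replace(",", " ").split()
                if len(fields) < 2:
                    raise SpectraFormatError(f"bad XYDATA line: {line!r}")
                row = [float(v) for v in fields]
                xs.append(row[0])
                ys.extend(row[1:])
    if not ys:
        raise SpectraFormatError(f"no XYDATA block found in {path}")
    x0 = np.asarray(xs)
    ny_per_line = len(ys) / len(xs)
    if len(xs) > 1:
        per = np.diff(x0) / round(ny_per_line)
        step = per.mean()
    else:
        step = 0.0
    x = x0[0] + step * np.arange(len(ys)) if len(ys) > 1 else x0
    return np.asarray(x, float), np.asarray(ys, float), title


def _read_spectra_table(path: str | os.PathLike) -> pd.DataFrame:
    """Spectra file -> DataFrame indexed by wavenumber, one column per spectrum."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.read(2)
    if head.startswith("##"):
        x, y, title = read_jcamp(path)
        return pd.DataFrame({title: y}, index=pd.Index(x, name="wavenumber"))
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectraFormatError("spectra CSV needs wavenumber + >=1 spectrum column")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(float)
    df.index.name = "wavenumber"
    return df


def read_spectra(spectra_path: str | os.PathLike,
                 metadata_path: str | os.PathLike,
                 reference_path: str | os.PathLike | None = None) -> SpectraSet:
    """Load and join a spectra file with its metadata (and optional reference).

    The join between spectra columns and metadata rows must be exact; any
    orphan identifier on either side raises :class:`JoinError` naming it.
    Ascending grids are flipped to the descending storage convention.
    """
    table = _read_spectra_table(spectra_path)
    meta = pd.read_csv(metadata_path, dtype={"spectrum_id": str, "sample_id": str})
    required = {"spectrum_id", "sample_id", "replicate"}
    if not required.issubset(meta.columns):
        raise SpectraFormatError(
            f"metadata must have columns {sorted(required)}; got {list(meta.columns)}")

    spec_ids = [str(c) for c in table.columns]
    meta_ids = meta["spectrum_id"].astype(str).tolist()
    only_spectra = sorted(set(spec_ids) - set(meta_ids))
    only_meta = sorted(set(meta_ids) - set(spec_ids))
    if only_spectra or only_meta:
        raise JoinError(
            "spectrum id mismatch between spectra and metadata files; "
            f"only in spectra: {only_spectra}; only in metadata: {only_meta}")
    meta = meta.set_index(meta["spectrum_id"].astype(str)).loc[spec_ids]

    wn = table.index.to_numpy(float)
    X = table.to_numpy(float).T  # rows = spectra
    if wn.size > 1 and wn[1] > wn[0]:  # ascending file -> flip
        wn = wn[::-1]
        X = X[:, ::-1]

    species = None
    if "species" in meta.columns and meta["species"].notna().any():
        species = meta["species"].to_numpy(object)

    reference = None
    if reference_path is not None:
        reference = pd.read_csv(reference_path, dtype={"sample_id": str},
                                float_precision="round_trip")
        reference = reference.set_index("sample_id")

    return SpectraSet(
        wavenumbers=wn,
        absorbance=X,
        spectrum_id=np.asarray(spec_ids, object),
        sample_id=meta["sample_id"].to_numpy(object),
        replicate_idx=meta["replicate"].to_numpy(int),
        species=species,
        reference=reference,
    )


def write_spectra(s: SpectraSet, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write the CSV triple ``<prefix>_spectra/metadata/reference.csv``.

    Floats are written at 17 significant digits so that a read-back
    reproduces the arrays bit-for-bit. Returns the paths written.
    """
    prefix = os.fspath(out_prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    paths = {"spectra": f"{prefix}_spectra.csv", "metadata": f"{prefix}_metadata.csv"}

    buf = io.StringIO()
    header = ["wavenumber"] + [str(i) for i in s.spectrum_id]
    buf.write(",".join(header) + "\n")
    for j, wn in enumerate(s.wavenumbers):
        row = [f"{wn:.17g}"] + [f"{v:.17g}" for v in s.absorbance[:, j]]
        buf.write(",".join(row) + "\n")
    with open(paths["spectra"], "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())

    meta = pd.DataFrame({
        "spectrum_id": s.spectrum_id,
        "sample_id": s.sample_id,
        "replicate": s.replicate_idx,
        "species": s.species if s.species is not None else "",
    })
    meta.to_csv(paths["metadata"], index=False)

    if s.reference is not None:
        paths["reference"] = f"{prefix}_reference.csv"
        s.reference.to_csv(paths["reference"], index=True,
                           index_label="sample_id", float_format="%.17g")
    return paths


# ---------------------------------------------------------------------------
# Region subsetting
# ---------------------------------------------------------------------------

def _region_assignment(wavenumbers: np.ndarray) -> np.ndarray:
    """Region index (0-based) per column, -1 if outside all regions.

    A wavenumber falling in two regions (cannot happen on the 8 cm^-1
    instrument grid, but guard anyway) goes to the lower-numbered region.
    """
    out = np.full(wavenumbers.size, -1, dtype=int)
    for k in range(len(REGION_NAMES) - 1, -1, -1):
        lo, hi = REGIONS[REGION_NAMES[k]]
        out[(wavenumbers >= lo) & (wavenumbers <= hi)] = k
    return out


def subset_regions(s: SpectraSet, combo) -> SpectraSet:
    """Restrict a SpectraSet to the union of the chosen spectral regions.

    ``combo`` is a non-empty iterable of region names (``"R1"``..``"R5"``).
    Retained blocks are concatenated in descending-wavenumber order and the
    block boundaries are recorded so that windowed operators know where
    contiguity breaks.
    """
    combo = tuple(combo)
    if not combo:
        raise ValueError("region combination must be non-empty")
    bad = [r for r in combo if r not in REGIONS]
    if bad:
        raise ValueError(f"unknown region(s) {bad}; valid: {list(REGION_NAMES)}")
    chosen = sorted(set(combo), key=lambda r: REGIONS[r][1], reverse=True)

    assign = _region_assignment(s.wavenumbers)
    cols: list[np.ndarray] = []
    boundaries: list[int] = []
    total = 0
    for r in chosen:
        k = REGION_NAMES.index(r)
        block = np.flatnonzero(assign == k)
        if block.size == 0:
            continue
        # columns within a region follow storage (descending) order
        cols.append(block)
        total += block.size
        boundaries.append(total)
    if total == 0:
        raise ValueError(f"no wavenumbers fall inside regions {combo}")
    idx = np.concatenate(cols)
    return replace(
        s,
        wavenumbers=s.wavenumbers[idx],
        absorbance=s.absorbance[:, idx],
        block_boundaries=tuple(boundaries[:-1]),
    )


# ---------------------------------------------------------------------------
# Reference-table validation
# ---------------------------------------------------------------------------

def plausibility_bounds(widen: float = 0.5) -> dict[str, tuple[float, float]]:
    """Per-parameter bounds: the observed ranges widened by ``widen`` (total)."""
    out = {}
    for p, (lo, hi) in TABLE_RANGES.items():
        margin = 0.5 * widen * (hi - lo)
        out[p] = (lo - margin, hi + margin)
    return out


def validate_reference(ref: pd.DataFrame,
                       bounds: dict[str, tuple[float, float]] | None = None) -> None:
    """Check reference values against plausibility bounds and the closure
    constraint SFA+MUFA+PUFA in (90, 100] (fatty acids are relative %).

    Raises ``ValueError`` naming the offending sample/parameter.
    """
    if bounds is None:
        bounds = plausibility_bounds()
    for p in ref.columns:
        if p not in bounds:
            continue
        lo, hi = bounds[p]
        vals = ref[p].to_numpy(float)
        off = np.flatnonzero((vals < lo) | (vals > hi))
        if off.size:
            sid = ref.index[off[0]]
            raise ValueError(
                f"reference value {p}={vals[off[0]]:g} for sample {sid!r} "
                f"outside plausibility bounds [{lo:g}, {hi:g}]")
    fam = ["SFA", "MUFA", "PUFA"]
    if all(f in ref.columns for f in fam):
        total = ref[fam].sum(axis=1).to_numpy(float)
        off = np.flatnonzero((total <= 90.0) | (total > 100.0))
        if off.size:
            raise ValueError(
                f"SFA+MUFA+PUFA={total[off[0]]:.2f} for sample "
                f"{ref.index[off[0]]!r} outside (90, 100]")
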