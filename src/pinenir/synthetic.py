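"""Synthetic NIR spectra generator with ground truth.

The generator emulates the statistical structure the calibration pipeline
assumes: each sample's clean spectrum is a Beer-Lambert-style linear
mixture of Gaussian-band component signatures (oil, individual fatty
acids, vitamin E, protein, cellulose, water) on the instrument grid
(10,000 -> 4,000 cm^-1, 8 cm^-1 step), and each replicate measurement
adds multiplicative scatter, an additive linear baseline, white noise and
extra water-band variability. Band centers follow the prominent seed
absorptions: oil near 8300, 5840, 5700, 4640 and 4340 cm^-1, protein near
4860, cellulose near 4255, water inside the R2 (~5200) and R4 (~6900)
intervals.

Reference concentrations are drawn inside the observed per-parameter
ranges; fatty acids are generated as a composition (family sums SFA, MUFA,
PUFA are the sums of their constituent acids and the grand total is held in
(90, 100], since fatty acids are relative percentages). Species enter in
two ways: selected parameters (total fat, vitamin E, C14:0 by default) are
drawn from species-specific sub-windows of their global range, and the
latent cellulose level is scaled per species — so both the spectra and the
chemical values carry a recoverable species signal.

Each individual fatty acid receives a slightly band-jittered copy of the
oil signature, fixed at library creation: acids are spectroscopically
near-collinear but not identical, matching the real difficulty of
resolving them by NIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import (FATTY_ACID_FAMILIES, SPECIES, TABLE_RANGES,
                         SpectraSet, default_grid)

__all__ = ["Band", "BandLibrary", "SimulationConfig", "default_band_library",
           "signature", "simulate", "truth_table", "chemical_replicates"]

_FAMILY_OF = {a: fam for fam, acids in FATTY_ACID_FAMILIES.items() for a in acids}
FATTY_ACIDS: tuple[str, ...] = tuple(_FAMILY_OF)


@dataclass(frozen=True)
class Band:
    center: float   # cm^-1
    sigma: float    # cm^-1
    amplitude: float

    def __post_init__(self):
        if not 4000.0 <= self.center <= 10000.0:
            raise ValueError(f"band center {self.center} outside [4000, 10000]")
        if self.amplitude < 0 or self.sigma <= 0:
            raise ValueError("band amplitude must be >= 0 and sigma > 0")


def signature(bands: list[Band], grid: np.ndarray) -> np.ndarray:
    """Sum of Gaussian profiles a*exp(-(v-mu)^2/(2 sigma^2)) on the grid."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for b in bands:
        out += b.amplitude * np.exp(-((grid - b.center) ** 2) / (2.0 * b.sigma ** 2))
    return out


@dataclass
class BandLibrary:
    """Per-component Gaussian band lists plus a mixing weight per component."""
    bands: dict[str, list[Band]]
    weights: dict[str, float]

    def signature(self, component: str, grid: np.ndarray) -> np.ndarray:
        return signature(self.bands[component], grid)


_OIL_BANDS = [(8300.0, 60.0, 0.25), (5840.0, 35.0, 1.00), (5700.0, 35.0, 0.70),
              (4640.0, 25.0, 0.60), (4340.0, 20.0, 0.80)]


# Broad carbohydrate/protein matrix absorption common to every ground-seed
# spectrum: it dominates total absorbance (as the seed matrix does in real
# reflectance spectra), which keeps the per-spectrum SNV normalization
# nearly constant across samples and hence the mixture close to linear
# after scatter correction.
_MATRIX_BANDS = [(8500.0, 400.0, 0.30), (6900.0, 300.0, 0.50),
                 (5600.0, 300.0, 0.80), (4700.0, 250.0, 0.90),
                 (4300.0, 150.0, 0.70)]


def default_band_library(jitter_seed: int = 1234,
                         acid_jitter_sd: float = 0.15,
                         acid_center_jitter: float = 10.0) -> BandLibrary:
    """Band library anchored at the prominent seed absorptions.

    Each fatty acid gets the oil band set with per-band amplitude jitter
    (multiplicative, sd ``acid_jitter_sd``) and a small center shift
    (sd ``acid_center_jitter`` cm^-1), drawn once from ``jitter_seed`` so
    libraries are reproducible. The center shifts keep the acid signatures
    linearly independent (amplitude jitter alone would leave all acids in
    the span of the five oil bands, making per-acid recovery impossible
    even from noiseless spectra) while remaining strongly collinear with
    the oil signature, matching the real difficulty of resolving
    individual acids by NIR.
    """
    rng = np.random.default_rng(jitter_seed)
    bands: dict[str, list[Band]] = {
        "matrix": [Band(*t) for t in _MATRIX_BANDS],
        "oil": [Band(*t) for t in _OIL_BANDS],
        "protein": [Band(4860.0, 30.0, 1.0)],
        "cellulose": [Band(4255.0, 18.0, 1.0), Band(5400.0, 30.0, 0.3)],
        "water": [Band(5200.0, 60.0, 1.0), Band(6900.0, 80.0, 0.8)],
        "vitaminE": [Band(5520.0, 25.0, 1.0), Band(5410.0, 20.0, 0.6)],
    }
    for acid in FATTY_ACIDS:
        jit = []
        for c, s, a in _OIL_BANDS:
            factor = max(0.05, 1.0 + acid_jitter_sd * rng.standard_normal())
            center = float(np.clip(c + acid_center_jitter * rng.standard_normal(),
                                   4000.0, 10000.0))
            jit.append(Band(center, s, a * factor))
        bands[acid] = jit
    weights = {"matrix": 2.5, "oil": 0.80, "protein": 0.45, "cellulose": 0.35,
               "water": 0.50, "vitaminE": 0.12}
    weights.update({acid: 0.08 for acid in FATTY_ACIDS})
    return BandLibrary(bands=bands, weights=weights)


# Default species sub-windows inside the global parameter ranges: total fat
# and vitamin E are highest in Aleppo and lowest in Maritime seeds, and
# C14:0 is the discriminative acid.
DEFAULT_SPECIES_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "TotalFat": {"Aleppo": (22.0, 33.7), "Maritime": (13.6, 22.0),
                 "Brutia": (16.0, 28.0)},
    "VitaminE": {"Aleppo": (170.0, 260.0), "Maritime": (125.0, 185.0),
                 "Brutia": (140.0, 230.0)},
    "C14:0": {"Aleppo": (0.058, 0.0796), "Maritime": (0.0406, 0.050),
              "Brutia": (0.048, 0.064)},
}

# Latent cellulose level multiplier per species (disjoint once combined
# with the U(0.9, 1.1) per-sample draw).
DEFAULT_CELLULOSE_SCALE: dict[str, float] = {
    "Aleppo": 1.0, "Maritime": 1.35, "Brutia": 0.75}


@dataclass
class SimulationConfig:
    """Study-design and disturbance settings for the generator.

    Defaults emulate the seed-set design: 16 Aleppo + 2 Maritime + 2 Brutia
    samples, three replicate spectra each, concentration ranges equal to
    the observed parameter ranges. All disturbance sds are in absorbance
    units except ``scatter_sd`` (log of the multiplicative factor) and the
    water replicate factor (log-scale sd).
    """
    n_per_species: dict[str, int] = field(
        default_factory=lambda: {"Aleppo": 16, "Maritime": 2, "Brutia": 2})
    replicates: int = 3
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_RANGES))
    species_windows: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_SPECIES_WINDOWS.items()})
    cellulose_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELLULOSE_SCALE))
    scatter_sd: float = 0.10          # lognormal multiplicative scatter
    baseline_offset_sd: float = 0.02  # additive constant per replicate
    baseline_slope_sd: float = 0.01   # additive linear-in-index ramp
    noise_sd: float = 0.008           # white noise per channel
    water_replicate_sd: float = 0.25  # log-scale water-amplitude variability
    seed: int = 0

    def __post_init__(self):
        for name in ("scatter_sd", "baseline_offset_sd", "baseline_slope_sd",
                     "noise_sd", "water_replicate_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for p, (lo, hi) in self.ranges.items():
            if not hi > lo:
                raise ValueError(f"empty range for {p}: ({lo}, {hi})")
        for p, wins in self.species_windows.items():
            glo, ghi = self.ranges[p]
            for sp, (lo, hi) in wins.items():
                if not (glo <= lo < hi <= ghi):
                    raise ValueError(
                        f"species window {sp}/{p} ({lo}, {hi}) outside "
                        f"global range ({glo}, {ghi})")

    def window(self, parameter: str, species: str) -> tuple[float, float]:
        wins = self.species_windows.get(parameter)
        if wins and species in wins:
            return wins[species]
        return self.ranges[parameter]


# ---------------------------------------------------------------------------
# Concentration draws
# ---------------------------------------------------------------------------

_MAX_COMPOSITION_DRAWS = 10_000


def _draw_fatty_acids(cfg: SimulationConfig, species: str,
                      rng: np.random.Generator) -> dict[str, float]:
    """Rejection-sample a consistent fatty-acid composition.

    Individual acids are uniform in their (species-windowed) ranges; the
    draw is accepted when each family sum (SFA/MUFA/PUFA) lands inside its
    own observed range and the grand total lies in (90, 100].
    """
    for _ in range(_MAX_COMPOSITION_DRAWS):
        vals = {a: rng.uniform(*cfg.window(a, species)) for a in FATTY_ACIDS}
        fams = {fam: sum(vals[a] for a in acids)
                for fam, acids in FATTY_ACID_FAMILIES.items()}
        ok = all(cfg.ranges[f][0] <= fams[f] <= cfg.ranges[f][1] for f in fams)
        total = sum(fams.values())
        if ok and 90.0 < total <= 100.0:
            vals.update(fams)
            return vals
    raise RuntimeError("fatty-acid composition constraints unsatisfiable "
                       "with the configured ranges")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(cfg: SimulationConfig | None = None,
             bands: BandLibrary | None = None) -> SpectraSet:
    """Generate a SpectraSet with a ground-truth reference table.

    Per sample: draw concentrations, build the clean mixture spectrum; per
    replicate: rescale the water contribution, apply multiplicative
    scatter, a linear baseline and white noise. Fully reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    bands = bands or default_band_library()
    rng = np.random.default_rng(cfg.seed)
    grid = default_grid()
    ramp = np.linspace(0.0, 1.0, grid.size)

    sigs = {k: bands.signature(k, grid) for k in bands.bands}

    spectra, spec_ids, sample_ids, species_col, reps = [], [], [], [], []
    ref_rows = []
    sample_no = 0
    for sp in SPECIES:
        for _ in range(cfg.n_per_species.get(sp, 0)):
            sample_no += 1
            sid = f"S{sample_no:02d}"
            conc = _draw_fatty_acids(cfg, sp, rng)
            conc["TotalFat"] = rng.uniform(*cfg.window("TotalFat", sp))
            conc["VitaminE"] = rng.uniform(*cfg.window("VitaminE", sp))
            ref_rows.append({"sample_id": sid, "species": sp, **conc})

            # normalized mixture: reference components scaled by their
            # global maximum; latent interferents ~ U around 1
            mix = {"matrix": 1.0,
                   "oil": conc["TotalFat"] / cfg.ranges["TotalFat"][1],
                   "vitaminE": conc["VitaminE"] / cfg.ranges["VitaminE"][1],
                   "protein": rng.uniform(0.8, 1.2),
                   "cellulose": rng.uniform(0.9, 1.1)
                   * (cfg.cellulose_scale or {}).get(sp, 1.0)}
            for a in FATTY_ACIDS:
                mix[a] = conc[a] / cfg.ranges[a][1]
            water_level = rng.uniform(0.9, 1.1)

            clean = np.zeros_like(grid)
            for k, c in mix.items():
                clean += bands.weights[k] * c * sigs[k]

            for r in range(1, cfg.replicates + 1):
                w = water_level * np.exp(
                    cfg.water_replicate_sd * rng.standard_normal())
                spectrum = clean + bands.weights["water"] * w * sigs["water"]
                mult = np.exp(cfg.scatter_sd * rng.standard_normal())
                offset = cfg.baseline_offset_sd * rng.standard_normal()
                slope = cfg.baseline_slope_sd * rng.standard_normal()
                noise = cfg.noise_sd * rng.standard_normal(grid.size)
                spectra.append(mult * spectrum + offset + slope * ramp + noise)
                spec_ids.append(f"{sid}r{r}")
                sample_ids.append(sid)
                species_col.append(sp)
                reps.append(r)

    reference = (pd.DataFrame(ref_rows).set_index("sample_id")
                 .drop(columns=["species"]))
    return SpectraSet(
        wavenumbers=grid,
        absorbance=np.asarray(spectra),
        spectrum_id=np.asarray(spec_ids, object),
        sample_id=np.asarray(sample_ids, object),
        replicate_idx=np.asarray(reps, int),
        species=np.asarray(species_col, object),
        reference=reference,
    )


def truth_table(s: SpectraSet) -> pd.DataFrame:
    """Ground-truth per-sample concentrations of a synthetic SpectraSet."""
    if s.reference is None:
        raise ValueError("SpectraSet carries no ground-truth reference table "
                         "(not produced by simulate?)")
    return s.reference.copy()


def chemical_replicates(s: SpectraSet, assay_rel_sd: float = 0.01,
                        seed: int = 0,
                        parameters: list[str] | None = None) -> pd.DataFrame:
    """Replicate-level chemical table: one row per spectrum.

    Emulates running the wet-chemistry reference assays in triplicate: each
    replicate row is the sample's true value perturbed by multiplicative
    assay noise with relative sd ``assay_rel_sd``.
    """
    truth = truth_table(s)
    if parameters is not None:
        truth = truth[list(parameters)]
    rng = np.random.default_rng(seed)
    base = truth.reindex(s.sample_id).to_numpy(float)
    noisy = base * (1.0 + assay_rel_sd * rng.standard_normal(base.shape))
    return pd.DataFrame(noisy, index=pd.Index(s.spectrum_id, name="spectrum_id"),
                        columns=truth.columns)
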