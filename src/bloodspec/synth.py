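"""Synthetic FT-NIR spectra of duck blood tofu (DBT) adulterated with
cow/pig blood-based gels (CBG/PBG).

The simulator emulates diffuse-reflectance absorbance spectra on the
instrument's native grid (1,557 points, 4,000-10,000 cm^-1): each species is
a sum of broad Gaussian absorption bands at the twelve key wavenumbers where
the species differ chemically, mixtures combine the pure-component
("endmember") spectra linearly by mass fraction (Beer-Lambert), and each
measured spectrum carries multiplicative/additive scatter artifacts plus
white noise, averaged over triplicate scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCompositionError

SPECIES = ("DBT", "CBG", "PBG")

#: The six sample categories of the adulteration design.
CLASS_LABELS = ("raw_dbt", "pure_cbg", "pure_pbg", "dbt_cbg", "dbt_pbg", "ternary")

#: Adulteration levels (total adulterant mass fraction, %) of the design.
LEVELS = (10, 20, 30, 40, 50)

SAMPLES_PER_CELL = 30

#: Key wavenumbers (cm^-1) where the blood species differ spectrally:
#: C-H combination/overtone bands (fat, CH/CH2/CH3), C=O and RCO2H second
#: overtones (protein backbone, sugars), S-H/C-H first overtones, aromatic
#: C-H, O-H/amide, and N-H second overtones (amino groups).
KEY_WAVENUMBERS = (
    4108.0, 4405.0, 5238.0, 5326.0, 5477.0, 5774.0,
    6241.0, 6931.0, 7189.0, 8015.0, 9399.0, 9997.0,
)

#: Gaussian sigma (cm^-1) per band; NIR bands are broad, the high-wavenumber
#: overtones broadest.
BAND_WIDTHS = (60.0, 60.0, 70.0, 70.0, 70.0, 80.0, 90.0, 100.0, 100.0, 120.0, 110.0, 90.0)

# Band amplitudes (absorbance units) per species.  Hand-set so that relative
# strengths qualitatively track measured composition contrasts: CBG is the
# fat-rich gel (strongest C-H bands at 4108/4405/5774/7189/8015), PBG is
# richest in protein and total sugars (strongest C=O/RCO2H bands at
# 5238/5326/5477 and N-H bands at 9399/9997), DBT has the highest free
# amino-acid load (strong O-H/amide band at 6931).
BAND_AMPLITUDES = {
    "DBT": (0.55, 0.50, 0.70, 0.60, 0.45, 0.40, 0.30, 0.65, 0.50, 0.35, 0.25, 0.15),
    "CBG": (0.80, 0.75, 0.55, 0.50, 0.40, 0.60, 0.35, 0.50, 0.65, 0.50, 0.18, 0.10),
    "PBG": (0.60, 0.55, 0.80, 0.70, 0.55, 0.45, 0.25, 0.55, 0.45, 0.30, 0.35, 0.22),
}

BASELINE_LEVELS = {"DBT": 0.30, "CBG": 0.25, "PBG": 0.28}

N_VARIABLES = 1557
GRID_MIN = 4000.0
GRID_MAX = 10000.0


def default_grid() -> np.ndarray:
    """The instrument wavenumber grid: 1,557 equally spaced points on
    [4000, 10000] cm^-1 (spacing ~3.856 cm^-1), ascending."""
    return np.linspace(GRID_MIN, GRID_MAX, N_VARIABLES)


@dataclass(frozen=True)
class EndmemberSet:
    """Pure-component absorption model for one species.

    ``bands`` is a sequence of (center cm^-1, Gaussian sigma cm^-1,
    amplitude AU) triples; the spectrum is the band sum plus a flat baseline.
    """

    species: str
    bands: tuple[tuple[float, float, float], ...]
    baseline_level: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        for center, width, amp in self.bands:
            if not (GRID_MIN <= center <= GRID_MAX):
                raise ValueError(f"band center {center} outside [{GRID_MIN}, {GRID_MAX}]")
            if width <= 0 or amp <= 0:
                raise ValueError("band widths and amplitudes must be positive")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance of the pure component on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        out = np.full(grid.shape, self.baseline_level, dtype=float)
        for center, width, amp in self.bands:
            out += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        return out


def default_endmembers() -> dict[str, EndmemberSet]:
    """The three default species endmembers, keyed by species code.

    All species share the twelve key band centers and widths but differ in
    amplitude at every band, so the classes are spectrally separable.
    """
    out = {}
    for sp in SPECIES:
        bands = tuple(
            (c, w, a)
            for c, w, a in zip(KEY_WAVENUMBERS, BAND_WIDTHS, BAND_AMPLITUDES[sp])
        )
        out[sp] = EndmemberSet(species=sp, bands=bands, baseline_level=BASELINE_LEVELS[sp])
    return out


def mix_spectrum(
    endmembers: dict[str, EndmemberSet],
    fractions: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Convex (Beer-Lambert) combination of the endmember spectra.

    ``fractions`` are the (f_DBT, f_CBG, f_PBG) mass fractions; they must lie
    in [0, 1] and sum to one (tolerance 1e-9).
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,):
        raise InvalidCompositionError("fractions must be a 3-vector (DBT, CBG, PBG)")
    if np.any(fractions < -1e-12) or np.any(fractions > 1 + 1e-12):
        raise InvalidCompositionError(f"fractions outside [0, 1]: {fractions}")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise InvalidCompositionError(f"fractions sum to {fractions.sum()}, not 1")
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for f, sp in zip(fractions, SPECIES):
        if f != 0.0:
            out += f * endmembers[sp].evaluate(grid)
    return out


@dataclass(frozen=True)
class ArtifactParams:
    """Measurement-artifact model: per-replicate multiplicative slope
    (log-normal around 1), additive offset, linear baseline tilt, and white
    noise, averaged over ``n_replicates`` scans.

    The slope+offset terms are exactly what multiplicative scatter correction
    models; defaults reflect a well-behaved FT-NIR instrument with 32-scan
    internal averaging.
    """

    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    tilt_sd: float = 2e-6
    noise_sd: float = 0.002
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("scatter_slope_sd", "scatter_offset_sd", "tilt_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def apply_artifacts(
    spectrum: np.ndarray,
    grid: np.ndarray,
    params: ArtifactParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate-averaged measured spectrum.

    Each replicate r is ``b_r * spectrum + a_r + t_r * (nu - mean(nu)) +
    eps_r`` with b ~ exp(N(0, scatter_slope_sd)), a ~ N(0, scatter_offset_sd),
    t ~ N(0, tilt_sd) and iid white noise eps; the output is the mean over
    replicates, reproducible given ``rng``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if (
        params.scatter_slope_sd == 0.0
        and params.scatter_offset_sd == 0.0
        and params.tilt_sd == 0.0
        and params.noise_sd == 0.0
    ):
        return spectrum.copy()  # exact identity in the degenerate-noise case
    centered_nu = grid - grid.mean()
    acc = np.zeros_like(spectrum)
    for _ in range(params.n_replicates):
        b = np.exp(rng.normal(0.0, params.scatter_slope_sd))
        a = rng.normal(0.0, params.scatter_offset_sd)
        tilt = rng.normal(0.0, params.tilt_sd)
        eps = rng.normal(0.0, params.noise_sd, size=spectrum.shape) if params.noise_sd > 0 else 0.0
        acc += b * spectrum + a + tilt * centered_nu + eps
    return acc / params.n_replicates


def classify_fractions(fractions: np.ndarray, tol: float = 1e-9) -> str:
    """Deterministic class label from (f_DBT, f_CBG, f_PBG)."""
    f_dbt, f_cbg, f_pbg = np.asarray(fractions, dtype=float)
    if f_dbt > 1 - tol:
        return "raw_dbt"
    if f_cbg > 1 - tol:
        return "pure_cbg"
    if f_pbg > 1 - tol:
        return "pure_pbg"
    if f_cbg > tol and f_pbg > tol and f_dbt > tol:
        return "ternary"
    if f_cbg > tol:
        return "dbt_cbg"
    return "dbt_pbg"


@dataclass
class SpectraSet:
    """A sample x wavenumber absorbance matrix with class labels and
    adulterant mass fractions — the currency of the whole pipeline."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    class_labels: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        self.fractions = np.asarray(self.fractions, dtype=float)
        n, p = self.absorbance.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError("wavenumber count does not match absorbance columns")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if len(self.sample_ids) != n or self.class_labels.shape != (n,):
            raise ValueError("sample_ids/class_labels length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.fractions.shape != (n, 3):
            raise ValueError("fractions must be n x 3")
        if np.any(self.fractions < -1e-12) or np.any(
            np.abs(self.fractions.sum(axis=1) - 1.0) > 1e-9
        ):
            raise InvalidCompositionError("fractions must lie on the unit simplex")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices: np.ndarray) -> "SpectraSet":
        """A new SpectraSet restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[indices].copy(),
            sample_ids=[self.sample_ids[i] for i in indices],
            class_labels=self.class_labels[indices].copy(),
            fractions=self.fractions[indices].copy(),
        )


def design_table() -> list[tuple[str, np.ndarray]]:
    """The full mixing design: (sample-id stem, fractions) per design cell,
    30 samples each — 30 raw DBT, 30 pure CBG, 30 pure PBG, 5 levels x 30 for
    each binary series, and 5 levels x 30 ternary with equal CBG/PBG split
    (540 samples in total)."""
    cells: list[tuple[str, np.ndarray]] = [
        ("DBT", np.array([1.0, 0.0, 0.0])),
        ("CBG", np.array([0.0, 1.0, 0.0])),
        ("PBG", np.array([0.0, 0.0, 1.0])),
    ]
    for lev in LEVELS:
        f = lev / 100.0
        cells.append((f"DBT-CBG{lev:02d}", np.array([1.0 - f, f, 0.0])))
    for lev in LEVELS:
        f = lev / 100.0
        cells.append((f"DBT-PBG{lev:02d}", np.array([1.0 - f, 0.0, f])))
    for lev in LEVELS:
        f = lev / 100.0
        cells.append((f"DBT-TER{lev:02d}", np.array([1.0 - f, f / 2, f / 2])))
    return cells


def generate_design(
    endmembers: dict[str, EndmemberSet] | None = None,
    params: ArtifactParams | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> SpectraSet:
    """Generate the full 540-sample adulteration design.

    Per-sample random substreams are spawned deterministically from the
    master seed by absolute design index, so subsetting the design never
    shifts other samples' spectra.
    """
    endmembers = endmembers if endmembers is not None else default_endmembers()
    params = params if params is not None else ArtifactParams()
    grid = np.asarray(grid, dtype=float) if grid is not None else default_grid()

    rows, ids, labels, fracs = [], [], [], []
    index = 0
    for stem, f in design_table():
        clean = mix_spectrum(endmembers, f, grid)
        for rep in range(SAMPLES_PER_CELL):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))
            rows.append(apply_artifacts(clean, grid, params, rng))
            ids.append(f"{stem}_s{rep:02d}")
            labels.append(classify_fractions(f))
            fracs.append(f)
            index += 1
    return SpectraSet(
        wavenumbers=grid,
        absorbance=np.vstack(rows),
        sample_ids=ids,
        class_labels=np.array(labels, dtype=object),
        fractions=np.vstack(fracs),
    )
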