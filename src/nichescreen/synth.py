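"""Synthetic landscapes with known drivers for offline testing.

Each environmental layer is a smoothed Gaussian random field (seeded white
noise passed through a Gaussian filter, then min-max rescaled to [0, 1]),
which gives realistic spatial autocorrelation without any geostatistics
machinery.  Decoy layers are built as α·source + √(1−α²)·independent-field
with the independent field orthogonalized against the source first, so the
sample correlation with the source equals the requested target exactly
(min-max rescaling is affine and preserves correlation).

The "true" habitat suitability is a logistic function of a linear
combination of a small subset of driver layers (centered so median
suitability sits near 0.5); presences are drawn without replacement from
grid cells with probability proportional to suitability, at cell centers so
extraction and thinning are exactly testable.

``benchmark_default`` mirrors the 19-variable screening scale: 19 layers,
2 drivers, 1 decoy correlated at r ≈ 0.9 with a driver, 300 presences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .rasters_io import (
    GridSpec,
    Layer,
    OccurrenceSet,
    PredictorCollection,
    write_ascii_grid,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic landscape."""

    grid: GridSpec
    n_vars: int
    driver_effects: dict[str, float]          # variable -> log-suitability slope
    decoy_correlations: dict[str, tuple[str, float]] = field(default_factory=dict)
    noise_spatial_scale: float = 5.0          # Gaussian-filter sigma, in cells
    n_presences: int = 300
    seed: int = 0
    name_prefix: str = "env"
    response: str = "logistic"                # or "loglinear" (Gibbs density)

    def __post_init__(self) -> None:
        if self.response not in ("logistic", "loglinear"):
            raise ValueError("response must be 'logistic' or 'loglinear'")
        names = set(self.variable_names)
        if not set(self.driver_effects) <= names:
            raise ValueError("driver names must be among the generated variables")
        for decoy, (source, r) in self.decoy_correlations.items():
            if decoy not in names or source not in names:
                raise ValueError("decoy and source must be among the generated variables")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"decoy target correlation {r} outside [-1, 1]")

    @property
    def variable_names(self) -> list[str]:
        return [f"{self.name_prefix}{i + 1:02d}" for i in range(self.n_vars)]

    @property
    def drivers(self) -> list[str]:
        return sorted(self.driver_effects)


@dataclass
class Truth:
    """Ground truth of a generated landscape, for assertions."""

    drivers: list[str]
    effects: dict[str, float]
    decoys: dict[str, tuple[str, float]]
    suitability: Layer


def _random_field(grid: GridSpec, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized smoothed Gaussian random field on the grid."""
    if min(grid.n_rows, grid.n_cols) <= 2 * scale:
        raise ValueError(
            f"grid ({grid.n_rows}×{grid.n_cols}) too small for smoothing scale {scale}"
        )
    z = gaussian_filter(rng.standard_normal((grid.n_rows, grid.n_cols)), sigma=scale, mode="reflect")
    z = z - z.mean()
    return z / z.std()


def _rescale01(z: np.ndarray) -> np.ndarray:
    lo, hi = z.min(), z.max()
    return (z - lo) / (hi - lo)


def make_landscape(spec: SynthSpec, directory: str | Path) -> PredictorCollection:
    """Generate the layers as ASCII grids in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = spec.variable_names
    fields: dict[str, np.ndarray] = {}
    # independent base fields first (decoys consume a source, so two passes)
    for i, name in enumerate(names):
        if name in spec.decoy_correlations:
            continue
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        fields[name] = _random_field(spec.grid, spec.noise_spatial_scale, rng)
    for i, name in enumerate(names):
        if name not in spec.decoy_correlations:
            continue
        source, r = spec.decoy_correlations[name]
        if abs(r) == 1.0:
            fields[name] = np.sign(r) * fields[source]
            continue
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i)))
        indep = _random_field(spec.grid, spec.noise_spatial_scale, rng)
        src = fields[source]
        # orthogonalize so the sample correlation is exactly r
        resid = indep - (indep.ravel() @ src.ravel()) / (src.ravel() @ src.ravel()) * src
        resid = resid - resid.mean()
        resid /= resid.std()
        fields[name] = r * src + np.sqrt(1.0 - r * r) * resid
    for name in names:
        layer = Layer(name=name, grid=spec.grid, values=_rescale01(fields[name]))
        write_ascii_grid(layer, directory / f"{name}.asc")
    collection = PredictorCollection.from_directory(directory)
    for decoy, (source, r) in spec.decoy_correlations.items():
        got = float(
            np.corrcoef(
                collection.layer(decoy).values.compressed(),
                collection.layer(source).values.compressed(),
            )[0, 1]
        )
        if abs(got - r) > 0.05:
            raise RuntimeError(
                f"decoy {decoy}: achieved correlation {got:.3f} misses target {r:.3f}"
            )
        logger.info("decoy %s ~ %s: sample r = %.4f (target %.2f)", decoy, source, got, r)
    return collection


def true_suitability(collection: PredictorCollection, spec: SynthSpec) -> Layer:
    """Suitability surface implied by the driver effects.

    ``logistic`` (default): expit of the centered linear predictor, a
    bounded habitat-suitability index.  ``loglinear``: exp of the linear
    predictor rescaled to (0, 1], i.e. a Gibbs density whose log is exactly
    linear in the drivers (useful when the true response class matters).
    """
    lin = np.zeros((spec.grid.n_rows, spec.grid.n_cols))
    for name, effect in spec.driver_effects.items():
        lin = lin + effect * collection.layer(name).values.filled(np.nan)
    if spec.response == "loglinear":
        vals = np.exp(lin - np.nanmax(lin))
    else:
        vals = expit(lin - np.nanmean(lin))  # center: median suitability near 0.5
    return Layer(name="true_suitability", grid=spec.grid, values=vals)


def sample_presences(collection: PredictorCollection, spec: SynthSpec) -> OccurrenceSet:
    """Draw presences ∝ true suitability, without replacement, at cell centers."""
    suit = true_suitability(collection, spec)
    grid = spec.grid
    probs = suit.values.filled(0.0).ravel()
    valid = np.flatnonzero(probs > 0)
    if spec.n_presences > valid.size:
        raise ValueError(
            f"requested {spec.n_presences} presences but only {valid.size} valid cells"
        )
    p = probs[valid] / probs[valid].sum()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 999_983)))
    chosen = rng.choice(valid, size=spec.n_presences, replace=False, p=p)
    rr, cc = np.divmod(chosen, grid.n_cols)
    xs = grid.x_origin + (cc + 0.5) * grid.cell_size
    ys = grid.y_origin + (grid.n_rows - rr - 0.5) * grid.cell_size
    return OccurrenceSet(
        species="synthetic_species",
        points=np.column_stack([xs, ys]),
        notes=[f"sampled from true suitability (seed {spec.seed})"],
    )


def benchmark_spec(seed: int = 2021) -> SynthSpec:
    """The default recovery benchmark: N=19, 2 drivers, 1 decoy at r≈0.9."""
    grid = GridSpec(
        n_rows=100, n_cols=100, x_origin=-105.0, y_origin=30.0, cell_size=0.05
    )
    return SynthSpec(
        grid=grid,
        n_vars=19,
        driver_effects={"env01": 10.0, "env02": -10.0},
        decoy_correlations={"env03": ("env01", 0.9)},
        noise_spatial_scale=5.0,
        n_presences=300,
        seed=seed,
    )


def benchmark_default(
    directory: str | Path, seed: int = 2021
) -> tuple[PredictorCollection, OccurrenceSet, Truth]:
    """Build the default benchmark landscape under ``directory``."""
    spec = benchmark_spec(seed)
    collection = make_landscape(spec, directory)
    occurrences = sample_presences(collection, spec)
    truth = Truth(
        drivers=spec.drivers,
        effects=dict(spec.driver_effects),
        decoys=dict(spec.decoy_correlations),
        suitability=true_suitability(collection, spec),
    )
    return collection, occurrences, truth
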