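"""Synthetic environmental stacks, occurrence tables, and disease-severity data.

Every downstream stage of the pipeline is testable without any real-layer
download: this module fabricates gridded environmental components with a
known zone (cluster) structure, samples occurrence points whose intensity
genuinely depends on chosen variables, and simulates 0-100 disease severity
ratings (DSr) from a logistic link on the environment.  All ground truth —
zone grids, sampling intensity, link coefficients — is recorded on the
:class:`SyntheticTruth` object so recovery can be asserted.

Zone geometry: each component partitions the grid into axis-aligned
contiguous bands (rows for the bioclimatic component, columns for the
edaphic, fine row sub-bands for the geophysic), one band set per cluster
center.  Centers are placed at scaled unit vectors in the component's layer
space, so all pairwise center distances are equal — the cleanest possible
geometry for testing cluster-count recovery.  Layer values are the zone
center plus white noise, optionally mapped through a per-layer affine
transform to physical units (z-standardization in the clustering stage makes
recovery invariant to these transforms).

None of this imitates real European climate gradients or real Lens niche
envelopes; it provides controlled structure, not realism.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import extract_at_points
from .types import COMPONENTS, EnvironmentalStack, GridSpec, ValidationError

MAX_CLUSTERS = 6

#: Taxon sampling weights mirroring the relative abundances of the four wild
#: lentil taxa with usable occurrence data (most records L. nigricans, then
#: L. ervoides, few L. lamottei and L. culinaris ssp. orientalis).
DEFAULT_TAXA_WEIGHTS = {
    "L. nigricans": 0.710,
    "L. ervoides": 0.232,
    "L. lamottei": 0.047,
    "L. culinaris ssp. orientalis": 0.011,
}

#: Month weights for splitting annual precipitation into monthly values
#: (January first; drier summer, wetter autumn/winter) and additive monthly
#: temperature offsets, used by the "study" flavored stack.
MONTH_PRECIP_WEIGHTS = (0.11, 0.10, 0.10, 0.09, 0.07, 0.04, 0.02, 0.02, 0.06, 0.12, 0.14, 0.13)
MONTH_TEMP_OFFSETS = (-7.0, -6.0, -4.0, -1.0, 3.0, 7.0, 9.0, 9.0, 5.0, 0.0, -4.0, -6.0)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of one master seed.

    Stages draw from independent substreams so regenerating one stage never
    perturbs another.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(zlib.crc32(name.encode()),))
    )


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study; filled in as stages run."""

    seed: int
    true_k: dict[str, int]
    layer_names: dict[str, list[str]]
    centers: dict[str, np.ndarray]
    informative_variables: list[str]
    beta: dict[str, float]
    dsr_link: dict[str, float]
    dsr_intercept: float = 0.0
    noise_sd: float = 0.05
    dsr_noise_sd: float = 5.0
    #: optional per-layer affine map latent -> physical: name -> (offset, scale)
    affine: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: filled by make_stack
    zone_grids: dict[str, np.ndarray] = field(default_factory=dict)
    realized_triples: int | None = None
    #: filled by sample_occurrences
    intensity_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        for comp, k in self.true_k.items():
            if comp not in COMPONENTS:
                raise ValidationError(f"unknown component {comp!r}")
            if not 1 <= k <= MAX_CLUSTERS:
                raise ValidationError(f"true_k[{comp!r}] = {k} outside [1, {MAX_CLUSTERS}]")
            if k > len(self.layer_names[comp]):
                raise ValidationError(
                    f"component {comp!r} needs at least {k} layers for {k} orthogonal centers"
                )
        registered = {n for names in self.layer_names.values() for n in names}
        for coeff_map, label in ((self.beta, "beta"), (self.dsr_link, "dsr_link")):
            unknown = set(coeff_map) - registered
            if unknown:
                raise ValidationError(f"{label} references unregistered variables: {sorted(unknown)}")

    def component_of(self, name: str) -> str:
        for comp, names in self.layer_names.items():
            if name in names:
                return comp
        raise KeyError(name)


def default_truth(
    seed: int = 0,
    true_k: tuple[int, int, int] = (4, 3, 3),
    noise_sd: float = 0.05,
    separation: float = 6.0,
    informative: str = "bio1",
    beta: float = 0.8,
) -> SyntheticTruth:
    """Clean latent-space truth with generic layer names (bio1.., eda1.., geo1..)."""
    n_layers = {"bioclimatic": 6, "edaphic": 5, "geophysic": 4}
    prefix = {"bioclimatic": "bio", "edaphic": "eda", "geophysic": "geo"}
    names = {c: [f"{prefix[c]}{i + 1}" for i in range(n_layers[c])] for c in COMPONENTS}
    kmap = dict(zip(COMPONENTS, true_k))
    centers = {
        c: separation * np.eye(n_layers[c])[: kmap[c]] for c in COMPONENTS
    }
    return SyntheticTruth(
        seed=seed,
        true_k=kmap,
        layer_names=names,
        centers=centers,
        informative_variables=[informative],
        beta={informative: beta},
        dsr_link={informative: 1.5, "eda1": 1.0},
        noise_sd=noise_sd,
    )


def study_truth(seed: int = 0, noise_sd: float = 0.05, separation: float = 6.0) -> SyntheticTruth:
    """Truth whose layers carry physical names/units for end-to-end runs.

    Bioclimatic layers include annual precipitation and temperature (so the
    aridity indices can be computed), the edaphic layers include topsoil
    clay/silt fractions and conductivity (texture and salinity rules), and
    the geophysic layers mirror the solar-radiation/longitude flavor of real
    geophysic components.  ``topsoil_sand`` is derived as 100 - clay - silt
    by :func:`make_stack`, keeping compositions valid.
    """
    names = {
        "bioclimatic": ["annual_mean_temp", "annual_precip", "temp_range", "isothermality"],
        "edaphic": ["topsoil_clay", "topsoil_silt", "topsoil_ec", "bulk_density", "water_capacity"],
        "geophysic": ["radiation_annual", "radiation_december", "elevation"],
    }
    kmap = {"bioclimatic": 4, "edaphic": 3, "geophysic": 3}
    centers = {c: separation * np.eye(len(names[c]))[: kmap[c]] for c in COMPONENTS}
    affine = {
        "annual_mean_temp": (12.0, 1.2),
        "annual_precip": (380.0, 60.0),
        "temp_range": (24.0, 1.5),
        "isothermality": (38.0, 2.0),
        "topsoil_clay": (30.0, 6.0),
        "topsoil_silt": (28.0, 5.0),
        "topsoil_ec": (0.8, 0.4),
        "bulk_density": (1.35, 0.05),
        "water_capacity": (110.0, 8.0),
        "radiation_annual": (14000.0, 700.0),
        "radiation_december": (4200.0, 350.0),
        "elevation": (400.0, 90.0),
    }
    return SyntheticTruth(
        seed=seed,
        true_k=kmap,
        layer_names=names,
        centers=centers,
        informative_variables=["annual_mean_temp"],
        beta={"annual_mean_temp": 0.8},
        dsr_link={"radiation_annual": 1.4, "water_capacity": 0.9},
        noise_sd=noise_sd,
        affine=affine,
    )


def _zone_grid(component: str, k: int, n_rows: int, n_cols: int, k_bio: int) -> np.ndarray:
    """Axis-aligned contiguous zone bands; orientation differs per component."""
    if component == "bioclimatic":
        edges = np.linspace(0, n_rows, k + 1).astype(int)
        zone = np.zeros((n_rows, n_cols), dtype=int)
        for j in range(k):
            zone[edges[j]: edges[j + 1], :] = j
        return zone
    if component == "edaphic":
        edges = np.linspace(0, n_cols, k + 1).astype(int)
        zone = np.zeros((n_rows, n_cols), dtype=int)
        for j in range(k):
            zone[:, edges[j]: edges[j + 1]] = j
        return zone
    # geophysic: fine row sub-bands cycling within each bioclimatic band so
    # every (bio, geo) pair is realized
    sub = max(1, n_rows // (k_bio * k))
    zone = (np.arange(n_rows)[:, None] // sub) % k
    return np.broadcast_to(zone, (n_rows, n_cols)).copy()


def make_stack(
    truth: SyntheticTruth,
    n_rows: int = 36,
    n_cols: int = 36,
    grid: GridSpec | None = None,
) -> EnvironmentalStack:
    """Generate the environmental stack encoded by ``truth``.

    Layer values are zone-center coordinates plus N(0, noise_sd) white noise,
    mapped through the per-layer affine transforms where declared.  Zone
    membership grids and the realized-triple count are stored back on
    ``truth`` for later recovery checks.
    """
    total_zones = max(truth.true_k.values())
    if n_rows * n_cols < sum(truth.true_k.values()):
        raise ValidationError(f"grid of {n_rows * n_cols} cells cannot host all zones")
    del total_zones
    if grid is None:
        grid = GridSpec(n_rows=n_rows, n_cols=n_cols, xll=-10.0, yll=35.0)
    rng = substream(truth.seed, "stack")

    stack = EnvironmentalStack(grid=grid)
    k_bio = truth.true_k["bioclimatic"]
    for comp in COMPONENTS:
        k = truth.true_k[comp]
        zone = _zone_grid(comp, k, n_rows, n_cols, k_bio)
        truth.zone_grids[comp] = zone
        centers = truth.centers[comp]
        for idx, name in enumerate(truth.layer_names[comp]):
            latent = centers[zone, idx] + rng.normal(0.0, truth.noise_sd, size=zone.shape)
            offset, scale = truth.affine.get(name, (0.0, 1.0))
            stack.add_layer(name, offset + scale * latent, comp)

    if "topsoil_clay" in stack.layers and "topsoil_silt" in stack.layers:
        sand = 100.0 - stack.layers["topsoil_clay"] - stack.layers["topsoil_silt"]
        stack.add_layer("topsoil_sand", np.clip(sand, 0.0, 100.0), "edaphic")
        truth.layer_names["edaphic"] = list(
            dict.fromkeys(truth.layer_names["edaphic"] + ["topsoil_sand"])
        )
    if "topsoil_ec" in stack.layers:
        np.clip(stack.layers["topsoil_ec"], 0.0, None, out=stack.layers["topsoil_ec"])
    if "annual_precip" in stack.layers:
        np.clip(stack.layers["annual_precip"], 0.0, None, out=stack.layers["annual_precip"])

    triples = np.stack([truth.zone_grids[c] for c in COMPONENTS])
    truth.realized_triples = len(np.unique(triples.reshape(3, -1), axis=1).T)
    return stack


def _zscore(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)


def sample_occurrences(
    truth: SyntheticTruth,
    stack: EnvironmentalStack,
    n: int = 624,
    taxa_weights: dict[str, float] | None = None,
    genebank_fraction: float = 105 / 624,
    monthly_columns: bool = False,
) -> pd.DataFrame:
    """Sample occurrence points with environment-dependent intensity.

    Cell sampling probability is proportional to exp(sum beta_v * z(v)) over
    the stack's valid cells (z = per-layer standardization), so the declared
    informative variables genuinely shape the distribution; beta = 0 gives
    uniform occupancy.  Points sit at cell centers, drawn without
    replacement.  With ``monthly_columns`` the table gains monthly
    precipitation/temperature columns derived from the annual layers via the
    fixed seasonal profile (needed by the flowering aridity index).
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = substream(truth.seed, "occurrences")
    valid = stack.valid_mask
    n_valid = int(valid.sum())
    if n > n_valid:
        raise ValidationError(f"requested {n} points but only {n_valid} valid cells")

    log_intensity = np.zeros(stack.grid.n_rows * stack.grid.n_cols)
    for name, b in truth.beta.items():
        log_intensity += b * _zscore(stack.layers[name]).ravel()
    intensity = np.exp(log_intensity)
    intensity[~valid.ravel()] = 0.0
    truth.intensity_grid = intensity.reshape(valid.shape)

    p = intensity / intensity.sum()
    flat_idx = rng.choice(intensity.size, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(flat_idx, valid.shape)
    lon = np.array([stack.grid.cell_center(r, c)[0] for r, c in zip(rows, cols)])
    lat = np.array([stack.grid.cell_center(r, c)[1] for r, c in zip(rows, cols)])

    weights = taxa_weights or DEFAULT_TAXA_WEIGHTS
    taxa = list(weights)
    probs = np.array([weights[t] for t in taxa], dtype=float)
    probs /= probs.sum()
    taxon = rng.choice(taxa, size=n, p=probs)

    is_ge = rng.random(n) < genebank_fraction
    ids = [
        (f"GE_{200000 + i:06d}" if ge else f"ID_{6950000 + i:07d}")
        for i, ge in enumerate(is_ge)
    ]
    country = np.array([f"Country_{z + 1}" for z in truth.zone_grids["bioclimatic"][rows, cols]])

    df = pd.DataFrame(
        {"pop_id": ids, "taxon": taxon, "lon": lon, "lat": lat, "country": country}
    )
    df["genebank_held"] = is_ge
    env = extract_at_points(stack, lon, lat)
    env_cols = stack.names()
    df = pd.concat([df, env[env_cols]], axis=1)

    if monthly_columns and "annual_precip" in df.columns and "annual_mean_temp" in df.columns:
        for m in range(1, 13):
            df[f"precip_m{m:02d}"] = df["annual_precip"] * MONTH_PRECIP_WEIGHTS[m - 1]
            df[f"temp_m{m:02d}"] = df["annual_mean_temp"] + MONTH_TEMP_OFFSETS[m - 1]

    df.attrs["env_columns"] = env_cols
    # plain list, not ndarray: DataFrame.attrs must stay comparable
    df.attrs["zone_triples"] = np.stack(
        [truth.zone_grids[c][rows, cols] for c in COMPONENTS], axis=1
    ).tolist()
    return df


def simulate_dsr(
    truth: SyntheticTruth,
    points: pd.DataFrame,
    trait: str = "rust",
    n: int | None = None,
) -> pd.DataFrame:
    """Simulate disease severity ratings from the logistic link in ``truth``.

    DSr = 100 * (1 - logistic(eta)) + Gaussian noise, clipped to [0, 100],
    where eta = intercept + sum dsr_link[v] * z(env_v).  High linear
    predictor means low severity, i.e. the resistant end of the scale; with
    zero link and zero noise every record scores exactly 50.
    """
    rng = substream(truth.seed, f"dsr-{trait}")
    if n is not None:
        points = points.iloc[:n]
    eta = np.full(len(points), truth.dsr_intercept, dtype=float)
    for name, coef in truth.dsr_link.items():
        if name in points.columns:
            eta += coef * _zscore(points[name].to_numpy(dtype=float))
    dsr = 100.0 * (1.0 - 1.0 / (1.0 + np.exp(-eta)))
    if truth.dsr_noise_sd > 0:
        dsr = dsr + rng.normal(0.0, truth.dsr_noise_sd, size=len(points))
    dsr = np.clip(dsr, 0.0, 100.0)
    out = pd.DataFrame(
        {
            "accession_id": [f"AC_{i:05d}" for i in range(len(points))],
            "lon": points["lon"].to_numpy(),
            "lat": points["lat"].to_numpy(),
            "trait": trait,
            "dsr": dsr,
        }
    )
    out.attrs["eta"] = eta.tolist()
    return out
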