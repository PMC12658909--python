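"""Synthetic two-lineage genotype, environment and current-field generators.

These generators produce data with the statistical structure the analysis
pipeline assumes, plus a ground-truth record for parameter-recovery tests:

* two divergent ancestral lineages under the Balding–Nichols model, whose
  single divergence parameter ``F`` matches the Weir–Cockerham theta one
  measures between pure descendant populations;
* admixed populations whose individuals carry ancestry proportions ``q``
  drawn around a population mean (Beta-distributed, with a point mass when
  the dispersion is 0), genotypes binomial at the mixture frequency
  ``q·p_A + (1−q)·p_B``;
* per-site environmental covariates tied to the site-mean ancestry through
  an inverse-logit (beta-regression) relation with beta-distributed noise;
* a gridded current field (uniform flow or a closed gyre) with a land mask;
* uniform at-random genotype dropout;
* a discrete-generation Wright–Fisher population of unlinked loci used as
  the drift oracle for linkage-disequilibrium Ne estimation.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, SiteTable
from .connectivity import CurrentRaster

__all__ = [
    "PopSpec",
    "RasterSpec",
    "SimConfig",
    "SimTruth",
    "simulate_ancestral_frequencies",
    "simulate_genotypes",
    "simulate_site_environment",
    "simulate_current_field",
    "inject_missingness",
    "simulate_wright_fisher",
]


@dataclass
class PopSpec:
    """One simulated population: site code, size, mean lineage-A ancestry
    and the within-population ancestry dispersion (0 = identical q)."""

    site_code: str
    n_individuals: int
    mean_q: float
    q_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_q <= 1.0:
            raise ValueError(f"mean_q must be in [0,1], got {self.mean_q}")
        if self.q_dispersion < 0 or self.q_dispersion >= 1:
            raise ValueError("q_dispersion must be in [0,1)")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass
class RasterSpec:
    """Geometry and circulation pattern of a simulated current raster."""

    n_cols: int = 20
    n_rows: int = 20
    cell_size: float = 0.1  # decimal degrees
    origin_lon: float = -10.0
    origin_lat: float = 51.0
    pattern: str = "gyre"  # 'uniform' or 'gyre'
    u0: float = 0.1  # m/s, uniform pattern
    v0: float = 0.0
    gyre_speed: float = 0.3  # peak tangential speed, m/s
    land_mask: np.ndarray | Callable[[int, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n_cols < 2 or self.n_rows < 2:
            raise ValueError("raster must be at least 2x2")
        if self.pattern not in ("uniform", "gyre"):
            raise ValueError("pattern must be 'uniform' or 'gyre'")


@dataclass
class SimConfig:
    """Full synthetic-study configuration (the study conditions)."""

    n_loci: int = 91
    divergence_F: float = 0.3
    pop_specs: list[PopSpec] = field(default_factory=list)
    env_coefs: dict[str, float] = field(default_factory=lambda: {
        "intercept": 1.5,
        "max_wave_height_m": -0.89,
        "min_sst_c": -0.14,
        "max_salinity_psu": -0.05,
    })
    env_precision: float = 30.0
    raster_spec: RasterSpec = field(default_factory=RasterSpec)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0.0 < self.divergence_F < 1.0) or not np.isfinite(self.divergence_F):
            raise ValueError("divergence_F must be in the open interval (0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        if self.env_precision <= 0:
            raise ValueError("env_precision must be positive")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    lineage_freqs: np.ndarray  # (2, n_loci)
    true_q: np.ndarray  # per individual, lineage-A ancestry
    individual_ids: list[str]
    population_labels: list[str]
    true_env_coefs: dict[str, float] | None
    seed: int

    def to_json(self, path: str | Path) -> None:
        obj = {
            "lineage_freqs": self.lineage_freqs.tolist(),
            "true_q": self.true_q.tolist(),
            "individual_ids": list(self.individual_ids),
            "population_labels": list(self.population_labels),
            "true_env_coefs": self.true_env_coefs,
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            np.asarray(obj["lineage_freqs"], float),
            np.asarray(obj["true_q"], float),
            obj["individual_ids"],
            obj["population_labels"],
            obj["true_env_coefs"],
            obj["seed"],
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_ancestral_frequencies(n_loci: int, divergence_F: float,
                                   seed: int) -> np.ndarray:
    """Balding–Nichols lineage frequencies, shape (2, n_loci).

    Per locus a shared ancestral frequency p ~ Uniform(0.05, 0.95) is drawn,
    then each lineage's frequency follows Beta(p(1−F)/F, (1−p)(1−F)/F); the
    single parameter F is the expected differentiation (theta) between the
    two lineages.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not np.isfinite(divergence_F) or not (0.0 < divergence_F < 1.0):
        raise ValueError("divergence_F must be finite and in (0,1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, size=n_loci)
    a = p * (1.0 - divergence_F) / divergence_F
    b = (1.0 - p) * (1.0 - divergence_F) / divergence_F
    freqs = rng.beta(a, b, size=(2, n_loci))
    return np.clip(freqs, 1e-12, 1.0 - 1e-12)


def _beta_with_mean(rng: np.random.Generator, mean: float, dispersion: float,
                    size: int) -> np.ndarray:
    if dispersion == 0.0 or mean in (0.0, 1.0):
        return np.full(size, mean)
    a = mean * (1.0 - dispersion) / dispersion
    b = (1.0 - mean) * (1.0 - dispersion) / dispersion
    return rng.beta(a, b, size=size)


def simulate_genotypes(lineage_freqs: np.ndarray, pop_specs: Sequence[PopSpec],
                       seed: int) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw admixed genotypes: g ~ Binomial(2, q·p_A + (1−q)·p_B)."""
    lineage_freqs = np.asarray(lineage_freqs, float)
    if lineage_freqs.ndim != 2 or lineage_freqs.shape[0] != 2 or lineage_freqs.shape[1] < 1:
        raise ValueError("lineage_freqs must have shape (2, n_loci) with n_loci >= 1")
    if not pop_specs:
        raise ValueError("pop_specs must be non-empty")
    specs = [s if isinstance(s, PopSpec) else PopSpec(*s) for s in pop_specs]
    rng = np.random.default_rng(seed)
    pA, pB = lineage_freqs
    calls, q_all, ids, labels = [], [], [], []
    for spec in specs:
        q = _beta_with_mean(rng, spec.mean_q, spec.q_dispersion, spec.n_individuals)
        mix = q[:, None] * pA[None, :] + (1.0 - q[:, None]) * pB[None, :]
        calls.append(rng.binomial(2, mix).astype(np.int16))
        q_all.append(q)
        ids.extend(f"{spec.site_code}_{i + 1}" for i in range(spec.n_individuals))
        labels.extend([spec.site_code] * spec.n_individuals)
    G = GenotypeMatrix(
        np.vstack(calls), ids, np.asarray(labels, dtype=object),
        [f"L{j + 1:03d}" for j in range(lineage_freqs.shape[1])],
    )
    truth = SimTruth(lineage_freqs, np.concatenate(q_all), ids, labels, None, seed)
    return G, truth


DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "max_wave_height_m": (0.0, 3.0),
    "min_sst_c": (8.0, 14.0),
    "max_salinity_psu": (30.0, 36.0),
    "mean_sst_c": (10.0, 16.0),
    "max_sst_c": (14.0, 20.0),
    "min_salinity_psu": (20.0, 34.0),
    "mean_salinity_psu": (28.0, 35.0),
    "min_wave_height_m": (0.0, 0.5),
    "mean_wave_height_m": (0.2, 1.5),
}


def simulate_site_environment(classification_truth: pd.DataFrame,
                              env_coefs: dict[str, float],
                              env_precision: float, seed: int,
                              covariate_correlation: float = 0.0) -> pd.DataFrame:
    """Site environments plus a beta-noised site-level ancestry response.

    ``classification_truth`` needs columns ``site_code`` (one row per site);
    a ``true_mean_q`` column, if present, is carried through.  Covariates
    named in ``env_coefs`` (all keys except ``intercept``) are drawn
    uniformly on their field-realistic ranges; the observed site ancestry is
    Beta(μφ, (1−μ)φ) with logit(μ) = intercept + Σ coef·covariate and
    φ = ``env_precision`` (μ returned exactly when φ is infinite).

    ``covariate_correlation`` in [0,1) imposes a common Gaussian-copula
    factor across covariates to exercise collinearity diagnostics.
    """
    if env_precision <= 0:
        raise ValueError("env_precision must be positive")
    if "site_code" not in classification_truth.columns:
        raise ValueError("classification_truth needs a site_code column")
    rng = np.random.default_rng(seed)
    n = len(classification_truth)
    covars = [k for k in env_coefs if k != "intercept"]
    out = classification_truth.reset_index(drop=True).copy()

    if covariate_correlation:
        rho = float(covariate_correlation)
        shared = rng.standard_normal(n)
        from scipy.stats import norm
        z = {c: np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
             for c in covars}
        unif = {c: norm.cdf(z[c]) for c in covars}
    else:
        unif = {c: rng.uniform(size=n) for c in covars}

    eta = np.full(n, float(env_coefs.get("intercept", 0.0)))
    for c in covars:
        lo, hi = DEFAULT_COVARIATE_RANGES.get(c, (0.0, 1.0))
        out[c] = lo + (hi - lo) * unif[c]
        eta += env_coefs[c] * out[c].to_numpy()
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.isinf(env_precision):
        out["observed_q"] = mu
    else:
        out["observed_q"] = rng.beta(mu * env_precision, (1.0 - mu) * env_precision)
    out["true_mu_q"] = mu
    return out


def simulate_current_field(spec: RasterSpec, seed: int = 0) -> CurrentRaster:
    """Gridded u/v current field with a land mask.

    'uniform' gives constant (u0, v0) on water; 'gyre' gives solid-body
    anticlockwise rotation about the grid centre with peak tangential speed
    ``gyre_speed`` at the grid edge.  Land cells carry NaN.
    """
    nr, nc = spec.n_rows, spec.n_cols
    if callable(spec.land_mask):
        land = np.asarray(spec.land_mask(nr, nc), bool)
    elif spec.land_mask is not None:
        land = np.asarray(spec.land_mask, bool)
    else:
        land = np.zeros((nr, nc), bool)
    if land.shape != (nr, nc):
        raise ValueError("land mask shape mismatch")
    if land.all():
        raise ValueError("land mask covers the whole grid")

    if spec.pattern == "uniform":
        u = np.full((nr, nc), float(spec.u0))
        v = np.full((nr, nc), float(spec.v0))
    else:  # gyre
        # x east, y north, centred; row 0 is the northern row
        col = np.arange(nc)[None, :] - (nc - 1) / 2.0
        row = (nr - 1) / 2.0 - np.arange(nr)[:, None]
        rmax = max((nc - 1) / 2.0, (nr - 1) / 2.0)
        u = -spec.gyre_speed * (row / rmax) * np.ones((nr, nc))
        v = spec.gyre_speed * (col / rmax) * np.ones((nr, nc))
    u = np.where(land, np.nan, u)
    v = np.where(land, np.nan, v)
    return CurrentRaster(u, v, spec.origin_lon, spec.origin_lat, spec.cell_size)


def inject_missingness(G: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each call missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0,1)")
    if rate == 0.0:
        return GenotypeMatrix(G.calls.copy(), list(G.individual_ids),
                              G.population_labels.copy(), list(G.locus_ids))
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=G.calls.shape) < rate
    calls = np.where(mask, MISSING, G.calls).astype(np.int16)
    return GenotypeMatrix(calls, list(G.individual_ids),
                          G.population_labels.copy(), list(G.locus_ids))


def simulate_wright_fisher(n_e: int, n_loci: int, n_generations: int,
                           sample_size: int, seed: int) -> GenotypeMatrix:
    """Discrete-generation Wright–Fisher population of unlinked loci.

    ``n_e`` monoecious diploids mate at random (selfing allowed); each
    parent transmits one allele per locus independently (free
    recombination), so linkage disequilibrium among the unlinked loci is
    generated purely by drift and pedigree structure — the signal the
    LD-based Ne estimator measures.  Returns a sample of ``sample_size``
    individuals from the final generation as a single-population matrix.
    """
    if sample_size > n_e:
        raise ValueError("sample_size cannot exceed the population size")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.2, 0.8, size=n_loci)
    # genotypes as two allele arrays (n_e, n_loci) in {0,1}
    hap1 = (rng.uniform(size=(n_e, n_loci)) < p0).astype(np.int8)
    hap2 = (rng.uniform(size=(n_e, n_loci)) < p0).astype(np.int8)
    for _ in range(n_generations):
        mothers = rng.integers(0, n_e, size=n_e)
        fathers = rng.integers(0, n_e, size=n_e)
        pick_m = rng.integers(0, 2, size=(n_e, n_loci), dtype=np.int8)
        pick_f = rng.integers(0, 2, size=(n_e, n_loci), dtype=np.int8)
        new1 = np.where(pick_m == 0, hap1[mothers], hap2[mothers])
        new2 = np.where(pick_f == 0, hap1[fathers], hap2[fathers])
        hap1, hap2 = new1, new2
    take = rng.choice(n_e, size=sample_size, replace=False)
    calls = (hap1[take] + hap2[take]).astype(np.int16)
    ids = [f"WF_{i + 1}" for i in range(sample_size)]
    return GenotypeMatrix(calls, ids, np.asarray(["WF"] * sample_size, dtype=object),
                          [f"L{j + 1:03d}" for j in range(n_loci)])


# ---------------------------------------------------------------------------
# Whole-study generation (used by the pipeline and the CLI)
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> dict:
    """Generate the full synthetic study: genotypes, sites, rasters, truth.

    Returns a dict with keys ``genotypes`` (GenotypeMatrix), ``truth``
    (SimTruth), ``sites`` (SiteTable with coordinates on water cells and
    environmental covariates), and ``raster`` (CurrentRaster).
    Sub-seeds for each stage are spawned deterministically from
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_geno, s_env, s_rast, s_miss, s_site = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    )
    freqs = simulate_ancestral_frequencies(config.n_loci, config.divergence_F, s_freq)
    G, truth = simulate_genotypes(freqs, config.pop_specs, s_geno)
    if config.missing_rate > 0:
        G = inject_missingness(G, config.missing_rate, s_miss)
    raster = simulate_current_field(config.raster_spec, s_rast)

    # place sites on distinct water cells, deterministically
    rng = np.random.default_rng(s_site)
    water = np.argwhere(raster.water_mask)
    if len(water) < len(config.pop_specs):
        raise ValueError("not enough water cells to place all sites")
    chosen = water[rng.choice(len(water), size=len(config.pop_specs), replace=False)]
    lat, lon = raster.cell_center(chosen[:, 0], chosen[:, 1])
    base = pd.DataFrame({
        "site_code": [s.site_code for s in config.pop_specs],
        "true_mean_q": [s.mean_q for s in config.pop_specs],
    })
    env = simulate_site_environment(base, config.env_coefs, config.env_precision, s_env)
    env.insert(1, "latitude", np.asarray(lat, float))
    env.insert(2, "longitude", np.asarray(lon, float))
    truth = dataclasses.replace(truth, true_env_coefs=dict(config.env_coefs))
    return dict(genotypes=G, truth=truth, sites=SiteTable(env), raster=raster)
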