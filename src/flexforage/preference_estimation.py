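"""Estimation of prey body-mass preference distributions from survey tables.

A consumer's realized prey-size distribution (stomach contents) is the
product of what it encounters — the environmental distribution E(x) of
log10 prey body mass — and what it selects, the preference distribution
P(x) = R(x) / E(x). Rather than forming the ratio of two kernel density
estimates, the moments of P are computed directly as weighted moments of
the observed stomach masses r_i with inverse-availability weights
w_i = 1 / E(r_i): prey sizes that are common in the environment count
less, rare ones more.

The pipeline mirrors a demersal-fish stomach survey workflow: fish
lengths are converted to masses with species-specific power laws,
conspecifics of equal integer length caught in the same sampling event
are pooled into "statistical fish", each is matched to the nearest
environmental benthos sample on the same route within a strict 31-day
window, fish whose diet is poorly covered by the environmental sample
(<90 % of diet biomass) are discarded, and hard-bodied prey occurrences
are down-weighted by 0.8 to offset their longer gut residence time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "LENGTH_MASS_CONSTANTS",
    "StatisticalFish",
    "DensityEstimate",
    "PreferenceSummary",
    "length_to_mass",
    "pool_statistical_fish",
    "match_environment",
    "filter_coverage",
    "estimate_env_density",
    "preference_moments",
    "weighted_median",
    "estimate_preferences",
]

#: FishBase length(cm)-mass(g) power-law constants (a, b): BM = a * BL**b.
LENGTH_MASS_CONSTANTS: dict[str, tuple[float, float]] = {
    "Gadus morhua": (0.00708, 3.08),
    "Merlangius merlangus": (0.00631, 3.05),
    "Limanda": (0.00776, 3.08),
    "Pleuronectes platessa": (0.00776, 3.06),
    "Platichthys flesus": (0.00776, 3.07),
    "Hippoglossoides platessoides": (0.00562, 3.09),
    "Enchelyopus cimbrius": (0.00389, 3.08),
}


def length_to_mass(species: str, length_cm: float,
                   constants: dict[str, tuple[float, float]] | None = None
                   ) -> float:
    """Convert fish body length (cm) to body mass (g) via ``a * L**b``."""
    table = constants if constants is not None else LENGTH_MASS_CONSTANTS
    if species not in table:
        raise KeyError(f"no length-mass constants for species {species!r}")
    if length_cm <= 0:
        raise ValueError("length must be positive")
    a, b = table[species]
    return a * length_cm ** b


@dataclass
class StatisticalFish:
    """Pooled analysis unit: one species x route x date x cm length class."""

    species: str
    functional_group: str
    length_cm: int
    body_mass_g: float
    date: pd.Timestamp
    route: str
    prey_items: pd.DataFrame  # columns: taxon, mass_g, count, biomass, hard_body
    matched_env_id: tuple | None = None
    temperature_C: float | None = None
    resource_availability: float | None = None

    @property
    def n_individuals(self) -> int:
        return int(self.prey_items.attrs.get("n_individuals", 1))


@dataclass
class DensityEstimate:
    """Environmental density E(x) on a log10 prey-mass grid.

    Normalized to integrate to 1 over its support (trapezoid rule) and
    floored at a small positive value inside the support so inverse
    weights 1/E stay bounded.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    support: tuple[float, float]
    floor: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        vals = np.interp(x, self.grid, self.density,
                         left=self.floor, right=self.floor)
        clipped = np.maximum(vals, self.floor)
        return clipped if clipped.shape else float(clipped)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class PreferenceSummary:
    """Weighted summary of one statistical fish's preference distribution."""

    weighted_median: float
    weighted_mean: float
    weighted_sd: float
    weighted_skewness: float
    total_weight: float
    n_prey_items: int
    n_clipped: int = 0
    temperature_C: float | None = None
    log10_resource: float | None = None
    log10_fish_mass: float | None = None
    functional_group: str | None = None


def pool_statistical_fish(stomachs: pd.DataFrame,
                          constants: dict[str, tuple[float, float]] | None = None
                          ) -> list[StatisticalFish]:
    """Pool individual fish rows into statistical fish.

    The grouping key is (species, route, date, integer length in cm);
    prey items of pooled individuals are concatenated with counts and
    biomasses summed per (taxon, mass). Expected columns: ``fish_id,
    species, functional_group, length_cm, date, route, prey_taxon,
    prey_mass_g, prey_count, prey_biomass, hard_body``.
    """
    if stomachs.empty:
        return []
    df = stomachs.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["length_cm"] = np.rint(df["length_cm"].astype(float)).astype(int)
    out: list[StatisticalFish] = []
    keys = ["species", "route", "date", "length_cm"]
    for (species, route, date, length), grp in df.groupby(keys, sort=True):
        prey = (grp.groupby(["prey_taxon", "prey_mass_g", "hard_body"],
                            as_index=False)
                   .agg(count=("prey_count", "sum"),
                        biomass=("prey_biomass", "sum")))
        prey = prey.rename(columns={"prey_taxon": "taxon",
                                    "prey_mass_g": "mass_g"})
        prey.attrs["n_individuals"] = grp["fish_id"].nunique()
        out.append(StatisticalFish(
            species=species,
            functional_group=str(grp["functional_group"].iloc[0]),
            length_cm=int(length),
            body_mass_g=length_to_mass(species, int(length), constants),
            date=date,
            route=route,
            prey_items=prey,
        ))
    return out


def _pool_environment(env: pd.DataFrame) -> pd.DataFrame:
    """Pool environment grabs by (route, date); sums duplicated taxa."""
    env = env.copy()
    env["date"] = pd.to_datetime(env["date"])
    pooled = (env.groupby(["route", "date", "taxon", "body_mass_g"],
                          as_index=False)
                 .agg(abundance=("abundance", "sum"),
                      biomass=("biomass", "sum"),
                      temperature_C=("temperature_C", "mean")))
    return pooled


def match_environment(fish: list[StatisticalFish], env: pd.DataFrame,
                      max_gap_days: int = 31) -> list[StatisticalFish]:
    """Match each statistical fish to its nearest same-route env sample.

    Environmental grabs are first pooled by (route, date). A fish is
    matched to the pooled sample on its route minimizing the absolute
    date difference, strictly below ``max_gap_days``; ties are broken
    toward the earlier sample. Fish without a candidate in the window
    are dropped (counted in a log message, not an error).
    """
    pooled = _pool_environment(env)
    sample_dates = (pooled.groupby("route")["date"]
                    .apply(lambda s: np.sort(s.unique())))
    matched: list[StatisticalFish] = []
    n_dropped = 0
    for f in fish:
        if f.route not in sample_dates.index:
            n_dropped += 1
            continue
        dates = pd.DatetimeIndex(sample_dates[f.route])
        gaps = np.abs((dates - f.date).days)
        best = np.min(gaps)
        if best >= max_gap_days:
            n_dropped += 1
            continue
        candidates = dates[gaps == best]
        env_date = candidates.min()  # tie -> earlier sample
        f.matched_env_id = (f.route, env_date)
        sample = pooled[(pooled["route"] == f.route)
                        & (pooled["date"] == env_date)]
        f.temperature_C = float(sample["temperature_C"].mean())
        f.resource_availability = float(sample["biomass"].sum())
        matched.append(f)
    if n_dropped:
        logger.info("match_environment: dropped %d fish without an "
                    "environmental sample within %d days", n_dropped,
                    max_gap_days)
    return matched


def filter_coverage(fish: StatisticalFish, env_sample: pd.DataFrame,
                    threshold: float = 0.9) -> tuple[bool, float]:
    """Keep a fish iff >= ``threshold`` of its diet biomass is from taxa
    also present in the matched environmental sample."""
    diet = fish.prey_items
    total = float(diet["biomass"].sum())
    if total <= 0:
        logger.warning("fish %s/%s/%s: zero diet biomass, dropped",
                       fish.species, fish.route, fish.date.date())
        return False, 0.0
    env_taxa = set(env_sample["taxon"])
    covered = float(diet.loc[diet["taxon"].isin(env_taxa), "biomass"].sum())
    coverage = covered / total
    return coverage >= threshold, coverage


def estimate_env_density(env_logmasses, env_weights=None,
                         floor_frac: float = 1e-6,
                         pad_bandwidths: float = 3.0,
                         n_grid: int = 512) -> DensityEstimate:
    """Abundance-weighted Gaussian KDE of the environmental log10-mass
    distribution, Silverman bandwidth, renormalized on a padded grid.

    The support is the data range padded by ``pad_bandwidths`` kernel
    bandwidths; the density is floored at ``floor_frac`` times its
    maximum so downstream inverse weights stay finite.
    """
    x = np.asarray(env_logmasses, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct prey masses for a density "
                         "estimate; pool more environmental samples")
    w = None
    if env_weights is not None:
        w = np.asarray(env_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative environmental weights")
    kde = gaussian_kde(x, bw_method="silverman", weights=w)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    lo = x.min() - pad_bandwidths * bw
    hi = x.max() + pad_bandwidths * bw
    grid = np.linspace(lo, hi, n_grid)
    dens = kde(grid)
    floor = floor_frac * float(dens.max())
    dens = np.maximum(dens, floor)
    dens = dens / np.trapezoid(dens, grid)
    floor = max(floor, float(dens.min()))
    return DensityEstimate(grid=grid, density=dens, bandwidth=bw,
                           support=(lo, hi), floor=float(dens.min()))


def weighted_median(values, weights) -> float:
    """Weighted 0.5-quantile with linear interpolation (midpoint
    convention: reduces to the sample median for equal weights)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    W = w.sum()
    p = (np.cumsum(w) - 0.5 * w) / W
    return float(np.interp(0.5, p, v))


def preference_moments(fish: StatisticalFish, env_density: DensityEstimate,
                       soft_body_correction: float = 0.8,
                       apply_correction: bool = True) -> PreferenceSummary:
    """Inverse-availability weighted moments of the preference distribution.

    Each stomach item i at log10 mass r_i receives weight
    ``w_i = count_i * k_i / E(r_i)`` where ``k_i`` is the hard-body
    correction (0.8 by default, 1 for soft-bodied prey). With
    ``W = sum w_i``: mean ``mu = sum(w r)/W``, variance
    ``sigma^2 = sum(w (r-mu)^2)/W`` and skewness
    ``gamma = sum(w (r-mu)^3)/(W sigma^3)``. Items falling where E is at
    its floor are clipped to the floor (logged), not dropped.
    """
    prey = fish.prey_items
    r = np.log10(prey["mass_g"].to_numpy(dtype=float))
    counts = prey["count"].to_numpy(dtype=float)
    k = np.ones_like(counts)
    if apply_correction:
        k = np.where(prey["hard_body"].to_numpy(dtype=bool),
                     soft_body_correction, 1.0)
    E = np.atleast_1d(env_density(r))
    n_clipped = int(np.sum(E <= env_density.floor * (1 + 1e-12)))
    if n_clipped:
        logger.warning("%d stomach items at the density floor for fish "
                       "%s/%s", n_clipped, fish.species, fish.date.date())
    w = counts * k / E
    W = float(w.sum())
    mu = float((w * r).sum() / W)
    var = float((w * (r - mu) ** 2).sum() / W)
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float((w * (r - mu) ** 3).sum() / (W * sd ** 3))
    else:
        skew = 0.0
    return PreferenceSummary(
        weighted_median=weighted_median(r, w),
        weighted_mean=mu,
        weighted_sd=sd,
        weighted_skewness=skew,
        total_weight=W,
        n_prey_items=int(counts.sum()),
        n_clipped=n_clipped,
        temperature_C=fish.temperature_C,
        log10_resource=(np.log10(fish.resource_availability)
                        if fish.resource_availability else None),
        log10_fish_mass=float(np.log10(fish.body_mass_g)),
        functional_group=fish.functional_group,
    )


def estimate_preferences(stomachs: pd.DataFrame, env: pd.DataFrame,
                         max_gap_days: int = 31,
                         coverage_threshold: float = 0.9,
                         soft_body_correction: float = 0.8,
                         apply_correction: bool = True,
                         constants: dict | None = None) -> pd.DataFrame:
    """Full survey-to-preferences pipeline; one output row per kept fish.

    Output columns: the preference summary (weighted median / mean / sd /
    skewness, total weight, item count) plus covariates (temperature in
    Celsius, log10 resource availability, log10 fish body mass,
    functional group) and bookkeeping identifiers.
    """
    fish = pool_statistical_fish(stomachs, constants)
    fish = match_environment(fish, env, max_gap_days)
    pooled_env = _pool_environment(env)
    rows = []
    for f in fish:
        route, env_date = f.matched_env_id
        sample = pooled_env[(pooled_env["route"] == route)
                            & (pooled_env["date"] == env_date)]
        keep, coverage = filter_coverage(f, sample, coverage_threshold)
        if not keep:
            continue
        logm = np.log10(sample["body_mass_g"].to_numpy(dtype=float))
        if np.unique(logm).size < 2:
            logger.warning("degenerate environment for %s/%s, skipped",
                           f.species, env_date.date())
            continue
        dens = estimate_env_density(logm,
                                    sample["abundance"].to_numpy(dtype=float))
        summ = preference_moments(f, dens, soft_body_correction,
                                  apply_correction)
        rows.append({
            "species": f.species,
            "functional_group": f.functional_group,
            "route": f.route,
            "date": f.date,
            "length_cm": f.length_cm,
            "body_mass_g": f.body_mass_g,
            "coverage": coverage,
            "weighted_median": summ.weighted_median,
            "weighted_mean": summ.weighted_mean,
            "weighted_sd": summ.weighted_sd,
            "weighted_skewness": summ.weighted_skewness,
            "total_weight": summ.total_weight,
            "n_prey_items": summ.n_prey_items,
            "temperature_C": summ.temperature_C,
            "log10_resource": summ.log10_resource,
            "log10_fish_mass": summ.log10_fish_mass,
        })
    return pd.DataFrame(rows)
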