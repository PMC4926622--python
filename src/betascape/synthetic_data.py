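"""Synthetic landscapes and faunas with known structure.

The generator emulates the statistical features the downstream analyses
assume of European-scale territorial inventories:

* ~36 unequal-area territorial units scattered over a latitude span with a
  linear "temperature declines northward" gradient (T_ann = T(lat36) +
  lapse * (Lat - 36) + noise);
* a pool of species occupying sites through multiplicative suitability
  kernels — a Gaussian thermal niche around a species-specific temperature
  optimum and a soft range disc (logistic plateau) around a range centre —
  sharpened into quasi-deterministic occupancy, because a territorial
  checklist is a range map, not a noisy sample;
* *endemics*, whose range is the footprint of one of a few southern
  refugia (anchored on actual southern units, spread by farthest-point
  selection) and which never cross the recolonisation latitude: they make
  southern faunas compositionally singular;
* *refugial exclusion*: each refugium shuts a random subset of generalists
  out of its footprint (old saturated faunas resist recolonisation), so
  refugial units substitute species instead of merely adding endemics —
  turnover that a nestedness-blind index can see;
* *generalists* with continent-scale, south-biased range discs and
  per-species northern range limits: species drop out northward in a
  consistent order, so richness declines with latitude while northern
  assemblages stay nested and therefore alike under beta_sim.

Mixing many disc radii, centres and limits yields a smooth, roughly
exponential decline of pairwise similarity with distance.  The truth object
records every latent assignment plus *planted decay rates*: the exponential
rates fitted to the noise-free plug-in similarity surface computed from the
latent occupancy probabilities, separately for the southern and northern
site groups.  Recovering those rates from one Bernoulli realisation is then
a well-posed test of sampling noise.

Occupancy is Bernoulli only — inventories are treated as complete, with no
observation/detection error layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import OccurrenceMatrix, SiteTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_landscape", "generate_occurrences"]

_KM_PER_DEG_LAT = 111.2


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic landscape; defaults are the study conditions
    every recovery test runs under."""

    n_sites: int = 36
    n_species: int = 300
    lat_span: tuple[float, float] = (36.0, 70.0)
    long_span: tuple[float, float] = (-10.0, 60.0)
    temp_at_lat36: float = 16.0          # deg C at the southern edge
    temp_lapse: float = -0.55            # deg C per degree latitude northward
    temp_noise_sd: float = 0.8           # local deviation from the lapse line
    niche_breadth_sd: float = 3.0        # deg C, endemic thermal niche width
    generalist_niche_sd: float = 12.0    # deg C, hardy wide-niche generalists
    endemic_fraction: float = 0.4
    n_refugia: int = 3
    refugium_radius: float = 500.0       # km, endemic range scale
    generalist_range_km: float = 6000.0
    range_edge_km: float = 100.0         # softness of range-disc boundaries
    occupancy_sharpness: float = 2.5     # suitability -> occupancy steepness
    refugial_exclusion: float = 0.65     # share of generalists shut out of a refugium
    southern_center_bias: float = 1.0    # >0 skews generalist range centres south
    northern_limit_span: tuple[float, float] | None = None  # default: lat span + margin
    recolonization_lat: float = 48.0     # north of this: generalists only
    area_lognormal_params: tuple[float, float] = (11.5, 0.8)  # ln km^2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_species < 2 or self.n_refugia < 1:
            raise ValueError("counts must be >= 2 (>= 1 refugium)")
        if not 0.0 <= self.endemic_fraction <= 1.0:
            raise ValueError("endemic_fraction must lie in [0, 1]")
        for lo, hi, name in (*[(*self.lat_span, "lat_span")], *[(*self.long_span, "long_span")]):
            if not hi > lo:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.refugium_radius <= 0 or self.generalist_range_km <= 0:
            raise ValueError("range scales must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent assignments behind one generated occurrence matrix."""

    species_niche_optima: np.ndarray       # deg C per species
    species_range_centers: np.ndarray      # (lat, long) per species
    species_northern_limits: np.ndarray    # deg latitude; inf for endemics
    endemic_flags: np.ndarray              # bool per species
    refugium_of_species: np.ndarray        # -1 for generalists
    planted_cluster_labels: np.ndarray     # per site; 0 = northern generalist pool
    planted_decay_rate_south: float        # per km, > 0
    planted_decay_rate_north: float        # per km, > 0
    dropped_species: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        out = {}
        for k, v in asdict(self).items():
            out[k] = v.tolist() if isinstance(v, np.ndarray) else v
        with open(path, "w") as fh:
            json.dump(out, fh, sort_keys=True, indent=1)


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    # one seed per run; fixed per-stage offsets keep stages independently
    # reproducible when re-run in isolation
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), offset]))


def generate_landscape(config: SyntheticConfig) -> SiteTable:
    """Scatter site centroids over the spans and derive the predictor table.

    Areas are lognormal; each site's lat/long extent grows with sqrt(area);
    T_ann follows the latitudinal lapse line plus noise, with T_max/T_min
    displaced from it (correlated); precipitation fields are independent of
    latitude by default.
    """
    rng = _rng(config, 0)
    n = config.n_sites
    lat = rng.uniform(*config.lat_span, size=n)
    lon = rng.uniform(*config.long_span, size=n)
    area = np.exp(rng.normal(*config.area_lognormal_params, size=n))  # km^2

    # half-extent of a square of that area, in degrees
    half_km = np.sqrt(area) / 2.0
    half_lat = half_km / _KM_PER_DEG_LAT
    half_lon = half_km / (_KM_PER_DEG_LAT * np.cos(np.radians(lat)))

    t_ann = (
        config.temp_at_lat36
        + config.temp_lapse * (lat - 36.0)
        + rng.normal(0.0, config.temp_noise_sd, size=n)
    )
    seasonal = rng.normal(10.0, 1.5, size=n)        # half annual amplitude
    t_max = t_ann + seasonal + rng.normal(0, 0.5, n)
    t_min = t_ann - seasonal - rng.normal(0, 0.5, n)
    t_ran = 0.6 * (half_lat * -config.temp_lapse * 2) + rng.gamma(2.0, 0.5, n)

    alt = rng.gamma(2.0, 200.0, size=n)             # m
    alt_ran = alt * rng.uniform(0.5, 2.0, size=n)

    p_ann = rng.gamma(4.0, 180.0, size=n)           # mm, latitude-independent
    p_ran = p_ann * rng.uniform(0.1, 0.5, size=n)
    p_dri = p_ann * rng.uniform(0.05, 0.25, size=n)
    p_drn = p_dri * rng.uniform(0.2, 0.8, size=n)

    df = pd.DataFrame(
        {
            "Area": area,
            "Long": lon,
            "Long_min": lon - half_lon,
            "Long_max": lon + half_lon,
            "Long_ran": 2 * half_lon,
            "Lat": lat,
            "Lat_min": lat - half_lat,
            "Lat_max": lat + half_lat,
            "Lat_ran": 2 * half_lat,
            "Alt": alt,
            "Alt_ran": alt_ran,
            "T_ann": t_ann,
            "T_ran": t_ran,
            "T_max": t_max,
            "T_min": t_min,
            "P_ann": p_ann,
            "P_ran": p_ran,
            "P_dri": p_dri,
            "P_drn": p_drn,
        },
        index=[f"U{i+1:02d}" for i in range(n)],
    )
    return SiteTable(df)


def _site_km_coords(lat: np.ndarray, lon: np.ndarray, lat0: float) -> np.ndarray:
    """Equirectangular km coordinates, good enough for kernel evaluation."""
    x = _KM_PER_DEG_LAT * np.cos(np.radians(lat0)) * lon
    y = _KM_PER_DEG_LAT * lat
    return np.column_stack([y, x])


def _refugium_centers(
    config: SyntheticConfig,
    rng: np.random.Generator,
    lat: np.ndarray,
    lon: np.ndarray,
) -> np.ndarray:
    """Anchor refugia on actual southern territorial units.

    A glacial refugium is wherever biota persisted, i.e. a real piece of
    land: the first anchor is a random southern unit and the rest are added
    by farthest-point selection, which spreads refugia out (the
    peninsular-refugium geometry: separated in space, alike in climate).
    Falls back to uniform southern positions if too few units are southern.
    """
    lat_lo, lat_hi = config.lat_span
    south_hi = min(config.recolonization_lat, lat_hi) - 2.0
    cand = np.flatnonzero(lat <= south_hi)
    if cand.size < config.n_refugia:
        lats = rng.uniform(lat_lo + 1.0, max(south_hi, lat_lo + 2.0),
                           size=config.n_refugia)
        lons = rng.uniform(*config.long_span, size=config.n_refugia)
        return np.column_stack([lats, lons])
    pts = np.column_stack([lat[cand], lon[cand]])
    km = _site_km_coords(pts[:, 0], pts[:, 1], float(np.mean(config.lat_span)))
    chosen = [int(rng.integers(cand.size))]
    while len(chosen) < config.n_refugia:
        d = np.min(
            np.linalg.norm(km[:, None, :] - km[chosen][None, :, :], axis=2), axis=1
        )
        d[chosen] = -1.0
        chosen.append(int(np.argmax(d)))
    return pts[chosen]


def _occupancy_probability(
    config: SyntheticConfig,
    site_t: np.ndarray,
    site_km: np.ndarray,
    optima: np.ndarray,
    centers_km: np.ndarray,
    range_scale: np.ndarray,
    niche_sd: np.ndarray,
    northern_limit: np.ndarray,
    site_lat: np.ndarray,
    exclusion_mult: np.ndarray | None = None,
) -> np.ndarray:
    """P(species s in site i) = thermal x range-disc x northern-limit
    kernels, optionally damped by refugial exclusion of generalists.

    The spatial kernel is a soft disc — a logistic plateau of radius
    ``range_scale`` (per species) with an edge of ``range_edge_km`` — rather
    than a smoothly decaying cloud: a territorial checklist records a
    species wherever its range polygon overlaps the unit, so occupancy
    should be near-certain inside the range and near-impossible outside it.

    The per-species northern range limit models incomplete post-glacial
    recolonisation: species drop out northward in a consistent order, so
    richness declines with latitude while northern assemblages stay nested
    (and hence alike under a turnover-only index).
    """
    thermal = np.exp(
        -((site_t[:, None] - optima[None, :]) ** 2)
        / (2.0 * niche_sd[None, :] ** 2)
    )
    d = np.linalg.norm(site_km[:, None, :] - centers_km[None, :, :], axis=2)
    spatial = 1.0 / (1.0 + np.exp((d - range_scale[None, :]) / config.range_edge_km))
    lat_gap_km = (site_lat[:, None] - northern_limit[None, :]) * _KM_PER_DEG_LAT
    attrition = 1.0 / (1.0 + np.exp(lat_gap_km / config.range_edge_km))
    k = thermal * spatial * attrition
    if exclusion_mult is not None:
        k = k * exclusion_mult
    # sharpen suitability into quasi-deterministic occupancy: territorial
    # inventories are complete checklists, so a clearly suitable unit holds
    # the species almost surely and a marginal one almost surely does not
    s = config.occupancy_sharpness
    if s != 1.0:
        ks = k ** s
        k = ks / (ks + (1.0 - k) ** s)
    return k


def generate_occurrences(
    config: SyntheticConfig, landscape: SiteTable, max_redraws: int = 20
) -> tuple[OccurrenceMatrix, SyntheticTruth]:
    """Draw one occurrence matrix from the latent niche/range model.

    Species never observed anywhere are redrawn (new centre and optimum) up
    to ``max_redraws`` times, then dropped with a warning.  The truth object
    carries the latent assignments, the planted site cluster labels
    (refugium of the nearest refugium for southern sites, 0 for northern
    sites) and the planted decay rates fitted to the expected similarity
    surface.
    """
    rng = _rng(config, 1)
    lat = landscape["Lat"]
    lon = landscape["Long"]
    t_ann = landscape["T_ann"]
    lat0 = float(np.mean(config.lat_span))
    site_km = _site_km_coords(lat, lon, lat0)

    n_sp = config.n_species
    n_end = int(round(config.endemic_fraction * n_sp))
    endemic = np.zeros(n_sp, dtype=bool)
    endemic[:n_end] = True

    ref_centers = _refugium_centers(config, rng, lat, lon)
    ref_km = _site_km_coords(ref_centers[:, 0], ref_centers[:, 1], lat0)

    def draw_species(is_endemic: np.ndarray, refugium: np.ndarray):
        """Centres, thermal optima and range-disc radii for a species batch.

        Endemic centres fall inside their refugium and their disc spans the
        refugium zone; generalist centres are scattered with a southern bias
        (recolonisation spread from the south) and carry large discs of
        variable radius.  Optima track the lapse-line temperature at the
        centre latitude.
        """
        k = len(is_endemic)
        centers = np.empty((k, 2))
        optima = np.empty(k)
        radii = np.empty(k)
        limits = np.empty(k)
        lat_lo, lat_hi = config.lat_span
        lon_lo, lon_hi = config.long_span
        for s in range(k):
            if is_endemic[s]:
                # the refugium footprint IS the endemic's range: every
                # endemic of refugium r shares the zone centred on it
                centers[s] = ref_centers[refugium[s]]
                radii[s] = 2.0 * config.refugium_radius
                # endemics are strictly southern: never beyond the
                # recolonisation latitude, however far the zone reaches
                limits[s] = config.recolonization_lat
            else:
                u = rng.uniform() ** (1.0 + config.southern_center_bias)
                centers[s] = (lat_lo + u * (lat_hi - lat_lo),
                              rng.uniform(lon_lo, lon_hi))
                radii[s] = rng.uniform(0.3, 1.0) * config.generalist_range_km
                # northern range limit: how far recolonisation has reached
                lim_span = config.northern_limit_span or (lat_lo + 4.0, lat_hi + 12.0)
                limits[s] = rng.uniform(*lim_span)
            centers_t = config.temp_at_lat36 + config.temp_lapse * (centers[s, 0] - 36.0)
            optima[s] = centers_t + rng.normal(0.0, 2.0)
        return centers, optima, radii, limits

    refugium = np.where(
        endemic, rng.integers(0, config.n_refugia, size=n_sp), -1
    )
    centers, optima, range_scale, northern_limit = draw_species(endemic, refugium)
    niche_sd = np.where(endemic, config.niche_breadth_sd, config.generalist_niche_sd)

    species_ids = [
        f"end{refugium[s]}_sp{s:03d}" if endemic[s] else f"gen_sp{s:03d}"
        for s in range(n_sp)
    ]

    dropped: list[str] = []
    centers_km = _site_km_coords(centers[:, 0], centers[:, 1], lat0)

    # refugial exclusion: each refugium shuts a random subset of generalists
    # out of its sphere of influence (old, saturated faunas resist
    # recolonisation), so refugial units *substitute* rather than merely add
    # species — turnover visible to a nestedness-blind index
    d_site_ref = np.linalg.norm(site_km[:, None, :] - ref_km[None, :, :], axis=2)
    influence = 1.0 / (1.0 + np.exp(                               # [n_sites, R]
        (d_site_ref - 2.0 * config.refugium_radius) / config.range_edge_km
    ))
    # the saturated old fauna doing the excluding exists only in the south
    south_soft = 1.0 / (1.0 + np.exp(
        (lat - config.recolonization_lat) * _KM_PER_DEG_LAT / config.range_edge_km
    ))
    influence = influence * south_soft[:, None]

    def exclusion_mult(is_endemic: np.ndarray) -> np.ndarray:
        shut = (rng.uniform(size=(len(is_endemic), config.n_refugia))
                < config.refugial_exclusion) & ~is_endemic[:, None]
        return np.prod(1.0 - shut[None, :, :] * influence[:, None, :], axis=2)

    mult = exclusion_mult(endemic)
    prob = _occupancy_probability(
        config, t_ann, site_km, optima, centers_km, range_scale, niche_sd,
        northern_limit, lat, mult,
    )
    inc = (rng.uniform(size=prob.shape) < prob).astype(np.int8)

    for _ in range(max_redraws):
        empty = np.flatnonzero(inc.sum(axis=0) == 0)
        if empty.size == 0:
            break
        c_new, o_new, r_new, l_new = draw_species(endemic[empty], refugium[empty])
        centers[empty] = c_new
        optima[empty] = o_new
        range_scale[empty] = r_new
        northern_limit[empty] = l_new
        ck = _site_km_coords(c_new[:, 0], c_new[:, 1], lat0)
        centers_km[empty] = ck
        p_new = _occupancy_probability(
            config, t_ann, site_km, o_new, ck, r_new,
            niche_sd[empty], l_new, lat, exclusion_mult(endemic[empty]),
        )
        prob[:, empty] = p_new
        inc[:, empty] = (rng.uniform(size=p_new.shape) < p_new).astype(np.int8)
    else:
        empty = np.flatnonzero(inc.sum(axis=0) == 0)
        dropped = [species_ids[s] for s in empty]
        warnings.warn(f"dropping {len(dropped)} never-observed species after redraws")
        keep = inc.sum(axis=0) > 0
        inc = inc[:, keep]
        prob = prob[:, keep]
        centers = centers[keep]
        optima = optima[keep]
        northern_limit = northern_limit[keep]
        endemic = endemic[keep]
        refugium = refugium[keep]
        species_ids = [s for s, k in zip(species_ids, keep) if k]

    # planted site labels: 1..K for southern sites inside a refugium's sphere
    # of influence (2x the endemic range scale, beyond which endemic
    # occupancy has fallen below e^-2), 0 for the widespread generalist pool
    south = lat <= config.recolonization_lat
    in_reach = d_site_ref.min(axis=1) <= 2.0 * config.refugium_radius
    labels = np.where(south & in_reach, d_site_ref.argmin(axis=1) + 1, 0)

    b_south, b_north = _planted_decay_rates(prob, site_km, south)

    occ = OccurrenceMatrix(landscape.site_ids, tuple(species_ids), inc)
    truth = SyntheticTruth(
        species_niche_optima=optima,
        species_range_centers=centers,
        species_northern_limits=northern_limit,
        endemic_flags=endemic,
        refugium_of_species=refugium,
        planted_cluster_labels=labels,
        planted_decay_rate_south=b_south,
        planted_decay_rate_north=b_north,
        dropped_species=tuple(dropped),
    )
    return occ, truth


def _expected_similarity(prob: np.ndarray) -> np.ndarray:
    """Plug-in expected 1 - beta_sim from occupancy probabilities: expected
    matching components a = sum p_i p_j, b/c = sum p(1-p)."""
    a = prob @ prob.T
    r = prob.sum(axis=1)
    b = r[:, None] - a
    c = r[None, :] - a
    m = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(a + m > 0, m / (a + m), 0.0)
    np.fill_diagonal(beta, 0.0)
    return 1.0 - beta


def _planted_decay_rates(
    prob: np.ndarray, site_km: np.ndarray, south: np.ndarray
) -> tuple[float, float]:
    # local import: distance_decay imports nothing from here, no cycle risk
    from .distance_decay import _fit_exponential

    sim = _expected_similarity(prob)
    dist = np.linalg.norm(site_km[:, None, :] - site_km[None, :, :], axis=2)
    rates = []
    for mask in (south, ~south):
        idx = np.flatnonzero(mask)
        if idx.size < 3:
            rates.append(np.nan)
            continue
        iu = np.triu_indices(idx.size, k=1)
        x = dist[np.ix_(idx, idx)][iu]
        y = sim[np.ix_(idx, idx)][iu]
        _, b, _ = _fit_exponential(x, y)
        rates.append(max(b, 1e-12))
    return float(rates[0]), float(rates[1])
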