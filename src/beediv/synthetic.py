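"""Synthetic study systems with known ground truth.

Everything downstream — diversity computation, trait imputation, mixed
models, gridded projection — is exercised against data generated here: a
birth–death phylogeny over a species pool with genus/family structure,
traits evolved on the tree (Brownian motion for continuous, a symmetric
continuous-time Markov chain for categorical), a multi-study network of
sites spanning six collapsed land-use levels, communities whose expected
log effective species diversity follows an injected linear mixed model,
and aligned covariate rasters (land-use fractions, cropland intensity,
human population density, country/subregion IDs).

The generator emulates the *structure* of a European bee site network —
studies with internal blocks, heavy-tailed human population density,
log-scale land-use effects on the order of −0.4 to −0.5 for pasture and
medium/high-intensity cropland — without mimicking real geography or real
bee taxonomy.
"""

from __future__ import annotations

import math
import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.ndimage import gaussian_filter

from ._util import child_seeds, rng_from
from .rasters import FRACTION_CLASSES, LAND_USE_LEVELS, RasterStack

__all__ = [
    "TraitSpec",
    "GroundTruth",
    "simulate_tree",
    "simulate_traits",
    "mask_traits",
    "simulate_sites",
    "simulate_communities",
    "simulate_rasters",
    "default_trait_specs",
    "default_ground_truth",
    "default_landuse_mix",
    "tree_height",
    "is_ultrametric",
]

# ---------------------------------------------------------------------------
# species pool & phylogeny


def tree_height(tree: dendropy.Tree) -> float:
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    return (max(depths) - min(depths)) <= tol


def _enforce_ultrametric(tree: dendropy.Tree) -> None:
    """Absorb floating-point depth drift into terminal branches."""
    h = tree_height(tree)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += h - leaf.distance_from_root()


def _assign_clade_groups(tree: dendropy.Tree, max_size: int, prefix: str) -> dict[str, str]:
    """Name maximal clades of at most ``max_size`` tips; tip label -> group."""
    groups: dict[str, str] = {}
    counter = [0]

    def rec(node):
        leaves = node.leaf_nodes()
        if len(leaves) <= max_size:
            counter[0] += 1
            name = f"{prefix}{counter[0]:03d}"
            for lf in leaves:
                groups[lf.taxon.label] = name
            return
        for child in node.child_nodes():
            rec(child)

    rec(tree.seed_node)
    return groups


def simulate_tree(
    n_species: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    genus_size: int = 5,
    family_size: int = 25,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Simulate an ultrametric birth–death phylogeny over a species pool.

    Returns the tree (tips ``sp0001`` ...) and a pool table with columns
    ``species_id``, ``genus``, ``family``; genera and families are maximal
    clades, so taxonomy is consistent with the phylogeny (which the
    grafting of missing species relies on).
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0 for a viable clade")
    rng = _pyrandom.Random(seed)
    # simulate one extra tip: the process stops at the final birth, which
    # leaves that cherry with zero-length branches; prune one of the pair.
    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_species + 1,
        rng=rng,
        repeat_until_success=True,
    )
    youngest = min(tree.leaf_node_iter(), key=lambda lf: lf.edge.length)
    tree.prune_taxa([youngest.taxon])
    tree.purge_taxon_namespace()
    while len(tree.seed_node.child_nodes()) == 1:
        (child,) = tree.seed_node.child_nodes()
        child.parent_node = None
        tree.seed_node = child
    tree.seed_node.edge.length = None  # drop any stem above the crown
    _enforce_ultrametric(tree)
    # deterministic relabelling in leaf order
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
    if any(e.length is not None and e.length <= 0 for e in tree.edges() if e.tail_node):
        raise RuntimeError("degenerate zero-length branch in simulated tree")
    genera = _assign_clade_groups(tree, genus_size, "G")
    families = _assign_clade_groups(tree, family_size, "F")
    labels = sorted(genera)
    pool = pd.DataFrame(
        {
            "species_id": labels,
            "genus": [genera[s] for s in labels],
            "family": [families[s] for s in labels],
        }
    )
    return tree, pool


# ---------------------------------------------------------------------------
# traits


@dataclass(frozen=True)
class TraitSpec:
    """One trait to evolve on the tree.

    kind 'continuous': Brownian motion with variance ``rate`` per unit
    branch length around ``root``. kind 'categorical': symmetric CTMC with
    total leave-rate ``rate`` over ``levels``.
    """

    name: str
    kind: str  # 'continuous' | 'categorical'
    rate: float = 1.0
    root: float = 0.0
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError("categorical trait needs >= 2 levels")


def default_trait_specs() -> list[TraitSpec]:
    """Bee-like trait battery: body size, flight season, diet breadth,
    nesting strategy, sociality."""
    return [
        TraitSpec("body_size_mm", "continuous", rate=4.0, root=10.0),
        TraitSpec("flight_season_weeks", "continuous", rate=9.0, root=16.0),
        TraitSpec("diet_breadth", "continuous", rate=2.0, root=5.0),
        TraitSpec("nesting", "categorical", rate=0.15, levels=("ground", "cavity", "stem", "parasitic")),
        TraitSpec("sociality", "categorical", rate=0.15, levels=("solitary", "social", "polymorphic")),
    ]


def _brownian_tips(tree: dendropy.Tree, rate: float, root: float, rng: np.random.Generator) -> dict[str, float]:
    values: dict[int, float] = {id(tree.seed_node): root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, math.sqrt(max(rate, 0.0) * node.edge.length))
    return {lf.taxon.label: values[id(lf)] for lf in tree.leaf_node_iter()}


def _ctmc_tips(
    tree: dendropy.Tree, rate: float, levels: tuple[str, ...], rng: np.random.Generator
) -> dict[str, str]:
    k = len(levels)
    states: dict[int, int] = {id(tree.seed_node): int(rng.integers(k))}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = states[id(node.parent_node)]
        # symmetric k-state chain: P(stay) = e^{-qt} + (1 - e^{-qt})/k
        # with q = rate * k/(k-1)
        q = rate * k / (k - 1)
        stay = math.exp(-q * node.edge.length)
        if rng.random() < stay:
            states[id(node)] = s
        else:
            states[id(node)] = int(rng.integers(k))
    return {lf.taxon.label: levels[states[id(lf)]] for lf in tree.leaf_node_iter()}


def simulate_traits(
    tree: dendropy.Tree, specs: list[TraitSpec] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Evolve traits on the tree; returns a complete species × trait table
    indexed by ``species_id`` with phylogenetic signal in every trait."""
    if specs is None:
        specs = default_trait_specs()
    if not specs:
        raise ValueError("empty trait specification")
    rng = rng_from(seed)
    cols: dict[str, dict] = {}
    for spec in specs:
        if spec.kind == "continuous":
            cols[spec.name] = _brownian_tips(tree, spec.rate, spec.root, rng)
        else:
            cols[spec.name] = _ctmc_tips(tree, spec.rate, spec.levels, rng)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    out = pd.DataFrame({name: [vals[s] for s in labels] for name, vals in cols.items()}, index=labels)
    out.index.name = "species_id"
    return out


def mask_traits(
    traits: pd.DataFrame, frac_partial: float, frac_total: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Knock out trait cells: ``round(frac_partial*S)`` species lose at
    least one (but not every) cell, ``round(frac_total*S)`` species lose
    all cells. Returns (masked table, boolean mask of masked cells)."""
    for f in (frac_partial, frac_total):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    if frac_partial + frac_total > 1:
        raise ValueError("frac_partial + frac_total must be <= 1")
    rng = rng_from(seed)
    S, T = traits.shape
    n_total = round(frac_total * S)
    n_partial = round(frac_partial * S)
    order = rng.permutation(S)
    total_idx = order[:n_total]
    partial_idx = order[n_total : n_total + n_partial]
    mask = pd.DataFrame(False, index=traits.index, columns=traits.columns)
    mask.iloc[total_idx, :] = True
    for i in partial_idx:
        n_cells = int(rng.integers(1, T)) if T > 1 else 1
        cells = rng.choice(T, size=n_cells, replace=False)
        mask.iloc[i, cells] = True
    masked = traits.copy()
    for col in traits.columns:
        masked[col] = masked[col].where(~mask[col], other=np.nan)
    return masked, mask


# ---------------------------------------------------------------------------
# sites & communities


def default_landuse_mix() -> dict[str, float]:
    """Mix of sites across the six collapsed land-use levels, proportional
    to a realistic multi-study network dominated by cropland."""
    counts = {
        "seminatural": 121,
        "pasture": 76,
        "cropland_low": 208,
        "cropland_medium": 417,
        "cropland_high": 577,
        "urban": 47,
    }
    tot = sum(counts.values())
    return {k: v / tot for k, v in counts.items()}


def simulate_sites(
    n_studies: int = 10,
    sites_per_study: int = 20,
    landuse_mix: dict[str, float] | None = None,
    seed: int = 0,
    n_subregions: int = 4,
    block_size: int = 5,
) -> pd.DataFrame:
    """Simulate a multi-study site network.

    Sites are nested in studies, each study partitioned into spatial
    blocks of ``block_size`` sites. Human population density and distance
    to roads are log-normal (heavy-tailed, like the real covariates);
    coordinates are jittered around a per-study cluster centre. Sampling
    effort varies among sites within a study.
    """
    mix = default_landuse_mix() if landuse_mix is None else dict(landuse_mix)
    if set(mix) != set(LAND_USE_LEVELS):
        raise ValueError(f"landuse_mix must cover exactly {LAND_USE_LEVELS}")
    probs = np.array([mix[k] for k in LAND_USE_LEVELS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("landuse_mix proportions must sum to 1")
    rng = rng_from(seed)
    rows = []
    for s in range(n_studies):
        study = f"study{s + 1:02d}"
        subregion = f"SR{s % n_subregions + 1}"
        cx, cy = rng.uniform(0, 1000, size=2)
        for i in range(sites_per_study):
            lu = LAND_USE_LEVELS[int(rng.choice(len(LAND_USE_LEVELS), p=probs))]
            rows.append(
                {
                    "site_id": f"{study}_site{i + 1:03d}",
                    "study_id": study,
                    "block_id": f"{study}_b{i // block_size + 1:02d}",
                    "land_use": lu,
                    # median 50 persons/km2, heavy right tail
                    "hpd": float(rng.lognormal(mean=math.log(50.0), sigma=1.2)),
                    "dist_roads": float(rng.lognormal(mean=0.0, sigma=1.0)),
                    "subregion": subregion,
                    "x": float(cx + rng.normal(0, 2.0)),
                    "y": float(cy + rng.normal(0, 2.0)),
                    "effort": float(rng.integers(1, 6)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Injected effects the downstream models should recover.

    Land-use effects are offsets from the semi-natural baseline: on the
    natural-log scale of effective species number for the species facet,
    on the identity (effective-number) scale for the functional and
    phylogenetic facets. ``hpd_slopes`` act on centred log1p(HPD).
    ``filter_signal`` in [0, 1] is the phylogenetic correlation of species'
    land-use sensitivities: at 0 species drop out at random (facets move
    together), at 1 whole clades drop out first (functional/phylogenetic
    losses diverge from species losses).
    """

    lu_effects_sd: dict[str, float] = field(
        default_factory=lambda: {
            "seminatural": 0.0,
            "pasture": -0.39,
            "cropland_low": -0.10,
            "cropland_medium": -0.50,
            "cropland_high": -0.48,
            "urban": -0.06,
        }
    )
    lu_effects_fd: dict[str, float] = field(
        default_factory=lambda: {
            "seminatural": 0.0,
            "pasture": -0.25,
            "cropland_low": -0.05,
            "cropland_medium": -0.35,
            "cropland_high": -0.30,
            "urban": -0.12,
        }
    )
    lu_effects_pd: dict[str, float] = field(
        default_factory=lambda: {
            "seminatural": 0.0,
            "pasture": -0.30,
            "cropland_low": -0.06,
            "cropland_medium": -0.40,
            "cropland_high": -0.36,
            "urban": -0.15,
        }
    )
    hpd_slopes: dict[str, float] = field(default_factory=lambda: {k: 0.0 for k in LAND_USE_LEVELS})
    roads_slope: float = 0.0
    baseline_ln_e_sd: float = math.log(8.0)
    baseline_e_fd: float = 3.0
    baseline_e_pd: float = 3.5
    sd_study: float = 0.25
    sd_slope: float = 0.0
    sd_block: float = 0.10
    sd_resid: float = 0.30
    filter_signal: float = 0.6

    def __post_init__(self):
        for v in (self.sd_study, self.sd_slope, self.sd_block, self.sd_resid):
            if v < 0:
                raise ValueError("variance components must be >= 0")
        for d in (self.lu_effects_sd, self.lu_effects_fd, self.lu_effects_pd, self.hpd_slopes):
            missing = set(LAND_USE_LEVELS) - set(d)
            if missing:
                raise ValueError(f"ground truth missing land-use level(s): {sorted(missing)}")


def default_ground_truth(**overrides) -> GroundTruth:
    return GroundTruth(**overrides)


def _dominance_profile(n: int, target_e: float) -> np.ndarray:
    """Relative abundances of n species whose inverse Simpson index equals
    ``target_e`` exactly: one dominant species, the rest equiabundant."""
    if n == 1 or target_e <= 1.0 + 1e-12:
        return np.array([1.0])
    target_e = min(target_e, float(n) - 1e-12)
    m = n - 1
    # solve a^2 + (1-a)^2/m = 1/E for the dominant share a in [1/n, 1]
    A = 1.0 + 1.0 / m
    B = -2.0 / m
    C = 1.0 / m - 1.0 / target_e
    disc = B * B - 4 * A * C
    a = (-B + math.sqrt(max(disc, 0.0))) / (2 * A)
    a = min(max(a, 1.0 / n), 1.0)
    p = np.full(n, (1.0 - a) / m)
    p[0] = a
    return p


def simulate_communities(
    sites: pd.DataFrame,
    pool: pd.DataFrame,
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw site communities so that the expected log effective species
    diversity at a site equals the injected linear predictor.

    The site's inverse Simpson index is matched *exactly* to
    exp(linear predictor + residual), by construction of the abundance
    profile; which species make up the community is driven by a
    phylogenetically correlated sensitivity score, so that harsher land
    uses filter out related species together and the functional and
    phylogenetic facets respond differently from the species facet.

    Returns a long table site_id × species_id with raw (pre effort
    correction) abundances.
    """
    truth = truth or GroundTruth()
    rng = rng_from(seed)
    S = len(pool)
    species = list(pool["species_id"])
    # phylogenetically correlated sensitivity (higher = more tolerant)
    z_phylo = _brownian_tips(tree, rate=1.0 / max(tree_height(tree), 1e-9), root=0.0, rng=rng)
    zp = np.array([z_phylo[s] for s in species])
    zp = (zp - zp.mean()) / max(zp.std(), 1e-12)
    lam = truth.filter_signal
    z = lam * zp + math.sqrt(max(1 - lam * lam, 0.0)) * rng.normal(size=S)

    hpd_c = np.log1p(sites["hpd"].to_numpy())
    hpd_c = hpd_c - hpd_c.mean()
    roads_c = np.log1p(sites["dist_roads"].to_numpy())
    roads_c = roads_c - roads_c.mean()

    studies = sites["study_id"].unique()
    u_study = dict(zip(studies, rng.normal(0, truth.sd_study, len(studies))))
    v_study = dict(zip(studies, rng.normal(0, truth.sd_slope, len(studies))))
    blocks = sites["block_id"].unique()
    u_block = dict(zip(blocks, rng.normal(0, truth.sd_block, len(blocks))))
    max_effort = sites.groupby("study_id")["effort"].transform("max").to_numpy()

    records = []
    for i, row in enumerate(sites.itertuples(index=False)):
        lu = row.land_use
        eta = (
            truth.baseline_ln_e_sd
            + truth.lu_effects_sd[lu]
            + (truth.hpd_slopes[lu] + v_study[row.study_id]) * hpd_c[i]
            + truth.roads_slope * roads_c[i]
            + u_study[row.study_id]
            + u_block[row.block_id]
            + rng.normal(0, truth.sd_resid)
        )
        target_e = min(max(math.exp(eta), 1.0), S - 2.0)
        n_present = min(S, int(math.ceil(target_e)) + 5)
        # severity of ecological filtering scales with the injected loss
        severity = -truth.lu_effects_sd[lu] * 3.0
        scores = severity * z + rng.gumbel(size=S)
        present = np.argsort(scores)[::-1][:n_present]
        p = _dominance_profile(n_present, target_e)
        present = present[: len(p)]
        total = 100.0 * row.effort / max_effort[i]
        for j, sp_idx in enumerate(present):
            records.append(
                {
                    "site_id": row.site_id,
                    "species_id": species[sp_idx],
                    "abundance": float(p[j] * total),
                }
            )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# rasters


def _smooth_positive_field(shape, rng, sigma=3.0):
    f = gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="wrap")
    sd = f.std() if f.std() > 0 else 1.0
    return f / sd


def simulate_rasters(
    shape: tuple[int, int] = (40, 50),
    n_countries: int = 5,
    seed: int = 0,
    n_subregions: int = 4,
    cellsize: float = 1.0,
) -> RasterStack:
    """Generate an aligned covariate stack over a rows × cols grid.

    Per cell: land-use class fractions (>= 0, summing to 1) with spatial
    autocorrelation; a use-intensity class over {other, extensive/intensive
    pasture, light/moderate/intensive cropland}; log-normal human
    population density; contiguous country regions (Voronoi partition of
    random seed points) and a subregion ID derived from the country.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError("raster extent must be at least 1 x 1")
    rng = rng_from(seed)
    alphas = {
        "primary": 0.9,
        "secondary": 0.5,
        "cropland": 1.4,
        "plantation": 0.15,
        "pasture": 0.8,
        "urban": 0.25,
    }
    raw = {}
    for cls in FRACTION_CLASSES:
        field_ = _smooth_positive_field((rows, cols), rng)
        raw[cls] = alphas[cls] * np.exp(field_)
    total = sum(raw.values())
    fractions = {cls: raw[cls] / total for cls in FRACTION_CLASSES}

    hpd = np.exp(math.log(20.0) + 1.2 * _smooth_positive_field((rows, cols), rng))

    # intensity: cropland cells tiled into light/moderate/intensive by a
    # smooth field; pasture-dominated cells get pasture classes; the rest
    # 'other' (incl. many cells that do contain a little cropland).
    intens_field = _smooth_positive_field((rows, cols), rng, sigma=2.0)
    terciles = np.quantile(intens_field, [1 / 3, 2 / 3])
    crop_code = np.digitize(intens_field, terciles) + 3  # 3,4,5
    intensity = np.zeros((rows, cols))
    crop_dominant = fractions["cropland"] > 0.25
    pasture_dominant = (~crop_dominant) & (fractions["pasture"] > 0.30)
    intensity[crop_dominant] = crop_code[crop_dominant]
    intensity[pasture_dominant] = np.where(hpd[pasture_dominant] > 20.0, 2, 1)

    yy, xx = np.mgrid[0:rows, 0:cols]
    pts = np.column_stack([rng.uniform(0, rows, n_countries), rng.uniform(0, cols, n_countries)])
    d2 = (yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2
    country = np.argmin(d2, axis=-1) + 1.0
    subregion = (country - 1) % n_subregions + 1.0

    layers = {f"frac_{cls}": fractions[cls] for cls in FRACTION_CLASSES}
    layers.update(
        {
            "intensity_class": intensity.astype(float),
            "hpd": hpd,
            "country_id": country,
            "subregion_id": subregion,
        }
    )
    return RasterStack(layers=layers, cellsize=cellsize)
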