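"""Species, functional and phylogenetic diversity via Rao's quadratic entropy.

One framework covers all three facets: for a site with relative
abundances p and a species dissimilarity matrix D scaled to [0, 1],

    Q = sum_ij d_ij p_i p_j           (quadratic entropy)
    E = 1 / (1 - Q)                   (effective number of species)

The facet is set by D: unit distances (species diversity, where Q is the
Gini–Simpson index and E the inverse Simpson index), square-root-corrected
Gower trait dissimilarities (functional), or half-cophenetic phylogenetic
distances rescaled by their maximum (phylogenetic, averaged over a sample
of trees to absorb uncertainty in the placement of grafted species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "effort_correct",
    "species_distances",
    "gower_distances",
    "phylo_distances",
    "rao_q",
    "effective_number",
    "site_diversity",
    "community_matrix",
]


@dataclass
class DistanceMatrix:
    """Square symmetric species dissimilarities in [0, 1]."""

    species: list[str]
    matrix: np.ndarray
    facet: str  # 'species' | 'functional' | 'phylogenetic'

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("self-distances must be zero")
        if m.min() < -1e-12 or m.max() > 1 + 1e-9:
            raise ValueError("distances must lie in [0, 1]")
        self.matrix = m

    def reindex(self, species: list[str]) -> np.ndarray:
        """Submatrix in the requested species order."""
        pos = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in pos]
        if missing:
            raise KeyError(f"species absent from {self.facet} distances: {missing[:5]}")
        idx = np.array([pos[s] for s in species])
        return self.matrix[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# sampling-effort correction


def effort_correct(comm: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Rescale abundances assuming they increase linearly with sampling
    effort: within each study, every site is brought up to the study's
    maximum effort (abundance × max-effort / site-effort)."""
    meta = sites.set_index("site_id")[["study_id", "effort"]]
    unknown = set(comm["site_id"]) - set(meta.index)
    if unknown:
        raise KeyError(f"sites missing from site table: {sorted(unknown)[:5]}")
    if (meta["effort"] <= 0).any():
        raise ValueError("all sampling efforts must be > 0")
    out = comm.merge(meta, left_on="site_id", right_index=True, how="left")
    max_effort = out.groupby("study_id")["effort"].transform("max")
    out["abundance"] = out["abundance"] * max_effort / out["effort"]
    return out[list(comm.columns)]


# ---------------------------------------------------------------------------
# distance constructions


def species_distances(species: list[str] | pd.Index) -> DistanceMatrix:
    """Unit distances: every species fully distinct (Rao's Q reduces to the
    Gini–Simpson index)."""
    species = list(species)
    if len(set(species)) != len(species):
        raise ValueError("duplicate species ids")
    n = len(species)
    m = np.ones((n, n)) - np.eye(n)
    return DistanceMatrix(species, m, "species")


def gower_distances(traits: pd.DataFrame, sqrt_correction: bool = True) -> DistanceMatrix:
    """Gower dissimilarity over mixed trait types.

    Continuous traits contribute range-normalized absolute differences
    (ranges taken over the full species pool so distances are consistent
    across sites); categorical traits contribute 0/1 mismatches. The
    per-trait contributions are averaged, then the square-root correction
    is applied so the matrix has Euclidean properties. Missing values are
    handled by pairwise deletion over available traits (the main pipeline
    imputes first, so this matters only for diagnostic use).
    """
    n = len(traits)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used_any = False
    for col in traits.columns:
        s = traits[col]
        if pd.api.types.is_numeric_dtype(s):
            v = s.to_numpy(dtype=float)
            obs = np.isfinite(v)
            rng_ = np.nanmax(v) - np.nanmin(v) if obs.any() else 0.0
            if rng_ == 0 or not np.isfinite(rng_):
                warnings.warn(f"continuous trait {col!r} has zero range; excluded from Gower")
                continue
            diff = np.abs(v[:, None] - v[None, :]) / rng_
            w = obs[:, None] & obs[None, :]
            num += np.where(w, np.nan_to_num(diff), 0.0)
            den += w
        else:
            v = s.to_numpy(dtype=object)
            obs = np.array([x is not None and x == x for x in v])
            mismatch = (v[:, None] != v[None, :]).astype(float)
            w = obs[:, None] & obs[None, :]
            num += np.where(w, mismatch, 0.0)
            den += w
        used_any = True
    if not used_any:
        raise ValueError("no usable traits for Gower distances")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    if sqrt_correction:
        d = np.sqrt(d)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(list(traits.index), d, "functional")


def phylo_distances(tree: dendropy.Tree, species: list[str] | None = None) -> DistanceMatrix:
    """Half-cophenetic distances (distance to the most recent common
    ancestor on an ultrametric tree), rescaled by the matrix maximum so the
    entries lie in [0, 1] as the effective-number transform requires."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label}
    if species is None:
        species = sorted(taxa)
    missing = [s for s in species if s not in taxa]
    if missing:
        raise KeyError(f"species absent from tree: {missing[:5]}")
    n = len(species)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[species[i]], taxa[species[j]]) / 2.0
    mx = m.max()
    if mx > 0:
        m = m / mx
    return DistanceMatrix(list(species), m, "phylogenetic")


# ---------------------------------------------------------------------------
# entropies


def rao_q(p: np.ndarray, d: np.ndarray | DistanceMatrix) -> float:
    """Quadratic entropy Q = sum_ij d_ij p_i p_j for one community."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12):
        raise ValueError("negative relative abundances")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"relative abundances sum to {p.sum():.6f}, not 1")
    m = d.matrix if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if m.shape[0] != p.size:
        raise ValueError("abundance vector not aligned with distance matrix")
    return float(p @ m @ p)


def effective_number(q: float | np.ndarray) -> float | np.ndarray:
    """E = 1/(1-Q): the number of equally abundant, maximally distinct
    species giving the same entropy."""
    q = np.asarray(q, dtype=float)
    if np.any(q < -1e-12) or np.any(q >= 1.0):
        raise ValueError("Q must lie in [0, 1); rescale the distance matrix")
    e = 1.0 / (1.0 - q)
    return float(e) if e.ndim == 0 else e


def community_matrix(comm: pd.DataFrame) -> tuple[pd.Index, list[str], np.ndarray]:
    """Pivot a long community table to site × species relative abundances."""
    wide = comm.pivot_table(
        index="site_id", columns="species_id", values="abundance", aggfunc="sum", fill_value=0.0
    )
    a = wide.to_numpy(dtype=float)
    if np.any(a < 0):
        raise ValueError("negative abundances")
    tot = a.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        empty = wide.index[(a.sum(axis=1) <= 0)]
        raise ValueError(f"sites with no positive abundance: {list(empty)[:5]}")
    return wide.index, list(wide.columns), a / tot


def _q_all_sites(p: np.ndarray, m: np.ndarray) -> np.ndarray:
    return np.einsum("si,ij,sj->s", p, m, p)


def site_diversity(
    comm: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    trees: list[dendropy.Tree] | None = None,
    average: str = "Q",
) -> pd.DataFrame:
    """Per-site Q and E for every requested facet.

    Species diversity always; functional if ``traits`` given; phylogenetic
    if ``trees`` given, in which case Q is averaged across the tree sample
    before the effective-number transform (``average='Q'``, the default)
    or E is averaged after it (``average='E'``).
    """
    if average not in ("Q", "E"):
        raise ValueError("average must be 'Q' or 'E'")
    sites, species, p = community_matrix(comm)
    out = pd.DataFrame({"site_id": sites})

    q_sd = _q_all_sites(p, species_distances(species).matrix)
    out["Q_sd"] = q_sd
    out["E_sd"] = effective_number(q_sd)

    if traits is not None:
        missing = set(species) - set(traits.index)
        if missing:
            raise KeyError(f"species missing from trait table: {sorted(missing)[:5]}")
        d_fd = gower_distances(traits.loc[species])
        q_fd = _q_all_sites(p, d_fd.matrix)
        out["Q_fd"] = q_fd
        out["E_fd"] = effective_number(q_fd)

    if trees:
        qs = np.stack([_q_all_sites(p, phylo_distances(t, species).matrix) for t in trees])
        if average == "Q":
            q_pd = qs.mean(axis=0)
            e_pd = effective_number(q_pd)
        else:
            q_pd = qs.mean(axis=0)
            e_pd = np.mean([effective_number(q) for q in qs], axis=0)
        out["Q_pd"] = q_pd
        out["E_pd"] = e_pd

    return out
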