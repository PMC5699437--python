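"""Phylogeny-assisted trait imputation and completion of the species pool.

Missing trait values are imputed with an iterative random-forest scheme
(the missForest algorithm): each incompletely observed trait is regressed
on all other traits plus phylogenetic eigenvectors — principal-coordinate
axes of the species' phylogenetic distance matrix — and imputations are
refined until the change in imputed values first increases. Out-of-bag
errors summarize accuracy as NRMSE (continuous) and the proportion of
falsely classified cells (categorical); both run from 0 (good) to ~1
(poor).

Species absent from the phylogeny are grafted into their genus (fallback:
family) clade at a uniformly random depth, preserving ultrametricity; a
sample of grafted trees propagates placement uncertainty downstream.
"""

from __future__ import annotations

import random as _pyrandom
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

__all__ = [
    "ImputationReport",
    "phylo_eigenvectors",
    "impute_traits",
    "nrmse",
    "pfc",
    "graft_missing_species",
    "sample_trees",
]


@dataclass
class ImputationReport:
    nrmse: float
    pfc: float
    iterations: int

    def __post_init__(self):
        if self.nrmse < 0:
            raise ValueError("nrmse must be >= 0")
        if not 0 <= self.pfc <= 1:
            raise ValueError("pfc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# phylogenetic eigenvectors


def phylo_eigenvectors(
    tree: dendropy.Tree,
    k: int | None = None,
    var_explained: float = 0.6,
    cap: int = 30,
) -> pd.DataFrame:
    """Principal-coordinate axes of the pairwise phylogenetic distances.

    If ``k`` is None, retains the leading axes explaining ``var_explained``
    of the (positive) eigenvalue mass, capped at ``cap``. Axes are centred,
    mutually orthogonal and ordered by decreasing eigenvalue.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t for t in tree.taxon_namespace if t.label), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    if k is not None and k >= n:
        raise ValueError("k must be smaller than the number of tips")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[i], taxa[j]) / 2.0
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite phylogenetic distances")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ord_res = pcoa(_SkbioDM(m, ids=labels), method="eigh", warn_neg_eigval=False)
    coords = ord_res.samples.to_numpy()
    prop = ord_res.proportion_explained.to_numpy()
    if k is None:
        k = int(np.searchsorted(np.cumsum(prop), var_explained) + 1)
        k = min(max(k, 1), cap, n - 1)
    ev = pd.DataFrame(
        coords[:, :k], index=pd.Index(labels, name="species_id"),
        columns=[f"phylo_ev{i + 1}" for i in range(k)],
    )
    return ev


# ---------------------------------------------------------------------------
# missForest-style iterative imputation


def nrmse(true: np.ndarray, imputed: np.ndarray) -> float:
    """Normalized RMSE: sqrt(mean squared error / variance of the truth)."""
    true = np.asarray(true, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    v = true.var()
    if v == 0:
        raise ValueError("zero variance in true values; NRMSE undefined")
    return float(np.sqrt(np.mean((true - imputed) ** 2) / v))


def pfc(true: np.ndarray, imputed: np.ndarray) -> float:
    """Proportion of categorical cells falsely classified."""
    true = np.asarray(true, dtype=object)
    imputed = np.asarray(imputed, dtype=object)
    if true.size == 0:
        raise ValueError("no categorical cells to score")
    return float(np.mean(true != imputed))


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def impute_traits(
    traits: pd.DataFrame,
    eigenvectors: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 10,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Iterative random-forest imputation of missing trait cells.

    Missing cells start at the column mean (continuous) or mode
    (categorical). Traits are then revisited in order of increasing
    missingness; each is modelled on all other traits plus the
    phylogenetic eigenvectors, and its missing cells are re-predicted.
    Iteration stops when the aggregate change in imputed values first
    increases (the previous iterate is returned) or after ``max_iter``
    passes. Observed cells are never altered. Accuracy is reported from
    out-of-bag predictions on the observed cells of incomplete traits.
    """
    if not set(traits.index) <= set(eigenvectors.index):
        raise ValueError("eigenvectors must cover every species in the trait table")
    eig = eigenvectors.loc[traits.index]
    mask = traits.isna()
    fully_missing = [c for c in traits.columns if mask[c].all()]
    if fully_missing:
        raise ValueError(f"trait(s) entirely missing, cannot impute: {fully_missing}")
    if not mask.any().any():
        return traits.copy(), ImputationReport(0.0, 0.0, 0)

    rng = np.random.default_rng(seed)
    work = traits.copy()
    numeric_cols = [c for c in traits.columns if _is_numeric(traits[c])]
    for c in traits.columns:
        if mask[c].any():
            if c in numeric_cols:
                work.loc[mask[c], c] = traits[c].mean()
            else:
                work.loc[mask[c], c] = traits[c].mode(dropna=True).iloc[0]

    def design(exclude: str) -> np.ndarray:
        parts = [eig.to_numpy(dtype=float)]
        for c in traits.columns:
            if c == exclude:
                continue
            if c in numeric_cols:
                parts.append(work[c].to_numpy(dtype=float)[:, None])
            else:
                parts.append(pd.get_dummies(work[c]).to_numpy(dtype=float))
        return np.hstack(parts)

    order = [c for c in mask.sum().sort_values().index if mask[c].any()]
    prev = work.copy()
    prev_delta = np.inf
    oob_num: dict[str, float] = {}
    oob_cat: dict[str, tuple[float, int]] = {}
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        for c in order:
            obs = ~mask[c]
            X = design(c)
            if c in numeric_cols:
                model = RandomForestRegressor(
                    n_estimators=n_estimators,
                    oob_score=True,
                    random_state=int(rng.integers(2**31)),
                    bootstrap=True,
                )
                model.fit(X[obs.to_numpy()], work.loc[obs, c].to_numpy(dtype=float))
                work.loc[mask[c], c] = model.predict(X[mask[c].to_numpy()])
                y = work.loc[obs, c].to_numpy(dtype=float)
                oob_num[c] = nrmse(y, model.oob_prediction_) if y.var() > 0 else 0.0
            else:
                model = RandomForestClassifier(
                    n_estimators=n_estimators,
                    oob_score=True,
                    random_state=int(rng.integers(2**31)),
                    bootstrap=True,
                )
                y = work.loc[obs, c].to_numpy(dtype=object)
                model.fit(X[obs.to_numpy()], y)
                work.loc[mask[c], c] = model.predict(X[mask[c].to_numpy()])
                oob_cat[c] = (1.0 - float(model.oob_score_), int(obs.sum()))
        # missForest stopping rule: stop when the change first increases
        d_num = 0.0
        for c in order:
            if c in numeric_cols:
                new = work.loc[mask[c], c].to_numpy(dtype=float)
                old = prev.loc[mask[c], c].to_numpy(dtype=float)
                denom = np.sum(work[c].to_numpy(dtype=float) ** 2)
                d_num += np.sum((new - old) ** 2) / max(denom, 1e-12)
            else:
                new = work.loc[mask[c], c].to_numpy(dtype=object)
                old = prev.loc[mask[c], c].to_numpy(dtype=object)
                d_num += np.mean(new != old) if new.size else 0.0
        if d_num >= prev_delta:
            work = prev  # keep the better (previous) iterate
            iterations = it - 1
            break
        prev = work.copy()
        prev_delta = d_num
        if d_num == 0.0:
            break

    rep_nrmse = float(np.mean(list(oob_num.values()))) if oob_num else 0.0
    if oob_cat:
        tot = sum(n for _, n in oob_cat.values())
        rep_pfc = float(sum(e * n for e, n in oob_cat.values()) / tot)
    else:
        rep_pfc = 0.0
    # observed cells must be untouched
    for c in traits.columns:
        obs = ~mask[c]
        if c in numeric_cols:
            assert np.allclose(
                work.loc[obs, c].astype(float), traits.loc[obs, c].astype(float)
            )
        else:
            assert (work.loc[obs, c] == traits.loc[obs, c]).all()
    return work, ImputationReport(rep_nrmse, min(rep_pfc, 1.0), iterations)


# ---------------------------------------------------------------------------
# grafting species missing from the phylogeny


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def _graft_one(tree: dendropy.Tree, species: str, anchors: list[str], rng: _pyrandom.Random) -> None:
    """Attach ``species`` at a uniformly random point within the clade
    spanned by ``anchors``, keeping the tree ultrametric."""
    anchor_nodes = [tree.find_node_with_taxon_label(a) for a in anchors]
    if len(anchor_nodes) == 1:
        clade_root = anchor_nodes[0]
    else:
        clade_root = tree.mrca(taxa=[n.taxon for n in anchor_nodes])
    depths = _node_depths(tree)
    height = max(depths[lf] for lf in tree.leaf_node_iter())
    # candidate attachment edges: everything inside the clade plus its stem
    nodes = list(clade_root.preorder_iter())
    edges = [n.edge for n in nodes if n.edge.tail_node is not None]
    lengths = [e.length for e in edges]
    total = sum(lengths)
    if total <= 0:
        raise ValueError(f"no positive-length edges to graft {species!r} onto")
    u = rng.random() * total
    acc = 0.0
    edge = edges[-1]
    for e, ln in zip(edges, lengths):
        acc += ln
        if u <= acc:
            edge = e
            break
    child = edge.head_node
    tail = edge.tail_node
    d_child = depths[child]
    d_tail = d_child - edge.length
    attach_depth = d_tail + rng.random() * edge.length
    # split the edge at attach_depth and hang the new tip
    tail.remove_child(child)
    joint = tail.new_child(edge_length=attach_depth - d_tail)
    joint.add_child(child)
    child.edge.length = d_child - attach_depth
    taxon = dendropy.Taxon(label=species)
    tree.taxon_namespace.add_taxon(taxon)
    joint.new_child(taxon=taxon, edge_length=height - attach_depth)


def graft_missing_species(
    tree: dendropy.Tree,
    pool: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Produce ``n_trees`` complete trees by grafting pool species missing
    from the phylogeny into their genus clade (fallback: family clade) at a
    uniformly random, ultrametricity-preserving position. Placement varies
    independently across output trees."""
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = pool[~pool["species_id"].isin(tip_labels)]
    by_id = pool.set_index("species_id")
    plans: list[tuple[str, list[str]]] = []
    for sp in missing["species_id"]:
        genus, family = by_id.loc[sp, "genus"], by_id.loc[sp, "family"]
        congeners = [
            s for s in by_id.index[by_id["genus"] == genus] if s in tip_labels and s != sp
        ]
        if congeners:
            plans.append((sp, congeners))
            continue
        confamilials = [
            s for s in by_id.index[by_id["family"] == family] if s in tip_labels and s != sp
        ]
        if not confamilials:
            raise ValueError(f"species {sp!r} has no congeneric or confamilial anchor in the tree")
        plans.append((sp, confamilials))

    rng = _pyrandom.Random(seed)
    newick = tree.as_string(schema="newick")
    out = []
    for _ in range(n_trees):
        # round-trip through Newick so every output tree owns its namespace
        t = dendropy.Tree.get(data=newick, schema="newick")
        for sp, anchors in plans:
            _graft_one(t, sp, anchors, rng)
        out.append(t)
    return out


def sample_trees(trees: list[dendropy.Tree], n: int, seed: int = 0) -> list[dendropy.Tree]:
    """Uniform sample of ``n`` distinct trees without replacement."""
    if n > len(trees):
        raise ValueError(f"requested {n} trees but only {len(trees)} available")
    rng = _pyrandom.Random(seed)
    return [trees[i] for i in sorted(rng.sample(range(len(trees)), n))]


# ---------------------------------------------------------------------------
# multi-tree Newick I/O (one tree per line)


def write_trees(trees: list[dendropy.Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


def read_trees(path) -> list[dendropy.Tree]:
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(tl)
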