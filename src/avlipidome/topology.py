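"""Structure-aware lipidome topology (UMAP embedding).

Feature matrix per lipid species: a z-scored abundance block, min-max
scaled chain features (total carbons, double bonds), and a structural
block derived from pairwise maximum-common-edge-subgraph (MCES)
distances between class backbone structures (acyl chains stripped),
reduced by PCA to its top 5 components and min-max scaled. Per-block
weight factors rescale each block before the 2-D UMAP embedding.

The MCES distance between two labeled molecular graphs is
``|E1| + |E2| - 2 |MCES|`` — the number of edges outside a maximum
common edge subgraph. It is computed exactly by branch-and-bound over
edge matchings with a consistent vertex map; backbones are small enough
(< ~35 bonds) for this to terminate, and a precomputed matrix for the
packaged panel ships with the repository.
"""

from __future__ import annotations

import logging
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler

from .errors import MissingFeature, UnparsableStructure

logger = logging.getLogger(__name__)

__all__ = [
    "smiles_to_graph",
    "mces_size",
    "mces_distance",
    "backbone_distances",
    "load_backbone_structures",
    "load_default_backbone_distances",
    "pca_top",
    "build_feature_matrix",
    "embed_2d",
]


def smiles_to_graph(smiles: str) -> nx.Graph:
    """Labeled molecular graph (heavy atoms): node 'element', edge 'order'."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparsableStructure(f"cannot parse SMILES {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=float(bond.GetBondTypeAsDouble()),
        )
    return g


def _edge_label(g: nx.Graph, e) -> float:
    return g.edges[e].get("order", 1.0)


def _node_label(g: nx.Graph, v) -> str:
    return g.nodes[v].get("element", "C")


def _edge_class(g: nx.Graph, e) -> tuple:
    """Matching class of an edge: bond order + sorted endpoint elements."""
    a, b = e
    return (
        _edge_label(g, e),
        tuple(sorted((_node_label(g, a), _node_label(g, b)))),
    )


def mces_size(g1: nx.Graph, g2: nx.Graph) -> int:
    """Edge count of a maximum common edge subgraph (exact).

    Common subgraphs may be disconnected; node ('element') and edge
    ('order') labels must match. Solved as a small 0/1 integer program
    (HiGHS branch-and-bound): one variable per oriented compatible edge
    pair, tied to an injective vertex-assignment layer that keeps the
    edge matching consistent with a single vertex map. Backbone-sized
    molecular graphs (tens of bonds) solve in well under a second.
    """
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import lil_matrix

    if g1.number_of_edges() == 0 or g2.number_of_edges() == 0:
        return 0
    edges1 = list(g1.edges)
    edges2 = list(g2.edges)

    # Vertex-assignment variables y[(a,u)] for label-compatible pairs.
    y_index: dict[tuple, int] = {}
    for a in g1.nodes:
        for u in g2.nodes:
            if _node_label(g1, a) == _node_label(g2, u):
                y_index[(a, u)] = len(y_index)
    # Oriented edge-match variables x[(i, j, flip)].
    x_list: list[tuple[int, int, tuple, tuple]] = []
    for i, (a, b) in enumerate(edges1):
        for j, (u, v) in enumerate(edges2):
            if _edge_label(g1, (a, b)) != _edge_label(g2, (u, v)):
                continue
            for p, q in (((a, u), (b, v)), ((a, v), (b, u))):
                if p in y_index and q in y_index:
                    x_list.append((i, j, p, q))
    if not x_list:
        return 0

    n_x, n_y = len(x_list), len(y_index)
    n_var = n_x + n_y

    rows: list[tuple[dict[int, float], float, float]] = []

    def add_le(coeffs: dict[int, float], ub: float) -> None:
        rows.append((coeffs, -np.inf, ub))

    # Each edge of either graph matched at most once.
    for i in range(len(edges1)):
        add_le({k: 1.0 for k, x in enumerate(x_list) if x[0] == i}, 1.0)
    for j in range(len(edges2)):
        add_le({k: 1.0 for k, x in enumerate(x_list) if x[1] == j}, 1.0)
    # An edge match requires both endpoint assignments.
    for k, (_, _, p, q) in enumerate(x_list):
        add_le({k: 1.0, n_x + y_index[p]: -1.0}, 0.0)
        add_le({k: 1.0, n_x + y_index[q]: -1.0}, 0.0)
    # The vertex map is injective in both directions.
    for a in g1.nodes:
        cols = {n_x + idx: 1.0 for (p, u), idx in y_index.items() if p == a}
        if cols:
            add_le(cols, 1.0)
    for u in g2.nodes:
        cols = {n_x + idx: 1.0 for (p, q), idx in y_index.items() if q == u}
        if cols:
            add_le(cols, 1.0)

    A = lil_matrix((len(rows), n_var))
    lo = np.empty(len(rows))
    up = np.empty(len(rows))
    for r, (coeffs, lb, ub) in enumerate(rows):
        for c, val in coeffs.items():
            A[r, c] = val
        lo[r], up[r] = lb, ub

    c = np.zeros(n_var)
    c[:n_x] = -1.0  # maximize matched edges
    res = milp(
        c=c,
        constraints=LinearConstraint(A.tocsr(), lo, up),
        integrality=np.ones(n_var),
        bounds=Bounds(0, 1),
    )
    if not res.success:  # pragma: no cover - solver failure is unexpected
        raise RuntimeError(f"MCES integer program failed: {res.message}")
    return int(round(-res.fun))


def mces_distance(g1: nx.Graph, g2: nx.Graph) -> int:
    """Edges outside a maximum common edge subgraph: |E1| + |E2| - 2|MCES|."""
    return g1.number_of_edges() + g2.number_of_edges() - 2 * mces_size(g1, g2)


def backbone_distances(structures: dict[str, str]) -> pd.DataFrame:
    """Pairwise MCES distance matrix over backbone SMILES.

    ``structures`` maps backbone id -> SMILES (acyl chains stripped).
    The result is square, symmetric with a zero diagonal, and tagged
    ``attrs["provenance"] = "computed"``.
    """
    ids = list(structures)
    graphs = {k: smiles_to_graph(s) for k, s in structures.items()}
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = float(mces_distance(graphs[a], graphs[b]))
            out.loc[a, b] = out.loc[b, a] = d
    _check_distance_matrix(out)
    out.attrs["provenance"] = "computed"
    return out


def _check_distance_matrix(d: pd.DataFrame) -> None:
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (arr < 0).any():
        raise ValueError("distances must be >= 0")


def load_backbone_structures() -> pd.DataFrame:
    """Packaged subclass -> (backbone_id, smiles) table."""
    ref = resources.files("avlipidome.data").joinpath("backbone_smiles.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t").set_index("subclass")


def load_default_backbone_distances() -> pd.DataFrame:
    """Precomputed MCES distances for the packaged backbone panel.

    Generated once by :func:`backbone_distances` on the packaged SMILES;
    tagged ``attrs["provenance"] = "loaded"``.
    """
    ref = resources.files("avlipidome.data").joinpath("backbone_distances.tsv")
    with ref.open("r") as fh:
        out = pd.read_csv(fh, sep="\t", index_col=0)
    out.columns.name = None
    _check_distance_matrix(out)
    out.attrs["provenance"] = "loaded"
    return out


def pca_top(
    distances: pd.DataFrame, n_components: int = 10, keep: int = 5
) -> pd.DataFrame:
    """PCA of the distance-matrix rows; top ``keep`` component scores.

    Each backbone's row of distances to all backbones is its feature
    vector; rows are centered (no scaling) before the decomposition.
    """
    _check_distance_matrix(distances)
    n_components = min(n_components, *distances.shape)
    scores = PCA(n_components=n_components).fit_transform(
        distances.to_numpy(dtype=float)
    )
    keep = min(keep, scores.shape[1])
    return pd.DataFrame(
        scores[:, :keep],
        index=distances.index,
        columns=[f"PC{i + 1}" for i in range(keep)],
    )


def build_feature_matrix(
    abundance: pd.DataFrame,
    chain_features: pd.DataFrame,
    backbone_block: pd.DataFrame,
    lipid_backbones: pd.Series,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Concatenate weighted abundance / chain / backbone blocks per lipid.

    ``abundance``: lipids x sample-groups, z-scored per column here.
    ``chain_features``: lipids x (total_carbons, total_double_bonds, ...),
    min-max scaled per column. ``backbone_block``: backbone id x PCA
    scores, min-max scaled then broadcast to lipids through
    ``lipid_backbones`` (lipid -> backbone id). ``weights`` maps block
    names ('abundance', 'chains', 'backbone') to positive factors
    (default 1.0 each).
    """
    weights = {"abundance": 1.0, "chains": 1.0, "backbone": 1.0,
               **(weights or {})}
    if any(w <= 0 for w in weights.values()):
        raise ValueError("block weights must be > 0")
    lipids = list(abundance.index)

    missing = set(lipids) - set(chain_features.index)
    if missing:
        raise MissingFeature(f"no chain features for {sorted(missing)[:5]}")
    missing = set(lipids) - set(lipid_backbones.index)
    if missing:
        raise MissingFeature(f"no backbone id for {sorted(missing)[:5]}")
    unknown = set(lipid_backbones.loc[lipids]) - set(backbone_block.index)
    if unknown:
        raise MissingFeature(f"backbones outside PCA block: {sorted(unknown)}")

    ab = abundance.to_numpy(dtype=float)
    sd = ab.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (ab - ab.mean(axis=0)) / sd

    chains = MinMaxScaler().fit_transform(
        chain_features.loc[lipids].to_numpy(dtype=float)
    )
    bb_scaled = pd.DataFrame(
        MinMaxScaler().fit_transform(backbone_block.to_numpy(dtype=float)),
        index=backbone_block.index,
        columns=backbone_block.columns,
    )
    bb = bb_scaled.loc[lipid_backbones.loc[lipids]].to_numpy()

    blocks = [
        weights["abundance"] * z,
        weights["chains"] * chains,
        weights["backbone"] * bb,
    ]
    cols = (
        [f"ab_{c}" for c in abundance.columns]
        + [f"chain_{c}" for c in chain_features.columns]
        + [f"bb_{c}" for c in backbone_block.columns]
    )
    out = pd.DataFrame(np.hstack(blocks), index=lipids, columns=cols)
    if out.isna().to_numpy().any():
        raise MissingFeature("feature matrix contains missing values")
    return out


def embed_2d(
    features: pd.DataFrame,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """Deterministic 2-D UMAP embedding of the feature matrix.

    Coordinates carry no contract beyond determinism per seed; cluster
    structure is evaluated downstream. ``n_neighbors`` is clamped below
    the row count for small inputs.
    """
    import umap

    if len(features) < 10:
        raise ValueError("embedding needs >= 10 rows")
    n_neighbors = min(n_neighbors, len(features) - 1)
    coords = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
    ).fit_transform(features.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=features.index, columns=["x", "y"])
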