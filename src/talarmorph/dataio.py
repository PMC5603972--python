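"""Input/output and validation for trees, trait tables and landmark data.

The pipeline consumes three kinds of external data: a rooted, branch-length
bearing phylogeny (Newick), 3D landmark configurations (TPS blocks or
long-form CSV), and species-level trait tables (CSV with a leading
``species`` column).  Everything is validated on the way in and
cross-referenced with :func:`align_datasets` before analysis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "TraitTable",
    "LandmarkConfiguration",
    "read_tree",
    "write_tree",
    "read_landmarks",
    "write_landmarks_csv",
    "read_trait_table",
    "align_datasets",
    "normalize_label",
]

#: TPS convention for a missing landmark: an all-9999 triplet.
TPS_MISSING_SENTINEL = 9999.0

#: Expected number of landmarks per talus unless overridden.
DEFAULT_N_LANDMARKS = 30


def normalize_label(label: str) -> str:
    """Canonical species label: trimmed, underscores mapped to spaces."""
    return " ".join(str(label).replace("_", " ").split())


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted, metric phylogeny with array-based access.

    Nodes are indexed in preorder (root = 0).  Every non-root node carries
    the length of the edge leading to it, so an edge can be identified by
    its child node index.  The phylogenetic covariance ``C`` implied by
    Brownian motion — ``C[i, j]`` equal to the shared root-to-MRCA path
    length of tips *i* and *j* — is computed on demand and cached.

    Parameters
    ----------
    dtree:
        A rooted :class:`dendropy.Tree` in which every non-root edge has a
        finite, non-negative length.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        self._nodes = nodes
        n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(n, -1, dtype=int)
        length = np.zeros(n)
        heights = np.zeros(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                if nd.edge.length is None:
                    raise ValueError(f"edge into node {i} has no branch length")
                bl = float(nd.edge.length)
                if not np.isfinite(bl) or bl < 0:
                    raise ValueError(f"edge into node {i} has invalid length {bl!r}")
                length[i] = bl
                heights[i] = heights[p] + bl
            if nd.is_leaf():
                labels[i] = normalize_label(nd.taxon.label)
        self.parent = parent
        self.edge_length = length
        self.heights = heights
        self.is_tip = np.array([nd.is_leaf() for nd in nodes])
        self.tip_ids = np.flatnonzero(self.is_tip)
        self.tip_labels = [labels[i] for i in self.tip_ids]
        if len(set(self.tip_labels)) != len(self.tip_labels):
            seen, dups = set(), set()
            for t in self.tip_labels:
                (dups if t in seen else seen).add(t)
            raise ValueError(f"duplicate tip labels: {sorted(dups)}")
        self.node_labels = labels
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[parent[i]].append(i)
        self._C: np.ndarray | None = None

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def root(self) -> int:
        return 0

    @property
    def tree_height(self) -> float:
        return float(self.heights[self.tip_ids].max())

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self.heights[self.tip_ids]
        h = depths.max()
        return bool(h == 0 or np.ptp(depths) <= rel_tol * h)

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        return np.array(order[::-1], dtype=int)

    def tip_set(self, node: int) -> np.ndarray:
        """Indices (into ``tip_labels``) of tips descending from ``node``."""
        tip_pos = {t: k for k, t in enumerate(self.tip_ids)}
        out: list[int] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if self.is_tip[nd]:
                out.append(tip_pos[nd])
            else:
                stack.extend(self.children[nd])
        return np.array(sorted(out), dtype=int)

    def lineage(self, node: int) -> list[int]:
        """Nodes from the root down to ``node`` (inclusive)."""
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        return path[::-1]

    # -- phylogenetic covariance -------------------------------------------

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance among tips (shared path lengths).

        Computed by a single postorder sweep: every internal node
        contributes its height as the covariance of all tip pairs whose
        MRCA it is.
        """
        if self._C is None:
            n = self.n_tips
            C = np.zeros((n, n))
            for nd in self.postorder():
                if self.is_tip[nd]:
                    continue
                kids = self.children[nd]
                sets = [self.tip_set(k) for k in kids]
                h = self.heights[nd]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        C[np.ix_(sets[a], sets[b])] = h
                        C[np.ix_(sets[b], sets[a])] = h
            d = self.heights[self.tip_ids]
            np.fill_diagonal(C, d)
            self._C = C
        return self._C

    def mrca_depth(self, tip_a: str, tip_b: str) -> float:
        i = self.tip_labels.index(tip_a)
        j = self.tip_labels.index(tip_b)
        return float(self.vcv()[i, j])

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parser errors
            raise ValueError(f"unparseable Newick: {exc}") from exc
        dtree.is_rooted = True
        return cls(dtree)

    def to_newick(self) -> str:
        def render(node: int) -> str:
            if self.is_tip[node]:
                lab = self.node_labels[node].replace(" ", "_")
                return f"{lab}:{self.edge_length[node]:.17g}"
            inner = ",".join(render(c) for c in self.children[node])
            if node == self.root:
                return f"({inner});"
            return f"({inner}):{self.edge_length[node]:.17g}"

        return render(self.root)

    def prune_to(self, keep: list[str]) -> "PhyloTree":
        """Subtree spanned by the tips in ``keep`` (suppresses unifurcations)."""
        keep_norm = {normalize_label(k) for k in keep}
        missing = keep_norm - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        dtree = self._dtree.clone(depth=1)
        taxa = [t for t in dtree.taxon_namespace if normalize_label(t.label) in keep_norm]
        dtree.retain_taxa(taxa)
        return PhyloTree(dtree)


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Species-level trait data: one row per species.

    ``data`` is indexed by normalized species label.  When ``kind`` is
    ``"lmp"`` the numeric columns are locomotor-mode percentages and each
    row must sum to 100 (tolerance 1e-6).
    """

    data: pd.DataFrame
    kind: str = "generic"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate species rows: {dups}")
        if self.kind == "lmp":
            sums = self.numeric().sum(axis=1)
            bad = sums[(sums - 100.0).abs() > 1e-6]
            if len(bad):
                raise ValueError(
                    f"LMP rows must sum to 100%: offending species {bad.index.tolist()}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def numeric(self) -> pd.DataFrame:
        return self.data.select_dtypes(include=[np.number])

    def matrix(self, columns=None) -> np.ndarray:
        df = self.numeric() if columns is None else self.data[list(columns)]
        return df.to_numpy(dtype=float)

    def subset(self, species: list[str]) -> "TraitTable":
        keep = [normalize_label(s) for s in species]
        return TraitTable(self.data.loc[keep].copy(), kind=self.kind)


def read_trait_table(path, kind: str = "generic") -> TraitTable:
    """CSV with a header row whose first column is ``species``."""
    df = pd.read_csv(path)
    first = df.columns[0]
    if first.strip().lower() != "species":
        raise ValueError(f"first column must be 'species', got {first!r}")
    df[first] = df[first].map(normalize_label)
    df = df.set_index(first)
    df.index.name = "species"
    return TraitTable(df, kind=kind)


# ---------------------------------------------------------------------------
# Landmark configurations
# ---------------------------------------------------------------------------

@dataclass
class LandmarkConfiguration:
    """One specimen's raw landmark coordinates with a missing-value mask."""

    specimen_id: str
    species: str
    side: str  # "left" | "right"
    coords: np.ndarray  # (k, 3) float, mm; missing rows are NaN
    missing: np.ndarray = field(default=None)  # (k,) bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (k, 3)")
        if self.missing is None:
            self.missing = np.isnan(self.coords).any(axis=1)
        self.missing = np.asarray(self.missing, dtype=bool)
        present = self.coords[~self.missing]
        if not np.all(np.isfinite(present)):
            raise ValueError(
                f"specimen {self.specimen_id}: non-finite coordinate outside missing mask"
            )
        self.species = normalize_label(self.species)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.specimen_id, self.species, self.side,
            self.coords.copy(), self.missing.copy(),
        )


def _read_landmarks_tps(text: str, n_landmarks: int) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if not ln.upper().startswith("LM3="):
            raise ValueError(f"expected LM3= block, got {ln!r}")
        k = int(ln.split("=", 1)[1])
        rows = []
        for j in range(k):
            parts = lines[i + 1 + j].split()
            if len(parts) != 3:
                raise ValueError(f"bad coordinate line: {lines[i + 1 + j]!r}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"non-numeric coordinate: {lines[i + 1 + j]!r}") from exc
        i += 1 + k
        meta = {"ID": f"specimen_{len(configs)}", "SPECIES": "unknown", "SIDE": "right"}
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, val = lines[i].split("=", 1)
            meta[key.strip().upper()] = val.strip()
            i += 1
        coords = np.array(rows, dtype=float)
        miss = np.all(coords == TPS_MISSING_SENTINEL, axis=1)
        coords[miss] = np.nan
        if k != n_landmarks:
            raise ValueError(
                f"specimen {meta['ID']}: {k} landmarks, expected {n_landmarks}"
            )
        configs.append(
            LandmarkConfiguration(meta["ID"], meta["SPECIES"], meta["SIDE"].lower(), coords, miss)
        )
    return configs


def _read_landmarks_csv(text: str, n_landmarks: int) -> list[LandmarkConfiguration]:
    df = pd.read_csv(io.StringIO(text), na_values=["NA"])
    required = ["specimen", "species", "side", "landmark_index", "x", "y", "z"]
    if list(df.columns) != required:
        raise ValueError(f"long-form CSV must have columns {required}, got {list(df.columns)}")
    configs = []
    for spec_id, grp in df.groupby("specimen", sort=False):
        grp = grp.sort_values("landmark_index")
        k = len(grp)
        if k != n_landmarks:
            raise ValueError(f"specimen {spec_id}: {k} landmarks, expected {n_landmarks}")
        if not np.array_equal(grp["landmark_index"].to_numpy(), np.arange(1, k + 1)):
            raise ValueError(f"specimen {spec_id}: landmark_index must run 1..{k}")
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(
            LandmarkConfiguration(
                str(spec_id), str(grp["species"].iloc[0]),
                str(grp["side"].iloc[0]).lower(), coords,
            )
        )
    return configs


def read_landmarks(path, dialect: str = "csv",
                   n_landmarks: int = DEFAULT_N_LANDMARKS) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or long-form CSV file.

    TPS files use ``LM3=k`` blocks with all-9999 triplets marking missing
    landmarks; the CSV dialect is long form
    ``specimen,species,side,landmark_index,x,y,z`` with ``NA`` tokens.
    Every specimen must carry exactly ``n_landmarks`` landmarks.
    """
    with open(path) as fh:
        text = fh.read()
    if dialect == "tps":
        return _read_landmarks_tps(text, n_landmarks)
    if dialect == "csv":
        return _read_landmarks_csv(text, n_landmarks)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmarks_csv(configs: list[LandmarkConfiguration], path) -> None:
    rows = []
    for c in configs:
        for j in range(c.n_landmarks):
            x, y, z = (
                (np.nan, np.nan, np.nan) if c.missing[j] else tuple(c.coords[j])
            )
            rows.append((c.specimen_id, c.species, c.side, j + 1, x, y, z))
    df = pd.DataFrame(rows, columns=["specimen", "species", "side", "landmark_index", "x", "y", "z"])
    df.to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Cross-referencing
# ---------------------------------------------------------------------------

@dataclass
class AlignedData:
    """Species-matched view over a tree, trait tables and landmark data."""

    species: list[str]
    tree: PhyloTree
    tables: list[TraitTable]
    shapes: list[LandmarkConfiguration]
    dropped: dict[str, list[str]]


def align_datasets(tree: PhyloTree | None = None,
                   tables: list[TraitTable] | None = None,
                   shapes: list[LandmarkConfiguration] | None = None) -> AlignedData:
    """Intersect species labels across inputs, reporting what was dropped.

    Downstream analyses only ever see the matched species set; an empty
    intersection is an error.
    """
    tables = tables or []
    label_sets: list[tuple[str, set[str]]] = []
    if tree is not None:
        label_sets.append(("tree", set(tree.tip_labels)))
    for i, tab in enumerate(tables):
        label_sets.append((f"table_{i}", set(tab.species)))
    if shapes:
        label_sets.append(("shapes", {c.species for c in shapes}))
    if not label_sets:
        raise ValueError("nothing to align")
    common = set.intersection(*(s for _, s in label_sets))
    if not common:
        raise ValueError("empty species intersection across datasets")
    dropped = {name: sorted(s - common) for name, s in label_sets if s - common}
    species = sorted(common)
    out_tree = tree.prune_to(species) if tree is not None else None
    out_tables = [t.subset(species) for t in tables]
    out_shapes = [c for c in (shapes or []) if c.species in common]
    return AlignedData(species, out_tree, out_tables, out_shapes, dropped)
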