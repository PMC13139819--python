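"""Band presence/absence profiles: similarity indices and dendrograms.

Electrophoretic protein (or IgE-reactive) band patterns are scored per species
as presence/absence of annotated bands.  Two species are compared either with
the band-sharing similarity index

    SI = 2Z / (X + Y) x 100

(Z = bands present in both, X and Y = band counts of the two species; this is
the Dice coefficient on a percent scale), or with the Pearson product-moment
correlation of the two binary vectors (the phi coefficient).  Species are then
clustered hierarchically (UPGMA by default) on the induced distances
``100 - SI`` or ``1 - r``.

Band identity across species is taken from the shared ``band_label`` assigned
at annotation time; no automatic molecular-weight matching is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .trees import Node, leaf, to_newick, write_newick  # noqa: F401  (re-export)

__all__ = [
    "BandProfileMatrix",
    "SimilarityMatrix",
    "DegenerateProfileError",
    "read_band_calls",
    "similarity_index",
    "pairwise_si_matrix",
    "pearson_similarity_matrix",
    "build_dendrogram",
    "write_newick",
]


class DegenerateProfileError(ValueError):
    """Raised when a similarity is undefined (e.g., both profiles empty)."""


_PRESENT_MAP = {
    "0": 0, "1": 1,
    "+": 1, "-": 0, "−": 0,  # ASCII hyphen and Unicode minus both mean absent
    "true": 1, "false": 0,
}


@dataclass
class BandProfileMatrix:
    """Species x band binary presence/absence matrix with molecular weights.

    Parameters
    ----------
    species_ids
        Ordered species labels (rows).
    band_labels
        Ordered band identifiers (columns), unique.
    mw_kda
        Molecular weight of each band in kDa, parallel to ``band_labels``.
    calls
        Binary (0/1) matrix of shape (n_species, n_bands).
    """

    species_ids: list[str]
    band_labels: list[str]
    mw_kda: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.mw_kda = np.asarray(self.mw_kda, dtype=float)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_sp, n_bd = len(self.species_ids), len(self.band_labels)
        if self.calls.shape != (n_sp, n_bd):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_sp} species x {n_bd} bands"
            )
        if len(set(self.band_labels)) != n_bd:
            raise ValueError("band_labels must be unique")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be strictly binary (0/1)")
        if self.mw_kda.shape != (n_bd,):
            raise ValueError("mw_kda must be parallel to band_labels")
        if not (self.mw_kda > 0).all():
            raise ValueError("molecular weights must be positive")

    def row(self, species: str) -> np.ndarray:
        return self.calls[self.species_ids.index(species)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.species_ids, columns=self.band_labels)


@dataclass
class SimilarityMatrix:
    """Symmetric species similarity matrix on a declared scale."""

    labels: list[str]
    values: np.ndarray
    scale: str  # "percent_0_100" or "correlation_minus1_1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if self.scale not in ("percent_0_100", "correlation_minus1_1"):
            raise ValueError(f"unknown scale {self.scale!r}")
        lo, hi = (0.0, 100.0) if self.scale == "percent_0_100" else (-1.0, 1.0)
        if self.values.min() < lo - 1e-9 or self.values.max() > hi + 1e-9:
            raise ValueError(f"values outside declared scale bounds [{lo}, {hi}]")

    @property
    def diagonal_value(self) -> float:
        return 100.0 if self.scale == "percent_0_100" else 1.0

    def to_distance(self) -> np.ndarray:
        """Distance matrix: 100 - SI on the percent scale, 1 - r on correlation."""
        return self.diagonal_value - self.values

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        values = self.values
        if decimals is None and self.scale == "percent_0_100":
            decimals = 1  # percent similarity reported to one decimal place
        if decimals is not None:
            values = np.round(values, decimals)
        return pd.DataFrame(values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


def read_band_calls(path, sep: str | None = None) -> BandProfileMatrix:
    """Read a delimited band-call table into a :class:`BandProfileMatrix`.

    The table needs columns ``species``, ``band_label``, ``mw_kda`` and
    ``present`` (accepted presence codes: 0/1, +/-, true/false).  Rows appear
    in any order; species keep their input order while bands are sorted by
    descending molecular weight.  Pairs absent from the table are scored 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"species", "band_label", "mw_kda", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    dup = df.duplicated(subset=["species", "band_label"], keep=False)
    if dup.any():
        i = int(df.index[dup][0])
        rec = df.loc[i]
        raise ValueError(
            f"{path}: duplicate (species, band_label) pair "
            f"({rec['species']!r}, {rec['band_label']!r}) at row {i + 2}"
        )

    calls_raw = {}
    for i, rec in df.iterrows():
        code = str(rec["present"]).strip().lower()
        if code not in _PRESENT_MAP:
            raise ValueError(
                f"{path}: non-binary presence call {rec['present']!r} at row {i + 2}"
            )
        calls_raw[(str(rec["species"]), str(rec["band_label"]))] = _PRESENT_MAP[code]

    species = list(dict.fromkeys(df["species"].astype(str)))
    first = df.drop_duplicates("band_label")
    mw = pd.Series(
        first["mw_kda"].astype(float).to_numpy(),
        index=first["band_label"].astype(str),
    )
    # bands by descending molecular weight, label as deterministic tie-break
    bands = sorted(mw.index, key=lambda b: (-mw[b], b))
    calls = np.zeros((len(species), len(bands)), dtype=np.int8)
    for (sp, bd), v in calls_raw.items():
        calls[species.index(sp), bands.index(bd)] = v
    return BandProfileMatrix(species, bands, mw.loc[bands].to_numpy(), calls)


def similarity_index(row_a: Sequence[int], row_b: Sequence[int]) -> float:
    """Band-sharing similarity index 2Z/(X+Y) x 100 between two binary profiles."""
    a = np.asarray(row_a, dtype=np.int8)
    b = np.asarray(row_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("profiles must have the same length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("profiles must be binary")
    x, y = int(a.sum()), int(b.sum())
    if x + y == 0:
        raise DegenerateProfileError(
            "similarity index undefined: both profiles have no bands (X + Y = 0)"
        )
    z = int((a & b).sum())
    return 2.0 * z / (x + y) * 100.0


def pairwise_si_matrix(m: BandProfileMatrix) -> SimilarityMatrix:
    """All-pairs similarity-index matrix (percent scale) over the species rows."""
    n = len(m.species_ids)
    if n < 2:
        raise ValueError("need at least two species")
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                values[i, j] = values[j, i] = similarity_index(m.calls[i], m.calls[j])
            except DegenerateProfileError as err:
                raise DegenerateProfileError(
                    f"{err} (pair {m.species_ids[i]!r}, {m.species_ids[j]!r})"
                ) from None
    return SimilarityMatrix(list(m.species_ids), values, "percent_0_100")


def pearson_similarity_matrix(m: BandProfileMatrix) -> SimilarityMatrix:
    """Pearson correlation (phi coefficient) matrix of the binary band rows."""
    if len(m.species_ids) < 2:
        raise ValueError("need at least two species")
    for sp, row in zip(m.species_ids, m.calls):
        if row.min() == row.max():
            raise ValueError(
                f"species {sp!r} has a constant band profile (zero variance); "
                "Pearson similarity is undefined"
            )
    values = np.corrcoef(m.calls.astype(float))
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(m.species_ids), values, "correlation_minus1_1")


_LINKAGES = ("upgma", "single", "complete")


def build_dendrogram(s: SimilarityMatrix, linkage: str = "upgma") -> Node:
    """Agglomeratively cluster species from a similarity matrix.

    Distances are ``100 - value`` (percent scale) or ``1 - value`` (correlation
    scale).  The default UPGMA (average) linkage yields an ultrametric tree
    whose node heights are the merge distances.  Ties between equally close
    cluster pairs are broken by the lexicographically smallest pair of cluster
    keys (a cluster is keyed by its smallest leaf label), so the output is
    deterministic.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    dist = s.to_distance()
    n = len(s.labels)
    if n < 2:
        raise ValueError("need at least two species to cluster")

    # active clusters: key -> (node, size); distances in a dict keyed by pairs
    clusters: dict[str, tuple[Node, int]] = {
        lab: (leaf(lab), 1) for lab in s.labels
    }
    d: dict[frozenset[str], float] = {
        frozenset((s.labels[i], s.labels[j])): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }

    while len(clusters) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        pair, height = best
        ka, kb = sorted(pair)
        node_a, size_a = clusters.pop(ka)
        node_b, size_b = clusters.pop(kb)
        merged = Node(height=height, children=(node_a, node_b))
        new_key = min(ka, kb)
        for other in list(clusters):
            da = d.pop(frozenset((ka, other)))
            db = d.pop(frozenset((kb, other)))
            if linkage == "upgma":
                dn = (size_a * da + size_b * db) / (size_a + size_b)
            elif linkage == "single":
                dn = min(da, db)
            else:
                dn = max(da, db)
            d[frozenset((new_key, other))] = dn
        del d[pair]
        clusters[new_key] = (merged, size_a + size_b)

    (root, _), = clusters.values()
    return root


def cophenetic_matrix(tree: Node, labels: Sequence[str]) -> np.ndarray:
    """Pairwise merge heights (cophenetic distances) between leaves."""
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for node in tree.iter_nodes():
        if node.is_leaf:
            continue
        for ia, child_a in enumerate(node.children):
            for child_b in node.children[ia + 1:]:
                for la in child_a.leaf_labels():
                    for lb in child_b.leaf_labels():
                        out[index[la], index[lb]] = out[index[lb], index[la]] = node.height
    return out


def write_band_bundle(out_dir, matrix: SimilarityMatrix, tree: Node, params: dict) -> None:
    """Write the matrix (TSV), tree (Newick) and a JSON bundle to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(out / "similarity_matrix.tsv")
    write_newick(tree, out / "dendrogram.nwk")
    bundle = {
        "labels": matrix.labels,
        "scale": matrix.scale,
        "matrix": np.round(matrix.values, 4).tolist(),
        "newick": to_newick(tree),
        "parameters": params,
    }
    (out / "bands.json").write_text(json.dumps(bundle, indent=2) + "\n")
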