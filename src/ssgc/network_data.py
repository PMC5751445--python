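"""Entity registries, association/similarity containers, and file I/O.

Every file the pipeline touches goes through this module: two-column edge
lists (TSV/CSV) for bipartite and unipartite associations, square similarity
matrices with an id header row and id first column, fingerprint bit-set
files, and ranked pair-score tables.

Conventions
-----------
* All matrices are indexed 0-based internally. A drug-disease pair
  ``(i, j)`` maps to the flat index ``s = i * n + j`` where ``n`` is the
  number of diseases; :class:`PairField` is the single bridge between the
  ``m x n`` matrix view and the length-``q`` vector view.
* Ids are case-sensitive opaque strings.
* Gene-gene edge lists are undirected and stored symmetrically.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EntityRegistry",
    "AssociationMatrix",
    "SimilarityMatrix",
    "FingerprintSet",
    "PairField",
    "read_edge_list",
    "write_edge_list",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_fingerprints",
    "write_fingerprints",
    "write_pair_scores",
    "read_pair_scores",
]

_SYM_TOL = 1e-12
_READ_SYM_TOL = 1e-6
_CLIP_TOL = 1e-9


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered set of unique string identifiers of one kind.

    Parameters
    ----------
    kind : str
        One of ``"drug"``, ``"disease"``, ``"gene"`` (free-form accepted for
        tests, but the pipeline only produces these three).
    ids : tuple of str
        Unique, non-empty identifiers; position in the tuple is the 0-based
        matrix index of the entity.
    """

    kind: str
    ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(not i for i in self.ids):
            raise ValueError("registry ids must be non-empty strings")
        index = {s: k for k, s in enumerate(self.ids)}
        if len(index) != len(self.ids):
            raise ValueError(f"duplicate ids in {self.kind} registry")
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_ids(cls, kind: str, ids: Iterable[str]) -> "EntityRegistry":
        return cls(kind, tuple(ids))

    @property
    def size(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in self._index

    def index(self, entity_id: str) -> int:
        """0-based position of ``entity_id``; raises ``KeyError`` if absent."""
        return self._index[entity_id]

    def subset(self, keep: Sequence[int]) -> "EntityRegistry":
        """Registry over the entities at positions ``keep`` (order kept)."""
        return EntityRegistry(self.kind, tuple(self.ids[k] for k in keep))


@dataclass
class AssociationMatrix:
    """Binary bipartite relation between two entity sets.

    ``values[i, j] == 1`` iff row entity ``i`` is associated with column
    entity ``j``. Row ``i`` of a drug-gene matrix is exactly the binary gene
    profile of drug ``i``; columns play the symmetric role for diseases.
    """

    rows: EntityRegistry
    cols: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.rows.size, self.cols.size):
            raise ValueError(
                f"association shape {self.values.shape} does not match "
                f"registries ({self.rows.size}, {self.cols.size})"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity set.

    Invariants enforced at construction: symmetry within 1e-12, diagonal
    exactly 1, all entries in [0, 1].
    """

    registry: EntityRegistry
    values: np.ndarray
    layer_tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != self.registry.size:
            raise ValueError("similarity size does not match registry")
        if not np.isfinite(v).all():
            raise ValueError("similarity entries must be finite")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if v.size and np.abs(np.diag(v) - 1.0).max(initial=0.0) != 0.0:
            raise ValueError("similarity diagonal must be exactly 1")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("similarity entries must lie in [0, 1]")
        self.values = v

    @classmethod
    def from_raw(
        cls, registry: EntityRegistry, values: np.ndarray, layer_tag: str = ""
    ) -> "SimilarityMatrix":
        """Build from a nearly-valid matrix: symmetrize by averaging, force
        the unit diagonal, and clip rounding noise just outside [0, 1]."""
        v = np.asarray(values, dtype=float)
        v = 0.5 * (v + v.T)
        np.clip(v, 0.0, 1.0, out=v)
        np.fill_diagonal(v, 1.0)
        return cls(registry, v, layer_tag)


@dataclass
class FingerprintSet:
    """Per-drug sets of set-bit indices of a 2D structural fingerprint."""

    registry: EntityRegistry
    bits: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.bits) != self.registry.size:
            raise ValueError("one bit set required per registry entry")
        for b in self.bits:
            if any(x < 0 for x in b):
                raise ValueError("bit indices must be non-negative")


@dataclass
class PairField:
    """Real field over the drug x disease grid.

    The ``m x n`` matrix view and the length ``q = m * n`` vector view are
    linked by ``s = i * n + j`` (0-based); :meth:`flat` and
    :meth:`from_flat` are the only conversion points.
    """

    drugs: EntityRegistry
    diseases: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.drugs.size, self.diseases.size):
            raise ValueError("pair field shape does not match registries")
        if not np.isfinite(self.values).all():
            raise ValueError("pair field entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def flat(self) -> np.ndarray:
        """Length-q vector in row-major (s = i*n + j) order."""
        return self.values.ravel()

    @classmethod
    def from_flat(
        cls, drugs: EntityRegistry, diseases: EntityRegistry, f: np.ndarray
    ) -> "PairField":
        return cls(drugs, diseases, np.asarray(f, float).reshape(drugs.size, diseases.size))

    @classmethod
    def zeros(cls, drugs: EntityRegistry, diseases: EntityRegistry) -> "PairField":
        return cls(drugs, diseases, np.zeros((drugs.size, diseases.size)))

    def copy(self) -> "PairField":
        return PairField(self.drugs, self.diseases, self.values.copy())


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    if "\t" in line:
        return [p.strip() for p in line.split("\t")]
    return [p.strip() for p in line.split(",")]


def read_edge_list(
    path: str | Path,
    rows: EntityRegistry | None = None,
    cols: EntityRegistry | None = None,
    *,
    row_kind: str = "drug",
    col_kind: str = "gene",
    symmetric: bool = False,
) -> AssociationMatrix:
    """Read a two-column TSV/CSV edge list into a binary association matrix.

    Lines starting with ``#`` are treated as headers/comments and skipped.
    Duplicate edges collapse to a single 1. When ``rows``/``cols`` are not
    supplied, registries are built in first-appearance order. With
    ``symmetric=True`` the edge list is read as an undirected unipartite
    graph over a single registry (gene-gene interactions).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = _split_line(line)
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge line {raw!r}")
            edges.append((parts[0], parts[1]))

    if symmetric and cols is None:
        cols = rows

    if rows is None:
        seen: dict[str, None] = {}
        for a, b in edges:
            seen.setdefault(a, None)
            if symmetric:
                seen.setdefault(b, None)
        rows = EntityRegistry.from_ids(row_kind, seen.keys())
    if cols is None:
        if symmetric:
            cols = rows
        else:
            seen = {}
            for _, b in edges:
                seen.setdefault(b, None)
            cols = EntityRegistry.from_ids(col_kind, seen.keys())

    values = np.zeros((rows.size, cols.size))
    for a, b in edges:
        if a not in rows:
            raise KeyError(f"{path}: id {a!r} not in {rows.kind} registry")
        if b not in cols:
            raise KeyError(f"{path}: id {b!r} not in {cols.kind} registry")
        values[rows.index(a), cols.index(b)] = 1.0
        if symmetric:
            values[rows.index(b), cols.index(a)] = 1.0
    return AssociationMatrix(rows, cols, values)


def write_edge_list(assoc: AssociationMatrix, path: str | Path) -> None:
    """Write the positive entries of an association matrix as a 2-col TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#{assoc.rows.kind}\t{assoc.cols.kind}\n")
        ii, jj = np.nonzero(assoc.values)
        for i, j in zip(ii, jj):
            fh.write(f"{assoc.rows.ids[i]}\t{assoc.cols.ids[j]}\n")


def read_id_list(path: str | Path, kind: str) -> EntityRegistry:
    """Read a one-id-per-line registry file (``#`` lines skipped)."""
    path = Path(path)
    ids = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return EntityRegistry.from_ids(kind, ids)


def write_id_list(registry: EntityRegistry, path: str | Path) -> None:
    Path(path).write_text(
        f"#{registry.kind}\n" + "\n".join(registry.ids) + "\n"
    )


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------

def read_similarity_matrix(
    path: str | Path, kind: str = "entity", layer_tag: str = ""
) -> SimilarityMatrix:
    """Read a square similarity TSV (id header row, id first column).

    Values within 1e-9 outside [0, 1] are clipped; larger violations raise.
    Asymmetry or a diagonal differing from 1 beyond 1e-6 also raises.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        col_ids = header.lstrip("#").split("\t")[1:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(col_ids) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(col_ids) + 1} columns")
            row_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_ids != col_ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    v = np.asarray(rows, dtype=float)
    if v.shape[0] != v.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if (v.min(initial=0.0) < -_CLIP_TOL) or (v.max(initial=1.0) > 1.0 + _CLIP_TOL):
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    np.clip(v, 0.0, 1.0, out=v)
    if np.abs(v - v.T).max(initial=0.0) > _READ_SYM_TOL:
        raise ValueError(f"{path}: matrix asymmetric beyond {_READ_SYM_TOL}")
    if np.abs(np.diag(v) - 1.0).max(initial=0.0) > _READ_SYM_TOL:
        raise ValueError(f"{path}: diagonal differs from 1 beyond {_READ_SYM_TOL}")
    registry = EntityRegistry.from_ids(kind, row_ids)
    return SimilarityMatrix.from_raw(registry, v, layer_tag)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV at 12 significant digits."""
    path = Path(path)
    ids = sim.registry.ids
    with path.open("w") as fh:
        fh.write("#id\t" + "\t".join(ids) + "\n")
        for i, rid in enumerate(ids):
            fh.write(rid + "\t" + "\t".join(f"{x:.12g}" for x in sim.values[i]) + "\n")


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def read_fingerprints(path: str | Path) -> FingerprintSet:
    """Read ``drug_id<TAB>comma-separated bit indices`` lines.

    An empty second field denotes a drug with no set bits.
    """
    path = Path(path)
    ids: list[str] = []
    bits: list[frozenset[int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 1 or not parts[0]:
                raise ValueError(f"{path}:{lineno}: malformed fingerprint line")
            ids.append(parts[0])
            payload = parts[1] if len(parts) > 1 else ""
            bits.append(
                frozenset(int(x) for x in payload.split(",") if x.strip() != "")
            )
    return FingerprintSet(EntityRegistry.from_ids("drug", ids), tuple(bits))


def write_fingerprints(fps: FingerprintSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#drug\tbits\n")
        for drug_id, b in zip(fps.registry.ids, fps.bits):
            fh.write(drug_id + "\t" + ",".join(str(x) for x in sorted(b)) + "\n")


# ---------------------------------------------------------------------------
# Pair scores
# ---------------------------------------------------------------------------

def ranked_pairs(scores: PairField) -> list[tuple[str, str, float]]:
    """All (drug_id, disease_id, score) triples sorted by score descending,
    ties broken by (drug_id, disease_id) lexicographic order."""
    drugs, diseases = scores.drugs.ids, scores.diseases.ids
    triples = [
        (drugs[i], diseases[j], float(scores.values[i, j]))
        for i in range(len(drugs))
        for j in range(len(diseases))
    ]
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    return triples


def write_pair_scores(
    scores: PairField, path: str | Path, top_k: int | None = None
) -> None:
    """Write ranked (drug_id, disease_id, score) rows as a 3-column TSV."""
    path = Path(path)
    triples = ranked_pairs(scores)
    if top_k is not None:
        triples = triples[: max(0, int(top_k))]
    with path.open("w") as fh:
        fh.write("#drug\tdisease\tscore\n")
        for d, z, s in triples:
            fh.write(f"{d}\t{z}\t{s:.12g}\n")


def read_pair_scores(path: str | Path) -> list[tuple[str, str, float]]:
    path = Path(path)
    out: list[tuple[str, str, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out.append((parts[0], parts[1], float(parts[2])))
    return out
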