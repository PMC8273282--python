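"""Typed entity catalogs and binary relation matrices for a multi-type network.

The data model mirrors a heterogeneous association network over five entity
types — lncRNAs, miRNAs, genes, cancers, and (per-cancer) prognosis — where
each observed relation between two types is a binary matrix ``R_ij`` whose
rows and columns are indexed by stable entity catalogs.  One designated block
(lncRNA–cancer) is the *target*: its zero cells are the candidate associations
a fused factorization model will score.

External formats are deliberately plain: catalogs are one identifier per
line, relations are ``source_id<TAB>target_id[<TAB>weight]`` edge lists with
``#`` comments, and summaries are TSV tables.  Files carry identifiers only;
indices are an internal, 0-based concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RelationKey = tuple[str, str]

#: Entity types whose axes are keyed one-to-one to the cancer catalog.
#: Prognosis columns are per-cancer indicators, so restricting the network to
#: a single cancer must slice prognosis-indexed axes in lockstep.
CANCER_ALIGNED_TYPES = ("cancer", "prognosis")


class ValidationError(ValueError):
    """Raised when catalogs, edge lists, or graphs violate an invariant."""


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered, duplicate-free identifier list for one entity type."""

    entity_type: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValidationError(f"catalog for {self.entity_type!r} is empty")
        if any(not i for i in self.ids):
            raise ValidationError(f"catalog for {self.entity_type!r} has an empty identifier")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for lineno, ident in enumerate(self.ids, start=1):
                if ident in seen:
                    raise ValidationError(
                        f"duplicate identifier {ident!r} in {self.entity_type!r} "
                        f"catalog (entry {lineno})"
                    )
                seen.add(ident)
        object.__setattr__(self, "_index", {i: n for n, i in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, identifier: str) -> int:
        """0-based position of ``identifier``; raises ``KeyError`` if absent."""
        return self._index[identifier]  # type: ignore[attr-defined]

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._index  # type: ignore[attr-defined]


@dataclass
class RelationMatrix:
    """One observed block ``R_ij`` between two entity types.

    Entries are 0/1 after binarization; real values in [0, 1] are permitted
    (prognosis scores before thresholding, or exactly low-rank synthetic
    blocks).
    """

    source_type: str
    target_type: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"relation {self.key} must be a 2-D matrix, got ndim={self.values.ndim}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"relation {self.key} contains non-finite entries")
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValidationError(f"relation {self.key} has entries outside [0, 1]")

    @property
    def key(self) -> RelationKey:
        return (self.source_type, self.target_type)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def copy(self) -> "RelationMatrix":
        return RelationMatrix(self.source_type, self.target_type, self.values.copy())


@dataclass
class RelationGraph:
    """The full multi-type network: catalogs plus relation blocks.

    ``target_key`` names the block whose unobserved (zero) cells are scored;
    every other block is side information fused into the factorization.
    """

    catalogs: dict[str, EntityCatalog]
    relations: dict[RelationKey, RelationMatrix]
    target_key: RelationKey

    def __post_init__(self) -> None:
        validate_graph(self.catalogs, self.relations, self.target_key)

    @property
    def target(self) -> RelationMatrix:
        return self.relations[self.target_key]

    def entity_types(self) -> list[str]:
        return list(self.catalogs)

    def incident(self, entity_type: str) -> list[RelationKey]:
        """Relation keys in which ``entity_type`` participates."""
        return [k for k in self.relations if entity_type in k]

    def copy(self) -> "RelationGraph":
        return RelationGraph(
            catalogs=dict(self.catalogs),
            relations={k: r.copy() for k, r in self.relations.items()},
            target_key=self.target_key,
        )

    def drop_relation(self, key: RelationKey) -> "RelationGraph":
        """New graph without block ``key``; the target block cannot be dropped.

        An entity type left with no incident relation (e.g. prognosis after
        removing the gene-prognosis block) leaves the graph along with its
        catalog: an ablated network simply no longer contains that feature.
        """
        if key == self.target_key:
            raise ValidationError("cannot drop the target relation block")
        if key not in self.relations:
            raise KeyError(f"no relation block {key}")
        rels = {k: r.copy() for k, r in self.relations.items() if k != key}
        used = {typ for k in rels for typ in k}
        cats = {typ: cat for typ, cat in self.catalogs.items() if typ in used}
        return RelationGraph(cats, rels, self.target_key)


def validate_graph(
    catalogs: Mapping[str, EntityCatalog],
    relations: Mapping[RelationKey, RelationMatrix],
    target_key: RelationKey,
) -> None:
    seen_pairs: set[frozenset[str]] = set()
    for key, rel in relations.items():
        src, tgt = key
        if key != rel.key:
            raise ValidationError(f"relation stored under {key} declares key {rel.key}")
        for typ in key:
            if typ not in catalogs:
                raise ValidationError(f"relation {key} references undeclared catalog {typ!r}")
        pair = frozenset(key)
        if len(pair) != 2:
            raise ValidationError(f"relation {key} relates a type to itself")
        if pair in seen_pairs:
            raise ValidationError(f"duplicate relation between types {src!r} and {tgt!r}")
        seen_pairs.add(pair)
        expect = (len(catalogs[src]), len(catalogs[tgt]))
        if rel.shape != expect:
            raise ValidationError(
                f"relation {key} has shape {rel.shape}, expected {expect} from catalogs"
            )
    if target_key not in relations:
        raise ValidationError(f"target relation {target_key} missing from graph")


# ---------------------------------------------------------------------------
# I/O


def load_catalog(path: str | Path, entity_type: str) -> EntityCatalog:
    """Read a catalog file: one identifier per line, ``#`` comments ignored."""
    path = Path(path)
    ids: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate identifier {line!r} in "
                    f"{entity_type} catalog"
                )
            seen.add(line)
            ids.append(line)
    if not ids:
        raise ValidationError(f"{path}: catalog file is empty")
    return EntityCatalog(entity_type, tuple(ids))


def save_catalog(catalog: EntityCatalog, path: str | Path) -> None:
    Path(path).write_text("\n".join(catalog.ids) + "\n")


def load_relation(
    path: str | Path, source: EntityCatalog, target: EntityCatalog
) -> RelationMatrix:
    """Read a TSV edge list into a dense relation block.

    Rows are ``source_id<TAB>target_id[<TAB>weight]``; omitted weights mean 1.
    Repeated identical edges collapse to a single entry with a logged warning;
    weights outside [0, 1] and identifiers missing from the catalogs are
    errors naming the offending row.
    """
    path = Path(path)
    values = np.zeros((len(source), len(target)))
    duplicates = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(parts)}"
                )
            sid, tid = parts[0].strip(), parts[1].strip()
            if sid not in source:
                raise ValidationError(
                    f"{path}:{lineno}: unknown {source.entity_type} identifier {sid!r}"
                )
            if tid not in target:
                raise ValidationError(
                    f"{path}:{lineno}: unknown {target.entity_type} identifier {tid!r}"
                )
            weight = 1.0
            if len(parts) == 3:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise ValidationError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if not 0.0 <= weight <= 1.0:
                    raise ValidationError(
                        f"{path}:{lineno}: weight {weight} outside [0, 1]"
                    )
            i, j = source.index(sid), target.index(tid)
            if values[i, j] != 0.0:
                duplicates += 1
            values[i, j] = weight
    if duplicates:
        logger.warning("%s: collapsed %d duplicate edges", path, duplicates)
    return RelationMatrix(source.entity_type, target.entity_type, values)


def save_relation(
    rel: RelationMatrix,
    path: str | Path,
    source: EntityCatalog,
    target: EntityCatalog,
) -> None:
    """Write the nonzero entries of a block as a TSV edge list.

    Weights are written only when an entry is not exactly 1, so binary blocks
    round-trip to two-column files.
    """
    rows, cols = np.nonzero(rel.values)
    with Path(path).open("w") as fh:
        for i, j in zip(rows.tolist(), cols.tolist()):
            v = rel.values[i, j]
            if v == 1.0:
                fh.write(f"{source.ids[i]}\t{target.ids[j]}\n")
            else:
                fh.write(f"{source.ids[i]}\t{target.ids[j]}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Transformations


def binarize_prognosis(scores: RelationMatrix, threshold: float = 0.5) -> RelationMatrix:
    """Threshold real-valued prognosis scores into a 0/1 indicator block.

    An entry becomes 1 iff it is *strictly* greater than ``threshold`` — a
    score exactly at the cutoff does not count as highly prognosis-correlated.
    """
    return RelationMatrix(
        scores.source_type,
        scores.target_type,
        (scores.values > threshold).astype(float),
    )


def build_graph(
    catalogs: Mapping[str, EntityCatalog],
    relations: Mapping[RelationKey, RelationMatrix] | list[RelationMatrix],
    target_key: RelationKey,
) -> RelationGraph:
    """Assemble and validate a relation graph from catalogs and blocks."""
    if isinstance(relations, list):
        rel_map: dict[RelationKey, RelationMatrix] = {}
        for rel in relations:
            if rel.key in rel_map:
                raise ValidationError(f"duplicate relation block {rel.key}")
            rel_map[rel.key] = rel
    else:
        rel_map = dict(relations)
    return RelationGraph(dict(catalogs), rel_map, target_key)


def restrict_to_cancer(graph: RelationGraph, cancer_id: str) -> RelationGraph:
    """Slice the network down to a single cancer.

    The cancer catalog shrinks to ``[cancer_id]`` and every cancer-indexed
    axis — including prognosis axes, whose columns are keyed positionally to
    cancers — keeps only the corresponding column (or row).  Blocks not
    indexed by cancer or prognosis are untouched, so per-cancer models share
    all molecular side information.
    """
    if "cancer" not in graph.catalogs:
        raise ValidationError("graph has no cancer catalog")
    cancers = graph.catalogs["cancer"]
    if cancer_id not in cancers:
        raise ValidationError(f"unknown cancer identifier {cancer_id!r}")
    pos = cancers.index(cancer_id)

    catalogs = dict(graph.catalogs)
    for typ in CANCER_ALIGNED_TYPES:
        if typ in catalogs:
            catalogs[typ] = EntityCatalog(typ, (catalogs[typ].ids[pos],))

    relations: dict[RelationKey, RelationMatrix] = {}
    for key, rel in graph.relations.items():
        vals = rel.values
        if rel.source_type in CANCER_ALIGNED_TYPES:
            vals = vals[pos : pos + 1, :]
        if rel.target_type in CANCER_ALIGNED_TYPES:
            vals = vals[:, pos : pos + 1]
        relations[key] = RelationMatrix(rel.source_type, rel.target_type, vals.copy())
    return RelationGraph(catalogs, relations, graph.target_key)


def dataset_summary(graph: RelationGraph) -> pd.DataFrame:
    """Per-block shape and association counts, with target positives/negatives.

    Negatives are target cells with value 0 — unobserved pairs are treated as
    the negative class, so positives + negatives always equals the number of
    target cells.
    """
    rows = []
    for key, rel in graph.relations.items():
        n_rows, n_cols = rel.shape
        row = {
            "source": key[0],
            "target": key[1],
            "n_source": n_rows,
            "n_target": n_cols,
            "associations": rel.nnz,
            "is_target": key == graph.target_key,
        }
        if key == graph.target_key:
            row["positives"] = rel.nnz
            row["negatives"] = n_rows * n_cols - rel.nnz
        rows.append(row)
    return pd.DataFrame(rows)
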