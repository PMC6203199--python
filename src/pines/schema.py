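"""Ordered catalog of annotation columns.

The annotation vector layout is fixed by an :class:`AnnotationSchema`:
an ordered list of columns, each identified by a unique id and carrying
the histone mark / assay, the cell type (or ``"global"`` for
cell-type-independent tracks such as conservation), and a tissue group.
The canonical full layout pairs 5 marks (H3K4me1, H3K4me3, H3K27ac,
H3K9ac, DNase) with each of 127 reference epigenomes, plus 4 global
columns (GERP and SiPhy conserved elements, an aggregated ChromHMM DHS
state, and aggregated chromatin-interaction anchors), for 639 columns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K9ac", "DNase")
GLOBAL_COLUMNS = (
    ("GERP", "conservation"),
    ("SiPhy", "conservation"),
    ("ChromHMM_DHS", "chromatin_state"),
    ("chromatin_interaction", "interaction"),
)


@dataclass(frozen=True)
class AnnotationColumn:
    annotation_id: str
    mark: str
    cell_type: str  # "global" for cell-type-independent tracks
    group: str

    @property
    def is_global(self) -> bool:
        return self.cell_type == "global"


@dataclass
class AnnotationSchema:
    """Fixed, persisted ordering of annotation columns."""

    columns: list[AnnotationColumn]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [c.annotation_id for c in self.columns]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate annotation ids: {dupes}")
        self._index = {c.annotation_id: j for j, c in enumerate(self.columns)}

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def ids(self) -> list[str]:
        return [c.annotation_id for c in self.columns]

    def index_of(self, annotation_id: str) -> int:
        try:
            return self._index[annotation_id]
        except KeyError:
            raise KeyError(f"unknown annotation id: {annotation_id!r}") from None

    def indices_of(self, annotation_ids: Iterable[str]) -> list[int]:
        return [self.index_of(a) for a in annotation_ids]

    def __len__(self) -> int:
        return self.n_columns

    def __contains__(self, annotation_id: str) -> bool:
        return annotation_id in self._index

    def schema_hash(self) -> str:
        """Stable hash of the column layout, stamped into outputs."""
        h = hashlib.sha256()
        for c in self.columns:
            h.update(f"{c.annotation_id}\t{c.mark}\t{c.cell_type}\t{c.group}\n".encode())
        return h.hexdigest()[:12]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "annotation_id": [c.annotation_id for c in self.columns],
                "mark": [c.mark for c in self.columns],
                "cell_type": [c.cell_type for c in self.columns],
                "group": [c.group for c in self.columns],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationSchema":
        required = {"annotation_id", "mark", "cell_type", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"schema table missing columns: {sorted(missing)}")
        cols = [
            AnnotationColumn(str(r.annotation_id), str(r.mark), str(r.cell_type), str(r.group))
            for r in frame.itertuples(index=False)
        ]
        return cls(cols)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationSchema":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def roadmap_schema(
    cell_types: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    marks: Sequence[str] = MARKS,
) -> AnnotationSchema:
    """Build the canonical mark-by-cell-type layout plus global columns.

    With the defaults (127 epigenomes, 5 marks) this yields the full
    639-column layout: 635 cell-type-specific columns followed by the 4
    global columns.
    """
    if cell_types is None:
        cell_types = [f"E{i:03d}" for i in range(1, 128)]
    if groups is None:
        groups = ["unassigned"] * len(cell_types)
    if len(groups) != len(cell_types):
        raise ValueError("groups must align with cell_types")
    cols = [
        AnnotationColumn(f"{mark}.{ct}", mark, ct, grp)
        for ct, grp in zip(cell_types, groups)
        for mark in marks
    ]
    cols += [
        AnnotationColumn(name, name, "global", grp) for name, grp in GLOBAL_COLUMNS
    ]
    return AnnotationSchema(cols)


def generic_schema(n_columns: int, prefix: str = "ann") -> AnnotationSchema:
    """Anonymous schema for simulated annotation matrices."""
    cols = [
        AnnotationColumn(f"{prefix}{j:03d}", "simulated", f"cell{j:03d}", "simulated")
        for j in range(n_columns)
    ]
    return AnnotationSchema(cols)
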