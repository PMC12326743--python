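"""MRNet-layout dataset I/O and label-powerset encoding.

An exam carries three binary findings — general abnormality, ACL tear,
meniscus tear — stored in three two-column CSV tables. Only five of the
eight conceivable triples occur (a tear implies the abnormality flag), and
they are encoded as a single five-class label:

    (0,0,0) -> 0   healthy
    (1,0,0) -> 1   abnormal, no tear
    (1,0,1) -> 2   abnormal + meniscus tear
    (1,1,0) -> 3   abnormal + ACL tear
    (1,1,1) -> 4   abnormal + both tears

Volumes live as one ``.npy`` stack per exam and plane under
``<root>/<split>/<plane>/<exam_id>.npy`` with label tables
``<root>/<split>-{abnormal,acl,meniscus}.csv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

PLANES = ("axial", "coronal", "sagittal")
SPLITS = ("train", "valid")

#: the five observed (abnormal, acl, meniscus) combinations, in class order
VALID_TRIPLES = ((0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1))


class LabelTriple(NamedTuple):
    abnormal: int
    acl: int
    meniscus: int


class MissingLabelError(KeyError):
    """Exam id present in one label table but absent from another."""


class LabelParseError(ValueError):
    """Label value is not binary."""


class InvalidCombinationError(ValueError):
    """Label triple is not one of the five observed combinations."""


class MissingVolumeError(FileNotFoundError):
    """Labeled exam has no volume file on disk."""


class EmptyClassError(ValueError):
    """Requested class has no exams (strict mode)."""


def combine_labels(triple: Union[LabelTriple, Sequence[int]]) -> int:
    """Encode a finding triple as its powerset class id (0-4)."""
    t = tuple(int(v) for v in triple)
    try:
        return VALID_TRIPLES.index(t)
    except ValueError:
        raise InvalidCombinationError(
            f"triple {t} is not one of the five observed combinations "
            f"{VALID_TRIPLES}"
        ) from None


def decode_class(class_id: int) -> LabelTriple:
    """Inverse of :func:`combine_labels`."""
    if not 0 <= int(class_id) <= 4:
        raise InvalidCombinationError(f"class id {class_id} outside 0-4")
    return LabelTriple(*VALID_TRIPLES[int(class_id)])


@dataclass
class ExamRecord:
    """One exam: id, per-plane volumes (arrays or lazy file paths), labels."""

    exam_id: str
    volumes: Dict[str, Union[np.ndarray, Path]]
    triple: LabelTriple
    class_id: int

    def __post_init__(self):
        if self.class_id != combine_labels(self.triple):
            raise InvalidCombinationError(
                f"class_id {self.class_id} inconsistent with triple {self.triple}"
            )
        unknown = set(self.volumes) - set(PLANES)
        if unknown:
            raise ValueError(f"unknown plane names {sorted(unknown)}")

    def volume(self, plane: str) -> np.ndarray:
        """Materialize the volume for one plane (loads ``.npy`` lazily)."""
        v = self.volumes[plane]
        if isinstance(v, (str, Path)):
            v = np.load(v)
            self.volumes[plane] = v
        return v


@dataclass
class DatasetIndex:
    records: List[ExamRecord]
    split: str = "train"
    class_counts: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.exam_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate exam ids in index")
        if not self.class_counts:
            self.class_counts = self._count()
        elif sum(self.class_counts.values()) != len(self.records):
            raise ValueError("class_counts does not sum to record count")

    def _count(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for r in self.records:
            counts[r.class_id] = counts.get(r.class_id, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def classes(self) -> List[int]:
        return sorted(self.class_counts)

    def by_class(self) -> Dict[int, List[ExamRecord]]:
        out: Dict[int, List[ExamRecord]] = {}
        for r in self.records:
            out.setdefault(r.class_id, []).append(r)
        return out


def _read_table(path: Union[str, Path]) -> Dict[str, int]:
    """One two-column (exam id, 0/1) CSV; optional header row; ids kept as text."""
    try:
        df = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if df.shape[1] != 2:
        raise LabelParseError(f"{path}: expected two columns, got {df.shape[1]}")
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first == ["exam", "label"]:
        df = df.iloc[1:]
    out: Dict[str, int] = {}
    for exam_id, raw in zip(df.iloc[:, 0], df.iloc[:, 1]):
        val = str(raw).strip()
        if val not in ("0", "1"):
            raise LabelParseError(f"{path}: non-binary label {raw!r} for exam {exam_id!r}")
        out[str(exam_id).strip()] = int(val)
    return out


def read_label_tables(
    abnormal_table: Union[str, Path],
    acl_table: Union[str, Path],
    meniscus_table: Union[str, Path],
) -> Dict[str, LabelTriple]:
    """Merge the three per-finding tables into one triple per exam id."""
    abnormal = _read_table(abnormal_table)
    acl = _read_table(acl_table)
    meniscus = _read_table(meniscus_table)
    keys = set(abnormal) | set(acl) | set(meniscus)
    for name, table in (("abnormal", abnormal), ("acl", acl), ("meniscus", meniscus)):
        missing = keys - set(table)
        if missing:
            raise MissingLabelError(
                f"exam ids {sorted(missing)} missing from the {name} table"
            )
    return {
        k: LabelTriple(abnormal[k], acl[k], meniscus[k]) for k in sorted(keys)
    }


def label_table_paths(root: Union[str, Path], split: str) -> Dict[str, Path]:
    root = Path(root)
    return {
        "abnormal": root / f"{split}-abnormal.csv",
        "acl": root / f"{split}-acl.csv",
        "meniscus": root / f"{split}-meniscus.csv",
    }


def load_dataset(
    root: Union[str, Path],
    split: str = "train",
    plane: Union[str, Sequence[str]] = PLANES,
) -> DatasetIndex:
    """Index an MRNet-layout directory; volumes stay on disk until accessed."""
    if split not in SPLITS:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    planes = (plane,) if isinstance(plane, str) else tuple(plane)
    for p in planes:
        if p not in PLANES:
            raise ValueError(f"unknown plane {p!r}")
    root = Path(root)
    tables = label_table_paths(root, split)
    triples = read_label_tables(tables["abnormal"], tables["acl"], tables["meniscus"])
    records = []
    for exam_id, triple in triples.items():
        volumes: Dict[str, Union[np.ndarray, Path]] = {}
        for p in planes:
            path = root / split / p / f"{exam_id}.npy"
            if not path.exists():
                raise MissingVolumeError(
                    f"labeled exam {exam_id!r} has no {p} volume at {path}"
                )
            volumes[p] = path
        records.append(
            ExamRecord(exam_id, volumes, triple, combine_labels(triple))
        )
    return DatasetIndex(records, split=split)


def subset_by_class(
    index: DatasetIndex,
    classes: Sequence[int],
    strict: bool = False,
) -> DatasetIndex:
    """Restrict an index to the given class ids (class-split experiments)."""
    wanted = set(int(c) for c in classes)
    if not wanted <= set(range(5)):
        raise ValueError(f"classes must be within 0-4, got {sorted(wanted)}")
    absent = wanted - set(index.class_counts)
    if absent:
        msg = f"classes {sorted(absent)} have no exams in this index"
        if strict:
            raise EmptyClassError(msg)
        warnings.warn(msg, stacklevel=2)
    records = [r for r in index.records if r.class_id in wanted]
    return DatasetIndex(records, split=index.split)
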