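"""Reading, cleaning and partitioning of omics matrices and label tables.

Cleaning rules: duplicate sample IDs keep the most recent (last-occurring)
entry; features with more than ``max_na_fraction`` missing values are
dropped and remaining missing values are replaced with 0; samples missing
from any omics view or from the label table are excluded.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OmicsMatrix",
    "LabelTable",
    "DataSplit",
    "ParseError",
    "read_omics_matrix",
    "read_label_table",
    "deduplicate_samples",
    "filter_missing_features",
    "align_samples",
    "stratified_split",
    "write_omics_matrix",
]

#: strings treated as missing markers when parsing matrix cells
NA_STRINGS = {"", "na", "nan", "n/a", "null", "none"}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass
class OmicsMatrix:
    """One omics view: samples x features with row/column labels.

    ``values`` may contain NaN (missing markers) before cleaning; after
    :func:`filter_missing_features` no missing values remain.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    name: str = "omics"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} rows")
        if d != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names but {d} columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, row_index: np.ndarray) -> "OmicsMatrix":
        """Return a copy restricted (and reordered) to ``row_index``."""
        return OmicsMatrix(
            sample_ids=[self.sample_ids[i] for i in row_index],
            feature_names=list(self.feature_names),
            values=self.values[row_index].copy(),
            name=self.name,
        )


@dataclass
class LabelTable:
    """Sample-ID -> class label mapping.

    ``classes`` lists distinct labels in first-appearance order; the class
    index of sample ``i`` is ``classes.index(labels[i])``.
    """

    sample_ids: list[str]
    labels: list[str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in label table")
        if not self.classes:
            seen: dict[str, None] = {}
            for lab in self.labels:
                seen.setdefault(lab, None)
            self.classes = list(seen)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_indices(self) -> np.ndarray:
        """Integer class index per sample, in ``classes`` order."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[lab] for lab in self.labels], dtype=int)

    def subset(self, row_index: np.ndarray) -> "LabelTable":
        return LabelTable(
            sample_ids=[self.sample_ids[i] for i in row_index],
            labels=[self.labels[i] for i in row_index],
            classes=list(self.classes),
        )


@dataclass
class DataSplit:
    """Disjoint train/test index sets over the aligned samples."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")

    def to_json(self, sample_ids: list[str]) -> str:
        return json.dumps({
            "seed": self.seed,
            "train": [sample_ids[i] for i in self.train_indices],
            "test": [sample_ids[i] for i in self.test_indices],
        }, indent=2)


def _parse_cell(text: str) -> float:
    if text.strip().lower() in NA_STRINGS:
        return math.nan
    try:
        return float(text)
    except ValueError:
        return math.nan


def read_omics_matrix(path: str, delimiter: str = ",",
                      samples_as: str = "rows",
                      name: str | None = None) -> OmicsMatrix:
    """Read a delimited numeric matrix with a header row and ID column.

    The first row holds feature names (after an ignored corner cell) and
    the first column holds sample IDs; ``samples_as='columns'`` transposes
    the cBioPortal samples-as-columns convention. Unparseable or NA cells
    become missing markers (NaN). Duplicate sample IDs are allowed (see
    :func:`deduplicate_samples`); duplicate feature names are an error.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader if row]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ParseError(f"{path}: empty or header-only matrix")
    header = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    row_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(row)} fields, expected {width}")
        row_ids.append(row[0].strip())
        data.append([_parse_cell(c) for c in row[1:]])
    values = np.array(data, dtype=float)

    if samples_as == "columns":
        sample_ids, feature_names = header, row_ids
        values = values.T
    elif samples_as == "rows":
        sample_ids, feature_names = row_ids, header
    else:
        raise ValueError("samples_as must be 'rows' or 'columns'")

    from collections import Counter
    dupes = sorted(f for f, c in Counter(feature_names).items() if c > 1)
    if dupes:
        raise ParseError(
            f"{path}: duplicated feature names: {', '.join(dupes)}")
    return OmicsMatrix(sample_ids=list(sample_ids),
                       feature_names=list(feature_names),
                       values=values,
                       name=name or "omics")


def write_omics_matrix(m: OmicsMatrix, path: str,
                       delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["sample_id", *m.feature_names])
        for sid, row in zip(m.sample_ids, m.values):
            writer.writerow([sid] + ["NA" if math.isnan(v) else repr(float(v))
                                     for v in row])


def read_label_table(path: str, delimiter: str = ",") -> LabelTable:
    """Read a two-column (sample_id, label) table; a header row is
    detected by the literal column name ``sample_id``."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = [row for row in reader if row]
    if not rows:
        raise ParseError(f"{path}: empty label file")
    if rows[0][0].strip().lower() in {"sample_id", "sample", "id"}:
        rows = rows[1:]
    sample_ids = [r[0].strip() for r in rows]
    labels = [r[1].strip() for r in rows]
    return LabelTable(sample_ids=sample_ids, labels=labels)


def deduplicate_samples(m: OmicsMatrix, keep: str = "last") -> OmicsMatrix:
    """Drop duplicate sample IDs, keeping the most recent entry.

    Recency is positional: ``keep='last'`` (default) retains the
    last-occurring row for each duplicated ID; ``keep='first'`` the first.
    Retained rows stay in file order.
    """
    if keep not in ("first", "last"):
        raise ValueError("keep must be 'first' or 'last'")
    chosen: dict[str, int] = {}
    for i, sid in enumerate(m.sample_ids):
        if keep == "last" or sid not in chosen:
            chosen[sid] = i
    index = np.array(sorted(chosen.values()), dtype=int)
    return m.subset(index)


def filter_missing_features(m: OmicsMatrix,
                            max_na_fraction: float = 0.10) -> OmicsMatrix:
    """Drop features with strictly more than ``max_na_fraction`` missing
    values, then replace remaining missing values with 0."""
    na_frac = np.mean(np.isnan(m.values), axis=0)
    keep = na_frac <= max_na_fraction
    if not keep.any():
        raise ValueError(
            f"all {m.n_features} features exceed the NA threshold "
            f"{max_na_fraction:g}")
    values = m.values[:, keep].copy()
    values[np.isnan(values)] = 0.0
    return OmicsMatrix(
        sample_ids=list(m.sample_ids),
        feature_names=[f for f, k in zip(m.feature_names, keep) if k],
        values=values,
        name=m.name,
    )


def align_samples(omics: list[OmicsMatrix], labels: LabelTable
                  ) -> tuple[list[OmicsMatrix], LabelTable]:
    """Restrict all views and the label table to their common samples.

    The canonical order is the first view's sample order filtered to the
    intersection; samples without labels are dropped.
    """
    if not omics:
        raise ValueError("need at least one omics view")
    common = set(omics[0].sample_ids)
    for m in omics[1:]:
        common &= set(m.sample_ids)
    common &= set(labels.sample_ids)
    order = [sid for sid in omics[0].sample_ids if sid in common]
    if not order:
        raise ValueError("no samples shared across all views and labels")

    aligned = []
    for m in omics:
        pos = {sid: i for i, sid in enumerate(m.sample_ids)}
        aligned.append(m.subset(np.array([pos[sid] for sid in order])))
    lpos = {sid: i for i, sid in enumerate(labels.sample_ids)}
    aligned_labels = labels.subset(np.array([lpos[sid] for sid in order]))
    return aligned, aligned_labels


def stratified_split(labels: LabelTable, train_fraction: float = 0.75,
                     seed: int = 0) -> DataSplit:
    """Per-class proportional train/test partition, deterministic in seed.

    The overall train size is ``round(n * train_fraction)``; per-class
    counts are allocated by largest remainder so every class deviates from
    the target fraction by less than one sample. Singleton classes go to
    the training set with a warning.
    """
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must be in (0, 1]")
    y = labels.class_indices()
    n = len(y)
    rng = np.random.default_rng(seed)

    groups = [np.flatnonzero(y == c) for c in range(labels.n_classes)]
    for c, g in enumerate(groups):
        if len(g) == 1:
            warnings.warn(
                f"class {labels.classes[c]!r} has a single sample; "
                "placing it in the training set")

    target_total = int(round(n * train_fraction))
    exact = [len(g) * train_fraction for g in groups]
    counts = [int(math.floor(e)) for e in exact]
    # singletons always train
    for c, g in enumerate(groups):
        if len(g) == 1:
            counts[c] = 1
    remainders = sorted(
        ((exact[c] - math.floor(exact[c]), c) for c in range(len(groups))
         if len(groups[c]) > 1 and counts[c] < len(groups[c])),
        key=lambda t: (-t[0], t[1]))
    deficit = target_total - sum(counts)
    for _, c in remainders:
        if deficit <= 0:
            break
        counts[c] += 1
        deficit -= 1

    train, test = [], []
    for c, g in enumerate(groups):
        perm = rng.permutation(g)
        train.extend(perm[:counts[c]])
        test.extend(perm[counts[c]:])
    return DataSplit(train_indices=np.sort(train),
                     test_indices=np.sort(test), seed=seed)
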