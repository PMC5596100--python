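"""Domain types for multimodal feature tables and their delimited-text I/O.

A *measure* is one homogeneous block of features (e.g. per-parcel cortical
thickness, or the vectorized group-ICA connectivity matrix) stored as a
subjects x features matrix.  A :class:`MultimodalDataset` bundles several
measures that share one subject cohort and one binary diagnosis label per
subject.  Subject order is canonicalized to the label file's order at
assembly so that row misalignment between measures cannot occur silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("cortical", "subcortical", "wholebrain", "gica")


class DataValidationError(ValueError):
    """Raised when a feature table or label file violates an invariant."""


@dataclass(frozen=True)
class FeatureMeasure:
    """One measure's subjects x features matrix with anatomical group tag.

    Parameters
    ----------
    label
        Measure name, unique within a dataset (e.g. ``"Thickness"``).
    group
        One of ``cortical``, ``subcortical``, ``wholebrain``, ``gica``.
    values
        Real matrix, shape ``(n_subjects, n_features)``; all entries finite.
    feature_names, subject_ids
        Column and row identifiers; lengths must match ``values``.
    weight_key
        Label of the fusion weight this measure uses.  Defaults to
        ``label``; distinct measures may share one weight (the whole-brain
        intensity and global-connectivity blocks share the weights of their
        subcortical counterparts, keeping twelve weights for fourteen
        feature blocks).
    """

    label: str
    group: str
    values: np.ndarray
    feature_names: list[str]
    subject_ids: list[str]
    weight_key: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.weight_key:
            object.__setattr__(self, "weight_key", self.label)
        if self.group not in GROUPS:
            raise DataValidationError(
                f"measure {self.label!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if self.values.ndim != 2:
            raise DataValidationError(f"measure {self.label!r}: values must be 2-D")
        n, d = self.values.shape
        if n != len(self.subject_ids):
            raise DataValidationError(
                f"measure {self.label!r}: {n} rows but {len(self.subject_ids)} subject ids"
            )
        if d != len(self.feature_names):
            raise DataValidationError(
                f"measure {self.label!r}: {d} columns but {len(self.feature_names)} feature names"
            )
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise DataValidationError(
                f"measure {self.label!r}: duplicated subject ids {dupes}"
            )
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DataValidationError(
                f"measure {self.label!r}: non-finite value at subject "
                f"{self.subject_ids[i]!r}, feature {self.feature_names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def reordered(self, subject_ids: list[str]) -> "FeatureMeasure":
        """Return a copy with rows reordered to ``subject_ids``."""
        missing = [s for s in subject_ids if s not in set(self.subject_ids)]
        if missing:
            raise DataValidationError(
                f"measure {self.label!r}: missing subjects {missing}"
            )
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = np.array([pos[s] for s in subject_ids])
        return replace(self, values=self.values[idx], subject_ids=list(subject_ids))


@dataclass(frozen=True)
class SubjectLabels:
    """Per-subject binary diagnosis (``control`` vs ``patient``)."""

    subject_ids: list[str]
    diagnosis: list[str]

    CLASSES = ("control", "patient")

    def __post_init__(self):
        if len(self.subject_ids) != len(self.diagnosis):
            raise DataValidationError("subject_ids and diagnosis length mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataValidationError("duplicated subject ids in label file")
        bad = sorted(set(self.diagnosis) - set(self.CLASSES))
        if bad:
            raise DataValidationError(f"unknown diagnosis values {bad}")
        if len(set(self.diagnosis)) < 2:
            raise DataValidationError("both classes must be present")

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 0 = control, 1 = patient."""
        return np.array([self.CLASSES.index(d) for d in self.diagnosis])


@dataclass(frozen=True)
class MultimodalDataset:
    """Ordered collection of measures aligned to one label vector."""

    measures: tuple[FeatureMeasure, ...]
    labels: SubjectLabels

    def __post_init__(self):
        object.__setattr__(self, "measures", tuple(self.measures))
        labels_seen = [m.label for m in self.measures]
        if len(set(labels_seen)) != len(labels_seen):
            raise DataValidationError(f"duplicate measure labels in {labels_seen}")
        for m in self.measures:
            if m.subject_ids != self.labels.subject_ids:
                raise DataValidationError(
                    f"measure {m.label!r}: subject ids do not match label order"
                )

    def __getitem__(self, label: str) -> FeatureMeasure:
        for m in self.measures:
            if m.label == label:
                return m
        raise KeyError(label)

    @property
    def measure_labels(self) -> list[str]:
        return [m.label for m in self.measures]

    @property
    def weight_keys(self) -> list[str]:
        """Distinct weight keys in first-appearance order."""
        seen: list[str] = []
        for m in self.measures:
            if m.weight_key not in seen:
                seen.append(m.weight_key)
        return seen

    @property
    def n_subjects(self) -> int:
        return len(self.labels)


def total_feature_count(dataset: MultimodalDataset) -> int:
    """Sum of per-measure column counts."""
    return int(sum(m.n_features for m in dataset.measures))


def _read_table(path, sep: str) -> pd.DataFrame:
    # na_filter=False keeps "NA"/"" as literal strings so they can be
    # reported as parse errors instead of silently becoming NaN
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, na_filter=False)
    if df.columns.size == 0:
        raise DataValidationError(f"{path}: no feature columns found in header")
    return df


def load_measure(path, label: str, group: str, *, weight_key: str = "",
                 sep: str = ",") -> FeatureMeasure:
    """Read a delimited feature table (header = feature names, first column
    = subject id) into a validated :class:`FeatureMeasure`.

    Row order of the file is preserved.  Non-numeric or missing cells are a
    hard error naming the offending subject and feature.
    """
    df = _read_table(path, sep)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        cells = df[col].to_numpy()
        try:
            # exact round-trip parsing (pd.to_numeric can be 1 ulp off)
            values[:, j] = cells.astype(float)
        except ValueError:
            for i, raw in enumerate(cells):
                try:
                    float(raw)
                except ValueError:
                    raise DataValidationError(
                        f"{path}: non-numeric value {raw!r} at subject "
                        f"{df.index[i]!r}, feature {col!r}"
                    ) from None
            raise
    return FeatureMeasure(
        label=label, group=group, values=values,
        feature_names=[str(c) for c in df.columns],
        subject_ids=[str(s) for s in df.index],
        weight_key=weight_key,
    )


def save_measure(measure: FeatureMeasure, path, *, sep: str = ",") -> None:
    """Write a measure as delimited text (inverse of :func:`load_measure`)."""
    df = pd.DataFrame(measure.values, index=measure.subject_ids,
                      columns=measure.feature_names)
    df.index.name = "subject_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def load_labels(path, *, sep: str = ",") -> SubjectLabels:
    """Read a labels file with columns ``subject_id`` and ``diagnosis``."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("subject_id", "diagnosis"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    return SubjectLabels(subject_ids=list(df["subject_id"]),
                         diagnosis=list(df["diagnosis"]))


def save_labels(labels: SubjectLabels, path, *, sep: str = ",") -> None:
    pd.DataFrame({"subject_id": labels.subject_ids,
                  "diagnosis": labels.diagnosis}).to_csv(path, sep=sep, index=False)


def assemble_dataset(measures, labels: SubjectLabels) -> MultimodalDataset:
    """Align measures row-wise to the label order and validate the bundle.

    Measures whose subject sets differ from the label file raise an error
    listing the offending ids; matching measures are reordered, never
    silently subset.
    """
    measures = list(measures)
    if not measures:
        raise DataValidationError("at least one measure is required")
    canonical = labels.subject_ids
    aligned = []
    for m in measures:
        extra = sorted(set(m.subject_ids) - set(canonical))
        missing = sorted(set(canonical) - set(m.subject_ids))
        if extra or missing:
            raise DataValidationError(
                f"measure {m.label!r}: subject ids disagree with labels "
                f"(missing from measure: {missing}; not in labels: {extra})"
            )
        aligned.append(m.reordered(canonical))
    return MultimodalDataset(measures=tuple(aligned), labels=labels)
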