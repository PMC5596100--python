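"""Seeded generator of synthetic multimodal datasets.

Produces two-class Gaussian feature tables with the statistical structure
the fusion method assumes: per measure, a configurable fraction of
*informative* columns whose class means are separated by an effect size
delta (in noise-SD units) and which are equicorrelated at rho within the
measure; the remaining columns are pure noise.  Per-feature separability
is analytic under this model (two-sample AUC = Phi(delta / sqrt(2))), so
programmed effect sizes translate predictably into per-measure accuracies
and hence into fusion weights.

The default spec mirrors the reimplemented study's feature inventory:
fourteen feature blocks mapped onto twelve weighted measures (the
whole-brain intensity and global-connectivity blocks share their
subcortical counterparts' weights), 748 features total, and two balanced
groups of 72 subjects.  It makes no attempt to mimic the marginal
distributions of real morphometry; it exists to exercise the method.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .datamodel import (FeatureMeasure, MultimodalDataset, SubjectLabels,
                        assemble_dataset)


@dataclass(frozen=True)
class MeasureSpec:
    """Generative description of one feature block."""

    label: str
    group: str
    n_features: int
    effect_size: float = 0.0          # class-mean separation, noise-SD units
    informative_fraction: float = 0.5  # fraction of columns carrying signal
    rho: float = 0.2                   # equicorrelation of informative columns
    weight_key: str = ""

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError(f"{self.label!r}: n_features must be positive")
        if self.effect_size < 0:
            raise ValueError(f"{self.label!r}: effect size must be >= 0")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValueError(f"{self.label!r}: informative fraction in (0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"{self.label!r}: rho must be in [0, 1)")
        if not self.weight_key:
            object.__setattr__(self, "weight_key", self.label)

    @property
    def n_informative(self) -> int:
        return max(1, math.ceil(self.informative_fraction * self.n_features))


@dataclass(frozen=True)
class SynthSpec:
    """Full generative description of a multimodal dataset."""

    measures: tuple
    n_per_group: tuple = (72, 72)
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "measures", tuple(self.measures))
        object.__setattr__(self, "n_per_group", tuple(self.n_per_group))
        if not self.measures:
            raise ValueError("spec needs at least one measure")
        if min(self.n_per_group) < 1 or len(self.n_per_group) != 2:
            raise ValueError("n_per_group must be two positive counts")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")

    @property
    def total_features(self) -> int:
        return sum(m.n_features for m in self.measures)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# (label, group, n_features, effect size, weight key or None)
# Feature counts follow the study's inventory: 449 cortical, 76 subcortical,
# 52 whole-brain structural/connectivity, 171 group-ICA; 748 in total.
# Effect sizes are fixed, moderate, and deliberately unequal so that
# per-measure accuracies differ and the weighting scheme has work to do;
# the group-ICA block gets the largest separation.
_TABLE_BLOCKS = (
    ("Thickness",         "cortical",    64, 0.80, None),
    ("Thickness STD",     "cortical",    62, 0.70, None),
    ("Surface Area",      "cortical",    64, 0.50, None),
    ("Volume",            "cortical",    62, 0.70, None),
    ("Curvature",         "cortical",    62, 0.90, None),
    ("WM",                "cortical",    68, 0.60, None),
    ("Cortical GCOR",     "cortical",    67, 0.70, None),
    ("SC Volume",         "subcortical", 26, 0.65, None),
    ("SC Intensity",      "subcortical", 26, 0.65, None),
    ("SC GCOR",           "subcortical", 24, 0.80, None),
    ("Overall Volume",    "wholebrain",  27, 0.75, None),
    ("Overall Intensity", "wholebrain",  14, 0.65, "SC Intensity"),
    ("Overall GCOR",      "wholebrain",  11, 0.80, "SC GCOR"),
    ("Group ICA",         "gica",       171, 1.00, None),
)


def table2_spec(seed: int = 0) -> SynthSpec:
    """Default spec reproducing the study's feature inventory: fourteen
    blocks, twelve weight keys, 748 features, 72 + 72 subjects."""
    measures = tuple(
        MeasureSpec(label=label, group=group, n_features=n,
                    effect_size=delta, weight_key=wk or "")
        for label, group, n, delta, wk in _TABLE_BLOCKS
    )
    return SynthSpec(measures=measures, n_per_group=(72, 72), seed=seed)


def _generate_block(spec: MeasureSpec, y: np.ndarray, noise: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    d = spec.n_features
    k = spec.n_informative
    X = rng.standard_normal((n, d))
    if spec.rho > 0 and k > 1:
        shared = rng.standard_normal((n, 1))
        X[:, :k] = (math.sqrt(spec.rho) * shared
                    + math.sqrt(1.0 - spec.rho) * X[:, :k])
    X *= noise
    # class means at -delta/2 and +delta/2 (in noise-SD units)
    shift = (y - 0.5) * spec.effect_size * noise
    X[:, :k] += shift[:, None]
    return X


def generate_dataset(spec: SynthSpec) -> MultimodalDataset:
    """Draw one dataset from a spec; deterministic given ``spec.seed``."""
    n0, n1 = spec.n_per_group
    n = n0 + n1
    width = max(3, len(str(n)))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    diagnosis = ["control"] * n0 + ["patient"] * n1
    labels = SubjectLabels(subject_ids=subject_ids, diagnosis=diagnosis)
    y = labels.y.astype(float)

    rng = np.random.default_rng(spec.seed)
    measures = []
    for mspec in spec.measures:
        values = _generate_block(mspec, y, spec.noise_scale, rng)
        measures.append(FeatureMeasure(
            label=mspec.label, group=mspec.group, values=values,
            feature_names=[f"{mspec.label}_f{j + 1}" for j in range(mspec.n_features)],
            subject_ids=subject_ids, weight_key=mspec.weight_key,
        ))
    return assemble_dataset(measures, labels)
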