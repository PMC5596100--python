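import numpy as np
import pytest

from mmfuse.datamodel import FeatureMeasure, SubjectLabels, assemble_dataset
from mmfuse.synthdata import MeasureSpec, SynthSpec, generate_dataset


def make_measure(label, group, values, *, weight_key="", ids=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    ids = ids if ids is not None else [f"S{i:03d}" for i in range(1, n + 1)]
    return FeatureMeasure(
        label=label, group=group, values=values,
        feature_names=[f"{label}_f{j + 1}" for j in range(d)],
        subject_ids=list(ids), weight_key=weight_key,
    )


def make_labels(n_control, n_patient):
    n = n_control + n_patient
    return SubjectLabels(
        subject_ids=[f"S{i:03d}" for i in range(1, n + 1)],
        diagnosis=["control"] * n_control + ["patient"] * n_patient,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def tiny_spec():
    """Small three-group spec: one informative cortical measure among nulls."""
    return SynthSpec(
        measures=(
            MeasureSpec("CortA", "cortical", 10, effect_size=3.0),
            MeasureSpec("CortB", "cortical", 10, effect_size=0.0),
            MeasureSpec("SubA", "subcortical", 8, effect_size=0.0),
            MeasureSpec("ICA", "gica", 6, effect_size=0.0),
        ),
        n_per_group=(20, 20),
        seed=7,
    )


@pytest.fixture
def tiny_dataset(tiny_spec):
    return generate_dataset(tiny_spec)
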