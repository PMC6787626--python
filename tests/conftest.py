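import numpy as np
import pytest

from wstkit.forest import RFParams, fit_rf
from wstkit.scoring import score_table
from wstkit.synthetic import ClassMarkerSpec, CohortConfig, generate_cohort

SEP_FEATURES = ["marker_sep", "noise0", "noise1", "noise2", "noise3", "noise4"]


def separable_config(seed: int = 3, n_per_class: int = 40,
                     medians=(100.0, 170.0, 240.0)) -> CohortConfig:
    """Three case classes, one marker shifted several IQRs between classes,
    five exchangeable noise markers.  Using 4-class ids 1/2/3 makes the
    merged labels 0/1/2 with equal sizes."""
    specs = []
    for cls, med in zip((1, 2, 3), medians):
        specs.append(
            ClassMarkerSpec("marker_sep", cls, med,
                            med * np.exp(-0.6745 * 0.1), med * np.exp(0.6745 * 0.1))
        )
        for j in range(5):
            specs.append(
                ClassMarkerSpec(f"noise{j}", cls, 50.0,
                                50 * np.exp(-0.6745 * 0.3), 50 * np.exp(0.6745 * 0.3))
            )
    return CohortConfig(
        class_sizes={1: n_per_class, 2: n_per_class, 3: n_per_class},
        marker_specs=specs,
        urine_missing_rate=0.0,
        seed=seed,
        missing_markers=(),
    )


@pytest.fixture(scope="session")
def separable_cohort():
    return score_table(generate_cohort(separable_config()))


@pytest.fixture(scope="session")
def separable_model(separable_cohort):
    return fit_rf(
        separable_cohort[SEP_FEATURES],
        separable_cohort["class3"].to_numpy(),
        RFParams(ntree=500, seed=1),
    )
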