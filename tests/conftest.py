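import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from brainfc.pipeline import RunConfig, extract_measure
from brainfc.synthetic import CohortSpec, make_cohort, make_group_models


@pytest.fixture(scope="session")
def demo_cohort():
    """The default demo cohort: 20 ROIs, 60+60 subjects, 8 planted edges at
    correlation shift 0.4, T=370, TR=0.8 s."""
    models = make_group_models(20, 8, 0.4, seed=1)
    spec = CohortSpec(n_subjects_per_group=(60, 60), t_points=370, seed=1)
    return make_cohort(models, spec)


@pytest.fixture(scope="session")
def demo_pc_table(demo_cohort):
    """Residualized Pearson-FC feature table for the demo cohort."""
    return extract_measure(demo_cohort, "PC", RunConfig(seed=1))


def mini_cohort(seed: int, n_subjects: int = 3, t_points: int = 30, n_rois: int = 5):
    """Tiny random cohort for solver oracle checks (no group structure)."""
    import types

    from brainfc.connectivity import RoiTimeSeries

    rng = np.random.default_rng(seed)
    subs = [RoiTimeSeries(rng.standard_normal((t_points, n_rois)))
            for _ in range(n_subjects)]
    return types.SimpleNamespace(subjects=subs)
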