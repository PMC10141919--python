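import numpy as np
import pandas as pd
import pytest

from flowsense import preprocessing as pp
from flowsense import features as ft
from flowsense import rasch
from flowsense import synthetic as syn


def labelled_feature_table(bundle: syn.StudyBundle) -> pd.DataFrame:
    """Feature table with the observed (survey-derived) flow labels."""
    windows = []
    for session in bundle.sessions:
        windows.extend(pp.build_task_windows(session))
    table = ft.build_feature_table(windows)
    labels = rasch.label_flow(bundle.fss_matrix())
    key = pd.MultiIndex.from_frame(table[["participant_id", "task_id"]])
    table["flow"] = labels.reindex(key).to_numpy().astype(int)
    return table


@pytest.fixture(scope="session")
def study1_bundle():
    """A default five-participant synthetic study (fixed seed)."""
    return syn.generate_study(syn.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def study1_table(study1_bundle):
    return labelled_feature_table(study1_bundle)


@pytest.fixture(scope="session")
def small_bundle():
    """A fast miniature study for I/O and plumbing tests: short baselines
    and tasks (still longer than every trim window)."""
    config = syn.GeneratorConfig(
        n_participants=2,
        activities_per_participant=1,
        tasks_per_activity=3,
        baseline_s=40.0,
        task_duration_range=(30.0, 90.0),
        task_duration_mean=50.0,
        seed=5,
    )
    return syn.generate_study(config)


@pytest.fixture()
def small_session(small_bundle):
    return small_bundle.sessions[0]


@pytest.fixture(scope="session")
def rsm_simulated():
    """Responses simulated from a known Rating Scale Model (N = 200)."""
    rng = np.random.default_rng(42)
    n = 200
    beta_true = rng.normal(0.0, 1.5, size=n)
    delta_true = np.array([-1.5, -1.0, -0.5, -0.2, 0.0, 0.3, 0.6, 1.0, 1.3])
    tau = np.array([-1.5, -0.5, 0.5, 1.5])
    rows = [syn.generate_fss_responses(b, delta_true, tau, rng) for b in beta_true]
    return pd.DataFrame(rows, columns=list(rasch.ITEM_NAMES)), beta_true, delta_true, tau
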