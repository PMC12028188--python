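import numpy as np
import pytest

from tyromark.multimodel import HyperSpace, run_multimodel
from tyromark.preprocess import build_dataset
from tyromark.synthetic import SyntheticConfig, VisitRecord, generate_cohorts

#: compact hyperparameter space used throughout the tests to keep runs fast
FAST_SPACE = HyperSpace(tree_depth=(2, 3))
FAST_ESTIMATORS = 20


def complete_record(**overrides) -> VisitRecord:
    """A visit record with every variable present; fields overridable."""
    base = dict(
        patient_id="P001", cohort="A", hcc=False,
        age_at_diagnosis=9.0, age_at_control=24.0,
        ntbc=40.0, afp=3.0, phe=55.0, met=30.0, tyr=380.0,
        alt=25.0, ast=35.0, ggt=30.0, prothrombin_time=1.0,
        total_bilirubin=0.6, alkaline_phosphatase=250.0,
        glycemia=90.0, suac_detected=False,
    )
    base.update(overrides)
    return VisitRecord(**base)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def records(default_config):
    return generate_cohorts(default_config)


@pytest.fixture(scope="session")
def dataset_biochem(records):
    return build_dataset(records, include_age=False, seed=7)


@pytest.fixture(scope="session")
def split_datasets(dataset_biochem):
    """(train cohort A, externals {B, C}) from the session dataset."""
    ds = dataset_biochem
    c = ds.cohort_labels
    train = ds.subset(np.where(c == "A")[0])
    external = {x: ds.subset(np.where(c == x)[0]) for x in ("B", "C")}
    return train, external


@pytest.fixture(scope="session")
def mini_result(split_datasets):
    """A small retained-round collection shared by consensus-level tests."""
    train, external = split_datasets
    return run_multimodel(train, external, n_rounds=30, auc_threshold=0.7,
                          space=FAST_SPACE, master_seed=11,
                          n_estimators=FAST_ESTIMATORS)
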