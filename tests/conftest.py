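import numpy as np
import pytest

from petmine.synthetic import (
    SyntheticConfig,
    gen_homolog_family,
    gen_ogt_proteomes,
    gen_triage_scenario,
)
from petmine.thermoprot import (
    ClassifierSpec,
    LabeledDataset,
    dataset_from_ogt,
    train_classifier,
)


def train_model_on_proteomes(delta: float, seed: int, n_per_class: int = 250,
                             length=(90, 110), scheme: str = "MTH",
                             method: str = "support_vector_machine"):
    """Train a classifier on a fresh proteome draw, 80/20 train/tune by index."""
    cfg = SyntheticConfig(seed=seed + 1000, n_per_class=n_per_class,
                          delta=delta, length=length)
    records, _ = gen_ogt_proteomes(cfg)
    ds = dataset_from_ogt(records)
    n = len(ds.records) // 2          # records come class-blocked
    cut = int(0.8 * n)
    idx_tr = list(range(cut)) + list(range(n, n + cut))
    idx_tu = list(range(cut, n)) + list(range(n + cut, 2 * n))
    def sub(idx):
        return LabeledDataset(
            [ds.records[i] for i in idx], [ds.labels[i] for i in idx],
            ds.features[idx], ds.feature_names,
        )
    spec = ClassifierSpec(scheme=scheme, method=method, seed=seed)
    return train_classifier(spec, sub(idx_tr), sub(idx_tu))


@pytest.fixture(scope="session")
def separable_family():
    """Homolog family in the separable regime (diverged inactive subfamily)."""
    cfg = SyntheticConfig(seed=1, length=(80, 120), n_active=20, n_inactive=20,
                          mutation_rate=0.05, inactive_extra_rate=0.15)
    records, aln, truth = gen_homolog_family(cfg)
    return records, aln, truth


@pytest.fixture(scope="session")
def triage_scenario():
    scenario = gen_triage_scenario(3)
    model = train_model_on_proteomes(scenario["classifier_delta"], seed=3)
    return scenario, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
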