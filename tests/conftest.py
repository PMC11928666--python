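import numpy as np
import pytest

from _utils import mutate, random_seq
from ayu.seq_io import ProteinRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def homolog_fixture():
    """Planted homolog chains: 10 families of 3 chained mutants (~70%
    pairwise identity within a chain link) plus 18 unrelated singletons,
    with localization labels spread over the classes."""
    from ayu.seq_io import LocalizationLabel

    rng = np.random.default_rng(7)
    records, labels = [], {}
    classes = [LocalizationLabel.CYTOPLASMIC, LocalizationLabel.PERIPLASMIC,
               LocalizationLabel.EXTRACELLULAR]
    n = 0
    for fam in range(10):
        base = random_seq(rng, 120)
        chain = [base, mutate(rng, base, 0.3)]
        chain.append(mutate(rng, chain[1], 0.3))
        for seq in chain:
            records.append(ProteinRecord(id=f"h{n:03d}", seq=seq))
            labels[f"h{n:03d}"] = classes[n % 3]
            n += 1
    for _ in range(18):
        records.append(ProteinRecord(id=f"h{n:03d}", seq=random_seq(rng, 110)))
        labels[f"h{n:03d}"] = classes[n % 3]
        n += 1
    return records, labels


@pytest.fixture(scope="session")
def trained_pipeline():
    """The full study-condition pipeline, computed once per session:
    2,600 synthetic proteins (200/200/2,200 extracellular/periplasmic/
    cytoplasmic), features, homology-aware 70/15/15 split at 30% identity,
    and multiclass models trained with and without SMOTE."""
    from ayu.dataset import homology_partition
    from ayu.descriptors import feature_matrix
    from ayu.model import ModelConfig, train_classifier
    from ayu.synthetic import GeneratorConfig, sample_proteome

    seed = 42
    config = GeneratorConfig(class_counts=(200, 200, 2200), seed=seed)
    records, bundles, labels = sample_proteome(config)
    X = feature_matrix(records, bundles)
    ids = [r.id for r in records]
    y = np.array([int(labels[i]) for i in ids])
    assignment = homology_partition(records, labels, (0.7, 0.15, 0.15),
                                    id_thr=0.30, seed=seed)
    split_of = {i: assignment.split_names[f]
                for i, f in assignment.folds.items()}
    masks = {s: np.array([split_of[i] == s for i in ids])
             for s in ("train", "val", "test")}
    eval_set = (X[masks["val"]], y[masks["val"]])
    models = {
        smote: train_classifier(X[masks["train"]], y[masks["train"]],
                                mode="multiclass",
                                config=ModelConfig(smote=smote),
                                seed=seed, eval_set=eval_set)
        for smote in (True, False)
    }
    return {
        "records": records, "bundles": bundles, "labels": labels,
        "X": X, "y": y, "ids": ids, "masks": masks,
        "assignment": assignment, "models": models, "seed": seed,
    }
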