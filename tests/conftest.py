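import pytest

from thermocough.audio import classifier, synth


@pytest.fixture(scope="session")
def tiny_manifest():
    """Small balanced five-class dataset: 60 clips per class, seeded."""
    return synth.build_dataset(300, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_manifest):
    """A briefly trained CNN good enough for streaming/monitor tests."""
    model = classifier.build_model(classifier.ModelConfig(seed=0))
    result = classifier.train_model(
        model, tiny_manifest, classifier.TrainConfig(epochs=6, seed=0))
    return model, result
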