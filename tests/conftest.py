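import pytest
from hypothesis import HealthCheck, settings

from pathmention import PathwayTagger, load_dictionary
from pathmention.dictionary import DictionaryEntry, PathwayDictionary
from pathmention.resources import demo_dictionary_path

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def demo_dictionary():
    return load_dictionary(demo_dictionary_path())


@pytest.fixture(scope="session")
def demo_tagger(demo_dictionary):
    return PathwayTagger(demo_dictionary)


def build_dictionary(names: dict[str, str]) -> PathwayDictionary:
    """Toy dictionary from an {entry_id: name} mapping."""
    return PathwayDictionary(
        [DictionaryEntry.make(entry_id, name) for entry_id, name in names.items()]
    )


@pytest.fixture()
def toy_dictionary():
    return build_dictionary(
        {
            "TOY:1": "p53 signalling pathway",
            "TOY:2": "MAPK signalling pathway",
            "TOY:3": "Wnt signalling cascade",
            "TOY:4": "RNA degradation",
            "TOY:5": "oxidative stress response",
        }
    )
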