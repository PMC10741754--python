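import pytest

from uskg import extract_skg, rules_with_status
from uskg.synthetic import (default_grammar, example_gold_skg, example_report,
                            generate_reports)


@pytest.fixture(scope="session")
def worked_example():
    """The liver passage, its gold lexicon and structuring config."""
    text, lexicon, config = example_report()
    return {"text": text, "lexicon": lexicon, "config": config,
            "gold": example_gold_skg("ex")}


@pytest.fixture(scope="session")
def example_skg(worked_example):
    return extract_skg(worked_example["text"], worked_example["lexicon"],
                       rules_with_status(), worked_example["config"],
                       report_id="ex")


@pytest.fixture(scope="session")
def grammar():
    return default_grammar(omission_probability=0.3)


@pytest.fixture(scope="session")
def zero_omission_reports():
    return generate_reports(default_grammar(0.0), 25, seed=11)
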