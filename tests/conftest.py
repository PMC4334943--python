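import pytest

import metacap as mc


@pytest.fixture(scope="session")
def template() -> mc.MetadataTemplate:
    return mc.load_template(mc.example_template_path())


@pytest.fixture(scope="session")
def vocabs(template):
    return template.vocabularies


@pytest.fixture()
def bundle(template) -> mc.ProjectBundle:
    """A small, fully valid synthetic bundle."""
    return mc.make_valid_bundle(
        template, seed=42, n_samples=3, n_libraries_per_sample=2, package="water"
    )


def minimal_template_doc() -> str:
    """Smallest template satisfying the structural invariants, as YAML."""
    return """
name: tiny
version: "0"
collections:
  - name: project
    fields:
      - {key: project_name, label: Project Name, type: text, required: true}
  - name: sample
    fields:
      - {key: collection_date, label: Date, type: date}
  - name: library
    subtype: metagenome
    fields:
      - {key: sample_name, label: Sample Name, type: text, required: true}
  - name: ep
    subtype: water
    fields:
      - {key: sample_name, label: Sample Name, type: text, required: true}
"""


@pytest.fixture()
def tiny_template(tmp_path) -> mc.MetadataTemplate:
    p = tmp_path / "tiny.yaml"
    p.write_text(minimal_template_doc(), encoding="utf-8")
    return mc.load_template(p)
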