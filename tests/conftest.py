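import pytest

from druglabel import CorpusSpec, generate_corpus
from druglabel.core import LabelDocument
from druglabel.drugbank import parse_drugbank
from druglabel.freetext import load_label_text
from druglabel.orange_book import parse_products_file
from druglabel.spl import parse_spl


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus (all four formats) plus its manifest."""
    outdir = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(n_drugs=20, seed=11)
    manifest = generate_corpus(spec, outdir)
    return outdir, manifest, spec


@pytest.fixture(scope="session")
def parsed_docs(corpus) -> list[LabelDocument]:
    outdir, _manifest, _spec = corpus
    docs = [parse_spl(p) for p in sorted((outdir / "spl").glob("*.xml"))]
    docs += [load_label_text(p) for p in sorted((outdir / "freetext").glob("*.txt"))]
    docs += parse_drugbank(outdir / "drugbank.xml")
    return docs


@pytest.fixture(scope="session")
def reference(corpus):
    outdir, _manifest, _spec = corpus
    return parse_products_file(outdir / "products.txt")
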