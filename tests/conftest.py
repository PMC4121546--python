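import pytest

from litgraph.fixtures import worked_example_fixtures
from litgraph.kb_index import build_indices


@pytest.fixture(scope="session")
def bundle():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def toy_indices(bundle):
    return build_indices(
        list(bundle.toy_kb),
        bundle.toy_provenance,
        term_order=bundle.expected_term_order,
        source_order=bundle.expected_source_order,
    )


MEDLINE_XML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
{articles}
</PubmedArticleSet>
"""

ARTICLE_TEMPLATE = """<PubmedArticle>
 <MedlineCitation>
  <PMID>{pmid}</PMID>
  <Article>
   <ArticleTitle>{title}</ArticleTitle>
   {abstract}
  </Article>
 </MedlineCitation>
</PubmedArticle>"""


def make_medline_xml(records):
    """records: list of (pmid, title, abstract_or_None)."""
    articles = []
    for pmid, title, abstract in records:
        abstract_xml = (
            f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>"
            if abstract is not None
            else ""
        )
        articles.append(
            ARTICLE_TEMPLATE.format(pmid=pmid, title=title, abstract=abstract_xml)
        )
    return MEDLINE_XML_TEMPLATE.format(articles="\n".join(articles))


@pytest.fixture
def medline_factory():
    return make_medline_xml
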