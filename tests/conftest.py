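import pytest

from scholarprofiler.metrics_semantic import MeshVocabulary, serialize_mesh_xml
from scholarprofiler.records import (
    Author,
    MeshHeading,
    PublicationRecord,
    ResearcherDossier,
)

PUBMED_XML_3_ARTICLES = b"""<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>11111111</PMID>
   <Article>
    <Journal><JournalIssue><PubDate><Year>2020</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>Deep phenotyping of heart failure</ArticleTitle>
    <Abstract><AbstractText>We study heart failure phenotypes with electronic health records.</AbstractText></Abstract>
    <AuthorList>
     <Author><LastName>Doe</LastName><ForeName>Jane</ForeName>
      <AffiliationInfo><Affiliation>Columbia University</Affiliation></AffiliationInfo></Author>
     <Author><LastName>Roe</LastName><ForeName>Richard</ForeName></Author>
    </AuthorList>
   </Article>
   <MeshHeadingList>
    <MeshHeading><DescriptorName MajorTopicYN="Y">Heart Failure</DescriptorName></MeshHeading>
    <MeshHeading><DescriptorName MajorTopicYN="N">Natural Language Processing</DescriptorName></MeshHeading>
   </MeshHeadingList>
  </MedlineCitation>
 </PubmedArticle>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>22222222</PMID>
   <Article>
    <Journal><JournalIssue><PubDate><Year>2018</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>An abstract-less methods note</ArticleTitle>
    <AuthorList>
     <Author><LastName>Doe</LastName><ForeName>Jane</ForeName></Author>
    </AuthorList>
   </Article>
  </MedlineCitation>
 </PubmedArticle>
 <PubmedArticle>
  <MedlineCitation>
   <PMID>33333333</PMID>
   <Article>
    <Journal><JournalIssue><PubDate><Year>2023</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>Topic models for clinical notes</ArticleTitle>
    <Abstract><AbstractText>Latent topic structure in clinical narratives.</AbstractText></Abstract>
    <AuthorList>
     <Author><LastName>Smith</LastName><ForeName>Ann</ForeName></Author>
     <Author><LastName>Doe</LastName><ForeName>Jane</ForeName></Author>
    </AuthorList>
   </Article>
  </MedlineCitation>
 </PubmedArticle>
</PubmedArticleSet>
"""


@pytest.fixture
def pubmed_xml():
    return PUBMED_XML_3_ARTICLES


@pytest.fixture
def mesh_fixture_vocab():
    """Tiny MeSH vocabulary covering methodology (L/E) and health (C/F)
    branches plus multi-word entry terms."""
    v = MeshVocabulary()
    v.add("Natural Language Processing", ["L01.224.050.375.580"], ["NLP"])
    v.add("Neoplasms", ["C04"], ["Tumors", "Cancer"])
    v.add("Machine Learning", ["L01.224.050.375.530"], ["Deep Learning"])
    v.add("Heart Failure", ["C14.280.434"], ["Cardiac Failure"])
    v.add("Precision Medicine", ["E02.095.700"], ["Individualized Medicine"])
    return v


@pytest.fixture
def mesh_fixture_xml(mesh_fixture_vocab):
    return serialize_mesh_xml(mesh_fixture_vocab)


def make_record(pmid="1", year=2020, n_authors=2, researcher_index=0,
                abstract="some abstract text.", mesh=()):
    """Toy publication with researcher 'Jane Doe' at a chosen author index."""
    authors = [Author(f"Other{i}", "X") for i in range(n_authors)]
    authors[researcher_index] = Author("Doe", "Jane", "Columbia University")
    return PublicationRecord(
        pmid=pmid,
        title=f"title {pmid}",
        abstract=abstract,
        authors=tuple(authors),
        mesh_headings=tuple(MeshHeading(m) for m in mesh),
        pub_year=year,
    )


@pytest.fixture
def toy_dossier():
    years = [2010, 2016, 2020, 2024, 2024]
    pubs = [make_record(pmid=str(i), year=y) for i, y in enumerate(years)]
    return ResearcherDossier(name="Jane Doe", affiliation="Columbia University",
                             publications=pubs, human_profile="I study hearts.")
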