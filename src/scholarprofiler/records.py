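"""Publication records, researcher dossiers, and inclusion filtering.

A researcher's profile is generated from the PubMed articles on which they
made a primary contribution: publications from the last ``window_years``
calendar years where the researcher appears among the first three or last
three authors. Both rules are configurable; the stricter variant (first three
or sole last author) is available as ``author_rule="first3senior"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

from lxml import etree

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input; message carries the reported byte/line position."""


class AuthorPosition(str, Enum):
    FIRST_BLOCK = "first_block"
    LAST_BLOCK = "last_block"
    MIDDLE = "middle"
    ABSENT = "absent"


@dataclass(frozen=True)
class Author:
    surname: str
    given: str = ""
    affiliation: str = ""


@dataclass(frozen=True)
class MeshHeading:
    descriptor: str
    major_topic: bool = False


@dataclass(frozen=True)
class PublicationRecord:
    """One PubMed article: identifiers, text and indexing metadata."""

    pmid: str
    title: str = ""
    abstract: str = ""
    authors: tuple[Author, ...] = ()
    mesh_headings: tuple[MeshHeading, ...] = ()
    pub_year: int | None = None

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "authors": [
                {"surname": a.surname, "given": a.given, "affiliation": a.affiliation}
                for a in self.authors
            ],
            "mesh_headings": [
                {"descriptor": m.descriptor, "major_topic": m.major_topic}
                for m in self.mesh_headings
            ],
            "pub_year": self.pub_year,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PublicationRecord":
        return cls(
            pmid=d["pmid"],
            title=d.get("title", ""),
            abstract=d.get("abstract", ""),
            authors=tuple(
                Author(a["surname"], a.get("given", ""), a.get("affiliation", ""))
                for a in d.get("authors", [])
            ),
            mesh_headings=tuple(
                MeshHeading(m["descriptor"], m.get("major_topic", False))
                for m in d.get("mesh_headings", [])
            ),
            pub_year=d.get("pub_year"),
        )


@dataclass
class ResearcherDossier:
    """A researcher with their publications and (optionally) the research
    profile they wrote themselves."""

    name: str
    affiliation: str = ""
    publications: list[PublicationRecord] = field(default_factory=list)
    human_profile: str | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "affiliation": self.affiliation,
            "publications": [p.to_dict() for p in self.publications],
            "human_profile": self.human_profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResearcherDossier":
        return cls(
            name=d["name"],
            affiliation=d.get("affiliation", ""),
            publications=[PublicationRecord.from_dict(p) for p in d.get("publications", [])],
            human_profile=d.get("human_profile"),
        )


def save_dossiers(dossiers: Iterable[ResearcherDossier], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([d.to_dict() for d in dossiers], fh, indent=1)


def load_dossiers(path) -> list[ResearcherDossier]:
    with open(path, encoding="utf-8") as fh:
        return [ResearcherDossier.from_dict(d) for d in json.load(fh)]


# ---------------------------------------------------------------------------
# PubMed efetch XML (PubmedArticleSet dialect)
# ---------------------------------------------------------------------------


def _text(node, path: str) -> str:
    found = node.find(path)
    return "".join(found.itertext()).strip() if found is not None else ""


def parse_pubmed_xml(source: IO[bytes] | str | bytes) -> list[PublicationRecord]:
    """Parse E-utilities efetch XML into publication records.

    Articles lacking a PMID are skipped with a warning; a missing abstract
    yields empty text. MeSH descriptor names are captured verbatim.
    """
    try:
        if isinstance(source, (str, bytes)):
            root = etree.fromstring(source.encode() if isinstance(source, str) else source)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed PubMed XML at {exc.position}: {exc}") from exc

    records: list[PublicationRecord] = []
    for art in root.iter("PubmedArticle"):
        pmid = _text(art, ".//MedlineCitation/PMID") or _text(art, ".//PMID")
        if not pmid:
            logger.warning("article without PMID skipped")
            continue
        title = _text(art, ".//ArticleTitle")
        abstract = " ".join(
            "".join(t.itertext()).strip() for t in art.findall(".//Abstract/AbstractText")
        ).strip()
        authors = tuple(
            Author(
                surname=_text(a, "LastName"),
                given=_text(a, "ForeName") or _text(a, "Initials"),
                affiliation=_text(a, ".//AffiliationInfo/Affiliation"),
            )
            for a in art.findall(".//AuthorList/Author")
            if a.find("LastName") is not None or a.find("CollectiveName") is not None
        )
        mesh = tuple(
            MeshHeading(
                descriptor="".join(d.itertext()).strip(),
                major_topic=d.get("MajorTopicYN", "N") == "Y",
            )
            for d in art.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
        )
        year_text = (
            _text(art, ".//JournalIssue/PubDate/Year")
            or _text(art, ".//ArticleDate/Year")
            or _text(art, ".//PubDate/MedlineDate")[:4]
        )
        pub_year = int(year_text) if year_text[:4].isdigit() else None
        records.append(
            PublicationRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                authors=authors,
                mesh_headings=mesh,
                pub_year=pub_year,
            )
        )
    return records


def serialize_pubmed_xml(records: Iterable[PublicationRecord]) -> bytes:
    """Write records back out in the PubmedArticleSet dialect (round-trip
    support for fixtures and the synthetic generator)."""
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.pub_year is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.pub_year)
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        authors = etree.SubElement(article, "AuthorList")
        for a in rec.authors:
            author = etree.SubElement(authors, "Author")
            etree.SubElement(author, "LastName").text = a.surname
            etree.SubElement(author, "ForeName").text = a.given
            if a.affiliation:
                aff_info = etree.SubElement(author, "AffiliationInfo")
                etree.SubElement(aff_info, "Affiliation").text = a.affiliation
        if rec.mesh_headings:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for m in rec.mesh_headings:
                mh = etree.SubElement(mhl, "MeshHeading")
                d = etree.SubElement(mh, "DescriptorName")
                d.text = m.descriptor
                d.set("MajorTopicYN", "Y" if m.major_topic else "N")
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def parse_medline(handle: IO[str] | str) -> list[PublicationRecord]:
    """Read MEDLINE flat text (the ``rettype=medline`` efetch format)."""
    from Bio import Medline

    if isinstance(handle, str):
        import io

        handle = io.StringIO(handle)
    records = []
    for rec in Medline.parse(handle):
        pmid = rec.get("PMID", "")
        if not pmid:
            logger.warning("MEDLINE record without PMID skipped")
            continue
        authors = []
        for fau in rec.get("FAU", []):
            surname, _, given = fau.partition(",")
            authors.append(Author(surname.strip(), given.strip()))
        mesh = tuple(
            MeshHeading(h.lstrip("*"), major_topic=h.startswith("*"))
            for h in rec.get("MH", [])
        )
        dp = rec.get("DP", "")
        pub_year = int(dp[:4]) if dp[:4].isdigit() else None
        records.append(
            PublicationRecord(
                pmid=pmid,
                title=rec.get("TI", ""),
                abstract=rec.get("AB", ""),
                authors=tuple(authors),
                mesh_headings=mesh,
                pub_year=pub_year,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Authorship position and inclusion filtering
# ---------------------------------------------------------------------------


def _name_matches(author: Author, surname: str, given_initial: str) -> bool:
    if author.surname.casefold() != surname.casefold():
        return False
    if not given_initial:
        return True
    return (author.given[:1].casefold() or "") in ("", given_initial.casefold())


def _match_author_index(record: PublicationRecord, researcher_name: str,
                        affiliation: str = "") -> int | None:
    """Index (0-based) of the author matching the researcher, or None.

    Matching is case-folded surname plus first given-initial; when several
    authors match, an affiliation substring check disambiguates.
    """
    parts = researcher_name.replace(",", " ").split()
    if not parts:
        return None
    # Accept "Given Surname" or "Surname, Given"; surname taken as last token
    # of the space form, first token of the comma form.
    if "," in researcher_name:
        surname = researcher_name.split(",")[0].strip()
        given = researcher_name.split(",", 1)[1].strip()
    else:
        surname, given = parts[-1], " ".join(parts[:-1])
    initial = given[:1]
    matches = [
        i for i, a in enumerate(record.authors) if _name_matches(a, surname, initial)
    ]
    if len(matches) > 1 and affiliation:
        key = affiliation.casefold()
        narrowed = [i for i in matches if key in record.authors[i].affiliation.casefold()]
        if narrowed:
            matches = narrowed
    return matches[0] if matches else None


def author_position(record: PublicationRecord, researcher_name: str,
                    affiliation: str = "") -> AuthorPosition:
    """Classify the researcher's byline position on one paper.

    First-block = authors 1-3; last-block = the final three authors. On short
    bylines (<= 6 authors) where the blocks overlap, first-block wins.
    """
    idx = _match_author_index(record, researcher_name, affiliation)
    if idx is None:
        return AuthorPosition.ABSENT
    n = len(record.authors)
    if idx < 3:
        return AuthorPosition.FIRST_BLOCK
    if idx >= n - 3:
        return AuthorPosition.LAST_BLOCK
    return AuthorPosition.MIDDLE


def filter_publications(
    dossier: ResearcherDossier,
    reference_year: int,
    window_years: int = 10,
    author_rule: str = "first3last3",
) -> ResearcherDossier:
    """Apply the recency window and the authorship-position rule.

    Keeps publications with ``pub_year >= reference_year - window_years + 1``
    (a closed 10-calendar-year window by default) on which the researcher is
    in the first or last author block (``first3last3``) or first block / sole
    last author (``first3senior``). Returns a new dossier; input unmodified.
    Records with no publication year are dropped with a warning.
    """
    if window_years < 1:
        raise ValueError(f"window_years must be >= 1, got {window_years}")
    if author_rule not in ("first3last3", "first3senior"):
        raise ValueError(f"unknown author_rule {author_rule!r}")
    earliest = reference_year - window_years + 1
    kept: list[PublicationRecord] = []
    for rec in dossier.publications:
        if rec.pub_year is None:
            logger.warning("pmid %s has no publication year; excluded", rec.pmid)
            continue
        if not (earliest <= rec.pub_year <= reference_year):
            continue
        pos = author_position(rec, dossier.name, dossier.affiliation)
        if pos == AuthorPosition.FIRST_BLOCK:
            kept.append(rec)
        elif pos == AuthorPosition.LAST_BLOCK:
            if author_rule == "first3last3":
                kept.append(rec)
            else:  # senior author = very last position only
                idx = _match_author_index(rec, dossier.name, dossier.affiliation)
                if idx == len(rec.authors) - 1:
                    kept.append(rec)
    return replace_publications(dossier, kept)


def replace_publications(
    dossier: ResearcherDossier, publications: list[PublicationRecord]
) -> ResearcherDossier:
    return ResearcherDossier(
        name=dossier.name,
        affiliation=dossier.affiliation,
        publications=list(publications),
        human_profile=dossier.human_profile,
    )
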