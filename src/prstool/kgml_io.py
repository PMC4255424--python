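"""Parsing and writing of KGML (KEGG Markup Language) pathway files.

KGML describes one KEGG pathway per XML file using three object classes:

* ``entry``   -- the boxes and circles on the pathway map (genes/enzymes,
  compounds, linked maps, groups of entries);
* ``relation`` -- directed links between entries (the edges of signalling
  pathways);
* ``reaction`` -- enzymatic conversions of substrate compounds into product
  compounds (the backbone of metabolic pathways).

This module turns a KGML file into a :class:`PathwayDefinition` and can write
one back out, which is used for round-trip testing.  Classification into
signalling vs metabolic is structural: a pathway with at least one reaction is
metabolic, otherwise signalling.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

SIGNALLING = "signalling"
METABOLIC = "metabolic"

ENTRY_TYPES = frozenset(
    {"gene", "compound", "map", "group", "ortholog", "enzyme", "other", "brite"}
)

#: entry types whose members are treated as gene products
GENE_LIKE_TYPES = frozenset({"gene", "enzyme", "ortholog"})


class KgmlError(Exception):
    """Base class for KGML input problems."""


class KgmlParseError(KgmlError):
    """Malformed XML."""


class KgmlFormatError(KgmlError):
    """Well-formed XML that is not a KGML pathway document."""


def strip_organism_prefix(token: str) -> str:
    """Return the canonical gene/compound ID without its database prefix.

    ``"hsa:5594" -> "5594"``, ``"cpd:C00076" -> "C00076"``.  Tokens without a
    colon are returned unchanged.
    """
    _, _, tail = token.rpartition(":")
    return tail or token


@dataclass(frozen=True)
class KgmlEntry:
    """One ``entry`` element: a node candidate on the pathway map."""

    entry_id: str
    entry_type: str
    gene_ids: tuple[str, ...] = ()
    component_ids: tuple[str, ...] = ()
    display_name: str = ""
    #: raw ``name`` tokens as they appeared in the file (with prefixes)
    raw_names: tuple[str, ...] = ()
    #: reaction names this entry catalyses (``reaction`` attribute)
    reaction_names: tuple[str, ...] = ()

    @property
    def is_gene_like(self) -> bool:
        return self.entry_type in GENE_LIKE_TYPES and bool(self.gene_ids)


@dataclass(frozen=True)
class KgmlRelation:
    """One ``relation`` element: a directed link entry1 -> entry2."""

    entry1_id: str
    entry2_id: str
    relation_type: str
    subtypes: tuple[str, ...] = ()


@dataclass(frozen=True)
class KgmlReaction:
    """One ``reaction`` element: substrates -> products catalysed by enzymes."""

    reaction_name: str
    enzyme_entry_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...]
    product_ids: tuple[str, ...]
    reversible: bool = False


@dataclass
class PathwayDefinition:
    """Parsed content of one KGML file."""

    kegg_id: str
    title: str
    organism_code: str
    entries: list[KgmlEntry] = field(default_factory=list)
    relations: list[KgmlRelation] = field(default_factory=list)
    reactions: list[KgmlReaction] = field(default_factory=list)

    @property
    def category(self) -> str:
        return classify_pathway(self)

    def entry_map(self) -> dict[str, KgmlEntry]:
        return {e.entry_id: e for e in self.entries}


def classify_pathway(defn: PathwayDefinition) -> str:
    """Classify a pathway as ``"metabolic"`` or ``"signalling"``.

    A pathway is metabolic iff it contains at least one reaction element;
    reaction presence is the only structural discriminator KGML offers, and
    reactions dominate when relations are also present.
    """
    return METABOLIC if defn.reactions else SIGNALLING


def _parse_entry(el: etree._Element) -> KgmlEntry:
    entry_type = el.get("type", "other")
    raw = tuple(tok for tok in (el.get("name") or "").split() if tok)
    gene_ids: tuple[str, ...] = ()
    if entry_type in GENE_LIKE_TYPES:
        gene_ids = tuple(
            dict.fromkeys(
                strip_organism_prefix(tok) for tok in raw if tok != "undefined"
            )
        )
    components = tuple(c.get("id") for c in el.findall("component") if c.get("id"))
    graphics = el.find("graphics")
    display = graphics.get("name") if graphics is not None else None
    reactions = tuple((el.get("reaction") or "").split())
    return KgmlEntry(
        entry_id=el.get("id", ""),
        entry_type=entry_type,
        gene_ids=gene_ids,
        component_ids=components,
        display_name=display or "",
        raw_names=raw,
        reaction_names=reactions,
    )


def parse_kgml(xml_source: str | os.PathLike) -> PathwayDefinition:
    """Parse one KGML file (or an XML string) into a :class:`PathwayDefinition`.

    Unresolvable references (relations pointing at unknown entries, reactions
    without a catalysing enzyme entry or without both substrates and products)
    are dropped with a logged warning rather than raised, because real KEGG
    exports routinely contain dangling links.

    Parameters
    ----------
    xml_source:
        Path to a ``.xml`` KGML file, or the KGML document itself as a string
        (recognised by a leading ``<``).

    Raises
    ------
    KgmlParseError
        If the XML is malformed.
    KgmlFormatError
        If the document root is not a ``pathway`` element.
    """
    name = "<string>"
    text: bytes
    if isinstance(xml_source, (str,)) and xml_source.lstrip().startswith("<"):
        text = xml_source.encode()
    else:
        path = Path(xml_source)
        name = str(path)
        text = path.read_bytes()
    # KGML files carry a DTD reference to genome.jp; never try to fetch it.
    parser = etree.XMLParser(no_network=True, load_dtd=False, resolve_entities=False)
    try:
        root = etree.fromstring(text, parser=parser)
    except etree.XMLSyntaxError as exc:
        raise KgmlParseError(f"malformed KGML in {name}: {exc}") from exc
    if root.tag != "pathway":
        raise KgmlFormatError(
            f"{name}: expected <pathway> root element, found <{root.tag}>"
        )

    kegg_id = strip_organism_prefix(root.get("name", ""))
    defn = PathwayDefinition(
        kegg_id=kegg_id or root.get("number", ""),
        title=root.get("title", ""),
        organism_code=root.get("org", ""),
    )
    for el in root.findall("entry"):
        defn.entries.append(_parse_entry(el))
    known = {e.entry_id for e in defn.entries}

    for el in root.findall("relation"):
        e1, e2 = el.get("entry1", ""), el.get("entry2", "")
        if e1 not in known or e2 not in known:
            logger.warning(
                "%s: dropping relation %s->%s with unresolved endpoint", name, e1, e2
            )
            continue
        subtypes = tuple(s.get("name", "") for s in el.findall("subtype"))
        defn.relations.append(
            KgmlRelation(e1, e2, el.get("type", ""), subtypes)
        )

    # Enzymes for a reaction: entries whose `reaction` attribute names it,
    # plus (KGML >= 0.7.1) the entry whose id equals the reaction's `id`.
    catalysts: dict[str, list[str]] = {}
    for e in defn.entries:
        for rname in e.reaction_names:
            catalysts.setdefault(rname, []).append(e.entry_id)
    for el in root.findall("reaction"):
        rname = el.get("name", "")
        enzymes = list(catalysts.get(rname, []))
        rid = el.get("id")
        if rid in known and rid not in enzymes:
            enzymes.append(rid)
        substrates = tuple(
            strip_organism_prefix(s.get("name", "")) for s in el.findall("substrate")
        )
        products = tuple(
            strip_organism_prefix(p.get("name", "")) for p in el.findall("product")
        )
        if not enzymes:
            logger.warning("%s: dropping reaction %s with no enzyme entry", name, rname)
            continue
        if not substrates or not products:
            logger.warning(
                "%s: dropping reaction %s lacking substrates or products", name, rname
            )
            continue
        # missing `type` (older KGML dialects) defaults to irreversible
        reversible = el.get("type", "irreversible") == "reversible"
        defn.reactions.append(
            KgmlReaction(rname, tuple(enzymes), substrates, products, reversible)
        )
    return defn


def parse_kgml_dir(directory: str | os.PathLike) -> list[PathwayDefinition]:
    """Parse every ``*.xml`` file in a directory, sorted by filename."""
    directory = Path(directory)
    defns = []
    for path in sorted(directory.glob("*.xml")):
        defns.append(parse_kgml(path))
    return defns


def write_kgml(defn: PathwayDefinition, path: str | os.PathLike | None = None) -> str:
    """Serialize a :class:`PathwayDefinition` back to KGML text.

    Only the fields the parser consumes are emitted; used for fixture
    generation and round-trip tests.
    """
    org = defn.organism_code
    root = etree.Element(
        "pathway",
        name=f"path:{defn.kegg_id}" if defn.kegg_id else "path:unknown",
        org=org,
        title=defn.title,
    )
    for e in defn.entries:
        names = e.raw_names or tuple(
            f"{org}:{g}" if org else g for g in e.gene_ids
        )
        el = etree.SubElement(
            root, "entry", id=e.entry_id, name=" ".join(names) or "undefined",
            type=e.entry_type,
        )
        if e.reaction_names:
            el.set("reaction", " ".join(e.reaction_names))
        if e.display_name:
            etree.SubElement(el, "graphics", name=e.display_name)
        for c in e.component_ids:
            etree.SubElement(el, "component", id=c)
    for r in defn.relations:
        el = etree.SubElement(
            root, "relation", entry1=r.entry1_id, entry2=r.entry2_id, type=r.relation_type
        )
        for s in r.subtypes:
            etree.SubElement(el, "subtype", name=s, value="")
    for rx in defn.reactions:
        el = etree.SubElement(
            root, "reaction", name=rx.reaction_name,
            type="reversible" if rx.reversible else "irreversible",
        )
        for s in rx.substrate_ids:
            etree.SubElement(el, "substrate", id=s, name=f"cpd:{s}")
        for p in rx.product_ids:
            etree.SubElement(el, "product", id=p, name=f"cpd:{p}")
    text = etree.tostring(root, pretty_print=True, encoding="unicode")
    if path is not None:
        Path(path).write_text(text)
    return text
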