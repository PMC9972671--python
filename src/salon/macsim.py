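"""Reader and writer for MACSIM XML alignments (BAliBASE dialect).

MACSIM is the annotated-alignment XML format distributed with BAliBASE.  The
elements honoured here are the ones the SALON mapping defines: ``<aln-name>``
(sub-alignment name), ``<sequence seq-type="Protein">`` blocks with
``<seq-name>``, ``<accession>``, an inner ``<sequence>`` holding the aligned
residues, and ``<fitem>`` features with ``<ftype>/<fstart>/<fstop>/<fnote>``.
Unknown elements are preserved verbatim in a pass-through bag and re-emitted,
so files with richer MACSIM content survive round-trips.  The gap character is
derived from the residues themselves.  One extension element,
``<construction-method approach="...">``, keeps the construction method
lossless across write/parse cycles; standard MACSIM files simply omit it.
"""

from __future__ import annotations

from lxml import etree

from .errors import MacsimParseError, SalonError
from .model import (
    Alignment,
    AlignmentSequence,
    ConstructionMethod,
    Feature,
    SubAlignment,
    detect_gap_character,
)

__all__ = ["parse_macsim", "write_macsim"]

_KNOWN_SEQ_CHILDREN = {"seq-name", "accession", "sequence", "seq-data", "fitem", "organism", "keyword"}
_KNOWN_ALN_CHILDREN = {"aln-name", "sequence", "construction-method"}
_KNOWN_FITEM_CHILDREN = {"ftype", "fstart", "fstop", "fnote", "fscore"}


def _text(elem, tag: str) -> str | None:
    child = elem.find(tag)
    if child is None or child.text is None:
        return None if child is None else ""
    return child.text.strip()


def _parse_feature(fitem, seq_pos: int) -> Feature:
    ftype = _text(fitem, "ftype") or ""
    fstart = _text(fitem, "fstart")
    fstop = _text(fitem, "fstop")
    if fstart is None or fstop is None:
        raise MacsimParseError(
            f"<fitem> of sequence {seq_pos} lacks <fstart>/<fstop>",
            line=fitem.sourceline,
        )
    fnote = _text(fitem, "fnote")
    fscore = _text(fitem, "fscore")
    return Feature(
        ftype=ftype,
        fstart=int(fstart),
        fstop=int(fstop),
        fnote=fnote,
        fscore=float(fscore) if fscore else None,
    )


def _parse_sequence(seq_elem, seq_pos: int) -> AlignmentSequence:
    name = _text(seq_elem, "seq-name")
    if not name:
        raise MacsimParseError(
            f"sequence {seq_pos} has no <seq-name>", line=seq_elem.sourceline
        )
    # the aligned residues live in a nested <sequence>; some files use
    # <seq-data> instead — accepted as an alias
    residues_elem = seq_elem.find("sequence")
    if residues_elem is None:
        residues_elem = seq_elem.find("seq-data")
    if residues_elem is None or not (residues_elem.text or "").strip():
        raise MacsimParseError(
            f"sequence {seq_pos} ({name!r}) has no residue data",
            line=seq_elem.sourceline,
        )
    residues = "".join((residues_elem.text or "").split()).upper()

    seq_type = seq_elem.get("seq-type", "Protein")
    molecule = "Protein" if seq_type.lower() == "protein" else "DNA"

    features = tuple(
        _parse_feature(f, seq_pos) for f in seq_elem.findall("fitem")
    )
    keywords = tuple(
        (k.text or "").strip() for k in seq_elem.findall("keyword")
    )
    extras = tuple(
        etree.tostring(child, encoding="unicode").strip()
        for child in seq_elem
        if child.tag not in _KNOWN_SEQ_CHILDREN
    )
    return AlignmentSequence(
        identifier=name,
        residues=residues,
        accession_number=_text(seq_elem, "accession") or None,
        organism=_text(seq_elem, "organism") or None,
        keywords=keywords,
        molecule=molecule,
        features=features,
        extras=extras,
    )


def parse_macsim(xml_text: str | bytes) -> Alignment:
    """Parse MACSIM XML into an :class:`~salon.model.Alignment`.

    Each ``<alignment>`` element becomes one sub-alignment; the alignment id
    is taken from the root ``id`` attribute when present, otherwise from the
    first sub-alignment name.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise MacsimParseError(
            f"malformed MACSIM XML: {exc.msg}", line=exc.lineno
        ) from exc

    aln_elems = root.findall(".//alignment") if root.tag != "alignment" else [root]
    if not aln_elems:
        raise MacsimParseError("no <alignment> element found")

    subs = []
    for aln_elem in aln_elems:
        name = _text(aln_elem, "aln-name") or ""
        seqs = []
        for pos, seq_elem in enumerate(aln_elem.findall("sequence"), start=1):
            seqs.append(_parse_sequence(seq_elem, pos))
        method = None
        method_elem = aln_elem.find("construction-method")
        if method_elem is not None and (method_elem.text or "").strip():
            method = ConstructionMethod(
                name=method_elem.text.strip(),
                approach=method_elem.get("approach", "deterministic"),
            )
        gap = detect_gap_character([s.residues for s in seqs]) if seqs else "-"
        extras = tuple(
            etree.tostring(child, encoding="unicode").strip()
            for child in aln_elem
            if child.tag not in _KNOWN_ALN_CHILDREN
        )
        subs.append(
            SubAlignment(
                name=name,
                sequences=tuple(seqs),
                construction_method=method,
                gap_character=gap,
                extras=extras,
            )
        )

    alignment_id = root.get("id") or (subs[0].name if subs[0].name else "alignment")
    return Alignment(alignment_id=alignment_id, sub_alignments=tuple(subs))


def _append_text(parent, tag: str, text: str) -> None:
    child = etree.SubElement(parent, tag)
    child.text = text


def write_macsim(alignment: Alignment) -> str:
    """Serialize an alignment back to MACSIM XML (inverse of parse)."""
    root = etree.Element("macsim")
    root.set("id", alignment.alignment_id)
    for sub in alignment.sub_alignments:
        aln_elem = etree.SubElement(root, "alignment")
        _append_text(aln_elem, "aln-name", sub.name)
        if sub.construction_method is not None:
            m_elem = etree.SubElement(aln_elem, "construction-method")
            m_elem.set("approach", sub.construction_method.approach)
            m_elem.text = sub.construction_method.name
        for seq in sub.sequences:
            seq_elem = etree.SubElement(aln_elem, "sequence")
            seq_elem.set("seq-type", seq.molecule)
            _append_text(seq_elem, "seq-name", seq.identifier)
            if seq.accession_number:
                _append_text(seq_elem, "accession", seq.accession_number)
            if seq.organism:
                _append_text(seq_elem, "organism", seq.organism)
            for kw in seq.keywords:
                _append_text(seq_elem, "keyword", kw)
            for f in seq.features:
                fitem = etree.SubElement(seq_elem, "fitem")
                _append_text(fitem, "ftype", f.ftype)
                _append_text(fitem, "fstart", str(f.fstart))
                _append_text(fitem, "fstop", str(f.fstop))
                if f.fnote is not None:
                    _append_text(fitem, "fnote", f.fnote)
                if f.fscore is not None:
                    _append_text(fitem, "fscore", repr(f.fscore))
            _append_text(seq_elem, "sequence", seq.residues)
            for snippet in seq.extras:
                seq_elem.append(etree.fromstring(snippet))
        for snippet in sub.extras:
            aln_elem.append(etree.fromstring(snippet))
    try:
        etree.indent(root)
    except AttributeError:  # pragma: no cover - very old lxml
        pass
    return etree.tostring(root, encoding="unicode", pretty_print=False) + "\n"
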