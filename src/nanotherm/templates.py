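"""Bundled germline-like nanobody templates on the 149-position scheme.

Each template is a synthetic VHH-like variable-domain alignment assembled from
a shared framework with template-specific CDR loops. The 149 columns follow
the fixed antibody numbering convention: framework regions are fully occupied
and CDR loops are left/right justified inside fixed-width slots with gaps in
the middle, which is how variable-length loops are conventionally placed in a
fixed-length numbering scheme. These templates are synthetic constructs for
simulation and for the fallback numbering backend; they are not curated
germline sequences.
"""

from __future__ import annotations

from .scales import AHO_LENGTH, GAP

# slot widths: FR1 26 | CDR1 16 | FR2 14 | CDR2 13 | FR3 37 | CDR3 32 | FR4 11
_FR1 = "QVQLVESGGGLVQPGGSLRLSCAASG"
_FR2 = "GWFRQAPGKEREFV"
_FR2_SHORT = "GWYRQAPGKQRELV"  # hallmark variant used by short-CDR templates
_FR3 = "YADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC"
_FR4 = "WGQGTQVTVSS"

_CDR1_W, _CDR2_W, _CDR3_W = 16, 13, 32

# (name, cdr1, fr2, cdr2, cdr3)
_TEMPLATE_PARTS: list[tuple[str, str, str, str, str]] = [
    ("t1", "GRTFSSYA", _FR2, "ISWSGGST", "AAKDPSTYYRGSYDY"),
    ("t2", "GSIFSINA", _FR2_SHORT, "ITSGGST", "NAKWGSSTLDY"),
    ("t3", "GFTFDDYA", _FR2, "ISWNGGRT", "AADRGQVTSSWYEYDY"),
    ("t4", "GRTFSMG", _FR2, "ISRTGGIT", "AAGLRYSGTYWNR"),
    ("t5", "GSIASGSVF", _FR2_SHORT, "ITSDGST", "NVWGPDY"),
    ("t6", "GFTLDYYA", _FR2, "IRSSDGST", "AAADPRGWGTLRDEYAY"),
    ("t7", "GRTISRYA", _FR2, "ISGSGDIT", "AADLQTGSWSPRAYNYDY"),
    ("t8", "GGSEYSYST", _FR2_SHORT, "IDSDGST", "NAGRLVAGTDY"),
]


def _pad_loop(content: str, width: int) -> str:
    """Place a loop in a fixed slot: left/right justified, gaps in the middle."""
    if len(content) > width:
        raise ValueError(f"loop of {len(content)} residues exceeds slot {width}")
    left = (len(content) + 1) // 2
    return content[:left] + GAP * (width - len(content)) + content[left:]


def _assemble(cdr1: str, fr2: str, cdr2: str, cdr3: str) -> str:
    aligned = (
        _FR1
        + _pad_loop(cdr1, _CDR1_W)
        + fr2
        + _pad_loop(cdr2, _CDR2_W)
        + _FR3
        + _pad_loop(cdr3, _CDR3_W)
        + _FR4
    )
    assert len(aligned) == AHO_LENGTH
    return aligned


#: name -> 149-character aligned template
GERMLINE_TEMPLATES: dict[str, str] = {
    name: _assemble(c1, f2, c2, c3) for name, c1, f2, c2, c3 in _TEMPLATE_PARTS
}
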