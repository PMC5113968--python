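"""Shared helpers: hand-written PDB records and small parsed structures."""

from __future__ import annotations

import pytest

from pirkit.structure_io import parse_pdb


def atom_line(
    serial: int,
    name: str,
    res: str,
    chain: str,
    num: int,
    x: float,
    y: float,
    z: float,
    icode: str = " ",
    het: bool = False,
    altloc: str = " ",
    element: str = "C",
) -> str:
    rec = "HETATM" if het else "ATOM  "
    pad = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{rec}{serial:5d} {pad}{altloc}{res:>3s} {chain}{num:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def simple_chain_pdb(letters_and_codes, chain="A", start=1, extra_lines=(), ligands=()):
    """PDB text for a chain of CA-only residues plus optional HETATM ligands.

    ``letters_and_codes``: list of 3-letter residue codes (None = skip the
    ATOM record, leaving a numbering gap).
    """
    lines = list(extra_lines)
    serial = 1
    num = start
    for code in letters_and_codes:
        if code is not None:
            lines.append(atom_line(serial, "CA", code, chain, num, float(num), 0.0, 0.0))
            serial += 1
        num += 1
    for het, lig_num in ligands:
        lines.append(
            atom_line(serial, "C1", het, chain, lig_num, 50.0 + serial, 0.0, 0.0, het=True)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def ags_model():
    """Minimal 3-residue chain: ALA, GLY, SER."""
    return parse_pdb(simple_chain_pdb(["ALA", "GLY", "SER"]))


@pytest.fixture
def missing_lys_model():
    """ALA, (missing LYS at 2), GLY, SER via REMARK 465."""
    text = simple_chain_pdb(
        ["ALA", None, "GLY", "SER"],
        extra_lines=[
            "REMARK 465 MISSING RESIDUES",
            "REMARK 465   M RES C SSSEQI",
            "REMARK 465     LYS A     2",
        ],
    )
    return parse_pdb(text)
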