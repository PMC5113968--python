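"""Residue-level PDB parsing for homology-modeling input preparation.

Comparative-modeling pipelines need more from a coordinate file than a list of
atoms: they need the *polymer sequence as the depositor intended it*, with
every position classified as observed, missing (present in the construct but
unresolved, listed in REMARK 465) or chemically modified (MODRES, or a
polymer HETATM such as selenomethionine), plus the non-polymer HETATM content
(ligands, ions, waters) in coordinate order so ligand positions can later be
referenced from a PIR alignment file.

This module parses wwPDB v3.3 fixed-column records into :class:`StructureModel`
and renders per-chain :class:`AnnotatedSequence` objects.  Missing and modified
positions render as ``X`` for the alignment stage and as ``-`` / ``.`` for the
PIR stage — the two conventions comparative-modeling software expects.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.PDBData import protein_letters_3to1_extended as _3TO1_EXT
from Bio.Data.PDBData import protein_letters_3to1 as _3TO1

__all__ = [
    "ResidueRecord",
    "LigandRecord",
    "StructureModel",
    "AnnotatedSequence",
    "PdbFormatError",
    "parse_pdb",
    "extract_chain_sequence",
    "list_ligands",
    "write_fasta",
]

# Status constants
OBSERVED = "observed_standard"
MODIFIED = "observed_modified"
MISSING = "missing"

WATER_CODES = {"HOH", "WAT", "DOD", "H2O"}

# Modified residues mapped to a parent amino acid; used when MODRES records
# are absent.  Anything else in-chain renders as 'X'.
MODIFIED_PARENTS = {"MSE": "M", "SEP": "S", "TPO": "T", "PTR": "Y", "CSO": "C"}

STANDARD_AA3 = set(_3TO1)


class PdbFormatError(ValueError):
    """Raised for malformed or empty PDB input."""


def three_to_one(res_name: str) -> str:
    """Translate a 3-letter residue code to one letter, 'X' if unknown."""
    res_name = res_name.strip().upper()
    if res_name in _3TO1:
        return _3TO1[res_name]
    if res_name in MODIFIED_PARENTS:
        return MODIFIED_PARENTS[res_name]
    one = _3TO1_EXT.get(res_name, "X")
    return one if len(one) == 1 and one.isalpha() else "X"


@dataclass
class ResidueRecord:
    """One polymer position: observed, missing, or modified.

    ``author_number`` / ``insertion_code`` follow the depositor's numbering and
    are part of residue identity; ordering follows file order, never numeric
    sort.  Missing residues carry no atoms.
    """

    chain_id: str
    res_name: str
    author_number: int
    insertion_code: str = ""
    one_letter: str = "X"
    status: str = OBSERVED
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)
    is_hetatm_polymer: bool = False
    order_key: float = 0.0  # file-order serial; interpolated for missing residues

    @property
    def label(self) -> str:
        return f"{self.author_number}{self.insertion_code}"


@dataclass
class LigandRecord:
    """A non-polymer HETATM group (ligand, ion or water)."""

    het_code: str
    chain_id: str
    author_number: int
    insertion_code: str = ""
    coord_index: int = 0
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)
    is_water: bool = False
    order_key: float = 0.0

    @property
    def label(self) -> str:
        return f"{self.author_number}{self.insertion_code}"


@dataclass
class StructureModel:
    """Parsed structure: ordered chains of polymer residues plus ligands."""

    pdb_id: str = "xxxx"
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    ligands: list[LigandRecord] = field(default_factory=list)
    seqres: dict[str, list[str]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"chain {chain_id!r} not present (have {sorted(self.chains)})")
        return self.chains[chain_id]


@dataclass
class AnnotatedSequence:
    """Per-position sequence carrying observed/missing/modified status.

    Rendering is a pure function of status:

    * ``alignment`` mode — 'X' at missing and modified positions (what goes
      into the multiple sequence alignment);
    * ``pir`` mode — '-' at missing, '.' at modified (what MODELLER reads).
    """

    positions: list[tuple[str, str, ResidueRecord | None]]

    def __len__(self) -> int:
        return len(self.positions)

    def render(self, mode: str = "alignment") -> str:
        if mode == "alignment":
            return "".join(
                "X" if status != OBSERVED else letter
                for letter, status, _ in self.positions
            )
        if mode == "pir":
            out = []
            for letter, status, _ in self.positions:
                if status == MISSING:
                    out.append("-")
                elif status == MODIFIED:
                    out.append(".")
                else:
                    out.append(letter)
            return "".join(out)
        if mode == "plain":
            return "".join(letter for letter, _, _ in self.positions)
        raise ValueError(f"unknown rendering mode {mode!r}")

    @property
    def statuses(self) -> str:
        """Compact per-position status string: o / m / x (observed/modified/missing)."""
        code = {OBSERVED: "o", MODIFIED: "m", MISSING: "x"}
        return "".join(code[s] for _, s, _ in self.positions)


# ---------------------------------------------------------------------------
# parsing

def _parse_remark_465(lines: list[str]) -> list[tuple[str, str, int, str]]:
    """Extract (res_name, chain, number, icode) tuples from REMARK 465 lines."""
    out = []
    for ln in lines:
        body = ln[10:].strip()
        if not body:
            continue
        parts = body.split()
        # data rows: RES C SSSEQI  (optionally preceded by model number)
        if len(parts) == 4 and parts[0].isdigit():
            parts = parts[1:]
        if len(parts) != 3:
            continue
        res_name, chain, num = parts
        if len(chain) != 1 or not res_name.isalnum() or len(res_name) > 3:
            continue
        icode = ""
        if num and num[-1].isalpha():
            num, icode = num[:-1], num[-1]
        try:
            number = int(num)
        except ValueError:
            continue
        if res_name.upper() in ("RES", "SSSEQI"):
            continue
        out.append((res_name.upper(), chain, number, icode))
    return out


def parse_pdb(text: str, pdb_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Chains are populated in file order.  REMARK 465 entries become
    missing-status residues inserted at their author positions.  MODRES-listed
    residues and in-chain polymer HETATMs (e.g. MSE) become observed-modified
    residues; other HETATMs become ligands with ``coord_index`` following the
    coordinate section.  Altloc duplicates collapse to the first conformer.

    Raises :class:`PdbFormatError` if there are no coordinate records or an
    observed residue identity is duplicated within a chain.
    """
    header_id = pdb_id
    remark465_lines: list[str] = []
    modres: set[tuple[str, str, int, str]] = set()  # (res_name, chain, num, icode)
    seqres: dict[str, list[str]] = {}
    # raw coordinate groups, in file order: key -> record
    groups: list[dict] = []
    group_index: dict[tuple, int] = {}
    last_key_per_chain: dict[str, tuple] = {}

    for lineno, line in enumerate(text.splitlines()):
        rec = line[:6]
        if rec == "HEADER" and not header_id:
            header_id = line[62:66].strip().lower()
        elif rec == "REMARK" and line[7:10].strip() == "465":
            remark465_lines.append(line)
        elif rec == "MODRES":
            res_name = line[12:15].strip().upper()
            chain = line[16:17]
            try:
                num = int(line[18:22])
            except ValueError:
                continue
            icode = line[22:23].strip()
            modres.add((res_name, chain, num, icode))
        elif rec == "SEQRES":
            chain = line[11:12]
            codes = line[19:].split()
            seqres.setdefault(chain, []).extend(c.upper() for c in codes)
        elif rec in ("ATOM  ", "HETATM"):
            atom_name = line[12:16].strip()
            altloc = line[16:17]
            res_name = line[17:20].strip().upper()
            chain = line[21:22]
            try:
                num = int(line[22:26])
            except ValueError:
                raise PdbFormatError(f"unreadable residue number on line {lineno + 1}")
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            key = (chain, num, icode, res_name)
            if key in group_index:
                g = groups[group_index[key]]
                if last_key_per_chain.get(chain) != key and not g["is_het"]:
                    raise PdbFormatError(
                        f"duplicate residue {res_name} {chain} {num}{icode}"
                    )
                # altloc collapse: first conformer per atom name wins
                if atom_name not in g["seen_atoms"]:
                    g["atoms"].append((atom_name, x, y, z))
                    g["seen_atoms"].add(atom_name)
            else:
                group_index[key] = len(groups)
                groups.append(
                    {
                        "key": key,
                        "is_het": rec == "HETATM",
                        "atoms": [(atom_name, x, y, z)],
                        "seen_atoms": {atom_name},
                        "order": lineno,
                    }
                )
            last_key_per_chain[chain] = key
        # TER lines need no handling: a chain is defined purely by chain_id

    if not groups:
        raise PdbFormatError("no ATOM or HETATM records found")

    # polymer numbering range per chain, from ATOM records
    atom_range: dict[str, tuple[int, int]] = {}
    for g in groups:
        chain, num, _, _ = g["key"]
        if not g["is_het"]:
            lo, hi = atom_range.get(chain, (num, num))
            atom_range[chain] = (min(lo, num), max(hi, num))

    model = StructureModel(pdb_id=header_id or "xxxx", seqres=seqres)
    ligand_count_per_chain: dict[str, int] = {}

    for g in groups:
        chain, num, icode, res_name = g["key"]
        is_polymer = False
        status = OBSERVED
        if not g["is_het"]:
            is_polymer = True
            status = MODIFIED if (res_name, chain, num, icode) in modres else OBSERVED
            if res_name not in STANDARD_AA3 and status == OBSERVED:
                status = MODIFIED
        else:
            if res_name in WATER_CODES:
                is_polymer = False
            elif (res_name, chain, num, icode) in modres:
                is_polymer, status = True, MODIFIED
            elif res_name in MODIFIED_PARENTS and chain in atom_range:
                lo, hi = atom_range[chain]
                if lo <= num <= hi:
                    is_polymer, status = True, MODIFIED
            elif res_name in MODIFIED_PARENTS and chain not in atom_range and not modres:
                # chain built entirely of HETATM polymer (e.g. all-MSE): treat
                # known parent codes as polymer
                is_polymer, status = True, MODIFIED

        if is_polymer:
            one = three_to_one(res_name)
            model.chains.setdefault(chain, []).append(
                ResidueRecord(
                    chain_id=chain,
                    res_name=res_name,
                    author_number=num,
                    insertion_code=icode,
                    one_letter=one if status == OBSERVED else three_to_one(res_name),
                    status=status,
                    atoms=g["atoms"],
                    is_hetatm_polymer=g["is_het"],
                    order_key=float(g["order"]),
                )
            )
        else:
            idx = ligand_count_per_chain.get(chain, 0)
            ligand_count_per_chain[chain] = idx + 1
            model.ligands.append(
                LigandRecord(
                    het_code=res_name,
                    chain_id=chain,
                    author_number=num,
                    insertion_code=icode,
                    coord_index=idx,
                    atoms=g["atoms"],
                    is_water=res_name in WATER_CODES,
                    order_key=float(g["order"]),
                )
            )

    _insert_missing_residues(model, remark465_lines)
    return model


def _insert_missing_residues(model: StructureModel, remark465_lines: list[str]) -> None:
    """Insert missing-status residues from REMARK 465, or infer from SEQRES.

    REMARK 465 is the primary source.  If absent but SEQRES is present,
    missing runs are inferred by exact-match anchoring of the observed residue
    codes against SEQRES.  Otherwise no residues are assumed missing.
    """
    entries = _parse_remark_465(remark465_lines)
    if entries:
        for res_name, chain, num, icode in entries:
            residues = model.chains.setdefault(chain, [])
            rec = ResidueRecord(
                chain_id=chain,
                res_name=res_name,
                author_number=num,
                insertion_code=icode,
                one_letter=three_to_one(res_name),
                status=MISSING,
                atoms=[],
            )
            idx = len(residues)
            for i, r in enumerate(residues):
                if (r.author_number, r.insertion_code) > (num, icode):
                    idx = i
                    break
            if idx > 0:
                rec.order_key = residues[idx - 1].order_key + 1e-3
            elif residues:
                rec.order_key = residues[0].order_key - 1e-3
            residues.insert(idx, rec)
        return

    if not model.seqres:
        return

    import difflib

    for chain, codes in model.seqres.items():
        residues = model.chains.get(chain)
        if not residues:
            continue
        observed_codes = [r.res_name for r in residues]
        sm = difflib.SequenceMatcher(a=codes, b=observed_codes, autojunk=False)
        matched_seqres: set[int] = set()
        anchor: dict[int, int] = {}  # seqres index -> observed index
        for blk in sm.get_matching_blocks():
            for k in range(blk.size):
                matched_seqres.add(blk.a + k)
                anchor[blk.a + k] = blk.b + k
        if len(matched_seqres) < len(observed_codes):
            continue  # ambiguous anchoring; assume no missing residues
        new_list: list[ResidueRecord] = []
        for i, code in enumerate(codes):
            if i in anchor:
                new_list.append(residues[anchor[i]])
            else:
                # extrapolate author number from nearest anchored neighbour
                prev_nums = [anchor[j] for j in range(i) if j in anchor]
                if prev_nums:
                    base = residues[prev_nums[-1]]
                    num = base.author_number + (i - max(j for j in range(i) if j in anchor))
                    okey = base.order_key + 1e-3
                else:
                    nxt = min(j for j in anchor if j > i)
                    base = residues[anchor[nxt]]
                    num = base.author_number - (nxt - i)
                    okey = base.order_key - 1e-3
                new_list.append(
                    ResidueRecord(
                        chain_id=chain,
                        res_name=code,
                        author_number=num,
                        insertion_code="",
                        one_letter=three_to_one(code),
                        status=MISSING,
                        atoms=[],
                        order_key=okey,
                    )
                )
        model.chains[chain] = new_list


# ---------------------------------------------------------------------------
# queries

def extract_chain_sequence(model: StructureModel, chain: str) -> AnnotatedSequence:
    """Annotated polymer sequence of one chain, one position per residue.

    Alignment-mode rendering substitutes 'X' at missing and modified
    positions, per the masking convention used before multiple sequence
    alignment.
    """
    residues = model.chain(chain)
    return AnnotatedSequence(
        positions=[(r.one_letter, r.status, r) for r in residues]
    )


def list_ligands(
    model: StructureModel,
    chain: str | None = None,
    include_water: bool = False,
) -> list[LigandRecord]:
    """Non-polymer HETATM records in coordinate order, optionally per chain."""
    out = [
        lig
        for lig in model.ligands
        if (chain is None or lig.chain_id == chain)
        and (include_water or not lig.is_water)
    ]
    return sorted(out, key=lambda l: l.order_key)


def write_fasta(sequences: dict[str, str]) -> str:
    """Render named sequences as FASTA text (Biopython writer)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
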