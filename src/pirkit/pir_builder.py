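"""Construction of MODELLER-dialect PIR alignment files.

A PIR file links the target–template alignment to specific coordinate spans
of each template PDB file.  Its dialect rules, all enforced here:

* template rows render missing residues as ``-`` and modified residues as
  ``.`` (MODELLER recognizes ``.`` as a non-standard/ligand position);
* every structure entry carries the author numbers of its first and last
  residue so MODELLER can locate the span in the coordinate file;
* every template row is verified position-by-position against the sequence
  extracted from its PDB file before the file is written;
* when ligands are selected for modeling, the template entry is extended with
  one column per residue/HETATM up to the last selected ligand in coordinate
  order, the template's ending residue becomes that ligand, and the target
  row gains ``.`` at the selected-ligand columns (``-`` elsewhere).

All entries keep equal body length; each body ends in a single ``*``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import yaml

from .alignment_ops import Alignment, EditVerdict
from .structure_io import (
    MISSING,
    MODIFIED,
    OBSERVED,
    LigandRecord,
    ResidueRecord,
    StructureModel,
)

__all__ = [
    "PirEntry",
    "PirFile",
    "LigandSelection",
    "ModelJobConfig",
    "render_pir_sequences",
    "determine_span",
    "verify_template_sequence",
    "build_pir",
    "graft_ligands",
    "write_pir",
    "parse_pir",
    "build_job_config",
    "write_modeller_script",
]

STRUCTURE = "structure"
SEQUENCE = "sequence"

WRAP = 75  # sequence wrap width in the written file


class SpanResolutionError(ValueError):
    """Entry sequence matches zero or several runs of the chain."""


class SelectionError(ValueError):
    """A selected ligand does not exist in its template structure."""


@dataclass
class PirEntry:
    """One PIR entry (a template structure or the target sequence)."""

    name: str
    kind: str  # STRUCTURE | SEQUENCE
    sequence_text: str  # body plus single trailing '*'
    pdb_file: str = ""
    start_residue: str = ""
    start_chain: str = ""
    end_residue: str = ""
    end_chain: str = ""

    def __post_init__(self) -> None:
        if not self.sequence_text.endswith("*") or "*" in self.sequence_text[:-1]:
            raise ValueError(f"{self.name}: sequence_text needs exactly one trailing '*'")

    @property
    def body(self) -> str:
        return self.sequence_text[:-1]


@dataclass
class PirFile:
    """Ordered PIR entries; the target sequence entry comes last."""

    entries: list[PirEntry] = field(default_factory=list)

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("PIR file has no entries")
        lengths = {len(e.body) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"unequal PIR entry lengths: {sorted(lengths)}")
        if self.entries[-1].kind != SEQUENCE:
            raise ValueError("last PIR entry must be the target sequence")
        for e in self.entries:
            if e.kind == STRUCTURE and not (e.start_residue and e.end_residue):
                raise ValueError(f"structure entry {e.name} lacks start/end residues")

    @property
    def target(self) -> PirEntry:
        return self.entries[-1]

    @property
    def templates(self) -> list[PirEntry]:
        return [e for e in self.entries if e.kind == STRUCTURE]


@dataclass(frozen=True)
class LigandSelection:
    """One selected ligand: template entry name, HET code, and the ligand's
    coordinate-section ordinal within its chain (None = first match)."""

    template: str
    het_code: str
    ordinal: int | None = None


@dataclass
class ModelJobConfig:
    """Parameters handed to the (externally executed) modeling script."""

    n_models: int = 10
    refinement: str = "very_slow"  # none | fast | very_slow
    read_hetatm: bool = False
    read_water: bool = False
    selected_ligands: list[LigandSelection] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "refinement": self.refinement,
            "read_hetatm": self.read_hetatm,
            "read_water": self.read_water,
            "selected_ligands": [
                {"template": s.template, "het_code": s.het_code, "ordinal": s.ordinal}
                for s in self.selected_ligands
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


# ---------------------------------------------------------------------------
# rendering and span resolution

def render_pir_sequences(aln: Alignment) -> dict[str, str]:
    """Render a trimmed alignment's rows as PIR bodies (no '*' yet).

    Template rows require per-position status annotations: missing → '-',
    modified → '.', observed → the residue letter.  The target renders
    verbatim with '-' gaps.
    """
    out: dict[str, str] = {}
    for e in aln.entries:
        if e.role == "target":
            out[e.name] = e.gapped
            continue
        if e.status is None:
            raise ValueError(f"template {e.name} carries no status annotations")
        chars = []
        for c, s in zip(e.gapped, e.status):
            if c == "-":
                chars.append("-")
            elif s == "x":
                chars.append("-")
            elif s == "m":
                chars.append(".")
            else:
                chars.append(c)
        out[e.name] = "".join(chars)
    return out


def _matches(char: str, res: ResidueRecord) -> bool:
    if char == ".":
        return res.status == MODIFIED
    return res.status == OBSERVED and res.one_letter.upper() == char.upper()


def determine_span(
    entry_sequence: str, model: StructureModel, chain: str
) -> tuple[str, str]:
    """Author numbers (+ insertion codes) of the first and last residues the
    entry covers.

    The entry's gap-stripped characters must match exactly one contiguous run
    of the chain's observed residues ('.' matching modified residues).
    Raises :class:`SpanResolutionError` on zero or multiple matches.
    """
    probe = entry_sequence.rstrip("*").replace("-", "")
    observed = [r for r in model.chain(chain) if r.status != MISSING]
    n = len(probe)
    if n == 0:
        raise SpanResolutionError("entry sequence is empty after removing gaps")
    matches = [
        i
        for i in range(len(observed) - n + 1)
        if all(_matches(probe[k], observed[i + k]) for k in range(n))
    ]
    if not matches:
        raise SpanResolutionError(
            f"entry sequence not found in chain {chain} of {model.pdb_id}"
        )
    if len(matches) > 1:
        starts = [observed[i].label for i in matches]
        raise SpanResolutionError(
            f"entry sequence matches chain {chain} at multiple positions: {starts}"
        )
    i = matches[0]
    return observed[i].label, observed[i + n - 1].label


def verify_template_sequence(
    entry_sequence: str,
    model: StructureModel,
    chain: str,
    span: tuple[str, str],
) -> EditVerdict:
    """Check a PIR template body against the sequence extracted from its PDB.

    Within the resolved span, letters must match observed one-letter codes,
    '.' modified residues, and '-' missing residues; '-' over positions with
    no polymer counterpart are treated as alignment gaps.  Returns a verdict
    with the first mismatching body position when invalid.
    """
    body = entry_sequence.rstrip("*")
    residues = model.chain(chain)
    labels = [r.label for r in residues]
    try:
        i0 = labels.index(span[0])
        i1 = labels.index(span[1])
    except ValueError:
        return EditVerdict("invalid", f"span {span} not found in chain {chain}")
    polymer = residues[i0 : i1 + 1]
    k = 0  # index into polymer
    for pos, c in enumerate(body):
        if c == "-":
            if k < len(polymer) and polymer[k].status == MISSING:
                k += 1
            # else: alignment gap, no polymer position consumed
            continue
        if k >= len(polymer):
            return EditVerdict("invalid", "entry longer than structure span", pos)
        res = polymer[k]
        if c == ".":
            if res.status != MODIFIED:
                return EditVerdict(
                    "invalid", f"'.' over non-modified residue {res.res_name} {res.label}", pos
                )
        else:
            if res.status == MISSING:
                return EditVerdict(
                    "invalid", f"letter {c!r} over missing residue {res.label}", pos
                )
            if res.one_letter.upper() != c.upper():
                return EditVerdict(
                    "invalid",
                    f"{c!r} does not match {res.res_name} ({res.one_letter}) at {res.label}",
                    pos,
                )
        k += 1
    # any leftover observed polymer positions mean the entry under-covers the span
    while k < len(polymer) and polymer[k].status == MISSING:
        k += 1
    if k != len(polymer):
        return EditVerdict("invalid", "entry shorter than structure span")
    return EditVerdict("valid")


def build_pir(
    aln: Alignment,
    models: dict[str, StructureModel],
    chains: dict[str, str],
    pdb_files: dict[str, str] | None = None,
) -> PirFile:
    """Assemble a verified PIR file from a trimmed, annotated alignment.

    ``models`` and ``chains`` map template entry names to their parsed
    structures and chain IDs; ``pdb_files`` optionally overrides the filename
    written into each structure header (default ``<name>.pdb``).
    """
    rendered = render_pir_sequences(aln)
    entries: list[PirEntry] = []
    for t in aln.templates:
        body = rendered[t.name]
        model = models[t.name]
        chain = chains[t.name]
        start, end = determine_span(body, model, chain)
        verdict = verify_template_sequence(body, model, chain, (start, end))
        if not verdict:
            raise ValueError(f"template {t.name} failed verification: {verdict.reason}")
        entries.append(
            PirEntry(
                name=t.name,
                kind=STRUCTURE,
                sequence_text=body + "*",
                pdb_file=(pdb_files or {}).get(t.name, f"{t.name}.pdb"),
                start_residue=start,
                start_chain=chain,
                end_residue=end,
                end_chain=chain,
            )
        )
    tgt = aln.target
    entries.append(PirEntry(name=tgt.name, kind=SEQUENCE, sequence_text=tgt.gapped + "*"))
    pir = PirFile(entries=entries)
    pir.validate()
    return pir


# ---------------------------------------------------------------------------
# ligand grafting

def _resolve_selection(
    model: StructureModel, sel: LigandSelection
) -> LigandRecord:
    candidates = [
        lig
        for lig in model.ligands
        if lig.het_code == sel.het_code
        and (sel.ordinal is None or lig.coord_index == sel.ordinal)
    ]
    if not candidates:
        raise SelectionError(
            f"ligand {sel.het_code} (ordinal {sel.ordinal}) not found in template "
            f"{sel.template}"
        )
    return candidates[0]


def graft_ligands(
    pir: PirFile,
    models: dict[str, StructureModel],
    selection: list[LigandSelection],
) -> PirFile:
    """Extend a verified PIR file with ligand columns for selected HETATMs.

    For each template with selections, the ending residue becomes the last
    selected ligand (coordinate order); every polymer residue and HETATM
    between the old end and that ligand contributes one appended column
    (letter / '.' / '-' by status for residues, '.' for HETATMs).  The target
    is padded with '-' and then given '.' exactly at selected-ligand columns;
    unselected HETATM columns stay '-'.  All other entries pad with '-'.
    """
    if not selection:
        return pir
    pir.validate()
    by_template: dict[str, list[LigandSelection]] = {}
    for sel in selection:
        by_template.setdefault(sel.template, []).append(sel)

    entries = {e.name: e for e in pir.entries}
    bodies = {e.name: e.body for e in pir.entries}
    meta = {e.name: replace(e) for e in pir.entries}
    target_name = pir.target.name

    for tname, sels in by_template.items():
        if tname not in entries:
            raise SelectionError(f"no PIR entry named {tname}")
        if entries[tname].kind != STRUCTURE:
            raise ValueError(f"ligand selection for sequence entry {tname}")
        model = models[tname]
        chain = entries[tname].end_chain
        records = [_resolve_selection(model, s) for s in sels]
        selected_keys = {id(r) for r in records}
        last = max(records, key=lambda r: r.order_key)

        residues = model.chain(chain)
        labels = [r.label for r in residues]
        end_idx = labels.index(entries[tname].end_residue)
        end_key = residues[end_idx].order_key

        tail: list[tuple[float, str, bool]] = []  # (order, char, is_selected_ligand)
        for r in residues[end_idx + 1 :]:
            if r.order_key > last.order_key:
                continue
            char = "." if r.status == MODIFIED else ("-" if r.status == MISSING else r.one_letter)
            tail.append((r.order_key, char, False))
        for lig in model.ligands:
            if end_key < lig.order_key <= last.order_key:
                tail.append((lig.order_key, ".", id(lig) in selected_keys))
        tail.sort(key=lambda t: t[0])

        n = len(tail)
        for name in bodies:
            if name == tname:
                bodies[name] += "".join(c for _, c, _ in tail)
            elif name == target_name:
                bodies[name] += "".join("." if sel else "-" for _, _, sel in tail)
            else:
                bodies[name] += "-" * n
        meta[tname].end_residue = last.label
        meta[tname].end_chain = last.chain_id

    new_entries = []
    for e in pir.entries:
        m = meta[e.name]
        m.sequence_text = bodies[e.name] + "*"
        new_entries.append(m)
    out = PirFile(entries=new_entries)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# serialization

def write_pir(pir: PirFile) -> str:
    """Serialize to MODELLER-dialect PIR text (LF endings, 75-column wrap)."""
    pir.validate()
    lines: list[str] = []
    for e in pir.entries:
        lines.append(f">P1;{e.name}")
        if e.kind == STRUCTURE:
            lines.append(
                f"structureX:{e.pdb_file}:{e.start_residue}:{e.start_chain}:"
                f"{e.end_residue}:{e.end_chain}::::"
            )
        else:
            lines.append(f"sequence:{e.name}::::::::")
        seq = e.sequence_text
        for i in range(0, len(seq), WRAP):
            lines.append(seq[i : i + WRAP])
    return "\n".join(lines) + "\n"


def parse_pir(text: str) -> PirFile:
    """Minimal PIR reader (round-trip testing and manual inspection)."""
    entries: list[PirEntry] = []
    name = header = None
    seq_parts: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(seq_parts)
        fields = header.split(":")
        if fields[0].startswith("structure"):
            entries.append(
                PirEntry(
                    name=name,
                    kind=STRUCTURE,
                    sequence_text=seq,
                    pdb_file=fields[1],
                    start_residue=fields[2],
                    start_chain=fields[3],
                    end_residue=fields[4],
                    end_chain=fields[5],
                )
            )
        else:
            entries.append(PirEntry(name=name, kind=SEQUENCE, sequence_text=seq))

    for ln in text.splitlines():
        if ln.startswith(">P1;"):
            flush()
            name = ln[4:].strip()
            header = None
            seq_parts = []
        elif name is not None and header is None:
            header = ln.strip()
        elif name is not None:
            seq_parts.append(ln.strip())
    flush()
    return PirFile(entries=entries)


# ---------------------------------------------------------------------------
# job configuration

_REFINEMENT_LEVELS = {"none", "fast", "very_slow"}


def build_job_config(
    selection: list[LigandSelection] | None = None,
    *,
    n_models: int = 10,
    refinement: str = "very_slow",
    water_codes: frozenset[str] = frozenset({"HOH", "WAT", "DOD"}),
) -> ModelJobConfig:
    """Modeling-job configuration: 10 models with very-slow refinement by
    default; HETATM/water read flags follow the ligand selection."""
    if refinement not in _REFINEMENT_LEVELS:
        raise ValueError(
            f"unknown refinement level {refinement!r}; expected one of "
            f"{sorted(_REFINEMENT_LEVELS)}"
        )
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    selection = selection or []
    waters = [s for s in selection if s.het_code.upper() in water_codes]
    others = [s for s in selection if s.het_code.upper() not in water_codes]
    return ModelJobConfig(
        n_models=n_models,
        refinement=refinement,
        read_hetatm=bool(others),
        read_water=bool(waters),
        selected_ligands=list(selection),
    )


def write_modeller_script(
    config: ModelJobConfig, pir_filename: str, template_names: list[str], target_name: str
) -> str:
    """Template-filled modeling-script stub (never executed by this package)."""
    refine = {"none": "None", "fast": "refine.fast", "very_slow": "refine.very_slow"}
    lines = [
        "# auto-generated comparative-modeling script stub",
        "from modeller import *",
        "from modeller.automodel import *",
        "",
        "env = Environ()",
        f"env.io.hetatm = {config.read_hetatm}",
        f"env.io.water = {config.read_water}",
        "a = AutoModel(env,",
        f"    alnfile='{pir_filename}',",
        f"    knowns={tuple(template_names)!r},",
        f"    sequence='{target_name}')",
        "a.starting_model = 1",
        f"a.ending_model = {config.n_models}",
    ]
    if config.refinement != "none":
        lines.append(f"a.md_level = {refine[config.refinement]}")
    lines += ["a.make()", ""]
    return "\n".join(lines)
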