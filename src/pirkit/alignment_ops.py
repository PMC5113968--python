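"""Target–template alignment handling: identity, bins, coverage, trimming,
and validation of interactive alignment edits.

The alignment itself is produced externally (MAFFT, MUSCLE, Clustal Omega,
T-Coffee, or the pairwise alignment from a template search); this module
consumes aligned FASTA/Clustal and applies the bookkeeping rules a modeling
pipeline needs before PIR construction:

* percent identity over both-non-gap columns, with 'X' (masked missing or
  modified positions) never counting as a match;
* decade identity bins on [20, 90), lower bound inclusive — a 30%-identity
  template belongs to the 30–40% bin, not 20–30%;
* terminal trimming so the modeled target span has template support at both
  ends, and target coverage relative to the full untrimmed target;
* validation of user edits: gaps may move anywhere, but template sequences
  may only be trimmed from the outside.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import AlignIO

from .structure_io import AnnotatedSequence

__all__ = [
    "AlignmentEntry",
    "Alignment",
    "BinKey",
    "EditVerdict",
    "compute_identity",
    "assign_bin",
    "compute_coverage",
    "trim_termini",
    "validate_edit",
    "read_alignment",
    "write_alignment_fasta",
]

TARGET = "target"
TEMPLATE = "template"

# per-position status characters carried alongside template rows:
# 'o' observed, 'm' modified, 'x' missing, '-' gap column
_STATUS_GAP = "-"


@dataclass
class AlignmentEntry:
    """One aligned row: a gapped sequence plus, for templates, per-position
    observed/modified/missing status threaded from the structure."""

    name: str
    role: str  # TARGET or TEMPLATE
    gapped: str
    status: str | None = None  # same length as gapped; templates only

    def ungapped(self) -> str:
        return self.gapped.replace("-", "")

    def with_status_from(self, annotated: AnnotatedSequence) -> "AlignmentEntry":
        """Thread an AnnotatedSequence's statuses through this gapped row.

        The row's non-gap characters must correspond 1:1 (in order) to the
        annotated sequence's positions.
        """
        n_resid = sum(1 for c in self.gapped if c != "-")
        if n_resid != len(annotated):
            raise ValueError(
                f"{self.name}: {n_resid} aligned residues vs "
                f"{len(annotated)} annotated positions"
            )
        codes = annotated.statuses
        out, k = [], 0
        for c in self.gapped:
            if c == "-":
                out.append(_STATUS_GAP)
            else:
                out.append(codes[k])
                k += 1
        return AlignmentEntry(self.name, self.role, self.gapped, "".join(out))


@dataclass
class Alignment:
    """A target plus one or more template rows, all the same length."""

    entries: list[AlignmentEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.entries:
            lengths = {len(e.gapped) for e in self.entries}
            if len(lengths) != 1:
                raise ValueError(f"unequal row lengths: {sorted(lengths)}")
            roles = [e.role for e in self.entries]
            if roles.count(TARGET) != 1:
                raise ValueError("alignment must contain exactly one target row")
            if roles.count(TEMPLATE) < 1:
                raise ValueError("alignment must contain at least one template row")

    @property
    def width(self) -> int:
        return len(self.entries[0].gapped)

    @property
    def target(self) -> AlignmentEntry:
        return next(e for e in self.entries if e.role == TARGET)

    @property
    def templates(self) -> list[AlignmentEntry]:
        return [e for e in self.entries if e.role == TEMPLATE]


@dataclass(frozen=True)
class BinKey:
    """Decade identity bin [lower, upper), upper = lower + 10."""

    lower: int

    @property
    def upper(self) -> int:
        return self.lower + 10

    def __contains__(self, identity: float) -> bool:
        return self.lower <= identity < self.upper

    def __str__(self) -> str:
        return f"{self.lower}-{self.upper}%"


@dataclass
class EditVerdict:
    status: str  # "valid" | "invalid"
    reason: str = ""
    position: int | None = None

    def __bool__(self) -> bool:
        return self.status == "valid"

    def to_json(self) -> dict:
        return {"status": self.status, "reason": self.reason, "position": self.position}


def compute_identity(a: str, b: str) -> float:
    """Percent identity over both-non-gap columns; 'X' never matches.

    Raises ValueError on unequal lengths or when no column has residues in
    both rows (identity undefined).
    """
    if len(a) != len(b):
        raise ValueError(f"unequal alignment lengths: {len(a)} vs {len(b)}")
    both = ident = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb and ca != "X":
                ident += 1
    if both == 0:
        raise ValueError("identity undefined: no both-non-gap columns")
    return 100.0 * ident / both


def assign_bin(identity: float) -> BinKey | None:
    """Decade bin for an identity in [20, 90); None when out of range.

    Bins are lower-inclusive: 30.0 falls in [30, 40), 40.0 in [40, 50).
    Out-of-range identities are excluded from benchmarking rather than
    raising.
    """
    if not 20.0 <= identity < 90.0:
        return None
    return BinKey(lower=int(identity // 10) * 10)


def _template_supported(aln: Alignment, col: int) -> bool:
    """True when ≥1 template has an observed (non-gap, non-missing) residue."""
    for t in aln.templates:
        c = t.gapped[col]
        if c == "-":
            continue
        if t.status is not None and t.status[col] == "x":
            continue
        return True
    return False


def _support_bounds(aln: Alignment) -> tuple[int, int] | None:
    """First and last column where the target is non-gap and some template
    supports it; None when no such column exists."""
    tgt = aln.target.gapped
    cols = [
        i for i in range(aln.width) if tgt[i] != "-" and _template_supported(aln, i)
    ]
    if not cols:
        return None
    return cols[0], cols[-1]


def trim_termini(aln: Alignment) -> Alignment:
    """Trim terminal columns so the modeled span is template-supported.

    Leading and trailing columns are removed up to the first/last column where
    the target is non-gap and at least one template is non-gap (missing-status
    template positions count as gaps).  Interior columns are untouched.
    """
    bounds = _support_bounds(aln)
    if bounds is None:
        raise ValueError("no column with target residue and template support")
    lo, hi = bounds
    return Alignment(
        entries=[
            AlignmentEntry(
                e.name,
                e.role,
                e.gapped[lo : hi + 1],
                e.status[lo : hi + 1] if e.status is not None else None,
            )
            for e in aln.entries
        ]
    )


def compute_coverage(aln: Alignment) -> float:
    """Percent of the full target sequence that would be modeled.

    Numerator: target residues inside the post-trim span whose column has
    support from ≥1 template (non-gap, non-missing).  Denominator: the full
    target length including any termini the trim removes — so a mostly
    unsupported target genuinely fails an 80% coverage threshold.
    """
    tgt = aln.target.gapped
    total = sum(1 for c in tgt if c != "-")
    if total == 0:
        return 0.0
    bounds = _support_bounds(aln)
    if bounds is None:
        return 0.0
    lo, hi = bounds
    covered = sum(
        1
        for i in range(lo, hi + 1)
        if tgt[i] != "-" and _template_supported(aln, i)
    )
    return 100.0 * covered / total


_AA_AND_GAP = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ-")


def validate_edit(original: str, edited: str, role: str) -> EditVerdict:
    """Check a hand-edited alignment row against the editor rules.

    Gaps may be added or moved anywhere.  A template row may only be trimmed
    from the outside: its ungapped sequence must remain a contiguous substring
    of the original's ungapped sequence.  A target row is valid whenever it
    uses only amino-acid letters and '-'.
    """
    for i, c in enumerate(edited.upper()):
        if c not in _AA_AND_GAP:
            return EditVerdict("invalid", f"invalid character {c!r}", i)
    if role == TARGET:
        return EditVerdict("valid")
    if role != TEMPLATE:
        raise ValueError(f"unknown role {role!r}")
    orig_seq = original.upper().replace("-", "")
    edit_seq = edited.upper().replace("-", "")
    if edit_seq not in orig_seq:
        return EditVerdict(
            "invalid",
            "edited template is not a contiguous substring of the original "
            "(sequences can only be trimmed from the outsides)",
        )
    return EditVerdict("valid")


# ---------------------------------------------------------------------------
# I/O

def read_alignment(
    text: str,
    target_name: str,
    fmt: str = "fasta",
) -> Alignment:
    """Read an aligned FASTA or Clustal alignment; the row named
    ``target_name`` becomes the target, the rest templates.  Lowercase
    letters are uppercased."""
    msa = AlignIO.read(io.StringIO(text), fmt)
    entries = []
    for rec in msa:
        role = TARGET if rec.id == target_name else TEMPLATE
        entries.append(AlignmentEntry(rec.id, role, str(rec.seq).upper()))
    return Alignment(entries=entries)


def write_alignment_fasta(aln: Alignment) -> str:
    out = []
    for e in aln.entries:
        out.append(f">{e.name}")
        out.append(e.gapped)
    return "\n".join(out) + "\n"
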