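"""Parsers for template-search reports (BLAST XML, HHsearch .hhr).

Both report formats are reduced to the same hit table: PDB ID and chain,
percent identity, percent query coverage, E-value, and the pairwise
query/template alignment — everything needed to pick and align templates
without re-running the search programs.

BLAST XML (``-outfmt 5``) is parsed with Biopython's NCBIXML reader; the
hhr format has no established parser and is handled here directly.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Blast import NCBIXML

from .alignment_ops import compute_identity

__all__ = ["TemplateHit", "parse_blast_xml", "parse_hhr", "hits_to_table"]


@dataclass
class TemplateHit:
    """One template candidate from a search report."""

    pdb_id: str
    chain_id: str
    seq_identity_pct: float
    query_coverage_pct: float
    evalue: float
    aligned_query: str
    aligned_template: str
    query_start: int
    query_end: int
    template_start: int
    template_end: int
    source: str  # "blast" | "hhsearch"
    metadata: dict = field(default_factory=dict)  # e.g. hhr Probab / Score


_SUBJECT_PATTERNS = [
    re.compile(r"pdb\|(?P<pdb>\w{4})\|(?P<chain>\w)"),
    re.compile(r"^(?P<pdb>\w{4})_(?P<chain>\w)\b"),
    re.compile(r"^(?P<pdb>\w{4})\|(?P<chain>\w)\b"),
]


def _split_subject_id(*candidates: str) -> tuple[str, str] | None:
    for text in candidates:
        for pat in _SUBJECT_PATTERNS:
            m = pat.search(text)
            if m:
                return m.group("pdb").lower(), m.group("chain")
    return None


def parse_blast_xml(text: str, query_length: int) -> list[TemplateHit]:
    """Parse BLAST XML (outfmt 5) into template hits.

    One hit per subject, keeping the best (lowest-E-value) HSP.  Identity is
    BLAST's own convention, 100·identities/alignment-length (gap columns in
    the denominator); coverage is the HSP query span over ``query_length``.
    Hits are sorted by ascending E-value.  Subjects whose ID does not encode a
    PDB chain are skipped with a warning.
    """
    record = NCBIXML.read(io.StringIO(text))
    hits: list[TemplateHit] = []
    for alignment in record.alignments:
        ids = _split_subject_id(alignment.hit_id or "", alignment.hit_def or "",
                                alignment.accession or "")
        if ids is None:
            warnings.warn(
                f"subject {alignment.hit_id!r}: no PDB chain in ID, hit skipped"
            )
            continue
        pdb_id, chain = ids
        hsp = min(alignment.hsps, key=lambda h: h.expect)
        identity = 100.0 * hsp.identities / hsp.align_length
        coverage = 100.0 * (hsp.query_end - hsp.query_start + 1) / query_length
        hits.append(
            TemplateHit(
                pdb_id=pdb_id,
                chain_id=chain,
                seq_identity_pct=identity,
                query_coverage_pct=coverage,
                evalue=hsp.expect,
                aligned_query=hsp.query,
                aligned_template=hsp.sbjct,
                query_start=hsp.query_start,
                query_end=hsp.query_end,
                template_start=hsp.sbjct_start,
                template_end=hsp.sbjct_end,
                source="blast",
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.seq_identity_pct))
    return hits


# ---------------------------------------------------------------------------
# hhr

_HHR_HIT_HEADER = re.compile(r"^No (\d+)\s*$")
_HHR_STAT = re.compile(
    r"Probab=(?P<prob>[\d.]+)\s+E-value=(?P<evalue>[\d.eE+-]+)\s+Score=(?P<score>[\d.]+)"
)
_HHR_IDENT = re.compile(r"Identities=(?P<ident>[\d.]+)%")
_HHR_ALNLINE = re.compile(
    r"^(?P<role>[QT]) (?P<name>\S+)\s+(?P<start>\d+) (?P<seq>\S+)\s+(?P<end>\d+) \(\d+\)"
)
_SKIP_NAMES = {"Consensus", "ss_pred", "ss_dssp", "ss_conf"}


def parse_hhr(text: str, query_length: int) -> list[TemplateHit]:
    """Parse an HHsearch .hhr report into template hits.

    Multi-block Q/T alignment lines are concatenated per hit in order.
    Identity is taken from the ``Identities=NN%`` field when present, else
    recomputed from the concatenated alignment over both-non-gap columns.
    Coverage is recomputed from the query start/end over ``query_length``.
    """
    lines = text.splitlines()
    # summary table: count rows between "No Hit" header and first blank
    n_summary = 0
    in_summary = False
    for ln in lines:
        if ln.lstrip().startswith("No Hit"):
            in_summary = True
            continue
        if in_summary:
            if not ln.strip():
                break
            if re.match(r"^\s*\d+\s", ln):
                n_summary += 1

    # alignment blocks
    blocks: dict[int, dict] = {}
    current: dict | None = None
    for ln in lines:
        m = _HHR_HIT_HEADER.match(ln)
        if m:
            idx = int(m.group(1))
            current = blocks[idx] = {
                "q_parts": [],
                "t_parts": [],
                "q_start": None,
                "q_end": None,
                "t_start": None,
                "t_end": None,
                "name": None,
                "evalue": None,
                "prob": None,
                "score": None,
                "ident": None,
            }
            continue
        if current is None:
            continue
        if ln.startswith(">") and current["name"] is None:
            current["name"] = ln[1:].split()[0]
            continue
        s = _HHR_STAT.search(ln)
        if s:
            current["evalue"] = float(s.group("evalue"))
            current["prob"] = float(s.group("prob"))
            current["score"] = float(s.group("score"))
            mi = _HHR_IDENT.search(ln)
            if mi:
                current["ident"] = float(mi.group("ident"))
            continue
        a = _HHR_ALNLINE.match(ln)
        if a and a.group("name") not in _SKIP_NAMES:
            start, end = int(a.group("start")), int(a.group("end"))
            if a.group("role") == "Q":
                current["q_parts"].append(a.group("seq"))
                if current["q_start"] is None:
                    current["q_start"] = start
                current["q_end"] = end
            else:
                current["t_parts"].append(a.group("seq"))
                if current["t_start"] is None:
                    current["t_start"] = start
                current["t_end"] = end

    hits: list[TemplateHit] = []
    for idx in range(1, n_summary + 1):
        if idx not in blocks or not blocks[idx]["q_parts"]:
            raise ValueError(f"hhr summary row {idx} has no alignment block")
        b = blocks[idx]
        aligned_q = "".join(b["q_parts"])
        aligned_t = "".join(b["t_parts"])
        if len(aligned_q) != len(aligned_t):
            raise ValueError(f"hhr hit {idx}: Q/T alignment length mismatch")
        ids = _split_subject_id(b["name"] or "")
        pdb_id, chain = ids if ids else ((b["name"] or f"hit{idx}").lower(), "A")
        identity = (
            b["ident"]
            if b["ident"] is not None
            else compute_identity(aligned_q, aligned_t)
        )
        coverage = 100.0 * (b["q_end"] - b["q_start"] + 1) / query_length
        hits.append(
            TemplateHit(
                pdb_id=pdb_id,
                chain_id=chain,
                seq_identity_pct=identity,
                query_coverage_pct=coverage,
                evalue=b["evalue"] if b["evalue"] is not None else 0.0,
                aligned_query=aligned_q,
                aligned_template=aligned_t,
                query_start=b["q_start"],
                query_end=b["q_end"],
                template_start=b["t_start"],
                template_end=b["t_end"],
                source="hhsearch",
                metadata={"probab": b["prob"], "score": b["score"]},
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.seq_identity_pct))
    return hits


def hits_to_table(hits: list[TemplateHit]) -> pd.DataFrame:
    """Hit list as a DataFrame (TSV-exportable via ``.to_csv(sep='\\t')``)."""
    return pd.DataFrame(
        [
            {
                "pdb_id": h.pdb_id,
                "chain": h.chain_id,
                "identity": h.seq_identity_pct,
                "coverage": h.query_coverage_pct,
                "evalue": h.evalue,
                "source": h.source,
            }
            for h in hits
        ]
    )
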