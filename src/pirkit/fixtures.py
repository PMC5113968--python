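"""Deterministic synthetic fixtures: PDB pairs, alignments, search reports,
and benchmark sets with controlled properties.

Every other module in this package is testable offline because this one can
manufacture its inputs.  A fixture pair is a target structure plus a template
derived from it by a controlled recipe: point mutations to reach a requested
sequence identity, isotropic Gaussian coordinate noise, terminal deletions,
missing-residue runs (REMARK 465 + absent ATOM records), modified residues
(MODRES + in-chain HETATM MSE), and appended ligand HETATMs.

Backbone geometry is an idealized helical CA trace (≈3.8 Å consecutive-CA
spacing) — sufficient for superposition and all four comparison scores; no
physical realism is claimed.  All randomness flows through a seeded
``numpy.random.Generator`` (PCG64), so equal seeds give byte-identical
output on any platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_ops import Alignment, AlignmentEntry, compute_identity

__all__ = [
    "FixtureSpec",
    "FixturePair",
    "generate_pair",
    "generate_hit_report",
    "generate_benchmark",
    "BENCH_ALIGNERS",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

BENCH_ALIGNERS = ("mafft", "muscle", "clustalo", "tcoffee", "search_alignment")


@dataclass
class FixtureSpec:
    """Recipe for one target/template fixture pair."""

    seed: int
    length: int = 80
    target_identity_pct: float = 100.0
    coord_noise_sigma: float = 0.0
    missing_runs: list[tuple[int, int]] = field(default_factory=list)  # (start, len), template idx
    modified_positions: list[int] = field(default_factory=list)  # template idx
    ligands: list[tuple[str, bool]] = field(default_factory=list)  # (het_code, after_polymer)
    terminal_deletions: tuple[int, int] = (0, 0)  # residues absent from template ends

    def validate(self) -> None:
        n, c = self.terminal_deletions
        span = self.length - n - c
        if span < 3:
            raise ValueError("template span shorter than 3 residues")
        for start, ln in self.missing_runs:
            if not (0 <= start and start + ln <= span):
                raise ValueError(f"missing run ({start},{ln}) outside template span")
        for p in self.modified_positions:
            if not 0 <= p < span:
                raise ValueError(f"modified position {p} outside template span")
        if not 0 < self.target_identity_pct <= 100:
            raise ValueError("target_identity_pct must be in (0, 100]")


@dataclass
class FixturePair:
    target_pdb: str
    template_pdb: str
    alignment: Alignment  # true alignment, plain letters, '-' at deletions
    target_seq: str
    template_seq: str  # polymer sequence of the template span
    template_statuses: str  # o/m/x per template polymer position


def _helix_trace(n: int) -> np.ndarray:
    """Idealized alpha-helical CA trace: 2.3 Å radius, 1.5 Å rise, 100°/res
    (consecutive-CA distance ≈ 3.8 Å)."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        (2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i)
    )


def _fmt_atom(
    serial: int, name: str, res: str, chain: str, num: int, xyz, het: bool = False,
    element: str = "C",
) -> str:
    rec = "HETATM" if het else "ATOM  "
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{rec}{serial:5d} {pad_name}{'':1s}{res:>3s} {chain}{num:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
    )


def _write_pdb(
    pdb_id: str,
    chain: str,
    residues: list[tuple[int, str, str]],  # (author_number, res_name, status o/m/x)
    coords: dict[int, np.ndarray],
    ligands: list[tuple[str, int, np.ndarray]],  # (het_code, author_number, xyz)
) -> str:
    lines = [f"HEADER    SYNTHETIC FIXTURE                       01-JAN-00   {pdb_id.upper():<4s}"]
    missing = [(num, res) for num, res, st in residues if st == "x"]
    if missing:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for num, res in missing:
            lines.append(f"REMARK 465     {res:>3s} {chain} {num:5d}")
    for num, res, st in residues:
        if st == "m":
            lines.append(f"MODRES {pdb_id.upper():<4s} {res:>3s} {chain} {num:4d}  MET  MODIFIED RESIDUE")
    codes = [res for _, res, _ in residues]
    for row in range(0, len(codes), 13):
        chunk = codes[row : row + 13]
        lines.append(
            f"SEQRES {row // 13 + 1:3d} {chain} {len(codes):4d}  " + " ".join(f"{c:>3s}" for c in chunk)
        )
    serial = 1
    for num, res, st in residues:
        if st == "x":
            continue
        lines.append(_fmt_atom(serial, "CA", res, chain, num, coords[num], het=(st == "m")))
        serial += 1
    lines.append(f"TER   {serial:5d}      {residues[-1][1]:>3s} {chain}{residues[-1][0]:4d}")
    serial += 1
    lig_num = residues[-1][0] + 100
    for het, num, xyz in ligands:
        element = "O" if het in ("HOH", "WAT") else "C"
        lines.append(_fmt_atom(serial, "C1", het, chain, num if num else lig_num, xyz, het=True, element=element))
        serial += 1
        lig_num += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_pair(spec: FixtureSpec) -> FixturePair:
    """Build a (target PDB, template PDB, true alignment) fixture.

    The template span covers the target minus terminal deletions, numbered
    identically to the target so residue labels agree across the pair.
    Mutations are placed on a deterministic position subset to hit the
    requested identity within ±1 percentage point (count rounding resolved
    toward lower identity).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    target_seq = "".join(rng.choice(list(AA20), size=L))
    target_xyz = _helix_trace(L)

    n_del, c_del = spec.terminal_deletions
    span = L - n_del - c_del  # template polymer indices 0..span-1 ↔ target n_del..L-c_del-1

    statuses = ["o"] * span
    for start, ln in spec.missing_runs:
        for k in range(start, start + ln):
            statuses[k] = "x"
    for p in spec.modified_positions:
        statuses[p] = "m"

    template_letters = list(target_seq[n_del : L - c_del])
    # mutate to reach the requested identity over plain aligned letters
    mutable = [i for i in range(span) if statuses[i] == "o"]
    n_mut = math.ceil(span * (1.0 - spec.target_identity_pct / 100.0))
    n_mut = min(n_mut, len(mutable))
    mut_sites = rng.choice(mutable, size=n_mut, replace=False) if n_mut else []
    for i in mut_sites:
        old = template_letters[i]
        choices = [a for a in AA20 if a != old]
        template_letters[i] = choices[int(rng.integers(len(choices)))]
    for p in spec.modified_positions:
        template_letters[p] = "M"  # selenomethionine parent
    template_seq = "".join(template_letters)

    noise = rng.normal(0.0, spec.coord_noise_sigma, size=(span, 3)) if spec.coord_noise_sigma else np.zeros((span, 3))
    template_xyz = target_xyz[n_del : L - c_del] + noise

    # target PDB
    target_residues = [(i + 1, _ONE_TO_THREE[target_seq[i]], "o") for i in range(L)]
    target_coords = {i + 1: target_xyz[i] for i in range(L)}
    target_pdb = _write_pdb("targ", "A", target_residues, target_coords, [])

    # template PDB: author numbers continue the target numbering over the span
    tmpl_residues = []
    tmpl_coords = {}
    for i in range(span):
        num = n_del + i + 1
        st = statuses[i]
        res3 = "MSE" if st == "m" else _ONE_TO_THREE[template_letters[i]]
        tmpl_residues.append((num, res3, st))
        if st != "x":
            tmpl_coords[num] = template_xyz[i]
    lig_records = []
    last_num = n_del + span
    anchor = template_xyz[-1]
    for j, (het, _after) in enumerate(spec.ligands):
        lig_records.append((het, last_num + 10 + j, anchor + np.array([5.0 + 3 * j, 0.0, 0.0])))
    template_pdb = _write_pdb("tmpl", "A", tmpl_residues, tmpl_coords, lig_records)

    aligned_template = "-" * n_del + template_seq + "-" * c_del
    alignment = Alignment(
        entries=[
            AlignmentEntry("target", "target", target_seq),
            AlignmentEntry("template", "template", aligned_template),
        ]
    )
    return FixturePair(
        target_pdb=target_pdb,
        template_pdb=template_pdb,
        alignment=alignment,
        target_seq=target_seq,
        template_seq=template_seq,
        template_statuses="".join(statuses),
    )


# ---------------------------------------------------------------------------
# search reports

_BLAST_TEMPLATE = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
<BlastOutput>
  <BlastOutput_program>blastp</BlastOutput_program>
  <BlastOutput_version>BLASTP 2.12.0+</BlastOutput_version>
  <BlastOutput_db>pdbaa</BlastOutput_db>
  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
  <BlastOutput_query-def>target</BlastOutput_query-def>
  <BlastOutput_query-len>{qlen}</BlastOutput_query-len>
  <BlastOutput_param><Parameters><Parameters_expect>10</Parameters_expect></Parameters></BlastOutput_param>
  <BlastOutput_iterations>
    <Iteration>
      <Iteration_iter-num>1</Iteration_iter-num>
      <Iteration_hits>
{hits}
      </Iteration_hits>
    </Iteration>
  </BlastOutput_iterations>
</BlastOutput>
"""

_BLAST_HIT = """        <Hit>
          <Hit_num>{num}</Hit_num>
          <Hit_id>pdb|{pdb}|{chain}</Hit_id>
          <Hit_def>synthetic template</Hit_def>
          <Hit_accession>{pdb}_{chain}</Hit_accession>
          <Hit_len>{hlen}</Hit_len>
          <Hit_hsps>
            <Hsp>
              <Hsp_num>1</Hsp_num>
              <Hsp_bit-score>200.0</Hsp_bit-score>
              <Hsp_score>500</Hsp_score>
              <Hsp_evalue>{evalue}</Hsp_evalue>
              <Hsp_query-from>{qfrom}</Hsp_query-from>
              <Hsp_query-to>{qto}</Hsp_query-to>
              <Hsp_hit-from>{hfrom}</Hsp_hit-from>
              <Hsp_hit-to>{hto}</Hsp_hit-to>
              <Hsp_identity>{identity}</Hsp_identity>
              <Hsp_positive>{identity}</Hsp_positive>
              <Hsp_gaps>{gaps}</Hsp_gaps>
              <Hsp_align-len>{alen}</Hsp_align-len>
              <Hsp_qseq>{qseq}</Hsp_qseq>
              <Hsp_hseq>{hseq}</Hsp_hseq>
              <Hsp_midline>{midline}</Hsp_midline>
            </Hsp>
          </Hit_hsps>
        </Hit>"""


def generate_hit_report(
    spec: FixtureSpec, fmt: str = "blast_xml", pdb_id: str = "1tmp", chain: str = "A",
    evalue: float = 1e-30,
) -> str:
    """Serialize the fixture pair's true alignment as a search report whose
    parsed hit reproduces the requested identity/coverage within rounding."""
    pair = generate_pair(spec)
    n_del, c_del = spec.terminal_deletions
    L = spec.length
    qseq = pair.target_seq[n_del : L - c_del]
    hseq = pair.template_seq
    identities = sum(1 for a, b in zip(qseq, hseq) if a == b)
    if fmt == "blast_xml":
        if not qseq:
            hits = ""
        else:
            midline = "".join(a if a == b else " " for a, b in zip(qseq, hseq))
            hits = _BLAST_HIT.format(
                num=1, pdb=pdb_id, chain=chain, hlen=len(hseq), evalue=f"{evalue:g}",
                qfrom=n_del + 1, qto=L - c_del, hfrom=1, hto=len(hseq),
                identity=identities, gaps=0, alen=len(qseq), qseq=qseq, hseq=hseq,
                midline=midline,
            )
        return _BLAST_TEMPLATE.format(qlen=L, hits=hits)
    if fmt == "hhr":
        name = f"{pdb_id}_{chain}"
        lines = [
            "Query         target",
            f"Match_columns {L}",
            "No_of_seqs    1 out of 1",
            "",
            " No Hit                             Prob E-value P-value  Score    SS Cols Query HMM  Template HMM",
            f"  1 {name:<30s} 99.9 {evalue:.0e} 1e-35  200.0   0.0  {len(qseq)}    {n_del + 1}-{L - c_del}     1-{len(hseq)} ({len(hseq)})",
            "",
            "No 1",
            f">{name}  synthetic template",
            f"Probab=99.90  E-value={evalue:g}  Score=200.00  Aligned_cols={len(qseq)}  "
            f"Identities={100.0 * identities / len(qseq):.0f}%  Similarity=1.000  Sum_probs=0.0",
            "",
        ]
        block = 40
        qpos, tpos = n_del + 1, 1
        for off in range(0, len(qseq), block):
            qchunk = qseq[off : off + block]
            tchunk = hseq[off : off + block]
            qend = qpos + len(qchunk) - 1
            tend = tpos + len(tchunk) - 1
            lines.append(f"Q target          {qpos:>4d} {qchunk} {qend:>4d} ({L})")
            lines.append(f"Q Consensus       {qpos:>4d} {qchunk.lower()} {qend:>4d} ({L})")
            lines.append(f"T {name:<15s} {tpos:>4d} {tchunk} {tend:>4d} ({len(hseq)})")
            lines.append(f"T Consensus       {tpos:>4d} {tchunk.lower()} {tend:>4d} ({len(hseq)})")
            lines.append("")
            qpos, tpos = qend + 1, tend + 1
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# benchmark generation

def _split_column(rows: dict[str, str], col: int) -> dict[str, str]:
    """Split one aligned column into two half-gapped columns (the local
    realignment difference fake aligners introduce)."""
    out = {}
    for name, s in rows.items():
        if name == "target":
            out[name] = s[:col] + s[col] + "-" + s[col + 1 :]
        else:
            out[name] = s[:col] + "-" + s[col] + s[col + 1 :]
    return out


def _variant_alignment(
    aln: Alignment, rng: np.random.Generator, delta_matches: int
) -> Alignment:
    """Perturb a pairwise alignment: remove `delta_matches` match columns (or
    mismatch columns when negative) from the both-non-gap set by splitting
    them, mimicking aligner-to-aligner differences."""
    tgt, tmpl = aln.target.gapped, aln.templates[0].gapped
    rows = {"target": tgt, "template": tmpl}
    want_match = delta_matches > 0
    n = abs(delta_matches)
    cols = [
        i
        for i in range(len(tgt))
        if tgt[i] != "-" and tmpl[i] != "-" and ((tgt[i] == tmpl[i]) == want_match)
    ]
    picked = sorted(rng.choice(cols, size=min(n, len(cols)), replace=False), reverse=True)
    for c in picked:
        rows = _split_column(rows, int(c))
    return Alignment(
        entries=[
            AlignmentEntry("target", "target", rows["target"]),
            AlignmentEntry("template", "template", rows["template"]),
        ]
    )


def _degrade_coverage(aln: Alignment, fraction: float) -> Alignment:
    """Strip template support from the leading `fraction` of columns."""
    tgt, tmpl = aln.target.gapped, aln.templates[0].gapped
    k = int(len(tgt) * fraction)
    tmpl2 = "-" * k + tmpl[k:]
    return Alignment(
        entries=[
            AlignmentEntry("target", "target", tgt),
            AlignmentEntry("template", "template", tmpl2),
        ]
    )


def generate_benchmark(
    n_per_bin: int,
    seed: int,
    outdir: str | Path,
    length: int = 70,
    n_models: int = 10,
) -> pd.DataFrame:
    """Miniature benchmark collection with planted filter failures.

    For each decade bin in [20, 90), ``n_per_bin`` regular sets are produced
    (identity sampled inside the bin, coordinate noise growing as identity
    falls), plus planted failures with ground-truth labels: one low-coverage
    set, one bin-straddling set, and one template–target RMSD outlier per
    bin.  Returns the manifest (also written to ``manifest.tsv``); the
    ``label`` column holds ``ok`` / ``low_coverage`` / ``bin_straddle`` /
    ``rmsd_outlier``.
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    set_no = 0
    bins = list(range(20, 90, 10))
    low_cov_bin = bins[int(rng.integers(len(bins)))]
    straddle_bin = bins[int(rng.integers(len(bins)))]

    for lower in bins:
        sigma_bin = 0.4 + (80 - lower) / 60.0 * 1.8
        plans = [("ok", None)] * n_per_bin + [("rmsd_outlier", None)]
        if lower == low_cov_bin:
            plans.append(("low_coverage", None))
        if lower == straddle_bin:
            plans.append(("bin_straddle", None))
        for label, _ in plans:
            set_no += 1
            sid = f"set{set_no:03d}"
            identity = float(rng.uniform(lower + 4.0, lower + 8.0))
            sigma = sigma_bin * float(rng.uniform(0.7, 1.3))
            if label == "rmsd_outlier":
                sigma = 12.0
            spec = FixtureSpec(
                seed=int(rng.integers(2**31 - 1)),
                length=length,
                target_identity_pct=identity,
                coord_noise_sigma=sigma,
                terminal_deletions=(1, 1),
            )
            pair = generate_pair(spec)
            sdir = outdir / sid
            sdir.mkdir(exist_ok=True)
            (sdir / "target.pdb").write_text(pair.target_pdb)
            (sdir / "template.pdb").write_text(pair.template_pdb)

            row = {"set_id": sid, "bin": lower, "label": label,
                   "target": str(sdir / "target.pdb"),
                   "template": str(sdir / "template.pdb"),
                   "scores": str(sdir / "scores.tsv")}
            score_rows = []
            for i, aligner in enumerate(BENCH_ALIGNERS):
                delta = int(rng.integers(0, 3)) if i else 0
                var = _variant_alignment(pair.alignment, rng, delta)
                if label != "bin_straddle" or aligner != "tcoffee":
                    # aligner jitter must not move a regular set out of its bin
                    vid = compute_identity(var.target.gapped, var.templates[0].gapped)
                    if not lower <= vid < lower + 10:
                        var = pair.alignment
                if label == "low_coverage" and aligner == "muscle":
                    var = _degrade_coverage(var, 0.3)
                if label == "bin_straddle" and aligner == "tcoffee":
                    # push this aligner's identity below the bin's lower edge:
                    # removing m match columns from B both-non-gap columns
                    # takes identity I% to 100(IB/100 - m)/(B - m)
                    tg, tp = var.target.gapped, var.templates[0].gapped
                    B = sum(1 for a, b in zip(tg, tp) if a != "-" and b != "-")
                    cur = compute_identity(tg, tp)
                    t = lower - 2.0
                    need = int(math.ceil(B * (cur - t) / (100.0 - t))) + 1
                    var = _variant_alignment(var, rng, need)
                path = sdir / f"aln_{aligner}.fasta"
                path.write_text(f">target\n{var.target.gapped}\n>template\n{var.templates[0].gapped}\n")
                row[f"aln_{aligner}"] = str(path)

                # top "model": target coordinates re-noised per aligner
                mspec = FixtureSpec(
                    seed=int(rng.integers(2**31 - 1)),
                    length=length,
                    target_identity_pct=100.0,
                    coord_noise_sigma=max(sigma * 0.8, 0.3) if label != "rmsd_outlier" else 2.0,
                )
                mpair = generate_pair(mspec)
                mpath = sdir / f"model_{aligner}.pdb"
                mpath.write_text(mpair.template_pdb)
                row[f"model_{aligner}"] = str(mpath)

                mu = -2.5 + (80 - lower) / 60.0 * 2.2  # DOPE-Z-like level per bin
                for k in range(n_models):
                    score_rows.append(
                        {"aligner": aligner, "model": f"m{k + 1}",
                         "score": float(rng.normal(mu, 0.3))}
                    )
            pd.DataFrame(score_rows).to_csv(sdir / "scores.tsv", sep="\t", index=False)
            rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
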