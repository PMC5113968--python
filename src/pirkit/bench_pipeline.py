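"""Benchmark protocol: per-target modeling sets across five alignment
options, the three filters, top-model selection, and per-bin summaries.

A *set* is one target modeled from one template.  Each set carries five
aligner records (mafft, muscle, clustalo, tcoffee, and the search program's
own pairwise alignment), each with its recomputed identity, decade bin and
target coverage.  Sets pass through three filters, in order:

1. **bin consistency** — all five alignments must fall in the same identity
   bin (realigning with different programs shifts identity, and sets that
   straddle a bin edge are not comparable);
2. **coverage** — at least 80% of the target sequence modeled, for all five
   alignment options;
3. **RMSD outliers** — per bin, sets whose template–target RMSD exceeds the
   upper Tukey fence (Q3 + 1.5·IQR) are dropped, removing template–target
   combinations whose conformational difference makes RMSD meaningless as a
   modeling-accuracy yardstick.

Model quality scores (e.g. DOPE Z-scores) are supplied as a table, never
computed here; the minimum-score model is the top model, native-like when
its score is −1.0 or below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_ops import (
    Alignment,
    AlignmentEntry,
    BinKey,
    assign_bin,
    compute_coverage,
    compute_identity,
    read_alignment,
)
from .pir_builder import PirFile, build_pir
from .struct_compare import (
    CoordSet,
    ScoreSet,
    coords_from_structure,
    kabsch_superpose,
    pair_by_label,
    score_pair,
)
from .structure_io import StructureModel, extract_chain_sequence, parse_pdb

__all__ = [
    "AlignerRecord",
    "BenchmarkSet",
    "BinSummary",
    "ALIGNERS",
    "NATIVE_LIKE_CUTOFF",
    "bin_consistency_filter",
    "coverage_filter",
    "rmsd_outlier_filter",
    "run_filter_chain",
    "select_top_model",
    "remodel_control",
    "summarize_bins",
    "count_models",
    "run_benchmark",
]

ALIGNERS = ("mafft", "muscle", "clustalo", "tcoffee", "search_alignment")
NATIVE_LIKE_CUTOFF = -1.0


@dataclass
class AlignerRecord:
    aligner: str
    identity: float
    bin: BinKey | None
    coverage: float


@dataclass
class BenchmarkSet:
    """One (target, template) pair under the five alignment options."""

    target_id: str
    template_id: str
    aligner_records: dict[str, AlignerRecord]
    template_target_rmsd: float | None = None
    model_scores: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    filter_flags: dict[str, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def consensus_bin(self) -> BinKey | None:
        bins = {r.bin for r in self.aligner_records.values()}
        return bins.pop() if len(bins) == 1 else None


@dataclass
class BinSummary:
    bin: BinKey
    n_sets: int
    means: dict[str, dict[str, float]]  # aligner -> metric -> mean


def bin_consistency_filter(sets: list[BenchmarkSet]) -> list[BenchmarkSet]:
    """Keep sets whose five alignments all fall in the same (valid) bin."""
    out = []
    for s in sets:
        ok = s.consensus_bin is not None
        s.filter_flags["bin_consistency"] = ok
        if ok:
            out.append(s)
    return out


def coverage_filter(
    sets: list[BenchmarkSet], threshold: float = 80.0
) -> list[BenchmarkSet]:
    """Keep sets where at least `threshold`% of the target is modeled for all
    five alignment options (boundary-inclusive: exactly 80% passes)."""
    out = []
    for s in sets:
        ok = all(r.coverage >= threshold for r in s.aligner_records.values())
        s.filter_flags["coverage"] = ok
        if ok:
            out.append(s)
    return out


def rmsd_outlier_filter(
    sets: list[BenchmarkSet], rule: str = "tukey"
) -> list[BenchmarkSet]:
    """Drop, per bin, sets whose template–target RMSD exceeds the upper Tukey
    fence (Q3 + 1.5·IQR) of that bin.  Low RMSD is never suspect."""
    if rule != "tukey":
        raise ValueError(f"unknown outlier rule {rule!r}")
    by_bin: dict[BinKey, list[BenchmarkSet]] = {}
    for s in sets:
        b = s.consensus_bin
        if b is None:
            raise ValueError(f"set {s.target_id}/{s.template_id} has no consensus bin")
        if s.template_target_rmsd is None:
            raise ValueError(f"set {s.target_id}/{s.template_id} lacks template RMSD")
        by_bin.setdefault(b, []).append(s)
    out = []
    for b, members in by_bin.items():
        vals = np.array([s.template_target_rmsd for s in members])
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        for s in members:
            ok = s.template_target_rmsd <= fence
            s.filter_flags["rmsd_outlier"] = ok
            if ok:
                out.append(s)
    # restore input order
    order = {id(s): i for i, s in enumerate(sets)}
    out.sort(key=lambda s: order[id(s)])
    return out


def run_filter_chain(
    sets: list[BenchmarkSet],
    coverage_threshold: float = 80.0,
    outlier_rule: str = "tukey",
) -> list[BenchmarkSet]:
    """Bin consistency, then coverage, then per-bin RMSD outliers."""
    kept = bin_consistency_filter(sets)
    kept = coverage_filter(kept, coverage_threshold)
    kept = rmsd_outlier_filter(kept, outlier_rule)
    return kept


def select_top_model(
    model_scores: list[tuple[str, float]]
) -> tuple[str, bool]:
    """Minimum-score model and whether it is native-like (score ≤ −1.0).

    Ties break toward the earlier model in input order.
    """
    if not model_scores:
        raise ValueError("no scored models")
    best_id, best_score = model_scores[0]
    for mid, score in model_scores[1:]:
        if score < best_score:
            best_id, best_score = mid, score
    return best_id, best_score <= NATIVE_LIKE_CUTOFF


def remodel_control(target: StructureModel, chain: str = "A") -> PirFile:
    """PIR file modeling a target from its own structure (ideal conditions).

    The template entry is the target itself; the rows are identical except
    that missing residues render as '-' ('.' for modified) in the template
    entry, and the pairing's identity is 100%.
    """
    annotated = extract_chain_sequence(target, chain)
    plain = annotated.render("plain")
    name = target.pdb_id
    tgt_row = AlignmentEntry(f"{name}_target", "target", plain)
    tmpl_row = AlignmentEntry(name, "template", plain).with_status_from(annotated)
    aln = Alignment(entries=[tgt_row, tmpl_row])
    return build_pir(aln, models={name: target}, chains={name: chain})


def count_models(n_sets: int, n_aligners: int = 5, n_models_per_run: int = 10) -> int:
    """Bookkeeping identity: total models = sets × alignment options × models
    per run."""
    if min(n_sets, n_aligners, n_models_per_run) < 0:
        raise ValueError("counts must be non-negative")
    return n_sets * n_aligners * n_models_per_run


def summarize_bins(
    sets: list[BenchmarkSet],
    scores: dict[tuple[str, str], ScoreSet],
) -> list[BinSummary]:
    """Arithmetic means of the comparison scores (and the supplied quality
    score of the top model) per (bin, aligner); empty bins are omitted.

    ``scores`` maps (set target_id, aligner) to that aligner's top-model
    ScoreSet.
    """
    by_bin: dict[BinKey, list[BenchmarkSet]] = {}
    for s in sets:
        by_bin.setdefault(s.consensus_bin, []).append(s)
    out = []
    for b in sorted(by_bin, key=lambda k: k.lower):
        members = by_bin[b]
        means: dict[str, dict[str, float]] = {}
        for aligner in ALIGNERS:
            metrics: dict[str, list[float]] = {}
            for s in members:
                ss = scores.get((s.target_id, aligner))
                if ss is not None:
                    for k, v in ss.to_dict().items():
                        metrics.setdefault(k, []).append(v)
                if aligner in s.model_scores and s.model_scores[aligner]:
                    _, top = min(
                        enumerate(s.model_scores[aligner]), key=lambda kv: kv[1][1]
                    )
                    metrics.setdefault("top_model_score", []).append(top[1])
            if metrics:
                means[aligner] = {k: float(np.mean(v)) for k, v in metrics.items()}
        out.append(BinSummary(bin=b, n_sets=len(members), means=means))
    return out


# ---------------------------------------------------------------------------
# manifest-driven run

def _load_set(row: pd.Series, aligners: tuple[str, ...] = ALIGNERS) -> tuple[BenchmarkSet, dict]:
    target = parse_pdb(Path(row["target"]).read_text(), pdb_id=f"{row['set_id']}_t")
    template = parse_pdb(Path(row["template"]).read_text(), pdb_id=f"{row['set_id']}_m")
    records: dict[str, AlignerRecord] = {}
    for aligner in aligners:
        aln = read_alignment(Path(row[f"aln_{aligner}"]).read_text(), "target")
        ident = compute_identity(aln.target.gapped, aln.templates[0].gapped)
        records[aligner] = AlignerRecord(
            aligner=aligner,
            identity=ident,
            bin=assign_bin(ident),
            coverage=compute_coverage(aln),
        )
    t_coords = coords_from_structure(target, "A")
    m_coords = coords_from_structure(template, "A")
    a, b = pair_by_label(m_coords, t_coords)
    rmsd = kabsch_superpose(a, b).rmsd
    scores_df = pd.read_csv(row["scores"], sep="\t")
    model_scores = {
        aligner: [
            (r.model, float(r.score))
            for r in scores_df[scores_df.aligner == aligner].itertuples()
        ]
        for aligner in aligners
    }
    s = BenchmarkSet(
        target_id=str(row["set_id"]),
        template_id=str(row["set_id"]) + "_template",
        aligner_records=records,
        template_target_rmsd=rmsd,
        model_scores=model_scores,
        metadata=dict(row),
    )
    extras = {"target_coords": t_coords}
    return s, extras


def run_benchmark(
    manifest: pd.DataFrame | str | Path,
    outdir: str | Path | None = None,
    coverage_threshold: float = 80.0,
    outlier_rule: str = "tukey",
    compute_model_scores: bool = True,
) -> dict:
    """Load a benchmark manifest, apply the filter chain, score each
    surviving set's top model against its target, and summarize per bin.

    Returns a run report dict; when ``outdir`` is given, writes
    ``filtered_manifest.tsv``, ``bin_summary.tsv`` and ``report.json``.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    loaded = [_load_set(row) for _, row in manifest.iterrows()]
    sets = [s for s, _ in loaded]
    coords = {s.target_id: x["target_coords"] for s, x in loaded}

    kept = run_filter_chain(sets, coverage_threshold, outlier_rule)
    kept_ids = {s.target_id for s in kept}

    scores: dict[tuple[str, str], ScoreSet] = {}
    if compute_model_scores:
        for s in kept:
            row = s.metadata
            for aligner in ALIGNERS:
                model = parse_pdb(Path(row[f"model_{aligner}"]).read_text())
                mc = coords_from_structure(model, "A")
                scores[(s.target_id, aligner)] = score_pair(
                    mc, coords[s.target_id],
                    template_vs_target_rmsd=s.template_target_rmsd,
                )
    summaries = summarize_bins(kept, scores)

    report = {
        "n_input_sets": len(sets),
        "n_kept_sets": len(kept),
        "removed_set_ids": sorted(
            s.target_id for s in sets if s.target_id not in kept_ids
        ),
        "total_models": count_models(
            len(kept), len(ALIGNERS),
            int(pd.read_csv(manifest.iloc[0]["scores"], sep="\t")
                .groupby("aligner").size().iloc[0]) if len(manifest) else 10,
        ),
        "bins": [
            {
                "bin": str(b.bin),
                "n_sets": b.n_sets,
                "means": b.means,
            }
            for b in summaries
        ],
    }

    if outdir is not None:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest[manifest.set_id.isin(kept_ids)].to_csv(
            outdir / "filtered_manifest.tsv", sep="\t", index=False
        )
        rows = []
        for b in summaries:
            for aligner, metrics in b.means.items():
                rows.append({"bin": str(b.bin), "n_sets": b.n_sets, "aligner": aligner, **metrics})
        pd.DataFrame(rows).to_csv(outdir / "bin_summary.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
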