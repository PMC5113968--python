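"""Rigid-body superposition and model-quality scores.

Implements the four comparison scores used to benchmark comparative models
against their known reference structures:

* **RMSD** after least-squares (Kabsch/SVD) superposition, in Å;
* **TM-score** — length-normalized similarity in (0, 1], with the standard
  length-dependent distance scale d0(L) = 1.24·(L−15)^⅓ − 1.8 (floored at
  0.5 Å) and normalization by the reference length;
* **GDT-HA** — mean over the 0.5/1/2/4 Å thresholds of the maximal percentage
  of residues superposable under that threshold;
* **lDDT** — superposition-free fraction of reference interatomic distances
  (inclusion radius 15 Å, different residues) preserved within
  0.5/1/2/4 Å, averaged over the four thresholds.

TM and GDT require a search over superpositions; this module seeds the search
with sliding windows (full length, half length, and 7 residues) and refines
each seed by iterative reassignment of the fitted subset — the approach used
by the reference programs, documented as an approximation of them.

Residues are paired by alignment-derived labels, never by raw author
numbering across different proteins.  Default atom selection is CA-only for
RMSD/TM/GDT; lDDT accepts all heavy atoms or CA-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import MISSING, StructureModel

__all__ = [
    "CoordSet",
    "SuperpositionResult",
    "ScoreSet",
    "coords_from_structure",
    "pair_by_label",
    "kabsch_superpose",
    "tm_score",
    "gdt_ha",
    "lddt",
    "rmsd_diff",
    "longest_common_segment",
    "score_pair",
]

GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0


@dataclass
class CoordSet:
    """Ordered residue labels with one representative point each (CA)."""

    labels: list[str]
    points: np.ndarray  # (n, 3) float array, Å

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: list[int] | np.ndarray) -> "CoordSet":
        idx = np.asarray(idx, dtype=int)
        return CoordSet([self.labels[i] for i in idx], self.points[idx])


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class ScoreSet:
    """Model-vs-reference comparison scores."""

    rmsd: float
    tm: float
    gdt_ha: float
    lddt: float
    rmsd_diff: float | None = None

    def to_dict(self) -> dict:
        d = {"rmsd": self.rmsd, "tm": self.tm, "gdt_ha": self.gdt_ha, "lddt": self.lddt}
        if self.rmsd_diff is not None:
            d["rmsd_diff"] = self.rmsd_diff
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def coords_from_structure(
    model: StructureModel, chain: str, atom: str = "CA"
) -> CoordSet:
    """CA (or other named atom) coordinates of a chain's observed residues,
    labelled by author number + insertion code."""
    labels, pts = [], []
    for r in model.chain(chain):
        if r.status == MISSING:
            continue
        for name, x, y, z in r.atoms:
            if name == atom:
                labels.append(r.label)
                pts.append((x, y, z))
                break
    return CoordSet(labels, np.array(pts, dtype=float).reshape(-1, 3))


def pair_by_label(a: CoordSet, b: CoordSet) -> tuple[CoordSet, CoordSet]:
    """Restrict both sets to their common labels, in ``a``'s order."""
    b_index = {lab: i for i, lab in enumerate(b.labels)}
    common = [(i, b_index[lab]) for i, lab in enumerate(a.labels) if lab in b_index]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} common labels; need >= 3")
    ia, ib = zip(*common)
    return a.subset(list(ia)), b.subset(list(ib))


def kabsch_superpose(mobile: CoordSet, fixed: CoordSet) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed`` (SVD).

    Returns the proper rotation (det +1), translation, and minimized RMSD.
    """
    P, Q = mobile.points, fixed.points
    if len(P) != len(Q):
        raise ValueError("paired coordinate sets required")
    if len(P) < 3:
        raise ValueError("need >= 3 points for superposition")
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:  # rank < 2: all points collinear
        raise ValueError("degenerate (collinear) geometry; superposition ill-conditioned")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def _d0(L: int) -> float:
    return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5) if L > 15 else 0.5


def _seed_windows(n: int) -> list[tuple[int, int]]:
    """Sliding seed windows (start, length): full length, n/2, n/4, and the
    short lengths 7/5/4/3 that let the search lock onto small rigid cores."""
    windows: list[tuple[int, int]] = [(0, n)]
    for L in sorted({max(n // 2, 3), 7}, reverse=True):
        if 3 <= L < n:
            windows.extend((s, L) for s in range(0, n - L + 1))
    return windows


def _candidate_transforms(
    model: np.ndarray, ref: np.ndarray, cutoffs: tuple[float, ...], max_iter: int = 20
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Superposition candidates from window seeds plus iterative refinement.

    For each seed window and each distance cutoff, the fitted subset is
    iteratively reassigned to the residues within the cutoff until it
    stabilizes; every intermediate transform is kept as a candidate.
    """
    n = len(model)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for start, length in _seed_windows(n):
        idx0 = np.arange(start, start + length)
        try:
            R0, t0 = _kabsch(model[idx0], ref[idx0])
        except ValueError:
            continue
        out.append((R0, t0))
        for cutoff in cutoffs:
            idx, R, t = idx0, R0, t0
            for _ in range(max_iter):
                d = np.linalg.norm(model @ R.T + t - ref, axis=1)
                c = cutoff
                new_idx = np.flatnonzero(d < c)
                while len(new_idx) < 3:
                    c += 0.5
                    new_idx = np.flatnonzero(d < c)
                if np.array_equal(new_idx, idx):
                    break
                idx = new_idx
                try:
                    R, t = _kabsch(model[idx], ref[idx])
                except ValueError:
                    break
                out.append((R, t))
    return out


def tm_score(model: CoordSet, ref: CoordSet) -> float:
    """TM-score of ``model`` against ``ref`` (normalized by reference length).

    Maximized over superpositions from the window-seeded iterative search.
    """
    m, r = pair_by_label(model, ref)
    L_ref = len(ref)
    d0 = _d0(L_ref)
    best = 0.0
    for R, t in _candidate_transforms(m.points, r.points, (d0,)):
        d = np.linalg.norm(m.points @ R.T + t - r.points, axis=1)
        score = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_ref)
        best = max(best, score)
    return best


def gdt_ha(model: CoordSet, ref: CoordSet) -> float:
    """GDT-HA score in [0, 100]: mean over 0.5/1/2/4 Å of the maximal
    percentage of residue pairs fitting under that threshold."""
    m, r = pair_by_label(model, ref)
    n_ref = len(ref)
    best_counts = {thr: 0 for thr in GDT_HA_THRESHOLDS}
    for R, t in _candidate_transforms(m.points, r.points, GDT_HA_THRESHOLDS):
        d = np.linalg.norm(m.points @ R.T + t - r.points, axis=1)
        for thr in GDT_HA_THRESHOLDS:
            best_counts[thr] = max(best_counts[thr], int(np.sum(d <= thr)))
    return float(
        np.mean([100.0 * best_counts[thr] / n_ref for thr in GDT_HA_THRESHOLDS])
    )


def _atoms_by_residue(
    obj: StructureModel | CoordSet, chain: str | None, ca_only: bool
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Flatten to (atom keys, residue ids, coords) for lDDT pairing."""
    if isinstance(obj, CoordSet):
        keys = [f"{lab}:CA" for lab in obj.labels]
        resid = np.arange(len(obj))
        return keys, resid, obj.points
    keys, resid, pts = [], [], []
    chains = [chain] if chain else list(obj.chains)
    ridx = 0
    for ch in chains:
        for r in obj.chain(ch):
            if r.status == MISSING:
                continue
            for name, x, y, z in r.atoms:
                if name.startswith("H"):
                    continue
                if ca_only and name != "CA":
                    continue
                keys.append(f"{ch}/{r.label}:{name}")
                resid.append(ridx)
                pts.append((x, y, z))
            ridx += 1
    return keys, np.asarray(resid), np.asarray(pts, dtype=float).reshape(-1, 3)


def lddt(
    model: StructureModel | CoordSet,
    ref: StructureModel | CoordSet,
    chain: str | None = None,
    ca_only: bool = False,
) -> float:
    """Local distance difference test score in [0, 1] (superposition-free).

    Over all reference atom pairs from different residues within the 15 Å
    inclusion radius, the fraction of distances preserved in the model within
    each of 0.5/1/2/4 Å, averaged over the four thresholds.  Atoms are matched
    by residue label + atom name; pairs with either atom absent from the model
    count as not preserved.
    """
    rkeys, rresid, rpts = _atoms_by_residue(ref, chain, ca_only)
    mkeys, _, mpts = _atoms_by_residue(model, chain, ca_only)
    mmap = {k: i for i, k in enumerate(mkeys)}
    if len(rpts) < 2:
        raise ValueError("reference has too few atoms for lDDT")

    rd = cdist(rpts, rpts)
    iu, ju = np.triu_indices(len(rpts), k=1)
    mask = (rd[iu, ju] <= LDDT_INCLUSION_RADIUS) & (rresid[iu] != rresid[ju])
    iu, ju = iu[mask], ju[mask]
    if len(iu) == 0:
        raise ValueError("no qualifying atom pairs within the inclusion radius")

    ref_d = rd[iu, ju]
    # model distances where both atoms exist; else the pair is unpreserved
    mi = np.array([mmap.get(rkeys[i], -1) for i in iu])
    mj = np.array([mmap.get(rkeys[j], -1) for j in ju])
    have = (mi >= 0) & (mj >= 0)
    delta = np.full(len(iu), np.inf)
    if np.any(have):
        delta[have] = np.abs(
            np.linalg.norm(mpts[mi[have]] - mpts[mj[have]], axis=1) - ref_d[have]
        )
    fractions = [float(np.mean(delta <= thr)) for thr in LDDT_THRESHOLDS]
    return float(np.mean(fractions))


def rmsd_diff(model_vs_target: float, template_vs_target: float) -> float:
    """Model RMSD minus template RMSD against the same target (Å; may be
    negative when the model lands closer to the target than its template)."""
    if model_vs_target < 0 or template_vs_target < 0:
        raise ValueError("RMSD values must be non-negative")
    return model_vs_target - template_vs_target


def longest_common_segment(models: list[CoordSet]) -> list[CoordSet]:
    """Trim every model to the longest contiguous label run shared by all.

    Contiguity follows the first model's label order; ties break toward the
    earliest start.  Raises when no common run exists.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    common = set(models[0].labels)
    for m in models[1:]:
        common &= set(m.labels)
    if not common:
        raise ValueError("models share no labels")
    ref_labels = models[0].labels

    def _num(lab: str) -> int | None:
        try:
            return int(lab)
        except ValueError:
            return None

    def _consecutive(a: str, b: str) -> bool:
        na, nb = _num(a), _num(b)
        return na + 1 == nb if na is not None and nb is not None else True

    best: tuple[int, int] | None = None  # (start, length)
    start = None
    for i, lab in enumerate(ref_labels + [None]):
        breaks = (
            lab is None
            or lab not in common
            or (start is not None and i > start and not _consecutive(ref_labels[i - 1], lab))
        )
        if not breaks:
            if start is None:
                start = i
            continue
        if start is not None:
            length = i - start
            if best is None or length > best[1]:
                best = (start, length)
        start = i if (lab is not None and lab in common) else None
    run = ref_labels[best[0] : best[0] + best[1]]
    run_set = list(run)
    out = []
    for m in models:
        idx = [m.labels.index(lab) for lab in run_set]
        out.append(m.subset(idx))
    return out


def score_pair(
    model: CoordSet,
    ref: CoordSet,
    template_vs_target_rmsd: float | None = None,
) -> ScoreSet:
    """All four scores for one model/reference pair (CA representation)."""
    m, r = pair_by_label(model, ref)
    sup = kabsch_superpose(m, r)
    scores = ScoreSet(
        rmsd=sup.rmsd,
        tm=tm_score(model, ref),
        gdt_ha=gdt_ha(model, ref),
        lddt=lddt(model, ref),
    )
    if template_vs_target_rmsd is not None:
        scores.rmsd_diff = rmsd_diff(sup.rmsd, template_vs_target_rmsd)
    return scores
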