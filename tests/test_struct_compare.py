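"""Superposition and comparison scores against independent oracles.

Oracles implemented here, deliberately independent of the library code:

* Horn's closed-form quaternion method for optimal superposition RMSD;
* exhaustive 7-residue-window seed superpositions for TM/GDT on toy pairs;
* direct O(n²) recomputation of lDDT from its definition.
"""

import numpy as np
import pytest

from pirkit.fixtures import FixtureSpec, generate_pair
from pirkit.struct_compare import (
    CoordSet,
    coords_from_structure,
    gdt_ha,
    kabsch_superpose,
    lddt,
    longest_common_segment,
    pair_by_label,
    rmsd_diff,
    score_pair,
    tm_score,
)
from pirkit.structure_io import parse_pdb


# ---------------------------------------------------------------------------
# oracles

def horn_quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = (P[:, 0] * Q[:, 0]).sum(), (P[:, 0] * Q[:, 1]).sum(), (P[:, 0] * Q[:, 2]).sum()
    Syx, Syy, Syz = (P[:, 1] * Q[:, 0]).sum(), (P[:, 1] * Q[:, 1]).sum(), (P[:, 1] * Q[:, 2]).sum()
    Szx, Szy, Szz = (P[:, 2] * Q[:, 0]).sum(), (P[:, 2] * Q[:, 1]).sum(), (P[:, 2] * Q[:, 2]).sum()
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(N)[-1]
    e2 = (P**2).sum() + (Q**2).sum() - 2.0 * lam
    return float(np.sqrt(max(e2, 0.0) / len(P)))


def _fit(P: np.ndarray, Q: np.ndarray):
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    U, S, Vt = np.linalg.svd((P - pc).T @ (Q - qc))
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def window_seed_transforms(model: np.ndarray, ref: np.ndarray, cutoff: float):
    """Superpositions from every 7- and half-length window (plus full
    length), each refined by iterative reassignment of the residues within
    ``cutoff`` — a direct, loop-level re-implementation of the published
    window-seeded search, independent of the library code."""
    n = len(model)
    wins = [(0, n)]
    for L in (max(n // 2, 3), 7):
        wins += [(s, L) for s in range(0, n - L + 1)]
    for s, L in wins:
        idx = np.arange(s, s + L)
        R, t = _fit(model[idx], ref[idx])
        yield R, t
        for _ in range(50):
            d = np.linalg.norm(model @ R.T + t - ref, axis=1)
            c = cutoff
            new = np.flatnonzero(d < c)
            while len(new) < 3:
                c += 0.5
                new = np.flatnonzero(d < c)
            if np.array_equal(new, idx):
                break
            idx = new
            R, t = _fit(model[idx], ref[idx])
            yield R, t


def oracle_tm(model: np.ndarray, ref: np.ndarray) -> float:
    L = len(ref)
    d0 = max(1.24 * (L - 15) ** (1 / 3) - 1.8, 0.5) if L > 15 else 0.5
    best = 0.0
    for R, t in window_seed_transforms(model, ref, d0):
        d = np.linalg.norm(model @ R.T + t - ref, axis=1)
        best = max(best, float(np.sum(1 / (1 + (d / d0) ** 2)) / L))
    return best


def oracle_gdt_ha(model: np.ndarray, ref: np.ndarray) -> float:
    counts = {thr: 0 for thr in (0.5, 1.0, 2.0, 4.0)}
    pool = [
        (R, t)
        for cutoff in counts
        for R, t in window_seed_transforms(model, ref, cutoff)
    ]
    for R, t in pool:
        d = np.linalg.norm(model @ R.T + t - ref, axis=1)
        for thr in counts:
            counts[thr] = max(counts[thr], int((d <= thr).sum()))
    return float(np.mean([100 * c / len(ref) for c in counts.values()]))


def oracle_lddt_ca(model: CoordSet, ref: CoordSet) -> float:
    """Direct per-pair recomputation of CA-only lDDT (the definition)."""
    fractions = []
    for thr in (0.5, 1.0, 2.0, 4.0):
        kept = total = 0
        for i in range(len(ref)):
            for j in range(i + 1, len(ref)):
                dref = np.linalg.norm(ref.points[i] - ref.points[j])
                if dref > 15.0:
                    continue
                total += 1
                dmod = np.linalg.norm(model.points[i] - model.points[j])
                if abs(dmod - dref) <= thr:
                    kept += 1
        fractions.append(kept / total)
    return float(np.mean(fractions))


def _noisy_pair(seed, n=30, sigma=1.0):
    rng = np.random.default_rng(seed)
    ref = rng.normal(scale=8.0, size=(n, 3))
    model = ref + rng.normal(scale=sigma, size=(n, 3))
    labels = [str(i) for i in range(n)]
    return CoordSet(labels, model), CoordSet(labels, ref)


def _helix_coordsets(seed, n=40, sigma=1.0):
    spec = FixtureSpec(seed=seed, length=n, coord_noise_sigma=sigma)
    pair = generate_pair(spec)
    ref = coords_from_structure(parse_pdb(pair.target_pdb), "A")
    model = coords_from_structure(parse_pdb(pair.template_pdb), "A")
    return model, ref


# ---------------------------------------------------------------------------
# tests

class TestPairByLabel:
    def test_identical_sets_full_pairing(self):
        a, _ = _noisy_pair(0, n=10)
        pa, pb = pair_by_label(a, a)
        assert pa.labels == pb.labels == a.labels

    def test_disjoint_raises(self):
        a, _ = _noisy_pair(0, n=5)
        b = CoordSet([f"z{i}" for i in range(5)], a.points)
        with pytest.raises(ValueError):
            pair_by_label(a, b)

    def test_partial_overlap(self):
        a, _ = _noisy_pair(0, n=10)
        b = CoordSet(a.labels[5:] + ["x1", "x2"], np.vstack([a.points[5:], a.points[:2]]))
        pa, pb = pair_by_label(a, b)
        assert len(pa) == len(pb) == 5


class TestKabsch:
    def test_identical_points(self):
        a, _ = _noisy_pair(1, n=12)
        res = kabsch_superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_transform_gives_zero_rmsd(self):
        a, _ = _noisy_pair(2, n=12)
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = CoordSet(a.labels, a.points @ Q.T + np.array([1.0, -2.0, 3.0]))
        assert kabsch_superpose(moved, a).rmsd == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(scale=5.0, size=(10, 3))
        Q = rng.normal(scale=5.0, size=(10, 3))
        labels = [str(i) for i in range(10)]
        ours = kabsch_superpose(CoordSet(labels, P), CoordSet(labels, Q)).rmsd
        assert ours == pytest.approx(horn_quaternion_rmsd(P, Q), abs=1e-6)

    def test_rotation_is_proper(self):
        a, b = _noisy_pair(4, n=15, sigma=2.0)
        res = kabsch_superpose(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_collinear_raises(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        a = CoordSet(list("abcde"), pts)
        with pytest.raises(ValueError):
            kabsch_superpose(a, a)

    def test_superposed_rmsd_never_exceeds_raw(self):
        for seed in range(5):
            a, b = _noisy_pair(seed, n=20, sigma=3.0)
            raw = float(np.sqrt(np.mean(np.sum((a.points - b.points) ** 2, axis=1))))
            assert kabsch_superpose(a, b).rmsd <= raw + 1e-9


class TestScoresSelfAndOracles:
    def test_self_comparison_perfect_scores(self):
        model, ref = _helix_coordsets(5, n=35, sigma=0.0)
        ss = score_pair(model, ref)
        assert ss.rmsd == pytest.approx(0.0, abs=1e-8)
        assert ss.tm == pytest.approx(1.0, abs=1e-9)
        assert ss.gdt_ha == pytest.approx(100.0)
        assert ss.lddt == pytest.approx(1.0)

    def test_tm_noise_monotonicity(self):
        m1, ref = _helix_coordsets(6, n=40, sigma=0.5)
        m2, _ = _helix_coordsets(6, n=40, sigma=5.0)
        assert tm_score(m2, ref) < tm_score(m1, ref)

    @pytest.mark.parametrize("seed", range(8))
    def test_tm_and_gdt_match_exhaustive_seed_oracle(self, seed):
        model, ref = _helix_coordsets(seed, n=30, sigma=1.5)
        m, r = pair_by_label(model, ref)
        tm_o = oracle_tm(m.points, r.points)
        gdt_o = oracle_gdt_ha(m.points, r.points)
        tm_i = tm_score(model, ref)
        gdt_i = gdt_ha(model, ref)
        assert abs(tm_i - tm_o) <= 0.01
        assert abs(gdt_i - gdt_o) <= 1.0

    def test_gdt_rigid_displacement_scores_100(self):
        _, ref = _helix_coordsets(9, n=30, sigma=0.0)
        moved = CoordSet(ref.labels, ref.points + np.array([10.0, 0.0, 0.0]))
        assert gdt_ha(moved, ref) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_lddt_matches_brute_force(self, seed):
        model, ref = _noisy_pair(seed, n=10, sigma=1.0)
        assert lddt(model, ref) == pytest.approx(oracle_lddt_ca(model, ref), abs=1e-12)

    def test_lddt_invariant_under_independent_rigid_motion(self):
        model, ref = _noisy_pair(7, n=15, sigma=1.0)
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = CoordSet(model.labels, model.points @ Q.T + np.array([20.0, 1.0, 2.0]))
        assert lddt(moved, ref) == pytest.approx(lddt(model, ref))

    def test_lddt_all_heavy_atoms_on_structures(self):
        spec = FixtureSpec(seed=12, length=25, coord_noise_sigma=0.0)
        pair = generate_pair(spec)
        t = parse_pdb(pair.target_pdb)
        assert lddt(t, t) == pytest.approx(1.0)


class TestRmsdDiff:
    @pytest.mark.parametrize(
        "m,t,expected", [(2.5, 1.0, 1.5), (3.3, 3.3, 0.0), (1.0, 2.0, -1.0)]
    )
    def test_arithmetic(self, m, t, expected):
        assert rmsd_diff(m, t) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rmsd_diff(-1.0, 0.5)


class TestLongestCommonSegment:
    def _cs(self, labels):
        return CoordSet(list(labels), np.arange(len(labels) * 3, dtype=float).reshape(-1, 3))

    def test_identical_models_unchanged(self):
        a = self._cs([str(i) for i in range(10)])
        out = longest_common_segment([a, a])
        assert out[0].labels == a.labels

    def test_nested_spans_trim_to_intersection(self):
        a = self._cs([str(i) for i in range(1, 101)])
        b = self._cs([str(i) for i in range(5, 91)])
        out = longest_common_segment([a, b])
        assert out[0].labels[0] == "5" and out[0].labels[-1] == "90"
        assert out[0].labels == out[1].labels

    def test_longest_run_wins(self):
        a = self._cs([str(i) for i in range(1, 11)] + [str(i) for i in range(20, 31)])
        b = self._cs([str(i) for i in range(1, 11)] + [str(i) for i in range(20, 26)])
        out = longest_common_segment([a, b])
        assert out[0].labels == [str(i) for i in range(1, 11)]

    def test_no_common_labels_raises(self):
        with pytest.raises(ValueError):
            longest_common_segment([self._cs("abc"), self._cs("xyz")])


class TestMonotoneDegradation:
    def test_mean_scores_degrade_with_noise(self):
        """Mean RMSD strictly rises, TM/GDT-HA/lDDT strictly fall with σ."""
        sigmas = (0.5, 1.0, 2.0, 4.0)
        means = {"rmsd": [], "tm": [], "gdt_ha": [], "lddt": []}
        for sigma in sigmas:
            vals = {k: [] for k in means}
            for seed in range(20):
                model, ref = _helix_coordsets(100 + seed, n=40, sigma=sigma)
                ss = score_pair(model, ref)
                for k in vals:
                    vals[k].append(getattr(ss, k))
            for k in means:
                means[k].append(np.mean(vals[k]))
        assert all(np.diff(means["rmsd"]) > 0)
        for k in ("tm", "gdt_ha", "lddt"):
            assert all(np.diff(means[k]) < 0)
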