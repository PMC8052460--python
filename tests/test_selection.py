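"""EHH/iHS/XP-EHH scans, PCA-outlier scan, q-values and sweep consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tetrasnp.io import DosageMatrix, MarkerMap
from tetrasnp.selection import (
    HaplotypePanel,
    SweepRegion,
    consensus_sweeps,
    ehh,
    genes_near,
    ihs_scan,
    pca_outlier_scan,
    storey_qvalues,
    xpehh_scan,
)
from tetrasnp.simulate import SimConfig, simulate_sweep_pair, simulate_sweep_panel


def ehh_pair_counting_oracle(alleles, positions, focal, allele):
    """Shared-prefix pair counting: EHH at each marker and trapezoid iES."""
    if allele is None:
        carriers = list(range(alleles.shape[0]))
    else:
        carriers = [h for h in range(alleles.shape[0]) if alleles[h, focal] == allele]
    n = len(carriers)
    pairs = list(itertools.combinations(carriers, 2))
    focal_val = sum(1 for a, b in pairs if alleles[a, focal] == alleles[b, focal]) / len(pairs)
    xs, ys = [positions[focal]], [focal_val]
    for direction in (-1, 1):
        k = focal
        while True:
            k += direction
            if k < 0 or k >= alleles.shape[1]:
                break
            lo, hi = min(focal, k), max(focal, k)
            same = sum(
                1 for a, b in pairs if np.array_equal(alleles[a, lo : hi + 1], alleles[b, lo : hi + 1])
            )
            val = same / len(pairs)
            xs.append(positions[k])
            ys.append(val)
            if val < 0.05:
                break
    order = np.argsort(xs)
    return np.trapezoid(np.array(ys)[order], np.array(xs)[order])


def tiny_panel(seed=0, H=8, m=20):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, 10_000), size=m, replace=False))
    mmap = MarkerMap(
        pd.DataFrame({"marker_id": [f"m{i}" for i in range(m)], "chrom": 1, "pos": pos})
    )
    A = rng.integers(0, 2, size=(H, m)).astype(np.int8)
    A[: H // 2, m // 2] = 1  # guarantee both alleles at the middle marker
    A[H // 2 :, m // 2] = 0
    return HaplotypePanel([f"h{i}" for i in range(H)], A, mmap)


class TestEhh:
    def test_focal_value_is_one(self):
        panel = tiny_panel()
        curve, _ = ehh(panel, panel.n_markers // 2, allele=1)
        assert curve.loc[curve["side"] == "focal", "ehh"].iloc[0] == 1.0

    def test_identical_haplotypes_ehh_stays_one(self):
        m = 12
        mmap = MarkerMap(
            pd.DataFrame(
                {"marker_id": [f"m{i}" for i in range(m)], "chrom": 1, "pos": np.arange(1, m + 1) * 100}
            )
        )
        A = np.tile(np.arange(m) % 2, (6, 1)).astype(np.int8)
        panel = HaplotypePanel([f"h{i}" for i in range(6)], A, mmap)
        curve, _ = ehh(panel, 6, allele=0)
        assert (curve["ehh"] == 1.0).all()
        assert len(curve) == m  # extends to both chromosome ends

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("allele", [0, 1, None])
    def test_matches_pair_counting_oracle(self, seed, allele):
        panel = tiny_panel(seed=seed, H=10, m=24)
        focal = panel.n_markers // 2
        _, ies = ehh(panel, focal, allele=allele)
        pos = panel.marker_map.table["pos"].to_numpy()
        expected = ehh_pair_counting_oracle(panel.alleles, pos, focal, allele)
        assert ies == pytest.approx(expected)

    def test_single_carrier_rejected(self):
        panel = tiny_panel()
        A = panel.alleles.copy()
        A[:, 3] = 0
        A[0, 3] = 1
        panel2 = HaplotypePanel(panel.hap_ids, A, panel.marker_map)
        with pytest.raises(ValueError):
            ehh(panel2, 3, allele=1)

    def test_ehh_nonincreasing_with_distance(self):
        panel = tiny_panel(seed=5, H=16, m=40)
        curve, _ = ehh(panel, 20, allele=None)
        for side in ("left", "right"):
            vals = curve.loc[curve["side"] == side, "ehh"].to_numpy()
            ordered = vals if side == "right" else vals[::-1]
            assert (np.diff(ordered) <= 1e-12).all()

    def test_ies_invariant_to_row_order(self):
        panel = tiny_panel(seed=6, H=12, m=30)
        perm = np.random.default_rng(1).permutation(12)
        shuffled = HaplotypePanel(
            [panel.hap_ids[i] for i in perm], panel.alleles[perm], panel.marker_map
        )
        _, ies1 = ehh(panel, 15, allele=None)
        _, ies2 = ehh(shuffled, 15, allele=None)
        assert ies1 == pytest.approx(ies2)


class TestIhs:
    def test_symmetric_structure_gives_zero(self):
        # ancestral and derived carriers with mirror-identical haplotypes
        m = 11
        mmap = MarkerMap(
            pd.DataFrame(
                {"marker_id": [f"m{i}" for i in range(m)], "chrom": 1, "pos": np.arange(1, m + 1) * 50}
            )
        )
        block = np.array([[0, 1] * 6, [1, 0] * 6])[:, :m]
        A = np.vstack([block, block]).astype(np.int8)
        A[:2, 5] = 1
        A[2:, 5] = 0
        panel = HaplotypePanel([f"h{i}" for i in range(4)], A, mmap)
        _, ies_a = ehh(panel, 5, allele=0)
        _, ies_d = ehh(panel, 5, allele=1)
        assert np.log(ies_a / ies_d) == pytest.approx(0.0, abs=1e-12)

    def test_bin_standardization_moments(self):
        panel, _ = simulate_sweep_panel(SimConfig(seed=3, n_haplotypes=60, sweep_m_markers=200))
        res = ihs_scan(panel, bins=10, min_bin=20)
        t = res.table.dropna(subset=["z"])
        freq = panel.alleles.mean(axis=0)
        # overall moments near standard after per-bin standardization
        assert abs(t["z"].mean()) < 0.15
        assert t["z"].std() == pytest.approx(1.0, abs=0.1)

    def test_sweep_region_in_top_percentile(self):
        hits = 0
        reps = 5
        for r in range(reps):
            cfg = SimConfig(seed=300 + r)
            panel, truth = simulate_sweep_panel(cfg)
            res = ihs_scan(panel)
            t = res.table
            pos = t["pos"].to_numpy()
            locus_pos = t.set_index("marker_id").loc[truth.sweep_markers[0], "pos"]
            window = np.abs(pos - locus_pos) <= cfg.sweep_decay_bp
            z = np.abs(t["z"].to_numpy())
            hits += np.nanmax(z[window]) >= np.nanquantile(z, 0.99)
        assert hits >= 4


class TestXpehh:
    def test_identical_panels_give_zero_scores(self):
        panel = tiny_panel(seed=9, H=12, m=25)
        res = xpehh_scan(panel, panel)
        np.testing.assert_allclose(res.table["raw"].dropna(), 0.0, atol=1e-12)

    def test_antisymmetry_under_panel_swap(self):
        cfg = SimConfig(seed=12, n_haplotypes=40, sweep_m_markers=120)
        A, B, _ = simulate_sweep_pair(cfg)
        r1 = xpehh_scan(A, B)
        r2 = xpehh_scan(B, A)
        np.testing.assert_allclose(r1.table["raw"], -r2.table["raw"], atol=1e-12)

    def test_sweep_in_a_positive_top_score(self):
        cfg = SimConfig(seed=13)
        A, B, truth = simulate_sweep_pair(cfg)
        res = xpehh_scan(A, B)
        t = res.table
        locus_pos = t.set_index("marker_id").loc[truth.sweep_markers[0], "pos"]
        window = np.abs(t["pos"].to_numpy() - locus_pos) <= cfg.sweep_decay_bp
        zw = t["z"].to_numpy()[window]
        assert np.nanmax(zw) > 0
        assert np.nanmax(np.abs(zw)) >= np.nanquantile(np.abs(t["z"].to_numpy()), 0.99)

    def test_too_few_haplotypes_rejected(self):
        panel = tiny_panel(H=8)
        small = HaplotypePanel(panel.hap_ids[:3], panel.alleles[:3], panel.marker_map)
        with pytest.raises(ValueError):
            xpehh_scan(small, panel)


class TestPcaOutlier:
    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(71)
        p = rng.uniform(0.1, 0.5, 2000)
        X = rng.binomial(4, p, size=(200, 2000)).astype(float)
        D = DosageMatrix([f"c{i}" for i in range(200)], [f"m{j}" for j in range(2000)], X)
        res = pca_outlier_scan(D, K=3)
        assert 0.8 <= res.lambda_gc <= 1.2

    def test_planted_outliers_detected(self):
        from tetrasnp.simulate import simulate_structured_population

        cfg = SimConfig(n_per_pop=(50, 50), m_markers=2000, fst=(0.02, 0.02), seed=72, missing_rate=0)
        D, _, _, truth = simulate_structured_population(cfg)
        rng = np.random.default_rng(73)
        X = D.dosage.copy()
        groups = np.array([truth.subpopulation[c] for c in D.clone_ids])
        planted = rng.choice(2000, 20, replace=False)
        for j in planted:  # strong group differentiation at planted markers
            X[groups == 0, j] = rng.binomial(4, 0.05, size=(groups == 0).sum())
            X[groups == 1, j] = rng.binomial(4, 0.75, size=(groups == 1).sum())
        D2 = DosageMatrix(D.clone_ids, D.marker_ids, X)
        res = pca_outlier_scan(D2, K=2)
        q = res.table["q"].to_numpy()
        assert np.mean(q[planted] < 0.05) >= 0.8

    def test_k_too_large_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            pca_outlier_scan(toy_matrix, K=4)


class TestStoreyQvalues:
    def test_single_pvalue_identity(self):
        q, pi0 = storey_qvalues(np.array([0.001]))
        assert pi0 == 1.0
        assert q[0] == pytest.approx(0.001)

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(81)
        q, pi0 = storey_qvalues(rng.uniform(0, 1, 10_000))
        assert 0.9 <= pi0 <= 1.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_monotone_in_p(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.beta(0.3, 5, 200), rng.uniform(0, 1, 800)])
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([]))
        with pytest.raises(ValueError):
            storey_qvalues(np.array([1.2]))


def _fake_result(method, marker_ids, chrom, pos, sig_idx):
    m = len(marker_ids)
    q = np.full(m, 0.5)
    q[list(sig_idx)] = 1e-4
    z = np.where(q < 0.05, 5.0, 0.1)
    table = pd.DataFrame(
        {"marker_id": marker_ids, "chrom": chrom, "pos": pos, "raw": z, "z": z, "p": q, "q": q}
    )
    from tetrasnp.selection import ScanResult

    return ScanResult(method, table)


class TestConsensus:
    def setup_method(self):
        self.ids = [f"m{i}" for i in range(10)]
        self.pos = np.arange(1, 11) * 1_000_000
        self.chrom = np.ones(10, dtype=int)

    def test_single_method_significance_no_region(self):
        r1 = _fake_result("ihs", self.ids, self.chrom, self.pos, {3})
        r2 = _fake_result("xpehh", self.ids, self.chrom, self.pos, set())
        assert consensus_sweeps([r1, r2]) == []

    def test_two_method_marker_centers_region(self):
        r1 = _fake_result("ihs", self.ids, self.chrom, self.pos, {4})
        r2 = _fake_result("xpehh", self.ids, self.chrom, self.pos, {4})
        regions = consensus_sweeps([r1, r2])
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.start, reg.end) == (self.pos[4] - 250_000, self.pos[4] + 250_000)
        assert reg.end - reg.start == 500_000
        assert set(reg.methods) == {"ihs", "xpehh"}

    def test_overlapping_regions_not_merged(self):
        r1 = _fake_result("ihs", self.ids, self.chrom, self.pos, {4, 5})
        r2 = _fake_result("xpehh", self.ids, self.chrom, self.pos, {4, 5})
        regions = consensus_sweeps([r1, r2])
        assert len(regions) == 2

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        from tetrasnp.selection import ScanResult

        results = []
        for method in ("ihs", "xpehh"):
            q = rng.uniform(0, 0.2, 10)
            table = pd.DataFrame(
                {
                    "marker_id": self.ids,
                    "chrom": self.chrom,
                    "pos": self.pos,
                    "raw": q,
                    "z": q,
                    "p": q,
                    "q": q,
                }
            )
            results.append(ScanResult(method, table))
        counts = [
            len(consensus_sweeps(results, q_thresholds={"ihs": t, "xpehh": t}))
            for t in (0.2, 0.1, 0.05, 0.01)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_fewer_than_two_results_rejected(self):
        r1 = _fake_result("ihs", self.ids, self.chrom, self.pos, set())
        with pytest.raises(ValueError):
            consensus_sweeps([r1])


GFF_HEADER = "##gff-version 3\n"


class TestGenesNear:
    def write_gff(self, tmp_path, genes):
        lines = [GFF_HEADER]
        for gid, chrom, start, end in genes:
            lines.append(
                f"{chrom}\ttest\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n"
            )
        path = tmp_path / "genes.gff3"
        path.write_text("".join(lines))
        return str(path)

    def test_gene_inside_and_boundary(self, tmp_path):
        region = SweepRegion(chrom=1, start=1_000_000, end=1_500_000, top_snp="s")
        genes = [
            ("inside", "chr1", 1_100_000, 1_200_000),
            ("at_left_pad_edge", "chr1", 700_000, 750_000),  # ends exactly at start - 250 kb
            ("beyond", "chr1", 100_000, 749_999),
            ("other_chrom", "chr2", 1_100_000, 1_200_000),
        ]
        found = genes_near(region, self.write_gff(tmp_path, genes))
        assert "inside" in found
        assert "at_left_pad_edge" in found
        assert "beyond" not in found
        assert "other_chrom" not in found

    def test_matches_bruteforce_interval_oracle(self, tmp_path):
        rng = np.random.default_rng(55)
        genes = []
        for i in range(30):
            start = int(rng.integers(1, 5_000_000))
            genes.append((f"g{i}", "chr3", start, start + int(rng.integers(100, 50_000))))
        region = SweepRegion(chrom=3, start=2_000_000, end=2_500_000, top_snp="s")
        found = set(genes_near(region, self.write_gff(tmp_path, genes)))
        lo, hi = region.start - 250_000, region.end + 250_000
        expected = {g for g, _, s, e in genes if e >= lo and s <= hi}
        assert found == expected

    def test_chromosome_mismatch_raises(self, tmp_path):
        region = SweepRegion(chrom=7, start=100, end=200, top_snp="s")
        path = self.write_gff(tmp_path, [("g", "scaffold_12", 50, 150)])
        with pytest.raises(ValueError, match="chromosome"):
            genes_near(region, path)
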