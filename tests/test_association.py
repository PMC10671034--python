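import numpy as np
import pandas as pd
import pytest

from qtlallele.association import (
    ScanSettings,
    classify_contribution,
    name_qtl,
    stage1_scan,
    stage2_stepwise,
    two_stage_scan,
)
from qtlallele.simulate import SimulationConfig, simulate_population
from qtlallele.snpldb import (
    build_blocks,
    qc_filter,
    similarity_matrix,
    structure_covariates,
)


def make_marker(allele_index, chrom=1, start=1000, mid=None, alleles=None):
    from qtlallele.snpldb import SnpldbMarker

    allele_index = np.asarray(allele_index, dtype=np.int32)
    n_all = allele_index.max() + 1
    alleles = alleles or [f"h{k}" for k in range(n_all)]
    freqs = np.bincount(allele_index, minlength=n_all) / allele_index.size
    return SnpldbMarker(
        id=mid or f"m_{chrom}_{start}",
        chrom=chrom,
        start=start,
        end=start,
        snp_ids=[f"s_{chrom}_{start}"],
        alleles=alleles,
        frequencies=freqs,
        allele_index=allele_index,
    )


def phen_table(values, accessions, envs=("E1",)):
    rows = []
    for j, env in enumerate(envs):
        for a, v in zip(accessions, np.atleast_2d(values)[min(j, 0)]):
            rows.append({"accession": a, "environment": env, "replicate": 1, "value": v})
    return pd.DataFrame(rows)


class TestStage1:
    def test_perfect_marker_retained_with_tiny_p(self):
        rng = np.random.default_rng(0)
        n = 100
        accs = [f"a{i}" for i in range(n)]
        split = np.array([0] * 50 + [1] * 50)
        y = 40 + 10 * split + rng.normal(0, 0.5, n)
        marker = make_marker(split)
        out = stage1_scan([marker], phen_table(y, accs), accs)
        assert out.loc[0, "p"] < 1e-6
        assert out.loc[0, "preselected"]

    def test_constant_phenotype_retains_nothing(self):
        n = 60
        accs = [f"a{i}" for i in range(n)]
        marker = make_marker(np.arange(n) % 2)
        out = stage1_scan([marker], phen_table(np.full(n, 5.0), accs), accs)
        assert not out["preselected"].any()

    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(123)
        n = 200
        accs = [f"a{i}" for i in range(n)]
        markers = [
            make_marker(rng.integers(0, 2, n), start=1000 + i, mid=f"m{i}")
            for i in range(300)
        ]
        y = rng.normal(50, 5, n)
        out = stage1_scan(markers, phen_table(y, accs), accs)
        frac = out["preselected"].mean()
        # binomial(300, 0.05): 3 sigma ~ 0.05 +/- 0.038
        assert 0.01 <= frac <= 0.10

    def test_single_allele_marker_skipped(self):
        n = 40
        accs = [f"a{i}" for i in range(n)]
        marker = make_marker(np.zeros(n, dtype=int), alleles=["h0", "h1"])
        out = stage1_scan([marker], phen_table(np.random.default_rng(1).normal(size=n), accs), accs)
        assert out.empty


class TestStage2:
    def test_two_planted_qtls_recovered(self):
        cfg = SimulationConfig(
            n_accessions=400, n_true_qtls=2, effect_scale=4.0,
            heritability_target=0.8, master_seed=21,
        )
        g, ph, truth = simulate_population(cfg)
        f, _ = qc_filter(g)
        markers = build_blocks(f)
        cov = structure_covariates(similarity_matrix(markers), 10)
        res = two_stage_scan(
            markers, ph, f.accessions, cov,
            ScanSettings(heritability_cap=truth.realized_h2),
        )
        main = [q for q in res.qtls if q.has_main]
        hits = sum(
            any(q.chrom == c and abs(q.start - p) <= 300_000 for q in main)
            for c, p in truth.qtl_positions
        )
        assert hits == 2
        assert len(main) - hits <= 1

    def test_duplicate_markers_enter_once(self):
        rng = np.random.default_rng(3)
        n = 120
        accs = [f"a{i}" for i in range(n)]
        split = rng.integers(0, 2, n)
        y = 40 + 8 * split + rng.normal(0, 1, n)
        m1 = make_marker(split, start=1000, mid="dup1")
        m2 = make_marker(split, start=2000, mid="dup2")
        res = stage2_stepwise([m1, m2], phen_table(y, accs), accs,
                              settings=ScanSettings(correction="none"))
        assert len(res.qtls) == 1
        assert res.qtls[0].marker_id == "dup1"  # tie broken by position

    def test_retained_loci_satisfy_removal_threshold(self, small_scan):
        res, _, _ = small_scan
        for q in res.qtls:
            p = q.main_neglog10p if q.has_main else q.qei_neglog10p
            # -log10 p of a retained term must clear the Bonferroni threshold
            assert p >= -np.log10(0.05)

    def test_empty_preselection_raises(self):
        with pytest.raises(ValueError):
            stage2_stepwise([], pd.DataFrame(), [])


class TestAlleleEffects:
    def test_balanced_biallelic_effects(self):
        n = 80
        accs = [f"a{i}" for i in range(n)]
        split = np.array([0, 1] * 40)
        y = 50.0 + np.where(split == 1, 5.0, -5.0)
        marker = make_marker(split)
        res = stage2_stepwise([marker], phen_table(y, accs), accs,
                              settings=ScanSettings(correction="none"))
        eff = res.qtls[0].allele_effects
        np.testing.assert_allclose(sorted(eff), [-5.0, 5.0], atol=1e-8)

    def test_three_allele_effects_match_normal_equations(self):
        rng = np.random.default_rng(8)
        n = 150
        accs = [f"a{i}" for i in range(n)]
        alleles = rng.integers(0, 3, n)
        group_means = np.array([35.0, 50.0, 58.0])
        y = group_means[alleles]
        marker = make_marker(alleles)
        res = stage2_stepwise([marker], phen_table(y, accs), accs,
                              settings=ScanSettings(correction="none"))
        eff = res.qtls[0].allele_effects
        # oracle: direct least squares on the saturated one-way model gives
        # the group means; sum-to-zero effects are means minus their average
        oracle = group_means - group_means.mean()
        np.testing.assert_allclose(np.sort(eff), np.sort(oracle), atol=1e-8)

    def test_effects_sum_to_zero(self, small_scan):
        res, _, _ = small_scan
        for q in res.qtls:
            if q.allele_effects is not None:
                assert q.allele_effects.sum() == pytest.approx(0.0, abs=1e-8)


class TestR2Partition:
    def test_single_locus_noise_free_r2_is_total(self):
        n = 60
        accs = [f"a{i}" for i in range(n)]
        split = np.array([0, 1] * 30)
        y = 40.0 + 6.0 * split
        marker = make_marker(split)
        res = stage2_stepwise([marker], phen_table(y, accs), accs,
                              settings=ScanSettings(correction="none"))
        assert res.qtls[0].main_r2 == pytest.approx(100.0, abs=1e-6)

    def test_orthogonal_loci_partial_equals_sequential(self):
        n = 200
        accs = [f"a{i}" for i in range(n)]
        a = np.tile([0, 1], 100)
        b = np.repeat([0, 1], 100)  # orthogonal to a
        y = 40.0 + 4.0 * a + 2.0 * b
        m1 = make_marker(a, start=1000, mid="ma")
        m2 = make_marker(b, chrom=2, start=1000, mid="mb")
        res = stage2_stepwise([m1, m2], phen_table(y, accs), accs,
                              settings=ScanSettings(correction="none"))
        ss_total = np.sum((y - y.mean()) ** 2)
        seq_a = 100 * np.sum((4.0 * (a - a.mean())) ** 2) / ss_total
        seq_b = 100 * np.sum((2.0 * (b - b.mean())) ** 2) / ss_total
        got = {q.marker_id: q.main_r2 for q in res.qtls}
        assert got["ma"] == pytest.approx(seq_a, rel=1e-6)
        assert got["mb"] == pytest.approx(seq_b, rel=1e-6)

    def test_cumulative_r2_capped_by_heritability(self, small_scan, small_population):
        res, _, _ = small_scan
        _, _, truth = small_population
        total = sum(q.main_r2 or 0 for q in res.qtls) + sum(q.qei_r2 or 0 for q in res.qtls)
        assert total <= 100 * truth.realized_h2 + 1e-6

    def test_planted_r2_recovered_within_tolerance(self, small_scan, small_population):
        res, markers, filtered = small_scan
        g, ph, truth = small_population
        cov = structure_covariates(similarity_matrix(markers), 10)
        cell = ph.groupby(["accession", "environment"])["value"].mean().reset_index()
        env_means = cell.groupby("environment")["value"].transform("mean")
        tss = ((cell["value"] - env_means) ** 2).sum()
        acc_index = {a: i for i, a in enumerate(filtered.accessions)}
        obs_acc = cell["accession"].map(acc_index).to_numpy()
        env_d = pd.get_dummies(cell["environment"], drop_first=True).to_numpy(float)
        base = np.column_stack([np.ones(len(cell)), env_d, cov[obs_acc]])
        for q, (c, p) in enumerate(truth.qtl_positions):
            rec = [r for r in res.qtls
                   if r.has_main and r.chrom == c and abs(r.start - p) <= 300_000]
            if not rec:
                continue
            # the estimand is the partial contribution given environment and
            # structure covariates, so the oracle projects those out too
            contrib = truth.allele_effects[q][truth.allele_assignment[q]][obs_acc]
            beta, *_ = np.linalg.lstsq(base, contrib, rcond=None)
            resid = contrib - base @ beta
            true_r2 = 100 * float(resid @ resid) / tss
            assert rec[0].main_r2 == pytest.approx(true_r2, rel=0.3)


class TestClassification:
    @pytest.mark.parametrize(
        "r2, expected", [(5.16, "LC"), (0.08, "SC"), (1.00, "LC"), (0.99, "SC")]
    )
    def test_contribution_boundary(self, r2, expected):
        assert classify_contribution(r2) == expected

    def test_negative_r2_rejected(self):
        with pytest.raises(ValueError):
            classify_contribution(-0.1)

    @pytest.mark.parametrize(
        "chrom, rank, expected",
        [(12, 4, "q-DLP-12-4"), (1, 1, "q-DLP-01-1")],
    )
    def test_qtl_naming(self, chrom, rank, expected):
        assert name_qtl("DLP", chrom, rank) == expected

    def test_ranks_follow_physical_order(self, small_scan):
        res, _, _ = small_scan
        by_chrom = {}
        for q in res.qtls:
            by_chrom.setdefault(q.chrom, []).append(q)
        for chrom, qtls in by_chrom.items():
            ranks = [int(q.name.rsplit("-", 1)[1]) for q in qtls]
            positions = [q.start for q in qtls]
            assert ranks == sorted(ranks)
            assert positions == sorted(positions)
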