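"""Imputation / phasing pipelines and the switch-error metric."""

from fractions import Fraction

import numpy as np
import pytest

from lssurface.experiments import (
    OptimalInterval,
    RegionLossCurve,
    StudyConfig,
    SwitchError,
    imputation_loss,
    impute_from_path,
    loss_curve,
    maf_weights,
    optimal_interval,
    run_imputation_replicates,
    run_phasing_replicates,
    summarize_fraction_optimal,
    switch_error,
)
from lssurface.haploid import partition_haploid
from lssurface.model import AlleleMatrix, CopyPath, Haplotype


class TestImputeFromPath:
    def panel(self):
        # 8 sites x 6 templates with distinct columns
        return AlleleMatrix(np.arange(48).reshape(8, 6) % 2)

    def test_flanking_same_template(self):
        H = AlleleMatrix(np.array([[0, 1], [1, 0], [0, 1]]))
        retained, masked = np.array([0, 2]), np.array([1])
        path = CopyPath(np.array([1, 1]))
        out = impute_from_path(path, retained, masked, H)
        assert out.tolist() == [0]  # template 1's allele at the masked site

    def test_tie_goes_left(self):
        H = AlleleMatrix(np.array([[0, 0], [0, 1], [1, 0]]))
        retained, masked = np.array([0, 2]), np.array([1])
        # left flank copies template 0, right flank copies template 1
        path = CopyPath(np.array([0, 1]))
        out = impute_from_path(path, retained, masked, H)
        assert out.tolist() == [int(H.alleles[1, 0])]

    def test_leading_masked_sites_use_first_marker(self):
        H = AlleleMatrix(np.array([[1, 0], [0, 0], [1, 1]]))
        retained, masked = np.array([1, 2]), np.array([0])
        path = CopyPath(np.array([0, 0]))
        assert impute_from_path(path, retained, masked, H).tolist() == [1]

    def test_zero_error_regime_end_to_end(self, rng):
        # focal equals one panel column: the surface's single path imputes
        # every masked site correctly
        H = AlleleMatrix(rng.integers(0, 2, size=(30, 5)))
        h = Haplotype(H.alleles[:, 3].copy())
        retained = np.arange(0, 30, 2)
        masked = np.arange(1, 30, 2)
        s = partition_haploid(Haplotype(h.alleles[retained]), AlleleMatrix(H.alleles[retained]))
        assert len(s.vertices) == 1
        imp = impute_from_path(s.representative_paths[0], retained, masked, H)
        assert (imp == h.alleles[masked]).all()

    def test_empty_retained_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            impute_from_path(CopyPath(np.array([0])), np.array([], dtype=int), np.array([0]), self.panel())


class TestImputationLoss:
    def test_perfect_and_hamming(self, rng):
        t = rng.integers(0, 2, size=20)
        assert imputation_loss(t, t) == 0.0
        x = t.copy()
        x[[2, 5, 11]] ^= 1
        assert imputation_loss(t, x) == 3.0

    def test_weighted_contribution(self):
        # one error at MAF 0.5: weight 1/(0.5*0.5) = 4
        cols = np.zeros((1, 10), dtype=int)
        cols[0, :5] = 1
        w = maf_weights(cols, np.array([0]))
        assert w.tolist() == [4.0]
        assert imputation_loss([0], [1], w) == 4.0

    def test_zero_maf_rejected(self):
        cols = np.zeros((1, 10), dtype=int)
        with pytest.raises(ValueError, match="MAF"):
            maf_weights(cols, np.array([0]))

    def test_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            imputation_loss([0, 1], [0])
        with pytest.raises(ValueError, match="positive"):
            imputation_loss([0], [1], weights=np.array([-1.0]))


def _curve(losses, breaks):
    """Build a RegionLossCurve directly from losses and breakpoints."""
    from lssurface.hull import regions_from_breakpoints

    regions = regions_from_breakpoints([Fraction(b) for b in breaks])
    records = tuple(
        (interval, (i, 0), float(loss)) for i, (interval, loss) in enumerate(zip(regions, losses))
    )
    return RegionLossCurve(records=records, loss_kind="hamming")


class TestOptimalInterval:
    def test_constant_curve_covers_everything(self):
        opt = optimal_interval(_curve([2.0, 2.0, 2.0], [5, 2]), reference_c=1.0)
        assert opt.lo == 0 and opt.hi is None
        assert opt.contains_reference_beta and not opt.multimodal

    def test_unique_minimal_region(self):
        opt = optimal_interval(_curve([3.0, 1.0, 2.0], [5, 2]), reference_c=3.0)
        assert (opt.lo, opt.hi) == (Fraction(2), Fraction(5))
        assert opt.contains_reference_beta
        assert optimal_interval(_curve([3.0, 1.0, 2.0], [5, 2]), 7.0).contains_reference_beta is False

    def test_multimodal_reports_all_runs_primary_smallest_lo(self):
        opt = optimal_interval(_curve([1.0, 2.0, 1.0, 1.0], [6, 3, 1]), reference_c=0.5)
        assert opt.multimodal
        assert opt.runs == ((Fraction(6), None), (Fraction(0), Fraction(3)))
        assert (opt.lo, opt.hi) == (Fraction(0), Fraction(3))
        assert opt.contains_reference_beta

    def test_contiguous_regions_merge(self):
        opt = optimal_interval(_curve([5.0, 1.0, 1.0, 9.0], [6, 3, 1]), reference_c=2.0)
        assert not opt.multimodal
        assert (opt.lo, opt.hi) == (Fraction(1), Fraction(6))


class TestSwitchError:
    def hap(self, *alleles):
        return Haplotype(np.array(alleles))

    def test_exact_match_and_global_swap(self):
        t1, t2 = self.hap(0, 1, 0, 1), self.hap(1, 0, 1, 0)
        assert switch_error((t1, t2), (t1, t2)).count == 0
        assert switch_error((t1, t2), (t2, t1)).count == 0
        assert switch_error((t2, t1), (t1, t2)).count == 0

    def test_hand_worked_double_switch(self):
        # truth 0|1,0|1,0|1; estimate 0|1,1|0,0|1 -> orientation +,-,+ : 2 switches
        t1, t2 = self.hap(0, 0, 0), self.hap(1, 1, 1)
        e1, e2 = self.hap(0, 1, 0), self.hap(1, 0, 1)
        se = switch_error((t1, t2), (e1, e2))
        assert se.count == 2 and se.n_comparable == 3
        assert se.rate == pytest.approx(1.0)

    def test_discordant_and_hom_sites_excluded(self):
        # site 1: truth hom -> excluded; site 2: estimate hom -> excluded
        t1, t2 = self.hap(0, 1, 0, 0), self.hap(1, 1, 1, 1)
        e1, e2 = self.hap(0, 0, 0, 1), self.hap(1, 1, 0, 0)
        se = switch_error((t1, t2), (e1, e2))
        assert se.n_comparable == 2

    def test_single_comparable_site(self):
        t1, t2 = self.hap(0, 0), self.hap(1, 0)
        se = switch_error((t1, t2), (t1, t2))
        assert se.count == 0 and se.rate == 0.0 and se.n_comparable == 1

    def test_no_comparable_sites_undefined(self):
        t1 = t2 = self.hap(0, 0)
        se = switch_error((t1, t2), (t1, t2))
        assert se.rate is None and se.n_comparable == 0


class TestLossCurve:
    def test_single_region_single_entry(self, rng):
        H = AlleleMatrix(rng.integers(0, 2, size=(10, 3)))
        h = Haplotype(H.alleles[:, 0].copy())
        s = partition_haploid(h, H)
        curve = loss_curve(s, lambda path: 7.5, "hamming")
        assert len(curve.records) == len(s.vertices) == 1
        assert curve.records[0][2] == 7.5

    def test_one_loss_per_region_matches_vertices(self, rng):
        H = AlleleMatrix(rng.integers(0, 2, size=(20, 4)))
        h = Haplotype(rng.integers(0, 2, size=20))
        s = partition_haploid(h, H)
        seen = []
        curve = loss_curve(s, lambda path: seen.append(1) or len(seen), "hamming")
        assert len(curve.records) == len(s.vertices)
        assert [rec[1] for rec in curve.records] == s.vertex_coords()


class TestReplicateStudies:
    def test_imputation_mosaic_smoke(self):
        cfg = StudyConfig(engine="mosaic", N=25, L=120, p_theta=2e-2, p_rho=4e-3, seed=5)
        df = run_imputation_replicates(cfg, 3)
        good = df[df["ok"]]
        assert len(good) == 6  # two loss kinds per replicate
        assert set(good["loss_kind"]) == {"hamming", "maf_weighted"}
        assert (good["min_loss"] >= 0).all()
        assert (good["opt_lo"] < good["opt_hi"]).all()
        frac = summarize_fraction_optimal(df)
        assert ((0 <= frac) & (frac <= 1)).all()

    def test_phasing_mosaic_smoke(self):
        cfg = StudyConfig(engine="mosaic", N=12, L=80, p_theta=2e-2, p_rho=4e-3, seed=8)
        df = run_phasing_replicates(cfg, 2)
        good = df[df["ok"]]
        assert len(good) == 2
        assert (good["min_loss"] >= 0).all()
        assert (good["n_regions"] >= 1).all()

    def test_reference_c_consistency(self):
        from lssurface.model import alpha_from_p, beta_from_p

        cfg = StudyConfig(engine="mosaic", N=50, p_theta=1e-2, p_rho=1e-3, seed=0)
        expect = beta_from_p(1e-3, 50) / alpha_from_p(1e-2)
        assert cfg.reference_c() == pytest.approx(expect)
        # coalescent reference reproduces the population-scaled convention
        ccfg = StudyConfig(engine="coalescent", N=100, mutation_rate=1e-4, recombination_rate=1e-4)
        from lssurface.model import penalty_ratio

        assert ccfg.reference_c() == pytest.approx(penalty_ratio(2e-4, 2e-4, 100))
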