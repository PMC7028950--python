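import numpy as np
import pytest

from hapsweep import (
    EHHProfile,
    HapsweepError,
    ScanParams,
    SweepConfig,
    SyntheticConfig,
    ehh_curve,
    generate_neutral,
    generate_two_pops,
    ihh,
    ihs_scan,
    nsl_scan,
    plant_sweep,
    xpehh_scan,
)
from hapsweep.io_model import PopulationLabels
from conftest import make_matrix
from oracles import brute_ehh, brute_sl


class TestEHHCurve:
    def test_subhaplotype_counts_formula(self):
        """Class of 4 splitting into sub-haplotype counts {3,1} then {2,1,1}:
        EHH = 3/6 then C(2,2)/C(4,2) = 1/6."""
        alleles = [
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 0, 1],
            [0, 0, 0],  # ancestral class (keeps the core polymorphic)
            [0, 1, 1],
        ]
        hm, vmap = make_matrix(alleles)
        prof = ehh_curve(hm, vmap, core=0, allele_class=1, direction="right")
        np.testing.assert_allclose(prof.ehh, [1.0, 3 / 6, 1 / 6])

    def test_identical_class_never_decays_and_truncates(self):
        alleles = [[1, 0, 1, 0, 1]] * 4 + [[0, 1, 0, 1, 0]] * 2
        hm, vmap = make_matrix(alleles)
        prof = ehh_curve(hm, vmap, core=2, allele_class=1, direction="right")
        np.testing.assert_allclose(prof.ehh, 1.0)
        assert prof.truncated and prof.stop == "chrom_end"

    def test_degenerate_class_raises(self):
        alleles = [[1, 0], [0, 0], [0, 1], [0, 0]]
        hm, vmap = make_matrix(alleles)
        with pytest.raises(HapsweepError, match="degenerate allele class"):
            ehh_curve(hm, vmap, core=0, allele_class=1)

    def test_matches_pairwise_brute_force(self, random_matrix):
        hm, vmap = random_matrix
        for core in (5, 20, 34):
            for allele in (0, 1):
                carriers = np.flatnonzero(hm.alleles[:, core] == allele)
                if len(carriers) < 2:
                    continue
                for direction in ("left", "right"):
                    prof = ehh_curve(
                        hm, vmap, core, allele, direction=direction,
                        use_bp_limits=False, cutoff_override=0.0,
                    )
                    for site, val in zip(prof.site_idx, prof.ehh):
                        assert val == pytest.approx(
                            brute_ehh(hm.alleles, carriers, core, int(site))
                        )

    def test_monotone_non_increasing(self, random_matrix):
        hm, vmap = random_matrix
        for core in range(0, 40, 7):
            for allele in (0, 1):
                if min((hm.alleles[:, core] == allele).sum(), 2) < 2:
                    continue
                prof = ehh_curve(hm, vmap, core, allele, use_bp_limits=False,
                                 cutoff_override=0.0)
                assert (np.diff(prof.ehh) <= 1e-12).all()


class TestIHH:
    def _profile(self, sites, values, direction="right", truncated=False):
        return EHHProfile(sites[0], direction, np.asarray(sites), np.asarray(values), truncated)

    def test_hand_trapezoid(self):
        """Points (0 cM, 1.0), (0.01, 0.5), (0.02, 0.04) -> 0.0102."""
        _, vmap = make_matrix(np.zeros((2, 3)), spacing_bp=10_000)  # 0.01 cM spacing
        left = self._profile([0], [1.0], "left")
        right = self._profile([0, 1, 2], [1.0, 0.5, 0.04], "right")
        value, unreliable = ihh(left, right, vmap)
        assert value == pytest.approx(0.0102)
        assert not unreliable

    def test_truncated_constant_curve(self):
        """EHH = 1 over a 0.5 cM truncated extension -> iHH = 0.5, flagged."""
        _, vmap = make_matrix(np.zeros((2, 6)), spacing_bp=100_000)  # 0.1 cM steps
        left = self._profile([0], [1.0], "left")
        right = self._profile(list(range(6)), [1.0] * 6, "right", truncated=True)
        value, unreliable = ihh(left, right, vmap)
        assert value == pytest.approx(0.5)
        assert unreliable

    def test_linear_in_genetic_distance(self):
        _, vmap1 = make_matrix(np.zeros((2, 4)), spacing_bp=10_000)
        _, vmap2 = make_matrix(np.zeros((2, 4)), spacing_bp=20_000)
        left = self._profile([0], [1.0], "left")
        right = self._profile([0, 1, 2, 3], [1.0, 0.6, 0.3, 0.02], "right")
        v1, _ = ihh(left, right, vmap1)
        v2, _ = ihh(left, right, vmap2)
        assert v2 == pytest.approx(2 * v1)


class TestIHSScan:
    def test_mirror_symmetric_classes_give_zero(self):
        """Class-1 and class-0 carriers with identical haplotype structure
        away from the core produce raw iHS = 0 exactly."""
        rng = np.random.default_rng(3)
        block = (rng.random((6, 21)) < 0.5).astype(np.uint8)
        core = 10
        up = block.copy()
        up[:, core] = 1
        down = block.copy()
        down[:, core] = 0
        hm, vmap = make_matrix(np.vstack([up, down]))
        res = ihs_scan(hm, vmap, ScanParams(), trunc_ok=True)
        assert res.raw[core] == pytest.approx(0.0)

    def test_core_recode_flips_sign(self):
        from hapsweep import HaplotypeMatrix

        cfg = SyntheticConfig(n_samples=25, n_sites=120, rng_seed=9)
        hm, vmap = generate_neutral(cfg)
        res = ihs_scan(hm, vmap, trunc_ok=True)
        core = int(np.flatnonzero(np.isfinite(res.raw))[3])
        flipped = hm.alleles.copy()
        flipped[:, core] ^= 1
        res2 = ihs_scan(HaplotypeMatrix(flipped, hm.sample_ids), vmap, trunc_ok=True)
        assert res2.raw[core] == pytest.approx(-res.raw[core])

    def test_skips_are_recorded_never_silent(self):
        cfg = SyntheticConfig(n_samples=20, n_sites=100, rng_seed=4)
        hm, vmap = generate_neutral(cfg)
        res = ihs_scan(hm, vmap)
        nan_rows = res[~np.isfinite(res.raw)]
        assert (nan_rows.skip_reason != "").all()

    def test_planted_sweep_core_outscores_matched_neutral(self):
        """Hard sweep at derived frequency 0.7: |raw iHS| at the core beats
        the 95th percentile of matched-frequency neutral scores."""
        cfg = SyntheticConfig(
            n_samples=50, n_sites=600, rng_seed=42,
            sweep=SweepConfig(core_index=300, target_derived_freq=0.7,
                              tract_scale_bp=2_000_000),
        )
        hm, vmap, core = plant_sweep(cfg)
        res = ihs_scan(hm, vmap)
        ncfg = SyntheticConfig(n_samples=50, n_sites=600, rng_seed=43)
        nhm, nvmap = generate_neutral(ncfg)
        nres = ihs_scan(nhm, nvmap)
        m = np.isfinite(nres.raw) & (np.abs(nres.freq1 - 0.7) <= 0.1)
        threshold = np.percentile(np.abs(nres.raw[m]), 95)
        assert abs(res.raw[core]) > threshold


class TestXPEHH:
    def _two_pop_same_haplotypes(self):
        rng = np.random.default_rng(11)
        block = (rng.random((20, 60)) < rng.uniform(0.2, 0.8, 60)).astype(np.uint8)
        hm, vmap = make_matrix(np.vstack([block, block]))
        labels = PopulationLabels(
            {s: ("A" if i < 10 else "B") for i, s in enumerate(hm.sample_ids)}
        )
        return hm, vmap, labels

    def test_identical_populations_score_zero(self):
        hm, vmap, labels = self._two_pop_same_haplotypes()
        res = xpehh_scan(hm, vmap, labels, "A", "B", trunc_ok=True)
        scored = res.raw[np.isfinite(res.raw)]
        assert len(scored) > 0
        np.testing.assert_allclose(scored, 0.0, atol=1e-12)

    def test_swapping_populations_flips_sign_exactly(self):
        cfg = SyntheticConfig(
            n_samples=25, n_samples_ref=12, n_sites=150,
            divergence_drift=0.1, rng_seed=6,
        )
        hm, vmap, labels = generate_two_pops(cfg)
        ab = xpehh_scan(hm, vmap, labels, "focal", "reference", trunc_ok=True)
        ba = xpehh_scan(hm, vmap, labels, "reference", "focal", trunc_ok=True)
        m = np.isfinite(ab.raw.to_numpy())
        np.testing.assert_allclose(
            ab.raw.to_numpy()[m], -ba.raw.to_numpy()[m], atol=1e-12
        )

    def test_focal_only_sweep_raises_mean_core_score(self):
        """A sweep planted only in the focal population pushes XP-EHH at the
        core above the neutral-site average."""
        vals, neutral_means = [], []
        for rep in range(5):
            cfg = SyntheticConfig(
                n_samples=40, n_samples_ref=20, n_sites=400,
                divergence_drift=0.1, rng_seed=70 + rep,
                sweep=SweepConfig(core_index=200, target_derived_freq=0.8,
                                  tract_scale_bp=2_000_000),
            )
            hm, vmap, labels, core = generate_two_pops(cfg, return_core_index=True)
            res = xpehh_scan(hm, vmap, labels, "focal", "reference")
            raw = res.raw.to_numpy()
            if np.isfinite(raw[core]):
                vals.append(raw[core])
            neutral_means.append(np.nanmean(np.delete(raw, core)))
        assert np.mean(vals) > 0
        assert np.mean(vals) > np.mean(neutral_means)

    def test_empty_population_is_an_error(self):
        hm, vmap, labels = self._two_pop_same_haplotypes()
        with pytest.raises(HapsweepError):
            xpehh_scan(hm, vmap, labels, "A", "C")


class TestNSL:
    def test_identical_pair_counts_all_seven_sites(self):
        """Two identical haplotypes over 7 sites, core central: SL = 7."""
        alleles = [
            [0, 1, 0, 1, 1, 0, 1],
            [0, 1, 0, 1, 1, 0, 1],
            [1, 0, 1, 0, 0, 1, 0],
            [1, 1, 1, 0, 1, 1, 0],
        ]
        hm, vmap = make_matrix(alleles)
        res = nsl_scan(hm, vmap)
        assert res.comp1[3] == pytest.approx(7.0)  # class 1 at core 3
        assert res.comp0[3] == pytest.approx(2.0)  # runs: 1 left + core
        assert res.raw[3] == pytest.approx(np.log(7.0 / 2.0))

    def test_core_recode_flips_sign(self):
        cfg = SyntheticConfig(n_samples=20, n_sites=80, rng_seed=12)
        hm, vmap = generate_neutral(cfg)
        res = nsl_scan(hm, vmap)
        core = int(np.flatnonzero(np.isfinite(res.raw))[5])
        from hapsweep import HaplotypeMatrix

        flipped = hm.alleles.copy()
        flipped[:, core] ^= 1
        res2 = nsl_scan(HaplotypeMatrix(flipped, hm.sample_ids), vmap)
        assert res2.raw[core] == pytest.approx(-res.raw[core])

    def test_matches_pairwise_brute_force(self, rng):
        a = (rng.random((20, 50)) < rng.uniform(0.2, 0.8, 50)).astype(np.uint8)
        hm, vmap = make_matrix(a)
        params = ScanParams(max_extend_sites_nsl=100)
        res = nsl_scan(hm, vmap, params)
        for core in range(0, 50, 5):
            if res.skip_reason[core]:
                continue
            for allele, col in ((1, "comp1"), (0, "comp0")):
                carriers = np.flatnonzero(a[:, core] == allele)
                assert res[col][core] == pytest.approx(
                    brute_sl(a, carriers, core, cap=100)
                )

    def test_direction_cap_limits_tract_length(self):
        alleles = np.vstack([np.ones((2, 31)), np.zeros((2, 31))]).astype(np.uint8)
        hm, vmap = make_matrix(alleles)
        res = nsl_scan(hm, vmap, ScanParams(max_extend_sites_nsl=5))
        # identical class-1 pair: 1 + 5 + 5 with the cap, not 31
        assert res.comp1[15] == pytest.approx(11.0)
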