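import itertools

import numpy as np
import pytest

from glycosim import (
    GlycanComposition,
    ModificationIsoform,
    ProteinModel,
    SiteTable,
    backbone_mass_from_sequence,
    build_zero_charge_spectrum,
    enumerate_proteoforms,
    normalize_site,
    site_convolution,
)
from glycosim.proteoforms import (
    CombinatorialExplosionError,
    DegenerateSiteError,
    Proteoform,
)
from glycosim.sequences import (
    RHEPO_BACKBONE_MASS,
    RHEPO_MATURE_DES_ARG166,
    RHEPO_N_DISULFIDES,
)

from conftest import random_model


def _site(abundances, deltas=None, sid="S"):
    deltas = deltas if deltas is not None else [0.0] * len(abundances)
    return SiteTable(
        sid,
        tuple(
            ModificationIsoform(f"iso{j}", d, a)
            for j, (d, a) in enumerate(zip(deltas, abundances))
        ),
    )


class TestNormalizeSite:
    @pytest.mark.parametrize(
        "abundances, expected",
        [([2, 2], [0.5, 0.5]), ([1], [1.0]), ([3, 1, 1, 5], [0.3, 0.1, 0.1, 0.5])],
    )
    def test_examples(self, abundances, expected):
        assert normalize_site(_site(abundances)) == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one(self, rng):
        a = rng.uniform(0.01, 5.0, size=7)
        assert normalize_site(_site(list(a))).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_abundances_rejected(self):
        with pytest.raises(DegenerateSiteError):
            _site([0.0, 0.0])


class TestBackboneMass:
    def test_single_glycine(self):
        # Gly residue 57.0519 + water 18.0153
        assert backbone_mass_from_sequence("G") == pytest.approx(75.067, abs=0.01)

    def test_disulfide_offset_is_two_hydrogens(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert backbone_mass_from_sequence(seq, 1) == pytest.approx(
            backbone_mass_from_sequence(seq, 0) - 2.0159, abs=1e-3
        )

    def test_rhepo_mature_chain(self):
        m = backbone_mass_from_sequence(RHEPO_MATURE_DES_ARG166, RHEPO_N_DISULFIDES)
        assert m == pytest.approx(RHEPO_BACKBONE_MASS, abs=0.5)

    def test_unknown_residue_named_by_position(self):
        with pytest.raises(ValueError, match="position 3"):
            backbone_mass_from_sequence("GGXGG")


class TestEnumerate:
    def test_uniform_two_by_two(self, two_site_model):
        pf = enumerate_proteoforms(two_site_model)
        masses = sorted(p.total_mass for p in pf)
        assert masses == pytest.approx([1000.0, 1100.0, 1100.0, 1200.0])
        assert all(p.probability == pytest.approx(0.25) for p in pf)

    def test_single_site_direct_product(self):
        model = ProteinModel(
            "one", 10_000.0,
            (_site([3, 7], deltas=[0.0, 162.1424]),),
        )
        pf = sorted(enumerate_proteoforms(model), key=lambda p: p.total_mass)
        assert pf[0].total_mass == pytest.approx(10_000.0)
        assert pf[0].probability == pytest.approx(0.3)
        assert pf[1].total_mass == pytest.approx(10_162.1424)
        assert pf[1].probability == pytest.approx(0.7)

    def test_matches_brute_force_nested_loops(self, rng):
        """3 sites x 3 isoforms vs an independent nested-loop oracle."""
        model = random_model(rng, 3, max_isoforms=3)
        while any(s.k != 3 for s in model.sites):
            model = random_model(rng, 3, max_isoforms=3)
        got = {
            p.choices: p
            for p in enumerate_proteoforms(model, with_choices=True)
        }
        assert len(got) == 27
        norm = [
            np.array([i.abundance for i in s.isoforms]) / sum(i.abundance for i in s.isoforms)
            for s in model.sites
        ]
        for j0, j1, j2 in itertools.product(range(3), repeat=3):
            mass = model.backbone_mass + sum(
                model.sites[i].isoforms[j].mass() for i, j in enumerate((j0, j1, j2))
            )
            prob = norm[0][j0] * norm[1][j1] * norm[2][j2]
            key = tuple(model.sites[i].isoforms[j].label for i, j in enumerate((j0, j1, j2)))
            assert got[key].total_mass == pytest.approx(mass, abs=1e-9)
            assert got[key].probability == pytest.approx(prob, abs=1e-12)

    def test_probabilities_sum_to_one(self, rng):
        model = random_model(rng, 4)
        total = sum(p.probability for p in enumerate_proteoforms(model, 0.0))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_explosion_error_suggests_convolution(self, rng):
        model = random_model(rng, 3)
        with pytest.raises(CombinatorialExplosionError, match="site_convolution"):
            enumerate_proteoforms(model, max_combinations=2)


class TestZeroChargeSpectrum:
    def test_positional_isomers_merge(self):
        pf = [Proteoform(1500.0, 0.25), Proteoform(1500.0, 0.25)]
        zc = build_zero_charge_spectrum(pf, merge_tol=0.0)
        assert len(zc) == 1
        assert zc.abundances[0] == pytest.approx(0.5)

    def test_merge_within_tolerance_weighted_mean(self):
        pf = [Proteoform(100.000, 0.75), Proteoform(100.004, 0.25)]
        zc = build_zero_charge_spectrum(pf, merge_tol=0.01)
        assert len(zc) == 1
        assert zc.masses[0] == pytest.approx(100.001)

    def test_zero_tolerance_counts_distinct_masses(self, rng):
        masses = rng.choice(np.arange(1000, 1050, dtype=float), size=30)
        pf = [Proteoform(float(m), 1 / 30) for m in masses]
        zc = build_zero_charge_spectrum(pf, merge_tol=0.0)
        assert len(zc) == len(set(masses))
        assert zc.abundances.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input(self):
        zc = build_zero_charge_spectrum([], 0.01)
        assert len(zc) == 0 and zc.retained_probability == 0.0


class TestSiteConvolution:
    def test_single_site_is_shifted_site_distribution(self):
        site = _site([1, 3], deltas=[0.0, 250.0])
        model = ProteinModel("one", 5_000.0, (site,))
        zc = site_convolution(model, merge_tol=0.0, prune_threshold=0.0)
        assert zc.masses == pytest.approx([5_000.0, 5_250.0])
        assert zc.abundances == pytest.approx([0.25, 0.75])

    @pytest.mark.parametrize("n_sites", [1, 2, 3, 4, 5])
    def test_equals_brute_force_enumeration(self, rng, n_sites):
        model = random_model(rng, n_sites)
        zc = site_convolution(model, merge_tol=0.0, prune_threshold=0.0)
        oracle = build_zero_charge_spectrum(enumerate_proteoforms(model, 0.0), merge_tol=0.0)
        assert zc.masses == pytest.approx(oracle.masses, abs=1e-9)
        assert zc.abundances == pytest.approx(oracle.abundances, abs=1e-9)

    def test_22_binary_sites_collapse(self):
        sites = tuple(
            SiteTable(
                f"W{i}",
                (
                    ModificationIsoform("free", GlycanComposition(), 0.4),
                    ModificationIsoform("man", GlycanComposition({"Hex": 1}), 0.6),
                ),
                kind="C",
            )
            for i in range(22)
        )
        model = ProteinModel("binary22", 46_000.0, sites)
        zc = site_convolution(model, prune_threshold=0.0)
        # 22 equivalent hexose increments collapse to 23 mass states
        assert len(zc) == 23
        assert zc.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_expectation_linearity(self, rng):
        """Mean proteoform mass equals backbone + sum of site means."""
        for _ in range(10):
            model = random_model(rng, int(rng.integers(1, 6)))
            zc = site_convolution(model, merge_tol=0.0, prune_threshold=0.0)
            mean_mass = float(np.sum(zc.masses * zc.abundances))
            expected = model.backbone_mass + sum(
                float(np.dot(normalize_site(s), s.masses())) for s in model.sites
            )
            assert mean_mass == pytest.approx(expected, abs=1e-6)

    def test_pruning_reports_retained_probability(self, rng):
        model = random_model(rng, 5)
        zc = site_convolution(model, prune_threshold=1e-3)
        assert zc.retained_probability <= 1.0 + 1e-12
        assert zc.abundances.sum() == pytest.approx(zc.retained_probability, abs=1e-12)
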