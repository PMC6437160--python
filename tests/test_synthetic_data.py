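import numpy as np
import pytest

from globinchar import synthetic_data as syn
from globinchar.electrochem import convert_reference, nernst_slope
from globinchar.genetics.linkage import (
    DiseaseModel,
    FULLY_PENETRANT_DOMINANT,
    lod_single_marker,
)
from globinchar.genetics.pedigree import AFFECTED, Individual, Pedigree
from globinchar.spectra import decompose

WT_KOBS_10UM = syn.WT_TRUTH.k_on * 10e-6 + syn.WT_TRUTH.k_off


class TestNoiseSpec:
    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            syn.NoiseSpec(sigma_abs=-1e-3)

    def test_same_seed_bit_identical(self):
        a = syn.gen_binding_traces(1e7, 10.0, [1e-5], noise=syn.NoiseSpec(0.002, 42))
        b = syn.gen_binding_traces(1e7, 10.0, [1e-5], noise=syn.NoiseSpec(0.002, 42))
        assert np.array_equal(a[0].signal, b[0].signal)

    def test_different_seed_differs(self):
        a = syn.gen_binding_traces(1e7, 10.0, [1e-5], noise=syn.NoiseSpec(0.002, 1))
        b = syn.gen_binding_traces(1e7, 10.0, [1e-5], noise=syn.NoiseSpec(0.002, 2))
        assert not np.array_equal(a[0].signal, b[0].signal)


class TestGroundTruth:
    def test_kd_consistency(self):
        assert syn.WT_TRUTH.K_D == pytest.approx(1.2e-6)
        assert syn.H98Y_TRUTH.K_D == pytest.approx(8.4e-6)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            syn.GroundTruth(k_on=-1, k_off=1, k_minus_H=1, k_ox=1, E0=0.0)
        with pytest.raises(ValueError):
            syn.GroundTruth(k_on=1, k_off=1, k_minus_H=1, k_ox=1, E0=0.0, theta_true=0.7)


class TestBindingTraces:
    def test_complete_by_68ms_at_10uM(self):
        # closed form: 1 - exp(-k_obs * 0.068) >= 0.99 at WT parameters
        t = np.linspace(syn.DEAD_TIME_S, 0.07, 200)
        tr = syn.gen_binding_traces(
            syn.WT_TRUTH.k_on, syn.WT_TRUTH.k_off, [10e-6], t_grid=t
        )[0]
        i = np.argmin(np.abs(tr.time - 0.068))
        completeness = (tr.signal[i] - 0.05) / (0.15 - 0.05)
        assert completeness >= 0.99
        assert completeness == pytest.approx(
            1 - np.exp(-WT_KOBS_10UM * tr.time[i]), abs=1e-12
        )

    def test_koff_only_same_kobs_everywhere(self):
        t = np.linspace(syn.DEAD_TIME_S, 0.5, 100)
        traces = syn.gen_binding_traces(0.0, 13.9, [1e-6, 1e-5, 4e-5], t_grid=t)
        signals = np.array([tr.signal for tr in traces])
        assert np.allclose(signals, signals[0])

    def test_noiseless_matches_closed_form_exactly(self):
        tr = syn.gen_binding_traces(1.16e7, 13.92, [1e-5])[0]
        expected = 0.15 - (0.15 - 0.05) * np.exp(-WT_KOBS_10UM * tr.time)
        np.testing.assert_array_equal(tr.signal, expected)

    def test_monotone_toward_plateau(self):
        tr = syn.gen_binding_traces(1e7, 5.0, [2e-5])[0]
        assert np.all(np.diff(tr.signal) > 0)

    def test_metadata_carries_concentration(self):
        traces = syn.gen_binding_traces(1e7, 5.0, [2.5e-6, 4e-5])
        assert [tr.ligand_conc_M for tr in traces] == [2.5e-6, 4e-5]

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_binding_traces(1e7, 5.0, [])
        with pytest.raises(ValueError):
            syn.gen_binding_traces(1e7, 5.0, [-1e-6])
        with pytest.raises(ValueError):
            syn.gen_binding_traces(1e7, 5.0, [1e-6], t_grid=np.array([]))


class TestHeminLoss:
    def test_zero_rate_constant_trace(self):
        tr = syn.gen_hemin_loss_trace(0.0, amplitude=0.6, offset=0.25)
        np.testing.assert_array_equal(tr.signal, np.full(tr.time.size, 0.85))

    def test_half_life_on_grid(self):
        k = 0.22
        t_half_min = np.log(2) / k * 60.0
        grid = np.array([0, 30, 60, 90, 120, 150, t_half_min, 250, 300, 350])
        tr = syn.gen_hemin_loss_trace(k, t_grid_min=np.sort(grid))
        i = np.argmin(np.abs(tr.time - np.log(2) / k))
        assert tr.signal[i] == pytest.approx(0.25 + 0.3, abs=1e-12)

    def test_ph5_variant_decays_faster_than_wt(self):
        fast = syn.gen_hemin_loss_trace(1.86)
        slow = syn.gen_hemin_loss_trace(1.44)
        assert np.all(fast.signal[1:] < slow.signal[1:])

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_hemin_loss_trace(0.5, amplitude=-0.1)

    def test_unit_is_hours(self):
        tr = syn.gen_hemin_loss_trace(1.0)
        assert tr.time_unit == "h"
        assert tr.time[-1] == pytest.approx(350.0 / 60.0)


class TestAutoxidation:
    def test_t0_pure_oxy(self, basis):
        s = syn.gen_autoxidation_series(1.96, np.array([0.0, 1.0]), basis)
        np.testing.assert_allclose(s.spectra[:, 0], basis.column("oxy"))

    def test_half_conversion_at_half_life(self, basis):
        k = 1.96
        s = syn.gen_autoxidation_series(k, np.array([0.0, np.log(2) / k]), basis)
        d = decompose(s.spectra[:, 1], basis)
        assert d.fractions.f_met == pytest.approx(0.5, abs=1e-9)

    def test_zero_rate_series_constant(self, basis):
        s = syn.gen_autoxidation_series(0.0, np.linspace(0, 10, 5), basis)
        assert np.allclose(s.spectra, s.spectra[:, [0]])

    def test_missing_basis_state_rejected(self, basis):
        from globinchar.spectra import BasisSet

        partial = BasisSet(
            wavelengths=basis.wavelengths,
            states=("deoxy", "met"),
            matrix=basis.matrix[:, [0, 2]],
        )
        with pytest.raises(ValueError, match="oxy"):
            syn.gen_autoxidation_series(1.0, np.array([0.0, 1.0]), partial)


class TestRedoxTitration:
    def test_half_reduced_at_e0(self):
        assert syn.fraction_reduced(0.040, 0.040) == pytest.approx(0.5)

    def test_one_decade_from_e0(self):
        s = nernst_slope(25.0)
        f = syn.fraction_reduced(0.040 + s, 0.040)
        assert (1 - f) / f == pytest.approx(10.0, rel=1e-12)
        # the printed one-decade potential +0.099 V gives ~1/11
        assert syn.fraction_reduced(0.099, 0.040) == pytest.approx(1 / 11, abs=2e-3)

    def test_strongly_oxidizing_gives_met_basis(self, basis):
        pot = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        titr = syn.gen_redox_titration(0.040, 1, pot, basis)
        for j in range(pot.size):
            np.testing.assert_allclose(
                titr.spectra[:, j], basis.column("met"), atol=1e-6
            )

    def test_too_few_potentials_rejected(self, basis):
        with pytest.raises(ValueError):
            syn.gen_redox_titration(0.04, 1, [0.04], basis)


class TestSwv:
    def test_noiseless_argmax_on_grid(self):
        vg = syn.gen_swv(-0.297, width=0.04)
        assert vg.potential[np.argmax(vg.net_current)] == pytest.approx(-0.297, abs=1e-9)

    def test_seed_reproducibility(self):
        a = syn.gen_swv(-0.1, noise=syn.NoiseSpec(0.002, 3))
        b = syn.gen_swv(-0.1, noise=syn.NoiseSpec(0.002, 3))
        c = syn.gen_swv(-0.1, noise=syn.NoiseSpec(0.002, 4))
        assert np.array_equal(a.net_current, b.net_current)
        assert not np.array_equal(a.net_current, c.net_current)

    def test_sce_to_she_shift(self):
        assert convert_reference(-0.297, "SCE", "SHE") == pytest.approx(-0.0558)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_swv(-0.1, width=0.0)


class TestFtirMapGen:
    def test_no_beta_sheet_without_weight(self):
        fmap = syn.gen_ftir_map(
            shape=(2, 2),
            region_labels=np.full((2, 2), "surround", dtype=object),
        )
        wn = fmap.wavenumber
        sel = np.abs(wn - 1627) <= 2
        far = (wn > 3500)
        # surround has no beta-sheet band: 1627 region is just the amide-I tail
        assert fmap.absorbance[0][sel].max() < 0.2

    def test_inclusion_truth_carbonyl_ratio_higher(self):
        fmap = syn.gen_ftir_map(shape=(4, 4))
        wn = fmap.wavenumber
        carbonyl = np.abs(wn - 1739) <= 2
        ch2 = np.abs(wn - 2925) <= 2

        def tr(region):
            i = np.where(fmap.regions == region)[0][0]
            return fmap.absorbance[i][carbonyl].max() / fmap.absorbance[i][ch2].max()

        assert tr("inclusion") > tr("surround")

    def test_pure_protein_amide_dominates(self):
        comp = {"surround": {"amide_i": 1.0}}
        fmap = syn.gen_ftir_map(
            shape=(2, 2),
            region_labels=np.full((2, 2), "surround", dtype=object),
            composition=comp,
        )
        wn = fmap.wavenumber
        amide = fmap.absorbance[0][np.abs(wn - 1654) <= 2].max()
        lipid = fmap.absorbance[0][np.abs(wn - 2925) <= 2].max()
        assert amide > lipid

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError, match="unknown band"):
            syn.gen_ftir_map(composition={"surround": {"nope": 1.0}})


class TestExpressionGen:
    def test_fold_one_scores_near_zero(self):
        from globinchar.genetics.enrichment import enrichment_score

        labels = ["skeletal_muscle"] * 5 + ["other"] * 45
        m, g = syn.gen_expression_matrix(200, 50, labels, [], 1.0, seed=0)
        scores = enrichment_score(m, g, "skeletal_muscle")["score"]
        assert scores.abs().max() < 1.5
        assert abs(scores.mean()) < 0.5

    def test_planted_genes_exceed_threshold(self):
        from globinchar.genetics.enrichment import enrichment_score

        labels = ["skeletal_muscle"] * 5 + ["other"] * 45
        planted = [f"g{i:05d}" for i in range(5)]
        m, g = syn.gen_expression_matrix(300, 50, labels, planted, 1e4, seed=1)
        scores = enrichment_score(m, g, "skeletal_muscle")
        flagged = set(scores.index[scores["passes"]])
        assert flagged == set(planted)

    def test_empty_enriched_set(self):
        labels = ["skeletal_muscle"] * 2 + ["other"] * 8
        m, _ = syn.gen_expression_matrix(50, 10, labels, [], 1e4, seed=2)
        m2, _ = syn.gen_expression_matrix(50, 10, labels, [], 1.0, seed=2)
        assert m.equals(m2)

    def test_unknown_enriched_id_rejected(self):
        labels = ["skeletal_muscle"] * 2 + ["other"] * 8
        with pytest.raises(ValueError, match="subset"):
            syn.gen_expression_matrix(50, 10, labels, ["nope"], 10.0)


def _nuclear(n_children: int) -> Pedigree:
    members = [
        Individual("f0", None, None, 1, 0, None),
        Individual("m0", None, None, 2, 0, None),
    ]
    members += [
        Individual(f"c{i}", "f0", "m0", 1 + i % 2, 0, None) for i in range(n_children)
    ]
    return Pedigree(members)


class TestPedigreeGen:
    def test_theta_zero_cosegregation(self):
        # fully penetrant, fully linked: affected children carry the
        # disease-coupled founder marker allele
        ped = _nuclear(10)
        model = FULLY_PENETRANT_DOMINANT
        g = syn.gen_pedigree_genotypes(ped, [0.25] * 4, 0.0, model, seed=6)
        carrier = g.by_id["f0"]
        if carrier.affected != AFFECTED:
            pytest.skip("carrier founder not affected under this seed")
        # disease-coupled allele is the carrier's first haplotype's marker
        coupled = carrier.genotype[0]
        for m in g.members:
            if m.id.startswith("c") and m.affected == AFFECTED:
                assert coupled in m.genotype

    def test_theta_half_no_linkage_info(self):
        ped = _nuclear(14)
        lods = []
        for seed in range(8):
            g = syn.gen_pedigree_genotypes(
                ped, [0.25] * 4, 0.5, DiseaseModel(), seed=seed
            )
            lods.append(lod_single_marker(g, DiseaseModel(), [0.25] * 4, 0.05))
        assert np.mean(lods) < 0.5

    def test_ten_meioses_closed_form_lod(self):
        # grandparents pin the phase; ten non-recombinant children
        members = [
            Individual("gf", None, None, 1, 2, (1, 1)),
            Individual("gm", None, None, 2, 1, (2, 2)),
            Individual("p", "gf", "gm", 1, 2, (1, 2)),
            Individual("sp", None, None, 2, 1, (2, 2)),
        ]
        for i in range(10):
            aff = i % 2 == 0
            members.append(Individual(
                f"c{i}", "p", "sp", 1, 2 if aff else 1,
                (1, 2) if aff else (2, 2),
            ))
        ped = Pedigree(members)
        lod0 = lod_single_marker(ped, FULLY_PENETRANT_DOMINANT, [0.5, 0.5], 0.0)
        assert lod0 == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_invalid_pedigree_rejected(self):
        with pytest.raises(ValueError, match="missing parent"):
            Pedigree([Individual("a", "ghost", "ghost2", 1, 0, None)])
        with pytest.raises(ValueError, match="cycle"):
            Pedigree([
                Individual("a", "b", "c", 1, 0, None),
                Individual("b", "a", "c", 1, 0, None),
                Individual("c", None, None, 2, 0, None),
            ])

    def test_determinism(self):
        ped = _nuclear(5)
        a = syn.gen_pedigree_genotypes(ped, [0.5, 0.5], 0.1, DiseaseModel(), seed=9)
        b = syn.gen_pedigree_genotypes(ped, [0.5, 0.5], 0.1, DiseaseModel(), seed=9)
        assert a.to_ped() == b.to_ped()
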