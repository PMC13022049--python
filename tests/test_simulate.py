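"""Spectrum synthesis and synthetic strain generation."""

import numpy as np
import pytest
from scipy.stats import binom

from phycomatch.proteoform import Chain, Family
from phycomatch.simulate import (
    DEFAULT_BASE_SEQUENCES,
    InstrumentModel,
    MixtureSpec,
    SyntheticSpectrum,
    charge_envelope,
    generate_strain_family,
    generate_strain_families,
    mass_to_mz,
    neutral_mass_from_mz,
    read_spectrum_csv,
    render_spectrum,
    write_spectrum_csv,
)
from phycomatch.complexes import ComplexComposition, DimerUnit, TheoreticalComplex

from conftest import ORACLE_RESIDUE_MASSES


def species(mass, strain="X"):
    comp = ComplexComposition((DimerUnit(Family.APC, strain),) * 3)
    return TheoreticalComplex(comp, ((False, False),) * 3, mass)


class TestMzConversion:
    def test_single_proton(self):
        assert mass_to_mz(1000.0, 1) == pytest.approx(1001.00728, abs=1e-9)

    def test_example_110kda_22plus(self):
        assert mass_to_mz(110000.0, 22) == pytest.approx(5001.0073, abs=1e-3)

    def test_round_trip(self):
        mz = mass_to_mz(123456.7, 17)
        assert neutral_mass_from_mz(mz, 17) == pytest.approx(123456.7, abs=1e-6)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            mass_to_mz(1000.0, 0)
        with pytest.raises(ValueError):
            neutral_mass_from_mz(5000.0, -2)


class TestChargeEnvelope:
    def test_normalized_and_nonnegative(self):
        model = InstrumentModel()
        for mass in (40000.0, 110000.0, 300000.0):
            _, w = charge_envelope(mass, model)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()

    def test_modal_charge_esi_scaling(self):
        # 0.078 * sqrt(110000) = 25.87 -> modal charge 26
        charges, w = charge_envelope(110000.0, InstrumentModel())
        assert charges[np.argmax(w)] == 26

    def test_center_scale_override(self):
        scale = 22.0 / (0.078 * np.sqrt(110000.0))
        model = InstrumentModel(envelope_center_scale=scale)
        charges, w = charge_envelope(110000.0, model)
        assert charges[np.argmax(w)] == 22

    def test_empty_window_rejected(self):
        model = InstrumentModel(mz_min=1000.0, mz_max=1100.0)
        with pytest.raises(ValueError, match="window"):
            charge_envelope(3.0e6, model)


class TestRenderSpectrum:
    def test_noise_free_intensity_conservation(self):
        mix = MixtureSpec(((species(110000.0), 3.0), (species(150000.0), 1.0)))
        model = InstrumentModel(noise_sd=0.0)
        spec = render_spectrum(mix, model)
        total = np.trapezoid(spec.intensity, spec.mz)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_per_charge_area_proportional_to_envelope(self):
        mix = MixtureSpec(((species(110000.0), 1.0),))
        model = InstrumentModel(noise_sd=0.0)
        spec = render_spectrum(mix, model)
        charges, w = charge_envelope(110000.0, model)
        for z, weight in zip(charges, w):
            center = mass_to_mz(110000.0, int(z))
            lo, hi = np.searchsorted(spec.mz, [center - 8, center + 8])
            area = np.trapezoid(spec.intensity[lo:hi], spec.mz[lo:hi])
            assert area == pytest.approx(weight, rel=1e-4)

    def test_seed_determinism(self):
        mix = MixtureSpec(((species(110000.0), 1.0),))
        model = InstrumentModel(noise_sd=0.01, seed=42)
        a = render_spectrum(mix, model)
        b = render_spectrum(mix, model)
        assert np.array_equal(a.intensity, b.intensity)
        c = render_spectrum(mix, InstrumentModel(noise_sd=0.01, seed=43))
        assert not np.array_equal(a.intensity, c.intensity)

    def test_close_species_locally_distinguishable(self):
        # 400 Da apart at z=22: ~18 m/z separation >> FWHM (~2.4) at 5000
        mix = MixtureSpec(((species(110000.0), 1.0), (species(110400.0), 1.0)))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        for mass in (110000.0, 110400.0):
            center = mass_to_mz(mass, 22)
            lo, hi = np.searchsorted(spec.mz, [center - 2, center + 2])
            window = spec.intensity[lo:hi]
            assert window.max() > 0
            peak_at = spec.mz[lo + np.argmax(window)]
            assert abs(peak_at - center) < 0.5

    def test_csv_round_trip(self, tmp_path):
        mix = MixtureSpec(((species(110000.0), 1.0),))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        path = tmp_path / "spectrum.csv"
        write_spectrum_csv(spec, path)
        back = read_spectrum_csv(path)
        assert np.allclose(back.mz, spec.mz)
        assert np.allclose(back.intensity, spec.intensity)


class TestStrainGeneration:
    def test_zero_divergence_identical_to_base(self):
        fs = generate_strain_family(family=Family.APC, divergence=0.0, seed=1)
        base_a = DEFAULT_BASE_SEQUENCES[(Family.APC, Chain.ALPHA)]
        for seq in fs.sequences:
            if seq.chain is Chain.ALPHA:
                assert seq.residues == base_a

    def test_full_protection_identical_regardless_of_divergence(self):
        base_a = DEFAULT_BASE_SEQUENCES[(Family.APC, Chain.ALPHA)]
        base_b = DEFAULT_BASE_SEQUENCES[(Family.APC, Chain.BETA)]
        protected = range(1, max(len(base_a), len(base_b)) + 1)
        fs = generate_strain_family(family=Family.APC, divergence=0.5,
                                    protected_columns=protected, seed=2)
        assert all(
            seq.residues == (base_a if seq.chain is Chain.ALPHA else base_b)
            for seq in fs.sequences
        )

    def test_substitution_count_within_binomial_interval(self):
        """Observed substitutions over 100 seeds sit in the 99% interval of
        the binomial oracle (position 1 is pinned to keep the initiator
        Met, so n = L - 1 sites per chain)."""
        base = DEFAULT_BASE_SEQUENCES[(Family.APC, Chain.ALPHA)]
        p = 0.05
        n_sites = (len(base) - 1) * 2 * 100  # 2 strains x 100 seeds
        total = 0
        for seed in range(100):
            fs = generate_strain_family(family=Family.APC, divergence=p,
                                        seed=seed)
            for seq in fs.sequences:
                if seq.chain is Chain.ALPHA:
                    total += sum(a != b for a, b in zip(seq.residues, base))
        lo, hi = binom.ppf([0.005, 0.995], n_sites, p)
        assert lo <= total <= hi

    def test_dimer_mass_difference_equals_substitution_deltas(self):
        fs = generate_strain_family(family=Family.APC, seed=5, n_strains=2)
        seqs = {(s.strain_id, s.chain): s.residues for s in fs.sequences}
        delta = 0.0
        for chain in (Chain.ALPHA, Chain.BETA):
            for a, b in zip(seqs[("S1", chain)], seqs[("S2", chain)]):
                delta += ORACLE_RESIDUE_MASSES[b] - ORACLE_RESIDUE_MASSES[a]
        truth = fs.truth
        # APC chains have one proteoform each; dimer = alpha + beta
        def dimer_mass(strain):
            return truth[truth.strain_id == strain].mass_da.sum()
        observed = dimer_mass("S2") - dimer_mass("S1")
        assert observed == pytest.approx(delta, abs=1e-6)

    def test_resolvable_family_pair_respects_relative_gap(self):
        from phycomatch.simulate import _min_relative_gap, _species_masses
        fs = generate_strain_family(family=Family.PC, seed=3,
                                    min_relative_gap=0.001)
        reg = fs.registry()
        gap = _min_relative_gap(_species_masses(reg, Family.PC, ["S1", "S2"]))
        assert gap >= 0.001

    def test_joint_generation_keeps_decoys_off_real_masses(self):
        from phycomatch.complexes import (ProteoformRegistry,
                                          decoy_compositions,
                                          composition_mass_variants)
        from phycomatch.simulate import _species_masses
        fsets = generate_strain_families(seed=11, min_relative_gap=0.001)
        seqs = [s for fs in fsets.values() for s in fs.sequences]
        reg = ProteoformRegistry.from_sequences(seqs)
        real = []
        for fam in (Family.APC, Family.PC):
            real += [m for _, m in _species_masses(reg, fam, ["S1", "S2"])]
        real = np.array(sorted(real))
        for comp in decoy_compositions(["S1", "S2"], reg):
            if len(comp.families) > 1:
                for tc in composition_mass_variants(comp, reg):
                    rel = np.abs(real - tc.neutral_mass) / tc.neutral_mass
                    assert rel.min() >= 0.00025

    def test_invalid_divergence_rejected(self):
        with pytest.raises(ValueError):
            generate_strain_family(family=Family.APC, divergence=1.5)


class TestSpectrumValidation:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpectrum(mz=np.array([1.0, 2.0]),
                              intensity=np.array([1.0]))

    def test_non_monotonic_mz_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpectrum(mz=np.array([2.0, 1.0]),
                              intensity=np.array([1.0, 1.0]))
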