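"""Deconvolution, matching, quantification and the model interface."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phycomatch.assign import (
    AssignmentStatus,
    Centroid,
    SpectrumAssigner,
    infer_charge_series,
    match_series,
    percent_error,
    pick_centroids,
    predict_mixture_absorbance,
    quantify,
)
from phycomatch.complexes import ComplexComposition, DimerUnit, TheoreticalComplex
from phycomatch.proteoform import Family
from phycomatch.simulate import (
    InstrumentModel,
    MixtureSpec,
    SyntheticSpectrum,
    mass_to_mz,
    render_spectrum,
)

PROTON = 1.00728


def species(mass, strain="X", family=Family.APC, n_dimers=3, decoy=False):
    if decoy:
        units = (DimerUnit(Family.APC, strain), DimerUnit(Family.PC, strain),
                 DimerUnit(Family.APC, strain))[:n_dimers]
        comp = ComplexComposition(tuple(units), is_decoy=True)
    else:
        comp = ComplexComposition((DimerUnit(family, strain),) * n_dimers)
    return TheoreticalComplex(comp, ((False, False),) * n_dimers, mass)


def gaussian_spectrum(centers, areas, sigma=1.0, lo=1000.0, hi=8000.0,
                      step=0.25, noise=0.0, seed=0):
    x = np.arange(lo, hi, step)
    y = np.zeros_like(x)
    for c, a in zip(centers, areas):
        y += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, x.size)
        y = np.clip(y, 0, None)
    return SyntheticSpectrum(mz=x, intensity=y)


class TestPickCentroids:
    def test_single_gaussian_apex_recovered(self):
        spec = gaussian_spectrum([5000.0], [1.0])
        cents = pick_centroids(spec)
        assert len(cents) == 1
        assert cents[0].mz == pytest.approx(5000.0, abs=0.025)
        assert cents[0].intensity == pytest.approx(1.0, rel=0.02)

    def test_pure_noise_empty(self):
        x = np.arange(1000, 8000, 0.25)
        y = np.clip(np.random.default_rng(1).normal(0, 1.0, x.size), 0, None)
        assert pick_centroids(SyntheticSpectrum(mz=x, intensity=y), 5.0) == []

    def test_two_gaussians_separated_by_three_fwhm(self):
        fwhm = 2.3548
        spec = gaussian_spectrum([5000.0, 5000.0 + 3 * fwhm], [1.0, 0.7])
        assert len(pick_centroids(spec)) == 2

    def test_flat_spectrum_empty(self):
        x = np.arange(1000, 2000, 0.25)
        spec = SyntheticSpectrum(mz=x, intensity=np.zeros_like(x))
        assert pick_centroids(spec) == []


class TestInferChargeSeries:
    def test_round_trip_single_mass(self):
        M = 110000.0
        cents = [Centroid(mass_to_mz(M, z), 1.0) for z in range(20, 25)]
        series = infer_charge_series(cents, z_range=(5, 40))
        assert len(series) == 1
        assert abs(series[0].neutral_mass - M) / M < 2e-6
        # outermost charges may fall outside the ESI plausibility window
        assert set(series[0].charges) <= {20, 21, 22, 23, 24}
        assert len(series[0].charges) >= 3

    def test_two_species_from_rendered_spectrum(self):
        mix = MixtureSpec(((species(110000.0), 1.0), (species(113000.0), 1.0)))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        series = infer_charge_series(pick_centroids(spec))
        masses = sorted(s.neutral_mass for s in series)
        assert len(masses) == 2
        assert abs(masses[0] - 110000.0) / 110000.0 < 5e-6
        assert abs(masses[1] - 113000.0) / 113000.0 < 5e-6

    def test_random_unrelated_centroids_empty(self):
        rng = np.random.default_rng(7)
        cents = [Centroid(float(mz), 1.0)
                 for mz in rng.uniform(2000, 7000, size=4)]
        assert infer_charge_series(cents, min_states=3) == []

    def test_min_states_validation(self):
        with pytest.raises(ValueError):
            infer_charge_series([Centroid(5000.0, 1.0)], min_states=1)

    def test_dimer_not_absorbed_by_hexamer_harmonic(self):
        """A hexamer at exactly three dimer masses must not cannibalize the
        dimer's charge series through its M/3 harmonic image."""
        dimer, hexamer = 36700.0, 3 * 36700.0
        mix = MixtureSpec(((species(hexamer), 0.95),
                           (species(dimer, n_dimers=1), 0.05)))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        series = infer_charge_series(pick_centroids(spec))
        masses = sorted(s.neutral_mass for s in series)
        assert len(masses) == 2
        assert abs(masses[0] - dimer) < 1.0
        assert abs(masses[1] - hexamer) < 2.0


class TestPercentError:
    @pytest.mark.parametrize("observed, theoretical, expected", [
        (110000.0, 110000.0, 0.0),
        (110055.0, 110000.0, 0.05),
        (110200.0, 110000.0, pytest.approx(0.1818, abs=1e-4)),
    ])
    def test_examples(self, observed, theoretical, expected):
        assert percent_error(observed, theoretical) == expected

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            percent_error(100.0, 0.0)

    @given(st.floats(1e3, 1e6), st.floats(1e3, 1e6), st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, m1, m2, k):
        assert percent_error(k * m1, k * m2) == pytest.approx(
            percent_error(m1, m2), rel=1e-9)


def make_series(mass, intensity=1.0, z0=24, n=4):
    members = tuple(
        (z, Centroid(mass_to_mz(mass, z), intensity / n))
        for z in range(z0, z0 + n)
    )
    from phycomatch.assign import ChargeSeries
    return ChargeSeries(neutral_mass=mass, members=members,
                        intensity_sum=intensity)


class TestMatchSeries:
    def test_unique_when_single_candidate_in_tolerance(self):
        cands = [species(110000.0, "A"), species(111000.0, "B")]
        a = match_series(make_series(110000.0), cands)
        assert a.status is AssignmentStatus.UNIQUE
        assert a.best.neutral_mass == 110000.0

    def test_ambiguous_below_criterion_spacing(self):
        # 60 Da apart at 110 kDa = 0.055% < 0.1%
        cands = [species(110000.0, "A"), species(110060.0, "B")]
        a = match_series(make_series(110000.0), cands)
        assert a.status is AssignmentStatus.AMBIGUOUS
        assert len(a.candidates) == 2
        errors = [e for _, e in a.candidates]
        assert errors == sorted(errors)

    def test_unassigned_when_all_far(self):
        cands = [species(110000.0, "A")]
        a = match_series(make_series(110220.1), cands)  # 0.2% away
        assert a.status is AssignmentStatus.UNASSIGNED
        assert a.candidates == ()

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            match_series(make_series(110000.0), [])


class TestQuantify:
    def test_single_unique_is_100pct(self):
        a = match_series(make_series(110000.0), [species(110000.0)])
        report = quantify([a])
        assert report.composition_table.abundance_pct.iloc[0] == pytest.approx(100.0)

    def test_family_abundances_sum_to_100(self):
        cands = [species(110000.0, "A"), species(111000.0, "B")]
        assignments = [match_series(make_series(m, i), cands)
                       for m, i in ((110000.0, 3.0), (111000.0, 1.0))]
        report = quantify(assignments)
        assert report.composition_table.abundance_pct.sum() == pytest.approx(100.0)

    def test_equal_split_on_exact_tie(self):
        cands = [species(110000.0, "A"), species(110060.0, "B")]
        a = match_series(make_series(110030.0), cands)
        report = quantify([a], split="equal")
        shares = report.composition_table.abundance_pct
        assert list(shares) == [pytest.approx(50.0), pytest.approx(50.0)]

    def test_likelihood_split_prefers_nearer_candidate(self):
        cands = [species(110000.0, "A"), species(110060.0, "B")]
        a = match_series(make_series(110001.0), cands)
        report = quantify([a], split="likelihood")
        table = report.composition_table.set_index("label")
        assert table.loc["APC:3xA", "abundance_pct"] > 99.0

    def test_zero_hexamer_ratio_undefined(self):
        a = match_series(make_series(36700.0),
                         [species(36700.0, n_dimers=1)])
        report = quantify([a])
        assert np.isnan(report.dimer_to_hexamer_pct["APC"])

    def test_decoy_intensity_reported(self):
        cands = [species(110000.0, "A"), species(113100.0, decoy=True)]
        assignments = [
            match_series(make_series(110000.0, 9.0), cands),
            match_series(make_series(113100.0, 1.0), cands),
        ]
        report = quantify(assignments)
        assert report.decoy_intensity_pct == pytest.approx(10.0)

    def test_simulated_dimer_to_hexamer_ratio(self):
        """95:5 hexamer:dimer by weight recovers 100*5/95 = 5.26%."""
        hexamer = species(110100.0)
        dimer = species(36700.0, n_dimers=1)
        mix = MixtureSpec(((hexamer, 0.95), (dimer, 0.05)))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        res = SpectrumAssigner(spec, [hexamer, dimer]).fit()
        assert res.abundance.dimer_to_hexamer_pct["APC"] == pytest.approx(
            5.263, rel=0.05)

    def test_dimer_ratio_monotone_in_dimer_weight(self):
        hexamer = species(110100.0)
        dimer = species(36700.0, n_dimers=1)
        ratios = []
        for dw in (0.02, 0.05, 0.10, 0.20):
            mix = MixtureSpec(((hexamer, 1 - dw), (dimer, dw)))
            spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
            res = SpectrumAssigner(spec, [hexamer, dimer]).fit()
            ratios.append(res.abundance.dimer_to_hexamer_pct["APC"])
        assert ratios == sorted(ratios)


class TestAbsorbance:
    def test_identical_profiles_zero_rms(self):
        w = np.linspace(300, 750, 50)
        prof = np.column_stack([w, np.sin(w / 100) + 2])
        _, pred, rms = predict_mixture_absorbance(prof, prof, prof)
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(pred, prof[:, 1])

    def test_constant_profiles_average_to_midpoint(self):
        w = np.linspace(300, 750, 20)
        a = np.column_stack([w, np.zeros_like(w)])
        b = np.column_stack([w, np.full_like(w, 2.0)])
        grid, pred, _ = predict_mixture_absorbance(a, b, a)
        assert np.allclose(pred, 1.0)

    def test_measured_equal_to_mean_zero_rms(self):
        w = np.linspace(300, 750, 30)
        a = np.column_stack([w, np.linspace(0, 1, 30)])
        b = np.column_stack([w, np.linspace(1, 0, 30)])
        mean = np.column_stack([w, 0.5 * (a[:, 1] + b[:, 1])])
        _, _, rms = predict_mixture_absorbance(a, b, mean)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_ranges_rejected(self):
        a = np.column_stack([np.linspace(300, 400, 5), np.ones(5)])
        b = np.column_stack([np.linspace(600, 700, 5), np.ones(5)])
        with pytest.raises(ValueError, match="disjoint"):
            predict_mixture_absorbance(a, b, a)


class TestModelInterface:
    def test_fit_returns_summary_and_tables(self):
        hexamer = species(110100.0)
        mix = MixtureSpec(((hexamer, 1.0),))
        spec = render_spectrum(mix, InstrumentModel(noise_sd=0.0))
        res = SpectrumAssigner(spec, [hexamer]).fit()
        text = res.summary()
        assert "Native-MS complex assignment" in text
        assert "unique" in text
        table = res.assignment_table()
        assert (table.status == "unique").any()
        assert table.ppm_error.min() < 10

    def test_empty_candidates_rejected(self):
        spec = gaussian_spectrum([5000.0], [1.0])
        with pytest.raises(ValueError):
            SpectrumAssigner(spec, [])
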