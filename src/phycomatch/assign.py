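"""Charge-series deconvolution and composition assignment.

The experimental logic: each complex in a native mass spectrum appears as
several consecutive charge states; back-computing M = z·(m/z − mp) for each
picked centroid over a charge range and clustering the hypotheses recovers
the neutral masses present.  Each deconvolved mass is then compared with the
theoretical masses of every candidate composition; a percentage error below
0.1% indicates the presence of the corresponding complex.  Candidates whose
masses are closer together than the criterion can resolve are reported as
ambiguous rather than silently collapsed.

The stage is exposed both as the individual operations and as a
statsmodels-style model: ``SpectrumAssigner(spectrum, candidates).fit()``
returns an :class:`AssignmentResults` carrying the charge series, the
assignments, the abundance report and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .proteoform import DEFAULT_CONSTANTS, Family
from .complexes import TheoreticalComplex
from .simulate import SyntheticSpectrum

__all__ = [
    "Centroid",
    "ChargeSeries",
    "Assignment",
    "AssignmentStatus",
    "AbundanceReport",
    "pick_centroids",
    "infer_charge_series",
    "percent_error",
    "match_series",
    "quantify",
    "predict_mixture_absorbance",
    "SpectrumAssigner",
    "AssignmentResults",
]


class Centroid(NamedTuple):
    """A picked peak: apex m/z (parabolically refined) and integrated area."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class ChargeSeries:
    """A deconvolved neutral mass supported by several charge states."""

    neutral_mass: float
    members: tuple[tuple[int, Centroid], ...]
    intensity_sum: float

    @property
    def charges(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.members)


class AssignmentStatus(str, Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Assignment:
    """A charge series with its sub-threshold candidates, sorted by error."""

    series: ChargeSeries
    candidates: tuple[tuple[TheoreticalComplex, float], ...]  # (candidate, % err)
    status: AssignmentStatus

    @property
    def best(self) -> TheoreticalComplex | None:
        return self.candidates[0][0] if self.candidates else None


@dataclass(frozen=True)
class AbundanceReport:
    """Relative abundances of assigned compositions.

    ``composition_table`` has one row per composition with its summed
    intensity and per-family relative abundance (%); decoys are excluded
    from the family totals and reported via ``decoy_intensity_pct``.
    ``dimer_to_hexamer_pct`` maps family → 100 × dimer/hexamer intensity
    (NaN when no hexamer intensity was assigned).
    """

    composition_table: pd.DataFrame
    dimer_to_hexamer_pct: dict[str, float]
    decoy_intensity_pct: float
    total_assigned_intensity: float


def pick_centroids(spectrum: SyntheticSpectrum,
                   snr_threshold: float = 5.0,
                   smooth_window: int = 7) -> list[Centroid]:
    """Pick local maxima above ``snr_threshold`` × a robust noise estimate.

    Apex positions are refined by 3-point parabolic interpolation.  Each
    centroid's intensity is an area estimate in m/z units — apex height ×
    measured FWHM × 1.0645 (the Gaussian area relation), with the FWHM
    taken from the half-maximum crossings; when a neighbouring peak
    prevents a crossing on one side, the other side's half-width is
    mirrored, and if both sides fail the trapezoidal area between the
    flanking minima is used.  Height-based areas stay accurate in crowded
    regions where watershed integration bleeds between peaks.

    A light Savitzky-Golay smooth (quadratic, ``smooth_window`` points;
    set 0 to disable) suppresses the baseline-noise ripple that would
    otherwise fragment low peaks into several local maxima; peaks several
    grid points wide are barely attenuated, and the noise floor is scaled
    by the filter's variance reduction.
    """
    y_raw = np.asarray(spectrum.intensity, float)
    x = spectrum.mz
    if y_raw.size < 3 or np.all(y_raw == y_raw[0]):
        return []
    # Detect maxima on a lightly smoothed trace (noise ripple fragments low
    # peaks into several maxima) but measure position and area on the raw
    # profile (smoothing distorts peaks only a few grid points wide).
    noise_scale = 1.0
    y = y_raw
    if smooth_window and y_raw.size > smooth_window >= 5:
        from scipy.signal import savgol_coeffs, savgol_filter

        y = savgol_filter(y_raw, smooth_window, 2)
        np.clip(y, 0.0, None, out=y)
        noise_scale = float(
            np.sqrt(np.sum(savgol_coeffs(smooth_window, 2) ** 2))
        )
    # Robust noise scale from the median nonzero first difference of the
    # raw signal (~0.66 sigma for a zero-clipped Gaussian baseline, a
    # modest overestimate for unclipped noise).  First differences are
    # insensitive to smooth peaks sampled at several points per FWHM, so
    # dense signal does not inflate the floor.
    dy = np.abs(np.diff(y_raw))
    dy = dy[dy > 0]
    noise = (float(np.median(dy)) / 0.66 if dy.size else 0.0) * noise_scale
    floor = max(noise * snr_threshold, 1e-9 * y.max())
    idx, _ = find_peaks(y, height=floor)
    if idx.size == 0:
        return []
    # flanking minima for area integration
    minima = np.concatenate(([0], find_peaks(-y)[0], [y.size - 1]))
    minima.sort()
    out = []
    step = np.median(np.diff(x))
    def half_width(i: int, bound: int, direction: int, half: float) -> float | None:
        j = i
        while j != bound:
            nxt = j + direction
            if y_raw[nxt] < half:
                # linear interpolation to the half-max crossing
                frac = (y_raw[j] - half) / (y_raw[j] - y_raw[nxt])
                return abs((j - i) + frac * direction * 1) * step
            if y_raw[nxt] > y_raw[j]:  # climbing into a neighbour
                return None
            j = nxt
        return None

    for i_s in idx:
        # re-locate the apex on the raw profile near the smoothed maximum
        lo_r = max(1, i_s - 3)
        hi_r = min(y_raw.size - 2, i_s + 3)
        i = lo_r + int(np.argmax(y_raw[lo_r:hi_r + 1]))
        y0, y1, y2 = y_raw[i - 1], y_raw[i], y_raw[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        apex_mz = x[i] + delta * step
        height = float(y1 - 0.25 * (y0 - y2) * delta)
        lo = minima[np.searchsorted(minima, i) - 1]
        hi = minima[np.searchsorted(minima, i, side="right")]
        area = None
        # Weighted LS log-parabola over the apex neighbourhood: the log of
        # a Gaussian is exactly quadratic at any sampling density, so this
        # recovers position, height and width without shape bias while the
        # inverse-variance weights (var(log y) ~ 1/y^2) average the noise.
        js = np.arange(max(lo, i - 3), min(hi, i + 3) + 1)
        js = js[y_raw[js] > max(floor * 0.3, 0.0)]
        if js.size >= 3:
            xs = (js - i).astype(float)
            ys = y_raw[js]
            c2l, c1l, c0l = np.polyfit(xs, np.log(ys), 2, w=ys)
            if c2l < 0:
                vertex = -c1l / (2 * c2l)
                if abs(vertex) <= 1.5:
                    apex_mz = x[i] + vertex * step
                    sigma = step / math.sqrt(-2 * c2l)
                    peak = math.exp(c0l - c1l ** 2 / (4 * c2l))
                    area = peak * sigma * math.sqrt(2 * math.pi)
        if area is None:
            wl = half_width(i, lo, -1, height / 2)
            wr = half_width(i, hi, +1, height / 2)
            if wl is None and wr is not None:
                wl = wr
            elif wr is None and wl is not None:
                wr = wl
            if wl is not None and wr is not None:
                area = height * (wl + wr) * 1.0645
            else:
                area = float(np.trapezoid(y_raw[lo:hi + 1], x[lo:hi + 1]))
        out.append(Centroid(float(apex_mz), area))
    return out


def infer_charge_series(
    centroids: Sequence[Centroid],
    z_range: tuple[int, int] = (5, 40),
    cluster_tol_ppm: float = 50.0,
    min_states: int = 3,
    proton_mass: float = DEFAULT_CONSTANTS.proton_mass,
    envelope_z_window: float | None = 4.5,
    envelope_center_scale: float = 1.0,
    coherence_tol_ppm: float = 25.0,
) -> list[ChargeSeries]:
    """Cluster (centroid, z) neutral-mass hypotheses into charge series.

    Every centroid spawns one hypothesis M = z·(m/z − mp) per charge in
    ``z_range``; hypotheses within ``cluster_tol_ppm`` (single linkage)
    form clusters, and clusters supported by ≥ ``min_states`` distinct
    charges — at least ``min_states`` of them consecutive — become series,
    consumed greedily by support (then intensity) so each peak backs at
    most one series.  The series mass is the intensity-weighted mean of
    its member hypotheses.

    Charge-state envelopes are harmonically degenerate: a complex of mass
    M observed at charges z also yields exact hypothesis clusters at k·M
    (from charges k·z) and at M/k (from the charges divisible by k) — a
    hexamer is exactly three dimer masses, so its M/3 image lands on the
    genuine dimer cluster.  Two guards remove the ghosts: the
    consecutive-run requirement (super-harmonic charges arrive with gaps
    of k), and an electrospray plausibility window that drops hypotheses
    whose charge is further than ``envelope_z_window`` from the native-ESI
    expectation z ≈ ``envelope_center_scale`` · 0.078·sqrt(M) (harmonic
    images sit at k-fold the plausible charge).  Set
    ``envelope_z_window=None`` to disable the physics prior.
    """
    z_lo, z_hi = z_range
    if not (math.isfinite(z_lo) and math.isfinite(z_hi)) or z_lo < 1:
        raise ValueError("z_range must be finite with z_min >= 1")
    if min_states < 2:
        raise ValueError("min_states must be >= 2")
    if not centroids:
        return []

    from .simulate import ESI_CHARGE_COEFF

    hyps = []  # (mass, z, centroid index)
    for ci, c in enumerate(centroids):
        for z in range(int(z_lo), int(z_hi) + 1):
            mass = z * (c.mz - proton_mass)
            if envelope_z_window is not None:
                z_expected = (envelope_center_scale * ESI_CHARGE_COEFF
                              * math.sqrt(mass))
                if abs(z - z_expected) > envelope_z_window:
                    continue
            hyps.append((mass, z, ci))
    if not hyps:
        return []
    hyps.sort()
    # single-linkage split on relative gaps
    clusters: list[list[tuple[float, int, int]]] = []
    current = [hyps[0]]
    for h in hyps[1:]:
        if h[0] - current[-1][0] <= cluster_tol_ppm * 1e-6 * h[0]:
            current.append(h)
        else:
            clusters.append(current)
            current = [h]
    clusters.append(current)

    def longest_run(zs: set[int]) -> int:
        best = run = 1
        ordered = sorted(zs)
        for a, b in zip(ordered, ordered[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        return best

    used = [False] * len(centroids)
    series: list[ChargeSeries] = []
    while True:
        best = None
        best_key = None
        for cl in clusters:
            live = [h for h in cl if not used[h[2]]]
            zs = {h[1] for h in live}
            if len(zs) < min_states or longest_run(zs) < min_states:
                continue
            inten = sum(centroids[h[2]].intensity for h in live)
            key = (len(zs), inten)
            if best_key is None or key > best_key:
                best, best_key = live, key
        if best is None:
            break
        # Post-acceptance cleanup: centroids shifted by peak overlap land
        # tens of ppm off the series core; drop them from the series (their
        # position and area are compromised, and the envelope fit bridges
        # the missing charge) unless that would break the series itself.
        center = float(np.median([h[0] for h in best]))
        coherent = [h for h in best
                    if abs(h[0] - center) / center * 1e6 <= coherence_tol_ppm]
        zs_c = {h[1] for h in coherent}
        if len(zs_c) >= min_states and longest_run(zs_c) >= min_states:
            for h in best:  # consume the dropped members too
                used[h[2]] = True
            best = coherent
        # one hypothesis per centroid: keep the one nearest the cluster mean
        mean0 = np.mean([h[0] for h in best])
        by_centroid: dict[int, tuple[float, int, int]] = {}
        for h in best:
            prev = by_centroid.get(h[2])
            if prev is None or abs(h[0] - mean0) < abs(prev[0] - mean0):
                by_centroid[h[2]] = h
        members = []
        wsum = msum = 0.0
        for h in sorted(by_centroid.values(), key=lambda t: t[1]):
            c = centroids[h[2]]
            members.append((h[1], c))
            wsum += c.intensity
            msum += c.intensity * h[0]
            used[h[2]] = True
        if len({z for z, _ in members}) < min_states:
            continue
        series.append(ChargeSeries(
            neutral_mass=msum / wsum,
            members=tuple(members),
            intensity_sum=wsum,
        ))
    series.sort(key=lambda s: s.neutral_mass)
    return series


def percent_error(observed: float, theoretical: float) -> float:
    """100 × |observed − theoretical| / theoretical."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be > 0")
    return 100.0 * abs(observed - theoretical) / theoretical


def match_series(
    series: ChargeSeries,
    candidates: Sequence[TheoreticalComplex],
    max_pct_error: float = 0.1,
) -> Assignment:
    """Match a deconvolved mass against candidate complexes.

    Candidates within ``max_pct_error`` percent are retained, sorted by
    error; exactly one retained candidate → ``unique``, several →
    ``ambiguous`` (including the case of Met-loss variants of a single
    composition), none → ``unassigned``.  Decoy candidates compete on equal
    footing and are distinguished downstream via their composition flag.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    scored = sorted(
        ((tc, percent_error(series.neutral_mass, tc.neutral_mass))
         for tc in candidates),
        key=lambda t: t[1],
    )
    retained = tuple((tc, err) for tc, err in scored if err <= max_pct_error)
    if not retained:
        status = AssignmentStatus.UNASSIGNED
    elif len(retained) == 1:
        status = AssignmentStatus.UNIQUE
    else:
        status = AssignmentStatus.AMBIGUOUS
    return Assignment(series=series, candidates=retained, status=status)


def _envelope_total_intensity(series: ChargeSeries) -> float:
    """Estimate a series' full charge-envelope intensity from its members.

    Peaks below the detection threshold truncate a weak species' envelope
    asymmetrically relative to a strong one, biasing summed intensities.
    Fitting a discrete Gaussian (log-parabola) to the detected (z, area)
    profile and summing it over all charges gives a detection-threshold-
    independent total.  Falls back to the raw sum when the fit is
    degenerate (fewer than 3 usable points or non-concave profile).
    """
    zs = np.array([z for z, _ in series.members], float)
    areas = np.array([c.intensity for _, c in series.members], float)
    ok = areas > 0
    if ok.sum() < 3:
        return series.intensity_sum
    z, a = zs[ok], areas[ok]
    # Robust weighted parabola in log space: members whose area is inflated
    # (a coinciding peak of another species) or deflated (overlap split) by
    # more than ~1.8x of the fitted envelope are dropped and the envelope
    # refit, as long as enough points remain.
    coeffs = None
    for _ in range(3):
        coeffs = np.polyfit(z, np.log(a), 2, w=np.sqrt(a))
        if len(z) < 4:
            break
        resid = np.abs(np.log(a) - np.polyval(coeffs, z))
        worst = int(np.argmax(resid))
        if resid[worst] <= math.log(1.8):
            break
        z = np.delete(z, worst)
        a = np.delete(a, worst)
    c2, c1, _c0 = coeffs
    if c2 >= 0:
        return series.intensity_sum
    zc = -c1 / (2 * c2)
    sigma_z = math.sqrt(-1.0 / (2 * c2))
    # flat or displaced fits carry no envelope information
    if sigma_z > 15 or not 1 <= zc <= 200:
        return series.intensity_sum
    lo = int(math.floor(zc - 5 * sigma_z))
    hi = int(math.ceil(zc + 5 * sigma_z))
    grid = np.arange(max(1, lo), hi + 1, dtype=float)
    total = float(np.exp(np.polyval(coeffs, grid)).sum())
    # guard against wild extrapolation from noisy few-point fits
    if not np.isfinite(total) or not (series.intensity_sum / 5 < total
                                      < 25 * series.intensity_sum):
        return series.intensity_sum
    return total


def _candidate_weights(assignment: Assignment, split: str,
                       mass_sigma_ppm: float) -> np.ndarray:
    errs_da = np.array([err / 100.0 * tc.neutral_mass
                        for tc, err in assignment.candidates])
    if split == "equal":
        w = np.ones(errs_da.size)
    elif split == "likelihood":
        sigma = mass_sigma_ppm * 1e-6 * assignment.series.neutral_mass
        ll = -0.5 * (errs_da / sigma) ** 2
        w = np.exp(ll - ll.max())
    else:
        raise ValueError("split must be 'equal' or 'likelihood'")
    return w / w.sum()


def quantify(
    assignments: Iterable[Assignment],
    split: str = "likelihood",
    mass_sigma_ppm: float = 50.0,
    intensity_mode: str = "envelope_fit",
) -> AbundanceReport:
    """Aggregate assigned series intensities into relative abundances.

    Each series' intensity — the integral of its fitted charge envelope by
    default, or the raw sum of assigned centroid areas with
    ``intensity_mode="summed"`` — is divided over its sub-threshold
    candidates, by a Gaussian mass-error likelihood at instrument precision
    (``mass_sigma_ppm``) by default or in equal shares with
    ``split="equal"``, and pooled by composition.  Relative abundance is
    the intensity share within each family (decoys excluded); the
    dimer:hexamer percentage is reported per family and is NaN (undefined)
    when no hexamer intensity was assigned.
    """
    if intensity_mode not in ("envelope_fit", "summed"):
        raise ValueError("intensity_mode must be 'envelope_fit' or 'summed'")
    rows: dict[tuple[str, str, int, bool], float] = {}
    total = 0.0
    for a in assignments:
        if not a.candidates:
            continue
        inten = (_envelope_total_intensity(a.series)
                 if intensity_mode == "envelope_fit"
                 else a.series.intensity_sum)
        total += inten
        weights = _candidate_weights(a, split, mass_sigma_ppm)
        for (tc, _err), w in zip(a.candidates, weights):
            comp = tc.composition
            fam = "/".join(sorted(f.value for f in comp.families))
            key = (comp.label, fam, comp.n_dimers, comp.is_decoy)
            rows[key] = rows.get(key, 0.0) + w * inten
    if not rows:
        return AbundanceReport(
            composition_table=pd.DataFrame(
                columns=["label", "family", "n_dimers", "is_decoy",
                         "intensity", "abundance_pct"]),
            dimer_to_hexamer_pct={},
            decoy_intensity_pct=float("nan"),
            total_assigned_intensity=0.0,
        )
    df = pd.DataFrame(
        [{"label": k[0], "family": k[1], "n_dimers": k[2],
          "is_decoy": k[3], "intensity": v} for k, v in rows.items()]
    )
    genuine = df[~df.is_decoy]
    fam_tot = genuine.groupby("family")["intensity"].transform("sum")
    df["abundance_pct"] = np.nan
    df.loc[~df.is_decoy, "abundance_pct"] = 100.0 * genuine["intensity"] / fam_tot
    ratios: dict[str, float] = {}
    for fam, sub in genuine.groupby("family"):
        hex_int = sub.loc[sub.n_dimers == 3, "intensity"].sum()
        dim_int = sub.loc[sub.n_dimers == 1, "intensity"].sum()
        ratios[fam] = 100.0 * dim_int / hex_int if hex_int > 0 else float("nan")
    decoy_pct = 100.0 * df.loc[df.is_decoy, "intensity"].sum() / df["intensity"].sum()
    return AbundanceReport(
        composition_table=df.sort_values(
            ["family", "n_dimers", "label"], ignore_index=True),
        dimer_to_hexamer_pct=ratios,
        decoy_intensity_pct=float(decoy_pct),
        total_assigned_intensity=float(total),
    )


def _as_profile(profile) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(profile, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        arr = np.asarray(pd.DataFrame(profile), float)
    return arr[:, 0], arr[:, 1]


def predict_mixture_absorbance(profile_a, profile_b, measured_mix):
    """Predict a mixture's UV-vis profile as the mean of its components.

    When two phycobiliprotein extracts are combined 1:1, the absorbance
    profile of the mixture matches the pointwise average of the individual
    profiles.  Profiles are (wavelength, absorbance) two-column arrays;
    they are linearly interpolated onto the measured profile's wavelengths
    within the overlapping range.  Returns
    (wavelengths, predicted, rms deviation from the measured profile).
    """
    wa, ya = _as_profile(profile_a)
    wb, yb = _as_profile(profile_b)
    wm, ym = _as_profile(measured_mix)
    lo = max(wa.min(), wb.min(), wm.min())
    hi = min(wa.max(), wb.max(), wm.max())
    if lo >= hi:
        raise ValueError("absorbance profiles have disjoint wavelength ranges")
    keep = (wm >= lo) & (wm <= hi)
    grid = wm[keep]
    predicted = 0.5 * (np.interp(grid, wa, ya) + np.interp(grid, wb, yb))
    rms = float(np.sqrt(np.mean((predicted - ym[keep]) ** 2)))
    return grid, predicted, rms


class SpectrumAssigner:
    """Model: explain one native mass spectrum by a candidate complex set.

    Parameters
    ----------
    spectrum
        Profile spectrum (:class:`~phycomatch.simulate.SyntheticSpectrum`
        or anything with ``mz``/``intensity`` arrays).
    candidates
        Theoretical complexes to match against (decoys included).
    snr_threshold, z_range, cluster_tol_ppm, min_states
        Peak picking and deconvolution settings.
    max_pct_error
        Assignment criterion (percent); 0.1 by default.
    ambiguity_split, mass_sigma_ppm
        How ambiguous series intensity is divided among candidates.

    ``fit()`` runs pick → deconvolve → match → quantify and returns an
    :class:`AssignmentResults`.
    """

    def __init__(
        self,
        spectrum: SyntheticSpectrum,
        candidates: Sequence[TheoreticalComplex],
        *,
        snr_threshold: float = 5.0,
        z_range: tuple[int, int] = (5, 40),
        cluster_tol_ppm: float = 50.0,
        min_states: int = 3,
        max_pct_error: float = 0.1,
        ambiguity_split: str = "likelihood",
        mass_sigma_ppm: float = 50.0,
        intensity_mode: str = "envelope_fit",
        envelope_z_window: float | None = 4.5,
        envelope_center_scale: float = 1.0,
        proton_mass: float = DEFAULT_CONSTANTS.proton_mass,
    ) -> None:
        if not candidates:
            raise ValueError("candidate list must be nonempty")
        self.spectrum = spectrum
        self.candidates = list(candidates)
        self.snr_threshold = snr_threshold
        self.z_range = z_range
        self.cluster_tol_ppm = cluster_tol_ppm
        self.min_states = min_states
        self.max_pct_error = max_pct_error
        self.ambiguity_split = ambiguity_split
        self.mass_sigma_ppm = mass_sigma_ppm
        self.intensity_mode = intensity_mode
        self.envelope_z_window = envelope_z_window
        self.envelope_center_scale = envelope_center_scale
        self.proton_mass = proton_mass

    def fit(self) -> "AssignmentResults":
        centroids = pick_centroids(self.spectrum, self.snr_threshold)
        series = infer_charge_series(
            centroids, self.z_range, self.cluster_tol_ppm,
            self.min_states, self.proton_mass,
            self.envelope_z_window, self.envelope_center_scale,
        )
        assignments = [
            match_series(s, self.candidates, self.max_pct_error) for s in series
        ]
        abundance = quantify(
            (a for a in assignments if a.status is not AssignmentStatus.UNASSIGNED),
            split=self.ambiguity_split, mass_sigma_ppm=self.mass_sigma_ppm,
            intensity_mode=self.intensity_mode,
        )
        return AssignmentResults(self, centroids, series, assignments, abundance)


@dataclass
class AssignmentResults:
    """Results of :meth:`SpectrumAssigner.fit`."""

    model: SpectrumAssigner
    centroids: list[Centroid]
    series: list[ChargeSeries]
    assignments: list[Assignment]
    abundance: AbundanceReport

    def assignment_table(self) -> pd.DataFrame:
        """One row per (series, retained candidate) with errors in % and ppm."""
        rows = []
        for i, a in enumerate(self.assignments):
            if not a.candidates:
                rows.append({
                    "series": i, "neutral_mass_da": a.series.neutral_mass,
                    "n_charges": len(a.series.members),
                    "intensity": a.series.intensity_sum,
                    "status": a.status.value, "candidate": None,
                    "is_decoy": None, "pct_error": np.nan, "ppm_error": np.nan,
                })
            for tc, err in a.candidates:
                rows.append({
                    "series": i, "neutral_mass_da": a.series.neutral_mass,
                    "n_charges": len(a.series.members),
                    "intensity": a.series.intensity_sum,
                    "status": a.status.value, "candidate": tc.label,
                    "is_decoy": tc.composition.is_decoy,
                    "pct_error": err, "ppm_error": err * 1e4,
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a fitted-model report."""
        lines = [
            "Native-MS complex assignment",
            "=" * 60,
            f"centroids picked: {len(self.centroids):5d}    "
            f"charge series: {len(self.series):3d}",
            f"assignment criterion: {self.model.max_pct_error:g}% mass error",
        ]
        counts = {s: 0 for s in AssignmentStatus}
        for a in self.assignments:
            counts[a.status] += 1
        lines.append(
            "series status: "
            + ", ".join(f"{k.value}={v}" for k, v in counts.items())
        )
        lines.append("-" * 60)
        for a in self.assignments:
            head = (f"M = {a.series.neutral_mass:11.1f} Da  "
                    f"z = {min(a.series.charges)}-{max(a.series.charges)}  "
                    f"[{a.status.value}]")
            lines.append(head)
            for tc, err in a.candidates[:4]:
                lines.append(
                    f"    {tc.label:<44s} {err:7.4f}% ({err * 1e4:7.1f} ppm)"
                )
        tab = self.abundance.composition_table
        if len(tab):
            lines.append("-" * 60)
            lines.append("relative abundance (% of family intensity):")
            for _, r in tab.iterrows():
                if not r.is_decoy:
                    lines.append(f"    {r['label']:<44s} {r.abundance_pct:6.2f}")
            for fam, ratio in self.abundance.dimer_to_hexamer_pct.items():
                lines.append(f"dimer:hexamer ({fam}): {ratio:.2f}%")
            lines.append(
                f"decoy intensity: {self.abundance.decoy_intensity_pct:.3f}%"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the spectrum with assigned charge-series peaks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        ax.plot(self.spectrum.mz, self.spectrum.intensity, lw=0.7, color="0.3")
        for a in self.assignments:
            if a.status is AssignmentStatus.UNASSIGNED:
                continue
            for z, c in a.series.members:
                ax.axvline(c.mz, color="C0", alpha=0.25, lw=0.8)
        ax.set_xlabel("m/z")
        ax.set_ylabel("intensity")
        return ax
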