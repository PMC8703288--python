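"""Feature detection and sulfur-signature mining of centroided runs.

The discovery step of the workflow: build extracted ion chromatograms
(XICs), detect chromatographic features, attach M+1/M+2 isotopologue
companions, flag sulfur-containing features through the +1.995796 Da
(34S) spacing, and select salinity-up-regulated candidates by fold change
and a Welch test across replicates.

The package-wide mass tolerance default is 5 ppm — the published XIC
window of +-0.0005% re-expressed in ppm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .chem import SULFUR_M2_RATIO, SULFUR_M2_SHIFT
from .run_io import SyntheticRun

__all__ = [
    "DEFAULT_TOL_PPM",
    "C13_SHIFT",
    "XIC",
    "Feature",
    "Candidate",
    "extract_xic",
    "detect_features",
    "attach_isotopologues",
    "sulfur_flag",
    "differential_screen",
]

DEFAULT_TOL_PPM = 5.0
#: 13C - 12C spacing, the M+1 isotopologue offset.
C13_SHIFT = 1.0033548


@dataclass
class XIC:
    """Extracted ion chromatogram: summed intensity in a narrow m/z window."""

    target_mz: float
    tol_ppm: float
    times_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("XIC times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("XIC intensities must be >= 0")


@dataclass
class Feature:
    """A chromatographic peak: apex m/z and RT, area, S/N, envelope."""

    mz: float
    rt_min: float
    area: float
    snr: float
    height: float
    t_left: float
    t_right: float
    envelope: tuple[tuple[float, float], ...] = ()  # (delta mass, rel abundance)
    sulfur: bool | None = None
    is_isotopologue: bool = False
    sample_id: str = ""


@dataclass
class Candidate:
    """A differential-screen hit: matched feature with fold change and p."""

    mz: float
    rt_min: float
    fold_change: float
    p_value: float
    sulfur: bool
    mean_low: float
    mean_high: float
    test_skipped: bool = False


def extract_xic(run: SyntheticRun, mz: float, tol_ppm: float = DEFAULT_TOL_PPM) -> XIC:
    """XIC at ``mz`` within a relative window of ``tol_ppm``.

    Intensities of all centroids within ``mz * (1 +- tol_ppm * 1e-6)`` are
    summed per scan.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be > 0, got {tol_ppm}")
    if run.n_scans == 0:
        raise ValueError("run has no scans")
    half = mz * tol_ppm * 1e-6
    mask = np.abs(run.mz - mz) <= half
    trace = np.bincount(
        run.scan_index[mask], weights=run.intensity[mask], minlength=run.n_scans
    )
    return XIC(target_mz=mz, tol_ppm=tol_ppm, times_min=run.times_min,
               intensity=trace)


# -- feature detection ---------------------------------------------------

def _split_mz_bins(mz_sorted: np.ndarray, tol_ppm: float) -> list[slice]:
    """Partition sorted m/z values into traces.

    First split at gaps wider than the tolerance window, then recursively
    split any bin whose total spread still exceeds 2x the window (stray
    baseline centroids can otherwise bridge two nearby analytes).
    """
    n = mz_sorted.size
    if n == 0:
        return []
    rel = tol_ppm * 1e-6
    out: list[slice] = []

    def recurse(lo: int, hi: int) -> None:  # [lo, hi)
        seg = mz_sorted[lo:hi]
        if hi - lo == 1 or (seg[-1] - seg[0]) <= 2 * rel * seg[0]:
            out.append(slice(lo, hi))
            return
        gaps = np.diff(seg)
        cut = int(np.argmax(gaps)) + 1
        recurse(lo, lo + cut)
        recurse(lo + cut, hi)

    gaps = np.diff(mz_sorted)
    breaks = np.nonzero(gaps > 2 * rel * mz_sorted[:-1])[0] + 1
    edges = np.concatenate(([0], breaks, [n]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        recurse(int(lo), int(hi))
    return out


def _noise_floor(run: SyntheticRun) -> float:
    """Robust per-scan noise scale: 1.4826 x MAD of centroid intensities."""
    if run.n_peaks == 0:
        return 0.0
    med = np.median(run.intensity)
    return 1.4826 * float(np.median(np.abs(run.intensity - med)))


def _peak_bounds(trace: np.ndarray, apex: int, floor: float) -> tuple[int, int]:
    """Walk outward from the apex until the trace falls to the noise floor.

    No monotonicity is required on the flanks — multiplicative noise makes
    even a clean Gaussian locally non-monotone near its top.
    """
    lo = apex
    while lo > 0 and trace[lo - 1] > floor:
        lo -= 1
    hi = apex
    while hi < trace.size - 1 and trace[hi + 1] > floor:
        hi += 1
    return lo, hi


def detect_features(
    run: SyntheticRun,
    min_snr: float = 3.0,
    min_scans: int = 5,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[Feature]:
    """Detect chromatographic features by per-trace local-maximum picking.

    Centroids are binned into m/z traces at the given ppm tolerance; local
    maxima above ``min_snr`` times the noise scale and wider than
    ``min_scans`` scans become features.  Noise is estimated as the MAD of
    the off-peak part of the trace, with the run-wide centroid-intensity
    MAD as a floor; a noise-free run has zero noise and every planted peak
    has infinite S/N.  Features whose m/z sits one or two isotopologue
    spacings above a larger co-eluting feature are marked
    ``is_isotopologue`` so downstream screening counts each compound once.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be > 0")
    if min_scans < 3:
        raise ValueError("min_scans must be >= 3")
    if run.n_peaks == 0:
        return []
    order = np.argsort(run.mz, kind="stable")
    mz_sorted = run.mz[order]
    scan_sorted = run.scan_index[order]
    inten_sorted = run.intensity[order]
    floor_global = _noise_floor(run)
    sample_id = str(run.metadata.get("sample_id", ""))

    features: list[Feature] = []
    for sl in _split_mz_bins(mz_sorted, tol_ppm):
        scans = scan_sorted[sl]
        if np.unique(scans).size < min_scans:
            continue
        intens = inten_sorted[sl]
        mzs = mz_sorted[sl]
        trace = np.bincount(scans, weights=intens, minlength=run.n_scans)
        # off-peak noise: MAD of the trace away from its maximum region
        med = np.median(trace)
        mad = 1.4826 * float(np.median(np.abs(trace - med)))
        noise = max(mad, floor_global)
        height_min = min_snr * noise if noise > 0 else 0.0
        apexes, _ = _signal.find_peaks(trace, height=height_min,
                                       distance=max(min_scans, 3))
        for apex in apexes:
            lo, hi = _peak_bounds(trace, int(apex), 2.0 * noise)
            if hi - lo + 1 < min_scans:
                continue
            area = float(np.trapezoid(trace[lo:hi + 1],
                                      run.times_min[lo:hi + 1]))
            if area <= 0:
                continue
            in_peak = (scans >= lo) & (scans <= hi)
            w = intens[in_peak]
            apex_mz = float(np.average(mzs[in_peak], weights=w)) if w.sum() > 0 else float(np.mean(mzs))
            snr = float(trace[apex] / noise) if noise > 0 else math.inf
            features.append(Feature(
                mz=apex_mz,
                rt_min=float(run.times_min[apex]),
                area=area,
                snr=snr,
                height=float(trace[apex]),
                t_left=float(run.times_min[lo]),
                t_right=float(run.times_min[hi]),
                sample_id=sample_id,
            ))
    _mark_isotopologues(features, tol_ppm)
    return sorted(features, key=lambda f: (-f.area, f.mz))


def _mark_isotopologues(features: list[Feature], tol_ppm: float,
                        rt_tol_min: float = 0.05) -> None:
    """Flag features sitting +1/+2 isotopologue spacings above a larger
    co-eluting feature (generous windows: 0.995-1.007 and 1.990-2.010 Da)."""
    by_area = sorted(features, key=lambda f: -f.area)
    for child in features:
        for parent in by_area:
            if parent.area <= child.area:
                break
            if abs(parent.rt_min - child.rt_min) > rt_tol_min:
                continue
            d = child.mz - parent.mz
            if 0.995 <= d <= 1.007 or 1.990 <= d <= 2.010:
                child.is_isotopologue = True
                break


def attach_isotopologues(
    features: list[Feature],
    run: SyntheticRun,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[Feature]:
    """Attach M+1/M+2 envelope entries to each feature.

    For each feature, centroids co-eluting within its peak bounds at
    +1.0033548 and +1.995796 Da (within the mass tolerance at that m/z)
    are collected; envelope abundances are area ratios to the feature
    itself, and delta masses are the intensity-weighted measured offsets.
    """
    out = []
    for feat in features:
        in_rt = (run.times_min[run.scan_index] >= feat.t_left) & (
            run.times_min[run.scan_index] <= feat.t_right
        )
        envelope = [(0.0, 1.0)]
        for shift in (C13_SHIFT, SULFUR_M2_SHIFT):
            target = feat.mz + shift
            half = feat.mz * tol_ppm * 1e-6
            mask = in_rt & (np.abs(run.mz - target) <= half)
            if not np.any(mask):
                continue
            trace = np.bincount(run.scan_index[mask],
                                weights=run.intensity[mask],
                                minlength=run.n_scans)
            area = float(np.trapezoid(trace, run.times_min))
            if area <= 0 or feat.area <= 0:
                continue
            ratio = area / feat.area
            dmass = float(
                np.average(run.mz[mask], weights=run.intensity[mask])
            ) - feat.mz
            if ratio > 1e-4:
                envelope.append((dmass, min(ratio, 1.0)))
        out.append(replace(feat, envelope=tuple(envelope)))
    return out


def sulfur_flag(
    feature: Feature,
    expected_ratio_window: tuple[float, float] = (0.7 * SULFUR_M2_RATIO,
                                                  1.3 * SULFUR_M2_RATIO),
    shift_tol: float = 0.0005,
) -> bool:
    """True iff the feature's envelope shows the 34S M+2 signature.

    Requires an envelope entry within ``shift_tol`` of +1.995796 Da whose
    relative abundance falls inside ``expected_ratio_window`` (default
    0.7-1.3x the per-sulfur natural ratio of 0.0447).  Invariant to
    overall intensity scaling, since envelope entries are area ratios.
    """
    lo, hi = expected_ratio_window
    for dmass, ratio in feature.envelope:
        if abs(dmass - SULFUR_M2_SHIFT) <= shift_tol and lo <= ratio <= hi:
            return True
    return False


# -- differential screen -------------------------------------------------

def _match_features(
    tables: list[list[Feature]],
    tol_ppm: float,
    rt_tol_min: float,
) -> list[list[Feature | None]]:
    """Greedy nearest-neighbour matching of features across samples.

    Clusters are seeded by descending area; a feature joins the first
    cluster within the m/z and RT tolerances that has no member from its
    sample yet.  Returns one row per cluster with one slot per sample.
    """
    order = sorted(
        ((i, f) for i, table in enumerate(tables) for f in table
         if not f.is_isotopologue),
        key=lambda t: -t[1].area,
    )
    clusters: list[dict] = []
    for sample_i, feat in order:
        placed = False
        for cluster in clusters:
            if sample_i in cluster["members"]:
                continue
            if (abs(feat.mz - cluster["mz"]) <= cluster["mz"] * tol_ppm * 1e-6
                    and abs(feat.rt_min - cluster["rt"]) <= rt_tol_min):
                cluster["members"][sample_i] = feat
                placed = True
                break
        if not placed:
            clusters.append({"mz": feat.mz, "rt": feat.rt_min,
                             "members": {sample_i: feat}})
    n = len(tables)
    return [
        [c["members"].get(i) for i in range(n)] for c in clusters
    ]


def differential_screen(
    features_low: list[list[Feature]],
    features_high: list[list[Feature]],
    fc_min: float = 1.5,
    p_max: float = 0.05,
    tol_ppm: float = DEFAULT_TOL_PPM,
    rt_tol_min: float = 0.3,
) -> list[Candidate]:
    """Select features up-regulated in the high condition.

    Features are matched across all replicates of both conditions by m/z
    (ppm tolerance) and RT; a matched feature becomes a candidate when
    mean(high)/mean(low) >= ``fc_min`` and a two-sided Welch t-test across
    replicate areas gives p <= ``p_max``.  With fewer than 2 replicates
    per condition the test is skipped and candidates are flagged.
    Isotopologue child features are ignored.  Candidates are sorted by
    fold change, largest first.
    """
    n_low, n_high = len(features_low), len(features_high)
    rows = _match_features(list(features_low) + list(features_high),
                           tol_ppm, rt_tol_min)
    can_test = n_low >= 2 and n_high >= 2
    candidates: list[Candidate] = []
    for row in rows:
        low = [f.area if f is not None else 0.0 for f in row[:n_low]]
        high = [f.area if f is not None else 0.0 for f in row[n_low:]]
        mean_low, mean_high = float(np.mean(low)), float(np.mean(high))
        if mean_low <= 0:
            continue
        fc = mean_high / mean_low
        if fc < fc_min:
            continue
        if can_test:
            if np.var(low) == 0 and np.var(high) == 0:
                p = 1.0 if mean_low == mean_high else 0.0
            else:
                p = float(_stats.ttest_ind(high, low, equal_var=False).pvalue)
            if p > p_max:
                continue
            skipped = False
        else:
            p = math.nan
            skipped = True
        members = [f for f in row if f is not None]
        best = max(members, key=lambda f: f.area)
        candidates.append(Candidate(
            mz=best.mz,
            rt_min=best.rt_min,
            fold_change=fc,
            p_value=p,
            sulfur=any(sulfur_flag(f) for f in members if f.envelope),
            mean_low=mean_low,
            mean_high=mean_high,
            test_skipped=skipped,
        ))
    return sorted(candidates, key=lambda c: -c.fold_change)
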