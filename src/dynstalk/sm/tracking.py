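"""Track linking, straightening, displacement statistics, and phenotypes.

Localizations are linked frame-to-frame by a greedy nearest-neighbor rule
(candidate pairs sorted by distance, closest first, ties by lowest track
id), tracks are straightened onto their principal axis of motion, and
displacements are binned into fixed (default 1-s, non-overlapping) intervals
— the statistic used to show that a diffusive motor's displacement histogram
is a zero-centred Gaussian. Phenotype calls (directional / diffusive /
static / transient) follow explicit threshold rules, and microtubule
polarity is assigned from the net direction of plus-end-directed kinesin
reference tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Track",
    "link_tracks",
    "StraightenedTrack",
    "straighten_track",
    "DisplacementStats",
    "displacement_stats",
    "PhenotypeThresholds",
    "PhenotypeCall",
    "classify_phenotype",
    "PolarityCall",
    "assign_polarity",
]


@dataclass
class Track:
    track_id: int
    frames: np.ndarray   # strictly increasing ints
    t: np.ndarray        # s
    x: np.ndarray        # nm
    y: np.ndarray        # nm
    gaps: list = field(default_factory=list)  # skipped frame indices

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frame indices must be strictly increasing")
        for name in ("t", "x", "y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def duration(self):
        return float(self.t[-1] - self.t[0]) if self.t.size > 1 else 0.0


def link_tracks(localizations, max_jump=500.0, max_gap=1, frame_interval=None):
    """Greedy nearest-neighbor linking of localizations into tracks.

    ``localizations`` is a flat list with ``frame``, ``t``, ``x``, ``y``
    attributes (e.g. :class:`~dynstalk.sm.localize.Localization`), sorted or
    sortable by frame. Within each frame transition, candidate (track,
    localization) pairs closer than ``max_jump`` nm are assigned closest
    first (ties to the lowest track id); unmatched localizations open new
    tracks; a track ends after ``max_gap`` consecutive missed frames.
    """
    locs = sorted(localizations, key=lambda l: (l.frame, l.x, l.y))
    if not locs:
        return []
    by_frame = {}
    for l in locs:
        by_frame.setdefault(int(l.frame), []).append(l)

    next_id = 0
    open_tracks = []   # dicts: id, frames, t, x, y, gaps, last_frame
    closed = []
    for f in range(min(by_frame), max(by_frame) + 1):
        frame_locs = by_frame.get(f, [])
        # Close tracks that exceeded the gap allowance.
        still_open = []
        for tr in open_tracks:
            if f - tr["last_frame"] > max_gap + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        candidates = []
        for tr in open_tracks:
            for j, loc in enumerate(frame_locs):
                d = float(np.hypot(loc.x - tr["x"][-1], loc.y - tr["y"][-1]))
                if d <= max_jump:
                    candidates.append((d, tr["id"], tr, j))
        candidates.sort(key=lambda c: (c[0], c[1]))
        assigned_tracks, assigned_locs = set(), set()
        for d, tid, tr, j in candidates:
            if tid in assigned_tracks or j in assigned_locs:
                continue
            loc = frame_locs[j]
            skipped = list(range(tr["last_frame"] + 1, f))
            tr["gaps"].extend(skipped)
            tr["frames"].append(f)
            tr["t"].append(loc.t)
            tr["x"].append(loc.x)
            tr["y"].append(loc.y)
            tr["last_frame"] = f
            assigned_tracks.add(tid)
            assigned_locs.add(j)
        for j, loc in enumerate(frame_locs):
            if j in assigned_locs:
                continue
            open_tracks.append({
                "id": next_id, "frames": [f], "t": [loc.t],
                "x": [loc.x], "y": [loc.y], "gaps": [], "last_frame": f,
            })
            next_id += 1
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: tr["id"])
    return [
        Track(track_id=tr["id"], frames=tr["frames"], t=tr["t"],
              x=tr["x"], y=tr["y"], gaps=tr["gaps"])
        for tr in closed
    ]


@dataclass
class StraightenedTrack:
    track_id: int
    t: np.ndarray
    s: np.ndarray            # nm along the principal axis, centred
    perp: np.ndarray         # nm perpendicular residuals
    axis: np.ndarray         # unit 2-vector
    principal_ratio: float   # sqrt(var_parallel / var_perp); inf when perp = 0
    reliable: bool


def straighten_track(track, reference_direction=None, min_ratio=1.05):
    """Project a track onto its first principal component of motion.

    The axis is the leading right singular vector of the centred (x, y)
    scatter. Orientation: along ``reference_direction`` when given (e.g. the
    known polarity or a kinesin direction), otherwise the net displacement
    of the track itself is made non-negative. Tracks whose parallel/perp
    spread ratio is below ``min_ratio`` (isotropic clouds) are flagged
    unreliable rather than rejected.
    """
    if track.t.size < 3:
        raise ValueError("straightening needs at least 3 localizations")
    xy = np.column_stack([track.x, track.y])
    centered = xy - xy.mean(axis=0)
    _, svals, Vt = np.linalg.svd(centered, full_matrices=False)
    axis = Vt[0]
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float)
        if np.dot(axis, ref) < 0:
            axis = -axis
    else:
        net = centered[-1] - centered[0]
        d = np.dot(axis, net)
        if d < 0 or (d == 0 and axis[0] < 0):
            axis = -axis
    s = centered @ axis
    perp = centered @ np.array([-axis[1], axis[0]])
    with np.errstate(divide="ignore"):
        ratio = float(svals[0] / svals[1]) if svals[1] > 0 else np.inf
    return StraightenedTrack(
        track_id=track.track_id, t=track.t.copy(), s=s, perp=perp,
        axis=axis, principal_ratio=ratio,
        reliable=bool(ratio >= min_ratio),
    )


@dataclass
class DisplacementStats:
    interval: float
    displacements: np.ndarray   # nm
    mean: float
    sd: float
    n: int
    n_short_tracks: int         # tracks too short to contribute
    gaussian_fit: tuple = None  # (mu, sigma) from histogram least squares
    sample_fit: tuple = None    # (mean, sd) of the raw sample


def displacement_stats(straightened_tracks, interval=1.0, overlapping=False,
                       bin_width=20.0):
    """Displacements over fixed time windows, pooled across tracks.

    Windows of length ``interval`` tile each track from its first time point
    (non-overlapping by default; ``overlapping`` slides by one frame for
    sensitivity analysis). Window-edge positions are linearly interpolated
    when frames do not align. Alongside the arithmetic mean and SD (the
    primary statistics), a Gaussian is least-squares fit to the binned
    histogram, mirroring a histogram-level fit.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    disp = []
    n_short = 0
    for st in straightened_tracks:
        t0, t1 = st.t[0], st.t[-1]
        if t1 - t0 < interval:
            n_short += 1
            continue
        if overlapping:
            starts = st.t[st.t <= t1 - interval]
        else:
            n_win = int(np.floor((t1 - t0) / interval))
            starts = t0 + interval * np.arange(n_win)
        s_start = np.interp(starts, st.t, st.s)
        s_end = np.interp(starts + interval, st.t, st.s)
        disp.extend(s_end - s_start)
    disp = np.asarray(disp, dtype=float)
    if disp.size == 0:
        return DisplacementStats(
            interval=float(interval), displacements=disp,
            mean=np.nan, sd=np.nan, n=0, n_short_tracks=n_short,
        )
    mean = float(disp.mean())
    sd = float(disp.std(ddof=1)) if disp.size > 1 else 0.0
    gauss = _histogram_gaussian_fit(disp, bin_width) if disp.size >= 10 else None
    return DisplacementStats(
        interval=float(interval), displacements=disp, mean=mean, sd=sd,
        n=int(disp.size), n_short_tracks=n_short,
        gaussian_fit=gauss, sample_fit=(mean, sd),
    )


def _histogram_gaussian_fit(disp, bin_width):
    from scipy.optimize import curve_fit

    lo, hi = disp.min(), disp.max()
    if hi - lo < bin_width:
        return (float(disp.mean()), float(disp.std(ddof=0)))
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(disp, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if centers.size < 4:   # fewer bins than fit parameters
        return (float(disp.mean()), float(disp.std(ddof=0)))

    def gauss(x, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        popt, _ = curve_fit(
            gauss, centers, counts,
            p0=[counts.max(), disp.mean(), max(disp.std(), bin_width)],
            maxfev=10000,
        )
        return (float(popt[1]), float(abs(popt[2])))
    except (RuntimeError, TypeError):
        return (float(disp.mean()), float(disp.std(ddof=0)))


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Package-default decision thresholds, tuned on synthetic data.

    min_velocity : nm/s, slope below which motion is not called directional.
    min_dwell    : s, track duration below which binding is transient.
    min_D        : nm²/s, MSD-fit diffusion coefficient separating diffusive
                   from static.
    drift_sig    : multiple of the SEM the mean interval displacement must
                   exceed for significant drift.
    """

    min_velocity: float = 20.0
    min_dwell: float = 5.0
    min_D: float = 1000.0
    drift_sig: float = 3.0


@dataclass
class PhenotypeCall:
    category: str            # directional | diffusive | static | transient
    velocity: float          # nm/s, slope of s vs t
    run_length: float        # nm, |net displacement|
    D: float                 # nm²/s from the MSD slope
    dwell: float             # s, track duration
    evidence: dict
    low_confidence: bool = False


def _msd_diffusion_coefficient(st, n_lags=3):
    """1-D D from a through-origin fit of MSD(τ) over the first lags."""
    dt = np.median(np.diff(st.t))
    taus, msds = [], []
    for lag in range(1, n_lags + 1):
        if st.s.size <= lag:
            break
        d = st.s[lag:] - st.s[:-lag]
        taus.append(lag * dt)
        msds.append(np.mean(d ** 2))
    if not taus:
        return 0.0
    taus = np.asarray(taus)
    msds = np.asarray(msds)
    slope = float(np.sum(taus * msds) / np.sum(taus ** 2))
    return max(slope / 2.0, 0.0)


def classify_phenotype(straightened_track, thresholds=None, interval=1.0):
    """Call a motion phenotype from explicit threshold rules.

    Order of tests: transient when the track is shorter than ``min_dwell``;
    directional when the mean interval displacement is significantly nonzero
    (``drift_sig`` SEMs) and |velocity| clears ``min_velocity``; diffusive
    when the MSD-fit D clears ``min_D``; otherwise static. All evidence
    metrics are returned; an unreliable straightening axis lowers confidence
    without changing the rules.
    """
    th = thresholds or PhenotypeThresholds()
    st = straightened_track
    dwell = float(st.t[-1] - st.t[0])
    velocity = float(np.polyfit(st.t, st.s, 1)[0]) if st.t.size > 1 else 0.0
    run_length = float(abs(st.s[-1] - st.s[0]))
    D = _msd_diffusion_coefficient(st)
    stats = displacement_stats([st], interval=interval)
    if stats.n > 1:
        sem = stats.sd / np.sqrt(stats.n)
        # Noise-free drift has zero spread; any nonzero mean is then significant.
        drift_significant = bool(abs(stats.mean) > th.drift_sig * sem
                                 if sem > 0 else abs(stats.mean) > 0)
    else:
        drift_significant = False
    evidence = {
        "velocity_nm_s": velocity,
        "run_length_nm": run_length,
        "D_nm2_s": D,
        "dwell_s": dwell,
        "mean_interval_disp_nm": stats.mean,
        "interval_disp_sem_nm": (stats.sd / np.sqrt(stats.n)) if stats.n else np.nan,
        "n_intervals": stats.n,
        "drift_significant": drift_significant,
        "thresholds": vars(th),
    }
    if dwell < th.min_dwell:
        category = "transient"
    elif drift_significant and abs(velocity) >= th.min_velocity:
        category = "directional"
    elif D >= th.min_D:
        category = "diffusive"
    else:
        category = "static"
    return PhenotypeCall(
        category=category, velocity=velocity, run_length=run_length,
        D=D, dwell=dwell, evidence=evidence,
        low_confidence=not st.reliable,
    )


@dataclass
class PolarityCall:
    sign: int               # +1 / -1 along the straightening axis; 0 undetermined
    n_supporting: int
    conflict: bool
    net_displacement: float  # nm, summed over supporting tracks


def assign_polarity(kinesin_tracks, thresholds=None, interval=1.0):
    """Microtubule plus-end direction from kinesin reference tracks.

    ``kinesin_tracks`` are straightened on the shared filament axis. Tracks
    passing the directional classification vote with the sign of their net
    displacement; the plus end is the sign of the summed net displacement.
    No passing track → undetermined (sign 0); passing tracks with opposite
    significant signs → undetermined with the conflict flag set.
    """
    nets = []
    for st in kinesin_tracks:
        call = classify_phenotype(st, thresholds=thresholds, interval=interval)
        if call.category == "directional":
            nets.append(float(st.s[-1] - st.s[0]))
    if not nets:
        return PolarityCall(sign=0, n_supporting=0, conflict=False,
                            net_displacement=0.0)
    signs = {int(np.sign(n)) for n in nets if n != 0}
    if len(signs) > 1:
        return PolarityCall(sign=0, n_supporting=len(nets), conflict=True,
                            net_displacement=float(sum(nets)))
    total = float(sum(nets))
    return PolarityCall(sign=int(np.sign(total)), n_supporting=len(nets),
                        conflict=False, net_displacement=total)
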