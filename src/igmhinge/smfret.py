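"""Single-molecule FRET trace analysis and dye accessible-volume distances.

Channel model: under donor excitation, ``D`` is the donor-emission intensity
and ``F`` the acceptor-emission (FRET-channel) intensity; ``A`` is the
acceptor intensity under direct acceptor excitation.  The corrections are

* donor bleed-through ``alpha`` (fraction of donor fluorescence appearing in
  the FRET channel, measured as F/D on donor-only molecules),
* direct excitation ``beta`` (fraction of the FRET channel due to direct
  excitation of the acceptor, measured as F/A on acceptor-only molecules),
* the detection factor ``gamma`` relating FRET-channel to donor-channel
  counts, measured from donor recovery after acceptor photobleaching:
  ``gamma = (F_before - F_after) / (D_after - D_before)``.

FRET efficiency per frame is ``E = (F - aD - bA) / (F - aD - bA + gD)``.
Distances are predicted from dye accessible volumes with the Foerster
relation ``E = 1 / (1 + (r / R0)^6)``; for the Alexa Fluor 555/647 pair
``R0 = 51 A``.

Intensities are in camera counts, times in seconds, distances in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    BuriedSiteError,
    FitError,
    NoRecoveryError,
    SamplingError,
)
from .model_geometry import AtomicModel

R0_ALEXA555_647 = 51.0          # Foerster radius, Angstrom
DEFAULT_FRAME_S = 0.030         # camera frame pitch


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FluorescenceTrace:
    """Synchronized per-frame D / F / A intensity series of one molecule."""

    molecule_id: str
    donor: np.ndarray
    fret: np.ndarray
    acceptor: np.ndarray
    frame_s: float = DEFAULT_FRAME_S

    def __post_init__(self):
        self.donor = np.asarray(self.donor, float)
        self.fret = np.asarray(self.fret, float)
        self.acceptor = np.atleast_1d(np.asarray(self.acceptor, float))
        if self.donor.size != self.fret.size:
            raise SamplingError("donor and FRET series must have equal length")
        if self.acceptor.size not in (1, self.donor.size):
            raise SamplingError("acceptor must be a snapshot or a full series")
        for arr in (self.donor, self.fret, self.acceptor):
            if not np.all(np.isfinite(arr)):
                raise SamplingError("intensities must be finite")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def acceptor_series(self) -> np.ndarray:
        if self.acceptor.size == 1:
            return np.full(self.donor.size, float(self.acceptor[0]))
        return self.acceptor

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_s


@dataclass
class CorrectionFactors:
    """Bleed-through and detection corrections (all dimensionless)."""

    donor_bleed: float = 0.09        # alpha
    direct_excitation: float = 0.08  # beta
    gamma: float = 1.8

    def __post_init__(self):
        if self.donor_bleed < 0 or self.direct_excitation < 0:
            raise ValueError("bleed factors must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class FretTrace:
    """Per-frame FRET efficiencies with the valid (pre-bleach) mask."""

    molecule_id: str
    efficiency: np.ndarray
    valid: np.ndarray
    donor_bleach: int | None = None
    acceptor_bleach: int | None = None
    frame_s: float = DEFAULT_FRAME_S

    @property
    def valid_efficiencies(self) -> np.ndarray:
        return self.efficiency[self.valid]


# ---------------------------------------------------------------------------
# correction-factor estimation
# ---------------------------------------------------------------------------


def estimate_donor_bleed(donor_only_traces) -> float:
    """alpha = mean of F/D over all frames of donor-only molecules."""
    ratios = []
    for tr in donor_only_traces:
        ok = tr.donor > 0
        if ok.any():
            ratios.append(tr.fret[ok] / tr.donor[ok])
    if not ratios:
        raise SamplingError("no frames with positive donor intensity")
    return float(np.concatenate(ratios).mean())


def estimate_direct_excitation(acceptor_only_traces) -> float:
    """beta = mean of F/A over all frames of acceptor-only molecules."""
    ratios = []
    for tr in acceptor_only_traces:
        a = tr.acceptor_series
        ok = a > 0
        if ok.any():
            ratios.append(tr.fret[ok] / a[ok])
    if not ratios:
        raise SamplingError("no frames with positive acceptor intensity")
    return float(np.concatenate(ratios).mean())


def estimate_gamma(trace: FluorescenceTrace, acceptor_bleach_frame: int,
                   window: int = 10) -> float:
    """gamma = (F_before - F_after) / (D_after - D_before) around the bleach.

    Means are taken over ``window`` frames on each side of the bleach frame,
    excluding the bleach frame itself.  Raises when the donor does not
    recover (molecule to be excluded).
    """
    i = int(acceptor_bleach_frame)
    if not 0 < i < len(trace) - 1:
        raise SamplingError("bleach frame must be strictly inside the trace")
    lo = max(0, i - window)
    hi = min(len(trace), i + 1 + window)
    d_before = float(trace.donor[lo:i].mean())
    d_after = float(trace.donor[i + 1:hi].mean())
    f_before = float(trace.fret[lo:i].mean())
    f_after = float(trace.fret[i + 1:hi].mean())
    if d_after <= d_before:
        raise NoRecoveryError(
            f"no donor recovery (D {d_before:.3g} -> {d_after:.3g})")
    return (f_before - f_after) / (d_after - d_before)


def _acceptor_bleach_step(trace: FluorescenceTrace) -> BleachStep:
    """Acceptor-bleach step: from the direct-excitation series when
    available (state-independent), else from the FRET channel."""
    if trace.acceptor.size > 1:
        return detect_bleach_step(trace.acceptor)
    return detect_bleach_step(trace.fret)


def estimate_gamma_pooled(traces, window: int = 10,
                          min_gamma: float = 0.2,
                          max_gamma: float = 10.0) -> float:
    """Mean gamma over molecules with detectable acceptor bleach + recovery.

    Only molecules exhibiting non-zero FRET before the bleach (a clear drop
    in F and a clear donor recovery, both >10%/5% relative) contribute;
    implausible per-molecule values are excluded.
    """
    gammas = []
    for tr in traces:
        try:
            step = _acceptor_bleach_step(tr)
        except SamplingError:
            continue
        if step.status != "single":
            continue
        i = step.index
        if i - window < 0 or i + 1 + window > len(tr):
            continue  # need full windows on both sides
        f_b = float(tr.fret[i - window:i].mean())
        f_a = float(tr.fret[i + 1:i + 1 + window].mean())
        d_b = float(tr.donor[i - window:i].mean())
        d_a = float(tr.donor[i + 1:i + 1 + window].mean())
        # the FRET drop and donor recovery must both clear the channel
        # noise; this excludes molecules with near-zero FRET and molecules
        # whose donor had already bleached before the acceptor
        sd_f = _robust_frame_sd(tr.fret)
        sd_d = _robust_frame_sd(tr.donor)
        if f_b - f_a <= 4.0 * sd_f or d_a - d_b <= 4.0 * sd_d:
            continue
        g = (f_b - f_a) / (d_a - d_b)
        if min_gamma < g < max_gamma:
            gammas.append(g)
    if not gammas:
        raise SamplingError("no molecules usable for gamma estimation")
    return float(np.mean(gammas))


# ---------------------------------------------------------------------------
# efficiency
# ---------------------------------------------------------------------------


def recovered_donor(donor, fret, gamma: float):
    """Total donor fluorescence had there been no transfer: D + F/gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.asarray(donor, float) + np.asarray(fret, float) / gamma


def fret_efficiency(donor, fret, acceptor, factors: CorrectionFactors,
                    e_bounds: tuple = (-0.2, 1.2)):
    """Per-frame corrected FRET efficiency and validity mask.

    ``E = (F - aD - bA) / (F - aD - bA + gD)``.  Frames with a non-positive
    denominator or with E outside ``e_bounds`` are masked invalid (E = nan),
    not raised: correction-factor noise can push single frames outside the
    physical range.
    """
    d = np.asarray(donor, float)
    f = np.asarray(fret, float)
    a = np.broadcast_to(np.asarray(acceptor, float), d.shape)
    num = f - factors.donor_bleed * d - factors.direct_excitation * a
    den = num + factors.gamma * d
    valid = den > 0
    e = np.full(d.shape, np.nan)
    np.divide(num, den, out=e, where=valid)
    valid &= (e >= e_bounds[0]) & (e <= e_bounds[1])
    e[~valid] = np.nan
    return e, valid


# ---------------------------------------------------------------------------
# photobleach detection
# ---------------------------------------------------------------------------


def _robust_frame_sd(series) -> float:
    """Frame-to-frame noise sd, robust to occasional jumps (MAD of diffs)."""
    d = np.diff(np.asarray(series, float))
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


@dataclass
class BleachStep:
    """Classification of a single-molecule intensity series."""

    index: int | None
    status: str          # "none", "single", "multi"
    n_steps: int = 0


def detect_bleach_step(series, noise_mult: float = 4.0,
                       window: int = 5) -> BleachStep:
    """Locate a single-step photobleach as the dominant downward jump.

    The step statistic at frame i is the difference of means over ``window``
    frames after and before i; qualifying events exceed ``noise_mult`` times
    the expected statistic noise (estimated robustly from frame-to-frame
    differences).  Series with two or more qualifying downward events are
    classified multi-step and rejected.
    """
    x = np.asarray(series, float)
    if x.size < 10:
        raise SamplingError("series too short for bleach detection")
    d = np.diff(x)
    frame_sd = _robust_frame_sd(x)
    stat_sd = frame_sd * np.sqrt(2.0 / window)
    w = window
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(w, x.size - w)
    before = (csum[idx] - csum[idx - w]) / w
    after = (csum[idx + w] - csum[idx]) / w
    stat = after - before
    thresh = -noise_mult * max(stat_sd, 1e-12)
    cand = idx[stat < thresh]
    if cand.size == 0:
        return BleachStep(None, "none", 0)
    # cluster candidates separated by < window into single events
    events = []
    start = cand[0]
    prev = cand[0]
    for c in cand[1:]:
        if c - prev >= w:
            events.append((start, prev))
            start = c
        prev = c
    events.append((start, prev))
    # per event, the frame with the largest single-frame drop
    steps = []
    for lo, hi in events:
        seg = slice(max(lo - 1, 0), min(hi + 1, d.size))
        k = int(np.argmin(d[seg])) + seg.start
        steps.append(k + 1)  # step located between frames k and k+1
    if len(steps) >= 2:
        return BleachStep(None, "multi", len(steps))
    return BleachStep(int(steps[0]), "single", 1)


# ---------------------------------------------------------------------------
# state fitting and dwell analysis
# ---------------------------------------------------------------------------


@dataclass
class StateFit:
    """Gaussian-mixture fit of pooled FRET efficiencies."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    bic: dict

    def __post_init__(self):
        order = np.argsort(self.means)
        self.means = np.asarray(self.means, float)[order]
        self.sds = np.asarray(self.sds, float)[order]
        self.weights = np.asarray(self.weights, float)[order]


def fit_states(e_values, k_max: int = 2, seed: int = 0,
               n_init: int = 10) -> StateFit:
    """One- or two-state Gaussian mixture on pooled E values, chosen by BIC."""
    from sklearn.mixture import GaussianMixture

    e = np.asarray(e_values, float)
    e = e[np.isfinite(e)].reshape(-1, 1)
    if e.shape[0] < 100:
        raise SamplingError(f"need >= 100 E values, got {e.shape[0]}")
    fits = {}
    bic = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, n_init=n_init, random_state=seed,
                             covariance_type="full", max_iter=500)
        gm.fit(e)
        if not gm.converged_:
            raise FitError(f"mixture fit with k={k} did not converge")
        fits[k] = gm
        bic[k] = float(gm.bic(e))
    best = min(bic, key=bic.get)
    gm = fits[best]
    return StateFit(best, gm.means_.ravel(),
                    np.sqrt(gm.covariances_.reshape(best)),
                    gm.weights_.ravel(), bic)


@dataclass
class DwellResult:
    """Transition statistics of one or more two-state traces."""

    transitions_per_s: float
    occupancy: np.ndarray
    n_transitions: int
    observation_s: float
    applicable: bool = True


def dwell_analysis(traces, fit: StateFit) -> DwellResult:
    """Transition rate and state occupancies by hysteresis assignment.

    Frames are assigned to the nearer state mean with a hysteresis band of
    one fitted sd around each mean (a switch requires crossing into the
    other state's band), which suppresses noise-induced chatter.  Accepts a
    single :class:`FretTrace` or an iterable of them.  With a one-state fit
    the result is flagged not applicable.
    """
    if isinstance(traces, FretTrace):
        traces = [traces]
    if fit.k < 2:
        return DwellResult(0.0, np.array([1.0]), 0, 0.0, applicable=False)
    m1, m2 = fit.means[0], fit.means[1]
    s1, s2 = fit.sds[0], fit.sds[1]
    up = m2 - s2      # must exceed to switch low -> high
    down = m1 + s1    # must fall below to switch high -> low
    if up <= down:    # bands overlap: fall back to the midpoint
        up = down = 0.5 * (m1 + m2)
    n_trans = 0
    time_s = 0.0
    occ_frames = np.zeros(2)
    for tr in traces:
        e = tr.valid_efficiencies
        e = e[np.isfinite(e)]
        if e.size < 2:
            continue
        state = 0 if abs(e[0] - m1) <= abs(e[0] - m2) else 1
        for v in e:
            if state == 0 and v > up:
                state = 1
                n_trans += 1
            elif state == 1 and v < down:
                state = 0
                n_trans += 1
            occ_frames[state] += 1
        time_s += e.size * tr.frame_s
    if time_s <= 0:
        raise SamplingError("no valid frames for dwell analysis")
    occ = occ_frames / occ_frames.sum()
    return DwellResult(n_trans / time_s, occ, n_trans, time_s)


# ---------------------------------------------------------------------------
# end-to-end trace analysis
# ---------------------------------------------------------------------------


def analyze_traces(traces, factors: CorrectionFactors,
                   require_single_bleach: bool = True) -> list:
    """Compute per-molecule FRET traces with bleach annotation and masking.

    The valid mask covers frames before the earliest detected bleach.  Donor
    bleach is detected on the recovered donor fluorescence ``D + F/gamma``,
    which is independent of the FRET state (raw D and F both jump at every
    state transition); acceptor bleach is detected on the direct-excitation
    acceptor series when available, else on the FRET channel.  Molecules
    with a multi-step channel are dropped when ``require_single_bleach`` is
    set.
    """
    out = []
    for tr in traces:
        total = recovered_donor(tr.donor, tr.fret, factors.gamma)
        don = detect_bleach_step(total)
        acc = _acceptor_bleach_step(tr)
        if require_single_bleach and ("multi" in (don.status, acc.status)):
            continue
        e, valid = fret_efficiency(tr.donor, tr.fret, tr.acceptor_series,
                                   factors)
        cut = len(tr)
        for step in (don, acc):
            if step.index is not None:
                cut = min(cut, step.index)
        mask = valid & (np.arange(len(tr)) < cut)
        out.append(FretTrace(tr.molecule_id, e, mask, don.index, acc.index,
                             tr.frame_s))
    return out


# ---------------------------------------------------------------------------
# accessible volume and distance prediction
# ---------------------------------------------------------------------------


@dataclass
class AVParams:
    """Dye linker geometry in Angstrom.

    Defaults are generic maleimide-linker values (single-sphere dye,
    straight-line reachability from the attachment atom); the exact settings
    used with any given dye pair should be supplied by the caller.
    """

    linker_length: float = 20.0
    linker_width: float = 4.5
    dye_radius: float = 3.5
    grid_pitch: float = 1.0
    atom_radius: float = 1.5

    def __post_init__(self):
        if self.linker_length <= self.dye_radius:
            raise ValueError("linker length must exceed dye radius")


@dataclass
class DyeCloud:
    """Sterically allowed dye positions around a labelled residue."""

    attachment: np.ndarray
    positions: np.ndarray
    weights: np.ndarray
    params: AVParams

    def __post_init__(self):
        self.attachment = np.asarray(self.attachment, float)
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.weights = np.asarray(self.weights, float)
        self.weights = self.weights / self.weights.sum()

    @property
    def centroid(self) -> np.ndarray:
        return (self.positions * self.weights[:, None]).sum(axis=0)


def _pseudo_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from backbone N, CA, C (for glycine)."""
    b = ca - n
    c2 = c - ca
    a = np.cross(b, c2)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c2 + ca


def accessible_volume(model: AtomicModel, chain: str, resnum: int,
                      params: AVParams | None = None) -> DyeCloud:
    """Uniform-weight accessible volume of a dye attached at a residue's CB.

    Candidate dye-center positions on a cubic grid within the linker length
    of the attachment point are kept if (i) the dye sphere does not clash
    with any model atom and (ii) the straight path from the attachment point
    is unobstructed at half the linker width.  The labelled residue's own
    side chain is removed (label replaces it); for glycine a pseudo-CB is
    constructed from the backbone.
    """
    params = params or AVParams()
    res_mask = (model.chain == chain) & (model.resnum == int(resnum))
    if not res_mask.any():
        raise BuriedSiteError(f"residue {chain}:{resnum} not in model")
    names = model.name[res_mask].astype(str)
    coords = model.coords[res_mask]
    if "CB" in names:
        attachment = coords[list(names).index("CB")]
    else:
        try:
            n = coords[list(names).index("N")]
            ca = coords[list(names).index("CA")]
            c = coords[list(names).index("C")]
        except ValueError as exc:
            raise BuriedSiteError(
                f"residue {chain}:{resnum} lacks CB and full backbone") from exc
        attachment = _pseudo_cbeta(n, ca, c)
    # obstruction set: everything except the labelled residue's atoms
    obstacles = model.coords[~res_mask]

    l, g = params.linker_length, params.grid_pitch
    ax = np.arange(-l, l + g / 2, g)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= l] + attachment

    if obstacles.shape[0]:
        tree = cKDTree(obstacles)
        clash_r = params.dye_radius + params.atom_radius
        d, _ = tree.query(pts, k=1)
        pts = pts[d > clash_r]
        # straight-line reachability at half linker width clearance
        if pts.shape[0]:
            clear = params.linker_width / 2.0 + params.atom_radius
            keep = np.ones(pts.shape[0], bool)
            n_samp = max(2, int(np.ceil(l / 1.0)))
            frac = np.linspace(0.0, 1.0, n_samp)[1:-1]
            for t in frac:
                mid = attachment + t * (pts - attachment)
                dmid, _ = tree.query(mid, k=1)
                # ignore obstruction right at the attachment exit
                near_exit = np.linalg.norm(mid - attachment, axis=1) \
                    < params.dye_radius
                keep &= (dmid > clear) | near_exit
            pts = pts[keep]
    if pts.shape[0] == 0:
        raise BuriedSiteError(
            f"no sterically allowed dye positions at {chain}:{resnum}")
    return DyeCloud(attachment, pts, np.full(pts.shape[0], 1.0), params)


@dataclass
class DistancePrediction:
    """FRET-weighted mean inter-dye distance and predicted efficiency."""

    mean_distance: float
    efficiency: float
    r0: float

    def __post_init__(self):
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("predicted efficiency outside [0, 1]")


def fret_of_distance(r, r0: float = R0_ALEXA555_647):
    """Foerster curve E(r) = 1 / (1 + (r/R0)^6)."""
    return 1.0 / (1.0 + (np.asarray(r, float) / r0) ** 6)


def distance_of_fret(e: float, r0: float = R0_ALEXA555_647) -> float:
    """Inverse Foerster curve; E -> R_E with E(R_E) = E."""
    e = float(np.clip(e, 1e-12, 1.0 - 1e-12))
    return r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


def mean_fret_distance(donor: DyeCloud, acceptor: DyeCloud,
                       r0: float = R0_ALEXA555_647,
                       max_pairs: int = 4_000_000,
                       seed: int = 0) -> DistancePrediction:
    """Predicted E averaged over dye position pairs, and R_E matching it.

    The predicted efficiency is the weighted average of E(r) over all
    donor/acceptor position pairs (dye reorientation is fast compared to
    transfer; position exchange is slow, hence averaging E, not r).  When
    the pair count exceeds ``max_pairs`` a seeded Monte-Carlo subsample of
    that size is used.  The FRET-weighted mean distance is the distance
    whose point efficiency equals the average.
    """
    n1, n2 = donor.positions.shape[0], acceptor.positions.shape[0]
    if n1 * n2 <= max_pairs:
        e_sum = 0.0
        w_sum = 0.0
        for i in range(0, n1, 2048):
            chunk = donor.positions[i:i + 2048]
            wd = donor.weights[i:i + 2048]
            diff = chunk[:, None, :] - acceptor.positions[None, :, :]
            r = np.sqrt((diff ** 2).sum(axis=2))
            w = wd[:, None] * acceptor.weights[None, :]
            e_sum += float((fret_of_distance(r, r0) * w).sum())
            w_sum += float(w.sum())
        e_mean = e_sum / w_sum
    else:
        rng = np.random.default_rng(seed)
        i = rng.choice(n1, size=max_pairs, p=donor.weights)
        j = rng.choice(n2, size=max_pairs, p=acceptor.weights)
        r = np.linalg.norm(donor.positions[i] - acceptor.positions[j], axis=1)
        e_mean = float(fret_of_distance(r, r0).mean())
    return DistancePrediction(distance_of_fret(e_mean, r0), float(e_mean), r0)


# ---------------------------------------------------------------------------
# trace I/O
# ---------------------------------------------------------------------------


def read_traces(path, frame_s: float = DEFAULT_FRAME_S) -> list:
    """Read traces from delimited text with columns molecule,frame,D,F,A."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"molecule", "frame", "D", "F", "A"}
    missing = required - set(df.columns)
    if missing:
        raise SamplingError(f"trace table missing columns {sorted(missing)}")
    out = []
    for mol, grp in df.groupby("molecule", sort=False):
        grp = grp.sort_values("frame")
        out.append(FluorescenceTrace(str(mol), grp["D"].to_numpy(),
                                     grp["F"].to_numpy(), grp["A"].to_numpy(),
                                     frame_s))
    return out


def write_traces(traces, path) -> None:
    """Write traces as CSV with columns molecule,frame,D,F,A."""
    import pandas as pd

    rows = []
    for tr in traces:
        a = tr.acceptor_series
        for k in range(len(tr)):
            rows.append({"molecule": tr.molecule_id, "frame": k,
                         "D": tr.donor[k], "F": tr.fret[k], "A": a[k]})
    pd.DataFrame(rows).to_csv(path, index=False)
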