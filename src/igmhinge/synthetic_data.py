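"""Ground-truth synthetic fixtures: toy hinge models, pivot-ensemble maps
with known angular ranges, and two-state FRET traces with known correction
factors and kinetics.

Every generator is deterministic given its seed; seeds are recorded in the
returned ground-truth objects so that outputs can be regenerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arc_quantifier import SubunitConfig
from .density_sim import (
    DensityMap,
    GridSpec,
    OrientationGrid,
    simulate_pivot_ensemble,
)
from .model_geometry import (
    AtomicModel,
    DomainSelection,
    PivotFrame,
    SelectionInterval,
)
from .smfret import CorrectionFactors, FluorescenceTrace

ARM_CHAINS = ("A", "B")
CORE_CHAIN = "X"


# ---------------------------------------------------------------------------
# hinge model and pivot maps
# ---------------------------------------------------------------------------


@dataclass
class HingeGroundTruth:
    """Generating parameters of a synthetic two-arm hinge.

    Angles in degrees, lengths in Angstrom.  The defaults are the conditions
    of the motion-range study: pivoting over +-50 deg on both axes at 10 deg
    steps with the two arms splayed 50 deg in the out-of-plane direction.
    """

    in_plane_range: float = 50.0
    out_of_plane_range: float = 50.0
    splay: float = 50.0
    arm_length: float = 90.0
    step: float = 10.0
    noise_sd_rel: float = 0.0
    seed: int = 0
    arm_start: float = 8.0
    atom_spacing: float = 2.5

    def __post_init__(self):
        if self.in_plane_range < 0 or self.out_of_plane_range < 0:
            raise ValueError("angular ranges must be non-negative")
        if not 0.0 <= self.splay <= 180.0:
            raise ValueError("splay must be in [0, 180] degrees")
        if self.arm_length <= 0:
            raise ValueError("arm length must be positive")


def make_toy_hinge_model(truth: HingeGroundTruth) -> tuple:
    """Deterministic two-arm rigid body attached to a planar core slab.

    The pivot sits at the origin; the core platform lies in the z = 0 plane
    on the negative-x side; the two arms (chains A and B) emanate from the
    pivot along +x, splayed symmetrically out of plane by +-splay/2.  The
    returned frame has the in-plane zero axis along +x and the platform
    normal along +z, so the arms' rest bisector measures (alpha, beta) =
    (0, 0).
    """
    atoms = []
    # anchor atom at the pivot (stand-in for the Cmu2 C-terminus)
    atoms.append((CORE_CHAIN, 1, "PIV", "CA", "C", (0.0, 0.0, 0.0)))
    res = 2
    for x in np.arange(-24.0, -3.9, 4.0):
        for y in np.arange(-10.0, 10.1, 4.0):
            atoms.append((CORE_CHAIN, res, "COR", "CA", "C", (x, y, 0.0)))
            res += 1
    half = np.radians(truth.splay / 2.0)
    radii = np.arange(truth.arm_start, truth.arm_length + 1e-9,
                      truth.atom_spacing)
    for chain, sign in zip(ARM_CHAINS, (+1.0, -1.0)):
        d = np.array([np.cos(half), 0.0, sign * np.sin(half)])
        for i, r in enumerate(radii, start=1):
            atoms.append((chain, i, "ARM", "CA", "C", tuple(r * d)))
    model = AtomicModel.from_atoms(
        atoms, metadata=f"toy hinge (splay={truth.splay:g} deg)")
    frame = PivotFrame(pivot=(0.0, 0.0, 0.0), in_plane_zero=(1.0, 0.0, 0.0),
                       plane_normal=(0.0, 0.0, 1.0), beta_sign=1)
    return model, frame


def arm_selection(truth: HingeGroundTruth) -> DomainSelection:
    """Selection of the mobile arms (everything that pivots)."""
    n = int((truth.arm_length - truth.arm_start) / truth.atom_spacing) + 2
    return DomainSelection.of(
        SelectionInterval("A", 1, n), SelectionInterval("B", 1, n))


def make_pivot_map(model: AtomicModel, frame: PivotFrame,
                   truth: HingeGroundTruth,
                   voxel_size: float = 2.0, atom_sigma: float = 2.0,
                   extent_factor: float = 1.65,
                   include_core: bool = False) -> tuple:
    """Pivot-ensemble density of the toy hinge with optional voxel noise.

    Renders the mobile arms averaged over the truth's +-range orientation
    grid.  The static core platform is excluded by default: it is not part
    of the moving cloud and would dominate the grey-value dynamic range.
    Additive i.i.d. Gaussian voxel noise has sd ``noise_sd_rel`` times the
    clean map's peak; the truth's seed drives the noise generator.
    """
    grid = GridSpec.cube_around(frame.pivot,
                                extent_factor * truth.arm_length, voxel_size)
    orientations = OrientationGrid.regular(truth.in_plane_range,
                                           truth.out_of_plane_range,
                                           truth.step)
    mobile = arm_selection(truth)
    if include_core:
        density = simulate_pivot_ensemble(model, frame, orientations, grid,
                                          atom_sigma, mobile=mobile)
    else:
        arms = model.subset(mobile.mask(model))
        density = simulate_pivot_ensemble(arms, frame, orientations, grid,
                                          atom_sigma)
    if truth.noise_sd_rel > 0:
        rng = np.random.default_rng(truth.seed)
        sd = truth.noise_sd_rel * float(density.values.max())
        density.values = density.values + rng.normal(0.0, sd,
                                                     density.values.shape)
    return density, truth


def toy_subunit_config(truth: HingeGroundTruth, **overrides) -> SubunitConfig:
    """Quantifier configuration matched to the toy hinge geometry.

    Arc radii are fractions of the arm length: the outer (variable-domain)
    arc at 0.85 and the inner (constant-domain) arc at 0.45 of the arm tip
    radius.
    """
    cfg = dict(label="toy",
               radii={"inner": 0.45 * truth.arm_length,
                      "outer": 0.85 * truth.arm_length},
               boundary_arc="outer")
    cfg.update(overrides)
    return SubunitConfig(**cfg)


# ---------------------------------------------------------------------------
# FRET traces
# ---------------------------------------------------------------------------


@dataclass
class FretGroundTruth:
    """Generating parameters of two-state FRET traces.

    The channel model inverts the efficiency equation: for true state
    efficiency E and total donor-excited intensity I,
    ``D = I (1 - E)``, ``F = gamma I E + alpha D + beta A`` and ``A`` is the
    constant direct-excitation acceptor intensity.  Noise is Gaussian with
    variance proportional to intensity (Poisson surrogate); photobleaching
    of either dye is a single step at an exponentially distributed time.
    """

    e_states: tuple = (0.35, 0.75)
    k12: float = 2.0                      # low -> high rate, 1/s
    k21: float = 2.0                      # high -> low rate, 1/s
    factors: CorrectionFactors = field(default_factory=CorrectionFactors)
    total_intensity: float = 300.0
    acceptor_intensity: float = 150.0     # direct-excitation snapshot level
    noise_scale: float = 1.0              # shot noise: sd ~ sqrt(intensity)
    read_noise_sd: float = 5.0            # camera read noise, counts
    donor_bleach_mean_s: float = 10.0
    acceptor_bleach_mean_s: float = 5.0
    frame_s: float = 0.030
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 < e < 1.0 for e in self.e_states):
            raise ValueError("state efficiencies must be in (0, 1)")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimulatedTrace:
    """A simulated trace with its per-frame ground-truth labels."""

    trace: FluorescenceTrace
    state_labels: np.ndarray
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None


def _markov_states(rng, truth: FretGroundTruth, n_frames: int) -> np.ndarray:
    """Per-frame state indices of the two-state continuous-time chain."""
    k12, k21 = truth.k12, truth.k21
    total = k12 + k21
    if total <= 0:
        state = int(rng.integers(0, len(truth.e_states)))
        return np.full(n_frames, state)
    p0 = k21 / total
    state = 0 if rng.random() < p0 else 1
    t = float(rng.exponential(1.0 / (k12 if state == 0 else k21)))
    out = np.empty(n_frames, int)
    dt = truth.frame_s
    now = 0.0
    for i in range(n_frames):
        out[i] = state
        now += dt
        while t <= now:
            state = 1 - state
            t += float(rng.exponential(1.0 / (k12 if state == 0 else k21)))
    return out


def simulate_fret_traces(truth: FretGroundTruth, n_molecules: int = 100,
                         duration_s: float = 10.0) -> list:
    """Simulate two-state FRET traces with bleed-through and bleaching.

    Returns a list of :class:`SimulatedTrace`.  Applying the corrected
    efficiency equation with the true factors to noise-free pre-bleach
    frames returns the true state efficiencies exactly (model inversion).
    """
    rng = np.random.default_rng(truth.seed)
    fac = truth.factors
    n_frames = int(round(duration_s / truth.frame_s))
    e_states = np.asarray(truth.e_states, float)
    out = []
    for m in range(n_molecules):
        states = _markov_states(rng, truth, n_frames)
        t_acc = float(rng.exponential(truth.acceptor_bleach_mean_s))
        t_don = float(rng.exponential(truth.donor_bleach_mean_s))
        times = np.arange(n_frames) * truth.frame_s
        i_tot = truth.total_intensity
        a0 = truth.acceptor_intensity
        e = e_states[states]
        d = i_tot * (1.0 - e)
        a = np.full(n_frames, a0)
        f = fac.gamma * i_tot * e + fac.donor_bleed * d \
            + fac.direct_excitation * a
        acc_bleached = times >= t_acc
        don_bleached = times >= t_don
        # acceptor gone: no transfer, donor fully recovered, bleed remains
        d = np.where(acc_bleached, i_tot, d)
        f = np.where(acc_bleached, fac.donor_bleed * i_tot, f)
        a = np.where(acc_bleached, 0.0, a)
        # donor gone: donor-excited channels dark
        d = np.where(don_bleached, 0.0, d)
        f = np.where(don_bleached, 0.0, f)
        if truth.noise_scale > 0 or truth.read_noise_sd > 0:
            for arr in (d, f, a):
                sd = np.sqrt(truth.noise_scale ** 2 * np.maximum(arr, 0.0)
                             + truth.read_noise_sd ** 2)
                arr += rng.normal(0.0, 1.0, arr.shape) * sd
        acc_frame = int(np.argmax(acc_bleached)) if acc_bleached.any() else None
        don_frame = int(np.argmax(don_bleached)) if don_bleached.any() else None
        trace = FluorescenceTrace(f"mol{m:04d}", d, f, a, truth.frame_s)
        out.append(SimulatedTrace(trace, states, don_frame, acc_frame))
    return out


def simulate_reference_traces(truth: FretGroundTruth, kind: str,
                              n_molecules: int = 20,
                              duration_s: float = 3.0) -> list:
    """Donor-only or acceptor-only control traces for factor calibration."""
    rng = np.random.default_rng(truth.seed + 1 if kind == "donor-only"
                                else truth.seed + 2)
    fac = truth.factors
    n_frames = int(round(duration_s / truth.frame_s))
    out = []
    for m in range(n_molecules):
        if kind == "donor-only":
            d = np.full(n_frames, truth.total_intensity)
            f = fac.donor_bleed * d
            a = np.zeros(n_frames)
        elif kind == "acceptor-only":
            d = np.zeros(n_frames)
            a = np.full(n_frames, truth.acceptor_intensity)
            f = fac.direct_excitation * a
        else:
            raise ValueError(f"unknown control kind {kind!r}")
        if truth.noise_scale > 0 or truth.read_noise_sd > 0:
            for arr in (d, f, a):
                sd = np.sqrt(truth.noise_scale ** 2 * np.maximum(arr, 0.0)
                             + truth.read_noise_sd ** 2)
                arr += rng.normal(0.0, 1.0, arr.shape) * sd
        out.append(FluorescenceTrace(f"{kind}{m:03d}", d, f, a, truth.frame_s))
    return out
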