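"""Brownian-dynamics confocal photon-trace simulator and synthetic
titration generators — the data source for validating every analysis
step against a known ground truth.

Molecules perform free Brownian motion (Gaussian steps of variance
2 D dt per axis) in a periodic cubic box containing a Gaussian detection
volume W(r) = exp(-2 (x^2+y^2)/w_xy^2 - 2 z^2/w_z^2). Per time bin, each
molecule's expected photon count is brightness x W at its position;
photons are Poisson-distributed and split between donor and acceptor
channels with acceptor probability equal to the molecule's FRET
efficiency (a binomial split of a Poisson count is two independent
Poisson streams, which is how it is drawn). Uniform Poisson background
is added per channel. The simulator logs, per millisecond-scale bin, the
expected photon count of every molecule, from which ground-truth transit
windows and the dominant molecule under any burst are read off.

The titration generator evaluates the mass-action models of
:mod:`pscfcs.equilibria` on a concentration grid and adds Gaussian
noise, emulating the binding-curve experiments at the level of their
observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .hydro import FocusGeometry
from .trace import BackgroundModel, BinnedTrace
from . import equilibria

__all__ = [
    "MoleculeSpec",
    "SimulationConfig",
    "GroundTruthLog",
    "simulate_confocal_smd",
    "synth_equilibrium_data",
]


@dataclass(frozen=True)
class MoleculeSpec:
    """One simulated fluorescent species.

    ``e_true`` is the acceptor branching probability (the theoretical
    FRET efficiency); ``brightness`` the expected photons per time bin
    for a molecule at the focus centre; ``count`` how many independent
    molecules of this species diffuse in the box. ``immobile`` clamps
    the molecules at the focus centre (calibration aid).
    """

    e_true: float
    diffusion_coefficient: float
    brightness: float
    count: int = 1
    immobile: bool = False

    def __post_init__(self):
        if not 0 <= self.e_true <= 1:
            raise InvalidArgumentError("e_true must lie in [0, 1]")
        if self.diffusion_coefficient <= 0:
            raise InvalidArgumentError("diffusion coefficient must be > 0")
        if self.brightness <= 0:
            raise InvalidArgumentError("brightness must be > 0")
        if self.count < 1:
            raise InvalidArgumentError("count must be >= 1")

    @classmethod
    def from_tau(
        cls, e_true: float, tau: float, focus: FocusGeometry, brightness: float,
        count: int = 1,
    ) -> "MoleculeSpec":
        """Specify the species by its diffusion time through ``focus``
        (tau = w_xy^2 / 4D)."""
        if tau <= 0:
            raise InvalidArgumentError("tau must be > 0")
        d = focus.waist**2 / (4.0 * tau)
        return cls(e_true=e_true, diffusion_coefficient=d, brightness=brightness, count=count)


@dataclass(frozen=True)
class SimulationConfig:
    """Box, focus, timing, background and seed of one simulation run.

    The periodic box is elongated along the optical axis so that the
    detection weight at the wrap plane is negligible, and the lateral
    edges are wide enough (24 waists) that periodic recurrence truncates
    the correlation tail only a few percent inside the 1 s fit window;
    the default detection volume has an axial ratio w_z/w_xy = 10, for
    which a two-dimensional diffusion model describes the correlation
    decay to about 2%. ``dynamics_stride`` is the number of photon bins
    between Brownian position updates; the default stride of 4 (3.8 us
    at the 0.96 us binning) resolves the ~150 us focal transits
    comfortably and sits below the 10 us lower edge of the FCS fit
    window (the per-update r.m.s. displacement is ~30 nm, an eighth of
    the focal waist).
    """

    duration: float
    seed: int
    box_edges: tuple[float, float, float] = (6.0e-6, 6.0e-6, 10.0e-6)
    focus: FocusGeometry = field(
        default_factory=lambda: FocusGeometry(waist=0.25e-6, axial=2.5e-6)
    )
    time_step: float = 0.96e-6
    background: BackgroundModel = field(default_factory=lambda: BackgroundModel(2e-4, 2e-4))
    ground_truth_factor: int | None = None  # coarse bins for the log; default ~1 ms
    dynamics_stride: int = 4
    # optional spectral leakage: fraction of donor photons registered in
    # the acceptor channel, and direct acceptor excitation as a fraction
    # of the molecule's brightness added to the acceptor channel
    donor_leak: float = 0.0
    direct_excitation: float = 0.0
    # optional two-state (on/off) emission dynamics, (k_on, k_off) in 1/s;
    # produces the exponential relaxation term of the 2D1R model
    blinking: tuple[float, float] | None = None

    def __post_init__(self):
        if self.time_step <= 0:
            raise InvalidArgumentError("time_step must be > 0")
        if self.duration < self.time_step:
            raise InvalidArgumentError("duration must cover at least one bin")
        edges = tuple(float(e) for e in np.broadcast_to(self.box_edges, (3,)))
        object.__setattr__(self, "box_edges", edges)
        if edges[0] < 3 * self.focus.waist or edges[1] < 3 * self.focus.waist:
            raise InvalidArgumentError("lateral box edges must be several times the waist")
        if edges[2] < 3 * self.focus.axial:
            raise InvalidArgumentError("axial box edge must be several times the axial extent")
        if self.dynamics_stride < 1:
            raise InvalidArgumentError("dynamics_stride must be >= 1")
        if not 0 <= self.donor_leak < 1:
            raise InvalidArgumentError("donor_leak must lie in [0, 1)")
        if self.direct_excitation < 0:
            raise InvalidArgumentError("direct_excitation must be >= 0")
        if self.blinking is not None and min(self.blinking) <= 0:
            raise InvalidArgumentError("blinking rates must be > 0")

    @property
    def n_bins(self) -> int:
        return int(self.duration / self.time_step)

    @property
    def gt_factor(self) -> int:
        if self.ground_truth_factor is not None:
            return self.ground_truth_factor
        return max(1, int(round(1e-3 / self.time_step)))


@dataclass
class GroundTruthLog:
    """Per-molecule expected photon counts on a coarse (~1 ms) grid,
    plus species identities; transit windows and burst attribution are
    derived views."""

    coarse_intensity: np.ndarray  # (n_coarse, n_molecules) expected photons
    coarse_bin_width: float  # seconds
    e_true: np.ndarray  # (n_molecules,)
    brightness: np.ndarray  # (n_molecules,) photons per fine bin at centre
    fine_per_coarse: int

    @property
    def n_molecules(self) -> int:
        return self.coarse_intensity.shape[1]

    def transit_windows(
        self, molecule: int, rel_cutoff: float = np.exp(-2)
    ) -> list[tuple[int, int]]:
        """Contiguous coarse-bin runs where the molecule's expected count
        exceeds ``rel_cutoff`` of its maximal per-coarse-bin emission
        (default: the 1/e^2 surface of the detection profile)."""
        peak = self.brightness[molecule] * self.fine_per_coarse
        above = self.coarse_intensity[:, molecule] >= rel_cutoff * peak
        edges = np.diff(above.astype(np.int8), prepend=0, append=0)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        return list(zip(starts.tolist(), ends.tolist()))

    def window_peak_intensity(self, molecule: int, window: tuple[int, int]) -> float:
        """Peak expected photons per coarse bin of a molecule within a
        coarse-bin window."""
        s, e = window
        return float(self.coarse_intensity[s:e, molecule].max())

    def dominant_molecule(self, start: int, end: int) -> int:
        """Molecule contributing the most expected photons over a coarse
        window [start, end)."""
        return int(self.coarse_intensity[start:end].sum(axis=0).argmax())

    def dominant_species(self, start: int, end: int) -> float:
        """``e_true`` of the dominant molecule over a coarse window."""
        return float(self.e_true[self.dominant_molecule(start, end)])


def _telegraph_states(rng, state0: int, n_steps: int, k_on: float, k_off: float,
                      dt: float) -> np.ndarray:
    """Alternating-sojourn sampling of a two-state (0/1) Markov emitter
    at step resolution. Sojourns are exponential with rates k_on (leaving
    the dark state) and k_off (leaving the bright state), rounded up to
    whole steps. Because the exponential law is memoryless, restarting
    the sojourn clock at chunk boundaries is statistically exact."""
    est = max(int(n_steps * dt * (k_on + k_off) * 2) + 16, 16)
    while True:
        order = np.arange(est) % 2
        states = np.where(order == 0, state0, 1 - state0)
        scales = np.where(states == 1, 1.0 / k_off, 1.0 / k_on)
        lens = np.maximum(
            np.ceil(rng.exponential(scales) / dt).astype(np.int64), 1
        )
        if lens.sum() >= n_steps:
            return np.repeat(states, lens)[:n_steps]
        est *= 2


def simulate_confocal_smd(
    molecules: Sequence[MoleculeSpec], config: SimulationConfig
) -> tuple[BinnedTrace, GroundTruthLog]:
    """Simulate a two-channel photon trace of freely diffusing labelled
    molecules in a confocal detection volume.

    Fully reproducible for a fixed ``config.seed``. Returns the binned
    trace at ``config.time_step`` and the ground-truth log on the coarse
    grid (default ~1 ms).
    """
    if not molecules:
        raise InvalidArgumentError("at least one molecule species required")
    specs = list(molecules)
    e_mol = np.concatenate([[m.e_true] * m.count for m in specs])
    d_mol = np.concatenate([[m.diffusion_coefficient] * m.count for m in specs])
    b_mol = np.concatenate([[m.brightness] * m.count for m in specs])
    imm_mol = np.concatenate([[m.immobile] * m.count for m in specs]).astype(bool)
    n_mol = len(e_mol)
    n_bins = config.n_bins
    dt = config.time_step
    stride = config.dynamics_stride
    edges = np.asarray(config.box_edges)
    wxy2 = config.focus.waist**2
    wz2 = config.focus.axial**2
    # per-axis displacement scale per Brownian update (stride fine bins)
    step_sigma = np.sqrt(2.0 * d_mol * dt * stride)

    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(-edges / 2, edges / 2, size=(n_mol, 3))
    pos[imm_mol] = 0.0
    blink_state = None
    if config.blinking is not None:
        k_on, k_off = config.blinking
        p_on = k_on / (k_on + k_off)
        blink_state = (rng.uniform(size=n_mol) < p_on).astype(np.int64)

    gt_factor = config.gt_factor
    n_coarse = int(np.ceil(n_bins / gt_factor))
    gt = np.zeros((n_coarse, n_mol))

    donor = np.empty(n_bins, dtype=np.int32)
    acceptor = np.empty(n_bins, dtype=np.int32)

    # group molecules by e_true: the binomial donor/acceptor split of a
    # Poisson emission equals two independent Poisson streams with rates
    # (1-e) lam and e lam, so channels are drawn directly per species
    unique_e = np.unique(e_mol)
    groups = [(e, np.flatnonzero(e_mol == e)) for e in unique_e]

    chunk_bins = stride * 65536
    mobile = ~imm_mol
    # trajectories in float32, laid out (molecule, axis, step) so the
    # cumulative sum runs along the contiguous axis
    sigma32 = step_sigma.astype(np.float32)
    edges32 = edges.astype(np.float32)[None, :, None]
    for start in range(0, n_bins, chunk_bins):
        stop = min(start + chunk_bins, n_bins)
        n = stop - start
        n_steps = -(-n // stride)
        lam_step = np.empty((n_mol, n_steps))
        if mobile.any():
            k = int(mobile.sum())
            steps = rng.standard_normal(size=(k, 3, n_steps), dtype=np.float32)
            steps *= sigma32[mobile][:, None, None]
            traj = np.cumsum(steps, axis=2)
            traj += pos[mobile].astype(np.float32)[:, :, None]
            traj -= edges32 * np.round(traj / edges32)  # periodic wrap
            pos[mobile] = traj[:, :, -1]
            w = np.exp(
                -2.0 * (traj[:, 0] ** 2 + traj[:, 1] ** 2) / wxy2
                - 2.0 * traj[:, 2] ** 2 / wz2
            )
            lam_step[mobile] = b_mol[mobile][:, None] * w
        if imm_mol.any():
            lam_step[imm_mol] = b_mol[imm_mol][:, None]
        if blink_state is not None:
            dt_step = dt * stride
            for mol in range(n_mol):
                seq = _telegraph_states(
                    rng, int(blink_state[mol]), n_steps, k_on, k_off, dt_step
                )
                lam_step[mol] *= seq
                blink_state[mol] = seq[-1]

        # photon draws per fine bin; positions are held between updates
        d_counts = rng.poisson(config.background.donor_rate, size=n)
        a_counts = rng.poisson(config.background.acceptor_rate, size=n)
        for e, idx in groups:
            lam = np.repeat(lam_step[idx].sum(axis=0), stride)[:n]
            p_donor = (1.0 - e) * (1.0 - config.donor_leak)
            p_acceptor = e + (1.0 - e) * config.donor_leak + config.direct_excitation
            if p_donor > 0:
                d_counts += rng.poisson(p_donor * lam)
            if p_acceptor > 0:
                a_counts += rng.poisson(p_acceptor * lam)
        donor[start:stop] = d_counts
        acceptor[start:stop] = a_counts

        # expected counts accumulated on the coarse ground-truth grid at
        # step resolution (each step covers `stride` fine bins; the
        # sub-step misalignment with coarse-bin edges is < 1% of a bin)
        step_bins = np.minimum(
            np.arange(n_steps) * stride + stride, n
        ) - np.arange(n_steps) * stride
        coarse_idx = (start + np.arange(n_steps) * stride) // gt_factor
        bounds = np.concatenate([[0], np.flatnonzero(np.diff(coarse_idx)) + 1])
        gt[coarse_idx[bounds]] += np.add.reduceat(
            (lam_step * step_bins[None, :]).T, bounds, axis=0
        )

    trace = BinnedTrace(bin_width=dt, donor=donor, acceptor=acceptor)
    log = GroundTruthLog(
        coarse_intensity=gt,
        coarse_bin_width=dt * gt_factor,
        e_true=e_mol,
        brightness=b_mol,
        fine_per_coarse=gt_factor,
    )
    return trace, log


def synth_equilibrium_data(
    kind: str,
    true_params,
    concentrations: Sequence[float],
    sigma: float,
    replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Synthetic titration tables for the equilibrium fitting routines.

    ``kind`` selects the model: ``"trimer_titration"`` (observable
    n = 1 + 2f, concentrations in nM, ``true_params`` a
    :class:`~pscfcs.equilibria.TrimerEquilibrium`), ``"hill"``
    (observable p, concentrations in the K_D units, ``true_params`` a
    :class:`~pscfcs.equilibria.HillBinding`), or ``"second_trimer"``
    (observable f, concentrations in uM, ``true_params`` a
    :class:`~pscfcs.equilibria.SecondTrimerBinding`). Independent
    Gaussian noise of standard deviation ``sigma`` is added; the result
    is a long-format DataFrame with columns (concentration, observable,
    replicate), deterministic under ``seed``.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if kind == "trimer_titration":
        f = np.array([equilibria.trimer_species(true_params, c)[2] for c in conc])
        clean = 1.0 + 2.0 * f
    elif kind == "hill":
        clean = equilibria.hill_fraction(true_params, conc)
    elif kind == "second_trimer":
        clean = equilibria.second_trimer_fraction(true_params, conc)
    else:
        raise InvalidArgumentError(f"unknown titration kind {kind!r}")
    if sigma < 0:
        raise InvalidArgumentError("noise sigma must be >= 0")
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        noisy = clean + rng.normal(0.0, sigma, size=len(conc)) if sigma > 0 else clean.copy()
        for c, y in zip(conc, np.atleast_1d(noisy)):
            rows.append({"concentration": c, "observable": y, "replicate": rep})
    return pd.DataFrame(rows, columns=["concentration", "observable", "replicate"])
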