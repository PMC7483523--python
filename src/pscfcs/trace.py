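"""Two-channel binned fluorescence traces and burst-level preprocessing.

The raw object of every analysis here is a pair of aligned photon-count
time series — donor and acceptor detection channels binned at a fixed bin
width. Confocal acquisition uses microsecond bins (default 0.96 us); burst
analysis and smFRET histogramming use millisecond bins. This module holds
the trace container, rebinning between the two time bases, burst detection
by a peak threshold on the summed channels, background-rate estimation
from the inter-burst bins, and the Poisson replacement step in which all
bins outside a kept selection are redrawn from the background statistics.

Burst definition: a maximal run of consecutive bins whose donor+acceptor
count is at or above the peak threshold. Bins in no burst are background
bins; together the two sets partition the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError

__all__ = [
    "BinnedTrace",
    "Burst",
    "BackgroundModel",
    "rebin",
    "detect_bursts",
    "background_corrected_efficiency",
    "estimate_background",
    "poisson_masked_trace",
    "burst_windows_to_fine",
    "read_trace",
    "write_trace",
    "bursts_to_table",
]


@dataclass(frozen=True)
class BinnedTrace:
    """Aligned donor/acceptor photon counts on a uniform time grid.

    Parameters
    ----------
    bin_width : float
        Bin width in seconds, > 0.
    donor, acceptor : array-like of int
        Non-negative photon counts per bin; equal length.
    direct_acceptor : array-like of int, optional
        Acceptor counts under direct (red) excitation for alternating
        excitation data; same length when present.
    origin_time : float
        Time of the first bin edge in seconds.
    """

    bin_width: float
    donor: np.ndarray
    acceptor: np.ndarray
    direct_acceptor: np.ndarray | None = None
    origin_time: float = 0.0

    def __post_init__(self):
        if not self.bin_width > 0:
            raise InvalidArgumentError(f"bin_width must be > 0, got {self.bin_width}")
        for name in ("donor", "acceptor", "direct_acceptor"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.ascontiguousarray(arr)
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(arr == np.floor(arr)):
                    raise InvalidArgumentError(f"{name} counts must be integral")
                arr = arr.astype(np.int32)
            if arr.ndim != 1:
                raise InvalidArgumentError(f"{name} must be one-dimensional")
            if arr.size and arr.min() < 0:
                raise InvalidArgumentError(f"{name} counts must be non-negative")
            object.__setattr__(self, name, arr)
        if len(self.donor) != len(self.acceptor):
            raise InvalidArgumentError("donor and acceptor must have equal length")
        if self.direct_acceptor is not None and len(self.direct_acceptor) != len(self.donor):
            raise InvalidArgumentError("direct_acceptor length mismatch")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def n_bins(self) -> int:
        return len(self.donor)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_bins * self.bin_width

    def channel_sum(self) -> np.ndarray:
        """Donor + acceptor counts per bin (the anti-correlation-free sum)."""
        return self.donor + self.acceptor


@dataclass(frozen=True)
class Burst:
    """A contiguous above-threshold segment of a trace.

    ``start_bin`` is inclusive, ``end_bin`` exclusive; ``e_app`` is the
    apparent FRET efficiency acceptor/(donor+acceptor) of the burst,
    optionally background-corrected (then it may fall below zero).
    """

    start_bin: int
    end_bin: int
    donor_sum: int
    acceptor_sum: int
    e_app: float

    def __post_init__(self):
        if self.end_bin <= self.start_bin:
            raise InvalidArgumentError("end_bin must exceed start_bin")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def total(self) -> int:
        return self.donor_sum + self.acceptor_sum


@dataclass(frozen=True)
class BackgroundModel:
    """Per-channel Poisson background rates in counts per bin."""

    donor_rate: float
    acceptor_rate: float

    def __post_init__(self):
        if self.donor_rate < 0 or self.acceptor_rate < 0:
            raise InvalidArgumentError("background rates must be >= 0")

    def scaled(self, factor: float) -> "BackgroundModel":
        """Rates rescaled to a different bin width (rate per bin is
        proportional to the bin width)."""
        return BackgroundModel(self.donor_rate * factor, self.acceptor_rate * factor)


def _rebin_channel(arr: np.ndarray, factor: int) -> np.ndarray:
    n = (len(arr) // factor) * factor
    return arr[:n].reshape(-1, factor).sum(axis=1, dtype=np.int64)


def rebin(trace: BinnedTrace, factor: int) -> BinnedTrace:
    """Sum ``factor`` consecutive bins into one.

    Bridges the fine acquisition binning and the coarser burst-analysis
    binning. A trailing remainder shorter than ``factor`` is dropped, so
    total counts are conserved up to that remainder.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise InvalidArgumentError(f"rebin factor must be a positive integer, got {factor}")
    if len(trace) < factor:
        raise InvalidArgumentError("trace shorter than rebin factor")
    if factor == 1:
        return trace
    direct = None
    if trace.direct_acceptor is not None:
        direct = _rebin_channel(trace.direct_acceptor, factor)
    return BinnedTrace(
        bin_width=trace.bin_width * factor,
        donor=_rebin_channel(trace.donor, factor),
        acceptor=_rebin_channel(trace.acceptor, factor),
        direct_acceptor=direct,
        origin_time=trace.origin_time,
    )


def _raw_e_app(donor_sum: float, acceptor_sum: float) -> float:
    total = donor_sum + acceptor_sum
    if total <= 0:
        return float("nan")
    return acceptor_sum / total


def detect_bursts(trace: BinnedTrace, peak_threshold: float) -> list[Burst]:
    """Find maximal runs of bins with donor+acceptor >= ``peak_threshold``.

    Returns disjoint bursts ordered by start bin, each carrying its raw
    channel sums and apparent FRET efficiency. Background correction of
    the efficiency, when wanted, is applied afterwards with
    :func:`background_corrected_efficiency`.
    """
    if peak_threshold < 0:
        raise InvalidArgumentError("peak_threshold must be >= 0")
    if len(trace) == 0:
        return []
    above = trace.channel_sum() >= peak_threshold
    if not above.any():
        return []
    # run boundaries of the boolean mask
    padded = np.diff(above.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    cs_d = np.concatenate([[0], np.cumsum(trace.donor, dtype=np.int64)])
    cs_a = np.concatenate([[0], np.cumsum(trace.acceptor, dtype=np.int64)])
    bursts = []
    for s, e in zip(starts, ends):
        d = int(cs_d[e] - cs_d[s])
        a = int(cs_a[e] - cs_a[s])
        bursts.append(Burst(int(s), int(e), d, a, _raw_e_app(d, a)))
    return bursts


def background_corrected_efficiency(
    bursts: Iterable[Burst], background: BackgroundModel
) -> list[Burst]:
    """Recompute each burst's ``e_app`` after subtracting the expected
    background (rate x burst length) from both channel sums.

    The corrected efficiency may be negative (acceptor below background,
    as for a donor-only dye); it is clipped to [-1, 1]. Bursts whose
    corrected total signal is non-positive get ``e_app = nan``.
    """
    out = []
    for b in bursts:
        d = b.donor_sum - background.donor_rate * b.n_bins
        a = b.acceptor_sum - background.acceptor_rate * b.n_bins
        total = d + a
        e = float("nan") if total <= 0 else float(np.clip(a / total, -1.0, 1.0))
        out.append(replace(b, e_app=e))
    return out


def _background_mask(n_bins: int, bursts: Iterable[Burst]) -> np.ndarray:
    mask = np.ones(n_bins, dtype=bool)
    for b in bursts:
        mask[b.start_bin : b.end_bin] = False
    return mask


def estimate_background(trace: BinnedTrace, bursts: Iterable[Burst]) -> BackgroundModel:
    """Per-channel mean count over the bins outside every burst."""
    mask = _background_mask(len(trace), bursts)
    n_bg = int(mask.sum())
    if n_bg == 0:
        raise DegenerateInputError("no background bins: every bin lies in a burst")
    return BackgroundModel(
        donor_rate=float(trace.donor[mask].mean()),
        acceptor_rate=float(trace.acceptor[mask].mean()),
    )


def _as_windows(keep) -> list[tuple[int, int]]:
    windows = []
    for item in keep:
        if isinstance(item, Burst):
            windows.append((item.start_bin, item.end_bin))
        else:
            s, e = item
            windows.append((int(s), int(e)))
    windows.sort()
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if s1 < e0:
            raise InvalidArgumentError(f"overlapping keep windows: ({s0},{e0}) and ({s1},{e1})")
    return windows


def poisson_masked_trace(
    trace: BinnedTrace,
    keep,
    background: BackgroundModel,
    seed: int,
) -> BinnedTrace:
    """Copy kept windows verbatim; redraw every other bin from the
    per-channel Poisson background.

    This is the replacement step of subpopulation-selective FCS: the
    trace segments assigned to the chosen subpopulation survive
    bit-exactly while everything else is exchanged for synthetic
    background with the measured rates. Deterministic for a fixed seed.

    ``keep`` may hold :class:`Burst` objects or ``(start, end)`` bin
    windows; windows must not overlap and must lie inside the trace.
    """
    windows = _as_windows(keep)
    n = len(trace)
    for s, e in windows:
        if s < 0 or e > n or e <= s:
            raise InvalidArgumentError(f"keep window ({s},{e}) outside trace of {n} bins")
    rng = np.random.default_rng(seed)
    donor = rng.poisson(background.donor_rate, size=n).astype(np.int32, copy=False)
    acceptor = rng.poisson(background.acceptor_rate, size=n).astype(np.int32, copy=False)
    for s, e in windows:
        donor[s:e] = trace.donor[s:e]
        acceptor[s:e] = trace.acceptor[s:e]
    return BinnedTrace(
        bin_width=trace.bin_width,
        donor=donor,
        acceptor=acceptor,
        origin_time=trace.origin_time,
    )


def burst_windows_to_fine(
    bursts: Iterable[Burst], factor: int, n_fine: int | None = None
) -> list[tuple[int, int]]:
    """Map burst windows on a coarse (rebinned) trace back to bin windows
    on the underlying fine trace.

    Coarse bin ``i`` covers fine bins ``[i*factor, (i+1)*factor)``.
    Adjacent or overlapping windows are merged. ``n_fine`` clips the last
    window to the fine-trace length when given.
    """
    if factor < 1:
        raise InvalidArgumentError("factor must be >= 1")
    raw = sorted((b.start_bin * factor, b.end_bin * factor) for b in bursts)
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    if n_fine is not None:
        merged = [(s, min(e, n_fine)) for s, e in merged if s < n_fine]
    return merged


# ---------------------------------------------------------------------------
# I/O: HDF5 container with a delimited-text fallback


def write_trace(path, trace: BinnedTrace) -> None:
    """Write a trace to HDF5 (``.h5``/``.hdf5``) or tab-separated text.

    HDF5 layout: datasets ``/donor``, ``/acceptor`` (and
    ``/direct_acceptor`` when present) with root attributes
    ``bin_width_s`` and ``origin_time_s``. The text fallback has columns
    ``bin_index, donor, acceptor`` with the bin width in a header line.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("donor", data=trace.donor, compression="gzip")
            f.create_dataset("acceptor", data=trace.acceptor, compression="gzip")
            if trace.direct_acceptor is not None:
                f.create_dataset("direct_acceptor", data=trace.direct_acceptor, compression="gzip")
            f.attrs["bin_width_s"] = trace.bin_width
            f.attrs["origin_time_s"] = trace.origin_time
    else:
        with open(path, "w") as f:
            f.write(f"# bin_width_s={trace.bin_width!r} origin_time_s={trace.origin_time!r}\n")
            f.write("bin_index\tdonor\tacceptor\n")
            for i, (d, a) in enumerate(zip(trace.donor, trace.acceptor)):
                f.write(f"{i}\t{d}\t{a}\n")


def read_trace(path) -> BinnedTrace:
    """Read a trace written by :func:`write_trace`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            direct = f["direct_acceptor"][:] if "direct_acceptor" in f else None
            return BinnedTrace(
                bin_width=float(f.attrs["bin_width_s"]),
                donor=f["donor"][:],
                acceptor=f["acceptor"][:],
                direct_acceptor=direct,
                origin_time=float(f.attrs.get("origin_time_s", 0.0)),
            )
    with open(path) as f:
        header = f.readline()
    meta = dict(
        item.split("=") for item in header.lstrip("# ").split() if "=" in item
    )
    data = np.loadtxt(path, skiprows=2, dtype=np.int64)
    data = np.atleast_2d(data)
    return BinnedTrace(
        bin_width=float(meta["bin_width_s"]),
        donor=data[:, 1],
        acceptor=data[:, 2],
        origin_time=float(meta.get("origin_time_s", 0.0)),
    )


def bursts_to_table(bursts: Iterable[Burst]):
    """Burst list as a pandas DataFrame (start_bin, end_bin, donor_sum,
    acceptor_sum, e_app) suitable for delimited-text export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start_bin": b.start_bin,
                "end_bin": b.end_bin,
                "donor_sum": b.donor_sum,
                "acceptor_sum": b.acceptor_sum,
                "e_app": b.e_app,
            }
            for b in bursts
        ],
        columns=["start_bin", "end_bin", "donor_sum", "acceptor_sum", "e_app"],
    )
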