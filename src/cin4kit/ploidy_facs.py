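"""DNA-index estimation and ploidy calling from DNA-content histograms.

A propidium-iodide FACS histogram of nuclei shows a diploid G1 peak (the
reference, from stromal/normal and diploid tumor cells), its G2/M companion
at twice the channel, and — in aneuploid tumors — an extra G1 peak whose
position relative to the diploid G1 defines the DNA index (DI).  A tumor
with DI strictly greater than 1.10 is called aneuploid; a single G1 peak
means DI = 1.0 exactly (diploid).

Peak logic: moving-average smoothing, local maxima by prominence, and
exclusion of candidates lying within [1.90, 2.10] times an accepted G1 peak
(those are G2/M companions).  Near-tetraploid tumors (true DI around 2)
therefore fall in the exclusion window and are not evaluable — a documented
limitation of ratio-based DI calling without cell-cycle deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "DnaHistogram",
    "Peak",
    "PloidyCall",
    "detect_g1_peaks",
    "dna_index",
    "classify_ploidy",
    "call_ploidy",
    "ANEUPLOIDY_THRESHOLD",
    "G2M_WINDOW",
]

ANEUPLOIDY_THRESHOLD = 1.10
G2M_WINDOW = (1.90, 2.10)
MIN_EVENTS = 1000


@dataclass
class DnaHistogram:
    """Binned DNA-content distribution: channel (fluorescence) vs count."""

    channels: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channels.shape != self.counts.shape or self.channels.ndim != 1:
            raise ValueError("channels and counts must be 1-d arrays of equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(np.diff(self.channels) <= 0):
            raise ValueError("channels must be strictly increasing")

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class Peak:
    channel: float
    height: float
    prominence: float


@dataclass
class PloidyCall:
    g1_peaks: list
    g2m_peaks: list
    reference_g1_channel: float | None
    tumor_g1_channel: float | None
    dna_index: float | None
    call: str  # "diploid" | "aneuploid" | "unevaluable"
    threshold: float = ANEUPLOIDY_THRESHOLD
    flags: list = field(default_factory=list)


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window < 1:
        raise ValueError("smooth_window must be >= 1")
    if window % 2 == 0:
        window += 1  # keep the kernel centered
    kernel = np.ones(window) / window
    half = window // 2
    padded = np.pad(counts, half, mode="edge")  # no artificial edge dips
    return np.convolve(padded, kernel, mode="valid")


def detect_g1_peaks(
    hist: DnaHistogram,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.05,
    min_events: int = MIN_EVENTS,
) -> tuple[list[Peak], list[Peak]]:
    """Locate candidate G1 peaks, excluding G2/M companions.

    Returns ``(g1_peaks, g2m_peaks)`` sorted by channel.  Candidates whose
    channel falls within ``G2M_WINDOW`` times an already-accepted G1 peak
    are tagged G2/M.  Raises ``ValueError`` when the histogram carries fewer
    than ``min_events`` events (unusable acquisition).
    """
    if hist.total_events < min_events:
        raise ValueError(
            f"histogram has {hist.total_events} events; need >= {min_events}"
        )
    smoothed = _smooth(hist.counts, smooth_window)
    if smoothed.max() <= 0:
        return [], []
    idx, props = find_peaks(smoothed, prominence=min_prominence_frac * smoothed.max())
    order = np.argsort(hist.channels[idx])
    g1: list[Peak] = []
    g2m: list[Peak] = []
    for i in order:
        pk = Peak(
            channel=float(hist.channels[idx[i]]),
            height=float(smoothed[idx[i]]),
            prominence=float(props["prominences"][i]),
        )
        is_g2m = any(
            G2M_WINDOW[0] * g.channel <= pk.channel <= G2M_WINDOW[1] * g.channel
            for g in g1
        )
        (g2m if is_g2m else g1).append(pk)
    return g1, g2m


def dna_index(
    g1_peaks: list[Peak], reference_channel: float | None = None
) -> tuple[float, list[str]]:
    """DNA index = tumor G1 channel / reference (diploid) G1 channel.

    The reference defaults to the lowest-channel G1 peak (assumed to contain
    the diploid/stromal population); the tumor peak is the highest-prominence
    remaining G1 peak.  With exactly one G1 peak the tumor is diploid and
    DI = 1.0 exactly.  Returns ``(dna_index, flags)``.
    """
    if not g1_peaks:
        raise ValueError("need at least one G1 peak")
    if reference_channel is not None and reference_channel <= 0:
        raise ValueError("reference channel must be positive")
    flags: list[str] = []
    peaks = sorted(g1_peaks, key=lambda p: p.channel)
    if reference_channel is None:
        ref = peaks[0].channel
        others = peaks[1:]
    else:
        ref = float(reference_channel)
        others = [p for p in peaks if p.channel != ref]
    if not others:
        return 1.0, flags
    tumor = max(others, key=lambda p: p.prominence)
    if tumor.channel < ref:
        # tumor peak below the supplied reference: ambiguous hypo-diploid
        flags.append("hypodiploid-ambiguous")
        return float(ref / tumor.channel), flags
    return float(tumor.channel / ref), flags


def classify_ploidy(di: float, threshold: float = ANEUPLOIDY_THRESHOLD) -> str:
    """Aneuploid iff the DNA index strictly exceeds the threshold (1.10)."""
    if di < 1.0:
        raise ValueError("DNA index below 1.0 not supported (hypo-diploid)")
    return "aneuploid" if di > threshold else "diploid"


def call_ploidy(
    hist: DnaHistogram,
    smooth_window: int = 5,
    min_prominence_frac: float = 0.05,
    min_events: int = MIN_EVENTS,
    threshold: float = ANEUPLOIDY_THRESHOLD,
    reference_channel: float | None = None,
) -> PloidyCall:
    """Full pipeline on one histogram: peaks -> DI -> diploid/aneuploid call.

    Degenerate inputs (too few events, no detectable peak) yield an
    ``unevaluable`` call rather than an exception.
    """
    try:
        g1, g2m = detect_g1_peaks(hist, smooth_window, min_prominence_frac, min_events)
    except ValueError as exc:
        return PloidyCall(
            g1_peaks=[], g2m_peaks=[], reference_g1_channel=None,
            tumor_g1_channel=None, dna_index=None, call="unevaluable",
            threshold=threshold, flags=[str(exc)],
        )
    if not g1:
        return PloidyCall(
            g1_peaks=[], g2m_peaks=g2m, reference_g1_channel=None,
            tumor_g1_channel=None, dna_index=None, call="unevaluable",
            threshold=threshold, flags=["no G1 peak found"],
        )
    di, flags = dna_index(g1, reference_channel)
    ref = reference_channel if reference_channel is not None else min(
        p.channel for p in g1
    )
    tumor = None
    if di != 1.0:
        others = [p for p in g1 if p.channel != ref]
        if others:
            tumor = max(others, key=lambda p: p.prominence).channel
    return PloidyCall(
        g1_peaks=g1,
        g2m_peaks=g2m,
        reference_g1_channel=float(ref),
        tumor_g1_channel=tumor,
        dna_index=di,
        call=classify_ploidy(di, threshold),
        threshold=threshold,
        flags=flags,
    )
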