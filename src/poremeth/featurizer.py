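"""Fixed-length signal features for candidate modification sites.

A candidate site is an A (m6A mode) or C (m5C mode) at the centre of a
9-mer.  The pore senses ~5 nt at a time, so the five overlapping 5-mers
starting at offsets −4…0 from the centre all carry signal from the
candidate base.  Each 5-mer's variable-dwell sample list is summarised by
20 order-preserving segment medians, giving a 5 × 20 = 100 observed-signal
vector; the pore model provides a matching expected vector (each level
repeated 20×) and the per-read classifier consumes the observed vector
together with the elementwise absolute distance |observed − expected|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Sequence, Tuple

import numpy as np

from .signal_io import KMER_SIZE, PoreModel, ReadTrack

N_SEGMENTS = 20
N_KMERS = KMER_SIZE  # five overlapping 5-mers span the 9-mer
FEATURE_LEN = N_KMERS * N_SEGMENTS  # 100

CENTER_BASE = {"m6A": "A", "m5C": "C"}


@dataclass(frozen=True)
class SignalWindow:
    """One read's signal for the five 5-mers of a 9-mer centred on A or C."""

    read_id: str
    contig: str
    center_pos: int
    nine_mer: str
    fivemer_samples: Tuple[Tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.fivemer_samples) != N_KMERS:
            raise ValueError("a window needs exactly five 5-mer sample lists")
        if any(len(s) == 0 for s in self.fivemer_samples):
            raise ValueError("empty 5-mer sample list in window")


@dataclass(frozen=True)
class FeatureVector:
    observed: np.ndarray  # (100,)
    expected: np.ndarray  # (100,) piecewise constant in blocks of 20
    distance: np.ndarray  # (100,) |observed - expected|


def segment_medians(samples: Sequence[float]) -> np.ndarray:
    """Summarise an ordered sample list as 20 medians.

    With ≥20 samples the list is split into 20 contiguous, order-preserving
    subsets of near-equal size (boundaries at ``floor(i·n/20)``) and each
    subset is reduced to its median.  With <20 samples the original values
    are kept and padded to length 20 with copies of their overall median.
    Exactly 20 samples pass through unchanged.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("segment_medians: empty sample list")
    if n == N_SEGMENTS:
        return x.copy()
    if n < N_SEGMENTS:
        pad = np.full(N_SEGMENTS - n, np.median(x))
        return np.concatenate([x, pad])
    bounds = (np.arange(N_SEGMENTS + 1) * n) // N_SEGMENTS
    return np.array(
        [np.median(x[bounds[i] : bounds[i + 1]]) for i in range(N_SEGMENTS)]
    )


def extract_windows(track: ReadTrack, mode: str) -> Iterator[SignalWindow]:
    """Yield one window per candidate centre fully covered by the read.

    A centre at coordinate ``p`` requires signal for the five 5-mers
    starting at ``p−4 … p``.  Centres near read ends that lack any of the
    five are skipped.  Runs of the centre base (AA, AAA, …) each yield
    their own window.
    """
    base = CENTER_BASE[mode]
    covered = track.kmers
    for start in sorted(covered):
        center = start + KMER_SIZE - 1  # centre base = last base of leftmost 5-mer
        starts = [center - (KMER_SIZE - 1) + i for i in range(N_KMERS)]
        if any(s not in covered for s in starts):
            continue
        # centre base is at offset 4 of the leftmost 5-mer
        if covered[starts[0]][KMER_SIZE - 1] != base:
            continue
        nine_mer = covered[starts[0]] + covered[starts[-1]][1:]
        yield SignalWindow(
            read_id=track.read_id,
            contig=track.contig,
            center_pos=center,
            nine_mer=nine_mer,
            fivemer_samples=tuple(track.samples[s] for s in starts),
        )


def build_features(window: SignalWindow, model: PoreModel) -> FeatureVector:
    """Map a window to (observed, expected, distance) length-100 vectors."""
    observed = np.concatenate(
        [segment_medians(s) for s in window.fivemer_samples]
    )
    starts = range(N_KMERS)
    kmers = [window.nine_mer[i : i + KMER_SIZE] for i in starts]
    expected = np.repeat([model.level(k) for k in kmers], N_SEGMENTS).astype(float)
    return FeatureVector(
        observed=observed,
        expected=expected,
        distance=np.abs(observed - expected),
    )


def feature_matrix(
    windows: Sequence[SignalWindow], model: PoreModel
) -> Tuple[np.ndarray, List[Tuple[str, str, int]]]:
    """Stack windows into an (n, 2, 100) array of (observed, distance) channels.

    Returns the array and the parallel list of (read_id, contig, center_pos)
    keys in the same order.
    """
    feats = np.empty((len(windows), 2, FEATURE_LEN), dtype=float)
    keys = []
    for i, w in enumerate(windows):
        fv = build_features(w, model)
        feats[i, 0] = fv.observed
        feats[i, 1] = fv.distance
        keys.append((w.read_id, w.contig, w.center_pos))
    return feats, keys
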