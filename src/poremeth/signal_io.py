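"""Reading and writing of pore-model tables and signal-to-reference event tables.

Direct-RNA nanopore reads are sequenced 3′→5′, so the raw current samples
that an event aligner assigns to each reference 5-mer arrive in 3′→5′
order even though the 5-mer string itself is reported 5′→3′.  Assembling a
per-read track therefore reverses every per-5-mer sample list before any
downstream use, so that all signal vectors in this package are 5′→3′.

The on-disk dialect is the tab-separated eventalign table (one row per
event: contig, position, reference_kmer, read_name, samples) plus a
two-column pore-model table mapping each 5-mer to its expected unmodified
current level in picoamperes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, TextIO, Tuple, Union

log = logging.getLogger(__name__)

KMER_SIZE = 5
_ALPHABET = frozenset("ACGT")

#: number of decimals used when serializing current samples; round-trips are
#: exact at this precision.
FLOAT_DECIMALS = 6

EVENTALIGN_COLUMNS = ("contig", "position", "reference_kmer", "read_name", "samples")


class FormatError(ValueError):
    """Malformed pore-model or eventalign input."""


class DataError(ValueError):
    """Structurally valid input with inconsistent content."""


def _check_kmer(kmer: str) -> str:
    if len(kmer) != KMER_SIZE or not _ALPHABET.issuperset(kmer):
        raise FormatError(f"not a valid {KMER_SIZE}-mer over ACGT: {kmer!r}")
    return kmer


@dataclass(frozen=True)
class PoreModel:
    """Expected unmodified current level (pA) per 5-mer."""

    entries: Dict[str, float]

    def level(self, kmer: str) -> float:
        try:
            return self.entries[kmer]
        except KeyError:
            raise KeyError(f"5-mer {kmer!r} absent from pore model") from None

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SignalEvent:
    """One eventalign row: raw samples assigned to one reference 5-mer.

    ``samples`` are in file order, i.e. 3′→5′ as emitted by the event
    aligner; they are flipped only during track assembly.
    """

    read_id: str
    contig: str
    position: int
    kmer: str
    samples: Tuple[float, ...]

    def __post_init__(self):
        if not self.samples:
            raise FormatError("event with empty sample list")


@dataclass
class ReadTrack:
    """Per-read 5′→3′ signal, keyed by 5-mer start position."""

    read_id: str
    contig: str
    samples: Dict[int, Tuple[float, ...]] = field(default_factory=dict)
    kmers: Dict[int, str] = field(default_factory=dict)

    def positions(self) -> List[int]:
        return sorted(self.samples)


def load_pore_model(path) -> PoreModel:
    """Load a tab-separated (kmer, level_mean, [extras]) table.

    Duplicate 5-mers, non-ACGT 5-mers, and empty files are format errors.
    """
    entries: Dict[str, float] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("kmer", "k_mer", "model_kmer"):
                continue  # optional header
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            kmer = _check_kmer(fields[0])
            if kmer in entries:
                raise FormatError(f"{path}:{lineno}: duplicate 5-mer {kmer}")
            try:
                entries[kmer] = float(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad level {fields[1]!r}") from exc
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: empty pore-model file")
    return PoreModel(entries)


def write_pore_model(model: PoreModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\n")
        for kmer in sorted(model.entries):
            fh.write(f"{kmer}\t{model.entries[kmer]:.{FLOAT_DECIMALS}f}\n")


def read_eventalign(path) -> Iterator[SignalEvent]:
    """Stream events from an eventalign TSV in file order.

    Sample lists are parsed as floats in file order and are *not* flipped
    here.  A row whose samples field is missing or unparsable raises a
    :class:`FormatError` naming the row.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {name: header.index(name) for name in EVENTALIGN_COLUMNS}
        except ValueError as exc:
            raise FormatError(f"{path}: missing required column: {exc}") from exc
        for rowno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= max(idx.values()):
                raise FormatError(f"{path}:{rowno}: truncated row")
            raw = fields[idx["samples"]]
            if not raw:
                raise FormatError(f"{path}:{rowno}: empty samples field")
            try:
                samples = tuple(float(v) for v in raw.split(","))
                position = int(fields[idx["position"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{rowno}: unparsable value ({exc})") from exc
            yield SignalEvent(
                read_id=fields[idx["read_name"]],
                contig=fields[idx["contig"]],
                position=position,
                kmer=fields[idx["reference_kmer"]],
                samples=samples,
            )


def assemble_read_tracks(events: Iterable[SignalEvent]) -> Iterator[ReadTrack]:
    """Group events by read and flip each per-position sample list to 5′→3′.

    Events for one read must be contiguous in the stream (as they are in
    eventalign output).  Multiple events for the same (read, position) —
    re-segmentation artifacts — are concatenated in row order before the
    flip, preserving every raw sample.  Rows whose 5-mer is not a valid
    ACGT 5-mer are dropped with a logged count; conflicting 5-mer strings
    at one position are a :class:`DataError`.
    """
    current_key: Union[Tuple[str, str], None] = None
    pending: Dict[int, List[float]] = {}
    kmers: Dict[int, str] = {}
    n_dropped = 0

    def _finish() -> ReadTrack:
        read_id, contig = current_key  # type: ignore[misc]
        track = ReadTrack(read_id=read_id, contig=contig)
        for pos, chunk in pending.items():
            track.samples[pos] = tuple(reversed(chunk))
            track.kmers[pos] = kmers[pos]
        return track

    for ev in events:
        if len(ev.kmer) != KMER_SIZE or not _ALPHABET.issuperset(ev.kmer):
            n_dropped += 1
            continue
        key = (ev.read_id, ev.contig)
        if key != current_key:
            if current_key is not None:
                yield _finish()
            current_key, pending, kmers = key, {}, {}
        if ev.position in kmers and kmers[ev.position] != ev.kmer:
            raise DataError(
                f"read {ev.read_id}: conflicting 5-mers at position "
                f"{ev.position}: {kmers[ev.position]} vs {ev.kmer}"
            )
        pending.setdefault(ev.position, []).extend(ev.samples)
        kmers.setdefault(ev.position, ev.kmer)
    if current_key is not None:
        yield _finish()
    if n_dropped:
        log.info("dropped %d events with non-ACGT reference 5-mers", n_dropped)


def _format_samples(samples: Sequence[float]) -> str:
    return ",".join(f"{v:.{FLOAT_DECIMALS}f}" for v in samples)


def write_eventalign(events: Iterable[SignalEvent], path_or_fh) -> None:
    """Write events in the eventalign dialect (samples stay in event order).

    ``read_eventalign(write_eventalign(x))`` reproduces ``x`` up to
    :data:`FLOAT_DECIMALS`-decimal float formatting, and a second
    write of the re-read stream is byte-identical.
    """

    def _write(fh: TextIO) -> None:
        fh.write("\t".join(EVENTALIGN_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                f"{ev.contig}\t{ev.position}\t{ev.kmer}\t{ev.read_id}\t"
                f"{_format_samples(ev.samples)}\n"
            )

    if hasattr(path_or_fh, "write"):
        _write(path_or_fh)
    else:
        with open(path_or_fh, "w") as fh:
            _write(fh)
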