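"""Coverage-track normalization and threshold-based peak calling.

The caller reproduces the run/merge/filter logic of browser-style
"thresholding": bins at or above a signal threshold are enriched, maximal
runs of enriched bins are candidate regions, nearby regions are merged
(gap <= max_gap), and merged regions shorter than min_run are dropped.
Downstream operations classify interphase vs mitotic peak sets, count
GAGAG-type motifs, annotate peaks against TSS/enhancer sets, and build
metagene matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import BedRecord, CoverageTrack, GenomeIntervals

__all__ = [
    "Peak",
    "PeakSet",
    "PeakClassification",
    "rescale_rpm",
    "subtract_input",
    "mean_replicates",
    "call_peaks",
    "classify_peaks",
    "count_motif",
    "annotate_peaks",
    "metagene_matrix",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based half-open, on bin boundaries
    end: int
    max_value: float
    n_enriched_bins: int

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)
    threshold: float = float("nan")
    min_run: int = 0
    max_gap: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def total_bp(self) -> int:
        return sum(len(p) for p in self.peaks)

    def to_intervals(self) -> GenomeIntervals:
        return GenomeIntervals(
            [
                BedRecord(p.chrom, p.start, p.end, f"{self.label or 'peak'}_{i}",
                          p.max_value, ".")
                for i, p in enumerate(self.peaks)
            ]
        )

    @classmethod
    def from_intervals(cls, intervals: GenomeIntervals, label: str = "") -> "PeakSet":
        return cls(
            peaks=[
                Peak(r.chrom, r.start, r.end, r.score, 0) for r in intervals
            ],
            label=label,
        )


@dataclass
class PeakClassification:
    interphase_only: PeakSet
    mitotically_retained: PeakSet
    mitosis_only: PeakSet

    def counts(self) -> dict[str, int]:
        return {
            "interphase_only": len(self.interphase_only),
            "mitotically_retained": len(self.mitotically_retained),
            "mitosis_only": len(self.mitosis_only),
        }


# ---------------------------------------------------------------------------
# Track arithmetic


def rescale_rpm(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale enrichment values to reads per million (x 1e6/library_size)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    f = 1e6 / library_size
    return CoverageTrack(
        bin_size=track.bin_size,
        values={c: v * f for c, v in track.values.items()},
        origins=dict(track.origins),
    )


def subtract_input(
    chip: CoverageTrack, input_track: CoverageTrack, floor_at_zero: bool = True
) -> CoverageTrack:
    """Per-bin ChIP minus Input; negatives clamped to 0 unless disabled."""
    if chip.bin_size != input_track.bin_size:
        raise ValueError(
            f"bin_size mismatch: {chip.bin_size} vs {input_track.bin_size}"
        )
    out: dict[str, np.ndarray] = {}
    for chrom, v in chip.values.items():
        if chrom not in input_track.values:
            raise ValueError(f"chromosome {chrom} absent from input track")
        diff = v - input_track.values[chrom]
        out[chrom] = np.maximum(diff, 0.0) if floor_at_zero else diff
    return CoverageTrack(chip.bin_size, out, dict(chip.origins))


def mean_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Arithmetic mean of replicate tracks on an identical bin grid."""
    if not tracks:
        raise ValueError("need at least one track")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_grid(t):
            raise ValueError("replicate tracks are not on the same grid")
    out = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values
    }
    return CoverageTrack(first.bin_size, out, dict(first.origins))


# ---------------------------------------------------------------------------
# Peak calling


def call_peaks(
    track: CoverageTrack,
    threshold: float,
    min_run: int = 50,
    max_gap: int = 200,
    label: str = "",
) -> PeakSet:
    """Threshold peak caller on binned coverage.

    1. bins with value >= threshold are enriched;
    2. maximal runs of consecutive enriched bins form candidate regions;
    3. successive regions on one chromosome separated by a gap <= max_gap
       bp are merged (the gap bins stay unenriched but join the peak span);
    4. merged regions with span >= min_run bp are returned, with
       boundaries on enriched-bin edges.
    """
    if min_run < 0 or max_gap < 0:
        raise ValueError("min_run and max_gap must be nonnegative")
    bs = track.bin_size
    peaks: list[Peak] = []
    for chrom in track.chroms:
        v = track.values[chrom]
        origin = track.origins[chrom]
        enriched = v >= threshold
        if not enriched.any():
            continue
        # maximal runs of consecutive enriched bins, as (start_bin, end_bin)
        padded = np.concatenate(([False], enriched, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        # merge runs whose inter-run gap (bp) <= max_gap
        merged: list[list[int]] = [[starts[0], ends[0]]]
        for s, e in zip(starts[1:], ends[1:]):
            gap_bp = (s - merged[-1][1]) * bs
            if gap_bp <= max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            span_bp = (e - s) * bs
            if span_bp < min_run:
                continue
            seg = v[s:e]
            mask = enriched[s:e]
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=origin + s * bs,
                    end=origin + e * bs,
                    max_value=float(seg[mask].max()),
                    n_enriched_bins=int(mask.sum()),
                )
            )
    return PeakSet(
        peaks=peaks, threshold=threshold, min_run=min_run, max_gap=max_gap,
        label=label,
    )


# ---------------------------------------------------------------------------
# Interphase vs mitosis classification


def _overlaps_any(peak: Peak, others: PeakSet) -> bool:
    # peaks are few enough per call that a per-chromosome scan suffices
    return any(peak.overlaps(o) for o in others if o.chrom == peak.chrom)


def classify_peaks(interphase: PeakSet, mitotic: PeakSet) -> PeakClassification:
    """Split peaks by >=1 bp overlap between the interphase and mitotic sets.

    Interphase peaks overlapping any mitotic peak are *mitotically
    retained*; the rest are *interphase only*.  Mitotic peaks with no
    interphase overlap are *mitosis only*.
    """
    retained, inter_only = [], []
    for p in interphase:
        (retained if _overlaps_any(p, mitotic) else inter_only).append(p)
    mito_only = [p for p in mitotic if not _overlaps_any(p, interphase)]
    return PeakClassification(
        interphase_only=PeakSet(inter_only, label="interphase_only"),
        mitotically_retained=PeakSet(retained, label="mitotically_retained"),
        mitosis_only=PeakSet(mito_only, label="mitosis_only"),
    )


# ---------------------------------------------------------------------------
# Motif counting

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _count_occurrences(seq: str, motif: str, overlapping: bool) -> int:
    if not motif:
        raise ValueError("empty motif")
    count = start = 0
    step = 1 if overlapping else len(motif)
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + step


def count_motif(
    peaks: PeakSet,
    genome: dict[str, str],
    motif: str = "GAGAG",
    both_strands: bool = True,
    overlapping: bool = True,
) -> pd.DataFrame:
    """Count motif occurrences inside each peak's sequence.

    Overlapping occurrences are counted by default (GAGAG arrays are
    self-overlapping); with ``both_strands`` the reverse-complement
    occurrences are added.  Returns a per-peak table with a ``count``
    column; the mean is ``df["count"].mean()``.
    """
    motif = motif.upper()
    rc = reverse_complement(motif)
    rows = []
    for p in peaks:
        if p.chrom not in genome:
            raise KeyError(f"chromosome {p.chrom} not in genome")
        seq = genome[p.chrom]
        if p.end > len(seq):
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} exceeds chromosome length "
                f"{len(seq)}"
            )
        sub = seq[p.start : p.end].upper()
        n = _count_occurrences(sub, motif, overlapping)
        if both_strands and rc != motif:
            n += _count_occurrences(sub, rc, overlapping)
        rows.append((p.chrom, p.start, p.end, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# Annotation


def annotate_peaks(
    peaks: PeakSet,
    tss: GenomeIntervals,
    enhancers: GenomeIntervals,
    tss_flank: int = 100,
) -> pd.DataFrame:
    """Label peaks promoter / enhancer / other by >=1 bp interval overlap.

    A peak overlapping the window ``[tss - tss_flank, tss + tss_flank)``
    around any TSS is a promoter; otherwise a peak overlapping any
    enhancer interval is an enhancer; otherwise other.  Promoter takes
    precedence.
    """
    tss_windows = [
        (r.chrom, max(0, r.start - tss_flank), r.start + tss_flank) for r in tss
    ]
    enh = [(r.chrom, r.start, r.end) for r in enhancers]

    def hits(p: Peak, windows) -> bool:
        return any(
            c == p.chrom and p.start < e and s < p.end for c, s, e in windows
        )

    rows = []
    for p in peaks:
        if hits(p, tss_windows):
            label = "promoter"
        elif hits(p, enh):
            label = "enhancer"
        else:
            label = "other"
        rows.append((p.chrom, p.start, p.end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return df


def annotation_proportions(labels: pd.DataFrame) -> pd.Series:
    props = labels["label"].value_counts(normalize=True)
    return props.reindex(["promoter", "enhancer", "other"], fill_value=0.0)


# ---------------------------------------------------------------------------
# Metagene matrices


def metagene_matrix(
    track: CoverageTrack, peaks: PeakSet, flank: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Signal matrix (peaks x bins) centered on peak midpoints, +/- flank bp.

    Out-of-bounds positions are filled with 0.  Returns the matrix and
    the mean (column-wise) profile.
    """
    bs = track.bin_size
    ncols = (2 * flank) // bs
    mat = np.zeros((len(peaks), ncols))
    for i, p in enumerate(peaks):
        center = (p.start + p.end) // 2
        first_bin = (center - flank - track.origins[p.chrom]) // bs
        v = track.values.get(p.chrom)
        if v is None:
            continue
        for j in range(ncols):
            b = first_bin + j
            if 0 <= b < len(v):
                mat[i, j] = v[b]
    return mat, mat.mean(axis=0) if len(peaks) else np.zeros(ncols)
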