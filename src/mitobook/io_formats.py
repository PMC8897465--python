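"""Readers and writers for the text formats the pipeline touches.

Genomic coordinates are 0-based half-open everywhere inside the package;
only the wiggle layer converts to/from the 1-based fixedStep declarations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

try:  # Python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "BedRecord",
    "GenomeIntervals",
    "CoverageTrack",
    "FormatError",
    "ConfigError",
    "read_wiggle",
    "write_wiggle",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "load_config",
    "DEFAULT_CONFIG",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


class ConfigError(ValueError):
    """Raised when a configuration file is malformed or ill-typed."""


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative start: {self}")
        if self.end <= self.start:
            raise FormatError(f"end <= start: {self}")
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"bad strand {self.strand!r}")


@dataclass
class GenomeIntervals:
    """A set of genomic intervals (BED3–BED6), 0-based half-open."""

    records: list[BedRecord] = field(default_factory=list)

    def sorted(self) -> "GenomeIntervals":
        return GenomeIntervals(
            sorted(self.records, key=lambda r: (r.chrom, r.start, r.end))
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class CoverageTrack:
    """Fixed-step binned coverage: one value per ``bin_size``-bp bin.

    ``origins[chrom]`` is the 0-based genomic coordinate of the left edge
    of the first bin; bin ``i`` covers
    ``[origin + i*bin_size, origin + (i+1)*bin_size)``.
    """

    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    origins: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, v in self.values.items():
            self.values[chrom] = np.asarray(v, dtype=float)
            self.origins.setdefault(chrom, 0)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.values) == set(other.values)
            and all(self.origins[c] == other.origins[c] for c in self.values)
            and all(
                self.values[c].shape == other.values[c].shape for c in self.values
            )
        )


# ---------------------------------------------------------------------------
# fixedStep wiggle


def _parse_declaration(line: str, lineno: int) -> dict[str, str]:
    fields = {}
    for tok in line.split()[1:]:
        if "=" not in tok:
            raise FormatError(f"line {lineno}: bad declaration token {tok!r}")
        k, v = tok.split("=", 1)
        fields[k] = v
    return fields


def read_wiggle(path: str | Path) -> CoverageTrack:
    """Read a fixedStep wiggle file into a :class:`CoverageTrack`.

    The declaration's 1-based ``start`` becomes a 0-based ``origin``;
    ``step`` becomes the track bin size.  ``span``, when present, must
    equal ``step`` (bins must tile).  variableStep is rejected.
    """
    path = Path(path)
    bin_size: int | None = None
    values: dict[str, list[float]] = {}
    origins: dict[str, int] = {}
    current: list[float] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("variableStep"):
                raise FormatError(
                    f"line {lineno}: variableStep wiggle is not supported "
                    "(fixed 50-bp-style bins expected)"
                )
            if line.startswith("fixedStep"):
                decl = _parse_declaration(line, lineno)
                try:
                    chrom = decl["chrom"]
                    start = int(decl["start"])
                    step = int(decl["step"])
                except KeyError as e:
                    raise FormatError(f"line {lineno}: missing {e} in declaration")
                if "span" in decl and int(decl["span"]) != step:
                    raise FormatError(
                        f"line {lineno}: span {decl['span']} != step {step}; "
                        "bins must tile"
                    )
                if bin_size is None:
                    bin_size = step
                elif step != bin_size:
                    raise FormatError(
                        f"line {lineno}: mixed step sizes ({step} vs {bin_size})"
                    )
                if chrom in values:
                    raise FormatError(
                        f"line {lineno}: chromosome {chrom} declared twice"
                    )
                values[chrom] = current = []
                origins[chrom] = start - 1  # 1-based -> 0-based
                continue
            if current is None:
                raise FormatError(f"line {lineno}: data before any declaration")
            current.append(float(line))
    if bin_size is None:
        raise FormatError(f"{path}: no fixedStep declaration found")
    return CoverageTrack(
        bin_size=bin_size,
        values={c: np.array(v, dtype=float) for c, v in values.items()},
        origins=origins,
    )


def write_wiggle(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as fixedStep wiggle (1-based starts), chroms sorted."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            origin = track.origins[chrom]
            fh.write(
                f"fixedStep chrom={chrom} start={origin + 1} "
                f"step={track.bin_size} span={track.bin_size}\n"
            )
            for v in track.values[chrom]:
                fh.write(f"{v:.6g}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> GenomeIntervals:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED fields")
            try:
                rec = BedRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            except FormatError as e:
                raise FormatError(f"line {lineno}: {e}") from None
            records.append(rec)
    return GenomeIntervals(records)


def write_bed(intervals: GenomeIntervals, path: str | Path, bed6: bool = True) -> None:
    with open(path, "w") as fh:
        for r in intervals:
            if bed6:
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
                )
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{id: uppercase sequence}``; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Run configuration

DEFAULT_CONFIG: dict[str, dict] = {
    "peaks": {
        "threshold": 100.0,  # GAF ChIP default; 22 fits the acetylation track
        "min_run": 50,
        "max_gap": 200,
        "floor_at_zero": True,
        "tss_flank": 100,
        "motif": "GAGAG",
    },
    "frap": {
        "fit_frames": 1100,
        "n_prebleach": 10,
        "frame_dt": 0.053,
        "beam_radius_um": 0.83,
    },
    "fcs": {
        "n_species": 2,
        "s_param": 5.0,
        "d_cal": 414.0,
        "triplet_tau_max": 1e-5,
    },
    "memory": {
        "n_states": 4,
        "t0_mode": "pooled",
    },
    "spots": {
        "log_sigma": 1.0,
        "thr": 3.0,
        "max_dist_um": 1.0,
    },
}


def load_config(path: str | Path | None) -> dict[str, dict]:
    """Load a TOML run configuration, filling defaults for missing keys.

    Unknown keys produce a warning but are kept; a known key whose value
    has the wrong type raises :class:`ConfigError`.
    """
    config = {sec: dict(vals) for sec, vals in DEFAULT_CONFIG.items()}
    if path is None:
        return config
    try:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"malformed config {path}: {e}") from None
    for section, vals in user.items():
        if section not in config:
            warnings.warn(f"unknown config section [{section}]", stacklevel=2)
            config[section] = dict(vals)
            continue
        if not isinstance(vals, dict):
            raise ConfigError(f"[{section}] must be a table")
        for key, value in vals.items():
            if key in config[section]:
                default = config[section][key]
                if isinstance(default, bool):
                    ok = isinstance(value, bool)
                elif isinstance(default, (int, float)):
                    ok = isinstance(value, (int, float)) and not isinstance(
                        value, bool
                    )
                else:
                    ok = isinstance(value, type(default))
                if not ok:
                    raise ConfigError(
                        f"{section}.{key}: expected {type(default).__name__}, "
                        f"got {type(value).__name__}"
                    )
            else:
                warnings.warn(f"unknown config key {section}.{key}", stacklevel=2)
            config[section][key] = value
    return config
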