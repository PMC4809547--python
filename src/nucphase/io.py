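"""Readers and writers for the interval, fragment and expression-table formats
the pipeline touches.

All genomic coordinates are 0-based half-open (the BED convention): ``start``
is inclusive, ``end`` exclusive, so interval length is ``end - start``.
Supported formats:

* BED6 / ENCODE narrowPeak for binding-site intervals,
* BEDPE (columns 1-6) or BED3 for paired-end fragments,
* a four-column tab-delimited table for differential-expression results
  (``gene_id  fold_change  p_value  q_value``),
* a two-column TSV dialect for metaprofiles with a comment header carrying
  the normalization constants.

SAM/BAM is deliberately out of scope: fragments are accepted as pre-extracted
intervals (``samtools`` + ``bedtools bamtobed -bedpe`` produce the BEDPE
input from a name-sorted BAM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SiteRecord",
    "FragmentRecord",
    "GeneRecord",
    "ParseError",
    "read_sites",
    "write_sites",
    "read_fragments",
    "write_fragments",
    "read_de_table",
    "write_de_table",
    "write_profile",
    "read_profile",
]


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


@dataclass(frozen=True)
class SiteRecord:
    """A transcription-factor binding-site interval.

    ``summit_offset`` is the narrowPeak point-source offset from ``start``
    (column 10); ``None`` means absent (a value of -1 in the file is mapped
    to ``None``).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    summit_offset: int | None = None
    score: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.end - self.start})"
            )

    @property
    def center(self) -> int:
        """Anchor point: summit if recorded, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced paired-end fragment as a genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Dyad proxy: start + floor(length / 2)."""
        return self.start + (self.end - self.start) // 2


@dataclass(frozen=True)
class GeneRecord:
    """One row of a differential-expression table (linear fold change)."""

    gene_id: str
    fold_change: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        for label, v in (("p_value", self.p_value), ("q_value", self.q_value)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} outside [0, 1]: {v}")


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_sites(path: str | Path, format: str = "bed6") -> list[SiteRecord]:
    """Read binding-site intervals from a BED6 or ENCODE narrowPeak file.

    Records preserve file order. A narrowPeak column-10 value of -1 maps to
    ``summit_offset=None``.
    """
    fmt = format.lower()
    if fmt not in {"bed6", "narrowpeak"}:
        raise ValueError(f"unknown site format {format!r}")
    min_cols = 6 if fmt == "bed6" else 10
    out: list[SiteRecord] = []
    for lineno, cols in _data_lines(path):
        if len(cols) < min_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected >= {min_cols} columns, got {len(cols)}"
            )
        try:
            start, end = int(cols[1]), int(cols[2])
            score = float(cols[4]) if cols[4] not in {".", ""} else None
            summit = None
            if fmt == "narrowpeak":
                raw_summit = int(cols[9])
                summit = None if raw_summit < 0 else raw_summit
            rec = SiteRecord(
                chrom=cols[0],
                start=start,
                end=end,
                strand=cols[5] if cols[5] else ".",
                summit_offset=summit,
                score=score,
                name=cols[3],
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        out.append(rec)
    return out


def write_sites(
    sites: Sequence[SiteRecord], path: str | Path, format: str = "bed6"
) -> None:
    """Write sites as BED6 or narrowPeak (summit -1 when absent)."""
    fmt = format.lower()
    if fmt not in {"bed6", "narrowpeak"}:
        raise ValueError(f"unknown site format {format!r}")
    with open(path, "w") as fh:
        for s in sites:
            score = "." if s.score is None else f"{s.score:g}"
            cols = [s.chrom, str(s.start), str(s.end), s.name, score, s.strand]
            if fmt == "narrowpeak":
                summit = -1 if s.summit_offset is None else s.summit_offset
                cols += ["0", "-1", "-1", str(summit)]
            fh.write("\t".join(cols) + "\n")


def read_fragments(
    path: str | Path, format: str = "bedpe", max_length: int = 500
) -> tuple[list[FragmentRecord], int]:
    """Read paired-end fragments, returning ``(kept, n_dropped)``.

    BEDPE mates are merged to their outer span
    ``[min(start1, start2), max(end1, end2))``. Fragments longer than
    ``max_length`` and pairs with mates on different chromosomes are dropped
    and counted, mirroring the aligner-side fragment-length cap applied to
    the sequencing data (500 bp for nucleosomal, 1500 bp for ChIP fragments).
    """
    fmt = format.lower()
    if fmt not in {"bedpe", "bed3"}:
        raise ValueError(f"unknown fragment format {format!r}")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    kept: list[FragmentRecord] = []
    dropped = 0
    for lineno, cols in _data_lines(path):
        try:
            if fmt == "bed3":
                if len(cols) < 3:
                    raise ParseError("expected >= 3 columns")
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            else:
                if len(cols) < 6:
                    raise ParseError("expected >= 6 columns")
                c1, s1, e1 = cols[0], int(cols[1]), int(cols[2])
                c2, s2, e2 = cols[3], int(cols[4]), int(cols[5])
                if c1 != c2:
                    dropped += 1
                    continue
                chrom, start, end = c1, min(s1, s2), max(e1, e2)
            rec = FragmentRecord(chrom, start, end)
        except (ValueError, ParseError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        if rec.length > max_length:
            dropped += 1
        else:
            kept.append(rec)
    return kept, dropped


def write_fragments(
    fragments: Sequence[FragmentRecord], path: str | Path, read_length: int = 50
) -> None:
    """Write fragments as BEDPE, splitting each interval into two synthetic
    mates of ``read_length`` bp at the fragment's outer ends (shorter if the
    fragment itself is shorter). The outer span round-trips exactly through
    :func:`read_fragments`.
    """
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            r = min(read_length, f.length)
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        str(f.start),
                        str(f.start + r),
                        f.chrom,
                        str(f.end - r),
                        str(f.end),
                        f"frag{i}",
                        "0",
                        "+",
                        "-",
                    ]
                )
                + "\n"
            )


_DE_COLUMNS = ("gene_id", "fold_change", "p_value", "q_value")


def read_de_table(path: str | Path) -> list[GeneRecord]:
    """Read a differential-expression table.

    The header row must name the columns ``gene_id``, ``fold_change``,
    ``p_value`` and ``q_value`` (any order, extra columns ignored).
    Duplicate gene ids keep the first occurrence with a warning.
    """
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        try:
            idx = {c: header.index(c) for c in _DE_COLUMNS}
        except ValueError as exc:
            raise ParseError(
                f"{path}: header must contain columns {_DE_COLUMNS}, got {header}"
            ) from exc
        seen: set[str] = set()
        out: list[GeneRecord] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            try:
                rec = GeneRecord(
                    gene_id=cols[idx["gene_id"]],
                    fold_change=float(cols[idx["fold_change"]]),
                    p_value=float(cols[idx["p_value"]]),
                    q_value=float(cols[idx["q_value"]]),
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if rec.gene_id in seen:
                warnings.warn(
                    f"{path}: duplicate gene id {rec.gene_id!r} at line {lineno}; "
                    "keeping first occurrence",
                    stacklevel=2,
                )
                continue
            seen.add(rec.gene_id)
            out.append(rec)
    return out


def write_de_table(records: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.fold_change:.10g}\t{r.p_value:.10g}\t{r.q_value:.10g}\n"
            )


def write_profile(profile, path: str | Path) -> None:
    """Write a :class:`~nucphase.profile.DyadProfile` as two-column TSV.

    The comment header records the normalization constants so the file
    round-trips through :func:`read_profile` to 1e-9.
    """
    offsets = profile.offsets
    if len(offsets) != 2 * profile.half_window + 1:
        raise ValueError("profile positions are not contiguous over the window")
    with open(path, "w") as fh:
        fh.write(
            f"# nsites={profile.n_sites} total_fragments={profile.total_fragments}\n"
        )
        fh.write(
            f"# half_window={profile.half_window} smoothing_bp={profile.smoothing_bp} "
            f"rescaled_mean={profile.rescaled_mean:.10g}\n"
        )
        for o, v in zip(offsets, profile.values):
            fh.write(f"{o}\t{v:.12g}\n")


def read_profile(path: str | Path):
    """Read a profile TSV written by :func:`write_profile`."""
    import numpy as np

    from .profile import DyadProfile

    meta: dict[str, str] = {}
    offsets: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            cols = line.split("\t")
            try:
                offsets.append(int(cols[0]))
                values.append(float(cols[1]))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if not offsets:
        raise ParseError(f"{path}: empty profile")
    half_window = (len(offsets) - 1) // 2
    expected = list(range(-half_window, half_window + 1))
    if offsets != expected:
        raise ParseError(f"{path}: offsets are not contiguous and centered")
    return DyadProfile(
        half_window=half_window,
        values=np.asarray(values, dtype=float),
        n_sites=int(meta.get("nsites", 1)),
        total_fragments=int(meta.get("total_fragments", len(offsets))),
        smoothing_bp=int(meta.get("smoothing_bp", 0)),
        rescaled_mean=float(meta.get("rescaled_mean", 1.0)),
    )
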